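"""Equivariance and mechanics of the graph denoiser."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fdcdiff import chem_data as cd
from fdcdiff.egnn_denoiser import (
    DenoiserConfig,
    EGNNDenoiser,
    GraphBatch,
    INPUT_DIM,
    build_graph_batch,
    predict_noise,
    rbf_expand,
)
from fdcdiff.errors import ContextError, ParameterError
from fdcdiff.generator import ConditioningContext
from fdcdiff.nnet import Tensor


@pytest.fixture(scope="module")
def small_model():
    return EGNNDenoiser(
        DenoiserConfig(n_layers=3, hidden_dim=24, K=8), seed=0
    ).train(False)


@pytest.fixture(scope="module")
def scaffold_ctx():
    pocket, ligand, fragment, scaffold, rgroup = cd.make_toy_complex(
        cd.ToyComplexSpec("ethanol", seed=1)
    )
    return ConditioningContext("scaffold", pocket, fragment=fragment)


def _transform_ctx(ctx, R=None, t=None):
    def move(coords):
        out = coords
        if R is not None:
            out = out @ R.T
        if t is not None:
            out = out + t
        return out

    pocket = cd.PocketContext(
        cd.AtomSet(
            ctx.pocket.atoms.element_onehot,
            move(ctx.pocket.atoms.coords),
            ctx.pocket.atoms.real_mask,
        ),
        ctx.pocket.residue_labels,
    )
    fragment = cd.FragmentSeed(
        cd.AtomSet(
            ctx.fragment.atoms.element_onehot,
            move(ctx.fragment.atoms.coords),
            ctx.fragment.atoms.real_mask,
        ),
        ctx.fragment.anchors,
    )
    return ConditioningContext("scaffold", pocket, fragment=fragment), move


class TestRbf:
    def test_center_response_is_one(self):
        config = DenoiserConfig(K=8, d_max=10.0)
        for k in [0, 3, 7]:
            out = rbf_expand(config.centers[k], config)
            assert out[k] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        config = DenoiserConfig(K=4, d_max=3.0, sigma=1.0,
                                centers=np.array([0.0, 1.0, 2.0, 3.0]))
        out = rbf_expand(1.0, config)
        assert np.allclose(
            out, [np.exp(-0.5), 1.0, np.exp(-0.5), np.exp(-2.0)]
        )

    def test_rigid_motion_invariance(self, rng):
        """Distances are preserved by rigid motions, hence so is the RBF
        feature of any generating point pair."""
        config = DenoiserConfig(K=8)
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.standard_normal(3)
        d0 = np.linalg.norm(a - b)
        d1 = np.linalg.norm((R @ a + t) - (R @ b + t))
        assert np.allclose(rbf_expand(d0, config), rbf_expand(d1, config))

    def test_negative_distance_rejected(self):
        with pytest.raises(ParameterError):
            rbf_expand(-0.1, DenoiserConfig())


class TestEquivariance:
    def _predict(self, model, ctx, feats, coords):
        return predict_noise((feats, coords), ctx, 5, 10, model)

    def test_translation_invariance(self, small_model, scaffold_ctx, rng):
        feats = rng.standard_normal((2, cd.N_CATEGORIES))
        coords = rng.standard_normal((2, 3))
        base = self._predict(small_model, scaffold_ctx, feats, coords)
        for k in range(5):
            t = rng.standard_normal(3) * 10
            moved, mv = _transform_ctx(scaffold_ctx, t=t)
            out = self._predict(small_model, moved, feats, coords + t)
            assert np.allclose(out.eps_coords, base.eps_coords, atol=1e-8)
            assert np.allclose(out.eps_features, base.eps_features,
                               atol=1e-8)

    def test_rotation_equivariance_20_random_motions(
        self, small_model, scaffold_ctx, rng
    ):
        """Rotating all inputs rotates the coordinate noise and leaves the
        feature noise unchanged (float64, 1e-8 relative)."""
        feats = rng.standard_normal((2, cd.N_CATEGORIES))
        coords = rng.standard_normal((2, 3))
        base = self._predict(small_model, scaffold_ctx, feats, coords)
        scale = np.abs(base.eps_coords).max()
        for k in range(20):
            R = Rotation.random(random_state=k).as_matrix()
            t = rng.standard_normal(3)
            moved, mv = _transform_ctx(scaffold_ctx, R=R, t=t)
            out = self._predict(small_model, moved, feats, mv(coords))
            dev = np.abs(out.eps_coords - base.eps_coords @ R.T).max()
            assert dev / scale < 1e-8
            assert np.allclose(out.eps_features, base.eps_features,
                               atol=1e-8)

    def test_permutation_equivariance(self, small_model, scaffold_ctx, rng):
        feats = rng.standard_normal((4, cd.N_CATEGORIES))
        coords = rng.standard_normal((4, 3)) * 2
        base = self._predict(small_model, scaffold_ctx, feats, coords)
        perm = rng.permutation(4)
        out = self._predict(
            small_model, scaffold_ctx, feats[perm], coords[perm]
        )
        assert np.allclose(out.eps_coords, base.eps_coords[perm],
                           atol=1e-8)
        assert np.allclose(out.eps_features, base.eps_features[perm],
                           atol=1e-8)


class TestMechanics:
    def test_context_atoms_never_move(self, small_model, scaffold_ctx, rng):
        """Across all stacked layers the frozen context keeps its exact
        coordinates (zero coordinate update by construction)."""
        feats = rng.standard_normal((3, cd.N_CATEGORIES))
        coords = rng.standard_normal((3, 3))
        batch = build_graph_batch(feats, coords, scaffold_ctx, 0.5)
        frozen_before = batch.node_coords[batch.context_mask].copy()
        update_col = Tensor(
            (~batch.context_mask).astype(float)[:, None]
        )
        import fdcdiff.nnet as nnet

        h = nnet.silu(small_model.embed(Tensor(batch.node_features)))
        r = Tensor(batch.node_coords)
        for layer in small_model.layers:
            h, r = layer(
                h, r, batch, small_model.config.centers,
                small_model.config.sigma, update_col,
            )
        assert np.array_equal(
            r.data[batch.context_mask], frozen_before
        )

    def test_single_node_graph_keeps_coordinates(self, rng):
        batch = GraphBatch(
            rng.standard_normal((1, INPUT_DIM)),
            np.array([[1.0, 2.0, 3.0]]),
            np.array([False]),
        )
        model = EGNNDenoiser(
            DenoiserConfig(n_layers=2, hidden_dim=16, K=4), seed=1
        ).train(False)
        eps_r, eps_h = model.forward(batch)
        assert np.allclose(eps_r.data, 0.0)
        assert eps_h.data.shape == (1, cd.N_CATEGORIES)

    def test_output_rows_cover_only_noisy_atoms(
        self, small_model, scaffold_ctx, rng
    ):
        for n in [1, 2, 5]:
            out = predict_noise(
                (
                    rng.standard_normal((n, cd.N_CATEGORIES)),
                    rng.standard_normal((n, 3)),
                ),
                scaffold_ctx, 3, 10, small_model,
            )
            assert out.eps_coords.shape == (n, 3)
            assert out.eps_features.shape == (n, cd.N_CATEGORIES)

    def test_empty_fragment_context_rejected(self, rng):
        pocket, *_ = cd.make_toy_complex(cd.ToyComplexSpec("ethanol"))
        ctx = ConditioningContext(
            "scaffold", pocket,
            fragment=cd.FragmentSeed(
                cd.AtomSet.from_symbols([], np.zeros((0, 3)))
            ),
        )
        with pytest.raises(ContextError):
            build_graph_batch(
                rng.standard_normal((1, cd.N_CATEGORIES)),
                rng.standard_normal((1, 3)),
                ctx,
                0.1,
            )

    def test_two_node_layer_matches_manual_evaluation(self):
        """One EGCL on a two-node graph reproduces an independent NumPy
        evaluation of the message/feature/coordinate updates."""
        config = DenoiserConfig(n_layers=1, hidden_dim=4, K=2, d_max=2.0)
        model = EGNNDenoiser(config, seed=5).train(False)
        layer = model.layers[0]
        feats = np.zeros((2, INPUT_DIM))
        feats[0, 0] = feats[1, 2] = 1.0
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        batch = GraphBatch(feats, coords, np.array([True, False]))

        h0 = Tensor(batch.node_features)
        import fdcdiff.nnet as nnet

        h_emb = nnet.silu(model.embed(h0))
        update_col = Tensor(np.array([[0.0], [1.0]]))
        h1, r1 = layer(
            h_emb, Tensor(coords), batch, config.centers, config.sigma,
            update_col,
        )

        # independent evaluation with plain numpy
        def np_silu(x):
            return x / (1.0 + np.exp(-x))

        def np_linear(lin, x):
            return x @ lin.W.data + lin.b.data

        def np_mlp(mlp, x, final_act):
            for i, lin in enumerate(mlp.layers):
                x = np_linear(lin, x)
                if i < len(mlp.layers) - 1 or final_act:
                    x = np_silu(x)
            return x

        h = np_silu(np_linear(model.embed, feats))
        d = 1.0
        e = np.exp(-((d - config.centers) ** 2) / (2 * config.sigma**2))
        msgs, disp = [], np.zeros((2, 3))
        agg = np.zeros((2, 4))
        for i, j in [(0, 1), (1, 0)]:
            inp = np.concatenate([h[i], h[j], [d**2], e])[None, :]
            agg[i] += np_mlp(layer.phi_e, inp, True)[0]
            w = np_mlp(layer.phi_r, inp, False)[0, 0]
            disp[i] += (coords[i] - coords[j]) / (d + 1.0) * w
        disp[0] = 0.0  # context node frozen
        def np_bn(bn, z):
            mu = z.mean(axis=0, keepdims=True)
            var = z.var(axis=0, keepdims=True)
            zh = (z - mu) / np.sqrt(var + bn.eps)
            return zh * bn.gamma.data + bn.beta.data

        z = np.concatenate([h, agg], axis=1)
        z = np_bn(layer.h_bn1, np_linear(layer.h_lin1, z))
        z = np_silu(z)
        z = np_bn(layer.h_bn2, np_linear(layer.h_lin2, z))
        h_manual = h + z
        r_manual = coords + disp

        assert np.allclose(h1.data, h_manual, atol=1e-10)
        assert np.allclose(r1.data, r_manual, atol=1e-10)


def test_checkpoint_round_trip(tmp_path, scaffold_ctx, rng):
    model = EGNNDenoiser(
        DenoiserConfig(n_layers=2, hidden_dim=16, K=4), seed=2
    ).train(False)
    feats = rng.standard_normal((2, cd.N_CATEGORIES))
    coords = rng.standard_normal((2, 3))
    before = predict_noise((feats, coords), scaffold_ctx, 2, 10, model)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    loaded = EGNNDenoiser.load(path).train(False)
    after = predict_noise((feats, coords), scaffold_ctx, 2, 10, loaded)
    assert np.array_equal(before.eps_coords, after.eps_coords)
    assert np.array_equal(before.eps_features, after.eps_features)
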