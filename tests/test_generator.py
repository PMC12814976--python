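"""Two-stage conditional sampling and decoupled training mechanics.

The heavy overfit-recovery experiments live in the acceptance suite; here
the stages run with tiny schedules and untrained or briefly trained models
to pin down the structural contracts: frozen context, padding bounds,
determinism, decoupling and gradient clipping.
"""

import numpy as np
import pytest

from fdcdiff import chem_data as cd
from fdcdiff.diffusion_core import make_schedule
from fdcdiff.egnn_denoiser import DenoiserConfig, EGNNDenoiser
from fdcdiff.errors import ContextError, ModelError, ParameterError
from fdcdiff.generator import (
    ConditioningContext,
    RGROUP_MAX_ATOMS,
    SizeModel,
    TrainConfig,
    generate_rgroup,
    generate_scaffold,
    rgroup_example,
    sample_size,
    scaffold_example,
    train_stage,
)


@pytest.fixture(scope="module")
def tiny_model():
    return EGNNDenoiser(
        DenoiserConfig(n_layers=2, hidden_dim=16, K=4), seed=3
    ).train(False)


@pytest.fixture(scope="module")
def short_schedule():
    return make_schedule("linear", 5)


@pytest.fixture(scope="module")
def contexts(ethanol_complex):
    pocket, ligand, fragment, scaffold, rgroup = ethanol_complex
    sctx = ConditioningContext("scaffold", pocket, fragment=fragment)
    rctx = ConditioningContext("rgroup", pocket, scaffold=scaffold)
    return sctx, rctx


class TestSizeModel:
    def test_single_support_always_drawn(self):
        model = SizeModel({5: 1.0})
        assert all(sample_size(model, s) == 5 for s in range(10))

    def test_same_seed_same_draw(self):
        model = SizeModel.from_counts([3, 3, 4, 5, 5, 5])
        assert sample_size(model, 42) == sample_size(model, 42)

    def test_frequencies_match_histogram(self):
        model = SizeModel({2: 0.25, 4: 0.75})
        rng = np.random.default_rng(0)
        draws = np.array([sample_size(model, rng) for _ in range(10_000)])
        p_hat = float(np.mean(draws == 4))
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(p_hat - 0.75) < 3 * se

    def test_empty_histogram_rejected(self):
        with pytest.raises(ModelError):
            SizeModel({})


class TestScaffoldStage:
    def test_zero_new_atoms_returns_fragment(self, contexts, tiny_model,
                                             short_schedule):
        sctx, _ = contexts
        state = generate_scaffold(sctx, tiny_model, short_schedule, 0, 0)
        assert state.n_new == 0
        assert np.array_equal(
            state.atoms.coords, sctx.fragment.atoms.coords
        )

    def test_fragment_atoms_bit_identical_in_output(
        self, contexts, tiny_model, short_schedule
    ):
        sctx, _ = contexts
        nf = sctx.fragment.atoms.n
        for n_new in [1, 3]:
            state = generate_scaffold(
                sctx, tiny_model, short_schedule, n_new, 7
            )
            assert state.atoms.n == nf + n_new
            assert np.array_equal(
                state.atoms.coords[:nf], sctx.fragment.atoms.coords
            )
            assert np.array_equal(
                state.atoms.element_onehot[:nf],
                sctx.fragment.atoms.element_onehot,
            )

    def test_seeded_sampling_is_deterministic(self, contexts, tiny_model,
                                              short_schedule):
        sctx, _ = contexts
        a = generate_scaffold(sctx, tiny_model, short_schedule, 2, 11)
        b = generate_scaffold(sctx, tiny_model, short_schedule, 2, 11)
        assert np.array_equal(a.atoms.coords, b.atoms.coords)
        assert a.atoms.symbols == b.atoms.symbols

    def test_context_never_mutated_by_sampling(self, contexts, tiny_model,
                                               short_schedule):
        """Pocket and fragment coordinates are bit-identical before and
        after a full sampling trajectory."""
        sctx, _ = contexts
        pocket_before = sctx.pocket.atoms.coords.copy()
        frag_before = sctx.fragment.atoms.coords.copy()
        generate_scaffold(sctx, tiny_model, short_schedule, 3, 5)
        assert np.array_equal(sctx.pocket.atoms.coords, pocket_before)
        assert np.array_equal(sctx.fragment.atoms.coords, frag_before)

    def test_anchorless_fragment_rejected(self, contexts, tiny_model,
                                          short_schedule):
        sctx, _ = contexts
        bare = ConditioningContext(
            "scaffold",
            sctx.pocket,
            fragment=cd.FragmentSeed(sctx.fragment.atoms, anchors=()),
        )
        with pytest.raises(ContextError):
            generate_scaffold(bare, tiny_model, short_schedule, 1, 0)

    def test_rigid_motion_covariance_with_matched_noise(
        self, contexts, tiny_model, short_schedule
    ):
        """Sampling the rotated context with rotated noise draws equals
        rotating the sample (tolerance 1e-4)."""
        from scipy.spatial.transform import Rotation

        sctx, _ = contexts
        R = Rotation.random(random_state=5).as_matrix()

        class RotatedNoise:
            """Wraps a generator, rotating every (n, 3) coordinate draw."""

            def __init__(self, seed, rot):
                self._rng = np.random.default_rng(seed)
                self._rot = rot

            def standard_normal(self, shape):
                z = self._rng.standard_normal(shape)
                if len(shape) == 2 and shape[1] == 3:
                    return z @ self._rot.T
                return z

        rot_ctx = ConditioningContext(
            "scaffold",
            cd.PocketContext(
                cd.AtomSet(
                    sctx.pocket.atoms.element_onehot,
                    sctx.pocket.atoms.coords @ R.T,
                    sctx.pocket.atoms.real_mask,
                ),
                sctx.pocket.residue_labels,
            ),
            fragment=cd.FragmentSeed(
                cd.AtomSet(
                    sctx.fragment.atoms.element_onehot,
                    sctx.fragment.atoms.coords @ R.T,
                    sctx.fragment.atoms.real_mask,
                ),
                sctx.fragment.anchors,
            ),
        )
        base = generate_scaffold(
            sctx, tiny_model, short_schedule, 2,
            RotatedNoise(9, np.eye(3)),
        )
        rotated = generate_scaffold(
            rot_ctx, tiny_model, short_schedule, 2, RotatedNoise(9, R)
        )
        assert np.allclose(
            rotated.atoms.coords, base.atoms.coords @ R.T, atol=1e-4
        )
        assert rotated.atoms.symbols == base.atoms.symbols


class TestRGroupStage:
    def test_output_never_exceeds_padding_width(self, contexts, tiny_model,
                                                short_schedule):
        _, rctx = contexts
        for seed in range(5):
            state = generate_rgroup(
                rctx, tiny_model, short_schedule, seed
            )
            assert state.atoms.n <= RGROUP_MAX_ATOMS
            assert "virtual" not in state.atoms.symbols

    def test_scaffold_never_mutated(self, contexts, tiny_model,
                                    short_schedule):
        _, rctx = contexts
        before = rctx.scaffold.coords.copy()
        generate_rgroup(rctx, tiny_model, short_schedule, 1)
        assert np.array_equal(rctx.scaffold.coords, before)

    def test_empty_scaffold_rejected(self, contexts, tiny_model,
                                     short_schedule):
        _, rctx = contexts
        with pytest.raises(ContextError):
            generate_rgroup(
                ConditioningContext(
                    "rgroup",
                    rctx.pocket,
                    scaffold=cd.AtomSet.from_symbols([], np.zeros((0, 3))),
                ),
                tiny_model, short_schedule, 0,
            )

    def test_all_virtual_decode_gives_empty_rgroup(self, ethanol_complex):
        from fdcdiff.generator import _decode_elements

        feats = np.zeros((4, cd.N_CATEGORIES))
        feats[:, cd.VIRTUAL_INDEX] = 5.0
        assert _decode_elements(feats, allow_virtual=True) == [
            "virtual"
        ] * 4
        # without the virtual channel the arg-max falls back to elements
        assert "virtual" not in _decode_elements(feats,
                                                 allow_virtual=False)


class TestTraining:
    def _examples(self, complex_):
        pocket, ligand, fragment, scaffold, rgroup = complex_
        return (
            scaffold_example(pocket, fragment, scaffold),
            rgroup_example(pocket, scaffold, rgroup),
        )

    def test_examples_have_stage_consistent_targets(self, ethanol_complex):
        s_ex, r_ex = self._examples(ethanol_complex)
        assert s_ex.context.stage == "scaffold"
        assert len(s_ex.target_coords) == 1  # one atom beyond the fragment
        assert r_ex.target_features.shape == (
            RGROUP_MAX_ATOMS, cd.N_CATEGORIES
        )
        n_virtual = int(
            r_ex.target_features[:, cd.VIRTUAL_INDEX].sum()
        )
        assert n_virtual == RGROUP_MAX_ATOMS - 1  # ethanol R-group is one O

    def test_post_clip_gradient_norm_bounded(self, ethanol_complex):
        s_ex, _ = self._examples(ethanol_complex)
        sched = make_schedule("linear", 5)
        norms = []
        train_stage(
            [s_ex],
            TrainConfig("scaffold", batch_size=2, iterations=5,
                        grad_clip_norm=0.5, seed=0),
            sched,
            denoiser_config=DenoiserConfig(n_layers=1, hidden_dim=8, K=4),
            grad_norm_log=norms,
        )
        assert len(norms) == 5
        assert all(n <= 0.5 + 1e-12 for n in norms)

    def test_stages_train_decoupled_parameters(self, ethanol_complex):
        """An R-group training run leaves the scaffold model's parameters
        bit-identical."""
        s_ex, r_ex = self._examples(ethanol_complex)
        sched = make_schedule("linear", 5)
        cfgnet = DenoiserConfig(n_layers=1, hidden_dim=8, K=4)
        model_s, _ = train_stage(
            [s_ex],
            TrainConfig("scaffold", batch_size=1, iterations=3, seed=0),
            sched, denoiser_config=cfgnet,
        )
        snapshot = [p.data.copy() for p in model_s.params()]
        train_stage(
            [r_ex],
            TrainConfig("rgroup", batch_size=1, iterations=3, seed=0),
            sched, denoiser_config=cfgnet,
        )
        for p, snap in zip(model_s.params(), snapshot):
            assert np.array_equal(p.data, snap)

    def test_wrong_stage_dataset_rejected(self, ethanol_complex):
        s_ex, _ = self._examples(ethanol_complex)
        with pytest.raises(ParameterError):
            train_stage(
                [s_ex],
                TrainConfig("rgroup", iterations=1),
                make_schedule("linear", 5),
                denoiser_config=DenoiserConfig(n_layers=1, hidden_dim=8,
                                               K=4),
            )

    def test_loss_decreases_on_short_overfit(self, ethanol_complex):
        s_ex, _ = self._examples(ethanol_complex)
        sched = make_schedule("linear", 20)
        _, losses = train_stage(
            [s_ex],
            TrainConfig("scaffold", learning_rate=2e-3, batch_size=4,
                        iterations=60, seed=1),
            sched,
            denoiser_config=DenoiserConfig(n_layers=2, hidden_dim=24, K=8),
        )
        assert np.mean(losses[-10:]) < np.mean(losses[:10])
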