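"""E(3)-equivariant graph denoiser with RBF distance expansion.

The network stacks equivariant graph convolution layers (EGCL) over a fully
connected graph of context atoms (pocket, fragment or scaffold — frozen)
and generated atoms (noisy — updated).  Feature updates consume only
rotation/translation-invariant scalars (node embeddings, squared distances,
Gaussian RBF responses), and coordinate updates are linear in relative
positions, so feature outputs are E(3)-invariant and coordinate outputs
E(3)-equivariant by construction.  Context atoms receive a coordinate
update of exactly zero.

The noise prediction subtracts the input coordinates from the coordinate
output (the feature part subtracts nothing), restricted to the generated
atoms, which makes the coordinate prediction translation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_data import AtomSet, N_CATEGORIES
from .errors import ContextError, NumericError, ParameterError
from .nnet import MLP, BatchNorm1d, Linear, Tensor, concat, gather, segment_sum, silu

#: node roles, one-hot alongside the element channels
ROLES = ("pocket", "fragment", "scaffold", "generated")


@dataclass
class DenoiserConfig:
    """Architecture and RBF hyper-parameters.

    ``centers`` defaults to ``K`` points uniformly spaced on [0, d_max];
    ``sigma`` defaults to d_max / K so adjacent kernels overlap.
    """

    n_layers: int = 6
    hidden_dim: int = 128
    K: int = 16
    d_max: float = 10.0
    sigma: float | None = None
    centers: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma is None:
            self.sigma = self.d_max / self.K
        if self.centers is None:
            self.centers = np.linspace(0.0, self.d_max, self.K)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (self.K,):
            raise ParameterError("centers must have length K")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "hidden_dim": self.hidden_dim,
            "K": self.K,
            "d_max": self.d_max,
            "sigma": self.sigma,
            "centers": self.centers.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        return cls(
            n_layers=int(d["n_layers"]),
            hidden_dim=int(d["hidden_dim"]),
            K=int(d["K"]),
            d_max=float(d["d_max"]),
            sigma=float(d["sigma"]),
            centers=np.asarray(d["centers"]),
        )


#: R-group padding slots are an ordered tensor; a one-hot slot encoding
#: breaks their permutation symmetry so the denoiser can commit
#: individual slots to real-atom or virtual roles (zero for context atoms
#: and scaffold-stage generated atoms)
SLOT_WIDTH = 10

#: layout of the raw node feature vector fed to the embedding layer
IDX_ANCHOR = N_CATEGORIES + len(ROLES)
IDX_TIME = IDX_ANCHOR + 1
IDX_SLOT = IDX_TIME + 1
INPUT_DIM = IDX_SLOT + SLOT_WIDTH


def rbf_expand(d, config: DenoiserConfig) -> np.ndarray:
    """Gaussian RBF responses of distance(s) ``d`` at the config's centers.

    exp(-(d - mu_k)^2 / (2 sigma^2)), k = 1..K; values in (0, 1].
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ParameterError("distances must be nonnegative")
    diff = d[..., None] - config.centers
    return np.exp(-(diff**2) / (2.0 * config.sigma**2))


@dataclass
class GraphBatch:
    """Fully connected graph over context ∪ generated atoms.

    ``node_features`` rows: element channels ⊕ role one-hot ⊕ anchor flag ⊕
    t/T scalar.  ``context_mask`` is true for frozen atoms.
    """

    node_features: np.ndarray
    node_coords: np.ndarray
    context_mask: np.ndarray
    src: np.ndarray = field(init=False)
    dst: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.context_mask)
        idx = np.arange(n)
        # directed edges (i, j), j != i: message m_ij aggregates at i
        self.src = np.repeat(idx, n - 1) if n > 1 else np.zeros(0, int)
        mat = np.tile(idx, (n, 1))
        self.dst = (
            mat[~np.eye(n, dtype=bool)].reshape(-1)
            if n > 1
            else np.zeros(0, int)
        )

    @property
    def n(self) -> int:
        return len(self.context_mask)


class EGCL:
    """One equivariant graph convolution layer.

    phi_e — two dense layers with SiLU (messages); phi_h — dense, batch
    norm, SiLU, dense, batch norm, residual add (features); phi_r — three
    dense layers with SiLU between, scalar output (coordinate weights).
    """

    def __init__(self, hidden_dim: int, K: int, rng: np.random.Generator):
        edge_in = 2 * hidden_dim + 1 + K
        self.phi_e = MLP([edge_in, hidden_dim, hidden_dim], rng,
                         final_activation=True)
        self.h_lin1 = Linear(2 * hidden_dim, hidden_dim, rng)
        self.h_bn1 = BatchNorm1d(hidden_dim)
        self.h_lin2 = Linear(hidden_dim, hidden_dim, rng)
        self.h_bn2 = BatchNorm1d(hidden_dim)
        self.phi_r = MLP([edge_in, hidden_dim, hidden_dim, 1], rng)

    def params(self):
        return (
            self.phi_e.params()
            + self.h_lin1.params()
            + self.h_bn1.params()
            + self.h_lin2.params()
            + self.h_bn2.params()
            + self.phi_r.params()
        )

    def batchnorms(self):
        return [self.h_bn1, self.h_bn2]

    def __call__(self, h: Tensor, r: Tensor, batch: GraphBatch,
                 centers: np.ndarray, sigma: float, update_col: Tensor):
        n = batch.n
        if len(batch.src) == 0:
            # single-node graph: empty message sum, coordinates unchanged
            agg = Tensor(np.zeros((n, h.shape[1])))
        else:
            hi = gather(h, batch.src)
            hj = gather(h, batch.dst)
            diff = gather(r, batch.src) - gather(r, batch.dst)
            d2 = diff.square().sum(axis=1, keepdims=True)
            d = (d2 + 1e-12).sqrt()
            e = (
                -((d - Tensor(centers[None, :])).square())
                * (1.0 / (2.0 * sigma**2))
            ).exp()
            edge_in = concat([hi, hj, d2, e], axis=1)
            m = self.phi_e(edge_in)
            agg = segment_sum(m, batch.src, n)
            w = self.phi_r(edge_in)
            disp = segment_sum(diff / (d + 1.0) * w, batch.src, n)
            r = r + disp * update_col
        z = concat([h, agg], axis=1)
        z = self.h_bn1(self.h_lin1(z))
        z = self.h_lin2(silu(z))
        h = h + self.h_bn2(z)
        return h, r


class EGNNDenoiser:
    """Stack of EGCLs with an input embedding and a feature noise head."""

    def __init__(self, config: DenoiserConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.embed = Linear(INPUT_DIM, config.hidden_dim, rng)
        self.layers = [
            EGCL(config.hidden_dim, config.K, rng)
            for _ in range(config.n_layers)
        ]
        self.feature_head = Linear(config.hidden_dim, N_CATEGORIES, rng)

    def params(self):
        out = self.embed.params()
        for layer in self.layers:
            out += layer.params()
        out += self.feature_head.params()
        return out

    def train(self, flag: bool = True):
        for layer in self.layers:
            for bn in layer.batchnorms():
                bn.training = flag
        return self

    def forward(self, batch: GraphBatch):
        """Run the network; returns (eps_coords, eps_features) Tensors for
        the generated (non-context) rows."""
        update_col = Tensor((~batch.context_mask).astype(float)[:, None])
        h = silu(self.embed(Tensor(batch.node_features)))
        r0 = Tensor(batch.node_coords)
        r = r0
        for li, layer in enumerate(self.layers):
            h, r = layer(
                h, r, batch, self.config.centers, self.config.sigma,
                update_col,
            )
            if not (
                np.isfinite(h.data).all() and np.isfinite(r.data).all()
            ):
                raise NumericError(f"non-finite values in EGCL layer {li}")
        gen = np.flatnonzero(~batch.context_mask)
        eps_coords = gather(r - r0, gen)
        eps_features = gather(self.feature_head(h), gen)
        return eps_coords, eps_features

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {
            f"p{i}": p.data for i, p in enumerate(self.params())
        }
        k = 0
        for layer in self.layers:
            for bn in layer.batchnorms():
                arrays[f"bn{k}_mean"] = bn.running_mean
                arrays[f"bn{k}_var"] = bn.running_var
                k += 1
        import json

        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez_compressed(str(path), **arrays)

    @classmethod
    def load(cls, path) -> "EGNNDenoiser":
        import json

        with np.load(str(path)) as data:
            config = DenoiserConfig.from_dict(
                json.loads(bytes(data["config_json"]).decode())
            )
            model = cls(config)
            for i, p in enumerate(model.params()):
                p.data = data[f"p{i}"].astype(float)
            k = 0
            for layer in model.layers:
                for bn in layer.batchnorms():
                    bn.running_mean = data[f"bn{k}_mean"].astype(float)
                    bn.running_var = data[f"bn{k}_var"].astype(float)
                    k += 1
        return model


def _context_entries(context):
    """Flatten a conditioning context into (atoms, role, anchors) blocks."""
    entries = []
    if context.stage == "scaffold":
        if context.fragment is None or context.fragment.atoms.n == 0:
            raise ContextError("scaffold stage requires a fragment")
        entries.append((context.pocket.atoms, "pocket", ()))
        entries.append(
            (context.fragment.atoms, "fragment", context.fragment.anchors)
        )
    elif context.stage == "rgroup":
        if context.scaffold is None or context.scaffold.n == 0:
            raise ContextError("rgroup stage requires a scaffold")
        entries.append((context.pocket.atoms, "pocket", ()))
        entries.append((context.scaffold, "scaffold", ()))
    else:
        raise ContextError(f"unknown stage {context.stage!r}")
    return entries


def build_graph_batch(noisy_features: np.ndarray, noisy_coords: np.ndarray,
                      context, t_frac: float) -> GraphBatch:
    """Assemble the fully connected batch for context ∪ generated atoms.

    The whole system is translated so the context centroid sits at the
    origin (translation gauge; the network output is translation invariant
    either way, this keeps coordinates well-scaled).
    """
    entries = _context_entries(context)
    feats, coords, mask = [], [], []
    for atoms, role, anchors in entries:
        f = np.zeros((atoms.n, INPUT_DIM))
        f[:, :N_CATEGORIES] = atoms.element_onehot
        f[:, N_CATEGORIES + ROLES.index(role)] = 1.0
        for a in anchors:
            f[a, IDX_ANCHOR] = 1.0
        f[:, IDX_TIME] = t_frac
        feats.append(f)
        coords.append(atoms.coords)
        mask.append(np.ones(atoms.n, dtype=bool))

    noisy_features = np.asarray(noisy_features, dtype=float)
    noisy_coords = np.asarray(noisy_coords, dtype=float)
    n_gen = len(noisy_coords)
    f = np.zeros((n_gen, INPUT_DIM))
    f[:, :N_CATEGORIES] = noisy_features
    f[:, N_CATEGORIES + ROLES.index("generated")] = 1.0
    f[:, IDX_TIME] = t_frac
    if context.stage == "rgroup":
        for k in range(n_gen):
            f[k, IDX_SLOT + min(k, SLOT_WIDTH - 1)] = 1.0
    feats.append(f)
    coords.append(noisy_coords)
    mask.append(np.zeros(len(noisy_coords), dtype=bool))

    all_coords = np.concatenate(coords)
    context_mask = np.concatenate(mask)
    center = all_coords[context_mask].mean(axis=0)
    return GraphBatch(
        np.concatenate(feats), all_coords - center, context_mask
    )


def predict_noise(noisy, context, t: int, T: int, model: EGNNDenoiser):
    """Predict the injected noise for the generated atoms.

    ``noisy`` is either an AtomSet or a ``(features, coords)`` pair of
    arrays (the continuous relaxation used mid-trajectory).  Returns a
    :class:`~fdcdiff.diffusion_core.NoisePrediction` whose rows cover the
    generated atoms only.
    """
    from .diffusion_core import NoisePrediction

    if isinstance(noisy, AtomSet):
        features, coords = noisy.element_onehot, noisy.coords
    else:
        features, coords = noisy
    if len(coords) == 0:
        return NoisePrediction(np.zeros((0, 3)), np.zeros((0, N_CATEGORIES)))
    batch = build_graph_batch(features, coords, context, t / T)
    eps_r, eps_h = model.forward(batch)
    return NoisePrediction(eps_r.data.copy(), eps_h.data.copy())
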