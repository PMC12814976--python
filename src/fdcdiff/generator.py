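"""The two conditional diffusion stages and their decoupled training.

Stage 1 (scaffold) grows new atoms around a fragment's anchor atoms inside
a protein pocket; the fragment and pocket are frozen context.  Stage 2
(R-group) completes the molecule conditioned on pocket and scaffold, using
virtual-atom padding: exactly ``max_atoms`` slots are denoised and slots
that decode to the virtual category are dropped, which lets one tensorial
shape carry variable-size R-groups.

The two stages are trained separately, each with its own parameters,
optimizer state and training tuples; gradients are clipped by global norm.
Both stages minimize the L2 loss between true and predicted noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_data import (
    AtomSet,
    ELEMENTS,
    FragmentSeed,
    N_CATEGORIES,
    PocketContext,
    VIRTUAL_INDEX,
    concat_atomsets,
)
from .diffusion_core import NoiseSchedule, forward_marginal, posterior_step
from .egnn_denoiser import (
    DenoiserConfig,
    EGNNDenoiser,
    build_graph_batch,
    predict_noise,
)
from .errors import ContextError, ModelError, NumericError, ParameterError
from .nnet import Adam, Tensor, clip_global_norm

#: virtual-atom padding width of the R-group stage
RGROUP_MAX_ATOMS = 10


@dataclass
class ConditioningContext:
    """Stage-tagged frozen context for one generation problem."""

    stage: str
    pocket: PocketContext
    fragment: FragmentSeed | None = None
    scaffold: AtomSet | None = None

    def __post_init__(self):
        if self.stage == "scaffold":
            if self.fragment is None:
                raise ContextError("scaffold stage requires fragment")
        elif self.stage == "rgroup":
            if self.scaffold is None:
                raise ContextError("rgroup stage requires scaffold")
        else:
            raise ContextError(f"unknown stage {self.stage!r}")


@dataclass
class ScaffoldState:
    """Stage-1 output: fragment ∪ newly generated atoms."""

    atoms: AtomSet
    n_new: int


@dataclass
class RGroupState:
    """Stage-2 output: decoded real atoms (virtual slots dropped)."""

    atoms: AtomSet
    n_slots: int = RGROUP_MAX_ATOMS


@dataclass
class SizeModel:
    """Empirical histogram over new-atom counts with a seedable sampler."""

    histogram: dict

    def __post_init__(self):
        if not self.histogram:
            raise ModelError("empty size histogram")
        total = float(sum(self.histogram.values()))
        if total <= 0:
            raise ModelError("size histogram has no mass")
        self.histogram = {
            int(k): float(v) / total for k, v in self.histogram.items()
        }

    @classmethod
    def from_counts(cls, counts) -> "SizeModel":
        hist: dict = {}
        for c in counts:
            hist[int(c)] = hist.get(int(c), 0) + 1
        return cls(hist)


def sample_size(model: SizeModel, seed) -> int:
    """Draw a new-atom count from the size histogram (deterministic given
    the seed; an ``np.random.Generator`` is also accepted)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    keys = sorted(model.histogram)
    probs = np.array([model.histogram[k] for k in keys])
    return int(rng.choice(keys, p=probs))


@dataclass
class TrainConfig:
    """Per-stage optimization settings."""

    stage: str
    learning_rate: float = 2e-4
    batch_size: int = 32
    iterations: int = 2000
    grad_clip_norm: float = 1.0
    seed: int = 0
    #: exponential moving average of parameters used for sampling
    #: (0 disables)
    ema_decay: float = 0.995

    def __post_init__(self):
        if (
            self.learning_rate <= 0
            or self.batch_size <= 0
            or self.iterations <= 0
            or self.grad_clip_norm <= 0
        ):
            raise ParameterError("train config values must be positive")


@dataclass
class StageExample:
    """One training tuple: frozen context plus target atoms to denoise.

    ``target_features`` has the full category width; for the R-group stage
    the rows are padded to ``RGROUP_MAX_ATOMS`` with virtual-category slots
    whose reference coordinates sit at the real R-group centroid (scaffold
    centroid when the R-group is empty).
    """

    context: ConditioningContext
    target_features: np.ndarray
    target_coords: np.ndarray


def scaffold_example(pocket: PocketContext, fragment: FragmentSeed,
                     scaffold: AtomSet) -> StageExample:
    """Stage-1 tuple: targets are the scaffold atoms beyond the fragment."""
    frag_coords = fragment.atoms.coords
    keep = []
    for i in range(scaffold.n):
        d = np.linalg.norm(frag_coords - scaffold.coords[i], axis=1)
        if d.min() > 1e-8:
            keep.append(i)
    new = scaffold.subset(keep) if keep else AtomSet.from_symbols(
        [], np.zeros((0, 3))
    )
    ctx = ConditioningContext("scaffold", pocket, fragment=fragment)
    return StageExample(ctx, new.element_onehot.copy(), new.coords.copy())


def rgroup_example(pocket: PocketContext, scaffold: AtomSet,
                   rgroup: AtomSet) -> StageExample:
    """Stage-2 tuple: targets are the padded R-group slots."""
    n_real = rgroup.n
    if n_real > RGROUP_MAX_ATOMS:
        raise ParameterError(
            f"R-group exceeds padding width {RGROUP_MAX_ATOMS}"
        )
    feats = np.zeros((RGROUP_MAX_ATOMS, N_CATEGORIES))
    coords = np.zeros((RGROUP_MAX_ATOMS, 3))
    feats[:n_real] = rgroup.element_onehot
    coords[:n_real] = rgroup.coords
    pad_center = (
        rgroup.coords.mean(axis=0) if n_real else scaffold.coords.mean(axis=0)
    )
    feats[n_real:, VIRTUAL_INDEX] = 1.0
    coords[n_real:] = pad_center
    ctx = ConditioningContext("rgroup", pocket, scaffold=scaffold)
    return StageExample(ctx, feats, coords)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _example_loss(model: EGNNDenoiser, ex: StageExample, t: int,
                  schedule: NoiseSchedule, rng: np.random.Generator):
    """Autodiff loss Tensor for one (example, t) draw."""
    n = len(ex.target_coords)
    eps_r = rng.standard_normal((n, 3))
    eps_h = rng.standard_normal((n, N_CATEGORIES))
    xt_r = forward_marginal(ex.target_coords, t, schedule, eps_r)
    xt_h = forward_marginal(ex.target_features, t, schedule, eps_h)
    batch = build_graph_batch(xt_h, xt_r, ex.context, t / schedule.T)
    out_r, out_h = model.forward(batch)
    n_terms = n * (3 + N_CATEGORIES)
    loss = (
        (out_r - Tensor(eps_r)).square().sum()
        + (out_h - Tensor(eps_h)).square().sum()
    ) * (1.0 / n_terms)
    return loss


def train_stage(dataset, config: TrainConfig, schedule: NoiseSchedule,
                model: EGNNDenoiser | None = None,
                denoiser_config: DenoiserConfig | None = None,
                callback=None, grad_norm_log: list | None = None):
    """Train one stage's denoiser on its tuples; returns (model, losses).

    Per step: draw a mini-batch of examples, a uniform t in 1..T for each,
    noise the targets through the closed-form marginal, predict the noise,
    and take one Adam step on the mean L2 loss after global-norm gradient
    clipping.  The other stage's parameters are never touched (each stage
    owns its own ``EGNNDenoiser``).
    """
    dataset = [
        ex
        for ex in dataset
        if ex.context.stage == config.stage and len(ex.target_coords) > 0
    ]
    if not dataset:
        raise ParameterError(
            f"no {config.stage!r} tuples with target atoms in dataset"
        )
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = EGNNDenoiser(
            denoiser_config or DenoiserConfig(),
            seed=int(rng.integers(2**31)),
        )
    model.train(True)
    opt = Adam(model.params(), lr=config.learning_rate)
    shadow = (
        [p.data.copy() for p in opt.params] if config.ema_decay else None
    )
    losses = []
    for step in range(config.iterations):
        idx = rng.integers(len(dataset), size=config.batch_size)
        opt.zero_grad()
        batch_losses = []
        for k in idx:
            ex = dataset[int(k)]
            if len(ex.target_coords) == 0:
                continue
            t = int(rng.integers(1, schedule.T + 1))
            loss = _example_loss(model, ex, t, schedule, rng)
            loss.backward(np.full((), 1.0 / config.batch_size))
            batch_losses.append(float(loss.data))
        if not batch_losses:
            continue
        step_loss = float(np.mean(batch_losses))
        if not np.isfinite(step_loss):
            raise NumericError(f"NaN loss at training step {step}")
        post_clip = clip_global_norm(opt.params, config.grad_clip_norm)
        if grad_norm_log is not None:
            grad_norm_log.append(post_clip)
        opt.step()
        if shadow is not None:
            d = config.ema_decay
            for sh, p in zip(shadow, opt.params):
                sh *= d
                sh += (1.0 - d) * p.data
        losses.append(step_loss)
        if callback is not None and callback(step, step_loss):
            break
    if shadow is not None:
        for sh, p in zip(shadow, opt.params):
            p.data = sh
    model.train(False)
    return model, losses


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


#: numerical guards on the reverse chain: generated coordinates may not
#: stray further than this from the context bounding box, and feature
#: channels are kept in a generous band around the one-hot range.  A
#: well-trained denoiser never reaches either bound; they only stop
#: undertrained models from diverging.
_COORD_MARGIN = 15.0
_FEATURE_BOUND = 8.0


def _context_box(context):
    if context.stage == "scaffold":
        pts = [context.pocket.atoms.coords, context.fragment.atoms.coords]
    else:
        pts = [context.pocket.atoms.coords, context.scaffold.coords]
    allpts = np.concatenate(pts)
    return allpts.min(axis=0) - _COORD_MARGIN, allpts.max(axis=0) + _COORD_MARGIN


def _clip_denoised_eps(x_t, eps_hat, t, schedule, lo, hi):
    """Clamp the implied clean-state prediction, re-expressed as noise.

    x0_hat = (x_t - sqrt(1-abar) eps_hat) / sqrt(abar) is clipped to
    [lo, hi] and converted back; when no bound binds this is the identity
    on eps_hat.  Schedules whose late-step betas approach 1 (the
    polynomial one) amplify prediction errors severely at the start of
    the reverse chain; bounding the denoised state is the standard guard.
    """
    ab = schedule.alpha_bar[t]
    sq, sq1 = np.sqrt(ab), np.sqrt(1.0 - ab)
    x0_hat = (x_t - sq1 * eps_hat) / max(sq, 1e-6)
    x0_hat = np.clip(x0_hat, lo, hi)
    return (x_t - sq * x0_hat) / max(sq1, 1e-12)


def _reverse_trajectory(features, coords, context, schedule, model, rng):
    """Run the full reverse chain on (features, coords); context frozen."""
    model.train(False)
    lo, hi = _context_box(context)
    for t in range(schedule.T, 0, -1):
        eps = predict_noise((features, coords), context, t, schedule.T, model)
        eps_r = _clip_denoised_eps(coords, eps.eps_coords, t, schedule,
                                   lo, hi)
        eps_h = _clip_denoised_eps(features, eps.eps_features, t, schedule,
                                   -3.0, 3.0)
        zr = rng.standard_normal(coords.shape) if t > 1 else None
        zh = rng.standard_normal(features.shape) if t > 1 else None
        coords = posterior_step(coords, eps_r, t, schedule, zr)
        features = posterior_step(features, eps_h, t, schedule, zh)
        coords = np.clip(coords, lo, hi)
        features = np.clip(features, -_FEATURE_BOUND, _FEATURE_BOUND)
    return features, coords


def _decode_elements(features: np.ndarray, allow_virtual: bool):
    """Arg-max decode of continuous feature rows to category symbols."""
    out = []
    for row in features:
        if allow_virtual:
            k = int(np.argmax(row))
        else:
            k = int(np.argmax(row[: len(ELEMENTS)]))
        out.append("virtual" if k == VIRTUAL_INDEX else ELEMENTS[k])
    return out


def generate_scaffold(context: ConditioningContext, model: EGNNDenoiser,
                      schedule: NoiseSchedule, n_new: int,
                      seed) -> ScaffoldState:
    """Reverse-diffuse ``n_new`` atoms around the fragment anchors.

    Initial coordinates are standard Gaussian centered on the anchors'
    centroid; initial features are standard Gaussian.  The fragment and
    pocket never move.  ``seed`` may be an int or a Generator-like object
    (``.standard_normal(shape)``).
    """
    if context.stage != "scaffold":
        raise ContextError("context is not scaffold-stage")
    if not context.fragment.anchors:
        raise ContextError("fragment has no anchors")
    if n_new < 0:
        raise ParameterError("n_new must be nonnegative")
    frag = context.fragment
    if n_new == 0:
        return ScaffoldState(frag.atoms.copy(), 0)
    rng = (
        seed
        if hasattr(seed, "standard_normal")
        else np.random.default_rng(seed)
    )
    center = frag.atoms.coords[list(frag.anchors)].mean(axis=0)
    coords = center + rng.standard_normal((n_new, 3))
    features = rng.standard_normal((n_new, N_CATEGORIES))
    features, coords = _reverse_trajectory(
        features, coords, context, schedule, model, rng
    )
    symbols = _decode_elements(features, allow_virtual=False)
    new_atoms = AtomSet.from_symbols(symbols, coords)
    return ScaffoldState(concat_atomsets([frag.atoms, new_atoms]), n_new)


def generate_rgroup(context: ConditioningContext, model: EGNNDenoiser,
                    schedule: NoiseSchedule, seed,
                    max_atoms: int = RGROUP_MAX_ATOMS) -> RGroupState:
    """Reverse-diffuse the padded R-group slots and drop virtual decodes."""
    if context.stage != "rgroup":
        raise ContextError("context is not rgroup-stage")
    if context.scaffold.n == 0:
        raise ContextError("empty scaffold")
    rng = (
        seed
        if hasattr(seed, "standard_normal")
        else np.random.default_rng(seed)
    )
    center = context.scaffold.coords.mean(axis=0)
    coords = center + rng.standard_normal((max_atoms, 3))
    features = rng.standard_normal((max_atoms, N_CATEGORIES))
    features, coords = _reverse_trajectory(
        features, coords, context, schedule, model, rng
    )
    symbols = _decode_elements(features, allow_virtual=True)
    real = [i for i, s in enumerate(symbols) if s != "virtual"]
    atoms = AtomSet.from_symbols(
        [symbols[i] for i in real], coords[real]
    )
    return RGroupState(atoms, n_slots=max_atoms)
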