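"""Denoising diffusion chain that splits a semantic mask into two fields.

The method: given an image I, its foreground mask S and two random fields
A0, B0, a network is trained so that the Markov chain

    A_{i+1} = S * [(1 - w_i) A_i + w_i NN(I, S, A_i, B_i)]   (same for B)

converges to a partition of S in which every instance mask lies wholly in
A_n or wholly in B_n.  The training label for a mask M is the A split iff
sum(A_i * M) >= sum(B_i * M) — the split "chiefly implied by the noise" —
so the object-identity symmetry is broken spontaneously by A0, B0 rather
than by specialized per-object predictors.  The network predicts the clean
sample (the split targets), not the noise.

The time grid is log-scaled, t_i = 10^(10 (i/n - 1)), which reduces to the
reference 100-step grid t_i = 10^(i/10 - 10); blend weights are
w_i = (t_{i+1} - t_i)/(1 - t_i), with the final weight exactly 1 so the
last step fully trusts the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .datamodel import Image, InstanceLabelSet, Scene, SemanticMask, ShapeError
from .nn import Adam, BackboneSpec, ConfigError, UNet, lr_schedule
from .semantic import SemanticModel, bce_grad_through_sigmoid, predict_semantic

_EPS = 1e-7


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Schedule:
    """Time grid t_0..t_n in (0, 1] and blend weights w_0..w_{n-1}."""

    n: int
    t: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        w = np.asarray(self.w, dtype=np.float64)
        if len(t) != self.n + 1 or len(w) != self.n:
            raise ConfigError("schedule arrays have inconsistent lengths")
        if np.any(np.diff(t) <= 0) or abs(t[-1] - 1.0) > 1e-12:
            raise ConfigError("t must be strictly increasing with t_n = 1")
        if np.any(w <= 0) or np.any(w > 1):
            raise ConfigError("weights must lie in (0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "w", w)


def make_schedule(n: int) -> Schedule:
    """Log-scaled schedule with n steps: t_i = 10^(10 (i/n - 1)), i = 0..n."""
    if n < 2:
        raise ConfigError("schedule needs at least 2 steps")
    i = np.arange(n + 1, dtype=np.float64)
    t = 10.0 ** (10.0 * (i / n - 1.0))
    t[-1] = 1.0
    w = (t[1:] - t[:-1]) / (1.0 - t[:-1])
    w[-1] = 1.0  # (1 - t_{n-1}) / (1 - t_{n-1})
    return Schedule(n=n, t=t, w=w)


# ---------------------------------------------------------------------------
# fields and targets
# ---------------------------------------------------------------------------
@dataclass
class SplitFieldPair:
    """The two real-valued fields evolved by the chain; zero on background."""

    A: np.ndarray
    B: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float32)
        self.B = np.asarray(self.B, dtype=np.float32)
        if self.A.shape != self.B.shape or self.A.ndim != 2:
            raise ShapeError("A and B must be 2-D fields of equal shape")


@dataclass(frozen=True)
class SplitTargets:
    """Per-split target fields M^A, M^B.

    Ground-truth targets are binary unions of the masks assigned to each
    split; bootstrap targets are soft fields in [0, 1] (``assignment`` is
    then None).
    """

    MA: np.ndarray
    MB: np.ndarray
    assignment: tuple[str, ...] | None = ()

    def __post_init__(self) -> None:
        ma = np.asarray(self.MA, dtype=np.float32)
        mb = np.asarray(self.MB, dtype=np.float32)
        if ma.shape != mb.shape or ma.ndim != 2:
            raise ShapeError("MA and MB must be 2-D fields of equal shape")
        object.__setattr__(self, "MA", ma)
        object.__setattr__(self, "MB", mb)


def sample_noise_fields(
    shape: tuple[int, int],
    S: SemanticMask,
    mean: float = 0.5,
    sigma: float = 0.25,
    seed: int = 0,
) -> SplitFieldPair:
    """I.i.d. Gaussian fields, clipped to [0, 1] and masked by binary S."""
    if sigma <= 0:
        raise ConfigError("noise sigma must be positive")
    if S.shape != tuple(shape):
        raise ShapeError("S shape does not match requested field shape")
    rng = np.random.default_rng(seed)
    support = S.binary.astype(np.float32)
    a = np.clip(rng.normal(mean, sigma, shape), 0.0, 1.0).astype(np.float32) * support
    b = np.clip(rng.normal(mean, sigma, shape), 0.0, 1.0).astype(np.float32) * support
    return SplitFieldPair(A=a, B=b, step_index=0)


def assign_split_targets(
    fields: SplitFieldPair, labels: InstanceLabelSet
) -> SplitTargets:
    """Label each mask for the A split iff sum(A·M) >= sum(B·M); ties go to A."""
    if len(labels) == 0:
        z = np.zeros_like(fields.A)
        return SplitTargets(MA=z, MB=z.copy(), assignment=())
    if labels.shape != fields.A.shape:
        raise ShapeError("labels and fields have different shapes")
    ma = np.zeros(fields.A.shape, dtype=bool)
    mb = np.zeros(fields.A.shape, dtype=bool)
    assignment = []
    for m in labels:
        px = m.pixels
        if float(fields.A[px].sum()) >= float(fields.B[px].sum()):
            ma |= px
            assignment.append("A")
        else:
            mb |= px
            assignment.append("B")
    return SplitTargets(
        MA=ma.astype(np.float32), MB=mb.astype(np.float32), assignment=tuple(assignment)
    )


def blend_training_fields(
    noise: SplitFieldPair, targets: SplitTargets, w: float
) -> SplitFieldPair:
    """Per-pixel convex combination A = (1 - w) A0 + w M^A (same for B)."""
    if not (0.0 <= w <= 1.0):
        raise ConfigError("blend weight must be in [0, 1]")
    return SplitFieldPair(
        A=(1.0 - w) * noise.A + w * targets.MA,
        B=(1.0 - w) * noise.B + w * targets.MB,
        step_index=0,
    )


def split_loss(
    predA: np.ndarray,
    predB: np.ndarray,
    targets: SplitTargets,
    S: SemanticMask,
    eps: float = _EPS,
) -> float:
    """Foreground-weighted cross-entropy, summed over pixels:
    sum_S [ H(predA, M^A) + H(predB, M^B) ].  Background contributes 0."""
    s = S.pixels
    pa = np.clip(predA, eps, 1.0 - eps)
    pb = np.clip(predB, eps, 1.0 - eps)
    ha = -(targets.MA * np.log(pa) + (1.0 - targets.MA) * np.log1p(-pa))
    hb = -(targets.MB * np.log(pb) + (1.0 - targets.MB) * np.log1p(-pb))
    return float((s * (ha + hb)).sum())


# ---------------------------------------------------------------------------
# inference chain
# ---------------------------------------------------------------------------
def _model_forward(model, x: np.ndarray) -> np.ndarray:
    return model.forward(x, training=False)


def _swap_ab(x: np.ndarray) -> np.ndarray:
    y = x.copy()
    y[:, -2], y[:, -1] = x[:, -1], x[:, -2]
    return y


def _stack_inputs(image: Image, S: SemanticMask, fields: SplitFieldPair) -> np.ndarray:
    return np.concatenate(
        [
            image.pixels.transpose(2, 0, 1),
            S.pixels[None],
            fields.A[None],
            fields.B[None],
        ]
    )[None]


def denoise_step(
    model, image: Image, S: SemanticMask, fields: SplitFieldPair, w_i: float
) -> SplitFieldPair:
    """One chain step: fields <- S * [(1 - w_i) fields + w_i NN(I,S,A,B)]."""
    if not (0.0 <= w_i <= 1.0):
        raise ConfigError("w_i must be in [0, 1]")
    x = _stack_inputs(image, S, fields)
    out = _model_forward(model, x)
    if out.shape[1] != 2:
        raise ConfigError("split model must emit exactly two probability fields")
    s = S.pixels
    a = s * ((1.0 - w_i) * fields.A + w_i * out[0, 0])
    b = s * ((1.0 - w_i) * fields.B + w_i * out[0, 1])
    return SplitFieldPair(A=a, B=b, step_index=fields.step_index + 1)


def run_denoising_chain(
    model,
    image: Image,
    S: SemanticMask,
    schedule: Schedule,
    seed: int = 0,
    noise_mean: float = 0.5,
    noise_sigma: float = 0.25,
) -> SplitFieldPair:
    """Maximum-likelihood chain: noise is sampled only at i = 0, then every
    step applies the deterministic update; the final step has w = 1 so the
    output is S times the network prediction."""
    fields = sample_noise_fields(S.shape, S, noise_mean, noise_sigma, seed)
    for w_i in schedule.w:
        fields = denoise_step(model, image, S, fields, float(w_i))
    return fields


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class DiffusionTrainConfig:
    """Training settings for the split network.

    ``p_w_zero`` puts an explicit probability atom on w = 0 (pure-noise
    inputs, where the symmetry is actually broken); ``p_bootstrap`` replaces
    ground-truth targets with the gradient-stopped model output on the noise
    so the chain learns to correct bad initial guesses; ``p_label_drop``
    removes instances from S during sample construction so the model also
    sees foregrounds with missing objects.
    """

    schedule: Schedule = field(default_factory=lambda: make_schedule(100))
    p_w_zero: float = 0.3
    p_bootstrap: float = 0.25
    p_label_drop: float = 0.3
    batch_size: int = 16
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    steps: int = 600
    noise_mean: float = 0.5
    noise_sigma: float = 0.25
    binarize_s_input: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_w_zero", "p_bootstrap", "p_label_drop"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (self.lr_start >= self.lr_end > 0):
            raise ConfigError("need lr_start >= lr_end > 0")
        if self.noise_sigma <= 0:
            raise ConfigError("noise_sigma must be positive")


class TrainingSample(NamedTuple):
    inputs: np.ndarray  # (C+3, H, W): image, S, A, B
    targets: SplitTargets
    w: float
    noise: SplitFieldPair
    s_used: SemanticMask
    labels: InstanceLabelSet


def make_training_sample(
    scene: Scene,
    predicted_S: SemanticMask,
    cfg: DiffusionTrainConfig,
    rng: np.random.Generator,
) -> TrainingSample:
    """Build one training record.

    The image is untouched.  S starts from ``predicted_S``; each instance is
    dropped with probability ``p_label_drop`` (its exclusive pixels zeroed in
    S and the instance removed from the target labels).  Noise fields are
    sampled on the resulting support, split targets are assigned from the
    noise, and the network input fields are the w-blend of noise and targets,
    with w = 0 drawn with probability ``p_w_zero`` and otherwise a schedule
    weight at a uniform step index.
    """
    if len(scene.labels) == 0:
        raise ValueError("scene has no labels")
    masks = list(scene.labels)
    for _ in range(20):
        keep = [m for m in masks if rng.random() >= cfg.p_label_drop]
        if keep:
            break
    else:
        raise RuntimeError("label drop removed all instances in every retry")

    s_px = predicted_S.pixels.copy()
    if len(keep) < len(masks):
        kept_union = np.zeros(s_px.shape, dtype=bool)
        for m in keep:
            kept_union |= m.pixels
        dropped = np.zeros(s_px.shape, dtype=bool)
        for m in masks:
            if all(m is not k for k in keep):
                dropped |= m.pixels
        s_px[dropped & ~kept_union] = 0.0
    if cfg.binarize_s_input:
        s_px = (s_px >= 0.5).astype(np.float32)
    s_used = SemanticMask(s_px)
    labels = InstanceLabelSet(tuple(keep))

    noise = sample_noise_fields(
        s_used.shape, s_used, cfg.noise_mean, cfg.noise_sigma,
        seed=int(rng.integers(2**31)),
    )
    targets = assign_split_targets(noise, labels)
    if rng.random() < cfg.p_w_zero:
        w = 0.0
    else:
        w = float(cfg.schedule.w[int(rng.integers(cfg.schedule.n))])
    blended = blend_training_fields(noise, targets, w)
    inputs = _stack_inputs(scene.image, s_used, blended)[0]
    return TrainingSample(inputs, targets, w, noise, s_used, labels)


def bootstrap_targets(
    model, image: Image, S: SemanticMask, noise: SplitFieldPair, labels=None
) -> SplitTargets:
    """Replacement targets: the model's own (gradient-stopped) output on the
    pure-noise fields, masked by S.  The forward pass runs in evaluation
    mode and caches nothing, so no gradient can flow through it."""
    out = _model_forward(model, _stack_inputs(image, S, noise))
    s = S.pixels
    return SplitTargets(
        MA=np.clip(out[0, 0] * s, 0.0, 1.0),
        MB=np.clip(out[0, 1] * s, 0.0, 1.0),
        assignment=None,
    )


class SplitModel:
    """Trained split network plus the inference-time noise parameters.

    The two output fields share one set of weights: the underlying network
    predicts a single field M^A from (I, S, A, B), and the B field is the
    same network applied with the A and B input channels swapped.  This
    makes the predictor exactly equivariant under relabeling the two splits
    — the A/B symmetry is then broken only by the input fields, never by a
    bias learned into separate output heads.  (A two-output-channel network
    is also accepted and run in a single pass.)
    """

    def __init__(self, unet: UNet, noise_mean: float = 0.5, noise_sigma: float = 0.25):
        self.unet = unet
        self.noise_mean = noise_mean
        self.noise_sigma = noise_sigma
        self.loss_trace: list[float] = []

    @property
    def twin(self) -> bool:
        return self.unet.spec.out_channels == 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not self.twin:
            return self.unet.forward(x, training)
        pa = self.unet.forward(x, training=False)
        pb = self.unet.forward(_swap_ab(x), training=False)
        return np.concatenate([pa, pb], axis=1)

    @property
    def spec(self) -> BackboneSpec:
        return self.unet.spec

    def save(self, path: str | Path) -> None:
        self.unet.save(path)

    @classmethod
    def load(cls, path: str | Path, noise_mean: float = 0.5, noise_sigma: float = 0.25):
        return cls(UNet.load(path), noise_mean, noise_sigma)


def train_split_model(
    scenes: list[Scene],
    spec: BackboneSpec,
    cfg: DiffusionTrainConfig,
    semantic_model: SemanticModel | None = None,
) -> SplitModel:
    """Optimize the split loss over constructed samples.

    S comes from ``semantic_model`` predictions when given, else from the
    ground-truth union (useful for isolating this module).  The network
    predicts the sample (the split targets), not the noise.  Deterministic
    given ``cfg.seed``; per-step normalized loss on ``model.loss_trace``.
    """
    if not scenes:
        raise ConfigError("no training scenes")
    c = scenes[0].image.n_channels
    if spec.in_channels != c + 3:
        raise ConfigError(
            f"split network needs C+3={c + 3} input channels, spec has {spec.in_channels}"
        )
    if spec.out_channels != 2:
        raise ConfigError("split network must have 2 output channels")

    rng = np.random.default_rng(cfg.seed)
    # shared-weight twin: one output field, the other by swapping A and B
    unet = UNet(replace(spec, out_channels=1), seed=int(rng.integers(2**31)))
    model = SplitModel(unet, cfg.noise_mean, cfg.noise_sigma)

    if semantic_model is not None:
        s_pred = [predict_semantic(semantic_model, s.image) for s in scenes]
    else:
        s_pred = [s.semantic for s in scenes]

    opt = Adam(unet.parameters())
    lr_at = lr_schedule(cfg.lr_start, cfg.lr_end, cfg.steps)
    for step in range(cfg.steps):
        idx = rng.integers(0, len(scenes), size=cfg.batch_size)
        samples = []
        for i in idx:
            smp = make_training_sample(scenes[i], s_pred[i], cfg, rng)
            if rng.random() < cfg.p_bootstrap:
                # replace the M^A/M^B used to build the blended input with the
                # model's own gradient-stopped prediction on the raw noise:
                # the input then looks like a chain state reached from a bad
                # initial guess, and the loss (still against the noise-implied
                # assignment) teaches the model to correct it
                boot = bootstrap_targets(
                    model, scenes[i].image, smp.s_used, smp.noise, smp.labels
                )
                blended = blend_training_fields(smp.noise, boot, smp.w)
                inputs = smp.inputs.copy()
                inputs[-2] = blended.A
                inputs[-1] = blended.B
                smp = smp._replace(inputs=inputs)
            samples.append(smp)

        x = np.stack([s.inputs for s in samples])
        ta = np.stack([s.targets.MA for s in samples])
        tb = np.stack([s.targets.MB for s in samples])
        sw = np.stack([s.s_used.pixels for s in samples])

        norm = max(float(sw.sum()), 1.0)
        unet.zero_grad()
        # two weight-sharing passes: (…, A, B) predicts M^A, (…, B, A)
        # predicts M^B; gradients from both accumulate into the same weights
        pa = unet.forward(x, training=True)[:, 0]
        unet.backward(bce_grad_through_sigmoid(pa, ta, sw / norm)[:, None])
        pb = unet.forward(_swap_ab(x), training=True)[:, 0]
        unet.backward(bce_grad_through_sigmoid(pb, tb, sw / norm)[:, None])
        opt.step(lr_at(step))

        pa = np.clip(pa, _EPS, 1 - _EPS)
        pb = np.clip(pb, _EPS, 1 - _EPS)
        loss = float(
            (
                sw
                * (
                    -(ta * np.log(pa) + (1 - ta) * np.log1p(-pa))
                    - (tb * np.log(pb) + (1 - tb) * np.log1p(-pb))
                )
            ).sum()
            / norm
        )
        model.loss_trace.append(loss)
    return model
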