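"""Progressive context-encoder GAN: growth, inpainting training, freezing.

The generator is an encoder--decoder trained to inpaint a masked square
of a normal-tissue patch: the network only ever sees normal tissue, so
after freezing, its reconstructions of anomalous tissue carry large
errors — the signal the downstream anomaly model consumes.

Both networks grow progressively.  Training starts at 4x4 and doubles
the working resolution, blending each new resolution in through a
fade-in weight alpha that ramps linearly from 0 to 1 in images seen:
at alpha = 0 the grown network reproduces, exactly, the previous
network's output upsampled by nearest neighbor (generator) or applied
to the average-pooled input (discriminator), so growth never perturbs
what has been learned.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor, blend
from .wsi_tiling import Patch, read_record_shards

__all__ = [
    "NetworkConfig", "GrowthState", "InpaintSpec", "FrozenModel",
    "TrainingError", "fade_in_blend", "apply_inpaint_mask",
    "Generator", "Discriminator", "grow_generator", "train_phase1",
    "reconstruct", "save_model", "load_model",
]


class TrainingError(RuntimeError):
    pass


def default_channels(max_resolution: int) -> dict[int, int]:
    """Channel schedule: wider at coarse levels, halving as resolution grows."""
    sched, c, level = {}, 32, 4
    while level <= max_resolution:
        sched[level] = max(c, 4)
        c //= 2 if level >= 16 else 1
        level *= 2
    return sched


@dataclass
class NetworkConfig:
    """Hyperparameters shared by generator and discriminator.

    ``lambda_rec`` weights the mean absolute reconstruction error over
    the whole patch; ``lambda_adv`` weights the least-squares adversarial
    term (set 0 for a pure context encoder).
    """

    max_resolution: int = 32
    channels: dict[int, int] | None = None
    bottleneck: int = 32
    lambda_rec: float = 1.0
    lambda_adv: float = 0.05
    adv_loss: str = "lsgan"          # or "wgan-gp" (not implemented at desk scale)
    learning_rate: float = 2e-3
    batch_size: int = 16

    def __post_init__(self):
        m = self.max_resolution
        if m < 4 or (m & (m - 1)) != 0 or m > 1024:
            raise ValueError("max_resolution must be a power of two in [4, 1024]")
        if self.channels is None:
            self.channels = default_channels(m)
        level = 4
        while level <= m:
            if level not in self.channels:
                raise ValueError(f"channel schedule missing level {level}")
            level *= 2

    def ladder(self) -> list[int]:
        out, level = [], 4
        while level <= self.max_resolution:
            out.append(level)
            level *= 2
        return out


@dataclass
class GrowthState:
    """Where progressive training currently stands."""

    level: int = 4
    alpha: float = 1.0
    images_seen: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class InpaintSpec:
    """Centered-square inpainting mask.

    ``mask_fraction`` f is the masked side as a fraction of the patch
    side; the masked square is filled with ``fill`` (RGB triple in
    [0, 1], typically the training-set mean color).
    """

    mask_fraction: float = 0.5
    fill: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in (0, 1]")

    def mask_for(self, size: int) -> np.ndarray:
        side = int(round(size * self.mask_fraction))
        m = np.zeros((size, size), dtype=bool)
        if side > 0:
            lo = (size - side) // 2
            m[lo : lo + side, lo : lo + side] = True
        return m


def fade_in_blend(prev_output: np.ndarray, new_output: np.ndarray,
                  alpha: float) -> np.ndarray:
    """(1 - alpha) * prev + alpha * new, elementwise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    prev_output = np.asarray(prev_output)
    new_output = np.asarray(new_output)
    if prev_output.shape != new_output.shape:
        raise ValueError("blend inputs must share a shape")
    return (1.0 - alpha) * prev_output + alpha * new_output


def apply_inpaint_mask(patch: Patch, spec: InpaintSpec) -> tuple[Patch, np.ndarray]:
    """Fill the centered square with the spec's fill color.

    Returns the masked patch and the boolean mask (True inside the
    square); pixels outside are untouched.
    """
    mask = spec.mask_for(patch.level_size)
    img = patch.image.copy()
    img[mask] = np.clip(spec.fill, 0.0, 1.0)
    return Patch(image=img, slide=patch.slide, origin=patch.origin), mask


class Generator:
    """Encoder--decoder inpainting generator with progressive fade-in.

    Parameters per resolution level l: ``fromRGB[l]`` (1x1, 3->C(l)) and
    ``enc[l]`` (3x3, C(l)->C(l/2)) on the way down; ``dec[l]`` (3x3,
    C(l/2)->C(l), after nearest upsampling) and ``toRGB[l]`` (1x1,
    C(l)->3, sigmoid) on the way up; a 3x3 bottleneck at 4x4.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        C = config.channels
        self.params: dict[str, _nn.Parameter] = {}

        def add(name, pair):
            self.params[name + ".w"], self.params[name + ".b"] = pair

        for l in config.ladder():
            add(f"fromRGB{l}", _nn.he_conv(rng, C[l], 3, 1))
            add(f"toRGB{l}", _nn.he_conv(rng, 3, C[l], 1))
            if l > 4:
                add(f"enc{l}", _nn.he_conv(rng, C[l // 2], C[l], 3))
                add(f"dec{l}", _nn.he_conv(rng, C[l], C[l // 2], 3))
        add("bottleneck", _nn.he_conv(rng, C[4], C[4], 3))

    def _p(self, name):
        return self.params[name + ".w"], self.params[name + ".b"]

    def forward(self, x: Tensor, level: int, alpha: float) -> Tensor:
        """x: (n, 3, level, level) in [0, 1] -> reconstruction, same shape."""
        if level > self.config.max_resolution:
            raise ValueError(f"level {level} above max resolution")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        C = self.config.channels
        # encoder with input-side fade-in
        if level == 4:
            h = _nn.leaky_relu(_nn.conv2d(x, *self._p("fromRGB4")))
        else:
            new = _nn.leaky_relu(_nn.conv2d(x, *self._p(f"fromRGB{level}")))
            new = _nn.avg_pool2(_nn.leaky_relu(_nn.conv2d(new, *self._p(f"enc{level}"))))
            if alpha < 1.0:
                old = _nn.leaky_relu(
                    _nn.conv2d(_nn.avg_pool2(x), *self._p(f"fromRGB{level // 2}")))
                h = blend(old, new, alpha)
            else:
                h = new
            l = level // 2
            while l > 4:
                h = _nn.avg_pool2(_nn.leaky_relu(_nn.conv2d(h, *self._p(f"enc{l}"))))
                l //= 2
        h = _nn.leaky_relu(_nn.conv2d(h, *self._p("bottleneck")))
        # decoder with output-side fade-in
        feats = {4: h}
        l = 4
        while l < level:
            h = _nn.leaky_relu(
                _nn.conv2d(_nn.upsample_nearest2(h), *self._p(f"dec{2 * l}")))
            l *= 2
            feats[l] = h
        if level == 4 or alpha >= 1.0:
            return _nn.sigmoid(_nn.conv2d(h, *self._p(f"toRGB{level}")))
        rgb_new = _nn.sigmoid(_nn.conv2d(feats[level], *self._p(f"toRGB{level}")))
        rgb_old = _nn.upsample_nearest2(
            _nn.sigmoid(_nn.conv2d(feats[level // 2], *self._p(f"toRGB{level // 2}"))))
        return blend(rgb_old, rgb_new, alpha)

    def __call__(self, images: np.ndarray, level: int, alpha: float = 1.0) -> np.ndarray:
        """Inference on (n, level, level, 3) HWC float arrays in [0, 1]."""
        x = Tensor(np.transpose(images, (0, 3, 1, 2)))
        out = self.forward(x, level, alpha)
        return np.transpose(out.data, (0, 2, 3, 1)).astype(np.float64)


class Discriminator:
    """Patch critic with the mirrored progressive input fade-in."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        C = config.channels
        self.params: dict[str, _nn.Parameter] = {}

        def add(name, pair):
            self.params[name + ".w"], self.params[name + ".b"] = pair

        for l in config.ladder():
            add(f"fromRGB{l}", _nn.he_conv(rng, C[l], 3, 1))
            if l > 4:
                add(f"down{l}", _nn.he_conv(rng, C[l // 2], C[l], 3))
        add("final", _nn.he_conv(rng, C[4], C[4], 3))
        add("score", _nn.he_dense(rng, 1, C[4] * 16))

    def _p(self, name):
        return self.params[name + ".w"], self.params[name + ".b"]

    def forward(self, x: Tensor, level: int, alpha: float) -> Tensor:
        if level == 4:
            h = _nn.leaky_relu(_nn.conv2d(x, *self._p("fromRGB4")))
        else:
            new = _nn.leaky_relu(_nn.conv2d(x, *self._p(f"fromRGB{level}")))
            new = _nn.avg_pool2(_nn.leaky_relu(_nn.conv2d(new, *self._p(f"down{level}"))))
            if alpha < 1.0:
                old = _nn.leaky_relu(
                    _nn.conv2d(_nn.avg_pool2(x), *self._p(f"fromRGB{level // 2}")))
                h = blend(old, new, alpha)
            else:
                h = new
            l = level // 2
            while l > 4:
                h = _nn.avg_pool2(_nn.leaky_relu(_nn.conv2d(h, *self._p(f"down{l}"))))
                l //= 2
        h = _nn.leaky_relu(_nn.conv2d(h, *self._p("final")))
        return _nn.dense(_nn.flatten(h), *self._p("score"))


def grow_generator(config: NetworkConfig, state: GrowthState,
                   generator: Generator | None = None, seed: int = 0):
    """Return a callable generator at the growth state's level and alpha.

    If no trained generator is given, a fresh seeded one is built — the
    call is then useful for structural checks (fade-in identity).
    """
    if state.level > config.max_resolution:
        raise ValueError(
            f"growth level {state.level} above max resolution {config.max_resolution}")
    gen = generator or Generator(config, np.random.default_rng(seed))

    def run(images: np.ndarray) -> np.ndarray:
        return gen(images, state.level, state.alpha)

    run.generator = gen
    return run


@dataclass
class FrozenModel:
    """Trained, frozen generator plus everything needed to reuse it."""

    config: NetworkConfig
    state: GrowthState
    inpaint: InpaintSpec
    seed: int
    gen_params: dict = field(repr=False, default_factory=dict)
    disc_params: dict = field(repr=False, default_factory=dict)

    def _generator(self) -> Generator:
        g = Generator(self.config, np.random.default_rng(self.seed))
        for k, v in self.gen_params.items():
            g.params[k].data = v.copy()
        return g

    @property
    def resolution(self) -> int:
        return self.state.level

    def reconstruct(self, patch: Patch) -> Patch:
        return reconstruct(self, patch)


def reconstruct(model: FrozenModel, patch: Patch) -> Patch:
    """Inpaint-reconstruct a patch with the frozen generator.

    The model's inpaint mask is applied, the generator fills it, and the
    result is composited: unmasked pixels come from the input verbatim,
    masked pixels from the generator.  Deterministic across calls.
    """
    if patch.level_size != model.resolution:
        raise ValueError(
            f"patch level {patch.level_size} != model resolution {model.resolution}")
    masked, mask = apply_inpaint_mask(patch, model.inpaint)
    gen = model._generator()
    out = gen(masked.image[None], model.resolution, 1.0)[0]
    composite = patch.image.copy()
    composite[mask] = np.clip(out[mask], 0.0, 1.0)
    return Patch(image=composite, slide=patch.slide, origin=patch.origin)


def _load_level_arrays(records, ladder) -> dict[int, np.ndarray]:
    """Materialize record-store patches per level as (n, s, s, 3) arrays."""
    if isinstance(records, dict):
        return {l: np.asarray(v, dtype=np.float64) for l, v in records.items()}
    paths = sorted(Path(records).glob("*.rec"))
    by_level: dict[int, list[np.ndarray]] = {l: [] for l in ladder}
    for patch in read_record_shards(paths):
        if patch.level_size in by_level:
            by_level[patch.level_size].append(patch.image)
    return {l: np.stack(v) if v else np.empty((0, l, l, 3)) for l, v in by_level.items()}


def train_phase1(records, config: NetworkConfig, budget_per_level: int,
                 seed: int, inpaint: InpaintSpec | None = None,
                 log=None) -> FrozenModel:
    """Phase 1: progressive inpainting training on normal patches only.

    ``records`` is a record-store directory (or a {level: array} mapping
    of (n, s, s, 3) patches).  For every level of the ladder the loop
    runs a fade-in sub-phase (alpha ramping linearly 0 -> 1 over
    ``budget_per_level`` images seen; skipped at 4x4 where there is
    nothing to fade from) followed by a stabilization sub-phase at
    alpha = 1 of the same budget.  Per step the generator minimizes
    lambda_rec * L1(reconstruction, input) + lambda_adv * LSGAN term,
    and the discriminator (when lambda_adv > 0) its LSGAN counterpart.
    Deterministic given the seed.  Returns the frozen model.
    """
    if budget_per_level <= 0:
        raise TrainingError("per-level image budget must be positive")
    ladder = config.ladder()
    data = _load_level_arrays(records, ladder)
    for l in ladder:
        if l not in data or len(data[l]) == 0:
            raise TrainingError(f"record store has no patches at level {l}")

    rng = np.random.default_rng(seed)
    gen = Generator(config, rng)
    disc = Discriminator(config, rng)
    if inpaint is None:
        inpaint = InpaintSpec(fill=tuple(data[ladder[-1]].mean(axis=(0, 1, 2))))
    opt_g = _nn.Adam(gen.params.values(), lr=config.learning_rate)
    opt_d = _nn.Adam(disc.params.values(), lr=config.learning_rate)
    bs = config.batch_size
    state = GrowthState(level=4, alpha=1.0, images_seen=0)

    def masked_batch(level, n):
        idx = rng.integers(0, len(data[level]), size=n)
        real = data[level][idx]
        m = inpaint.mask_for(level)
        masked = real.copy()
        masked[:, m] = np.clip(inpaint.fill, 0.0, 1.0)
        to_nchw = lambda a: np.ascontiguousarray(np.transpose(a, (0, 3, 1, 2)), dtype=np.float32)
        return to_nchw(real), to_nchw(masked)

    def train_subphase(level, fade, budget):
        seen = 0
        while seen < budget:
            n = min(bs, budget - seen)
            alpha = min(seen / budget, 1.0) if fade else 1.0
            real, masked = masked_batch(level, n)
            x_real = Tensor(real)
            fake = gen.forward(Tensor(masked), level, alpha)
            rec = _nn.mean_abs(fake - x_real)
            if config.lambda_adv > 0:
                d_fake_for_g = disc.forward(fake, level, alpha)
                # LSGAN generator target: D(fake) -> 1
                adv_g = _nn.mean_square(d_fake_for_g - Tensor(np.ones_like(d_fake_for_g.data)))
                loss_g = rec.scale(config.lambda_rec) + adv_g.scale(config.lambda_adv)
            else:
                loss_g = rec.scale(config.lambda_rec)
            if not np.isfinite(loss_g.data):
                raise TrainingError(
                    f"non-finite generator loss at level {level}, alpha {alpha:.3f}")
            opt_d.zero_grad()
            loss_g.backward()
            opt_d.zero_grad()          # discriminator does not follow G's gradient
            opt_g.step()
            if config.lambda_adv > 0:
                d_real = disc.forward(Tensor(real), level, alpha)
                d_fake = disc.forward(Tensor(fake.data), level, alpha)
                loss_d = (_nn.mean_square(d_real - Tensor(np.ones_like(d_real.data)))
                          + _nn.mean_square(d_fake)).scale(0.5)
                if not np.isfinite(loss_d.data):
                    raise TrainingError(
                        f"non-finite discriminator loss at level {level}")
                opt_g.zero_grad()
                loss_d.backward()
                opt_g.zero_grad()
                opt_d.step()
            seen += n
            state.images_seen += n
            if log is not None:
                log(level=level, alpha=alpha, rec=float(rec.data))
        return seen

    for level in ladder:
        state.level = level
        if level > 4:
            state.alpha = 0.0
            train_subphase(level, fade=True, budget=budget_per_level)
        state.alpha = 1.0
        train_subphase(level, fade=False, budget=budget_per_level)

    return FrozenModel(
        config=config,
        state=GrowthState(level=ladder[-1], alpha=1.0, images_seen=state.images_seen),
        inpaint=inpaint,
        seed=seed,
        gen_params={k: p.data.copy() for k, p in gen.params.items()},
        disc_params={k: p.data.copy() for k, p in disc.params.items()},
    )


# -- checkpoint I/O: zip of npz parameter blobs + a JSON manifest ----------

CKPT_VERSION = 1


def save_model(model: FrozenModel, path) -> None:
    path = Path(path)
    meta = {
        "version": CKPT_VERSION,
        "config": {**asdict(model.config)},
        "state": asdict(model.state),
        "inpaint": {"mask_fraction": model.inpaint.mask_fraction,
                    "fill": list(model.inpaint.fill)},
        "seed": model.seed,
    }
    meta["config"]["channels"] = {str(k): v for k, v in model.config.channels.items()}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for group, params in (("gen", model.gen_params), ("disc", model.disc_params)):
            buf = io.BytesIO()
            np.savez(buf, **params)
            zf.writestr(f"{group}.npz", buf.getvalue())


def load_model(path) -> FrozenModel:
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["version"] != CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = meta["config"]
        cfg["channels"] = {int(k): v for k, v in cfg["channels"].items()}
        params = {}
        for group in ("gen", "disc"):
            with np.load(io.BytesIO(zf.read(f"{group}.npz"))) as z:
                params[group] = {k: z[k] for k in z.files}
    return FrozenModel(
        config=NetworkConfig(**cfg),
        state=GrowthState(**meta["state"]),
        inpaint=InpaintSpec(mask_fraction=meta["inpaint"]["mask_fraction"],
                            fill=tuple(meta["inpaint"]["fill"])),
        seed=meta["seed"],
        gen_params=params["gen"],
        disc_params=params["disc"],
    )
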