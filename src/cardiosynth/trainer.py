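"""Preprocessing, augmentation and the adversarial training loop.

Training alternates critic and generator updates under a warm-up schedule:
for the first ``warmup_epochs`` epochs the critic takes
``critic_updates_warmup`` steps per generator step (it must stay close to
optimal for the Wasserstein estimate to be meaningful), afterwards
``critic_updates_main``.  Both networks use AdamW.  Covariate gaps are drawn
uniformly and truncated so the target covariate stays inside the cohort
range.  Checkpoints carry parameters, optimizer moments, config and rng
state, so an interrupted run resumes bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from ._rng import stream
from .networks import CriticNet, GeneratorNet, NetConfig, toy_config
from .nn import AdamW, grad
from .objectives import LossWeights, critic_loss_t, generator_loss_t

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 12
    warmup_epochs: int = 20
    critic_updates_warmup: int = 50
    critic_updates_main: int = 5
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    betas: tuple = (0.9, 0.999)
    crop_pixels_x: int = 90
    target_size: int = 128
    gap_min: float = -25.0
    gap_max: float = 25.0
    lambda_gp: float = 10.0
    lambda_cc: float = 1.0
    augment: bool = True
    covariate: str = "age"          # column used as the conditioning scalar
    steps_per_epoch: int | None = None   # cap generator steps (small runs)
    seed: int = 0
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self):
        for name in ("epochs", "batch_size", "warmup_epochs",
                     "critic_updates_warmup", "critic_updates_main"):
            if getattr(self, name) < 1 and name != "warmup_epochs":
                raise ValueError(f"{name} must be positive")
        div = 2 ** (self.net.levels - 1)
        if self.target_size % div:
            raise ValueError(
                f"target_size {self.target_size} not divisible by {div}")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(gp=self.lambda_gp, cc=self.lambda_cc)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["betas"] = list(self.betas)
        d["net"] = self.net.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["betas"] = tuple(d.get("betas", (0.9, 0.999)))
        d["net"] = NetConfig.from_dict(d["net"])
        return cls(**d)


def toy_train_config(image_size: int = 32, **overrides) -> TrainConfig:
    """CPU-scale configuration for phantom experiments."""
    defaults = dict(
        epochs=8, batch_size=8, warmup_epochs=1, critic_updates_warmup=10,
        critic_updates_main=3, learning_rate=2e-4, target_size=image_size,
        steps_per_epoch=8, net=toy_config(image_size))
    defaults.update(overrides)
    return TrainConfig(**defaults)


# ---------------------------------------------------------------------------
# preprocessing & augmentation
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, crop_pixels_x: int = 90,
               target_size: int = 128) -> np.ndarray:
    """Center-crop ``crop_pixels_x`` total columns, resize, min-max rescale.

    The crop removes half the columns from each side (an odd count removes
    the extra column from the right, favoring the left half).  Constant
    images map to all-zeros rather than dividing by zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("preprocess expects a single 2-D grayscale image")
    h, w = image.shape
    if w <= crop_pixels_x:
        raise ValueError(
            f"image width {w} must exceed crop of {crop_pixels_x} px")
    left = crop_pixels_x // 2
    right = crop_pixels_x - left
    image = image[:, left:w - right]
    if image.shape != (target_size, target_size):
        image = _sk_resize(image, (target_size, target_size), order=1,
                           preserve_range=True, anti_aliasing=False)
    lo, hi = image.min(), image.max()
    if hi - lo < 1e-12:
        return np.zeros((target_size, target_size), dtype=np.float32)
    return ((image - lo) / (hi - lo)).astype(np.float32)


def _bias_field(shape, rng, strength=0.15):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy / max(h - 1, 1) * 2 - 1
    xx = xx / max(w - 1, 1) * 2 - 1
    c = rng.uniform(-strength, strength, 5)
    return 1.0 + c[0] * xx + c[1] * yy + c[2] * xx * yy + c[3] * xx ** 2 \
        + c[4] * yy ** 2


def _histogram_shift(image, rng, n_points=5, strength=0.08):
    xs = np.linspace(0.0, 1.0, n_points)
    ys = xs + rng.uniform(-strength, strength, n_points)
    ys[0], ys[-1] = 0.0, 1.0
    ys = np.maximum.accumulate(ys)            # monotone => rank-preserving
    return np.interp(image, xs, ys)


def augment(image: np.ndarray, rng_seed: int = 0) -> np.ndarray:
    """Random bias field, histogram shift and contrast (gamma) adjustment,
    each applied with probability 0.5; output clipped back to [0, 1]."""
    rng = np.random.default_rng(rng_seed)
    out = np.asarray(image, dtype=np.float64)
    if rng.uniform() < 0.5:
        out = out * _bias_field(out.shape, rng)
    if rng.uniform() < 0.5:
        out = _histogram_shift(np.clip(out, 0, 1), rng)
    if rng.uniform() < 0.5:
        gamma = rng.uniform(0.7, 1.4)
        out = np.clip(out, 0, 1) ** gamma
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def critic_schedule(epoch: int, warmup_epochs: int = 20,
                    updates_warmup: int = 50, updates_main: int = 5) -> int:
    """Critic updates per generator update at a given epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return updates_warmup if epoch < warmup_epochs else updates_main


# ---------------------------------------------------------------------------
# batch sampling
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """In-memory training set: images stacked (N, H, W), covariates (N,)."""

    images: np.ndarray
    covariates: np.ndarray

    def __post_init__(self):
        if len(self.images) != len(self.covariates):
            raise ValueError("images/covariates length mismatch")
        if len(self.images) == 0:
            raise ValueError("empty dataset")
        self.covariates = np.asarray(self.covariates, dtype=np.float64)

    @property
    def cov_range(self):
        return float(self.covariates.min()), float(self.covariates.max())

    @classmethod
    def from_cohort(cls, cohort, covariate="age", split="train"):
        sub = cohort.split(split) if split else cohort
        if len(sub) == 0:
            raise ValueError(f"cohort has no rows in split {split!r}")
        images, _ = sub.load_arrays()
        return cls(images, sub.table[covariate].to_numpy(dtype=np.float64))

    @classmethod
    def from_samples(cls, samples, covariate="age"):
        images = np.stack([s.image for s in samples])
        cov = np.array([getattr(s, covariate) for s in samples], dtype=float)
        return cls(images, cov)


def sample_gaps(a_s: np.ndarray, gap_min: float, gap_max: float,
                cov_range: tuple, rng: np.random.Generator,
                max_tries: int = 100) -> np.ndarray:
    """Uniform gaps, truncated so a_s + gap stays inside the cohort range."""
    lo, hi = cov_range
    gaps = rng.uniform(gap_min, gap_max, len(a_s))
    for _ in range(max_tries):
        bad = (a_s + gaps < lo) | (a_s + gaps > hi)
        if not bad.any():
            return gaps
        gaps[bad] = rng.uniform(gap_min, gap_max, int(bad.sum()))
    return np.clip(gaps, lo - a_s, hi - a_s)


def sample_training_pair(data: ArrayDataset, gap_config: dict,
                         rng: np.random.Generator, batch_size: int = 12,
                         augment_seed: int | None = None):
    """One training draw: a source batch with gaps, plus an independent real
    batch presented with its own true covariates."""
    n = len(data.images)
    idx_s = rng.integers(0, n, batch_size)
    idx_r = rng.integers(0, n, batch_size)
    x_s = data.images[idx_s].copy()
    x_r = data.images[idx_r].copy()
    if augment_seed is not None:
        for i in range(batch_size):
            x_s[i] = augment(x_s[i], augment_seed + 2 * i)
            x_r[i] = augment(x_r[i], augment_seed + 2 * i + 1)
    a_s = data.covariates[idx_s]
    a_r = data.covariates[idx_r]
    gaps = sample_gaps(a_s, gap_config.get("min", -25.0),
                       gap_config.get("max", 25.0), data.cov_range, rng)
    return x_s, a_s, gaps, x_r, a_r


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator, critic, config: TrainConfig,
                    opt_g: AdamW, opt_c: AdamW, rng: np.random.Generator,
                    epoch: int, history: list) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, a in enumerate(generator.state_arrays()):
        arrays[f"g_{i}"] = a
    for i, a in enumerate(critic.state_arrays()):
        arrays[f"c_{i}"] = a
    for tag, opt in (("og", opt_g), ("oc", opt_c)):
        st = opt.state()
        for i, a in enumerate(st["m"]):
            arrays[f"{tag}_m_{i}"] = a
        for i, a in enumerate(st["v"]):
            arrays[f"{tag}_v_{i}"] = a
        arrays[f"{tag}_t"] = np.asarray(st["t"])
    meta = {"version": CHECKPOINT_VERSION, "epoch": epoch,
            "config": config.to_dict(), "rng_state": rng.bit_generator.state,
            "history": history}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns (generator, critic, config, state dict)."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        arrays = {k: z[k] for k in z.files if k != "meta"}
    config = TrainConfig.from_dict(meta["config"])
    init_rng = np.random.default_rng(0)
    generator = GeneratorNet(config.net, init_rng)
    critic = CriticNet(config.net, init_rng)
    generator.load_state_arrays(
        [arrays[f"g_{i}"] for i in range(sum(1 for k in arrays
                                             if k.startswith("g_")))])
    critic.load_state_arrays(
        [arrays[f"c_{i}"] for i in range(sum(1 for k in arrays
                                             if k.startswith("c_")))])
    state = {"epoch": meta["epoch"], "rng_state": meta["rng_state"],
             "history": meta["history"], "arrays": arrays}
    return generator, critic, config, state


@dataclass
class TrainResult:
    generator: GeneratorNet
    critic: CriticNet
    config: TrainConfig
    history: pd.DataFrame
    checkpoint_path: Path | None


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _make_optimizers(generator, critic, cfg: TrainConfig):
    opt_g = AdamW(generator.parameters(), lr=cfg.learning_rate,
                  betas=cfg.betas, weight_decay=cfg.weight_decay)
    opt_c = AdamW(critic.parameters(), lr=cfg.learning_rate,
                  betas=cfg.betas, weight_decay=cfg.weight_decay)
    return opt_g, opt_c


def train(config: TrainConfig, data: ArrayDataset | object,
          out_dir=None, resume_from=None, log=None) -> TrainResult:
    """Run the alternating WGAN-GP + cycle training loop.

    ``data`` is an :class:`ArrayDataset` or a cohort table (its train split
    is used).  If ``out_dir`` is given, a checkpoint and a CSV loss history
    are written there.  ``resume_from`` restarts mid-run from a checkpoint,
    reproducing the uninterrupted trajectory exactly.
    """
    if not isinstance(data, ArrayDataset):
        data = ArrayDataset.from_cohort(data, covariate=config.covariate)
    size = data.images.shape[-1]
    if size != config.target_size:
        raise ValueError(
            f"images are {size}px but config.target_size={config.target_size}")

    if resume_from is not None:
        requested_epochs = config.epochs
        generator, critic, config, state = load_checkpoint(resume_from)
        config = dataclasses.replace(config, epochs=requested_epochs)
        opt_g, opt_c = _make_optimizers(generator, critic, config)
        arrays = state["arrays"]

        def opt_state(tag, n):
            return {"m": [arrays[f"{tag}_m_{i}"] for i in range(n)],
                    "v": [arrays[f"{tag}_v_{i}"] for i in range(n)],
                    "t": arrays[f"{tag}_t"]}

        opt_g.load_state(opt_state("og", len(opt_g.params)))
        opt_c.load_state(opt_state("oc", len(opt_c.params)))
        rng = np.random.default_rng(0)
        rng.bit_generator.state = state["rng_state"]
        start_epoch = state["epoch"]
        history = list(state["history"])
    else:
        init_rng = stream(config.seed, "trainer.init")
        generator = GeneratorNet(config.net, init_rng)
        critic = CriticNet(config.net, init_rng)
        opt_g, opt_c = _make_optimizers(generator, critic, config)
        rng = stream(config.seed, "trainer.loop")
        start_epoch = 0
        history = []

    gap_cfg = {"min": config.gap_min, "max": config.gap_max}
    n_train = len(data.images)
    steps = config.steps_per_epoch or max(1, n_train // config.batch_size)
    weights = config.weights
    ckpt_path = Path(out_dir) / "checkpoint.npz" if out_dir else None

    for epoch in range(start_epoch, config.epochs):
        k = critic_schedule(epoch, config.warmup_epochs,
                            config.critic_updates_warmup,
                            config.critic_updates_main)
        rec = {"epoch": epoch, "critic_updates": k, "critic_core": 0.0,
               "gp": 0.0, "critic_total": 0.0, "generator_adv": 0.0,
               "cycle": 0.0, "generator_total": 0.0}
        n_c = 0
        for step in range(steps):
            for _ in range(k):
                aug = (int(rng.integers(0, 2 ** 31 - 1))
                       if config.augment else None)
                x_s, a_s, gaps, x_r, a_r = sample_training_pair(
                    data, gap_cfg, rng, config.batch_size, aug)
                total, rep = critic_loss_t(critic, generator, x_s, a_s,
                                           x_r, a_r, gaps, rng, weights)
                if not np.isfinite(total.item()):
                    raise FloatingPointError(
                        f"non-finite critic loss at epoch {epoch}")
                opt_c.zero_grad()
                grad(total, opt_c.params, accumulate=True)
                opt_c.step()
                rec["critic_core"] += rep.critic_core
                rec["gp"] += rep.gp
                rec["critic_total"] += rep.critic_total
                n_c += 1
            gtotal, grep = generator_loss_t(critic, generator, x_s, a_s,
                                            gaps, weights)
            if not np.isfinite(gtotal.item()):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}")
            opt_g.zero_grad()
            grad(gtotal, opt_g.params, accumulate=True)
            opt_g.step()
            rec["generator_adv"] += grep.generator_adv
            rec["cycle"] += grep.cycle
            rec["generator_total"] += grep.generator_total
        for key in ("critic_core", "gp", "critic_total"):
            rec[key] /= max(n_c, 1)
        for key in ("generator_adv", "cycle", "generator_total"):
            rec[key] /= steps
        history.append(rec)
        if log is not None:
            log(f"epoch {epoch:3d}  k={k:2d}  "
                f"critic={rec['critic_total']:+.4f}  gp={rec['gp']:.4f}  "
                f"cycle={rec['cycle']:.4f}  adv={rec['generator_adv']:+.4f}")
        if ckpt_path is not None:
            save_checkpoint(ckpt_path, generator, critic, config, opt_g,
                            opt_c, rng, epoch + 1, history)

    hist = pd.DataFrame(history)
    if out_dir is not None:
        hist.to_csv(Path(out_dir) / "history.csv", index=False)
    return TrainResult(generator=generator, critic=critic, config=config,
                       history=hist, checkpoint_path=ckpt_path)
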