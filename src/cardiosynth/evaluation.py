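"""Quantitative evaluation of synthesized images.

Mirrors the protocol used for covariate-shift generators:

* predicted-covariate MAE from a trained image regressor, against a
  *zero-order* baseline in which the input image is left unmodified while
  the target covariate changes (its error therefore contains the full gap);
* Frechet distance between Gaussian fits of deep features of real and
  synthesized image sets, with a small CNN classifier (trained on phantom
  age-quartile bins) as the feature extractor;
* PSNR between synthesized and original images;
* volumetric analysis (LV cavity area, interventricular septum width,
  ejection fraction) from label masks, reported as normalized variation
  against the original distribution's mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import stream
from .nn import AdamW, Conv2d, GroupNorm, Linear, Module, Tensor, grad
from .nn import autodiff as ad
from .phantom import AORTA, BG, LA, LV, MYO, RA, RV, DEFAULT_INTENSITIES


# ---------------------------------------------------------------------------
# small CNN regressor / feature extractor
# ---------------------------------------------------------------------------

class _ConvBackbone(Module):
    """conv stem + three strided residual stages + global average pool."""

    def __init__(self, width, rng, groups=4):
        w = width
        self.stem = Conv2d(1, w, 3, rng)
        self.stages = []
        c = w
        for mult in (1, 2, 4):
            c_out = w * mult
            self.stages.append({
                "down": Conv2d(c, c_out, 3, rng, stride=2),
                "norm1": GroupNorm(c_out, groups),
                "conv": Conv2d(c_out, c_out, 3, rng),
                "norm2": GroupNorm(c_out, groups),
            })
            c = c_out
        self.out_dim = c

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        for st in self.stages:
            h = st["down"](h)
            h = ad.silu(st["norm1"](h))
            h = st["conv"](h) + h
            h = ad.silu(st["norm2"](h))
        return h.mean(axis=(2, 3))            # (N, out_dim)


class CovariateRegressor(Module):
    """CNN regressor predicting the scalar covariate from an image."""

    def __init__(self, width: int, rng: np.random.Generator,
                 target_mean: float = 0.0, target_sd: float = 1.0):
        self.backbone = _ConvBackbone(width, rng)
        self.head = Linear(self.backbone.out_dim, 1, rng)
        self.target_mean = target_mean
        self.target_sd = target_sd
        self.heldout_mae: float | None = None

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.backbone(x)).reshape(x.shape[0])

    def predict(self, images: np.ndarray) -> np.ndarray:
        x = _as_nchw(images)
        preds = []
        for i in range(0, len(x), 64):
            z = self.forward(Tensor(x[i:i + 64])).data
            preds.append(z * self.target_sd + self.target_mean)
        return np.concatenate(preds)


class FeatureExtractor(Module):
    """CNN classifier over covariate-quartile bins; penultimate-layer
    (pooled) activations serve as the FID feature space."""

    def __init__(self, width: int, n_classes: int, rng: np.random.Generator):
        self.backbone = _ConvBackbone(width, rng)
        self.head = Linear(self.backbone.out_dim, n_classes, rng)
        self.feature_dim = self.backbone.out_dim

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.backbone(x))

    def features(self, images: np.ndarray) -> np.ndarray:
        x = _as_nchw(images)
        out = []
        for i in range(0, len(x), 64):
            out.append(self.backbone(Tensor(x[i:i + 64])).data)
        return np.concatenate(out)


def _as_nchw(images) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    return x


def _iter_minibatches(n, batch, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch):
        yield idx[i:i + batch]


def train_covariate_regressor(images, covariates, *, width: int = 8,
                              epochs: int = 20, batch_size: int = 16,
                              lr: float = 2e-3, seed: int = 0,
                              val_fraction: float = 0.15,
                              log=None) -> CovariateRegressor:
    """Fit the regressor with an AdamW/MSE loop; stores held-out MAE."""
    images = _as_nchw(images)
    y = np.asarray(covariates, dtype=np.float64)
    if y.std() < 1e-9:
        raise ValueError("degenerate covariate variance: nothing to regress")
    rng = stream(seed, "regressor")
    n = len(images)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    mean, sd = y[tr_idx].mean(), y[tr_idx].std()
    model = CovariateRegressor(width, rng, target_mean=mean, target_sd=sd)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-5)
    yn = (y - mean) / sd
    for epoch in range(epochs):
        for mb in _iter_minibatches(len(tr_idx), batch_size, rng):
            bidx = tr_idx[mb]
            pred = model.forward(Tensor(images[bidx]))
            err = pred - Tensor(yn[bidx].astype(np.float32))
            loss = (err * err).mean()
            opt.zero_grad()
            grad(loss, opt.params, accumulate=True)
            opt.step()
        if log is not None:
            mae = np.abs(model.predict(images[val_idx]) - y[val_idx]).mean()
            log(f"regressor epoch {epoch}: val MAE {mae:.2f}")
    model.heldout_mae = float(
        np.abs(model.predict(images[val_idx]) - y[val_idx]).mean())
    return model


def train_feature_extractor(images, covariates, *, width: int = 8,
                            n_bins: int = 4, epochs: int = 6,
                            batch_size: int = 16, lr: float = 2e-3,
                            seed: int = 0) -> FeatureExtractor:
    """Train the FID feature extractor as a quartile-bin classifier."""
    images = _as_nchw(images)
    y = np.asarray(covariates, dtype=np.float64)
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    labels = np.digitize(y, edges)
    rng = stream(seed, "fid-extractor")
    model = FeatureExtractor(width, n_bins, rng)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-5)
    onehot = np.eye(n_bins, dtype=np.float32)[labels]
    for _ in range(epochs):
        for mb in _iter_minibatches(len(images), batch_size, rng):
            logits = model.forward(Tensor(images[mb]))
            logp = ad.log(ad.softmax_lastdim(logits) + 1e-9)
            loss = -(logp * Tensor(onehot[mb])).sum(axis=1).mean()
            opt.zero_grad()
            grad(loss, opt.params, accumulate=True)
            opt.step()
    return model


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

@dataclass
class FeatureStats:
    """Gaussian fit (mean vector, covariance matrix) of a feature cloud."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def extract_features(images, extractor: FeatureExtractor) -> FeatureStats:
    """Feature cloud -> Gaussian moments, with Ledoit-Wolf shrinkage when
    there are too few images for a well-conditioned covariance."""
    images = _as_nchw(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images for feature statistics")
    feats = extractor.features(images)
    mu = feats.mean(axis=0)
    if len(feats) <= feats.shape[1]:
        from sklearn.covariance import LedoitWolf
        sigma = LedoitWolf(assume_centered=False).fit(feats).covariance_
    else:
        sigma = np.cov(feats, rowvar=False)
    sigma = 0.5 * (sigma + sigma.T)
    return FeatureStats(mu=mu, sigma=sigma)


def _psd_sqrt(mat: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    floor = -tol * max(1.0, float(np.abs(vals).max()))
    if vals.min() < floor:
        raise ValueError(
            f"matrix has negative eigenvalue {vals.min():.3e} beyond tolerance")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(stats_a: FeatureStats, stats_b: FeatureStats) -> float:
    """Frechet distance between two feature Gaussians.

    ``||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2})`` with the cross
    term computed from the symmetric product ``S_a^{1/2} S_b S_a^{1/2}``
    (same trace, numerically stable); tiny negative eigenvalues from
    round-off are clamped to zero.
    """
    if stats_a.mu.size != stats_b.mu.size:
        raise ValueError("feature dimensions differ")
    diff = stats_a.mu - stats_b.mu
    a_half = _psd_sqrt(stats_a.sigma)
    inner = a_half @ stats_b.sigma @ a_half
    vals = np.linalg.eigvalsh(0.5 * (inner + inner.T))
    tol = 1e-8 * max(1.0, float(np.abs(vals).max()))
    if vals.min() < -tol:
        raise ValueError("cross-covariance product not PSD")
    cross = np.sqrt(np.clip(vals, 0.0, None)).sum()
    val = float(diff @ diff + np.trace(stats_a.sigma)
                + np.trace(stats_b.sigma) - 2.0 * cross)
    return max(val, 0.0)


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


# ---------------------------------------------------------------------------
# volumetric analysis
# ---------------------------------------------------------------------------

def septum_width_from_mask(mask: np.ndarray) -> float:
    """Mean width of the myocardial band between the LV and RV cavities.

    Scanlines crossing both cavities measure the myocardial gap between
    them; the gap is minimal on the line through the cavity centers and
    grows quadratically off-axis, so the width is taken as the mean of the
    three narrowest scanline gaps (row- and column-wise scans are both
    tried to tolerate rotation).  A gap qualifies when it is at least half
    myocardium and free of cavity labels — pure-myocardium scanlines are
    rare on automatically segmented masks at small image sizes, where
    single boundary pixels are routinely misassigned.
    """
    gaps = []
    for m in (mask, mask.T):
        for r in range(m.shape[0]):
            row = m[r]
            lv_cols = np.flatnonzero(row == LV)
            rv_cols = np.flatnonzero(row == RV)
            if len(lv_cols) == 0 or len(rv_cols) == 0:
                continue
            if lv_cols.max() < rv_cols.min():
                seg = row[lv_cols.max() + 1:rv_cols.min()]
            elif rv_cols.max() < lv_cols.min():
                seg = row[rv_cols.max() + 1:lv_cols.min()]
            else:
                continue
            if len(seg) and (seg == MYO).mean() >= 0.5 \
                    and not np.any((seg == LV) | (seg == RV)):
                gaps.append(len(seg))
    if not gaps:
        raise ValueError("no scanline crosses both LV and RV cavities")
    gaps = np.sort(np.asarray(gaps, dtype=float))
    return float(gaps[:3].mean())


def volumetric_metrics(mask: np.ndarray, es_mask: np.ndarray | None = None
                       ) -> dict:
    """LV cavity area (px^2), septum width (px) and, given an ED/ES mask
    pair, the ejection fraction (ED - ES) / ED on areas."""
    mask = np.asarray(mask)
    out = {}
    for label, name in ((LV, "lv_cavity"), (MYO, "myocardium"),
                        (RV, "rv_cavity")):
        if not (mask == label).any():
            raise ValueError(f"mask contains no '{name}' (label {label})")
    out["lv_area"] = float((mask == LV).sum())
    out["septum_width"] = septum_width_from_mask(mask)
    if es_mask is not None:
        es_area = float((np.asarray(es_mask) == LV).sum())
        out["ejection_fraction"] = (out["lv_area"] - es_area) / out["lv_area"]
    return out


def ejection_fraction(ed_mask: np.ndarray, es_mask: np.ndarray) -> float:
    return volumetric_metrics(ed_mask, es_mask)["ejection_fraction"]


def normalized_variation(metric_values, original_values) -> np.ndarray:
    """Per-subject (m_i - mean(original)) / mean(original)."""
    original_values = np.asarray(original_values, dtype=np.float64)
    if original_values.size == 0:
        raise ValueError("original_values is empty")
    ref = original_values.mean()
    if ref == 0:
        raise ValueError("original distribution has zero mean")
    return (np.asarray(metric_values, dtype=np.float64) - ref) / ref


# ---------------------------------------------------------------------------
# rule-based phantom segmentation
# ---------------------------------------------------------------------------

_BANDS = [
    (BG, DEFAULT_INTENSITIES["background"]),
    (MYO, DEFAULT_INTENSITIES["myocardium"]),
    (BG, DEFAULT_INTENSITIES["fat"]),          # fat band is background tissue
    (RA, DEFAULT_INTENSITIES["ra_cavity"]),
    (LA, DEFAULT_INTENSITIES["la_cavity"]),
    (RV, DEFAULT_INTENSITIES["rv_cavity"]),
    (LV, DEFAULT_INTENSITIES["lv_cavity"]),
    (AORTA, DEFAULT_INTENSITIES["aorta"]),
]


def segment_generated(image: np.ndarray, core_tol: float = 0.04,
                      min_area: int = 3) -> np.ndarray:
    """Rule-based segmentation of phantom-domain images.

    Pixels within ``core_tol`` of a tissue's nominal intensity are 'core'
    pixels of that tissue; remaining (edge/blended/noisy) pixels inherit the
    label of the nearest core pixel.  One geometric prior is applied: the
    myocardium is the band around the LV cavity, so myocardium-intensity
    components not adjacent to the LV core (e.g. blended pixels of the
    peripheral fat band crossing the same intensity) are demoted to
    ambiguous.  Raises if no labeled region reaches ``min_area`` core
    pixels.
    """
    image = np.asarray(image, dtype=np.float64)
    levels = np.array([v for _, v in _BANDS])
    labels = np.array([l for l, _ in _BANDS])
    dist = np.abs(image[..., None] - levels[None, None, :])
    nearest = dist.argmin(axis=-1)
    core = dist.min(axis=-1) <= core_tol
    seg = np.where(core, labels[nearest], -1).astype(np.int16)
    if int((seg > 0).sum()) < min_area:
        raise ValueError("no labeled region found above minimum area")
    # myocardium must touch the LV cavity
    lv_near = ndimage.binary_dilation(seg == LV, iterations=2)
    myo_cc, n_cc = ndimage.label(seg == MYO)
    for cc in range(1, n_cc + 1):
        comp = myo_cc == cc
        if not (comp & lv_near).any():
            seg[comp] = -1
            core[comp] = False
    if (~core).any():
        # ambiguous (anti-aliased / noisy) pixels sit on the blend between
        # two tissues: pick the two nearest core tissues and split at the
        # intensity midpoint, which reproduces the half-coverage boundary
        band_dists = []
        for b, (_, level) in enumerate(_BANDS):
            band_core = core & (nearest == b)
            if band_core.any():
                band_dists.append(
                    (b, ndimage.distance_transform_edt(~band_core)))
        dstack = np.stack([d for _, d in band_dists])
        bidx = np.array([b for b, _ in band_dists])
        order = np.argsort(dstack, axis=0)
        first, second = bidx[order[0]], bidx[order[1 % len(bidx)]]
        d1 = np.take_along_axis(dstack, order[:1], 0)[0]
        d2 = np.take_along_axis(dstack, order[1:2] if len(bidx) > 1
                                else order[:1], 0)[0]
        i_first = np.abs(image - levels[first])
        i_second = np.abs(image - levels[second])
        # the midpoint rule only applies where both tissues are locally
        # present; isolated blends (e.g. a sub-pixel fat band) keep the
        # nearest tissue
        use_second = (d2 <= d1 + 3.0) & (i_second < i_first)
        choice = np.where(use_second, second, first)
        seg = np.where(core, seg, labels[choice])
    return seg.astype(np.uint8)


# ---------------------------------------------------------------------------
# evaluation tables
# ---------------------------------------------------------------------------

@dataclass
class EvalTable:
    """Per-gap evaluation rows (model and zero-order baseline)."""

    table: pd.DataFrame

    def row(self, gap: float, method: str) -> pd.Series:
        t = self.table
        hit = t[(t["gap"] == gap) & (t["method"] == method)]
        if len(hit) != 1:
            raise KeyError(f"no unique row for gap={gap}, method={method}")
        return hit.iloc[0]

    def save(self, path):
        self.table.to_csv(path, index=False)


def predicted_covariate_mae(regressor, generator, images, covariates,
                            gaps) -> EvalTable:
    """MAE of predicted vs. target covariate per gap, plus zero-order rows.

    For each gap g the generator synthesizes every test image at target
    ``a_t = a_s + g`` and the regressor's prediction is compared with
    ``a_t``.  The zero-order row scores the unmodified images against the
    same moving target, so a perfect regressor gives exactly ``|g|``.
    """
    images = np.asarray(images)
    a_s = np.asarray(covariates, dtype=np.float64)
    if len(images) == 0:
        raise ValueError("empty test set")
    pred_orig = regressor.predict(images)
    rows = []
    for g in gaps:
        a_t = a_s + g
        res = generator.synthesize(images, float(g))
        pred = regressor.predict(res.output)
        err = np.abs(pred - a_t)
        err0 = np.abs(pred_orig - a_t)
        rows.append({"gap": g, "method": "model",
                     "mae_mean": float(err.mean()),
                     "mae_sd": float(err.std())})
        rows.append({"gap": g, "method": "zero_order",
                     "mae_mean": float(err0.mean()),
                     "mae_sd": float(err0.std())})
    return EvalTable(pd.DataFrame(rows))


def evaluate_generator(generator, regressor, extractor, images, covariates,
                       gaps) -> EvalTable:
    """Full per-gap table: predicted-covariate MAE (model vs zero order),
    FID against the real test set, and PSNR against the originals."""
    images = np.asarray(images)
    a_s = np.asarray(covariates, dtype=np.float64)
    if len(images) == 0:
        raise ValueError("empty test set")
    real_stats = extract_features(images, extractor)
    pred_orig = regressor.predict(images)
    rows = []
    for g in gaps:
        a_t = a_s + g
        res = generator.synthesize(images, float(g))
        pred = regressor.predict(res.output)
        stats = extract_features(res.output, extractor)
        psnrs = [psnr(images[i], res.output[i]) for i in range(len(images))]
        psnrs = [p for p in psnrs if np.isfinite(p)]
        rows.append({
            "gap": g, "method": "model",
            "mae_mean": float(np.abs(pred - a_t).mean()),
            "mae_sd": float(np.abs(pred - a_t).std()),
            "fid": fid(real_stats, stats),
            "psnr_mean": float(np.mean(psnrs)) if psnrs else float("inf")})
        rows.append({
            "gap": g, "method": "zero_order",
            "mae_mean": float(np.abs(pred_orig - a_t).mean()),
            "mae_sd": float(np.abs(pred_orig - a_t).std()),
            "fid": 0.0, "psnr_mean": float("inf")})
    return EvalTable(pd.DataFrame(rows))
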