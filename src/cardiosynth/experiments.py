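"""Dataset-debiasing experiment and alternative covariate tasks.

The debiasing experiment asks whether a trained covariate-shift generator
can repair an age-biased training set: an imbalanced dataset (e.g. 90% of
subjects younger than a threshold) is augmented with a growing fraction of
synthetically age-shifted majority subjects whose *target* ages fall in the
under-represented region, and a fresh age regressor is trained on each
variant and scored on a fixed balanced held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .evaluation import train_covariate_regressor
from .phantom import AGE_RANGE


@dataclass(frozen=True)
class ImbalanceSpec:
    """Construction recipe for an age-imbalanced dataset."""

    n_total: int = 1000
    threshold: float = 70.0
    minority_side: str = "older"          # {older, younger}
    minority_fraction: float = 0.10
    synth_fractions: tuple = (0.01, 0.05, 0.10, 0.25)

    def __post_init__(self):
        if not 0.0 < self.minority_fraction < 0.5:
            raise ValueError("minority_fraction must be in (0, 0.5)")
        if self.minority_side not in ("older", "younger"):
            raise ValueError(f"unknown minority_side {self.minority_side!r}")
        if any(not 0.0 < f < 1.0 for f in self.synth_fractions):
            raise ValueError("synth_fractions must lie in (0, 1)")

    def minority_mask(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return (ages >= self.threshold if self.minority_side == "older"
                else ages < self.threshold)


D1_SPEC = ImbalanceSpec(threshold=70.0, minority_side="older")
D2_SPEC = ImbalanceSpec(threshold=60.0, minority_side="younger")


def imbalanced_indices(ages: np.ndarray, spec: ImbalanceSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of an exact-count imbalanced subsample of ``ages``."""
    ages = np.asarray(ages, dtype=float)
    minority = np.flatnonzero(spec.minority_mask(ages))
    majority = np.flatnonzero(~spec.minority_mask(ages))
    n_min = int(round(spec.n_total * spec.minority_fraction))
    n_maj = spec.n_total - n_min
    if len(minority) < n_min or len(majority) < n_maj:
        raise ValueError(
            f"cohort too small: need {n_maj} majority / {n_min} minority, "
            f"have {len(majority)} / {len(minority)}")
    pick_min = rng.choice(minority, n_min, replace=False)
    pick_maj = rng.choice(majority, n_maj, replace=False)
    return np.sort(np.concatenate([pick_min, pick_maj]))


def build_imbalanced_dataset(cohort, spec: ImbalanceSpec, seed: int = 0):
    """Subsample a cohort table to the spec's exact majority/minority counts."""
    rng = stream(seed, "experiments.imbalance")
    idx = imbalanced_indices(cohort.table["age"].to_numpy(), spec, rng)
    from .phantom import CohortTable
    return CohortTable(cohort.table.iloc[idx].copy(), cohort.root)


def synthesize_minority(images: np.ndarray, ages: np.ndarray, generator,
                        spec: ImbalanceSpec, fraction: float,
                        rng: np.random.Generator,
                        age_range=AGE_RANGE):
    """Shift random majority-side subjects into the minority age region.

    Returns (synthetic images, synthetic target ages).  Target ages are
    drawn uniformly over the minority interval; the labels of the synthetic
    rows are the *target* ages.
    """
    n_add = int(round(fraction * len(ages)))
    if n_add == 0:
        return (np.empty((0,) + images.shape[1:], dtype=images.dtype),
                np.empty(0))
    majority = np.flatnonzero(~spec.minority_mask(ages))
    src = rng.choice(majority, n_add, replace=True)
    lo, hi = ((spec.threshold, age_range[1])
              if spec.minority_side == "older"
              else (age_range[0], spec.threshold))
    targets = rng.uniform(lo, hi, n_add)
    out = np.empty((n_add,) + images.shape[1:], dtype=np.float32)
    for i, (j, a_t) in enumerate(zip(src, targets)):
        gap = a_t - ages[j]
        out[i] = generator.synthesize(images[j], gap).output
    return out, targets


def augment_with_synthetic(images: np.ndarray, ages: np.ndarray, generator,
                           spec: ImbalanceSpec, fraction: float,
                           seed: int = 0) -> pd.DataFrame:
    """Imbalanced arrays + synthetic minority rows, flagged ``synthetic=1``.

    Returns a frame with columns (index into the returned image stack kept
    implicit): age, synthetic — alongside the stacked image array in
    ``.attrs['images']``.
    """
    rng = stream(seed, "experiments.synth")
    syn_x, syn_a = synthesize_minority(images, ages, generator, spec,
                                       fraction, rng)
    all_x = np.concatenate([images, syn_x]) if len(syn_x) else images
    frame = pd.DataFrame({
        "age": np.concatenate([ages, syn_a]),
        "synthetic": np.concatenate([np.zeros(len(ages), dtype=int),
                                     np.ones(len(syn_a), dtype=int)])})
    frame.attrs["images"] = all_x
    return frame


def balanced_indices(ages: np.ndarray, n: int, rng: np.random.Generator,
                     n_bins: int = 8, age_range=AGE_RANGE) -> np.ndarray:
    """Approximately age-uniform subsample via stratified binning."""
    ages = np.asarray(ages, dtype=float)
    edges = np.linspace(age_range[0], age_range[1] + 1e-9, n_bins + 1)
    per_bin = n // n_bins
    picks = []
    for b in range(n_bins):
        pool = np.flatnonzero((ages >= edges[b]) & (ages < edges[b + 1]))
        take = min(per_bin, len(pool))
        picks.append(rng.choice(pool, take, replace=False))
    picks = np.concatenate(picks)
    if len(picks) < n:
        rest = np.setdiff1d(np.arange(len(ages)), picks)
        extra = rng.choice(rest, min(n - len(picks), len(rest)),
                           replace=False)
        picks = np.concatenate([picks, extra])
    return np.sort(picks)


def run_debias_experiment(images: np.ndarray, ages: np.ndarray, generator,
                          spec: ImbalanceSpec = D1_SPEC, *,
                          seeds=(0, 1, 2, 3, 4), n_test: int = 200,
                          include_balanced: bool = True,
                          regressor_config: dict | None = None,
                          log=None) -> pd.DataFrame:
    """MAE of fresh regressors vs. synthetic-augmentation fraction.

    A fixed balanced held-out set of ``n_test`` subjects is carved out
    first and never feeds any training or synthetic-source role.  Rows:
    one per (fraction, seed) plus the balanced-dataset reference per seed.
    """
    reg_cfg = dict(width=6, epochs=4, batch_size=16, lr=2e-3)
    reg_cfg.update(regressor_config or {})
    images = np.asarray(images, dtype=np.float32)
    ages = np.asarray(ages, dtype=np.float64)
    split_rng = stream(int(seeds[0]), "experiments.testsplit")
    test_idx = balanced_indices(ages, n_test, split_rng)
    train_mask = np.ones(len(ages), dtype=bool)
    train_mask[test_idx] = False
    x_test, a_test = images[test_idx], ages[test_idx]
    x_pool, a_pool = images[train_mask], ages[train_mask]

    rows = []
    for seed in seeds:
        rng = stream(int(seed), "experiments.run")
        idx = imbalanced_indices(a_pool, spec, rng)
        x_imb, a_imb = x_pool[idx], a_pool[idx]
        for frac in (0.0,) + tuple(spec.synth_fractions):
            if frac > 0:
                syn_x, syn_a = synthesize_minority(
                    x_imb, a_imb, generator, spec, frac, rng)
                x_tr = np.concatenate([x_imb, syn_x])
                a_tr = np.concatenate([a_imb, syn_a])
            else:
                x_tr, a_tr = x_imb, a_imb
            reg = train_covariate_regressor(x_tr, a_tr, seed=int(seed),
                                            **reg_cfg)
            mae = float(np.abs(reg.predict(x_test) - a_test).mean())
            rows.append({"dataset": spec.minority_side, "fraction": frac,
                         "seed": int(seed), "mae": mae,
                         "n_train": len(a_tr)})
            if log is not None:
                log(f"seed {seed} frac {frac:.2f}: MAE {mae:.2f} "
                    f"(n={len(a_tr)})")
        if include_balanced:
            bidx = balanced_indices(a_pool, spec.n_total, rng)
            reg = train_covariate_regressor(x_pool[bidx], a_pool[bidx],
                                            seed=int(seed), **reg_cfg)
            mae = float(np.abs(reg.predict(x_test) - a_test).mean())
            rows.append({"dataset": "balanced", "fraction": np.nan,
                         "seed": int(seed), "mae": mae,
                         "n_train": len(bidx)})
    return pd.DataFrame(rows)


def summarize_debias(table: pd.DataFrame) -> pd.DataFrame:
    """mean_sd MAE per (dataset, fraction) across seeds."""
    def agg(g):
        return pd.Series({"mae_mean": g["mae"].mean(),
                          "mae_sd": g["mae"].std(ddof=0)})
    return (table.groupby(["dataset", "fraction"], dropna=False)
            .apply(agg, include_groups=False).reset_index())


# ---------------------------------------------------------------------------
# alternative covariate tasks
# ---------------------------------------------------------------------------

BMI_GAP_BINS = (-8, -6, -4, -2, -1, 0, 1, 2, 4, 6, 8)
PHASE_GAPS = (-1, 0, 1)


def configure_alternative_task(task: str) -> dict:
    """Covariate configuration for the BMI-shift and ED->ES tasks.

    Returns the phantom ``covariate_mode``, the cohort column used for
    conditioning, the training gap range and the evaluation gap bins.
    """
    if task == "age":
        return {"covariate_mode": "age", "covariate": "age",
                "gap_min": -25.0, "gap_max": 25.0,
                "eval_gaps": (-20, -15, -10, -5, 5, 10, 15, 20)}
    if task == "bmi":
        return {"covariate_mode": "bmi", "covariate": "bmi",
                "gap_min": -8.0, "gap_max": 8.0,
                "eval_gaps": BMI_GAP_BINS}
    if task == "phase":
        return {"covariate_mode": "phase", "covariate": "phase_idx",
                "gap_min": -1.0, "gap_max": 1.0,
                "eval_gaps": PHASE_GAPS}
    raise ValueError(f"unknown task {task!r}")


def phase_rmse(generator, ed_images: np.ndarray, es_images: np.ndarray
               ) -> float:
    """Whole-image RMSE between synthesized ES frames (ED shifted by +1
    phase) and the paired real ES frames."""
    ed_images = np.asarray(ed_images)
    res = generator.synthesize(ed_images, 1.0)
    return float(np.sqrt(np.mean((res.output - np.asarray(es_images)) ** 2)))
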