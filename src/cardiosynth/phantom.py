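"""Synthetic four-chamber cardiac phantoms with covariate-controlled morphology.

Real population-scale cardiac MR (the natural training data for an aging
model) is access-restricted, so this module provides a stand-in cohort in
which the covariate -> morphology mapping is *known exactly* and linear:

* interventricular septum width increases with age,
* LV cavity radius decreases with age,
* aortic radius increases with age,
* BMI widens a peripheral fat band,
* the ES phase shrinks both ventricular cavities and thickens the myocardium.

Because the generating law is known, every downstream claim (regressor
accuracy, synthesis monotonicity, volumetric trends) can be checked against
ground truth rather than eyeballed.

Geometry is specified at a 128 x 128 reference scale and scaled linearly to
other image sizes.  Coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream

# mask label coding (fixed; rendering is back-to-front with the aorta last)
BG, LV, MYO, RV, LA, RA, AORTA = 0, 1, 2, 3, 4, 5, 6
LABEL_NAMES = {BG: "background", LV: "lv_cavity", MYO: "myocardium",
               RV: "rv_cavity", LA: "la_cavity", RA: "ra_cavity",
               AORTA: "aorta"}

AGE_RANGE = (45.0, 82.0)
AGE_MEAN, AGE_SD = 64.1, 7.7

DEFAULT_INTENSITIES = {
    "lv_cavity": 0.85, "myocardium": 0.40, "rv_cavity": 0.80,
    "la_cavity": 0.72, "ra_cavity": 0.65, "aorta": 0.90,
    "background": 0.08, "fat": 0.50,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Linear covariate->geometry law, in pixels at the 128^2 reference scale.

    Slopes are chosen so a 20-year gap moves each structure by roughly
    2-4 rendered pixels at 128^2 (sub-pixel effects would be unlearnable,
    larger ones unrealistic).
    """

    lv_radius_45: float = 22.0
    lv_radius_slope: float = 0.15      # px lost per year
    septum_45: float = 4.0
    septum_slope: float = 0.10         # px gained per year
    aorta_45: float = 6.0
    aorta_slope: float = 0.12          # px gained per year
    rv_radius: float = 13.0
    la_radius: float = 9.0
    ra_radius: float = 9.0
    bmi_fat_slope: float = 0.20        # fat-band px per BMI unit above 18
    es_cavity_factor: float = 0.72     # ES shrink of LV/RV cavities
    es_septum_factor: float = 1.35     # ES myocardial thickening
    sex_scale: float = 0.0             # optional global male scale-up (off)
    jitter: bool = True
    jitter_sd: dict = field(default_factory=lambda: {
        "lv_cavity_radius": 0.8, "septum_width": 0.3, "rv_radius": 0.6,
        "la_radius": 0.5, "ra_radius": 0.5, "aorta_radius": 0.3,
        "center": 2.0, "rotation": 3.0})
    tissue_intensities: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    age_range: tuple = AGE_RANGE


def toy_phantom_config(image_size: int = 32, jitter: bool = True
                       ) -> PhantomConfig:
    """Phantom law for small-image experiments.

    Geometry *sizes* scale with the render resolution, but the aging
    *effect* is pixel-scale morphology change: naively scaling the 128^2
    slopes down to 32^2 would leave sub-pixel, unlearnable effects.  This
    configuration steepens the reference slopes (raising the LV intercept
    so radii stay positive across the age range) so that at 32^2 a 20-year
    gap still moves each structure by roughly one rendered pixel, with
    every structure inside the frame across ages 45-82.
    """
    sd = {"lv_cavity_radius": 0.5, "septum_width": 0.25, "rv_radius": 0.4,
          "la_radius": 0.3, "ra_radius": 0.3, "aorta_radius": 0.25,
          "center": 1.5, "rotation": 3.0}
    return PhantomConfig(
        lv_radius_45=26.0, lv_radius_slope=0.20,
        septum_45=4.0, septum_slope=0.18,
        aorta_45=6.0, aorta_slope=0.16,
        jitter=jitter, jitter_sd=sd)


@dataclass
class GeometryParams:
    """Resolved per-subject geometry, in pixels at the target image size."""

    lv_cavity_radius: float
    septum_width: float
    rv_radius: float
    la_radius: float
    ra_radius: float
    aorta_radius: float
    heart_center: tuple          # (row, col)
    rotation: float              # degrees
    tissue_intensities: dict
    fat_band_width: float = 0.0
    image_size: int = 128

    def validate(self) -> None:
        radii = {"lv_cavity_radius": self.lv_cavity_radius,
                 "septum_width": self.septum_width,
                 "rv_radius": self.rv_radius, "la_radius": self.la_radius,
                 "ra_radius": self.ra_radius,
                 "aorta_radius": self.aorta_radius}
        for name, v in radii.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.septum_width < self.lv_cavity_radius:
            raise ValueError(
                f"septum_width {self.septum_width} must be smaller than "
                f"lv_cavity_radius {self.lv_cavity_radius}")
        for name, (center, radius) in self._structures().items():
            for k in (0, 1):
                if center[k] - radius < 0 or center[k] + radius > self.image_size - 1:
                    raise ValueError(
                        f"structure '{name}' exceeds the image frame")

    def _structures(self):
        """Center/radius of every drawn disk, after layout and rotation."""
        s = self.image_size / 128.0
        r_lv, sept = self.lv_cavity_radius, self.septum_width
        d_lv_rv = r_lv + sept + self.rv_radius
        lv_off = np.array([14.0 * s, -20.0 * s])
        rv_off = lv_off + np.array([0.0, d_lv_rv])
        la_row = lv_off[0] - (r_lv + sept + self.la_radius + 4.0 * s)
        la_off = np.array([la_row, lv_off[1]])
        ra_off = np.array([la_row, rv_off[1]])
        ao_off = np.array([la_row - 0.6 * self.la_radius,
                           0.5 * (la_off[1] + ra_off[1])])
        th = np.deg2rad(self.rotation)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(self.heart_center, dtype=float)

        def place(off):
            return tuple(c + rot @ off)

        return {
            "la_cavity": (place(la_off), self.la_radius),
            "ra_cavity": (place(ra_off), self.ra_radius),
            "myocardium": (place(lv_off), r_lv + sept),
            "lv_cavity": (place(lv_off), r_lv),
            "rv_cavity": (place(rv_off), self.rv_radius),
            "aorta": (place(ao_off), self.aorta_radius),
        }


@dataclass
class PhantomSample:
    image: np.ndarray            # float, [0,1]
    mask: np.ndarray             # uint8 labels
    age: float
    bmi: float
    sex: str
    phase: str
    geometry: GeometryParams
    subject_id: str

    @property
    def phase_idx(self) -> int:
        """Numeric cardiac-phase covariate: ED = 0, ES = 1."""
        return {"ED": 0, "ES": 1}[self.phase]


class CohortTable:
    """Cohort listing: one row per (subject, phase) with covariates, file
    paths and a train/val/test split tag."""

    COLUMNS = ["subject_id", "age", "bmi", "sex", "phase",
               "image_path", "mask_path", "split"]

    def __init__(self, table: pd.DataFrame, root: Path | None = None):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        if table.duplicated(["subject_id", "phase"]).any():
            raise ValueError("duplicate (subject_id, phase) rows")
        self.table = table.reset_index(drop=True)
        self.root = Path(root) if root is not None else None

    def __len__(self):
        return len(self.table)

    def split(self, tag: str) -> "CohortTable":
        sub = self.table[self.table["split"] == tag]
        return CohortTable(sub.copy(), self.root)

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "CohortTable":
        path = Path(path)
        return cls(pd.read_csv(path), root=path.parent)

    def load_arrays(self):
        """Read every image/mask into memory (images float in [0,1])."""
        from .imgio import read_image, read_mask
        images, masks = [], []
        for _, row in self.table.iterrows():
            ip = Path(row["image_path"])
            if self.root is not None and not ip.is_absolute():
                ip = self.root / ip
            images.append(read_image(ip))
            mp = row["mask_path"]
            if isinstance(mp, str) and mp:
                p = Path(mp)
                if self.root is not None and not p.is_absolute():
                    p = self.root / p
                masks.append(read_mask(p))
            else:
                masks.append(None)
        return np.stack(images), masks


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------

def geometry_from_covariates(age: float, bmi: float = 27.0, sex: str = "F",
                             rng_seed: int | None = None, *,
                             config: PhantomConfig | None = None,
                             image_size: int = 128, phase: str = "ED",
                             max_retries: int = 10) -> GeometryParams:
    """Resolve covariates into rendered geometry.

    Deterministic given (age, bmi, sex, rng_seed).  With ``config.jitter``
    per-subject Gaussian jitter is added to every parameter; draws that
    violate the septum < LV-radius constraint are resampled up to
    ``max_retries`` times.
    """
    cfg = config or PhantomConfig()
    lo, hi = cfg.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    if phase not in ("ED", "ES"):
        raise ValueError(f"unknown phase {phase!r}")
    s = image_size / 128.0
    dy = age - 45.0
    base = {
        "lv_cavity_radius": (cfg.lv_radius_45 - cfg.lv_radius_slope * dy) * s,
        "septum_width": (cfg.septum_45 + cfg.septum_slope * dy) * s,
        "rv_radius": cfg.rv_radius * s,
        "la_radius": cfg.la_radius * s,
        "ra_radius": cfg.ra_radius * s,
        "aorta_radius": (cfg.aorta_45 + cfg.aorta_slope * dy) * s,
    }
    if sex == "M" and cfg.sex_scale:
        base = {k: v * (1.0 + cfg.sex_scale) for k, v in base.items()}
    if phase == "ES":
        base["lv_cavity_radius"] *= cfg.es_cavity_factor
        base["rv_radius"] *= cfg.es_cavity_factor
        base["septum_width"] *= cfg.es_septum_factor
    center = (0.5 * image_size, 0.5 * image_size)
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None

    for attempt in range(max_retries + 1):
        jittered = dict(base)
        rotation = 0.0
        if cfg.jitter and rng is not None:
            sd = cfg.jitter_sd
            for k in jittered:
                jittered[k] += rng.normal(0.0, sd[k] * s)
            center_j = (center[0] + rng.normal(0.0, sd["center"] * s),
                        center[1] + rng.normal(0.0, sd["center"] * s))
            rotation = rng.normal(0.0, sd["rotation"])
        else:
            center_j = center
        params = GeometryParams(
            lv_cavity_radius=jittered["lv_cavity_radius"],
            septum_width=jittered["septum_width"],
            rv_radius=jittered["rv_radius"],
            la_radius=jittered["la_radius"],
            ra_radius=jittered["ra_radius"],
            aorta_radius=jittered["aorta_radius"],
            heart_center=center_j,
            rotation=rotation,
            tissue_intensities=dict(cfg.tissue_intensities),
            fat_band_width=max(0.0, (bmi - 18.0) * cfg.bmi_fat_slope * s),
            image_size=image_size,
        )
        try:
            params.validate()
            return params
        except ValueError:
            if not (cfg.jitter and rng is not None) or attempt == max_retries:
                raise
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk_coverage(shape, center, radius):
    rr = np.arange(shape[0], dtype=np.float64)[:, None]
    cc = np.arange(shape[1], dtype=np.float64)[None, :]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _annulus_coverage(shape, center, r_inner, width):
    outer = _disk_coverage(shape, center, r_inner + width)
    inner = _disk_coverage(shape, center, r_inner)
    return np.clip(outer - inner, 0.0, 1.0)


def render_phantom(params: GeometryParams, image_size: int | None = None,
                   noise_sd: float = 0.01, rng_seed: int = 0, *,
                   age: float = 64.0, bmi: float = 27.0, sex: str = "F",
                   phase: str = "ED", subject_id: str = "sub00000"
                   ) -> PhantomSample:
    """Render anti-aliased disks back-to-front into image and label mask.

    The image blends region coverage with region intensity (painter's
    algorithm) and then adds Gaussian pixel noise clipped to [0, 1]; the
    mask thresholds coverage at 0.5 and carries no noise.
    """
    size = image_size or params.image_size
    if size < 32:
        raise ValueError("image_size must be >= 32")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if size != params.image_size:
        params = replace(params, image_size=size)
    params.validate()
    shape = (size, size)
    ti = params.tissue_intensities
    image = np.full(shape, ti["background"], dtype=np.float64)
    mask = np.zeros(shape, dtype=np.uint8)

    if params.fat_band_width > 0:
        cov = _annulus_coverage(shape, params.heart_center,
                                0.41 * size, params.fat_band_width)
        image = cov * ti["fat"] + (1 - cov) * image

    order = [("la_cavity", LA), ("ra_cavity", RA), ("myocardium", MYO),
             ("lv_cavity", LV), ("rv_cavity", RV), ("aorta", AORTA)]
    structures = params._structures()
    for name, label in order:
        center, radius = structures[name]
        cov = _disk_coverage(shape, center, radius)
        image = cov * ti[name] + (1 - cov) * image
        mask[cov >= 0.5] = label

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        image = image + rng.normal(0.0, noise_sd, shape)
    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(image=image.astype(np.float32), mask=mask, age=age,
                         bmi=bmi, sex=sex, phase=phase, geometry=params,
                         subject_id=subject_id)


def sample_phantom(age: float, bmi: float = 27.0, sex: str = "F",
                   rng_seed: int = 0, *, config: PhantomConfig | None = None,
                   image_size: int = 128, noise_sd: float = 0.01,
                   phase: str = "ED", subject_id: str = "sub00000"
                   ) -> PhantomSample:
    """Covariates -> geometry -> rendered sample in one call."""
    params = geometry_from_covariates(age, bmi, sex, rng_seed, config=config,
                                      image_size=image_size, phase=phase)
    return render_phantom(params, image_size, noise_sd, rng_seed + 1,
                          age=age, bmi=bmi, sex=sex, phase=phase,
                          subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _sample_ages(n, distribution, rng):
    lo, hi = AGE_RANGE
    if distribution == "uniform":
        return rng.uniform(lo, hi, n)
    if distribution in ("truncnorm", "truncated-normal"):
        from scipy import stats
        a, b = (lo - AGE_MEAN) / AGE_SD, (hi - AGE_MEAN) / AGE_SD
        return stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD,
                                   size=n, random_state=rng)
    raise ValueError(f"unknown age distribution {distribution!r}")


def generate_samples(n: int, age_distribution: str = "truncnorm",
                     covariate_mode: str = "age", rng_seed: int = 0, *,
                     config: PhantomConfig | None = None,
                     image_size: int = 128, noise_sd: float = 0.01
                     ) -> list[PhantomSample]:
    """In-memory cohort; ``generate_cohort`` adds the on-disk layout."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if covariate_mode not in ("age", "bmi", "phase"):
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")
    rng = stream(rng_seed, "phantom.cohort")
    ages = _sample_ages(n, age_distribution, rng)
    bmis = np.clip(rng.normal(27.0, 4.0, n), 18.0, 40.0)
    sexes = rng.choice(["F", "M"], n)
    samples = []
    for i in range(n):
        sid = f"sub{i:05d}"
        seed_i = int(rng.integers(0, 2 ** 31 - 1))
        phases = ("ED", "ES") if covariate_mode == "phase" else ("ED",)
        for phase in phases:
            samples.append(sample_phantom(
                float(ages[i]), float(bmis[i]), str(sexes[i]), seed_i,
                config=config, image_size=image_size, noise_sd=noise_sd,
                phase=phase, subject_id=sid))
    return samples


def _assign_splits(subject_ids, rng):
    ids = list(dict.fromkeys(subject_ids))
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = max(1, int(round(0.8 * n)))
    n_val = max(0, int(round(0.1 * n)))
    tags = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            tags[ids[idx]] = "train"
        elif rank < n_train + n_val:
            tags[ids[idx]] = "val"
        else:
            tags[ids[idx]] = "test"
    return [tags[s] for s in subject_ids]


def generate_cohort(n: int, age_distribution: str = "truncnorm",
                    covariate_mode: str = "age", rng_seed: int = 0,
                    out_dir=None, *, config: PhantomConfig | None = None,
                    image_size: int = 128, noise_sd: float = 0.01,
                    image_format: str = "png") -> CohortTable:
    """Generate a phantom cohort and write images/masks/CSV to ``out_dir``."""
    from .imgio import write_image, write_mask
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    samples = generate_samples(n, age_distribution, covariate_mode, rng_seed,
                               config=config, image_size=image_size,
                               noise_sd=noise_sd)
    ext = {"png": ".png", "nifti": ".nii.gz"}[image_format]
    rows = []
    for sm in samples:
        stem = f"{sm.subject_id}_{sm.phase}"
        img_rel = f"images/{stem}{ext}"
        msk_rel = f"masks/{stem}{ext}"
        write_image(out_dir / img_rel, sm.image)
        write_mask(out_dir / msk_rel, sm.mask)
        rows.append({"subject_id": sm.subject_id, "age": sm.age,
                     "bmi": sm.bmi, "sex": sm.sex, "phase": sm.phase,
                     "image_path": img_rel, "mask_path": msk_rel})
    df = pd.DataFrame(rows)
    df["split"] = _assign_splits(df["subject_id"].tolist(),
                                 stream(rng_seed, "phantom.split"))
    cohort = CohortTable(df, root=out_dir)
    cohort.save(out_dir / "cohort.csv")
    return cohort
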