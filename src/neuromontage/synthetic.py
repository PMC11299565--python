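"""Synthetic lesioned-brain cohorts with known causal ground truth.

Real stroke cohorts pairing normalised T1 volumes with clinical tables are
not freely distributable, so every downstream stage here is exercised on
simulated data: an ellipsoidal "brain" partitioned into left/right
Voronoi regions (standing in for an anatomical atlas), focal hypointense
lesions biased to the left hemisphere, three tabular features (initial
severity category, left-hemisphere lesion size, recovery time in months),
and a binary impaired/healthy outcome drawn from a logistic model of
damage to designated causal regions plus tabular effects.  The intercept
is calibrated so the cohort prevalence matches a target (default 34 %
impaired, the skew observed in the clinical population emulated here).

All randomness flows from ``(config.seed, subject index)``; everything is
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

SEVERITY_LEVELS = ("severe", "moderate", "mild", "normal", "unknown")
# ordinal code used for outcome/tabular effects; unknown imputed mid-scale
SEVERITY_CODE = {"normal": 0.0, "mild": 1.0, "moderate": 2.0, "severe": 3.0,
                 "unknown": 1.5}

__all__ = ["SyntheticAtlas", "CohortConfig", "TabularRecord",
           "SyntheticSubject", "generate_atlas", "generate_subject",
           "generate_cohort", "calibrate_intercept", "SEVERITY_LEVELS",
           "SEVERITY_CODE"]


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    name: str
    hemisphere: str              # "L" or "R"
    centroid: tuple[float, float, float]


@dataclass(frozen=True)
class SyntheticAtlas:
    """Integer label volume (0 = background) plus a region table."""

    label_volume: np.ndarray
    region_table: tuple[RegionInfo, ...]
    voxel_size: float = 3.0      # mm, isotropic

    def __post_init__(self):
        labels = set(np.unique(self.label_volume)) - {0}
        table_ids = {r.region_id for r in self.region_table}
        if labels != table_ids:
            raise ValueError("label volume and region table disagree")

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(r.region_id for r in self.region_table)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def save(self, path) -> None:
        import nibabel as nib
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(
            self.label_volume.astype(np.int16), affine), str(path))


@dataclass(frozen=True)
class TabularRecord:
    initial_severity: str
    left_lesion_size: int
    recovery_time: float         # months
    outcome: int | None = None   # 1 = impaired, 0 = healthy

    def __post_init__(self):
        if self.initial_severity not in SEVERITY_LEVELS:
            raise ValueError(
                f"unknown severity category {self.initial_severity!r}")
        if self.left_lesion_size < 0 or self.recovery_time < 0:
            raise ValueError("lesion size and recovery time must be ≥ 0")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    volume: np.ndarray
    lesion_mask: np.ndarray
    tabular: TabularRecord
    outcome: int
    truth: dict[int, float]      # region id → damaged-voxel fraction


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    ``effect_weights`` (per causal region, on the damage fraction in [0,1])
    and ``tabular_effects`` feed the logistic outcome model; ``intercept``
    is solved numerically when left ``None`` so the expected impaired
    fraction equals ``target_prevalence``.
    """

    n_subjects: int
    n_regions: int = 20
    causal_region_ids: tuple[int, ...] = (1, 3)
    effect_weights: tuple[float, ...] = (5.0, 5.0)
    tabular_effects: dict = field(default_factory=lambda: {
        "severity": 0.6, "recovery_time": -0.3})
    target_prevalence: float = 0.34
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (4.0, 10.0)   # voxels
    left_bias: float = 0.7
    noise_sd: float = 0.05
    unknown_severity_fraction: float = 0.2
    intercept: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if len(self.effect_weights) != len(self.causal_region_ids):
            raise ValueError("one effect weight per causal region required")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be ≥ 0")

    def validate_against(self, atlas: SyntheticAtlas) -> None:
        missing = set(self.causal_region_ids) - set(atlas.region_ids)
        if missing:
            raise ValueError(f"causal regions {missing} not in atlas")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    ax = [np.linspace(-1, 1, s) for s in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    # semi-axes < 1 leave a background rim like a skull-stripped scan
    return (gx / 0.82) ** 2 + (gy / 0.9) ** 2 + (gz / 0.82) ** 2 <= 1.0


def generate_atlas(n_regions: int, grid_shape: tuple[int, int, int] = (64, 64, 64),
                   seed: int = 0, voxel_size: float = 3.0) -> SyntheticAtlas:
    """Voronoi-style parcellation of an ellipsoidal brain mask.

    Region seed points alternate between hemispheres (midline at half the
    first axis, the left hemisphere being the lower indices); each voxel
    takes the label of the nearest seed point in its own hemisphere, so no
    region straddles the midline.  Deterministic given ``seed``.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    mask = _ellipsoid_mask(grid_shape)
    mid = grid_shape[0] // 2
    coords = np.argwhere(mask)
    left_pool = coords[coords[:, 0] < mid]
    right_pool = coords[coords[:, 0] >= mid]
    hemis = ["L" if i % 2 == 0 else "R" for i in range(n_regions)]
    n_left, n_right = hemis.count("L"), hemis.count("R")
    if n_left > len(left_pool) or n_right > len(right_pool):
        raise ValueError(
            f"cannot place {n_regions} regions in grid {grid_shape}")
    rng = np.random.default_rng(seed)
    seeds = np.zeros((n_regions, 3))
    picks_l = left_pool[rng.choice(len(left_pool), n_left, replace=False)]
    picks_r = right_pool[rng.choice(len(right_pool), n_right, replace=False)]
    il = ir = 0
    for i, h in enumerate(hemis):
        if h == "L":
            seeds[i] = picks_l[il]; il += 1
        else:
            seeds[i] = picks_r[ir]; ir += 1

    labels = np.zeros(grid_shape, dtype=np.int32)
    for pool, hemi in ((left_pool, "L"), (right_pool, "R")):
        own = np.array([i for i, h in enumerate(hemis) if h == hemi])
        d = ((pool[:, None, :] - seeds[own][None, :, :]) ** 2).sum(axis=2)
        nearest = own[d.argmin(axis=1)]
        labels[tuple(pool.T)] = nearest + 1

    table = []
    for i in range(n_regions):
        rid = i + 1
        vox = np.argwhere(labels == rid)
        centroid = tuple(float(v) for v in vox.mean(axis=0))
        table.append(RegionInfo(rid, f"{hemis[i]}_region_{rid:02d}",
                                hemis[i], centroid))
    return SyntheticAtlas(label_volume=labels, region_table=tuple(table),
                          voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# subject geometry (lesions + tabular) — separable from intensity rendering
# so intercept calibration can run on geometry alone
# ---------------------------------------------------------------------------

def _sample_geometry(atlas: SyntheticAtlas, config: CohortConfig,
                     rng: np.random.Generator):
    shape = atlas.label_volume.shape
    mask = atlas.brain_mask
    mid = shape[0] // 2
    lo, hi = config.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    lesion = np.zeros(shape, dtype=bool)
    coords = np.argwhere(mask)
    left_coords = coords[coords[:, 0] < mid]
    right_coords = coords[coords[:, 0] >= mid]
    grids = np.indices(shape)
    for _ in range(n_lesions):
        pool = left_coords if rng.random() < config.left_bias else right_coords
        centre = pool[rng.integers(len(pool))]
        r = rng.uniform(*config.lesion_radius_range)
        # mildly anisotropic ellipsoidal lesion
        semi = r * rng.uniform(0.7, 1.3, size=3)
        d2 = sum(((grids[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
        lesion |= d2 <= 1.0
    lesion &= mask

    max_label = int(atlas.label_volume.max())
    region_sizes = np.bincount(atlas.label_volume.ravel(),
                               minlength=max_label + 1)
    damaged = np.bincount(atlas.label_volume[lesion],
                          minlength=max_label + 1)
    truth = {info.region_id:
             float(damaged[info.region_id] / region_sizes[info.region_id])
             for info in atlas.region_table}

    left_size = int(np.count_nonzero(lesion[:mid, :, :]))
    total_frac = np.count_nonzero(lesion) / np.count_nonzero(mask)

    # severity: ordered thresholds on lesion burden + reporting noise,
    # then a configurable fraction reassigned to "unknown"
    latent = 8.0 * total_frac + rng.normal(0.0, 0.35)
    if latent > 0.9:
        severity = "severe"
    elif latent > 0.55:
        severity = "moderate"
    elif latent > 0.25:
        severity = "mild"
    else:
        severity = "normal"
    if rng.random() < config.unknown_severity_fraction:
        severity = "unknown"

    # months since stroke, long right tail (lognormal ≈ mean 46, sd 54)
    recovery = float(rng.lognormal(mean=3.40, sigma=0.93))
    return lesion, truth, left_size, severity, recovery


def _linear_predictor(truth: dict[int, float], severity: str, recovery: float,
                      config: CohortConfig) -> float:
    eta = sum(w * truth[rid] for rid, w in
              zip(config.causal_region_ids, config.effect_weights))
    eta += config.tabular_effects.get("severity", 0.0) * SEVERITY_CODE[severity]
    # standardised log-months so the weight is scale-free
    eta += config.tabular_effects.get("recovery_time", 0.0) * \
        (np.log1p(recovery) - 3.4)
    return float(eta)


def calibrate_intercept(atlas: SyntheticAtlas, config: CohortConfig,
                        n_probe: int = 400) -> float:
    """Solve the logistic intercept so E[impaired] ≈ target_prevalence.

    Uses a deterministic probe sample of subject geometries (no intensity
    rendering) drawn from ``config.seed``; Brent root-finding on the mean
    predicted probability.
    """
    rng = np.random.default_rng((config.seed, 0xCA11))
    etas = []
    for _ in range(n_probe):
        _, truth, _, severity, recovery = _sample_geometry(atlas, config, rng)
        etas.append(_linear_predictor(truth, severity, recovery, config))
    etas = np.asarray(etas)

    def gap(b):
        return (1.0 / (1.0 + np.exp(-(etas + b)))).mean() \
            - config.target_prevalence

    return float(optimize.brentq(gap, -30.0, 30.0))


def _render_volume(atlas: SyntheticAtlas, lesion: np.ndarray,
                   rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    mask = atlas.brain_mask
    shape = mask.shape
    texture = ndimage.gaussian_filter(rng.normal(size=shape), sigma=6.0)
    t = texture.std()
    texture = texture / t if t > 0 else texture
    vol = np.where(mask, 0.7 + 0.12 * texture, 0.0)
    vol[lesion] = 0.15            # focal hypointensity
    vol += np.where(mask, rng.normal(0.0, noise_sd, size=shape), 0.0)
    return np.clip(vol, 0.0, 1.2)


def generate_subject(atlas: SyntheticAtlas, config: CohortConfig,
                     subject_seed: int, subject_id: str | None = None
                     ) -> SyntheticSubject:
    """One simulated subject: volume, lesion mask, tabular record, outcome."""
    config.validate_against(atlas)
    intercept = config.intercept
    if intercept is None:
        intercept = calibrate_intercept(atlas, config)
    rng = np.random.default_rng((config.seed, int(subject_seed)))
    lesion, truth, left_size, severity, recovery = \
        _sample_geometry(atlas, config, rng)
    eta = intercept + _linear_predictor(truth, severity, recovery, config)
    outcome = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
    volume = _render_volume(atlas, lesion, rng, config.noise_sd)
    return SyntheticSubject(
        subject_id=subject_id or f"sub-{subject_seed:05d}",
        volume=volume, lesion_mask=lesion,
        tabular=TabularRecord(severity, left_size, recovery, outcome),
        outcome=outcome, truth=truth)


def generate_cohort(atlas: SyntheticAtlas, config: CohortConfig,
                    out_dir=None, render: bool = True
                    ) -> tuple[list[SyntheticSubject], dict]:
    """Generate ``config.n_subjects`` subjects plus a manifest.

    ``render=False`` skips intensity rendering (volumes filled with zeros)
    for analyses that only need lesion geometry and tabular data.  When
    ``out_dir`` is given, writes NIfTI volumes/masks, ``cohort.csv``,
    ``truth.csv`` and ``manifest.json``.
    """
    config.validate_against(atlas)
    if config.intercept is None:
        config = replace(config, intercept=calibrate_intercept(atlas, config))
    rng = np.random.default_rng((config.seed, 0x5EED))
    subject_seeds = rng.integers(0, 2 ** 31 - 1,
                                 size=config.n_subjects).tolist()
    subjects = []
    for i, ss in enumerate(subject_seeds):
        if render:
            subj = generate_subject(atlas, config, ss,
                                    subject_id=f"sub-{i:05d}")
        else:
            srng = np.random.default_rng((config.seed, int(ss)))
            lesion, truth, left_size, severity, recovery = \
                _sample_geometry(atlas, config, srng)
            eta = config.intercept + _linear_predictor(
                truth, severity, recovery, config)
            outcome = int(srng.random() < 1.0 / (1.0 + np.exp(-eta)))
            subj = SyntheticSubject(
                subject_id=f"sub-{i:05d}",
                # read-only zero view: geometry-only subjects carry no
                # rendered intensities, and no per-subject allocation
                volume=np.broadcast_to(np.float64(0.0),
                                       atlas.label_volume.shape),
                lesion_mask=lesion,
                tabular=TabularRecord(severity, left_size, recovery, outcome),
                outcome=outcome, truth=truth)
        subjects.append(subj)

    manifest = {
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "subject_seeds": [int(s) for s in subject_seeds],
        "intercept": config.intercept,
        "target_prevalence": config.target_prevalence,
        "causal_region_ids": list(config.causal_region_ids),
        "effect_weights": list(config.effect_weights),
        "grid_shape": list(config.grid_shape),
    }
    if out_dir is not None:
        _write_cohort(Path(out_dir), atlas, subjects, manifest, render)
    return subjects, manifest


def cohort_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": s.subject_id,
        "initial_severity": s.tabular.initial_severity,
        "left_lesion_size": s.tabular.left_lesion_size,
        "recovery_time_months": s.tabular.recovery_time,
        "outcome": s.outcome,
    } for s in subjects])


def truth_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update({f"region_{rid:03d}": frac for rid, frac in s.truth.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _write_cohort(out: Path, atlas: SyntheticAtlas,
                  subjects: list[SyntheticSubject], manifest: dict,
                  render: bool) -> None:
    import nibabel as nib

    try:
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([atlas.voxel_size] * 3 + [1.0])
        atlas.save(out / "atlas.nii.gz")
        if render:
            for s in subjects:
                nib.save(nib.Nifti1Image(
                    s.volume.astype(np.float32), affine),
                    str(out / f"{s.subject_id}_T1.nii.gz"))
                nib.save(nib.Nifti1Image(
                    s.lesion_mask.astype(np.uint8), affine),
                    str(out / f"{s.subject_id}_lesion.nii.gz"))
        cohort_table(subjects).to_csv(out / "cohort.csv", index=False)
        truth_table(subjects).to_csv(out / "truth.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing cohort to {out}: {exc}") from exc
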