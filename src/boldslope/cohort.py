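"""Synthetic lifespan rs-fMRI cohort generator.

Produces everything the downstream analysis consumes: a subject covariate
table, spherical parcel geometry with network probabilities, per-subject
parcel timeseries whose expected spectra are 1/f-like (semilog-linear) over
a flat noise floor, parcel-level metabolic maps, and small T2w-like
volumes with a frontal-white-matter lesion effect in divergent subjects.

The planted structure mirrors the statistical features the analysis is
meant to detect:

* per-parcel spectral slopes decline with age along one of two trajectory
  families — continuous flattening from age 20, or flat until a mid-life
  onset (default 50 y) followed by steeper flattening;
* decline is fastest in parcels with steep youthful slopes, so the map of
  age effects correlates with the (slope-derived) metabolic maps;
* a minority of older subjects have their across-parcel slope profile
  rank-permuted — topography destroyed, marginal values untouched — and
  those subjects also carry elevated T2w intensity in the FLWM ROI.

Everything is reproducible from CohortSpec.seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .spectral import FrameSeries

RSN_NAMES = ("VIS", "SMN", "AUD", "CON", "SAL", "DMN", "FPN")

#: networks whose parcels preferentially follow the delayed-onset family
_CLUSTER2_RSNS = ("AUD", "CON", "SAL")

# seed directions of the network probability fields, in (|x|, y, z) space
# so the two hemispheres are mirror-symmetric
_RSN_SEEDS = {
    "VIS": (0.25, -0.90, -0.10),
    "SMN": (0.15, 0.05, 0.95),
    "AUD": (0.95, 0.10, -0.20),
    "CON": (0.55, 0.45, 0.60),
    "SAL": (0.70, 0.60, 0.10),
    "DMN": (0.15, 0.60, -0.55),
    "FPN": (0.60, -0.35, 0.55),
}

# generator constants (see docs/methods.md for rationale)
_BASELINE_MEAN = 10.0        # mean youthful spectral slope (per Hz)
_BASELINE_GRAD = 4.0         # amplitude of the smooth baseline gradient
_BASELINE_QUAD = 1.0
_BASELINE_NOISE = 0.5        # unstructured per-parcel baseline scatter
_SUBJECT_OFFSET_SD = 1.2     # per-subject global slope offset
_PARCEL_JITTER_SD = 0.3      # per-(subject, parcel) slope jitter
_ASSUMED_EST_NOISE_SD = 1.0  # estimation noise assumed in the rate calibration
_RATE_TOPO_GAIN = 0.3        # decline-rate modulation by baseline z-score
_LOG_AMPLITUDE = 2.0         # log10 power at f = 0
_DECLINE_START_AGE = 20.0
_MEDIAL_CAP_DEG = 25.0       # angular radius of the medial-wall cap

_T2W_SHAPE = (24, 24, 24)
_T2W_NOISE_SD = 5.0
# contiguous frontal-white-matter box (anterior = +y, mid-superior z)
_FLWM_BOX = (slice(8, 14), slice(16, 22), slice(12, 18))
_ATLAS_AGE_CUTOFF = 40.0

_STREAM_SUBJECTS = 1
_STREAM_GEOMETRY = 2
_STREAM_SLOPES = 3
_STREAM_SERIES = 4
_STREAM_METABOLIC = 5
_STREAM_T2W = 6


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 88.0)
    n_parcels: int = 100
    n_frames: int = 261
    tr: float = 1.97
    seed: int = 0
    frac_cluster2: float = 0.30
    onset_age: float = 50.0
    outlier_frac: float = 0.10
    noise_floor: float = 0.1
    slope_effect_frac: float = 0.10
    lesion_effect: float = 10.0
    censor_rate: float = 0.10
    decline_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError(f"n_frames must be >= 64, got {self.n_frames}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range lo must be < hi, got {self.age_range}")
        for name in ("frac_cluster2", "outlier_frac", "censor_rate", "slope_effect_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.slope_effect_frac <= 0.12:
            raise ValueError(
                f"slope_effect_frac must be in [0, 0.12], got {self.slope_effect_frac}"
            )
        if self.noise_floor < 0:
            raise ValueError(f"noise_floor must be >= 0, got {self.noise_floor}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")


def _rng(spec: CohortSpec, stream: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream, *keys]))


# ---------------------------------------------------------------------------
# subjects


def generate_subject_table(spec: CohortSpec) -> pd.DataFrame:
    """Subject covariates plus the planted divergence (outlier) flag.

    Ages are uniform over the age range; sex is balanced Bernoulli; head
    motion is log-normal (median ~0.15 mm); grey-matter volume is Gaussian
    in 3 mm voxel counts.  Only subjects older than 45 y can be flagged as
    outliers, at rate ``outlier_frac`` among them; covariates are drawn
    independently of the flag, so covariate-vs-outlier tests have a true
    null.
    """
    rng = _rng(spec, _STREAM_SUBJECTS)
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, spec.n_subjects)
    sex = rng.choice(["F", "M"], size=spec.n_subjects)
    motion = np.exp(rng.normal(np.log(0.15), 0.5, spec.n_subjects))
    gmv = np.clip(rng.normal(24000.0, 2500.0, spec.n_subjects), 8000, None).round()
    outlier = (age > 45.0) & (rng.random(spec.n_subjects) < spec.outlier_frac)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(spec.n_subjects)],
            "age": age,
            "sex": sex,
            "head_motion": motion,
            "gmv": gmv,
            "outlier": outlier,
        }
    )


# ---------------------------------------------------------------------------
# geometry


def _fibonacci_sphere(n: int, offset: float = 0.5) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + offset) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _mirror_coords(xyz: np.ndarray, hemi: np.ndarray) -> np.ndarray:
    """Coordinates in the mirror-symmetric (|x|, y, z) frame."""
    out = xyz.copy()
    out[:, 0] = np.abs(out[:, 0])
    return out


def generate_parcel_geometry(spec: CohortSpec) -> pd.DataFrame:
    """Quasi-uniform unit-sphere centroids per hemisphere with RSN weights.

    Each hemisphere gets its own Fibonacci lattice (the spin test treats
    each hemisphere as a full sphere).  Parcels inside a fixed angular cap
    around the medial pole (+x for L, -x for R) are flagged medial_wall.
    RSN probabilities are softmax fields around mirrored seed directions
    and sum to one per parcel.
    """
    if spec.n_parcels < 10:
        raise ValueError(f"n_parcels must be >= 10, got {spec.n_parcels}")
    n_left = spec.n_parcels - spec.n_parcels // 2
    n_right = spec.n_parcels // 2
    left = _fibonacci_sphere(n_left)
    right = _fibonacci_sphere(n_right)
    right[:, 0] *= -1.0  # mirror
    xyz = np.vstack([left, right])
    hemi = np.array(["L"] * n_left + ["R"] * n_right)

    # medial pole is +x on the left sphere, -x on the right
    pole_x = np.where(hemi == "L", 1.0, -1.0)
    cos_to_pole = xyz[:, 0] * pole_x
    medial = cos_to_pole > np.cos(np.deg2rad(_MEDIAL_CAP_DEG))

    cm = _mirror_coords(xyz, hemi)
    probs = np.empty((spec.n_parcels, len(RSN_NAMES)))
    for j, name in enumerate(RSN_NAMES):
        seed = np.asarray(_RSN_SEEDS[name], dtype=float)
        seed = seed / np.linalg.norm(seed)
        theta = np.arccos(np.clip(cm @ seed, -1.0, 1.0))
        probs[:, j] = np.exp(-0.5 * (theta / 0.5) ** 2)
    probs /= probs.sum(axis=1, keepdims=True)

    geom = pd.DataFrame(
        {
            "parcel_id": np.arange(1, spec.n_parcels + 1),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "hemisphere": hemi,
            "medial_wall": medial,
        }
    )
    for j, name in enumerate(RSN_NAMES):
        geom[f"rsn_{name}"] = probs[:, j]
    return geom


# ---------------------------------------------------------------------------
# trajectories and target slopes


def _age_term(age: np.ndarray, onset: float, exponent: float) -> np.ndarray:
    return np.maximum(0.0, np.asarray(age, dtype=float) - onset) ** exponent


def _calibrated_rate(spec: CohortSpec) -> float:
    """Decline rate hitting the target fraction of SS variance due to age.

    Solves var(rate * g(age)) / (var(rate * g(age)) + sigma_off^2) =
    slope_effect_frac, where g is the cluster-1 age term over a uniform age
    distribution and sigma_off^2 collects subject offsets, parcel jitter
    and the assumed estimation noise.
    """
    p = spec.slope_effect_frac
    if p == 0:
        return 0.0
    lo, hi = spec.age_range
    grid = np.linspace(lo, hi, 4001)
    g = _age_term(grid, _DECLINE_START_AGE, spec.decline_exponent)
    sd_g = float(np.std(g))
    sigma_off2 = (
        _SUBJECT_OFFSET_SD**2 + _PARCEL_JITTER_SD**2 + _ASSUMED_EST_NOISE_SD**2
    )
    return float(np.sqrt(p / (1.0 - p) * sigma_off2) / sd_g)


def assign_trajectories(spec: CohortSpec, geometry: pd.DataFrame) -> pd.DataFrame:
    """Per-parcel trajectory family, baseline slope and decline rate.

    The delayed-onset family (cluster 2) is assigned to the parcels with
    the highest combined AUD+CON+SAL probability; its rate is scaled so the
    total decline by the end of the age range matches cluster 1.  Baseline
    slopes form a smooth gradient on the sphere plus scatter, and the rate
    is modulated by the baseline z-score (steep youthful parcels flatten
    fastest).
    """
    rng = _rng(spec, _STREAM_GEOMETRY)
    xyz = geometry[["x", "y", "z"]].to_numpy()
    cm = _mirror_coords(xyz, geometry["hemisphere"].to_numpy())
    u1 = np.array([0.3, 0.75, 0.59])
    u1 /= np.linalg.norm(u1)
    u2 = np.array([0.8, -0.2, 0.56])
    u2 /= np.linalg.norm(u2)
    s0 = (
        _BASELINE_MEAN
        + _BASELINE_GRAD * (cm @ u1)
        + _BASELINE_QUAD * ((cm @ u2) ** 2 - 1.0 / 3.0)
        + rng.normal(0.0, _BASELINE_NOISE, len(geometry))
    )
    s0 = np.clip(s0, 3.0, None)

    score = sum(geometry[f"rsn_{n}"].to_numpy() for n in _CLUSTER2_RSNS)
    n_c2 = int(round(spec.frac_cluster2 * len(geometry)))
    order = np.argsort(-score, kind="stable")
    cluster = np.ones(len(geometry), dtype=int)
    cluster[order[:n_c2]] = 2

    rate1 = _calibrated_rate(spec)
    lo, hi = spec.age_range
    span1 = max(hi - _DECLINE_START_AGE, 1.0)
    span2 = max(hi - spec.onset_age, 1.0)
    z = (s0 - s0.mean()) / max(s0.std(), 1e-12)
    topo = np.clip(1.0 + _RATE_TOPO_GAIN * z, 0.3, 2.0)
    rate = np.where(cluster == 1, rate1, rate1 * span1 / span2) * topo

    return pd.DataFrame(
        {
            "parcel_id": geometry["parcel_id"].to_numpy(),
            "cluster": cluster,
            "baseline_slope": s0,
            "decline_rate": rate,
            "onset_age": np.where(cluster == 1, _DECLINE_START_AGE, spec.onset_age),
        }
    )


def trajectory_curve(
    traj_row: pd.Series, ages: np.ndarray, exponent: float = 1.0
) -> np.ndarray:
    """Planted mean slope trajectory of one parcel over an age grid."""
    return traj_row["baseline_slope"] - traj_row["decline_rate"] * _age_term(
        ages, traj_row["onset_age"], exponent
    )


def target_slope_matrix(
    spec: CohortSpec,
    subjects: pd.DataFrame,
    trajectories: pd.DataFrame,
    geometry: pd.DataFrame,
) -> np.ndarray:
    """Planted per-(subject, parcel) target spectral slopes.

    Adds a per-subject global offset and per-cell jitter to the trajectory
    means; for outlier subjects the profile across non-medial parcels is
    randomly permuted, which destroys the topography while preserving the
    marginal multiset of values.
    """
    rng = _rng(spec, _STREAM_SLOPES)
    ages = subjects["age"].to_numpy()
    base = trajectories["baseline_slope"].to_numpy()[None, :]
    rate = trajectories["decline_rate"].to_numpy()[None, :]
    onset = trajectories["onset_age"].to_numpy()
    term = np.stack(
        [_age_term(ages, o, spec.decline_exponent) for o in np.unique(onset)], axis=1
    )
    onset_idx = np.searchsorted(np.unique(onset), onset)
    s = base - rate * term[:, onset_idx]
    s = s + rng.normal(0.0, _SUBJECT_OFFSET_SD, (len(subjects), 1))
    s = s + rng.normal(0.0, _PARCEL_JITTER_SD, s.shape)
    s = np.clip(s, 0.5, None)

    nonmed = ~geometry["medial_wall"].to_numpy()
    idx_nonmed = np.flatnonzero(nonmed)
    for i in np.flatnonzero(subjects["outlier"].to_numpy()):
        perm = _rng(spec, _STREAM_SLOPES, 1000 + int(i)).permutation(len(idx_nonmed))
        s[i, idx_nonmed] = s[i, idx_nonmed[perm]]
    return s


# ---------------------------------------------------------------------------
# timeseries synthesis


def _expected_psd(freq: np.ndarray, slope: np.ndarray, noise_floor: float) -> np.ndarray:
    """Two-sided target density: semilog line over a flat floor."""
    return 10.0 ** (_LOG_AMPLITUDE - np.outer(freq, slope)) + noise_floor


def synthesize_series(
    slopes: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
    noise_floor: float | None = None,
) -> np.ndarray:
    """Gaussian series (frames x len(slopes)) via random-phase synthesis.

    The expected periodogram of column j equals
    10^(A - slopes[j] * f) + noise_floor, so the lag-window estimator's
    in-band semilog slope targets slopes[j] exactly (Gaussian-in-frequency
    smoothing of an exponential preserves its log-slope).
    """
    if noise_floor is None:
        noise_floor = spec.noise_floor
    if noise_floor < 0:
        raise ValueError(f"noise_floor must be >= 0, got {noise_floor}")
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    n = spec.n_frames
    k = np.arange(n // 2 + 1)
    freq = k / (n * spec.tr)
    s2 = _expected_psd(freq, slopes, noise_floor)  # (n_freq, n_parcels)
    amp = np.sqrt(n * s2 / (2.0 * spec.tr))
    zr = rng.standard_normal(s2.shape)
    zi = rng.standard_normal(s2.shape)
    spec_c = amp * (zr + 1j * zi)
    spec_c[0] = 0.0  # no DC; series are demeaned downstream anyway
    if n % 2 == 0:
        spec_c[-1] = np.sqrt(n * s2[-1] / spec.tr) * zr[-1]
    return np.fft.irfft(spec_c, n=n, axis=0)


def _valid_mask(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(spec.n_frames) >= spec.censor_rate
    if mask.sum() < 2:  # pathological censor rates; keep the series usable
        mask[:2] = True
    return mask


def generate_timeseries(
    subject: pd.Series,
    parcel: pd.Series,
    traj: pd.Series,
    spec: CohortSpec,
) -> FrameSeries:
    """Single subject x parcel series with its valid-frame mask.

    The cohort-level rank permutation for outlier subjects operates across
    parcels and therefore lives in :func:`target_slope_matrix`; this
    single-parcel entry point uses the unpermuted trajectory target.
    """
    ages = np.array([subject["age"]])
    s = float(
        traj["baseline_slope"]
        - traj["decline_rate"] * _age_term(ages, traj["onset_age"], spec.decline_exponent)[0]
    )
    sub_key = int(str(subject["subject_id"]).split("-")[-1])
    rng = _rng(spec, _STREAM_SERIES, sub_key, int(parcel["parcel_id"]))
    values = synthesize_series(np.array([s]), spec, rng)[:, 0]
    return FrameSeries(values=values, tr=spec.tr, valid=_valid_mask(spec, rng))


def generate_cohort_timeseries(
    spec: CohortSpec,
    subjects: pd.DataFrame,
    trajectories: pd.DataFrame,
    geometry: pd.DataFrame,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """All subjects' frames x parcels matrices with shared per-subject masks.

    Returns mapping subject_id -> (values, valid).
    """
    slopes = target_slope_matrix(spec, subjects, trajectories, geometry)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, sid in enumerate(subjects["subject_id"]):
        rng = _rng(spec, _STREAM_SERIES, i)
        values = synthesize_series(slopes[i], spec, rng)
        out[str(sid)] = (values, _valid_mask(spec, rng))
    return out


# ---------------------------------------------------------------------------
# metabolic maps


def generate_metabolic_maps(
    geometry: pd.DataFrame,
    trajectories: pd.DataFrame,
    spec: CohortSpec,
    noise_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Parcel maps of CMRGlc, CMRO2 and CBF tied to youthful slope topography.

    CMRGlc is a monotone (sigmoidal) transform of the baseline slope map
    plus noise, so its rank correlation with the youthful SS map is high by
    construction; CMRO2 and CBF use progressively larger noise, making
    their correlations weaker.
    """
    sd = {"cmrglc": 8.0, "cmro2": 14.0, "cbf": 18.0}
    if noise_sd:
        sd.update(noise_sd)
    rng = _rng(spec, _STREAM_METABOLIC)
    s0 = trajectories["baseline_slope"].to_numpy()
    signal = 40.0 / (1.0 + np.exp(-(s0 - _BASELINE_MEAN) / 2.0))
    out = pd.DataFrame({"parcel_id": geometry["parcel_id"].to_numpy()})
    for name in ("cmrglc", "cmro2", "cbf"):
        out[name] = signal + rng.normal(0.0, sd[name], len(geometry))
    return out


# ---------------------------------------------------------------------------
# T2w volumes


@dataclass
class T2wData:
    """Per-subject intensity volumes plus ROI mask and young reference atlas."""

    volumes: np.ndarray      # (n_subjects, *shape)
    roi_mask: np.ndarray     # boolean FLWM box
    atlas_mean: np.ndarray
    atlas_sd: np.ndarray
    affine: np.ndarray = field(
        default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0])
    )
    subject_ids: list[str] = field(default_factory=list)


def generate_t2w_volumes(
    subjects: pd.DataFrame,
    spec: CohortSpec,
    shape: tuple[int, int, int] = _T2W_SHAPE,
    noise_sd: float = _T2W_NOISE_SD,
) -> T2wData:
    """T2w-like volumes: pure noise outside the FLWM ROI, lesion shift inside.

    Within the contiguous FLWM box the intensity is
    lesion_effect * outlier + noise; the reference atlas (voxelwise mean
    and sd) is computed from subjects younger than 40 y.
    """
    roi = np.zeros(shape, dtype=bool)
    roi[_FLWM_BOX] = True
    if not roi.any():
        raise ValueError("FLWM ROI is empty for the requested volume shape")
    rng = _rng(spec, _STREAM_T2W)
    n = len(subjects)
    vols = rng.normal(0.0, noise_sd, (n, *shape)) if noise_sd > 0 else np.zeros((n, *shape))
    shift = spec.lesion_effect * subjects["outlier"].to_numpy().astype(float)
    vols[:, roi] += shift[:, None]

    young = subjects["age"].to_numpy() < _ATLAS_AGE_CUTOFF
    if young.sum() < 2:
        raise ValueError("need at least 2 subjects under 40 y for the reference atlas")
    atlas_mean = vols[young].mean(axis=0)
    atlas_sd = vols[young].std(axis=0, ddof=0)
    return T2wData(
        volumes=vols,
        roi_mask=roi,
        atlas_mean=atlas_mean,
        atlas_sd=atlas_sd,
        subject_ids=[str(s) for s in subjects["subject_id"]],
    )
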