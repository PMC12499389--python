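"""SS Youthful Index: individual similarity to the young slope topography.

The SSYI of a subject is the Spearman correlation between their parcel SS
map and the mean SS map of young subjects (< 45 y).  Subjects whose SSYI
falls more than 3 scaled MADs below/above the median are flagged as
outliers — these are the individuals whose slope topography has diverged
from the youthful pattern.  White-matter correlates are probed by
z-normalizing T2w volumes against a young-subject intensity atlas,
mapping voxelwise Pearson correlations between intensity and SSYI
(VLSM-style), and fitting a linear model of outlier status on age, GMV,
head motion, sex and FLWM T2w intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spin import spearman_map_correlation

MAD_SCALE = 1.4826          # Gaussian-consistency constant
SS_REFERENCE_CUTOFF = 45.0  # years; subjects below this define the young map


@dataclass
class ReferenceMap:
    values: pd.Series     # parcel-wise mean SS over reference subjects
    n_reference: int
    age_cutoff: float


def young_reference_map(
    ss_maps: pd.DataFrame, subjects: pd.DataFrame, cutoff: float = SS_REFERENCE_CUTOFF
) -> ReferenceMap:
    """Parcel-wise mean SS over subjects strictly younger than ``cutoff``.

    ``ss_maps`` is subjects x parcels, indexed by subject_id.
    """
    ages = subjects.set_index("subject_id")["age"].reindex(ss_maps.index)
    young = ages < cutoff
    n = int(young.sum())
    if n < 10:
        raise ValueError(f"need >= 10 subjects under {cutoff} y, got {n}")
    return ReferenceMap(
        values=ss_maps.loc[young.to_numpy()].mean(axis=0),
        n_reference=n,
        age_cutoff=cutoff,
    )


def compute_ssyi(subject_map: pd.Series, reference: ReferenceMap | pd.Series) -> float:
    """Spearman correlation of one subject's SS map with the young mean map."""
    ref = reference.values if isinstance(reference, ReferenceMap) else reference
    return spearman_map_correlation(subject_map, ref)


def mad_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Flag values more than k scaled MADs from the median.

    Scaled MAD = 1.4826 * median(|x - median(x)|); a zero MAD (all values
    equal) flags nothing.  Flags are invariant under increasing affine
    transforms of the data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 values, got {x.size}")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    if smad == 0:
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) > k * smad


def normalize_t2w(
    volume: np.ndarray, atlas_mean: np.ndarray, atlas_sd: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Voxelwise z-score against the young-subject reference atlas."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != atlas_mean.shape or volume.shape != atlas_sd.shape:
        raise ValueError(
            f"grid mismatch: volume {volume.shape} vs atlas {atlas_mean.shape}"
        )
    return (volume - atlas_mean) / np.maximum(atlas_sd, eps)


def voxelwise_ssyi_correlation(
    volumes: np.ndarray, ssyi: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel Pearson r between normalized intensity and SSYI.

    ``volumes`` is subjects x voxels (any trailing shape).  Returns
    (r volume, significance mask at two-sided p < alpha, zero-variance
    flags).  No multiple-comparison correction — exploratory map.
    """
    vols = np.asarray(volumes, dtype=float)
    y = np.asarray(ssyi, dtype=float)
    n = vols.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 subjects, got {n}")
    if y.size != n:
        raise ValueError("ssyi length must match number of volumes")
    shape = vols.shape[1:]
    flat = vols.reshape(n, -1)
    yc = y - y.mean()
    xc = flat - flat.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sx * sy)
    r[zero_var] = np.nan
    # two-sided p from the t transform
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    mask = (p < alpha) & ~zero_var
    return r.reshape(shape), mask.reshape(shape), zero_var.reshape(shape)


def roi_mean_intensity(volume: np.ndarray, mask: np.ndarray) -> float:
    """Mean normalized intensity over masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(np.asarray(volume, dtype=float)[mask].mean())


@dataclass
class RegressionResult:
    """Linear probability model of youthful status (1 = non-outlier)."""

    coefficients: pd.DataFrame  # index: term; columns: estimate, se, p
    n_used: int


_EQ_TERMS = ("const", "age", "gmv", "head_motion", "sex", "flwm_t2w")


def outlier_regression(records: pd.DataFrame, min_age: float = 45.0) -> RegressionResult:
    """OLS of the binarized youthful index on the five covariates.

    ``records`` needs columns ssyi-outlier (boolean ``outlier_flag``), age,
    gmv, head_motion, sex and flwm_t2w.  The response is coded 1 for
    subjects retaining the youthful pattern and 0 for outliers, so an
    elevated-FLWM-in-outliers effect yields a negative FLWM coefficient.
    Only subjects older than ``min_age`` enter the fit.
    """
    import statsmodels.api as sm

    sel = records[records["age"] > min_age].copy()
    if len(sel) < 30:
        raise ValueError(f"need >= 30 subjects older than {min_age}, got {len(sel)}")
    y = 1.0 - sel["outlier_flag"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response has no variance (all subjects in one group)")
    sex = sel["sex"]
    sex_num = (
        sex.map({"F": 0.0, "M": 1.0}).to_numpy()
        if sex.dtype == object
        else sex.to_numpy(dtype=float)
    )
    X = np.column_stack(
        [
            sel["age"].to_numpy(dtype=float),
            sel["gmv"].to_numpy(dtype=float),
            sel["head_motion"].to_numpy(dtype=float),
            sex_num,
            sel["flwm_t2w"].to_numpy(dtype=float),
        ]
    )
    for j, name in enumerate(_EQ_TERMS[1:]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant predictor '{name}'")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues},
        index=pd.Index(_EQ_TERMS, name="term"),
    )
    return RegressionResult(coefficients=coefs, n_used=int(fit.nobs))
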