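"""Spatial association between parcellated maps with spin-permutation nulls.

Two parcel maps are compared with Spearman correlation; significance comes
from randomly rotating one map's spherical parcel centroids (uniform
rotations drawn via normalized Gaussian quaternions, mirrored across
hemispheres) and re-assigning values by nearest centroid.  The rotation
null preserves the map's values and spatial autocorrelation while breaking
its alignment with the other map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_ROTATIONS = 10000


def spearman_map_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman rho over jointly non-missing parcels (average ranks for ties)."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 10:
        raise ValueError(f"need >= 10 jointly non-missing parcels, got {len(joined)}")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant map: Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) rotations from normalized 4-D Gaussian quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def mirror_rotation(R: np.ndarray) -> np.ndarray:
    """The x-flipped rotation applied to the opposite hemisphere."""
    M = np.diag([-1.0, 1.0, 1.0])
    return M @ R @ M


@dataclass
class SpinEnsemble:
    """Precomputed nearest-centroid reassignments for a rotation ensemble.

    ``assignment[r, j]`` is the source-parcel row index whose rotated
    centroid is nearest to original (non-medial) target row j under
    rotation r.  Sources whose rotated position lands nearest a
    medial-wall centroid are dropped before targets choose, implementing
    the 'rotated into the medial wall' exclusion.
    """

    assignment: np.ndarray    # (n_rotations, n_targets) indices into targets
    target_rows: np.ndarray   # row indices of non-medial parcels in geometry
    n_rotations: int
    seed: int


def _hemi_assign(
    cen: np.ndarray, medial: np.ndarray, rotated: np.ndarray
) -> np.ndarray:
    """Nearest-source assignment for one hemisphere, one rotation.

    ``cen``/``medial`` describe all original parcels of the hemisphere;
    ``rotated`` holds the rotated centroids of its non-medial sources.
    Returns, per non-medial target, the index into the source list (or -1
    if every source was lost to the medial wall).
    """
    # great-circle distance is monotone in chordal distance on the unit
    # sphere, so nearest-by-dot-product is equivalent
    dots_all = rotated @ cen.T                      # sources x all targets
    nearest_target = np.argmax(dots_all, axis=1)
    alive = ~medial[nearest_target]
    targets = np.flatnonzero(~medial)
    if not alive.any():
        return np.full(len(targets), -1, dtype=np.int64)
    live_idx = np.flatnonzero(alive)
    dots_live = dots_all[alive][:, targets]         # live sources x targets
    return live_idx[np.argmax(dots_live, axis=0)]


def build_spin_ensemble(
    geometry: pd.DataFrame, n_rotations: int = DEFAULT_N_ROTATIONS, seed: int = 0
) -> SpinEnsemble:
    """Draw rotations and precompute parcel reassignments for a geometry.

    The left hemisphere gets each rotation directly, the right hemisphere
    its x-mirrored counterpart; each hemisphere is treated as a full unit
    sphere.
    """
    rng = np.random.default_rng(seed)
    Rs = random_rotations(n_rotations, rng)
    hemi = geometry["hemisphere"].to_numpy()
    medial = geometry["medial_wall"].to_numpy(dtype=bool)
    cen = geometry[["x", "y", "z"]].to_numpy(dtype=float)
    nonmed = np.flatnonzero(~medial)

    # position of each non-medial parcel within the target list
    pos_in_targets = {row: k for k, row in enumerate(nonmed)}
    assignment = np.empty((n_rotations, len(nonmed)), dtype=np.int64)
    for h in ("L", "R"):
        rows_h = np.flatnonzero(hemi == h)
        if rows_h.size == 0:
            continue
        med_h = medial[rows_h]
        cen_h = cen[rows_h]
        src_rows = rows_h[~med_h]
        tgt_cols = np.array([pos_in_targets[r] for r in rows_h[~med_h]])
        for r in range(n_rotations):
            R = Rs[r] if h == "L" else mirror_rotation(Rs[r])
            rotated = cen_h[~med_h] @ R.T
            local = _hemi_assign(cen_h, med_h, rotated)
            # map local source indices back to target-list positions
            assignment[r, tgt_cols] = np.where(local >= 0, tgt_cols[local], -1)
    return SpinEnsemble(
        assignment=assignment, target_rows=nonmed, n_rotations=n_rotations, seed=seed
    )


@dataclass
class SpinResult:
    rho: float
    p_spin: float
    n_rotations: int
    seed: int
    null_corrs: np.ndarray


def spin_pvalue(
    a: pd.Series,
    b: pd.Series,
    geometry: pd.DataFrame,
    n_rotations: int = DEFAULT_N_ROTATIONS,
    seed: int = 0,
    ensemble: SpinEnsemble | None = None,
) -> SpinResult:
    """One-sided spin-permutation p-value for Spearman(a, b).

    p_spin = (#{null > rho_obs} + 1) / (n_rotations + 1); the +1 guards the
    finite-sample zero.  Map ``a`` is the one being rotated.
    """
    geometry = geometry.reset_index(drop=True)
    pid = geometry["parcel_id"]
    medial = geometry["medial_wall"].to_numpy(dtype=bool)
    a_vals = a.reindex(pid).to_numpy(dtype=float)
    b_vals = b.reindex(pid).to_numpy(dtype=float)
    if np.isnan(a_vals[~medial]).all():
        raise ValueError("map a covers no non-medial parcels of this geometry")
    if np.isnan(b_vals[~medial]).mean() > 0.5:
        raise ValueError("map b missing for more than 50% of parcels")
    if ensemble is None:
        ensemble = build_spin_ensemble(geometry, n_rotations, seed)
    tgt = ensemble.target_rows
    a_t = a_vals[tgt]
    b_t = b_vals[tgt]
    obs_ok = ~(np.isnan(a_t) | np.isnan(b_t))
    if obs_ok.sum() < 10:
        raise ValueError("fewer than 10 jointly non-missing parcels")
    rho_obs = float(stats.spearmanr(a_t[obs_ok], b_t[obs_ok]).statistic)

    null = np.empty(ensemble.n_rotations)
    for r in range(ensemble.n_rotations):
        src = ensemble.assignment[r]
        ok = (src >= 0) & ~np.isnan(b_t)
        a_rot = a_t[src[ok]]
        keep = ~np.isnan(a_rot)
        null[r] = (
            stats.spearmanr(a_rot[keep], b_t[ok][keep]).statistic
            if keep.sum() >= 10
            else np.nan
        )
    valid_null = null[~np.isnan(null)]
    p = (float((valid_null > rho_obs).sum()) + 1.0) / (len(valid_null) + 1.0)
    return SpinResult(
        rho=rho_obs,
        p_spin=p,
        n_rotations=ensemble.n_rotations,
        seed=ensemble.seed,
        null_corrs=null,
    )
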