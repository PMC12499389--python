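"""Per-parcel lifespan GAMs of spectral slope on age.

Each cortical parcel gets a generalized additive model with a penalized
thin-plate spline of age (basis dimension k = 4, REML-selected smoothing)
plus linear sex and head-motion covariates, fitted by mgcv through an
Rscript worker.  The age effect is summarized two ways: the approximate
p-value of the smooth term, and the age-specific R² difference between the
full model and a covariates-only OLS reduced model.  P-values are
controlled across parcels with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_K = 4
DEFAULT_AGE_GRID = np.linspace(20.0, 85.0, 66)
MIN_ROWS = 50

_R_SCRIPT = Path(__file__).with_name("_mgcv.R")


class GamFitError(RuntimeError):
    pass


def _coerce_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        mapping = {"F": 0.0, "M": 1.0}
        try:
            return np.array([mapping[str(v)] for v in arr], dtype=float)
        except KeyError as exc:
            raise ValueError(f"unrecognized sex code {exc}") from exc
    return arr.astype(float)


@dataclass
class ParcelDesign:
    """Rows of (ss, age, sex, motion) across subjects for one parcel."""

    ss: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    motion: np.ndarray

    def __post_init__(self) -> None:
        self.ss = np.asarray(self.ss, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = _coerce_sex(self.sex)
        self.motion = np.asarray(self.motion, dtype=float)
        n = self.ss.size
        if any(a.size != n for a in (self.age, self.sex, self.motion)):
            raise ValueError("design columns must have equal length")
        if np.isnan(self.ss).any():
            raise ValueError("missing ss values in design")
        if n < MIN_ROWS:
            raise ValueError(f"need at least {MIN_ROWS} rows for fitting, got {n}")
        for name in ("age", "sex", "motion"):
            col = getattr(self, name)
            if np.ptp(col) == 0:
                raise ValueError(f"covariate '{name}' is constant; design is rank-deficient")

    def key(self) -> tuple:
        return (self.ss.size, float(self.age.sum()), float(self.sex.sum()), float(self.motion.sum()))


@dataclass
class GamResult:
    """Lifespan fit of one parcel: age smooth on a grid plus effect sizes."""

    age_grid: np.ndarray
    smooth: np.ndarray
    p_age: float
    edf: float
    r2_full: float
    r2_reduced: float
    delta_r2: float
    design_key: tuple | None = None


@dataclass
class ReducedFit:
    """Covariates-only OLS model (ss ~ sex + motion)."""

    r2: float
    params: np.ndarray
    nobs: int
    design_key: tuple


@dataclass
class GamTable:
    """Batch fit over parcels: results frame + smooth trajectory matrix."""

    results: pd.DataFrame   # index parcel_id: p_age, edf, r2_full, r2_reduced, delta_r2
    smooths: pd.DataFrame   # index parcel_id, columns age-grid values
    age_grid: np.ndarray


def _run_rscript(args: list[str]) -> None:
    exe = shutil.which("Rscript")
    if exe is None:
        raise GamFitError("Rscript not found on PATH; mgcv backend unavailable")
    proc = subprocess.run(
        [exe, "--vanilla", str(_R_SCRIPT), *args],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise GamFitError(f"mgcv worker failed:\n{proc.stderr.strip()}")


def fit_parcel_gams(
    ss: pd.DataFrame,
    covariates: pd.DataFrame,
    age_grid: np.ndarray = DEFAULT_AGE_GRID,
    k: int = DEFAULT_K,
) -> GamTable:
    """Fit the full GAM and reduced OLS model for every parcel column of ``ss``.

    ``ss`` is subjects x parcels (columns are parcel ids); ``covariates``
    must align row-wise and contain age, sex and motion (a ``head_motion``
    column is accepted).  One Rscript invocation handles all parcels.
    """
    cov = covariates.rename(columns={"head_motion": "motion"})
    design0 = ParcelDesign(
        ss.iloc[:, 0].to_numpy(), cov["age"], cov["sex"], cov["motion"]
    )  # validates shared covariates and row count
    if ss.isna().any().any():
        raise ValueError("missing ss values in design")
    resp = ss.astype(float).copy()
    resp.columns = [f"p{c}" for c in ss.columns]
    table = pd.concat(
        [
            pd.DataFrame(
                {"age": design0.age, "sex": design0.sex, "motion": design0.motion}
            ),
            resp.reset_index(drop=True),
        ],
        axis=1,
    )

    with tempfile.TemporaryDirectory(prefix="boldslope_gam_") as td:
        in_tsv = Path(td) / "design.tsv"
        out_res = Path(td) / "results.tsv"
        out_sm = Path(td) / "smooths.tsv"
        table.to_csv(in_tsv, sep="\t", index=False, float_format="%.15g")
        _run_rscript(
            [
                str(in_tsv),
                str(out_res),
                str(out_sm),
                str(k),
                f"{age_grid[0]:.15g}",
                f"{age_grid[-1]:.15g}",
                str(len(age_grid)),
            ]
        )
        res = pd.read_csv(out_res, sep="\t")
        sm = pd.read_csv(out_sm, sep="\t")

    idx = pd.Index([c[1:] for c in res["parcel"]], name="parcel_id")
    try:
        idx = idx.astype(int)
    except (TypeError, ValueError):
        pass
    results = res.drop(columns="parcel").set_index(idx)
    smooths = sm.drop(columns="parcel").set_index(idx)
    smooths.columns = age_grid
    return GamTable(results=results, smooths=smooths, age_grid=np.asarray(age_grid))


def fit_full_gam(
    design: ParcelDesign,
    age_grid: np.ndarray = DEFAULT_AGE_GRID,
    k: int = DEFAULT_K,
) -> GamResult:
    """Penalized thin-plate smooth of age (k basis functions, REML) for one parcel."""
    ss = pd.DataFrame({"1": design.ss})
    cov = pd.DataFrame({"age": design.age, "sex": design.sex, "motion": design.motion})
    tab = fit_parcel_gams(ss, cov, age_grid=age_grid, k=k)
    row = tab.results.iloc[0]
    return GamResult(
        age_grid=tab.age_grid,
        smooth=tab.smooths.iloc[0].to_numpy(),
        p_age=float(row["p_age"]),
        edf=float(row["edf"]),
        r2_full=float(row["r2_full"]),
        r2_reduced=float(row["r2_reduced"]),
        delta_r2=float(row["delta_r2"]),
        design_key=design.key(),
    )


def fit_reduced_model(design: ParcelDesign) -> ReducedFit:
    """OLS of ss on sex and motion only ("covariates-only" model)."""
    import statsmodels.api as sm

    exog = sm.add_constant(np.column_stack([design.sex, design.motion]))
    fit = sm.OLS(design.ss, exog).fit()
    return ReducedFit(
        r2=float(fit.rsquared),
        params=np.asarray(fit.params),
        nobs=int(fit.nobs),
        design_key=design.key(),
    )


def age_effect_test(full: GamResult, reduced: ReducedFit) -> tuple[float, float]:
    """Age-effect p-value and ΔR² = R²(full) - R²(reduced).

    Both models must have been fit on the identical rows.
    """
    if full.design_key is None or full.design_key != reduced.design_key:
        raise ValueError("full and reduced models were fit on different rows")
    return full.p_age, full.r2_full - reduced.r2


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up across parcels."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({"p": p, "q": q, "significant": reject})


def trajectory_curves(
    gam_table: GamTable,
    fdr_table: pd.DataFrame | None = None,
    exclude: set | None = None,
    mean_center: bool = True,
) -> pd.DataFrame:
    """Matrix of fitted age smooths for parcels passing FDR.

    Rows are mean-centered by default so clustering is driven by the shape
    (onset) of decline rather than the parcel's overall slope level.
    """
    keep = pd.Series(True, index=gam_table.smooths.index)
    if fdr_table is not None:
        keep &= np.asarray(fdr_table["significant"], dtype=bool)
    if exclude:
        keep &= ~gam_table.smooths.index.isin(list(exclude))
    out = gam_table.smooths.loc[keep.to_numpy()]
    if out.empty:
        raise ValueError("no parcels survive FDR/exclusion selection")
    if mean_center:
        out = out.sub(out.mean(axis=1), axis=0)
    return out
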