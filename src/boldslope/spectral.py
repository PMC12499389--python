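"""Spectral-slope estimation from motion-censored BOLD timeseries.

The power spectral density is obtained via the Wiener-Khinchin route: a
lagged autocovariance computed over valid (motion-free) frame pairs only,
tapered by a Gaussian lag window, then cosine-transformed onto a regular
frequency grid.  The spectral slope (SS) is the negative of the OLS slope
of log10 power on raw frequency inside the infra-slow analysis band
(0.015-0.145 Hz by default); larger SS means slow activity dominates.

Censoring support is the reason for this route: invalid frames simply drop
out of the pair sums, so no interpolation or tapering of the timeseries
itself is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: analysis band in Hz used throughout the package
DEFAULT_BAND = (0.015, 0.145)

#: seconds; normalization of the scaled lag q = (m-1)*tr/30
LAG_SCALE_SECONDS = 30.0

#: Gaussian taper exp(-q^2/2) drops below 1e-3 past this q
_Q_CUTOFF = float(np.sqrt(-2.0 * np.log(1e-3)))

#: default number of positive frequency bins of the cosine transform
DEFAULT_N_FREQ = 256


@dataclass
class FrameSeries:
    """One parcel's timeseries with sampling interval and valid-frame mask."""

    values: np.ndarray
    tr: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask and values must have equal length")

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass
class Autocovariance:
    """Taper-adjusted lagged autocovariance over valid frame pairs.

    Lags are 1-based (m = 1 is lag zero), matching the scaled lag
    q = (m - 1) * tr / 30.  ``adjusted`` is raw_sum * exp(-q^2/2) / n_pairs,
    set to 0 (and flagged) where no valid pair exists.
    """

    lag_m: np.ndarray
    q: np.ndarray
    raw_sum: np.ndarray
    n_pairs: np.ndarray
    adjusted: np.ndarray
    tr: float
    empty_lag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.empty_lag is None:
            self.empty_lag = self.n_pairs == 0


@dataclass
class PowerSpectrum:
    freq: np.ndarray            # Hz, starts at 0
    power: np.ndarray           # floored at a small positive epsilon
    floored: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.floored is None:
            self.floored = np.zeros(self.freq.shape, dtype=bool)


@dataclass
class SlopeFit:
    slope: float                 # SS: -d log10(power) / df, per Hz
    intercept: float             # log10 power at f = 0
    r2: float
    band: tuple[float, float]
    n_inband: int


def default_max_lag(n_frames: int, tr: float) -> int:
    """Largest useful lag count: where the Gaussian taper falls below 1e-3.

    Beyond q ~ 3.72 (about 112 s for the default scale) the taper kills any
    contribution; capped at n_frames - 1.
    """
    m_cut = int(np.ceil(_Q_CUTOFF * LAG_SCALE_SECONDS / tr)) + 1
    return max(2, min(n_frames - 1, m_cut))


def _censored_acv_matrix(
    values: np.ndarray, valid: np.ndarray, tr: float, max_lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pair sums for a frames x parcels matrix with a shared mask.

    Returns (raw_sum, n_pairs, q); raw_sum has shape (max_lag, n_parcels).
    """
    n = values.shape[0]
    nv = int(valid.sum())
    if nv < 2:
        raise ValueError("need at least 2 valid frames")
    if max_lag >= n:
        raise ValueError(
            f"max_lag ({max_lag}) must be smaller than the series length ({n})"
        )
    # demean over valid frames only, then zero out invalid frames so they
    # drop from every pair product
    mean = values[valid].mean(axis=0)
    x = np.where(valid[:, None], values - mean, 0.0)
    v = valid.astype(np.int64)
    raw = np.empty((max_lag, values.shape[1]))
    npairs = np.empty(max_lag, dtype=np.int64)
    for lag in range(max_lag):  # lag = m - 1
        if lag == 0:
            raw[0] = (x * x).sum(axis=0)
            npairs[0] = nv
        else:
            raw[lag] = (x[:-lag] * x[lag:]).sum(axis=0)
            npairs[lag] = int((v[:-lag] * v[lag:]).sum())
    q = np.arange(max_lag) * tr / LAG_SCALE_SECONDS
    return raw, npairs, q


def censored_autocovariance(ts: FrameSeries, max_lag: int | None = None) -> Autocovariance:
    """Lagged autocovariance over valid frame pairs, Gaussian-tapered.

    For lag m (1-based), raw_sum(m) = sum of x_t * x_{t+m-1} over pairs with
    both frames valid, after demeaning over valid frames; the adjusted value
    is raw_sum * exp(-q^2/2) / n_pairs with q = (m-1) * tr / 30.
    """
    if max_lag is None:
        max_lag = default_max_lag(ts.n_frames, ts.tr)
    raw, npairs, q = _censored_acv_matrix(
        ts.values[:, None], ts.valid, ts.tr, max_lag
    )
    taper = np.exp(-0.5 * q**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        adjusted = np.where(npairs > 0, raw[:, 0] * taper / np.maximum(npairs, 1), 0.0)
    return Autocovariance(
        lag_m=np.arange(1, max_lag + 1),
        q=q,
        raw_sum=raw[:, 0],
        n_pairs=npairs,
        adjusted=adjusted,
        tr=ts.tr,
    )


def _cosine_basis(tr: float, n_lag: int, n_freq: int) -> tuple[np.ndarray, np.ndarray]:
    freq = np.arange(n_freq + 1) / (2.0 * n_freq * tr)
    lags_s = np.arange(n_lag) * tr
    basis = np.cos(2.0 * np.pi * freq[:, None] * lags_s[None, :])
    weights = np.full(n_lag, 2.0)
    weights[0] = 1.0
    return freq, tr * basis * weights[None, :]


def _floor_power(power: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # lag-window estimates can go slightly negative; floor before logging
    top = float(np.max(power)) if power.size else 0.0
    eps = 1e-12 * max(top, 1e-300)
    floored = power < eps
    return np.maximum(power, eps), floored


def psd_via_cosine_transform(
    acv: Autocovariance, tr: float | None = None, n_freq: int = DEFAULT_N_FREQ
) -> PowerSpectrum:
    """Cosine transform of the adjusted autocovariance (Wiener-Khinchin).

    S(f_j) = tr * [a(1) + 2 * sum_{m>=2} a(m) cos(2 pi f_j (m-1) tr)] on the
    grid f_j = j / (2 n_freq tr), j = 0..n_freq (so f_max is Nyquist).
    """
    if acv.adjusted.size == 0:
        raise ValueError("empty autocovariance")
    tr = acv.tr if tr is None else tr
    freq, basis = _cosine_basis(tr, acv.adjusted.size, n_freq)
    power = basis @ acv.adjusted
    power, floored = _floor_power(power)
    return PowerSpectrum(freq=freq, power=power, floored=floored)


def _band_index(freq: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    idx = (freq >= lo) & (freq <= hi)
    if int(idx.sum()) < 5:
        raise ValueError(
            f"fewer than 5 grid points in band {band}; grid resolution "
            f"{freq[1] - freq[0]:.6g} Hz is too coarse"
        )
    return idx


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    return float(slope), float(intercept), min(max(r2, 0.0), 1.0)


def fit_spectral_slope(
    ps: PowerSpectrum, band: tuple[float, float] = DEFAULT_BAND
) -> SlopeFit:
    """OLS of log10(power) on raw frequency in-band; SS = -(fitted slope)."""
    idx = _band_index(ps.freq, band)
    slope, intercept, r2 = _ols_r2(ps.freq[idx], np.log10(ps.power[idx]))
    return SlopeFit(
        slope=-slope, intercept=intercept, r2=r2, band=band, n_inband=int(idx.sum())
    )


def compare_spectral_models(
    ps: PowerSpectrum, band: tuple[float, float] = DEFAULT_BAND
) -> dict[str, float]:
    """R² of the semilog (log-power ~ f) vs log-log (log-power ~ log f) fit.

    Both fits use the same in-band grid points, so the R² values are directly
    comparable as a model-form choice.
    """
    idx = _band_index(ps.freq, band)
    logp = np.log10(ps.power[idx])
    _, _, r2_semilog = _ols_r2(ps.freq[idx], logp)
    _, _, r2_loglog = _ols_r2(np.log10(ps.freq[idx]), logp)
    return {"r2_semilog": r2_semilog, "r2_loglog": r2_loglog}


def estimate_ss_matrix(
    values: np.ndarray,
    tr: float,
    valid: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    max_lag: int | None = None,
    n_freq: int = DEFAULT_N_FREQ,
) -> tuple[np.ndarray, np.ndarray]:
    """SS and fit R² for every column of a frames x parcels matrix.

    All parcels of one subject share the valid-frame mask, which makes the
    pair sums and the cosine transform a single matrix product.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape[0], dtype=bool)
    if max_lag is None:
        max_lag = default_max_lag(values.shape[0], tr)
    raw, npairs, q = _censored_acv_matrix(values, valid, tr, max_lag)
    taper = np.exp(-0.5 * q**2)
    adj = np.where(npairs[:, None] > 0, raw * (taper / np.maximum(npairs, 1))[:, None], 0.0)
    freq, basis = _cosine_basis(tr, max_lag, n_freq)
    power = basis @ adj
    power, _ = _floor_power(power)
    idx = _band_index(freq, band)
    f = freq[idx]
    logp = np.log10(power[idx, :])
    fc = f - f.mean()
    slope = (fc @ (logp - logp.mean(axis=0))) / (fc @ fc)
    resid = logp - logp.mean(axis=0) - fc[:, None] * slope[None, :]
    tss = ((logp - logp.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - (resid**2).sum(axis=0) / np.maximum(tss, 1e-300), 1.0)
    return -slope, np.clip(r2, 0.0, 1.0)


def subject_ss_map(
    series: dict[int, FrameSeries],
    band: tuple[float, float] = DEFAULT_BAND,
    medial_wall: set[int] | None = None,
):
    """Per-parcel spectral slopes for one subject.

    Parameters
    ----------
    series
        Mapping parcel_id -> FrameSeries; all entries must share tr and
        mask length.  Medial-wall parcels are dropped from the output.

    Returns a pandas DataFrame indexed by parcel_id with columns
    ``ss``, ``r2`` and ``n_inband``.
    """
    import pandas as pd

    if not series:
        raise ValueError("no parcels supplied")
    medial_wall = medial_wall or set()
    ids = [pid for pid in sorted(series) if pid not in medial_wall]
    first = series[ids[0]]
    for pid in ids:
        s = series[pid]
        if s.tr != first.tr or s.n_frames != first.n_frames:
            raise ValueError(f"parcel {pid}: tr/mask length differ across parcels")
        if not np.array_equal(s.valid, first.valid):
            raise ValueError(f"parcel {pid}: valid mask differs across parcels")
    mat = np.column_stack([series[pid].values for pid in ids])
    try:
        ss, r2 = estimate_ss_matrix(mat, first.tr, first.valid, band=band)
    except ValueError as exc:
        raise ValueError(f"spectral fit failed for subject parcels {ids}: {exc}") from exc
    n_inband = _band_index(
        _cosine_basis(first.tr, 2, DEFAULT_N_FREQ)[0], band
    ).sum()
    return pd.DataFrame(
        {"ss": ss, "r2": r2, "n_inband": int(n_inband)},
        index=pd.Index(ids, name="parcel_id"),
    )
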