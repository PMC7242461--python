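"""Relaxation-rate mapping and echo-ratio statistics.

Per-voxel R2* (or R2) is estimated by ordinary least squares of
``ln S(TE)`` on TE — the mono-exponential model ``S = S0 * exp(-R*TE)``
made linear by the logarithm.  Echoes at or below a signal floor are
excluded voxelwise; voxels with fewer than two usable echoes are flagged
invalid rather than raising, mirroring how blooming regions with no
fittable first-echo signal are excluded from analysis.

Echo-ratio maps quantify fractional signal loss between an echo pair,

    R_ij = (S(TE_i) - S(TE_j)) / S(TE_i),

zero when no signal is lost and approaching one at complete loss.  A
two-point rate estimate follows as ``-ln(1 - R_ij) / (TE_j - TE_i)``,
which inverts the mono-exponential model exactly.

All echo times are milliseconds at interfaces; all rates are s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import MultiEchoSeries

MS_PER_S = 1000.0

RATIO_ECHO_PAIRS = {"R12": (0, 1), "R15": (0, 4), "R25": (1, 4)}


@dataclass
class RelaxationMap:
    """Per-voxel decay-rate estimate with fit diagnostics."""

    rate: np.ndarray  # s^-1
    intercept: np.ndarray  # ln(signal) at TE = 0
    r_squared: np.ndarray  # in [0, 1] where valid
    valid_mask: np.ndarray
    mode: str  # "r2star" or "r2"
    echo_times_used: tuple[float, ...]  # ms

    @property
    def shape(self) -> tuple[int, ...]:
        return self.rate.shape


@dataclass
class RatioMap:
    """Per-voxel fractional signal loss between one echo pair."""

    value: np.ndarray
    echo_pair: tuple[int, int]
    kind: str
    valid_mask: np.ndarray
    echo_times: tuple[float, ...]  # ms, full series echo times

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape


def fit_loglinear(series: MultiEchoSeries, signal_floor: float) -> RelaxationMap:
    """Log-linear OLS relaxation map.

    ``signal_floor`` must be positive; a sensible default is three times
    the background noise sigma (see :func:`default_signal_floor`).
    """
    if signal_floor <= 0:
        raise ValueError("signal_floor must be > 0")
    if series.n_echoes < 2:
        raise ValueError("need at least 2 echoes to fit a decay rate")

    s = series.data
    te = np.asarray(series.echo_times, dtype=float) / MS_PER_S  # seconds
    use = s > signal_floor
    n_used = use.sum(axis=-1)
    valid = n_used >= 2

    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(use, np.log(np.where(use, s, 1.0)), 0.0)
    w = use.astype(float)

    sw = n_used.astype(float)
    sw_safe = np.where(sw > 0, sw, 1.0)
    x_mean = (w * te).sum(axis=-1) / sw_safe
    y_mean = (w * y).sum(axis=-1) / sw_safe
    dx = (te - x_mean[..., None]) * w
    dy = (y - y_mean[..., None]) * w
    sxx = (dx * te).sum(axis=-1)
    sxy = (dx * y).sum(axis=-1)

    # constant signal across echoes (sxx > 0 but sxy = 0) fits rate 0;
    # sxx = 0 can only happen with < 2 used echoes, already invalid
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    slope = sxy / sxx_safe
    rate = -slope
    intercept = y_mean - slope * x_mean

    resid = (y - (intercept[..., None] + slope[..., None] * te)) * w
    ss_res = (resid**2).sum(axis=-1)
    ss_tot = (dy * y).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    # a flat (zero-variance) log-signal is a perfect fit of rate 0
    r2 = np.where(ss_tot <= 1e-30, 1.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)

    rate = np.where(valid, rate, np.nan)
    intercept = np.where(valid, intercept, np.nan)
    r2 = np.where(valid, r2, np.nan)

    return RelaxationMap(
        rate=rate,
        intercept=intercept,
        r_squared=r2,
        valid_mask=valid,
        mode=series.protocol.mode,
        echo_times_used=series.echo_times,
    )


def default_signal_floor(series: MultiEchoSeries) -> float:
    """3x the noise sigma, or a tiny positive floor for noiseless data."""
    if series.noise_sigma > 0:
        return 3.0 * series.noise_sigma
    return 1e-12


def ratio_map(series: MultiEchoSeries, kind: str) -> RatioMap:
    """Echo-ratio map R12, R15 or R25 (fractional signal loss)."""
    if kind not in RATIO_ECHO_PAIRS:
        raise ValueError(f"unknown ratio kind {kind!r}; expected one of "
                         f"{sorted(RATIO_ECHO_PAIRS)}")
    i, j = RATIO_ECHO_PAIRS[kind]
    if series.n_echoes <= j:
        raise ValueError(
            f"{kind} needs at least {j + 1} echoes; series has {series.n_echoes}"
        )
    si = series.echo(i)
    sj = series.echo(j)
    valid = si > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(valid, (si - sj) / np.where(valid, si, 1.0), np.nan)
    return RatioMap(
        value=value,
        echo_pair=(i, j),
        kind=kind,
        valid_mask=valid,
        echo_times=series.echo_times,
    )


def two_point_r2star(ratio: RatioMap, echo_times: tuple[float, ...] | None = None) -> RelaxationMap:
    """Rate map from a single echo-ratio: ``-ln(1 - R) / dTE``.

    Exact for mono-exponential decay.  Voxels with R outside [0, 1) are
    flagged invalid (noise can push a ratio negative or to >= 1).
    """
    tes = tuple(echo_times) if echo_times is not None else ratio.echo_times
    i, j = ratio.echo_pair
    dte_s = (tes[j] - tes[i]) / MS_PER_S
    if dte_s == 0:
        raise ValueError("degenerate echo pair: identical echo times")

    r = ratio.value
    valid = ratio.valid_mask & np.isfinite(r) & (r >= 0) & (r < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(valid, -np.log1p(-np.where(valid, r, 0.0)) / dte_s, np.nan)
    return RelaxationMap(
        rate=rate,
        intercept=np.full(r.shape, np.nan),
        r_squared=np.full(r.shape, np.nan),
        valid_mask=valid,
        mode="r2star",
        echo_times_used=(tes[i], tes[j]),
    )


def subtraction_image(series: MultiEchoSeries, i: int, j: int) -> np.ndarray:
    """Echo-subtraction image ``S(TE_i) - S(TE_j)``, unclipped.

    Highlights fast-decaying tissue (bone, SPIO-laden regions) as
    hyperintense and slowly decaying tissue as hypointense.
    """
    n = series.n_echoes
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"echo indices ({i}, {j}) out of range for {n} echoes")
    if i >= j:
        raise ValueError("require i < j (earlier echo minus later echo)")
    return series.echo(i) - series.echo(j)


class MonoExponentialModel:
    """Mono-exponential decay model for a multi-echo series.

    A thin statsmodels-style wrapper around :func:`fit_loglinear`:
    construct from the data, call :meth:`fit`, inspect the results.
    """

    def __init__(self, series: MultiEchoSeries, signal_floor: float | None = None):
        self.series = series
        self.signal_floor = (
            signal_floor if signal_floor is not None else default_signal_floor(series)
        )

    def fit(self) -> "MonoExponentialResults":
        return MonoExponentialResults(self, fit_loglinear(self.series, self.signal_floor))


class MonoExponentialResults:
    """Fitted relaxation map plus convenience diagnostics."""

    def __init__(self, model: MonoExponentialModel, rate_map: RelaxationMap):
        self.model = model
        self.rate_map = rate_map

    @property
    def rate(self) -> np.ndarray:
        return self.rate_map.rate

    @property
    def valid_fraction(self) -> float:
        return float(self.rate_map.valid_mask.mean())

    def summary(self) -> str:
        m = self.rate_map
        rates = m.rate[m.valid_mask]
        lines = [
            "Mono-exponential log-linear fit",
            f"  mode:            {m.mode}",
            f"  echoes (ms):     {', '.join(f'{t:g}' for t in m.echo_times_used)}",
            f"  signal floor:    {self.model.signal_floor:g}",
            f"  valid voxels:    {int(m.valid_mask.sum())} / {m.valid_mask.size}"
            f" ({100 * self.valid_fraction:.1f}%)",
        ]
        if rates.size:
            lines += [
                f"  rate median:     {np.median(rates):.2f} s^-1",
                f"  rate IQR:        [{np.percentile(rates, 25):.2f}, "
                f"{np.percentile(rates, 75):.2f}] s^-1",
                f"  negative rates:  {int((rates < 0).sum())}",
                f"  median R^2:      {np.nanmedian(m.r_squared[m.valid_mask]):.4f}",
            ]
        return "\n".join(lines)
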