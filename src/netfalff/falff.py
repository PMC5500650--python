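"""Vertex-wise and network-level fALFF.

fALFF is the fraction of a BOLD signal's spectral power that falls in the
low-frequency band (0.01-0.1 Hz by default): in-band power divided by the
power over the entire detectable frequency range (DC excluded, Nyquist
included when present).

Network-level fALFF follows the spatial-regression route: each template map
is regressed (per time point, with an intercept) against the vertex pattern
of both the unfiltered and the band-pass-filtered data, and the power of the
filtered representative time series is divided by that of the unfiltered
one.  Because the band-pass is an ideal DFT mask and both series come from
the same linear regression design, the ratio is guaranteed to lie in [0, 1].

"Power" here means the sum of squared deviations from the series mean —
equal, by Parseval, to the sum of squared DFT amplitudes over nonzero
frequencies.  A classical "amplitude" mode (summing DFT amplitudes rather
than their squares) is available for cross-checking against the original
vertex-wise literature convention.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateInputError
from .preprocess import band_mask
from .types import ICNTemplateSet, VertexTimeSeries

__all__ = [
    "spatial_regression",
    "SpatialRegressor",
    "series_power",
    "network_falff",
    "vertex_falff",
    "global_falff",
    "global_falff_of_mean_series",
    "spectral_weights",
]


def spectral_weights(n_timepoints: int) -> np.ndarray:
    """Conjugate-pair multiplicities for rfft bins: 2 for interior bins, 1
    for DC and (when T is even) the Nyquist bin.  With these weights,
    sum(w * |rfft|^2) / T equals the time-domain sum of squares (Parseval).
    """
    n_bins = n_timepoints // 2 + 1
    w = np.full(n_bins, 2.0)
    w[0] = 1.0
    if n_timepoints % 2 == 0:
        w[-1] = 1.0
    return w


class SpatialRegressor:
    """Precomputed least-squares operator for repeated spatial regression
    against one template set.

    The design is [intercept | variance-normalized template columns]; the
    normalization makes network fALFF invariant to template scaling.
    """

    def __init__(self, templates: ICNTemplateSet, cond_warn: float = 1e8):
        maps = templates.maps
        sd = maps.std(axis=0)
        design = np.column_stack([np.ones(maps.shape[0]), maps / sd])
        cond = np.linalg.cond(design)
        if cond > cond_warn:
            warnings.warn(
                f"template design is ill-conditioned (cond={cond:.3g}); "
                "collinear templates resolved by pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
        self._pinv = np.linalg.pinv(design)
        self.templates = templates

    def __call__(self, data: np.ndarray) -> np.ndarray:
        """Regress each time point's vertex pattern; returns the T x K slope
        series (intercept dropped)."""
        if data.shape[1] != self.templates.n_vertices:
            raise DataError(
                f"data has {data.shape[1]} vertices, templates {self.templates.n_vertices}"
            )
        coef = self._pinv @ data.T  # (K+1) x T
        return coef[1:].T


def spatial_regression(ts: VertexTimeSeries, templates: ICNTemplateSet) -> np.ndarray:
    """Representative time series of each template network (T x K).

    For each time point, the vertex pattern is regressed on
    [intercept | normalized templates]; the K slope series are returned.
    """
    if templates.n_networks >= templates.n_vertices:
        raise DataError("need fewer templates than vertices")
    return SpatialRegressor(templates)(ts.data)


def series_power(series: np.ndarray, demean: bool = True) -> np.ndarray | float:
    """Sum of squared deviations from the mean (per column for 2-D input)."""
    x = np.asarray(series, dtype=np.float64)
    if x.shape[0] < 2:
        raise DataError("series needs at least 2 time points")
    if demean:
        x = x - x.mean(axis=0)
    out = (x**2).sum(axis=0)
    return float(out) if np.ndim(out) == 0 else out


def network_falff(
    raw: VertexTimeSeries,
    filtered: VertexTimeSeries,
    templates: ICNTemplateSet,
    *,
    regressor: SpatialRegressor | None = None,
    mode: str = "power",
) -> pd.DataFrame:
    """Network fALFF: filtered-to-original power ratio of the representative
    time series obtained by spatial regression.

    Returns a tidy frame with one row per network: columns
    (subject_id, network, falff).  A network whose unfiltered representative
    series has zero power yields a missing fALFF with a warning.
    """
    if raw.data.shape != filtered.data.shape:
        raise DataError("raw and filtered series must share T and V")
    if not np.isclose(raw.tr, filtered.tr):
        raise DataError("raw and filtered series must share tr")
    reg = regressor if regressor is not None else SpatialRegressor(templates)
    rep_raw = reg(raw.data)
    rep_filt = reg(filtered.data)
    if mode == "power":
        p_raw = series_power(rep_raw)
        p_filt = series_power(rep_filt)
    elif mode == "amplitude":
        # classical convention: sum of DFT amplitudes instead of their squares
        w = np.sqrt(spectral_weights(rep_raw.shape[0]))[:, None]
        p_raw = (w * np.abs(np.fft.rfft(rep_raw - rep_raw.mean(0), axis=0))).sum(axis=0)
        p_filt = (w * np.abs(np.fft.rfft(rep_filt - rep_filt.mean(0), axis=0))).sum(axis=0)
    else:
        raise ConfigError(f"unknown fALFF mode {mode!r}")
    falff = np.full(templates.n_networks, np.nan)
    ok = p_raw > 0
    falff[ok] = p_filt[ok] / p_raw[ok]
    if not ok.all():
        bad = [templates.labels[i] for i in np.flatnonzero(~ok)]
        warnings.warn(
            f"zero unfiltered power for networks {bad}; fALFF emitted as missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "subject_id": raw.subject_id,
            "network": list(templates.labels),
            "falff": falff,
        }
    )


def vertex_falff(
    ts: VertexTimeSeries, f_lo: float = 0.01, f_hi: float = 0.1
) -> np.ndarray:
    """Per-vertex fALFF: in-band squared-amplitude sum over the sum across
    all nonzero frequencies (DC excluded from both).  Zero-variance vertices
    yield NaN."""
    T = ts.n_timepoints
    band = band_mask(T, ts.tr, f_lo, f_hi)
    w = spectral_weights(T)
    power = w[:, None] * np.abs(np.fft.rfft(ts.data, axis=0)) ** 2
    nonzero = np.fft.rfftfreq(T, ts.tr) > 0
    num = power[band].sum(axis=0)
    den = power[nonzero].sum(axis=0)
    out = np.full(ts.n_vertices, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def global_falff(vfalff: np.ndarray) -> float:
    """Cohort-conventional global fALFF: mean of the vertex-wise values over
    non-missing vertices."""
    v = np.asarray(vfalff, dtype=np.float64)
    if v.size == 0 or np.all(np.isnan(v)):
        raise DegenerateInputError("no non-missing vertex fALFF values")
    return float(np.nanmean(v))


def global_falff_of_mean_series(
    ts: VertexTimeSeries, f_lo: float = 0.01, f_hi: float = 0.1
) -> float:
    """Alternative global summary: fALFF of the spatial-mean time series."""
    mean_series = ts.data.mean(axis=1, keepdims=True)
    one = VertexTimeSeries(mean_series, tr=ts.tr, subject_id=ts.subject_id)
    val = vertex_falff(one, f_lo, f_hi)[0]
    if np.isnan(val):
        raise DegenerateInputError("global mean series has zero variance")
    return float(val)
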