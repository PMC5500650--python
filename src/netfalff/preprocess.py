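"""Temporal preprocessing of vertex x time BOLD data, plus motion QC.

The default chain mirrors a conventional connectome-preprocessing stack on
surface-sampled resting-state data: discard equilibration volumes ->
normalize the 4-D grand-mean intensity to 10,000 -> regress nuisance signals
(Friston-24 motion expansion plus WM/CSF channels) -> remove linear and
quadratic trends -> ideal FFT band-pass at 0.01-0.1 Hz.  Every stage appends
a tag to :attr:`VertexTimeSeries.stage_tag` and refuses to re-apply itself
silently.

The band-pass is an ideal rectangular DFT mask rather than an IIR design so
that band power can never exceed total power and fALFF stays in [0, 1]
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError, DegenerateInputError
from .types import MotionTrace, QCRecord, QCThresholds, VertexTimeSeries

__all__ = [
    "discard_initial_volumes",
    "normalize_global_intensity",
    "friston24_expand",
    "regress_nuisance",
    "detrend_poly",
    "bandpass_fft",
    "band_mask",
    "framewise_displacement",
    "qc_evaluate",
    "preprocess_subject",
    "PreprocessResult",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER = ("discard", "normalize", "regress", "detrend", "bandpass")


def discard_initial_volumes(ts: VertexTimeSeries, n: int = 5) -> VertexTimeSeries:
    """Drop the first ``n`` volumes (signal equilibration)."""
    if n < 0:
        raise ConfigError("n must be non-negative")
    if n >= ts.n_timepoints:
        raise DataError(
            f"cannot discard {n} of {ts.n_timepoints} volumes: nothing would remain"
        )
    if n == 0:
        return ts.with_stage(ts.data.copy(), "discard")
    return ts.with_stage(ts.data[n:].copy(), "discard")


def normalize_global_intensity(ts: VertexTimeSeries, target: float = 10000.0) -> VertexTimeSeries:
    """Scale the whole 4-D volume so its grand mean equals ``target``.

    A single global factor: shape-preserving, hence fALFF-invariant.
    """
    grand = float(ts.data.mean())
    if np.abs(ts.data).mean() == 0.0:
        raise DegenerateInputError("all-zero scan cannot be intensity-normalized")
    if abs(grand) < 1e-12 * max(1.0, float(np.abs(ts.data).mean())):
        raise DegenerateInputError(
            "grand mean is (numerically) zero; global intensity normalization "
            "is undefined — normalize before demeaning/detrending"
        )
    return ts.with_stage(ts.data * (target / grand), "normalize")


def friston24_expand(motion: MotionTrace) -> np.ndarray:
    """Friston-24 expansion of the six rigid-body parameters.

    Columns, in order: R(t), R(t)^2, R(t-1), R(t-1)^2 for each of the six
    parameters (24 columns total).  The lagged rows at t=0 are zero-filled.
    """
    r = motion.params
    lag = np.zeros_like(r)
    lag[1:] = r[:-1]
    return np.column_stack([r, r**2, lag, lag**2])


def regress_nuisance(ts: VertexTimeSeries, nuisance: np.ndarray) -> VertexTimeSeries:
    """Per-vertex least-squares removal of nuisance signals.

    The design is [intercept | nuisance]; residuals are orthogonal to every
    nuisance column.  Rank-deficient designs are handled by the pseudo-inverse
    solution (numpy lstsq), not treated as failures.
    """
    nuis = np.asarray(nuisance, dtype=np.float64)
    if nuis.ndim == 1:
        nuis = nuis[:, None]
    if not np.all(np.isfinite(nuis)):
        raise DataError("nuisance matrix contains non-finite entries")
    T = ts.n_timepoints
    if nuis.shape[0] != T:
        raise DataError(
            f"nuisance has {nuis.shape[0]} rows for {T} time points"
        )
    if nuis.shape[1] >= T:
        raise DataError("more nuisance regressors than time points")
    design = np.column_stack([np.ones(T), nuis])
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return ts.with_stage(resid, "regress")


def detrend_poly(ts: VertexTimeSeries, order: int = 2) -> VertexTimeSeries:
    """Remove a polynomial trend of the given order (default quadratic) from
    every vertex; order 0 is plain demeaning."""
    if order < 0:
        raise ConfigError("order must be >= 0")
    T = ts.n_timepoints
    if order + 1 >= T:
        raise DataError(f"polynomial order {order} too high for T={T}")
    t = np.linspace(-1.0, 1.0, T)
    design = np.vander(t, order + 1, increasing=True)  # [1, t, t^2, ...]
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_stage(ts.data - design @ beta, "detrend")


def band_mask(n_timepoints: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Boolean mask over rfft bins with f_lo <= f <= f_hi (DC never included)."""
    if not (0 <= f_lo < f_hi):
        raise ConfigError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    nyquist = 1.0 / (2.0 * tr)
    if f_hi > nyquist + 1e-12:
        raise ConfigError(f"f_hi={f_hi} Hz exceeds Nyquist {nyquist} Hz at tr={tr}")
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    eps = 1e-12
    mask = (freqs >= f_lo - eps) & (freqs <= f_hi + eps) & (freqs > 0)
    if not mask.any():
        raise ConfigError(
            f"band [{f_lo}, {f_hi}] Hz contains no DFT bins at T={n_timepoints}, tr={tr}"
        )
    return mask


def bandpass_fft(ts: VertexTimeSeries, f_lo: float = 0.01, f_hi: float = 0.1) -> VertexTimeSeries:
    """Ideal rectangular DFT band-pass.

    Bins with f_lo <= |f| <= f_hi are retained; all others, including DC, are
    zeroed.  Output variance therefore never exceeds input variance.
    """
    mask = band_mask(ts.n_timepoints, ts.tr, f_lo, f_hi)
    spec = np.fft.rfft(ts.data, axis=0)
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=ts.n_timepoints, axis=0)
    return ts.with_stage(out, "bandpass")


def framewise_displacement(
    motion: MotionTrace, head_radius: float = 50.0
) -> tuple[np.ndarray, float, float]:
    """Power-style frame-wise displacement.

    FD(t) = sum |Delta translation_i(t)| + head_radius * sum |Delta rotation_j(t)|
    for t >= 1, with FD(0) = 0.  Returns (fd, mean_fd, rms_fd), the summaries
    taken over frames t >= 1.
    """
    d = np.diff(motion.params, axis=0)
    fd_body = np.abs(d[:, :3]).sum(axis=1) + head_radius * np.abs(d[:, 3:]).sum(axis=1)
    fd = np.concatenate([[0.0], fd_body])
    mean_fd = float(fd_body.mean())
    rms_fd = float(np.sqrt((fd_body**2).mean()))
    return fd, mean_fd, rms_fd


def qc_evaluate(
    motion: MotionTrace,
    thresholds: QCThresholds = QCThresholds(),
    subject_id: str = "subject",
    head_radius: float = 50.0,
) -> QCRecord:
    """Motion QC summary: max translation distance and max rotation from the
    first frame, plus mean/RMS frame-wise displacement, with pass flags."""
    trans = motion.translations - motion.translations[0]
    max_tran = float(np.linalg.norm(trans, axis=1).max())
    rot = motion.rotations - motion.rotations[0]
    max_rot = float(np.degrees(np.abs(rot).max()))
    _, mean_fd, rms_fd = framewise_displacement(motion, head_radius=head_radius)
    passes = {
        "max_tran": max_tran < thresholds.max_tran_mm,
        "max_rot": max_rot < thresholds.max_rot_deg,
        "mean_fd": mean_fd < thresholds.mean_fd_mm,
    }
    return QCRecord(
        subject_id=subject_id,
        max_tran=max_tran,
        max_rot=max_rot,
        mean_fd=mean_fd,
        rms_fd=rms_fd,
        passes=passes,
    )


@dataclass(frozen=True)
class PreprocessResult:
    """Both the preprocessed-but-unfiltered residual series and its band-pass
    filtered counterpart (network fALFF needs the pair), plus the motion QC
    record when a motion trace was supplied."""

    unfiltered: VertexTimeSeries
    filtered: VertexTimeSeries
    qc: QCRecord | None = None


def preprocess_subject(
    ts: VertexTimeSeries,
    motion: MotionTrace | None = None,
    extra_nuisance: np.ndarray | None = None,
    *,
    order: tuple[str, ...] = DEFAULT_ORDER,
    n_discard: int = 5,
    intensity_target: float = 10000.0,
    detrend_order: int = 2,
    band: tuple[float, float] = (0.01, 0.1),
    qc_thresholds: QCThresholds = QCThresholds(),
) -> PreprocessResult:
    """Run the configured temporal chain on one subject.

    ``extra_nuisance`` carries WM/CSF-style channels (T rows matching the
    scan *before* volume discard); the motion trace is Friston-24 expanded.
    The band-pass must be the final stage of ``order``; the stage just before
    it defines the "unfiltered" series used as the fALFF denominator.
    """
    if "bandpass" in order and order[-1] != "bandpass":
        raise ConfigError("the band-pass must be the last preprocessing stage")
    current = ts
    motion_cur = motion
    nuis_cur = None
    if extra_nuisance is not None:
        nuis_cur = np.asarray(extra_nuisance, dtype=np.float64)
        if nuis_cur.ndim == 1:
            nuis_cur = nuis_cur[:, None]
    unfiltered = None
    for stage in order:
        if stage == "discard":
            n_before = current.n_timepoints
            current = discard_initial_volumes(current, n_discard)
            kept = current.n_timepoints
            if motion_cur is not None and motion_cur.n_frames == n_before:
                motion_cur = MotionTrace(motion_cur.params[n_before - kept:])
            if nuis_cur is not None and nuis_cur.shape[0] == n_before:
                nuis_cur = nuis_cur[n_before - kept:]
        elif stage == "normalize":
            current = normalize_global_intensity(current, intensity_target)
        elif stage == "regress":
            blocks = []
            if motion_cur is not None:
                blocks.append(friston24_expand(motion_cur))
            if nuis_cur is not None:
                blocks.append(nuis_cur)
            if blocks:
                current = regress_nuisance(current, np.column_stack(blocks))
        elif stage == "detrend":
            current = detrend_poly(current, detrend_order)
        elif stage == "bandpass":
            unfiltered = current
            current = bandpass_fft(current, *band)
        else:
            raise ConfigError(f"unknown preprocessing stage {stage!r}")
    if unfiltered is None:  # no band-pass requested
        unfiltered = current
    qc = None
    if motion_cur is not None:
        qc = qc_evaluate(motion_cur, qc_thresholds, subject_id=ts.subject_id)
    return PreprocessResult(unfiltered=unfiltered, filtered=current, qc=qc)
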