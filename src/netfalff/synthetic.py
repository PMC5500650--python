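"""Synthetic multi-subject resting-state cohorts with fully known ground truth.

The generator emulates the study design the analysis targets: two groups
(22 experienced Tai Chi Chuan practitioners vs 18 matched controls) scanned
with TR = 2 s for 243 volumes (5 discarded for equilibration), vertex-sampled
signals built as a linear mixture of network time courses through spatial
template maps plus Gaussian noise, random-walk head motion, WM/CSF-style
nuisance channels, and planted group differences / covariate-adjusted
correlations in network fALFF.

Network time courses are built directly in the Fourier domain so that the
planted in-band power fraction (the fALFF target) holds *exactly*: the DFT
amplitudes inside 0.01-0.1 Hz and outside it are scaled so their
squared-amplitude sums have exactly the requested ratio.  This makes
noise-free end-to-end recovery an identity rather than an approximation,
which is what turns every downstream stage into a testable contract.

The synthetic space is a flat vertex grid (default V = 4000, a stand-in for
a down-sampled cortical surface); no mesh topology is modeled because the
analysis only ever consumes vertex vectors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError, DataError
from .falff import spectral_weights
from .preprocess import band_mask
from .types import ICNTemplateSet, MotionTrace, VertexTimeSeries

__all__ = [
    "generate_templates",
    "synthesize_network_series",
    "generate_subject_scan",
    "generate_motion_trace",
    "generate_nuisance_channels",
    "generate_cohort",
    "PlantedEffect",
    "SyntheticCohort",
    "SubjectScan",
    "GroundTruth",
    "DEFAULT_NETWORK_PROFILE",
    "DEFAULT_EFFECTS",
    "null_profile",
]

# Per-network fALFF levels (mean, sd) for controls and practitioners; these
# are the generator's default study conditions, one row per intrinsic
# connectivity network.  Format: label -> (ctr_mean, ctr_sd, tcc_mean, tcc_sd).
DEFAULT_NETWORK_PROFILE: dict[str, tuple[float, float, float, float]] = {
    "ICN01": (0.738, 0.125, 0.724, 0.145),
    "ICN02": (0.655, 0.117, 0.611, 0.173),
    "ICN03": (0.831, 0.075, 0.751, 0.124),  # default mode network
    "ICN04": (0.692, 0.117, 0.699, 0.151),
    "ICN05": (0.685, 0.087, 0.614, 0.123),  # right frontoparietal
    "ICN06": (0.602, 0.111, 0.545, 0.168),
    "ICN07": (0.738, 0.084, 0.700, 0.095),
    "ICN08": (0.765, 0.079, 0.672, 0.095),  # left frontoparietal
    "ICN09": (0.690, 0.103, 0.679, 0.138),
    "ICN10": (0.677, 0.084, 0.599, 0.146),
    "ICN11": (0.662, 0.114, 0.660, 0.136),
    "ICN12": (0.718, 0.075, 0.670, 0.122),
}


def null_profile(
    profile: dict[str, tuple[float, float, float, float]] | None = None,
) -> dict[str, tuple[float, float, float, float]]:
    """Copy of a network profile with the practitioner levels set equal to
    the control levels (no group effect anywhere)."""
    prof = DEFAULT_NETWORK_PROFILE if profile is None else profile
    return {k: (m, s, m, s) for k, (m, s, _, _) in prof.items()}


@dataclass(frozen=True)
class PlantedEffect:
    """A covariate-adjusted correlation planted into the cohort.

    ``x`` and ``y`` name cohort columns; a ``"log:"`` prefix takes the
    natural log first and a ``"falff:"`` prefix addresses a network's planted
    fALFF.  ``r`` is realized as the (near-exact, by in-sample
    orthogonalization) partial correlation given ``covariates`` within
    ``group``.
    """

    x: str
    y: str
    r: float
    covariates: tuple[str, ...] = ("age", "sex", "education")
    group: str = "TCC"


DEFAULT_EFFECTS: tuple[PlantedEffect, ...] = (
    # longer practice history -> faster conflict resolution (plain correlation)
    PlantedEffect(x="tcc_years", y="conflict_rt", r=-0.659, covariates=(), group="TCC"),
    # heavier weekly practice -> higher default-mode fALFF, given age/sex/education
    PlantedEffect(x="log:tcc_hours_per_week", y="falff:ICN03", r=0.473),
    # slower conflict RT -> higher left-frontoparietal fALFF, given covariates
    PlantedEffect(x="log:conflict_rt", y="falff:ICN08", r=0.851),
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_templates(
    n_vertices: int,
    n_networks: int,
    smoothness: float = 4.0,
    overlap: float = 0.0,
    seed: int = 0,
) -> ICNTemplateSet:
    """Smooth, localized, z-scored network maps on a flat vertex grid.

    Each network occupies a windowed bump inside its own block of vertices;
    with ``overlap = 0`` the supports are disjoint and (because each bump is
    mean-centered over its support) pairwise column correlations are exactly
    zero.  Larger ``overlap`` widens supports into neighboring blocks.
    """
    if n_networks < 1:
        raise ConfigError("need at least one network")
    if n_networks > n_vertices:
        raise ConfigError(
            f"invalid dimensions: {n_networks} networks on {n_vertices} vertices"
        )
    if n_vertices < 10 * n_networks:
        raise ConfigError(
            f"need n_vertices >= 10 * n_networks ({n_vertices} < {10 * n_networks})"
        )
    rng = _rng(seed)
    block = n_vertices // n_networks
    width = max(8, int(round(block * (0.6 + overlap))))
    width = min(width, n_vertices)
    maps = np.zeros((n_vertices, n_networks))
    for k in range(n_networks):
        start = k * block + (block - width) // 2
        start = min(max(start, 0), n_vertices - width)
        idx = np.arange(start, start + width)
        window = np.hanning(width + 2)[1:-1]  # strictly positive taper
        rough = gaussian_filter1d(rng.standard_normal(width), smoothness, mode="nearest")
        bump = window * (1.0 + 0.5 * np.tanh(rough))
        bump -= bump.mean()  # support-mean zero => exact orthogonality when disjoint
        maps[idx, k] = bump
    maps -= maps.mean(axis=0)
    maps /= maps.std(axis=0)
    labels = tuple(f"ICN{k + 1:02d}" for k in range(n_networks))
    return ICNTemplateSet(maps=maps, labels=labels)


def synthesize_network_series(
    n_timepoints: int,
    tr: float,
    target_falff: float,
    rms: float = 1.0,
    seed=0,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
) -> np.ndarray:
    """One network time course whose in-band power fraction equals
    ``target_falff`` exactly.

    The series is assembled in the DFT domain with random phases and random
    bin amplitudes; in-band and out-of-band amplitude groups are then scaled
    so (in-band squared-amplitude sum) / (total over nonzero frequencies)
    equals the target.  DC is zero (zero-mean series) and the final series is
    rescaled to the requested RMS, which preserves the ratio.
    """
    if not (0.0 <= target_falff <= 1.0):
        raise ConfigError(f"target_falff must lie in [0, 1], got {target_falff}")
    band = band_mask(n_timepoints, tr, f_lo, f_hi)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    nonzero = freqs > 0
    out_band = nonzero & ~band
    if target_falff < 1.0 and not out_band.any():
        raise ConfigError(
            "band covers every nonzero DFT bin; cannot place out-of-band power"
        )
    rng = _rng(seed)
    n_bins = freqs.size
    amps = rng.uniform(0.5, 1.5, n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_bins)
    spec = amps * np.exp(1j * phases)
    spec[0] = 0.0
    if n_timepoints % 2 == 0:
        spec[-1] = amps[-1]  # Nyquist bin must be real
    w = spectral_weights(n_timepoints)
    e_in = float((w[band] * np.abs(spec[band]) ** 2).sum())
    e_out = float((w[out_band] * np.abs(spec[out_band]) ** 2).sum())
    if target_falff == 0.0:
        spec[band] = 0.0
    else:
        spec[band] *= np.sqrt(target_falff / e_in)
    if target_falff == 1.0:
        spec[out_band] = 0.0
    else:
        spec[out_band] *= np.sqrt((1.0 - target_falff) / e_out)
    x = np.fft.irfft(spec, n=n_timepoints)
    cur_rms = float(np.sqrt((x**2).mean()))
    if cur_rms > 0:
        x *= rms / cur_rms
    return x


def generate_subject_scan(
    templates: ICNTemplateSet,
    planted_falff: np.ndarray,
    noise_sd: float = 1.0,
    seed=0,
    *,
    n_timepoints: int = 238,
    tr: float = 2.0,
    rms: float = 1.0,
    baseline: float = 1000.0,
    subject_id: str = "subject",
    f_lo: float = 0.01,
    f_hi: float = 0.1,
) -> tuple[VertexTimeSeries, dict]:
    """One subject's scan: X(t, v) = sum_k s_k(t) m_k(v) + baseline + noise.

    Returns the scan and a ground-truth slice holding the planted network
    time courses and fALFF targets, for oracle tests downstream.
    """
    planted = np.asarray(planted_falff, dtype=np.float64)
    if planted.shape != (templates.n_networks,):
        raise DataError(
            f"planted_falff must have length {templates.n_networks}, got {planted.shape}"
        )
    rng = _rng(seed)
    series = np.column_stack(
        [
            synthesize_network_series(
                n_timepoints, tr, float(f), rms=rms, seed=rng, f_lo=f_lo, f_hi=f_hi
            )
            for f in planted
        ]
    )
    data = series @ templates.maps.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    data = data + baseline
    ts = VertexTimeSeries(data, tr=tr, subject_id=subject_id, stage_tag=("simulated",))
    return ts, {"series": series, "planted_falff": planted}


def generate_motion_trace(
    n_timepoints: int, severity: float = 0.5, seed=0
) -> MotionTrace:
    """Random-walk head motion: T x 6 (translations mm, rotations radians).

    Increments scale linearly with ``severity`` (0.05 mm and 0.001 rad per
    unit severity), so mean FD is strictly monotone in severity for a fixed
    seed; severity 0 yields an all-zero trace.
    """
    if n_timepoints < 2:
        raise DataError("motion trace needs at least 2 frames")
    rng = _rng(seed)
    z = rng.standard_normal((n_timepoints - 1, 6))
    inc = np.empty_like(z)
    inc[:, :3] = 0.05 * severity * z[:, :3]
    inc[:, 3:] = 0.001 * severity * z[:, 3:]
    params = np.vstack([np.zeros(6), np.cumsum(inc, axis=0)])
    return MotionTrace(params)


def generate_nuisance_channels(
    n_timepoints: int, n_channels: int = 2, seed=0, smooth: float = 4.0
) -> np.ndarray:
    """Smooth unit-variance noise channels standing in for WM/CSF mean
    time series in synthetic runs."""
    rng = _rng(seed)
    x = gaussian_filter1d(
        rng.standard_normal((n_timepoints, n_channels)), smooth, axis=0, mode="nearest"
    )
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def _trunc_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def _standardized_residual(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    r = v - design @ beta
    sd = r.std()
    if sd == 0:
        raise DataError("degenerate residual while planting an effect")
    return r / sd


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    template_maps: np.ndarray  # V x K
    network_labels: tuple[str, ...]
    planted_falff: np.ndarray  # n_subjects x K, each entry in [0, 1]
    group_labels: tuple[str, ...]
    effects: tuple[PlantedEffect, ...]


@dataclass(frozen=True)
class SubjectScan:
    ts: VertexTimeSeries  # acquired scan, equilibration volumes included
    motion: MotionTrace
    nuisance: np.ndarray  # T x 2 WM/CSF surrogate channels
    series: np.ndarray  # post-discard network time courses (ground truth)
    planted_falff: np.ndarray


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: demographics table, templates, planted fALFF and
    lazily generated per-subject scans (deterministic per subject)."""

    table: pd.DataFrame
    templates: ICNTemplateSet
    planted_falff: pd.DataFrame  # subjects x networks
    ground_truth: GroundTruth
    n_volumes: int
    n_discard: int
    tr: float
    noise_sd: float
    motion_severity: float
    baseline: float
    _scan_seeds: np.ndarray = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def subject_scan(self, i: int) -> SubjectScan:
        """Generate subject ``i``'s scan, motion trace and nuisance channels.

        The first ``n_discard`` acquired volumes are equilibration frames
        (elevated baseline plus noise, no network signal); the remaining
        volumes carry the planted mixture, so the standard discard step
        recovers the ground-truth series exactly.
        """
        seeds = self._scan_seeds[i]
        subject_id = str(self.table["subject_id"].iloc[i])
        t_use = self.n_volumes - self.n_discard
        ts_core, _gt = generate_subject_scan(
            self.templates,
            self.planted_falff.iloc[i].to_numpy(),
            noise_sd=self.noise_sd,
            seed=int(seeds[0]),
            n_timepoints=t_use,
            tr=self.tr,
            baseline=self.baseline,
            subject_id=subject_id,
        )
        rng = np.random.default_rng(int(seeds[1]))
        if self.n_discard > 0:
            drift = self.baseline * (1.0 + 0.05 * np.linspace(1.0, 0.2, self.n_discard))
            dummy = drift[:, None] + self.noise_sd * rng.standard_normal(
                (self.n_discard, self.templates.n_vertices)
            )
            data = np.vstack([dummy, ts_core.data])
        else:
            data = ts_core.data
        ts = VertexTimeSeries(
            data, tr=self.tr, subject_id=subject_id, stage_tag=("simulated",)
        )
        motion = generate_motion_trace(
            self.n_volumes, severity=self.motion_severity, seed=int(seeds[2])
        )
        nuisance = generate_nuisance_channels(self.n_volumes, 2, seed=int(seeds[3]))
        return SubjectScan(
            ts=ts,
            motion=motion,
            nuisance=nuisance,
            series=_gt["series"],
            planted_falff=_gt["planted_falff"],
        )


def generate_cohort(
    n_tcc: int = 22,
    n_ctr: int = 18,
    effects: tuple[PlantedEffect, ...] = DEFAULT_EFFECTS,
    seed: int = 0,
    *,
    profile: dict[str, tuple[float, float, float, float]] | None = None,
    n_vertices: int = 4000,
    n_volumes: int = 243,
    n_discard: int = 5,
    tr: float = 2.0,
    noise_sd: float = 1.0,
    motion_severity: float = 0.5,
    baseline: float = 1000.0,
    template_smoothness: float = 4.0,
    template_overlap: float = 0.0,
    missing_behavior: bool = False,
    plant_outlier: bool = True,
) -> SyntheticCohort:
    """Generate a two-group cohort with planted network fALFF structure.

    Demographics follow the emulated study's group summaries (practitioners:
    age 52.4 +/- 6.8 y, education 12.2 +/- 2.9 y, 14.6 +/- 8.6 y of practice;
    controls: 54.8 +/- 6.8 y, 11.8 +/- 2.9 y), drawn from truncated
    Gaussians.  Per-network fALFF levels come from ``profile`` (default:
    the per-group network levels of the emulated study).  ``effects`` are
    realized by residual-space mixing after the covariate structure is fixed,
    so the planted value is the partial correlation by construction.

    ``plant_outlier`` places one practitioner at 30 h/week of practice (a
    genuine Tukey far-out point against the others' 3-20 h range).
    ``missing_behavior`` keeps behavioral scores for only 10 subjects per
    group, emulating partial task acquisition.
    """
    if n_tcc < 2 or n_ctr < 2:
        raise ConfigError("need at least 2 subjects per group")
    prof = DEFAULT_NETWORK_PROFILE if profile is None else profile
    labels = tuple(prof.keys())
    for eff in effects:
        if not (-1.0 < eff.r < 1.0):
            raise DataError(
                f"requested correlation r={eff.r} for ({eff.x}, {eff.y}) is not "
                "realizable (correlation structure not positive definite)"
            )
    targets = [e.y for e in effects]
    if len(set(targets)) != len(targets):
        raise DataError("two planted effects target the same variable")

    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    rng_demo = np.random.default_rng(kids[0])
    rng_falff = np.random.default_rng(kids[1])
    rng_eff = np.random.default_rng(kids[2])
    rng_tpl = np.random.default_rng(kids[3])
    rng_scan = np.random.default_rng(kids[4])

    templates = generate_templates(
        n_vertices,
        len(labels),
        smoothness=template_smoothness,
        overlap=template_overlap,
        seed=rng_tpl,
    )

    n = n_tcc + n_ctr
    group = np.array(["TCC"] * n_tcc + ["CTR"] * n_ctr)
    age = np.concatenate(
        [
            _trunc_normal(rng_demo, 52.4, 6.8, 30, 80, n_tcc),
            _trunc_normal(rng_demo, 54.8, 6.8, 30, 80, n_ctr),
        ]
    )
    education = np.concatenate(
        [
            _trunc_normal(rng_demo, 12.2, 2.9, 6, 22, n_tcc),
            _trunc_normal(rng_demo, 11.8, 2.9, 6, 22, n_ctr),
        ]
    )

    def _sexes(n_g, n_male):
        s = np.array(["M"] * n_male + ["F"] * (n_g - n_male))
        rng_demo.shuffle(s)
        return s

    sex = np.concatenate(
        [_sexes(n_tcc, round(n_tcc * 7 / 22)), _sexes(n_ctr, round(n_ctr * 8 / 18))]
    )

    tcc_years = np.full(n, np.nan)
    tcc_hours = np.full(n, np.nan)
    tcc_years[:n_tcc] = _trunc_normal(rng_demo, 14.6, 8.6, 1, 45, n_tcc)
    # non-outlier practitioners cluster at ~11 h/week; the planted outlier at
    # 30 h pushes the sample toward the emulated 11.9 +/- 5.1 summary, and the
    # tight [4, 18] range keeps 30 h beyond the Tukey far-out fence
    tcc_hours[:n_tcc] = _trunc_normal(rng_demo, 11.0, 3.0, 4, 18, n_tcc)
    if plant_outlier and n_tcc >= 5:
        tcc_hours[int(np.argmax(tcc_hours[:n_tcc]))] = 30.0

    conflict_rt = np.concatenate(
        [
            _trunc_normal(rng_demo, 100.0, 30.0, 30, 250, n_tcc),
            _trunc_normal(rng_demo, 115.0, 30.0, 30, 250, n_ctr),
        ]
    )
    conflict_acc = _trunc_normal(rng_demo, 0.95, 0.04, 0.70, 1.0, n)

    # planted per-network fALFF, group-specific levels
    k_nets = len(labels)
    planted = np.empty((n, k_nets))
    for j, lab in enumerate(labels):
        cm, cs, tm, tsd = prof[lab]
        planted[:n_tcc, j] = _trunc_normal(rng_falff, tm, tsd, 0.02, 0.98, n_tcc)
        planted[n_tcc:, j] = _trunc_normal(rng_falff, cm, cs, 0.02, 0.98, n_ctr)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "education": education,
            "tcc_years": tcc_years,
            "tcc_hours_per_week": tcc_hours,
            "conflict_rt": conflict_rt,
            "conflict_acc": conflict_acc,
        }
    )

    def _resolve(name: str, tbl: pd.DataFrame, fal: np.ndarray, rows: np.ndarray):
        """Return (values, kind, index) for an effect variable name."""
        if name.startswith("log:"):
            vals, kind, idx = _resolve(name[4:], tbl, fal, rows)
            if np.any(vals <= 0):
                raise DataError(f"cannot log-transform non-positive values of {name}")
            return np.log(vals), kind, idx
        if name.startswith("falff:"):
            lab = name[6:]
            if lab not in labels:
                raise DataError(f"unknown network {lab!r} in effect spec")
            j = labels.index(lab)
            return fal[rows, j], "falff", j
        if name not in tbl.columns:
            raise DataError(f"unknown cohort variable {name!r} in effect spec")
        return tbl[name].to_numpy()[rows], "column", name

    nominal = {"conflict_rt": (100.0, 30.0), "conflict_acc": (0.95, 0.04)}
    for eff in effects:
        rows = np.flatnonzero(group == eff.group) if eff.group != "all" else np.arange(n)
        x_vals, _, _ = _resolve(eff.x, table, planted, rows)
        keep = np.isfinite(x_vals)
        rows = rows[keep]
        x_vals = x_vals[keep]
        m = rows.size
        if m < len(eff.covariates) + 3:
            raise DataError(f"too few subjects ({m}) to plant effect on {eff.y}")
        z_cols = [np.ones(m)]
        for c in eff.covariates:
            col = table[c].to_numpy()[rows]
            if c == "sex":
                col = (col == "M").astype(float)
            z_cols.append(np.asarray(col, dtype=np.float64))
        design = np.column_stack(z_cols)
        zx = _standardized_residual(x_vals, design)
        noise = rng_eff.standard_normal(m)
        ze = _standardized_residual(noise, np.column_stack([design, zx]))
        mix = eff.r * zx + np.sqrt(1.0 - eff.r**2) * ze
        y_name = eff.y[4:] if eff.y.startswith("log:") else eff.y
        if y_name.startswith("falff:"):
            j = labels.index(y_name[6:])
            gm, gs = (
                (prof[labels[j]][2], prof[labels[j]][3])
                if eff.group == "TCC"
                else (prof[labels[j]][0], prof[labels[j]][1])
            )
            vals = np.clip(gm + gs * mix, 0.02, 0.98)
            if eff.y.startswith("log:"):
                raise DataError("log transform of a planted fALFF target is not supported")
            planted[rows, j] = vals
        else:
            gm, gs = nominal.get(y_name, (float(np.mean(x_vals)), float(np.std(x_vals))))
            if eff.y.startswith("log:"):
                # realize the correlation on the log scale (delta-method sd)
                vals = np.exp(np.log(gm) + (gs / gm) * mix)
            else:
                vals = gm + gs * mix
            col = table[y_name].to_numpy(dtype=np.float64)
            col[rows] = vals
            table[y_name] = col

    if missing_behavior:
        for lo, hi in ((0, n_tcc), (n_tcc, n)):
            idx = np.arange(lo, hi)
            drop = idx[10:] if idx.size > 10 else idx[:0]
            table.loc[drop, ["conflict_rt", "conflict_acc"]] = np.nan

    planted_df = pd.DataFrame(planted, columns=list(labels))
    planted_df.insert(0, "subject_id", table["subject_id"])
    planted_df = planted_df.set_index("subject_id")

    gt = GroundTruth(
        template_maps=templates.maps,
        network_labels=labels,
        planted_falff=planted,
        group_labels=tuple(group),
        effects=tuple(effects),
    )
    scan_seeds = rng_scan.integers(0, 2**31 - 1, size=(n, 4))
    return SyntheticCohort(
        table=table,
        templates=templates,
        planted_falff=planted_df,
        ground_truth=gt,
        n_volumes=n_volumes,
        n_discard=n_discard,
        tr=tr,
        noise_sd=noise_sd,
        motion_severity=motion_severity,
        baseline=baseline,
        _scan_seeds=scan_seeds,
    )
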