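"""End-to-end pipeline orchestration with a single validated config.

Stages: simulate -> preprocess -> align (or load fixed templates) -> falff
-> stats.  Every stage writes into its own subdirectory of the run
directory and never mutates another stage's outputs; a stage is skipped on
rerun when its completion marker carries the current config hash, so a rerun
with an identical config and seed is byte-identical.  All randomness flows
from the single top-level seed through documented per-stage derivations
(numpy SeedSequence spawning).
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import io as nfio
from .align import align_components
from .errors import ConfigError, DataError, NetfalffError
from .experiments import _decompose_with_retry
from .falff import SpatialRegressor, global_falff, network_falff, vertex_falff
from .preprocess import preprocess_subject
from .stats import (
    encode_covariates,
    flag_outliers,
    network_group_table,
    normality_gate_log_transform,
    partial_correlation,
)
from .synthetic import generate_cohort
from .types import QCThresholds

log = logging.getLogger("netfalff")

__all__ = ["PipelineConfig", "SyntheticSpec", "run_pipeline", "load_config"]


class SyntheticSpec(BaseModel):
    n_tcc: int = 22
    n_ctr: int = 18
    n_vertices: int = 4000
    n_volumes: int = 243
    tr: float = 2.0
    noise_sd: float = 1.0
    motion_severity: float = 0.5
    plant_outlier: bool = True
    missing_behavior: bool = False


class GraicarParams(BaseModel):
    n_components: int = 6
    n_perm: int = 199
    n_bins: int = 64
    alpha: float = 0.05
    min_fraction: float = 0.6


class StatsParams(BaseModel):
    covariates: list[str] = Field(default_factory=lambda: ["age", "sex", "education"])
    alpha: float = 0.05
    correction: str | None = None


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; every run emits the resolved config
    and its hash alongside the outputs."""

    out_dir: str
    seed: int = 0
    band: tuple[float, float] = (0.01, 0.1)
    n_discard: int = 5
    preprocess_order: list[str] = Field(
        default_factory=lambda: ["discard", "normalize", "regress", "detrend", "bandpass"]
    )
    detrend_order: int = 2
    templates_path: str | None = None
    use_ground_truth_templates: bool = False
    synthetic: SyntheticSpec = Field(default_factory=SyntheticSpec)
    graicar: GraicarParams = Field(default_factory=GraicarParams)
    stats: StatsParams = Field(default_factory=StatsParams)

    def config_hash(self) -> str:
        payload = self.model_dump()
        payload.pop("out_dir")  # paths do not affect the science
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    try:
        payload = yaml.safe_load(Path(path).read_text())
        return PipelineConfig(**payload)
    except (ValidationError, yaml.YAMLError) as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


def _stage_dir(run_dir: Path, name: str) -> Path:
    d = run_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _done(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / ".done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark(stage_dir: Path, cfg_hash: str) -> None:
    (stage_dir / ".done").write_text(cfg_hash)


def stage_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic cohort and write every subject's scan, motion
    trace and WM/CSF channels, the cohort TSV and the ground-truth sidecar."""
    run_dir = Path(config.out_dir)
    out = _stage_dir(run_dir, "simulate")
    h = config.config_hash()
    if _done(out, h):
        log.info("simulate: cached, skipping")
        return out
    spec = config.synthetic
    cohort = generate_cohort(
        spec.n_tcc,
        spec.n_ctr,
        seed=config.seed,
        n_vertices=spec.n_vertices,
        n_volumes=spec.n_volumes,
        n_discard=config.n_discard,
        tr=spec.tr,
        noise_sd=spec.noise_sd,
        motion_severity=spec.motion_severity,
        plant_outlier=spec.plant_outlier,
        missing_behavior=spec.missing_behavior,
    )
    nfio.save_cohort(out / "cohort.tsv", cohort.table)
    nfio.save_templates(out / "true_templates.tsv", cohort.templates, config_hash=h)
    nfio.save_table(
        out / "planted_falff.tsv",
        cohort.planted_falff.reset_index(),
        comment_lines=[f"config_hash={h}"],
    )
    gt = {
        "network_labels": list(cohort.ground_truth.network_labels),
        "group_labels": list(cohort.ground_truth.group_labels),
        "effects": [
            {"x": e.x, "y": e.y, "r": e.r, "covariates": list(e.covariates), "group": e.group}
            for e in cohort.ground_truth.effects
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    for i in range(cohort.n_subjects):
        scan = cohort.subject_scan(i)
        sid = scan.ts.subject_id
        nfio.save_scan(out / f"{sid}_scan.tsv.gz", scan.ts)
        nfio.save_motion(out / f"{sid}_motion.txt", scan.motion)
        np.savetxt(out / f"{sid}_wmcsf.txt", scan.nuisance, fmt=nfio.FLOAT_FMT)
        log.info("simulate: wrote %s", sid)
    _mark(out, h)
    return out


def _subject_ids(sim_dir: Path) -> list[str]:
    cohort = nfio.load_cohort(sim_dir / "cohort.tsv")
    return cohort["subject_id"].tolist()


def stage_preprocess(config: PipelineConfig) -> Path:
    """Temporal preprocessing of every subject: writes the unfiltered
    residual and band-passed series plus the motion QC table."""
    run_dir = Path(config.out_dir)
    sim = run_dir / "simulate"
    out = _stage_dir(run_dir, "preprocess")
    h = config.config_hash()
    if _done(out, h):
        log.info("preprocess: cached, skipping")
        return out
    if not (sim / "cohort.tsv").exists():
        raise DataError("preprocess: no simulated cohort found; run simulate first")
    qc_records = []
    for sid in _subject_ids(sim):
        try:
            ts = nfio.load_scan(sim / f"{sid}_scan.tsv.gz")
            motion = nfio.load_motion(sim / f"{sid}_motion.txt")
            wmcsf = np.loadtxt(sim / f"{sid}_wmcsf.txt", ndmin=2)
            res = preprocess_subject(
                ts,
                motion,
                wmcsf,
                order=tuple(config.preprocess_order),
                n_discard=config.n_discard,
                detrend_order=config.detrend_order,
                band=config.band,
                qc_thresholds=QCThresholds(),
            )
        except NetfalffError as exc:
            raise DataError(
                f"preprocess failed for subject {sid}: {exc} "
                "(inspect the simulate outputs for this subject)"
            ) from exc
        nfio.save_scan(out / f"{sid}_residual.tsv.gz", res.unfiltered)
        nfio.save_scan(out / f"{sid}_filtered.tsv.gz", res.filtered)
        if res.qc is not None:
            qc_records.append(res.qc)
        log.info("preprocess: %s done", sid)
    if qc_records:
        nfio.save_table(out / "qc.tsv", nfio.qc_records_to_table(qc_records))
    _mark(out, h)
    return out


def stage_align(config: PipelineConfig) -> Path:
    """Per-subject spatial ICA and cross-subject alignment into ICN
    templates; skipped (with a log line) when fixed templates are supplied."""
    run_dir = Path(config.out_dir)
    out = _stage_dir(run_dir, "align")
    h = config.config_hash()
    if _done(out, h):
        log.info("align: cached, skipping")
        return out
    if config.templates_path is not None:
        log.info("align: fixed templates supplied (%s); stage skipped", config.templates_path)
        tpl = nfio.load_templates(config.templates_path)
        nfio.save_templates(out / "templates.tsv", tpl, config_hash=h)
        _mark(out, h)
        return out
    if config.use_ground_truth_templates:
        log.info("align: using generator ground-truth templates; ICA skipped")
        tpl = nfio.load_templates(run_dir / "simulate" / "true_templates.tsv")
        nfio.save_templates(out / "templates.tsv", tpl, config_hash=h)
        _mark(out, h)
        return out
    pre = run_dir / "preprocess"
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    components = []
    for sid in _subject_ids(run_dir / "simulate"):
        ts = nfio.load_scan(pre / f"{sid}_residual.tsv.gz")
        comp = _decompose_with_retry(
            ts, config.graicar.n_components, seed=int(rng.integers(2**31))
        )
        components.append(comp)
        log.info("align: decomposed %s (K=%d)", sid, comp.n_components)
    acs, templates = align_components(
        components,
        n_bins=config.graicar.n_bins,
        n_perm=config.graicar.n_perm,
        alpha=config.graicar.alpha,
        min_fraction=config.graicar.min_fraction,
        seed=int(rng.integers(2**31)),
    )
    report = []
    for ac_id, ac in enumerate(acs):
        for (sid, comp), cent, p in zip(ac.members, ac.centrality, ac.centrality_p):
            report.append(
                {
                    "ac_id": ac_id,
                    "subject": sid,
                    "component": comp,
                    "centrality": cent,
                    "p": p,
                    "consistency": ac.consistency,
                }
            )
    nfio.save_table(out / "ac_report.tsv", pd.DataFrame(report), [f"config_hash={h}"])
    if templates is None:
        log.warning("align: consistency filter retained no component")
        raise DataError("alignment retained no consistent component")
    nfio.save_templates(out / "templates.tsv", templates, config_hash=h)
    _mark(out, h)
    return out


def stage_falff(config: PipelineConfig) -> Path:
    """Network and global fALFF for every subject from the preprocessed
    residual/filtered pair and the stage templates."""
    run_dir = Path(config.out_dir)
    out = _stage_dir(run_dir, "falff")
    h = config.config_hash()
    if _done(out, h):
        log.info("falff: cached, skipping")
        return out
    templates = nfio.load_templates(run_dir / "align" / "templates.tsv")
    reg = SpatialRegressor(templates)
    pre = run_dir / "preprocess"
    net_rows, glob_rows = [], []
    for sid in _subject_ids(run_dir / "simulate"):
        raw = nfio.load_scan(pre / f"{sid}_residual.tsv.gz")
        filt = nfio.load_scan(pre / f"{sid}_filtered.tsv.gz")
        net_rows.append(network_falff(raw, filt, templates, regressor=reg))
        glob_rows.append(
            {
                "subject_id": sid,
                "global_falff": global_falff(vertex_falff(raw, *config.band)),
            }
        )
        log.info("falff: %s done", sid)
    comments = [f"config_hash={h}", f"band={config.band[0]}-{config.band[1]}Hz"]
    nfio.save_table(out / "falff_by_network.tsv", pd.concat(net_rows, ignore_index=True), comments)
    nfio.save_table(out / "falff_global.tsv", pd.DataFrame(glob_rows), comments)
    _mark(out, h)
    return out


def stage_stats(config: PipelineConfig) -> Path:
    """Group comparisons per network and covariate-adjusted correlations
    with practice exposure and behavior, with an audit trail of transform
    and exclusion decisions."""
    run_dir = Path(config.out_dir)
    out = _stage_dir(run_dir, "stats")
    h = config.config_hash()
    if _done(out, h):
        log.info("stats: cached, skipping")
        return out
    cohort = nfio.load_cohort(run_dir / "simulate" / "cohort.tsv")
    falff_long = pd.read_csv(run_dir / "falff" / "falff_by_network.tsv", sep="\t", comment="#")
    wide = falff_long.pivot(index="subject_id", columns="network", values="falff")
    covs = tuple(config.stats.covariates)
    group_stats = network_group_table(
        wide, cohort, covariates=covs, correction=config.stats.correction,
        alpha=config.stats.alpha,
    )
    nfio.save_table(out / "group_stats.tsv", group_stats, [f"config_hash={h}"])

    audit: dict = {"config_hash": h, "transforms": {}, "exclusions": {}}
    corr_rows = []
    sig_nets = group_stats.loc[group_stats["p_F"] < config.stats.alpha, "network"].tolist()
    tcc = cohort[cohort["group"] == "TCC"].set_index("subject_id")
    tcc = tcc.join(wide, how="inner")
    intensity = tcc["tcc_hours_per_week"].to_numpy(dtype=float)
    rep = flag_outliers(intensity)
    excluded = tuple(tcc.index[rep.flags])
    audit["exclusions"]["tcc_hours_per_week"] = {
        "rule": "tukey_far_out_3iqr",
        "excluded_subjects": list(excluded),
        "fences": [rep.lo_fence, rep.hi_fence],
    }
    keep = ~rep.flags
    tr_rep = normality_gate_log_transform(intensity[keep])
    audit["transforms"]["tcc_hours_per_week"] = {
        "applied": tr_rep.transformed,
        "shapiro_p_before": tr_rep.shapiro_p_before,
        "shapiro_p_after": tr_rep.shapiro_p_after,
    }
    z_all = encode_covariates(tcc.reset_index(), covs)
    for net in sig_nets:
        try:
            corr_rows.append(
                partial_correlation(
                    tr_rep.values,
                    tcc[net].to_numpy(dtype=float)[keep],
                    z_all[keep],
                    names=("tcc_hours_per_week", net),
                    covariate_names=covs,
                    excluded=excluded,
                )
            )
        except DataError as exc:
            log.warning("stats: skipping intensity correlation for %s (%s)", net, exc)
        rt = tcc["conflict_rt"].to_numpy(dtype=float)
        rt_ok = np.isfinite(rt)
        if rt_ok.sum() >= len(covs) + 3:
            rt_rep = normality_gate_log_transform(rt[rt_ok])
            corr_rows.append(
                partial_correlation(
                    rt_rep.values,
                    tcc[net].to_numpy(dtype=float)[rt_ok],
                    z_all[rt_ok],
                    names=("conflict_rt", net),
                    covariate_names=covs,
                )
            )
    corr_table = pd.DataFrame(
        [
            {
                "x": r.x,
                "y": r.y,
                "covariates": ",".join(r.covariates),
                "n": r.n,
                "r": r.r,
                "p": r.p,
                "excluded_subjects": ";".join(r.excluded),
            }
            for r in corr_rows
        ]
    )
    nfio.save_table(out / "correlations.tsv", corr_table, [f"config_hash={h}"])
    (out / "audit.json").write_text(json.dumps(audit, indent=1))
    _mark(out, h)
    return out


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "align": stage_align,
    "falff": stage_falff,
    "stats": stage_stats,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the run directory.

    The resolved config (with its hash) is written to the run directory
    first, so any output can be traced back to the exact settings.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump()
    resolved["config_hash"] = config.config_hash()
    (run_dir / "config.resolved.json").write_text(json.dumps(resolved, indent=1))
    for name, fn in _STAGES.items():
        log.info("=== stage %s ===", name)
        try:
            fn(config)
        except NetfalffError as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc
    return run_dir
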