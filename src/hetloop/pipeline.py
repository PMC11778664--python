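"""Config-driven orchestration: simulate -> discover -> replicate -> prs -> enrich.

A :class:`RunConfig` (typically loaded from YAML) names the inputs, the
half-loop parameters, the covariate conventions, the evaluation interval and
the PRS thresholds; :func:`run_pipeline` executes the requested stages in
dependency order, writing self-describing TSV/JSON outputs per stage.  With a
fixed master seed every numeric table is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biclustering import HalfLoopConfig, run_discovery
from .covariates import select_covariates
from .genotype_io import (
    ComboMatrix,
    GenotypeDataset,
    annotation_from_mapping,
    expand_allele_combinations,
    filter_by_maf,
    read_covariate_table,
    read_genotypes,
    read_gene_annotation,
    read_gmt,
    write_genotypes,
)
from .prs import clump, gwas, threshold_sweep
from .replication import replicate
from .synthetic_data import SyntheticConfig, generate_study, make_gene_sets
from .enrichment import permutation_enrichment

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "discover", "replicate", "prs", "enrich")


@dataclass
class RunConfig:
    """Everything a full run needs; unset stages are skipped."""

    stages: tuple[str, ...] = ALL_STAGES
    synthetic: dict = field(default_factory=dict)
    maf_threshold: float = 0.25
    halfloop: dict = field(default_factory=dict)
    discovery_covariates: list[int] | None = None  # None -> forward selection
    evaluation_covariates: list[int] = field(default_factory=lambda: [0, 1])
    interval: tuple[int, int] | None = None
    interval_halfwidth: int = 15  # fallback interval around the peak-z iteration
    stride: int = 1
    replication_shuffles: int = 64
    prs_thresholds: list[float] = field(
        default_factory=lambda: [1e-4, 1e-3, 1e-2, 0.1, 0.5, 1.0]
    )
    clump_params: dict = field(
        default_factory=lambda: {"r2_threshold": 0.1, "window_bp": 500_000, "maf_threshold": 0.05}
    )
    prevalence: dict = field(
        default_factory=lambda: {"all": 0.02, "BDI": 0.01, "BDII": 0.01}
    )
    gmt_path: str | None = None
    annotation_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.interval is not None:
            cfg.interval = tuple(cfg.interval)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _split_cm(ds: GenotypeDataset, maf_threshold: float) -> tuple[ComboMatrix, ComboMatrix]:
    cm = expand_allele_combinations(filter_by_maf(ds, maf_threshold))
    case = np.flatnonzero(ds.case_mask())
    ctrl = np.flatnonzero(~ds.case_mask())
    return cm.restrict_subjects(case), cm.restrict_subjects(ctrl)


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def simulate_stage(cfg: RunConfig, out: Path) -> list:
    """Generate all arms and write them in the package's text formats."""
    syn = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
    arms = generate_study(syn)
    out = Path(out)
    for a, (ds, cov, truth) in enumerate(arms, start=1):
        prefix = out / f"arm{a}" / f"arm{a}"
        write_genotypes(ds, prefix, format="ped_map")
        cov.to_csv(prefix.with_suffix(".cov.tsv"), sep="\t")
    truth0 = arms[0][2]
    _write_json(
        out / "truth.json",
        {
            "planted_case_ids": sorted(truth0.planted_case_ids),
            "planted_snp_ids": sorted(truth0.planted_snp_ids),
            "planted_combo_ids": sorted(truth0.planted_combo_ids),
            "arm_panels": {str(k): v for k, v in truth0.arm_panels.items()},
            "seed": cfg.seed,
        },
    )
    return arms


def discover_stage(
    cfg: RunConfig,
    ds: GenotypeDataset,
    cov: pd.DataFrame,
    out: Path,
):
    """Half-loop discovery on the training arm, with nulls and significance."""
    D, X = _split_cm(ds, cfg.maf_threshold)
    selected = cfg.discovery_covariates
    if selected is None:
        order = np.concatenate(
            [np.flatnonzero(ds.case_mask()), np.flatnonzero(~ds.case_mask())]
        )
        status = ds.subjects["status"].to_numpy()[order]
        cov_rows = cov.loc[ds.subject_ids[order]].to_numpy(dtype=float)
        selected = select_covariates(status, cov_rows)
        logger.info("forward selection kept covariates %s", selected)
    hl = HalfLoopConfig(
        **{**cfg.halfloop, "seed": cfg.seed, "selected_covariates": selected}
    )
    traj = run_discovery(D, X, cov, hl, record_null_cols=True)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(out / "trajectory.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"case_id": traj.case_ids, "removal_iteration": traj.row_removal_iter}
    ).to_csv(out / "row_removal.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"combo_id": traj.combo_ids, "removal_iteration": traj.col_removal_iter}
    ).to_csv(out / "col_removal.tsv", sep="\t", index=False)
    pd.DataFrame(traj.null_traces).to_csv(
        out / "null_traces.tsv", sep="\t", index=False
    )
    _write_json(
        out / "discovery.json",
        {
            "p_overall": traj.p_overall,
            "peak_z_iteration": traj.peak_z_iteration(),
            "selected_covariates": list(selected),
            "n_iterations": traj.n_iterations,
            "config": cfg.echo(),
        },
    )
    return traj, selected


def _interval_for(cfg: RunConfig, traj) -> tuple[int, int]:
    if cfg.interval is not None:
        return cfg.interval
    pk = traj.peak_z_iteration()
    lo = max(0, pk - cfg.interval_halfwidth)
    hi = min(traj.n_iterations - 1, pk + cfg.interval_halfwidth)
    hi = min(hi, int(np.searchsorted(-traj.M, -2)))  # keep M(i) >= 2
    return lo, hi


def replicate_stage(
    cfg: RunConfig,
    traj,
    D1: ComboMatrix,
    X1: ComboMatrix,
    arm_name: str,
    ds_repl: GenotypeDataset,
    cov1: pd.DataFrame,
    cov_repl: pd.DataFrame,
    out: Path,
):
    D2, X2 = _split_cm(ds_repl, cfg.maf_threshold)
    lo, hi = _interval_for(cfg, traj)
    res = replicate(
        traj,
        D1,
        X1,
        D2,
        X2,
        cov1,
        cov_repl,
        selected=cfg.evaluation_covariates,
        interval=(lo, hi),
        stride=cfg.stride,
        n_shuffles=cfg.replication_shuffles,
        seed=cfg.seed,
    )
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    res.to_frame().to_csv(out / f"replication_{arm_name}.tsv", sep="\t", index=False)
    _write_json(
        out / f"replication_{arm_name}.json",
        {
            "arm": arm_name,
            "interval": [lo, hi],
            "auc_repl_mean": res.auc_repl_mean,
            "p_repl_mean": res.p_repl_mean,
        },
    )
    return res


def prs_stage(
    cfg: RunConfig,
    ds_train: GenotypeDataset,
    traj,
    iteration: int,
    ds_test: GenotypeDataset,
    cov_train: pd.DataFrame,
    cov_test: pd.DataFrame,
    out: Path,
):
    """Population-wide vs bicluster-informed PRS sweep on a testing arm."""
    sel = cfg.evaluation_covariates
    stats_wide = gwas(ds_train, None, cov_train, sel)
    J = set(traj.retained_case_ids(iteration))
    stats_bicl = gwas(ds_train, J, cov_train, sel)
    summaries = {"wide": stats_wide, f"bicl_{iteration}": stats_bicl}
    survivors = {
        name: clump(summary, ds_train, **cfg.clump_params)
        for name, summary in summaries.items()
    }
    frames = []
    for subtype, prev in cfg.prevalence.items():
        ev = threshold_sweep(
            summaries,
            survivors,
            ds_test,
            cfg.prs_thresholds,
            cov_test,
            sel,
            subtype_filter=subtype,
            prevalence=prev,
        )
        ev.curve["subtype"] = subtype
        frames.append(ev.curve)
    curve = pd.concat(frames, ignore_index=True)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_csv(out / "prs_curves.tsv", sep="\t", index=False)
    for name, summary in summaries.items():
        summary.to_csv(out / f"gwas_{name}.tsv", sep="\t", index=False)
    return curve


def enrich_stage(
    cfg: RunConfig,
    traj,
    annotation,
    pathways,
    out: Path,
):
    lo, hi = _interval_for(cfg, traj)
    res = permutation_enrichment(traj, annotation, pathways, (lo, hi), stride=max(1, cfg.stride))
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    _write_json(
        out / "enrichment.json",
        {"interval": [lo, hi], "z_bar": res.z_bar, "p_z_bar": res.p_z_bar},
    )
    return res


def run_pipeline(cfg: RunConfig, out: Path) -> dict:
    """Execute the configured stages end to end on synthetic data.

    Returns a summary dict with the principal numbers of each stage; all
    stage outputs are also written under ``out``.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.echo()}
    if "simulate" not in cfg.stages:
        raise ValueError("run_pipeline orchestrates synthetic runs; include 'simulate'")
    arms = simulate_stage(cfg, out / "data")
    (ds1, cov1, truth) = arms[0]
    if ds1.case_mask().sum() == 0:
        raise ValueError("training arm has no cases")
    if "discover" not in cfg.stages:
        return summary
    traj, selected = discover_stage(cfg, ds1, cov1, out / "discovery")
    summary["p_overall"] = traj.p_overall
    summary["peak_z_iteration"] = traj.peak_z_iteration()
    D1, X1 = _split_cm(ds1, cfg.maf_threshold)

    if "replicate" in cfg.stages:
        repl = {}
        for a, (ds_r, cov_r, _) in enumerate(arms[1:], start=2):
            res = replicate_stage(
                cfg, traj, D1, X1, f"arm{a}", ds_r, cov1, cov_r, out / "replication"
            )
            repl[f"arm{a}"] = {
                "auc_repl_mean": res.auc_repl_mean,
                "p_repl_mean": res.p_repl_mean,
            }
        summary["replication"] = repl

    if "prs" in cfg.stages and len(arms) > 1:
        iteration = traj.peak_z_iteration()
        curve = prs_stage(
            cfg, ds1, traj, iteration, arms[1][0], cov1, arms[1][1], out / "prs"
        )
        summary["prs"] = {
            "iteration": iteration,
            "n_rows": int(len(curve)),
        }

    if "enrich" in cfg.stages:
        if cfg.gmt_path and cfg.annotation_path:
            panel = filter_by_maf(ds1, cfg.maf_threshold).snp_ids
            annotation = read_gene_annotation(cfg.annotation_path, panel)
            pathways = read_gmt(cfg.gmt_path)
        else:
            panel = filter_by_maf(ds1, cfg.maf_threshold).snp_ids
            gene_to_snps, pathways, _ = make_gene_sets(
                panel, truth.planted_snp_ids, seed=cfg.seed
            )
            annotation = annotation_from_mapping(gene_to_snps, panel)
        res = enrich_stage(cfg, traj, annotation, pathways, out / "enrichment")
        summary["enrichment"] = {"z_bar": res.z_bar, "p_z_bar": res.p_z_bar}

    _write_json(out / "summary.json", summary)
    return summary


def load_trajectory(discovery_dir: Path):
    """Rebuild a BiclusterTrajectory from a discover stage's output files."""
    from .biclustering import BiclusterTrajectory, HalfLoopConfig

    d = Path(discovery_dir)
    frame = pd.read_csv(d / "trajectory.tsv", sep="\t")
    rows = pd.read_csv(d / "row_removal.tsv", sep="\t")
    cols = pd.read_csv(d / "col_removal.tsv", sep="\t")
    with open(d / "discovery.json") as fh:
        meta = json.load(fh)
    nulls = None
    if (d / "null_traces.tsv").exists():
        nulls = pd.read_csv(d / "null_traces.tsv", sep="\t").to_numpy()
    hl_raw = meta.get("config", {}).get("halfloop", {})
    cfg = HalfLoopConfig(
        **{**hl_raw, "selected_covariates": meta.get("selected_covariates")}
    )
    traj = BiclusterTrajectory(
        case_ids=rows["case_id"].to_numpy(),
        combo_ids=cols["combo_id"].to_numpy(),
        M=frame["M"].to_numpy(),
        N=frame["N"].to_numpy(),
        trace=frame["trace"].to_numpy(),
        trace_norm=frame["trace_norm"].to_numpy(),
        row_removal_iter=rows["removal_iteration"].to_numpy(),
        col_removal_iter=cols["removal_iteration"].to_numpy(),
        schedule_rows=np.array([]),
        schedule_cols=np.array([]),
        config=cfg,
        null_traces=nulls,
    )
    if "z" in frame.columns:
        traj.z = frame["z"].to_numpy()
        traj.p = frame["p"].to_numpy()
        traj.p_overall = meta.get("p_overall")
    return traj
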