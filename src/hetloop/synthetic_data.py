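"""Synthetic multi-arm case/control genotype studies with planted biclusters.

The generator emulates the structure of a multi-cohort GWAS heterogeneity
study: common SNPs in Hardy-Weinberg proportions, per-SNP allele frequencies
tied to continuous ancestry covariates through logit-scale loadings, a
planted bicluster (a subset of cases whose minor-allele probability is
shifted over a subset of SNPs, absent from controls), case subtype labels
enriched inside the planted set, and replication arms drawing fresh subjects
on SNP panels whose overlap coefficient with the training panel is
controlled.  Genotypes are drawn per haplotype, optionally with an AR(1)
latent field inducing adjacent-SNP linkage disequilibrium.

All randomness derives from the config seed; generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .biclustering import BiclusterTrajectory
from .genotype_io import COMBO_KINDS, SNP_COLUMNS, GenotypeDataset

N_CHROMS = 22
SNP_SPACING_BP = 10_000


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Sizes are per arm.  ``effect_delta`` shifts the minor-allele probability
    of planted cases at planted SNPs (allele-frequency scale); the planted
    case and SNP fractions default to a bicluster occupying 30% of cases and
    10% of the training panel.  ``arm_overlaps`` are the target overlap
    coefficients of the replication panels with the training panel.
    ``case_covariate_shift`` moves the case covariate distribution along the
    first covariate axis, creating purely covariate-driven case/control
    structure for confounding experiments.
    """

    n_cases: int = 300
    n_controls: int = 300
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.25, 0.5)
    n_covariates: int = 2
    ancestry_loading_sd: float = 0.1
    bicluster_case_fraction: float = 0.3
    bicluster_snp_fraction: float = 0.1
    effect_delta: float = 0.4
    subtype_base_fraction: float = 0.69
    subtype_bicluster_fraction: float = 0.74
    arm_overlaps: tuple[float, ...] = (0.85, 0.50, 0.30)
    arm_panel_fraction: float = 0.5
    ld_autocorr: float = 0.0
    case_covariate_shift: float = 0.0
    control_bicluster: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bicluster_case_fraction",
            "bicluster_snp_fraction",
            "subtype_base_fraction",
            "subtype_bicluster_fraction",
            "arm_panel_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not 0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within [0, 0.5]")
        if any(not 0 < c <= 1 for c in self.arm_overlaps):
            raise ValueError("arm overlaps must lie in (0, 1]")
        if self.effect_delta < 0 or self.ancestry_loading_sd < 0:
            raise ValueError("effect_delta and ancestry_loading_sd must be >= 0")
        if not 0 <= self.ld_autocorr < 1:
            raise ValueError("ld_autocorr must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    planted_case_ids: set
    planted_snp_ids: set
    planted_combo_ids: set
    planted_control_ids: set
    arm_panels: dict
    covariates: pd.DataFrame


@dataclass
class _Master:
    """Structure shared by all arms (derived deterministically from seed)."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    maf: np.ndarray
    loadings: np.ndarray
    panels: dict  # arm index (1-based) -> sorted array of master SNP indices
    planted_snps: np.ndarray  # master indices, subset of arm 1's panel


def _master_structure(cfg: SyntheticConfig) -> _Master:
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_snps
    snp_ids = np.array([f"snp{i:05d}" for i in range(n)])
    per_chrom = int(np.ceil(n / N_CHROMS))
    chrom = np.array([str(1 + i // per_chrom) for i in range(n)])
    pos = np.array([1 + (i % per_chrom) * SNP_SPACING_BP for i in range(n)])
    maf = rng.uniform(*cfg.maf_range, size=n)
    loadings = rng.normal(0.0, cfg.ancestry_loading_sd, size=(n, cfg.n_covariates))

    panel_size = max(1, round(cfg.arm_panel_fraction * n))
    arm1 = np.sort(rng.choice(n, panel_size, replace=False))
    outside = np.setdiff1d(np.arange(n), arm1)
    panels = {1: arm1}
    for a, target in enumerate(cfg.arm_overlaps, start=2):
        n_inter = round(target * panel_size)
        n_out = panel_size - n_inter
        if n_out > len(outside):
            raise ValueError(
                f"arm {a}: overlap target {target} infeasible — needs {n_out} "
                f"SNPs outside the training panel but only {len(outside)} exist"
            )
        inter = rng.choice(arm1, n_inter, replace=False)
        extra = rng.choice(outside, n_out, replace=False)
        panels[a] = np.sort(np.concatenate([inter, extra]))
    n_planted = round(cfg.bicluster_snp_fraction * panel_size)
    planted = np.sort(rng.choice(arm1, n_planted, replace=False))
    return _Master(snp_ids, chrom, pos, maf, loadings, panels, planted)


def _draw_genotypes(
    p: np.ndarray, ld_autocorr: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial(2, p) per entry; with LD, each haplotype thresholds an AR(1)
    latent Gaussian so marginals stay Hardy-Weinberg."""
    n, s = p.shape
    if ld_autocorr == 0.0:
        return rng.binomial(2, p).astype(float)
    calls = np.zeros((n, s))
    rho = ld_autocorr
    for _hap in range(2):
        z = np.empty((n, s))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, s))
        for j in range(1, s):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
        u = norm.cdf(z)
        calls += (u < p).astype(float)
    return calls


def generate_arm(
    cfg: SyntheticConfig, arm_index: int = 1
) -> tuple[GenotypeDataset, pd.DataFrame, GroundTruth]:
    """Generate one arm: genotypes, covariate table, and its ground truth.

    Arm 1 is the training arm; arms 2.. are replication arms on panels whose
    overlap coefficient with arm 1's panel matches ``cfg.arm_overlaps``.
    Every arm has fresh subjects but carries the same planted SNP signature
    (restricted to its panel) in a fresh planted case subset.
    """
    master = _master_structure(cfg)
    if arm_index not in master.panels:
        raise ValueError(f"arm_index must be in {sorted(master.panels)}")
    rng = np.random.default_rng([cfg.seed, 100 + arm_index])

    panel = master.panels[arm_index]
    n_case, n_ctrl = cfg.n_cases, cfg.n_controls
    n = n_case + n_ctrl
    arm = f"arm{arm_index}"
    subject_ids = np.array(
        [f"{arm}_case{i:04d}" for i in range(n_case)]
        + [f"{arm}_ctrl{i:04d}" for i in range(n_ctrl)]
    )

    cov = rng.standard_normal((n, cfg.n_covariates))
    if cfg.case_covariate_shift:
        cov[:n_case, 0] += cfg.case_covariate_shift

    # minor-allele probability per subject x SNP on this arm's panel
    base = logit(master.maf[panel])[None, :]
    eta = base + cov @ master.loadings[panel].T
    p = expit(eta)

    panel_pos = {snp: j for j, snp in enumerate(panel)}
    planted_local = np.array(
        [panel_pos[s] for s in master.planted_snps if s in panel_pos], dtype=int
    )
    n_planted_cases = round(cfg.bicluster_case_fraction * n_case)
    planted_cases = np.sort(rng.choice(n_case, n_planted_cases, replace=False))
    if len(planted_local) and n_planted_cases:
        p[np.ix_(planted_cases, planted_local)] = np.clip(
            p[np.ix_(planted_cases, planted_local)] + cfg.effect_delta, 0.01, 0.99
        )

    planted_controls = np.array([], dtype=int)
    if cfg.control_bicluster:
        cb = cfg.control_bicluster
        n_cb = round(cb.get("fraction", 0.3) * n_ctrl)
        planted_controls = np.sort(rng.choice(n_ctrl, n_cb, replace=False)) + n_case
        cb_rng = np.random.default_rng([cfg.seed, 1])
        n_cb_snps = round(cb.get("snp_fraction", 0.1) * len(panel))
        cb_local = np.sort(cb_rng.choice(len(panel), n_cb_snps, replace=False))
        p[np.ix_(planted_controls, cb_local)] = np.clip(
            p[np.ix_(planted_controls, cb_local)] + cb.get("effect_delta", 0.4),
            0.01,
            0.99,
        )

    calls = _draw_genotypes(p, cfg.ld_autocorr, rng)

    # subtype labels: enriched inside the planted set, marginal matches base
    f = cfg.bicluster_case_fraction
    q_in = cfg.subtype_bicluster_fraction
    q_out = cfg.subtype_base_fraction
    if f < 1:
        q_out = np.clip((cfg.subtype_base_fraction - f * q_in) / (1 - f), 0.0, 1.0)
    is_planted_case = np.zeros(n_case, dtype=bool)
    is_planted_case[planted_cases] = True
    bdi = np.where(
        is_planted_case,
        rng.random(n_case) < q_in,
        rng.random(n_case) < q_out,
    )
    subtype = np.array(["BDI" if b else "BDII" for b in bdi] + ["unknown"] * n_ctrl)

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "status": ["case"] * n_case + ["control"] * n_ctrl,
            "subtype": subtype,
            "arm_id": arm,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": master.snp_ids[panel],
            "chrom": master.chrom[panel],
            "pos_bp": master.pos_bp[panel],
            "allele_major": "A",
            "allele_minor": "B",
            "maf": np.nan,
        },
        columns=SNP_COLUMNS,
    )
    ds = GenotypeDataset(subjects=subjects, snps=snps, calls=calls)
    # store the realized sample frequency of the designated minor allele; for
    # strongly shifted planted SNPs it may exceed 0.5 — allele labels stay
    # harmonized across arms rather than flipping per arm
    ds.snps["maf"] = ds.computed_maf()

    cov_tbl = pd.DataFrame(
        cov,
        index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"U{k + 1}" for k in range(cfg.n_covariates)],
    )
    planted_snp_ids = set(master.snp_ids[master.planted_snps])
    truth = GroundTruth(
        planted_case_ids=set(subject_ids[planted_cases]),
        planted_snp_ids=planted_snp_ids,
        planted_combo_ids={
            f"{s}:{kind}" for s in planted_snp_ids for kind in COMBO_KINDS
        },
        planted_control_ids=set(subject_ids[planted_controls]),
        arm_panels={a: list(master.snp_ids[idx]) for a, idx in master.panels.items()},
        covariates=cov_tbl,
    )
    return ds, cov_tbl, truth


def generate_study(
    cfg: SyntheticConfig,
) -> list[tuple[GenotypeDataset, pd.DataFrame, GroundTruth]]:
    """Generate the training arm plus one replication arm per overlap target."""
    return [generate_arm(cfg, a) for a in range(1, len(cfg.arm_overlaps) + 2)]


def recovery_metrics(
    traj: BiclusterTrajectory,
    truth: GroundTruth,
    iteration: int,
) -> dict:
    """Set-overlap metrics between J(i)/K(i) and the planted sets."""
    rows = set(traj.retained_case_ids(iteration))
    cols = set(traj.retained_combo_ids(iteration))
    true_rows = set(truth.planted_case_ids)
    true_cols = set(truth.planted_combo_ids) & set(traj.combo_ids)

    def _prf(found: set, true: set) -> tuple[float, float, float]:
        inter = len(found & true)
        precision = inter / len(found) if found else 0.0
        recall = inter / len(true) if true else 0.0
        union = len(found | true)
        jaccard = inter / union if union else 0.0
        return precision, recall, jaccard

    rp, rr, rj = _prf(rows, true_rows)
    cp, cr, cj = _prf(cols, true_cols)
    return {
        "row_precision": rp,
        "row_recall": rr,
        "row_jaccard": rj,
        "col_precision": cp,
        "col_recall": cr,
        "col_jaccard": cj,
    }


def make_gene_sets(
    snp_ids: np.ndarray,
    planted_snp_ids: set,
    seed: int = 0,
    snps_per_gene: int = 4,
    n_pathways: int = 20,
    pathway_size: int = 8,
    n_signal_pathways: int = 2,
) -> tuple[dict, "PathwayCollection", list]:
    """Synthetic gene->SNP annotation and pathway collection for enrichment.

    Genes tile the SNP panel in consecutive blocks; planted SNPs are kept in
    separate blocks from background SNPs so "signal genes" are well defined.
    ``n_signal_pathways`` pathways are drawn from the signal genes, the rest
    uniformly from the background genes.  Returns the annotation mapping, the
    pathway collection, and the names of the signal pathways.
    """
    from .genotype_io import PathwayCollection

    rng = np.random.default_rng([seed, 11])
    snp_ids = np.asarray(snp_ids)
    planted = [s for s in snp_ids if s in planted_snp_ids]
    background = [s for s in snp_ids if s not in planted_snp_ids]
    gene_to_snps: dict[str, list] = {}
    g = 0
    for pool in (planted, background):
        for start in range(0, len(pool), snps_per_gene):
            block = pool[start : start + snps_per_gene]
            if block:
                gene_to_snps[f"gene{g:04d}"] = list(block)
                g += 1
    signal_genes = [
        gene
        for gene, snps in gene_to_snps.items()
        if sum(s in planted_snp_ids for s in snps) > len(snps) / 2
    ]
    bg_genes = [gene for gene in gene_to_snps if gene not in signal_genes]
    pathways: dict[str, set] = {}
    signal_names = []
    for l in range(n_pathways):
        if l < n_signal_pathways and len(signal_genes) >= 2:
            size = min(pathway_size, len(signal_genes))
            members = rng.choice(signal_genes, size, replace=False)
            name = f"signal_pathway_{l}"
            signal_names.append(name)
        else:
            size = min(pathway_size, len(bg_genes))
            members = rng.choice(bg_genes, size, replace=False)
            name = f"background_pathway_{l}"
        pathways[name] = set(members)
    collection = PathwayCollection(pathways=pathways, universe=set(gene_to_snps))
    return gene_to_snps, collection, signal_names
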