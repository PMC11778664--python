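"""Polygenic risk scoring, population-wide and bicluster-informed.

A per-SNP logistic GWAS (status ~ minor-allele count + ancestry covariates)
produces summary statistics, either contrasting *all* training cases with the
training controls (the population-wide score) or only the cases retained in
the bicluster at some iteration ``i`` (the bicluster-informed score).  Greedy
LD clumping keeps the most significant SNP per correlated neighborhood, a
p-value threshold selects the weight vector, and subjects of a testing arm
are scored by the weighted sum of their minor-allele counts.  Performance is
summarized by the covariate-corrected AUC (optionally restricted to a case
subtype) and its conversion to variance explained on the liability scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic_batch
from .genotype_io import GenotypeDataset
from .replication import corrected_auc

RIDGE_PENALTY = 1e-3  # stabilizing penalty for separated / non-converged fits
_GWAS_CHUNK = 512


@dataclass
class PrsModel:
    """Clumped, thresholded SNP weight vector.

    ``snps`` holds the ordered clump survivors with their GWAS betas and
    p-values; scoring uses only those with ``p <= p_threshold``.
    """

    snps: pd.DataFrame  # snp_id, beta, p
    p_threshold: float
    provenance: str = "wide"

    def active(self) -> pd.DataFrame:
        return self.snps[self.snps["p"] <= self.p_threshold]

    @property
    def n_snps(self) -> int:
        return int(len(self.active()))


@dataclass
class PrsEvaluation:
    """AUC/liability-R² results across thresholds and model provenances."""

    curve: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------


def gwas(
    ds: GenotypeDataset,
    case_subset: set | None = None,
    cov: pd.DataFrame | np.ndarray | None = None,
    selected: list[int] | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic association scan over (case subset ∪ all controls).

    Returns one record per SNP: effect allele (the minor allele), log-odds
    ``beta`` per minor-allele copy, Wald ``se`` and ``p``, sample maf and the
    number of cases used.  Separated or non-converged fits are refit with a
    small ridge penalty and flagged; zero-variance SNPs are emitted with
    ``beta=0, p=1`` and flagged.
    """
    status = ds.subjects["status"].to_numpy()
    case_mask = status == "case"
    if case_subset is not None:
        case_subset = set(case_subset)
        case_mask &= np.isin(ds.subject_ids, list(case_subset))
        if case_mask.sum() == 0:
            raise ValueError("case_subset selects no cases")
    keep = case_mask | (status == "control")
    idx = np.flatnonzero(keep)
    y = case_mask[idx].astype(float)
    n_cases = int(y.sum())

    calls = ds.calls[idx]
    col_mean = np.nanmean(np.where(np.isnan(calls), np.nan, calls), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    calls = np.where(np.isnan(calls), col_mean[None, :], calls)

    if cov is not None and selected:
        if isinstance(cov, pd.DataFrame):
            covm = cov.loc[ds.subject_ids[idx]].to_numpy(dtype=float)
        else:
            covm = np.asarray(cov, dtype=float)[idx]
        covm = covm[:, selected]
    else:
        covm = np.empty((len(idx), 0))

    n, n_snp = calls.shape
    p_design = 2 + covm.shape[1]
    beta = np.zeros(n_snp)
    se = np.full(n_snp, np.nan)
    pval = np.ones(n_snp)
    flags = np.array([""] * n_snp, dtype=object)

    variable = calls.std(axis=0) > 0
    flags[~variable] = "zero_variance"

    var_idx = np.flatnonzero(variable)
    for start in range(0, len(var_idx), _GWAS_CHUNK):
        chunk = var_idx[start : start + _GWAS_CHUNK]
        S = len(chunk)
        X = np.empty((S, n, p_design))
        X[:, :, 0] = 1.0
        X[:, :, 1] = calls[:, chunk].T
        if covm.shape[1]:
            X[:, :, 2:] = covm[None, :, :]
        fit = fit_logistic_batch(X, y)
        bad = fit.separated
        if bad.any():
            refit = fit_logistic_batch(X[bad], y, ridge=RIDGE_PENALTY)
            fit.beta[bad] = refit.beta
            fit.se[bad] = refit.se
            flags[chunk[bad]] = "ridge"
        beta[chunk] = fit.beta[:, 1]
        se[chunk] = fit.se[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            wald = (fit.beta[:, 1] / fit.se[:, 1]) ** 2
        pv = stats.chi2.sf(wald, df=1)
        pval[chunk] = np.where(np.isfinite(pv), pv, 1.0)

    maf = calls.sum(axis=0) / (2.0 * n)
    out = ds.snps[["snp_id", "chrom", "pos_bp", "allele_minor"]].copy()
    out = out.rename(columns={"allele_minor": "effect_allele"})
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(pval, np.finfo(float).tiny, 1.0)
    out["maf"] = maf
    out["n_cases"] = n_cases
    out["flag"] = flags
    return out


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


def clump(
    summary: pd.DataFrame,
    ds: GenotypeDataset,
    r2_threshold: float = 0.1,
    window_bp: int = 500_000,
    maf_threshold: float = 0.05,
) -> list[str]:
    """Greedy LD clumping: keep the most significant SNP per neighborhood.

    SNPs below the maf threshold are dropped.  The smallest-p unclaimed SNP
    (ties by position, then snp_id) becomes an index; unclaimed SNPs on the
    same chromosome within ±window whose squared Pearson correlation of
    minor-allele counts with the index (in ``ds``, the LD reference) exceeds
    ``r2_threshold`` are claimed and removed.
    """
    stats_tbl = summary[summary["maf"] >= maf_threshold].copy()
    if stats_tbl.empty:
        return []
    order = stats_tbl.sort_values(["p", "pos_bp", "snp_id"]).index
    pos_of = pd.Index(ds.snp_ids)
    calls = ds.calls
    col_mean = np.nanmean(calls, axis=0)
    calls = np.where(np.isnan(calls), col_mean[None, :], calls)

    unclaimed = set(order)
    survivors: list[str] = []
    meta = stats_tbl[["snp_id", "chrom", "pos_bp"]]
    for i in order:
        if i not in unclaimed:
            continue
        unclaimed.discard(i)
        snp = meta.loc[i]
        survivors.append(snp["snp_id"])
        g_index = calls[:, pos_of.get_loc(snp["snp_id"])]
        neighbors = [
            j
            for j in unclaimed
            if meta.loc[j, "chrom"] == snp["chrom"]
            and abs(meta.loc[j, "pos_bp"] - snp["pos_bp"]) <= window_bp
        ]
        for j in neighbors:
            g_j = calls[:, pos_of.get_loc(meta.loc[j, "snp_id"])]
            if g_j.std() == 0 or g_index.std() == 0:
                continue
            r = np.corrcoef(g_index, g_j)[0, 1]
            if r * r > r2_threshold:
                unclaimed.discard(j)
    return survivors


def build_model(
    summary: pd.DataFrame,
    survivors: list[str],
    p_threshold: float,
    provenance: str = "wide",
) -> PrsModel:
    """Assemble a PRS model from clump survivors and a p-value threshold."""
    tbl = summary.set_index("snp_id").loc[survivors].reset_index()
    model = PrsModel(
        snps=tbl[["snp_id", "beta", "p"]].copy(),
        p_threshold=p_threshold,
        provenance=provenance,
    )
    if model.n_snps == 0:
        raise ValueError(f"no SNPs survive p <= {p_threshold}")
    return model


# ---------------------------------------------------------------------------
# scoring and evaluation
# ---------------------------------------------------------------------------


def score(ds: GenotypeDataset, model: PrsModel) -> np.ndarray:
    """Weighted sum of minor-allele counts over the model's active SNPs.

    SNPs absent from the arm contribute 0; missing calls contribute the
    arm-mean call for that SNP.
    """
    active = model.active()
    if active.empty:
        raise ValueError("PRS model is empty after thresholding")
    panel = pd.Index(ds.snp_ids)
    pos = panel.get_indexer(active["snp_id"])
    present = pos >= 0
    if not present.all():
        import logging

        logging.getLogger(__name__).info(
            "%d model SNPs absent from arm; contributing 0", int((~present).sum())
        )
    pos = pos[present]
    betas = active["beta"].to_numpy()[present]
    calls = ds.calls[:, pos]
    col_mean = np.nanmean(calls, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    calls = np.where(np.isnan(calls), col_mean[None, :], calls)
    return calls @ betas


def liability_r2(
    auc: float, prevalence: float, case_fraction: float | None = None
) -> float:
    """Variance explained on the liability scale implied by an AUC.

    Probit mapping under the liability-threshold model: a predictor
    correlating ρ with a standard-normal liability (threshold
    ``t = Φ⁻¹(1-K)``, prevalence ``K``) separates case and control scores by

        d = ρ · z / (K(1-K)),   z = φ(t),

    in population-SD units, and the normal approximation of the two score
    distributions gives ``Φ⁻¹(AUC) = d / sqrt(V₁+V₀)``.  Starting from the
    weak-predictor value ``V₁+V₀ = 2`` (i.e. ``d = √2·Φ⁻¹(AUC)``), the exact
    truncated-normal group variances are iterated to a fixed point, and
    ``R² = ρ²``.  The AUC of the threshold model is unchanged by case/control
    ascertainment, so ``case_fraction`` is accepted for interface
    compatibility but unused by this route.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0 <= auc <= 1:
        raise ValueError("AUC must lie in [0, 1]")
    K = prevalence
    t = stats.norm.ppf(1 - K)
    z = stats.norm.pdf(t)
    q = abs(stats.norm.ppf(np.clip(auc, 1e-12, 1 - 1e-12)))
    if q == 0.0:
        return 0.0
    c = K * (1 - K) / z
    mu1 = z / K  # mean liability of cases
    mu0 = -z / (1 - K)  # mean liability of controls
    var1 = 1 + t * mu1 - mu1**2
    var0 = 1 + t * mu0 - mu0**2

    def q_of_rho(rho: float) -> float:
        v_sum = rho**2 * (var1 + var0) + 2 * (1 - rho**2)
        return rho / (c * np.sqrt(v_sum))

    # beyond the AUC a perfect liability predictor can reach, R² saturates at 1
    if q >= q_of_rho(1.0):
        return 1.0
    from scipy.optimize import brentq

    rho = brentq(lambda r: q_of_rho(r) - q, 0.0, 1.0, xtol=1e-12)
    return float(np.clip(rho**2, 0.0, 1.0))


def evaluate(
    scores: np.ndarray,
    subjects: pd.DataFrame,
    cov: pd.DataFrame | np.ndarray | None = None,
    selected: list[int] | None = None,
    subtype_filter: str = "all",
    prevalence: float = 0.02,
) -> tuple[float, float]:
    """Covariate-corrected AUC of the scores plus liability-scale R².

    ``subtype_filter`` restricts the case side to a subtype (controls are
    always all controls); prevalence should match the filtered phenotype
    (e.g. 2% for the broad diagnosis, 1% for a subtype).
    """
    status = subjects["status"].to_numpy()
    case_mask = status == "case"
    if subtype_filter != "all":
        case_mask &= (subjects["subtype"] == subtype_filter).to_numpy()
        if case_mask.sum() == 0:
            raise ValueError(f"no cases with subtype {subtype_filter!r}")
    ctrl_mask = status == "control"
    scores = np.asarray(scores, float)
    sel_idx = np.concatenate([np.flatnonzero(case_mask), np.flatnonzero(ctrl_mask)])
    cov_rows = None
    if cov is not None and selected:
        if isinstance(cov, pd.DataFrame):
            cov_rows = cov.loc[subjects["subject_id"].to_numpy()[sel_idx]].to_numpy(
                dtype=float
            )
        else:
            cov_rows = np.asarray(cov, float)[sel_idx]
    auc = corrected_auc(
        scores[case_mask], scores[ctrl_mask], cov_rows, selected
    )
    p_sample = case_mask.sum() / (case_mask.sum() + ctrl_mask.sum())
    return auc, liability_r2(auc, prevalence, p_sample)


def threshold_sweep(
    summaries: dict,
    survivors: dict,
    arm: GenotypeDataset,
    thresholds: list[float],
    cov: pd.DataFrame | np.ndarray | None = None,
    selected: list[int] | None = None,
    subtype_filter: str = "all",
    prevalence: float = 0.02,
) -> PrsEvaluation:
    """AUC/R² curves over p-value thresholds for several PRS provenances.

    ``summaries`` maps a provenance name (e.g. ``"wide"``, ``"bicl_175"``) to
    its GWAS summary table, ``survivors`` to the matching clump survivors.
    """
    rows = []
    for name, summary in summaries.items():
        surv = survivors[name]
        for pt in thresholds:
            tbl = summary.set_index("snp_id").loc[surv]
            n_active = int((tbl["p"] <= pt).sum())
            if n_active == 0:
                rows.append(
                    {
                        "model": name,
                        "p_threshold": pt,
                        "n_snps": 0,
                        "auc": np.nan,
                        "liability_r2": np.nan,
                    }
                )
                continue
            model = build_model(summary, surv, pt, provenance=name)
            s = score(arm, model)
            auc, r2 = evaluate(
                s, arm.subjects, cov, selected, subtype_filter, prevalence
            )
            rows.append(
                {
                    "model": name,
                    "p_threshold": pt,
                    "n_snps": n_active,
                    "auc": auc,
                    "liability_r2": r2,
                }
            )
    return PrsEvaluation(curve=pd.DataFrame(rows))
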