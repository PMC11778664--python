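"""Gene-set over-representation of the combos surviving the half-loop.

At iteration ``i`` the surviving combo set defines a retained gene set
``G(i)``: a gene is retained when strictly more than half of its annotated
allele-combinations on the analysis panel survive.  For each pathway the
gene-count overlap ``κ(i, l) = |G(i) ∩ H_l|`` is assigned a hypergeometric
over-representation p-value and, using the same label-shuffled trajectories
that calibrated the biclustering, a permutation z-score; the average z̄ over
an iteration interval and a pathway collection gets a permutation p-value of
its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biclustering import BiclusterTrajectory
from .genotype_io import GeneAnnotation, PathwayCollection


@dataclass
class EnrichmentResult:
    """Per-(iteration, pathway) gene counts with significance summaries."""

    table: pd.DataFrame  # iteration, pathway, kappa, p, z
    z_bar: float
    p_z_bar: float | None
    interval: tuple[int, int]


def retained_genes(K_i: set, annotation: GeneAnnotation) -> set:
    """Genes with strictly more than half their annotated combos surviving."""
    K_i = set(K_i)
    retained = set()
    for gene, combos in annotation.gene_to_combos.items():
        if not combos:
            continue
        if len(combos & K_i) > 0.5 * len(combos):
            retained.add(gene)
    return retained


def overrepresentation_p(
    k: int, n_selected: int, n_pathway: int, n_universe: int
) -> float:
    """Upper hypergeometric tail P[X >= k] of the pathway/selection overlap."""
    if not (0 <= k <= min(n_selected, n_pathway) <= n_universe):
        raise ValueError(
            f"inconsistent counts: k={k}, selected={n_selected}, "
            f"pathway={n_pathway}, universe={n_universe}"
        )
    return float(stats.hypergeom.sf(k - 1, n_universe, n_pathway, n_selected))


def _gene_combo_matrix(
    annotation: GeneAnnotation, combo_ids: np.ndarray
) -> tuple[list, np.ndarray, np.ndarray]:
    """Genes × combos membership matrix plus per-gene annotated totals."""
    idx = pd.Index(combo_ids)
    genes = sorted(annotation.gene_to_combos)
    mat = np.zeros((len(genes), len(combo_ids)), dtype=bool)
    totals = np.zeros(len(genes))
    for g, gene in enumerate(genes):
        combos = annotation.gene_to_combos[gene]
        pos = idx.get_indexer(list(combos))
        pos = pos[pos >= 0]
        mat[g, pos] = True
        totals[g] = len(combos)
    return genes, mat, totals


def permutation_enrichment(
    traj: BiclusterTrajectory,
    annotation: GeneAnnotation,
    pathways: PathwayCollection,
    interval: tuple[int, int],
    stride: int = 1,
    pathway_subset: list[str] | None = None,
) -> EnrichmentResult:
    """Pathway gene-count enrichment across an iteration interval.

    Null gene counts reuse the trajectory's label-shuffled trials (the same
    null that calibrated the trace), so the trajectory must have been run
    with ``record_null_cols=True``.
    """
    lo, hi = interval
    if not (0 <= lo <= hi < traj.n_iterations):
        raise ValueError(f"interval {interval} outside trajectory")
    names = sorted(pathway_subset or pathways.pathways)
    genes, mat, totals = _gene_combo_matrix(annotation, traj.combo_ids)
    gene_index = pd.Index(genes)
    universe = sorted(set(genes) & pathways.universe)
    n_universe = len(universe)
    in_universe = gene_index.isin(universe)
    pw_mask = np.zeros((len(names), len(genes)), dtype=bool)
    for l, name in enumerate(names):
        pw_mask[l] = gene_index.isin(pathways.pathways[name] & set(universe))

    iterations = np.arange(lo, hi + 1, stride)

    def _kappas(col_removal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """kappa (iters × pathways) and selected-set sizes per iteration."""
        kappas = np.zeros((len(iterations), len(names)))
        n_sel = np.zeros(len(iterations), dtype=int)
        for a, i in enumerate(iterations):
            surviving = col_removal >= i
            counts = mat @ surviving.astype(float)
            retained = (counts > 0.5 * totals) & in_universe
            n_sel[a] = int(retained.sum())
            kappas[a] = pw_mask.astype(float) @ retained.astype(float)
        return kappas, n_sel

    kappa_data, n_sel = _kappas(traj.col_removal_iter)

    rows = []
    for a, i in enumerate(iterations):
        for l, name in enumerate(names):
            n_pw = int(pw_mask[l].sum())
            rows.append(
                {
                    "iteration": int(i),
                    "pathway": name,
                    "kappa": int(kappa_data[a, l]),
                    "p": overrepresentation_p(
                        int(kappa_data[a, l]), int(n_sel[a]), n_pw, n_universe
                    ),
                }
            )
    table = pd.DataFrame(rows)

    p_z_bar = None
    z_bar = np.nan
    if traj.null_col_removal is not None:
        T = traj.null_col_removal.shape[0]
        null_kappa = np.stack(
            [_kappas(traj.null_col_removal[t])[0] for t in range(T)]
        )  # (T, iters, pathways)
        mean = null_kappa.mean(axis=0)
        sd = null_kappa.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (kappa_data - mean) / sd, 0.0)
        table["z"] = z.reshape(-1)
        z_bar = float(z.mean())
        # leave-one-out z̄ for each null trial
        s1 = null_kappa.sum(axis=0)
        s2 = (null_kappa**2).sum(axis=0)
        z_bar_null = np.empty(T)
        for t in range(T):
            m_loo = (s1 - null_kappa[t]) / (T - 1)
            if T > 2:
                v_loo = (s2 - null_kappa[t] ** 2 - (T - 1) * m_loo**2) / (T - 2)
                s_loo = np.sqrt(np.maximum(v_loo, 0.0))
            else:
                s_loo = np.zeros_like(m_loo)
            with np.errstate(invalid="ignore", divide="ignore"):
                zt = np.where(s_loo > 0, (null_kappa[t] - m_loo) / s_loo, 0.0)
            z_bar_null[t] = zt.mean()
        p_z_bar = float((1 + (z_bar_null >= z_bar).sum()) / (1 + T))
    return EnrichmentResult(
        table=table, z_bar=z_bar, p_z_bar=p_z_bar, interval=(int(lo), int(hi))
    )
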