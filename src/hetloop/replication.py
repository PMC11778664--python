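"""Out-of-sample replication of a discovered bicluster.

A bicluster found in the training arm is summarized, at each iteration ``i``
of its trajectory, by the dominant principal component ``v(i)`` of the
retained case submatrix restricted to the combos also genotyped in the
replication arm.  Projecting every subject onto ``v(i)`` yields a scalar
bicluster score; the covariate-corrected AUC between case and control scores
measures how well the signature separates the groups, in the training arm
(``A(i)``) and the replication arm (``A'(i)``).  Replication significance of
the interval average of ``A'`` is assessed against a label-shuffled null in
the replication arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .covariates import StratumAssignment, residualize
from .genotype_io import ComboMatrix
from .biclustering import BiclusterTrajectory


@dataclass
class BiclusterComponent:
    """Dominant SNP-wise principal component of a bicluster submatrix.

    ``centers`` are the training-bicluster column means; they are reused when
    projecting replication subjects so no replication information leaks into
    the score definition.
    """

    v: np.ndarray
    centers: np.ndarray
    combo_ids: np.ndarray


@dataclass
class ReplicationResult:
    """Per-iteration replication AUCs and the interval-average summary."""

    iterations: np.ndarray
    auc_train: np.ndarray
    auc_repl: np.ndarray
    p_train: np.ndarray | None
    p_repl: np.ndarray | None
    interval: tuple[int, int]
    auc_repl_mean: float
    p_repl_mean: float | None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "iteration": self.iterations,
            "auc_train": self.auc_train,
            "auc_repl": self.auc_repl,
        }
        if self.p_train is not None:
            cols["p_train"] = self.p_train
        if self.p_repl is not None:
            cols["p_repl"] = self.p_repl
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# component and scores
# ---------------------------------------------------------------------------


def bicluster_component(
    D: ComboMatrix,
    rows: np.ndarray,
    combo_indices: np.ndarray,
    center_rows: np.ndarray | None = None,
) -> BiclusterComponent:
    """Top right-singular vector of the centered bicluster submatrix.

    Columns are centered by their means over ``center_rows`` (default: all
    rows of ``D``, i.e. the full training case array) so the component
    captures how the bicluster deviates from the cohort average; centering by
    the bicluster's own means would zero its mean projection exactly and
    leave the component unable to separate signature carriers from the rest.
    The sign is fixed so the mean projection of the bicluster rows is >= 0.
    """
    rows = np.asarray(rows)
    combo_indices = np.asarray(combo_indices)
    if len(rows) < 2:
        raise ValueError("need at least 2 bicluster rows")
    if len(combo_indices) < 1:
        raise ValueError("need at least 1 combo")
    base = D.values[:, combo_indices]
    if center_rows is None:
        center_rows = np.arange(base.shape[0])
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(base[center_rows], axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    sub = base[rows]
    sub = np.where(np.isnan(sub), col_means[None, :], sub)
    centered = sub - col_means
    if not centered.any():
        raise ValueError("bicluster submatrix is constant; no dominant direction")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if (centered @ v).mean() < 0:
        v = -v
    return BiclusterComponent(
        v=v, centers=col_means, combo_ids=D.combo_ids[combo_indices]
    )


def project_scores(cm: ComboMatrix, component: BiclusterComponent) -> np.ndarray:
    """Project subjects onto the component: u_j = sum_k (B_jk - c_k) v_k.

    Missing entries contribute 0.  The matrix must carry every combo in the
    component's support.
    """
    pos = pd.Index(cm.combo_ids).get_indexer(component.combo_ids)
    missing = component.combo_ids[pos < 0]
    if len(missing):
        raise ValueError(f"combo panel lacks component combos: {list(missing[:5])}")
    B = cm.values[:, pos]
    B = np.where(np.isnan(B), component.centers[None, :], B)
    return (B - component.centers) @ component.v


def corrected_auc(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    cov: pd.DataFrame | np.ndarray | None = None,
    selected: list[int] | None = None,
) -> float:
    """Covariate-corrected AUC: residualize-then-rank Mann-Whitney.

    Scores of cases and controls are residualized jointly on an intercept
    plus the selected covariates (rows of ``cov`` ordered [cases; controls]),
    then the AUC is the Mann-Whitney statistic over case/control pairs with
    ties counted 1/2.  Without covariates this is the classical rank AUC.
    """
    u = np.concatenate([np.asarray(case_scores, float), np.asarray(control_scores, float)])
    m = len(case_scores)
    n = len(control_scores)
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    if cov is not None and selected:
        if isinstance(cov, pd.DataFrame):
            cov = cov.to_numpy(dtype=float)
        u = residualize(u, cov, selected)
    ranks = rankdata(u)
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _auc_from_ranks(ranks: np.ndarray, case_mask: np.ndarray) -> float:
    m = int(case_mask.sum())
    n = len(ranks) - m
    return float((ranks[case_mask].sum() - m * (m + 1) / 2.0) / (m * n))


# ---------------------------------------------------------------------------
# replication driver
# ---------------------------------------------------------------------------


def _residual_ranks(
    scores: np.ndarray,
    cov: pd.DataFrame | np.ndarray | None,
    selected: list[int] | None,
) -> np.ndarray:
    u = np.asarray(scores, float)
    if cov is not None and selected:
        if isinstance(cov, pd.DataFrame):
            cov = cov.to_numpy(dtype=float)
        u = residualize(u, cov, selected)
    return rankdata(u)


def select_interval(
    traj: BiclusterTrajectory,
    p_train_auc: np.ndarray,
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Maximal contiguous run where both the trace p and the training-AUC p
    are significant."""
    if traj.p is None:
        raise ValueError("trajectory carries no per-iteration p-values")
    ok = (traj.p <= alpha) & (np.asarray(p_train_auc) <= alpha)
    if not ok.any():
        raise ValueError(f"no iteration significant at alpha={alpha}")
    best, cur_start, best_span = None, None, 0
    for i, flag in enumerate(np.append(ok, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_span:
                best_span = i - cur_start
                best = (cur_start, i - 1)
            cur_start = None
    return best


def replicate(
    traj: BiclusterTrajectory,
    D_train: ComboMatrix,
    X_train: ComboMatrix,
    D_repl: ComboMatrix,
    X_repl: ComboMatrix,
    cov_train: pd.DataFrame | np.ndarray | None = None,
    cov_repl: pd.DataFrame | np.ndarray | None = None,
    selected: list[int] | None = None,
    interval: tuple[int, int] | None = None,
    stride: int = 1,
    n_shuffles: int = 64,
    strata_repl: StratumAssignment | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> ReplicationResult:
    """Evaluate training and replication AUCs of the bicluster score.

    At each iteration in the evaluation grid the component ``v(i)`` is fit on
    the training bicluster restricted to the replication arm's combo panel,
    all subjects of both arms are projected, and covariate-corrected AUCs are
    computed.  Per-iteration p-values and the interval-average significance
    come from label shuffles (within strata when supplied) of each arm.
    """
    if not np.array_equal(D_repl.combo_ids, X_repl.combo_ids):
        raise ValueError("replication case/control combo panels must be aligned")
    repl_panel = pd.Index(D_repl.combo_ids)

    def _cov_rows(cov, D, X):
        if isinstance(cov, pd.DataFrame):
            ids = np.concatenate([D.subject_ids, X.subject_ids])
            return cov.loc[ids].to_numpy(dtype=float)
        return cov

    cov_train_all = _cov_rows(cov_train, D_train, X_train)
    cov_repl_all = _cov_rows(cov_repl, D_repl, X_repl)
    m_tr, n_tr = len(D_train.subject_ids), len(X_train.subject_ids)
    m_re, n_re = len(D_repl.subject_ids), len(X_repl.subject_ids)
    case_tr = np.zeros(m_tr + n_tr, bool)
    case_tr[:m_tr] = True
    case_re = np.zeros(m_re + n_re, bool)
    case_re[:m_re] = True

    # precompute label shuffles (shared across iterations)
    if strata_repl is None:
        strata_repl = StratumAssignment(labels=np.zeros(m_re + n_re, dtype=int))
    null_case_re = np.zeros((n_shuffles, m_re + n_re), dtype=bool)
    labels = strata_repl.labels
    for t in range(n_shuffles):
        trng = np.random.default_rng([seed, 3, t])
        for s in np.unique(labels):
            idx = np.flatnonzero(labels == s)
            k = int(case_re[idx].sum())
            null_case_re[t, trng.choice(idx, size=k, replace=False)] = True
    null_case_tr = np.zeros((n_shuffles, m_tr + n_tr), dtype=bool)
    for t in range(n_shuffles):
        trng = np.random.default_rng([seed, 4, t])
        null_case_tr[t, trng.choice(m_tr + n_tr, size=m_tr, replace=False)] = True

    def _evaluate(iterations: np.ndarray, with_nulls: bool):
        aucs_tr, aucs_re = [], []
        p_tr, p_re = [], []
        null_re_rows = []
        for i in iterations:
            rows = traj.retained_case_indices(i)
            combo_ids_i = traj.retained_combo_ids(i)
            in_panel = repl_panel.get_indexer(combo_ids_i) >= 0
            kprime = combo_ids_i[in_panel]
            train_pos = pd.Index(D_train.combo_ids).get_indexer(kprime)
            comp = bicluster_component(D_train, rows, train_pos)
            u_tr = np.concatenate(
                [project_scores(D_train, comp), project_scores(X_train, comp)]
            )
            u_re = np.concatenate(
                [project_scores(D_repl, comp), project_scores(X_repl, comp)]
            )
            r_tr = _residual_ranks(u_tr, cov_train_all, selected)
            r_re = _residual_ranks(u_re, cov_repl_all, selected)
            aucs_tr.append(_auc_from_ranks(r_tr, case_tr))
            aucs_re.append(_auc_from_ranks(r_re, case_re))
            if with_nulls:
                nt = np.array(
                    [_auc_from_ranks(r_tr, null_case_tr[t]) for t in range(n_shuffles)]
                )
                nr = np.array(
                    [_auc_from_ranks(r_re, null_case_re[t]) for t in range(n_shuffles)]
                )
                p_tr.append((1 + (nt >= aucs_tr[-1]).sum()) / (1 + n_shuffles))
                p_re.append((1 + (nr >= aucs_re[-1]).sum()) / (1 + n_shuffles))
                null_re_rows.append(nr)
        return (
            np.array(aucs_tr),
            np.array(aucs_re),
            np.array(p_tr) if with_nulls else None,
            np.array(p_re) if with_nulls else None,
            np.array(null_re_rows) if with_nulls else None,
        )

    max_iter = traj.n_iterations - 1
    if interval is None:
        if traj.p is None:
            raise ValueError("supply an interval or run discovery with a null first")
        cand = np.flatnonzero(traj.p <= alpha)
        cand = cand[traj.M[cand] >= 2]
        if len(cand) == 0:
            raise ValueError(f"no iteration significant at alpha={alpha}")
        a_tr, _, p_a_tr, _, _ = _evaluate(cand, True)
        p_full = np.ones(traj.n_iterations)
        p_full[cand] = p_a_tr
        interval = select_interval(traj, p_full, alpha)
    lo, hi = interval
    if not (0 <= lo <= hi <= max_iter):
        raise ValueError(f"interval {interval} outside trajectory [0, {max_iter}]")

    grid = np.arange(lo, hi + 1, stride)
    grid = grid[traj.M[grid] >= 2]
    aucs_tr, aucs_re, p_tr, p_re, null_re = _evaluate(grid, n_shuffles > 0)

    auc_mean = float(aucs_re.mean())
    p_mean = None
    if n_shuffles > 0:
        null_means = null_re.mean(axis=0)  # per shuffle, averaged over grid
        p_mean = float((1 + (null_means >= auc_mean).sum()) / (1 + n_shuffles))
    return ReplicationResult(
        iterations=grid,
        auc_train=aucs_tr,
        auc_repl=aucs_re,
        p_train=p_tr,
        p_repl=p_re,
        interval=(int(lo), int(hi)),
        auc_repl_mean=auc_mean,
        p_repl_mean=p_mean,
    )


def replication_significance(
    result: ReplicationResult,
) -> float:
    """Interval-average replication p-value recorded on the result."""
    if result.p_repl_mean is None:
        raise ValueError("result was computed without null shuffles")
    return result.p_repl_mean


def degrade_overlap(
    cm: ComboMatrix,
    train_panel: set,
    target_overlap: float,
    seed: int = 0,
) -> ComboMatrix:
    """Randomly drop SNPs (all 3 combos) until the overlap coefficient with
    the training panel first reaches <= target.

    Removal is uniform over the SNPs shared with the training panel: dropping
    a SNP outside the intersection shrinks numerator's complement and the
    min-denominator together and therefore cannot reduce the coefficient.
    """
    from .genotype_io import restrict_to_panel, snp_overlap_coefficient

    panel = list(dict.fromkeys(cm.snp_ids))  # unique, order-preserving
    current = snp_overlap_coefficient(train_panel, panel)
    if target_overlap > current + 1e-12:
        raise ValueError(
            f"target overlap {target_overlap} exceeds current {current:.4f}"
        )
    rng = np.random.default_rng(seed)
    shared = [s for s in panel if s in train_panel]
    keep = set(panel)
    order = list(rng.permutation(shared))
    while (
        len(keep) > 1
        and order
        and snp_overlap_coefficient(train_panel, keep) > target_overlap
    ):
        keep.discard(order.pop())
    if snp_overlap_coefficient(train_panel, keep) > target_overlap:
        raise ValueError("cannot reach target overlap by dropping SNPs")
    return restrict_to_panel(cm, keep)
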