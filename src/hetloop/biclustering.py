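"""The half-loop biclustering algorithm and its permutation null.

The algorithm searches a case/control study for a *disease-specific*
bicluster: a subset of cases sharing a pattern over a subset of
allele-combinations that is not similarly present among controls.  At each
iteration it scores every retained case ``j`` and combination ``k`` by the
differential agreement

    Q(j, k) = [D<-D](j, k) - [D<-X](j, k),

the (weighted) fraction of *other* cases whose +/-1 state at ``k`` agrees with
case ``j``'s, minus the corresponding fraction of controls.  Row and column
sums of ``Q`` rank cases and combinations; the fraction ``gamma`` with the
lowest scores is removed and the process repeats until the case set is
exhausted.  The per-iteration size-normalized trace of ``Q`` is compared with
the traces of label-shuffled trials (shuffled within covariate strata, run on
the identical elimination schedule) to produce per-iteration z-scores and an
overall permutation p-value for the existence of a bicluster.

Covariate correction reweights the agreement fractions with Gaussian
covariate-proximity kernels so that differential expression contributed by
structures unevenly distributed in covariate space is suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import KernelWeights, StratumAssignment, kernel_weights
from .genotype_io import ComboMatrix

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.5**8  # fraction of rows/columns removed per iteration


@dataclass
class HalfLoopConfig:
    """Parameters of a half-loop run.

    gamma: fraction of remaining rows and columns removed per iteration.
    n_shuffles: number of label-shuffled null trials.
    seed: master seed; per-shuffle generators are seeded ``[seed, t]``.
    correct_covariates: reweight scores by covariate proximity and shuffle
        labels within covariate strata.
    selected_covariates: covariate column indices used by the correction.
    bandwidth_scale: kernel bandwidth in units of the median pairwise
        covariate distance.
    n_strata: strata for constrained shuffling (default ``n_subjects // 500``,
        at least 1).
    """

    gamma: float = DEFAULT_GAMMA
    n_shuffles: int = 128
    seed: int = 0
    correct_covariates: bool = False
    selected_covariates: list[int] | None = None
    bandwidth_scale: float = 1.0
    n_strata: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class DifferentialScores:
    """Case x combo differential-agreement scores and their aggregates."""

    Q: np.ndarray
    q_row: np.ndarray
    q_col: np.ndarray
    trace: float
    trace_norm: float


@dataclass
class BiclusterTrajectory:
    """Record of a half-loop run (plus, optionally, its null ensemble).

    ``row_removal_iter[j]`` is the iteration at which case ``j`` was removed
    (rows surviving past the last scored iteration carry ``n_iterations``);
    likewise for columns.  ``J(i)`` / ``K(i)`` are recovered as the rows /
    columns with removal iteration >= ``i``.
    """

    case_ids: np.ndarray
    combo_ids: np.ndarray
    M: np.ndarray
    N: np.ndarray
    trace: np.ndarray
    trace_norm: np.ndarray
    row_removal_iter: np.ndarray
    col_removal_iter: np.ndarray
    schedule_rows: np.ndarray
    schedule_cols: np.ndarray
    config: HalfLoopConfig
    null_traces: np.ndarray | None = None
    null_col_removal: np.ndarray | None = None
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    p_overall: float | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.M)

    def retained_case_indices(self, iteration: int) -> np.ndarray:
        self._check_iteration(iteration)
        return np.flatnonzero(self.row_removal_iter >= iteration)

    def retained_combo_indices(self, iteration: int) -> np.ndarray:
        self._check_iteration(iteration)
        return np.flatnonzero(self.col_removal_iter >= iteration)

    def retained_case_ids(self, iteration: int) -> np.ndarray:
        return self.case_ids[self.retained_case_indices(iteration)]

    def retained_combo_ids(self, iteration: int) -> np.ndarray:
        return self.combo_ids[self.retained_combo_indices(iteration)]

    def peak_z_iteration(self) -> int:
        if self.z is None:
            raise ValueError("trajectory has no z-scores; run the null first")
        return int(np.argmax(self.z))

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "iteration": np.arange(self.n_iterations),
            "M": self.M,
            "N": self.N,
            "trace": self.trace,
            "trace_norm": self.trace_norm,
        }
        if self.z is not None:
            cols["z"] = self.z
            cols["p"] = self.p
        return pd.DataFrame(cols)

    def _check_iteration(self, iteration: int) -> None:
        if not 0 <= iteration < self.n_iterations:
            raise IndexError(
                f"iteration {iteration} outside trajectory [0, {self.n_iterations})"
            )


# ---------------------------------------------------------------------------
# differential scores
# ---------------------------------------------------------------------------


def _scores_general(
    Dv: np.ndarray,
    Xv: np.ndarray,
    Wdd: np.ndarray,
    Wdx: np.ndarray,
) -> DifferentialScores:
    """Masked, weighted differential scores.

    ``Wdd`` is an unnormalized case-to-case kernel with zero diagonal (self
    excluded); ``Wdx`` an unnormalized case-to-control kernel.  Missing
    entries are excluded from numerator and denominator; a (j, k) with no
    usable reference (or a missing focal entry) scores 0.
    """
    M, N = Dv.shape
    obs_d = np.isfinite(Dv)
    obs_x = np.isfinite(Xv)
    Ad = np.where(obs_d, Dv, 0.0)
    Ax = np.where(obs_x, Xv, 0.0)

    num_dd = Wdd @ Ad  # sum of weighted reference states
    den_dd = Wdd @ obs_d.astype(float)
    num_dx = Wdx @ Ax
    den_dx = Wdx @ obs_x.astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_dd = 0.5 * (1.0 + Ad * num_dd / den_dd)
        frac_dx = 0.5 * (1.0 + Ad * num_dx / den_dx)
    usable = obs_d & (den_dd > 0) & (den_dx > 0)
    Q = np.where(usable, frac_dd - frac_dx, 0.0)
    q_row = Q.sum(axis=1)
    q_col = Q.sum(axis=0)
    trace = float(Q.sum())
    return DifferentialScores(Q, q_row, q_col, trace, trace / (M * N))


def differential_scores(
    D: ComboMatrix | np.ndarray,
    X: ComboMatrix | np.ndarray,
    weights: KernelWeights | tuple[np.ndarray, np.ndarray] | None = None,
) -> DifferentialScores:
    """Case-minus-control differential agreement scores Q(j, k).

    ``weights`` may be ``None`` (uniform), a pair of raw kernel matrices
    ``(case x case, case x control)``, or a :class:`KernelWeights` provider
    built on the concatenated ``[cases; controls]`` covariates.
    """
    Dv = D.values if isinstance(D, ComboMatrix) else np.asarray(D, float)
    Xv = X.values if isinstance(X, ComboMatrix) else np.asarray(X, float)
    M, N = Dv.shape
    MX = Xv.shape[0]
    if M < 2:
        raise ValueError("need at least 2 cases (self-exclusion empties references)")
    if MX < 1:
        raise ValueError("need at least 1 control")
    if Xv.shape[1] != N:
        raise ValueError("case and control combo panels must be identical")
    if weights is None:
        Wdd = np.ones((M, M))
        Wdx = np.ones((M, MX))
    elif isinstance(weights, KernelWeights):
        cases = np.arange(M)
        controls = np.arange(M, M + MX)
        Wdd = weights.raw_kernel(cases, cases)
        Wdx = weights.raw_kernel(cases, controls)
    else:
        Wdd, Wdx = (np.asarray(w, float) for w in weights)
    Wdd = Wdd.copy()
    np.fill_diagonal(Wdd, 0.0)
    return _scores_general(Dv, Xv, Wdd, Wdx)


# ---------------------------------------------------------------------------
# the half-loop iteration
# ---------------------------------------------------------------------------


def _removal_count(gamma: float, size: int) -> int:
    """max(1, round(gamma * size)), half rounded up, capped at size."""
    return min(size, max(1, int(np.floor(gamma * size + 0.5))))


def _halfloop_pass(
    Dv: np.ndarray,
    Xv: np.ndarray,
    gamma: float,
    schedule: tuple[np.ndarray, np.ndarray] | None = None,
    Kdd: np.ndarray | None = None,
    Wdx_norm: np.ndarray | None = None,
) -> dict:
    """Run one half-loop elimination pass and record the trajectory.

    ``Kdd`` (raw case kernel, diagonal ignored) and ``Wdx_norm``
    (row-normalized case-to-control weights) switch on covariate correction.
    Missing data falls back to the fully general masked scorer.
    """
    M0, N0 = Dv.shape
    MX = Xv.shape[0]
    has_nan = bool(np.isnan(Dv).any() or np.isnan(Xv).any())
    weighted = Kdd is not None

    row_removal = np.full(M0, -1, dtype=np.int32)
    col_removal = np.full(N0, -1, dtype=np.int32)
    act_r = np.arange(M0)
    act_c = np.arange(N0)

    Dact = np.array(Dv, dtype=float)
    traces: list[float] = []
    traces_norm: list[float] = []
    Ms: list[int] = []
    Ns: list[int] = []
    sched_r: list[int] = []
    sched_c: list[int] = []

    if weighted:
        Kact = np.array(Kdd, dtype=float)
        np.fill_diagonal(Kact, 0.0)
        if not has_nan:
            VX = Wdx_norm @ Xv  # controls never change; precompute once
    elif not has_nan:
        S = Dact.sum(axis=0)
        T = Xv.sum(axis=0)
    if has_nan:
        Xact = np.array(Xv, dtype=float)
        if weighted:
            Wdx_act = np.array(Wdx_norm, dtype=float)

    i = 0
    while len(act_r) >= 2 and len(act_c) >= 1:
        M, N = len(act_r), len(act_c)
        if has_nan:
            Wdd_i = Kact if weighted else np.ones((M, M))
            Wdx_i = Wdx_act if weighted else np.ones((M, MX))
            if not weighted:
                Wdd_i = Wdd_i.copy()
                np.fill_diagonal(Wdd_i, 0.0)
            sc = _scores_general(Dact, Xact, Wdd_i, Wdx_i)
            q_row, q_col, trace = sc.q_row, sc.q_col, sc.trace
        elif weighted:
            W = Kact / Kact.sum(axis=1, keepdims=True)
            Q = Dact * ((W @ Dact) - VX) / 2.0
            q_row = Q.sum(axis=1)
            q_col = Q.sum(axis=0)
            trace = float(Q.sum())
        else:
            # uniform weights, complete data: everything reduces to column
            # sums.  Scores are ranked on the scale 2(M-1)·MX·Q, where they
            # are exact integers for ±1 data — ties then break identically to
            # exact rational arithmetic.
            G = MX * S - (M - 1) * T
            q_row = Dact @ G - N * MX
            q_col = S * G - M * MX
            scale = 2.0 * (M - 1) * MX
            trace = float((S @ G - M * N * MX) / scale)
            q_row = q_row / scale
            q_col = q_col / scale

        Ms.append(M)
        Ns.append(N)
        traces.append(trace)
        traces_norm.append(trace / (M * N))

        if schedule is not None:
            n_r = int(schedule[0][i])
            n_c = int(schedule[1][i])
        else:
            n_r = _removal_count(gamma, M)
            n_c = _removal_count(gamma, N)
        sched_r.append(n_r)
        sched_c.append(n_c)

        # lowest scores removed; stable sort breaks ties by original index
        rem_r = np.argsort(q_row, kind="stable")[:n_r]
        rem_c = np.argsort(q_col, kind="stable")[:n_c]
        row_removal[act_r[rem_r]] = i
        col_removal[act_c[rem_c]] = i

        keep_r = np.ones(M, dtype=bool)
        keep_r[rem_r] = False
        keep_c = np.ones(N, dtype=bool)
        keep_c[rem_c] = False

        if not has_nan and not weighted:
            S = S - Dact[rem_r].sum(axis=0)
            S = S[keep_c]
            T = T[keep_c]
        Dact = Dact[np.ix_(keep_r, keep_c)]
        if weighted:
            Kact = Kact[np.ix_(keep_r, keep_r)]
            if has_nan:
                Wdx_act = Wdx_act[keep_r]
            else:
                VX = VX[np.ix_(keep_r, keep_c)]
        if has_nan:
            Xact = Xact[:, keep_c]
        act_r = act_r[keep_r]
        act_c = act_c[keep_c]
        i += 1

    row_removal[row_removal < 0] = i
    col_removal[col_removal < 0] = i
    return {
        "M": np.array(Ms, dtype=np.int64),
        "N": np.array(Ns, dtype=np.int64),
        "trace": np.array(traces),
        "trace_norm": np.array(traces_norm),
        "row_removal": row_removal,
        "col_removal": col_removal,
        "schedule_rows": np.array(sched_r, dtype=np.int64),
        "schedule_cols": np.array(sched_c, dtype=np.int64),
    }


def _align_cov(
    cov: pd.DataFrame | np.ndarray | None,
    D: ComboMatrix,
    X: ComboMatrix,
) -> np.ndarray | None:
    """Covariate rows for [cases; controls], aligned by subject_id when the
    table is indexed by it."""
    if cov is None:
        return None
    if isinstance(cov, pd.DataFrame):
        ids = np.concatenate([D.subject_ids, X.subject_ids])
        return cov.loc[ids].to_numpy(dtype=float)
    return np.asarray(cov, dtype=float)


def _build_kernels(
    cov_all: np.ndarray | None,
    n_cases: int,
    n_controls: int,
    cfg: HalfLoopConfig,
) -> tuple[np.ndarray | None, np.ndarray | None, KernelWeights | None]:
    if not cfg.correct_covariates or cov_all is None:
        return None, None, None
    kw = kernel_weights(cov_all, cfg.selected_covariates, cfg.bandwidth_scale)
    cases = np.arange(n_cases)
    controls = np.arange(n_cases, n_cases + n_controls)
    Kdd = kw.raw_kernel(cases, cases)
    Wdx = kw.weights(cases, controls)
    return Kdd, Wdx, kw


def half_loop(
    D: ComboMatrix,
    X: ComboMatrix,
    cov: pd.DataFrame | np.ndarray | None = None,
    cfg: HalfLoopConfig | None = None,
    schedule: tuple[np.ndarray, np.ndarray] | None = None,
) -> BiclusterTrajectory:
    """Run the half-loop elimination on the observed data (no null trials).

    ``cov`` is a covariate table (DataFrame indexed by subject_id, or an
    array with rows ordered [cases; controls]); it is only consulted when
    ``cfg.correct_covariates`` is set.
    """
    cfg = cfg or HalfLoopConfig()
    if not np.array_equal(D.combo_ids, X.combo_ids):
        raise ValueError("case and control combo panels must be aligned")
    cov_all = _align_cov(cov, D, X)
    Kdd, Wdx, _ = _build_kernels(cov_all, len(D.subject_ids), len(X.subject_ids), cfg)
    rec = _halfloop_pass(D.values, X.values, cfg.gamma, schedule, Kdd, Wdx)
    return BiclusterTrajectory(
        case_ids=np.asarray(D.subject_ids).copy(),
        combo_ids=D.combo_ids.copy(),
        M=rec["M"],
        N=rec["N"],
        trace=rec["trace"],
        trace_norm=rec["trace_norm"],
        row_removal_iter=rec["row_removal"],
        col_removal_iter=rec["col_removal"],
        schedule_rows=rec["schedule_rows"],
        schedule_cols=rec["schedule_cols"],
        config=cfg,
    )


def control_search(
    D: ComboMatrix,
    X: ComboMatrix,
    cov: pd.DataFrame | np.ndarray | None = None,
    cfg: HalfLoopConfig | None = None,
) -> BiclusterTrajectory:
    """Search for control-side biclusters: the half-loop with roles swapped."""
    if cov is not None and not isinstance(cov, pd.DataFrame):
        cov = np.asarray(cov, dtype=float)
        n_d = len(D.subject_ids)
        cov = np.vstack([cov[n_d:], cov[:n_d]])
    return half_loop(X, D, cov, cfg)


def shuffled_null(
    D: ComboMatrix,
    X: ComboMatrix,
    cov: pd.DataFrame | np.ndarray | None,
    strata: StratumAssignment,
    cfg: HalfLoopConfig,
    schedule: tuple[np.ndarray, np.ndarray],
    record_col_removal: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Label-shuffled null ensemble of trace trajectories.

    Case/control labels are permuted within each covariate stratum (per-
    stratum counts preserved), D and X rebuilt, and the half-loop rerun on
    the supplied elimination schedule.  Returns the ``n_shuffles x n_iter``
    trace_norm ensemble and, optionally, per-trial combo removal iterations
    (used by the enrichment stage's null gene counts).
    """
    M0 = len(D.subject_ids)
    MX0 = len(X.subject_ids)
    n = M0 + MX0
    labels = np.asarray(strata.labels)
    if len(labels) != n:
        raise ValueError("strata must cover all subjects (cases then controls)")
    pool = np.vstack([D.values, X.values])
    is_case = np.zeros(n, dtype=bool)
    is_case[:M0] = True

    cov_all = _align_cov(cov, D, X)
    use_kernel = cfg.correct_covariates and cov_all is not None
    if use_kernel:
        kw = kernel_weights(cov_all, cfg.selected_covariates, cfg.bandwidth_scale)
        K_all = kw.raw_kernel(np.arange(n), np.arange(n))

    for s in range(int(labels.max()) + 1):
        in_s = labels == s
        ncs = int(is_case[in_s].sum())
        if ncs == 0 or ncs == in_s.sum():
            logger.info(
                "stratum %d has only %s; its labels are fixed under shuffling",
                s,
                "cases" if ncs else "controls",
            )

    n_iter = len(schedule[0])
    traces = np.empty((cfg.n_shuffles, n_iter))
    col_removal = (
        np.empty((cfg.n_shuffles, pool.shape[1]), dtype=np.int32)
        if record_col_removal
        else None
    )
    for t in range(cfg.n_shuffles):
        rng = np.random.default_rng([cfg.seed, t])
        perm_case = np.zeros(n, dtype=bool)
        for s in np.unique(labels):
            idx = np.flatnonzero(labels == s)
            k = int(is_case[idx].sum())
            chosen = rng.choice(idx, size=k, replace=False)
            perm_case[chosen] = True
        case_idx = np.flatnonzero(perm_case)
        ctrl_idx = np.flatnonzero(~perm_case)
        Dv = pool[case_idx]
        Xv = pool[ctrl_idx]
        if use_kernel:
            Kdd = K_all[np.ix_(case_idx, case_idx)].copy()
            Wdx = K_all[np.ix_(case_idx, ctrl_idx)]
            Wdx = Wdx / Wdx.sum(axis=1, keepdims=True)
        else:
            Kdd = Wdx = None
        rec = _halfloop_pass(Dv, Xv, cfg.gamma, schedule, Kdd, Wdx)
        traces[t] = rec["trace_norm"]
        if record_col_removal:
            col_removal[t] = rec["col_removal"]
    return traces, col_removal


def trajectory_significance(
    data_trace: np.ndarray,
    null_traces: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-iteration z and p plus the overall max-z permutation p-value.

    ``z(i)`` standardizes the data trace against the null ensemble at
    iteration ``i`` (zero when the null spread vanishes); ``p(i)`` is the
    add-one upper-tail count.  The overall p compares the data's maximum z
    against the null trials' maxima, each null z-scored leave-one-out against
    the remaining trials.
    """
    data = np.asarray(data_trace, dtype=float)
    nulls = np.asarray(null_traces, dtype=float)
    if nulls.ndim != 2 or nulls.shape[1] != len(data):
        raise ValueError(
            f"null trace length {nulls.shape} does not match data ({len(data)})"
        )
    T = nulls.shape[0]
    if T < 2:
        raise ValueError("need at least 2 null traces")
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (data - mean) / sd, 0.0)
    p = (1.0 + (nulls >= data[None, :]).sum(axis=0)) / (1.0 + T)

    # leave-one-out z for each null trial
    s1 = nulls.sum(axis=0)
    s2 = (nulls**2).sum(axis=0)
    mean_loo = (s1[None, :] - nulls) / (T - 1)
    if T > 2:
        var_loo = (s2[None, :] - nulls**2 - (T - 1) * mean_loo**2) / (T - 2)
        var_loo = np.maximum(var_loo, 0.0)
        sd_loo = np.sqrt(var_loo)
    else:
        sd_loo = np.zeros_like(nulls)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_null = np.where(sd_loo > 0, (nulls - mean_loo) / sd_loo, 0.0)
    stat_data = float(z.max())
    stat_null = z_null.max(axis=1)
    p_overall = (1.0 + float((stat_null >= stat_data).sum())) / (1.0 + T)
    return z, p, p_overall


def run_discovery(
    D: ComboMatrix,
    X: ComboMatrix,
    cov: pd.DataFrame | np.ndarray | None = None,
    cfg: HalfLoopConfig | None = None,
    strata: StratumAssignment | None = None,
    record_null_cols: bool = False,
) -> BiclusterTrajectory:
    """Full discovery: data pass, stratified null ensemble, significance."""
    cfg = cfg or HalfLoopConfig()
    traj = half_loop(D, X, cov, cfg)
    if strata is None:
        cov_all = _align_cov(cov, D, X)
        n = len(D.subject_ids) + len(X.subject_ids)
        if cfg.correct_covariates and cov_all is not None:
            from .covariates import build_strata

            strata = build_strata(
                cov_all, cfg.selected_covariates, cfg.n_strata, seed=cfg.seed
            )
        else:
            n_strata = cfg.n_strata or 1
            strata = StratumAssignment(labels=np.zeros(n, dtype=int))
            if n_strata > 1 and cov is not None:
                from .covariates import build_strata

                strata = build_strata(
                    _align_cov(cov, D, X), cfg.selected_covariates, n_strata, cfg.seed
                )
    nulls, null_cols = shuffled_null(
        D,
        X,
        cov,
        strata,
        cfg,
        (traj.schedule_rows, traj.schedule_cols),
        record_col_removal=record_null_cols,
    )
    z, p, p_overall = trajectory_significance(traj.trace_norm, nulls)
    traj.null_traces = nulls
    traj.null_col_removal = null_cols
    traj.z = z
    traj.p = p
    traj.p_overall = p_overall
    return traj


# ---------------------------------------------------------------------------
# trajectory interrogation
# ---------------------------------------------------------------------------


def label_enrichment_trajectory(
    traj: BiclusterTrajectory,
    label: np.ndarray,
) -> pd.DataFrame:
    """Per-iteration label ratio and hypergeometric enrichment tail.

    ``label`` is a boolean (or 0/1) vector over the trajectory's cases,
    e.g. BDI membership.  At each iteration the ratio of label-positive to
    label-negative retained cases is reported together with the upper
    hypergeometric tail of observing at least that many positives when
    drawing ``|J(i)|`` cases from the iteration-0 composition.
    """
    lab = np.asarray(label).astype(bool)
    if len(lab) != len(traj.case_ids):
        raise ValueError("label must be defined for every case")
    M0 = len(lab)
    K0 = int(lab.sum())
    rows = []
    for i in range(traj.n_iterations):
        idx = traj.retained_case_indices(i)
        m = len(idx)
        pos = int(lab[idx].sum())
        neg = m - pos
        ratio = pos / neg if neg else np.inf
        p = float(stats.hypergeom.sf(pos - 1, M0, K0, m))
        rows.append(
            {
                "iteration": i,
                "n_retained": m,
                "n_positive": pos,
                "ratio": ratio,
                "p": p,
                "minus_log10_p": -np.log10(max(p, np.finfo(float).tiny)),
            }
        )
    return pd.DataFrame(rows)


def scramble_bicluster(
    cm: ComboMatrix,
    rows: Sequence[int],
    cols: Sequence[int],
    seed: int = 0,
) -> ComboMatrix:
    """Destroy a bicluster by permuting each selected column within the
    selected rows (independently per column; column sums preserved)."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    values = cm.values.copy()
    rng = np.random.default_rng(seed)
    for c in cols:
        perm = rng.permutation(len(rows))
        values[rows, c] = values[rows[perm], c]
    return ComboMatrix(cm.subject_ids.copy(), cm.combos.copy(), values)
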