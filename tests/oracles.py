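"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and no shared code with the
package's vectorized implementations, so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def brute_differential(D, X, Wdd=None, Wdx=None):
    """Q(j,k), row/col scores and trace by explicit double loops.

    Agreement means equal +/-1 state; self excluded from the case reference;
    missing entries excluded from numerator and denominator; weights
    renormalized over the usable reference set.
    """
    D = np.asarray(D, float)
    X = np.asarray(X, float)
    M, N = D.shape
    MX = X.shape[0]
    Q = np.zeros((M, N))
    for j in range(M):
        for k in range(N):
            if not np.isfinite(D[j, k]):
                continue
            num = den = 0.0
            for jp in range(M):
                if jp == j or not np.isfinite(D[jp, k]):
                    continue
                w = 1.0 if Wdd is None else Wdd[j, jp]
                num += w * (1.0 if D[jp, k] == D[j, k] else 0.0)
                den += w
            if den <= 0:
                continue
            f_dd = num / den
            num = den = 0.0
            for x in range(MX):
                if not np.isfinite(X[x, k]):
                    continue
                w = 1.0 if Wdx is None else Wdx[j, x]
                num += w * (1.0 if X[x, k] == D[j, k] else 0.0)
                den += w
            if den <= 0:
                continue
            Q[j, k] = f_dd - num / den
    q_row = Q.sum(axis=1)
    q_col = Q.sum(axis=0)
    return Q, q_row, q_col, Q.sum()


def brute_removal_count(gamma, size):
    return min(size, max(1, int(math.floor(gamma * size + 0.5))))


def _brute_differential_exact(D, X):
    """Q as exact Fractions (uniform weights, complete +/-1 data)."""
    from fractions import Fraction

    M, N = D.shape
    MX = X.shape[0]
    Q = [[Fraction(0)] * N for _ in range(M)]
    for j in range(M):
        for k in range(N):
            agree_d = sum(1 for jp in range(M) if jp != j and D[jp, k] == D[j, k])
            agree_x = sum(1 for x in range(MX) if X[x, k] == D[j, k])
            Q[j][k] = Fraction(agree_d, M - 1) - Fraction(agree_x, MX)
    q_row = [sum(Q[j]) for j in range(M)]
    q_col = [sum(Q[j][k] for j in range(M)) for k in range(N)]
    trace = sum(q_row)
    return q_row, q_col, trace


def brute_half_loop(D, X, gamma):
    """Full elimination trajectory by explicit loops in exact arithmetic.

    Returns per-iteration lists of retained row indices, retained column
    indices and normalized traces (indices refer to the original matrices).
    """
    D = np.asarray(D, float)
    X = np.asarray(X, float)
    rows = list(range(D.shape[0]))
    cols = list(range(D.shape[1]))
    Js, Ks, traces = [], [], []
    while len(rows) >= 2 and len(cols) >= 1:
        Dsub = D[np.ix_(rows, cols)]
        Xsub = X[:, cols]
        q_row, q_col, trace = _brute_differential_exact(Dsub, Xsub)
        Js.append(list(rows))
        Ks.append(list(cols))
        traces.append(float(trace) / (len(rows) * len(cols)))
        n_r = brute_removal_count(gamma, len(rows))
        n_c = brute_removal_count(gamma, len(cols))
        row_order = sorted(range(len(rows)), key=lambda i: (q_row[i], i))
        col_order = sorted(range(len(cols)), key=lambda i: (q_col[i], i))
        dead_r = sorted(row_order[:n_r], reverse=True)
        dead_c = sorted(col_order[:n_c], reverse=True)
        for i in dead_r:
            rows.pop(i)
        for i in dead_c:
            cols.pop(i)
    return Js, Ks, traces


def brute_auc(case_scores, control_scores):
    """AUC by exhaustive pair counting with ties worth 1/2."""
    total = 0.0
    for u in case_scores:
        for v in control_scores:
            if u > v:
                total += 1.0
            elif u == v:
                total += 0.5
    return total / (len(case_scores) * len(control_scores))


def brute_hypergeom_tail(k, n_selected, n_pathway, n_universe):
    """P[|S ∩ P| >= k] by enumerating all size-n_selected subsets."""
    universe = range(n_universe)
    pathway = set(range(n_pathway))
    hits = total = 0
    for subset in itertools.combinations(universe, n_selected):
        total += 1
        if len(pathway & set(subset)) >= k:
            hits += 1
    return hits / total


def threshold_model_auc(rho, prevalence, ngrid=4001):
    """Exact AUC of a score correlating rho with liability, by integration."""
    t = norm.ppf(1 - prevalence)
    x = np.linspace(-8, 8, ngrid)
    p_case = norm.cdf((rho * x - t) / np.sqrt(1 - rho**2))
    f1 = norm.pdf(x) * p_case / prevalence
    f0 = norm.pdf(x) * (1 - p_case) / (1 - prevalence)
    F0 = np.cumsum(f0) * (x[1] - x[0])
    return float(np.trapezoid(F0 * f1, x))
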