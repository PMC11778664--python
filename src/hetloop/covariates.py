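"""Covariate handling for ancestry correction.

Four mechanisms, all operating on a table of continuous covariates (in
practice genome-wide principal components) aligned with the subjects of a
genotype dataset:

* forward likelihood-ratio selection of the covariates associated with
  case/control status,
* covariate-space stratification (k-means) used to constrain label shuffles,
* Gaussian kernel weights used to reweight the biclustering's
  differential-expression scores toward covariate-local comparisons, and
* least-squares residualization used by the covariate-corrected AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._glm import fit_logistic


def _as_matrix(cov: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(cov, pd.DataFrame):
        arr = cov.to_numpy(dtype=float)
    else:
        arr = np.asarray(cov, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


@dataclass
class StratumAssignment:
    """Subject -> stratum index partition used for constrained shuffles."""

    labels: np.ndarray  # stratum index per subject

    @property
    def n_strata(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def counts(self, case_mask: np.ndarray) -> pd.DataFrame:
        case_mask = np.asarray(case_mask, bool)
        rows = []
        for s in range(self.n_strata):
            in_s = self.labels == s
            rows.append(
                {
                    "stratum": s,
                    "n_cases": int((in_s & case_mask).sum()),
                    "n_controls": int((in_s & ~case_mask).sum()),
                }
            )
        return pd.DataFrame(rows)


def select_covariates(
    status: np.ndarray,
    cov: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
) -> list[int]:
    """Forward likelihood-ratio selection of status-associated covariates.

    Candidates are visited in column order; each is tested by a deviance
    likelihood-ratio chi-square (1 df) of ``status ~ selected + candidate``
    against ``status ~ selected`` and kept when significant at ``alpha``.
    """
    y = np.asarray(status)
    if y.dtype.kind in "US" or y.dtype == object:
        y = (y == "case").astype(float)
    y = y.astype(float)
    X = _as_matrix(cov)
    if X.shape[0] != len(y):
        raise ValueError("covariate rows must match subjects")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")

    selected: list[int] = []
    ones = np.ones((len(y), 1))
    for c in range(X.shape[1]):
        base = np.hstack([ones] + [X[:, [j]] for j in selected])
        full = np.hstack([base, X[:, [c]]])
        ll0 = fit_logistic(base, y).loglik
        ll1 = fit_logistic(full, y).loglik
        lr = max(0.0, 2.0 * (ll1 - ll0))
        p = stats.chi2.sf(lr, df=1)
        if p < alpha:
            selected.append(c)
    return selected


def build_strata(
    cov: pd.DataFrame | np.ndarray,
    selected: list[int] | None,
    n_strata: int | None = None,
    seed: int = 0,
) -> StratumAssignment:
    """Partition subjects into covariate-space strata via seeded k-means.

    Default ``n_strata = max(1, n_subjects // 500)``.  With no selected
    covariates (or a single stratum) all subjects share one stratum, which
    reduces constrained shuffling to plain label shuffling.
    """
    X = _as_matrix(cov)
    n = X.shape[0]
    if n_strata is None:
        n_strata = max(1, n // 500)
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    if n_strata > n:
        raise ValueError(f"n_strata={n_strata} exceeds {n} subjects")
    if not selected or n_strata == 1:
        return StratumAssignment(labels=np.zeros(n, dtype=int))
    Xs = X[:, selected]
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - Xs.mean(axis=0)) / sd
    km = KMeans(n_clusters=n_strata, n_init=10, random_state=seed)
    labels = km.fit_predict(Xs)
    return StratumAssignment(labels=labels.astype(int))


class KernelWeights:
    """Gaussian covariate-proximity weights.

    For a focal subject ``j`` and a reference set ``S`` the weight of
    ``s ∈ S`` is proportional to ``exp(-||c_j - c_s||² / (2h²))`` on the
    selected covariate columns, normalized to sum 1 over ``S``.  The
    bandwidth is ``h = bandwidth_scale × median pairwise distance`` among all
    subjects.  An infinite bandwidth (or no selected covariates) yields
    uniform weights.
    """

    def __init__(
        self,
        cov: pd.DataFrame | np.ndarray,
        selected: list[int] | None,
        bandwidth_scale: float = 1.0,
        max_pairs_subjects: int = 2000,
        seed: int = 0,
    ):
        if bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be positive")
        X = _as_matrix(cov)
        self.uniform = not selected or np.isinf(bandwidth_scale)
        self.n = X.shape[0]
        if self.uniform:
            self.X = None
            self.h = np.inf
            return
        self.X = np.ascontiguousarray(X[:, selected])
        n = self.X.shape[0]
        if n > max_pairs_subjects:
            rng = np.random.default_rng(seed)
            sub = self.X[rng.choice(n, max_pairs_subjects, replace=False)]
        else:
            sub = self.X
        from scipy.spatial.distance import pdist

        d = pdist(sub)
        med = float(np.median(d)) if len(d) else 0.0
        if med <= 0:
            self.uniform = True  # all subjects coincide
            self.h = np.inf
        else:
            self.h = bandwidth_scale * med

    def raw_kernel(self, focal_idx: np.ndarray, ref_idx: np.ndarray) -> np.ndarray:
        """Unnormalized kernel matrix between focal and reference subjects."""
        focal_idx = np.asarray(focal_idx)
        ref_idx = np.asarray(ref_idx)
        if self.uniform:
            return np.ones((len(focal_idx), len(ref_idx)))
        A, B = self.X[focal_idx], self.X[ref_idx]
        d2 = (
            (A**2).sum(1)[:, None]
            + (B**2).sum(1)[None, :]
            - 2.0 * A @ B.T
        )
        np.maximum(d2, 0.0, out=d2)
        return np.exp(-d2 / (2.0 * self.h**2))

    def weights(self, focal_idx: np.ndarray, ref_idx: np.ndarray) -> np.ndarray:
        """Row-normalized weights of each focal subject over the reference set."""
        if len(np.asarray(ref_idx)) == 0:
            raise ValueError("reference set must be non-empty")
        K = self.raw_kernel(focal_idx, ref_idx)
        return K / K.sum(axis=1, keepdims=True)


def kernel_weights(
    cov: pd.DataFrame | np.ndarray,
    selected: list[int] | None,
    bandwidth_scale: float = 1.0,
) -> KernelWeights:
    """Construct a :class:`KernelWeights` pairwise weight provider."""
    return KernelWeights(cov, selected, bandwidth_scale)


def residualize(
    scores: np.ndarray,
    cov: pd.DataFrame | np.ndarray | None,
    selected: list[int] | None,
) -> np.ndarray:
    """OLS residuals of scores on an intercept plus the selected covariates.

    With no covariates selected the residuals are the mean-centered scores.
    """
    y = np.asarray(scores, dtype=float)
    if cov is None or not selected:
        return y - y.mean()
    X = _as_matrix(cov)[:, selected]
    if X.shape[0] != len(y):
        raise ValueError("covariate rows must match scores")
    design = np.hstack([np.ones((len(y), 1)), X])
    if len(y) < design.shape[1] + 1:
        raise ValueError("need at least |selected| + 2 subjects")
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return y - design @ beta
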