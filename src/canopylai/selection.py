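"""Feature screening: Pearson correlation and the successive
projections algorithm (SPA).

SPA is a forward selector that fights collinearity: starting from a
candidate column, it repeatedly projects every unselected column onto
the orthogonal complement of the span of the selected ones and appends
the column with the largest residual norm. Chains are grown from every
candidate start; each chain prefix is scored by k-fold cross-validated
RMSE of a multiple linear regression (classic SPA-MLR), and the
(start, length) pair with the smallest RMSECV wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable


@dataclass
class CorrelationScreen:
    """Per-column Pearson correlation of features with LAI."""
    table: pd.DataFrame          # columns: r, p, sig_05, sig_01, family
    family_mean_abs_r: dict

    def significant(self, alpha: float = 0.01) -> list:
        col = "sig_01" if alpha <= 0.01 else "sig_05"
        return list(self.table.index[self.table[col]])


@dataclass
class SPAResult:
    start_column: int
    chain: list
    rmsecv_path: np.ndarray
    chosen_k: int
    chosen_columns: list
    chosen_indices: list = field(default_factory=list)


def correlation_screen(table: FeatureTable, lai: np.ndarray
                       ) -> CorrelationScreen:
    """Pearson r and two-sided p of every feature column against LAI,
    with significance flags at 0.05/0.01 and a per-family mean |r|."""
    y = np.asarray(lai, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if len(table.data) != y.size:
        raise ValueError("lai length does not match table")
    rows = {}
    for c in table.data.columns:
        x = table.data[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows[c] = (np.nan, np.nan, False, False, True)
            continue
        r, p = stats.pearsonr(x, y)
        rows[c] = (r, p, p < 0.05, p < 0.01, False)
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["r", "p", "sig_05", "sig_01", "degenerate"])
    df["family"] = [table.families[c] for c in df.index]
    fam_means = {f: float(np.nanmean(np.abs(sub["r"])))
                 for f, sub in df.groupby("family")}
    return CorrelationScreen(df, fam_means)


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero mean / unit variance per column; constant columns map to 0."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def spa_chain(X: np.ndarray, start_column: int,
              kmax: int | None = None, tol: float = 1e-9) -> list:
    """Ordered SPA projection chain from one start column.

    ``X`` must be column-standardized. Selection stops at
    ``min(n - 1, kmax)`` columns or when every residual norm falls
    below ``tol`` (numerical collinearity).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_column < p:
        raise IndexError("start_column out of range")
    limit = n - 1 if kmax is None else min(kmax, n - 1)
    limit = min(limit, p)
    R = X.copy()                      # residuals w.r.t. selected span
    chain = [start_column]
    selected = np.zeros(p, dtype=bool)
    selected[start_column] = True
    for _ in range(limit - 1):
        u = R[:, chain[-1]]
        nu = u @ u
        if nu <= tol ** 2:
            break
        R = R - np.outer(u, (u @ R) / nu)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        best = int(np.argmax(norms))
        if norms[best] <= tol:
            break
        chain.append(best)
        selected[best] = True
    return chain


def _rmsecv_path(X, y, chain, folds, rng, repeats: int = 3):
    """RMSECV of an intercept + chain-prefix MLR for every prefix length.

    The k-fold partition is repeated ``repeats`` times with fresh
    seeded shuffles and the squared errors pooled, which stabilizes the
    prefix comparison. One QR per fold over the full chain; prefix
    solutions come from the leading blocks of R.
    """
    n = X.shape[0]
    k = len(chain)
    sq_err = np.zeros(k)
    A = np.column_stack([np.ones(n), X[:, chain]])
    for _ in range(repeats):
        order = rng.permutation(n)
        fold_id = np.empty(n, dtype=int)
        fold_id[order] = np.arange(n) % folds
        for f in range(folds):
            test = fold_id == f
            train = ~test
            Q, R = np.linalg.qr(A[train])
            qty = Q.T @ y[train]
            for kk in range(1, k + 1):
                beta = np.linalg.solve(R[:kk + 1, :kk + 1], qty[:kk + 1])
                pred = A[test][:, :kk + 1] @ beta
                sq_err[kk - 1] += ((y[test] - pred) ** 2).sum()
    return np.sqrt(sq_err / (n * repeats))


def spa_select(table: FeatureTable, lai: np.ndarray,
               kmax: int | None = None, folds: int = 5,
               seed: int = 0) -> SPAResult:
    """Full SPA selection over a feature table.

    Chains are grown from *every* candidate start column (removing the
    start-vector randomness of the textbook algorithm); the chain
    prefix with the globally smallest cross-validated RMSE is chosen,
    first minimum on ties. Fold assignment is seeded and shared across
    starts so RMSECVs are comparable.
    """
    y = np.asarray(lai, dtype=float)
    n, p = table.data.shape
    if n != y.size:
        raise ValueError("lai length does not match table")
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n samples")
    if kmax is None:
        kmax = min(30, n // 3)
    kmax = max(1, min(kmax, p, n - 1))
    X = standardize_columns(table.data.to_numpy(dtype=float))
    best = None
    for start in range(p):
        chain = spa_chain(X, start, kmax=kmax)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
        path = _rmsecv_path(X, y, chain, folds, rng)
        k_opt = int(np.argmin(path))          # first minimum on ties
        score = path[k_opt]
        if best is None or score < best[0]:
            best = (score, start, chain, path, k_opt)
    score, start, chain, path, k_opt = best
    chosen_idx = chain[:k_opt + 1]
    cols = list(table.data.columns)
    return SPAResult(start_column=start, chain=list(chain),
                     rmsecv_path=path, chosen_k=k_opt + 1,
                     chosen_columns=[cols[i] for i in chosen_idx],
                     chosen_indices=list(chosen_idx))
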