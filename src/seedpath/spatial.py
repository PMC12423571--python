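"""Permutation nulls, spatial weights, Moran's I and the SAR error model.

The permutation null shuffles the focal variable (assemblage maximum seed
width) across assemblages, refits the final path model, and compares the
observed standardized effects against the resulting distributions with the
add-one empirical p-value, which can never be exactly zero.

The spatial-error model is y = Xb + u with u = lambda W u + eps; lambda is
estimated by maximising the concentrated log-likelihood, with the
log-determinant ln|I - lambda W| evaluated from the precomputed eigenvalues
of W.  At lambda = 0 the model reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .assemblage import Grid
from .model import PathModel
from .sem import SemData, fit_ml, standardized_solution

__all__ = [
    "SpatialWeights",
    "NullDistribution",
    "build_weights",
    "morans_i",
    "fit_sar_error",
    "permutation_null",
]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------
@dataclass
class SpatialWeights:
    """Sparse neighbour weights over a set of cells."""

    w: sparse.csr_matrix
    scheme: str
    row_standardized: bool
    eig_range: tuple[float, float]  # of the matrix as stored

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def dense(self) -> np.ndarray:
        return self.w.toarray()


def _neighbor_pairs_lattice(rows: np.ndarray, cols: np.ndarray, scheme: str):
    """Adjacency among cells given their lattice (row, col) coordinates."""
    pos = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:  # queen
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    ii, jj = [], []
    for (r, c), i in pos.items():
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None:
                ii.append(i)
                jj.append(j)
    return ii, jj


def build_weights(
    table: pd.DataFrame,
    grid: Grid,
    scheme: str = "queen",
    row_standardize: bool = True,
    k: int = 4,
) -> SpatialWeights:
    """Neighbour weights for the (possibly filtered) assemblage set.

    ``rook``/``queen`` use lattice contiguity of the grid cell ids;
    ``knn`` uses the k nearest centroids.  Cells isolated under a
    contiguity scheme are linked to their single nearest neighbour so the
    weights matrix has no empty rows.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least two cells")
    cell_ids = table["cell_id"].to_numpy(dtype=int)
    rows, cols = np.divmod(cell_ids, grid.n_cols)
    xy = table[["x", "y"]].to_numpy(dtype=float)

    if scheme in ("rook", "queen"):
        ii, jj = _neighbor_pairs_lattice(rows, cols, scheme)
        A = sparse.coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n)).tocsr()
        isolated = np.flatnonzero(A.sum(axis=1).A1 == 0)
        if len(isolated):
            warnings.warn(
                f"{len(isolated)} isolated cell(s) linked to nearest neighbour",
                stacklevel=2,
            )
            A = A.tolil()
            for i in isolated:
                d = np.linalg.norm(xy - xy[i], axis=1)
                d[i] = np.inf
                j = int(np.argmin(d))
                A[i, j] = 1.0
                A[j, i] = 1.0
            A = A.tocsr()
    elif scheme == "knn":
        if not 1 <= k < n:
            raise ValueError("k must be in [1, n-1]")
        A = sparse.lil_matrix((n, n))
        for i in range(n):
            d = np.linalg.norm(xy - xy[i], axis=1)
            d[i] = np.inf
            for j in np.argsort(d)[:k]:
                A[i, j] = 1.0
        A = A.tocsr()
    else:
        raise ValueError("scheme must be rook, queen or knn")

    A.setdiag(0.0)
    A.eliminate_zeros()
    if row_standardize:
        rs = A.sum(axis=1).A1
        rs[rs == 0] = 1.0
        W = sparse.diags(1.0 / rs) @ A
    else:
        W = A
    ev = np.linalg.eigvals(W.toarray())
    ev = np.real(ev[np.abs(np.imag(ev)) < 1e-8])
    return SpatialWeights(
        w=W.tocsr(),
        scheme=scheme,
        row_standardized=row_standardize,
        eig_range=(float(ev.min()), float(ev.max())),
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------
def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Global Moran's I with a permutation p-value.

    I = (n / S0) * (z' W z) / (z' z) with centred values z and
    S0 = sum of all weights; the null expectation is -1/(n-1).  The
    permutation p is two-sided on the deviation from the expectation.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least three cells")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    z = z - z.mean()
    W = weights.w
    s0 = W.sum()

    def stat(v: np.ndarray) -> float:
        return float(n / s0 * (v @ (W @ v)) / (v @ v))

    I = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    if n_perm > 0:
        null = np.array([stat(rng.permutation(z)) for _ in range(n_perm)])
        p = (1 + np.sum(np.abs(null - expected) >= abs(I - expected))) / (n_perm + 1)
    else:
        null, p = np.array([]), np.nan
    return {"I": I, "expected": expected, "p": float(p), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# SAR error model
# ---------------------------------------------------------------------------
def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
    add_intercept: bool = True,
    lam: float | None = None,
) -> dict:
    """ML spatial-error regression via the concentrated log-likelihood.

    For each candidate lambda the data are spatially filtered,
    (I - lambda W), beta and sigma^2 drop out in closed form, and the
    concentrated log-likelihood ln|I - lambda W| - (n/2) ln RSS/n is
    maximised over lambda in (1/ev_min, 1).  Passing ``lam`` evaluates
    the profiled solution at that fixed value instead (``lam=0`` is
    exactly ordinary least squares).
    """
    if not weights.row_standardized:
        raise ValueError("SAR expects row-standardized weights")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    Wd = weights.w.toarray()
    ev = np.linalg.eigvals(Wd)
    ev = np.real(ev[np.abs(np.imag(ev)) < 1e-8])
    lam_lo = 1.0 / ev.min() + 1e-6 if ev.min() < 0 else -0.999
    lam_hi = 1.0 - 1e-6

    def neg_cll(lam: float) -> float:
        A = np.eye(n) - lam * Wd
        yt = A @ y
        Xt = A @ X
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        logdet = float(np.sum(np.log(np.abs(1.0 - lam * ev))))
        return -(logdet - n / 2.0 * np.log(rss / n))

    if lam is None:
        res = optimize.minimize_scalar(
            neg_cll, bounds=(lam_lo, lam_hi), method="bounded"
        )
        lam = float(res.x)
        if lam - lam_lo < 1e-4 or lam_hi - lam < 1e-4:
            warnings.warn("lambda estimate at the search boundary", stacklevel=2)
    else:
        lam = float(lam)
    A = np.eye(n) - lam * Wd
    yt, Xt = A @ y, A @ X
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    cov_beta = sigma2 * np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(np.diag(cov_beta))
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    loglik = (
        -n / 2.0 * (np.log(2 * np.pi) + 1.0)
        - n / 2.0 * np.log(sigma2)
        + float(np.sum(np.log(np.abs(1.0 - lam * ev))))
    )
    return {
        "lambda": lam,
        "beta": beta,
        "se": se,
        "z": zvals,
        "p": pvals,
        "sigma2": sigma2,
        "loglik": float(loglik),
        "add_intercept": add_intercept,
    }


# ---------------------------------------------------------------------------
# permutation null for the path model
# ---------------------------------------------------------------------------
@dataclass
class NullDistribution:
    """Null standardized effects from refits on permuted seed widths."""

    labels: list[str]
    observed: np.ndarray  # standardized path estimates of the observed fit
    null: np.ndarray  # (n_success, n_paths)
    n_perm: int
    n_failed: int
    seed: int
    empirical_p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # add-one rule: p in (0, 1], never exactly zero
        exceed = (np.abs(self.null) >= np.abs(self.observed)[None, :]).sum(axis=0)
        self.empirical_p = (exceed + 1) / (self.null.shape[0] + 1)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "observed_std": self.observed,
                "null_mean": self.null.mean(axis=0),
                "null_sd": self.null.std(axis=0, ddof=1),
                "empirical_p": self.empirical_p,
            }
        )


def permutation_null(
    table: pd.DataFrame,
    model: PathModel,
    n_perm: int = 1000,
    seed: int = 0,
    focal: str = "seed",
    preprocess=None,
) -> NullDistribution:
    """Refit the model on datasets with the focal column randomly permuted.

    Each permutation rearranges the assemblage-level focal values across
    assemblages while leaving every other column fixed, so the null keeps
    all non-focal structure intact.  ``preprocess`` converts a table into
    a :class:`SemData`; by default the package's log + min-max transform
    is applied.
    """
    from .sem import preprocess_variables

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if preprocess is None:
        preprocess = lambda t: preprocess_variables(t, variables=list(model.variables))
    obs_fit = fit_ml(preprocess(table), model)
    n_paths = len(model.regressions)
    observed = standardized_solution(obs_fit)["std_estimate"].to_numpy()[:n_paths]
    labels = [f"{t}~{s}" for t, s in model.regressions]

    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_perm):
        t = table.copy()
        t[focal] = rng.permutation(t[focal].to_numpy())
        try:
            f = fit_ml(preprocess(t), model)
            if not f.converged:
                raise RuntimeError("non-converged")
            rows.append(standardized_solution(f)["std_estimate"].to_numpy()[:n_paths])
        except Exception:
            n_failed += 1
    if not rows:
        raise RuntimeError("all permutation fits failed")
    if n_failed > 0.05 * n_perm:
        warnings.warn(f"{n_failed} of {n_perm} permutation fits failed", stacklevel=2)
    return NullDistribution(
        labels=labels,
        observed=observed,
        null=np.vstack(rows),
        n_perm=n_perm,
        n_failed=n_failed,
        seed=seed,
    )
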