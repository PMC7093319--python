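"""Partial-correlation network estimation.

The network is a Gaussian graphical model (GGM): nodes are the symptom
items plus the risk score, and an edge between two nodes is the partial
correlation between them after conditioning on all other variables —
the standardized negative inverse covariance.  Because the symptom items
are ordinal, the input correlation matrix is Spearman (Pearson on ranks),
which consistently estimates the latent association structure under the
latent-Gaussian threshold model.

Three estimators are provided:

``modselect``
    The primary estimator: unregularized stepwise model search.  Starting
    from the best structure along a regularization path (or from the
    empty graph), single-edge additions and removals are refit by
    constrained maximum likelihood and the move with the largest BIC
    decrease is applied, until no move decreases BIC.

``ebic_path``
    Graphical-lasso regularization path scored by the extended BIC
    (EBIC), the common default in the applied network literature; the
    selected pattern is refit without penalty for reporting.

``threshold``
    Saturated partial correlations thresholded by the Fisher-z
    significance test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, EstimationError, InputError
from .synthetic import SymptomDataset

__all__ = [
    "CorrelationMatrix", "NetworkModel", "spearman_matrix", "precision_to_pcor",
    "fit_constrained_ggm", "model_bic", "estimate_modselect",
    "estimate_ebic_path", "estimate_threshold", "ESTIMATORS", "estimate",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman correlation matrix with provenance.

    ``n_effective`` is the smallest pairwise-complete count, used as the
    sample size in all likelihood and threshold formulas (conservative
    under missing data).  ``repaired`` flags a nearest-correlation-matrix
    projection (eigenvalue clipping) applied to restore positive
    semi-definiteness.
    """

    matrix: np.ndarray
    labels: tuple[str, ...]
    n_effective: int
    method: str = "spearman"
    repaired: bool = False

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown variable {label!r}") from None


@dataclass(frozen=True)
class NetworkModel:
    """An estimated partial-correlation network.

    ``weights`` is the symmetric matrix of partial correlations (zero
    diagonal, zeros exactly where ``adjacency`` is false); ``bic`` equals
    ``-2 * loglik + k_params * log(n)``.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    adjacency: np.ndarray
    loglik: float
    k_params: int
    bic: float
    estimator: str
    n: int
    settings: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown node {label!r}") from None

    def edge_list(self) -> pd.DataFrame:
        ii, jj = np.where(np.triu(self.adjacency, 1))
        return pd.DataFrame({
            "node_i": [self.labels[i] for i in ii],
            "node_j": [self.labels[j] for j in jj],
            "weight": self.weights[ii, jj],
        })


# ---------------------------------------------------------------------------
# input correlations

def _nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project onto the correlation matrices by eigenvalue clipping followed
    by re-standardization to a unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2
    np.fill_diagonal(fixed, 1.0)
    return fixed


def spearman_matrix(data: SymptomDataset | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations of a subject-by-variable table.

    Ties get average ranks (Pearson on mid-ranks).  With no missing cells
    all columns are ranked once and correlated in one pass; under
    missingness each pair is re-ranked on its complete cases.  A matrix
    that is not positive semi-definite is projected to the nearest
    correlation matrix and flagged ``repaired``.
    """
    table = data.table if isinstance(data, SymptomDataset) else data
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    labels = tuple(str(c) for c in table.columns)
    X = table.to_numpy(dtype=float)
    n, p = X.shape

    notna = ~np.isnan(X)
    for k, lab in enumerate(labels):
        col = X[notna[:, k], k]
        if col.size == 0 or np.all(col == col[0]):
            raise EstimationError(f"column {lab!r} is constant (or empty); "
                                  "its correlations are undefined")
    pair_counts = notna.astype(np.int64).T @ notna.astype(np.int64)
    n_effective = int(pair_counts[~np.eye(p, dtype=bool)].min()) if p > 1 else n
    if n_effective < 3:
        ii, jj = np.unravel_index(np.argmin(pair_counts + np.eye(p, dtype=np.int64) * (n + 1)),
                                  pair_counts.shape)
        raise EstimationError(
            f"pair ({labels[ii]!r}, {labels[jj]!r}) has only "
            f"{pair_counts[ii, jj]} complete observations (< 3)")

    if notna.all():
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        with np.errstate(invalid="raise"):
            mat = np.corrcoef(ranks, rowvar=False)
    else:
        # pandas re-ranks each pair on its complete cases
        mat = table.corr(method="spearman", min_periods=3).to_numpy()
        if np.isnan(mat).any():
            raise EstimationError("a variable pair has an undefined Spearman "
                                  "correlation (constant on complete cases)")

    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 1.0)
    repaired = False
    # repair only genuinely indefinite matrices; a singular PSD matrix
    # (e.g. perfectly rank-correlated columns) is left untouched
    if np.linalg.eigvalsh(mat)[0] < -1e-10:
        mat = _nearest_correlation(mat)
        repaired = True
    return CorrelationMatrix(matrix=mat, labels=labels, n_effective=n_effective,
                             method="spearman", repaired=repaired)


# ---------------------------------------------------------------------------
# precision <-> partial correlations

def precision_to_pcor(precision: np.ndarray) -> np.ndarray:
    """Standardize a precision (inverse covariance) matrix into partial
    correlations: ``-kappa_ij / sqrt(kappa_ii * kappa_jj)``, zero diagonal."""
    K = np.asarray(precision, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError("precision must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise InputError("precision must be symmetric")
    try:
        np.linalg.cholesky((K + K.T) / 2)
    except np.linalg.LinAlgError:
        raise InputError("precision must be positive definite") from None
    d = np.sqrt(np.diag(K))
    pcor = -K / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2


def _as_matrix_and_n(S, n):
    if isinstance(S, CorrelationMatrix):
        return S.matrix, (S.n_effective if n is None else int(n)), S.labels
    if n is None:
        raise InputError("n must be given when S is a bare matrix")
    S = np.asarray(S, dtype=float)
    return S, int(n), tuple(f"V{i}" for i in range(S.shape[0]))


def gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (n/2)(log det K - tr(S K)); additive
    constants are dropped consistently so BIC differences are unaffected."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise InputError("precision must be positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * K)))


@dataclass(frozen=True)
class ConstrainedFit:
    precision: np.ndarray
    loglik: float
    n_iter: int
    max_violation: float

    @property
    def W(self) -> np.ndarray:  # fitted covariance (model-implied)
        return np.linalg.inv(self.precision)


def _fit_pattern(S: np.ndarray, adj: np.ndarray, tol: float, max_iter: int,
                 warm_W: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, int]:
    """Block-coordinate ascent for the GGM MLE under a fixed zero pattern.

    Maintains the working covariance W; for each variable j, the free
    entries of column j are matched to S over j's neighborhood (a small
    linear solve), which is the stationarity condition of the constrained
    likelihood.  Returns (K, W, sweeps)."""
    p = S.shape[0]
    W = S.copy() if warm_W is None else warm_W.copy()
    np.fill_diagonal(W, np.diag(S))
    arange = np.arange(p)
    cols = []
    for j in range(p):
        nb = np.flatnonzero(adj[:, j])
        rest = np.delete(arange, j)
        cols.append((nb, rest, np.ix_(nb, nb), np.ix_(rest, nb), S[nb, j]))

    sweeps = 0
    delta = np.inf
    w_tol = max(tol * 1e-2, 1e-15)
    while sweeps < max_iter and delta > w_tol:
        delta = 0.0
        for j in range(p):
            nb, rest, ix_nb, ix_rest_nb, s12 = cols[j]
            if nb.size == 0:
                new = np.zeros(rest.size)
            else:
                beta = np.linalg.solve(W[ix_nb], s12)
                new = W[ix_rest_nb] @ beta
            old = W[rest, j]
            d = np.max(np.abs(new - old)) if rest.size else 0.0
            if d > delta:
                delta = d
            W[rest, j] = new
            W[j, rest] = new
        sweeps += 1

    # assemble K from the final regression coefficients
    K = np.zeros((p, p))
    for j in range(p):
        nb, _, ix_nb, _, s12 = cols[j]
        if nb.size == 0:
            K[j, j] = 1.0 / S[j, j]
            continue
        beta = np.linalg.solve(W[ix_nb], s12)
        resid_var = S[j, j] - float(W[nb, j] @ beta)
        kjj = 1.0 / resid_var
        K[j, j] = kjj
        # each edge receives half its value from either endpoint's column;
        # the two halves agree in exact arithmetic
        K[nb, j] += -beta * kjj / 2
        K[j, nb] += -beta * kjj / 2
    K = (K + K.T) / 2
    return K, W, sweeps


def _moment_violation(S: np.ndarray, K: np.ndarray, adj: np.ndarray) -> float:
    Kinv = np.linalg.inv(K)
    modeled = adj | np.eye(S.shape[0], dtype=bool)
    return float(np.max(np.abs((Kinv - S)[modeled])))


def fit_constrained_ggm(S, adjacency: np.ndarray, n: int | None = None, *,
                        tol: float = 1e-10, max_iter: int = 1000,
                        warm_W: np.ndarray | None = None) -> ConstrainedFit:
    """Maximum-likelihood precision matrix under a fixed edge pattern.

    Maximizes (n/2)(log det K - tr(S K)) subject to K[i,j] = 0 wherever
    ``adjacency[i,j]`` is false (i != j).  At the optimum the moment
    conditions hold: (K^-1)[i,j] = S[i,j] on every modeled pair and on the
    diagonal, and K[i,j] = 0 on excluded pairs.  ``tol`` bounds the
    largest moment violation at convergence.
    """
    Smat, n, _ = _as_matrix_and_n(S, n)
    p = Smat.shape[0]
    adj = np.asarray(adjacency, dtype=bool)
    if adj.shape != (p, p) or not np.array_equal(adj, adj.T) or adj.diagonal().any():
        raise InputError("adjacency must be symmetric boolean with a false diagonal")
    if np.linalg.eigvalsh(Smat)[0] <= 0:
        raise InputError("S must be positive definite")

    K, W, sweeps = _fit_pattern(Smat, adj, tol, max_iter, warm_W)
    viol = _moment_violation(Smat, K, adj)
    while viol > tol and sweeps < max_iter:
        K, W, extra = _fit_pattern(Smat, adj, tol * 1e-2, max_iter - sweeps, W)
        sweeps += extra
        new_viol = _moment_violation(Smat, K, adj)
        if new_viol >= viol:  # no further progress possible in float arithmetic
            viol = new_viol
            break
        viol = new_viol
    if viol > tol:
        raise ConvergenceError(
            f"constrained GGM fit did not converge: max moment violation "
            f"{viol:.3e} > tol {tol:.1e} after {sweeps} sweeps",
            n_iter=sweeps, violation=viol)
    ll = gaussian_loglik(Smat, K, n)
    return ConstrainedFit(precision=K, loglik=ll, n_iter=sweeps, max_violation=viol)


def model_bic(loglik: float, k_params: int, n: int) -> float:
    """Bayesian information criterion: -2*loglik + k*log(n)."""
    if n < 2:
        raise InputError("n must be >= 2")
    return -2.0 * loglik + k_params * np.log(n)


def _pcor_with_pattern(K: np.ndarray, adj: np.ndarray) -> np.ndarray:
    w = precision_to_pcor(K)
    w[~adj] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def _model_from_fit(labels, fit: ConstrainedFit, adj, n, estimator, settings):
    p = adj.shape[0]
    k = p + int(np.triu(adj, 1).sum())
    return NetworkModel(labels=tuple(labels), weights=_pcor_with_pattern(fit.precision, adj),
                        adjacency=adj.copy(), loglik=fit.loglik, k_params=k,
                        bic=model_bic(fit.loglik, k, n), estimator=estimator,
                        n=n, settings=dict(settings))


# ---------------------------------------------------------------------------
# estimator 1: unregularized stepwise BIC search (primary)

def estimate_modselect(S: CorrelationMatrix, n: int | None = None, *,
                       start: str = "path_best", max_sweeps: int = 100,
                       candidate_tol: float = 1e-5,
                       final_tol: float = 1e-10) -> NetworkModel:
    """Unregularized stepwise model search arbitrated by plain BIC.

    From the starting structure, every single-edge addition and removal is
    refit by constrained maximum likelihood (warm-started, at a screening
    tolerance) and the move with the largest BIC decrease is applied after
    a confirming refit at full tolerance; the search stops when no move
    decreases BIC or after ``max_sweeps`` accepted moves.  Ties are broken
    by preferring removals, then the lexicographically smallest pair.
    """
    Smat, n, labels = _as_matrix_and_n(S, n)
    p = Smat.shape[0]
    if np.linalg.eigvalsh(Smat)[0] <= 0:
        raise InputError("S must be positive definite")
    if n < p + 2:
        warnings.warn(f"n = {n} < p + 2 = {p + 2}: stepwise selection may be unstable",
                      stacklevel=2)

    if start == "empty":
        adj = np.zeros((p, p), dtype=bool)
    elif start == "path_best":
        init = estimate_ebic_path(S if isinstance(S, CorrelationMatrix) else Smat,
                                  n, gamma=0.5)
        adj = init.adjacency.copy()
    else:
        raise InputError(f"unknown start {start!r} (use 'empty' or 'path_best')")

    fit = fit_constrained_ggm(Smat, adj, n, tol=final_tol)
    k = p + int(np.triu(adj, 1).sum())
    bic = model_bic(fit.loglik, k, n)
    bic_sequence = [bic]
    W = fit.W

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    for _ in range(max_sweeps):
        candidates = []  # (delta_bic, is_addition, i, j)
        for (i, j) in pairs:
            cand_adj = adj.copy()
            adding = not adj[i, j]
            cand_adj[i, j] = cand_adj[j, i] = adding
            # screening refit: warm-started, moderate tolerance; the winning
            # move is confirmed at full tolerance below
            try:
                cand_K, _, _ = _fit_pattern(Smat, cand_adj, candidate_tol, 60, W)
                cand_ll = gaussian_loglik(Smat, cand_K, n)
            except (np.linalg.LinAlgError, InputError) as err:
                raise ConvergenceError(
                    f"candidate move on edge ({labels[i]}, {labels[j]}) "
                    f"failed: {err}") from err
            dk = 1 if adding else -1
            cand_bic = model_bic(cand_ll, k + dk, n)
            candidates.append((cand_bic - bic, adding, i, j))
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
        accepted = False
        for delta, adding, i, j in candidates:
            if delta >= 0:
                break
            cand_adj = adj.copy()
            cand_adj[i, j] = cand_adj[j, i] = adding
            cand_fit = fit_constrained_ggm(Smat, cand_adj, n, tol=final_tol, warm_W=W)
            dk = 1 if adding else -1
            cand_bic = model_bic(cand_fit.loglik, k + dk, n)
            if cand_bic < bic - 1e-9:
                adj, fit, k, bic = cand_adj, cand_fit, k + dk, cand_bic
                W = fit.W
                bic_sequence.append(bic)
                accepted = True
                break
        if not accepted:
            break

    settings = {"start": start, "max_sweeps": max_sweeps,
                "bic_sequence": bic_sequence}
    return _model_from_fit(labels, fit, adj, n, "modselect", settings)


# ---------------------------------------------------------------------------
# estimator 2: graphical-lasso path scored by EBIC

def estimate_ebic_path(S, n: int | None = None, *, gamma: float = 0.5,
                       n_lambda: int = 100, lambda_min_ratio: float = 0.01
                       ) -> NetworkModel:
    """Graphical lasso over a log-spaced penalty grid, selected by EBIC.

    The grid runs from lambda_max (the smallest penalty that empties the
    graph: the largest absolute off-diagonal of S) down to
    ``lambda_max * lambda_min_ratio``.  Each penalized fit is scored by
    EBIC = -2*loglik + k*log(n) + 4*gamma*k*log(p); the winning nonzero
    pattern is refit without penalty for the reported weights.
    """
    from sklearn.covariance import graphical_lasso
    from sklearn.exceptions import ConvergenceWarning

    Smat, n, labels = _as_matrix_and_n(S, n)
    p = Smat.shape[0]
    if gamma < 0:
        raise InputError("gamma must be >= 0")
    if n_lambda < 2:
        raise InputError("n_lambda must be >= 2")
    if np.linalg.eigvalsh(Smat)[0] <= 0:
        raise InputError("S must be positive definite")

    lam_max = float(np.max(np.abs(Smat[~np.eye(p, dtype=bool)])))
    if lam_max == 0:  # S is the identity: the empty graph is the only candidate
        grid = np.array([1.0])
    else:
        grid = np.exp(np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio),
                                  n_lambda))

    best = None  # (ebic, adjacency, lam, fit)
    n_failed = 0
    seen: set[bytes] = set()
    warm = None
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                # moderate tolerance: only the nonzero pattern is consumed;
                # each pattern is refit without penalty before scoring
                _, prec = graphical_lasso(Smat, alpha=float(lam), mode="cd",
                                          tol=1e-4, max_iter=100)
        except FloatingPointError:
            n_failed += 1
            continue
        adj = np.abs(prec) > 1e-8
        np.fill_diagonal(adj, False)
        adj = adj | adj.T
        key = np.packbits(adj).tobytes()
        if key in seen:  # same pattern as an earlier penalty
            continue
        seen.add(key)
        # EBIC on the unpenalized maximum-likelihood refit of the pattern,
        # consistent with reporting refit weights
        try:
            fit = fit_constrained_ggm(Smat, adj, n, warm_W=warm)
        except ConvergenceError:
            n_failed += 1
            continue
        warm = fit.W
        k = p + int(np.triu(adj, 1).sum())
        ebic = -2.0 * fit.loglik + k * np.log(n) + 4.0 * gamma * k * np.log(p)
        if best is None or ebic < best[0]:
            best = (ebic, adj, float(lam), fit)
    if best is None:
        raise EstimationError("graphical lasso failed on every penalty in the grid")

    ebic, adj, lam, fit = best
    settings = {"gamma": gamma, "n_lambda": n_lambda,
                "lambda_min_ratio": lambda_min_ratio, "lambda_selected": lam,
                "ebic_selected": ebic, "n_lambda_failed": n_failed}
    return _model_from_fit(labels, fit, adj, n, "ebic_path", settings)


# ---------------------------------------------------------------------------
# estimator 3: thresholded saturated partial correlations

def estimate_threshold(S, n: int | None = None, *, alpha: float = 0.01
                       ) -> NetworkModel:
    """Keep saturated partial correlations that pass a Fisher-z test.

    The saturated partial-correlation matrix is computed from S^-1; edge
    (i, j) is retained iff |atanh(r_ij)| * sqrt(n - (p - 2) - 3) exceeds
    the two-sided normal critical value at ``alpha`` (p - 2 = number of
    conditioning variables among p nodes).  Retained edges keep their
    saturated weights; the reported log-likelihood and BIC are those of
    the retained pattern's maximum-likelihood refit, so the three
    estimators are comparable on fit.
    """
    Smat, n, labels = _as_matrix_and_n(S, n)
    p = Smat.shape[0]
    df = n - (p - 2) - 3
    if df < 1:
        raise InputError(f"degrees of freedom exhausted: n = {n} <= p + 1 = {p + 1}")
    if np.linalg.eigvalsh(Smat)[0] <= 0:
        raise InputError("S must be positive definite")

    sat = precision_to_pcor(np.linalg.inv(Smat))
    crit = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore"):
        z = np.abs(np.arctanh(np.clip(sat, -1, 1))) * np.sqrt(df)
    adj = z > crit
    np.fill_diagonal(adj, False)
    adj = adj | adj.T

    weights = np.where(adj, sat, 0.0)
    np.fill_diagonal(weights, 0.0)
    adj = adj & (weights != 0)
    weights[~adj] = 0.0

    fit = fit_constrained_ggm(Smat, adj, n)
    k = p + int(np.triu(adj, 1).sum())
    return NetworkModel(labels=tuple(labels), weights=weights, adjacency=adj,
                        loglik=fit.loglik, k_params=k,
                        bic=model_bic(fit.loglik, k, n), estimator="threshold",
                        n=n, settings={"alpha": alpha})


ESTIMATORS = {
    "modselect": estimate_modselect,
    "ebic_path": estimate_ebic_path,
    "threshold": estimate_threshold,
}


def estimate(S: CorrelationMatrix, estimator: str = "modselect",
             n: int | None = None, **settings) -> NetworkModel:
    """Dispatch to one of the registered estimators by name."""
    if estimator not in ESTIMATORS:
        raise InputError(f"unknown estimator {estimator!r}; "
                         f"choose from {sorted(ESTIMATORS)}")
    return ESTIMATORS[estimator](S, n, **settings)
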