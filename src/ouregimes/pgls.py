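"""Phylogenetic generalized least squares of a log-scale trait on the COX
regime state, with BM / OU / Pagel-lambda error structures.

The categorical predictor uses LS (the ancestral state) as the reference
level, so the intercept is the LS mean and the remaining coefficients are
the CC and CS offsets.  Error-model parameters (OU alpha, or lambda) are
estimated by maximum likelihood jointly with the coefficients: beta and
sigma^2 are profiled analytically and a bounded one-dimensional search is
run over the structure parameter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .tree import Phylogeny, DEFAULT_REGIMES, normalize_name

ERROR_MODELS = ("BM", "OUfixedRoot", "OUrandomRoot", "lambda")

__all__ = ["PGLSFit", "PGLSError", "error_covariance", "fit_pgls",
           "select_error_model", "ERROR_MODELS"]


class PGLSError(ValueError):
    pass


def _shared_depth(tree: Phylogeny):
    d = tree.depths()
    M = tree.mrca_matrix()
    t_ij = d[M]
    dt = d[tree.tips]
    d_ij = dt[:, None] + dt[None, :] - 2.0 * t_ij
    return t_ij, d_ij


def error_covariance(tree: Phylogeny, model: str, alpha: float | None = None,
                     lam: float | None = None) -> np.ndarray:
    """Unit-sigma^2 residual covariance among tips for the given structure.

    BM: V_ij = t_ij (shared root-to-MRCA path length).
    OUfixedRoot: V_ij = exp(-alpha d_ij) (1 - exp(-2 alpha t_ij)) / (2 alpha).
    OUrandomRoot (stationary): V_ij = exp(-alpha d_ij) / (2 alpha).
    lambda: off-diagonals of the BM matrix multiplied by lambda.
    """
    t_ij, d_ij = _shared_depth(tree)
    if model == "BM":
        return t_ij
    if model in ("OUfixedRoot", "OUrandomRoot"):
        if alpha is None or alpha <= 0:
            raise PGLSError("OU error structure needs alpha > 0")
        if model == "OUfixedRoot":
            return np.exp(-alpha * d_ij) * (-np.expm1(-2.0 * alpha * t_ij)) \
                / (2.0 * alpha)
        return np.exp(-alpha * d_ij) / (2.0 * alpha)
    if model == "lambda":
        if lam is None or not (0.0 <= lam <= 1.0):
            raise PGLSError("lambda must be in [0, 1]")
        V = lam * t_ij
        np.fill_diagonal(V, np.diag(t_ij))
        return V
    raise PGLSError(f"unknown error model {model!r}; choose from {ERROR_MODELS}")


@dataclasses.dataclass
class PGLSFit:
    """Fitted phylogenetic regression."""

    error_model: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    sigma2: float
    param: float | None          # alpha (OU) or lambda; None for BM
    lnL: float
    n: int
    n_params: int
    r2: float
    r2_adj: float                # 1 - (1-R2)(n-1)/(n-k)
    r2_adj_alt: float            # 1 - (1-R2)(n-1)/(n-k-1)
    aic_weight: float | None = None
    species: list[str] = dataclasses.field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnL

    def table(self):
        import pandas as pd

        return pd.DataFrame({
            "term": self.terms, "estimate": self.beta, "s.e.": self.se,
            "t": self.tvals, "p": self.pvals,
        })


def _design(states_vec: list[str], alphabet=DEFAULT_REGIMES):
    levels = [a for a in alphabet if a in set(states_vec)]
    extra = sorted(set(states_vec) - set(alphabet))
    levels += extra
    if len(levels) < 2:
        raise PGLSError(
            f"need >= 2 predictor levels, found {levels}; "
            "a single-regime dataset has no contrast to estimate")
    ref = levels[0]
    X = np.ones((len(states_vec), len(levels)))
    terms = [f"COX_{ref} (intercept)"]
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if s == lv else 0.0 for s in states_vec]
        terms.append(f"COX_{lv}")
    return X, terms


def _profile_lnl(y, X, V0):
    n = y.size
    try:
        cf = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return None
    XtVi = cho_solve(cf, X)
    G = X.T @ XtVi
    try:
        beta = np.linalg.solve(G, X.T @ cho_solve(cf, y))
    except np.linalg.LinAlgError:
        raise PGLSError("singular design matrix")
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    if rss <= 0:
        return None
    s2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    lnL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return lnL, beta, s2, np.linalg.inv(G), cf


def fit_pgls(tree: Phylogeny, traits: dict, states: dict,
             error_model: str = "OUfixedRoot",
             alphabet=DEFAULT_REGIMES) -> PGLSFit:
    """ML phylogenetic regression of the trait on the regime state.

    ``traits`` and ``states`` map species to log-scale values and regime
    labels; species must cover all tree tips (prune first).  Returns the
    coefficient table with t-tests (df = n - p) and GLS-whitened R^2
    against the intercept-only model under the same fitted correlation.
    """
    tmap = {normalize_name(k): float(v) for k, v in traits.items()}
    smap = {normalize_name(k): v for k, v in states.items()}
    labs = tree.tip_labels
    missing = [s for s in labs if s not in tmap or s not in smap]
    if missing:
        raise PGLSError(f"tips lacking trait or state: {missing[:5]}")
    y = np.array([tmap[s] for s in labs])
    sv = [smap[s] for s in labs]
    X, terms = _design(sv, alphabet)
    n, k = X.shape
    if n <= k:
        raise PGLSError("more coefficients than observations")
    height = tree.height

    if error_model == "BM":
        V0 = error_covariance(tree, "BM")
        out = _profile_lnl(y, X, V0)
        if out is None:
            raise PGLSError("BM covariance is singular")
        lnL, beta, s2, Ginv, cf = out
        param = None
        n_params = k + 1
    elif error_model in ("OUfixedRoot", "OUrandomRoot"):
        lo, hi = np.log(1e-8 / height), np.log(50.0 / height)

        def neg(la):
            V0 = error_covariance(tree, error_model, alpha=float(np.exp(la)))
            out = _profile_lnl(y, X, V0)
            return 1e12 if out is None else -out[0]

        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        param = float(np.exp(res.x))
        V0 = error_covariance(tree, error_model, alpha=param)
        lnL, beta, s2, Ginv, cf = _profile_lnl(y, X, V0)
        n_params = k + 2
    elif error_model == "lambda":
        def neg(lam):
            out = _profile_lnl(y, X, error_covariance(tree, "lambda", lam=lam))
            return 1e12 if out is None else -out[0]

        res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-9})
        param = float(res.x)
        V0 = error_covariance(tree, "lambda", lam=param)
        lnL, beta, s2, Ginv, cf = _profile_lnl(y, X, V0)
        n_params = k + 2
    else:
        raise PGLSError(f"unknown error model {error_model!r}")

    se = np.sqrt(s2 * np.diag(Ginv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)

    # whitened R^2 vs intercept-only refit under the same correlation
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    ones = np.ones((n, 1))
    _, b0, _, _, _ = _profile_lnl(y, ones, V0)
    r0 = y - ones @ b0
    rss0 = float(r0 @ cho_solve(cf, r0))
    r2 = 1.0 - rss / rss0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    r2_adj_alt = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)

    return PGLSFit(error_model=error_model, terms=terms, beta=beta, se=se,
                   tvals=tvals, pvals=pvals, sigma2=s2, param=param, lnL=lnL,
                   n=n, n_params=n_params, r2=r2, r2_adj=r2_adj,
                   r2_adj_alt=r2_adj_alt, species=labs)


def select_error_model(tree, traits, states,
                       candidates=("BM", "OUfixedRoot", "OUrandomRoot"),
                       alphabet=DEFAULT_REGIMES):
    """Fit each candidate error structure by ML and rank by Akaike weight.

    Returns ``(fits, notes)`` with fits best-first; ``notes['comparable']``
    is set when the top two weights differ by less than a factor e (~2.7).
    """
    if len(candidates) < 2:
        raise PGLSError("need >= 2 candidate error models")
    fits, failures = [], {}
    for c in candidates:
        try:
            fits.append(fit_pgls(tree, traits, states, error_model=c,
                                 alphabet=alphabet))
        except PGLSError as exc:
            failures[c] = str(exc)
    if len(fits) < 2:
        raise PGLSError(f"too few candidates fitted; failures: {failures}")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.aic_weight = float(wi)
    fits.sort(key=lambda f: f.aic)
    notes = {"failures": failures,
             "comparable": len(fits) > 1 and
             fits[0].aic_weight / max(fits[1].aic_weight, 1e-300) < np.e}
    return fits, notes
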