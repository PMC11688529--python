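"""Multi-regime Brownian-motion / Ornstein-Uhlenbeck trait evolution.

Seven model specifications are supported, following the OUwie naming:

========  ======================  =====================  ==================
name      optimum theta           attraction alpha       diffusion sigma^2
========  ======================  =====================  ==================
BM1       (none)                  0                      one global
BMS       (none)                  0                      one per regime
OU1       one global              one global             one global
OUM       one per regime          one global             one global
OUMV      one per regime          one global             one per regime
OUMA      one per regime          one per regime         one global
OUMVA     one per regime          one per regime         one per regime
========  ======================  =====================  ==================

The trait follows dX = alpha (theta - X) dt + sigma dW along each branch,
with regime-specific parameters given by a branch painting.  Likelihoods are
available through two independent routes that must agree: an explicit
multivariate-normal construction with exact piecewise accumulation of the
attraction decay along root-to-tip paths, and Gaussian belief propagation
(post-order message passing with the OU transition kernel).

By default the root trait value is tied to the optimum of the root regime
(the smaller model); a free root value is available via ``root='free'``.
Traits are analysed on a log10 scale in this package's pipeline; theta
estimates back-transform monotonically to the measurement scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize

from .tree import Phylogeny, RegimePainting

MODEL_NAMES = ("BM1", "BMS", "OU1", "OUM", "OUMV", "OUMA", "OUMVA")

_SPEC_TABLE = {
    #          theta_per  alpha_per  sigma_per  has_alpha
    "BM1":    (False, False, False, False),
    "BMS":    (False, False, True,  False),
    "OU1":    (False, False, False, True),
    "OUM":    (True,  False, False, True),
    "OUMV":   (True,  False, True,  True),
    "OUMA":   (True,  True,  False, True),
    "OUMVA":  (True,  True,  True,  True),
}

__all__ = [
    "MODEL_NAMES",
    "OUModelSpec",
    "OUParams",
    "OUFit",
    "branch_transition",
    "simulate_traits",
    "ou_likelihood",
    "fit_ou",
    "fit_all_models",
    "aic_weights",
    "theta_standard_errors",
    "OUError",
]


class OUError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class OUModelSpec:
    """One of the seven BM/OU model structures plus the root-handling rule."""

    name: str
    root: str = "tied"  # 'tied' (root value = root-regime optimum) or 'free'

    def __post_init__(self):
        if self.name not in _SPEC_TABLE:
            raise OUError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.root not in ("tied", "free"):
            raise OUError("root must be 'tied' or 'free'")

    @property
    def theta_per_regime(self) -> bool:
        return _SPEC_TABLE[self.name][0]

    @property
    def alpha_per_regime(self) -> bool:
        return _SPEC_TABLE[self.name][1]

    @property
    def sigma_per_regime(self) -> bool:
        return _SPEC_TABLE[self.name][2]

    @property
    def has_alpha(self) -> bool:
        return _SPEC_TABLE[self.name][3]

    @property
    def multi_regime(self) -> bool:
        return self.name not in ("BM1", "OU1")

    def n_params(self, n_regimes: int) -> int:
        R = n_regimes
        counts = {"BM1": 2, "BMS": R + 1, "OU1": 3, "OUM": R + 2,
                  "OUMV": 2 * R + 1, "OUMA": 2 * R + 1, "OUMVA": 3 * R}
        return counts[self.name] + (1 if self.root == "free" else 0)


@dataclasses.dataclass
class OUParams:
    """Concrete parameter values for a spec on R regimes.

    ``theta``/``alpha``/``sigma2`` are length-R arrays (broadcast when the
    spec shares them); BM models carry ``theta=None`` and ``alpha`` zero.
    ``root_value`` is the trait value at the root.
    """

    theta: np.ndarray | None
    alpha: np.ndarray
    sigma2: np.ndarray
    root_value: float

    def __post_init__(self):
        if self.theta is not None:
            self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if np.any(self.alpha < 0):
            raise OUError("alpha must be >= 0")
        if np.any(self.sigma2 <= 0):
            raise OUError("sigma2 must be > 0")


def branch_transition(x_parent: float, theta: float, alpha: float,
                      sigma2: float, t: float) -> tuple[float, float]:
    """Conditional mean and variance of the OU transition over a branch.

    mean = theta + (x_parent - theta) e^(-alpha t);
    var  = sigma2 (1 - e^(-2 alpha t)) / (2 alpha), with the BM limit
    sigma2 * t as alpha t -> 0 (series-safe via expm1).
    """
    if t < 0:
        raise OUError("negative branch length")
    if alpha * t < 1e-12:
        return (x_parent if alpha == 0 else
                theta + (x_parent - theta) * np.exp(-alpha * t),
                sigma2 * t)
    mean = theta + (x_parent - theta) * np.exp(-alpha * t)
    var = sigma2 * (-np.expm1(-2.0 * alpha * t)) / (2.0 * alpha)
    return mean, var


def _branch_arrays(tree: Phylogeny, painting: RegimePainting, spec: OUModelSpec,
                   params: OUParams):
    """Per-node (branch-above) alpha, sigma2, theta arrays."""
    R = painting.n_regimes
    reg = painting.regime

    def expand(arr, per_regime):
        a = np.atleast_1d(arr)
        if not per_regime or a.size != R:
            return np.full(R, float(a[0]))
        return a

    alpha_r = (expand(params.alpha, spec.alpha_per_regime)
               if spec.has_alpha else np.zeros(R))
    sigma_r = expand(params.sigma2, spec.sigma_per_regime)
    theta_r = (expand(params.theta, spec.theta_per_regime)
               if params.theta is not None else np.zeros(R))
    return alpha_r[reg], sigma_r[reg], theta_r[reg]


def _node_moments(tree: Phylogeny, alpha_b: np.ndarray, sigma_b: np.ndarray,
                  reg: np.ndarray, n_regimes: int):
    """Pre-order accumulation of the lineage decay D, variance V and the
    linear theta-design W (coefficients of each regime optimum in the mean)."""
    n = tree.n_nodes
    D = np.ones(n)
    V = np.zeros(n)
    W = np.zeros((n, n_regimes))
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        a, t = alpha_b[v], tree.lengths[v]
        e = np.exp(-a * t)
        D[v] = D[p] * e
        vb = sigma_b[v] * t if a * t < 1e-12 else \
            sigma_b[v] * (-np.expm1(-2.0 * a * t)) / (2.0 * a)
        V[v] = V[p] * e * e + vb
        W[v] = W[p] * e
        if a * t >= 1e-12:
            W[v, reg[v]] += -np.expm1(-a * t)
    return D, V, W


def _tip_order(tree: Phylogeny, traits: dict) -> np.ndarray:
    from .tree import normalize_name

    tmap = {normalize_name(k): float(v) for k, v in traits.items()}
    missing = [lab for lab in tree.tip_labels if lab not in tmap]
    if missing:
        raise OUError(f"traits missing for tips: {missing[:5]}")
    return np.array([tmap[lab] for lab in tree.tip_labels])


def _mean_cov(tree: Phylogeny, painting: RegimePainting, spec: OUModelSpec,
              params: OUParams):
    alpha_b, sigma_b, theta_b = _branch_arrays(tree, painting, spec, params)
    D, V, W = _node_moments(tree, alpha_b, sigma_b, painting.regime,
                            painting.n_regimes)
    tips = tree.tips
    M = tree.mrca_matrix()
    Dt = D[tips]
    C = V[M] * np.outer(Dt, Dt) / np.square(D[M])
    R = painting.n_regimes

    if spec.has_alpha and params.theta is not None:
        th = np.atleast_1d(params.theta)
        theta_r = (th if spec.theta_per_regime and th.size == R
                   else np.full(R, float(th[0])))
        mean = W[tips] @ theta_r + Dt * params.root_value
    else:
        mean = Dt * params.root_value  # BM: D == 1 everywhere
    return mean, C


def ou_likelihood(tree: Phylogeny, painting: RegimePainting, spec: OUModelSpec,
                  params: OUParams, traits: dict, method: str = "mvn") -> float:
    """Log-likelihood of tip traits under the painted OU/BM model.

    ``method='mvn'`` builds the exact multivariate normal (piecewise
    attraction decay along paths); ``method='bp'`` runs Gaussian belief
    propagation with the branch transition kernels.  The two agree to
    numerical precision and serve as mutual checks.
    """
    y = _tip_order(tree, traits)
    if method == "mvn":
        mean, C = _mean_cov(tree, painting, spec, params)
        return _mvn_loglik(y, mean, C)
    if method == "bp":
        return _bp_loglik(tree, painting, spec, params, y)
    raise OUError(f"unknown method {method!r}")


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, C: np.ndarray) -> float:
    from scipy.linalg import cho_factor, cho_solve

    n = y.size
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise OUError(
            f"singular trait covariance (cond={np.linalg.cond(C):.3g})"
        ) from exc
    r = y - mean
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def _bp_loglik(tree: Phylogeny, painting: RegimePainting, spec: OUModelSpec,
               params: OUParams, y: np.ndarray) -> float:
    alpha_b, sigma_b, theta_b = _branch_arrays(tree, painting, spec, params)
    tips = tree.tips
    yv = {int(t): y[i] for i, t in enumerate(tips)}

    def combine(msgs):
        logc, mu, var = msgs[0]
        for lc, m2, v2 in msgs[1:]:
            logc += lc + _norm_logpdf(mu, m2, var + v2)
            if var + v2 > 0:
                w = v2 / (var + v2)
                mu = w * mu + (1 - w) * m2
                var = var * v2 / (var + v2)
        return logc, mu, var

    def to_parent(v, belief):
        logc, mu, var = belief
        a, t = alpha_b[v], tree.lengths[v]
        th = theta_b[v]
        e = np.exp(-a * t)
        vb = sigma_b[v] * t if a * t < 1e-12 else \
            sigma_b[v] * (-np.expm1(-2 * a * t)) / (2 * a)
        return (logc + np.log(1.0 / e),
                th + (mu - th) / e,
                (var + vb) / (e * e))

    msg: dict[int, tuple] = {}
    for v in tree.postorder():
        if v == tree.root:
            continue
        if not tree.children[v]:
            belief = (0.0, yv[v], 0.0)
        else:
            belief = combine([msg[c] for c in tree.children[v]])
        msg[v] = to_parent(v, belief)
    logc, mu, var = combine([msg[c] for c in tree.children[tree.root]])
    return float(logc + _norm_logpdf(params.root_value, mu, var))


def _norm_logpdf(x, m, v):
    if v <= 0:
        return 0.0 if x == m else -np.inf
    return -0.5 * (np.log(2 * np.pi * v) + (x - m) ** 2 / v)


def simulate_traits(tree: Phylogeny, painting: RegimePainting, spec: OUModelSpec,
                    params: OUParams, seed=None) -> dict[str, float]:
    """Simulate tip traits by the pre-order recursion of branch transitions.

    The root value is ``params.root_value`` (for the tied-root rule, pass the
    root-regime optimum there).  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    alpha_b, sigma_b, theta_b = _branch_arrays(tree, painting, spec, params)
    x = np.zeros(tree.n_nodes)
    x[tree.root] = params.root_value
    for v in tree.preorder():
        if v == tree.root:
            continue
        mean, var = branch_transition(x[tree.parent[v]], theta_b[v],
                                      alpha_b[v], sigma_b[v], tree.lengths[v])
        x[v] = mean + np.sqrt(var) * rng.standard_normal()
    return {tree.labels[t]: float(x[t]) for t in tree.tips}


# -- maximum-likelihood fitting -------------------------------------------


@dataclasses.dataclass
class OUFit:
    """A fitted trait-evolution model."""

    spec: OUModelSpec
    alphabet: tuple[str, ...]
    theta: np.ndarray | None
    alpha: np.ndarray
    sigma2: np.ndarray
    root_value: float
    lnL: float
    n_params: int
    n: int
    converged: bool
    starts: list
    aic_weight: float | None = None
    _data_key: tuple = ()

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnL

    @property
    def aicc(self) -> float:
        d = self.n - self.n_params - 1
        if d <= 0:
            return np.inf
        return self.aic + 2.0 * self.n_params * (self.n_params + 1) / d

    @property
    def params(self) -> OUParams:
        return OUParams(self.theta, self.alpha, self.sigma2, self.root_value)

    def theta_backtransformed(self) -> np.ndarray | None:
        """Optima on the measurement (e.g. Mbp) scale for log10-scale fits."""
        return None if self.theta is None else 10.0 ** self.theta

    def summary(self) -> dict:
        out = {"model": self.spec.name, "lnL": self.lnL, "p": self.n_params,
               "n": self.n, "AIC": self.aic, "AICc": self.aicc,
               "AICw": self.aic_weight, "converged": self.converged,
               "root_value": self.root_value}
        R = len(self.alphabet)
        for i, a in enumerate(self.alphabet):
            out[f"theta_{a}"] = None if self.theta is None else float(
                self.theta[i if self.theta.size == R else 0])
            out[f"alpha_{a}"] = float(
                self.alpha[i if self.alpha.size == R else 0])
            out[f"sigma2_{a}"] = float(
                self.sigma2[i if self.sigma2.size == R else 0])
        return out


def _single_regime_painting(painting: RegimePainting) -> RegimePainting:
    return RegimePainting(np.zeros_like(painting.regime), ("all",), 0)


def _phi_layout(spec: OUModelSpec, R: int):
    """Outer optimisation vector: log alphas, then log sigma ratios (first
    regime's sigma fixed as the profiled scale)."""
    n_alpha = (R if spec.alpha_per_regime else 1) if spec.has_alpha else 0
    n_ratio = R - 1 if spec.sigma_per_regime else 0
    return n_alpha, n_ratio


def _assemble(tree, painting, spec, phi, y, return_fit=False):
    """Profile likelihood at structural parameters phi.

    theta (or the BM root mean) enters the mean linearly and is solved by
    GLS; the overall sigma^2 scale is profiled analytically.
    """
    from scipy.linalg import cho_factor, cho_solve

    R = painting.n_regimes
    n_alpha, n_ratio = _phi_layout(spec, R)
    alpha = np.exp(phi[:n_alpha]) if n_alpha else np.zeros(1)
    ratios = np.ones(R)
    if n_ratio:
        ratios[1:] = np.exp(phi[n_alpha:n_alpha + n_ratio])
    sigma_unit = ratios if spec.sigma_per_regime else np.ones(1)

    unit = OUParams(np.zeros(R) if spec.has_alpha else None,
                    alpha if spec.has_alpha else np.zeros(1),
                    sigma_unit, 0.0)
    alpha_b, sigma_b, _ = _branch_arrays(tree, painting, spec, unit)
    D, V, W = _node_moments(tree, alpha_b, sigma_b, painting.regime, R)
    tips = tree.tips
    M = tree.mrca_matrix()
    Dt = D[tips]
    C0 = V[M] * np.outer(Dt, Dt) / np.square(D[M])

    # mean design
    if spec.has_alpha:
        X = W[tips].copy()
        if not spec.theta_per_regime:
            X = X.sum(axis=1, keepdims=True)
        if spec.root == "tied":
            col = painting.root_regime if spec.theta_per_regime else 0
            X[:, col] += Dt
        else:
            X = np.column_stack([X, Dt])
    else:
        X = np.ones((tips.size, 1))

    n = y.size
    try:
        cf = cho_factor(C0, lower=True)
    except np.linalg.LinAlgError:
        return None
    Xw = cho_solve(cf, X)
    XtCiX = X.T @ Xw
    XtCiy = X.T @ cho_solve(cf, y)
    try:
        beta = np.linalg.solve(XtCiX, XtCiy)
    except np.linalg.LinAlgError:
        return None
    r = y - X @ beta
    quad = float(r @ cho_solve(cf, r))
    # near-perfect fits can round quad to <= 0; floor it at machine noise
    quad = max(quad, 1e-25 * max(1.0, float(y @ y)))
    s2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    lnL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    if not return_fit:
        return lnL

    sigma2 = s2 * (ratios if spec.sigma_per_regime else np.ones(1))
    if spec.has_alpha:
        if spec.root == "free":
            theta_hat, root_value = beta[:-1], float(beta[-1])
        else:
            theta_hat = beta
            col = painting.root_regime if spec.theta_per_regime else 0
            root_value = float(beta[col])
        theta = theta_hat if spec.theta_per_regime else np.full(1, theta_hat[0])
    else:
        theta, root_value = None, float(beta[0])
    return lnL, OUParams(theta, alpha if spec.has_alpha else np.zeros(1),
                         sigma2, root_value)


def fit_ou(tree: Phylogeny, painting: RegimePainting, spec, traits: dict,
           n_starts: int = 8, seed: int = 0,
           warm_starts: list[np.ndarray] | None = None) -> OUFit:
    """Maximum-likelihood fit of one of the seven models.

    alpha and the sigma^2 ratios are optimised on log scale from ``n_starts``
    dispersed initial points (deterministic under ``seed``); theta and the
    overall sigma^2 scale are profiled analytically.  alpha is bounded in
    [1e-8, 50/tree height].
    """
    if isinstance(spec, str):
        spec = OUModelSpec(spec)
    pane = painting if spec.multi_regime else _single_regime_painting(painting)
    R = pane.n_regimes
    if spec.multi_regime:
        counts = pane.branch_counts(tree)
        absent = [k for k, c in counts.items() if c == 0]
        if absent:
            raise OUError(
                f"regime(s) {absent} absent from the painting: per-regime "
                "parameters are unidentifiable; restrict the alphabet")
        small = [k for k, c in counts.items() if c < 2]
        if small:
            warnings.warn(f"regime(s) on < 2 branches: {small}", stacklevel=2)
    y = _tip_order(tree, traits)
    n = y.size
    if n < R + 2:
        raise OUError("too few tips for the number of regimes")
    if np.var(y) <= 0:
        raise OUError("trait variance is zero")

    height = tree.height
    lo_a, hi_a = np.log(1e-8), np.log(50.0 / height)
    n_alpha, n_ratio = _phi_layout(spec, R)
    dim = n_alpha + n_ratio

    def neg(phi):
        phi = np.asarray(phi, dtype=float)
        phi_c = phi.copy()
        phi_c[:n_alpha] = np.clip(phi_c[:n_alpha], lo_a, hi_a)
        phi_c[n_alpha:] = np.clip(phi_c[n_alpha:], -20, 20)
        val = _assemble(tree, pane, spec, phi_c, y)
        pen = 1e3 * float(np.sum((phi - phi_c) ** 2))
        return (1e12 if val is None else -val) + pen

    rng = np.random.default_rng(seed)
    starts = []
    if dim > 0:
        base = np.concatenate([
            np.full(n_alpha, np.log(np.log(2.0) / (0.5 * height))),
            np.zeros(n_ratio)])
        starts.append(base)
        for _ in range(max(0, n_starts - 1)):
            starts.append(np.concatenate([
                rng.uniform(np.log(0.05 / height), np.log(20.0 / height),
                            n_alpha),
                rng.normal(0.0, 1.0, n_ratio)]))
        if warm_starts:
            starts.extend(np.asarray(w, dtype=float) for w in warm_starts)

    trace = []
    best_phi, best_val = None, np.inf
    if dim == 0:
        best_phi = np.zeros(0)
        best_val = neg(best_phi)
        trace.append((best_phi, -best_val))
        converged = best_val < 1e11
    else:
        converged = False
        for s in starts:
            if dim == 1:
                res = optimize.minimize_scalar(
                    lambda x: neg(np.array([x])),
                    bounds=(lo_a if n_alpha else -20,
                            hi_a if n_alpha else 20),
                    method="bounded", options={"xatol": 1e-7})
                phi, val, ok = np.array([res.x]), res.fun, res.success
            else:
                res = optimize.minimize(neg, s, method="Nelder-Mead",
                                        options={"xatol": 1e-6, "fatol": 1e-8,
                                                 "maxiter": 400 * dim})
                phi, val, ok = res.x, res.fun, True
            trace.append((phi, -val))
            if val < best_val:
                best_phi, best_val, converged = phi, val, ok or converged
            if dim == 1:
                break  # bounded scalar search is global enough on [lo, hi]
        if dim > 1 and best_val < 1e11:
            res = optimize.minimize(
                neg, best_phi, method="L-BFGS-B",
                bounds=[(lo_a, hi_a)] * n_alpha + [(-20, 20)] * n_ratio)
            if res.fun <= best_val:
                best_phi, best_val = res.x, res.fun
            converged = True
    if best_val >= 1e11:
        raise OUError(f"all optimisation starts failed for {spec.name}")

    best_phi = np.asarray(best_phi, dtype=float)
    best_phi[:n_alpha] = np.clip(best_phi[:n_alpha], lo_a, hi_a)
    lnL, params = _assemble(tree, pane, spec, best_phi, y, return_fit=True)
    if n_alpha and np.any(best_phi[:n_alpha] > hi_a - 1e-6):
        warnings.warn(f"{spec.name}: alpha at upper bound (near-white-noise)",
                      stacklevel=2)
    fit = OUFit(spec=spec, alphabet=pane.alphabet, theta=params.theta,
                alpha=params.alpha, sigma2=params.sigma2,
                root_value=params.root_value, lnL=lnL,
                n_params=spec.n_params(R), n=n, converged=converged,
                starts=trace, _data_key=(n, float(np.sum(y)), float(np.sum(y**2))))
    return fit


def fit_all_models(tree, painting, traits, models=MODEL_NAMES, n_starts=8,
                   seed=0, criterion="AICc", root="tied"):
    """Fit the seven-model set and attach AIC weights; returns fits sorted
    by the criterion (best first)."""
    fits = []
    for i, name in enumerate(models):
        fits.append(fit_ou(tree, painting, OUModelSpec(name, root=root), traits,
                           n_starts=n_starts, seed=seed + 1000 * i))
    aic_weights(fits, criterion=criterion)
    fits.sort(key=lambda f: f.aicc if criterion == "AICc" else f.aic)
    return fits


def aic_weights(fits, criterion: str = "AICc") -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    if len(fits) < 2:
        raise OUError("need >= 2 fits to compute weights")
    keys = {f._data_key for f in fits if f._data_key}
    if len(keys) > 1:
        raise OUError("fits were computed on different data")
    crit = np.array([f.aicc if criterion == "AICc" else f.aic for f in fits])
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    for f, wi in zip(fits, w):
        f.aic_weight = float(wi)
    return w


def theta_standard_errors(tree, painting, fit: OUFit, traits: dict,
                          eps: float = 1e-4) -> np.ndarray | None:
    """Standard errors of the regime optima from the observed information
    (numeric Hessian of the log-likelihood in the full natural parameters)."""
    if fit.theta is None:
        return None
    pane = painting if fit.spec.multi_regime else _single_regime_painting(painting)
    R = pane.n_regimes
    theta = fit.theta if fit.theta.size == R else np.full(1, fit.theta[0])
    k_t = theta.size
    la = np.log(fit.alpha if fit.spec.has_alpha else [1.0])
    ls = np.log(fit.sigma2)
    x0 = np.concatenate([theta, np.atleast_1d(la), np.atleast_1d(ls)])

    def lnl(x):
        th = x[:k_t]
        al = np.exp(x[k_t:k_t + la.size])
        s2 = np.exp(x[k_t + la.size:])
        root = (th[pane.root_regime if fit.spec.theta_per_regime else 0]
                if fit.spec.root == "tied" else fit.root_value)
        p = OUParams(th, al if fit.spec.has_alpha else np.zeros(1), s2, root)
        try:
            return ou_likelihood(tree, pane, fit.spec, p, traits)
        except OUError:
            return -1e12

    d = x0.size
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            H[i, j] = H[j, i] = (
                lnl(x0 + ei + ej) - lnl(x0 + ei - ej)
                - lnl(x0 - ei + ej) + lnl(x0 - ei - ej)
            ) / (4 * eps * eps)
    cov = np.linalg.pinv(-H)
    se = np.sqrt(np.clip(np.diag(cov)[:k_t], 0, None))
    return se
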