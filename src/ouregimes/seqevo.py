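"""Nucleotide substitution models with discrete-Gamma rate heterogeneity,
pruning likelihoods, BIC model selection and marginal ancestral sequence
reconstruction.

Branch lengths here are expected in substitutions/site; when the input tree
is in relative time units a single global rescaling factor can be estimated
by maximum likelihood (``optimize_scale``).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .tree import Phylogeny

NUC = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUC)}

# IUPAC ambiguity -> compatible bases (gap / N fully missing)
AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}

__all__ = [
    "SubstitutionModelSpec",
    "Alignment",
    "AncestralReconstruction",
    "discrete_gamma_rates",
    "site_likelihood",
    "select_model_bic",
    "marginal_asr",
    "mk_rate_matrix",
    "SeqEvoError",
]


class SeqEvoError(ValueError):
    pass


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Equal-probability discrete Gamma category rates, mean-of-band
    convention (as in MEGA/PAML's "mean" discretisation); rates average 1."""
    if shape <= 0 or k < 1:
        raise SeqEvoError("gamma shape and k must be positive")
    if k == 1:
        return np.ones(1)
    # X ~ Gamma(shape, scale=1/shape), band means via the Gamma(shape+1) CDF
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    upper = stats.gamma.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = k * np.diff(upper)
    return rates / rates.mean()


def mk_rate_matrix(n_states: int, allowed: list[tuple[int, int]] | None = None,
                   rate: float = 1.0) -> np.ndarray:
    """k-state Markov rate matrix; symmetric Mk by default or restricted to
    the given directed transitions (used for regime characters)."""
    Q = np.zeros((n_states, n_states))
    pairs = allowed
    if pairs is None:
        pairs = [(i, j) for i in range(n_states) for j in range(n_states) if i != j]
    for i, j in pairs:
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclasses.dataclass
class SubstitutionModelSpec:
    """DNA substitution model: JC, K2P or HKY, optionally +Gamma.

    The rate matrix is normalised to one expected substitution per site per
    unit branch length at stationarity.
    """

    family: str = "JC"
    gamma: bool = False
    shape: float = 1.0
    k: int = 4
    kappa: float = 2.0
    freqs: np.ndarray | None = None  # stationary frequencies (HKY); JC/K2P uniform

    def __post_init__(self):
        if self.family not in ("JC", "K2P", "HKY"):
            raise SeqEvoError(f"unknown model family {self.family!r}")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)
            self.freqs = self.freqs / self.freqs.sum()

    @property
    def name(self) -> str:
        return self.family + ("+G" if self.gamma else "")

    @property
    def pi(self) -> np.ndarray:
        if self.family == "HKY" and self.freqs is not None:
            return self.freqs
        return np.full(4, 0.25)

    def rate_matrix(self) -> np.ndarray:
        pi = self.pi
        kappa = self.kappa if self.family in ("K2P", "HKY") else 1.0
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(Q)))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.shape, self.k) if self.gamma else np.ones(1)

    def n_free_params(self) -> int:
        p = 0
        if self.gamma:
            p += 1
        if self.family in ("K2P", "HKY"):
            p += 1
        if self.family == "HKY":
            p += 3
        return p


@dataclasses.dataclass
class Alignment:
    """Aligned sequences, one per species; common length enforced."""

    sequences: dict[str, str]

    def __post_init__(self):
        seqs = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(v) for v in seqs.values()}
        if len(lengths) != 1:
            raise SeqEvoError("sequences differ in length")
        bad = {
            ch for v in seqs.values() for ch in v if ch not in AMBIG
        }
        if bad:
            raise SeqEvoError(f"invalid characters in alignment: {sorted(bad)}")
        self.sequences = seqs

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def partials(self, species: str) -> np.ndarray:
        """L x 4 matrix of tip partial likelihoods (ambiguities as 0/1)."""
        seq = self.sequences[species]
        out = np.zeros((len(seq), 4))
        for i, ch in enumerate(seq):
            for b in AMBIG[ch]:
                out[i, NUC_INDEX[b]] = 1.0
        return out

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        from Bio import SeqIO
        from .tree import normalize_name

        seqs = {}
        for rec in SeqIO.parse(path, "fasta"):
            seqs[normalize_name(rec.id)] = str(rec.seq)
        if not seqs:
            raise SeqEvoError(f"no FASTA records in {path}")
        return cls(seqs)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


# -- pruning likelihood ----------------------------------------------------


def _transition_matrices(tree: Phylogeny, Q: np.ndarray, rates: np.ndarray,
                         scale: float) -> np.ndarray:
    """P[c, node] = expm(Q * rate_c * length_node * scale), via eigen."""
    lam, U = np.linalg.eig(Q)
    Uinv = np.linalg.inv(U)
    n = tree.n_nodes
    P = np.empty((rates.size, n, Q.shape[0], Q.shape[0]))
    for ci, r in enumerate(rates):
        for v in range(n):
            t = 0.0 if v == tree.root else tree.lengths[v] * r * scale
            M = (U * np.exp(lam * t)) @ Uinv
            P[ci, v] = np.clip(M.real, 0.0, None)
    return P


def _tip_partials(tree: Phylogeny, alignment: Alignment) -> np.ndarray:
    idx = tree.tip_index()
    missing = [s for s in alignment.species if s not in idx]
    if missing:
        raise SeqEvoError(
            f"alignment species not on tree (prune first?): {missing[:5]}"
        )
    absent = [lab for lab in idx if lab not in alignment.sequences]
    if absent:
        raise SeqEvoError(f"tree tips without sequence: {absent[:5]}")
    L = alignment.length
    partials = np.ones((tree.n_nodes, L, 4))
    for lab, node in idx.items():
        partials[node] = alignment.partials(lab)
    return partials


def _down_pass(tree: Phylogeny, tip_part: np.ndarray, P: np.ndarray):
    """Per category: conditional likelihood arrays (node, site, state) and
    per-site log scaling factors."""
    n_cat = P.shape[0]
    L = tip_part.shape[1]
    down = np.empty((n_cat, tree.n_nodes, L, 4))
    logscale = np.zeros((n_cat, L))
    post = tree.postorder()
    for c in range(n_cat):
        for v in post:
            if not tree.children[v]:
                down[c, v] = tip_part[v]
            else:
                acc = np.ones((L, 4))
                for ch in tree.children[v]:
                    acc = acc * (down[c, ch] @ P[c, ch].T)
                mx = acc.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                logscale[c] += np.log(mx)
                down[c, v] = acc / mx[:, None]
    return down, logscale


def site_likelihood(tree: Phylogeny, alignment: Alignment,
                    model: SubstitutionModelSpec, scale: float = 1.0):
    """Felsenstein pruning: per-site log-likelihoods and their total.

    With +Gamma the site likelihood is the equal-weight mixture over the
    discrete category rates.
    """
    Q = model.rate_matrix()
    rates = model.category_rates()
    P = _transition_matrices(tree, Q, rates, scale)
    tip_part = _tip_partials(tree, alignment)
    down, logscale = _down_pass(tree, tip_part, P)
    pi = model.pi
    # per category per site: log( pi . down_root ) + logscale
    root_like = down[:, tree.root] @ pi  # (cat, site)
    with np.errstate(divide="ignore"):
        cat_logs = np.log(root_like) + logscale
    site_logs = logsumexp(cat_logs, axis=0) - np.log(rates.size)
    if not np.all(np.isfinite(site_logs)):
        bad = int(np.flatnonzero(~np.isfinite(site_logs))[0])
        raise SeqEvoError(f"non-finite likelihood at site {bad}")
    return site_logs, float(site_logs.sum())


def optimize_scale(tree, alignment, model, bounds=(1e-4, 100.0)) -> float:
    """ML global rescaling of branch lengths (time units -> subst/site)."""

    def nll(logs):
        return -site_likelihood(tree, alignment, model, float(np.exp(logs)))[1]

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    return float(np.exp(res.x))


def select_model_bic(tree: Phylogeny, alignment: Alignment,
                     candidates: list[SubstitutionModelSpec] | None = None,
                     optimize_branch_scale: bool = True):
    """Fit each candidate by ML and rank by BIC = -2 lnL + p ln(n_sites).

    Free parameters per candidate: Gamma shape, kappa (K2P/HKY), 3 base
    frequencies (HKY, counted from the data), plus one global branch-length
    scale when ``optimize_branch_scale`` is on.
    """
    if candidates is None:
        candidates = default_candidates(alignment)
    if len(candidates) < 2:
        raise SeqEvoError("need at least 2 candidate models")
    n = alignment.length
    rows = []
    for spec in candidates:
        spec = dataclasses.replace(spec)
        free: list[str] = []
        if spec.gamma:
            free.append("shape")
        if spec.family in ("K2P", "HKY"):
            free.append("kappa")
        x0 = np.log([getattr(spec, f) for f in free]) if free else np.array([])
        if optimize_branch_scale:
            free.append("scale")
            x0 = np.append(x0, 0.0)
        converged = True

        def nll(x, spec=spec, free=free):
            s = dataclasses.replace(spec)
            scale = 1.0
            for name, val in zip(free, np.exp(x)):
                if name == "scale":
                    scale = val
                else:
                    setattr(s, name, float(val))
            try:
                return -site_likelihood(tree, alignment, s, scale)[1]
            except SeqEvoError:
                return 1e12

        if free:
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-7,
                                             "maxiter": 2000})
            converged = bool(res.success)
            best_x = res.x
            lnl = -float(res.fun)
        else:
            best_x = x0
            lnl = -nll(x0)
        fitted = dataclasses.replace(spec)
        scale = 1.0
        for name, val in zip(free, np.exp(best_x)):
            if name == "scale":
                scale = float(val)
            else:
                setattr(fitted, name, float(val))
        p = fitted.n_free_params() + (1 if optimize_branch_scale else 0)
        rows.append({
            "model": fitted.name, "spec": fitted, "scale": scale,
            "lnL": lnl, "n_params": p, "BIC": -2.0 * lnl + p * np.log(n),
            "converged": converged,
        })
        if not converged:
            warnings.warn(f"optimizer did not report convergence for {fitted.name}",
                          stacklevel=2)
    rows.sort(key=lambda r: r["BIC"])
    return rows


def default_candidates(alignment: Alignment) -> list[SubstitutionModelSpec]:
    """JC, K2P, HKY with and without Gamma; HKY frequencies counted."""
    counts = np.zeros(4)
    for seq in alignment.sequences.values():
        for ch in seq:
            if ch in NUC_INDEX:
                counts[NUC_INDEX[ch]] += 1
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    out = []
    for fam in ("JC", "K2P", "HKY"):
        for g in (False, True):
            out.append(SubstitutionModelSpec(
                family=fam, gamma=g, shape=0.5,
                freqs=freqs if fam == "HKY" else None))
    return out


# -- marginal ancestral reconstruction ------------------------------------


@dataclasses.dataclass
class AncestralReconstruction:
    """Marginal posteriors over {A,C,G,T} per node and site, with MAP states.

    ``posterior[v]`` is an L x 4 array; ``map_state[v]`` the argmax string;
    ``tie[v]`` flags sites whose MAP was resolved by alphabet order.
    """

    posterior: dict[int, np.ndarray]
    map_state: dict[int, str]
    tie: dict[int, np.ndarray]
    log_likelihood: float

    def map_sequence(self, node: int) -> str:
        return self.map_state[node]


def marginal_asr(tree: Phylogeny, alignment: Alignment,
                 model: SubstitutionModelSpec, scale: float = 1.0
                 ) -> AncestralReconstruction:
    """Inside-outside marginal posteriors at every internal node, mixed over
    Gamma categories; MAP ties broken by A<C<G<T and flagged."""
    Q = model.rate_matrix()
    rates = model.category_rates()
    P = _transition_matrices(tree, Q, rates, scale)
    tip_part = _tip_partials(tree, alignment)
    down, logscale = _down_pass(tree, tip_part, P)
    pi = model.pi
    n_cat, L = rates.size, alignment.length

    root_like = down[:, tree.root] @ pi
    with np.errstate(divide="ignore"):
        cat_logs = np.log(root_like) + logscale          # (cat, site)
    site_logs = logsumexp(cat_logs, axis=0) - np.log(n_cat)
    cat_weight = np.exp(cat_logs - logsumexp(cat_logs, axis=0))  # (cat, site)

    # outside messages ("up"): up[c, v, site, state] excludes v's subtree
    up = np.empty((n_cat, tree.n_nodes, L, 4))
    for c in range(n_cat):
        up[c, tree.root] = pi[None, :]
        for v in tree.preorder():
            for ch in tree.children[v]:
                sib = np.ones((L, 4))
                for other in tree.children[v]:
                    if other is not ch:
                        sib = sib * (down[c, other] @ P[c, other].T)
                msg = up[c, v] * sib
                up[c, ch] = msg @ P[c, ch]
    posterior: dict[int, np.ndarray] = {}
    map_state: dict[int, str] = {}
    ties: dict[int, np.ndarray] = {}
    for v in range(tree.n_nodes):
        joint = up[:, v] * down[:, v]                    # (cat, site, 4)
        tot = joint.sum(axis=2)
        tot = np.where(tot > 0, tot, 1.0)
        post = np.einsum("cs,csk->sk", cat_weight, joint / tot[:, :, None])
        post = post / post.sum(axis=1, keepdims=True)
        posterior[v] = post
        near_max = post >= post.max(axis=1, keepdims=True) - 1e-12
        best = near_max.argmax(axis=1)  # first True = alphabet-order tie break
        tie = near_max.sum(axis=1) > 1
        map_state[v] = "".join(NUC[b] for b in best)
        ties[v] = tie
    return AncestralReconstruction(posterior, map_state, ties, float(site_logs.sum()))


# -- brute-force oracle (tiny trees; used for validation) ------------------


def brute_force_loglik(tree: Phylogeny, alignment: Alignment,
                       model: SubstitutionModelSpec, scale: float = 1.0):
    """Likelihood by explicit enumeration over internal-node states.

    Exponential in the number of internal nodes; intended for <= 6-tip trees.
    Returns (site_logs, total).
    """
    Q = model.rate_matrix()
    rates = model.category_rates()
    P = _transition_matrices(tree, Q, rates, scale)
    tip_part = _tip_partials(tree, alignment)
    pi = model.pi
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    L = alignment.length
    site_like = np.zeros(L)
    for c in range(rates.size):
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(internals, states))
            w = np.full(L, pi[assign[tree.root]])
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                ps = assign[tree.parent[v]]
                if tree.children[v]:
                    w = w * P[c, v][ps, assign[v]]
                else:
                    w = w * (tip_part[v] @ P[c, v][ps])
            site_like += w / rates.size
    site_logs = np.log(site_like)
    return site_logs, float(site_logs.sum())


def brute_force_marginal(tree: Phylogeny, alignment: Alignment,
                         model: SubstitutionModelSpec, node: int,
                         scale: float = 1.0) -> np.ndarray:
    """Marginal posterior at one internal node by enumeration (oracle)."""
    Q = model.rate_matrix()
    rates = model.category_rates()
    P = _transition_matrices(tree, Q, rates, scale)
    tip_part = _tip_partials(tree, alignment)
    pi = model.pi
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    L = alignment.length
    acc = np.zeros((L, 4))
    for c in range(rates.size):
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(internals, states))
            w = np.full(L, pi[assign[tree.root]])
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                ps = assign[tree.parent[v]]
                if tree.children[v]:
                    w = w * P[c, v][ps, assign[v]]
                else:
                    w = w * (tip_part[v] @ P[c, v][ps])
            acc[:, assign[node]] += w / rates.size
    return acc / acc.sum(axis=1, keepdims=True)
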