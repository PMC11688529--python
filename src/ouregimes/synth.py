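"""Synthetic studies: Yule trees, Mk regime histories, COX-like alignments
and multi-regime OU traits, with a truth ledger for recovery scoring.

The generator emulates the structure of the Lentibulariaceae dataset: a
relative-time ultrametric phylogeny, a three-state COX regime history with
the documented shape (LS at the root, a CC gain, CS arising from CC, and an
optional CC->LS reversal), a 237-bp COX subunit-I-like alignment whose two
mapped codons encode each tip's regime, and log10-scale genome-size and
mean-chromosome-size traits evolving under a multi-regime OU process whose
default optima sit at the study-scale values (597/210/51.09 Mbp genomes,
55.41/12.21/2.18 Mbp chromosomes).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .tree import (Phylogeny, RegimePainting, DEFAULT_REGIMES, paint_regimes,
                   write_newick)
from .seqevo import Alignment, SubstitutionModelSpec, NUC, discrete_gamma_rates
from .cox import DEFAULT_SITE_MAP
from .oumodels import OUModelSpec, OUParams, simulate_traits

__all__ = ["SyntheticStudyConfig", "SyntheticStudy", "simulate_yule_tree",
           "simulate_regime_history", "simulate_alignment",
           "simulate_alignment_with_cox_site", "simulate_regime_traits",
           "build_synthetic_study"]

# synonymous codon pools for the two mutation-site residues
_CODONS = {"K": ("AAA", "AAG"), "S": ("TCT", "TCC", "TCA", "TCG"),
           "C": ("TGT", "TGC")}
_STATE_AA = {"LS": ("K", "S"), "CC": ("C", "C"), "CS": ("C", "S")}


@dataclasses.dataclass
class SyntheticStudyConfig:
    """Generating conditions of a synthetic study.

    Defaults mirror the real study's scale: ~112 species with genome sizes
    (a fraction of which also have chromosome counts), a height-1 relative
    time tree, a 237-site alignment, and OU optima at the study estimates
    on the log10-Mbp scale.  ``q`` is the regime transition rate per unit
    time; ``alpha``/``sigma2`` set the attraction and diffusion of the OU
    trait process (half-life ~0.23 tree heights, stationary s.d. ~0.09
    log10 units by default - well-separated regimes, as in the study).
    """

    n_tips: int = 112
    birth_rate: float = 1.0
    height: float = 1.0
    q: float = 0.4
    allow_reversal: bool = True
    symmetric_mk: bool = False
    L: int = 237
    site_map: tuple = DEFAULT_SITE_MAP
    gamma_shape: float = 0.5
    subst_scale: float = 0.3     # substitutions/site per unit time
    trait_model: str = "OUM"
    theta_genome: tuple = (np.log10(597.0), np.log10(210.0), np.log10(51.09))
    theta_chrom: tuple = (np.log10(55.41), np.log10(12.21), np.log10(2.18))
    alpha: float = 3.0
    sigma2: float = 0.05
    chrom_fraction: float = 0.6  # fraction of species with chromosome data
    n_extra_species: int = 15    # trait-table species absent from the tree
    min_regime_tips: int | None = None  # default: max(4, 5% of tips)
    seed: int = 0

    def __post_init__(self):
        if self.min_regime_tips is None:
            # the rarest regime in the real data (CS) holds ~6% of species
            self.min_regime_tips = max(4, self.n_tips // 20)
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.L < 6:
            raise ValueError("alignment must hold at least two codons")
        if self.q < 0 or self.birth_rate <= 0:
            raise ValueError("rates must be non-negative")


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None,
                       height: float | None = 1.0) -> Phylogeny:
    """Pure-birth tree conditioned on n tips, optionally rescaled to a fixed
    height; tips are labelled sp0001, sp0002, ...

    The process starts at the crown (two lineages at the root, no stem);
    lineages split at exponential waiting times (rate k*birth_rate while k
    lineages are extant) and after the last split the present is placed an
    Exp(n*birth_rate) interval later.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    lengths = [0.0, 0.0, 0.0]
    birth = [0.0, 0.0, 0.0]            # time each open lineage was created
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = active.pop(rng.integers(k))
        lengths[i] = t - birth[i]
        for _ in range(2):
            parent.append(i)
            lengths.append(0.0)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i in active:
        lengths[i] = t - birth[i]
    lengths = np.array(lengths)
    if height is not None:
        lengths *= height / t
    labels: list = [None] * len(parent)
    internal = set(parent)
    k = 0
    for v in range(len(parent)):
        if v not in internal:
            k += 1
            labels[v] = f"sp{k:04d}"
    return Phylogeny(np.array(parent), lengths, labels, 0)


def _transition_targets(alphabet, allow_reversal, symmetric):
    if symmetric:
        return {i: [j for j in range(len(alphabet)) if j != i]
                for i in range(len(alphabet))}
    targets = {0: [1], 1: [2], 2: []}     # LS -> CC -> CS
    if allow_reversal:
        targets[1] = [2, 0]               # CC -> LS reversal possible
    return targets


def simulate_regime_history(tree: Phylogeny, q: float, seed=None,
                            alphabet=DEFAULT_REGIMES,
                            allow_reversal: bool = True,
                            symmetric: bool = False):
    """Continuous-time Markov regime jumps along branches from an LS root.

    Rate ``q`` applies per allowed transition.  Returns ``(node_states,
    painting)`` with the child-branch painting convention.
    """
    rng = np.random.default_rng(seed)
    targets = _transition_targets(alphabet, allow_reversal, symmetric)
    state = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = state[tree.parent[v]]
        t_left = tree.lengths[v]
        while targets[s] and q > 0:
            rate = q * len(targets[s])
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            t_left -= wait
            s = targets[s][rng.integers(len(targets[s]))]
        state[v] = s
    node_states = {v: alphabet[state[v]] for v in range(tree.n_nodes)}
    return node_states, paint_regimes(tree, node_states, alphabet)


def _evolve_sequences(tree, model, L, scale, rng):
    """Neutral evolution of L sites; returns per-node integer arrays."""
    from .seqevo import _transition_matrices

    rates = model.category_rates()
    cat = rng.integers(rates.size, size=L)
    P = _transition_matrices(tree, model.rate_matrix(), rates, scale)
    pi = model.pi
    seq = {tree.root: rng.choice(4, size=L, p=pi)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        par = seq[tree.parent[v]]
        child = np.empty(L, dtype=int)
        for c in range(rates.size):
            sel = cat == c
            if not sel.any():
                continue
            probs = P[c, v][par[sel]]
            u = rng.random(sel.sum())
            child[sel] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        seq[v] = np.clip(child, 0, 3)
    return seq


def simulate_alignment(tree: Phylogeny,
                       model: SubstitutionModelSpec | None = None,
                       L: int = 237, seed=None, scale: float = 1.0
                       ) -> Alignment:
    """Neutral alignment evolved under the given substitution model."""
    rng = np.random.default_rng(seed)
    model = model or SubstitutionModelSpec("JC")
    seqs = _evolve_sequences(tree, model, L, scale, rng)
    return Alignment({tree.labels[t]: "".join(NUC[i] for i in seqs[t])
                      for t in tree.tips})


def simulate_alignment_with_cox_site(tree: Phylogeny, node_states: dict,
                                     model: SubstitutionModelSpec | None = None,
                                     L: int = 237,
                                     site_map=DEFAULT_SITE_MAP, seed=None,
                                     scale: float = 0.3) -> Alignment:
    """JC+Gamma-evolved alignment whose two mapped codons are overwritten at
    the tips to encode each tip's regime (with synonymous randomisation), so
    that classify_cox_state recovers the generated regime exactly."""
    (a1, b1), (a2, b2) = site_map
    cols1 = set(range(a1 - 1, b1))
    cols2 = set(range(a2 - 1, b2))
    if cols1 & cols2:
        raise ValueError("site_map codons overlap")
    if b1 - a1 != 2 or b2 - a2 != 2 or min(a1, a2) < 1 or max(b1, b2) > L:
        raise ValueError(f"site_map {site_map} invalid for L={L}")
    rng = np.random.default_rng(seed)
    model = model or SubstitutionModelSpec("JC", gamma=True, shape=0.5)
    seqs_int = _evolve_sequences(tree, model, L, scale, rng)
    out = {}
    for t in tree.tips:
        chars = [NUC[i] for i in seqs_int[t]]
        aa1, aa2 = _STATE_AA[node_states[t]]
        cod1 = _CODONS[aa1][rng.integers(len(_CODONS[aa1]))]
        cod2 = _CODONS[aa2][rng.integers(len(_CODONS[aa2]))]
        chars[a1 - 1:b1] = list(cod1)
        chars[a2 - 1:b2] = list(cod2)
        out[tree.labels[t]] = "".join(chars)
    return Alignment(out)


def simulate_regime_traits(tree: Phylogeny, painting: RegimePainting,
                           theta, alpha: float, sigma2: float,
                           model: str = "OUM", seed=None) -> dict[str, float]:
    """Multi-regime OU traits on the log10 scale, root tied to the root
    regime's optimum."""
    theta = np.asarray(theta, dtype=float)
    spec = OUModelSpec(model)
    R = painting.n_regimes
    params = OUParams(theta,
                      np.full(R if spec.alpha_per_regime else 1, alpha),
                      np.full(R if spec.sigma_per_regime else 1, sigma2),
                      float(theta[painting.root_regime]))
    return simulate_traits(tree, painting, spec, params, seed=seed)


@dataclasses.dataclass
class SyntheticStudy:
    """A complete synthetic study bundle plus its truth ledger."""

    config: SyntheticStudyConfig
    tree: Phylogeny
    node_states: dict
    painting: RegimePainting
    alignment: Alignment
    traits: "object"             # pandas DataFrame
    truth: dict

    def write(self, outdir: str) -> dict:
        """Write newick/fasta/csv/json files; returns the path map."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "newick": os.path.join(outdir, "tree.nwk"),
            "fasta": os.path.join(outdir, "alignment.fasta"),
            "traits": os.path.join(outdir, "traits.csv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        with open(paths["newick"], "w") as fh:
            fh.write(write_newick(self.tree) + "\n")
        self.alignment.to_fasta(paths["fasta"])
        self.traits.to_csv(paths["traits"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def build_synthetic_study(config: SyntheticStudyConfig | None = None,
                          seed: int | None = None) -> SyntheticStudy:
    """One call producing every pipeline input plus the truth ledger.

    The regime history is redrawn (bounded, sub-seeded retries) until every
    regime reaches ``min_regime_tips`` tips, i.e. the generator conditions
    on histories with the documented LS/CC/CS shape actually represented in
    the data.  Deterministic under the config seed.
    """
    import pandas as pd

    config = config or SyntheticStudyConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    root = np.random.SeedSequence(config.seed)
    s_tree, s_hist, s_aln, s_tr1, s_tr2, s_misc = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]

    tree = simulate_yule_tree(config.n_tips, config.birth_rate, seed=s_tree,
                              height=config.height)
    node_states = painting = None
    for attempt in range(200):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ns, pt = simulate_regime_history(
                tree, config.q, seed=s_hist + attempt,
                allow_reversal=config.allow_reversal,
                symmetric=config.symmetric_mk)
        tip_counts = {a: 0 for a in DEFAULT_REGIMES}
        for t in tree.tips:
            tip_counts[ns[t]] += 1
        if min(tip_counts.values()) >= config.min_regime_tips:
            node_states, painting = ns, pt
            break
    if node_states is None:
        raise RuntimeError(
            "could not draw a regime history with all regimes represented; "
            "raise q or n_tips")

    alignment = simulate_alignment_with_cox_site(
        tree, node_states, L=config.L, site_map=config.site_map, seed=s_aln,
        scale=config.subst_scale,
        model=SubstitutionModelSpec("JC", gamma=True, shape=config.gamma_shape))

    genome_log = simulate_regime_traits(
        tree, painting, config.theta_genome, config.alpha, config.sigma2,
        model=config.trait_model, seed=s_tr1)
    chrom_log = simulate_regime_traits(
        tree, painting, config.theta_chrom, config.alpha, config.sigma2,
        model=config.trait_model, seed=s_tr2)

    rng = np.random.default_rng(s_misc)
    species = list(tree.tip_labels)
    has_chrom = {s: bool(rng.random() < config.chrom_fraction) for s in species}
    rows = []
    for s in species:
        g = 10.0 ** genome_log[s]
        c = 10.0 ** chrom_log[s]
        n_chr = max(1, int(round(g / c)))
        rows.append({
            "species": s,
            "genome_size_1C_Mbp": round(g, 3),
            "chromosome_number": n_chr if has_chrom[s] else "",
            "mean_chromosome_size_Mbp": round(c, 4) if has_chrom[s] else "",
        })
    # trait-table species that are not on the tree (exercise the funnel)
    for j in range(config.n_extra_species):
        g = float(10.0 ** rng.normal(np.log10(300.0), 0.4))
        rows.append({"species": f"offtree{j + 1:03d}",
                     "genome_size_1C_Mbp": round(g, 3),
                     "chromosome_number": "", "mean_chromosome_size_Mbp": ""})
    traits = pd.DataFrame(rows)

    tip_states = {tree.labels[t]: node_states[t] for t in tree.tips}
    truth = {
        "seed": config.seed,
        "node_states": {str(v): node_states[v] for v in node_states},
        "tip_states": tip_states,
        "root_state": node_states[tree.root],
        "painting_alphabet": list(DEFAULT_REGIMES),
        "trait_model": config.trait_model,
        "theta_genome_log10": list(map(float, config.theta_genome)),
        "theta_chrom_log10": list(map(float, config.theta_chrom)),
        "theta_genome_Mbp": [float(10.0 ** t) for t in config.theta_genome],
        "theta_chrom_Mbp": [float(10.0 ** t) for t in config.theta_chrom],
        "alpha": config.alpha, "sigma2": config.sigma2,
        "genome_log10": genome_log, "chrom_log10": chrom_log,
        "site_map": [list(s) for s in config.site_map],
        "n_tips": config.n_tips,
        "n_extra_species": config.n_extra_species,
    }
    return SyntheticStudy(config, tree, node_states, painting, alignment,
                          traits, truth)
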