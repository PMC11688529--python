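"""Full-study orchestration: load and reconcile inputs, reconstruct COX
states, paint regimes, run the phylogenetic regression, the seven-model
trait-evolution comparison and the parametric bootstrap, and assemble a
report with an auditable species-drop manifest.

The study design runs every analysis twice where possible: once with only
species whose COX state comes from sequence data, and once adding species
whose state is imputed from their genus/section affiliation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .tree import (Phylogeny, read_tree, prune_to, paint_regimes,
                   check_ultrametric, normalize_name, DEFAULT_REGIMES)
from .seqevo import Alignment, select_model_bic, marginal_asr
from .cox import classify_cox_state, classify_nodes, mk_marginal_asr, \
    DEFAULT_SITE_MAP
from .oumodels import fit_all_models, theta_standard_errors, OUError
from .pgls import select_error_model, PGLSError
from .bootstrap import parametric_bootstrap_theta, compare_regime_optima

TRAIT_COLUMNS = ("genome_size_1C_Mbp", "mean_chromosome_size_Mbp")

# genus/section -> COX state rules used for affiliation-based imputation
AFFILIATION_RULES = {
    ("Pinguicula", None): "LS",
    ("Utricularia", None): "CC",
    ("Genlisea", "Tayloria"): "LS",
    ("Genlisea", "Recurvatae"): "CC",
    ("Genlisea", "Genlisea"): "CS",
}

__all__ = ["run_study", "impute_states_by_affiliation", "load_traits",
           "TRAIT_COLUMNS", "AFFILIATION_RULES", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def load_traits(source) -> pd.DataFrame:
    """Trait table from CSV/TSV path or DataFrame; species names normalised."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)
    if "species" not in df.columns:
        raise PipelineError("trait table needs a 'species' column")
    df["species"] = df["species"].map(normalize_name)
    return df


def impute_states_by_affiliation(states: dict, taxonomy: pd.DataFrame):
    """Fill missing COX states from genus/section membership.

    ``taxonomy`` needs columns species, genus and (for Genlisea) section.
    Returns ``(completed_states, provenance, unresolved)`` where provenance
    flags each species 'sequenced' or 'imputed'.
    """
    states = {normalize_name(k): v for k, v in states.items()}
    completed = dict(states)
    provenance = {s: "sequenced" for s in states}
    unresolved = []
    for _, row in taxonomy.iterrows():
        sp = normalize_name(row["species"])
        if sp in completed:
            continue
        genus = str(row.get("genus", "")).strip()
        section = str(row.get("section", "")).strip() or None
        rule = AFFILIATION_RULES.get((genus, section if genus == "Genlisea"
                                      else None))
        if rule is None:
            unresolved.append(sp)
        else:
            completed[sp] = rule
            provenance[sp] = "imputed"
    return completed, provenance, unresolved


def _states_from_alignment(tree: Phylogeny, alignment: Alignment,
                           site_map, seed: int):
    """BIC model choice, marginal ASR and per-tip COX classification on the
    subtree spanned by the sequenced species."""
    shared = sorted(set(alignment.species) & set(tree.tip_labels))
    if len(shared) < 4:
        raise PipelineError(
            f"only {len(shared)} sequenced species on the tree")
    sub = prune_to(tree, shared)
    aln = Alignment({s: alignment.sequences[s] for s in shared})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranking = select_model_bic(sub, aln)
        best = ranking[0]
        recon = marginal_asr(sub, aln, best["spec"], scale=best["scale"])
        node_states = classify_nodes(sub, recon, site_map)
    tip_states = {sub.labels[t]: node_states[t] for t in sub.tips}
    root_state = node_states[sub.root]
    return {
        "model_ranking": [{k: r[k] for k in ("model", "lnL", "n_params", "BIC")}
                          for r in ranking],
        "best_model": best["model"],
        "branch_scale": best["scale"],
        "root_state": root_state,
        "tip_states": tip_states,
        "n_sequenced_on_tree": len(shared),
    }


def _analyse_variant(tree, traits_df, states, trait_col, seed, n_starts,
                     criterion, n_boot, models, do_bootstrap):
    """One trait x one state-source variant: funnel, PGLS, OU models,
    bootstrap."""
    tdf = traits_df[["species", trait_col]].dropna()
    tdf = tdf[tdf[trait_col].astype(str).str.strip() != ""]
    trait_map = {r["species"]: float(r[trait_col]) for _, r in tdf.iterrows()}
    tips = set(tree.tip_labels)
    manifest = {"loaded": int(len(traits_df))}
    drops = {}
    have_trait = set(trait_map)
    drops["no_trait_value"] = sorted(set(traits_df["species"]) - have_trait)
    on_tree = have_trait & tips
    drops["not_on_tree"] = sorted(have_trait - tips)
    with_state = {s for s in on_tree if s in states}
    drops["no_cox_state"] = sorted(on_tree - with_state)
    keep = sorted(with_state)
    manifest["analysed"] = len(keep)
    manifest["dropped"] = {k: len(v) for k, v in drops.items()}
    manifest["drop_lists"] = drops
    if len(keep) < 8:
        raise PipelineError(
            f"only {len(keep)} usable species for {trait_col}")
    sub = prune_to(tree, keep)
    ok, dev, bad = check_ultrametric(sub, rel_tol=1e-3)
    if not ok:
        raise PipelineError(
            f"pruned tree not ultrametric (tip {bad}, deviation {dev:.2g})")
    y_log = {s: float(np.log10(trait_map[s])) for s in keep}
    tip_states = {s: states[s] for s in keep}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        node_states, _, q_hat = mk_marginal_asr(sub, tip_states)
        present = [a for a in DEFAULT_REGIMES
                   if a in set(node_states.values())]
        painting = paint_regimes(sub, node_states, tuple(present))

        pgls_fits, pgls_notes = select_error_model(sub, y_log, tip_states)
        best_pgls = pgls_fits[0]

        fits = fit_all_models(sub, painting, y_log, models=models,
                              n_starts=n_starts, seed=seed,
                              criterion=criterion)
    best_fit = fits[0]
    boot_block = None
    if do_bootstrap:
        boot_target = next((f for f in fits if f.theta is not None
                            and f.theta.size > 1), None)
        if boot_target is not None:
            boot = parametric_bootstrap_theta(sub, painting, boot_target,
                                              n_replicates=n_boot, seed=seed)
            tests = compare_regime_optima(boot)
            boot_block = {
                "model": boot_target.spec.name,
                "n_replicates": n_boot,
                "n_failed": boot.n_failed,
                "summary": boot.summary(),
                "tests": tests.to_dict(orient="records"),
            }
    se = None
    if best_fit.theta is not None:
        try:
            se = theta_standard_errors(sub, painting, best_fit, y_log)
        except Exception:
            se = None
    return {
        "trait": trait_col,
        "manifest": manifest,
        "mk_rate_qhat": q_hat,
        "regimes_present": present,
        "pgls": {
            "best_error_model": best_pgls.error_model,
            "comparable_runner_up": pgls_notes["comparable"],
            "ranking": [{"error_model": f.error_model, "lnL": f.lnL,
                         "AIC": f.aic, "AICw": f.aic_weight}
                        for f in pgls_fits],
            "table": best_pgls.table().to_dict(orient="records"),
            "r2": best_pgls.r2, "r2_adj": best_pgls.r2_adj,
            "r2_adj_alt": best_pgls.r2_adj_alt,
            "alpha": best_pgls.param,
            "second_best_table": (pgls_fits[1].table().to_dict(orient="records")
                                  if len(pgls_fits) > 1 else None),
        },
        "trait_models": {
            "criterion": criterion,
            "ranking": [f.summary() for f in fits],
            "best_model": best_fit.spec.name,
            "theta_log10": (None if best_fit.theta is None
                            else [float(t) for t in best_fit.theta]),
            "theta_Mbp": (None if best_fit.theta is None else
                          [float(t) for t in best_fit.theta_backtransformed()]),
            "theta_se_log10": (None if se is None
                               else [float(s) for s in se]),
            "regime_order": list(best_fit.alphabet),
        },
        "bootstrap": boot_block,
    }


def run_study(tree, traits, alignment=None, states=None, taxonomy=None,
              site_map=DEFAULT_SITE_MAP, seed: int = 0, n_boot: int = 100,
              n_starts: int = 8, criterion: str = "AICc",
              variant: str = "both", trait_columns=TRAIT_COLUMNS,
              models=None, do_bootstrap: bool = True) -> dict:
    """Execute the complete comparative analysis and return the report.

    ``tree`` is a Phylogeny or a Newick/Nexus path; ``traits`` a DataFrame
    or CSV path; state sources are an alignment (sequence route: BIC model
    choice, marginal ASR, COX-site classification) and/or a species->state
    table (direct route), optionally completed by affiliation imputation
    when a taxonomy table is supplied.  When both a sequence-derived and an
    imputed state set exist, both analysis variants are run.
    """
    from .oumodels import MODEL_NAMES

    models = models or MODEL_NAMES
    if not isinstance(tree, Phylogeny):
        tree = read_tree(tree)
    traits_df = load_traits(traits)
    if alignment is not None and not isinstance(alignment, Alignment):
        alignment = Alignment.from_fasta(alignment)
    if states is not None and not isinstance(states, dict):
        sdf = load_traits(states)
        col = "cox_state" if "cox_state" in sdf.columns else sdf.columns[1]
        states = dict(zip(sdf["species"], sdf[col]))
    if taxonomy is not None and not isinstance(taxonomy, pd.DataFrame):
        taxonomy = load_traits(taxonomy)

    report: dict = {"provenance": {"package": "ouregimes",
                                   "version": __version__, "seed": seed,
                                   "variant_request": variant},
                    "asr": None, "variants": {}}

    sequenced: dict[str, str] = {}
    if alignment is not None:
        asr_block = _states_from_alignment(tree, alignment, site_map, seed)
        report["asr"] = {k: v for k, v in asr_block.items()
                        if k != "tip_states"}
        sequenced.update({s: st for s, st in asr_block["tip_states"].items()
                          if st in DEFAULT_REGIMES})
    if states:
        for s, st in states.items():
            sequenced.setdefault(normalize_name(s), st)

    if not sequenced:
        raise PipelineError(
            "no COX state source: provide an alignment and/or a state table")

    state_sets = {}
    if variant in ("sequenced-only", "both"):
        state_sets["sequenced_only"] = (sequenced, None)
    if variant in ("imputed", "both") and taxonomy is not None:
        completed, prov, unresolved = impute_states_by_affiliation(
            sequenced, taxonomy)
        state_sets["imputed"] = (completed, {"provenance_counts": {
            "sequenced": sum(1 for v in prov.values() if v == "sequenced"),
            "imputed": sum(1 for v in prov.values() if v == "imputed")},
            "unresolved": unresolved})
    if variant == "imputed" and "imputed" not in state_sets:
        raise PipelineError("imputed variant requires a taxonomy table")

    for vname, (vstates, vmeta) in state_sets.items():
        vblock = {"meta": vmeta, "traits": {}}
        for col in trait_columns:
            if col not in traits_df.columns:
                continue
            try:
                vblock["traits"][col] = _analyse_variant(
                    tree, traits_df, vstates, col, seed=seed,
                    n_starts=n_starts, criterion=criterion, n_boot=n_boot,
                    models=models, do_bootstrap=do_bootstrap)
            except (PipelineError, PGLSError, OUError) as exc:
                raise PipelineError(
                    f"stage '{vname}/{col}' failed: {exc}") from exc
        report["variants"][vname] = vblock
    return report
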