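"""End-to-end orchestration of the community production screen.

A screen walks four stages for every requested condition x substrate
regime: monoculture FBA/FVA per model, pairwise community construction
and steady-state solving, interaction/cross-feeding/yield/efficiency
analysis, and min-max ranking of the viable cohort.  Knockout design runs
separately on a chosen community.  Pair-level solves are independent;
outputs are sorted by pair id, so a re-run with the same configuration
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from cobra import Model

from . import __version__
from .community import (
    CommunityModel, apply_community_condition, build_pair_community,
    iter_pairs,
)
from .config import CampConfig
from .exceptions import CampError, ConfigurationError, InfeasibleError
from .io import (
    NutrientCondition, half_max_uptake, load_model, monoculture_growth,
    save_model,
)
from .knockout import evaluate_deletions, fseof_scan, select_strategies
from .production import (
    efficiency_scenarios, jaccard_distance, monoculture_yield,
    observed_yield, rank_communities, yield_record,
)
from .screening import (
    detect_cross_feeding, make_interaction_record, summarize_screen,
)
from .steadycom import solve_steadycom
from .synthetic import make_panel

logger = logging.getLogger("camp")

__all__ = ["load_models", "run_screen", "run_knockout", "write_fixtures"]

_TSV_KW = dict(sep="\t", index=False, float_format="%.6g")


def load_models(config: CampConfig) -> List[Model]:
    """Models for a run: SBML files from ``model_dir``, else the seeded
    fixture panel."""
    if config.model_dir:
        paths = sorted(Path(config.model_dir).glob("*.xml"))
        paths += sorted(Path(config.model_dir).glob("*.sbml"))
        if len(paths) < 2:
            raise ConfigurationError(
                f"model_dir {config.model_dir!r} holds fewer than 2 SBML files"
            )
        return [load_model(p) for p in paths]
    return make_panel(config.panel_size, config.seed)


def _regime_substrates(config: CampConfig, regime: str) -> List[str]:
    if regime == "glc_xyl":
        keys: Sequence[str] = list(config.substrates)
    else:
        keys = [regime]
    return [config.substrates[k] for k in keys if k in config.substrates]


def _base_condition(name: str, config: CampConfig,
                    half_max: Mapping[str, Mapping[str, float]],
                    model_ids: Sequence[str]) -> Dict[str, NutrientCondition]:
    """Per-model monoculture condition for one named nutrient condition."""
    atpm = config.thresholds.atpm
    subs = list(config.substrates.values())
    if name == "minimal":
        cond = NutrientCondition(
            "minimal", {ex: -1.0 for ex in subs}, atpm_flux=atpm)
        return {mid: cond for mid in model_ids}
    if name == "excess":
        bounds = {}
        for key, ex in config.substrates.items():
            bounds[ex] = -30.0 if key == "glc" else -10.0
        cond = NutrientCondition("excess", bounds, atpm_flux=atpm)
        return {mid: cond for mid in model_ids}
    return {
        mid: NutrientCondition.community_specific(
            {ex: half_max[mid].get(ex, 0.0) for ex in subs}, atpm_flux=atpm)
        for mid in model_ids
    }


def _pair_condition(name: str, cond_a: NutrientCondition,
                    cond_b: NutrientCondition) -> NutrientCondition:
    """Community-level condition: shared bounds, or the summed half-max
    uptakes of the two members for the community-specific condition."""
    if name != "community_specific":
        return cond_a
    bounds = {
        ex: cond_a.substrate_bounds.get(ex, 0.0)
        + cond_b.substrate_bounds.get(ex, 0.0)
        for ex in set(cond_a.substrate_bounds) | set(cond_b.substrate_bounds)
    }
    return NutrientCondition.community_specific(
        bounds, atpm_flux=cond_a.atpm_flux, anaerobic=cond_a.anaerobic)


def run_screen(config: CampConfig, out_dir: str,
               models: Optional[Sequence[Model]] = None) -> Path:
    """Execute the full screen and write TSV/JSON artifacts.

    Per condition x regime subdirectory: ``mono.tsv``,
    ``interactions.tsv``, ``crossfeed.tsv``, ``occurrence.tsv``,
    ``label_fractions.tsv``, ``yields.tsv``, ``efficiency.tsv`` and
    ``ranking.tsv``; a top-level ``manifest.json`` records the
    configuration and solve counts.  Pair-level failures are logged and
    recorded as non-viable; configuration errors abort.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = list(models) if models is not None else load_models(config)
    models.sort(key=lambda m: m.id)
    medium = config.medium_exchange_ids()
    thresholds = config.thresholds
    product = config.product_exchange

    needs_half_max = "community_specific" in config.conditions
    half_max: Dict[str, Dict[str, float]] = {}
    if needs_half_max:
        for model in models:
            half_max[model.id] = {
                ex: half_max_uptake(model, ex)
                for ex in config.substrates.values()
            }

    reaction_sets = {
        m.id: {r.id for r in m.reactions} for m in models
    }
    model_ids = [m.id for m in models]
    by_id = {m.id: m for m in models}
    n_solves = 0

    for cond_name in config.conditions:
        mono_conditions = _base_condition(
            cond_name, config, half_max, model_ids)
        for regime in config.regimes:
            subs = _regime_substrates(config, regime)
            tag = f"{cond_name}__{regime}"
            subdir = out / tag
            subdir.mkdir(exist_ok=True)
            logger.info("screening %s (%d models)", tag, len(models))

            mono_rows, mono_growth, mono_yields = [], {}, {}
            for mid in model_ids:
                cond = mono_conditions[mid].restricted_to(subs)
                growth = monoculture_growth(by_id[mid], cond, medium)
                mono_growth[mid] = growth
                my = monoculture_yield(by_id[mid], cond, product, medium)
                mono_yields[mid] = my
                mono_rows.append({
                    "model": mid, "growth": growth,
                    "product_max": my.product_max if my else 0.0,
                    "substrate_uptake": my.substrate_uptake if my else 0.0,
                    "yield": my.yield_value if my else 0.0,
                })
            pd.DataFrame(mono_rows).to_csv(subdir / "mono.tsv", **_TSV_KW)

            interactions, crossfeeds, yields, effs = [], [], [], []
            solutions = {}
            rank_input, jaccards = [], {}
            for model_a, model_b in iter_pairs(models):
                pair = (model_a.id, model_b.id)
                pair_cond = _pair_condition(
                    cond_name, mono_conditions[model_a.id],
                    mono_conditions[model_b.id],
                ).restricted_to(subs)
                try:
                    cm = build_pair_community(
                        model_a, model_b, product_exchange=product)
                    apply_community_condition(cm, pair_cond, medium)
                    solution = solve_steadycom(
                        cm, mu_tolerance=config.mu_tolerance)
                    n_solves += 1
                except ConfigurationError:
                    raise
                except CampError as exc:
                    logger.info("pair %s: %s (recorded non-viable)",
                                pair, exc)
                    interactions.append(make_interaction_record(
                        pair,
                        (mono_growth[pair[0]], mono_growth[pair[1]]),
                        (0.0, 0.0),
                        thresholds.interaction_frac,
                        thresholds.viability_growth,
                    ))
                    continue
                solutions[pair] = solution
                co = tuple(solution.member_growth[m] for m in pair)
                monos = (mono_growth[pair[0]], mono_growth[pair[1]])
                if min(monos) <= 0:
                    label_rec = make_interaction_record(
                        pair, monos, (0.0, 0.0),
                        thresholds.interaction_frac,
                        thresholds.viability_growth)
                else:
                    label_rec = make_interaction_record(
                        pair, monos, co,
                        thresholds.interaction_frac,
                        thresholds.viability_growth)
                interactions.append(label_rec)
                for rec in detect_cross_feeding(
                        cm, solution, thresholds.crossfeed_flux, medium
                        | set(pair_cond.substrate_bounds)):
                    crossfeeds.append({
                        "pair": "|".join(pair), "metabolite": rec.metabolite_id,
                        "donor": rec.donor, "receiver": rec.receiver,
                        "donor_flux": rec.donor_flux,
                        "receiver_flux": rec.receiver_flux,
                    })
                viable = label_rec.label != "non_viable"
                if viable and all(
                        mono_yields[m] is not None for m in pair):
                    obs = observed_yield(
                        cm, solution.mu,
                        substrate_exchanges=[
                            s.replace("(e)", "(u)") for s in subs],
                    )
                    yr = yield_record(pair, obs,
                                      {m: mono_yields[m] for m in pair},
                                      thresholds.yield_fold)
                    yields.append(yr)
                    eff = efficiency_scenarios(
                        cm, min_growth=thresholds.viability_growth)
                    effs.append((pair, eff))
                    if eff.overall:
                        rank_input.append((pair, solution.mu, yr.moi))
                        jaccards[pair] = jaccard_distance(
                            reaction_sets[pair[0]], reaction_sets[pair[1]])

            pd.DataFrame([{
                "member_a": r.pair[0], "member_b": r.pair[1],
                "mono_a": r.mono_growth[0], "mono_b": r.mono_growth[1],
                "co_a": r.co_growth[0], "co_b": r.co_growth[1],
                "change_a": r.relative_change[0],
                "change_b": r.relative_change[1],
                "label": r.label,
            } for r in interactions], columns=[
                "member_a", "member_b", "mono_a", "mono_b", "co_a", "co_b",
                "change_a", "change_b", "label",
            ]).to_csv(subdir / "interactions.tsv", **_TSV_KW)
            pd.DataFrame(
                crossfeeds,
                columns=["pair", "metabolite", "donor", "receiver",
                         "donor_flux", "receiver_flux"],
            ).to_csv(subdir / "crossfeed.tsv", **_TSV_KW)
            summary = summarize_screen(interactions, solutions)
            summary["occurrence"].to_csv(subdir / "occurrence.tsv", **_TSV_KW)
            summary["label_fractions"].to_csv(
                subdir / "label_fractions.tsv", **_TSV_KW)
            pd.DataFrame([{
                "member_a": y.pair[0], "member_b": y.pair[1],
                "s1": y.s1, "s2": y.s2, "y1i": y.y1i, "y2i": y.y2i,
                "MEi": y.mei, "MOi": y.moi, "candidate": y.candidate,
            } for y in yields], columns=[
                "member_a", "member_b", "s1", "s2", "y1i", "y2i",
                "MEi", "MOi", "candidate",
            ]).to_csv(subdir / "yields.tsv", **_TSV_KW)
            pd.DataFrame([{
                "member_a": pair[0], "member_b": pair[1],
                "no_crossfeed_a": eff.scenario_pass[f"no_crossfeed_{pair[0]}"],
                "no_crossfeed_b": eff.scenario_pass[f"no_crossfeed_{pair[1]}"],
                "primary_a": eff.scenario_pass[f"primary_{pair[0]}"],
                "primary_b": eff.scenario_pass[f"primary_{pair[1]}"],
                "overall": eff.overall,
            } for pair, eff in effs], columns=[
                "member_a", "member_b", "no_crossfeed_a", "no_crossfeed_b",
                "primary_a", "primary_b", "overall",
            ]).to_csv(subdir / "efficiency.tsv", **_TSV_KW)
            ranked = rank_communities(rank_input, jaccards)
            pd.DataFrame([{
                "rank": i + 1, "member_a": r.pair[0], "member_b": r.pair[1],
                "normalized_growth": r.normalized_growth,
                "normalized_yield": r.normalized_yield,
                "score": r.score, "jaccard_distance": r.jaccard_distance,
            } for i, r in enumerate(ranked)], columns=[
                "rank", "member_a", "member_b", "normalized_growth",
                "normalized_yield", "score", "jaccard_distance",
            ]).to_csv(subdir / "ranking.tsv", **_TSV_KW)

    manifest = {
        "camp_version": __version__,
        "config": _config_digestable(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_digestable(config), sort_keys=True).encode()
        ).hexdigest(),
        "models": model_ids,
        "n_pairs": len(model_ids) * (len(model_ids) - 1) // 2,
        "n_community_solves": n_solves,
        "solver": "glpk",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _config_digestable(config: CampConfig) -> Dict:
    data = asdict(config)
    if isinstance(data.get("medium"), (set, frozenset)):
        data["medium"] = sorted(data["medium"])
    return data


def run_knockout(
    config: CampConfig,
    pair: Tuple[str, str],
    out_dir: str,
    models: Optional[Sequence[Model]] = None,
    condition_name: str = "minimal",
    regime: str = "glc_xyl",
) -> Path:
    """FSEOF shortlist + deletion testing for one community; writes
    ``knockout.tsv`` (all evaluated deletions) and ``strategies.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = list(models) if models is not None else load_models(config)
    by_id = {m.id: m for m in models}
    for mid in pair:
        if mid not in by_id:
            raise ConfigurationError(f"model {mid!r} not in the run set")
    medium = config.medium_exchange_ids()
    half_max: Dict[str, Dict[str, float]] = {}
    if condition_name == "community_specific":
        for mid in pair:
            half_max[mid] = {
                ex: half_max_uptake(by_id[mid], ex)
                for ex in config.substrates.values()
            }
    mono_conditions = _base_condition(
        condition_name, config, half_max, list(pair))
    subs = _regime_substrates(config, regime)
    pair_cond = _pair_condition(
        condition_name, mono_conditions[pair[0]], mono_conditions[pair[1]]
    ).restricted_to(subs)
    cm = build_pair_community(
        by_id[pair[0]], by_id[pair[1]],
        product_exchange=config.product_exchange)
    apply_community_condition(cm, pair_cond, medium)
    scan = fseof_scan(cm)
    results = evaluate_deletions(
        cm, scan.candidates,
        single_only_threshold=config.thresholds.fseof_candidate_max,
        min_growth=config.thresholds.viability_growth)
    rows = [{
        "deleted": "|".join(sorted(r.deleted_reactions)),
        "n_deletions": len(r.deleted_reactions),
        "mutant_mu": r.mutant_mu,
        "mutant_product_flux": r.mutant_product_flux,
        "wildtype_product_flux": r.wildtype_product_flux,
        "fold_change": (r.mutant_product_flux / r.wildtype_product_flux
                        if r.wildtype_product_flux > 1e-9 else float("nan")),
        "viable": r.viable, "improved": r.improved,
    } for r in results]
    pd.DataFrame(rows).to_csv(out / "knockout.tsv", **_TSV_KW)
    strategies = select_strategies(results)
    pd.DataFrame([{
        "rank": i + 1,
        "deleted": "|".join(sorted(r.deleted_reactions)),
        "mutant_mu": r.mutant_mu,
        "mutant_product_flux": r.mutant_product_flux,
        "wildtype_product_flux": r.wildtype_product_flux,
    } for i, r in enumerate(strategies)]).to_csv(
        out / "strategies.tsv", **_TSV_KW)
    with open(out / "fseof.json", "w") as fh:
        json.dump({
            "enforced_levels": list(scan.enforced_levels),
            "candidates": sorted(scan.candidates),
            "amplification_targets": sorted(scan.amplification_targets),
            "wildtype_product_flux": scan.wildtype_product_flux,
            "product_max": scan.product_max,
        }, fh, indent=1, sort_keys=True)
    return out


def write_fixtures(config: CampConfig, out_dir: str) -> Path:
    """Write the seeded fixture panel as SBML plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = make_panel(config.panel_size, config.seed)
    manifest = []
    for model in models:
        path = out / f"{model.id}.xml"
        save_model(model, str(path))
        manifest.append({
            "model_id": model.id,
            "n_reactions": len(model.reactions),
            "file": path.name,
        })
    with open(out / "panel.json", "w") as fh:
        json.dump({"seed": config.seed, "models": manifest}, fh,
                  indent=1, sort_keys=True)
    return out
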