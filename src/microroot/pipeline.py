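"""Pipeline orchestration: simulate -> screen -> genotype -> DE -> filter ->
enrich, with input validation and a reproducibility manifest.

All stage parameters live in a YAML/dict config; a fixed global seed makes
the whole run replay-identical (non-float outputs byte-identical, floats to
full printed precision).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from . import (diff_expression, enrichment, genotype_response,
               hierarchical_filter, phenotype_screen, synthetic_data)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "screen": {
        "n_strains": 96, "n_features": 21, "n_plants": 10, "n_latent": 3,
        "active_fraction": 0.5, "effect_size": 2.0, "noise_sd": 1.0,
        "alpha": 0.05, "k_clusters": 24, "linkage": "average", "cut": 0.3,
    },
    "panel": {
        "n_strains": 8, "n_plants": 10, "family": "gaussian",
        "baseline": 5.0, "effect_size": 1.0, "alpha": 0.05, "n_mc": 10_000,
    },
    "expression": {
        "n_genes": 2000, "module_sizes": [40, 40, 40], "n_reps": 3,
        "n_strains": 16, "effect_size": 2.0, "baseline_mean": 200.0,
        "nb_dispersion": 0.05,
        "genotypes": ["Col-0", "arf7arf19", "nph4", "lbd16", "gnom"],
        "wild_type": "Col-0",
    },
    "de": {"d0": 4.0, "alpha": 0.05},
    "filter": {"q_max": 0.05, "lfc_min": 1.0, "min_mutants": 1,
               "min_treatments": 1, "stage2_mode": "retain-shared",
               "r_min": 0.5, "alpha": 0.05, "high_lfc": 3.0},
    "enrich": {"recall": 0.8, "precision": 0.8, "n_decoys": 5,
               "alpha": 0.05},
}


def load_config(path=None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(config.get(key), dict):
                config[key].update(val)
            else:
                config[key] = val
    return config


def _expression_truth(cfg: dict, seed: int) -> synthetic_data.PlantedTruth:
    """Planted strain effects for the expression design: half the strains
    active with alternating-sign effects scaled by cfg['effect_size']."""
    rng = np.random.default_rng(seed)
    n = cfg["n_strains"]
    names = [f"B{i + 1:03d}" for i in range(n)]
    active = np.zeros(n, dtype=bool)
    active[: n // 2] = True
    active = active[rng.permutation(n)]
    signs = rng.choice([-1.0, 1.0], n)
    mags = rng.uniform(0.5, 1.0, n) * cfg["effect_size"]
    e = np.where(active, signs * mags, 0.0)
    return synthetic_data.PlantedTruth(
        strain_effects={synthetic_data.CONTROL: 0.0,
                        **{s: float(v) for s, v in zip(names, e)}},
        active_strains={s for s, a in zip(names, active) if a})


def validate_inputs(bundle: dict) -> dict:
    """Schema checks per input; returns {input: {passed, problems, rows}}."""
    report = {}
    if "feature_table" in bundle:
        problems = io.validate_feature_table(bundle["feature_table"])
        report["feature_table"] = {"passed": not problems,
                                   "problems": problems,
                                   "rows": len(bundle["feature_table"])}
    if "condition_table" in bundle:
        problems = io.validate_condition_table(bundle["condition_table"])
        report["condition_table"] = {"passed": not problems,
                                     "problems": problems,
                                     "rows": len(bundle["condition_table"])}
    if "counts" in bundle:
        problems = io.validate_counts(bundle["counts"], bundle["meta"])
        report["counts"] = {"passed": not problems, "problems": problems,
                            "rows": int(bundle["counts"].shape[0])}
    return report


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage on a synthetic bundle and write artifacts + manifest.

    Returns the manifest dict (also written to ``manifest.json``). Rerunning
    with the same config and seed reproduces all outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config, "timestamp": time.time()}

    # --- simulate + screen -------------------------------------------------
    scr = config["screen"]
    screen_cfg = synthetic_data.ScreenSimConfig(
        n_strains=scr["n_strains"], n_features=scr["n_features"],
        n_plants=scr["n_plants"], n_latent=scr["n_latent"],
        active_fraction=scr["active_fraction"],
        effect_size=scr["effect_size"], noise_sd=scr["noise_sd"], seed=seed)
    table, screen_truth = synthetic_data.simulate_screen(screen_cfg)
    report = validate_inputs({"feature_table": table})
    if not all(v["passed"] for v in report.values()):
        raise RuntimeError(f"stage screen: input validation failed: {report}")
    io.write_table(table, out / "feature_table.tsv")

    effects = phenotype_screen.estimate_effects(table, alpha=scr["alpha"])
    io.write_table(effects, out / "effects.tsv")
    markers = phenotype_screen.select_marker_features(
        table, linkage=scr["linkage"], cut=scr["cut"])
    with open(out / "markers.json", "w") as fh:
        json.dump(markers.to_dict(), fh, indent=1, sort_keys=True)
    k = min(scr["k_clusters"], scr["n_strains"])
    clusters = phenotype_screen.cluster_strain_responses(
        effects, markers.markers, k=k, linkage=scr["linkage"])
    clusters.rename_axis("strain").reset_index().to_csv(
        out / "strain_clusters.tsv", sep="\t", index=False)
    _, frac_any = phenotype_screen.summarize_significance(effects)
    manifest["screen"] = {
        "n_strains": scr["n_strains"],
        "fraction_strains_with_effect": frac_any,
        "n_markers": len(markers.markers), "k_clusters": k,
    }

    # --- genotype panel ----------------------------------------------------
    pan = config["panel"]
    panel_cfg = synthetic_data.PanelSimConfig(
        n_strains=pan["n_strains"], n_plants=pan["n_plants"],
        family=pan["family"], baseline=pan["baseline"],
        effect_size=pan["effect_size"], seed=seed + 1)
    cond_table, _ = synthetic_data.simulate_genotype_panel(panel_cfg)
    io.write_table(cond_table, out / "condition_table.tsv")
    fams = {}
    for i, g in enumerate(panel_cfg.genotypes):
        fams[g] = genotype_response.dunnett_vs_control(
            cond_table, genotype=g, alpha=pan["alpha"], n_mc=pan["n_mc"],
            seed=seed + 2 + i)
    dunnett = genotype_response.bh_across_families(fams, alpha=pan["alpha"])
    io.write_table(dunnett, out / "dunnett.tsv")
    manifest["panel"] = {
        "n_treatments": pan["n_strains"],
        "n_significant": int(dunnett["significant"].sum()),
    }

    # --- expression + DE ---------------------------------------------------
    ex = config["expression"]
    expr_truth = _expression_truth(ex, seed + 50)
    expr_cfg = synthetic_data.ExpressionSimConfig(
        n_genes=ex["n_genes"], module_sizes=tuple(ex["module_sizes"]),
        genotypes=tuple(ex["genotypes"]), wild_type=ex["wild_type"],
        n_reps=ex["n_reps"], nb_dispersion=ex["nb_dispersion"],
        baseline_mean=ex["baseline_mean"], seed=seed + 51)
    counts, meta, expr_truth = synthetic_data.simulate_expression(
        expr_cfg, expr_truth)
    report = validate_inputs({"counts": counts, "meta": meta})
    if not all(v["passed"] for v in report.values()):
        raise RuntimeError(f"stage de: input validation failed: {report}")
    io.write_counts(counts, out / "counts.tsv")
    meta.reset_index().to_csv(out / "samples.tsv", sep="\t", index=False)
    expr_truth.to_json(out / "truth.json")

    de = diff_expression.de_all_contrasts(
        counts, meta, d0=config["de"]["d0"], alpha=config["de"]["alpha"])
    io.write_table(de, out / "de.tsv")

    # --- hierarchical filter ----------------------------------------------
    flt = config["filter"]
    phenotype = pd.Series({s: e for s, e in expr_truth.strain_effects.items()
                           if s != synthetic_data.CONTROL}, name="phenotype")
    io.write_table(phenotype.rename_axis("treatment").reset_index(),
                   out / "phenotype.tsv")
    mutants = [g for g in ex["genotypes"] if g != ex["wild_type"]]
    pos, neg, trace = hierarchical_filter.run_filter(
        de, phenotype, ex["wild_type"], mutants, q_max=flt["q_max"],
        lfc_min=flt["lfc_min"], min_mutants=flt["min_mutants"],
        min_treatments=flt["min_treatments"],
        stage2_mode=flt["stage2_mode"], r_min=flt["r_min"],
        alpha=flt["alpha"])
    trace.to_json(out / "filter_trace.json")
    (out / "panel_positive.txt").write_text("\n".join(sorted(pos)) + "\n")
    (out / "panel_negative.txt").write_text("\n".join(sorted(neg)) + "\n")
    final = pos | neg
    high = hierarchical_filter.high_lfc_subset(
        final, de, ex["wild_type"], threshold=flt["high_lfc"]) if final else set()
    manifest["filter"] = {"stage_counts": trace.counts,
                          "n_positive": len(pos), "n_negative": len(neg),
                          "n_high_lfc": len(high)}

    # --- enrichment --------------------------------------------------------
    en = config["enrich"]
    sets = synthetic_data.simulate_gene_sets(
        expr_truth, recall=en["recall"], precision=en["precision"],
        n_decoys=en["n_decoys"], seed=seed + 90)
    collection = enrichment.GeneSetCollection(
        sets=sets, universe=set(expr_truth.module_membership))
    collection.to_gmt(out / "gene_sets.gmt")
    queries = {"panel_positive": pos & collection.universe,
               "panel_negative": neg & collection.universe}
    enr = enrichment.enrichment_panel(queries, collection,
                                      alpha=en["alpha"])
    io.write_table(enr, out / "enrichment.tsv")
    manifest["enrich"] = {
        "n_sets": len(sets),
        "n_significant": int(enr["significant"].sum()),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
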