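"""End-to-end pipeline orchestration from a structured YAML config.

A run executes the stages in dependency order — input generation or loading,
absolute quantification, within-species dynamics, ortholog resolution,
cross-species stage correspondence, and the SNP-robustness digestion check —
and writes every table, JSON summary, the resolved configuration, and a log
into the run directory.  All randomness flows from the single config seed
(per-stage streams are derived from it with fixed offsets), so reruns with an
identical config reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import absquant, digest as digest_mod, dynamics, orthology, simulate, xspecies
from .errors import ConfigError, EmbryoprotError
from .io import (
    read_blast_tab,
    read_complex_catalog,
    read_expression_tsv,
    read_fasta,
    read_spikein_tsv,
    write_expression_tsv,
)

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {
    "spikein": 11, "complexes": 13, "two_species": 17, "snp": 19,
    "hits": 23, "kmeans": 29, "cocluster": 31, "hourglass": 37,
}

DEMO_CONFIG: dict[str, Any] = {
    "seed": 17,
    "log_level": "INFO",
    "simulate": {
        "spikein": {
            "n_standards": 48, "n_sample_proteins": 2000,
            "slope": 1.0, "intercept": 2.0, "noise_sd": 0.1,
            "dynamic_range_orders": 8.0,
        },
        "complexes": {
            "n_complexes": 20, "subunits_per_complex": 5,
            "within_sd": 0.1, "global_sd": 1.0, "n_background": 500,
        },
        "two_species": {
            "n_orthologs": 400, "n_stages_a": 8, "n_stages_b": 8,
            "shape": "inverse_hourglass", "effect_size": 1.0,
            "noise_sd": 0.05,
        },
        "snp": {"n_sequences": 100, "mean_length": 300, "snp_rate": 0.001},
        "n_decoys": 20,
    },
    "absquant": {"total_mM": 2.0, "cutoff_uM": 0.01},
    "dynamics": {"k_within": 8, "k_cocluster": 5, "n_restarts": 100},
    "orthology": {"evalue_max": 0.01},
    "xspecies": {"metric": "pearson", "n_permutations": 1000},
    "digest": {"protease": "trypsin", "missed_cleavages": 0},
}


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    """Schema check; raises ConfigError before any computation."""
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("config needs an explicit integer 'seed'")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or an 'inputs' block")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        if not isinstance(inputs, dict):
            raise ConfigError("'inputs' must be a mapping of names to paths")
        for name, path in inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input path for {name!r} not found: {path}")
    for block in ("absquant", "dynamics", "orthology", "xspecies", "digest"):
        if block in cfg and not isinstance(cfg[block], dict):
            raise ConfigError(f"config block {block!r} must be a mapping")
    shape = (
        cfg.get("simulate", {}).get("two_species", {}).get("shape", "flat")
    )
    if shape not in simulate.SHAPES:
        raise ConfigError(f"unknown two_species shape {shape!r}")
    return cfg


def _stage_seed(base: int, stage: str) -> int:
    return (base * 1_000 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: dict[str, Any] | str | Path, run_dir: str | Path) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("embryoprot")
    root.addHandler(handler)
    root.setLevel(getattr(logging, str(cfg.get("log_level", "INFO")).upper()))

    seed = cfg["seed"]
    summary: dict[str, Any] = {"seed": seed}
    stage = "setup"
    try:
        with open(run_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)

        sim_cfg = cfg.get("simulate")
        inputs = cfg.get("inputs", {})

        # ---- absolute quantification -----------------------------------
        stage = "absquant"
        aq = cfg.get("absquant", {})
        total_nm = float(aq.get("total_mM", 2.0)) * 1e6
        cutoff_nm = float(aq.get("cutoff_uM", 0.01)) * 1e3
        spikeins = signals = None
        if sim_cfg and "spikein" in sim_cfg:
            spikeins, signals, spike_truth = simulate.gen_spikein_experiment(
                seed=_stage_seed(seed, "spikein"), **sim_cfg["spikein"],
            )
        elif "spikeins" in inputs and "signals" in inputs:
            spikeins = read_spikein_tsv(inputs["spikeins"])
            signals = read_expression_tsv(
                inputs["signals"], modality="protein_relative",
            )
        if spikeins is not None:
            curve = absquant.fit_standard_curve(spikeins)
            conc = absquant.estimate_concentrations(
                curve, signals,
                total_concentration_nM=total_nm, cutoff_nM=cutoff_nm,
            )
            logger.info(
                "standard curve: slope=%.4f intercept=%.4f (n=%d)",
                curve.slope, curve.intercept, curve.n_points_used,
            )
            (run_dir / "standard_curve.json").write_text(json.dumps({
                "slope": curve.slope, "intercept": curve.intercept,
                "n_points_used": curve.n_points_used,
                "n_excluded_zero_signal": curve.n_excluded_zero_signal,
                "n_below_cutoff": conc.provenance["n_below_cutoff"],
                "n_dropped_signal": conc.provenance["n_dropped_signal"],
            }, indent=2))
            conc.to_frame().to_csv(run_dir / "concentrations.tsv", sep="\t")
            summary["standard_curve"] = {
                "slope": curve.slope, "intercept": curve.intercept,
            }
            summary["median_concentration_nM"] = absquant.median_concentration(conc)

        # complex stoichiometry (synthetic complex dataset or catalog input)
        stage = "stoichiometry"
        if sim_cfg and "complexes" in sim_cfg:
            conc_table, catalog, _ = simulate.gen_complex_dataset(
                seed=_stage_seed(seed, "complexes"), **sim_cfg["complexes"],
            )
            stoich = absquant.complex_stoichiometry_test(conc_table, catalog)
        elif spikeins is not None and "catalog" in inputs:
            catalog = read_complex_catalog(inputs["catalog"])
            stoich = absquant.complex_stoichiometry_test(conc, catalog)
        else:
            stoich = None
        if stoich is not None:
            stoich.per_complex.to_csv(
                run_dir / "stoichiometry.tsv", sep="\t", index=False,
            )
            summary["stoichiometry"] = {
                "n_tested": len(stoich),
                "n_flagged_p01": int(len(stoich.flagged(0.01))),
            }

        # ---- two-species data ------------------------------------------
        stage = "dynamics"
        dyn = cfg.get("dynamics", {})
        mat_a = mat_b = omap_true = truth = None
        if sim_cfg and "two_species" in sim_cfg:
            mat_a, mat_b, omap_true, truth = simulate.gen_two_species_timeseries(
                seed=_stage_seed(seed, "two_species"), **sim_cfg["two_species"],
            )
        elif "profiles_a" in inputs and "profiles_b" in inputs:
            mat_a = read_expression_tsv(
                inputs["profiles_a"], modality="protein_relative", species="a",
            )
            mat_b = read_expression_tsv(
                inputs["profiles_b"], modality="protein_relative", species="b",
            )
        prof_a = prof_b = None
        if mat_a is not None:
            write_expression_tsv(mat_a, run_dir / "profiles_a.tsv")
            write_expression_tsv(mat_b, run_dir / "profiles_b.tsv")
            prof_a = dynamics.sum_to_one(dynamics.median_normalize(mat_a))
            prof_b = dynamics.sum_to_one(dynamics.median_normalize(mat_b))
            model = dynamics.kmeans_profiles(
                prof_a, k=int(dyn.get("k_within", 8)),
                n_restarts=int(dyn.get("n_restarts", 100)),
                seed=_stage_seed(seed, "kmeans"),
            )
            model.assignments.to_csv(run_dir / "clusters_a.tsv", sep="\t")
            summary["kmeans_within"] = {
                "k": model.k,
                "total_within_ss": model.total_within_ss,
            }

        # ---- orthology --------------------------------------------------
        stage = "orthology"
        orth = cfg.get("orthology", {})
        omap = None
        if omap_true is not None:
            hits_ab, hits_ba = simulate.gen_hit_tables(
                omap_true, n_decoys=int(sim_cfg.get("n_decoys", 0)),
                seed=_stage_seed(seed, "hits"),
            )
            omap = orthology.reciprocal_best_hits(
                hits_ab, hits_ba,
                evalue_max=float(orth.get("evalue_max", 0.01)),
            )
            summary["orthology"] = {
                "n_pairs": len(omap),
                "recovered_planted_map": omap.as_dict() == omap_true.as_dict(),
            }
        elif "hits_ab" in inputs and "hits_ba" in inputs:
            omap = orthology.reciprocal_best_hits(
                read_blast_tab(inputs["hits_ab"]),
                read_blast_tab(inputs["hits_ba"]),
                evalue_max=float(orth.get("evalue_max", 0.01)),
            )
            summary["orthology"] = {"n_pairs": len(omap)}
        if omap is not None:
            orthology.write_ortholog_tsv(omap, run_dir / "orthologs.tsv")

        # ---- cross-species comparison ----------------------------------
        stage = "xspecies"
        if prof_a is not None and omap is not None and len(omap) >= 10:
            xs = cfg.get("xspecies", {})
            model_co = dynamics.co_cluster_orthologs(
                prof_a, prof_b, omap,
                k=int(dyn.get("k_cocluster", 5)),
                n_restarts=int(dyn.get("n_restarts", 100)),
                seed=_stage_seed(seed, "cocluster"),
            )
            model_co.assignments.to_csv(run_dir / "coclusters.tsv", sep="\t")
            sim = xspecies.stage_similarity(
                prof_a, prof_b, omap, metric=xs.get("metric", "pearson"),
            )
            sim.values.to_csv(run_dir / "similarity_matrix.tsv", sep="\t")
            trace = xspecies.best_match_trace(sim)
            trace.to_csv(run_dir / "best_match_trace.tsv", sep="\t")
            curve = xspecies.divergence_curve(sim)
            curve.values.to_csv(run_dir / "divergence_curve.tsv", sep="\t")
            classes = xs.get("stage_classes") or simulate.stage_classes_by_thirds(
                prof_a.stage_labels,
            )
            result = xspecies.hourglass_classify(
                curve, classes,
                n_permutations=int(xs.get("n_permutations", 1000)),
                seed=_stage_seed(seed, "hourglass"),
            )
            hourglass = {
                "label": result.label,
                "direction": result.direction,
                "statistic": result.statistic,
                "p_value": result.p_value,
            }
            if truth is not None:
                hourglass["generator_shape"] = truth.shape_label
            (run_dir / "hourglass.json").write_text(
                json.dumps(hourglass, indent=2)
            )
            summary["hourglass"] = hourglass

        # ---- SNP robustness --------------------------------------------
        stage = "digest"
        dg = cfg.get("digest", {})
        batches = None
        if sim_cfg and "snp" in sim_cfg:
            b1, b2, _ = simulate.gen_fasta_with_snps(
                seed=_stage_seed(seed, "snp"), **sim_cfg["snp"],
            )
            batches = (b1, b2)
        elif "fasta_batch1" in inputs and "fasta_batch2" in inputs:
            batches = (
                read_fasta(inputs["fasta_batch1"]),
                read_fasta(inputs["fasta_batch2"]),
            )
        if batches is not None:
            report = digest_mod.snp_robustness_report(
                *batches,
                protease=dg.get("protease", "trypsin"),
                missed_cleavages=int(dg.get("missed_cleavages", 0)),
            )
            (run_dir / "snp_report.json").write_text(json.dumps(report, indent=2))
            summary["snp_report"] = report

        (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("pipeline run complete: %s", run_dir)
        return run_dir
    except EmbryoprotError:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    except Exception as exc:  # noqa: BLE001 — annotate the failing stage
        logger.exception("pipeline failed at stage %r", stage)
        raise EmbryoprotError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
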