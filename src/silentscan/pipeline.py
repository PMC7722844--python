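"""Stage wiring, configuration, and the end-to-end synthetic demonstration.

Every stage consumes seeded synthetic data; all randomness flows from a
single root seed expanded into per-stage seeds.  ``run_demo`` writes one
machine-readable JSON report plus TSV summary tables and aborts with the
stage name on any failure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chip_norm, deg_stats, mapping_screen, phylo, synthetic_data, te_survey, variant_triage
from .read_mapping import build_index, map_pairs
from .synthetic_data import ReadSimConfig, TruthInsertion
from .te_survey import SurveyConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return {
        "seed": 1,
        "strains": {
            "roster": ["cw15arg", "Elow47", "UVM4", "UVM11"],
            "progenitor": "Elow47",
            "mutants": ["UVM4", "UVM11"],
        },
        "genome": {"length": 60_000, "gc_fraction": 0.64},
        "te": {"families": ["TEa", "TEb"], "length": 1000},
        "reads": {
            "read_length": 100, "insert_mean": 300.0, "insert_sd": 30.0,
            "coverage": 15.0, "error_rate": 0.002,
        },
        "survey": {
            "min_locus_reads": 10, "presence_threshold": 10,
            "differential_ratio": 10.0, "merge_distance": 200,
        },
        "counts": {"n_genes": 500, "n_replicates": 4, "dispersion": 0.05, "n_planted": 20},
        "deg": {"mode": "ma"},
        "chip": {"reference_region": "CYC6", "n_replicates": 6},
        "screen": {
            "n_segregants": 48,
            "rf": {"CNA83": 0.10, "PF25": 0.15, "X1": 0.0, "FAR_MARKER": 0.5},
        },
        "phylo": {"n_taxa": 6, "n_sites": 400, "bootstrap": 100},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = default_config()
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    _validate_config(config)
    return config


def _validate_config(config: Mapping):
    roster = config["strains"]["roster"]
    if len(set(roster)) != len(roster):
        raise ValueError("strain roster contains duplicates")
    referenced = {config["strains"]["progenitor"], *config["strains"]["mutants"]}
    unknown = referenced - set(roster)
    if unknown:
        raise ValueError(f"strains referenced but not in roster: {sorted(unknown)}")


def stage_seeds(root_seed: int) -> dict:
    """Expand the root seed into one independent seed per stage."""
    names = ["genome", "reads", "counts", "cq", "genotypes", "variants", "phylo"]
    seq = np.random.SeedSequence(root_seed)
    children = seq.spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# reusable survey driver
# ---------------------------------------------------------------------------


def run_te_survey(
    backbone: Mapping[str, str],
    te_library: Mapping[str, str],
    design: Sequence[TruthInsertion],
    strains: Sequence[str],
    read_config: ReadSimConfig,
    survey_config: SurveyConfig = SurveyConfig(),
    reads_seed: int = 0,
):
    """Simulate reads per strain and run the full half-mapped-read survey.

    Returns a dict with loci, the presence matrix, differential flags, the
    per-TE summary and per-strain pair counts.
    """
    genomes, _ = synthetic_data.plant_te_insertions(backbone, te_library, design)
    for strain in strains:
        genomes.setdefault(strain, dict(backbone))

    te_index = build_index(te_library)
    genome_index = build_index(backbone)

    anchored = []
    pair_counts = {}
    for i, strain in enumerate(strains):
        cfg = ReadSimConfig(
            read_length=read_config.read_length,
            insert_mean=read_config.insert_mean,
            insert_sd=read_config.insert_sd,
            coverage=read_config.coverage,
            error_rate=read_config.error_rate,
            seed=reads_seed + i,
        )
        pairs = synthetic_data.simulate_paired_reads(genomes[strain], cfg, name_prefix=strain)
        pair_counts[strain] = len(pairs)
        mates1 = [(p.name, p.seq1) for p in pairs]
        mates2 = [(p.name, p.seq2) for p in pairs]
        alignments = map_pairs(mates1, mates2, te_index)
        half = te_survey.classify_half_mapped(alignments, strain)
        anchored.extend(te_survey.anchor_map(half, genome_index))

    loci = te_survey.call_loci(anchored, survey_config)
    matrix = te_survey.score_presence(loci, strains, survey_config)
    flags = te_survey.flag_differential(matrix.counts, survey_config)
    present_any = matrix.presence.any(axis=1)
    summary = (
        te_survey.summarize_survey(
            matrix.presence[present_any], matrix.te_of_locus[present_any], strains
        )
        if present_any.any()
        else pd.DataFrame()
    )
    return {
        "loci": loci,
        "presence": matrix,
        "flags": flags,
        "summary": summary,
        "pair_counts": pair_counts,
    }


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------


def run_demo(config: Mapping, out_dir) -> dict:
    """Execute every stage on seeded synthetic data and emit a report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _validate_config(config)
    seeds = stage_seeds(int(config["seed"]))
    report = {"seed": int(config["seed"]), "stages": {}, "checks": {}}
    roster = list(config["strains"]["roster"])

    # --- transposon survey -------------------------------------------------
    try:
        gcfg = config["genome"]
        backbone = {"chr1": synthetic_data.simulate_genome(gcfg["length"], gcfg["gc_fraction"], seeds["genome"])}
        te_len = config["te"]["length"]
        te_library = {
            name: synthetic_data.simulate_genome(te_len, 0.5, seeds["genome"] + 17 + i)
            for i, name in enumerate(config["te"]["families"])
        }
        te_names = list(te_library)
        step = gcfg["length"] // 8
        design = [
            TruthInsertion(te_names[0], frozenset(roster), "chr1", step, te_len),
            TruthInsertion(te_names[0], frozenset(roster), "chr1", 3 * step, te_len),
            TruthInsertion(te_names[1], frozenset(roster), "chr1", 5 * step, te_len),
            TruthInsertion(te_names[1], frozenset([roster[-1]]), "chr1", 7 * step, te_len),
        ]
        rcfg = config["reads"]
        survey_cfg = SurveyConfig(**config["survey"])
        survey = run_te_survey(
            backbone, te_library, design, roster,
            ReadSimConfig(seed=seeds["reads"], **rcfg), survey_cfg,
            reads_seed=seeds["reads"],
        )
        survey["presence"].counts.to_csv(out / "te_counts.tsv", sep="\t")
        survey["presence"].presence.to_csv(out / "te_presence.tsv", sep="\t")
        if len(survey["summary"]):
            survey["summary"].to_csv(out / "te_summary.tsv", sep="\t")
        report["stages"]["te_survey"] = {
            "pairs": survey["pair_counts"],
            "n_loci": len(survey["loci"]),
            "n_flagged": int(survey["flags"].sum()),
        }
        summary = survey["summary"]
        row_sum_ok = bool(
            len(summary) == 0
            or (summary["total"] == summary.drop(columns="total").sum(axis=1)).all()
        )
        report["checks"]["survey_row_sum_conservation"] = row_sum_ok
        report["checks"]["survey_presence_invariant"] = bool(
            (survey["presence"].presence
             == (survey["presence"].counts >= survey_cfg.presence_threshold)).all().all()
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("te_survey", exc) from exc

    # --- variant triage ----------------------------------------------------
    try:
        progenitor = config["strains"]["progenitor"]
        mutants = list(config["strains"]["mutants"])
        specs = [
            {"gene": "geneX", "effect": "missense_variant", "carriers": {mutants[0]}},
            {"gene": "geneX", "effect": "missense_variant", "carriers": {mutants[1]}},
            {"gene": "geneY", "effect": "synonymous_variant", "carriers": {mutants[0]}},
            {"gene": "geneZ", "effect": "missense_variant", "carriers": set(roster)},
            {"gene": "geneW", "effect": "missense_variant", "carriers": {mutants[0], mutants[1]}},
        ]
        variants = synthetic_data.simulate_variants(roster, specs, seed=seeds["variants"])
        selected = variant_triage.select_mutant_specific(variants, progenitor, mutants)
        hits = variant_triage.genes_hit_in_both(selected, mutants[0], mutants[1])
        variant_triage.write_vcf(variants, out / "variants.vcf")
        report["stages"]["variant_triage"] = {
            "n_variants": len(variants), "n_selected": len(selected), "genes_hit": hits,
        }
        report["checks"]["triage_expected_gene"] = hits == ["geneX"]
    except Exception as exc:
        raise PipelineError("variant_triage", exc) from exc

    # --- DEG stage ---------------------------------------------------------
    try:
        ccfg = config["counts"]
        rng = np.random.default_rng(seeds["counts"])
        planted_idx = rng.choice(ccfg["n_genes"], size=ccfg["n_planted"], replace=False)
        planted = tuple(
            (int(i), 2.0 if k % 2 == 0 else -2.0) for k, i in enumerate(sorted(planted_idx))
        )
        counts, truth = synthetic_data.simulate_counts(
            synthetic_data.CountSimConfig(
                n_genes=ccfg["n_genes"], n_replicates=ccfg["n_replicates"],
                dispersion=ccfg["dispersion"], planted_de=planted, seed=seeds["counts"],
            )
        )
        lengths = pd.Series(1000, index=counts.index)
        group_a = [c for c in counts.columns if c.startswith("A")]
        group_b = [c for c in counts.columns if c.startswith("B")]
        table = deg_stats.gene_stats(counts, group_a, group_b, lengths)
        up, down = deg_stats.call_degs(table, deg_stats.DEGCriteria(mode=config["deg"]["mode"]))
        table.to_csv(out / "gene_stats.tsv", sep="\t")
        truth_up = set(truth.loc[truth["direction"] == "up", "gene"])
        truth_down = set(truth.loc[truth["direction"] == "down", "gene"])
        intersection, regions = deg_stats.venn_candidates(up, truth_up, up | down, truth_up | truth_down)
        report["stages"]["deg"] = {
            "n_genes": len(counts), "n_up": len(up), "n_down": len(down),
            "venn_regions": regions,
        }
        report["checks"]["deg_no_sign_flips"] = bool(
            not (up & truth_down) and not (down & truth_up)
        )
    except Exception as exc:
        raise PipelineError("deg", exc) from exc

    # --- ChIP normalization ------------------------------------------------
    try:
        ref_region = config["chip"]["reference_region"]
        truth_chip = {}
        for strain, scale in zip(roster, (1.0, 1.0, 4.0, 4.0)):
            truth_chip[(strain, "H3ac", ref_region)] = 10.0
            truth_chip[(strain, "H3ac", "YFP_TSS")] = 2.0 * scale
        cq = synthetic_data.simulate_cq(
            truth_chip, n_replicates=config["chip"]["n_replicates"],
            seed=seeds["cq"], noise_sd=0.05,
        )
        enrich = chip_norm.enrichment_table(cq, ref_region)
        enrich.to_csv(out / "chip_enrichment.tsv", sep="\t", index=False)
        ref_rows = enrich[enrich["region"] == ref_region]
        report["stages"]["chip"] = {"n_measurements": len(cq), "n_regions": enrich["region"].nunique()}
        report["checks"]["chip_reference_is_one"] = bool(
            np.allclose(ref_rows["normalized"], 1.0)
        )
    except Exception as exc:
        raise PipelineError("chip", exc) from exc

    # --- mapping screen ----------------------------------------------------
    try:
        scfg = config["screen"]
        genotypes, rf_truth = synthetic_data.simulate_genotypes(
            scfg["n_segregants"], scfg["rf"], seed=seeds["genotypes"]
        )
        rf = mapping_screen.rf_table(genotypes)
        rf.to_csv(out / "rf_table.tsv", sep="\t", index=False)
        screens = [
            mapping_screen.TransformantScreen("line1", 0, 20),
            mapping_screen.TransformantScreen("line2", 3, 20),
            mapping_screen.TransformantScreen("line3", 6, 20),
            mapping_screen.TransformantScreen("line4", 15, 20),
        ]
        yet_row = mapping_screen.summarize_complementation(screens)
        report["stages"]["screen"] = {"rf": rf.to_dict("records"), "yet": yet_row}
        counts_sum = sum(yet_row[f"count_{c}"] for c in mapping_screen.YET_CLASSES[:4])
        report["checks"]["yet_total_consistency"] = counts_sum == yet_row["count_lt30"]
    except Exception as exc:
        raise PipelineError("screen", exc) from exc

    # --- phylogeny ---------------------------------------------------------
    try:
        pcfg = config["phylo"]
        names, seqs, true_splits = synthetic_data.simulate_protein_alignment(
            pcfg["n_taxa"], pcfg["n_sites"], seed=seeds["phylo"]
        )
        tree, skipped = phylo.bootstrap_support(
            names, seqs, n_replicates=pcfg["bootstrap"], seed=seeds["phylo"]
        )
        newick = phylo.to_newick(tree)
        (out / "tree.nwk").write_text(newick + "\n")
        recovered = set(phylo.internal_splits(tree))
        report["stages"]["phylo"] = {
            "n_taxa": len(names),
            "total_branch_length": float(phylo.total_branch_length(tree)),
            "bootstrap_skipped": skipped,
        }
        report["checks"]["phylo_true_splits_recovered"] = true_splits <= recovered
    except Exception as exc:
        raise PipelineError("phylo", exc) from exc

    report["all_checks_passed"] = all(report["checks"].values())
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
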