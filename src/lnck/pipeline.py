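"""End-to-end orchestration: simulate inputs, run every analysis stage in
dependency order, and write one summary JSON aggregating all statistics.

Reruns with the same config are byte-identical: a single seed determines
every stage (per-stage RNG streams are derived from it independently, so
toggling one stage never perturbs another's randomness), no timestamps are
written, and the serialized config plus its hash accompany every output
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, expression, identify, networks, profiles, recombination, simulate
from .io import (
    ValidationError,
    write_annotation,
    write_coverage,
    write_expression,
    write_intervals,
    write_samples,
    write_table,
)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "lnck_run"
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    # stage toggles
    run_identify: bool = True
    run_expression: bool = True
    run_recomb: bool = True
    run_profiles: bool = True
    run_assoc: bool = True
    run_networks: bool = True
    write_inputs: bool = True
    # thresholds
    fpkm_threshold: float = 0.1
    de_min_mean_count: float = 10.0
    assoc_alpha: float = 1e-5
    module_min_size: int = 30
    module_beta: float = 6.0
    module_cut_height: float = 0.9
    max_module_genes: int = 2000

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            marks = self.sim.pop("marks", None)
            self.sim = simulate.SimConfig(**self.sim)
            if marks:
                self.sim.marks = {
                    k: simulate.MarkProfile(**v) if isinstance(v, dict) else v
                    for k, v in marks.items()
                }
        self.sim.seed = self.seed


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["marks"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
                         for k, v in cfg.sim.marks.items()}
    return d


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_dict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    return obj


def run_all(cfg: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written to
    ``out_dir/summary.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed}

    sim = cfg.sim
    samples = simulate.generate_samples(sim)
    genes, class_truth = simulate.generate_annotation(sim)
    expr_sim = simulate.generate_expression(sim, genes, samples)
    lnc_genes = [g for g in genes if g.biotype != "coding"]
    coding_genes = [g for g in genes if g.biotype == "coding"]

    inputs = out / "inputs"
    if cfg.write_inputs:
        inputs.mkdir(exist_ok=True)
        write_samples(samples, inputs / "samples.tsv")
        write_annotation(genes, inputs / "annotation.gtf")
        write_expression(expr_sim.counts, inputs / "counts.tsv")
        write_expression(expr_sim.fpkm, inputs / "fpkm.tsv")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        write_table(class_truth, truth_dir / "positional_classes.tsv")
        expr_sim.gene_truth.reset_index().to_csv(truth_dir / "gene_truth.tsv", sep="\t", index=False)
        write_table(expr_sim.de_truth, truth_dir / "de_truth.tsv")

    summary["annotation"] = {
        "n_coding": len(coding_genes),
        "n_lnc": len(lnc_genes),
        "lnc_single_exon_frac": float(
            np.mean([g.n_exons == 1 for g in lnc_genes])
        ),
    }

    # ---- identification -------------------------------------------------
    if cfg.run_identify:
        features, cascade_truth = simulate.generate_cascade_features(sim, genes)
        result = identify.run_cascade(features)
        classes = identify.classify_positions(lnc_genes, coding_genes)
        class_frame = identify.positions_to_frame(classes)
        merged = class_frame.merge(class_truth, left_on="lnc_gene_id", right_on="gene_id")
        class_recovery = float(
            (merged["position_class"] == merged["planted_class"]).mean()
        )
        counts_per_sample, _spec = identify.count_expressed(
            expr_sim.fpkm, samples, threshold=cfg.fpkm_threshold
        )
        truth_map = cascade_truth.set_index("transcript_id")["planted_stage"]
        stage_match = float(
            np.mean(
                [
                    result.stage_of_elimination[t] == truth_map[t]
                    for t in truth_map.index
                ]
            )
        )
        summary["identify"] = {
            "per_stage_counts": result.per_stage_counts,
            "n_retained": len(result.retained),
            "cascade_stage_accuracy": stage_match,
            "positional_class_recovery": class_recovery,
            "class_counts": class_frame["position_class"].value_counts().to_dict(),
            "median_expressed_per_sample": float(counts_per_sample.median()),
        }
        write_table(class_frame, out / "positional_classes.tsv")
        write_table(
            pd.DataFrame(result.per_stage_counts, columns=["stage", "surviving"]),
            out / "cascade_counts.tsv",
        )

    # ---- expression statistics ------------------------------------------
    de = None
    specific_generation: dict[str, set] = {}
    if cfg.run_expression:
        de = expression.de_all_lines(
            expr_sim.counts, samples, min_mean_count=cfg.de_min_mean_count
        )
        de.to_csv(out / "de_results.tsv", sep="\t", index=False)
        biotype = expr_sim.gene_truth["biotype"]
        tested = de[de["tested"]]
        merged = tested.merge(
            expr_sim.de_truth, on=["gene_id", "line_id"], how="left"
        )
        merged["biotype"] = biotype.reindex(merged["gene_id"]).to_numpy()
        frac = {}
        for cls, sub in merged.groupby("biotype"):
            frac[cls] = {
                "down_called": float((sub["status"] == "down").mean()),
                "up_called": float((sub["status"] == "up").mean()),
                "down_planted": float((sub["label"] == "down").mean()),
                "up_planted": float((sub["label"] == "up").mean()),
            }
        ent = expression.entropy_table(expr_sim.fpkm)
        hk = expression.select_housekeeping(expr_sim.fpkm)
        specific_generation = expression.call_specific(
            expr_sim.fpkm, samples, "generation", threshold=cfg.fpkm_threshold
        )
        spec_tol = expression.call_specific(
            expr_sim.fpkm, samples, "tolerance", threshold=cfg.fpkm_threshold
        )
        lnc_ids = set(biotype[biotype != "coding"].index)
        n_lnc = len(lnc_ids)
        n_cod = len(biotype) - n_lnc
        spec_table = [
            [
                sum(1 for g in specific_generation.get("RIL", set()) if g in lnc_ids),
                n_lnc,
            ],
            [
                sum(1 for g in specific_generation.get("RIL", set()) if g not in lnc_ids),
                n_cod,
            ],
        ]
        summary["expression"] = {
            "de_fractions": frac,
            "entropy_median": {
                cls: float(ent.loc[biotype.reindex(ent.index) == cls, "H"].median())
                for cls in ("coding", "lncRNA")
                if (biotype == cls).any()
            },
            "n_housekeeping_called": len(hk),
            "offspring_specific": {
                "lnc_pct": expression.proportion(spec_table[0][0], n_lnc),
                "coding_pct": expression.proportion(spec_table[1][0], n_cod),
            },
            "tolerance_specific_counts": {
                k: len(v) for k, v in sorted(spec_tol.items())
            },
        }
        ent.reset_index().to_csv(out / "entropy.tsv", sep="\t", index=False)

    # ---- recombination ---------------------------------------------------
    fragments, snps, pop_traits, snp_truth = simulate.generate_population_data(
        sim, genes, samples, expr_sim.gene_truth["specific_line"]
    )
    if cfg.write_inputs:
        write_intervals(fragments, inputs / "fragments.bed")
        write_table(snps, inputs / "snps.tsv")
        pop_traits.reset_index().to_csv(inputs / "pop_traits.tsv", sep="\t", index=False)
        lnc_mir_in, circ_mir_in, mrna_mir_in, bridge_truth_in = simulate.generate_mirna_targets(sim, genes)
        write_table(lnc_mir_in, inputs / "lnc_mir.tsv")
        write_table(circ_mir_in, inputs / "circ_mir.tsv")
        write_table(mrna_mir_in, inputs / "mrna_mir.tsv")
        write_table(bridge_truth_in, out / "truth" / "mirna_bridges.tsv")
    if cfg.run_recomb:
        overlaps = recombination.overlap_fragments(genes, fragments)
        offspring = specific_generation.get("RIL", set()) if specific_generation else set()
        if overlaps and offspring:
            enr = recombination.recomb_enrichment(overlaps, offspring)
            summary["recombination"] = {
                "n_fragments": len(fragments),
                "n_overlapping": enr["n_overlapping"],
                "specific_proportion_pct": enr["specific_proportion_pct"],
                "specific_p": enr["specific_test"].p if enr["specific_test"] else None,
                "multiplicity_proportion_pct": enr["multiplicity_proportion_pct"],
            }
            write_table(recombination.overlaps_to_frame(overlaps), out / "recomb_overlaps.tsv")

    # ---- epigenome profiles ----------------------------------------------
    if cfg.run_profiles:
        tracks = simulate.generate_tracks(sim, genes)
        layout = profiles.MetageneLayout()
        prof_summary = {}
        rows = []
        for (mark, cond), track in sorted(tracks.items()):
            if cfg.write_inputs:
                write_coverage(track, inputs / f"track_{mark}_{cond}.bedGraph")
            for cls_name, gene_set in (("coding", coding_genes), ("lncRNA", lnc_genes)):
                prof = profiles.metagene(track, gene_set, layout, mark, cls_name, cond)
                peak_bin = int(np.argmax(prof.bins))
                prof_summary[f"{mark}_{cond}_{cls_name}"] = {
                    "peak_bin": peak_bin,
                    "tss_bin": layout.n_up_bins,
                    "max_signal": float(prof.bins.max()),
                }
                for label, value in prof.labelled():
                    rows.append(
                        {"mark": mark, "condition": cond, "gene_class": cls_name,
                         "bin": label, "mean_signal": value}
                    )
        write_table(pd.DataFrame(rows), out / "metagene_profiles.tsv")
        summary["profiles"] = prof_summary

    # ---- association ------------------------------------------------------
    if cfg.run_assoc:
        mean_logfpkm = np.log1p(expr_sim.fpkm).mean(axis=1)
        lnc_ids = [g.gene_id for g in lnc_genes]
        controls, quality = association.match_controls(
            mean_logfpkm.loc[lnc_ids],
            mean_logfpkm.drop(index=lnc_ids),
        )
        control_genes = [g for g in coding_genes if g.gene_id in set(controls)]
        d_lnc = association.snp_density(lnc_genes, snps, "living", cfg.assoc_alpha, "lncRNA")
        d_ctl = association.snp_density(control_genes, snps, "living", cfg.assoc_alpha, "matched_coding")
        d_oil = association.snp_density(lnc_genes, snps, "oil", cfg.assoc_alpha, "lncRNA")
        snp_tests = []
        sig = snps[snps["p_living"] < cfg.assoc_alpha]
        pop_lines = pop_traits.index.tolist()
        for _, row in sig.iterrows():
            genotypes = pd.Series({ln: row[ln] for ln in pop_lines}).replace("", np.nan)
            try:
                snp_tests.append(
                    association.genotype_trait_test(genotypes, pop_traits["living"], row["snp_id"])
                )
            except ValidationError:
                continue
        summary["association"] = {
            "match_quality_mean_abs_delta": quality,
            "lnc_density_per_kb": d_lnc.snps_per_kb,
            "control_density_per_kb": d_ctl.snps_per_kb,
            "density_ratio": (
                d_lnc.snps_per_kb / d_ctl.snps_per_kb if d_ctl.snps_per_kb > 0 else None
            ),
            "oil_density_per_kb": d_oil.snps_per_kb,
            "n_planted_snps": len(snp_truth),
            "n_significant_genotype_tests": sum(1 for t in snp_tests if t["p"] < 0.05),
            "n_genotype_tests": len(snp_tests),
        }

    # ---- networks ----------------------------------------------------------
    if cfg.run_networks and de is not None:
        de_genes = sorted(set(de.loc[de["status"] != "equal", "gene_id"]))
        expr = np.log2(expr_sim.fpkm.loc[de_genes] + 1)
        if len(expr) > cfg.max_module_genes:
            top = expr.var(axis=1).sort_values(ascending=False).index[: cfg.max_module_genes]
            expr = expr.loc[sorted(top)]
        traits = simulate.generate_traits(sim, samples, expr_sim.module_factors)
        try:
            modules = networks.detect_modules(
                expr,
                min_module_size=cfg.module_min_size,
                beta=cfg.module_beta,
                cut_height=cfg.module_cut_height,
            )
            mt = networks.module_trait(modules, traits)
            mmgs_sig = {}
            for mod in modules:
                if mod.module_label == networks.GREY or len(mod.member_genes) < 3:
                    continue
                res = networks.mm_gs(mod, expr, traits["living"])
                mmgs_sig[mod.module_label] = {
                    "cor_mm_gs": res.cor_mm_gs, "p": res.p, "significant": res.significant
                }
            summary["networks"] = {
                "n_modules": sum(1 for m in modules if m.module_label != networks.GREY),
                "module_sizes": {m.module_label: len(m.member_genes) for m in modules},
                "module_trait_retained": mt[mt["retained"]][["module", "trait"]]
                .to_dict("records"),
                "mm_gs": mmgs_sig,
            }
            mt.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        except ValidationError as exc:
            summary["networks"] = {"skipped": str(exc)}

        lnc_mir, circ_mir, mrna_mir, bridge_truth = simulate.generate_mirna_targets(sim, genes)
        edges, bridges = networks.build_cerna(lnc_mir, circ_mir, mrna_mir)
        stats = networks.network_stats(edges)
        found = set(map(tuple, bridges[["ncrna_id", "mirna_id", "mrna_id"]].to_numpy()))
        planted = set(map(tuple, bridge_truth.to_numpy()))
        summary["cerna"] = {
            "n_edges": stats["relationships"],
            "n_lncRNA": stats["lncRNA"],
            "n_circRNA": stats["circRNA"],
            "n_mRNA": stats["mRNA"],
            "n_miRNA": stats["miRNA"],
            "n_bridges": len(found),
            "planted_bridges_recovered": len(found & planted),
            "n_planted": len(planted),
            "spurious_bridges": len(found - planted),
        }
        write_table(edges, out / "cerna_edges.tsv")
        write_table(bridges, out / "cerna_bridges.tsv")

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_dict(cfg), fh, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary
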