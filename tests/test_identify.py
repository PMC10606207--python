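import time
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import gene
from lnck.identify import (
    CascadeConfig,
    TranscriptFeatures,
    classify_position,
    classify_positions,
    count_expressed,
    passes_stage,
    positions_to_frame,
    run_cascade,
)
from lnck.io import ValidationError
from lnck.simulate import generate_cascade_features


def tf(**kw):
    base = dict(
        transcript_id="t1", gene_id="g1", length_nt=500,
        noncoding_call_a=True, noncoding_call_b=True,
        best_protein_hit=None, rnc_abundance=0.0, rna_abundance=1.0,
    )
    base.update(kw)
    return TranscriptFeatures(**base)


class TestStages:
    @pytest.mark.parametrize(
        "hit,survives",
        [
            ((70.0, 40.0, 1e-12), False),  # all three alignment conditions met
            ((70.0, 40.0, 1e-8), True),    # E-value too weak
            ((60.0, 40.0, 1e-12), True),   # identity below 65
            ((70.0, 30.0, 1e-12), True),   # aligned length not > 30 aa
            ((65.0, 31.0, 1e-9), False),   # boundary: >= 65, > 30, <= 1e-9
            (None, True),                  # no hit passes
        ],
    )
    def test_protein_hit_rule(self, hit, survives):
        assert passes_stage(tf(best_protein_hit=hit), "no_protein_hit") is survives

    def test_length_strictly_over_200(self):
        assert not passes_stage(tf(length_nt=200), "length_and_abundance")
        assert passes_stage(tf(length_nt=201), "length_and_abundance")

    def test_rnc_threshold_inclusive_retention(self):
        assert passes_stage(tf(rnc_abundance=0.1), "not_translated")
        assert not passes_stage(tf(rnc_abundance=0.100001), "not_translated")

    def test_consensus_requires_both_predictors(self):
        t = tf(noncoding_call_b=False)
        assert not passes_stage(t, "noncoding_consensus")
        assert passes_stage(t, "noncoding_consensus", CascadeConfig(consensus="either"))

    def test_unknown_stage_error(self):
        with pytest.raises(ValidationError, match="unknown"):
            passes_stage(tf(), "mystery_stage")


class TestCascade:
    def test_planted_decoys_eliminated_at_their_stage(self, sim_cfg, sim_annotation):
        genes, _ = sim_annotation
        features, truth = generate_cascade_features(sim_cfg, genes)
        result = run_cascade(features)
        expect = truth.set_index("transcript_id")["planted_stage"]
        for tid, stage in expect.items():
            assert result.stage_of_elimination[tid] == stage
        n_true = (expect == "retained").sum()
        assert len(result.retained) == n_true

    def test_no_violations_retains_all(self, sim_cfg, sim_annotation):
        genes, _ = sim_annotation
        cfg = sim_cfg
        features, _ = generate_cascade_features(cfg, genes)
        clean = features[features["transcript_id"].str.startswith("LNCT")]
        result = run_cascade(clean)
        assert result.retained == set(clean["transcript_id"])

    def test_all_translated_eliminates_all(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "length_nt": [500, 600],
                "noncoding_call_a": True,
                "noncoding_call_b": True,
                "hit_identity_pct": np.nan,
                "hit_aligned_aa": np.nan,
                "hit_evalue": np.nan,
                "rnc_abundance": 1.0,
                "rna_abundance": 5.0,
            }
        )
        result = run_cascade(df)
        assert result.retained == set()
        assert all(v == "not_translated" for v in result.stage_of_elimination.values())

    def test_counts_monotone_and_order_invariant(self, sim_cfg, sim_annotation):
        genes, _ = sim_annotation
        features, _ = generate_cascade_features(sim_cfg, genes)
        result = run_cascade(features)
        counts = [c for _, c in result.per_stage_counts]
        assert counts == sorted(counts, reverse=True)
        shuffled = features.sample(frac=1.0, random_state=0).reset_index(drop=True)
        again = run_cascade(shuffled)
        assert again.retained == result.retained
        assert again.per_stage_counts == result.per_stage_counts

    def test_tightening_thresholds_shrinks_retention(self, sim_cfg, sim_annotation):
        """Monotonicity over a grid: stricter thresholds never retain more."""
        genes, _ = sim_annotation
        features, _ = generate_cascade_features(sim_cfg, genes)
        prev = None
        for max_rnc, min_rna, min_len in [(0.2, 0.05, 150), (0.1, 0.1, 200), (0.05, 0.5, 400)]:
            cfg = CascadeConfig(max_rnc=max_rnc, min_rna=min_rna, min_length_nt=min_len)
            retained = run_cascade(features, cfg).retained
            if prev is not None:
                assert retained <= prev
            prev = retained

    def test_duplicate_ids_error(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "a"], "length_nt": 500,
                "noncoding_call_a": True, "noncoding_call_b": True,
                "hit_identity_pct": np.nan, "hit_aligned_aa": np.nan,
                "hit_evalue": np.nan, "rnc_abundance": 0.0, "rna_abundance": 1.0,
            }
        )
        with pytest.raises(ValidationError, match="duplicate"):
            run_cascade(df)

    def test_empty_table_error(self):
        with pytest.raises(ValidationError, match="empty"):
            run_cascade(pd.DataFrame(columns=["transcript_id"]))

    def test_runtime_at_ten_thousand_transcripts(self):
        n = 10_000
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "length_nt": rng.integers(100, 3000, n),
                "noncoding_call_a": rng.random(n) < 0.9,
                "noncoding_call_b": rng.random(n) < 0.9,
                "hit_identity_pct": rng.uniform(0, 100, n),
                "hit_aligned_aa": rng.uniform(0, 200, n),
                "hit_evalue": 10.0 ** -rng.uniform(0, 30, n),
                "rnc_abundance": rng.uniform(0, 0.3, n),
                "rna_abundance": rng.uniform(0, 5, n),
            }
        )
        t0 = time.perf_counter()
        run_cascade(df)
        assert time.perf_counter() - t0 < 5.0


class TestPositional:
    def test_antisense_overlap_opposite_strand(self):
        coding = [gene("c1", "chr1", 1000, 5000, "+")]
        lnc = gene("l1", "chr1", 2000, 2500, "-", "lncRNA")
        res = classify_position(lnc, coding)
        assert res.position_class == "antisense"
        assert res.partner_coding_gene == "c1"

    def test_divergent_within_2kb_head_to_head(self):
        coding = [gene("c1", "chr1", 10_000, 15_000, "+")]
        lnc = gene("l1", "chr1", 8_000, 8_500, "-", "lncRNA")  # TSS at 8500, 1500 bp upstream
        assert classify_position(lnc, coding).position_class == "divergent"
        # same geometry but lnc pointing toward the gene -> not divergent
        lnc2 = gene("l2", "chr1", 8_000, 8_500, "+", "lncRNA")
        assert classify_position(lnc2, coding).position_class == "intergenic"

    def test_divergent_window_inclusive(self):
        coding = [gene("c1", "chr1", 10_000, 15_000, "+")]
        at_limit = gene("l1", "chr1", 7_900, 8_000, "-", "lncRNA")  # TSS-to-TSS 2000
        beyond = gene("l2", "chr1", 7_899, 7_999, "-", "lncRNA")    # 2001
        assert classify_position(at_limit, coding).position_class == "divergent"
        assert classify_position(beyond, coding).position_class == "intergenic"

    def test_far_gene_intergenic(self):
        coding = [gene("c1", "chr1", 1000, 5000, "+")]
        lnc = gene("l1", "chr1", 55_000, 55_400, "-", "lncRNA")
        assert classify_position(lnc, coding).position_class == "intergenic"

    def test_intronic_inside_intron_same_strand(self):
        coding = [gene("c1", "chr1", 1000, 9000, "+", exons=[(1000, 2000), (8000, 9000)])]
        lnc = gene("l1", "chr1", 3000, 3400, "+", "lncRNA")
        assert classify_position(lnc, coding[:1]).position_class == "intronic"
        # same span, opposite strand takes antisense precedence
        lnc2 = gene("l2", "chr1", 3000, 3400, "-", "lncRNA")
        assert classify_position(lnc2, coding[:1]).position_class == "antisense"

    def test_sense_overlap_partial_same_strand(self):
        coding = [gene("c1", "chr1", 1000, 5000, "+")]
        lnc = gene("l1", "chr1", 4500, 5600, "+", "lncRNA")
        assert classify_position(lnc, coding).position_class == "sense_overlapping"

    def test_missing_chromosome_warns_intergenic(self):
        coding = [gene("c1", "chr1", 1000, 5000, "+")]
        lnc = gene("l1", "chr9", 1000, 1400, "+", "lncRNA")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = classify_position(lnc, coding)
        assert res.position_class == "intergenic"
        assert rec

    def test_planted_classes_recovered_exactly(self, sim_annotation):
        genes, truth = sim_annotation
        lnc = [g for g in genes if g.biotype != "coding"]
        coding = [g for g in genes if g.biotype == "coding"]
        frame = positions_to_frame(classify_positions(lnc, coding))
        merged = frame.merge(truth, left_on="lnc_gene_id", right_on="gene_id")
        assert (merged["position_class"] == merged["planted_class"]).all()

    def test_classes_partition_the_set(self, sim_annotation):
        genes, _ = sim_annotation
        lnc = [g for g in genes if g.biotype != "coding"]
        coding = [g for g in genes if g.biotype == "coding"]
        classes = classify_positions(lnc, coding)
        assert len(classes) == len(lnc)
        assert len({c.lnc_gene_id for c in classes}) == len(lnc)

    def test_strand_mirror_invariance(self, sim_annotation):
        """Flipping all strands and mirroring coordinates preserves classes."""
        genes, _ = sim_annotation
        L = max(g.end for g in genes) + 10_000

        def mirror(g):
            exons = [(L + 1 - b, L + 1 - a) for a, b in g.transcripts[0].exons][::-1]
            return gene(
                g.gene_id, g.chrom, L + 1 - g.end, L + 1 - g.start,
                "+" if g.strand == "-" else "-", g.biotype, exons,
            )

        lnc = [g for g in genes if g.biotype != "coding"]
        coding = [g for g in genes if g.biotype == "coding"]
        orig = {c.lnc_gene_id: c.position_class for c in classify_positions(lnc, coding)}
        flipped = {
            c.lnc_gene_id: c.position_class
            for c in classify_positions([mirror(g) for g in lnc], [mirror(g) for g in coding])
        }
        assert orig == flipped


class TestCountExpressed:
    def test_threshold_inclusive(self, four_sample_meta):
        fpkm = pd.DataFrame(
            {"L_WW_1": [0.1, 0.0999], "L_WW_2": 0.0, "L_WS_1": 0.0, "L_WS_2": 0.0},
            index=["g1", "g2"],
        )
        counts, _ = count_expressed(fpkm, four_sample_meta)
        assert counts["L_WW_1"] == 1  # 0.1 counts, 0.0999 does not

    def test_all_zero_matrix(self, four_sample_meta):
        fpkm = pd.DataFrame(0.0, index=["g1"], columns=four_sample_meta["sample_id"])
        counts, specific = count_expressed(fpkm, four_sample_meta)
        assert (counts == 0).all()
        assert all(len(s) == 0 for s in specific.values())

    def test_single_line_specificity(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["RIL8_WS_1", "RIL8_WW_1", "RIL9_WS_1", "RIL9_WW_1"],
                "line_id": ["RIL8", "RIL8", "RIL9", "RIL9"],
                "generation": "RIL", "tolerance": "D",
                "condition": ["WS", "WW", "WS", "WW"], "replicate": 1,
            }
        )
        fpkm = pd.DataFrame(
            {"RIL8_WS_1": [5.0], "RIL8_WW_1": [0.0], "RIL9_WS_1": [0.0], "RIL9_WW_1": [0.0]},
            index=["g1"],
        )
        _, specific = count_expressed(fpkm, samples)
        assert specific["RIL8"] == {"g1"}
        assert specific["RIL9"] == set()
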