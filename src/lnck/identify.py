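"""lncRNA identification cascade and positional classification.

The cascade applies, in fixed order, the four evidence filters used to call
high-confidence lncRNAs from an assembled transcriptome:

1. ``noncoding_consensus`` — both coding-potential predictors call the
   transcript noncoding (intersection; the conservative reading, switchable
   to union).
2. ``no_protein_hit`` — the best protein-database hit does NOT satisfy all
   of: percent identity >= 65, aligned length > 30 aa, E-value <= 1e-9.
   A transcript with no hit passes.
3. ``not_translated`` — RNC-seq abundance <= 0.1 (ribosome-bound RNA above
   that level is treated as translated).
4. ``length_and_abundance`` — spliced length > 200 nt and RNA-seq abundance
   above 0.1 (comparison configurable: strict by default).

Positional classes are assigned relative to coding genes with the precedence
antisense > intronic > sense_overlapping > divergent > intergenic.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, ValidationError

CASCADE_STAGES = (
    "noncoding_consensus",
    "no_protein_hit",
    "not_translated",
    "length_and_abundance",
)

POSITIONAL_CLASSES = (
    "intergenic",
    "antisense",
    "divergent",
    "intronic",
    "sense_overlapping",
)

DEFAULT_PRECEDENCE = ("antisense", "intronic", "sense_overlapping", "divergent")

FEATURE_COLUMNS = [
    "transcript_id", "gene_id", "length_nt",
    "noncoding_call_a", "noncoding_call_b",
    "hit_identity_pct", "hit_aligned_aa", "hit_evalue",
    "rnc_abundance", "rna_abundance",
]


@dataclass
class TranscriptFeatures:
    """The per-transcript evidence vector consumed by the cascade.

    ``best_protein_hit`` is (identity_pct, aligned_aa, evalue) for the best
    (lowest E-value) hit, or None when the transcript hit nothing.
    """

    transcript_id: str
    gene_id: str
    length_nt: int
    noncoding_call_a: bool
    noncoding_call_b: bool
    best_protein_hit: tuple[float, float, float] | None
    rnc_abundance: float
    rna_abundance: float

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValidationError(f"{self.transcript_id}: length_nt must be > 0")
        if self.best_protein_hit is not None:
            ident, _aa, ev = self.best_protein_hit
            if not 0 <= ident <= 100:
                raise ValidationError(f"{self.transcript_id}: identity_pct not in [0,100]")
            if ev < 0:
                raise ValidationError(f"{self.transcript_id}: negative E-value")
        if self.rnc_abundance < 0 or self.rna_abundance < 0:
            raise ValidationError(f"{self.transcript_id}: negative abundance")


@dataclass
class CascadeResult:
    retained: set[str]
    per_stage_counts: list[tuple[str, int]]
    stage_of_elimination: dict[str, str]  # transcript -> stage or "retained"


@dataclass
class PositionalClass:
    lnc_gene_id: str
    position_class: str
    partner_coding_gene: str | None = None


@dataclass
class CascadeConfig:
    """Threshold set for the cascade; defaults are the published values."""

    consensus: str = "both"          # "both" (intersection) or "either"
    min_identity_pct: float = 65.0
    min_aligned_aa: float = 30.0     # strict: hit needs aligned_aa > this
    max_evalue: float = 1e-9
    max_rnc: float = 0.1             # retained iff rnc <= this
    min_length_nt: float = 200.0     # strict: length > this
    min_rna: float = 0.1
    rna_cmp: str = "gt"              # "gt" (strict, methods wording) or "ge"


def passes_stage(
    t: TranscriptFeatures, stage: str, config: CascadeConfig | None = None
) -> bool:
    """Does one transcript survive one named cascade stage?"""
    cfg = config or CascadeConfig()
    if stage == "noncoding_consensus":
        if cfg.consensus == "both":
            return bool(t.noncoding_call_a and t.noncoding_call_b)
        return bool(t.noncoding_call_a or t.noncoding_call_b)
    if stage == "no_protein_hit":
        if t.best_protein_hit is None:
            return True
        ident, aa, ev = t.best_protein_hit
        successful = (
            ident >= cfg.min_identity_pct
            and aa > cfg.min_aligned_aa
            and ev <= cfg.max_evalue
        )
        return not successful
    if stage == "not_translated":
        return t.rnc_abundance <= cfg.max_rnc
    if stage == "length_and_abundance":
        long_enough = t.length_nt > cfg.min_length_nt
        if cfg.rna_cmp == "gt":
            expressed = t.rna_abundance > cfg.min_rna
        elif cfg.rna_cmp == "ge":
            expressed = t.rna_abundance >= cfg.min_rna
        else:
            raise ValidationError(f"unknown rna_cmp {cfg.rna_cmp!r}")
        return long_enough and expressed
    raise ValidationError(f"unknown cascade stage {stage!r}")


def _stage_masks(features: pd.DataFrame, cfg: CascadeConfig) -> dict[str, np.ndarray]:
    """Vectorized pass/fail per stage for a feature table."""
    a = features["noncoding_call_a"].astype(bool).to_numpy()
    b = features["noncoding_call_b"].astype(bool).to_numpy()
    consensus = (a & b) if cfg.consensus == "both" else (a | b)

    ident = features["hit_identity_pct"].to_numpy(dtype=float)
    aa = features["hit_aligned_aa"].to_numpy(dtype=float)
    ev = features["hit_evalue"].to_numpy(dtype=float)
    has_hit = ~np.isnan(ev)
    with np.errstate(invalid="ignore"):
        successful = (
            has_hit
            & (ident >= cfg.min_identity_pct)
            & (aa > cfg.min_aligned_aa)
            & (ev <= cfg.max_evalue)
        )

    rnc_ok = features["rnc_abundance"].to_numpy(dtype=float) <= cfg.max_rnc
    length_ok = features["length_nt"].to_numpy(dtype=float) > cfg.min_length_nt
    rna = features["rna_abundance"].to_numpy(dtype=float)
    rna_ok = rna > cfg.min_rna if cfg.rna_cmp == "gt" else rna >= cfg.min_rna

    return {
        "noncoding_consensus": consensus,
        "no_protein_hit": ~successful,
        "not_translated": rnc_ok,
        "length_and_abundance": length_ok & rna_ok,
    }


def run_cascade(
    features: pd.DataFrame, config: CascadeConfig | None = None
) -> CascadeResult:
    """Apply the four stages in the published order to a feature table.

    ``features`` needs columns ``transcript_id``, ``noncoding_call_a/b``,
    ``hit_identity_pct/_aligned_aa/_evalue`` (NaN = no hit),
    ``rnc_abundance``, ``rna_abundance``, ``length_nt``.
    """
    cfg = config or CascadeConfig()
    if len(features) == 0:
        raise ValidationError("empty feature table")
    tids = features["transcript_id"]
    if tids.duplicated().any():
        dups = tids[tids.duplicated()].tolist()
        raise ValidationError(f"duplicate transcript_ids: {dups}")
    masks = _stage_masks(features, cfg)

    surviving = np.ones(len(features), dtype=bool)
    eliminated_at = np.full(len(features), "retained", dtype=object)
    per_stage_counts: list[tuple[str, int]] = []
    for stage in CASCADE_STAGES:
        newly_out = surviving & ~masks[stage]
        eliminated_at[newly_out] = stage
        surviving &= masks[stage]
        per_stage_counts.append((stage, int(surviving.sum())))

    tid_arr = tids.to_numpy()
    return CascadeResult(
        retained=set(tid_arr[surviving]),
        per_stage_counts=per_stage_counts,
        stage_of_elimination=dict(zip(tid_arr, eliminated_at)),
    )


def features_to_frame(features: Iterable[TranscriptFeatures]) -> pd.DataFrame:
    rows = []
    for t in features:
        hit = t.best_protein_hit or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "length_nt": t.length_nt,
                "noncoding_call_a": t.noncoding_call_a,
                "noncoding_call_b": t.noncoding_call_b,
                "hit_identity_pct": hit[0],
                "hit_aligned_aa": hit[1],
                "hit_evalue": hit[2],
                "rnc_abundance": t.rnc_abundance,
                "rna_abundance": t.rna_abundance,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def classify_position(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    upstream_window: int = 2000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> PositionalClass:
    """Classify one lncRNA gene relative to a coding annotation."""
    return classify_positions([lnc], coding, upstream_window, precedence)[0]


def classify_positions(
    lncs: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    upstream_window: int = 2000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[PositionalClass]:
    """Classify lncRNA genes; each gets exactly one class.

    Precedence (configurable): overlap on the opposite strand -> antisense;
    same-strand overlap fully inside an intron -> intronic; any other
    same-strand overlap -> sense_overlapping; no overlap but TSS-to-TSS
    distance <= ``upstream_window`` (inclusive) to an opposite-strand coding
    gene with the lncRNA upstream and pointing away -> divergent; otherwise
    intergenic. The partner is the nearest candidate (largest overlap for
    overlap classes; smallest TSS distance for divergent).
    """
    unknown = set(precedence) - set(POSITIONAL_CLASSES)
    if unknown:
        raise ValidationError(f"unknown classes in precedence: {sorted(unknown)}")

    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        # interval ends are exclusive in intervaltree
        trees[chrom] = IntervalTree.from_tuples(
            (g.start, g.end + 1, g) for g in gs
        )

    out: list[PositionalClass] = []
    for lnc in lncs:
        if lnc.chrom not in trees:
            warnings.warn(
                f"{lnc.gene_id}: chromosome {lnc.chrom} absent from coding "
                f"annotation; classified intergenic"
            )
            out.append(PositionalClass(lnc.gene_id, "intergenic"))
            continue
        overlaps = [iv.data for iv in trees[lnc.chrom].overlap(lnc.start, lnc.end + 1)]

        candidates: dict[str, tuple[float, GeneModel]] = {}
        for g in overlaps:
            ov = min(lnc.end, g.end) - max(lnc.start, g.start) + 1
            if g.strand != lnc.strand:
                prev = candidates.get("antisense")
                if prev is None or ov > prev[0] or (ov == prev[0] and g.gene_id < prev[1].gene_id):
                    candidates["antisense"] = (ov, g)
            else:
                inside_intron = any(
                    a <= lnc.start and lnc.end <= b for a, b in g.introns()
                )
                cls = "intronic" if inside_intron else "sense_overlapping"
                prev = candidates.get(cls)
                if prev is None or ov > prev[0] or (ov == prev[0] and g.gene_id < prev[1].gene_id):
                    candidates[cls] = (ov, g)

        if not overlaps:
            # divergent: lncRNA within the upstream window of a coding TSS,
            # opposite strand, transcribed away (head-to-head)
            best: tuple[float, GeneModel] | None = None
            for g in by_chrom[lnc.chrom]:
                if g.strand == lnc.strand:
                    continue
                if g.strand == "+" and lnc.strand == "-":
                    upstream_of = lnc.end < g.start
                else:
                    upstream_of = lnc.start > g.end
                if not upstream_of:
                    continue
                dist = abs(g.tss - lnc.tss)
                if dist <= upstream_window:
                    if best is None or dist < best[0] or (dist == best[0] and g.gene_id < best[1].gene_id):
                        best = (dist, g)
            if best is not None:
                candidates["divergent"] = best

        for cls in precedence:
            if cls in candidates:
                out.append(PositionalClass(lnc.gene_id, cls, candidates[cls][1].gene_id))
                break
        else:
            out.append(PositionalClass(lnc.gene_id, "intergenic"))
    return out


def positions_to_frame(classes: Sequence[PositionalClass]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_gene_id": [c.lnc_gene_id for c in classes],
            "position_class": [c.position_class for c in classes],
            "partner_coding_gene": [c.partner_coding_gene for c in classes],
        }
    )


# ---------------------------------------------------------------------------
# Expressed-gene counting
# ---------------------------------------------------------------------------

def count_expressed(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = 0.1,
    cmp: str = "ge",
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Per-sample expressed-gene counts and per-line specific sets.

    A gene counts as expressed in a sample iff FPKM >= threshold (the
    published rule; ``cmp="gt"`` for strict). A gene is *specific to line L*
    iff expressed in at least one sample of L and in no sample of any other
    line.
    """
    if (fpkm.to_numpy() < 0).any():
        raise ValidationError("negative FPKM")
    if cmp == "ge":
        expressed = fpkm >= threshold
    elif cmp == "gt":
        expressed = fpkm > threshold
    else:
        raise ValidationError(f"unknown cmp {cmp!r}")
    counts = expressed.sum(axis=0)
    counts.name = "n_expressed"

    line_of = samples.set_index("sample_id")["line_id"]
    expr_by_line = expressed.T.groupby(line_of.reindex(expressed.columns)).any().T
    n_lines_expr = expr_by_line.sum(axis=1)
    specific: dict[str, set[str]] = {}
    for line in expr_by_line.columns:
        mask = expr_by_line[line] & (n_lines_expr == 1)
        specific[line] = set(expr_by_line.index[mask])
    return counts, specific


def time_cascade(features: pd.DataFrame, config: CascadeConfig | None = None) -> float:
    """Wall-clock seconds for one cascade run (used by the demo report)."""
    t0 = time.perf_counter()
    run_cascade(features, config)
    return time.perf_counter() - t0
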