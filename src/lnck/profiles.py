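"""Metagene enrichment profiles and group-level modification comparisons.

A metagene profile averages a coverage track over a set of stranded genes in
a fixed layout: upstream flank (fixed-width bins), length-normalized gene
body (equal fractional bins), downstream flank. Minus-strand genes are
reversed so every profile reads 5' to 3' left to right. Genes shorter than
the body bin count are handled by fractional coverage, not an error.

The m6A transcript profile works in spliced transcript coordinates: exons
are concatenated 5' to 3' and the profile is binned along the transcript,
so an intron never contributes signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CoverageTrack, GeneModel, TranscriptModel, ValidationError


@dataclass(frozen=True)
class MetageneLayout:
    upstream_bp: int = 1000
    n_up_bins: int = 20
    n_body_bins: int = 40
    n_down_bins: int = 20
    downstream_bp: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_up_bins, self.n_body_bins, self.n_down_bins) < 1:
            raise ValidationError("every layout region needs >= 1 bin")

    @property
    def n_bins(self) -> int:
        return self.n_up_bins + self.n_body_bins + self.n_down_bins

    def labels(self) -> list[str]:
        up = [f"up{i}" for i in range(self.n_up_bins)]
        body = [f"body{i}" for i in range(self.n_body_bins)]
        down = [f"down{i}" for i in range(self.n_down_bins)]
        return up + body + down


@dataclass
class MetageneProfile:
    mark: str
    gene_class: str
    condition: str
    layout: MetageneLayout
    bins: np.ndarray  # mean signal per bin, 5'->3'
    n_genes: int = 0

    def labelled(self) -> list[tuple[str, float]]:
        return list(zip(self.layout.labels(), self.bins.tolist()))


def _gene_bin_edges(gene: GeneModel, layout: MetageneLayout) -> np.ndarray:
    """Continuous bin edges (0-based) for one gene, genomic orientation,
    ordered 5'->3' on the gene's strand."""
    lo = float(gene.start - 1)
    hi = float(gene.end)
    up_w = layout.upstream_bp / layout.n_up_bins
    down_w = layout.downstream_bp / layout.n_down_bins
    if gene.strand == "+":
        up = lo - layout.upstream_bp + up_w * np.arange(layout.n_up_bins + 1)
        body = lo + (hi - lo) / layout.n_body_bins * np.arange(layout.n_body_bins + 1)
        down = hi + down_w * np.arange(layout.n_down_bins + 1)
        edges = np.concatenate([up[:-1], body[:-1], down])
    else:
        up = hi + layout.upstream_bp - up_w * np.arange(layout.n_up_bins + 1)
        body = hi - (hi - lo) / layout.n_body_bins * np.arange(layout.n_body_bins + 1)
        down = lo - down_w * np.arange(layout.n_down_bins + 1)
        edges = np.concatenate([up[:-1], body[:-1], down])
    return edges


def metagene(
    track: CoverageTrack,
    genes: list[GeneModel],
    layout: MetageneLayout | None = None,
    mark: str = "",
    gene_class: str = "",
    condition: str = "",
) -> MetageneProfile:
    """Per-bin mean signal across genes (flanks fixed-width, body
    length-normalized, strand-aware)."""
    layout = layout or MetageneLayout()
    if not genes:
        raise ValidationError("metagene needs at least one gene")
    total = np.zeros(layout.n_bins)
    for gene in genes:
        edges = _gene_bin_edges(gene, layout)
        if gene.strand == "+":
            lo, hi = edges[:-1], edges[1:]
        else:
            lo, hi = edges[1:], edges[:-1]
        # flank bins can reach below coordinate 0 near a chromosome start
        lo = np.maximum(lo, 0.0)
        hi = np.maximum(hi, lo + 1e-9)
        total += track.segment_means(gene.chrom, lo, hi)
    return MetageneProfile(
        mark, gene_class, condition, layout, total / len(genes), len(genes)
    )


def compare_profiles(a: MetageneProfile, b: MetageneProfile) -> dict:
    """Per-bin difference b - a with TSS-region and body-region summaries."""
    if a.layout != b.layout:
        raise ValidationError("profile layouts differ")
    diff = b.bins - a.bins
    lay = a.layout
    tss = slice(max(0, lay.n_up_bins - 2), lay.n_up_bins + 3)
    body = slice(lay.n_up_bins, lay.n_up_bins + lay.n_body_bins)
    return {
        "diff": diff,
        "tss_mean_diff": float(diff[tss].mean()),
        "body_mean_diff": float(diff[body].mean()),
        "tss_sign": int(np.sign(diff[tss].mean())),
        "body_sign": int(np.sign(diff[body].mean())),
    }


def region_signal(
    track: CoverageTrack,
    genes: list[GeneModel],
    region: str = "body",
    flank_bp: int = 500,
) -> dict[str, float]:
    """Mean signal per gene over a named region: the gene body, the 5' end
    (TSS +/- flank) or the 3' end (TES +/- flank)."""
    out: dict[str, float] = {}
    for g in genes:
        if region == "body":
            lo, hi = float(g.start - 1), float(g.end)
        elif region == "5prime":
            lo, hi = float(g.tss - 1 - flank_bp), float(g.tss + flank_bp)
        elif region == "3prime":
            lo, hi = float(g.tes - 1 - flank_bp), float(g.tes + flank_bp)
        else:
            raise ValidationError(f"unknown region {region!r}")
        lo = max(lo, 0.0)
        out[g.gene_id] = float(
            track.segment_means(g.chrom, np.array([lo]), np.array([hi]))[0]
        )
    return out


def group_signal_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    equal_var: bool = False,
) -> dict:
    """Two-sample t-test on per-gene region signals (Welch by default).

    Returns group means, the effect (mean_b - mean_a), t and p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 genes")
    t, p = stats.ttest_ind(b, a, equal_var=equal_var)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "effect": float(b.mean() - a.mean()),
        "t": float(t),
        "p": float(p),
    }


def transcript_profile_m6a(
    track: CoverageTrack,
    gene: GeneModel,
    transcript: TranscriptModel | None = None,
    n_bins: int = 40,
    mark: str = "m6A",
    condition: str = "",
) -> np.ndarray:
    """Signal along one spliced transcript, 5'->3', fixed bin count."""
    tx = transcript or (gene.transcripts[0] if gene.transcripts else None)
    if tx is None or tx.length_nt == 0:
        raise ValidationError(f"{gene.gene_id}: zero-length transcript")
    # piecewise map of transcript coordinate -> genomic continuous coordinate
    exons = tx.exons if gene.strand == "+" else tx.exons[::-1]
    length = tx.length_nt
    edges_t = length / n_bins * np.arange(n_bins + 1)  # transcript-space edges
    sums = np.zeros(n_bins)
    offset = 0.0
    for a, b in exons:
        ex_len = b - a + 1
        t_lo, t_hi = offset, offset + ex_len
        # overlap of every bin with this exon in transcript space
        lo = np.clip(edges_t[:-1], t_lo, t_hi)
        hi = np.clip(edges_t[1:], t_lo, t_hi)
        w = hi - lo
        nz = w > 1e-12
        if nz.any():
            if gene.strand == "+":
                g_lo = (a - 1) + (lo[nz] - t_lo)
                g_hi = g_lo + w[nz]
            else:
                g_hi = b - (lo[nz] - t_lo)
                g_lo = g_hi - w[nz]
            means = track.segment_means(gene.chrom, g_lo, g_hi)
            sums[nz] += means * w[nz]
        offset += ex_len
    widths = edges_t[1:] - edges_t[:-1]
    return sums / widths


def transcript_metagene(
    track: CoverageTrack,
    genes: list[GeneModel],
    n_bins: int = 40,
) -> np.ndarray:
    """Mean spliced-transcript profile across genes (first transcript each)."""
    if not genes:
        raise ValidationError("needs at least one gene")
    total = np.zeros(n_bins)
    for g in genes:
        total += transcript_profile_m6a(track, g, n_bins=n_bins)
    return total / len(genes)
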