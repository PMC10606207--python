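"""Readers and writers for the external formats the pipeline touches.

Internal coordinate convention is 1-based inclusive (the GTF convention);
BED and bedGraph are 0-based half-open on disk and are converted at the
boundary, in both directions.  Strand is mandatory everywhere because
positional classification of lncRNAs is strand-defined; records with
strand "." are rejected.

TSV dialect: tab-separated, UTF-8, header row.  Missing cells are hard
errors, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = frozenset({"+", "-"})
VALID_BIOTYPES = frozenset({"coding", "lncRNA_candidate", "lncRNA"})


class ValidationError(ValueError):
    """Raised when an input file or record violates a format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A transcript: an ordered list of exon intervals on its gene's strand."""

    transcript_id: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in exons:
            if a > b:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {a} > end {b}"
                )
            if a < 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon start {a} < 1"
                )
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length_nt(self) -> int:
        """Spliced (exonic) length in nucleotides."""
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    """A stranded genomic locus with exon structure and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "coding"
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.biotype not in VALID_BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown biotype {self.biotype!r}"
            )
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        for tx in self.transcripts:
            if tx.start < self.start or tx.end > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {tx.transcript_id} "
                    f"outside gene span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start site (5' end on the gene's strand)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end on the gene's strand."""
        return self.end if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        """Exon count of the transcript with the most exons."""
        return max(tx.n_exons for tx in self.transcripts) if self.transcripts else 0

    def merged_exons(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all transcripts, sorted and merged."""
        ivals = sorted(e for tx in self.transcripts for e in tx.exons)
        merged: list[list[int]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return [(a, b) for a, b in merged]

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between merged exons."""
        ex = self.merged_exons()
        return [(b0 + 1, a1 - 1) for (_, b0), (a1, _) in zip(ex, ex[1:])]


@dataclass(frozen=True)
class Fragment:
    """A recombination fragment assigned to one RIL, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    line_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValidationError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start < 1"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, value = part.split(" ", 1)
        except ValueError:
            raise ValidationError(f"line {lineno}: malformed attribute {part!r}")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF (Ensembl attribute dialect) into validated GeneModels.

    Only ``exon`` features are used for structure; a ``gene_biotype``
    attribute, when present, sets the gene's biotype (default ``coding``).
    Raises :class:`ValidationError` naming the offending line for malformed
    coordinates or missing strand.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                )
            if start > end:
                raise ValidationError(
                    f"{path.name} line {lineno}: start {start} > end {end}"
                )
            if strand not in VALID_STRANDS:
                raise ValidationError(
                    f"{path.name} line {lineno}: missing or invalid strand "
                    f"{strand!r} (strand is mandatory)"
                )
            attrs = _parse_attributes(attr, lineno)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise ValidationError(
                        f"{path.name} line {lineno}: missing {key} attribute"
                    )
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            g = genes.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", "coding"),
                    "tx": {},
                    "order": len(genes),
                },
            )
            if g["chrom"] != chrom or g["strand"] != strand:
                raise ValidationError(
                    f"{path.name} line {lineno}: gene {gid} spans multiple "
                    f"chromosomes or strands"
                )
            g["tx"].setdefault(tid, []).append((start, end))

    out: list[GeneModel] = []
    for gid, g in sorted(genes.items(), key=lambda kv: kv[1]["order"]):
        transcripts = [
            TranscriptModel(tid, exons) for tid, exons in g["tx"].items()
        ]
        transcripts.sort(key=lambda t: (t.start, t.transcript_id))
        start = min(t.start for t in transcripts)
        end = max(t.end for t in transcripts)
        out.append(
            GeneModel(gid, g["chrom"], start, end, g["strand"], g["biotype"], transcripts)
        )
    return out


def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as GTF (transcript + exon features), round-trippable."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            common = (
                f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            )
            for tx in gene.transcripts:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom, "lnck", "transcript",
                            str(tx.start), str(tx.end), ".", gene.strand, ".",
                            f'{common} transcript_id "{tx.transcript_id}";',
                        ]
                    )
                    + "\n"
                )
                for a, b in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom, "lnck", "exon",
                                str(a), str(b), ".", gene.strand, ".",
                                f'{common} transcript_id "{tx.transcript_id}";',
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "line_id", "generation", "tolerance", "condition", "replicate"]


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (line, generation P/RIL, tolerance D/S,
    condition WW/WS, replicate >= 1); returns the validated frame."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample metadata missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_ids: {dup}")
    for col, allowed in [
        ("generation", {"P", "RIL"}),
        ("tolerance", {"D", "S"}),
        ("condition", {"WW", "WS"}),
    ]:
        bad = set(samples[col].unique()) - allowed
        if bad:
            raise ValidationError(f"invalid {col} values: {sorted(bad)}")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate must be >= 1")
    key = samples[["line_id", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValidationError("(line_id, condition, replicate) not unique")
    return samples


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line_id": str})
    return validate_samples(samples)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    validate_samples(samples).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, samples: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a genes x samples abundance TSV (first column gene_id).

    Rejects missing cells, negative values and duplicated gene_ids; when
    ``samples`` metadata is given, every matrix column must be a known
    sample_id (offenders listed in the error).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated gene_id rows: {dups}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"missing cells in columns: {bad}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric expression values: {exc}")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative expression values")
    if samples is not None:
        known = set(samples["sample_id"])
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValidationError(
                f"samples in matrix absent from metadata: {unknown}"
            )
    df.index.name = "gene_id"
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED fragments
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[Fragment]:
    """Read BED4 (chrom, start, end, line_id) recombination fragments.

    BED's 0-based half-open coordinates are converted to the internal
    1-based inclusive convention (start+1, end). An empty file yields an
    empty list; negative coordinates are errors. Overlapping fragments for
    one line are accepted and preserved.
    """
    path = Path(path)
    out: list[Fragment] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path.name} line {lineno}: BED4 requires 4 columns"
                )
            chrom, start_s, end_s, line_id = fields[:4]
            start, end = int(start_s), int(end_s)
            if start < 0 or end < 0:
                raise ValidationError(
                    f"{path.name} line {lineno}: negative coordinates"
                )
            if end <= start:
                raise ValidationError(
                    f"{path.name} line {lineno}: end {end} <= start {start}"
                )
            out.append(Fragment(chrom, start + 1, end, line_id))
    return out


def write_intervals(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as BED4 (back-converted to 0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.line_id}\n")


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Binned per-base signal held as a step function per chromosome.

    Internally 1-based inclusive intervals with float values; regions not
    covered by any interval read as 0.  Supports O(log n) point queries and
    vectorized interval means over fractional (continuous) coordinates, where
    base ``b`` occupies the continuous unit interval ``[b-1, b)``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            start, end = int(start), int(end)
            if start < 1:
                raise ValidationError(f"{chrom}:{start}-{end}: start < 1")
            if start > end:
                raise ValidationError(f"{chrom}:{start}-{end}: start > end")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in by_chrom.items():
            starts = np.array([i[0] for i in ivals])
            if not (np.diff(starts) > 0).all():
                raise ValidationError(f"{chrom}: intervals not sorted by start")
            ends = np.array([i[1] for i in ivals])
            if (starts[1:] <= ends[:-1]).any():
                raise ValidationError(f"{chrom}: overlapping intervals")
            values = np.array([i[2] for i in ivals])
            # cumulative integral of the step function up to each interval start
            lengths = (ends - starts + 1).astype(float)
            cum = np.concatenate([[0.0], np.cumsum(values * lengths)])[:-1]
            self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at 1-based position ``pos``; 0.0 outside any interval."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values, _ = self._chroms[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos > ends[i]:
            return 0.0
        return float(values[i])

    def _cumint(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the step function over continuous [0, x)."""
        starts, ends, values, cum = self._chroms[chrom]
        x = np.asarray(x, dtype=float)
        # continuous interval for record i is [starts[i]-1, ends[i])
        i = np.searchsorted(starts - 1, x, side="right") - 1
        i_c = np.clip(i, 0, len(starts) - 1)
        partial = values[i_c] * np.clip(x - (starts[i_c] - 1), 0.0, ends[i_c] - starts[i_c] + 1.0)
        out = np.where(i < 0, 0.0, cum[i_c] + partial)
        return out

    def segment_means(
        self, chrom: str, lo: np.ndarray, hi: np.ndarray
    ) -> np.ndarray:
        """Mean signal over continuous segments [lo, hi) (0-based continuous;
        the 1-based inclusive interval [a, b] corresponds to lo=a-1, hi=b)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if (hi <= lo).any():
            raise ValidationError("segment with non-positive width")
        if chrom not in self._chroms:
            return np.zeros(lo.shape)
        return (self._cumint(chrom, hi) - self._cumint(chrom, lo)) / (hi - lo)

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over the 1-based inclusive interval [start, end]."""
        return float(
            self.segment_means(chrom, np.array([start - 1.0]), np.array([float(end)]))[0]
        )


def read_coverage(path: str | Path) -> CoverageTrack:
    """Read a bedGraph (0-based half-open, sorted, non-overlapping)."""
    path = Path(path)
    records: list[tuple[str, int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path.name} line {lineno}: bedGraph requires 4 columns"
                )
            chrom, start_s, end_s, value_s = fields[:4]
            start, end = int(start_s), int(end_s)
            if start < 0:
                raise ValidationError(f"{path.name} line {lineno}: negative coordinate")
            if end <= start:
                raise ValidationError(f"{path.name} line {lineno}: end <= start")
            records.append((chrom, start + 1, end, float(value_s)))
    return CoverageTrack(records)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            starts, ends, values, _ = track._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Generic TSV helpers
# ---------------------------------------------------------------------------

def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{Path(path).name}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
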