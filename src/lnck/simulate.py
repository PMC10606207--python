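"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a biparental maize RIL drought experiment: two
parents (a drought-tolerant and a drought-sensitive inbred) plus 14 RILs,
each sampled under well-watered (WW) and water-stressed (WS) conditions
with two replicates. Defaults mirror the observed structure of such data:
82.3% of lncRNAs single-exon; positional classes dominated by intergenic
lncRNAs (90.1%) with small antisense (4.6%) and divergent (3.7%) classes;
lncRNA expression drawn an order of magnitude below coding expression;
drought shifting more lncRNAs down than up (down/up/equal probabilities
0.505/0.389/0.106 for lncRNAs vs 0.298/0.214/0.488 for coding genes);
TSS-peaked activating histone marks that are weaker on lncRNA genes;
stop-codon-proximal m6A on mRNAs only; 1320 recombination fragments;
trait-associated SNPs planted inside lncRNA loci; and miRNA bridges planted
into the ceRNA input tables.

Every planted truth label is returned alongside the data (and written as
sidecar tables by the CLI); the analysis pipeline never reads the truth.
All outputs are fully determined by the seed; per-stage RNG streams are
derived independently, so generating one input never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Fragment, GeneModel, TranscriptModel, ValidationError
from .io import CoverageTrack

# published RIL line names, split by drought tolerance
TOLERANT_RILS = ["RIL231", "RIL131", "RIL155", "RIL203", "RIL142", "RIL208", "RIL165"]
SENSITIVE_RILS = ["RIL126", "RIL64", "RIL226", "RIL27", "RIL47", "RIL8", "RIL166"]

_STAGE = {
    "annotation": 1,
    "expression": 2,
    "cascade": 3,
    "tracks": 4,
    "population": 5,
    "mirna": 6,
    "traits": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage],)))


@dataclass(frozen=True)
class MarkProfile:
    """Shape parameters of one modification's metagene signal."""

    peak_at: str           # "tss" | "stop" | "none"
    peak_coding: float
    peak_lnc: float
    body_coding: float
    body_lnc: float
    ws_shift: float        # multiplicative shift under WS: x * (1 + ws_shift)
    peak_sd: float = 150.0


DEFAULT_MARKS: dict[str, MarkProfile] = {
    "H3K4me3": MarkProfile("tss", 3.0, 1.5, 0.3, 0.2, -0.25),
    "H3K9ac": MarkProfile("tss", 2.5, 1.2, 0.3, 0.2, -0.2),
    "H3K27ac": MarkProfile("tss", 2.0, 1.0, 0.3, 0.2, -0.2),
    "H3K9me3": MarkProfile("tss", 0.3, 0.3, 0.8, 1.0, 0.25),
    "H3K4me1": MarkProfile("none", 0.0, 0.0, 1.0, 0.8, 0.25),
    "H3K36me3": MarkProfile("none", 0.0, 0.0, 1.2, 0.4, 0.25),
    "mC": MarkProfile("none", 0.0, 0.0, 0.5, 0.9, 0.0),
    "m6A": MarkProfile("stop", 2.5, 0.0, 0.3, 0.3, 0.3),
}

DEFAULT_CLASS_PROPS = {
    "intergenic": 0.901,
    "antisense": 0.046,
    "divergent": 0.037,
    "intronic": 0.010,
    "sense_overlapping": 0.006,
}

DEFAULT_DE_CONFIG = {
    "coding": {"up": 0.214, "down": 0.298, "equal": 0.488},
    "lncRNA": {"up": 0.389, "down": 0.505, "equal": 0.106},
}


@dataclass
class SimConfig:
    seed: int = 0
    # annotation
    n_coding: int = 1200
    n_lnc: int = 250
    chrom_names: tuple[str, ...] = ("chr1", "chr2")
    chrom_lengths: tuple[int, ...] | None = None  # auto-sized when None
    gap_bp: int = 6000
    frac_lnc_single_exon: float = 0.823
    class_props: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPS))
    # samples
    n_ril: int = 14
    n_reps: int = 2
    # expression
    de_config: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DE_CONFIG.items()})
    dispersion: float = 0.1
    hk_dispersion: float = 0.01
    depth: float = 150.0           # expected counts per FPKM * kb at size factor 1
    coding_meanlog: float = 2.0    # natural-log FPKM location, coding
    lnc_meanlog: float = 0.5       # lncRNA location (must be < coding)
    expr_sdlog: float = 1.0
    n_housekeeping: int = 50
    frac_specific_lnc: float = 0.192
    frac_specific_coding: float = 0.081
    n_modules: int = 3
    module_size: int = 60
    module_loading: float = 0.8
    # cascade
    n_decoys_per_stage: int = 25
    # tracks
    marks: dict = field(default_factory=lambda: dict(DEFAULT_MARKS))
    track_bin: int = 50
    track_noise_sd: float = 0.05
    # population
    n_fragments: int = 1320
    fragment_mean_kb: float = 20.0
    frac_fragments_anchored: float = 0.3
    n_snps: int = 2000
    n_planted_snps: int = 10
    n_pop_lines: int = 120
    snp_effect: float = 0.8        # per-allele effect in trait SDs
    # ceRNA
    n_bridges: int = 10
    n_distractor_edges: int = 100

    def __post_init__(self) -> None:
        for cls, probs in self.de_config.items():
            total = probs["up"] + probs["down"] + probs["equal"]
            if not np.isclose(total, 1.0):
                raise ValidationError(f"de_config[{cls}] probabilities sum to {total}")
            if min(probs.values()) < 0:
                raise ValidationError("de_config probabilities must be >= 0")
        if not 0 <= self.frac_lnc_single_exon <= 1:
            raise ValidationError("frac_lnc_single_exon must be in [0,1]")
        if not np.isclose(sum(self.class_props.values()), 1.0):
            raise ValidationError("class proportions must sum to 1")
        if self.lnc_meanlog >= self.coding_meanlog:
            raise ValidationError("lncRNA expression scale must be below coding")


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

def generate_samples(cfg: SimConfig) -> pd.DataFrame:
    """Sample metadata: 2 parents + n_ril RILs x {WW, WS} x replicates."""
    lines: list[tuple[str, str, str]] = [
        ("AC7643", "P", "D"),
        ("AC7729/TZSRW", "P", "S"),
    ]
    tol = list(TOLERANT_RILS)
    sen = list(SENSITIVE_RILS)
    for i in range(cfg.n_ril):
        src = tol if i % 2 == 0 else sen
        if src:
            name = src.pop(0)
        else:
            name = f"RIL9{i:02d}"
        lines.append((name, "RIL", "D" if i % 2 == 0 else "S"))
    rows = []
    for line, gen, tolr in lines:
        for cond in ("WW", "WS"):
            for rep in range(1, cfg.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{line}_{cond}_{rep}",
                        "line_id": line,
                        "generation": gen,
                        "tolerance": tolr,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Partition [start, end] into n_exons exons separated by introns."""
    length = end - start + 1
    if n_exons == 1:
        return [(start, end)]
    n_seg = 2 * n_exons - 1
    min_seg = 30
    if length < n_seg * min_seg:
        return [(start, end)]
    free = length - n_seg * min_seg
    w = rng.dirichlet(np.ones(n_seg))
    sizes = (w * free).astype(int) + min_seg
    sizes[-1] += length - sizes.sum()
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + size - 1))
        pos += size
    return exons


def _draw_len(rng: np.random.Generator, meanlog: float, sdlog: float, lo: int, hi: int) -> int:
    return int(np.clip(rng.lognormal(meanlog, sdlog), lo, hi))


def _lnc_exon_layout(
    rng: np.random.Generator, start: int, end: int, n_exons: int,
    min_spliced: int = 210, min_seg: int = 30,
) -> list[tuple[int, int]]:
    """Exons for an lncRNA transcript guaranteeing spliced length > 200 nt."""
    length = end - start + 1
    if n_exons > 1:
        n_exons = min(n_exons, 1 + max(0, (length - min_spliced) // min_seg))
    if n_exons <= 1:
        return [(start, end)]
    exon_total = max(min_spliced, int(0.6 * length))
    exon_total = min(exon_total, length - min_seg * (n_exons - 1))
    intron_total = length - exon_total
    ex = (rng.dirichlet(np.ones(n_exons)) * (exon_total - min_seg * n_exons)).astype(int) + min_seg
    ex[-1] += exon_total - ex.sum()
    intr = (
        rng.dirichlet(np.ones(n_exons - 1)) * (intron_total - min_seg * (n_exons - 1))
    ).astype(int) + min_seg
    intr[-1] += intron_total - intr.sum()
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(ex[i]) - 1))
        pos += int(ex[i])
        if i < n_exons - 1:
            pos += int(intr[i])
    return exons


def generate_annotation(cfg: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Coding + lncRNA gene models with planted positional-class truth.

    Returns (genes, truth) where truth has one row per lncRNA gene with its
    planted class and partner. Raises when a fixed genome length cannot
    hold the requested genes.
    """
    rng = _rng(cfg.seed, "annotation")
    n_chrom = len(cfg.chrom_names)

    # ---- coding genes, sequential placement with generous gaps
    coding: list[GeneModel] = []
    gaps_before: dict[str, list[int]] = {}
    cursors: dict[str, int] = {}
    per_chrom = [cfg.n_coding // n_chrom + (1 if i < cfg.n_coding % n_chrom else 0) for i in range(n_chrom)]
    gidx = 0
    for chrom, n_here in zip(cfg.chrom_names, per_chrom):
        cursor = 10_000
        gaps_before[chrom] = []
        for _ in range(n_here):
            gap = cfg.gap_bp + int(rng.integers(0, 2000))
            start = cursor + gap
            length = _draw_len(rng, np.log(2500), 0.5, 400, 15_000)
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = 1 + min(9, int(rng.poisson(3)))
            tid = f"CODT_{gidx:05d}"
            exons = _make_exons(rng, start, end, n_ex)
            coding.append(
                GeneModel(
                    f"COD_{gidx:05d}", chrom, start, end, strand, "coding",
                    [TranscriptModel(tid, exons)],
                )
            )
            gaps_before[chrom].append(gap)
            cursor = end
            gidx += 1
        cursors[chrom] = cursor

    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(coding):
        by_chrom.setdefault(g.chrom, []).append(i)

    # ---- class assignment for lncRNAs
    classes = list(cfg.class_props)
    counts = np.floor(np.array([cfg.class_props[c] for c in classes]) * cfg.n_lnc).astype(int)
    while counts.sum() < cfg.n_lnc:
        counts[int(np.argmax(np.array([cfg.class_props[c] for c in classes]) * cfg.n_lnc - counts))] += 1
    assignment = [c for c, n in zip(classes, counts) for _ in range(n)]
    rng.shuffle(assignment)

    available = set(range(len(coding)))
    lncs: list[GeneModel] = []
    truth_rows = []
    tail_cursor = {chrom: cursors[chrom] + 10_000 for chrom in cfg.chrom_names}

    def lnc_exons(rng, start, end):
        single = rng.random() < cfg.frac_lnc_single_exon
        n_ex = 1 if single else int(rng.integers(2, 6))
        return _lnc_exon_layout(rng, start, end, n_ex)

    for li, cls in enumerate(assignment):
        lnc_id = f"LNC_{li:05d}"
        tid = f"LNCT_{li:05d}"
        length = _draw_len(rng, np.log(700), 0.5, 250, 2000)
        partner: GeneModel | None = None
        if cls == "intergenic":
            chrom = cfg.chrom_names[li % n_chrom]
            start = tail_cursor[chrom] + 5000
            end = start + length - 1
            tail_cursor[chrom] = end
            strand = "+" if rng.random() < 0.5 else "-"
            lncs.append(GeneModel(lnc_id, chrom, start, end, strand, "lncRNA",
                                  [TranscriptModel(tid, lnc_exons(rng, start, end))]))
        elif cls == "antisense":
            cand = [i for i in available if coding[i].length >= length + 50]
            if not cand:
                raise ValidationError("no partner available for antisense placement")
            pi = int(rng.choice(cand))
            available.discard(pi)
            partner = coding[pi]
            off = int(rng.integers(0, partner.length - length + 1))
            start = partner.start + off
            end = start + length - 1
            strand = "-" if partner.strand == "+" else "+"
            lncs.append(GeneModel(lnc_id, partner.chrom, start, end, strand, "lncRNA",
                                  [TranscriptModel(tid, lnc_exons(rng, start, end))]))
        elif cls == "intronic":
            cand = []
            for i in available:
                introns = coding[i].introns()
                if introns and max(b - a + 1 for a, b in introns) >= 320:
                    cand.append(i)
            if not cand:
                raise ValidationError("no partner with a large enough intron")
            pi = int(rng.choice(cand))
            available.discard(pi)
            partner = coding[pi]
            a, b = max(partner.introns(), key=lambda iv: iv[1] - iv[0])
            ilen = b - a + 1
            use_len = min(length, ilen - 60)
            start = a + int(rng.integers(20, ilen - use_len - 20))
            end = start + use_len - 1
            lncs.append(GeneModel(lnc_id, partner.chrom, start, end, partner.strand, "lncRNA",
                                  [TranscriptModel(tid, [(start, end)])]))
        elif cls == "sense_overlapping":
            cand = [i for i in available if coding[i].length >= 400]
            if not cand:
                raise ValidationError("no partner for sense_overlapping placement")
            pi = int(rng.choice(cand))
            available.discard(pi)
            partner = coding[pi]
            ov = int(rng.integers(100, min(length - 100, partner.length - 100) + 1))
            start = partner.end - ov + 1
            end = start + length - 1
            lncs.append(GeneModel(lnc_id, partner.chrom, start, end, partner.strand, "lncRNA",
                                  [TranscriptModel(tid, lnc_exons(rng, start, end))]))
        elif cls == "divergent":
            pi = None
            for i in rng.permutation(sorted(available)):
                g = coding[i]
                chrom_idx = by_chrom[g.chrom].index(i)
                if g.strand == "+":
                    room = gaps_before[g.chrom][chrom_idx]
                else:
                    pos_in_chrom = by_chrom[g.chrom]
                    j = chrom_idx + 1
                    room = (
                        gaps_before[g.chrom][j] if j < len(pos_in_chrom) else 10_000
                    )
                if room >= length + 400:
                    pi = int(i)
                    break
            if pi is None:
                raise ValidationError("no partner with room for divergent placement")
            available.discard(pi)
            partner = coding[pi]
            g = partner
            if g.strand == "+":
                chrom_idx = by_chrom[g.chrom].index(pi)
                room = gaps_before[g.chrom][chrom_idx]
                d = int(rng.integers(200, min(1800, room - length - 100) + 1))
                end = g.start - d
                start = end - length + 1
                strand = "-"
            else:
                chrom_idx = by_chrom[g.chrom].index(pi)
                j = chrom_idx + 1
                room = gaps_before[g.chrom][j] if j < len(by_chrom[g.chrom]) else 10_000
                d = int(rng.integers(200, min(1800, room - length - 100) + 1))
                start = g.end + d
                end = start + length - 1
                strand = "+"
            lncs.append(GeneModel(lnc_id, g.chrom, start, end, strand, "lncRNA",
                                  [TranscriptModel(tid, lnc_exons(rng, start, end))]))
        else:
            raise ValidationError(f"unknown positional class {cls!r}")
        truth_rows.append(
            {
                "gene_id": lnc_id,
                "planted_class": cls,
                "partner": partner.gene_id if partner is not None else "",
            }
        )

    if cfg.chrom_lengths is not None:
        for chrom, limit in zip(cfg.chrom_names, cfg.chrom_lengths):
            needed = tail_cursor[chrom] + 10_000
            if needed > limit:
                raise ValidationError(
                    f"{chrom}: genome length {limit} cannot hold the requested "
                    f"genes (needs {needed})"
                )
    genes = coding + lncs
    return genes, pd.DataFrame(truth_rows)


def genome_lengths(cfg: SimConfig, genes: list[GeneModel]) -> dict[str, int]:
    out = {}
    for chrom in cfg.chrom_names:
        ends = [g.end for g in genes if g.chrom == chrom]
        out[chrom] = (max(ends) if ends else 0) + 10_000
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class SimExpression:
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    gene_truth: pd.DataFrame       # per gene: biotype, base_fpkm, housekeeping, specific_line, module
    de_truth: pd.DataFrame         # per gene x line: label, lfc
    size_factors: pd.Series
    module_factors: pd.DataFrame   # samples x modules realized log2 expression profile


def generate_expression(
    cfg: SimConfig, genes: list[GeneModel], samples: pd.DataFrame
) -> SimExpression:
    """Counts + FPKM with planted DE labels, specificity, housekeeping and
    module structure.

    Per gene and line a DE label is drawn from the per-class up/down/equal
    probabilities; the planted log2 fold change magnitude is
    1 + Gamma(shape 2, scale 0.75), so effects start exactly at the DE
    threshold and average 2.5. WW means are the baseline; WS means are
    baseline * 2^lfc. Counts are negative-binomial around FPKM-implied
    means; FPKM is derived back from counts with fixed per-sample size
    factors. Housekeeping genes are expressed uniformly everywhere;
    line-specific genes are expressed in a single RIL only.
    """
    per_line = samples.groupby(["line_id", "condition"]).size()
    if (per_line < 2).any():
        raise ValidationError("need >= 2 replicates per line and condition")
    rng = _rng(cfg.seed, "expression")
    gene_ids = [g.gene_id for g in genes]
    biotype = pd.Series({g.gene_id: g.biotype for g in genes})
    length_kb = pd.Series({g.gene_id: g.length / 1000.0 for g in genes})
    lines = sorted(samples["line_id"].unique())
    rils = sorted(samples.loc[samples["generation"] == "RIL", "line_id"].unique())
    n_genes = len(gene_ids)

    is_lnc = (biotype[gene_ids] != "coding").to_numpy()
    base = np.where(
        is_lnc,
        rng.lognormal(cfg.lnc_meanlog, cfg.expr_sdlog, n_genes),
        rng.lognormal(cfg.coding_meanlog, cfg.expr_sdlog, n_genes),
    )

    coding_idx = np.flatnonzero(~is_lnc)
    hk_idx = rng.choice(coding_idx, size=min(cfg.n_housekeeping, coding_idx.size), replace=False)
    hk = np.zeros(n_genes, dtype=bool)
    hk[hk_idx] = True
    base[hk] = rng.lognormal(3.5, 0.3, int(hk.sum()))

    # line-specific genes (RILs only; parents contribute essentially none)
    specific_line = np.array([""] * n_genes, dtype=object)
    for mask, frac in ((is_lnc, cfg.frac_specific_lnc), (~is_lnc & ~hk, cfg.frac_specific_coding)):
        idx = np.flatnonzero(mask & ~hk)
        n_spec = int(round(frac * idx.size))
        chosen = rng.choice(idx, size=n_spec, replace=False)
        specific_line[chosen] = rng.choice(rils, size=n_spec)

    # co-expression module structure: members share a per-line drought
    # response (they are co-regulated DEGs) plus a latent per-sample factor
    module = np.full(n_genes, -1)
    free = np.flatnonzero(~hk & (specific_line == ""))
    for m in range(cfg.n_modules):
        take = rng.choice(free, size=min(cfg.module_size, free.size), replace=False)
        module[take] = m
        free = np.setdiff1d(free, take)
    factor_z = rng.normal(size=(len(samples), max(cfg.n_modules, 1)))

    # planted DE labels per gene x line
    labels = np.empty((n_genes, len(lines)), dtype=object)
    lfc = np.zeros((n_genes, len(lines)))
    for cls, mask in (("coding", ~is_lnc), ("lncRNA", is_lnc)):
        probs = cfg.de_config[cls]
        draw = rng.choice(
            ["up", "down", "equal"],
            size=(int(mask.sum()), len(lines)),
            p=[probs["up"], probs["down"], probs["equal"]],
        )
        labels[mask] = draw
    labels[hk] = "equal"
    mag = 1.0 + rng.gamma(2.0, 0.75, size=lfc.shape)
    lfc = np.where(labels == "up", mag, np.where(labels == "down", -mag, 0.0))

    # module members: shared per-line response with small per-gene jitter
    mod_lfc = np.zeros((max(cfg.n_modules, 1), len(lines)))
    if cfg.n_modules > 0:
        sign = np.where(rng.random((cfg.n_modules, len(lines))) < 0.5, 1.0, -1.0)
        mod_lfc[: cfg.n_modules] = sign * (1.0 + rng.gamma(2.0, 0.75, (cfg.n_modules, len(lines))))
        for g_idx in np.flatnonzero(module >= 0):
            m = module[g_idx]
            lfc[g_idx] = mod_lfc[m] + rng.normal(0, 0.25, len(lines))
            labels[g_idx] = np.where(
                lfc[g_idx] >= 1, "up", np.where(lfc[g_idx] <= -1, "down", "equal")
            )

    size_factors = pd.Series(
        rng.uniform(0.7, 1.3, len(samples)), index=samples["sample_id"].tolist(),
        name="size_factor",
    )

    line_pos = {line: i for i, line in enumerate(lines)}
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    disp = np.where(hk, cfg.hk_dispersion, cfg.dispersion)
    r = 1.0 / disp
    lkb = length_kb[gene_ids].to_numpy()
    for si, sample in enumerate(samples.itertuples(index=False)):
        li = line_pos[sample.line_id]
        fold = np.where(sample.condition == "WS", 2.0 ** lfc[:, li], 1.0)
        mu = base * fold * lkb * cfg.depth * size_factors[sample.sample_id]
        mod_mask = module >= 0
        if mod_mask.any():
            z = factor_z[si]
            mu = mu * np.where(
                mod_mask, 2.0 ** (cfg.module_loading * z[np.clip(module, 0, None)]), 1.0
            )
        off = (specific_line != "") & (specific_line != sample.line_id)
        mu = np.where(off, 0.0, mu)
        pos = mu > 0
        c = np.zeros(n_genes)
        c[pos] = rng.negative_binomial(r[pos], r[pos] / (r[pos] + mu[pos]))
        counts[:, si] = c
    sample_ids = samples["sample_id"].tolist()
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    fpkm = counts_df / (lkb[:, None] * cfg.depth * size_factors[sample_ids].to_numpy()[None, :])

    gene_truth = pd.DataFrame(
        {
            "biotype": biotype[gene_ids].to_numpy(),
            "base_fpkm": base,
            "housekeeping": hk,
            "specific_line": specific_line,
            "module": module,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    de_truth = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, len(lines)),
            "line_id": np.tile(lines, n_genes),
            "label": labels.ravel(),
            "lfc": lfc.ravel(),
        }
    )
    # realized per-sample module expression profile (what the eigengene
    # should recover): shared line response under WS + latent factor
    profile = np.zeros((len(samples), max(cfg.n_modules, 1)))
    for si, sample in enumerate(samples.itertuples(index=False)):
        li = line_pos[sample.line_id]
        ws = 1.0 if sample.condition == "WS" else 0.0
        profile[si] = mod_lfc[:, li] * ws + cfg.module_loading * factor_z[si]
    module_factors = pd.DataFrame(
        profile[:, : max(cfg.n_modules, 1)],
        index=samples["sample_id"].tolist(),
        columns=[f"module_{m}" for m in range(max(cfg.n_modules, 1))],
    )
    return SimExpression(counts_df, fpkm, gene_truth, de_truth, size_factors, module_factors)


def generate_traits(cfg: SimConfig, samples: pd.DataFrame, module_factors: pd.DataFrame) -> pd.DataFrame:
    """Per-sample phenotype traits; survival under drought ('living') is
    driven by the first planted co-expression module, the rest are noise."""
    rng = _rng(cfg.seed, "traits")
    idx = samples["sample_id"].tolist()
    traits = pd.DataFrame(index=pd.Index(idx, name="sample_id"))
    if cfg.n_modules > 0:
        z = module_factors.loc[idx, "module_0"].to_numpy()
        z = (z - z.mean()) / max(z.std(), 1e-12)
    else:
        z = np.zeros(len(idx))
    traits["living"] = 50 + 10 * (0.7 * z + 0.3 * rng.normal(size=len(idx)))
    for name in ("ph", "root_dw", "SPAD"):
        traits[name] = rng.normal(size=len(idx))
    return traits


# ---------------------------------------------------------------------------
# Cascade features
# ---------------------------------------------------------------------------

def generate_cascade_features(
    cfg: SimConfig, genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table for the identification cascade with planted decoys.

    True lncRNA transcripts satisfy every cascade predicate; each decoy
    violates exactly one named stage. Returns (features, truth) where truth
    has planted_stage per transcript ("retained" for true lncRNAs).
    """
    rng = _rng(cfg.seed, "cascade")
    rows, truth = [], []

    def weak_hit() -> tuple[float, float, float]:
        kind = rng.integers(0, 3)
        ident = rng.uniform(65, 95) if kind != 0 else rng.uniform(20, 64.9)
        aa = rng.uniform(31, 200) if kind != 1 else rng.uniform(5, 30)
        ev = 10.0 ** -rng.uniform(10, 30) if kind != 2 else 10.0 ** -rng.uniform(0, 8.9)
        return float(ident), float(aa), float(ev)

    for g in genes:
        if g.biotype == "coding":
            continue
        tx = g.transcripts[0]
        has_weak = rng.random() < 0.3
        ident, aa, ev = weak_hit() if has_weak else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "gene_id": g.gene_id,
                "length_nt": tx.length_nt,
                "noncoding_call_a": True,
                "noncoding_call_b": True,
                "hit_identity_pct": ident,
                "hit_aligned_aa": aa,
                "hit_evalue": ev,
                "rnc_abundance": float(rng.uniform(0, 0.1)),
                "rna_abundance": float(rng.uniform(0.2, 20)),
            }
        )
        truth.append({"transcript_id": tx.transcript_id, "planted_stage": "retained"})

    stages = ["noncoding_consensus", "no_protein_hit", "not_translated", "length_and_abundance"]
    di = 0
    for stage in stages:
        for _ in range(cfg.n_decoys_per_stage):
            row = {
                "transcript_id": f"DECOY_{di:04d}",
                "gene_id": f"GDECOY_{di:04d}",
                "length_nt": int(rng.integers(300, 3000)),
                "noncoding_call_a": True,
                "noncoding_call_b": True,
                "hit_identity_pct": np.nan,
                "hit_aligned_aa": np.nan,
                "hit_evalue": np.nan,
                "rnc_abundance": float(rng.uniform(0, 0.1)),
                "rna_abundance": float(rng.uniform(0.2, 20)),
            }
            if stage == "noncoding_consensus":
                which = "noncoding_call_a" if rng.random() < 0.5 else "noncoding_call_b"
                row[which] = False
            elif stage == "no_protein_hit":
                row["hit_identity_pct"] = float(rng.uniform(65, 95))
                row["hit_aligned_aa"] = float(rng.uniform(31, 200))
                row["hit_evalue"] = float(10.0 ** -rng.uniform(9.5, 30))
            elif stage == "not_translated":
                row["rnc_abundance"] = float(rng.uniform(0.2, 5))
            else:
                if rng.random() < 0.5:
                    row["length_nt"] = int(rng.integers(50, 201))
                else:
                    row["rna_abundance"] = float(rng.uniform(0, 0.1))
            rows.append(row)
            truth.append({"transcript_id": row["transcript_id"], "planted_stage": stage})
            di += 1
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def generate_tracks(
    cfg: SimConfig,
    genes: list[GeneModel],
    peak_boost: dict[str, dict[str, float]] | None = None,
) -> dict[tuple[str, str], CoverageTrack]:
    """Per-mark, per-condition coverage with strand-aware planted shapes.

    Signal near each gene = body level over the span + a Gaussian peak at
    the TSS (or near the 3' end for stop-proximal marks) + white noise,
    scaled by (1 + ws_shift) under WS. ``peak_boost[mark][gene_id]`` adds
    to that gene's peak height (used to plant group-level differences).
    """
    rng = _rng(cfg.seed, "tracks")
    lengths = genome_lengths(cfg, genes)
    bw = cfg.track_bin
    out: dict[tuple[str, str], CoverageTrack] = {}
    flank = 1500

    for mark, prof in cfg.marks.items():
        boost = (peak_boost or {}).get(mark, {})
        for cond in ("WW", "WS"):
            scale = 1.0 + prof.ws_shift if cond == "WS" else 1.0
            arrays = {
                chrom: np.zeros(length // bw + 2 * flank // bw + 4)
                for chrom, length in lengths.items()
            }
            covered = {chrom: np.zeros_like(a, dtype=bool) for chrom, a in arrays.items()}
            for g in genes:
                is_lnc = g.biotype != "coding"
                body = prof.body_lnc if is_lnc else prof.body_coding
                peak = prof.peak_lnc if is_lnc else prof.peak_coding
                peak += boost.get(g.gene_id, 0.0)
                lo = max(0, (g.start - flank) // bw)
                hi = (g.end + flank) // bw + 1
                arr = arrays[g.chrom]
                hi = min(hi, arr.size)
                centers = (np.arange(lo, hi) + 0.5) * bw
                sig = np.where((centers >= g.start) & (centers <= g.end), body, 0.0)
                if prof.peak_at != "none" and peak != 0.0:
                    if prof.peak_at == "tss":
                        center = g.tss
                    else:  # stop-proximal: inside the last (3'-most) exon
                        last_exon = g.merged_exons()[-1 if g.strand == "+" else 0]
                        if g.strand == "+":
                            center = max(last_exon[0], g.tes - 150)
                        else:
                            center = min(last_exon[1], g.tes + 150)
                    sig = sig + peak * np.exp(-0.5 * ((centers - center) / prof.peak_sd) ** 2)
                arr[lo:hi] += sig * scale
                covered[g.chrom][lo:hi] = True
            records = []
            for chrom in sorted(arrays):
                arr, cov = arrays[chrom], covered[chrom]
                idx = np.flatnonzero(cov)
                if idx.size == 0:
                    continue
                noise = rng.normal(0, cfg.track_noise_sd, idx.size)
                vals = np.round(np.maximum(arr[idx] + noise, 0.0), 4)
                starts = idx * bw + 1
                keep = vals > 0
                for s, v in zip(starts[keep], vals[keep]):
                    records.append((chrom, int(s), int(s + bw - 1), float(v)))
            out[(mark, cond)] = CoverageTrack(records)
    return out


# ---------------------------------------------------------------------------
# Population data
# ---------------------------------------------------------------------------

def generate_population_data(
    cfg: SimConfig,
    genes: list[GeneModel],
    samples: pd.DataFrame,
    specific_line: pd.Series | None = None,
) -> tuple[list[Fragment], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Recombination fragments, SNP genotype+association table, population
    traits, and the planted-SNP truth table.

    A configurable fraction of fragments is anchored on genes specifically
    expressed in the fragment's RIL (lncRNA-weighted), planting the excess
    of offspring-specific lncRNAs at recombination sites. Trait-associated
    SNPs are planted inside lncRNA loci with additive genotype effects on
    survival; every other SNP is null for both traits.
    """
    rng = _rng(cfg.seed, "population")
    lengths = genome_lengths(cfg, genes)
    rils = sorted(samples.loc[samples["generation"] == "RIL", "line_id"].unique())
    if not rils:
        raise ValidationError("no RIL lines in sample metadata")

    spec = specific_line if specific_line is not None else pd.Series(dtype=object)
    by_line: dict[str, list[GeneModel]] = {}
    for g in genes:
        line = spec.get(g.gene_id, "")
        if line:
            by_line.setdefault(str(line), []).append(g)

    fragments: list[Fragment] = []
    chroms = sorted(lengths)
    for _ in range(cfg.n_fragments):
        line = str(rng.choice(rils))
        flen = max(2000, int(rng.lognormal(np.log(cfg.fragment_mean_kb * 1000), 0.6)))
        anchors = by_line.get(line, [])
        if anchors and rng.random() < cfg.frac_fragments_anchored:
            weights = np.array([3.0 if a.biotype != "coding" else 1.0 for a in anchors])
            anchor = anchors[int(rng.choice(len(anchors), p=weights / weights.sum()))]
            mid = (anchor.start + anchor.end) // 2
            start = max(1, mid - flen // 2)
            chrom = anchor.chrom
        else:
            chrom = str(rng.choice(chroms))
            start = int(rng.integers(1, max(2, lengths[chrom] - flen)))
        fragments.append(Fragment(chrom, start, min(start + flen - 1, lengths[chrom]), line))

    # ---- SNPs in the natural association panel
    pop_lines = [f"NP{i:04d}" for i in range(cfg.n_pop_lines)]
    lnc_genes = [g for g in genes if g.biotype != "coding"]
    planted_idx = (
        rng.choice(len(lnc_genes), size=min(cfg.n_planted_snps, len(lnc_genes)), replace=False)
        if cfg.n_planted_snps > 0 and lnc_genes
        else np.array([], dtype=int)
    )
    base_trait = rng.normal(50, 10, cfg.n_pop_lines)
    oil = rng.normal(4.0, 0.5, cfg.n_pop_lines)
    rows = []
    genotype_cols = {line: [] for line in pop_lines}
    effect_sum = np.zeros(cfg.n_pop_lines)
    truth_rows = []
    for i in range(cfg.n_snps):
        if i < planted_idx.size:
            g = lnc_genes[int(planted_idx[i])]
            chrom = g.chrom
            pos = int(rng.integers(g.start, g.end + 1))
            planted = True
        else:
            chrom = str(rng.choice(chroms))
            pos = int(rng.integers(1, lengths[chrom]))
            planted = False
        freq = rng.uniform(0.2, 0.8)
        gt_codes = rng.binomial(2, freq, cfg.n_pop_lines).astype(float)
        miss = rng.random(cfg.n_pop_lines) < 0.02
        if planted:
            effect_sum += cfg.snp_effect * 10 * (gt_codes - gt_codes.mean())
            p_living = float(10.0 ** -rng.uniform(6, 12))
        else:
            p_living = float(rng.uniform(0, 1))
        p_oil = float(rng.uniform(0, 1))
        snp_id = f"snp_{i:05d}"
        rows.append(
            {"snp_id": snp_id, "chrom": chrom, "pos": pos,
             "p_living": p_living, "p_oil": p_oil}
        )
        gt_names = np.array(["AA", "Aa", "aa"])[gt_codes.astype(int)]
        gt_names = np.where(miss, "", gt_names)
        for line, gt in zip(pop_lines, gt_names):
            genotype_cols[line].append(gt)
        if planted:
            truth_rows.append({"snp_id": snp_id, "gene_id": lnc_genes[int(planted_idx[i])].gene_id})
    snps = pd.concat([pd.DataFrame(rows), pd.DataFrame(genotype_cols)], axis=1)
    pop_traits = pd.DataFrame(
        {"living": base_trait + effect_sum / max(1, cfg.n_planted_snps), "oil": oil},
        index=pd.Index(pop_lines, name="line_id"),
    )
    return fragments, snps, pop_traits, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# miRNA target tables
# ---------------------------------------------------------------------------

def generate_mirna_targets(
    cfg: SimConfig, genes: list[GeneModel] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(lnc_mir, circ_mir, mrna_mir, truth_bridges) with planted bridges.

    Planted triples share a bridge miRNA between an lncRNA edge and an mRNA
    edge; distractor edges use miRNAs private to one RNA class, so they can
    never form a bridge.
    """
    rng = _rng(cfg.seed, "mirna")
    interactions = sorted(INTERACTIONS)
    lnc_ids = (
        [g.gene_id for g in genes if g.biotype != "coding"]
        if genes else [f"LNC_{i:05d}" for i in range(max(cfg.n_bridges, 20))]
    )
    mrna_ids = (
        [g.gene_id for g in genes if g.biotype == "coding"]
        if genes else [f"COD_{i:05d}" for i in range(200)]
    )
    lnc_rows, circ_rows, mrna_rows, truth = [], [], [], []
    for i in range(cfg.n_bridges):
        mir = f"zma-miR{i + 100:03d}-5p"
        lnc = lnc_ids[i % len(lnc_ids)]
        mrna = mrna_ids[i % len(mrna_ids)]
        lnc_rows.append({"rna_id": lnc, "mirna_id": mir,
                         "interaction": interactions[int(rng.integers(3))]})
        mrna_rows.append({"rna_id": mrna, "mirna_id": mir,
                          "interaction": interactions[int(rng.integers(3))]})
        if rng.random() < 0.3:
            circ = f"circRNA_{i}_{int(rng.integers(1e6))}"
            circ_rows.append({"rna_id": circ, "mirna_id": mir,
                              "interaction": interactions[int(rng.integers(3))]})
            truth.append({"ncrna_id": circ, "mirna_id": mir, "mrna_id": mrna})
        truth.append({"ncrna_id": lnc, "mirna_id": mir, "mrna_id": mrna})
    for j in range(cfg.n_distractor_edges):
        cls = j % 3
        mir = f"zma-miR{900 + j:04d}-3p"  # private namespace per distractor
        if cls == 0:
            lnc_rows.append({"rna_id": lnc_ids[int(rng.integers(len(lnc_ids)))],
                             "mirna_id": mir, "interaction": interactions[int(rng.integers(3))]})
        elif cls == 1:
            circ_rows.append({"rna_id": f"circRNA_d{j}", "mirna_id": mir,
                              "interaction": interactions[int(rng.integers(3))]})
        else:
            mrna_rows.append({"rna_id": mrna_ids[int(rng.integers(len(mrna_ids)))],
                              "mirna_id": mir, "interaction": interactions[int(rng.integers(3))]})
    cols = ["rna_id", "mirna_id", "interaction"]
    return (
        pd.DataFrame(lnc_rows, columns=cols),
        pd.DataFrame(circ_rows, columns=cols),
        pd.DataFrame(mrna_rows, columns=cols),
        pd.DataFrame(truth, columns=["ncrna_id", "mirna_id", "mrna_id"]),
    )


INTERACTIONS = frozenset({"cleavage", "translation_inhibition", "mimic"})
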