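"""SNP-density enrichment in lncRNA loci with expression-matched coding
controls, and per-SNP genotype-phenotype comparisons.

Association p-values are inputs (from a GWAS run upstream or the synthetic
generator); this module counts trait-associated SNPs falling inside gene
spans, normalizes by the summed gene length in kb, and compares lncRNA loci
against a coding control set matched on mean log(FPKM + 1) by greedy
nearest-neighbor matching without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, ValidationError

SNP_COLUMNS = ["snp_id", "chrom", "pos"]
GENOTYPES = ("AA", "Aa", "aa")


@dataclass
class DensityReport:
    gene_set_label: str
    n_genes: int
    total_kb: float
    n_significant_snps: int
    snps_per_kb: float


def match_controls(
    lnc_expr: pd.Series,
    coding_expr: pd.Series,
    k: int | None = None,
) -> tuple[list[str], float]:
    """Greedy nearest-neighbor expression matching without replacement.

    ``lnc_expr`` and ``coding_expr`` are per-gene mean log(FPKM+1); returns
    (matched coding gene ids, mean |delta| match quality). Targets are
    processed in order of decreasing expression so dense regions are matched
    before the pool thins out.
    """
    k = len(lnc_expr) if k is None else k
    if len(coding_expr) < k:
        raise ValidationError(
            f"coding pool ({len(coding_expr)}) smaller than k ({k})"
        )
    pool = coding_expr.sort_values(kind="stable")
    pool_vals = pool.to_numpy(dtype=float)
    pool_ids = pool.index.to_numpy()
    used = np.zeros(len(pool_vals), dtype=bool)
    targets = lnc_expr.sort_values(ascending=False, kind="stable").head(k)

    chosen: list[str] = []
    deltas: list[float] = []
    for value in targets.to_numpy(dtype=float):
        i = int(np.searchsorted(pool_vals, value))
        left, right = i - 1, i
        while left >= 0 and used[left]:
            left -= 1
        while right < len(pool_vals) and used[right]:
            right += 1
        left_ok = left >= 0
        right_ok = right < len(pool_vals)
        if not (left_ok or right_ok):
            raise ValidationError("pool exhausted")
        if left_ok and right_ok:
            pick = left if value - pool_vals[left] <= pool_vals[right] - value else right
        else:
            pick = left if left_ok else right
        used[pick] = True
        chosen.append(str(pool_ids[pick]))
        deltas.append(abs(pool_vals[pick] - value))
    return chosen, float(np.mean(deltas)) if deltas else 0.0


def validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_COLUMNS if c not in snps.columns]
    if missing:
        raise ValidationError(f"SNP table missing columns {missing}")
    if (snps["pos"] < 1).any():
        raise ValidationError("SNP pos must be >= 1")
    return snps


def snp_density(
    genes: list[GeneModel],
    snps: pd.DataFrame,
    trait: str,
    alpha: float = 1e-5,
    label: str = "",
) -> DensityReport:
    """Density (per kb of summed gene span) of SNPs associated with a trait.

    A SNP counts iff its association p for ``trait`` (column ``p_<trait>``)
    is below ``alpha`` and its position lies within a gene's [start, end]
    span (gene span, not exons, matching 'located within' the locus).
    """
    if not genes:
        raise ValidationError("empty gene set")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0,1)")
    validate_snps(snps)
    pcol = f"p_{trait}"
    if pcol not in snps.columns:
        raise ValidationError(f"SNP table missing column {pcol}")
    sig = snps[snps[pcol] < alpha]
    total_kb = sum(g.length for g in genes) / 1000.0
    n_hits = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, sub in sig.groupby("chrom"):
        gs = by_chrom.get(str(chrom))
        if not gs:
            continue
        starts = np.array([g.start for g in gs])
        ends = np.array([g.end for g in gs])
        pos = sub["pos"].to_numpy()
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        n_hits += int(inside.any(axis=1).sum())
    return DensityReport(label, len(genes), total_kb, n_hits, n_hits / total_kb)


def genotype_trait_test(
    genotypes: pd.Series,
    traits: pd.Series,
    snp_id: str = "",
) -> dict:
    """Per-genotype trait means with a two-class Welch t-test or three-class
    one-way ANOVA; missing genotypes are dropped.

    Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
    """
    df = pd.DataFrame({"g": genotypes, "y": traits}).dropna()
    df = df[df["g"].isin(GENOTYPES)]
    groups = {g: sub["y"].to_numpy(dtype=float) for g, sub in df.groupby("g")}
    groups = {g: v for g, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValidationError(f"{snp_id}: monomorphic")
    keys = sorted(groups)
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[keys[0]], groups[keys[1]], equal_var=False)
        test = "welch_t"
        statistic = float(t)
    else:
        f, p = stats.f_oneway(*(groups[k] for k in keys))
        test = "anova"
        statistic = float(f)
    p = float(p)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {
        "snp_id": snp_id,
        "means": {g: float(v.mean()) for g, v in groups.items()},
        "n": {g: int(v.size) for g, v in groups.items()},
        "test": test,
        "statistic": statistic,
        "p": p,
        "stars": stars,
    }
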