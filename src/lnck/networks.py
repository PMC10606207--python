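"""Co-expression module detection with eigengene statistics, and
miRNA-bridged ceRNA network assembly.

Module detection is a transparent simplification of the weighted
co-expression workflow: signed adjacency a_ij = ((1 + cor_ij)/2)^beta,
dissimilarity 1 - a_ij, average-linkage hierarchical clustering cut at a
fixed height, clusters below the minimum size labelled grey. The module
eigengene is the first principal component of the standardized member
expression, with its sign fixed so the mean gene-eigengene correlation
(module membership, MM) is non-negative. Gene significance (GS) is the
gene-trait correlation; module-trait and MM-GS statistics are plain
Pearson correlations with their t-test p-values.

The ceRNA network joins lncRNA/circRNA-miRNA edges with miRNA-mRNA edges on
the shared miRNA: a bridge triple (ncRNA, miRNA, mRNA) exists iff both
edges do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ValidationError

INTERACTION_TYPES = frozenset({"cleavage", "translation_inhibition", "mimic"})
RNA_TYPES = frozenset({"lncRNA", "circRNA", "mRNA"})
GREY = "grey"


@dataclass
class ModuleResult:
    module_label: str
    member_genes: list[str]
    eigengene: pd.Series  # per-sample score, unit variance
    trait_correlations: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class MMGS:
    module_label: str
    mm: pd.Series  # per-gene correlation with the eigengene
    gs: pd.Series  # per-gene correlation with the trait
    cor_mm_gs: float
    p: float
    significant: bool  # |cor| > 0.3 and p < 0.05


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def eigengene(expr_module: pd.DataFrame) -> pd.Series:
    """First principal component score of standardized member expression.

    ``expr_module`` is genes x samples with >= 2 genes; the returned score
    has unit variance and its sign makes the mean gene-eigengene
    correlation non-negative.
    """
    if expr_module.shape[0] < 2:
        raise ValidationError("eigengene needs >= 2 genes")
    x = expr_module.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValidationError("rank-0 module: all genes constant")
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValidationError("rank-0 module")
    score = vt[0]
    score = score / score.std(ddof=0)
    corrs = np.array([np.corrcoef(row, score)[0, 1] for row in z])
    if corrs.mean() < 0:
        score = -score
    return pd.Series(score, index=expr_module.columns, name="eigengene")


def detect_modules(
    expr: pd.DataFrame,
    min_module_size: int = 30,
    beta: float = 6.0,
    cut_height: float = 0.9,
) -> list[ModuleResult]:
    """Detect co-expression modules among (differentially expressed) genes.

    ``expr`` is genes x samples with >= 4 samples. Constant-expression genes
    are dropped with a warning. Genes whose cluster falls below
    ``min_module_size`` are collected in the grey module. Deterministic and
    invariant to input row order (genes are canonicalized by id first).
    Labels M1, M2, ... are assigned by decreasing size, ties broken by the
    lexicographically smallest member.
    """
    if expr.shape[1] < 4:
        raise ValidationError("module detection needs >= 4 samples")
    expr = expr.sort_index(kind="stable")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        import warnings

        warnings.warn(f"dropping {int((sd == 0).sum())} constant-expression genes")
        expr = expr.loc[sd > 0]
        x = expr.to_numpy(dtype=float)
    if expr.shape[0] < min_module_size:
        raise ValidationError(
            f"need >= min_module_size ({min_module_size}) non-constant genes"
        )
    cor = np.corrcoef(x)
    adjacency = ((1.0 + cor) / 2.0) ** beta
    diss = 1.0 - adjacency
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # exact symmetry for squareform
    tree = linkage(squareform(diss, checks=False), method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")

    genes = expr.index.to_numpy()
    clusters: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(str(g))
    kept = [sorted(m) for m in clusters.values() if len(m) >= min_module_size]
    grey = sorted(
        g for m in clusters.values() if len(m) < min_module_size for g in m
    )
    kept.sort(key=lambda m: (-len(m), m[0]))

    out: list[ModuleResult] = []
    for i, members in enumerate(kept, start=1):
        eg = eigengene(expr.loc[members])
        out.append(ModuleResult(f"M{i}", members, eg))
    if grey:
        sub = expr.loc[grey]
        eg = (
            eigengene(sub)
            if len(grey) >= 2 and (sub.std(axis=1) > 0).any()
            else pd.Series(np.zeros(expr.shape[1]), index=expr.columns)
        )
        out.append(ModuleResult(GREY, grey, eg))
    return out


# ---------------------------------------------------------------------------
# Module-trait and MM-GS statistics
# ---------------------------------------------------------------------------

def module_trait(
    modules: list[ModuleResult],
    traits: pd.DataFrame,
    r_min: float = 0.2,
    alpha: float = 0.05,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    ``traits`` is samples x traits, measured for every sample. Returns a
    long frame (module, trait, r, p, retained) where retained means
    |r| > r_min and p < alpha. Constant traits are skipped with a warning.
    """
    rows = []
    for mod in modules:
        if mod.module_label == GREY and not include_grey:
            continue
        eg = mod.eigengene.reindex(traits.index)
        if eg.isna().any():
            raise ValidationError("trait table missing samples of the eigengene")
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            if np.std(y) == 0:
                import warnings

                warnings.warn(f"trait {trait} is constant; skipped")
                continue
            r, p = stats.pearsonr(eg.to_numpy(), y)
            rows.append(
                {
                    "module": mod.module_label,
                    "trait": trait,
                    "r": float(r),
                    "p": float(p),
                    "retained": bool(abs(r) > r_min and p < alpha),
                }
            )
        mod.trait_correlations = [
            (row["trait"], row["r"], row["p"]) for row in rows
            if row["module"] == mod.module_label
        ]
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "retained"])


def mm_gs(
    module: ModuleResult,
    expr: pd.DataFrame,
    trait: pd.Series,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> MMGS:
    """Module membership vs gene significance for one module and one trait."""
    if len(module.member_genes) < 3:
        raise ValidationError("module size < 3")
    sub = expr.loc[module.member_genes]
    y = trait.reindex(sub.columns).to_numpy(dtype=float)
    eg = module.eigengene.reindex(sub.columns).to_numpy(dtype=float)
    x = sub.to_numpy(dtype=float)
    mm = np.array([stats.pearsonr(row, eg)[0] for row in x])
    gs = np.array([stats.pearsonr(row, y)[0] for row in x])
    r, p = stats.pearsonr(mm, gs)
    return MMGS(
        module.module_label,
        pd.Series(mm, index=sub.index, name="MM"),
        pd.Series(gs, index=sub.index, name="GS"),
        float(r),
        float(p),
        bool(abs(r) > r_min and p < alpha),
    )


# ---------------------------------------------------------------------------
# ceRNA assembly
# ---------------------------------------------------------------------------

def _validate_mir_table(df: pd.DataFrame, rna_type: str) -> pd.DataFrame:
    for col in ("rna_id", "mirna_id", "interaction"):
        if col not in df.columns:
            raise ValidationError(f"{rna_type} table missing column {col!r}")
    bad = set(df["interaction"].unique()) - INTERACTION_TYPES
    if bad:
        raise ValidationError(f"unknown interaction type(s): {sorted(bad)}")
    out = df[["rna_id", "mirna_id", "interaction"]].copy()
    out["rna_type"] = rna_type
    return out


def build_cerna(
    lnc_mir: pd.DataFrame,
    circ_mir: pd.DataFrame,
    mrna_mir: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the typed edge list and the miRNA-bridged triples.

    Returns (edges, bridges): edges has columns rna_id, rna_type, mirna_id,
    interaction; bridges has (ncrna_id, ncrna_type, mirna_id, mrna_id), one
    row per (ncRNA, miRNA, mRNA) with both edges present. Output is
    independent of input row order (canonically sorted).
    """
    parts = [
        _validate_mir_table(lnc_mir, "lncRNA"),
        _validate_mir_table(circ_mir, "circRNA"),
        _validate_mir_table(mrna_mir, "mRNA"),
    ]
    edges = (
        pd.concat(parts, ignore_index=True)
        .drop_duplicates(subset=["rna_id", "rna_type", "mirna_id", "interaction"])
        .sort_values(["rna_type", "rna_id", "mirna_id", "interaction"], kind="stable")
        .reset_index(drop=True)
    )
    nc = edges[edges["rna_type"].isin(["lncRNA", "circRNA"])]
    m = edges[edges["rna_type"] == "mRNA"]
    bridges = (
        nc[["rna_id", "rna_type", "mirna_id"]]
        .drop_duplicates()
        .merge(
            m[["rna_id", "mirna_id"]].drop_duplicates().rename(columns={"rna_id": "mrna_id"}),
            on="mirna_id",
        )
        .rename(columns={"rna_id": "ncrna_id", "rna_type": "ncrna_type"})
        .sort_values(["ncrna_id", "mirna_id", "mrna_id"], kind="stable")
        .reset_index(drop=True)
    )
    return edges, bridges


def network_stats(edges: pd.DataFrame) -> dict:
    """Node counts per RNA type, miRNA count, edge count and the degree
    distribution over all nodes."""
    if len(edges) == 0:
        raise ValidationError("empty edge list")
    counts = {
        t: int(edges.loc[edges["rna_type"] == t, "rna_id"].nunique())
        for t in sorted(RNA_TYPES)
    }
    counts["miRNA"] = int(edges["mirna_id"].nunique())
    unique_edges = edges.drop_duplicates(subset=["rna_id", "rna_type", "mirna_id"])
    counts["relationships"] = int(len(unique_edges))
    degree = pd.concat(
        [
            unique_edges.groupby("rna_id").size(),
            unique_edges.groupby("mirna_id").size(),
        ]
    )
    counts["degree_distribution"] = degree.sort_index().to_dict()
    return counts
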