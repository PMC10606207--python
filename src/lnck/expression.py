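"""Differential expression, expression specificity and proportion statistics.

Differential expression between two watering conditions with two replicates
each is tested with a conditional exact negative-binomial test: replicate
counts are library-size-equalized, summed within condition, and the p-value
is the two-sided tail of the conditional distribution of one condition's sum
given the pooled total, with both sums negative-binomial around a common
mean under the null. The common dispersion is a trimmed method-of-moments
estimate across genes, floored at 0.01. Benjamini-Hochberg adjustment is
applied per line across genes. A gene is called up when padj < 0.05 and
log2FC >= 1, down when padj < 0.05 and log2FC <= -1, and equal otherwise.

Expression specificity is quantified by Shannon entropy over a gene's
relative expression across samples, H = -sum p_i log2 p_i, which ranges from
0 (expressed in a single sample) to log2 N (uniform across N samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

DE_ALPHA = 0.05
DE_LFC_MIN = 1.0


@dataclass
class DEResult:
    gene_id: str
    line_id: str
    log2fc: float
    p: float
    padj: float
    status: str


@dataclass
class EntropyResult:
    gene_id: str
    H: float
    n_samples: int


@dataclass
class ContingencyReport:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    proportions: np.ndarray  # per-cell row percentages, 1 decimal
    warning: str | None = None


# ---------------------------------------------------------------------------
# Exact negative-binomial test
# ---------------------------------------------------------------------------

def _exact_nb_pvalue(
    s1: int, s2: int, n_reps: int, dispersion: float, max_exact: int = 2000
) -> float:
    """Two-sided conditional exact NB p-value for condition sums s1 vs s2.

    Each condition sum is the sum of ``n_reps`` NB(mu, dispersion) counts,
    i.e. NB with size r = n_reps/dispersion and mean n_reps*mu. Under the
    null the common mean is estimated from the pooled total. The p-value
    sums the probabilities of all splits of the total at most as likely as
    the observed one (the standard two-sided exact construction). Above
    ``max_exact`` pooled counts the enumeration is replaced by the
    asymptotically equivalent z-test on the log ratio of sums, whose
    variance 1/s + dispersion/n per sum follows from the NB law.
    """
    total = int(s1) + int(s2)
    if total == 0:
        return 1.0
    if total > max_exact:
        a, b = max(float(s1), 0.5), max(float(s2), 0.5)
        var = 1.0 / a + 1.0 / b + 2.0 * dispersion / n_reps
        z = np.log(b / a) / np.sqrt(var)
        return float(2.0 * stats.norm.sf(abs(z)))
    r = n_reps / dispersion
    mu = total / 2.0
    k = np.arange(total + 1)
    logp = stats.nbinom.logpmf(k, r, r / (r + mu))
    logprod = logp + logp[::-1]
    logprod -= logprod.max()
    probs = np.exp(logprod)
    obs = probs[int(s1)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum() / probs.sum()))


def _mom_dispersion(counts: np.ndarray, groups: np.ndarray, floor: float = 0.01) -> float:
    """Pooled method-of-moments common dispersion across genes.

    With within-condition replicate mean m and variance v per gene,
    E[v - m] = phi * m^2 under NB(mu, phi), so phi is estimated by
    sum(v - m) / sum(m^2) pooled over genes (mean count >= 5) and
    conditions — unbiased and dominated by well-measured genes — then
    floored.
    """
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = counts[:, groups == g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m >= 5
        num += float((v[ok] - m[ok]).sum())
        den += float((m[ok] ** 2).sum())
    if den == 0:
        return floor
    return float(max(floor, num / den))


def classify_status(
    log2fc: float, padj: float, alpha: float = DE_ALPHA, lfc_min: float = DE_LFC_MIN
) -> str:
    """Published DE call: padj < 0.05 and |log2FC| >= 1."""
    if not (np.isfinite(log2fc) and np.isfinite(padj)):
        raise ValidationError("classify_status requires finite inputs")
    if padj < alpha and log2fc >= lfc_min:
        return "up"
    if padj < alpha and log2fc <= -lfc_min:
        return "down"
    return "equal"


def test_de(
    counts_ww: np.ndarray,
    counts_ws: np.ndarray,
    norm_factors: np.ndarray | None = None,
    dispersion: float = 0.1,
    gene_id: str = "",
    line_id: str = "",
) -> DEResult:
    """Exact NB test for one gene (2 replicates per condition)."""
    ww = np.asarray(counts_ww, dtype=float)
    ws = np.asarray(counts_ws, dtype=float)
    if ww.size < 2 or ws.size < 2:
        raise ValidationError("need >= 2 replicates per condition")
    if (ww < 0).any() or (ws < 0).any():
        raise ValidationError("negative counts")
    if norm_factors is not None:
        nf = np.asarray(norm_factors, dtype=float)
        scale = np.exp(np.mean(np.log(nf))) / nf
        ww = ww * scale[: ww.size]
        ws = ws * scale[ww.size:]
    if ww.sum() == 0 and ws.sum() == 0:
        return DEResult(gene_id, line_id, 0.0, 1.0, 1.0, "equal")
    log2fc = float(np.log2((ws.mean() + 0.5) / (ww.mean() + 0.5)))
    p = _exact_nb_pvalue(
        int(round(ww.sum())), int(round(ws.sum())), ww.size, dispersion
    )
    return DEResult(gene_id, line_id, log2fc, p, p, classify_status(log2fc, p))


def de_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    line_id: str,
    dispersion: float | None = None,
    min_mean_count: float = 10.0,
    alpha: float = DE_ALPHA,
    lfc_min: float = DE_LFC_MIN,
) -> pd.DataFrame:
    """Per-gene WS-vs-WW exact NB tests for one line, BH-adjusted.

    Genes with normalized mean count below ``min_mean_count`` are reported
    with ``tested=False`` and excluded from the adjustment (standard
    independent filtering); all-zero genes get p = 1, log2fc = 0, equal.
    Returns a frame indexed by gene_id with columns log2fc, p, padj, status,
    tested.
    """
    meta = samples[samples["line_id"] == line_id]
    ww_ids = meta.loc[meta["condition"] == "WW", "sample_id"].tolist()
    ws_ids = meta.loc[meta["condition"] == "WS", "sample_id"].tolist()
    if len(ww_ids) < 2 or len(ws_ids) < 2:
        raise ValidationError(
            f"line {line_id}: need >= 2 replicates per condition"
        )
    sub = counts[ww_ids + ws_ids].to_numpy(dtype=float)
    groups = np.array([0] * len(ww_ids) + [1] * len(ws_ids))

    # Two-step normalization. (1) Replicates within a condition share one
    # expression profile, so library-size equalization within condition is
    # composition-free. (2) The between-condition factor is the
    # 35%-trimmed mean of condition-level M-values (log ratio of condition
    # means): trimming both tails discards the differentially expressed
    # genes — which sit several null-SDs out at this aggregation level —
    # so the offset is anchored on the unchanged majority. A plain median
    # or per-gene-reference ratio is biased here because asymmetric DE
    # shifts it inside the wide null ratio distribution.
    if (sub.sum(axis=0) == 0).any():
        raise ValidationError(f"line {line_id}: a sample has zero total counts")
    sf = sub.sum(axis=0).astype(float)
    for g in (0, 1):
        cols = groups == g
        sf[cols] = sf[cols] / np.exp(np.mean(np.log(sf[cols])))
    norm = sub / sf
    ww0 = norm[:, groups == 0].mean(axis=1)
    ws0 = norm[:, groups == 1].mean(axis=1)
    pos = (ww0 > 0) & (ws0 > 0)
    if pos.sum() >= 10:
        m = np.log(ws0[pos]) - np.log(ww0[pos])
        delta = float(stats.trim_mean(m, 0.35))
        norm[:, groups == 1] /= np.exp(delta)

    if dispersion is None:
        dispersion = _mom_dispersion(norm, groups)

    ww = norm[:, groups == 0]
    ws = norm[:, groups == 1]
    mean_all = norm.mean(axis=1)
    tested = mean_all >= min_mean_count

    log2fc = np.log2((ws.mean(axis=1) + 0.5) / (ww.mean(axis=1) + 0.5))
    p = np.ones(len(sub))
    s1 = np.rint(ww.sum(axis=1)).astype(int)
    s2 = np.rint(ws.sum(axis=1)).astype(int)
    for i in np.flatnonzero(tested):
        p[i] = _exact_nb_pvalue(s1[i], s2[i], ww.shape[1], dispersion)

    padj = np.ones(len(sub))
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    status = np.where(
        tested & (padj < alpha) & (log2fc >= lfc_min), "up",
        np.where(tested & (padj < alpha) & (log2fc <= -lfc_min), "down", "equal"),
    )
    zero = norm.sum(axis=1) == 0
    log2fc[zero] = 0.0

    return pd.DataFrame(
        {
            "line_id": line_id,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "status": status,
            "tested": tested,
            "dispersion": dispersion,
        },
        index=pd.Index(counts.index, name="gene_id"),
    )


def de_all_lines(
    counts: pd.DataFrame, samples: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Per-line DE tables stacked; the union caller works off this."""
    frames = [
        de_table(counts, samples, line, **kwargs)
        for line in sorted(samples["line_id"].unique())
    ]
    return pd.concat(frames).reset_index()


def de_union(de: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary over lines: DE in at least one line, direction mix."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_lines_tested": int(sub["tested"].sum()),
                "n_up": int((sub["status"] == "up").sum()),
                "n_down": int((sub["status"] == "down").sum()),
                "is_de": bool((sub["status"] != "equal").any()),
            }
        )

    return de.groupby("gene_id").apply(agg, include_groups=False)


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def shannon_entropy(expr: np.ndarray, gene_id: str = "") -> EntropyResult:
    """H = -sum p log2 p over a gene's relative expression across samples."""
    x = np.asarray(expr, dtype=float)
    if (x < 0).any():
        raise ValidationError(f"{gene_id}: negative expression")
    total = x.sum()
    if total == 0:
        raise ValidationError(f"{gene_id}: all-zero gene; entropy undefined")
    p = x / total
    nz = p > 0
    h = float(-(p[nz] * np.log2(p[nz])).sum())
    return EntropyResult(gene_id, h, int(x.size))


def entropy_table(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene entropy; all-zero genes are excluded with a reason column."""
    x = fpkm.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative FPKM")
    total = x.sum(axis=1)
    ok = total > 0
    p = np.zeros_like(x)
    p[ok] = x[ok] / total[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h = -plogp.sum(axis=1)
    out = pd.DataFrame(
        {
            "H": np.where(ok, h, np.nan),
            "n_samples": fpkm.shape[1],
            "excluded": np.where(ok, "", "all_zero"),
        },
        index=fpkm.index,
    )
    return out


# ---------------------------------------------------------------------------
# Specific expression
# ---------------------------------------------------------------------------

GROUPINGS = {"tolerance", "condition", "generation", "line_id"}


def call_specific(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    group_by: str,
    threshold: float = 0.1,
    rule: str = "any",
) -> dict[str, set[str]]:
    """Per-group specifically expressed gene sets.

    A gene is specific to group G iff expressed (FPKM >= threshold) in at
    least one sample of G (``rule="any"``; ``rule="all"`` demands every
    replicate) and in zero samples of every other group.
    """
    if group_by not in GROUPINGS:
        raise ValidationError(f"unknown grouping {group_by!r}")
    group_of = samples.set_index("sample_id")[group_by]
    groups = group_of.reindex(fpkm.columns)
    if groups.isna().any():
        raise ValidationError("matrix columns missing from metadata")
    if groups.nunique() < 2:
        raise ValidationError(f"grouping {group_by!r} has fewer than 2 groups")
    expressed = fpkm >= threshold
    by_group_any = expressed.T.groupby(groups).any().T
    if rule == "any":
        in_group = by_group_any
    elif rule == "all":
        in_group = expressed.T.groupby(groups).all().T
    else:
        raise ValidationError(f"unknown rule {rule!r}")
    n_other = by_group_any.sum(axis=1)
    out: dict[str, set[str]] = {}
    for g in by_group_any.columns:
        mask = in_group[g] & (n_other - by_group_any[g].astype(int) == 0)
        out[g] = set(by_group_any.index[mask])
    return out


def select_housekeeping(
    fpkm: pd.DataFrame, threshold: float = 0.1, cv_max: float = 0.3
) -> set[str]:
    """Genes expressed (>= threshold) in every sample with CV <= cv_max."""
    x = fpkm.to_numpy(dtype=float)
    everywhere = (x >= threshold).all(axis=1)
    mean = x.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, x.std(axis=1, ddof=1) / mean, np.inf)
    sel = everywhere & (cv <= cv_max)
    if not sel.any():
        import warnings

        warnings.warn("no housekeeping genes selected")
    return set(fpkm.index[sel])


# ---------------------------------------------------------------------------
# Contingency and proportions
# ---------------------------------------------------------------------------

def contingency(table, correction: bool = False) -> ContingencyReport:
    """Pearson chi-square on a 2 x k count table.

    Continuity (Yates) correction is off by default — the published tables
    are large enough that it is immaterial — and can be enabled for small
    tables, where the corrected p tracks the conditional permutation null.
    Row percentages are reported to one decimal. An expected cell below 1
    attaches a warning; the p-value is still reported.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValidationError("negative cell counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("all-zero margin")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=correction)
    warning = None
    if (expected < 1).any():
        warning = "expected cell count below 1; chi-square approximation poor"
    props = np.round(100.0 * arr / arr.sum(axis=1, keepdims=True), 1)
    return ContingencyReport(arr.astype(int), float(chi2), int(df), float(p), props, warning)


def goodness_of_fit(observed, expected_probs=None) -> tuple[float, float]:
    """Chi-square goodness of fit of observed counts against expected
    proportions (uniform when omitted); the published up-vs-down contrast
    within one gene class is this test on (n_up, n_down)."""
    obs = np.asarray(observed, dtype=float)
    if expected_probs is None:
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        exp = obs.sum() * np.asarray(expected_probs, dtype=float)
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), float(p)


def permutation_chi2_p(
    table, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Permutation (conditional, fixed-margin) p for a 2x2 chi-square.

    Shuffling binary labels fixes both margins, so the null distribution of
    the top-left cell is hypergeometric; the p-value is the fraction of
    draws whose chi-square statistic is at least the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("permutation oracle is for 2x2 tables")
    n = arr.sum()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)

    def chi2_of(a: np.ndarray) -> np.ndarray:
        b = row[0] - a
        c = col[0] - a
        d = row[1] - c
        num = n * (a * d - b * c) ** 2
        den = row[0] * row[1] * col[0] * col[1]
        return num / den

    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(col[0], col[1], row[0], size=n_draws).astype(float)
    obs = chi2_of(np.array([arr[0, 0]]))[0]
    return float((chi2_of(draws) >= obs - 1e-9).mean())


def proportion(numerator: int, denominator: int, decimals: int | None = None) -> float:
    """Percentage with half-up rounding at the published precision:
    one decimal generally, two decimals below 10%."""
    if denominator <= 0:
        raise ValidationError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must be within [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    if decimals is None:
        decimals = 2 if pct < 10 else 1
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Fold-change distributions
# ---------------------------------------------------------------------------

def fc_distribution(
    de: pd.DataFrame, gene_class: pd.Series
) -> dict[str, dict]:
    """Per-class ECDF of log2FC with an IQR spread summary.

    ``gene_class`` maps gene_id -> class label (e.g. coding / lncRNA /
    housekeeping); ``de`` must carry gene_id and log2fc columns.
    """
    merged = de[["gene_id", "log2fc"]].copy()
    merged["gene_class"] = gene_class.reindex(merged["gene_id"]).to_numpy()
    out: dict[str, dict] = {}
    for cls, sub in merged.groupby("gene_class", dropna=True):
        x = np.sort(sub["log2fc"].to_numpy(dtype=float))
        if x.size == 0:
            continue
        y = np.arange(1, x.size + 1) / x.size
        q1, q3 = np.percentile(x, [25, 75])
        out[str(cls)] = {"x": x, "y": y, "iqr": float(q3 - q1), "n": int(x.size)}
    if not out:
        raise ValidationError("no genes per class")
    return out
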