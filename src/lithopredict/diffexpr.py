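"""Differential-expression filtering and immunoglobulin enrichment.

The DE stage is deliberately simple and fully specified: genes with fewer
than 10 total counts are dropped, counts are normalized by median-of-ratios
size factors, each gene is tested between the two groups with a two-sided
Mann-Whitney U test (exact by rank enumeration for small samples, normal
approximation with tie correction otherwise), p-values are adjusted by the
Benjamini-Hochberg step-up procedure, and genes with adjusted p < 0.05 and
|log2 fold-change| >= 1 are called differentially expressed.  This
reproduces the filtering semantics of a typical count-based DE workflow
without the negative-binomial dispersion machinery of a full GLM fit.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "EnrichmentReport",
    "filter_low_counts",
    "size_factors",
    "mwu_test",
    "exact_mwu_p",
    "de_test",
    "bh_adjust",
    "call_degs",
    "ig_fraction",
    "collapse_replicates",
]

EXACT_MAX_N = 12  # exact rank enumeration up to this total sample count


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p_value: float
    p_adjusted: float = np.nan


@dataclass
class EnrichmentReport:
    denominator_threshold: float
    background_fraction: float
    target_fraction: float
    enrichment_ratio: float

    def to_dict(self) -> dict:
        return {
            "denominator_threshold": self.denominator_threshold,
            "background_fraction": self.background_fraction,
            "target_fraction": self.target_fraction,
            "enrichment_ratio": self.enrichment_ratio,
        }


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across all samples is below ``min_total``.

    'Below' is exclusive: a gene totalling exactly ``min_total`` is kept.
    """
    keep = counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(
            f"no gene reaches {min_total} total counts; lower the threshold"
        )
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Reference is the per-gene geometric mean over samples, computed on
    genes expressed (count > 0) in every sample; each sample's factor is
    the median of its count/reference ratios.
    """
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = np.exp(np.log(vals[allpos]).mean(axis=1))
    factors = np.median(vals[allpos] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample, mid-ranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def exact_mwu_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments over the pooled mid-ranks.

    p = min(1, 2 * min(P(U <= u), P(U >= u))) under the permutation null,
    which handles ties exactly (the null distribution is computed on the
    observed tie pattern).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    us = [
        sum(combo) - offset
        for combo in itertools.combinations(ranks, n1)
    ]
    us = np.asarray(us)
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mwu_test(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """(U, two-sided p) for sample x vs y.

    Exact enumeration when n1+n2 <= ``exact_max_n``; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    u = _u_statistic(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u, 1.0  # all values identical: no evidence either way
    if len(x) + len(y) <= exact_max_n:
        return u, exact_mwu_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def collapse_replicates(
    X: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average a subject's replicate samples into one column per subject.

    Returns the collapsed matrix (columns = subject ids) and a per-subject
    metadata frame.  Used so repeated RNA samples of one subject do not
    count as independent observations.
    """
    meta = metadata.set_index("sample_id").loc[X.columns]
    meta.index.name = "sample_id"
    subj = meta["subject_id"].to_numpy()
    collapsed = X.T.groupby(subj, sort=False).mean().T
    per_subject = (
        meta.reset_index()
        .groupby("subject_id", sort=False)
        .first()
        .reset_index()
        .drop(columns=["sample_id", "replicate_index"])
    )
    per_subject = per_subject.set_index("subject_id").loc[collapsed.columns]
    per_subject.index.name = "subject_id"
    return collapsed, per_subject.reset_index()


def de_test(
    counts: pd.DataFrame,
    groups,
    metadata: pd.DataFrame | None = None,
    collapse: bool = True,
) -> pd.DataFrame:
    """Two-group differential-expression table.

    ``groups`` holds one of two labels per column of ``counts``; the
    log2 fold-change is group2 vs group1 with the levels in sorted order,
    on size-factor-normalized means with pseudocount 0.5.  When
    ``metadata`` is given and ``collapse`` is True, a subject's replicate
    samples are averaged (after normalization) before testing.

    Returns a DataFrame with columns
    ``gene_id, base_mean, log2fc, p_value, p_adjusted``.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    levels = sorted(groups.unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()
    norm = pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    if metadata is not None and collapse:
        norm, per_subject = collapse_replicates(norm, metadata)
        meta_idx = metadata.set_index("sample_id").loc[groups.index]
        subj_groups = (
            pd.Series(groups.to_numpy(), index=meta_idx["subject_id"].to_numpy())
            .groupby(level=0, sort=False)
            .first()
        )
        groups = subj_groups.loc[norm.columns]
    g1 = norm.loc[:, (groups == levels[0]).to_numpy()].to_numpy()
    g2 = norm.loc[:, (groups == levels[1]).to_numpy()].to_numpy()
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    mean1 = g1.mean(axis=1)
    mean2 = g2.mean(axis=1)
    log2fc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    base_mean = norm.to_numpy().mean(axis=1)
    pvals = np.empty(len(norm))
    for i in range(len(norm)):
        _, pvals[i] = mwu_test(g2[i], g1[i])
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene_id": norm.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": padj,
        }
    )


def call_degs(
    results: pd.DataFrame, fdr: float = 0.05, min_abs_log2fc: float = 1.0
) -> list[str]:
    """Genes with adjusted p < ``fdr`` and |log2FC| >= ``min_abs_log2fc``,
    sorted by ascending adjusted p (ties by raw p, then gene_id)."""
    if len(results) == 0:
        raise ValueError("empty results table")
    hits = results[
        (results["p_adjusted"] < fdr)
        & (results["log2fc"].abs() >= min_abs_log2fc)
    ]
    hits = hits.sort_values(["p_adjusted", "p_value", "gene_id"], kind="mergesort")
    return hits["gene_id"].tolist()


def ig_fraction(
    gene_list,
    annotation: pd.DataFrame,
    background_counts: pd.DataFrame,
    expression_threshold: float = 100.0,
) -> EnrichmentReport:
    """Immunoglobulin-gene share of a DEG list vs the expressed background.

    Background = genes whose mean count exceeds ``expression_threshold``;
    both fractions are shares of Ig-flagged genes.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("empty gene list")
    ann = annotation.set_index("gene_id")
    missing = [g for g in gene_list if g not in ann.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} missing from annotation")
    ig = ann["is_immunoglobulin"].astype(bool)
    mean_count = background_counts.mean(axis=1)
    background = mean_count.index[mean_count > expression_threshold]
    if len(background) == 0:
        raise ValueError("no background gene passes the expression threshold")
    bg_frac = float(ig.reindex(background).fillna(False).mean())
    tgt_frac = float(ig.loc[gene_list].mean())
    ratio = tgt_frac / bg_frac if bg_frac > 0 else np.inf
    return EnrichmentReport(
        denominator_threshold=expression_threshold,
        background_fraction=bg_frac,
        target_fraction=tgt_frac,
        enrichment_ratio=ratio,
    )
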