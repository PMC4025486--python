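"""Gene-level alternative-polyadenylation (APA) classification.

Genes with at least two PACs are APA genes; single-PAC genes carry a
*constitutive* poly(A) site.  In an APA gene, a PAC holding at least 75 %
of the gene's site-supporting reads is *strong* and its siblings *weak*;
APA genes without a strong PAC have all-*median* PACs.  The APA extent of
a dataset is the percentage of PAC-bearing genes with two or more PACs;
it grows steeply with sequencing depth, which the extent-vs-size Pearson
correlation quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "GenePACSummary",
    "ExtentRecord",
    "classify_sites",
    "summarize_genes",
    "apa_extent",
    "category_counts",
    "category_table",
    "extent_size_correlation",
    "CATEGORIES",
]

CATEGORIES = ("constitutive", "strong", "weak", "median")


@dataclass
class GenePACSummary:
    gene_id: str
    pac_ids: list[str]
    supports: list[int]
    categories: list[str]

    @property
    def n_pacs(self) -> int:
        return len(self.pac_ids)

    @property
    def is_apa(self) -> bool:
        return self.n_pacs >= 2

    @property
    def is_high_quality_apa(self) -> bool:
        return self.n_pacs >= 5


@dataclass(frozen=True)
class ExtentRecord:
    dataset: str
    n_pacs: int
    apa_extent: float  # percentage


def classify_sites(
    supports: Sequence[int], strong_fraction: float = 0.75
) -> list[str]:
    """Categorize one gene's PACs from their read supports.

    A single PAC is constitutive.  Otherwise, the PAC with a support
    share >= ``strong_fraction`` (inclusive) is strong and the rest weak;
    if none reaches the threshold all are median.
    """
    if len(supports) == 0:
        raise ValueError("gene without PACs")
    if any(s < 1 for s in supports):
        raise ValueError("supports must be >= 1")
    if len(supports) == 1:
        return ["constitutive"]
    total = sum(supports)
    shares = [s / total for s in supports]
    if max(shares) >= strong_fraction:
        strongest = shares.index(max(shares))
        return ["strong" if i == strongest else "weak" for i in range(len(supports))]
    return ["median"] * len(supports)


def summarize_genes(
    pac_gene_table: pd.DataFrame, strong_fraction: float = 0.75
) -> list[GenePACSummary]:
    """Group genic PACs by gene and classify each gene's sites.

    ``pac_gene_table`` needs columns ``pac_id``, ``gene_id`` and
    ``total_support`` (intergenic PACs must already be excluded).
    """
    summaries = []
    for gene_id, group in pac_gene_table.groupby("gene_id", sort=True):
        supports = group["total_support"].tolist()
        summaries.append(
            GenePACSummary(
                gene_id=str(gene_id),
                pac_ids=group["pac_id"].tolist(),
                supports=supports,
                categories=classify_sites(supports, strong_fraction),
            )
        )
    return summaries


def apa_extent(summaries: Sequence[GenePACSummary]) -> float:
    """Percentage of PAC-bearing genes with >= 2 PACs."""
    if not summaries:
        raise ValueError("no PAC-bearing genes")
    n_apa = sum(1 for s in summaries if s.is_apa)
    return 100.0 * n_apa / len(summaries)


def category_counts(
    summaries: Sequence[GenePACSummary],
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-category PAC counts and gene counts.

    A gene counts toward a category when it carries at least one PAC of
    that category (so strong-gene and weak-gene counts coincide).
    """
    pac_counts = {c: 0 for c in CATEGORIES}
    gene_counts = {c: 0 for c in CATEGORIES}
    for s in summaries:
        seen = set()
        for cat in s.categories:
            pac_counts[cat] += 1
            seen.add(cat)
        for cat in seen:
            gene_counts[cat] += 1
    return pac_counts, gene_counts


def category_table(
    pac_counts: Mapping[str, int],
    gene_counts: Mapping[str, int] | None = None,
    gene_denominator: int | None = None,
) -> pd.DataFrame:
    """Category table: PAC counts/percentages and optional gene columns.

    PAC percentages are over all classified PACs; gene percentages are
    emitted only when a denominator (total annotated genes) is supplied.
    """
    total_pacs = sum(pac_counts.get(c, 0) for c in CATEGORIES)
    if total_pacs == 0:
        raise ValueError("no classified PACs")
    rows = []
    for cat in CATEGORIES:
        n = pac_counts.get(cat, 0)
        row = {"category": cat, "n_pacs": n, "pac_pct": 100.0 * n / total_pacs}
        if gene_counts is not None:
            g = gene_counts.get(cat, 0)
            row["n_genes"] = g
            if gene_denominator:
                row["gene_pct"] = 100.0 * g / gene_denominator
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def extent_size_correlation(
    records: Sequence[ExtentRecord] | Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between dataset size and APA extent.

    ``records`` are ExtentRecords or plain ``(n_pacs, extent)`` pairs;
    the p-value comes from the t transform with n-2 degrees of freedom.
    """
    pairs = [
        (r.n_pacs, r.apa_extent) if isinstance(r, ExtentRecord) else tuple(r)
        for r in records
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 records")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        raise ValueError("correlation undefined for a constant coordinate")
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)
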