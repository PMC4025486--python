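"""Interplay between intronic polyadenylation and splicing.

Intronic PACs are crossed with intron splice classes (constitutive vs
retained) and host-gene coding classes, yielding the 2x2 percentage table
whose row/column means summarize which intron kinds attract
polyadenylation.  Length effects (features containing a PAC are longer)
are assessed against resampled PAC-free control groups with a two-sided
rank-sum test: exact enumeration for small samples, tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthComparison",
    "intron_pac_table",
    "table_from_counts",
    "sample_controls",
    "rank_sum_test",
    "length_comparison",
]

SPLICE_CLASSES = ("constitutive", "retained")
GENE_CLASSES = ("coding", "noncoding")


def table_from_counts(
    totals: pd.DataFrame, with_pac: pd.DataFrame
) -> dict[str, object]:
    """Percentages and class means from 2x2 intron counts.

    ``totals`` and ``with_pac`` are indexed by gene class (coding,
    noncoding) with splice-class columns (constitutive, retained).
    The class means average cell *percentages*, matching how the summary
    is usually quoted (e.g. the constitutive mean averages the coding and
    noncoding constitutive cells).
    """
    totals = totals.loc[list(GENE_CLASSES), list(SPLICE_CLASSES)].astype(float)
    with_pac = with_pac.loc[list(GENE_CLASSES), list(SPLICE_CLASSES)].astype(float)
    pct = 100.0 * with_pac / totals.where(totals > 0, other=np.nan)
    pct = pct.fillna(0.0)
    means = {
        "constitutive": float(pct["constitutive"].mean()),
        "retained": float(pct["retained"].mean()),
        "coding": float(pct.loc["coding"].mean()),
        "noncoding": float(pct.loc["noncoding"].mean()),
    }
    return {"totals": totals, "with_pac": with_pac, "pct": pct, "means": means}


def intron_pac_table(
    introns: pd.DataFrame,
    pacs: pd.DataFrame,
    use_span: bool = False,
) -> dict[str, object]:
    """Cross intronic PACs with splice and gene classes.

    ``introns`` needs columns intron_id, chrom, strand, start, end,
    splice_class, gene_class; ``pacs`` needs chrom, strand and
    representative_position (plus start/end when ``use_span``).  An
    intron "contains" a PAC when a representative position lies strictly
    inside its interval on the same strand (or, with ``use_span``, when
    the PAC span overlaps the interval); multi-PAC introns count once.

    Returns totals, with-PAC counts, cell percentages and class means,
    plus the per-intron ``contains_pac`` flags.
    """
    introns = introns.reset_index(drop=True).copy()
    flags = np.zeros(len(introns), dtype=bool)
    for key, grp in pacs.groupby(["chrom", "strand"], sort=False):
        mask = (introns["chrom"] == key[0]) & (introns["strand"] == key[1])
        sub = introns[mask]
        if sub.empty:
            continue
        if use_span:
            for _, pac in grp.iterrows():
                hit = (sub["start"] <= pac["end"]) & (sub["end"] >= pac["start"])
                flags[sub.index[hit]] = True
        else:
            positions = np.sort(grp["representative_position"].to_numpy())
            for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
                lo = np.searchsorted(positions, s, side="right")
                hi = np.searchsorted(positions, e, side="left")
                if hi > lo:
                    flags[idx] = True
    introns["contains_pac"] = flags
    totals = (
        introns.pivot_table(
            index="gene_class", columns="splice_class", values="intron_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(index=list(GENE_CLASSES), columns=list(SPLICE_CLASSES), fill_value=0)
    )
    withp = (
        introns[introns["contains_pac"]]
        .pivot_table(
            index="gene_class", columns="splice_class", values="intron_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(index=list(GENE_CLASSES), columns=list(SPLICE_CLASSES), fill_value=0)
    )
    out = table_from_counts(totals, withp)
    out["introns"] = introns
    return out


def sample_controls(
    pool: pd.DataFrame | Sequence,
    n: int,
    n_groups: int = 3,
    seed: int = 0,
) -> list:
    """Draw ``n_groups`` independent control samples of size ``n``.

    Sampling is without replacement within each group (groups may
    overlap), seeded for reproducibility.
    """
    size = len(pool)
    if size < n:
        raise ValueError(f"pool of {size} smaller than requested {n}")
    rng = np.random.default_rng(seed)
    groups = []
    for _ in range(n_groups):
        idx = rng.choice(size, size=n, replace=False)
        if isinstance(pool, pd.DataFrame):
            groups.append(pool.iloc[np.sort(idx)].reset_index(drop=True))
        else:
            arr = np.asarray(pool)
            groups.append(arr[np.sort(idx)])
    return groups


def _rank_sum_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U of x over y with 0.5 credit for ties."""
    u = 0.0
    for xv in x:
        for yv in y:
            if xv > yv:
                u += 1.0
            elif xv == yv:
                u += 0.5
    return u


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    For n1, n2 <= 8 the null distribution of U is enumerated exactly over
    all assignments of the pooled values (ties handled with half-credit);
    larger samples use the tie-corrected normal approximation.
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 <= 8 and n2 <= 8:
        pooled = x + y
        mu = n1 * n2 / 2.0
        u_obs = _rank_sum_u(x, y)
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            xs = [pooled[i] for i in combo]
            rest = set(combo)
            ys = [pooled[i] for i in range(n1 + n2) if i not in rest]
            u = _rank_sum_u(xs, ys)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass
class LengthComparison:
    """Length statistics of with-PAC features vs resampled controls."""

    feature_kind: str
    n: int
    with_mean: float
    with_median: float
    control_means: list[float]
    control_medians: list[float]
    pvalues: list[float]
    seed: int = 0


def length_comparison(
    with_pac_lengths: Sequence[float],
    control_groups: Sequence[Sequence[float]],
    feature_kind: str = "intron",
    seed: int = 0,
) -> LengthComparison:
    """Compare with-PAC feature lengths against each control group."""
    w = [float(v) for v in with_pac_lengths]
    if not w or any(len(g) == 0 for g in control_groups):
        raise ValueError("empty length set")
    return LengthComparison(
        feature_kind=feature_kind,
        n=len(w),
        with_mean=float(np.mean(w)),
        with_median=float(np.median(w)),
        control_means=[float(np.mean(list(g))) for g in control_groups],
        control_medians=[float(np.median(list(g))) for g in control_groups],
        pvalues=[rank_sum_test(w, list(g)) for g in control_groups],
        seed=seed,
    )
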