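"""Cleavage-site calling, internal-priming filtering and aggregation.

A cleavage site is the genomic coordinate of the last templated
nucleotide of a transcript (the "-1 position").  Trailing aligned
adenines cannot be distinguished from tail adenines, so up to
``max_genomic_a_in_tail`` of them are reassigned to the tail and the
site moves upstream accordingly; alignments with more trailing A's are
rejected.  Candidate sites whose genomic neighbourhood is A-rich are
internal-priming artifacts (an oligo(dT) primer annealed to genomic
adenines rather than a true tail) and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .mapping import Alignment
from .tails import TailParams, revcomp

__all__ = [
    "SiteCandidate",
    "call_site",
    "internal_priming_filter",
    "aggregate_unique_sites",
]

REJECT_CONTIG_EDGE = "contig_edge"
REJECT_GENOMIC_A = "genomic_a_run"
REJECT_ALL_A = "alignment_all_a"
REJECT_NONTEMPLATED = "nontemplated_excess"
DROP_A_RUN = "ip_a_run"
DROP_A_RICH = "ip_a_rich_window"


@dataclass(frozen=True)
class SiteCandidate:
    """A strand-aware candidate cleavage position with provenance label."""

    chrom: str
    strand: str
    position: int  # 1-based coordinate of the last templated base
    label: str = "sim"
    read_id: str | None = None


def call_site(
    alignment: Alignment,
    genome: Mapping[str, str],
    params: TailParams,
) -> tuple[SiteCandidate | None, str | None]:
    """Derive the cleavage coordinate from an alignment, or reject.

    Trailing aligned adenines (sense strand) are reassigned to the tail
    up to ``params.max_genomic_a_in_tail``; the site is the last aligned
    base after reassignment.  Rejections return ``(None, reason)``.
    """
    if alignment.nontemplated_count > params.max_nontemplated:
        return None, REJECT_NONTEMPLATED
    seq = genome[alignment.chrom].upper()
    if alignment.strand == "+":
        if alignment.end >= len(seq):
            # tail continues past the contig edge; templated status unknowable
            return None, REJECT_CONTIG_EDGE
        t = 0
        while t < alignment.matched_length and seq[alignment.end - 1 - t] == "A":
            t += 1
        if t > params.max_genomic_a_in_tail:
            return None, REJECT_GENOMIC_A
        if t >= alignment.matched_length:
            return None, REJECT_ALL_A
        position = alignment.end - t
    else:
        if alignment.start <= 1:
            return None, REJECT_CONTIG_EDGE
        t = 0
        # sense-strand A == plus-strand T when the transcript is on "-"
        while t < alignment.matched_length and seq[alignment.start - 1 + t] == "T":
            t += 1
        if t > params.max_genomic_a_in_tail:
            return None, REJECT_GENOMIC_A
        if t >= alignment.matched_length:
            return None, REJECT_ALL_A
        position = alignment.start + t
    return SiteCandidate(alignment.chrom, alignment.strand, position), None


def internal_priming_filter(
    genome: Mapping[str, str],
    chrom: str,
    strand: str,
    position: int,
    run_threshold: int = 6,
    count_threshold: int = 7,
    flank: int = 10,
    subwindow: int = 10,
) -> tuple[bool, str | None]:
    """Decide whether a candidate site is an internal-priming artifact.

    The sense-strand genomic window ``-flank..+flank`` around the site is
    inspected (clamped at contig edges).  The site is dropped when the
    window contains a run of >= ``run_threshold`` consecutive adenines, or
    any fully contained ``subwindow``-nt stretch with >= ``count_threshold``
    adenines.  Returns ``(keep, reason)`` with ``reason`` set when dropped.
    """
    seq = genome[chrom].upper()
    lo = max(0, position - 1 - flank)
    hi = min(len(seq), position + flank)
    window = seq[lo:hi]
    if strand == "-":
        window = revcomp(window)
    if "A" * run_threshold in window:
        return False, DROP_A_RUN
    if len(window) >= subwindow:
        a_count = window[:subwindow].count("A")
        if a_count >= count_threshold:
            return False, DROP_A_RICH
        for i in range(subwindow, len(window)):
            a_count += (window[i] == "A") - (window[i - subwindow] == "A")
            if a_count >= count_threshold:
                return False, DROP_A_RICH
    return True, None


def aggregate_unique_sites(candidates: Iterable[SiteCandidate]) -> pd.DataFrame:
    """Collapse candidates into nonredundant unique sites with read support.

    Returns one row per (chrom, strand, position), sorted by coordinate,
    with total ``support`` plus one count column per provenance label
    (``n_<label>``).
    """
    rows = [
        {"chrom": c.chrom, "strand": c.strand, "position": c.position, "label": c.label}
        for c in candidates
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "strand", "position", "support"])
    df = pd.DataFrame(rows)
    support = (
        df.groupby(["chrom", "strand", "position"]).size().rename("support")
    )
    per_label = (
        df.groupby(["chrom", "strand", "position", "label"])
        .size()
        .unstack("label", fill_value=0)
        .add_prefix("n_")
    )
    out = pd.concat([support, per_label], axis=1).reset_index()
    out = out.sort_values(["chrom", "position", "strand"], kind="mergesort")
    return out.reset_index(drop=True)
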