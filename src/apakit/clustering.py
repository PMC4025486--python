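"""Clustering of unique cleavage sites into poly(A) site clusters (PACs).

The cleavage reaction is sloppy: reads from one biological poly(A) site
scatter over a few nucleotides (microheterogeneity).  Adjacent unique
sites on the same chromosome and strand are therefore merged into PACs.
Sites contribute their position with multiplicity equal to read support,
and the partition optimizes the Ward minimum-variance criterion subject
to a maximum genomic span per cluster: among contiguous partitions whose
every block spans at most ``max_span`` nt, the one with the fewest
blocks is chosen, ties broken by minimal support-weighted within-cluster
sum of squares.  The optimum is computed exactly by dynamic programming.

Each PAC is represented by its highest-support member site; -100..+50 nt
flanking sequence around the representative site feeds the signal scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tails import revcomp

__all__ = [
    "PAC",
    "FlankSequence",
    "filter_supported_sites",
    "cluster_sites",
    "cluster_all",
    "representative_site",
    "extract_flank",
]


@dataclass
class PAC:
    """A cluster of adjacent unique poly(A) sites on one chrom/strand."""

    pac_id: str
    chrom: str
    strand: str
    start: int
    end: int
    members: list[tuple[int, int]]  # (position, support)
    representative_position: int
    total_support: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class FlankSequence:
    """Sense-strand sequence around a representative site.

    Position labels run -upstream..-1 (site at -1) then +1..+downstream;
    off-contig positions are padded with ``N`` and flagged.
    """

    pac_id: str
    sequence: str
    upstream: int = 100
    downstream: int = 50
    padded: bool = False

    def labels(self) -> list[int]:
        return list(range(-self.upstream, 0)) + list(range(1, self.downstream + 1))


def filter_supported_sites(sites: pd.DataFrame, min_support: int = 3) -> pd.DataFrame:
    """Keep unique sites with read support >= ``min_support``."""
    if sites.empty:
        return sites.copy()
    return sites[sites["support"] >= min_support].reset_index(drop=True)


def representative_site(members: Sequence[tuple[int, int]], strand: str) -> int:
    """Highest-support member position; ties go to the 3'-most in sense."""
    if not members:
        raise ValueError("empty PAC")
    best_support = max(s for _, s in members)
    tied = [p for p, s in members if s == best_support]
    return max(tied) if strand == "+" else min(tied)


def _block_wcss(
    lo: int, hi: int, cw: np.ndarray, cwp: np.ndarray, cwp2: np.ndarray
) -> float:
    """Support-weighted within-cluster sum of squares of sites lo..hi-1."""
    w = cw[hi] - cw[lo]
    s = cwp[hi] - cwp[lo]
    s2 = cwp2[hi] - cwp2[lo]
    return float(s2 - s * s / w)


def _partition_positions(
    positions: Sequence[int], supports: Sequence[int], max_span: int
) -> list[tuple[int, int]]:
    """Optimal contiguous partition as (lo, hi) index blocks (half-open).

    Primary objective: fewest blocks such that every block's genomic
    span (last - first + 1) is <= ``max_span``; secondary: minimal total
    weighted within-cluster sum of squares (the Ward criterion).
    """
    n = len(positions)
    pos = np.asarray(positions, dtype=float)
    w = np.asarray(supports, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwp = np.concatenate([[0.0], np.cumsum(w * pos)])
    cwp2 = np.concatenate([[0.0], np.cumsum(w * pos * pos)])

    INF = float("inf")
    nclust = [0] + [n + 1] * n
    cost = [0.0] + [INF] * n
    back = [0] * (n + 1)
    for i in range(1, n + 1):
        for j in range(i - 1, -1, -1):
            if positions[i - 1] - positions[j] + 1 > max_span:
                break
            cand_n = nclust[j] + 1
            cand_c = cost[j] + _block_wcss(j, i, cw, cwp, cwp2)
            if cand_n < nclust[i] or (
                cand_n == nclust[i] and cand_c < cost[i] - 1e-9
            ):
                nclust[i] = cand_n
                cost[i] = cand_c
                back[i] = j
    blocks: list[tuple[int, int]] = []
    i = n
    while i > 0:
        j = back[i]
        blocks.append((j, i))
        i = j
    blocks.reverse()
    return blocks


def cluster_sites(
    sites: pd.DataFrame, max_span: int = 24, pac_prefix: str = "PAC"
) -> list[PAC]:
    """Cluster filtered unique sites of one chromosome+strand into PACs.

    ``sites`` must carry ``chrom``, ``strand``, ``position`` and
    ``support`` and hold a single (chrom, strand) combination.
    """
    if sites.empty:
        return []
    chroms = sites["chrom"].unique()
    strands = sites["strand"].unique()
    if len(chroms) != 1 or len(strands) != 1:
        raise ValueError("cluster_sites expects a single chromosome and strand")
    chrom, strand = chroms[0], strands[0]
    srt = sites.sort_values("position", kind="mergesort")
    positions = srt["position"].tolist()
    supports = srt["support"].tolist()
    blocks = _partition_positions(positions, supports, max_span)
    pacs = []
    for k, (lo, hi) in enumerate(blocks):
        members = list(zip(positions[lo:hi], supports[lo:hi]))
        pacs.append(
            PAC(
                pac_id=f"{pac_prefix}{k + 1:05d}",
                chrom=chrom,
                strand=strand,
                start=positions[lo],
                end=positions[hi - 1],
                members=members,
                representative_position=representative_site(members, strand),
                total_support=int(sum(supports[lo:hi])),
            )
        )
    return pacs


def cluster_all(
    sites: pd.DataFrame, max_span: int = 24, min_support: int | None = None
) -> list[PAC]:
    """Cluster sites genome-wide, strand-separated per chromosome."""
    if min_support is not None:
        sites = filter_supported_sites(sites, min_support)
    pacs: list[PAC] = []
    if sites.empty:
        return pacs
    counter = 0
    for (chrom, strand), group in sites.groupby(["chrom", "strand"], sort=True):
        for pac in cluster_sites(group, max_span=max_span):
            counter += 1
            pac.pac_id = f"PAC{counter:05d}"
            pacs.append(pac)
    return pacs


def pacs_to_frame(pacs: Iterable[PAC]) -> pd.DataFrame:
    """Tabular view of PACs (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "pac_id": p.pac_id,
                "chrom": p.chrom,
                "strand": p.strand,
                "start": p.start,
                "end": p.end,
                "representative_position": p.representative_position,
                "total_support": p.total_support,
                "n_members": p.n_members,
            }
            for p in pacs
        ]
    )


def extract_flank(
    genome: Mapping[str, str],
    chrom: str,
    strand: str,
    position: int,
    upstream: int = 100,
    downstream: int = 50,
    pac_id: str = "",
) -> FlankSequence:
    """Sense-strand flank around a site, the site base at label -1.

    For a plus-strand site at 1-based ``position`` the sequence covers
    genomic bases ``position-upstream+1 .. position+downstream``; minus
    strand is the reverse complement of the mirrored span.  Positions
    beyond the contig are padded with ``N`` and the flank is flagged.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom].upper()
    n = len(seq)
    if strand == "+":
        lo = position - upstream  # 0-based
        hi = position + downstream
    else:
        lo = position - downstream - 1
        hi = position + upstream - 1
    pad_left = max(0, -lo)
    pad_right = max(0, hi - n)
    chunk = seq[max(0, lo) : min(n, hi)]
    flank = "N" * pad_left + chunk + "N" * pad_right
    if strand == "-":
        flank = revcomp(flank)
    return FlankSequence(
        pac_id=pac_id,
        sequence=flank,
        upstream=upstream,
        downstream=downstream,
        padded=(pad_left > 0 or pad_right > 0),
    )
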