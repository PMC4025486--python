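"""Genic-region assignment of poly(A) sites.

Each PAC representative site is assigned to 5'-UTR, 3'-UTR, CDS, intron
or intergenic space using the gene annotation.  Annotated 3' ends are
frequently too short, so every 3'-UTR is first extended downstream (50 nt
by default, truncated at the contig edge or the next same-strand gene
start); a site inside the extension counts as 3'-UTR of that gene.

Precedence when a coordinate falls into several features of one gene:
extended 3'-UTR > CDS > 5'-UTR > intron.  Across overlapping genes the
gene whose annotated 3' end is nearest wins.  Strand-mismatched
containment is treated as intergenic (antisense sites are not analyzed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "RegionAssignment",
    "load_gene_models",
    "extend_utr3",
    "assign_region",
    "region_distribution",
    "distance_profile",
    "REGION_LABELS",
]

REGION_LABELS = ("UTR5", "UTR3", "CDS", "INTRON", "INTERGENIC")

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class GeneModel:
    """A gene with unioned per-type feature intervals (1-based inclusive).

    ``utr3_extension_interval`` is filled in by :func:`extend_utr3`.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    utr3_extension_interval: Interval | None = None

    @property
    def introns(self) -> list[Interval]:
        exons = sorted(self.exons)
        return [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
            if exons[i + 1][0] - exons[i][1] > 1
        ]

    @property
    def three_prime_end(self) -> int:
        """Annotated 3'-end coordinate in transcript sense."""
        return self.end if self.strand == "+" else self.start

    @property
    def transcript_start(self) -> int:
        return self.start if self.strand == "+" else self.end

    def covers(self, position: int) -> bool:
        if self.start <= position <= self.end:
            return True
        ext = self.utr3_extension_interval
        return ext is not None and ext[0] <= position <= ext[1]


@dataclass(frozen=True)
class RegionAssignment:
    pac_id: str
    region: str
    gene_id: str | None
    distance_to_three_end: float  # signed nt, positive downstream


def _in_any(position: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= position <= e for s, e in intervals)


def load_gene_models(gff3_path: str) -> list[GeneModel]:
    """Read gene models from GFF3, unioning features across transcripts."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    type_map = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_UTR": "utr5",
        "three_prime_UTR": "utr3",
    }
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
        )
        seen: dict[str, set[Interval]] = {v: set() for v in type_map.values()}
        for ftype, attr in type_map.items():
            for feat in db.children(gene, featuretype=ftype):
                seen[attr].add((feat.start, feat.end))
        for attr, intervals in seen.items():
            setattr(model, attr, sorted(intervals))
        models.append(model)
    return models


def extend_utr3(
    models: Sequence[GeneModel],
    extension: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Grow each gene's 3'-UTR downstream in transcript sense.

    The extension is truncated at the nearer of the contig edge and the
    next same-strand gene start.  Returns new models; inputs untouched.
    """
    out = [replace(m) for m in models]
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for m in out:
        by_group.setdefault((m.chrom, m.strand), []).append(m)
    for (chrom, strand), group in by_group.items():
        group.sort(key=lambda m: m.start)
        for idx, m in enumerate(group):
            ext = extension
            if strand == "+":
                nxt = [g.transcript_start for g in group if g.transcript_start > m.three_prime_end]
                if nxt:
                    ext = min(ext, min(nxt) - m.three_prime_end - 1)
                if chrom_lengths is not None:
                    ext = min(ext, chrom_lengths[chrom] - m.three_prime_end)
                if ext > 0:
                    m.utr3_extension_interval = (
                        m.three_prime_end + 1,
                        m.three_prime_end + ext,
                    )
            else:
                nxt = [g.transcript_start for g in group if g.transcript_start < m.three_prime_end]
                if nxt:
                    ext = min(ext, m.three_prime_end - max(nxt) - 1)
                ext = min(ext, m.three_prime_end - 1)
                if ext > 0:
                    m.utr3_extension_interval = (
                        m.three_prime_end - ext,
                        m.three_prime_end - 1,
                    )
    return out


def _classify_within_gene(position: int, model: GeneModel) -> str | None:
    utr3 = list(model.utr3)
    if model.utr3_extension_interval is not None:
        utr3.append(model.utr3_extension_interval)
    if _in_any(position, utr3):
        return "UTR3"
    if _in_any(position, model.cds):
        return "CDS"
    if _in_any(position, model.utr5):
        return "UTR5"
    if _in_any(position, model.introns):
        return "INTRON"
    return None


def _signed_distance(position: int, model: GeneModel) -> int:
    """Distance from the annotated 3' end, positive downstream in sense."""
    if model.strand == "+":
        return position - model.three_prime_end
    return model.three_prime_end - position


def assign_region(
    chrom: str,
    strand: str,
    position: int,
    models: Sequence[GeneModel],
    pac_id: str = "",
) -> RegionAssignment:
    """Assign a site to a genic region or intergenic space.

    Containment is strand-matched.  When several genes contain the site,
    the gene with the nearest annotated 3' end wins; within a gene the
    precedence is extended 3'-UTR > CDS > 5'-UTR > intron.
    """
    candidates = []
    for m in models:
        if m.chrom != chrom or m.strand != strand or not m.covers(position):
            continue
        label = _classify_within_gene(position, m)
        if label is not None:
            candidates.append((abs(_signed_distance(position, m)), m, label))
    if candidates:
        candidates.sort(key=lambda t: (t[0], t[1].gene_id))
        dist, model, label = candidates[0]
        return RegionAssignment(
            pac_id=pac_id,
            region=label,
            gene_id=model.gene_id,
            distance_to_three_end=float(_signed_distance(position, model)),
        )
    same_strand = [m for m in models if m.chrom == chrom and m.strand == strand]
    if not same_strand:
        return RegionAssignment(pac_id, "INTERGENIC", None, math.nan)
    nearest = min(same_strand, key=lambda m: abs(_signed_distance(position, m)))
    return RegionAssignment(
        pac_id=pac_id,
        region="INTERGENIC",
        gene_id=None,
        distance_to_three_end=float(_signed_distance(position, nearest)),
    )


def assignments_to_frame(assignments: Iterable[RegionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pac_id": a.pac_id,
                "region": a.region,
                "gene_id": a.gene_id,
                "distance_to_three_end": a.distance_to_three_end,
            }
            for a in assignments
        ]
    )


def region_distribution(assignments: pd.DataFrame) -> pd.Series:
    """Percentage of sites per region label (sums to 100)."""
    if assignments.empty:
        raise ValueError("no assignments")
    counts = assignments["region"].value_counts()
    counts = counts.reindex(REGION_LABELS, fill_value=0)
    return 100.0 * counts / counts.sum()


def distance_profile(
    distances: Sequence[float],
    max_distance: int = 1000,
    bin_width: int = 50,
    cutoffs: Sequence[int] = (50,),
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Histogram of |distance| to annotated 3' ends + cumulative fractions.

    The cumulative fraction at a cutoff is computed over *all* supplied
    distances (not only those below ``max_distance``).
    """
    vals = [abs(d) for d in distances if not math.isnan(d)]
    if not vals:
        raise ValueError("no distances")
    edges = list(range(0, max_distance + bin_width, bin_width))
    counts = [0] * (len(edges) - 1)
    for v in vals:
        if v > max_distance:
            continue
        idx = min(int(v // bin_width), len(counts) - 1)
        counts[idx] += 1
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
    cum = {c: sum(v <= c for v in vals) / len(vals) for c in cutoffs}
    return hist, cum
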