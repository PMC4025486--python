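"""End-to-end orchestration: reads -> unique sites -> PACs -> regions.

Also ingests precomputed alignments (SAM, or a plain coordinate table)
in place of the built-in exact-match mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import PAC, cluster_all, extract_flank, pacs_to_frame
from .mapping import GenomeIndex, map_read
from .regions import (
    GeneModel,
    RegionAssignment,
    assign_region,
    assignments_to_frame,
    extend_utr3,
)
from .sites import (
    SiteCandidate,
    aggregate_unique_sites,
    call_site,
    internal_priming_filter,
)
from .tails import TailParams, find_tail, orient_read

__all__ = [
    "PipelineResult",
    "call_unique_sites",
    "run_pipeline",
    "sites_from_sam",
    "sites_from_table",
]


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    rejected: pd.DataFrame
    pacs: list[PAC]
    pac_table: pd.DataFrame
    flanks: list
    assignments: pd.DataFrame | None = None


def call_unique_sites(
    reads,
    genome,
    params: TailParams,
    index: GenomeIndex | None = None,
    label: str = "sim",
    run_threshold: int = 6,
    count_threshold: int = 7,
    min_body_length: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tail detection, mapping, site calling and internal-priming filtering.

    ``reads`` are (id, sequence) pairs.  Returns the unique-site table and
    a table of rejected reads with reason codes.
    """
    if index is None:
        index = GenomeIndex(genome)
    candidates: list[SiteCandidate] = []
    rejected: list[dict] = []

    def reject(read_id, reason):
        rejected.append({"read_id": read_id, "reason": reason})

    for read_id, seq in reads:
        try:
            oriented, was_t = orient_read(seq, params)
        except ValueError:
            reject(read_id, "empty_read")
            continue
        tailed = find_tail(oriented, params)
        if tailed is None:
            reject(read_id, "no_tail")
            continue
        aln = map_read(
            tailed.body, index,
            max_nontemplated=params.max_nontemplated,
            min_body_length=min_body_length,
        )
        if aln is None:
            reject(read_id, "unmapped_or_ambiguous")
            continue
        cand, reason = call_site(aln, genome, params)
        if cand is None:
            reject(read_id, reason)
            continue
        keep, reason = internal_priming_filter(
            genome, cand.chrom, cand.strand, cand.position,
            run_threshold=run_threshold, count_threshold=count_threshold,
        )
        if not keep:
            reject(read_id, reason)
            continue
        candidates.append(
            SiteCandidate(cand.chrom, cand.strand, cand.position,
                          label=label, read_id=read_id)
        )
    sites = aggregate_unique_sites(candidates)
    rej = pd.DataFrame(rejected, columns=["read_id", "reason"])
    return sites, rej


def run_pipeline(
    genome,
    reads,
    params: TailParams,
    models: list[GeneModel] | None = None,
    min_support: int = 3,
    max_span: int = 24,
    utr3_extension: int = 50,
    label: str = "sim",
) -> PipelineResult:
    """Full analysis from raw tailed reads to annotated PACs."""
    sites, rejected = call_unique_sites(reads, genome, params, label=label)
    pacs = cluster_all(sites, max_span=max_span, min_support=min_support)
    flanks = [
        extract_flank(genome, p.chrom, p.strand, p.representative_position,
                      pac_id=p.pac_id)
        for p in pacs
    ]
    assignments = None
    if models is not None:
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        extended = extend_utr3(models, utr3_extension, chrom_lengths)
        assignments = assignments_to_frame(
            assign_region(p.chrom, p.strand, p.representative_position,
                          extended, pac_id=p.pac_id)
            for p in pacs
        )
    return PipelineResult(
        sites=sites,
        rejected=rejected,
        pacs=pacs,
        pac_table=pacs_to_frame(pacs),
        flanks=flanks,
        assignments=assignments,
    )


def sites_from_sam(
    sam_path: str,
    genome,
    params: TailParams,
    label: str = "sam",
    require_tail_clip: bool = True,
    run_threshold: int = 6,
    count_threshold: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique sites from a SAM file of tail-soft-clipped alignments.

    The aligned 3' end gives the candidate cleavage position; the
    soft-clipped segment at the 3' end is validated against the tail
    rules (length and adenine purity in read orientation) unless
    ``require_tail_clip`` is off.  Genomic trailing-A reassignment and
    the internal-priming filter then apply as for the built-in mapper.
    """
    import pysam

    from .mapping import Alignment

    candidates: list[SiteCandidate] = []
    rejected: list[dict] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                rejected.append({"read_id": read.query_name, "reason": "unmapped"})
                continue
            strand = "-" if read.is_reverse else "+"
            cigar = read.cigartuples or []
            # soft clip at the transcript 3' end: last op for forward reads,
            # first op for reverse reads (SAM stores reverse-complemented seq)
            clip_len = 0
            if cigar:
                op, length = cigar[-1] if strand == "+" else cigar[0]
                if op == 4:  # BAM_CSOFT_CLIP
                    clip_len = length
            if require_tail_clip:
                seq = read.query_sequence or ""
                clip = seq[-clip_len:] if strand == "+" else seq[:clip_len]
                if strand == "-":
                    from .tails import revcomp

                    clip = revcomp(clip)
                ok = (
                    clip_len >= params.min_tail_length
                    and clip.upper().count("A") / max(clip_len, 1)
                    >= params.min_purity
                )
                if not ok:
                    rejected.append(
                        {"read_id": read.query_name, "reason": "no_tail_clip"}
                    )
                    continue
            aln = Alignment(
                chrom=read.reference_name,
                strand=strand,
                start=read.reference_start + 1,
                end=read.reference_end,
            )
            cand, reason = call_site(aln, genome, params)
            if cand is None:
                rejected.append({"read_id": read.query_name, "reason": reason})
                continue
            keep, reason = internal_priming_filter(
                genome, cand.chrom, cand.strand, cand.position,
                run_threshold=run_threshold, count_threshold=count_threshold,
            )
            if not keep:
                rejected.append({"read_id": read.query_name, "reason": reason})
                continue
            candidates.append(
                SiteCandidate(cand.chrom, cand.strand, cand.position, label=label)
            )
    return (
        aggregate_unique_sites(candidates),
        pd.DataFrame(rejected, columns=["read_id", "reason"]),
    )


def sites_from_table(
    table: pd.DataFrame,
    genome,
    label: str = "table",
    run_threshold: int = 6,
    count_threshold: int = 7,
) -> pd.DataFrame:
    """Unique sites from precomputed (chrom, strand, position) rows.

    Each row is one read's cleavage coordinate; the internal-priming
    filter is applied, then rows aggregate into unique sites.
    """
    candidates = []
    for r in table.itertuples(index=False):
        keep, _reason = internal_priming_filter(
            genome, r.chrom, r.strand, int(r.position),
            run_threshold=run_threshold, count_threshold=count_threshold,
        )
        if keep:
            candidates.append(
                SiteCandidate(r.chrom, r.strand, int(r.position), label=label)
            )
    return aggregate_unique_sites(candidates)
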