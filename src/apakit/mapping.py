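"""Exact-match placement of trimmed read bodies on the genome.

The tail-trimmed body of a read is a 3'-terminal transcript fragment; its
last templated base marks the cleavage position.  Bodies are placed by an
exact match of the 3'-terminal seed k-mer, extended maximally toward the
5' end, with up to ``max_nontemplated`` unmatched bases tolerated between
the aligned end and the tail start.  Ambiguous seeds (more than one
genomic hit) are discarded: a unique placement is required.

This deliberately is not a spliced aligner — the bodies this package
produces and consumes are unspliced 3'-terminal fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .tails import revcomp

__all__ = ["Alignment", "GenomeIndex", "map_read"]


@dataclass(frozen=True)
class Alignment:
    """Genomic placement of a read body (1-based inclusive plus-strand span).

    ``strand`` is the transcript strand: for ``-`` the body matches the
    reverse complement of the plus-strand span.  ``nontemplated_count``
    is the number of body bases beyond the aligned 3' end (between the
    mapped end and the tail).
    """

    chrom: str
    strand: str
    start: int
    end: int
    nontemplated_count: int = 0

    @property
    def matched_length(self) -> int:
        return self.end - self.start + 1

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the aligned base closest to the tail."""
        return self.end if self.strand == "+" else self.start


class GenomeIndex:
    """Seed k-mer index over the plus strands of a genome.

    Parameters
    ----------
    genome:
        Mapping of chromosome id to its plus-strand sequence.
    seed_length:
        Length of the 3'-terminal seed used for lookup (default 20 nt,
        which is also the minimum mappable body length).
    """

    def __init__(self, genome: Mapping[str, str], seed_length: int = 20):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_length = seed_length
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for pos in range(len(seq) - seed_length + 1):
                kmer = seq[pos : pos + seed_length]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Plus-strand 0-based positions at which ``kmer`` occurs."""
        return self._index.get(kmer, [])


def _extend_plus(body: str, seq: str, q0: int, seed_len: int) -> tuple[int, int]:
    """Maximal leftward extension of a plus-strand seed hit.

    Returns the matched plus-strand span as a 0-based half-open interval.
    """
    i = len(body) - seed_len - 1
    g = q0 - 1
    while i >= 0 and g >= 0 and body[i] == seq[g]:
        i -= 1
        g -= 1
    return g + 1, q0 + seed_len


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _extend_minus(body: str, seq: str, q0: int, seed_len: int) -> tuple[int, int]:
    """Maximal extension of a minus-strand hit (rightward in plus coords)."""
    j = 0
    n_extra = len(body) - seed_len
    while (
        j < n_extra
        and q0 + seed_len + j < len(seq)
        and body[len(body) - seed_len - 1 - j] == _COMP[seq[q0 + seed_len + j]]
    ):
        j += 1
    return q0, q0 + seed_len + j


def map_read(
    body: str,
    index: GenomeIndex,
    max_nontemplated: int = 3,
    min_body_length: int = 20,
) -> Alignment | None:
    """Place a tail-trimmed body on the genome, or return ``None``.

    Seeds are tried at 3'-end offsets 0..``max_nontemplated`` so that
    nontemplated additions between the mapped end and the tail are
    tolerated; the smallest offset that yields a hit wins and becomes
    the alignment's ``nontemplated_count``.  A seed with more than one
    genomic hit (summed over strands) is ambiguous and returns ``None``.
    """
    body = body.upper()
    k = index.seed_length
    for nt in range(0, max_nontemplated + 1):
        core = body[: len(body) - nt] if nt else body
        if len(core) < max(min_body_length, k):
            break
        seed = core[-k:]
        plus_hits = index.lookup(seed)
        minus_hits = index.lookup(revcomp(seed))
        if len(plus_hits) + len(minus_hits) == 0:
            continue
        if len(plus_hits) + len(minus_hits) > 1:
            return None
        if plus_hits:
            chrom, q0 = plus_hits[0]
            lo, hi = _extend_plus(core, index.genome[chrom], q0, k)
            strand = "+"
        else:
            chrom, q0 = minus_hits[0]
            lo, hi = _extend_minus(core, index.genome[chrom], q0, k)
            strand = "-"
        if hi - lo < min_body_length:
            return None
        return Alignment(
            chrom=chrom,
            strand=strand,
            start=lo + 1,
            end=hi,
            nontemplated_count=nt,
        )
    return None
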