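"""Poly(A)/(T) tail detection and read orientation.

cDNA reads derived from polyadenylated transcripts end in a poly(A) run
(sense reads) or begin with a poly(T) run (reads recorded from the
antisense strand of the cDNA).  The rules that decide whether a terminal
run is a *valid* tail differ by platform: classic EST chemistry yields
long, clean tails, so a strict A-run of >= 10 nt is required; short-read
(NGS) protocols tolerate sequencing noise, so a terminal window of
>= 15 nt with >= 95 % adenine content qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TailParams",
    "TailedRead",
    "revcomp",
    "find_tail",
    "orient_read",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TailParams:
    """Platform-dependent rule set for tail detection and site calling.

    Attributes
    ----------
    mode:
        ``"EST"`` or ``"NGS"`` — only a label; the numeric fields rule.
    min_tail_length:
        Minimum length of a valid terminal poly(A) run (nt).
    min_purity:
        Minimum adenine fraction of the tail window.  EST mode uses 1.0
        (a strict A-run), NGS mode 0.95.
    max_genomic_a_in_tail:
        Maximum adenines that are part of the tail but also map to the
        genome; trailing aligned A's up to this number are reassigned to
        the tail when the cleavage site is called.
    max_nontemplated:
        Maximum nontemplated nucleotides tolerated between the mapped
        read end and the start of its poly(A) tail.
    """

    mode: str = "NGS"
    min_tail_length: int = 15
    min_purity: float = 0.95
    max_genomic_a_in_tail: int = 4
    max_nontemplated: int = 3

    def __post_init__(self) -> None:
        if self.min_tail_length < 1:
            raise ValueError("min_tail_length must be >= 1")
        if not 0.0 < self.min_purity <= 1.0:
            raise ValueError("min_purity must be in (0, 1]")
        if self.mode not in ("EST", "NGS"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "TailParams":
        """Default rule set for a platform mode (``"EST"`` or ``"NGS"``)."""
        if mode == "EST":
            base = dict(mode="EST", min_tail_length=10, min_purity=1.0)
        elif mode == "NGS":
            base = dict(mode="NGS", min_tail_length=15, min_purity=0.95)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class TailedRead:
    """A read with a detected terminal poly(A) tail, in transcript sense.

    ``sequence`` is the full oriented read; the tail occupies
    ``sequence[tail_start:]`` and the (possibly nontemplated-suffixed)
    body is ``sequence[:tail_start]``.
    """

    sequence: str
    tail_start: int
    tail_length: int
    tail_purity: float
    read_id: str | None = None
    was_polyt_head: bool = False
    nontemplated_count: int = 0

    @property
    def body(self) -> str:
        return self.sequence[: self.tail_start]


def find_tail(sequence: str, params: TailParams) -> TailedRead | None:
    """Locate the poly(A) tail at the 3' end of an oriented read.

    Returns the *longest* terminal window whose adenine fraction is at
    least ``params.min_purity`` and whose length is at least
    ``params.min_tail_length`` (maximal by left extension), or ``None``
    if no window qualifies.  ``N`` counts as non-A.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < params.min_tail_length:
        return None
    # suffix_a[i] = number of A in seq[i:]
    suffix_a = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_a[i] = suffix_a[i + 1] + (seq[i] == "A")
    for start in range(0, n - params.min_tail_length + 1):
        length = n - start
        if suffix_a[start] / length >= params.min_purity:
            return TailedRead(
                sequence=sequence,
                tail_start=start,
                tail_length=length,
                tail_purity=suffix_a[start] / length,
            )
    return None


def orient_read(sequence: str, params: TailParams) -> tuple[str, bool]:
    """Orient a raw read into transcript sense.

    A read whose *leading* T-run satisfies the mirrored tail criteria —
    and that has no qualifying trailing A-run — is the reverse
    complement of the sense cDNA; it is flipped and flagged.  When both
    a qualifying trailing A-run and leading T-run exist, the A-tail
    wins and the read is kept as-is (avoids double-counting chimeras).

    Returns ``(oriented_sequence, was_polyt_head)``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if find_tail(sequence, params) is not None:
        return sequence, False
    flipped = revcomp(sequence)
    if find_tail(flipped, params) is not None:
        return flipped, True
    return sequence, False


def tail_from_oriented(
    sequence: str, params: TailParams, read_id: str | None = None
) -> TailedRead | None:
    """Orient a raw read, then detect its tail; convenience wrapper."""
    oriented, flipped = orient_read(sequence, params)
    tr = find_tail(oriented, params)
    if tr is None:
        return None
    return replace(tr, read_id=read_id, was_polyt_head=flipped)
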