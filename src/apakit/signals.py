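"""Exhaustive k-mer scanning of flank sequences and motif significance.

Poly(A) signals are short k-mers (pentamers by default) enriched in fixed
windows relative to the cleavage site: the near-upstream element (NUE,
about -28..-5, hosting the canonical UGUAA in Chlamydomonas) and the far
upstream element (FUE, about -100..-28).  Three scanning modes are
supported:

``overlapping``
    every match start is counted;
``distribution``
    greedy left-to-right counting where a new occurrence must start at
    least ``k + gap`` positions after the previously counted one —
    overlapping matches are not double-counted (in ATATATAT with gap=2,
    ATATAT and TATATA are each counted once);
``frequency``
    at most one count per sequence, taken at the occurrence closest to
    the poly(A) site (ties resolved toward the 3' occurrence).

Significance is scored as a Z-score against an order-m Markov background
trained on the scanned sequences themselves: with p the background
probability of the motif and n the number of scanned window starts,
E = n*p and Z = (observed - E) / sqrt(n*p*(1-p)).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScanSpec",
    "MarkovBackground",
    "scan_kmers",
    "nucleotide_profile",
    "motif_pssm",
    "train_markov",
    "motif_zscore",
    "score_motifs",
]

MODES = ("overlapping", "distribution", "frequency")
_DNA = "ACGT"


def _to_dna(motif: str) -> str:
    return motif.upper().replace("U", "T")


def _to_rna(kmer: str) -> str:
    return kmer.replace("T", "U")


@dataclass(frozen=True)
class ScanSpec:
    """What to scan: motif length, window, mode and gap.

    ``window`` is an inclusive position-label range relative to the site
    (labels -upstream..-1 then +1..+downstream; the site base is -1), or
    ``None`` to scan whole sequences without label bookkeeping.  ``gap``
    applies to distribution mode only.
    """

    k: int = 5
    window: tuple[int, int] | None = (-28, -5)
    mode: str = "distribution"
    gap: int = 0
    upstream: int = 100
    downstream: int = 50

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.window is not None:
            lo, hi = self.window
            if lo == 0 or hi == 0 or lo > hi:
                raise ValueError("window labels are nonzero and ordered")
            if lo < -self.upstream or hi > self.downstream:
                raise ValueError("window outside the flank layout")
            if self.k > self.window_length:
                raise ValueError("k exceeds window length")

    def _label_to_index(self, label: int) -> int:
        return self.upstream + label if label < 0 else self.upstream + label - 1

    @property
    def window_length(self) -> int:
        if self.window is None:
            raise ValueError("unbounded window")
        return self._label_to_index(self.window[1]) - self._label_to_index(self.window[0]) + 1

    def window_indices(self, seq_len: int) -> tuple[int, int]:
        """0-based [start, end) indices of the window within a sequence."""
        if self.window is None:
            return 0, seq_len
        return (
            self._label_to_index(self.window[0]),
            self._label_to_index(self.window[1]) + 1,
        )

    def site_index(self, seq_len: int) -> int:
        """Index of the cleavage-site base (position label -1)."""
        if self.window is None:
            return seq_len - 1
        return self.upstream - 1


def _window_occurrences(seq: str, spec: ScanSpec) -> tuple[dict[str, list[int]], int]:
    """All match starts per k-mer within the window, and the number of
    valid (N-free) starts."""
    lo, hi = spec.window_indices(len(seq))
    k = spec.k
    occ: dict[str, list[int]] = {}
    n_valid = 0
    for s in range(lo, hi - k + 1):
        kmer = seq[s : s + k]
        if "N" in kmer:
            continue
        n_valid += 1
        occ.setdefault(kmer, []).append(s)
    return occ, n_valid


def _greedy_count(starts: Sequence[int], k: int, gap: int) -> list[int]:
    """Greedy left-to-right selection: next start >= previous + k + gap."""
    chosen: list[int] = []
    next_ok = -(10**9)
    for s in starts:
        if s >= next_ok:
            chosen.append(s)
            next_ok = s + k + gap
    return chosen


def _counted_starts(
    occ: dict[str, list[int]], spec: ScanSpec, site_idx: int
) -> dict[str, list[int]]:
    """Mode-dependent counted occurrence starts per k-mer, one sequence."""
    if spec.mode == "overlapping":
        return occ
    if spec.mode == "distribution":
        return {m: _greedy_count(starts, spec.k, spec.gap) for m, starts in occ.items()}
    # frequency: one occurrence per sequence, closest motif end to the site
    out = {}
    for m, starts in occ.items():
        best = min(starts, key=lambda s: (abs(s + spec.k - 1 - site_idx), -s))
        out[m] = [best]
    return out


def scan_kmers(
    sequences: Iterable[str], spec: ScanSpec, all_kmers: bool = False
) -> pd.DataFrame:
    """Exhaustive k-mer count table for a set of flank sequences.

    Returns a DataFrame indexed by RNA-alphabet k-mer with columns
    ``count``, ``frequency`` (count / number of scanned sequences) and
    ``rank`` (1 = most frequent; ties broken lexicographically).  The
    total number of scanned (N-free) window starts is stored in
    ``df.attrs["n_positions"]`` and the sequence count in
    ``df.attrs["n_sequences"]``; both feed the Z-score computation.

    With ``all_kmers=True`` every k-mer over {A,C,G,U} appears in the
    table, zero counts included.
    """
    counts: Counter[str] = Counter()
    n_seq = 0
    n_positions = 0
    for seq in sequences:
        seq = str(seq).upper()
        n_seq += 1
        occ, n_valid = _window_occurrences(seq, spec)
        n_positions += n_valid
        site_idx = spec.site_index(len(seq))
        for motif, starts in _counted_starts(occ, spec, site_idx).items():
            counts[motif] += len(starts)
    if n_seq == 0:
        raise ValueError("no sequences to scan")
    if all_kmers:
        index = ["".join(p) for p in itertools.product(_DNA, repeat=spec.k)]
    else:
        index = sorted(counts)
    df = pd.DataFrame(
        {"count": [counts.get(m, 0) for m in index]},
        index=pd.Index([_to_rna(m) for m in index], name="motif"),
    )
    df["frequency"] = df["count"] / n_seq
    # stable sort on a lexicographically sorted index = ties break alphabetically
    order = df.loc[sorted(df.index)].sort_values(
        "frequency", ascending=False, kind="mergesort"
    )
    rank = pd.Series(range(1, len(order) + 1), index=order.index)
    df["rank"] = rank
    df.attrs["n_sequences"] = n_seq
    df.attrs["n_positions"] = n_positions
    df.attrs["mode"] = spec.mode
    return df


def nucleotide_profile(
    sequences: Iterable[str], upstream: int = 100, downstream: int = 50
) -> pd.DataFrame:
    """Per-position base frequencies of equal-length labeled sequences.

    Rows are position labels (-upstream..-1, +1..+downstream), columns
    A/C/G/U; frequencies are taken over non-N bases so each row sums to
    one wherever any base was observed.  T is reported as U.
    """
    seqs = [str(s).upper() for s in sequences]
    if not seqs:
        raise ValueError("empty sequence set")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    labels = list(range(-upstream, 0)) + list(range(1, downstream + 1))
    if len(labels) != length:
        raise ValueError("sequence length does not match the flank layout")
    rows = []
    for i in range(length):
        c = Counter(s[i] for s in seqs)
        total = sum(c[b] for b in _DNA)
        if total == 0:
            rows.append({b: 0.0 for b in "ACGU"})
        else:
            rows.append(
                {"A": c["A"] / total, "C": c["C"] / total,
                 "G": c["G"] / total, "U": c["T"] / total}
            )
    return pd.DataFrame(rows, index=pd.Index(labels, name="position"))


def motif_pssm(sequences: Iterable[str], motif: str, spec: ScanSpec) -> pd.DataFrame:
    """Distribution of counted occurrence starts of one motif.

    Rows are the window's position labels; ``count`` is the number of
    counted occurrences (under ``spec.mode``) starting at that label and
    ``frequency`` normalizes counts to sum to one (all-zero when the
    motif never occurs).
    """
    motif_dna = _to_dna(motif)
    if len(motif_dna) != spec.k:
        raise ValueError("motif length must equal spec.k")
    start_counts: Counter[int] = Counter()
    seqs = [str(s).upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    lo, hi = spec.window_indices(len(seqs[0]))
    for seq in seqs:
        occ, _ = _window_occurrences(seq, spec)
        counted = _counted_starts(occ, spec, spec.site_index(len(seq)))
        for s in counted.get(motif_dna, []):
            start_counts[s] += 1
    if spec.window is not None:
        labels = [
            lab
            for lab in range(spec.window[0], spec.window[1] + 1)
            if lab != 0
        ]
        indices = [spec._label_to_index(lab) for lab in labels]
    else:
        indices = list(range(lo, hi))
        labels = indices
    counts = [start_counts.get(i, 0) for i in indices]
    total = sum(counts)
    freq = [c / total if total else 0.0 for c in counts]
    return pd.DataFrame(
        {"count": counts, "frequency": freq},
        index=pd.Index(labels, name="position"),
    )


class MarkovBackground:
    """Order-m Markov model of base composition with add-one smoothing.

    Trained on a sequence set (by default, the very sequences being
    scanned); supplies the expected probability of any motif longer than
    the order.
    """

    def __init__(self, order: int, context_counts: dict[str, Counter],
                 mgram_counts: Counter, total_mgrams: int):
        self.order = order
        self._ctx = context_counts
        self._mgrams = mgram_counts
        self._total_mgrams = total_mgrams

    def transition(self, context: str, base: str) -> float:
        c = self._ctx.get(context)
        total = sum(c.values()) if c else 0
        count = c[base] if c else 0
        return (count + 1) / (total + 4)

    def mgram_probability(self, mgram: str) -> float:
        if self.order == 0:
            return 1.0
        return (self._mgrams[mgram] + 1) / (self._total_mgrams + 4**self.order)

    def motif_probability(self, motif: str) -> float:
        motif = _to_dna(motif)
        if len(motif) <= self.order:
            raise ValueError("motif not longer than the Markov order")
        p = self.mgram_probability(motif[: self.order])
        for i in range(self.order, len(motif)):
            p *= self.transition(motif[i - self.order : i], motif[i])
        return p


def train_markov(sequences: Iterable[str], order: int = 3) -> MarkovBackground:
    """Maximum-likelihood Markov background with add-one smoothing.

    Counts (order+1)-grams (and order-grams for the prefix marginal) over
    A/C/G/T, skipping N-containing grams.  Warns when the data are too
    sparse for the requested order.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    ctx: dict[str, Counter] = {}
    mgrams: Counter = Counter()
    total_mgrams = 0
    total_transitions = 0
    for seq in sequences:
        seq = _to_dna(str(seq).upper())
        for i in range(len(seq) - order):
            gram = seq[i : i + order + 1]
            if any(b not in _DNA for b in gram):
                continue
            ctx.setdefault(gram[:order], Counter())[gram[order]] += 1
            total_transitions += 1
        if order > 0:
            for i in range(len(seq) - order + 1):
                g = seq[i : i + order]
                if any(b not in _DNA for b in g):
                    continue
                mgrams[g] += 1
                total_mgrams += 1
    if total_transitions < 4 ** (order + 1):
        warnings.warn(
            f"only {total_transitions} (order+1)-grams for 4^{order + 1} "
            "parameters; background estimates rely heavily on smoothing",
            stacklevel=2,
        )
    return MarkovBackground(order, ctx, mgrams, total_mgrams)


def motif_zscore(
    observed: float, motif: str, background: MarkovBackground, n_positions: int
) -> tuple[float, float]:
    """Binomial Z-score of an observed motif count against the background.

    Returns ``(z, expected)`` with expected ``E = n*p`` and
    ``Z = (observed - E) / sqrt(n*p*(1-p))``.
    """
    if len(_to_dna(motif)) <= background.order:
        raise ValueError("motif not longer than the Markov order")
    p = background.motif_probability(motif)
    expected = n_positions * p
    var = n_positions * p * (1 - p)
    z = (observed - expected) / math.sqrt(var)
    return z, expected


def score_motifs(table: pd.DataFrame, background: MarkovBackground) -> pd.DataFrame:
    """Add ``expected`` and ``zscore`` columns to a scan table."""
    n_positions = table.attrs["n_positions"]
    out = table.copy()
    zs, es = [], []
    for motif, row in table.iterrows():
        z, e = motif_zscore(row["count"], motif, background, n_positions)
        zs.append(z)
        es.append(e)
    out["expected"] = es
    out["zscore"] = zs
    out.attrs.update(table.attrs)
    return out
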