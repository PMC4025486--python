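"""Synthetic genome, annotation and tailed-read generator.

Generates a toy GC-biased genome (the default 63.45 % GC matches the
strongly GC-rich Chlamydomonas genome), gene models with UTRs, CDS exons
and introns on both strands, planted ground-truth poly(A) sites with the
canonical UGUAA signal in the NUE, and reads carrying untrimmed poly(A)
tails with platform-dependent length/purity, nontemplated additions,
poly(T)-headed antisense copies, and genomic A-run internal-priming
decoys.  Every downstream stage of the pipeline is testable against the
returned ground truth without any external download.

All randomness flows from ``SimConfig.seed``; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .regions import GeneModel
from .sites import internal_priming_filter
from .tails import revcomp

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_genome",
    "simulate_reads",
    "save_outputs",
]

_BASES = np.array(list("ACGT"))
_NON_A = "CGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data generator.

    Lengths are nt; fractions lie in [0, 1].  ``platform`` selects the
    tail regime: EST reads are long with strict pure tails (>= 10 nt),
    NGS reads are short (fixed ``ngs_read_length``) with >= 15 nt tails
    at 95 % purity.
    """

    seed: int = 0
    genome_length: int = 50_000
    gc_fraction: float = 0.6345
    n_genes: int = 20
    introns_per_gene: tuple[int, int] = (1, 2)
    apa_gene_fraction: float = 0.5
    pacs_per_apa_gene: tuple[int, int] = (2, 3)
    nue_motif: str = "TGTAA"  # planted at -22..-18 upstream of each true site
    microheterogeneity_sd: float = 1.0
    platform: str = "NGS"  # "EST" or "NGS"
    est_read_length: int = 400
    ngs_read_length: int = 50
    est_tail_range: tuple[int, int] = (12, 35)
    ngs_tail_range: tuple[int, int] = (15, 26)
    tail_impurity_rate: float = 0.01
    nontemplated_rate: tuple[float, float, float, float] = (0.7, 0.15, 0.1, 0.05)
    antisense_fraction: float = 0.2
    decoy_count: int = 5
    decoy_run_range: tuple[int, int] = (6, 12)
    intron_site_fraction: float = 0.1
    downstream_site_fraction: float = 0.3
    # per-site depth mirrors the shallowest real platform: ~338k EST reads
    # over ~11k clusters is ~30 supporting reads per site
    reads_per_site: int = 30
    # fixed gene architecture ranges (transcript sense)
    utr5_range: tuple[int, int] = (60, 120)
    exon_range: tuple[int, int] = (100, 200)
    intron_range: tuple[int, int] = (80, 150)
    utr3_range: tuple[int, int] = (150, 250)
    intergenic_range: tuple[int, int] = (200, 500)
    retained_intron_fraction: float = 0.2
    noncoding_gene_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "apa_gene_fraction",
            "tail_impurity_rate",
            "antisense_fraction",
            "intron_site_fraction",
            "downstream_site_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.platform not in ("EST", "NGS"):
            raise ValueError("platform must be 'EST' or 'NGS'")
        if abs(sum(self.nontemplated_rate) - 1.0) > 1e-9:
            raise ValueError("nontemplated_rate must sum to 1")
        if self.reads_per_site < 1:
            raise ValueError("reads_per_site must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth: sites, internal-priming decoys and intron classes."""

    sites: pd.DataFrame  # chrom,strand,position,region,gene_id,expected_support
    decoys: pd.DataFrame  # chrom,strand,position(run start),run_length,gene_id
    introns: pd.DataFrame  # intron_id,gene_id,chrom,strand,start,end,classes


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def _sanitize_site_window(seq: list[str], g0: int, strand: str, chrom: str,
                          rng: np.random.Generator) -> None:
    """Rewrite the genomic neighbourhood of a planted site so the pipeline
    can recover it cleanly.

    The sense bases at -4..-1 must not be A (otherwise trailing-A
    reassignment shifts the called coordinate), and the -10..+10 window
    must pass the internal-priming filter.
    """
    n = len(seq)
    step = 1 if strand == "+" else -1

    def sense_idx(offset: int) -> int:
        # offset -1 is the site base itself; +1 the first downstream base
        return g0 + (offset + 1) * step if offset < 0 else g0 + offset * step

    for off in range(-4, 0):
        i = sense_idx(off)
        if 0 <= i < n:
            base = seq[i] if strand == "+" else revcomp(seq[i])
            if base == "A":
                repl = _NON_A[rng.integers(0, 3)]
                seq[i] = repl if strand == "+" else revcomp(repl)
    # break A-runs / A-rich stretches in the sense -10..+10 window
    for _ in range(40):
        genome_view = {chrom: "".join(seq)}
        keep, _reason = internal_priming_filter(
            genome_view, chrom, strand, g0 + 1
        )
        if keep:
            break
        offsets = list(range(-10, 0)) + list(range(1, 11))
        a_offsets = []
        for off in offsets:
            i = sense_idx(off)
            if 0 <= i < n:
                base = seq[i] if strand == "+" else revcomp(seq[i])
                if base == "A":
                    a_offsets.append(off)
        if not a_offsets:
            break
        off = a_offsets[len(a_offsets) // 2]
        i = sense_idx(off)
        repl = _NON_A[rng.integers(0, 3)]
        seq[i] = repl if strand == "+" else revcomp(repl)


def _plant_sense(seq: list[str], strand: str, sense_positions: range | list[int],
                 sense_seq: str) -> None:
    """Write ``sense_seq`` at 0-based plus-strand-ordered sense coordinates."""
    if strand == "+":
        for i, base in zip(sense_positions, sense_seq):
            seq[i] = base
    else:
        for i, base in zip(sense_positions, revcomp(sense_seq)):
            seq[i] = base


def make_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Generate the genome, gene models and planted ground truth.

    Genes are laid out left to right with random intergenic spacers, each
    with the fixed architecture 5'UTR, alternating CDS exons and introns,
    3'UTR, on a random strand.  True poly(A) sites sit in the 3'-UTR (a
    configurable fraction up to 30 nt downstream of the annotated end to
    exercise the 3'-UTR extension, and a fraction of APA sites inside
    introns); the NUE motif is planted at -22..-18 of every site and the
    site neighbourhood is sanitized so that recovery is limited by the
    pipeline, not by planted-sequence artifacts.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chr1"
    seq_codes = _rand_seq(rng, config.genome_length, config.gc_fraction)
    seq = list("".join(_BASES[seq_codes]))

    models: list[GeneModel] = []
    site_rows: list[dict] = []
    decoy_rows: list[dict] = []
    intron_rows: list[dict] = []

    cursor = int(rng.integers(*config.intergenic_range))
    for g in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.integers(config.introns_per_gene[0],
                                     config.introns_per_gene[1] + 1))
        utr5_len = int(rng.integers(*config.utr5_range))
        utr3_len = int(rng.integers(*config.utr3_range))
        exon_lens = [int(rng.integers(*config.exon_range))
                     for _ in range(n_introns + 1)]
        intron_lens = [int(rng.integers(*config.intron_range))
                       for _ in range(n_introns)]
        footprint = utr5_len + utr3_len + sum(exon_lens) + sum(intron_lens)
        if cursor + footprint + 60 > config.genome_length:
            raise ValueError(
                "gene footprints exceed genome_length; enlarge the genome "
                "or reduce n_genes"
            )
        gene_id = f"gene{g + 1:03d}"
        start = cursor + 1  # 1-based genomic start of the gene span
        # build transcript-sense segment list then place on the chosen strand
        segments: list[tuple[str, int]] = [("utr5", utr5_len)]
        for i, ex in enumerate(exon_lens):
            segments.append(("cds", ex))
            if i < n_introns:
                segments.append(("intron", intron_lens[i]))
        segments.append(("utr3", utr3_len))
        if strand == "-":
            segments = segments[::-1]
        model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                          start=start, end=start + footprint - 1)
        pos = start
        cds_intervals, intron_intervals = [], []
        for kind, length in segments:
            iv = (pos, pos + length - 1)
            if kind == "utr5":
                model.utr5.append(iv)
            elif kind == "utr3":
                model.utr3.append(iv)
            elif kind == "cds":
                model.cds.append(iv)
                cds_intervals.append(iv)
            else:
                intron_intervals.append(iv)
            pos += length
        # exons = everything transcribed that is not intron
        exon_edges = sorted(
            model.utr5 + model.cds + model.utr3
        )
        merged: list[list[int]] = []
        for s, e in exon_edges:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        model.exons = [(s, e) for s, e in merged]
        models.append(model)

        for k, (s, e) in enumerate(sorted(intron_intervals)):
            intron_rows.append(
                {
                    "intron_id": f"{gene_id}.i{k + 1}",
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "start": s,
                    "end": e,
                    "splice_class": (
                        "retained"
                        if rng.random() < config.retained_intron_fraction
                        else "constitutive"
                    ),
                    "gene_class": (
                        "noncoding"
                        if rng.random() < config.noncoding_gene_fraction
                        else "coding"
                    ),
                }
            )

        # --- plant true poly(A) sites -------------------------------------
        three_end = model.three_prime_end
        step = 1 if strand == "+" else -1
        utr3_iv = model.utr3[0]
        sites: list[tuple[int, str]] = []  # (1-based position, region label)
        if rng.random() < config.downstream_site_fraction:
            distal = three_end + step * int(rng.integers(5, 31))
            sites.append((distal, "UTR3"))
        else:
            distal = three_end - step * int(rng.integers(5, 16))
            sites.append((distal, "UTR3"))
        if rng.random() < config.apa_gene_fraction:
            n_extra = int(rng.integers(config.pacs_per_apa_gene[0],
                                       config.pacs_per_apa_gene[1] + 1)) - 1
            for j in range(n_extra):
                if intron_intervals and rng.random() < config.intron_site_fraction:
                    iv = intron_intervals[int(rng.integers(len(intron_intervals)))]
                    mid = (iv[0] + iv[1]) // 2
                    sites.append((mid, "INTRON"))
                else:
                    # proximal 3'-UTR sites, spaced >= 60 nt from the distal one
                    offset = 60 * (j + 1) + int(rng.integers(0, 15))
                    prox = three_end - step * offset
                    if utr3_iv[0] + 30 <= prox <= utr3_iv[1] - 30:
                        sites.append((prox, "UTR3"))
        # de-duplicate and keep sites that leave room for the NUE motif
        seen_pos = set()
        for position, region in sites:
            if position in seen_pos:
                continue
            seen_pos.add(position)
            g0 = position - 1
            # NUE motif occupies sense labels -22..-18
            motif = config.nue_motif
            if strand == "+":
                lo = g0 - 21
                span = range(lo, lo + len(motif))
            else:
                hi = g0 + 21
                span = range(hi - len(motif) + 1, hi + 1)
            if span[0] < 0 or span[-1] >= config.genome_length:
                continue
            _plant_sense(seq, strand, span, motif)
            _sanitize_site_window(seq, g0, strand, chrom, rng)
            site_rows.append(
                {
                    "chrom": chrom,
                    "strand": strand,
                    "position": position,
                    "region": region,
                    "gene_id": gene_id,
                    "expected_support": config.reads_per_site,
                }
            )
        cursor = start + footprint - 1 + int(rng.integers(*config.intergenic_range))

    # --- plant internal-priming decoys inside CDS/introns -----------------
    host_pool = [
        (m, iv)
        for m in models
        for iv in (m.cds + m.introns)
        if iv[1] - iv[0] + 1 >= config.decoy_run_range[1] + 50
    ]
    n_decoys = min(config.decoy_count, len(host_pool))
    if n_decoys:
        chosen = rng.choice(len(host_pool), size=n_decoys, replace=False)
        for ci in np.sort(chosen):
            model, iv = host_pool[int(ci)]
            run_len = int(rng.integers(config.decoy_run_range[0],
                                       config.decoy_run_range[1] + 1))
            if model.strand == "+":
                run_start0 = iv[0] - 1 + 30  # leave >= 30 nt upstream body room
                span = range(run_start0, run_start0 + run_len)
            else:
                run_end0 = iv[1] - 1 - 30
                span = range(run_end0 - run_len + 1, run_end0 + 1)
            _plant_sense(seq, model.strand, span, "A" * run_len)
            # the base 5' of the run must be non-A so the decoy body maps cleanly
            before0 = span[0] - 1 if model.strand == "+" else span[-1] + 1
            base = seq[before0] if model.strand == "+" else revcomp(seq[before0])
            if base == "A":
                seq[before0] = "C" if model.strand == "+" else "G"
            decoy_rows.append(
                {
                    "chrom": chrom,
                    "strand": model.strand,
                    "position": span[0] + 1 if model.strand == "+" else span[-1] + 1,
                    "run_length": run_len,
                    "gene_id": model.gene_id,
                }
            )

    genome = {chrom: "".join(seq)}
    site_cols = ["chrom", "strand", "position", "region", "gene_id",
                 "expected_support"]
    decoy_cols = ["chrom", "strand", "position", "run_length", "gene_id"]
    intron_cols = ["intron_id", "gene_id", "chrom", "strand", "start", "end",
                   "splice_class", "gene_class"]
    truth = GroundTruth(
        sites=pd.DataFrame(site_rows, columns=site_cols),
        decoys=pd.DataFrame(decoy_rows, columns=decoy_cols),
        introns=pd.DataFrame(intron_rows, columns=intron_cols),
    )
    return genome, models, truth


def _sense_fragment(seq: str, strand: str, end_pos: int, length: int) -> str:
    """Transcript-sense genomic fragment of ``length`` nt ending at the
    1-based sense coordinate ``end_pos``."""
    if strand == "+":
        lo = max(0, end_pos - length)
        return seq[lo:end_pos]
    hi = min(len(seq), end_pos - 1 + length)
    return revcomp(seq[end_pos - 1 : hi])


def simulate_reads(
    genome: Mapping[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate tailed reads from the planted truth.

    Returns ``(reads, read_truth)`` where reads are ``(read_id, sequence)``
    pairs and the truth table records, per read, its source site/decoy,
    cleavage position, tail length, impurity and nontemplated counts and
    whether it was emitted as a poly(T)-headed antisense copy.  Decoy
    reads end at the planted genomic A-run and carry no synthetic tail.
    """
    rng = np.random.default_rng([config.seed, 1])
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    counter = 0

    for site in truth.sites.itertuples(index=False):
        seq = genome[site.chrom].upper()
        if not 1 <= site.position <= len(seq):
            raise ValueError(f"site {site.position} outside {site.chrom}")
        step = 1 if site.strand == "+" else -1
        for _ in range(config.reads_per_site):
            counter += 1
            jitter = int(round(rng.normal(0.0, config.microheterogeneity_sd)))
            cleavage = site.position + step * jitter
            cleavage = min(max(cleavage, 1), len(seq))
            n_nontemplated = int(rng.choice(4, p=config.nontemplated_rate))
            if config.platform == "NGS":
                tail_len = int(rng.integers(*config.ngs_tail_range))
                body_len = config.ngs_read_length - tail_len - n_nontemplated
            else:
                tail_len = int(rng.integers(*config.est_tail_range))
                body_len = min(
                    config.est_read_length - tail_len - n_nontemplated,
                    int(rng.integers(150, config.est_read_length - 40)),
                )
            body = _sense_fragment(seq, site.strand, cleavage, body_len)
            tail = list("A" * tail_len)
            n_impure = 0
            if config.tail_impurity_rate > 0:
                flips = rng.random(tail_len) < config.tail_impurity_rate
                for i in np.flatnonzero(flips):
                    tail[i] = _NON_A[rng.integers(0, 3)]
                    n_impure += 1
            extra = "".join(_NON_A[rng.integers(0, 3)]
                            for _ in range(n_nontemplated))
            read = body + extra + "".join(tail)
            antisense = bool(rng.random() < config.antisense_fraction)
            if antisense:
                read = revcomp(read)
            read_id = f"read{counter:06d}"
            reads.append((read_id, read))
            rows.append(
                {
                    "read_id": read_id,
                    "gene_id": site.gene_id,
                    "chrom": site.chrom,
                    "strand": site.strand,
                    "site": site.position,
                    "cleavage": cleavage,
                    "body_length": len(body),
                    "tail_length": tail_len,
                    "tail_purity": (tail_len - n_impure) / tail_len,
                    "n_impure": n_impure,
                    "n_nontemplated": n_nontemplated,
                    "antisense": antisense,
                    "is_decoy": False,
                }
            )

    for decoy in truth.decoys.itertuples(index=False):
        seq = genome[decoy.chrom].upper()
        step = 1 if decoy.strand == "+" else -1
        run_end = decoy.position + step * (decoy.run_length - 1)
        for _ in range(config.reads_per_site):
            counter += 1
            body_len = int(rng.integers(30, 61))
            read = _sense_fragment(
                seq, decoy.strand, run_end, body_len + decoy.run_length
            )
            read_id = f"read{counter:06d}"
            reads.append((read_id, read))
            rows.append(
                {
                    "read_id": read_id,
                    "gene_id": decoy.gene_id,
                    "chrom": decoy.chrom,
                    "strand": decoy.strand,
                    "site": decoy.position,
                    "cleavage": run_end,
                    "body_length": body_len,
                    "tail_length": decoy.run_length,
                    "tail_purity": 1.0,
                    "n_impure": 0,
                    "n_nontemplated": 0,
                    "antisense": False,
                    "is_decoy": True,
                }
            )

    read_truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "gene_id", "chrom", "strand", "site", "cleavage",
            "body_length", "tail_length", "tail_purity", "n_impure",
            "n_nontemplated", "antisense", "is_decoy",
        ],
    )
    return reads, read_truth


def save_outputs(outdir, genome, models, truth, reads, read_truth) -> dict:
    """Write a simulated dataset in its standard on-disk formats.

    Produces genome.fa, genes.gff3, truth_sites.bed (BED6, score =
    expected support), truth_sites.tsv, introns.tsv, reads.fastq and
    read_truth.tsv under ``outdir``; returns the path of each file.
    """
    from pathlib import Path

    from .io import write_fasta, write_fastq, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "truth_bed": outdir / "truth_sites.bed",
        "truth_tsv": outdir / "truth_sites.tsv",
        "introns": outdir / "introns.tsv",
        "reads": outdir / "reads.fastq",
        "read_truth": outdir / "read_truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(models, paths["annotation"])
    with open(paths["truth_bed"], "w") as fh:
        for i, r in enumerate(truth.sites.itertuples(index=False), start=1):
            fh.write(
                f"{r.chrom}\t{r.position - 1}\t{r.position}\tsite{i}\t"
                f"{r.expected_support}\t{r.strand}\n"
            )
    truth.sites.to_csv(paths["truth_tsv"], sep="\t", index=False)
    truth.introns.to_csv(paths["introns"], sep="\t", index=False)
    write_fastq(reads, paths["reads"])
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths
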