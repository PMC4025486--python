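"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; GFF3 is written directly (1-based
inclusive, gene/mRNA/exon/CDS/UTR features) and read back through
gffutils (see :func:`apakit.regions.load_gene_models`); site and truth
tables are plain TSV via pandas; BED exports are BED6 (0-based
half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import PAC
from .regions import GeneModel

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_reads",
    "write_gff3",
    "sites_to_bed",
    "pacs_to_bed",
    "write_flanks_fasta",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality: int = 40) -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ reads as (id, sequence) pairs; format inferred
    from the suffix when not given."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    lines = ["##gff-version 3"]

    def row(chrom, source, ftype, start, end, strand, attrs):
        return "\t".join(
            [chrom, source, ftype, str(start), str(end), ".", strand, ".", attrs]
        )

    for m in models:
        lines.append(
            row(m.chrom, "apakit", "gene", m.start, m.end, m.strand,
                f"ID={m.gene_id}")
        )
        mrna_id = f"{m.gene_id}.t1"
        lines.append(
            row(m.chrom, "apakit", "mRNA", m.start, m.end, m.strand,
                f"ID={mrna_id};Parent={m.gene_id}")
        )
        for ftype, intervals in (
            ("exon", m.exons),
            ("CDS", m.cds),
            ("five_prime_UTR", m.utr5),
            ("three_prime_UTR", m.utr3),
        ):
            for k, (s, e) in enumerate(sorted(intervals), start=1):
                lines.append(
                    row(m.chrom, "apakit", ftype, s, e, m.strand,
                        f"ID={mrna_id}.{ftype}.{k};Parent={mrna_id}")
                )
    Path(path).write_text("\n".join(lines) + "\n")


def sites_to_bed(sites: pd.DataFrame, path: str | Path,
                 name_prefix: str = "site") -> None:
    """Unique sites as BED6 single-base intervals, score = support."""
    with open(path, "w") as fh:
        for i, r in enumerate(sites.itertuples(index=False), start=1):
            fh.write(
                f"{r.chrom}\t{r.position - 1}\t{r.position}\t"
                f"{name_prefix}{i}\t{r.support}\t{r.strand}\n"
            )


def pacs_to_bed(pacs: Sequence[PAC], path: str | Path) -> None:
    """PAC spans as BED6 (0-based half-open), score = total support."""
    with open(path, "w") as fh:
        for p in pacs:
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.pac_id}\t"
                f"{p.total_support}\t{p.strand}\n"
            )


def write_flanks_fasta(flanks, path: str | Path) -> None:
    """FASTA of flank sequences; headers carry the pac id and layout."""
    with open(path, "w") as fh:
        for f in flanks:
            fh.write(
                f">{f.pac_id} upstream={f.upstream} downstream={f.downstream} "
                f"padded={int(f.padded)}\n{f.sequence}\n"
            )
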