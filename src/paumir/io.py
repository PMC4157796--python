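"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ parsing is delegated to Biopython; the collapsed-tag dialects
(TSV and ``>tag<i>_x<count>`` FASTA headers) are the small-RNA field's
conventional exchange formats for unique-tag libraries.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "write_collapsed_tsv",
    "read_collapsed_tsv",
    "write_tally_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{identifier: sequence}`` map.

    Sequences are uppercased and U is normalised to T so that DNA- and
    RNA-alphabet references can be mixed freely.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (identifier, sequence, phred qualities) from a Sanger FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def write_collapsed_fasta(tags: dict[str, int], path: str | Path, prefix: str = "tag") -> None:
    """Write unique tags as ``>tag<i>_x<count>`` records (count-suffixed headers)."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(tags.items()), start=1):
            fh.write(f">{prefix}{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    tags: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        seq = str(rec.seq).upper().replace("U", "T")
        tags[seq] = tags.get(seq, 0) + count
    return tags


def write_collapsed_tsv(tags: dict[str, int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "count"])
        for seq, count in sorted(tags.items()):
            w.writerow([seq, count])


def read_collapsed_tsv(path: str | Path) -> dict[str, int]:
    tags: dict[str, int] = {}
    with open(path) as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header[:2] != ["sequence", "count"]:
            raise ValueError(f"not a collapsed-tag TSV: header {header!r}")
        for row in r:
            tags[row[0].upper().replace("U", "T")] = int(row[1])
    return tags


def write_tally_tsv(tally: dict[str, int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reason", "reads"])
        for k, v in tally.items():
            w.writerow([k, v])
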