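"""Sequence-format ingestion and tabular output.

FASTA and FASTQ (Phred+33) are read through Biopython's SeqIO; gzip-compressed
files are handled transparently by extension. One FASTA file is one genome: a
multi-record file (chromosome + plasmids) contributes all of its records to a
single :class:`GenomeRecord`.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO

from Bio import SeqIO

_VALID = set("ACGTN")

#: Sentinel genome id meaning "read not assigned to any genome".
DISCARD = 0


@dataclass
class GenomeRecord:
    """One reference genome: id, label, and its sequences.

    genome_id is a positive integer; 0 and -1 are reserved as index-entry
    sentinels (empty / dirty).
    """

    genome_id: int
    name: str
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_id < 1:
            raise ValueError(f"genome_id must be >= 1, got {self.genome_id}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass
class SequencingRead:
    """A short read with per-base Phred qualities."""

    read_id: str
    bases: str
    qualities: list[int]
    mate: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadAssignment:
    """Classifier verdict for one read.

    ``predicted_genome_id`` is a positive genome id, or :data:`DISCARD` when
    the majority rule failed. ``votes_for``/``votes_total`` count k-mers kept
    after the unanimity and quality gates.
    """

    read_id: str
    predicted_genome_id: int
    votes_for: int
    votes_total: int
    read_length: int
    kmers_skipped_quality: int = 0

    @property
    def identified(self) -> bool:
        return self.predicted_genome_id != DISCARD


def _normalize_seq(raw: str) -> str:
    s = raw.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def _open_text(path: str | os.PathLike) -> TextIO:
    p = str(path)
    if p.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(p, "rb"))
    return open(p, "rt")


def read_fasta_genomes(
    paths: Sequence[str | os.PathLike],
    names: Optional[Sequence[str]] = None,
) -> list[GenomeRecord]:
    """Load one genome per FASTA file, assigning ids 1..G in input order.

    Names default to the file stem; a parallel ``names`` sequence overrides
    them. Lowercase bases are uppercased and characters outside ACGTN are
    mapped to N.
    """
    if names is not None and len(names) != len(paths):
        raise ValueError("names must parallel paths")
    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for i, path in enumerate(paths):
        stem = Path(str(path).removesuffix(".gz")).stem
        name = names[i] if names is not None else stem
        if name in seen:
            raise ValueError(f"duplicate genome name: {name!r}")
        seen.add(name)
        with _open_text(path) as fh:
            seqs = [_normalize_seq(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        if not seqs or sum(map(len, seqs)) == 0:
            raise ValueError(f"empty FASTA file: {path}")
        genomes.append(GenomeRecord(genome_id=i + 1, name=name, sequences=seqs))
    return genomes


def read_fastq(path: str | os.PathLike) -> Iterator[SequencingRead]:
    """Stream reads from a FASTQ file (Phred+33), in file order."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield SequencingRead(
                read_id=rec.id,
                bases=_normalize_seq(str(rec.seq)),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )


def write_fasta(genome: GenomeRecord, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for j, seq in enumerate(genome.sequences):
            fh.write(f">{genome.name}|seq{j}\n")
            for start in range(0, len(seq), 80):
                fh.write(seq[start : start + 80] + "\n")


def write_fastq(reads: Iterable[SequencingRead], path: str | os.PathLike) -> None:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


_ASSIGN_HEADER = ["read_id", "genome_id", "genome_name", "votes_for", "votes_total"]


def write_assignments(
    assignments: Iterable[ReadAssignment],
    path: str | os.PathLike,
    genome_names: Optional[dict[int, str]] = None,
) -> None:
    """Write identified reads as TSV; discarded reads are omitted."""
    names = genome_names or {}
    with open(path, "wt") as fh:
        fh.write("\t".join(_ASSIGN_HEADER) + "\n")
        for a in assignments:
            if not a.identified:
                continue
            name = names.get(a.predicted_genome_id, str(a.predicted_genome_id))
            fh.write(
                f"{a.read_id}\t{a.predicted_genome_id}\t{name}\t"
                f"{a.votes_for}\t{a.votes_total}\n"
            )


def read_assignments(
    path: str | os.PathLike, read_lengths: Optional[dict[str, int]] = None
) -> list[ReadAssignment]:
    """Re-parse a TSV written by :func:`write_assignments`.

    Read lengths are not stored in the TSV; supply a mapping if coverage is to
    be recomputed from the parsed assignments (0 otherwise).
    """
    out: list[ReadAssignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ASSIGN_HEADER:
            raise ValueError(f"unexpected assignment header: {header}")
        for line in fh:
            rid, gid, _name, vf, vt = line.rstrip("\n").split("\t")
            out.append(
                ReadAssignment(
                    read_id=rid,
                    predicted_genome_id=int(gid),
                    votes_for=int(vf),
                    votes_total=int(vt),
                    read_length=(read_lengths or {}).get(rid, 0),
                )
            )
    return out
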