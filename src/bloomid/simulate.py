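"""Synthetic communities with known ground truth.

Generates i.i.d. uniform-ACGT reference genomes and substitution-error short
reads from a chosen subset of them, so the whole pipeline — index build, read
classification, coverage filtering, evaluation — is testable without any
download. Erroneous bases receive low Phred scores and correct bases high
ones, giving the k-mer quality gate a realistic signal to act on.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import GenomeRecord, SequencingRead, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Design of a synthetic metagenomic experiment.

    The reference universe has ``g_total`` genomes of ``genome_length`` bp;
    only ``present_ids`` are sequenced, each to its target ``coverage``.
    Reads of ``read_length`` bp carry substitution errors at
    ``substitution_error_rate`` per base; correct/erroneous bases draw Phred
    scores around ``qual_correct_mean``/``qual_error_mean`` (sd ``qual_sd``,
    clipped to 2..41). ``related_pairs`` optionally overwrites genome b with
    a mutated copy of genome a at the given per-base divergence, to create
    shared k-mers between references.
    """

    g_total: int = 20
    present_ids: Optional[Sequence[int]] = None
    genome_length: int = 20_000
    coverage: float = 2.0
    read_length: int = 75
    substitution_error_rate: float = 0.005
    qual_correct_mean: float = 38.0
    qual_error_mean: float = 12.0
    qual_sd: float = 3.0
    master_seed: int = 0
    related_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.present_ids is None:
            self.present_ids = list(range(1, self.g_total // 2 + 1))
        self.present_ids = list(self.present_ids)
        if not set(self.present_ids) <= set(range(1, self.g_total + 1)):
            raise ValueError("present_ids must be a subset of 1..g_total")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be >= 10 x read_length")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    # substitute with one of the three other bases
    lut = {b: [c for c in _BASES if c != b] for b in _BASES}
    for i in hit:
        arr[i] = rng.choice(lut[arr[i]])
    return arr.tobytes().decode("ascii")


def make_genomes(spec: CommunitySpec) -> list[GenomeRecord]:
    """Generate the reference universe, deterministic under the master seed."""
    rng = np.random.default_rng(spec.master_seed)
    genomes = [
        GenomeRecord(
            genome_id=i, name=f"species_{i:03d}",
            sequences=[_random_seq(rng, spec.genome_length)],
        )
        for i in range(1, spec.g_total + 1)
    ]
    for src, dst, divergence in spec.related_pairs:
        genomes[dst - 1].sequences = [
            _mutate(rng, s, divergence) for s in genomes[src - 1].sequences
        ]
    return genomes


def make_reads(
    genomes: Sequence[GenomeRecord], spec: CommunitySpec
) -> tuple[list[SequencingRead], dict[str, int]]:
    """Simulate reads from the present genomes; returns (reads, truth).

    Per present species, round(coverage * genome_length / read_length) reads
    are drawn uniformly over both strands; errors are substitution-only. The
    truth dict maps read_id -> source genome id.
    """
    rng = np.random.default_rng((spec.master_seed, 1))
    by_id = {g.genome_id: g for g in genomes}
    rl = spec.read_length
    reads: list[SequencingRead] = []
    truth: dict[str, int] = {}
    for gid in spec.present_ids:
        genome = by_id[gid]
        seq = genome.sequences[0] if len(genome.sequences) == 1 else "".join(
            genome.sequences
        )
        n_reads = round(spec.coverage * genome.total_length / rl)
        starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            frag = seq[starts[i] : starts[i] + rl]
            if strands[i]:
                frag = frag.translate(_RC)[::-1]
            arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
            err = rng.random(rl) < spec.substitution_error_rate
            for j in np.nonzero(err)[0]:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = rng.choice(choices)
            qmeans = np.where(err, spec.qual_error_mean, spec.qual_correct_mean)
            quals = np.clip(
                np.rint(rng.normal(qmeans, spec.qual_sd)), 2, 41
            ).astype(int)
            rid = f"r{gid}_{i}"
            reads.append(
                SequencingRead(
                    read_id=rid, bases=arr.tobytes().decode("ascii"),
                    qualities=list(quals),
                )
            )
            truth[rid] = gid
    return reads, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def strain_pair_community(
    n_pairs: int = 10,
    genome_length: int = 20_000,
    coverage: float = 2.0,
    read_length: int = 75,
    substitution_error_rate: float = 0.005,
    divergence: float = 0.02,
    master_seed: int = 0,
) -> CommunitySpec:
    """A community built to exercise the false-positive filter.

    The universe holds ``n_pairs`` present genomes plus one absent twin per
    present genome at the given per-base divergence — the strain-variation
    regime where sequencing errors occasionally convert a read k-mer into
    the absent twin's unique signature, producing spurious low-coverage
    species calls.
    """
    return CommunitySpec(
        g_total=2 * n_pairs,
        present_ids=list(range(1, n_pairs + 1)),
        genome_length=genome_length,
        coverage=coverage,
        read_length=read_length,
        substitution_error_rate=substitution_error_rate,
        related_pairs=[(i, i + n_pairs, divergence) for i in range(1, n_pairs + 1)],
        master_seed=master_seed,
    )


def truth_species(spec: CommunitySpec, genomes: Sequence[GenomeRecord]) -> set[str]:
    """Names of the species actually present in the simulated sample."""
    by_id = {g.genome_id: g.name for g in genomes}
    return {by_id[g] for g in spec.present_ids}


def write_sample(
    spec: CommunitySpec, out_dir: str | os.PathLike
) -> tuple[list[GenomeRecord], list[SequencingRead], dict[str, int]]:
    """Materialize a full synthetic sample on disk.

    Writes genomes/*.fasta, reads.fastq, truth.tsv and spec.lock.json under
    ``out_dir``; returns the in-memory objects as well.
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    genomes = make_genomes(spec)
    reads, truth = make_reads(genomes, spec)
    for g in genomes:
        write_fasta(g, out / "genomes" / f"{g.name}.fasta")
    write_fastq(reads, out / "reads.fastq")
    with open(out / "truth.tsv", "wt") as fh:
        fh.write("read_id\tgenome_id\n")
        for rid, gid in truth.items():
            fh.write(f"{rid}\t{gid}\n")
    lock = asdict(spec)
    lock["present_ids"] = list(spec.present_ids)
    with open(out / "spec.lock.json", "wt") as fh:
        json.dump(lock, fh, indent=2)
    return genomes, reads, truth
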