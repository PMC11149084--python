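"""The genome-id Bloom index.

A classic Bloom filter stores membership bits; here each of the ``m`` entries
stores a small signed integer instead:

* ``0``  — never written (empty),
* ``-1`` — "dirty": written by k-mers of at least two distinct genomes,
* ``g > 0`` — written only by genome ``g`` so far.

Every k-mer of every reference genome — on both the forward and the
reverse-complement strand — is hashed by ``n`` seeded hash functions to ``n``
entries. A query gathers its ``n`` entry values and reports genome ``g`` only
when all of them unanimously equal the same positive ``g``; any empty entry,
dirty entry, or disagreement discards the k-mer. Because both strands were
inserted at build time, queries look up the k-mer as read.

k-mers are packed into 2 bits per base (so ``k`` is limited to 32), and the
hash family is a seeded 64-bit avalanche mix applied to the packed code,
reduced mod ``m`` — deterministic for a fixed master seed and fully
vectorized over numpy arrays of k-mer codes.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .io_formats import DISCARD, GenomeRecord

#: Entry value meaning "written by two or more genomes".
DIRTY = -1

FORMAT_VERSION = 1
_MAGIC = b"MBIX"

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c
    _BASE_CODE[ord(chr(_b).lower())] = _c

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

# murmur3 fmix64 constants
_C1 = np.uint64(0xFF51AFD7ED558CCD)
_C2 = np.uint64(0xC4CEB9FE1A85EC53)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def enumerate_kmers(sequence: str, k: int) -> Iterator[tuple[str, int]]:
    """Yield ``(kmer, position)`` for every N-free window of ``sequence``.

    Positions are 0-based; a sequence shorter than ``k`` yields nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if "N" not in kmer:
            yield kmer, i


def encode_kmers(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack all N-free k-mers of ``sequence`` into uint64 codes.

    Returns ``(codes, positions)``; windows containing an ambiguous base are
    dropped. Equivalent to :func:`enumerate_kmers` but vectorized.
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in 1..32, got {k}")
    vals = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_win = len(vals) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    bad = (vals == 255).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    ok = (cbad[k:] - cbad[:-k]) == 0
    positions = np.nonzero(ok)[0].astype(np.int64)
    if positions.size == 0:
        return np.empty(0, dtype=np.uint64), positions
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)[positions]
    codes = (windows.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    return codes, positions


def _splitmix64(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return state, z ^ (z >> 31)


@dataclass(frozen=True)
class HashFamily:
    """``n`` seeded hash functions mapping uint64 k-mer codes into ``[0, m)``.

    Per-function seeds are derived from ``master_seed`` by a splitmix64
    recurrence, so the whole family is reproducible from one integer.
    """

    n: int
    m: int
    master_seed: int
    seeds: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("need n >= 1 hash functions and m >= 1 entries")
        if not self.seeds:
            state, seeds = self.master_seed & 0xFFFFFFFFFFFFFFFF, []
            while len(seeds) < self.n:
                state, s = _splitmix64(state)
                if s not in seeds:
                    seeds.append(s)
            object.__setattr__(self, "seeds", tuple(seeds))

    def positions(self, codes: np.ndarray) -> np.ndarray:
        """Hash positions, shape ``(n, len(codes))``."""
        codes = np.asarray(codes, dtype=np.uint64)
        out = np.empty((self.n, codes.size), dtype=np.int64)
        m = np.uint64(self.m)
        for i, seed in enumerate(self.seeds):
            x = codes ^ np.uint64(seed)
            x ^= x >> np.uint64(33)
            x *= _C1
            x ^= x >> np.uint64(33)
            x *= _C2
            x ^= x >> np.uint64(33)
            out[i] = (x % m).astype(np.int64)
        return out


@dataclass
class GenomeTable:
    """id -> (name, total genome length in bp), ids contiguous 1..G."""

    names: list[str]
    lengths: list[int]

    @classmethod
    def from_genomes(cls, genomes: Sequence[GenomeRecord]) -> "GenomeTable":
        ids = [g.genome_id for g in genomes]
        if sorted(ids) != list(range(1, len(genomes) + 1)):
            raise ValueError("genome ids must be contiguous 1..G")
        by_id = sorted(genomes, key=lambda g: g.genome_id)
        return cls([g.name for g in by_id], [g.total_length for g in by_id])

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, genome_id: int) -> bool:
        return 1 <= genome_id <= len(self.names)

    def name_of(self, genome_id: int) -> str:
        return self.names[genome_id - 1]

    def length_of(self, genome_id: int) -> int:
        return self.lengths[genome_id - 1]

    def name_map(self) -> dict[int, str]:
        return {i + 1: n for i, n in enumerate(self.names)}


def _entry_dtype(n_genomes: int) -> np.dtype:
    if n_genomes <= np.iinfo(np.int8).max:
        return np.dtype(np.int8)
    if n_genomes <= np.iinfo(np.int16).max:
        return np.dtype(np.int16)
    return np.dtype(np.int32)


@dataclass
class BloomIndex:
    k: int
    hash_family: HashFamily
    entries: np.ndarray
    genome_table: GenomeTable
    format_version: int = FORMAT_VERSION

    @property
    def m(self) -> int:
        return self.hash_family.m

    @property
    def n(self) -> int:
        return self.hash_family.n


def insert_genome(index: BloomIndex, genome: GenomeRecord) -> BloomIndex:
    """Insert every k-mer of ``genome`` (both strands) into the index.

    Entry update rule, per hash position: empty -> genome id; same id ->
    unchanged; another genome's id -> dirty; dirty -> unchanged. In-place;
    returns the index for chaining.
    """
    gid = genome.genome_id
    if gid not in index.genome_table:
        raise ValueError(f"genome id {gid} not registered in the genome table")
    entries = index.entries
    for seq in genome.sequences:
        for strand in (seq, reverse_complement(seq)):
            codes, _ = encode_kmers(strand, index.k)
            if codes.size == 0:
                continue
            pos = index.hash_family.positions(codes).ravel()
            cur = entries[pos]
            entries[pos[cur == 0]] = gid
            entries[pos[(cur > 0) & (cur != gid)]] = DIRTY
    return index


def default_table_size(total_bp: int, n: int) -> int:
    # distinct k-mers ~ 2 x total bp (both strands); n writes per k-mer;
    # load factor <= 0.5 then needs m >= 4 n bp
    return max(64, 4 * n * total_bp)


def build_index(
    genomes: Sequence[GenomeRecord],
    k: int = 31,
    m: Optional[int] = None,
    n: int = 3,
    master_seed: int = 0,
) -> BloomIndex:
    """Build the index over ``genomes``; deterministic for fixed arguments.

    ``m`` defaults to a size keeping the expected load factor at or below
    one half for the given genomes.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    table = GenomeTable.from_genomes(genomes)
    if any(length < k for length in table.lengths):
        raise ValueError(f"every genome must be at least k={k} bp long")
    total_bp = sum(table.lengths)
    if m is None:
        m = default_table_size(total_bp, n)
    if m < len(genomes):
        warnings.warn(
            f"table size m={m} is smaller than the number of genomes "
            f"({len(genomes)}); expect heavy dirtying", stacklevel=2,
        )
    hf = HashFamily(n=n, m=m, master_seed=master_seed)
    entries = np.zeros(m, dtype=_entry_dtype(len(genomes)))
    index = BloomIndex(k=k, hash_family=hf, entries=entries, genome_table=table)
    for genome in genomes:
        insert_genome(index, genome)
    return index


def query_codes(index: BloomIndex, codes: np.ndarray) -> np.ndarray:
    """Vectorized unanimity query over packed k-mer codes.

    Returns an int array: genome id where all ``n`` entries agree on the same
    positive id, :data:`DISCARD` (0) otherwise.
    """
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.size == 0:
        return np.empty(0, dtype=np.int64)
    vals = index.entries[index.hash_family.positions(codes)].astype(np.int64)
    first = vals[0]
    unanimous = (first > 0) & np.all(vals == first[np.newaxis, :], axis=0)
    return np.where(unanimous, first, DISCARD)


def query_kmer(index: BloomIndex, kmer: str) -> int:
    """Query one k-mer; returns a genome id or :data:`DISCARD`."""
    if len(kmer) != index.k:
        raise ValueError(f"k-mer length {len(kmer)} != index k {index.k}")
    codes, _ = encode_kmers(kmer, index.k)
    if codes.size == 0:  # contained N
        return DISCARD
    return int(query_codes(index, codes)[0])


def save_index(index: BloomIndex, path) -> None:
    """Binary serialization: MBIX magic, header, genome table, raw entries."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(
            struct.pack(
                "<IIIQQIB",
                index.format_version,
                index.k,
                index.n,
                index.m,
                index.hash_family.master_seed & 0xFFFFFFFFFFFFFFFF,
                len(index.genome_table),
                index.entries.dtype.itemsize,
            )
        )
        for gid in range(1, len(index.genome_table) + 1):
            name = index.genome_table.name_of(gid).encode("utf-8")
            fh.write(struct.pack("<II", gid, len(name)))
            fh.write(name)
            fh.write(struct.pack("<Q", index.genome_table.length_of(gid)))
        fh.write(index.entries.astype(index.entries.dtype.newbyteorder("<")).tobytes())


def load_index(path) -> BloomIndex:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"not an index file (bad magic {magic!r})")
        header = fh.read(struct.calcsize("<IIIQQIB"))
        if len(header) < struct.calcsize("<IIIQQIB"):
            raise ValueError("truncated index file header")
        version, k, n, m, master_seed, n_genomes, width = struct.unpack(
            "<IIIQQIB", header
        )
        if version != FORMAT_VERSION:
            raise ValueError(
                f"index format version {version}, expected {FORMAT_VERSION}"
            )
        names, lengths = [], []
        for _ in range(n_genomes):
            gid, name_len = struct.unpack("<II", fh.read(8))
            names.append(fh.read(name_len).decode("utf-8"))
            (length,) = struct.unpack("<Q", fh.read(8))
            lengths.append(length)
        dtype = {1: np.int8, 2: np.int16, 4: np.int32}[width]
        raw = fh.read(m * width)
        if len(raw) != m * width:
            raise ValueError("truncated index file entry array")
        entries = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(
            dtype
        )
    hf = HashFamily(n=n, m=m, master_seed=master_seed)
    table = GenomeTable(names=names, lengths=lengths)
    return BloomIndex(
        k=k, hash_family=hf, entries=entries, genome_table=table,
        format_version=version,
    )
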