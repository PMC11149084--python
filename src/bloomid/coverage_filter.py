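"""Coverage clustering to remove false-positive species.

A falsely predicted species accrues only scattered misidentified reads, so
its approximate genomic coverage (identified bases / genome length) sits far
below that of species actually present. Species are clustered by coverage
with 1-D K-means — on a log10 scale by default, since coverages span orders
of magnitude — and the cluster with the lowest mean coverage is dropped.
The same filter applies to any external classifier's per-read assignment
table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bloom_index import GenomeTable
from .io_formats import ReadAssignment

_COLUMNS = ["species", "n_reads", "total_bases", "genome_length", "coverage"]


@dataclass
class SpeciesCoverageTable:
    """Per-species identified-read tallies and approximate coverage.

    ``df`` is indexed by species id with columns species (name), n_reads,
    total_bases, genome_length, coverage. Species with zero identified reads
    never appear.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"coverage table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species_names(self) -> list[str]:
        return list(self.df["species"])

    @property
    def coverages(self) -> np.ndarray:
        return self.df["coverage"].to_numpy()


@dataclass
class ClusterResult:
    """K-means partition of the coverage table.

    ``filtered`` is False for the no-filtering sentinel (fewer species than
    K, or zero coverage variance), in which case labels are all zero and no
    cluster is flagged for removal.
    """

    K: int
    labels: np.ndarray
    cluster_means: np.ndarray  # on the clustering scale
    lowest_mean_cluster: int
    scale: str
    random_seed: int
    filtered: bool = True


@dataclass
class PredictionReport:
    kept: pd.DataFrame
    removed: pd.DataFrame
    cluster_result: ClusterResult

    @property
    def kept_species(self) -> set[str]:
        return set(self.kept["species"])

    @property
    def removed_species(self) -> set[str]:
        return set(self.removed["species"])

    def to_tsv(self, path) -> None:
        cr = self.cluster_result
        rows = pd.concat([self.kept.assign(kept=True), self.removed.assign(kept=False)])
        rows = rows.sort_index()
        rows["cluster_mean"] = cr.cluster_means[rows["cluster"]]
        rows[["species", "n_reads", "coverage", "cluster", "cluster_mean", "kept"]].to_csv(
            path, sep="\t", index_label="species_id"
        )


def compute_coverages(
    assignments: Sequence[ReadAssignment], genome_table: GenomeTable
) -> SpeciesCoverageTable:
    """Tally identified reads per species and derive approximate coverage.

    Coverage is total identified read bases divided by genome length; for
    uniform read length L this is n_reads * L / genome_length.
    """
    identified = [a for a in assignments if a.identified]
    bad = sorted(
        {a.predicted_genome_id for a in identified} - set(range(1, len(genome_table) + 1))
    )
    if bad:
        raise ValueError(f"assigned genome ids missing from genome table: {bad}")
    n_reads: dict[int, int] = {}
    bases: dict[int, int] = {}
    for a in identified:
        gid = a.predicted_genome_id
        n_reads[gid] = n_reads.get(gid, 0) + 1
        bases[gid] = bases.get(gid, 0) + a.read_length
    ids = sorted(n_reads)
    df = pd.DataFrame(
        {
            "species": [genome_table.name_of(g) for g in ids],
            "n_reads": [n_reads[g] for g in ids],
            "total_bases": [bases[g] for g in ids],
            "genome_length": [genome_table.length_of(g) for g in ids],
        },
        index=pd.Index(ids, name="species_id"),
    )
    df["coverage"] = df["total_bases"] / df["genome_length"]
    return SpeciesCoverageTable(df)


def _kmeans_1d(x: np.ndarray, K: int) -> np.ndarray:
    """Exact 1-D K-means by dynamic programming over contiguous splits.

    The K-means optimum in one dimension is a contiguous partition of the
    sorted values, so it can be solved exactly in O(K n^2) with prefix sums
    rather than approximated by Lloyd restarts. Labels are returned in input
    order and numbered from the lowest-value block upward.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    s = x[order]
    c1 = np.concatenate(([0.0], np.cumsum(s)))
    c2 = np.concatenate(([0.0], np.cumsum(s * s)))

    def seg_cost(i: int, j: int) -> float:  # values s[i:j]
        m = j - i
        total = c1[j] - c1[i]
        return (c2[j] - c2[i]) - total * total / m

    cost = np.full((K + 1, n + 1), np.inf)
    split = np.zeros((K + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            for i in range(k - 1, j):
                c = cost[k - 1, i] + seg_cost(i, j)
                if c < cost[k, j]:
                    cost[k, j] = c
                    split[k, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for k in range(K, 0, -1):
        i = split[k, j]
        labels_sorted[i:j] = k - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_coverages(
    table: SpeciesCoverageTable,
    K: int = 2,
    scale: str = "log10",
    seed: int = 0,
) -> ClusterResult:
    """1-D K-means over (scaled) species coverages.

    Solved exactly (dynamic programming), so the result is deterministic and
    globally optimal; ``seed`` is recorded in the result for provenance but
    does not influence the partition. Degenerate tables (fewer species than
    K, or all coverages equal) return a no-filtering sentinel. The
    lowest-mean cluster is reported with ties broken by smallest label.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if len(table) == 0:
        raise ValueError("coverage table is empty")
    cov = table.coverages.astype(float)
    x = np.log10(cov) if scale == "log10" else cov
    if len(table) < K or np.all(x == x[0]):
        return ClusterResult(
            K=K, labels=np.zeros(len(table), dtype=int),
            cluster_means=np.array([float(np.mean(x))]), lowest_mean_cluster=-1,
            scale=scale, random_seed=seed, filtered=False,
        )
    labels = _kmeans_1d(x, K)
    means = np.array([x[labels == c].mean() for c in range(K)])
    lowest = int(np.argmin(means))  # argmin takes the smallest label on ties
    return ClusterResult(
        K=K, labels=labels, cluster_means=means, lowest_mean_cluster=lowest,
        scale=scale, random_seed=seed,
    )


def filter_species(
    table: SpeciesCoverageTable, cluster_result: ClusterResult
) -> PredictionReport:
    """Drop the lowest-mean cluster; keep everything else.

    On a no-filtering sentinel all species are kept.
    """
    if len(cluster_result.labels) != len(table):
        raise ValueError("cluster labels do not cover the coverage table")
    df = table.df.assign(cluster=cluster_result.labels)
    if not cluster_result.filtered:
        return PredictionReport(
            kept=df, removed=df.iloc[0:0], cluster_result=cluster_result
        )
    drop = df["cluster"] == cluster_result.lowest_mean_cluster
    return PredictionReport(
        kept=df[~drop], removed=df[drop], cluster_result=cluster_result
    )


def ingest_external_assignments(
    assignments_path: str | os.PathLike,
    genome_lengths_path: str | os.PathLike,
    read_length: Optional[int] = None,
) -> SpeciesCoverageTable:
    """Build a coverage table from another classifier's read table.

    ``assignments_path``: TSV with columns ``read_id`` and ``species`` (a
    ``read_length`` column is optional; otherwise a uniform ``read_length``
    must be given). ``genome_lengths_path``: TSV with columns ``species`` and
    ``genome_length``. The resulting table feeds the same clustering filter.
    """
    lengths = pd.read_csv(genome_lengths_path, sep="\t")
    if not {"species", "genome_length"} <= set(lengths.columns):
        raise ValueError("genome lengths file needs columns: species, genome_length")
    lengths = lengths.set_index("species")["genome_length"]

    asg = pd.read_csv(assignments_path, sep="\t")
    if asg.empty:
        return SpeciesCoverageTable(
            pd.DataFrame(columns=_COLUMNS, index=pd.Index([], name="species_id"))
        )
    if not {"read_id", "species"} <= set(asg.columns):
        raise ValueError("assignment file needs columns: read_id, species")
    if "read_length" not in asg.columns:
        if read_length is None:
            raise ValueError(
                "assignment file has no read_length column; pass a uniform read_length"
            )
        asg = asg.assign(read_length=read_length)

    unknown = sorted(set(asg["species"]) - set(lengths.index))
    if unknown:
        raise ValueError(f"species not in the genome length table: {unknown}")

    grouped = asg.groupby("species")["read_length"].agg(["count", "sum"])
    names = sorted(grouped.index)
    df = pd.DataFrame(
        {
            "species": names,
            "n_reads": grouped.loc[names, "count"].to_numpy(),
            "total_bases": grouped.loc[names, "sum"].to_numpy(),
            "genome_length": lengths.loc[names].to_numpy(),
        },
        index=pd.Index(range(1, len(names) + 1), name="species_id"),
    )
    df["coverage"] = df["total_bases"] / df["genome_length"]
    return SpeciesCoverageTable(df)
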