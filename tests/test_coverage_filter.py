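import numpy as np
import pandas as pd
import pytest

from bloomid import (
    GenomeTable,
    ReadAssignment,
    cluster_coverages,
    compute_coverages,
    filter_species,
    ingest_external_assignments,
)
from bloomid.coverage_filter import SpeciesCoverageTable

from oracles import best_contiguous_split, wcss


def _assignments(counts, read_length=75):
    out = []
    for gid, n in counts.items():
        out += [
            ReadAssignment(f"r{gid}_{i}", gid, 40, 45, read_length=read_length)
            for i in range(n)
        ]
    return out


def _table(coverages):
    ids = range(1, len(coverages) + 1)
    df = pd.DataFrame(
        {
            "species": [f"sp{i}" for i in ids],
            "n_reads": 1,
            "total_bases": [c * 1000 for c in coverages],
            "genome_length": 1000,
            "coverage": list(coverages),
        },
        index=pd.Index(ids, name="species_id"),
    )
    return SpeciesCoverageTable(df)


class TestComputeCoverages:
    def test_coverage_arithmetic(self):
        table = GenomeTable(names=["a"], lengths=[3000])
        cov = compute_coverages(_assignments({1: 100}), table)
        assert cov.df.loc[1, "coverage"] == pytest.approx(2.5)  # 7500/3000
        assert cov.df.loc[1, "n_reads"] == 100

    def test_empty_assignments_empty_table(self):
        table = GenomeTable(names=["a"], lengths=[3000])
        assert len(compute_coverages([], table)) == 0

    def test_unknown_id_rejected(self):
        table = GenomeTable(names=["a"], lengths=[3000])
        with pytest.raises(ValueError, match="\\[7\\]"):
            compute_coverages(_assignments({7: 1}), table)

    def test_totals_match_independent_recount(self, toy_index, toy_reads):
        from bloomid import classify_sample

        reads, _ = toy_reads
        identified, _ = classify_sample(toy_index, reads)
        cov = compute_coverages(identified, toy_index.genome_table)
        # brute-force recount straight off the assignment list
        for gid in cov.df.index:
            mine = [a for a in identified if a.predicted_genome_id == gid]
            assert cov.df.loc[gid, "n_reads"] == len(mine)
            assert cov.df.loc[gid, "total_bases"] == sum(a.read_length for a in mine)


class TestClusterCoverages:
    def test_two_scale_groups_split_correctly(self):
        table = _table([5.1, 4.9, 0.01, 0.02])
        result = cluster_coverages(table, K=2, seed=0)
        report = filter_species(table, result)
        assert report.kept_species == {"sp1", "sp2"}
        assert report.removed_species == {"sp3", "sp4"}

    def test_single_species_sentinel(self):
        result = cluster_coverages(_table([3.0]), K=2, seed=0)
        assert not result.filtered

    def test_equal_coverages_sentinel(self):
        result = cluster_coverages(_table([2.0, 2.0, 2.0]), K=3, seed=0)
        assert not result.filtered

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_coverages(_table([1.0, 2.0]), K=1)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        table = _table(10 ** rng.normal(0, 1, size=15))
        a = cluster_coverages(table, seed=42)
        b = cluster_coverages(table, seed=42)
        assert np.array_equal(a.labels, b.labels)
        assert a.lowest_mean_cluster == b.lowest_mean_cluster

    @pytest.mark.parametrize("K", [2, 3])
    def test_matches_exhaustive_contiguous_oracle(self, K):
        """sklearn's 1-D K-means attains the optimal contiguous split."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(K + 1, 20))
            cov = 10 ** rng.normal(0, 1.2, size=n)
            table = _table(cov)
            result = cluster_coverages(table, K=K, seed=1)
            x = np.log10(cov)
            opt_cost, _ = best_contiguous_split(x, K)
            assert wcss(x, result.labels) == pytest.approx(opt_cost, abs=1e-9)

    def test_never_worse_than_lloyd_kmeans(self):
        """Cross-check against scikit-learn's Lloyd K-means: the exact DP
        partition is at least as good (often strictly better)."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(5)
        for K in (2, 3):
            for _ in range(10):
                cov = 10 ** rng.normal(0, 1.2, size=int(rng.integers(K + 1, 25)))
                x = np.log10(cov)
                ours = cluster_coverages(_table(cov), K=K, seed=0)
                lloyd = KMeans(n_clusters=K, n_init=10, random_state=0).fit_predict(
                    x.reshape(-1, 1)
                )
                assert wcss(x, ours.labels) <= wcss(x, lloyd) + 1e-9

    def test_contiguity_of_labels(self):
        rng = np.random.default_rng(7)
        cov = 10 ** rng.normal(0, 1, size=12)
        result = cluster_coverages(_table(cov), K=3, seed=5)
        order = np.argsort(cov)
        runs = np.sum(np.diff(result.labels[order]) != 0)
        assert runs == 2  # three contiguous blocks along sorted coverage


class TestFilterSpecies:
    def test_partition_property(self):
        rng = np.random.default_rng(1)
        table = _table(10 ** rng.normal(0, 1, size=9))
        report = filter_species(table, cluster_coverages(table, seed=0))
        kept, removed = set(report.kept.index), set(report.removed.index)
        assert kept | removed == set(table.df.index)
        assert kept & removed == set()

    def test_sentinel_keeps_everything(self):
        table = _table([2.0, 2.0])
        report = filter_species(table, cluster_coverages(table, seed=0))
        assert report.kept_species == {"sp1", "sp2"}
        assert len(report.removed) == 0

    def test_separated_communities_filtered_exactly(self):
        """With a >=20x coverage gap, the filter recovers the present set
        exactly across 50 random communities."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_true = int(rng.integers(3, 12))
            n_false = int(rng.integers(1, 8))
            cov = np.concatenate(
                [10 ** rng.uniform(0.3, 1.5, n_true),  # >= 2x
                 10 ** rng.uniform(-2, -1.3, n_false)]  # <= 0.05x
            )
            table = _table(cov)
            report = filter_species(table, cluster_coverages(table, seed=3))
            assert set(report.kept.index) == set(range(1, n_true + 1))


class TestExternalIngestion:
    def _write_inputs(self, tmp_path, rows, lengths, with_length_col=False):
        asg = tmp_path / "asg.tsv"
        header = "read_id\tspecies" + ("\tread_length" if with_length_col else "")
        asg.write_text("\n".join([header] + rows) + ("\n" if rows else "\n"))
        lens = tmp_path / "lens.tsv"
        lens.write_text(
            "species\tgenome_length\n"
            + "".join(f"{s}\t{l}\n" for s, l in lengths.items())
        )
        return asg, lens

    def test_uniform_read_length_coverage(self, tmp_path):
        rows = [f"r{i}\tEcoli" for i in range(10)] + ["r10\tBsub"]
        asg, lens = self._write_inputs(tmp_path, rows, {"Ecoli": 500, "Bsub": 1500})
        table = ingest_external_assignments(asg, lens, read_length=150)
        df = table.df.set_index("species")
        assert df.loc["Ecoli", "coverage"] == pytest.approx(10 * 150 / 500)
        assert df.loc["Bsub", "coverage"] == pytest.approx(150 / 1500)

    def test_per_read_lengths_honoured(self, tmp_path):
        rows = ["r0\tEcoli\t100", "r1\tEcoli\t50"]
        asg, lens = self._write_inputs(
            tmp_path, rows, {"Ecoli": 300}, with_length_col=True
        )
        table = ingest_external_assignments(asg, lens)
        assert table.df.iloc[0]["coverage"] == pytest.approx(0.5)

    def test_missing_length_information_is_an_error(self, tmp_path):
        asg, lens = self._write_inputs(tmp_path, ["r0\tEcoli"], {"Ecoli": 300})
        with pytest.raises(ValueError, match="read_length"):
            ingest_external_assignments(asg, lens)

    def test_unresolvable_species_listed(self, tmp_path):
        asg, lens = self._write_inputs(tmp_path, ["r0\tMystery"], {"Ecoli": 300})
        with pytest.raises(ValueError, match="Mystery"):
            ingest_external_assignments(asg, lens, read_length=100)

    def test_empty_file_empty_table(self, tmp_path):
        asg, lens = self._write_inputs(tmp_path, [], {"Ecoli": 300})
        table = ingest_external_assignments(asg, lens, read_length=100)
        assert len(table) == 0
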