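"""Dereplication, swarm-style clustering, chimera removal, abundance filter."""

import itertools

import numpy as np
import pytest

from gyrbench.amplicon_pipeline import (
    abundance_filter,
    build_otu_table,
    cluster_reads,
    dereplicate,
    remove_chimeras,
    swarm_cluster,
)


def brute_force_components(seqs, d):
    """Independent oracle: naive single-linkage via repeated set merging."""
    import edlib

    comps = [{s} for s in seqs]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(comps)), 2):
            if any(
                edlib.align(a, b, mode="NW", task="distance")["editDistance"] <= d
                for a in comps[i]
                for b in comps[j]
            ):
                comps[i] |= comps[j]
                del comps[j]
                changed = True
                break
    return {frozenset(c) for c in comps}


class TestDereplicate:
    def test_exact_grouping(self):
        derep = dereplicate({"s1": ["AAA", "AAA", "AAT"]})
        assert dict(zip(derep.sequences, derep.totals)) == {"AAA": 2, "AAT": 1}

    def test_empty_input(self):
        derep = dereplicate({"s1": []})
        assert len(derep) == 0 and derep.total_reads == 0

    def test_shared_sequence_keeps_per_sample_counts(self):
        derep = dereplicate({"s1": ["AAA"], "s2": ["AAA", "CCC"]})
        idx = derep.sequences.index("AAA")
        assert derep.counts[idx].tolist() == [1, 1]
        assert derep.total_reads == 3


class TestSwarmCluster:
    def test_transitive_chain_merges(self):
        # A-B at 3 edits, B-C at 3 edits, A-C at 6: one OTU by single linkage
        a = "AAAAAAAAAAAAAAAAAAAA"
        b = "AAAAAAAAAAAAAAAAATTT"
        c = "TTTAAAAAAAAAAAAAATTT"
        derep = dereplicate({"s": [a, a, b, c]})
        otus = swarm_cluster(derep, d=3)
        assert len(otus) == 1
        assert otus[0].representative == a  # most abundant member
        assert brute_force_components([a, b, c], 3) == {frozenset({a, b, c})}

    def test_distance_over_threshold_splits(self):
        a, b = "AAAAAAAAAA", "AAAAAATTTT"
        otus = swarm_cluster(dereplicate({"s": [a, b]}), d=3)
        assert len(otus) == 2

    def test_singleton(self):
        otus = swarm_cluster(dereplicate({"s": ["ACGT"]}), d=3)
        assert len(otus) == 1 and otus[0].representative == "ACGT"

    def test_ids_by_decreasing_abundance(self):
        reads = ["AAAAAAAAAA"] * 5 + ["CCCCCCCCCC"] * 9 + ["GGGGGGGGGG"] * 2
        otus = swarm_cluster(dereplicate({"s": reads}), d=1)
        assert [o.otu_id for o in otus] == ["Cluster_1", "Cluster_2", "Cluster_3"]
        assert otus[0].representative == "CCCCCCCCCC"

    @pytest.mark.parametrize("n_centers,length", [(5, 60), (8, 40)])
    def test_matches_brute_force_oracle(self, rng, n_centers, length):
        # ~180 sequences scattered around centers, including inter-center
        # bridges; clustering must equal naive single-linkage components
        bases = np.array(list("ACGT"))
        centers = ["".join(rng.choice(bases, length)) for _ in range(n_centers)]
        seqs = set(centers)
        for c in centers:
            for _ in range(20):
                arr = np.array(list(c))
                k = rng.integers(0, 5)
                pos = rng.choice(length, size=k, replace=False)
                for p in pos:
                    arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
                seqs.add("".join(arr))
        seqs = sorted(seqs)
        counts = {s: int(rng.integers(1, 50)) for s in seqs}
        derep = dereplicate({"s": [s for s in seqs for _ in range(counts[s])]})
        otus = swarm_cluster(derep, d=3)
        got = {frozenset(o.members) for o in otus}
        assert got == brute_force_components(seqs, 3)

    def test_large_path_agrees_with_brute_force(self, rng):
        # force the pigeonhole candidate-filter path (> brute-force limit)
        bases = np.array(list("ACGT"))
        length = 50
        centers = ["".join(rng.choice(bases, length)) for _ in range(8)]
        seqs = set(centers)
        for c in centers:
            for _ in range(110):
                arr = np.array(list(c))
                for p in rng.choice(length, size=rng.integers(1, 4), replace=False):
                    arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
                seqs.add("".join(arr))
        seqs = sorted(seqs)
        assert len(seqs) > 600
        derep = dereplicate({"s": list(seqs)})
        got = {frozenset(o.members) for o in swarm_cluster(derep, d=3)}
        # independent oracle: dense all-pairs adjacency + scipy components
        import edlib
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n = len(seqs)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance", k=3)[
                    "editDistance"
                ]
                adj[i, j] = adj[j, i] = d != -1
        _, labels = connected_components(csr_matrix(adj), directed=False)
        oracle = {}
        for i, lab in enumerate(labels):
            oracle.setdefault(lab, set()).add(seqs[i])
        assert got == {frozenset(v) for v in oracle.values()}


class TestChimeraRemoval:
    def _otu(self, seq, total, otu_id="x"):
        from gyrbench.amplicon_pipeline import OTU

        return OTU(otu_id, seq, (seq,), np.array([total]))

    def test_constructed_chimera_removed(self):
        pa = "A" * 140 + "C" * 140
        pb = "G" * 140 + "T" * 140
        chim = pa[:140] + pb[140:]
        otus = [self._otu(pa, 1000, "a"), self._otu(pb, 1000, "b"), self._otu(chim, 100, "c")]
        kept, flagged = remove_chimeras(otus)
        assert [o.otu_id for o in flagged] == ["c"]
        assert {o.otu_id for o in kept} == {"a", "b"}

    def test_no_decomposition_kept(self):
        otus = [
            self._otu("A" * 100, 1000, "a"),
            self._otu("C" * 100, 1000, "b"),
            self._otu("G" * 50 + "T" * 50, 10, "c"),
        ]
        kept, flagged = remove_chimeras(otus)
        assert flagged == []

    def test_rare_parents_do_not_flag(self):
        # decomposition exists but the "parents" are rarer than the query:
        # checked over all parent pairs by the abundance-order rule
        pa = "A" * 100 + "C" * 100
        pb = "G" * 100 + "T" * 100
        chim = pa[:100] + pb[100:]
        otus = [self._otu(pa, 5, "a"), self._otu(pb, 5, "b"), self._otu(chim, 100, "c")]
        kept, flagged = remove_chimeras(otus)
        assert flagged == []
        assert len(kept) == 3


class TestAbundanceFilter:
    def _table(self, totals):
        from gyrbench.amplicon_pipeline import OTU

        otus = [
            OTU(f"Cluster_{i + 1}", "A" * (i + 5), ("A" * (i + 5),), np.array([t]))
            for i, t in enumerate(totals)
        ]
        return build_otu_table(otus, ["s1"])

    def test_strictly_greater_than_ten(self):
        table = self._table([11, 10, 500])
        out = abundance_filter(table, min_total=11)
        assert sorted(out.df.sum(axis=1)) == [11, 500]
        assert out.removed.to_numpy().sum() == 10

    def test_all_below_threshold_warns_not_raises(self):
        table = self._table([3, 4])
        out = abundance_filter(table, min_total=11)
        assert len(out.df) == 0

    def test_threshold_zero_identity(self):
        table = self._table([1, 2, 3])
        out = abundance_filter(table, min_total=0)
        assert out.df.equals(table.df)


class TestConservation:
    def test_read_ledger_balances(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 120))
        other = "".join(rng.choice(list("ACGT"), 120))
        chim = base[:60] + other[60:]
        reads = {"s1": [base] * 400 + [other] * 300 + [chim] * 20 + ["ACGT" * 30] * 3}
        table, ledger = cluster_reads(reads, d=3, min_total=11)
        assert (
            ledger["reads_in"]
            == ledger["reads_kept"] + ledger["chimera_removed"] + ledger["filter_removed"]
        )
        assert ledger["chimera_removed"] == 20
        assert ledger["filter_removed"] == 3

    def test_error_free_run_matches_expected_cluster_count(self, mc1_small):
        from gyrbench.evaluation import expected_cluster_count

        spec, refs, reads, truth = mc1_small
        table, _ = cluster_reads(reads, d=3, min_total=0, detect_chimeras=False)
        assert len(table.df) == expected_cluster_count(refs, d=3)
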