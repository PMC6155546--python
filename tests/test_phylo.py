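"""K2P distances, neighbor joining, marker trees, newick round trips."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from gyrbench.phylo import (
    SaturationError,
    build_marker_tree,
    k2p_distance,
    k2p_matrix,
    neighbor_joining,
    p_distance,
)


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        # 100 sites, 10 transitions (A<->G), 5 transversions (A<->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.17018, abs=5e-6)

    def test_saturation_error(self):
        # P=0, Q=0.5: log argument hits zero
        a = "A" * 100
        b = "C" * 50 + "A" * 50
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_pairwise_deletion_of_ambiguous_sites(self):
        assert k2p_distance("ACGTN-", "ACGAAC"[:6]) == k2p_distance("ACGT", "ACGA")

    def test_k2p_at_least_p_distance(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, 200))
            arr = np.array(list(a))
            for p in rng.choice(200, size=rng.integers(0, 40), replace=False):
                arr[p] = rng.choice([x for x in "ACGT" if x != arr[p]])
            b = "".join(arr)
            assert k2p_distance(a, b) >= p_distance(a, b) - 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["a", "b", "c"])
        tree = neighbor_joining(dm)
        tips = {t.name: t for t in tree.tips()}
        dists = {
            (i, j): tips[i].distance(tips[j])
            for i in "abc"
            for j in "abc"
            if i < j
        }
        assert dists[("a", "b")] == pytest.approx(3)
        assert dists[("a", "c")] == pytest.approx(4)
        assert dists[("b", "c")] == pytest.approx(5)

    def test_four_taxa_topology_recovery(self):
        # additive distances from ((a:1,b:2):1,(c:3,d:4)): a-b cherry
        dm = DistanceMatrix(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            ids=list("abcd"),
        )
        tree = neighbor_joining(dm)
        tips = {t.name: t for t in tree.tips()}
        for i, j in [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]:
            assert tips[i].distance(tips[j]) == pytest.approx(dm[i, j], abs=1e-9)

    def test_identical_leaves_zero_cherry(self):
        dm = DistanceMatrix(
            [[0, 0, 5], [0, 0, 5], [5, 5, 0]], ids=["a1", "a2", "b"]
        )
        tree = neighbor_joining(dm)
        tips = {t.name: t for t in tree.tips()}
        assert tips["a1"].distance(tips["a2"]) == pytest.approx(0.0, abs=1e-12)

    def test_exact_on_random_additive_matrices(self, rng):
        # oracle: distances generated from random trees must be reproduced
        for n_leaves in (5, 6, 7, 8):
            tree = _random_tree(n_leaves, rng)
            dm = tree.tip_tip_distances()
            recon = neighbor_joining(dm)
            tips = {t.name: t for t in recon.tips()}
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1 :]:
                    assert tips[a].distance(tips[b]) == pytest.approx(dm[a, b], abs=1e-9)

    def test_matches_skbio_nj_reconstruction(self, rng):
        # cross-check against the reference NJ: both must reproduce the
        # additive input distances exactly (which pins the unrooted topology;
        # rooting conventions differ, so path lengths are the comparator)
        from skbio.tree import nj as skbio_nj

        tree = _random_tree(6, rng)
        dm = tree.tip_tip_distances()
        mine_d = neighbor_joining(dm).tip_tip_distances(list(dm.ids))
        theirs_d = skbio_nj(dm).tip_tip_distances(list(dm.ids))
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1 :]:
                assert mine_d[a, b] == pytest.approx(dm[a, b], abs=1e-9)
                assert theirs_d[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def _random_tree(n_leaves: int, rng) -> TreeNode:
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self, rng):
        tree = _random_tree(6, rng)
        text = io.StringIO()
        tree.write(text)
        back = TreeNode.read(io.StringIO(text.getvalue()))
        assert tree.compare_rfd(back) == 0.0
        d1, d2 = tree.tip_tip_distances(), back.tip_tip_distances()
        for i, a in enumerate(d1.ids):
            for b in d1.ids[i + 1 :]:
                assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-9)


class TestMarkerTree:
    def test_firmicutes_pare_closer_to_firmicutes_gyrb(self):
        """The paralog geometry: Firmicutes gyrB and parE group together,
        away from Proteobacteria gyrB."""
        from gyrbench.synthetic_data import make_reference_set, mock_preset

        refs = make_reference_set(mock_preset("MC2", seed=8))
        tree = build_marker_tree(refs)
        tips = {t.name: t for t in tree.tips()}
        groups = {"firm_gyrB": [], "firm_parE": [], "prot_gyrB": []}
        for r in refs:
            key = ("firm_" if r.taxonomy[1] == "Firmicutes" else "prot_") + r.gene
            groups[key].append(r.label)
        # mean within/between distances: Firmicutes parE is nearer to
        # Firmicutes gyrB than to Proteobacteria gyrB
        def mean_dist(g1, g2):
            vals = [
                tips[a].distance(tips[b]) for a in groups[g1] for b in groups[g2] if a != b
            ]
            return float(np.mean(vals))

        assert mean_dist("firm_parE", "firm_gyrB") < mean_dist("firm_parE", "prot_gyrB")
        assert mean_dist("firm_gyrB", "firm_gyrB") < mean_dist("firm_gyrB", "prot_gyrB")

    def test_strain_cherries_follow_divergence_plan(self):
        from gyrbench.synthetic_data import make_reference_set, mock_preset

        refs = make_reference_set(mock_preset("MC4", seed=8))
        sakei = [r for r in refs if r.species == "Lactobacillus sakei" and r.gene == "gyrB"]
        tree = build_marker_tree(refs)
        tips = {t.name: t for t in tree.tips()}
        d_close = tips[_label(sakei, "23K")].distance(tips[_label(sakei, "DSM15831")])
        d_far = tips[_label(sakei, "23K")].distance(tips[_label(sakei, "DSM20017")])
        assert d_close < d_far

    def test_too_few_sequences_rejected(self, toy_db):
        with pytest.raises(ValueError):
            build_marker_tree(toy_db[:2])


def _label(records, strain):
    return next(r.label for r in records if r.strain == strain)
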