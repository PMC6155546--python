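"""Mock-community generator: presets, divergence plans, reads, qPCR."""

import math

import edlib
import numpy as np
import pytest

from gyrbench.synthetic_data import (
    CURVE_16S,
    CURVE_HOUSEKEEPING,
    MOCK_PRESETS,
    PARE_FRACTIONS,
    UnrealizablePlanError,
    make_genome_records,
    make_reference_set,
    mock_preset,
    simulate_qpcr,
    simulate_reads,
)


def _ed(a, b):
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


class TestPresets:
    @pytest.mark.parametrize("name,firm", [("MC1", 0.99), ("MC2", 0.50), ("MC3", 0.01), ("MC4", 0.65)])
    def test_phylum_split_and_sum(self, name, firm):
        spec = mock_preset(name)
        total = sum(m.proportion for m in spec.members)
        assert total == pytest.approx(1.0, abs=1e-12)
        firm_total = sum(m.proportion for m in spec.members if m.phylum == "Firmicutes")
        assert firm_total == pytest.approx(firm, abs=1e-12)

    def test_inter_species_preset_has_15_species(self):
        assert len(mock_preset("MC1").species) == 15

    def test_intra_species_preset_has_14_strains_5_species(self):
        spec = mock_preset("MC4")
        assert len(spec.members) == 14
        assert len(spec.species) == 5

    def test_proteobacteria_never_pare(self):
        spec = mock_preset("MC2")
        for m in spec.members:
            if m.phylum == "Proteobacteria":
                assert spec.parE_fraction.get(m.species, 0.0) == 0.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            mock_preset("MC9")


class TestReferenceSet:
    def test_planned_strain_distances_realized(self):
        # L. sakei plan: 23K~DSM15831 at 2 edits, DSM20017 at 8 from both
        refs = make_reference_set(mock_preset("MC4", seed=3))
        by_id = {r.marker_id: r.sequence for r in refs}
        assert _ed(by_id["23K_gyrB"], by_id["DSM15831_gyrB"]) == 2
        assert _ed(by_id["23K_gyrB"], by_id["DSM20017_gyrB"]) == 8
        assert _ed(by_id["DSM15831_gyrB"], by_id["DSM20017_gyrB"]) == 8
        # clonal species: identical sequences at planned distance 0
        assert by_id["160x8_gyrB"] == by_id["cH814_gyrB"] == by_id["ATCC11509_gyrB"]

    def test_proteobacteria_get_no_pare_record(self):
        refs = make_reference_set(mock_preset("MC1", seed=3))
        for r in refs:
            if r.taxonomy[1] == "Proteobacteria":
                assert r.gene == "gyrB"
        firm_species_with_pare = {
            r.species for r in refs if r.gene == "parE"
        }
        assert firm_species_with_pare == {
            s for s in mock_preset("MC1").species if PARE_FRACTIONS.get(s, 0) > 0
        }

    def test_paralog_divergence_floor(self):
        refs = make_reference_set(mock_preset("MC4", seed=3), length=280)
        gyrb = [r.sequence for r in refs if r.gene == "gyrB"]
        pare = [r.sequence for r in refs if r.gene == "parE"]
        assert pare
        assert min(_ed(a, b) for a in pare for b in gyrb) >= 0.20 * 280

    def test_interspecies_distance_floor(self):
        refs = make_reference_set(mock_preset("MC1", seed=3))
        for i, a in enumerate(refs):
            for b in refs[i + 1 :]:
                if a.gene == b.gene and a.species != b.species:
                    assert _ed(a.sequence, b.sequence) >= 7

    def test_unrealizable_plan_rejected(self):
        plan = {
            "Lactobacillus sakei": {
                frozenset({"23K", "DSM15831"}): 1,
                frozenset({"23K", "DSM20017"}): 1,
                frozenset({"DSM15831", "DSM20017"}): 10,  # violates triangle
            }
        }
        with pytest.raises(UnrealizablePlanError):
            make_reference_set(mock_preset("MC4"), divergence_plan=plan)


class TestSimulateReads:
    def test_error_free_reads_equal_references(self, mc1_small):
        spec, refs, reads, truth = mc1_small
        ref_seqs = {r.sequence for r in refs}
        sample = spec.sample_names()[0]
        assert set(reads[sample]) <= ref_seqs

    def test_counts_conserved_and_match_depth(self, mc1_small):
        spec, refs, reads, truth = mc1_small
        sample = spec.sample_names()[0]
        per_sample = truth.reads.groupby("sample")["count"].sum()
        assert (per_sample == spec.depth).all()
        assert len(reads[sample]) == spec.depth

    def test_mc1_firmicutes_fraction_within_3sd(self):
        spec = mock_preset("MC1", depth=100_000, error_rate=0.0, seed=5)
        refs = make_reference_set(spec)
        _, truth = simulate_reads(spec, refs)
        frac = truth.phylum_fractions(spec.sample_names()[0])["Firmicutes"]
        sd = math.sqrt(0.99 * 0.01 / spec.depth)
        assert abs(frac - 0.99) <= 3 * sd

    def test_pare_split_within_3sd(self):
        # L. algidus at parE fraction 0.8: ~80% of its reads are parE-origin
        spec = mock_preset("MC1", depth=100_000, error_rate=0.0, seed=5)
        refs = make_reference_set(spec)
        _, truth = simulate_reads(spec, refs)
        sub = truth.reads[truth.reads["species"] == "Lactobacillus algidus"]
        by_gene = sub.groupby("gene")["count"].sum()
        n = by_gene.sum()
        frac = by_gene["parE"] / n
        assert abs(frac - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / n)

    def test_error_rate_produces_expected_mismatches(self):
        spec = mock_preset("MC2", depth=5_000, error_rate=5e-3, seed=5)
        refs = make_reference_set(spec)
        reads, _ = simulate_reads(spec, refs)
        sample = spec.sample_names()[0]
        dists = [
            min(_ed(read, r.sequence) for r in refs) for read in reads[sample][:500]
        ]
        mean_errors = np.mean(dists)
        expect = 280 * 5e-3
        assert abs(mean_errors - expect) <= 3 * math.sqrt(expect / 500)

    def test_chimeras_join_two_parents(self):
        spec = mock_preset("MC2", depth=2_000, error_rate=0.0, chimera_rate=0.01, seed=5)
        refs = make_reference_set(spec)
        reads, truth = simulate_reads(spec, refs)
        sample = spec.sample_names()[0]
        n_chim = truth.chimeras[sample]
        assert n_chim > 0
        assert len(reads[sample]) == spec.depth + n_chim
        ref_seqs = {r.sequence for r in refs}
        for read in reads[sample][-n_chim:]:
            assert read not in ref_seqs

    def test_fixed_seed_byte_identical(self):
        spec = mock_preset("MC2", depth=2_000, error_rate=1e-3, seed=9)
        refs = make_reference_set(spec)
        r1, _ = simulate_reads(spec, refs)
        r2, _ = simulate_reads(spec, refs)
        assert r1 == r2

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads(mock_preset("MC1"), [])


class TestSimulateQpcr:
    def test_closed_form_cts(self, mc1_small):
        spec, refs, reads, truth = mc1_small
        t = truth
        t.loads = t.loads.copy()
        t.loads.loc[:, "cfu"] = 1.0
        q = simulate_qpcr(t, noise_sd=0.0)
        species_rows = q[q["species"] != "all_bacteria"]
        assert np.allclose(species_rows["Ct"], 40.98, rtol=1e-12)
        t.loads.loc[:, "cfu"] = math.e
        q = simulate_qpcr(t, noise_sd=0.0, species_curve=CURVE_16S)
        species_rows = q[q["species"] != "all_bacteria"]
        assert species_rows["Ct"].to_numpy() == pytest.approx(39.43 - 1.52)

    def test_nonpositive_cfu_rejected(self, mc1_small):
        _, _, _, truth = mc1_small
        bad = truth.loads.copy()
        bad.loc[bad.index[0], "cfu"] = 0.0
        t = type(truth)(reads=truth.reads, loads=bad, totals=truth.totals)
        with pytest.raises(ValueError):
            simulate_qpcr(t, noise_sd=0.0)


class TestGenomeEmbedding:
    def test_database_roundtrip_recovers_references(self):
        from gyrbench.insilico_pcr import PRIMER_PRESETS
        from gyrbench.refdb import build_database

        spec = mock_preset("MC4", seed=3)
        refs = make_reference_set(spec)
        genomes = make_genome_records(refs, seed=3)
        db = build_database(genomes, PRIMER_PRESETS["gyrB"])
        # dedup collapses the clonal strains; every ref sequence is present
        assert {r.sequence for r in refs} == {m.sequence for m in db}
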