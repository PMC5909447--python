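"""Synthetic cohort generator: composition targets, filters, planted signals."""

import numpy as np
import pytest

import stopscan as ss
from stopscan.genetics import CODON_INDEX
from stopscan.synth import AA_PROFILE, _osc_replacement_table


def protein(seq, table):
    return "".join(table.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


class TestCodonUsageSampling:
    @pytest.mark.parametrize("target", [0.15, 0.35, 0.5, 0.7, 0.9])
    def test_expected_gc3_hits_target(self, target):
        rng = np.random.default_rng(1)
        usage = ss.sample_codon_usage(target, 50.0, rng)
        assert usage.expected_gc3(AA_PROFILE) == pytest.approx(target, abs=0.02)

    def test_infeasible_target_clamps_with_warning(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="clamp"):
            ss.sample_codon_usage(0.01, 50.0, rng)

    def test_symmetric_tilt_at_half(self):
        # NNY 2-fold blocks (e.g. Asp GAT/GAC) get near-equal C/T at mid GC3
        rng = np.random.default_rng(2)
        usage = ss.sample_codon_usage(0.5, 1e6, rng)  # huge concentration: no jitter
        asp = dict(zip(usage.table.synonyms["D"], usage.probs["D"]))
        assert asp["GAC"] == pytest.approx(asp["GAT"], abs=0.05)

    def test_same_seed_identical_table(self):
        u1 = ss.sample_codon_usage(0.4, 50.0, np.random.default_rng(9))
        u2 = ss.sample_codon_usage(0.4, 50.0, np.random.default_rng(9))
        for aa in u1.probs:
            np.testing.assert_array_equal(u1.probs[aa], u2.probs[aa])

    def test_bad_target_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.sample_codon_usage(1.2, 50.0, rng)


class TestGenerateGenome:
    @pytest.mark.parametrize("table_id", [11, 4])
    def test_every_cds_passes_all_filters(self, table_id):
        rng = np.random.default_rng(3)
        table = ss.get_table(table_id)
        g = ss.generate_genome(
            "g", rng, n_cds=30, cds_length=(10, 80), gc3_target=0.4, table=table
        )
        for cds in g.cds_list:
            assert ss.filter_cds(cds.sequence, table).accepted

    def test_table4_internal_tga_permitted(self):
        # under table 4 TGA is Trp: with enough codons some internal TGA appears
        rng = np.random.default_rng(4)
        g = ss.generate_genome(
            "g", rng, n_cds=40, cds_length=(100, 200), gc3_target=0.3,
            table=ss.TABLE_4,
        )
        internal_tga = sum(
            int((cds.codon_idx[1:-1] == CODON_INDEX["TGA"]).sum())
            for cds in g.cds_list
        )
        assert internal_tga > 0
        for cds in g.cds_list:
            assert cds.codons[-1] in {"TAA", "TAG"}

    def test_realized_gc3_near_target_for_large_genome(self):
        rng = np.random.default_rng(5)
        g = ss.generate_genome(
            "g", rng, n_cds=300, cds_length=(150, 210), gc3_target=0.6
        )
        assert g.total_codons > 50_000
        assert g.gc3 == pytest.approx(0.6, abs=0.02)


class TestInjectOscBias:
    def test_delta_zero_is_identity(self, at_rich_genome, rng):
        out = ss.inject_osc_bias(at_rich_genome, "TAA", "+1", 0.0, rng)
        for a, b in zip(out.cds_list, at_rich_genome.cds_list):
            assert a.sequence == b.sequence

    def test_delta_one_saturates_eligible_sites(self, at_rich_genome, rng):
        out = ss.inject_osc_bias(at_rich_genome, "TAA", "+1", 1.0, rng)
        repl = _osc_replacement_table(out.table, "TAA", 1)
        for cds in out.cds_list:
            cod = cds.codon_idx
            for i in range(1, len(cod) - 1):
                if repl[cod[i]] >= 0 and cds.sequence[3 * i + 3] == "A":
                    # an OSC-forming synonym exists and the neighbour completes
                    # TAA: the site must carry it
                    assert cds.sequence[3 * i + 1 : 3 * i + 4] == "TAA"

    def test_amino_acid_sequence_unchanged(self, at_rich_genome, rng):
        out = ss.inject_osc_bias(at_rich_genome, "TAA", "+1", 0.5, rng)
        t = at_rich_genome.table
        for a, b in zip(out.cds_list, at_rich_genome.cds_list):
            assert protein(a.sequence, t) == protein(b.sequence, t)

    def test_density_monotone_in_delta(self, at_rich_genome):
        dens = []
        for delta in (0.0, 0.4, 1.0):
            out = ss.inject_osc_bias(
                at_rich_genome, "TAA", "+1", delta, np.random.default_rng(7)
            )
            dens.append(ss.osc_density(out, {"TAA"}, ["+1"]))
        assert dens[0] < dens[1] < dens[2]

    def test_plus2_frame_targeting(self, at_rich_genome, rng):
        base = ss.osc_density(at_rich_genome, {"TAA"}, ["+2"])
        out = ss.inject_osc_bias(at_rich_genome, "TAA", "+2", 1.0, rng)
        assert ss.osc_density(out, {"TAA"}, ["+2"]) > base

    def test_bad_delta_rejected(self, at_rich_genome, rng):
        with pytest.raises(ValueError):
            ss.inject_osc_bias(at_rich_genome, "TAA", "+1", 1.5, rng)


class TestInjectDicodonBias:
    def test_site3_usage_increases(self, at_rich_genome):
        cfg = ss.ile_taa()
        before = ss.genome_site_usage(at_rich_genome, cfg)
        out = ss.inject_dicodon_bias(
            at_rich_genome, cfg, 1.0, np.random.default_rng(8)
        )
        after = ss.genome_site_usage(out, cfg)
        assert after.a3 == pytest.approx(1.0)
        assert after.n_contexts >= before.n_contexts  # swaps keep eligibility
        t = at_rich_genome.table
        for a, b in zip(out.cds_list, at_rich_genome.cds_list):
            assert protein(a.sequence, t) == protein(b.sequence, t)

    def test_delta_zero_identity(self, at_rich_genome, rng):
        out = ss.inject_dicodon_bias(at_rich_genome, ss.ile_taa(), 0.0, rng)
        for a, b in zip(out.cds_list, at_rich_genome.cds_list):
            assert a.sequence == b.sequence


class TestCohort:
    def test_reproducible_from_master_seed(self):
        spec = ss.CohortSpec(n_genomes=4, n_cds=(5, 8), cds_length=(20, 50))
        g1, t1 = ss.generate_cohort(spec, seed=33)
        g2, t2 = ss.generate_cohort(spec, seed=33)
        for a, b in zip(g1, g2):
            assert [c.sequence for c in a.cds_list] == [c.sequence for c in b.cds_list]
        assert t1.equals(t2)

    def test_truth_table_shape_and_monotone_gc3(self):
        spec = ss.CohortSpec(
            n_genomes=8, n_cds=(20, 25), cds_length=(100, 160), gc3=(0.2, 0.8)
        )
        genomes, truth = ss.generate_cohort(spec, seed=1)
        assert len(truth) == 8
        assert (truth["gc3_target"].diff().dropna() > 0).all()
        # realized GC3 tracks the requested gradient
        assert truth["gc3_realized"].is_monotonic_increasing

    def test_mixed_tables_group_sizes(self):
        ids = [11, 11, 4, 11, 4]
        spec = ss.CohortSpec(n_genomes=5, n_cds=(5, 6), cds_length=(20, 40), table_id=ids)
        genomes, truth = ss.generate_cohort(spec, seed=2)
        assert [g.table.table_id for g in genomes] == ids
        assert truth["table_id"].tolist() == ids

    def test_enrichment_recorded_in_truth(self):
        spec = ss.CohortSpec(
            n_genomes=3, n_cds=(5, 6), cds_length=(30, 60),
            enrichment=ss.EnrichmentSpec("TAA", "+1", 0.2),
        )
        _, truth = ss.generate_cohort(spec, seed=3)
        assert (truth["delta"] == 0.2).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ss.CohortSpec(n_cds=(10, 5))
        with pytest.raises(ValueError):
            ss.CohortSpec(gc3=(0.0, 0.5))
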