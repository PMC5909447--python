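"""The four null simulators and the ensemble driver."""

import numpy as np
import pytest

import stopscan as ss
from stopscan.null_models import default_tracked_sets


def protein(seq: str, table) -> str:
    return "".join(table.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


class TestMarkov:
    def test_deterministic_homopolymer_training(self, table11, rng):
        g = ss.GenomeRecord("g", table11, [ss.CodingSequence("c", "ATGAAAAAATAA")])
        m = ss.build_markov_model(g, 2)
        np.testing.assert_allclose(m.transitions[2][("AA", 0)], [1, 0, 0, 0])
        assert ss.simulate_cds_markov(g.cds_list[0], m, rng) == "ATGAAAAAATAA"

    def test_training_is_deterministic(self, small_genome):
        m1 = ss.build_markov_model(small_genome, 2)
        m2 = ss.build_markov_model(small_genome, 2)
        assert m1.transitions.keys() == m2.transitions.keys()
        for k in m1.transitions:
            assert m1.transitions[k].keys() == m2.transitions[k].keys()
            for key in m1.transitions[k]:
                np.testing.assert_array_equal(
                    m1.transitions[k][key], m2.transitions[k][key]
                )

    def test_probabilities_sum_to_one(self, small_genome):
        m = ss.build_markov_model(small_genome, 5)
        for d in m.transitions.values():
            for probs in d.values():
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("order", [2, 5])
    def test_output_preserves_length_start_stop(self, small_genome, order, rng):
        m = ss.build_markov_model(small_genome, order)
        for cds in small_genome.cds_list[:20]:
            out = ss.simulate_cds_markov(cds, m, rng)
            assert len(out) == len(cds.sequence)
            assert out[:3] == cds.sequence[:3]
            assert out[-3:] == cds.sequence[-3:]

    def test_backoff_always_returns_a_distribution(self, small_genome):
        m = ss.build_markov_model(small_genome, 5)
        # a context that cannot have been observed in full still resolves
        probs = m.lookup("GGGGG", 0)
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_untrainable_genome_raises(self, table11):
        g = ss.GenomeRecord("g", table11, [ss.CodingSequence("c", "ATGTAA")])
        with pytest.raises(ValueError):
            ss.build_markov_model(g, 2)

    def test_bad_order_rejected(self, small_genome):
        with pytest.raises(ValueError):
            ss.build_markov_model(small_genome, 3)


class TestShuffle:
    def test_single_internal_codon_is_identity(self, rng):
        cds = ss.CodingSequence("c", "ATGAAATAA")
        assert ss.shuffle_codons(cds, rng) == "ATGAAATAA"

    def test_two_internal_codons_give_both_orders_evenly(self):
        cds = ss.CodingSequence("c", "ATGAAAGGGTAA")
        rng = np.random.default_rng(1)
        outs = [ss.shuffle_codons(cds, rng) for _ in range(400)]
        counts = {s: outs.count(s) for s in set(outs)}
        assert set(counts) == {"ATGAAAGGGTAA", "ATGGGGAAATAA"}
        # each permutation ~200; 4 sd of Binomial(400, .5) is 40
        assert abs(counts["ATGAAAGGGTAA"] - 200) < 40

    def test_codon_multiset_preserved(self, small_genome, rng):
        for cds in small_genome.cds_list[:20]:
            out = ss.shuffle_codons(cds, rng)
            assert sorted(ss.CodingSequence("s", out).codons) == sorted(cds.codons)
            assert out[:3] == cds.sequence[:3] and out[-3:] == cds.sequence[-3:]


class TestSynonymousResampling:
    def test_block_frequencies_from_counts(self, table11):
        # Lys codons AAA x3, AAG x1 -> block (K, AA): P(A)=0.75, P(G)=0.25
        g = ss.GenomeRecord(
            "g", table11, [ss.CodingSequence("c", "ATG" + "AAA" * 3 + "AAG" + "TAA")]
        )
        t = ss.build_synsite_table(g)
        np.testing.assert_allclose(t.probs[("K", "AA")], [0.75, 0.25])

    def test_synsite_preserves_protein_and_blocks(self, small_genome, rng):
        t = ss.build_synsite_table(small_genome)
        table = small_genome.table
        for cds in small_genome.cds_list[:20]:
            out = ss.simulate_cds_synsite(cds, t, rng)
            assert protein(out, table) == protein(cds.sequence, table)
            # block membership: first two nucleotides of every codon unchanged
            for i in range(0, len(out), 3):
                assert out[i : i + 2] == cds.sequence[i : i + 2]

    def test_met_codon_never_changes(self, table11, rng):
        g = ss.GenomeRecord(
            "g", table11, [ss.CodingSequence("c", "ATGATGATGTAA")]
        )
        t = ss.build_synsite_table(g)
        assert ss.simulate_cds_synsite(g.cds_list[0], t, rng) == "ATGATGATGTAA"

    def test_syncodon_pools_blocks(self, table11):
        # Leu CTG x2, TTA x2 -> pooled Leu vector 0.5/0.5; cross-block moves allowed
        g = ss.GenomeRecord(
            "g", table11, [ss.CodingSequence("c", "ATG" + "CTG" * 2 + "TTA" * 2 + "TAA")]
        )
        usage = ss.build_codon_usage(g)
        leu = dict(zip(table11.synonyms["L"], usage.probs["L"]))
        assert leu["CTG"] == pytest.approx(0.5)
        assert leu["TTA"] == pytest.approx(0.5)
        rng = np.random.default_rng(3)
        outs = {ss.simulate_cds_syncodon(g.cds_list[0], usage, rng) for _ in range(100)}
        crossed = any("CTG" not in o or "TTA" not in o for o in outs)
        assert crossed  # a TTA resampled to CTG (or vice versa) occurred

    def test_syncodon_preserves_protein(self, small_genome, rng):
        usage = ss.build_codon_usage(small_genome)
        table = small_genome.table
        for cds in small_genome.cds_list[:20]:
            out = ss.simulate_cds_syncodon(cds, usage, rng)
            assert protein(out, table) == protein(cds.sequence, table)

    def test_syncodon_usage_recovered_from_large_pool(self, small_genome):
        usage = ss.build_codon_usage(small_genome)
        rng = np.random.default_rng(7)
        counts = np.zeros(64)
        for cds in small_genome.cds_list:
            out = ss.CodingSequence("s", ss.simulate_cds_syncodon(cds, usage, rng))
            counts += np.bincount(out.codon_idx[1:-1], minlength=64)
        table = small_genome.table
        for aa, codons in table.synonyms.items():
            idx = [ss.genetics.CODON_INDEX[c] for c in codons]
            tot = counts[idx].sum()
            if tot < 200:
                continue
            emp = counts[idx] / tot
            tv = 0.5 * np.abs(emp - usage.probs[aa]).sum()
            assert tv < 0.1

    def test_table4_trp_block_is_twofold(self, table4, rng):
        # under table 4, Trp = {TGA, TGG} forms one coding block
        g = ss.GenomeRecord(
            "g", table4, [ss.CodingSequence("c", "ATG" + "TGA" * 2 + "TGG" * 2 + "TAA")]
        )
        t = ss.build_synsite_table(g)
        np.testing.assert_allclose(t.probs[("W", "TG")], [0.5, 0.5])


class TestEnsemble:
    def test_identical_seed_identical_ensemble(self, small_genome):
        e1 = ss.run_ensemble(small_genome, "shuffle", n_reps=20, seed=42)
        e2 = ss.run_ensemble(small_genome, "shuffle", n_reps=20, seed=42)
        for key in e1.sims:
            np.testing.assert_array_equal(e1.sims[key], e2.sims[key])

    def test_zero_reps_rejected(self, small_genome):
        with pytest.raises(ValueError):
            ss.run_ensemble(small_genome, "shuffle", n_reps=0, seed=1)

    def test_unknown_model_rejected(self, small_genome):
        with pytest.raises(ValueError):
            ss.run_ensemble(small_genome, "bogus", n_reps=5, seed=1)

    def test_fixed_case_shuffle_mean(self, table11):
        # exactly two permutations: one yields +1 TGA (density 25), one none
        g = ss.GenomeRecord("g", table11, [ss.CodingSequence("c", "ATGAAAGGGTAA")])
        e = ss.run_ensemble(g, "shuffle", n_reps=200, seed=9)
        exact_mean, exact_sd = 12.5, 12.5
        se = exact_sd / np.sqrt(200)
        assert abs(e.sim_mean("TGA", "+1") - exact_mean) < 3 * se

    def test_both_frame_is_sum(self, small_genome):
        e = ss.run_ensemble(small_genome, "synsite", n_reps=10, seed=4)
        for label in default_tracked_sets(small_genome.table):
            np.testing.assert_allclose(
                e.sims[(label, "both")],
                e.sims[(label, "+1")] + e.sims[(label, "+2")],
            )
            assert e.real[(label, "both")] == pytest.approx(
                e.real[(label, "+1")] + e.real[(label, "+2")]
            )

    def test_real_density_matches_osc_density(self, small_genome):
        e = ss.run_ensemble(small_genome, "shuffle", n_reps=2, seed=1)
        assert e.real[("TGA", "+1")] == pytest.approx(
            ss.osc_density(small_genome, {"TGA"}, ["+1"])
        )
        assert e.real[("stops", "both")] == pytest.approx(
            ss.osc_density(small_genome, small_genome.table.stop_codons, ["+1", "+2"])
        )

    def test_markov_ensemble_runs(self, table11):
        rng = np.random.default_rng(5)
        g = ss.generate_genome("m", rng, n_cds=10, cds_length=(20, 60), gc3_target=0.4)
        e = ss.run_ensemble(g, "markov2", n_reps=5, seed=2)
        assert all(np.isfinite(v).all() for v in e.sims.values())
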