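"""Properties of the synthetic allele/colony generator."""

import numpy as np
import pytest

import csdtrflp as c
from csdtrflp.errors import ConfigError, EditConflict
from csdtrflp.simulate import genotype_viability


class TestMakeAllele:
    def test_zero_edits_reproduces_template(self, template, reference_allele):
        again = c.make_allele(template, [], "again")
        assert again.amplicon_seq == reference_allele.amplicon_seq
        assert again.psd_protein == reference_allele.psd_protein

    def test_hvr_insertion_shifts_five_prime_fragment(self, template):
        ref = c.make_allele(template, [], "ref")
        ins = c.make_allele(template, [("hvr_insert", 0, "AAT")], "ins")
        assert ins.pattern.five_prime_len == ref.pattern.five_prime_len + 3
        assert ins.pattern.three_prime_len == ref.pattern.three_prime_len

    def test_edit_destroying_site_raises(self, template):
        with pytest.raises(EditConflict):
            c.make_allele(template, [("spacer_sub", 0, "G")], "x")

    def test_edit_creating_stop_raises(self, template):
        with pytest.raises(EditConflict):
            c.make_allele(template, [("rs_sub", 0, "TAA")], "x")


class TestAllelePool:
    def test_every_allele_passes_digest_validation(self, allele_pool):
        for a in allele_pool:
            assert a.amplicon_seq.count("ATTAAT") == 1
            pat = c.vsp_digest(a.amplicon_seq)
            assert pat.five_prime_len + pat.three_prime_len \
                == len(a.amplicon_seq)
            # ORF is open through explicit splice + translation
            s, e = a.ground_truth["intron_coords"]
            cds = c.splice_intron(a.amplicon_seq, "explicit", coords=(s, e))
            assert c.translate_and_validate(cds) == a.psd_protein

    def test_amplicons_are_distinct(self, allele_pool):
        assert len({a.amplicon_seq for a in allele_pool}) == len(allele_pool)

    def test_distinct_repeat_counts_give_distinct_five_prime(self,
                                                             allele_pool):
        by_units = {}
        for a in allele_pool:
            by_units.setdefault(a.ground_truth["n_hvr_units"],
                                set()).add(a.pattern.five_prime_len)
        lens = [next(iter(v)) for v in by_units.values()]
        assert all(len(v) == 1 for v in by_units.values())
        assert len(set(lens)) == len(lens)


class TestObserveTrflp:
    def test_noise_free_peaks_are_fragment_unions(self, template):
        a = c.make_allele(template, [], "a")
        b = c.make_allele(template, [("hvr_insert", 0, "AAT")], "b")
        rng = np.random.default_rng(0)
        obs = c.observe_trflp("w", "col", a, b, 0.0, rng)
        assert obs.hex_peaks == {a.pattern.five_prime_len,
                                 b.pattern.five_prime_len}
        assert obs.fam_peaks == {a.pattern.three_prime_len,
                                 b.pattern.three_prime_len}

    def test_identical_patterns_collapse_to_single_peaks(self,
                                                         reference_allele):
        rng = np.random.default_rng(0)
        obs = c.observe_trflp("w", "col", reference_allele,
                              reference_allele, 0.0, rng)
        assert len(obs.hex_peaks) == 1 and len(obs.fam_peaks) == 1

    def test_gaussian_jitter_mostly_within_one_nt(self, template):
        a = c.make_allele(template, [], "a")
        b = c.make_allele(template, [("hvr_insert", 0, "AAT")] * 4, "b")
        rng = np.random.default_rng(5)
        truth = {a.pattern.five_prime_len, b.pattern.five_prime_len}
        within = total = 0
        for _ in range(2500):
            obs = c.observe_trflp("w", "col", a, b, 0.5, rng)
            for peak in obs.hex_peaks:
                total += 1
                within += min(abs(peak - t) for t in truth) <= 1
        assert within / total >= 0.99


class TestSimulateColony:
    def test_full_viability_keeps_every_conception(self, quiet_colony):
        assert len(quiet_colony.observations) == len(quiet_colony.truth)
        assert quiet_colony.truth["survives"].all()

    def test_maternal_split_is_near_binomial_half(self, quiet_colony):
        truth = quiet_colony.truth
        m1 = quiet_colony.queen[0].allele_id
        k = (truth["maternal_id"] == m1).sum()
        n = len(truth)
        assert abs(k - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_lethal_genotype_skews_patriline(self, allele_pool):
        """Zero viability for one maternal x paternal pair removes that
        maternal allele from the patriline entirely."""
        rng = np.random.default_rng(3)
        probe = c.ColonySimConfig(n_drones=4, allele_pool_size=30,
                                  n_workers=1, unique_drone_alleles=True,
                                  rng_seed=3)
        scout = c.simulate_colony(probe, allele_pool,
                                  np.random.default_rng(3))
        queen_a = scout.queen[0].allele_id
        target = scout.drones[0].allele_id
        cfg = c.ColonySimConfig(
            n_drones=4, allele_pool_size=30, n_workers=400,
            unique_drone_alleles=True, rng_seed=3,
            viability={frozenset((queen_a, target)): 0.0})
        col = c.simulate_colony(cfg, allele_pool, np.random.default_rng(3))
        truth = col.truth
        pat = truth[truth["paternal_id"] == target]
        survivors = pat[pat["survives"]]
        assert (survivors["maternal_id"] != queen_a).all()
        assert len(survivors) >= 16

    def test_queen_identical_drone_halves_patriline(self, allele_pool):
        """A drone carrying one queen allele fathers diploid males on half
        its conceptions; with the default zero viability its patriline
        survivorship is ~50%."""
        rng = np.random.default_rng(6)
        pool = allele_pool[:6]
        cfg = c.ColonySimConfig(n_drones=3, allele_pool_size=6,
                                n_workers=3000,
                                patriline_concentration=100.0, rng_seed=6)
        # force one drone to share the first queen allele
        col = None
        for seed in range(40):
            cand = c.simulate_colony(cfg, pool, np.random.default_rng(seed))
            shared = [d for d in cand.drones
                      if d.allele_id == cand.queen[0].allele_id]
            if shared:
                col = cand
                break
        assert col is not None, "no queen-identical drone drawn in 40 seeds"
        truth = col.truth
        shared_id = col.queen[0].allele_id
        pat = truth[truth["paternal_id"] == shared_id]
        rate = pat["survives"].mean()
        se = np.sqrt(0.25 / len(pat))
        assert abs(rate - 0.5) < 4 * se

    def test_pool_without_distinct_patterns_rejected(self, reference_allele):
        clone = c.CsdAllele("twin", reference_allele.amplicon_seq)
        other = c.CsdAllele("thrice", reference_allele.amplicon_seq)
        cfg = c.ColonySimConfig(n_drones=2, allele_pool_size=3, n_workers=10)
        with pytest.raises(ConfigError):
            c.simulate_colony(cfg, [reference_allele, clone, other],
                              np.random.default_rng(0))

    def test_viability_classes(self):
        cfg = c.ColonySimConfig(viability={frozenset(("a", "b")): 0.5})
        assert genotype_viability(cfg, "a", "a") == 0.0
        assert genotype_viability(cfg, "a", "b") == 0.5
        assert genotype_viability(cfg, "a", "c") == 1.0
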