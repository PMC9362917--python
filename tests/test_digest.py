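"""Unit and property tests for amplicon trimming, VspI digest, intron
splicing, translation and pattern-catalog construction."""

import random

import pytest
from hypothesis import given, strategies as st

import csdtrflp as c
from csdtrflp.digest import (
    brute_force_terminal_fragments,
    expand_iupac,
    revcomp,
)
from csdtrflp.errors import (
    AmbiguousSequence,
    CorruptOrf,
    IntronNotFound,
    NoRestrictionSite,
    PrimerNotFound,
)

FWD = "TATCGAGAAASATCGAAAGAACGAT"
REV = "ATTGAAATCCAAGGTCCCATTGGT"

nt = st.sampled_from("ACGT")
random_seq = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestExtractAmplicon:
    def test_embedded_amplicon_is_recovered_exactly(self):
        insert = "ACGT" * 10
        seq = "CCCC" + FWD.replace("S", "G") + insert + revcomp(REV) + "GGGG"
        amp = c.extract_amplicon(seq, FWD, REV)
        assert len(amp) == 25 + 40 + 24
        assert amp == FWD.replace("S", "G") + insert + revcomp(REV)

    def test_missing_reverse_primer_raises(self):
        seq = FWD.replace("S", "C") + "ACGT" * 10
        with pytest.raises(PrimerNotFound):
            c.extract_amplicon(seq, FWD, REV)

    @pytest.mark.parametrize("s_base", ["G", "C"])
    def test_degenerate_s_matches_both_expansions(self, s_base):
        # the forward primer's S position accepts G and C contexts with
        # identical trimming behaviour
        concrete = FWD.replace("S", s_base)
        seq = "TT" + concrete + "A" * 30 + revcomp(REV) + "TT"
        amp = c.extract_amplicon(seq, FWD, REV)
        assert amp.startswith(concrete)
        # brute-force oracle: search every plain expansion of the primer
        hits = [seq.find(p) for p in expand_iupac(FWD) if p in seq]
        assert hits == [2]

    @given(flank5=random_seq, flank3=random_seq)
    def test_embedding_identity_property(self, flank5, flank3):
        core = FWD.replace("S", "G") + "CATCATCAT" + revcomp(REV)
        seq = flank5 + core + flank3
        # flanks may accidentally recreate a primer; only the clean case
        # is asserted
        try:
            amp = c.extract_amplicon(seq, FWD, REV)
        except c.CsdTrflpError:
            return
        assert core in amp


class TestVspDigest:
    def test_single_site_cut_convention(self):
        # AT^TAAT: site at offset 2 cuts after position 3
        pat = c.vsp_digest("GGATTAATCC")
        assert pat.as_tuple() == (4, 6)

    def test_no_site_raises(self):
        with pytest.raises(NoRestrictionSite):
            c.vsp_digest("GGGGCCCC")

    def test_two_sites_keep_terminal_fragments_only(self):
        # cuts at 4 and 12 (AT^TAAT at offsets 2 and 10); the unlabelled
        # middle fragment [4, 12) is invisible to T-RFLP
        assert c.vsp_digest("GGATTAATCCATTAATGG").as_tuple() == (4, 6)

    def test_fragments_sum_to_length_for_single_site(self, allele_pool):
        for allele in allele_pool:
            pat = c.vsp_digest(allele.amplicon_seq)
            assert (pat.five_prime_len + pat.three_prime_len
                    == len(allele.amplicon_seq))

    def test_ambiguous_base_near_site_rejected(self):
        # N could complete ATTAAT -> pattern undefined
        with pytest.raises(AmbiguousSequence):
            c.vsp_digest("GGATTAATCCATTANT")

    def test_ambiguous_base_in_flank_tolerated(self):
        pat = c.vsp_digest("GGGNGGATTAATCC")
        assert pat.as_tuple() == (8, 6)

    def test_matches_brute_force_scan_on_random_sequences(self):
        rng = random.Random(42)
        checked = 0
        for _ in range(1000):
            # A/T-rich alphabet so ATTAAT sites actually occur
            seq = "".join(rng.choice("AATTACGT")
                          for _ in range(rng.randint(6, 120)))
            try:
                expected = brute_force_terminal_fragments(seq)
            except NoRestrictionSite:
                with pytest.raises(NoRestrictionSite):
                    c.vsp_digest(seq)
                continue
            assert c.vsp_digest(seq).as_tuple() == expected
            checked += 1
        assert checked > 50  # random 6-mers do occur


class TestSpliceIntron:
    def test_explicit_coordinates(self):
        exon7, exon8 = "ATGAAA", "CCCGGG"
        intron = "GT" + "A" * 20 + "AG"
        seq = exon7 + intron + exon8
        assert c.splice_intron(seq, "explicit", coords=(6, 6 + len(intron))) \
            == exon7 + exon8

    def test_canonical_matches_explicit_on_template(self, template):
        amp = template.amplicon
        s, e = template.intron_coords
        explicit = c.splice_intron(amp, "explicit", coords=(s, e))
        canonical = c.splice_intron(
            amp, "canonical", search_start=(s - 5, s + 5),
            length_bounds=(e - s - 5, e - s + 5))
        assert canonical == explicit == template.cds

    def test_reference_guided_matches_explicit(self, template):
        spliced = c.splice_intron(
            template.amplicon, "reference",
            exon_template=(template.exon7, template.exon8))
        assert spliced == template.cds

    def test_intronless_input_raises(self):
        with pytest.raises(IntronNotFound):
            c.splice_intron("ATGAAACCCGGG", "canonical",
                            length_bounds=(10, 50))


def _oracle_translate(cds, offset=0):
    table = {}
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
           "VVVVAAAADDEEGGGG")
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            for k, d in enumerate(bases):
                table[a + b + d] = aas[16 * i + 4 * j + k]
    out = []
    s = cds[offset:]
    for i in range(0, len(s) - len(s) % 3, 3):
        out.append(table[s[i:i + 3]])
    return "".join(out)


class TestTranslateAndValidate:
    def test_terminal_stop_tolerated(self):
        assert c.translate_and_validate("ATGAAATAA") == "MK"

    def test_internal_stop_raises(self):
        with pytest.raises(CorruptOrf):
            c.translate_and_validate("ATGTAAAAA")

    def test_matches_codon_table_oracle_on_random_orf(self):
        rng = random.Random(7)
        non_stop = [a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"
                    if a + b + d not in ("TAA", "TAG", "TGA")]
        cds = "".join(rng.choice(non_stop) for _ in range(100))
        for offset in (0,):
            assert c.translate_and_validate(cds, offset) \
                == _oracle_translate(cds, offset)

    def test_trailing_partial_codon_dropped(self):
        assert c.translate_and_validate("ATGAAATA") == "MK"


class TestPatternCatalog:
    def test_synonymous_substitution_shares_pattern_id(self, template):
        a = c.make_allele(template, [], "a")
        # TCG -> TCA is synonymous (Ser) and off-site: same fragment pair
        b = c.make_allele(template, [("rs_sub", 1, "TCA")], "b")
        cat = c.build_pattern_catalog([a, b])
        assert cat.pattern_id_of("a") == cat.pattern_id_of("b")

    def test_distinct_hvr_lengths_give_distinct_patterns(self, template):
        from dataclasses import replace
        alleles = [
            c.make_allele(replace(template,
                                  hvr_units=("TAT", "AAT") * (6 + k)),
                          [], f"h{k}")
            for k in range(10)]
        cat = c.build_pattern_catalog(alleles)
        assert cat.n_alleles == cat.n_patterns == 10
        # brute-force confirmation that 5' lengths all differ
        fives = {brute_force_terminal_fragments(a.amplicon_seq)[0]
                 for a in alleles}
        assert len(fives) == 10

    def test_exact_duplicates_are_excluded(self, template):
        a = c.make_allele(template, [], "a")
        b = c.make_allele(template, [], "b")
        cat = c.build_pattern_catalog([a, b])
        assert cat.n_alleles == 1
        assert cat.duplicates == {"b": "a"}

    def test_permutation_invariance(self, allele_pool):
        cat1 = c.build_pattern_catalog(allele_pool)
        cat2 = c.build_pattern_catalog(list(reversed(allele_pool)))
        assert cat1.pattern_ids == cat2.pattern_ids
        assert {a: cat1.pattern_id_of(a) for a in cat1.patterns} \
            == {a: cat2.pattern_id_of(a) for a in cat2.patterns}

    def test_digest_failures_collected_not_raised(self, reference_allele):
        broken = c.CsdAllele("nosite", "ACGT" * 30)
        cat = c.build_pattern_catalog([reference_allele, broken])
        assert cat.n_alleles == 1
        assert "nosite" in cat.rejects
        assert not cat.rejects_frame().empty

    def test_patterns_never_outnumber_alleles(self, allele_pool):
        cat = c.build_pattern_catalog(allele_pool)
        assert cat.n_patterns <= cat.n_alleles
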