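# Published reference datasets (user-supplied)

Some checks in `tests/test_acceptance.py` evaluate this package against the
published datasets that accompany the original colony survey.  Those
datasets are not redistributable here; to run the checks, convert them to
the plain-text formats below and drop them in this directory.

- `reference_alleles.fasta` — the public-database csd amplicon catalog
  (151 distinct primer-flanked genomic records, intron included; record id
  = allele id).
- `study_alleles.fasta` — the maternal and paternal amplicon sequences
  identified in the surveyed colonies, with ids such as `mA`, `mB`, `p29`,
  `p66`.
- `patriline_summary.tsv` — per-patriline maternal-allele counts, columns:
  `colony_id`, `paternal_allele_id`, `maternal_allele_id` (of maternal 1),
  `count_maternal_1`, `count_maternal_2`.

Without these files the corresponding acceptance tests fail with a pointer
to this note; everything else in the package runs on synthetic data.
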