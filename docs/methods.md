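# Methods

This note documents the models, conventions and numerical choices behind
`csdtrflp`, and what the synthetic-data tests do and do not establish about
real colony data.

## In-silico digest and pattern identity

An allele is represented by its primer-inclusive amplicon (forward primer
start through the reverse-primer binding end on the forward strand). The
fluorophores ride on the primers, so primer-inclusive lengths are the
quantity comparable to capillary-electrophoresis sizes. VspI recognises
ATTAAT and cleaves AT^TAAT; fragment lengths are measured to that cut on
the labelled strand. With more than one site only the terminal fragments
are reported, because interior fragments carry no label and are invisible
to T-RFLP. For a single-site amplicon ℓ₅′ + ℓ₃′ equals the amplicon length
— an invariant the test suite enforces and cross-checks against a
brute-force substring scan.

Degenerate IUPAC codes are tolerated in amplicon flanks but rejected
whenever an ambiguous base could create or destroy an ATTAAT match, since
the pattern would then be undefined. Primer matching honours IUPAC
degeneracy on both primers (the forward primer used in this assay carries
an S = G/C position); the reverse primer is matched via its reverse
complement on the forward strand.

Intron removal between exons 7 and 8 supports three locating strategies:
explicit coordinates (synthetic data and curated records), canonical
GT…AG search within configurable donor-position and length bounds, and
reference-guided anchoring on exon-template flanks. The canonical search
additionally discards candidates whose removal leaves an internal stop
codon (the spliced product must be an open reading frame); if several
candidates survive at the 5′-most donor the call is refused as ambiguous
rather than guessed. Translation uses the standard code with the reading
frame anchored so the forward primer starts on a codon boundary (a shipped
constant, overridable for sequence sets anchored differently); a single
terminal stop is tolerated, an internal stop rejects the record as a
corrupted open reading frame.

Catalogs deduplicate by exact amplicon nucleotide identity (first record
kept) and assign pattern ids to distinct (ℓ₅′, ℓ₃′) pairs sorted
ascending, which makes ids independent of input order.

## Virtual spermatheca

Subsets of 80 distinct records are drawn without replacement from the
catalog; spermathecas of size k are drawn with replacement from the
subset, uniformly — the experiment deliberately ignores real-world allele
frequency skew. All draws come from one seeded NumPy generator in a fixed
order (per size, per subset, per repetition), so a seed reproduces the
table bit-for-bit. Means are pooled over all subsets × repetitions (10 ×
10 by default); the closed form for the expected number of distinct draws,
n(1 − (1 − 1/n)^k), is exposed for analytic cross-checking. Formatted
tables round to one decimal; machine outputs keep full precision. The
distinct-pattern column depends on the catalog's pattern-sharing
structure, so its published value is only reproducible on the original
catalog, not on synthetic ones.

## Worker calling and patrilines

A maternal pattern "explains" an observation when its 5′ length matches a
HEX peak and its 3′ length a FAM peak within tolerance (default ±1 nt for
measured data, 0 for in-silico data). The paternal pattern is assembled
from the unexplained residual peaks, reusing the maternal coordinate on a
channel with no residual (the paternal allele may share one fragment
length with the mother). Failure modes are statuses, not exceptions:

- *ambiguous_maternal* — both maternal patterns explain the peaks;
- *homozygous_pattern* — no residual at all (paternal indistinguishable
  from the maternal pattern);
- *inconsistent* — neither maternal pattern explains the peaks.

Only unambiguous (*ok*) calls enter patriline counts. Excluding the other
statuses is the one policy that cannot bias the 0.5/0.5 segregation test:
an ambiguous worker assigned by any tie-break rule would inject that
rule's bias into the maternal counts.

Observed patterns are canonicalised by single-linkage clustering per
coordinate within the tolerance, because peak-size jitter is per-fragment.
A class spanning more than twice the tolerance triggers a warning (chained
jitter may have merged genuinely distinct alleles), as does a patriline
more than twice the median size (possibly two drones sharing a pattern —
indistinguishable in this method, so the group is not split). Patrilines
below 16 workers are excluded from testing; 16 is the design constant from
which the 240-worker sampling target derives (15 assumed drones × 16).

## Segregation testing

Each included patriline is tested with the Pearson chi-squared
goodness-of-fit statistic against equal expected counts — (a−b)²/(a+b)
with 1 df, no continuity correction (Yates' correction would be a
different named test) — and p-values are Bonferroni-adjusted within the
colony (m = number of patrilines tested in that colony, adjusted
p = min(1, m·p)), flagged at adjusted p < 0.1. A validity caveat is
carried whenever an expected count falls below 5. The Monte-Carlo
`power_estimate` quantifies detectability: surviving workers carry the
disfavoured maternal allele with probability s/(1+s) for relative
viability s, and power is the flagged fraction after Bonferroni. At the
minimum patriline size of 16, full lethality (s = 0) is detected
essentially always, while s = 0.5 gives modest power — the reason roughly
half of real patrilines are too small to inform the test.

## PSD difference metrics

The HVR cannot be aligned reliably, so a genotype is characterised by
d_HVR (absolute HVR length difference in residues) and the number of
differences outside the HVR. The pre- and post-HVR flanks are aligned
globally and independently with identity scoring and affine gaps (match
+1, mismatch 0, gap open −10, gap extend −0.5; fixed, documented,
configurable); d_outside counts substituted columns plus gapped columns,
i.e. indels count per residue — a 3-residue indel contributes 3. A
best-effort HVR alignment yields the substitution count d_hvr_mismatch,
reported but treated as low-confidence and excluded from the
two-parameter summary. The total is d_PSD = d_HVR + d_hvr_mismatch +
d_outside. The exon-8 term d_e8 is computed over the exon-8-encoded
suffixes when annotation provides the boundary; without annotation the
three-clause rule returns *indeterminate* rather than guessing.

HVR delimitation is either *annotated* (simulator ground truth or curated
coordinates — preferred for reproducing published counts) or *motif*: the
window of ≥8 residues with tyrosine+asparagine fraction above 0.5 that
maximises the Y/N excess (#Y/N − #other), shortest then leftmost on ties.
The excess criterion, rather than raw window length, keeps the window
from bleeding into flanks that dilute but do not break the threshold.

Both heterozygosity rules are evaluated as published; note that they are
descriptive screens — a fully functional genotype differing by a single
asparagine indel fails both, which is precisely why the workflow reports
the underlying metrics and not just the verdicts.

## Synthetic data

The generator emulates the sequence features the digest relies on, not the
honey-bee genome: an amplicon of
`fwd-primer · RS-rich codons · (TAT|AAT)* HVR · ATTAAT spacer · GT…AG
intron · (TTCCTG|TTCCTA)* proline region · rev-primer site`, in frame 0
throughout, with exactly one VspI site. The HVR codons TAT/AAT translate
to the tyrosine/asparagine-rich peptide and reproduce the TAT/TAA
nucleotide repeat structure; HVR length differences propagate to ℓ₅′ and
proline-repeat differences to ℓ₃′, as at the real locus. Edits
(repeat-unit indels, codon substitutions) are validated to keep the
reading frame open and the site count at one, and every allele carries
ground-truth HVR, exon and intron coordinates plus its edit list.

Colonies follow the workflow's stated design point by default: 15 drones,
240 workers, minimum patriline 16. Patriline skew uses a symmetric
Dirichlet over drones (concentration 1 by default — substantial natural
skew; large values approach equal contributions). Workers are
*conceptions*: each draws a drone by weight and a maternal allele
uniformly, then survives with a genotype-class viability (keyed by the
unordered allele-id pair; identical-allele genotypes are diploid males
with default viability 0). Only survivors yield observations, since the
real assay genotypes surviving pupae. Peak noise is integer-rounded
Gaussian jitter per fragment.

What the generator does *not* emulate: real allele-frequency skew across
populations, PCR artefacts and stutter, partial digestion, pull-up peaks
and size-standard miscalibration, and sequence heterogeneity of the
conserved spacer. Passing tests therefore establish the correctness of
the algorithms under the assay's idealised assumptions, not the wet-lab
error profile; the tolerance and canonicalisation machinery is exercised
with synthetic Gaussian jitter only.

## Problem sizes and determinism

The test suite and the acceptance script are sized to run in well under a
minute on one CPU: 100-simulation spermatheca experiments (matching the
published design), 151-allele synthetic catalogs, colonies of 240–400
workers, 40-colony flag-rate experiments and 10⁴-replicate Monte-Carlo
checks. Every stochastic component takes an explicit seed (NumPy
`default_rng`), and pipeline runs write a manifest containing a
config-content hash (excluding the output directory), the seed, and
per-stage counts; identical config + inputs + seed reproduce byte-identical
outputs.

## Known limitations

- Pattern collisions: distinct paternal alleles sharing a restriction
  pattern are merged into one patriline; the workflow flags size outliers
  but cannot split them.
- The motif HVR delimiter is a heuristic stand-in; annotated coordinates
  are preferred wherever available.
- The chi-squared test is asymptotic; at the minimum patriline size its
  small-count caveat fires only for extreme splits, but exact tests are
  deliberately out of scope (the published analysis uses Pearson's test).
- d_hvr_mismatch depends on a heuristic alignment of an explicitly
  alignment-hostile region and should be read qualitatively.
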