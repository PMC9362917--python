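"""In-silico VspI terminal restriction digest of csd amplicons.

The potential-specifying domain (PSD) of the honey-bee *csd* gene is amplified
with end-labelled primers (HEX on the forward, 6-FAM on the reverse primer) and
cut with VspI, whose recognition site ATTAAT sits in a conserved spacer between
the hypervariable region (HVR) and the proline-rich repeats.  Because only the
end-labelled fragments are detected, an allele is characterised by the pair of
terminal fragment lengths — its restriction pattern.

This module turns raw amplicon nucleotide sequences into validated
:class:`CsdAllele` records and :class:`RestrictionPattern` pairs:

* degenerate-primer trimming (:func:`extract_amplicon`),
* intron removal between exons 7 and 8 (:func:`splice_intron`),
* translation with open-reading-frame validation (:func:`translate_and_validate`),
* the digest itself (:func:`vsp_digest`) and catalog construction
  (:func:`build_pattern_catalog`).

Conventions (fixed, documented, overridable where noted):

* VspI cleaves AT^TAAT; fragment lengths are measured to the cut.
* With multiple sites only the terminal fragments are reported — middle
  fragments carry no label and are invisible to T-RFLP.
* Fragment lengths are primer-inclusive, so in-silico lengths are comparable
  to electrophoresis sizes (the fluorophores ride on the primers).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd
from Bio.Seq import Seq

from .errors import (
    AmbiguousIntron,
    AmbiguousSequence,
    CorruptOrf,
    IntronNotFound,
    MultipleAmplicons,
    NoRestrictionSite,
    PrimerNotFound,
)

VSPI_SITE = "ATTAAT"
#: Offset of the cut within the recognition site: AT^TAAT.
VSPI_CUT_OFFSET = 2

#: HEX-labelled forward primer (csdF2) and 6-FAM-labelled reverse primer
#: (csdR2) used for the csd-PSD amplicon; lowercase IUPAC codes as published.
CSD_F2 = "TATCGAGAAASATCGAAAGAACGAT"
CSD_R2 = "ATTGAAATCCAAGGTCCCATTGGT"

#: Frame offset anchoring the csdF2 primer start to codon boundaries.  The
#: synthetic templates shipped with this package place the primer on a codon
#: boundary; override for sequence sets anchored differently.
DEFAULT_FRAME_OFFSET = 0

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement honouring IUPAC degeneracy codes."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_regex(primer: str) -> re.Pattern[str]:
    """Compile a degenerate primer into a character-class regex."""
    parts = []
    for base in primer.upper():
        try:
            expansion = IUPAC[base]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {base!r}")
        parts.append(expansion if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class RestrictionPattern:
    """Terminal VspI fragment pair identifying an allele class.

    ``five_prime_len`` is the HEX-labelled (forward) fragment,
    ``three_prime_len`` the 6-FAM-labelled (reverse) fragment, both in
    nucleotides and primer-inclusive.  Equality is exact; matching against
    measured peaks uses a tolerance (see :mod:`csdtrflp.genotyping`).
    """

    five_prime_len: int
    three_prime_len: int

    def __post_init__(self) -> None:
        if self.five_prime_len < 1 or self.three_prime_len < 1:
            raise ValueError("fragment lengths must be >= 1 nt")

    def as_tuple(self) -> tuple[int, int]:
        return (self.five_prime_len, self.three_prime_len)


@dataclass
class CsdAllele:
    """One csd amplicon with its derived coding sequence and protein.

    ``hvr_span`` is a half-open ``(start, end)`` interval in protein
    coordinates delimiting the hypervariable region; it may be ``None`` when
    no annotation is available (motif detection lives in :mod:`csdtrflp.psd`).
    """

    allele_id: str
    amplicon_seq: str
    cds_seq: str | None = None
    psd_protein: str | None = None
    hvr_span: tuple[int, int] | None = None
    source_tag: Literal["maternal", "paternal", "reference"] = "reference"
    exon8_protein_start: int | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplicon_seq = self.amplicon_seq.upper()
        bad = set(self.amplicon_seq) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letters in amplicon: {sorted(bad)}")
        if self.hvr_span is not None and self.psd_protein is not None:
            s, e = self.hvr_span
            if not (0 <= s < e <= len(self.psd_protein)):
                raise ValueError(f"HVR span {self.hvr_span} outside protein")

    @property
    def pattern(self) -> RestrictionPattern:
        return vsp_digest(self.amplicon_seq)


def extract_amplicon(seq: str, fwd_primer: str = CSD_F2,
                     rev_primer: str = CSD_R2) -> str:
    """Trim a genomic record to the primer-inclusive amplicon.

    Both primers are given 5'->3'; the reverse primer is matched against the
    reverse strand, i.e. its reverse complement is searched on the forward
    strand downstream of the forward-primer match.  IUPAC degeneracy is
    honoured in both primers and treated as a literal wildcard in the target.

    Raises
    ------
    PrimerNotFound
        if either primer has no match.
    MultipleAmplicons
        if more than one non-overlapping forward/reverse pairing exists.
    """
    seq = seq.upper()
    fwd_re = iupac_regex(fwd_primer)
    rev_re = iupac_regex(revcomp(rev_primer))
    fwd_hits = [m.start() for m in fwd_re.finditer(seq)]
    rev_hits = [m.end() for m in rev_re.finditer(seq)]
    if not fwd_hits:
        raise PrimerNotFound("forward primer has no match")
    if not rev_hits:
        raise PrimerNotFound("reverse primer has no match")
    pairings = [(f, r) for f in fwd_hits for r in rev_hits
                if r - f >= len(fwd_primer) + len(rev_primer)]
    if not pairings:
        raise PrimerNotFound("primers found but never in amplifiable order")
    if len(pairings) > 1:
        # Nested pairings describe the same outermost product only when they
        # share an endpoint; disjoint alternatives are genuinely ambiguous.
        starts = {f for f, _ in pairings}
        ends = {r for _, r in pairings}
        if len(starts) > 1 and len(ends) > 1:
            raise MultipleAmplicons(f"{len(pairings)} primer pairings found")
        # keep the outermost (longest) product
    f, r = min(pairings, key=lambda p: (p[0], -p[1]))
    return seq[f:r]


def vsp_digest(amplicon: str) -> RestrictionPattern:
    """Locate ATTAAT sites and return the terminal fragment lengths.

    The cut is placed between positions 2 and 3 of the site (AT^TAAT).  The
    5' fragment runs from the amplicon start to the cut of the 5'-most site;
    the 3' fragment from the cut of the 3'-most site to the amplicon end.
    Middle fragments, if any, are unlabelled and discarded.

    Raises
    ------
    NoRestrictionSite
        if ATTAAT is absent.
    AmbiguousSequence
        if degenerate bases could create or destroy a site.
    """
    amplicon = amplicon.upper()
    certain = [m.start() for m in re.finditer(f"(?={VSPI_SITE})", amplicon)]
    if set(amplicon) - {"A", "C", "G", "T"}:
        possible = []
        for i in range(len(amplicon) - len(VSPI_SITE) + 1):
            window = amplicon[i:i + len(VSPI_SITE)]
            if all(set(IUPAC[b]) & set(IUPAC[s])
                   for b, s in zip(window, VSPI_SITE)):
                possible.append(i)
        if possible != certain:
            raise AmbiguousSequence(
                "degenerate bases overlap a potential ATTAAT site")
    if not certain:
        raise NoRestrictionSite("no ATTAAT site in amplicon")
    five = certain[0] + VSPI_CUT_OFFSET
    three = len(amplicon) - (certain[-1] + VSPI_CUT_OFFSET)
    return RestrictionPattern(five, three)


IntronStrategy = Literal["explicit", "canonical", "reference"]


def splice_intron(
    amplicon: str,
    strategy: IntronStrategy = "canonical",
    *,
    coords: tuple[int, int] | None = None,
    search_start: tuple[int, int] | None = None,
    length_bounds: tuple[int, int] = (30, 2000),
    exon_template: tuple[str, str] | None = None,
    frame_offset: int = DEFAULT_FRAME_OFFSET,
    require_open_orf: bool = True,
) -> str:
    """Remove the intron between exons 7 and 8, returning the exonic sequence.

    Strategies
    ----------
    explicit
        ``coords=(start, end)`` half-open intron coordinates (synthetic data
        and curated records).
    canonical
        searches for GT...AG donor/acceptor pairs with the donor inside
        ``search_start`` (half-open amplicon interval; whole amplicon when
        ``None``) and intron length within ``length_bounds``.  When
        ``require_open_orf`` is set, candidates whose removal leaves an
        internal stop codon are discarded first.  Exactly one surviving
        candidate is required.
    reference
        ``exon_template=(exon7, exon8)``: the intron is the segment between
        the end of the exon7 prefix and the start of the exon8 suffix shared
        with the template (anchored exact match of the template flanks).

    Raises
    ------
    IntronNotFound, AmbiguousIntron
    """
    amplicon = amplicon.upper()
    if strategy == "explicit":
        if coords is None:
            raise ValueError("explicit strategy requires coords")
        s, e = coords
        if not (0 <= s < e <= len(amplicon)):
            raise ValueError(f"intron coords {coords} outside amplicon")
        return amplicon[:s] + amplicon[e:]

    if strategy == "reference":
        if exon_template is None:
            raise ValueError("reference strategy requires exon_template")
        exon7, exon8 = (t.upper() for t in exon_template)
        # anchor on the terminal 12 nt of exon7 / initial 12 nt of exon8
        left, right = exon7[-12:], exon8[:12]
        i = amplicon.find(left)
        if i < 0:
            raise IntronNotFound("exon7 anchor not found")
        j = amplicon.find(right, i + len(left))
        if j < 0:
            raise IntronNotFound("exon8 anchor not found")
        return amplicon[:i + len(left)] + amplicon[j:]

    if strategy != "canonical":
        raise ValueError(f"unknown intron strategy: {strategy!r}")

    lo, hi = search_start if search_start is not None else (0, len(amplicon))
    donors = [i for i in range(lo, min(hi, len(amplicon) - 1))
              if amplicon[i:i + 2] == "GT"]
    lmin, lmax = length_bounds
    candidates: list[tuple[int, int]] = []
    for i in donors:
        for j in range(i + lmin, min(i + lmax, len(amplicon)) + 1):
            if amplicon[j - 2:j] == "AG":
                candidates.append((i, j))
    if require_open_orf:
        open_orf = []
        for i, j in candidates:
            spliced = amplicon[:i] + amplicon[j:]
            try:
                translate_and_validate(spliced, frame_offset)
            except CorruptOrf:
                continue
            open_orf.append((i, j))
        candidates = open_orf
    if not candidates:
        raise IntronNotFound("no GT...AG candidate within bounds")
    # 5'-most donor wins; several acceptors for that donor are ambiguous
    best_donor = min(i for i, _ in candidates)
    at_donor = [c for c in candidates if c[0] == best_donor]
    if len(at_donor) > 1:
        raise AmbiguousIntron(
            f"{len(at_donor)} acceptor candidates for donor at {best_donor}")
    i, j = at_donor[0]
    return amplicon[:i] + amplicon[j:]


def translate_and_validate(cds: str, frame_offset: int = DEFAULT_FRAME_OFFSET,
                           ) -> str:
    """Translate ``cds`` from ``frame_offset`` with the standard genetic code.

    A trailing partial codon is dropped and a single terminal stop is
    tolerated; any internal stop raises :class:`CorruptOrf` (such records are
    excluded from catalogs as corrupted open reading frames).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    trimmed = cds.upper()[frame_offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    protein = str(Seq(trimmed).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise CorruptOrf(
            f"internal stop codon at residue {protein.index('*')}")
    return protein


@dataclass
class PatternCatalog:
    """Deduplicated alleles with their VspI patterns and pattern-class ids.

    Pattern ids ``P001, P002, ...`` are assigned to distinct fragment pairs
    sorted ascending by (5' length, 3' length) — a documented ordering rule
    that makes the catalog invariant to input order.
    """

    alleles: dict[str, CsdAllele]
    patterns: dict[str, RestrictionPattern]          # allele_id -> pattern
    pattern_ids: dict[tuple[int, int], str]          # fragment pair -> Pxxx
    rejects: dict[str, str]                          # allele_id -> reason
    duplicates: dict[str, str]                       # dropped id -> kept id

    @property
    def n_alleles(self) -> int:
        return len(self.patterns)

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_ids)

    def pattern_id_of(self, allele_id: str) -> str:
        return self.pattern_ids[self.patterns[allele_id].as_tuple()]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aid, pat in self.patterns.items():
            rows.append({
                "allele_id": aid,
                "pattern_id": self.pattern_id_of(aid),
                "five_prime_len": pat.five_prime_len,
                "three_prime_len": pat.three_prime_len,
                "amplicon_len": len(self.alleles[aid].amplicon_seq),
                "status": "ok",
            })
        return pd.DataFrame(
            rows, columns=["allele_id", "pattern_id", "five_prime_len",
                           "three_prime_len", "amplicon_len", "status"])

    def rejects_frame(self) -> pd.DataFrame:
        rows = [{"allele_id": aid, "reason": why}
                for aid, why in self.rejects.items()]
        rows += [{"allele_id": aid, "reason": f"duplicate of {kept}"}
                 for aid, kept in self.duplicates.items()]
        return pd.DataFrame(rows, columns=["allele_id", "reason"])


def build_pattern_catalog(alleles: Iterable[CsdAllele]) -> PatternCatalog:
    """Digest every allele and assign pattern-class ids.

    Alleles are deduplicated by exact amplicon nucleotide identity (first
    record of each sequence is kept).  Digest failures do not abort the
    catalog; they are collected in the rejects report with their reason.
    """
    kept: dict[str, CsdAllele] = {}
    seen_seq: dict[str, str] = {}
    duplicates: dict[str, str] = {}
    rejects: dict[str, str] = {}
    for allele in alleles:
        if allele.allele_id in kept or allele.allele_id in rejects:
            raise ValueError(f"duplicate allele id {allele.allele_id!r}")
        prior = seen_seq.get(allele.amplicon_seq)
        if prior is not None:
            duplicates[allele.allele_id] = prior
            continue
        seen_seq[allele.amplicon_seq] = allele.allele_id
        kept[allele.allele_id] = allele

    patterns: dict[str, RestrictionPattern] = {}
    for aid, allele in list(kept.items()):
        try:
            patterns[aid] = vsp_digest(allele.amplicon_seq)
        except (NoRestrictionSite, AmbiguousSequence) as exc:
            rejects[aid] = f"{type(exc).__name__}: {exc}"
            del kept[aid]

    distinct = sorted({p.as_tuple() for p in patterns.values()})
    width = max(3, len(str(len(distinct))))
    pattern_ids = {pair: f"P{idx + 1:0{width}d}"
                   for idx, pair in enumerate(distinct)}
    return PatternCatalog(kept, patterns, pattern_ids, rejects, duplicates)


def brute_force_terminal_fragments(amplicon: str) -> tuple[int, int]:
    """Independent oracle: scan every substring for the VspI site.

    Enumerates all positions i with amplicon[i:i+6] == ATTAAT by explicit
    substring comparison and derives terminal fragment lengths from the
    extreme cut positions.  Used in tests to cross-check :func:`vsp_digest`.
    """
    amplicon = amplicon.upper()
    sites = [i for i in range(len(amplicon))
             if amplicon[i:i + 6] == VSPI_SITE]
    if not sites:
        raise NoRestrictionSite("no site (oracle)")
    cuts = [i + VSPI_CUT_OFFSET for i in sites]
    return (min(cuts), len(amplicon) - max(cuts))


def expand_iupac(primer: str, limit: int = 4096) -> list[str]:
    """Enumerate all plain-ACGT expansions of a degenerate primer."""
    pools = [IUPAC[b] for b in primer.upper()]
    n = 1
    for p in pools:
        n *= len(p)
        if n > limit:
            raise ValueError("too many expansions")
    return ["".join(t) for t in itertools.product(*pools)]
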