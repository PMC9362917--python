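"""Amino-acid difference metrics between the two csd-PSD sequences of a
genotype, and published functional-heterozygosity criteria.

The hypervariable region (HVR) is microsatellite-like and cannot be aligned
reliably, so a genotype is characterised by

* ``d_hvr_len`` — the absolute difference in HVR length (residues), and
* ``d_outside`` — substitutions plus per-residue indels in the flanking
  RS-rich and proline-rich fragments, obtained from global alignment of the
  flanks only.

A best-effort HVR alignment also yields ``d_hvr_mismatch`` (substitutions
inside the HVR), reported but flagged low-confidence.  The total
``d_psd = d_hvr_len + d_hvr_mismatch + d_outside`` feeds two published
rules for functional heterozygosity:

* Lechner rule:  d_HVR >= 6  and  d_PSD >= 1  and  3*d_PSD + 2*d_e8 >= 9,
  where d_e8 counts differences in the exon-8-encoded part;
* Beye rule:  at least 5 amino-acid differences including length variation
  in the csd-PSD.

Both rules are descriptive screens, not oracles — fully functional genotypes
violating them exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .errors import HvrNotFound

#: Fraction of tyrosine+asparagine needed for a window to qualify as HVR.
HVR_YN_THRESHOLD = 0.5
HVR_MIN_WINDOW = 8

#: Identity scoring with affine gaps for flank alignment.  Values are fixed
#: and documented; override via ``make_flank_aligner``.
FLANK_MATCH = 1.0
FLANK_MISMATCH = 0.0
FLANK_GAP_OPEN = -10.0
FLANK_GAP_EXTEND = -0.5


def make_flank_aligner(match: float = FLANK_MATCH,
                       mismatch: float = FLANK_MISMATCH,
                       gap_open: float = FLANK_GAP_OPEN,
                       gap_extend: float = FLANK_GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class GenotypeDiff:
    """Difference metrics between two csd-PSD sequences (symmetric)."""

    d_hvr_len: int
    d_hvr_mismatch: int
    d_outside: int
    d_e8: int | None = None

    def __post_init__(self) -> None:
        for name in ("d_hvr_len", "d_hvr_mismatch", "d_outside"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d_e8 is not None and self.d_e8 > self.d_psd:
            raise ValueError("d_e8 cannot exceed d_psd")

    @property
    def d_psd(self) -> int:
        """Total per-residue amino-acid differences in the analysed PSD."""
        return self.d_hvr_len + self.d_hvr_mismatch + self.d_outside


@dataclass
class CriteriaVerdict:
    """Deterministic evaluation of the published heterozygosity rules.

    ``lechner_pass`` is ``None`` (indeterminate) when the rule's exon-8 term
    cannot be evaluated for lack of annotation.
    """

    lechner_pass: bool | None
    beye_pass: bool
    notes: str = ""


def delimit_hvr(psd: str,
                strategy: Literal["annotated", "motif"] = "motif",
                *,
                coords: tuple[int, int] | None = None,
                yn_threshold: float = HVR_YN_THRESHOLD,
                min_window: int = HVR_MIN_WINDOW) -> tuple[int, int]:
    """Return the half-open HVR interval in protein coordinates.

    ``annotated`` uses provided ``coords`` (simulator ground truth or a
    curated reference).  ``motif`` scans every window of at least
    ``min_window`` residues whose tyrosine+asparagine fraction exceeds
    ``yn_threshold`` and returns the one maximising the Y/N excess
    (#Y/N − #other, so flank residues are penalised); ties go to the
    shortest, then leftmost, window — this recovers a clean repeat block
    without bleeding into the flanks.
    """
    if strategy == "annotated":
        if coords is None:
            raise ValueError("annotated strategy requires coords")
        s, e = coords
        if not (0 <= s < e <= len(psd)):
            raise ValueError(f"HVR coords {coords} outside protein")
        return (s, e)
    if strategy != "motif":
        raise ValueError(f"unknown HVR strategy: {strategy!r}")

    n = len(psd)
    is_yn = np.fromiter((c in "YN" for c in psd), dtype=float, count=n)
    cum = np.concatenate([[0.0], np.cumsum(is_yn)])
    best: tuple[int, int] | None = None
    best_key: tuple[float, int, int] | None = None
    for length in range(min_window, n + 1):
        for start in range(0, n - length + 1):
            yn = cum[start + length] - cum[start]
            if yn / length <= yn_threshold:
                continue
            excess = yn - (length - yn)
            key = (-excess, length, start)
            if best_key is None or key < best_key:
                best_key = key
                best = (start, start + length)
    if best is None:
        raise HvrNotFound(
            f"no Y/N-rich window (>= {min_window} aa, fraction > "
            f"{yn_threshold}) found")
    return best


def _aligned_rows(a: str, b: str,
                  aligner: Align.PairwiseAligner) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _count_columns(row_a: str, row_b: str) -> tuple[int, int]:
    """(substitution columns, gap columns) of a pairwise alignment."""
    subs = sum(1 for x, y in zip(row_a, row_b)
               if x != "-" and y != "-" and x != y)
    gaps = sum(1 for x, y in zip(row_a, row_b) if x == "-" or y == "-")
    return subs, gaps


def diff_metrics(psd_a: str, psd_b: str,
                 hvr_a: tuple[int, int], hvr_b: tuple[int, int],
                 *,
                 e8_start_a: int | None = None,
                 e8_start_b: int | None = None,
                 aligner: Align.PairwiseAligner | None = None) -> GenotypeDiff:
    """Compute the difference metrics between two PSD sequences.

    The pre-HVR and post-HVR flanks are aligned globally and independently
    (identity scoring, affine gaps); ``d_outside`` counts substituted columns
    plus gapped columns, so a 3-residue indel contributes 3.  The HVRs are
    aligned best-effort for ``d_hvr_mismatch`` (substitution columns only —
    their length difference is already ``d_hvr_len``).  When both exon-8
    protein start coordinates are given, ``d_e8`` counts substitutions plus
    per-residue indels over the aligned exon-8-encoded suffixes.
    """
    aligner = aligner or make_flank_aligner()
    (sa, ea), (sb, eb) = hvr_a, hvr_b
    d_hvr_len = abs((ea - sa) - (eb - sb))

    pre = _aligned_rows(psd_a[:sa], psd_b[:sb], aligner)
    post = _aligned_rows(psd_a[ea:], psd_b[eb:], aligner)
    d_outside = sum(sum(_count_columns(*rows)) for rows in (pre, post))

    hvr_rows = _aligned_rows(psd_a[sa:ea], psd_b[sb:eb], aligner)
    d_hvr_mismatch = _count_columns(*hvr_rows)[0]

    d_e8: int | None = None
    if e8_start_a is not None and e8_start_b is not None:
        rows = _aligned_rows(psd_a[e8_start_a:], psd_b[e8_start_b:], aligner)
        d_e8 = sum(_count_columns(*rows))
    return GenotypeDiff(d_hvr_len=d_hvr_len, d_hvr_mismatch=d_hvr_mismatch,
                        d_outside=d_outside, d_e8=d_e8)


def evaluate_criteria(diff: GenotypeDiff) -> CriteriaVerdict:
    """Evaluate the Lechner and Beye heterozygosity rules on a diff."""
    beye = diff.d_psd >= 5 and diff.d_hvr_len >= 1
    notes = []
    if diff.d_e8 is None:
        lechner: bool | None = None
        notes.append("lechner indeterminate: no exon-8 annotation")
    else:
        lechner = (diff.d_hvr_len >= 6 and diff.d_psd >= 1
                   and 3 * diff.d_psd + 2 * diff.d_e8 >= 9)
    return CriteriaVerdict(lechner_pass=lechner, beye_pass=beye,
                           notes="; ".join(notes))


def heatmap_table(diffs: Sequence[GenotypeDiff],
                  flagged: Iterable[int] = (),
                  ) -> tuple[pd.DataFrame, set[tuple[int, int]]]:
    """Genotype counts on the (d_hvr_len, d_outside) plane.

    Returns a count matrix (rows = HVR length difference, columns = number
    of differences outside the HVR, ranges covering the observed values) and
    the set of cells containing genotypes whose indices appear in
    ``flagged`` (underrepresented genotypes, for overplotting).
    """
    if not diffs:
        return pd.DataFrame(), set()
    xs = [d.d_hvr_len for d in diffs]
    ys = [d.d_outside for d in diffs]
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(0, max(xs) + 1, name="d_hvr_len"),
        columns=pd.RangeIndex(0, max(ys) + 1, name="d_outside"))
    for x, y in zip(xs, ys):
        counts.loc[x, y] += 1
    flagged_cells = {(diffs[i].d_hvr_len, diffs[i].d_outside)
                     for i in flagged}
    return counts, flagged_cells
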