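"""Synthetic csd alleles, polyandrous colonies and T-RFLP observations.

The generator emulates the sequence architecture the digest relies on: a
primer-flanked amplicon whose exon-7 part carries an RS-rich flank and a
TAT/AAT trinucleotide-repeat hypervariable region (HVR, translating to a
tyrosine/asparagine-rich peptide), a conserved spacer with exactly one VspI
site (ATTAAT, supplied in frame as the codons ATT+AAT), a GT...AG intron,
and an exon-8 part of TTCCTG/TTCCTA (Phe-Leu) proline-region repeats ending
in the reverse-primer binding site.  HVR length differences therefore
propagate to the 5' fragment length and proline-repeat differences to the
3' fragment, as in the real locus.

Colonies are polyandrous: a queen with two distinct alleles mated to several
drones whose contributions are skewed by a symmetric Dirichlet.  Workers are
conceived by drawing a drone (by weight) and a maternal allele (uniformly)
and survive with a genotype-class viability; identical-allele genotypes are
diploid males and destroyed by default.  Ground truth (HVR coordinates,
exon boundaries, genotypes, sex labels) is retained for every record.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import (
    CsdAllele,
    DEFAULT_FRAME_OFFSET,
    RestrictionPattern,
    VSPI_SITE,
    translate_and_validate,
    vsp_digest,
)
from .errors import ConfigError, CorruptOrf, EditConflict
from .genotyping import WorkerObservation

#: Concrete (degeneracy-resolved) primer regions used by the templates.
FWD_REGION = "TATCGAGAAAGATCGAAAGAACGAT"          # csdF2 with S -> G
REV_REGION = "ACCAATGGGACCTTGGATTTCAAT"           # revcomp of csdR2

_FRAME_PAD = "CA"   # completes the codon spanning the primer/flank boundary

HVR_UNITS = ("TAT", "AAT")      # Tyr / Asn codons; nucleotide TAT/TAA repeats
P_UNITS = ("TTCCTG", "TTCCTA")  # Phe-Leu repeat units of the proline region

DEFAULT_RS_CODONS = ("AGA", "TCG", "AGA", "AGC", "CGA",
                     "TCA", "AGG", "AGC", "AGA", "TCG")
DEFAULT_SPACER = "ATTAATGGATCG"          # ATT AAT GGA TCG = I N G S
DEFAULT_INTRON = "GT" + "CCCT" * 14 + "AG"


@dataclass
class AlleleTemplate:
    """Blueprint of a synthetic csd amplicon, edited codon-wise."""

    rs_codons: tuple[str, ...] = DEFAULT_RS_CODONS
    hvr_units: tuple[str, ...] = ("TAT", "AAT") * 6
    spacer: str = DEFAULT_SPACER
    p_units: tuple[str, ...] = ("TTCCTG",) * 6
    intron_seq: str = DEFAULT_INTRON
    fwd_region: str = FWD_REGION
    rev_region: str = REV_REGION

    def __post_init__(self) -> None:
        if not self.intron_seq.startswith("GT") or not self.intron_seq.endswith("AG"):
            raise ConfigError("intron must start GT and end AG")
        if self.spacer.count(VSPI_SITE) != 1:
            raise ConfigError("spacer must contain exactly one ATTAAT")
        if any(len(c) != 3 for c in self.rs_codons + self.hvr_units):
            raise ConfigError("rs and HVR units must be codons")
        if any(len(u) != 6 for u in self.p_units):
            raise ConfigError("proline-region units must be 6 nt")

    # -- sequence assembly -------------------------------------------------
    @property
    def exon7(self) -> str:
        return (self.fwd_region + _FRAME_PAD + "".join(self.rs_codons)
                + "".join(self.hvr_units) + self.spacer)

    @property
    def exon8(self) -> str:
        return "".join(self.p_units) + self.rev_region

    @property
    def amplicon(self) -> str:
        return self.exon7 + self.intron_seq + self.exon8

    @property
    def intron_coords(self) -> tuple[int, int]:
        s = len(self.exon7)
        return (s, s + len(self.intron_seq))

    @property
    def cds(self) -> str:
        return self.exon7 + self.exon8

    # -- protein coordinates (frame 0 from amplicon start) -----------------
    @property
    def hvr_protein_span(self) -> tuple[int, int]:
        start = (len(self.fwd_region) + len(_FRAME_PAD)) // 3 + len(self.rs_codons)
        return (start, start + len(self.hvr_units))

    @property
    def exon8_protein_start(self) -> int:
        return len(self.exon7) // 3


Edit = tuple  # ("hvr_insert", i, unit) | ("hvr_delete", i) |
#               ("hvr_sub", i, codon)  | ("rs_sub", i, codon) |
#               ("p_insert", i, unit)  | ("p_delete", i) | ("p_sub", i, unit)


def _apply_edit(tpl: AlleleTemplate, edit: Edit) -> AlleleTemplate:
    kind = edit[0]
    if kind == "hvr_insert":
        _, i, unit = edit
        units = list(tpl.hvr_units)
        units.insert(i, unit)
        return replace(tpl, hvr_units=tuple(units))
    if kind == "hvr_delete":
        _, i = edit
        units = list(tpl.hvr_units)
        del units[i]
        return replace(tpl, hvr_units=tuple(units))
    if kind == "hvr_sub":
        _, i, codon = edit
        units = list(tpl.hvr_units)
        units[i] = codon
        return replace(tpl, hvr_units=tuple(units))
    if kind == "rs_sub":
        _, i, codon = edit
        codons = list(tpl.rs_codons)
        codons[i] = codon
        return replace(tpl, rs_codons=tuple(codons))
    if kind == "p_insert":
        _, i, unit = edit
        units = list(tpl.p_units)
        units.insert(i, unit)
        return replace(tpl, p_units=tuple(units))
    if kind == "p_delete":
        _, i = edit
        units = list(tpl.p_units)
        del units[i]
        return replace(tpl, p_units=tuple(units))
    if kind == "p_sub":
        _, i, unit = edit
        units = list(tpl.p_units)
        units[i] = unit
        return replace(tpl, p_units=tuple(units))
    if kind == "spacer_sub":
        _, i, base = edit
        spacer = tpl.spacer[:i] + base + tpl.spacer[i + 1:]
        return replace(tpl, spacer=spacer)
    raise ValueError(f"unknown edit kind {kind!r}")


def make_allele(template: AlleleTemplate, edits: list[Edit] = (),
                allele_id: str = "synthetic",
                source_tag: str = "reference") -> CsdAllele:
    """Apply edits to a template and return a validated allele.

    Ground truth (HVR span, exon-8 start, intron coordinates, the edit list)
    rides along on the allele.  Edits that corrupt the reading frame or that
    create or destroy an ATTAAT site raise :class:`EditConflict`.
    """
    tpl = copy.deepcopy(template)
    for edit in edits:
        try:
            tpl = _apply_edit(tpl, edit)
        except (IndexError, ConfigError) as exc:
            raise EditConflict(f"edit {edit!r} invalid: {exc}") from exc
    amplicon = tpl.amplicon
    if amplicon.count(VSPI_SITE) != 1:
        raise EditConflict("edits changed the number of ATTAAT sites")
    try:
        protein = translate_and_validate(tpl.cds, DEFAULT_FRAME_OFFSET)
    except CorruptOrf as exc:
        raise EditConflict(f"edits corrupt the open reading frame: {exc}") from exc
    span = tpl.hvr_protein_span
    hvr_aa = protein[span[0]:span[1]]
    if hvr_aa and sum(c in "YN" for c in hvr_aa) / len(hvr_aa) <= 0.5:
        raise EditConflict("edits made the HVR insufficiently Y/N-rich")
    return CsdAllele(
        allele_id=allele_id,
        amplicon_seq=amplicon,
        cds_seq=tpl.cds,
        psd_protein=protein,
        hvr_span=span,
        source_tag=source_tag,  # type: ignore[arg-type]
        exon8_protein_start=tpl.exon8_protein_start,
        ground_truth={
            "intron_coords": tpl.intron_coords,
            "edits": list(edits),
            "n_hvr_units": len(tpl.hvr_units),
            "n_p_units": len(tpl.p_units),
        },
    )


def make_allele_pool(n: int, rng: np.random.Generator,
                     template: AlleleTemplate | None = None,
                     hvr_units_range: tuple[int, int] = (6, 22),
                     p_units_range: tuple[int, int] = (4, 9),
                     sub_rate: float = 0.3,
                     id_prefix: str = "A") -> list[CsdAllele]:
    """Draw ``n`` distinct synthetic alleles.

    HVR length (the dominant diversity axis), HVR unit composition,
    proline-repeat count and occasional RS-flank substitutions are randomised;
    alleles are rejected and redrawn until amplicon sequences are distinct.
    """
    template = template or AlleleTemplate()
    alleles: list[CsdAllele] = []
    seen: set[str] = set()
    attempts = 0
    while len(alleles) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ConfigError("cannot draw enough distinct alleles; "
                              "widen the template ranges")
        n_hvr = int(rng.integers(hvr_units_range[0], hvr_units_range[1] + 1))
        hvr = tuple(HVR_UNITS[i] for i in rng.integers(0, 2, size=n_hvr))
        n_p = int(rng.integers(p_units_range[0], p_units_range[1] + 1))
        p_units = tuple(P_UNITS[i] for i in rng.integers(0, 2, size=n_p))
        tpl = replace(template, hvr_units=hvr, p_units=p_units)
        edits: list[Edit] = []
        if rng.random() < sub_rate:
            i = int(rng.integers(0, len(tpl.rs_codons)))
            edits.append(("rs_sub", i, "GGA"))     # Gly substitution
        try:
            allele = make_allele(tpl, edits,
                                 allele_id=f"{id_prefix}{len(alleles) + 1:03d}")
        except EditConflict:
            continue
        if allele.amplicon_seq in seen:
            continue
        seen.add(allele.amplicon_seq)
        alleles.append(allele)
    return alleles


@dataclass
class ColonySimConfig:
    """Study-condition defaults: 15 drones, 240 workers, minimum patriline
    16, diploid males destroyed."""

    n_drones: int = 15
    allele_pool_size: int = 30
    n_workers: int = 240
    patriline_concentration: float = 1.0
    viability: dict[frozenset, float] = field(default_factory=dict)
    identical_allele_viability: float = 0.0
    trflp_noise_sd: float = 0.0
    rng_seed: int = 0
    unique_drone_alleles: bool = False

    def __post_init__(self) -> None:
        if self.n_drones < 1 or self.n_workers < 1:
            raise ConfigError("n_drones and n_workers must be >= 1")
        if self.patriline_concentration <= 0:
            raise ConfigError("Dirichlet concentration must be > 0")
        for v in list(self.viability.values()) + [self.identical_allele_viability]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError("viabilities must be in [0, 1]")
        if self.allele_pool_size < self.n_drones + 2 and self.unique_drone_alleles:
            raise ConfigError("pool too small for unique drone alleles")
        if self.allele_pool_size < 3:
            raise ConfigError("pool must hold the queen's two alleles "
                              "plus at least one more")


@dataclass
class SimulatedColony:
    colony_id: str
    queen: tuple[CsdAllele, CsdAllele]
    drones: list[CsdAllele]
    patriline_weights: np.ndarray
    truth: pd.DataFrame              # one row per conceived worker
    observations: list[WorkerObservation]   # surviving workers only
    alleles: dict[str, CsdAllele]

    @property
    def maternal_patterns(self) -> list[tuple[str, RestrictionPattern]]:
        return [(a.allele_id, vsp_digest(a.amplicon_seq)) for a in self.queen]


def genotype_viability(cfg: ColonySimConfig, maternal_id: str,
                       paternal_id: str) -> float:
    if maternal_id == paternal_id:
        return cfg.identical_allele_viability
    return cfg.viability.get(frozenset((maternal_id, paternal_id)), 1.0)


def simulate_colony(cfg: ColonySimConfig, pool: list[CsdAllele],
                    rng: np.random.Generator,
                    colony_id: str = "sim") -> SimulatedColony:
    """Simulate one polyandrous colony with genotype-dependent viability.

    The queen receives the first two pool alleles with distinct restriction
    patterns; drones are drawn uniformly from the pool (without replacement
    when ``unique_drone_alleles``).  Each of ``n_workers`` conceptions draws
    a drone by the Dirichlet patriline weights and a maternal allele
    uniformly, then survives with its genotype-class viability.  Identical
    alleles make a diploid male (sex label "diploid_male"), destroyed with
    probability 1 - identical_allele_viability.  Only survivors yield T-RFLP
    observations.
    """
    if len(pool) < 3:
        raise ConfigError("pool too small")
    queen = None
    for j in range(1, len(pool)):
        if vsp_digest(pool[0].amplicon_seq).as_tuple() != \
                vsp_digest(pool[j].amplicon_seq).as_tuple():
            queen = (pool[0], pool[j])
            break
    if queen is None:
        raise ConfigError("no two pool alleles with distinct patterns")

    if cfg.unique_drone_alleles:
        queen_ids = {queen[0].allele_id, queen[1].allele_id}
        candidates = [a for a in pool if a.allele_id not in queen_ids]
        if len(candidates) < cfg.n_drones:
            raise ConfigError("pool too small for unique drone alleles")
        idx = rng.choice(len(candidates), size=cfg.n_drones, replace=False)
        drones = [candidates[i] for i in idx]
    else:
        idx = rng.integers(0, len(pool), size=cfg.n_drones)
        drones = [pool[i] for i in idx]

    weights = rng.dirichlet(
        np.full(cfg.n_drones, cfg.patriline_concentration))

    rows = []
    observations: list[WorkerObservation] = []
    for w in range(cfg.n_workers):
        drone_i = int(rng.choice(cfg.n_drones, p=weights))
        maternal = queen[int(rng.integers(0, 2))]
        paternal = drones[drone_i]
        viability = genotype_viability(cfg, maternal.allele_id,
                                       paternal.allele_id)
        survives = bool(rng.random() < viability)
        diploid_male = maternal.allele_id == paternal.allele_id
        worker_id = f"{colony_id}-w{w + 1:04d}"
        rows.append({
            "worker_id": worker_id,
            "colony_id": colony_id,
            "drone_index": drone_i,
            "maternal_id": maternal.allele_id,
            "paternal_id": paternal.allele_id,
            "sex": "diploid_male" if diploid_male else "female",
            "survives": survives,
        })
        if survives:
            observations.append(observe_trflp(
                worker_id, colony_id, maternal, paternal,
                cfg.trflp_noise_sd, rng))

    truth = pd.DataFrame(rows)
    alleles = {a.allele_id: a for a in pool}
    return SimulatedColony(colony_id, queen, drones, weights, truth,
                           observations, alleles)


def observe_trflp(worker_id: str, colony_id: str,
                  maternal: CsdAllele, paternal: CsdAllele,
                  noise_sd: float, rng: np.random.Generator,
                  ) -> WorkerObservation:
    """Turn a worker genotype into a peak observation.

    Peaks are the union of the two alleles' terminal fragment lengths with
    integer-rounded Gaussian jitter (sd ``noise_sd``) applied independently
    per fragment; coincident lengths collapse to one peak.  Propagates
    :class:`NoRestrictionSite` for undigestible alleles.
    """
    pat_m = vsp_digest(maternal.amplicon_seq)
    pat_p = vsp_digest(paternal.amplicon_seq)

    def jitter(length: int) -> int:
        if noise_sd <= 0:
            return length
        return max(1, int(round(length + rng.normal(0.0, noise_sd))))

    hex_peaks = {jitter(pat_m.five_prime_len), jitter(pat_p.five_prime_len)}
    fam_peaks = {jitter(pat_m.three_prime_len), jitter(pat_p.three_prime_len)}
    return WorkerObservation.from_lists(worker_id, colony_id,
                                        hex_peaks, fam_peaks)
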