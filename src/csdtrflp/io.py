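"""Readers and writers for the toolkit's interchange formats.

Sequences travel as FASTA (record id = allele id); everything tabular is
TSV so stage outputs stay diff-able.  Peak-length sets are serialised as
semicolon-joined integers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import CsdAllele, PatternCatalog, RestrictionPattern
from .genotyping import WorkerObservation


def read_fasta(path: str | Path,
               source_tag: str = "reference") -> list[CsdAllele]:
    """Load amplicon sequences; one :class:`CsdAllele` shell per record."""
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        alleles.append(CsdAllele(allele_id=rec.id,
                                 amplicon_seq=str(rec.seq),
                                 source_tag=source_tag))  # type: ignore[arg-type]
    return alleles


def write_fasta(alleles: Iterable[CsdAllele], path: str | Path) -> None:
    records = [SeqRecord(Seq(a.amplicon_seq), id=a.allele_id, description="")
               for a in alleles]
    SeqIO.write(records, str(path), "fasta")


def write_catalog(catalog: PatternCatalog, path: str | Path,
                  rejects_path: str | Path | None = None) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)
    if rejects_path is not None:
        catalog.rejects_frame().to_csv(rejects_path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_allele_annotation(alleles: Iterable[CsdAllele],
                            path: str | Path) -> None:
    """Ground-truth sidecar for synthetic alleles (HVR/exon coordinates)."""
    rows = []
    for a in alleles:
        rows.append({
            "allele_id": a.allele_id,
            "hvr_start": a.hvr_span[0] if a.hvr_span else "",
            "hvr_end": a.hvr_span[1] if a.hvr_span else "",
            "exon8_protein_start": (a.exon8_protein_start
                                    if a.exon8_protein_start is not None else ""),
            "intron_start": a.ground_truth.get("intron_coords", ("", ""))[0],
            "intron_end": a.ground_truth.get("intron_coords", ("", ""))[1],
            "source_tag": a.source_tag,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _join_peaks(peaks: Iterable[int]) -> str:
    return ";".join(str(p) for p in sorted(peaks))


def _split_peaks(text: str | float) -> list[int]:
    return [int(p) for p in str(text).split(";") if p]


def write_workers(observations: Sequence[WorkerObservation],
                  path: str | Path) -> None:
    rows = [{"worker_id": o.worker_id, "colony_id": o.colony_id,
             "hex_peaks": _join_peaks(o.hex_peaks),
             "fam_peaks": _join_peaks(o.fam_peaks)} for o in observations]
    pd.DataFrame(rows, columns=["worker_id", "colony_id",
                                "hex_peaks", "fam_peaks"]
                 ).to_csv(path, sep="\t", index=False)


def read_workers(path: str | Path) -> list[WorkerObservation]:
    frame = pd.read_csv(path, sep="\t")
    return [WorkerObservation.from_lists(
                str(r.worker_id), str(r.colony_id),
                _split_peaks(r.hex_peaks), _split_peaks(r.fam_peaks))
            for r in frame.itertuples()]


def write_maternal(patterns: dict[str, list[tuple[str, RestrictionPattern]]],
                   path: str | Path) -> None:
    """``patterns`` maps colony_id -> [(allele_id, pattern), (allele_id, pattern)]."""
    rows = []
    for colony_id, pair in patterns.items():
        for allele_id, pat in pair:
            rows.append({"colony_id": colony_id, "allele_id": allele_id,
                         "five_prime_len": pat.five_prime_len,
                         "three_prime_len": pat.three_prime_len})
    pd.DataFrame(rows, columns=["colony_id", "allele_id", "five_prime_len",
                                "three_prime_len"]
                 ).to_csv(path, sep="\t", index=False)


def read_maternal(path: str | Path,
                  ) -> dict[str, list[tuple[str, RestrictionPattern]]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, RestrictionPattern]]] = {}
    for r in frame.itertuples():
        out.setdefault(str(r.colony_id), []).append(
            (str(r.allele_id),
             RestrictionPattern(int(r.five_prime_len),
                                int(r.three_prime_len))))
    for colony, pair in out.items():
        if len(pair) != 2:
            raise ValueError(
                f"colony {colony} must list exactly two maternal alleles")
    return out
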