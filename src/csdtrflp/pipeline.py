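"""Pipeline orchestration: digest -> genotype -> patrilines -> bias -> diffs.

Runs the five analysis stages over file inputs, writing every stage's TSV
plus a run manifest (config hash, seed, per-stage counts, exclusions with
reasons).  Identical config + inputs + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import bias as bias_mod
from . import io as io_mod
from . import psd as psd_mod
from .digest import (
    CSD_F2,
    CSD_R2,
    build_pattern_catalog,
    extract_amplicon,
    splice_intron,
    translate_and_validate,
)
from .errors import CsdTrflpError
from .genotyping import (
    DEFAULT_MIN_PATRILINE_SIZE,
    DEFAULT_TOLERANCE,
    CallStatus,
    call_worker,
    group_patrilines,
)

log = logging.getLogger("csdtrflp")


@dataclass
class PipelineConfig:
    alleles_fasta: str = ""
    workers_tsv: str = ""
    maternal_tsv: str = ""
    annotation_tsv: str | None = None
    out_dir: str = "csdtrflp-out"
    fwd_primer: str = CSD_F2
    rev_primer: str = CSD_R2
    trim_primers: bool = False
    tolerance: int = DEFAULT_TOLERANCE
    min_patriline_size: int = DEFAULT_MIN_PATRILINE_SIZE
    alpha: float = bias_mod.DEFAULT_ALPHA
    hvr_strategy: str = "annotated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0 or self.min_patriline_size < 1:
            raise ValueError("tolerance >= 0 and min_patriline_size >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.hvr_strategy not in ("annotated", "motif"):
            raise ValueError("hvr_strategy must be annotated or motif")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def digest_hash(self) -> str:
        # out_dir is a destination, not an analysis parameter
        cfg = dataclasses.asdict(self)
        cfg.pop("out_dir")
        text = yaml.safe_dump(cfg, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CsdTrflpError as exc:
                raise CsdTrflpError(f"[stage {name}] {exc}") from exc
            except FileNotFoundError as exc:
                raise CsdTrflpError(f"[stage {name}] missing input: {exc}") from exc
        return inner
    return wrap


@_stage("digest")
def _run_digest(cfg: PipelineConfig, out: Path) -> dict:
    alleles = io_mod.read_fasta(cfg.alleles_fasta)
    if cfg.trim_primers:
        for a in alleles:
            a.amplicon_seq = extract_amplicon(
                a.amplicon_seq, cfg.fwd_primer, cfg.rev_primer)
    catalog = build_pattern_catalog(alleles)
    io_mod.write_catalog(catalog, out / "catalog.tsv", out / "rejects.tsv")
    log.info("digest: %d alleles, %d patterns, %d rejects, %d duplicates",
             catalog.n_alleles, catalog.n_patterns,
             len(catalog.rejects), len(catalog.duplicates))
    return {"catalog": catalog,
            "counts": {"alleles": catalog.n_alleles,
                       "patterns": catalog.n_patterns,
                       "rejects": len(catalog.rejects),
                       "duplicates": len(catalog.duplicates)}}


@_stage("genotype")
def _run_genotype(cfg: PipelineConfig, out: Path) -> dict:
    observations = io_mod.read_workers(cfg.workers_tsv)
    maternal = io_mod.read_maternal(cfg.maternal_tsv)
    calls_rows = []
    calls_by_colony: dict[str, list] = {}
    for obs in observations:
        if obs.colony_id not in maternal:
            raise CsdTrflpError(
                f"no maternal patterns for colony {obs.colony_id}")
        call = call_worker(obs, maternal[obs.colony_id], cfg.tolerance)
        calls_by_colony.setdefault(obs.colony_id, []).append(call)
        calls_rows.append({
            "worker_id": call.worker_id,
            "colony_id": obs.colony_id,
            "status": call.status.value,
            "maternal_allele_id": call.maternal_allele_id or "",
            "paternal_five": (call.paternal_pattern.five_prime_len
                              if call.paternal_pattern else ""),
            "paternal_three": (call.paternal_pattern.three_prime_len
                               if call.paternal_pattern else ""),
        })
    pd.DataFrame(calls_rows).to_csv(out / "calls.tsv", sep="\t", index=False)

    tables = {}
    patriline_frames = []
    for colony_id, calls in sorted(calls_by_colony.items()):
        ids = tuple(aid for aid, _ in maternal[colony_id])
        table = group_patrilines(colony_id, calls, ids,  # type: ignore[arg-type]
                                 cfg.min_patriline_size,
                                 tolerance=cfg.tolerance)
        tables[colony_id] = table
        patriline_frames.append(table.to_frame())
    pd.concat(patriline_frames, ignore_index=True).to_csv(
        out / "patrilines.tsv", sep="\t", index=False) if patriline_frames \
        else pd.DataFrame().to_csv(out / "patrilines.tsv", sep="\t", index=False)

    status_totals: dict[str, int] = {s.value: 0 for s in CallStatus}
    for table in tables.values():
        for k, v in table.status_counts.items():
            status_totals[k] += v
    excluded = sum(1 for t in tables.values()
                   for r in t.rows if not r.included)
    log.info("genotype: %d workers (%s); %d patrilines excluded (n < %d)",
             len(observations), status_totals, excluded,
             cfg.min_patriline_size)
    return {"tables": tables,
            "counts": {"workers": len(observations), **status_totals,
                       "patrilines_excluded": excluded}}


@_stage("bias")
def _run_bias(cfg: PipelineConfig, tables: dict, out: Path) -> dict:
    results = []
    for colony_id in sorted(tables):
        results.extend(bias_mod.evaluate_colony(tables[colony_id], cfg.alpha))
    bias_mod.results_frame(results).to_csv(out / "bias.tsv", sep="\t",
                                           index=False)
    flagged = [r for r in results if r.flagged]
    log.info("bias: %d patrilines tested, %d flagged at adjusted p < %g",
             len(results), len(flagged), cfg.alpha)
    return {"results": results,
            "counts": {"tested": len(results), "flagged": len(flagged)}}


@_stage("diff")
def _run_diff(cfg: PipelineConfig, catalog, tables: dict, out: Path) -> dict:
    """Difference metrics for each (maternal allele, paternal allele) genotype.

    Paternal patriline patterns are matched back to catalog alleles within
    tolerance; patrilines matching zero or several catalog alleles are
    skipped with a note (T-RFLP cannot separate pattern-sharing alleles).
    """
    annotation = (io_mod.read_allele_annotation(cfg.annotation_tsv)
                  .set_index("allele_id")
                  if cfg.annotation_tsv else None)

    def hvr_of(aid: str, protein: str) -> tuple[int, int]:
        if annotation is not None and aid in annotation.index:
            row = annotation.loc[aid]
            return (int(row["hvr_start"]), int(row["hvr_end"]))
        return psd_mod.delimit_hvr(protein, "motif")

    def e8_of(aid: str) -> int | None:
        if annotation is not None and aid in annotation.index:
            val = annotation.loc[aid]["exon8_protein_start"]
            return int(val) if pd.notna(val) and val != "" else None
        return None

    proteins: dict[str, str] = {}
    for aid, allele in catalog.alleles.items():
        if allele.psd_protein:
            proteins[aid] = allele.psd_protein
            continue
        # derive: explicit splice from annotation, else canonical search
        try:
            if annotation is not None and aid in annotation.index:
                row = annotation.loc[aid]
                cds = splice_intron(
                    allele.amplicon_seq, "explicit",
                    coords=(int(row["intron_start"]), int(row["intron_end"])))
            else:
                cds = splice_intron(allele.amplicon_seq, "canonical")
            proteins[aid] = translate_and_validate(cds)
        except CsdTrflpError:
            continue

    rows = []
    skipped = []
    for colony_id in sorted(tables):
        table = tables[colony_id]
        for prow in table.rows:
            if not prow.included:
                continue
            matches = [aid for aid, pat in catalog.patterns.items()
                       if abs(pat.five_prime_len - prow.five_prime_len)
                       <= cfg.tolerance
                       and abs(pat.three_prime_len - prow.three_prime_len)
                       <= cfg.tolerance]
            if len(matches) != 1:
                skipped.append({"colony_id": colony_id,
                                "paternal_pattern_id": prow.paternal_pattern_id,
                                "reason": f"{len(matches)} catalog matches"})
                continue
            paternal = matches[0]
            for maternal in table.maternal_ids:
                if maternal not in proteins or paternal not in proteins:
                    skipped.append({"colony_id": colony_id,
                                    "paternal_pattern_id": prow.paternal_pattern_id,
                                    "reason": "protein unavailable"})
                    continue
                pa, pb = proteins[maternal], proteins[paternal]
                diff = psd_mod.diff_metrics(
                    pa, pb, hvr_of(maternal, pa), hvr_of(paternal, pb),
                    e8_start_a=e8_of(maternal), e8_start_b=e8_of(paternal))
                verdict = psd_mod.evaluate_criteria(diff)
                rows.append({
                    "colony_id": colony_id,
                    "maternal_allele_id": maternal,
                    "paternal_allele_id": paternal,
                    "d_hvr_len": diff.d_hvr_len,
                    "d_hvr_mismatch": diff.d_hvr_mismatch,
                    "d_outside": diff.d_outside,
                    "d_psd": diff.d_psd,
                    "d_e8": diff.d_e8 if diff.d_e8 is not None else "",
                    "lechner_pass": ("" if verdict.lechner_pass is None
                                     else verdict.lechner_pass),
                    "beye_pass": verdict.beye_pass,
                })
    diff_cols = ["colony_id", "maternal_allele_id", "paternal_allele_id",
                 "d_hvr_len", "d_hvr_mismatch", "d_outside", "d_psd",
                 "d_e8", "lechner_pass", "beye_pass"]
    pd.DataFrame(rows, columns=diff_cols).to_csv(
        out / "genotype_diffs.tsv", sep="\t", index=False)
    pd.DataFrame(skipped, columns=["colony_id", "paternal_pattern_id",
                                   "reason"]).to_csv(
        out / "diff_skipped.tsv", sep="\t", index=False)
    log.info("diff: %d genotype diffs, %d patrilines skipped",
             len(rows), len(skipped))
    return {"counts": {"genotype_diffs": len(rows),
                       "diff_skipped": len(skipped)}}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the manifest; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config_hash": cfg.digest_hash(), "seed": cfg.seed,
                      "stages": {}}
    digest_res = _run_digest(cfg, out)
    manifest["stages"]["digest"] = digest_res["counts"]

    genotype_res = _run_genotype(cfg, out)
    manifest["stages"]["genotype"] = genotype_res["counts"]

    bias_res = _run_bias(cfg, genotype_res["tables"], out)
    manifest["stages"]["bias"] = bias_res["counts"]

    diff_res = _run_diff(cfg, digest_res["catalog"],
                         genotype_res["tables"], out)
    manifest["stages"]["diff"] = diff_res["counts"]

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
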