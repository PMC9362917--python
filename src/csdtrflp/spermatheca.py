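"""Virtual-spermatheca resampling: alleles vs restriction patterns.

A queen stores sperm from the 10–20 drones she mated with.  Because distinct
csd alleles can share a VspI restriction pattern, a T-RFLP survey of a colony
may merge two paternal alleles into one class.  This module quantifies that
collision risk by resampling: draw subsets of distinct alleles from a catalog
(emulating a local allele pool), fill "virtual spermathecas" of a given size
by sampling with replacement from the subset, and count distinct alleles vs
distinct patterns per spermatheca.

Defaults reproduce the published experiment: subsets of 80 distinct records,
10 subsets × 10 spermathecas per size, sizes 10–20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import PatternCatalog
from .errors import DatasetTooSmall


@dataclass
class SpermathecaExperimentConfig:
    subset_size: int = 80
    n_subsets: int = 10
    spermatheca_sizes: tuple[int, ...] = (10, 12, 14, 16, 18, 20)
    reps_per_subset: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1 or self.n_subsets < 1 or self.reps_per_subset < 1:
            raise ValueError("sizes and repetition counts must be >= 1")
        if any(k < 1 for k in self.spermatheca_sizes):
            raise ValueError("spermatheca sizes must be >= 1")


@dataclass
class SpermathecaResultRow:
    spermatheca_size: int
    mean_distinct_alleles: float
    mean_distinct_patterns: float
    sd_alleles: float
    sd_patterns: float
    n_sims: int

    def __post_init__(self) -> None:
        if not (1 <= self.mean_distinct_patterns
                <= self.mean_distinct_alleles + 1e-12
                <= self.spermatheca_size + 1e-12):
            raise ValueError("inconsistent distinct-count means")


def sample_spermatheca(pool: np.ndarray | list, k: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Fill a virtual spermatheca: k uniform draws with replacement."""
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("empty pool")
    return rng.choice(pool, size=k, replace=True)


def expected_distinct(pool_size: int, k: int) -> float:
    """Closed-form mean number of distinct items after k uniform draws
    with replacement from ``pool_size`` equally likely items:
    n (1 - (1 - 1/n)^k)."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    n = float(pool_size)
    return n * (1.0 - (1.0 - 1.0 / n) ** k)


def run_experiment(catalog: PatternCatalog | pd.DataFrame,
                   cfg: SpermathecaExperimentConfig,
                   ) -> list[SpermathecaResultRow]:
    """Run the full subset × spermatheca-size resampling experiment.

    ``catalog`` maps allele ids to pattern ids (a :class:`PatternCatalog` or
    a DataFrame with ``allele_id``/``pattern_id`` columns).  Subsets of
    distinct alleles are drawn *without* replacement from the catalog;
    spermathecas are drawn *with* replacement from the subset.  A single
    seeded generator drives everything in a fixed order (per size, per
    subset, per repetition), so a seed reproduces the table exactly.
    """
    if isinstance(catalog, PatternCatalog):
        frame = catalog.to_frame()
    else:
        frame = catalog
    allele_ids = frame["allele_id"].to_numpy()
    pattern_of = dict(zip(frame["allele_id"], frame["pattern_id"]))
    if cfg.subset_size > len(allele_ids):
        raise DatasetTooSmall(
            f"subset_size {cfg.subset_size} > catalog size {len(allele_ids)}")

    rng = np.random.default_rng(cfg.rng_seed)
    rows: list[SpermathecaResultRow] = []
    for size in cfg.spermatheca_sizes:
        n_alleles: list[int] = []
        n_patterns: list[int] = []
        for _ in range(cfg.n_subsets):
            subset = rng.choice(allele_ids, size=cfg.subset_size,
                                replace=False)
            for _ in range(cfg.reps_per_subset):
                draw = sample_spermatheca(subset, size, rng)
                distinct = set(draw.tolist())
                n_alleles.append(len(distinct))
                n_patterns.append(len({pattern_of[a] for a in distinct}))
        a = np.asarray(n_alleles, dtype=float)
        p = np.asarray(n_patterns, dtype=float)
        rows.append(SpermathecaResultRow(
            spermatheca_size=size,
            mean_distinct_alleles=float(a.mean()),
            mean_distinct_patterns=float(p.mean()),
            sd_alleles=float(a.std(ddof=1)) if a.size > 1 else 0.0,
            sd_patterns=float(p.std(ddof=1)) if p.size > 1 else 0.0,
            n_sims=int(a.size),
        ))
    return rows


def results_frame(rows: list[SpermathecaResultRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def format_table(rows: list[SpermathecaResultRow]) -> str:
    """One-decimal summary table (machine output keeps full precision)."""
    lines = ["size\tmean_alleles\tmean_patterns"]
    for r in sorted(rows, key=lambda r: -r.spermatheca_size):
        lines.append(f"{r.spermatheca_size}\t{r.mean_distinct_alleles:.1f}"
                     f"\t{r.mean_distinct_patterns:.1f}")
    return "\n".join(lines)
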