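"""Maternal-allele segregation testing within patrilines.

Within a patriline every worker inherited the same paternal csd allele and
one of the queen's two alleles; under Mendelian segregation and equal
viability the maternal split is Binomial(n, 0.5).  A deficit of one maternal
allele signals a lethal or partially lethal csd genotype (diploid males are
destroyed; weakly functional heterozygotes are underrepresented).

Each included patriline gets a Pearson chi-squared goodness-of-fit test
against 0.5/0.5 (1 df, no continuity correction); p-values are
Bonferroni-adjusted per colony (the family is the set of patrilines tested
in that colony) and flagged at adjusted p < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyPatriline
from .genotyping import PatrilineTable

DEFAULT_ALPHA = 0.1


@dataclass
class BiasTestResult:
    colony_id: str
    paternal_pattern_id: str
    count_m1: int
    count_m2: int
    chi2_stat: float
    p_raw: float
    p_adjusted: float
    flagged: bool
    alpha: float = DEFAULT_ALPHA
    expected_count_warning: bool = False

    @property
    def total(self) -> int:
        return self.count_m1 + self.count_m2


def chi2_gof(a: int, b: int) -> tuple[float, float]:
    """Pearson chi-squared GOF of (a, b) against equal expected counts.

    With e = (a+b)/2 the statistic is (a-e)^2/e + (b-e)^2/e = (a-b)^2/(a+b);
    p comes from the chi-squared distribution with 1 degree of freedom.  No
    continuity correction is applied.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise EmptyPatriline("cannot test an empty patriline")
    stat = (a - b) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def bonferroni_flag(results: Sequence[BiasTestResult],
                    alpha: float = DEFAULT_ALPHA) -> list[BiasTestResult]:
    """Bonferroni-adjust raw p-values within one colony and set flags.

    m = number of tests performed in the colony; p_adjusted = min(1, m * p).
    """
    if not results:
        return []
    colonies = {r.colony_id for r in results}
    if len(colonies) > 1:
        raise ValueError("bonferroni family must be a single colony")
    praw = [r.p_raw for r in results]
    _, p_adj, _, _ = multipletests(praw, alpha=alpha, method="bonferroni")
    out = []
    for r, p in zip(results, p_adj):
        out.append(BiasTestResult(
            colony_id=r.colony_id,
            paternal_pattern_id=r.paternal_pattern_id,
            count_m1=r.count_m1, count_m2=r.count_m2,
            chi2_stat=r.chi2_stat, p_raw=r.p_raw,
            p_adjusted=float(min(1.0, p)),
            flagged=bool(p < alpha), alpha=alpha,
            expected_count_warning=r.expected_count_warning))
    return out


def evaluate_colony(table: PatrilineTable,
                    alpha: float = DEFAULT_ALPHA) -> list[BiasTestResult]:
    """Chi-squared + Bonferroni over the included patrilines of one colony.

    Patrilines excluded for size never enter the family (they contribute
    neither a test nor to m).  A warning flag is carried when any expected
    count is below 5, where the chi-squared approximation is shaky.
    """
    raw: list[BiasTestResult] = []
    for row in table.rows:
        if not row.included:
            continue
        a, b = row.count_maternal_1, row.count_maternal_2
        stat, p = chi2_gof(a, b)
        raw.append(BiasTestResult(
            colony_id=table.colony_id,
            paternal_pattern_id=row.paternal_pattern_id,
            count_m1=a, count_m2=b, chi2_stat=stat, p_raw=p,
            p_adjusted=p, flagged=False, alpha=alpha,
            expected_count_warning=(a + b) / 2 < 5))
    return bonferroni_flag(raw, alpha=alpha)


def results_frame(results: Sequence[BiasTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results], columns=[
        "colony_id", "paternal_pattern_id", "count_m1", "count_m2",
        "chi2_stat", "p_raw", "p_adjusted", "flagged", "alpha",
        "expected_count_warning"])


def power_estimate(n: int, survival_ratio: float, alpha: float = DEFAULT_ALPHA,
                   m: int = 1, reps: int = 10_000,
                   rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo power of the per-patriline bias test.

    ``survival_ratio`` is the relative viability of the underrepresented
    genotype (1 = no deficit, 0 = fully lethal).  Surviving workers carry the
    disfavoured maternal allele with probability s/(1+s).  Returns the
    fraction of simulated patrilines of size ``n`` flagged after Bonferroni
    correction for ``m`` tests at level ``alpha``.
    """
    if not 0 <= survival_ratio <= 1:
        raise ValueError("survival_ratio must be in [0, 1]")
    if n < 1 or m < 1 or reps < 1:
        raise ValueError("n, m and reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    p_success = survival_ratio / (1.0 + survival_ratio)
    a = rng.binomial(n, p_success, size=reps)
    b = n - a
    stat = (a - b) ** 2 / n
    p_raw = stats.chi2.sf(stat, df=1)
    p_adj = np.minimum(1.0, m * p_raw)
    return float(np.mean(p_adj < alpha))
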