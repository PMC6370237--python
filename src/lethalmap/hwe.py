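"""Genotype-frequency analysis across life stages.

For a biallelic locus with genotype counts (n_GG, n_GT, n_TT) the module
computes the allele frequency q by counting, observed and expected
heterozygosity, the disequilibrium statistic

    alpha = 1 - Hobs / Hexp,        Hexp = 2 q (1 - q),

and the 3-class Hardy-Weinberg chi-square on 1 df, which satisfies the
algebraic identity chi2 = n * alpha**2 (asserted on every input).  A
positive alpha indicates heterozygote deficit, a negative alpha heterozygote
excess — the signature of selective loss of homozygotes, as when recessive
lethal homozygotes disappear between birth and later weight stages.

The genotype-change test asks the complementary question: restricted to the
surviving genotype classes (GG, GT), do relative frequencies change across
stages?  A non-significant result supports purely selective loss of the
homozygote class rather than selection against the allele itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CohortCounts", "cohort_stats", "stage_comparison", "genotype_change_test"]


@dataclass
class CohortCounts:
    """Per-stage genotype counts with derived Hardy-Weinberg statistics."""

    stage: str
    n_GG: int
    n_GT: int
    n_TT: int
    q: float = 0.0
    h_obs: float = 0.0
    h_exp: float = 0.0
    alpha: float = float("nan")
    chi2: float = float("nan")
    p_value: float = float("nan")
    alpha_defined: bool = True

    @property
    def n(self) -> int:
        return self.n_GG + self.n_GT + self.n_TT


def cohort_stats(n_GG: int, n_GT: int, n_TT: int, stage: str = "") -> CohortCounts:
    """Allele frequency, heterozygosity, alpha and HWE chi-square (1 df).

    ``alpha`` is undefined (NaN, ``alpha_defined=False``) at a monomorphic
    cohort (q in {0, 1}); chi2 is 0 there (observed equals expected).
    """
    for c in (n_GG, n_GT, n_TT):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_GG + n_GT + n_TT
    if n == 0:
        raise ValueError("empty cohort")
    q = (n_GT + 2 * n_TT) / (2 * n)
    h_obs = n_GT / n
    h_exp = 2 * q * (1 - q)
    if h_exp == 0:
        alpha, chi2, p, defined = float("nan"), 0.0, 1.0, False
    else:
        alpha = 1.0 - h_obs / h_exp
        chi2 = n * alpha * alpha
        p = float(stats.chi2.sf(chi2, df=1))
        defined = True
        # algebraic identity with the 3-class Pearson statistic
        p_allele = 1 - q
        exp = n * np.array([p_allele**2, 2 * p_allele * q, q**2])
        obs = np.array([n_GG, n_GT, n_TT], dtype=float)
        pearson = float(((obs - exp) ** 2 / np.where(exp > 0, exp, 1)).sum())
        assert abs(pearson - chi2) < 1e-9 * max(1.0, chi2), "chi2 != n*alpha^2"
    return CohortCounts(stage, n_GG, n_GT, n_TT, q, h_obs, h_exp, alpha, chi2, p, defined)


def stage_comparison(cohorts: list[CohortCounts], alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-stage statistics plus between-stage deltas.

    ``cohorts`` must be in life-stage order (e.g. birth, 40 kg, 110 kg).
    Adds a significance flag for departure from HWE at ``alpha_level`` and
    Delta_q / Delta_alpha relative to the previous stage.  A note column
    records that slightly negative alpha (order -1/(2N)) is expected even
    under random mating in a dioecious population.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two stages to compare")
    rows = []
    prev = None
    for c in cohorts:
        row = {
            "stage": c.stage, "n": c.n, "n_GG": c.n_GG, "n_GT": c.n_GT, "n_TT": c.n_TT,
            "q": c.q, "h_obs": c.h_obs, "h_exp": c.h_exp, "alpha": c.alpha,
            "chi2": c.chi2, "p_value": c.p_value,
            "hwe_departure": bool(c.p_value < alpha_level),
            "delta_q": c.q - prev.q if prev else 0.0,
            "delta_alpha": (c.alpha - prev.alpha) if prev else 0.0,
            "note": f"random-mating expectation of alpha ~ -1/(2N) = {-1/(2*c.n):.4f}",
        }
        rows.append(row)
        prev = c
    return pd.DataFrame(rows)


def genotype_change_test(cohorts: list[CohortCounts], classes=("GG", "GT")) -> dict:
    """Contingency chi-square for change in the named genotype classes across
    stages (TT excluded by default), df = (k-1)(c-1)."""
    table = np.array(
        [[getattr(c, f"n_{cls}") for cls in classes] for c in cohorts], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(df), "p": float(p)}


def read_cohort_tsv(path) -> list[CohortCounts]:
    """Read a cohort-counts TSV (stage, n_GG, n_GT, n_TT) into stats records."""
    df = pd.read_csv(path, sep="\t")
    return [
        cohort_stats(int(r.n_GG), int(r.n_GT), int(r.n_TT), stage=str(r.stage))
        for r in df.itertuples()
    ]
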