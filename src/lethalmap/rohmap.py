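"""Case/control homozygosity mapping.

A fully penetrant recessive mutation descending from a single ancestral
haplotype leaves every affected individual homozygous and identical across
the marker segment surrounding it (identity-by-descent).  The mapping
strategy is therefore: keep informative SNPs, and per chromosome find the
longest run of consecutive SNPs at which all cases are homozygous for the
same allele; unaffected controls are expected to be heterozygous or
homozygous for the other allele at some SNPs inside the run.

Genotypes are coded 0 (hom A1), 1 (het), 2 (hom A2), -1/NaN missing.
Missing case genotypes do not interrupt a run (they are compatible with
either shared allele) but are counted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RohSegment",
    "filter_informative",
    "classify_snp",
    "longest_shared_segment",
    "segment_span_mbp",
    "summary_rows",
]

MISSING = -1

CASE_SHARED_INFORMATIVE = "case_shared_hom & control_informative"
CASE_SHARED_ONLY = "case_shared_hom_only"
NOT_SHARED = "not_shared"


@dataclass
class RohSegment:
    """Maximal run of case-shared homozygous SNPs on one chromosome."""

    chrom: object
    start_snp: str
    end_snp: str
    start_bp: int
    end_bp: int
    n_snps: int
    shared_alleles: np.ndarray  # per-SNP shared case code (0 or 2; -1 all-missing)
    n_missing_case_calls: int = 0

    @property
    def span_mbp(self) -> float:
        return segment_span_mbp(self.start_bp, self.end_bp)


def _as_codes(genotypes) -> np.ndarray:
    g = np.asarray(genotypes, dtype=float)
    g = np.where(np.isnan(g), MISSING, g)
    return g.astype(np.int8)


def filter_informative(genotypes, snp_map: pd.DataFrame, autosomes=None):
    """Drop non-autosomal, monomorphic and all-heterozygous SNPs.

    ``genotypes`` is (samples x SNPs); ``snp_map`` rows align with SNP
    columns.  ``autosomes`` is an optional collection of chromosome labels to
    keep (default: chromosomes not named X/Y/MT).  Returns the reduced matrix,
    the reduced map, and the retained count.
    """
    g = _as_codes(genotypes)
    if g.shape[1] != len(snp_map):
        raise ValueError("genotype columns do not match the SNP map")
    chrom = snp_map["chrom"].astype(str).to_numpy()
    if autosomes is None:
        auto = ~np.isin(np.char.upper(chrom.astype(str)), ("X", "Y", "MT", "M"))
    else:
        auto = np.isin(chrom, [str(c) for c in autosomes])
    keep = auto.copy()
    for j in range(g.shape[1]):
        if not keep[j]:
            continue
        col = g[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            keep[j] = False
            continue
        if np.all(obs == 1):  # completely heterozygous
            keep[j] = False
            continue
        alleles_present = set()
        if np.any(obs == 0) or np.any(obs == 1):
            alleles_present.add(0)
        if np.any(obs == 2) or np.any(obs == 1):
            alleles_present.add(2)
        if len(alleles_present) < 2:  # fixed
            keep[j] = False
    if not keep.any():
        raise ValueError("no informative SNPs retained")
    return g[:, keep], snp_map.loc[keep].reset_index(drop=True), int(keep.sum())


def classify_snp(case_codes, control_codes) -> str:
    """Classify one SNP by the case-shared-homozygosity predicate.

    ``case_shared_hom``: all non-missing cases homozygous for the same allele
    (all-missing counts as not shared); ``control_informative``: at that SNP,
    at least one control is heterozygous or homozygous for the other allele.
    """
    cases = _as_codes(case_codes)
    if cases.size == 0:
        raise ValueError("need at least one case")
    obs = cases[cases != MISSING]
    if obs.size == 0:
        return NOT_SHARED
    if np.any(obs == 1) or (np.any(obs == 0) and np.any(obs == 2)):
        return NOT_SHARED
    shared = 0 if np.any(obs == 0) else 2
    controls = _as_codes(control_codes)
    cobs = controls[controls != MISSING]
    informative = np.any(cobs == 1) or np.any(cobs == (2 - shared))
    return CASE_SHARED_INFORMATIVE if informative else CASE_SHARED_ONLY


def _case_shared_flags(case_g: np.ndarray, allow_case_het: int):
    """Per-SNP (shared?, shared allele, n missing) under a het tolerance.

    With ``allow_case_het`` > 0 a SNP still qualifies if at most that many
    cases are heterozygous and the homozygous cases all share one allele.
    """
    m = case_g.shape[1]
    shared = np.full(m, False)
    allele = np.full(m, MISSING, dtype=np.int8)
    miss = np.zeros(m, dtype=int)
    for j in range(m):
        col = case_g[:, j]
        obs = col[col != MISSING]
        miss[j] = int((col == MISSING).sum())
        if obs.size == 0:
            continue
        n_het = int((obs == 1).sum())
        hom = obs[obs != 1]
        if n_het > allow_case_het:
            continue
        if hom.size and np.any(hom == 0) and np.any(hom == 2):
            continue
        shared[j] = True
        if hom.size:
            allele[j] = 0 if np.any(hom == 0) else 2
    return shared, allele, miss


def longest_shared_segment(
    genotypes, snp_map: pd.DataFrame, case_mask, allow_case_het: int = 0
) -> list[RohSegment]:
    """Maximal runs of consecutive case-shared homozygous SNPs, per
    chromosome, ranked by SNP count (ties: bp length, then lowest
    chromosome/position).

    Within a run the shared allele may differ between SNPs (homozygosity, not
    a single-allele haplotype, is the mapped signal).  Returns [] if no SNP
    qualifies.
    """
    g = _as_codes(genotypes)
    case_mask = np.asarray(case_mask, dtype=bool)
    case_g = g[case_mask]
    if case_g.shape[0] == 0:
        raise ValueError("need at least one case")
    shared, allele, miss = _case_shared_flags(case_g, allow_case_het)

    segments: list[RohSegment] = []
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    snps = snp_map["snp"].to_numpy()
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        flags = shared[idx]
        j = 0
        while j < len(idx):
            if not flags[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(idx) and flags[k + 1]:
                k += 1
            sel = idx[j : k + 1]
            segments.append(
                RohSegment(
                    chrom=c,
                    start_snp=str(snps[sel[0]]),
                    end_snp=str(snps[sel[-1]]),
                    start_bp=int(pos[sel[0]]),
                    end_bp=int(pos[sel[-1]]),
                    n_snps=len(sel),
                    shared_alleles=allele[sel].copy(),
                    n_missing_case_calls=int(miss[sel].sum()),
                )
            )
            j = k + 1
    segments.sort(
        key=lambda s: (-s.n_snps, -(s.end_bp - s.start_bp), str(s.chrom), s.start_bp)
    )
    return segments


def segment_span_mbp(first_bp: int, last_bp: int) -> float:
    """Segment length (last - first) in Mbp, rounded to one decimal."""
    if last_bp < first_bp:
        raise ValueError("last position precedes first")
    return round((last_bp - first_bp) / 1e6, 1)


def summary_rows(genotypes, group_labels) -> pd.DataFrame:
    """Per-group per-SNP consensus codes for a mapping-figure-style summary.

    Rule: if every non-missing animal in a group is homozygous for the same
    allele, the consensus is that homozygote code (0 or 2); if any animal is
    heterozygous — or homozygotes for both alleles occur — the consensus is
    the heterozygote code 1; all-missing gives -1.
    """
    g = _as_codes(genotypes)
    labels = np.asarray(group_labels)
    rows = {}
    for grp in pd.unique(labels):
        sub = g[labels == grp]
        cons = np.empty(g.shape[1], dtype=np.int8)
        for j in range(g.shape[1]):
            obs = sub[:, j][sub[:, j] != MISSING]
            if obs.size == 0:
                cons[j] = MISSING
            elif np.any(obs == 1) or (np.any(obs == 0) and np.any(obs == 2)):
                cons[j] = 1
            else:
                cons[j] = 0 if np.any(obs == 0) else 2
        rows[grp] = cons
    return pd.DataFrame(rows).T


def segments_table(segments: list[RohSegment]) -> pd.DataFrame:
    """Ranked segments as a TSV-ready table."""
    return pd.DataFrame(
        [
            dict(
                chrom=s.chrom, start_snp=s.start_snp, end_snp=s.end_snp,
                start_bp=s.start_bp, end_bp=s.end_bp, n_snps=s.n_snps,
                span_mbp=s.span_mbp, n_missing_case_calls=s.n_missing_case_calls,
            )
            for s in segments
        ],
        columns=[
            "chrom", "start_snp", "end_snp", "start_bp", "end_bp",
            "n_snps", "span_mbp", "n_missing_case_calls",
        ],
    )
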