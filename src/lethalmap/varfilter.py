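"""Candidate causal-variant identification from a multi-sample VCF.

Three layers, mirroring a case/control resequencing design for a recessive
condition:

1. GATK-style site hard filters on INFO metrics (QD, FS, MQ, MQRankSum,
   ReadPosRankSum).  The inequalities are strict — a site sitting exactly on
   a threshold passes — and a missing metric cannot fail a site (flagged).
2. The recessive segregation pattern across sample groups: affected animals
   homozygous for one shared allele, obligate-carrier parents heterozygous,
   unaffected controls homozygous for the other allele.  Tolerances of one
   heterozygous case and/or one homozygous-reference carrier give the
   relaxed criteria appropriate to low-coverage data, where heterozygotes
   are under-called.
3. Consequence annotation of candidate SNVs against a coding gene model:
   genomic -> CDS coordinate mapping honouring strand, codon translation,
   and HGVS-like c./p. strings, with premature stop (stop_gained) detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "VariantRecord",
    "FilterCriteria",
    "GeneModel",
    "read_vcf",
    "site_hard_filter",
    "candidate_filter",
    "annotate_consequence",
    "tabulate_candidates",
]

HOM_REF, HET, HOM_ALT, MISSING_GT = "hom_ref", "het", "hom_alt", "missing"

HARD_FILTERS = (
    # (metric, operator, threshold): fail iff metric OP threshold (strict)
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict  # sample -> one of HOM_REF/HET/HOM_ALT/MISSING_GT
    metrics: dict = field(default_factory=dict)  # INFO site metrics

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class FilterCriteria:
    """Recessive-pattern tolerances: 0 = strict, 1 = relaxed."""

    max_het_cases: int = 0
    max_homref_carriers: int = 0

    def __post_init__(self):
        if self.max_het_cases not in (0, 1) or self.max_homref_carriers not in (0, 1):
            raise ValueError("tolerances must be 0 (strict) or 1 (relaxed)")


def _classify_gt(alleles) -> str:
    if alleles is None or any(a is None for a in alleles):
        return MISSING_GT
    a = set(alleles)
    if a == {0}:
        return HOM_REF
    if len(a) == 1:
        return HOM_ALT
    return HET


def read_vcf(path, decompose: bool = True) -> list[VariantRecord]:
    """Read a VCF 4.x via pysam; multi-allelic sites are decomposed into
    biallelic records (genotypes carrying a third allele become missing for
    the decomposed record)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            alt_list = list(enumerate(alts, start=1)) if decompose else list(enumerate(alts[:1], 1))
            for alt_idx, alt in alt_list:
                genos = {}
                for s in samples:
                    alleles = rec.samples[s].get("GT")
                    if alleles is None or any(a is None for a in alleles):
                        genos[s] = MISSING_GT
                        continue
                    # map to the biallelic sub-record: ref->0, this alt->1
                    if any(a not in (0, alt_idx) for a in alleles):
                        genos[s] = MISSING_GT
                        continue
                    mapped = tuple(0 if a == 0 else 1 for a in alleles)
                    genos[s] = _classify_gt(mapped)
                metrics = {}
                for key, *_ in HARD_FILTERS:
                    if key in rec.info:
                        val = rec.info[key]
                        metrics[key] = float(val[0] if isinstance(val, tuple) else val)
                out.append(
                    VariantRecord(str(rec.chrom), rec.pos, rec.ref, str(alt), genos, metrics)
                )
    return out


def site_hard_filter(variants: list[VariantRecord]) -> pd.DataFrame:
    """Apply the hard-filter clauses; returns pass/fail with reasons and a
    list of metrics that were missing (those clauses pass, flagged)."""
    rows = []
    for v in variants:
        reasons, absent = [], []
        for metric, op, thr in HARD_FILTERS:
            val = v.metrics.get(metric)
            if val is None:
                absent.append(metric)
                continue
            if (op == "<" and val < thr) or (op == ">" and val > thr):
                reasons.append(f"{metric}{op}{thr}")
        rows.append(
            dict(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                passed=not reasons, fail_reasons=";".join(reasons),
                missing_metrics=";".join(absent),
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "passed", "fail_reasons", "missing_metrics"]
    )


def _pattern_ok(v: VariantRecord, cases, carriers, controls, crit: FilterCriteria):
    """Does the variant segregate as a recessive candidate?  Missing
    genotypes never count against a clause (low coverage tolerance)."""
    case_gts = [v.genotypes.get(s, MISSING_GT) for s in cases]
    obs = [g for g in case_gts if g != MISSING_GT]
    if not obs:
        return False, "all cases missing"
    n_het = sum(g == HET for g in obs)
    homs = {g for g in obs if g in (HOM_REF, HOM_ALT)}
    if n_het > crit.max_het_cases or len(homs) > 1:
        return False, "cases not shared-homozygous"
    if homs:
        shared = homs.pop()
    elif obs:  # only hets observed within tolerance: no shared homozygote
        return False, "no homozygous case observed"
    other = HOM_REF if shared == HOM_ALT else HOM_ALT

    carrier_gts = [v.genotypes.get(s, MISSING_GT) for s in carriers]
    n_bad_carrier = sum(g == other for g in carrier_gts)
    # a carrier homozygous for the case allele always disqualifies
    if any(g == shared for g in carrier_gts):
        return False, "carrier homozygous for case allele"
    if n_bad_carrier > crit.max_homref_carriers:
        return False, "carriers not heterozygous"

    control_gts = [v.genotypes.get(s, MISSING_GT) for s in controls]
    if any(g in (HET, shared) for g in control_gts):
        return False, "control carries case allele"
    return True, shared


def candidate_filter(
    variants: list[VariantRecord],
    groups: dict,
    criteria: FilterCriteria | None = None,
) -> list[VariantRecord]:
    """Variants matching the recessive candidate pattern.

    ``groups`` maps 'cases', 'carriers', 'controls' to sample-id lists; the
    groups must not overlap.  InDels are carried through (their consequence
    annotation is a separate concern).
    """
    criteria = criteria or FilterCriteria()
    cases = list(groups.get("cases", []))
    carriers = list(groups.get("carriers", []))
    controls = list(groups.get("controls", []))
    seen: set = set()
    for name, grp in (("cases", cases), ("carriers", carriers), ("controls", controls)):
        overlap = seen & set(grp)
        if overlap:
            raise ValueError(f"samples in more than one group: {sorted(overlap)}")
        seen |= set(grp)
    kept = []
    for v in variants:
        ok, _ = _pattern_ok(v, cases, carriers, controls, criteria)
        if ok:
            kept.append(v)
    return kept


# --------------------------------------------------------------------------
# consequence annotation

@dataclass
class GeneModel:
    """Coding gene model: ordered CDS exon intervals plus the CDS sequence.

    ``exons`` are (start, end) 1-based inclusive genomic intervals given in
    5'->3' transcript order; for minus-strand genes the first exon has the
    highest coordinates.  ``cds`` is the spliced coding sequence (sense
    strand), length divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list
    cds: str

    def __post_init__(self):
        self.cds = str(self.cds).upper()
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        total = sum(e - s + 1 for s, e in self.exons)
        if total != len(self.cds):
            raise ValueError("exon intervals do not sum to CDS length")
        genomic_order = sorted(self.exons)
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if list(self.exons) != [tuple(e) for e in expected]:
            raise ValueError("exons must be listed in 5'->3' transcript order")

    @property
    def span(self) -> tuple:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    def genomic_to_cds(self, pos: int):
        """1-based CDS coordinate of a genomic position, or None if intronic
        / outside all exons."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def annotate_consequence(variant: VariantRecord, gene: GeneModel) -> dict:
    """Annotate an SNV against a gene model.

    Returns region (intergenic/intronic/CDS) and, for CDS variants, the
    consequence class (synonymous, missense, stop_gained, stop_lost), codon
    index (ceil(cds_pos / 3)), reference/alternate amino acids and HGVS-like
    c. / p. strings.  InDels are unsupported.
    """
    if not variant.is_snv:
        raise ValueError("consequence annotation supports SNVs only")
    out = dict(
        chrom=variant.chrom, pos=variant.pos, ref=variant.ref, alt=variant.alt,
        gene=gene.gene_id, region="intergenic", consequence=None, cds_pos=None,
        codon_index=None, aa_ref=None, aa_alt=None, hgvs_c=None, hgvs_p=None,
    )
    lo, hi = gene.span
    if variant.chrom != gene.chrom or not lo <= variant.pos <= hi:
        return out
    cds_pos = gene.genomic_to_cds(variant.pos)
    if cds_pos is None:
        out["region"] = "intronic"
        return out
    out["region"] = "CDS"
    ref_base = variant.ref.upper()
    alt_base = variant.alt.upper()
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if gene.cds[cds_pos - 1] != ref_base:
        raise ValueError(
            f"reference mismatch at CDS {cds_pos}: model has {gene.cds[cds_pos - 1]}, "
            f"variant ref (sense strand) is {ref_base}"
        )
    codon_index = ceil(cds_pos / 3)
    start = (codon_index - 1) * 3
    ref_codon = gene.cds[start : start + 3]
    within = cds_pos - 1 - start
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())  # standard genetic code
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        consequence = "synonymous"
    elif aa_alt == "*":
        consequence = "stop_gained"
    elif aa_ref == "*":
        consequence = "stop_lost"
    else:
        consequence = "missense"
    out.update(
        consequence=consequence, cds_pos=cds_pos, codon_index=codon_index,
        aa_ref=aa_ref, aa_alt=aa_alt,
        hgvs_c=f"c.{cds_pos}{ref_base}>{alt_base}",
        hgvs_p=f"p.{aa_ref}{codon_index}{'*' if aa_alt == '*' else aa_alt}",
    )
    return out


def tabulate_candidates(annotations: list[dict]) -> pd.DataFrame:
    """Counts of candidates per class (intergenic, intronic and, within CDS,
    each consequence); totals sum to the candidate count."""
    classes = ["intergenic", "intronic", "synonymous", "missense", "stop_gained", "stop_lost"]
    counts = dict.fromkeys(classes, 0)
    for a in annotations:
        key = a["consequence"] if a["region"] == "CDS" else a["region"]
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame({"class": list(counts), "count": list(counts.values())})
    assert df["count"].sum() == len(annotations)
    return df
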