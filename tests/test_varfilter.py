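"""Variant filtering and consequence annotation tests, with brute-force
predicate oracles and full codon-substitution enumeration."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from lethalmap.io import build_coding_gene
from lethalmap.varfilter import (
    FilterCriteria,
    GeneModel,
    VariantRecord,
    annotate_consequence,
    candidate_filter,
    site_hard_filter,
    tabulate_candidates,
)

OK_METRICS = dict(QD=25.0, FS=1.2, MQ=60.0, MQRankSum=0.5, ReadPosRankSum=0.3)


def variant(genotypes, metrics=None, pos=100, ref="G", alt="T"):
    return VariantRecord("1", pos, ref, alt, genotypes, metrics or dict(OK_METRICS))


class TestHardFilter:
    def test_low_qd_fails_with_reason(self):
        res = site_hard_filter([variant({}, {**OK_METRICS, "QD": 1.9})])
        assert not res["passed"].iloc[0]
        assert "QD<2.0" in res["fail_reasons"].iloc[0]

    def test_exact_thresholds_pass(self):
        """The printed operators are strict inequalities: boundary passes."""
        at_threshold = dict(QD=2.0, FS=60.0, MQ=40.0, MQRankSum=-12.5, ReadPosRankSum=-8.0)
        res = site_hard_filter([variant({}, at_threshold)])
        assert res["passed"].iloc[0]
        assert res["fail_reasons"].iloc[0] == ""

    def test_missing_metric_passes_but_flagged(self):
        res = site_hard_filter([variant({}, {"QD": 30.0})])
        assert res["passed"].iloc[0]
        assert "FS" in res["missing_metrics"].iloc[0]

    @given(st.integers(0, 2**40 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_clause_evaluation(self, packed):
        rng = np.random.default_rng(packed)
        metrics = {
            "QD": float(rng.uniform(0, 5)),
            "FS": float(rng.uniform(0, 120)),
            "MQ": float(rng.uniform(20, 70)),
            "MQRankSum": float(rng.uniform(-20, 5)),
            "ReadPosRankSum": float(rng.uniform(-12, 4)),
        }
        res = site_hard_filter([variant({}, metrics)])
        expected_fail = (
            metrics["QD"] < 2.0 or metrics["FS"] > 60.0 or metrics["MQ"] < 40.0
            or metrics["MQRankSum"] < -12.5 or metrics["ReadPosRankSum"] < -8.0
        )
        assert bool(res["passed"].iloc[0]) == (not expected_fail)


GROUPS = {"cases": ["a1", "a2", "a3"], "carriers": ["c1", "c2"], "controls": ["u1", "u2"]}
STATES = ["hom_ref", "het", "hom_alt", "missing"]


def pattern_oracle(gts, max_het_cases=0, max_homref_carriers=0):
    """Direct restatement of the recessive candidate criteria."""
    case_gts = [gts[s] for s in GROUPS["cases"] if gts[s] != "missing"]
    if not case_gts:
        return False
    hets = sum(g == "het" for g in case_gts)
    homs = {g for g in case_gts if g != "het"}
    if hets > max_het_cases or len(homs) != 1:
        return False
    shared = homs.pop()
    other = "hom_ref" if shared == "hom_alt" else "hom_alt"
    carr = [gts[s] for s in GROUPS["carriers"] if gts[s] != "missing"]
    if any(g == shared for g in carr):
        return False
    if sum(g == other for g in carr) > max_homref_carriers:
        return False
    ctrl = [gts[s] for s in GROUPS["controls"] if gts[s] != "missing"]
    return not any(g in ("het", shared) for g in ctrl)


class TestCandidateFilter:
    def test_causal_pattern_retained(self):
        gts = {"a1": "hom_alt", "a2": "hom_alt", "a3": "hom_alt",
               "c1": "het", "c2": "het", "u1": "hom_ref", "u2": "hom_ref"}
        assert candidate_filter([variant(gts)], GROUPS) != []

    def test_one_het_case_needs_relaxed_criteria(self):
        gts = {"a1": "het", "a2": "hom_alt", "a3": "hom_alt",
               "c1": "het", "c2": "het", "u1": "hom_ref", "u2": "hom_ref"}
        v = variant(gts)
        assert candidate_filter([v], GROUPS, FilterCriteria(0, 0)) == []
        assert candidate_filter([v], GROUPS, FilterCriteria(1, 0)) == [v]

    def test_exhaustive_enumeration_matches_oracle(self):
        """All 4^7 genotype assignments, strict and relaxed."""
        samples = GROUPS["cases"] + GROUPS["carriers"] + GROUPS["controls"]
        for crit in (FilterCriteria(0, 0), FilterCriteria(1, 1)):
            for combo in itertools.product(STATES, repeat=7):
                gts = dict(zip(samples, combo))
                got = candidate_filter([variant(gts)], GROUPS, crit) != []
                want = pattern_oracle(gts, crit.max_het_cases, crit.max_homref_carriers)
                assert got == want, (gts, crit)

    @given(st.lists(st.sampled_from(STATES), min_size=7, max_size=7))
    @settings(max_examples=120, deadline=None)
    def test_strict_subset_of_relaxed(self, combo):
        samples = GROUPS["cases"] + GROUPS["carriers"] + GROUPS["controls"]
        gts = dict(zip(samples, combo))
        v = variant(gts)
        strict = candidate_filter([v], GROUPS, FilterCriteria(0, 0))
        relaxed = candidate_filter([v], GROUPS, FilterCriteria(1, 1))
        assert set(id(x) for x in strict) <= set(id(x) for x in relaxed)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="more than one group"):
            candidate_filter([], {"cases": ["x"], "carriers": ["x"], "controls": []})

    def test_tolerances_limited_to_zero_or_one(self):
        with pytest.raises(ValueError):
            FilterCriteria(2, 0)


@pytest.fixture
def gene():
    return build_coding_gene(chrom="1", causal_pos=1_000_000)


class TestAnnotate:
    def test_premature_stop_worked_example(self, gene):
        v = variant({}, pos=1_000_000, ref="G", alt="T")
        a = annotate_consequence(v, gene)
        assert a["consequence"] == "stop_gained"
        assert a["cds_pos"] == 820 and a["codon_index"] == 274
        assert a["hgvs_c"] == "c.820G>T" and a["hgvs_p"] == "p.E274*"

    def test_third_position_gaa_to_gag_synonymous(self, gene):
        v = variant({}, pos=1_000_002, ref="A", alt="G")
        a = annotate_consequence(v, gene)
        assert a["consequence"] == "synonymous"
        assert a["aa_ref"] == a["aa_alt"] == "E"

    def test_all_nine_substitutions_of_gaa_codon(self, gene):
        """Every single-base change of the GAA codon matches direct
        translation of the mutated codon."""
        for offset, alts in ((0, "ACT"), (1, "CGT"), (2, "CGT")):
            for alt in alts:
                ref = "GAA"[offset]
                v = variant({}, pos=1_000_000 + offset, ref=ref, alt=alt)
                a = annotate_consequence(v, gene)
                codon = list("GAA")
                codon[offset] = alt
                aa = str(Seq("".join(codon)).translate())
                if aa == "E":
                    assert a["consequence"] == "synonymous"
                elif aa == "*":
                    assert a["consequence"] == "stop_gained"
                else:
                    assert a["consequence"] == "missense"
                assert a["aa_alt"] == aa

    def test_stop_gain_iff_truncated_protein(self, gene):
        """stop_gained <=> the alt protein is a strict prefix of the ref."""
        for offset, alt in ((0, "T"), (1, "C"), (2, "G")):
            ref = "GAA"[offset]
            v = variant({}, pos=1_000_000 + offset, ref=ref, alt=alt)
            a = annotate_consequence(v, gene)
            cds = list(gene.cds)
            cds[a["cds_pos"] - 1] = alt
            prot_ref = str(Seq(gene.cds).translate(to_stop=True))
            prot_alt = str(Seq("".join(cds)).translate(to_stop=True))
            truncated = prot_alt != prot_ref and prot_ref.startswith(prot_alt)
            assert (a["consequence"] == "stop_gained") == truncated

    def test_intronic_and_intergenic_regions(self, gene):
        intron = gene.exons[0][1] + 10
        assert annotate_consequence(variant({}, pos=intron, ref="G", alt="A"), gene)[
            "region"
        ] == "intronic"
        assert annotate_consequence(
            variant({}, pos=gene.span[0] - 500, ref="G", alt="A"), gene
        )["region"] == "intergenic"

    def test_indel_unsupported(self, gene):
        v = VariantRecord("1", 1_000_000, "GA", "G", {}, {})
        with pytest.raises(ValueError, match="SNVs only"):
            annotate_consequence(v, gene)

    def test_minus_strand_mapping(self):
        # single-exon minus-strand gene: CDS is reverse complement of genome
        cds = "ATGGAATAA"  # M E *
        gene = GeneModel("g", "1", "-", [(100, 108)], cds)
        # genomic position 103 is CDS position 108-103+1 = 6 (third base of GAA);
        # genome there carries the complement of CDS base 'A' -> 'T'
        v = VariantRecord("1", 103, "T", "C", {}, {})
        a = annotate_consequence(v, gene)
        assert a["cds_pos"] == 6
        assert a["consequence"] == "synonymous"  # GAA -> GAG, still Glu

    def test_reference_mismatch_detected(self, gene):
        v = variant({}, pos=1_000_000, ref="C", alt="T")
        with pytest.raises(ValueError, match="mismatch"):
            annotate_consequence(v, gene)

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            GeneModel("g", "1", "+", [(1, 4)], "ATGG")


class TestTabulate:
    def test_empty_gives_zero_table(self):
        tab = tabulate_candidates([])
        assert tab["count"].sum() == 0

    def test_counts_by_class(self, gene):
        annos = [
            annotate_consequence(variant({}, pos=1_000_000, ref="G", alt="T"), gene),
            annotate_consequence(
                variant({}, pos=gene.exons[0][1] + 5, ref="G", alt="A"), gene
            ),
            annotate_consequence(
                variant({}, pos=gene.span[0] - 100, ref="G", alt="A"), gene
            ),
        ]
        tab = tabulate_candidates(annos).set_index("class")["count"]
        assert tab["stop_gained"] == 1
        assert tab["intronic"] == 1
        assert tab["intergenic"] == 1
        assert tab.sum() == 3
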