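"""File formats and artifact emission.

Formats are deliberately plain:

* pedigree CSV: id,sire,dam,sex,litter,generation (0 = unknown parent);
* genotypes: PLINK-compatible text .ped/.map pair (two allele columns per
  marker, alleles coded 1/2, missing 0) and a wide TSV (rows = individuals,
  columns = markers, codes 0/1/2/NA);
* cohort genotype counts TSV: stage, n_GG, n_GT, n_TT;
* VCF 4.2 with the GATK-style INFO site metrics (QD, FS, MQ, MQRankSum,
  ReadPosRankSum) and GT per sample;
* gene model: exon-interval TSV plus a CDS FASTA.

``emit_artifacts`` writes the complete bundle for a simulated population:
the case/control SNP-chip panel for homozygosity mapping, staged genotype
counts for the Hardy-Weinberg analysis, and a small VCF around the causal
locus containing the causal stop-gain plus decoy variants, with sample
groups (cases / carrier dams / controls) matching a resequencing design.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .varfilter import GeneModel

__all__ = [
    "write_ped_map",
    "read_ped_map",
    "write_wide_tsv",
    "read_wide_tsv",
    "write_vcf",
    "write_gene_model",
    "read_gene_model",
    "build_coding_gene",
    "emit_artifacts",
]

_PED_ALLELES = {0: ("1", "1"), 1: ("1", "2"), 2: ("2", "2"), -1: ("0", "0")}


def write_ped_map(prefix, ids, genotypes, snp_map: pd.DataFrame, phenotype=None) -> None:
    """Write a PLINK text .ped/.map pair (space-separated)."""
    prefix = Path(prefix)
    g = np.asarray(genotypes)
    pheno = phenotype if phenotype is not None else [-9] * len(ids)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for row, ind, ph in zip(g, ids, pheno):
            alleles = " ".join(" ".join(_PED_ALLELES[int(c)]) for c in row)
            fh.write(f"FAM {ind} 0 0 0 {ph} {alleles}\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in snp_map.itertuples():
            fh.write(f"{r.chrom} {r.snp} 0 {r.pos}\n")


def read_ped_map(prefix):
    """Read a text .ped/.map pair -> (ids, phenotypes, genotype matrix, map).

    Genotypes are recoded 0/1/2 (count of allele '2'), -1 for missing.
    """
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos"],
    )
    snp_map["a1"], snp_map["a2"] = "1", "2"
    ids, phenos, rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            phenos.append(parts[5])
            alleles = parts[6:]
            codes = []
            for j in range(0, len(alleles), 2):
                a, b = alleles[j], alleles[j + 1]
                codes.append(-1 if "0" in (a, b) else (a == "2") + (b == "2"))
            rows.append(codes)
    g = np.asarray(rows, dtype=np.int8)
    if g.shape[1] != len(snp_map):
        raise ValueError(".ped allele columns do not match .map")
    return ids, phenos, g, snp_map[["snp", "chrom", "pos", "a1", "a2"]]


def write_wide_tsv(path, ids, genotypes, snp_map: pd.DataFrame) -> None:
    g = np.asarray(genotypes, dtype=float)
    df = pd.DataFrame(g, index=pd.Index(ids, name="id"), columns=snp_map["snp"])
    df = df.replace(-1, np.nan)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_wide_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col="id")
    g = df.to_numpy(dtype=float)
    g = np.where(np.isnan(g), -1, g).astype(np.int8)
    return list(df.index), g, list(df.columns)


# --------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMSMappingQuality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MappingQualityRankSumTest">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSumTest">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(path, rows, samples, contigs) -> None:
    """Write a VCF 4.2.  ``rows`` are dicts with chrom, pos, ref, alt,
    metrics (dict) and genotypes (sample -> hom_ref/het/hom_alt/missing)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in samples) + "\n")
        for r in sorted(rows, key=lambda r: (str(r["chrom"]), r["pos"])):
            info = ";".join(f"{k}={v:g}" for k, v in r.get("metrics", {}).items())
            gts = "\t".join(_GT_STRING[r["genotypes"].get(s, "missing")] for s in samples)
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t{r.get('id', '.')}\t{r['ref']}\t{r['alt']}"
                f"\t.\tPASS\t{info or '.'}\tGT\t{gts}\n"
            )


# --------------------------------------------------------------------------
# gene model

def write_gene_model(gene: GeneModel, exon_path, cds_path) -> None:
    pd.DataFrame(
        [
            dict(gene=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                 exon=i + 1, start=s, end=e)
            for i, (s, e) in enumerate(gene.exons)
        ]
    ).to_csv(exon_path, sep="\t", index=False)
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(gene.cds), id=f"{gene.gene_id}_CDS", description="")],
        str(cds_path), "fasta",
    )


def read_gene_model(exon_path, cds_path) -> GeneModel:
    df = pd.read_csv(exon_path, sep="\t")
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(cds_path), "fasta"))
    df = df.sort_values("exon")
    return GeneModel(
        gene_id=str(df["gene"].iat[0]), chrom=str(df["chrom"].iat[0]),
        strand=str(df["strand"].iat[0]),
        exons=[(int(r.start), int(r.end)) for r in df.itertuples()],
        cds=str(rec.seq),
    )


def build_coding_gene(
    chrom, causal_pos: int, gene_id: str = "mstn_like", n_codons: int = 378,
    stop_codon_index: int = 274,
) -> GeneModel:
    """Construct a 3-exon plus-strand coding gene whose CDS carries GAA at
    ``stop_codon_index`` and is positioned so that the genomic coordinate
    ``causal_pos`` maps to the first base of that codon (a G>T substitution
    there creates a premature TAA stop).

    The layout mirrors a myostatin-like locus: the vulnerable glutamate codon
    sits in the third exon of a ~1.1 kb CDS.
    """
    cds = ["ATG"] + ["GCT"] * (n_codons - 2) + ["TAA"]
    cds[stop_codon_index - 1] = "GAA"
    cds = "".join(cds)
    total = len(cds)
    e1_len, e2_len = 400, 374
    e3_len = total - e1_len - e2_len
    cds_pos = (stop_codon_index - 1) * 3 + 1  # first base of the codon
    offset_in_e3 = cds_pos - (e1_len + e2_len) - 1
    if offset_in_e3 < 0 or offset_in_e3 >= e3_len:
        raise ValueError("stop codon does not fall in exon 3 for this layout")
    e3_start = causal_pos - offset_in_e3
    e2_end = e3_start - 1501
    e2_start = e2_end - (e2_len - 1)
    e1_end = e2_start - 1001
    e1_start = e1_end - (e1_len - 1)
    return GeneModel(
        gene_id=gene_id, chrom=str(chrom), strand="+",
        exons=[(e1_start, e1_end), (e2_start, e2_end), (e3_start, e3_start + e3_len - 1)],
        cds=cds,
    )


# --------------------------------------------------------------------------
# artifact bundle

def emit_artifacts(
    pop, outdir, n_cases: int = 10, n_controls: int = 10,
    n_carriers: int = 6, n_vcf_controls: int = 22, seed: int = 0,
) -> dict:
    """Write the full artifact bundle for a simulated population.

    Returns a dict of written paths.  The VCF contains the causal stop-gain
    (cases hom-alt, carriers het, controls hom-ref, all site metrics
    passing) plus decoy variants that each fail exactly one layer: a site
    hard filter, the strict case clause (one heterozygous case), the control
    clause, or the carrier clause.
    """
    from . import popsim as ps

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ped_path = outdir / "pedigree.csv"
    pop.pedigree.table.to_csv(ped_path, index=False)
    paths["pedigree"] = ped_path

    ph_path = outdir / "phenotypes.csv"
    pop.phenotypes.to_csv(ph_path, index=False)
    paths["phenotypes"] = ph_path

    cc = ps.cohort_counts(pop)
    cc_path = outdir / "cohort_counts.tsv"
    cc.to_csv(cc_path, sep="\t", index=False)
    paths["cohort_counts"] = cc_path

    ids, labels, gm = ps.case_control_panel(pop, n_cases, n_controls, seed=seed)
    write_ped_map(outdir / "genotypes", ids, gm, pop.snp_map,
                  phenotype=[2 if l == "case" else 1 for l in labels])
    write_wide_tsv(outdir / "genotypes.tsv", ids, gm, pop.snp_map)
    pd.DataFrame({"id": ids, "group": labels}).to_csv(
        outdir / "panel_samples.tsv", sep="\t", index=False
    )
    paths["ped"] = outdir / "genotypes.ped"
    paths["map"] = outdir / "genotypes.map"
    paths["wide_tsv"] = outdir / "genotypes.tsv"
    paths["panel_samples"] = outdir / "panel_samples.tsv"

    # --- VCF around the causal locus -------------------------------------
    cfg = pop.config
    g = pop.causal_genotypes
    t = pop.pedigree.table
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(t))
    pick = lambda want, k, taken: [
        i for i in order if g[i] == want and i not in taken
    ][:k]
    taken: set = set()
    case_idx = pick(2, n_cases, taken); taken |= set(case_idx)
    carrier_idx = pick(1, n_carriers, taken); taken |= set(carrier_idx)
    control_idx = pick(0, n_vcf_controls, taken)
    name = lambda i: f"S{t['id'].iat[i]}"
    cases = [name(i) for i in case_idx]
    carriers = [name(i) for i in carrier_idx]
    controls = [name(i) for i in control_idx]
    samples = cases + carriers + controls

    ok_metrics = dict(QD=25.0, FS=1.2, MQ=60.0, MQRankSum=0.5, ReadPosRankSum=0.3)
    pattern = {s: "hom_alt" for s in cases}
    pattern.update({s: "het" for s in carriers})
    pattern.update({s: "hom_ref" for s in controls})

    chrom = str(cfg.causal_chrom)
    pos = cfg.causal_pos_bp
    gene = build_coding_gene(chrom, pos)
    write_gene_model(gene, outdir / "gene_model.tsv", outdir / "cds.fasta")
    paths["gene_model"] = outdir / "gene_model.tsv"
    paths["cds"] = outdir / "cds.fasta"

    lo, hi = gene.span
    intron_pos = gene.exons[1][1] + 700  # inside intron 2
    rows = [
        dict(chrom=chrom, pos=pos, id="causal_stop", ref="G", alt="T",
             metrics=ok_metrics, genotypes=dict(pattern)),
        # fails QD hard filter, otherwise perfect pattern
        dict(chrom=chrom, pos=lo - 50_000, id="decoy_lowqd", ref="A", alt="C",
             metrics={**ok_metrics, "QD": 1.5}, genotypes=dict(pattern)),
        # one heterozygous case: fails strict, passes relaxed criteria
        dict(chrom=chrom, pos=intron_pos, id="decoy_onehet", ref="T", alt="G",
             metrics=ok_metrics,
             genotypes={**pattern, cases[0]: "het"} if cases else dict(pattern)),
        # a control carries the case allele
        dict(chrom=chrom, pos=hi + 80_000, id="decoy_control", ref="C", alt="A",
             metrics=ok_metrics,
             genotypes={**pattern, controls[0]: "het"} if controls else dict(pattern)),
        # carriers not heterozygous (all hom-ref): fails the carrier clause
        dict(chrom=chrom, pos=lo + 150, id="decoy_carrier", ref="G", alt="A",
             metrics=ok_metrics,
             genotypes={**pattern, **{s: "hom_ref" for s in carriers}}),
    ]
    vcf_path = outdir / "region.vcf"
    contigs = [(str(c + 1), l) for c, l in enumerate(cfg.snp_panel.chrom_lengths_bp)]
    write_vcf(vcf_path, rows, samples, contigs)
    paths["vcf"] = vcf_path
    pd.DataFrame(
        {"sample": samples,
         "group": ["case"] * len(cases) + ["carrier"] * len(carriers)
                  + ["control"] * len(controls)}
    ).to_csv(outdir / "vcf_samples.tsv", sep="\t", index=False)
    paths["vcf_samples"] = outdir / "vcf_samples.tsv"
    return paths
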