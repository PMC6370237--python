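"""Forward simulation of a closed nucleus herd segregating a recessive lethal.

The generator emulates the data structure of a multi-generation pig breeding
line in which a biallelic recessive lethal allele T is maintained at moderate
frequency by heterozygote advantage on the selection index: carriers (GT)
have deeper muscle and less back fat than wild-type (GG) animals, while TT
piglets show a fully penetrant leg-weakness syndrome and essentially never
survive to the end of performance test.

Key structural features produced:

* a pedigree spanning ``n_generations`` (default 9) with litters nested in
  dams and truncation selection of parents on a muscle-minus-fat phenotypic
  index;
* SNP-chip-like marker haplotypes transmitted with recombination (uniform
  1 cM/Mbp, Haldane mapping, no interference).  Every copy of the lethal
  allele descends from a single ancestral haplotype, so all TT individuals
  are homozygous and identical across a configurable marker window around
  the causal locus (an identity-by-descent segment, the signal exploited by
  homozygosity mapping);
* genotype-dependent survival to the 40 kg and 110 kg stages (TT survival
  0.02 and 0.0 by default: almost all affected piglets die or are euthanized
  shortly after birth);
* phenotypes: the binary leg-weakness trait with optional litter, maternal,
  polygenic and residual variance on a background liability; and Gaussian
  performance traits (muscle depth, fat depth, live weight) with genotype
  means, polygenic effects bred down the pedigree, litter and maternal
  environment effects.

All randomness flows from a single seed through named sub-streams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedkin import Pedigree, validate_pedigree

__all__ = [
    "emit_artifacts",
    "SnpPanelConfig",
    "QuantTrait",
    "LegWeaknessModel",
    "TraitModel",
    "SimConfig",
    "Population",
    "simulate_population",
    "assign_phenotypes",
    "deterministic_recursion",
    "cohort_counts",
    "case_control_panel",
    "stream",
]

GENO_LABELS = ("GG", "GT", "TT")


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


# --------------------------------------------------------------------------
# configuration

@dataclass
class SnpPanelConfig:
    """Marker panel layout: ``n_snps`` spread evenly over ``chrom_lengths_bp``."""

    n_snps: int = 1200
    chrom_lengths_bp: tuple = (100_000_000, 100_000_000)
    recomb_rate_cm_per_mbp: float = 1.0


@dataclass
class QuantTrait:
    """Gaussian performance trait with per-genotype means.

    ``mean_tt`` defaults to the additive extrapolation 2*GT - GG because TT
    animals rarely survive to measurement in the emulated design.
    """

    mean_gg: float
    mean_gt: float
    mean_tt: float | None = None
    var_polygenic: float = 0.0
    var_litter: float = 0.0
    var_maternal: float = 0.0
    var_residual: float = 1.0

    def genotype_means(self) -> np.ndarray:
        tt = self.mean_tt if self.mean_tt is not None else 2 * self.mean_gt - self.mean_gg
        return np.array([self.mean_gg, self.mean_gt, tt])

    @property
    def sigma_p(self) -> float:
        return float(
            np.sqrt(self.var_polygenic + self.var_litter + self.var_maternal + self.var_residual)
        )


@dataclass
class LegWeaknessModel:
    """Binary leg-weakness trait: fully penetrant in TT by default, with an
    optional background liability (litter + maternal + polygenic + residual)
    that can affect non-TT piglets at rate ``background_prevalence``."""

    penetrance: float = 1.0
    background_prevalence: float = 0.0
    var_litter: float = 0.0
    var_maternal: float = 0.0
    var_polygenic: float = 0.0
    var_residual: float = 1.0


@dataclass
class TraitModel:
    leg_weakness: LegWeaknessModel = field(default_factory=LegWeaknessModel)
    # default genotype means and phenotypic SDs mirror a commercial pig
    # performance test (ultrasound depths in mm, weight in kg)
    muscle_depth: QuantTrait = field(
        default_factory=lambda: QuantTrait(48.38, 53.21, None, 12.4, 3.0, 0.0, 20.0)
    )
    fat_depth: QuantTrait = field(
        default_factory=lambda: QuantTrait(10.19, 8.42, None, 2.6, 0.6, 0.0, 4.2)
    )
    live_weight: QuantTrait = field(
        default_factory=lambda: QuantTrait(87.13, 84.89, None, 19.0, 6.0, 0.0, 38.4)
    )

    def quantitative(self) -> dict[str, QuantTrait]:
        return {
            "muscle_depth": self.muscle_depth,
            "fat_depth": self.fat_depth,
            "live_weight": self.live_weight,
        }


@dataclass
class SimConfig:
    n_founders: int = 80
    n_generations: int = 9
    litter_mean: float = 8.0
    litter_dispersion: float = 0.0  # 0 => Poisson; >0 => negative binomial
    q0: float = 0.22
    s1: float = 0.282  # carrier advantage (wGG = 1 - s1 relative to GT)
    n_sires: int = 10
    n_dams: int = 32
    index_weights: tuple = (1.0, 1.0)  # (muscle, fat) truncation index w_m*M - w_f*F
    # noise added to the selection index before truncation: a stand-in for
    # ranking on an EBV of limited accuracy within a broader economic index,
    # which dilutes the realised carrier advantage to the "slight" level that
    # keeps the lethal near its moderate equilibrium frequency
    index_noise_sd: float = 25.0
    # per-genotype survival probabilities (GG, GT, TT): birth->40kg, 40->110kg
    survival_40kg: tuple = (0.80, 0.80, 0.02)
    survival_110kg: tuple = (0.75, 0.75, 0.0)
    snp_panel: SnpPanelConfig = field(default_factory=SnpPanelConfig)
    causal_chrom: int = 2
    causal_pos_bp: int = 60_000_000
    ibd_window_bp: int = 4_000_000  # half-width of the shared founder segment
    traits: TraitModel = field(default_factory=TraitModel)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.q0 < 1.0:
            raise ValueError(f"q0 must be in [0, 1), got {self.q0}")
        if self.litter_mean <= 0:
            raise ValueError("litter_mean must be positive")
        for s in (*self.survival_40kg, *self.survival_110kg):
            if not 0.0 <= s <= 1.0:
                raise ValueError("survival probabilities must be in [0, 1]")
        k = len(self.snp_panel.chrom_lengths_bp)
        if not 1 <= self.causal_chrom <= k:
            raise ValueError(f"causal chromosome {self.causal_chrom} outside panel (1..{k})")
        if not 1 <= self.causal_pos_bp <= self.snp_panel.chrom_lengths_bp[self.causal_chrom - 1]:
            raise ValueError("causal locus position outside its chromosome")


# --------------------------------------------------------------------------
# population container

@dataclass
class Population:
    pedigree: Pedigree
    snp_map: pd.DataFrame  # snp, chrom, pos, a1, a2
    haplotypes: np.ndarray  # (n, 2, m) marker alleles in {0, 1}
    causal_hap: np.ndarray  # (n, 2) copies of T per haplotype
    phenotypes: pd.DataFrame
    stage_flags: pd.DataFrame  # id, alive_birth, alive_40kg, alive_110kg
    config: SimConfig

    @property
    def causal_genotypes(self) -> np.ndarray:
        """Copies of the lethal allele T per individual (0/1/2)."""
        return self.causal_hap.sum(axis=1)

    def genotype_matrix(self) -> np.ndarray:
        """Marker genotypes coded 0 (hom A1), 1 (het), 2 (hom A2)."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)


# --------------------------------------------------------------------------
# genetic map helpers

def _build_snp_map(panel: SnpPanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_chrom = np.full(len(panel.chrom_lengths_bp), panel.n_snps // len(panel.chrom_lengths_bp))
    per_chrom[: panel.n_snps % len(per_chrom)] += 1
    for c, (length, m) in enumerate(zip(panel.chrom_lengths_bp, per_chrom), start=1):
        pos = np.sort(rng.choice(np.arange(1, length, dtype=np.int64), size=m, replace=False))
        for j, p in enumerate(pos):
            rows.append((f"snp{c}_{j}", c, int(p), "1", "2"))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2"])


def deterministic_recursion(s1: float, s2: float, q0: float, n_gen: int):
    """Deterministic one-locus viability-selection recursion.

    Genotype fitnesses are wGG = 1 - s1, wGT = 1, wTT = 1 - s2 (heterozygote
    advantage when s1 > 0).  Returns ``(trajectory, q_star, defined)`` where
    ``trajectory`` holds q at generations 0..n_gen and ``q_star`` is the
    interior equilibrium s1 / (s1 + s2), undefined (returns q0, flag False)
    when s1 = s2 = 0.

    With s1 = 0 and s2 = 1 (plain recessive lethal) the recursion reduces to
    the classical q' = q / (1 + q) decline.
    """
    if s1 < 0:
        raise ValueError("s1 must be >= 0")
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("s2 must be in [0, 1]")
    q = float(q0)
    traj = [q]
    w = np.array([1.0 - s1, 1.0, 1.0 - s2])
    for _ in range(n_gen):
        p = 1.0 - q
        f = np.array([p * p, 2 * p * q, q * q]) * w
        tot = f.sum()
        if tot <= 0:
            q = 0.0
        else:
            q = (0.5 * f[1] + f[2]) / tot
        traj.append(q)
    if s1 == 0 and s2 == 0:
        return np.array(traj), q0, False
    return np.array(traj), s1 / (s1 + s2), True


# --------------------------------------------------------------------------
# main simulation

def simulate_population(config: SimConfig) -> Population:
    """Simulate the full population; see the module docstring for structure."""
    config.validate()
    panel = config.snp_panel
    rng_map = stream(config.seed, "map")
    rng_found = stream(config.seed, "founders")
    rng_mate = stream(config.seed, "mating")
    rng_meio = stream(config.seed, "meiosis")
    rng_surv = stream(config.seed, "survival")

    snp_map = _build_snp_map(panel, rng_map)
    m = len(snp_map)
    chroms = list(range(1, len(panel.chrom_lengths_bp) + 1))
    chrom_slices, gpos_chrom = [], []
    rate_m_per_bp = panel.recomb_rate_cm_per_mbp / 100.0 / 1e6  # Morgans per bp
    for c in chroms:
        idx = np.flatnonzero(snp_map["chrom"].to_numpy() == c)
        chrom_slices.append(slice(idx[0], idx[-1] + 1))
        gpos_chrom.append(snp_map["pos"].to_numpy()[idx] * rate_m_per_bp)
    ci = config.causal_chrom - 1
    causal_gpos = config.causal_pos_bp * rate_m_per_bp

    # IBD window: markers on the causal chromosome within +- ibd_window_bp
    on_chrom = snp_map["chrom"].to_numpy() == config.causal_chrom
    in_window = on_chrom & (
        np.abs(snp_map["pos"].to_numpy() - config.causal_pos_bp) <= config.ibd_window_bp
    )
    window_idx = np.flatnonzero(in_window)

    # founder haplotypes: per-marker allele frequencies ~ U(0.2, 0.8); every
    # carrier haplotype copies one shared ancestral segment in the window
    nf = config.n_founders
    freqs = rng_found.uniform(0.2, 0.8, size=m)
    shared_segment = (rng_found.random(len(window_idx)) < 0.5).astype(np.int8)

    haps = [
        (rng_found.random((2, m)) < freqs).astype(np.int8) for _ in range(nf)
    ]
    causal = [np.zeros(2, dtype=np.int8) for _ in range(nf)]
    for i in range(nf):
        for h in range(2):
            if rng_found.random() < config.q0:
                causal[i][h] = 1
                haps[i][h, window_idx] = shared_segment

    records = [
        dict(id=i + 1, sire=0, dam=0, sex="M" if i < nf // 2 else "F", litter=0, generation=0)
        for i in range(nf)
    ]

    def meiosis(ind: int):
        hap_pair = haps[ind]
        out = np.empty(m, dtype=np.int8)
        for cj, (sl, gpos) in enumerate(zip(chrom_slices, gpos_chrom)):
            length_m = gpos[-1] if len(gpos) else 0.0
            n_xo = rng_meio.poisson(length_m)
            xo = np.sort(rng_meio.uniform(0.0, length_m, size=n_xo)) if n_xo else np.empty(0)
            start = rng_meio.integers(2)
            phase = (start + np.searchsorted(xo, gpos)) % 2
            out[sl] = np.where(phase == 0, hap_pair[0, sl], hap_pair[1, sl])
            if cj == ci:
                cphase = int((start + np.searchsorted(xo, causal_gpos)) % 2)
                c_allele = causal[ind][cphase]
        if c_allele:
            # the ancestral segment travels intact with the lethal allele
            # (complete LD within the window), so every TT individual is
            # homozygous for it across the whole configured window
            out[window_idx] = shared_segment
        return out, c_allele

    # phenotype state bred down the pedigree (polygenic BVs per trait)
    traits = config.traits.quantitative()
    rng_ph = stream(config.seed, "phenotypes")
    bv = {t: [] for t in traits}
    pheno_rows = []
    litter_counter = 0
    litter_eff = {t: {} for t in traits}
    maternal_eff = {t: {} for t in traits}

    def draw_phenotype(ind_idx, geno, sire_idx, dam_idx, litter_id, dam_id):
        row = {}
        for tname, tr in traits.items():
            if sire_idx is None:
                u = rng_ph.normal(0.0, np.sqrt(tr.var_polygenic)) if tr.var_polygenic > 0 else 0.0
            else:
                mid = 0.5 * (bv[tname][sire_idx] + bv[tname][dam_idx])
                ms_var = 0.5 * tr.var_polygenic
                u = mid + (rng_ph.normal(0.0, np.sqrt(ms_var)) if ms_var > 0 else 0.0)
            bv[tname].append(u)
            v = litter_eff[tname].setdefault(
                litter_id,
                rng_ph.normal(0.0, np.sqrt(tr.var_litter)) if tr.var_litter > 0 else 0.0,
            )
            w = maternal_eff[tname].setdefault(
                dam_id,
                rng_ph.normal(0.0, np.sqrt(tr.var_maternal)) if tr.var_maternal > 0 else 0.0,
            )
            e = rng_ph.normal(0.0, np.sqrt(tr.var_residual)) if tr.var_residual > 0 else 0.0
            row[tname] = tr.genotype_means()[geno] + u + v + w + e
        return row

    lw = config.traits.leg_weakness
    survive = lambda probs, g: rng_surv.random() < probs[g]

    for i in range(nf):
        g = int(causal[i].sum())
        row = dict(id=i + 1, geno=g, sex=records[i]["sex"], generation=0, litter=0, parity=0)
        row.update(draw_phenotype(i, g, None, None, f"L0_{i}", f"D0_{i}"))
        row["leg_weakness"] = int(g == 2 and rng_ph.random() < lw.penetrance)
        pheno_rows.append(row)

    alive40 = [survive(config.survival_40kg, int(causal[i].sum())) for i in range(nf)]
    alive110 = [alive40[i] and survive(config.survival_110kg, int(causal[i].sum())) for i in range(nf)]

    gen_members = {0: list(range(nf))}
    next_id = nf + 1

    for gen in range(1, config.n_generations):
        # parent selection: survivors to 110 kg of the previous generation,
        # truncation on the phenotypic index w_m * muscle - w_f * fat
        cand = [i for i in gen_members[gen - 1] if alive110[i]]
        wm, wf = config.index_weights
        index_val = {
            i: wm * pheno_rows[i]["muscle_depth"]
            - wf * pheno_rows[i]["fat_depth"]
            + (rng_mate.normal(0.0, config.index_noise_sd) if config.index_noise_sd > 0 else 0.0)
            for i in cand
        }
        males = sorted(
            (i for i in cand if records[i]["sex"] == "M"), key=index_val.get, reverse=True
        )
        females = sorted(
            (i for i in cand if records[i]["sex"] == "F"), key=index_val.get, reverse=True
        )
        sires = males[: config.n_sires]
        dams = females[: config.n_dams]
        if not sires or not dams:
            raise RuntimeError(f"no surviving parents available at generation {gen}")

        members = []
        for dam in dams:
            sire = sires[int(rng_mate.integers(len(sires)))]
            if config.litter_dispersion > 0:
                r = config.litter_mean / config.litter_dispersion
                size = rng_mate.negative_binomial(
                    r, r / (r + config.litter_mean)
                )
            else:
                size = rng_mate.poisson(config.litter_mean)
            size = max(int(size), 1)
            litter_counter += 1
            parity = records[dam]["generation"] + 1  # proxy: first litter at own gen+1
            for _ in range(size):
                hap_s, c_s = meiosis(sire)
                hap_d, c_d = meiosis(dam)
                haps.append(np.stack([hap_s, hap_d]))
                causal.append(np.array([c_s, c_d], dtype=np.int8))
                sex = "M" if rng_mate.random() < 0.5 else "F"
                records.append(
                    dict(
                        id=next_id,
                        sire=records[sire]["id"],
                        dam=records[dam]["id"],
                        sex=sex,
                        litter=litter_counter,
                        generation=gen,
                    )
                )
                g = int(c_s + c_d)
                idx = len(records) - 1
                row = dict(
                    id=next_id, geno=g, sex=sex, generation=gen,
                    litter=litter_counter, parity=int(parity),
                )
                row.update(
                    draw_phenotype(idx, g, sire, dam, litter_counter, records[dam]["id"])
                )
                row["leg_weakness"] = int(g == 2 and rng_ph.random() < lw.penetrance)
                pheno_rows.append(row)
                a40 = survive(config.survival_40kg, g)
                alive40.append(a40)
                alive110.append(a40 and survive(config.survival_110kg, g))
                members.append(idx)
                next_id += 1
        gen_members[gen] = members

    ped = validate_pedigree(pd.DataFrame(records))
    pheno = pd.DataFrame(pheno_rows)
    # litter-level covariates used as fixed effects downstream
    litter_sizes = pheno.groupby("litter")["id"].transform("size")
    pheno["n_born_alive"] = litter_sizes
    pheno["batch"] = pheno["generation"]

    stage = pd.DataFrame(
        {
            "id": [r["id"] for r in records],
            "alive_birth": True,
            "alive_40kg": alive40,
            "alive_110kg": alive110,
        }
    )
    return Population(
        pedigree=ped,
        snp_map=snp_map,
        haplotypes=np.stack(haps),
        causal_hap=np.stack(causal),
        phenotypes=pheno,
        stage_flags=stage,
        config=config,
    )


def assign_phenotypes(pop: Population, model: TraitModel, seed: int) -> pd.DataFrame:
    """Regenerate the phenotype table for an existing population.

    Quantitative traits are genotype mean + polygenic effect (midparent +
    Mendelian-sampling deviation, variance sigma2_a/2 scaled by parental
    inbreeding) + litter + maternal + residual.  Leg weakness is 1 with
    probability ``penetrance`` iff TT, plus an optional background liability
    shared through litter/maternal/polygenic components.

    Individuals with unknown causal genotype get missing trait values and a
    ``flag_missing_genotype`` marker.
    """
    rng = np.random.default_rng(seed)
    ped = pop.pedigree
    t = ped.table
    n = len(t)
    sire_pos, dam_pos = ped.parent_arrays()
    from .pedkin import inbreeding

    geno = pd.Series(pop.causal_genotypes, index=pop.pedigree.ids).reindex(t["id"]).to_numpy()
    F = inbreeding(ped).reindex(t["id"]).to_numpy()

    out = t[["id", "sex", "litter", "generation"]].copy()
    missing = pd.isna(geno)
    out["geno"] = geno
    out["flag_missing_genotype"] = missing

    traits = model.quantitative()
    for tname, tr in traits.items():
        u = np.zeros(n)
        for i in range(n):
            s, d = sire_pos[i], dam_pos[i]
            if s < 0 and d < 0:
                u[i] = rng.normal(0.0, np.sqrt(tr.var_polygenic)) if tr.var_polygenic > 0 else 0.0
            else:
                mid = 0.5 * ((u[s] if s >= 0 else 0.0) + (u[d] if d >= 0 else 0.0))
                fs = F[s] if s >= 0 else 0.0
                fd = F[d] if d >= 0 else 0.0
                ms_var = 0.5 * tr.var_polygenic * (1.0 - 0.5 * (fs + fd))
                u[i] = mid + (rng.normal(0.0, np.sqrt(ms_var)) if ms_var > 0 else 0.0)
        litters = t["litter"].to_numpy()
        dams = t["dam"].to_numpy()
        v = _group_effects(litters, tr.var_litter, rng)
        w = _group_effects(dams, tr.var_maternal, rng)
        e = rng.normal(0.0, np.sqrt(tr.var_residual), size=n) if tr.var_residual > 0 else np.zeros(n)
        means = tr.genotype_means()
        vals = np.where(missing, np.nan, means[np.where(missing, 0, geno).astype(int)])
        out[tname] = vals + u + v + w + e

    lw = model.leg_weakness
    tt = (geno == 2) & ~missing
    affected = tt & (rng.random(n) < lw.penetrance)
    bg_var = lw.var_litter + lw.var_maternal + lw.var_polygenic + lw.var_residual
    if lw.background_prevalence > 0 and bg_var > 0:
        from scipy.stats import norm

        z = (
            _group_effects(t["litter"].to_numpy(), lw.var_litter, rng)
            + _group_effects(t["dam"].to_numpy(), lw.var_maternal, rng)
            + rng.normal(0.0, np.sqrt(lw.var_polygenic + lw.var_residual), size=n)
        )
        tau = norm.ppf(1.0 - lw.background_prevalence) * np.sqrt(bg_var)
        affected = affected | (z > tau)
    out["leg_weakness"] = np.where(missing, np.nan, affected.astype(float))
    return out


def _group_effects(labels, var, rng) -> np.ndarray:
    if var <= 0:
        return np.zeros(len(labels))
    uniq, inv = np.unique(labels, return_inverse=True)
    eff = rng.normal(0.0, np.sqrt(var), size=len(uniq))
    return eff[inv]


def simulate_carrier_litters(
    n_litters: int = 500,
    litter_mean: float = 6.0,
    penetrance: float = 1.0,
    residual_var: float = 0.01,
    seed: int = 0,
    parent_phenotypes: bool = True,
):
    """Litters from known carrier x carrier matings with a fully (or partly)
    penetrant recessive binary trait on the 0/1 scale plus Gaussian residual.

    This is the textbook segregation-analysis design: every offspring is TT
    with probability 1/4.  Returns ``(pedigree, phenotypes, genotypes)`` with
    phenotypes indexed by id; carrier parents score 0 (plus residual noise)
    when ``parent_phenotypes`` is set, and are unobserved otherwise.
    """
    rng = np.random.default_rng(seed)
    rows, phen, genos = [], {}, {}
    nid = 0
    sd = float(np.sqrt(residual_var))
    for lit in range(1, n_litters + 1):
        s, d = nid + 1, nid + 2
        nid += 2
        rows.append(dict(id=s, sire=0, dam=0, sex="M", litter=0, generation=0))
        rows.append(dict(id=d, sire=0, dam=0, sex="F", litter=0, generation=0))
        genos[s] = genos[d] = 1
        if parent_phenotypes:
            phen[s] = rng.normal(0.0, sd)
            phen[d] = rng.normal(0.0, sd)
        size = max(int(rng.poisson(litter_mean)), 1)
        for _ in range(size):
            nid += 1
            g = int(rng.integers(2) + rng.integers(2))
            genos[nid] = g
            affected = float(g == 2 and rng.random() < penetrance)
            phen[nid] = affected + rng.normal(0.0, sd)
            rows.append(dict(id=nid, sire=s, dam=d, sex="M", litter=lit, generation=1))
    ped = validate_pedigree(pd.DataFrame(rows))
    return ped, pd.Series(phen).reindex(ped.ids), pd.Series(genos).reindex(ped.ids)


# --------------------------------------------------------------------------
# derived views

def cohort_counts(pop: Population) -> pd.DataFrame:
    """Genotype counts (GG, GT, TT) among animals alive at each life stage."""
    g = pop.causal_genotypes
    flags = pop.stage_flags
    rows = []
    for stage, col in (("birth", "alive_birth"), ("40kg", "alive_40kg"), ("110kg", "alive_110kg")):
        alive = flags[col].to_numpy()
        rows.append(
            dict(
                stage=stage,
                n_GG=int(((g == 0) & alive).sum()),
                n_GT=int(((g == 1) & alive).sum()),
                n_TT=int(((g == 2) & alive).sum()),
            )
        )
    return pd.DataFrame(rows)


def case_control_panel(pop: Population, n_cases: int = 10, n_controls: int = 10, seed: int = 0):
    """Select TT cases (from distinct litters where possible) and unaffected
    full-sib controls, mirroring a SNP-chip case/control genotyping design.

    Returns ``(sample_ids, labels, genotype_matrix)`` with genotypes coded
    0/1/2 against the map's A2 allele.
    """
    rng = np.random.default_rng(seed)
    t = pop.pedigree.table
    g = pop.causal_genotypes
    order = rng.permutation(len(t))
    cases, case_litters = [], set()
    for i in order:  # prefer cases from distinct litters
        if g[i] == 2 and len(cases) < n_cases and t["litter"].iat[i] not in case_litters:
            cases.append(i)
            case_litters.add(t["litter"].iat[i])
    if len(cases) < n_cases:  # fall back to allowing shared litters
        for i in order:
            if g[i] == 2 and i not in cases and len(cases) < n_cases:
                cases.append(i)
    controls = []
    case_set = set(cases)
    for i in order:
        if len(controls) >= n_controls:
            break
        if g[i] != 2 and i not in case_set and t["litter"].iat[i] in case_litters:
            controls.append(i)
    for i in order:  # top up with any unaffected animal
        if len(controls) >= n_controls:
            break
        if g[i] != 2 and i not in case_set and i not in controls:
            controls.append(i)
    sel = cases + controls
    ids = t["id"].to_numpy()[sel]
    labels = ["case"] * len(cases) + ["control"] * len(controls)
    gm = pop.genotype_matrix()[sel]
    return ids, labels, gm


def emit_artifacts(pop: Population, outdir, **kwargs) -> dict:
    """Write the population's artifact bundle (pedigree/phenotype CSVs,
    PED/MAP + wide-TSV case/control panel, staged cohort counts, gene model
    and a VCF around the causal locus).  See :func:`lethalmap.io.emit_artifacts`."""
    from .io import emit_artifacts as _emit

    return _emit(pop, outdir, **kwargs)
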