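"""Tests of monogenic recessive inheritance.

Two complementary analyses:

* ``litter_ratio_test`` — the classical pooled within-litter segregation
  ratio: among litters containing at least one affected piglet, the affected
  proportion under a fully penetrant recessive locus segregating from
  carrier x carrier matings is 1/4, tested by a 1-df chi-square.  (The test
  conditions on litters with >= 1 affected, which slightly biases the pooled
  proportion downward of 0.25 for small litters — litters of carriers with
  zero affected by chance are excluded; the bias vanishes as litter size
  grows.)

* ``GibbsSegregation`` — Bayesian monogenic segregation analysis.  A single
  biallelic major locus with Hardy-Weinberg founders (allele frequency q),
  Mendelian transmission down the pedigree, and a Gaussian penetrance on the
  phenotype scale: y ~ N(mu + a*x_add + d*x_dom, sigma2_e) with
  (x_add, x_dom) = (-1,0), (0,1), (+1,0) for the three genotypes.  For a
  fully penetrant recessive 0/1 trait the generating values are mu = 0.5,
  a = 0.5, d = -0.5 (TT mean 1, GG and GT mean 0).

  The sampler is single-site Gibbs: each genotype from its full conditional
  (parental transmission x transmission to offspring given current mates x
  phenotype likelihood), q from a conjugate Beta update on founder allele
  counts, (mu, a, d) jointly from the conjugate normal linear-model update,
  sigma2_e from a scaled inverse-chi-square.  The additive effect is made
  identifiable by allele relabelling: draws with a < 0 are reported with
  a -> -a, q -> 1-q and genotypes mirrored, which leaves the likelihood
  unchanged.

``exact_enumeration`` provides an exact oracle for small pedigrees by
summing over all genotype configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.base import BaseEstimator

from .pedkin import Pedigree

__all__ = [
    "LitterSummary",
    "litter_ratio_test",
    "GibbsSegregation",
    "gibbs_segregation",
    "exact_enumeration",
    "MonogenicPosterior",
]


# --------------------------------------------------------------------------
# litter ratio test

@dataclass
class LitterSummary:
    litter: object
    n_offspring: int
    n_affected: int
    sire: object = None
    dam: object = None

    def __post_init__(self):
        if not 0 <= self.n_affected <= self.n_offspring:
            raise ValueError("need 0 <= n_affected <= n_offspring")


def litter_ratio_test(litters, expected_p: float = 0.25) -> dict:
    """Pooled segregation-ratio test over litters with >= 1 affected.

    Returns the pooled affected proportion ``p_hat``, a 1-df chi-square
    against ``expected_p``, and the mean within-litter affected proportion
    with its standard error.
    """
    if isinstance(litters, pd.DataFrame):
        litters = [
            LitterSummary(r.Index, int(r.n_offspring), int(r.n_affected))
            for r in litters.itertuples()
        ]
    affected_litters = [l for l in litters if l.n_affected > 0]
    if not affected_litters:
        raise ValueError("no litters with affected offspring")
    n_pooled = sum(l.n_offspring for l in affected_litters)
    n_aff = sum(l.n_affected for l in affected_litters)
    p_hat = n_aff / n_pooled
    exp_aff = n_pooled * expected_p
    exp_un = n_pooled * (1 - expected_p)
    chi2 = (n_aff - exp_aff) ** 2 / exp_aff + ((n_pooled - n_aff) - exp_un) ** 2 / exp_un
    props = np.array([l.n_affected / l.n_offspring for l in affected_litters])
    return {
        "p_hat": p_hat,
        "chi2": float(chi2),
        "p_value": float(stats.chi2.sf(chi2, df=1)),
        "n_pooled": n_pooled,
        "n_litters": len(affected_litters),
        "mean_within_litter": float(props.mean()),
        "se_within_litter": float(props.std(ddof=1) / np.sqrt(len(props)))
        if len(props) > 1
        else float("nan"),
    }


# --------------------------------------------------------------------------
# Mendelian transmission tables

def transmission_table() -> np.ndarray:
    """T[gs, gd, go]: P(offspring genotype | parent genotypes), genotypes
    coded as copies of the T allele (0, 1, 2)."""
    tprob = np.array([0.0, 0.5, 1.0])  # P(transmit T | parent genotype)
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            ps, pd_ = tprob[gs], tprob[gd]
            T[gs, gd, 0] = (1 - ps) * (1 - pd_)
            T[gs, gd, 1] = ps * (1 - pd_) + (1 - ps) * pd_
            T[gs, gd, 2] = ps * pd_
    return T


def hwe_probs(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


_T = transmission_table()

# genotype design: means[g] = mu + a*x_add[g] + d*x_dom[g]
X_DESIGN = np.array([[1.0, -1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sweep(geno, sire, dam, off_ptr, off_child, off_mate, y, has_y, T, T1, hwe, means, s2e):
    """One single-site Gibbs pass over all genotypes (in pedigree order)."""
    n = geno.shape[0]
    logp = np.empty(3)
    for i in range(n):
        for g in range(3):
            s = sire[i]
            d = dam[i]
            if s >= 0 and d >= 0:
                pr = T[geno[s], geno[d], g]
            elif s >= 0:
                pr = T1[geno[s], g]
            elif d >= 0:
                pr = T1[geno[d], g]
            else:
                pr = hwe[g]
            lp = np.log(pr + 1e-300)
            for k in range(off_ptr[i], off_ptr[i + 1]):
                c = off_child[k]
                mt = off_mate[k]
                if mt >= 0:
                    pc = T[g, geno[mt], geno[c]]
                else:
                    pc = T1[g, geno[c]]
                lp += np.log(pc + 1e-300)
            if has_y[i]:
                r = y[i] - means[g]
                lp += -0.5 * r * r / s2e
            logp[g] = lp
        mx = max(logp[0], max(logp[1], logp[2]))
        p0 = np.exp(logp[0] - mx)
        p1 = np.exp(logp[1] - mx)
        p2 = np.exp(logp[2] - mx)
        u = np.random.random() * (p0 + p1 + p2)
        if u < p0:
            geno[i] = 0
        elif u < p0 + p1:
            geno[i] = 1
        else:
            geno[i] = 2


@dataclass
class MonogenicPosterior:
    """Posterior summaries of the monogenic model.

    ``draws`` holds kept post-burn-in samples of (q, mu, a, d, sigma2_e)
    after identifiability relabelling; ``summary`` their mean/SD/95% credible
    interval; ``genotype_probs`` the per-individual marginal genotype
    probabilities (rows sum to 1); ``var_share_locus`` the posterior mean
    share of phenotypic variance explained by the locus.
    """

    draws: pd.DataFrame
    summary: pd.DataFrame
    genotype_probs: pd.DataFrame
    var_share_locus: float


class GibbsSegregation(BaseEstimator):
    """Bayesian monogenic segregation analysis by single-site Gibbs sampling.

    Parameters
    ----------
    n_iter, burn_in, thin : chain controls (defaults 20000 / 5000 / 5).
    seed : master seed for the sampler (mandatory for reproducibility).
    q_prior : (alpha, beta) of the Beta prior on the T-allele frequency.
    theta_prior_precision : ridge precision on (mu, a, d); the default is a
        numerically-proper stand-in for a flat prior.
    fix_params : optional dict holding any of q, mu, a, d, sigma2_e to hold
        fixed instead of sampling (mu/a/d must be fixed together).  With all
        parameters fixed the chain samples genotypes from their exact
        conditional model — the configuration comparable to the
        :func:`exact_enumeration` oracle.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : MonogenicPosterior
    summary_, draws_, genotype_probs_ : convenience views of the same.
    """

    def __init__(
        self,
        n_iter: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 5,
        seed: int = 0,
        q_prior=(1.0, 1.0),
        theta_prior_precision: float = 1e-8,
        fix_params: dict | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.q_prior = q_prior
        self.theta_prior_precision = theta_prior_precision
        self.fix_params = fix_params

    def fit(self, pedigree: Pedigree, phenotypes: pd.Series):
        """Run the chain.  ``phenotypes`` is indexed by individual id; ids
        absent from it (or NaN) contribute pedigree structure only."""
        if self.n_iter <= self.burn_in:
            raise ValueError("chain shorter than burn-in")
        t = pedigree.table
        n = len(t)
        sire, dam = pedigree.parent_arrays()
        y = phenotypes.reindex(t["id"]).to_numpy(dtype=float)
        if np.isinf(y).any():
            raise ValueError("non-finite phenotypes present")
        has_y = np.isfinite(y)  # NaN = unobserved, structure-only individual
        if not has_y.any():
            raise ValueError("no finite phenotypes")
        y = np.where(has_y, y, 0.0)

        # offspring adjacency (parent -> (child, mate)) in CSR form
        off: list[list] = [[] for _ in range(n)]
        for c in range(n):
            s, d = sire[c], dam[c]
            if s >= 0:
                off[s].append((c, d))
            if d >= 0:
                off[d].append((c, s))
        off_ptr = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            off_ptr[i + 1] = off_ptr[i] + len(off[i])
        off_child = np.empty(off_ptr[-1], dtype=np.int64)
        off_mate = np.empty(off_ptr[-1], dtype=np.int64)
        k = 0
        for i in range(n):
            for c, mt in off[i]:
                off_child[k] = c
                off_mate[k] = mt
                k += 1

        founder = (sire < 0) & (dam < 0)
        n_founder_alleles = 2 * int(founder.sum())

        rng = np.random.default_rng(self.seed)
        _seed_numba(int(rng.integers(2**31 - 1)))

        fix = dict(self.fix_params or {})
        theta_keys = {"mu", "a", "d"} & fix.keys()
        if theta_keys and theta_keys != {"mu", "a", "d"}:
            raise ValueError("mu, a and d must be fixed together")
        fix_theta = bool(theta_keys)

        # initial state
        q = float(fix.get("q", 0.5))
        geno = rng.integers(0, 3, size=n).astype(np.int64)
        ybar = y[has_y].mean()
        theta = (
            np.array([fix["mu"], fix["a"], fix["d"]])
            if fix_theta
            else np.array([ybar, 0.0, 0.0])
        )
        s2e = float(fix.get("sigma2_e", max(float(y[has_y].var()), 1e-4)))
        a0, b0 = self.q_prior
        n_obs = int(has_y.sum())

        kept = []
        geno_acc = np.zeros((n, 3))
        n_kept = 0
        Xg = X_DESIGN
        ridge = self.theta_prior_precision * np.eye(3)

        for it in range(self.n_iter):
            hwe = hwe_probs(q)
            T1 = np.einsum("m,gmo->go", hwe, _T)  # one parent unknown
            means = Xg @ theta
            _sweep(
                geno, sire, dam, off_ptr, off_child, off_mate,
                y, has_y, _T, T1, hwe, means, s2e,
            )

            # q | genotypes of founders (conjugate Beta)
            if "q" not in fix:
                t_alleles = int(geno[founder].sum())
                q = float(rng.beta(a0 + t_alleles, b0 + n_founder_alleles - t_alleles))

            # (mu, a, d) | genotypes, s2e  (conjugate normal)
            if not fix_theta:
                counts = np.bincount(geno[has_y], minlength=3).astype(float)
                sums = np.bincount(geno[has_y], weights=y[has_y], minlength=3)
                WtW = (Xg.T * counts) @ Xg + ridge
                Wty = Xg.T @ sums
                cov = np.linalg.inv(WtW)
                mean_theta = cov @ Wty
                theta = rng.multivariate_normal(mean_theta, s2e * cov, method="cholesky")

            # s2e | rest (scaled inverse-chi-square, flat prior nu=-2)
            if "sigma2_e" not in fix:
                resid = y[has_y] - (Xg @ theta)[geno[has_y]]
                sse = float(resid @ resid)
                df = max(n_obs - 2, 1)
                s2e = max(sse / float(rng.chisquare(df)), 1e-12)

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                flip = theta[1] < 0
                qq, mu, a, d = (1 - q, theta[0], -theta[1], theta[2]) if flip else (
                    q, theta[0], theta[1], theta[2]
                )
                kept.append((qq, mu, a, d, s2e))
                gidx = (2 - geno) if flip else geno
                geno_acc[np.arange(n), gidx] += 1
                n_kept += 1

        draws = pd.DataFrame(kept, columns=["q", "mu", "a", "d", "sigma2_e"])
        summary = draws.agg(["mean", "std"]).T
        ci = draws.quantile([0.025, 0.975]).T
        summary["ci_2.5"] = ci[0.025]
        summary["ci_97.5"] = ci[0.975]
        gp = pd.DataFrame(
            geno_acc / n_kept, index=t["id"], columns=["P_GG", "P_GT", "P_TT"]
        )
        # posterior mean share of phenotypic variance at the locus
        shares = []
        for qq, mu, a, d, s2 in kept:
            p = hwe_probs(qq)
            m = X_DESIGN @ np.array([mu, a, d])
            vg = float(p @ (m - p @ m) ** 2)
            shares.append(vg / (vg + s2))
        self.posterior_ = MonogenicPosterior(draws, summary, gp, float(np.mean(shares)))
        self.summary_ = summary
        self.draws_ = draws
        self.genotype_probs_ = gp
        return self


def gibbs_segregation(pedigree, phenotypes, priors=None, chain=None) -> MonogenicPosterior:
    """Functional wrapper around :class:`GibbsSegregation`."""
    chain = chain or {}
    priors = priors or {}
    est = GibbsSegregation(
        n_iter=chain.get("n_iter", 20_000),
        burn_in=chain.get("burn_in", 5_000),
        thin=chain.get("thin", 5),
        seed=chain["seed"] if "seed" in chain else 0,
        q_prior=priors.get("q_prior", (1.0, 1.0)),
    )
    return est.fit(pedigree, phenotypes).posterior_


def exact_enumeration(
    pedigree: Pedigree, phenotypes: pd.Series, q: float, mu: float, a: float, d: float,
    sigma2_e: float,
):
    """Exact genotype posteriors and marginal likelihood by summing over all
    3^n genotype configurations (n <= 10).

    Returns ``(genotype_probs DataFrame, log marginal likelihood)``.
    """
    n = len(pedigree)
    if n > 10:
        raise ValueError("exact enumeration limited to 10 individuals")
    t = pedigree.table
    sire, dam = pedigree.parent_arrays()
    y = phenotypes.reindex(t["id"]).to_numpy(dtype=float)
    has_y = np.isfinite(y)

    grids = np.meshgrid(*([np.arange(3)] * n), indexing="ij")
    configs = np.stack([g.ravel() for g in grids], axis=1)  # (3^n, n)
    hwe = hwe_probs(q)
    T1 = np.einsum("m,gmo->go", hwe, _T)
    means = X_DESIGN @ np.array([mu, a, d])

    logp = np.zeros(configs.shape[0])
    for i in range(n):
        s, dd = sire[i], dam[i]
        gi = configs[:, i]
        if s >= 0 and dd >= 0:
            pr = _T[configs[:, s], configs[:, dd], gi]
        elif s >= 0:
            pr = T1[configs[:, s], gi]
        elif dd >= 0:
            pr = T1[configs[:, dd], gi]
        else:
            pr = hwe[gi]
        logp += np.log(pr + 1e-300)
        if has_y[i]:
            r = y[i] - means[gi]
            logp += -0.5 * r * r / sigma2_e - 0.5 * np.log(2 * np.pi * sigma2_e)

    from scipy.special import logsumexp

    log_ml = float(logsumexp(logp))
    w = np.exp(logp - log_ml)
    probs = np.zeros((n, 3))
    for g in range(3):
        probs[:, g] = w @ (configs == g)
    gp = pd.DataFrame(probs, index=t["id"], columns=["P_GG", "P_GT", "P_TT"])
    return gp, log_ml
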