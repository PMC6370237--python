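"""Variance components for a binary trait, heritability, and the
observed-to-liability-scale transformation.

The binary phenotype is analysed on the observed 0/1 scale with the linear
mixed model

    y = X beta + Z1 u + Z2 v + Z3 w + e

where u are genetic effects — an animal polygenic term, or sire and/or dam
terms — distributed MVN(0, A sigma2) with A the numerator relationship
matrix; v are litter effects and w maternal-environment effects, both iid
normal; and e is the residual.  Fitting is by a conjugate Gibbs sampler:
each effect block from its multivariate-normal full conditional (the
mixed-model equations), each variance from a scaled inverse-chi-square with
the flat prior nu = -2, s2 = 0.

Heritability follows the model-specific convention:

    animal:     h2 = sigma2_a / sigma2_p
    sire:       h2 = 4 sigma2_s / sigma2_p
    sire_dam:   h2 = 2 (sigma2_s + sigma2_d) / sigma2_p

with sigma2_p the sum of all fitted components.  Observed-scale h2 of a
binary trait is converted to the liability scale by the Dempster-Lerner
transformation h2_liab = h2_obs * p(1-p) / z^2, where p is prevalence and z
the standard normal density at the threshold Phi^-1(1-p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .pedkin import Pedigree, a_matrix

__all__ = [
    "VarianceComponents",
    "HeritabilityResult",
    "GibbsVarianceComponents",
    "gibbs_varcomp",
    "heritability",
    "liability_transform",
]


@dataclass
class VarianceComponents:
    """Posterior means (or plug-in values) of the fitted components; unset
    components are None.  ``sigma2_p`` is the sum of the fitted ones."""

    sigma2_s: float | None = None
    sigma2_d: float | None = None
    sigma2_a: float | None = None
    sigma2_v: float | None = None
    sigma2_w: float | None = None
    sigma2_e: float | None = None
    posterior_sd: dict = field(default_factory=dict)

    @property
    def sigma2_p(self) -> float:
        return sum(
            v
            for v in (self.sigma2_s, self.sigma2_d, self.sigma2_a,
                      self.sigma2_v, self.sigma2_w, self.sigma2_e)
            if v is not None
        )


@dataclass
class HeritabilityResult:
    h2: float
    ratio_v: float | None
    ratio_w: float | None
    scale: str  # "observed" or "liability"
    model: str
    flagged: bool = False  # h2 outside [0, 1] (possible for sire models)


def heritability(vc: VarianceComponents, model: str) -> HeritabilityResult:
    """h2 and the litter / maternal variance ratios for the given model
    ('sire', 'sire_dam' or 'animal')."""
    s2p = vc.sigma2_p
    if s2p <= 0:
        raise ValueError("phenotypic variance is zero")
    if model == "sire":
        if vc.sigma2_s is None:
            raise ValueError("sire model requires sigma2_s")
        h2 = 4.0 * vc.sigma2_s / s2p
    elif model == "sire_dam":
        if vc.sigma2_s is None or vc.sigma2_d is None:
            raise ValueError("sire_dam model requires sigma2_s and sigma2_d")
        h2 = 2.0 * (vc.sigma2_s + vc.sigma2_d) / s2p
    elif model == "animal":
        if vc.sigma2_a is None:
            raise ValueError("animal model requires sigma2_a")
        h2 = vc.sigma2_a / s2p
    else:
        raise ValueError(f"unknown model {model!r}")
    ratio_v = vc.sigma2_v / s2p if vc.sigma2_v is not None else None
    ratio_w = vc.sigma2_w / s2p if vc.sigma2_w is not None else None
    return HeritabilityResult(h2, ratio_v, ratio_w, "observed", model, flagged=not 0 <= h2 <= 1)


def liability_transform(h2_obs: float, prevalence: float) -> float:
    """Dempster-Lerner conversion of observed-scale h2 of a 0/1 trait to the
    underlying liability scale: h2 * p(1-p) / z^2 with z = phi(Phi^-1(1-p)).

    Monotone increasing in h2_obs; for p < 0.5 the multiplier decreases as p
    grows toward 0.5 (minimum pi/2 at p = 0.5).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    z = norm.pdf(norm.ppf(1 - prevalence))
    return h2_obs * prevalence * (1 - prevalence) / (z * z)


# --------------------------------------------------------------------------
# Gibbs sampler

def _design(labels) -> tuple[np.ndarray, np.ndarray]:
    """Factor design as (level index per record, level labels)."""
    levels, idx = np.unique(np.asarray(labels), return_inverse=True)
    return idx, levels


class GibbsVarianceComponents(BaseEstimator):
    """Conjugate Gibbs sampler for the litter / maternal / genetic mixed
    model on the observed 0/1 scale.

    Parameters
    ----------
    genetic : 'sire', 'sire_dam', 'animal' or None — which pedigree-linked
        term(s) to fit (covariance A sigma2 over the corresponding ids).
    litter, maternal : whether to fit the iid litter / maternal terms.
    n_iter, burn_in, thin, seed : chain controls.

    ``fit(data, pedigree)`` expects a DataFrame with columns ``y`` plus the
    fixed-effect columns named in ``fixed`` (treated as categorical), and
    ``id``, ``sire``, ``dam``, ``litter`` as needed by the fitted terms.
    """

    def __init__(
        self,
        genetic: str | None = "sire_dam",
        litter: bool = True,
        maternal: bool = True,
        fixed: tuple = (),
        n_iter: int = 2000,
        burn_in: int = 500,
        thin: int = 2,
        seed: int = 0,
    ):
        self.genetic = genetic
        self.litter = litter
        self.maternal = maternal
        self.fixed = fixed
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _fixed_matrix(self, data: pd.DataFrame) -> tuple[np.ndarray, list]:
        cols = [np.ones(len(data))]
        names = ["intercept"]
        for f in self.fixed:
            idx, levels = _design(data[f])
            for j, lv in enumerate(levels[1:], start=1):  # first level absorbed
                cols.append((idx == j).astype(float))
                names.append(f"{f}[{lv}]")
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the aliased columns via pivoted QR
            _, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            aliased = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"confounded fixed effects; aliased columns: {aliased}")
        return X, names

    def fit(self, data: pd.DataFrame, pedigree: Pedigree | None = None):
        rng = np.random.default_rng(self.seed)
        y = data["y"].to_numpy(dtype=float)
        n = len(y)
        X, self.fixed_names_ = self._fixed_matrix(data)

        # random terms: (name, level index per record, A-structure or None)
        terms = []
        if self.genetic in ("sire", "sire_dam"):
            for col in (("sire",) if self.genetic == "sire" else ("sire", "dam")):
                idx, levels = _design(data[col])
                A = a_matrix(pedigree, list(levels)).to_numpy() if pedigree is not None else None
                terms.append([f"sigma2_{col[0]}", idx, levels, A])
        elif self.genetic == "animal":
            idx, levels = _design(data["id"])
            A = a_matrix(pedigree, list(levels)).to_numpy() if pedigree is not None else None
            terms.append(["sigma2_a", idx, levels, A])
        elif self.genetic is not None:
            raise ValueError(f"unknown genetic term {self.genetic!r}")
        if self.litter:
            idx, levels = _design(data["litter"])
            terms.append(["sigma2_v", idx, levels, None])
        if self.maternal:
            idx, levels = _design(data["dam"])
            terms.append(["sigma2_w", idx, levels, None])

        Ainvs = [np.linalg.inv(t[3]) if t[3] is not None else None for t in terms]
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)

        beta = XtX_inv @ (X.T @ y)
        u = [np.zeros(len(t[2])) for t in terms]
        vary = float(np.var(y))
        s2 = {t[0]: max(vary / (len(terms) + 1), 1e-6) for t in terms}
        s2e = max(vary, 1e-6)

        kept: list[dict] = []
        for it in range(self.n_iter):
            # beta | rest
            resid = y - sum(u[k][terms[k][1]] for k in range(len(terms)))
            mean_b = XtX_inv @ (X.T @ resid)
            beta = rng.multivariate_normal(mean_b, s2e * XtX_inv, method="cholesky")

            # each random block | rest
            for k, (name, idx, levels, A) in enumerate(terms):
                resid = y - X @ beta - sum(
                    u[j][terms[j][1]] for j in range(len(terms)) if j != k
                )
                counts = np.bincount(idx, minlength=len(levels)).astype(float)
                zt_r = np.bincount(idx, weights=resid, minlength=len(levels))
                if A is None:
                    prec = counts / s2e + 1.0 / s2[name]
                    mean_u = zt_r / s2e / prec
                    u[k] = mean_u + rng.standard_normal(len(levels)) / np.sqrt(prec)
                    quad = float(u[k] @ u[k])
                else:
                    C = np.diag(counts / s2e) + Ainvs[k] / s2[name]
                    L = np.linalg.cholesky(C)
                    mean_u = np.linalg.solve(C, zt_r / s2e)
                    z = rng.standard_normal(len(levels))
                    u[k] = mean_u + np.linalg.solve(L.T, z)
                    quad = float(u[k] @ Ainvs[k] @ u[k])
                # variance | u : scaled inverse-chi-square, flat prior nu=-2
                df = max(len(levels) - 2, 1)
                s2[name] = max(quad / float(rng.chisquare(df)), 1e-10)

            resid = y - X @ beta - sum(u[k][terms[k][1]] for k in range(len(terms)))
            sse = float(resid @ resid)
            s2e = max(sse / float(rng.chisquare(max(n - 2, 1))), 1e-10)

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                row = dict(s2)
                row["sigma2_e"] = s2e
                kept.append(row)

        self.draws_ = pd.DataFrame(kept)
        post_mean = self.draws_.mean()
        post_sd = self.draws_.std()
        vc = VarianceComponents(posterior_sd=post_sd.to_dict())
        for name in post_mean.index:
            setattr(vc, name, float(post_mean[name]))
        self.components_ = vc
        return self

    def heritability_(self, scale: str = "observed", prevalence: float | None = None):
        model = {"sire": "sire", "sire_dam": "sire_dam", "animal": "animal"}[self.genetic]
        res = heritability(self.components_, model)
        if scale == "liability":
            if prevalence is None:
                raise ValueError("liability scale requires a prevalence")
            res = HeritabilityResult(
                liability_transform(res.h2, prevalence), res.ratio_v, res.ratio_w,
                "liability", res.model, res.flagged,
            )
        return res


def gibbs_varcomp(
    data: pd.DataFrame,
    pedigree: Pedigree | None = None,
    genetic: str | None = "sire_dam",
    litter: bool = True,
    maternal: bool = True,
    fixed: tuple = (),
    chain: dict | None = None,
) -> VarianceComponents:
    """Functional wrapper around :class:`GibbsVarianceComponents`."""
    chain = chain or {}
    est = GibbsVarianceComponents(
        genetic=genetic, litter=litter, maternal=maternal, fixed=tuple(fixed),
        n_iter=chain.get("n_iter", 2000), burn_in=chain.get("burn_in", 500),
        thin=chain.get("thin", 2), seed=chain.get("seed", 0),
    )
    return est.fit(data, pedigree).components_
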