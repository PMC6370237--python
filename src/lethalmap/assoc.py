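"""Carrier-effect association with a pedigree mixed model.

The genotype contrast of interest is carrier (GT) versus wild type (GG) —
with lethal homozygotes absent from the measured cohort the locus effect has
a single degree of freedom.  Each trait is analysed with

    y = 1 mu + X1 beta + X2 b + Z u + e,    u ~ MVN(0, A sigma2_a),

where b is the fixed genotype effect, X1 holds nuisance covariates, and A is
the numerator relationship matrix.  Writing lambda = sigma2_e / sigma2_a,
the covariance of y is sigma2_a * H with H = Z A Z' + lambda I; b and its
standard error come from generalised least squares at the REML-maximising
lambda (profiled over a log-spaced grid with golden-section refinement), and
significance from the 1-df Wald statistic (b / se)^2.

Effects are also reported standardised by the phenotypic SD (b / sigma_P),
and the share of additive genetic variance attributable to the locus is the
frequency-weighted variance of the genotype means divided by itself plus the
residual polygenic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .pedkin import Pedigree, a_matrix

__all__ = [
    "AssocResult",
    "MixedModelAssociation",
    "fit_association",
    "standardize_effect",
    "locus_variance_share",
]


@dataclass
class AssocResult:
    b: float
    se_b: float
    wald: float
    p_value: float
    b_std: float | None
    sigma_p: float
    lambda_: float
    sigma2_a: float
    sigma2_e: float
    ls_means: dict  # genotype least-squares means at covariate means
    n: int


def standardize_effect(b: float, sigma_p: float, ndigits: int | None = None) -> float:
    """Effect in phenotypic-SD units (b / sigma_P)."""
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    out = b / sigma_p
    return round(out, ndigits) if ndigits is not None else out


def locus_variance_share(freqs, means, sigma2_a_background: float) -> float:
    """Fraction of additive genetic variance explained by the locus.

    ``freqs`` and ``means`` are per-genotype frequencies (summing to 1) and
    trait means; the locus variance is the frequency-weighted variance of
    the means, and the share is locus / (locus + background polygenic).
    """
    f = np.asarray(freqs, dtype=float)
    m = np.asarray(means, dtype=float)
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("genotype frequencies must sum to 1")
    if sigma2_a_background < 0:
        raise ValueError("background variance must be >= 0")
    if np.count_nonzero(f) < 2 and sigma2_a_background == 0:
        raise ValueError("degenerate genotype frequencies")
    mbar = float(f @ m)
    v_locus = float(f @ (m - mbar) ** 2)
    denom = v_locus + sigma2_a_background
    return 0.0 if denom == 0 else v_locus / denom


class MixedModelAssociation(BaseEstimator):
    """GLS fit of the 1-df genotype effect with an A-structured polygenic
    term; lambda = sigma2_e / sigma2_a is REML-profiled unless given.

    ``fit(data, pedigree)`` expects columns ``y``, ``genotype`` (0 = GG,
    1 = GT), ``id``, plus any ``fixed`` covariate columns (categorical) and
    ``covariates`` (numeric).
    """

    def __init__(
        self,
        fixed: tuple = (),
        covariates: tuple = (),
        lambda_: float | None = None,
        grid: tuple = (1e-3, 1e3, 50),
    ):
        self.fixed = fixed
        self.covariates = covariates
        self.lambda_ = lambda_
        self.grid = grid

    def _design(self, data: pd.DataFrame) -> tuple[np.ndarray, int]:
        g = data["genotype"].to_numpy(dtype=float)
        if np.all(g == g[0]):
            raise ValueError("genotype column is constant")
        cols = [np.ones(len(data))]
        for f in self.fixed:
            levels, idx = np.unique(data[f].to_numpy(), return_inverse=True)
            for j in range(1, len(levels)):
                cols.append((idx == j).astype(float))
        for c in self.covariates:
            cols.append(data[c].to_numpy(dtype=float))
        cols.append(g)  # genotype last
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design")
        return X, X.shape[1] - 1

    @staticmethod
    def _reml_pieces(yt, Xt, evals, lam):
        """Profiled REML log-likelihood pieces at H = A + lambda*I, in the
        eigenbasis of A (yt = Q'y, Xt = Q'X, evals the eigenvalues)."""
        n, p = Xt.shape
        d = evals + lam
        Hi_y = yt / d
        Hi_X = Xt / d[:, None]
        XtHiX = Xt.T @ Hi_X
        beta = np.linalg.solve(XtHiX, Xt.T @ Hi_y)
        r = yt - Xt @ beta
        ypy = float(r @ (r / d))
        s2a = ypy / (n - p)
        logdet_H = float(np.log(d).sum())
        _, logdet_X = np.linalg.slogdet(XtHiX)
        ll = -0.5 * ((n - p) * np.log(s2a) + logdet_H + logdet_X + (n - p))
        return ll, beta, s2a, XtHiX

    def fit(self, data: pd.DataFrame, pedigree: Pedigree):
        y = data["y"].to_numpy(dtype=float)
        X, gcol = self._design(data)
        A = a_matrix(pedigree, list(data["id"])).to_numpy()
        n = len(y)
        evals, Q = np.linalg.eigh(A)
        evals = np.maximum(evals, 0.0)  # clip tiny negative round-off
        yt = Q.T @ y
        Xt = Q.T @ X

        def pieces(lam):
            return self._reml_pieces(yt, Xt, evals, lam)

        if self.lambda_ is not None:
            lam = float(self.lambda_)
        else:
            lo, hi, npts = self.grid
            grid = np.geomspace(lo, hi, int(npts))
            lls = [pieces(l)[0] for l in grid]
            k = int(np.argmax(lls))
            a = grid[max(k - 1, 0)]
            b_ = grid[min(k + 1, len(grid) - 1)]
            lam = _golden_section(lambda l: pieces(np.exp(l))[0], np.log(a), np.log(b_))
            lam = float(np.exp(lam))

        ll, beta, s2a, XtHiX = pieces(lam)
        cov_beta = s2a * np.linalg.inv(XtHiX)
        b = float(beta[gcol])
        se = float(np.sqrt(cov_beta[gcol, gcol]))
        wald = (b / se) ** 2
        p = float(stats.chi2.sf(wald, df=1))
        sigma_p = float(np.sqrt(s2a + s2a * lam))  # sigma2_a + sigma2_e

        # least-squares means: linear predictor at covariate means, per genotype
        xbar = X.mean(axis=0)
        x0, x1 = xbar.copy(), xbar.copy()
        x0[gcol], x1[gcol] = 0.0, 1.0
        ls_means = {"GG": float(x0 @ beta), "GT": float(x1 @ beta)}

        self.result_ = AssocResult(
            b=b, se_b=se, wald=float(wald), p_value=p,
            b_std=standardize_effect(b, sigma_p), sigma_p=sigma_p,
            lambda_=lam, sigma2_a=float(s2a), sigma2_e=float(s2a * lam),
            ls_means=ls_means, n=n,
        )
        self.reml_loglik_ = float(ll)
        return self


def _golden_section(f, a, b, tol=1e-4, max_iter=60):
    """Golden-section maximisation of a unimodal f on [a, b]."""
    phi = (np.sqrt(5) - 1) / 2
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    return (a + b) / 2


def fit_association(
    data: pd.DataFrame,
    pedigree: Pedigree,
    fixed: tuple = (),
    covariates: tuple = (),
    lambda_: float | None = None,
) -> AssocResult:
    """Functional wrapper around :class:`MixedModelAssociation`."""
    est = MixedModelAssociation(
        fixed=tuple(fixed), covariates=tuple(covariates), lambda_=lambda_
    )
    return est.fit(data, pedigree).result_
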