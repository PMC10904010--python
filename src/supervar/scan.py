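"""Covariate design construction and covariate-adjusted per-SNP association.

The design follows the imaging-GWAS convention: intercept, age, sex, site
indicators (one reference level dropped), age², age×sex, age²×sex and the
top 10 principal components — each term present only when its raw columns
exist in the cohort.  Per-SNP statistics come from ordinary least squares of
the phenotype on [design, dosage]; for speed the scan residualizes both the
phenotype and every dosage column against the design once (Frisch–Waugh),
which reproduces the joint-fit coefficient, standard error and t exactly,
using the joint fit's residual degrees of freedom n − p − 1.

Two-sided p-values use the t distribution with n − p − 1 degrees of freedom
rather than a normal approximation, so they are exact at small sample sizes.
Missing hard calls are mean-imputed per SNP at regression time only.
Monomorphic SNPs (zero dosage variance after imputation) are reported with
t = 0, p = 1 and flagged, so rankings stay total but such SNPs never lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genotypes import GenotypeMatrix

__all__ = ["CovariateDesign", "build_design", "marginal_stats", "ols_single"]

_RANK_TOL = 1e-8


@dataclass
class CovariateDesign:
    """A numeric design matrix with named columns and aligned sample ids."""

    X: np.ndarray
    columns: list[str]
    index: pd.Index
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> np.ndarray:
        """Orthonormal basis of the column space (cached QR factor)."""
        if not hasattr(self, "_q"):
            self._q, _ = np.linalg.qr(self.X)
        return self._q

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Project a vector/matrix onto the orthocomplement of the design."""
        q = self.q
        return v - q @ (q.T @ v)


def build_design(covariates: pd.DataFrame) -> CovariateDesign:
    """Build the regression design from a raw covariate table.

    Derived columns (age², age×sex, age²×sex) are formed here from the raw
    ``age``/``sex`` columns; ``site`` must be categorical or string-valued and
    contributes indicator columns with the first level as reference (a
    single-level site contributes nothing).  ``PC1..PC10`` enter as-is when
    present.  Rows with any missing covariate are dropped (count recorded on
    the result).  Raises if the assembled matrix is rank-deficient, naming
    the suspect columns.
    """
    cov = covariates.dropna()
    n_dropped = len(covariates) - len(cov)
    n = len(cov)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if "age" in cov:
        age = cov["age"].to_numpy(dtype=float)
        cols["age"] = age
    if "sex" in cov:
        sex = cov["sex"].to_numpy(dtype=float)
        cols["sex"] = sex
    if "site" in cov:
        site = cov["site"].astype("category")
        levels = [lv for lv in site.cat.categories if (site == lv).any()]
        for lv in levels[1:]:  # first observed level is the reference
            cols[f"site[{lv}]"] = (site == lv).to_numpy(dtype=float)
    if "age" in cov:
        cols["age2"] = age**2
        if "sex" in cov:
            cols["age_x_sex"] = age * sex
            cols["age2_x_sex"] = age**2 * sex
    for k in range(1, 11):
        name = f"PC{k}"
        if name in cov:
            cols[name] = cov[name].to_numpy(dtype=float)

    X = np.column_stack(list(cols.values()))
    names = list(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offenders via pivoted-QR diagonal decay
        from scipy.linalg import qr as _qr

        _, r, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < _RANK_TOL * max(diag[0], 1.0)]
        bad += [names[j] for j in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    return CovariateDesign(X, names, cov.index, n_dropped)


def _stats_from_residuals(
    gr: np.ndarray, yr: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(beta, se, t, p, monomorphic flag) from design-residualized g and y."""
    gr = np.atleast_2d(gr.T).T  # ensure (n, m)
    ss = np.einsum("ij,ij->j", gr, gr)
    mono = ss <= _RANK_TOL * gr.shape[0]
    ss_safe = np.where(mono, 1.0, ss)
    beta = (gr.T @ yr) / ss_safe
    rss = yr @ yr - beta**2 * ss_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / ss_safe)
        t = beta / se  # se == 0 with beta != 0 (perfect fit) -> +/- inf, p -> 0
    t = np.where(np.isnan(t), 0.0, t)
    beta = np.where(mono, 0.0, beta)
    t = np.where(mono, 0.0, t)
    se = np.where(mono, np.nan, se)
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p = np.where(mono, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    return beta, se, t, p, mono


def marginal_stats(
    gm: GenotypeMatrix, phenotype: pd.Series, design: CovariateDesign
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted OLS statistics for ranking.

    Samples are aligned to the design's index (phenotype and genotypes are
    subset accordingly).  Returns a DataFrame indexed like ``gm.snps`` with
    columns ``snp_id chrom pos beta se t p n monomorphic``; each row equals
    the joint OLS fit ``y ~ design + g`` for that SNP.
    """
    sub = gm.select_samples(design.index)
    y = phenotype.loc[design.index].to_numpy(dtype=float)
    G = sub.imputed()
    df = design.n - design.p - 1
    if df < 1:
        raise ValueError(f"not enough residual degrees of freedom (n={design.n}, p={design.p})")
    yr = design.residualize(y)
    Gr = design.residualize(G)
    beta, se, t, p, mono = _stats_from_residuals(Gr, yr, df)
    return pd.DataFrame(
        {
            "snp_id": gm.snps["id"].to_numpy(),
            "chrom": gm.snps["chrom"].to_numpy(),
            "pos": gm.snps["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "n": design.n,
            "monomorphic": mono,
        }
    )


def ols_single(
    x: np.ndarray, phenotype: np.ndarray, design: CovariateDesign,
    extra: np.ndarray | None = None,
) -> dict:
    """OLS statistics for one predictor adjusted for the design (+ extras).

    Returns a dict with beta/se/t/p/n/df for the coefficient of ``x`` in the
    joint fit ``y ~ design [+ extra] + x``; used for burden-score association
    and conditional tests.  If ``x`` is (numerically) in the span of the
    design and extras, the result is flagged ``collinear`` with t=0, p=1.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(x, dtype=float)
    if extra is not None and extra.size:
        extra = np.atleast_2d(extra.T).T
        Xfull = np.column_stack([design.X, extra])
        q, _ = np.linalg.qr(Xfull)
        resid = lambda v: v - q @ (q.T @ v)
        p_cols = Xfull.shape[1]
    else:
        resid = design.residualize
        p_cols = design.p
    df = len(y) - p_cols - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    xr = resid(x)
    yr = resid(y)
    beta, se, t, p, mono = _stats_from_residuals(xr[:, None], yr, df)
    return {
        "beta": float(beta[0]),
        "se": float(se[0]),
        "t": float(t[0]),
        "p": float(p[0]),
        "n": len(y),
        "df": df,
        "collinear": bool(mono[0]),
    }
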