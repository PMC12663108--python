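"""LD score regression: SNP-heritability and genetic correlation.

Under a polygenic model the expected association chi-square of variant j
grows linearly in its LD score l_j (the sum of squared correlations with
its neighbours):

    E[chi2_j] = N h2 l_j / M + intercept

so a weighted regression of chi2 on l separates true polygenic signal
(slope) from confounding (intercept, 1 under no confounding).  The
bivariate analogue regresses z1*z2 on l to estimate genetic covariance,
and r_g = gcov / sqrt(h1^2 * h2^2).  Standard errors come from a block
jackknife over contiguous variant blocks.

LD scores are computed in-sample from the genotype matrix with the usual
small-sample bias adjustment r~^2 = r^2 - (1 - r^2)/(n - 2), over a
window defined in variant count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gweis import ModelSpec, run_stratified

__all__ = [
    "LdScoreTable",
    "LdscEstimate",
    "CrossTraitEstimate",
    "StratumEstimate",
    "compute_ld_scores",
    "ldsc_h2",
    "ldsc_rg",
    "stratified_h2",
]


@dataclass
class LdScoreTable:
    scores: pd.DataFrame       # variant_id, ld_score
    window_variants: int
    n_ld: int

    @property
    def values(self) -> np.ndarray:
        return self.scores["ld_score"].to_numpy(dtype=float)


@dataclass
class LdscEstimate:
    h2: float
    se_h2: float
    intercept: float
    se_intercept: float
    n_blocks: int


@dataclass
class CrossTraitEstimate:
    rg: float
    se_rg: float
    gcov: float
    gcov_intercept: float


@dataclass
class StratumEstimate:
    label: object
    n: int
    h2: float
    se_h2: float


def compute_ld_scores(
    g: GenotypeMatrix, window_variants: int = 200
) -> LdScoreTable:
    """Bias-adjusted in-sample LD scores over a variant-count window.

    l_j sums the adjusted squared correlations of variant j with every
    same-chromosome variant within ``window_variants`` positions either
    side, including the self term (which the adjustment leaves at 1).
    """
    if window_variants < 1:
        raise ValueError("window_variants must be >= 1")
    n = g.n_samples
    if n < 50:
        raise ValueError("need at least 50 samples for stable LD scores")
    m = g.n_variants
    dos = np.array(g.dosage, dtype=float)
    miss = np.isnan(dos)
    if miss.any():
        mu = np.nanmean(dos, axis=0)
        dos[miss] = np.broadcast_to(mu, dos.shape)[miss]
    dos = dos - dos.mean(axis=0)
    sd = dos.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: zero correlation with everything
    dos /= sd

    chrom = g.variants["chrom"].to_numpy()
    ell = np.zeros(m)
    w = window_variants
    # chunked: correlations of a column block with its +/- w neighbourhood
    step = max(w, 256)
    for lo in range(0, m, step):
        hi = min(lo + step, m)
        nlo, nhi = max(0, lo - w), min(m, hi + w)
        r = dos[:, lo:hi].T @ dos[:, nlo:nhi] / n
        r2 = r * r
        adj = r2 - (1.0 - r2) / (n - 2)
        jj = np.arange(lo, hi)[:, None]
        kk = np.arange(nlo, nhi)[None, :]
        in_win = (np.abs(jj - kk) <= w) & (chrom[jj] == chrom[kk])
        ell[lo:hi] = np.where(in_win, adj, 0.0).sum(axis=1)
    table = pd.DataFrame({"variant_id": g.variants["id"], "ld_score": ell})
    return LdScoreTable(table, window_variants, n)


def _jackknife(theta_full: np.ndarray, theta_del: np.ndarray) -> np.ndarray:
    """Delete-one-block jackknife SE for each column of theta_del."""
    b = theta_del.shape[0]
    mean = theta_del.mean(axis=0)
    return np.sqrt((b - 1) / b * ((theta_del - mean) ** 2).sum(axis=0))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    xw = x * w[:, None]
    return np.linalg.solve(x.T @ xw, xw.T @ y)


def _ldsc_fit(
    y: np.ndarray, ell: np.ndarray, scale: float, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-step weighted LDSC regression of y on ell.

    ``scale`` = N/M (univariate) or sqrt(N1 N2)/M (bivariate).  Returns
    (slope_coef, intercept) on the h2/gcov scale plus delete-block
    estimates for the jackknife: ((h2, intercept), (B, 2) deletes).
    """
    m = len(y)
    if np.ptp(ell) == 0:
        raise ValueError("LD scores are constant; regression is degenerate")
    if n_blocks < 2 or m < 2 * n_blocks:
        raise ValueError("need >= 2 blocks and enough variants per block")
    x = np.column_stack([ell * scale, np.ones(m)])
    w1 = 1.0 / np.maximum(ell, 1.0)
    coef = _wls(x, y, w1)
    # second step: re-weight by the squared predicted mean (oversampling of
    # large-chi2 variants) times the heteroskedasticity weight
    pred = np.maximum(x @ coef, 0.1)
    w2 = 1.0 / (np.maximum(ell, 1.0) * pred**2)
    coef = _wls(x, y, w2)

    blocks = np.array_split(np.arange(m), n_blocks)
    deletes = np.empty((n_blocks, 2))
    for i, blk in enumerate(blocks):
        mask = np.ones(m, dtype=bool)
        mask[blk] = False
        deletes[i] = _wls(x[mask], y[mask], w2[mask])
    return coef, deletes


def ldsc_h2(
    chi2: np.ndarray,
    ld: LdScoreTable,
    n_gwas: int,
    m: int | None = None,
    n_blocks: int = 20,
) -> LdscEstimate:
    """Univariate LD score regression: chi2_j ~ 1 + (N h2 / M) l_j.

    ``chi2`` must be aligned with the LD score table.  Weights are the
    standard heteroskedasticity weights 1/max(l, 1), re-computed once from
    the first-pass fit; SEs are a delete-one block jackknife over
    ``n_blocks`` contiguous variant blocks.  The intercept is free — 1
    under no confounding.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = ld.values
    if chi2.shape != ell.shape:
        raise ValueError("chi2 and LD scores must be aligned")
    m = m if m is not None else len(chi2)
    scale = n_gwas / m
    coef, deletes = _ldsc_fit(chi2, ell, scale, n_blocks)
    se = _jackknife(coef, deletes)
    return LdscEstimate(
        h2=float(coef[0]),
        se_h2=float(se[0]),
        intercept=float(coef[1]),
        se_intercept=float(se[1]),
        n_blocks=n_blocks,
    )


def ldsc_rg(
    z1: np.ndarray,
    z2: np.ndarray,
    ld: LdScoreTable,
    n1: int,
    n2: int,
    m: int | None = None,
    n_blocks: int = 20,
) -> CrossTraitEstimate:
    """Bivariate LD score regression for the genetic correlation.

    z1_j z2_j ~ intercept + (sqrt(N1 N2) gcov / M) l_j estimates the
    genetic covariance; r_g = gcov / sqrt(h1^2 h2^2) with the univariate
    fits run on the same blocks, and the jackknife propagates through the
    ratio.  Estimation noise can push |r_g| slightly beyond 1.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    ell = ld.values
    if z1.shape != ell.shape or z2.shape != ell.shape:
        raise ValueError("z-scores and LD scores must be aligned")
    m = m if m is not None else len(z1)
    c1, d1 = _ldsc_fit(z1**2, ell, n1 / m, n_blocks)
    c2, d2 = _ldsc_fit(z2**2, ell, n2 / m, n_blocks)
    if c1[0] <= 0 or c2[0] <= 0:
        raise ValueError(
            f"undefined r_g: non-positive heritability estimates "
            f"(h1={c1[0]:.4g}, h2={c2[0]:.4g})"
        )
    cx, dx = _ldsc_fit(z1 * z2, ell, np.sqrt(n1 * n2) / m, n_blocks)
    rg = cx[0] / np.sqrt(c1[0] * c2[0])
    with np.errstate(invalid="ignore"):
        rg_del = dx[:, 0] / np.sqrt(np.maximum(d1[:, 0] * d2[:, 0], 1e-12))
    se = float(_jackknife(np.array([rg]), rg_del[:, None])[0])
    return CrossTraitEstimate(
        rg=float(rg), se_rg=se, gcov=float(cx[0]), gcov_intercept=float(cx[1])
    )


def stratified_h2(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    strata: np.ndarray | None = None,
    window_variants: int = 200,
    n_blocks: int = 20,
    min_stratum_size: int = 50,
) -> list[StratumEstimate]:
    """Marginal-test SNP-heritability per exposure/BMI stratum.

    Each stratum gets its own GWEIS (phenotype re-standardized within
    stratum) and its own LDSC fit with the stratum sample size; LD scores
    come from the full genotype matrix (the LD structure is shared).
    """
    ld = compute_ld_scores(g, window_variants)
    runs = run_stratified(g, cohort, spec, strata, min_stratum_size)
    out = []
    for lab in sorted(runs, key=str):
        res = runs[lab]
        chi2 = ((res["beta_marginal"] / res["se_marginal"]) ** 2).to_numpy()
        ok = np.isfinite(chi2)
        ld_use = ld
        if not ok.all():
            ld_use = LdScoreTable(
                ld.scores.loc[ok].reset_index(drop=True), ld.window_variants, ld.n_ld
            )
        est = ldsc_h2(
            chi2[ok], ld_use, n_gwas=int(res["n"].iloc[0]), n_blocks=n_blocks
        )
        out.append(StratumEstimate(lab, int(res["n"].iloc[0]), est.h2, est.se_h2))
    return out
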