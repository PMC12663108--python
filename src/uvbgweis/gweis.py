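"""Genome-wide gene-environment interaction testing engine.

For each variant three tests are reported on a standardized
log-transformed phenotype y:

* marginal:     y ~ b_marginal*G + covariates (exposure E among them);
                1-df Wald test of b_marginal.
* interaction:  y ~ b_G*G + b_GxE*(G*E) + covariates; 1-df Wald test of
                b_GxE.
* joint:        2-df Wald test of (b_G, b_GxE) in the interaction model —
                significant when there is a main and/or an interaction
                effect, the more powerful choice when the true mode of
                gene-environment action is unknown.

Both the model-based covariance sigma^2 (X'X)^-1 and the HC0 sandwich
(heteroskedasticity-consistent) covariance are computed and stored; which
one feeds the interaction/joint p-values is selectable (robust by
default, since an interaction on the log scale is exactly the kind of
scale misspecification the sandwich guards against).  The marginal test
always uses the model-based standard error, as in an ordinary GWAS.

``run_gweis`` takes a fast path: the phenotype and the per-variant
[G, G*E] columns are residualized against the shared covariates once
(Frisch-Waugh-Lovell), after which each variant costs a 2x2 solve.  The
result is algebraically identical to the per-variant full-design fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "ModelSpec",
    "DEFAULT_COVARIATES",
    "prepare_phenotype",
    "fit_variant",
    "run_gweis",
    "run_stratified",
    "exposure_quintiles",
    "bmi_category",
    "RESULT_COLUMNS",
]

LOD_NMOL_L = 10.0  # assay lower limit of detection for 25OHD

DEFAULT_COVARIATES = (
    ["age", "sex", "vitd_supp", "fishoil_supp"] + [f"pc{i}" for i in range(1, 11)]
)

RESULT_COLUMNS = [
    "chromosome", "base_pair_location", "variant_id", "effect_allele",
    "other_allele", "effect_allele_frequency", "n",
    "beta_marginal", "se_marginal", "p_marginal",
    "beta_g", "beta_gxe",
    "se_g_robust", "se_gxe_robust", "cov_g_gxe_robust",
    "se_g_model", "se_gxe_model", "cov_g_gxe_model",
    "p_int", "p_joint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Covariate set, exposure column, and testing conventions."""

    covariates: tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    exposure: str = "cwduvb"
    se_type: str = "robust"              # covariance for interaction/joint tests
    significance_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if self.se_type not in ("model", "robust"):
            raise ValueError("se_type must be 'model' or 'robust'")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance_threshold must be in (0,1)")

    @property
    def design_columns(self) -> list[str]:
        cols = list(self.covariates)
        if self.exposure not in cols:
            cols.append(self.exposure)
        return cols


def prepare_phenotype(raw: np.ndarray, lod: float = LOD_NMOL_L) -> np.ndarray:
    """Clamp at the assay detection limit, log-transform, z-score.

    The raw biomarker is right-skewed; values below the detection limit
    are set to it before the natural log, and the log values are
    standardized to mean 0, SD 1 against the analysis sample.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(~np.isfinite(raw)):
        raise ValueError("phenotype contains non-finite values")
    clamped = np.maximum(raw, lod)
    if np.any(clamped <= 0):
        raise ValueError("phenotype must be positive after clamping")
    logged = np.log(clamped)
    sd = logged.std()
    if sd == 0:
        raise ValueError("phenotype is constant; cannot standardize")
    return (logged - logged.mean()) / sd


def _covariate_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    missing = [c for c in spec.design_columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks covariate columns: {missing}")
    cov = cohort[spec.design_columns].to_numpy(dtype=float)
    intercept = np.ones((len(cohort), 1))
    c = np.hstack([intercept, cov])
    rank = np.linalg.matrix_rank(c)
    if rank < c.shape[1]:
        # name the offending columns via QR pivoting on the scaled design
        r = np.abs(np.diag(np.linalg.qr(c, mode="r")))
        bad = [
            (["intercept"] + list(spec.design_columns))[i]
            for i in np.nonzero(r < 1e-10 * r.max())[0]
        ]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return c


def _impute_mean(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float).copy()
    if g.ndim == 1:
        g = g[:, None]
    miss = np.isnan(g)
    if miss.any():
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(g, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        g[miss] = np.broadcast_to(mu, g.shape)[miss]
    return g


def fit_variant(
    dosage: np.ndarray,
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> dict:
    """Direct full-design least-squares fit of one variant (slow path).

    Missing dosages are mean-imputed.  Returns the per-variant statistics
    of both the marginal and the interaction model; raises on a constant
    dosage (no information) and on a rank-deficient design.
    """
    y = cohort["pheno_std"].to_numpy(dtype=float)
    c = _covariate_matrix(cohort, spec)
    g = _impute_mean(dosage)[:, 0]
    if len(g) != len(cohort):
        raise ValueError("dosage length does not match cohort size")
    if np.ptp(g) == 0:
        raise ValueError("constant dosage")
    e = cohort[spec.exposure].to_numpy(dtype=float)
    n, k = c.shape

    def ols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (n - x.shape[1])
        v_model = sigma2 * xtx_inv
        xe = x * resid[:, None]
        v_robust = xtx_inv @ (xe.T @ xe) @ xtx_inv
        return beta, v_model, v_robust, resid

    # marginal model: [G | 1 covars E]
    bm, vm_model, _, _ = ols(np.column_stack([g, c]))
    beta_marg = bm[0]
    se_marg = float(np.sqrt(vm_model[0, 0]))
    p_marg = float(stats.chi2.sf((beta_marg / se_marg) ** 2, 1))

    # interaction model: [G, G*E | 1 covars E]
    bi, vi_model, vi_rob, _ = ols(np.column_stack([g, g * e, c]))
    beta_g, beta_gxe = bi[0], bi[1]
    vmod = vi_model[:2, :2]
    vrob = vi_rob[:2, :2]
    v_test = vrob if spec.se_type == "robust" else vmod
    p_int = float(stats.chi2.sf(beta_gxe**2 / v_test[1, 1], 1))
    p_joint = float(stats.chi2.sf(_wald2(beta_g, beta_gxe, v_test), 2))

    return {
        "n": n,
        "effect_allele_frequency": float(np.mean(g) / 2.0),
        "beta_marginal": float(beta_marg),
        "se_marginal": se_marg,
        "p_marginal": p_marg,
        "beta_g": float(beta_g),
        "beta_gxe": float(beta_gxe),
        "se_g_robust": float(np.sqrt(vrob[0, 0])),
        "se_gxe_robust": float(np.sqrt(vrob[1, 1])),
        "cov_g_gxe_robust": float(vrob[0, 1]),
        "se_g_model": float(np.sqrt(vmod[0, 0])),
        "se_gxe_model": float(np.sqrt(vmod[1, 1])),
        "cov_g_gxe_model": float(vmod[0, 1]),
        "p_int": p_int,
        "p_joint": p_joint,
    }


def _wald2(b1: float, b2: float, v: np.ndarray) -> float:
    det = v[0, 0] * v[1, 1] - v[0, 1] ** 2
    return (b1 * b1 * v[1, 1] - 2 * b1 * b2 * v[0, 1] + b2 * b2 * v[0, 0]) / det


def run_gweis(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    chunk_size: int = 512,
) -> pd.DataFrame:
    """All-variant GWEIS via the covariate-residualized fast path.

    Samples are aligned by participant_id; a mismatch is an error listing
    the unmatched ids.  Constant-dosage variants appear in the output with
    NaN statistics and a ``skip_reason``.
    """
    cohort = align_cohort(g, cohort)
    y = cohort["pheno_std"].to_numpy(dtype=float)
    c = _covariate_matrix(cohort, spec)
    e = cohort[spec.exposure].to_numpy(dtype=float)
    n, k = c.shape

    q, _ = np.linalg.qr(c)
    y_t = y - q @ (q.T @ y)

    m = g.n_variants
    out = {name: np.full(m, np.nan) for name in RESULT_COLUMNS[5:]}
    skip = np.array([""] * m, dtype=object)

    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        gd = _impute_mean(g.dosage[:, lo:hi])
        const = np.ptp(gd, axis=0) == 0
        eaf = gd.mean(axis=0) / 2.0
        h = gd * e[:, None]
        gt = gd - q @ (q.T @ gd)
        ht = h - q @ (q.T @ h)

        sgg = np.einsum("ij,ij->j", gt, gt)
        sgy = gt.T @ y_t
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_m = sgy / sgg
        resid_m = y_t[:, None] - gt * beta_m
        rss_m = np.einsum("ij,ij->j", resid_m, resid_m)
        sigma2_m = rss_m / (n - k - 1)
        se_m = np.sqrt(sigma2_m / sgg)
        p_m = stats.chi2.sf((beta_m / se_m) ** 2, 1)

        a = sgg
        b = np.einsum("ij,ij->j", gt, ht)
        cc = np.einsum("ij,ij->j", ht, ht)
        d = sgy
        f = ht.T @ y_t
        det = a * cc - b * b
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (cc * d - b * f) / det
            beta_x = (a * f - b * d) / det
        resid = y_t[:, None] - gt * beta_g - ht * beta_x
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / (n - k - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_gg = cc / det
            inv_xx = a / det
            inv_gx = -b / det
        v_gg_mod = sigma2 * inv_gg
        v_xx_mod = sigma2 * inv_xx
        v_gx_mod = sigma2 * inv_gx

        r2 = resid * resid
        s_gg = np.einsum("ij,ij->j", gt * r2, gt)
        s_gh = np.einsum("ij,ij->j", gt * r2, ht)
        s_hh = np.einsum("ij,ij->j", ht * r2, ht)
        # A^-1 S A^-1, written out for the 2x2 case
        v_gg_rob = inv_gg * (s_gg * inv_gg + s_gh * inv_gx) + inv_gx * (
            s_gh * inv_gg + s_hh * inv_gx
        )
        v_gx_rob = inv_gg * (s_gg * inv_gx + s_gh * inv_xx) + inv_gx * (
            s_gh * inv_gx + s_hh * inv_xx
        )
        v_xx_rob = inv_gx * (s_gg * inv_gx + s_gh * inv_xx) + inv_xx * (
            s_gh * inv_gx + s_hh * inv_xx
        )

        if spec.se_type == "robust":
            tv_gg, tv_xx, tv_gx = v_gg_rob, v_xx_rob, v_gx_rob
        else:
            tv_gg, tv_xx, tv_gx = v_gg_mod, v_xx_mod, v_gx_mod
        with np.errstate(divide="ignore", invalid="ignore"):
            p_int = stats.chi2.sf(beta_x**2 / tv_xx, 1)
            tdet = tv_gg * tv_xx - tv_gx**2
            q2 = (
                beta_g**2 * tv_xx - 2 * beta_g * beta_x * tv_gx + beta_x**2 * tv_gg
            ) / tdet
            p_joint = stats.chi2.sf(q2, 2)

        sl = slice(lo, hi)
        out["n"][sl] = n
        out["effect_allele_frequency"][sl] = eaf
        out["beta_marginal"][sl] = beta_m
        out["se_marginal"][sl] = se_m
        out["p_marginal"][sl] = p_m
        out["beta_g"][sl] = beta_g
        out["beta_gxe"][sl] = beta_x
        out["se_g_robust"][sl] = np.sqrt(v_gg_rob)
        out["se_gxe_robust"][sl] = np.sqrt(v_xx_rob)
        out["cov_g_gxe_robust"][sl] = v_gx_rob
        out["se_g_model"][sl] = np.sqrt(v_gg_mod)
        out["se_gxe_model"][sl] = np.sqrt(v_xx_mod)
        out["cov_g_gxe_model"][sl] = v_gx_mod
        out["p_int"][sl] = p_int
        out["p_joint"][sl] = p_joint
        skip[sl][const] = "constant_dosage"
        for name in out:
            if name != "n":
                out[name][sl][const] = np.nan

    res = pd.DataFrame(
        {
            "chromosome": g.variants["chrom"].to_numpy(),
            "base_pair_location": g.variants["pos"].to_numpy(),
            "variant_id": g.variants["id"].to_numpy(),
            "effect_allele": g.variants["alt"].to_numpy(),
            "other_allele": g.variants["ref"].to_numpy(),
            **out,
        }
    )
    res["n"] = res["n"].astype(int)
    res["skip_reason"] = skip
    return res


def align_cohort(g: GenotypeMatrix, cohort: pd.DataFrame) -> pd.DataFrame:
    """Reorder the cohort table to the genotype sample order.

    Every genotyped sample must appear exactly once in the cohort table.
    """
    tab = cohort.set_index("participant_id", drop=False)
    missing = [s for s in g.sample_ids if s not in tab.index]
    if missing:
        raise ValueError(f"cohort table lacks genotyped samples: {missing[:10]}")
    return tab.loc[g.sample_ids].reset_index(drop=True)


def run_stratified(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    strata: pd.Series | np.ndarray | None = None,
    min_stratum_size: int = 50,
) -> dict[object, pd.DataFrame]:
    """Independent GWEIS per stratum, phenotype re-standardized within.

    ``strata`` is a per-sample label vector aligned with the cohort table
    (e.g. BMI category or exposure quintile).  Each stratum is analysed
    exactly as a full cohort would be.
    """
    cohort = align_cohort(g, cohort)
    labels = np.asarray(strata)
    if labels.shape[0] != len(cohort):
        raise ValueError("strata labels must align with the cohort")
    results: dict[object, pd.DataFrame] = {}
    for lab in pd.unique(labels):
        mask = labels == lab
        if mask.sum() < min_stratum_size:
            raise ValueError(
                f"stratum {lab!r} has {int(mask.sum())} samples "
                f"(< {min_stratum_size})"
            )
        sub = cohort.loc[mask].copy()
        sub["pheno_std"] = prepare_phenotype(sub["pheno_raw"].to_numpy())
        results[lab] = run_gweis(g.subset(sample_mask=mask), sub, spec)
    return results


def exposure_quintiles(values: np.ndarray) -> np.ndarray:
    """Quintile labels 1..5 from sample quantiles; ties broken by rank.

    A stable argsort makes the labelling deterministic: tied exposures are
    assigned in input order, so even a constant vector splits into five
    near-equal strata.  Labels are invariant under any strictly monotone
    transformation of the values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        raise ValueError("need at least 5 observations for quintiles")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 5) // n + 1


def bmi_category(bmi: np.ndarray) -> np.ndarray:
    """WHO-style labels: normal [18.5, 25), overweight [25, 30), obese >= 30."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.full(bmi.shape, "", dtype=object)
    out[(bmi >= 18.5) & (bmi < 25)] = "normal"
    out[(bmi >= 25) & (bmi < 30)] = "overweight"
    out[bmi >= 30] = "obese"
    return out
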