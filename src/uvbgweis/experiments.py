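"""Simulation studies exercising the pipeline end to end.

Each driver generates data under a declared condition, runs the relevant
pipeline stage, and returns plain dictionaries of measured quantities.
They are used by the numbered analysis scripts and by the acceptance
machinery; problem sizes are desk-scale study conditions chosen once:

* calibration and power studies run 2000 tests at n = 2000;
* heritability studies use n = 5000 samples and m = 2000 variants, with
  10 replicates per condition;
* variance-explained checks use n = 10000 with independent causal loci.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import GridSpec
from .genotypes import GenotypeMatrix
from .gweis import ModelSpec, exposure_quintiles, fit_variant, run_gweis
from .heritability import compute_ld_scores, ldsc_h2, ldsc_rg, stratified_h2
from .postgwas import stepwise_conditional_selection, variance_explained
from .simulate import SimConfig, simulate_cohort, simulate_genotypes, simulate_uvb_grid

__all__ = [
    "seasonal_contrast",
    "null_calibration",
    "power_ordering",
    "planted_effect_recovery",
    "stepwise_recovery",
    "ldsc_h2_recovery",
    "ldsc_null_calibration",
    "ldsc_rg_recovery",
    "h2_exposure_gradient",
    "variance_explained_check",
    "qc_plant_recovery",
    "discovery_replication_study",
]


def _seeds(seed: int, n: int) -> list[int]:
    """Derive per-replicate integer seeds below 2**31."""
    root = np.random.SeedSequence(seed)
    return [int(s) for s in root.generate_state(n) % (2**31 - 1)]


def _gamma_exposure(seed: int, n: int) -> pd.DataFrame:
    """Right-skewed cumulative UVB doses, gamma(5, 20) kJ/m^2."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i + 1:06d}" for i in range(n)],
            "cwduvb": rng.gamma(5.0, 20.0, n),
        }
    )


def _simulated_cohort(seed: int, **cfg_kwargs):
    cfg = SimConfig(seed=seed, **cfg_kwargs)
    g, _ = simulate_genotypes(cfg)
    exposures = _gamma_exposure(seed + 1, cfg.n_samples)
    cohort, truth = simulate_cohort(g, exposures, cfg)
    return g, cohort, truth


def seasonal_contrast(seed: int = 0) -> dict:
    """June/December monthly-mean daily doses at latitude 51.5 deg N.

    Clear-sky (noise off) over one leap year; the default calibration
    targets the printed London averages of 5.56 and 0.11 kJ/m^2.
    """
    grid = GridSpec(lat_min=51.375, lon_min=-0.375, n_lat=1, n_lon=1)
    gd = simulate_uvb_grid(grid, date(2008, 1, 1), 366, seed=seed,
                           cloud_noise=False)
    months = pd.date_range("2008-01-01", periods=366).month
    june = float(gd.dose[months == 6, 0, 0].mean())
    december = float(gd.dose[months == 12, 0, 0].mean())
    return {"june_mean": june, "december_mean": december,
            "ratio": june / december}


def null_calibration(seed: int = 0, n: int = 2000, m: int = 2000) -> dict:
    """Type-I error of the three tests on null linkage-equilibrium variants.

    Returns empirical rejection rates at alpha = 0.05 and the KS p-value
    of the joint-test p-values against uniform (equivalently, of the
    joint statistic against chi2 with 2 df).
    """
    g, cohort, _ = _simulated_cohort(
        seed, n_samples=n, n_variants=m, ld_rho=0.0, n_causal_main=0
    )
    res = run_gweis(g, cohort)
    out = {
        f"type1_{k}": float((res[p] < 0.05).mean())
        for k, p in (("marginal", "p_marginal"), ("interaction", "p_int"),
                     ("joint", "p_joint"))
    }
    out["ks_p_joint"] = float(stats.kstest(res["p_joint"], "uniform").pvalue)
    out["m"] = m
    return out


def power_ordering(
    seed: int = 0, n: int = 2000, n_reps: int = 200, beta_gxe: float = 0.07
) -> dict:
    """Power of the three tests under a pure-interaction model.

    Each replicate plants beta_G = 0, beta_GxE != 0 at one biallelic
    variant (MAF 0.3) and tests at alpha = 0.05.  The marginal test sees
    (essentially) nothing; the interaction and joint tests carry the
    signal, the joint paying one extra degree of freedom.
    """
    rng = np.random.default_rng(seed)
    cohort = _toy_cohort_frame(rng, n)
    e = cohort["cwduvb"].to_numpy()
    e_std = (e - e.mean()) / e.std()
    hits = {"marginal": 0, "interaction": 0, "joint": 0}
    for _ in range(n_reps):
        g = rng.binomial(2, 0.3, n).astype(float)
        y = beta_gxe * (g - g.mean()) * e_std + rng.standard_normal(n)
        cohort["pheno_std"] = (y - y.mean()) / y.std()
        row = fit_variant(g, cohort, ModelSpec())
        hits["marginal"] += row["p_marginal"] < 0.05
        hits["interaction"] += row["p_int"] < 0.05
        hits["joint"] += row["p_joint"] < 0.05
    return {f"power_{k}": v / n_reps for k, v in hits.items()} | {
        "n_reps": n_reps
    }


def _toy_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cohort = pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "age": rng.normal(57, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "vitd_supp": (rng.random(n) < 0.2).astype(float),
            "fishoil_supp": (rng.random(n) < 0.3).astype(float),
            "cwduvb": rng.gamma(5, 20, n),
        }
    )
    for i in range(1, 11):
        cohort[f"pc{i}"] = rng.standard_normal(n)
    cohort["pheno_std"] = rng.standard_normal(n)
    return cohort


def planted_effect_recovery(
    seed: int = 0, n: int = 2000, maf: float = 0.3, beta: float = 0.3
) -> dict:
    """Recover a planted main effect; reports the standardized-scale error.

    The fit runs on a standardized phenotype, so the planted dosage-scale
    effect is compared after rescaling by the realized phenotype SD.
    """
    rng = np.random.default_rng(seed)
    cohort = _toy_cohort_frame(rng, n)
    g = rng.binomial(2, maf, n).astype(float)
    y = beta * g + rng.standard_normal(n)
    cohort["pheno_std"] = (y - y.mean()) / y.std()
    row = fit_variant(g, cohort, ModelSpec())
    target = beta / y.std()
    return {
        "beta_hat": row["beta_marginal"],
        "se": row["se_marginal"],
        "target": target,
        "abs_error_in_se": abs(row["beta_marginal"] - target) / row["se_marginal"],
    }


def stepwise_recovery(seed: int = 0, n: int = 5000) -> dict:
    """Conditional selection: two unlinked causals and an r2 = 1 pair.

    Variant layout: v0 (causal), v1 = exact copy of v0, v2 (causal,
    unlinked), v3..v5 noise.  Correct behaviour selects exactly two
    variants — one member of the perfect-LD pair plus the second causal.
    """
    rng = np.random.default_rng(seed)
    cohort = _toy_cohort_frame(rng, n)
    g0 = rng.binomial(2, 0.4, n).astype(float)
    g2 = rng.binomial(2, 0.3, n).astype(float)
    noise = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
    dosage = np.column_stack([g0, g0, g2, noise])
    y = 0.25 * g0 + 0.25 * g2 + rng.standard_normal(n)
    cohort["pheno_std"] = (y - y.mean()) / y.std()
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_000 * (np.arange(6) + 1),
            "id": [f"v{j}" for j in range(6)],
            "ref": "A",
            "alt": "G",
            "info_score": 1.0,
        }
    )
    g = GenotypeMatrix(cohort["participant_id"].to_numpy(object), variants, dosage)
    sel = stepwise_conditional_selection(g, cohort)
    n_from_pair = sum(v in ("v0", "v1") for v in sel.ids)
    return {
        "selected": sel.ids,
        "n_selected": len(sel.ids),
        "n_from_perfect_ld_pair": n_from_pair,
        "second_causal_selected": "v2" in sel.ids,
    }


def _marginal_chi2(res: pd.DataFrame) -> np.ndarray:
    return ((res["beta_marginal"] / res["se_marginal"]) ** 2).to_numpy()


def ldsc_h2_recovery(
    seed: int = 0,
    h2: float = 0.10,
    n: int = 5000,
    m: int = 2000,
    n_reps: int = 10,
) -> dict:
    """Mean LDSC heritability estimate for a polygenic trait of known h2.

    The trait is purely genetic plus noise (no exposure or covariate
    effects): a GWAS adjusts covariates out, so any non-genetic signal
    would redefine the target as the heritability of the adjusted trait,
    h2 / (1 - covariate share), rather than h2 itself.  LD blocks of 10
    variants give 200 independent LD units at the default m, enough
    clusters for the 20-block jackknife and the slope to be well
    estimated.
    """
    ests, intercepts = [], []
    for s in _seeds(seed, n_reps):
        g, cohort, truth = _simulated_cohort(
            s, n_samples=n, n_variants=m, h2_target=h2, n_causal_main=m,
            gxe_strength=0.0, env_strength=0.0, covariate_effects=(),
            block_size=10,
        )
        res = run_gweis(g, cohort)
        ld = compute_ld_scores(g, 200)
        est = ldsc_h2(_marginal_chi2(res), ld, n_gwas=n)
        ests.append(est.h2)
        intercepts.append(est.intercept)
    return {
        "h2_true": h2,
        "h2_mean": float(np.mean(ests)),
        "h2_sd": float(np.std(ests)),
        "intercept_mean": float(np.mean(intercepts)),
        "estimates": ests,
        "n_reps": n_reps,
    }


def ldsc_null_calibration(seed: int = 0, n: int = 5000, m: int = 2000) -> dict:
    """Null trait: slope-implied h2 ~ 0 and intercept ~ 1."""
    g, cohort, _ = _simulated_cohort(
        seed, n_samples=n, n_variants=m, n_causal_main=0, gxe_strength=0.0
    )
    res = run_gweis(g, cohort)
    ld = compute_ld_scores(g, 200)
    est = ldsc_h2(_marginal_chi2(res), ld, n_gwas=n)
    return {
        "h2": est.h2, "se_h2": est.se_h2,
        "intercept": est.intercept, "se_intercept": est.se_intercept,
    }


def ldsc_rg_recovery(
    seed: int = 0,
    rg: float = 0.5,
    h2: float = 0.5,
    n: int = 5000,
    m: int = 3000,
    n_reps: int = 10,
) -> dict:
    """Bivariate LDSC on trait pairs with genetically correlated effects.

    Strongly heritable traits keep the denominator sqrt(h1^2 h2^2) away
    from zero, where the correlation ratio becomes unstable.

    Both traits are scanned on the same genotype panel; their causal
    effect vectors are correlated at the target r_g and their noises are
    independent.  The shared samples inflate only the gcov intercept,
    which the regression leaves free — exactly the role it plays for
    overlapping GWAS cohorts.
    """
    ests = []
    for s in _seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        cfg = SimConfig(seed=s, n_samples=n, n_variants=m)
        g, _ = simulate_genotypes(cfg)
        gs = (g.dosage - g.dosage.mean(0)) / g.dosage.std(0)
        ld = compute_ld_scores(g, 200)
        b1 = rng.standard_normal(m)
        b2 = rg * b1 + np.sqrt(1 - rg**2) * rng.standard_normal(m)
        zs = []
        for b in (b1, b2):
            b = b * np.sqrt(h2 / m)
            y = gs @ b + rng.normal(0, np.sqrt(1 - h2), n)
            cohort = _toy_cohort_frame(rng, n)
            cohort["participant_id"] = g.sample_ids
            cohort["pheno_std"] = (y - y.mean()) / y.std()
            res = run_gweis(g, cohort)
            zs.append((res["beta_marginal"] / res["se_marginal"]).to_numpy())
        est = ldsc_rg(zs[0], zs[1], ld, n, n)
        ests.append(est.rg)
    return {
        "rg_true": rg,
        "rg_mean": float(np.mean(ests)),
        "rg_sd": float(np.std(ests)),
        "estimates": ests,
        "n_reps": n_reps,
    }


def h2_exposure_gradient(
    seed: int = 0,
    architecture: str = "amplification",
    kappa: float = 0.5,
    h2: float = 0.2,
    n: int = 5000,
    m: int = 2000,
    n_reps: int = 10,
) -> dict:
    """Stratified SNP-heritability across exposure quintiles.

    Under amplification (effects scaled by 1 + kappa * E_std) detectable
    heritability should rise with the exposure; under an additive-only
    architecture there is no systematic trend.
    """
    per_q = np.zeros((n_reps, 5))
    for i, s in enumerate(_seeds(seed, n_reps)):
        g, cohort, _ = _simulated_cohort(
            s, n_samples=n, n_variants=m, h2_target=h2, n_causal_main=200,
            architecture=architecture, kappa=kappa if architecture ==
            "amplification" else 0.0, gxe_strength=0.0,
        )
        labels = exposure_quintiles(cohort["cwduvb"].to_numpy())
        strata = stratified_h2(g, cohort, strata=labels)
        for est in strata:
            per_q[i, int(est.label) - 1] = est.h2
    mean_q = per_q.mean(axis=0)
    slopes = np.polyfit(np.arange(1, 6), per_q.T, 1)[0]
    return {
        "architecture": architecture,
        "kappa": kappa if architecture == "amplification" else 0.0,
        "h2_by_quintile": mean_q.tolist(),
        "q5_minus_q1": float(mean_q[4] - mean_q[0]),
        "slope_mean": float(slopes.mean()),
        "slope_se": float(slopes.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def qc_plant_recovery(seed: int, work_dir) -> dict:
    """Plant one QC failure of each kind and count what QC removes.

    The bundle plants a duplicate sample, a heterozygosity-outlier sample,
    a high-missingness variant, and an all-heterozygote (HWE-violating)
    variant on top of a clean background.
    """
    from pathlib import Path

    from .genotypes import read_genotypes
    from .qc import apply_qc
    from .simulate import make_fixture_bundle

    cfg = SimConfig(seed=seed, n_samples=80, n_variants=2000,
                    maf_range=(0.1, 0.5), n_causal_main=10)
    paths = make_fixture_bundle(cfg, Path(work_dir) / "bundle")
    g = read_genotypes(paths["genotypes"])
    _, report = apply_qc(g)
    planted = {"kinship": 1, "heterozygosity": 1, "missingness": 1, "hwe": 1}
    removed = dict(report.samples_removed) | dict(report.variants_removed)
    return {
        "n_planted": sum(planted.values()),
        "n_recovered": sum(min(removed.get(k, 0), v) for k, v in planted.items()),
        "n_extra_removals": sum(removed.values()) - sum(planted.values()),
        "n_samples": g.n_samples,
        "n_variants": g.n_variants,
        "removed_by_reason": removed,
    }


def discovery_replication_study(
    seed: int, n: int = 6000, m: int = 1000
) -> dict:
    """Discovery scan, variant selection, split-sample replication, GRS.

    One cohort with locus-specific interactions is split in half; the
    discovery half supplies lead variants (joint-test clumping) and
    conditionally independent variants, the replication half checks effect
    signs and carries the age/sex-adjusted risk-score evaluation.
    """
    from .postgwas import (
        build_risk_scores,
        clump_leads,
        evaluate_risk_scores,
        sign_concordance_test,
    )
    from .gweis import prepare_phenotype

    cfg = SimConfig(seed=seed, n_samples=n, n_variants=m, h2_target=0.3,
                    n_causal_main=25, n_causal_gxe=12,
                    architecture="interaction", gxe_strength=0.05)
    g, _ = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    exposures = pd.DataFrame(
        {"participant_id": g.sample_ids, "cwduvb": rng.gamma(5.0, 20.0, n)}
    )
    cohort, _truth = simulate_cohort(g, exposures, cfg)

    half = n // 2
    disc_mask = np.zeros(n, dtype=bool)
    disc_mask[rng.permutation(n)[:half]] = True
    spec = ModelSpec()

    def scan(mask):
        sub = cohort.loc[mask].copy()
        sub["pheno_std"] = prepare_phenotype(sub["pheno_raw"].to_numpy())
        return sub, run_gweis(g.subset(sample_mask=mask), sub, spec)

    disc_cohort, disc = scan(disc_mask)
    repl_cohort, repl = scan(~disc_mask)

    thr = spec.significance_threshold
    out = {
        "n_discovery": half,
        "n_replication": n - half,
        "n_significant_marginal": int((disc["p_marginal"] < thr).sum()),
        "n_significant_interaction": int((disc["p_int"] < thr).sum()),
        "n_significant_joint": int((disc["p_joint"] < thr).sum()),
    }
    from .postgwas import stepwise_conditional_selection

    leads = clump_leads(disc, g.subset(sample_mask=disc_mask), "p_joint",
                        thr, 0.1)
    cojo = stepwise_conditional_selection(
        g.subset(sample_mask=disc_mask), disc_cohort, spec
    )
    out["n_lead_variants_joint"] = len(leads.ids)
    out["n_conditionally_independent"] = len(cojo.ids)

    sel_ids = leads.ids if leads.ids else list(
        disc.sort_values("p_joint")["variant_id"].head(10)
    )
    d = disc.set_index("variant_id").loc[sel_ids]
    r = repl.set_index("variant_id").loc[sel_ids]
    summary = sign_concordance_test(
        d["beta_marginal"].to_numpy(), r["beta_marginal"].to_numpy()
    )
    out["sign_concordance_fraction"] = summary.n_concordant / summary.n_total
    out["sign_concordance_binomial_p"] = summary.p_binom
    out["beta_correlation"] = summary.pearson_r
    out["n_overlapping_leads"] = summary.n_total

    weights = d.reset_index()[
        ["variant_id", "effect_allele", "beta_marginal", "beta_g", "beta_gxe"]
    ]
    repl_geno = g.subset(sample_mask=~disc_mask)
    scores = build_risk_scores(repl_geno, weights,
                               repl_cohort["cwduvb"].to_numpy())
    evaluation = evaluate_risk_scores(scores, repl_cohort).set_index("score")
    out["grs_marginal_slope_nmol_per_unit"] = float(
        evaluation.loc["marginal_score", "slope_nmol_per_unit"]
    )
    out["grs_interaction_slope_nmol_per_unit"] = float(
        evaluation.loc["interaction_score", "slope_nmol_per_unit"]
    )
    out["grs_marginal_decile_contrast_nmol"] = float(
        evaluation.loc["marginal_score", "top_vs_bottom_decile_nmol"]
    )
    out["grs_interaction_decile_contrast_nmol"] = float(
        evaluation.loc["interaction_score", "top_vs_bottom_decile_nmol"]
    )
    return out


def variance_explained_check(
    seed: int = 0, n: int = 10_000, m: int = 30
) -> dict:
    """2 beta^2 f (1-f) summed over independent causal SNPs vs empirical R^2."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.5, m)
    dosage = (rng.random((n, m)) < f).astype(float) + (rng.random((n, m)) < f)
    beta = rng.normal(0, 0.05, m)
    y = dosage @ beta + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    betas_marg = np.array(
        [np.cov(dosage[:, j], y)[0, 1] / np.var(dosage[:, j]) for j in range(m)]
    )
    freqs = dosage.mean(axis=0) / 2
    total = variance_explained(betas_marg, freqs).attrs["total"]
    x = np.column_stack([dosage, np.ones(n)])
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    r2_emp = float(1 - resid @ resid / (y @ y))
    return {
        "sum_2b2f1f": float(total),
        "empirical_r2": r2_emp,
        "relative_error": abs(total - r2_emp) / r2_emp,
        "n": n,
    }
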