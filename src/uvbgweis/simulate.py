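"""Synthetic genotypes, UVB dose grids, and cohorts with known truth.

Every pipeline stage is testable without any external download:

* Genotypes — per haplotype, a latent standard-normal AR(1) series within
  LD blocks (independence across blocks) is thresholded at the
  allele-frequency quantile; the dosage is the sum of two independent
  haplotypes, so Hardy-Weinberg equilibrium holds by construction and the
  within-block squared correlation is tunable through the autocorrelation.
* Ambient UVB — a clear-sky dose proportional to a power of the noon
  solar elevation, which at UK latitudes produces the observed roughly
  50-fold June/December contrast, multiplied by lognormal day-to-day
  cloud noise.
* Cohort — a standardized latent phenotype assembled from main genetic,
  exposure, gene-environment interaction, and covariate effects plus
  noise, exponentiated into a right-skewed raw biomarker clamped at the
  assay detection limit.  Under the ``amplification`` architecture every
  causal main effect is scaled by (1 + kappa * E_std), i.e. beta_GxE is
  proportional to beta_G genome-wide; under ``interaction`` the GxE
  effects are locus-specific and independent of the main effects.

Randomness is fully deterministic under the config seed, with separate
spawned streams per component and per genotype block, so enlarging one
part of the simulation does not perturb the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import (
    DailyDoseGrid,
    GridSpec,
    ResidenceRecord,
    WeightingParams,
    build_exposure_table,
    write_dose_grid,
)
from .genotypes import GenotypeMatrix, write_genotypes
from .gweis import bmi_category, prepare_phenotype

__all__ = [
    "SimConfig",
    "UvbCalibration",
    "simulate_genotypes",
    "simulate_uvb_grid",
    "simulate_residences",
    "simulate_cohort",
    "make_fixture_bundle",
]

# log-scale location/spread of the raw biomarker (median ~47 nmol/L,
# right-skewed, matching population 25OHD distributions)
_LOG_MU = 3.85
_LOG_SIGMA = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters; the defaults are the study conditions."""

    seed: int = 0
    n_samples: int = 2000
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.01, 0.5)
    # latent AR(1) autocorrelation; a scalar fixes it for every block, a
    # (lo, hi) pair draws one value per block — heterogeneous LD across
    # loci, as in real genomes, which also gives LD scores the spread that
    # LD score regression needs for identification
    ld_rho: float | tuple[float, float] = (0.0, 0.95)
    block_size: int = 20
    n_causal_main: int = 20
    n_causal_gxe: int = 10
    h2_target: float = 0.10           # variance share of main genetic effects
    gxe_strength: float = 0.05        # variance share of interaction terms
    env_strength: float = 0.12        # variance share of the exposure itself
    architecture: str = "additive"    # additive | interaction | amplification
    kappa: float = 0.0                # amplification slope on standardized E
    covariate_effects: tuple[tuple[str, float], ...] = (
        ("age", -0.005), ("sex", -0.05), ("vitd_supp", 0.15),
        ("fishoil_supp", 0.10),
    )
    noise_sd: float | None = None     # residual SD; None -> fill to unit variance

    def __post_init__(self) -> None:
        if self.architecture not in ("additive", "interaction", "amplification"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not (0 < self.h2_target < 1 and 0 <= self.gxe_strength < 1):
            raise ValueError("h2_target in (0,1), gxe_strength in [0,1)")
        if self.h2_target + self.gxe_strength + self.env_strength >= 1:
            raise ValueError("variance shares must sum below 1")
        rho = self.ld_rho if isinstance(self.ld_rho, tuple) else (self.ld_rho,)
        if not all(0 <= r < 1 for r in rho) or (
            len(rho) == 2 and rho[0] > rho[1]
        ):
            raise ValueError("ld_rho values must lie in [0, 1) with lo <= hi")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass(frozen=True)
class UvbCalibration:
    """Clear-sky dose = scale * max(sin(noon elevation), 0)^gamma.

    The defaults put the June and December monthly-mean daily doses at
    latitude 51.5 deg N at 5.56 and 0.11 kJ/m^2 — the observed ~50-fold
    seasonal contrast for London.
    """

    scale_kjm2: float = 8.484
    gamma: float = 3.284
    cloud_noise_sd: float = 0.4       # SD of log cloud multiplier (mean 1)


# fixed registry: every component owns one position in the root spawn, so
# the same stream is never handed to two components and adding draws to one
# component never perturbs another
_STREAM_NAMES = (
    "genotypes", "uvb", "residences", "effects", "covariates", "noise",
    "qc_plants",
)


def _streams(seed: int, *names: str) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAM_NAMES))
    table = dict(zip(_STREAM_NAMES, children))
    unknown = set(names) - set(table)
    if unknown:
        raise KeyError(f"unknown stream names: {sorted(unknown)}")
    return {n: table[n] for n in names}


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """LD-block genotype dosages; returns (matrix, per-variant block index).

    Each block draws from its own spawned random stream, so the content of
    block b never depends on how many blocks follow it.
    """
    ss = _streams(config.seed, "genotypes")["genotypes"]
    n, m, bs = config.n_samples, config.n_variants, config.block_size
    n_blocks = math.ceil(m / bs)
    block_seeds = ss.spawn(n_blocks)
    lo_f, hi_f = config.maf_range

    dosage = np.empty((n, m))
    block_of = np.empty(m, dtype=int)
    for b in range(n_blocks):
        j0, j1 = b * bs, min((b + 1) * bs, m)
        w = j1 - j0
        rng = np.random.default_rng(block_seeds[b])
        if isinstance(config.ld_rho, tuple):
            rho = float(rng.uniform(*config.ld_rho))
        else:
            rho = float(config.ld_rho)
        freqs = rng.uniform(lo_f, hi_f, size=w)
        thresh = stats.norm.ppf(freqs)
        hap_sum = np.zeros((n, w))
        for _hap in range(2):
            eps = rng.standard_normal((n, w))
            z = np.empty((n, w))
            z[:, 0] = eps[:, 0]
            for t in range(1, w):
                z[:, t] = rho * z[:, t - 1] + math.sqrt(1 - rho * rho) * eps[:, t]
            hap_sum += z < thresh
        dosage[:, j0:j1] = hap_sum
        block_of[j0:j1] = b

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 10_000 * (np.arange(m) + 1),
            "id": [f"rs{j + 1}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "info_score": 1.0,
        }
    )
    sample_ids = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(sample_ids, variants, dosage), block_of


def _noon_sin_elevation(lat_deg: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """sin of noon solar elevation, shape (n_days, n_lat)."""
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.25))
    lat = np.deg2rad(lat_deg)
    out = np.sin(lat)[None, :] * np.sin(decl)[:, None] + np.cos(lat)[None, :] * np.cos(
        decl
    )[:, None]
    return np.clip(out, 0.0, None)


def simulate_uvb_grid(
    grid: GridSpec,
    start_date: date,
    n_days: int,
    calibration: UvbCalibration = UvbCalibration(),
    seed: int = 0,
    cloud_noise: bool = True,
) -> DailyDoseGrid:
    """Seasonal daily UVB doses on a grid, optionally with cloud noise.

    The clear-sky dose follows the calibrated power of the noon solar
    elevation (peaked at the summer solstice, amplitude falling with
    latitude); cloud noise multiplies each day/cell by an independent
    mean-1 lognormal factor.
    """
    if n_days < 1:
        raise ValueError("date range must contain at least one day")
    rng = np.random.default_rng(_streams(seed, "uvb")["uvb"])
    doy = np.array(
        [
            (start_date + timedelta(days=d)).timetuple().tm_yday
            for d in range(n_days)
        ],
        dtype=float,
    )
    lat_centers = np.array(
        [grid.cell_center(i, 0)[0] for i in range(grid.n_lat)]
    )
    sin_el = _noon_sin_elevation(lat_centers, doy)  # (n_days, n_lat)
    clear = calibration.scale_kjm2 * sin_el**calibration.gamma
    dose = np.repeat(clear[:, :, None], grid.n_lon, axis=2)
    if cloud_noise and calibration.cloud_noise_sd > 0:
        s = calibration.cloud_noise_sd
        mult = rng.lognormal(-0.5 * s * s, s, size=dose.shape)
        dose = dose * mult
    return DailyDoseGrid(grid=grid, start_date=start_date, dose=dose)


def simulate_residences(
    n: int,
    grid: GridSpec,
    first_sample_date: date,
    last_sample_date: date,
    seed: int = 0,
) -> list[ResidenceRecord]:
    """Uniform residences inside the grid with uniform sampling dates."""
    rng = np.random.default_rng(_streams(seed, "residences")["residences"])
    span = (last_sample_date - first_sample_date).days
    lat_hi = np.nextafter(grid.lat_max, -np.inf)
    lon_hi = np.nextafter(grid.lon_max, -np.inf)
    recs = []
    for i in range(n):
        lat = min(rng.uniform(grid.lat_min, grid.lat_max), lat_hi)
        lon = min(rng.uniform(grid.lon_min, grid.lon_max), lon_hi)
        offset = int(rng.integers(0, span + 1))
        recs.append(
            ResidenceRecord(
                participant_id=f"S{i + 1:06d}",
                sample_date=first_sample_date + timedelta(days=offset),
                lat_deg=float(lat),
                lon_deg=float(lon),
            )
        )
    return recs


def simulate_cohort(
    g: GenotypeMatrix,
    exposures: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype + covariates from genotypes and exposures, with truth.

    Returns (cohort, truth).  The latent standardized phenotype is

        z = sum_j bG_j g~_j + gamma E_std + sum_j bGxE_j g~_j E_std
            + covariates + eps

    with g~ the standardized dosage; effect vectors are scaled so the
    realized variance shares match the config targets at the simulated
    sample.  Raw 25OHD = exp(mu + sigma z) clamped at the 10 nmol/L
    detection limit.
    """
    streams = _streams(config.seed, "effects", "covariates", "noise")
    exp_tab = exposures.set_index("participant_id")
    missing = [s for s in g.sample_ids if s not in exp_tab.index]
    if missing:
        raise ValueError(f"exposure table lacks samples: {missing[:10]}")
    e_raw = exp_tab.loc[g.sample_ids, "cwduvb"].to_numpy(dtype=float)
    if e_raw.std() == 0:
        raise ValueError("exposure is constant; cannot standardize")
    e_std = (e_raw - e_raw.mean()) / e_raw.std()

    n, m = g.n_samples, g.n_variants
    dos = np.array(g.dosage, dtype=float)
    mu_d = np.nanmean(dos, axis=0)
    miss = np.isnan(dos)
    if miss.any():
        dos[miss] = np.broadcast_to(mu_d, dos.shape)[miss]
    sd_d = dos.std(axis=0)
    sd_d[sd_d == 0] = 1.0
    g_std = (dos - dos.mean(axis=0)) / sd_d

    rng_eff = np.random.default_rng(streams["effects"])
    beta_g = np.zeros(m)
    beta_gxe = np.zeros(m)
    causal_main = rng_eff.choice(m, size=min(config.n_causal_main, m), replace=False)
    beta_g[causal_main] = rng_eff.standard_normal(len(causal_main))
    g_comp = g_std @ beta_g
    if g_comp.std() > 0:
        beta_g *= math.sqrt(config.h2_target) / g_comp.std()
        g_comp = g_std @ beta_g

    if config.architecture == "amplification":
        beta_gxe = config.kappa * beta_g
        gxe_comp = (g_std @ beta_gxe) * e_std
    elif config.architecture == "interaction" and config.n_causal_gxe > 0:
        causal_gxe = rng_eff.choice(m, size=min(config.n_causal_gxe, m), replace=False)
        beta_gxe[causal_gxe] = rng_eff.standard_normal(len(causal_gxe))
        gxe_comp = (g_std @ beta_gxe) * e_std
        if gxe_comp.std() > 0:
            beta_gxe *= math.sqrt(config.gxe_strength) / gxe_comp.std()
            gxe_comp = (g_std @ beta_gxe) * e_std
    else:
        gxe_comp = np.zeros(n)

    rng_cov = np.random.default_rng(streams["covariates"])
    cov = pd.DataFrame(
        {
            "age": rng_cov.normal(57.0, 8.0, n),
            "sex": rng_cov.integers(0, 2, n).astype(float),
            "vitd_supp": (rng_cov.random(n) < 0.2).astype(float),
            "fishoil_supp": (rng_cov.random(n) < 0.3).astype(float),
            "bmi": np.clip(rng_cov.normal(27.0, 4.5, n), 15.0, None),
            "outdoors_hours": np.clip(rng_cov.normal(2.5, 1.5, n), 0.0, None),
        }
    )
    for i in range(1, 11):
        cov[f"pc{i}"] = rng_cov.standard_normal(n)

    cov_comp = np.zeros(n)
    for name, eff in config.covariate_effects:
        cov_comp = cov_comp + eff * cov[name].to_numpy()
    cov_comp = cov_comp - cov_comp.mean()

    gamma_env = math.sqrt(config.env_strength)
    env_comp = gamma_env * e_std

    explained = np.var(g_comp) + np.var(gxe_comp) + np.var(env_comp) + np.var(cov_comp)
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    else:
        noise_sd = math.sqrt(max(1.0 - explained, 0.05))
    rng_noise = np.random.default_rng(streams["noise"])
    eps = noise_sd * rng_noise.standard_normal(n)

    z = g_comp + env_comp + gxe_comp + cov_comp + eps
    raw = np.maximum(np.exp(_LOG_MU + _LOG_SIGMA * z), 10.0)

    cohort = pd.DataFrame({"participant_id": g.sample_ids})
    cohort["pheno_raw"] = raw
    cohort["pheno_std"] = prepare_phenotype(raw)
    cohort["cwduvb"] = e_raw
    for c in cov.columns:
        cohort[c] = cov[c].to_numpy()
    cohort["bmi_category"] = bmi_category(cohort["bmi"].to_numpy())

    var_z = float(np.var(z))
    truth = pd.DataFrame(
        {
            "variant_id": g.variants["id"],
            "beta_g": beta_g,
            "beta_gxe": beta_gxe,
            "causal_main": beta_g != 0,
            "causal_gxe": beta_gxe != 0,
        }
    )
    truth.attrs["realized_h2"] = float(np.var(g_comp)) / var_z
    truth.attrs["realized_gxe_share"] = float(np.var(gxe_comp)) / var_z
    truth.attrs["realized_env_share"] = float(np.var(env_comp)) / var_z
    truth.attrs["noise_sd"] = float(noise_sd)
    return cohort, truth


def genetic_variance_by_stratum(
    g_comp_like: np.ndarray, labels: np.ndarray, z: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-stratum variance of a (true) genetic component; helper for
    inspecting amplification architectures before any estimation."""
    out = []
    for lab in np.unique(labels):
        mask = labels == lab
        row = {"stratum": lab, "genetic_variance": float(np.var(g_comp_like[mask]))}
        if z is not None:
            row["share"] = row["genetic_variance"] / float(np.var(z[mask]))
        out.append(row)
    return pd.DataFrame(out)


def make_fixture_bundle(
    config: SimConfig,
    out_dir: str | Path,
    params: WeightingParams = WeightingParams(),
) -> dict[str, Path]:
    """Write a complete, seed-reproducible input bundle to ``out_dir``.

    Contains genotypes (with planted QC failures: one high-missingness
    variant, one all-heterozygote variant, one duplicate sample, one
    heterozygosity-outlier sample), a seasonal dose grid, residences,
    the phenotype/covariate table, and the truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, _ = simulate_genotypes(config)

    grid = GridSpec(lat_min=50.0, lon_min=-6.0, n_lat=8, n_lon=8)
    start = date(2008, 1, 1)
    n_days = 365 + params.window_days
    grid_data = simulate_uvb_grid(
        grid, start, n_days, seed=config.seed, cloud_noise=True
    )
    residences = simulate_residences(
        config.n_samples,
        grid,
        first_sample_date=start + timedelta(days=params.window_days),
        last_sample_date=start + timedelta(days=n_days - 1),
        seed=config.seed,
    )
    exposures, failures = build_exposure_table(residences, grid_data, params)
    if failures:
        raise RuntimeError(f"exposure failures in fixture bundle: {failures[:5]}")
    cohort, truth = simulate_cohort(g, exposures, config)

    # plant QC failures on top of the clean bundle
    rng = np.random.default_rng(_streams(config.seed, "qc_plants")["qc_plants"])
    n, m = g.n_samples, g.n_variants
    dosage = np.column_stack([g.dosage, np.zeros((n, 2))])
    # high-missingness variant
    miss_rows = rng.choice(n, size=n // 2, replace=False)
    col_missing = np.round(rng.binomial(2, 0.3, size=n)).astype(float)
    col_missing[miss_rows] = np.nan
    dosage[:, m] = col_missing
    # all-heterozygote variant (gross HWE violation)
    dosage[:, m + 1] = 1.0
    pos_last = int(g.variants["pos"].iloc[-1])
    extra = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [pos_last + 10_000, pos_last + 20_000],
            "id": ["planted_missing", "planted_hwe"],
            "ref": "A",
            "alt": "G",
            "info_score": 1.0,
        }
    )
    variants = pd.concat([g.variants, extra], ignore_index=True)
    # duplicate sample + heterozygosity outlier sample
    dup = dosage[0].copy()
    outlier = np.ones(m + 2)
    dosage = np.vstack([dosage, dup, outlier])
    sample_ids = np.concatenate(
        [g.sample_ids, ["planted_dup", "planted_het_outlier"]]
    )
    g_planted = GenotypeMatrix(sample_ids, variants, dosage)

    paths = {
        "grid": out / "uvb_grid.tsv",
        "residences": out / "residences.tsv",
        "exposure": out / "exposure.tsv",
        "cohort": out / "cohort.tsv",
        "truth": out / "truth.tsv",
        "genotypes": out / "genotypes",
    }
    write_dose_grid(paths["grid"], grid_data)
    res_df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in residences],
            "lat": [r.lat_deg for r in residences],
            "lon": [r.lon_deg for r in residences],
            "sample_date": [r.sample_date.isoformat() for r in residences],
        }
    )
    res_df.to_csv(paths["residences"], sep="\t", index=False, float_format="%.6f")
    exposures.to_csv(paths["exposure"], sep="\t", index=False, float_format="%.6f")
    cohort.to_csv(paths["cohort"], sep="\t", index=False, float_format="%.6f")
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    write_genotypes(paths["genotypes"], g_planted)
    return paths
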