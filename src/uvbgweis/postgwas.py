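"""Post-GWAS variant selection, replication statistics, and risk scores.

Two complementary routes to an independent-variant set:

* greedy LD clumping — take the most significant remaining variant as a
  lead and discard everything in LD (r^2 above threshold) with it;
* stepwise conditional (joint) selection — forward-add the variant with
  the smallest conditional p-value when fitted jointly with the variants
  already selected, with backward elimination, run here on
  individual-level data (exact conditional fits).

Plus the downstream summaries: per-variant variance explained
2 beta^2 f (1-f) on a standardized trait, sign-concordance replication
tests, and genetic risk scores — marginal (sum of dosage * beta_marginal)
and interaction-aware (sum of dosage * (beta_G + E_i * beta_GxE) with each
participant's own exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .gweis import ModelSpec, _covariate_matrix, _impute_mean

__all__ = [
    "LeadVariantSet",
    "ConditionalSet",
    "ReplicationSummary",
    "clump_leads",
    "stepwise_conditional_selection",
    "variance_explained",
    "sign_concordance_test",
    "build_risk_scores",
    "evaluate_risk_scores",
]


@dataclass
class LeadVariantSet:
    source_test: str
    leads: pd.DataFrame          # variant_id, p
    r2_threshold: float
    removed: dict = field(default_factory=dict)  # lead -> clumped ids

    @property
    def ids(self) -> list[str]:
        return list(self.leads["variant_id"])


@dataclass
class ConditionalSet:
    ids: list[str]
    betas: np.ndarray
    conditional_p: np.ndarray


@dataclass
class ReplicationSummary:
    n_total: int
    n_concordant: int
    p_binom: float
    pearson_r: float
    p_pearson: float


def _ld_r2(dosage: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    g = _impute_mean(dosage)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.nan
    r = (g.T @ g) / len(g) / np.outer(sd, sd)
    return r**2


def clump_leads(
    results: pd.DataFrame,
    ld_source: GenotypeMatrix,
    p_field: str = "p_joint",
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
) -> LeadVariantSet:
    """Greedy LD clumping of significant variants.

    Significant variants are sorted by ascending p (ties by chromosome,
    position); the best remaining becomes a lead and all remaining
    variants with r^2 >= threshold to it are clumped under it.  No
    significant variants yields an empty set.
    """
    sig = results.loc[results[p_field] < p_threshold].copy()
    sig = sig.sort_values(
        [p_field, "chromosome", "base_pair_location"], kind="stable"
    )
    if sig.empty:
        return LeadVariantSet(p_field, sig.head(0)[["variant_id", p_field]],
                              r2_threshold)
    vid_to_col = {v: i for i, v in enumerate(ld_source.variants["id"])}
    missing = [v for v in sig["variant_id"] if v not in vid_to_col]
    if missing:
        raise ValueError(f"LD source lacks significant variants: {missing[:10]}")
    cols = [vid_to_col[v] for v in sig["variant_id"]]
    r2 = _ld_r2(ld_source.dosage[:, cols])

    remaining = list(range(len(sig)))
    leads, removed = [], {}
    while remaining:
        lead = remaining[0]
        leads.append(lead)
        lead_id = sig["variant_id"].iloc[lead]
        linked = [j for j in remaining[1:] if r2[lead, j] >= r2_threshold]
        removed[lead_id] = [sig["variant_id"].iloc[j] for j in linked]
        remaining = [j for j in remaining[1:] if j not in set(linked)]
    lead_df = sig.iloc[leads][["variant_id", p_field]].rename(
        columns={p_field: "p"}
    ).reset_index(drop=True)
    return LeadVariantSet(p_field, lead_df, r2_threshold, removed)


def stepwise_conditional_selection(
    g: GenotypeMatrix,
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    p_threshold: float = 5e-8,
    window_bp: float = 10e6,
    collinearity_r2: float = 0.9,
) -> ConditionalSet:
    """Forward-backward conditional selection on individual-level data.

    At each forward step the candidate with the smallest conditional
    p-value (marginal model with all already-selected variants within
    ``window_bp`` as extra covariates) enters while that p-value is below
    threshold; after each addition any selected variant whose joint
    p-value rises above threshold is dropped.  Candidates with r^2 above
    ``collinearity_r2`` to a selected variant are skipped.
    """
    from .gweis import align_cohort

    cohort = align_cohort(g, cohort)
    y = cohort["pheno_std"].to_numpy(dtype=float)
    c = _covariate_matrix(cohort, spec)
    dos = _impute_mean(g.dosage)
    chrom = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy(dtype=float)
    m = g.n_variants
    n = len(y)

    selected: list[int] = []

    def conditional_p(j: int, conditioning: list[int]) -> float:
        x = np.column_stack([dos[:, j]] + [dos[:, s] for s in conditioning] + [c])
        xtx = x.T @ x
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            return 1.0
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (n - x.shape[1])
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        return float(stats.chi2.sf((beta[0] / se) ** 2, 1))

    def joint_fit(sel: list[int]) -> tuple[np.ndarray, np.ndarray]:
        x = np.column_stack([dos[:, s] for s in sel] + [c])
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (n - x.shape[1])
        se = np.sqrt(sigma2 * np.diag(xtx_inv)[: len(sel)])
        p = stats.chi2.sf((beta[: len(sel)] / se) ** 2, 1)
        return beta[: len(sel)], p

    excluded: set[int] = set()
    while True:
        best_j, best_p = -1, p_threshold
        for j in range(m):
            if j in selected or j in excluded:
                continue
            if np.ptp(dos[:, j]) == 0:
                continue
            near = [
                s for s in selected
                if chrom[s] == chrom[j] and abs(pos[s] - pos[j]) <= window_bp
            ]
            if near:
                sub = _ld_r2(dos[:, [j] + near])
                if np.nanmax(sub[0, 1:]) > collinearity_r2:
                    continue
            p = conditional_p(j, near)
            if p < best_p:
                best_j, best_p = j, p
        if best_j < 0:
            break
        selected.append(best_j)
        # backward elimination: drop whichever selected variant no longer
        # clears the threshold in the joint fit; a dropped variant stays out
        while len(selected) > 1:
            _, pj = joint_fit(selected)
            worst = int(np.argmax(pj))
            if pj[worst] < p_threshold:
                break
            dropped = selected.pop(worst)
            excluded.add(dropped)

    if not selected:
        return ConditionalSet([], np.empty(0), np.empty(0))
    betas, ps = joint_fit(selected)
    ids = [g.variants["id"].iloc[s] for s in selected]
    return ConditionalSet(ids, betas, ps)


def variance_explained(betas: np.ndarray, freqs: np.ndarray) -> pd.DataFrame:
    """Per-variant 2 beta^2 f (1-f) on a standardized trait, plus the total.

    Returns a frame with per-variant contributions; the total is the sum
    (stored in ``.attrs['total']``).
    """
    betas = np.asarray(betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    contrib = 2.0 * betas**2 * freqs * (1.0 - freqs)
    out = pd.DataFrame({"beta": betas, "freq": freqs, "variance_explained": contrib})
    out.attrs["total"] = float(contrib.sum())
    return out


def sign_concordance_test(
    discovery_betas: np.ndarray, replication_betas: np.ndarray
) -> ReplicationSummary:
    """Sign agreement between discovery and replication effect estimates.

    Pairs where either beta is exactly zero are excluded.  The binomial
    test is exact and two-sided against p0 = 0.5 (random sign under the
    null); the Pearson correlation of the paired betas is reported with
    its two-sided p-value.
    """
    d = np.asarray(discovery_betas, dtype=float)
    r = np.asarray(replication_betas, dtype=float)
    if d.shape != r.shape:
        raise ValueError("beta vectors must be paired (equal length)")
    nz = (d != 0) & (r != 0)
    if nz.sum() == 0:
        raise ValueError("no overlapping variants with nonzero effects")
    k = int((np.sign(d[nz]) == np.sign(r[nz])).sum())
    n = int(nz.sum())
    p_binom = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    if n >= 3 and np.std(d[nz]) > 0 and np.std(r[nz]) > 0:
        pear = stats.pearsonr(d[nz], r[nz])
        r_val, p_pear = float(pear.statistic), float(pear.pvalue)
    else:
        r_val, p_pear = float("nan"), float("nan")
    return ReplicationSummary(n, k, p_binom, r_val, p_pear)


def build_risk_scores(
    g: GenotypeMatrix,
    weights: pd.DataFrame,
    exposure: np.ndarray,
) -> pd.DataFrame:
    """Marginal and interaction-aware genetic risk scores.

    ``weights`` needs columns ``variant_id, effect_allele, beta_marginal,
    beta_g, beta_gxe``; effect alleles must match the genotype ALT allele
    (mismatch is an error — harmonize upstream).  Missing dosages are
    mean-imputed.  The interaction score weights each variant by
    beta_G + E_i * beta_GxE with participant i's own exposure.
    """
    idx = {v: i for i, v in enumerate(g.variants["id"])}
    missing = [v for v in weights["variant_id"] if v not in idx]
    if missing:
        raise ValueError(f"genotypes lack weighted variants: {missing[:10]}")
    cols = [idx[v] for v in weights["variant_id"]]
    alt = g.variants["alt"].to_numpy()[cols]
    mismatch = weights.loc[
        weights["effect_allele"].to_numpy() != alt, "variant_id"
    ].tolist()
    if mismatch:
        raise ValueError(f"effect-allele mismatch for: {mismatch[:10]}")
    dos = _impute_mean(g.dosage[:, cols])
    e = np.asarray(exposure, dtype=float)
    if e.shape[0] != g.n_samples:
        raise ValueError("exposure vector must align with samples")
    b_marg = weights["beta_marginal"].to_numpy(dtype=float)
    b_g = weights["beta_g"].to_numpy(dtype=float)
    b_gxe = weights["beta_gxe"].to_numpy(dtype=float)
    marginal = dos @ b_marg
    interaction = dos @ b_g + (dos @ b_gxe) * e
    return pd.DataFrame(
        {
            "participant_id": g.sample_ids,
            "marginal_score": marginal,
            "interaction_score": interaction,
        }
    )


def evaluate_risk_scores(
    scores: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Age- and sex-adjusted association of each score with raw 25OHD.

    For each score: least-squares slope of raw 25OHD (nmol/L) per unit
    score with age and sex as covariates, its SE and Wald p, and the
    difference in mean raw 25OHD between the top and bottom score deciles.
    """
    tab = cohort.set_index("participant_id").loc[
        scores["participant_id"]
    ].reset_index()
    y = tab["pheno_raw"].to_numpy(dtype=float)
    rows = []
    for name in ("marginal_score", "interaction_score"):
        s = scores[name].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            raise ValueError(f"{name} is constant")
        x = np.column_stack(
            [s, np.ones_like(s), tab["age"].to_numpy(float), tab["sex"].to_numpy(float)]
        )
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        sigma2 = resid @ resid / (len(y) - x.shape[1])
        se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
        p = float(stats.chi2.sf((beta[0] / se) ** 2, 1))
        dec = np.quantile(s, [0.1, 0.9])
        contrast = float(y[s >= dec[1]].mean() - y[s <= dec[0]].mean())
        rows.append(
            {
                "score": name,
                "slope_nmol_per_unit": float(beta[0]),
                "se": se,
                "p": p,
                "top_vs_bottom_decile_nmol": contrast,
            }
        )
    return pd.DataFrame(rows)
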