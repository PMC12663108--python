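"""Variant- and sample-level genotype quality control.

Filters mirror standard imputed-array GWAS practice: imputation quality,
per-variant and per-sample missingness, minor-allele frequency, the exact
Hardy-Weinberg test, heterozygosity outliers, and pruning of close
relatives detected with the KING-robust kinship estimator (0.0884 is the
conventional cutoff separating 2nd-degree relatives from more distant
pairs).  Hard-call statistics (HWE, heterozygosity, kinship) operate on
dosages rounded to the nearest integer, with strongly intermediate
dosages treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, hard_calls

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "king_robust_kinship",
    "kinship_matrix",
    "variant_qc",
    "sample_qc",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    max_missing: float = 0.02      # variants and samples alike
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_info: float = 0.8
    kinship_max: float = 0.0884    # 2nd-degree relatives or closer
    het_sd: float = 6.0
    min_shared_sites: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("max_missing in [0,1], min_maf in [0,0.5]")
        if not (0 <= self.min_hwe_p <= 1 and 0 <= self.min_info <= 1):
            raise ValueError("min_hwe_p and min_info must be in [0,1]")
        if self.het_sd <= 0 or self.min_shared_sites < 1:
            raise ValueError("het_sd > 0 and min_shared_sites >= 1 required")


@dataclass
class QcReport:
    """Removal counts per filter, per axis; removed + retained = input."""

    n_variants_in: int = 0
    n_samples_in: int = 0
    variants_removed: dict = field(default_factory=dict)
    samples_removed: dict = field(default_factory=dict)

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - sum(self.variants_removed.values())

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - sum(self.samples_removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("variant", k, v) for k, v in self.variants_removed.items()]
        rows += [("sample", k, v) for k, v in self.samples_removed.items()]
        rows += [
            ("variant", "retained", self.n_variants_out),
            ("sample", "retained", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["axis", "reason", "count"])


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    With the minor-allele count fixed, the probability of observing h
    heterozygotes is proportional to n! / (n_AA! h! n_aa!) * 2^h; the
    p-value sums the probabilities of all heterozygote counts with
    probability not exceeding the observed one (standard two-sided exact
    test, not mid-p).  Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # admissible heterozygote counts share the parity of the minor-allele count
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to a constant: -lgamma terms + h ln 2
    n_hom_min = (n_minor - hs) // 2
    n_hom_maj = n - hs - n_hom_min
    logp = (
        hs * math.log(2.0)
        - _lgamma_arr(hs + 1)
        - _lgamma_arr(n_hom_min + 1)
        - _lgamma_arr(n_hom_maj + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(hs, n_het)]
    # tolerance guards against float ties in the <= comparison
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def king_robust_kinship(
    calls_i: np.ndarray, calls_j: np.ndarray, min_shared_sites: int = 100
) -> float:
    """KING-robust between-family kinship estimate from hard calls.

    phi = N_het,het / (2 N_min) + 1/2 - (N_het_i + N_het_j) / (4 N_min)
          - N_opposite_hom / N_min
    with N_min = min(N_het_i, N_het_j), computed over shared non-missing
    sites.  Returns NaN when neither sample has a heterozygous call on the
    shared sites (estimator undefined).
    """
    gi = np.asarray(calls_i, dtype=float)
    gj = np.asarray(calls_j, dtype=float)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must have equal length")
    shared = ~np.isnan(gi) & ~np.isnan(gj)
    if shared.sum() < min_shared_sites:
        raise ValueError(
            f"only {int(shared.sum())} shared non-missing sites "
            f"(< {min_shared_sites})"
        )
    gi, gj = gi[shared], gj[shared]
    het_i = gi == 1
    het_j = gj == 1
    n_het_i = int(het_i.sum())
    n_het_j = int(het_j.sum())
    n_min = min(n_het_i, n_het_j)
    if n_min == 0:
        return float("nan")
    n_hh = int((het_i & het_j).sum())
    n_opp = int(((gi == 0) & (gj == 2)).sum() + ((gi == 2) & (gj == 0)).sum())
    return (
        n_hh / (2.0 * n_min)
        + 0.5
        - (n_het_i + n_het_j) / (4.0 * n_min)
        - n_opp / n_min
    )


def kinship_matrix(g: GenotypeMatrix, t: QcThresholds = QcThresholds()) -> np.ndarray:
    """All-pairs KING-robust kinship (NaN where undefined)."""
    calls = hard_calls(g.dosage)
    n = g.n_samples
    phi = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                phi[i, j] = phi[j, i] = king_robust_kinship(
                    calls[i], calls[j], t.min_shared_sites
                )
            except ValueError:
                pass
    return phi


def variant_qc(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[np.ndarray, pd.Series]:
    """Variant keep-mask and the first failing filter per dropped variant.

    Filters apply in order info -> missingness -> MAF -> HWE (on hard
    calls); a variant's recorded reason is the first filter it fails.
    """
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    reasons = pd.Series([""] * m, index=g.variants["id"].to_numpy(), dtype=object)

    info = g.variants["info_score"].to_numpy(dtype=float)
    fail = ~np.isnan(info) & (info < t.min_info)
    _mark(keep, reasons, fail, "info")

    miss = np.isnan(g.dosage).mean(axis=0)
    _mark(keep, reasons, keep & (miss > t.max_missing), "missingness")

    af = g.allele_freq()
    maf = np.minimum(af, 1 - af)
    _mark(keep, reasons, keep & ~np.isnan(maf) & (maf < t.min_maf), "maf")

    calls = hard_calls(g.dosage)
    hwe_fail = np.zeros(m, dtype=bool)
    for j in np.nonzero(keep)[0]:
        c = calls[:, j]
        c = c[~np.isnan(c)]
        if c.size == 0:
            continue
        n0 = int((c == 0).sum())
        n1 = int((c == 1).sum())
        n2 = int((c == 2).sum())
        if hwe_exact_test(n0, n1, n2) < t.min_hwe_p:
            hwe_fail[j] = True
    _mark(keep, reasons, hwe_fail, "hwe")

    return keep, reasons[reasons != ""]


def _mark(keep, reasons, fail, label) -> None:
    fail = fail & keep
    keep[fail] = False
    reasons.iloc[np.nonzero(fail)[0]] = label


def sample_qc(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[np.ndarray, pd.Series]:
    """Sample keep-mask and removal reasons.

    Order: missingness, then heterozygosity-rate outliers beyond
    ``het_sd`` standard deviations of the retained-sample mean, then
    greedy kinship pruning — of each pair at or above ``kinship_max`` the
    member with higher missingness is dropped (ties: the later sample).
    """
    n = g.n_samples
    if n < 3:
        raise ValueError("sample QC requires at least 3 samples")
    keep = np.ones(n, dtype=bool)
    reasons = pd.Series([""] * n, index=g.sample_ids, dtype=object)

    miss = np.isnan(g.dosage).mean(axis=1)
    _mark(keep, reasons, miss > t.max_missing, "missingness")

    calls = hard_calls(g.dosage)
    non_missing = (~np.isnan(calls)).sum(axis=1)
    het = (calls == 1).sum(axis=1) / np.maximum(non_missing, 1)
    mu = het[keep].mean()
    sd = het[keep].std()
    if sd > 0:
        _mark(keep, reasons, np.abs(het - mu) > t.het_sd * sd, "heterozygosity")

    sub = g.subset(sample_mask=keep)
    phi = kinship_matrix(sub, t)
    idx = np.nonzero(keep)[0]
    sub_keep = np.ones(len(idx), dtype=bool)
    with np.errstate(invalid="ignore"):
        pairs = np.argwhere(np.triu(phi >= t.kinship_max, k=1))
    for a, b in pairs:
        if not (sub_keep[a] and sub_keep[b]):
            continue
        drop = b if miss[idx[b]] >= miss[idx[a]] else a
        sub_keep[drop] = False
    kin_fail = np.zeros(n, dtype=bool)
    kin_fail[idx[~sub_keep]] = True
    _mark(keep, reasons, kin_fail, "kinship")

    return keep, reasons[reasons != ""]


def apply_qc(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Sample QC, then variant QC on the retained samples."""
    report = QcReport(n_variants_in=g.n_variants, n_samples_in=g.n_samples)
    s_keep, s_reasons = sample_qc(g, t)
    report.samples_removed = s_reasons.value_counts().to_dict()
    g2 = g.subset(sample_mask=s_keep)
    if g2.n_samples == 0:
        raise ValueError("all samples removed by QC")
    v_keep, v_reasons = variant_qc(g2, t)
    report.variants_removed = v_reasons.value_counts().to_dict()
    out = g2.subset(variant_mask=v_keep)
    if out.n_variants == 0:
        raise ValueError("all variants removed by QC")
    return out, report
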