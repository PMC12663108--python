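"""Genotype container and file I/O.

Dosages are stored as a dense ``samples x variants`` float array of ALT
allele counts in [0, 2] (imputed dosages allowed), with NaN for missing.
Variant metadata travels in a DataFrame with columns
``chrom, pos, id, ref, alt, info_score``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "write_genotypes", "hard_calls"]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info_score"]


@dataclass
class GenotypeMatrix:
    """Sample x variant ALT-dosage matrix with variant metadata."""

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.dosage < 0) or np.any(self.dosage > 2):
                raise ValueError("dosages must lie in [0, 2] (NaN for missing)")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("variant positions must be nondecreasing per chromosome")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        vm = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[sm],
            variants=self.variants.loc[vm].reset_index(drop=True),
            dosage=self.dosage[np.ix_(sm, vm)],
        )

    def allele_freq(self) -> np.ndarray:
        """Effect (ALT) allele frequency from mean dosage / 2, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0


def hard_calls(dosage: np.ndarray, uncertainty_band: float = 0.1) -> np.ndarray:
    """Round dosages to hard genotype calls {0, 1, 2}; ambiguous -> NaN.

    Dosages farther than ``uncertainty_band`` from every integer (i.e. in
    (0.1, 0.9) or (1.1, 1.9) at the default) are treated as missing for
    hard-call statistics, guarding HWE and kinship against imputation
    uncertainty.
    """
    g = np.asarray(dosage, dtype=float)
    rounded = np.rint(g)
    out = np.where(np.abs(g - rounded) <= uncertainty_band, rounded, np.nan)
    return out


def write_genotypes(prefix, g: GenotypeMatrix) -> None:
    """Plain-text pair: ``<prefix>.dosage.tsv`` + ``<prefix>.variants.tsv``."""
    var = g.variants[VARIANT_COLUMNS]
    var.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False, float_format="%.6g")
    df = pd.DataFrame(g.dosage, columns=var["id"])
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(f"{prefix}.dosage.tsv", sep="\t", index=False, float_format="%.4f")


def read_genotypes(prefix) -> GenotypeMatrix:
    var = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"chrom": str, "id": str})
    df = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", dtype={"sample_id": str})
    dosage = df[var["id"]].to_numpy(dtype=float)
    return GenotypeMatrix(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        variants=var,
        dosage=dosage,
    )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; DS preferred over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, cols = [], []
    for v in vcf:
        try:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError):
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(v.gt_types, dtype=float)
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        info = v.INFO.get("INFO", v.INFO.get("R2", np.nan))
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "info_score": float(info) if info is not None else np.nan,
            }
        )
        cols.append(ds)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosage=dosage)
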