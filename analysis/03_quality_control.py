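"""Genotype QC on the study bundle.

The bundle plants one failure of each kind (duplicate sample,
heterozygosity outlier, high-missingness variant, all-heterozygote
variant); QC should remove exactly those and nothing else.  Writes the
removal report and the cleaned genotypes for the association scan.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from uvbgweis.genotypes import read_genotypes, write_genotypes
from uvbgweis.qc import apply_qc

OUT = Path(__file__).resolve().parents[1]
STUDY = OUT / "scratch" / "study"


def main() -> None:
    g = read_genotypes(STUDY / "genotypes")
    clean, report = apply_qc(g)
    print(
        f"retained {report.n_samples_out}/{report.n_samples_in} samples, "
        f"{report.n_variants_out}/{report.n_variants_in} variants"
    )
    print(report.to_frame().to_string(index=False))
    write_genotypes(STUDY / "genotypes_clean", clean)
    report.to_frame().to_csv(OUT / "results" / "03_qc_report.tsv", sep="\t",
                             index=False)


if __name__ == "__main__":
    main()
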