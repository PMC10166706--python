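#!/usr/bin/env python
"""KO counts -> normalized EC abundance matrix.

Regroups KO-annotated gene counts into EC reactions (full count to every
mapped EC), normalizes each sample by its glycolysis/TCA-cycle total, and
attaches up-to-5 KEGG pathway annotations per EC.  Writes
results/ec_matrix.tsv (+ JSON sidecar with denominators and unmapped mass).
"""

from pathlib import Path

from mpmi import profiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    table = profiles.read_counts(data / "counts.tsv")
    ec_counts, unmapped = profiles.regroup_ko_to_ec(
        table, profiles.read_ko_to_ec(data / "ko_to_ec.tsv")
    )
    matrix = profiles.normalize(ec_counts, unmapped_mass=unmapped)
    matrix = profiles.annotate_pathways(
        matrix, profiles.read_ec_pathways(data / "ec_pathways.tsv")
    )
    profiles.write_matrix(matrix, ROOT / "ec_matrix.tsv")
    print(f"matrix: {matrix.abundance.shape[0]} samples x "
          f"{matrix.abundance.shape[1]} ECs")
    print(f"median normalization denominator: "
          f"{matrix.normalization_denominator.median():.0f} counts")
    print(f"unmapped KO mass: {matrix.unmapped_mass.sum():.0f} counts total")


if __name__ == "__main__":
    main()
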