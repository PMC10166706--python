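#!/usr/bin/env python
"""The quantitative (qPCR) MPMI from plate and calibration tables.

Fits the per-primer-set log-linear calibration (shared slope, per-source
intercept offsets), turns duplicate-well Ct readings into 16S-normalized
relative abundances, and computes the 4-marker qMPMI per sample.  Writes
fits/abundances/qmpmi tables under results/ and prints the treatment-group
comparison.
"""

from pathlib import Path

import pandas as pd

from mpmi import catalog, index, qpcr

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    cal = qpcr.read_calibration(data / "calibration.tsv")
    fits = {
        str(m): qpcr.fit_calibration(g, key=str(m)) for m, g in cal.groupby("marker")
    }
    qpcr.fits_frame(fits).to_csv(ROOT / "calibration_fits.tsv", sep="\t")
    print("calibration slopes (cycles/decade):")
    for k, f in sorted(fits.items()):
        print(f"  {k:<10} m = {f.slope:+.3f}  R^2 = {f.r_squared:.4f}")

    plate = qpcr.read_plate(data / "plate.tsv")
    abundances = qpcr.average_replicates(plate, fits, nondetect_policy="floor")
    pd.DataFrame(
        [{"sample": a.sample_id, "marker": a.marker_ec, "a_value": a.a_value,
          "n_replicates": a.n_replicates, "any_nondetect": a.any_nondetect}
         for a in abundances]
    ).to_csv(ROOT / "abundances.tsv", sep="\t", index=False)

    markers, _ = catalog.load_catalog()
    labels = pd.read_csv(data / "qpcr_metadata.tsv", sep="\t", index_col=0)["treatment"]
    table = qpcr.compute_qmpmi(abundances, markers).join(labels)
    table.to_csv(ROOT / "qmpmi.tsv", sep="\t")
    ctl = table.loc[table["treatment"] == "control", "qmpmi"]
    pb = table.loc[table["treatment"] == "pb", "qmpmi"]
    comp = index.compare_groups(list(ctl), list(pb), labels=["control", "pb"])
    print(f"qMPMI median control: {ctl.median():.3f}   pb: {pb.median():.3f}   "
          f"ratio {pb.median() / ctl.median():.1f}")
    print(f"Mann-Whitney p = {comp.p_value:.2e}")


if __name__ == "__main__":
    main()
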