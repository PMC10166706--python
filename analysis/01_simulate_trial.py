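#!/usr/bin/env python
"""Generate the synthetic trial data every later step consumes.

Emulates the study design: a two-arm feeding trial (control vs. precision
biotic, "pb") with 21 cecal metagenomes per arm, a 3-fold treatment
enrichment of numerator-reaction genes; qPCR calibration/plate tables for
the 4-marker assay; 21 pens x 40 birds of grow-out records at the
published effect sizes; and ex vivo SCFA tables.  Everything is written
under results/data/ as plain TSV.
"""

from pathlib import Path

import pandas as pd

from mpmi import profiles
from mpmi import simulate as sim

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sim.SimulationConfig(seed=SEED)

    counts = sim.gen_counts(cfg)
    profiles.write_counts(counts.table, OUT / "counts.tsv")
    counts.labels.to_csv(OUT / "metadata.tsv", sep="\t")
    pd.DataFrame(
        [(ko, ec) for ko, ecs in counts.ko_to_ec.items() for ec in sorted(ecs)],
        columns=["ko", "ec"],
    ).to_csv(OUT / "ko_to_ec.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(ec, pw, r + 1) for ec, pws in counts.ec_pathways.items() for r, pw in enumerate(pws)],
        columns=["ec", "pathway", "rank"],
    ).to_csv(OUT / "ec_pathways.tsv", sep="\t", index=False)
    print(f"counts: {counts.table.counts.shape[0]} samples x "
          f"{counts.table.counts.shape[1]} KOs (true MPMI fold {counts.true_mpmi_ratio})")

    q = sim.gen_qpcr(cfg)
    q.calibration.to_csv(OUT / "calibration.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample": m.sample_id, "marker": m.marker_ec, "pair_id": m.pair_id,
             "replicate": m.replicate_index, "ct": m.ct if m.detected else "",
             "detected": int(m.detected)}
            for m in q.plate
        ]
    ).to_csv(OUT / "plate.tsv", sep="\t", index=False)
    q.labels.to_csv(OUT / "qpcr_metadata.tsv", sep="\t")
    n_nd = sum(not m.detected for m in q.plate)
    print(f"qPCR: {len(q.plate)} wells ({n_nd} non-detects), "
          f"{len(q.calibration)} calibration points")

    pens = sim.gen_pens(cfg)
    sim.pens_frame(pens).to_csv(OUT / "pens.tsv", sep="\t", index=False)
    print(f"pens: {len(pens)} pens "
          f"(+{cfg.pen_effect_sizes['bwg_shift_g']:.0f} g BWG, "
          f"{cfg.pen_effect_sizes['fcr_shift']:+.3f} FCR shifts)")

    sim.gen_scfa(cfg).to_csv(OUT / "scfa.tsv", sep="\t")
    print("scfa: ex vivo table written")


if __name__ == "__main__":
    main()
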