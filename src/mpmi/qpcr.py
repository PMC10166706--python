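"""qPCR assay mathematics for the quantitative MPMI (qMPMI).

The targeted assay replaces whole-metagenome sequencing with four marker
reactions amplified by blended primer sets, normalized against universal
16S rDNA.  The moving parts:

* **Calibration** — for each primer set, cycle-threshold values from a
  serial dilution of template DNA follow the log-linear model
  ``Ct = m * log10(D) + b``, fit jointly across several template sources
  with additive per-source intercept offsets (``Ct ~ log10(D) + C(source)``,
  first source as reference).  A perfectly efficient reaction has
  m ≈ −3.32 (one cycle per doubling).

* **Relative abundance** — ``A_i = 10 ** (Ct_i / m_i − Ct_16S / m_16S)``,
  the marker-to-16S template ratio implied by the two calibration slopes.
  Note that with distinct intercepts this is *proportional* to the true
  concentration ratio by the constant ``10**(b_i/m_i − b_16S/m_16S)``;
  group ratios are unaffected.  ``intercept_correction=True`` removes the
  constant and recovers the ratio exactly.

* **qMPMI** — (sum of A over the catalog's numerator qPCR markers) /
  (sum over denominator qPCR markers), after averaging PCR replicates on
  the A scale.

Non-detects (no amplification within ``max_cycles`` = 40) default to a
floor abundance equal to the A value implied by Ct = 40, keeping the index
finite and ordered; ``"censor"`` and ``"zero"`` policies are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .catalog import MarkerReaction, SIXTEEN_S

MAX_CYCLES = 40.0


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: a (sample, marker, replicate) cycle-threshold reading."""

    sample_id: str
    marker_ec: str  # EC number or "16S"
    pair_id: str
    replicate_index: int
    ct: float | None  # None when not detected
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if self.ct is None or not 0 < self.ct <= MAX_CYCLES:
                raise QpcrError(
                    f"detected well must have Ct in (0, {MAX_CYCLES}]: {self.ct}"
                )
        elif self.ct is not None:
            raise QpcrError("undetected well must not carry a Ct")


@dataclass(frozen=True)
class CalibrationFit:
    key: str  # marker EC or "16S"
    slope: float
    intercept: float  # reference-source intercept
    source_offsets: dict[str, float] = field(default_factory=dict)
    r_squared: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0 or not math.isfinite(self.slope):
            raise QpcrError(f"calibration slope must be nonzero: {self.slope}")


@dataclass(frozen=True)
class RelativeAbundance:
    sample_id: str
    marker_ec: str
    a_value: float
    n_replicates: int = 1
    any_nondetect: bool = False


def fit_calibration(
    series: list[tuple[str, float, float]] | pd.DataFrame,
    key: str,
) -> CalibrationFit:
    """Fit ``Ct ~ log10(dilution) + C(source)`` by least squares.

    Parameters
    ----------
    series
        (source, dilution factor, Ct) triples, or a DataFrame with columns
        ``source``, ``dilution``, ``ct``.  Dilutions must span >= 3 distinct
        levels.
    key
        Marker EC (or ``"16S"``) the fit belongs to.

    Returns a slope shared across sources, the reference-source intercept,
    additive per-source offsets, and R².
    """
    if isinstance(series, pd.DataFrame):
        df = series[["source", "dilution", "ct"]].copy()
    else:
        df = pd.DataFrame(series, columns=["source", "dilution", "ct"])
    if df["dilution"].nunique() < 3:
        raise QpcrError(f"{key}: need >= 3 distinct dilution levels")
    if (df["dilution"] <= 0).any():
        raise QpcrError(f"{key}: dilution factors must be positive")
    df["log10_d"] = np.log10(df["dilution"].astype(float))
    df["source"] = df["source"].astype(str)
    sources = sorted(df["source"].unique())
    formula = "ct ~ log10_d" if len(sources) == 1 else "ct ~ log10_d + C(source)"
    model = smf.ols(formula, data=df).fit()
    if not np.isfinite(model.params).all():
        raise QpcrError(f"{key}: collinear calibration design")
    slope = float(model.params["log10_d"])
    intercept = float(model.params["Intercept"])
    offsets = {sources[0]: 0.0}
    for s in sources[1:]:
        offsets[s] = float(model.params[f"C(source)[T.{s}]"])
    r2 = float(model.rsquared) if len(df) > 2 else 1.0
    return CalibrationFit(
        key=key, slope=slope, intercept=intercept, source_offsets=offsets, r_squared=r2
    )


def relative_abundance(
    ct_marker: float,
    fit_marker: CalibrationFit,
    ct_16s: float,
    fit_16s: CalibrationFit,
    sample_id: str = "",
    intercept_correction: bool = False,
) -> RelativeAbundance:
    """A = 10 ** (Ct_i/m_i − Ct_16S/m_16S) for one detected well pair."""
    t_m = ct_marker / fit_marker.slope
    t_s = ct_16s / fit_16s.slope
    if intercept_correction:
        t_m -= fit_marker.intercept / fit_marker.slope
        t_s -= fit_16s.intercept / fit_16s.slope
    return RelativeAbundance(
        sample_id=sample_id, marker_ec=fit_marker.key, a_value=10.0 ** (t_m - t_s)
    )


def floor_abundance(fit_marker: CalibrationFit, fit_16s: CalibrationFit, ct_16s: float) -> float:
    """A value implied by a marker Ct at the detection limit (Ct = 40)."""
    return 10.0 ** (MAX_CYCLES / fit_marker.slope - ct_16s / fit_16s.slope)


def average_replicates(
    measurements: list[QpcrMeasurement],
    fits: dict[str, CalibrationFit],
    nondetect_policy: str = "floor",
    intercept_correction: bool = False,
) -> list[RelativeAbundance]:
    """Collapse well-level Ct readings to one A value per (sample, marker).

    Each marker replicate is paired with the same-sample, same-replicate
    16S well; A values are averaged arithmetically on the A scale.
    Non-detect handling:

    * ``"floor"`` (default) — replace with the abundance implied by
      Ct = 40 for that replicate;
    * ``"censor"`` — drop the replicate (flagged); all-non-detect markers
      fall back to the floor value;
    * ``"zero"`` — contribute 0.
    """
    if nondetect_policy not in ("floor", "censor", "zero"):
        raise QpcrError(f"unknown non-detect policy {nondetect_policy!r}")
    wells = pd.DataFrame(
        [
            {
                "sample": m.sample_id,
                "marker": m.marker_ec,
                "replicate": m.replicate_index,
                "ct": m.ct,
                "detected": m.detected,
            }
            for m in measurements
        ]
    )
    if wells.empty:
        return []
    sixteen = wells[wells["marker"] == SIXTEEN_S].set_index(["sample", "replicate"])
    out: list[RelativeAbundance] = []
    for (sample, marker), grp in wells[wells["marker"] != SIXTEEN_S].groupby(
        ["sample", "marker"], sort=True
    ):
        if marker not in fits:
            raise QpcrError(f"no calibration fit for marker {marker}")
        fit_m, fit_s = fits[marker], fits[SIXTEEN_S]
        a_vals: list[float] = []
        any_nd = False
        floors: list[float] = []
        for _, w in grp.iterrows():
            try:
                ref = sixteen.loc[(sample, w["replicate"])]
            except KeyError as err:
                raise QpcrError(
                    f"sample {sample} replicate {w['replicate']}: missing 16S well"
                ) from err
            if isinstance(ref, pd.DataFrame):
                ref = ref.iloc[0]
            if not ref["detected"]:
                raise QpcrError(f"sample {sample}: 16S well not detected")
            ct16 = float(ref["ct"])
            floor = floor_abundance(fit_m, fit_s, ct16)
            floors.append(floor)
            if w["detected"]:
                a_vals.append(
                    relative_abundance(
                        float(w["ct"]), fit_m, ct16, fit_s,
                        sample_id=str(sample),
                        intercept_correction=intercept_correction,
                    ).a_value
                )
            else:
                any_nd = True
                if nondetect_policy == "floor":
                    a_vals.append(floor)
                elif nondetect_policy == "zero":
                    a_vals.append(0.0)
                # "censor": skip
        if not a_vals:  # all replicates non-detect under "censor"
            a_vals = [min(floors)] if nondetect_policy == "censor" else [0.0]
        out.append(
            RelativeAbundance(
                sample_id=str(sample),
                marker_ec=str(marker),
                a_value=float(np.mean(a_vals)),
                n_replicates=len(grp),
                any_nondetect=any_nd,
            )
        )
    return out


def compute_qmpmi(
    abundances: list[RelativeAbundance],
    markers: list[MarkerReaction],
) -> pd.DataFrame:
    """qMPMI per sample: sum of numerator-marker A values over sum of
    denominator-marker A values (roles per the catalog's qPCR markers).

    Samples whose denominator sum is zero get NaN with ``defined=False``.
    """
    roles = {m.ec_number: m.role for m in markers if m.is_qpcr_marker}
    rows: dict[str, dict[str, float]] = {}
    for ab in abundances:
        if ab.marker_ec in roles:
            rows.setdefault(ab.sample_id, {})[ab.marker_ec] = ab.a_value
    if not rows:
        raise QpcrError("no qPCR-marker abundances supplied")
    records = []
    for sample, vals in sorted(rows.items()):
        num = sum(v for ec, v in vals.items() if roles[ec] == "N")
        den = sum(v for ec, v in vals.items() if roles[ec] == "D")
        has_n = any(roles[ec] == "N" for ec in vals)
        has_d = any(roles[ec] == "D" for ec in vals)
        if not (has_n and has_d):
            raise QpcrError(
                f"sample {sample}: need at least one numerator and one "
                "denominator marker"
            )
        records.append(
            {
                "sample": sample,
                "qmpmi": num / den if den > 0 else float("nan"),
                "numerator_sum": num,
                "denominator_sum": den,
                "defined": den > 0,
            }
        )
    return pd.DataFrame(records).set_index("sample")


# ---------------------------------------------------------------- file I/O

def read_plate(path) -> list[QpcrMeasurement]:
    """Read a plate TSV: ``sample  marker  pair_id  replicate  ct  detected``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "marker": str, "pair_id": str})
    out = []
    for _, row in df.iterrows():
        detected = bool(int(row["detected"]))
        out.append(
            QpcrMeasurement(
                sample_id=str(row["sample"]),
                marker_ec=str(row["marker"]),
                pair_id=str(row["pair_id"]),
                replicate_index=int(row["replicate"]),
                ct=float(row["ct"]) if detected else None,
                detected=detected,
            )
        )
    return out


def read_calibration(path) -> pd.DataFrame:
    """Read a calibration TSV: ``source  dilution  marker  ct``."""
    return pd.read_csv(path, sep="\t", dtype={"source": str, "marker": str})


def fits_frame(fits: dict[str, CalibrationFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": f.key,
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                **{f"offset_{s}": o for s, o in f.source_offsets.items()},
            }
            for f in fits.values()
        ]
    ).set_index("marker")
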