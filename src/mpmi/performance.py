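"""Broiler growth-performance indices and treatment contrasts.

Pen-level records (body weights at d 0/10/24/42, cumulative feed intake,
mortality) are reduced to the standard grow-out metrics:

* **BWG** — body-weight gain per bird over 0–42 d (g);
* **FCR** — feed conversion ratio, total feed intake over total gain;
  mortality-corrected by crediting dead birds' gain (recorded removal
  weight when available, otherwise linear interpolation over the phase);
* **cFCR** — FCR adjusted linearly toward the strain's target 42-d body
  weight (``fcr_correction_per_g`` defaults to 0, i.e. no adjustment,
  because the correction coefficient is strain/integrator specific);
* **EPEF** — European Poultry Efficiency Factor,
  ADG / (mortality-corrected FCR × 10) × livability %.

Treatment contrasts follow the convention of pen as the experimental unit:
one-way ANOVA (optionally blocked) on pen means, SEM as the pooled
residual standard error of a treatment mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

PHASE_DAYS = (0, 10, 24, 42)


class PerformanceError(ValueError):
    pass


@dataclass(frozen=True)
class PenPerformance:
    """One pen over the 0-42 d grow-out."""

    pen_id: str
    treatment: str
    block: str
    bird_count_start: int
    body_weight_g: tuple[float, float, float, float]  # d 0, 10, 24, 42 per bird
    feed_intake_g: float  # total per pen, 0-42 d
    mortality_count: int = 0
    removal_weight_sum_g: float | None = None  # summed BW of dead birds

    def __post_init__(self) -> None:
        bw = self.body_weight_g
        if len(bw) != 4 or any(w is None or not np.isfinite(w) for w in bw):
            raise PerformanceError(f"pen {self.pen_id}: need 4 finite body weights")
        if any(b > a for a, b in zip(bw[1:], bw)):
            raise PerformanceError(f"pen {self.pen_id}: body weights must be non-decreasing")
        if self.mortality_count > self.bird_count_start:
            raise PerformanceError(f"pen {self.pen_id}: mortality exceeds bird count")
        if self.feed_intake_g <= 0:
            raise PerformanceError(f"pen {self.pen_id}: feed intake must be positive")


@dataclass(frozen=True)
class PenMetrics:
    pen_id: str
    treatment: str
    block: str
    bwg_g: float  # per-bird gain 0-42 d
    fi_g: float  # per-bird feed intake
    fcr: float  # mortality-corrected
    cfcr: float
    adg_g: float
    livability_pct: float
    epef: float


def pen_metrics(
    pen: PenPerformance,
    target_bw_g: float,
    fcr_correction_per_g: float = 0.0,
) -> PenMetrics:
    """Reduce one pen's records to its performance metrics."""
    bw0, _, _, bw42 = pen.body_weight_g
    bwg = bw42 - bw0
    if bwg <= 0:
        raise PerformanceError(f"pen {pen.pen_id}: non-positive gain")
    survivors = pen.bird_count_start - pen.mortality_count
    if survivors <= 0:
        raise PerformanceError(f"pen {pen.pen_id}: no surviving birds")
    # mortality-corrected total gain: survivors' gain plus dead birds' gain
    if pen.removal_weight_sum_g is not None:
        dead_gain = pen.removal_weight_sum_g - pen.mortality_count * bw0
    else:  # linear interpolation: assume death midway through the grow-out
        dead_gain = pen.mortality_count * bwg / 2.0
    total_gain = survivors * bwg + max(dead_gain, 0.0)
    fcr = pen.feed_intake_g / total_gain
    cfcr = fcr + fcr_correction_per_g * (target_bw_g - bw42)
    adg = bwg / PHASE_DAYS[-1]
    livability = 100.0 * survivors / pen.bird_count_start
    return PenMetrics(
        pen_id=pen.pen_id,
        treatment=pen.treatment,
        block=pen.block,
        bwg_g=bwg,
        fi_g=pen.feed_intake_g / pen.bird_count_start,
        fcr=fcr,
        cfcr=cfcr,
        adg_g=adg,
        livability_pct=livability,
        epef=epef(adg, cfcr, livability),
    )


def epef(adg_g_per_day: float, mortality_corrected_fcr: float, livability_pct: float) -> float:
    """EPEF = ADG / (mcFCR × 10) × livability%."""
    if mortality_corrected_fcr <= 0:
        raise PerformanceError("FCR must be positive")
    if adg_g_per_day <= 0 or not 0 < livability_pct <= 100:
        raise PerformanceError("ADG must be positive and livability in (0, 100]")
    return adg_g_per_day / (mortality_corrected_fcr * 10.0) * livability_pct


def percent_improvement(control: float, treated: float, better_is_lower: bool) -> float:
    """Relative improvement of ``treated`` over ``control``, in percent."""
    if control == 0:
        raise PerformanceError("control value must be nonzero")
    if better_is_lower:
        return 100.0 * (control - treated) / control
    return 100.0 * (treated - control) / control


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    treatment_means: dict[str, float]
    sem: float  # pooled SE of a treatment mean
    n_per_treatment: dict[str, int]


def treatment_anova(
    values: pd.Series,
    treatments: pd.Series,
    blocks: pd.Series | None = None,
) -> AnovaResult:
    """One-way (optionally block-adjusted) ANOVA with pen as the unit.

    SEM is the pooled residual standard error of a treatment mean,
    sqrt(MSE / n), using the harmonic mean of group sizes when unbalanced.
    """
    df = pd.DataFrame({"value": values.astype(float), "treatment": treatments.astype(str)})
    counts = df.groupby("treatment").size()
    if (counts < 2).any():
        raise PerformanceError("every treatment needs >= 2 pens")
    if blocks is not None:
        df["block"] = blocks.astype(str)
        model = smf.ols("value ~ C(treatment) + C(block)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        f_stat = float(table.loc["C(treatment)", "F"])
        p_value = float(table.loc["C(treatment)", "PR(>F)"])
        mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    else:
        groups = [g["value"].to_numpy() for _, g in df.groupby("treatment")]
        f_stat, p_value = stats.f_oneway(*groups)
        n_total = len(df)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        mse = ss_within / (n_total - len(groups))
    n_harm = len(counts) / (1.0 / counts).sum()
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p_value),
        treatment_means=df.groupby("treatment")["value"].mean().to_dict(),
        sem=float(np.sqrt(mse / n_harm)),
        n_per_treatment=counts.to_dict(),
    )


def summarize(metrics: list[PenMetrics]) -> pd.DataFrame:
    """Per-treatment mean table (BWG, FI, FCR, cFCR, EPEF) with pen counts."""
    df = metrics_frame(metrics)
    out = df.groupby("treatment")[["bwg_g", "fi_g", "fcr", "cfcr", "epef"]].mean()
    out["n_pens"] = df.groupby("treatment").size()
    return out


def metrics_frame(metrics: list[PenMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pen": m.pen_id,
                "treatment": m.treatment,
                "block": m.block,
                "bwg_g": m.bwg_g,
                "fi_g": m.fi_g,
                "fcr": m.fcr,
                "cfcr": m.cfcr,
                "adg_g": m.adg_g,
                "livability_pct": m.livability_pct,
                "epef": m.epef,
            }
            for m in metrics
        ]
    ).set_index("pen")


def read_pens(path) -> list[PenPerformance]:
    """Read a pen TSV: ``pen treatment block n0 bw0 bw10 bw24 bw42 fi_total
    mortality removal_wt_sum`` (removal_wt_sum may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"pen": str, "treatment": str, "block": str})
    pens = []
    for _, row in df.iterrows():
        removal = row.get("removal_wt_sum")
        pens.append(
            PenPerformance(
                pen_id=str(row["pen"]),
                treatment=str(row["treatment"]),
                block=str(row["block"]),
                bird_count_start=int(row["n0"]),
                body_weight_g=(
                    float(row["bw0"]),
                    float(row["bw10"]),
                    float(row["bw24"]),
                    float(row["bw42"]),
                ),
                feed_intake_g=float(row["fi_total"]),
                mortality_count=int(row["mortality"]),
                removal_weight_sum_g=(
                    float(removal) if removal is not None and pd.notna(removal) else None
                ),
            )
        )
    return pens
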