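"""Synthetic study data with the statistical structure the analyses assume.

Every analysis stage in this package can be exercised without any external
download: this module emulates

* shallow-shotgun KO gene-count tables for a two-arm trial (control vs. a
  precision-biotic "pb" treatment) in which treatment multiplies the
  abundance of the catalog's numerator-reaction genes by a known fold —
  applied at the KO level, before regrouping, so the KO→EC logic is
  exercised by parameter-recovery tests;
* qPCR serial-dilution calibration tables and duplicate-well plate tables
  generated from known log-linear calibration lines with Gaussian Ct
  noise and censoring at 40 cycles;
* pen-level grow-out records matching the trial design (two treatments,
  21 pens × 40 birds by default) with configurable treatment shifts,
  between-pen variability and binomial mortality;
* ex vivo short-chain fatty-acid concentration tables in which control
  propionate/butyrate fall below the detection limit.

Counts follow a depth-scaled log-normal relative-abundance model — the
simplest generative story consistent with compositional count data.  Each
generator is a pure function of its :class:`SimulationConfig` (same seed,
same bytes); ground truth is returned alongside every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import catalog as cat
from .performance import PenPerformance
from .profiles import GLYCOLYSIS_TCA_ECS, GeneCountTable
from .qpcr import MAX_CYCLES, QpcrMeasurement


class SimulationError(ValueError):
    pass


#: Per-primer-set true calibration slopes (cycles per decade of template).
#: Near the perfect-efficiency value of -log2(10) ≈ -3.32.
DEFAULT_TRUE_SLOPES: dict[str, float] = {
    "2.3.1.109": -3.40,
    "2.6.1.19": -3.22,
    "3.5.3.12": -3.48,
    "2.8.3.18": -3.30,
    cat.SIXTEEN_S: -3.35,
}

#: Grow-out study conditions: printed control means, treatment shifts and
#: between-pen SDs implied by the published SEMs at 21 pens/treatment
#: (SD = SEM * sqrt(21): 17.59 g -> 80.6 g BWG, 0.01 -> 0.0458 FCR).
PEN_STUDY_CONDITIONS = {
    "control_bwg_g": 2463.0,
    "control_fcr": 1.855,
    "bwg_pen_sd": 17.59 * np.sqrt(21),
    "fcr_pen_sd": 0.01 * np.sqrt(21),
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples_per_group: int = 21
    n_ec: int = 100
    marker_effect_fold: float = 3.0
    #: between-sample log-normal sigma of an EC's abundance.  Functional
    #: profiles are far more stable across hosts than taxonomic ones;
    #: 0.3 (~30% CV) reflects that stability.
    abundance_lognormal_sigma: float = 0.3
    depth_range: tuple[int, int] = (50_000, 200_000)
    ct_noise_sd: float = 0.2
    true_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_SLOPES))
    pen_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"bwg_shift_g": 75.0, "fcr_shift": -0.069}
    )
    mortality_prob: float = 0.03

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise SimulationError("n_samples_per_group must be >= 1")
        if self.marker_effect_fold <= 0 or self.abundance_lognormal_sigma <= 0:
            raise SimulationError("fold and sigma must be positive")
        if not 0 <= self.mortality_prob <= 1:
            raise SimulationError("mortality_prob must be in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise SimulationError("invalid depth_range")
        if self.ct_noise_sd < 0:
            raise SimulationError("ct_noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ----------------------------------------------------------------- counts

@dataclass
class SimulatedCounts:
    table: GeneCountTable
    labels: pd.Series  # sample -> "control" | "pb"
    ko_to_ec: dict[str, set[str]]
    normalization_ecs: tuple[str, ...]
    ec_pathways: dict[str, list[str]]
    true_mpmi_ratio: float  # expected MPMI(pb) / MPMI(control)


def gen_counts(config: SimulationConfig) -> SimulatedCounts:
    """Simulate a samples × KO count table for a two-group trial.

    The EC universe is the 22-reaction marker catalog, the 19
    glycolysis/TCA normalization enzymes, and synthetic filler ECs up to
    ``n_ec``.  Treatment multiplies numerator-marker KO abundances by
    ``marker_effect_fold``; because the internal normalization cancels in
    the index's N/D ratio, the expected MPMI(pb)/MPMI(control) ratio is
    the fold itself.
    """
    markers, _ = cat.load_catalog()
    base_ecs = [m.ec_number for m in markers] + list(GLYCOLYSIS_TCA_ECS)
    if config.n_ec < len(base_ecs):
        raise SimulationError(
            f"n_ec must be >= {len(base_ecs)} (catalog + normalization ECs)"
        )
    n_filler = config.n_ec - len(base_ecs)
    filler = [f"9.9.9.{i + 1}" for i in range(n_filler)]
    ec_ids = base_ecs + filler

    ko_to_ec: dict[str, set[str]] = {}
    for m in markers:
        for ko in m.kegg_ids:
            ko_to_ec.setdefault(ko, set()).add(m.ec_number)
    synth = 80000
    for ec in list(GLYCOLYSIS_TCA_ECS) + filler:
        ko_to_ec[f"K{synth}"] = {ec}
        synth += 1
    ko_ids = sorted(ko_to_ec)

    rng = np.random.default_rng(config.seed)
    sigma = config.abundance_lognormal_sigma
    # per-EC baseline relative abundance (wide spread across ECs);
    # housekeeping energy enzymes high
    baseline = {
        ec: float(rng.lognormal(mean=0.0, sigma=1.0)) for ec in ec_ids
    }
    for ec in GLYCOLYSIS_TCA_ECS:
        baseline[ec] *= 50.0
    numerators = {m.ec_number for m in markers if m.role == "N"}
    n_kos = {ko for m in markers if m.role == "N" for ko in m.kegg_ids}

    n = config.n_samples_per_group
    sample_ids = [f"S{i + 1:03d}" for i in range(2 * n)]
    labels = pd.Series(
        ["control"] * n + ["pb"] * n, index=sample_ids, name="treatment"
    )
    counts = np.zeros((2 * n, len(ko_ids)), dtype=np.int64)
    # a KO mapping to k ECs carries the mean baseline of its ECs
    ko_base = np.array(
        [np.mean([baseline[ec] for ec in ko_to_ec[ko]]) for ko in ko_ids]
    )
    is_n_ko = np.array([ko in n_kos for ko in ko_ids])
    for i, sample in enumerate(sample_ids):
        rel = ko_base * rng.lognormal(mean=0.0, sigma=sigma, size=len(ko_ids))
        if labels[sample] == "pb":
            rel = np.where(is_n_ko, rel * config.marker_effect_fold, rel)
        depth = rng.integers(config.depth_range[0], config.depth_range[1] + 1)
        counts[i] = rng.poisson(depth * rel / rel.sum())

    pathways = _synthetic_pathways(ec_ids, np.random.default_rng(config.seed + 7))
    table = GeneCountTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=ko_ids)
    )
    return SimulatedCounts(
        table=table,
        labels=labels,
        ko_to_ec=ko_to_ec,
        normalization_ecs=tuple(GLYCOLYSIS_TCA_ECS),
        ec_pathways=pathways,
        true_mpmi_ratio=config.marker_effect_fold,
    )


def _synthetic_pathways(ec_ids: list[str], rng: np.random.Generator) -> dict[str, list[str]]:
    pool = [f"map{100 + i:05d}" for i in range(25)]
    return {
        ec: list(rng.choice(pool, size=int(rng.integers(1, 6)), replace=False))
        for ec in ec_ids
    }


# ------------------------------------------------------------------- qPCR

@dataclass
class SimulatedQpcr:
    calibration: pd.DataFrame  # source, dilution, marker, ct
    plate: list[QpcrMeasurement]
    labels: pd.Series  # sample -> "control" | "pb"
    true_ratios: pd.DataFrame  # samples × markers, true [R_i]/[16S]
    true_slopes: dict[str, float]
    true_intercepts: dict[str, float]
    true_source_offsets: dict[str, float]


def gen_qpcr(
    config: SimulationConfig,
    n_sources: int = 3,
    dilutions: tuple[float, ...] = (1.0, 1e-1, 1e-2, 1e-3, 1e-4),
    replicates: int = 2,
    template_scale: float = 1.0,
    marker_base_ratio: float = 1e-3,
) -> SimulatedQpcr:
    """Simulate calibration dilution series and duplicate-well plates.

    Ct values are generated from the same log-linear model the fitting
    stage assumes (4 orders of magnitude of dilution, additive per-source
    offsets, Gaussian noise) and censored at 40 cycles.
    ``template_scale`` multiplies every template concentration uniformly —
    handy for dilution-invariance checks.
    """
    rng = np.random.default_rng(config.seed + 11)
    slopes = dict(config.true_slopes)
    intercepts = {k: float(rng.uniform(19.0, 23.0)) for k in slopes}
    sources = [f"src{i + 1}" for i in range(n_sources)]
    offsets = {s: (0.0 if i == 0 else float(rng.normal(0.0, 1.0)))
               for i, s in enumerate(sources)}

    cal_rows = []
    for marker, m in slopes.items():
        for s in sources:
            for d in dilutions:
                for _ in range(replicates):
                    ct = (
                        m * np.log10(d)
                        + intercepts[marker]
                        + offsets[s]
                        + rng.normal(0.0, config.ct_noise_sd)
                    )
                    cal_rows.append(
                        {"source": s, "dilution": d, "marker": marker, "ct": float(ct)}
                    )
    calibration = pd.DataFrame(cal_rows)

    markers, _ = cat.load_catalog()
    roles = {m.ec_number: m.role for m in markers if m.is_qpcr_marker}
    n = config.n_samples_per_group
    sample_ids = [f"Q{i + 1:03d}" for i in range(2 * n)]
    labels = pd.Series(["control"] * n + ["pb"] * n, index=sample_ids, name="treatment")

    plate: list[QpcrMeasurement] = []
    ratio_rows = []
    for sample in sample_ids:
        r16 = template_scale * float(rng.lognormal(0.0, 0.3))
        row = {"sample": sample}
        concs = {cat.SIXTEEN_S: r16}
        for ec in roles:
            base = float(rng.lognormal(np.log(marker_base_ratio), 0.4))
            if labels[sample] == "pb" and roles[ec] == "N":
                base *= config.marker_effect_fold
            concs[ec] = base * r16
            row[ec] = base  # true [R_i]/[16S]
        ratio_rows.append(row)
        for marker, conc in concs.items():
            for rep in (1, 2):
                ct = (
                    slopes[marker] * np.log10(conc)
                    + intercepts[marker]
                    + rng.normal(0.0, config.ct_noise_sd)
                )
                detected = ct <= MAX_CYCLES
                plate.append(
                    QpcrMeasurement(
                        sample_id=sample,
                        marker_ec=marker,
                        pair_id="blend",
                        replicate_index=rep,
                        ct=float(ct) if detected else None,
                        detected=bool(detected),
                    )
                )
    true_ratios = pd.DataFrame(ratio_rows).set_index("sample")
    return SimulatedQpcr(
        calibration=calibration,
        plate=plate,
        labels=labels,
        true_ratios=true_ratios,
        true_slopes=slopes,
        true_intercepts=intercepts,
        true_source_offsets=offsets,
    )


# -------------------------------------------------------------------- pens

def gen_pens(
    config: SimulationConfig,
    n_pens: int = 21,
    birds_per_pen: int = 40,
    conditions: dict[str, float] | None = None,
) -> list[PenPerformance]:
    """Simulate a blocked two-treatment grow-out trial at the pen level.

    Pen BWG ~ Normal(control mean + shift, between-pen SD); feed intake is
    derived from the pen's FCR and its mortality-adjusted total gain (dead
    birds credited half the gain), so the analysis stage recovers the
    generating FCR exactly.
    """
    cond = dict(PEN_STUDY_CONDITIONS)
    if conditions:
        cond.update(conditions)
    rng = np.random.default_rng(config.seed + 23)
    bw0 = 40.0
    pens: list[PenPerformance] = []
    for b in range(n_pens):
        for trt in ("control", "pb"):
            shift_bwg = config.pen_effect_sizes["bwg_shift_g"] if trt == "pb" else 0.0
            shift_fcr = config.pen_effect_sizes["fcr_shift"] if trt == "pb" else 0.0
            bwg = float(rng.normal(cond["control_bwg_g"] + shift_bwg, cond["bwg_pen_sd"]))
            fcr = float(rng.normal(cond["control_fcr"] + shift_fcr, cond["fcr_pen_sd"]))
            mortality = int(rng.binomial(birds_per_pen, config.mortality_prob))
            survivors = birds_per_pen - mortality
            total_gain = survivors * bwg + mortality * bwg / 2.0
            pens.append(
                PenPerformance(
                    pen_id=f"P{b + 1:02d}{'C' if trt == 'control' else 'T'}",
                    treatment=trt,
                    block=f"B{b + 1:02d}",
                    bird_count_start=birds_per_pen,
                    body_weight_g=(
                        bw0,
                        bw0 + 0.10 * bwg,
                        bw0 + 0.48 * bwg,
                        bw0 + bwg,
                    ),
                    feed_intake_g=fcr * total_gain,
                    mortality_count=mortality,
                )
            )
    return pens


def pens_frame(pens: list[PenPerformance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pen": p.pen_id,
                "treatment": p.treatment,
                "block": p.block,
                "n0": p.bird_count_start,
                "bw0": p.body_weight_g[0],
                "bw10": p.body_weight_g[1],
                "bw24": p.body_weight_g[2],
                "bw42": p.body_weight_g[3],
                "fi_total": p.feed_intake_g,
                "mortality": p.mortality_count,
                "removal_wt_sum": (
                    p.removal_weight_sum_g if p.removal_weight_sum_g is not None else ""
                ),
            }
            for p in pens
        ]
    )


# -------------------------------------------------------------------- SCFA

def gen_scfa(
    config: SimulationConfig,
    n_per_group: int = 6,
    pb_effect: float = 10.0,
    detection_limit: float = 0.3,
) -> pd.DataFrame:
    """Simulate ex vivo supernatant SCFA concentrations (mM).

    Acetate is present in all groups; control propionate and butyrate fall
    below the detection limit and are flagged non-detected, while treatment
    raises all three acids by ``pb_effect``-fold.
    """
    rng = np.random.default_rng(config.seed + 31)
    rows = []
    i = 0
    for cohort in ("low_bw", "high_bw"):
        for trt in ("control", "pb"):
            for _ in range(n_per_group):
                i += 1
                fold = pb_effect if trt == "pb" else 1.0
                acetate = float(rng.lognormal(np.log(5.0 * fold), 0.3))
                propionate = float(rng.lognormal(np.log(0.1 * fold), 0.3))
                butyrate = float(rng.lognormal(np.log(0.08 * fold), 0.3))
                rows.append(
                    {
                        "sample": f"X{i:03d}",
                        "treatment": trt,
                        "cohort": cohort,
                        "acetate": acetate,
                        "propionate": propionate if propionate >= detection_limit else 0.0,
                        "butyrate": butyrate if butyrate >= detection_limit else 0.0,
                        "propionate_detected": propionate >= detection_limit,
                        "butyrate_detected": butyrate >= detection_limit,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")
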