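"""Calibration fitting, relative abundances, replicate policy, qMPMI."""

import math

import numpy as np
import pandas as pd
import pytest

from mpmi import catalog, qpcr, simulate as sim
from mpmi.qpcr import (
    CalibrationFit,
    QpcrError,
    QpcrMeasurement,
    RelativeAbundance,
)


def noise_free_series(m=-3.32, b=25.0, dilutions=(1.0, 0.1, 0.01, 1e-3, 1e-4)):
    return [("src1", d, m * math.log10(d) + b) for d in dilutions]


class TestFitCalibration:
    def test_noise_free_exact_recovery(self):
        fit = qpcr.fit_calibration(noise_free_series(), key="16S")
        assert fit.slope == pytest.approx(-3.32, abs=1e-9)
        assert fit.intercept == pytest.approx(25.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_sources_offset_recovery(self):
        # parameter-recovery: true offsets {0, +1.5}, Ct noise sd 0.15
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(100):
            rows = []
            for s, off in (("src1", 0.0), ("src2", 1.5)):
                for d in (1.0, 0.1, 0.01, 1e-3, 1e-4):
                    ct = -3.32 * math.log10(d) + 22.0 + off + rng.normal(0, 0.15)
                    rows.append((s, d, ct))
            fit = qpcr.fit_calibration(rows, key="x")
            errors.append(fit.source_offsets["src2"] - 1.5)
        assert abs(np.mean(errors)) < 0.05
        assert np.percentile(np.abs(errors), 90) < 0.25

    def test_single_dilution_level_rejected(self):
        with pytest.raises(QpcrError):
            qpcr.fit_calibration([("s", 1.0, 20.0), ("s", 1.0, 20.1), ("s", 1.0, 19.9)], "x")

    def test_nonpositive_dilution_rejected(self):
        with pytest.raises(QpcrError):
            qpcr.fit_calibration([("s", 1.0, 20.0), ("s", 0.0, 25.0), ("s", 0.1, 23.0)], "x")

    def test_dataframe_input(self):
        df = pd.DataFrame(noise_free_series(), columns=["source", "dilution", "ct"])
        fit = qpcr.fit_calibration(df, key="16S")
        assert fit.slope == pytest.approx(-3.32, abs=1e-9)


class TestRelativeAbundance:
    fit_m = CalibrationFit(key="2.3.1.109", slope=-3.4, intercept=22.0)
    fit_s = CalibrationFit(key="16S", slope=-3.3, intercept=20.0)

    def test_equal_exponents_give_unity(self):
        ct_m = self.fit_m.slope * 2.0
        ct_s = self.fit_s.slope * 2.0
        a = qpcr.relative_abundance(ct_m, self.fit_m, ct_s, self.fit_s)
        assert a.a_value == pytest.approx(1.0)

    def test_unit_exponent_difference_gives_ten(self):
        ct_m = self.fit_m.slope * 3.0
        ct_s = self.fit_s.slope * 2.0
        a = qpcr.relative_abundance(ct_m, self.fit_m, ct_s, self.fit_s)
        assert a.a_value == pytest.approx(10.0)

    def test_uniform_dilution_invariance(self):
        # diluting the template 10x shifts both Ct through their own lines
        r_marker, r_16s = 1e-3, 1.0
        for factor in (1.0, 0.1, 10.0):
            ct_m = self.fit_m.slope * math.log10(r_marker * factor) + self.fit_m.intercept
            ct_s = self.fit_s.slope * math.log10(r_16s * factor) + self.fit_s.intercept
            a = qpcr.relative_abundance(ct_m, self.fit_m, ct_s, self.fit_s)
            if factor == 1.0:
                reference = a.a_value
            else:
                assert a.a_value == pytest.approx(reference, abs=1e-9 * reference)

    def test_intercept_correction_recovers_true_ratio(self):
        r_marker, r_16s = 2.5e-3, 0.8
        ct_m = self.fit_m.slope * math.log10(r_marker) + self.fit_m.intercept
        ct_s = self.fit_s.slope * math.log10(r_16s) + self.fit_s.intercept
        a = qpcr.relative_abundance(
            ct_m, self.fit_m, ct_s, self.fit_s, intercept_correction=True
        )
        assert a.a_value == pytest.approx(r_marker / r_16s, rel=1e-9)

    def test_zero_slope_rejected(self):
        with pytest.raises(QpcrError):
            CalibrationFit(key="x", slope=0.0, intercept=20.0)


def make_wells(sample, marker, cts, ct16=15.0):
    wells = []
    for i, ct in enumerate(cts, start=1):
        wells.append(
            QpcrMeasurement(sample, marker, "p", i, ct, detected=ct is not None)
        )
        wells.append(QpcrMeasurement(sample, "16S", "u", i, ct16, detected=True))
    return wells


class TestReplicates:
    fits = {
        "2.3.1.109": CalibrationFit(key="2.3.1.109", slope=-3.4, intercept=22.0),
        "16S": CalibrationFit(key="16S", slope=-3.3, intercept=20.0),
    }

    def a_of(self, ct, ct16=15.0):
        return 10.0 ** (ct / -3.4 - ct16 / -3.3)

    def test_mean_on_a_scale(self):
        # choose Cts whose A values are exactly 2 and 4
        ct2 = -3.4 * (math.log10(2.0) + 15.0 / -3.3)
        ct4 = -3.4 * (math.log10(4.0) + 15.0 / -3.3)
        out = qpcr.average_replicates(make_wells("s", "2.3.1.109", [ct2, ct4]), self.fits)
        assert out[0].a_value == pytest.approx(3.0)
        assert out[0].n_replicates == 2

    def test_single_replicate_passthrough(self):
        out = qpcr.average_replicates(make_wells("s", "2.3.1.109", [20.0]), self.fits)
        assert out[0].a_value == pytest.approx(self.a_of(20.0))

    def test_censor_policy_keeps_detected_value_with_flag(self):
        out = qpcr.average_replicates(
            make_wells("s", "2.3.1.109", [20.0, None]),
            self.fits,
            nondetect_policy="censor",
        )
        assert out[0].a_value == pytest.approx(self.a_of(20.0))
        assert out[0].any_nondetect

    def test_floor_policy_uses_ct40_abundance(self):
        out = qpcr.average_replicates(
            make_wells("s", "2.3.1.109", [None, None]), self.fits
        )
        assert out[0].a_value == pytest.approx(self.a_of(40.0))
        assert out[0].any_nondetect

    def test_zero_policy(self):
        out = qpcr.average_replicates(
            make_wells("s", "2.3.1.109", [20.0, None]), self.fits,
            nondetect_policy="zero",
        )
        assert out[0].a_value == pytest.approx(self.a_of(20.0) / 2.0)

    def test_missing_16s_well_rejected(self):
        wells = [QpcrMeasurement("s", "2.3.1.109", "p", 1, 20.0, True)]
        with pytest.raises(QpcrError, match="16S"):
            qpcr.average_replicates(wells, self.fits)


class TestQmpmi:
    def abundances(self, values: dict[str, float]):
        return [RelativeAbundance("s", ec, v) for ec, v in values.items()]

    def test_balance_is_one(self, markers):
        values = {ec: 1.0 for ec in catalog.QPCR_MARKERS}
        table = qpcr.compute_qmpmi(self.abundances(values), markers)
        assert table.loc["s", "qmpmi"] == pytest.approx(1.0)

    def test_doubling_numerators_doubles_index(self, markers):
        base = {ec: 1.0 for ec in catalog.QPCR_MARKERS}
        doubled = dict(base, **{"2.3.1.109": 2.0, "2.6.1.19": 2.0})
        t1 = qpcr.compute_qmpmi(self.abundances(base), markers)
        t2 = qpcr.compute_qmpmi(self.abundances(doubled), markers)
        assert t2.loc["s", "qmpmi"] == pytest.approx(2 * t1.loc["s", "qmpmi"])

    def test_monotone_in_roles(self, markers):
        base = {ec: 1.0 for ec in catalog.QPCR_MARKERS}
        t0 = qpcr.compute_qmpmi(self.abundances(base), markers).loc["s", "qmpmi"]
        up_n = qpcr.compute_qmpmi(
            self.abundances(dict(base, **{"2.3.1.109": 1.5})), markers
        ).loc["s", "qmpmi"]
        up_d = qpcr.compute_qmpmi(
            self.abundances(dict(base, **{"3.5.3.12": 1.5})), markers
        ).loc["s", "qmpmi"]
        assert up_n > t0 > up_d

    def test_zero_denominator_flagged(self, markers):
        values = {"2.3.1.109": 1.0, "2.6.1.19": 1.0, "3.5.3.12": 0.0, "2.8.3.18": 0.0}
        table = qpcr.compute_qmpmi(self.abundances(values), markers)
        assert not table.loc["s", "defined"]
        assert math.isnan(table.loc["s", "qmpmi"])

    def test_missing_role_rejected(self, markers):
        with pytest.raises(QpcrError):
            qpcr.compute_qmpmi(self.abundances({"2.3.1.109": 1.0}), markers)


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_generating_ratios(self, markers):
        cfg = sim.SimulationConfig(seed=4, n_samples_per_group=4, ct_noise_sd=0.0)
        q = sim.gen_qpcr(cfg)
        fits = {
            str(m): qpcr.fit_calibration(g, key=str(m))
            for m, g in q.calibration.groupby("marker")
        }
        ab = qpcr.average_replicates(q.plate, fits, intercept_correction=True)
        for a in ab:
            true = q.true_ratios.loc[a.sample_id, a.marker_ec]
            assert a.a_value == pytest.approx(true, rel=1e-6)

    def test_qmpmi_dilution_invariance(self, markers):
        # templates kept within the quantifiable range (no Ct-40 censoring)
        cfg = sim.SimulationConfig(seed=4, n_samples_per_group=3, ct_noise_sd=0.0)
        tables = []
        for scale in (1e-2, 1.0, 1e2):
            q = sim.gen_qpcr(cfg, template_scale=scale, marker_base_ratio=1e-2)
            fits = {
                str(m): qpcr.fit_calibration(g, key=str(m))
                for m, g in q.calibration.groupby("marker")
            }
            ab = qpcr.average_replicates(q.plate, fits)
            tables.append(qpcr.compute_qmpmi(ab, markers)["qmpmi"])
        assert np.allclose(tables[0], tables[1], rtol=1e-6)
        assert np.allclose(tables[1], tables[2], rtol=1e-6)

    def test_hundredfold_enrichment_recovered_within_twofold(self, markers):
        cfg = sim.SimulationConfig(
            seed=6, n_samples_per_group=6, marker_effect_fold=100.0, ct_noise_sd=0.2
        )
        q = sim.gen_qpcr(cfg)
        fits = {
            str(m): qpcr.fit_calibration(g, key=str(m))
            for m, g in q.calibration.groupby("marker")
        }
        table = qpcr.compute_qmpmi(
            qpcr.average_replicates(q.plate, fits), markers
        ).join(q.labels)
        ratio = (
            table[table["treatment"] == "pb"]["qmpmi"].median()
            / table[table["treatment"] == "control"]["qmpmi"].median()
        )
        assert 50.0 <= ratio <= 200.0


def test_measurement_invariants():
    with pytest.raises(QpcrError):
        QpcrMeasurement("s", "16S", "p", 1, 41.0, detected=True)
    with pytest.raises(QpcrError):
        QpcrMeasurement("s", "16S", "p", 1, 20.0, detected=False)
    with pytest.raises(QpcrError):
        QpcrMeasurement("s", "16S", "p", 1, None, detected=True)
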