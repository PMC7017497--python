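"""Bile-acid post-processing: drift correction, calibration, pools."""

import numpy as np
import pandas as pd
import pytest

from quantgut import bileacids as ba
from quantgut.samples import SampleRecord

RF = {"TCA": 10000.0, "CA": 8000.0, "DCA": 12000.0, "TDCA": 11000.0,
      "UDCA": 9000.0, "HDCA": 9500.0}
IS_RF = 10000.0


def make_run(samples_um, drift=lambda i: 1.0, qc_every=4,
             cal_levels=(0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 30.0)):
    """Deterministic long-format run: QCs, one calibration series, samples.

    `samples_um` maps sample_id -> {species: extract concentration in uM}.
    """
    species = sorted(RF)
    payload = [("standard", c) for c in cal_levels] + [
        ("sample", s) for s in samples_um
    ]
    rows, idx, since_qc = [], 0, qc_every

    def emit(kind, ident, concs):
        nonlocal idx
        for sp in species:
            rows.append({
                "injection_index": idx, "sample_id": ident, "injection_type": kind,
                "standard_conc_uM": concs.get(sp, 0.0) if kind == "standard" else np.nan,
                "species": sp, "area": RF[sp] * concs.get(sp, 0.0) * drift(idx),
                "is_id": f"D4-{sp}", "is_area": IS_RF * 5.0 * drift(idx),
            })
        idx += 1

    for kind, ident in payload:
        if since_qc >= qc_every:
            emit("qc", f"QC_{idx}", {sp: 2.0 for sp in species})
            since_qc = 0
        if kind == "standard":
            emit("standard", f"STD_{ident}", {sp: float(ident) for sp in species})
        else:
            emit("sample", ident, samples_um[ident])
        since_qc += 1
    return pd.DataFrame(rows)


@pytest.fixture()
def panel():
    return ba.load_panel()


class TestPanel:
    def test_every_species_classified_on_both_axes(self, panel):
        assert panel["conjugation"].isin(["tauro", "glyco", "unconjugated"]).all()
        assert panel["ba_class"].isin(["primary", "secondary"]).all()

    def test_udca_hdca_are_a_merged_pair(self, panel):
        assert panel.loc["UDCA", "merged_with"] == "HDCA"
        assert panel.loc["HDCA", "merged_with"] == "UDCA"


class TestDrift:
    def test_constant_qc_leaves_areas_unchanged(self):
        run = make_run({"s1": {"TCA": 5.0}})
        out = ba.correct_drift(run)
        pd.testing.assert_frame_equal(out, run)

    def test_linear_decline_recovers_constant_series(self):
        # ten identical samples under a drift reaching 90% by the run's end
        samples = {f"s{i}": {"TCA": 5.0} for i in range(10)}
        run = make_run(samples, drift=lambda i: 1.0 - 0.004 * i)
        out = ba.correct_drift(run)
        smp = out[(out["injection_type"] == "sample") & (out["species"] == "TCA")]
        qc_idx = run.loc[run["injection_type"] == "qc", "injection_index"]
        bracketed = smp[smp["injection_index"] <= qc_idx.max()]
        areas = bracketed["area"].to_numpy()
        assert np.all(np.abs(areas / areas[0] - 1.0) < 1e-6)
        # beyond the last QC the nearest QC's factor is held (edge rule), so
        # residual drift there equals the drift accrued past that QC
        tail = smp[smp["injection_index"] > qc_idx.max()]
        for _, row in tail.iterrows():
            expected = areas[0] * (1 - 0.004 * row["injection_index"]) / (
                1 - 0.004 * qc_idx.max()
            )
            assert row["area"] == pytest.approx(expected, rel=1e-9)

    def test_single_qc_warns_and_skips(self):
        run = make_run({"s1": {"TCA": 5.0}}, qc_every=100)
        with pytest.warns(UserWarning):
            out = ba.correct_drift(run)
        pd.testing.assert_frame_equal(out, run)


class TestCalibration:
    def test_perfectly_linear_response(self):
        run = make_run({})
        fits = ba.fit_calibration(run)
        fit = fits["TCA"]
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        # back-calculating the midpoint standard returns its concentration
        mid_response = RF["TCA"] * 5.0 / (IS_RF * 5.0) * ba.IS_CONC_UM
        assert fit.concentration_at(mid_response) == pytest.approx(5.0, rel=1e-9)

    def test_zero_slope_flagged_invalid(self):
        run = make_run({})
        run["area"] = 100.0
        fit = ba.fit_calibration(run)["TCA"]
        assert not fit.is_valid


class TestQuantify:
    def _meta(self):
        return [
            SampleRecord("s1", "m1", "CTRL", "SI2", "contents",
                         mass_g=0.1, dilution_factor=100.0),
            SampleRecord("b1", "m1", "CTRL", "BILE", "bile",
                         dilution_factor=10000.0),
        ]

    def test_inversion_and_unit_chain(self, panel):
        run = make_run({"s1": {"TCA": 5.0, "CA": 1.0},
                        "b1": {"TCA": 2.0}})
        fits = ba.fit_calibration(run)
        conc = ba.quantify(run, fits, self._meta(), panel)
        # extract 5 uM x chain 100 -> 500 nmol/g
        assert conc.values.loc["s1", "TCA"] == pytest.approx(500.0, rel=1e-9)
        assert conc.units["s1"] == "nmol/g"
        assert conc.values.loc["b1", "TCA"] == pytest.approx(20000.0, rel=1e-9)
        assert conc.units["b1"] == "uM"

    def test_below_lloq_zeroed_and_flagged(self, panel):
        run = make_run({"s1": {"TCA": 0.01}})
        fits = ba.fit_calibration(run)
        conc = ba.quantify(run, fits, self._meta(), panel)
        assert conc.values.loc["s1", "TCA"] == 0.0
        assert conc.flags.loc["s1", "TCA"] == ba.FLAG_BELOW_LLOQ

    def test_above_range_flagged_but_reported(self, panel):
        run = make_run({"s1": {"TCA": 40.0}})
        fits = ba.fit_calibration(run)
        conc = ba.quantify(run, fits, self._meta(), panel)
        assert conc.flags.loc["s1", "TCA"] == ba.FLAG_ABOVE_RANGE
        assert conc.values.loc["s1", "TCA"] == pytest.approx(4000.0, rel=1e-6)

    def test_udca_hdca_merged_to_their_sum(self, panel):
        run = make_run({"s1": {"UDCA": 2.0, "HDCA": 3.0}})
        fits = ba.fit_calibration(run)
        conc = ba.quantify(run, fits, self._meta(), panel)
        assert "HDCA/UDCA" in conc.values.columns
        assert "UDCA" not in conc.values.columns
        assert conc.extract_um.loc["s1", "HDCA/UDCA"] == pytest.approx(5.0, rel=1e-9)


class TestSummary:
    def _conc(self, mapping):
        values = pd.DataFrame([mapping], index=["s"])
        return ba.ConcentrationTable(
            values, values.copy(),
            pd.DataFrame(ba.FLAG_OK, index=values.index, columns=values.columns),
            pd.Series({"s": "nmol/g"}),
        )

    def test_pool_fractions(self, panel):
        summary = ba.summarize_profile(self._conc({"TCA": 5.0}), panel)
        assert summary.loc["s", "fraction_unconjugated"] == 0.0
        assert summary.loc["s", "fraction_secondary"] == 0.0

        summary = ba.summarize_profile(self._conc({"TCA": 5.0, "CA": 5.0}), panel)
        assert summary.loc["s", "fraction_unconjugated"] == pytest.approx(0.5)

        summary = ba.summarize_profile(
            self._conc({"CA": 4.0, "DCA": 4.0, "TDCA": 2.0}), panel
        )
        assert summary.loc["s", "fraction_secondary"] == pytest.approx(0.6)
        assert summary.loc["s", "total"] == pytest.approx(10.0)

    def test_fractions_invariant_under_uniform_scaling(self, panel):
        a = ba.summarize_profile(self._conc({"TCA": 5.0, "CA": 3.0, "DCA": 2.0}), panel)
        b = ba.summarize_profile(
            self._conc({"TCA": 50.0, "CA": 30.0, "DCA": 20.0}), panel
        )
        assert a.loc["s", "fraction_unconjugated"] == pytest.approx(
            b.loc["s", "fraction_unconjugated"]
        )
        assert a.loc["s", "fraction_secondary"] == pytest.approx(
            b.loc["s", "fraction_secondary"]
        )

    def test_unclassified_species_rejected(self, panel):
        with pytest.raises(ValueError):
            ba.summarize_profile(self._conc({"XYZ": 1.0}), panel)
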