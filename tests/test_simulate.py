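"""Synthetic study generator: design contracts, closed forms, round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from quantgut import simulate
from quantgut.samples import UPPER_GIT_SITES, read_metadata
from quantgut.profiling import Taxonomy, read_counts


class TestDesign:
    def test_sample_arithmetic_of_the_full_design(self, default_study):
        # 6 mice x 4 groups x 6 sites of contents, plus SI2 mucosa and bile
        contents = [r for r in default_study.metadata if r.material == "contents"]
        assert len(contents) == 144
        assert default_study.asv_counts.shape[0] == 144
        mucosa = [r for r in default_study.metadata if r.material == "mucosa"]
        assert len(mucosa) == 24
        bile = [r for r in default_study.metadata if r.material == "bile"]
        assert len(bile) == 24

    def test_zero_depth_disallowed(self):
        with pytest.raises(ValueError, match="sequencing_depth"):
            simulate.generate_study(simulate.SimulationConfig(sequencing_depth=0))

    def test_bad_fields_name_the_field(self):
        with pytest.raises(ValueError, match="n_mice_per_group"):
            simulate.generate_study(simulate.SimulationConfig(n_mice_per_group=0))
        with pytest.raises(ValueError, match="count_model"):
            simulate.generate_study(simulate.SimulationConfig(count_model="poisson"))

    def test_same_seed_bit_identical(self):
        a = simulate.generate_study(simulate.SimulationConfig(seed=9))
        b = simulate.generate_study(simulate.SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(a.asv_counts, b.asv_counts)
        pd.testing.assert_series_equal(a.truth_loads, b.truth_loads)
        pd.testing.assert_frame_equal(a.bileacid_areas, b.bileacid_areas)

    def test_different_seed_differs(self):
        a = simulate.generate_study(simulate.SimulationConfig(seed=9))
        b = simulate.generate_study(simulate.SimulationConfig(seed=10))
        assert not a.asv_counts.equals(b.asv_counts)


class TestGroundTruthModel:
    def test_fecal_taxa_truly_absent_in_tcf_upper_git(self, default_study):
        fecal = [t.name for t in default_study.config.taxon_panel if t.behavior == "fecal"]
        for rec in default_study.metadata:
            if rec.group == "TC-F" and rec.site in UPPER_GIT_SITES and rec.material == "contents":
                assert (default_study.truth_absolute.loc[rec.sample_id, fecal] == 0).all()

    def test_contaminants_have_zero_truth_everywhere(self, default_study):
        contams = [c.name for c in default_study.config.contaminant_panel]
        assert (default_study.truth_absolute[contams] == 0).all().all()
        # yet their reads are nonzero somewhere (ambient-mass mechanism)
        assert default_study.asv_counts[contams].to_numpy().sum() > 0

    def test_contaminant_frequency_tracks_inverse_concentration(self, default_study):
        # pooled contaminant read frequency should fall with DNA concentration
        meta = {r.sample_id: r for r in default_study.metadata}
        contams = [c.name for c in default_study.config.contaminant_panel]
        freq = (
            default_study.asv_counts[contams].sum(axis=1)
            / default_study.asv_counts.sum(axis=1)
        )
        conc = pd.Series({s: meta[s].dna_conc_ng_ul for s in freq.index})
        present = freq > 0
        r = np.corrcoef(np.log(freq[present]), np.log(conc[present]))[0, 1]
        assert r < -0.9

    def test_tcf_upper_microbial_loads_are_orders_of_magnitude_lower(self, default_study):
        # microbial load excludes the constant dietary organellar 16S signal
        microbial = [
            t.name for t in default_study.config.taxon_panel if t.behavior != "dietary"
        ]
        truth = default_study.truth_absolute[microbial].sum(axis=1)
        meta = {r.sample_id: r for r in default_study.metadata}
        by = {}
        for sid, load in truth.items():
            rec = meta[sid]
            by.setdefault((rec.group == "TC-F", rec.site), []).append(math.log10(load))
        for site in ("SI1", "SI2", "SI3"):
            assert np.mean(by[(True, site)]) < np.mean(by[(False, site)]) - 1.5

    def test_expected_counts_mode_matches_composition_exactly(self, noise_free_study):
        counts = noise_free_study.asv_counts
        np.testing.assert_allclose(counts.sum(axis=1), 10000.0, rtol=1e-9)
        rel_counts = counts.div(counts.sum(axis=1), axis=0)
        truth = noise_free_study.truth_absolute
        rel_truth = truth.div(truth.sum(axis=1), axis=0)
        np.testing.assert_allclose(
            rel_counts.to_numpy(), rel_truth.to_numpy(), atol=1e-12
        )


class TestAssayGenerators:
    def test_ddpcr_occupancy_closed_form(self, rng):
        # lambda = ln 2 per droplet -> mean positive fraction 1/2
        conc = math.log(2) / (0.85e-3)
        fracs = [
            simulate.gen_ddpcr_run(conc, rng, 20000, 0.85).n_positive / 20000
            for _ in range(200)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.002)

    def test_ddpcr_extremes(self, rng):
        assert simulate.gen_ddpcr_run(0.0, rng).n_positive == 0
        run = simulate.gen_ddpcr_run(1e9, rng, 20000, 0.85, dilution=1.0)
        assert run.n_positive == 20000

    def test_mpn_zero_density_all_negative(self, rng):
        plate = simulate.gen_mpn_plate(0.0, rng)
        assert sum(plate.n_positive) == 0

    def test_mpn_expected_half_positive_at_ln2(self, rng):
        # density such that lambda = ln 2 in the first dilution's wells
        density = math.log(2) / 1e-3
        firsts = [
            simulate.gen_mpn_plate(density, rng, 1, 8, 0.01).n_positive[0]
            for _ in range(500)
        ]
        assert np.mean(firsts) == pytest.approx(4.0, abs=0.15)

    def test_mpn_positives_decline_with_dilution(self, rng):
        mean_pos = np.zeros(8)
        for _ in range(100):
            mean_pos += simulate.gen_mpn_plate(5e5, rng).n_positive
        diffs = np.diff(mean_pos)
        assert (diffs <= 0).all()

    def test_qpcr_decade_spacing_noise_free(self, rng):
        run = simulate.gen_qpcr_run(1e5, rng, cq_sd=0.0)
        cqs = sorted(cq for _, cq in run.standards)
        gaps = np.diff(cqs)
        np.testing.assert_allclose(gaps, 3.3219, rtol=1e-4)
        assert len(set(run.cq_values)) == 1  # identical triplicates

    def test_qpcr_doubling_lowers_cq_by_one_cycle(self, rng):
        a = simulate.gen_qpcr_run(1e5, rng, cq_sd=0.0).cq_values[0]
        b = simulate.gen_qpcr_run(2e5, rng, cq_sd=0.0).cq_values[0]
        assert a - b == pytest.approx(1.0, rel=1e-9)

    def test_qpcr_nonpositive_copies_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate.gen_qpcr_run(0.0, rng)

    def test_bileacid_run_drift_and_qc_contract(self, rng):
        pools = pd.DataFrame({"TCA": [500.0], "CA": [100.0]}, index=["s1"])
        run = simulate.gen_bileacid_run(
            pools, rng, drift_slope=-0.01, qc_every=8, peak_area_cv=0.0
        )
        qc = run[run["injection_type"] == "qc"]
        assert 0 in qc["injection_index"].tolist()
        # QC response declines ~8% over 8 injections under slope -0.01
        tca = qc[qc["species"] == "TCA"].sort_values("injection_index")
        idx = tca["injection_index"].to_numpy()
        areas = tca["area"].to_numpy()
        step = np.where(np.diff(idx) > 0)[0]
        ratio = areas[1] / areas[0]
        expected = (1 - 0.01 * idx[1]) / (1 - 0.01 * idx[0])
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_bileacid_drift_free_areas_proportional(self, rng):
        pools = pd.DataFrame({"TCA": [500.0], "CA": [250.0]}, index=["s1"])
        run = simulate.gen_bileacid_run(pools, rng, drift_slope=0.0, peak_area_cv=0.0)
        smp = run[run["injection_type"] == "sample"].set_index("species")
        ratio = smp.loc["TCA", "area"] / smp.loc["CA", "area"]
        expected = (500.0 * simulate.BA_RESPONSE_FACTORS["TCA"]) / (
            250.0 * simulate.BA_RESPONSE_FACTORS["CA"]
        )
        assert ratio == pytest.approx(expected, rel=1e-12)


class TestRoundTrips:
    def test_all_raw_files_round_trip(self, default_study, tmp_path):
        paths = simulate.write_study(default_study, tmp_path)

        meta = read_metadata(paths["metadata"])
        assert [r.sample_id for r in meta] == [r.sample_id for r in default_study.metadata]

        counts = read_counts(paths["counts"])
        pd.testing.assert_frame_equal(
            counts.sort_index().sort_index(axis=1),
            default_study.asv_counts.sort_index().sort_index(axis=1),
            check_names=False,
        )

        tax = Taxonomy.read(paths["taxonomy"])
        assert tax.lineages == default_study.taxonomy.lineages

        qpcr = simulate.read_qpcr_runs(paths["qpcr"])
        assert len(qpcr) == len(default_study.qpcr_runs)
        np.testing.assert_allclose(qpcr[0].cq_values, default_study.qpcr_runs[0].cq_values)

        ddpcr = simulate.read_ddpcr_runs(paths["ddpcr"])
        assert [(r.sample_id, r.n_positive) for r in ddpcr] == [
            (r.sample_id, r.n_positive) for r in default_study.ddpcr_runs
        ]

        mpn = simulate.read_mpn_plates(paths["mpn"])
        assert list(mpn[0].n_positive) == list(default_study.mpn_plates[0].n_positive)
        np.testing.assert_allclose(mpn[0].volumes_ml, default_study.mpn_plates[0].volumes_ml)

        areas = pd.read_csv(paths["bileacid_areas"])
        pd.testing.assert_frame_equal(areas, default_study.bileacid_areas)
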