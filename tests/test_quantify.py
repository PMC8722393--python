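"""Quantification tests: classification, Pol II density, summaries, profiles."""

import numpy as np
import pandas as pd
import pytest

from embryofish import (
    ActivationConfig,
    EmbryoGeometry,
    RenderConfig,
    T48,
    MIST,
    classify_spots,
    make_dorsal_profile,
    match_dual_probes,
    mrna_profile,
    polII_density,
    render_embryo,
    simulate_activation,
    summarize_columns,
)
from embryofish.quantify import NoSeparationError, probe_state_fractions
from embryofish.geometry import assign_columns, assign_nuclei
from tests.conftest import detect_3d


def _two_population_spots(n_mrna=300, n_ts=60, mrna_max=20.0, ts_max=1400.0, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "max_int": np.r_[
                mrna_max * rng.lognormal(0, 0.1, n_mrna),
                ts_max * rng.lognormal(0, 0.1, n_ts),
            ],
            "cum_int": np.r_[
                500 * rng.lognormal(0, 0.1, n_mrna),
                35000 * rng.lognormal(0, 0.1, n_ts),
            ],
        }
    )


class TestClassifySpots:
    def test_two_delta_populations_split_cleanly(self):
        spots = pd.DataFrame(
            {
                "max_int": [10.0] * 30 + [1000.0] * 10,
                "cum_int": [500.0] * 30 + [35000.0] * 10,
            }
        )
        res = classify_spots(spots)
        assert 10.0 < res.cutoff < 1000.0
        assert (res.spots["class"] == "TS").sum() == 10
        assert res.ratio == pytest.approx(70.0)

    def test_cutoff_invariant_to_intensity_scaling(self):
        spots = _two_population_spots()
        res1 = classify_spots(spots)
        res2 = classify_spots(spots.assign(max_int=spots.max_int * 137.0,
                                           cum_int=spots.cum_int * 137.0))
        pd.testing.assert_series_equal(res1.spots["class"], res2.spots["class"])
        assert res2.ratio == pytest.approx(res1.ratio)

    def test_unimodal_histogram_rejected(self):
        rng = np.random.default_rng(1)
        spots = pd.DataFrame(
            {"max_int": rng.lognormal(2, 0.1, 200), "cum_int": rng.lognormal(5, 0.1, 200)}
        )
        with pytest.raises(NoSeparationError) as err:
            classify_spots(spots)
        assert err.value.density.shape == err.value.grid.shape

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError):
            classify_spots(_two_population_spots(n_mrna=5, n_ts=5))

    @pytest.mark.parametrize("ratio", [10.0, 30.0, 70.0])
    def test_planted_ratio_recovered_on_rendered_fixture(self, profile, ratio):
        # default noise; single alleles keep the bright sites resolvable
        cfg = ActivationConfig(
            p_mid=1 / 15, T=15.0, n_nuclei_per_column=8, alleles_per_nucleus=1, seed=2
        )
        table = simulate_activation(profile, cfg)
        stacks, _ = render_embryo(table, profile, RenderConfig(seed=102, ratio=ratio))
        spots, _ = detect_3d(stacks)
        res = classify_spots(spots)
        assert res.ratio == pytest.approx(ratio, rel=0.10)


class TestPolIIDensity:
    def test_t48_worked_example(self):
        out = polII_density(70.0, T48)
        assert out["bp_per_polII"] == pytest.approx(1000 * 29 / 70)
        assert round(out["bp_per_polII"], -2) == 400  # ~400 bp, 1 sig fig

    def test_mist_density_relative_to_t48(self):
        out = polII_density(30.0, MIST, reference=(70.0, T48))
        assert out["bp_per_polII"] == pytest.approx(310.0)
        assert out["density_vs_reference"] == pytest.approx(414.29 / 310.0, rel=1e-3)

    def test_single_complex_density(self):
        assert polII_density(1.0, T48)["bp_per_polII"] == pytest.approx(29000.0)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            polII_density(0.0, T48)


def _toy_column_data():
    nuclei = pd.DataFrame(
        {"nucleus_id": range(6), "column": [0, 0, 0, 1, 1, 1]}
    )
    ts = pd.DataFrame(
        {
            "col": [0, 0, 0, 0, 1],
            "cum_int": [10.0, 12.0, 11.0, 13.0, 20.0],
            "nucleus_id": [0, 0, 1, 2, 3],
        }
    )
    counts = pd.Series([2, 1, 1, 1, 0, 0], index=pd.Index(range(6), name="nucleus_id"))
    return ts, nuclei, counts


class TestSummarizeColumns:
    def test_counts_fraction_histogram(self):
        ts, nuclei, counts = _toy_column_data()
        out = summarize_columns(ts, nuclei, counts).set_index("column")
        assert out.loc[0, "n_TS"] == 4
        assert out.loc[0, "F_hat"] == pytest.approx(4 / 6)
        assert (
            out.loc[0, ["n_nuc_0ts", "n_nuc_1ts", "n_nuc_2ts"]].tolist() == [0, 2, 1]
        )
        assert out.loc[0, "median_ts_int"] == pytest.approx(11.5)
        assert out.loc[1, "n_TS"] == 1
        assert out.loc[1, "F_hat"] == pytest.approx(1 / 6)

    def test_empty_column_flagged_missing(self):
        ts, nuclei, counts = _toy_column_data()
        nuclei.loc[5, "column"] = 2
        counts.loc[5] = 0
        out = summarize_columns(ts[ts.col == 0], nuclei, counts).set_index("column")
        assert out.loc[2, "n_TS"] == 0
        assert np.isnan(out.loc[2, "median_ts_int"])

    def test_saturated_fraction_is_one(self):
        nuclei = pd.DataFrame({"nucleus_id": [0, 1], "column": [0, 0]})
        ts = pd.DataFrame(
            {"col": [0] * 4, "cum_int": [1.0] * 4, "nucleus_id": [0, 0, 1, 1]}
        )
        counts = pd.Series([2, 2], index=pd.Index([0, 1], name="nucleus_id"))
        out = summarize_columns(ts, nuclei, counts)
        assert out.loc[0, "F_hat"] == 1.0

    def test_graded_fixture_fraction_tracks_gradient(self, noisy_detection, noisy_embryo):
        spots, _, truth = noisy_detection
        res = classify_spots(spots)
        ts = res.spots[res.spots["class"] == "TS"].reset_index(drop=True)
        geom = EmbryoGeometry(midline_px=truth.midline_y, spacing_px=truth.spacing)
        ts = assign_columns(ts, geom)
        ts, counts = assign_nuclei(ts, truth.nuclei, max_radius=6.0)
        summary = summarize_columns(ts, truth.nuclei, counts)
        inner = summary[np.abs(summary["column"]) <= 2]["F_hat"].mean()
        outer = summary[np.abs(summary["column"]) >= 7]["F_hat"].mean()
        assert inner > outer


class TestMrnaProfile:
    geom = EmbryoGeometry(midline_px=30.0, spacing_px=10.0)

    def test_constant_image_flat_profile(self):
        out = mrna_profile(np.full((61, 20), 5.0), self.geom)
        assert np.allclose(out["median_intensity"], 5.0)

    def test_matches_brute_force_median_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(61, 20))
        out = mrna_profile(img, self.geom).set_index("distance")
        rows = np.arange(61)
        cols = np.rint((rows - 30.0) / 10.0).astype(int)
        for c in np.unique(cols):
            expect = np.median(img[cols == c, :])
            assert out.loc[c, "median_intensity"] == pytest.approx(expect)

    def test_ts_pixels_masked_out(self):
        img = np.full((61, 20), 5.0)
        img[30, 10] = 1e6
        ts = pd.DataFrame({"y": [30.0], "x": [10.0]})
        out = mrna_profile(img, self.geom, ts_spots=ts).set_index("distance")
        assert out.loc[0, "median_intensity"] == pytest.approx(5.0)

    def test_graded_planted_mrna_recovered(self, profile):
        # plant a Dorsal-graded cytoplasmic mRNA density and check the
        # measured profile correlates with the planted gradient
        from scipy.stats import pearsonr

        counts = {int(c): int(round(40 * lvl)) for c, lvl in
                  zip(profile.columns, profile.levels)}
        cfg = ActivationConfig(p_mid=0.0, T=15.0, n_nuclei_per_column=8, seed=3)
        table = simulate_activation(profile, cfg)
        stacks, truth = render_embryo(
            table, profile, RenderConfig(seed=103, mrna_per_column=counts)
        )
        from embryofish import project_max

        geom = EmbryoGeometry(midline_px=truth.midline_y, spacing_px=truth.spacing)
        prof_df = mrna_profile(project_max(stacks["fish"]), geom).set_index("distance")
        shared = [c for c in profile.columns if c in prof_df.index]
        med = prof_df.loc[shared, "median_intensity"]
        lvl = [profile.level(c) for c in shared]
        assert pearsonr(med, lvl).statistic >= 0.9


class TestMatchDualProbes:
    def test_identical_coordinates_all_both(self):
        a = pd.DataFrame({"y": [1.0, 5.0, 9.0], "x": [0.0, 0.0, 0.0]})
        out = match_dual_probes(a, a.copy(), radius=1.0)
        assert (out["state"] == "both").all()

    def test_disjoint_sets_unmatched(self):
        a = pd.DataFrame({"y": [0.0], "x": [0.0]})
        b = pd.DataFrame({"y": [100.0], "x": [100.0]})
        out = match_dual_probes(a, b, radius=3.0)
        assert set(out["state"]) == {"a-only", "b-only"}

    def test_planted_colocalization_fraction_recovered(self):
        rng = np.random.default_rng(8)
        n = 1000
        pos = rng.uniform(20, 980, size=(n, 2))
        both = rng.uniform(size=n) < 0.6
        a = pd.DataFrame({"y": pos[:, 0], "x": pos[:, 1], "col": 0})
        b_pos = np.r_[
            pos[both] + rng.normal(0, 0.5, size=(both.sum(), 2)),
            rng.uniform(20, 980, size=(n - both.sum(), 2)),
        ]
        b = pd.DataFrame({"y": b_pos[:, 0], "x": b_pos[:, 1], "col": 0})
        out = match_dual_probes(a, b, radius=3.0)
        frac = probe_state_fractions(out).loc[0, "frac_both"]
        # "both" count / total loci: 0.6*n both + 0.4*n a-only + 0.4*n b-only
        expect = 0.6 / (0.6 + 0.4 + 0.4)
        assert frac == pytest.approx(expect, abs=0.05)
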