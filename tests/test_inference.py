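import numpy as np
import pandas as pd
import pytest

from resurvey.distances import identity_distance
from resurvey.diversity import bray_curtis
from resurvey.inference import (
    InferenceError,
    LinearFit,
    assign_bands,
    band_beta_contrast,
    band_gamma_contrast,
    crossing_elevation,
    delta_by_area,
    expected_warming_indicator_shift,
    fit_delta_elevation,
    fit_survey_lmm,
    pairwise_beta_table,
    pseudo_turnover_check,
)
from resurvey.preprocess import HISTORICAL, RESURVEY, PlotRecord


def _plot(pid, area, survey, abundances, elevation=800.0):
    return PlotRecord(
        plot_id=pid,
        area_id=area,
        survey=survey,
        elevation=elevation,
        abundances=abundances,
        abundance_type="fractional_cover",
    )


class TestSurveyLMM:
    def test_balanced_design_equals_difference_of_means(self):
        # with equal plot counts in every cell the GLS estimate reduces to
        # the plain difference of survey means, whatever the variances
        delta = -2.75
        rows = []
        base = {"a1": [10.0, 12.0, 14.0], "a2": [8.0, 9.0, 13.0]}
        for area, vals in base.items():
            for i, v in enumerate(vals):
                rows.append((f"{area}h{i}", area, HISTORICAL, v))
                rows.append((f"{area}r{i}", area, RESURVEY, v + delta))
        df = pd.DataFrame(rows, columns=["plot_id", "area_id", "survey", "value"])
        eff = fit_survey_lmm(df, metric="toy")
        assert eff.estimate == pytest.approx(delta, abs=1e-8)
        hist_mean = np.mean([v for vals in base.values() for v in vals])
        assert eff.percent_change == pytest.approx(delta / hist_mean * 100, abs=1e-6)

    def test_transformation_back_transforms_percent_change(self):
        rows = []
        for area in ("a1", "a2", "a3"):
            for i in range(3):
                rows.append((f"{area}h{i}", area, HISTORICAL, 20.0))
                rows.append((f"{area}r{i}", area, RESURVEY, 10.0))
        df = pd.DataFrame(rows, columns=["plot_id", "area_id", "survey", "value"])
        eff = fit_survey_lmm(df, transformation="log1p", metric="toy")
        assert eff.transformation == "log1p"
        assert eff.percent_change == pytest.approx(-50.0, abs=1e-6)

    def test_needs_two_areas_with_both_surveys(self):
        df = pd.DataFrame(
            {
                "plot_id": ["p1", "p2"],
                "area_id": ["a1", "a1"],
                "survey": [HISTORICAL, RESURVEY],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(InferenceError):
            fit_survey_lmm(df)


class TestDeltas:
    def test_known_differences(self):
        df = pd.DataFrame(
            {
                "area_id": ["a"] * 4 + ["b"] * 2,
                "survey": [HISTORICAL, HISTORICAL, RESURVEY, RESURVEY] + [HISTORICAL, RESURVEY],
                "elevation_m": [500.0] * 4 + [900.0] * 2,
                "value": [10, 10, 8, 8, 7, 7],
            }
        )
        out = delta_by_area(df)
        assert dict(zip(out["area_id"], out["delta"])) == pytest.approx(
            {"a": -2.0, "b": 0.0}
        )

    def test_one_survey_area_skipped(self):
        df = pd.DataFrame(
            {
                "area_id": ["a", "a", "b"],
                "survey": [HISTORICAL, RESURVEY, HISTORICAL],
                "elevation_m": [500.0] * 3,
                "value": [10, 8, 7],
            }
        )
        assert list(delta_by_area(df)["area_id"]) == ["a"]

    def test_matches_groupby_oracle(self, rng):
        n_areas = 12
        rows = []
        for a in range(n_areas):
            for s in (HISTORICAL, RESURVEY):
                for i in range(rng.integers(1, 4)):
                    rows.append((f"a{a}", s, 300.0 + 10 * a, rng.normal(20, 3)))
        df = pd.DataFrame(rows, columns=["area_id", "survey", "elevation_m", "value"])
        out = delta_by_area(df).set_index("area_id")["delta"]
        oracle = df.pivot_table(index="area_id", columns="survey", values="value")
        for a in oracle.index:
            assert out[a] == pytest.approx(
                oracle.loc[a, RESURVEY] - oracle.loc[a, HISTORICAL]
            )


class TestDeltaElevationFit:
    def test_exact_line_recovered(self):
        elev = np.array([400.0, 800, 1200, 1600, 2000])
        deltas = pd.DataFrame(
            {"area_id": list("abcde"), "elevation_m": elev, "delta": -6.0 + 0.003 * elev}
        )
        fit = fit_delta_elevation(deltas)
        assert fit.intercept == pytest.approx(-6.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.003, abs=1e-12)
        assert fit.r2_adj == pytest.approx(1.0)

    def test_constant_elevation_rejected(self):
        deltas = pd.DataFrame(
            {"area_id": list("abc"), "elevation_m": [500.0] * 3, "delta": [1.0, 2, 3]}
        )
        with pytest.raises(InferenceError):
            fit_delta_elevation(deltas)

    def test_null_slope_p_uniformish(self, rng):
        # under a flat truth the slope p-value should not pile up near 0
        ps = []
        for _ in range(200):
            elev = rng.uniform(300, 2500, 40)
            deltas = pd.DataFrame(
                {"area_id": range(40), "elevation_m": elev, "delta": rng.normal(0, 1, 40)}
            )
            ps.append(fit_delta_elevation(deltas).p_slope)
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.12


class TestCrossing:
    def test_matches_root_of_line(self):
        fit = LinearFit(intercept=-0.13, slope=7.0e-5, r2_adj=0.16, p_slope=0.001, n=100)
        assert crossing_elevation(fit) == pytest.approx(-(-0.13) / 7.0e-5)
        assert crossing_elevation(fit) == pytest.approx(1857.14, abs=0.01)

    def test_flat_line_undefined(self):
        fit = LinearFit(intercept=1.0, slope=0.0, r2_adj=0.0, p_slope=1.0, n=10)
        assert crossing_elevation(fit) is None

    def test_zero_intercept(self):
        fit = LinearFit(intercept=0.0, slope=-4e-4, r2_adj=0.1, p_slope=0.01, n=10)
        assert crossing_elevation(fit) == 0.0


class TestBands:
    @staticmethod
    def _areas(n, rng=None):
        elev = np.linspace(300, 2500, n)
        return pd.DataFrame({"area_id": [f"a{i:03d}" for i in range(n)], "elevation_m": elev})

    def test_277_gives_study_layout(self):
        assignment, summary = assign_bands(self._areas(277))
        assert list(summary["n_areas"]) == [26, 26] + [25] * 9

    def test_exact_division(self):
        _, summary = assign_bands(self._areas(275))
        assert list(summary["n_areas"]) == [25] * 11

    def test_remainder_to_lowest_bands(self):
        _, summary = assign_bands(self._areas(280))
        assert list(summary["n_areas"]) == [26] * 5 + [25] * 6

    def test_partition_and_ordering(self, rng):
        areas = pd.DataFrame(
            {"area_id": [f"a{i}" for i in range(60)], "elevation_m": rng.uniform(300, 2500, 60)}
        )
        assignment, summary = assign_bands(areas)
        assert sorted(assignment["area_id"]) == sorted(areas["area_id"])
        assert assignment["area_id"].is_unique
        med = summary.sort_values("band")["median_elevation_m"].to_numpy()
        assert (np.diff(med) >= 0).all()
        # bands are contiguous in elevation
        ordered = assignment.sort_values(["elevation_m", "area_id"])["band"].to_numpy()
        assert (np.diff(ordered) >= 0).all()

    def test_too_few_areas(self):
        with pytest.raises(InferenceError):
            assign_bands(self._areas(7))


class TestBandBeta:
    def test_within_area_pairs_excluded_and_null_effect(self, rng):
        labels = [f"s{i}" for i in range(20)]
        dm = identity_distance(labels)
        records, rows = [], []
        for a in range(6):
            for s, tag in ((HISTORICAL, "h"), (RESURVEY, "r")):
                for i in range(2):
                    chosen = rng.choice(labels, 8, replace=False)
                    v = rng.uniform(0.5, 2, 8)
                    rows.append((f"a{a}{tag}{i}", f"a{a}", s, dict(zip(chosen, v))))
        wide_index = [r[0] for r in rows]
        mat = pd.DataFrame(0.0, index=wide_index, columns=labels)
        for pid, _, _, ab in rows:
            for k, v in ab.items():
                mat.loc[pid, k] = v
        mat = mat.div(mat.sum(axis=1), axis=0)
        meta = pd.DataFrame(
            {"survey": [r[2] for r in rows], "area_id": [r[1] for r in rows]},
            index=wide_index,
        )
        pairs = pairwise_beta_table(mat, meta, dm)
        merged = pairs.merge(meta, left_on="plot_1", right_index=True)
        assert (merged["area_pair"].str.split("|").str[0] != merged["area_pair"].str.split("|").str[1]).all()
        # both surveys generated identically: effect should be small
        eff = band_beta_contrast(pairs, metric="beta_test")
        assert eff is not None
        assert abs(eff.estimate) < 4 * eff.se

    def test_too_few_pairs_skipped(self):
        pairs = pd.DataFrame(
            {"survey": [HISTORICAL], "area_pair": ["a|b"], "beta_additive": [0.5]}
        )
        assert band_beta_contrast(pairs) is None


class TestBandGamma:
    def test_single_area_band(self, rng):
        recs = [
            _plot("h1", "a1", HISTORICAL, {"x": 1.0, "y": 1.0}),
            _plot("r1", "a1", RESURVEY, {"x": 1.0, "z": 1.0, "w": 1.0}),
        ]
        assert band_gamma_contrast(recs, rng) == (2, 3)

    def test_seed_determinism_and_subsetting(self):
        recs = []
        for a in range(8):
            recs.append(_plot(f"h{a}", f"a{a}", HISTORICAL, {f"s{a}": 1.0}))
            for j in range(3):
                recs.append(
                    _plot(f"r{a}{j}", f"a{a}", RESURVEY, {f"s{a}": 1.0, f"t{a}{j}": 1.0})
                )
        g1 = band_gamma_contrast(recs, np.random.default_rng(5), n_target=6)
        g2 = band_gamma_contrast(recs, np.random.default_rng(5), n_target=6)
        assert g1 == g2
        assert g1[0] == 6  # one distinct species per selected area

    def test_missing_survey_area_skipped(self, rng):
        recs = [
            _plot("h1", "a1", HISTORICAL, {"x": 1.0}),
            _plot("r1", "a1", RESURVEY, {"y": 1.0}),
            _plot("h2", "a2", HISTORICAL, {"z": 1.0}),  # no resurvey twin
        ]
        with pytest.warns(UserWarning, match="a2"):
            g = band_gamma_contrast(recs, rng)
        assert g == (1, 1)


class TestPseudoTurnover:
    def test_identical_plots_zero(self):
        ab = {"x": 50.0, "y": 50.0}
        recs = [
            _plot("h1", "a1", HISTORICAL, dict(ab)),
            _plot("r1", "a1", RESURVEY, dict(ab)),
            _plot("r2", "a1", RESURVEY, dict(ab)),
            _plot("h2", "a2", HISTORICAL, dict(ab)),
            _plot("r3", "a2", RESURVEY, dict(ab)),
            _plot("r4", "a2", RESURVEY, dict(ab)),
        ]
        per_area, eff = pseudo_turnover_check(recs)
        assert per_area["difference"].to_numpy() == pytest.approx([0.0, 0.0])
        assert eff.estimate == pytest.approx(0.0, abs=1e-10)

    def test_disjoint_historical_max_difference(self):
        recs = [
            _plot("h1", "a1", HISTORICAL, {"old": 100.0}),
            _plot("r1", "a1", RESURVEY, {"new": 100.0}),
            _plot("r2", "a1", RESURVEY, {"new": 100.0}),
        ]
        per_area, _ = pseudo_turnover_check(recs)
        assert per_area["difference"].iloc[0] == pytest.approx(1.0)

    def test_ineligible_areas_skipped(self):
        recs = [
            _plot("h1", "a1", HISTORICAL, {"x": 1.0}),
            _plot("r1", "a1", RESURVEY, {"x": 1.0}),  # only one resurvey plot
        ]
        with pytest.raises(InferenceError):
            pseudo_turnover_check(recs)

    def test_per_area_values_match_direct_bray_curtis(self, small_records):
        per_area, _ = pseudo_turnover_check(small_records)
        by_area = {}
        for r in small_records:
            by_area.setdefault(r.area_id, {}).setdefault(r.survey, []).append(r)
        for _, row in per_area.iterrows():
            hist = by_area[row["area_id"]][HISTORICAL]
            res = by_area[row["area_id"]][RESURVEY]
            between = np.mean(
                [bray_curtis(h.abundances, x.abundances) for h in hist for x in res]
            )
            within = np.mean(
                [
                    bray_curtis(res[i].abundances, res[j].abundances)
                    for i in range(len(res))
                    for j in range(i + 1, len(res))
                ]
            )
            assert row["difference"] == pytest.approx(between - within, abs=1e-12)


def test_expected_warming_indicator_shift_value():
    # 2 °C warming over a 0.65 °C/100 m lapse rate and a −0.098/100 m
    # spatial indicator gradient -> ≈ +0.30 expected CWM increase
    assert expected_warming_indicator_shift() == pytest.approx(0.3015, abs=1e-4)
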