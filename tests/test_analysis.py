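"""Statistics and the experiment drivers on the coarse model suite."""

import numpy as np
import pandas as pd
import pytest

from spiculo.analysis import (
    NON_VOLUME_FEATURES,
    extract_suite_features,
    feature_correlation_matrix,
    flag_m4_outliers,
    percent_change,
    run_correlation_experiment,
    run_reference_comparison,
    run_volume_sensitivity,
    spearman,
    spearman_with_ci,
)

SMALL_SPACING = (1.0, 1.0, 2.0)

#: expected sign of the rank correlation of each feature with d
#: (d ascending = decreasing spiculatedness)
EXPECTED_SIGNS = {
    "surface_area": -1,
    "surface_to_volume": -1,
    "spherical_disproportion": -1,
    "compactness1": +1,
    "compactness2": +1,
    "compactness3": +1,
    "sphericity": +1,
    "fractional_concavity": +1,
}


@pytest.fixture(scope="module")
def small_table(small_suite, small_masks):
    return extract_suite_features(
        small_suite, SMALL_SPACING, ("M1", "M3"), masks=list(small_masks)
    )


def rank_oracle(values):
    """Average ranks by explicit tie grouping (independent of scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3], [1, 4, 9])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [9, 4, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_rank_and_pearson_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 3.0, 4.0]
        rho, _ = spearman(x, y)
        rx, ry = rank_oracle(x), rank_oracle(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_ci_brackets_rho(self):
        rho, lo, hi, p = spearman_with_ci(np.arange(20), np.arange(20) ** 2 + 0.1)
        assert lo <= rho <= hi
        assert p < 1e-4


class TestPercentChange:
    @pytest.mark.parametrize(
        "value,ref,want", [(110, 100, 10.0), (42.0, 42.0, 0.0), (25, 100, 75.0)]
    )
    def test_values(self, value, ref, want):
        assert percent_change(value, ref) == pytest.approx(want)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)


class TestCorrelationExperiment:
    def test_sign_pattern_matches_monotone_expectations(self, small_suite, small_table):
        corr = run_correlation_experiment(
            small_suite, methods=("M1", "M3"), features_table=small_table
        )
        for _, row in corr.iterrows():
            assert np.sign(row["rho"]) == EXPECTED_SIGNS[row["feature"]], row["feature"]
            assert -1 <= row["ci_low"] <= row["rho"] <= row["ci_high"] <= 1

    def test_constant_complexity_raises(self, small_suite, small_table):
        degenerate = small_table.copy()
        degenerate["d"] = 47.0
        with pytest.raises(ValueError):
            run_correlation_experiment(
                small_suite, methods=("M1", "M3"), features_table=degenerate
            )


class TestReferenceComparison:
    def test_identical_arms_give_zero_change(self, small_suite, small_table):
        table = run_reference_comparison(
            small_suite, pipeline_table=small_table, methods=("M1", "M3")
        )
        # self-comparison sanity: compare the pipeline against itself
        self_ref = small_table.copy()
        from spiculo.analysis import _percent_change_table

        zero = _percent_change_table(small_table, small_table, "self")
        assert np.allclose(zero["mean"], 0.0)
        assert (table["mean"] >= 0).all()

    def test_fine_rasterization_converges_to_stl_volume(self, small_suite):
        # at the mid-level isosurface rasterization is unbiased and the M1
        # volume converges to the source surface volume as the grid refines
        tiny = extract_suite_features(
            small_suite, (0.4, 0.4, 0.4), ("M1",), equalize=False, isovalue=0.5
        )
        table = run_reference_comparison(
            small_suite, pipeline_table=tiny, methods=("M1",)
        )
        vol = table[(table.feature == "volume") & (table.method == "M1")]
        assert float(vol["mean"].iloc[0]) < 1.0


class TestVolumeSensitivity:
    def test_dimensionless_features_have_zero_spread(self, small_suite, small_table):
        vs = run_volume_sensitivity(
            small_suite,
            d_select=(11.0, 92.0),
            spacing=SMALL_SPACING,
            method="M3",
            features_table=small_table,
        )
        vs = vs.set_index("feature")
        for name in (
            "compactness2",
            "compactness3",
            "spherical_disproportion",
            "sphericity",
            "fractional_concavity",
        ):
            assert vs.loc[name, "volume_spread"] < 1e-9
            assert vs.loc[name, "volume_robust"]
        assert not vs.loc["surface_to_volume", "volume_robust"]


class TestFeatureCorrelationMatrix:
    def test_algebraic_pairs_are_perfectly_ranked(self, small_table):
        mat = feature_correlation_matrix(small_table, "M1")
        assert mat.loc["compactness2", "sphericity"] == pytest.approx(1.0)
        assert mat.loc["spherical_disproportion", "sphericity"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_too_few_models_raise(self, small_table):
        with pytest.raises(ValueError):
            feature_correlation_matrix(small_table.iloc[:2], "M1")


class TestM4OutlierFlagging:
    def test_no_m4_rows_gives_empty_frame(self, small_table):
        flags = flag_m4_outliers(small_table)
        assert flags.empty

    def test_flags_injected_outlier(self, small_table):
        m4 = small_table[small_table.method == "M1"].copy()
        m4["method"] = "M4"
        m4["sphericity"] *= 10.0
        flags = flag_m4_outliers(pd.concat([small_table, m4], ignore_index=True))
        assert (flags["feature"] == "sphericity").any()
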