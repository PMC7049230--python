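"""Spot-level normalization chain: net signal through KNN imputation."""

import numpy as np
import pandas as pd
import pytest

from seroscreen import array_preprocess as ap
from seroscreen import synthetic


def spot_frame(rows):
    """rows: (sample, slide, sub, target, role, rep, fg, bg)"""
    return pd.DataFrame(
        [
            dict(
                sample_id=s,
                slide=sl,
                subarray=su,
                block=1,
                row=i + 1,
                column=1,
                target=t,
                role=role,
                replicate=rep,
                foreground=fg,
                background=bg,
                flag="ok",
            )
            for i, (s, sl, su, t, role, rep, fg, bg) in enumerate(rows)
        ]
    )


class TestNetSignal:
    def test_subtraction_missing_and_boundary(self):
        spots = spot_frame(
            [
                ("S1", 1, 1, "A", "antigen", 1, 1000, 300),
                ("S1", 1, 1, "A", "antigen", 2, 200, 300),
                ("S1", 1, 1, "A", "antigen", 3, 300, 300),
            ]
        )
        net = ap.net_signal(spots)["net"]
        assert net.iloc[0] == 700
        assert np.isnan(net.iloc[1])  # strictly negative -> missing
        assert net.iloc[2] == 0  # zero is kept


class TestSubtractNegativeControl:
    def base(self, antigen_fg):
        return spot_frame(
            [
                ("S1", 1, 1, "A", "antigen", 1, antigen_fg, 0),
                ("S1", 1, 1, "PBS", "negative_control", 1, 40, 0),
                ("S1", 1, 1, "PBS", "negative_control", 2, 60, 0),
            ]
        )

    def test_mean_control_subtracted(self):
        out = ap.subtract_negative_control(ap.net_signal(self.base(700)))
        assert out.loc[out["role"] == "antigen", "net"].iloc[0] == 650

    def test_below_control_becomes_missing(self):
        out = ap.subtract_negative_control(ap.net_signal(self.base(30)))
        assert np.isnan(out.loc[out["role"] == "antigen", "net"].iloc[0])

    def test_zero_control_mean_is_identity(self):
        spots = spot_frame(
            [
                ("S1", 1, 1, "A", "antigen", 1, 700, 0),
                ("S1", 1, 1, "PBS", "negative_control", 1, 0, 0),
            ]
        )
        out = ap.subtract_negative_control(ap.net_signal(spots))
        assert out.loc[out["role"] == "antigen", "net"].iloc[0] == 700

    def test_missing_controls_raise_naming_the_subarray(self):
        spots = spot_frame([("S1", 1, 2, "A", "antigen", 1, 700, 0)])
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            ap.subtract_negative_control(ap.net_signal(spots))

    def test_requires_net_signal_first(self):
        with pytest.raises(ValueError, match="net_signal"):
            ap.subtract_negative_control(self.base(700))


class TestAverageReplicates:
    def test_missing_aware_mean(self):
        spots = spot_frame(
            [
                ("S1", 1, 1, "A", "antigen", 1, 600, 0),
                ("S1", 1, 1, "A", "antigen", 2, 100, 200),  # negative -> missing
                ("S1", 1, 1, "A", "antigen", 3, 700, 0),
                ("S1", 1, 1, "B", "antigen", 1, 100, 300),
                ("S1", 1, 1, "B", "antigen", 2, 100, 300),
            ]
        )
        avg = ap.average_replicates(ap.net_signal(spots))
        a = avg.set_index("target")["intensity"]
        assert a["A"] == 650  # mean of observed replicates only
        assert np.isnan(a["B"])  # all replicates missing -> missing


class TestIggMedianCentring:
    def averaged(self, igg_by_sample, antigen=500.0):
        rows = []
        for s, igg in igg_by_sample.items():
            rows.append((s, 1, int(s[1:]), "T", "antigen", antigen))
            rows.append((s, 1, int(s[1:]), "IGG", "igg_control", igg))
        return pd.DataFrame(
            rows,
            columns=["sample_id", "slide", "subarray", "target", "role", "intensity"],
        )

    def test_equal_igg_medians_give_identity(self):
        nfi = ap.igg_median_centring(self.averaged({"S1": 100.0, "S2": 100.0}))
        assert (nfi.factors == 1.0).all()
        assert (nfi.values["T"] == 500.0).all()

    def test_double_igg_median_halves_intensities(self):
        nfi = ap.igg_median_centring(
            self.averaged({"S1": 100.0, "S2": 100.0, "S3": 200.0})
        )
        assert nfi.factors["S3"] == 2.0
        assert nfi.values.loc["S3", "T"] == 250.0
        assert nfi.values.loc["S1", "T"] == 500.0

    def test_postcondition_all_igg_medians_equal(self):
        rng = np.random.default_rng(6)
        igg = {f"S{i}": float(rng.uniform(50, 400)) for i in range(1, 21)}
        nfi = ap.igg_median_centring(self.averaged(igg))
        centred = pd.Series(igg) / nfi.factors
        global_median = np.median(list(igg.values()))
        assert np.allclose(centred, global_median)

    def test_nonpositive_igg_median_raises(self):
        with pytest.raises(ValueError, match="nonpositive IgG"):
            ap.igg_median_centring(self.averaged({"S1": 0.0, "S2": 100.0}))

    def test_sample_without_igg_raises(self):
        avg = self.averaged({"S1": 100.0})
        avg = pd.concat(
            [
                avg,
                pd.DataFrame(
                    [("S9", 1, 9, "T", "antigen", 1.0)], columns=avg.columns
                ),
            ]
        )
        with pytest.raises(ValueError, match="S9"):
            ap.igg_median_centring(avg)


class TestWinsorizeToMissing:
    def test_hundred_distinct_values_lose_ten(self):
        m = pd.DataFrame({"T": np.arange(100, dtype=float)})
        out = ap.winsorize_to_missing(m)
        assert out["T"].isna().sum() == 10

    def test_constant_target_untouched(self):
        m = pd.DataFrame({"T": np.ones(50)})
        out = ap.winsorize_to_missing(m)
        assert out["T"].notna().all()

    def test_agrees_with_sort_and_cut_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"T": rng.lognormal(7, 1, size=173)})
        out = ap.winsorize_to_missing(m)
        lo = np.quantile(m["T"], 0.05)
        hi = np.quantile(m["T"], 0.95)
        expected_missing = (m["T"] < lo) | (m["T"] > hi)
        assert (out["T"].isna() == expected_missing).all()


class TestMissingnessFilter:
    def column(self, n_missing, n=240):
        vals = np.ones(n)
        vals[:n_missing] = np.nan
        return vals

    def test_strictly_above_quarter_is_dropped(self):
        m = pd.DataFrame({"drop": self.column(61), "keep": self.column(60)})
        out = ap.missingness_filter(m)
        assert list(out.columns) == ["keep"]  # 60/240 = 25.0% is kept

    def test_no_missing_is_identity(self):
        m = pd.DataFrame({"A": np.ones(10), "B": np.zeros(10)})
        pd.testing.assert_frame_equal(ap.missingness_filter(m), m)


class TestKnnImpute:
    def test_duplicate_column_exact_recovery_with_k1(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(100, 900, size=30)
        m = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.uniform(0, 1, 30)})
        m.loc[4, "A"] = np.nan
        out = ap.knn_impute(m, k=1)
        assert out.loc[4, "A"] == pytest.approx(a[4])

    def test_two_column_closed_form_rescaled_by_means(self):
        # B = 2A exactly: the partner's value rescaled by the ratio of
        # co-observed column means recovers the masked cell perfectly
        a = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        m = pd.DataFrame({"A": a, "B": 2.0 * a})
        m.loc[2, "A"] = np.nan
        out = ap.knn_impute(m, k=5)
        assert out.loc[2, "A"] == pytest.approx(a[2])

    def test_no_missing_is_identity_and_observed_untouched(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.uniform(1, 9, (20, 4)), columns=list("ABCD"))
        pd.testing.assert_frame_equal(ap.knn_impute(m), m)
        holes = m.copy()
        holes.iloc[3, 1] = np.nan
        out = ap.knn_impute(holes)
        observed = ~holes.isna()
        assert out.where(observed).equals(holes.where(observed))

    def test_isolated_column_raises(self):
        m = pd.DataFrame({"A": [1.0, np.nan], "B": [np.nan, 2.0]})
        with pytest.raises(ValueError, match="neighbour"):
            ap.knn_impute(m, k=1)


class TestPipeline:
    def test_scale_invariance_to_subarray_factor(self, array_dataset):
        """Multiplying every spot of one subarray (including its IgG
        spots) by c > 0 leaves that subarray's NFIs unchanged."""
        spots, _, _ = array_dataset
        base = ap.preprocess_pipeline(spots, lower_pct=0, upper_pct=100)
        # scale up the subarray with the largest IgG median so the global
        # IgG median (an order statistic) is provably unaffected
        sample = base.factors.idxmax()
        scaled = spots.copy()
        scaled[["foreground", "background"]] = scaled[
            ["foreground", "background"]
        ].astype(float)
        mask = scaled["sample_id"] == sample
        scaled.loc[mask, ["foreground", "background"]] *= 3.7
        out = ap.preprocess_pipeline(scaled, lower_pct=0, upper_pct=100)
        pd.testing.assert_series_equal(
            out.values.loc[sample], base.values.loc[sample], rtol=1e-9
        )

    def test_no_batch_effect_gives_unit_factors(self):
        cfg = synthetic.ArraySimConfig(
            n_slides=2,
            cohort_sizes=(16, 16),
            subarray_scale_sd=0.0,
            spot_noise_log2=0.01,
            seed=4,
        )
        spots, _, _ = synthetic.generate_array_dataset(cfg)
        nfi = ap.preprocess_pipeline(spots, lower_pct=0, upper_pct=100)
        assert np.allclose(nfi.factors, 1.0, atol=0.05)

    def test_stage_audit_matches_recount(self, array_dataset):
        spots, _, _ = array_dataset
        nfi = ap.preprocess_pipeline(spots)
        audit = dict(nfi.audit)
        assert audit["input_spots"] == len(spots)
        net = ap.net_signal(ap.drop_flagged(spots))
        assert audit["nonmissing_net"] == int(net["net"].notna().sum())
        assert audit["targets_retained"] == nfi.values.shape[1]
        assert audit["imputed_cells"] == nfi.values.size

    def test_mask_and_recover_imputation_error_below_column_spread(
        self, array_dataset
    ):
        """Hide 5% of observed NFI cells; KNN refills them with a median
        absolute error below the per-target spread (the shared serum
        reactivity makes targets informative about each other)."""
        spots, _, _ = array_dataset
        nfi = ap.preprocess_pipeline(spots, lower_pct=0, upper_pct=100)
        full = nfi.values
        rng = np.random.default_rng(13)
        mask = rng.random(full.shape) < 0.05
        holes = full.mask(mask)
        recovered = ap.knn_impute(holes, k=5)
        errs = np.abs(np.log2(recovered) - np.log2(full)).to_numpy()[mask]
        spread = np.log2(full).std(axis=0).mean()
        assert np.median(errs) < spread
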