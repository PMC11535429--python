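import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psicoupling import (
    SimScenario,
    apply_variability_filters,
    bh_adjust,
    classify_events,
    compute_psi,
    cross_tissue_consistency,
    donor_level_reclassification,
    marker_correlation,
    simulate_dataset,
    slope_vs_mean_expression,
    split_by_poisson_mixture,
)
from psicoupling.quantification import PsiExpressionTable


def bh_oracle(p):
    """Brute-force step-up: sort, cumulative minimum of n*p/rank."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def make_table(psi_rows, y_rows, samples=None, gene_ids=None):
    """Single-tissue table from explicit psi and Y vectors per event."""
    psi_rows = np.atleast_2d(np.asarray(psi_rows, dtype=float))
    y_rows = np.atleast_2d(np.asarray(y_rows, dtype=float))
    n_events, n = psi_rows.shape
    samples = samples or [f"s{i}" for i in range(n)]
    event_ids = [f"g{i}:EV001" for i in range(n_events)]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_events)]
    inc = psi_rows * y_rows
    exc = (1 - psi_rows) * y_rows
    table = PsiExpressionTable(
        psi=pd.DataFrame(psi_rows, index=event_ids, columns=samples),
        inc=pd.DataFrame(inc, index=event_ids, columns=samples),
        exc=pd.DataFrame(exc, index=event_ids, columns=samples),
        gene_expression=pd.DataFrame(
            y_rows, index=gene_ids, columns=samples
        ),
        event_gene=pd.Series(gene_ids, index=event_ids, name="gene_id"),
    )
    meta = pd.DataFrame({"sample_id": samples, "tissue": ["liver"] * n})
    filters = pd.DataFrame(
        {
            "event_id": event_ids,
            "tissue": ["liver"] * n_events,
            "expressed_fraction": 1.0,
            "mean_level": 100.0,
            "ratio_95_5": 10.0,
            "passed": True,
        }
    )
    return table, filters, meta


class TestBhAdjust:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_oracle_property(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_empty_input(self):
        assert bh_adjust(np.array([])).size == 0


class TestClassifyEvents:
    def test_three_point_closed_form_fit(self):
        table, filters, meta = make_table(
            [[0.0, 0.5, 1.0]], [[10.0, 20.0, 30.0]]
        )
        cls = classify_events(table, filters, meta)
        row = cls.iloc[0]
        assert row["beta1"] == pytest.approx(20.0)
        assert row["beta0"] == pytest.approx(10.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_noise_free_uhp(self):
        psi = np.linspace(0, 1, 30)
        table, filters, meta = make_table([psi], [10 + 50 * psi])
        cls = classify_events(table, filters, meta)
        row = cls.iloc[0]
        assert row["label"] == "UHP"
        assert row["beta1"] == pytest.approx(50.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_noise_free_dhp(self):
        psi = np.linspace(0, 1, 30)
        table, filters, meta = make_table([psi], [100 - 50 * psi])
        cls = classify_events(table, filters, meta)
        assert cls.iloc[0]["label"] == "DHP"

    def test_failed_filters_unclassified(self):
        table, filters, meta = make_table(
            [[0.0, 0.5, 1.0]], [[10.0, 20.0, 30.0]]
        )
        filters["passed"] = False
        cls = classify_events(table, filters, meta)
        assert cls.iloc[0]["label"] == "UNCLASSIFIED"
        assert cls.iloc[0]["reason"] == "failed_filters"

    def test_too_few_samples_and_constant_psi(self):
        psi = np.array([[0.2, 0.8, np.nan, np.nan], [0.5, 0.5, 0.5, 0.5]])
        y = np.array([[10.0, 20, 30, 40], [10.0, 20, 30, 40]])
        table, filters, meta = make_table(psi, y)
        cls = classify_events(table, filters, meta)
        assert list(cls["reason"]) == ["too_few_samples", "constant_psi"]
        assert set(cls["label"]) == {"UNCLASSIFIED"}

    def test_missing_psi_dropped_pairwise(self):
        psi = np.array([[0.0, 0.5, 1.0, np.nan]])
        y = np.array([[10.0, 20.0, 30.0, 999.0]])
        table, filters, meta = make_table(psi, y)
        cls = classify_events(table, filters, meta)
        assert cls.iloc[0]["beta1"] == pytest.approx(20.0)
        assert cls.iloc[0]["n_samples"] == 3

    def test_null_fraction_controlled(self, rng):
        """Pure null (b1 = 0): few raw rejections, no coupled labels."""
        n_events, n = 200, 300
        psi = rng.beta(0.5, 0.5, size=(n_events, n))
        y = 60 + rng.normal(0, 20, size=(n_events, n))
        table, filters, meta = make_table(
            psi, y, gene_ids=[f"g{i}" for i in range(n_events)]
        )
        filters = pd.concat([filters], ignore_index=True)
        cls = classify_events(table, filters, meta)
        coupled = cls["label"].isin(["UHP", "DHP"]).mean()
        assert coupled <= 0.05
        raw_rej = (cls["p_raw"] <= 0.05).mean()
        assert raw_rej <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_events)

    def test_scaling_y_scales_slopes_only(self):
        psi = np.linspace(0.05, 0.95, 40)
        rng = np.random.default_rng(0)
        y = 30 + 40 * psi + rng.normal(0, 5, 40)
        t1, f1, meta = make_table([psi], [y])
        t2, f2, _ = make_table([psi], [y * 3.0])
        c1 = classify_events(t1, f1, meta)
        c2 = classify_events(t2, f2, meta)
        assert c2.iloc[0]["beta1"] == pytest.approx(3 * c1.iloc[0]["beta1"])
        assert c2.iloc[0]["p_raw"] == pytest.approx(c1.iloc[0]["p_raw"])
        assert c2.iloc[0]["r2"] == pytest.approx(c1.iloc[0]["r2"])
        assert c2.iloc[0]["label"] == c1.iloc[0]["label"]


class TestConsistency:
    def _cls(self, rows):
        return pd.DataFrame(rows, columns=["event_id", "tissue", "label"])

    def test_consistent_event_not_flagged(self):
        cls = self._cls(
            [["e1", "a", "UHP"], ["e1", "b", "UHP"], ["e1", "c", "UHP"]]
        )
        report = cross_tissue_consistency(cls)
        assert report.iloc[0]["tissues_as_UHP"] == 3
        assert not report.iloc[0]["conflict"]

    def test_conflicting_event_flagged(self):
        cls = self._cls([["e1", "a", "UHP"], ["e1", "b", "DHP"]])
        assert cross_tissue_consistency(cls).iloc[0]["conflict"]

    def test_planted_data_has_no_conflicts(self, small_pipeline):
        _, _, cls = small_pipeline
        report = cross_tissue_consistency(cls)
        assert not report["conflict"].any()


class TestDonorLevel:
    def test_strong_effects_agree_with_tissue_labels(self, small_sim, small_pipeline):
        table, _, cls = small_pipeline
        donor = donor_level_reclassification(
            table, small_sim.metadata, cls, min_samples_per_donor=20
        )
        assert donor.n_compared > 0
        assert donor.agreement_fraction >= 0.95

    def test_all_donors_below_threshold(self, small_sim, small_pipeline):
        table, _, cls = small_pipeline
        with pytest.warns(UserWarning, match="no donor"):
            donor = donor_level_reclassification(
                table, small_sim.metadata, cls, min_samples_per_donor=10_000
            )
        assert donor.report.empty
        assert donor.n_compared == 0

    def test_single_donor_reproduces_tissue_labels(self):
        psi = np.linspace(0, 1, 40)
        rng = np.random.default_rng(1)
        rows_psi = [psi, rng.permutation(psi)]
        rows_y = [20 + 60 * rows_psi[0], 150 - 140 * rows_psi[1]]
        table, filters, meta = make_table(rows_psi, rows_y)
        meta["donor"] = "d0"
        cls = classify_events(table, filters, meta)
        donor = donor_level_reclassification(
            table, meta, cls, min_samples_per_donor=20
        )
        assert donor.agreement_fraction == pytest.approx(1.0)


class TestSlopeVsMeanExpression:
    def _cls_and_table(self, slopes, means):
        rows = [
            {"event_id": f"g{i}:EV001", "tissue": "liver", "label": "UHP",
             "beta1": s}
            for i, s in enumerate(slopes)
        ]
        cls = pd.DataFrame(rows)
        n_events = len(slopes)
        psi = np.tile(np.linspace(0.1, 0.9, 5), (n_events, 1))
        y = np.tile(np.asarray(means, dtype=float)[:, None], (1, 5))
        table, _, _ = make_table(psi, y)
        return cls, table

    def test_two_point_line_has_unit_coefficient(self):
        cls, table = self._cls_and_table([10.0, 20.0], [10.0, 20.0])
        res = slope_vs_mean_expression(cls, table)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_means_raise(self):
        cls, table = self._cls_and_table([10.0, 10.0], [10.0, 10.0])
        with pytest.raises(ValueError, match="degenerate"):
            slope_vs_mean_expression(cls, table)

    def test_single_event_raises(self):
        cls, table = self._cls_and_table([10.0, 20.0], [10.0, 20.0])
        with pytest.raises(ValueError, match="at least 2"):
            slope_vs_mean_expression(cls[:1], table)


class TestMarkerCorrelation:
    def test_own_gene_noise_free_uhp_is_perfect(self):
        psi = np.linspace(0.1, 0.9, 20)
        table, filters, meta = make_table([psi], [10 + 50 * psi])
        cls = classify_events(table, filters, meta)
        out = marker_correlation(table, cls, marker_gene="g0")
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_marker_near_zero(self, rng):
        n_events, n = 50, 300
        psi = rng.beta(2, 2, size=(n_events, n))
        y = 50 + rng.normal(0, 10, size=(n_events, n))
        table, filters, meta = make_table(psi, y)
        cls = classify_events(table, filters, meta)
        out = marker_correlation(table, cls, marker_gene="g0")
        others = out.iloc[1:]["r"].to_numpy()
        assert abs(np.nanmean(others)) <= 3 / np.sqrt(n * (n_events - 1))

    def test_constant_marker_is_missing(self):
        psi = np.linspace(0.1, 0.9, 10)
        table, filters, meta = make_table(
            [psi, psi], [10 + 50 * psi, np.full(10, 42.0)]
        )
        cls = classify_events(table, filters, meta)
        out = marker_correlation(table, cls, marker_gene="g1")
        assert np.isnan(out.set_index("event_id").loc["g0:EV001", "r"])

    def test_unknown_marker_raises(self):
        psi = np.linspace(0.1, 0.9, 10)
        table, filters, meta = make_table([psi], [10 + 50 * psi])
        cls = classify_events(table, filters, meta)
        with pytest.raises(KeyError):
            marker_correlation(table, cls, marker_gene="nope")


class TestPoissonMixtureSplit:
    def test_recovers_well_separated_means(self, rng):
        counts = np.concatenate(
            [rng.poisson(5, 250), rng.poisson(50, 250)]
        )
        fit = split_by_poisson_mixture(counts)
        lo, hi = fit.means
        assert abs(lo - 5) / 5 <= 0.10
        assert abs(hi - 50) / 50 <= 0.10
        assert 5 < fit.threshold < 50

    def test_two_point_data_separated(self):
        fit = split_by_poisson_mixture(np.array([1, 1, 1, 100, 100]))
        assert 1 < fit.threshold <= 100
        assert list(fit.assignments) == [False, False, False, True, True]

    def test_all_equal_is_degenerate(self):
        with pytest.warns(UserWarning, match="merged"):
            fit = split_by_poisson_mixture(np.array([7, 7, 7, 7]))
        assert fit.degenerate
        assert fit.threshold == 8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_by_poisson_mixture(np.array([3]))
        with pytest.raises(ValueError):
            split_by_poisson_mixture(np.array([1.5, 2.5]))
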