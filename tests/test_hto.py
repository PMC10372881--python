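"""Unit tests for CLR normalization, k-medoids, Grubbs thresholds, demux."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sstats

from conftest import make_clr, single_cluster
from tilseq import hto
from tilseq._util import InputError


def _matrix(counts, array_id="a1"):
    counts = np.asarray(counts)
    return hto.HtoCountMatrix(
        counts, [f"c{i}" for i in range(counts.shape[0])],
        [f"HTO{j+1}" for j in range(counts.shape[1])], array_id=array_id)


class TestClr:
    def test_equal_counts_give_zero(self):
        clr = hto.clr_normalize(_matrix([[7, 7, 7]]))
        assert np.allclose(clr.values, 0)

    def test_two_hto_hand_arithmetic(self):
        # counts (0, 9), pseudocount 1: ln(1/sqrt(10)), ln(10/sqrt(10))
        clr = hto.clr_normalize(_matrix([[0, 9]]))
        assert clr.values[0] == pytest.approx([-1.1512925465, 1.1512925465])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(arrays(np.int64, st.tuples(st.integers(1, 20), st.integers(2, 6)),
                  elements=st.integers(0, 10_000)))
    def test_rows_sum_to_zero(self, counts):
        clr = hto.clr_normalize(_matrix(counts))
        assert np.all(np.abs(clr.values.sum(axis=1)) < 1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(InputError):
            hto.clr_normalize(_matrix([[1, 2]]), pseudocount=0)
        with pytest.raises(InputError):
            _matrix([[1, -2]])


class TestKmedoids:
    def test_k_equals_n_gives_zero_cost(self):
        clr = make_clr([0.0, 1.0, 5.0])
        res = hto.kmedoids_cluster(clr, k=3)
        assert res.cost == 0
        assert sorted(res.medoids) == [0, 1, 2]

    def test_two_blobs_match_exhaustive_medoid_pair_oracle(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-5, 0.5, 20), rng.normal(5, 0.5, 20)])
        clr = make_clr(x)
        res = hto.kmedoids_cluster(clr, k=2)
        # partition matches the blobs
        assert len(set(res.labels[:20])) == 1
        assert len(set(res.labels[20:])) == 1
        assert res.labels[0] != res.labels[20]
        # cost equals the brute-force optimum over all medoid pairs
        d = np.abs(x[:, None] - x[None, :]) * np.sqrt(2)
        best = min(np.minimum(d[:, i], d[:, j]).sum()
                   for i, j in itertools.combinations(range(40), 2))
        assert res.cost == pytest.approx(best)

    def test_k_defaults_to_number_of_htos(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(30, 5))
        res = hto.kmedoids_cluster(hto.clr_normalize(_matrix(counts)))
        assert len(res.medoids) == 5

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InputError):
            hto.kmedoids_cluster(make_clr([0.0, 1.0]), k=3)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        clr = make_clr(rng.normal(size=50))
        a = hto.kmedoids_cluster(clr, k=4)
        b = hto.kmedoids_cluster(clr, k=4)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoids, b.medoids)


class TestGrubbs:
    def test_constant_sample_is_never_an_outlier(self):
        assert not hto.grubbs_min_test([2.0] * 5).is_outlier

    def test_critical_value_n10(self):
        # published one-sided table value for N=10, alpha=0.05 is 2.176
        res = hto.grubbs_min_test(list(range(10)))
        assert res.critical == pytest.approx(2.17607, abs=1e-4)

    def test_low_value_flagged(self):
        vals = [1.0, 9.85, 9.9, 9.95, 10.0, 10.0, 10.05, 10.1, 10.15, 10.2]
        res = hto.grubbs_min_test(vals)
        assert res.is_outlier
        assert res.statistic == pytest.approx(2.844, abs=1e-3)

    @pytest.mark.parametrize("n", range(3, 51))
    def test_closed_form_matches_independent_t_quantile(self, n):
        alpha = 0.05
        t = sstats.t.isf(alpha / n, n - 2)
        expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        res = hto.grubbs_min_test(np.linspace(0, 1, n))
        assert res.critical == pytest.approx(expected, abs=1e-6)

    def test_too_few_values(self):
        res = hto.grubbs_min_test([1.0, 2.0])
        assert not res.is_outlier and "too few" in res.note


class TestEstablishThresholds:
    def _thresholds(self, values):
        clr = make_clr(values)
        return hto.establish_thresholds(clr, single_cluster(len(values)))

    def test_tight_cluster_keeps_minimum(self):
        ts = self._thresholds([2.0, 2.1, 2.05, 1.95, 2.02])
        assert ts.thresholds["HTO1"] == pytest.approx(1.95)
        assert ts.removed["HTO1"] == []

    def test_single_low_outlier_removed(self):
        ts = self._thresholds([-3.0, 2.0, 2.1, 2.05, 1.95, 2.02, 2.08, 1.98])
        assert ts.removed["HTO1"] == [-3.0]
        assert ts.thresholds["HTO1"] == pytest.approx(1.95)

    def test_two_stacked_outliers_mask_each_other(self):
        # two stacked lows inflate the SD enough that the minimum is not
        # Grubbs-significant (G = 1.94 < 2.18 at N=10): the loop stops
        # immediately and the raw minimum becomes the threshold
        vals = [-3.0, -2.8, 2.0, 2.1, 2.05, 1.95, 2.02, 2.08, 1.98, 2.03]
        ts = self._thresholds(vals)
        assert ts.removed["HTO1"] == []
        assert ts.thresholds["HTO1"] == pytest.approx(-3.0)

    def test_final_minimum_never_grubbs_significant(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(2, 0.1, 50), [-4.0, -3.0]])
        ts = self._thresholds(vals)
        survivors = np.sort(vals)[len(ts.removed["HTO1"]):]
        assert not hto.grubbs_min_test(survivors).is_outlier
        assert all(v < ts.thresholds["HTO1"] for v in ts.removed["HTO1"])

    def test_tiny_cluster_skips_grubbs(self):
        ts = self._thresholds([5.0, -9.0])
        assert ts.thresholds["HTO1"] == -9.0
        assert any("Grubbs skipped" in w for w in ts.warnings)


class TestClassify:
    def _result(self, values, thresholds):
        clr = make_clr(values)
        ts = hto.ThresholdSet(thresholds, {h: [] for h in thresholds})
        return hto.classify_cells(clr, ts)

    def test_singlet_doublet_negative(self):
        # cells at +2 (HTO1 high), -2 (HTO2 high), 0 (neither)
        res = self._result([2.0, -2.0, 0.0], {"HTO1": 1.0, "HTO2": 1.0})
        assert list(res.calls["call"]) == ["singlet", "singlet", "negative"]
        assert list(res.calls["label"]) == ["HTO1", "HTO2", ""]
        res2 = self._result([0.0], {"HTO1": -1.0, "HTO2": -1.0})
        assert res2.calls["call"].iloc[0] == "doublet"

    def test_threshold_cell_itself_is_positive(self):
        res = self._result([1.0], {"HTO1": 1.0, "HTO2": 5.0})
        assert res.positivity["HTO1"].iloc[0]

    def test_missing_threshold_rejected(self):
        with pytest.raises(InputError):
            self._result([0.0], {"HTO1": 1.0})

    def test_raising_a_threshold_never_creates_positives(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=60)
        base = self._result(values, {"HTO1": 0.3, "HTO2": 0.2})
        raised = self._result(values, {"HTO1": 1.1, "HTO2": 0.2})
        assert (raised.positivity.values <= base.positivity.values).all()
        allowed = {("singlet", "negative"), ("doublet", "singlet"),
                   ("doublet", "negative"), ("doublet", "doublet"),
                   ("singlet", "singlet"), ("negative", "negative")}
        for a, b in zip(base.calls["call"], raised.calls["call"]):
            assert (a, b) in allowed


class TestDemux:
    def test_noise_free_recovers_all_singlets(self):
        from tilseq import simulate
        cfg = simulate.HtoSimConfig(doublet_rate=0.0, negative_rate=0.0,
                                    background_mean=0.0, dispersion=1000.0,
                                    cells_per_sample=30, seed=2)
        m, truth = simulate.simulate_hto(cfg)
        res = hto.demux([m])[0]
        merged = truth.set_index("barcode").join(res.calls)
        assert (merged["call"] == "singlet").all()
        assert (merged["label"] == merged["true_label"]).all()

    def test_default_simulation_accuracy(self, default_demux):
        res, truth = default_demux
        merged = truth.set_index("barcode").join(res.calls)
        singlets = merged[~merged["true_label"].isin(["doublet", "negative"])]
        assert (singlets["label"] == singlets["true_label"]).mean() >= 0.95

    def test_arrays_thresholded_independently(self):
        from tilseq import simulate
        m1, _ = simulate.simulate_hto(simulate.HtoSimConfig(seed=10, cells_per_sample=50))
        m2raw, _ = simulate.simulate_hto(simulate.HtoSimConfig(seed=11, cells_per_sample=50))
        # second array at 4x depth: thresholds must differ, not pool
        m2 = hto.HtoCountMatrix(m2raw.counts * 4, m2raw.cell_barcodes,
                                m2raw.hto_names, array_id="deep")
        r1, r2 = hto.demux([m1, m2])
        assert r1.thresholds.thresholds != r2.thresholds.thresholds

    def test_manual_override_applied(self, default_hto_sim):
        matrix, _ = default_hto_sim
        res = hto.HtoDemultiplexer(matrix).fit(overrides={"HTO1": 99.0})
        assert res.thresholds.thresholds["HTO1"] == 99.0
        assert not res.positivity["HTO1"].any()

    def test_summary_lists_calls_and_thresholds(self, default_demux):
        res, _ = default_demux
        summary = res.summary()
        assert {"n_singlet", "n_doublet", "n_negative"} <= set(summary["quantity"])
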