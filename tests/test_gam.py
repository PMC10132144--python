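"""Spline association testing along pseudotime: calibration, power,
family equivalence, grid smoothing and trajectory clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from tonsilflow.gam import cluster_smoothed_curves, smooth_on_grid
from tonsilflow.gam import test_feature_association as feature_association
from tonsilflow.gam import test_gene_association as gene_association
from tonsilflow.gam import test_regulon_association as regulon_association


@pytest.fixture(scope="module")
def pseudotime_grid():
    rng = np.random.default_rng(111)
    return rng.uniform(0, 1, 500)


class TestGaussianAssociation:
    def test_affine_activity_reproduced_by_spline(self, pseudotime_grid):
        t = pseudotime_grid
        y = 0.2 + 0.5 * t
        df = pd.DataFrame([y], index=["aff"])
        res = regulon_association(df, t)
        curve = smooth_on_grid(res, g=50)
        pred = curve.values.loc["aff"].to_numpy()
        expect = 0.2 + 0.5 * curve.grid
        ss_res = ((pred - expect) ** 2).sum()
        ss_tot = ((expect - expect.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99

    def test_flat_regulon_not_significant(self, pseudotime_grid):
        rng = np.random.default_rng(112)
        t = pseudotime_grid
        df = pd.DataFrame(rng.normal(0.5, 0.05, (50, len(t))),
                          index=[f"r{i}" for i in range(50)])
        res = regulon_association(df, t, alpha_adj=1e-5)
        assert not res.table["significant"].any()

    def test_rising_activity_significant_and_monotone(self, pseudotime_grid):
        rng = np.random.default_rng(113)
        t = pseudotime_grid
        y = 1 / (1 + np.exp(-(t - 0.5) / 0.1)) + rng.normal(0, 0.05, len(t))
        res = regulon_association(pd.DataFrame([y], index=["ris"]), t)
        assert res.table["significant"].iloc[0]
        curve = smooth_on_grid(res, g=40).values.loc["ris"].to_numpy()
        assert curve[-1] > curve[0]

    def test_constant_row_gets_p_one(self, pseudotime_grid):
        df = pd.DataFrame([np.full(len(pseudotime_grid), 0.3)], index=["c"])
        res = regulon_association(df, pseudotime_grid)
        assert res.table["p"].iloc[0] == 1.0

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(114)
        t = rng.uniform(0, 1, 300)
        Y = pd.DataFrame(rng.normal(0, 1, (2000, 300)))
        res = feature_association(Y, t, "gaussian")
        assert kstest(res.table["p"], "uniform").statistic < 0.05


class TestNBAssociation:
    def test_constant_zero_gene_excluded_by_prefilter(self, pseudotime_grid):
        t = pseudotime_grid
        counts = pd.DataFrame([np.zeros(len(t), dtype=int)], index=["z"])
        res = gene_association(counts, t,
                                    library_sizes=np.full(len(t), 1000.0))
        assert res.table["excluded"].iloc[0]
        assert np.isnan(res.table["p"].iloc[0])

    def test_strong_trend_detected(self, pseudotime_grid):
        rng = np.random.default_rng(115)
        t = pseudotime_grid
        lib = np.full(len(t), 2000.0)
        mu = 0.002 * lib * np.exp(2.0 / (1 + np.exp(-(t - 0.5) / 0.1)))
        y = rng.poisson(rng.gamma(10, mu / 10))
        res = gene_association(pd.DataFrame([y], index=["g"]), t,
                                    library_sizes=lib)
        assert res.table["p"].iloc[0] < 1e-6

    def test_family_equivalence_on_gaussian_inputs(self, pseudotime_grid):
        # the gene- and regulon-level tests share one implementation:
        # identical Gaussian inputs give identical statistics
        rng = np.random.default_rng(116)
        t = pseudotime_grid
        Y = pd.DataFrame(rng.normal(0, 1, (10, len(t))),
                         index=[f"f{i}" for i in range(10)])
        a = feature_association(Y, t, "gaussian")
        b = regulon_association(Y, t)
        assert np.allclose(a.table["statistic"], b.table["statistic"])
        assert np.allclose(a.table["p"], b.table["p"])


class TestSmoothing:
    def test_grid_matches_direct_prediction(self, pseudotime_grid):
        rng = np.random.default_rng(117)
        t = pseudotime_grid
        y = np.sin(2 * t) + rng.normal(0, 0.1, len(t))
        res = regulon_association(pd.DataFrame([y], index=["s"]), t)
        curve = smooth_on_grid(res, g=30)
        direct = res.fits["s"].predict(curve.grid)
        assert np.allclose(curve.values.loc["s"].to_numpy(), direct,
                           atol=1e-12)

    def test_zscored_rows_standardized(self, pseudotime_grid):
        rng = np.random.default_rng(118)
        t = pseudotime_grid
        Y = pd.DataFrame(rng.normal(0, 1, (5, len(t))),
                         index=[f"f{i}" for i in range(5)])
        curve = smooth_on_grid(feature_association(Y, t, "gaussian"))
        z = curve.zscored.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(z.std(axis=1), 1, atol=1e-10)


def _template_curves(rng, g=100, per_family=10, noise=0.02):
    x = np.linspace(0, 1, g)
    fams = {
        "rising": 1 / (1 + np.exp(-(x - 0.5) / 0.08)),
        "falling": 1 / (1 + np.exp((x - 0.5) / 0.08)),
        "peak": np.exp(-((x - 0.5) / 0.12) ** 2),
        "dip": 1 - np.exp(-((x - 0.5) / 0.12) ** 2),
        "early": np.exp(-x / 0.15),
        "late": np.exp((x - 1) / 0.15),
    }
    rows, truth = [], []
    for name, base in fams.items():
        for i in range(per_family):
            rows.append(base + rng.normal(0, noise, g))
            truth.append(name)
    vals = pd.DataFrame(rows, index=[f"{t}{i}" for i, t in enumerate(truth)])
    return vals, truth, x


class TestCurveClustering:
    def test_six_template_families_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        from tonsilflow.gam import SmoothedCurveSet

        rng = np.random.default_rng(119)
        vals, truth, x = _template_curves(rng)
        z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=0),
                                                    axis=0)
        curves = SmoothedCurveSet(x, vals, z)
        labels = cluster_smoothed_curves(curves, k=6)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_rows_same_cluster(self):
        from tonsilflow.gam import SmoothedCurveSet

        rng = np.random.default_rng(120)
        vals, _, x = _template_curves(rng, per_family=2)
        vals.loc["dup"] = vals.iloc[0]
        z = vals.sub(vals.mean(axis=1), axis=0).div(vals.std(axis=1, ddof=0),
                                                    axis=0)
        labels = cluster_smoothed_curves(SmoothedCurveSet(x, vals, z), k=6)
        assert labels["dup"] == labels[vals.index[0]]

    def test_manhattan_distances_match_brute_force(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(121)
        rows = rng.normal(0, 1, (5, 20))
        got = pdist(rows, metric="cityblock")
        idx = 0
        for i in range(5):
            for j in range(i + 1, 5):
                assert got[idx] == pytest.approx(np.abs(rows[i] - rows[j]).sum())
                idx += 1

    def test_k_larger_than_features_raises(self):
        from tonsilflow.gam import SmoothedCurveSet

        rng = np.random.default_rng(122)
        vals, _, x = _template_curves(rng, per_family=1)
        z = vals.sub(vals.mean(axis=1), axis=0)
        with pytest.raises(ValueError):
            cluster_smoothed_curves(SmoothedCurveSet(x, vals.iloc[:3],
                                                     z.iloc[:3]), k=6)
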