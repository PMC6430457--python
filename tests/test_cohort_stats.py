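"""Cohort descriptives, Pearson matrix with t-tests, normality report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from femoromorph.cohort_stats import (CohortTable, descriptives,
                                      freedman_diaconis_edges,
                                      normality_report, pearson_matrix,
                                      render_report)
from femoromorph.errors import CohortSpecError
from femoromorph.mesh_io import PARAMETER_ORDER


def make_df(n, rng=None, **columns):
    """A 12-column cohort DataFrame; unspecified columns are N(10, 1)."""
    rng = rng or np.random.default_rng(0)
    data = {"specimen_id": [f"S{i}" for i in range(n)], "side": ["right"] * n}
    for name in PARAMETER_ORDER:
        data[name] = np.asarray(columns.get(name, rng.normal(10, 1, n)),
                                dtype=float)
    return pd.DataFrame(data)


class TestDescriptives:
    def test_constant_column(self):
        d = descriptives(make_df(3, FHD=[5.0, 5.0, 5.0]))
        row = d["FHD"]
        assert row["sd"] == 0.0
        assert row["min"] == row["max"] == row["median"] == 5.0

    def test_median_resists_outlier(self):
        d = descriptives(make_df(5, TFL=[1, 2, 3, 4, 100]))
        assert d["TFL"]["median"] == 3.0
        assert d["TFL"]["mean"] == 22.0

    def test_sample_sd_uses_n_minus_1(self):
        d = descriptives(make_df(4, OSA=[1.0, 2.0, 3.0, 4.0]))
        assert d["OSA"]["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_recovers_generating_moments(self):
        rng = np.random.default_rng(5)
        x = rng.normal(46.29, 4.02, 10_000)
        d = descriptives(make_df(10_000, rng=rng, FHD=x))
        se_mean = 4.02 / np.sqrt(10_000)
        assert abs(d["FHD"]["mean"] - 46.29) < 3 * se_mean
        assert abs(d["FHD"]["sd"] - 4.02) < 3 * 4.02 / np.sqrt(2 * 9_999)

    def test_permutation_invariance(self, rng):
        df = make_df(40, rng=rng)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(descriptives(df).table,
                                      descriptives(shuffled).table)

    def test_n_below_2_rejected(self):
        with pytest.raises(CohortSpecError):
            descriptives(make_df(1))


class TestPearson:
    def test_hand_computed_example(self):
        # product-moment by hand: r = 0.8, t = r sqrt((n-2)/(1-r^2)) = 2.3094
        df = make_df(5, OSA=[1, 2, 3, 4, 5], OSH=[2, 1, 4, 3, 5])
        res = pearson_matrix(df)
        assert res.r.loc["OSA", "OSH"] == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert t == pytest.approx(2.3094, abs=1e-4)
        want_p = 2 * stats.t.sf(t, df=3)
        assert res.p.loc["OSA", "OSH"] == pytest.approx(want_p, abs=1e-12)
        # independent route: scipy's pearsonr
        sp = stats.pearsonr(df["OSA"], df["OSH"])
        assert res.r.loc["OSA", "OSH"] == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p.loc["OSA", "OSH"] == pytest.approx(sp.pvalue, abs=1e-12)

    def test_self_correlation(self, rng):
        res = pearson_matrix(make_df(30, rng=rng))
        assert np.allclose(np.diag(res.r), 1.0)
        assert np.allclose(np.diag(res.p), 0.0)

    def test_matches_brute_force_double_loop(self, rng):
        df = make_df(50, rng=rng)
        res = pearson_matrix(df)
        X = df[PARAMETER_ORDER].to_numpy()
        for i in range(12):
            for j in range(12):
                x, y = X[:, i], X[:, j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2))
                assert res.r.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        res = pearson_matrix(make_df(25, rng=rng))
        assert np.allclose(res.r, res.r.T)
        assert np.allclose(res.p, res.p.T)
        assert (np.abs(res.r.to_numpy()) <= 1.0 + 1e-12).all()
        assert ((res.p.to_numpy() >= 0) & (res.p.to_numpy() <= 1)).all()

    def test_p_monotone_in_abs_r(self, rng):
        res = pearson_matrix(make_df(60, rng=rng))
        iu = np.triu_indices(12, 1)
        r = np.abs(res.r.to_numpy()[iu])
        p = res.p.to_numpy()[iu]
        order = np.argsort(r)
        assert (np.diff(p[order]) <= 1e-12).all()

    def test_zero_variance_column_flagged_not_fatal(self, rng):
        res = pearson_matrix(make_df(20, rng=rng, NCVD=np.full(20, 3.0)))
        assert "NCVD" in res.degenerate
        assert np.isnan(res.r.loc["NCVD", "FHD"])
        assert np.isfinite(res.r.loc["FHD", "TFL"])

    def test_significance_mask(self, rng):
        n = 169
        x = rng.normal(size=n)
        res = pearson_matrix(make_df(n, rng=rng, OSA=x, OSH=x + 0.3 * rng.normal(size=n)))
        assert bool(res.significant.loc["OSA", "OSH"])

    def test_small_n_rejected(self):
        with pytest.raises(CohortSpecError):
            pearson_matrix(make_df(2))


class TestNormality:
    def test_gaussian_called_normal_in_90pct_of_seeds(self):
        hits = 0
        for s in range(100):
            x = np.random.default_rng(1000 + s).normal(46.29, 4.02, 169)
            hits += stats.shapiro(x).pvalue >= 0.05
        assert hits >= 90

    def test_folded_gaussian_called_non_normal_in_90pct_of_seeds(self):
        hits = 0
        for s in range(100):
            x = np.abs(np.random.default_rng(2000 + s).normal(0.0, 1.22, 169))
            hits += stats.shapiro(x).pvalue < 0.05
        assert hits >= 90

    def test_report_classifies_columns(self):
        rng = np.random.default_rng(8)
        df = make_df(169, rng=rng,
                     TFL=rng.normal(439.22, 29.62, 169),
                     NCDF=np.abs(rng.normal(0.0, 1.22, 169)))
        rep = normality_report(df)
        assert bool(rep.loc["TFL", "normal"])
        assert not bool(rep.loc["NCDF", "normal"])
        edges = rep.loc["TFL", "bin_edges"]
        assert np.array_equal(edges, freedman_diaconis_edges(df["TFL"]))

    def test_constant_column_degenerate(self, rng):
        rep = normality_report(make_df(20, rng=rng, GTH=np.full(20, 1.5)))
        assert bool(rep.loc["GTH", "degenerate"])
        assert not bool(rep.loc["GTH", "normal"])

    def test_small_n_rejected(self, rng):
        with pytest.raises(CohortSpecError):
            normality_report(make_df(5, rng=rng))


class TestReport:
    def test_render_report_files_and_roundtrip(self, tmp_path, rng):
        df = make_df(40, rng=rng)
        out = str(tmp_path / "report")
        paths = render_report(df, out)
        assert len(paths) >= 4
        import os
        for p in paths:
            assert os.path.exists(p)
        back = pd.read_csv(os.path.join(out, "table1.csv"), index_col=0)
        want = descriptives(df).table
        assert np.allclose(back.to_numpy(), want.to_numpy(), atol=1e-9)
        r_back = pd.read_csv(os.path.join(out, "table2_r.csv"), index_col=0)
        assert np.allclose(r_back.to_numpy(),
                           pearson_matrix(df).r.to_numpy(), atol=1e-9)

    def test_rerun_is_deterministic(self, tmp_path, rng):
        df = make_df(30, rng=rng)
        a, b = str(tmp_path / "a"), str(tmp_path / "b")
        render_report(df, a)
        render_report(df, b)
        import os
        for name in ("cohort.csv", "table1.csv", "table2_r.csv",
                     "table2_p.csv", "normality.csv"):
            assert open(os.path.join(a, name), "rb").read() \
                == open(os.path.join(b, name), "rb").read()


def test_cohort_table_from_dataframe_roundtrip(rng):
    df = make_df(6, rng=rng)
    table = CohortTable.from_dataframe(df)
    assert table.n == 6
    assert np.allclose(table.matrix(), df[PARAMETER_ORDER].to_numpy())
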