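import numpy as np
import pandas as pd
import pytest

import stemfit
from stemfit import (
    HeightInterval,
    IntervalSummary,
    TreeInstance,
    match_trees,
    select_best_interval,
    summarize_errors,
)
from stemfit.evaluation import ErrorReport, PER_TREE_COLUMNS, read_report, write_report


def make_truth(xy, dbh=20.0):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"tree_id": np.arange(1, len(xy) + 1),
                         "x": xy[:, 0], "y": xy[:, 1],
                         "dbh_cm": np.full(len(xy), dbh)})


def make_instances(xy):
    return [TreeInstance(i + 1, np.arange(0), (float(x), float(y)))
            for i, (x, y) in enumerate(xy)]


def per_tree_frame(est, true, cred, interval="1.0-1.1m"):
    est, true, cred = map(np.asarray, (est, true, cred))
    err = est - true
    return pd.DataFrame({
        "tree_id": np.arange(1, len(est) + 1),
        "interval": interval,
        "dbh_est_cm": est,
        "dbh_true_cm": true,
        "abs_error_cm": np.abs(err),
        "rel_error_pct": 100 * err / true,
        "credibility": cred,
        "status": "ok",
    })


class TestMatchTrees:
    def test_identical_centroids_match_perfectly(self):
        xy = [(0, 0), (5, 5), (10, 0)]
        res = match_trees(make_instances(xy), make_truth(xy), max_dist=1.0)
        assert len(res.pairs) == 3
        assert not res.unmatched_instances
        assert len(res.unmatched_truth) == 0
        for inst, row in res.pairs:
            assert inst.centroid_xy == (row["x"], row["y"])

    def test_distant_instance_unmatched(self):
        res = match_trees(make_instances([(50, 50)]), make_truth([(0, 0)]),
                          max_dist=1.0)
        assert not res.pairs
        assert len(res.unmatched_instances) == 1
        assert len(res.unmatched_truth) == 1

    def test_matches_bruteforce_optimal_assignment(self):
        from itertools import permutations
        rng = np.random.default_rng(0)
        txy = rng.uniform(0, 20, size=(3, 2))
        perm = [2, 0, 1]
        ixy = txy[perm] + rng.normal(0, 0.05, (3, 2))
        instances = make_instances(ixy)
        res = match_trees(instances, make_truth(txy), max_dist=1.0)

        def cost(p):
            return sum(np.linalg.norm(ixy[i] - txy[j]) for i, j in enumerate(p))
        best = min(permutations(range(3)), key=cost)
        got = {inst.instance_id - 1: int(row["tree_id"]) - 1
               for inst, row in res.pairs}
        assert got == {i: j for i, j in enumerate(best)}

    def test_each_truth_used_once(self):
        # two instances near one stem: only the closer one matches
        truth = make_truth([(0, 0)])
        instances = make_instances([(0.1, 0), (0.3, 0)])
        res = match_trees(instances, truth, max_dist=1.0)
        assert len(res.pairs) == 1
        assert res.pairs[0][0].centroid_xy == (0.1, 0.0)


class TestSummarizeErrors:
    def test_perfect_estimates_all_zero(self):
        df = per_tree_frame([20, 25, 30], [20, 25, 30], [0.7, 0.8, 0.9])
        s = summarize_errors(df, "1.0-1.1m")
        assert s.mean_abs_error_cm == 0
        assert s.rmse_cm == 0
        assert s.mean_rel_error_pct == 0

    def test_hand_computed_two_tree_example(self):
        df = per_tree_frame([21.0, 19.0], [20.0, 20.0], [0.7, 0.9])
        s = summarize_errors(df, "1.0-1.1m")
        assert s.mean_abs_error_cm == pytest.approx(1.0)
        assert s.rmse_cm == pytest.approx(1.0)
        assert s.mean_rel_error_pct == pytest.approx(5.0)
        assert s.var_abs_error == pytest.approx(0.0)

    def test_matches_straightline_recomputation(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(12, 33, 20)
        est = true + rng.normal(0, 0.8, 20)
        cred = rng.uniform(0.3, 1.0, 20)
        s = summarize_errors(per_tree_frame(est, true, cred), "1.0-1.1m")

        e = est - true
        n = 20
        mean_abs = sum(abs(v) for v in e) / n
        rel = [100 * v / t for v, t in zip(e, true)]
        mean_rel = sum(abs(r) for r in rel) / n
        var_abs = sum((abs(v) - mean_abs) ** 2 for v in e) / (n - 1)
        rmse = (sum(v * v for v in e) / n) ** 0.5
        mc, me = sum(cred) / n, sum(abs(v) for v in e) / n
        cov = sum((c - mc) * (abs(v) - me) for c, v in zip(cred, e)) / n
        sdc = (sum((c - mc) ** 2 for c in cred) / n) ** 0.5
        sde = (sum((abs(v) - me) ** 2 for v in e) / n) ** 0.5
        assert s.mean_abs_error_cm == pytest.approx(mean_abs, rel=1e-12)
        assert s.mean_rel_error_pct == pytest.approx(mean_rel, rel=1e-12)
        assert s.var_abs_error == pytest.approx(var_abs, rel=1e-12)
        assert s.rmse_cm == pytest.approx(rmse, rel=1e-12)
        assert s.corr_credibility_abs_error == pytest.approx(cov / (sdc * sde), rel=1e-12)
        assert s.credibility_sd == pytest.approx(
            (sum((c - mc) ** 2 for c in cred) / (n - 1)) ** 0.5, rel=1e-12)

    def test_invariant_under_row_reordering(self):
        rng = np.random.default_rng(2)
        df = per_tree_frame(rng.uniform(15, 30, 10), rng.uniform(15, 30, 10),
                            rng.uniform(0, 1, 10))
        shuffled = df.sample(frac=1, random_state=3).reset_index(drop=True)
        a, b = summarize_errors(df, "1.0-1.1m"), summarize_errors(shuffled, "1.0-1.1m")
        for name in ("mean_abs_error_cm", "var_abs_error", "mean_rel_error_pct",
                     "rmse_cm", "corr_credibility_abs_error", "credibility_sd"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-12)

    def test_fewer_than_two_pairs_raises(self):
        df = per_tree_frame([20.0], [19.0], [0.8])
        with pytest.raises(ValueError, match=">= 2"):
            summarize_errors(df, "1.0-1.1m")

    def test_zero_variance_credibility_warns_nan_corr(self):
        df = per_tree_frame([21, 19, 22], [20, 20, 20], [0.8, 0.8, 0.8])
        with pytest.warns(UserWarning, match="zero variance"):
            s = summarize_errors(df, "1.0-1.1m")
        assert np.isnan(s.corr_credibility_abs_error)


class TestSelectBestInterval:
    @staticmethod
    def summary(label, mean_abs, rmse=1.0):
        return IntervalSummary(label, 71, mean_abs, 0.5, 2.0, 15.0, 15.0,
                               rmse, 0.05, 0.32)

    def test_smallest_mean_abs_error_wins(self):
        s = [self.summary("1.0-1.1m", 0.43), self.summary("1.1-1.2m", 0.63),
             self.summary("1.2-1.4m", 0.68)]
        assert select_best_interval(s) == "1.0-1.1m"

    def test_rmse_breaks_ties(self):
        s = [self.summary("1.0-1.1m", 0.5, rmse=0.9),
             self.summary("1.1-1.2m", 0.5, rmse=0.7),
             self.summary("1.2-1.4m", 0.5, rmse=0.8)]
        assert select_best_interval(s) == "1.1-1.2m"

    def test_lowest_interval_breaks_remaining_ties(self):
        s = [self.summary("1.1-1.2m", 0.5), self.summary("1.0-1.1m", 0.5)]
        assert select_best_interval(s) == "1.0-1.1m"

    def test_single_summary(self):
        assert select_best_interval([self.summary("1.2-1.4m", 2.0)]) == "1.2-1.4m"


class TestReports:
    def test_round_trip(self, tmp_path):
        per_tree = per_tree_frame([21.0, 19.5], [20.0, 20.0], [0.8, 0.6])
        s = summarize_errors(per_tree, "1.0-1.1m")
        report = ErrorReport(per_tree, pd.DataFrame([s.__dict__]), "1.0-1.1m")
        write_report(report, tmp_path / "out")
        back = read_report(tmp_path / "out")
        assert back.selected_interval == "1.0-1.1m"
        pd.testing.assert_frame_equal(back.per_tree, per_tree)
        pd.testing.assert_frame_equal(back.per_interval,
                                      report.per_interval)

    def test_empty_report_writes_headers(self, tmp_path):
        report = ErrorReport(pd.DataFrame(columns=PER_TREE_COLUMNS),
                             pd.DataFrame(columns=stemfit.evaluation.SUMMARY_COLUMNS))
        write_report(report, tmp_path / "out")
        assert (tmp_path / "out" / "per_tree.csv").exists()
        back = read_report(tmp_path / "out")
        assert len(back.per_tree) == 0
        assert back.selected_interval is None

    def test_plots_written(self, tmp_path):
        rng = np.random.default_rng(4)
        per_tree = per_tree_frame(rng.uniform(15, 30, 10),
                                  rng.uniform(15, 30, 10),
                                  rng.uniform(0.3, 1, 10))
        s = summarize_errors(per_tree, "1.0-1.1m")
        report = ErrorReport(per_tree, pd.DataFrame([s.__dict__]), "1.0-1.1m")
        write_report(report, tmp_path / "out", plots=True)
        assert (tmp_path / "out" / "report.png").stat().st_size > 0
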