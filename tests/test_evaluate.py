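"""Evaluation metrics: coverage, PR sweep, break-even, protein metrics, CV."""

import numpy as np
import pytest

from boundscan import (
    DomainDefinition,
    ProteinClass,
    SiteLabel,
    break_even,
    pr_curve,
    protein_metrics,
    signal_coverage,
    site_pr,
)
from boundscan.classify import ProteinCall, SitePrediction
from boundscan.evaluate import PRPoint, default_thresholds
from boundscan.signals import SignalSite


def _near(pos, s2):
    call = SiteLabel.NEAR if s2 > 0 else SiteLabel.AWAY
    return SitePrediction(pos, 1.0, s2, call)


TWO_DOM = DomainDefinition("c", ((1, 150), (151, 300)))  # points {150, 151}


class TestSignalCoverage:
    def test_saturated(self):
        sites = {"c": [SignalSite(150, 1), SignalSite(151, 1)]}
        assert signal_coverage(sites, {"c": TWO_DOM}) == 1.0

    def test_no_sites(self):
        assert signal_coverage({"c": []}, {"c": TWO_DOM}) == 0.0

    def test_inclusive_tolerance_boundary(self):
        # one point covered at distance exactly 20, the other missed at 21
        d = DomainDefinition("c", ((1, 100), (200, 300)))  # points {100, 200}
        sites = {"c": [SignalSite(120, 1), SignalSite(221, 1)]}
        assert signal_coverage(sites, {"c": d}) == 0.5

    def test_boundary_level_counting(self):
        # many sites near one point still count it once
        sites = {"c": [SignalSite(p, 1) for p in (140, 145, 150)]}
        d = DomainDefinition("c", ((1, 150), (151, 400), (401, 500)))
        assert signal_coverage(sites, {"c": d}) == pytest.approx(2 / 4)

    def test_no_multi_domain_chains_flagged_undefined(self):
        assert signal_coverage({}, {}) is None


class TestSitePR:
    def test_all_near_calls_correct(self):
        preds = {"c": [_near(150, 0.5), _near(160, 0.9)]}
        pt = site_pr(preds, {"c": TWO_DOM}, threshold=0.0)
        assert pt.precision == 1.0 and pt.n_predicted == 2

    def test_empty_prediction_edge(self):
        preds = {"c": [_near(150, 0.5)]}
        pt = site_pr(preds, {"c": TWO_DOM}, threshold=2.0)
        assert pt.precision is None and pt.recall == 0.0 and pt.n_predicted == 0

    def test_recall_is_boundary_level(self):
        # 4 eligible points in two transitions; sites recall one transition
        d = DomainDefinition("c", ((1, 150), (151, 300), (301, 450)))
        preds = {"c": [_near(150, 0.5), _near(148, 0.7), _near(152, 0.3)]}
        pt = site_pr(preds, {"c": d}, threshold=0.0)
        assert pt.recall == pytest.approx(2 / 4)

    def test_terminal_margin_excludes_points(self):
        # points {60, 61}: 60 is only 59 residues from the N-terminus start 1;
        # with margin 59 both are excluded from the recall denominator
        d = DomainDefinition("c", ((1, 60), (61, 300)))
        preds = {"c": []}
        pt = site_pr(preds, {"c": d}, threshold=0.0, terminal_margin=60)
        assert pt.recall == 0.0
        pt40 = site_pr({"c": [_near(61, 1.0)]}, {"c": d}, threshold=0.0)
        assert pt40.recall == 1.0  # both points within 20 of the site

    def test_matches_brute_force_confusion(self):
        rng = np.random.default_rng(5)
        d = DomainDefinition("c", ((1, 200), (201, 420)))
        points = {200, 201}
        preds = {
            "c": [
                _near(int(p), float(s))
                for p, s in zip(rng.integers(1, 421, 40), rng.normal(0, 1, 40))
            ]
        }
        for thr in (-0.5, 0.0, 0.5):
            near = [p for p in preds["c"] if p.stage2_score > thr]
            correct = [
                p for p in near if min(abs(p.position - b) for b in points) <= 20
            ]
            eligible = {b for b in points if b - 1 > 40 and 420 - b > 40}
            recalled = {
                b for b in eligible
                if any(abs(p.position - b) <= 20 for p in near)
            }
            pt = site_pr(preds, {"c": d}, thr)
            if near:
                assert pt.precision == pytest.approx(len(correct) / len(near))
            assert pt.recall == pytest.approx(len(recalled) / len(eligible))


class TestBreakEven:
    def _curve(self, thresholds, precisions, recalls):
        return [
            PRPoint(t, p, r, 10, 5)
            for t, p, r in zip(thresholds, precisions, recalls)
        ]

    def test_constant_equal_curves(self):
        curve = self._curve([0, 0.5, 1.0], [0.6] * 3, [0.6] * 3)
        assert break_even(curve) == pytest.approx(0.6)

    def test_no_crossing_absent(self):
        curve = self._curve([0, 0.5, 1.0], [0.9, 0.9, 0.9], [0.5, 0.4, 0.3])
        assert break_even(curve) is None

    def test_interpolated_crossing_matches_hand_computation(self):
        # precision rises 0.4 -> 0.8, recall falls 0.7 -> 0.5 over [0.1, 0.15]:
        # d(t) = (p - r) goes -0.3 -> +0.3, crossing at fraction 0.5
        curve = self._curve([0.10, 0.15], [0.4, 0.8], [0.7, 0.5])
        assert break_even(curve) == pytest.approx(0.6)

    def test_interpolation_agrees_with_fine_grid_brute_force(self):
        # piecewise-linear precision/recall in the threshold; compare the
        # interpolated break-even against scanning a 1e-4-step grid
        def precision(t):
            return 0.3 + 0.4 * (t + 1.5) / 3.0

        def recall(t):
            return 0.9 - 0.5 * (t + 1.5) / 3.0

        coarse = [
            PRPoint(t, precision(t), recall(t), 10, 5)
            for t in default_thresholds()
        ]
        grid = np.arange(-1.5, 1.5, 1e-4)
        diffs = np.array([precision(t) - recall(t) for t in grid])
        t_cross = grid[np.argmin(np.abs(diffs))]
        assert break_even(coarse) == pytest.approx(precision(t_cross), abs=1e-3)


class TestPRCurveProperties:
    def test_recall_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        preds = {
            "c": [
                _near(int(p), float(s))
                for p, s in zip(rng.integers(1, 301, 50), rng.normal(0, 1, 50))
            ]
        }
        curve = pr_curve(preds, {"c": TWO_DOM})
        recalls = [p.recall for p in curve]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_default_sweep_endpoints(self):
        ts = default_thresholds()
        assert ts[0] == -1.5 and ts[-1] == 1.5 and len(ts) == 61


class TestProteinMetrics:
    def _call(self, chain, cls):
        return ProteinCall(chain, cls)

    def test_perfect_calls(self):
        truth = {
            "a": DomainDefinition("a", ((1, 100),)),
            "b": TWO_DOM,
        }
        calls = {
            "a": self._call("a", ProteinClass.SINGLE_DOMAIN),
            "b": self._call("b", ProteinClass.MULTI_DOMAIN),
        }
        m = protein_metrics(calls, truth)
        assert m.accuracy == 1.0
        assert m.single_precision == m.single_recall == 1.0
        assert m.multi_precision == m.multi_recall == 1.0

    def test_all_single_on_balanced_truth(self):
        truth = {
            "a": DomainDefinition("a", ((1, 100),)),
            "b": TWO_DOM,
        }
        calls = {c: self._call(c, ProteinClass.SINGLE_DOMAIN) for c in truth}
        m = protein_metrics(calls, truth)
        assert m.accuracy == 0.5
        assert m.multi_recall == 0.0
        assert m.multi_precision is None  # no multi calls made

    def test_confusion_toy_matches_hand_arithmetic(self):
        # 68 true multi called multi, 32 single called multi, 28 multi called
        # single: multi precision 68/100, recall 68/96
        truth = {}
        calls = {}
        i = 0
        for n, true_multi, called_multi in ((68, True, True), (32, False, True),
                                            (28, True, False), (72, False, False)):
            for _ in range(n):
                cid = f"c{i}"; i += 1
                truth[cid] = TWO_DOM if true_multi else DomainDefinition(cid, ((1, 100),))
                calls[cid] = self._call(
                    cid,
                    ProteinClass.MULTI_DOMAIN if called_multi else ProteinClass.SINGLE_DOMAIN,
                )
        m = protein_metrics(calls, truth)
        assert m.multi_precision == pytest.approx(0.68)
        assert m.multi_recall == pytest.approx(68 / 96)
        assert m.accuracy == pytest.approx((68 + 72) / 200)

    def test_chain_missing_from_truth_raises(self):
        calls = {"a": self._call("a", ProteinClass.SINGLE_DOMAIN)}
        with pytest.raises(KeyError, match="a"):
            protein_metrics(calls, {})


@pytest.fixture(scope="module")
def chain_data(small_dataset):
    from conftest import to_chain_data

    chains, _ = small_dataset
    return to_chain_data(chains)


class TestCrossval:
    """Protein-level cross-validation on a small simulated dataset."""

    def test_k_larger_than_n_raises(self, chain_data):
        from boundscan import crossval

        with pytest.raises(ValueError, match="exceeds"):
            crossval(chain_data, k=len(chain_data) + 1)

    def test_seed_determinism(self, chain_data):
        from boundscan import crossval

        a = crossval(chain_data[:12], k=4, seed=5)
        b = crossval(chain_data[:12], k=4, seed=5)
        assert a.task1_accuracy == b.task1_accuracy
        assert a.task2_accuracy == b.task2_accuracy
        assert a.protein_metrics.accuracy == b.protein_metrics.accuracy
        assert a.break_even == b.break_even

    def test_loocv_runs_with_k_equal_n(self, chain_data):
        from boundscan import crossval

        subset = chain_data[:8]
        report = crossval(subset, k=len(subset), seed=1)
        assert report.task1_accuracy is not None
        assert 0.0 <= report.protein_metrics.accuracy <= 1.0

    def test_fold_sizes_differ_by_at_most_one(self):
        # the fold construction mirrors crossval's internal split
        rng = np.random.default_rng(3)
        folds = np.array_split(rng.permutation(23), 10)
        sizes = {len(f) for f in folds}
        assert max(sizes) - min(sizes) <= 1
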