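"""Scores, Youden-J threshold search, incidences and the G-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from ligload.relaxometry import ValidationError
from ligload.risk_strat import (
    ContingencyTable,
    RevisionStratification,
    lr_chi_square,
    optimal_threshold,
    score_failure_loads,
    stratify,
    youden_j,
)

#: 2x2 counts realizing the published clinical pilot: 24 low-score subjects
#: with 5 revisions, 22 high-score subjects with 1 revision.
PILOT_TABLE = ContingencyTable(tp=5, fn=1, tn=21, fp=19)


class TestScores:
    def test_endpoints_and_midpoint(self):
        s = score_failure_loads([500.0, 1000.0, 1500.0])
        np.testing.assert_allclose(s.scores, [0.0, 0.5, 1.0])
        assert (s.f_min, s.f_max) == (500.0, 1500.0)

    def test_affine_invariance(self, rng):
        loads = rng.uniform(300, 4000, 30)
        a = score_failure_loads(loads)
        b = score_failure_loads(3.7 * loads + 250.0)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_formula_oracle(self, rng):
        loads = rng.uniform(100, 5000, 50)
        s = score_failure_loads(loads)
        brute = [(x - loads.min()) / (loads.max() - loads.min()) for x in loads]
        np.testing.assert_allclose(s.scores, brute, atol=1e-15)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            score_failure_loads([1000.0, 1000.0])
        with pytest.raises(ValidationError):
            score_failure_loads([1000.0])

    def test_rank_monotonicity(self, rng):
        loads = rng.uniform(100, 5000, 25)
        s = score_failure_loads(loads)
        np.testing.assert_array_equal(np.argsort(s.scores), np.argsort(loads))


class TestYoudenJ:
    def test_pilot_counts(self):
        assert youden_j(PILOT_TABLE) == pytest.approx(5 / 6 + 21 / 40 - 1)
        assert round(youden_j(PILOT_TABLE), 2) == 0.36

    def test_perfect_classifier(self):
        assert youden_j(ContingencyTable(6, 0, 40, 0)) == 1.0

    def test_chance_level(self):
        assert youden_j(ContingencyTable(3, 3, 10, 10)) == pytest.approx(0.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            youden_j(ContingencyTable(0, 0, 10, 10))

    def test_formula_oracle_random_tables(self, rng):
        for _ in range(200):
            tp, fn, tn, fp = rng.integers(0, 30, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            t = ContingencyTable(int(tp), int(fn), int(tn), int(fp))
            brute = tp / (tp + fn) + tn / (tn + fp) - 1.0
            assert youden_j(t) == pytest.approx(brute, abs=1e-12)


def brute_force_best_threshold(scores, outcomes):
    """Enumerate every threshold-consistent low/high assignment."""
    scores = np.asarray(scores)
    outcomes = np.asarray(outcomes)
    best = (None, -np.inf)
    for t in np.unique(scores):
        low = scores <= t
        tp = int(np.sum(low & (outcomes == 1)))
        fn = int(np.sum(~low & (outcomes == 1)))
        tn = int(np.sum(~low & (outcomes == 0)))
        fp = int(np.sum(low & (outcomes == 0)))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best[1]:
            best = (float(t), j)
    return best


class TestOptimalThreshold:
    def test_separable_two_subjects(self):
        res = optimal_threshold([0.1, 0.9], [1, 0])
        assert res.threshold == pytest.approx(0.1)
        assert res.j == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_sweep_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        scores = np.round(rng.uniform(0, 1, n), 2)
        outcomes = rng.integers(0, 2, n)
        if outcomes.min() == outcomes.max():
            outcomes[0] = 1 - outcomes[0]
        res = optimal_threshold(scores, outcomes)
        t_exact, j_exact = brute_force_best_threshold(scores, outcomes)
        assert res.j == pytest.approx(j_exact, abs=1e-12)
        assert res.threshold == pytest.approx(t_exact)

    def test_tie_break_smallest_threshold(self):
        # thresholds 0.2 and 0.4 both give J = 1 - 0 = ... construct tie
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        outcomes = np.array([1, 0, 0, 0])
        res = optimal_threshold(scores, outcomes)
        assert res.threshold == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_bounded_below_by_youden_rectangle(self, seed):
        """AUC >= TPR*(1-FPR) at the Youden point: the ROC is monotone and
        passes through that point, so the rectangle under it is covered."""
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 1, 40)
        outcomes = rng.integers(0, 2, 40)
        outcomes[0], outcomes[1] = 0, 1
        res = optimal_threshold(scores, outcomes)
        tpr_fpr = {tuple(p) for p in res.roc_points}
        fpr, tpr = max(tpr_fpr, key=lambda p: p[1] - p[0])
        assert res.auc >= tpr * (1.0 - fpr) - 1e-12

    def test_permutation_null_auc(self, rng):
        scores = rng.uniform(0, 1, 46)
        outcomes = np.array([1] * 6 + [0] * 40)
        aucs = []
        for _ in range(300):
            perm = rng.permutation(outcomes)
            aucs.append(optimal_threshold(scores, perm).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            optimal_threshold([0.2, 0.8], [1, 1])


class TestStratify:
    def test_published_pilot_arithmetic(self):
        """5/24 low vs 1/22 high -> 20.8% vs 4.5%, a 362% risk increase."""
        scores = np.array([0.5] * 24 + [0.9] * 22)
        outcomes = np.array([1] * 5 + [0] * 19 + [1] * 1 + [0] * 21)
        tab, res = stratify(scores, outcomes, 0.81)
        assert (tab.tp, tab.fn, tab.tn, tab.fp) == (5, 1, 21, 19)
        assert res.incidence_low == pytest.approx(20.8, abs=0.05)
        assert res.incidence_high == pytest.approx(4.5, abs=0.05)
        assert round(res.percent_risk_increase) == 362
        assert round(res.percent_risk_increase_unrounded) == 358

    def test_zero_incidence_high_group_undefined(self):
        scores = np.array([0.2] * 24 + [0.9] * 22)
        outcomes = np.array([1] * 6 + [0] * 18 + [0] * 22)
        _, res = stratify(scores, outcomes, 0.33)
        assert res.incidence_low == pytest.approx(25.0)
        assert res.incidence_high == 0.0
        assert res.percent_risk_increase is None

    def test_empty_group_flagged(self):
        _, res = stratify(np.array([0.1, 0.2]), np.array([1, 0]), 0.9)
        assert res.incidence_high is None

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            stratify(np.array([0.1, 0.9]), np.array([1, 0]), 1.5)


def multinomial_g_oracle(table):
    """G from saturated vs independence multinomial log-likelihoods."""
    obs = np.array([[table.tp, table.fn], [table.fp, table.tn]], float)
    n = obs.sum()
    p_sat = obs / n
    p_ind = (obs.sum(1, keepdims=True) / n) @ (obs.sum(0, keepdims=True) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sat = np.where(obs > 0, obs * np.log(np.where(p_sat > 0, p_sat, 1.0)), 0.0).sum()
    ll_ind = np.where(obs > 0, obs * np.log(p_ind), 0.0).sum()
    return 2.0 * (ll_sat - ll_ind)


class TestLikelihoodRatio:
    def test_pilot_table(self):
        g, p = lr_chi_square(PILOT_TABLE)
        assert g == pytest.approx(2.93, abs=0.01)
        assert p == pytest.approx(0.09, abs=0.005)

    def test_independence_gives_zero(self):
        g, p = lr_chi_square(ContingencyTable(4, 4, 6, 6))
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_multinomial_oracle(self, rng):
        checked = 0
        while checked < 100:
            tp, fn, tn, fp = rng.integers(0, 25, 4)
            t = ContingencyTable(int(tp), int(fn), int(tn), int(fp))
            arr = t.as_array()
            if t.total == 0 or np.any(arr.sum(0) == 0) or np.any(arr.sum(1) == 0):
                continue
            g, p = lr_chi_square(t)
            assert g == pytest.approx(multinomial_g_oracle(t), abs=1e-10)
            assert p == pytest.approx(chi2.sf(g, 1), abs=1e-12)
            checked += 1

    def test_transpose_invariance(self, rng):
        for _ in range(50):
            tp, fn, tn, fp = (int(x) for x in rng.integers(1, 25, 4))
            g1, _ = lr_chi_square(ContingencyTable(tp, fn, tn, fp))
            # swapping rows with columns: (tp, fp, tn, fn)
            g2, _ = lr_chi_square(ContingencyTable(tp, fp, tn, fn))
            assert g1 == pytest.approx(g2, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            lr_chi_square(ContingencyTable(0, 0, 10, 10))


class TestRevisionStratification:
    def test_end_to_end_from_loads(self, rng):
        loads = rng.uniform(500, 3000, 46)
        risk = 1.0 / (1.0 + np.exp(0.004 * (loads - 1200)))
        outcomes = (rng.uniform(size=46) < risk).astype(int)
        if outcomes.sum() in (0, 46):
            outcomes[:2] = [0, 1]
        model = RevisionStratification(loads, outcomes)
        res = model.fit()
        assert 0.0 <= res.threshold <= 1.0
        assert res.table.total == 46
        assert -1.0 <= res.j <= 1.0
        assert 0.0 <= res.auc <= 1.0
        assert res.p_value is not None
        assert "Score threshold" in res.summary()

    def test_fixed_threshold_applied(self):
        model = RevisionStratification([100.0, 200, 300, 400], [1, 1, 0, 0])
        res = model.fit(threshold=0.5)
        assert res.threshold == 0.5
        assert (res.table.tp, res.table.fn) == (2, 0)

    def test_yaml_report(self, tmp_path):
        model = RevisionStratification([100.0, 200, 300, 400], [1, 0, 1, 0])
        res = model.fit()
        out = res.to_yaml(tmp_path / "strat.yaml")
        import yaml

        d = yaml.safe_load(out.read_text())
        assert set(d) >= {"threshold", "youden_j", "table", "p_value"}


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(1, 30), st.integers(0, 30), st.integers(1, 30), st.integers(0, 30))
def test_youden_j_bounds(tp, fn, tn, fp):
    j = youden_j(ContingencyTable(tp, fn, tn, fp))
    assert -1.0 <= j <= 1.0
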