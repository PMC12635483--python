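"""Gaussian HMM: EM correctness, decoding oracles, stage labelling, REM
sub-state identification, per-state FC."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from somnidyn.hmm import (
    HmmModel,
    StateLabeling,
    StatePath,
    decode,
    fit_hmm,
    identify_rem_substates,
    label_states,
    log_likelihood,
    standardize,
    state_network_fc,
    usable_segments,
)
from somnidyn.io_atlas import RoiTimeSeries

from conftest import make_ts


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_loglik(x, model):
    """Total likelihood by explicit summation over all K^T paths."""
    k, t = model.n_states, len(x)
    total = 0.0
    for path in itertools.product(range(k), repeat=t):
        p = model.initial[path[0]]
        p *= multivariate_normal.pdf(
            x[0], model.means[path[0]], model.covariances[path[0]]
        )
        for s in range(1, t):
            p *= model.transition[path[s - 1], path[s]]
            p *= multivariate_normal.pdf(
                x[s], model.means[path[s]], model.covariances[path[s]]
            )
        total += p
    return np.log(total)


def brute_force_viterbi(x, model):
    k, t = model.n_states, len(x)
    best, best_p = None, -np.inf
    for path in itertools.product(range(k), repeat=t):
        p = np.log(model.initial[path[0]])
        p += multivariate_normal.logpdf(
            x[0], model.means[path[0]], model.covariances[path[0]]
        )
        for s in range(1, t):
            p += np.log(model.transition[path[s - 1], path[s]])
            p += multivariate_normal.logpdf(
                x[s], model.means[path[s]], model.covariances[path[s]]
            )
        if p > best_p:
            best, best_p = path, p
    return np.array(best)


def toy_model(k=2, d=2, seed=0):
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((k, d)) * 2
    covs = np.stack([np.eye(d) * (1 + 0.5 * j) for j in range(k)])
    trans = rng.dirichlet(np.ones(k) * 5, size=k)
    init = rng.dirichlet(np.ones(k) * 5)
    return HmmModel(means=means, covariances=covs, transition=trans,
                    initial=init, loglik_trace=[0.0])


def sample_from(model, t, seed):
    rng = np.random.default_rng(seed)
    k = model.n_states
    states = np.empty(t, dtype=int)
    states[0] = rng.choice(k, p=model.initial)
    for s in range(1, t):
        states[s] = rng.choice(k, p=model.transition[states[s - 1]])
    x = np.stack(
        [
            rng.multivariate_normal(model.means[j], model.covariances[j])
            for j in states
        ]
    )
    return x, states


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestStandardize:
    def test_unit_sd_and_idempotence(self, rng):
        ts = make_ts(rng.standard_normal((200, 4)) * 7 + 3)
        out = standardize(ts)
        np.testing.assert_allclose(out.data.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        again = standardize(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_constant_roi_rejected(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 2.0
        with pytest.raises(ValueError, match="roi1"):
            standardize(make_ts(data))

    def test_statistics_over_usable_frames_only(self, rng):
        data = rng.standard_normal((100, 3))
        censor = np.ones(100, dtype=bool)
        censor[:20] = False
        data[:20] = 100.0  # censored junk must not leak into the stats
        out = standardize(make_ts(data, censor=censor))
        np.testing.assert_allclose(
            out.data[censor].std(axis=0), 1.0, atol=1e-12
        )


class TestUsableSegments:
    def test_censoring_splits_runs(self):
        censor = np.array([1, 1, 0, 1, 1, 1, 0, 0, 1], dtype=bool)
        ts = make_ts(np.zeros((9, 2)) + np.arange(9)[:, None], censor=censor)
        segs = usable_segments([ts])
        assert segs == [(0, 0, 2), (0, 3, 6), (0, 8, 9)]


class TestFitHmm:
    def test_k1_closed_form(self, rng):
        x = rng.standard_normal((300, 3)) * 1.5 + 0.3
        model = fit_hmm([make_ts(x)], K=1, seed=0, restarts=1, reg=1e-4)
        np.testing.assert_allclose(model.means[0], x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            model.covariances[0],
            np.cov(x, rowvar=False, ddof=0) + 1e-4 * np.eye(3),
            atol=1e-8,
        )
        np.testing.assert_allclose(model.transition, [[1.0]])

    def test_loglik_trace_nondecreasing(self, rng):
        model = toy_model(k=2, d=2, seed=1)
        x, _ = sample_from(model, 400, seed=2)
        fit = fit_hmm([make_ts(x)], K=2, seed=0, restarts=2, init="frames")
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))

    def test_best_restart_wins(self, rng):
        model = toy_model(k=2, d=2, seed=3)
        x, _ = sample_from(model, 300, seed=4)
        fit = fit_hmm([make_ts(x)], K=2, seed=0, restarts=4, init="frames")
        assert fit.loglik_trace[-1] == max(fit.restart_final_logliks)

    def test_well_separated_two_states_recovered(self):
        means = np.array([[0.0, 0.0], [6.0, 6.0]])
        model = HmmModel(
            means=means,
            covariances=np.stack([np.eye(2)] * 2),
            transition=np.array([[0.95, 0.05], [0.05, 0.95]]),
            initial=np.array([0.5, 0.5]),
            loglik_trace=[0.0],
        )
        x, states = sample_from(model, 5000, seed=5)
        fit = fit_hmm([make_ts(x)], K=2, seed=0, restarts=2, init="frames")
        path = decode(fit, [make_ts(x)])
        decoded = path.states[0]
        # Hungarian alignment of state labels
        conf = np.zeros((2, 2))
        for a, b in zip(states, decoded):
            conf[a, b] += 1
        rows, cols = linear_sum_assignment(-conf)
        acc = conf[rows, cols].sum() / len(states)
        assert acc >= 0.99

    def test_k_exceeding_frames_rejected(self, rng):
        x = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="exceeds"):
            fit_hmm([make_ts(x)], K=10, seed=0)


class TestDecodeOracles:
    @pytest.mark.parametrize("k,t", [(2, 3), (2, 6), (3, 4)])
    def test_forward_loglik_matches_path_summation(self, k, t):
        model = toy_model(k=k, d=2, seed=10 + k)
        x, _ = sample_from(model, t, seed=20 + t)
        ll = log_likelihood(model, [make_ts(x)])
        assert ll == pytest.approx(brute_force_loglik(x, model), abs=1e-9)

    @pytest.mark.parametrize("k,t", [(2, 3), (2, 5), (3, 4)])
    def test_viterbi_matches_exhaustive_enumeration(self, k, t):
        model = toy_model(k=k, d=2, seed=30 + k)
        x, _ = sample_from(model, t, seed=40 + t)
        path = decode(model, [make_ts(x)])
        np.testing.assert_array_equal(
            path.states[0], brute_force_viterbi(x, model)
        )

    def test_posterior_rows_sum_to_one(self, rng):
        model = toy_model(k=3, d=2, seed=50)
        x, _ = sample_from(model, 200, seed=51)
        path = decode(model, [make_ts(x)])
        np.testing.assert_allclose(
            path.posteriors[0].sum(axis=1), 1.0, atol=1e-10
        )

    def test_k1_decodes_all_zero(self, rng):
        x = rng.standard_normal((50, 2))
        model = fit_hmm([make_ts(x)], K=1, seed=0, restarts=1)
        path = decode(model, [make_ts(x)])
        assert (path.states[0] == 0).all()

    def test_censored_frames_marked(self, rng):
        model = toy_model(k=2, d=2, seed=60)
        x, _ = sample_from(model, 50, seed=61)
        censor = np.ones(50, dtype=bool)
        censor[10:15] = False
        path = decode(model, [make_ts(x, censor=censor)])
        assert (path.states[0][10:15] == -1).all()
        assert np.isnan(path.posteriors[0][10:15]).all()


def _path(states_per_run):
    return StatePath(
        run_ids=[f"r{i}" for i in range(len(states_per_run))],
        states=[np.asarray(s) for s in states_per_run],
        posteriors=[np.zeros((len(s), 1)) for s in states_per_run],
    )


class TestLabelStates:
    def test_majority_assignment(self):
        path = _path([[0] * 80])
        stages = ("REM",) * 50 + ("N2",) * 30
        lab = label_states(path, [stages], n_states=1)
        assert lab.state_to_stage[0] == "REM"
        assert lab.rem_states == [0]

    def test_tie_broken_by_stage_order_with_warning(self):
        path = _path([[0] * 20])
        stages = ("Wake",) * 10 + ("N1",) * 10
        with pytest.warns(UserWarning, match="tie"):
            lab = label_states(path, [stages], n_states=1)
        assert lab.state_to_stage[0] == "Wake"

    def test_unscored_excluded(self):
        path = _path([[0] * 30])
        stages = ("Unscored",) * 20 + ("N3",) * 10
        lab = label_states(path, [stages], n_states=1)
        assert lab.state_to_stage[0] == "N3"

    def test_matches_counting_oracle_on_random_paths(self, rng):
        n_states = 4
        states = rng.integers(0, n_states, size=500)
        stages = tuple(rng.choice(["Wake", "N1", "N2", "N3", "REM"], 500))
        lab = label_states(_path([states]), [stages], n_states)
        order = ["Wake", "N1", "N2", "N3", "REM"]
        for k in range(n_states):
            counts = {
                s: int(((states == k) & (np.array(stages) == s)).sum())
                for s in order
            }
            expect = max(order, key=lambda s: (counts[s], -order.index(s)))
            assert lab.state_to_stage[k] == expect


def _labeling(mapping):
    return StateLabeling(
        state_to_stage=mapping,
        rem_states=sorted(k for k, v in mapping.items() if v == "REM"),
        evidence={"occupancy": None},
    )


def _runs_for_identification(t=100):
    return [make_ts(np.zeros((t, 2)), tr_seconds=3.0, run_onset_seconds=0.0)]


class TestIdentifyRemSubstates:
    def _model(self, transition):
        k = len(transition)
        return HmmModel(
            means=np.zeros((k, 2)),
            covariances=np.stack([np.eye(2)] * k),
            transition=np.asarray(transition, dtype=float),
            initial=np.full(k, 1.0 / k),
            loglik_trace=[0.0],
        )

    def test_concordant_criteria(self):
        # state 1 REM early (tonic, high wake mass), state 2 REM late (phasic)
        model = self._model(
            [[0.9, 0.05, 0.05], [0.30, 0.65, 0.05], [0.05, 0.05, 0.90]]
        )
        lab = _labeling({0: "Wake", 1: "REM", 2: "REM"})
        states = np.array([1] * 20 + [0] * 40 + [2] * 40)
        out = identify_rem_substates(
            model, lab, _path([states]), _runs_for_identification()
        )
        assert out.tonic_state == 1
        assert out.phasic_state == 2
        assert not out.conflict

    def test_conflicting_criteria_yield_report(self):
        # state 2 has BOTH the higher wake mass and the later occurrence
        model = self._model(
            [[0.9, 0.05, 0.05], [0.05, 0.90, 0.05], [0.30, 0.05, 0.65]]
        )
        lab = _labeling({0: "Wake", 1: "REM", 2: "REM"})
        states = np.array([1] * 20 + [0] * 40 + [2] * 40)
        out = identify_rem_substates(
            model, lab, _path([states]), _runs_for_identification()
        )
        assert out.conflict
        assert out.phasic_state is None and out.tonic_state is None
        assert "conflict" in out.report

    def test_fewer_than_two_rem_states(self):
        model = self._model([[0.9, 0.1], [0.1, 0.9]])
        lab = _labeling({0: "Wake", 1: "REM"})
        out = identify_rem_substates(
            model, lab, _path([[0, 1, 0, 1]]), _runs_for_identification(4)
        )
        assert out.phasic_state is None
        assert "fewer than two" in out.report


class TestStateNetworkFc:
    def test_identical_covariances_give_zero_relative(self, tiny_atlas):
        d = tiny_atlas.n_rois
        cov = np.eye(d) + 0.2
        model = HmmModel(
            means=np.zeros((3, d)),
            covariances=np.stack([cov] * 3),
            transition=np.full((3, 3), 1 / 3),
            initial=np.full(3, 1 / 3),
            loglik_trace=[0.0],
        )
        mats, rel, intra = state_network_fc(model, tiny_atlas)
        for m in rel:
            np.testing.assert_allclose(m.values, 0.0, atol=1e-12)
        assert len(set(np.round(intra, 12))) == 1

    def test_two_state_relative_values_are_half_difference(self, tiny_atlas):
        d = tiny_atlas.n_rois
        c1 = np.eye(d) + 0.1
        np.fill_diagonal(c1, 1.0)
        c2 = np.eye(d) + 0.3
        np.fill_diagonal(c2, 1.0)
        model = HmmModel(
            means=np.zeros((2, d)),
            covariances=np.stack([c1, c2]),
            transition=np.eye(2) * 0.9 + 0.05,
            initial=np.array([0.5, 0.5]),
            loglik_trace=[0.0],
        )
        mats, rel, intra = state_network_fc(model, tiny_atlas)
        diff = mats[1].values - mats[0].values
        np.testing.assert_allclose(rel[1].values, diff / 2, atol=1e-12)
        np.testing.assert_allclose(rel[0].values, -diff / 2, atol=1e-12)


class TestAgainstHmmlearn:
    """Independent cross-check of likelihood and decoding against the
    hmmlearn reference implementation, with identical fixed parameters."""

    def _pair(self, k=3, d=4, seed=80):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        model = toy_model(k=k, d=d, seed=seed)
        ref = hmmlearn_hmm.GaussianHMM(
            n_components=k, covariance_type="full", init_params=""
        )
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.covariances
        return model, ref

    def test_total_loglik_agrees(self):
        model, ref = self._pair()
        x, _ = sample_from(model, 400, seed=81)
        ours = log_likelihood(model, [make_ts(x)])
        theirs = ref.score(x)
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_viterbi_path_agrees(self):
        model, ref = self._pair(seed=82)
        x, _ = sample_from(model, 300, seed=83)
        path = decode(model, [make_ts(x)])
        _, ref_path = ref.decode(x, algorithm="viterbi")
        np.testing.assert_array_equal(path.states[0], ref_path)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        model = toy_model(k=3, d=2, seed=70)
        model.to_json(tmp_path / "m.json")
        back = HmmModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.means, model.means)
        np.testing.assert_array_equal(back.transition, model.transition)
        np.testing.assert_array_equal(back.covariances, model.covariances)
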