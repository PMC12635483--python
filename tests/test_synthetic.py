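"""Generator: hypnogram chain, covariance construction, BOLD simulation,
censoring, dataset round-trip."""

import collections

import numpy as np
import pytest

from somnidyn.io_atlas import STAGES
from somnidyn.synthetic import (
    Coupling,
    GeneratorConfig,
    build_state_covariance,
    condition_covariances,
    default_coupling,
    participant_seed,
    scaled_config,
    simulate_bold,
    simulate_censoring,
    simulate_dataset,
    simulate_hypnogram,
    simulate_night,
    write_dataset,
    PHASIC,
    TONIC,
)


def cyclic_config(**kw):
    """Degenerate chain: Wake->N1->N2->N3->REM cycle with dwell 3."""
    trans = np.zeros((5, 5))
    for i in range(5):
        trans[i, (i + 1) % 5] = 1.0
    kw.setdefault("night_trs", 600)
    return GeneratorConfig(
        stage_transition=trans,
        stage_mean_dwell_epochs={s: 1.0 for s in STAGES},
        rem_latency_epochs=0,
        rem_exit_wake_bias=0.0,
        phasic_late_bias=False,
        **kw,
    )


class TestSimulateHypnogram:
    def test_deterministic_cycle_with_unit_dwell(self):
        cfg = cyclic_config()
        h, _ = simulate_hypnogram(cfg, 7)
        # geometric dwell with mean 1 is always exactly 1 epoch
        expect = [STAGES[i % 5] for i in range(60)]
        assert list(h.epoch_stages) == expect

    def test_absorbing_substate_stays_phasic_free(self):
        # identity substate transition starting tonic -> all REM TRs tonic
        cfg = cyclic_config(
            rem_substate_transition=np.array([[1.0, 0.0], [0.0, 1.0]])
        )
        h, sub = simulate_hypnogram(cfg, 3)
        rem_subs = {sub[t] for t, s in enumerate(h.tr_stages) if s == "REM"}
        assert rem_subs == {TONIC}

    def test_substates_nonnull_exactly_on_rem(self):
        cfg = scaled_config(1, 1200, 5)
        h, sub = simulate_hypnogram(cfg, participant_seed(5, 0))
        for t, s in enumerate(h.tr_stages):
            assert (sub[t] is not None) == (s == "REM")

    def test_rem_latency_respected(self):
        cfg = GeneratorConfig(night_trs=3200, rem_latency_epochs=50)
        h, _ = simulate_hypnogram(cfg, 11)
        assert "REM" not in h.epoch_stages[:50]

    def test_empirical_dwell_means_match_config(self):
        cfg = GeneratorConfig(night_trs=100_000, rem_latency_epochs=0)
        h, _ = simulate_hypnogram(cfg, 19)
        runs = collections.defaultdict(list)
        stages = h.epoch_stages
        i = 0
        while i < len(stages):
            j = i
            while j < len(stages) and stages[j] == stages[i]:
                j += 1
            runs[stages[i]].append(j - i)
            i = j
        for s, mean in cfg.stage_mean_dwell_epochs.items():
            if len(runs[s]) > 100:
                emp = np.mean(runs[s])
                assert emp == pytest.approx(mean, rel=0.12), s

    def test_absorbing_stage_rejected(self):
        trans = np.eye(5)
        with pytest.raises(ValueError, match="absorbing"):
            GeneratorConfig(stage_transition=trans)


class TestBuildStateCovariance:
    def test_zero_coupling_gives_identity(self, tiny_atlas):
        c = build_state_covariance(
            tiny_atlas, Coupling(r_within=0, r_between=0, r_thal=0,
                                 r_thal_sens=0)
        )
        np.testing.assert_allclose(c, np.eye(tiny_atlas.n_rois), atol=1e-12)

    def test_within_network_blocks(self):
        import pandas as pd

        from somnidyn.io_atlas import AtlasMap

        df = pd.DataFrame(
            {"roi_label": list("abcd"),
             "network": ["AUD", "AUD", "VIS", "VIS"],
             "role": ["cortical"] * 4}
        )
        c = build_state_covariance(
            AtlasMap(df), Coupling(r_within=0.5, r_between=0, r_thal=0,
                                   r_thal_sens=0)
        )
        block = np.array([[1, 0.5], [0.5, 1]])
        np.testing.assert_allclose(c[:2, :2], block)
        np.testing.assert_allclose(c[2:, 2:], block)
        np.testing.assert_allclose(c[:2, 2:], 0)

    def test_rem_vs_wake_intra_thalamic_difference(self, tiny_atlas):
        wake = build_state_covariance(tiny_atlas, Coupling(r_thal=0.1))
        rem = build_state_covariance(tiny_atlas, Coupling(r_thal=0.5))
        roles = tiny_atlas.table["role"] == "thalamic"
        nets = tiny_atlas.table["network"]
        idx = np.flatnonzero(roles)
        pairs = [
            (i, j)
            for i in idx
            for j in idx
            if i < j and nets.iloc[i] != nets.iloc[j]
        ]
        d_mean = np.mean([rem[i, j] - wake[i, j] for i, j in pairs])
        assert d_mean == pytest.approx(0.4, abs=0.02)

    def test_all_covariances_pd(self, bundled_atlas):
        for cond, cov in condition_covariances(
            bundled_atlas, GeneratorConfig()
        ).items():
            assert np.linalg.eigvalsh(cov).min() > 0, cond

    def test_infeasible_coupling_rejected(self, bundled_atlas):
        with pytest.raises(ValueError, match="infeasible"):
            build_state_covariance(
                bundled_atlas,
                Coupling(r_within=0.9, r_between=-0.3, r_thal=0.9,
                         r_thal_sens=0.9),
            )


class TestSimulateBold:
    def test_empirical_correlation_recovers_truth(self, tiny_atlas):
        cfg = cyclic_config(ar_coef=0.0, noise_sd=0.0, night_trs=600)
        cov = build_state_covariance(tiny_atlas, Coupling(r_thal=0.4))
        covs = {c: cov for c in ("Wake", "N1", "N2", "N3", PHASIC, TONIC)}
        h, sub = simulate_hypnogram(cfg, 1)
        # single condition everywhere: repeat hypnogram long
        rng = np.random.default_rng(0)
        from somnidyn.io_atlas import Hypnogram, resample_hypnogram_to_tr

        h_long = resample_hypnogram_to_tr(Hypnogram(("N2",) * 5000), 3.0)
        x = simulate_bold(h_long, np.full(50_000, None), covs,
                          cfg, rng)
        emp = np.corrcoef(x, rowvar=False)
        assert np.abs(emp - cov).max() < 0.02

    def test_null_covariance_gives_independent_rois(self, tiny_atlas):
        from somnidyn.io_atlas import Hypnogram, resample_hypnogram_to_tr

        cfg = cyclic_config(ar_coef=0.0, noise_sd=0.0)
        eye = np.eye(tiny_atlas.n_rois)
        covs = {c: eye for c in ("Wake", "N1", "N2", "N3", PHASIC, TONIC)}
        h_long = resample_hypnogram_to_tr(Hypnogram(("N3",) * 2000), 3.0)
        x = simulate_bold(h_long, np.full(20_000, None), covs,
                          np.random.default_rng(3) and cfg,
                          np.random.default_rng(3))
        emp = np.corrcoef(x, rowvar=False)
        off = emp[np.triu_indices_from(emp, 1)]
        assert np.abs(off).max() < 3.5 / np.sqrt(20_000)

    def test_ar_marginal_variance_is_stationary(self, tiny_atlas):
        from somnidyn.io_atlas import Hypnogram, resample_hypnogram_to_tr

        cfg = cyclic_config(ar_coef=0.8, noise_sd=0.0)
        cov = build_state_covariance(tiny_atlas, Coupling())
        covs = {c: cov for c in ("Wake", "N1", "N2", "N3", PHASIC, TONIC)}
        h_long = resample_hypnogram_to_tr(Hypnogram(("N2",) * 3000), 3.0)
        x = simulate_bold(h_long, np.full(30_000, None), covs, cfg,
                          np.random.default_rng(4))
        # stationary covariance of the AR(1) part equals the condition cov
        emp = np.cov(x, rowvar=False)
        assert np.abs(emp - cov).max() < 0.05

    def test_missing_condition_covariance_rejected(self, tiny_atlas):
        cfg = cyclic_config()
        h, sub = simulate_hypnogram(cfg, 1)
        with pytest.raises(ValueError, match="no covariance"):
            simulate_bold(h, sub, {"Wake": np.eye(tiny_atlas.n_rois)}, cfg,
                          np.random.default_rng(0))

    def test_deterministic_given_seed(self, tiny_atlas):
        cfg = scaled_config(1, 600, 9)
        a = simulate_night(cfg, tiny_atlas, 0)
        b = simulate_night(cfg, tiny_atlas, 0)
        np.testing.assert_array_equal(a.timeseries.data, b.timeseries.data)
        np.testing.assert_array_equal(a.timeseries.censor, b.timeseries.censor)
        assert a.hypnogram.epoch_stages == b.hypnogram.epoch_stages


class TestSimulateCensoring:
    def _h(self, n, stage="N2"):
        from somnidyn.io_atlas import Hypnogram, resample_hypnogram_to_tr

        return resample_hypnogram_to_tr(Hypnogram((stage,) * n), 3.0)

    def test_zero_rate_keeps_everything(self):
        cfg = GeneratorConfig(
            censor_rate_per_stage={s: 0.0 for s in STAGES}
        )
        mask = simulate_censoring(self._h(100), cfg, np.random.default_rng(0))
        assert mask.all()

    def test_rate_one_censors_stage_completely(self):
        cfg = GeneratorConfig(
            censor_rate_per_stage={"Wake": 1.0, "N1": 0, "N2": 0, "N3": 0,
                                   "REM": 0}
        )
        mask = simulate_censoring(self._h(50, "Wake"), cfg,
                                  np.random.default_rng(0))
        assert not mask.any()

    def test_empirical_rate_concentrates(self):
        cfg = GeneratorConfig(
            censor_rate_per_stage={s: 0.1 for s in STAGES}
        )
        mask = simulate_censoring(self._h(1000), cfg,
                                  np.random.default_rng(1))
        assert (1 - mask.mean()) == pytest.approx(0.1, abs=0.01)


class TestDatasetRoundTrip:
    def test_write_then_read_equals_generated(self, tiny_atlas, tmp_path):
        from somnidyn.io_atlas import read_censor_mask, read_hypnogram, \
            read_roi_timeseries

        cfg = scaled_config(2, 600, 21)
        nights, truth = simulate_dataset(cfg, tiny_atlas)
        write_dataset(nights, truth, tmp_path)
        files = sorted(p.name for p in (tmp_path / "sub-01").iterdir())
        assert files == ["bold.tsv", "censor.tsv", "hypnogram.tsv",
                         "substates.tsv"]
        for pid, rec in nights.items():
            ts = read_roi_timeseries(tmp_path / pid / "bold.tsv",
                                     censor_path=tmp_path / pid / "censor.tsv")
            np.testing.assert_array_equal(ts.data, rec.timeseries.data)
            np.testing.assert_array_equal(ts.censor, rec.timeseries.censor)
            h = read_hypnogram(tmp_path / pid / "hypnogram.tsv")
            assert h.epoch_stages == rec.hypnogram.epoch_stages
        truth_blob = (tmp_path / "truth.json").read_text()
        assert "observed_covariances" in truth_blob

    def test_monotone_coupling_warning(self, tiny_atlas):
        coupling = default_coupling()
        coupling[PHASIC] = Coupling(r_thal=0.05)  # below Wake
        with pytest.warns(UserWarning, match="monotone"):
            GeneratorConfig(coupling=coupling)
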