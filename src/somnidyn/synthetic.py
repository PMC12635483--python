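"""Synthetic whole-night dataset generator with exported ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline is verifiable without access to
real recordings:

* a semi-Markov hypnogram per participant at 30-s epoch resolution (geometric
  stage dwells, no self-transitions, configurable REM latency), with a
  phasic/tonic REM sub-state chain at TR (3 s) resolution;
* condition-specific ROI covariance built from four block-coupling parameters
  (within-network, between-network, intra-thalamic, thalamo-sensory), with
  REM — and phasic REM in particular — elevating intra-thalamic and
  thalamo-sensory coupling;
* AR(1)-smoothed Gaussian signals whose stationary covariance matches the
  condition covariance inside long same-condition segments, plus iid
  measurement noise;
* stage-dependent Bernoulli motion censoring (more censoring in Wake, less in
  deep sleep).

Two default-on mechanisms shape the REM sub-states the way the substate
identification step expects real data to look: REM episodes that end while in
the tonic sub-state preferentially exit to Wake (tonic borders arousal), and
the tonic→phasic entry probability grows linearly with time of night, placing
phasic REM later in the night.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_atlas import (
    SENSORY_NETWORKS,
    STAGES,
    AtlasMap,
    Hypnogram,
    RoiTimeSeries,
    resample_hypnogram_to_tr,
    write_censor_mask,
    write_hypnogram,
    write_roi_timeseries,
)

PHASIC = "phasic"
TONIC = "tonic"

#: Conditions a covariance must exist for: the four non-REM stages plus the
#: two REM sub-states (REM TRs take the sub-state's covariance).
CONDITIONS: tuple[str, ...] = ("Wake", "N1", "N2", "N3", PHASIC, TONIC)


@dataclass(frozen=True)
class Coupling:
    """Block-coupling parameters of one condition's correlation matrix."""

    r_within: float = 0.5
    r_between: float = 0.1
    r_thal: float = 0.1
    r_thal_sens: float = 0.1


def default_coupling() -> dict[str, Coupling]:
    """Default per-condition coupling: intra-thalamic and thalamo-sensory
    correlations rise monotonically Wake < NREM < tonic < phasic."""
    return {
        "Wake": Coupling(r_thal=0.10, r_thal_sens=0.10),
        "N1": Coupling(r_thal=0.15, r_thal_sens=0.15),
        "N2": Coupling(r_thal=0.20, r_thal_sens=0.20),
        "N3": Coupling(r_thal=0.20, r_thal_sens=0.15),
        TONIC: Coupling(r_thal=0.35, r_thal_sens=0.30),
        PHASIC: Coupling(r_thal=0.50, r_thal_sens=0.35),
    }


def default_stage_transition() -> np.ndarray:
    """Epoch-level next-stage probabilities (rows: Wake,N1,N2,N3,REM; zero
    diagonal — dwell is drawn separately)."""
    return np.array(
        [
            [0.00, 0.80, 0.15, 0.00, 0.05],  # Wake
            [0.25, 0.00, 0.65, 0.05, 0.05],  # N1
            [0.10, 0.15, 0.00, 0.45, 0.30],  # N2
            [0.05, 0.05, 0.70, 0.00, 0.20],  # N3
            [0.35, 0.25, 0.40, 0.00, 0.00],  # REM
        ]
    )


@dataclass
class GeneratorConfig:
    """All knobs of the whole-night generator; defaults are the study
    conditions every test and the acceptance run use."""

    n_participants: int = 12
    night_trs: int = 3200
    tr_seconds: float = 3.0
    epoch_seconds: float = 30.0
    stage_transition: np.ndarray = field(default_factory=default_stage_transition)
    stage_mean_dwell_epochs: dict[str, float] = field(
        default_factory=lambda: {"Wake": 8.0, "N1": 3.0, "N2": 16.0,
                                 "N3": 12.0, "REM": 16.0}
    )
    initial_stage: str = "Wake"
    rem_latency_epochs: int = 30
    rem_substate_transition: np.ndarray = field(
        # rows/cols ordered (phasic, tonic), per-TR; sticky, so sub-states
        # form contiguous minutes-scale segments rather than brief flickers
        default_factory=lambda: np.array([[0.98, 0.02], [0.01, 0.99]])
    )
    phasic_late_bias: bool = True
    rem_exit_wake_bias: float = 0.8
    coupling: dict[str, Coupling] = field(default_factory=default_coupling)
    ar_coef: float = 0.5
    noise_sd: float = 0.2
    censor_rate_per_stage: dict[str, float] = field(
        default_factory=lambda: {"Wake": 0.04, "N1": 0.03, "N2": 0.015,
                                 "N3": 0.01, "REM": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_transition = np.asarray(self.stage_transition, dtype=float)
        self.rem_substate_transition = np.asarray(
            self.rem_substate_transition, dtype=float
        )
        self.validate()

    @property
    def trs_per_epoch(self) -> int:
        ratio = self.epoch_seconds / self.tr_seconds
        n = round(ratio)
        if abs(ratio - n) > 1e-9:
            raise ValueError("epoch_seconds must be divisible by tr_seconds")
        return n

    @property
    def n_epochs(self) -> int:
        if self.night_trs % self.trs_per_epoch:
            raise ValueError("night_trs must be a whole number of epochs")
        return self.night_trs // self.trs_per_epoch

    def validate(self) -> None:
        a = self.stage_transition
        if a.shape != (5, 5):
            raise ValueError("stage_transition must be 5x5 over (Wake,N1,N2,N3,REM)")
        if np.any(np.abs(a.sum(axis=1) - 1) > 1e-12):
            raise ValueError("stage_transition rows must sum to 1")
        if np.any(a < 0):
            raise ValueError("stage_transition entries must be nonnegative")
        off = a - np.diag(np.diag(a))
        if np.any(off.sum(axis=1) <= 0):
            bad = STAGES[int(np.flatnonzero(off.sum(axis=1) <= 0)[0])]
            raise ValueError(f"absorbing stage in transition matrix: {bad}")
        s = self.rem_substate_transition
        if s.shape != (2, 2) or np.any(np.abs(s.sum(axis=1) - 1) > 1e-12):
            raise ValueError("rem_substate_transition must be 2x2 stochastic")
        if any(d < 1 for d in self.stage_mean_dwell_epochs.values()):
            raise ValueError("stage dwell means must be >= 1 epoch")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        c = self.coupling
        if all(k in c for k in ("Wake", TONIC, PHASIC)):
            if not (
                c[PHASIC].r_thal >= c[TONIC].r_thal >= c["Wake"].r_thal
            ):
                warnings.warn(
                    "coupling r_thal is not monotone phasic >= tonic >= Wake; "
                    "directional analyses will not match the intended ordering",
                    stacklevel=2,
                )


def scaled_config(
    n_participants: int, night_trs: int, seed: int, **overrides
) -> GeneratorConfig:
    """GeneratorConfig for a time-compressed night.

    The default dwell means and 30-epoch REM-latency constraint belong to the
    default 320-epoch night; when the night is shortened they scale
    proportionally (dwell floor 1 epoch), so the compressed night keeps the
    full night's stage composition and number of sleep cycles rather than its
    bout durations.
    """
    base = GeneratorConfig()
    frac = (night_trs / base.trs_per_epoch) / base.n_epochs
    latency = int(round(base.rem_latency_epochs * frac))
    dwells = {
        s: max(1.0, d * frac) for s, d in base.stage_mean_dwell_epochs.items()
    }
    return GeneratorConfig(
        n_participants=n_participants,
        night_trs=night_trs,
        rem_latency_epochs=latency,
        stage_mean_dwell_epochs=dwells,
        seed=seed,
        **overrides,
    )


@dataclass
class GroundTruth:
    """Everything the generator knows: per-participant hypnograms and
    sub-state paths, per-condition latent and observation covariances, and
    the full configuration."""

    hypnograms: dict[str, Hypnogram]
    substate_paths: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    observed_covariances: dict[str, np.ndarray]
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Hypnogram + substates
# ---------------------------------------------------------------------------


def _draw_next_stage(
    rng: np.random.Generator,
    row: np.ndarray,
    forbid: set[int],
) -> int:
    p = row.copy()
    p[list(forbid)] = 0.0
    if p.sum() <= 0:  # everything forbidden: fall back to Wake
        return 0
    return int(rng.choice(5, p=p / p.sum()))


def simulate_hypnogram(
    config: GeneratorConfig, participant_seed: int
) -> tuple[Hypnogram, np.ndarray]:
    """Simulate one night's hypnogram and per-TR REM sub-state path.

    Stages follow a semi-Markov chain at epoch resolution: a geometric dwell
    with the stage-specific mean, then a transition drawn from
    ``stage_transition`` with self-transitions forbidden.  REM is disallowed
    during the first ``rem_latency_epochs`` epochs.  Within REM, a
    phasic/tonic chain runs at TR resolution (entering REM in tonic).

    Returns the hypnogram (with ``tr_stages`` filled) and an object array of
    length ``night_trs`` that is 'phasic'/'tonic' on REM TRs and None
    elsewhere.
    """
    rng = np.random.default_rng(participant_seed)
    n_epochs = config.n_epochs
    tpe = config.trs_per_epoch
    night_trs = config.night_trs
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    trans = config.stage_transition

    epochs: list[str] = []
    substates = np.full(night_trs, None, dtype=object)
    cur = config.initial_stage
    sub = TONIC  # sub-state carried across consecutive REM epochs
    e = 0
    while e < n_epochs:
        mean_dwell = config.stage_mean_dwell_epochs[cur]
        dwell = int(rng.geometric(1.0 / mean_dwell))
        dwell = min(dwell, n_epochs - e)
        if cur != "REM":
            sub = TONIC  # REM always (re)entered in tonic
        for _ in range(dwell):
            epochs.append(cur)
            if cur == "REM":
                base = e * tpe
                for t in range(tpe):
                    substates[base + t] = sub
                    p_row = config.rem_substate_transition[0 if sub == PHASIC else 1]
                    p_to_phasic = p_row[0]
                    if sub == TONIC and config.phasic_late_bias:
                        # cubic ramp in normalized night time: phasic entry is
                        # negligible early and concentrated in the final third
                        # (mean entry rate over the night is preserved)
                        frac = (base + t) / night_trs
                        p_to_phasic = min(1.0, p_to_phasic * 4.0 * frac**3)
                    sub = PHASIC if rng.random() < p_to_phasic else TONIC
            e += 1
        if e >= n_epochs:
            break
        forbid = {stage_idx[cur]}
        if e < config.rem_latency_epochs:
            forbid.add(stage_idx["REM"])
        row = trans[stage_idx[cur]]
        if cur == "REM" and config.rem_exit_wake_bias:
            # tonic borders arousal: tonic-ending episodes preferentially
            # exit to Wake, phasic-ending episodes never do — this is the
            # inflated tonic-to-Wake transition mass the sub-state
            # identification relies on
            if substates[e * tpe - 1] == TONIC and (
                rng.random() < config.rem_exit_wake_bias
            ):
                nxt = stage_idx["Wake"]
            else:
                forbid_w = forbid | (
                    {stage_idx["Wake"]}
                    if substates[e * tpe - 1] == PHASIC
                    else set()
                )
                nxt = _draw_next_stage(rng, row, forbid_w)
        else:
            nxt = _draw_next_stage(rng, row, forbid)
        cur = STAGES[nxt]

    h = Hypnogram(tuple(epochs), config.epoch_seconds)
    h = resample_hypnogram_to_tr(h, config.tr_seconds)
    return h, substates


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------


def build_state_covariance(
    atlas: AtlasMap, coupling: Coupling, pd_tol: float = 0.05
) -> np.ndarray:
    """Block-structured unit-variance covariance for one condition.

    Entries: ``r_within`` for ROI pairs in the same network, ``r_between``
    otherwise, overridden by ``r_thal`` for pairs of thalamic ROIs in
    different subnetworks and by ``r_thal_sens`` for thalamic × sensory-
    cortical pairs.  Positive definiteness is enforced by an eigenvalue floor
    (1e-6) followed by re-scaling to unit diagonal; if that projection moves
    any entry by more than ``pd_tol`` the requested correlations are declared
    infeasible.
    """
    for v in (coupling.r_within, coupling.r_between, coupling.r_thal,
              coupling.r_thal_sens):
        if not -1 < v < 1:
            raise ValueError("coupling correlations must lie in (-1, 1)")
    nets = np.asarray(atlas.table["network"])
    roles = np.asarray(atlas.table["role"])
    r = atlas.n_rois
    c = np.full((r, r), coupling.r_between, dtype=float)
    same = nets[:, None] == nets[None, :]
    c[same] = coupling.r_within
    thal = roles == "thalamic"
    thal_pair = thal[:, None] & thal[None, :] & ~same
    c[thal_pair] = coupling.r_thal
    sensory = np.isin(nets, SENSORY_NETWORKS) & (roles == "cortical")
    ts_pair = (thal[:, None] & sensory[None, :]) | (sensory[:, None] & thal[None, :])
    c[ts_pair] = coupling.r_thal_sens
    np.fill_diagonal(c, 1.0)

    w, v = np.linalg.eigh(c)
    if w.min() < 1e-6:
        w2 = np.maximum(w, 1e-6)
        c2 = (v * w2) @ v.T
        d = np.sqrt(np.diag(c2))
        c2 = c2 / np.outer(d, d)
        distortion = float(np.abs(c2 - c).max())
        if distortion > pd_tol:
            raise ValueError(
                f"requested correlations infeasible: nearest-PD projection "
                f"distorts entries by up to {distortion:.3f} (> {pd_tol})"
            )
        c = (c2 + c2.T) / 2.0
        np.fill_diagonal(c, 1.0)
    return c


def condition_covariances(
    atlas: AtlasMap, config: GeneratorConfig
) -> dict[str, np.ndarray]:
    """Latent covariance for every condition in ``config.coupling``."""
    return {
        cond: build_state_covariance(atlas, cpl)
        for cond, cpl in config.coupling.items()
    }


# ---------------------------------------------------------------------------
# BOLD + censoring
# ---------------------------------------------------------------------------


def _tr_conditions(h: Hypnogram, substates: np.ndarray) -> list[str | None]:
    conds: list[str | None] = []
    for t, stage in enumerate(h.tr_stages):
        if stage == "REM":
            conds.append(substates[t])
        elif stage in STAGES:
            conds.append(stage)
        else:  # Unscored
            conds.append(None)
    return conds


def simulate_bold(
    h: Hypnogram,
    substates: np.ndarray,
    covariances: dict[str, np.ndarray],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1) Gaussian signal with condition-specific innovation covariance.

    x_t = a·x_{t-1} + sqrt(1-a²)·e_t with e_t ~ N(0, Σ_cond(t)); the output
    adds iid N(0, noise_sd²) measurement noise.  Within long same-condition
    segments the stationary covariance of the AR part equals Σ_cond.
    Unscored TRs reuse the Wake covariance (they are excluded from analysis
    anyway).
    """
    conds = _tr_conditions(h, substates)
    used = {c for c in conds if c is not None}
    missing = used - set(covariances)
    if missing:
        raise ValueError(f"no covariance supplied for conditions: {sorted(missing)}")
    t_total = len(conds)
    d = next(iter(covariances.values())).shape[0]
    chol = {c: np.linalg.cholesky(s) for c, s in covariances.items()}
    fallback = chol.get("Wake", next(iter(chol.values())))
    a = config.ar_coef
    scale = np.sqrt(1.0 - a * a)
    x = np.empty((t_total, d))
    innov = rng.standard_normal((t_total, d))
    l0 = chol.get(conds[0], fallback) if conds[0] else fallback
    x[0] = l0 @ innov[0]
    for t in range(1, t_total):
        lt = chol[conds[t]] if conds[t] is not None else fallback
        x[t] = a * x[t - 1] + scale * (lt @ innov[t])
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal((t_total, d))
    return x


def simulate_censoring(
    h: Hypnogram, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-TR usable-frame mask: each TR censored independently with its
    stage's rate (True = usable)."""
    rates = np.array(
        [config.censor_rate_per_stage.get(s, 0.0) for s in h.tr_stages]
    )
    return rng.random(len(rates)) >= rates


# ---------------------------------------------------------------------------
# Whole dataset
# ---------------------------------------------------------------------------


@dataclass
class NightRecording:
    timeseries: RoiTimeSeries
    hypnogram: Hypnogram
    substates: np.ndarray


def participant_seed(config_seed: int, index: int) -> int:
    """Stable per-participant seed derived from the dataset seed."""
    return int(
        np.random.SeedSequence([config_seed, index]).generate_state(1)[0] % (2**31)
    )


def simulate_night(
    config: GeneratorConfig, atlas: AtlasMap, index: int,
    covariances: dict[str, np.ndarray] | None = None,
) -> NightRecording:
    """Simulate one participant's night (deterministic given config.seed)."""
    seed = participant_seed(config.seed, index)
    rng = np.random.default_rng(seed)
    h, substates = simulate_hypnogram(config, seed)
    covs = covariances if covariances is not None else condition_covariances(atlas, config)
    bold = simulate_bold(h, substates, covs, config, rng)
    censor = simulate_censoring(h, config, rng)
    ts = RoiTimeSeries(
        data=bold,
        roi_labels=atlas.roi_labels,
        tr_seconds=config.tr_seconds,
        censor=censor,
        participant_id=f"sub-{index + 1:02d}",
        run_id="run-01",
        run_onset_seconds=0.0,
    )
    return NightRecording(ts, h, substates)


def simulate_dataset(
    config: GeneratorConfig, atlas: AtlasMap
) -> tuple[dict[str, NightRecording], GroundTruth]:
    """Simulate all participants and assemble the ground truth bundle."""
    covs = condition_covariances(atlas, config)
    d = atlas.n_rois
    observed = {c: s + config.noise_sd**2 * np.eye(d) for c, s in covs.items()}
    nights: dict[str, NightRecording] = {}
    for i in range(config.n_participants):
        rec = simulate_night(config, atlas, i, covariances=covs)
        nights[rec.timeseries.participant_id] = rec
    truth = GroundTruth(
        hypnograms={p: rec.hypnogram for p, rec in nights.items()},
        substate_paths={p: rec.substates for p, rec in nights.items()},
        covariances=covs,
        observed_covariances=observed,
        config=config,
    )
    return nights, truth


def write_dataset(
    nights: dict[str, NightRecording], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write per-participant TSVs plus a ground-truth JSON, re-readable by
    the io layer."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, rec in nights.items():
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        write_roi_timeseries(rec.timeseries, pdir / "bold.tsv")
        write_censor_mask(rec.timeseries.censor, pdir / "censor.tsv")
        write_hypnogram(rec.hypnogram, pdir / "hypnogram.tsv")
        with open(pdir / "substates.tsv", "w") as f:
            f.write("tr\tsubstate\n")
            for t, s in enumerate(rec.substates):
                f.write(f"{t}\t{s if s is not None else 'none'}\n")
    cfg = asdict(truth.config)
    cfg["stage_transition"] = truth.config.stage_transition.tolist()
    cfg["rem_substate_transition"] = truth.config.rem_substate_transition.tolist()
    cfg["coupling"] = {k: asdict(v) for k, v in truth.config.coupling.items()}
    blob = {
        "config": cfg,
        "covariances": {k: v.tolist() for k, v in truth.covariances.items()},
        "observed_covariances": {
            k: v.tolist() for k, v in truth.observed_covariances.items()
        },
        "participants": sorted(nights),
    }
    with open(out / "truth.json", "w") as f:
        json.dump(blob, f, indent=1)
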