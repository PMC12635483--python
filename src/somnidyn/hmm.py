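"""Maximum-likelihood Gaussian hidden Markov model over multivariate BOLD.

Brain states are modelled as a K-state HMM with full-covariance Gaussian
emissions, fitted by Baum-Welch EM with scaled forward-backward recursions
over the concatenated usable segments of all runs (runs are split at
censoring gaps; no transitions are carried across a gap — each segment
re-enters through the initial distribution).  Decoding uses exact Viterbi in
log space and posteriors from the same scaled forward-backward pass.

States are mapped to sleep stages by winner-take-all against the per-TR
hypnogram, and the two REM sub-states are identified from the fitted
transition structure (tonic REM = largest transition mass into Wake-labelled
states) and timing (phasic REM = latest mean normalized time of night).

This is a maximum-likelihood reimplementation, not a variational-Bayesian
observation model; only the state decomposition and transition structure are
consumed downstream, which the ML fit provides equally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from .dfc import NetworkAggregator, fisher_z, intra_thalamic_connection
from .io_atlas import STAGES, UNSCORED, AtlasMap, RoiTimeSeries

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def standardize(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Per-run, per-ROI z-scoring over usable frames.

    A zero-variance ROI is an error (it cannot carry FC information and
    breaks the Gaussian model).
    """
    usable = ts.data[ts.censor]
    mu = usable.mean(axis=0)
    sd = usable.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = ts.roi_labels[int(np.flatnonzero(sd <= 0)[0])]
        raise ValueError(f"ROI {bad!r} has zero variance over usable frames")
    return ts.copy_with(data=(ts.data - mu) / sd)


def prewhiten(ts: RoiTimeSeries) -> tuple[RoiTimeSeries, float]:
    """Remove the lag-1 autoregressive component from a run.

    A single AR(1) coefficient is estimated per run (pooled over ROIs and
    usable segments) and the innovation series x_t − â·x_{t−1} is returned;
    the first frame of every usable segment, which has no predecessor, is
    marked censored.  With AR(1)-smoothed signals the innovations are
    serially independent within a condition, which is what the iid-emission
    Gaussian HMM assumes; without this step the likelihood rewards states
    that absorb autocorrelation instead of connectivity structure.

    Returns the whitened run and the estimated coefficient.
    """
    x = ts.data
    segs = usable_segments([ts])
    num = den = 0.0
    for _, s, e in segs:
        if e - s > 2:
            num += float((x[s + 1 : e] * x[s : e - 1]).sum())
            den += float((x[s : e - 1] ** 2).sum())
    a = num / den if den > 0 else 0.0
    y = x.copy()
    censor = ts.censor.copy()
    for _, s, e in segs:
        y[s + 1 : e] = x[s + 1 : e] - a * x[s : e - 1]
        censor[s] = False
    return ts.copy_with(data=y, censor=censor), a


def pca_project(
    runs: list[RoiTimeSeries], n_components: int
) -> tuple[list[RoiTimeSeries], np.ndarray, np.ndarray]:
    """Project runs onto the leading principal components of the pooled
    usable frames.  Returns (projected runs, component matrix d×R, mean).

    Fitting the HMM in a reduced space shrinks each state's covariance from
    R(R+1)/2 to d(d+1)/2 free parameters, which curbs the tendency of
    full-covariance maximum likelihood to spend states on sampling noise.
    State covariances fitted in this space are not comparable to ROI-space
    FC; per-state FC must then be computed from the decoded frames.
    """
    x = np.concatenate([ts.data[ts.censor] for ts in runs])
    mu = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - mu, full_matrices=False)
    w = vt[:n_components]
    labels = [f"pc{i}" for i in range(n_components)]
    out = [
        ts.copy_with(data=(ts.data - mu) @ w.T, roi_labels=labels)
        for ts in runs
    ]
    return out, w, mu


def empirical_state_fc(
    runs: list[RoiTimeSeries], path: "StatePath", n_states: int,
    atlas, min_frames: int = 40,
):
    """Per-state network FC from the Viterbi-assigned frames themselves.

    For each state the ROI correlation over all its decoded frames (pooled
    across runs) is Fisher-transformed and aggregated to networks; states
    with fewer than ``min_frames`` frames yield None.  Also returns the
    relative matrices (state minus across-state mean) and the per-state
    intra-thalamic connection (NaN where undefined).
    """
    from .dfc import NetworkAggregator, intra_thalamic_connection, window_roi_fc

    agg = NetworkAggregator(atlas)
    mats = []
    for k in range(n_states):
        frames = [ts.data[st == k] for ts, st in zip(runs, path.states)]
        f = np.concatenate(frames)
        if len(f) < min_frames:
            mats.append(None)
            continue
        z = window_roi_fc(f)
        np.fill_diagonal(z, 0.0)
        mats.append(agg.aggregate(z))
    defined = [m.values for m in mats if m is not None]
    mean_vals = np.mean(defined, axis=0) if defined else None
    relative = [
        None if m is None else type(m)(m.networks, m.values - mean_vals)
        for m in mats
    ]
    intra = np.full(n_states, np.nan)
    for k, m in enumerate(mats):
        if m is not None:
            try:
                intra[k] = intra_thalamic_connection(m)
            except ValueError:
                pass
    return mats, relative, intra


def usable_segments(runs: list[RoiTimeSeries]) -> list[tuple[int, int, int]]:
    """Contiguous usable-frame segments as (run_index, start_tr, end_tr)."""
    segs = []
    for ri, ts in enumerate(runs):
        c = ts.censor
        t = 0
        while t < len(c):
            if c[t]:
                s = t
                while t < len(c) and c[t]:
                    t += 1
                segs.append((ri, s, t))
            else:
                t += 1
    return segs


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class HmmModel:
    """Fitted Gaussian HMM parameters plus fit metadata."""

    means: np.ndarray               # K x D
    covariances: np.ndarray         # K x D x D
    transition: np.ndarray          # K x K row-stochastic
    initial: np.ndarray             # length K simplex
    loglik_trace: list[float] = field(default_factory=list)
    restart_final_logliks: list[float] = field(default_factory=list)
    seed: int = 0
    restarts: int = 1
    tol: float = 1e-5
    reg: float = 1e-4

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        k = self.n_states
        if np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-10):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1) > 1e-10:
            raise ValueError("initial distribution must sum to 1")
        for j in range(k):
            w = np.linalg.eigvalsh(self.covariances[j])
            if w.min() <= 0:
                raise ValueError(f"state {j} covariance is not positive definite")

    def to_json(self, path: str | Path) -> None:
        blob = {
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "loglik_trace": list(map(float, self.loglik_trace)),
            "restart_final_logliks": list(map(float, self.restart_final_logliks)),
            "seed": self.seed,
            "restarts": self.restarts,
            "tol": self.tol,
            "reg": self.reg,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            means=np.array(blob["means"]),
            covariances=np.array(blob["covariances"]),
            transition=np.array(blob["transition"]),
            initial=np.array(blob["initial"]),
            loglik_trace=blob["loglik_trace"],
            restart_final_logliks=blob["restart_final_logliks"],
            seed=blob["seed"],
            restarts=blob["restarts"],
            tol=blob["tol"],
            reg=blob["reg"],
        )


# ---------------------------------------------------------------------------
# Gaussian log densities
# ---------------------------------------------------------------------------


def _state_log_densities(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """log N(x_t | mu_k, Sigma_k) for all t, k — via Cholesky solves."""
    t, d = x.shape
    k = means.shape[0]
    out = np.empty((t, k))
    for j in range(k):
        chol = np.linalg.cholesky(covs[j])
        diff = x - means[j]
        y = solve_triangular(chol, diff.T, lower=True)
        maha = np.einsum("ij,ij->j", y, y)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, j] = -0.5 * (d * _LOG2PI + logdet + maha)
    return out


# ---------------------------------------------------------------------------
# Forward-backward / EM
# ---------------------------------------------------------------------------


def _forward_backward(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward for one segment.

    Returns (loglik, gamma T×K, xi_sum K×K, gamma_0).
    """
    t, k = logb.shape
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])
    alpha = np.empty((t, k))
    c = np.empty(t)
    a0 = initial * b[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for s in range(1, t):
        a = (alpha[s - 1] @ transition) * b[s]
        c[s] = a.sum()
        alpha[s] = a / c[s]
    loglik = float(np.log(c).sum() + shift.sum())

    beta = np.empty((t, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for s in range(t - 2, -1, -1):
        bb = b[s + 1] * beta[s + 1]
        beta[s] = (transition @ bb) / c[s + 1]
        xi_sum += (alpha[s][:, None] * transition * bb[None, :]) / c[s + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma, xi_sum, gamma[0]


def _em_once(
    x: np.ndarray,
    seg_slices: list[slice],
    means: np.ndarray,
    covs: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
    reg: float,
    diagonal: bool,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM iteration over all segments; returns loglik of the *input*
    parameters and the updated parameters."""
    k, d = means.shape
    logb = _state_log_densities(x, means, covs)
    total_ll = 0.0
    gamma_all = np.empty((x.shape[0], k))
    xi_total = np.zeros((k, k))
    g0_total = np.zeros(k)
    for sl in seg_slices:
        ll, gamma, xi, g0 = _forward_backward(logb[sl], transition, initial)
        total_ll += ll
        gamma_all[sl] = gamma
        xi_total += xi
        g0_total += g0

    new_initial = g0_total / g0_total.sum()
    rows = xi_total.sum(axis=1, keepdims=True)
    new_transition = np.where(rows > 0, xi_total / np.where(rows > 0, rows, 1),
                              1.0 / k)
    nk = gamma_all.sum(axis=0)
    new_means = (gamma_all.T @ x) / nk[:, None]
    new_covs = np.empty((k, d, d))
    for j in range(k):
        diff = x - new_means[j]
        cov = (gamma_all[:, j][:, None] * diff).T @ diff / nk[j]
        if diagonal:
            cov = np.diag(np.diag(cov))
        new_covs[j] = cov + reg * np.eye(d)
    return total_ll, new_means, new_covs, new_transition, new_initial


def _init_frame_labels(
    x: np.ndarray,
    seg_slices: list[slice],
    K: int,
    seed: int,
    rng: np.random.Generator,
    method: str,
    init_window: int = 50,
) -> np.ndarray:
    """Initial per-frame state labels for EM.

    ``windows``: chop each segment into consecutive ``init_window``-frame
    blocks, describe each block by the Fisher-z upper triangle of its
    correlation matrix, k-means those features, and give every frame its
    block's cluster — this seeds EM with covariance (FC) differences, which
    frame-level k-means cannot see when all states share a zero mean.
    ``frames``: plain k-means on frames (mean-separated states).
    """
    if K == 1:
        return np.zeros(x.shape[0], dtype=int)
    if method == "frames":
        return KMeans(n_clusters=K, random_state=seed, n_init=3).fit(x).labels_
    blocks: list[tuple[slice, np.ndarray]] = []
    for sl in seg_slices:
        start = sl.start
        while start < sl.stop:
            stop = min(start + init_window, sl.stop)
            if stop - start >= max(4, init_window // 3) or not blocks:
                seg = x[start:stop]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(seg, rowvar=False)
                r = np.nan_to_num(np.clip(r, -0.999, 0.999))
                iu = np.triu_indices(x.shape[1], 1)
                blocks.append((slice(start, stop), np.arctanh(r[iu])))
            else:  # short tail joins the previous block
                prev_sl, prev_f = blocks[-1]
                blocks[-1] = (slice(prev_sl.start, stop), prev_f)
            start = stop
    if len(blocks) < K:
        return KMeans(n_clusters=K, random_state=seed, n_init=3).fit(x).labels_
    feats = np.stack([f for _, f in blocks])
    # project onto leading principal components: coherent (state-driven) FC
    # variation survives, per-window estimation noise is averaged out
    feats = feats - feats.mean(axis=0)
    n_comp = min(10, len(blocks) - 1, feats.shape[1])
    _, _, vt = np.linalg.svd(feats, full_matrices=False)
    feats = feats @ vt[:n_comp].T
    bl = KMeans(n_clusters=K, random_state=seed, n_init=20).fit(feats).labels_
    # restart perturbation: reassign a random 20% of blocks
    if rng is not None:
        flip = rng.random(len(bl)) < 0.2
        bl = bl.copy()
        bl[flip] = rng.integers(0, K, flip.sum())
    labels = np.empty(x.shape[0], dtype=int)
    for (sl, _), lab in zip(blocks, bl):
        labels[sl] = lab
    return labels


def fit_hmm(
    runs: list[RoiTimeSeries],
    K: int,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-5,
    reg: float = 1e-4,
    max_iter: int = 500,
    diagonal: bool = False,
    init: str = "windows",
) -> HmmModel:
    """Fit a K-state Gaussian HMM to (standardized) runs by Baum-Welch EM.

    Censored frames split each run into segments; every segment enters
    through the initial distribution and no transition spans a gap.  Each
    restart is initialised from a seeded clustering of the frames
    (``init='windows'``: k-means on short-window correlation features,
    suited to covariance-differentiated states; ``init='frames'``: k-means
    on raw frames), with a random perturbation per restart; the restart with
    the highest final log-likelihood wins.  The covariance M-step adds
    ``reg``·I diagonal loading.  The per-iteration log-likelihood is checked
    to be non-decreasing (relative tolerance 1e-8); a decrease is an
    internal error.
    """
    d = runs[0].n_rois
    if any(ts.n_rois != d for ts in runs):
        raise ValueError("all runs must share the same ROI dimension")
    segs = usable_segments(runs)
    pieces, seg_slices, off = [], [], 0
    for ri, s, e in segs:
        pieces.append(runs[ri].data[s:e])
        seg_slices.append(slice(off, off + (e - s)))
        off += e - s
    if not pieces:
        raise ValueError("no usable frames")
    x = np.concatenate(pieces, axis=0)
    if K > x.shape[0]:
        raise ValueError(f"K={K} exceeds number of usable frames ({x.shape[0]})")

    pooled_cov = np.cov(x, rowvar=False, ddof=0) + reg * np.eye(d)

    best: HmmModel | None = None
    final_lls: list[float] = []
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        labels = _init_frame_labels(
            x, seg_slices, K, seed + r, rng if r > 0 else None, init
        )
        means = np.empty((K, d))
        covs = np.empty((K, d, d))
        for j in range(K):
            mask = labels == j
            if mask.sum() >= 2:
                means[j] = x[mask].mean(axis=0)
                cj = np.cov(x[mask], rowvar=False, ddof=0)
                if diagonal:
                    cj = np.diag(np.diag(cj))
                # shrink rank-deficient cluster covariances toward pooled
                lam = min(1.0, mask.sum() / (2.0 * d))
                covs[j] = lam * cj + (1 - lam) * pooled_cov + reg * np.eye(d)
            else:
                means[j] = x.mean(axis=0) + 0.1 * rng.standard_normal(d)
                covs[j] = pooled_cov.copy()
        if r > 0 and init == "frames":
            means = means + 0.25 * rng.standard_normal(means.shape)
        # transition init from the label sequence (smoothed), so EM starts
        # with realistic stickiness instead of a flat guess
        counts = np.ones((K, K))
        for sl in seg_slices:
            lab = labels[sl]
            np.add.at(counts, (lab[:-1], lab[1:]), 1)
        transition = counts / counts.sum(axis=1, keepdims=True)
        initial = np.full(K, 1.0 / K)

        trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            ll, means, covs, transition, initial = _em_once(
                x, seg_slices, means, covs, transition, initial, reg, diagonal
            )
            if np.isfinite(prev_ll) and ll < prev_ll - 1e-8 * abs(prev_ll):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {prev_ll:.6f} -> {ll:.6f}"
                )
            trace.append(ll)
            # convergence on per-frame improvement, so tol is scale-free in T
            if np.isfinite(prev_ll) and (ll - prev_ll) / x.shape[0] <= tol:
                break
            prev_ll = ll
        final_lls.append(trace[-1])
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = HmmModel(
                means=means, covariances=covs, transition=transition,
                initial=initial, loglik_trace=trace, seed=seed,
                restarts=restarts, tol=tol, reg=reg,
            )
    assert best is not None
    best.restart_final_logliks = final_lls
    best.validate()
    return best


def log_likelihood(model: HmmModel, runs: list[RoiTimeSeries]) -> float:
    """Total forward log-likelihood of runs under the model."""
    total = 0.0
    for ri, s, e in usable_segments(runs):
        logb = _state_log_densities(
            runs[ri].data[s:e], model.means, model.covariances
        )
        ll, *_ = _forward_backward(logb, model.transition, model.initial)
        total += ll
    return total


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


@dataclass
class StatePath:
    """Viterbi states and posteriors per run; censored TRs carry -1 / NaN."""

    run_ids: list[str]
    states: list[np.ndarray]          # per run, length T, int, -1 = censored
    posteriors: list[np.ndarray]      # per run, T x K, NaN rows = censored

    def concat_states(self) -> np.ndarray:
        """All usable TRs' Viterbi states, concatenated in run order."""
        return np.concatenate([s[s >= 0] for s in self.states])


def _viterbi(logb: np.ndarray, transition: np.ndarray, initial: np.ndarray) -> np.ndarray:
    t, k = logb.shape
    with np.errstate(divide="ignore"):
        log_a = np.log(transition)
        log_pi = np.log(initial)
    delta = log_pi + logb[0]
    back = np.zeros((t, k), dtype=int)
    for s in range(1, t):
        cand = delta[:, None] + log_a
        back[s] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logb[s]
    path = np.empty(t, dtype=int)
    path[-1] = int(delta.argmax())
    for s in range(t - 2, -1, -1):
        path[s] = back[s + 1][path[s + 1]]
    return path


def decode(model: HmmModel, runs: list[RoiTimeSeries]) -> StatePath:
    """Exact Viterbi path (log space) and forward-backward posteriors.

    Each usable segment is decoded independently (the initial distribution
    applies at every segment start, mirroring the fit).
    """
    k = model.n_states
    states = [np.full(ts.n_trs, -1, dtype=int) for ts in runs]
    posts = [np.full((ts.n_trs, k), np.nan) for ts in runs]
    for ri, s, e in usable_segments(runs):
        logb = _state_log_densities(
            runs[ri].data[s:e], model.means, model.covariances
        )
        states[ri][s:e] = _viterbi(logb, model.transition, model.initial)
        _, gamma, _, _ = _forward_backward(logb, model.transition, model.initial)
        posts[ri][s:e] = gamma
    return StatePath(
        run_ids=[ts.run_id for ts in runs], states=states, posteriors=posts
    )


# ---------------------------------------------------------------------------
# Stage labelling and REM sub-state identification
# ---------------------------------------------------------------------------


@dataclass
class StateLabeling:
    """Winner-take-all stage map plus phasic/tonic REM identification."""

    state_to_stage: dict[int, str]
    rem_states: list[int]
    phasic_state: int | None = None
    tonic_state: int | None = None
    evidence: dict = field(default_factory=dict)
    conflict: bool = False
    report: str = ""


def label_states(
    path: StatePath, tr_stages_per_run: list[tuple[str, ...]], n_states: int
) -> StateLabeling:
    """Assign each HMM state its dominant sleep stage (winner-take-all).

    Unscored TRs are excluded; ties are broken by the fixed stage order
    Wake < N1 < N2 < N3 < REM with a warning.
    """
    counts = pd.DataFrame(0, index=range(n_states), columns=list(STAGES))
    for st, stages in zip(path.states, tr_stages_per_run):
        for s, lab in zip(st, stages):
            if s >= 0 and lab != UNSCORED:
                counts.loc[s, lab] += 1
    mapping: dict[int, str] = {}
    for k in range(n_states):
        row = counts.loc[k]
        if row.sum() == 0:
            mapping[k] = UNSCORED
            continue
        best = int(row.max())
        winners = [s for s in STAGES if row[s] == best]
        if len(winners) > 1:
            warnings.warn(
                f"state {k}: stage tie among {winners}; taking {winners[0]!r}",
                stacklevel=2,
            )
        mapping[k] = winners[0]
    rem_states = sorted(k for k, s in mapping.items() if s == "REM")
    return StateLabeling(
        state_to_stage=mapping,
        rem_states=rem_states,
        evidence={"occupancy": counts},
    )


def identify_rem_substates(
    model: HmmModel,
    labeling: StateLabeling,
    path: StatePath,
    runs: list[RoiTimeSeries],
) -> StateLabeling:
    """Tag the tonic and phasic REM states among the REM-labelled states.

    For each REM state k: ``wake_mass(k)`` is the total transition
    probability from k into Wake-labelled states, and ``occurrence(k)`` is
    the mean normalized time of night (run onset + TR·tr_seconds, divided by
    the night duration) over TRs Viterbi-assigned to k.  The state with the
    largest wake mass is tonic; the state with the latest occurrence is
    phasic.  If both criteria point at the same single state, no assignment
    is made and a conflict report is returned.  With more than two REM
    states, the two with the highest occupancy are compared (warning).
    """
    out = replace(labeling)
    rem = list(labeling.rem_states)
    if len(rem) < 2:
        out.report = (
            f"fewer than two REM-labelled states ({rem}); "
            "no phasic/tonic assignment"
        )
        return out
    if len(rem) > 2:
        occ = labeling.evidence["occupancy"].sum(axis=1)
        rem = sorted(sorted(rem, key=lambda k: -occ[k])[:2])
        warnings.warn(
            f"{len(labeling.rem_states)} REM states; comparing the two with "
            f"highest occupancy: {rem}",
            stacklevel=2,
        )
    wake_states = [k for k, s in labeling.state_to_stage.items() if s == "Wake"]
    wake_mass = {
        k: float(model.transition[k, wake_states].sum()) if wake_states else 0.0
        for k in rem
    }
    night_end = max(
        ts.run_onset_seconds + ts.n_trs * ts.tr_seconds for ts in runs
    )
    occurrence = {}
    for k in rem:
        times = []
        for ts, st in zip(runs, path.states):
            idx = np.flatnonzero(st == k)
            if len(idx):
                times.append(ts.run_onset_seconds + idx * ts.tr_seconds)
        occurrence[k] = (
            float(np.concatenate(times).mean() / night_end) if times else np.nan
        )
    out.evidence = dict(labeling.evidence)
    out.evidence["wake_mass"] = wake_mass
    out.evidence["occurrence"] = occurrence
    latest = max(rem, key=lambda k: occurrence[k])
    masses = sorted((wake_mass[k] for k in rem), reverse=True)
    # one observed transition in ~1e4 frames moves a row's mass by >= 1e-4;
    # smaller differences are smoothing/estimation noise, not evidence
    if masses[0] - masses[1] <= 1e-4:
        # no usable Wake-transition evidence (tie, typically both zero):
        # timing alone decides — phasic is the latest, tonic the other
        phasic = latest
        tonic = max((k for k in rem if k != phasic),
                    key=lambda k: wake_mass[k])
        out.tonic_state = tonic
        out.phasic_state = phasic
        out.report = (
            "wake-transition masses tied; assignment made on occurrence "
            "timing alone"
        )
        return out
    tonic = max(rem, key=lambda k: wake_mass[k])
    if tonic == latest:
        out.conflict = True
        out.report = (
            f"criteria conflict: state {tonic} has both the largest "
            f"Wake-transition mass ({wake_mass[tonic]:.3f}) and the latest "
            f"occurrence ({occurrence[tonic]:.3f}); no assignment"
        )
        return out
    remaining = [k for k in rem if k != tonic]
    phasic = max(remaining, key=lambda k: occurrence[k])
    out.tonic_state = tonic
    out.phasic_state = phasic
    return out


# ---------------------------------------------------------------------------
# Per-state network FC
# ---------------------------------------------------------------------------


def state_network_fc(model: HmmModel, atlas: AtlasMap):
    """Per-state network FC, its across-state-relative version, and the
    per-state intra-thalamic connection.

    Each state's covariance is converted to correlation, Fisher-transformed
    and aggregated to networks; the relative matrix subtracts the element-wise
    mean over all states.
    """
    agg = NetworkAggregator(atlas)
    mats = []
    for j in range(model.n_states):
        cov = model.covariances[j]
        d = np.sqrt(np.diag(cov))
        corr = np.clip(cov / np.outer(d, d), -1.0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = fisher_z(corr)
        np.fill_diagonal(z, 0.0)
        mats.append(agg.aggregate(z))
    mean_vals = np.mean([m.values for m in mats], axis=0)
    relative = [
        type(m)(m.networks, m.values - mean_vals) for m in mats
    ]
    intra = np.array([intra_thalamic_connection(m) for m in mats])
    return mats, relative, intra


def state_visit_values(
    runs: list[RoiTimeSeries],
    path: StatePath,
    state: int,
    atlas: AtlasMap,
    statistic,
    min_visit_trs: int = 10,
) -> list[float]:
    """One FC summary per contiguous Viterbi visit to ``state``.

    A visit is a maximal run of TRs assigned to the state (censored frames
    break visits).  Visits shorter than ``min_visit_trs`` are skipped; for
    each retained visit the ROI correlation over its frames is
    Fisher-transformed, aggregated to networks, and summarised by
    ``statistic`` (a callable on NetworkFcMatrix).
    """
    from .dfc import window_roi_fc

    agg = NetworkAggregator(atlas)
    values: list[float] = []
    for ts, st in zip(runs, path.states):
        t = 0
        n = len(st)
        while t < n:
            if st[t] == state:
                s0 = t
                while t < n and st[t] == state:
                    t += 1
                if t - s0 >= min_visit_trs:
                    z = window_roi_fc(ts.data[s0:t])
                    np.fill_diagonal(z, 0.0)
                    values.append(float(statistic(agg.aggregate(z))))
            else:
                t += 1
    return values
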