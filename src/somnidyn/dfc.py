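"""Sliding-window dynamic functional connectivity (DFC).

Each 30-TR (90 s) window inside a stage-pure episode yields a full ROI×ROI
Pearson correlation matrix, which is Fisher-transformed (z = atanh r) and then
aggregated to the 19 networks: the (A, B) network entry is the mean z over all
ROI pairs with one ROI in A and one in B; the (A, A) diagonal entry is the
mean over unordered distinct ROI pairs within A.  Fisher-z is applied at the
ROI-pair level *before* averaging.

The intra-thalamic connection statistic is the mean of the 10 unordered
distinct thalamic-subnetwork pair entries (off-diagonal only; a
diagonal-inclusive variant is available via a flag).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_atlas import (
    SENSORY_NETWORKS,
    THALAMIC_SUBNETWORKS,
    AtlasMap,
    RoiTimeSeries,
)
from .segmentation import Episode

logger = logging.getLogger(__name__)

#: Correlations of |r| >= 1 are clamped here before the Fisher transform.
CLAMP = 0.999999


def fisher_z(r):
    """Fisher transform z = atanh(r), clamping |r| = 1 to ±0.999999.

    Accepts scalars or arrays; NaNs pass through.  |r| > 1 (beyond floating
    slack) is an error.
    """
    scalar = np.isscalar(r) or np.ndim(r) == 0
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    finite = np.isfinite(arr)
    if np.any(np.abs(arr[finite]) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    if np.any(np.abs(arr[finite]) >= 1 - 1e-15):
        warnings.warn(
            "correlation at ±1 clamped to ±0.999999 before Fisher transform",
            stacklevel=2,
        )
    out = np.arctanh(np.clip(arr, -CLAMP, CLAMP))
    out[~finite] = np.nan
    if scalar:
        return float(out[0])
    return out


@dataclass
class NetworkFcMatrix:
    """Symmetric network-level FC matrix in Fisher-z units.

    Diagonal entries are within-network FC (NaN for single-ROI networks);
    off-diagonal entries are between-network FC.
    """

    networks: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.networks)
        if self.values.shape != (n, n):
            raise ValueError("values shape must match networks")
        if not np.allclose(
            self.values, self.values.T, atol=1e-10, equal_nan=True
        ):
            raise ValueError("network FC matrix must be symmetric")

    def entry(self, a: str, b: str) -> float:
        i, j = self.networks.index(a), self.networks.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.networks, columns=self.networks)


@dataclass
class WindowFc:
    """FC of one sliding window (ROI matrix optional, network matrix always)."""

    participant_id: str
    run_id: str
    stage: str
    window_start_tr: int
    net_fc: NetworkFcMatrix
    roi_fc: np.ndarray | None = None


class NetworkAggregator:
    """Cached ROI→network index structure for fast block averaging."""

    def __init__(self, atlas: AtlasMap):
        self.atlas = atlas
        self.networks = atlas.networks
        self.members = [atlas.rois_in_network(n) for n in self.networks]
        r = atlas.n_rois
        m = np.zeros((r, len(self.networks)))
        for k, idx in enumerate(self.members):
            m[idx, k] = 1.0
        self._m = m
        counts = m.T @ np.ones((r, r)) @ m
        sizes = m.sum(axis=0)
        np.fill_diagonal(counts, sizes * (sizes - 1) / 2.0)
        self._pair_counts = counts

    def aggregate(self, roi_fc: np.ndarray) -> NetworkFcMatrix:
        """Mean Fisher-z per network block; NaN ROI pairs are excluded."""
        z = np.array(roi_fc, dtype=float)
        if z.shape != (self.atlas.n_rois,) * 2:
            raise ValueError("roi_fc shape does not match atlas")
        if not np.allclose(z, z.T, atol=1e-10, equal_nan=True):
            raise ValueError("roi_fc must be symmetric")
        np.fill_diagonal(z, 0.0)  # excluded from within-network sums below
        nan_mask = np.isnan(z)
        if nan_mask.any():
            valid = (~nan_mask).astype(float)
            np.fill_diagonal(valid, 0.0)
            zf = np.where(nan_mask, 0.0, z)
            sums = self._m.T @ zf @ self._m
            counts = self._m.T @ valid @ self._m
            np.fill_diagonal(sums, np.diag(sums) / 2.0)
            np.fill_diagonal(counts, np.diag(counts) / 2.0)
        else:
            sums = self._m.T @ z @ self._m
            counts = self._pair_counts.copy()
            np.fill_diagonal(sums, np.diag(sums) / 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
        vals = (vals + vals.T) / 2.0  # exact symmetry
        return NetworkFcMatrix(list(self.networks), vals)


def aggregate_to_networks(roi_fc: np.ndarray, atlas: AtlasMap) -> NetworkFcMatrix:
    """Aggregate an ROI-pair Fisher-z matrix to network level (see module doc)."""
    return NetworkAggregator(atlas).aggregate(roi_fc)


def window_roi_fc(x: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlation of every ROI pair over one window's frames.

    An ROI with zero variance in the window yields NaN for all its pairs.
    The diagonal is set to NaN (self-correlation is undefined in z units).
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return z


def sliding_window_fc(
    ts: RoiTimeSeries,
    e: Episode,
    starts: list[int],
    atlas: AtlasMap,
    window_trs: int = 30,
    max_missing_frac: float = 0.05,
    keep_roi_fc: bool = False,
    aggregator: NetworkAggregator | None = None,
) -> list[WindowFc]:
    """Compute per-window ROI FC and network aggregation for given starts.

    Windows whose ROI matrix has >= ``max_missing_frac`` missing off-diagonal
    entries (zero-variance ROIs) are dropped with a log entry.
    """
    agg = aggregator or NetworkAggregator(atlas)
    r = ts.n_rois
    n_offdiag = r * (r - 1)
    out: list[WindowFc] = []
    for s in starts:
        seg = ts.data[s : s + window_trs]
        z = window_roi_fc(seg)
        n_missing = int(np.isnan(z).sum()) - r  # diagonal NaNs don't count
        if n_missing / n_offdiag >= max_missing_frac and n_missing > 0:
            logger.info(
                "window %s/%s start=%d dropped: %d/%d FC entries missing",
                ts.participant_id, ts.run_id, s, n_missing, n_offdiag,
            )
            continue
        zz = z.copy()
        np.fill_diagonal(zz, 0.0)
        out.append(
            WindowFc(
                participant_id=ts.participant_id,
                run_id=ts.run_id,
                stage=e.stage,
                window_start_tr=s,
                net_fc=agg.aggregate(zz),
                roi_fc=z if keep_roi_fc else None,
            )
        )
    return out


def intra_thalamic_connection(
    net_fc: NetworkFcMatrix, include_within: bool = False
) -> float:
    """Mean FC over the 10 distinct thalamic-subnetwork pairs (Fisher-z units).

    With ``include_within=True`` the 5 within-subnetwork diagonal entries are
    averaged in as well.
    """
    missing = [s for s in THALAMIC_SUBNETWORKS if s not in net_fc.networks]
    if missing:
        raise ValueError(f"thalamic subnetworks absent from matrix: {missing}")
    idx = [net_fc.networks.index(s) for s in THALAMIC_SUBNETWORKS]
    vals = []
    for a in range(len(idx)):
        lo = a if include_within else a + 1
        for b in range(lo, len(idx)):
            v = net_fc.values[idx[a], idx[b]]
            if np.isnan(v):
                raise ValueError(
                    f"missing thalamic pair entry "
                    f"({THALAMIC_SUBNETWORKS[a]}, {THALAMIC_SUBNETWORKS[b]})"
                )
            vals.append(v)
    return float(np.mean(vals))


def thalamo_cortical_block(
    net_fc: NetworkFcMatrix, cortical_set: list[str] | tuple[str, ...] = SENSORY_NETWORKS
) -> pd.Series:
    """The thalamic-subnetwork × cortical-network between-network entries.

    Returns a Series indexed by (thalamic subnetwork, cortical network).
    """
    for n in list(THALAMIC_SUBNETWORKS) + list(cortical_set):
        if n not in net_fc.networks:
            raise ValueError(f"network {n!r} not in matrix")
    index = pd.MultiIndex.from_product(
        [list(THALAMIC_SUBNETWORKS), list(cortical_set)],
        names=["thalamic", "cortical"],
    )
    vals = [net_fc.entry(a, b) for a, b in index]
    return pd.Series(vals, index=index, name="fc_z")


def global_signal_regress(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Regress the across-ROI mean signal out of every ROI (OLS with intercept).

    The regression is estimated on usable frames; residuals are formed for all
    frames using the fitted coefficients.
    """
    g = ts.data.mean(axis=1)
    design = np.column_stack([np.ones(ts.n_trs), g])
    usable = ts.censor
    beta, *_ = np.linalg.lstsq(design[usable], ts.data[usable], rcond=None)
    resid = ts.data - design @ beta
    return ts.copy_with(data=resid)


def stage_average_fc(
    windows: list[WindowFc], stage: str
) -> tuple[NetworkFcMatrix | None, dict[str, NetworkFcMatrix]]:
    """Element-wise mean network FC over all windows of ``stage``.

    Averaged per participant first, then across participants (both levels
    returned: grand matrix and per-participant dict).  Returns (None, {}) if
    no windows of that stage exist.
    """
    sel = [w for w in windows if w.stage == stage]
    if not sel:
        return None, {}
    networks = sel[0].net_fc.networks
    per_part: dict[str, NetworkFcMatrix] = {}
    for pid in sorted({w.participant_id for w in sel}):
        mats = np.stack([w.net_fc.values for w in sel if w.participant_id == pid])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_part[pid] = NetworkFcMatrix(networks, np.nanmean(mats, axis=0))
    grand = NetworkFcMatrix(
        networks,
        np.nanmean(np.stack([m.values for m in per_part.values()]), axis=0),
    )
    return grand, per_part


def windows_to_table(windows: list[WindowFc]) -> pd.DataFrame:
    """Long-format DFC table: one row per window per unordered network pair."""
    if not windows:
        return pd.DataFrame(
            columns=[
                "participant", "run", "stage", "window_start_tr",
                "network_a", "network_b", "fc_z",
            ]
        )
    networks = windows[0].net_fc.networks
    n = len(networks)
    iu, ju = np.triu_indices(n)
    rows = {
        "participant": np.repeat([w.participant_id for w in windows], len(iu)),
        "run": np.repeat([w.run_id for w in windows], len(iu)),
        "stage": np.repeat([w.stage for w in windows], len(iu)),
        "window_start_tr": np.repeat(
            [w.window_start_tr for w in windows], len(iu)
        ),
        "network_a": np.tile([networks[i] for i in iu], len(windows)),
        "network_b": np.tile([networks[j] for j in ju], len(windows)),
        "fc_z": np.concatenate([w.net_fc.values[iu, ju] for w in windows]),
    }
    return pd.DataFrame(rows)
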