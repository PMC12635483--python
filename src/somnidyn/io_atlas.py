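"""Data model, file I/O and atlas handling.

The pipeline operates on ROI-level BOLD matrices (one row per fMRI volume,
one column per region of interest), per-epoch hypnograms scored on 30-second
epochs, per-TR motion-censoring masks, and an atlas table that maps every ROI
to a functional network.  Networks come in two flavours: 14 cortical networks
and 5 thalamic subnetworks (groups of thalamic ROIs named after the cortical
network they couple to most strongly during wake), for 19 networks in total.

All tabular formats are plain TSV: time series have a header row of ROI
labels; censor masks are a single 0/1 column; hypnograms have columns
``epoch_index`` and ``stage``; atlases have columns ``roi_label``, ``network``
and ``role``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical sleep-stage order; also the tie-break order for winner-take-all
#: state labelling.
STAGES: tuple[str, ...] = ("Wake", "N1", "N2", "N3", "REM")

#: Label for epochs without a sleep score; excluded from every analysis.
UNSCORED: str = "Unscored"

#: The 14 cortical networks, in display order.
CORTICAL_NETWORKS: tuple[str, ...] = (
    "Un", "DMN", "FPN", "REW", "DAN", "VAN", "SAL",
    "CON", "VIS", "dSMN", "lSMN", "AUD", "PMN", "MTL",
)

#: The 5 thalamic subnetworks, in display order.
THALAMIC_SUBNETWORKS: tuple[str, ...] = (
    "THAL_DMN", "THAL_VIS", "THAL_CON", "THAL_lSMN", "THAL_dSMN",
)

#: Sensory-related cortical networks: vision, audition, lateral/dorsal
#: somatomotor and the cingulo-opercular (action-mode) network.
SENSORY_NETWORKS: tuple[str, ...] = ("AUD", "VIS", "lSMN", "dSMN", "CON")

ROLES: tuple[str, ...] = ("cortical", "thalamic", "subcortical_other", "cerebellar")


class FormatError(ValueError):
    """A file does not conform to the expected TSV layout."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtlasMap:
    """ROI → network assignment table.

    Parameters
    ----------
    table:
        DataFrame indexed by 0-based ``roi_id`` with columns ``roi_label``,
        ``network`` and ``role``.  Every ROI maps to exactly one network.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"roi_label", "network", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"atlas table missing columns: {sorted(missing)}")
        labels = self.table["roi_label"]
        if labels.duplicated().any():
            dupes = labels[labels.duplicated()].tolist()
            raise FormatError(f"duplicate roi_label entries: {dupes}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown roles: {sorted(bad_roles)}")
        thal = self.table[self.table["role"] == "thalamic"]
        if len(thal):
            present = set(thal["network"])
            absent = [s for s in THALAMIC_SUBNETWORKS if s not in present]
            if absent:
                raise FormatError(
                    f"thalamic subnetworks with 0 ROIs: {absent}"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def roi_labels(self) -> list[str]:
        return self.table["roi_label"].tolist()

    @property
    def networks(self) -> list[str]:
        """All distinct networks in canonical order (cortical, thalamic, rest)."""
        present = set(self.table["network"])
        ordered = [n for n in CORTICAL_NETWORKS + THALAMIC_SUBNETWORKS if n in present]
        extra = sorted(present - set(ordered))
        return ordered + extra

    def rois_in_network(self, network: str) -> np.ndarray:
        """0-based ROI indices belonging to ``network``."""
        return np.flatnonzero((self.table["network"] == network).to_numpy())

    def rois_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.table["role"] == role).to_numpy())

    def network_sizes(self) -> dict[str, int]:
        counts = self.table["network"].value_counts()
        return {n: int(counts[n]) for n in self.networks}


def load_atlas(path: str | Path = "bundled") -> AtlasMap:
    """Read an atlas TSV, or the bundled reduced synthetic atlas.

    The bundled default is a 60-ROI synthetic atlas (not the published
    300-ROI coordinates) with the full 19-network structure: 48 cortical ROIs
    over the 14 cortical networks plus 12 thalamic ROIs partitioned 2/2/4/2/2
    over THAL_DMN / THAL_VIS / THAL_CON / THAL_lSMN / THAL_dSMN.
    """
    if str(path) == "bundled":
        ref = resources.files("somnidyn").joinpath("data/atlas_default.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df.index = pd.RangeIndex(len(df), name="roi_id")
    return AtlasMap(df)


def write_atlas(atlas: AtlasMap, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def assign_subcortical_to_networks(mean_fc: np.ndarray, atlas: AtlasMap) -> AtlasMap:
    """Assign each non-cortical, non-thalamic ROI to its strongest cortical network.

    Each ROI with role ``subcortical_other`` or ``cerebellar`` is reassigned to
    the cortical network whose cortical ROIs have the largest mean Fisher-z FC
    with it in ``mean_fc``.  Cortical and thalamic assignments are unchanged.
    Ties are broken by lexicographic network name order (a warning is emitted).
    """
    mean_fc = np.asarray(mean_fc, dtype=float)
    if mean_fc.shape != (atlas.n_rois, atlas.n_rois):
        raise ValueError(
            f"mean_fc shape {mean_fc.shape} does not match atlas ({atlas.n_rois} ROIs)"
        )
    if not np.allclose(mean_fc, mean_fc.T, atol=1e-10, equal_nan=True):
        raise ValueError("mean_fc must be symmetric")

    cortical_nets = [n for n in CORTICAL_NETWORKS if n in set(atlas.table["network"])]
    cortical_members = {
        n: atlas.rois_in_network(n)[
            np.isin(atlas.rois_in_network(n), atlas.rois_with_role("cortical"))
        ]
        for n in cortical_nets
    }
    cortical_members = {n: m for n, m in cortical_members.items() if len(m)}
    if not cortical_members:
        raise ValueError("atlas has no cortical ROIs to assign against")

    table = atlas.table.copy()
    movable = np.concatenate(
        [atlas.rois_with_role("subcortical_other"), atlas.rois_with_role("cerebellar")]
    )
    # lexicographic candidate order makes the argmax tie-break deterministic
    candidates = sorted(cortical_members)
    for roi in movable:
        scores = np.array(
            [mean_fc[roi, cortical_members[n]].mean() for n in candidates]
        )
        best = float(scores.max())
        winners = [n for n, s in zip(candidates, scores) if s == best]
        if len(winners) > 1:
            warnings.warn(
                f"ROI {atlas.table['roi_label'].iloc[roi]!r}: tie in strongest-FC "
                f"assignment among {winners}; taking {winners[0]!r}",
                stacklevel=2,
            )
        table.iloc[roi, table.columns.get_loc("network")] = winners[0]
    return AtlasMap(table)


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------


@dataclass
class RoiTimeSeries:
    """One run's T×R BOLD matrix with metadata.

    ``censor`` is True for usable frames.  ``run_onset_seconds`` is the time
    since the start of the night, used for time-of-night computations.
    """

    data: np.ndarray
    roi_labels: list[str]
    tr_seconds: float = 3.0
    censor: np.ndarray | None = None
    participant_id: str = "p0"
    run_id: str = "r0"
    run_onset_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T x R) matrix")
        t, r = self.data.shape
        if t < 1 or r < 2:
            raise ValueError(f"need T >= 1 and R >= 2, got T={t}, R={r}")
        if len(self.roi_labels) != r:
            raise ValueError("roi_labels length must equal number of columns")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.run_onset_seconds < 0:
            raise ValueError("run_onset_seconds must be nonnegative")
        if self.censor is None:
            self.censor = np.ones(t, dtype=bool)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.censor.shape != (t,):
            raise ValueError("censor length must equal T")
        usable = self.data[self.censor]
        if not np.isfinite(usable).all():
            bad = np.argwhere(~np.isfinite(self.data))
            t0, r0 = bad[0]
            raise FormatError(
                f"non-finite value in usable frame at row {t0}, column {r0} "
                f"({self.roi_labels[r0]!r})"
            )

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "RoiTimeSeries":
        return replace(self, **kw)


def read_roi_timeseries(
    path: str | Path,
    participant_id: str = "p0",
    run_id: str = "r0",
    censor_path: str | Path | None = None,
    tr_seconds: float = 3.0,
    run_onset_seconds: float = 0.0,
) -> RoiTimeSeries:
    """Read a T×R TSV (header = ROI labels, one row per TR).

    A censor-mask file (single 0/1 column, one row per TR) may be supplied;
    otherwise all frames are marked usable.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"{path}: {e}") from e
    labels = [str(c) for c in df.columns]
    try:
        data = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            raw_na = df[col].isna() | df[col].str.strip().str.lower().isin(
                ["nan", ""]
            )
            bad = coerced.isna() & ~raw_na
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"{path}: non-numeric cell at row {i}, column {j} ({labels[j]!r})"
                ) from None
        data = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    censor = None
    if censor_path is not None:
        censor = read_censor_mask(censor_path)
    return RoiTimeSeries(
        data=data,
        roi_labels=labels,
        tr_seconds=tr_seconds,
        censor=censor,
        participant_id=participant_id,
        run_id=run_id,
        run_onset_seconds=run_onset_seconds,
    )


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_censor_mask(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None)
    vals = df.iloc[:, 0].to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise FormatError(f"{path}: censor mask entries must be 0 or 1")
    return vals.astype(bool)


def write_censor_mask(censor: np.ndarray, path: str | Path) -> None:
    pd.Series(np.asarray(censor).astype(int)).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------


@dataclass
class Hypnogram:
    """Sleep-stage labels over 30-s scoring epochs, optionally resampled to TR."""

    epoch_stages: tuple[str, ...]
    epoch_seconds: float = 30.0
    tr_stages: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.epoch_stages = tuple(self.epoch_stages)
        allowed = set(STAGES) | {UNSCORED}
        bad = set(self.epoch_stages) - allowed
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.tr_stages is not None:
            self.tr_stages = tuple(self.tr_stages)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_stages)


def resample_hypnogram_to_tr(h: Hypnogram, tr_seconds: float) -> Hypnogram:
    """Repeat each epoch label ``epoch_seconds / tr_seconds`` times.

    Categorical labels are never interpolated: the epoch length must be an
    integer multiple of the TR.
    """
    ratio = h.epoch_seconds / tr_seconds
    n_rep = round(ratio)
    if abs(ratio - n_rep) > 1e-9 or n_rep < 1:
        raise ValueError(
            f"epoch length {h.epoch_seconds}s is not divisible by TR {tr_seconds}s"
        )
    tr_stages = tuple(s for s in h.epoch_stages for _ in range(n_rep))
    return Hypnogram(h.epoch_stages, h.epoch_seconds, tr_stages)


def read_hypnogram(path: str | Path, epoch_seconds: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise FormatError(f"{path}: hypnogram needs columns epoch_index, stage")
    df = df.sort_values("epoch_index")
    return Hypnogram(tuple(df["stage"]), epoch_seconds)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": range(h.n_epochs), "stage": h.epoch_stages}
    ).to_csv(path, sep="\t", index=False)
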