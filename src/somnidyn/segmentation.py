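"""Sleep-episode extraction and sliding-window position enumeration.

An *episode* is a maximal run of at least ``min_epochs`` consecutive
same-stage scoring epochs (default 3 epochs = 90 s), expressed in TR
coordinates.  Dynamic FC windows are placed only inside episodes, never
across episode or run boundaries, so every window is stage-pure.  Windows
that overlap motion-censored frames are excluded under the default policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_atlas import UNSCORED, Hypnogram


@dataclass(frozen=True)
class Episode:
    """A maximal same-stage run, in half-open TR coordinates [start_tr, end_tr)."""

    participant_id: str
    run_id: str
    stage: str
    start_tr: int
    end_tr: int
    n_epochs: int

    @property
    def n_trs(self) -> int:
        return self.end_tr - self.start_tr


def segment_episodes(
    h: Hypnogram,
    min_epochs: int = 3,
    tr_seconds: float = 3.0,
    participant_id: str = "p0",
    run_id: str = "r0",
) -> list[Episode]:
    """Extract maximal same-stage runs of >= ``min_epochs`` epochs.

    Unscored epochs never form episodes.  Output is sorted by ``start_tr``.
    TR coordinates assume the hypnogram starts at TR 0 of the run.
    """
    ratio = h.epoch_seconds / tr_seconds
    trs_per_epoch = round(ratio)
    if abs(ratio - trs_per_epoch) > 1e-9 or trs_per_epoch < 1:
        raise ValueError(
            f"epoch length {h.epoch_seconds}s not divisible by TR {tr_seconds}s"
        )
    stages = h.epoch_stages
    episodes: list[Episode] = []
    i = 0
    n = len(stages)
    while i < n:
        j = i
        while j < n and stages[j] == stages[i]:
            j += 1
        run_len = j - i
        if stages[i] != UNSCORED and run_len >= min_epochs:
            episodes.append(
                Episode(
                    participant_id=participant_id,
                    run_id=run_id,
                    stage=stages[i],
                    start_tr=i * trs_per_epoch,
                    end_tr=j * trs_per_epoch,
                    n_epochs=run_len,
                )
            )
        i = j
    return episodes


def valid_window_starts(
    e: Episode,
    censor: np.ndarray | None = None,
    window_trs: int = 30,
    step_trs: int = 1,
    policy: str = "drop_any",
    max_censored_frac: float = 0.0,
) -> list[int]:
    """Enumerate window start TRs inside an episode, honouring censoring.

    Windows are half-open ``[s, s + window_trs)`` and must lie entirely within
    the episode.  Under ``drop_any`` (default) a window containing any
    censored frame is excluded; under ``max_frac`` a window is kept while its
    censored fraction is <= ``max_censored_frac``.  A window longer than the
    episode yields an empty list.
    """
    if window_trs < 1 or step_trs < 1:
        raise ValueError("window_trs and step_trs must be positive")
    if policy not in ("drop_any", "max_frac"):
        raise ValueError(f"unknown censor policy {policy!r}")
    last_start = e.end_tr - window_trs
    if last_start < e.start_tr:
        return []
    starts = list(range(e.start_tr, last_start + 1, step_trs))
    if censor is None:
        return starts
    censor = np.asarray(censor, dtype=bool)
    bad = ~censor
    # prefix sums give the censored count of any window in O(1)
    cum = np.concatenate([[0], np.cumsum(bad)])
    kept = []
    for s in starts:
        n_bad = cum[s + window_trs] - cum[s]
        if policy == "drop_any":
            if n_bad == 0:
                kept.append(s)
        else:
            if n_bad / window_trs <= max_censored_frac:
                kept.append(s)
    return kept


def episodes_to_table(episodes: list[Episode]):
    """Episodes as a BED-like table: participant, run, stage, start_tr, end_tr."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant": e.participant_id,
                "run": e.run_id,
                "stage": e.stage,
                "start_tr": e.start_tr,
                "end_tr": e.end_tr,
                "n_epochs": e.n_epochs,
            }
            for e in episodes
        ],
        columns=["participant", "run", "stage", "start_tr", "end_tr", "n_epochs"],
    )
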