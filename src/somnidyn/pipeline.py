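"""End-to-end orchestration: simulate → segment → DFC → HMM → stats.

``run_pipeline`` produces, per run: stage-average network FC matrices,
per-participant intra-thalamic distributions per stage, the LME + FWE stage
contrast table, the HMM state labelling with phasic/tonic identification,
per-state (relative) network FC with the phasic outlier z, and the
phasic-vs-tonic per-visit t-test — everything deterministic given the seed.
Intermediates are cached as TSV/JSON so each stage can be re-run on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfc as dfc_mod
from . import hmm as hmm_mod
from . import stats as stats_mod
from .io_atlas import STAGES, AtlasMap, load_atlas
from .segmentation import episodes_to_table, segment_episodes, valid_window_starts
from .synthetic import GeneratorConfig, NightRecording, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis settings; defaults follow the standard 90-s window design
    (window = 3 scoring epochs at TR 3 s)."""

    window_trs: int = 30
    step_trs: int = 1
    min_epochs: int = 3
    K: int = 21
    seed: int = 0
    alpha: float = 0.05
    fwe_method: str = "bonferroni"
    censor_policy: str = "drop_any"
    gsr: bool = False
    hmm_restarts: int = 2
    hmm_max_iter: int = 300
    hmm_tol: float = 1e-5
    hmm_reg: float = 1e-4
    hmm_prewhiten: bool = True
    hmm_pca_dims: int | None = 16
    min_visit_trs: int = 10
    lme_stages: tuple[str, ...] = tuple(STAGES)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def analysis_fields(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d.pop("generator")
        gen["stage_transition"] = self.generator.stage_transition.tolist()
        gen["rem_substate_transition"] = (
            self.generator.rem_substate_transition.tolist()
        )
        d["generator"] = gen
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_fields(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Bundle of every pipeline output."""

    config_hash: str
    stage_matrices: dict[str, dfc_mod.NetworkFcMatrix | None]
    stage_matrices_per_participant: dict[str, dict[str, dfc_mod.NetworkFcMatrix]]
    intra_thalamic: pd.DataFrame       # participant x stage, Fisher-z
    dfc_table: pd.DataFrame
    lme_table: pd.DataFrame
    model: hmm_mod.HmmModel | None
    labeling: hmm_mod.StateLabeling | None
    state_fc: list | None
    state_fc_relative: list | None
    state_intra_thalamic: np.ndarray | None
    phasic_outlier: tuple[float, float] | None
    phasic_vs_tonic: dict | None
    timings: dict[str, float] = field(default_factory=dict)


def _dfc_stage(nights, config, atlas) -> tuple[list, pd.DataFrame]:
    agg = dfc_mod.NetworkAggregator(atlas)
    windows = []
    for pid, rec in nights.items():
        ts = rec.timeseries
        if config.gsr:
            ts = dfc_mod.global_signal_regress(ts)
        episodes = segment_episodes(
            rec.hypnogram,
            min_epochs=config.min_epochs,
            tr_seconds=ts.tr_seconds,
            participant_id=pid,
            run_id=ts.run_id,
        )
        for e in episodes:
            starts = valid_window_starts(
                e, ts.censor, config.window_trs, config.step_trs,
                policy=config.censor_policy,
            )
            windows.extend(
                dfc_mod.sliding_window_fc(
                    ts, e, starts, atlas, config.window_trs, aggregator=agg
                )
            )
    return windows, dfc_mod.windows_to_table(windows)


def run_pipeline(
    config: PipelineConfig,
    atlas: AtlasMap | None = None,
    nights: dict[str, NightRecording] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full analysis on simulated (default) or supplied nights.

    When ``nights`` is None the generator in ``config.generator`` is run
    first.  When ``out_dir`` is given, intermediates and results are written
    there as TSV/JSON.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    atlas = atlas or load_atlas("bundled")

    if nights is None:
        nights, _truth = simulate_dataset(config.generator, atlas)
    timings["simulate"] = time.time() - t0

    # --- DFC ---------------------------------------------------------------
    t1 = time.time()
    windows, dfc_table = _dfc_stage(nights, config, atlas)
    timings["dfc"] = time.time() - t1

    stage_matrices: dict[str, dfc_mod.NetworkFcMatrix | None] = {}
    per_part: dict[str, dict] = {}
    for stage in STAGES:
        grand, pp = dfc_mod.stage_average_fc(windows, stage)
        stage_matrices[stage] = grand
        per_part[stage] = pp

    intra_rows = {}
    for stage, pp in per_part.items():
        for pid, mat in pp.items():
            try:
                val = dfc_mod.intra_thalamic_connection(mat)
            except ValueError:
                val = np.nan
            intra_rows.setdefault(pid, {})[stage] = val
    intra_df = pd.DataFrame(intra_rows).T.reindex(columns=list(STAGES))
    intra_df.index.name = "participant"

    # --- LME + FWE ---------------------------------------------------------
    t2 = time.time()
    present = set(dfc_table["stage"].unique()) if len(dfc_table) else set()
    if "Wake" in present and len(present) > 1:
        lme_table = stats_mod.lme_all_pairs(
            dfc_table[dfc_table["stage"].isin(config.lme_stages)],
            alpha=config.alpha,
            fwe_method=config.fwe_method,
            n_comparisons=stats_mod.n_network_comparisons(len(atlas.networks)),
        )
    else:
        lme_table = pd.DataFrame()
        logger.warning("fewer than two stages with windows; LME skipped")
    timings["lme"] = time.time() - t2

    # --- HMM ---------------------------------------------------------------
    t3 = time.time()
    runs = [hmm_mod.standardize(rec.timeseries) for rec in nights.values()]
    tr_stages = [tuple(rec.hypnogram.tr_stages) for rec in nights.values()]
    model = labeling = None
    state_fc = state_rel = None
    state_intra = None
    phasic_outlier = None
    phasic_vs_tonic = None
    if runs:
        fit_runs = runs
        if config.hmm_prewhiten:
            fit_runs = [hmm_mod.prewhiten(ts)[0] for ts in fit_runs]
            fit_runs = [hmm_mod.standardize(ts) for ts in fit_runs]
        if config.hmm_pca_dims:
            fit_runs, _, _ = hmm_mod.pca_project(fit_runs, config.hmm_pca_dims)
        model = hmm_mod.fit_hmm(
            fit_runs, config.K, seed=config.seed,
            restarts=config.hmm_restarts, tol=config.hmm_tol,
            reg=config.hmm_reg, max_iter=config.hmm_max_iter,
        )
        path = hmm_mod.decode(model, fit_runs)
        labeling = hmm_mod.label_states(path, tr_stages, model.n_states)
        labeling = hmm_mod.identify_rem_substates(model, labeling, path, runs)
        # state FC from the decoded frames in ROI space (the fitted space may
        # be prewhitened/PCA-reduced, whose covariances are not ROI FC)
        state_fc, state_rel, state_intra = hmm_mod.empirical_state_fc(
            runs, path, model.n_states, atlas
        )
        if labeling.phasic_state is not None:
            defined = np.flatnonzero(~np.isnan(state_intra))
            if labeling.phasic_state in defined and len(defined) >= 3:
                z, p = stats_mod.state_outlier_z(
                    state_intra[defined],
                    int(np.flatnonzero(defined == labeling.phasic_state)[0]),
                )
                phasic_outlier = (z, p)
            x = hmm_mod.state_visit_values(
                runs, path, labeling.phasic_state, atlas,
                statistic=lambda m: float(
                    dfc_mod.thalamo_cortical_block(m).mean()
                ),
                min_visit_trs=config.min_visit_trs,
            )
            y = hmm_mod.state_visit_values(
                runs, path, labeling.tonic_state, atlas,
                statistic=lambda m: float(
                    dfc_mod.thalamo_cortical_block(m).mean()
                ),
                min_visit_trs=config.min_visit_trs,
            )
            if len(x) >= 2 and len(y) >= 2:
                t, df_, p = stats_mod.two_sample_t(x, y)
                phasic_vs_tonic = {
                    "t": t, "df": df_, "pvalue": p,
                    "n_phasic_visits": len(x), "n_tonic_visits": len(y),
                    "mean_phasic": float(np.mean(x)),
                    "mean_tonic": float(np.mean(y)),
                }
    timings["hmm"] = time.time() - t3

    report = PipelineReport(
        config_hash=config.config_hash(),
        stage_matrices=stage_matrices,
        stage_matrices_per_participant=per_part,
        intra_thalamic=intra_df,
        dfc_table=dfc_table,
        lme_table=lme_table,
        model=model,
        labeling=labeling,
        state_fc=state_fc,
        state_fc_relative=state_rel,
        state_intra_thalamic=state_intra,
        phasic_outlier=phasic_outlier,
        phasic_vs_tonic=phasic_vs_tonic,
        timings=timings,
    )
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def write_report(
    report: PipelineReport, config: PipelineConfig, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.dfc_table.to_csv(out / "dfc_windows.tsv", sep="\t", index=False)
    if len(report.lme_table):
        report.lme_table.to_csv(out / "lme_contrasts.tsv", sep="\t", index=False)
    report.intra_thalamic.to_csv(out / "intra_thalamic_by_stage.tsv", sep="\t")
    for stage, mat in report.stage_matrices.items():
        if mat is not None:
            mat.to_frame().to_csv(out / f"stage_fc_{stage}.tsv", sep="\t")
    if report.model is not None:
        report.model.to_json(out / "hmm_model.json")
    summary = {
        "config_hash": report.config_hash,
        "config": config.analysis_fields(),
        "timings": report.timings,
    }
    if report.labeling is not None:
        summary["state_to_stage"] = {
            str(k): v for k, v in report.labeling.state_to_stage.items()
        }
        summary["phasic_state"] = report.labeling.phasic_state
        summary["tonic_state"] = report.labeling.tonic_state
        summary["conflict"] = report.labeling.conflict
        summary["report"] = report.labeling.report
    if report.state_intra_thalamic is not None:
        summary["state_intra_thalamic"] = [
            float(v) for v in report.state_intra_thalamic
        ]
    if report.phasic_outlier is not None:
        summary["phasic_outlier_z"] = report.phasic_outlier[0]
        summary["phasic_outlier_p"] = report.phasic_outlier[1]
    if report.phasic_vs_tonic is not None:
        summary["phasic_vs_tonic"] = report.phasic_vs_tonic
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=str)
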