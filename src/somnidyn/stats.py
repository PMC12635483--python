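"""Stage contrasts, family-wise error control, and REM sub-state tests.

Window-level FC values are compared across sleep stages with a linear
mixed-effects model, ``fc_z ~ stage + (1 | participant)``, fitted by REML
(statsmodels MixedLM); Wald z-tests give per-stage contrasts against the
reference stage (Wake).  Family-wise error is controlled by Bonferroni
(default) or Holm over the 190 unique network-pair tests (19 networks,
self-pairs included).  The phasic-REM outlier test standardizes a per-state
scalar against the mean and SD over all K states; phasic-vs-tonic FC is
compared by a Welch two-sample t-test on per-visit FC estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io_atlas import STAGES


def n_network_comparisons(n_networks: int = 19) -> int:
    """Number of unique network-pair FC tests, self-pairs included:
    C(n, 2) + n = n (n + 1) / 2; for 19 networks this is 190."""
    return n_networks * (n_networks + 1) // 2


@dataclass
class LmeResult:
    """Per-pair stage contrasts versus the reference stage."""

    network_pair: tuple[str, str]
    reference_stage: str
    contrasts: pd.DataFrame  # index = stage; estimate, se, stat, pvalue
    n_obs: int
    n_participants: int
    converged: bool = True
    method: str = "mixedlm-reml"
    fwe_significant: dict[str, bool] = field(default_factory=dict)


def fit_lme(
    dfc_table: pd.DataFrame,
    pair: tuple[str, str] | None = None,
    reference_stage: str = "Wake",
) -> LmeResult:
    """Fit ``fc_z ~ stage + (1 | participant)`` to window-level FC values.

    ``dfc_table`` needs columns participant, stage, fc_z (and network_a/b if
    ``pair`` is given, to select the rows).  With a single participant the
    random intercept is degenerate and the model falls back to OLS with a
    warning.  Non-convergence is reported via ``converged=False``.
    """
    df = dfc_table
    if pair is not None:
        a, b = sorted(pair)
        key = df[["network_a", "network_b"]].apply(sorted, axis=1)
        df = df[key.apply(lambda x: x == [a, b])]
    else:
        a, b = ("", "")
        if {"network_a", "network_b"} <= set(df.columns):
            ua, ub = df["network_a"].unique(), df["network_b"].unique()
            if len(ua) == 1 and len(ub) == 1:
                a, b = str(ua[0]), str(ub[0])
    df = df.dropna(subset=["fc_z"]).copy()
    stages_present = [s for s in STAGES if s in set(df["stage"])]
    if len(stages_present) < 2:
        raise ValueError("need at least two stages to contrast")
    if reference_stage not in stages_present:
        raise ValueError(f"reference stage {reference_stage!r} absent")
    df["stage"] = pd.Categorical(
        df["stage"],
        categories=[reference_stage]
        + [s for s in stages_present if s != reference_stage],
    )
    n_participants = df["participant"].nunique()
    formula = "fc_z ~ C(stage)"
    method = "mixedlm-reml"
    converged = True
    if n_participants < 2:
        warnings.warn(
            "single participant: random intercept degenerate, using OLS",
            stacklevel=2,
        )
        fit = smf.ols(formula, data=df).fit()
        params, bse = fit.params, fit.bse
        stats_, pvals = fit.tvalues, fit.pvalues
        method = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["participant"])
            fit = model.fit(reml=True)
        converged = bool(getattr(fit, "converged", True))
        params, bse = fit.params, fit.bse
        stats_, pvals = fit.tvalues, fit.pvalues

    rows = {}
    for s in stages_present:
        if s == reference_stage:
            continue
        name = f"C(stage)[T.{s}]"
        rows[s] = {
            "estimate": float(params[name]),
            "se": float(bse[name]),
            "stat": float(stats_[name]),
            "pvalue": float(pvals[name]),
        }
    return LmeResult(
        network_pair=(a, b),
        reference_stage=reference_stage,
        contrasts=pd.DataFrame(rows).T,
        n_obs=len(df),
        n_participants=n_participants,
        converged=converged,
        method=method,
    )


def fwe_correct(
    pvals,
    alpha: float = 0.05,
    method: str = "bonferroni",
    n_comparisons: int | None = None,
) -> tuple[np.ndarray, float]:
    """Family-wise error flags for a vector of p-values.

    Bonferroni (default) compares each p against ``alpha / n_comparisons``
    (``n_comparisons`` defaults to ``len(pvals)`` but may be set to the full
    family size, e.g. 190, when only a subset of pairs was fitted).  Holm is
    the step-down variant (always over ``len(pvals)``).  Returns (flags,
    per-test threshold); for Holm the threshold is the largest rejected
    p-value's cutoff (alpha/m if nothing is rejected at step one).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = n_comparisons if n_comparisons is not None else len(p)
        thresh = alpha / m
        return p <= thresh, thresh
    if method == "holm":
        m = len(p)
        order = np.argsort(p)
        flags = np.zeros(m, dtype=bool)
        thresh = alpha / m
        for rank, idx in enumerate(order):
            cut = alpha / (m - rank)
            if p[idx] <= cut:
                flags[idx] = True
                thresh = cut
            else:
                break
        return flags, thresh
    raise ValueError(f"unknown FWE method {method!r}")


def state_outlier_z(values, target_state: int) -> tuple[float, float]:
    """Is one state's scalar an outlier against all K states?

    z = (v_target − mean(v)) / sd(v) with sd over all states (K−1
    normalization); two-sided normal p.  Zero spread is an error.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("no variation across states (sd = 0)")
    z = float((v[target_state] - v.mean()) / sd)
    p = float(2.0 * (1.0 - sps.norm.cdf(abs(z))))
    return z, p


def two_sample_t(x, y, welch: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test (Welch by default): returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def lme_all_pairs(
    dfc_table: pd.DataFrame,
    alpha: float = 0.05,
    fwe_method: str = "bonferroni",
    n_comparisons: int | None = None,
    reference_stage: str = "Wake",
) -> pd.DataFrame:
    """Fit the stage-contrast LME for every network pair in a long table.

    Returns one row per (pair, non-reference stage) with estimate, p-value
    and FWE flag.  ``n_comparisons`` defaults to the number of distinct pairs
    in the table.
    """
    pairs = (
        dfc_table[["network_a", "network_b"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    records = []
    for a, b in pairs:
        sub = dfc_table[
            (dfc_table["network_a"] == a) & (dfc_table["network_b"] == b)
        ]
        if sub["fc_z"].notna().sum() == 0:
            continue
        try:
            res = fit_lme(sub, reference_stage=reference_stage)
        except ValueError:
            continue
        for stage, row in res.contrasts.iterrows():
            records.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "stage": stage,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "stat": row["stat"],
                    "pvalue": row["pvalue"],
                    "converged": res.converged,
                    "n_obs": res.n_obs,
                }
            )
    out = pd.DataFrame(records)
    if len(out):
        m = n_comparisons or out[["network_a", "network_b"]].drop_duplicates().shape[0]
        flags, thresh = fwe_correct(
            out["pvalue"].to_numpy(), alpha=alpha, method=fwe_method,
            n_comparisons=m if fwe_method == "bonferroni" else None,
        )
        out["fwe_significant"] = flags
        out.attrs["fwe_threshold"] = thresh
        out.attrs["n_comparisons"] = m
    return out
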