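"""Maximally selected survival cutpoints, log-rank tests, and nested Cox
likelihood-ratio tests.

``optimal_cutpoint`` dichotomizes samples by a continuous marker (here,
promoter methylation) at the threshold maximizing the standardized two-group
log-rank statistic, over all candidate thresholds that leave at least a
minimum fraction (default 0.1) of samples on each side — the maximally
selected rank statistic behind survminer's ``surv_cutpoint``. The reported
two-group p-value is the naive log-rank p, as Kaplan-Meier panels
conventionally show; an optional permutation-corrected p accounts for the
optimism introduced by selecting the cutpoint.

``nested_cox_lr`` fits a sequence of strictly nested Cox proportional-hazards
models (Efron tie handling, via lifelines) and reports the likelihood-ratio
increment 2*(loglik_larger - loglik_smaller) of each step with a chi-square
p-value on the added parameter count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError
from scipy import stats

logger = logging.getLogger(__name__)

MIN_GROUP_PROP = 0.1

DEFAULT_TIERS = (
    ("age", "sex"),
    ("age", "sex", "who_category"),
    ("age", "sex", "who_category", "lncrna_cluster"),
)


@dataclass
class CutpointResult:
    """A maximally selected split of samples into low/high marker groups."""

    cutpoint: float
    max_stat: float  # |standardized log-rank| at the cutpoint
    groups: pd.Series  # sample -> {"low", "high"}
    n_low: int
    n_high: int
    logrank_p: float  # naive two-group log-rank p at the chosen split
    corrected_p: float | None = None


class CutpointError(ValueError):
    """No candidate threshold satisfies the minimum group proportion."""


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_group: np.ndarray
                ) -> tuple[float, float, float]:
    """Observed events, expectation and hypergeometric variance for a group.

    Standard two-group log-rank accounting at each distinct event time.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), in_group[order].astype(bool)
    n = len(t)
    O = E = V = 0.0
    i = 0
    at_risk = n
    at_risk_g = int(g.sum())
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            d_g = int((e[i:j] & g[i:j]).sum())
            O += d_g
            E += d * at_risk_g / at_risk
            if at_risk > 1:
                V += (
                    d * (at_risk_g / at_risk) * (1 - at_risk_g / at_risk)
                    * (at_risk - d) / (at_risk - 1)
                )
        at_risk -= j - i
        at_risk_g -= int(g[i:j].sum())
        i = j
    return O, E, V


def logrank_test(
    groups: Mapping[str, object] | pd.Series,
    time: pd.Series,
    event: pd.Series,
) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and two-sided p."""
    groups = pd.Series(groups)
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(labels)}")
    idx = groups.dropna().index
    t = time.loc[idx]
    e = event.loc[idx]
    if e.sum() < 1:
        raise ValueError("need at least one event")
    res = lls.logrank_test(
        t[groups == labels[0]], t[groups == labels[1]],
        event_observed_A=e[groups == labels[0]],
        event_observed_B=e[groups == labels[1]],
    )
    return float(res.test_statistic), float(res.p_value)


def _candidate_stats(
    values: np.ndarray, time: np.ndarray, event: np.ndarray, min_count: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate cutpoints (midpoints of consecutive distinct values kept by
    the group-size constraint), their |z| statistics and low-group sizes."""
    distinct = np.unique(values)
    cuts, zs, n_lows = [], [], []
    n = len(values)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = (lo + hi) / 2.0
        low = values <= cut
        n_low = int(low.sum())
        if n_low < min_count or n - n_low < min_count:
            continue
        O, E, V = _logrank_oe(time, event, low)
        z = (O - E) / np.sqrt(V) if V > 0 else 0.0
        cuts.append(cut)
        zs.append(abs(z))
        n_lows.append(n_low)
    return np.array(cuts), np.array(zs), np.array(n_lows)


def optimal_cutpoint(
    values: Mapping[str, float] | pd.Series,
    time: pd.Series,
    event: pd.Series,
    min_prop: float = MIN_GROUP_PROP,
    corrected_p: bool = False,
    n_perm: int = 200,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for one continuous marker.

    Every threshold between consecutive distinct marker values leaving at
    least ``min_prop`` of samples on each side is scored by the standardized
    log-rank statistic; the maximizer wins, with ties broken toward the more
    balanced split (then toward the smaller cutpoint). With ``corrected_p``
    the selection-adjusted p-value is estimated by recomputing the maximal
    statistic on permuted marker values.
    """
    values = pd.Series(values, dtype=float).dropna()
    idx = values.index
    t = time.loc[idx].to_numpy(dtype=float)
    e = event.loc[idx].to_numpy(dtype=int)
    v = values.to_numpy()
    if len(np.unique(v)) < 2:
        raise CutpointError("need >= 2 distinct marker values")
    if e.sum() < 1:
        raise CutpointError("need >= 1 event")
    n = len(v)
    min_count = int(np.ceil(min_prop * n))
    cuts, zs, n_lows = _candidate_stats(v, t, e, min_count)
    if len(cuts) == 0:
        raise CutpointError(
            f"no admissible split leaves >= {min_prop:.0%} of {n} samples per group"
        )
    balance = np.abs(n_lows - (n - n_lows))
    # lexicographic: max |z|, then most balanced, then smallest cutpoint;
    # |z| is rounded so exact statistical ties are not broken by float noise
    order = np.lexsort((cuts, balance, -np.round(zs, 9)))
    best = order[0]
    cut = float(cuts[best])
    groups = pd.Series(np.where(v <= cut, "low", "high"), index=idx)
    _, p_naive = logrank_test(groups, time.loc[idx], event.loc[idx])

    corrected = None
    if corrected_p:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            vp = rng.permutation(v)
            _, zp, _ = _candidate_stats(vp, t, e, min_count)
            if len(zp) and zp.max() >= zs[best]:
                exceed += 1
        corrected = (1 + exceed) / (n_perm + 1)

    return CutpointResult(
        cutpoint=cut, max_stat=float(zs[best]), groups=groups,
        n_low=int(n_lows[best]), n_high=int(n - n_lows[best]),
        logrank_p=p_naive, corrected_p=corrected,
    )


# ---------------------------------------------------------------------------
# Nested Cox likelihood-ratio tests
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-code categorical covariates (drop-first) for a Cox design.

    Exactly duplicated and zero-variance columns are dropped (with a
    warning): they carry no information, so a redundant added covariate
    contributes a likelihood-ratio increment of zero rather than a singular
    fit.
    """
    X = df.loc[:, list(covariates)].copy()
    cat_cols = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    if cat_cols:
        X = pd.get_dummies(X, columns=cat_cols, drop_first=True, dtype=float)
    X = X.astype(float)
    dup = X.T.duplicated()
    flat = X.nunique() <= 1
    drop = X.columns[dup.to_numpy() | flat.to_numpy()]
    if len(drop):
        warnings.warn(f"redundant design columns dropped: {list(drop)}")
        X = X.drop(columns=drop)
    return X


def nested_cox_lr(
    surv: pd.DataFrame,
    tiers: Sequence[Sequence[str]] = DEFAULT_TIERS,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Likelihood-ratio increments along strictly nested Cox models.

    Each tier is a covariate set that must contain the previous tier. Models
    are fit by partial-likelihood maximization with Efron tie handling; the
    increment statistic is ``2 * (ll_i - ll_{i-1})`` with a chi-square p on
    the added parameter count. Non-convergence is reported per tier rather
    than raised. Returns one row per tier with columns
    ``tier, covariates, n_params, log_likelihood, lr_vs_null, delta_lr,
    delta_df, p, converged``.
    """
    for small, big in zip(tiers[:-1], tiers[1:]):
        if not set(small) < set(big):
            raise ValueError(f"tiers must be strictly nested: {small} vs {big}")
    rows = []
    prev_ll: float | None = None
    prev_df = 0
    for i, covs in enumerate(tiers):
        X = _design(surv, covs)
        data = pd.concat([surv[[time_col, event_col]], X], axis=1)
        # flag separation: a dummy level with no events
        for col in X.columns:
            if X[col].nunique() == 2 and surv.loc[X[col] == 1, event_col].sum() == 0:
                warnings.warn(f"tier {i}: covariate level {col!r} has no events (separation)")
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data, duration_col=time_col, event_col=event_col)
                ll = float(cph.log_likelihood_)
                lr_null = float(cph.log_likelihood_ratio_test().test_statistic)
            converged = True
        except ConvergenceError as err:
            logger.warning("tier %d failed to converge: %s", i, err)
            ll = np.nan
            lr_null = np.nan
            converged = False
        n_params = X.shape[1]
        if prev_ll is None or not converged or np.isnan(prev_ll):
            delta_lr, delta_df, p = np.nan, n_params - prev_df, np.nan
        else:
            delta_lr = 2.0 * (ll - prev_ll)
            delta_df = n_params - prev_df
            p = float(stats.chi2.sf(max(delta_lr, 0.0), df=delta_df))
        rows.append(
            {"tier": i, "covariates": "+".join(covs), "n_params": n_params,
             "log_likelihood": ll,
             "lr_vs_null": lr_null,
             "delta_lr": delta_lr, "delta_df": delta_df, "p": p,
             "converged": converged}
        )
        prev_ll, prev_df = ll, n_params
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier export
# ---------------------------------------------------------------------------


def km_coordinates(
    groups: Mapping[str, object] | pd.Series,
    time: pd.Series,
    event: pd.Series,
) -> pd.DataFrame:
    """Kaplan-Meier step coordinates per group, for plotting or export."""
    groups = pd.Series(groups)
    frames = []
    for label, members in groups.groupby(groups):
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[members.index], event.loc[members.index], label=str(label))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = str(label)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be binary")
    return df
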