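"""Responder labeling at the PFS cut-off and survival analysis.

Progression-free survival (PFS) runs from treatment start to progression
or death; patients alive without progression are censored at last
follow-up.  A patient is a *poor responder* when the event occurred before
the cut-off (default 274 days = 9 months at 365.25/12 days per month,
rounded).  A sample censored *before* the cut-off is unevaluable for
classification — its true 9-month status is unknown — and is excluded
from training with a warning.

Kaplan-Meier estimation, the (unweighted) logrank test, and Cox
proportional-hazards fits (Efron tie handling) are delegated to lifelines.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .datatypes import GOOD, POOR, PipelineError, UNFAVORABLE

logger = logging.getLogger(__name__)

#: 9 months at 365.25/12 days per month, rounded
DEFAULT_CUTOFF_DAYS = 274


@dataclass
class ResponderLabels:
    """Good/poor dichotomy at the PFS cut-off.

    ``labels`` holds good/poor for evaluable samples only; samples censored
    before the cut-off appear in ``unevaluable``.
    """

    labels: pd.Series
    unevaluable: list[str]
    cutoff_days: float

    @property
    def n_poor(self) -> int:
        return int((self.labels == POOR).sum())

    @property
    def n_good(self) -> int:
        return int((self.labels == GOOD).sum())


def label_responders(
    clinical: pd.DataFrame, cutoff_days: float = DEFAULT_CUTOFF_DAYS
) -> ResponderLabels:
    """Poor iff event observed before the cut-off; censored-early samples
    are flagged unevaluable rather than silently labeled."""
    pfs = clinical["pfs_days"].astype(float)
    event = clinical["event"].astype(bool)
    poor = event & (pfs < cutoff_days)
    unevaluable = list(clinical.index[~event & (pfs < cutoff_days)])
    if unevaluable:
        logger.warning(
            "%d samples censored before %.0f days are unevaluable: %s",
            len(unevaluable), cutoff_days, unevaluable[:10],
        )
    evaluable = clinical.index.difference(unevaluable, sort=False)
    labels = pd.Series(
        np.where(poor.loc[evaluable], POOR, GOOD), index=evaluable, name="class"
    )
    return ResponderLabels(labels=labels, unevaluable=unevaluable, cutoff_days=cutoff_days)


@dataclass
class KmEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.time,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def kaplan_meier(
    times: pd.Series,
    events: pd.Series,
    groups: Optional[pd.Series] = None,
) -> dict[str, KmEstimate]:
    """Kaplan-Meier estimate per group (single group "all" when omitted)."""
    if groups is None:
        groups = pd.Series("all", index=times.index)
    out: dict[str, KmEstimate] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        table = kmf.event_table
        med = kmf.median_survival_time_
        out[str(g)] = KmEstimate(
            group=str(g),
            time=table.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            at_risk=table["at_risk"].to_numpy(),
            events=table["observed"].to_numpy(),
            median=float(med) if np.isfinite(med) else float("inf"),
            n=int(sel.sum()),
        )
    return out


def logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Unweighted logrank chi-square (df = k-1) and p-value."""
    if events.astype(bool).sum() == 0:
        logger.warning("logrank: no events observed; statistic undefined")
        return float("nan"), float("nan")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("logrank requires at least two groups")
    if len(levels) == 2:
        a, b = (groups == levels[0]), (groups == levels[1])
        res = logrank_test(times[a], times[b], events[a], events[b])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with 95% Wald confidence intervals."""

    summary: pd.DataFrame  # columns: coef, hr, ci_lower, ci_upper, p
    n: int
    n_events: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": self.n,
            "n_events": self.n_events,
            "covariates": {
                cov: {
                    k: (None if isinstance(v, float) and math.isnan(v) else float(v))
                    for k, v in row.items()
                }
                for cov, row in self.summary.to_dict(orient="index").items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def cox_fit(
    times: pd.Series, events: pd.Series, covariates: pd.DataFrame
) -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    Ties are handled with the Efron approximation.  Non-convergence or
    complete separation raises a diagnostic error.
    """
    if events.astype(bool).sum() == 0:
        raise ValueError("cox_fit requires at least one event")
    df = covariates.astype(float).copy()
    df["_time"] = times.astype(float)
    df["_event"] = events.astype(bool)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:  # pragma: no cover - diagnostic path
        raise PipelineError(
            f"cox_fit failed to converge (possible separation or "
            f"collinearity): {exc}"
        ) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary, n=len(df), n_events=int(df["_event"].sum())
    )


def encode_covariates(
    clinical: pd.DataFrame, profile: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Dummy-code the standard clinical covariates for a Cox model.

    CTC count dichotomized at 5; disease-free interval in 3 groups as two
    dummies against the <=5y reference; dominant relapse site as
    visceral vs non-visceral; optionally the unfavorable-profile call.
    """
    cov = pd.DataFrame(index=clinical.index)
    if "ctc_group" in clinical.columns:
        cov["ctc_ge5"] = (clinical["ctc_group"] == ">=5").astype(float)
    if "dfi_group" in clinical.columns:
        cov["dfi_gt5y"] = (clinical["dfi_group"] == ">5y").astype(float)
        cov["dfi_metastatic"] = (
            clinical["dfi_group"] == "metastatic-at-diagnosis"
        ).astype(float)
    if "relapse_site" in clinical.columns:
        cov["visceral"] = (clinical["relapse_site"] == "visceral").astype(float)
    if profile is not None:
        cov["unfavorable_profile"] = (
            profile.reindex(clinical.index) == UNFAVORABLE
        ).astype(float)
    return cov


def km_to_tsv(estimates: dict[str, KmEstimate], path: str | Path) -> None:
    pd.concat([e.to_frame() for e in estimates.values()], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
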