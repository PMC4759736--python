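"""Diagnostic 2x2 test performance of the profile against observed outcome.

Positive class = poor responder (progression or death before the PFS
cut-off); a positive call = unfavorable profile.  The chi-square is the
uncorrected Pearson statistic on the 2x2 table (df = 1, no Yates
continuity correction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FAVORABLE, GOOD, POOR, UNFAVORABLE, profile_from_class


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of profile x observed outcome.

    ``tp`` = unfavorable profile & poor responder; ``tn`` = favorable
    profile & good responder; ``fp``/``fn`` accordingly.
    """

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def to_frame(self) -> pd.DataFrame:
        """Table laid out as rows = observed (poor responder no/yes),
        columns = profile (favorable/unfavorable), with totals."""
        frame = pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=pd.Index(["no", "yes"], name="poor_responder"),
            columns=pd.Index([FAVORABLE, UNFAVORABLE], name="profile"),
        )
        frame["total"] = frame.sum(axis=1)
        frame.loc["total"] = frame.sum(axis=0)
        return frame


def confusion(predicted: pd.Series, observed: pd.Series) -> ConfusionTable:
    """Cross-tabulate profile calls against observed responder status.

    ``predicted`` takes values favorable/unfavorable (good/poor calls are
    accepted and mapped); ``observed`` is the true responder class
    (good/poor) or a boolean poor-responder indicator.
    """
    predicted = predicted.copy()
    if set(predicted.unique()) <= {GOOD, POOR}:
        predicted = profile_from_class(predicted)
    if not set(predicted.unique()) <= {FAVORABLE, UNFAVORABLE}:
        raise ValueError("predicted calls must be favorable/unfavorable")
    if observed.dtype == bool:
        poor = observed
    elif set(observed.unique()) <= {GOOD, POOR}:
        poor = observed == POOR
    else:
        raise ValueError("observed must be good/poor or boolean poor indicator")
    if set(predicted.index) != set(observed.index):
        raise ValueError("predicted and observed cover different samples")
    poor = poor.reindex(predicted.index)
    unfav = predicted == UNFAVORABLE
    return ConfusionTable(
        tn=int((~unfav & ~poor).sum()),
        fp=int((unfav & ~poor).sum()),
        fn=int((~unfav & poor).sum()),
        tp=int((unfav & poor).sum()),
    )


@dataclass(frozen=True)
class TestMetrics:
    """Sensitivity/specificity/PPV/NPV plus the uncorrected Pearson test.

    A metric whose denominator is zero is reported as NaN (undefined),
    never as 0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    chi_square: float
    chi_p: float

    def to_dict(self) -> dict:
        return {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in self.__dict__.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(tab: ConfusionTable) -> TestMetrics:
    """Test-performance statistics from a 2x2 table.

    chi-square is Pearson's statistic without continuity correction; its
    p-value is the df=1 upper tail.  Degenerate margins leave the
    chi-square undefined (NaN).
    """
    observed = np.array([[tab.tn, tab.fp], [tab.fn, tab.tp]], dtype=float)
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(observed, correction=False)
    return TestMetrics(
        sensitivity=_ratio(tab.tp, tab.tp + tab.fn),
        specificity=_ratio(tab.tn, tab.tn + tab.fp),
        ppv=_ratio(tab.tp, tab.tp + tab.fp),
        npv=_ratio(tab.tn, tab.tn + tab.fn),
        chi_square=float(chi2),
        chi_p=float(p),
    )
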