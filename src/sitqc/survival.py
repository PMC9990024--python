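"""Kaplan-Meier survival analysis of chilled male lifespan cohorts.

Survival is summarised per treatment with the product-limit estimator and
the restricted mean survival time (area under the curve up to the last
observed time; with complete follow-up this equals the arithmetic mean
lifespan). Treatments are compared pairwise with the log-rank test, the
p-values Holm-adjusted to control the familywise error, and summarised as
a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from statsmodels.stats.multitest import multipletests

from .letters import compact_letter_display

__all__ = [
    "KMCurve",
    "km_estimate",
    "pairwise_logrank",
    "SurvivalModel",
    "SurvivalResults",
]


@dataclass
class KMCurve:
    """Product-limit survival curve for one group.

    ``event_times`` are the distinct death times; ``survival`` the value
    of S(t) just after each, ``at_risk`` and ``n_events`` the risk-set
    size and deaths at each time. ``mean_survival`` is the restricted
    mean (area under S up to the largest observed time, in days).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    mean_survival: float
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): proportion surviving beyond time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(
    times: Sequence[float], events: Sequence[bool] | None = None
) -> KMCurve:
    """Kaplan-Meier estimate for one group of lifespans.

    ``events`` defaults to all True (complete follow-up). Deaths are
    processed before censorings at tied times, the standard convention.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("cannot estimate survival from no records")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    e = np.ones_like(t, dtype=bool) if events is None else np.asarray(events, bool)
    if e.shape != t.shape:
        raise ValueError("times and events differ in length")

    kmf = KaplanMeierFitter().fit(t, event_observed=e)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    event_times = death_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_
    survival = np.array([float(surv.loc[tt].iloc[0]) for tt in event_times])
    rmst = float(restricted_mean_survival_time(kmf, t=float(t.max())))
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=death_rows["at_risk"].to_numpy(dtype=int),
        n_events=death_rows["observed"].to_numpy(dtype=int),
        mean_survival=rmst,
        n=int(t.size),
    )


def pairwise_logrank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise log-rank tests with Holm adjustment and compact letters.

    ``groups`` maps a label to ``(times, events)``. Returns the pairwise
    table (chi-square statistic, raw and Holm-adjusted p-values) and a
    letter per group; sharing a letter means no adjusted significance at
    ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = {}
    for lab in labels:
        t, e = groups[lab]
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if not e.any():
            raise ValueError(f"group {lab!r} has no observed events")
        data[lab] = (t, e)

    pairs = [
        (i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))
    ]
    rows, pvals = [], []
    for i, j in pairs:
        ta, ea = data[labels[i]]
        tb, eb = data[labels[j]]
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        rows.append(
            {
                "group_1": labels[i],
                "group_2": labels[j],
                "statistic": float(res.test_statistic),
                "p_value": float(res.p_value),
            }
        )
        pvals.append(float(res.p_value))
    reject, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    table = pd.DataFrame(rows)
    table["p_holm"] = p_holm
    table["significant"] = reject
    sig = np.zeros((len(labels), len(labels)), dtype=bool)
    for (i, j), rej in zip(pairs, reject):
        sig[i, j] = sig[j, i] = bool(rej)
    return table, compact_letter_display(labels, sig)


class SurvivalModel:
    """Lifespan analysis for the chilling treatments.

    Parameters
    ----------
    data
        Long table with columns ``treatment, replicate, time_days, event``;
        one row per male. Replicates are pooled within treatment.
    """

    def __init__(self, data: pd.DataFrame):
        from .io import validate_lifespans

        self.data = validate_lifespans(data)

    @classmethod
    def from_csv(cls, path) -> "SurvivalModel":
        from .io import read_lifespans

        model = cls.__new__(cls)
        model.data = read_lifespans(path)
        return model

    def fit(self, alpha: float = 0.05) -> "SurvivalResults":
        by_treatment = {}
        groups = {}
        order = self.data["treatment"].unique().tolist()
        for treatment in order:
            sub = self.data[self.data["treatment"] == treatment]
            t = sub["time_days"].to_numpy(dtype=float)
            e = sub["event"].to_numpy(dtype=bool)
            by_treatment[treatment] = km_estimate(t, e)
            groups[treatment] = (t, e)
        if len(order) >= 2:
            pairwise, letters = pairwise_logrank(groups, alpha=alpha)
        else:
            pairwise, letters = pd.DataFrame(), {order[0]: "a"}
        return SurvivalResults(
            model=self, curves=by_treatment, pairwise=pairwise,
            letters=letters, alpha=alpha,
        )


@dataclass
class SurvivalResults:
    """Fitted survival analysis; see :class:`SurvivalModel`."""

    model: SurvivalModel
    curves: dict[str, KMCurve]
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float

    @property
    def mean_survival(self) -> pd.Series:
        return pd.Series(
            {t: c.mean_survival for t, c in self.curves.items()},
            name="mean_survival_days",
        )

    def curves_frame(self) -> pd.DataFrame:
        frames = []
        for treatment, curve in self.curves.items():
            f = curve.to_frame()
            f.insert(0, "treatment", treatment)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Kaplan-Meier survival by treatment", ""]
        for treatment, curve in self.curves.items():
            lines.append(
                f"  {treatment:>8}: n = {curve.n:4d}, mean survival "
                f"{curve.mean_survival:6.1f} d  {self.letters.get(treatment, '')}"
            )
        if len(self.pairwise):
            n_sig = int(self.pairwise["significant"].sum())
            lines.append("")
            lines.append(
                f"  {len(self.pairwise)} pairwise log-rank tests, "
                f"{n_sig} significant after Holm adjustment at "
                f"alpha = {self.alpha}"
            )
        return "\n".join(lines)
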