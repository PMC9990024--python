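"""Flight-test escape ability: rates, rank tests, and a binomial GLM.

The escape rate of a trial is the number of males that flew out of the
flight-test device divided by the number loaded. Treatments are compared
on per-replicate escape rates with the tie-corrected Kruskal-Wallis test
followed by an LSD-style separation on mean ranks (Conover), and the
effect of the second chill duration is modelled with a binomial-response
logistic regression, logit(p) = beta0 + beta1 * duration, fitted by
iteratively reweighted least squares (IRLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .letters import compact_letter_display

__all__ = [
    "SECOND_EXPOSURE_TREATMENTS",
    "EscapeGlmFit",
    "escape_rate",
    "rate_table",
    "kruskal_wallis",
    "pairwise_lsd",
    "fit_escape_glm",
    "predict_escape_probability",
    "EscapeModel",
    "EscapeResults",
]

#: Treatments entering the duration regression (second chill of 25/50/100 min).
SECOND_EXPOSURE_TREATMENTS: tuple[str, ...] = ("2_25", "2_50", "2_100")

_MAX_ITER = 50
_DEV_TOL = 1e-8


def escape_rate(n_escaped: int, n_loaded: int) -> float:
    """Escaped males over loaded males for one trial."""
    if n_loaded <= 0:
        raise ValueError("n_loaded must be positive")
    if not 0 <= n_escaped <= n_loaded:
        raise ValueError("n_escaped must be between 0 and n_loaded")
    return n_escaped / n_loaded


def rate_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean and SE of per-replicate escape rates."""
    rates = trials["n_escaped"] / trials["n_loaded"]
    grouped = rates.groupby(trials["treatment"], sort=False)
    out = grouped.agg(["count", "mean"]).rename(
        columns={"count": "n_replicates", "mean": "rate_mean"}
    )
    out["rate_se"] = grouped.apply(
        lambda r: r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan
    )
    return out.reset_index()


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    When every observation is tied the statistic is 0 and p is 1 by
    convention (the test carries no information).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        arrays.append(v)
    pooled = np.concatenate(arrays)
    if pooled.size < 2:
        raise ValueError("need at least two observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_lsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """LSD-style separation of groups on mean ranks (Conover's procedure).

    Protected by the global Kruskal-Wallis test: when the global p-value
    is at or above ``alpha`` no pair is declared different and all groups
    share one letter. Otherwise pair (i, j) differs when

        |Rbar_i - Rbar_j| > t_{1-alpha/2, N-k} *
            sqrt(S^2 * (N - 1 - H) / (N - k) * (1/n_i + 1/n_j))

    with S^2 the variance of the pooled (tie-averaged) ranks and H the
    tie-corrected Kruskal-Wallis statistic.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    h, p_global = kruskal_wallis(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    k = len(labels)
    if n_total <= k:
        raise ValueError("need more observations than groups")
    ranks = stats.rankdata(pooled)
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, splits)])
    # S^2 = (sum R^2 - N (N+1)^2 / 4) / (N - 1); equals N(N+1)/12 untied.
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    df = n_total - k
    scale = s2 * max(n_total - 1 - h, 0.0) / df

    rows = []
    sig = np.zeros((k, k), dtype=bool)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    for i in range(k):
        for j in range(i + 1, k):
            diff = mean_ranks[i] - mean_ranks[j]
            se = np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
            if se == 0:
                t_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
            else:
                t_stat = diff / se
            p_pair = float(2 * stats.t.sf(abs(t_stat), df))
            significant = p_global < alpha and abs(diff) > tcrit * se
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_rank_1": mean_ranks[i],
                    "mean_rank_2": mean_ranks[j],
                    "t": float(t_stat),
                    "p_value": p_pair,
                    "significant": bool(significant),
                }
            )
            sig[i, j] = sig[j, i] = bool(significant)
    return pd.DataFrame(rows), compact_letter_display(labels, sig)


@dataclass
class EscapeGlmFit:
    """Binomial GLM of escape probability against second-chill duration."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    deviance: float
    null_deviance: float
    converged: bool
    n_obs: int
    n_iter: int
    dummy_columns: list[str] = field(default_factory=list)
    dummy_coefs: dict[str, float] = field(default_factory=dict)


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, n: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(n * (t1 + t2)))


def _irls(
    X: np.ndarray, y: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Logistic IRLS on grouped binomial data (y = successes/n)."""
    beta = np.zeros(X.shape[1])
    dev = np.inf
    converged = False
    it = 0
    cov = np.full((X.shape[1], X.shape[1]), np.nan)
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        xtw = X.T * w
        try:
            beta = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            converged = False
            break
        new_dev = _binomial_deviance(y, np.clip(expit(X @ beta), 1e-12, 1 - 1e-12), n)
        if abs(dev - new_dev) / (abs(new_dev) + 0.1) < _DEV_TOL:
            converged = True
            dev = new_dev
            break
        dev = new_dev
    # Complete separation drives |eta| to infinity; flag, don't report.
    if converged and np.max(np.abs(X @ beta)) > 15:
        converged = False
    if converged:
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = n * mu * (1 - mu)
        cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, dev, converged, it


def fit_escape_glm(
    trials: pd.DataFrame,
    include_influence_dummies: bool = False,
    pooled: bool = False,
) -> EscapeGlmFit:
    """Fit the escape-probability GLM on second-exposure treatments.

    Rows are restricted to treatments with a second chill (durations 25,
    50 and 100 min); controls and the single-chill treatment are not part
    of the duration regression. By default each replicate contributes a
    binomial observation; with ``pooled=True`` replicates are summed per
    duration first.

    ``include_influence_dummies`` adds, after a first pass, one indicator
    column per observation whose absolute Pearson residual exceeds 3 —
    a reproducible reading of dummy-variable mitigation of influential
    points. The added columns are reported in ``dummy_columns``.
    """
    sub = trials[trials["treatment"].isin(SECOND_EXPOSURE_TREATMENTS)].copy()
    sub = sub[sub["second_chill_min"].notna() & (sub["second_chill_min"] > 0)]
    if pooled:
        sub = (
            sub.groupby("second_chill_min", as_index=False)[["n_loaded", "n_escaped"]]
            .sum()
        )
    durations = sub["second_chill_min"].to_numpy(dtype=float)
    if np.unique(durations).size < 2:
        raise ValueError("need at least two distinct second-chill durations")
    n = sub["n_loaded"].to_numpy(dtype=float)
    y = sub["n_escaped"].to_numpy(dtype=float) / n

    X = np.column_stack([np.ones_like(durations), durations])
    beta, cov, dev, converged, it = _irls(X, y, n)

    dummy_columns: list[str] = []
    dummy_coefs: dict[str, float] = {}
    if include_influence_dummies and converged:
        mu = expit(X @ beta)
        pearson = (y * n - n * mu) / np.sqrt(n * mu * (1 - mu))
        flagged = np.where(np.abs(pearson) > 3)[0]
        if flagged.size:
            dummies = np.zeros((len(y), flagged.size))
            for col, idx in enumerate(flagged):
                dummies[idx, col] = 1.0
                dummy_columns.append(f"obs_{idx}")
            X = np.hstack([X, dummies])
            beta, cov, dev, converged, it = _irls(X, y, n)
            dummy_coefs = {
                name: float(b) for name, b in zip(dummy_columns, beta[2:])
            }

    # Null model: common escape probability across durations.
    mu0 = np.clip(np.sum(n * y) / np.sum(n), 1e-12, 1 - 1e-12)
    null_dev = _binomial_deviance(y, np.full_like(y, mu0), n)

    se = np.sqrt(np.diag(cov)) if np.all(np.isfinite(cov)) else np.full(X.shape[1], np.nan)
    return EscapeGlmFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        deviance=float(dev),
        null_deviance=float(null_dev),
        converged=bool(converged),
        n_obs=len(y),
        n_iter=it,
        dummy_columns=dummy_columns,
        dummy_coefs=dummy_coefs,
    )


def predict_escape_probability(fit: EscapeGlmFit, duration: float) -> float:
    """Inverse-logit of the fitted linear predictor at ``duration`` minutes."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    return float(expit(fit.intercept + fit.slope * duration))


class EscapeModel:
    """Flight-test analysis across chilling treatments and controls.

    Parameters
    ----------
    data
        Long table with columns ``treatment, replicate, second_chill_min,
        n_loaded, n_escaped``; one row per flight-device run.
    """

    def __init__(self, data: pd.DataFrame):
        from .io import validate_flight

        self.data = validate_flight(data)

    @classmethod
    def from_csv(cls, path) -> "EscapeModel":
        from .io import read_flight

        model = cls.__new__(cls)
        model.data = read_flight(path)
        return model

    def fit(
        self,
        alpha: float = 0.05,
        include_influence_dummies: bool = False,
        pooled_glm: bool = False,
    ) -> "EscapeResults":
        rates = rate_table(self.data)
        groups = {
            treatment: (sub["n_escaped"] / sub["n_loaded"]).to_numpy()
            for treatment, sub in self.data.groupby("treatment", sort=False)
        }
        h, p = kruskal_wallis(groups)
        lsd_table, letters = pairwise_lsd(groups, alpha=alpha)
        glm = fit_escape_glm(
            self.data,
            include_influence_dummies=include_influence_dummies,
            pooled=pooled_glm,
        )
        return EscapeResults(
            model=self, rates=rates, kw_h=h, kw_p=p,
            lsd=lsd_table, letters=letters, glm=glm, alpha=alpha,
        )


@dataclass
class EscapeResults:
    """Fitted escape-ability analysis; see :class:`EscapeModel`."""

    model: EscapeModel
    rates: pd.DataFrame
    kw_h: float
    kw_p: float
    lsd: pd.DataFrame
    letters: dict[str, str]
    glm: EscapeGlmFit
    alpha: float

    def predict(self, duration: float) -> float:
        return predict_escape_probability(self.glm, duration)

    def summary(self) -> str:
        lines = ["Escape ability by treatment", ""]
        for row in self.rates.itertuples():
            se = f"{100 * row.rate_se:.1f}" if np.isfinite(row.rate_se) else "NA"
            lines.append(
                f"  {row.treatment:>8}: {100 * row.rate_mean:5.1f}% "
                f"(SE {se}%, {row.n_replicates} replicates)  "
                f"{self.letters.get(row.treatment, '')}"
            )
        lines.append("")
        lines.append(
            f"  Kruskal-Wallis H = {self.kw_h:.3f}, p = {self.kw_p:.3g}"
        )
        g = self.glm
        lines.append(
            f"  GLM (second chill): logit(p) = {g.intercept:.3f} "
            f"{g.slope:+.4f} * minutes  (SE {g.se_intercept:.3f}/"
            f"{g.se_slope:.4f}; deviance {g.deviance:.1f} vs null "
            f"{g.null_deviance:.1f}; converged={g.converged})"
        )
        if g.dummy_columns:
            lines.append(f"  influence dummies: {', '.join(g.dummy_columns)}")
        return "\n".join(lines)
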