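"""Sexual competitiveness of sterile males from competition-cage hatch data.

The experimental design places 50 fertile females with fertile males only
(arm ``Hn``), sterile males only (``Hs``), or both in a 1:1:1 ratio
(``Ho``, ``Ho_1_25``, ``Ho_2_25`` for unchilled, once-chilled and
twice-chilled sterile males). Fried's mating-competitiveness index

    C = (Hn - Ho) / (Ho - Hs) * (N / S)

compares the hatch rates of the three cage types, scaled by the ratio of
fertile (N) to sterile (S) males, and induced egg sterility is

    IS = (1 - Ho / Hn) * 100.

Variability is obtained by a stratified nonparametric bootstrap over cages
(the independent experimental unit), resampling cages with replacement
within each arm and recomputing C and IS for every replicate. Between-cage
overdispersion of hatch counts is quantified with a per-arm beta-binomial
maximum-likelihood fit, and competition arms are compared familywise with
Holm-adjusted bootstrap-difference tests summarised as compact letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .letters import compact_letter_display

__all__ = [
    "ARM_ORDER",
    "COMPETITION_ARMS",
    "FriedInputs",
    "FriedResult",
    "BetaBinomFit",
    "FriedUndefinedError",
    "FriedDomainWarning",
    "pooled_hatch_rate",
    "per_cage_hatch_rate",
    "mixture_mean_hatch",
    "fried_index",
    "induced_sterility",
    "bootstrap_fried",
    "fit_beta_binomial",
    "compare_arms",
    "CompetitivenessModel",
    "CompetitivenessResults",
]

#: Canonical processing order for cage arms; fixes the random stream layout.
ARM_ORDER: tuple[str, ...] = ("Hn", "Hs", "Ho", "Ho_1_25", "Ho_2_25")

#: Arms in which fertile and sterile males compete for matings.
COMPETITION_ARMS: tuple[str, ...] = ("Ho", "Ho_1_25", "Ho_2_25")


class FriedUndefinedError(ValueError):
    """Raised when Fried's index is undefined (Ho equals Hs)."""


class FriedDomainWarning(UserWarning):
    """Hatch rates fall outside the domain of Fried's mixture model."""


@dataclass(frozen=True)
class FriedInputs:
    """Hatch rates and male counts entering Fried's equation."""

    hn: float  # hatch rate, fertile-males-only control
    ho: float  # hatch rate, competition cage
    hs: float  # hatch rate, sterile-males-only control
    n_fertile: int = 50
    n_sterile: int = 50

    def __post_init__(self) -> None:
        for name in ("hn", "ho", "hs"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a proportion in [0, 1]")
        if self.n_fertile < 1 or self.n_sterile < 1:
            raise ValueError("male counts must be >= 1")


@dataclass
class FriedResult:
    """Point estimates and bootstrap distributions of C and IS for one arm."""

    arm: str
    C_point: float
    IS_point: float
    C_resamples: np.ndarray
    IS_resamples: np.ndarray
    C_mean: float
    C_se: float
    C_ci95: tuple[float, float]
    IS_mean: float
    IS_se: float
    IS_ci95: tuple[float, float]
    n_undefined: int
    B: int


@dataclass
class BetaBinomFit:
    """Per-arm beta-binomial maximum-likelihood fit of hatch counts."""

    arm: str
    mean_hatch: float
    overdispersion: float
    log_likelihood: float
    converged: bool
    se_mean: float = float("nan")
    se_overdispersion: float = float("nan")
    n_cages: int = 0


def pooled_hatch_rate(eggs_total: Sequence[int], eggs_hatched: Sequence[int]) -> float:
    """Egg-weighted hatch rate: total hatched over total laid, across cages."""
    total = int(np.sum(eggs_total))
    hatched = int(np.sum(eggs_hatched))
    if total <= 0:
        raise ValueError("cannot compute a hatch rate from zero eggs")
    if hatched > total:
        raise ValueError("hatched eggs exceed total eggs")
    return hatched / total


def per_cage_hatch_rate(
    eggs_total: Sequence[int], eggs_hatched: Sequence[int]
) -> float:
    """Unweighted mean of per-cage hatch proportions (cages with eggs)."""
    tot = np.asarray(eggs_total, dtype=float)
    hat = np.asarray(eggs_hatched, dtype=float)
    mask = tot > 0
    if not mask.any():
        raise ValueError("cannot compute a hatch rate from zero eggs")
    return float(np.mean(hat[mask] / tot[mask]))


def mixture_mean_hatch(
    c: float, hn: float, hs: float, n_fertile: int = 50, n_sterile: int = 50
) -> float:
    """Expected competition-cage hatch rate under Fried's mixture model.

    With each female mating a fertile male with probability
    ``N / (N + C*S)`` and a sterile male otherwise, the expected pooled
    hatch rate is ``(N*hn + C*S*hs) / (N + C*S)``. This is the exact
    inverse of :func:`fried_index`.
    """
    if c < 0:
        raise ValueError("competitiveness C must be non-negative")
    denom = n_fertile + c * n_sterile
    if denom <= 0:
        raise ValueError("N + C*S must be positive")
    return (n_fertile * hn + c * n_sterile * hs) / denom


def fried_index(
    hn: float | FriedInputs,
    ho: float | None = None,
    hs: float | None = None,
    n_fertile: int = 50,
    n_sterile: int = 50,
) -> float:
    """Fried's mating-competitiveness index C = (Hn-Ho)/(Ho-Hs) * N/S.

    Accepts either a :class:`FriedInputs` or the individual rates. The
    value can legitimately be negative when the competition cage hatches
    better than the fertile control (Ho > Hn). When ``Ho < Hs`` the
    denominator has the wrong sign for Fried's mixture model and a
    :class:`FriedDomainWarning` is issued alongside the raw value.

    Raises
    ------
    FriedUndefinedError
        When ``Ho == Hs`` (zero denominator).
    """
    if isinstance(hn, FriedInputs):
        inputs = hn
        hn, ho, hs = inputs.hn, inputs.ho, inputs.hs
        n_fertile, n_sterile = inputs.n_fertile, inputs.n_sterile
    if ho is None or hs is None:
        raise TypeError("ho and hs are required when hn is a scalar")
    if n_sterile < 1:
        raise ValueError("number of sterile males must be >= 1")
    if ho == hs:
        raise FriedUndefinedError(
            f"Fried's index undefined: Ho == Hs == {ho}"
        )
    if ho < hs:
        warnings.warn(
            f"Ho={ho} < Hs={hs}: hatch rates outside Fried's model domain; "
            "the returned index is not interpretable as a competitiveness",
            FriedDomainWarning,
            stacklevel=2,
        )
    return (hn - ho) / (ho - hs) * (n_fertile / n_sterile)


def induced_sterility(hn: float, ho: float) -> float:
    """Induced egg sterility IS = (1 - Ho/Hn) * 100, in percent.

    Negative when the competition cage hatches better than the fertile
    control.
    """
    if hn <= 0:
        raise ValueError("Hn must be positive to compute induced sterility")
    return (1.0 - ho / hn) * 100.0


def _arm_arrays(cages: pd.DataFrame, arm: str) -> tuple[np.ndarray, np.ndarray]:
    sub = cages.loc[cages["arm"] == arm]
    return (
        sub["eggs_total"].to_numpy(dtype=np.int64),
        sub["eggs_hatched"].to_numpy(dtype=np.int64),
    )


def _male_counts(cages: pd.DataFrame, arm: str) -> tuple[int, int]:
    sub = cages.loc[cages["arm"] == arm]
    n_vals = sub["n_fertile_males"].unique()
    s_vals = sub["n_sterile_males"].unique()
    if len(n_vals) != 1 or len(s_vals) != 1:
        raise ValueError(
            f"arm {arm}: male counts differ across cages; Fried's N/S is ambiguous"
        )
    return int(n_vals[0]), int(s_vals[0])


def _resample_rates(
    tot: np.ndarray,
    hat: np.ndarray,
    B: int,
    rng: np.random.Generator,
    pooling: str,
) -> np.ndarray:
    """Bootstrap hatch rates for one arm: resample cages with replacement."""
    n = len(tot)
    idx = rng.integers(0, n, size=(B, n))
    if pooling == "weighted":
        tot_b = tot[idx].sum(axis=1).astype(float)
        hat_b = hat[idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(tot_b > 0, hat_b / np.where(tot_b > 0, tot_b, 1), np.nan)
    elif pooling == "per_cage":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot > 0, hat / np.where(tot > 0, tot, 1), np.nan)
        rates = np.nanmean(r[idx], axis=1)
    else:
        raise ValueError(f"unknown pooling {pooling!r}; use 'weighted' or 'per_cage'")
    return rates


def bootstrap_fried(
    cages: pd.DataFrame,
    B: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    pooling: str = "weighted",
) -> dict[str, FriedResult]:
    """Fried's C and induced sterility with cage-bootstrap variability.

    Cages are resampled with replacement *within* each arm (stratified
    cluster bootstrap; the cage is the independent experimental unit), the
    pooled hatch rates, C and IS are recomputed for each of the ``B``
    replicates, and moments plus percentile confidence intervals are
    reported per competition arm. All competition arms share the same
    resampled ``Hn``/``Hs`` controls within a replicate, so the returned
    resample vectors are paired across arms and suitable for
    :func:`compare_arms`.

    Resamples where C is undefined (``Ho_b == Hs_b``) or where the
    denominator has the wrong sign (``Ho_b < Hs_b``) are counted in
    ``n_undefined`` and excluded from the C moments; a warning is issued
    when they exceed 1% of ``B``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    present = [a for a in ARM_ORDER if a in set(cages["arm"])]
    for required in ("Hn", "Hs"):
        if required not in present:
            raise ValueError(f"control arm {required} has no cages")
    comp_arms = [a for a in present if a in COMPETITION_ARMS]
    if not comp_arms:
        raise ValueError("no competition (Ho-type) arm present")

    pool = pooled_hatch_rate if pooling == "weighted" else per_cage_hatch_rate
    point_rates: dict[str, float] = {}
    boot_rates: dict[str, np.ndarray] = {}
    for arm in present:
        tot, hat = _arm_arrays(cages, arm)
        if len(tot) == 0:
            raise ValueError(f"arm {arm} has no cages")
        point_rates[arm] = pool(tot, hat)
        boot_rates[arm] = _resample_rates(tot, hat, B, rng, pooling)

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    results: dict[str, FriedResult] = {}
    for arm in comp_arms:
        n_fertile, n_sterile = _male_counts(cages, arm)
        hn_b, hs_b, ho_b = boot_rates["Hn"], boot_rates["Hs"], boot_rates[arm]
        valid = np.isfinite(hn_b) & np.isfinite(hs_b) & np.isfinite(ho_b)
        defined = valid & (ho_b > hs_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            c_b = np.where(
                defined,
                (hn_b - ho_b) / np.where(defined, ho_b - hs_b, 1.0) * (n_fertile / n_sterile),
                np.nan,
            )
            is_b = np.where(
                valid & (hn_b > 0), (1.0 - ho_b / np.where(hn_b > 0, hn_b, 1.0)) * 100.0, np.nan
            )
        n_undef = int(B - defined.sum())
        if n_undef > 0.01 * B:
            warnings.warn(
                f"arm {arm}: {n_undef}/{B} bootstrap resamples had undefined "
                "or out-of-domain Fried index and were excluded",
                FriedDomainWarning,
                stacklevel=2,
            )
        if n_undef == B:
            c_mean = c_se = float("nan")
            c_ci = (float("nan"), float("nan"))
        else:
            c_def = c_b[defined]
            c_mean = float(np.mean(c_def))
            c_se = float(np.std(c_def, ddof=1)) if c_def.size > 1 else 0.0
            c_ci = tuple(np.percentile(c_def, [lo_q, hi_q]))
        is_def = is_b[np.isfinite(is_b)]
        is_mean = float(np.mean(is_def))
        is_se = float(np.std(is_def, ddof=1)) if is_def.size > 1 else 0.0
        is_ci = tuple(np.percentile(is_def, [lo_q, hi_q]))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FriedDomainWarning)
            try:
                c_point = fried_index(
                    point_rates["Hn"], point_rates[arm], point_rates["Hs"],
                    n_fertile, n_sterile,
                )
            except FriedUndefinedError:
                c_point = float("nan")
        results[arm] = FriedResult(
            arm=arm,
            C_point=float(c_point),
            IS_point=induced_sterility(point_rates["Hn"], point_rates[arm]),
            C_resamples=c_b,
            IS_resamples=is_b,
            C_mean=c_mean,
            C_se=c_se,
            C_ci95=(float(c_ci[0]), float(c_ci[1])),
            IS_mean=is_mean,
            IS_se=is_se,
            IS_ci95=(float(is_ci[0]), float(is_ci[1])),
            n_undefined=n_undef,
            B=B,
        )
    return results


def _beta_binom_nll(
    params: np.ndarray, k: np.ndarray, n: np.ndarray
) -> float:
    mu, rho = params
    if not (0 < mu < 1) or not (0 <= rho < 1):
        return np.inf
    if rho < 1e-10:
        return -float(stats.binom.logpmf(k, n, mu).sum())
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return -float(stats.betabinom.logpmf(k, n, a, b).sum())


def fit_beta_binomial(
    eggs_total: Sequence[int],
    eggs_hatched: Sequence[int],
    arm: str = "",
) -> BetaBinomFit:
    """Beta-binomial ML fit of per-cage hatch counts for one arm.

    The hatch probability of cage *i* is Beta-distributed with mean ``mu``
    and intraclass correlation ``rho`` (so ``rho = 0`` collapses to a plain
    binomial), and ``eggs_hatched[i] ~ BetaBinomial(eggs_total[i], mu, rho)``.
    Maximised numerically over ``(mu, rho)`` with standard errors from the
    finite-difference observed information.

    Requires at least two cages: rho is unidentifiable from a single cage.
    """
    n = np.asarray(eggs_total, dtype=np.int64)
    k = np.asarray(eggs_hatched, dtype=np.int64)
    if len(n) < 2:
        raise ValueError("beta-binomial overdispersion needs >= 2 cages")
    if (n <= 0).all():
        raise ValueError("all cages have zero eggs; nothing to fit")
    if k.sum() == 0 or (k == n).all():
        raise ValueError(
            "all-zero or all-hatched counts put the mean on the boundary; "
            "beta-binomial fit is degenerate"
        )

    mu0 = float(np.clip(k.sum() / n.sum(), 1e-4, 1 - 1e-4))
    # Method-of-moments start for rho from the excess per-cage variance.
    r = k / np.maximum(n, 1)
    var_r = float(np.var(r, ddof=1))
    binom_var = float(np.mean(mu0 * (1 - mu0) / np.maximum(n, 1)))
    denom = mu0 * (1 - mu0)
    rho0 = float(np.clip((var_r - binom_var) / denom if denom > 0 else 0.0, 1e-4, 0.9))

    best = None
    for start in ((mu0, rho0), (mu0, 1e-3), (mu0, 0.1)):
        res = optimize.minimize(
            _beta_binom_nll,
            x0=np.asarray(start),
            args=(k, n),
            method="L-BFGS-B",
            bounds=((1e-6, 1 - 1e-6), (0.0, 0.999)),
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    mu_hat, rho_hat = best.x

    se_mu = se_rho = float("nan")
    try:
        from statsmodels.tools.numdiff import approx_hess

        hess = approx_hess(best.x, _beta_binom_nll, args=(k, n))
        cov = np.linalg.inv(hess)
        if np.all(np.diag(cov) > 0):
            se_mu, se_rho = np.sqrt(np.diag(cov))
    except Exception:  # boundary fits have no valid curvature
        pass

    return BetaBinomFit(
        arm=arm,
        mean_hatch=float(mu_hat),
        overdispersion=float(rho_hat),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        se_mean=float(se_mu),
        se_overdispersion=float(se_rho),
        n_cages=len(n),
    )


def compare_arms(
    results: Mapping[str, FriedResult],
    alpha: float = 0.05,
    metrics: Sequence[str] = ("C", "IS"),
) -> dict[str, tuple[pd.DataFrame, dict[str, str]]]:
    """Familywise comparison of competition arms on C and/or IS.

    Uses the paired bootstrap resample vectors produced by a single
    :func:`bootstrap_fried` call: for each pair of arms the distribution
    of differences yields a two-sided bootstrap p-value, Holm-adjusted
    across pairs to control the familywise error rate, and a compact
    letter display (shared letter = not significantly different).
    """
    arms = [a for a in ARM_ORDER if a in results]
    if len(arms) < 2:
        raise ValueError("need >= 2 arms to compare")
    B = {results[a].B for a in arms}
    if len(B) != 1:
        raise ValueError("resample vectors come from different bootstrap runs")
    for a in arms:
        if results[a].n_undefined == results[a].B and "C" in metrics:
            raise ValueError(f"arm {a}: every bootstrap resample was undefined")

    out: dict[str, tuple[pd.DataFrame, dict[str, str]]] = {}
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for metric in metrics:
        rows = []
        pvals = []
        pairs = [(i, j) for i in range(len(arms)) for j in range(i + 1, len(arms))]
        for i, j in pairs:
            a, b = arms[i], arms[j]
            va = results[a].C_resamples if metric == "C" else results[a].IS_resamples
            vb = results[b].C_resamples if metric == "C" else results[b].IS_resamples
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 2:
                raise ValueError(f"pair ({a}, {b}): too few defined resamples")
            d = va[ok] - vb[ok]
            frac_le = float(np.mean(d <= 0))
            frac_ge = float(np.mean(d >= 0))
            p = min(1.0, max(2 * min(frac_le, frac_ge), 1.0 / ok.sum()))
            ci = np.percentile(d, [lo_q, hi_q])
            rows.append(
                {
                    "arm_1": a,
                    "arm_2": b,
                    "diff_mean": float(np.mean(d)),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "p_boot": p,
                }
            )
            pvals.append(p)
        reject, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        table = pd.DataFrame(rows)
        table["p_holm"] = p_holm
        table["significant"] = reject
        sig = np.zeros((len(arms), len(arms)), dtype=bool)
        for (i, j), rej in zip(pairs, reject):
            sig[i, j] = sig[j, i] = bool(rej)
        out[metric] = (table, compact_letter_display(arms, sig))
    return out


class CompetitivenessModel:
    """Competition-cage analysis: hatch rates, Fried's C, induced sterility.

    Parameters
    ----------
    data
        Long-format cage table with columns ``arm, replicate,
        n_fertile_males, n_sterile_males, n_females, eggs_total,
        eggs_hatched``; one row per cage.
    """

    def __init__(self, data: pd.DataFrame):
        from .io import validate_competition

        self.data = validate_competition(data)

    @classmethod
    def from_csv(cls, path) -> "CompetitivenessModel":
        from .io import read_competition

        model = cls.__new__(cls)
        model.data = read_competition(path)
        return model

    def fit(
        self,
        B: int = 5000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        alpha: float = 0.05,
        pooling: str = "weighted",
    ) -> "CompetitivenessResults":
        """Run the full competitiveness analysis.

        ``B`` bootstrap resamples (cages within arm), significance level
        ``alpha`` for intervals, letters and comparisons, and the hatch
        ``pooling`` convention ('weighted' = egg-weighted pooled rate,
        'per_cage' = unweighted mean of cage proportions).
        """
        cages = self.data
        arms = [a for a in ARM_ORDER if a in set(cages["arm"])]

        hatch_rows = []
        betabinom: dict[str, BetaBinomFit] = {}
        for arm in arms:
            tot, hat = _arm_arrays(cages, arm)
            r = hat[tot > 0] / tot[tot > 0]
            hatch_rows.append(
                {
                    "arm": arm,
                    "n_cages": len(tot),
                    "eggs_total": int(tot.sum()),
                    "eggs_hatched": int(hat.sum()),
                    "hatch_pooled": pooled_hatch_rate(tot, hat),
                    "hatch_cage_mean": per_cage_hatch_rate(tot, hat),
                    "hatch_cage_se": float(np.std(r, ddof=1) / np.sqrt(len(r)))
                    if len(r) > 1
                    else float("nan"),
                }
            )
            if len(tot) >= 2:
                try:
                    betabinom[arm] = fit_beta_binomial(tot, hat, arm=arm)
                except ValueError:
                    pass
        fried = bootstrap_fried(
            cages, B=B, seed=seed, rng=rng, alpha=alpha, pooling=pooling
        )
        comp_arms = [a for a in COMPETITION_ARMS if a in fried]
        comparisons = (
            compare_arms(fried, alpha=alpha) if len(comp_arms) >= 2 else None
        )
        return CompetitivenessResults(
            model=self,
            hatch_table=pd.DataFrame(hatch_rows),
            betabinom=betabinom,
            fried=fried,
            comparisons=comparisons,
            alpha=alpha,
            B=B,
            pooling=pooling,
        )


@dataclass
class CompetitivenessResults:
    """Fitted competitiveness analysis; see :class:`CompetitivenessModel`."""

    model: CompetitivenessModel
    hatch_table: pd.DataFrame
    betabinom: dict[str, BetaBinomFit]
    fried: dict[str, FriedResult]
    comparisons: dict[str, tuple[pd.DataFrame, dict[str, str]]] | None
    alpha: float
    B: int
    pooling: str
    _letters: dict[str, dict[str, str]] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.comparisons is not None:
            self._letters = {m: lett for m, (_, lett) in self.comparisons.items()}

    @property
    def letters_C(self) -> dict[str, str]:
        return self._letters.get("C", {})

    @property
    def letters_IS(self) -> dict[str, str]:
        return self._letters.get("IS", {})

    def fried_table(self) -> pd.DataFrame:
        rows = []
        for arm, res in self.fried.items():
            rows.append(
                {
                    "arm": arm,
                    "C_point": res.C_point,
                    "C_mean": res.C_mean,
                    "C_se": res.C_se,
                    "C_ci_low": res.C_ci95[0],
                    "C_ci_high": res.C_ci95[1],
                    "IS_point": res.IS_point,
                    "IS_mean": res.IS_mean,
                    "IS_se": res.IS_se,
                    "IS_ci_low": res.IS_ci95[0],
                    "IS_ci_high": res.IS_ci95[1],
                    "n_undefined": res.n_undefined,
                    "letters_C": self.letters_C.get(arm, ""),
                    "letters_IS": self.letters_IS.get(arm, ""),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Sexual competitiveness analysis",
            f"  bootstrap resamples B = {self.B}, alpha = {self.alpha}, "
            f"pooling = {self.pooling}",
            "",
            "Hatch rates by arm:",
        ]
        for row in self.hatch_table.itertuples():
            lines.append(
                f"  {row.arm:>8}: pooled {100 * row.hatch_pooled:6.2f}%  "
                f"cage mean {100 * row.hatch_cage_mean:6.2f}% "
                f"(SE {100 * row.hatch_cage_se:.2f}%, {row.n_cages} cages, "
                f"{row.eggs_total} eggs)"
            )
        if self.betabinom:
            lines.append("")
            lines.append("Beta-binomial overdispersion (per arm):")
            for arm, bb in self.betabinom.items():
                lines.append(
                    f"  {arm:>8}: mu = {bb.mean_hatch:.4f}, rho = "
                    f"{bb.overdispersion:.4f}, logL = {bb.log_likelihood:.2f}"
                )
        lines.append("")
        lines.append("Fried competitiveness index and induced sterility:")
        for arm, res in self.fried.items():
            lines.append(
                f"  {arm:>8}: C = {res.C_point:6.3f} "
                f"(boot mean {res.C_mean:6.3f} +/- {res.C_se:.3f}, "
                f"95% CI [{res.C_ci95[0]:.3f}, {res.C_ci95[1]:.3f}]) "
                f"{self.letters_C.get(arm, '')}"
            )
            lines.append(
                f"  {'':>8}  IS = {res.IS_point:6.2f}% "
                f"(boot mean {res.IS_mean:6.2f} +/- {res.IS_se:.2f}, "
                f"95% CI [{res.IS_ci95[0]:.2f}, {res.IS_ci95[1]:.2f}]) "
                f"{self.letters_IS.get(arm, '')}"
            )
            if res.n_undefined:
                lines.append(
                    f"  {'':>8}  ({res.n_undefined}/{res.B} resamples undefined)"
                )
        return "\n".join(lines)
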