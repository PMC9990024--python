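"""Synthetic data with the statistical structure of the three experiments.

Three generators emulate the quality-control assays for chilled sterile
male *Aedes aegypti*:

* competition cages — each of 50 females mates exactly once, a fertile
  male with probability ``N / (N + C*S)`` and a sterile male otherwise,
  lays a Poisson number of eggs, and each egg hatches with a probability
  drawn per (cage x mate type) from a Beta distribution with mean
  ``hatch_fertile`` or ``hatch_sterile`` and intraclass correlation
  ``cage_overdispersion`` (0 = pure binomial). Inverting the resulting
  mixture of hatch rates is exactly Fried's index, which makes the
  generator a parameter-recovery harness for the competitiveness module.
* flight trials — 50 males per run, 11 replicates per treatment; escape
  counts are binomial with logit(p) linear in the duration of the second
  chill (0, 25, 50 or 100 min); the unchilled controls get their own
  intercept.
* survival cohorts — 100 males x 4 replicates per treatment; lifespans
  are Weibull (shared shape, per-treatment scale) rounded up to whole
  days to match daily mortality recording, with complete follow-up.

Default parameter values follow the published experiment: hatch rate
0.3766 for fertile matings, a 50 Gy irradiation dose inducing 99.4%
sterility (so the sterile-mating hatch rate is 0.006 x 0.3766), true
competitiveness 1.16 / 0.32 / 0 for unchilled / once- / twice-chilled
sterile males, and mean lifespans of 67 d (control) falling to 54-56 d
under chilling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .competitiveness import ARM_ORDER, COMPETITION_ARMS

__all__ = [
    "SURVIVAL_TREATMENTS",
    "FLIGHT_TREATMENTS",
    "FLIGHT_CONTROLS",
    "SimulationConfig",
    "simulate_competition_cage",
    "simulate_competition_experiment",
    "simulate_flight_experiment",
    "simulate_lifespans",
]

SURVIVAL_TREATMENTS: tuple[str, ...] = ("control", "1_25", "2_25", "2_50", "2_100")
#: Flight treatments and the duration (min) of their second chill exposure.
FLIGHT_TREATMENTS: dict[str, int] = {"1_25": 0, "2_25": 25, "2_50": 50, "2_100": 100}
FLIGHT_CONTROLS: tuple[str, ...] = ("C_1_25", "C_2_25", "C_2_50", "C_2_100")

_GAMMA_1_25 = math.gamma(1.25)  # Weibull mean factor at shape 4


def _default_c_true() -> dict[str, float]:
    return {"Ho": 1.16, "Ho_1_25": 0.32, "Ho_2_25": 0.0}


def _default_scales() -> dict[str, float]:
    means = {"control": 67.0, "1_25": 56.0, "2_25": 56.0, "2_50": 55.0, "2_100": 54.0}
    return {t: m / _GAMMA_1_25 for t, m in means.items()}


@dataclass
class SimulationConfig:
    """True parameters for all three synthetic experiments, plus the seed.

    ``hatch_sterile`` defaults to ``(1 - 0.994) * hatch_fertile``,
    matching the residual fertility left by a 50 Gy dose. The flight
    escape model is ``logit(p) = escape_logit_intercept +
    escape_logit_slope * second_chill_min`` for treatments, with
    ``escape_control_logit`` as the separate control intercept.
    """

    seed: int
    hatch_fertile: float = 0.3766
    hatch_sterile: float = (1.0 - 0.994) * 0.3766
    c_true_by_arm: dict[str, float] = field(default_factory=_default_c_true)
    n_fertile_males: int = 50
    n_sterile_males: int = 50
    n_females: int = 50
    eggs_per_female_mean: float = 50.0
    cage_overdispersion: float = 0.0
    n_cages_per_arm: int = 4
    flight_n_loaded: int = 50
    flight_replicates: int = 11
    escape_logit_intercept: float = -2.405
    escape_logit_slope: float = -0.0287
    escape_control_logit: float = -0.9377  # logit of the 28.1% mean control rate
    lifespan_shape: float = 4.0
    lifespan_scale_by_treatment: dict[str, float] = field(default_factory=_default_scales)
    n_males_per_survival_replicate: int = 100
    survival_replicates: int = 4

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if not 0.0 < self.hatch_fertile <= 1.0:
            raise ValueError("hatch_fertile must be in (0, 1]")
        if not 0.0 <= self.hatch_sterile < 1.0:
            raise ValueError("hatch_sterile must be in [0, 1)")
        if self.hatch_sterile >= self.hatch_fertile:
            raise ValueError(
                "hatch_sterile must be below hatch_fertile; the mixture is "
                "not identifiable otherwise"
            )
        for arm, c in self.c_true_by_arm.items():
            if arm not in COMPETITION_ARMS:
                raise ValueError(f"unknown competition arm {arm!r}")
            if c < 0:
                raise ValueError(f"c_true for {arm} must be non-negative")
        for name in (
            "n_fertile_males",
            "n_sterile_males",
            "n_females",
            "n_cages_per_arm",
            "flight_n_loaded",
            "flight_replicates",
            "n_males_per_survival_replicate",
            "survival_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.eggs_per_female_mean <= 0:
            raise ValueError("eggs_per_female_mean must be positive")
        if not 0.0 <= self.cage_overdispersion < 1.0:
            raise ValueError("cage_overdispersion must be in [0, 1)")
        if self.lifespan_shape <= 0:
            raise ValueError("lifespan_shape must be positive")
        for t, s in self.lifespan_scale_by_treatment.items():
            if s <= 0:
                raise ValueError(f"lifespan scale for {t} must be positive")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text + "\n" if not text.endswith("\n") else text)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        if "seed" not in d:
            raise ValueError(f"{path}: config must carry an explicit seed")
        return cls.from_dict(d)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _beta_hatch_prob(
    mean: float, rho: float, rng: np.random.Generator
) -> float:
    """Draw one cage-level hatch probability: Beta(mean, ICC rho)."""
    if rho == 0.0 or mean in (0.0, 1.0):
        return mean
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    return float(rng.beta(a, b))


def simulate_competition_cage(
    config: SimulationConfig,
    arm: str,
    rng: np.random.Generator,
    replicate: int = 1,
) -> dict:
    """Simulate one competition cage; returns a cage record (dict).

    Mating follows Fried's mixture: each female independently takes a
    fertile male with probability ``N / (N + C*S)`` (probability 1 in the
    ``Hn`` control, 0 in the ``Hs`` control) and a sterile male otherwise,
    then lays ``Poisson(eggs_per_female_mean)`` eggs that hatch with the
    mate-type hatch probability, Beta-perturbed when
    ``cage_overdispersion > 0``.
    """
    if arm not in ARM_ORDER:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARM_ORDER}")
    if config.n_females < 1:
        raise ValueError("a cage needs at least one female")
    n = config.n_fertile_males
    s = config.n_sterile_males
    if arm == "Hn":
        n_arm, s_arm, p_fertile = n, 0, 1.0
    elif arm == "Hs":
        n_arm, s_arm, p_fertile = 0, s, 0.0
    else:
        c = config.c_true_by_arm.get(arm, 0.0)
        denom = n + c * s
        if denom == 0:
            raise ValueError(f"arm {arm}: N + C*S = 0, no male can mate")
        n_arm, s_arm, p_fertile = n, s, n / denom

    n_fertile_mated = int(rng.binomial(config.n_females, p_fertile))
    n_sterile_mated = config.n_females - n_fertile_mated
    eggs = rng.poisson(config.eggs_per_female_mean, size=config.n_females)
    eggs_fertile = int(eggs[:n_fertile_mated].sum())
    eggs_sterile = int(eggs[n_fertile_mated:].sum())

    rho = config.cage_overdispersion
    p_hn = _beta_hatch_prob(config.hatch_fertile, rho, rng)
    p_hs = _beta_hatch_prob(config.hatch_sterile, rho, rng)
    hatched = int(rng.binomial(eggs_fertile, p_hn)) + int(
        rng.binomial(eggs_sterile, p_hs)
    )
    return {
        "arm": arm,
        "replicate": replicate,
        "n_fertile_males": n_arm,
        "n_sterile_males": s_arm,
        "n_females": config.n_females,
        "eggs_total": eggs_fertile + eggs_sterile,
        "eggs_hatched": hatched,
    }


def simulate_competition_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """All cages of a competition experiment: controls plus every arm in
    ``c_true_by_arm``, ``n_cages_per_arm`` cages each, in canonical order."""
    if rng is None:
        rng = config.rng()
    arms = ["Hn", "Hs"] + [a for a in ARM_ORDER if a in config.c_true_by_arm]
    rows = [
        simulate_competition_cage(config, arm, rng, replicate=rep)
        for arm in arms
        for rep in range(1, config.n_cages_per_arm + 1)
    ]
    return pd.DataFrame(rows)


def simulate_flight_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Flight-device trials: binomial escape counts per replicate.

    Treatments use ``logit(p) = intercept + slope * second_chill_min``
    (the once-chilled treatment sits at duration 0); each control shares
    the single control intercept. Controls carry a missing
    ``second_chill_min`` because they were never chilled.
    """
    if rng is None:
        rng = config.rng()
    rows = []
    for treatment, duration in FLIGHT_TREATMENTS.items():
        p = float(
            expit(config.escape_logit_intercept + config.escape_logit_slope * duration)
        )
        for rep in range(1, config.flight_replicates + 1):
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": rep,
                    "second_chill_min": duration,
                    "n_loaded": config.flight_n_loaded,
                    "n_escaped": int(rng.binomial(config.flight_n_loaded, p)),
                }
            )
    p_control = float(expit(config.escape_control_logit))
    for treatment in FLIGHT_CONTROLS:
        for rep in range(1, config.flight_replicates + 1):
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": rep,
                    "second_chill_min": np.nan,
                    "n_loaded": config.flight_n_loaded,
                    "n_escaped": int(rng.binomial(config.flight_n_loaded, p_control)),
                }
            )
    return pd.DataFrame(rows)


def simulate_lifespans(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Survival cohorts: Weibull lifespans rounded up to whole days.

    Complete follow-up (every death observed), matching an experiment run
    until all adults are dead.
    """
    if rng is None:
        rng = config.rng()
    shape = config.lifespan_shape
    rows = []
    for treatment, scale in config.lifespan_scale_by_treatment.items():
        for rep in range(1, config.survival_replicates + 1):
            draws = scale * rng.weibull(shape, size=config.n_males_per_survival_replicate)
            days = np.maximum(np.ceil(draws), 1.0).astype(int)
            for t in days:
                rows.append(
                    {
                        "treatment": treatment,
                        "replicate": rep,
                        "time_days": int(t),
                        "event": True,
                    }
                )
    return pd.DataFrame(rows)
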