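"""Life-history scenario definitions for the urban red squirrel PVA.

A :class:`LifeHistoryScenario` bundles every demographic parameter a
projection needs: age at first reproduction, survival rates with their
among-year (environmental) SDs, reproductive rates, carrying capacity and
run length.  The park population's defaults ("Sceaux defaults") encode the
published parameterization: polygynous mating, 35 % of breeding females
producing a second annual litter, litter size mean 3 / max 6, sex ratio
1:1, adult annual survival 0.68 (SD 0.12) for females and 0.63 (SD 0.13)
for males, carrying capacity 120, 1000 replicates over 20 years.

Age at first litter (1 or 2 years), juvenile survival (20-50 %) and the
proportion of females breeding at high density (35 % or 50 %) are the
uncertain axes; :func:`scenario_grid` enumerates the 2 x 4 x 2 = 16 scenario
grid explored in the viability analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import yaml

__all__ = [
    "LifeHistoryScenario",
    "ImmigrationPlan",
    "ScenarioError",
    "load_scenario",
    "serialize_scenario",
    "scenario_grid",
    "SCEAUX_DEFAULTS",
]

logger = logging.getLogger(__name__)


class ScenarioError(ValueError):
    """Raised for missing mandatory keys or out-of-range parameter values."""


#: Default parameter values for the Parc de Sceaux population.  Values not
#: published for this population (max_age, male first breeding age, EV SDs of
#: juvenile survival and breeding rate) are package choices, override-able
#: from any config file.
SCEAUX_DEFAULTS: dict[str, float | int] = {
    "age_first_breeding_m": 1,
    "max_age": 8,
    "prob_second_litter": 0.35,
    "litter_size_mean": 3.0,
    "litter_size_max": 6,
    "sex_ratio_birth": 0.5,
    "adult_survival_f": 0.68,
    "adult_survival_f_ev_sd": 0.12,
    "adult_survival_m": 0.63,
    "adult_survival_m_ev_sd": 0.13,
    "juvenile_survival_ev_sd": 0.10,
    "breeding_ev_sd": 0.10,
    "carrying_capacity": 120,
    "initial_n": 120,
    "years": 20,
    "replicates": 1000,
}

#: Keys that have no sensible default and must be present in every config.
MANDATORY_KEYS = ("age_first_litter_f", "juvenile_survival", "prop_females_breeding")

_PROBABILITY_FIELDS = (
    "prop_females_breeding",
    "prob_second_litter",
    "sex_ratio_birth",
    "adult_survival_f",
    "adult_survival_f_ev_sd",
    "adult_survival_m",
    "adult_survival_m_ev_sd",
    "juvenile_survival",
    "juvenile_survival_ev_sd",
    "breeding_ev_sd",
)


@dataclass(frozen=True)
class LifeHistoryScenario:
    """One complete PVA parameterization.

    Parameters
    ----------
    age_first_litter_f
        Age (completed years) at which females produce their first litter.
    age_first_breeding_m
        Minimum male age to sire litters.
    max_age
        Maximum attainable age; individuals die on exceeding it.
    prop_females_breeding
        Annual probability that an adult female breeds (the "high density"
        breeding rate).
    prob_second_litter
        Probability that a breeding female raises a second litter in the
        same year.
    litter_size_mean, litter_size_max
        Mean and maximum litter size; litters are drawn Binomial(max, mean/max).
    sex_ratio_birth
        Probability an offspring is male.
    adult_survival_f, adult_survival_m, juvenile_survival
        Annual survival probabilities; juveniles are the age 0 -> 1 class.
    *_ev_sd
        Among-year (environmental) SDs of the corresponding rates.
    carrying_capacity
        Ceiling population size K, enforced by probabilistic removal.
    initial_n
        Founding population size.
    years, replicates
        Projection horizon and number of stochastic replicates.
    """

    age_first_litter_f: int
    juvenile_survival: float
    prop_females_breeding: float
    age_first_breeding_m: int = 1
    max_age: int = 8
    prob_second_litter: float = 0.35
    litter_size_mean: float = 3.0
    litter_size_max: int = 6
    sex_ratio_birth: float = 0.5
    adult_survival_f: float = 0.68
    adult_survival_f_ev_sd: float = 0.12
    adult_survival_m: float = 0.63
    adult_survival_m_ev_sd: float = 0.13
    juvenile_survival_ev_sd: float = 0.10
    breeding_ev_sd: float = 0.10
    carrying_capacity: int = 120
    initial_n: int = 120
    years: int = 20
    replicates: int = 1000
    #: explicit override for founding above K (e.g. invasion experiments)
    allow_initial_overshoot: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check invariants; raise :class:`ScenarioError` naming the field."""
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ScenarioError(f"{name}={v!r} is not a probability in [0, 1]")
        if self.litter_size_mean > self.litter_size_max:
            raise ScenarioError(
                f"litter_size_mean={self.litter_size_mean} exceeds "
                f"litter_size_max={self.litter_size_max}"
            )
        if self.age_first_litter_f < 1:
            raise ScenarioError("age_first_litter_f must be >= 1 year")
        if self.max_age <= self.age_first_litter_f:
            raise ScenarioError("max_age must exceed age_first_litter_f")
        if self.years < 1:
            raise ScenarioError("years must be >= 1")
        if self.replicates < 1:
            raise ScenarioError("replicates must be >= 1")
        if self.carrying_capacity < 1:
            raise ScenarioError("carrying_capacity must be >= 1")
        if self.initial_n < 0:
            raise ScenarioError("initial_n must be >= 0")
        if not self.allow_initial_overshoot and self.initial_n > self.carrying_capacity:
            raise ScenarioError(
                f"initial_n={self.initial_n} exceeds carrying_capacity="
                f"{self.carrying_capacity}; set allow_initial_overshoot to permit"
            )

    def replace(self, **changes) -> "LifeHistoryScenario":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ImmigrationPlan:
    """Immigration regime: Poisson arrivals from a stable source population.

    The published immigration experiment varied the expected arrival rate
    from 0.2/year (one immigrant every five years) to 5/year, with
    immigrants drawn from the juvenile/subadult (1-2 year) classes of an
    artificially stable source population of 100 animals.
    """

    expected_immigrants_per_year: float = 0.0
    immigrant_min_age: int = 1
    immigrant_max_age: int = 2
    source_size: int = 100
    idealized_source: bool = False  # source never drifts (testing aid)

    def __post_init__(self) -> None:
        if self.expected_immigrants_per_year < 0:
            raise ScenarioError("expected_immigrants_per_year must be >= 0")
        if not (1 <= self.immigrant_min_age <= self.immigrant_max_age):
            raise ScenarioError(
                "require 1 <= immigrant_min_age <= immigrant_max_age"
            )
        if self.enabled and self.source_size < 2:
            raise ScenarioError("source_size must be >= 2 when immigration is on")

    @property
    def enabled(self) -> bool:
        return self.expected_immigrants_per_year > 0


#: Canonical rate values published for the scenario grid.
GRID_AFL = (1, 2)
GRID_SJ = (0.20, 0.30, 0.40, 0.50)
GRID_BREED = (0.35, 0.50)


def scenario_grid(**overrides) -> list[LifeHistoryScenario]:
    """Enumerate the 16 published scenario combinations, in table row order.

    Outer loop: age at first litter (1, 2 years); middle: juvenile survival
    (20, 30, 40, 50 %); inner: breeding females at high density (35, 50 %).
    Keyword overrides (e.g. ``replicates=200``) apply to every scenario.
    """
    grid = []
    for afl in GRID_AFL:
        for sj in GRID_SJ:
            for breed in GRID_BREED:
                grid.append(
                    LifeHistoryScenario(
                        age_first_litter_f=afl,
                        juvenile_survival=sj,
                        prop_females_breeding=breed,
                        **overrides,
                    )
                )
    return grid


def load_scenario(config_text: str) -> LifeHistoryScenario:
    """Parse a flat YAML key/value document into a validated scenario.

    Keys absent from the document fall back to the Sceaux defaults; every
    filled default is logged at INFO level.  The three axes with no
    defensible default (``age_first_litter_f``, ``juvenile_survival``,
    ``prop_females_breeding``) are mandatory.
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml detail
        raise ScenarioError(f"config is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ScenarioError("scenario config must be a flat key/value mapping")

    known = {f.name for f in dataclasses.fields(LifeHistoryScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
    missing = [k for k in MANDATORY_KEYS if k not in raw]
    if missing:
        raise ScenarioError(f"missing mandatory scenario keys: {missing}")

    for key in sorted(known - set(raw)):
        logger.info("scenario key %r not in config; using default", key)

    return LifeHistoryScenario(**raw)


def serialize_scenario(scenario: LifeHistoryScenario) -> str:
    """Render a scenario as the flat YAML dialect read by :func:`load_scenario`."""
    return yaml.safe_dump(scenario.to_dict(), sort_keys=True)
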