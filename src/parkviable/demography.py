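"""Deterministic female demography: life tables, Leslie matrices, lambda.

The asymptotic growth rate of a scenario is obtained from the female life
table it implies, using a pre-breeding birth-pulse census in which age 1 is
the first censused class.  Survivorship is ``l_1 = Sj`` (juvenile survival
from birth to the first census) and ``l_{x+1} = l_x * Sa_f`` thereafter;
fecundity is constant from the age at first litter onward,

    m = prop_females_breeding * (1 + prob_second_litter)
        * litter_size_mean * (1 - sex_ratio_birth)     [daughters/female/yr]

lambda solves the Euler-Lotka equation sum_x l_x m_x lambda^-x = 1 on the
truncated age range, and is cross-checked against the dominant eigenvalue
of the equivalent Leslie matrix.  Generation time is the mean age of
mothers in the stable population, T = sum x l_x m_x lambda^-x / sum l_x
m_x lambda^-x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .scenarios import LifeHistoryScenario

__all__ = [
    "LifeTable",
    "DeterministicResult",
    "build_life_table",
    "leslie_matrix",
    "deterministic_lambda",
    "lambda_surface",
    "annual_fecundity",
    "scenario_lambda",
    "viability_threshold",
]


def annual_fecundity(scenario: LifeHistoryScenario) -> float:
    """Expected daughters per breeding-age female per year."""
    return (
        scenario.prop_females_breeding
        * (1.0 + scenario.prob_second_litter)
        * scenario.litter_size_mean
        * (1.0 - scenario.sex_ratio_birth)
    )


@dataclass(frozen=True)
class LifeTable:
    """Female life table on ages ``1..max_age``.

    ``survivorship[i]`` is l_x, the probability of surviving from birth to
    age ``ages[i]``; ``fecundity[i]`` is m_x, expected daughters per female
    of that age per year.
    """

    ages: np.ndarray
    survivorship: np.ndarray
    fecundity: np.ndarray
    adult_survival_f: float

    def __post_init__(self) -> None:
        lx = np.asarray(self.survivorship, dtype=float)
        if not np.all(np.isfinite(lx)) or not np.all(np.isfinite(self.fecundity)):
            raise ValueError("life table contains non-finite entries")
        if np.any(lx < -1e-12) or np.any(lx > 1 + 1e-12):
            raise ValueError("survivorship outside [0, 1]")
        if np.any(np.diff(lx) > 1e-12):
            raise ValueError("survivorship must be non-increasing in age")


@dataclass(frozen=True)
class DeterministicResult:
    """Asymptotic growth rate and generation time of a life table."""

    lambda_: float
    generation_time: float


def build_life_table(scenario: LifeHistoryScenario) -> LifeTable:
    """Construct the female life table implied by a scenario.

    Subadult females (age 1 under an age-at-first-litter of 2) survive at
    the adult female rate; the published parameter set gives no separate
    subadult rate.
    """
    ages = np.arange(1, scenario.max_age + 1)
    lx = scenario.juvenile_survival * scenario.adult_survival_f ** (ages - 1.0)
    m = annual_fecundity(scenario)
    mx = np.where(ages >= scenario.age_first_litter_f, m, 0.0)
    return LifeTable(
        ages=ages, survivorship=lx, fecundity=mx,
        adult_survival_f=scenario.adult_survival_f,
    )


def leslie_matrix(lt: LifeTable) -> np.ndarray:
    """Leslie matrix of the censused age classes (pre-breeding census).

    Row 0 holds per-capita recruitment to age 1, ``Sj * m_x`` with the
    juvenile survival recovered from ``l_1``; the subdiagonal holds the
    adult survival rate.  The terminal class has no survival (truncation
    at max_age).
    """
    k = len(lt.ages)
    sj = lt.survivorship[0]
    A = np.zeros((k, k))
    A[0, :] = sj * lt.fecundity
    for i in range(k - 1):
        A[i + 1, i] = lt.adult_survival_f
    return A


def _euler_lotka_root(lt: LifeTable) -> float:
    lx, mx, ages = lt.survivorship, lt.fecundity, lt.ages

    def f(lam: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.sum(lx * mx * lam ** (-ages.astype(float)))) - 1.0

    # f is decreasing in lambda; bracket [tiny, 5] always contains the root
    # for the parameter ranges of interest.
    lo, hi = 1e-6, 5.0
    if f(lo) < 0:  # pragma: no cover - requires pathological fecundity
        raise ValueError("Euler-Lotka equation has no root above 1e-6")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def deterministic_lambda(lt: LifeTable) -> DeterministicResult:
    """Solve the Euler-Lotka equation for lambda and the generation time.

    With all-zero fecundity there is no renewal equation; the population
    declines at the adult survival rate, so lambda = Sa_f and the
    generation time is undefined (returned as NaN).
    """
    if np.all(lt.survivorship * lt.fecundity == 0):
        # no reproduction (or no recruit survives): survival-only decline
        return DeterministicResult(
            lambda_=float(lt.adult_survival_f), generation_time=float("nan")
        )
    lam = _euler_lotka_root(lt)
    w = lt.survivorship * lt.fecundity * lam ** (-lt.ages.astype(float))
    T = float(np.sum(lt.ages * w) / np.sum(w))
    return DeterministicResult(lambda_=lam, generation_time=T)


def scenario_lambda(scenario: LifeHistoryScenario) -> DeterministicResult:
    """Convenience: life table construction + Euler-Lotka solve."""
    return deterministic_lambda(build_life_table(scenario))


def lambda_surface(
    base: LifeHistoryScenario,
    sj_values,
    afl_values=(1, 2),
) -> pd.DataFrame:
    """Grid of asymptotic growth rates over juvenile survival and age at
    first litter, mirroring the deterministic sensitivity analysis.

    Returns a DataFrame with columns ``age_first_litter``,
    ``juvenile_survival`` and ``lambda``.
    """
    sj_values = list(sj_values)
    afl_values = list(afl_values)
    if not sj_values or not afl_values:
        raise ValueError("sj_values and afl_values must be non-empty")
    rows = []
    for afl in afl_values:
        for sj in sj_values:
            sc = base.replace(age_first_litter_f=int(afl), juvenile_survival=float(sj))
            res = scenario_lambda(sc)
            rows.append(
                {
                    "age_first_litter": int(afl),
                    "juvenile_survival": float(sj),
                    "lambda": res.lambda_,
                }
            )
    return pd.DataFrame(rows)


def viability_threshold(
    base: LifeHistoryScenario, afl: int, lo: float = 0.01, hi: float = 0.99
) -> float:
    """Juvenile survival at which lambda crosses 1 for a given age at first
    litter (bisection on the Euler-Lotka solution)."""

    def g(sj: float) -> float:
        sc = base.replace(age_first_litter_f=afl, juvenile_survival=sj)
        return scenario_lambda(sc).lambda_ - 1.0

    return float(brentq(g, lo, hi, xtol=1e-10))
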