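"""Simulation-based power and sample size for two-arm, two-visit CT trials.

The endpoint is the 48-week change of a volume-fraction subscore analysed
on its square-root scale.  A trial of ``n_per_arm`` patients per arm is
simulated from the progression LMM::

    SOS_i = mu + u_i + e_i1
    EOS_i = mu + delta (1 - reduction * I(active)) + u_i + e_i2

with ``u_i ~ N(0, tau^2)`` and ``e_ij ~ N(0, sigma^2)`` on the analysis
(square-root) scale: the placebo arm progresses by ``delta`` and the
active arm's progression is reduced by the scenario fraction (10, 30 or
50%).  Each replicate is analysed with the reduced progression LMM
(intercept, time, arm, time x arm) and the treatment effect is the Wald
test of ``time x arm`` at two-sided ``alpha``; power is the rejection
fraction over replicates.

Default scenarios are calibrated to the published reanalysis: progression
0.212 (sqrt %Disease, intercept 2.839) and 0.175 (sqrt %Mucus Plugging,
intercept 1.114).  The between-patient variance comes from the observed
score dispersion; the residual variance — which is what drives the power
of a change-score comparison — is recovered analytically from the
published requirement "110 patients per arm give 0.9 power under a 50%
reduction in %Disease progression" (the variance components of the
original simulation were not published).  The %Mucus Plugging sample size
is then an out-of-sample consistency check, not a fitted quantity.

Seeding uses one master ``SeedSequence`` spawned into per-replicate
streams, so enlarging the replicate count or the grid never reshuffles
earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScenarioParams",
    "PowerEstimate",
    "PowerCurve",
    "simulate_trial",
    "estimate_power",
    "find_n_for_power",
    "disease_scenario",
    "mucus_plugging_scenario",
    "two_sample_power",
    "change_sd_for_power",
]

# Published calibration constants (sqrt-scale intercepts and time effects;
# raw-scale means/SDs used for the between-patient variance).
DISEASE_BASELINE_SQRT = 2.839
DISEASE_PROGRESSION_SQRT = 0.212
DISEASE_MEAN, DISEASE_SD = 9.96, 7.58
MP_BASELINE_SQRT = 1.114
MP_PROGRESSION_SQRT = 0.175
MP_MEAN, MP_SD = 2.14, 2.47
_CALIBRATION_N, _CALIBRATION_POWER, _CALIBRATION_REDUCTION = 110, 0.9, 0.5


@dataclass(frozen=True)
class ScenarioParams:
    """Data-generating parameters of one power scenario (analysis scale)."""

    progression: float
    reduction: float
    var_between: float
    var_residual: float
    baseline_mean: float
    alpha: float = 0.05
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.var_residual < 0:
            raise ValueError("variances must be >= 0")
        if not (0.0 <= self.reduction <= 1.0):
            raise ValueError("reduction must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PowerEstimate:
    n_per_arm: int
    power: float
    mc_se: float
    n_replicates: int
    seed: int
    n_failures: int = 0


@dataclass(frozen=True)
class PowerCurve:
    scenario: ScenarioParams
    estimates: tuple[PowerEstimate, ...]
    smoothed_power: tuple[float, ...]
    target_power: float
    n_star: int | None


def two_sample_power(effect: float, sd_change: float, n_per_arm: int, alpha: float = 0.05) -> float:
    """Exact noncentral-t power of the two-sample change-score comparison."""
    df = 2 * n_per_arm - 2
    ncp = effect / (sd_change * math.sqrt(2.0 / n_per_arm))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def change_sd_for_power(
    effect: float, n_per_arm: int, power: float, alpha: float = 0.05
) -> float:
    """Invert the two-sample power formula for the change-score SD."""
    return float(
        optimize.brentq(
            lambda sd: two_sample_power(effect, sd, n_per_arm, alpha) - power,
            1e-6,
            100.0,
            xtol=1e-10,
        )
    )


def _calibrated_residual_variance() -> float:
    """Residual variance implied by the published %Disease power statement."""
    effect = _CALIBRATION_REDUCTION * DISEASE_PROGRESSION_SQRT
    sd_change = change_sd_for_power(effect, _CALIBRATION_N, _CALIBRATION_POWER)
    return sd_change**2 / 2.0


def _sqrt_scale_variance(mean: float, sd: float) -> float:
    """Variance on the sqrt scale of a score with the given raw moments.

    If sqrt(Y) ~ N(m, s^2) then E[Y] = m^2 + s^2 and Var(Y) = 2 s^4 +
    4 m^2 s^2; inverting gives s^2 = mean - sqrt(mean^2 - sd^2 / 2).
    """
    disc = mean**2 - sd**2 / 2.0
    if disc < 0:
        raise ValueError("raw moments inconsistent with a squared-normal score")
    return mean - math.sqrt(disc)


def disease_scenario(reduction: float = 0.5, alpha: float = 0.05) -> ScenarioParams:
    """%Disease scenario calibrated to the published reanalysis."""
    vr = _calibrated_residual_variance()
    vb = _sqrt_scale_variance(DISEASE_MEAN, DISEASE_SD) - vr
    return ScenarioParams(
        progression=DISEASE_PROGRESSION_SQRT,
        reduction=reduction,
        var_between=vb,
        var_residual=vr,
        baseline_mean=DISEASE_BASELINE_SQRT,
        alpha=alpha,
    )


def mucus_plugging_scenario(reduction: float = 0.5, alpha: float = 0.05) -> ScenarioParams:
    """%Mucus Plugging scenario; shares the calibrated residual variance."""
    vr = _calibrated_residual_variance()
    vb = _sqrt_scale_variance(MP_MEAN, MP_SD) - vr
    return ScenarioParams(
        progression=MP_PROGRESSION_SQRT,
        reduction=reduction,
        var_between=vb,
        var_residual=vr,
        baseline_mean=MP_BASELINE_SQRT,
        alpha=alpha,
    )


def _simulate_arrays(
    params: ScenarioParams, n_per_arm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (sos, eos, active) arrays for one trial; active is 0/1."""
    n = 2 * n_per_arm
    active = np.repeat([1.0, 0.0], n_per_arm)  # 1:1 allocation
    u = rng.normal(0.0, math.sqrt(params.var_between), n)
    e1 = rng.normal(0.0, math.sqrt(params.var_residual), n)
    e2 = rng.normal(0.0, math.sqrt(params.var_residual), n)
    prog = params.progression * (1.0 - params.reduction * active)
    sos = params.baseline_mean + u + e1
    eos = params.baseline_mean + prog + u + e2
    if params.truncate_at_zero:
        sos = np.maximum(sos, 0.0)
        eos = np.maximum(eos, 0.0)
    return sos, eos, active


def simulate_trial(params: ScenarioParams, n_per_arm: int, seed: int) -> pd.DataFrame:
    """Simulate one trial as a long cohort table (deterministic given seed)."""
    if n_per_arm < 2:
        raise ValueError("need n_per_arm >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sos, eos, active = _simulate_arrays(params, n_per_arm, rng)
    n = 2 * n_per_arm
    pid = [f"P{i:05d}" for i in range(n)]
    arm = np.where(active == 1.0, "active", "placebo")
    rows = {
        "patient_id": pid * 2,
        "visit": ["SOS"] * n + ["EOS"] * n,
        "arm": np.concatenate([arm, arm]),
        "tobramycin": ["no"] * (2 * n),
        "outcome": ["score"] * (2 * n),
        "value": np.concatenate([sos, eos]),
    }
    return pd.DataFrame(rows)


def _interaction_p(sos: np.ndarray, eos: np.ndarray, active: np.ndarray) -> float:
    """Wald p for time x arm in the reduced LMM.

    For a complete two-visit trial this reduces exactly to the two-sample
    t-test on per-patient change scores (same REML estimate, SE and the
    nested within-patient df), which is what the closed-form balanced REML
    route in :mod:`pragmascore.progression` computes.
    """
    d = eos - sos
    d1, d0 = d[active == 1.0], d[active == 0.0]
    n1, n0 = d1.size, d0.size
    est = d1.mean() - d0.mean()
    rss = float(np.sum((d1 - d1.mean()) ** 2) + np.sum((d0 - d0.mean()) ** 2))
    df = n1 + n0 - 2
    s2 = rss / df
    if s2 <= 0:
        return float("nan")
    se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    return float(2.0 * stats.t.sf(abs(est) / se, df))


def estimate_power(
    params: ScenarioParams, n_per_arm: int, n_replicates: int, seed: int
) -> PowerEstimate:
    """Monte-Carlo power of the time x arm Wald test at ``params.alpha``."""
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    if n_per_arm < 2:
        raise ValueError("need n_per_arm >= 2")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rejected = 0
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        sos, eos, active = _simulate_arrays(params, n_per_arm, rng)
        p = _interaction_p(sos, eos, active)
        if math.isnan(p):
            failures += 1
            continue
        if p < params.alpha:
            rejected += 1
    if failures > 0.05 * n_replicates:
        raise RuntimeError(f"{failures}/{n_replicates} replicate fits failed")
    n_ok = n_replicates - failures
    power = rejected / n_ok
    return PowerEstimate(
        n_per_arm=n_per_arm,
        power=power,
        mc_se=math.sqrt(power * (1.0 - power) / n_ok),
        n_replicates=n_replicates,
        seed=seed,
        n_failures=failures,
    )


def find_n_for_power(
    params: ScenarioParams,
    target_power: float,
    n_grid: Sequence[int],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PowerCurve:
    """Estimate power over a sample-size grid and locate the smallest
    adequate per-arm size.

    Raw Monte-Carlo estimates are smoothed by isotonic regression (true
    power is non-decreasing in n); ``n_star`` is the smallest grid point
    whose smoothed power reaches ``target_power``, or None if the grid
    tops out below it.
    """
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty sample-size grid")
    if sorted(n_grid) != n_grid or len(set(n_grid)) != len(n_grid):
        raise ValueError("n_grid must be strictly increasing")
    grid_seeds = np.random.SeedSequence(seed).spawn(len(n_grid))
    estimates = tuple(
        estimate_power(params, n, n_replicates, int(child.generate_state(1)[0] % (2**31)))
        for n, child in zip(n_grid, grid_seeds)
    )
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=True)
    smoothed = iso.fit_transform(
        np.asarray(n_grid, dtype=float), np.asarray([e.power for e in estimates])
    )
    n_star = None
    for n, p in zip(n_grid, smoothed):
        if p >= target_power:
            n_star = int(n)
            break
    return PowerCurve(
        scenario=params,
        estimates=estimates,
        smoothed_power=tuple(float(p) for p in smoothed),
        target_power=float(target_power),
        n_star=n_star,
    )
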