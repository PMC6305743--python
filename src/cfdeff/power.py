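"""Two-sample t-test power and design-effect-corrected sample sizes.

Exact power of the two-sided, equal-variance, equal-allocation two-sample
t test from the noncentral t distribution: with n per group, standardised
effect d = (mu2 - mu1) / sigma, the test statistic under the alternative is
noncentral t with df = 2n - 2 and noncentrality delta = d sqrt(n/2).

Sample sizes planned for independent replicates are inflated by the design
effect of group sampling before use: n_adjusted = ceil(n * deff), applied
per treatment group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay import CORRECTOR, AssayRecord
from .errors import ArgumentError, DegenerateDataError, InsufficientDataError

_N_GUARD = 10**6  # upper bound of the sample-size search


@dataclass(frozen=True)
class PowerSpec:
    """Planning inputs for comparing corrector B against corrector A.

    mu1 is corrector A's mean response (uA/cm^2), sigma the common s.d.,
    and effect_fraction the relative improvement of corrector B (0.2 means
    a 20% higher mean).  The default sigma 0.962 uA/cm^2 is the pooled
    corrector-treated s.d. of the reference 20-patient panel.
    """

    alpha: float = 0.05
    target_power: float = 0.80
    mu1: float = 3.3
    sigma: float = 0.962
    effect_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ArgumentError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise ArgumentError(
                f"target_power must be in (0, 1), got {self.target_power}"
            )
        if self.sigma <= 0:
            raise ArgumentError(f"sigma must be > 0, got {self.sigma}")
        if self.effect_fraction < 0:
            raise ArgumentError(
                f"effect_fraction must be >= 0, got {self.effect_fraction}"
            )

    @property
    def mu2(self) -> float:
        return self.mu1 * (1.0 + self.effect_fraction)

    @property
    def d(self) -> float:
        """Standardised effect size (mu2 - mu1) / sigma."""
        return (self.mu2 - self.mu1) / self.sigma


@dataclass(frozen=True)
class SampleSizePlan:
    n_per_group_independent: int
    achieved_power: float
    design_effect: float = 1.0
    n_adjusted: int = 0
    counting_basis: str = "per_group"
    spec: PowerSpec | None = None

    def to_dict(self) -> dict:
        out = {
            "n_per_group_independent": self.n_per_group_independent,
            "achieved_power": self.achieved_power,
            "design_effect": self.design_effect,
            "n_adjusted": self.n_adjusted,
            "counting_basis": self.counting_basis,
        }
        if self.spec is not None:
            out["spec"] = {
                "alpha": self.spec.alpha,
                "target_power": self.spec.target_power,
                "mu1": self.spec.mu1,
                "sigma": self.spec.sigma,
                "effect_fraction": self.spec.effect_fraction,
                "d": self.spec.d,
            }
        return out


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Exact two-sided power at n per group and standardised effect d.

    At d = 0 this returns exactly alpha (the test's size).
    """
    if n_per_group < 2:
        raise ArgumentError(f"n_per_group must be >= 2, got {n_per_group}")
    if d < 0:
        raise ArgumentError(f"d must be >= 0, got {d}")
    if not 0 < alpha < 1:
        raise ArgumentError(f"alpha must be in (0, 1), got {alpha}")
    df = 2 * n_per_group - 2
    t_crit = stats.t.isf(alpha / 2.0, df)
    nc = d * math.sqrt(n_per_group / 2.0)
    return float(stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc))


def min_n_per_group(spec: PowerSpec) -> SampleSizePlan:
    """Smallest n per group with power >= target (independent replicates).

    Exhaustive increment from n = 2 (deterministic, and the grid is small
    for any realistic effect size).
    """
    d = spec.d
    if d == 0:
        raise ArgumentError(
            "effect_fraction 0 gives power = alpha for any n; target unattainable"
        )
    for n in range(2, _N_GUARD + 1):
        pw = power_two_sample_t(n, d, spec.alpha)
        if pw >= spec.target_power:
            return SampleSizePlan(
                n_per_group_independent=n,
                achieved_power=pw,
                design_effect=1.0,
                n_adjusted=n,
                spec=spec,
            )
    raise ArgumentError(f"no n <= {_N_GUARD} reaches power {spec.target_power}")


def adjust_for_design_effect(plan: SampleSizePlan, deff: float) -> SampleSizePlan:
    """Inflate the per-group count: n_adjusted = ceil(n_independent * deff)."""
    if deff < 1:
        raise ArgumentError(
            f"design effect must be >= 1 for planning, got {deff} "
            "(truncate the ICC at 0 upstream)"
        )
    return replace(
        plan,
        design_effect=deff,
        n_adjusted=math.ceil(plan.n_per_group_independent * deff),
    )


def replicate_table(
    spec_base: PowerSpec,
    effect_fractions: Sequence[float],
    powers: Sequence[float],
    deff: float = 1.0,
) -> pd.DataFrame:
    """Adjusted replicate counts over an effect-fraction x power grid.

    Rows are target powers, columns effect fractions; each cell is the
    design-effect-inflated per-group count.
    """
    if len(effect_fractions) == 0 or len(powers) == 0:
        raise ArgumentError("effect_fractions and powers must be nonempty")
    table = {}
    for frac in effect_fractions:
        col = []
        for pw in powers:
            spec = replace(spec_base, effect_fraction=frac, target_power=pw)
            plan = adjust_for_design_effect(min_n_per_group(spec), deff)
            col.append(plan.n_adjusted)
        table[frac] = col
    frame = pd.DataFrame(table, index=list(powers))
    frame.index.name = "power"
    frame.columns.name = "effect_fraction"
    return frame


def per_patient_replicates(
    records: Sequence[AssayRecord],
    effect_fractions: Sequence[float],
    alpha: float = 0.05,
    target_power: float = 0.80,
    treatment: str = CORRECTOR,
) -> dict[float, SampleSizePlan]:
    """Replicates needed per effect size from one patient's treated cultures.

    Uses the patient's corrector-treated mean and s.d. as mu1 and sigma; no
    design-effect adjustment is applied (the per-patient panels are single
    cultures, not group samples).
    """
    values = [r.delta_isc for r in records if r.treatment == treatment]
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ArgumentError(
            f"records span multiple patients {sorted(patients)}; "
            "pass one patient's records"
        )
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >= 2 {treatment!r} replicates to estimate the s.d., got {len(values)}"
        )
    mu1 = float(np.mean(values))
    sigma = float(np.std(values, ddof=1))
    if sigma == 0:
        raise DegenerateDataError(
            "treated replicates have zero variance; sample size is undefined"
        )
    out = {}
    for frac in effect_fractions:
        spec = PowerSpec(
            alpha=alpha,
            target_power=target_power,
            mu1=mu1,
            sigma=sigma,
            effect_fraction=frac,
        )
        out[frac] = min_n_per_group(spec)
    return out


def clustered_null_rejection_rates(
    rho: float,
    group_size: int,
    n_groups: int,
    n_sims: int,
    seed: int,
    alpha: float = 0.05,
    sigma_total: float = 1.0,
) -> dict[str, float]:
    """Empirical type-I error of naive vs group-mean t-tests on clustered data.

    Simulates two treatment arms with identical means, each sampled as
    n_groups aliquot groups of group_size cultures with intraclass
    correlation rho.  The naive test treats every culture as independent;
    the clustered test aggregates to group means first.  Returns the two
    rejection rates at nominal two-sided level alpha.
    """
    if not 0 <= rho < 1:
        raise ArgumentError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    sigma_b = math.sqrt(rho) * sigma_total
    sigma_w = math.sqrt(1.0 - rho) * sigma_total

    def arm() -> np.ndarray:
        b = rng.normal(0.0, sigma_b, size=(n_sims, n_groups, 1))
        e = rng.normal(0.0, sigma_w, size=(n_sims, n_groups, group_size))
        return b + e

    x, y = arm(), arm()

    def reject(a: np.ndarray, b: np.ndarray) -> float:
        n = a.shape[1]
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * math.sqrt(2.0 / n))
        t_crit = stats.t.isf(alpha / 2.0, 2 * n - 2)
        return float(np.mean(np.abs(t) > t_crit))

    flat_x = x.reshape(n_sims, -1)
    flat_y = y.reshape(n_sims, -1)
    return {
        "naive": reject(flat_x, flat_y),
        "group_mean": reject(x.mean(axis=2), y.mean(axis=2)),
    }
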