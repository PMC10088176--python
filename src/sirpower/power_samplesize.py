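"""Reference-averaged power and minimal sample size for the SIR test.

With no data from the index hospital, its covariate mix p is unknown, so the
power of the one-sided test cannot be evaluated at "the" mix.  The design
instead averages over the I reference hospitals' mixes p^(i), treating them
as the empirical distribution of plausible index mixes:

    1 − β  =  (1/I) Σ_i [ 1 − Φ( (z_{1−α} − δ√n / σ(1, p^(i)))
                                  · σ(1, p^(i)) / σ(1+δ, p^(i)) ) ] ,

where δ is the minimal detectable SIR excess (alternative SIR = 1+δ).  The
expression is strictly increasing in n, so the minimal n achieving a target
power is found by bracketing and scalar root-finding, then an integer
minimality check.

Two traditional fixed-denominator designs are provided for comparison.  They
treat the expected prevalence m = Σ λ_j mix_j as a known constant — the mix
taken either from a small preliminary index sample or from the pooled
reference mix — so θ̂ = q̂/m carries only binomial uncertainty with scale
σ_f(θ) = √(θm(1−θm))/m, and the classical one-sample normal design applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sir_core import sigma, test_sir  # noqa: F401  (re-export convenience)
from .standards import (
    DegenerateDenominatorError,
    IndexSample,
    InfeasibleSIRError,
    ReferenceStandard,
    _check_prob_vector,
)
from .sir_core import SIRTestResults

__all__ = [
    "PowerSpec",
    "DesignResult",
    "power",
    "per_hospital_power",
    "sample_size",
    "sample_size_fixed_denominator",
    "test_sir_fixed_denominator",
    "PRELIMINARY_SAMPLE_SIZE",
]

#: preliminary index exams used by the fixed-denominator-from-index-sample design
PRELIMINARY_SAMPLE_SIZE = 100

_N_MAX = 10**9


@dataclass(frozen=True)
class PowerSpec:
    """Design targets: level α, target power 1−β, detectable excess δ."""

    alpha: float = 0.05
    target_power: float = 0.80
    delta: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must lie in (0, 1)")
        if self.delta < 0.0:
            raise ValueError("delta must be nonnegative")
        # alpha + beta < 1, i.e. the design must be informative
        if self.alpha + (1.0 - self.target_power) >= 1.0:
            raise ValueError("alpha + beta must be < 1")


@dataclass(frozen=True)
class DesignResult:
    """Minimal sample size and the power it achieves.

    ``per_hospital_power`` holds, for the proposed design, the bracketed
    per-reference-hospital terms of the power average at the returned n.
    """

    n: int
    achieved_power: float
    method: str
    per_hospital_power: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"SIR sample-size design  ({self.method})",
            f"  minimal n        {self.n}",
            f"  achieved power   {self.achieved_power:.4f}",
        ]
        if self.per_hospital_power is not None:
            ph = self.per_hospital_power
            lines.append(
                f"  per-hospital power over {ph.size} reference mixes: "
                f"min {ph.min():.4f}, median {np.median(ph):.4f}, max {ph.max():.4f}"
            )
        return "\n".join(lines)


def _design_scales(reference: ReferenceStandard, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """σ(1, p^(i)) and σ(1+δ, p^(i)) across the reference hospitals."""
    I = reference.n_hospitals
    s_null = np.empty(I)
    s_alt = np.empty(I)
    ids = reference.hospital_ids or tuple(range(I))
    for i in range(I):
        mix = reference.hospital_mixes[i]
        m = float(reference.lam @ mix)
        if m <= 0.0:
            raise DegenerateDenominatorError(
                f"reference hospital {ids[i]!r} has zero expected prevalence"
            )
        if (1.0 + delta) * m >= 1.0:
            raise InfeasibleSIRError(
                f"alternative SIR {1 + delta:g} infeasible for reference hospital "
                f"{ids[i]!r}: implied prevalence {(1 + delta) * m:.4g} >= 1"
            )
        s_null[i] = sigma(reference, 1.0, mix)
        s_alt[i] = sigma(reference, 1.0 + delta, mix)
    return s_null, s_alt


def per_hospital_power(reference: ReferenceStandard, spec: PowerSpec, n: float) -> np.ndarray:
    """Per-reference-hospital detection probabilities at sample size n."""
    if n <= 0:
        raise ValueError("n must be positive")
    s_null, s_alt = _design_scales(reference, spec.delta)
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    arg = (z_a - spec.delta * np.sqrt(n) / s_null) * s_null / s_alt
    return 1.0 - stats.norm.cdf(arg)


def power(reference: ReferenceStandard, spec: PowerSpec, n: float) -> float:
    """Reference-averaged power of the one-sided SIR test at sample size n.

    Uses no information from the index hospital.  Equals α when δ = 0 and
    increases strictly with n and δ.
    """
    return float(per_hospital_power(reference, spec, n).mean())


def _minimal_integer_n(power_fn, target: float, n_real: float) -> tuple[int, float]:
    """Ceil a continuous root then scan ±1 so that power(n) >= target > power(n-1)."""
    n = max(int(np.ceil(n_real - 1e-9)), 1)
    while power_fn(n) < target:
        n += 1
    while n > 1 and power_fn(n - 1) >= target:
        n -= 1
    return n, power_fn(n)


def sample_size(reference: ReferenceStandard, spec: PowerSpec) -> DesignResult:
    """Minimal n whose reference-averaged power reaches ``spec.target_power``.

    Brackets the monotone power curve, solves the continuous relaxation by
    Brent's method, and verifies integer minimality.  Deterministic.
    """
    if spec.delta <= 0.0:
        raise ValueError("sample_size requires delta > 0")

    def gap(n: float) -> float:
        return power(reference, spec, n) - spec.target_power

    hi = 4.0
    while gap(hi) < 0.0:
        hi *= 4.0
        if hi > _N_MAX:
            raise RuntimeError(f"failed to bracket the target power below n = {_N_MAX}")
    if gap(1.0) >= 0.0:
        n_real = 1.0
    else:
        n_real = optimize.brentq(gap, 1.0, hi, xtol=1e-6)
    n, achieved = _minimal_integer_n(lambda k: power(reference, spec, k), spec.target_power, n_real)
    return DesignResult(
        n=n,
        achieved_power=achieved,
        method="proposed",
        per_hospital_power=per_hospital_power(reference, spec, n),
    )


# -- traditional fixed-denominator comparators --------------------------


def _sigma_fixed(m: float, theta: float) -> float:
    q = theta * m
    if q >= 1.0:
        raise InfeasibleSIRError(f"SIR {theta:g} implies prevalence {q:.4g} >= 1")
    return float(np.sqrt(q * (1.0 - q)) / m)


def _power_fixed(m: float, spec: PowerSpec, n: float) -> float:
    s1 = _sigma_fixed(m, 1.0)
    s2 = _sigma_fixed(m, 1.0 + spec.delta)
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    return float(1.0 - stats.norm.cdf((z_a - spec.delta * np.sqrt(n) / s1) * s1 / s2))


def sample_size_fixed_denominator(
    reference: ReferenceStandard,
    mix,
    spec: PowerSpec,
    method: str = "fixed_reference_mean",
) -> DesignResult:
    """Classical design treating the SIR denominator m = Σ λ_j mix_j as known.

    ``mix`` is the covariate distribution assumed known: the pooled reference
    mix for the reference-mean variant, or p̂ from a preliminary index sample
    of :data:`PRELIMINARY_SAMPLE_SIZE` exams for the index-sample variant.
    Uses the one-sided one-sample normal design
    n = ((z_{1−α}·σ_f(1) + z_{1−β}·σ_f(1+δ)) / δ)² with σ_f(θ) = √(θm(1−θm))/m.
    """
    if spec.delta <= 0.0:
        raise ValueError("sample size requires delta > 0")
    mix, = (_check_prob_vector(np.asarray(mix, dtype=float), "mix"),)
    m = float(reference.lam @ mix)
    if m <= 0.0:
        raise DegenerateDenominatorError("assumed mix gives zero expected prevalence")
    if (1.0 + spec.delta) * m >= 1.0:
        raise InfeasibleSIRError(
            f"alternative SIR {1 + spec.delta:g} implies prevalence >= 1 under the assumed mix"
        )
    s1 = _sigma_fixed(m, 1.0)
    s2 = _sigma_fixed(m, 1.0 + spec.delta)
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    z_b = stats.norm.ppf(spec.target_power)
    n_real = ((z_a * s1 + z_b * s2) / spec.delta) ** 2
    n, achieved = _minimal_integer_n(
        lambda k: _power_fixed(m, spec, k), spec.target_power, n_real
    )
    return DesignResult(n=n, achieved_power=achieved, method=method)


def test_sir_fixed_denominator(
    sample: IndexSample,
    reference: ReferenceStandard,
    mix,
    alpha: float = 0.05,
) -> SIRTestResults:
    """One-sided SIR test with the denominator fixed from an assumed mix.

    θ̂ = q̂ / m with m = Σ λ_j mix_j held constant (not re-estimated from the
    analysis sample); rejects when (θ̂ − 1)/(σ_f(1)/√n) > z_{1−α}.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    mix = _check_prob_vector(np.asarray(mix, dtype=float), "mix")
    m = float(reference.lam @ mix)
    if m <= 0.0:
        raise DegenerateDenominatorError("assumed mix gives zero expected prevalence")
    theta_hat = sample.q_hat / m
    sigma_null = _sigma_fixed(m, 1.0)
    z = (theta_hat - 1.0) * np.sqrt(sample.n) / sigma_null
    crit = float(stats.norm.ppf(1.0 - alpha))
    return SIRTestResults(
        theta_hat=float(theta_hat),
        sigma_null=float(sigma_null),
        z_statistic=float(z),
        critical_value=crit,
        reject=bool(z > crit),
        alpha=float(alpha),
        n=sample.n,
        p_value=float(stats.norm.sf(z)),
    )
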