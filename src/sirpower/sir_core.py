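"""SIR point estimation, delta-method variance, and the one-sided test.

The standardized incidence ratio of an index hospital against a reference
standard is

    θ(Λ, p, q) = q / Σ_j λ_j p_j ,

the observed outcome prevalence q divided by the prevalence expected if the
reference stratum risks Λ applied to the index covariate mix p.  Both q and p
are unknown before sampling; estimating them from the same n exams gives the
plug-in estimator θ̂ = q̂ / Σ λ_j p̂_j whose asymptotic variance follows from
the delta method with covariance

    Σ = blockdiag( q(1−q),  D_p − p pᵀ ),

the binomial variance of q̂ and the multinomial covariance of p̂.  Writing
σ²(θ, p) for ∇θᵀ Σ ∇θ evaluated at q = θ·m (m = Σ λ_j p_j), the one-sided
level-α test of H0: θ = 1 against θ > 1 rejects when

    (θ̂ − 1) / (σ(1, p) / √n)  >  z_{1−α} .

At analysis time p is unknown, so the null scale plugs in p̂ (an optional
``known_mix`` override is provided for when the index mix is known).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .standards import (
    DegenerateDenominatorError,
    IndexSample,
    InfeasibleSIRError,
    ReferenceStandard,
    UnknownStratumError,
    _check_prob_vector,
)

__all__ = [
    "compute_sir",
    "delta_method_parts",
    "sigma2",
    "sigma",
    "test_sir",
    "batch_z_statistics",
    "DeltaMethodParts",
    "SIRTestResults",
    "TestResult",
    "SIRModel",
]


def _expected_prevalence(reference: ReferenceStandard, mix) -> tuple[np.ndarray, float]:
    mix = _check_prob_vector(np.asarray(mix, dtype=float), "mix")
    if mix.shape != reference.lam.shape:
        raise ValueError(
            f"mix has length {mix.shape[0]}, reference has {reference.n_strata} strata"
        )
    m = float(reference.lam @ mix)
    if m <= 0.0:
        raise DegenerateDenominatorError(
            "expected prevalence Σ λ_j p_j is zero; SIR undefined for this mix"
        )
    return mix, m


def compute_sir(reference: ReferenceStandard, mix, prevalence: float) -> float:
    """Standardized incidence ratio θ = prevalence / Σ_j λ_j mix_j.

    Parameters
    ----------
    reference
        Reference standard supplying the stratum risks Λ.
    mix
        Covariate distribution of the index population (length J, sums to 1).
    prevalence
        Outcome prevalence q in the index population, in [0, 1].
    """
    mix, m = _expected_prevalence(reference, mix)
    q = float(prevalence)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {q}")
    return q / m


@dataclass(frozen=True)
class DeltaMethodParts:
    """Gradient, covariance and resulting asymptotic variance of θ̂.

    ``gradient`` is ∇θ with respect to (q, p_1, ..., p_J); ``covariance`` is
    the (J+1)×(J+1) block-diagonal matrix of the estimators' scaled
    covariance; ``sigma2`` = ∇θᵀ Σ ∇θ is the asymptotic variance of
    √n(θ̂ − θ).
    """

    gradient: np.ndarray
    covariance: np.ndarray
    sigma2: float


def delta_method_parts(reference: ReferenceStandard, mix, prevalence: float) -> DeltaMethodParts:
    """Delta-method pieces for the SIR estimator at (mix, prevalence).

    The gradient entries are ∂θ/∂q = 1/m and ∂θ/∂p_j = −q λ_j / m² with
    m = Σ λ_j mix_j; the covariance stacks the binomial variance q(1−q) of q̂
    on top of the multinomial block D_p − p pᵀ of p̂.
    """
    mix, m = _expected_prevalence(reference, mix)
    q = float(prevalence)
    lam = reference.lam
    J = lam.shape[0]
    grad = np.empty(J + 1)
    grad[0] = 1.0 / m
    grad[1:] = -q * lam / m**2
    cov = np.zeros((J + 1, J + 1))
    cov[0, 0] = q * (1.0 - q)
    cov[1:, 1:] = np.diag(mix) - np.outer(mix, mix)
    s2 = float(grad @ cov @ grad)
    return DeltaMethodParts(gradient=grad, covariance=cov, sigma2=max(s2, 0.0))


def sigma2(reference: ReferenceStandard, theta: float, mix) -> float:
    """Asymptotic variance σ²(θ, p) of √n(θ̂ − θ) at a hypothesized SIR.

    Because q = θ·m is implied by θ and the mix, σ² is a function of (θ, p)
    alone once Λ is fixed.  Raises :class:`InfeasibleSIRError` when the
    implied prevalence θ·m exceeds 1.
    """
    mix, m = _expected_prevalence(reference, mix)
    theta = float(theta)
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    q = theta * m
    if q > 1.0 + 1e-12:
        raise InfeasibleSIRError(
            f"SIR {theta} implies prevalence {q:.6g} > 1 for this mix"
        )
    return delta_method_parts(reference, mix, min(q, 1.0)).sigma2


def sigma(reference: ReferenceStandard, theta: float, mix) -> float:
    """σ(θ, p) = sqrt of :func:`sigma2`; the scale appearing in the test and
    power formulas.  σ = 0 (prevalence boundary) is degenerate as a null scale."""
    return float(np.sqrt(sigma2(reference, theta, mix)))


def _sigma_null_batch(lam: np.ndarray, p_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (m, σ(1, p̂)) over rows of p̂; used by the simulation loops."""
    m = p_hat @ lam
    lam2 = p_hat @ lam**2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (1.0 - m) / m + (lam2 - m**2) / m**2
    return m, np.sqrt(np.maximum(s2, 0.0))


def batch_z_statistics(
    reference: ReferenceStandard, stratum_counts: np.ndarray, outcome_counts: np.ndarray, n: int
) -> np.ndarray:
    """Test statistics of many index samples at once.

    ``stratum_counts`` is (R, J), ``outcome_counts`` length R; each row is an
    independent sample of ``n`` exams.  Returns the R z statistics of the
    one-sided test, identical to calling :func:`test_sir` per row.  Rows with
    a degenerate null scale get −inf (never reject).
    """
    counts = np.asarray(stratum_counts, dtype=float)
    p_hat = counts / n
    q_hat = np.asarray(outcome_counts, dtype=float) / n
    m, sig = _sigma_null_batch(reference.lam, p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (q_hat / m - 1.0) * np.sqrt(n) / sig
    return np.where((m > 0) & (sig > 0), z, -np.inf)


@dataclass(frozen=True)
class SIRTestResults:
    """Result of the one-sided SIR test (the Results object of :class:`SIRModel`).

    Attributes
    ----------
    theta_hat : estimated SIR θ̂ = q̂ / Σ λ_j p̂_j
    sigma_null : null scale σ(1, p̂) (or σ(1, known_mix) if overridden)
    z_statistic : (θ̂ − 1) / (sigma_null / √n)
    critical_value : z_{1−α}
    reject : z_statistic > critical_value
    p_value : one-sided normal p-value
    """

    theta_hat: float
    sigma_null: float
    z_statistic: float
    critical_value: float
    reject: bool
    alpha: float
    n: int
    p_value: float

    def summary(self) -> str:
        lines = [
            "One-sided SIR test  (H0: theta = 1  vs  H1: theta > 1)",
            f"  n exams          {self.n}",
            f"  SIR estimate     {self.theta_hat:.4f}",
            f"  null scale sigma {self.sigma_null:.4f}",
            f"  z statistic      {self.z_statistic:.4f}",
            f"  critical value   {self.critical_value:.4f}  (alpha = {self.alpha:g})",
            f"  p-value          {self.p_value:.4g}",
            f"  decision         {'REJECT: SIR elevated' if self.reject else 'fail to reject'}",
        ]
        return "\n".join(lines)


# alias: the plain functional API calls this TestResult
TestResult = SIRTestResults


def test_sir(
    reference: ReferenceStandard,
    sample: IndexSample,
    alpha: float = 0.05,
    known_mix=None,
) -> SIRTestResults:
    """One-sided asymptotic test of H0: SIR = 1 against SIR > 1.

    Rejects when (θ̂ − 1)/(σ(1, p̂)/√n) > z_{1−α}.  ``known_mix`` substitutes
    an externally known covariate distribution for p̂ in the null scale only.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if sample.strata is not None and tuple(sample.strata) != reference.strata:
        unknown = set(sample.strata) - set(reference.strata)
        if unknown:
            raise UnknownStratumError(f"sample strata {sorted(map(str, unknown))} not in reference")
        raise ValueError("sample strata are ordered differently from the reference standard")
    if sample.stratum_counts.shape[0] != reference.n_strata:
        raise ValueError("sample stratum_counts length does not match reference strata")
    p_hat = sample.p_hat
    theta_hat = compute_sir(reference, p_hat, sample.q_hat)
    scale_mix = p_hat if known_mix is None else known_mix
    sigma_null = sigma(reference, 1.0, scale_mix)
    if sigma_null <= 0.0:
        raise DegenerateDenominatorError("null scale sigma(1, p) is zero; test undefined")
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


class SIRModel:
    """Indirect-standardization model for one index hospital.

    Thin statsmodels-style wrapper: construct from the data
    (an :class:`IndexSample` and a :class:`ReferenceStandard`), call
    :meth:`fit` to obtain :class:`SIRTestResults`.

    Examples
    --------
    >>> model = SIRModel(sample, reference)
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(self, sample: IndexSample, reference: ReferenceStandard):
        self.sample = sample
        self.reference = reference

    def fit(self, alpha: float = 0.05, known_mix=None) -> SIRTestResults:
        return test_sir(self.reference, self.sample, alpha=alpha, known_mix=known_mix)
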