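"""Synthetic multi-hospital registries and simulated index hospitals.

The generator emulates the statistical structure of a large CT dose
registry: ~150 hospitals of widely varying size, strata formed by crossing
anatomic areas with patient-size categories, stratum-level high-dose risks
rising with patient size from roughly 7% to 51%, strongly heterogeneous
covariate mixes across hospitals, and hospital-level risk multipliers that
spread true SIRs over roughly [0.4, 2.6].  It emits the same exam-level
table schema that :mod:`sirpower.registry_io` reads, so synthetic and real
registries flow through identical code paths.

Simulated index hospitals keep a base hospital's covariate distribution
fixed and rescale its per-stratum outcome probabilities to hit a prescribed
true SIR: r'_j = θ*·λ_j, clipped to [0, 1] with the unclipped strata
rescaled so the overall expected prevalence still equals θ*·Σλ_j p_j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .registry_io import HospitalSummary
from .standards import IndexSample, InfeasibleSIRError, ReferenceStandard

__all__ = [
    "RegistryConfig",
    "SimulatedHospital",
    "stratum_risks",
    "generate_registry",
    "make_simulated_hospital",
    "draw_index_sample",
    "draw_index_counts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistryConfig:
    """Parameters of the synthetic registry generator.

    Defaults mirror the emulated registry: 154 usable hospitals of which 103
    serve as the reference split, 4 anatomic areas × 4 size categories
    (J = 16 strata), stratum risks spanning [0.07, 0.51] and increasing over
    size categories, log-uniform hospital sizes in [500, 50000], Dirichlet
    hospital mixes around a common global mix (``mix_concentration`` scales
    the Dirichlet weights; smaller means more between-hospital heterogeneity),
    and log-normal hospital risk multipliers with mean 1 and log-scale sd
    ``sir_multiplier_sd``, clipped to ``sir_multiplier_range``.
    """

    n_hospitals: int = 154
    n_reference: int = 103
    n_areas: int = 4
    n_size_categories: int = 4
    lambda_range: tuple[float, float] = (0.07, 0.51)
    mix_concentration: float = 1.5
    hospital_size_range: tuple[float, float] = (500, 50000)
    sir_multiplier_range: tuple[float, float] = (0.0, 3.0)
    sir_multiplier_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference >= self.n_hospitals:
            raise ValueError("n_reference must be smaller than n_hospitals")
        if self.n_areas * self.n_size_categories < 2:
            raise ValueError("need at least two strata")
        lo, hi = self.lambda_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lambda_range must satisfy 0 < lo < hi < 1")
        if self.mix_concentration <= 0:
            raise ValueError("mix_concentration must be positive")
        slo, shi = self.hospital_size_range
        if not (0 < slo <= shi):
            raise ValueError("hospital_size_range must be positive and ordered")
        mlo, mhi = self.sir_multiplier_range
        if not (0.0 <= mlo < mhi):
            raise ValueError("sir_multiplier_range must be ordered and nonnegative")
        if self.sir_multiplier_sd < 0:
            raise ValueError("sir_multiplier_sd must be nonnegative")

    @property
    def n_strata(self) -> int:
        return self.n_areas * self.n_size_categories

    @classmethod
    def from_file(cls, path) -> "RegistryConfig":
        """Load a config from a YAML (or JSON) mapping; keys match field names."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("lambda_range", "hospital_size_range", "sir_multiplier_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(self).items()}, fh)


def stratum_risks(config: RegistryConfig) -> tuple[list[str], np.ndarray]:
    """Global stratum risks λ*_j on the area × size-category grid.

    Risks increase monotonically across size categories within each area
    (size carries 3/4 of the spread, area 1/4) and span ``lambda_range``
    exactly: the smallest patients in the first area sit at the lower bound,
    the largest patients in the last area at the upper bound.
    """
    lo, hi = config.lambda_range
    A, S = config.n_areas, config.n_size_categories
    strata, lam = [], []
    for a in range(A):
        u = a / max(A - 1, 1)
        for s in range(S):
            t = s / max(S - 1, 1)
            strata.append(f"a{a + 1}s{s + 1}")
            lam.append(lo + (hi - lo) * (0.75 * t + 0.25 * u))
    return strata, np.asarray(lam)


def generate_registry(config: RegistryConfig) -> pd.DataFrame:
    """Generate an exam-level registry table, reproducible from the seed.

    Per hospital: size log-uniform; covariate mix Dirichlet around the global
    mix; per-stratum outcome probability clip(c_i·λ*_j, 0, 1) with c_i the
    hospital's risk multiplier; exams drawn independently.
    """
    rng = np.random.default_rng(config.seed)
    strata, lam_star = stratum_risks(config)
    J = config.n_strata
    H = config.n_hospitals

    # near-uniform global mix with mild, reproducible imbalance
    global_mix = rng.dirichlet(np.full(J, 10.0))
    alpha = config.mix_concentration * J * global_mix
    mixes = rng.dirichlet(np.maximum(alpha, 1e-3), size=H)

    slo, shi = config.hospital_size_range
    sizes = np.exp(rng.uniform(np.log(slo), np.log(shi), size=H)).astype(np.int64)
    sizes = np.maximum(sizes, 1)

    mu = -0.5 * config.sir_multiplier_sd**2  # mean-one log-normal
    c = np.exp(rng.normal(mu, config.sir_multiplier_sd, size=H))
    c = np.clip(c, *config.sir_multiplier_range)

    rates = np.clip(c[:, None] * lam_star[None, :], 0.0, 1.0)

    hosp_col, strat_col, dose_col = [], [], []
    for h in range(H):
        counts = rng.multinomial(sizes[h], mixes[h])
        events = rng.binomial(counts, rates[h])
        for j in range(J):
            nj, ej = int(counts[j]), int(events[j])
            if nj == 0:
                continue
            hosp_col.append(np.full(nj, h + 1, dtype=np.int64))
            strat_col.append(np.full(nj, j, dtype=np.int64))
            out = np.zeros(nj, dtype=np.int8)
            out[:ej] = 1
            dose_col.append(out)
    table = pd.DataFrame(
        {
            "hospital_id": np.concatenate(hosp_col),
            "stratum_id": np.asarray(strata, dtype=object)[np.concatenate(strat_col)],
            "high_dose": np.concatenate(dose_col),
        }
    )
    logger.info(
        "generated registry: %d hospitals, %d exams, %d strata (seed %d)",
        H, len(table), J, config.seed,
    )
    return table


@dataclass(frozen=True)
class SimulatedHospital:
    """An index hospital with its base covariate mix and prescribed SIR.

    ``rates`` are the adjusted per-stratum outcome probabilities r'_j;
    ``realized_sir`` is the SIR those rates imply against the reference
    standard (equal to ``target_sir`` unless clipping made it infeasible).
    """

    base_hospital_id: object
    target_sir: float
    stratum_counts: np.ndarray
    rates: np.ndarray
    realized_sir: float
    strata: tuple | None = None

    @property
    def mix(self) -> np.ndarray:
        return self.stratum_counts / self.stratum_counts.sum()

    @property
    def expected_prevalence(self) -> float:
        return float(self.rates @ self.mix)


def make_simulated_hospital(
    base: HospitalSummary, reference: ReferenceStandard, target_sir: float
) -> SimulatedHospital:
    """Rescale a base hospital's stratum risks to a prescribed true SIR.

    Sets r'_j = target_sir·λ_j clipped to [0, 1]; when clipping occurs, the
    unclipped strata are scaled up so that Σ r'_j p_j = target_sir·Σ λ_j p_j
    whenever feasible.  The covariate distribution (stratum counts) is kept
    identical to the base hospital's.
    """
    if target_sir < 0:
        raise ValueError("target_sir must be nonnegative")
    p = base.mix
    lam = reference.lam
    m = float(lam @ p)
    if m <= 0.0:
        raise InfeasibleSIRError("base hospital has zero expected prevalence")
    q_target = target_sir * m
    if q_target > float(p[p > 0].sum()) + 1e-12:
        raise InfeasibleSIRError(
            f"target SIR {target_sir:g} implies prevalence {q_target:.4g} > 1"
        )
    rates = np.clip(target_sir * lam, 0.0, 1.0)
    # clip-and-rebalance: push the clipped-off mass onto unclipped strata
    for _ in range(reference.n_strata + 1):
        achieved = float(rates @ p)
        deficit = q_target - achieved
        if deficit <= 1e-12:
            break
        free = (rates < 1.0) & (p > 0) & (lam > 0)
        capacity = float((rates[free] * p[free]).sum())
        if capacity <= 0.0:
            break
        scale = 1.0 + deficit / capacity
        rates = np.where(free, np.minimum(rates * scale, 1.0), rates)
    if q_target - float(rates @ p) > 1e-9 * max(q_target, 1.0):
        raise InfeasibleSIRError(
            f"target SIR {target_sir:g} unreachable even after clip-and-rebalance "
            f"(achievable expected prevalence {float(rates @ p):.4g} < {q_target:.4g})"
        )
    realized = float(rates @ p) / m
    return SimulatedHospital(
        base_hospital_id=base.hospital_id,
        target_sir=float(target_sir),
        stratum_counts=base.stratum_counts.copy(),
        rates=rates,
        realized_sir=realized,
        strata=reference.strata,
    )


def draw_index_counts(
    sim: SimulatedHospital, n: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized generative draws: (reps, J) stratum counts and reps outcome counts.

    Each exam's stratum follows the hospital's mix and its outcome is
    Bernoulli(r'_j) given stratum j.
    """
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be positive")
    counts = rng.multinomial(n, sim.mix, size=reps)
    outcomes = rng.binomial(counts, sim.rates[None, :]).sum(axis=1)
    return counts, outcomes


def draw_index_sample(sim: SimulatedHospital, n: int, seed) -> IndexSample:
    """Draw one sample of n exams from a simulated hospital, seeded."""
    rng = np.random.default_rng(seed)
    counts, outcomes = draw_index_counts(sim, n, 1, rng)
    return IndexSample(
        n=n,
        stratum_counts=counts[0],
        outcome_count=int(outcomes[0]),
        strata=sim.strata,
    )
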