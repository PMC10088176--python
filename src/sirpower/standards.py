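"""Core data containers for indirect standardization.

A :class:`ReferenceStandard` bundles everything the method treats as known:
the per-stratum outcome probabilities ``lam`` (the vector Λ of stratum risks,
estimated once from a large reference registry) together with the covariate
distributions of the individual reference hospitals and their exam-weighted
pooled mix.  An :class:`IndexSample` is the sufficient summary of n exams
sampled from the hospital being profiled: stratum counts and the number of
high-dose outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReferenceStandard",
    "IndexSample",
    "DegenerateDenominatorError",
    "InfeasibleSIRError",
    "UnknownStratumError",
    "SchemaError",
]

# tolerance for "sums to one" checks on user-supplied probability vectors
_PROB_ATOL = 1e-8


class DegenerateDenominatorError(ValueError):
    """Expected prevalence Σ λ_j p_j is zero: the SIR is undefined."""


class InfeasibleSIRError(ValueError):
    """A requested SIR implies an outcome probability outside [0, 1]."""


class UnknownStratumError(KeyError):
    """A stratum was observed that the reference standard does not define."""


class SchemaError(ValueError):
    """An input table does not conform to the expected column schema."""


def _check_prob_vector(x: np.ndarray, name: str, atol: float = _PROB_ATOL) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a 1-d vector, got shape {x.shape}")
    if np.any(x < -atol):
        raise ValueError(f"{name} has negative entries")
    total = float(x.sum())
    if abs(total - 1.0) > atol:
        raise ValueError(f"{name} must sum to 1 (got {total:.12g})")
    return np.clip(x, 0.0, None)


@dataclass(frozen=True)
class ReferenceStandard:
    """Reference population for indirect standardization.

    Parameters
    ----------
    strata
        Ordered stratum identifiers (length J).  The order fixes the meaning
        of every length-J vector held here and of
        :attr:`IndexSample.stratum_counts`.
    lam
        Stratum-level outcome probabilities Λ = (λ_1, ..., λ_J), each in
        [0, 1], estimated from the pooled reference registry.
    hospital_mixes
        (I, J) array; row i is the covariate distribution p^(i) of reference
        hospital i.  These rows drive the reference-averaged power formula.
    pooled_mix
        Exam-weighted mean covariate distribution of the whole reference
        registry (length J).
    hospital_ids
        Optional identifiers for the I reference hospitals.
    """

    strata: tuple
    lam: np.ndarray
    hospital_mixes: np.ndarray
    pooled_mix: np.ndarray
    hospital_ids: tuple | None = None

    def __post_init__(self) -> None:
        strata = tuple(self.strata)
        lam = np.asarray(self.lam, dtype=float)
        mixes = np.atleast_2d(np.asarray(self.hospital_mixes, dtype=float))
        pooled = np.asarray(self.pooled_mix, dtype=float)
        J = len(strata)
        if J < 1:
            raise ValueError("need at least one stratum")
        if lam.shape != (J,):
            raise ValueError(f"lam must have length {J}, got {lam.shape}")
        if np.any(lam < 0) or np.any(lam > 1):
            raise ValueError("lam entries must lie in [0, 1]")
        if not np.any((lam > 0) & (lam < 1)):
            raise ValueError("at least one stratum risk must be strictly in (0, 1)")
        if mixes.shape[0] < 1 or mixes.shape[1] != J:
            raise ValueError(f"hospital_mixes must be (I, {J}), got {mixes.shape}")
        mixes = np.vstack([_check_prob_vector(row, f"hospital mix {i}") for i, row in enumerate(mixes)])
        pooled = _check_prob_vector(pooled, "pooled_mix")
        ids = None if self.hospital_ids is None else tuple(self.hospital_ids)
        if ids is not None and len(ids) != mixes.shape[0]:
            raise ValueError("hospital_ids length must match hospital_mixes rows")
        for arr in (lam, mixes, pooled):
            arr.setflags(write=False)
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "hospital_mixes", mixes)
        object.__setattr__(self, "pooled_mix", pooled)
        object.__setattr__(self, "hospital_ids", ids)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def n_hospitals(self) -> int:
        """Number of reference hospitals I."""
        return self.hospital_mixes.shape[0]

    def expected_prevalence(self, mix: Sequence[float]) -> float:
        """Expected outcome prevalence m = Σ_j λ_j mix_j under this standard."""
        mix = _check_prob_vector(np.asarray(mix, dtype=float), "mix")
        if mix.shape != self.lam.shape:
            raise ValueError("mix length does not match number of strata")
        return float(self.lam @ mix)

    def stratum_index(self, stratum) -> int:
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise UnknownStratumError(
                f"stratum {stratum!r} not in reference standard"
            ) from None

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "strata": list(self.strata),
            "lambda": self.lam.tolist(),
            "hospital_mixes": self.hospital_mixes.tolist(),
            "pooled_mix": self.pooled_mix.tolist(),
        }
        if self.hospital_ids is not None:
            d["hospital_ids"] = list(self.hospital_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceStandard":
        return cls(
            strata=tuple(d["strata"]),
            lam=np.asarray(d["lambda"], dtype=float),
            hospital_mixes=np.asarray(d["hospital_mixes"], dtype=float),
            pooled_mix=np.asarray(d["pooled_mix"], dtype=float),
            hospital_ids=tuple(d["hospital_ids"]) if "hospital_ids" in d else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceStandard":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class IndexSample:
    """Summary of n exams sampled from one index hospital.

    ``stratum_counts`` follows the stratum order of the reference standard it
    will be analysed against (``strata`` may record that order explicitly).
    The observed proportions p̂ = stratum_counts / n and q̂ = outcome_count / n
    are the plug-in estimators used throughout.
    """

    n: int
    stratum_counts: np.ndarray
    outcome_count: int
    strata: tuple | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.stratum_counts)
        if counts.ndim != 1:
            raise ValueError("stratum_counts must be a 1-d vector")
        if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
            raise ValueError("stratum_counts must be nonnegative integers")
        counts = counts.astype(np.int64)
        n = int(self.n)
        if n < 1:
            raise ValueError("sample size n must be positive")
        if int(counts.sum()) != n:
            raise ValueError(f"stratum_counts sum to {counts.sum()}, expected n={n}")
        k = int(self.outcome_count)
        if not 0 <= k <= n:
            raise ValueError("outcome_count must lie in [0, n]")
        counts.setflags(write=False)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "stratum_counts", counts)
        object.__setattr__(self, "outcome_count", k)
        if self.strata is not None:
            strata = tuple(self.strata)
            if len(strata) != counts.shape[0]:
                raise ValueError("strata length must match stratum_counts")
            object.__setattr__(self, "strata", strata)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IndexSample):
            return NotImplemented
        return (
            self.n == other.n
            and self.outcome_count == other.outcome_count
            and self.strata == other.strata
            and np.array_equal(self.stratum_counts, other.stratum_counts)
        )

    def __hash__(self):
        return hash((self.n, self.outcome_count, self.strata, self.stratum_counts.tobytes()))

    @property
    def p_hat(self) -> np.ndarray:
        """Observed covariate distribution p̂."""
        return self.stratum_counts / self.n

    @property
    def q_hat(self) -> float:
        """Observed outcome prevalence q̂."""
        return self.outcome_count / self.n
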