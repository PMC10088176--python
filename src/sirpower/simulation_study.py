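"""Monte-Carlo evaluation of SIR test calibration and design comparison.

The study follows a five-step template: (1) split the registry's hospitals
into a reference group and base index hospitals; (2) from each base index
hospital construct simulated index hospitals over a grid of true SIR values
(identical covariate mix, rescaled stratum risks); (3) compute the design
sample size for an alternative SIR of 1+δ; (4) repeatedly sample that many
exams from each simulated hospital and run the one-sided test; (5) tabulate
per-hospital empirical type I error (true SIR ≤ 1: rejection rate) and
type II error (true SIR > 1: non-rejection rate).  The two traditional
fixed-denominator designs are run alongside at the SIR values of primary
interest for a paired comparison.

All randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawn keys — stream (0,) for the hospital
split, (1, h) for hospital h's preliminary design sample, and
(2, h, g, m) for the testing replicates of hospital h at grid point g under
method m — so any subset of the study reruns identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .power_samplesize import (
    DesignResult,
    PowerSpec,
    sample_size,
    sample_size_fixed_denominator,
)
from .registry_io import build_reference_standard, summarize_hospitals
from .sir_core import batch_z_statistics
from .standards import InfeasibleSIRError, ReferenceStandard
from .synthetic_registry import (
    RegistryConfig,
    draw_index_counts,
    generate_registry,
    make_simulated_hospital,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "ERROR_TABLE_COLUMNS",
    "split_hospitals",
    "run_study",
    "compare_methods",
    "plot_error_rates",
]

logger = logging.getLogger(__name__)

PROPOSED = "proposed"
FIXED_INDEX = "fixed_index_sample"
FIXED_REFERENCE = "fixed_reference_mean"

ERROR_TABLE_COLUMNS = [
    "hospital_id",
    "true_sir",
    "method",
    "n_used",
    "rejection_rate",
    "error_type",
    "error_rate",
]

_DEFAULT_GRID = tuple(round(0.5 + 0.1 * k, 1) for k in range(11))


@dataclass(eq=False)
class StudyConfig:
    """Configuration of a full simulation study.

    ``registry`` is either an exam-level table (DataFrame) or a
    :class:`RegistryConfig` to generate one; ``None`` means the default
    synthetic registry.  Comparator methods are evaluated only at
    ``comparator_sir_values`` (the SIR values of primary interest);
    the proposed method runs on the whole ``sir_grid``.
    """

    registry: object = None
    n_reference: int = 103
    seed: int = 0
    sir_grid: tuple = _DEFAULT_GRID
    reps: int = 1000
    alpha: float = 0.05
    target_power: float = 0.80
    delta: float = 0.2
    methods: tuple = (PROPOSED, FIXED_INDEX, FIXED_REFERENCE)
    comparator_sir_values: tuple = (1.0, 1.2)
    preliminary_sample_size: int = 100
    index_selection: str = "random_split"
    sir_bands: tuple = (0.9, 0.95, 1.0, 1.25, 1.5)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(s < 0 for s in self.sir_grid):
            raise ValueError("sir_grid values must be nonnegative")
        unknown = set(self.methods) - {PROPOSED, FIXED_INDEX, FIXED_REFERENCE}
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if self.index_selection not in ("random_split", "sir_banded"):
            raise ValueError("index_selection must be 'random_split' or 'sir_banded'")
        if self.preliminary_sample_size < 1:
            raise ValueError("preliminary_sample_size must be positive")

    @property
    def power_spec(self) -> PowerSpec:
        return PowerSpec(alpha=self.alpha, target_power=self.target_power, delta=self.delta)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load a study config from YAML; ``registry`` may be a mapping of
        :class:`RegistryConfig` fields or ``{"csv": <path>}``."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        reg = data.get("registry")
        if isinstance(reg, dict):
            if "csv" in reg:
                from .registry_io import read_exam_table

                data["registry"] = read_exam_table(reg["csv"], reg.get("column_map"))
            else:
                for key in ("lambda_range", "hospital_size_range", "sir_multiplier_range"):
                    if key in reg:
                        reg[key] = tuple(reg[key])
                data["registry"] = RegistryConfig(**reg)
        for key in ("sir_grid", "methods", "comparator_sir_values", "sir_bands"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(eq=False)
class StudyResult:
    """Outputs of :func:`run_study`."""

    error_rates: pd.DataFrame
    designs: dict
    reference: ReferenceStandard
    reference_ids: tuple
    index_ids: tuple
    skipped: list = field(default_factory=list)


def _resolve_table(config: StudyConfig) -> pd.DataFrame:
    if isinstance(config.registry, pd.DataFrame):
        return config.registry
    reg_config = config.registry if isinstance(config.registry, RegistryConfig) else RegistryConfig(
        seed=config.seed
    )
    return generate_registry(reg_config)


def split_hospitals(table: pd.DataFrame, config: StudyConfig) -> tuple[tuple, tuple]:
    """Partition hospitals into reference and index groups.

    ``random_split``: a seeded uniform partition with ``n_reference``
    reference hospitals.  ``sir_banded``: full-data SIR bands (edges in
    ``sir_bands``); from each nonempty band max(2, ⌈size/3⌉) hospitals are
    drawn as index hospitals and the remainder are the reference group.
    """
    hospitals = sorted(table["hospital_id"].unique(), key=str)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    if config.index_selection == "random_split":
        if len(hospitals) < config.n_reference + 1:
            raise ValueError(
                f"{len(hospitals)} hospitals cannot supply {config.n_reference} "
                "reference hospitals plus at least one index hospital"
            )
        perm = rng.permutation(len(hospitals))
        ref = [hospitals[i] for i in sorted(perm[: config.n_reference])]
        idx = [hospitals[i] for i in sorted(perm[config.n_reference:])]
        return tuple(ref), tuple(idx)

    full_reference = build_reference_standard(table)
    sirs = {s.hospital_id: s.true_sir for s in summarize_hospitals(table, full_reference)}
    edges = (-math.inf,) + tuple(config.sir_bands) + (math.inf,)
    index_ids: list = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = [h for h in hospitals if lo <= sirs[h] < hi]
        if not band:
            logger.warning("SIR band [%s, %s) contains no hospitals; skipped", lo, hi)
            continue
        k = min(len(band), max(2, math.ceil(len(band) / 3)))
        chosen = rng.choice(len(band), size=k, replace=False)
        index_ids.extend(band[i] for i in sorted(chosen))
    ref = tuple(h for h in hospitals if h not in set(index_ids))
    return ref, tuple(index_ids)


def _fixed_rejections(
    lam: np.ndarray,
    assumed_mix: np.ndarray,
    counts: np.ndarray,
    outcomes: np.ndarray,
    n: int,
    crit: float,
) -> np.ndarray:
    m = float(lam @ assumed_mix)
    sigma_f = math.sqrt(m * (1.0 - m)) / m
    q_hat = outcomes / n
    z = (q_hat / m - 1.0) * math.sqrt(n) / sigma_f
    return z > crit


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full evaluation; deterministic given (config, seed)."""
    table = _resolve_table(config)
    ref_ids, idx_ids = split_hospitals(table, config)
    ref_std = build_reference_standard(table[table["hospital_id"].isin(ref_ids)])
    idx_summaries = summarize_hospitals(table[table["hospital_id"].isin(idx_ids)], ref_std)
    spec = config.power_spec
    crit = float(stats.norm.ppf(1.0 - config.alpha))
    lam = ref_std.lam

    designs: dict = {}
    if PROPOSED in config.methods:
        designs[PROPOSED] = sample_size(ref_std, spec)
        logger.info("proposed design: n = %d", designs[PROPOSED].n)
    if FIXED_REFERENCE in config.methods:
        designs[FIXED_REFERENCE] = sample_size_fixed_denominator(
            ref_std, ref_std.pooled_mix, spec, method=FIXED_REFERENCE
        )
        logger.info("fixed-reference-mean design: n = %d", designs[FIXED_REFERENCE].n)
    prelim_mixes: dict = {}
    if FIXED_INDEX in config.methods:
        per_hosp: dict = {}
        for h_idx, summ in enumerate(idx_summaries):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, h_idx))
            )
            prelim = rng.multinomial(config.preliminary_sample_size, summ.mix)
            p_hat = prelim / config.preliminary_sample_size
            prelim_mixes[summ.hospital_id] = p_hat
            per_hosp[summ.hospital_id] = sample_size_fixed_denominator(
                ref_std, p_hat, spec, method=FIXED_INDEX
            )
        designs[FIXED_INDEX] = per_hosp
        ns = [d.n for d in per_hosp.values()]
        logger.info(
            "fixed-index-sample designs: median n = %.0f, range %d-%d",
            np.median(ns), min(ns), max(ns),
        )

    comparator_values = np.asarray(config.comparator_sir_values, dtype=float)
    rows = []
    skipped = []
    for h_idx, summ in enumerate(idx_summaries):
        for g_idx, target in enumerate(config.sir_grid):
            try:
                sim = make_simulated_hospital(summ, ref_std, target)
            except InfeasibleSIRError as err:
                skipped.append((summ.hospital_id, target, str(err)))
                logger.warning(
                    "hospital %r at SIR %.2f skipped: %s", summ.hospital_id, target, err
                )
                continue
            for m_idx, method in enumerate(config.methods):
                if method != PROPOSED and not np.any(
                    np.isclose(comparator_values, target)
                ):
                    continue
                if method == FIXED_INDEX:
                    n_used = designs[FIXED_INDEX][summ.hospital_id].n
                else:
                    n_used = designs[method].n
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(2, h_idx, g_idx, m_idx))
                )
                counts, outcomes = draw_index_counts(sim, n_used, config.reps, rng)
                if method == PROPOSED:
                    rej = batch_z_statistics(ref_std, counts, outcomes, n_used) > crit
                elif method == FIXED_REFERENCE:
                    rej = _fixed_rejections(
                        lam, ref_std.pooled_mix, counts, outcomes, n_used, crit
                    )
                else:
                    rej = _fixed_rejections(
                        lam, prelim_mixes[summ.hospital_id], counts, outcomes, n_used, crit
                    )
                rate = float(np.mean(rej))
                is_null = target <= 1.0
                rows.append(
                    {
                        "hospital_id": summ.hospital_id,
                        "true_sir": float(target),
                        "method": method,
                        "n_used": int(n_used),
                        "rejection_rate": rate,
                        "error_type": "type_I" if is_null else "type_II",
                        "error_rate": rate if is_null else 1.0 - rate,
                    }
                )
    error_rates = pd.DataFrame(rows, columns=ERROR_TABLE_COLUMNS)
    return StudyResult(
        error_rates=error_rates,
        designs=designs,
        reference=ref_std,
        reference_ids=ref_ids,
        index_ids=idx_ids,
        skipped=skipped,
    )


def compare_methods(error_rates: pd.DataFrame) -> pd.DataFrame:
    """Paired per-hospital comparison of each comparator against the proposed test.

    For every (true SIR, comparator) cell present for both methods, reports
    the fraction of hospitals whose comparator error rate strictly exceeds
    the proposed method's (ties count as non-exceedances).
    """
    methods = set(error_rates["method"].unique())
    if PROPOSED not in methods or len(methods) < 2:
        raise ValueError("comparison requires the proposed method plus at least one comparator")
    prop = error_rates[error_rates["method"] == PROPOSED].set_index(["hospital_id", "true_sir"])
    out = []
    for method in sorted(methods - {PROPOSED}):
        comp = error_rates[error_rates["method"] == method].set_index(
            ["hospital_id", "true_sir"]
        )
        missing = comp.index.difference(prop.index)
        if len(missing):
            raise ValueError(f"cells missing for the proposed method: {list(missing)[:5]}")
        for sir in sorted(comp.index.get_level_values("true_sir").unique()):
            c = comp.xs(sir, level="true_sir")["error_rate"]
            p = prop.xs(sir, level="true_sir")["error_rate"].reindex(c.index)
            out.append(
                {
                    "true_sir": float(sir),
                    "method": method,
                    "n_hospitals": int(len(c)),
                    "fraction_exceeding_proposed": float((c > p).mean()),
                }
            )
    return pd.DataFrame(out)


def plot_error_rates(error_rates: pd.DataFrame, ax=None):
    """Scatter of per-hospital error rates against true SIR (simple helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, sub in error_rates.groupby("method"):
        ax.scatter(sub["true_sir"], sub["error_rate"], s=12, alpha=0.5, label=method)
    ax.set_xlabel("true SIR")
    ax.set_ylabel("empirical error rate")
    ax.legend()
    return ax
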