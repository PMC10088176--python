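"""Read/write exam-level registry tables and derive reference standards.

The on-disk schema is one CSV row per exam with a hospital identifier, a
covariate-stratum identifier (one token per cell of the crossed categorical
adjusters, e.g. anatomic area × patient size category), and a binary
high-dose outcome.  Default column names are ``fac``, ``sizeC`` and
``dlp.over``; in memory the canonical names ``hospital_id``, ``stratum_id``
and ``high_dose`` are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sir_core import compute_sir
from .standards import (
    IndexSample,
    ReferenceStandard,
    SchemaError,
    UnknownStratumError,
)

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "HospitalSummary",
    "read_exam_table",
    "write_exam_table",
    "build_reference_standard",
    "summarize_hospitals",
    "sample_index_exams",
]

logger = logging.getLogger(__name__)

#: file column -> canonical column
DEFAULT_COLUMN_MAP = {"fac": "hospital_id", "sizeC": "stratum_id", "dlp.over": "high_dose"}

_CANONICAL = ("hospital_id", "stratum_id", "high_dose")


def read_exam_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Parse an exam-level CSV into a canonical three-column table.

    ``column_map`` maps file headers to the canonical names; unmapped file
    columns are dropped.  Row order is preserved.  Raises
    :class:`~sirpower.standards.SchemaError` on missing columns and a
    row-numbered ValueError on outcomes outside {0, 1}.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(path)
    missing = [c for c in column_map if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing} in {path}; available headers: {list(raw.columns)}"
        )
    table = raw[list(column_map)].rename(columns=column_map)
    extra = [c for c in _CANONICAL if c not in table.columns]
    if extra:
        raise SchemaError(f"column_map does not provide canonical column(s) {extra}")
    table = table[list(_CANONICAL)]
    if table.empty:
        logger.warning("exam table %s is empty (header only)", path)
        return table.assign(high_dose=table["high_dose"].astype(np.int8))
    for col in _CANONICAL:
        if table[col].isna().any():
            row = int(table.index[table[col].isna()][0]) + 2  # 1-based + header
            raise ValueError(f"missing value in column {col!r} at line {row} of {path}")
    outcome = pd.to_numeric(table["high_dose"], errors="coerce")
    bad = outcome.isna() | ~outcome.isin((0, 1))
    if bad.any():
        row = int(table.index[bad][0]) + 2
        raise ValueError(
            f"high-dose outcome must be 0/1; invalid value "
            f"{table['high_dose'].iloc[int(table.index[bad][0])]!r} at line {row} of {path}"
        )
    table["high_dose"] = outcome.astype(np.int8)
    return table.reset_index(drop=True)


def write_exam_table(table: pd.DataFrame, path, column_map: dict | None = None) -> None:
    """Write a canonical exam table back to CSV using the file-side headers."""
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    inverse = {v: k for k, v in column_map.items()}
    table[list(_CANONICAL)].rename(columns=inverse).to_csv(path, index=False)


def _sorted_strata(table: pd.DataFrame) -> list:
    # lexicographic over the stratum tokens for a deterministic order
    return sorted(table["stratum_id"].unique(), key=str)


def build_reference_standard(table: pd.DataFrame) -> ReferenceStandard:
    """Derive (Λ, per-hospital mixes, pooled mix) from a reference exam table.

    λ_j is the pooled high-dose fraction among all exams in stratum j;
    hospital mixes and the pooled mix are observed stratum proportions.
    Stratum order is lexicographic over the stratum identifiers.
    """
    if table.empty:
        raise ValueError("cannot build a reference standard from an empty table")
    strata = _sorted_strata(table)
    J = len(strata)
    col = pd.Categorical(table["stratum_id"], categories=strata)
    counts = pd.crosstab(table["hospital_id"], col, dropna=False)
    events = pd.crosstab(
        table["hospital_id"], col, values=table["high_dose"], aggfunc="sum", dropna=False
    ).fillna(0.0)
    stratum_n = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(stratum_n == 0):
        empty = [s for s, c in zip(strata, stratum_n) if c == 0]
        logger.warning("excluding strata with zero exams: %s", empty)
        keep = stratum_n > 0
        strata = [s for s, k in zip(strata, keep) if k]
        counts = counts.loc[:, keep]
        events = events.loc[:, keep]
        stratum_n = stratum_n[keep]
        J = len(strata)
    lam = events.sum(axis=0).to_numpy(dtype=float) / stratum_n
    hosp_n = counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(hosp_n == 0):
        bad = [h for h, c in zip(counts.index, hosp_n) if c == 0]
        raise ValueError(f"hospital(s) with zero exams: {bad}")
    mixes = counts.to_numpy(dtype=float) / hosp_n[:, None]
    pooled = stratum_n / stratum_n.sum()
    return ReferenceStandard(
        strata=tuple(strata),
        lam=lam,
        hospital_mixes=mixes,
        pooled_mix=pooled,
        hospital_ids=tuple(counts.index),
    )


@dataclass(frozen=True)
class HospitalSummary:
    """Per-hospital summary against a reference standard.

    ``stratum_counts`` and ``stratum_outcome_counts`` follow the reference
    stratum order; ``true_sir`` is the SIR of the hospital's full data.
    """

    hospital_id: object
    exam_count: int
    stratum_counts: np.ndarray
    stratum_outcome_counts: np.ndarray
    prevalence: float
    true_sir: float

    @property
    def mix(self) -> np.ndarray:
        return self.stratum_counts / self.exam_count


def summarize_hospitals(table: pd.DataFrame, reference: ReferenceStandard) -> list[HospitalSummary]:
    """Counts, observed prevalence and full-data SIR for every hospital."""
    unknown = set(table["stratum_id"].unique()) - set(reference.strata)
    if unknown:
        raise UnknownStratumError(
            f"strata {sorted(map(str, unknown))} not present in the reference standard"
        )
    col = pd.Categorical(table["stratum_id"], categories=list(reference.strata))
    counts = pd.crosstab(table["hospital_id"], col, dropna=False)
    events = pd.crosstab(
        table["hospital_id"], col, values=table["high_dose"], aggfunc="sum", dropna=False
    ).fillna(0.0)
    out = []
    for hid in counts.index:
        c = counts.loc[hid].to_numpy(dtype=np.int64)
        e = events.loc[hid].to_numpy(dtype=float).astype(np.int64)
        n = int(c.sum())
        q = float(e.sum()) / n
        sir = compute_sir(reference, c / n, q)
        out.append(
            HospitalSummary(
                hospital_id=hid,
                exam_count=n,
                stratum_counts=c,
                stratum_outcome_counts=e,
                prevalence=q,
                true_sir=float(sir),
            )
        )
    return out


def sample_index_exams(
    table: pd.DataFrame,
    hospital_id,
    n: int,
    seed,
    reference: ReferenceStandard | None = None,
    replace: bool = True,
) -> IndexSample:
    """Resample n exams from one hospital's rows and summarize them.

    Draws uniformly with replacement by default (n may exceed the hospital's
    exam count); ``replace=False`` is allowed when n does not.  Stratum counts
    follow the reference stratum order when a reference is given, otherwise
    the lexicographic order of the hospital's own strata.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rows = table[table["hospital_id"] == hospital_id]
    if rows.empty:
        raise ValueError(f"hospital {hospital_id!r} has no exams")
    if not replace and n > len(rows):
        raise ValueError("n exceeds hospital size; use replace=True")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=replace)
    picked = rows.iloc[idx]
    strata = list(reference.strata) if reference is not None else _sorted_strata(rows)
    unknown = set(picked["stratum_id"].unique()) - set(strata)
    if unknown:
        raise UnknownStratumError(
            f"sampled strata {sorted(map(str, unknown))} not present in the reference standard"
        )
    counts = (
        picked["stratum_id"].value_counts().reindex(strata, fill_value=0).to_numpy(dtype=np.int64)
    )
    return IndexSample(
        n=n,
        stratum_counts=counts,
        outcome_count=int(picked["high_dose"].sum()),
        strata=tuple(strata),
    )
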