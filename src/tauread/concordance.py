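"""Agreement tables, Cohen's kappa, discordance patterns, and trajectories.

Besides building 2x2 agreement tables from paired statuses, this module can
reconstruct the full table from the marginals a results section typically
prints — total n, the two positive marginals, and the number of concordant
cases — via the identity ``a = (row_pos + col_pos + n_agree - n) / 2``.
Cohen's kappa is the chance-corrected agreement
``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_e`` from the marginal products.

Longitudinal diagnosis sequences over {CN, UD, AD, FTD} are classified into
trajectory categories (stable, converter, reverter, reassigned non-AD) with a
fixed rule order; "UD" (uncertain dementia) never by itself terminates a
converter classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .suvr import POSITIVE, CutoffConfig

TRAJECTORY_CATEGORIES = (
    "stable_CN",
    "stable_AD",
    "converter_AD",
    "reverter",
    "reassigned_nonAD",
    "indeterminate",
)


class InconsistentMarginalsError(ValueError):
    """The printed marginals admit no non-negative integer 2x2 table."""


@dataclass
class ContingencyTable2x2:
    """Counts a (both+), b (row+/col-), c (row-/col+), d (both-)."""

    a: int
    b: int
    c: int
    d: int
    row_label: str = "row"
    col_label: str = "col"

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d, self.col_label, self.row_label)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "n": self.n,
            "row_label": self.row_label,
            "col_label": self.col_label,
        }


@dataclass
class ConcordanceResult:
    po: float
    pe: float
    kappa: float
    n: int

    def to_dict(self) -> dict:
        return {"percent_agreement": 100.0 * self.po, "po": self.po, "pe": self.pe, "kappa": self.kappa, "n": self.n}


def crosstab(
    rows: Sequence[str], cols: Sequence[str], row_label: str = "row", col_label: str = "col"
) -> ContingencyTable2x2:
    """2x2 table from paired binary statuses ("positive"/"negative")."""
    if len(rows) != len(cols):
        raise ValueError(f"paired columns differ in length ({len(rows)} vs {len(cols)})")
    if len(rows) == 0:
        raise ValueError("cannot cross-tabulate empty inputs")
    rp = np.asarray([r == POSITIVE for r in rows])
    cp = np.asarray([c == POSITIVE for c in cols])
    return ContingencyTable2x2(
        a=int(np.sum(rp & cp)),
        b=int(np.sum(rp & ~cp)),
        c=int(np.sum(~rp & cp)),
        d=int(np.sum(~rp & ~cp)),
        row_label=row_label,
        col_label=col_label,
    )


def solve_cells(
    n: int, row_pos: int, col_pos: int, n_agree: int, row_label: str = "row", col_label: str = "col"
) -> ContingencyTable2x2:
    """Reconstruct the 2x2 table from printed marginals.

    With n observations, ``row_pos``/``col_pos`` positives per modality, and
    ``n_agree`` concordant cases, the both-positive cell is
    ``a = (row_pos + col_pos + n_agree - n) / 2``; the remaining cells follow.
    Raises :class:`InconsistentMarginalsError` when the solution is
    non-integer or any cell is negative.
    """
    twice_a = row_pos + col_pos + n_agree - n
    if twice_a % 2 != 0:
        raise InconsistentMarginalsError(
            f"marginals (n={n}, row_pos={row_pos}, col_pos={col_pos}, n_agree={n_agree}) give non-integer a"
        )
    a = twice_a // 2
    b = row_pos - a
    c = col_pos - a
    d = n_agree - a
    if min(a, b, c, d) < 0:
        raise InconsistentMarginalsError(
            f"marginals (n={n}, row_pos={row_pos}, col_pos={col_pos}, n_agree={n_agree}) "
            f"give a negative cell in ({a}, {b}, {c}, {d})"
        )
    return ContingencyTable2x2(a, b, c, d, row_label, col_label)


def percent_agreement(tab: ContingencyTable2x2) -> float:
    """Observed agreement fraction (a + d) / n."""
    return (tab.a + tab.d) / tab.n


def cohen_kappa(tab: ContingencyTable2x2) -> ConcordanceResult:
    """Cohen's kappa for a 2x2 table (unweighted, no CI)."""
    n = tab.n
    po = percent_agreement(tab)
    row_pos, col_pos = tab.a + tab.b, tab.a + tab.c
    pe = (row_pos * col_pos + (n - row_pos) * (n - col_pos)) / (n * n)
    if pe >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 (degenerate marginals)")
    return ConcordanceResult(po=po, pe=pe, kappa=(po - pe) / (1.0 - pe), n=n)


# ---------------------------------------------------------------------------
# Discordance patterns
# ---------------------------------------------------------------------------

#: Status columns compared pairwise; visual_read holds a status already, the
#: others are binarized from their value columns with the active cutoffs.
STATUS_MODALITIES = ("visual", "suvr", "centiloid", "ptau181", "abeta42_40_ratio")


def add_status_columns(cohort: pd.DataFrame, cutoffs: CutoffConfig | None = None) -> pd.DataFrame:
    """Return a copy with ``<biomarker>_status`` columns (NaN values stay NaN)."""
    cutoffs = cutoffs or CutoffConfig()
    out = cohort.copy()
    for name in ("suvr", "centiloid", "ptau181", "abeta42_40_ratio"):
        if name not in out.columns:
            raise KeyError(f"cohort table lacks required column {name!r}")
        values = out[name]
        out[f"{name}_status"] = [
            cutoffs.status_for(name, v) if np.isfinite(v) else None for v in values.to_numpy(dtype=float)
        ]
    return out


@dataclass
class DiscordanceReport:
    records: list[dict]
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {"counts": dict(sorted(self.counts.items())), "records": self.records}


def discordance_report(cohort: pd.DataFrame, cutoffs: CutoffConfig | None = None) -> DiscordanceReport:
    """Per-participant pairwise discordance patterns among the tau/amyloid statuses.

    Each pair is evaluated on its complete cases (rows where either status is
    missing — e.g. no lumbar puncture — are dropped for that pair only).
    """
    if "visual_read" not in cohort.columns:
        raise KeyError("cohort table lacks required column 'visual_read'")
    with_status = add_status_columns(cohort, cutoffs)
    status_col = {
        "visual": "visual_read",
        "suvr": "suvr_status",
        "centiloid": "centiloid_status",
        "ptau181": "ptau181_status",
        "abeta42_40_ratio": "abeta42_40_ratio_status",
    }
    records: list[dict] = []
    counts: dict[str, int] = {}
    for i, left in enumerate(STATUS_MODALITIES):
        for right in STATUS_MODALITIES[i + 1 :]:
            pair = f"{left}_vs_{right}"
            sub = with_status[["participant_id", status_col[left], status_col[right]]].dropna()
            discordant = sub[sub[status_col[left]] != sub[status_col[right]]]
            counts[pair] = int(len(discordant))
            for _, row in discordant.iterrows():
                records.append(
                    {
                        "participant_id": row["participant_id"],
                        "pair": pair,
                        left: row[status_col[left]],
                        right: row[status_col[right]],
                    }
                )
    return DiscordanceReport(records=records, counts=counts)


# ---------------------------------------------------------------------------
# Longitudinal trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryRecord:
    baseline_status: str
    followups: list[tuple[int, str]]  # (year, diagnosis), years strictly increasing

    def __post_init__(self) -> None:
        years = [y for y, _ in self.followups]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("follow-up years must be strictly increasing")


def classify_trajectory(record: TrajectoryRecord) -> str:
    """Trajectory category from the baseline diagnosis and yearly follow-ups.

    Rules applied in order: FTD at the last available visit -> reassigned_nonAD;
    baseline CN with an AD diagnosis later walked back -> reverter; baseline CN
    ending in AD -> converter_AD; all CN -> stable_CN; all AD -> stable_AD;
    anything else -> indeterminate.
    """
    if not record.followups:
        raise ValueError("at least one follow-up diagnosis is required")
    dxs = [dx for _, dx in record.followups]
    baseline = record.baseline_status
    if dxs[-1] == "FTD":
        return "reassigned_nonAD"
    if baseline == "CN":
        ad_positions = [i for i, dx in enumerate(dxs) if dx == "AD"]
        if ad_positions and any(dx != "AD" for dx in dxs[ad_positions[0] + 1 :]):
            return "reverter"
        if dxs[-1] == "AD":
            return "converter_AD"
    if baseline == "CN" and all(dx == "CN" for dx in dxs):
        return "stable_CN"
    if baseline == "AD" and all(dx == "AD" for dx in dxs):
        return "stable_AD"
    return "indeterminate"


def classify_cohort_trajectories(cohort: pd.DataFrame) -> pd.Series:
    """Trajectory category per cohort row (from baseline_dx and dx_year_* columns)."""
    year_cols = sorted(
        (c for c in cohort.columns if c.startswith("dx_year_")), key=lambda c: int(c.rsplit("_", 1)[1])
    )
    if not year_cols:
        raise KeyError("cohort table has no dx_year_* columns")
    categories = []
    for _, row in cohort.iterrows():
        followups = [
            (int(c.rsplit("_", 1)[1]), row[c]) for c in year_cols if isinstance(row[c], str) and row[c]
        ]
        record = TrajectoryRecord(baseline_status=row["baseline_dx"], followups=followups)
        categories.append(classify_trajectory(record))
    return pd.Series(categories, index=cohort.index, name="trajectory")
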