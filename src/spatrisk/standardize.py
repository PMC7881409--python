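"""Internal (indirect) standardization, SIRs and descriptive summaries.

The standardized incidence ratio SIR_i = O_i / E_i is the crude estimate of
area-level relative risk. Expected counts come from internal
standardization: the pooled study population's stratum-specific rates are
applied to each area's stratum populations, so expected counts sum exactly
to observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import StudyDataset, ValidationError


@dataclass
class SirSummary:
    """Per-sex descriptive summary of the area-level SIR distribution."""

    sex: str
    n_areas: int
    total_cases: int
    mean: float
    sd: float
    max: float
    min: float
    incidence_rate: Optional[float] = None  # per 1e5 person-years


@dataclass
class SirTable:
    """Per-area SIRs for one sex, plus the summary block."""

    sex: str
    table: pd.DataFrame  # columns: area, sex, observed, expected, sir
    summary: SirSummary

    def sir_for(self, area_id: str) -> float:
        sel = self.table.loc[self.table["area"] == area_id, "sir"]
        if sel.empty:
            raise KeyError(area_id)
        return float(sel.iloc[0])


def expected_internal(strata: pd.DataFrame) -> pd.Series:
    """Expected counts by internal standardization.

    ``strata`` has columns stratum_id, area_id, population (person-years,
    > 0) and cases. E_i = Σ_s n_is · (O_·s / n_·s) with rates pooled over
    the whole study population, which conserves the total: Σ E = Σ O.
    """
    required = {"stratum_id", "area_id", "population", "cases"}
    missing = required - set(strata.columns)
    if missing:
        raise ValidationError(f"stratum table missing columns {sorted(missing)}")
    if strata.duplicated(["stratum_id", "area_id"]).any():
        raise ValidationError("duplicate (stratum_id, area_id) pairs")
    if (strata["population"] <= 0).any():
        bad = strata.loc[strata["population"] <= 0]
        raise ValidationError(
            f"non-positive population in rows {bad.index.tolist()}"
        )
    if (strata["cases"] < 0).any():
        raise ValidationError("negative case counts in stratum table")
    by_stratum = strata.groupby("stratum_id").agg(
        cases=("cases", "sum"), population=("population", "sum")
    )
    rates = by_stratum["cases"] / by_stratum["population"]
    contrib = strata["population"].to_numpy() * rates.loc[
        strata["stratum_id"]
    ].to_numpy()
    return pd.Series(contrib, index=strata.index).groupby(
        strata["area_id"]
    ).sum()


def compute_sir(
    dataset: StudyDataset,
    sex: str = "both",
    person_years: Optional[float] = None,
) -> SirTable:
    """SIR_i = O_i / E_i per area, with the per-sex summary block.

    ``sex="both"`` pools observed and expected counts per area before the
    ratio is taken. ``person_years`` (optional, external) enables the crude
    incidence rate per 1e5 person-years in the summary.
    """
    recs = dataset.for_sex(sex)
    for r in recs:
        if r.expected <= 0:
            raise ValidationError(
                f"expected must be > 0 for an SIR (area {r.area_id!r})"
            )
    df = pd.DataFrame(
        {
            "area": [r.area_id for r in recs],
            "sex": sex,
            "observed": [r.observed for r in recs],
            "expected": [r.expected for r in recs],
        }
    )
    df["sir"] = df["observed"] / df["expected"]
    return SirTable(sex=sex, table=df, summary=summarize_sir(df, sex, person_years))


def summarize_sir(
    table: pd.DataFrame, sex: str, person_years: Optional[float] = None
) -> SirSummary:
    """Mean, sample sd (n−1), max and min of the SIRs across areas.

    The sample standard deviation is deliberate: it is what reproduces
    published summaries of this kind from the printed counts.
    """
    sirs = table["sir"].to_numpy(dtype=float)
    if sirs.size < 2:
        raise ValidationError("need >= 2 areas for an SIR summary (sd undefined)")
    total = int(table["observed"].sum())
    return SirSummary(
        sex=sex,
        n_areas=int(sirs.size),
        total_cases=total,
        mean=float(np.mean(sirs)),
        sd=float(np.std(sirs, ddof=1)),
        max=float(np.max(sirs)),
        min=float(np.min(sirs)),
        incidence_rate=(
            incidence_rate(total, person_years) if person_years else None
        ),
    )


def incidence_rate(total_cases: int, person_years: float) -> float:
    """Crude incidence rate per 1e5 person-years."""
    if person_years <= 0:
        raise ValidationError("person_years must be > 0")
    return 1e5 * total_cases / person_years


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding, matching printed-table precision conventions."""
    return float(np.round(x, ndigits))
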