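"""Curve response class (CRC) assignment for qHTS dose-response curves.

CRC codes grade each curve by completeness, efficacy, and fit quality:

* ``-1.x`` -- complete curve: both asymptotes spanned by the tested range.
* ``-2.x`` -- incomplete curve: only the upper asymptote spanned (the
  response has not plateaued at the top dose).
* ``-3``   -- activity at the single highest concentration only.
* ``4``    -- inactive: no dose reaches the activity floor.

The sub-digit distinguishes efficacy and fit quality: ``.1`` near-complete
response with a good fit, ``.2`` partial response with a good fit, ``.3``/``.4``
their poor-fit counterparts.  Negative codes denote inhibition (viability
decrease); activation classes do not occur in a cytotoxicity screen.

Hit tiers follow the qHTS convention: {-1.1, -1.2, -2.1, -2.2} are
highest-quality hits, {-1.3, -1.4, -2.3, -2.4, -3} inconclusive, 4 inactive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import ConcentrationSeries, FourPLFit, ViabilityProfile

__all__ = ["CrcRubric", "CrcCode", "classify_crc", "hit_tier", "HIGH_QUALITY_CODES"]

ALLOWED_CODES = frozenset(
    {-1.1, -1.2, -1.3, -1.4, -2.1, -2.2, -2.3, -2.4, -3.0, 4.0}
)
HIGH_QUALITY_CODES = frozenset({-1.1, -1.2, -2.1, -2.2})


@dataclass
class CrcRubric:
    """Numeric thresholds behind the class semantics (all config-exposed).

    activity_floor
        minimum % activity (100 - viability) any dose must reach for the
        compound to be considered active at all.
    high_efficacy
        % activity separating near-complete (.1) from partial (.2) response.
    r2_cutoff
        fit quality below which .1/.2 degrade to .3/.4.
    bottom_agreement
        max |observed top-dose viability - fitted lower asymptote| (in %)
        for the lower plateau to count as reached (curve "complete").
    edge_margin
        fraction of one dilution step the fitted logAC50 must sit inside
        the tested range for the curve to count as complete.
    """

    activity_floor: float = 30.0
    high_efficacy: float = 80.0
    r2_cutoff: float = 0.9
    bottom_agreement: float = 10.0
    edge_margin: float = 0.5


@dataclass(frozen=True)
class CrcCode:
    value: float

    def __post_init__(self) -> None:
        if round(self.value, 1) not in {round(c, 1) for c in ALLOWED_CODES}:
            raise ValueError(f"unknown CRC code {self.value}")

    @property
    def tier(self) -> str:
        return hit_tier(self.value)

    def __float__(self) -> float:
        return self.value


def hit_tier(crc: "CrcCode | float") -> str:
    """Map a CRC code to its hit-quality tier."""
    v = round(float(crc), 1)
    if v not in {round(c, 1) for c in ALLOWED_CODES}:
        raise ValueError(f"unknown CRC code {crc}")
    if v in {round(c, 1) for c in HIGH_QUALITY_CODES}:
        return "high_quality"
    if v == 4.0:
        return "inactive"
    return "inconclusive"


def classify_crc(
    profile: ViabilityProfile,
    fit: FourPLFit,
    series: ConcentrationSeries,
    rubric: CrcRubric = CrcRubric(),
) -> CrcCode:
    """Assign exactly one CRC code to a fitted curve.

    Decision order: inactive (floor never reached) and degenerate fits first,
    then the single-top-dose class, then complete vs incomplete with the
    efficacy and fit-quality sub-digits.
    """
    v = np.asarray(profile.viability_pct, dtype=float)
    finite = np.isfinite(v)
    activity = 100.0 - v[finite]
    if activity.size == 0:
        return CrcCode(4.0)
    max_act = float(np.max(activity))
    floor = rubric.activity_floor
    # activity confined to the single highest tested concentration
    single_top = (
        bool(finite[-1])
        and (100.0 - v[-1]) >= floor
        and np.all(activity[:-1] < floor)
    )

    if max_act < floor:
        return CrcCode(4.0)
    if not fit.converged:
        return CrcCode(-3.0) if single_top else CrcCode(4.0)

    x = series.log10_molar
    step = series.log_step
    inside = (
        x[0] + rubric.edge_margin * step
        <= fit.logac50
        <= x[-1] - rubric.edge_margin * step
    )
    plateau_reached = (
        bool(finite[-1]) and abs(v[-1] - fit.bottom_pct) <= rubric.bottom_agreement
    )
    complete = inside and plateau_reached

    if not complete and single_top:
        return CrcCode(-3.0)

    base = -1.0 if complete else -2.0
    sub = 0.1 if max_act >= rubric.high_efficacy else 0.2
    if fit.r2 < rubric.r2_cutoff:
        sub += 0.2
    return CrcCode(round(base - sub, 1))
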