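"""Safety-margin validation against repeat-dose inhalation NOAECs.

Experimental no-observed-adverse-effect concentrations (NOAEC, mg/m³) are
converted to daily doses (NOAEL, μg/day) with the default rat breathing rate
of 0.2 L/min over a 360 min/day exposure (72 L/day). Each chemical's NOAEL
is then compared with the headspace exposure the screening model permits at
its recommended concentration in a given solvent:

    margin = NOAEL / adjusted headspace exposure

A margin >= 1 means the model's recommendation is health-protective for that
chemical. Margins are summarized per solvent by geometric mean, range, and
strict counts below 1 and below 10 (the <10 count includes the <1 chemicals).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import gmean

from .errors import InputError
from .headspace import HeadspaceScenario, Solvent, adjusted_headspace_mass, get_solvent
from .screening import ScreeningResult

logger = logging.getLogger(__name__)

#: default rat breathing rate, L/min
DEFAULT_BREATHING_RATE_L_MIN = 0.2
#: default daily exposure duration, min/day
DEFAULT_EXPOSURE_MIN_PER_DAY = 360.0


@dataclass(frozen=True)
class ToxRecord:
    """One experimental inhalation NOAEC with exposure assumptions."""

    chemical_id: str
    noaec_mg_m3: float
    breathing_rate_L_min: float = DEFAULT_BREATHING_RATE_L_MIN
    exposure_min_per_day: float = DEFAULT_EXPOSURE_MIN_PER_DAY

    def __post_init__(self) -> None:
        if self.noaec_mg_m3 < 0:
            raise InputError(f"NOAEC must be >= 0 mg/m3, got {self.noaec_mg_m3}")
        if self.breathing_rate_L_min <= 0 or self.exposure_min_per_day <= 0:
            raise InputError("breathing rate and exposure duration must be > 0")


def noaec_to_noael(tox: ToxRecord) -> float:
    """Daily dose (μg/day) from an air concentration (mg/m³).

    NOAEL = NOAEC · breathing rate · duration, with mg/m³·L → μg via
    10⁻³ m³/L · 10³ μg/mg (the two factors cancel). Defaults give
    NOAEC × 72 μg/day.
    """
    litres_per_day = tox.breathing_rate_L_min * tox.exposure_min_per_day
    return tox.noaec_mg_m3 * litres_per_day  # mg/m3 * L/day * 1e-3 m3/L * 1e3 ug/mg


@dataclass
class SafetyMarginRecord:
    """Margin between an experimental NOAEL and the model's permitted exposure."""

    chemical_id: str
    solvent: str
    noael_ug_per_day: float
    adjusted_exposure_ug_per_day: float
    margin: float
    #: True when the permitted exposure is zero and the margin is +inf
    infinite: bool = False


def safety_margin(
    noael_ug_per_day: float,
    screening: ScreeningResult,
    solvent: str | Solvent,
    scenario: HeadspaceScenario | None = None,
    *,
    exposures_per_day: float = 1.0,
) -> SafetyMarginRecord:
    """Safety margin for one screened chemical in one solvent.

    The exposure term is the headspace mass above a solution at the model's
    recommended concentration (equal to the neat mass for capped chemicals,
    where the mole fraction is 1).
    """
    if noael_ug_per_day < 0:
        raise InputError(f"NOAEL must be >= 0 μg/day, got {noael_ug_per_day}")
    solv = get_solvent(solvent)
    if screening.capped:
        mass = screening.neat_headspace_mass_ug
    else:
        mass = adjusted_headspace_mass(
            screening.max_conc_pct_ww, screening.record, solv, scenario
        )
    exposure = mass * exposures_per_day
    if exposure > 0:
        margin, infinite = noael_ug_per_day / exposure, False
    else:
        margin, infinite = math.inf, True
        logger.warning(
            "record %s: permitted exposure is zero; margin reported as +inf",
            screening.record.id,
        )
    return SafetyMarginRecord(
        chemical_id=screening.record.id,
        solvent=solv.name,
        noael_ug_per_day=noael_ug_per_day,
        adjusted_exposure_ug_per_day=exposure,
        margin=margin,
        infinite=infinite,
    )


@dataclass
class MarginSummary:
    """Per-solvent margin statistics."""

    solvent: str
    geometric_mean: float
    min: float
    max: float
    n_below_1: int
    n_below_10: int
    n_total: int
    n_infinite: int

    @property
    def pct_above_1(self) -> float:
        """Percent of chemicals with margin >= 1 (the complement of n_below_1)."""
        return 100.0 * (self.n_total - self.n_below_1) / self.n_total

    @property
    def pct_above_10(self) -> float:
        """Percent of chemicals with margin >= 10."""
        return 100.0 * (self.n_total - self.n_below_10) / self.n_total


def summarize_margins(records: list[SafetyMarginRecord]) -> dict[str, MarginSummary]:
    """Summarize margins per solvent.

    The geometric mean runs over finite positive margins only; infinite
    margins (zero permitted exposure) are excluded from it and counted
    separately. "<1" and "<10" are strict counts, with the <10 count
    including the <1 chemicals.
    """
    if not records:
        raise InputError("no margin records to summarize")
    by_solvent: dict[str, list[SafetyMarginRecord]] = {}
    for r in records:
        by_solvent.setdefault(r.solvent, []).append(r)
    out: dict[str, MarginSummary] = {}
    for solvent, group in by_solvent.items():
        if not group:
            raise InputError(f"empty margin group for solvent {solvent}")
        margins = [r.margin for r in group]
        finite = [m for m in margins if math.isfinite(m) and m > 0]
        n_inf = sum(1 for m in margins if math.isinf(m))
        if n_inf:
            logger.info("solvent %s: %d infinite margins excluded from geometric mean",
                        solvent, n_inf)
        if not finite:
            raise InputError(f"solvent {solvent}: no finite positive margins to summarize")
        out[solvent] = MarginSummary(
            solvent=solvent,
            geometric_mean=float(gmean(finite)),
            min=min(margins),
            max=max(m for m in margins if math.isfinite(m)),
            n_below_1=sum(1 for m in margins if m < 1.0),
            n_below_10=sum(1 for m in margins if m < 10.0),
            n_total=len(group),
            n_infinite=n_inf,
        )
    return out


def run_validation(
    screenings: list[ScreeningResult],
    tox: dict[str, ToxRecord],
    solvents: list[str | Solvent],
    scenario: HeadspaceScenario | None = None,
    *,
    exposures_per_day: float = 1.0,
) -> tuple[list[SafetyMarginRecord], dict[str, MarginSummary]]:
    """Compute margins for every (screened chemical, solvent) pair and summarize.

    Chemicals without a tox record are skipped with a log message.
    """
    margins: list[SafetyMarginRecord] = []
    for s in screenings:
        t = tox.get(s.record.id)
        if t is None:
            logger.warning("no NOAEC for record %s; skipped in validation", s.record.id)
            continue
        noael = noaec_to_noael(t)
        for solvent in solvents:
            margins.append(
                safety_margin(noael, s, solvent, scenario,
                              exposures_per_day=exposures_per_day)
            )
    return margins, summarize_margins(margins)
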