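"""End-to-end screening: SMILES + vapor pressure → maximum safe concentration.

For each chemical the pipeline (i) classifies hazard and assigns a TTC,
(ii) computes the equilibrium headspace mass above the neat liquid, treats
one headspace volume per day as the exposure, and (iii) inverts the TTC into
a maximum solution concentration:

    max conc (% w/w) = min(100, TTC (μg/day) · 100 / exposure (μg/day))

Relatively non-volatile chemicals cap at 100 %; volatile and hazardous ones
are pushed down. Cohort-of-concern chemicals still produce numbers but the
result is marked out-of-domain and must not be used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import hazard as _hazard
from .chem import ChemicalRecord
from .errors import ConfigurationError, OdorsafeError
from .hazard import HazardResult
from .headspace import HeadspaceScenario, headspace_mass

logger = logging.getLogger(__name__)


def max_solution_concentration(ttc_ug_per_day: float, exposure_ug_per_day: float) -> float:
    """Maximum solution concentration (% w/w), capped at 100 %.

    Returns 100 when the neat exposure does not exceed the TTC.
    """
    if ttc_ug_per_day <= 0:
        raise ConfigurationError(f"TTC must be > 0 μg/day, got {ttc_ug_per_day}")
    if exposure_ug_per_day < 0:
        raise ConfigurationError(f"exposure must be >= 0 μg/day, got {exposure_ug_per_day}")
    if exposure_ug_per_day <= ttc_ug_per_day:
        return 100.0
    return ttc_ug_per_day * 100.0 / exposure_ug_per_day


@dataclass
class ScreeningResult:
    """One auditable per-chemical screening outcome."""

    record: ChemicalRecord
    hazard: HazardResult
    neat_headspace_mass_ug: float
    exposure_ug_per_day: float
    max_conc_pct_ww: float
    capped: bool
    out_of_domain: bool
    audit: list[dict] = field(default_factory=list)


def screen_chemical(
    record: ChemicalRecord,
    scenario: HeadspaceScenario | None = None,
    *,
    exposures_per_day: float = 1.0,
    ttc_table: dict[str, float] | None = None,
    override_label: str | None = None,
) -> ScreeningResult:
    """Run the full screening pipeline on one chemical.

    Parameters
    ----------
    record : ChemicalRecord
    scenario : HeadspaceScenario, optional
        Defaults to 0.1 L at 298 K with the reference constants.
    exposures_per_day : float
        Headspace volumes inhaled per day (default 1, once-daily exposure).
    ttc_table : dict, optional
        Override of the hazard-label → TTC mapping.
    override_label : str, optional
        Externally supplied hazard label (e.g. from a Toxtree export) used in
        place of the structure-based classification; the structure is still
        screened for cohort-of-concern flags.
    """
    scenario = scenario or HeadspaceScenario()
    if exposures_per_day <= 0:
        raise ConfigurationError(f"exposures_per_day must be > 0, got {exposures_per_day}")

    if override_label is None:
        hz = _hazard.classify(record.smiles, ttc_table)
        hazard_source = "structure"
    else:
        if override_label not in _hazard.HAZARD_PRECEDENCE:
            raise ConfigurationError(f"unknown override hazard label {override_label!r}")
        coc = _hazard.check_cohort_of_concern(record.smiles)
        hz = HazardResult(
            mutagen_alerts=[],
            cramer_class={"cramer_I": "I", "cramer_II": "II", "cramer_III": "III"}.get(
                override_label, "III"
            ),
            cramer_path=[],
            hazard_label=override_label,
            coc_flags=coc,
            ttc_ug_per_day=_hazard.assign_ttc(override_label, ttc_table),
            rulebook_versions={
                "cohort_of_concern": _hazard.cohort_of_concern_rulebook().tag,
                "hazard_source": "external override",
            },
        )
        hazard_source = "override"

    mass = headspace_mass(record.vp_mmHg, record.mw, scenario)
    exposure = mass * exposures_per_day
    conc = max_solution_concentration(hz.ttc_ug_per_day, exposure)
    capped = exposure <= hz.ttc_ug_per_day

    audit = [
        {"step": "hazard", "source": hazard_source, "label": hz.hazard_label,
         "rulebooks": hz.rulebook_versions, "cramer_path": hz.cramer_path},
        {"step": "ttc", "ttc_ug_per_day": hz.ttc_ug_per_day},
        {"step": "headspace", **scenario.describe(),
         "neat_headspace_mass_ug": mass, "exposures_per_day": exposures_per_day},
        {"step": "concentration", "max_conc_pct_ww": conc, "capped": capped},
    ]
    if hz.out_of_domain:
        logger.warning(
            "record %s matches cohort-of-concern classes %s; TTC screening "
            "must not be used for it", record.id, hz.coc_flags,
        )
    return ScreeningResult(
        record=record,
        hazard=hz,
        neat_headspace_mass_ug=mass,
        exposure_ug_per_day=exposure,
        max_conc_pct_ww=conc,
        capped=capped,
        out_of_domain=hz.out_of_domain,
        audit=audit,
    )


@dataclass
class BatchReport:
    """Summary of a batch screening run."""

    n_total: int
    n_ok: int
    errors: list[dict]
    hazard_counts: dict[str, int]
    n_capped: int
    n_out_of_domain: int


def screen_batch(
    records: list[ChemicalRecord],
    scenario: HeadspaceScenario | None = None,
    *,
    exposures_per_day: float = 1.0,
    ttc_table: dict[str, float] | None = None,
    overrides: dict[str, str] | None = None,
) -> tuple[list[ScreeningResult], BatchReport]:
    """Screen a list of chemicals, continuing past per-record failures.

    Order-preserving and deterministic. Per-record errors are collected into
    the report (with the chemical id attached) instead of aborting the run.
    """
    results: list[ScreeningResult] = []
    errors: list[dict] = []
    overrides = overrides or {}
    for rec in records:
        try:
            results.append(
                screen_chemical(
                    rec, scenario,
                    exposures_per_day=exposures_per_day,
                    ttc_table=ttc_table,
                    override_label=overrides.get(rec.id),
                )
            )
        except OdorsafeError as exc:
            logger.error("record %s failed: %s", rec.id, exc)
            errors.append({"id": rec.id, "error": type(exc).__name__, "message": str(exc)})
    counts: dict[str, int] = {}
    for r in results:
        counts[r.hazard.hazard_label] = counts.get(r.hazard.hazard_label, 0) + 1
    report = BatchReport(
        n_total=len(records),
        n_ok=len(results),
        errors=errors,
        hazard_counts=counts,
        n_capped=sum(r.capped for r in results),
        n_out_of_domain=sum(r.out_of_domain for r in results),
    )
    return results, report
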