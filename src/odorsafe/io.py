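"""Readers and writers for the tabular file boundary.

Column names carry their units (``vp_mmHg``, ``noaec_mg_m3``,
``max_conc_pct_ww``) so files are unambiguous on their own. Output files
start with a machine-readable ``# key = value`` metadata block (package
version, rulebook versions/checksums, scenario, config hash) sufficient to
reproduce them; readers skip ``#`` lines, so outputs round-trip.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .chem import ChemicalRecord
from .errors import LoadError, OdorsafeError
from .headspace import HeadspaceScenario
from .screening import ScreeningResult
from .validation import MarginSummary, SafetyMarginRecord, ToxRecord

logger = logging.getLogger(__name__)

REQUIRED_CHEMICAL_COLUMNS = ("id", "smiles", "vp_mmHg")
#: reporting precision for concentrations (significant figures)
CONC_SIGFIGS = 3


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{path}: file does not exist")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: file is empty") from None
    if df.empty and len(df.columns) == 0:
        raise LoadError(f"{path}: no data rows")
    return df


def read_chemicals(
    path: str | Path,
    fmt: str | None = None,
    vp_table: dict[str, float] | None = None,
) -> list[ChemicalRecord]:
    """Load chemical records from a CSV/TSV table or a .smi file.

    CSV/TSV needs columns id, smiles, vp_mmHg (name, cas, mw, vp_source
    optional; MW is computed from the structure when absent and a supplied
    MW deviating >0.5 % from the computed one flags the record). ``.smi``
    files carry ``SMILES id`` per line with vapor pressures supplied through
    *vp_table*. Unparseable rows are itemized in a single LoadError.
    """
    path = Path(path)
    if fmt is None:
        fmt = "smi" if path.suffix.lower() == ".smi" else "csv"

    rows: list[dict]
    if fmt == "smi":
        if not path.exists():
            raise LoadError(f"{path}: file does not exist")
        vp_table = vp_table or {}
        rows = []
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise LoadError(f"{path}:{ln}: expected 'SMILES id'")
            smiles, rid = parts[0], parts[1]
            if rid not in vp_table:
                raise LoadError(f"{path}:{ln}: no vapor pressure supplied for id {rid!r}")
            rows.append({"id": rid, "name": rid, "smiles": smiles,
                         "vp_mmHg": vp_table[rid]})
    elif fmt == "csv":
        df = _read_table(path)
        missing = [c for c in REQUIRED_CHEMICAL_COLUMNS if c not in df.columns]
        if missing:
            raise LoadError(f"{path}: missing required columns {missing}")
        rows = df.to_dict("records")
    else:
        raise LoadError(f"unknown chemical input format {fmt!r}")

    records: list[ChemicalRecord] = []
    problems: list[str] = []
    for i, row in enumerate(rows):
        try:
            def _opt(key):
                v = row.get(key)
                if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
                    return None
                return v

            mw = _opt("mw")
            records.append(
                ChemicalRecord(
                    id=str(row["id"]),
                    name=str(_opt("name") or row["id"]),
                    smiles=str(row["smiles"]),
                    vp_mmHg=float(row["vp_mmHg"]),
                    mw=float(mw) if mw is not None else None,
                    cas=_opt("cas"),
                    vp_source=str(_opt("vp_source") or "predicted"),
                )
            )
        except (OdorsafeError, ValueError, KeyError) as exc:
            problems.append(f"row {i + 1} (id={row.get('id', '?')}): {exc}")
    if problems:
        raise LoadError(f"{path}: {len(problems)} unloadable rows:\n  " + "\n  ".join(problems))
    if not records:
        raise LoadError(f"{path}: no data rows")
    return records


def read_tox_records(path: str | Path) -> dict[str, ToxRecord]:
    """Load NOAEC records: CSV with chemical_id, noaec_mg_m3 (+ optional
    breathing_rate_L_min, exposure_min_per_day)."""
    df = _read_table(path)
    for col in ("chemical_id", "noaec_mg_m3"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column {col!r}")
    out: dict[str, ToxRecord] = {}
    for i, row in enumerate(df.to_dict("records")):
        rid = str(row["chemical_id"])
        if rid in out:
            raise LoadError(f"{path}: duplicate chemical_id {rid!r}")
        kwargs = {}
        for key in ("breathing_rate_L_min", "exposure_min_per_day"):
            v = row.get(key)
            if v is not None and not pd.isna(v) and str(v).strip() != "":
                kwargs[key] = float(v)
        try:
            out[rid] = ToxRecord(chemical_id=rid, noaec_mg_m3=float(row["noaec_mg_m3"]), **kwargs)
        except (OdorsafeError, ValueError) as exc:
            raise LoadError(f"{path}: row {i + 1} (id={rid}): {exc}") from None
    return out


#: Toxtree-style Cramer verdict strings → hazard label
_CRAMER_VERDICTS = {
    "high (class iii)": "cramer_III",
    "intermediate (class ii)": "cramer_II",
    "low (class i)": "cramer_I",
    "class iii": "cramer_III",
    "class ii": "cramer_II",
    "class i": "cramer_I",
}
_NEGATIVE_MUTAGENICITY = {"", "no alerts", "no alerts for genotoxic carcinogenicity",
                          "negative", "none"}


def read_toxtree_overrides(path: str | Path) -> dict[str, str]:
    """Map a Toxtree-style CSV export to per-id hazard labels.

    Expects columns ``id`` and ``cramer`` (the Cramer verdict string) and
    optionally ``mutagenicity`` (any value other than a recognized negative
    counts as alert-positive and wins by precedence). Unrecognized verdicts
    and conflicting duplicate ids raise LoadError naming the row.
    """
    df = _read_table(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "id" not in cols or "cramer" not in cols:
        raise LoadError(f"{path}: need columns 'id' and 'cramer'")
    out: dict[str, str] = {}
    for i, row in enumerate(df.to_dict("records")):
        rid = str(row[cols["id"]])
        verdict = str(row[cols["cramer"]]).strip().lower()
        if verdict not in _CRAMER_VERDICTS:
            raise LoadError(f"{path}: row {i + 1} (id={rid}): unrecognized Cramer "
                            f"verdict {row[cols['cramer']]!r}")
        label = _CRAMER_VERDICTS[verdict]
        if "mutagenicity" in cols:
            mut = row[cols["mutagenicity"]]
            mut = "" if mut is None or pd.isna(mut) else str(mut).strip().lower()
            if mut not in _NEGATIVE_MUTAGENICITY:
                label = "mutagen"
        if rid in out and out[rid] != label:
            raise LoadError(f"{path}: conflicting duplicate id {rid!r} "
                            f"({out[rid]} vs {label})")
        out[rid] = label
    return out


def _sig(value: float, figures: int = CONC_SIGFIGS) -> str:
    return f"{value:.{figures}g}"


def _metadata_block(scenario: HeadspaceScenario, extra: dict | None = None) -> str:
    from .cramer import cramer_rulebook
    from .hazard import cohort_of_concern_rulebook, mutagenicity_rulebook

    meta = {
        "generator": f"odorsafe {__version__}",
        "rulebook_mutagenicity": mutagenicity_rulebook().tag,
        "rulebook_cohort_of_concern": cohort_of_concern_rulebook().tag,
        "rulebook_cramer": cramer_rulebook().tag,
        **scenario.describe(),
        **(extra or {}),
    }
    meta["config_sha256"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()
    ).hexdigest()[:16]
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def write_results(
    results: list[ScreeningResult],
    path: str | Path,
    scenario: HeadspaceScenario | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write screening results as CSV with a metadata header block.

    Byte-stable for identical inputs and configuration. Concentrations are
    reported to 3 significant figures; masses to 6.
    """
    scenario = scenario or HeadspaceScenario()
    rows = []
    for r in results:
        rows.append({
            "id": r.record.id,
            "name": r.record.name,
            "cas": r.record.cas or "",
            "smiles": r.record.smiles,
            "mw": f"{r.record.mw:.6g}",
            "mw_source": r.record.mw_source,
            "vp_mmHg": f"{r.record.vp_mmHg:.6g}",
            "vp_source": r.record.vp_source,
            "mutagen_alerts": ";".join(r.hazard.mutagen_alerts),
            "cramer_class": r.hazard.cramer_class,
            "hazard_label": r.hazard.hazard_label,
            "coc_flags": ";".join(r.hazard.coc_flags),
            "ttc_ug_per_day": f"{r.hazard.ttc_ug_per_day:.6g}",
            "neat_headspace_mass_ug": f"{r.neat_headspace_mass_ug:.6g}",
            "exposure_ug_per_day": f"{r.exposure_ug_per_day:.6g}",
            "max_conc_pct_ww": _sig(r.max_conc_pct_ww),
            "capped": str(r.capped).lower(),
            "out_of_domain": str(r.out_of_domain).lower(),
        })
    columns = ["id", "name", "cas", "smiles", "mw", "mw_source", "vp_mmHg",
               "vp_source", "mutagen_alerts", "cramer_class", "hazard_label",
               "coc_flags", "ttc_ug_per_day", "neat_headspace_mass_ug",
               "exposure_ug_per_day", "max_conc_pct_ww", "capped", "out_of_domain"]
    df = pd.DataFrame(rows, columns=columns)
    buf = _io.StringIO()
    buf.write(_metadata_block(scenario, extra_metadata))
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def write_margins(
    margins: list[SafetyMarginRecord],
    summaries: dict[str, MarginSummary],
    margins_path: str | Path,
    summary_path: str | Path,
    scenario: HeadspaceScenario | None = None,
) -> None:
    """Write per-chemical margins and the per-solvent summary as CSVs."""
    scenario = scenario or HeadspaceScenario()
    meta = _metadata_block(scenario)

    mrows = [{
        "chemical_id": m.chemical_id,
        "solvent": m.solvent,
        "noael_ug_per_day": f"{m.noael_ug_per_day:.6g}",
        "adjusted_exposure_ug_per_day": f"{m.adjusted_exposure_ug_per_day:.6g}",
        "margin": "inf" if m.infinite else f"{m.margin:.6g}",
    } for m in margins]
    buf = _io.StringIO()
    buf.write(meta)
    pd.DataFrame(mrows, columns=["chemical_id", "solvent", "noael_ug_per_day",
                                 "adjusted_exposure_ug_per_day", "margin"]
                 ).to_csv(buf, index=False, lineterminator="\n")
    Path(margins_path).write_text(buf.getvalue())

    srows = [{
        "solvent": s.solvent,
        "geometric_mean": f"{s.geometric_mean:.6g}",
        "min": f"{s.min:.6g}",
        "max": f"{s.max:.6g}",
        "n_below_1": s.n_below_1,
        "n_below_10": s.n_below_10,
        "n_total": s.n_total,
        "n_infinite": s.n_infinite,
        "pct_above_1": f"{s.pct_above_1:.1f}",
        "pct_above_10": f"{s.pct_above_10:.1f}",
    } for s in sorted(summaries.values(), key=lambda s: s.solvent)]
    buf = _io.StringIO()
    buf.write(meta)
    pd.DataFrame(srows).to_csv(buf, index=False, lineterminator="\n")
    Path(summary_path).write_text(buf.getvalue())


def write_panel(panel, chem_path: str | Path, tox_path: str | Path | None = None) -> None:
    """Write a fixture panel as a `screen`-compatible chemicals CSV (and,
    when present, a `validate`-compatible NOAEC CSV)."""
    rows = [{
        "id": r.id, "name": r.name, "cas": r.cas or "", "smiles": r.smiles,
        "vp_mmHg": f"{r.vp_mmHg:.6g}", "vp_source": r.vp_source, "mw": f"{r.mw:.6g}",
    } for r in panel.records]
    buf = _io.StringIO()
    buf.write(f"# generator = odorsafe {__version__}\n")
    buf.write(f"# panel_seed = {panel.seed}\n")
    pd.DataFrame(rows, columns=["id", "name", "cas", "smiles", "vp_mmHg",
                                "vp_source", "mw"]).to_csv(buf, index=False,
                                                           lineterminator="\n")
    Path(chem_path).write_text(buf.getvalue())
    if tox_path is not None and panel.tox:
        trows = [{
            "chemical_id": t.chemical_id,
            "noaec_mg_m3": f"{t.noaec_mg_m3:.6g}",
            "breathing_rate_L_min": t.breathing_rate_L_min,
            "exposure_min_per_day": t.exposure_min_per_day,
        } for t in panel.tox.values()]
        buf = _io.StringIO()
        buf.write(f"# generator = odorsafe {__version__}\n")
        buf.write(f"# panel_seed = {panel.seed}\n")
        pd.DataFrame(trows).to_csv(buf, index=False, lineterminator="\n")
        Path(tox_path).write_text(buf.getvalue())
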