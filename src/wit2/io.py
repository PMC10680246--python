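"""CSV/JSON/YAML glue: glucose panels, dose ledgers, cohorts, configs.

All CSV dialects are comma-separated UTF-8 with a mandatory header row,
glucose in mmol/L with a decimal point, days 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import CohortConfig, PatientProfile
from .protocol import MEALS, GlucosePanel, administered_units
from .trial import CohortResult, TrialRecord, records_to_frame

PANEL_COLUMNS = ["day", "fbg", "ppg_breakfast", "ppg_lunch", "ppg_dinner", "bg_0300"]


def read_panels_csv(path: str | Path) -> list[GlucosePanel]:
    """Read a per-day glucose panel history.

    Raises ``ValueError`` naming any missing column, or the offending line
    for unparseable/implausible values.
    """
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    panels = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            panels.append(
                GlucosePanel(
                    day=int(row["day"]),
                    fbg=float(row["fbg"]),
                    ppg={m: float(row[f"ppg_{m}"]) for m in MEALS},
                    bg_0300=float(row["bg_0300"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return panels


def write_panels_csv(panels: Sequence[GlucosePanel], path: str | Path) -> None:
    rows = [
        {
            "day": p.day,
            "fbg": p.fbg,
            **{f"ppg_{m}": p.ppg[m] for m in MEALS},
            "bg_0300": p.bg_0300,
        }
        for p in panels
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, index=False)


def write_dose_ledger_csv(record: TrialRecord, path: str | Path) -> None:
    """One row per patient-day: per-kg ledger, administered units, reasons."""
    rows = []
    for day_row in record.daily:
        row = dict(day_row)
        for inj, col in (
            ("basal", "basal_perkg"),
            ("breakfast", "bolus_breakfast_perkg"),
            ("lunch", "bolus_lunch_perkg"),
            ("dinner", "bolus_dinner_perkg"),
        ):
            row[f"{inj}_units"] = administered_units(row[col], record.weight)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort_csv(profiles: Sequence[PatientProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = dataclasses.asdict(p)
        ppg = row.pop("ppg_base")
        for m in MEALS:
            row[f"ppg_base_{m}"] = ppg[m]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientProfile]:
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            PatientProfile(
                id=str(row["id"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                fbg_base=float(row["fbg_base"]),
                ppg_base={m: float(row[f"ppg_base_{m}"]) for m in MEALS},
                s_basal=float(row["s_basal"]),
                s_bolus=float(row["s_bolus"]),
                c_spill=float(row["c_spill"]),
                lag=float(row["lag"]),
                noise_sd=float(row["noise_sd"]),
                nocturnal_dip=float(row["nocturnal_dip"]),
            )
        )
    return profiles


def write_results(result: CohortResult, outdir: str | Path) -> dict[str, Path]:
    """Write the tidy per-patient CSV and a provenance/metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.csv",
        "meta": outdir / "meta.json",
    }
    records_to_frame(result).to_csv(paths["results"], index=False)
    paths["meta"].write_text(json.dumps(dict(result.meta), indent=2, sort_keys=True))
    return paths


#: Run-level options recognized in the YAML config, with defaults.
RUN_OPTION_DEFAULTS = {
    "arm": None,
    "hypo_action": "reduce",
    "bolus_stop": "suspend",
    "rounding_mode": "nearest",
    "tdd_ceiling_per_kg": 3.0,
    "dropout_rate": 0.0,
    "noise": True,
}


def load_config(path: str | Path) -> tuple[CohortConfig, dict]:
    """Load a YAML config: a ``cohort`` block plus run-level options."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = dict(raw.get("cohort", {}))
    if "n_per_arm" in cohort_kwargs and isinstance(cohort_kwargs["n_per_arm"], list):
        cohort_kwargs["n_per_arm"] = tuple(cohort_kwargs["n_per_arm"])
    for key in ("weight_bounds", "height_bounds", "admission_bg_bounds", "lag_bounds"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(cohort_kwargs) - known
    if unknown:
        raise ValueError(f"{path}: unknown cohort option(s): {', '.join(sorted(unknown))}")
    config = CohortConfig(**cohort_kwargs)
    options = dict(RUN_OPTION_DEFAULTS)
    for key in options:
        if key in raw:
            options[key] = raw[key]
    return config, options
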