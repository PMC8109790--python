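"""CSV / SBP / JSON readers and writers and run configuration.

The single tabular interchange format is comma-delimited UTF-8 CSV with
a required header.  Tissue concentrations are g kg^-1, fertilizer doses
kg ha^-1, yields ton ha^-1.  Error messages always name the offending
column and row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .coda import (
    NUTRIENTS,
    PARTS,
    CodaError,
    ConfigurationError,
    SequentialBinaryPartition,
    TissueComposition,
    ValidationError,
    close_composition,
)
from .simulate import (
    DENSITY_FIELDS,
    FERTILIZER_ELEMENTS,
    MONTHS,
    SOIL_TEST_FIELDS,
    TEXTURE_FIELDS,
    ObservationRecord,
)

__all__ = [
    "OBSERVATION_COLUMNS",
    "SchemaError",
    "RunConfig",
    "read_observations",
    "write_observations",
    "observations_to_frame",
    "read_sbp",
    "write_sbp",
    "write_report",
    "read_report",
    "read_run_config",
]


class SchemaError(CodaError):
    """The file header does not match the expected schema."""


_KEY_COLUMNS = ("region", "site", "bed", "year", "cultivar", "farming_system")
_FERT_COLUMNS = tuple(f"fert_{e}" for e in FERTILIZER_ELEMENTS)
_TISSUE_COLUMNS = tuple(f"tissue_{p}" for p in NUTRIENTS)
_SOIL_COLUMNS = tuple(f"soil_{s}" for s in SOIL_TEST_FIELDS)
_TEXTURE_COLUMNS = tuple(f"texture_{t}" for t in TEXTURE_FIELDS)
_CLIMATE_COLUMNS = tuple(f"temp_{m}" for m in MONTHS) + tuple(f"precip_{m}" for m in MONTHS)

#: Full observation CSV schema, in column order.  ``tissue_Fv`` is
#: optional on read (validated when present, computed by closure when
#: absent) but always written.
OBSERVATION_COLUMNS: tuple[str, ...] = (
    _KEY_COLUMNS
    + _FERT_COLUMNS
    + _TISSUE_COLUMNS
    + ("tissue_Fv",)
    + _SOIL_COLUMNS
    + _TEXTURE_COLUMNS
    + DENSITY_FIELDS
    + ("soil_series",)
    + _CLIMATE_COLUMNS
    + ("yield",)
)


def observations_to_frame(records: Iterable[ObservationRecord]) -> pd.DataFrame:
    """Flatten records into the observation CSV schema."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "region": rec.region, "site": rec.site, "bed": rec.bed,
            "year": rec.year, "cultivar": rec.cultivar,
            "farming_system": rec.farming_system,
        }
        for e in FERTILIZER_ELEMENTS:
            row[f"fert_{e}"] = rec.fertilization[e]
        for p in NUTRIENTS:
            row[f"tissue_{p}"] = rec.composition[p]
        row["tissue_Fv"] = rec.composition.filling_value
        for s in SOIL_TEST_FIELDS:
            row[f"soil_{s}"] = rec.soil[s]
        for t in TEXTURE_FIELDS:
            row[f"texture_{t}"] = rec.texture[t]
        for d in DENSITY_FIELDS:
            row[d] = rec.bulk_density[d]
        row["soil_series"] = rec.soil_series
        for m in MONTHS:
            row[f"temp_{m}"] = rec.temperature[m]
        for m in MONTHS:
            row[f"precip_{m}"] = rec.precipitation[m]
        row["yield"] = rec.yield_t
        rows.append(row)
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    observations_to_frame(records).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Read and validate an observation CSV into typed records.

    The filling value column is optional: when present it must be
    consistent with closure to 1000 g kg^-1; when absent it is computed.
    Row numbers in error messages count data rows from 1.
    """
    df = pd.read_csv(path)
    required = [c for c in OBSERVATION_COLUMNS if c != "tissue_Fv"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        # report the bare nutrient name for tissue columns, as users know them
        names = [m.removeprefix("tissue_") if m.startswith("tissue_") else m
                 for m in missing]
        raise SchemaError(f"missing column(s): {', '.join(names)}")
    has_fv = "tissue_Fv" in df.columns
    records: list[ObservationRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            comp = close_composition([float(row[f"tissue_{p}"]) for p in NUTRIENTS])
            if has_fv and not np.isnan(row["tissue_Fv"]):
                if abs(float(row["tissue_Fv"]) - comp.filling_value) > 0.2:
                    raise ValidationError(
                        f"tissue_Fv={row['tissue_Fv']} inconsistent with closure "
                        f"value {comp.filling_value:.3f}"
                    )
            rec = ObservationRecord(
                region=str(row["region"]), site=str(row["site"]),
                bed=str(row["bed"]), year=int(row["year"]),
                cultivar=str(row["cultivar"]),
                farming_system=str(row["farming_system"]),
                fertilization={e: float(row[f"fert_{e}"]) for e in FERTILIZER_ELEMENTS},
                composition=comp,
                soil={s: float(row[f"soil_{s}"]) for s in SOIL_TEST_FIELDS},
                texture={t: float(row[f"texture_{t}"]) for t in TEXTURE_FIELDS},
                bulk_density={d: float(row[d]) for d in DENSITY_FIELDS},
                soil_series=str(row["soil_series"]),
                temperature={m: float(row[f"temp_{m}"]) for m in MONTHS},
                precipitation={m: float(row[f"precip_{m}"]) for m in MONTHS},
                yield_t=float(row["yield"]),
            )
        except CodaError as exc:
            raise type(exc)(f"row {i}: {exc}") from None
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# SBP sign-matrix files
# ---------------------------------------------------------------------------


def write_sbp(sbp: SequentialBinaryPartition, path: str | Path) -> None:
    """Write the SBP as a tab-separated sign matrix with a part header."""
    lines = ["\t".join(PARTS)]
    for row in sbp.contrasts:
        lines.append("\t".join(f"{v:+d}" if v else "0" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sbp(path: str | Path, sbp_id: str | None = None) -> SequentialBinaryPartition:
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header = tuple(text[0].split("\t"))
    if header != PARTS:
        raise ConfigurationError(
            f"SBP header must list parts {PARTS} in order, got {header}"
        )
    rows = []
    for i, line in enumerate(text[1:], start=1):
        try:
            rows.append([int(v) for v in line.split("\t")])
        except ValueError:
            raise ConfigurationError(f"SBP row {i}: entries must be integers") from None
    return SequentialBinaryPartition(np.array(rows), sbp_id=sbp_id or Path(path).stem)


# ---------------------------------------------------------------------------
# Diagnosis report JSON
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Serialize a DiagnosisReport deterministically.

    Distances are displayed at 2 decimal places with full precision kept
    in a ``raw`` block; two writes of the same report are byte-identical.
    """
    doc = report.to_dict()
    Path(path).write_text(
        json.dumps(doc, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings shared by the CLI commands."""

    cutoff: float = 40.0
    folds: int = 10
    seed: int = 0
    feature_sets: tuple[str, ...] = ()
    sbp_path: str = "default"
    filter_policy: str = "cultivar"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be > 0")
        if self.folds not in (5, 10, 20):
            raise ConfigurationError(f"folds must be one of 5, 10, 20; got {self.folds}")


def read_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "feature_sets" in raw:
        raw["feature_sets"] = tuple(raw["feature_sets"])
    return RunConfig(**raw)
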