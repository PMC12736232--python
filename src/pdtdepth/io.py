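"""Configuration, CSV formats, and the end-to-end pipeline run.

Everything tabular is plain CSV (UTF-8, LF line endings); the pipeline
config is a single YAML file.  Output files start with one comment line
carrying the package version, the SHA-256 of the canonical config text
and the seed, so a run is identifiable and a rerun with the same config
is byte-identical.

Serialization conventions: thickness in mm with one decimal, viability
in percent with two decimals, radiant exposure in J/cm2 with three
decimals; censored depths are the strings ``">max"`` and ``"none"``.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .dosimetry import IrradiationProtocol
from .optics import (
    AttenuationModel,
    TransmissionTable,
    fit_attenuation,
    load_transmission_csv,
    reference_transmission_table,
)
from .response import (
    DepthZoneProfile,
    NormalizedViability,
    normalize_viability,
    profiles_from_normalized,
    track_shifts,
)
from .synthetic import (
    CellLineProfile,
    DEFAULT_PROFILES,
    StudyDesign,
    ViabilityRecord,
    generate_study,
)
from .decision import Method, PACKAGED_SCENARIOS, scenario_report


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Parsed pipeline configuration plus its canonical raw mapping."""

    raw: dict
    protocol: IrradiationProtocol
    design: StudyDesign
    profiles: tuple[CellLineProfile, ...]
    optics_tables: dict[str, str | None]  # tissue -> CSV path or None (packaged)
    noise_cv: float
    seed: int | None
    output_dir: str

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def default_config_dict() -> dict:
    return {
        "protocol": {
            "source_irradiance_mw_cm2": 42.25,
            "duration_s": 3600,
            "wavelength_nm": 630,
            "ala_ug_ml": 100,
            "preincubation_h": 4,
        },
        "design": {
            "tissues": ["white", "gray"],
            "thickness_grid_white": [0, 1, 2, 3, 4, 5, 6],
            "thickness_grid_gray": [0, 1, 2, 3, 5, 7, 9],
            "assay_days": [5, 7, 11],
            "irradiation_day": 4,
            "replicates": 3,
        },
        "profiles": [
            {
                "name": p.name, "ed50": p.ed50, "hill": p.hill,
                "growth_rate": p.growth_rate, "regrowth_rate": p.regrowth_rate,
                "perm_threshold": p.perm_threshold,
                "cells_per_spheroid": p.cells_per_spheroid,
            }
            for p in DEFAULT_PROFILES
        ],
        "optics_tables": {"white": None, "gray": None},
        "noise_cv": 0.10,
        "seed": 1,
        "output_dir": "pdtdepth_out",
    }


def parse_config(raw: dict) -> PipelineConfig:
    try:
        proto = raw.get("protocol", {})
        protocol = IrradiationProtocol(
            source_irradiance=float(proto.get("source_irradiance_mw_cm2", 42.25)),
            duration_s=float(proto.get("duration_s", 3600)),
            wavelength_nm=float(proto.get("wavelength_nm", 630)),
            ala_concentration_ug_ml=float(proto.get("ala_ug_ml", 100)),
            preincubation_h=float(proto.get("preincubation_h", 4)),
        )
        des = raw.get("design", {})
        design = StudyDesign(
            tissues=tuple(des.get("tissues", ("white", "gray"))),
            thickness_grid_white=tuple(des.get("thickness_grid_white", (0, 1, 2, 3, 4, 5, 6))),
            thickness_grid_gray=tuple(des.get("thickness_grid_gray", (0, 1, 2, 3, 5, 7, 9))),
            assay_days=tuple(des.get("assay_days", (5, 7, 11))),
            irradiation_day=float(des.get("irradiation_day", 4)),
            replicates=int(des.get("replicates", 3)),
        )
        profs = tuple(
            CellLineProfile(
                name=p["name"], ed50=float(p["ed50"]), hill=float(p["hill"]),
                growth_rate=float(p.get("growth_rate", 0.35)),
                regrowth_rate=float(p.get("regrowth_rate", 0.12)),
                perm_threshold=float(p.get("perm_threshold", 25.0)),
                cells_per_spheroid=float(p.get("cells_per_spheroid", 7500.0)),
            )
            for p in raw.get("profiles", default_config_dict()["profiles"])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc

    noise_cv = float(raw.get("noise_cv", 0.10))
    seed = raw.get("seed")
    if noise_cv > 0 and seed is None:
        raise ConfigError("a seed is required whenever noise_cv > 0")
    tables = dict(raw.get("optics_tables") or {})
    for tissue in design.tissues:
        tables.setdefault(tissue, None)
    return PipelineConfig(
        raw=raw, protocol=protocol, design=design, profiles=profs,
        optics_tables=tables, noise_cv=noise_cv,
        seed=None if seed is None else int(seed),
        output_dir=str(raw.get("output_dir", "pdtdepth_out")),
    )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    return parse_config(raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Plate CSV round trip
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["cell_line", "condition", "tissue", "thickness_mm",
                 "day", "replicate", "luminescence"]


def records_to_plate_frame(records: Sequence[ViabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": r.cell_line,
            "condition": r.condition,
            "tissue": "" if r.tissue is None else r.tissue,
            "thickness_mm": "" if r.thickness_mm is None else f"{r.thickness_mm:.1f}",
            "day": r.day,
            "replicate": r.replicate,
            "luminescence": r.luminescence,
        }
        for r in records
    )[PLATE_COLUMNS]


def read_plate_csv(path) -> list[ViabilityRecord]:
    df = pd.read_csv(path, comment="#")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        tissue = None if pd.isna(row.tissue) or row.tissue == "" else str(row.tissue)
        thick = None if pd.isna(row.thickness_mm) else float(row.thickness_mm)
        out.append(ViabilityRecord(
            cell_line=str(row.cell_line), condition=str(row.condition),
            tissue=tissue, thickness_mm=thick, day=float(row.day),
            replicate=int(row.replicate), luminescence=float(row.luminescence),
        ))
    return out


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _header_comment(config_hash: str, seed) -> str:
    return f"# pdtdepth {__version__} config_sha256={config_hash} seed={seed}\n"


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str, seed) -> None:
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(_header_comment(config_hash, seed) + buf.getvalue(),
                    encoding="utf-8", newline="\n")


def normalized_to_frame(normalized: Sequence[NormalizedViability]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": nv.cell_line,
            "condition": nv.condition,
            "tissue": "" if nv.tissue is None else nv.tissue,
            "thickness_mm": "" if nv.thickness_mm is None else f"{nv.thickness_mm:.1f}",
            "day": nv.day,
            "mean_pct": f"{nv.mean_pct:.2f}",
            "sd_pct": f"{nv.sd_pct:.2f}",
            "n": nv.n,
            "zone": nv.zone.value,
        }
        for nv in normalized
    )


def _fmt_depth(value) -> str:
    if isinstance(value, str):
        return value
    if value is None:
        return "none"
    return f"{value:.1f}"


def profiles_to_frame(profiles: Sequence[DepthZoneProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": p.cell_line,
            "tissue": p.tissue,
            "day": p.day,
            "deepest_effect_mm": _fmt_depth(p.deepest_effect_mm),
            "no_effect_onset_mm": _fmt_depth(p.no_effect_onset_mm),
        }
        for p in profiles
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    models: dict[str, AttenuationModel]
    records: list[ViabilityRecord]
    normalized: list[NormalizedViability]
    profiles: list[DepthZoneProfile]
    shift_tables: dict[tuple[str, str], pd.DataFrame]
    decision_table: pd.DataFrame


def fit_optics_stage(config: PipelineConfig) -> dict[str, AttenuationModel]:
    models = {}
    for tissue in config.design.tissues:
        path = config.optics_tables.get(tissue)
        table = (reference_transmission_table(tissue) if path is None
                 else load_transmission_csv(path))
        models[tissue] = fit_attenuation(table)
    return models


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    plates_csv: str | Path | None = None,
) -> PipelineResult:
    """Execute fit-optics -> simulate/load -> analyze -> shifts -> decision.

    When ``plates_csv`` is given those measurements are analyzed instead
    of simulating; otherwise the synthetic generator runs with the
    config's profiles, design, noise and seed.  If ``out_dir`` is given
    all stage outputs are written there (deterministically, so identical
    config means identical bytes).
    """
    models = fit_optics_stage(config)

    if plates_csv is not None:
        records = read_plate_csv(plates_csv)
    else:
        records = generate_study(
            profiles=config.profiles, design=config.design, models=models,
            protocol=config.protocol, noise_cv=config.noise_cv, seed=config.seed,
        )

    normalized = normalize_viability(records)
    grids = {t: config.design.grid(t) for t in config.design.tissues}
    profiles = profiles_from_normalized(normalized, grids)

    shift_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for key in sorted({(p.cell_line, p.tissue) for p in profiles}):
        group = [p for p in profiles if (p.cell_line, p.tissue) == key]
        shift_tables[key] = track_shifts(group)

    decision_table = scenario_report(
        PACKAGED_SCENARIOS, method=Method.MONTE_CARLO, reps=100_000,
        seed=config.seed if config.seed is not None else 0,
    )

    result = PipelineResult(models, records, normalized, profiles,
                            shift_tables, decision_table)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    h, seed = config.config_hash, config.seed

    fits = pd.DataFrame(
        {
            "tissue": m.tissue,
            "surface_irradiance_mw_cm2": f"{m.surface_irradiance_fit:.4f}",
            "mu_eff_per_mm": f"{m.mu_eff_fit:.4f}",
            "r_squared": f"{m.r_squared:.4f}",
            "n_points": m.n_points,
        }
        for m in result.models.values()
    )
    _write_csv(fits, out / "optics_fits.csv", h, seed)
    _write_csv(records_to_plate_frame(result.records), out / "plates.csv", h, seed)
    _write_csv(normalized_to_frame(result.normalized), out / "normalized.csv", h, seed)
    _write_csv(profiles_to_frame(result.profiles), out / "profiles.csv", h, seed)

    shift_rows = []
    for (cell_line, tissue), table in result.shift_tables.items():
        for day, row in table.iterrows():
            shift_rows.append({
                "cell_line": cell_line, "tissue": tissue, "day": day,
                "deepest_effect_mm": row["deepest_effect_mm"],
                "no_effect_onset_mm": row["no_effect_onset_mm"],
                "anomalous_deepening": row["anomalous_deepening"],
            })
    _write_csv(pd.DataFrame(shift_rows), out / "shifts.csv", h, seed)

    dec = result.decision_table.copy()
    for col in ("p_correct", "p_incorrect", "standard_error"):
        dec[col] = dec[col].map(lambda v: f"{v:.6f}")
    _write_csv(dec, out / "decision.csv", h, seed)

    counts = {
        "plates": len(result.records),
        "normalized": len(result.normalized),
        "profiles": len(result.profiles),
        "shift_tables": len(result.shift_tables),
        "decision_rows": len(result.decision_table),
    }
    log_lines = [
        f"pdtdepth {__version__}",
        f"config_sha256={h}",
        f"seed={seed}",
        f"noise_cv={config.noise_cv}",
    ] + [f"records[{k}]={v}" for k, v in counts.items()]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                     encoding="utf-8", newline="\n")
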