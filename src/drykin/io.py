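"""CSV I/O, pipeline configuration, and the end-to-end analysis pipeline.

The drying-curve CSV schema has columns ``temperature_C, replicate,
time_h, mass_g`` (or ``moisture_db`` in place of ``mass_g``), UTF-8 with
dot decimal separator, preceded by an optional header block of
``# key = value`` lines carrying per-file metadata (``slab_thickness_m``,
``initial_wet_basis_moisture_pct``, ``dry_solid_mass_g``).  Carotenoid
CSVs mirror published concentration tables: ``temperature_C, compound,
concentration_mg_per_100g, sd``.

``run_pipeline`` strings the stages together: moisture-ratio conversion,
per-temperature thin-layer model fitting and ranking, effective
diffusivity and Arrhenius activation-energy estimation, specific drying
energy, and carotenoid degradation fitting, producing CSV reports plus a
run log recording seeds and every default not taken from data.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .degradation import CarotenoidSeries, fit_degradation, predict_concentration
from .diffusion import estimate_deff, fit_arrhenius
from .drying_data import (
    DryingCurve,
    DryingDataError,
    MoistureObservation,
    moisture_ratio_series,
)
from .energy import EnergyConfig, specific_energy
from .model_fitting import FitOptions, fit_all
from .thin_layer_models import MODEL_NAMES

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "read_drying_csv",
    "write_drying_csv",
    "read_carotenoid_csv",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("drykin")

_METADATA_KEYS = {
    "slab_thickness_m",
    "initial_wet_basis_moisture_pct",
    "dry_solid_mass_g",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration, with the offending key in the message."""


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; loadable from a TOML file."""

    drying_csv: Path | None = None
    carotenoid_csv: Path | None = None
    models: tuple[str, ...] = MODEL_NAMES
    intercept_mode: str = "fixed"
    r2_variant: str = "conventional"
    degradation_form: str = "logistic"
    energy: dict | None = None  # keys of EnergyConfig minus per-run ones
    output_dir: Path = Path("drykin_out")
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {}
        for key in ("drying_csv", "carotenoid_csv", "output_dir"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        for key in ("models",):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        for key in ("intercept_mode", "r2_variant", "degradation_form", "seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "energy" in raw:
            kwargs["energy"] = dict(raw.pop("energy"))
        if raw:
            raise ConfigError(f"unknown config keys in {path}: {sorted(raw)}")
        config = cls(**kwargs)
        config.validate()
        return config

    def validate(self) -> None:
        if len(self.models) == 0:
            raise ConfigError("config key 'models': empty model list")
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ConfigError(
                f"config key 'models': unknown model(s) {unknown}; valid: {list(MODEL_NAMES)}"
            )
        if self.intercept_mode not in ("fixed", "free"):
            raise ConfigError(
                f"config key 'intercept_mode': must be 'fixed' or 'free', got {self.intercept_mode!r}"
            )
        if self.r2_variant not in ("conventional", "as_printed"):
            raise ConfigError(
                f"config key 'r2_variant': must be 'conventional' or 'as_printed', "
                f"got {self.r2_variant!r}"
            )
        if self.degradation_form not in ("logistic", "exponential"):
            raise ConfigError(
                f"config key 'degradation_form': must be 'logistic' or 'exponential', "
                f"got {self.degradation_form!r}"
            )


def _read_metadata_block(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key = key.strip()
            if key in _METADATA_KEYS:
                meta[key] = float(value.strip())
    return meta


def read_drying_csv(path: str | Path) -> list[DryingCurve]:
    """Read drying curves from CSV, one curve per (temperature, replicate).

    Raises a schema error naming missing columns; malformed numeric values
    and non-monotone times are reported with their line numbers.
    """
    path = Path(path)
    meta = _read_metadata_block(path)
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise DryingDataError(f"{path}: cannot parse CSV: {exc}") from exc

    required = {"temperature_C", "replicate", "time_h"}
    missing = required - set(df.columns)
    if missing:
        raise DryingDataError(f"{path}: missing required column(s): {sorted(missing)}")
    has_mass = "mass_g" in df.columns
    has_mdb = "moisture_db" in df.columns
    if not has_mass and not has_mdb:
        raise DryingDataError(f"{path}: need a 'mass_g' or 'moisture_db' column")

    value_col = "mass_g" if has_mass else "moisture_db"
    for col in ("temperature_C", "time_h", value_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # header + 1-based
            raise DryingDataError(
                f"{path}:{row}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} (comma decimal separators are not accepted; use '.')"
            )
        df[col] = coerced

    thickness = meta.get("slab_thickness_m", 0.01)
    curves = []
    for (temp, rep), grp in df.groupby(["temperature_C", "replicate"], sort=True):
        grp = grp.reset_index()
        times = grp["time_h"].to_numpy()
        if np.any(np.diff(times) <= 0):
            j = int(np.argmax(np.diff(times) <= 0))
            row = int(grp.loc[j + 1, "index"]) + 2
            raise DryingDataError(
                f"{path}:{row}: non-monotone time_h within curve T={temp}, replicate={rep}"
            )
        obs = tuple(
            MoistureObservation(
                time=float(t * 3600.0),
                mass=float(v) if has_mass else None,
                moisture_dry_basis=None if has_mass else float(v),
            )
            for t, v in zip(times, grp[value_col])
        )
        curves.append(
            DryingCurve(
                temperature=float(temp),
                slab_thickness=thickness,
                observations=obs,
                initial_wet_basis_moisture=meta.get("initial_wet_basis_moisture_pct"),
                dry_solid_mass=meta.get("dry_solid_mass_g"),
                replicate_id=str(rep),
            )
        )
    return curves


def write_drying_csv(curves: list[DryingCurve], path: str | Path) -> None:
    """Write drying curves in the same schema :func:`read_drying_csv` consumes."""
    path = Path(path)
    first = curves[0]
    rows = []
    for curve in curves:
        for obs in curve.observations:
            rows.append(
                {
                    "temperature_C": curve.temperature,
                    "replicate": curve.replicate_id,
                    "time_h": obs.time / 3600.0,
                    "mass_g": obs.mass,
                }
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# slab_thickness_m = {first.slab_thickness!r}\n")
        if first.initial_wet_basis_moisture is not None:
            fh.write(
                f"# initial_wet_basis_moisture_pct = {first.initial_wet_basis_moisture!r}\n"
            )
        if first.dry_solid_mass is not None:
            fh.write(f"# dry_solid_mass_g = {first.dry_solid_mass!r}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_carotenoid_csv(path: str | Path) -> list[CarotenoidSeries]:
    """Read carotenoid series (one per compound) from CSV."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    required = {"temperature_C", "compound", "concentration_mg_per_100g"}
    missing = required - set(df.columns)
    if missing:
        raise DryingDataError(f"{path}: missing required column(s): {sorted(missing)}")
    out = []
    for compound, grp in df.groupby("compound", sort=True):
        grp = grp.sort_values("temperature_C")
        out.append(
            CarotenoidSeries(
                compound=str(compound),
                temperatures=grp["temperature_C"].to_numpy(dtype=float),
                concentrations=grp["concentration_mg_per_100g"].to_numpy(dtype=float),
                uncertainties=grp["sd"].to_numpy(dtype=float) if "sd" in grp else None,
            )
        )
    return out


def run_pipeline(config: PipelineConfig, curves: list[DryingCurve] | None = None,
                 carotenoids: list[CarotenoidSeries] | None = None) -> dict:
    """Run the full drying-kinetics analysis.

    Inputs come from the config's CSV paths or may be passed directly.
    Returns a report bundle of DataFrames:

    * ``model_fits`` — per-temperature model constants and statistics;
    * ``deff`` — per-temperature D_eff regression results;
    * ``arrhenius`` — one-row activation-energy fit (when >= 3 temperatures);
    * ``energy`` — per-temperature specific energy (when configured);
    * ``degradation`` — per-compound retention fits and predictions;
    * ``log`` — run metadata: version, seed, non-data defaults used.

    Per-model fit failures become flagged rows; stage-level data errors
    abort with the stage named.
    """
    config.validate()
    if curves is None and config.drying_csv is not None:
        curves = read_drying_csv(config.drying_csv)
    if carotenoids is None and config.carotenoid_csv is not None:
        carotenoids = read_carotenoid_csv(config.carotenoid_csv)

    bundle: dict = {}
    log_lines = [
        f"drykin {__version__}",
        f"seed = {config.seed}",
        f"models = {','.join(config.models)}",
        f"intercept_mode = {config.intercept_mode} (default: fixed at ln(8/pi^2))",
        f"r2_variant = {config.r2_variant}",
    ]

    options = FitOptions(r2_variant=config.r2_variant)  # type: ignore[arg-type]

    if curves:
        fit_rows = []
        deff_rows = []
        deff_map: dict[float, float] = {}
        for curve in curves:
            try:
                series = moisture_ratio_series(curve)
            except DryingDataError as exc:
                raise DryingDataError(
                    f"stage moisture_ratio (T={curve.temperature} °C, "
                    f"replicate={curve.replicate_id}): {exc}"
                ) from exc
            table = fit_all(series, config.models, options)
            for r in table:
                fit_rows.append(
                    {
                        "model": r.model,
                        "temperature_C": curve.temperature,
                        "replicate": curve.replicate_id,
                        "constants": ";".join(
                            f"{k}={v:.6g}" for k, v in (r.params.items() if r.error is None else [])
                        ),
                        "r_squared": r.r_squared,
                        "chi_squared": r.chi_squared,
                        "rmse": r.rmse,
                        "rank": table.results.index(r) + 1,
                        "error": r.error or "",
                    }
                )
            est = estimate_deff(series, config.intercept_mode)  # type: ignore[arg-type]
            deff_rows.append(
                {
                    "temperature_C": curve.temperature,
                    "slope_per_s": est.slope,
                    "d_eff_m2_per_s": est.d_eff,
                    "r_squared": est.r_squared,
                    "chi_squared": est.chi_squared,
                    "rmse": est.rmse,
                }
            )
            deff_map.setdefault(curve.temperature, est.d_eff)
        bundle["model_fits"] = pd.DataFrame(fit_rows)
        bundle["deff"] = pd.DataFrame(deff_rows)
        if len(deff_map) >= 3:
            arr = fit_arrhenius(deff_map)
            bundle["arrhenius"] = pd.DataFrame(
                [
                    {
                        "d0_m2_per_s": arr.d0,
                        "e_a_kj_per_mol": arr.e_a / 1000.0,
                        "r_squared": arr.r_squared,
                        "chi_squared": arr.chi_squared,
                        "rmse": arr.rmse,
                    }
                ]
            )

    if config.energy is not None and curves:
        e = dict(config.energy)
        times = {c.temperature: c.times[-1] / 3600.0 for c in curves}
        rows = []
        for temp, t_h in sorted(times.items()):
            cfg = EnergyConfig(
                plate_area=e.get("plate_area", 0.09),
                air_velocity=e.get("air_velocity", 1.0),
                air_density=e.get("air_density", 1.06),
                air_specific_heat=e.get("air_specific_heat", 1.007),
                air_temperature=temp,
                ambient_temperature=e.get("ambient_temperature", 25.0),
                sample_mass=e.get("sample_mass", 0.03),
                drying_time=t_h,
                formula_variant=e.get("formula_variant", "dimensional"),
            )
            rows.append(
                {
                    "temperature_C": temp,
                    "drying_time_h": t_h,
                    "specific_energy_kwh_per_kg": specific_energy(cfg),
                }
            )
        bundle["energy"] = pd.DataFrame(rows)
        log_lines.append(
            "energy defaults (non-data unless overridden): plate_area=0.09 m^2, "
            "air_velocity=1.0 m/s, air_density=1.06 kg/m^3, "
            "air_specific_heat=1.007 kJ/kg/°C, ambient=25 °C"
        )

    if carotenoids:
        rows = []
        for series in carotenoids:
            fit = fit_degradation(series, config.degradation_form)  # type: ignore[arg-type]
            grid = np.arange(series.temperatures[0], 111.0, 5.0)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")  # extrapolation to 110 °C is intended here
                pred = predict_concentration(fit, grid)
            rows.append(
                {
                    "compound": series.compound,
                    "form": fit.form,
                    "params": ";".join(f"{k}={v:.6g}" for k, v in fit.params.items()),
                    "c_ref_mg_per_100g": fit.reference_concentration,
                    "r_squared": fit.r_squared,
                    "chi_squared": fit.chi_squared,
                    "rmse": fit.rmse,
                    "predictions": ";".join(
                        f"{t:g}C={p:.2f}" for t, p in zip(grid, pred)
                    ),
                }
            )
        bundle["degradation"] = pd.DataFrame(rows)

    bundle["log"] = pd.DataFrame({"entry": log_lines})
    return bundle


def write_report(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write every table of a report bundle as CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
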