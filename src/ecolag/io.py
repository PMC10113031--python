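"""File formats: LPD-style wide population tables, long environment tables,
traits, and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environment import EnvSeries
from .trends import AbundanceSeries

__all__ = [
    "RunConfig",
    "read_populations",
    "write_populations",
    "read_environment",
    "write_environment",
    "read_traits",
    "write_traits",
]

META_COLS = [
    "population_id",
    "binomial",
    "class",
    "latitude",
    "longitude",
    "realm",
    "pa",
    "man",
    "use",
    "location",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    populations_csv: str
    environment_csv: str
    traits_csv: str
    taxon_class: str = "bird"
    structures: list[str] = field(default_factory=lambda: ["MU"])
    currencies: list[str] = field(default_factory=lambda: ["years"])
    max_year_lag: int = 49
    subset_dimensions: list[str] = field(default_factory=lambda: ["all"])
    scenarios: list[str] = field(default_factory=lambda: ["SSP1", "SSP3", "SSP5"])
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    run_influence_screen: bool = False
    run_projection: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def write_populations(series: list[AbundanceSeries], path: str | Path) -> None:
    """LPD-style wide CSV: metadata columns then one column per year."""
    if not series:
        raise ValueError("nothing to write")
    y0 = min(s.span[0] for s in series)
    y1 = max(s.span[1] for s in series)
    years = list(range(y0, y1 + 1))
    rows = []
    for s in series:
        row = {
            "population_id": s.population_id,
            "binomial": s.binomial,
            "class": s.taxon_class,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "realm": s.realm,
            "pa": s.pa,
            "man": s.man,
            "use": s.use,
            "location": s.location or "",
        }
        for y, v in zip(s.years, s.values):
            row[str(int(y))] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLS + [str(y) for y in years])
    df.to_csv(path, index=False)


def read_populations(path: str | Path) -> list[AbundanceSeries]:
    """Read the wide CSV back into AbundanceSeries; blank cells = unobserved.

    Duplicate ids, negative abundances, unparseable year columns and all-blank
    rows are reported as itemized errors.
    """
    df = pd.read_csv(path, dtype={"population_id": str})
    errors: list[str] = []
    year_cols = []
    for c in df.columns:
        if c in META_COLS:
            continue
        try:
            year_cols.append((int(c), c))
        except ValueError:
            errors.append(f"unparseable year column {c!r}")
    dup = df["population_id"][df["population_id"].duplicated()]
    for pid in dup:
        errors.append(f"duplicate population id {pid!r}")
    out: list[AbundanceSeries] = []
    for _, row in df.iterrows():
        yrs, vals = [], []
        for y, c in year_cols:
            v = row[c]
            if pd.isna(v):
                continue
            v = float(v)
            if v < 0:
                errors.append(f"{row['population_id']}: negative abundance {v} in {y}")
                continue
            yrs.append(y)
            vals.append(v)
        if not yrs:
            errors.append(f"{row['population_id']}: no observations")
            continue
        loc = row.get("location", "")
        out.append(
            AbundanceSeries(
                population_id=str(row["population_id"]),
                binomial=str(row["binomial"]),
                taxon_class=str(row["class"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                realm=str(row["realm"]),
                pa=int(row["pa"]),
                man=int(row["man"]),
                use=int(row["use"]),
                years=np.array(yrs),
                values=np.array(vals),
                location=str(loc) if isinstance(loc, str) and loc else None,
            )
        )
    if errors:
        raise ValueError("population table errors:\n" + "\n".join(errors))
    return out


def write_environment(
    historical: dict[str, EnvSeries],
    path: str | Path,
    scenarios: dict[str, dict[str, EnvSeries]] | None = None,
) -> None:
    """Long CSV: location_key, year, temperature_C, anthro_fraction, scenario."""
    frames = []

    def block(env: dict[str, EnvSeries], label: str) -> pd.DataFrame:
        return pd.concat(
            pd.DataFrame(
                {
                    "location_key": s.location,
                    "year": s.years,
                    "temperature_C": s.temperature,
                    "anthro_fraction": s.anthro,
                    "scenario": label,
                }
            )
            for s in env.values()
        )

    frames.append(block(historical, ""))
    if scenarios:
        for name, env in scenarios.items():
            frames.append(block(env, name))
    pd.concat(frames).to_csv(path, index=False)


def read_environment(
    path: str | Path,
) -> tuple[dict[str, EnvSeries], dict[str, dict[str, EnvSeries]]]:
    """Read the long environment CSV into historical and scenario series."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["scenario"] = df["scenario"].astype(str)
    historical: dict[str, EnvSeries] = {}
    scenarios: dict[str, dict[str, EnvSeries]] = {}
    for (label, loc), g in df.groupby(["scenario", "location_key"]):
        g = g.sort_values("year")
        s = EnvSeries(
            str(loc),
            g["year"].to_numpy(),
            g["temperature_C"].to_numpy(),
            g["anthro_fraction"].to_numpy(),
        )
        if label == "":
            historical[str(loc)] = s
        else:
            scenarios.setdefault(label, {})[str(loc)] = s
    return historical, scenarios


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=True)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("binomial")
    if "body_mass" in df and (df["body_mass"] <= 0).any():
        raise ValueError("non-positive body mass in traits table")
    return df


def pop_meta_frame(series: list[AbundanceSeries]) -> pd.DataFrame:
    """Metadata frame (indexed by population_id) from an AbundanceSeries list."""
    rows = []
    for s in series:
        rows.append(
            {
                "population_id": s.population_id,
                "binomial": s.binomial,
                "class": s.taxon_class,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "realm": s.realm,
                "pa": s.pa,
                "man": s.man,
                "use": s.use,
                "location": s.location or f"{s.latitude:.4f}_{s.longitude:.4f}",
            }
        )
    return pd.DataFrame(rows).set_index("population_id")
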