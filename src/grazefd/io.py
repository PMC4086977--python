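"""CSV interchange for trait tables, community matrices and plot-year records.

CSV is the interchange format throughout; units are embedded in column
headers (``rain_mm``, ``cwm_ldmc_mg_per_g``, ``productivity_lu``) so they
cannot silently drift.  Trait tables travel with a YAML sidecar recording the
coding schemes, weights and transforms.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .fdmetrics import validate_community
from .traits import TraitScheme, TraitTable, RawTraitEntry, build_trait_table

__all__ = [
    "read_raw_trait_entries",
    "read_trait_table",
    "write_trait_table",
    "read_community",
    "write_community",
    "read_records",
    "write_records",
    "read_inputs",
]

KEY_COLS = ["experiment", "block", "plot", "year"]
RECORD_REQUIRED = KEY_COLS + ["productivity_lu", "rain_mm", "temp_c"]


class SchemaError(ValueError):
    """A CSV does not match its documented schema."""


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


def read_raw_trait_entries(path: str | Path) -> list[RawTraitEntry]:
    """Long-format raw entries: species_id, trait_name, value, replication."""
    df = pd.read_csv(path)
    _require(df, ["species_id", "trait_name", "value"], "raw trait CSV")
    if "replication" not in df.columns:
        df["replication"] = 1
    return [
        RawTraitEntry(str(r.species_id), str(r.trait_name), r.value, int(r.replication))
        for r in df.itertuples(index=False)
    ]


def write_trait_table(table: TraitTable, csv_path: str | Path,
                      sidecar_path: str | Path | None = None) -> None:
    """Wide coded CSV plus a YAML sidecar with the coding metadata."""
    csv_path = Path(csv_path)
    table.data.rename_axis("species_id").to_csv(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.yaml")
    meta = {
        "log_base": "e",
        "schemes": {
            name: {
                "kind": s.kind,
                "coding_map": dict(s.coding_map),
                "log_transform": s.log_transform,
                "weight": s.weight,
                "scale": list(s.scale) if s.scale else None,
            }
            for name, s in table.schemes.items()
        },
    }
    # keep insertion order so the reconstructed table has identical columns
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))


def read_trait_table(csv_path: str | Path,
                     sidecar_path: str | Path | None = None) -> TraitTable:
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path, index_col="species_id")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.yaml")
    meta = yaml.safe_load(sidecar.read_text())
    schemes = {
        name: TraitScheme(
            trait_name=name,
            kind=d["kind"],
            coding_map=d.get("coding_map") or {},
            log_transform=bool(d.get("log_transform", False)),
            weight=float(d.get("weight", 1.0)),
            scale=tuple(d["scale"]) if d.get("scale") else None,
        )
        for name, d in meta["schemes"].items()
    }
    extra = set(data.columns) - set(schemes)
    if extra:
        raise SchemaError(f"trait CSV columns without schemes: {sorted(extra)}")
    return TraitTable(data=data[list(schemes)], schemes=schemes)


def write_community(community: pd.DataFrame, path: str | Path) -> None:
    community.to_csv(path)


def read_community(path: str | Path, strict: bool = True, tol: float = 1e-9) -> pd.DataFrame:
    """Wide community CSV keyed by experiment/block/plot/year.

    Rows not summing to 1 are an error under ``strict``; otherwise they are
    renormalised with a warning.
    """
    df = pd.read_csv(path)
    _require(df, KEY_COLS, "community CSV")
    df = df.set_index(KEY_COLS)
    sums = df.sum(axis=1)
    off = (sums - 1.0).abs() > tol
    if off.any():
        if strict:
            raise SchemaError(
                f"{int(off.sum())} community rows do not sum to 1 "
                f"(first offender {df.index[off.argmax()]})"
            )
        import warnings

        warnings.warn(f"renormalising {int(off.sum())} community rows not summing to 1")
        df = df.div(sums, axis=0)
    validate_community(df, tol=max(tol, 1e-9))
    return df


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RECORD_REQUIRED, "plot-year record CSV")
    dup = df.duplicated(subset=["experiment", "plot", "year", "block"])
    if dup.any():
        raise SchemaError(f"{int(dup.sum())} duplicate (experiment, plot, year) records")
    if (df["rain_mm"] < 0).any() or (df["productivity_lu"] < 0).any():
        raise SchemaError("rain_mm and productivity_lu must be nonnegative")
    return df


def read_inputs(trait_csv, community_csv, records_csv):
    """Read and cross-validate the three analysis inputs.

    The community's species must all exist in the trait table; a mismatch is
    reported as the symmetric difference of the two species sets.
    """
    traits = read_trait_table(trait_csv)
    community = read_community(community_csv)
    records = read_records(records_csv)
    sp_c, sp_t = set(community.columns), set(traits.species)
    if sp_c - sp_t:
        raise SchemaError(
            "species mismatch between community and trait table; symmetric difference: "
            f"{sorted(sp_c.symmetric_difference(sp_t))}"
        )
    return traits, community, records
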