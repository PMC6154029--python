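"""Delimited-text readers/writers for the pipeline's table schemas.

All tables are plain CSV with headers: genotype matrices (rows = lines,
columns = markers, cells E/K or empty for missing), genetic maps (marker,
group, pos_cm), growth series (plant_id, line, treatment, replicate, day,
psa_kpixels), line trait tables (line, trait, value, n_replicates) and field
plot tables (site, year, salt_level, row, range, line, trait columns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_genotype_csv(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, index_label="line", na_rep="NA")


def read_genotype_csv(path) -> pd.DataFrame:
    geno = pd.read_csv(path, index_col="line", dtype=str, na_values=["NA"])
    return geno.astype(object).where(geno.notna(), np.nan)


def write_map_csv(gmap: pd.DataFrame, path) -> None:
    gmap.to_csv(path, index=False)


def read_map_csv(path) -> pd.DataFrame:
    gmap = pd.read_csv(path, dtype={"marker": str, "group": str, "pos_cm": float})
    required = {"marker", "group", "pos_cm"}
    if not required <= set(gmap.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    return gmap


def write_growth_csv(growth: pd.DataFrame, path) -> None:
    growth.to_csv(path, index=False)


def read_growth_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"plant_id": str, "line": str, "treatment": str,
               "replicate": int, "day": int, "psa_kpixels": float},
    )


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=False)


def read_traits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"line": str, "trait": str, "value": float})


def trait_series(traits: pd.DataFrame, name: str) -> pd.Series:
    """One trait as a Series indexed by line (input to the QTL scan)."""
    sub = traits[traits["trait"] == name]
    if sub.empty:
        raise ValueError(f"trait {name!r} not present in the trait table")
    return pd.Series(sub["value"].to_numpy(), index=sub["line"].to_numpy(), name=name)


def write_field_csv(field: pd.DataFrame, path) -> None:
    field.to_csv(path, index=False)


def read_field_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
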