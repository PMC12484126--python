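"""Per-shoot composite traits from leaf-level records.

Leaf tables are plain DataFrames with canonical columns

    shoot, species, length, width [, area, mass]

(lengths/widths cm, areas cm^2, masses g). Aggregation produces one row per
shoot with the composite traits the shoot-level models consume:

- ``n_leaves``    leaf count N_T
- ``area_total``  total lamina area A_T = sum A_i
- ``mass_total``  total leaf dry mass M_T (from leaf masses or a per-shoot table)
- ``width_sum``   sum of leaf widths (the L_KS composite)
- ``length_max``  maximum leaf length (the W_KS composite)

The sum-of-widths / max-length pair are the Koyama-Smith composites whose
product stands in for total area in the shoot-level proportionality; their
two labels are swapped in parts of the literature, but the fitted product is
label-invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, MissingDataError

__all__ = ["LEAF_COLUMNS", "SHOOT_COLUMNS", "aggregate_shoots", "validate_leaf_table"]

LEAF_COLUMNS = ("shoot", "species", "length", "width", "area", "mass")
SHOOT_COLUMNS = (
    "shoot",
    "species",
    "n_leaves",
    "area_total",
    "mass_total",
    "width_sum",
    "length_max",
)


def validate_leaf_table(leaves: pd.DataFrame) -> pd.DataFrame:
    """Check the leaf-table contract; returns the table unchanged.

    Requires ``shoot, length, width`` columns, positive lengths and widths,
    and positive area/mass where present. A missing ``species`` column is
    filled with a single placeholder label.
    """
    for col in ("shoot", "length", "width"):
        if col not in leaves.columns:
            raise DataValidationError(f"leaf table lacks required column {col!r}")
    if "species" not in leaves.columns:
        leaves = leaves.assign(species="unspecified")
    for col in ("length", "width"):
        bad = ~(pd.to_numeric(leaves[col], errors="coerce") > 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"leaf table column {col!r} must be positive; first offending row {row} "
                f"(value {leaves[col].iloc[row]!r})"
            )
    for col in ("area", "mass"):
        if col in leaves.columns:
            vals = pd.to_numeric(leaves[col], errors="coerce")
            bad = leaves[col].notna() & ~(vals > 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataValidationError(
                    f"leaf table column {col!r} must be positive where present; "
                    f"first offending row {row} (value {leaves[col].iloc[row]!r})"
                )
    return leaves


def aggregate_shoots(
    leaves: pd.DataFrame,
    shoot_mass: pd.DataFrame | None = None,
    montgomery_k: float | None = None,
) -> pd.DataFrame:
    """Aggregate leaf records into one ShootRecord row per shoot.

    Parameters
    ----------
    leaves
        Leaf table (see module docstring). If ``area`` is absent it is
        derived as ``montgomery_k * length * width``; with neither available
        a :class:`MissingDataError` is raised.
    shoot_mass
        Optional per-shoot dry-mass table with columns ``shoot, mass_total``,
        used when leaf masses were pooled before weighing. Ignored for shoots
        whose leaves carry individual masses.
    montgomery_k
        Proportionality constant used to impute missing leaf areas.
    """
    leaves = validate_leaf_table(leaves)

    species_per_shoot = leaves.groupby("shoot")["species"].nunique()
    mixed = species_per_shoot[species_per_shoot > 1]
    if len(mixed):
        raise DataValidationError(
            f"shoot(s) {list(mixed.index)[:5]} contain leaves from more than one species"
        )

    if "area" in leaves.columns and leaves["area"].notna().all():
        area = leaves["area"].astype(float)
    elif montgomery_k is not None:
        if not montgomery_k > 0:
            raise DataValidationError("montgomery_k must be positive")
        observed = (
            leaves["area"].astype(float)
            if "area" in leaves.columns
            else pd.Series(np.nan, index=leaves.index)
        )
        area = observed.fillna(montgomery_k * leaves["length"] * leaves["width"])
    else:
        raise MissingDataError(
            "leaf areas are missing and no Montgomery constant was supplied to derive them"
        )

    work = leaves.assign(area=area)
    grouped = work.groupby("shoot", sort=True)
    shoots = pd.DataFrame(
        {
            "species": grouped["species"].first(),
            "n_leaves": grouped.size(),
            "area_total": grouped["area"].sum(),
            "width_sum": grouped["width"].sum(),
            "length_max": grouped["length"].max(),
        }
    )

    if "mass" in work.columns and work["mass"].notna().all():
        shoots["mass_total"] = grouped["mass"].sum()
    elif shoot_mass is not None:
        if not {"shoot", "mass_total"} <= set(shoot_mass.columns):
            raise DataValidationError("shoot_mass table needs columns 'shoot' and 'mass_total'")
        mass = shoot_mass.set_index("shoot")["mass_total"].astype(float)
        if not (mass > 0).all():
            raise DataValidationError("shoot_mass mass_total values must be positive")
        shoots["mass_total"] = shoots.index.map(mass)
    else:
        shoots["mass_total"] = np.nan

    shoots = shoots.reset_index().rename(columns={"index": "shoot"})
    return shoots[list(SHOOT_COLUMNS)]
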