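"""End-to-end analysis: tables in, machine-readable run report out.

``run_analysis`` takes a leaf-level trait table (and optionally a per-shoot
dry-mass table), aggregates it to shoots, fits the per-species trait
distributions (normal / log-normal / Weibull), the proportional Montgomery
and shoot-level (MKSE) models, and the three shoot-level power laws —
total area against the width-sum x max-length composite (OLS, same
dimensions), against leaf count (RMA) and against total dry mass (RMA) —
with percentile-bootstrap CIs, isometry tests and, for two-species runs,
cross-species difference tests. The report is a plain nested dict that
serialises to JSON and round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import aggregate_shoots, validate_leaf_table
from .bootstrap import DEFAULT_REPLICATES, bootstrap_param, compare_two, test_against_value
from .distributions import (
    LogNormalDistribution,
    NormalDistribution,
    WeibullDistribution,
)
from .exceptions import DataValidationError, ShootScaleError
from .regression import PowerLawRegression, ProportionalRegression, select_method

__all__ = ["run_analysis", "read_leaf_table", "read_shoot_mass_table", "write_report", "read_report"]

_TRAITS = {
    "leaf_count": "n_leaves",
    "total_area": "area_total",
    "total_mass": "mass_total",
}
_FAMILIES = {
    "normal": NormalDistribution,
    "lognormal": LogNormalDistribution,
    "weibull": WeibullDistribution,
}
# relationship -> (x column, y column, x dimension, y dimension)
_RELATIONSHIPS = {
    "area_vs_composite": ("composite", "area_total", "area", "area"),
    "area_vs_count": ("n_leaves", "area_total", "count", "area"),
    "area_vs_mass": ("mass_total", "area_total", "mass", "area"),
}


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays so json round-trips exactly."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def read_leaf_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a delimited leaf table into the canonical schema.

    ``column_map`` maps canonical names (shoot, species, length, width,
    area, mass) to the file's column names when they differ. Non-numeric or
    non-positive trait cells raise a load error naming the row and column.
    """
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise DataValidationError(f"{path}: mapped column(s) {missing} not found")
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    for col in ("length", "width", "area", "mass"):
        if col in df.columns:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & parsed.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataValidationError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} "
                    f"in column {col!r}, row {row}"
                )
            df[col] = parsed
    try:
        return validate_leaf_table(df)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def read_shoot_mass_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a per-shoot dry-mass table (columns shoot, mass_total)."""
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    if not {"shoot", "mass_total"} <= set(df.columns):
        raise DataValidationError(f"{path}: needs columns 'shoot' and 'mass_total'")
    return df


def _distribution_section(sample: np.ndarray) -> dict:
    section: dict = {"families": {}}
    best_family, best_p = None, -1.0
    for name, cls in _FAMILIES.items():
        try:
            fit = cls().fit(sample).summary(sample)
            section["families"][name] = {
                "params": fit.params,
                "loglik": fit.loglik,
                "ks_D": fit.ks_D,
                "ks_p": fit.ks_p,
                "skew_class": fit.skew_class,
            }
            if fit.ks_p > best_p:
                best_family, best_p = name, fit.ks_p
        except ShootScaleError as exc:
            section["families"][name] = {"error": str(exc)}
    section["best_family"] = best_family
    # the distribution figure annotates both spreads; emit both readings
    section["mean"] = float(np.mean(sample))
    section["sd"] = float(np.std(sample, ddof=1))
    section["se"] = float(np.std(sample, ddof=1) / np.sqrt(len(sample)))
    section["n"] = int(len(sample))
    return section


def _proportional_section(x, y, boot_reps, seed, level, log_base) -> tuple[dict, np.ndarray]:
    est = ProportionalRegression(log_base=log_base)
    boot = bootstrap_param(x, y, est, param="k_", B=boot_reps, seed=seed, level=level)
    fit = est.result()
    section = {
        "k": fit.k_hat,
        "log_k": fit.log_k,
        "n": fit.n,
        "rmse": fit.rmse,
        "rmse_dof": "n-1",
        "r2": fit.r2,
        "mape": fit.mape,
        "ci_k": [boot.ci_lo, boot.ci_hi],
        "boot_seed": seed,
    }
    return section, boot.replicates


def _powerlaw_section(x, y, method, boot_reps, seed, level, log_base) -> dict:
    est = PowerLawRegression(method=method, log_base=log_base)
    boot_a = bootstrap_param(x, y, est, param="alpha_", B=boot_reps, seed=seed, level=level)
    boot_g = bootstrap_param(x, y, est, param="gamma_", B=boot_reps, seed=seed, level=level)
    boot_b = bootstrap_param(x, y, est, param="beta_", B=boot_reps, seed=seed, level=level)
    fit = est.result()
    iso_ci, contains_one = test_against_value(boot_a.replicates, 1.0, level=level)
    return {
        "alpha": fit.alpha,
        "gamma": fit.gamma,
        "beta": fit.beta,
        "method": method,
        "n": fit.n,
        "rmse": fit.rmse,
        "rmse_dof": "n-2",
        "r2": fit.r2,
        "ci_alpha": [boot_a.ci_lo, boot_a.ci_hi],
        "ci_gamma": [boot_g.ci_lo, boot_g.ci_hi],
        "ci_beta": [boot_b.ci_lo, boot_b.ci_hi],
        "isometry": {"ci_alpha": list(iso_ci), "contains_one": contains_one},
        "boot_seed": seed,
        "_alpha_replicates": boot_a.replicates,
        "_beta_replicates": boot_b.replicates,
    }


def run_analysis(
    leaves: pd.DataFrame,
    shoot_mass: pd.DataFrame | None = None,
    *,
    boot_reps: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    ci_level: float = 0.95,
    log_base: str | float = "e",
    montgomery_k: float | None = None,
) -> dict:
    """Run the full shoot-scaling analysis and return the run report.

    Deterministic given ``seed``: one master stream derives a logged
    sub-seed for every bootstrap task in a fixed order. Species with fewer
    than 3 shoots have their shoot-level sections marked unavailable; a
    missing mass column simply omits the area-vs-mass section.
    """
    leaves = validate_leaf_table(leaves)
    shoots_all = aggregate_shoots(leaves, shoot_mass=shoot_mass, montgomery_k=montgomery_k)
    master = np.random.default_rng(seed)

    def task_seed() -> int:
        return int(master.integers(2**31))

    species_names = sorted(leaves["species"].unique())
    report: dict = {
        "provenance": {
            "package": "shootscale",
            "version": __version__,
            "seed": seed,
            "boot_reps": int(boot_reps),
            "ci_level": float(ci_level),
            "log_base": str(log_base),
            "n_leaves": int(len(leaves)),
            "n_shoots": int(len(shoots_all)),
            "species": species_names,
        },
        "species": {},
        "comparisons": {},
    }

    replicate_store: dict[tuple[str, str, str], np.ndarray] = {}

    for sp in species_names:
        sp_leaves = leaves[leaves["species"] == sp]
        sp_shoots = shoots_all[shoots_all["species"] == sp]
        sp_report: dict = {
            "n_shoots": int(len(sp_shoots)),
            "n_leaves": int(len(sp_leaves)),
            "distributions": {},
        }
        has_mass = sp_shoots["mass_total"].notna().all()

        for trait, col in _TRAITS.items():
            if col == "mass_total" and not has_mass:
                continue
            sample = sp_shoots[col].to_numpy(dtype=float)
            try:
                sp_report["distributions"][trait] = _distribution_section(sample)
            except ShootScaleError as exc:
                sp_report["distributions"][trait] = {"error": str(exc)}

        # per-leaf Montgomery fit needs observed leaf areas
        if "area" in sp_leaves.columns and sp_leaves["area"].notna().all():
            lw = (sp_leaves["length"] * sp_leaves["width"]).to_numpy(dtype=float)
            a = sp_leaves["area"].to_numpy(dtype=float)
            sp_report["montgomery"], replicate_store[(sp, "montgomery", "k")] = (
                _proportional_section(lw, a, boot_reps, task_seed(), ci_level, log_base)
            )

        composite = (sp_shoots["width_sum"] * sp_shoots["length_max"]).to_numpy(dtype=float)
        area_t = sp_shoots["area_total"].to_numpy(dtype=float)
        if len(sp_shoots) >= 3:
            sp_report["mkse"], replicate_store[(sp, "mkse", "k")] = _proportional_section(
                composite, area_t, boot_reps, task_seed(), ci_level, log_base
            )
            shoot_cols = sp_shoots.assign(composite=composite)
            sp_report["power_laws"] = {}
            for rel, (xcol, ycol, dim_x, dim_y) in _RELATIONSHIPS.items():
                if xcol == "mass_total" and not has_mass:
                    continue
                method = select_method(dim_x, dim_y)
                x = shoot_cols[xcol].to_numpy(dtype=float)
                y = shoot_cols[ycol].to_numpy(dtype=float)
                try:
                    section = _powerlaw_section(
                        x, y, method, boot_reps, task_seed(), ci_level, log_base
                    )
                except ShootScaleError as exc:
                    sp_report["power_laws"][rel] = {"error": str(exc), "method": method}
                    continue
                replicate_store[(sp, rel, "alpha")] = section.pop("_alpha_replicates")
                replicate_store[(sp, rel, "beta")] = section.pop("_beta_replicates")
                sp_report["power_laws"][rel] = section
        else:
            sp_report["mkse"] = {"error": "fewer than 3 shoots; shoot-level fits unavailable"}
            sp_report["power_laws"] = {}

        report["species"][sp] = sp_report

    if len(species_names) == 2:
        sp_a, sp_b = species_names
        comp: dict = {"species": [sp_a, sp_b]}
        pairs = [(rel, param) for rel in _RELATIONSHIPS for param in ("alpha", "beta")]
        pairs += [("montgomery", "k"), ("mkse", "k")]
        for rel, param in pairs:
            ra = replicate_store.get((sp_a, rel, param))
            rb = replicate_store.get((sp_b, rel, param))
            if ra is None or rb is None:
                continue
            lo, hi, sig = compare_two(ra, rb, level=ci_level)
            comp[f"{rel}_{param}"] = {
                "diff_ci": [lo, hi],
                "significant": sig,
            }
        report["comparisons"] = comp

    return _jsonify(report)


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a run report to JSON (sorted keys, stable formatting)."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration, for provenance records."""
    blob = json.dumps(_jsonify(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
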