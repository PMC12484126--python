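"""Synthetic shoot populations with controllable isometry structure.

The generator builds leaf- and shoot-level tables with the statistical
features the scaling analysis assumes: Weibull-distributed (or fixed) leaf
counts per shoot, within-shoot leaf areas laid out as a geometric series,
a width-length power allometry ``W = c * L**b``, a Montgomery ratio that is
constant or declines with leaf size, log-normal multiplicative measurement
noise on areas, and a per-leaf mass-area power law.

Four structural conditions jointly force exact shoot-level isometry between
total area ``A_T`` and the composite ``(sum of widths) x (max length)``:

1. the leaf count is constant across shoots;
2. within-shoot areas follow a geometric series;
3. the common ratio of that series is constant across shoots;
4. leaf width is a power function of leaf length.

The default configuration encodes those conditions exactly (with zero
noise this drives the fitted log-log slope to one at machine precision,
the module's headline oracle); every condition can be relaxed or broken
individually so the sensitivity of the slope to each assumption can be
measured rather than asserted.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .aggregate import aggregate_shoots
from .exceptions import DataValidationError, MissingDataError

__all__ = [
    "SyntheticConfig",
    "generate_shoot",
    "generate_population",
    "attach_mass",
    "weibull_from_moments",
    "study_conditions",
]


def weibull_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Weibull (shape, scale) whose mean and SD match the given moments."""
    if mean <= 0 or sd <= 0:
        raise DataValidationError("mean and sd must be positive")
    cv = sd / mean

    def gap(shape):
        g1 = special.gamma(1 + 1 / shape)
        g2 = special.gamma(1 + 2 / shape)
        return np.sqrt(g2 / g1**2 - 1) - cv

    shape = float(optimize.brentq(gap, 0.02, 200.0, xtol=1e-12))
    scale = mean / special.gamma(1 + 1 / shape)
    return shape, float(scale)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic shoot population (one species).

    Leaf counts: ``leaf_count_model='fixed'`` uses ``n_leaves`` everywhere
    (isometry condition 1); ``'weibull'`` draws counts from a Weibull with
    ``(count_shape, count_scale)`` and takes the ceiling (>= 1).

    Within-shoot areas: smallest area ``a_min`` is log-uniform over
    ``a_min_range`` (cm^2); areas ascend as ``a_min * q**i`` (condition 2).
    ``q_sd > 0`` jitters the ratio per shoot on the log scale (breaking
    condition 3); ``within_ratio`` instead fixes the largest/smallest area
    ratio so ``q`` adapts to the leaf count (also breaking condition 3 when
    counts vary, as in real shoots); ``series='uniform'`` scatters areas
    uniformly over the same span (breaking condition 2).

    Leaf shape: ``W = c * L**b`` (condition 4); ``width_offset`` adds an
    affine term (breaking it). The Montgomery ratio is ``k0`` everywhere, or
    declines with lamina length as ``k = k0 * (L / L0)**(-eta)`` when
    ``eta > 0`` (larger leaves gaining less area per unit L*W).

    Mass: with ``mass_level='leaf'``, per-leaf ``m = m0 * A**theta`` with
    log-normal noise (masses are then pooled per shoot); with
    ``mass_level='shoot'``, the pooled dry mass is drawn directly as
    ``M_T = m0 * A_T**theta`` with log-normal noise, emulating a survey that
    weighs each shoot's leaves together. ``m0 = None`` omits masses.
    ``area_noise_sd`` is the SD of log-scale multiplicative noise applied to
    areas after the series is laid down (so the noiseless ideal limit stays
    exact).
    """

    species: str = "synthetic"
    n_shoots: int = 60
    leaf_count_model: Literal["fixed", "weibull"] = "fixed"
    n_leaves: int = 8
    count_shape: float = 2.0
    count_scale: float = 10.0
    a_min_range: tuple[float, float] = (1.0, 50.0)
    q: float = 1.3
    q_sd: float = 0.0
    within_ratio: float | None = None
    series: Literal["geometric", "uniform"] = "geometric"
    b: float = 1.0
    c: float = 0.15
    k0: float = 0.72
    eta: float = 0.0
    L0: float = 10.0
    width_offset: float = 0.0
    area_noise_sd: float = 0.0
    m0: float | None = None
    theta: float = 1.0
    mass_noise_sd: float = 0.0
    mass_level: Literal["leaf", "shoot"] = "leaf"

    def __post_init__(self):
        if self.n_shoots < 1:
            raise DataValidationError("n_shoots must be >= 1")
        if self.q <= 0:
            raise DataValidationError("q must be positive")
        if self.c <= 0:
            raise DataValidationError("c must be positive")
        if not 0 < self.k0 <= 1:
            raise DataValidationError("k0 must lie in (0, 1]")
        if self.area_noise_sd < 0 or self.mass_noise_sd < 0 or self.q_sd < 0:
            raise DataValidationError("noise SDs must be >= 0")
        if 1 + self.b - self.eta <= 0:
            raise DataValidationError("need 1 + b - eta > 0 to invert the area model")
        lo, hi = self.a_min_range
        if not 0 < lo <= hi:
            raise DataValidationError("a_min_range must be positive and ordered")


def _solve_leaf_dimensions(
    areas: np.ndarray, cfg: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert A = k(L) * L * W(L) for each leaf; returns (L, W, k)."""
    if cfg.width_offset == 0.0:
        # closed form: A = k0 (L/L0)^-eta * L * c L^b  =>  L^(1+b-eta)
        expo = 1.0 + cfg.b - cfg.eta
        lengths = (areas * cfg.L0 ** (-cfg.eta) / (cfg.k0 * cfg.c)) ** (1.0 / expo)
    else:
        lengths = np.empty_like(areas)
        for i, a in enumerate(areas):
            def gap(L, a=a):
                k = cfg.k0 * (L / cfg.L0) ** (-cfg.eta)
                return k * L * (cfg.c * L**cfg.b + cfg.width_offset) - a

            lengths[i] = optimize.brentq(gap, 1e-9, 1e9, xtol=1e-12, rtol=8.9e-16)
    widths = cfg.c * lengths**cfg.b + cfg.width_offset
    k = cfg.k0 * (lengths / cfg.L0) ** (-cfg.eta)
    return lengths, widths, k


def generate_shoot(
    n: int,
    a_min: float,
    q: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Leaf records for one shoot (columns length, width, area, leaf_k)."""
    if n < 1:
        raise DataValidationError("a shoot has at least one leaf")
    if a_min <= 0 or q <= 0:
        raise DataValidationError("a_min and q must be positive")
    if cfg.series == "geometric":
        areas = a_min * q ** np.arange(n)
    elif cfg.series == "uniform":
        areas = np.sort(rng.uniform(a_min, a_min * q ** max(n - 1, 1), size=n))
    else:
        raise DataValidationError(f"unknown series model {cfg.series!r}")
    lengths, widths, k = _solve_leaf_dimensions(areas, cfg)
    # measurement-style noise perturbs the recorded area after the dimensions
    # are laid down, so the per-leaf A/(L W) ratio scatters around k while the
    # noiseless limit keeps the Montgomery identity exact
    if cfg.area_noise_sd > 0:
        areas = areas * np.exp(rng.normal(0.0, cfg.area_noise_sd, size=n))
    return pd.DataFrame(
        {"length": lengths, "width": widths, "area": areas, "leaf_k": areas / (lengths * widths)}
    )


def attach_mass(
    leaves: pd.DataFrame,
    m0: float,
    theta: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Add per-leaf dry mass m = m0 * A**theta with log-normal noise."""
    if "area" not in leaves.columns or leaves["area"].isna().any():
        raise MissingDataError("leaf areas must be present to attach masses")
    if m0 <= 0:
        raise DataValidationError("m0 must be positive")
    if noise_sd < 0:
        raise DataValidationError("noise_sd must be >= 0")
    area = leaves["area"].to_numpy(dtype=float)
    mass = m0 * area**theta
    if noise_sd > 0:
        mass = mass * np.exp(rng.normal(0.0, noise_sd, size=len(mass)))
    return leaves.assign(mass=mass)


def _draw_counts(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.leaf_count_model == "fixed":
        return np.full(cfg.n_shoots, cfg.n_leaves, dtype=int)
    if cfg.leaf_count_model == "weibull":
        draws = stats.weibull_min(cfg.count_shape, scale=cfg.count_scale).rvs(
            size=cfg.n_shoots, random_state=rng
        )
        return np.maximum(np.ceil(draws).astype(int), 1)
    raise DataValidationError(f"unknown leaf_count_model {cfg.leaf_count_model!r}")


def generate_population(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one population: (leaf table, shoot table, manifest).

    The leaf table follows the canonical schema (shoot, species, length,
    width, area [, mass]); the shoot table is its aggregation. Byte-identical
    for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    counts = _draw_counts(config, rng)
    lo, hi = config.a_min_range
    a_mins = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_shoots))
    if config.within_ratio is not None:
        qs = np.array(
            [config.within_ratio ** (1.0 / max(n - 1, 1)) for n in counts]
        )
    elif config.q_sd > 0:
        qs = config.q * np.exp(rng.normal(0.0, config.q_sd, size=config.n_shoots))
    else:
        qs = np.full(config.n_shoots, config.q)

    frames = []
    width = len(str(config.n_shoots))
    for i in range(config.n_shoots):
        shoot = generate_shoot(int(counts[i]), float(a_mins[i]), float(qs[i]), config, rng)
        shoot.insert(0, "shoot", f"{config.species}-{i + 1:0{width}d}")
        shoot.insert(1, "species", config.species)
        frames.append(shoot)
    leaves = pd.concat(frames, ignore_index=True)

    shoot_mass = None
    if config.m0 is not None:
        if config.mass_level == "leaf":
            leaves = attach_mass(leaves, config.m0, config.theta, config.mass_noise_sd, rng)
        else:
            area_total = leaves.groupby("shoot", sort=True)["area"].sum()
            mass = config.m0 * area_total.to_numpy() ** config.theta
            if config.mass_noise_sd > 0:
                mass = mass * np.exp(rng.normal(0.0, config.mass_noise_sd, size=len(mass)))
            shoot_mass = pd.DataFrame({"shoot": area_total.index, "mass_total": mass})

    shoots = aggregate_shoots(leaves.drop(columns=["leaf_k"]), shoot_mass=shoot_mass)
    manifest = {"config": asdict(config), "seed": seed}
    return leaves, shoots, manifest


def study_conditions(
    n_shoots: tuple[int, int] = (122, 120),
    mean_counts: tuple[float, float] = (26.34, 12.51),
    sd_counts: tuple[float, float] = (13.14, 6.52),
    at_mt_exponents: tuple[float, float] = (0.912, 0.936),
) -> list[SyntheticConfig]:
    """Two-species configurations emulating a paired bamboo field survey.

    Each species gets Weibull leaf counts moment-matched to the requested
    mean and SD, a shared Montgomery ratio k0 = 0.72, a fixed largest/
    smallest within-shoot area ratio (so the geometric common ratio adapts
    to the leaf count), log-scale area noise of 0.03, and a pooled per-shoot
    dry mass following M_T = m0 * A_T**theta with theta = 1/alpha, so the
    shoot-level area-vs-mass scaling exponent is alpha by construction.
    """
    configs = []
    for i in range(2):
        shape, scale = weibull_from_moments(mean_counts[i], sd_counts[i])
        configs.append(
            SyntheticConfig(
                species=f"species_{'AB'[i]}",
                n_shoots=n_shoots[i],
                leaf_count_model="weibull",
                count_shape=shape,
                count_scale=scale,
                a_min_range=(4.0, 40.0),
                within_ratio=5.0,
                b=1.0,
                c=0.15,
                k0=0.72,
                area_noise_sd=0.03,
                m0=0.0045,
                theta=1.0 / at_mt_exponents[i],
                mass_noise_sd=0.05,
                mass_level="shoot",
            )
        )
    return configs
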