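"""Density families of the simulation design.

Gaussian niches f (optimum mu0, breadth sigma0), five sampling-effort shapes
along the longitude gradient, and three target-group (TG) cumulated densities
a, plus the Gaussian product/quotient closed forms that serve as analytic
bias targets: under a uniform background the estimate tends to f*s_x (a
Gaussian product when both factors are Gaussian), under a target-group
background it tends to f/a (a Gaussian quotient when the precisions allow).

Effort shapes (profiles along z1, constant in z2, all valued in [0, 1]):

====  ==========================================================
CST   constant effort everywhere
LIN   1/10 - z1/50, linearly decreasing from west to east
CUT   (1/5) * 1{z1 in [-5, 0]}, all effort on the western half
HOL   prop. to log(1 + (z1+1)^2), a "hole" of zero effort at z1=-1
GS    standard normal profile, effort concentrated around z1=0
====  ==========================================================

TG shapes are centered Gaussians: FLAT sd 20 (nearly constant), THICK sd 2,
THIN sd 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .env_geometry import Domain, EnvDensity, EnvGrid

__all__ = [
    "NicheParams",
    "EffortSpec",
    "TGShape",
    "EXPULSION",
    "EFFORT_TAGS",
    "TG_SDS",
    "gaussian_niche",
    "effort_function",
    "effort_profile",
    "effort_env_density",
    "tg_density",
    "gaussian_product",
    "gaussian_quotient",
]

EFFORT_TAGS = ("CST", "LIN", "CUT", "HOL", "GS")
TG_SDS = {"FLAT": 20.0, "THICK": 2.0, "THIN": 1.0}

# normalization of the HOL profile: integral of log(1+(w+1)^2) over [-5, 5]
_HOL_NORM = None


class _Expulsion(enum.Enum):
    """Sentinel: the Gaussian quotient f/a has no integrable Gaussian form."""

    EXPULSION = "EXPULSION"

    def __repr__(self) -> str:
        return "EXPULSION"


EXPULSION = _Expulsion.EXPULSION


@dataclass(frozen=True)
class NicheParams:
    """Gaussian niche: environmental optimum and breadth (sd), both in
    environmental units.  The study design uses mu0 in {-1, -4} (typical vs
    marginal optimum) and sigma0 in {0.6, 1.5} (specialist vs generalist)."""

    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")


@dataclass(frozen=True)
class EffortSpec:
    """Sampling-effort shape by tag; profiles are constant in latitude."""

    tag: str = "CST"

    def __post_init__(self) -> None:
        if self.tag not in EFFORT_TAGS:
            raise ValueError(f"unknown effort tag {self.tag!r}; use one of {EFFORT_TAGS}")


@dataclass(frozen=True)
class TGShape:
    """Target-group cumulated density shape: a centered Gaussian whose sd
    encodes how environmentally concentrated the group is."""

    tag: str = "FLAT"

    def __post_init__(self) -> None:
        if self.tag not in TG_SDS:
            raise ValueError(f"unknown TG tag {self.tag!r}; use one of {tuple(TG_SDS)}")

    @property
    def sd(self) -> float:
        return TG_SDS[self.tag]


def gaussian_niche(params: NicheParams, grid: EnvGrid) -> EnvDensity:
    """Species density f: Gaussian(mu0, sigma0^2) renormalized on Im(x)."""
    vals = stats.norm.pdf(grid.nodes, loc=params.mu0, scale=params.sigma0)
    return EnvDensity(grid, vals, gaussian=(params.mu0, params.sigma0))


def _hol_norm() -> float:
    global _HOL_NORM
    if _HOL_NORM is None:
        w = np.linspace(-5.0, 5.0, 20001)
        _HOL_NORM = float(np.trapezoid(np.log1p((w + 1.0) ** 2), w))
    return _HOL_NORM


def effort_profile(spec: EffortSpec) -> Callable[[np.ndarray], np.ndarray]:
    """The effort as a function of the environmental value alone.

    All profiles already lie in [0, 1] at their natural scale (the
    non-constant ones integrate to 1 over [-5, 5], so they double as the
    exact observation density s_x under the linear gradient).
    """
    tag = spec.tag
    if tag == "CST":
        return lambda w: np.ones_like(np.asarray(w, dtype=float))
    if tag == "LIN":
        return lambda w: 0.1 - np.asarray(w, dtype=float) / 50.0
    if tag == "CUT":
        return lambda w: 0.2 * ((np.asarray(w, dtype=float) >= -5.0) & (np.asarray(w) <= 0.0))
    if tag == "HOL":
        norm = _hol_norm()
        return lambda w: np.log1p((np.asarray(w, dtype=float) + 1.0) ** 2) / norm
    if tag == "GS":
        return lambda w: stats.norm.pdf(np.asarray(w, dtype=float))
    raise ValueError(f"unknown effort tag {tag!r}")  # pragma: no cover


def effort_function(spec: EffortSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Sampling effort s on the domain: the profile applied to z1, constant
    in z2.  Accepts an (n, 2) coordinate array."""
    profile = effort_profile(spec)
    return lambda z: profile(np.asarray(z, dtype=float)[..., 0])


def effort_env_density(
    spec: EffortSpec, grid: EnvGrid, domain: Domain = Domain()
) -> EnvDensity:
    """Exact observation density s_x for a longitude-only effort under the
    linear gradient: the normalized effort profile on the grid.

    ``gaussian`` metadata is attached for the GS shape (standard normal) so
    product closed forms apply.
    """
    profile = effort_profile(spec)
    vals = profile(grid.nodes)
    gaussian = (0.0, 1.0) if spec.tag == "GS" else None
    return EnvDensity(grid, vals, gaussian=gaussian)


def tg_density(shape: TGShape, grid: EnvGrid) -> EnvDensity:
    """Cumulated TG species density a: centered Gaussian renormalized on
    Im(x); strictly positive everywhere on the grid."""
    vals = stats.norm.pdf(grid.nodes, loc=0.0, scale=shape.sd)
    return EnvDensity(grid, vals, gaussian=(0.0, shape.sd))


def gaussian_product(
    p: tuple[float, float], q: tuple[float, float]
) -> tuple[float, float]:
    """Parameters of the normalized product of two Gaussian densities.

    Precision-weighted: 1/sd*^2 = 1/sd_p^2 + 1/sd_q^2 and
    mean* = sd*^2 (mean_p/sd_p^2 + mean_q/sd_q^2).
    """
    mp, sp = _unpack(p)
    mq, sq = _unpack(q)
    prec = 1.0 / sp**2 + 1.0 / sq**2
    var = 1.0 / prec
    mean = var * (mp / sp**2 + mq / sq**2)
    return mean, float(np.sqrt(var))


def gaussian_quotient(p: tuple[float, float], a: tuple[float, float]):
    """Parameters of the normalized quotient of two Gaussian densities, or
    :data:`EXPULSION` when the numerator is broader than the denominator.

    In the expulsion regime f/a grows without bound in the tails: the
    estimated niche is pushed out of the target group's environmental range
    instead of concentrating around a finite optimum.
    """
    mp, sp = _unpack(p)
    ma, sa = _unpack(a)
    prec = 1.0 / sp**2 - 1.0 / sa**2
    if prec <= 0:
        return EXPULSION
    var = 1.0 / prec
    mean = var * (mp / sp**2 - ma / sa**2)
    return mean, float(np.sqrt(var))


def _unpack(p) -> tuple[float, float]:
    if isinstance(p, NicheParams):
        mean, sd = p.mu0, p.sigma0
    else:
        mean, sd = p
    if sd <= 0:
        raise ValueError("standard deviation must be > 0")
    return float(mean), float(sd)
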