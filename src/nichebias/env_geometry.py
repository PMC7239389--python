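"""Geographic domain, environmental field, and the induced environmental measure.

The study region is a bounded rectangle ``D`` carrying a deterministic
environmental field ``x(z)``.  Everything downstream (niche densities,
observation densities, Kullback-Leibler machinery) lives on the environmental
axis ``Im(x)``, discretized as an :class:`EnvGrid` whose per-node weights
record the *habitat measure* mu_x: the geographic area mapping into each unit
of environmental value.  For the default linear west-east gradient on the
square [-5, 5]^2, mu_x is uniform with density 10 (area units per
environmental unit).

The observation density ``s_x`` — the average of the sampling effort over all
locations sharing an environmental value, normalized into a density — is
estimated here numerically by Monte-Carlo binning of the effort field.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Domain",
    "EnvField",
    "EnvGrid",
    "EnvDensity",
    "make_env_grid",
    "observation_density",
]

DEFAULT_SEED = 20200520


@dataclass(frozen=True)
class Domain:
    """Rectangular study region [x0, x1] x [y0, y1]."""

    lower: tuple[float, float] = (-5.0, -5.0)
    upper: tuple[float, float] = (5.0, 5.0)

    def __post_init__(self) -> None:
        if not (self.upper[0] > self.lower[0] and self.upper[1] > self.lower[1]):
            raise ValueError("domain must have strictly positive area")

    @property
    def width(self) -> float:
        return self.upper[0] - self.lower[0]

    @property
    def height(self) -> float:
        return self.upper[1] - self.lower[1]

    @property
    def area(self) -> float:
        return self.width * self.height

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` uniform points, returned as an (n, 2) array."""
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return rng.uniform(lo, hi, size=(n, 2))

    def lattice(self, n_side: int = 201) -> np.ndarray:
        """Regular (n_side^2, 2) evaluation lattice covering the rectangle."""
        xs = np.linspace(self.lower[0], self.upper[0], n_side)
        ys = np.linspace(self.lower[1], self.upper[1], n_side)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class EnvField:
    """Deterministic map from domain points to an environmental value.

    ``func`` takes an (n, 2) coordinate array and returns (n,) environmental
    values.  ``support`` is the closed interval Im(x).  The default is the
    linear longitude gradient x(z) = z1 with Im(x) = [-5, 5]; that case is
    flagged so the habitat measure can be computed exactly instead of by
    Monte-Carlo.
    """

    func: Callable[[np.ndarray], np.ndarray] = dc_field(
        default=lambda z: np.asarray(z)[..., 0]
    )
    support: tuple[float, float] = (-5.0, 5.0)
    linear_gradient: bool = True

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(self.func(np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class EnvGrid:
    """Ordered grid over Im(x) with per-node habitat-measure weights.

    ``weights[i]`` is the mu_x density at node i: geographic area per unit of
    environmental value.  The trapezoid integral of the weights over the grid
    equals the domain area.
    """

    nodes: np.ndarray
    weights: np.ndarray
    domain_area: float

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least 2 nodes")
        if np.any(weights < 0):
            raise ValueError("mu_x weights must be non-negative")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def cell_width(self) -> float:
        return float(self.nodes[1] - self.nodes[0])

    @property
    def support(self) -> tuple[float, float]:
        return float(self.nodes[0]), float(self.nodes[-1])

    def bin_edges(self) -> np.ndarray:
        """Node-centered cell edges (first and last cells are half-cells)."""
        mid = 0.5 * (self.nodes[1:] + self.nodes[:-1])
        return np.concatenate([[self.nodes[0]], mid, [self.nodes[-1]]])

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        """Assign environmental values to node cells.

        Values exactly on an interior edge go to the left cell; values
        outside the support are clipped to the end cells.
        """
        edges = self.bin_edges()
        idx = np.searchsorted(edges[1:-1], values, side="left")
        return np.clip(idx, 0, self.n_nodes - 1)

    def integrate(self, values: np.ndarray) -> float:
        """Trapezoid integral of a nodal function over Im(x)."""
        return float(np.trapezoid(values, self.nodes))

    def to_csv(self, path_or_buf) -> None:
        _write_two_col(path_or_buf, "env_value", "mu_x_weight", self.nodes, self.weights)


class EnvDensity:
    """A non-negative density tabulated on an :class:`EnvGrid`.

    Shared representation of the niche f, the observation density s_x, the
    target-group density a, and the bias targets f*s_x and f/a.  Values are
    normalized to integrate to one over Im(x) by the trapezoid rule.  When
    the density is a (truncated) Gaussian, the untruncated ``(mean, sd)``
    pair may be attached as ``gaussian`` for closed-form shortcuts.
    """

    def __init__(
        self,
        grid: EnvGrid,
        values: np.ndarray,
        gaussian: Optional[tuple[float, float]] = None,
        normalize: bool = True,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != grid.nodes.shape:
            raise ValueError("values must match grid nodes")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("density values must be finite and non-negative")
        self.grid = grid
        self.normalization = grid.integrate(values) if normalize else 1.0
        if normalize:
            if self.normalization <= 0:
                raise ValueError("density integrates to zero")
            values = values / self.normalization
        self.values = values
        self.gaussian = gaussian

    def __call__(self, w: np.ndarray) -> np.ndarray:
        return np.interp(w, self.grid.nodes, self.values)

    def mean(self) -> float:
        return self.grid.integrate(self.grid.nodes * self.values)

    def var(self) -> float:
        m = self.mean()
        return self.grid.integrate((self.grid.nodes - m) ** 2 * self.values)

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def mass_between(self, lo: float, hi: float) -> float:
        """Probability mass on [lo, hi] by trapezoid rule on the sub-grid."""
        w = self.grid.nodes
        inside = (w >= lo) & (w <= hi)
        if inside.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.values[inside], w[inside]))

    def to_csv(self, path_or_buf) -> None:
        _write_two_col(path_or_buf, "env_value", "density", self.grid.nodes, self.values)

    def __repr__(self) -> str:  # pragma: no cover
        g = f", gaussian={self.gaussian}" if self.gaussian else ""
        return f"EnvDensity(n={self.grid.n_nodes}, mean={self.mean():.4f}{g})"


def _write_two_col(path_or_buf, h1, h2, col1, col2) -> None:
    def _dump(fh):
        fh.write(f"{h1},{h2}\n")
        for a, b in zip(col1, col2):
            fh.write(f"{a:.17g},{b:.17g}\n")

    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            _dump(fh)
    else:
        _dump(path_or_buf)


def make_env_grid(
    domain: Domain = Domain(),
    field: EnvField = EnvField(),
    n_nodes: int = 2001,
    n_mc: int = 1_000_000,
    seed: int = DEFAULT_SEED,
) -> EnvGrid:
    """Discretize Im(x) and estimate the habitat-measure weights mu_x.

    For the linear longitude gradient the weights are exact (uniform density
    ``height`` of the domain per environmental unit).  For a general field
    they are estimated by binning ``n_mc`` uniform Monte-Carlo points; the
    seed makes the estimate reproducible.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if domain.area <= 0:  # defensive; Domain already validates
        raise ValueError("degenerate domain")
    lo, hi = field.support
    nodes = np.linspace(lo, hi, n_nodes)
    if field.linear_gradient:
        weights = np.full(n_nodes, domain.height)
        return EnvGrid(nodes=nodes, weights=weights, domain_area=domain.area)
    rng = np.random.default_rng(seed)
    pts = domain.sample_uniform(n_mc, rng)
    env = field(pts)
    grid = EnvGrid(nodes=nodes, weights=np.ones(n_nodes), domain_area=domain.area)
    idx = grid.bin_index(env)
    counts = np.bincount(idx, minlength=n_nodes).astype(float)
    cell_sizes = np.diff(grid.bin_edges())
    dens = counts / n_mc * domain.area / cell_sizes
    # rescale so the trapezoid integral matches the domain area exactly
    total = float(np.trapezoid(dens, nodes))
    if total > 0:
        dens *= domain.area / total
    return EnvGrid(nodes=nodes, weights=dens, domain_area=domain.area)


def observation_density(
    effort: Callable[[np.ndarray], np.ndarray],
    field: EnvField,
    grid: EnvGrid,
    n_mc: int = 1_000_000,
    seed: int = DEFAULT_SEED,
    domain: Domain = Domain(),
) -> EnvDensity:
    """Estimate the observation density s_x from a sampling-effort function.

    Per grid cell, averages the effort over uniform Monte-Carlo domain points
    whose environmental value falls in the cell (the finite-bin version of
    the averaging that defines the observation intensity), then normalizes
    the profile to integrate to one over Im(x).  Cells receiving no points
    are set to zero with a warning.
    """
    rng = np.random.default_rng(seed)
    pts = domain.sample_uniform(n_mc, rng)
    s_vals = np.asarray(effort(pts), dtype=float)
    if np.any(s_vals < -1e-12) or np.any(s_vals > 1 + 1e-12):
        raise ValueError("sampling effort must take values in [0, 1]")
    env = field(pts)
    idx = grid.bin_index(env)
    counts = np.bincount(idx, minlength=grid.n_nodes).astype(float)
    sums = np.bincount(idx, weights=s_vals, minlength=grid.n_nodes)
    empty = counts == 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} environmental bins received no Monte-Carlo "
            "points; their observation density is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        s_bar = np.where(empty, 0.0, sums / np.maximum(counts, 1.0))
    return EnvDensity(grid, s_bar)
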