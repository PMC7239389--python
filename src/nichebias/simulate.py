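"""Point-pattern simulation by rejection sampling.

Occurrence sets are drawn conditionally on a fixed sample size n (default
20000): proposals are uniform on the domain and accepted with probability
density(z)/B, where B is a safety-factored upper bound of the density over an
evaluation lattice.  Conditioning on n means only density *shapes* are
estimable downstream, never absolute intensities — which is exactly the
setting in which background-point bias is studied.

Three point roles exist:

* ``focal_occurrence`` — the reported presences of the focal species, i.e.
  the niche thinned by the sampling effort, density prop. to f(x(z)) s(z);
* ``tg_occurrence``    — pooled reported presences of a target group,
  density prop. to a(x(z)) s(z);
* ``background``       — pseudo-absence points under one of three schemes:
  uniform on D, drawn from the effort density s, or drawn like a TG sample.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .densities import EffortSpec, NicheParams, TGShape, effort_function
from .env_geometry import Domain, EnvField

__all__ = [
    "SimConfig",
    "PointSample",
    "rejection_sample",
    "simulate_focal",
    "simulate_tg",
    "make_background",
]


@dataclass(frozen=True)
class SimConfig:
    """Rejection-sampling configuration.

    ``n`` accepted points are returned (fixed-size conditional sampling);
    the bound is ``safety_factor`` times the lattice maximum of the density;
    the sampler aborts with the observed acceptance rate if it would need
    more than ``max_proposals`` proposals.
    """

    n: int = 20000
    safety_factor: float = 1.1
    seed: int = 20200520
    max_proposals: int = 50_000_000
    batch_size: int = 100_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.safety_factor <= 1.0:
            raise ValueError("safety_factor must be > 1")


@dataclass
class PointSample:
    """A set of domain points with environmental values and a role tag."""

    coords: np.ndarray  # (n, 2)
    env: np.ndarray  # (n,)
    role: str
    seed: int
    density_id: str = ""
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        if self.coords.shape != (self.env.size, 2):
            raise ValueError("coords must be (n, 2) matching env")

    @property
    def n(self) -> int:
        return self.env.size

    def with_role(self, role: str) -> "PointSample":
        """Same points, re-tagged (e.g. a TG sample reused as background)."""
        return PointSample(
            coords=self.coords,
            env=self.env,
            role=role,
            seed=self.seed,
            density_id=self.density_id,
            acceptance_rate=self.acceptance_rate,
        )

    def to_csv(self, path_or_buf) -> None:
        def _dump(fh):
            fh.write(f"#seed={self.seed}\n")
            fh.write(f"#density_id={self.density_id}\n")
            fh.write(f"#n={self.n}\n")
            fh.write("z1,z2,env,role\n")
            for (z1, z2), w in zip(self.coords, self.env):
                fh.write(f"{z1:.17g},{z2:.17g},{w:.17g},{self.role}\n")

        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w", encoding="utf-8", newline="\n") as fh:
                _dump(fh)
        else:
            _dump(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PointSample":
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = path_or_buf.read()
        meta = {}
        rows = []
        role = "background"
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k] = v
            elif line and not line.startswith("z1,"):
                z1, z2, w, role = line.split(",")
                rows.append((float(z1), float(z2), float(w)))
        arr = np.asarray(rows, dtype=float)
        return cls(
            coords=arr[:, :2],
            env=arr[:, 2],
            role=role,
            seed=int(meta.get("seed", -1)),
            density_id=meta.get("density_id", ""),
        )


def rejection_sample(
    target_density: Callable[[np.ndarray], np.ndarray],
    domain: Domain,
    config: SimConfig,
    role: str = "background",
    density_id: str = "",
    field: Optional[EnvField] = None,
) -> PointSample:
    """Draw exactly ``config.n`` i.i.d. points from a density on the domain.

    The unnormalized density is evaluated on a 201x201 lattice to set the
    bound B = safety_factor * max; proposals z ~ U(D), u ~ U(0, 1) are
    accepted iff u * B <= density(z).
    """
    field = field or EnvField()
    dens_max = float(np.max(target_density(domain.lattice(201))))
    if not np.isfinite(dens_max) or dens_max <= 0:
        raise ValueError("target density is zero (or not finite) on the domain")
    bound = config.safety_factor * dens_max

    rng = np.random.default_rng(config.seed)
    accepted = []
    n_acc = 0
    n_prop = 0
    batch = max(config.batch_size, config.n)
    while n_acc < config.n:
        m = min(batch, config.max_proposals - n_prop)
        if m <= 0:
            rate = n_acc / max(n_prop, 1)
            raise RuntimeError(
                f"rejection sampling exceeded {config.max_proposals} proposals "
                f"(acceptance rate {rate:.2e}); density {density_id!r}"
            )
        z = domain.sample_uniform(m, rng)
        u = rng.uniform(size=m)
        keep = u * bound <= target_density(z)
        n_prop += m
        z_keep = z[keep]
        accepted.append(z_keep)
        n_acc += z_keep.shape[0]
    coords = np.concatenate(accepted)[: config.n]
    env = field(coords)
    return PointSample(
        coords=coords,
        env=env,
        role=role,
        seed=config.seed,
        density_id=density_id,
        acceptance_rate=n_acc / n_prop,
    )


def simulate_focal(
    niche: NicheParams,
    effort: EffortSpec,
    domain: Domain = Domain(),
    field: EnvField = EnvField(),
    config: SimConfig = SimConfig(),
) -> PointSample:
    """Reported presences of the focal species: density prop. to
    f(x(z)) * s(z), the effort-thinned niche."""
    s = effort_function(effort)

    def dens(z):
        w = field(z)
        return stats.norm.pdf(w, niche.mu0, niche.sigma0) * s(z)

    return rejection_sample(
        dens,
        domain,
        config,
        role="focal_occurrence",
        density_id=f"focal:N({niche.mu0},{niche.sigma0})*{effort.tag}",
        field=field,
    )


def simulate_tg(
    shape: TGShape,
    effort: EffortSpec,
    domain: Domain = Domain(),
    field: EnvField = EnvField(),
    config: SimConfig = SimConfig(),
) -> PointSample:
    """Pooled target-group occurrences: density prop. to a(x(z)) * s(z)."""
    s = effort_function(effort)

    def dens(z):
        w = field(z)
        return stats.norm.pdf(w, 0.0, shape.sd) * s(z)

    return rejection_sample(
        dens,
        domain,
        config,
        role="tg_occurrence",
        density_id=f"tg:{shape.tag}*{effort.tag}",
        field=field,
    )


def make_background(
    kind: str,
    domain: Domain = Domain(),
    field: EnvField = EnvField(),
    config: SimConfig = SimConfig(),
    effort: Optional[EffortSpec] = None,
    tg_shape: Optional[TGShape] = None,
    tg_sample: Optional[PointSample] = None,
) -> PointSample:
    """Background points under one of the three schemes.

    ``uniform``  — uniform on D, ignoring the effort entirely;
    ``effort``   — drawn from the effort-proportional density (requires
                   ``effort``);
    ``tg``       — drawn like pooled TG occurrences, density a*s (requires
                   ``tg_shape`` and ``effort``), or an existing TG sample
                   re-tagged via ``tg_sample``.
    """
    if kind == "uniform":
        return rejection_sample(
            lambda z: np.ones(np.asarray(z).shape[0]),
            domain,
            config,
            role="background",
            density_id="bg:uniform",
            field=field,
        )
    if kind == "effort":
        if effort is None:
            raise ValueError("effort-kind background requires an EffortSpec")
        s = effort_function(effort)
        return rejection_sample(
            s,
            domain,
            config,
            role="background",
            density_id=f"bg:effort:{effort.tag}",
            field=field,
        )
    if kind == "tg":
        if tg_sample is not None:
            return tg_sample.with_role("background")
        if tg_shape is None or effort is None:
            raise ValueError("tg-kind background requires TGShape and EffortSpec")
        sample = simulate_tg(tg_shape, effort, domain, field, config)
        return sample.with_role("background")
    raise ValueError(f"unknown background kind {kind!r}")
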