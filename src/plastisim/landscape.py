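"""Quasi-potential landscape dynamics in one state-space coordinate.

The cell state is a particle in a potential V(x) (the quasi-potential
"elevation"), driven by the force F(x) = -dV/dx and by gene-expression
noise of intensity D(x). Two complementary solvers are provided for the
same dynamics:

- :func:`fp_solve` evolves the cell-number density N(x, t) under the
  drift-diffusion-growth equation

      dN/dt = d/dx [ D(x) dN/dx - F(x) N ] + g(x) N,

  with reflecting (no-flux) boundaries. The spatial flux uses the
  exponentially-fitted Scharfetter-Gummel discretization, whose discrete
  stationary state for constant D is exactly the Boltzmann profile
  exp(-V/D) on the grid; mass is conserved to round-off when g = 0. The
  growth term is applied as an exact pointwise factor exp(g dt) per step.

- :func:`simulate_langevin` integrates particles through
  dx = F(x) dt + sqrt(2 D) dW (Euler-Maruyama, reflecting walls), giving
  an independent stochastic realisation of the same density evolution.

Barrier height controls the state-transition rate: a lowered barrier (the
perturbed, cancer-prone landscape) yields a higher probability of finding
the particle in the other well at a later time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeSpec", "DensityField", "double_well", "preset_landscape",
    "fp_solve", "transition_probability", "simulate_langevin",
]


def double_well(a: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Quartic double well V(x) = a (x^2 - 1)^2 with barrier height a."""
    def V(x):
        return a * (np.asarray(x) ** 2 - 1.0) ** 2
    return V


@dataclass
class LandscapeSpec:
    """Potential, noise intensity, growth rate and grid of a 1D landscape."""

    potential: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=double_well)
    diffusion: float | Callable[[np.ndarray], np.ndarray] = 1.0
    growth: float | Callable[[np.ndarray], np.ndarray] | None = None
    x_min: float = -2.0
    x_max: float = 2.0
    n_grid: int = 401

    def __post_init__(self) -> None:
        if self.n_grid < 3:
            raise ValueError("grid must have at least 3 points")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if np.min(self.D(self.grid())) <= 0:
            raise ValueError("diffusion must be positive on the domain")

    def grid(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_grid)

    @property
    def h(self) -> float:
        return (self.x_max - self.x_min) / (self.n_grid - 1)

    def V(self, x) -> np.ndarray:
        return np.asarray(self.potential(np.asarray(x, dtype=float)), dtype=float)

    def D(self, x) -> np.ndarray:
        if callable(self.diffusion):
            return np.asarray(self.diffusion(np.asarray(x, dtype=float)), dtype=float)
        return np.full_like(np.asarray(x, dtype=float), float(self.diffusion))

    def g(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.growth is None:
            return np.zeros_like(x)
        if callable(self.growth):
            return np.asarray(self.growth(x), dtype=float)
        return np.full_like(x, float(self.growth))

    def drift(self, x, dh: float = 1e-6) -> np.ndarray:
        """F(x) = -dV/dx by central difference."""
        x = np.asarray(x, dtype=float)
        return -(self.V(x + dh) - self.V(x - dh)) / (2 * dh)

    def stable_dt(self, safety: float = 0.9) -> float:
        return safety * self.h**2 / (2.0 * float(np.max(self.D(self.grid()))))


PRESET_BARRIERS = {"normal": 2.0, "cancer": 0.5}


def preset_landscape(name: str, diffusion: float = 0.4, **kwargs) -> LandscapeSpec:
    """Shipped double-well landscapes: 'normal' (high barrier) and
    'cancer' (oncogenically lowered barrier)."""
    if name not in PRESET_BARRIERS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_BARRIERS)}")
    return LandscapeSpec(potential=double_well(PRESET_BARRIERS[name]),
                         diffusion=diffusion, **kwargs)


@dataclass
class DensityField:
    """Density N(x, t) on the grid at saved times."""

    x: np.ndarray
    times: np.ndarray
    density: np.ndarray  # shape (len(times), len(x))

    def mass(self) -> np.ndarray:
        """Total mass at each saved time (finite-volume cell sum, the
        quantity the scheme conserves exactly when growth is off)."""
        h = self.x[1] - self.x[0]
        return self.density.sum(axis=1) * h

    def final(self) -> np.ndarray:
        return self.density[-1]

    def normalized(self) -> "DensityField":
        """Per-time renormalized copy (unit mass), for probability readouts."""
        m = self.mass()
        return DensityField(self.x, self.times, self.density / m[:, None])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.density.T,
                             columns=[f"t={t:g}" for t in self.times])
        frame.insert(0, "x", self.x)
        return frame


def _bernoulli(w: np.ndarray) -> np.ndarray:
    """B(w) = w / (e^w - 1), with the removable singularity at 0 handled."""
    w = np.asarray(w, dtype=float)
    out = np.empty_like(w)
    small = np.abs(w) < 1e-10
    out[small] = 1.0 - w[small] / 2.0
    ws = w[~small]
    out[~small] = ws / np.expm1(ws)
    return out


def fp_solve(
    spec: LandscapeSpec,
    initial_density: np.ndarray | Callable[[np.ndarray], np.ndarray],
    t_end: float,
    dt: float | None = None,
    n_save: int = 11,
) -> DensityField:
    """Explicit finite-volume solution of the density equation.

    ``initial_density`` is evaluated/validated on the grid; ``dt`` defaults
    to the stability bound h^2/(2 max D) with a 0.9 safety factor and is
    rejected if it exceeds that bound. ``n_save`` output times are spaced
    evenly over [0, t_end].
    """
    x = spec.grid()
    h = spec.h
    N = np.asarray(initial_density(x) if callable(initial_density)
                   else initial_density, dtype=float).copy()
    if N.shape != x.shape:
        raise ValueError("initial density shape does not match the grid")
    if (N < 0).any():
        raise ValueError("initial density must be non-negative")
    dt_max = spec.h**2 / (2.0 * float(np.max(spec.D(x))))
    if dt is None:
        dt = spec.stable_dt()
    elif dt > dt_max:
        raise ValueError(
            f"dt={dt:g} violates the stability bound {dt_max:g}; "
            f"use dt <= {spec.stable_dt():g}")
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    x_mid = 0.5 * (x[:-1] + x[1:])
    D_mid = spec.D(x_mid)
    V = spec.V(x)
    # Peclet number per face; -dV is the potential drop, so w = F h / D
    w = -(V[1:] - V[:-1]) / D_mid
    b_plus = _bernoulli(w)    # weight of the right neighbour
    b_minus = _bernoulli(-w)  # weight of the left neighbour
    coef = D_mid / h
    growth_factor = np.exp(spec.g(x) * dt)
    save_times = np.linspace(0.0, t_end, n_save)
    save_steps = np.round(save_times / dt).astype(int)
    out = np.empty((n_save, x.size))
    out[0] = N
    next_save = 1
    for step in range(1, n_steps + 1):
        flux = coef * (b_plus * N[1:] - b_minus * N[:-1])
        dN = np.zeros_like(N)
        dN[:-1] += flux
        dN[1:] -= flux
        N = (N + dt * dN / h) * growth_factor
        np.clip(N, 0.0, None, out=N)
        while next_save < n_save and step >= save_steps[next_save]:
            out[next_save] = N
            next_save += 1
    return DensityField(x=x, times=save_times, density=out)


def transition_probability(
    spec: LandscapeSpec,
    start_well: tuple[float, float],
    target_well: tuple[float, float],
    t: float,
    sigma0: float | None = None,
) -> float:
    """Probability mass in the target well at time t, starting from a
    narrow Gaussian at the bottom of the start well, with growth off.

    The wells are disjoint subintervals of the domain; the start point is
    the potential minimum inside ``start_well``.
    """
    a0, a1 = sorted(start_well)
    b0, b1 = sorted(target_well)
    if max(a0, b0) < min(a1, b1):
        raise ValueError("start and target wells must be disjoint")
    spec_g0 = LandscapeSpec(potential=spec.potential, diffusion=spec.diffusion,
                            growth=None, x_min=spec.x_min, x_max=spec.x_max,
                            n_grid=spec.n_grid)
    x = spec_g0.grid()
    inside = (x >= a0) & (x <= a1)
    if not inside.any():
        raise ValueError("start well contains no grid point")
    x0 = x[inside][np.argmin(spec_g0.V(x[inside]))]
    sigma0 = sigma0 if sigma0 is not None else 3.0 * spec_g0.h
    # narrow Gaussian truncated to the start well: all mass begins there
    N0 = np.where(inside, np.exp(-0.5 * ((x - x0) / sigma0) ** 2), 0.0)
    N0 /= np.trapezoid(N0, x)
    if t == 0:
        field = DensityField(x, np.array([0.0]), N0[None, :])
    else:
        field = fp_solve(spec_g0, N0, t_end=t, n_save=2)
    dens = field.final()
    total = np.trapezoid(dens, x)
    target = (x >= b0) & (x <= b1)
    return float(np.trapezoid(np.where(target, dens, 0.0), x) / total)


def simulate_langevin(
    spec: LandscapeSpec,
    n_particles: int,
    t_end: float,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
    init: np.ndarray | float | None = None,
    n_save: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama particles in the landscape with reflecting walls.

    ``init`` may be a scalar start point, an array of start positions, or
    None (uniform over the domain). Returns ``(times, positions)`` with
    positions of shape (n_save, n_particles).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    if init is None:
        x = rng.uniform(spec.x_min, spec.x_max, n_particles)
    elif np.isscalar(init):
        x = np.full(n_particles, float(init))
    else:
        x = np.asarray(init, dtype=float).copy()
        if x.shape != (n_particles,):
            raise ValueError("init array must have shape (n_particles,)")
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    save_times = np.linspace(0.0, t_end, n_save)
    save_steps = np.round(save_times / dt).astype(int)
    out = np.empty((n_save, n_particles))
    out[0] = x
    next_save = 1
    span = spec.x_max - spec.x_min
    for step in range(1, n_steps + 1):
        noise = np.sqrt(2.0 * spec.D(x) * dt) * rng.standard_normal(n_particles)
        x = x + spec.drift(x) * dt + noise
        # reflect into [x_min, x_max] (handles multiple bounces)
        x = spec.x_min + np.abs((x - spec.x_min) % (2 * span))
        over = x > spec.x_max
        x[over] = 2 * spec.x_max - x[over]
        while next_save < n_save and step >= save_steps[next_save]:
            out[next_save] = x
            next_save += 1
    return save_times, out
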