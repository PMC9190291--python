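"""Two-gene multistable regulatory circuit with stability diagnostics.

The core dynamical system is the canonical pair of mutually inhibiting,
self-activating genes:

    dx_i/dt = theta * [ a * x_i^n / (K^n + x_i^n)        (self-activation)
                        + b * K^n / (K^n + x_j^n) ]      (mutual inhibition)
              - k * x_i                                  (degradation)

The control parameter theta scales overall production against
degradation. In the default parameterisation the circuit is bistable for
theta above a critical value theta_c: two asymmetric attractors (one gene
high, the other low) separated by a symmetric saddle. As theta decreases
toward theta_c the attractors destabilize — the leading Jacobian
eigenvalue lambda* rises to zero — and merge with the saddle in a
pitchfork, leaving a single symmetric state. This is the generic
destabilization scenario that snapshot statistics (:mod:`.indices`) are
designed to detect.

Snapshots emulate single-cell expression data: cells are independent
Langevin realisations fluctuating around one attractor, observed through
m noisy linear gene readouts of the 2D core state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GRNParams", "FixedPoint", "SnapshotMatrix", "drift", "jacobian",
    "find_attractors", "jacobian_eigs", "theta_critical", "lambda_star",
    "generate_snapshot",
]


@dataclass(frozen=True)
class GRNParams:
    """Circuit, noise and observation parameters."""

    self_activation: float = 0.25
    inhibition: float = 1.0
    hill: float = 4.0
    threshold: float = 0.5     # half-saturation constant K
    degradation: float = 1.0
    theta: float = 1.0         # production scale; bifurcation control
    sigma: float = 0.05        # Langevin noise intensity of the core genes
    n_genes: int = 20          # observed readout genes m
    obs_noise: float = 0.05
    obs_offset: float = 1.0    # basal expression added to every readout

    def __post_init__(self) -> None:
        if min(self.inhibition, self.threshold, self.degradation) <= 0:
            raise ValueError("inhibition, threshold and degradation must be positive")
        if self.self_activation < 0 or self.theta < 0 or self.sigma < 0:
            raise ValueError("self_activation, theta and sigma must be non-negative")
        if self.hill < 1:
            raise ValueError("Hill coefficient must be at least 1")
        if self.n_genes < 2:
            raise ValueError("at least two observed genes are required")

    @property
    def x_max(self) -> float:
        """Upper bound of the invariant box [0, x_max]^2."""
        return self.theta * (self.self_activation + self.inhibition) / self.degradation


@dataclass(frozen=True)
class FixedPoint:
    x: np.ndarray                 # coordinates (2,)
    stable: bool
    eigenvalues: np.ndarray       # sorted by real part, descending

    @property
    def lambda_star(self) -> float:
        return float(self.eigenvalues[0].real)


@dataclass
class SnapshotMatrix:
    """m-gene x c-cell expression snapshot at condition label T."""

    values: np.ndarray
    genes: list[str]
    cells: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("snapshot values must be a 2D matrix")
        m, c = self.values.shape
        if len(self.genes) != m or len(self.cells) != c:
            raise ValueError("gene/cell identifier counts must match the matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("snapshot contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _hill_act(x, K, n):
    xn = np.power(x, n)
    return xn / (K**n + xn)


def _hill_rep(x, K, n):
    Kn = K**n
    return Kn / (Kn + np.power(x, n))


def drift(x: np.ndarray, params: GRNParams) -> np.ndarray:
    """Deterministic rate of change F(x) of the two core genes."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("expression state must be non-negative")
    p = params
    x1, x2 = x[..., 0], x[..., 1]
    f1 = p.theta * (p.self_activation * _hill_act(x1, p.threshold, p.hill)
                    + p.inhibition * _hill_rep(x2, p.threshold, p.hill)) \
        - p.degradation * x1
    f2 = p.theta * (p.self_activation * _hill_act(x2, p.threshold, p.hill)
                    + p.inhibition * _hill_rep(x1, p.threshold, p.hill)) \
        - p.degradation * x2
    return np.stack([f1, f2], axis=-1)


def jacobian(x: np.ndarray, params: GRNParams) -> np.ndarray:
    """Analytic Jacobian of the drift at state x."""
    x = np.asarray(x, dtype=float)
    p = params
    Kn = p.threshold**p.hill
    xn1 = np.power(x[0], p.hill)
    xn2 = np.power(x[1], p.hill)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_act1 = p.hill * Kn * np.power(x[0], p.hill - 1) / (Kn + xn1) ** 2
        d_act2 = p.hill * Kn * np.power(x[1], p.hill - 1) / (Kn + xn2) ** 2
        d_rep1 = -p.hill * Kn * np.power(x[0], p.hill - 1) / (Kn + xn1) ** 2
        d_rep2 = -p.hill * Kn * np.power(x[1], p.hill - 1) / (Kn + xn2) ** 2
    d_act1, d_act2 = np.nan_to_num(d_act1), np.nan_to_num(d_act2)
    d_rep1, d_rep2 = np.nan_to_num(d_rep1), np.nan_to_num(d_rep2)
    return np.array([
        [p.theta * p.self_activation * d_act1 - p.degradation,
         p.theta * p.inhibition * d_rep2],
        [p.theta * p.inhibition * d_rep1,
         p.theta * p.self_activation * d_act2 - p.degradation],
    ])


def jacobian_eigs(params: GRNParams, x_star: np.ndarray,
                  tol: float = 1e-6) -> np.ndarray:
    """Eigenvalues of the analytic Jacobian at a fixed point, sorted by
    real part (descending). Warns if x_star is not actually a fixed point."""
    x_star = np.asarray(x_star, dtype=float)
    residual = float(np.linalg.norm(drift(x_star, params)))
    if residual > tol:
        import warnings

        warnings.warn(f"state has |F(x)| = {residual:.2e} > {tol:g}; "
                      "evaluating the Jacobian anyway", stacklevel=2)
    eigs = np.linalg.eigvals(jacobian(x_star, params))
    return eigs[np.argsort(-eigs.real)]


def find_attractors(
    params: GRNParams,
    grid_points: int = 12,
    root_tol: float = 1e-10,
    dedupe_tol: float = 1e-5,
) -> list[FixedPoint]:
    """Locate fixed points by multi-start root finding on a state-space grid.

    Returns deduplicated fixed points (stable and unstable) sorted by the
    first coordinate. Raises if no start converges.
    """
    hi = params.x_max * 1.05 + 1e-6
    starts = [np.array([u, v])
              for u in np.linspace(0.0, hi, grid_points)
              for v in np.linspace(0.0, hi, grid_points)]
    found: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(lambda z: drift(np.abs(z), params), x0,
                            method="hybr", tol=root_tol)
        if not sol.success:
            continue
        x = np.abs(sol.x)
        if np.linalg.norm(drift(x, params)) > 1e-8:
            continue
        if any(np.linalg.norm(x - y) < dedupe_tol for y in found):
            continue
        found.append(x)
    if not found:
        raise RuntimeError("no fixed point converged from any grid start")
    points = []
    for x in sorted(found, key=lambda z: (round(z[0], 6), round(z[1], 6))):
        eigs = np.linalg.eigvals(jacobian(x, params))
        eigs = eigs[np.argsort(-eigs.real)]
        points.append(FixedPoint(x=x, stable=bool((eigs.real < 0).all()),
                                 eigenvalues=eigs))
    return points


def lambda_star(params: GRNParams) -> float:
    """Leading eigenvalue over the *stable* attractors (the least negative);
    falls back to the overall minimum of leading eigenvalues if none is stable."""
    points = find_attractors(params)
    stable = [fp for fp in points if fp.stable]
    pool = stable if stable else points
    return max(fp.lambda_star for fp in pool)


def _count_stable(params: GRNParams) -> int:
    return sum(fp.stable for fp in find_attractors(params))


def theta_critical(params: GRNParams, lo: float = 0.05, hi: float | None = None,
                   tol: float = 1e-4) -> float:
    """Bisection for the theta at which bistability is lost.

    ``lo`` must be on the monostable side and ``hi`` (default: the params'
    own theta) on the bistable side.
    """
    hi = params.theta if hi is None else hi
    if _count_stable(replace(params, theta=lo)) >= 2:
        raise ValueError("lo is not on the monostable side")
    if _count_stable(replace(params, theta=hi)) < 2:
        raise ValueError("hi is not on the bistable side")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _count_stable(replace(params, theta=mid)) >= 2:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _select_attractor(params: GRNParams, basin: str) -> np.ndarray:
    stable = [fp for fp in find_attractors(params) if fp.stable]
    if not stable:
        raise RuntimeError("no stable attractor for these parameters")
    if basin == "upper":
        return max(stable, key=lambda fp: fp.x[0] - fp.x[1]).x
    if basin == "lower":
        return min(stable, key=lambda fp: fp.x[0] - fp.x[1]).x
    raise ValueError("basin must be 'upper' or 'lower'")


def simulate_cells(
    params: GRNParams,
    n_cells: int,
    burn_in: float,
    rng: np.random.Generator,
    dt: float = 0.01,
    basin: str = "upper",
) -> np.ndarray:
    """Core states of n_cells independent Langevin realisations started at
    an attractor and integrated for the burn-in time (Euler-Maruyama,
    additive noise, reflection at zero). Returns an (n_cells, 2) array."""
    x_star = _select_attractor(params, basin)
    x = np.tile(x_star, (n_cells, 1))
    n_steps = max(1, int(np.ceil(burn_in / dt)))
    scale = params.sigma * np.sqrt(dt)
    for _ in range(n_steps):
        x = x + drift(x, params) * dt + scale * rng.standard_normal(x.shape)
        np.abs(x, out=x)  # reflect at zero
    return x


def generate_snapshot(
    params: GRNParams,
    n_cells: int,
    burn_in: float = 50.0,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
    basin: str = "upper",
    mixing: np.ndarray | None = None,
    condition: str = "",
) -> SnapshotMatrix:
    """Generate an m-gene x c-cell snapshot from one basin of attraction.

    Each cell's observed expression vector is ``obs_offset + W @ x +
    noise`` clipped at zero, with mixing weights W (m x 2) drawn once from
    the supplied generator unless given explicitly. The burn-in should be
    several relaxation times (1/|lambda*|) so the sample is stationary.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = rng if rng is not None else np.random.default_rng()
    m = params.n_genes
    if mixing is None:
        mixing = rng.standard_normal((m, 2))
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (m, 2):
        raise ValueError(f"mixing must have shape ({m}, 2)")
    cores = simulate_cells(params, n_cells, burn_in, rng, dt=dt, basin=basin)
    observed = params.obs_offset + mixing @ cores.T
    if params.obs_noise > 0:
        observed = observed + params.obs_noise * rng.standard_normal(observed.shape)
    np.clip(observed, 0.0, None, out=observed)
    genes = [f"g{i:03d}" for i in range(m)]
    cells = [f"c{j:04d}" for j in range(n_cells)]
    return SnapshotMatrix(values=observed, genes=genes, cells=cells,
                          condition=condition)
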