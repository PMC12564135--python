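"""Overdamped Langevin dynamics and constant-velocity steered pulls in 1-D.

The solute centre-of-mass coordinate z (Å) evolves under a membrane
potential U(z) by the Euler–Maruyama scheme

    z <- z - D U'(z)/(kB T) dt + sqrt(2 D dt) eta,   eta ~ N(0, 1),

with reflecting boundaries at the potential's domain edges.  Steered pulls
add a harmonic guide at lambda(t) moving at constant speed v; the external
work is accumulated as the trapezoidal integral of f*v dt with
f = k_spring (lambda - z).  All stochastic output is a pure function of the
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .constants import KB
from .potentials import PotentialSpec

__all__ = [
    "LangevinParams",
    "PullProtocol",
    "Path1D",
    "WorkTrace",
    "StabilityError",
    "check_stability",
    "simulate_langevin_1d",
    "simulate_smd_pull",
    "sample_boltzmann_start",
]

#: stability threshold for dt * D * max|U''| / (kB T)
STABILITY_LIMIT = 0.1


class StabilityError(ValueError):
    """Time step too large for the potential's curvature."""


@dataclass(frozen=True)
class LangevinParams:
    """Diffusive dynamics parameters: D in Å²/ns, T in K, dt in ns."""

    D: float
    T: float
    dt: float
    kB: float = KB

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be > 0")
        if self.T <= 0:
            raise ValueError("temperature T must be > 0")
        if self.dt <= 0:
            raise ValueError("time step dt must be > 0")

    @property
    def kBT(self) -> float:
        return self.kB * self.T


@dataclass(frozen=True)
class PullProtocol:
    """Constant-velocity guide protocol.

    ``v`` is the (positive) guide speed in Å/ns; the traversal sense is set
    by z_start -> z_end.  ``direction`` is the bookkeeping label used by the
    forward–reverse estimator; paired F and R protocols must traverse the
    identical interval in opposite senses.
    """

    direction: str
    v: float
    k_spring: float
    z_start: float
    z_end: float
    record_stride: int = 100

    def __post_init__(self) -> None:
        if self.direction not in ("F", "R"):
            raise ValueError("direction must be 'F' or 'R'")
        if self.v <= 0:
            raise ValueError("guide speed v must be > 0")
        if self.k_spring <= 0:
            raise ValueError("k_spring must be > 0")
        if self.z_start == self.z_end:
            raise ValueError("z_start and z_end must differ")
        if self.record_stride < 1:
            raise ValueError("record_stride must be a positive integer")

    @property
    def signed_v(self) -> float:
        return self.v if self.z_end > self.z_start else -self.v

    @property
    def duration(self) -> float:
        """Traversal time, ns."""
        return abs(self.z_end - self.z_start) / self.v


@dataclass
class Path1D:
    """Recorded unbiased trajectory of the 1-D coordinate."""

    times: np.ndarray
    z: np.ndarray
    seed: int
    params: LangevinParams
    potential: PotentialSpec


@dataclass
class WorkTrace:
    """One steered pull: guide, particle, spring force and cumulative work."""

    direction: str
    times: np.ndarray
    lam: np.ndarray
    z: np.ndarray
    f: np.ndarray
    W: np.ndarray
    protocol: PullProtocol
    seed: int

    def recompute_work(self) -> np.ndarray:
        """Trapezoidal re-integration of f*v over the recorded samples.

        With dense recording this reproduces W; with a coarse stride it is a
        consistency check at the recording resolution.
        """
        v = self.protocol.signed_v
        out = np.zeros_like(self.W)
        out[1:] = np.cumsum(0.5 * (self.f[1:] + self.f[:-1]) * v * np.diff(self.times))
        return out


def check_stability(potential: PotentialSpec, params: LangevinParams, k_spring: float = 0.0) -> float:
    """Enforce dt * D * max|U''| / (kB T) < 0.1 (spring curvature included)."""
    curv = potential.max_curvature() + k_spring
    s = params.dt * params.D * curv / params.kBT
    if s >= STABILITY_LIMIT:
        raise StabilityError(
            f"dt*D*max|U''|/(kB*T) = {s:.3g} >= {STABILITY_LIMIT}; "
            f"reduce dt below {STABILITY_LIMIT * params.kBT / (params.D * curv):.3g} ns"
        )
    return s


# --------------------------------------------------------------------------
# numba kernels; the potential gradient enters as a dense uniform lookup
# table with linear interpolation (grid fine enough that the interpolation
# error is far below the Euler-Maruyama discretisation error).
# --------------------------------------------------------------------------


@njit(cache=True)
def _grad(z, g0, inv_dz, gtab):
    x = (z - g0) * inv_dz
    j = int(x)
    if j < 0:
        j = 0
    n2 = gtab.shape[0] - 2
    if j > n2:
        j = n2
    w = x - j
    return gtab[j] * (1.0 - w) + gtab[j + 1] * w


@njit(cache=True)
def _free_kernel(z, noise, mob_dt, g0, inv_dz, gtab, zmin, zmax, out):
    """Evolve one walker for len(noise) steps, recording every step."""
    for i in range(noise.shape[0]):
        z = z - mob_dt * _grad(z, g0, inv_dz, gtab) + noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        if z > zmax:
            z = 2.0 * zmax - z
        if z < zmin or z > zmax:
            return np.nan
        out[i] = z
    return z


@njit(cache=True)
def _pull_kernel(
    state, noise, mob_dt, vdt, k, g0, inv_dz, gtab, zmin, zmax,
    stride, step0, rec, ri0,
):
    z, lam, W, f = state[0], state[1], state[2], state[3]
    ri = ri0
    for i in range(noise.shape[0]):
        z = z + mob_dt * (f - _grad(z, g0, inv_dz, gtab)) + noise[i]
        if z < zmin:
            z = 2.0 * zmin - z
        if z > zmax:
            z = 2.0 * zmax - z
        if z < zmin or z > zmax:
            return -1
        lam += vdt
        fn = k * (lam - z)
        W += 0.5 * (f + fn) * vdt  # trapezoid of f * v dt (vdt = signed v * dt)
        f = fn
        if (step0 + i + 1) % stride == 0:
            rec[0, ri] = lam
            rec[1, ri] = z
            rec[2, ri] = fn
            rec[3, ri] = W
            ri += 1
    state[0], state[1], state[2], state[3] = z, lam, W, f
    return ri


_CHUNK = 1 << 20


def simulate_langevin_1d(
    potential: PotentialSpec,
    dynamics: LangevinParams,
    n_steps: int,
    z0: float,
    seed: int,
    record_stride: int = 1,
) -> Path1D:
    """Unbiased overdamped Langevin path on ``potential``.

    Returns a :class:`Path1D` whose ``z[0]`` is z0 and which records every
    ``record_stride``-th step thereafter.  Identical seed gives an identical
    path bit for bit.
    """
    lo, hi = potential.domain
    if not lo <= z0 <= hi:
        raise ValueError(f"z0={z0} outside potential domain {potential.domain}")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    check_stability(potential, dynamics)

    g0, dz, gtab = potential.gradient_table()
    mob_dt = dynamics.D / dynamics.kBT * dynamics.dt
    sig = np.sqrt(2.0 * dynamics.D * dynamics.dt)
    rng = np.random.default_rng(seed)

    zs = np.empty(n_steps, dtype=float)
    z = float(z0)
    done = 0
    while done < n_steps:
        m = min(_CHUNK, n_steps - done)
        noise = rng.standard_normal(m) * sig
        z = _free_kernel(z, noise, mob_dt, g0, 1.0 / dz, gtab, lo, hi, zs[done : done + m])
        if np.isnan(z):
            raise StabilityError("coordinate left the domain even after reflection; dt too large")
        done += m

    rec = zs[record_stride - 1 :: record_stride]
    z_out = np.concatenate(([z0], rec))
    t_out = dynamics.dt * record_stride * np.arange(len(z_out), dtype=float)
    return Path1D(times=t_out, z=z_out, seed=seed, params=dynamics, potential=potential)


def sample_boltzmann_start(
    potential: PotentialSpec,
    dynamics: LangevinParams,
    z_center: float,
    k_spring: float,
    rng: np.random.Generator,
) -> float:
    """Draw z0 from exp(-(U(z) + k/2 (z - z_center)^2)/kBT).

    Discrete inverse-CDF sampling on a dense grid spanning +-6 thermal
    widths of the restraint, clipped to the potential domain.
    """
    sigma = np.sqrt(dynamics.kBT / k_spring)
    lo, hi = potential.domain
    a = max(lo, z_center - 6 * sigma)
    b = min(hi, z_center + 6 * sigma)
    zg = np.linspace(a, b, 2001)
    u = potential.energy(zg) + 0.5 * k_spring * (zg - z_center) ** 2
    w = np.exp(-(u - u.min()) / dynamics.kBT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, zg))


def simulate_smd_pull(
    potential: PotentialSpec,
    dynamics: LangevinParams,
    pull: PullProtocol,
    seed: int,
    z0: Optional[float] = None,
) -> WorkTrace:
    """Constant-velocity steered pull; returns the recorded work trace.

    If z0 is None it is drawn from the Boltzmann distribution of the system
    restrained at z_start by the pull spring (stiff-spring consistent start).
    """
    lo, hi = potential.domain
    if not (lo <= pull.z_start <= hi and lo <= pull.z_end <= hi):
        raise ValueError("pull interval leaves the potential domain")
    check_stability(potential, dynamics, k_spring=pull.k_spring)

    rng = np.random.default_rng(seed)
    if z0 is None:
        z0 = sample_boltzmann_start(potential, dynamics, pull.z_start, pull.k_spring, rng)
    if not lo <= z0 <= hi:
        raise ValueError(f"z0={z0} outside potential domain")

    n_steps = int(np.ceil(pull.duration / dynamics.dt))
    stride = pull.record_stride
    n_rec = n_steps // stride

    g0, dz, gtab = potential.gradient_table()
    mob_dt = dynamics.D / dynamics.kBT * dynamics.dt
    sig = np.sqrt(2.0 * dynamics.D * dynamics.dt)
    vdt = pull.signed_v * dynamics.dt

    rec = np.empty((4, n_rec), dtype=float)
    state = np.array([z0, pull.z_start, 0.0, pull.k_spring * (pull.z_start - z0)])
    done = 0
    ri = 0
    while done < n_steps:
        m = min(_CHUNK, n_steps - done)
        noise = rng.standard_normal(m) * sig
        ri = _pull_kernel(
            state, noise, mob_dt, vdt, pull.k_spring,
            g0, 1.0 / dz, gtab, lo, hi, stride, done, rec, ri,
        )
        if ri < 0:
            raise StabilityError("coordinate left the domain during pull; dt too large")
        done += m

    times = np.concatenate(([0.0], dynamics.dt * stride * (1.0 + np.arange(ri))))
    lam = np.concatenate(([pull.z_start], rec[0, :ri]))
    z = np.concatenate(([z0], rec[1, :ri]))
    f = np.concatenate(([pull.k_spring * (pull.z_start - z0)], rec[2, :ri]))
    W = np.concatenate(([0.0], rec[3, :ri]))
    return WorkTrace(
        direction=pull.direction, times=times, lam=lam, z=z, f=f, W=W,
        protocol=pull, seed=seed,
    )
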