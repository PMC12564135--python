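"""One-dimensional membrane potentials U(z).

A :class:`PotentialSpec` is the ground truth that the Langevin generator
samples and the forward-reverse work estimator tries to recover.  Energies
are in kcal/mol, positions in Å.  Supported analytic forms:

``flat``
    U = 0 on the domain.
``linear``
    U = slope * (z - z_ref).
``harmonic``
    U = 0.5 * kappa * (z - z0)**2.
``double_well``
    Quartic with minima at z1 and z2 (U=0 there) and a barrier of height
    ``barrier`` at the midpoint.
``tabulated``
    Cubic-spline interpolation of (z, U) samples; continuously
    differentiable on the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["PotentialSpec", "PotentialError"]


class PotentialError(ValueError):
    """Invalid potential definition or evaluation outside the domain."""


@dataclass(frozen=True)
class PotentialSpec:
    form: str
    params: dict[str, Any]
    domain: tuple[float, float]
    _spline: Any = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not np.isfinite(lo) or not np.isfinite(hi) or not lo < hi:
            raise PotentialError(f"invalid domain {self.domain!r}")
        if self.form not in ("flat", "linear", "harmonic", "double_well", "tabulated"):
            raise PotentialError(f"unknown potential form {self.form!r}")
        if self.form == "tabulated":
            z = np.asarray(self.params["z"], dtype=float)
            u = np.asarray(self.params["U"], dtype=float)
            if z.ndim != 1 or z.shape != u.shape or z.size < 4:
                raise PotentialError("tabulated form needs >=4 (z, U) samples")
            if not np.all(np.diff(z) > 0):
                raise PotentialError("tabulated z values must be strictly increasing")
            if not np.all(np.isfinite(u)):
                raise PotentialError("tabulated U values must be finite")
            object.__setattr__(self, "_spline", CubicSpline(z, u))
        test = self.energy(np.linspace(lo, hi, 257))
        if not np.all(np.isfinite(test)):
            raise PotentialError("U not finite everywhere on the domain")

    # ------------------------------------------------------------------ API
    @classmethod
    def flat(cls, domain: tuple[float, float]) -> "PotentialSpec":
        return cls("flat", {}, domain)

    @classmethod
    def linear(cls, slope: float, domain: tuple[float, float], z_ref: float = 0.0) -> "PotentialSpec":
        return cls("linear", {"slope": float(slope), "z_ref": float(z_ref)}, domain)

    @classmethod
    def harmonic(cls, kappa: float, domain: tuple[float, float], z0: float = 0.0) -> "PotentialSpec":
        if kappa <= 0:
            raise PotentialError("harmonic kappa must be > 0")
        return cls("harmonic", {"kappa": float(kappa), "z0": float(z0)}, domain)

    @classmethod
    def double_well(
        cls,
        z1: float,
        z2: float,
        barrier: float,
        domain: tuple[float, float],
    ) -> "PotentialSpec":
        """Quartic double well: minima (U=0) at z1 < z2, barrier at the midpoint."""
        if not z1 < z2:
            raise PotentialError("double_well requires z1 < z2")
        if barrier <= 0:
            raise PotentialError("double_well barrier must be > 0")
        return cls(
            "double_well",
            {"z1": float(z1), "z2": float(z2), "barrier": float(barrier)},
            domain,
        )

    @classmethod
    def tabulated(cls, z: np.ndarray, U: np.ndarray) -> "PotentialSpec":
        z = np.asarray(z, dtype=float)
        return cls("tabulated", {"z": z, "U": np.asarray(U, dtype=float)}, (float(z[0]), float(z[-1])))

    # --------------------------------------------------------------- values
    def energy(self, z):
        """U(z), kcal/mol. Vectorized."""
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "linear":
            return p["slope"] * (z - p["z_ref"])
        if self.form == "harmonic":
            return 0.5 * p["kappa"] * (z - p["z0"]) ** 2
        if self.form == "double_well":
            zm = 0.5 * (p["z1"] + p["z2"])
            d = 0.5 * (p["z2"] - p["z1"])
            x = (z - zm) / d
            return p["barrier"] * (x**2 - 1.0) ** 2
        return self._spline(z)

    def gradient(self, z):
        """dU/dz, kcal/mol/Å. Vectorized, finite everywhere on the domain."""
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "linear":
            return np.full_like(z, p["slope"])
        if self.form == "harmonic":
            return p["kappa"] * (z - p["z0"])
        if self.form == "double_well":
            zm = 0.5 * (p["z1"] + p["z2"])
            d = 0.5 * (p["z2"] - p["z1"])
            x = (z - zm) / d
            return p["barrier"] * 4.0 * x * (x**2 - 1.0) / d
        return self._spline(z, 1)

    def gradient_table(self, n: int = 4097) -> tuple[float, float, np.ndarray]:
        """Dense uniform gradient lookup (z0, dz, values) used by the integrators."""
        lo, hi = self.domain
        zg = np.linspace(lo, hi, n)
        g = np.asarray(self.gradient(zg), dtype=float)
        if not np.all(np.isfinite(g)):
            raise PotentialError("non-finite gradient on the domain")
        return lo, (hi - lo) / (n - 1), g

    def max_curvature(self, n: int = 4097) -> float:
        """max |U''| over the domain, from second differences of the gradient."""
        lo, dz, g = self.gradient_table(n)
        return float(np.max(np.abs(np.diff(g))) / dz) if len(g) > 1 else 0.0
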