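"""Forward–reverse nonequilibrium PMF estimation.

Pairs of steered pulls traverse the same z interval in opposite senses.
Writing W_F(z) for the mean forward work accumulated from the forward
start a up to z, and W_R(z) for the mean reverse work accumulated over the
segment between z and a (the tail of each reverse pull), the overdamped
linear-response dissipation over a given segment is direction-independent,
so it cancels in the half-difference and adds in the half-sum:

    ΔU(z) = ½ (W_F(z) − W_R(z)),      W_d(z) = ½ (W_F(z) + W_R(z)) ≥ 0.

The optional friction/diffusion profile D(z) = kB·T·v / W_d'(z) follows
from the same linear-response framework (reconstructed from the method the
work bookkeeping is based on; shipped as optional).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB
from .dynamics import PullProtocol, WorkTrace

__all__ = [
    "MeanWorkProfile",
    "PmfProfile",
    "bin_work",
    "average_works",
    "estimate_pmf",
    "estimate_dissipation",
    "estimate_friction_diffusion",
    "write_work_trace",
    "read_work_trace",
    "default_grid",
]


@dataclass
class MeanWorkProfile:
    z: np.ndarray
    mean_F: np.ndarray
    mean_R: np.ndarray
    se_F: Optional[np.ndarray]
    se_R: Optional[np.ndarray]
    n_F: int
    n_R: int
    v: float
    T: Optional[float] = None
    #: standard errors of the central work increments W(z[i+1]) - W(z[i-1]);
    #: cumulative-work SEs are strongly correlated between nodes, so slope
    #: significance must come from these, not from se_F/se_R
    se_dF: Optional[np.ndarray] = None
    se_dR: Optional[np.ndarray] = None


@dataclass
class PmfProfile:
    z: np.ndarray
    dU: np.ndarray
    se: Optional[np.ndarray]
    anchor: Optional[float]
    Wd: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z": self.z, "dU": self.dU})
        df["se"] = self.se if self.se is not None else np.nan
        if self.Wd is not None:
            df["Wd"] = self.Wd
        if self.D is not None:
            df["D"] = self.D
        return df


def default_grid(z_min: float = 0.0, z_max: float = 19.0, spacing: float = 0.5) -> np.ndarray:
    """Uniform z grid; the 0.5 Å default resolves the few-Å PMF features."""
    n = int(round((z_max - z_min) / spacing))
    return z_min + spacing * np.arange(n + 1)


def bin_work(trace: WorkTrace, grid: np.ndarray) -> np.ndarray:
    """Work of one pull on the shared spatial grid.

    Forward traces: cumulative work linearly interpolated at the grid
    nodes (guide position λ is the spatial axis).  Reverse traces are
    re-indexed to the same axis as the segment work between the node and
    the reverse end point, W_total − W(λ=z), which is what the
    half-difference estimator needs.  Nodes may exceed the recorded λ
    range by at most one recording step (end values are used there);
    anything farther is an error.
    """
    grid = np.asarray(grid, dtype=float)
    lam, W = trace.lam, trace.W
    forward_sense = lam[-1] > lam[0]
    if not forward_sense:
        lam, W = lam[::-1], W[::-1]
    tol = np.max(np.abs(np.diff(lam))) + 1e-9 if len(lam) > 1 else 1e-9
    if grid.min() < lam[0] - tol or grid.max() > lam[-1] + tol:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside traversed interval "
            f"[{lam[0]:.6g}, {lam[-1]:.6g}]"
        )
    w = np.interp(grid, lam, W)
    if trace.direction == "R":
        w_end = trace.W[-1]
        w = w_end - w
    return w


def average_works(traces: Sequence[WorkTrace], grid: np.ndarray) -> MeanWorkProfile:
    """Direction-wise mean works and standard errors on a shared grid.

    All traces must share the guide speed and traversal interval; the F
    and R sets must each be non-empty.  With a single pull in a direction
    the standard error is undefined and reported as None.
    """
    grid = np.asarray(grid, dtype=float)
    f_traces = [t for t in traces if t.direction == "F"]
    r_traces = [t for t in traces if t.direction == "R"]
    if not f_traces or not r_traces:
        raise ValueError("need at least one trace in each direction")
    p0 = traces[0].protocol
    interval = {p0.z_start, p0.z_end}
    for t in traces:
        p = t.protocol
        if p.v != p0.v or {p.z_start, p.z_end} != interval:
            raise ValueError("mixed protocols: all pulls must share speed and interval")

    def stats(ts):
        w = np.array([bin_work(t, grid) for t in ts])
        mean = w.mean(axis=0)
        se = sed = None
        if len(ts) > 1:
            se = w.std(axis=0, ddof=1) / np.sqrt(len(ts))
            if w.shape[1] >= 3:
                incr = w[:, 2:] - w[:, :-2]
                sed = np.full(w.shape[1], np.nan)
                sed[1:-1] = incr.std(axis=0, ddof=1) / np.sqrt(len(ts))
        return mean, se, sed

    mF, seF, sedF = stats(f_traces)
    mR, seR, sedR = stats(r_traces)
    return MeanWorkProfile(
        z=grid, mean_F=mF, mean_R=mR, se_F=seF, se_R=seR,
        n_F=len(f_traces), n_R=len(r_traces), v=p0.v,
        se_dF=sedF, se_dR=sedR,
    )


def estimate_pmf(meanworks: MeanWorkProfile, anchor: Optional[float] = 19.0) -> PmfProfile:
    """ΔU(z) = ½(⟨W_F⟩ − ⟨W_R⟩), shifted so ΔU(anchor) = 0.

    ``anchor=None`` skips the shift.  Propagated standard error is
    ½·sqrt(SE_F² + SE_R²) where both are defined.
    """
    z = meanworks.z
    dU = 0.5 * (meanworks.mean_F - meanworks.mean_R)
    if anchor is not None:
        if anchor < z.min() - 1e-9 or anchor > z.max() + 1e-9:
            raise ValueError(f"anchor {anchor} outside grid [{z.min()}, {z.max()}]")
        dU = dU - np.interp(anchor, z, dU)
    se = None
    if meanworks.se_F is not None and meanworks.se_R is not None:
        se = 0.5 * np.sqrt(meanworks.se_F**2 + meanworks.se_R**2)
    return PmfProfile(z=z.copy(), dU=dU, se=se, anchor=anchor)


def estimate_dissipation(meanworks: MeanWorkProfile) -> np.ndarray:
    """Dissipated work W_d(z) = ½(⟨W_F⟩ + ⟨W_R⟩), nonnegative in expectation."""
    return 0.5 * (meanworks.mean_F + meanworks.mean_R)


def estimate_friction_diffusion(
    meanworks: MeanWorkProfile,
    T: float,
    significance: float = 2.0,
) -> np.ndarray:
    """Position-dependent diffusion D(z) = kB·T·v / W_d'(z).

    The dissipation slope is taken by central differences; nodes where the
    slope is non-positive or not significant (below ``significance`` times
    its propagated standard error) are NaN — never a negative D.
    """
    z = meanworks.z
    Wd = estimate_dissipation(meanworks)
    D = np.full_like(Wd, np.nan)
    h = z[1] - z[0]
    if meanworks.se_dF is not None and meanworks.se_dR is not None:
        se_slope = 0.5 * np.sqrt(meanworks.se_dF**2 + meanworks.se_dR**2) / (2 * h)
    elif meanworks.se_F is not None and meanworks.se_R is not None:
        # conservative fallback: treats node works as independent
        se = 0.5 * np.sqrt(meanworks.se_F**2 + meanworks.se_R**2)
        se_slope = np.full_like(Wd, np.nan)
        se_slope[1:-1] = np.sqrt(se[2:] ** 2 + se[:-2] ** 2) / (2 * h)
    else:
        se_slope = np.zeros_like(Wd)
    for i in range(1, len(z) - 1):
        slope = (Wd[i + 1] - Wd[i - 1]) / (2 * h)
        if slope > 0 and slope > significance * se_slope[i]:
            D[i] = KB * T * meanworks.v / slope
    return D


# ------------------------------------------------------------------ trace I/O

def write_work_trace(path, trace: WorkTrace) -> None:
    """CSV with columns t, lam, z, f, W plus a JSON protocol sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"t": trace.times, "lam": trace.lam, "z": trace.z, "f": trace.f, "W": trace.W}
    ).to_csv(path, index=False, float_format="%.10g")
    p = trace.protocol
    sidecar = {
        "direction": trace.direction,
        "seed": trace.seed,
        "protocol": {
            "direction": p.direction, "v": p.v, "k_spring": p.k_spring,
            "z_start": p.z_start, "z_end": p.z_end, "record_stride": p.record_stride,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_work_trace(path) -> WorkTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    proto = PullProtocol(**meta["protocol"])
    return WorkTrace(
        direction=meta["direction"],
        times=df["t"].to_numpy(),
        lam=df["lam"].to_numpy(),
        z=df["z"].to_numpy(),
        f=df["f"].to_numpy(),
        W=df["W"].to_numpy(),
        protocol=proto,
        seed=int(meta["seed"]),
    )
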