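"""Validation and reporting utilities: velocity probes, normalized mean
absolute error, linear fits, and canopy-relative-height profiles."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .porosity import stratified_porosity

__all__ = [
    "ProbeSet",
    "FitResult",
    "sample_velocity",
    "nmae",
    "linear_fit",
    "crh_profiles",
    "default_probe_grid",
]


@dataclass
class ProbeSet:
    """Velocity sampling points (m, domain frame) grouped by canopy layer."""

    points: np.ndarray                 # (p, 3)
    layers: list = field(default_factory=list)  # per-point labels

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if not self.layers:
            self.layers = ["all"] * len(self.points)
        if len(self.layers) != len(self.points):
            raise ValueError("one layer label per point required")


def default_probe_grid(domain_size: float = 1.5, canopy_height: float = 1.3):
    """3 layers x 3 points smoke-test grid (the field protocol's probe
    coordinates are instrument-specific and must normally be supplied)."""
    c = domain_size / 2
    pts, labs = [], []
    for lab, frac in (("lower", 0.2), ("middle", 0.55), ("upper", 0.85)):
        for dx in (-0.2, 0.0, 0.2):
            pts.append([c + dx, c, frac * canopy_height])
            labs.append(lab)
    return ProbeSet(points=np.array(pts), layers=labs)


def sample_velocity(fluid, scaling, probes: ProbeSet) -> pd.DataFrame:
    """Trilinear interpolation of the speed |u| (m/s) at the probe points.

    ``fluid`` is a FluidState (or a (3, nx, ny, nz) physical-velocity
    array with ``scaling=None``).
    """
    if hasattr(fluid, "u"):
        u = scaling.u_to_physical(fluid.u)
        dx = scaling.dx
        shape = fluid.shape
    else:
        u = np.asarray(fluid, float)
        dx = scaling if np.isscalar(scaling) else 1.0
        shape = u.shape[1:]
    from .coupling import kernel_weights
    pos_lat = probes.points / dx
    idx, w = kernel_weights(pos_lat, shape, "linear")
    flat = np.ravel_multi_index((idx[..., 0], idx[..., 1], idx[..., 2]), shape)
    comps = np.stack([(u[c].ravel()[flat] * w).sum(axis=1) for c in range(3)],
                     axis=1)
    return pd.DataFrame({
        "point_id": np.arange(len(probes.points)),
        "layer": probes.layers,
        "speed_mps": np.linalg.norm(comps, axis=1),
    })


def nmae(simulated, measured, normalization: str = "mean") -> float:
    """Normalized mean absolute error, percent.

    ``mean`` (default): mean(|s - m|) / mean(m) * 100.
    ``pointwise``: mean(|s - m| / |m|) * 100.
    """
    s = np.asarray(simulated, float)
    m = np.asarray(measured, float)
    if s.shape != m.shape or s.size == 0:
        raise ValueError("series must be equal-length and non-empty")
    if normalization == "mean":
        mbar = m.mean()
        if mbar == 0:
            raise ValueError("mean of measured series is zero")
        return float(np.abs(s - m).mean() / mbar * 100.0)
    if normalization == "pointwise":
        if np.any(m == 0):
            raise ValueError("measured series contains zeros")
        return float((np.abs(s - m) / np.abs(m)).mean() * 100.0)
    raise ValueError(f"unknown normalization {normalization!r}")


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def linear_fit(simulated, measured) -> FitResult:
    """Ordinary least squares of measured on simulated (M = a*S + b) with
    the coefficient of determination R^2 = 1 - SS_res/SS_tot."""
    s = np.asarray(simulated, float)
    m = np.asarray(measured, float)
    if s.size < 2 or s.shape != m.shape:
        raise ValueError("need two equal-length series with n >= 2")
    if np.ptp(s) == 0:
        raise ValueError("simulated series is constant; fit undefined")
    res = stats.linregress(s, m)
    pred = res.slope * s + res.intercept
    ss_res = float(((m - pred) ** 2).sum())
    ss_tot = float(((m - m.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=r2, n=int(s.size))


def crh_profiles(record, n_bands: int = 10, resolution: int = 384,
                 frame: int = -1) -> pd.DataFrame:
    """Windward area, porosity, mean speed and mean vorticity per
    canopy-relative-height band (10%, 20%, ..., 100% by default).

    Fluid quantities are slab means over each band's horizontal layers at
    the requested frame; porosity comes from the imaging pipeline.
    Empty bands propagate as NaN.
    """
    frames = [len(record.frames) + frame if frame < 0 else frame]
    try:
        por = stratified_porosity(record, n_crh_bands=n_bands,
                                  resolution=resolution, frames=frames)
        por = por[por["frame"] != "initial"]
    except ValueError:
        por = pd.DataFrame(columns=["band", "A_mm2", "P_literal",
                                    "P_optical", "P"])
    f = record.frames[frames[0]]
    # band edges over the canopy extent, mapped to lattice layers
    tris = record.shell.triangles[record.leaf_triangles]
    if len(tris):
        nodes0 = record.initial_frame.nodes
        z = nodes0[np.unique(tris), 2]
        z0, z1 = float(z.min()), float(z.max())
    else:
        z0, z1 = 0.0, record.config.domain_size
    dz = record.scaling.dx
    nz = len(f.mean_speed_profile)
    rows = []
    for k in range(n_bands):
        lab = f"{int(100 * (k + 1) / n_bands)}%"
        lo = z0 + (z1 - z0) * k / n_bands
        hi = z0 + (z1 - z0) * (k + 1) / n_bands
        i0 = int(np.floor(lo / dz))
        i1 = max(int(np.ceil(hi / dz)), i0 + 1)
        sl = slice(max(i0, 0), min(i1, nz))
        row = {"crh": lab,
               "mean_speed_mps": float(f.mean_speed_profile[sl].mean()),
               "mean_vorticity_hz": float(f.mean_vorticity_profile[sl].mean())}
        sub = por[por["band"] == lab] if len(por) else []
        if len(sub):
            row.update(A_mm2=float(sub["A_mm2"].iloc[0]),
                       P_literal=float(sub["P_literal"].iloc[0]),
                       P_optical=float(sub["P_optical"].iloc[0]),
                       P=float(sub["P"].iloc[0]))
        else:
            row.update(A_mm2=np.nan, P_literal=np.nan, P_optical=np.nan,
                       P=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
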