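"""Stratified canopy porosity from projection images.

The five-step procedure: (1) render an orthographic projection of the
leaves of a layer (top view for downward airflow), (2) denoise /
grayscale / Otsu-threshold / binarize, (3) take the outer contour of the
canopy projection and measure its area S_i, (4) count plant pixels for
the windward area A_i, (5) porosity per layer.

Two porosity conventions coexist in the field and both are provided:

* ``optical``  : P = 1 - A/S  (void fraction of the contour — matches the
  verbal definition of optical porosity; the default),
* ``literal``  : P = A/S      (the printed per-layer formula with A the
  leaf area).

They sum to one for the same mask; output tables carry both.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

__all__ = [
    "ProjectionImage",
    "LayerPorosity",
    "EmptyLayerError",
    "render_projection",
    "preprocess",
    "outer_contour_area",
    "windward_area",
    "porosity_from_mask",
    "stratified_porosity",
]

_VIEW_AXES = {"top": 2, "front": 1}


class EmptyLayerError(ValueError):
    """A layer's projection holds too few foreground pixels."""


@dataclass
class ProjectionImage:
    """Grayscale orthographic projection (uint8, white background)."""

    pixels: np.ndarray
    mm_per_pixel: float
    view_axis: str = "top"
    label: str = ""
    frame_time: float = 0.0

    def __post_init__(self):
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.pixels.size == 0:
            raise ValueError("empty raster")


@dataclass
class LayerPorosity:
    """Windward area A (mm^2), contour area S (mm^2) and porosity of one
    layer/band.  ``p_literal`` = A/S, ``p_optical`` = 1 - A/S."""

    label: str
    area_windward: float
    area_contour: float

    @property
    def p_literal(self) -> float:
        return self.area_windward / self.area_contour

    @property
    def p_optical(self) -> float:
        return 1.0 - self.p_literal


def render_projection(meshes, view_axis: str = "top", bounds=None,
                      resolution: int = 512, label: str = "",
                      frame_time: float = 0.0) -> ProjectionImage:
    """Orthographic rasterization of triangle meshes (mm) onto a white
    background (foreground black).

    ``meshes`` is a list of (vertices, faces) or trimesh objects.
    ``bounds`` is ((min0, min1), (max0, max1)) in the projection plane,
    mm; by default the joint bounding box plus a 2% margin.
    ``resolution`` is the pixel count of the longer image side (the short
    side must come out at least 64 px).
    """
    if view_axis not in _VIEW_AXES:
        raise ValueError(f"view_axis must be one of {sorted(_VIEW_AXES)}")
    pairs = []
    for m in meshes:
        if hasattr(m, "vertices"):
            pairs.append((np.asarray(m.vertices, float), np.asarray(m.faces)))
        else:
            v, f = m
            pairs.append((np.asarray(v, float), np.asarray(f)))
    pairs = [(v, f) for v, f in pairs if len(f)]
    if not pairs:
        raise ValueError("no meshes to render")
    drop = _VIEW_AXES[view_axis]
    keep = [a for a in range(3) if a != drop]
    pts = np.vstack([v[:, keep] for v, _ in pairs])
    if bounds is None:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        margin = 0.02 * max((hi - lo).max(), 1e-6)
        lo, hi = lo - margin, hi + margin
    else:
        lo = np.asarray(bounds[0], float)
        hi = np.asarray(bounds[1], float)
    extent = hi - lo
    mm_per_pixel = float(extent.max() / resolution)
    npx = np.maximum(np.round(extent / mm_per_pixel).astype(int), 1)
    if npx.min() < 64:
        raise ValueError("resolution too low: short side under 64 px")
    img = np.zeros(tuple(npx), dtype=bool)
    for v, f in pairs:
        p2 = (v[:, keep] - lo) / mm_per_pixel - 0.5  # pixel-centre coords
        for tri in f:
            rr, cc = draw_polygon(p2[tri, 0], p2[tri, 1], shape=img.shape)
            img[rr, cc] = True
    pixels = np.where(img, 0, 255).astype(np.uint8)
    return ProjectionImage(pixels=pixels, mm_per_pixel=mm_per_pixel,
                           view_axis=view_axis, label=label,
                           frame_time=frame_time)


def preprocess(image, foreground: str = "dark") -> np.ndarray:
    """Binary plant mask from a projection image.

    3x3 median denoise, grayscale conversion, Otsu threshold.
    ``foreground`` is 'dark' (default: plant renders black on white),
    'light', or 'auto' (the minority side is taken as plant).
    """
    px = image.pixels if isinstance(image, ProjectionImage) else np.asarray(image)
    if px.ndim == 3:  # RGB(A) -> luminance
        px = px[..., :3].mean(axis=-1)
    px = px.astype(float)
    if px.max() == px.min():
        raise ValueError("no threshold: image has no contrast")
    den = ndimage.median_filter(px, size=3)
    thr = threshold_otsu(den)
    dark = den <= thr
    if foreground == "dark":
        return dark
    if foreground == "light":
        return ~dark
    if foreground == "auto":
        return dark if dark.mean() <= 0.5 else ~dark
    raise ValueError(f"bad foreground flag {foreground!r}")


def outer_contour_area(mask, mm_per_pixel: float,
                       pixel_extent_correction: bool = True,
                       alpha: float | None = None) -> float:
    """Projection area S_i (mm^2) enclosed by the outermost leaf edge.

    Convex hull of the foreground pixel centres; with
    ``pixel_extent_correction`` the hull is offset outward by half a
    pixel (mitred), compensating the half-pixel rim the centre hull
    misses (a full 10x10 px block then measures exactly 100 px^2).
    ``alpha`` switches to an alpha-shape-like concave outline: the union
    of pixel squares closed with a disc of that radius (in pixels).
    """
    mask = np.asarray(mask, bool)
    ii, jj = np.nonzero(mask)
    if len(ii) < 3:
        raise EmptyLayerError(f"only {len(ii)} foreground pixels")
    pts = MultiPoint(list(zip(ii.tolist(), jj.tolist())))
    if alpha is not None:
        geom = pts.buffer(0.5, cap_style="square")
        geom = geom.buffer(alpha).buffer(-alpha)
        return float(geom.area) * mm_per_pixel ** 2
    hull = pts.convex_hull
    if hull.area == 0.0:
        raise EmptyLayerError("foreground pixels are collinear")
    if pixel_extent_correction:
        hull = hull.buffer(0.5, join_style="mitre")
    return float(hull.area) * mm_per_pixel ** 2


def windward_area(mask, mm_per_pixel: float) -> float:
    """Windward leaf area A_i (mm^2): foreground pixel count times the
    pixel area."""
    return float(np.count_nonzero(mask)) * mm_per_pixel ** 2


def porosity_from_mask(mask, mm_per_pixel: float, label: str = "",
                       **contour_kw) -> LayerPorosity:
    a = windward_area(mask, mm_per_pixel)
    s = outer_contour_area(mask, mm_per_pixel, **contour_kw)
    return LayerPorosity(label=label, area_windward=a, area_contour=s)


def _band_edges_mm(record, layer_bounds=None, n_crh_bands=None):
    """(labels, z_lo, z_hi) in metres in the shell frame."""
    if (layer_bounds is None) == (n_crh_bands is None):
        raise ValueError("give exactly one of layer_bounds / n_crh_bands")
    if layer_bounds is not None:
        b = np.asarray(layer_bounds, float) * 10e-3  # cm -> m
        if len(b) == 4:
            labels = ["lower", "middle", "upper"]
        else:
            labels = [f"band_{i}" for i in range(len(b) - 1)]
        return labels, b[:-1], b[1:]
    # canopy relative height bands 10%..100% over the initial leaf extent
    nodes = record.initial_frame.nodes
    tris = record.shell.triangles[record.leaf_triangles]
    z = nodes[np.unique(tris), 2]
    z0, z1 = float(z.min()), float(z.max())
    edges = z0 + (z1 - z0) * np.arange(n_crh_bands + 1) / n_crh_bands
    labels = [f"{int(100 * (i + 1) / n_crh_bands)}%" for i in range(n_crh_bands)]
    return labels, edges[:-1], edges[1:]


def stratified_porosity(record, layer_bounds=None, n_crh_bands=None,
                        mode: str = "optical", view_axis: str = "top",
                        resolution: int = 384, frames=None) -> pd.DataFrame:
    """Per-frame, per-layer porosity table for a coupled simulation record.

    Bands are selected either as fixed layer bounds (cm, attachment-style
    layers rendered from triangles whose current centroid falls in the
    band) or as ``n_crh_bands`` canopy-relative-height bands.  Returns a
    DataFrame with columns (time_s, band, A_mm2, S_mm2, P_literal,
    P_optical, P, dP) where P is the requested ``mode`` and dP the
    dynamic variation against the no-wind initial frame.  Empty bands
    yield NaN with a warning rather than aborting.
    """
    if mode not in ("optical", "literal"):
        raise ValueError("mode must be 'optical' or 'literal'")
    if record.leaf_triangles.sum() == 0:
        raise ValueError("record has no leaf triangles")
    labels, zlo, zhi = _band_edges_mm(record, layer_bounds, n_crh_bands)
    tris = record.shell.triangles[record.leaf_triangles]

    # fixed render bounds from the whole-canopy initial footprint
    mm = 1e3
    nodes0 = record.initial_frame.nodes
    drop = _VIEW_AXES[view_axis]
    keep = [a for a in range(3) if a != drop]
    pts = nodes0[np.unique(tris)][:, keep] * mm
    lo = pts.min(axis=0) - 20.0
    hi = pts.max(axis=0) + 20.0

    todo = [("initial", record.initial_frame)]
    idxs = range(len(record.frames)) if frames is None else frames
    todo += [(i, record.frames[i]) for i in idxs]

    rows = []
    base = {}
    for fid, frame in todo:
        nodes = frame.nodes * mm
        cz = nodes[tris, 2].mean(axis=1) / mm
        top = len(labels) - 1
        for k, lab in enumerate(labels):
            sel = (cz >= zlo[k]) & ((cz < zhi[k]) if k < top else (cz <= zhi[k]))
            a = s = np.nan
            if sel.any():
                img = render_projection([(nodes, tris[sel])], view_axis,
                                        bounds=(lo, hi), resolution=resolution,
                                        label=lab, frame_time=frame.time)
                mask = preprocess(img)
                try:
                    lp = porosity_from_mask(mask, img.mm_per_pixel, label=lab)
                    a, s = lp.area_windward, lp.area_contour
                except EmptyLayerError as err:
                    warnings.warn(f"band {lab} at t={frame.time}: {err}")
            else:
                warnings.warn(f"band {lab} at t={frame.time}: no leaf triangles")
            p_lit = a / s if np.isfinite(a) and s else np.nan
            p_opt = 1.0 - p_lit if np.isfinite(p_lit) else np.nan
            p = p_opt if mode == "optical" else p_lit
            if fid == "initial":
                base[lab] = p
            rows.append({"time_s": frame.time, "band": lab, "A_mm2": a,
                         "S_mm2": s, "P_literal": p_lit, "P_optical": p_opt,
                         "P": p, "dP": p - base.get(lab, np.nan),
                         "frame": fid, "mode": mode})
    return pd.DataFrame(rows)
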