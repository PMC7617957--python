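"""Image-domain quantification of the barrel field.

Coordinates
-----------
Images are (row, col) = (y, x) with physical micrometres given by the
pixel size (default 1 um/px).  The *straightened* frame maps a point to
``(s, d)``: ``s`` is the arc length of its perpendicular foot on the
reference polyline (the L4/L5 boundary), ``d`` the signed normal
distance; ``+d`` points toward larger image y (deeper).  Barrel regions
are tangential ``s`` intervals extruded over the L4 band's ``d``
interval; segment clipping against these boxes is exact (parametric
line-box intersection), so overlap percentages sum to 100 to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "BarrelMap",
    "Morphology",
    "OverlapResult",
    "straighten",
    "straighten_image",
    "detect_barrels",
    "soma_position_index",
    "dendritic_overlap",
    "lhx2_ratio",
    "soma_mpi",
    "roi_expression_fraction",
]

EXCLUSION_PCT = 5.0  # morphologies under this max per-barrel overlap are excluded


@dataclass
class BarrelMap:
    """Barrel intervals and the reference boundary polyline.

    ``barrels`` are disjoint, sorted ``(s_start, s_end)`` intervals in
    arc-length coordinates; ``l4_band`` is the band's ``(d_lo, d_hi)``
    normal-offset interval.
    """

    reference_polyline: np.ndarray
    barrels: list
    l4_band: tuple

    def __post_init__(self) -> None:
        self.reference_polyline = np.asarray(self.reference_polyline, float)
        if self.reference_polyline.ndim != 2 or self.reference_polyline.shape[0] < 2:
            raise ValueError("reference polyline needs >= 2 (x, y) points")
        self.barrels = [(float(a), float(b)) for a, b in self.barrels]
        prev_end = -np.inf
        for a, b in self.barrels:
            if b <= a:
                raise ValueError("barrel intervals must have positive width")
            if a < prev_end:
                raise ValueError("barrel intervals must be disjoint and sorted")
            prev_end = b
        if self.l4_band[1] <= self.l4_band[0]:
            raise ValueError("l4_band must be an increasing (d_lo, d_hi) interval")

    @property
    def centers(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.barrels])

    @property
    def n_barrels(self) -> int:
        return len(self.barrels)


@dataclass
class Morphology:
    """SWC-style node tree: columns id, type, x, y, z, radius, parent."""

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "type", "x", "y", "z", "radius", "parent"}
        if not required.issubset(self.nodes.columns):
            raise ValueError(f"nodes table needs columns {sorted(required)}")
        roots = self.nodes[self.nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError("morphology must have exactly one root")
        ids = set(self.nodes["id"])
        parents = set(self.nodes["parent"]) - {-1}
        if not parents.issubset(ids):
            raise ValueError("every parent must reference an existing node")
        # acyclicity: walking parents from any node must reach the root
        parent_of = dict(zip(self.nodes["id"], self.nodes["parent"]))
        for nid in parent_of:
            seen = set()
            cur = nid
            while cur != -1:
                if cur in seen:
                    raise ValueError("morphology contains a cycle")
                seen.add(cur)
                cur = parent_of[cur]

    @property
    def soma_xy(self) -> np.ndarray:
        root = self.nodes[self.nodes["parent"] == -1].iloc[0]
        return np.array([root["x"], root["y"]])

    def segments(self) -> np.ndarray:
        """(n_segments, 2, 2) array of 2-D parent->child segments."""
        nodes = self.nodes.set_index("id")
        child = self.nodes[self.nodes["parent"] != -1]
        p0 = nodes.loc[child["parent"], ["x", "y"]].to_numpy(float)
        p1 = child[["x", "y"]].to_numpy(float)
        return np.stack([p0, p1], axis=1)

    @property
    def total_length(self) -> float:
        seg = self.segments()
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())


# ---------------------------------------------------------------------------
# straightening


def _polyline_geometry(polyline: np.ndarray):
    poly = np.asarray(polyline, dtype=float)
    a = poly[:-1]
    ab = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(ab, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("reference polyline has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return a, ab, seg_len, cum


def straighten(
    points: np.ndarray,
    polyline: np.ndarray,
    return_flags: bool = False,
):
    """Map points to (s, d) coordinates relative to a reference polyline.

    ``s`` is the arc length of the nearest foot on the polyline, ``d``
    the signed perpendicular distance (|d| equals the exact Euclidean
    point-to-polyline distance; the sign is positive on the side where
    ``cross(tangent, point - foot) > 0``).

    Parameters
    ----------
    points : ndarray, shape (n, 2)
    polyline : ndarray, shape (m, 2), m >= 2
    return_flags : bool
        Also return a boolean array marking points whose nearest foot is
        ambiguous (two non-adjacent feet at equal distance, e.g. at a
        polyline kink).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a, ab, seg_len, cum = _polyline_geometry(polyline)

    # (n, m) projection parameters, clamped to the segment
    ap = pts[:, None, :] - a[None, :, :]
    t = np.einsum("nmk,mk->nm", ap, ab) / (seg_len**2)[None, :]
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    diff = pts[:, None, :] - foot
    dist2 = np.einsum("nmk,nmk->nm", diff, diff)

    best = np.argmin(dist2, axis=1)
    n = np.arange(pts.shape[0])
    tb = t[n, best]
    s = cum[best] + tb * seg_len[best]
    fb = foot[n, best]
    db = pts - fb
    tang = ab[best] / seg_len[best, None]
    cross = tang[:, 0] * db[:, 1] - tang[:, 1] * db[:, 0]
    dist = np.sqrt(dist2[n, best])
    d = np.where(cross >= 0, dist, -dist)

    if not return_flags:
        return s, d
    # ambiguity: another segment ties for the minimum but lands at a
    # clearly different arc-length position
    scale = max(cum[-1], 1.0)
    tol = 1e-9 * scale
    flags = np.zeros(pts.shape[0], dtype=bool)
    for i in n:
        close = np.flatnonzero(dist2[i] <= dist2[i, best[i]] + tol**2)
        if close.size > 1:
            s_all = cum[close] + t[i, close] * seg_len[close]
            if s_all.max() - s_all.min() > 1e-6 * scale:
                flags[i] = True
    return s, d, flags


def straighten_image(
    image: np.ndarray,
    polyline: np.ndarray,
    d_range: tuple,
    pixel_size: float = 1.0,
):
    """Resample an image into the straightened (s, d) frame.

    Output pixel (i, j) corresponds to ``(s = j * px, d = d_lo + i * px)``
    and is bilinearly sampled from the input at the forward-mapped
    position ``P(s) + d * n(s)``.

    Returns
    -------
    straightened : ndarray, shape (n_d, n_s)
    s_axis, d_axis : ndarray
        Physical coordinates of columns and rows.
    """
    image = np.asarray(image, dtype=float)
    a, ab, seg_len, cum = _polyline_geometry(polyline)
    total = cum[-1]
    s_axis = np.arange(0.0, total, pixel_size)
    d_axis = np.arange(d_range[0], d_range[1], pixel_size)

    # dense arclength parameterization for interpolation
    step = min(pixel_size / 4.0, 0.5)
    s_dense = np.arange(0.0, total + step, step)
    poly = np.asarray(polyline, dtype=float)
    x_dense = np.interp(s_dense, cum, poly[:, 0])
    y_dense = np.interp(s_dense, cum, poly[:, 1])
    tx = np.gradient(x_dense, s_dense)
    ty = np.gradient(y_dense, s_dense)
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm

    xs = np.interp(s_axis, s_dense, x_dense)
    ys = np.interp(s_axis, s_dense, y_dense)
    txs = np.interp(s_axis, s_dense, tx)
    tys = np.interp(s_axis, s_dense, ty)

    dd, _ = np.meshgrid(d_axis, s_axis, indexing="ij")
    # +d along the normal (-ty, tx): cross(tangent, normal) = +1
    x_map = xs[None, :] + dd * (-tys[None, :])
    y_map = ys[None, :] + dd * txs[None, :]
    out = ndimage.map_coordinates(image, [y_map / pixel_size, x_map / pixel_size],
                                  order=1, mode="constant", cval=0.0)
    return out, s_axis, d_axis


# ---------------------------------------------------------------------------
# barrel detection


def detect_barrels(
    s: np.ndarray,
    profile: np.ndarray,
    smooth_sigma_um: float = 5.0,
    min_width_um: float = 20.0,
    floor_pct: float = 10.0,
    plateau_pct: float = 90.0,
) -> list:
    """Detect barrel intervals from a straightened L4 intensity profile.

    The profile is Gaussian-smoothed; the threshold is the midpoint
    between a robust septal floor and barrel plateau (percentiles).
    Maximal runs above threshold wider than ``min_width_um`` are
    barrels, with boundaries linearly interpolated at the threshold
    crossings.  Invariant to affine intensity rescaling a*I + b, a > 0.

    Raises
    ------
    ValueError
        When no run exceeds the minimum width ("no barrels detected").
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(profile, dtype=float)
    if s.size != y.size or s.size < 3:
        raise ValueError("profile and s must match and have >= 3 samples")
    ds = float(np.median(np.diff(s)))
    if smooth_sigma_um > 0:
        y = ndimage.gaussian_filter1d(y, smooth_sigma_um / ds)
    floor = np.percentile(y, floor_pct)
    plateau = np.percentile(y, plateau_pct)
    thr = (floor + plateau) / 2.0

    above = y > thr
    intervals = []
    i = 0
    n = s.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # interpolate boundaries at the threshold crossings
        if i > 0:
            f = (thr - y[i - 1]) / (y[i] - y[i - 1])
            s0 = s[i - 1] + f * (s[i] - s[i - 1])
        else:
            s0 = s[0]
        if j < n - 1:
            f = (thr - y[j]) / (y[j + 1] - y[j])
            s1 = s[j] + f * (s[j + 1] - s[j])
        else:
            s1 = s[-1]
        if s1 - s0 >= min_width_um:
            intervals.append((float(s0), float(s1)))
        i = j + 1
    if not intervals:
        raise ValueError("no barrels detected")
    return intervals


def band_profile(straightened: np.ndarray, d_axis: np.ndarray,
                 band: tuple) -> np.ndarray:
    """Mean intensity over the band's normal extent, per s column."""
    sel = (d_axis >= band[0]) & (d_axis <= band[1])
    if not np.any(sel):
        raise ValueError("band does not intersect the straightened image")
    return straightened[sel].mean(axis=0)


# ---------------------------------------------------------------------------
# soma position index


def _septal_midpoints(barrel_map: BarrelMap) -> np.ndarray:
    """Septal midpoints, with the outermost half-gaps mirrored.

    With a single barrel the barrel boundaries themselves act as the
    zero anchors.
    """
    b = barrel_map.barrels
    if len(b) == 1:
        return np.array([b[0][0], b[0][1]])
    mids = [(b[i][1] + b[i + 1][0]) / 2.0 for i in range(len(b) - 1)]
    c = barrel_map.centers
    left = 2.0 * c[0] - mids[0]
    right = 2.0 * c[-1] - mids[-1]
    return np.array([left, *mids, right])


def soma_position_index(
    s_soma: float,
    barrel_map: BarrelMap,
    ramp: str = "linear",
    return_flag: bool = False,
):
    """Barrel index: 1 at a barrel center, 0 at a septal midpoint.

    The index interpolates linearly between the nearest septal midpoint
    (0) and the nearest barrel center (1); ``ramp="cosine"`` applies a
    raised-cosine ramp to the same linear coordinate.  Somata beyond the
    mirrored outer midpoints are flagged (the index is still clipped to
    [0, 1]).

    Raises
    ------
    ValueError
        When the map holds no barrels.
    """
    if barrel_map.n_barrels == 0:
        raise ValueError("no barrels in the map")
    if ramp not in ("linear", "cosine"):
        raise ValueError("ramp must be 'linear' or 'cosine'")
    centers = barrel_map.centers
    mids = _septal_midpoints(barrel_map)
    c = centers[np.argmin(np.abs(centers - s_soma))]
    m = mids[np.argmin(np.abs(mids - s_soma))]
    if c == m:
        raise ValueError("degenerate barrel geometry: center equals midpoint")
    lin = float(np.clip(abs(s_soma - m) / abs(c - m), 0.0, 1.0))
    idx = lin if ramp == "linear" else 0.5 * (1.0 - np.cos(np.pi * lin))
    outside = bool(s_soma < mids.min() or s_soma > mids.max())
    if return_flag:
        return idx, outside
    return idx


# ---------------------------------------------------------------------------
# dendritic overlap


@dataclass
class OverlapResult:
    principal_barrel: int
    adjacent_barrel: Optional[int]
    pct_principal: float
    pct_adjacent: float
    pct_outside: float
    per_barrel_pct: dict
    excluded: bool
    total_length: float


def _clipped_length(p0: np.ndarray, p1: np.ndarray, box) -> float:
    """Exact length of a segment inside an axis-aligned box."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for dim in range(2):
        lo, hi = box[dim]
        if d[dim] == 0.0:
            if not (lo <= p0[dim] <= hi):
                return 0.0
        else:
            ta = (lo - p0[dim]) / d[dim]
            tb = (hi - p0[dim]) / d[dim]
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
    if t1 <= t0:
        return 0.0
    return float((t1 - t0) * np.hypot(d[0], d[1]))


def dendritic_overlap(
    morph: Morphology,
    barrel_map: BarrelMap,
    adjacent_rule: str = "nearest_center",
    exclusion_pct: float = EXCLUSION_PCT,
) -> OverlapResult:
    """Per-barrel dendritic length percentages in the straightened frame.

    Each parent->child segment is clipped exactly against every barrel
    region (s interval x L4 band), so percentages over all barrels plus
    outside sum to 100 to machine precision.  The principal barrel holds
    the largest length; the adjacent barrel is the non-principal barrel
    whose center is nearest the soma (``adjacent_rule="nearest_center"``)
    or the one with the second-highest overlap
    (``adjacent_rule="second_overlap"``).  Morphologies whose maximum
    per-barrel percentage is below ``exclusion_pct`` are flagged
    excluded.

    Raises
    ------
    ValueError
        On zero total dendritic length.
    """
    if adjacent_rule not in ("nearest_center", "second_overlap"):
        raise ValueError("unknown adjacent_rule")
    segs = morph.segments()
    total = float(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum())
    if total <= 0:
        raise ValueError("zero total dendritic length")

    lengths = np.zeros(barrel_map.n_barrels)
    for b, (s0, s1) in enumerate(barrel_map.barrels):
        box = ((s0, s1), barrel_map.l4_band)
        lengths[b] = sum(_clipped_length(p0, p1, box) for p0, p1 in segs)
    pct = 100.0 * lengths / total
    principal = int(np.argmax(lengths))
    pct_outside = 100.0 - pct.sum()

    adjacent: Optional[int] = None
    if barrel_map.n_barrels > 1:
        others = [b for b in range(barrel_map.n_barrels) if b != principal]
        if adjacent_rule == "nearest_center":
            soma_s = morph.soma_xy[0]
            adjacent = min(others,
                           key=lambda b: abs(barrel_map.centers[b] - soma_s))
        else:
            adjacent = max(others, key=lambda b: lengths[b])
    return OverlapResult(
        principal_barrel=principal,
        adjacent_barrel=adjacent,
        pct_principal=float(pct[principal]),
        pct_adjacent=float(pct[adjacent]) if adjacent is not None else 0.0,
        pct_outside=float(pct_outside),
        per_barrel_pct={b: float(pct[b]) for b in range(barrel_map.n_barrels)},
        excluded=bool(pct.max() < exclusion_pct),
        total_length=total,
    )


# ---------------------------------------------------------------------------
# intensity quantification


def soma_mpi(image: np.ndarray, center_xy, radius_um: float = 5.0,
             pixel_size: float = 1.0) -> float:
    """Mean pixel intensity over a fixed-radius disk around a centroid."""
    image = np.asarray(image, dtype=float)
    cx, cy = float(center_xy[0]) / pixel_size, float(center_xy[1]) / pixel_size
    r = radius_um / pixel_size
    yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if not mask.any():
        raise ValueError("soma disk lies outside the image")
    return float(image[mask].mean())


def lhx2_ratio(cell_mpi: float, neighbor_mpis: Sequence[float]) -> float:
    """Ratio of a cell's MPI over the mean MPI of exactly 3 neighbors.

    Raises
    ------
    ValueError
        Unless exactly 3 finite neighbor measurements are provided.
    """
    neighbors = np.asarray(neighbor_mpis, dtype=float)
    if neighbors.size != 3:
        raise ValueError("exactly 3 neighboring measurements required")
    if not (np.isfinite(neighbors).all() and np.isfinite(cell_mpi)):
        raise ValueError("intensities must be finite")
    mean_n = float(neighbors.mean())
    if mean_n <= 0:
        raise ValueError("neighbor mean intensity must be positive")
    return float(cell_mpi) / mean_n


def roi_expression_fraction(
    sections: Sequence[np.ndarray],
    roi_masks: Sequence[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Fraction of suprathreshold expression falling inside the ROI.

    Each section is thresholded with Otsu's method; the per-section
    fraction is (suprathreshold pixels inside the ROI) / (all
    suprathreshold pixels).  Returns the per-section fractions and their
    mean.

    Raises
    ------
    ValueError
        On mismatched shapes, no sections, or a section with no
        suprathreshold pixels.
    """
    if len(sections) == 0 or len(sections) != len(roi_masks):
        raise ValueError("need matching, non-empty section and mask lists")
    fractions = []
    for img, mask in zip(sections, roi_masks):
        img = np.asarray(img, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if img.shape != mask.shape:
            raise ValueError("image and ROI mask shapes differ")
        thr = threshold_otsu(img)
        supra = img > thr
        n_supra = int(supra.sum())
        if n_supra == 0:
            raise ValueError("no suprathreshold pixels in a section")
        fractions.append(float((supra & mask).sum()) / n_supra)
    fractions = np.asarray(fractions)
    return fractions, float(fractions.mean())
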