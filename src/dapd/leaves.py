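"""Individual leaf segmentation and counting from a rosette mask.

Leaves are separated by a marker-controlled watershed: the rosette contour
and centre are extracted, candidate leaf centres are taken as local maxima
of the (smoothed) Euclidean distance transform away from the rosette core,
nearby maxima are merged, and the watershed of the inverted distance
transform seeded at those markers splits touching leaves.  The number of
markers is the measured leaf count; leaves completely hidden below younger
leaves are invisible to the mask, so the count underestimates the true leaf
number by exactly the occluded count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class LeafLabelImage:
    """Per-leaf instance labels (0 = background, 1..L = leaves)."""

    labels: np.ndarray
    leaf_count: int

    def __post_init__(self) -> None:
        n = np.unique(self.labels[self.labels > 0]).size
        if n != self.leaf_count:
            raise ValueError("leaf_count must equal the number of labels")


def extract_contours(mask: np.ndarray):
    """Outer contours of connected components, largest component first.

    Returns ``(outer, holes)``: closed sub-pixel contours (row, col arrays)
    of each component's filled outline, and of each interior hole.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return [], []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    outer = []
    for lab in order:
        comp = ndimage.binary_fill_holes(labels == lab)
        padded = np.pad(comp.astype(float), 1)
        cs = measure.find_contours(padded, 0.5)
        if cs:
            largest = max(cs, key=len)
            outer.append(largest - 1.0)  # undo padding offset
    filled = ndimage.binary_fill_holes(mask)
    holes_mask = filled & ~mask
    holes = []
    if holes_mask.any():
        hl, hn = ndimage.label(holes_mask, structure=np.ones((3, 3), dtype=int))
        for lab in range(1, hn + 1):
            padded = np.pad((hl == lab).astype(float), 1)
            cs = measure.find_contours(padded, 0.5)
            if cs:
                holes.append(max(cs, key=len) - 1.0)
    return outer, holes


def rosette_center(mask: np.ndarray) -> tuple[float, float]:
    """Rosette centre: mask centroid refined by a circular-symmetry vote.

    Boundary pixels vote along their inward normals (radial accumulation in
    the spirit of a circular Hough transform); the smoothed accumulator
    peak is used when it is decisive, otherwise the plain centroid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no centre")
    cy, cx = ndimage.center_of_mass(mask)

    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    if ys.size < 8:
        return float(cy), float(cx)
    # inward normal approximated by the gradient of the smoothed mask
    smooth = ndimage.gaussian_filter(mask.astype(float), 2.0)
    gy = ndimage.sobel(smooth, axis=0)[ys, xs]
    gx = ndimage.sobel(smooth, axis=1)[ys, xs]
    norm = np.hypot(gy, gx)
    ok = norm > 1e-6
    ys, xs, gy, gx, norm = ys[ok], xs[ok], gy[ok], gx[ok], norm[ok]
    gy, gx = gy / norm, gx / norm

    acc = np.zeros(mask.shape)
    r_max = int(np.hypot(*mask.shape) / 2)
    steps = np.arange(2, r_max, 2)
    for t in steps:
        py = np.round(ys + gy * t).astype(int)
        px = np.round(xs + gx * t).astype(int)
        ok = (py >= 0) & (py < mask.shape[0]) & (px >= 0) & (px < mask.shape[1])
        np.add.at(acc, (py[ok], px[ok]), 1.0)
    acc = ndimage.gaussian_filter(acc, 3.0)
    peak = np.unravel_index(np.argmax(acc), acc.shape)
    # the vote may only *refine* the centroid: accept a decisive peak in the
    # centroid's close neighbourhood, otherwise the centroid stands (leaf
    # side-normals also pile up along each leaf's own axis, so far-away
    # hotspots are artefacts, not the rosette centre)
    if acc[peak] < 4.0 * acc.mean():
        return float(cy), float(cx)
    if np.hypot(peak[0] - cy, peak[1] - cx) > 0.08 * min(mask.shape):
        return float(cy), float(cx)
    return float(peak[0]), float(peak[1])


def _estimate_leaf_length(mask: np.ndarray, center) -> float:
    """Mean leaf length: component major axes, or radial extent for a blob."""
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    if len(props) > 1:
        return float(np.mean([p.axis_major_length for p in props]))
    ys, xs = np.nonzero(mask)
    radius = np.hypot(ys - center[0], xs - center[1]).max()
    edt = ndimage.distance_transform_edt(mask)
    iy, ix = int(round(center[0])), int(round(center[1]))
    core = edt[iy, ix] if mask[iy, ix] else 0.0
    return float(max(8.0, radius - core))


def leaf_markers(mask: np.ndarray, center=None, min_marker_sep: float | None = None,
                 edt_sigma: float = 2.0, angle_merge_deg: float = 5.0,
                 min_peak_edt: float = 4.0):
    """Candidate leaf-centre markers of a rosette mask.

    Two regimes, chosen by the mask topology:

    * several connected components (leaves that do not touch): local maxima
      of the Gaussian-smoothed distance transform, merged when closer than
      ``min_marker_sep`` (default 0.4 x mean leaf length);
    * one fused rosette: blades run separate radial ridges through the
      outer annulus even when their distance fields have merged near the
      apex, so radially aligned annulus ridge maxima become the primary
      markers (global distance maxima only fill unoccupied angular
      sectors), and markers on near-coincident rays (below
      ``angle_merge_deg``) are merged.  A compact mask whose centre is as
      thick as its thickest part (a single blade or disk) keeps a single
      marker.

    Returns ``(marker_label_image, coords)``.
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return markers, np.empty((0, 2), dtype=int)
    if center is None:
        center = rosette_center(mask)
    edt = ndimage.distance_transform_edt(mask)
    sm = ndimage.gaussian_filter(edt, edt_sigma)
    comp_labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if min_marker_sep is None:
        min_marker_sep = 0.4 * _estimate_leaf_length(mask, center) \
            if n_comp > 1 else 4.0
    sep = max(3, int(round(min_marker_sep)))

    iy, ix = int(round(center[0])), int(round(center[1]))
    core_edt = edt[iy, ix] if (0 <= iy < mask.shape[0]
                               and 0 <= ix < mask.shape[1]
                               and mask[iy, ix]) else 0.0
    core_r = 1.3 * core_edt

    coords = peak_local_max(sm, min_distance=4, labels=mask,
                            threshold_abs=min_peak_edt, exclude_border=False)
    if core_r > 0 and coords.size:
        d = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
        kept = coords[d > core_r]
        if kept.size:
            coords = kept
    single_blob = n_comp == 1 and core_edt >= 0.8 * edt.max()
    if n_comp == 1 and not single_blob:
        # In a fused rosette the global distance-transform maxima are
        # unreliable: a wide lump of two blades yields one peak midway
        # between their rays.  Blades, however, still run separate radial
        # ridges through the outer annulus, so aligned annulus ridge maxima
        # (local ridge direction from the EDT Hessian within 37 degrees of
        # the ray; junction webs run tangentially and fail this) become the
        # primary markers, and global peaks only fill angular sectors with
        # no annulus marker nearby.
        yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
        r_pix = np.hypot(yy - center[0], xx - center[1])
        ys, xs = np.nonzero(mask)
        r_max = np.hypot(ys - center[0], xs - center[1]).max()
        # several annulus radii: a wide one cuts deep fusion zones, a
        # narrow one still contains short blades; duplicates collapse in
        # the angular merge below
        found = []
        for frac in (0.45, 0.55, 0.65):
            annulus = mask & (r_pix > frac * r_max)
            if not annulus.any():
                continue
            cands = peak_local_max(sm, min_distance=4,
                                   labels=annulus.astype(np.int32),
                                   threshold_abs=2.5, exclude_border=False)
            found.extend(p for p in cands
                         if _ridge_radial_alignment(sm, p, center) >= 0.8)
        outer = _merge_peaks(np.array(found), sep, np.deg2rad(8.0), sm,
                             comp_labels, center) if found else np.array(found)
        if outer.size:
            def _ang(p):
                return np.arctan2(p[0] - center[0], p[1] - center[1])

            outer_angles = [_ang(p) for p in outer]
            gap = np.deg2rad(10.0)
            fillers = []
            for p in coords:
                a = _ang(p)
                if all(min(abs(a - b), 2 * np.pi - abs(a - b)) >= gap
                       for b in outer_angles):
                    fillers.append(p)
            coords = np.vstack([outer.reshape(-1, 2),
                                np.array(fillers).reshape(-1, 2)]) \
                if fillers else outer.reshape(-1, 2)
    coords = _merge_peaks(coords, sep, np.deg2rad(angle_merge_deg), sm,
                          comp_labels, center)

    # every connected component must carry at least one marker
    covered = set(comp_labels[tuple(coords.T)]) if coords.size else set()
    extra = []
    for lab in range(1, n_comp + 1):
        if lab not in covered:
            comp_edt = np.where(comp_labels == lab, edt, -1.0)
            extra.append(np.unravel_index(np.argmax(comp_edt), mask.shape))
    if extra:
        coords = np.vstack([coords.reshape(-1, 2), np.array(extra)])

    for i, (r, c) in enumerate(coords, start=1):
        markers[int(r), int(c)] = i
    return markers, coords.astype(int)


def _ridge_radial_alignment(sm: np.ndarray, p, center) -> float:
    """|cos| between the local EDT ridge direction and the ray from centre."""
    y, x = int(p[0]), int(p[1])
    if not (1 <= y < sm.shape[0] - 1 and 1 <= x < sm.shape[1] - 1):
        return 0.0
    dyy = sm[y + 1, x] - 2 * sm[y, x] + sm[y - 1, x]
    dxx = sm[y, x + 1] - 2 * sm[y, x] + sm[y, x - 1]
    dxy = (sm[y + 1, x + 1] - sm[y + 1, x - 1]
           - sm[y - 1, x + 1] + sm[y - 1, x - 1]) / 4.0
    w, v = np.linalg.eigh(np.array([[dyy, dxy], [dxy, dxx]]))
    ridge = v[:, int(np.argmax(w))]  # eigenvalue closest to zero
    ray = np.array([y - center[0], x - center[1]])
    n = np.hypot(*ray)
    if n < 1e-9:
        return 0.0
    return float(abs(ridge @ (ray / n)))


def _merge_peaks(coords: np.ndarray, sep: int, angle_tol: float,
                 score: np.ndarray, comp_labels: np.ndarray,
                 center) -> np.ndarray:
    """Greedy merge, strongest peak first."""
    if coords.shape[0] <= 1:
        return coords
    order = np.argsort(-score[tuple(coords.T)])
    kept: list[np.ndarray] = []
    kept_ang: list[float] = []
    kept_comp: list[int] = []
    for idx in order:
        p = coords[idx]
        ang = np.arctan2(p[0] - center[0], p[1] - center[1])
        comp = int(comp_labels[p[0], p[1]])
        dup = False
        for q, qa, qc in zip(kept, kept_ang, kept_comp):
            if np.hypot(*(p - q)) < sep:
                dup = True
                break
            if comp == qc:
                dang = abs(ang - qa)
                if min(dang, 2 * np.pi - dang) < angle_tol:
                    dup = True
                    break
        if not dup:
            kept.append(p)
            kept_ang.append(ang)
            kept_comp.append(comp)
    return np.array(kept)


def count_leaves(mask: np.ndarray, min_marker_sep: float | None = None,
                 edt_sigma: float = 2.0) -> LeafLabelImage:
    """Marker-controlled watershed leaf count of a rosette mask.

    The watershed of the inverted distance transform, seeded at the leaf
    markers and restricted to the mask, yields one region per visible leaf;
    the label support equals the input mask exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return LeafLabelImage(np.zeros(mask.shape, dtype=np.int32), 0)
    center = rosette_center(mask)
    markers, coords = leaf_markers(mask, center=center,
                                   min_marker_sep=min_marker_sep,
                                   edt_sigma=edt_sigma)
    edt = ndimage.distance_transform_edt(mask)
    labels = watershed(-edt, markers=markers, mask=mask)
    ids = np.unique(labels[labels > 0])
    # compact label ids to 1..L
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1)
    return LeafLabelImage(remap[labels], int(ids.size))


class LeafCounter(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: list of masks -> list of :class:`LeafLabelImage`."""

    def __init__(self, min_marker_sep: float | None = None,
                 edt_sigma: float = 2.0):
        self.min_marker_sep = min_marker_sep
        self.edt_sigma = edt_sigma

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[np.ndarray]) -> list[LeafLabelImage]:
        return [count_leaves(m, self.min_marker_sep, self.edt_sigma) for m in X]
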