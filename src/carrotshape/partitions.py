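"""Partitioned nonhomogeneity descriptors and the root count.

The silhouette is cut, in its principal-axis frame, into seven slices of
equal length indexed 1..7 from the thick end.  Two families of features
measure how far the shape departs from an ideal straight, smoothly
tapered root, always relative to the central (4th) slice:

    partial centroid nonhomogeneity  Fc_i = |v_i - v_4|   (i != 4)
    partial width nonhomogeneity     Fb_i = |b_i - b_4|   (i != 4)

where ``v_i`` is slice *i*'s centroid coordinate perpendicular to the
principal axis and ``b_i`` its maximum perpendicular width.  The centroid
offsets respond to curvature (a bent root's slice centroids swing away
from the midline), the width offsets to bulges, forks and blunt breaks.
Totals are normalised by the biggest slice width ``bm = max_i b_i``:

    Fc_t = sum(Fc_i) / bm        Fb_t = sum(Fb_i) / bm

making them scale-free.  Two reading notes: the centroid difference is
taken on the perpendicular coordinate only (the along-axis coordinates
differ by ~length/7 between slices by construction, carrying no shape
information), and absolute values are used so opposite-side offsets do
not cancel in the totals.

The root count ``N`` is the larger number of 8-connected foreground
components found in the two terminal slices: 1 for a single root, 2 or 3
for forked roots whose tips have separated by the end of the silhouette.
Taking the maximum over both ends makes the feature orientation-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import CarrotShapeError, NoObjectError, TooSmallError
from .features import project_onto_axis

__all__ = [
    "PartitionProfile",
    "partition_silhouette",
    "partial_centroid_nonhomogeneity",
    "partial_width_nonhomogeneity",
    "total_nonhomogeneity",
    "count_roots",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PartitionProfile:
    """Per-slice geometry of a silhouette in its principal-axis frame.

    Slices are indexed 0..n_parts-1 internally, ordered from the thick
    end; feature names use 1-based indices.  ``part_v_means`` holds the
    perpendicular centroid coordinate per slice (NaN for an empty slice),
    ``part_widths`` the maximum perpendicular extent per slice (0 for an
    empty slice), ``part_centroids`` absolute (row, col) centroids.
    """

    n_parts: int
    theta: float
    origin: tuple
    u_edges: np.ndarray
    part_v_means: np.ndarray
    part_u_means: np.ndarray
    part_widths: np.ndarray
    part_areas: np.ndarray
    part_centroids: np.ndarray
    part_labels: np.ndarray = field(repr=False)
    pixel_rows: np.ndarray = field(repr=False)
    pixel_cols: np.ndarray = field(repr=False)
    reversed: bool = False

    @property
    def bm(self):
        """Biggest slice width, the normaliser of the total features."""
        return float(self.part_widths.max())

    @property
    def broken(self):
        """True when some slice holds no pixels (a broken silhouette)."""
        return bool((self.part_areas == 0).any())


def partition_silhouette(mask, n_parts=7):
    """Cut a silhouette into equal-length slices along its principal axis.

    Pixel centers are projected onto the principal frame, the axial span
    is divided into ``n_parts`` equal intervals, and every foreground
    pixel is assigned to exactly one slice (so the slice areas tile the
    silhouette area).  Per-slice widths are the maximum perpendicular
    pixel span over unit axial columns.  Slices are renumbered so slice 1
    sits at the thick end, making feature indices orientation-free.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("cannot partition an empty mask")
    u, v, theta, origin = project_onto_axis(mask)
    umin, umax = u.min(), u.max()
    span = umax - umin
    if span + 1 < n_parts:
        raise TooSmallError(
            f"silhouette length {span + 1:.0f} px < {n_parts} parts"
        )

    rel = (u - umin) / span  # in [0, 1]
    labels = np.minimum((rel * n_parts).astype(int), n_parts - 1)
    edges = umin + span * np.arange(n_parts + 1) / n_parts

    cols = np.round(u).astype(int)
    v_means = np.full(n_parts, np.nan)
    u_means = np.full(n_parts, np.nan)
    widths = np.zeros(n_parts)
    areas = np.zeros(n_parts, dtype=int)
    centroids = np.full((n_parts, 2), np.nan)

    rows_img, cols_img = np.nonzero(mask)
    for i in range(n_parts):
        sel = labels == i
        areas[i] = int(sel.sum())
        if areas[i] == 0:
            continue
        v_means[i] = v[sel].mean()
        u_means[i] = u[sel].mean()
        centroids[i] = rows_img[sel].mean(), cols_img[sel].mean()
        # width: max perpendicular span over the slice's unit columns
        vi, ci = v[sel], cols[sel]
        order = np.argsort(ci, kind="stable")
        ci, vi = ci[order], vi[order]
        starts = np.flatnonzero(np.r_[True, np.diff(ci) != 0])
        ends = np.r_[starts[1:], ci.size]
        widths[i] = max(
            float(vi[s:e].max() - vi[s:e].min()) + 1.0
            for s, e in zip(starts, ends)
        )

    if widths.max() <= 0:
        raise NoObjectError("no slice has measurable width")

    # orient thick end first: compare total width mass of the two halves
    half = n_parts // 2
    flipped = widths[-half:].sum() > widths[:half].sum()
    if flipped:
        v_means, u_means = v_means[::-1].copy(), u_means[::-1].copy()
        widths, areas = widths[::-1].copy(), areas[::-1].copy()
        centroids = centroids[::-1].copy()
        labels = n_parts - 1 - labels

    return PartitionProfile(
        n_parts=n_parts,
        theta=theta,
        origin=origin,
        u_edges=edges,
        part_v_means=v_means,
        part_u_means=u_means,
        part_widths=widths,
        part_areas=areas,
        part_centroids=centroids,
        part_labels=labels,
        pixel_rows=rows_img,
        pixel_cols=cols_img,
        reversed=flipped,
    )


def _reference_index(profile):
    mid = profile.n_parts // 2  # 0-based index of the central slice
    return mid


def partial_centroid_nonhomogeneity(profile):
    """Perpendicular centroid offsets |v_i - v_4| of each non-central slice.

    An empty slice (broken root) borrows the centroid of its nearest
    non-empty neighbour, so a gap registers the offset of the surviving
    material next to it rather than poisoning the totals with NaN.
    Returns offsets in slice order, excluding the central slice.
    """
    mid = _reference_index(profile)
    v = profile.part_v_means.copy()
    nonempty = np.flatnonzero(~np.isnan(v))
    if nonempty.size == 0:
        raise NoObjectError("all slices empty")
    for i in np.flatnonzero(np.isnan(v)):
        v[i] = v[nonempty[np.argmin(np.abs(nonempty - i))]]
    ref = v[mid]
    return np.abs(np.delete(v, mid) - ref)


def partial_width_nonhomogeneity(profile):
    """Width offsets |b_i - b_4| of each non-central slice (empty slice
    contributes its literal width of 0)."""
    mid = _reference_index(profile)
    b = profile.part_widths
    return np.abs(np.delete(b, mid) - b[mid])


def total_nonhomogeneity(fc_partials, fb_partials, bm):
    """Totals ``Fc_t`` and ``Fb_t``: partial sums normalised by the
    biggest slice width, giving scale-free nonhomogeneity scores."""
    if bm <= 0:
        raise CarrotShapeError("bm must be positive")
    return float(np.sum(fc_partials) / bm), float(np.sum(fb_partials) / bm)


def count_roots(mask, profile):
    """Number of root tips: the larger 8-connected component count of the
    two terminal slices (>= 1)."""
    mask = np.asarray(mask, dtype=bool)
    best = 1
    for part in (0, profile.n_parts - 1):
        sel = profile.part_labels == part
        if not sel.any():
            continue
        sub = np.zeros_like(mask)
        sub[profile.pixel_rows[sel], profile.pixel_cols[sel]] = True
        _, n = ndi.label(sub, structure=_STRUCT8)
        best = max(best, n)
    return int(best)
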