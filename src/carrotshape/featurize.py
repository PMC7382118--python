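"""Assemble the full per-silhouette feature row and the CSV schema.

One mask in, one named row out: the classical descriptors, the six
centroid and six width nonhomogeneity partials, the raw central-slice
width ``b4``, the two totals, the root count and a broken flag.  The
column order is fixed so feature CSVs from different runs are
byte-comparable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import features as _feat
from . import partitions as _part

__all__ = [
    "FEATURE_COLUMNS",
    "CANDIDATE_FEATURES",
    "extract_features",
    "featurize_masks",
]

_PARTIAL_IDX = (1, 2, 3, 5, 6, 7)

FEATURE_COLUMNS = (
    "length",
    "width",
    "area",
    "perimeter",
    "extent",
    "eccentricity",
    "centroid_row",
    "centroid_col",
    "major_axis",
    "minor_axis",
    "roundness",
    "compactness",
    "elongation",
    *(f"Fc{i}" for i in _PARTIAL_IDX),
    *(f"Fb{i}" for i in _PARTIAL_IDX),
    "b4",
    "Fct",
    "Fbt",
    "N",
    "broken",
)

#: Default classifier inputs: every descriptor except the position of the
#: silhouette in the frame (translation-dependent) and the broken flag
#: (a derived quality marker, not a measurement).
CANDIDATE_FEATURES = tuple(
    c
    for c in FEATURE_COLUMNS
    if c not in ("centroid_row", "centroid_col", "broken")
)


def extract_features(mask, n_parts=7):
    """Compute the complete descriptor row for one cleaned mask.

    Returns a plain dict keyed by :data:`FEATURE_COLUMNS`.  The
    isoperimetric identity ``roundness * compactness == 4*pi`` is
    asserted for every sample as an internal consistency check.
    """
    row = _feat.basic_region_properties(mask)
    assert math.isclose(
        row["roundness"] * row["compactness"], 4.0 * math.pi, rel_tol=1e-12
    )

    profile = _part.partition_silhouette(mask, n_parts=n_parts)
    fc = _part.partial_centroid_nonhomogeneity(profile)
    fb = _part.partial_width_nonhomogeneity(profile)
    fct, fbt = _part.total_nonhomogeneity(fc, fb, profile.bm)

    for idx, val in zip(_PARTIAL_IDX, fc):
        row[f"Fc{idx}"] = float(val)
    for idx, val in zip(_PARTIAL_IDX, fb):
        row[f"Fb{idx}"] = float(val)
    row["b4"] = float(profile.part_widths[profile.n_parts // 2])
    row["Fct"] = fct
    row["Fbt"] = fbt
    row["N"] = _part.count_roots(mask, profile)
    row["broken"] = int(profile.broken)
    return {c: row[c] for c in FEATURE_COLUMNS}


def featurize_masks(masks, n_parts=7, index=None):
    """Featurise a sequence of masks into a DataFrame with the fixed
    column schema."""
    rows = [extract_features(m, n_parts=n_parts) for m in masks]
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    if index is not None:
        df.index = pd.Index(index, name="sample")
    return df
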