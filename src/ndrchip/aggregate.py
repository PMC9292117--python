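"""Anchor-aligned occupancy matrices, averaged profiles and difference maps.

A matrix row is the track signal in a fixed window around one anchor (motif
center, TBP summit, TSS, ...).  Windows running off a chromosome end are
padded with NaN and excluded from column means; zero-filling would bias
averaged occupancies downward at telomere-proximal features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable
from .tracks import OccupancyTrack, moving_average


@dataclass
class OccupancyMatrix:
    """Features x relative-position signal aligned to single-bp anchors."""

    ids: list[str]
    positions: np.ndarray  # -flank .. +flank
    values: np.ndarray  # shape (n_features, 2*flank+1); NaN marks missing
    anchor_kind: str = ""
    source: str = ""
    sort_note: str = "input order"

    def __post_init__(self):
        if self.values.shape != (len(self.ids), self.positions.size):
            raise ValueError("matrix shape does not match ids/positions")

    @property
    def flank(self) -> int:
        return int(self.positions.max())

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.ids.index(feature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.positions)


@dataclass
class AverageProfile:
    """Column-wise mean signal around an anchor with per-position counts."""

    positions: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    meta: dict = field(default_factory=dict)

    def argmax_position(self, lo: int | None = None, hi: int | None = None) -> int:
        """Relative position of the profile maximum, optionally within [lo, hi]."""
        mask = np.ones(self.positions.size, dtype=bool)
        if lo is not None:
            mask &= self.positions >= lo
        if hi is not None:
            mask &= self.positions <= hi
        vals = np.where(mask, self.mean, -np.inf)
        return int(self.positions[np.nanargmax(vals)])


def anchor_matrix(track: OccupancyTrack, anchors: FeatureTable, flank: int,
                  orient_by_strand: bool = False) -> OccupancyMatrix:
    """Extract track values at anchor + p for p in [-flank, +flank] per feature.

    Interval features are anchored at their midpoint (floor tie-break).  When
    ``orient_by_strand`` is set, rows of minus-strand features are reversed so
    that positive positions point downstream of the feature.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    positions = np.arange(-flank, flank + 1)
    values = np.full((len(anchors), positions.size), np.nan)
    ids = []
    for i, feature in enumerate(anchors):
        ids.append(feature.id)
        center = feature.anchor
        chrom_values = track.data[feature.chrom]
        lo = center - flank
        hi = center + flank + 1
        src_lo, src_hi = max(lo, 0), min(hi, chrom_values.size)
        row = np.full(positions.size, np.nan)
        row[src_lo - lo: src_hi - lo] = chrom_values[src_lo:src_hi]
        if orient_by_strand and feature.strand == "-":
            row = row[::-1]
        values[i] = row
    return OccupancyMatrix(ids, positions, values,
                           anchor_kind=anchors.features[0].kind if len(anchors) else "",
                           source=str(track.meta.get("sample", "")))


def average_profile(matrix: OccupancyMatrix) -> AverageProfile:
    """Column-wise mean over non-missing entries; all-missing columns give NaN."""
    if not matrix.ids:
        raise ValueError("cannot average an empty matrix")
    n = np.sum(~np.isnan(matrix.values), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0,
                        np.nansum(matrix.values, axis=0) / np.maximum(n, 1),
                        np.nan)
    return AverageProfile(matrix.positions.copy(), mean, n,
                          {"source": matrix.source, "anchor": matrix.anchor_kind})


def sort_rows(matrix: OccupancyMatrix, key: dict[str, float],
              descending: bool = False) -> OccupancyMatrix:
    """Stable reorder of rows by a per-feature key, ties broken by feature id."""
    missing = [i for i in matrix.ids if i not in key]
    if missing:
        raise KeyError(f"sort key missing for rows: {missing[:5]}")
    order = sorted(range(len(matrix.ids)),
                   key=lambda i: (key[matrix.ids[i]], matrix.ids[i]))
    if descending:
        order = sorted(range(len(matrix.ids)),
                       key=lambda i: (-key[matrix.ids[i]], matrix.ids[i]))
    return OccupancyMatrix(
        [matrix.ids[i] for i in order], matrix.positions.copy(),
        matrix.values[order], matrix.anchor_kind, matrix.source,
        sort_note=f"sorted {'desc' if descending else 'asc'} by key",
    )


def difference_matrix(a: OccupancyMatrix, b: OccupancyMatrix) -> OccupancyMatrix:
    """Cell-wise a - b; requires identical row order and window (no realignment)."""
    if a.ids != b.ids:
        raise ValueError("difference_matrix: row ids/order differ")
    if not np.array_equal(a.positions, b.positions):
        raise ValueError("difference_matrix: windows differ")
    return OccupancyMatrix(list(a.ids), a.positions.copy(), a.values - b.values,
                           a.anchor_kind, f"{a.source} - {b.source}", a.sort_note)


def dyad_profile(dyad_track: OccupancyTrack, anchors: FeatureTable, flank: int,
                 span: int = 31, orient_by_strand: bool = False) -> AverageProfile:
    """Averaged dyad density around anchors, then moving-average smoothed.

    The order is fixed: average across features first, then smooth the mean
    profile with the given span (odd).
    """
    if span % 2 == 0:
        raise ValueError("smoothing span must be odd")
    if not dyad_track.has("dyad_normalized"):
        raise ValueError("dyad_profile expects a normalized dyad-density track")
    profile = average_profile(anchor_matrix(dyad_track, anchors, flank,
                                            orient_by_strand))
    profile.meta["smoothing_span"] = span
    profile.mean = moving_average(profile.mean, span)
    return profile


def profile_to_frame(profile: AverageProfile) -> pd.DataFrame:
    return pd.DataFrame({"position": profile.positions, "mean": profile.mean,
                         "n": profile.n})
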