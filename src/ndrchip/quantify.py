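"""Window quantification, fold-change rankings and set partitions.

Occupancy per nucleotide over a window is the mean of the per-bp normalized
track values in that window (a peak interval, anchor +- flank, or a CDS).
Feature sets are built from rankings of fold changes or occupancies:
outer-quartile sets (first / middle-two / fourth quartiles, sizes
ceil(n/4) / remainder / ceil(n/4), giving 30/57/30 at n = 117), decile bins,
and two "equal" halves (first ceil(n/2) ranked items labelled High).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Feature, FeatureTable
from .tracks import OccupancyTrack

log = logging.getLogger("ndrchip")


# ---------------------------------------------------------------------------
# Window occupancy
# ---------------------------------------------------------------------------


def window_occupancy(track: OccupancyTrack, chrom: str, start: int, end: int) -> float:
    """Mean per-bp track value over [start, end), truncated to the chromosome."""
    if start >= end:
        raise ValueError("zero-length window")
    lo = max(start, 0)
    hi = min(end, track.layout.length(chrom))
    if lo >= hi:
        raise ValueError("window lies entirely off the chromosome")
    return float(track.data[chrom][lo:hi].mean())


def feature_window(feature: Feature, flank: int | None = None) -> tuple[str, int, int]:
    """Quantification window for a feature: its own interval, or anchor +- flank."""
    if flank is None:
        return feature.chrom, feature.start, feature.end
    a = feature.anchor
    return feature.chrom, a - flank, a + flank + 1


def occupancy_table(tracks: dict[str, OccupancyTrack], features: FeatureTable,
                    flank: int | None = None) -> pd.DataFrame:
    """One row per feature, one column per sample of window occupancies.

    ``flank=None`` quantifies over each feature's own interval (peak
    coordinates, CDS); an integer quantifies anchor +- flank windows.
    Feature attributes (e.g. fimo_score) are carried into the table.
    """
    rows = {}
    for feature in features:
        chrom, start, end = feature_window(feature, flank)
        rows[feature.id] = {
            sample: window_occupancy(track, chrom, start, end)
            for sample, track in tracks.items()
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature"
    for feature in features:
        for key, value in feature.attributes.items():
            table.loc[feature.id, key] = value
    return table


# ---------------------------------------------------------------------------
# log2 columns and fold-change ranking
# ---------------------------------------------------------------------------


def default_pseudocount(table: pd.DataFrame, columns: list[str]) -> float:
    """Half the smallest positive occupancy across the given columns."""
    values = table[columns].to_numpy(dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("no positive occupancies; cannot derive a pseudocount")
    return float(positive.min() / 2.0)


def log2_table(table: pd.DataFrame, columns: list[str],
               pseudocount: float | None = None) -> pd.DataFrame:
    """Append log2(occupancy + pseudocount) columns named ``log2_<col>``."""
    if pseudocount is None:
        pseudocount = default_pseudocount(table, columns)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = table.copy()
    for col in columns:
        if (out[col] < 0).any():
            raise ValueError(f"negative occupancy in uncorrected column {col!r}")
        out[f"log2_{col}"] = np.log2(out[col] + pseudocount)
    out.attrs["pseudocount"] = pseudocount
    return out


def fold_change_ranking(table: pd.DataFrame, mutant: str, wt: str,
                        pseudocount: float | None = None) -> pd.DataFrame:
    """Features ordered by ascending (mutant + pc) / (wt + pc) occupancy ratio.

    The most strongly reduced features rank first.  Rows with missing values
    are excluded with a log entry; ratio ties are broken by feature id.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(table, [mutant, wt])
    sub = table[[mutant, wt]].copy()
    missing = sub.index[sub.isna().any(axis=1)]
    if len(missing):
        log.info("fold_change_ranking: excluded %d features with missing values",
                 len(missing))
        sub = sub.drop(index=missing)
    ratio = (sub[mutant] + pseudocount) / (sub[wt] + pseudocount)
    out = sub.assign(ratio=ratio, log2_ratio=np.log2(ratio))
    order = sorted(out.index, key=lambda i: (out.at[i, "ratio"], i))
    out = out.loc[order]
    out.attrs["pseudocount"] = pseudocount
    return out


# ---------------------------------------------------------------------------
# Set partitions
# ---------------------------------------------------------------------------


@dataclass
class SetPartition:
    """Exact partition of ranked feature ids into labelled, ordered bins."""

    scheme: str
    labels: dict[str, str]  # feature id -> label
    order: list[str] = field(default_factory=list)  # label order
    ranking: str = ""

    def members(self, label: str) -> list[str]:
        return [i for i, l in self.labels.items() if l == label]

    def sizes(self) -> dict[str, int]:
        return {label: len(self.members(label)) for label in self.order}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": list(self.labels), "label": list(self.labels.values())})


def _check_partition(ids: list[str]) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError("ranked ids contain duplicates")


def quartile_sets(ranked_ids: list[str], prefix: str = "Set_") -> SetPartition:
    """First / middle-two / fourth quartile sets of a ranked list.

    Outer sets take ceil(n/4) items each, the middle set the remainder;
    n = 117 gives sizes 30 / 57 / 30.
    """
    _check_partition(ranked_ids)
    n = len(ranked_ids)
    if n < 4:
        raise ValueError("need at least 4 items for quartile sets")
    q = math.ceil(n / 4)
    labels = {}
    for i, fid in enumerate(ranked_ids):
        if i < q:
            labels[fid] = f"{prefix}1"
        elif i >= n - q:
            labels[fid] = f"{prefix}3"
        else:
            labels[fid] = f"{prefix}2"
    return SetPartition("quartile_135", labels,
                        [f"{prefix}1", f"{prefix}2", f"{prefix}3"])


def decile_bins(ranked_ids: list[str], k: int = 10) -> SetPartition:
    """Contiguous rank bins with sizes differing by at most one (larger first)."""
    _check_partition(ranked_ids)
    n = len(ranked_ids)
    if k > n:
        raise ValueError("more bins than items")
    base, extra = divmod(n, k)
    labels, order = {}, []
    pos = 0
    for b in range(k):
        size = base + (1 if b < extra else 0)
        label = f"Decile_{b + 1}"
        order.append(label)
        for fid in ranked_ids[pos:pos + size]:
            labels[fid] = label
        pos += size
    return SetPartition("deciles", labels, order)


def half_bins(ranked_ids: list[str], high_label: str = "High",
              low_label: str = "Low") -> SetPartition:
    """Two near-equal bins: the first ceil(n/2) ranked items are High."""
    _check_partition(ranked_ids)
    n = len(ranked_ids)
    if n < 2:
        raise ValueError("need at least 2 items for half bins")
    h = math.ceil(n / 2)
    labels = {fid: (high_label if i < h else low_label)
              for i, fid in enumerate(ranked_ids)}
    return SetPartition("halves", labels, [high_label, low_label])


# ---------------------------------------------------------------------------
# Peak-to-gene assignment
# ---------------------------------------------------------------------------


def assign_peaks_to_genes(summits: FeatureTable, tss: FeatureTable,
                          max_distance: int | None = 500) -> pd.DataFrame:
    """For each gene TSS, the nearest summit anchor on the same chromosome.

    Equidistant summits tie-break to the lower coordinate.  Assignments
    farther than ``max_distance`` (bp, None disables the cutoff) are reported
    with ``assigned=False``; genes with no same-chromosome summit are listed
    unassigned with NaN distance.
    """
    if len(summits) == 0 or len(tss) == 0:
        raise ValueError("assign_peaks_to_genes needs non-empty tables")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for s in summits:
        by_chrom.setdefault(s.chrom, []).append((s.anchor, s.id))
    for entries in by_chrom.values():
        entries.sort()
    rows = []
    for gene in tss:
        candidates = by_chrom.get(gene.chrom, [])
        if not candidates:
            rows.append({"gene": gene.id, "summit": None, "distance": np.nan,
                         "assigned": False})
            continue
        anchor = gene.anchor
        best = min(candidates, key=lambda c: (abs(c[0] - anchor), c[0]))
        distance = abs(best[0] - anchor)
        assigned = max_distance is None or distance <= max_distance
        rows.append({"gene": gene.id, "summit": best[1],
                     "distance": float(distance), "assigned": assigned})
    out = pd.DataFrame(rows).set_index("gene")
    n_discarded = int((~out["assigned"]).sum())
    if n_discarded:
        log.info("assign_peaks_to_genes: %d assignments beyond the distance cutoff",
                 n_discarded)
    return out
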