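"""Per-bp occupancy and dyad-density tracks.

The processing chain mirrors standard ChIP-seq practice for small genomes:
fragment coverage (a fragment contributes 1 to every bp it overlaps), division
by the per-chromosome mean so the average occupancy per nucleotide on each
chromosome equals one, arithmetic merging of normalized replicates,
subtraction of an untagged-strain background for epitope-tagged samples, and
zeroing of masked intervals (tDNA neighbourhoods) before downstream window
sums.  Dyad-density tracks place a unit count at the midpoint of each
nucleosome-size MNase fragment (125-175 bp by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, FragmentSet, GenomeLayout

NORMALIZATION_TOL = 1e-9


@dataclass
class OccupancyTrack:
    """Per-bp signal for every chromosome of one genome layout.

    ``states`` records the processing history as a set of flags
    (``raw_coverage``, ``dyad_raw``, ``normalized``, ``dyad_normalized``,
    ``merged``, ``corrected``, ``smoothed``, ``masked``, ``difference``).
    """

    layout: GenomeLayout
    data: dict[str, np.ndarray]
    states: frozenset[str] = frozenset()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, length in zip(self.layout.names, self.layout.lengths):
            if name not in self.data:
                raise ValueError(f"track missing chromosome {name!r}")
            if self.data[name].size != length:
                raise ValueError(f"track length mismatch on {name!r}")

    def has(self, *flags: str) -> bool:
        return all(f in self.states for f in flags)

    def with_state(self, *flags: str, **meta) -> "OccupancyTrack":
        return OccupancyTrack(self.layout, self.data, self.states | set(flags),
                              {**self.meta, **meta})

    def copy_data(self) -> dict[str, np.ndarray]:
        return {name: values.copy() for name, values in self.data.items()}

    @property
    def mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chromosome_means(self) -> dict[str, float]:
        return {name: float(v.mean()) for name, v in self.data.items()}

    def values_at(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[chrom][start:end]


@dataclass(frozen=True)
class DyadParams:
    """Fragment-length window and smoothing span for dyad-density estimation."""

    min_length: int = 125
    max_length: int = 175
    smoothing_span: int = 31

    def __post_init__(self):
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        if self.smoothing_span < 1 or self.smoothing_span % 2 == 0:
            raise ValueError("smoothing span must be odd and >= 1")


def compute_coverage(fragments: FragmentSet) -> OccupancyTrack:
    """Count, at every bp, the number of fragments overlapping it.

    Total track mass equals the sum of fragment lengths exactly.
    """
    if len(fragments) == 0:
        raise ValueError("cannot compute coverage of an empty fragment set")
    layout = fragments.layout
    data = {}
    for name, starts, ends in fragments.per_chromosome():
        length = layout.length(name)
        delta = np.zeros(length + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        data[name] = np.cumsum(delta[:-1])
    return OccupancyTrack(
        layout, data, frozenset({"raw_coverage"}),
        {"sample": fragments.meta.key, "n_fragments": len(fragments)},
    )


def compute_dyad_density(fragments: FragmentSet,
                         params: DyadParams = DyadParams()) -> OccupancyTrack:
    """Place a unit count at the midpoint of every nucleosome-size fragment.

    Fragments outside [min_length, max_length] contribute nothing; the even
    midpoint tie-break is floor((start+end)/2) in 0-based coordinates.
    """
    if fragments.meta.prep != "mnase":
        warnings.warn("dyad density computed from a non-MNase fragment set",
                      stacklevel=2)
    layout = fragments.layout
    data = {}
    n_kept = 0
    for name, starts, ends in fragments.per_chromosome():
        lengths = ends - starts
        keep = (lengths >= params.min_length) & (lengths <= params.max_length)
        mids = (starts[keep] + ends[keep]) // 2
        n_kept += int(keep.sum())
        data[name] = np.bincount(mids, minlength=layout.length(name)).astype(float)
    return OccupancyTrack(
        layout, data, frozenset({"dyad_raw"}),
        {"sample": fragments.meta.key, "n_dyads": n_kept,
         "dyad_range": (params.min_length, params.max_length)},
    )


def normalize_per_chromosome(track: OccupancyTrack) -> OccupancyTrack:
    """Divide each chromosome by its mean so the per-chromosome mean is one.

    Chromosomes with zero total signal are left at zero with a warning (the
    mean is undefined there).  Applying the operation twice is the identity.
    """
    if not (track.has("raw_coverage") or track.has("dyad_raw")
            or track.has("normalized") or track.has("dyad_normalized")):
        raise ValueError("normalize_per_chromosome expects a raw or normalized track")
    data = {}
    for name, values in track.data.items():
        mean = values.mean()
        if mean == 0.0:
            warnings.warn(f"chromosome {name!r} has zero signal; left unnormalized",
                          stacklevel=2)
            data[name] = values.copy()
        else:
            data[name] = values / mean
    flag = "dyad_normalized" if ("dyad_raw" in track.states
                                 or "dyad_normalized" in track.states) else "normalized"
    return OccupancyTrack(track.layout, data, track.states | {flag, "normalized"},
                          dict(track.meta))


def moving_average(signal: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    At positions closer than span//2 to an edge the mean is taken over the
    available positions only, so a constant signal is returned unchanged.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    signal = np.asarray(signal, dtype=float)
    kernel = np.ones(span)
    sums = np.convolve(signal, kernel, mode="same")
    counts = np.convolve(np.ones(signal.size), kernel, mode="same")
    return sums / counts


def smooth_track(track: OccupancyTrack, span: int) -> OccupancyTrack:
    data = {name: moving_average(values, span) for name, values in track.data.items()}
    return OccupancyTrack(track.layout, data, track.states | {"smoothed"},
                          {**track.meta, "smoothing_span": span})


def merge_replicates(tracks: list[OccupancyTrack]) -> OccupancyTrack:
    """Per-bp arithmetic mean of normalized replicate tracks.

    Merging normalized tracks (rather than pooling reads) gives each replicate
    equal weight regardless of sequencing depth.
    """
    if not tracks:
        raise ValueError("merge_replicates needs at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.layout != first.layout:
            raise ValueError("replicate tracks have mismatched layouts")
        if t.states != first.states:
            raise ValueError("replicate tracks have mismatched states")
    if not first.has("normalized"):
        raise ValueError("replicates must be normalized before merging")
    data = {
        name: np.mean([t.data[name] for t in tracks], axis=0)
        for name in first.layout.names
    }
    replicates = [t.meta.get("sample", "?") for t in tracks]
    return OccupancyTrack(first.layout, data, first.states | {"merged"},
                          {**first.meta, "replicates": replicates})


def correct_background(tagged: OccupancyTrack,
                       untagged: OccupancyTrack) -> OccupancyTrack:
    """Subtract the normalized untagged-strain signal from a tagged sample.

    Negative corrected occupancies are retained (difference maps are signed).
    """
    if tagged.layout != untagged.layout:
        raise ValueError("layout mismatch between tagged and untagged tracks")
    if not (tagged.has("normalized") and untagged.has("normalized")):
        raise ValueError("both tracks must be normalized before correction")
    data = {name: tagged.data[name] - untagged.data[name]
            for name in tagged.layout.names}
    return OccupancyTrack(
        tagged.layout, data, tagged.states | {"corrected"},
        {**tagged.meta, "background": untagged.meta.get("sample", "untagged")},
    )


def mask_intervals(track: OccupancyTrack, intervals: FeatureTable) -> OccupancyTrack:
    """Zero the track inside every listed interval (e.g. tDNA neighbourhoods)."""
    data = track.copy_data()
    for feature in intervals:
        data[feature.chrom][feature.start:feature.end] = 0.0
    return OccupancyTrack(track.layout, data, track.states | {"masked"},
                          {**track.meta, "n_masked_intervals": len(intervals)})


def difference_track(a: OccupancyTrack, b: OccupancyTrack) -> OccupancyTrack:
    """Per-bp a - b (mutant minus WT convention for difference maps)."""
    if a.layout != b.layout:
        raise ValueError("layout mismatch in difference_track")
    data = {name: a.data[name] - b.data[name] for name in a.layout.names}
    return OccupancyTrack(
        a.layout, data, (a.states & b.states) | {"difference"},
        {"minuend": a.meta.get("sample"), "subtrahend": b.meta.get("sample")},
    )
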