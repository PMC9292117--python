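"""Genomic input/output: chromosome layouts, fragment sets, feature tables, tracks.

All coordinates are 0-based half-open (BED convention) throughout the package.
Loaders are gzip-transparent: any path ending in ``.gz`` is decompressed on the
fly.  Annotation inputs (chrom.sizes, feature TSVs) are curated files, so any
inconsistency there is a hard error; fragment files are bulk evidence, so
fragments falling outside the genome layout are counted and dropped instead.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger("ndrchip")

#: Feature kinds with defined downstream semantics.  Unknown kinds are kept as
#: free-form labels (with a warning) so that extra annotation rows round-trip.
KNOWN_FEATURE_KINDS = frozenset(
    {
        "gcn4_peak_5prime",
        "gcn4_peak_orf",
        "gcn4_motif",
        "tbp_summit",
        "tss",
        "cds",
        "tdna_flank",
        "rpg",
    }
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ParseError("duplicate chromosome names in layout")
        if any(n <= 0 for n in self.lengths):
            raise ParseError("chromosome lengths must be >= 1")
        if len(self.names) != len(self.lengths):
            raise ParseError("names/lengths size mismatch")

    @property
    def total_size(self) -> int:
        return int(sum(self.lengths))

    def length(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))


def read_genome_layout(path) -> GenomeLayout:
    """Read a two-column (name, length) chrom.sizes file, order preserved."""
    names, lengths = [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: length not an integer") from exc
            if length <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive length for {name!r}")
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            names.append(name)
            lengths.append(length)
    if not names:
        raise ParseError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(names), tuple(lengths))


def write_genome_layout(layout: GenomeLayout, path) -> None:
    with _open_text(path, "wt") as fh:
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity: strain x condition x antibody target x prep x replicate."""

    strain: str = "WT"
    condition: str = "I"
    target: str = "Gcn4"
    prep: str = "sonicated"
    replicate: str = "rep1"

    def __post_init__(self):
        for f in ("strain", "condition", "target", "prep", "replicate"):
            if not getattr(self, f):
                raise ValueError(f"sample metadata field {f!r} must be non-empty")

    @property
    def key(self) -> str:
        return f"{self.target}:{self.strain}_{self.condition}:{self.prep}:{self.replicate}"


@dataclass
class FragmentSet:
    """Sample-tagged genomic fragment intervals (the raw ChIP evidence).

    Fragments are stored as parallel arrays for speed; every fragment is valid
    against ``layout`` (construct through :func:`make_fragment_set` to get
    validation and an exclusion count).
    """

    layout: GenomeLayout
    chrom: np.ndarray  # unicode array
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    meta: SampleMeta = field(default_factory=SampleMeta)
    n_excluded: int = 0

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def per_chromosome(self):
        """Yield (chrom_name, starts, ends) for each layout chromosome."""
        for name in self.layout.names:
            mask = self.chrom == name
            yield name, self.start[mask], self.end[mask]

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return replace(
            self, chrom=self.chrom[mask], start=self.start[mask], end=self.end[mask]
        )


def make_fragment_set(layout, chrom, start, end, meta=None) -> FragmentSet:
    """Validate raw arrays against a layout, dropping (and counting) invalid rows."""
    chrom = np.asarray(chrom, dtype="U32")
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    if not (chrom.size == start.size == end.size):
        raise ValueError("chrom/start/end arrays differ in size")
    lengths = layout.as_dict()
    chrom_len = np.array([lengths.get(c, -1) for c in chrom], dtype=np.int64)
    ok = (chrom_len >= 0) & (start >= 0) & (start < end) & (end <= chrom_len)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("excluded %d fragments outside the genome layout", n_excluded)
    return FragmentSet(
        layout=layout,
        chrom=chrom[ok],
        start=start[ok],
        end=end[ok],
        meta=meta or SampleMeta(),
        n_excluded=n_excluded,
    )


def read_fragments(path, layout: GenomeLayout, meta: SampleMeta | None = None,
                   dialect: str = "auto") -> FragmentSet:
    """Read fragment intervals from BED3 or BEDPE.

    BEDPE mates are joined as min(starts)..max(ends); records whose mates map
    to different chromosomes are skipped and logged.  ``dialect`` may be
    ``auto`` (sniffed from column count), ``bed`` or ``bedpe``.
    """
    if dialect not in ("auto", "bed", "bedpe"):
        raise ValueError(f"unknown fragment dialect {dialect!r}")
    chroms, starts, ends = [], [], []
    n_mate_mismatch = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            kind = dialect
            if kind == "auto":
                kind = "bedpe" if len(parts) >= 6 else "bed"
            try:
                if kind == "bedpe":
                    if len(parts) < 6:
                        raise ValueError("BEDPE needs 6 columns")
                    c1, s1, e1, c2, s2, e2 = parts[:6]
                    if c1 != c2:
                        n_mate_mismatch += 1
                        continue
                    chroms.append(c1)
                    starts.append(min(int(s1), int(s2)))
                    ends.append(max(int(e1), int(e2)))
                else:
                    c, s, e = parts[:3]
                    chroms.append(c)
                    starts.append(int(s))
                    ends.append(int(e))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed fragment line") from exc
    if n_mate_mismatch:
        log.info("skipped %d BEDPE records with mates on different chromosomes",
                 n_mate_mismatch)
    return make_fragment_set(layout, chroms, starts, ends, meta)


def write_fragments(fragments: FragmentSet, path, dialect: str = "bed") -> None:
    """Write a fragment set as BED3 or (degenerate single-span mate) BEDPE."""
    with _open_text(path, "wt") as fh:
        if dialect == "bed":
            for c, s, e in zip(fragments.chrom, fragments.start, fragments.end):
                fh.write(f"{c}\t{s}\t{e}\n")
        elif dialect == "bedpe":
            for c, s, e in zip(fragments.chrom, fragments.start, fragments.end):
                mid = (s + e) // 2
                fh.write(f"{c}\t{s}\t{mid}\t{c}\t{mid}\t{e}\n")
        else:
            raise ValueError(f"unknown fragment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """A typed genomic feature (peak, motif anchor, summit, TSS, CDS, ...)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "region"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ParseError(f"feature {self.id!r}: invalid interval "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ParseError(f"feature {self.id!r}: bad strand {self.strand!r}")

    @property
    def anchor(self) -> int:
        """Single-bp anchor: the position itself for 1-bp features, else the
        interval midpoint with a floor tie-break."""
        return self.start if self.end == self.start + 1 else (self.start + self.end) // 2


@dataclass
class FeatureTable:
    """Ordered collection of features validated against one genome layout."""

    layout: GenomeLayout
    features: list[Feature]
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for f in self.features:
            if f.id in seen:
                raise ParseError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
            if f.chrom not in self.layout:
                raise ParseError(f"feature {f.id!r}: unknown chromosome {f.chrom!r}")
            if f.end > self.layout.length(f.chrom):
                raise ParseError(f"feature {f.id!r}: interval off chromosome")

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_kind(self, *kinds: str) -> "FeatureTable":
        sub = [f for f in self.features if f.kind in kinds]
        return FeatureTable(self.layout, sub, provenance=self.provenance)

    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"bad attribute token {item!r}")
        key, val = item.split("=", 1)
        try:
            attrs[key] = float(val)
        except ValueError:
            attrs[key] = val
    return attrs


def read_features(path, layout: GenomeLayout, coordinate_base: int = 0) -> FeatureTable:
    """Read a BED6-like feature TSV: chrom, start, end, id, kind, strand[, attrs].

    ``coordinate_base`` accepts 1 for annotation files using 1-based inclusive
    starts (converted to the internal 0-based half-open convention); the
    default is 0-based half-open.
    """
    if coordinate_base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")
    feats = []
    unknown_kinds = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, start, end, fid, kind, strand = parts[:6]
            attrs = _parse_attributes(parts[6]) if len(parts) > 6 else {}
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if coordinate_base == 1:
                start_i -= 1
            if kind not in KNOWN_FEATURE_KINDS:
                unknown_kinds.add(kind)
            try:
                feats.append(Feature(fid, chrom, start_i, end_i, strand, kind, attrs))
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if unknown_kinds:
        warnings.warn(f"unknown feature kinds kept as labels: {sorted(unknown_kinds)}",
                      stacklevel=2)
    return FeatureTable(layout, feats, provenance=str(path))


def write_features(table: FeatureTable, path) -> None:
    with _open_text(path, "wt") as fh:
        for f in table:
            attrs = ";".join(
                f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                for k, v in sorted(f.attributes.items())
            )
            row = [f.chrom, str(f.start), str(f.end), f.id, f.kind, f.strand]
            if attrs:
                row.append(attrs)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph track I/O (run-length encoded, lossless for per-bp values)
# ---------------------------------------------------------------------------


def write_track(track, path) -> None:
    """Write an occupancy track as run-length-encoded bedGraph.

    The track must be finite-valued; the write -> read round trip reproduces
    the per-bp arrays exactly (values are serialised with full precision).
    """
    with _open_text(path, "wt") as fh:
        for name in track.layout.names:
            values = track.data[name]
            if not np.all(np.isfinite(values)):
                raise ValueError(f"track contains non-finite values on {name}")
            # run-length boundaries
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{float(values[s])!r}\n")


def read_track(path, layout: GenomeLayout):
    """Read a bedGraph file back into an OccupancyTrack (state ``loaded``)."""
    from .tracks import OccupancyTrack  # local import to avoid a cycle

    data = {name: np.zeros(length) for name, length in zip(layout.names, layout.lengths)}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            name, s, e, v = parts[:4]
            if name not in data:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {name!r}")
            data[name][int(s):int(e)] = float(v)
    return OccupancyTrack(layout=layout, data=data, states=frozenset({"loaded"}))
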