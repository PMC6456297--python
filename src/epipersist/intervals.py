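"""Genomic coordinate backbone: layouts, fixed-width tilings, features.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based formats are converted at the reader boundary.  Strand is
ignored: every analysis downstream operates on unstranded tiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class BedParseError(ValueError):
    """Raised for malformed BED / layout records; carries the line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in number")
        if any(length < 1 for length in self.lengths):
            raise ValueError("chromosome lengths must be >= 1")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(int(v) for v in lengths.values()))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeLayout":
        names: list[str] = []
        lengths: list[int] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"line {lineno}: expected 2 columns (name, length)")
            names.append(parts[0])
            lengths.append(int(parts[1]))
        return cls(tuple(names), tuple(lengths))

    def write_tsv(self, path: str | Path) -> None:
        from . import __version__

        with open(path, "w") as fh:
            fh.write(f"# epipersist v{__version__} chromosome layout\n")
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeTiling:
    """Dense, ordered, non-overlapping fixed-width tiles over a layout.

    Tiles are numbered 0..T-1 in layout order; the last tile of each
    chromosome may be shorter than ``width`` (it is kept, not dropped).
    Tiles are represented arithmetically, never materialised one by one.
    """

    layout: GenomeLayout
    width: int
    # number of tiles per chromosome and cumulative offsets, derived
    _per_chrom: tuple[int, ...] = field(init=False, repr=False)
    _offsets: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("tile width must be >= 1")
        per = tuple(-(-length // self.width) for length in self.layout.lengths)
        object.__setattr__(self, "_per_chrom", per)
        object.__setattr__(self, "_offsets", tuple(np.concatenate([[0], np.cumsum(per)]).tolist()))

    @property
    def n_tiles(self) -> int:
        return self._offsets[-1]

    def tiles_on(self, chrom: str) -> range:
        i = self.layout.names.index(chrom)
        return range(self._offsets[i], self._offsets[i + 1])

    def tile_id(self, chrom: str, pos: int) -> int:
        """Tile containing base ``pos`` (0-based) on ``chrom``."""
        i = self.layout.names.index(chrom)
        if not 0 <= pos < self.layout.lengths[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[i] + pos // self.width

    def tile_interval(self, tile_id: int) -> Interval:
        chrom_idx = int(np.searchsorted(self._offsets, tile_id, side="right")) - 1
        if not 0 <= tile_id < self.n_tiles:
            raise IndexError(f"tile id {tile_id} out of range")
        local = tile_id - self._offsets[chrom_idx]
        chrom = self.layout.names[chrom_idx]
        start = local * self.width
        end = min(start + self.width, self.layout.lengths[chrom_idx])
        return Interval(chrom, start, end)

    def to_frame(self, tile_ids: Sequence[int] | None = None) -> pd.DataFrame:
        """Tiles as a (tile_id, chrom, start, end) DataFrame."""
        ids = np.arange(self.n_tiles) if tile_ids is None else np.asarray(tile_ids, dtype=int)
        offsets = np.asarray(self._offsets)
        chrom_idx = np.searchsorted(offsets, ids, side="right") - 1
        local = ids - offsets[chrom_idx]
        start = local * self.width
        lengths = np.asarray(self.layout.lengths)
        end = np.minimum(start + self.width, lengths[chrom_idx])
        chroms = np.asarray(self.layout.names, dtype=object)[chrom_idx]
        return pd.DataFrame({"tile_id": ids, "chrom": chroms, "start": start, "end": end})

    def chrom_of(self, tile_ids: np.ndarray) -> np.ndarray:
        """Chromosome index per tile id (vectorised)."""
        return np.searchsorted(np.asarray(self._offsets), tile_ids, side="right") - 1


def make_tiling(layout: GenomeLayout, width: int) -> GenomeTiling:
    """Partition every chromosome into fixed-width tiles.

    The tile count per chromosome is ceil(length / width); the final tile
    carries the remainder so the tiling covers every base exactly once.
    """
    return GenomeTiling(layout, int(width))


@dataclass
class FeatureSet:
    """A labelled, sorted collection of intervals (TSS, enhancers, ...).

    Intervals may overlap one another.  Stored as a DataFrame with columns
    (chrom, start, end, name), sorted by (chrom, start).
    """

    label: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"feature frame needs columns {sorted(required)}")
        if "name" not in self.frame.columns:
            self.frame = self.frame.assign(name=".")
        self.frame = (
            self.frame.loc[:, ["chrom", "start", "end", "name"]]
            .sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_intervals(cls, label: str, intervals: Iterable[Interval]) -> "FeatureSet":
        rows = [(iv.chrom, iv.start, iv.end, iv.name or ".") for iv in intervals]
        return cls(label, pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end), None if r.name == "." else r.name)
            for r in self.frame.itertuples()
        ]

    def on(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]


def read_bed(path: str | Path, layout: GenomeLayout | None = None, label: str | None = None) -> FeatureSet:
    """Read a BED3/BED4 file (0-based half-open) into a sorted FeatureSet.

    Malformed records (start >= end, negative coordinates, chromosomes not
    in ``layout`` when one is given) raise :class:`BedParseError` naming the
    offending line.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedParseError(f"{path.name} line {lineno}: fewer than 3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise BedParseError(f"{path.name} line {lineno}: non-integer coordinates") from None
        if start < 0:
            raise BedParseError(f"{path.name} line {lineno}: negative coordinate {start}")
        if start >= end:
            raise BedParseError(f"{path.name} line {lineno}: start {start} >= end {end}")
        if layout is not None:
            if chrom not in layout:
                raise BedParseError(f"{path.name} line {lineno}: unknown chromosome {chrom!r}")
            if end > layout.length(chrom):
                raise BedParseError(f"{path.name} line {lineno}: end {end} beyond {chrom}")
        name = parts[3] if len(parts) > 3 and parts[3] else "."
        rows.append((chrom, start, end, name))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return FeatureSet(label or path.stem, frame)


def write_bed(features: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet as sorted BED4 with a version header comment."""
    from . import __version__

    buf = io.StringIO()
    buf.write(f"# epipersist v{__version__} features: {features.label}\n")
    for r in features.frame.itertuples():
        buf.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
    Path(path).write_text(buf.getvalue())


NO_NEIGHBOR = -1
"""Sentinel distance for queries with no feature on their chromosome."""


def _chrom_arrays(features: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in features.frame.groupby("chrom", sort=False):
        out[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def nearest_distance(query: Interval, features: FeatureSet) -> int:
    """Distance in bp from ``query`` to the nearest feature.

    0 when the query overlaps any feature; otherwise the smallest absolute
    distance from the query midpoint to a feature edge (start or end) on the
    same chromosome.  Returns :data:`NO_NEIGHBOR` (−1) when no feature lies
    on the query's chromosome — never silently 0.
    """
    sub = features.on(query.chrom)
    if sub.empty:
        return NO_NEIGHBOR
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if np.any((starts < query.end) & (ends > query.start)):
        return 0
    mid = query.midpoint
    return int(np.minimum(np.abs(starts - mid), np.abs(ends - mid)).min())


def nearest_distances(queries: pd.DataFrame, features: FeatureSet) -> np.ndarray:
    """Vectorised :func:`nearest_distance` for a (chrom, start, end) frame.

    Returns an int array aligned with ``queries`` rows; entries are
    :data:`NO_NEIGHBOR` where the chromosome carries no feature.
    """
    out = np.full(len(queries), NO_NEIGHBOR, dtype=np.int64)
    per_chrom = _chrom_arrays(features)
    qstart = queries["start"].to_numpy()
    qend = queries["end"].to_numpy()
    mids = (qstart + qend) // 2
    for chrom, idx in queries.groupby("chrom", sort=False).indices.items():
        if chrom not in per_chrom:
            continue
        starts, ends = per_chrom[chrom]
        order = np.argsort(starts, kind="mergesort")
        starts_s, ends_s = starts[order], ends[order]
        cummax_end = np.maximum.accumulate(ends_s)
        # edge distances from midpoints (both start and end edges)
        edges = np.sort(np.concatenate([starts, ends]))
        m = mids[idx]
        pos = np.searchsorted(edges, m)
        left = np.where(pos > 0, np.abs(m - edges[np.maximum(pos - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(pos < len(edges), np.abs(edges[np.minimum(pos, len(edges) - 1)] - m), np.iinfo(np.int64).max)
        dist = np.minimum(left, right)
        # overlap check: any feature with start < qend and end > qstart
        j = np.searchsorted(starts_s, qend[idx], side="left")  # features with start < qend
        overlap = (j > 0) & (cummax_end[np.maximum(j - 1, 0)] > qstart[idx])
        out[idx] = np.where(overlap, 0, dist)
    return out


def overlaps_any(query: Interval, features: FeatureSet) -> bool:
    """True iff ``query`` shares >= 1 bp with any feature (half-open)."""
    sub = features.on(query.chrom)
    if sub.empty:
        return False
    return bool(
        np.any((sub["start"].to_numpy() < query.end) & (sub["end"].to_numpy() > query.start))
    )


def overlaps_any_bulk(queries: pd.DataFrame, features: FeatureSet) -> np.ndarray:
    """Vectorised overlap flag per (chrom, start, end) row of ``queries``."""
    out = np.zeros(len(queries), dtype=bool)
    per_chrom = _chrom_arrays(features)
    qstart = queries["start"].to_numpy()
    qend = queries["end"].to_numpy()
    for chrom, idx in queries.groupby("chrom", sort=False).indices.items():
        if chrom not in per_chrom:
            continue
        starts, ends = per_chrom[chrom]
        order = np.argsort(starts, kind="mergesort")
        starts_s = starts[order]
        cummax_end = np.maximum.accumulate(ends[order])
        j = np.searchsorted(starts_s, qend[idx], side="left")
        out[idx] = (j > 0) & (cummax_end[np.maximum(j - 1, 0)] > qstart[idx])
    return out
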