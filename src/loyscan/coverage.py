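"""Windowed coverage: ingest per-base depth, bin, mask, normalize, summarize.

The unit of analysis is the :class:`WindowTrack`: one sample's coverage
over a genome layout, aggregated into non-overlapping windows (10 kb by
default, matching the analysis resolution). Coordinates are 0-based
half-open internally; the depth-TSV input dialect (``samtools depth``)
is 1-based and converted on read; BED inputs are 0-based half-open.

Typical flow for a whole-genome sample::

    records = read_depth_tsv(path, layout)
    track = bin_to_windows(records, layout, window_size=10_000)
    track = restrict_to_msy(track)
    track = mask_windows(track, read_bed(mask_path))
    track = normalize_by_library_size(track, library_size)
    summary = median_chrom_coverage(track)

Window values are mean per-base depth for binned input and raw window
counts for simulated tracks; every downstream statistic (medians, log2
ratios, dosage ratios) is scale-invariant within a sample, so the two
conventions are interchangeable as long as tracks are not mixed within
one comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ContractError, LayoutError, ParseError, ValidationError
from .genome import AUTOSOME, GenomeLayout

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ("chrom", "start", "end", "value")

#: Windows overlapping a gap mask by more than this fraction of their
#: length are dropped (assembly N-runs make their depth meaningless).
MASK_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class WindowTrack:
    """Per-window coverage of one sample over one layout.

    ``windows`` has columns (chrom, start, end, value), sorted by layout
    order then start, non-overlapping within a chromosome, values finite
    and >= 0. ``normalized`` records whether values have been divided by
    library size (per million unique mapped reads); normalizing twice is
    an error.
    """

    sample_id: str
    layout: GenomeLayout
    windows: pd.DataFrame
    normalized: bool = False
    library_size: float | None = None

    def __post_init__(self) -> None:
        df = self.windows
        missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"windows: missing columns {missing}")
        vals = df["value"].to_numpy(dtype=float)
        if len(vals) and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise ValidationError("windows: value must be finite and >= 0")
        for chrom in df["chrom"].unique():
            if chrom not in self.layout:
                raise LayoutError(f"chromosome {chrom!r} is not in the layout")

    def __len__(self) -> int:
        return len(self.windows)

    def chrom_values(self, chrom: str) -> np.ndarray:
        sel = self.windows["chrom"] == chrom
        return self.windows.loc[sel, "value"].to_numpy(dtype=float)

    def subset(self, chroms: Iterable[str]) -> "WindowTrack":
        keep = set(chroms)
        df = self.windows[self.windows["chrom"].isin(keep)].reset_index(drop=True)
        return replace(self, windows=df)

    def total_value(self) -> float:
        """Sum of window values; for count tracks this is the library size."""
        return float(self.windows["value"].sum())


@dataclass(frozen=True)
class ChromCoverageSummary:
    """Per-chromosome median window coverage for one sample.

    ``autosomal_median`` pools all autosomal windows before taking the
    median (robust to unequal window counts per chromosome); it is the
    proxy for the diploid copy-number expectation.
    """

    sample_id: str
    layout: GenomeLayout
    medians: dict[str, float]  # absent key = chromosome had no windows
    n_windows: dict[str, int]
    autosomal_median: float


# ---------------------------------------------------------------------------
# Readers


def read_depth_tsv(path: str | Path, layout: GenomeLayout) -> Iterator[tuple[str, int, float]]:
    """Stream per-base depth records from a ``samtools depth``-style TSV.

    Columns: chrom, 1-based position, depth. Positions absent from the
    file are implicitly depth 0. Yields (chrom, 0-based position, depth).
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            chrom = parts[0]
            if chrom not in layout:
                raise LayoutError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            try:
                pos1 = int(parts[1])
                depth = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed position/depth") from None
            if pos1 < 1:
                raise ParseError(f"{path}: line {lineno}: position must be >= 1")
            yield chrom, pos1 - 1, depth


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read 0-based half-open intervals from a BED file (first 3 columns)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed BED coordinates") from None
            if end < start:
                raise ParseError(f"{path}: line {lineno}: end < start")
            intervals.append((parts[0], start, end))
    return intervals


def read_window_tsv(path: str | Path, layout: GenomeLayout, sample_id: str | None = None) -> WindowTrack:
    """Read a pre-binned window-count track (BED-like TSV: chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=list(WINDOW_COLUMNS), dtype={"chrom": str},
    )
    if sample_id is None:
        sample_id = Path(path).stem
    df = _sort_windows(df, layout)
    return WindowTrack(sample_id=sample_id, layout=layout, windows=df)


def write_window_tsv(track: WindowTrack, path: str | Path) -> None:
    """Write a track as BED-like TSV (chrom, start, end, value; 0-based half-open)."""
    track.windows.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Operations


def _sort_windows(df: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    order = {name: i for i, name in enumerate(layout.names)}
    key = df["chrom"].map(order)
    if key.isna().any():
        bad = df.loc[key.isna(), "chrom"].iloc[0]
        raise LayoutError(f"chromosome {bad!r} is not in the layout")
    return (
        df.assign(_k=key)
        .sort_values(["_k", "start"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def bin_to_windows(
    records: Iterable[tuple[str, int, float]],
    layout: GenomeLayout,
    window_size: int,
    sample_id: str = "sample",
) -> WindowTrack:
    """Aggregate per-base depth into non-overlapping windows of mean depth.

    Windows tile every chromosome from 0 in steps of ``window_size``; the
    last window of a chromosome may be shorter. Bases absent from the
    record stream count as depth 0, so the window value is
    (sum of depths) / (window length).
    """
    if window_size <= 0:
        raise ValidationError("window_size: must be > 0")
    sums: dict[str, np.ndarray] = {
        c.name: np.zeros(math.ceil(c.length / window_size)) for c in layout.chromosomes
    }
    for chrom, pos, depth in records:
        length = layout[chrom].length
        if pos >= length:
            raise ParseError(f"position {pos + 1} beyond {chrom} length {length}")
        sums[chrom][pos // window_size] += depth
    rows = []
    for c in layout.chromosomes:
        for i, (start, end) in enumerate(layout.iter_windows(c.name, window_size)):
            rows.append((c.name, start, end, sums[c.name][i] / (end - start)))
    df = pd.DataFrame(rows, columns=list(WINDOW_COLUMNS))
    return WindowTrack(sample_id=sample_id, layout=layout, windows=df)


def restrict_to_msy(track: WindowTrack) -> WindowTrack:
    """Drop Y windows starting at or beyond the MSY bound; idempotent."""
    y = track.layout.y_name
    msy = track.layout.msy_length
    df = track.windows
    keep = (df["chrom"] != y) | (df["start"] < msy)
    return replace(track, windows=df[keep].reset_index(drop=True))


def mask_windows(
    track: WindowTrack,
    gap_mask: Iterable[tuple[str, int, int]] = (),
    min_value: float = 0.0,
) -> WindowTrack:
    """Drop windows that fall in assembly gaps or below a depth floor.

    A window is dropped when mask intervals cover more than half of its
    length, or when its value is below ``min_value`` (default 0: no value
    filter). Idempotent.
    """
    df = track.windows
    keep = np.ones(len(df), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in gap_mask:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    values = df["value"].to_numpy(dtype=float)
    for i in range(len(df)):
        if values[i] < min_value:
            keep[i] = False
            continue
        ivs = by_chrom.get(chroms[i])
        if not ivs:
            continue
        w0, w1 = int(starts[i]), int(ends[i])
        # mask intervals within one BED may overlap; merge before summing
        clipped = sorted(
            (max(s, w0), min(e, w1)) for s, e in ivs if min(e, w1) > max(s, w0)
        )
        covered, cur0, cur1 = 0, None, None
        for s, e in clipped:
            if cur1 is None or s > cur1:
                if cur1 is not None:
                    covered += cur1 - cur0
                cur0, cur1 = s, e
            else:
                cur1 = max(cur1, e)
        if cur1 is not None:
            covered += cur1 - cur0
        if covered > MASK_OVERLAP_FRACTION * (w1 - w0):
            keep[i] = False
    return replace(track, windows=df[keep].reset_index(drop=True))


def normalize_by_library_size(track: WindowTrack, library_size: float) -> WindowTrack:
    """Divide every window value by library size in millions of reads.

    Puts samples of different sequencing depth on a common per-million
    scale; all downstream dosage ratios are invariant to the unit chosen.
    """
    if library_size <= 0:
        raise ValidationError("library_size: must be > 0")
    if track.normalized:
        raise ContractError(f"track {track.sample_id!r} is already normalized")
    df = track.windows.copy()
    df["value"] = df["value"].to_numpy(dtype=float) / (library_size / 1e6)
    return replace(track, windows=df, normalized=True, library_size=float(library_size))


def median_chrom_coverage(track: WindowTrack) -> ChromCoverageSummary:
    """Per-chromosome median window value, plus the pooled autosomal median.

    The median of an even number of windows is the mean of the two middle
    values. A chromosome with zero (unmasked) windows is recorded as
    missing and a warning is logged.
    """
    medians: dict[str, float] = {}
    n_windows: dict[str, int] = {}
    auto_pool: list[np.ndarray] = []
    for c in track.layout.chromosomes:
        vals = track.chrom_values(c.name)
        n_windows[c.name] = len(vals)
        if len(vals) == 0:
            logger.warning("sample %s: chromosome %s has no windows; median missing",
                           track.sample_id, c.name)
            continue
        medians[c.name] = float(np.median(vals))
        if c.klass == AUTOSOME:
            auto_pool.append(vals)
    pooled = np.concatenate(auto_pool) if auto_pool else np.array([])
    autosomal_median = float(np.median(pooled)) if len(pooled) else float("nan")
    return ChromCoverageSummary(
        sample_id=track.sample_id,
        layout=track.layout,
        medians=medians,
        n_windows=n_windows,
        autosomal_median=autosomal_median,
    )


def summary_frame(summaries: Iterable[ChromCoverageSummary]) -> pd.DataFrame:
    """Tidy table of coverage summaries (one row per sample x chromosome)."""
    rows = []
    for s in summaries:
        for chrom in s.layout.names:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "chrom": chrom,
                    "median": s.medians.get(chrom, float("nan")),
                    "n_windows": s.n_windows.get(chrom, 0),
                    "autosomal_median": s.autosomal_median,
                }
            )
    return pd.DataFrame(rows)
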