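"""Genome layout: the coordinate frame for all coverage analyses.

A :class:`GenomeLayout` records the chromosomes of a male karyotype
(autosomes, one X, one Y), their lengths, and the extent of the Y
male-specific region (MSY) — the non-recombining, uniquely mappable
portion of the Y to which every Y-chromosome analysis is restricted.
For the rat this region spans the first 3.3 Mb of the Y assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import LayoutError

AUTOSOME = "autosome"
X = "X"
Y = "Y"
_CLASSES = frozenset({AUTOSOME, X, Y})

#: Analysis bound on the rat Y: the male-specific region spans the first
#: 3.3 Mb of the assembly, which also contains all Y protein-coding genes.
DEFAULT_MSY_LENGTH = 3_300_000


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    klass: str  # one of {"autosome", "X", "Y"}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes plus the MSY analysis bound on Y.

    Invariants (checked on construction): exactly one Y, at most one X,
    at least one autosome, unique names, positive lengths, and
    ``msy_length <= length(Y)``.
    """

    chromosomes: tuple[Chromosome, ...]
    msy_length: int
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise LayoutError("chromosome names are not unique")
        classes = [c.klass for c in self.chromosomes]
        for c in self.chromosomes:
            if c.klass not in _CLASSES:
                raise LayoutError(f"unknown chromosome class {c.klass!r} for {c.name}")
            if c.length <= 0:
                raise LayoutError(f"chromosome {c.name} has non-positive length")
        if classes.count(Y) != 1:
            raise LayoutError("layout must contain exactly one Y chromosome")
        if classes.count(X) > 1:
            raise LayoutError("layout must contain at most one X chromosome")
        if AUTOSOME not in classes:
            raise LayoutError("layout must contain at least one autosome")
        if not 0 < self.msy_length <= self.y_chromosome_unchecked().length:
            raise LayoutError("msy_length must be in (0, length of Y]")
        object.__setattr__(self, "_index", {c.name: c for c in self.chromosomes})

    # -- lookups ---------------------------------------------------------

    def y_chromosome_unchecked(self) -> Chromosome:
        return next(c for c in self.chromosomes if c.klass == Y)

    @property
    def y_name(self) -> str:
        return self.y_chromosome_unchecked().name

    @property
    def x_name(self) -> str | None:
        for c in self.chromosomes:
            if c.klass == X:
                return c.name
        return None

    @property
    def autosome_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes if c.klass == AUTOSOME)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._index[name]
        except KeyError:
            raise LayoutError(f"chromosome {name!r} is not in the layout") from None

    def class_of(self, name: str) -> str:
        return self[name].klass

    def order(self, name: str) -> int:
        """Rank of a chromosome in layout order (used for sorting windows)."""
        for i, c in enumerate(self.chromosomes):
            if c.name == name:
                return i
        raise LayoutError(f"chromosome {name!r} is not in the layout")

    def analysis_length(self, name: str) -> int:
        """Chromosome length, with Y truncated to the MSY bound."""
        c = self[name]
        return min(c.length, self.msy_length) if c.klass == Y else c.length

    def iter_windows(self, name: str, window_size: int) -> Iterator[tuple[int, int]]:
        """Non-overlapping windows tiling a chromosome from 0; the last
        window may be shorter. Y is tiled over the full assembly length
        (MSY restriction is a separate, explicit step)."""
        length = self[name].length
        for start in range(0, length, window_size):
            yield start, min(start + window_size, length)


def make_default_layout(
    autosome_length: int = 10_000_000,
    x_length: int = 10_000_000,
    y_length: int = 4_000_000,
    msy_length: int = DEFAULT_MSY_LENGTH,
) -> GenomeLayout:
    """A desk-scale male rat-like karyotype: 20 autosomes, one X, one Y.

    Chromosome sizes are deliberately small (10 Mb autosomes by default)
    so that simulation and tests run in seconds; all downstream statistics
    are medians and ratios, which are invariant to chromosome size. The
    MSY bound keeps its real value of 3.3 Mb so that the Y analysis region
    holds the same 330 windows of 10 kb as the real assembly.
    """
    chroms = [Chromosome(f"chr{i}", autosome_length, AUTOSOME) for i in range(1, 21)]
    chroms.append(Chromosome("chrX", x_length, X))
    chroms.append(Chromosome("chrY", y_length, Y))
    return GenomeLayout(tuple(chroms), msy_length)


def read_layout_tsv(path: str | Path, msy_length: int = DEFAULT_MSY_LENGTH) -> GenomeLayout:
    """Read a layout table: chrom, length, class (autosome|X|Y), tab-separated.

    Lines starting with '#' are ignored. An optional fourth column on the Y
    row overrides ``msy_length``.
    """
    chroms: list[Chromosome] = []
    msy = msy_length
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LayoutError(f"{path}: line {lineno}: expected >= 3 columns")
            name, length_s, klass = parts[0], parts[1], parts[2]
            try:
                length = int(length_s)
            except ValueError:
                raise LayoutError(f"{path}: line {lineno}: bad length {length_s!r}") from None
            chroms.append(Chromosome(name, length, klass))
            if klass == Y and len(parts) >= 4 and parts[3]:
                msy = int(parts[3])
    return GenomeLayout(tuple(chroms), msy)


def write_layout_tsv(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tlength\tclass\tmsy_length\n")
        for c in layout.chromosomes:
            extra = f"\t{layout.msy_length}" if c.klass == Y else ""
            fh.write(f"{c.name}\t{c.length}\t{c.klass}{extra}\n")


def layout_frame(layout: GenomeLayout) -> pd.DataFrame:
    """Layout as a tidy DataFrame (chrom, length, class)."""
    return pd.DataFrame(
        {
            "chrom": [c.name for c in layout.chromosomes],
            "length": [c.length for c in layout.chromosomes],
            "class": [c.klass for c in layout.chromosomes],
        }
    )
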