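"""LOY estimators: amplicon dosage score, chromosome loss fraction, and
windowed log2 ratio profiles.

Three complementary quantifications of mosaic Y loss from bulk data:

* ``amplicon_loy_score`` — log10 ratio of a Y-linked single-copy locus
  count to half an autosomal single-copy locus count. 0 at dosage
  parity, negative under loss (a score of log10(1 - f) for loss
  fraction f, in expectation).
* ``chrom_loss_estimate`` — observed chromosome median coverage against
  its expectation (half the autosomal median for the single-copy sex
  chromosomes, the autosomal median itself for autosomes), yielding a
  difference, a ratio, and a clipped loss fraction
  ``f_hat = clip(1 - ratio, 0, 1)``.
* ``window_log2_profile`` — per-window ``log2(sample / reference)``
  over the MSY against a young intact reference, summarized by its
  median (overall dosage) and variance (structural heterogeneity).

Sign convention, used consistently everywhere: loss is negative — a
sample below its dosage expectation has score < 0, diff < 0, and log2
ratios < 0. (For the profile this means aged-over-young inside the log,
so that increasing loss drives ratios more negative.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import ChromCoverageSummary, WindowTrack
from .errors import (
    AlignmentError,
    ContractError,
    EstimationError,
    ValidationError,
)
from .genome import AUTOSOME

#: Half-count pseudocount applied when the Y amplicon count is zero, so
#: the log-score stays finite; flagged by callers via n_Y == 0.
ZERO_Y_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class AmpliconCounts:
    """Unique-read counts for the two-locus amplicon pool of one sample:
    the Y-linked locus (EIF2S3Y role) and the autosomal locus (COL1A1
    role)."""

    sample_id: str
    tissue: str
    age_group: str  # young | old
    n_Y: int
    n_A: int

    def __post_init__(self) -> None:
        if self.n_Y < 0:
            raise ValidationError("n_Y: must be >= 0")
        if self.n_A < 0:
            raise ValidationError("n_A: must be >= 0")


@dataclass(frozen=True)
class LOYEstimate:
    """Observed vs expected dosage of one chromosome in one sample.

    ``ratio`` is reported unclipped; ``f_hat = clip(1 - ratio, 0, 1)``
    keeps the loss-fraction estimand in its natural range when coverage
    noise pushes the ratio above 1.
    """

    sample_id: str
    chrom: str
    observed: float
    expected: float
    diff: float
    ratio: float
    f_hat: float


@dataclass(frozen=True)
class RatioProfile:
    """Per-window log2 coverage ratios of one sample against a reference.

    ``variance_ratio`` uses the n-1 denominator; a constant profile has
    variance 0, and a profile with fewer than two retained windows is
    assigned variance 0 as well.
    """

    sample_id: str
    reference_id: str
    windows: pd.DataFrame  # chrom, start, end, log2_ratio
    median_ratio: float
    variance_ratio: float
    n_windows_used: int
    n_windows_dropped: int

    @property
    def ratios(self) -> np.ndarray:
        return self.windows["log2_ratio"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Operations


def amplicon_loy_score(counts: AmpliconCounts) -> float:
    """log10 dosage of the Y locus relative to half the autosomal locus.

    score = log10(n_Y) - log10(n_A / 2); 0 at parity, log10(1 - f) in
    expectation under loss fraction f. A zero Y count is replaced by a
    half-count pseudocount so the score stays finite (callers can flag
    such samples from n_Y == 0).
    """
    if counts.n_A <= 0:
        raise EstimationError(
            f"sample {counts.sample_id!r}: autosomal count is 0, score undefined"
        )
    n_y = counts.n_Y if counts.n_Y > 0 else ZERO_Y_PSEUDOCOUNT
    return math.log10(n_y) - math.log10(counts.n_A / 2.0)


def chrom_loss_estimate(summary: ChromCoverageSummary, chrom: str) -> LOYEstimate:
    """Observed vs expected median coverage for one chromosome.

    Expectation: half the pooled autosomal median for the single-copy
    sex chromosomes (X, Y), the pooled autosomal median itself for
    autosomes (making autosomal estimates centered at zero difference —
    the all-chromosome specificity panel).
    """
    klass = summary.layout.class_of(chrom)
    if chrom not in summary.medians:
        raise EstimationError(
            f"sample {summary.sample_id!r}: no median for chromosome {chrom!r}"
        )
    if not summary.autosomal_median > 0:
        raise EstimationError(
            f"sample {summary.sample_id!r}: autosomal median must be > 0"
        )
    observed = summary.medians[chrom]
    expected = (
        summary.autosomal_median if klass == AUTOSOME else summary.autosomal_median / 2.0
    )
    ratio = observed / expected
    return LOYEstimate(
        sample_id=summary.sample_id,
        chrom=chrom,
        observed=observed,
        expected=expected,
        diff=observed - expected,
        ratio=ratio,
        f_hat=float(np.clip(1.0 - ratio, 0.0, 1.0)),
    )


def estimates_frame(estimates: Sequence[LOYEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "chrom": [e.chrom for e in estimates],
            "observed": [e.observed for e in estimates],
            "expected": [e.expected for e in estimates],
            "diff": [e.diff for e in estimates],
            "ratio": [e.ratio for e in estimates],
            "f_hat": [e.f_hat for e in estimates],
        }
    )


def window_log2_profile(
    reference: WindowTrack,
    sample: WindowTrack,
    pseudocount: float = 0.0,
) -> RatioProfile:
    """Per-window log2(sample / reference) with median/variance summaries.

    Both tracks must be normalized and share an identical window grid.
    With the default pseudocount of 0, windows where either value is 0
    are dropped (and counted); a positive pseudocount retains every
    window as log2((s + pc) / (r + pc)).
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount: must be >= 0")
    if not (reference.normalized and sample.normalized):
        raise ContractError("both tracks must be normalized before profiling")
    ref = reference.windows
    smp = sample.windows
    if len(ref) != len(smp):
        raise AlignmentError(
            f"window grids differ in length: reference {len(ref)}, sample {len(smp)}"
        )
    for col in ("chrom", "start", "end"):
        a = ref[col].to_numpy()
        b = smp[col].to_numpy()
        neq = a != b
        if neq.any():
            i = int(np.argmax(neq))
            raise AlignmentError(
                f"window grids differ at index {i}: reference "
                f"{ref['chrom'].iat[i]}:{ref['start'].iat[i]}-{ref['end'].iat[i]} vs "
                f"sample {smp['chrom'].iat[i]}:{smp['start'].iat[i]}-{smp['end'].iat[i]}"
            )
    r = ref["value"].to_numpy(dtype=float) + pseudocount
    s = smp["value"].to_numpy(dtype=float) + pseudocount
    keep = (r > 0) & (s > 0)
    ratios = np.log2(s[keep] / r[keep])
    windows = pd.DataFrame(
        {
            "chrom": ref["chrom"].to_numpy()[keep],
            "start": ref["start"].to_numpy()[keep],
            "end": ref["end"].to_numpy()[keep],
            "log2_ratio": ratios,
        }
    )
    n_used = int(keep.sum())
    median = float(np.median(ratios)) if n_used else float("nan")
    variance = float(np.var(ratios, ddof=1)) if n_used >= 2 else 0.0
    return RatioProfile(
        sample_id=sample.sample_id,
        reference_id=reference.sample_id,
        windows=windows,
        median_ratio=median,
        variance_ratio=variance,
        n_windows_used=n_used,
        n_windows_dropped=int(len(ref) - n_used),
    )


def profile_regression_inputs(
    profiles: Sequence[RatioProfile], ages: Mapping[str, float]
) -> pd.DataFrame:
    """Tidy per-sample table (sample_id, age, median_ratio, variance_ratio)
    feeding the linear models; no statistics are computed here."""
    ids = [p.sample_id for p in profiles]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValidationError(f"duplicate sample id(s) in profiles: {sorted(dup)}")
    missing = [i for i in ids if i not in ages]
    if missing:
        raise ValidationError(f"no age entry for sample(s): {missing}")
    return pd.DataFrame(
        {
            "sample_id": ids,
            "age": [float(ages[i]) for i in ids],
            "median_ratio": [p.median_ratio for p in profiles],
            "variance_ratio": [p.variance_ratio for p in profiles],
        }
    )


def write_ratio_tsv(profile: RatioProfile, path: str | Path) -> None:
    """Per-window ratio track (chrom, start, end, log2_ratio), BED-like."""
    profile.windows.to_csv(path, sep="\t", header=False, index=False,
                           float_format="%.10g")


def read_amplicon_tsv(path: str | Path) -> list[AmpliconCounts]:
    """Read an amplicon count table (sample_id, age_group, tissue, n_Y, n_A)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age_group", "tissue", "n_Y", "n_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"amplicon table missing columns: {sorted(missing)}")
    return [
        AmpliconCounts(
            sample_id=str(r.sample_id), tissue=str(r.tissue),
            age_group=str(r.age_group), n_Y=int(r.n_Y), n_A=int(r.n_A),
        )
        for r in df.itertuples()
    ]
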