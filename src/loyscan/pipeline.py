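"""End-to-end LOY screens: amplicon screen, WGS dosage screen, Y-profile
analysis.

Each ``run_*`` function consumes in-memory objects from the other
modules and returns tidy tables plus test results; the CLI is a thin
wrapper around these. Conventions shared by all three screens:

* every family of p-values is BH-corrected within itself (one family
  per figure-style panel), and both raw and adjusted p are reported;
* groups with fewer than ``MIN_GROUP_N`` observations are flagged
  ``underpowered`` instead of tested;
* significance markers annotate adjusted p at 0.05 (``*``) and
  0.001 (``***``) but never replace the numeric columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (
    WindowTrack,
    median_chrom_coverage,
    restrict_to_msy,
)
from .errors import ContractError, DegenerateInputError, ValidationError
from .genome import GenomeLayout
from .loy import (
    AmpliconCounts,
    RatioProfile,
    amplicon_loy_score,
    chrom_loss_estimate,
    estimates_frame,
    profile_regression_inputs,
    window_log2_profile,
)
from .stats import (
    LinearFit,
    bh_adjust,
    fit_linear_model,
    location_test_vs_zero,
    two_sample_rank_test,
)

#: Below this group size a location test is not attempted.
MIN_GROUP_N = 3

ALPHA_STAR = 0.05
ALPHA_TRIPLE_STAR = 0.001


def _marker(p_adj: float) -> str:
    if not np.isfinite(p_adj):
        return ""
    if p_adj < ALPHA_TRIPLE_STAR:
        return "***"
    if p_adj < ALPHA_STAR:
        return "*"
    return ""


def _finish_family(rows: list[dict]) -> None:
    """BH-adjust the tested rows of one family in place."""
    tested = [r for r in rows if np.isfinite(r["p"])]
    if tested:
        adj = bh_adjust([r["p"] for r in tested])
        for r, q in zip(tested, adj):
            r["p_adjusted"] = float(q)
    for r in rows:
        r.setdefault("p_adjusted", float("nan"))
        r["marker"] = _marker(r["p_adjusted"])


@dataclass(frozen=True)
class ScreenReport:
    """Per-sample score table plus per-group test table with provenance."""

    scores: pd.DataFrame
    tests: pd.DataFrame
    fits: dict[str, LinearFit] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _provenance(seed: int | None = None, **extra) -> dict:
    import pandas
    import scipy

    prov = {
        "loyscan_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pandas.__version__,
    }
    if seed is not None:
        prov["seed"] = seed
    prov.update(extra)
    return prov


# ---------------------------------------------------------------------------
# Amplicon screen


def run_amplicon_screen(
    counts: Sequence[AmpliconCounts],
    min_group_n: int = MIN_GROUP_N,
) -> ScreenReport:
    """Per-tissue amplicon LOY screen across age groups.

    Computes the log10 dosage score per sample, then per tissue x age
    group a signed-rank test of the scores against dosage parity (0),
    and per tissue a young-vs-old two-sample rank test. Each of the
    three test families (location tests in young, location tests in old,
    young-vs-old) is BH-corrected separately.
    """
    if len(counts) == 0:
        raise ValidationError("amplicon table is empty")
    scores = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in counts],
            "tissue": [c.tissue for c in counts],
            "age_group": [c.age_group for c in counts],
            "n_Y": [c.n_Y for c in counts],
            "n_A": [c.n_A for c in counts],
            "score": [amplicon_loy_score(c) for c in counts],
            "zero_y_pseudocount": [c.n_Y == 0 for c in counts],
        }
    )

    all_rows: list[dict] = []
    for age_group in sorted(scores["age_group"].unique()):
        family = f"location_{age_group}"
        rows: list[dict] = []
        sub = scores[scores["age_group"] == age_group]
        for tissue in sorted(sub["tissue"].unique()):
            vals = sub.loc[sub["tissue"] == tissue, "score"].to_numpy()
            row = {
                "family": family, "tissue": tissue, "age_group": age_group,
                "test_name": "wilcoxon_signed_rank_vs_zero",
                "n": len(vals), "statistic": float("nan"), "p": float("nan"),
                "underpowered": len(vals) < min_group_n, "note": "",
            }
            if len(vals) >= min_group_n:
                try:
                    res = location_test_vs_zero(vals)
                    row["statistic"] = res.statistic
                    row["p"] = res.p_value
                    row["note"] = res.method_detail
                except DegenerateInputError:
                    row["note"] = "degenerate"
            else:
                row["note"] = "underpowered"
            rows.append(row)
        _finish_family(rows)
        all_rows.extend(rows)

    rows = []
    by_tissue = scores.groupby("tissue")
    for tissue in sorted(scores["tissue"].unique()):
        sub = by_tissue.get_group(tissue)
        young = sub.loc[sub["age_group"] == "young", "score"].to_numpy()
        old = sub.loc[sub["age_group"] == "old", "score"].to_numpy()
        row = {
            "family": "young_vs_old", "tissue": tissue, "age_group": "both",
            "test_name": "mann_whitney_u",
            "n": len(young) + len(old), "statistic": float("nan"),
            "p": float("nan"),
            "underpowered": min(len(young), len(old)) < min_group_n, "note": "",
        }
        if min(len(young), len(old)) >= min_group_n:
            res = two_sample_rank_test(young, old)
            row["statistic"] = res.statistic
            row["p"] = res.p_value
            row["note"] = res.method_detail
        else:
            row["note"] = "underpowered"
        rows.append(row)
    _finish_family(rows)
    all_rows.extend(rows)

    tests = pd.DataFrame(all_rows)
    return ScreenReport(scores=scores, tests=tests, provenance=_provenance())


# ---------------------------------------------------------------------------
# WGS dosage screen


def run_wgs_screen(
    tracks: Sequence[WindowTrack],
    layout: GenomeLayout,
    ages: Mapping[str, float] | None = None,
    min_group_n: int = MIN_GROUP_N,
) -> ScreenReport:
    """All-chromosome dosage screen over a set of normalized WGS tracks.

    Per sample and chromosome: median window coverage vs its expectation
    (autosomal median for autosomes, half of it for X and Y), yielding
    diff / ratio / f_hat. Per chromosome across samples: a signed-rank
    test of the diffs against 0, BH-corrected over the chromosome family
    — the all-chromosome specificity panel in which only Y should flag
    under pure LOY. If sample ages are supplied, OLS fits of the
    normalized Y and X dosage ratios against age and of Y against X are
    returned as well.
    """
    if len(tracks) == 0:
        raise ValidationError("need at least one track")
    for t in tracks:
        if not t.normalized:
            raise ContractError(f"track {t.sample_id!r} is not normalized")
    estimates = []
    for t in tracks:
        summary = median_chrom_coverage(restrict_to_msy(t))
        for chrom in layout.names:
            estimates.append(chrom_loss_estimate(summary, chrom))
    est_df = estimates_frame(estimates)

    rows: list[dict] = []
    for chrom in layout.names:
        diffs = est_df.loc[est_df["chrom"] == chrom, "diff"].to_numpy()
        row = {
            "family": "per_chromosome", "chrom": chrom, "klass": layout.class_of(chrom),
            "test_name": "wilcoxon_signed_rank_vs_zero",
            "n": len(diffs), "statistic": float("nan"), "p": float("nan"),
            "underpowered": len(diffs) < min_group_n, "note": "",
        }
        if len(diffs) >= min_group_n:
            try:
                res = location_test_vs_zero(diffs)
                row["statistic"] = res.statistic
                row["p"] = res.p_value
                row["note"] = res.method_detail
            except DegenerateInputError:
                row["note"] = "degenerate"
        else:
            row["note"] = "underpowered"
        rows.append(row)
    _finish_family(rows)
    for r in rows:
        r["flagged"] = bool(np.isfinite(r["p_adjusted"]) and r["p_adjusted"] < ALPHA_STAR)
    tests = pd.DataFrame(rows)

    fits: dict[str, LinearFit] = {}
    y_name, x_name = layout.y_name, layout.x_name
    ratio_of = {
        (e.sample_id, e.chrom): e.ratio for e in estimates
    }
    sample_ids = [t.sample_id for t in tracks]
    if ages is not None and len(sample_ids) >= 3:
        age_vec = [float(ages[s]) for s in sample_ids if s in ages]
        used = [s for s in sample_ids if s in ages]
        if len(used) >= 3 and len(set(age_vec)) > 1:
            y_ratio = [ratio_of[(s, y_name)] for s in used]
            fits["chrY_ratio_vs_age"] = fit_linear_model(y_ratio, age_vec)
            if x_name is not None:
                x_ratio = [ratio_of[(s, x_name)] for s in used]
                fits["chrX_ratio_vs_age"] = fit_linear_model(x_ratio, age_vec)
    if x_name is not None and len(sample_ids) >= 3:
        y_ratio = [ratio_of[(s, y_name)] for s in sample_ids]
        x_ratio = [ratio_of[(s, x_name)] for s in sample_ids]
        if len(set(x_ratio)) > 1:
            fits["chrY_ratio_vs_chrX_ratio"] = fit_linear_model(y_ratio, x_ratio)

    return ScreenReport(scores=est_df, tests=tests, fits=fits, provenance=_provenance())


# ---------------------------------------------------------------------------
# Y-profile analysis


@dataclass(frozen=True)
class ProfileAnalysis:
    """Per-sample MSY log2 ratio profiles with tests and linear fits."""

    profiles: list[RatioProfile]
    summary: pd.DataFrame  # sample_id, age, median_ratio, variance_ratio, ...
    tests: pd.DataFrame
    fits: dict[str, LinearFit]
    display_profiles: list[RatioProfile] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def rebin_track(track: WindowTrack, coarse_window_size: int) -> WindowTrack:
    """Aggregate consecutive windows into coarser ones (display resolution).

    Values are combined by length-weighted mean, so a mean-depth track
    stays a mean-depth track; coarse windows snap to multiples of
    ``coarse_window_size``.
    """
    if coarse_window_size <= 0:
        raise ValidationError("coarse_window_size: must be > 0")
    df = track.windows
    bucket = df["start"].to_numpy() // coarse_window_size
    lens = (df["end"] - df["start"]).to_numpy(dtype=float)
    g = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "bucket": bucket,
            "wsum": df["value"].to_numpy(dtype=float) * lens,
            "len": lens,
            "start": df["start"].to_numpy(),
            "end": df["end"].to_numpy(),
        }
    ).groupby(["chrom", "bucket"], sort=False)
    out = g.agg(
        start=("start", "min"), end=("end", "max"),
        wsum=("wsum", "sum"), len=("len", "sum"),
    ).reset_index()
    out["value"] = out["wsum"] / out["len"]
    out = out[["chrom", "start", "end", "value"]]
    from .coverage import _sort_windows

    out = _sort_windows(out, track.layout)
    from dataclasses import replace

    return replace(track, windows=out)


def run_profile_analysis(
    reference: WindowTrack,
    samples: Sequence[WindowTrack],
    ages: Mapping[str, float],
    pseudocount: float = 0.0,
    exclude_ids: Sequence[str] = (),
    display_window_size: int | None = None,
) -> ProfileAnalysis:
    """MSY log2 ratio profiles of aged samples against a young reference.

    Every track (reference included) is restricted to the Y MSY before
    profiling. The reference profiled against itself is included as the
    zero anchor point of the regressions. Per sample, a signed-rank test
    of the window ratios against 0 (BH-corrected across samples) asks
    whether that genome's Y coverage deviates from the reference.

    Fits returned: ``median_vs_age``; ``variance_vs_median`` on all
    points; and ``variance_vs_median_excluding_anchors`` which drops the
    reference self-anchor plus any user-designated extreme samples
    (``exclude_ids``).
    """
    for t in [reference, *samples]:
        if not t.normalized:
            raise ContractError(f"track {t.sample_id!r} is not normalized")
    y_name = reference.layout.y_name
    ref_y = restrict_to_msy(reference).subset([y_name])
    tracks_y = [restrict_to_msy(t).subset([y_name]) for t in samples]

    profiles = [window_log2_profile(ref_y, ref_y, pseudocount=pseudocount)]
    profiles += [window_log2_profile(ref_y, t, pseudocount=pseudocount) for t in tracks_y]

    rows: list[dict] = []
    for p in profiles:
        row = {
            "family": "per_sample_profile", "sample_id": p.sample_id,
            "test_name": "wilcoxon_signed_rank_vs_zero",
            "n": p.n_windows_used, "statistic": float("nan"), "p": float("nan"),
            "underpowered": p.n_windows_used < MIN_GROUP_N, "note": "",
        }
        if p.n_windows_used >= MIN_GROUP_N:
            try:
                res = location_test_vs_zero(p.ratios)
                row["statistic"] = res.statistic
                row["p"] = res.p_value
                row["note"] = res.method_detail
            except DegenerateInputError:
                row["note"] = "degenerate"  # e.g. the reference against itself
        else:
            row["note"] = "underpowered"
        rows.append(row)
    _finish_family(rows)
    tests = pd.DataFrame(rows)

    summary = profile_regression_inputs(profiles, ages)
    summary = summary.merge(
        tests[["sample_id", "p", "p_adjusted", "marker"]], on="sample_id", how="left"
    )

    fits: dict[str, LinearFit] = {}
    if len(summary) >= 3 and summary["age"].nunique() > 1:
        fits["median_vs_age"] = fit_linear_model(
            summary["median_ratio"], summary["age"]
        )
    if len(summary) >= 3 and summary["median_ratio"].nunique() > 1:
        fits["variance_vs_median"] = fit_linear_model(
            summary["variance_ratio"], summary["median_ratio"]
        )
    anchors = {reference.sample_id, *exclude_ids}
    kept = summary[~summary["sample_id"].isin(anchors)]
    if len(kept) >= 3 and kept["median_ratio"].nunique() > 1:
        fits["variance_vs_median_excluding_anchors"] = fit_linear_model(
            kept["variance_ratio"], kept["median_ratio"]
        )

    display = []
    if display_window_size is not None:
        ref_d = rebin_track(ref_y, display_window_size)
        display = [
            window_log2_profile(ref_d, rebin_track(t, display_window_size),
                                pseudocount=pseudocount)
            for t in tracks_y
        ]

    return ProfileAnalysis(
        profiles=profiles,
        summary=summary,
        tests=tests,
        fits=fits,
        display_profiles=display,
        provenance=_provenance(),
    )


def fits_frame(fits: Mapping[str, LinearFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": list(fits.keys()),
            "slope": [f.slope for f in fits.values()],
            "intercept": [f.intercept for f in fits.values()],
            "slope_p": [f.slope_p for f in fits.values()],
            "r_squared": [f.r_squared for f in fits.values()],
            "n": [f.n for f in fits.values()],
        }
    )
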