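"""Synthetic LOY cohorts: window-count tracks and amplicon pools with
known mosaic-loss fractions.

The generator emulates the data a bulk-sequencing LOY study produces,
without raw reads. A male genome carries two copies of each autosome and
one copy of X and Y; when a fraction ``f_Y`` of cells has lost the Y,
bulk Y coverage drops to ``(1 - f_Y)`` of the single-copy expectation.

Window counts
    For a window of length L, the expected count is
    ``mu = (base_depth / 2) * copy * m * L`` with copy = 2 for autosomes,
    ``1 - f_X`` for X and ``1 - f_Y`` for Y (haploid unit = base_depth/2,
    so intact autosomes sit at base_depth and an intact sex chromosome at
    base_depth/2), and m an optional per-Y-window repeat multiplier that
    mimics collapsed repeats in the assembly. Counts are drawn
    negative-binomial with mean mu and dispersion alpha
    (variance mu + alpha*mu^2; Poisson at alpha = 0). Structural
    heterogeneity on Y — losses co-occurring with other aberrations — is
    modelled as mean-one multiplicative log-normal noise whose log-scale
    standard deviation grows linearly with the loss fraction:
    ``sd = aberration_sd_scale * f_Y``.

Amplicon pools
    A two-locus pool (Y-linked single-copy gene vs autosomal single-copy
    gene) of ``amplicon_total`` reads, split multinomially with weights
    proportional to copy number times a per-locus log-normal
    amplification efficiency: ``w_Y = (1 - f_Y) * e_Y``, ``w_A = 2 * e_A``.

Everything is deterministic given the configuration seed; cohort members
get per-sample seeds derived by stable hashing of (master seed, sample
index), so adding samples never reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coverage import WINDOW_COLUMNS, WindowTrack
from .errors import ValidationError
from .genome import AUTOSOME, GenomeLayout, X, Y
from .loy import AmpliconCounts

YOUNG = "young"
OLD = "old"

#: The eleven tissues of the study design, used to label cohort samples.
TISSUES = (
    "blood", "brain", "heart", "kidney", "liver", "lung",
    "muscle", "pancreas", "skin", "spleen", "testis",
)

#: Age conventions (months): young reference animals are 3 months old,
#: aged animals 22-25 months.
YOUNG_AGE_MONTHS = 3
OLD_AGE_MONTHS_RANGE = (22, 25)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; defaults are the study regime.

    base_depth
        Mean autosomal per-base coverage (X-fold). Default 10, the upper
        end of the 7-10X unique-read coverage the analysis assumes.
    f_Y, f_X
        Fractions of cells lacking Y / X, in [0, 1].
    window_size
        Analysis window, default 10 kb.
    nb_dispersion
        Negative-binomial overdispersion alpha (variance mu + alpha*mu^2);
        0 gives Poisson counts. Default 0.05, mild overdispersion typical
        of PCR-free WGS.
    repeat_profile
        Optional per-Y-window multiplicative factors (> 0) emulating
        collapsed repeats; length must equal the number of MSY windows.
    amplicon_total
        Total reads in the two-locus amplicon pool; default 440,000, the
        study's mean pool size.
    efficiency_sd
        Log-scale SD of per-locus amplification efficiency; default 0.05
        (a few percent efficiency jitter between loci).
    aberration_sd_scale
        Coefficient linking Y window-level heterogeneity to f_Y; 0 (the
        default) disables it.
    """

    base_depth: float = 10.0
    f_Y: float = 0.0
    f_X: float = 0.0
    window_size: int = 10_000
    nb_dispersion: float = 0.05
    repeat_profile: tuple[float, ...] | None = None
    amplicon_total: int = 440_000
    efficiency_sd: float = 0.05
    aberration_sd_scale: float = 0.0
    seed: int = 0

    def validate(self, layout: GenomeLayout | None = None) -> None:
        if not self.base_depth > 0:
            raise ValidationError("base_depth: must be > 0")
        for name in ("f_Y", "f_X"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{name}: must be in [0, 1]")
        if not self.window_size > 0:
            raise ValidationError("window_size: must be > 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion: must be >= 0")
        if self.amplicon_total <= 0:
            raise ValidationError("amplicon_total: must be > 0")
        if self.efficiency_sd < 0:
            raise ValidationError("efficiency_sd: must be >= 0")
        if self.aberration_sd_scale < 0:
            raise ValidationError("aberration_sd_scale: must be >= 0")
        if self.repeat_profile is not None:
            if any(m <= 0 for m in self.repeat_profile):
                raise ValidationError("repeat_profile: all multipliers must be > 0")
            if layout is not None:
                n_y = _n_msy_windows(layout, self.window_size)
                if len(self.repeat_profile) != n_y:
                    raise ValidationError(
                        f"repeat_profile: length {len(self.repeat_profile)} != "
                        f"{n_y} Y windows"
                    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded per simulated sample, for recovery tests."""

    sample_id: str
    age_group: str  # young | old
    true_f_Y: float
    true_f_X: float
    seed: int
    tissue: str = "liver"
    age_months: int = YOUNG_AGE_MONTHS


def _n_msy_windows(layout: GenomeLayout, window_size: int) -> int:
    msy = min(layout.msy_length, layout[layout.y_name].length)
    return -(-msy // window_size)


def simulate_window_counts(
    layout: GenomeLayout, config: SimulationConfig, sample_id: str = "sim"
) -> WindowTrack:
    """Draw one whole-genome window-count track under the dosage model.

    Windows tile every chromosome in ``window_size`` steps; the Y is
    generated only over the MSY (the rest of the real Y is repeat-dense
    and excluded from any analysis). Window values are raw counts.
    """
    config.validate(layout)
    rng = np.random.default_rng(config.seed)
    copy_by_class = {AUTOSOME: 2.0, X: 1.0 - config.f_X, Y: 1.0 - config.f_Y}
    rows: list[pd.DataFrame] = []
    for c in layout.chromosomes:
        length = layout.analysis_length(c.name)
        starts = np.arange(0, length, config.window_size, dtype=np.int64)
        ends = np.minimum(starts + config.window_size, length)
        lens = (ends - starts).astype(float)
        mu = (config.base_depth / 2.0) * copy_by_class[c.klass] * lens
        if c.klass == Y:
            if config.repeat_profile is not None:
                mu = mu * np.asarray(config.repeat_profile, dtype=float)
            s = config.aberration_sd_scale * config.f_Y
            if s > 0:
                # mean-one log-normal: heterogeneity without dosage bias
                mu = mu * np.exp(rng.normal(-0.5 * s * s, s, size=len(mu)))
        if config.nb_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / config.nb_dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        rows.append(
            pd.DataFrame(
                {"chrom": c.name, "start": starts, "end": ends,
                 "value": counts.astype(float)}
            )
        )
    df = pd.concat(rows, ignore_index=True)[list(WINDOW_COLUMNS)]
    return WindowTrack(sample_id=sample_id, layout=layout, windows=df)


def simulate_amplicon_counts(
    config: SimulationConfig,
    sample_id: str = "sim",
    tissue: str = "liver",
    age_group: str = OLD,
) -> AmpliconCounts:
    """Draw one two-locus amplicon pool: (n_Y, n_A) summing to amplicon_total."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    eff = np.exp(rng.normal(0.0, config.efficiency_sd, size=2))
    weights = np.array([(1.0 - config.f_Y) * eff[0], 2.0 * eff[1]])
    n_y, n_a = rng.multinomial(config.amplicon_total, weights / weights.sum())
    return AmpliconCounts(
        sample_id=sample_id, tissue=tissue, age_group=age_group,
        n_Y=int(n_y), n_A=int(n_a),
    )


FractionSpec = Sequence[float] | tuple[str, float, float] | Callable[[np.random.Generator], float]


def _sample_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(0, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _resolve_fractions(
    f_distribution: FractionSpec | None, n_old: int, master_seed: int
) -> list[float]:
    if n_old == 0:
        return []
    if f_distribution is None:
        f_distribution = ("uniform", 0.0, 0.5)
    if callable(f_distribution):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(1, 0))
        )
        return [float(f_distribution(rng)) for _ in range(n_old)]
    if (
        isinstance(f_distribution, tuple)
        and len(f_distribution) == 3
        and f_distribution[0] == "uniform"
    ):
        _, lo, hi = f_distribution
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(1, 0))
        )
        return list(rng.uniform(float(lo), float(hi), size=n_old))
    fractions = [float(f) for f in f_distribution]
    if len(fractions) != n_old:
        raise ValidationError(
            f"f_distribution: expected {n_old} fractions, got {len(fractions)}"
        )
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValidationError("f_distribution: fractions must be in [0, 1]")
    return fractions


def simulate_cohort(
    layout: GenomeLayout,
    n_young: int,
    n_old: int,
    f_distribution: FractionSpec | None,
    config: SimulationConfig,
    tissues: Sequence[str] | None = None,
    with_tracks: bool = True,
    with_amplicons: bool = True,
) -> list[tuple[WindowTrack | None, AmpliconCounts | None, SimulationTruth]]:
    """Simulate a young-reference / aged cohort with recorded ground truth.

    Young samples always have ``f_Y = f_X = 0`` (3-month reference
    animals); old samples take loss fractions from ``f_distribution``
    (an explicit list of length ``n_old``, a ``("uniform", lo, hi)``
    spec, or a callable rng -> fraction) and ages drawn uniformly from
    22-25 months. Tissue labels cycle through ``tissues`` (default: the
    eleven study tissues). ``with_tracks`` / ``with_amplicons`` switch
    off unneeded outputs for speed.
    """
    if n_young < 1:
        raise ValidationError("n_young: at least one young reference sample required")
    if n_old < 0:
        raise ValidationError("n_old: must be >= 0")
    config.validate(layout)
    tissues = tuple(tissues) if tissues is not None else TISSUES
    fractions = _resolve_fractions(f_distribution, n_old, config.seed)

    out = []
    for i in range(n_young + n_old):
        is_young = i < n_young
        seed_i = _sample_seed(config.seed, i)
        rng_meta = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2, i))
        )
        if is_young:
            sample_id = f"young_{i + 1}"
            f_y, f_x = 0.0, 0.0
            age = YOUNG_AGE_MONTHS
        else:
            j = i - n_young
            sample_id = f"old_{j + 1}"
            f_y = fractions[j]
            f_x = config.f_X
            lo, hi = OLD_AGE_MONTHS_RANGE
            age = int(rng_meta.integers(lo, hi + 1))
        tissue = tissues[i % len(tissues)]
        cfg_i = replace(config, f_Y=f_y, f_X=f_x, seed=seed_i)
        truth = SimulationTruth(
            sample_id=sample_id,
            age_group=YOUNG if is_young else OLD,
            true_f_Y=f_y, true_f_X=f_x, seed=seed_i,
            tissue=tissue, age_months=age,
        )
        track = (
            simulate_window_counts(layout, cfg_i, sample_id=sample_id)
            if with_tracks else None
        )
        amplicon = (
            simulate_amplicon_counts(
                cfg_i, sample_id=sample_id, tissue=tissue, age_group=truth.age_group
            )
            if with_amplicons else None
        )
        out.append((track, amplicon, truth))
    return out


# ---------------------------------------------------------------------------
# Table writers (TSV interchange; all text, genome-browser friendly)


def truths_frame(truths: Sequence[SimulationTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "age_group": [t.age_group for t in truths],
            "tissue": [t.tissue for t in truths],
            "age_months": [t.age_months for t in truths],
            "true_f_Y": [t.true_f_Y for t in truths],
            "true_f_X": [t.true_f_X for t in truths],
            "seed": [t.seed for t in truths],
        }
    )


def write_truths_tsv(truths: Sequence[SimulationTruth], path: str | Path) -> None:
    truths_frame(truths).to_csv(path, sep="\t", index=False, float_format="%.10g")


def amplicon_frame(counts: Sequence[AmpliconCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in counts],
            "age_group": [a.age_group for a in counts],
            "tissue": [a.tissue for a in counts],
            "n_Y": [a.n_Y for a in counts],
            "n_A": [a.n_A for a in counts],
        }
    )


def write_amplicon_tsv(counts: Sequence[AmpliconCounts], path: str | Path) -> None:
    amplicon_frame(counts).to_csv(path, sep="\t", index=False)
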