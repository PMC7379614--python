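"""Seeded generators emulating rifampicin-chase experiments.

Three generators mirror the study designs the pipeline consumes:

* :func:`simulate_qpcr_chase` — isolate chase measured by qPCR: per-gene
  exponential decay after a short delay, a pre-treatment control several-fold
  below the post-treatment peak, triplicate Cq values derived from an ideal
  standard curve, plus the dilution standards and no-RT (residual DNA)
  controls a plate would carry.
* :func:`simulate_metatranscriptome` — a community chase: lognormal family
  abundances and half-lives (median 28 min), a rifampicin-resistant
  (non-decaying) subset, quasi-stable rRNA, and multinomial read sampling at
  realistic depths with a realistic mRNA fraction, in both family mode and
  class × COG-subcategory mode.
* :func:`simulate_growth_curve` — lag/log/stationary growth with a
  programmed generation time.

Every generator takes a seed, emits a truth table for every entity, and is
bit-for-bit reproducible.  Stochasticity in the community tables comes from
the multinomial read draw (plus optional lognormal pool noise); the qPCR
generator applies lognormal measurement noise to abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metat import COG_SUBCATEGORIES, PRE_LABEL, AnnotatedCounts

__all__ = [
    "ChaseConfig",
    "CommunityConfig",
    "GrowthConfig",
    "IDEAL_CURVE_SLOPE",
    "IDEAL_CURVE_INTERCEPT",
    "simulate_qpcr_chase",
    "simulate_metatranscriptome",
    "simulate_class_cog_tables",
    "simulate_growth_curve",
]

# ideal standard curve used to turn simulated copy numbers into Cq values
IDEAL_CURVE_SLOPE = -1.0 / np.log10(2.0)  # -3.3219: perfect doubling
IDEAL_CURVE_INTERCEPT = 38.0  # Cq at a single copy

#: chase sampling times (minutes after rifampicin) of the isolate experiments
ISOLATE_TIMEPOINTS = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0)

#: post-QC sampling times of the community experiment
COMMUNITY_TIMEPOINTS = (0.0, 5.0, 40.0, 60.0)


def _lognormal_from_mean_sd(rng, mean: float, sd: float, size=None, minimum=None):
    """Draw lognormals with the given arithmetic mean and SD, optionally truncated."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    draw = rng.lognormal(mu, np.sqrt(sigma2), size=size)
    if minimum is not None:
        for _ in range(1000):
            bad = draw <= minimum
            if not np.any(bad):
                break
            draw = np.where(bad, rng.lognormal(mu, np.sqrt(sigma2), size=size), draw)
    return draw


@dataclass
class ChaseConfig:
    """Conditions of a simulated qPCR chase.

    ``lag_mean``/``lag_sd`` parameterize the peak : pre-treatment abundance
    ratio (isolate chases showed the pre-treatment pool on average 9.3 ± 7.4
    times below the post-treatment peak); the lag factor is drawn lognormal
    truncated at > 1 because its SD exceeds its mean.  ``noise_cv`` is the
    lognormal coefficient of variation applied to every measured abundance.
    """

    timepoints: tuple[float, ...] = ISOLATE_TIMEPOINTS
    delay_range: tuple[float, float] = (0.0, 5.0)
    lag_mean: float = 9.3
    lag_sd: float = 7.4
    noise_cv: float = 0.2
    peak_copies: float = 1.0e5
    background_fraction: float = 0.05
    standard_dilutions: tuple[float, ...] = tuple(10.0**k for k in range(7, -1, -1))
    seed: int = 0


def _copies_to_cq(copies: np.ndarray) -> np.ndarray:
    return IDEAL_CURVE_INTERCEPT + IDEAL_CURVE_SLOPE * np.log10(copies)


def simulate_qpcr_chase(
    genes: Mapping[str, float | None], config: ChaseConfig = ChaseConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR plate for a rifampicin chase.

    ``genes`` maps gene name to true half-life in minutes (``None`` = the
    pool does not decay).  Per gene the post-treatment abundance follows
    ``A(t) = peak · 2^(−max(t − delay, 0)/h)`` and the pre-treatment control
    is ``peak / lag_factor``.  Returns ``(plate, truth)``: the plate is a
    long table (sample_id, gene, material, known_copies, cq) with one row
    per replicate — cDNA and no-RT wells per timepoint plus the standard
    dilution series — and the truth table carries each gene's programmed
    half-life and class.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    truth: list[dict] = []
    for gene, h in genes.items():
        delay = rng.uniform(*config.delay_range)
        lag = float(
            _lognormal_from_mean_sd(rng, config.lag_mean, config.lag_sd, minimum=1.0)
        )
        for dil in config.standard_dilutions:
            cq = float(_copies_to_cq(np.array([dil]))[0])
            rows.append(
                dict(sample_id="std", gene=gene, material="standard",
                     known_copies=dil, cq=cq)
            )
        samples = [("pre", config.peak_copies / lag)]
        for t in config.timepoints:
            if h is None:
                a = config.peak_copies
            else:
                a = config.peak_copies * 2.0 ** (-max(t - delay, 0.0) / h)
            samples.append((f"t{t:g}", a))
        for sample_id, a in samples:
            noisy = a * _noise(rng, config.noise_cv, 3)
            for cq in _copies_to_cq(noisy):
                rows.append(
                    dict(sample_id=sample_id, gene=gene, material="cDNA",
                         known_copies=np.nan, cq=float(cq))
                )
            if config.background_fraction > 0:
                bg = a * config.background_fraction * _noise(rng, config.noise_cv, 3)
                for cq in _copies_to_cq(bg):
                    rows.append(
                        dict(sample_id=sample_id, gene=gene, material="RNA_noRT",
                             known_copies=np.nan, cq=float(cq))
                    )
        truth.append(
            dict(entity=gene,
                 true_halflife=np.nan if h is None else h,
                 true_class="no_decay" if h is None else "exponential",
                 delay_min=delay, lag_factor=lag, seed=config.seed)
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def _noise(rng, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=size)


@dataclass
class CommunityConfig:
    """Conditions of a simulated community chase.

    Family half-lives are lognormal with median ``halflife_median`` (28 min)
    and log-SD ``halflife_sigma`` chosen so ~95% of draws fall inside the
    9–400 min range of observed family half-lives; ``resistant_fraction``
    of families do not decay (rifampicin resistance).  rRNA pools decay with
    the family half-life times ``rrna_halflife_multiplier`` (quasi-stable).
    Reads are drawn multinomially from the combined mRNA + rRNA pool at a
    per-sample depth uniform over ``depth_range``; the community's initial
    mRNA fraction is drawn once per run from ``mrna_fraction_range``, and
    the per-sample fraction then declines as mRNA decays during the chase —
    as in shotgun sequencing, where the split is a property of the RNA pool,
    not of the instrument.  ``noise_cv`` adds optional lognormal noise to
    the expected pools on top of the counting noise (0 by default: the
    multinomial draw is the measurement noise of count data).
    """

    n_families: int = 100
    timepoints: tuple[float, ...] = COMMUNITY_TIMEPOINTS
    include_pre: bool = True
    halflife_median: float = 28.0
    halflife_sigma: float = 0.6
    resistant_fraction: float = 0.16
    rrna_halflife_multiplier: float = 20.0
    depth_range: tuple[float, float] = (3.2e5, 2.2e6)
    mrna_fraction_range: tuple[float, float] = (0.563, 0.935)
    abundance_sigma: float = 1.0
    expression_sigma: float = 1.5
    lag_mean: float = 6.1
    lag_sd: float = 8.0
    delay_range: tuple[float, float] = (0.0, 5.0)
    noise_cv: float = 0.0
    n_classes: int = 5
    n_subcategories: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValidationError("resistant_fraction must lie in [0, 1]")
        if self.depth_range[0] <= 0:
            raise ValidationError("depth_range must be positive")
        if self.rrna_halflife_multiplier < 1:
            raise ValidationError("rrna_halflife_multiplier must be >= 1")


_FAMILY_PATH = "Bacteria;Proteobacteria;Gammaproteobacteria;SimOrder;SimFamily{:03d}"


def _sample_columns(config: CommunityConfig) -> list[str]:
    cols = [f"{t:g}" for t in config.timepoints]
    return ([PRE_LABEL] + cols) if config.include_pre else cols


def _draw_halflives(rng, config: CommunityConfig, n: int):
    h = rng.lognormal(np.log(config.halflife_median), config.halflife_sigma, size=n)
    resistant = rng.random(n) < config.resistant_fraction
    return h, resistant


def _sample_combined(
    rng, m_pool: np.ndarray, r_pool: np.ndarray, depth: int, noise_cv: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``depth`` reads from the combined mRNA + rRNA pool."""
    pools = np.concatenate([m_pool, r_pool])
    noisy = pools * _noise(rng, noise_cv, pools.shape)
    counts = rng.multinomial(depth, noisy / noisy.sum())
    return counts[: len(m_pool)], counts[len(m_pool):]


def simulate_metatranscriptome(
    config: CommunityConfig = CommunityConfig(),
) -> tuple[AnnotatedCounts, AnnotatedCounts, pd.DataFrame]:
    """Simulate paired family-level mRNA/rRNA count tables plus truth.

    Decaying families follow ``pool(t) = a · e · 2^(−max(t − delay, 0)/h)``
    with the pre-treatment pool ``a · e / lag_factor``; resistant families
    stay constant.  ``e`` is a per-family expression level (lognormal,
    ``expression_sigma``): real taxa differ by orders of magnitude in mRNA
    per unit rRNA, which is what keeps the rank structure of ratio profiles
    stable across chase samples.  rRNA pools decay with the multiplied
    half-life and are not lagged (rRNA is quasi-stable and plentiful before
    treatment).  Column sums of mRNA + rRNA equal the drawn per-sample
    depth exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_families
    features = [_FAMILY_PATH.format(i) for i in range(n)]
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    abundance /= abundance.sum()
    expression = rng.lognormal(0.0, config.expression_sigma, size=n)
    expression /= expression.mean()
    halflives, resistant = _draw_halflives(rng, config, n)
    delays = rng.uniform(*config.delay_range, size=n)
    lags = _lognormal_from_mean_sd(rng, config.lag_mean, config.lag_sd, size=n, minimum=1.0)

    cols = _sample_columns(config)
    mrna = pd.DataFrame(0, index=features, columns=cols, dtype=int)
    rrna = pd.DataFrame(0, index=features, columns=cols, dtype=int)
    f0 = rng.uniform(*config.mrna_fraction_range)  # initial community mRNA fraction
    rrna_scale = (1.0 - f0) / f0  # rRNA pool size relative to mRNA pool at the peak
    for col in cols:
        expr_ab = abundance * expression
        if col == PRE_LABEL:
            m_pool = np.where(resistant, expr_ab, expr_ab / lags)
            r_pool = abundance.copy()
        else:
            t = float(col)
            decay = 2.0 ** (-np.maximum(t - delays, 0.0) / halflives)
            m_pool = np.where(resistant, expr_ab, expr_ab * decay)
            r_pool = abundance * 2.0 ** (
                -t / (halflives * config.rrna_halflife_multiplier)
            )
        depth = int(rng.integers(int(config.depth_range[0]), int(config.depth_range[1]) + 1))
        mrna[col], rrna[col] = _sample_combined(
            rng, m_pool, rrna_scale * r_pool, depth, config.noise_cv
        )

    truth = pd.DataFrame(
        dict(
            entity=features,
            true_halflife=np.where(resistant, np.nan, halflives),
            true_class=np.where(resistant, "no_decay", "exponential"),
            abundance=abundance,
            expression=expression,
            delay_min=delays,
            lag_factor=lags,
            seed=config.seed,
        )
    )
    return (
        AnnotatedCounts(mrna, "mRNA", PRE_LABEL if config.include_pre else None),
        AnnotatedCounts(rrna, "rRNA", PRE_LABEL if config.include_pre else None),
        truth,
    )


_CLASS_NAMES = (
    "Gammaproteobacteria", "Alphaproteobacteria", "Bacilli",
    "Betaproteobacteria", "Actinobacteria",
)

#: COG subcategory base half-life span emulating the functional analysis
COG_HALFLIFE_RANGE = (9.0, 134.0)


def simulate_class_cog_tables(
    config: CommunityConfig = CommunityConfig(),
    class_sigma_range: tuple[float, float] = (0.15, 0.55),
) -> tuple[AnnotatedCounts, AnnotatedCounts, pd.DataFrame]:
    """Simulate class × COG-subcategory tables plus truth.

    Each subcategory gets a base half-life log-uniform over
    ``COG_HALFLIFE_RANGE`` (9–134 min); per class the half-life is the base
    times a lognormal factor whose log-SD grows linearly with the base
    half-life across ``class_sigma_range`` — short-lived functional groups
    are conserved across classes, long-lived ones variable, so the CV of a
    subcategory scales with its mean.  rRNA is keyed by bare class name,
    mRNA by ``Class|letter``.
    """
    rng = np.random.default_rng(config.seed + 1)
    classes = list(_CLASS_NAMES[: config.n_classes])
    if len(classes) < config.n_classes:
        classes += [f"SimClass{i}" for i in range(len(classes), config.n_classes)]
    subcats = list(COG_SUBCATEGORIES[: config.n_subcategories])

    lo, hi = COG_HALFLIFE_RANGE
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(subcats)))
    rel = (np.log(base) - np.log(lo)) / (np.log(hi) - np.log(lo))
    sigma = class_sigma_range[0] + rel * (class_sigma_range[1] - class_sigma_range[0])

    class_ab = rng.lognormal(0.0, 0.5, size=len(classes))
    class_ab /= class_ab.sum()
    share = rng.lognormal(0.0, 0.5, size=(len(classes), len(subcats)))
    share /= share.sum(axis=1, keepdims=True)

    halflives = np.empty((len(classes), len(subcats)))
    for j in range(len(subcats)):
        halflives[:, j] = base[j] * np.exp(rng.normal(0.0, sigma[j], size=len(classes)))
    delays = rng.uniform(*config.delay_range, size=(len(classes), len(subcats)))
    rrna_h = config.halflife_median * config.rrna_halflife_multiplier

    cols = _sample_columns(config)
    m_features = [f"{c}|{s}" for c in classes for s in subcats]
    mrna = pd.DataFrame(0, index=m_features, columns=cols, dtype=int)
    rrna = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    lag = config.lag_mean
    f0 = rng.uniform(*config.mrna_fraction_range)
    rrna_scale = (1.0 - f0) / f0
    for col in cols:
        if col == PRE_LABEL:
            m_pool = (class_ab[:, None] * share) / lag
            r_pool = class_ab.copy()
        else:
            t = float(col)
            decay = 2.0 ** (-np.maximum(t - delays, 0.0) / halflives)
            m_pool = class_ab[:, None] * share * decay
            r_pool = class_ab * 2.0 ** (-t / rrna_h)
        depth = int(rng.integers(int(config.depth_range[0]), int(config.depth_range[1]) + 1))
        mrna[col], rrna[col] = _sample_combined(
            rng, m_pool.ravel(), rrna_scale * r_pool, depth, config.noise_cv
        )

    truth = pd.DataFrame(
        dict(
            entity=m_features,
            true_halflife=halflives.ravel(),
            true_class="exponential",
            abundance=(class_ab[:, None] * share).ravel(),
            seed=config.seed,
        )
    )
    pre = PRE_LABEL if config.include_pre else None
    return AnnotatedCounts(mrna, "mRNA", pre), AnnotatedCounts(rrna, "rRNA", pre), truth


@dataclass
class GrowthConfig:
    """Piecewise growth curve: lag, exponential (doubling time G), stationary."""

    generation_time_h: float = 3.0
    lag_h: float = 6.0
    log_doublings: float = 5.0
    stationary_h: float = 12.0
    n0: float = 1.0e6
    sample_interval_h: float = 2.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generation_time_h <= 0:
            raise ValidationError("generation time must be positive")


def simulate_growth_curve(config: GrowthConfig = GrowthConfig()) -> tuple[pd.DataFrame, float]:
    """Simulate a batch-culture growth curve; returns (curve, true G).

    The curve holds time (hours), cell abundance (cells/mL, lognormal noise
    applied) and the phase label of each sample; the exponential segment
    doubles every ``generation_time_h`` hours.
    """
    rng = np.random.default_rng(config.seed)
    g = config.generation_time_h
    t_log_end = config.lag_h + config.log_doublings * g
    t_end = t_log_end + config.stationary_h
    times = np.arange(0.0, t_end + 1e-9, config.sample_interval_h)
    rows = []
    for t in times:
        if t <= config.lag_h:
            n, phase = config.n0, "lag"
        elif t <= t_log_end:
            n, phase = config.n0 * 2.0 ** ((t - config.lag_h) / g), "log"
        else:
            n, phase = config.n0 * 2.0**config.log_doublings, "stationary"
        rows.append(dict(time_h=t, cells_per_ml=n * float(_noise(rng, config.noise_cv, ())), phase=phase))
    return pd.DataFrame(rows), g
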