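"""Metatranscriptome mRNA:rRNA decay pipeline.

Consumes paired annotated count tables (features = taxonomic family paths or
``Class|COG-subcategory`` keys; columns = chase timepoints; one table of
mRNA assignments, one of rRNA assignments), applies sample-level QC,
normalizes mRNA by rRNA per feature and timepoint — cancelling sequencing
depth and cell abundance — and estimates half-lives with the two-phase
decay model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decay import DecayClass, DecayFit, ExpressionSeries, FitSettings, fit_two_phase
from .errors import QcAbortError, ValidationError

__all__ = [
    "AnnotatedCounts",
    "QcReport",
    "FeatureHalflife",
    "COG_SUBCATEGORIES",
    "qc_filter_samples",
    "mrna_rrna_ratio",
    "family_relative_abundance",
    "estimate_family_halflives",
    "estimate_class_cog_halflives",
]

#: one-letter COG subcategories covered by the class-level functional analysis
COG_SUBCATEGORIES = tuple("VNTUMODFCHGPEIQJKL")

PRE_LABEL = "pre"


@dataclass
class AnnotatedCounts:
    """Feature × timepoint count matrix for one RNA type.

    ``counts`` has unique feature keys as index and timepoint labels as
    columns; the optional pre-treatment control column (taken before
    rifampicin addition) is named by ``pre_col`` and every other column
    label must parse as minutes since rifampicin addition.
    """

    counts: pd.DataFrame
    rna_type: str
    pre_col: str | None = PRE_LABEL

    def __post_init__(self) -> None:
        if self.rna_type not in ("mRNA", "rRNA"):
            raise ValidationError(f"rna_type must be mRNA or rRNA, got {self.rna_type!r}")
        self.counts = self.counts.copy()
        self.counts.columns = [str(c) for c in self.counts.columns]
        if self.pre_col is not None and self.pre_col not in self.counts.columns:
            self.pre_col = None
        if self.counts.index.duplicated().any():
            raise ValidationError("feature keys must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        for c in self.post_cols:
            try:
                float(c)
            except ValueError:
                raise ValidationError(
                    f"column {c!r} is neither the pre-treatment column nor minutes"
                ) from None

    @property
    def post_cols(self) -> list[str]:
        return [c for c in self.counts.columns if c != self.pre_col]

    @property
    def post_times(self) -> np.ndarray:
        return np.array([float(c) for c in self.post_cols])

    def subset_cols(self, cols: list[str]) -> "AnnotatedCounts":
        pre = self.pre_col if self.pre_col in cols else None
        return AnnotatedCounts(self.counts[cols], self.rna_type, pre)


def _check_paired(mrna: AnnotatedCounts, rrna: AnnotatedCounts) -> None:
    if list(mrna.counts.columns) != list(rrna.counts.columns):
        raise ValidationError(
            "mRNA and rRNA tables must share the timepoint columns; got "
            f"{list(mrna.counts.columns)} vs {list(rrna.counts.columns)}"
        )


@dataclass
class QcReport:
    """Per-sample QC metrics and the retained timepoint set."""

    per_sample: pd.DataFrame  # index sample, cols mrna_fraction, retained_fraction, disagreement, outlier, dropped
    retained_cols: list[str]


@dataclass
class FeatureHalflife:
    """Ratio series, decay fit and (families) relative abundance for one feature."""

    feature: str
    series: ExpressionSeries
    fit: DecayFit
    relative_abundance_mean: float | None = None
    relative_abundance_sd: float | None = None


def mrna_rrna_ratio(
    mrna: AnnotatedCounts, rrna: AnnotatedCounts, feature: str
) -> ExpressionSeries:
    """Per-timepoint mRNA:rRNA ratio series for one feature.

    Timepoints where either count is zero are flagged undetected (a zero
    rRNA count gives no denominator, a zero mRNA count no signal); the ratio
    is reported as 0 there and the flag carries the information.  Raises
    ``KeyError`` when the feature is missing from either table (the caller
    counts such features outside the jointly assigned set).
    """
    _check_paired(mrna, rrna)
    m = mrna.counts.loc[feature]
    r = rrna.counts.loc[feature]
    cols = mrna.post_cols
    mv = m[cols].to_numpy(dtype=float)
    rv = r[cols].to_numpy(dtype=float)
    detected = (mv > 0) & (rv > 0)
    values = np.divide(mv, rv, out=np.zeros_like(mv), where=rv > 0)
    values[~detected] = 0.0
    pre_value = None
    if mrna.pre_col is not None and rrna.pre_col is not None:
        m0 = float(m[mrna.pre_col])
        r0 = float(r[rrna.pre_col])
        if m0 > 0 and r0 > 0:
            pre_value = m0 / r0
    return ExpressionSeries(
        entity_id=feature,
        timepoints=mrna.post_times,
        values=values,
        detected=detected,
        pre_treatment_value=pre_value,
    )


def family_relative_abundance(rrna: AnnotatedCounts) -> pd.DataFrame:
    """Mean ± SD fraction of total rRNA per family across samples.

    Each sample's family counts are divided by that sample's rRNA total;
    empty samples are excluded with a warning.  Returns a frame indexed by
    feature with columns mean and sd; per-sample fractions sum to 1.
    """
    totals = rrna.counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"samples with zero rRNA excluded: {empty}", stacklevel=2)
    kept = rrna.counts.loc[:, totals > 0]
    fractions = kept / kept.sum(axis=0)
    return pd.DataFrame(
        {"mean": fractions.mean(axis=1), "sd": fractions.std(axis=1, ddof=1)}
    )


def _disagreement(ratios: pd.DataFrame) -> pd.Series:
    """1 − Spearman correlation of each sample's ratio profile vs the median profile."""
    median_profile = ratios.median(axis=1)
    out = {}
    for col in ratios.columns:
        rho = stats.spearmanr(ratios[col], median_profile).statistic
        out[col] = 1.0 - (0.0 if np.isnan(rho) else rho)
    return pd.Series(out)


def qc_filter_samples(
    mrna: AnnotatedCounts,
    rrna: AnnotatedCounts,
    retention_min: float = 0.5,
    disagreement_max: float = 0.30,
    original_mrna_reads: dict[str, float] | None = None,
) -> QcReport:
    """Screen chase samples before decay fitting.

    Two rules: (1) samples keeping <= ``retention_min`` of their pre-QC mRNA
    reads are dropped (``original_mrna_reads`` maps sample label to the raw
    read count; samples without an entry are assumed lossless); (2) samples
    whose family-level ratio profile disagrees with the cohort by more than
    ``disagreement_max`` are dropped as outliers, where disagreement is one
    minus the Spearman rank correlation between the sample's mRNA:rRNA
    profile and the element-wise median profile, computed over features
    detected in every sample.  The pre-treatment sample participates in QC
    like any other.  Fewer than 3 surviving post-treatment samples abort
    the pipeline.
    """
    _check_paired(mrna, rrna)
    cols = list(mrna.counts.columns)
    if len(cols) < 3:
        raise ValidationError("need >= 3 timepoints for QC")

    m_tot = mrna.counts.sum(axis=0)
    r_tot = rrna.counts.sum(axis=0)
    mrna_fraction = m_tot / (m_tot + r_tot)

    retained_fraction = pd.Series(1.0, index=cols)
    if original_mrna_reads:
        for c, orig in original_mrna_reads.items():
            if c in retained_fraction.index and orig > 0:
                retained_fraction[c] = float(m_tot[c]) / float(orig)

    detected_everywhere = ((mrna.counts > 0) & (rrna.counts > 0)).all(axis=1)
    ratios = (
        mrna.counts.loc[detected_everywhere] / rrna.counts.loc[detected_everywhere]
    )
    if len(ratios) < 3:
        raise QcAbortError(
            "fewer than 3 features detected in every sample; disagreement "
            "statistic is meaningless"
        )
    disagreement = _disagreement(ratios)

    low_retention = retained_fraction <= retention_min
    outlier = disagreement > disagreement_max
    dropped = low_retention | outlier

    report = pd.DataFrame(
        {
            "mrna_fraction": mrna_fraction,
            "retained_fraction": retained_fraction,
            "disagreement": disagreement,
            "outlier": outlier,
            "dropped": dropped,
        }
    )
    retained = [c for c in cols if not dropped[c]]
    n_post = len([c for c in retained if c != mrna.pre_col])
    if n_post < 3:
        failing = [c for c in cols if dropped[c]]
        raise QcAbortError(
            f"only {n_post} post-treatment samples survive QC "
            f"(dropped: {', '.join(failing)})",
            failing_samples=failing,
        )
    return QcReport(per_sample=report, retained_cols=retained)


def estimate_family_halflives(
    mrna: AnnotatedCounts,
    rrna: AnnotatedCounts,
    settings: FitSettings = FitSettings(),
    retained_cols: list[str] | None = None,
) -> tuple[list[FeatureHalflife], dict[str, int]]:
    """Fit a half-life per family from its mRNA:rRNA ratio series.

    Families jointly assigned (non-zero total in both tables) are fitted;
    a family undetected at any retained post-treatment timepoint is
    excluded as insufficient detection, and families whose fit is not
    exponential (no decay or poor fit) are tallied together, mirroring the
    exclusion accounting of family-level chase analyses.  Returns the fits
    plus the tally ``{jointly_assigned, excluded_detection,
    excluded_non_exponential, retained_exponential}``.
    """
    _check_paired(mrna, rrna)
    if retained_cols is not None:
        mrna = mrna.subset_cols(retained_cols)
        rrna = rrna.subset_cols(retained_cols)
    rel_ab = family_relative_abundance(rrna)

    jointly = [
        f
        for f in mrna.counts.index
        if f in rrna.counts.index
        and mrna.counts.loc[f].sum() > 0
        and rrna.counts.loc[f].sum() > 0
    ]
    results: list[FeatureHalflife] = []
    tally = {
        "jointly_assigned": len(jointly),
        "excluded_detection": 0,
        "excluded_non_exponential": 0,
        "retained_exponential": 0,
    }
    for f in jointly:
        series = mrna_rrna_ratio(mrna, rrna, f)
        if not bool(np.all(series.detected)):
            fit = DecayFit(entity_id=f)  # insufficient_data
            tally["excluded_detection"] += 1
        else:
            fit = fit_two_phase(series, settings)
            if fit.decay_class == DecayClass.EXPONENTIAL:
                tally["retained_exponential"] += 1
            else:
                tally["excluded_non_exponential"] += 1
        results.append(
            FeatureHalflife(
                feature=f,
                series=series,
                fit=fit,
                relative_abundance_mean=float(rel_ab["mean"].get(f, np.nan)),
                relative_abundance_sd=float(rel_ab["sd"].get(f, np.nan)),
            )
        )
    return results, tally


def _class_of(feature: str) -> str:
    return feature.split("|", 1)[0]


def estimate_class_cog_halflives(
    mrna: AnnotatedCounts,
    rrna: AnnotatedCounts,
    min_rrna: float = 1000.0,
    min_mrna: float = 200.0,
    settings: FitSettings = FitSettings(),
    retained_cols: list[str] | None = None,
) -> list[FeatureHalflife]:
    """Half-lives of ``Class|COG-subcategory`` features for abundant classes.

    mRNA features are keyed ``ClassName|X`` with X a COG subcategory letter;
    rRNA carries no functional label, so the rRNA table may be keyed by bare
    class name or by ``Class|X`` (aggregated to class) and the class-level
    rRNA count is the ratio denominator.  Classes whose mean rRNA count per
    sample is <= ``min_rrna`` or mean mRNA count <= ``min_mrna`` are too
    sparse for subcategory-level fits and are excluded.
    """
    if retained_cols is not None:
        mrna = mrna.subset_cols(retained_cols)
        rrna = rrna.subset_cols(retained_cols)
    if list(mrna.counts.columns) != list(rrna.counts.columns):
        raise ValidationError("mRNA and rRNA tables must share the timepoint columns")

    for f in mrna.counts.index:
        if "|" not in f:
            raise ValidationError(f"mRNA feature {f!r} is not of the form Class|COG")
        letter = f.split("|", 1)[1]
        if letter not in COG_SUBCATEGORIES:
            raise ValidationError(
                f"unknown COG subcategory {letter!r} in feature {f!r}"
            )

    class_rrna = rrna.counts.groupby(_class_of).sum()
    class_mrna = mrna.counts.groupby(_class_of).sum()

    eligible = [
        c
        for c in class_mrna.index
        if c in class_rrna.index
        and class_rrna.loc[c].mean() > min_rrna
        and class_mrna.loc[c].mean() > min_mrna
    ]

    results: list[FeatureHalflife] = []
    post_cols = mrna.post_cols
    for f in mrna.counts.index:
        cls = _class_of(f)
        if cls not in eligible:
            continue
        mv = mrna.counts.loc[f, post_cols].to_numpy(dtype=float)
        rv = class_rrna.loc[cls, post_cols].to_numpy(dtype=float)
        detected = (mv > 0) & (rv > 0)
        values = np.divide(mv, rv, out=np.zeros_like(mv), where=rv > 0)
        values[~detected] = 0.0
        pre_value = None
        if mrna.pre_col is not None and rrna.pre_col is not None:
            m0 = float(mrna.counts.loc[f, mrna.pre_col])
            r0 = float(class_rrna.loc[cls, rrna.pre_col])
            if m0 > 0 and r0 > 0:
                pre_value = m0 / r0
        series = ExpressionSeries(
            entity_id=f,
            timepoints=mrna.post_times,
            values=values,
            detected=detected,
            pre_treatment_value=pre_value,
        )
        if not bool(np.all(detected)):
            fit = DecayFit(entity_id=f)
        else:
            fit = fit_two_phase(series, settings)
        results.append(FeatureHalflife(feature=f, series=series, fit=fit))
    return results
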