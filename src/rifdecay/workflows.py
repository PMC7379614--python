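"""End-to-end workflows tying the pipeline stages together.

Two workflows mirror the two experimental designs: ``run_qpcr_workflow``
(standards → quantification → background subtraction → two-phase fit →
t-test against the 16S rRNA reference) and ``run_metat_workflow`` (QC →
mRNA:rRNA ratios → fits → cohort summaries, optionally the class × COG
table and the CV-vs-mean regression).  Each run can write its tables plus a
JSON provenance record (config, seed, thresholds) sufficient to reproduce
the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as rio
from .decay import DecayClass, DecayFit, ExpressionSeries, FitSettings, fit_two_phase, fits_to_records
from .errors import ValidationError
from .metat import (
    AnnotatedCounts,
    estimate_class_cog_halflives,
    estimate_family_halflives,
    qc_filter_samples,
)
from .qpcr import fit_standard_curve, quantify_triplicate, subtract_dna_background
from .stats import cv_vs_mean_regression, one_sample_ttest, summarize_halflives

logger = logging.getLogger("rifdecay")

__all__ = ["run_qpcr_workflow", "run_metat_workflow", "QpcrResult", "MetatResult"]


@dataclasses.dataclass
class QpcrResult:
    fits: list[DecayFit]
    fit_table: pd.DataFrame  # gene, condition, m, R2, T1/2, class
    abundance_table: pd.DataFrame
    ttest: dict | None


@dataclasses.dataclass
class MetatResult:
    qc: pd.DataFrame
    retained_cols: list[str]
    family_table: pd.DataFrame
    tally: dict[str, int]
    summary: dict | None
    cog_table: pd.DataFrame | None = None
    cv_regression: dict | None = None


def _write_provenance(outdir: Path, payload: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=2, default=str))


def _sample_time(sample_id: str) -> float | None:
    """Parse 'tX' sample labels to minutes; 'pre' -> None."""
    if sample_id == "pre":
        return None
    if sample_id.startswith("t"):
        try:
            return float(sample_id[1:])
        except ValueError:
            pass
    raise ValidationError(f"cannot parse timepoint from sample_id {sample_id!r}")


def run_qpcr_workflow(
    plate: pd.DataFrame | str | Path,
    settings: FitSettings = FitSettings(),
    condition: str = "",
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> QpcrResult:
    """Run the isolate chase workflow on one qPCR plate.

    Per gene: fit the standard curve from its dilution series (genes without
    standards are skipped with a warning), quantify cDNA and no-RT
    triplicates on the copies scale, subtract the residual-DNA background,
    assemble the chase series (the ``pre`` sample becomes the pre-treatment
    control) and fit the two-phase decay model.  If the plate carries a
    16S rRNA assay with an exponential fit, the mRNA half-lives are tested
    against it with a one-sample t-test.
    """
    if not isinstance(plate, pd.DataFrame):
        plate = rio.read_plate_table(plate)
    if len(plate) == 0:
        raise ValidationError("empty plate")

    abundance_rows = []
    fits: list[DecayFit] = []
    for gene, gdf in plate.groupby("gene", sort=False):
        std = gdf[gdf.material == "standard"]
        if len(std) == 0:
            warnings.warn(f"gene {gene!r} has no standards; skipped", stacklevel=2)
            logger.warning("gene %s skipped: no standards", gene)
            continue
        std_pairs = [
            (float(c), float(sub["cq"].mean()))
            for c, sub in std.groupby("known_copies")
        ]
        curve = fit_standard_curve(std_pairs, warn_efficiency=False)

        series_points: dict[str, dict] = {}
        for sample_id, sdf in gdf[gdf.material == "cDNA"].groupby("sample_id"):
            q = quantify_triplicate(sample_id, gene, sdf["cq"], curve)
            bg_df = gdf[(gdf.material == "RNA_noRT") & (gdf.sample_id == sample_id)]
            bg_copies = 0.0
            if len(bg_df):
                bg_copies = quantify_triplicate(sample_id, gene, bg_df["cq"], curve).copies_mean
            corrected, frac, over = subtract_dna_background(q.copies_mean, bg_copies)
            series_points[sample_id] = dict(
                copies=corrected, copies_sd=q.copies_sd, background_fraction=frac,
                over_background=over,
            )
            abundance_rows.append(
                dict(sample_id=sample_id, gene=gene, copies_mean=corrected,
                     copies_sd=q.copies_sd, background_fraction=frac)
            )

        pre_value = series_points.pop("pre", {}).get("copies")
        times = sorted((_sample_time(s), s) for s in series_points)
        series = ExpressionSeries(
            entity_id=gene,
            condition=condition,
            timepoints=[t for t, _ in times],
            values=[series_points[s]["copies"] for _, s in times],
            pre_treatment_value=pre_value,
        )
        fits.append(fit_two_phase(series, settings))

    fit_table = pd.DataFrame(fits_to_records(fits)).rename(
        columns={"entity_id": "gene", "slope_ln": "m", "r_squared": "R2",
                 "half_life_min": "T_half_min"}
    )
    ttest = None
    ref = [f for f in fits if f.entity_id == "16S rRNA"]
    mrna_fits = [f for f in fits if f.entity_id != "16S rRNA"]
    if ref and len(mrna_fits) >= 2:
        mu = ref[0].half_life_min
        mu = 100.0 if mu is None else mu  # no-decay reference -> surrogate
        values = [
            f.half_life_min if f.decay_class == DecayClass.EXPONENTIAL else None
            for f in mrna_fits
        ]
        res = one_sample_ttest(values, mu)
        ttest = dataclasses.asdict(res)

    result = QpcrResult(
        fits=fits,
        fit_table=fit_table,
        abundance_table=pd.DataFrame(abundance_rows),
        ttest=ttest,
    )
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        fit_table.to_csv(outdir / "fits.tsv", sep="\t", index=False)
        result.abundance_table.to_csv(outdir / "abundances.tsv", sep="\t", index=False)
        if ttest:
            (outdir / "ttest.json").write_text(json.dumps(ttest, indent=2))
        _write_provenance(
            outdir,
            dict(workflow="qpcr", settings=dataclasses.asdict(settings),
                 condition=condition, seed=seed, n_genes=len(fits)),
        )
    return result


def run_metat_workflow(
    mrna: AnnotatedCounts | str | Path,
    rrna: AnnotatedCounts | str | Path,
    settings: FitSettings = FitSettings(),
    retention_min: float = 0.5,
    disagreement_max: float = 0.30,
    original_mrna_reads: Mapping[str, float] | None = None,
    cog_mrna: AnnotatedCounts | str | Path | None = None,
    cog_rrna: AnnotatedCounts | str | Path | None = None,
    min_rrna: float = 1000.0,
    min_mrna: float = 200.0,
    summary_threshold_min: float = 10.0,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> MetatResult:
    """Run the community chase workflow on paired count tables.

    QC screens the samples (retention and profile-disagreement rules), the
    surviving timepoints feed the per-family ratio fits, and the exponential
    half-lives are summarized (median, range, fraction below the threshold).
    If class × COG tables are supplied, subcategory half-lives and the
    CV-vs-mean regression are computed as well.
    """
    if not isinstance(mrna, AnnotatedCounts):
        mrna = rio.read_counts_table(mrna, "mRNA")
    if not isinstance(rrna, AnnotatedCounts):
        rrna = rio.read_counts_table(rrna, "rRNA")

    qc = qc_filter_samples(
        mrna, rrna, retention_min, disagreement_max,
        dict(original_mrna_reads) if original_mrna_reads else None,
    )
    results, tally = estimate_family_halflives(
        mrna, rrna, settings, retained_cols=qc.retained_cols
    )
    family_rows = []
    for r in results:
        rec = fits_to_records([r.fit])[0]
        rec.update(
            feature=r.feature,
            relative_abundance_mean=r.relative_abundance_mean,
            relative_abundance_sd=r.relative_abundance_sd,
        )
        del rec["entity_id"], rec["condition"]
        family_rows.append(rec)
    family_table = pd.DataFrame(family_rows)

    halflives = [
        r.fit.half_life_min
        for r in results
        if r.fit.decay_class == DecayClass.EXPONENTIAL
    ]
    summary = None
    if halflives:
        summary = dataclasses.asdict(
            summarize_halflives(halflives, summary_threshold_min)
        )

    cog_table = None
    cv_reg = None
    if cog_mrna is not None and cog_rrna is not None:
        if not isinstance(cog_mrna, AnnotatedCounts):
            cog_mrna = rio.read_counts_table(cog_mrna, "mRNA")
        if not isinstance(cog_rrna, AnnotatedCounts):
            cog_rrna = rio.read_counts_table(cog_rrna, "rRNA")
        cog_results = estimate_class_cog_halflives(
            cog_mrna, cog_rrna, min_rrna, min_mrna, settings
        )
        rows = []
        for r in cog_results:
            rec = fits_to_records([r.fit])[0]
            rec["feature"] = r.feature
            del rec["entity_id"], rec["condition"]
            rows.append(rec)
        cog_table = pd.DataFrame(rows)
        if len(cog_table):
            exp = cog_table[cog_table.decay_class == DecayClass.EXPONENTIAL].copy()
            exp["class"] = exp.feature.str.split("|").str[0]
            exp["subcat"] = exp.feature.str.split("|").str[1]
            matrix = exp.pivot_table(
                index="subcat", columns="class", values="half_life_min"
            )
            try:
                reg, per_subcat = cv_vs_mean_regression(matrix)
                cv_reg = dataclasses.asdict(reg)
            except Exception as e:  # degenerate cohorts: too few groups, zero CVs

                logger.warning("CV regression not computed: %s", e)

    result = MetatResult(
        qc=qc.per_sample,
        retained_cols=qc.retained_cols,
        family_table=family_table,
        tally=tally,
        summary=summary,
        cog_table=cog_table,
        cv_regression=cv_reg,
    )
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        qc.per_sample.to_csv(outdir / "qc_report.tsv", sep="\t", index_label="sample")
        family_table.to_csv(outdir / "family_fits.tsv", sep="\t", index=False)
        (outdir / "exclusion_tally.json").write_text(json.dumps(tally, indent=2))
        if summary:
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        if cog_table is not None:
            cog_table.to_csv(outdir / "cog_fits.tsv", sep="\t", index=False)
        if cv_reg:
            (outdir / "cv_regression.json").write_text(json.dumps(cv_reg, indent=2))
        _write_provenance(
            outdir,
            dict(
                workflow="metat", settings=dataclasses.asdict(settings),
                retention_min=retention_min, disagreement_max=disagreement_max,
                min_rrna=min_rrna, min_mrna=min_mrna,
                summary_threshold_min=summary_threshold_min,
                retained_cols=qc.retained_cols, seed=seed,
            ),
        )
    return result
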