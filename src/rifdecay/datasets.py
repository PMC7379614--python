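"""Published isolate half-life dataset.

The qPCR chase experiments on three marine bacterial isolates —
*Alcanivorax jadensis*, *Colwellia polaris* and *Croceibacter atlanticus*
grown at 4, 15 and 25 °C — yielded per-gene half-lives (minutes), the slope
m of the log-linear fit (per minute, natural log) and its R².  Those values
are bundled here as the worked input for the statistics layer: one-sample
t-tests of the mRNA half-lives against the 16S rRNA reference, and
correlations of per-temperature mean half-lives with temperature and
generation time.

``halflife_min`` is NaN where the transcript pool showed no decay (the 16S
pool of *Alcanivorax* at 15 °C); the t-test convention replaces that entry
with 100 min.  The *rpoB* half-life of *Croceibacter* at 25 °C (46.34 min)
was flagged as an outlier and excluded from that condition's t-test.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

from .stats import CorrelationResult, TTestResult, one_sample_ttest, pearson

__all__ = [
    "isolate_halflife_table",
    "colwellia_generation_times",
    "ttest_vs_16s",
    "temperature_correlations",
    "CONDITIONS",
]

#: (isolate, temperature °C) conditions in plate order
CONDITIONS = [
    ("Alcanivorax", 4), ("Alcanivorax", 15), ("Alcanivorax", 25),
    ("Colwellia", 4), ("Colwellia", 15), ("Colwellia", 25),
    ("Croceibacter", 4), ("Croceibacter", 15), ("Croceibacter", 25),
]

# gene, isolate, temperature_c, r_squared, slope_per_min, halflife_min
# (halflife empty = no decay)
_TABLE = """\
gene,isolate,temperature_c,r_squared,slope_per_min,halflife_min
16S rRNA,Alcanivorax,4,0.32,-0.01,41.25
16S rRNA,Alcanivorax,15,0.10,0.01,
16S rRNA,Alcanivorax,25,0.58,-0.05,11.29
16S rRNA,Colwellia,4,0.59,-0.10,6.23
16S rRNA,Colwellia,15,0.22,-0.21,2.46
16S rRNA,Colwellia,25,0.92,-0.03,19.22
16S rRNA,Croceibacter,4,0.70,-0.02,34.09
16S rRNA,Croceibacter,15,1.00,-0.06,11.06
16S rRNA,Croceibacter,25,0.88,-0.17,4.41
atpF,Colwellia,4,0.91,-0.14,5.17
atpF,Colwellia,15,0.52,-0.35,1.69
atpF,Colwellia,25,0.94,-0.15,4.63
atpF,Croceibacter,4,0.99,-0.08,8.39
atpF,Croceibacter,15,0.99,-0.32,2.20
atpF,Croceibacter,25,0.99,-0.45,1.51
dnaK,Colwellia,4,0.60,-0.20,3.07
dnaK,Colwellia,15,0.50,-0.44,1.32
dnaK,Colwellia,25,0.997,-0.13,8.97
hflB,Alcanivorax,4,0.99,-0.22,6.33
hflB,Alcanivorax,15,0.99,-0.23,2.98
hflB,Alcanivorax,25,0.98,-0.05,15.15
pykA,Croceibacter,4,0.97,-0.12,6.20
pykA,Croceibacter,15,0.90,-0.15,4.47
pykA,Croceibacter,25,0.99,-0.36,1.97
rpoB,Colwellia,4,1.00,-0.15,4.57
rpoB,Colwellia,15,0.90,-0.72,1.03
rpoB,Colwellia,25,0.99,-0.15,4.73
rpoB,Croceibacter,4,1.00,-0.06,11.70
rpoB,Croceibacter,15,0.94,-0.10,6.45
rpoB,Croceibacter,25,0.98,-0.02,46.34
pssA,Alcanivorax,4,0.99,-0.09,7.91
pssA,Alcanivorax,15,0.92,-0.34,2.19
pssA,Alcanivorax,25,0.98,-0.02,35.51
pepA,Croceibacter,4,0.86,-0.14,5.04
pepA,Croceibacter,15,0.72,-0.23,2.65
pepA,Croceibacter,25,0.96,-0.36,2.01
recA,Colwellia,4,0.94,-0.47,1.54
recA,Colwellia,15,0.36,-0.38,1.45
recA,Colwellia,25,0.93,-0.13,5.10
thyA,Croceibacter,4,0.98,-0.36,2.06
thyA,Croceibacter,15,0.90,-0.18,4.16
thyA,Croceibacter,25,0.95,-0.32,2.11
clpP,Croceibacter,4,0.99,-0.16,4.37
clpP,Croceibacter,15,0.76,-0.13,4.81
clpP,Croceibacter,25,0.96,-0.49,1.47
"""

#: generation times (h) of the Colwellia isolate at 4, 15 and 25 °C
_COLWELLIA_G = {4: 11.68, 15: 3.77, 25: 9.50}

#: genes entering the per-temperature mean half-life used in the
#: temperature / generation-time correlations of each isolate
CORRELATION_GENES = {
    "Alcanivorax": ["hflB", "pssA"],
    "Colwellia": ["atpF", "dnaK", "rpoB", "recA"],
    "Croceibacter": ["atpF", "pykA", "rpoB", "pepA", "thyA", "clpP"],
}

#: per-condition t-test exclusions: (gene, isolate, temperature)
TTEST_EXCLUSIONS = [("rpoB", "Croceibacter", 25)]


def isolate_halflife_table() -> pd.DataFrame:
    """Per-gene fit results of the isolate chase experiments (long format)."""
    return pd.read_csv(StringIO(_TABLE))


def colwellia_generation_times() -> pd.Series:
    """Generation time (hours) of the Colwellia isolate by temperature."""
    return pd.Series(_COLWELLIA_G, name="generation_time_h")


def ttest_vs_16s(
    isolate: str, temperature_c: int, no_decay_replacement: float = 100.0
) -> TTestResult:
    """One-sample t-test of one condition's mRNA half-lives against its 16S rRNA.

    The 16S half-life is the reference mu (replaced by
    ``no_decay_replacement`` when the 16S pool showed no decay); flagged
    outlier genes are excluded.
    """
    df = isolate_halflife_table()
    cond = df[(df.isolate == isolate) & (df.temperature_c == temperature_c)]
    ref = cond[cond.gene == "16S rRNA"]["halflife_min"].iloc[0]
    mu = no_decay_replacement if np.isnan(ref) else float(ref)
    mrna = cond[cond.gene != "16S rRNA"]
    values = [None if np.isnan(v) else float(v) for v in mrna["halflife_min"]]
    excl = [
        i
        for i, g in enumerate(mrna["gene"])
        if (g, isolate, temperature_c) in TTEST_EXCLUSIONS
    ]
    return one_sample_ttest(values, mu, no_decay_replacement, exclusions=excl)


def _per_temperature_means(isolate: str) -> pd.Series:
    df = isolate_halflife_table()
    genes = CORRELATION_GENES[isolate]
    sub = df[(df.isolate == isolate) & (df.gene.isin(genes))]
    # the flagged rpoB outlier is also left out of the 25 °C mean
    for g, iso, temp in TTEST_EXCLUSIONS:
        sub = sub[~((sub.gene == g) & (sub.isolate == iso) & (sub.temperature_c == temp))]
    return sub.groupby("temperature_c")["halflife_min"].mean()


def temperature_correlations() -> dict[str, CorrelationResult]:
    """The four printed mean-half-life correlations of the isolate study.

    Keys: ``colwellia_generation_time`` (r ≈ 0.69), ``colwellia_temperature``
    (r ≈ 0.48), ``alcanivorax_temperature`` (r ≈ 0.74) and
    ``croceibacter_temperature`` (r ≈ −0.999).
    """
    col = _per_temperature_means("Colwellia")
    alc = _per_temperature_means("Alcanivorax")
    cro = _per_temperature_means("Croceibacter")
    g = colwellia_generation_times()
    temps = [4.0, 15.0, 25.0]
    return {
        "colwellia_generation_time": pearson(col[[4, 15, 25]], g[[4, 15, 25]]),
        "colwellia_temperature": pearson(col[[4, 15, 25]], temps),
        "alcanivorax_temperature": pearson(alc[[4, 15, 25]], temps),
        "croceibacter_temperature": pearson(cro[[4, 15, 25]], temps),
    }
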