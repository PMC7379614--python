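"""Fit the relative two-phase decay model to one expression series.

The series shows a delay phase (the 0-min point is below the 5-min peak)
followed by exponential decay; the fit anchors at the peak, picks the
window with the best log-linear fit, and converts the endpoints into a
half-life.
"""

from rifdecay import ExpressionSeries, fit_two_phase

series = ExpressionSeries(
    entity_id="example-transcript",
    timepoints=[0, 5, 40, 60],          # minutes after rifampicin addition
    values=[0.02, 0.1, 0.025, 0.0125],  # mRNA:rRNA ratio
    pre_treatment_value=0.015,          # control taken before rifampicin
)

fit = fit_two_phase(series)
print(f"window: {fit.t0_time:g} -> {fit.end_time:g} min ({fit.n_window} points)")
print(f"slope (ln/min): {fit.slope_ln:.4f}   R^2: {fit.r_squared:.3f}")
print(f"half-life: {fit.half_life_min:.2f} min   class: {fit.decay_class}")
# The peak at 5 min ends the delay phase; over the 5->60 min window the pool
# halves three times, giving T1/2 = 55/3 ~ 18.3 min.
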