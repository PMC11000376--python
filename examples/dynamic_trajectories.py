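"""The 20 dynamic descriptors of a single enhancement trajectory.

Takes a wash-in/washout style 4-point series (plain, arterial, portal
venous, equilibrium) and prints every dynamic feature family: integrated
moments, segment-wise relative change rates, and the linear / quadratic /
exponential fit parameters with their curvature summaries.
"""

from dynrad import (
    FeatureSeries,
    discrete_features,
    fit_exponential,
    fit_linear,
    fit_quadratic,
    integrated_features,
)

series = FeatureSeries("lesion-mean", [100.0, 185.0, 140.0, 112.0])
print("trajectory:", series.values.tolist(), "at t =", list(series.time_grid))

print("\nintegrated:", {k: round(v, 4) for k, v in integrated_features(series).items()})
print("discrete:  ", {k: round(v, 4) for k, v in discrete_features(series).items()})
k, d = fit_linear(series)
print(f"linear:     k={k:.4f}, d={d:.4f}")
print("quadratic: ", {k: round(v, 4) for k, v in fit_quadratic(series).items()})
print("exponential:", {k: round(v, 6) for k, v in fit_exponential(series).items()})
# RCR_seg1 = |185-100|/100 = 0.85 is the arterial wash-in fraction; the
# negative quadratic 'a' reflects the peaked (wash-in then washout) shape.
# With alpha < 0 the printed exponential-curvature form has a non-positive
# denominator over the whole window, so T_maxEK / EK_max_feature are NaN
# here (they are median-imputed at modeling time); pass
# corrected_curvature=True to fit_exponential for the exact curvature.
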