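"""Segmentation-robustness filtering with intraclass correlation.

Re-segments phantom lesions with two simulated readers (boundary jitter of
the masks), re-extracts the arterial-phase static features, and keeps only
features whose intra- and inter-observer ICC(2,1) both exceed 0.8.
"""

import pandas as pd

from dynrad import (
    SyntheticCohortConfig,
    extract_static_vector,
    generate_cohort,
    generate_reader_variants,
    icc_filter,
    znormalize,
)

cfg = SyntheticCohortConfig(n_patients=8, prevalence=0.5,
                            volume_shape=(22, 22, 22),
                            lesion_radius_range=(4.0, 6.0), seed=3)
stacks, _, _ = generate_cohort(cfg)


def arterial_features(stack_list):
    return pd.DataFrame([
        extract_static_vector(znormalize(st.volumes[1]), st.masks[1], "arterial").as_dict()
        for st in stack_list
    ])


repeat, second_reader = zip(*[
    generate_reader_variants(st, jitter_mm=0.4, seed=10 + i)
    for i, st in enumerate(stacks)
])
table = icc_filter(arterial_features(stacks),
                   arterial_features(list(repeat)),
                   arterial_features(list(second_reader)),
                   threshold=0.8)
print(f"features passing ICC > 0.8 (both readers): "
      f"{int(table['passed'].sum())} / {len(table)}")
print("\nleast reproducible features under mask jitter:")
print(table.nsmallest(5, "inter_observer_icc").round(3))
# Features sensitive to the exact lesion boundary (e.g. size-zone and
# run-length statistics on high-frequency wavelet bands) drop out first.
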