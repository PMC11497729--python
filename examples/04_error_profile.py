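"""Profile forecast error across the amyloid range with bootstrap bands.

A single global MAPE hides where a biomarker fails: an analyte can look
excellent simply because most of a cohort is amyloid negative.  The sliding
window (25 Centiloids wide, stepping 1 CL along the predicted burden axis)
recomputes MAPE locally, with a 1000-iteration participant bootstrap giving
95% bands, and two profiles can be compared window by window.
"""

import numpy as np

from amyloidcast import PipelineConfig, compare_profiles, run_pipeline
from amyloidcast.network import NetworkConfig

config = PipelineConfig(
    n=346, master_seed=42,
    analytes=["pT217_T217", "pT231_T231"],
    grid=[NetworkConfig(hidden_widths=(64, 64, 32), dropout_rate=0.1,
                        learning_rate=1e-2)],
)
report = run_pipeline(config)

for name, r in report.analytes.items():
    p = r.profile
    ok = ~np.isnan(p.mape_point)
    lo = p.window_centers[ok][0]
    print(f"{name}: global MAPE {r.global_mape:.1f}%, "
          f"MAPE below 40 CL {r.low_range_mape:.1f}%, "
          f"windows populated from {lo:.0f} CL")

cmp = compare_profiles(report.analytes["pT217_T217"].profile,
                       report.analytes["pT231_T231"].profile)
if cmp.a_better_ranges:
    s, e = cmp.a_better_ranges[0]
    print(f"pT217-like significantly outperforms pT231-like over {s:.0f}-{e:.0f} CL "
          f"(non-overlapping 95% bands)")
else:
    print("no window separates the two analytes significantly")
# The low-noise analyte wins at low burden; where its response plateaus the
# bands widen and the advantage disappears.
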