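"""Published reference summaries for the six-ISG panel.

These are the printed per-gene summary statistics of the healthy-control
cohorts used to calibrate the assay (a ten-donor qPCR cohort on the
fold-change scale, and fifteen/twenty-donor RNA-seq cohorts on the FPKM
scale), plus the twenty paired per-subject IFN scores measured on both
platforms. They serve as simulator presets, as worked-example inputs, and
as the inputs to the power/adequacy computations.

Note on the paired score table: in the printed source the two summary rows
(mean/SD/CV) are swapped relative to the column headers — the column whose
entries include 94.25 is the one with mean 19.83. Consumers should identify
columns by their recomputed summaries, not by header position.
"""

from __future__ import annotations

import pandas as pd

from .panel import DEFAULT_TARGETS

#: qPCR relative-quantity summaries for ten healthy donors (dimensionless
#: fold changes vs. a ten-donor pooled calibrator).
QPCR_CONTROL_N = 10
QPCR_CONTROL_SUMMARY = pd.DataFrame(
    {
        "mean": [4.57, 0.72, 2.18, 4.61, 1.24, 5.14],
        "sd": [1.04, 0.91, 1.05, 0.60, 1.20, 0.42],
    },
    index=pd.Index(DEFAULT_TARGETS, name="gene"),
)
QPCR_CONTROL_SUMMARY["cv"] = QPCR_CONTROL_SUMMARY["sd"] / QPCR_CONTROL_SUMMARY["mean"]

#: FPKM summaries of the RNA-seq healthy-control cohorts, keyed by cohort size.
RNASEQ_CONTROL_SUMMARY: dict[int, pd.DataFrame] = {
    15: pd.DataFrame(
        {
            "mean": [0.35, 1.14, 5.06, 30.17, 2.21, 1.17],
            "sd": [0.23, 0.28, 1.29, 12.44, 0.86, 0.55],
        },
        index=pd.Index(DEFAULT_TARGETS, name="gene"),
    ),
    20: pd.DataFrame(
        {
            "mean": [0.33, 1.26, 5.17, 30.09, 2.47, 1.22],
            "sd": [0.22, 0.38, 1.38, 14.41, 1.00, 0.50],
        },
        index=pd.Index(DEFAULT_TARGETS, name="gene"),
    ),
}
for _df in RNASEQ_CONTROL_SUMMARY.values():
    _df["cv"] = _df["sd"] / _df["mean"]

#: IFN scores of twenty subjects measured on both platforms against the same
#: three-donor control set (columns as printed; see module docstring).
PAIRED_PLATFORM_SCORES = pd.DataFrame(
    {
        "rnaseq": [
            3.26, 6.79, 7.12, 8.58, 1.55, 1.11, 0.55, 0.22, 1.14, 3.68,
            77.73, 44.03, 17.44, 15.44, 37.43, 37.44, 1.07, 2.39, 3.01, 1.82,
        ],
        "qpcr": [
            5.01, 10.05, 9.85, 10.74, 1.37, 0.97, 0.67, 0.19, 1.05, 2.60,
            82.61, 94.25, 16.48, 16.35, 49.98, 84.99, 1.18, 4.70, 1.71, 1.82,
        ],
    },
    index=pd.Index([f"subject_{i}" for i in range(1, 21)], name="sample_id"),
)
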