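"""Published reference medians used as worked-example inputs.

These are the per-field median spike counts (raw and Euclidean-normalized)
reported for rat medial prefrontal multiunits under the oddball/cascade
protocol, plus the region-level median index values for the auditory
pathway comparison. They serve as printed-table inputs to the index
arithmetic — the pipeline never fits to them.
"""

from __future__ import annotations

import pandas as pd

# Median raw and normalized spike counts per mPFC field (columns) and
# condition (rows). Fields: M2 secondary motor, ACC anterior cingulate,
# PL prelimbic, IL infralimbic.
MPFC_FIELD_MEDIANS = pd.DataFrame(
    {
        "M2": {
            "raw_DEV": 8.6875, "raw_STD": 2.7000, "raw_CTR": 2.9875,
            "norm_DEV": 0.8693, "norm_STD": 0.2751, "norm_CTR": 0.3389,
        },
        "ACC": {
            "raw_DEV": 4.8125, "raw_STD": 1.5500, "raw_CTR": 1.7000,
            "norm_DEV": 0.8653, "norm_STD": 0.2280, "norm_CTR": 0.3189,
        },
        "PL": {
            "raw_DEV": 6.4750, "raw_STD": 1.7750, "raw_CTR": 2.5750,
            "norm_DEV": 0.8951, "norm_STD": 0.2583, "norm_CTR": 0.3225,
        },
        "IL": {
            "raw_DEV": 6.0750, "raw_STD": 1.1750, "raw_CTR": 2.4250,
            "norm_DEV": 0.8511, "norm_STD": 0.2202, "norm_CTR": 0.3926,
        },
    }
)

# Published difference rows of the same table (medians of per-tone
# differences; see docs/methods.md for why these can differ from
# differences of the medians above in the fourth decimal).
MPFC_FIELD_DIFFERENCES = pd.DataFrame(
    {
        "M2": {"raw_DEV_STD": 5.9875, "raw_DEV_CTR": 5.7000, "raw_CTR_STD": 0.2875,
               "iMM": 0.5941, "iPE": 0.5304, "iRS": 0.0638},
        "ACC": {"raw_DEV_STD": 3.2625, "raw_DEV_CTR": 3.1125, "raw_CTR_STD": 0.1500,
                "iMM": 0.6373, "iPE": 0.5464, "iRS": 0.0910},
        "PL": {"raw_DEV_STD": 4.7000, "raw_DEV_CTR": 3.9000, "raw_CTR_STD": 0.8000,
               "iMM": 0.6368, "iPE": 0.5726, "iRS": 0.0642},
        "IL": {"raw_DEV_STD": 4.9000, "raw_DEV_CTR": 3.6500, "raw_CTR_STD": 1.250,
               "iMM": 0.6310, "iPE": 0.4586, "iRS": 0.1724},
    }
)

# Region-level median indices along the auditory hierarchy for the
# prediction-error share comparison (iPE as a fraction of iMM).
REGION_MEDIAN_INDICES = pd.DataFrame(
    {
        "lemniscal_AC": {"iMM": 0.50, "iPE": 0.11, "iRS": 0.39},
        "nonlemniscal_AC": {"iMM": 0.60, "iPE": 0.27, "iRS": 0.33},
        "mPFC": {"iMM": 0.59, "iPE": 0.53, "iRS": 0.06},
    }
)
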