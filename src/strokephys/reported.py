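"""Published group-level reference values for consistency checks.

The raw recordings behind the sub-acute (28-day) photothrombotic-stroke
characterisation that this pipeline re-implements are not publicly
deposited, so the printed group-level summaries are bundled here as a
small reference table: back-transformed estimated marginal means per
group, the reported unpaired mean differences, and the directional
Bayes factors.  They support arithmetic consistency checks (difference
of marginal means vs reported difference; BF category assignment) — not
parameter fitting.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_group_means", "SAMPLER_SETTINGS"]

#: Reported MCMC bookkeeping of the source analysis: four chains of
#: 50 000 iterations with 10 000 warmup each.
SAMPLER_SETTINGS = {"chains": 4, "iterations": 50_000, "warmup": 10_000}

# outcome, unit, contrast, emm for the test group (stroke / GFP+), emm for
# the reference group (sham / GFP-), reported unpaired mean difference,
# reported directional Bayes factor
_ROWS = [
    ("ais_length", "um", "stroke-sham", 21.38, 20.99, 0.39, 1.16),
    ("ais_soma_distance", "um", "stroke-sham", 3.78, 4.70, -0.92, 2.56),
    ("ap_threshold", "mV", "stroke-sham", -44.58, -43.88, -0.70, 9.52),
    ("ap_amplitude", "mV", "stroke-sham", 90.21, 90.67, -0.46, 15.1),
    ("ap_half_width", "ms", "stroke-sham", 0.57, 0.54, 0.03, 4.45),
    ("max_firing_freq", "Hz", "stroke-sham", 26.78, 33.10, -6.32, 5.83),
    ("evoked_firing_freq", "Hz", "stroke-sham", 8.18, 10.11, -1.93, 11.2),
    ("capacitance", "pF", "stroke-sham", 151.7, 109.6, 42.1, 4.39),
    ("ap_amplitude", "mV", "gfp_pos-gfp_neg", 93.7, 88.7, 5.0, 50.4),
    ("capacitance", "pF", "gfp_pos-gfp_neg", 155.0, 126.0, 29.0, 3.90),
    ("ap_half_width", "ms", "gfp_pos-gfp_neg", 0.586, 0.524, 0.062, 3.28),
]


def reference_group_means() -> pd.DataFrame:
    """The bundled reference table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "outcome",
            "unit",
            "contrast",
            "emm_test",
            "emm_reference",
            "reported_mean_diff",
            "reported_bf",
        ],
    )
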