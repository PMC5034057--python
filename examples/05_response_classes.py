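"""Classify hypoxia-induced genes by their PHD/FIH-inhibition requirement.

Builds contrasts for three archetypal genes — one fully induced by a
selective PHD inhibitor, one needing combined PHD+FIH inhibition, one
refractory to both — and applies the deterministic three-class rule.
"""

import pandas as pd

import hifmimic as hm


def de_frame(lfc):
    return pd.DataFrame(
        {"log2FC": lfc, "qvalue": [1e-6] * len(lfc)},
        index=["BNIP3_like", "CA9_like", "SOX9_like"],
    )


de = {
    "hypoxia": de_frame([3.0, 3.0, 3.0]),
    "IOX2": de_frame([2.9, 0.5, 0.2]),      # selective PHD inhibitor
    "IOX2+FIHi": de_frame([2.9, 2.8, 0.3]),  # PHD + FIH inhibition
}

result = hm.classify_response(
    de, hypoxia_key="hypoxia", phi_keys=["IOX2"], combo_key="IOX2+FIHi", tau_full=0.7
)
print(result.table.round(2).to_string())
print(
    "\nr_phi and r_combo are induction ratios relative to hypoxia; a gene is "
    "'fully' induced when its ratio reaches tau_full = 0.7. BNIP3-like genes "
    "need only PHD inhibition (class I), CA9-like genes need PHD and FIH "
    "inhibition together (class II), SOX9-like genes stay refractory (class III)."
)
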