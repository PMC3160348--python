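"""Comparative-Ct quantification of follow-up qPCR measurements.

Each sample's target Ct is normalized to the 18S reference
(dCt = Ct_target - Ct_18S), then to a calibrator sample
(ddCt = dCt - dCt_calibrator); the relative quantity is 2^(-ddCt).
"""
import pandas as pd

import bcellsig as b

rows = pd.DataFrame(
    {
        "sample_id": ["control_cal", "patient_1", "patient_2"],
        "gene": ["XBP1", "XBP1", "XBP1"],
        "ct_target": [25.0, 23.0, 26.0],
        "ct_reference": [10.0, 10.0, 10.0],
    }
)
ct = b.CtTable(rows, calibrator_sample_id="control_cal")
out = b.delta_delta_ct(ct)
print(out.to_string(index=False))
# patient_1 amplifies two cycles earlier than the calibrator at equal
# 18S (ddCt = -2): a 4-fold higher XBP1 level; patient_2 is 2-fold lower.
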