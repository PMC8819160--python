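"""Bundled reference measurements used by the personalisation examples.

``PIG_ECG_FEATURES``: body-surface ECG features of six infarcted pigs
during RV pacing at a 500 ms cycle length — QRS duration and QT interval
(ms) from the averaged paced beat, their difference (the ECG-based mean-APD
estimate), and the mean +- SD activation-recovery interval measured on
intracardiac electrograms.  These feed the QT-based action-potential
fitting and serve as realistic QRSd targets for conduction-velocity
personalisation.
"""

from __future__ import annotations

import pandas as pd

PIG_ECG_FEATURES = pd.DataFrame(
    {
        "pig": [1, 2, 3, 4, 5, 6],
        "qrsd_ms": [92.52, 111.22, 104.33, 112.69, 106.29, 79.72],
        "qtint_ms": [391.53, 436.01, 440.42, 429.37, 406.13, 421.54],
        "qt_minus_qrs_ms": [299.01, 324.79, 336.09, 316.67, 299.83, 341.82],
        "mean_ari_ms": [317.13, 321.66, 275.64, 298.63, 331.45, 283.89],
        "sd_ari_ms": [14.24, 20.04, 18.11, 30.14, 17.15, 31.63],
    }
).set_index("pig")
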