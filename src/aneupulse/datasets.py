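"""Published bench and protocol measurements bundled as reference inputs.

These tables were measured on a silicone aneurysm phantom driven by a piston
pump on a hydraulic test bench, imaged with a 64-row CT scanner; they are the
calibration data the analysis code is validated against.  Values are
transcribed at printed precision.
"""

from __future__ import annotations

import pandas as pd

#: Irradiated length of the dynamic reconstruction: 64 slices × 0.6 mm, in cm.
SCAN_LENGTH_CM = 3.84

# (experiment, pulse pressure mmHg, number of pulsations, AVP mm³, SD mm³,
#  CoV %).  Experiments "0.x" had the pump amplitude at zero: the apparent
# pulsation there is artefactual and defines the noise floor of the method.
_PP_SWEEP = [
    ("0.1", 0, 7, 0.7, 0.3, 43, True),
    ("0.2", 0, 8, 0.5, 0.3, 53, True),
    ("0.3", 0, 8, 0.6, 0.3, 42, True),
    ("1.1", 19, 7, 3.6, 1.3, 35, False),
    ("1.2", 20, 7, 3.1, 0.5, 15, False),
    ("1.3", 19, 7, 3.0, 0.4, 12, False),
    ("2.1", 39, 7, 6.1, 0.5, 9, False),
    ("2.2", 38, 7, 6.6, 0.5, 7, False),
    ("2.3", 39, 7, 6.2, 0.6, 10, False),
    ("3.1", 54, 7, 8.7, 0.7, 8, False),
    ("3.2", 53, 7, 9.6, 0.5, 5, False),
    ("3.3", 53, 7, 9.2, 0.5, 5, False),
    ("4.1", 80, 7, 12.2, 0.8, 7, False),
    ("4.2", 82, 7, 14.6, 2.2, 15, False),
    ("4.3", 79, 7, 12.9, 0.5, 4, False),
    ("5.1", 132, 7, 24.1, 2.1, 9, False),
    ("5.2", 139, 7, 26.1, 1.9, 7, False),
    ("5.3", 130, 7, 24.4, 1.6, 7, False),
    ("6.1", 189, 7, 32.9, 1.7, 5, False),
    ("6.2", 192, 7, 34.5, 2.4, 5, False),
    ("6.3", 181, 7, 31.2, 0.6, 2, False),
]

# (kVp, mAs, scan time s, CTDI_vol mGy, DLP mGy·cm, effective dose mSv at
#  4 decimals).  CTDI_100 equals CTDI_vol for head acquisitions.
_DOSE_PROTOCOLS = [
    (80, 70, 5, 50.93, 196, 0.4508),
    (80, 110, 5, 79.44, 305, 0.7015),
    (80, 150, 5, 108.60, 417, 0.9591),
    (80, 190, 5, 137.33, 527, 1.2121),
    (100, 70, 5, 101.93, 391, 0.8993),
    (100, 110, 5, 158.99, 611, 1.4053),
    (100, 150, 5, 217.37, 835, 1.9205),
    (100, 190, 5, 275.30, 1057, 2.4311),
]

#: Dose record of the single in-vivo acquisition: the dynamic series alone,
#: and the full exam including topogram and bolus tracking.
PATIENT_DOSE = {
    "ctdi_vol_mgy": 108.2,
    "dlp_dynamic_mgy_cm": 415,
    "dlp_total_mgy_cm": 446,
}


def pulse_pressure_sweep() -> pd.DataFrame:
    """Bench sweep of volume pulsation against pump pulse pressure."""
    return pd.DataFrame(
        _PP_SWEEP,
        columns=[
            "experiment",
            "pulse_pressure_mmHg",
            "n_pulses",
            "avp_mm3",
            "sd_mm3",
            "cov_percent",
            "artefactual",
        ],
    )


def dose_protocols() -> pd.DataFrame:
    """Radiation dose recorded for each bench acquisition protocol."""
    return pd.DataFrame(
        _DOSE_PROTOCOLS,
        columns=["kvp", "mas", "scan_time_s", "ctdi_vol_mgy", "dlp_mgy_cm", "d_eff_msv"],
    )


def compliance_slope() -> float:
    """Least-squares slope (mm³/mmHg) of AVP against pulse pressure over the
    non-artefactual bench experiments; used as the default pressure→volume
    mapping of the synthetic phantom."""
    df = pulse_pressure_sweep()
    df = df[~df.artefactual]
    import numpy as np

    return float(np.polyfit(df.pulse_pressure_mmHg, df.avp_mm3, 1)[0])
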