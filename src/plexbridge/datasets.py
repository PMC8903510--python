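"""Bundled reference data: the clinical table of the validated vitreous study.

The multi-plex experiment this pipeline was validated on distributed 10
control (macular hole / epiretinal membrane) and 22 proliferative diabetic
retinopathy (PDR) vitreous samples across four TMT 10-plexes, with PDR
samples assigned to low/medium/high subphenotypes by vitreous hemoglobin
concentration. The printed per-sample values (plex, study id, subphenotype,
hemoglobin and bilirubin in g/dL and mg/dL) are transcribed here; one extra
PDR sample (study id 951) contributed only to the pooled bridge sample and
was never analyzed individually (``plex`` is empty for it).

Reference points for the blood-contamination argument: hemoglobin in whole
blood is ~15 g/dL, and the highest vitreous concentration in the study is
0.0084 g/dL.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "exp2_clinical",
    "BLOOD_HEMOGLOBIN_G_DL",
    "MAX_VITREOUS_HEMOGLOBIN_G_DL",
]

BLOOD_HEMOGLOBIN_G_DL = 15.0
MAX_VITREOUS_HEMOGLOBIN_G_DL = 0.0084

# (plex, study_id, phenotype, printed subphenotype, hemoglobin g/dL, bilirubin mg/dL)
_EXP2_ROWS = [
    ("2.1", "193", "CTL", "CTL", None, None),
    ("2.1", "229", "CTL", "CTL", None, None),
    ("2.1", "232", "CTL", "CTL", None, None),
    ("2.1", "423", "PDR", "PDR-L", 0.0, 0.00225),
    ("2.1", "503", "PDR", "PDR-L", 0.0, 0.00235),
    ("2.1", "508", "PDR", "PDR-L", 0.00010, 0.00319),
    ("2.1", "516", "PDR", "PDR-M", 0.00050, 0.00262),
    ("2.1", "526", "PDR", "PDR-M", 0.00020, 0.00271),
    ("2.2", "242", "CTL", "CTL", None, None),
    ("2.2", "334", "CTL", "CTL", None, None),
    ("2.2", "377", "CTL", "CTL", None, None),
    ("2.2", "554", "PDR", "PDR-L", 0.0, 0.00231),
    ("2.2", "715", "PDR", "PDR-L", 0.0, 0.00205),
    ("2.2", "728", "PDR", "PDR-L", 0.0, 0.00332),
    ("2.2", "661", "PDR", "PDR-M", 0.00080, 0.00281),
    ("2.2", "808", "PDR", "PDR-M", 0.00030, 0.00912),
    ("2.3", "519", "CTL", "CTL", None, None),
    ("2.3", "546", "CTL", "CTL", None, None),
    ("2.3", "780", "PDR", "PDR-L", 0.0, 0.00276),
    ("2.3", "842", "PDR", "PDR-L", 0.0, 0.00252),
    ("2.3", "856", "PDR", "PDR-L", 0.0, 0.00247),
    ("2.3", "942", "PDR", "PDR-L", 0.0, 0.00246),
    ("2.3", "890", "PDR", "PDR-M", 0.00170, 0.00280),
    ("2.3", "934", "PDR", "PDR-M", 0.00140, 0.00244),
    ("2.4", "875", "CTL", "CTL", None, None),
    ("2.4", "988", "CTL", "CTL", None, None),
    ("2.4", "315", "PDR", "PDR-H", 0.00660, 0.00366),
    ("2.4", "414", "PDR", "PDR-H", 0.00520, 0.00317),
    ("2.4", "449", "PDR", "PDR-H", 0.00840, 0.00286),
    ("2.4", "523", "PDR", "PDR-H", 0.00510, 0.00327),
    ("2.4", "632", "PDR", "PDR-H", 0.00490, 0.00342),
    ("2.4", "682", "PDR", "PDR-H", 0.00500, 0.00316),
    ("", "951", "PDR", "PDR-L", 0.00000, 0.00245),  # pool-2 contribution only
]


def exp2_clinical(individually_analyzed_only: bool = False) -> pd.DataFrame:
    """The study's clinical table as a DataFrame.

    With ``individually_analyzed_only=True``, the pool-only sample (empty
    plex) is dropped, leaving the 10 control and 22 PDR samples that formed
    the columns of the unified abundance matrix.
    """
    df = pd.DataFrame(
        _EXP2_ROWS,
        columns=["plex", "study_id", "phenotype", "subphenotype", "hemoglobin", "bilirubin"],
    )
    df["hemoglobin"] = df["hemoglobin"].astype(float)
    df["bilirubin"] = df["bilirubin"].astype(float)
    if individually_analyzed_only:
        df = df[df["plex"] != ""].reset_index(drop=True)
    return df
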