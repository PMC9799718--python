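"""Classify raw check-up measurements into metabolism-weight phenotypes.

Builds a tiny check-up table by hand, runs the classifier, and prints the
derived weight level, metabolic level, six-state phenotype and the binary
covariates.  Each visit maps to exactly one of MHNW/MHOW/MHO/MUNW/MUOW/MUO:
the weight category comes from BMI (cut-offs 24 and 28 kg/m²) and the
metabolic status from counting the four NCEP ATP III criteria (unhealthy
means at least two are met).
"""

import pandas as pd

from metatrans import classify_checkups

visits = pd.DataFrame(
    [
        # a healthy normal-weight male: nothing elevated
        dict(subject_id="a", visit_time=0.0, sex="male", age=34, bmi=21.5,
             sbp=114, dbp=69, fpg=5.18, tg=0.80, hdl=1.41, alt=15, ast=19,
             scr=59, ua=266),
        # overweight, TG and HDL criteria met -> metabolically unhealthy
        dict(subject_id="a", visit_time=1.1, sex="male", age=35, bmi=25.8,
             sbp=126, dbp=80, fpg=5.5, tg=1.9, hdl=0.95, alt=44, ast=22,
             scr=70, ua=430),
        # obese female with only the blood-pressure criterion -> MHO
        dict(subject_id="b", visit_time=0.0, sex="female", age=47, bmi=29.1,
             sbp=133, dbp=86, fpg=5.3, tg=1.2, hdl=1.45, alt=28, ast=23,
             scr=72, ua=371),
    ]
)

out = classify_checkups(visits)
cols = ["subject_id", "visit_time", "phenotype", "state", "weight_level",
        "metabolic_level", "female", "middle_aged", "alt_elevated", "ua_elevated"]
print(out[cols].to_string(index=False))
print()
print("Subject 'a' moves MHNW -> MUOW between visits; subject 'b' is MHO")
print("(obese but only one criterion met). 'state' is the 1-6 index used by")
print("the Markov model; the 0/1 columns are the transition covariates.")
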