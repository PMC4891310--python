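"""Published headline statistics of the emulated validation study.

A prospective study in an infant (piglet) asphyxial cardiac-arrest
model compared an uncalibrated pulse-contour test monitor against
femoral-arterial-thermodilution reference monitoring: 58 simultaneous
measurement pairs from 24 subjects at baseline and 15/30/60 min after
return of spontaneous circulation (12 survivors).  The printed summary
values below are used as *inputs* for internal-consistency
reconstructions (difference of the printed means, exclusion-zone size,
percentage error recomputed from the printed bias/limits of agreement)
— the study's raw data were never published.

Orientation: ``difference`` entries are reference - test, except heart
rate, which the study reported as calculated (test) - measured
(reference).
"""

STUDY: dict = {
    "n_pairs": 58,
    "n_subjects": 24,
    "n_rosc": 12,
    "ci": {  # cardiac index, L/min/m^2
        "mean_ref": 4.5,
        "mean_test": 4.0,
        "difference": 0.5,
        "cv_ref": 27.0,
        "cv_test": 37.0,
        "bias": 0.5,
        "bias_pct": 7.4,
        "loa": (-2.9, 4.0),
        "loa_pct": (-69.9, 84.9),
        "pct_error": 80.6,
        "r": 0.170,
    },
    "svi": {  # stroke volume index, mL/m^2
        "mean_ref": 30.4,
        "mean_test": 31.2,
        "difference": -0.8,
    },
    "svri": {  # systemic vascular resistance index, dyn.s.cm^-5.m^-2
        "mean_ref": 1412.0,
        "mean_test": 1701.0,
        "difference": -288.0,  # printed; the printed means give -289 (rounding)
    },
    "svv": {  # stroke volume variation, percent
        "mean_ref": 17.6,
        "mean_test": 15.5,
        "difference": 2.1,
    },
    "hr": {  # heart rate, beats/min; difference printed as calculated - measured
        "mean_measured": 153.1,
        "mean_calculated": 138.5,
        "difference": -14.6,
    },
    "trend": {
        "mean_angular_deviation": -13.8,
        "concordance_pct": 26.1,
        "limit_deg": 30.0,
        "exclusion_fraction": 0.10,
        "exclusion_threshold": 0.45,  # L/min/m^2, 10 % of the reference mean CI
    },
    "pct_error_limit": 30.0,
}
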