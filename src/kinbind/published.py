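"""Published kinetic constants for the kinase/inhibitor recognition study.

``GLOBAL_FIT_RATES`` holds the six rate constants reported from the global
ODE fit of the stopped-flow titrations.  ``TABLE1`` holds the per-construct
phase analysis (fast-phase linear fit and slow-phase hyperbolic fit) for the
three single-acceptor labelling schemes and the double-labelled inhibitor.
Values are in M, s units except where the column name says otherwise.
"""

from __future__ import annotations

import pandas as pd

from .kinetics import RateConstants

__all__ = ["GLOBAL_FIT_RATES", "TABLE1", "SCHEMES"]

#: Rate constants from the global fit of all stopped-flow datasets.
GLOBAL_FIT_RATES = RateConstants(
    k1=1.9e4,        # s^-1, I -> I*
    k_minus1=1.5e4,  # s^-1, I* -> I
    kb=1.5e7,        # M^-1 s^-1, encounter-complex formation
    k_minusb=0.5,    # s^-1, encounter-complex dissociation
    kr=2400.0,       # s^-1, rearrangement forward
    k_minusr=720.0,  # s^-1, rearrangement reverse
)

SCHEMES = ("ACCEPTOR-3", "ACCEPTOR-28", "ACCEPTOR-59", "DONOR-ACCEPTOR")

#: Per-construct phase summary. kon in M^-1 s^-1, koff/kslow in s^-1,
#: Kd_app in M, K0_5 in M.  NaN marks values not determined.
TABLE1 = pd.DataFrame(
    {
        "scheme": list(SCHEMES),
        "kon": [1.88e7, 1.40e7, 1.62e7, 0.85e7],
        "kon_se": [0.03e7, 0.02e7, 0.11e7, 0.04e7],
        "koff": [13.0, 5.0, 2.0, 6.0],
        "koff_se": [3.0, 1.0, 10.0, 7.0],
        "kd_app": [700e-9, 390e-9, 150e-9, 700e-9],
        "kd_app_se": [170e-9, 110e-9, 620e-9, 800e-9],
        "kslow": [24.0, float("nan"), float("nan"), 37.0],
        "kslow_se": [2.0, float("nan"), float("nan"), 2.0],
        "k0_5": [2.4e-6, 3.0e-6, 3.8e-6, 17e-6],
        "k0_5_se": [0.4e-6, 0.4e-6, 0.5e-6, 3e-6],
    }
).set_index("scheme")
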