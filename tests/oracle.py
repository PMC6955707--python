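"""Brute-force recomputation of every session measure from raw outcomes.

Written directly from the measure definitions, independently of the
package's scoring path, so tests can compare the two.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence


def oracle_metrics(
    outcomes: Sequence[str],
    rts: Sequence[Optional[float]],
    n_trials: int,
    theta: float,
) -> dict:
    C = sum(1 for o in outcomes if o == "correct")
    OE = sum(1 for o in outcomes if o == "omission")
    CE = sum(1 for o in outcomes if o == "commission")
    I = OE + CE
    K = n_trials - C - I
    T = C + I + K

    crts = [rt for o, rt in zip(outcomes, rts) if o == "correct"]
    assert all(rt is not None for rt in crts)
    M = sum(crts) / C if C else None
    if C > 1:
        SD = math.sqrt(sum((x - M) ** 2 for x in crts) / (C - 1))
    else:
        SD = 0.0

    GF = (C + I) / T
    IAF = OE / (C + I) if C + I else 0.0
    IMF = CE / (C + I) if C + I else 0.0
    EF = (OE + CE) / (C + I) if C + I else 0.0
    CRF = sum(crts) / (C * theta) if C else 0.0
    PI = ((1 - CRF) + (1 - EF)) / 2 * GF
    GT = sum(rt for rt in rts if rt is not None) + OE * theta
    return {
        "C": C, "OE": OE, "CE": CE, "I": I, "K": K, "T": T,
        "M": M, "SD": SD, "GF": GF, "IAF": IAF, "IMF": IMF,
        "EF": EF, "CRF": CRF, "PI": PI, "GT": GT, "ST": T * theta,
    }
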