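"""Hand-written, term-by-term oracle for the network's linear constraints.

Each expression below transcribes one canonical constraint row literally
(0-indexed: ``v[0]`` is flux v1), independent of the package's assembly
code.  Used to cross-check ConstraintSystem matrices row by row.
"""

import numpy as np


def equality_residuals(v, r):
    """The nine equality expressions; all must equal 0 for a feasible v."""
    return np.array(
        [
            v[0] - 100 * (r["glucose"] + r["galactose"]),
            v[2] - v[3] + 100 * r["glycerol"],
            v[10] - v[11] - v[12],
            v[13] - v[15],
            v[9] - v[10] - v[24] + 100 * r["gluconate"],
            -v[16] + v[17] - 100 * r["citrate"],
            -v[11] + v[13] + v[14] - 100 * r["xylose"],
            -v[17] + v[18] + v[23],
            -v[21] + v[22] - v[23] + v[28] - 100 * r["malate"],
        ]
    )


def inequality_values(v, r, lactate_to_pyruvate=True, acetate_to_accoa=True):
    """The twelve inequality expressions; all must be >= 0 for a feasible v.

    The optional lactate/acetate entry-point terms extend the canonical PYR
    and AceCoA rows (those substrates have no canonical balance term).
    """
    pyr_extra = 100 * r["lactate"] if lactate_to_pyruvate else 0.0
    ace_extra = 100 * r["acetate"] if acetate_to_accoa else 0.0
    return np.array(
        [
            v[0] - v[1] - v[9],
            v[1] - v[2] + v[14] + v[15] + 100 * r["fructose"],
            v[2] + v[3] - v[4] + v[13] + v[14] - v[15] + v[24],
            v[4] - v[5],
            v[5] - v[6] - v[27],
            v[6] - v[7] + v[24] - v[26] + v[28] + 100 * r["pyruvate"] + pyr_extra,
            v[7] - v[8] - v[16] - v[23] - v[25] + ace_extra,
            v[12] - v[13],
            -v[14] + v[15],
            v[18] - v[19] + 100 * r["glutamate"],
            -v[16] + v[22] + v[27],
            -v[20] + v[21],
        ]
    )


def suc_inequality_value(v, r):
    """The optional SUC-pool drain expression (>= 0 when enabled)."""
    return v[19] + v[23] - v[20] + 100 * r["succinate"]
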