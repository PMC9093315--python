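"""Default measurement-geometry tables for the 32-electrode scalp array.

The instrument injects current through 20 firmware-selected electrode pairs
chosen to be nearly diametrically opposed across the head, and measures
voltages between numerically adjacent non-injecting electrode pairs.  The
published array gives no electrode coordinates, so this module ships a
documented default: 32 unit directions on a head-like dome (right-handed
frame, +x toward the nose, +z up) arranged so that every injection pair in
``TABLE1_PATTERNS`` subtends more than 120 degrees at the head centre and all
electrodes are separated by at least 16 degrees.  Electrode 32 sits at the
vertex.  The table is overridable wherever a layout argument is accepted.
"""

from __future__ import annotations

import numpy as np

#: Injection electrode pairs (source, sink), 1-based, in frame order.
TABLE1_PATTERNS: list[tuple[int, int]] = [
    (1, 30), (1, 27), (22, 26), (9, 18), (7, 16),
    (3, 12), (1, 28), (8, 12), (5, 15), (1, 29),
    (4, 13), (8, 17), (7, 13), (20, 24), (6, 14),
    (1, 31), (1, 10), (2, 11), (21, 25), (19, 23),
]

#: Default drive amplitude, amperes peak-to-peak (Mk I instrument).
DEFAULT_AMPLITUDE_PKPK = 1.0e-3

#: Unit directions of electrodes 1..32 from the head centre.
ELECTRODE_DIRECTIONS = np.array([
    [+0.574764, -0.770445, -0.275791],
    [+0.770321, -0.623432, -0.133931],
    [+0.952236, -0.302912, -0.038611],
    [+0.937331, -0.188381, -0.293127],
    [+0.998481, -0.015072, -0.053004],
    [+0.959723, +0.280884, -0.005906],
    [+0.918998, +0.276135, -0.281410],
    [+0.814514, +0.560524, -0.149596],
    [+0.443308, +0.894291, -0.061010],
    [-0.443697, +0.866753, -0.227755],
    [-0.698657, +0.690995, -0.185485],
    [-0.982031, +0.179368, -0.058673],
    [-0.874844, +0.395548, -0.279625],
    [-0.986391, -0.106123, -0.125578],
    [-0.930362, -0.364992, -0.034741],
    [-0.826261, -0.502628, -0.254279],
    [-0.668365, -0.721486, -0.180959],
    [-0.457797, -0.888483, -0.031941],
    [+0.879750, -0.394099, +0.265941],
    [+0.971036, -0.137169, +0.195635],
    [+0.962272, +0.138353, +0.234287],
    [+0.850817, +0.301574, +0.430307],
    [-0.714287, +0.661729, +0.227833],
    [-0.868798, +0.414956, +0.270187],
    [-0.967701, +0.130649, +0.215606],
    [-0.912788, -0.295093, +0.282380],
    [-0.497522, +0.777941, +0.383771],
    [-0.653648, +0.574111, +0.493094],
    [-0.790524, +0.321774, +0.521089],
    [-0.842865, -0.018388, +0.537811],
    [-0.654556, +0.180591, +0.734127],
    [+0.000000, +0.000000, +1.000000],
])

#: Adjacent electrode pairs that are numerically adjacent but not spatially
#: neighbouring under the default layout.  The numbering discontinuities fall
#: between the front/back clusters at (17, 18) ... (18 starts the back-low arc
#: wrap) and between the upper arc and the vertex at (31, 32).
NON_NEIGHBOUR_PAIRS: list[tuple[int, int]] = [(17, 18), (31, 32)]


def default_rejection_entries() -> list[tuple[int, tuple[int, int]]]:
    """Explicit (pattern index, voltage pair) rejection list.

    Enumerates every appearance of the ``NON_NEIGHBOUR_PAIRS`` pairs across
    the default 20 current patterns, skipping patterns in which the pair is
    already excluded because it touches an injection electrode.  Under the
    default tables this yields exactly 37 entries, reducing the 546-element
    frame to 509 accepted measurements.
    """
    entries = []
    for p_idx, (src, snk) in enumerate(TABLE1_PATTERNS):
        for pair in NON_NEIGHBOUR_PAIRS:
            if src in pair or snk in pair:
                continue
            entries.append((p_idx, pair))
    return entries
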