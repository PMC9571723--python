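"""Independent brute-force oracle for the fuzzy inference system.

Membership functions are formulated with np.interp and the rule grid is
transcribed separately (p2-major, mirroring the printed table), so this
path shares no code with the implementation it checks.
"""

import numpy as np

# One row per p2 term (VS..VL), one column per p1 term (VS..VL).
ORACLE_GRID = [
    ["M", "L", "L", "VL", "VL"],
    ["S", "M", "L", "L", "VL"],
    ["S", "S", "M", "L", "L"],
    ["VS", "S", "S", "M", "L"],
    ["VS", "VS", "S", "S", "M"],
]

TERMS = ("VS", "S", "M", "L", "VL")


def oracle_membership(v, peaks, k):
    """Piecewise-linear grade of set k at v (np.interp formulation)."""
    peaks = list(peaks)
    if k == 0:
        return float(np.interp(v, [peaks[0], peaks[1]], [1.0, 0.0]))
    if k == 4:
        return float(np.interp(v, [peaks[3], peaks[4]], [0.0, 1.0]))
    return float(
        np.interp(v, [peaks[k - 1], peaks[k], peaks[k + 1]], [0.0, 1.0, 0.0])
    )


def oracle_degree(p1, p2, cfg, n_grid=10_000):
    """Brute-force center of gravity on a trapezoid-integrated fine grid."""
    qs = np.linspace(0.0, 1.0, n_grid)
    aggregate = np.zeros(n_grid)
    for j, row in enumerate(ORACLE_GRID):  # j indexes the p2 term
        for i, name in enumerate(row):  # i indexes the p1 term
            strength = min(
                oracle_membership(p1, cfg.alpha1, i),
                oracle_membership(p2, cfg.alpha2, j),
            )
            if strength == 0:
                continue
            b = np.array(
                [
                    oracle_membership(q, cfg.consequent_peaks, TERMS.index(name))
                    for q in qs
                ]
            )
            aggregate = np.maximum(aggregate, np.minimum(strength, b))
    denom = np.trapezoid(aggregate, qs)
    if denom == 0:
        return 0.0
    return float(np.trapezoid(qs * aggregate, qs) / denom)
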