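"""Mamdani fuzzy inference for water-patch candidacy.

Two antecedents feed the system: ``p1``, the minimum distance (pixels)
from a patch to any foam contour, and ``p2``, the patch's intensity
standard deviation (gray levels).  Five linguistic terms — very small
(VS), small (S), medium (M), large (L), very large (VL) — partition each
variable with triangular interior sets and trapezoidal shoulders whose
peaks are the five parameters of each antecedent.  A 25-rule table maps
every (p1, p2) term pair to a consequent term on the unit interval; the
farther a patch lies from foam and the flatter its texture, the larger
the inferred degree.

Inference is standard Mamdani: min conjunction for rule strength, max
aggregation of clipped consequent sets, and center-of-gravity
defuzzification by midpoint-rule integration on a fixed grid.  A
precomputed lookup table (LUT) over the integer (p1, p2) grid provides
the fast path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import DomainError

__all__ = [
    "TERMS",
    "FISConfig",
    "RuleBase",
    "DEFAULT_RULE_TABLE",
    "membership_grades",
    "fis_degree",
    "build_lut",
    "lut_lookup",
]

#: Linguistic term names, index order used everywhere.
TERMS = ("VS", "S", "M", "L", "VL")

#: Rule table: entry [i][j] is the consequent term when p1 has term i and
#: p2 has term j (i, j, value all indices into TERMS).
DEFAULT_RULE_TABLE = np.array(
    #  p2: VS  S  M   L  VL
    [
        [2, 1, 1, 0, 0],  # p1 VS
        [3, 2, 1, 1, 0],  # p1 S
        [3, 3, 2, 1, 1],  # p1 M
        [4, 3, 3, 2, 1],  # p1 L
        [4, 4, 3, 3, 2],  # p1 VL
    ]
)


def membership_grades(v, peaks) -> np.ndarray:
    """Grades of the five sets at ``v`` (scalar or array), stacked last.

    Set 0 is a left shoulder (grade 1 at or below the first peak), set 4 a
    right shoulder (grade 1 at or beyond the last peak); interior sets are
    triangles spanning adjacent peaks.
    """
    v = np.asarray(v, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    out = np.zeros(v.shape + (5,))
    out[..., 0] = np.clip((peaks[1] - v) / (peaks[1] - peaks[0]), 0.0, 1.0)
    out[..., 4] = np.clip((v - peaks[3]) / (peaks[4] - peaks[3]), 0.0, 1.0)
    for k in (1, 2, 3):
        rising = (v - peaks[k - 1]) / (peaks[k] - peaks[k - 1])
        falling = (peaks[k + 1] - v) / (peaks[k + 1] - peaks[k])
        out[..., k] = np.clip(np.minimum(rising, falling), 0.0, 1.0)
    return out


@dataclass
class FISConfig:
    """Membership-function parameters of the inference system.

    ``alpha1`` are the five peaks (pixels) on the foam-distance axis,
    ``alpha2`` the five peaks (gray levels) on the intensity axis; both
    start at 0 and are strictly increasing.  The consequent universe is
    [0, 1] with five equally spaced sets.  ``p1_max`` optionally caps the
    p1 domain at the diagonal length of the sampling band (the VL shoulder
    then plateaus from the last peak to that cap).
    """

    alpha1: tuple = (0.0, 25.0, 50.0, 75.0, 100.0)
    alpha2: tuple = (0.0, 45.0, 90.0, 135.0, 180.0)
    consequent_peaks: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_grid: int = 1001
    p1_max: float | None = None

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "consequent_peaks"):
            vals = tuple(float(x) for x in getattr(self, name))
            if len(vals) != 5 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise DomainError(f"{name} must be 5 strictly increasing values")
            setattr(self, name, vals)
        if self.alpha1[0] != 0 or self.alpha2[0] != 0:
            raise DomainError("antecedent parameters must start at 0")
        if self.n_grid < 3:
            raise DomainError("n_grid must be at least 3")

    # cached defuzzification grid (midpoint rule) and consequent grades
    def _consequent_cache(self):
        cache = getattr(self, "_cache", None)
        if cache is None:
            lo, hi = self.consequent_peaks[0], self.consequent_peaks[-1]
            q = lo + (np.arange(self.n_grid) + 0.5) * (hi - lo) / self.n_grid
            grades = membership_grades(q, self.consequent_peaks)  # (n_grid, 5)
            cache = (q, grades.T.copy())  # (5, n_grid)
            self._cache = cache
        return cache

    def to_dict(self) -> dict:
        return {
            "alpha1": list(self.alpha1),
            "alpha2": list(self.alpha2),
            "consequent_peaks": list(self.consequent_peaks),
            "n_grid": self.n_grid,
            "p1_max": self.p1_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FISConfig":
        return cls(**d)


@dataclass
class RuleBase:
    """The 25-rule table, exactly one rule per antecedent term pair."""

    table: np.ndarray = field(default_factory=lambda: DEFAULT_RULE_TABLE.copy())

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (5, 5):
            raise DomainError("rule table must be 5x5 (25 rules)")
        if self.table.min() < 0 or self.table.max() > 4:
            raise DomainError("rule consequents must be term indices 0..4")

    def __len__(self) -> int:
        return self.table.size

    def rules(self):
        """Iterate the 25 rules as (p1_term, p2_term, consequent_term)."""
        for i in range(5):
            for j in range(5):
                yield i, j, int(self.table[i, j])

    def _table_rows(self):
        """Cached plain-Python rule table for the scalar inference hot path."""
        cache = getattr(self, "_rows", None)
        if cache is None:
            cache = [[int(t) for t in row] for row in self.table]
            self._rows = cache
        return cache

    def to_dict(self) -> dict:
        # stored as a p2-major grid of term names, mirroring the printed table
        return {
            "rows_p2": list(TERMS),
            "cols_p1": list(TERMS),
            "grid": [
                [TERMS[self.table[i, j]] for i in range(5)] for j in range(5)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        grid = d["grid"]
        table = np.empty((5, 5), dtype=int)
        for j, row in enumerate(grid):
            for i, name in enumerate(row):
                table[i, j] = TERMS.index(name)
        return cls(table)


def _clamp_inputs(p1: float, p2: float, cfg: FISConfig) -> tuple:
    hi1 = cfg.p1_max if cfg.p1_max is not None else float("inf")
    if p1 < 0 or p1 > hi1 or p2 < 0 or p2 > 255:
        warnings.warn(
            f"FIS input ({p1:.3g}, {p2:.3g}) outside domain; clamping",
            stacklevel=3,
        )
    return min(max(p1, 0.0), hi1), min(max(p2, 0.0), 255.0)


def _grades_scalar(v: float, peaks: tuple) -> list:
    """Scalar twin of :func:`membership_grades` (identical arithmetic)."""
    g = [0.0] * 5
    g[0] = min(max((peaks[1] - v) / (peaks[1] - peaks[0]), 0.0), 1.0)
    g[4] = min(max((v - peaks[3]) / (peaks[4] - peaks[3]), 0.0), 1.0)
    for k in (1, 2, 3):
        rising = (v - peaks[k - 1]) / (peaks[k] - peaks[k - 1])
        falling = (peaks[k + 1] - v) / (peaks[k + 1] - peaks[k])
        g[k] = min(max(min(rising, falling), 0.0), 1.0)
    return g


def fis_degree(
    p1: float, p2: float, cfg: FISConfig | None = None, rules: RuleBase | None = None
) -> float:
    """Crisp degree q in [0, 1] that a patch is a water-only candidate."""
    cfg = cfg or FISConfig()
    rules = rules or RuleBase()
    p1, p2 = _clamp_inputs(p1, p2, cfg)
    mu1 = _grades_scalar(p1, cfg.alpha1)
    mu2 = _grades_scalar(p2, cfg.alpha2)
    table = rules._table_rows()
    ts = [0.0] * 5  # max firing strength per consequent term (min conjunction)
    for i in range(5):
        a = mu1[i]
        if a == 0.0:
            continue
        row = table[i]
        for j in range(5):
            b = mu2[j]
            s = a if a < b else b
            t = row[j]
            if s > ts[t]:
                ts[t] = s
    term_strength = np.array(ts)
    q_grid, consequent = cfg._consequent_cache()
    agg = np.max(np.minimum(term_strength[:, None], consequent), axis=0)
    denom = agg.sum()
    if denom <= 0:
        return 0.0
    return float((q_grid * agg).sum() / denom)


def build_lut(
    cfg: FISConfig | None = None,
    rules: RuleBase | None = None,
    image_diag: float | None = None,
) -> np.ndarray:
    """Precompute q over the integer grid p1 in 0..ceil(L1), p2 in 0..255.

    ``image_diag`` (L1) defaults to ``cfg.p1_max``; one of the two must be
    provided.  Entry ``[p1, p2]`` equals ``fis_degree(p1, p2)`` exactly.
    """
    cfg = cfg or FISConfig()
    rules = rules or RuleBase()
    l1 = image_diag if image_diag is not None else cfg.p1_max
    if l1 is None:
        raise DomainError("image_diag (L1) is required to size the LUT")
    n1 = int(np.ceil(l1)) + 1
    lut = np.empty((n1, 256))
    for p1 in range(n1):
        for p2 in range(256):
            lut[p1, p2] = fis_degree(float(p1), float(p2), cfg, rules)
    return lut


def lut_lookup(lut: np.ndarray, p1: float, p2: float) -> float:
    """Nearest-integer-grid lookup into a precomputed table."""
    i = int(np.clip(round(p1), 0, lut.shape[0] - 1))
    j = int(np.clip(round(p2), 0, lut.shape[1] - 1))
    return float(lut[i, j])
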