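"""Reference constants recorded from the original graded-treadmill study.

These are published values, shipped for reproducibility and as defaults;
they are not recomputable without that study's raw data.  ``y1`` is the
normalized reaction time and ``y2`` the normalized Borg rating (the
weighted combination of the level-3 bounds with the reference weights
reproduces the published moderate-fatigue band, which fixes this
assignment).
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_WEIGHTS",
    "REFERENCE_THRESHOLDS_5LEVEL",
    "REFERENCE_F_BANDS",
    "REFERENCE_CONSOLIDATION",
]

#: entropy-method weights the original study derived for its two
#: indicators: reaction time 0.39, Borg rating 0.61 (F = 0.39 R + 0.61 B).
REFERENCE_WEIGHTS: dict[str, float] = {"rt": 0.39, "borg": 0.61}

#: five-level normalized thresholds per indicator, ordered by severity:
#: per level, (lo, hi) for y1 = reaction time and y2 = Borg.
REFERENCE_THRESHOLDS_5LEVEL: list[dict[str, tuple[float, float]]] = [
    {"rt": (0.00, 0.21), "borg": (0.00, 0.18)},
    {"rt": (0.07, 0.36), "borg": (0.18, 0.33)},
    {"rt": (0.21, 0.79), "borg": (0.31, 0.58)},
    {"rt": (0.57, 1.00), "borg": (0.51, 0.88)},
    {"rt": (0.79, 0.93), "borg": (0.92, 1.00)},
]

#: three-level band edges of the composite index F:
#: mild [0, 0.27), moderate [0.27, 0.66), severe [0.66, 1].
REFERENCE_F_BANDS: tuple[float, float, float, float] = (0.0, 0.27, 0.66, 1.0)

#: published consolidation of the five levels into three.
REFERENCE_CONSOLIDATION: dict[int, int] = {1: 1, 2: 1, 3: 2, 4: 3, 5: 3}
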