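"""Packaged worked-example inputs: the secondary-indicator judgment matrix,
the published nine-indicator weight tree, and the four-zone partition of
China's 31 provincial administrative units.

These are inputs to the measurement system (the expert elicitation that
produced the judgment matrix is upstream of this package).  The judgment
matrix is available in two forms: ``exact`` rebuilds the reciprocal entries
from the upper triangle (1/0.95, 1/1.05, 1/1.2) and reproduces the published
consistency statistics (lambda_max = 3.000752, CI = 0.000376, CR = 0.000648)
to print precision; ``printed`` carries the 4 d.p. rounded reciprocals as
published (0.9524, 1.0526, 0.8333), which shift CI by ~8e-6.
"""

from __future__ import annotations

import numpy as np

from .ahp import JudgmentMatrix, WeightTree
from .io_panel import RegionPartition

__all__ = [
    "secondary_judgment_matrix",
    "published_weight_tree",
    "four_zone_partition",
    "INDICATORS",
    "GROUPS",
    "paper_fixtures",
]

GROUPS = ("facilities", "personnel", "beds")

#: indicator id -> (group, orientation, published global tertiary weight)
#: All nine indicators are per-capita provision quantities and are treated
#: as positive-orientation by default (more provision -> higher score); the
#: urban/rural technician ratio's orientation is not self-evident and can be
#: flipped in user metadata if a different reading is wanted.
INDICATORS = {
    "hospitals_per_10k":               ("facilities", "positive", 0.1100),
    "primary_institutions_per_10k":    ("facilities", "positive", 0.1145),
    "public_health_institutions_per_10k": ("facilities", "positive", 0.1079),
    "tech_urban_rural_ratio":          ("personnel", "positive", 0.1114),
    "physicians_per_10k":              ("personnel", "positive", 0.1284),
    "nurses_per_10k":                  ("personnel", "positive", 0.1198),
    "hospital_beds_per_10k":           ("beds", "positive", 0.1050),
    "primary_beds_per_10k":            ("beds", "positive", 0.0993),
    "public_health_beds_per_10k":      ("beds", "positive", 0.1037),
}

_FOUR_ZONES = {
    "northeast": ["Liaoning", "Jilin", "Heilongjiang"],
    "east": ["Beijing", "Tianjin", "Hebei", "Shanghai", "Jiangsu",
             "Zhejiang", "Shandong", "Fujian", "Guangdong", "Hainan"],
    "central": ["Shanxi", "Henan", "Anhui", "Hubei", "Hunan", "Jiangxi"],
    "west": ["Inner Mongolia", "Chongqing", "Sichuan", "Guangxi", "Guizhou",
             "Yunnan", "Shaanxi", "Gansu", "Ningxia", "Tibet", "Qinghai",
             "Xinjiang"],
}


def secondary_judgment_matrix(form: str = "exact") -> JudgmentMatrix:
    """The published 3x3 secondary-indicator judgment matrix.

    ``exact`` (default): reciprocals rebuilt exactly from the upper triangle
    0.95, 1.05, 1.20.  ``printed``: the 4 d.p. entries as published.
    """
    labels = list(GROUPS)
    if form == "exact":
        return JudgmentMatrix.from_upper_triangle(
            labels, {(0, 1): 0.95, (0, 2): 1.05, (1, 2): 1.20}
        )
    if form == "printed":
        x = np.array([
            [1.0,    0.9500, 1.0500],
            [1.0526, 1.0,    1.2000],
            [0.9524, 0.8333, 1.0],
        ])
        return JudgmentMatrix(labels=labels, x=x)
    raise ValueError(f"unknown form {form!r}; use 'exact' or 'printed'")


def published_weight_tree() -> WeightTree:
    """The published weight hierarchy over the nine tertiary indicators.

    Only the secondary judgment matrix was published; the tertiary matrices
    were not, so local tertiary weights are backed out as global/secondary
    from the published table and treated as given.
    """
    global_weights = {ind: w for ind, (_, _, w) in INDICATORS.items()}
    group_of = {ind: g for ind, (g, _, _) in INDICATORS.items()}
    return WeightTree.from_global_weights(global_weights, group_of)


def four_zone_partition() -> RegionPartition:
    """Four-zone partition of the 31 provincial units (3 NE, 10 E, 6 C, 12 W)."""
    assignment = {
        unit: zone for zone, units in _FOUR_ZONES.items() for unit in units
    }
    return RegionPartition(assignment=assignment,
                           group_order=list(_FOUR_ZONES))


def paper_fixtures() -> tuple[JudgmentMatrix, WeightTree, RegionPartition]:
    """All packaged worked-example objects in one call."""
    return (secondary_judgment_matrix(), published_weight_tree(),
            four_zone_partition())
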