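"""Bundled clinical characteristics of a two-centre cervical-cancer LVSI
cohort (training n=198: 94 LVSI-negative / 104 LVSI-positive; external test
n=102: 48 / 54).

Counts are given per variable as rows = (LVSI-, LVSI+) and columns = the
category levels listed in ``LEVELS``; continuous variables as printed
mean +/- SD summaries per group. These tables are the worked example for
the :mod:`habitatomics.clinical` battery: every p-value in the published
characteristics table is recomputable from them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "table1_categorical",
    "table1_continuous",
    "figo_lvsi_counts",
    "LEVELS",
]

LEVELS = {
    "histological_type": ("squamous", "adeno", "adenosquamous"),
    "differentiation": ("low", "middle", "high"),
    "hpv": ("negative", "positive"),
    "ca125": ("<=35", ">35"),
    "ca199": ("<=27", ">27"),
    "scc": ("<=1.5", ">1.5"),
    "figo_stage": ("I", "II", "III"),
}

# rows: (LVSI-, LVSI+); columns follow LEVELS
_TRAIN = {
    "histological_type": [[64, 24, 6], [83, 16, 5]],
    "differentiation": [[10, 68, 16], [21, 82, 1]],
    "hpv": [[48, 46], [44, 60]],
    "ca125": [[79, 15], [74, 30]],
    "ca199": [[75, 19], [81, 23]],
    "scc": [[44, 50], [44, 60]],
    "figo_stage": [[63, 29, 2], [47, 43, 14]],
}

_TEST = {
    "histological_type": [[36, 8, 4], [43, 6, 5]],
    "differentiation": [[11, 23, 14], [16, 23, 15]],
    "hpv": [[15, 33], [15, 39]],
    "ca125": [[36, 12], [36, 18]],
    "ca199": [[37, 11], [37, 17]],
    "scc": [[24, 24], [23, 31]],
    "figo_stage": [[29, 15, 4], [22, 18, 14]],
}

# (mean, sd, n) per (LVSI-, LVSI+) group
_CONTINUOUS = {
    "train": {
        "age": ((51.63, 10.84, 94), (51.35, 10.49, 104)),
        "max_diameter": ((22.94, 11.66, 94), (34.31, 12.75, 104)),
    },
    "test": {
        "age": ((51.81, 8.73, 48), (49.06, 10.52, 54)),
        "max_diameter": ((3.14, 1.45, 48), (3.85, 1.12, 54)),
    },
}


def table1_categorical(cohort: str = "train") -> dict[str, np.ndarray]:
    """Contingency tables (2 x levels) per categorical variable."""
    source = {"train": _TRAIN, "test": _TEST}[cohort]
    return {name: np.asarray(t, int) for name, t in source.items()}


def table1_continuous(cohort: str = "train") -> dict[str, tuple]:
    """(mean, sd, n) summaries per continuous variable and LVSI group."""
    return dict(_CONTINUOUS[cohort])


def figo_lvsi_counts() -> list[np.ndarray]:
    """Per-cohort FIGO-stage x LVSI tables (rows = stage I/II/III,
    columns = LVSI-negative, LVSI-positive), for pooled stage-wise rates."""
    out = []
    for cohort in ("train", "test"):
        t = table1_categorical(cohort)["figo_stage"]
        out.append(t.T.copy())  # transpose to stages x (neg, pos)
    return out
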