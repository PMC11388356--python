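"""Canonical experimental design coding shared by simulation and model.

Group labels 1..4 follow one fixed order so that simulation, model indices
and reported contrasts can never disagree silently:

====== ============ ======
group  isolate_type copper
====== ============ ======
1      community    0
2      community    1
3      SBW25        0
4      SBW25        1
====== ============ ======

``X1`` maps each group to its isolate-type index (1 = community,
2 = SBW25); ``X2`` is the copper indicator (1 = copper present).  Under
this coding the no-copper type difference is ``alpha_2 - alpha_1`` and the
with-copper difference is ``(alpha_2 + beta_2) - (alpha_1 + beta_1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GROUPS", "X1", "X2", "group_label", "assign_groups"]

GROUPS: tuple[tuple[str, int], ...] = (
    ("community", 0),
    ("community", 1),
    ("SBW25", 0),
    ("SBW25", 1),
)

#: 1-based isolate-type index per group (1 = community, 2 = SBW25).
X1: tuple[int, ...] = (1, 1, 2, 2)
#: Copper indicator per group (1 = copper present).
X2: tuple[int, ...] = (0, 1, 0, 1)

_GROUP_OF = {key: j for j, key in enumerate(GROUPS, start=1)}


def group_label(isolate_type: str, copper: int | bool) -> int:
    """1-based canonical group for an (isolate_type, copper) combination."""
    key = (str(isolate_type), int(bool(copper)))
    try:
        return _GROUP_OF[key]
    except KeyError:
        raise ValueError(
            f"unknown isolate_type/copper combination {key}; isolate_type "
            "must be 'community' or 'SBW25'"
        ) from None


def assign_groups(table: pd.DataFrame,
                  type_col: str = "isolate_type",
                  copper_col: str = "copper") -> np.ndarray:
    """Vector of 1-based canonical group labels for an isolate table."""
    for col in (type_col, copper_col):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    return np.array(
        [group_label(t, c) for t, c in zip(table[type_col], table[copper_col])],
        dtype=int,
    )
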