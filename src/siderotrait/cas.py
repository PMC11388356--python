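"""Chrome azurol S (CAS) assay quantification.

Converts raw plate reads (absorbance at 630 nm of the assay mixture, a
reference absorbance, and culture optical density at 600 nm) into
standardized siderophore-production scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssayRead",
    "siderophore_score",
    "standardize_min_zero",
    "quantify_reads",
    "OD_WARN_THRESHOLD",
]

#: OD below this triggers a warning: the 1/OD correction becomes ill-conditioned
#: for barely-growing isolates.
OD_WARN_THRESHOLD = 0.05


@dataclass(frozen=True)
class AssayRead:
    """One raw CAS plate read for a single isolate.

    Attributes
    ----------
    isolate_id : str
        Identifier of the assayed isolate.
    a630 : float
        Absorbance of the assay mixture at 630 nm (dimensionless).
    a630_ref : float
        Absorbance of the reference mixture at 630 nm; must be positive.
    od600 : float
        Optical density of the culture at 600 nm; must be positive.
    """

    isolate_id: str
    a630: float
    a630_ref: float
    od600: float

    def __post_init__(self) -> None:
        if not self.a630_ref > 0:
            raise ValueError(f"a630_ref must be > 0, got {self.a630_ref}")
        if not self.od600 > 0:
            raise ValueError(f"od600 must be > 0, got {self.od600}")
        if self.a630 < 0:
            raise ValueError(f"a630 must be >= 0, got {self.a630}")


def siderophore_score(read: AssayRead | None = None, *, a630: float | None = None,
                      a630_ref: float | None = None, od600: float | None = None) -> float:
    """Raw siderophore score ``(1 - a630/a630_ref) / od600``.

    Accepts either an :class:`AssayRead` or the three raw values as keyword
    arguments.  The score is the OD-corrected fractional loss of CAS dye
    absorbance; it may be negative when the assay read exceeds the reference
    (scores are shifted later by :func:`standardize_min_zero`).
    """
    if read is not None:
        a630, a630_ref, od600 = read.a630, read.a630_ref, read.od600
    if a630 is None or a630_ref is None or od600 is None:
        raise TypeError("provide an AssayRead or a630, a630_ref and od600")
    if not a630_ref > 0:
        raise ValueError(f"a630_ref must be > 0, got {a630_ref}")
    if not od600 > 0:
        raise ValueError(f"od600 must be > 0, got {od600}")
    if od600 < OD_WARN_THRESHOLD:
        warnings.warn(
            f"od600={od600} is below {OD_WARN_THRESHOLD}; the OD correction "
            "is poorly conditioned for non-growing isolates",
            RuntimeWarning,
            stacklevel=2,
        )
    return (1.0 - a630 / a630_ref) / od600


def standardize_min_zero(scores) -> np.ndarray:
    """Shift a score collection so the minimum observed value is zero.

    The shift is applied only when the minimum is negative (negative raw
    scores arise when reference-corrected absorbance reads are negative);
    all-nonnegative collections are returned unchanged.  Rank order is
    always preserved.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot standardize an empty score collection")
    lo = arr.min()
    if lo < 0:
        return arr - lo
    return arr.copy()


def quantify_reads(assays: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Quantify a table of assay reads into siderophore scores.

    Parameters
    ----------
    assays : DataFrame
        Must carry columns ``isolate_id``, ``a630``, ``a630_ref``, ``od600``.
    standardize : bool
        Apply the dataset-wide min-zero standardization (the shift scope is
        the whole table, not per plate).

    Returns
    -------
    DataFrame with columns ``isolate_id``, ``siderophore_raw``, ``siderophore``.
    """
    required = ["isolate_id", "a630", "a630_ref", "od600"]
    missing = [c for c in required if c not in assays.columns]
    if missing:
        raise ValueError(f"assay table is missing column(s): {missing}")
    if len(assays) == 0:
        raise ValueError("assay table is empty")
    a = assays["a630"].to_numpy(float)
    ref = assays["a630_ref"].to_numpy(float)
    od = assays["od600"].to_numpy(float)
    if np.any(ref <= 0):
        bad = assays.index[ref <= 0][0]
        raise ValueError(f"a630_ref must be > 0 (row {bad})")
    if np.any(od <= 0):
        bad = assays.index[od <= 0][0]
        raise ValueError(f"od600 must be > 0 (row {bad})")
    if np.any(od < OD_WARN_THRESHOLD):
        warnings.warn(
            f"{int(np.sum(od < OD_WARN_THRESHOLD))} read(s) have od600 below "
            f"{OD_WARN_THRESHOLD}; scores may be ill-conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
    raw = (1.0 - a / ref) / od
    out = pd.DataFrame(
        {
            "isolate_id": assays["isolate_id"].to_numpy(),
            "siderophore_raw": raw,
            "siderophore": standardize_min_zero(raw) if standardize else raw,
        }
    )
    return out
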