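"""Comparative-CT (2^-ddCt) quantification for qPCR data.

Relative expression of a target gene versus a reference (housekeeping) gene
is 2**-(Ct_target - Ct_ref); the fold change between two arms is
2**-(mean dCt treated - mean dCt control).  PCR efficiency is fixed at 2
(100%); no efficiency correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CT_COLUMNS", "relative_expression", "ddct_fold_change", "DdctResult"]

#: required columns of a Ct table
CT_COLUMNS = ["sample", "condition", "target_gene", "ct_target", "reference_gene", "ct_ref"]


def relative_expression(
    ct_target: float, ct_ref: float, calibrator: tuple[float, float] | None = None
) -> float:
    """Relative expression ``2**-(ct_target - ct_ref)``.

    Parameters
    ----------
    ct_target, ct_ref
        Threshold cycles of the target and the reference gene measured on
        the same sample.  Both must be finite.
    calibrator
        Optional ``(ct_target, ct_ref)`` of a calibrator sample; when given
        the result is rescaled so the calibrator's relative expression is 1
        (i.e. a per-sample 2**-ddCt against that sample).
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    rel = float(2.0 ** -(ct_target - ct_ref))
    if calibrator is not None:
        rel /= relative_expression(*calibrator)
    return rel


@dataclass
class DdctResult:
    """Fold change between two arms by the comparative-CT method."""

    fold_change: float
    #: per-replicate relative expressions (2^-dCt), treated arm
    treated_rel: np.ndarray
    #: per-replicate relative expressions, control arm
    control_rel: np.ndarray
    treated_mean: float = field(init=False)
    treated_sem: float = field(init=False)
    control_mean: float = field(init=False)
    control_sem: float = field(init=False)

    def __post_init__(self) -> None:
        self.treated_mean = float(np.mean(self.treated_rel))
        self.control_mean = float(np.mean(self.control_rel))
        self.treated_sem = _sem(self.treated_rel)
        self.control_sem = _sem(self.control_rel)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def _dct(rows: pd.DataFrame) -> np.ndarray:
    missing = [c for c in ("ct_target", "ct_ref") if c not in rows.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    dct = rows["ct_target"].to_numpy(dtype=float) - rows["ct_ref"].to_numpy(dtype=float)
    if not np.all(np.isfinite(dct)):
        raise ValueError("Ct values must be finite")
    return dct


def ddct_fold_change(treated: pd.DataFrame, control: pd.DataFrame) -> DdctResult:
    """Fold change of the treated arm over the control arm.

    ddCt is computed on the mean dCt of each arm (the standard comparative-CT
    convention); per-replicate relative expressions and their mean +/- SEM are
    reported alongside, since that is how such experiments are summarised.

    Parameters
    ----------
    treated, control
        Ct-table rows (one row per replicate) with ``ct_target`` and
        ``ct_ref`` columns; both arms must be non-empty.
    """
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("both arms must contain at least one replicate")
    dct_t = _dct(treated)
    dct_c = _dct(control)
    ddct = float(np.mean(dct_t) - np.mean(dct_c))
    return DdctResult(
        fold_change=float(2.0 ** -ddct),
        treated_rel=2.0 ** -dct_t,
        control_rel=2.0 ** -dct_c,
    )
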