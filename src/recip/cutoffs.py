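"""Data-driven selection of the volume-change cutoffs.

The response and progression thresholds of the classification are developed
by evaluating candidate percent-change cut points (by default 10/20/30/40/50%
in each direction) for their prognostic value: each candidate binarizes the
cohort (meets the cutoff vs not) and the Harrell C-index of that indicator
against overall survival is computed. Per direction the candidate with the
highest C-index wins; candidates within a small tolerance of the best are
treated as ties and resolved toward the larger magnitude, which is more
robust to measurement error and biologic variability in tumor-volume
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .criteria import VolumeCutoffs, percent_change
from .errors import UndefinedStatisticError
from .survival import SurvivalSample, harrell_cindex

DEFAULT_CANDIDATES = (10.0, 20.0, 30.0, 40.0, 50.0)
DEFAULT_TIE_TOLERANCE = 0.005


@dataclass
class CutoffTable:
    """Per-candidate prognostic C-indices and, once selected, the chosen cutoffs.

    ``rows`` has columns ``direction`` ('response'/'progression'), ``cutoff``
    (signed percent), ``magnitude``, ``c_index``, ``se``, ``n_meeting``;
    undefined C-indices (a candidate that splits off an empty group) are kept
    as NaN rows rather than dropped.
    """

    rows: pd.DataFrame
    selection: dict = field(default_factory=dict)


def evaluate_cutoffs(
    cohort: Cohort,
    candidates=DEFAULT_CANDIDATES,
) -> CutoffTable:
    """C-index of each candidate response/progression cutoff against survival.

    Directions are evaluated independently: a response candidate -m
    binarizes patients into change <= -m vs not (non-responders carry the
    higher risk), a progression candidate +m into change >= +m vs not
    (progressors carry the higher risk). Deterministic in the cohort;
    patient order is irrelevant.
    """
    magnitudes = sorted(float(abs(m)) for m in candidates)
    if any(m <= 0 for m in magnitudes):
        raise ValueError("cutoff magnitudes must be positive")
    changes = np.array(
        [percent_change(rec.baseline_vol, rec.interim_vol) for rec in cohort]
    )
    sample = SurvivalSample(
        times=np.array([rec.os_months for rec in cohort], dtype=float),
        events=np.array([rec.os_event for rec in cohort], dtype=int),
    )
    rows = []
    for direction in ("response", "progression"):
        for m in magnitudes:
            if direction == "response":
                meets = changes <= -m
                risk = (~meets).astype(float)  # non-response is the higher risk
                cutoff = -m
            else:
                meets = changes >= m
                risk = meets.astype(float)
                cutoff = m
            n_meeting = int(meets.sum())
            if n_meeting == 0 or n_meeting == len(changes):
                c, se = float("nan"), float("nan")
            else:
                try:
                    res = harrell_cindex(sample, risk)
                    c, se = res.c, res.se
                except UndefinedStatisticError:
                    c, se = float("nan"), float("nan")
            rows.append(
                {
                    "direction": direction,
                    "cutoff": cutoff,
                    "magnitude": m,
                    "c_index": c,
                    "se": se,
                    "n_meeting": n_meeting,
                }
            )
    return CutoffTable(rows=pd.DataFrame(rows))


def select_cutoffs(
    table: CutoffTable,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> VolumeCutoffs:
    """Pick the response and progression cutoffs from an evaluated table.

    Per direction the candidate with the maximal C-index is chosen; every
    candidate within ``tie_tolerance`` of the maximum is considered
    equivalent and the largest magnitude among them wins (measurement-error
    robustness). The selection rationale is recorded on the table.
    """
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be nonnegative")
    selection: dict = {"tie_tolerance": tie_tolerance}
    chosen: dict[str, float] = {}
    for direction in ("response", "progression"):
        sub = table.rows[table.rows["direction"] == direction].dropna(subset=["c_index"])
        if sub.empty:
            raise UndefinedStatisticError(
                f"no defined C-index for any {direction} candidate"
            )
        best_c = sub["c_index"].max()
        tied = sub[sub["c_index"] >= best_c - tie_tolerance]
        pick = tied.loc[tied["magnitude"].idxmax()]
        chosen[direction] = float(pick["magnitude"])
        selection[direction] = {
            "magnitude": float(pick["magnitude"]),
            "c_index": float(pick["c_index"]),
            "best_c_index": float(best_c),
            "tied_magnitudes": [float(m) for m in tied["magnitude"]],
            "tie_break_used": bool(len(tied) > 1),
        }
    table.selection = selection
    return VolumeCutoffs(pr_cut=-chosen["response"], pd_cut=chosen["progression"])
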