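"""RECIP 1.0 response classification and composite PSA+RECIP endpoints.

RECIP 1.0 grades treatment response on paired PSMA PET/CT scans from two
inputs: the percent change in total PSMA-positive tumor volume (PSMA-VOL)
between baseline and the ~12-week interim scan, and whether new lesions
appeared on the interim scan.

Categories:

* ``CR`` — no residual PSMA-ligand uptake on the interim scan (zero volume).
* ``PR`` — volume decline beyond the response cutoff (default 30%) *without*
  new lesions.
* ``PD`` — volume increase beyond the progression cutoff (default 20%)
  *with* new lesions.
* ``SD`` — everything else, including the heterogeneous-response pattern of
  a volume decline accompanied by new lesions.

PSA response follows PCWG3: a decline of at least 50% is a response, an
increase of at least 25% is progression. The composite PSA+RECIP endpoints
are two independent binary indicators: responder = PSA response OR
RECIP-PR/CR; progressor = PSA progression OR RECIP-PD.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import Cohort
from .consensus import consensus_call
from .errors import CohortValidationError, DegenerateBaselineError


class RecipCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class PsaCategory(str, Enum):
    RESPONSE = "response"
    PROGRESSION = "progression"
    NEITHER = "neither"


class VolumeResponse(str, Enum):
    """Volume-only response label, before new-lesion information is applied."""

    VOL_PR = "VOL_PR"
    VOL_SD = "VOL_SD"
    VOL_PD = "VOL_PD"


@dataclass(frozen=True)
class VolumeCutoffs:
    """Percent-change thresholds defining volume response and progression.

    ``pr_cut`` is the (negative) response threshold and ``pd_cut`` the
    (positive) progression threshold. ``inclusive`` controls boundary
    behavior: inclusive thresholds treat a change of exactly ``pr_cut`` as a
    response (the convention used for the PSA thresholds); the strict variant
    is retained for completeness.
    """

    pr_cut: float = -30.0
    pd_cut: float = 20.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.pr_cut < 0.0 < self.pd_cut):
            raise ValueError(
                f"require pr_cut < 0 < pd_cut, got ({self.pr_cut}, {self.pd_cut})"
            )


@dataclass(frozen=True)
class CompositeEndpoint:
    """The two independent PSA+RECIP binary endpoints.

    A patient can be both responder and progressor (e.g. a deep PSA decline
    with new lesions and volume progression); the two flags are analyzed
    separately and no precedence is imposed.
    """

    is_responder: int
    is_progressor: int


def percent_change(baseline: float, interim: float) -> float:
    """Signed percent change of ``interim`` relative to ``baseline``.

    Returns ``100 * (interim - baseline) / baseline``; -30 means a 30%
    decline. Raises :class:`DegenerateBaselineError` for a non-positive
    baseline, which has no defined percent change.
    """
    if baseline <= 0:
        raise DegenerateBaselineError(
            f"percent change undefined for baseline {baseline}"
        )
    return 100.0 * (interim - baseline) / baseline


def classify_volume_response(
    change: float, cutoffs: VolumeCutoffs = VolumeCutoffs()
) -> VolumeResponse:
    """Three-level volume-only label from a percent change in PSMA-VOL."""
    if cutoffs.inclusive:
        if change <= cutoffs.pr_cut:
            return VolumeResponse.VOL_PR
        if change >= cutoffs.pd_cut:
            return VolumeResponse.VOL_PD
    else:
        if change < cutoffs.pr_cut:
            return VolumeResponse.VOL_PR
        if change > cutoffs.pd_cut:
            return VolumeResponse.VOL_PD
    return VolumeResponse.VOL_SD


def classify_recip(
    baseline_vol: float,
    interim_vol: float,
    new_lesion: int,
    cutoffs: VolumeCutoffs = VolumeCutoffs(),
) -> RecipCategory:
    """RECIP 1.0 category from paired volumes and the consensus new-lesion call.

    CR requires zero interim volume and no new lesion (a new lesion with zero
    residual uptake is contradictory input). Otherwise PR/PD require the
    volume criterion *and* the matching new-lesion state; every remaining
    combination — including volume response with new lesions and volume
    progression without them — is SD.
    """
    if baseline_vol <= 0:
        raise DegenerateBaselineError(
            "RECIP requires measurable baseline disease (baseline_vol > 0)"
        )
    if interim_vol < 0:
        raise CohortValidationError(f"negative interim volume {interim_vol}")
    if new_lesion not in (0, 1):
        raise CohortValidationError(f"new_lesion must be 0 or 1, got {new_lesion}")
    if interim_vol == 0 and new_lesion == 0:
        return RecipCategory.CR
    vol = classify_volume_response(percent_change(baseline_vol, interim_vol), cutoffs)
    if vol is VolumeResponse.VOL_PR and new_lesion == 0:
        return RecipCategory.PR
    if vol is VolumeResponse.VOL_PD and new_lesion == 1:
        return RecipCategory.PD
    return RecipCategory.SD


def classify_psa(psa_baseline: float, psa_interim: float) -> PsaCategory:
    """PCWG3 PSA category: >=50% decline -> response, >=25% increase -> progression."""
    change = percent_change(psa_baseline, psa_interim)
    if change <= -50.0:
        return PsaCategory.RESPONSE
    if change >= 25.0:
        return PsaCategory.PROGRESSION
    return PsaCategory.NEITHER


def composite_endpoints(psa: PsaCategory, recip: RecipCategory) -> CompositeEndpoint:
    """PSA+RECIP composite flags: two independent disjunctions."""
    responder = int(
        psa is PsaCategory.RESPONSE or recip in (RecipCategory.PR, RecipCategory.CR)
    )
    progressor = int(psa is PsaCategory.PROGRESSION or recip is RecipCategory.PD)
    return CompositeEndpoint(is_responder=responder, is_progressor=progressor)


def classify_cohort(
    cohort: Cohort,
    cutoffs: VolumeCutoffs = VolumeCutoffs(),
    consensus_policy: str = "majority",
) -> pd.DataFrame:
    """Label every patient of a cohort.

    Consensus new-lesion calls are taken from the record when present and
    otherwise derived from the reader calls under ``consensus_policy``.
    Returns one row per patient, order preserved, with columns
    ``patient_id, vol_change_pct, new_lesion, recip, psa_cat,
    composite_responder, composite_progressor, os_months, os_event``.
    """
    rows = []
    for rec in cohort:
        if rec.consensus_new_lesion is not None:
            nl = rec.consensus_new_lesion
        elif rec.reader_calls:
            nl = consensus_call(rec.reader_calls, policy=consensus_policy)
        else:
            raise CohortValidationError(
                f"patient {rec.patient_id!r}: no consensus call and no reader calls"
            )
        change = percent_change(rec.baseline_vol, rec.interim_vol)
        recip = classify_recip(rec.baseline_vol, rec.interim_vol, nl, cutoffs)
        psa = classify_psa(rec.psa_baseline, rec.psa_interim)
        comp = composite_endpoints(psa, recip)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "vol_change_pct": change,
                "new_lesion": nl,
                "recip": recip.value,
                "psa_cat": psa.value,
                "composite_responder": comp.is_responder,
                "composite_progressor": comp.is_progressor,
                "os_months": rec.os_months,
                "os_event": rec.os_event,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "vol_change_pct",
            "new_lesion",
            "recip",
            "psa_cat",
            "composite_responder",
            "composite_progressor",
            "os_months",
            "os_event",
        ],
    )


#: Ordinal risk encoding of RECIP for prognostic analyses (higher = worse).
RECIP_RISK_ORDER = {
    RecipCategory.CR.value: -1,
    RecipCategory.PR.value: 0,
    RecipCategory.SD.value: 1,
    RecipCategory.PD.value: 2,
}


def recip_risk(labels) -> np.ndarray:
    """Map RECIP labels to ordinal risk scores (CR<PR<SD<PD)."""
    return np.asarray([RECIP_RISK_ORDER[str(v)] for v in labels], dtype=float)
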