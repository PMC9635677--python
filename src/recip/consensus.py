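"""Multi-reader consensus calls and inter-reader agreement (Fleiss kappa).

Interim scans are read independently by several masked readers for
appearance of new lesions. Clinically, disagreements are resolved in a
consensus session; in software that adjudication is approximated by an
explicit policy (majority vote by default). Agreement among the independent
reads is quantified by Fleiss' multi-rater kappa on the binary call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .errors import CohortValidationError, UndefinedStatisticError

POLICIES = ("majority", "unanimous-positive")


@dataclass(frozen=True)
class AgreementResult:
    """Fleiss kappa and the share of subjects with unanimous reads.

    ``kappa`` is NaN (with ``kappa_defined=False``) when every rating across
    all subjects and readers falls in one category, which makes the
    chance-corrected denominator zero.
    """

    kappa: float
    full_agreement_fraction: float
    n_subjects: int
    n_readers: int
    kappa_defined: bool = True


def consensus_call(calls: Sequence[int], policy: str = "majority") -> int:
    """Collapse per-reader binary calls into one consensus call.

    ``majority`` requires an odd number of readers and returns the modal
    call; ``unanimous-positive`` returns 1 only when every reader calls 1.
    """
    calls = [int(c) for c in calls]
    if not calls:
        raise CohortValidationError("no reader calls provided")
    if any(c not in (0, 1) for c in calls):
        raise CohortValidationError(f"reader calls must be binary, got {calls}")
    if policy == "majority":
        if len(calls) % 2 == 0:
            raise CohortValidationError(
                "majority policy undefined for an even reader count; "
                "choose an explicit policy"
            )
        return int(sum(calls) * 2 > len(calls))
    if policy == "unanimous-positive":
        return int(all(calls))
    raise ValueError(f"unknown consensus policy {policy!r}; choose from {POLICIES}")


def ratings_matrix(cohort) -> np.ndarray:
    """Stack the per-reader calls of a cohort into a subjects x readers array."""
    calls = [rec.reader_calls for rec in cohort]
    n_readers = {len(c) for c in calls}
    if len(n_readers) != 1:
        raise CohortValidationError("all patients must have the same reader count")
    return np.asarray(calls, dtype=int)


def fleiss_kappa(ratings: np.ndarray) -> AgreementResult:
    """Fleiss' kappa for binary ratings on a complete subjects x readers grid.

    Chance agreement is computed from the pooled category marginals
    (fixed-marginal convention). When all ratings are identical the statistic
    is undefined; the result then carries ``kappa = NaN`` and
    ``full_agreement_fraction = 1``.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2:
        raise CohortValidationError("ratings must be a 2-D subjects x readers array")
    n_subjects, n_readers = ratings.shape
    if n_subjects < 1 or n_readers < 2:
        raise CohortValidationError("need at least 1 subject and 2 readers")
    if not np.isin(ratings, (0, 1)).all():
        raise CohortValidationError("ratings must be binary (0/1)")

    positives = ratings.sum(axis=1)
    full_agreement = float(np.mean((positives == 0) | (positives == n_readers)))
    counts = np.column_stack([n_readers - positives, positives])

    p_marginal = counts.sum(axis=0) / counts.sum()
    p_expected = float((p_marginal**2).sum())
    if p_expected >= 1.0 - 1e-15:
        return AgreementResult(
            kappa=float("nan"),
            full_agreement_fraction=full_agreement,
            n_subjects=n_subjects,
            n_readers=n_readers,
            kappa_defined=False,
        )
    kappa = float(_sm_fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(
        kappa=kappa,
        full_agreement_fraction=full_agreement,
        n_subjects=n_subjects,
        n_readers=n_readers,
    )


def derive_consensus(cohort, policy: str = "majority"):
    """Fill missing consensus calls of a cohort in place-of (returns a new cohort).

    Records with an existing consensus call keep it; all others get the
    policy-derived call. Provenance records the policy used.
    """
    from .cohort import Cohort, PatientRecord

    records = []
    for rec in cohort:
        consensus = (
            rec.consensus_new_lesion
            if rec.consensus_new_lesion is not None
            else consensus_call(rec.reader_calls, policy=policy)
        )
        records.append(
            PatientRecord(
                patient_id=rec.patient_id,
                baseline_vol=rec.baseline_vol,
                interim_vol=rec.interim_vol,
                reader_calls=rec.reader_calls,
                psa_baseline=rec.psa_baseline,
                psa_interim=rec.psa_interim,
                os_months=rec.os_months,
                os_event=rec.os_event,
                consensus_new_lesion=consensus,
            )
        )
    provenance = dict(cohort.provenance)
    provenance["consensus_policy"] = policy
    return Cohort(records=records, provenance=provenance)
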