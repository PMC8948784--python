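"""Disease-activity state labelling and longitudinal sample pairing.

Two label families are supported.  The *biochemical* family uses fecal
calprotectin (FCP): active disease at >= 250 mg/g, remission below 100 mg/g,
anything in between indeterminate.  The *clinical* family uses the Harvey
Bradshaw Index for Crohn's disease (active >= 5, remission < 4; HBI = 4 sits
in the definitional gap and is indeterminate) and the Simple Clinical Colitis
Activity Index for UC/IBD-U (active >= 3, remission <= 2; no gap).

Consecutive same-patient samples whose states are both determinate form a
:class:`SamplePair` carrying a transition-group code: the letter encodes the
family (A clinical, B biochemical), the digit the state transition —
1 remission→remission, 2 remission→active, 3 active→active, 4 active→remission.
The first sample of a pair is the one whose VOC profile is later used to
predict the state at the second collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .io import SampleRecord

__all__ = [
    "ActivityState",
    "Family",
    "StateThresholds",
    "SamplePair",
    "LabellingError",
    "classify_biochemical",
    "classify_clinical",
    "classify",
    "pair_samples",
    "pair_samples_detailed",
    "group_counts",
    "GROUP_CODES",
]

logger = logging.getLogger(__name__)

GROUP_CODES = ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")


class LabellingError(ValueError):
    """Raised when a record cannot be labelled for the requested family."""


class ActivityState(Enum):
    REMISSION = "remission"
    ACTIVE = "active"
    INDETERMINATE = "indeterminate"


class Family(Enum):
    CLINICAL = "clinical"
    BIOCHEMICAL = "biochemical"

    @property
    def letter(self) -> str:
        return "A" if self is Family.CLINICAL else "B"


@dataclass(frozen=True)
class StateThresholds:
    """Activity cut-offs; defaults are the study definitions.

    ``*_active`` bounds are inclusive lower bounds for ACTIVE; ``fcp_remission``
    and ``hbi_remission`` are exclusive upper bounds for REMISSION, while
    ``sccai_remission`` is inclusive.  The gaps ([100, 250) mg/g FCP, HBI = 4)
    are labelled INDETERMINATE.  Kept configurable because the surrounding
    literature uses FCP cut-offs anywhere in 200-250 ug/g.
    """

    fcp_active: float = 250.0
    fcp_remission: float = 100.0
    hbi_active: int = 5
    hbi_remission: int = 4
    sccai_active: int = 3
    sccai_remission: int = 2

    def __post_init__(self) -> None:
        if self.fcp_remission > self.fcp_active:
            raise ValueError("fcp_remission must not exceed fcp_active")
        if self.hbi_remission > self.hbi_active:
            raise ValueError("hbi_remission must not exceed hbi_active")
        if self.sccai_remission > self.sccai_active:
            raise ValueError("sccai_remission must not exceed sccai_active")


DEFAULT_THRESHOLDS = StateThresholds()

# transition digit from (state_first, state_second)
_DIGIT = {
    (ActivityState.REMISSION, ActivityState.REMISSION): 1,
    (ActivityState.REMISSION, ActivityState.ACTIVE): 2,
    (ActivityState.ACTIVE, ActivityState.ACTIVE): 3,
    (ActivityState.ACTIVE, ActivityState.REMISSION): 4,
}


@dataclass(frozen=True)
class SamplePair:
    """Two consecutive state-labelled samples from one patient."""

    patient_id: str
    first: SampleRecord
    second: SampleRecord
    family: Family
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUP_CODES:
            raise ValueError(f"unknown transition group {self.group!r}")
        if self.first.seq_index >= self.second.seq_index:
            raise ValueError("first sample must precede second in collection order")


def classify_biochemical(
    fcp: float | None, thresholds: StateThresholds = DEFAULT_THRESHOLDS
) -> ActivityState:
    """Label a fecal calprotectin value (mg/g)."""
    if fcp is None:
        raise LabellingError("FCP value required for biochemical labelling")
    if fcp < 0:
        raise LabellingError("FCP must be non-negative")
    if fcp >= thresholds.fcp_active:
        return ActivityState.ACTIVE
    if fcp < thresholds.fcp_remission:
        return ActivityState.REMISSION
    return ActivityState.INDETERMINATE


def classify_clinical(
    record: SampleRecord, thresholds: StateThresholds = DEFAULT_THRESHOLDS
) -> ActivityState:
    """Label a sample by its clinical activity score (HBI for CD, SCCAI for UC/IBDU)."""
    if record.subtype == "CD":
        if record.hbi is None:
            raise LabellingError(f"sample {record.sample_id}: HBI required for CD")
        if record.hbi >= thresholds.hbi_active:
            return ActivityState.ACTIVE
        if record.hbi < thresholds.hbi_remission:
            return ActivityState.REMISSION
        return ActivityState.INDETERMINATE
    if record.sccai is None:
        raise LabellingError(f"sample {record.sample_id}: SCCAI required for {record.subtype}")
    if record.sccai >= thresholds.sccai_active:
        return ActivityState.ACTIVE
    return ActivityState.REMISSION


def classify(
    record: SampleRecord,
    family: Family,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> ActivityState:
    if family is Family.BIOCHEMICAL:
        return classify_biochemical(record.fcp, thresholds)
    return classify_clinical(record, thresholds)


@dataclass
class PairingResult:
    pairs: list[SamplePair] = field(default_factory=list)
    dropped: list[tuple[str, str, str, str]] = field(default_factory=list)
    """Exclusions as (patient_id, first_sample_id, second_sample_id, reason)."""


def pair_samples_detailed(
    records: list[SampleRecord],
    family: Family,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> PairingResult:
    """Assemble consecutive same-patient pairs, keeping a log of exclusions.

    Adjacency is in collection order (``seq_index``); a middle sample may
    serve as the second element of one pair and the first of the next.  Pairs
    where either state is INDETERMINATE or the family's variable is missing
    are dropped, never raised.
    """
    result = PairingResult()
    by_patient: dict[str, list[SampleRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    for patient_id in sorted(by_patient):
        recs = sorted(by_patient[patient_id], key=lambda r: r.seq_index)
        for first, second in zip(recs, recs[1:]):
            try:
                s1 = classify(first, family, thresholds)
                s2 = classify(second, family, thresholds)
            except LabellingError as exc:
                result.dropped.append((patient_id, first.sample_id, second.sample_id, str(exc)))
                continue
            if ActivityState.INDETERMINATE in (s1, s2):
                which = "first" if s1 is ActivityState.INDETERMINATE else "second"
                result.dropped.append(
                    (patient_id, first.sample_id, second.sample_id, f"{which} sample indeterminate")
                )
                continue
            group = f"{family.letter}{_DIGIT[(s1, s2)]}"
            result.pairs.append(SamplePair(patient_id, first, second, family, group))
    for patient_id, fid, sid, reason in result.dropped:
        logger.info("dropped pair %s (%s, %s): %s", patient_id, fid, sid, reason)
    return result


def pair_samples(
    records: list[SampleRecord],
    family: Family,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> list[SamplePair]:
    """Like :func:`pair_samples_detailed` but returning only the pairs."""
    return pair_samples_detailed(records, family, thresholds).pairs


def group_counts(pairs: list[SamplePair]) -> dict[str, int]:
    """Count pairs per transition group; absent codes are reported as 0."""
    counts = {code: 0 for code in GROUP_CODES}
    for pair in pairs:
        counts[pair.group] += 1
    return counts
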