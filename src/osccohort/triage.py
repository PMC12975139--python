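"""ClinVar-style clinical-significance triage.

A variant is "clinically relevant" when its normalized clinical-significance
labels intersect a configurable allowlist.  The default allowlist is the
union of the classifier classes used for downstream analysis (pathogenic,
likely pathogenic, risk allele, drug response, association, likely
association, protective) and the label variants that actually occur in
curated ClinVar exports alongside them ("risk factor", "uncertain risk
allele", "affects").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

from .variant_io import SampleCall

log = logging.getLogger(__name__)

#: Default set of qualifying (normalized) clinical-significance labels.
DEFAULT_QUALIFYING_LABELS = frozenset(
    {
        "pathogenic",
        "likely_pathogenic",
        "risk_factor",
        "risk_allele",
        "uncertain_risk_allele",
        "likely_risk_allele",
        "drug_response",
        "association",
        "likely_association",
        "protective",
        "affects",
    }
)

_TOKEN_SPLIT = re.compile(r"[|,]")


def parse_clnsig(raw: str | None) -> set[str]:
    """Normalize a raw CLNSIG string into a set of label tokens.

    Splits on ``|`` and ``,``; lowercases; spaces become underscores;
    slash-joined combinations (``Pathogenic/Likely_pathogenic``) expand to
    both tokens.  Unknown tokens are preserved verbatim, never dropped.
    Total function: empty/None input yields the empty set.
    """
    if not raw:
        return set()
    labels: set[str] = set()
    for part in _TOKEN_SPLIT.split(raw):
        part = part.strip().lower().replace(" ", "_")
        if not part:
            continue
        for token in part.split("/"):
            token = token.strip("_")
            if token:
                labels.add(token)
    return labels


@dataclass(frozen=True)
class TriageConfig:
    qualifying_labels: frozenset[str] = DEFAULT_QUALIFYING_LABELS
    match_mode: str = "any-label"  # or "all-labels"

    def __post_init__(self) -> None:
        if not self.qualifying_labels:
            raise ValueError("qualifying_labels must be nonempty")
        for tok in self.qualifying_labels:
            if tok != tok.lower() or " " in tok:
                raise ValueError(f"label token {tok!r} must be lowercase, underscored")
        if self.match_mode not in ("any-label", "all-labels"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")


@dataclass
class TriageResult:
    relevant_calls: list[SampleCall]
    per_patient_tumor_counts: dict[str, int]
    patients_without_tumor: list[str] = field(default_factory=list)


def call_qualifies(call: SampleCall, config: TriageConfig) -> bool:
    labels = call.variant.clnsig_labels
    if not labels:
        return False
    if config.match_mode == "any-label":
        return bool(labels & config.qualifying_labels)
    return labels <= config.qualifying_labels


def triage_cohort(
    calls: Iterable[SampleCall], config: TriageConfig | None = None
) -> TriageResult:
    """Retain calls whose labels qualify and count per-patient relevant
    variants over each patient's tumor sample.

    Patients with no tumor sample are excluded from the count table with a
    logged notice (their normal-tissue calls still pass through for origin
    comparison).  Idempotent: triaging an already-triaged set is a no-op.
    """
    config = config or TriageConfig()
    calls = list(calls)
    retained = [c for c in calls if call_qualifies(c, config)]

    counts: dict[str, int] = {}
    patients_with_tumor = {c.patient_id for c in calls if c.tissue == "tumor"}
    all_patients = {c.patient_id for c in calls}
    for call in retained:
        if call.tissue == "tumor":
            counts[call.patient_id] = counts.get(call.patient_id, 0) + 1
    no_tumor = sorted(all_patients - patients_with_tumor)
    for pid in no_tumor:
        log.info("patient %s has no tumor sample; excluded from relevant counts", pid)
    return TriageResult(
        relevant_calls=retained,
        per_patient_tumor_counts=dict(sorted(counts.items())),
        patients_without_tumor=no_tumor,
    )
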