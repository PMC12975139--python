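"""Germline / somatic origin classification by matched tumor-normal
comparison, cohort germline-fraction summary, and tumor-exclusive variant
detection.

A relevant tumor variant present in the patient's matched normal tissue is
germline; present only in the tumor (with a matched normal available) it is
somatic; without a matched normal it stays unclassified.  Matching is by
exact normalized :class:`~osccohort.variant_io.VariantKey` — rsids are
ignored because they can be absent or merged.

A variant is "tumor-exclusive" when it is somatic in at least one patient
and is never observed in any normal tissue of the cohort (not only the
matched one); its cohort frequency is the fraction of qualifying patients
over a configurable denominator (paired patients by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .variant_io import SampleCall, VariantKey

log = logging.getLogger(__name__)

ORIGINS = ("germline", "somatic", "unclassified")


@dataclass(frozen=True)
class OriginCall:
    patient_id: str
    key: VariantKey
    origin: str
    variant: object = None  # AnnotatedVariant when available (for reports)


@dataclass
class OriginSummary:
    per_patient_germline_fraction: dict[str, float]
    mean_germline_fraction: float
    sd_germline_fraction: float
    n_paired: int


def classify_origin(
    tumor_calls: Iterable[SampleCall],
    normal_calls: Iterable[SampleCall] | None,
    patient_id: str,
) -> list[OriginCall]:
    """Classify one patient's relevant tumor variants.

    ``normal_calls=None`` means the patient has no matched normal sample;
    every tumor variant is then unclassified.  Exactly one origin is emitted
    per distinct tumor variant key.
    """
    tumor_calls = [c for c in tumor_calls if c.patient_id == patient_id]
    tumor_samples = {c.sample_id for c in tumor_calls}
    if len(tumor_samples) > 1:
        raise ValueError(
            f"patient {patient_id}: {len(tumor_samples)} tumor samples; "
            "one tumor sample per patient is supported"
        )
    normal_keys: set[VariantKey] | None = None
    if normal_calls is not None:
        normal_keys = {c.key for c in normal_calls if c.patient_id == patient_id}

    out: list[OriginCall] = []
    seen: set[VariantKey] = set()
    for call in tumor_calls:
        if call.key in seen:
            continue
        seen.add(call.key)
        if normal_keys is None:
            origin = "unclassified"
        elif call.key in normal_keys:
            origin = "germline"
        else:
            origin = "somatic"
        out.append(OriginCall(patient_id, call.key, origin, variant=call.variant))
    return out


def classify_cohort_origins(
    relevant_calls: Iterable[SampleCall],
) -> list[OriginCall]:
    """Run :func:`classify_origin` for every patient with a tumor sample."""
    calls = list(relevant_calls)
    by_patient_tumor: dict[str, list[SampleCall]] = {}
    by_patient_normal: dict[str, list[SampleCall]] = {}
    for c in calls:
        d = by_patient_tumor if c.tissue == "tumor" else by_patient_normal
        d.setdefault(c.patient_id, []).append(c)
    # patients whose normal sample exists but yielded zero relevant calls
    # still count as paired; callers that need that distinction pass
    # paired_patients explicitly to cohort_origin_summary.
    out: list[OriginCall] = []
    for pid in sorted(by_patient_tumor):
        normals = by_patient_normal.get(pid)
        out.extend(classify_origin(by_patient_tumor[pid], normals, pid))
    return out


def cohort_origin_summary(origin_calls: Iterable[OriginCall]) -> OriginSummary:
    """Across-patient mean and SD of the per-patient germline proportion.

    Proportion = germline / (germline + somatic), over paired patients only
    (patients with any classified call).  SD is the population SD (divide
    by n), a fixed documented convention.
    """
    counts: dict[str, list[int]] = {}
    for oc in origin_calls:
        if oc.origin == "unclassified":
            continue
        g, s = counts.setdefault(oc.patient_id, [0, 0])
        if oc.origin == "germline":
            counts[oc.patient_id][0] += 1
        else:
            counts[oc.patient_id][1] += 1
    fractions: dict[str, float] = {}
    for pid, (g, s) in sorted(counts.items()):
        if g + s == 0:
            log.info("patient %s: zero classified variants; excluded from summary", pid)
            continue
        fractions[pid] = g / (g + s)
    if not fractions:
        raise ValueError("no paired patient with classified variants")
    vals = list(fractions.values())
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    return OriginSummary(fractions, mean, sd, n_paired=len(fractions))


@dataclass(frozen=True)
class ExclusiveVariant:
    key: VariantKey
    n_patients: int
    denominator: int
    frequency: float
    variant: object = None

    @property
    def percent(self) -> float:
        return 100.0 * self.frequency


def find_exclusive_variants(
    origin_calls: Iterable[OriginCall],
    min_patient_fraction: float,
    *,
    all_normal_keys: set[VariantKey] | None = None,
    denominator: int | None = None,
) -> list[ExclusiveVariant]:
    """Variants somatic in >= 1 patient and never germline in any patient.

    ``all_normal_keys``, when given, additionally excludes variants seen in
    *any* normal sample of the cohort (including unpaired normals), which is
    the strict reading of "exclusively tumor specific".  The frequency
    denominator defaults to the number of paired patients (patients with at
    least one classified call); pass ``denominator`` to use e.g. all tumor
    patients instead.  Results are sorted by descending frequency, ties by
    variant key.
    """
    if not 0 < min_patient_fraction <= 1:
        raise ValueError("min_patient_fraction must be in (0, 1]")
    calls = list(origin_calls)
    paired = {oc.patient_id for oc in calls if oc.origin != "unclassified"}
    if not paired:
        log.warning("no paired patients; exclusive-variant set is empty")
        return []
    denom = denominator if denominator is not None else len(paired)

    germline_keys = {oc.key for oc in calls if oc.origin == "germline"}
    somatic: dict[VariantKey, set[str]] = {}
    rep: dict[VariantKey, object] = {}
    for oc in calls:
        if oc.origin == "somatic":
            somatic.setdefault(oc.key, set()).add(oc.patient_id)
            rep.setdefault(oc.key, oc.variant)

    out = []
    for key, patients in somatic.items():
        if key in germline_keys:
            continue  # germline somewhere: not exclusive
        if all_normal_keys is not None and key in all_normal_keys:
            continue  # observed in some (possibly unpaired) normal tissue
        freq = len(patients) / denom
        if freq >= min_patient_fraction:
            out.append(
                ExclusiveVariant(key, len(patients), denom, freq, variant=rep[key])
            )
    out.sort(key=lambda ev: (-ev.frequency, ev.key))
    return out
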