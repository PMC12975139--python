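"""Patients x variants presence matrix, gene/variant prevalence at a
threshold, and the per-patient consequence-type distribution.

Prevalence is presence-based: a patient carries a gene when >= 1 of its
relevant variants is present in the patient's tumor sample.  The prevalence
denominator is the number of patients with a tumor sample and is carried in
every record so counts stay interpretable.  Thresholds are inclusive
("at least 80%" keeps prevalence == 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .variant_io import SampleCall, VariantKey

#: Reserved gene unit for variants without a gene annotation.
INTERGENIC = "(intergenic)"


@dataclass
class CohortMatrix:
    """Boolean presence matrix (patients x variant keys) with per-variant
    gene and consequence indexes."""

    presence: pd.DataFrame  # index: patient_id, columns: str(VariantKey)
    gene_of: pd.Series  # variant -> gene symbol (INTERGENIC when absent)
    consequence_of: pd.Series  # variant -> SO term
    keys: dict[str, VariantKey]  # column label -> VariantKey

    @property
    def n_patients(self) -> int:
        return self.presence.shape[0]


def build_matrix(relevant_tumor_calls: Iterable[SampleCall]) -> CohortMatrix:
    """Aggregate relevant tumor-sample calls into a cohort presence matrix."""
    calls = [c for c in relevant_tumor_calls if c.tissue == "tumor"]
    if not calls:
        raise ValueError("no tumor calls to aggregate")
    patients = sorted({c.patient_id for c in calls})
    keymap: dict[str, VariantKey] = {}
    gene_of: dict[str, str] = {}
    cons_of: dict[str, str] = {}
    cells: set[tuple[str, str]] = set()
    for c in calls:
        label = str(c.key)
        keymap[label] = c.key
        gene_of[label] = c.variant.gene or INTERGENIC
        cons_of[label] = c.variant.consequence or "unknown"
        cells.add((c.patient_id, label))
    variants = sorted(keymap, key=lambda lab: keymap[lab])
    presence = pd.DataFrame(False, index=patients, columns=variants)
    for pid, label in cells:
        presence.at[pid, label] = True
    return CohortMatrix(
        presence=presence,
        gene_of=pd.Series(gene_of).loc[variants],
        consequence_of=pd.Series(cons_of).loc[variants],
        keys=keymap,
    )


@dataclass(frozen=True)
class PrevalenceRecord:
    unit: str
    n_carriers: int
    denominator: int
    prevalence: float

    @property
    def percent(self) -> float:
        return 100.0 * self.prevalence


def gene_prevalence(
    matrix: CohortMatrix, threshold: float, *, include_intergenic: bool = False
) -> list[PrevalenceRecord]:
    """Genes carried (>= 1 relevant variant) by at least ``threshold`` of
    patients, sorted by descending prevalence then symbol."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    carriers = matrix.presence.T.groupby(matrix.gene_of).any().T  # patients x genes
    if not include_intergenic and INTERGENIC in carriers.columns:
        carriers = carriers.drop(columns=[INTERGENIC])
    return _prevalence_records(carriers, threshold, matrix.n_patients)


def variant_prevalence(matrix: CohortMatrix, threshold: float) -> list[PrevalenceRecord]:
    """Individual variants present in at least ``threshold`` of patients."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return _prevalence_records(matrix.presence, threshold, matrix.n_patients)


def _prevalence_records(
    carriers: pd.DataFrame, threshold: float, denom: int
) -> list[PrevalenceRecord]:
    counts = carriers.sum(axis=0)
    out = [
        PrevalenceRecord(unit, int(n), denom, n / denom)
        for unit, n in counts.items()
        if n / denom >= threshold
    ]
    out.sort(key=lambda r: (-r.prevalence, r.unit))
    return out


def consequence_distribution(
    relevant_tumor_calls: Iterable[SampleCall],
) -> pd.DataFrame:
    """Across-patient mean +/- SD of per-patient consequence proportions.

    Per-patient proportions are computed first (they sum to 1 per patient),
    then averaged across patients; SD is the population SD across patients.
    Returns a frame indexed by SO term with columns ``mean`` and ``sd``.
    """
    calls = [c for c in relevant_tumor_calls if c.tissue == "tumor"]
    if not calls:
        raise ValueError("no calls")
    df = pd.DataFrame(
        {
            "patient": [c.patient_id for c in calls],
            "term": [c.variant.consequence or "unknown" for c in calls],
        }
    )
    per_patient = (
        df.groupby(["patient", "term"]).size().unstack(fill_value=0).astype(float)
    )
    per_patient = per_patient.div(per_patient.sum(axis=1), axis=0)
    out = pd.DataFrame(
        {"mean": per_patient.mean(axis=0), "sd": per_patient.std(axis=0, ddof=0)}
    )
    return out.sort_values("mean", ascending=False)
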