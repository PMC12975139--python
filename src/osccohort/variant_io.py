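"""Reading and writing the annotated single-sample VCF dialect, variant
identity normalization, and manifest / clinical-table parsing.

The cohort is exchanged as one VCF 4.2 file per tissue sample, linked by a
manifest TSV (``sample_id, patient_id, tissue, vcf_path``).  Each VCF record
carries the annotation attributes the downstream analysis consumes as INFO
keys:

``GENE``
    gene symbol (absent for intergenic variants)
``CSQ_CONS``
    a single Sequence-Ontology consequence term (e.g. ``intron_variant``,
    ``missense_variant``, ``stop_gained``)
``CLNSIG``
    ClinVar-style clinical significance, labels joined by ``|`` with spaces
    written as underscores
``RS``
    dbSNP identifier (``rs...``), optional
``VARCLASS``
    one of ``SNV``/``insertion``/``deletion``, optional (recomputed from the
    alleles when absent)

Presence semantics: a :class:`SampleCall` is emitted only for non-reference
genotypes; the genotype dosage is recorded but cohort prevalence downstream
counts presence/absence per patient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

TISSUES = ("tumor", "normal")

#: INFO keys every dialect VCF must declare in its header.
REQUIRED_INFO_KEYS = ("GENE", "CSQ_CONS", "CLNSIG", "RS")

VALID_PT = {"1", "2", "3", "4", "4a"}
VALID_PN = {"0", "1", "2", "2a", "2b", "3", "3b", "x"}
VALID_PM = {"0", "1", "x"}

#: Known data-entry aliases in raw TNM strings, applied on the upper-cased
#: string before tokenization.  Unknown token patterns raise, never guess.
TNM_ALIASES = {"NB2": "N2B"}


class VcfDialectError(ValueError):
    """Raised for files that do not conform to the annotated-VCF dialect."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a single ALT allele.

    Coordinates are 1-based as in VCF; alleles are upper-case ACGTN and
    parsimonious (no shared redundant prefix/suffix beyond the anchor base
    required for indels).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} is not ACGTN")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")

    def __str__(self) -> str:  # chr1:100:A>G, used in reports
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def variant_class(ref: str, alt: str) -> str:
    """SNV / insertion / deletion from allele lengths."""
    if len(ref) == len(alt):
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim shared trailing then leading bases, keeping at least one base on
    each side (the indel anchor), and adjust the position.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    ref, alt = ref.upper(), alt.upper()
    for name, allele in (("ref", ref), ("alt", alt)):
        if not _ALLELE_RE.match(allele):
            raise ValueError(f"{name} allele {allele!r} is not ACGTN")
    # shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix (keep the anchor base for indels)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"{chrom}:{pos} {ref}>{alt}: alleles identical after trimming")
    return VariantKey(chrom, pos, ref, alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    key: VariantKey
    rsid: str | None = None
    gene: str | None = None
    consequence: str | None = None
    variant_class: str = "SNV"
    clnsig_raw: str = ""
    clnsig_labels: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SampleCall:
    """One non-reference call of one ALT allele in one tissue sample."""

    sample_id: str
    patient_id: str
    tissue: str
    variant: AnnotatedVariant
    genotype_dosage: int | None = None

    @property
    def key(self) -> VariantKey:
        return self.variant.key


@dataclass
class ClinicalRecord:
    patient_id: str
    tnm_raw: str
    pT: str | None
    pN: str | None
    pM: str | None
    age: int
    sex: str
    site: str = ""
    history: str = ""
    stage: str | None = None
    tnm_parse_error: str | None = None


# ---------------------------------------------------------------------------
# TNM parsing

_TNM_RE = re.compile(
    r"^P?T(?P<t>[1-4])(?P<ta>A)?N(?P<n>[0-3X])(?P<nsub>[AB])?(?:M(?P<m>[01X]))?$"
)


def parse_tnm(raw: str) -> tuple[str, str, str | None]:
    """Parse a raw pathological TNM string into (pT, pN, pM) tokens.

    Case-insensitive; a leading ``P``/``p`` is stripped; known data-entry
    aliases (e.g. ``Nb2`` for ``N2b``) are applied.  Raises ``ValueError``
    for anything else rather than guessing.
    """
    s = raw.strip().upper().replace(" ", "")
    for bad, good in TNM_ALIASES.items():
        s = s.replace(bad, good)
    m = _TNM_RE.match(s)
    if not m:
        raise ValueError(f"unparsable TNM string: {raw!r}")
    pt = m.group("t") + ("a" if m.group("ta") else "")
    pn = m.group("n").lower() + (m.group("nsub").lower() if m.group("nsub") else "")
    pm = m.group("m").lower() if m.group("m") else None
    if pt not in VALID_PT:
        raise ValueError(f"invalid pT token {pt!r} in {raw!r}")
    if pn not in VALID_PN:
        raise ValueError(f"invalid pN token {pn!r} in {raw!r}")
    if pm is not None and pm not in VALID_PM:
        raise ValueError(f"invalid pM token {pm!r} in {raw!r}")
    return pt, pn, pm


# ---------------------------------------------------------------------------
# Clinical table / manifest

REQUIRED_CLINICAL_COLUMNS = ("patient_id", "tnm", "age", "sex")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical TSV (patient_id, tnm, age, sex[, site, history]).

    Rows with unparsable TNM are flagged via ``tnm_parse_error``, never
    silently dropped.  Duplicate patient ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8-sig")
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path}: missing required column(s) {missing}")
    if df["patient_id"].duplicated().any():
        dups = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise ValueError(f"clinical table {path}: duplicate patient_id {dups}")
    records = []
    for row in df.itertuples(index=False):
        pt = pn = pm = None
        err = None
        try:
            pt, pn, pm = parse_tnm(row.tnm)
        except ValueError as exc:
            err = str(exc)
        age = int(row.age)
        if age <= 0:
            raise ValueError(f"patient {row.patient_id}: age must be positive")
        sex = row.sex.strip().lower()
        if sex not in ("male", "female"):
            raise ValueError(f"patient {row.patient_id}: sex must be male/female")
        records.append(
            ClinicalRecord(
                patient_id=row.patient_id,
                tnm_raw=row.tnm,
                pT=pt,
                pN=pn,
                pM=pm,
                age=age,
                sex=sex,
                site=getattr(row, "site", "") or "",
                history=getattr(row, "history", "") or "",
                tnm_parse_error=err,
            )
        )
    return records


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest TSV (sample_id, patient_id, tissue, vcf_path).

    VCF paths are resolved relative to the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8-sig")
    required = ("sample_id", "patient_id", "tissue", "vcf_path")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing required column(s) {missing}")
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"manifest {path}: invalid tissue label(s) {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"manifest {path}: duplicate sample_id")
    base = Path(path).parent
    df["vcf_path"] = [str((base / p)) if not Path(p).is_absolute() else p
                      for p in df["vcf_path"]]
    return df


# ---------------------------------------------------------------------------
# VCF reading

def _info_str(variant, key: str) -> str | None:
    val = variant.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, bytes):
        val = val.decode()
    val = str(val).strip()
    return val or None


def read_annotated_vcf(
    path: str | Path, sample_id: str, patient_id: str, tissue: str
) -> list[SampleCall]:
    """Read one single-sample dialect VCF into :class:`SampleCall` objects.

    One call per ALT allele carried at dosage >= 1; multi-allelic records are
    split into per-allele keys; records with a FILTER other than PASS/``.``
    are excluded.  A header missing a required INFO key is a hard error.
    """
    from .triage import parse_clnsig  # local import to avoid a cycle

    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
    vcf = VCF(str(path))
    try:
        declared = {
            h.info().get("ID")
            for h in vcf.header_iter()
            if h.type == "INFO"
        }
        for key in REQUIRED_INFO_KEYS:
            if key not in declared:
                raise VcfDialectError(
                    f"{path}: VCF header does not declare required INFO key {key!r}"
                )
        calls: list[SampleCall] = []
        for lineno, variant in enumerate(vcf, start=1):
            if variant.FILTER is not None:  # None covers PASS and '.'
                continue
            try:
                gt = variant.genotypes[0]
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                gene = _info_str(variant, "GENE")
                cons = _info_str(variant, "CSQ_CONS")
                clnsig_raw = _info_str(variant, "CLNSIG") or ""
                rsid = _info_str(variant, "RS")
                vclass = _info_str(variant, "VARCLASS")
                for alt_index, alt in enumerate(variant.ALT, start=1):
                    dosage = sum(1 for a in alleles if a == alt_index)
                    if dosage < 1:
                        continue  # reference or other-allele genotype
                    key = normalize_variant(variant.CHROM, variant.POS, variant.REF, alt)
                    av = AnnotatedVariant(
                        key=key,
                        rsid=rsid,
                        gene=gene,
                        consequence=cons,
                        variant_class=(
                            vclass
                            if vclass and len(variant.ALT) == 1
                            else variant_class(key.ref, key.alt)
                        ),
                        clnsig_raw=clnsig_raw,
                        clnsig_labels=frozenset(parse_clnsig(clnsig_raw)),
                    )
                    calls.append(
                        SampleCall(
                            sample_id=sample_id,
                            patient_id=patient_id,
                            tissue=tissue,
                            variant=av,
                            genotype_dosage=dosage,
                        )
                    )
            except VcfDialectError:
                raise
            except Exception as exc:  # surface the failing record
                raise VcfDialectError(
                    f"{path}: unparsable record #{lineno} "
                    f"({variant.CHROM}:{variant.POS}): {exc}"
                ) from exc
        return calls
    finally:
        vcf.close()


def read_cohort_calls(manifest: pd.DataFrame) -> list[SampleCall]:
    """Read every sample VCF referenced by a manifest frame."""
    calls: list[SampleCall] = []
    for row in manifest.itertuples(index=False):
        calls.extend(
            read_annotated_vcf(row.vcf_path, row.sample_id, row.patient_id, row.tissue)
        )
    return calls


# ---------------------------------------------------------------------------
# VCF writing (used by the synthetic generator and round-trip tests)

VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=osccohort
##reference=synthetic
{contigs}##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ_CONS,Number=1,Type=String,Description="Sequence Ontology consequence term">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance labels joined by |">
##INFO=<ID=RS,Number=1,Type=String,Description="dbSNP identifier">
##INFO=<ID=VARCLASS,Number=1,Type=String,Description="SNV, insertion or deletion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_annotated_vcf(
    path: str | Path,
    sample_id: str,
    records: Iterable[tuple[AnnotatedVariant, int]],
    contigs: Sequence[str] = (),
) -> None:
    """Write (variant, dosage) pairs as a sorted single-sample dialect VCF."""
    recs = sorted(records, key=lambda r: (_contig_rank(r[0].key.chrom), r[0].key.pos,
                                          r[0].key.ref, r[0].key.alt))
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    lines = [VCF_HEADER_TEMPLATE.format(contigs=contig_lines, sample=sample_id)]
    for av, dosage in recs:
        info = []
        if av.gene:
            info.append(f"GENE={av.gene}")
        if av.consequence:
            info.append(f"CSQ_CONS={av.consequence}")
        if av.clnsig_raw:
            info.append(f"CLNSIG={av.clnsig_raw.replace(' ', '_')}")
        if av.rsid:
            info.append(f"RS={av.rsid}")
        info.append(f"VARCLASS={av.variant_class}")
        gt = "1/1" if dosage == 2 else "0/1"
        k = av.key
        lines.append(
            f"{k.chrom}\t{k.pos}\t{av.rsid or '.'}\t{k.ref}\t{k.alt}\t.\tPASS\t"
            f"{';'.join(info)}\tGT\t{gt}\n"
        )
    Path(path).write_text("".join(lines))


def _contig_rank(chrom: str) -> tuple[int, str]:
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (int(body), "") if body.isdigit() else (10**6, body)
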