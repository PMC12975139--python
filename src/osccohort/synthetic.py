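"""Fully synthetic FFPE-like annotated-VCF cohort with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a matched tumor-normal oral-cancer exome cohort — not reads or
FFPE chemistry, only the post-annotation variant lists:

* 14 tumor-normal pairs plus 5 tumor-only and 2 normal-only patients;
* per-patient clinically relevant variant counts drawn from a truncated
  normal (mean 171, range 150-197 by default);
* a patient-level germline fraction drawn Normal(0.933, 0.039) truncated to
  [0, 1], applied per variant as a Bernoulli origin;
* a Sequence-Ontology consequence mixture dominated by intronic (~56%) and
  missense (~12%) variants;
* a core set of genes planted in every tumor patient, a configurable
  gene-prevalence spectrum, and tumor-exclusive variants planted at fixed
  patient fractions (never written to any normal VCF);
* PRS inputs: a base GWAS summary-statistic file, an individuals x SNPs
  effect-allele dosage matrix, and case/control labels with cases'
  effect-allele frequencies shifted toward higher expected scores.

Every quantity the analysis should recover is serialized to a JSON truth
file next to the VCFs, so each pipeline stage is testable without any
external download.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import AnnotatedVariant, VariantKey, variant_class, write_annotated_vcf

CONTIGS = tuple(f"chr{i}" for i in range(1, 23))

#: Genes planted with one qualifying variant in every tumor patient.
DEFAULT_CORE_GENES = (
    "ABCB1", "CAPN10", "CD44", "CDC27", "CHI3L1", "CNN2", "COMT",
    "CTBP2", "IGSF3", "IL6", "IL6-AS1", "MAPKAPK3", "MGST3", "NAT2",
    "NOS3", "OPRM1", "PADI2", "SLC2A9", "TBXT", "TLR1", "VKORC1",
)

#: Target patient proportions for additional genes (over tumor patients).
DEFAULT_GENE_PREVALENCE = {
    "PERM1": 0.95,
    "ITPKB": 0.95,
    "XRCC1": 0.80,
    "TP53": 0.24,
    "CDKN2A": 0.14,
    "EGFR": 0.05,
}

#: Tumor-exclusive variants planted at fixed paired-patient fractions, with
#: fixed genomic identity and annotations (rsid, chrom, pos, class, SO term,
#: gene, clinical significance).
DEFAULT_EXCLUSIVE_VARIANTS = (
    ("rs5743618", 1.00, "chr4", 38798648, "SNV", "missense_variant", "TLR1", "Uncertain_risk_allele"),
    ("rs1805010", 0.46, "chr16", 27356203, "SNV", "regulatory_region_variant", "IL4R", "Pathogenic"),
    ("rs546905091", 0.46, "chr8", 48844056, "insertion", "intron_variant", "PRKDC", "Pathogenic"),
    ("rs4337789", 0.31, "chr4", 69973044, "SNV", "intron_variant", "UGT2B7", "Drug_response"),
    ("rs752940775", 0.31, "chr15", 93540315, "insertion", "frameshift_variant", "CHD2", "Pathogenic"),
    ("rs1143634", 0.23, "chr2", 113590390, "SNV", "synonymous_variant", "IL1B", "Affects"),
    ("rs5744168", 0.23, "chr1", 223285200, "SNV", "stop_gained", "TLR5", "Risk_factor"),
    ("rs61737946", 0.23, "chr22", 42523505, "SNV", "missense_variant", "CYP2D6", "Drug_response"),
    ("rs764008859", 0.23, "chr13", 77581682, "deletion", "frameshift_variant", "FBXL3", "Pathogenic"),
    ("rs7809208", 0.23, "chr7", 87214275, "SNV", "intron_variant", "ABCB1", "Drug_response"),
)

DEFAULT_CONSEQUENCE_MIX = {
    "intron_variant": 0.56,
    "missense_variant": 0.12,
    "non_coding_transcript_variant": 0.10,
    "regulatory_region_variant": 0.08,
    "synonymous_variant": 0.06,
    "splice_region_variant": 0.05,
    "frameshift_variant": 0.025,
    "stop_gained": 0.005,
}

#: Qualifying clinical-significance strings (raw dialect form) with weights.
DEFAULT_CLNSIG_POOL = (
    ("Pathogenic", 0.12),
    ("Likely_pathogenic", 0.10),
    ("Pathogenic/Likely_pathogenic", 0.08),
    ("Drug_response", 0.20),
    ("Risk_factor", 0.15),
    ("Uncertain_risk_allele", 0.10),
    ("Association", 0.10),
    ("Likely_association", 0.05),
    ("Protective", 0.05),
    ("Affects", 0.05),
)

_NONRELEVANT_POOL = (("Benign", 0.5), ("Likely_benign", 0.3), ("Uncertain_significance", 0.2))

#: Genes deliberately withheld from the synthetic reference catalogue so the
#: novelty comparison has known-novel genes to find.
DEFAULT_NOVEL_GENES = ("TBXT", "PERM1")


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass
class SimulationConfig:
    n_paired: int = 14
    n_tumor_only: int = 5
    n_normal_only: int = 2
    relevant_count_mean: float = 171.0
    relevant_count_sd: float = 14.0
    relevant_count_min: int = 150
    relevant_count_max: int = 197
    germline_fraction_mean: float = 0.933
    germline_fraction_sd: float = 0.039
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    core_genes: tuple[str, ...] = DEFAULT_CORE_GENES
    gene_prevalence_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PREVALENCE)
    )
    exclusive_variants: tuple = DEFAULT_EXCLUSIVE_VARIANTS
    clnsig_label_pool: tuple = DEFAULT_CLNSIG_POOL
    nonrelevant_fraction: float = 0.15
    background_pool_size: int = 400
    # PRS block
    prs_n_snps: int = 5341
    prs_n_controls: int = 204
    prs_case_shift: float = 0.0067
    prs_beta_sd: float = 0.02
    prs_freq_low: float = 0.10
    prs_freq_high: float = 0.90
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return self.n_paired + self.n_tumor_only + self.n_normal_only

    @property
    def n_tumor_patients(self) -> int:
        return self.n_paired + self.n_tumor_only

    def validate(self) -> None:
        for f in ("n_paired", "n_tumor_only", "n_normal_only"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        if self.n_patients == 0:
            raise ConfigError("n_paired + n_tumor_only + n_normal_only must be > 0")
        if not (
            self.relevant_count_min <= self.relevant_count_mean <= self.relevant_count_max
        ):
            raise ConfigError(
                "relevant_count_min <= relevant_count_mean <= relevant_count_max required"
            )
        if not 0 <= self.germline_fraction_mean <= 1:
            raise ConfigError("germline_fraction_mean must be in [0, 1]")
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"consequence_mix proportions sum to {total}, not 1")
        for term, p in self.consequence_mix.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"consequence_mix[{term!r}] outside [0, 1]")
        for ev in self.exclusive_variants:
            if not 0 < ev[1] <= 1:
                raise ConfigError(f"exclusive variant {ev[0]}: fraction outside (0, 1]")
        if not 0 <= self.nonrelevant_fraction:
            raise ConfigError("nonrelevant_fraction must be >= 0")
        if self.prs_n_snps < 1:
            raise ConfigError("prs_n_snps must be >= 1")
        shifted_low = self.prs_freq_low - self.prs_case_shift
        shifted_high = self.prs_freq_high + self.prs_case_shift
        if shifted_low < 0 or shifted_high > 1:
            raise ConfigError(
                "prs_case_shift pushes case allele frequencies outside [0, 1] "
                f"(range {shifted_low:.3f}..{shifted_high:.3f})"
            )


@dataclass
class CohortBundle:
    outdir: Path
    manifest_path: Path
    clinical_path: Path
    truth_path: Path
    catalogue_path: Path
    prs_base_path: Path
    prs_dosage_path: Path
    prs_labels_path: Path
    truth: dict


# ---------------------------------------------------------------------------
# Primitive draws


def _trunc_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


class _VariantFactory:
    """Draws novel variants with unique per-contig positions."""

    def __init__(self, rng) -> None:
        self.rng = rng
        self.used: dict[str, set[int]] = {c: set() for c in CONTIGS}
        self.rs_counter = 7_000_000

    def reserve(self, chrom: str, pos: int) -> None:
        self.used.setdefault(chrom, set()).add(pos)

    def _position(self, chrom: str) -> int:
        while True:
            pos = int(self.rng.integers(1, 50_000_000))
            if pos not in self.used[chrom]:
                self.used[chrom].add(pos)
                return pos

    def _alleles(self, vclass: str) -> tuple[str, str]:
        bases = "ACGT"
        anchor = bases[self.rng.integers(4)]
        if vclass == "SNV":
            alt = bases[self.rng.integers(4)]
            while alt == anchor:
                alt = bases[self.rng.integers(4)]
            return anchor, alt
        tail = "".join(bases[i] for i in self.rng.integers(0, 4, size=int(self.rng.integers(1, 4))))
        if vclass == "insertion":
            return anchor, anchor + tail
        return anchor + tail, anchor

    def make(self, gene: str | None, consequence: str, clnsig: str,
             vclass: str | None = None) -> AnnotatedVariant:
        if vclass is None:
            if consequence == "frameshift_variant":
                vclass = "insertion" if self.rng.random() < 0.5 else "deletion"
            else:
                vclass = "SNV"
        chrom = CONTIGS[self.rng.integers(len(CONTIGS))]
        pos = self._position(chrom)
        ref, alt = self._alleles(vclass)
        self.rs_counter += int(self.rng.integers(1, 50))
        from .triage import parse_clnsig

        return AnnotatedVariant(
            key=VariantKey(chrom, pos, ref, alt),
            rsid=f"rs{self.rs_counter}",
            gene=gene,
            consequence=consequence,
            variant_class=vclass,
            clnsig_raw=clnsig,
            clnsig_labels=frozenset(parse_clnsig(clnsig)),
        )


def _weighted_choice(rng, pool: Sequence[tuple[str, float]]) -> str:
    labels = [p[0] for p in pool]
    weights = np.array([p[1] for p in pool], float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(config: SimulationConfig, outdir: str | Path) -> CohortBundle:
    """Write the full synthetic bundle (VCFs, manifest, clinical table,
    catalogue, PRS inputs, truth JSON) into ``outdir`` and return it."""
    config.validate()
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_universe = np.random.default_rng(streams[0])
    rng_patients = np.random.default_rng(streams[1])
    rng_clinical = np.random.default_rng(streams[2])
    rng_prs = np.random.default_rng(streams[3])

    factory = _VariantFactory(rng_universe)
    mix_terms = list(config.consequence_mix)
    mix_p = np.array([config.consequence_mix[t] for t in mix_terms], float)
    mix_p = mix_p / mix_p.sum()

    def draw_consequence() -> str:
        return mix_terms[rng_universe.choice(len(mix_terms), p=mix_p)]

    def draw_clnsig() -> str:
        return _weighted_choice(rng_universe, config.clnsig_label_pool)

    # --- variant universe ---------------------------------------------------
    universal = [
        factory.make(gene, draw_consequence(), draw_clnsig())
        for gene in config.core_genes
    ]
    spectrum = {
        gene: factory.make(gene, draw_consequence(), draw_clnsig())
        for gene in config.gene_prevalence_spectrum
    }
    exclusives = []
    for rsid, frac, chrom, pos, vclass, cons, gene, clnsig in config.exclusive_variants:
        factory.reserve(chrom, pos)
        ref, alt = factory._alleles(vclass)
        from .triage import parse_clnsig

        exclusives.append(
            (
                AnnotatedVariant(
                    key=VariantKey(chrom, pos, ref, alt),
                    rsid=rsid,
                    gene=gene,
                    consequence=cons,
                    variant_class=vclass,
                    clnsig_raw=clnsig,
                    clnsig_labels=frozenset(parse_clnsig(clnsig)),
                ),
                frac,
            )
        )
    background = [
        factory.make(f"BG{i:04d}" if rng_universe.random() > 0.05 else None,
                     draw_consequence(), draw_clnsig())
        for i in range(config.background_pool_size)
    ]
    nonrelevant = [
        factory.make(f"NR{i:04d}", draw_consequence(),
                     _weighted_choice(rng_universe, _NONRELEVANT_POOL))
        for i in range(max(50, int(config.background_pool_size * 0.25)))
    ]

    # --- patients -----------------------------------------------------------
    pad = max(2, len(str(config.n_patients)))
    patients = [f"P{i + 1:0{pad}d}" for i in range(config.n_patients)]
    paired = patients[: config.n_paired]
    tumor_only = patients[config.n_paired : config.n_paired + config.n_tumor_only]
    normal_only = patients[config.n_paired + config.n_tumor_only :]
    tumor_patients = paired + tumor_only

    # exact carrier subsets for the prevalence spectrum
    spectrum_carriers: dict[str, list[str]] = {}
    for gene, target in config.gene_prevalence_spectrum.items():
        k = min(len(tumor_patients), _round_half_up(target * len(tumor_patients)))
        idx = rng_patients.choice(len(tumor_patients), size=k, replace=False)
        spectrum_carriers[gene] = sorted(tumor_patients[i] for i in idx)

    # exact carrier subsets for exclusives (paired + tumor-only separately)
    exclusive_carriers: dict[str, list[str]] = {}
    for av, frac in exclusives:
        kp = min(len(paired), _round_half_up(frac * len(paired)))
        kt = min(len(tumor_only), _round_half_up(frac * len(tumor_only)))
        chosen = []
        if kp:
            idx = rng_patients.choice(len(paired), size=kp, replace=False)
            chosen += [paired[i] for i in idx]
        if kt:
            idx = rng_patients.choice(len(tumor_only), size=kt, replace=False)
            chosen += [tumor_only[i] for i in idx]
        exclusive_carriers[av.rsid] = sorted(chosen)

    exclusive_keys = {av.key for av, _ in exclusives}

    truth_patients: dict[str, dict] = {}
    truth_origins: dict[str, dict[str, str]] = {}
    sample_records: dict[str, list[tuple[AnnotatedVariant, int]]] = {}
    manifest_rows = []

    def dosage_for(av: AnnotatedVariant, rng) -> int:
        return 2 if rng.random() < 0.3 else 1

    for pid in tumor_patients:
        is_paired = pid in paired
        n_i = _round_half_up(
            _trunc_normal(
                rng_patients,
                config.relevant_count_mean,
                config.relevant_count_sd,
                config.relevant_count_min,
                config.relevant_count_max,
            )
        )
        g_i = _trunc_normal(
            rng_patients, config.germline_fraction_mean, config.germline_fraction_sd, 0.0, 1.0
        )
        planted: list[AnnotatedVariant] = list(universal)
        planted += [spectrum[g] for g, carriers in spectrum_carriers.items() if pid in carriers]
        planted += [av for av, _ in exclusives if pid in exclusive_carriers[av.rsid]]
        n_fill = n_i - len(planted)
        if n_fill < 0:
            raise ConfigError(
                f"relevant_count for {pid} ({n_i}) below planted minimum ({len(planted)}); "
                "raise relevant_count_min or shrink the planted sets"
            )
        if n_fill > len(background):
            raise ConfigError(
                f"background_pool_size {len(background)} too small for {n_fill} fill variants"
            )
        idx = rng_patients.choice(len(background), size=n_fill, replace=False)
        planted += [background[i] for i in sorted(idx)]

        # planted exclusives are forced somatic, so the Bernoulli probability
        # for the remaining variants is conditioned upward to keep the
        # patient-level expected germline fraction at the drawn g_i
        n_excl_i = sum(1 for av in planted if av.key in exclusive_keys)
        if n_i > n_excl_i:
            g_adj = min(1.0, g_i * n_i / (n_i - n_excl_i))
        else:
            g_adj = 1.0

        origins: dict[str, str] = {}
        tumor_records: list[tuple[AnnotatedVariant, int]] = []
        normal_records: list[tuple[AnnotatedVariant, int]] = []
        for av in planted:
            d = dosage_for(av, rng_patients)
            tumor_records.append((av, d))
            if not is_paired:
                origins[str(av.key)] = "unclassified"
                continue
            if av.key in exclusive_keys:
                origins[str(av.key)] = "somatic"
                continue
            if rng_patients.random() < g_adj:
                origins[str(av.key)] = "germline"
                normal_records.append((av, d))
            else:
                origins[str(av.key)] = "somatic"

        # non-qualifying extras exercise the triage filter
        m_i = _round_half_up(config.nonrelevant_fraction * n_i)
        m_i = min(m_i, len(nonrelevant))
        if m_i:
            idx = rng_patients.choice(len(nonrelevant), size=m_i, replace=False)
            for i in sorted(idx):
                av = nonrelevant[i]
                d = dosage_for(av, rng_patients)
                tumor_records.append((av, d))
                if is_paired and rng_patients.random() < g_i:
                    normal_records.append((av, d))

        g = sum(1 for o in origins.values() if o == "germline")
        s = sum(1 for o in origins.values() if o == "somatic")
        truth_patients[pid] = {
            "group": "paired" if is_paired else "tumor_only",
            "n_relevant": n_i,
            "germline_fraction_drawn": round(g_i, 6),
            "n_germline": g,
            "n_somatic": s,
        }
        truth_origins[pid] = origins
        sample_records[f"{pid}T"] = tumor_records
        manifest_rows.append((f"{pid}T", pid, "tumor", f"{pid}_tumor.vcf"))
        if is_paired:
            sample_records[f"{pid}N"] = normal_records
            manifest_rows.append((f"{pid}N", pid, "normal", f"{pid}_normal.vcf"))

    for pid in normal_only:
        n_i = _round_half_up(
            _trunc_normal(
                rng_patients,
                config.relevant_count_mean,
                config.relevant_count_sd,
                config.relevant_count_min,
                config.relevant_count_max,
            )
        )
        records: list[tuple[AnnotatedVariant, int]] = [
            (av, dosage_for(av, rng_patients)) for av in universal
        ]
        n_fill = max(0, n_i - len(records))
        idx = rng_patients.choice(len(background), size=min(n_fill, len(background)),
                                  replace=False)
        records += [(background[i], dosage_for(background[i], rng_patients))
                    for i in sorted(idx)]
        truth_patients[pid] = {"group": "normal_only", "n_relevant": 0,
                               "germline_fraction_drawn": None,
                               "n_germline": 0, "n_somatic": 0}
        sample_records[f"{pid}N"] = records
        manifest_rows.append((f"{pid}N", pid, "normal", f"{pid}_normal.vcf"))

    # --- exclusivity guard ----------------------------------------------------
    # A non-planted variant that happens to be somatic in every carrier and
    # absent from every normal would be indistinguishable from a planted
    # exclusive.  Flip one carrier to germline (and add it to that patient's
    # normal VCF) so the planted exclusives are exactly the exclusive set.
    exclusive_labels = {str(av.key) for av, _ in exclusives}
    normal_keys_all = {
        str(av.key)
        for sid, recs in sample_records.items()
        if sid.endswith("N")
        for av, _ in recs
    }
    germline_anywhere = {
        k for o in truth_origins.values() for k, v in o.items() if v == "germline"
    }
    somatic_carriers: dict[str, list[str]] = {}
    for pid in paired:
        for k, v in truth_origins[pid].items():
            if v == "somatic":
                somatic_carriers.setdefault(k, []).append(pid)
    for k, carriers in sorted(somatic_carriers.items()):
        if k in exclusive_labels or k in germline_anywhere or k in normal_keys_all:
            continue
        pid = sorted(carriers)[0]
        truth_origins[pid][k] = "germline"
        truth_patients[pid]["n_germline"] += 1
        truth_patients[pid]["n_somatic"] -= 1
        for av, d in sample_records[f"{pid}T"]:
            if str(av.key) == k:
                sample_records[f"{pid}N"].append((av, d))
                break

    # --- write VCFs + manifest ------------------------------------------------
    for sample_id, pid, tissue, fname in manifest_rows:
        write_annotated_vcf(outdir / fname, sample_id, sample_records[sample_id],
                            contigs=CONTIGS)
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "patient_id", "tissue", "vcf_path"]
    )
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)

    # --- clinical table -------------------------------------------------------
    clinical_path = outdir / "clinical.tsv"
    _write_clinical_table(clinical_path, patients, rng_clinical)

    # --- reference catalogue (novelty genes withheld) -------------------------
    all_genes = sorted(
        {av.gene for av in universal + list(spectrum.values()) + background
         if av.gene is not None}
        | {av.gene for av, _ in exclusives}
    )
    catalogue_genes = [g for g in all_genes if g not in DEFAULT_NOVEL_GENES]
    catalogue_path = outdir / "catalogue_synthetic.txt"
    catalogue_path.write_text(
        "# synthetic reference catalogue (known genes)\n"
        + "".join(f"{g}\n" for g in catalogue_genes)
    )

    # --- PRS inputs -----------------------------------------------------------
    prs_truth = generate_prs_inputs(config, outdir, cases=tumor_patients + normal_only,
                                    rng=rng_prs)

    # --- truth file -----------------------------------------------------------
    gene_prev_truth = {
        gene: {
            "carriers": len(carriers),
            "denominator": len(tumor_patients),
            "prevalence": round(len(carriers) / len(tumor_patients), 6),
            "carrier_patients": carriers,
        }
        for gene, carriers in spectrum_carriers.items()
    }
    for gene in config.core_genes:
        gene_prev_truth[gene] = {
            "carriers": len(tumor_patients),
            "denominator": len(tumor_patients),
            "prevalence": 1.0,
            "carrier_patients": tumor_patients,
        }
    exclusive_truth = {}
    for av, frac in exclusives:
        carriers = exclusive_carriers[av.rsid]
        paired_carriers = [p for p in carriers if p in paired]
        exclusive_truth[av.rsid] = {
            "key": str(av.key),
            "target_fraction": frac,
            "paired_carriers": paired_carriers,
            "all_tumor_carriers": carriers,
            "paired_frequency": (
                round(len(paired_carriers) / len(paired), 6) if paired else None
            ),
        }
    truth = {
        "seed": config.seed,
        "n_paired": config.n_paired,
        "n_tumor_only": config.n_tumor_only,
        "n_normal_only": config.n_normal_only,
        "consequence_mix": config.consequence_mix,
        "patients": truth_patients,
        "origins": truth_origins,
        "exclusive_variants": exclusive_truth,
        "gene_prevalence": gene_prev_truth,
        "prs": prs_truth,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return CohortBundle(
        outdir=outdir,
        manifest_path=manifest_path,
        clinical_path=clinical_path,
        truth_path=truth_path,
        catalogue_path=catalogue_path,
        prs_base_path=outdir / "prs_base.tsv",
        prs_dosage_path=outdir / "prs_dosages.tsv",
        prs_labels_path=outdir / "prs_labels.tsv",
        truth=truth,
    )


def _write_clinical_table(path: Path, patients: list[str], rng) -> None:
    """Sample clinical covariates from the packaged reference cohort's
    empirical distributions (TNM-string pool with its Mx/Nx and data-entry
    quirks, age ~ Normal(54.8, 10.1), sex and site frequencies)."""
    ref = pd.read_csv(
        resources.files("osccohort.data") / "clinical_reference.tsv", sep="\t"
    )
    tnm_pool = ref["tnm"].tolist()
    site_pool = ref["site"].tolist()
    rows = []
    for pid in patients:
        tnm = tnm_pool[rng.integers(len(tnm_pool))]
        age = max(25, int(round(rng.normal(54.8, 10.1))))
        sex = "male" if rng.random() < 16 / 24 else "female"
        site = site_pool[rng.integers(len(site_pool))]
        history = "No relevant history" if rng.random() < 0.5 else "Prior therapy"
        rows.append((pid, tnm, age, sex, site, history))
    pd.DataFrame(
        rows, columns=["patient_id", "tnm", "age", "sex", "site", "history"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PRS inputs


def generate_prs_inputs(
    config: SimulationConfig,
    outdir: str | Path,
    cases: Sequence[str] | None = None,
    rng=None,
) -> dict:
    """Write the base summary-statistic file, the dosage matrix and the
    case/control labels; return the PRS truth block.

    Controls' effect-allele dosages are Binomial(2, p_j); cases use
    p_j + prs_case_shift * sign(beta_j), so the expected case score exceeds
    the controls' by 2 * shift * sum_j |beta_j|.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    if cases is None:
        pad = max(2, len(str(config.n_patients)))
        cases = [f"P{i + 1:0{pad}d}" for i in range(config.n_patients)]
    cases = list(cases)
    controls = [f"C{i + 1:03d}" for i in range(config.prs_n_controls)]
    if not cases or not controls:
        raise ConfigError("need at least one case and one control")

    m = config.prs_n_snps
    snps = [f"snp{i + 1:05d}" for i in range(m)]
    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(1, 50_000_000, size=m)
    bases = np.array(list("ACGT"))
    a1_idx = rng.integers(0, 4, size=m)
    shift_ = rng.integers(1, 4, size=m)
    a2_idx = (a1_idx + shift_) % 4
    beta = rng.normal(0.0, config.prs_beta_sd, size=m)
    pvals = rng.uniform(1e-8, 1.0, size=m)
    freq = rng.uniform(config.prs_freq_low, config.prs_freq_high, size=m)

    base = pd.DataFrame(
        {
            "SNP": snps,
            "CHR": chrom,
            "BP": pos,
            "A1": bases[a1_idx],
            "A2": bases[a2_idx],
            "BETA": np.round(beta, 6),
            "P": np.round(pvals, 8),
        }
    )
    base.to_csv(outdir / "prs_base.tsv", sep="\t", index=False)
    beta = base["BETA"].to_numpy()  # use the printed precision downstream

    case_freq = np.clip(freq + config.prs_case_shift * np.sign(beta), 0.0, 1.0)
    dosage_controls = rng.binomial(2, freq, size=(len(controls), m))
    dosage_cases = rng.binomial(2, case_freq, size=(len(cases), m))
    individuals = cases + controls
    dosages = pd.DataFrame(
        np.vstack([dosage_cases, dosage_controls]), index=individuals, columns=snps
    )
    dosages.index.name = "individual"
    dosages.to_csv(outdir / "prs_dosages.tsv", sep="\t")

    labels = pd.DataFrame(
        {"individual": individuals, "status": ["case"] * len(cases) + ["control"] * len(controls)}
    )
    labels.to_csv(outdir / "prs_labels.tsv", sep="\t", index=False)

    expected_case = float(2.0 * (case_freq * beta).sum())
    expected_control = float(2.0 * (freq * beta).sum())
    realized = dosages.to_numpy() @ beta  # per-individual planted genetic value
    liabilities = {
        ind: round(float(v), 6) for ind, v in zip(individuals, realized)
    }
    return {
        "n_snps": m,
        "cases": cases,
        "n_controls": len(controls),
        "case_shift": config.prs_case_shift,
        "expected_case_score": round(expected_case, 6),
        "expected_control_score": round(expected_control, 6),
        "expected_liability": liabilities,
    }
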