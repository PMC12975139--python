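"""End-to-end orchestration: manifest + clinical table + config in, a
directory of report tables out.

Stages run in analysis order (triage -> origin -> recurrence -> exclusivity
-> catalogue/NR annotation -> stratified statistics -> PRS); each stage is a
pure function of its declared inputs, so re-running the pipeline on the same
inputs reproduces every table byte-for-byte.  Any stage failure aborts with
the stage name and removes the partially written report files.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, origin, prs, recurrence, stratify, triage, variant_io

log = logging.getLogger(__name__)

GENE_THRESHOLDS = (0.8, 1.0)
VARIANT_THRESHOLDS = (0.8, 1.0)
NOVELTY_PREVALENCE = 0.9


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    manifest_path: Path
    clinical_path: Path
    output_dir: Path
    triage_config: triage.TriageConfig = field(default_factory=triage.TriageConfig)
    gene_threshold: float = 0.8
    variant_threshold: float = 0.8
    exclusivity_threshold: float = 0.2
    exclusivity_denominator: str = "paired"  # or "tumor"
    catalogue_path: Path | None = None
    nr_table_path: Path | None = None  # None -> packaged table
    prs_base_path: Path | None = None
    prs_dosage_path: Path | None = None
    prs_labels_path: Path | None = None
    age_cutoff: int = 45
    seed: int = 0

    def validate(self) -> None:
        for name in ("manifest_path", "clinical_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for t in (self.gene_threshold, self.variant_threshold, self.exclusivity_threshold):
            if not 0 < t <= 1:
                raise ValueError(f"thresholds must be in (0, 1], got {t}")
        if self.exclusivity_denominator not in ("paired", "tumor"):
            raise ValueError("exclusivity_denominator must be 'paired' or 'tumor'")


@dataclass
class PipelineReport:
    output_dir: Path
    per_patient_counts: dict[str, int]
    origin_summary: origin.OriginSummary | None
    exclusive: list[origin.ExclusiveVariant]
    tables: dict[str, Path]


def _write(df: pd.DataFrame, path: Path, tables: dict[str, Path], name: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    tables[name] = path


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        return _run(config, outdir, written)
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError("pipeline", str(exc)) from exc


def _cleanup(written: dict[str, Path]) -> None:
    for p in written.values():
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def _run(config: PipelineConfig, outdir: Path, tables: dict[str, Path]) -> PipelineReport:
    # ---- inputs -----------------------------------------------------------
    manifest = _load_manifest(config)
    clinical = _load_clinical(config)

    calls = _read_calls(manifest)

    # ---- triage -----------------------------------------------------------
    tri = _triage(calls, config)
    counts = tri.per_patient_tumor_counts
    _write(
        pd.DataFrame(
            [(p, n) for p, n in counts.items()], columns=["patient_id", "n_relevant"]
        ),
        outdir / "triage_counts.tsv", tables, "triage_counts",
    )

    # ---- origin -----------------------------------------------------------
    origin_calls = _origins(tri.relevant_calls)
    rows = [
        (oc.patient_id, oc.key.chrom, oc.key.pos, oc.key.ref, oc.key.alt, oc.origin)
        for oc in origin_calls
    ]
    _write(
        pd.DataFrame(rows, columns=["patient_id", "chrom", "pos", "ref", "alt", "origin"]),
        outdir / "origin_calls.tsv", tables, "origin_calls",
    )
    summary = None
    if any(oc.origin != "unclassified" for oc in origin_calls):
        summary = origin.cohort_origin_summary(origin_calls)
        _write(
            pd.DataFrame(
                {
                    "n_paired": [summary.n_paired],
                    "mean_germline_fraction": [summary.mean_germline_fraction],
                    "sd_germline_fraction": [summary.sd_germline_fraction],
                }
            ),
            outdir / "origin_summary.tsv", tables, "origin_summary",
        )

    # ---- recurrence -------------------------------------------------------
    matrix = _matrix(tri.relevant_calls)
    dist = recurrence.consequence_distribution(tri.relevant_calls)
    _write(dist.reset_index().rename(columns={"index": "consequence"}),
           outdir / "consequence_distribution.tsv", tables, "consequence_distribution")
    for thr in sorted({config.gene_threshold, 1.0}):
        recs = recurrence.gene_prevalence(matrix, thr)
        _write(_prev_frame(recs), outdir / f"gene_prevalence_{int(thr * 100)}.tsv",
               tables, f"gene_prevalence_{int(thr * 100)}")
    for thr in sorted({config.variant_threshold, 1.0}):
        recs = recurrence.variant_prevalence(matrix, thr)
        _write(_prev_frame(recs), outdir / f"variant_prevalence_{int(thr * 100)}.tsv",
               tables, f"variant_prevalence_{int(thr * 100)}")

    # ---- tumor-exclusive variants ----------------------------------------
    exclusive = _exclusive(tri.relevant_calls, origin_calls, matrix, config)
    rows = []
    for ev in exclusive:
        av = ev.variant
        rows.append(
            {
                "mutation": getattr(av, "rsid", None) or str(ev.key),
                "frequency_percent": round(ev.percent, 1),
                "n_patients": ev.n_patients,
                "denominator": ev.denominator,
                "chrom": ev.key.chrom,
                "pos": ev.key.pos,
                "variant_class": getattr(av, "variant_class", ""),
                "consequence": getattr(av, "consequence", ""),
                "gene": getattr(av, "gene", "") or "(intergenic)",
                "clnsig": getattr(av, "clnsig_raw", ""),
            }
        )
    _write(pd.DataFrame(rows, columns=["mutation", "frequency_percent", "n_patients",
                                       "denominator", "chrom", "pos", "variant_class",
                                       "consequence", "gene", "clnsig"]),
           outdir / "exclusive_variants.tsv", tables, "exclusive_variants")

    # ---- catalogue novelty + NR categories --------------------------------
    if config.catalogue_path is not None:
        known, novel = _novelty(matrix, config)
        _write(pd.DataFrame({"gene": sorted(known)}), outdir / "catalogue_known.tsv",
               tables, "catalogue_known")
        _write(pd.DataFrame({"gene": sorted(novel)}), outdir / "catalogue_novel.tsv",
               tables, "catalogue_novel")
    nr_counts = _nr(config)
    _write(
        pd.DataFrame([(k, v) for k, v in nr_counts.items()],
                     columns=["category", "count"]),
        outdir / "nr_categories.tsv", tables, "nr_categories",
    )

    # ---- stratified statistics -------------------------------------------
    strat = _stratified(clinical, counts, matrix, config)
    _write(strat["tests"], outdir / "stratified_tests.tsv", tables, "stratified_tests")
    if strat["dunn"] is not None:
        _write(strat["dunn"], outdir / "stratified_dunn.tsv", tables, "stratified_dunn")
    if strat["fisher"] is not None:
        _write(strat["fisher"].reset_index().rename(columns={"index": "gene"}),
               outdir / "stratified_gene_fisher.tsv", tables, "stratified_gene_fisher")

    # ---- PRS --------------------------------------------------------------
    if config.prs_base_path is not None:
        prs_tables = _prs(config)
        for name, df in prs_tables.items():
            _write(df, outdir / f"{name}.tsv", tables, name)

    _write_summary(outdir, tables, counts, summary, exclusive, matrix)
    return PipelineReport(outdir, counts, summary, exclusive, tables)


@_stage("inputs")
def _load_manifest(config: PipelineConfig) -> pd.DataFrame:
    manifest = variant_io.read_manifest(config.manifest_path)
    if manifest.empty:
        raise ValueError("manifest is empty")
    missing = [p for p in manifest["vcf_path"] if not Path(p).exists()]
    if missing:
        raise ValueError(f"manifest references missing VCF(s): {missing[:3]}")
    return manifest


@_stage("inputs")
def _load_clinical(config: PipelineConfig):
    return variant_io.read_clinical_table(config.clinical_path)


@_stage("read-vcfs")
def _read_calls(manifest: pd.DataFrame):
    return variant_io.read_cohort_calls(manifest)


@_stage("triage")
def _triage(calls, config: PipelineConfig):
    return triage.triage_cohort(calls, config.triage_config)


@_stage("origin")
def _origins(relevant_calls):
    return origin.classify_cohort_origins(relevant_calls)


@_stage("recurrence")
def _matrix(relevant_calls):
    return recurrence.build_matrix(relevant_calls)


@_stage("exclusive")
def _exclusive(relevant_calls, origin_calls, matrix, config: PipelineConfig):
    normal_keys = {c.key for c in relevant_calls if c.tissue == "normal"}
    denominator = matrix.n_patients if config.exclusivity_denominator == "tumor" else None
    return origin.find_exclusive_variants(
        origin_calls,
        config.exclusivity_threshold,
        all_normal_keys=normal_keys,
        denominator=denominator,
    )


@_stage("annotate")
def _novelty(matrix, config: PipelineConfig):
    catalogue = annotate.read_catalogue(config.catalogue_path)
    frequent = [r.unit for r in recurrence.gene_prevalence(matrix, NOVELTY_PREVALENCE)]
    if not frequent:
        return set(), set()
    return annotate.compare_to_catalogue(frequent, catalogue)


@_stage("annotate")
def _nr(config: PipelineConfig):
    anns = annotate.read_nr_table(config.nr_table_path)
    return annotate.summarize_nr_categories(anns)


@_stage("stratify")
def _stratified(clinical, counts, matrix, config: PipelineConfig):
    stratify.assign_stages(clinical)
    recs = {r.patient_id: r for r in clinical if r.patient_id in counts}
    test_rows = []
    dunn = None
    fisher = None

    def burdens_by(keyfn):
        groups: dict[str, list[float]] = {}
        for pid, rec in recs.items():
            label = keyfn(rec)
            if label is not None:
                groups.setdefault(label, []).append(float(counts[pid]))
        return {k: v for k, v in sorted(groups.items())}

    groupings = {
        "stage": lambda r: r.stage,
        "nodal": lambda r: None if r.pN is None else ("N0" if r.pN in ("0", "x") else "N+"),
        "sex": lambda r: r.sex,
        "age": lambda r: f"<{config.age_cutoff}" if r.age < config.age_cutoff
        else f">={config.age_cutoff}",
    }
    for name, keyfn in groupings.items():
        groups = burdens_by(keyfn)
        if len(groups) < 2:
            log.info("grouping %s has <2 groups; skipped", name)
            continue
        res = stratify.burden_group_test(groups, grouping=name)
        test_rows.append(
            {
                "grouping": name,
                "groups": ";".join(f"{k}(n={len(v)})" for k, v in groups.items()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
        if name == "stage" and len(groups) >= 3:
            dunn = stratify.dunn_posthoc(groups)

    stage_of = {pid: rec.stage for pid, rec in recs.items() if rec.stage}
    advanced = {pid: stage in ("III", "IV") for pid, stage in stage_of.items()}
    if len(set(advanced.values())) == 2:
        fisher = stratify.per_gene_association(matrix, advanced)
    return {"tests": pd.DataFrame(test_rows), "dunn": dunn, "fisher": fisher}


@_stage("prs")
def _prs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    model = prs.read_base_summary(config.prs_base_path)
    dosages = pd.read_csv(config.prs_dosage_path, sep="\t", index_col=0)
    scores = prs.score_individuals(model, dosages)
    case_status = None
    if config.prs_labels_path is not None:
        labels = pd.read_csv(config.prs_labels_path, sep="\t", index_col=0)
        case_status = labels["status"].eq("case")
    result = prs.assign_quartiles(scores, case_status)
    out = {
        "prs_scores": pd.DataFrame(
            {"individual": result.quartile.index,
             "score": result.scores.values,
             "quartile": result.quartile.values}
        )
    }
    qt = pd.DataFrame(
        {"quartile": list(prs.QUARTILES),
         "size": [result.sizes()[q] for q in prs.QUARTILES]}
    )
    if case_status is not None:
        cc = result.case_counts()
        qt["cases"] = [cc[q] for q in prs.QUARTILES]
        chi_rows = []
        for q in ("Q2", "Q3", "Q4"):
            stat, p = prs.quartile_risk_test(result, q)
            chi_rows.append({"comparison": f"Q1 vs {q}", "chi_square": stat, "p_value": p})
        out["prs_chi_square"] = pd.DataFrame(chi_rows)
    out["prs_quartiles"] = qt
    return out


def _prev_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"unit": r.unit, "carriers": r.n_carriers, "denominator": r.denominator,
             "percent": round(r.percent, 1)}
            for r in records
        ],
        columns=["unit", "carriers", "denominator", "percent"],
    )


def _write_summary(outdir, tables, counts, summary, exclusive, matrix) -> None:
    lines = ["cohort analysis summary", "=" * 24, ""]
    lines.append(f"tumor patients analyzed: {matrix.n_patients}")
    if counts:
        vals = list(counts.values())
        lines.append(
            f"relevant variants per patient: mean {sum(vals) / len(vals):.1f} "
            f"(range {min(vals)}-{max(vals)})"
        )
    if summary is not None:
        lines.append(
            f"germline fraction over {summary.n_paired} paired patients: "
            f"{100 * summary.mean_germline_fraction:.1f}% "
            f"+/- {100 * summary.sd_germline_fraction:.1f}%"
        )
    lines.append(f"tumor-exclusive variants above threshold: {len(exclusive)}")
    lines.append("")
    lines.append("tables written:")
    for name, path in sorted(tables.items()):
        lines.append(f"  {name}: {path.name}")
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    tables["summary"] = path
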