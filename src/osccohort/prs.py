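"""Additive polygenic risk scoring and quartile risk stratification.

The score of individual *i* is the weighted allele count

    PRS_i = sum_j beta_j * d_ij

over the SNPs shared between a base GWAS summary-statistics file (columns
``SNP, CHR, BP, A1, A2, BETA|OR, P``) and a target dosage matrix
(individuals x SNPs, effect-allele dosage in [0, 2]).  Odds ratios are
converted to log-odds betas; missing dosages are imputed with twice the
cohort effect-allele frequency; no LD clumping is applied (the p-value
inclusion threshold defaults to 1.0 and is configurable).

Scored individuals are split into quartiles Q1 (lowest) .. Q4 (highest) of
as-equal-as-possible size, Q1 serving as the risk reference; per-quartile
case enrichment against Q1 uses the Pearson chi-square on the 2x2
quartile x case/control table without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def read_base_summary(path: str | Path, p_threshold: float = 1.0) -> pd.DataFrame:
    """Read base GWAS summary statistics into a per-SNP weight table.

    Requires columns SNP, A1, A2, P and either BETA or OR (OR is converted
    to beta by natural log).  SNPs with p > ``p_threshold`` are excluded;
    duplicate identifiers and non-positive ORs are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", encoding="utf-8-sig")
    df.columns = [c.upper() for c in df.columns]
    for col in ("SNP", "A1", "A2", "P"):
        if col not in df.columns:
            raise ValueError(f"base file {path}: missing mandatory column {col}")
    if "BETA" in df.columns:
        beta = df["BETA"].astype(float)
    elif "OR" in df.columns:
        orr = df["OR"].astype(float)
        if (orr <= 0).any():
            raise ValueError(f"base file {path}: non-positive OR")
        beta = np.log(orr)
    else:
        raise ValueError(f"base file {path}: need a BETA or OR column")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()[:5]
        raise ValueError(f"base file {path}: duplicate SNP identifiers {dups}")
    model = pd.DataFrame(
        {
            "chrom": df.get("CHR", pd.Series([""] * len(df))).astype(str).to_numpy(),
            "pos": df.get("BP", pd.Series([0] * len(df))).astype(int).to_numpy(),
            "a1": df["A1"].astype(str).str.upper().to_numpy(),
            "a2": df["A2"].astype(str).str.upper().to_numpy(),
            "beta": np.asarray(beta, dtype=float),
            "p": df["P"].astype(float).to_numpy(),
        },
        index=pd.Index(df["SNP"].astype(str), name="SNP"),
    )
    if ((model["p"] <= 0) | (model["p"] > 1)).any():
        raise ValueError(f"base file {path}: p-values must be in (0, 1]")
    if (model["a1"] == model["a2"]).any():
        raise ValueError(f"base file {path}: A1 == A2 for some SNPs")
    return model[model["p"] <= p_threshold]


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    model: pd.DataFrame, target_alleles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Align target allele coding with the base model.

    ``target_alleles`` has columns a1/a2 indexed by SNP.  Matching pairs are
    kept; swapped pairs mark the dosage for flipping (d -> 2 - d); strand
    (complement) equivalents are folded first.  Palindromic SNPs (A/T, C/G)
    are excluded with a logged count, as are irreconcilable pairs.

    Returns the restricted model and a boolean flip mask indexed like it.
    """
    shared = model.index.intersection(target_alleles.index)
    keep, flip = [], []
    n_palindromic = n_mismatch = 0
    for snp in shared:
        b1, b2 = model.at[snp, "a1"], model.at[snp, "a2"]
        t1, t2 = str(target_alleles.at[snp, "a1"]).upper(), str(
            target_alleles.at[snp, "a2"]
        ).upper()
        if is_palindromic(b1, b2) or is_palindromic(t1, t2):
            n_palindromic += 1
            continue
        if {t1, t2} != {b1, b2}:  # try the other strand
            t1, t2 = COMPLEMENT.get(t1, "?"), COMPLEMENT.get(t2, "?")
        if (t1, t2) == (b1, b2):
            keep.append(snp), flip.append(False)
        elif (t1, t2) == (b2, b1):
            keep.append(snp), flip.append(True)
        else:
            n_mismatch += 1
    if n_palindromic:
        log.info("excluded %d palindromic SNP(s)", n_palindromic)
    if n_mismatch:
        log.info("excluded %d allele-mismatched SNP(s)", n_mismatch)
    return model.loc[keep], pd.Series(flip, index=keep, dtype=bool)


def score_individuals(
    model: pd.DataFrame,
    dosages: pd.DataFrame,
    *,
    target_alleles: pd.DataFrame | None = None,
    average: bool = False,
) -> pd.Series:
    """Additive PRS per individual (rows of ``dosages``).

    Dosage entries are effect-allele counts in [0, 2]; NaN entries are
    imputed with twice the cohort effect-allele frequency at that SNP.
    Individuals overlapping the model at zero SNPs get a NaN score.  With
    ``average=True`` the sum is divided by 2 x (number of scored SNPs).
    """
    if target_alleles is not None:
        model, flip = harmonize_alleles(model, target_alleles)
        dosages = dosages.copy()
        for snp in model.index[flip.reindex(model.index, fill_value=False)]:
            if snp in dosages.columns:
                dosages[snp] = 2.0 - dosages[snp]
    shared = model.index.intersection(dosages.columns)
    if len(shared) == 0:
        raise ValueError("no SNP overlap between model and dosage matrix")
    d = dosages[shared].astype(float)
    if ((d < 0) | (d > 2)).any().any():
        raise ValueError("dosages must lie in [0, 2]")
    freq2 = d.mean(axis=0)  # 2 x effect-allele frequency
    n_observed = d.notna().sum(axis=1)
    d = d.fillna(freq2)
    scores = d.to_numpy() @ model.loc[shared, "beta"].to_numpy()
    out = pd.Series(scores, index=dosages.index, name="prs")
    out[n_observed == 0] = np.nan
    if (n_observed == 0).any():
        log.warning("%d individual(s) overlap the model at zero SNPs",
                    int((n_observed == 0).sum()))
    if average:
        out = out / (2.0 * len(shared))
    return out


@dataclass
class QuartileResult:
    scores: pd.Series  # ascending-sorted scores actually used
    quartile: pd.Series  # individual -> Q1..Q4
    case_status: pd.Series | None = None  # individual -> bool

    def sizes(self) -> dict[str, int]:
        return {q: int((self.quartile == q).sum()) for q in QUARTILES}

    def case_counts(self) -> dict[str, int]:
        if self.case_status is None:
            raise ValueError("no case/control labels attached")
        cc = self.case_status.reindex(self.quartile.index).astype(bool)
        return {q: int(cc[self.quartile == q].sum()) for q in QUARTILES}


def assign_quartiles(
    scores: pd.Series,
    case_status: Mapping[str, bool] | pd.Series | None = None,
    *,
    remainder: str = "low",
) -> QuartileResult:
    """Split scored individuals into four contiguous score-ordered blocks.

    Sizes differ by at most one; with ``remainder="low"`` (default) the
    extra individuals go to the lowest quartiles, with ``"high"`` to the
    highest.  Ties are broken by stable individual-id order; Q1 holds the
    lowest scores and is the risk reference.
    """
    scores = scores.dropna()
    if len(scores) < 4:
        raise ValueError("need at least 4 scored individuals")
    if remainder not in ("low", "high"):
        raise ValueError("remainder must be 'low' or 'high'")
    order = scores.rename("score").reset_index()
    id_col = order.columns[0]
    order = order.sort_values(["score", id_col], kind="stable")
    ordered_ids = order[id_col].tolist()
    n, base, rem = len(ordered_ids), len(ordered_ids) // 4, len(ordered_ids) % 4
    sizes = [base + (1 if (i < rem if remainder == "low" else i >= 4 - rem) else 0)
             for i in range(4)]
    labels = []
    for q, size in zip(QUARTILES, sizes):
        labels.extend([q] * size)
    quartile = pd.Series(labels, index=ordered_ids, name="quartile")
    cc = None
    if case_status is not None:
        cc = pd.Series(case_status).reindex(quartile.index).fillna(False).astype(bool)
    return QuartileResult(scores.loc[ordered_ids], quartile, cc)


def chi_square_2x2(n1: int, cases1: int, n2: int, cases2: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for case counts
    in two groups.  Returns (statistic, p)."""
    obs = np.array(
        [[cases1, n1 - cases1], [cases2, n2 - cases2]], dtype=float
    )
    if obs.min() < 0:
        raise ValueError("negative cell count")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    if (expected == 0).all():
        raise ValueError("all expected cell counts are zero")
    mask = expected > 0
    stat = float((((obs - expected) ** 2)[mask] / expected[mask]).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def quartile_risk_test(
    result: QuartileResult, comparison: str, reference: str = "Q1"
) -> tuple[float, float]:
    """Chi-square case-enrichment test of one quartile against the
    reference quartile (Q1 by default)."""
    if comparison not in QUARTILES or reference not in QUARTILES:
        raise ValueError("quartile labels must be Q1..Q4")
    sizes, cases = result.sizes(), result.case_counts()
    if sizes[comparison] == 0 or sizes[reference] == 0:
        raise ValueError("both quartiles must be nonempty")
    return chi_square_2x2(
        sizes[reference], cases[reference], sizes[comparison], cases[comparison]
    )
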