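"""TNM stage simplification and stratified burden / association statistics.

Staging collapses pathological TNM tokens to stages I-IV with a fixed rule
order (metastasis tokens are recorded but ignored for staging; ``Nx`` is
treated as ``N0`` with an audit warning):

1. ``T4*`` or ``N2*/N3*``  -> IV
2. ``N1`` or ``T3 N0``     -> III
3. ``T2 N0``               -> II
4. ``T1 N0``               -> I

Burden comparisons use the two-sided Wilcoxon rank-sum test for two groups
(exact by enumeration for small pooled sizes, normal approximation with tie
correction otherwise) and the tie-corrected Kruskal-Wallis test for more,
with Dunn's post-hoc z-tests (Bonferroni- or Holm-adjusted, capped at 1).
Per-gene carrier association across a binary grouping uses Fisher's exact
test (two-sided by the point-probability convention) with Benjamini-Hochberg
correction across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .recurrence import CohortMatrix, INTERGENIC

log = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")

#: Pooled sample size up to which the rank-sum null is enumerated exactly.
EXACT_RANKSUM_LIMIT = 20


@dataclass(frozen=True)
class StageAssignment:
    patient_id: str
    stage: str
    rule: str


def simplify_stage(pT: str, pN: str, pM: str | None = None) -> tuple[str, str]:
    """Collapse (pT, pN[, pM]) to a stage I-IV; returns (stage, rule fired)."""
    t, n = pT.lower(), pN.lower()
    if t not in {"1", "2", "3", "4", "4a"}:
        raise ValueError(f"invalid pT token {pT!r}")
    if n not in {"0", "1", "2", "2a", "2b", "3", "3b", "x"}:
        raise ValueError(f"invalid pN token {pN!r}")
    if n == "x":
        log.warning("Nx treated as N0 for staging")
        n = "0"
    if t.startswith("4") or n[0] in ("2", "3"):
        return "IV", "T4-or-N2+"
    if n == "1" or (t == "3" and n == "0"):
        return "III", "N1-or-T3N0"
    if t == "2" and n == "0":
        return "II", "T2N0"
    if t == "1" and n == "0":
        return "I", "T1N0"
    raise ValueError(f"no staging rule for pT={pT!r}, pN={pN!r}")


def assign_stages(records) -> list[StageAssignment]:
    """Stage every clinical record with a parsed TNM."""
    out = []
    for rec in records:
        if rec.pT is None or rec.pN is None:
            log.warning("patient %s: unparsed TNM, no stage assigned", rec.patient_id)
            continue
        stage, rule = simplify_stage(rec.pT, rec.pN, rec.pM)
        rec.stage = stage
        out.append(StageAssignment(rec.patient_id, stage, rule))
    return out


# ---------------------------------------------------------------------------
# Rank-based burden tests


@dataclass
class BurdenTestResult:
    grouping: str
    group_sizes: dict[str, int]
    statistic: float
    p_value: float
    method: str
    posthoc: pd.DataFrame | None = None


def _exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all allocations of the
    pooled (tie-averaged) ranks to the first group.

    Two-sided p doubles the smaller tail probability, capped at 1.
    Returns (rank sum of x, p).
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    total = comb(n, n1)
    le = ge = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(w_obs), p


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum; exact for pooled n <= 20, else normal
    approximation with tie correction.  Returns (statistic, p, method)."""
    x, y = list(map(float, x)), list(map(float, y))
    if min(len(x), len(y)) < 1:
        raise ValueError("each group needs at least one observation")
    pooled = x + y
    if len(set(pooled)) == 1:  # all observations identical: no evidence
        return float(stats.rankdata(pooled)[: len(x)].sum()), 1.0, "exact"
    if len(pooled) <= EXACT_RANKSUM_LIMIT:
        w, p = _exact_ranksum_p(x, y)
        return w, p, "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False)
    return float(res.statistic), float(res.pvalue), "normal-approx"


def burden_group_test(
    burdens: Mapping[str, Sequence[float]], grouping: str = ""
) -> BurdenTestResult:
    """Compare per-patient burden across groups.

    Two groups: two-sided rank-sum.  More: tie-corrected Kruskal-Wallis
    (with Dunn post-hoc left to :func:`dunn_posthoc`).
    """
    groups = {k: list(v) for k, v in burdens.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 1:
            raise ValueError(f"group {name!r} is empty")
    sizes = {k: len(v) for k, v in groups.items()}
    if len(groups) == 2:
        (xa, ya) = groups.values()
        stat, p, method = rank_sum_test(xa, ya)
        return BurdenTestResult(grouping, sizes, stat, p, f"wilcoxon-ranksum-{method}")
    vals = list(groups.values())
    if len({v for g in vals for v in g}) == 1:
        return BurdenTestResult(grouping, sizes, 0.0, 1.0, "kruskal-wallis")
    stat, p = stats.kruskal(*vals)
    return BurdenTestResult(grouping, sizes, float(stat), float(p), "kruskal-wallis")


def dunn_posthoc(
    burdens: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks after Kruskal-Wallis.

    Tie-corrected pooled variance; adjusted p capped at 1.  Returns a frame
    with columns group1, group2, z, p_raw, p_adjusted.
    """
    groups = {k: np.asarray(list(v), float) for k, v in burdens.items()}
    if len(groups) < 3:
        raise ValueError("Dunn post-hoc needs at least three groups")
    if adjust not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for k in names:
        m = len(groups[k])
        mean_rank[k] = float(ranks[i : i + m].mean())
        i += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        denom = base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
        if denom <= 0:  # every pooled value tied
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / sqrt(denom)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * len(df))
    else:
        df["p_adjusted"] = multipletests(df["p_raw"], method="holm")[1]
    return df


# ---------------------------------------------------------------------------
# Per-gene carrier association


def per_gene_association(
    matrix: CohortMatrix,
    grouping: Mapping[str, bool],
    *,
    include_intergenic: bool = False,
) -> pd.DataFrame:
    """Fisher's exact test per gene for carrier status across a binary
    grouping (e.g. advanced vs early stage), BH-corrected across genes.

    Returns a frame indexed by gene with the 2x2 table cells
    (carrier_a, noncarrier_a, carrier_b, noncarrier_b), p, and q.
    Genes carried by all or by no patients have p = 1 by construction
    (degenerate margin).
    """
    values = set(grouping.values())
    if values - {True, False} or len(values) < 2:
        raise ValueError("grouping must partition patients into two nonempty sets")
    patients = [p for p in matrix.presence.index if p in grouping]
    if not patients:
        raise ValueError("grouping shares no patients with the matrix")
    in_a = np.array([grouping[p] for p in patients])
    carriers = (
        matrix.presence.loc[patients].T.groupby(matrix.gene_of).any().T
    )
    if not include_intergenic and INTERGENIC in carriers.columns:
        carriers = carriers.drop(columns=[INTERGENIC])

    rows = {}
    for gene in carriers.columns:
        carrier = carriers[gene].to_numpy()
        a, b = int((carrier & in_a).sum()), int((carrier & ~in_a).sum())
        c, d = int((~carrier & in_a).sum()), int((~carrier & ~in_a).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows[gene] = {
            "carrier_a": a,
            "carrier_b": b,
            "noncarrier_a": c,
            "noncarrier_b": d,
            "p": float(p),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
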