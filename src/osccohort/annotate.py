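"""Reference-catalogue comparison and nuclear-hormone-receptor summaries.

Catalogues are plain gene lists (one symbol per line, ``#`` comments), e.g.
an oral-cancer variant catalogue or a TCGA-HNSCC driver list.  Novelty is a
simple case-insensitive membership partition.

The nuclear-receptor table flags each gene's curated association with the
vitamin D receptor (VDR), estrogen receptor (ER) and androgen receptor (AR);
genes are summarized into the eight disjoint flag categories plus two
derived totals.  An ``-``/unknown AR flag is treated as "no" so the derived
category is a pure function of the three flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Disjoint flag categories, in report order.
NR_CATEGORIES = (
    "all_three",
    "vdr_er_only",
    "ar_er_only",
    "ar_vdr_only",
    "vdr_only",
    "er_only",
    "ar_only",
    "none",
)


@dataclass(frozen=True)
class CatalogueRef:
    name: str
    genes: frozenset[str]  # uppercased symbols

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"catalogue {self.name!r} is empty")


def read_catalogue(path: str | Path, name: str | None = None) -> CatalogueRef:
    genes = set()
    for line in Path(path).read_text(encoding="utf-8-sig").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line.upper())
    return CatalogueRef(name or Path(path).stem, frozenset(genes))


def compare_to_catalogue(
    genes: Iterable[str], catalogue: CatalogueRef
) -> tuple[set[str], set[str]]:
    """Partition query genes into (known, novel) by case-insensitive
    membership.  The partition covers the input and is disjoint."""
    query = {g for g in genes}
    if not query:
        raise ValueError("empty query gene set")
    known = {g for g in query if g.upper() in catalogue.genes}
    return known, query - known


# ---------------------------------------------------------------------------
# Nuclear-receptor categories


@dataclass(frozen=True)
class NRAnnotation:
    gene: str
    vdr: bool
    er: bool
    ar: bool  # unknown folded to False
    role: str = ""

    @property
    def category(self) -> str:
        v, e, a = self.vdr, self.er, self.ar
        if v and e and a:
            return "all_three"
        if v and e:
            return "vdr_er_only"
        if a and e:
            return "ar_er_only"
        if a and v:
            return "ar_vdr_only"
        if v:
            return "vdr_only"
        if e:
            return "er_only"
        if a:
            return "ar_only"
        return "none"


def _flag(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("yes", "y", "true", "1"):
        return True
    if v in ("no", "n", "false", "0", "-", "", "nan", "unknown"):
        return False
    raise ValueError(f"unrecognized receptor flag {value!r}")


def read_nr_table(path: str | Path | None = None) -> list[NRAnnotation]:
    """Read a receptor-flag TSV (gene, vdr, er, ar[, role]).

    Without a path, the packaged table of the 21 genes mutated in every
    patient of the reference cohort is loaded.
    """
    if path is None:
        with resources.as_file(
            resources.files("osccohort.data") / "nr_flags.tsv"
        ) as p:
            return read_nr_table(p)
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8-sig").fillna("")
    out = [
        NRAnnotation(
            gene=row.gene,
            vdr=_flag(row.vdr),
            er=_flag(row.er),
            ar=_flag(row.ar),
            role=getattr(row, "role", "") or "",
        )
        for row in df.itertuples(index=False)
    ]
    return out


def summarize_nr_categories(annotations: Iterable[NRAnnotation]) -> dict[str, int]:
    """Counts per disjoint category plus derived totals.

    ``vdr_er_with_or_without_ar`` = all_three + vdr_er_only;
    ``any_nr`` = every gene with at least one receptor flag set.
    The disjoint categories plus ``none`` always sum to ``n_genes``.
    """
    anns = list(annotations)
    seen: set[str] = set()
    for a in anns:
        if a.gene in seen:
            raise ValueError(f"duplicate gene {a.gene!r} in receptor table")
        seen.add(a.gene)
    counts = {cat: 0 for cat in NR_CATEGORIES}
    for a in anns:
        counts[a.category] += 1
    counts["vdr_er_with_or_without_ar"] = counts["all_three"] + counts["vdr_er_only"]
    counts["any_nr"] = len(anns) - counts["none"]
    counts["n_genes"] = len(anns)
    return counts
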