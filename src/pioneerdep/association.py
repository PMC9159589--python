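"""Element-to-gene association and 2x2 enrichment tests.

Gene-level association follows the single-nearest-gene-within-100 kb rule:
a gene is "near" a category if at least one element of that category has it
as nearest gene (multiplicity ignored). Category↔DEG-set association is a
Fisher's exact test on the 2x2 table over a gene universe; enrichment is
the upper hypergeometric tail, the same kernel the ZOOPS motif enrichment
uses. By default the universe is the set of genes present in the DEG table
(genes never measured cannot be "unchanged") and p-values are reported raw;
a BH option is available for the association grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pioneerdep.diffsignal import bh_adjust


@dataclass
class ContingencyResult:
    """A 2x2 table with its odds ratio and Fisher/hypergeometric p-value.

    a = in both margins (e.g. near a category element AND in the gene set),
    b = first margin only, c = second margin only, d = neither.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    pvalue: float
    direction: str
    category: str = ""
    gene_set: str = ""

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_test(
    a: int, b: int, c: int, d: int, direction: str = "enrichment"
) -> ContingencyResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    enrichment: upper tail P(X >= a), X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b);
    depletion: lower tail P(X <= a); two_sided: standard Fisher (sum of all
    tables at most as probable as the observed one). The odds ratio is the
    sample (a*d)/(b*c), +inf when b*c = 0 with a*d > 0, nan when both are 0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if direction not in ("enrichment", "depletion", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    n_total = a + b + c + d
    if n_total == 0:
        warnings.warn("empty 2x2 table; p-value defined as 1", stacklevel=2)
        return ContingencyResult(a, b, c, d, float("nan"), 1.0, direction)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    if direction == "enrichment":
        p = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    elif direction == "depletion":
        p = float(stats.hypergeom.cdf(a, n_total, a + c, a + b))
    else:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return ContingencyResult(a, b, c, d, odds, min(p, 1.0), direction)


def genes_near(
    classifications: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    categories: Iterable[str],
    category_col: str = "category",
    id_col: str | None = None,
) -> set[str]:
    """Union of nearest genes over the elements of the chosen categories."""
    categories = list(categories)
    known = set(classifications[category_col])
    unknown = set(categories) - known
    if unknown:
        raise ValueError(f"unknown category name(s): {sorted(unknown)}")
    if id_col is None:
        id_col = "element_id" if "element_id" in classifications.columns else "peak_id"
    ids = set(
        classifications.loc[
            classifications[category_col].isin(categories), id_col
        ]
    )
    near = tss_annotation[
        tss_annotation["element_id"].isin(ids)
        & tss_annotation["nearest_gene"].notna()
    ]
    return set(near["nearest_gene"])


def associate(
    classifications: pd.DataFrame,
    deg: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    universe: str = "tested_genes",
    categories: Sequence[str] | None = None,
    direction: str = "enrichment",
    adjust: bool = False,
    category_col: str = "category",
) -> pd.DataFrame:
    """Category x DEG-direction Fisher association grid (the summary-table layout).

    For each category and each DEG set — activated_genes (down in knockout)
    and inhibited_genes (up in knockout) — builds the gene-level 2x2 table
    over the universe and reports the enrichment test. ``universe`` is
    "tested_genes" (all genes in the DEG table, the default) or "all_genes"
    (additionally every gene appearing as a nearest gene in the annotation).
    """
    if universe not in ("tested_genes", "all_genes"):
        raise ValueError(f"unknown universe {universe!r}")
    uni = set(deg["gene_id"])
    if universe == "all_genes":
        uni |= set(tss_annotation["nearest_gene"].dropna())
    if not uni:
        raise ValueError("empty gene universe")
    deg_sets = {
        "activated_genes": set(deg.loc[deg["status"] == "down", "gene_id"]) & uni,
        "inhibited_genes": set(deg.loc[deg["status"] == "up", "gene_id"]) & uni,
    }
    if categories is None:
        categories = sorted(set(classifications[category_col]))
    id_col = "element_id" if "element_id" in classifications.columns else "peak_id"
    rows = []
    for cat in categories:
        near = genes_near(
            classifications, tss_annotation, [cat], category_col=category_col
        ) & uni
        n_elements = int((classifications[category_col] == cat).sum())
        for set_name, gset in deg_sets.items():
            a = len(near & gset)
            b = len(near - gset)
            c = len(gset - near)
            d = len(uni) - a - b - c
            res = fisher_test(a, b, c, d, direction=direction)
            rows.append(
                {
                    "category": cat,
                    "gene_set": set_name,
                    "n_elements": n_elements,
                    "n_genes": len(near),
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": res.odds_ratio,
                    "pvalue": res.pvalue,
                }
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def set_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    direction: str = "enrichment",
) -> ContingencyResult:
    """Fisher test for the overlap of two gene sets within a universe."""
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("both sets must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    return fisher_test(a, b, c, d, direction=direction)
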