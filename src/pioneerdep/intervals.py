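"""Interval algebra: overlap calls and TSS-distance / nearest-gene annotation.

Overlap is unstranded and requires the same chromosome; two half-open
intervals overlap by ``min(end) - max(start)`` bases. TSS distance is the
unstranded distance from an element's reference point (summit when present,
else midpoint) to the nearest annotated TSS; elements within
``proximal_radius`` are promoter-proximal, those within ``domain_radius``
are distal with the nearest gene assigned (single-nearest-gene-within-domain
rule), and anything farther is an orphan with no gene.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from pioneerdep.genomic_io import GenomicInterval

PROXIMAL_RADIUS = 3_000
DOMAIN_RADIUS = 100_000


class OverlapResult(NamedTuple):
    flags: dict[str, bool]
    partners: dict[str, list[str]]


def _trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return trees


def overlaps(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> OverlapResult:
    """Mark each element of ``a`` that shares >= ``min_bp`` bases with ``b``.

    Returns per-element boolean flags and the (sorted) names of overlapping
    partners in ``b``. The result is independent of input order.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    trees = _trees(b)
    flags: dict[str, bool] = {}
    partners: dict[str, list[str]] = {}
    for iv in a:
        hits = []
        tree = trees.get(iv.chrom)
        if tree is not None:
            for h in tree.overlap(iv.start, iv.end):
                if min(iv.end, h.end) - max(iv.start, h.begin) >= min_bp:
                    hits.append(h.data)
        hits.sort()
        flags[iv.name] = bool(hits)
        partners[iv.name] = hits
    return OverlapResult(flags, partners)


def annotate_tss(
    elements: Sequence[GenomicInterval],
    genes: pd.DataFrame,
    proximal_radius: int = PROXIMAL_RADIUS,
    domain_radius: int = DOMAIN_RADIUS,
) -> pd.DataFrame:
    """Annotate each element with its nearest TSS within ``domain_radius``.

    ``genes`` has columns gene_id, chrom, tss. Returns a DataFrame with
    element_id, nearest_gene, tss_distance, locale. Equidistant TSSs are
    broken toward the lexicographically smallest gene_id so outputs are
    reproducible.
    """
    if not (0 < proximal_radius < domain_radius):
        raise ValueError("need 0 < proximal_radius < domain_radius")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in genes.groupby("chrom"):
        # pre-sort by (tss, gene_id) so ties resolve lexicographically
        grp = grp.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[str(chrom)] = (
            grp["tss"].to_numpy(dtype=np.int64),
            grp["gene_id"].to_numpy(dtype=object),
        )
    rows = []
    for iv in elements:
        point = iv.point
        nearest_gene: str | None = None
        distance: int | None = None
        if iv.chrom in by_chrom:
            tss, gids = by_chrom[iv.chrom]
            d = np.abs(tss - point)
            best = int(d.min())
            if best <= domain_radius:
                distance = best
                cand = gids[d == best]
                nearest_gene = str(min(cand))
        if distance is None:
            locale = "orphan"
        elif distance <= proximal_radius:
            locale = "promoter_proximal"
        else:
            locale = "distal"
        rows.append(
            {
                "element_id": iv.name,
                "nearest_gene": nearest_gene,
                "tss_distance": distance,
                "locale": locale,
            }
        )
    return pd.DataFrame(
        rows, columns=["element_id", "nearest_gene", "tss_distance", "locale"]
    )
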