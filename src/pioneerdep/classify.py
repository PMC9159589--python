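"""Element and dependency taxonomies.

``classify_elements`` assigns each TF-bound element one of the regulatory
categories defined by the joint knockout response of H3K27Ac (activity) and
ATAC (accessibility) signal:

* pioneered_activated — open & active in WT, loses both H3K27Ac and ATAC in
  the knockout (the TF maintains both the activity and the accessibility of
  the element: pioneer behaviour).
* nonpioneered_activated — open & active in WT, loses H3K27Ac only (the TF
  activates the element but accessibility is TF-independent).
* pioneered_inhibited — gains both H3K27Ac and ATAC in the knockout (the TF
  keeps the element closed and inactive).
* nonpioneered_inhibited_candidate — gains H3K27Ac only; retained but
  flagged, since elements in this cell frequently fail follow-up evidence of
  genuine inhibition.
* quiescent — no change in either signal.
* unclassified_atac_discordant — any remaining combination (e.g. H3K27Ac
  down with ATAC up, or an activated-like response at an element that is not
  open/active in WT); never forced into a category.

``classify_dependency`` assigns each second-TF peak its dependence on the
primary TF: activated (binding lost in primary-TF KO, subdivided by the ATAC
response), inhibited (binding gained), independent, or mutually dependent
when the primary TF's own binding also drops in the second TF's knockout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from pioneerdep.genomic_io import GenomicInterval
from pioneerdep.intervals import overlaps

ELEMENT_CATEGORIES = (
    "pioneered_activated",
    "nonpioneered_activated",
    "pioneered_inhibited",
    "nonpioneered_inhibited_candidate",
    "quiescent",
    "unclassified_atac_discordant",
)

DEPENDENCY_CATEGORIES = (
    "activated_pioneered",
    "activated_nonpioneered",
    "activated_atac_up",
    "inhibited_pioneered",
    "inhibited_nonpioneered",
    "mutually_dependent",
    "independent",
    "not_cobound",
)


def _status_map(diff: pd.DataFrame, which: str) -> dict[str, str]:
    if "status" not in diff.columns:
        raise ValueError(f"{which} differential table lacks a status column")
    return dict(zip(diff["element_id"], diff["status"]))


def _lookup(status: dict[str, str], element_id: str, which: str) -> str:
    try:
        return status[element_id]
    except KeyError:
        raise KeyError(
            f"element {element_id!r} missing from {which} differential table"
        ) from None


def _element_category(
    wt_open: bool, wt_active: bool, ac: str, atac: str
) -> str:
    if ac == "down" and atac == "down" and wt_open and wt_active:
        return "pioneered_activated"
    if ac == "down" and atac == "unchanged" and wt_open and wt_active:
        return "nonpioneered_activated"
    if ac == "up" and atac == "up":
        return "pioneered_inhibited"
    if ac == "up" and atac == "unchanged":
        return "nonpioneered_inhibited_candidate"
    if ac == "unchanged" and atac == "unchanged":
        return "quiescent"
    return "unclassified_atac_discordant"


def classify_elements(
    tf_peaks: Sequence[GenomicInterval],
    atac_peaks_wt: Sequence[GenomicInterval],
    ac_peaks_wt: Sequence[GenomicInterval],
    diff_ac: pd.DataFrame,
    diff_atac: pd.DataFrame,
    diff_k4: pd.DataFrame | None,
    tss_annotation: pd.DataFrame,
    scope: str = "enhancer",
    min_bp: int = 1,
) -> pd.DataFrame:
    """Assign every in-scope TF-bound element its regulatory category.

    ``scope`` = "enhancer" keeps promoter-distal elements, "promoter" keeps
    promoter-proximal ones; orphans (no TSS within the association domain)
    are excluded from both. "Open and active in WT" is a >= ``min_bp``
    overlap against the WT ATAC and H3K27Ac peak calls. H3K4Me3 status, when
    supplied, is carried as an annotation and never gates a category.
    """
    if scope not in ("enhancer", "promoter"):
        raise ValueError(f"unknown scope {scope!r}")
    keep_locale = "distal" if scope == "enhancer" else "promoter_proximal"
    locales = dict(zip(tss_annotation["element_id"], tss_annotation["locale"]))
    open_flags = overlaps(tf_peaks, atac_peaks_wt, min_bp=min_bp).flags
    active_flags = overlaps(tf_peaks, ac_peaks_wt, min_bp=min_bp).flags
    ac_status = _status_map(diff_ac, "H3K27Ac")
    atac_status = _status_map(diff_atac, "ATAC")
    k4_status = _status_map(diff_k4, "H3K4Me3") if diff_k4 is not None else None

    rows = []
    for iv in tf_peaks:
        locale = locales.get(iv.name)
        if locale is None:
            raise KeyError(f"element {iv.name!r} missing from TSS annotation")
        if locale != keep_locale:
            continue
        ac = _lookup(ac_status, iv.name, "H3K27Ac")
        atac = _lookup(atac_status, iv.name, "ATAC")
        k4 = _lookup(k4_status, iv.name, "H3K4Me3") if k4_status is not None else "unchanged"
        wt_open = open_flags[iv.name]
        wt_active = active_flags[iv.name]
        rows.append(
            {
                "element_id": iv.name,
                "locale": locale,
                "wt_open": wt_open,
                "wt_active": wt_active,
                "ac_status": ac,
                "atac_status": atac,
                "k4_status": k4,
                "category": _element_category(wt_open, wt_active, ac, atac),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "element_id",
            "locale",
            "wt_open",
            "wt_active",
            "ac_status",
            "atac_status",
            "k4_status",
            "category",
        ],
    )
    return df.sort_values("element_id", kind="mergesort").reset_index(drop=True)


def classify_dependency(
    second_tf_peaks: Sequence[GenomicInterval],
    primary_tf_peaks: Sequence[GenomicInterval],
    diff_secondtf: pd.DataFrame,
    diff_atac: pd.DataFrame,
    diff_reciprocal: pd.DataFrame | None = None,
    min_bp: int = 1,
) -> pd.DataFrame:
    """Assign each second-TF peak its dependency on the primary TF.

    ``diff_secondtf`` and ``diff_atac`` are KO-of-primary vs WT contrasts at
    the second-TF peaks; ``diff_reciprocal`` is the primary TF's own signal
    in the second TF's knockout (omit it and reciprocal_status becomes
    "not_tested", so mutually_dependent is never assigned). Peaks that do
    not overlap any primary-TF peak are labelled not_cobound and are
    excluded from the dependency denominator by ``summarize_categories``.
    """
    import warnings

    cobound = overlaps(second_tf_peaks, primary_tf_peaks, min_bp=min_bp).flags
    tf_status = _status_map(diff_secondtf, "second-TF")
    atac_status = _status_map(diff_atac, "ATAC")
    recip_status = (
        _status_map(diff_reciprocal, "reciprocal") if diff_reciprocal is not None else None
    )
    if recip_status is None:
        warnings.warn(
            "no reciprocal differential table: mutually_dependent will never be assigned",
            stacklevel=2,
        )

    rows = []
    for iv in second_tf_peaks:
        cb = cobound[iv.name]
        tf = _lookup(tf_status, iv.name, "second-TF")
        atac = _lookup(atac_status, iv.name, "ATAC")
        recip = (
            recip_status.get(iv.name, "not_tested")
            if recip_status is not None
            else "not_tested"
        )
        if not cb:
            cat = "not_cobound"
        elif tf == "down":
            if recip == "down":
                cat = "mutually_dependent"
            elif atac == "down":
                cat = "activated_pioneered"
            elif atac == "up":
                cat = "activated_atac_up"
            else:
                cat = "activated_nonpioneered"
        elif tf == "up":
            cat = "inhibited_pioneered" if atac == "up" else "inhibited_nonpioneered"
        else:
            cat = "independent"
        rows.append(
            {
                "peak_id": iv.name,
                "cobound": cb,
                "tf_binding_status": tf,
                "atac_status": atac,
                "reciprocal_status": recip,
                "category": cat,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "cobound",
            "tf_binding_status",
            "atac_status",
            "reciprocal_status",
            "category",
        ],
    )
    return df.sort_values("peak_id", kind="mergesort").reset_index(drop=True)


def percent(numerator: int, denominator: int) -> int:
    """Integer percent, rounding half away from zero (3083/5443 -> 57)."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    x = 100.0 * numerator / denominator
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def summarize_categories(
    classifications: pd.DataFrame,
    category_col: str = "category",
    parent: str = "all_classified",
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-category counts and integer percentages of the parent denominator.

    ``exclude`` drops categories (e.g. not_cobound) from both the rows and
    the denominator; the parent denominator is named explicitly in the
    output so every percentage is auditable.
    """
    if classifications.empty:
        raise ValueError("no classifications to summarize")
    counts = classifications[category_col].value_counts()
    counts = counts[~counts.index.isin(exclude)]
    denom = int(counts.sum())
    rows = [
        {
            "category": cat,
            "count": int(n),
            "percent": percent(int(n), denom) if denom else 0,
            "parent": parent,
            "parent_n": denom,
        }
        for cat, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent", "parent", "parent_n"])
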