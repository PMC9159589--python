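"""In-memory orchestration of the full analysis over a synthetic bundle.

`analyze_bundle` is the programmatic counterpart of the CLI ``run``
subcommand: differential tests on every contrast, TSS annotation, element
classification in both scopes, dependency classification, and the
category↔DEG association grids, all on an in-memory
:class:`~pioneerdep.synthetic.Bundle`.
"""

from __future__ import annotations

from typing import Any

from pioneerdep.association import associate
from pioneerdep.classify import classify_dependency, classify_elements
from pioneerdep.diffsignal import call_status, differential_test
from pioneerdep.intervals import annotate_tss
from pioneerdep.synthetic import Bundle

CONTRASTS = {
    "ATAC": ("KO_A", "WT"),
    "H3K27Ac": ("KO_A", "WT"),
    "H3K4Me3": ("KO_A", "WT"),
    "TF_B": ("KO_A", "WT"),
    "TF_A": ("KO_B", "WT"),
}


def analyze_bundle(bundle: Bundle, method: str = "moderated_t") -> dict[str, Any]:
    """Run diff -> classify -> associate on a bundle; returns all tables."""
    diffs = {
        assay: call_status(
            differential_test(
                bundle.matrices[assay], bundle.sheet, CONTRASTS[assay], method
            )
        )
        for assay in bundle.matrices
    }
    tss = annotate_tss(bundle.elements(), bundle.genes)
    out: dict[str, Any] = {"diffs": diffs, "tss": tss}
    for scope in ("enhancer", "promoter"):
        out[scope] = classify_elements(
            bundle.peaks["TF_A:WT"],
            bundle.peaks["ATAC:WT"],
            bundle.peaks["H3K27Ac:WT"],
            diffs["H3K27Ac"],
            diffs["ATAC"],
            diffs.get("H3K4Me3"),
            tss,
            scope=scope,
        )
        if len(out[scope]):
            out[f"association_{scope}"] = associate(out[scope], bundle.deg, tss)
    out["dependency"] = classify_dependency(
        bundle.peaks["TF_B:WT"],
        bundle.peaks["TF_A:WT"],
        diffs["TF_B"],
        diffs["ATAC"],
        diffs.get("TF_A"),
    )
    if len(out["dependency"]):
        out["association_dependency"] = associate(
            out["dependency"], bundle.deg, tss
        )
    return out
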