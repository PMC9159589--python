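"""PWM scanning and ZOOPS motif enrichment.

A sequence scores a ZOOPS (zero-or-one-occurrence-per-sequence) hit for a
motif if any offset on either strand reaches the log-odds threshold
(default: 80% of the motif's maximum attainable score against the
background). Enrichment of hits in a foreground set against a background
set is the upper hypergeometric tail — the same kernel as the gene-set
Fisher test — drawing |fg| sequences from the pooled fg+bg population with
all hit-carrying sequences as successes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

from pioneerdep.association import fisher_test
from pioneerdep.genomic_io import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A position weight matrix with a fraction-of-max score threshold.

    ``matrix`` holds per-position base probabilities (rows sum to 1);
    scanning scores are log2 odds against ``background``. ``threshold`` is a
    fraction of the maximum attainable score (in (0, 1]), the operative
    cut-off for a ZOOPS hit.
    """

    motif_id: str
    matrix: np.ndarray  # (length, 4) probabilities, A C G T order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be a fraction of max in (0, 1]")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 5) log2-odds; the last column (N) contributes 0."""
        lo = np.log2(self.matrix / self.background[None, :])
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def score_threshold(self) -> float:
        return self.threshold * self.max_score

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    threshold: float = 0.8,
) -> PWM:
    """Convert a 4-column count matrix to probabilities with a pseudocount."""
    counts = np.asarray(counts, dtype=float) + pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(motif_id, probs, bg, threshold)


def read_jaspar(path: str | Path, threshold: float = 0.8) -> list[PWM]:
    """Read JASPAR-format count matrices (via Bio.motifs) into PWMs."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
            name = m.matrix_id or m.name
            out.append(pwm_from_counts(str(name), counts, threshold=threshold))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for j, b in enumerate(BASES):
                row = " ".join(str(v) for v in counts[:, j])
                fh.write(f"{b} [ {row} ]\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _best_score(seq: str, lo: np.ndarray) -> float:
    L = lo.shape[0]
    enc = _encode(seq)
    n = enc.size - L + 1
    if n <= 0:
        return -np.inf
    idx = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = lo[np.arange(L)[None, :], idx].sum(axis=1)
    return float(scores.max())


def scan_zoops(seq: str, pwm: PWM, threshold: float | None = None) -> bool:
    """True iff any offset on either strand reaches the log-odds threshold.

    Ambiguous bases (N) contribute a log-odds of 0. Sequences shorter than
    the motif never hit.
    """
    if threshold is None:
        threshold = pwm.score_threshold
    lo = pwm.log_odds
    if len(seq) < len(pwm):
        return False
    fwd = _best_score(seq, lo)
    rev = _best_score(reverse_complement(seq), lo)
    return max(fwd, rev) >= threshold


def extract_windows(
    elements: Sequence[GenomicInterval],
    genome: str | Path | Fasta,
    half_width: int = 100,
) -> dict[str, str]:
    """Uppercase sequence windows centered on each element's summit.

    Windows are ``[point - half_width, point + half_width)`` clipped at the
    chromosome bounds, so a summit near an edge yields a shorter window.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out: dict[str, str] = {}
    for iv in elements:
        if iv.chrom not in fa:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        chrom_len = len(fa[iv.chrom])
        lo = max(0, iv.point - half_width)
        hi = min(chrom_len, iv.point + half_width)
        out[iv.name] = str(fa[iv.chrom][lo:hi]).upper()
    return out


def zoops_enrichment(
    fg: dict[str, str] | Sequence[str],
    bg: dict[str, str] | Sequence[str],
    pwms: Sequence[PWM] | PWM,
) -> pd.DataFrame:
    """ZOOPS hit counts in foreground vs background with hypergeometric p.

    The p-value is the upper tail of drawing ``fg_total`` sequences from the
    pooled fg+bg population containing ``fg_with_hit + bg_with_hit``
    hit-carrying sequences, evaluated at ``fg_with_hit`` — identical to the
    gene-set enrichment kernel.
    """
    if isinstance(pwms, PWM):
        pwms = [pwms]
    fg_seqs = list(fg.values()) if isinstance(fg, dict) else list(fg)
    bg_seqs = list(bg.values()) if isinstance(bg, dict) else list(bg)
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    rows = []
    for pwm in pwms:
        fg_hits = sum(scan_zoops(s, pwm) for s in fg_seqs)
        bg_hits = sum(scan_zoops(s, pwm) for s in bg_seqs)
        a = fg_hits
        b = len(fg_seqs) - fg_hits
        c = bg_hits
        d = len(bg_seqs) - bg_hits
        res = fisher_test(a, b, c, d, direction="enrichment")
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "fg_with_hit": fg_hits,
                "fg_total": len(fg_seqs),
                "bg_with_hit": bg_hits,
                "bg_total": len(bg_seqs),
                "fg_fraction": fg_hits / len(fg_seqs),
                "bg_fraction": bg_hits / len(bg_seqs),
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows)
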