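"""Truth-tagged synthetic multi-assay dataset generator.

The generator emulates the data layout of a pioneer-factor knockout study on
a toy genome: TF-bound elements with planted regulatory categories, per-peak
negative-binomial read counts with genotype-dependent fold changes, a
differential-expression table whose genes are placed near their planted
elements, and element sequences with an optionally planted binding motif.
Every element, gene and sequence carries its ground truth in a TruthFile so
each downstream stage is verifiable at desk scale.

Layout: the genome is tiled into fixed-size territories, one per element (or
per unlinked background gene). Each element sits near the territory start
with its target gene's TSS placed 0.2-2.8 kb away (promoter elements) or
3.5-20 kb away (distal elements), so the intended gene is provably the
single nearest gene within the 100 kb association domain and planted
geometric constraints hold by construction.

Count model: counts ~ NB(mean, dispersion) with variance = mean +
dispersion * mean^2; the knockout mean is mean_wt * 2^effect for the
element's category x assay, and every sample carries a log-normal
library-size factor so RPKM normalization is actually exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pioneerdep import genomic_io as gio
from pioneerdep.diffsignal import bh_adjust
from pioneerdep.genomic_io import (
    GenomicInterval,
    SampleSheet,
    SignalMatrix,
    assign_deg_status,
)
from pioneerdep.motifs import PWM, pwm_from_counts, write_jaspar

ELEMENT_CATEGORIES = (
    "pioneered_activated",
    "nonpioneered_activated",
    "pioneered_inhibited",
    "nonpioneered_inhibited_candidate",
    "quiescent",
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

#: per-category knockout effects in units of the configured |log2FC|.
#: Keys are assays; TF_A is the reciprocal contrast (primary-TF signal in
#: the second TF's knockout).
CATEGORY_EFFECTS: dict[str, dict[str, int]] = {
    "pioneered_activated": {"H3K27Ac": -1, "ATAC": -1},
    "nonpioneered_activated": {"H3K27Ac": -1},
    "pioneered_inhibited": {"H3K27Ac": +1, "ATAC": +1},
    "nonpioneered_inhibited_candidate": {"H3K27Ac": +1},
    "quiescent": {},
    "activated_pioneered": {"TF_B": -1, "ATAC": -1},
    "activated_nonpioneered": {"TF_B": -1},
    "activated_atac_up": {"TF_B": -1, "ATAC": +1},
    "inhibited_pioneered": {"TF_B": +1, "ATAC": +1},
    "inhibited_nonpioneered": {"TF_B": +1},
    "mutually_dependent": {"TF_B": -1, "ATAC": -1, "TF_A": -1},
    "independent": {},
    "not_cobound": {},
}

#: direction of the planted expression effect of an element's target gene
#: ("activated by the TF" means the gene goes down in the knockout).
CATEGORY_DEG_SIGN: dict[str, int] = {
    "pioneered_activated": -1,
    "nonpioneered_activated": -1,
    "pioneered_inhibited": +1,
    "nonpioneered_inhibited_candidate": +1,
    "quiescent": 0,
    "activated_pioneered": -1,
    "activated_nonpioneered": -1,
    "activated_atac_up": 0,
    "inhibited_pioneered": +1,
    "inhibited_nonpioneered": +1,
    "mutually_dependent": -1,
    "independent": 0,
    "not_cobound": 0,
}

#: categories whose elements are closed / inactive in wild-type chromatin
CLOSED_CATEGORIES = {
    "pioneered_inhibited",
    "nonpioneered_inhibited_candidate",
    "inhibited_pioneered",
    "inhibited_nonpioneered",
}

DEFAULT_MOTIF_CONSENSUS = "GCCTGAGGC"


def _default_counts(categories: Sequence[str], n: int) -> dict[str, int]:
    return {c: n for c in categories}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the contrast design the analysis assumes: 4 wild-type
    vs 4 knockout replicates per assay, negative-binomial counts at mean 300
    with dispersion 0.1, planted |log2FC| of 2 for every affected
    category x assay, and 40 elements per planted category.
    """

    seed: int = 0
    element_counts: dict[str, int] = field(
        default_factory=lambda: _default_counts(ELEMENT_CATEGORIES, 40)
    )
    promoter_counts: dict[str, int] = field(default_factory=dict)
    dependency_counts: dict[str, int] = field(
        default_factory=lambda: _default_counts(DEPENDENCY_CATEGORIES, 40)
    )
    replicates: int = 4
    mean_wt: float = 300.0
    dispersion: float = 0.1
    effect_log2fc: float = 2.0
    library_size_base: float = 1e7
    libsize_sigma: float = 0.1
    peak_width: int = 400
    n_background_genes: int = 200
    deg_link_prob: float = 0.9
    deg_effect_log2fc: float = 2.0
    deg_noise_sd: float = 0.25
    motif_plant_fraction: dict[str, float] = field(
        default_factory=lambda: {"pioneered_activated": 0.5}
    )
    motif_background_fraction: float = 0.05
    motif_consensus: str = DEFAULT_MOTIF_CONSENSUS
    n_chroms: int = 4
    territory_bp: int = 50_000
    chrom_length_bp: int | None = None
    promoter_distance_range: tuple[int, int] = (200, 2_800)
    distal_distance_range: tuple[int, int] = (3_500, 20_000)

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per genotype group")
        if not (0 <= self.deg_link_prob <= 1):
            raise ValueError("deg_link_prob must be in [0, 1]")
        bad = set(self.element_counts) - set(ELEMENT_CATEGORIES)
        bad |= set(self.promoter_counts) - set(ELEMENT_CATEGORIES)
        bad |= set(self.dependency_counts) - set(DEPENDENCY_CATEGORIES)
        if bad:
            raise ValueError(f"unknown category in counts: {sorted(bad)}")
        lo, hi = self.distal_distance_range
        if not (3_000 < lo < hi <= 100_000):
            raise ValueError("distal distances must lie in (3 kb, 100 kb]")
        plo, phi = self.promoter_distance_range
        if not (0 <= plo < phi <= 3_000):
            raise ValueError("promoter distances must lie in [0, 3 kb]")
        needed = hi + self.peak_width + 10_000
        if self.territory_bp < needed:
            raise ValueError(
                f"territory_bp {self.territory_bp} too small for the distal "
                f"distance range (need >= {needed})"
            )


@dataclass
class TruthFile:
    """Ground truth for every generated element, gene and sequence."""

    elements: dict[str, dict]
    genes: dict[str, dict]
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {"elements": self.elements, "genes": self.genes, "config": self.config},
            indent=1,
            sort_keys=True,
            default=str,
        )

    def category_ids(self, category: str) -> list[str]:
        return sorted(
            eid for eid, rec in self.elements.items() if rec["category"] == category
        )


@dataclass
class Bundle:
    """An in-memory synthetic dataset: peaks, counts, DEG, genome, truth."""

    config: SyntheticConfig
    sheet: SampleSheet
    peaks: dict[str, list[GenomicInterval]]  # keyed "ASSAY:GENOTYPE"
    matrices: dict[str, SignalMatrix]  # keyed by assay
    deg: pd.DataFrame
    genes: pd.DataFrame
    genome: dict[str, bytes]
    pwm: PWM
    truth: TruthFile

    def elements(self, ids: Sequence[str] | None = None) -> list[GenomicInterval]:
        """Element intervals (the TF-centric peak set), optionally filtered."""
        recs = self.truth.elements
        keys = sorted(recs) if ids is None else list(ids)
        return [
            GenomicInterval(
                recs[k]["chrom"],
                recs[k]["start"],
                recs[k]["end"],
                k,
                ".",
                recs[k]["summit_offset"],
            )
            for k in keys
        ]

    def window_sequences(
        self, ids: Sequence[str], half_width: int = 100
    ) -> dict[str, str]:
        """Summit-centered windows sliced from the in-memory genome."""
        out = {}
        for eid in ids:
            rec = self.truth.elements[eid]
            point = rec["start"] + rec["summit_offset"]
            chrom = self.genome[rec["chrom"]]
            lo = max(0, point - half_width)
            hi = min(len(chrom), point + half_width)
            out[eid] = chrom[lo:hi].decode()
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the bundle in exactly the formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for key in sorted(self.peaks):
            assay, genotype = key.split(":")
            p = outdir / f"peaks_{assay}_{genotype}.narrowPeak"
            gio.write_peaks(self.peaks[key], p, dialect="narrowPeak")
            paths[f"peaks:{key}"] = p
        for assay in sorted(self.matrices):
            p = outdir / f"counts_{assay}.tsv"
            gio.write_counts(self.matrices[assay], p)
            paths[f"counts:{assay}"] = p
        p = outdir / "sample_sheet.tsv"
        gio.write_sample_sheet(self.sheet, p)
        paths["sample_sheet"] = p
        p = outdir / "deg.tsv"
        self.deg.to_csv(p, sep="\t", index=False)
        paths["deg"] = p
        p = outdir / "genes.tsv"
        gio.write_gene_annotation(self.genes, p)
        paths["genes"] = p
        p = outdir / "genome.fa"
        with open(p, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80].decode() + "\n")
        paths["genome"] = p
        p = outdir / "motifs.jaspar"
        write_jaspar([self.pwm], p)
        paths["pwm"] = p
        p = outdir / "truth.json"
        p.write_text(self.truth.to_json())
        paths["truth"] = p
        return paths


def _consensus_pwm(consensus: str, strength: float = 0.85) -> PWM:
    """A sharp PWM around a consensus string (planted-motif ground truth)."""
    n_off = (1 - strength) / 3 * 100
    counts = np.full((len(consensus), 4), n_off)
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = strength * 100
    return pwm_from_counts("planted_motif", counts, pseudocount=1.0)


def plant_motif_sequences(
    n: int,
    plant_fraction: float,
    length: int,
    consensus: str,
    rng: np.random.Generator,
) -> tuple[list[str], list[bool]]:
    """Random sequences with the consensus planted centrally in a fraction."""
    seqs, flags = [], []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(n):
        arr = bases[rng.integers(0, 4, size=length)].copy()
        planted = bool(rng.random() < plant_fraction)
        if planted:
            start = (length - len(consensus)) // 2
            arr[start : start + len(consensus)] = np.frombuffer(
                consensus.encode(), dtype=np.uint8
            )
        seqs.append(arr.tobytes().decode())
        flags.append(planted)
    return seqs, flags


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate(config: SyntheticConfig | None = None) -> Bundle:
    """Generate the full truth-tagged bundle for the configured conditions.

    Fully reproducible from ``config.seed``: the same config always yields a
    byte-identical bundle.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- element roster ------------------------------------------------
    roster: list[tuple[str, str, str]] = []  # (element_id, family, category)
    i = 0
    for cat in ELEMENT_CATEGORIES:
        for _ in range(cfg.element_counts.get(cat, 0)):
            roster.append((f"e{i:04d}", "enhancer", cat))
            i += 1
    for cat in ELEMENT_CATEGORIES:
        for _ in range(cfg.promoter_counts.get(cat, 0)):
            roster.append((f"e{i:04d}", "promoter", cat))
            i += 1
    for cat in DEPENDENCY_CATEGORIES:
        for _ in range(cfg.dependency_counts.get(cat, 0)):
            roster.append((f"e{i:04d}", "dependency", cat))
            i += 1
    n_elements = len(roster)
    if n_elements == 0:
        raise ValueError("config plants no elements")

    # ---- territory layout ---------------------------------------------
    n_territories = n_elements + cfg.n_background_genes
    per_chrom = -(-n_territories // cfg.n_chroms)
    needed_len = per_chrom * cfg.territory_bp
    chrom_len = cfg.chrom_length_bp or needed_len
    if chrom_len < needed_len:
        raise ValueError(
            f"infeasible placement: {n_territories} territories of "
            f"{cfg.territory_bp} bp need {needed_len} bp per chromosome, "
            f"got chrom_length_bp={chrom_len}"
        )
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]

    def territory(t: int) -> tuple[str, int]:
        return chrom_names[t // per_chrom], (t % per_chrom) * cfg.territory_bp

    elements: dict[str, dict] = {}
    genes_rows = []
    for t, (eid, family, cat) in enumerate(roster):
        chrom, t0 = territory(t)
        start = t0 + 5_000
        end = start + cfg.peak_width
        summit = cfg.peak_width // 2
        point = start + summit
        if family == "promoter":
            lo, hi = cfg.promoter_distance_range
        else:
            lo, hi = cfg.distal_distance_range
        dist = int(rng.integers(lo, hi + 1))
        gene = f"g_{eid}"
        genes_rows.append({"gene_id": gene, "chrom": chrom, "tss": point + dist, "strand": "+"})
        elements[eid] = {
            "element_id": eid,
            "family": family,
            "category": cat,
            "chrom": chrom,
            "start": start,
            "end": end,
            "summit_offset": summit,
            "gene": gene,
            "tss_distance": dist,
            "wt_open": cat not in CLOSED_CATEGORIES,
            "wt_active": cat not in CLOSED_CATEGORIES,
            "effects": {
                assay: sign * cfg.effect_log2fc
                for assay, sign in CATEGORY_EFFECTS[cat].items()
            },
        }
    for b in range(cfg.n_background_genes):
        chrom, t0 = territory(n_elements + b)
        genes_rows.append(
            {"gene_id": f"g_bg{b:04d}", "chrom": chrom, "tss": t0 + 5_000, "strand": "+"}
        )
    genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "tss", "strand"])

    # ---- motif planting flags (drawn in roster order, before counts) ---
    for eid, family, cat in roster:
        frac = cfg.motif_plant_fraction.get(cat, cfg.motif_background_fraction)
        elements[eid]["motif_planted"] = bool(rng.random() < frac)

    # ---- sample sheet ---------------------------------------------------
    assay_groups = [
        ("ATAC", ["WT", "KO_A"]),
        ("H3K27Ac", ["WT", "KO_A"]),
        ("H3K4Me3", ["WT", "KO_A"]),
        ("TF_B", ["WT", "KO_A"]),
        ("TF_A", ["WT", "KO_B"]),
    ]
    sheet_rows = []
    size_factors: dict[str, float] = {}
    for assay, genotypes in assay_groups:
        for geno in genotypes:
            for r in range(1, cfg.replicates + 1):
                sid = f"{assay}_{geno}_r{r}"
                sf = float(rng.lognormal(0.0, cfg.libsize_sigma))
                size_factors[sid] = sf
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "assay": assay,
                        "genotype": geno,
                        "replicate": r,
                        "library_size": int(round(cfg.library_size_base * sf)),
                    }
                )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    # ---- count matrices -------------------------------------------------
    all_ids = [eid for eid, _, _ in roster]
    dep_ids = [eid for eid, fam, _ in roster if fam == "dependency"]
    tfa_ids = [
        eid for eid, fam, cat in roster if not (fam == "dependency" and cat == "not_cobound")
    ]
    assay_rows = {
        "ATAC": all_ids,
        "H3K27Ac": all_ids,
        "H3K4Me3": all_ids,
        "TF_B": dep_ids,
        "TF_A": tfa_ids,
    }
    ko_of = {"ATAC": "KO_A", "H3K27Ac": "KO_A", "H3K4Me3": "KO_A", "TF_B": "KO_A", "TF_A": "KO_B"}
    matrices: dict[str, SignalMatrix] = {}
    for assay, genotypes in assay_groups:
        ids = assay_rows[assay]
        col_geno = [
            (f"{assay}_{g}_r{r}", g)
            for g in genotypes
            for r in range(1, cfg.replicates + 1)
        ]
        cols = [c for c, _ in col_geno]
        lfc = np.array(
            [elements[eid]["effects"].get(assay, 0.0) for eid in ids]
        )
        mu = np.empty((len(ids), len(cols)))
        for j, (sid, geno) in enumerate(col_geno):
            eff = lfc if geno == ko_of[assay] else np.zeros_like(lfc)
            mu[:, j] = cfg.mean_wt * 2.0**eff * size_factors[sid]
        counts = _nb_draw(rng, mu, cfg.dispersion)
        matrices[assay] = SignalMatrix(
            ids, cols, counts, np.full(len(ids), cfg.peak_width, dtype=np.int64)
        )

    # ---- peak calls ------------------------------------------------------
    def interval(eid: str, name: str, pad: int = 0) -> GenomicInterval:
        rec = elements[eid]
        start = max(0, rec["start"] - pad)
        return GenomicInterval(
            rec["chrom"], start, rec["end"] + pad, name, ".",
            rec["start"] + rec["summit_offset"] - start,
        )

    peaks: dict[str, list[GenomicInterval]] = {
        "TF_A:WT": [interval(eid, eid) for eid in tfa_ids],
        "TF_B:WT": [interval(eid, eid) for eid in dep_ids],
        "ATAC:WT": [
            interval(eid, f"atac_{eid}", pad=100)
            for eid in all_ids
            if elements[eid]["wt_open"]
        ],
        "H3K27Ac:WT": [
            interval(eid, f"ac_{eid}", pad=100)
            for eid in all_ids
            if elements[eid]["wt_active"]
        ],
        "H3K4Me3:WT": [
            interval(eid, f"k4_{eid}", pad=100)
            for eid, fam, _ in roster
            if fam == "promoter"
        ],
    }

    # ---- DEG table -------------------------------------------------------
    gene_effect: dict[str, float] = {g: 0.0 for g in genes["gene_id"]}
    for eid, _, cat in roster:
        sign = CATEGORY_DEG_SIGN[cat]
        linked = sign != 0 and rng.random() < cfg.deg_link_prob
        elements[eid]["deg_linked"] = bool(linked)
        if linked:
            gene_effect[elements[eid]["gene"]] = sign * cfg.deg_effect_log2fc
    order = list(genes["gene_id"])
    eff = np.array([gene_effect[g] for g in order])
    log2fc = eff + rng.normal(0.0, cfg.deg_noise_sd, size=len(order))
    z = log2fc / cfg.deg_noise_sd
    pvals = 2 * stats.norm.sf(np.abs(z))
    deg = pd.DataFrame(
        {"gene_id": order, "log2fc": log2fc, "pvalue": pvals, "padj": bh_adjust(pvals)}
    )
    deg = assign_deg_status(deg, fc_thresh=1.0, padj_thresh=0.05)

    # ---- genome with planted motifs -------------------------------------
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, bytes] = {}
    arrays = {c: bases[rng.integers(0, 4, size=chrom_len)].copy() for c in chrom_names}
    consensus = np.frombuffer(cfg.motif_consensus.encode(), dtype=np.uint8)
    for eid, _, _ in roster:
        rec = elements[eid]
        if rec["motif_planted"]:
            point = rec["start"] + rec["summit_offset"]
            start = point - len(consensus) // 2
            arrays[rec["chrom"]][start : start + len(consensus)] = consensus
    genome = {c: arrays[c].tobytes() for c in chrom_names}

    truth = TruthFile(
        elements=elements,
        genes={
            g: {
                "planted_log2fc": float(gene_effect[g]),
                "status": str(deg.set_index("gene_id").loc[g, "status"]),
            }
            for g in order
        },
        config=asdict(cfg),
    )
    return Bundle(
        config=cfg,
        sheet=sheet,
        peaks=peaks,
        matrices=matrices,
        deg=deg,
        genes=genes,
        genome=genome,
        pwm=_consensus_pwm(cfg.motif_consensus),
        truth=truth,
    )


def regression_fixture(seed: int = 7) -> Bundle:
    """A small fixed bundle (20 elements, 20 genes) for end-to-end tests.

    Exercises every planted category at least once; deterministic for a
    given seed, so snapshots taken from it are stable across runs.
    """
    cfg = SyntheticConfig(
        seed=seed,
        element_counts=_default_counts(ELEMENT_CATEGORIES, 2),
        promoter_counts={"pioneered_activated": 1, "pioneered_inhibited": 1},
        dependency_counts=_default_counts(DEPENDENCY_CATEGORIES, 1),
        n_background_genes=0,
        n_chroms=2,
    )
    return simulate(cfg)
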