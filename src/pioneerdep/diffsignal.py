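"""Per-peak normalization and two-group differential signal testing.

Counts are normalized to RPKM (reads per kilobase per million library
reads). Differential signal between knockout and wild-type sample groups is
tested per peak on log2(RPKM + c), either with an empirical-Bayes moderated
pooled t test that shrinks per-peak variances toward a common prior
(``moderated_t``, the default — the standard approach for replicate-level
designs) or with Welch's unequal-variance t test (``logratio_t``); a
negative-binomial Wald test on raw counts with library-size offsets
(``nb_wald``) is also provided. P-values are adjusted by
Benjamini-Hochberg, and each peak is called up / down / unchanged against a
fold-change gate and a significance gate: a peak is "unchanged" if it fails
either gate, so the three statuses always partition the peak set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from pioneerdep.genomic_io import SampleSheet, SignalMatrix

PSEUDOCOUNT = 1.0  # RPKM units, applied before log/ratio

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"

#: default significance mode per assay contrast. The element taxonomy is
#: defined on BH-adjusted p-values (fdr mode); raw_p reproduces a
#: pooled-sample caller convention (alpha = 1e-5) and is selectable per assay.
DEFAULT_MODE = "fdr"
DEFAULT_ALPHA = {"fdr": 0.05, "raw_p": 1e-5}


def rpkm(matrix: SignalMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (library_size * length)."""
    libs = sheet.library_sizes(matrix.sample_ids)
    vals = (
        matrix.counts
        * 1e9
        / (libs[None, :] * matrix.peak_lengths.astype(float)[:, None])
    )
    return pd.DataFrame(vals, index=matrix.peak_ids, columns=matrix.sample_ids)


def _group_columns(
    matrix: SignalMatrix, sheet: SampleSheet, genotype: str
) -> list[str]:
    meta = sheet.df.set_index("sample_id")
    cols = [
        s
        for s in matrix.sample_ids
        if s in meta.index and meta.loc[s, "genotype"] == genotype
    ]
    if len(cols) < 2:
        raise ValueError(
            f"genotype group {genotype!r} has {len(cols)} replicate(s) in the "
            "matrix; need >= 2"
        )
    return cols


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y by Newton iteration (Smyth-style)."""
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10:
            break
    return float(x)


def _moderated_t(x_ko: np.ndarray, x_wt: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated pooled t test per row.

    Per-peak pooled variances are shrunk toward a common prior variance
    whose scale (s0^2) and weight (d0 degrees of freedom) are estimated
    from the observed variance distribution by the method of moments on
    log s^2; the statistic is referred to a t with d + d0 degrees of
    freedom. At replicate-level sample sizes this borrows strength across
    peaks the way count-model packages do, without any free parameter.
    """
    n1, n2 = x_ko.shape[1], x_wt.shape[1]
    d = n1 + n2 - 2
    mk, mw = x_ko.mean(axis=1), x_wt.mean(axis=1)
    s2 = (
        ((x_ko - mk[:, None]) ** 2).sum(axis=1)
        + ((x_wt - mw[:, None]) ** 2).sum(axis=1)
    ) / d
    pos = s2 > 0
    if not pos.any():
        # fully degenerate input: exact null wherever means agree
        diff = mk - mw
        return np.where(diff == 0, 1.0, 0.0)
    e = np.log(s2[pos]) - special.polygamma(0, d / 2) + np.log(d / 2)
    var_e = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = var_e - float(special.polygamma(1, d / 2))
    if excess <= 0:
        d0, s02 = np.inf, float(np.exp(e.mean()))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s02 = float(
            np.exp(e.mean() - special.polygamma(0, d0 / 2) + np.log(d0 / 2))
        )
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s02)
        df_total = 1e12
    else:
        s2_mod = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d + d0
    t = (mk - mw) / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df=df_total)
    return np.clip(np.where(np.isfinite(p), p, 1.0), 0.0, 1.0)


def _logratio_t(
    x_ko: np.ndarray, x_wt: np.ndarray
) -> np.ndarray:
    """Welch t p-values per row, with degenerate zero-variance handling.

    When both groups have zero variance the p-value is 1 if the means are
    equal; otherwise the variance is replaced by the smallest positive
    per-group variance observed across peaks in this contrast (conservative
    fallback for degenerate synthetic inputs).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x_ko, x_wt, axis=1, equal_var=False)
    p = np.asarray(p)
    bad = ~np.isfinite(p)
    if bad.any():
        v_ko = x_ko.var(axis=1, ddof=1)
        v_wt = x_wt.var(axis=1, ddof=1)
        pos = np.concatenate([v_ko[v_ko > 0], v_wt[v_wt > 0]])
        vmin = pos.min() if pos.size else 0.0
        mdiff = x_ko.mean(axis=1) - x_wt.mean(axis=1)
        for i in np.flatnonzero(bad):
            if mdiff[i] == 0 or vmin == 0.0:
                p[i] = 1.0
            else:
                n1, n2 = x_ko.shape[1], x_wt.shape[1]
                se = np.sqrt(vmin / n1 + vmin / n2)
                df = n1 + n2 - 2
                p[i] = 2 * stats.t.sf(abs(mdiff[i]) / se, df=df)
    return np.clip(p, 0.0, 1.0)


def _nb_wald(
    counts_ko: np.ndarray,
    counts_wt: np.ndarray,
    sf_ko: np.ndarray,
    sf_wt: np.ndarray,
) -> np.ndarray:
    """Delta-method Wald test on size-factor-normalized NB group means.

    Per peak, the dispersion is a pooled method-of-moments estimate from
    within-group residuals (floored at zero); the log-ratio of normalized
    group means is compared to its delta-method standard error on a t
    reference with n1 + n2 - 2 degrees of freedom, which keeps the test
    close to nominal at replicate-level sample sizes.
    """
    n1, n2 = counts_ko.shape[1], counts_wt.shape[1]
    y_ko = counts_ko / sf_ko[None, :]
    y_wt = counts_wt / sf_wt[None, :]
    m_ko = y_ko.mean(axis=1)
    m_wt = y_wt.mean(axis=1)
    ss = ((y_ko - m_ko[:, None]) ** 2).sum(axis=1) + (
        (y_wt - m_wt[:, None]) ** 2
    ).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    mean_sq = (m_ko**2 + m_wt**2) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(
            mean_sq > 0, np.maximum((pooled_var - (m_ko + m_wt) / 2) / mean_sq, 0.0), 0.0
        )
    eps = 1e-8
    v_ko = (m_ko + alpha * m_ko**2) / n1
    v_wt = (m_wt + alpha * m_wt**2) / n2
    b = np.log(np.maximum(m_ko, eps)) - np.log(np.maximum(m_wt, eps))
    se = np.sqrt(
        v_ko / np.maximum(m_ko, eps) ** 2 + v_wt / np.maximum(m_wt, eps) ** 2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b / se
    p = 2 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    p = np.where(np.isfinite(p), p, 1.0)
    # identical degenerate groups: exact null
    p = np.where((se == 0) & (b == 0), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def differential_test(
    matrix: SignalMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] = ("KO_A", "WT"),
    method: str = "moderated_t",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-peak two-group differential test, KO over WT.

    ``contrast`` names the (knockout, wild-type) genotype groups within the
    matrix's samples. Returns a DataFrame with element_id, mean_wt, mean_ko
    (mean RPKM per group), log2fc = log2((mean_ko + c)/(mean_wt + c)) and a
    two-sided p-value. Each group needs >= 2 replicates.
    """
    if method not in ("moderated_t", "logratio_t", "nb_wald"):
        raise ValueError(f"unknown method {method!r}")
    ko_geno, wt_geno = contrast
    ko_cols = _group_columns(matrix, sheet, ko_geno)
    wt_cols = _group_columns(matrix, sheet, wt_geno)
    vals = rpkm(matrix, sheet)
    r_ko = vals[ko_cols].to_numpy()
    r_wt = vals[wt_cols].to_numpy()
    mean_ko = r_ko.mean(axis=1)
    mean_wt = r_wt.mean(axis=1)
    log2fc = np.log2((mean_ko + pseudocount) / (mean_wt + pseudocount))
    if method == "moderated_t":
        p = _moderated_t(
            np.log2(r_ko + pseudocount), np.log2(r_wt + pseudocount)
        )
    elif method == "logratio_t":
        p = _logratio_t(
            np.log2(r_ko + pseudocount), np.log2(r_wt + pseudocount)
        )
    else:
        cf = matrix.to_frame()
        libs = sheet.library_sizes(matrix.sample_ids)
        sf = libs / libs.mean()
        sf_by = dict(zip(matrix.sample_ids, sf))
        p = _nb_wald(
            cf[ko_cols].to_numpy(dtype=float),
            cf[wt_cols].to_numpy(dtype=float),
            np.array([sf_by[s] for s in ko_cols]),
            np.array([sf_by[s] for s in wt_cols]),
        )
    return pd.DataFrame(
        {
            "element_id": matrix.peak_ids,
            "mean_wt": mean_wt,
            "mean_ko": mean_ko,
            "log2fc": log2fc,
            "pvalue": p,
        }
    )


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_status(
    results: pd.DataFrame,
    mode: str = DEFAULT_MODE,
    fc_thresh: float = 1.0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Attach padj and the up/down/unchanged status call.

    fdr mode gates on BH-adjusted p < alpha (default 0.05); raw_p mode gates
    on the unadjusted p-value (default alpha 1e-5). In both modes the status
    additionally requires |log2fc| > fc_thresh; anything failing either gate
    is "unchanged".
    """
    if mode not in DEFAULT_ALPHA:
        raise ValueError(f"unknown mode {mode!r}")
    if alpha is None:
        alpha = DEFAULT_ALPHA[mode]
    df = results.copy()
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    sig = df["padj"] < alpha if mode == "fdr" else df["pvalue"] < alpha
    df["status"] = np.where(
        sig & (df["log2fc"] > fc_thresh),
        STATUS_UP,
        np.where(sig & (df["log2fc"] < -fc_thresh), STATUS_DOWN, STATUS_UNCHANGED),
    )
    return df
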