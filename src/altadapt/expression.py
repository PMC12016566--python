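"""Expression analytics: TPM, per-gene altitude trend, BH-FDR flagging.

TPM (transcripts per million) length-normalises counts within a sample so
that every sample's column sums to 1e6.  The altitude trend is a per-gene
ordinary least-squares regression of log2(abundance + 1) on altitude with a
two-sided t-test (n - 2 df), and multiple testing is controlled by the
Benjamini-Hochberg step-up procedure.  Differential flags require both a
minimum |log2 fold change| and q strictly below the FDR ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionTable

__all__ = ["tpm", "altitude_trend", "bh_fdr", "de_flag"]


def tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and per-gene effective lengths.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum_g rate_g per
    sample.  An all-zero sample yields all-zero TPM (with a warning).
    """
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("effective lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        import warnings

        warnings.warn(
            f"samples with zero total counts: {list(counts.columns[zero])}",
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


def altitude_trend(
    abundance: pd.DataFrame,
    altitude: np.ndarray,
    transform=_log2p1,
) -> pd.DataFrame:
    """Per-gene OLS trend of transformed abundance on altitude.

    Returns slope (per metre), t statistic and two-sided p with n - 2 df,
    computed with the closed-form simple-regression formulas vectorised
    across genes.  Zero-variance genes are returned untestable (NaN) rather
    than erroring; constant altitude makes every gene untestable.
    """
    alt = np.asarray(altitude, dtype=float)
    n = alt.size
    if abundance.shape[1] != n:
        raise ValueError("abundance columns do not match altitude length")
    if n < 3:
        raise ValueError("need >= 3 samples")
    Y = transform(abundance.to_numpy(dtype=float))
    out = pd.DataFrame(index=abundance.index)
    testable_alt = np.unique(alt).size >= 2
    sxx = float(((alt - alt.mean()) ** 2).sum())
    if not testable_alt:
        out["slope"] = np.nan
        out["t"] = np.nan
        out["p"] = np.nan
        out["testable"] = False
        return out
    ac = alt - alt.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxy = Yc @ ac
    slope = sxy / sxx
    rss = (Yc**2).sum(axis=1) - slope**2 * sxx
    df = n - 2
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    gene_var = Yc.var(axis=1)
    testable = gene_var > 0
    out["slope"] = np.where(testable, slope, np.nan)
    out["t"] = np.where(testable, t, np.nan)
    out["p"] = np.where(testable, p, np.nan)
    out["testable"] = testable
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, never below raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_flag(
    log2_fold_changes,
    q_values,
    fc_min: float = 1.0,
    q_max: float = 0.05,
) -> np.ndarray:
    """Differential-expression flags: |log2FC| >= fc_min and q strictly < q_max."""
    fc = np.asarray(log2_fold_changes, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if fc.shape != q.shape:
        raise ValueError("fold changes and q-values must align")
    return (np.abs(fc) >= fc_min) & (q < q_max)
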