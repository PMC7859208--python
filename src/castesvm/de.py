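"""DE stand-in: Welch tests on log2-CPM with an interval (fold-change) null.

This module deliberately does NOT reimplement a negative-binomial shrinkage
GLM; it mirrors only the fold-change-threshold *semantics* used downstream:
each gene is tested against the composite null that the absolute log2 fold
change between two groups is at most ``lfc_threshold`` (default log2(1.5)),
so p-values refer to the probability of the observed difference if the true
change were within the baseline band. With ``lfc_threshold = 0`` this reduces
to the ordinary Welch two-sample test. An externally produced DE results
table (gene, log2fc, padj) can be used as a drop-in replacement for real
data; see :func:`read_external_de`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import normalize
from .stats import bh_adjust

__all__ = ["de_test", "read_external_de", "DEFAULT_LFC_THRESHOLD"]

DEFAULT_LFC_THRESHOLD = float(np.log2(1.5))


def _welch_interval_null(mean_a, var_a, n_a, mean_b, var_b, n_b, lfc_threshold):
    """Vectors of (delta, p) for H0: |delta| <= lfc_threshold (Welch)."""
    delta = mean_b - mean_a
    se = np.sqrt(var_a / n_a + var_b / n_b)
    se = np.where(se == 0, np.finfo(float).tiny, se)
    df_num = (var_a / n_a + var_b / n_b) ** 2
    df_den = (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
    df = np.where(df_den == 0, n_a + n_b - 2, df_num / np.where(df_den == 0, 1, df_den))
    # minimum-effect construction: reject when the estimate is extreme under
    # the nearest boundary of the interval null
    p_upper = sps.t.sf((delta - lfc_threshold) / se, df)   # evidence delta > +L
    p_lower = sps.t.cdf((delta + lfc_threshold) / se, df)  # evidence delta < -L
    p = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    return delta, p


def de_test(counts: pd.DataFrame, samples: pd.DataFrame, group_a: str,
            group_b: str, lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
            alpha: float = 0.05, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene differential-expression stand-in between two groups.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (group B over
    group A on log2-CPM), ``pvalue`` (Welch test against the interval null),
    ``padj`` (Benjamini-Hochberg) and ``significant`` (padj < alpha).
    """
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    ids_a = list(samples.loc[samples["group"] == group_a, "sample_id"])
    ids_b = list(samples.loc[samples["group"] == group_b, "sample_id"])
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {len(ids_a)} {group_a!r}, "
            f"{len(ids_b)} {group_b!r})")
    expr = normalize(counts, pseudocount=pseudocount)
    A = expr[ids_a].to_numpy()
    B = expr[ids_b].to_numpy()
    delta, p = _welch_interval_null(
        A.mean(axis=1), A.var(axis=1, ddof=1), A.shape[1],
        B.mean(axis=1), B.var(axis=1, ddof=1), B.shape[1],
        lfc_threshold,
    )
    padj = bh_adjust(p)
    out = pd.DataFrame({
        "log2fc": delta,
        "pvalue": p,
        "padj": padj,
        "significant": padj < alpha,
    }, index=counts.index.copy())
    out.attrs["label"] = "DE stand-in (Welch interval-null on log2-CPM)"
    out.attrs["contrast"] = f"{group_b} vs {group_a}"
    out.attrs["lfc_threshold"] = float(lfc_threshold)
    out.attrs["alpha"] = float(alpha)
    return out


def read_external_de(path, alpha: float = 0.05) -> pd.DataFrame:
    """Import an externally produced DE table (TSV: gene, log2fc, padj).

    Intended for dropping in real-data results from a dedicated DE tool in
    place of the stand-in; the returned frame carries the same columns.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external DE table missing column(s): {sorted(missing)}")
    df = df.set_index("gene")
    if "pvalue" not in df.columns:
        df["pvalue"] = np.nan
    df["significant"] = df["padj"] < alpha
    df.attrs["label"] = "external DE table"
    return df[["log2fc", "pvalue", "padj", "significant"]]
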