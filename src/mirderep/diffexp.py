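"""Gene-level differential expression from a normalized log2 matrix.

The input is an already-normalized probe- or gene-level log2 intensity matrix
with genotype/replicate metadata.  Per row, the log2 fold change is
mean(mutant) - mean(wildtype); p-values come from a two-sample location test
on the log2 values (Welch's t by default, pooled-variance optional) and are
FDR-adjusted by Benjamini-Hochberg across all rows.  Multiple probes mapping
to one gene are collapsed to the probe with the lowest adjusted p-value.
Presence calls (detected / not detected per genotype) use a median-over-
threshold rule with a configurable intensity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8  # log2-scale within-group variance floor


@dataclass
class ExpressionMatrix:
    """Log2 intensities (rows x samples) plus sample metadata.

    `samples` must have columns sample, genotype ('wildtype'/'mutant'),
    replicate; `probe2gene` optionally maps row ids to gene ids.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe2gene: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("row ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        for g in ("wildtype", "mutant"):
            if (self.samples["genotype"] == g).sum() < 2:
                raise ValueError(f"genotype {g!r} has fewer than 2 replicates")
        missing = set(self.samples["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"metadata samples missing from matrix: {sorted(missing)}")

    def genotype_columns(self, genotype: str) -> list[str]:
        return list(self.samples.loc[self.samples["genotype"] == genotype, "sample"])


def differential_expression(matrix: ExpressionMatrix,
                            method: str = "welch") -> pd.DataFrame:
    """Per-row log2fc, two-sided p, and BH-adjusted p.

    `method` is "welch" (unequal variances, default) or "pooled".  Within-group
    variances are floored at 1e-8 (with a warning) so that technically
    duplicated rows yield t=0, p=1 rather than NaN.
    """
    wt = matrix.values[matrix.genotype_columns("wildtype")].to_numpy(float)
    mut = matrix.values[matrix.genotype_columns("mutant")].to_numpy(float)
    n1, n2 = wt.shape[1], mut.shape[1]
    m1, m2 = wt.mean(axis=1), mut.mean(axis=1)
    v1, v2 = wt.var(axis=1, ddof=1), mut.var(axis=1, ddof=1)
    floored = (v1 < VARIANCE_FLOOR) | (v2 < VARIANCE_FLOOR)
    if floored.any():
        logger.warning("within-group variance floored for %d rows", int(floored.sum()))
    v1 = np.maximum(v1, VARIANCE_FLOOR)
    v2 = np.maximum(v2, VARIANCE_FLOOR)
    log2fc = m2 - m1
    if method == "welch":
        se2 = v1 / n1 + v2 / n2
        t = log2fc / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif method == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = log2fc / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full_like(t, n1 + n2 - 2, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj_p},
        index=matrix.values.index.copy())


def collapse_probes(results: pd.DataFrame,
                    probe2gene: Mapping[str, str]) -> pd.DataFrame:
    """One row per gene: its minimum-adj_p probe (ties -> lowest probe id).

    Probes absent from the mapping are dropped with a warning.
    """
    if not probe2gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = results.index.to_series().map(dict(probe2gene))
    unmapped = mapped.isna()
    if unmapped.any():
        logger.warning("dropping %d unmapped probes", int(unmapped.sum()))
    df = results.loc[~unmapped].copy()
    df["gene_id"] = mapped[~unmapped]
    # stable sorts: ties on adj_p resolve to the lexicographically lowest probe id
    df = df.sort_index(kind="mergesort").sort_values("adj_p", kind="mergesort")
    best = df.groupby("gene_id", sort=True).head(1)
    best = best.reset_index(names="probe_id")
    return best.set_index("gene_id").sort_index()


def presence_call(matrix: ExpressionMatrix,
                  threshold: float | None = None) -> pd.DataFrame:
    """Detected-per-genotype calls: median log2 intensity above `threshold`.

    Default threshold is the 25th percentile of the whole matrix (the
    platform's detection call is replaced by this simple, configurable rule).
    """
    if threshold is None:
        threshold = float(np.quantile(matrix.values.to_numpy(), 0.25))
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    wt = matrix.values[matrix.genotype_columns("wildtype")]
    mut = matrix.values[matrix.genotype_columns("mutant")]
    return pd.DataFrame({
        "present_wt": wt.median(axis=1) > threshold,
        "present_mut": mut.median(axis=1) > threshold,
    }, index=matrix.values.index.copy())


def filter_top_upregulated(results: pd.DataFrame, fold_min: float = 2.0,
                           p_max: float = 0.05,
                           use_adjusted: bool = True) -> pd.DataFrame:
    """Genes up more than `fold_min`-fold (linear) at p below `p_max`.

    Returns the qualifying rows sorted by descending log2fc.  `use_adjusted`
    selects adj_p (default) or raw p for the p-value filter.
    """
    if fold_min <= 0:
        raise ValueError("fold_min must be positive")
    pcol = "adj_p" if use_adjusted else "p"
    keep = (results["log2fc"] > np.log2(fold_min)) & (results[pcol] < p_max)
    return results.loc[keep].sort_values("log2fc", ascending=False)
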