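"""ECDF construction and Kolmogorov-Smirnov shift analysis of gene sets.

The central readout of a miRNA-loss experiment: when the repressing miRNA is
removed, the distribution of log2 fold changes of its target genes shifts to
the right of the non-target background.  Gene sets are made mutually
exclusive (a partition of the expressed universe), each non-background set is
compared against the background ECDF, and the shift is summarized by the
two-sample KS statistic D with its two-sided p-value.  Direction (up/down) is
reported separately from p, from the sign of the median difference.

The same machinery serves four analyses: global target derepression,
stratification by site class (seed7/seed6/non-canonical) or by conservation
(well/poor), absolute-expression comparisons within a genotype, and
progenitor/neuron signature shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ExpressionMatrix

logger = logging.getLogger(__name__)

#: sample-size bound below which the exact two-sample KS null is enumerated
EXACT_KS_MAX_N = 25


@dataclass
class ShiftResult:
    """One set-vs-background ECDF comparison."""

    set_name: str
    background_name: str
    n_set: int
    n_background: int
    D: float
    p: float
    direction: str  # up | down | none

    def to_dict(self) -> dict:
        return asdict(self)


def ecdf_eval(values: Sequence[float], x: float) -> float:
    """Right-continuous empirical CDF: fraction of values <= x."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    return float(np.searchsorted(np.sort(arr), x, side="right")) / arr.size


def ecdf_coordinates(values: Sequence[float]) -> pd.DataFrame:
    """Step-function coordinates (x, F) for external plotting."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    x, counts = np.unique(arr, return_counts=True)
    return pd.DataFrame({"x": x, "F": np.cumsum(counts) / arr.size})


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test: (D, p).

    D = sup |F_a - F_b|.  The exact null distribution is enumerated when the
    smaller sample has at most 25 values; the asymptotic Kolmogorov
    distribution is used otherwise (bounding runtime on transcriptome-sized
    sets).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two nonempty samples")
    method = "exact" if min(a.size, b.size) <= EXACT_KS_MAX_N else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(max(res.pvalue, 1e-300))


def _direction(set_values: np.ndarray, background_values: np.ndarray) -> str:
    d = np.median(set_values) - np.median(background_values)
    if d > 0:
        return "up"
    if d < 0:
        return "down"
    return "none"


def partition_target_sets(summary: pd.DataFrame, universe: Iterable[str],
                          stratifier: str = "class") -> dict[str, set[str]]:
    """Mutually exclusive gene sets over the expressed universe.

    `summary` is the per-gene site summary (index gene_id, columns site_class
    and conservation).  Stratifier:

    * ``class`` -- seed7 / seed6 / noncanonical / background
    * ``conservation`` -- well / poor (/ unassessed) / background
    * ``any_site`` -- target / background

    Background = expressed genes with no site of any class.  Genes with sites
    but outside the universe appear in no set.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty expressed universe")
    in_univ = summary.loc[summary.index.isin(universe)]
    sets: dict[str, set[str]] = {}
    if stratifier == "class":
        for cls in ("seed7", "seed6", "noncanonical"):
            sets[cls] = set(in_univ.index[in_univ["site_class"] == cls])
    elif stratifier == "conservation":
        for lab in ("well", "poor", "unassessed"):
            members = set(in_univ.index[in_univ["conservation"] == lab])
            if members or lab != "unassessed":
                sets[lab] = members
    elif stratifier == "any_site":
        sets["target"] = set(in_univ.index)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    with_site = set(in_univ.index)
    sets["background"] = universe - with_site
    return sets


def shift_analysis(de: pd.DataFrame, partition: Mapping[str, set[str]],
                   background_name: str = "background",
                   value_column: str = "log2fc") -> list[ShiftResult]:
    """KS comparison of each non-background set against the background.

    `de` must carry `value_column` for every partitioned gene.  Empty sets are
    skipped with a warning.
    """
    values = de[value_column]
    bg_genes = partition[background_name]
    if not bg_genes:
        raise ValueError("background set is empty")
    bg = values.loc[values.index.isin(bg_genes)].to_numpy()
    results = []
    for name, genes in partition.items():
        if name == background_name:
            continue
        if not genes:
            logger.warning("set %r is empty; skipped", name)
            continue
        vals = values.loc[values.index.isin(genes)].to_numpy()
        D, p = ks_two_sample(vals, bg)
        results.append(ShiftResult(name, background_name, vals.size, bg.size,
                                   D, p, _direction(vals, bg)))
    return results


def absolute_expression_shift(matrix: ExpressionMatrix,
                              partition: Mapping[str, set[str]],
                              genotype: str = "wildtype") -> list[ShiftResult]:
    """Shift analysis on absolute levels: mean log2 intensity within `genotype`."""
    cols = matrix.genotype_columns(genotype)
    means = matrix.values[cols].mean(axis=1).to_frame("abs_level")
    return shift_analysis(means, partition, value_column="abs_level")


def signature_shift(de: pd.DataFrame, nb_set: Iterable[str],
                    neuron_set: Iterable[str],
                    universe: Iterable[str]) -> list[ShiftResult]:
    """Progenitor (neuroblast) vs differentiated-neuron signature shifts.

    Both sets are restricted to the universe; genes in both sets are removed
    from each (logged).  Each set is compared against universe minus both.
    """
    universe = set(universe)
    nb = set(nb_set) & universe
    neu = set(neuron_set) & universe
    overlap = nb & neu
    if overlap:
        logger.warning("removing %d genes present in both signature sets",
                       len(overlap))
        nb -= overlap
        neu -= overlap
    if not nb or not neu:
        raise ValueError("signature set empty after universe restriction")
    background = universe - nb - neu
    if not background:
        raise ValueError("no background genes outside the signature sets")
    partition = {"nb": nb, "neuron": neu, "background": background}
    return shift_analysis(de, partition)


def shift_results_frame(results: Iterable[ShiftResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results],
                        columns=["set_name", "background_name", "n_set",
                                 "n_background", "D", "p", "direction"])
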