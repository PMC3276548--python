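"""Fisher-exact enrichment of gene sets against annotation terms.

Tests whether a gene set (predicted targets; up- or down-regulated cohorts)
is over-represented in annotation terms (tissue in-situ expression terms,
GO-style sets supplied as GMT).  The test is one-sided Fisher's exact
(hypergeometric upper tail, P(X >= a)) by default, with Bonferroni correction
over the terms tested; a two-sided variant is available by flag.

`exclusion_contrast` implements the comparison between bioinformatic and
functional mutual exclusion: a term may be enriched among all predicted
targets (site composition) yet show no enrichment among the targets that
actually respond to miRNA loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_TERM_SIZE = 3  # stability guard: terms with fewer universe genes are skipped


@dataclass
class EnrichmentResult:
    """One term's 2x2 contingency outcome."""

    term: str
    a: int  # in-set and in-term
    b: int  # in-set, not in-term
    c: int  # out-of-set, in-term
    d: int  # out-of-set, not in-term
    odds_ratio: float
    p: float
    p_bonferroni: float

    def to_dict(self) -> dict:
        return asdict(self)


def updown_gene_sets(de: pd.DataFrame, fc_min_linear: float = 1.3,
                     p_max: float = 0.05,
                     use_adjusted: bool = False) -> dict[str, set[str]]:
    """Up- and down-regulated cohorts: |fold change| above `fc_min_linear`
    (default 1.3, i.e. >30%) at p below `p_max`.  Disjoint by construction.

    Raw p is the default: without a moderated fit, FDR-adjusted p-values from
    a 3+3-replicate t-test retain no power, and the 0.05 scale of the filter
    reads as a per-gene test threshold.  Set `use_adjusted` to switch.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    if fc_min_linear <= 1:
        raise ValueError("fc_min_linear must exceed 1")
    pcol = "adj_p" if use_adjusted else "p"
    cut = np.log2(fc_min_linear)
    sig = de[pcol] < p_max
    return {
        "up": set(de.index[(de["log2fc"] > cut) & sig]),
        "down": set(de.index[(de["log2fc"] < -cut) & sig]),
    }


def term_enrichment(gene_set: Iterable[str],
                    annotation: Mapping[str, Iterable[str]],
                    universe: Iterable[str],
                    min_term_size: int = MIN_TERM_SIZE,
                    two_sided: bool = False) -> list[EnrichmentResult]:
    """Per-term Fisher enrichment of `gene_set` within `universe`.

    Annotation genes are intersected with the universe; set genes outside the
    universe are dropped with a warning.  Results are ranked by ascending p;
    Bonferroni multiplies by the number of terms actually tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    outside = gene_set - universe
    if outside:
        logger.warning("dropping %d set genes outside the universe", len(outside))
        gene_set &= universe
    N = len(universe)
    n_set = len(gene_set)
    results = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K < min_term_size:
            logger.debug("term %r has %d universe genes; skipped", term, K)
            continue
        a = len(gene_set & term_genes)
        b = n_set - a
        c = K - a
        d = N - K - b
        if two_sided:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        else:
            # one-sided enrichment: hypergeometric upper tail P(X >= a)
            p = float(stats.hypergeom.sf(a - 1, N, K, n_set))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else 0.0
        results.append(EnrichmentResult(term, a, b, c, d, float(odds),
                                        float(min(p, 1.0)), 0.0))
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def exclusion_contrast(target_partition: Mapping[str, set[str]],
                       up_set: Iterable[str],
                       annotation: Mapping[str, Iterable[str]],
                       universe: Iterable[str],
                       background_name: str = "background",
                       ) -> dict[str, list[EnrichmentResult]]:
    """Enrichment among (i) all predicted targets and (ii) derepressed targets.

    Targets = union of the non-background sets of `target_partition`;
    derepressed targets = targets intersected with `up_set`.  An empty
    derepressed set skips contrast (ii) with a warning.
    """
    targets = set()
    for name, genes in target_partition.items():
        if name != background_name:
            targets |= genes
    out = {"targets": term_enrichment(targets, annotation, universe)}
    derepressed = targets & set(up_set)
    if derepressed:
        out["derepressed_targets"] = term_enrichment(derepressed, annotation,
                                                     universe)
    else:
        logger.warning("no derepressed targets; functional contrast skipped")
    return out


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results],
                        columns=["term", "a", "b", "c", "d", "odds_ratio",
                                 "p", "p_bonferroni"])
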