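"""REDUCE-style motif regression on expression changes.

An unbiased complement to seed-directed analysis: which fixed-width sequence
motifs best explain transcriptome-wide log2 fold changes?  The model is
iterative single-motif least squares with residual subtraction:

    repeat:
        for every width-w motif observed in the UTRs, regress the current
        residual fold changes on the motif's occurrence count and score it by
        the two-sided t p-value of the slope;
        accept the best-scoring motif (ties: larger |slope|, then
        lexicographic), subtract its fitted contribution, and continue;
    until the best candidate's p-value exceeds the cutoff (default 0.05) or
    the iteration cap is reached.

Occurrence COUNT (not presence) is the regressor.  Positive coefficients mark
motifs whose carriers go up when the miRNA is lost (the cognate seed match
family); negative coefficients mark down-shifted cohorts (e.g. the Pumilio
site UGUAAAU).  Motif candidates live on the UTR sense strand in DNA; RNA
patterns are transliterated U->T for matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .sites import MatureMiRNA, MIR124, reverse_complement, seed_patterns

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype="u1")
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("N")] = 4


@dataclass
class KmerCountMatrix:
    """Sparse gene x motif occurrence counts (only observed motifs kept)."""

    genes: list[str]
    motifs: np.ndarray  # decoded motif strings, aligned to columns
    X: sparse.csr_matrix

    def column(self, motif: str) -> int:
        hits = np.flatnonzero(self.motifs == motif)
        if hits.size == 0:
            raise KeyError(motif)
        return int(hits[0])


def _decode_code(code: int, w: int) -> str:
    out = []
    for _ in range(w):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_counts(utrs: Mapping[str, str], w: int = 7) -> KmerCountMatrix:
    """Overlapping k-mer occurrence counts per gene (sparse).

    Windows containing N contribute nothing.  Only motifs occurring at least
    once appear as columns.  If no sequence is long enough for a window the
    result has zero columns (with a warning).
    """
    if w < 1:
        raise ValueError("motif width must be >= 1")
    genes = list(utrs)
    pow4 = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    gi_parts, code_parts = [], []
    for gi, gene in enumerate(genes):
        arr = _CODE[np.frombuffer(utrs[gene].upper().encode(), dtype="u1")]
        if (arr == 255).any():
            raise ValueError(f"{gene}: non-DNA characters in UTR")
        if arr.size < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, w)
        valid = (win < 4).all(axis=1)
        if not valid.any():
            continue
        codes = win[valid].astype(np.int64) @ pow4
        code_parts.append(codes)
        gi_parts.append(np.full(codes.size, gi, dtype=np.int64))
    if not code_parts:
        warnings.warn("no sequence long enough for the requested motif width")
        return KmerCountMatrix(genes, np.array([], dtype=object),
                               sparse.csr_matrix((len(genes), 0)))
    all_codes = np.concatenate(code_parts)
    all_gi = np.concatenate(gi_parts)
    uniq, inv = np.unique(all_codes, return_inverse=True)
    X = sparse.coo_matrix(
        (np.ones(all_codes.size), (all_gi, inv)),
        shape=(len(genes), uniq.size)).tocsr()
    X.sum_duplicates()
    motifs = np.array([_decode_code(int(c), w) for c in uniq], dtype=object)
    return KmerCountMatrix(genes, motifs, X)


@dataclass
class MotifHit:
    iteration: int
    motif: str
    coefficient: float
    p: float


@dataclass
class MotifModel:
    """Ordered motifs accepted by the iterative regression."""

    hits: list[MotifHit]
    rss_trace: list[float]  # RSS before iteration 1, then after each acceptance

    @property
    def motifs(self) -> list[str]:
        return [h.motif for h in self.hits]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"iteration": h.iteration, "motif": h.motif,
              "coefficient": h.coefficient, "p": h.p} for h in self.hits],
            columns=["iteration", "motif", "coefficient", "p"])


class ReduceMotifRegressor(BaseEstimator, RegressorMixin):
    """Iterative single-motif least squares on log2 fold changes.

    sklearn-style estimator: ``fit(X, y)`` where X is a mapping/list of UTR
    sequences (or a precomputed :class:`KmerCountMatrix`) aligned with y.

    Parameters
    ----------
    width : motif length in nt (the classic choice is 7).
    p_cutoff : per-motif slope p-value required to accept a motif (<= cutoff).
    max_iter : safety bound on accepted motifs.
    bonferroni : if True, multiply candidate p-values by the number of
        non-degenerate candidate motifs before applying the cutoff.

    Attributes (after fit)
    ----------------------
    motifs_, coefs_, pvalues_, intercepts_ : aligned per accepted motif.
    rss_trace_ : residual sum of squares, initial then after each acceptance.
    model_ : the :class:`MotifModel`.
    """

    def __init__(self, width: int = 7, p_cutoff: float = 0.05,
                 max_iter: int = 20, bonferroni: bool = False):
        self.width = width
        self.p_cutoff = p_cutoff
        self.max_iter = max_iter
        self.bonferroni = bonferroni

    def _counts(self, X) -> KmerCountMatrix:
        if isinstance(X, KmerCountMatrix):
            return X
        if isinstance(X, Mapping):
            return kmer_counts(X, self.width)
        return kmer_counts({f"seq{i}": s for i, s in enumerate(X)}, self.width)

    def fit(self, X, y):
        counts = self._counts(X)
        y = np.asarray(y, dtype=float)
        n = y.size
        if counts.X.shape[0] != n:
            raise ValueError("X and y are not aligned")
        if n < 10:
            raise ValueError("need at least 10 genes")
        M = counts.X
        m = M.shape[1]
        sx = np.asarray(M.sum(axis=0)).ravel()
        sxx = np.asarray(M.multiply(M).sum(axis=0)).ravel()
        Sxx = sxx - sx * sx / n
        degenerate = Sxx <= 0
        motif_keys = counts.motifs.astype(str)

        hits: list[MotifHit] = []
        intercepts: list[float] = []
        resid = y.copy()
        rss_trace = [float(((resid - resid.mean()) ** 2).sum())]
        taken = np.zeros(m, dtype=bool)
        n_candidates = int((~degenerate).sum())

        for it in range(1, self.max_iter + 1):
            yc = resid - resid.mean()
            Syy = float(yc @ yc)
            if Syy <= 1e-12 or m == 0 or n_candidates == 0:
                break
            Sxy = M.T @ yc
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(degenerate, 0.0, Sxy / np.where(degenerate, 1.0, Sxx))
                rss = np.maximum(Syy - b * Sxy, 0.0)
                s2 = rss / (n - 2)
                se = np.sqrt(s2 / np.where(degenerate, np.inf, Sxx))
                t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.inf * np.sign(b))
            p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), n - 2),
                         np.where(b == 0, 1.0, 0.0))
            p = np.where(degenerate | taken, np.inf, p)
            order = np.lexsort((motif_keys, -np.abs(b), p))
            j = int(order[0])
            p_best = p[j]
            if self.bonferroni and np.isfinite(p_best):
                p_best = min(1.0, p_best * n_candidates)
            if not np.isfinite(p_best) or p_best > self.p_cutoff:
                break
            xj = np.asarray(M[:, j].todense()).ravel()
            a = (resid.mean() - b[j] * xj.mean())
            resid = resid - (a + b[j] * xj)
            hits.append(MotifHit(it, str(motif_keys[j]), float(b[j]), float(p_best)))
            intercepts.append(float(a))
            taken[j] = True
            n_candidates -= 1
            rss_trace.append(float(((resid - resid.mean()) ** 2).sum()))

        self.model_ = MotifModel(hits, rss_trace)
        self.motifs_ = [h.motif for h in hits]
        self.coefs_ = np.array([h.coefficient for h in hits])
        self.pvalues_ = np.array([h.p for h in hits])
        self.intercepts_ = np.array(intercepts)
        self.rss_trace_ = rss_trace
        self.n_iter_ = len(hits)
        return self

    def predict(self, X):
        counts = self._counts(X)
        yhat = np.zeros(counts.X.shape[0])
        for motif, b, a in zip(self.motifs_, self.coefs_, self.intercepts_):
            try:
                j = counts.column(motif)
                xj = np.asarray(counts.X[:, j].todense()).ravel()
            except KeyError:
                xj = np.zeros(counts.X.shape[0])
            yhat += a + b * xj
        return yhat


def reduce_fit(logfc: Sequence[float] | pd.Series,
               counts: KmerCountMatrix | Mapping[str, str],
               w: int = 7, p_cutoff: float = 0.05, max_iter: int = 20,
               bonferroni: bool = False) -> MotifModel:
    """Functional wrapper over :class:`ReduceMotifRegressor`.

    When `logfc` is a Series and `counts` a mapping of sequences, the two are
    aligned by gene id.
    """
    if isinstance(logfc, pd.Series) and isinstance(counts, Mapping) \
            and not isinstance(counts, KmerCountMatrix):
        genes = [g for g in counts if g in logfc.index]
        counts = {g: counts[g] for g in genes}
        logfc = logfc.loc[genes]
    est = ReduceMotifRegressor(width=w, p_cutoff=p_cutoff, max_iter=max_iter,
                               bonferroni=bonferroni)
    est.fit(counts, np.asarray(logfc, dtype=float))
    return est.model_


DEFAULT_KNOWN_MOTIFS = {"Pumilio site": "UGUAAAU"}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_discovered_motifs(
    model: MotifModel | Iterable[str],
    mirna: MatureMiRNA = MIR124,
    known_motifs: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Annotate discovered motifs: cognate-seed variant, known motif, or orphan.

    A motif is a cognate-seed variant when it is within Hamming distance 1 of
    the seed7 target pattern, or exactly equals a shifted window of the
    reverse complement of miRNA positions 1-9.  Known motifs (default:
    Pumilio UGUAAAU) are matched exactly after U->T transliteration.
    """
    motifs = model.motifs if isinstance(model, MotifModel) else list(model)
    known = dict(DEFAULT_KNOWN_MOTIFS)
    if known_motifs:
        known.update(known_motifs)
    known_dna = {name: pat.upper().replace("U", "T") for name, pat in known.items()}
    seed7_pat = seed_patterns(mirna)["seed7"]
    rc19 = reverse_complement(mirna.sequence[:9].replace("U", "T"))
    out = {}
    for motif in motifs:
        w = len(motif)
        windows = {rc19[i:i + w] for i in range(len(rc19) - w + 1)}
        if (w == len(seed7_pat) and _hamming(motif, seed7_pat) <= 1) \
                or motif in windows:
            out[motif] = "cognate-seed"
            continue
        for name, pat in known_dna.items():
            if motif == pat:
                out[motif] = name
                break
        else:
            out[motif] = "orphan"
    return out
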