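"""Seed-site detection, import, and conservation labelling on 3'UTRs.

A miRNA represses transcripts through short complementary matches between its
5' "seed" region and the mRNA 3'UTR.  Two canonical site classes are used here:

* ``seed7`` -- a 7-nt UTR segment exactly reverse-complementary to miRNA
  positions 2-8 (the "2-8 match" / 7mer).
* ``seed6`` -- a 6-nt segment reverse-complementary to positions 2-7
  (the "2-7 match" / 6mer).

Non-canonical (seed-imperfect) sites are never called from sequence alone: they
are accepted only from an imported prediction table carrying a favourable site
score (mirSVR convention, more negative = stronger; cutoff < -0.1).

Conservation of a site is judged from a multi-species alignment of the UTR
projected onto reference coordinates.  Two rules are provided:

* ``methods_5of6`` -- well-conserved iff the site is base-identical (gapless)
  in at least 5 of {D. sechellia, D. simulans, D. yakuba, D. erecta,
  D. ananassae, D. pseudoobscura}, and D. pseudoobscura is among them.
* ``outgroup_fig_s8`` -- well-conserved iff the site is identical in at least
  one species outside the melanogaster group (pse, per, wil, moj, vir, gri).

Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")

#: species short codes used throughout (reference is dmel)
SPECIES_ALIASES = {
    "d. melanogaster": "dmel", "drosophila melanogaster": "dmel", "dmel": "dmel",
    "d. sechellia": "dsec", "dsec": "dsec",
    "d. simulans": "dsim", "dsim": "dsim",
    "d. yakuba": "dyak", "dyak": "dyak",
    "d. erecta": "dere", "dere": "dere",
    "d. ananassae": "dana", "dana": "dana",
    "d. pseudoobscura": "dpse", "dpse": "dpse",
    "d. persimilis": "dper", "dper": "dper",
    "d. willistoni": "dwil", "dwil": "dwil",
    "d. mojavensis": "dmoj", "dmoj": "dmoj",
    "d. virilis": "dvir", "dvir": "dvir",
    "d. grimshawi": "dgri", "dgri": "dgri",
}

REFERENCE_SPECIES = "dmel"


def normalize_species(name: str) -> str:
    """Resolve a species name (latin or short code) to its short code."""
    key = name.strip().lower()
    if key in SPECIES_ALIASES:
        return SPECIES_ALIASES[key]
    # MAF-style "species.chrom" source names
    head = key.split(".")[0]
    if head in SPECIES_ALIASES:
        return SPECIES_ALIASES[head]
    raise ValueError(f"unknown species name: {name!r}")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return dna.translate(_RC)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence (RNA alphabet, 5'->3') with derived seed windows."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.name}: sequence shorter than 8 nt")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.name}: non-RNA characters {sorted(bad)}")

    @property
    def seed6(self) -> str:
        """Positions 2-7 (1-based) of the miRNA."""
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        """Positions 2-8 (1-based) of the miRNA."""
        return self.sequence[1:8]


#: Drosophila miR-124 (identical in sequence to its vertebrate orthologs)
MIR124 = MatureMiRNA("miR-124", "UAAGGCACGCGGUGAAUGCCA")


def seed_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """DNA target patterns matched on the UTR sense strand.

    Returns ``{"seed7": ..., "seed6": ...}`` where each pattern is the reverse
    complement of the corresponding seed window written in DNA.  The seed6
    pattern is always a suffix of the seed7 pattern.
    """
    def rc_dna(rna: str) -> str:
        return reverse_complement(rna.replace("U", "T"))

    return {"seed7": rc_dna(mirna.seed7), "seed6": rc_dna(mirna.seed6)}


@dataclass
class TargetSite:
    """One seed-complementary match on a UTR (0-based half-open coordinates)."""

    gene_id: str
    start: int
    end: int
    site_class: str  # seed7 | seed6 | noncanonical
    score: float | None = None
    conservation: str = "unassessed"  # well | poor | unassessed
    source: str = "scanned"  # scanned | imported

    def __post_init__(self) -> None:
        if self.site_class == "seed7" and self.end - self.start != 7:
            raise ValueError("seed7 site must span 7 nt")
        if self.site_class == "seed6" and self.end - self.start != 6:
            raise ValueError("seed6 site must span 6 nt")
        if self.site_class == "noncanonical":
            if self.source != "imported" or self.score is None:
                raise ValueError(
                    "noncanonical sites require source='imported' and a score"
                )
        if self.site_class not in ("seed7", "seed6", "noncanonical"):
            raise ValueError(f"unknown site class {self.site_class!r}")


def _find_all(seq: str, pat: str) -> list[int]:
    out: list[int] = []
    i = seq.find(pat)
    while i != -1:
        out.append(i)
        i = seq.find(pat, i + 1)
    return out


def scan_utr(gene_id: str, sequence: str, mirna: MatureMiRNA = MIR124) -> list[TargetSite]:
    """Scan one UTR (sense strand) for canonical seed matches.

    Every occurrence of the seed7 pattern is reported as class ``seed7``;
    occurrences of the seed6 pattern are reported as ``seed6`` unless they lie
    inside a reported seed7 window (a seed7 match is never double-reported as
    its contained seed6).  ``N`` never matches.  Empty sequence returns [].
    """
    seq = sequence.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(f"{gene_id}: non-DNA characters {sorted(bad)}")
    pats = seed_patterns(mirna)
    starts7 = _find_all(seq, pats["seed7"])
    sites = [TargetSite(gene_id, s, s + 7, "seed7") for s in starts7]
    shadow = set()
    for t in starts7:
        shadow.add(t)
        shadow.add(t + 1)
    for s in _find_all(seq, pats["seed6"]):
        if s not in shadow:
            sites.append(TargetSite(gene_id, s, s + 6, "seed6"))
    sites.sort(key=lambda x: (x.start, x.end))
    return sites


def scan_utrs(utrs: Mapping[str, str], mirna: MatureMiRNA = MIR124) -> list[TargetSite]:
    """Scan a collection of UTRs; concatenation of per-gene scans."""
    out: list[TargetSite] = []
    for gene_id, seq in utrs.items():
        out.extend(scan_utr(gene_id, seq, mirna))
    return out


SITE_TABLE_COLUMNS = ("gene_id", "start", "end", "site_type", "score")


def import_site_predictions(
    table: pd.DataFrame | str,
    score_cutoff: float = -0.1,
    coords: str | None = None,
) -> list[TargetSite]:
    """Import externally predicted sites (miRanda/mirSVR-style TSV or frame).

    Canonical rows (site_type seed7/seed6) pass through with their declared
    class; non-canonical rows are retained only when ``score < score_cutoff``
    (mirSVR convention: favourable scores are negative).  Coordinates are
    normalized to 0-based half-open; a file must declare its convention in a
    ``#coords=`` header line (``0based-halfopen`` or ``1based-closed``) unless
    `coords` is given.
    """
    if isinstance(table, str) or hasattr(table, "__fspath__"):
        import io as _io

        declared = None
        body: list[str] = []
        with open(table) as fh:
            for line in fh:
                if line.startswith("#"):
                    meta = line[1:].strip()
                    if meta.startswith("coords="):
                        declared = meta.split("=", 1)[1]
                else:
                    body.append(line)
        df = pd.read_csv(_io.StringIO("".join(body)), sep="\t")
        coords = coords or declared
        if coords is None:
            raise FormatError(f"{table}: no #coords= declaration and none supplied")
    else:
        df = table
        coords = coords or "0based-halfopen"
    if coords not in ("0based-halfopen", "1based-closed"):
        raise FormatError(f"unknown coordinate convention {coords!r}")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"site table missing columns: {missing}")

    sites: list[TargetSite] = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if coords == "1based-closed":
            start -= 1
        score = None if pd.isna(row.score) else float(row.score)
        cls = str(row.site_type)
        if cls == "noncanonical":
            if score is None:
                logger.warning("imported noncanonical row for %s lacks a score; dropped",
                               row.gene_id)
                continue
            if not score < score_cutoff:
                continue
        sites.append(TargetSite(str(row.gene_id), start, end, cls,
                                score=score, source="imported"))
    return sites


MELANOGASTER_PANEL = ("dsec", "dsim", "dyak", "dere", "dana", "dpse")
OUTGROUP_PANEL = ("dpse", "dper", "dwil", "dmoj", "dvir", "dgri")


@dataclass(frozen=True)
class ConservationRule:
    """Panel and quorum defining the well- vs poorly-conserved call."""

    rule_name: str
    panel: tuple[str, ...]
    min_identical: int
    mandatory: str | None = None


def conservation_rule(name: str) -> ConservationRule:
    """Factory for the two supported rules (see module docstring)."""
    if name == "methods_5of6":
        return ConservationRule(name, MELANOGASTER_PANEL, 5, mandatory="dpse")
    if name == "outgroup_fig_s8":
        return ConservationRule(name, OUTGROUP_PANEL, 1, mandatory=None)
    raise ValueError(f"unknown conservation rule {name!r}")


def classify_site_conservation(
    site: TargetSite,
    aln: Mapping[str, str] | None,
    rule: ConservationRule | str = "methods_5of6",
) -> str:
    """Label one site well/poor/unassessed from reference-projected alignment rows.

    `aln` maps species name -> sequence in reference (ungapped) coordinates,
    with '-' for deleted columns; it must include the reference row.  Identity
    is gapless and base-exact over the site columns.  A missing alignment or
    missing reference row yields "unassessed".
    """
    if isinstance(rule, str):
        rule = conservation_rule(rule)
    if not aln:
        return "unassessed"
    rows = {}
    for name, seq in aln.items():
        try:
            rows[normalize_species(name)] = seq.upper()
        except ValueError:
            logger.warning("alignment row with unknown species %r ignored", name)
    ref = rows.get(REFERENCE_SPECIES)
    if ref is None or len(ref) < site.end:
        return "unassessed"
    ref_site = ref[site.start:site.end]
    identical = set()
    for sp in rule.panel:
        row = rows.get(sp)
        if row is None or len(row) < site.end:
            continue
        frag = row[site.start:site.end]
        if "-" not in frag and frag == ref_site:
            identical.add(sp)
    ok = len(identical) >= rule.min_identical
    if rule.mandatory is not None:
        ok = ok and rule.mandatory in identical
    return "well" if ok else "poor"


def classify_sites_conservation(
    sites: Iterable[TargetSite],
    alignments: Mapping[str, Mapping[str, str]],
    rule: ConservationRule | str = "methods_5of6",
) -> list[TargetSite]:
    """Return copies of `sites` with conservation labels filled in."""
    out = []
    for s in sites:
        label = classify_site_conservation(s, alignments.get(s.gene_id), rule)
        out.append(replace(s, conservation=label))
    return out


_CLASS_RANK = {"seed7": 0, "seed6": 1, "noncanonical": 2}
_CONS_RANK = {"well": 0, "poor": 1, "unassessed": 2}


def gene_site_summary(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """Collapse sites to one row per gene: strongest class, best conservation.

    Class precedence seed7 > seed6 > noncanonical; conservation is "well" if
    any site is well-conserved, else "poor" if any site was assessed, else
    "unassessed".  Genes with no sites are simply absent (background genes).
    """
    best: dict[str, dict] = {}
    for s in sites:
        rec = best.setdefault(
            s.gene_id, {"site_class": s.site_class, "conservation": s.conservation,
                        "n_sites": 0})
        rec["n_sites"] += 1
        if _CLASS_RANK[s.site_class] < _CLASS_RANK[rec["site_class"]]:
            rec["site_class"] = s.site_class
        if _CONS_RANK[s.conservation] < _CONS_RANK[rec["conservation"]]:
            rec["conservation"] = s.conservation
    df = pd.DataFrame.from_dict(best, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=["site_class", "conservation", "n_sites"])
    df.index.name = "gene_id"
    return df.sort_index()


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """Tabulate sites (0-based half-open coordinates)."""
    rows = [
        {"gene_id": s.gene_id, "start": s.start, "end": s.end,
         "site_class": s.site_class, "score": s.score,
         "conservation": s.conservation, "source": s.source}
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "site_class",
                                       "score", "conservation", "source"])
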