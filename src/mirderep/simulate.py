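"""Truth-labelled synthetic datasets for the derepression pipeline.

The generator emulates a sorted-cell expression experiment: two genotypes
(wildtype, in which the miRNA is active, and mutant, in which it is deleted)
with replicate log2 expression profiles of the same cell population.  Planted
structure:

* a fraction of genes carry one seed-complementary site of a given class in
  their (otherwise i.i.d. uniform) 3'UTR, and receive an additive log2
  derepression effect in the mutant, ordered seed7 > seed6 > non-canonical.
  Background genes occasionally acquire accidental seed matches by chance;
  because a real seed match represses regardless of how it arose, such genes
  receive the effect of their strongest realized site class, and the truth
  table marks the match as incidental;
* target genes sit at a higher baseline than background (targets of an active
  miRNA tend to be among the more highly expressed transcripts);
* each planted site receives a conservation label realized as identity
  patterns over a simulated species alignment of the UTR;
* a cohort of genes carries the Pumilio binding motif (UGUAAAU; DNA TGTAAAT)
  and a negative planted effect, emulating overactivity of a second
  post-transcriptional repressor when the miRNA is lost; these UTRs are kept
  free of canonical seed matches so the cohort's net effect stays negative;
* optional "signature" scenario: progenitor (neuroblast) genes shift up and
  differentiated-neuron genes shift down in the mutant;
* optional "exclusion" scenario: an "epidermis" annotation term is enriched
  among target genes whose planted effect is forced to zero, decoupling
  bioinformatic from functional enrichment.

Expression model: per-gene baseline ~ Normal(baseline_mean, baseline_sd) on
the log2 scale; replicate noise additive Gaussian; mutant samples add the
gene's planted effect.  A single master seed deterministically spawns
independent substreams per component, so the generator is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sites import (MIR124, MatureMiRNA, scan_utr, seed_patterns)

_BASES = np.frombuffer(b"ACGT", dtype="u1")
PUMILIO_DNA = "TGTAAAT"  # RNA UGUAAAU

#: non-reference species used in the simulated alignments (reference: dmel).
#: dpse first so the mandatory species is present at any simulated depth.
SIM_SPECIES = ("dpse", "dsec", "dsim", "dyak", "dere", "dana")

_FRACTION_FIELDS = ("frac_7mer", "frac_6mer", "frac_noncanonical",
                    "frac_conserved", "frac_pumilio_down", "frac_nb",
                    "frac_neuron", "frac_epidermis")


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Effects are mean log2 derepression added to mutant samples; fractions are
    proportions of the gene universe.  See module docstring for the model.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    frac_7mer: float = 0.10
    frac_6mer: float = 0.10
    frac_noncanonical: float = 0.05
    effect_7mer: float = 0.6
    effect_6mer: float = 0.3
    effect_nc: float = 0.15
    frac_conserved: float = 0.5
    expr_mean_offset_targets: float = 1.0
    frac_pumilio_down: float = 0.05
    pumilio_effect: float = -0.4
    noise_sd: float = 0.5
    utr_len: int = 500
    n_species: int = 7  # including the reference
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    ordered_effects: bool = True
    signature: bool = False
    frac_nb: float = 0.08
    frac_neuron: float = 0.08
    nb_effect: float = 0.3
    neuron_effect: float = -0.3
    frac_epidermis: float = 0.0
    epidermis_from_targets: float = 0.7
    with_alignments: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_7mer + self.frac_6mer + self.frac_noncanonical > 1.0:
            raise ConfigurationError("site-class fractions sum to more than 1")
        if self.ordered_effects and not (
            self.effect_7mer >= self.effect_6mer >= self.effect_nc
        ):
            raise ConfigurationError(
                "ordered_effects requires effect_7mer >= effect_6mer >= effect_nc")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates per genotype")
        if not 2 <= self.n_species <= 1 + len(SIM_SPECIES):
            raise ConfigurationError(
                f"n_species must be in [2, {1 + len(SIM_SPECIES)}]")
        if (self.with_alignments and self.frac_conserved > 0
                and self.n_species - 1 < 5):
            raise ConfigurationError(
                "well-conserved sites need at least 5 non-reference species")
        if self.utr_len < 20:
            raise ConfigurationError("utr_len too short to plant sites")
        # any class with a positive fraction must round to >= 1 gene
        for name in ("frac_7mer", "frac_6mer", "frac_noncanonical",
                     "frac_pumilio_down", "frac_nb", "frac_neuron",
                     "frac_epidermis"):
            v = getattr(self, name)
            if v > 0 and int(round(v * self.n_genes)) == 0:
                raise ConfigurationError(
                    f"{name}={v} rounds to 0 genes at n_genes={self.n_genes}")

    # -- flat key=value round-trip ------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SimConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"bad config line: {line!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in types:
                raise ConfigurationError(f"unknown config key: {key!r}")
            t = types[key]
            if t in ("int", int):
                kwargs[key] = int(val)
            elif t in ("float", float):
                kwargs[key] = float(val)
            elif t in ("bool", bool):
                kwargs[key] = val.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = val
        return cls(**kwargs)


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study conditions: default, null, signature, exclusion."""
    if name == "default":
        cfg = SimConfig(seed=seed)
    elif name == "null":
        cfg = SimConfig(seed=seed, effect_7mer=0.0, effect_6mer=0.0,
                        effect_nc=0.0, pumilio_effect=0.0)
    elif name == "signature":
        cfg = SimConfig(seed=seed, signature=True)
    elif name == "exclusion":
        cfg = SimConfig(seed=seed, frac_epidermis=0.06)
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    return dataclasses.replace(cfg, **overrides)


@dataclass
class SyntheticDataset:
    """One generated experiment, with planted truth."""

    config: SimConfig
    expression: pd.DataFrame  # genes x samples, log2
    samples: pd.DataFrame  # sample, genotype, replicate
    utrs: dict[str, str]
    alignments: dict[str, dict[str, str]]
    site_table: pd.DataFrame  # imported-style noncanonical predictions
    tissue_annotations: dict[str, set[str]]  # term -> gene ids
    nb_set: set[str]
    neuron_set: set[str]
    truth: pd.DataFrame


def extract_truth(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-gene planted class / effect / conservation table (a copy)."""
    truth = getattr(dataset, "truth", None)
    if truth is None or len(truth) == 0:
        raise ValueError("dataset carries no truth block")
    return truth.copy()


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _plant(utr: np.ndarray, pattern: str, pos: int) -> None:
    codes = np.frombuffer(pattern.encode(), dtype="u1")
    lut = np.zeros(256, dtype="u1")
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    utr[pos:pos + len(pattern)] = lut[codes]


def _pattern_codes(pattern: str) -> np.ndarray:
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    return np.array([lut[b] for b in pattern.encode()], dtype="u1")


def generate_dataset(config: SimConfig, mirna: MatureMiRNA = MIR124) -> SyntheticDataset:
    """Generate a complete truth-labelled dataset under `config`.

    Deterministic: identical config (including seed) gives byte-identical
    output.  Independent substreams are spawned per component so that, e.g.,
    the expression draw does not depend on how many alignments were simulated.
    """
    config.validate()
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    ss = np.random.SeedSequence(config.seed)
    (ss_assign, ss_seq, ss_expr, ss_aln, ss_annot) = ss.spawn(5)
    rng_assign = np.random.default_rng(ss_assign)
    rng_seq = np.random.default_rng(ss_seq)
    rng_aln = np.random.default_rng(ss_aln)
    rng_annot = np.random.default_rng(ss_annot)

    # ---- class assignment -------------------------------------------
    n7 = int(round(config.frac_7mer * n))
    n6 = int(round(config.frac_6mer * n))
    nnc = int(round(config.frac_noncanonical * n))
    perm = rng_assign.permutation(n)
    idx7 = perm[:n7]
    idx6 = perm[n7:n7 + n6]
    idxnc = perm[n7 + n6:n7 + n6 + nnc]
    rest = perm[n7 + n6 + nnc:]
    npum = int(round(config.frac_pumilio_down * n))
    nnb = int(round(config.frac_nb * n))
    nneu = int(round(config.frac_neuron * n))
    if npum + nnb + nneu > len(rest):
        raise ConfigurationError("not enough background genes for the planted cohorts")
    idxpum = rest[:npum]
    idxnb = rest[npum:npum + nnb]
    idxneu = rest[npum + nnb:npum + nnb + nneu]

    designed_class = np.array(["background"] * n, dtype=object)
    designed_class[idx7] = "seed7"
    designed_class[idx6] = "seed6"
    designed_class[idxnc] = "noncanonical"

    # conservation labels for deliberately planted target sites
    target_idx = np.concatenate([idx7, idx6, idxnc])
    conservation = np.array([""] * n, dtype=object)
    if len(target_idx):
        well_mask = rng_assign.random(len(target_idx)) < config.frac_conserved
        conservation[target_idx[well_mask]] = "well"
        conservation[target_idx[~well_mask]] = "poor"

    # exclusion scenario: "epidermis" genes, mostly targets whose class effect
    # will be forced to zero (bioinformatic enrichment without derepression)
    epid_null = np.zeros(n, dtype=bool)
    epidermis_idx = np.array([], dtype=int)
    nepi = int(round(config.frac_epidermis * n))
    if nepi:
        n_from_targets = min(int(round(config.epidermis_from_targets * nepi)),
                             len(target_idx))
        chosen_t = rng_assign.choice(target_idx, size=n_from_targets, replace=False)
        pool = np.setdiff1d(rest[npum + nnb + nneu:], chosen_t)
        chosen_b = rng_assign.choice(pool, size=nepi - n_from_targets, replace=False)
        epidermis_idx = np.concatenate([chosen_t, chosen_b])
        epid_null[chosen_t] = True

    # ---- UTR sequences with planted sites ---------------------------
    pats = seed_patterns(mirna)
    seed7_pat, seed6_pat = pats["seed7"], pats["seed6"]
    utr_mat = rng_seq.integers(0, 4, size=(n, config.utr_len), dtype="u1")
    site_start = np.full(n, -1, dtype=int)
    nc_scores = {}

    def random_pos(width: int, lo: int = 1) -> int:
        # keep one flanking base on each side for neighbour fix-ups
        return int(rng_seq.integers(lo, config.utr_len - width - 1))

    for i in idx7:
        p = random_pos(7)
        _plant(utr_mat[i], seed7_pat, p)
        site_start[i] = p
    for i in idx6:
        p = random_pos(6)
        _plant(utr_mat[i], seed6_pat, p)
        site_start[i] = p
        # keep the planted site a 6mer: the upstream base must not extend it
        # to a seed7 match, nor may the site start one itself
        first7 = _pattern_codes(seed7_pat)[0]
        if utr_mat[i, p - 1] == first7:
            utr_mat[i, p - 1] = (first7 + 1 + rng_seq.integers(0, 3)) % 4
        win = _decode(utr_mat[i, p:p + 7])
        if win == seed7_pat:
            utr_mat[i, p + 6] = (utr_mat[i, p + 6] + 1 + rng_seq.integers(0, 3)) % 4
    seed7_codes = _pattern_codes(seed7_pat)
    for i in idxnc:
        # one seed mismatch at a random seed position (pattern indices 1..6
        # correspond to miRNA positions 7..2)
        while True:
            mism = int(rng_seq.integers(1, 7))
            codes = seed7_codes.copy()
            codes[mism] = (codes[mism] + 1 + rng_seq.integers(0, 3)) % 4
            var = _decode(codes)
            if var != seed7_pat and seed6_pat not in var:
                break
        p = random_pos(7)
        utr_mat[i, p:p + 7] = codes
        site_start[i] = p
        nc_scores[i] = float(rng_seq.uniform(-0.5, -0.1))
    for i in idxpum:
        p = random_pos(len(PUMILIO_DNA))
        _plant(utr_mat[i], PUMILIO_DNA, p)
        site_start[i] = p
        # the Pumilio cohort must shift down: scrub accidental seed matches
        for _ in range(20):
            found = scan_utr(genes[i], _decode(utr_mat[i]), mirna)
            if not found:
                break
            for s in found:
                for q in range(s.start, s.end):
                    if not p <= q < p + len(PUMILIO_DNA):
                        utr_mat[i, q] = (utr_mat[i, q]
                                         + 1 + rng_seq.integers(0, 3)) % 4
                        break

    utrs = {genes[i]: _decode(utr_mat[i]) for i in range(n)}

    # realized class per gene: a seed match represses regardless of whether it
    # was deliberately planted, so effects follow the strongest realized site;
    # accidental matches are recorded as incidental
    _rank = {"seed7": 0, "seed6": 1, "noncanonical": 2, "background": 3}
    realized_class = designed_class.copy()
    incidental = []
    for i in range(n):
        found = scan_utr(genes[i], utrs[genes[i]], mirna)
        extra = sorted({s.site_class for s in found
                        if not (designed_class[i] in ("seed7", "seed6")
                                and s.start == site_start[i]
                                and s.site_class == designed_class[i])})
        incidental.append(",".join(extra))
        for s in found:
            if _rank[s.site_class] < _rank[realized_class[i]]:
                realized_class[i] = s.site_class

    class_effect = {"seed7": config.effect_7mer, "seed6": config.effect_6mer,
                    "noncanonical": config.effect_nc, "background": 0.0}
    effect = np.array([class_effect[c] for c in realized_class])
    effect[idxpum] += config.pumilio_effect
    if config.signature:
        effect[idxnb] += config.nb_effect
        effect[idxneu] += config.neuron_effect
    if nepi:
        epi_t = np.flatnonzero(epid_null)
        effect[epi_t] -= np.array([class_effect[c] for c in realized_class[epi_t]])

    # purely incidental targets carry no simulated site conservation
    incidental_targets = (realized_class != "background") & (conservation == "")
    conservation[incidental_targets] = "poor"

    # ---- imported-style site table for non-canonical sites ----------
    site_rows = [
        {"gene_id": genes[i], "start": int(site_start[i]),
         "end": int(site_start[i]) + 7, "site_type": "noncanonical",
         "score": nc_scores[i]}
        for i in idxnc
    ]
    site_table = pd.DataFrame(site_rows, columns=["gene_id", "start", "end",
                                                  "site_type", "score"])

    # ---- simulated species alignments -------------------------------
    alignments: dict[str, dict[str, str]] = {}
    if config.with_alignments:
        species = SIM_SPECIES[:config.n_species - 1]
        target_set = set(target_idx.tolist())
        identical_sets: dict[int, set[str]] = {}
        for i in sorted(target_set):
            if conservation[i] == "well":
                k = int(rng_aln.integers(5, min(6, len(species)) + 1))
                others = [s for s in species if s != "dpse"]
                pick = rng_aln.choice(len(others), size=k - 1, replace=False)
                identical_sets[i] = {"dpse"} | {others[j] for j in pick}
            else:
                if rng_aln.random() < 0.5 and len(species) > 1:
                    k = int(rng_aln.integers(0, 5))
                    pick = rng_aln.choice(len(species),
                                          size=min(k, len(species)), replace=False)
                    identical_sets[i] = {species[j] for j in pick}
                else:
                    # exactly the 5 non-mandatory species: exercises the
                    # "mandatory member" clause of the conservation rule
                    identical_sets[i] = {s for s in species if s != "dpse"}
        for si, sp in enumerate(species):
            mut_mask = rng_aln.random((n, config.utr_len)) < 0.2
            shift = rng_aln.integers(1, 4, size=(n, config.utr_len), dtype="u1")
            sp_mat = np.where(mut_mask, (utr_mat + shift) % 4, utr_mat)
            for i in sorted(target_set):
                w = 7 if designed_class[i] != "seed6" else 6
                p = site_start[i]
                if sp in identical_sets[i]:
                    sp_mat[i, p:p + w] = utr_mat[i, p:p + w]
                elif np.array_equal(sp_mat[i, p:p + w], utr_mat[i, p:p + w]):
                    mid = p + w // 2
                    sp_mat[i, mid] = (utr_mat[i, mid] + 1) % 4
            for i in range(n):
                alignments.setdefault(genes[i], {"dmel": utrs[genes[i]]})
                alignments[genes[i]][sp] = _decode(sp_mat[i])

    # ---- annotations and signature sets -----------------------------
    tissue_annotations: dict[str, set[str]] = {}
    for term in ("neural", "muscle", "gut"):
        m = rng_annot.random(n) < 0.10
        tissue_annotations[term] = {genes[i] for i in np.flatnonzero(m)}
    if nepi:
        tissue_annotations["epidermis"] = {genes[i] for i in epidermis_idx}
    nb_set = {genes[i] for i in idxnb}
    neuron_set = {genes[i] for i in idxneu}

    # ---- expression --------------------------------------------------
    rng_expr = np.random.default_rng(ss_expr)
    baseline = rng_expr.normal(config.baseline_mean, config.baseline_sd, size=n)
    is_target = realized_class != "background"
    baseline = baseline + config.expr_mean_offset_targets * is_target
    expression, samples = _draw_expression(baseline, effect, config, rng_expr)
    expression.index = pd.Index(genes, name="gene_id")

    truth = pd.DataFrame({
        "planted_class": realized_class,
        "designed_class": designed_class,
        "planted_effect": effect,
        "conservation": conservation,
        "site_start": site_start,
        "pumilio": np.isin(np.arange(n), idxpum),
        "nb": np.isin(np.arange(n), idxnb),
        "neuron": np.isin(np.arange(n), idxneu),
        "epidermis_null": epid_null,
        "baseline": baseline,
        "incidental": incidental,
    }, index=pd.Index(genes, name="gene_id"))

    return SyntheticDataset(
        config=config, expression=expression, samples=samples, utrs=utrs,
        alignments=alignments, site_table=site_table,
        tissue_annotations=tissue_annotations, nb_set=nb_set,
        neuron_set=neuron_set, truth=truth)


def _draw_expression(baseline: np.ndarray, effect: np.ndarray, config: SimConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(baseline)
    r = config.n_replicates
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * r))
    wt = baseline[:, None] + noise[:, :r]
    mut = (baseline + effect)[:, None] + noise[:, r:]
    cols = [f"wt_{j + 1}" for j in range(r)] + [f"mut_{j + 1}" for j in range(r)]
    expression = pd.DataFrame(np.hstack([wt, mut]), columns=cols)
    samples = pd.DataFrame({
        "sample": cols,
        "genotype": ["wildtype"] * r + ["mutant"] * r,
        "replicate": list(range(1, r + 1)) * 2,
    })
    return expression, samples


def resample_expression(dataset: SyntheticDataset, seed: int) -> pd.DataFrame:
    """Fresh replicate noise over the same planted truth (for calibration runs)."""
    truth = dataset.truth
    rng = np.random.default_rng(seed)
    expression, _ = _draw_expression(truth["baseline"].to_numpy(),
                                     truth["planted_effect"].to_numpy(),
                                     dataset.config, rng)
    expression.index = truth.index.copy()
    return expression
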