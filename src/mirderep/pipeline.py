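"""Orchestration of the full derepression analysis.

Stages (each independently skippable): simulate or load inputs -> seed-site
scan + import + conservation -> differential expression and presence calls ->
ECDF/KS shift analyses (class, conservation, absolute levels, signatures) ->
motif regression -> annotation enrichment -> summary counts.  The outcome is
an :class:`AnalysisReport` that serializes to JSON and round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import (ExpressionMatrix, differential_expression,
                      filter_top_upregulated, presence_call)
from .enrich import (enrichment_frame, exclusion_contrast, term_enrichment,
                     updown_gene_sets)
from .errors import ConfigurationError, FormatError
from .motifs import classify_discovered_motifs, reduce_fit
from .shifts import (absolute_expression_shift, partition_target_sets,
                     shift_analysis, shift_results_frame, signature_shift)
from .simulate import SimConfig, generate_dataset, scenario
from .sites import (MIR124, MatureMiRNA, classify_sites_conservation,
                    gene_site_summary, import_site_predictions, scan_utrs,
                    sites_to_frame)
from . import io as mio

logger = logging.getLogger(__name__)

ALL_STAGES = ("scan", "de", "shift", "reduce", "enrich", "counts")


@dataclass
class PipelineConfig:
    """Flat key=value configuration of one pipeline run.

    Either `scenario` (synthetic run) or `input_dir` (load mode, files as
    written by :func:`mirderep.io.write_dataset`) must be set.
    """

    scenario: str = "default"
    input_dir: str = ""
    seed: int = 0
    stages: str = ",".join(ALL_STAGES)
    mirna_name: str = MIR124.name
    mirna_sequence: str = MIR124.sequence
    conservation_rule: str = "methods_5of6"
    de_method: str = "welch"
    fold_min: float = 2.0
    fc_min_linear: float = 1.3
    p_max: float = 0.05
    use_adjusted: bool = False
    motif_width: int = 7
    motif_p_cutoff: float = 0.05
    motif_max_iter: int = 20

    def stage_list(self) -> list[str]:
        stages = [s.strip() for s in self.stages.split(",") if s.strip()]
        if not stages:
            raise ConfigurationError("no stages enabled")
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        return stages

    def to_text(self) -> str:
        return "\n".join(f"{f.name}={getattr(self, f.name)}"
                         for f in dataclasses.fields(self)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
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

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass
class AnalysisReport:
    """JSON-serializable record of one pipeline run."""

    provenance: dict
    blocks: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"provenance": self.provenance, "blocks": self.blocks,
                           "warnings": self.warnings}, indent=indent,
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        obj = json.loads(text)
        return cls(provenance=obj["provenance"], blocks=obj["blocks"],
                   warnings=obj.get("warnings", []))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "AnalysisReport":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _records(df: pd.DataFrame, index_name: str | None = None) -> list[dict]:
    if index_name is not None:
        df = df.reset_index().rename(columns={"index": index_name})
    recs = json.loads(df.to_json(orient="records"))
    return recs


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def _load_inputs(config: PipelineConfig):
    d = config.input_dir
    utr_path = os.path.join(d, "utrs.fasta")
    if not os.path.exists(utr_path):
        raise FileNotFoundError(utr_path)
    utrs = mio.read_fasta(utr_path)
    maf_path = os.path.join(d, "alignments.maf")
    alignments = mio.read_maf(maf_path) if os.path.exists(maf_path) else {}
    expression, samples = mio.read_expression(os.path.join(d, "expression"))
    sites_path = os.path.join(d, "sites.tsv")
    site_table = sites_path if os.path.exists(sites_path) else None
    annot_path = os.path.join(d, "annotations.gmt")
    annotations = mio.read_gmt(annot_path) if os.path.exists(annot_path) else {}
    sig_path = os.path.join(d, "signatures.gmt")
    sigs = mio.read_gmt(sig_path) if os.path.exists(sig_path) else {}
    return (utrs, alignments, expression, samples, site_table,
            annotations, sigs.get("nb", set()), sigs.get("neuron", set()))


def run_pipeline(config: PipelineConfig, dataset=None) -> AnalysisReport:
    """Execute the enabled stages and return the report.

    `dataset` (a :class:`~mirderep.simulate.SyntheticDataset`) may be passed
    directly for programmatic use; otherwise `config.input_dir` is loaded, or
    the named synthetic scenario is generated under `config.seed`.
    """
    stages = config.stage_list()
    collector = _WarningCollector()
    logging.getLogger("mirderep").addHandler(collector)
    try:
        mirna = MatureMiRNA(config.mirna_name, config.mirna_sequence)
        if dataset is None and config.input_dir:
            (utrs, alignments, expression, samples, site_table, annotations,
             nb_set, neuron_set) = _load_inputs(config)
        else:
            if dataset is None:
                dataset = generate_dataset(scenario(config.scenario,
                                                    seed=config.seed))
            utrs = dataset.utrs
            alignments = dataset.alignments
            expression, samples = dataset.expression, dataset.samples
            site_table = dataset.site_table
            annotations = dataset.tissue_annotations
            nb_set, neuron_set = dataset.nb_set, dataset.neuron_set

        offenders = [g for g in expression.index if g not in utrs]
        if offenders:
            raise FormatError(
                "gene ids in expression matrix missing from UTRs "
                f"(first {min(10, len(offenders))}): {offenders[:10]}")

        provenance = {
            "config": config.to_text(),
            "config_sha256": hashlib.sha256(
                config.to_text().encode()).hexdigest(),
            "seed": config.seed,
            "version": __version__,
        }
        report = AnalysisReport(provenance=provenance)

        summary = None
        if "scan" in stages:
            sites = scan_utrs(utrs, mirna)
            if site_table is not None and (
                    not isinstance(site_table, pd.DataFrame) or len(site_table)):
                sites += import_site_predictions(site_table)
            if alignments:
                sites = classify_sites_conservation(sites, alignments,
                                                    config.conservation_rule)
            summary = gene_site_summary(sites)
            report.blocks["sites"] = _records(sites_to_frame(sites))
            report.blocks["gene_summary"] = _records(summary, "gene_id")

        de = presence = None
        matrix = ExpressionMatrix(expression, samples)
        if "de" in stages:
            de = differential_expression(matrix, method=config.de_method)
            presence = presence_call(matrix)
            block = de.join(presence)
            report.blocks["diffexp"] = _records(block, "gene_id")

        universe = None
        if de is not None and presence is not None:
            universe = set(presence.index[presence["present_wt"]
                                          | presence["present_mut"]])

        if "shift" in stages:
            if de is None or summary is None:
                raise ConfigurationError("shift stage requires scan and de stages")
            shift_block = {}
            for strat in ("any_site", "class", "conservation"):
                part = partition_target_sets(summary, universe, strat)
                shift_block[strat] = _records(
                    shift_results_frame(shift_analysis(de, part)))
            part_any = partition_target_sets(summary, universe, "any_site")
            for genotype in ("wildtype", "mutant"):
                res = absolute_expression_shift(matrix, part_any, genotype)
                shift_block[f"absolute_{genotype}"] = _records(
                    shift_results_frame(res))
            if nb_set and neuron_set:
                res = signature_shift(de, nb_set, neuron_set, universe)
                shift_block["signature"] = _records(shift_results_frame(res))
            report.blocks["shifts"] = shift_block

        if "reduce" in stages:
            if de is None:
                raise ConfigurationError("reduce stage requires the de stage")
            model = reduce_fit(de["log2fc"], utrs, w=config.motif_width,
                               p_cutoff=config.motif_p_cutoff,
                               max_iter=config.motif_max_iter)
            annot = classify_discovered_motifs(model, mirna)
            frame = model.to_frame()
            frame["annotation"] = frame["motif"].map(annot)
            report.blocks["motifs"] = _records(frame)

        if "enrich" in stages:
            if de is None or summary is None:
                raise ConfigurationError("enrich stage requires scan and de stages")
            sets = updown_gene_sets(de, fc_min_linear=config.fc_min_linear,
                                    p_max=config.p_max,
                                    use_adjusted=config.use_adjusted)
            enrich_block = {
                "up": _records(enrichment_frame(
                    term_enrichment(sets["up"], annotations, universe))),
                "down": _records(enrichment_frame(
                    term_enrichment(sets["down"], annotations, universe))),
            }
            part_any = partition_target_sets(summary, universe, "any_site")
            contrast = exclusion_contrast(part_any, sets["up"], annotations,
                                          universe)
            enrich_block["contrast"] = {
                k: _records(enrichment_frame(v)) for k, v in contrast.items()}
            report.blocks["enrichment"] = enrich_block

        if "counts" in stages:
            if de is None or summary is None or presence is None:
                raise ConfigurationError("counts stage requires scan and de stages")
            report.blocks["counts"] = headline_counts(
                de, summary, presence, fold_min=config.fold_min,
                p_max=config.p_max, use_adjusted=config.use_adjusted)

        report.warnings = list(collector.messages)
        return report
    finally:
        logging.getLogger("mirderep").removeHandler(collector)


def headline_counts(de: pd.DataFrame, summary: pd.DataFrame,
                    presence: pd.DataFrame, fold_min: float = 2.0,
                    p_max: float = 0.05, use_adjusted: bool = True) -> dict:
    """Headline counts: top-deregulated genes, sites, presence transitions.

    Returns the number of genes upregulated more than `fold_min`-fold at
    p < `p_max`; how many of those bear a seed site; the number of site-bearing
    genes assessed; the site-bearing genes absent in wildtype but present in
    the mutant; and how many of those carry a well-conserved site.
    """
    if presence is None or not {"present_wt", "present_mut"} <= set(presence.columns):
        raise ValueError("presence calls are required")
    top = filter_top_upregulated(de, fold_min=fold_min, p_max=p_max,
                                 use_adjusted=use_adjusted)
    target_genes = set(summary.index)
    assessed = target_genes & set(de.index)
    trans = presence.loc[presence.index.isin(target_genes)
                         & presence["present_mut"] & ~presence["present_wt"]]
    conserved_trans = [g for g in trans.index
                       if summary.loc[g, "conservation"] == "well"]
    return {
        "n_top_up": int(len(top)),
        "n_top_up_with_site": int(len(set(top.index) & target_genes)),
        "n_targets_assessed": int(len(assessed)),
        "n_absent_wt_present_mut": int(len(trans)),
        "n_thereof_conserved": int(len(conserved_trans)),
    }
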