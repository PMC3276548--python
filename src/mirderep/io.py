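"""Readers and writers for the package's file formats.

UTRs: FASTA (Biopython).  Alignments: MAF with ``species.gene`` source names
(Biopython), projected onto reference coordinates on read.  Expression:
TSV (first column gene id, header sample ids) with a sidecar sample-metadata
TSV.  Gene sets and annotations: GMT.  Site tables and result tables: TSV;
site tables declare their coordinate convention in a ``#coords=`` header.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .sites import REFERENCE_SPECIES

COORDS_HEADER = "#coords=0based-halfopen"


# ---------------------------------------------------------------- FASTA
def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ------------------------------------------------------------------ MAF
def write_maf(alignments: Mapping[str, Mapping[str, str]], path: str) -> None:
    """One MAF block per gene; rows named ``species.gene``; reference first."""
    blocks = []
    for gene, rows in alignments.items():
        order = [REFERENCE_SPECIES] + sorted(sp for sp in rows
                                             if sp != REFERENCE_SPECIES)
        records = []
        for sp in order:
            seq = rows[sp]
            size = len(seq.replace("-", ""))
            rec = SeqRecord(Seq(seq), id=f"{sp}.{gene}")
            rec.annotations.update({"start": 0, "size": size, "strand": 1,
                                    "srcSize": size})
            records.append(rec)
        blocks.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(blocks, fh, "maf")


def read_maf(path: str) -> dict[str, dict[str, str]]:
    """Read MAF blocks and project every row onto reference coordinates.

    Columns where the reference row carries a gap are dropped, so returned
    rows all have the reference's ungapped length ('-' marks deletions in the
    other species).
    """
    out: dict[str, dict[str, str]] = {}
    for block in AlignIO.parse(path, "maf"):
        rows = {}
        gene = None
        for rec in block:
            if "." not in rec.id:
                raise FormatError(f"MAF source {rec.id!r} is not species.gene")
            sp, g = rec.id.split(".", 1)
            gene = gene or g
            rows[sp] = str(rec.seq).upper()
        if gene is None:
            continue
        ref = rows.get(REFERENCE_SPECIES)
        if ref is None:
            raise FormatError(f"MAF block for {gene!r} lacks the reference row")
        keep = [i for i, ch in enumerate(ref) if ch != "-"]
        out[gene] = {sp: "".join(seq[i] for i in keep) for sp, seq in rows.items()}
    return out


# ------------------------------------------------------- expression TSV
def write_expression(expression: pd.DataFrame, samples: pd.DataFrame,
                     prefix: str) -> None:
    expression.to_csv(f"{prefix}.tsv", sep="\t")
    samples.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_expression(prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    expr_path, meta_path = f"{prefix}.tsv", f"{prefix}.samples.tsv"
    for p in (expr_path, meta_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    expression = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(meta_path, sep="\t")
    required = {"sample", "genotype", "replicate"}
    if not required <= set(samples.columns):
        raise FormatError(f"sample sheet lacks columns {sorted(required)}")
    return expression, samples


# ------------------------------------------------------------------ GMT
def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gmt(path: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"bad GMT line in {path}: {line!r}")
            out[parts[0]] = set(parts[2:])
    return out


# ----------------------------------------------------------- site table
def write_site_table(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(COORDS_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------- whole dataset
def write_dataset(dataset, outdir: str) -> None:
    """Serialize a synthetic dataset as plain-text files under `outdir`."""
    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    write_fasta(dataset.utrs, j("utrs.fasta"))
    if dataset.alignments:
        write_maf(dataset.alignments, j("alignments.maf"))
    write_expression(dataset.expression, dataset.samples, j("expression"))
    write_gmt(dataset.tissue_annotations, j("annotations.gmt"))
    write_gmt({"nb": dataset.nb_set, "neuron": dataset.neuron_set},
              j("signatures.gmt"))
    write_site_table(dataset.site_table, j("sites.tsv"))
    dataset.truth.to_csv(j("truth.tsv"), sep="\t")
    with open(j("config.txt"), "w") as fh:
        fh.write(dataset.config.to_text())


def read_truth(path: str) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0,
                        keep_default_na=False,
                        dtype={"incidental": str, "conservation": str})
    for col in ("planted_effect", "baseline"):
        truth[col] = truth[col].astype(float)
    for col in ("pumilio", "nb", "neuron", "epidermis_null"):
        truth[col] = truth[col].astype(str).str.lower() == "true"
    truth["site_start"] = truth["site_start"].astype(int)
    return truth
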