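"""Readers/writers for the pipeline's external formats.

All tabular files are tab-separated UTF-8 with '#' comment lines ignored;
missing values are errors, not sentinels. Column layouts are documented in
FORMATS.md at the repository root. Promoter coordinates are 1-based
inclusive; the upstream axis runs -L..-1 relative to the transcription
start (helpers below convert).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .deg import DEResultRow
from .grn import LayeredNetwork, summarize_network
from .synthetic import ExpressionMatrix, PromoterSet, SampleInfo
from .verification import VerificationRecord

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FormatError", "read_expression", "write_expression",
           "read_annotation", "write_annotation", "read_de_table",
           "write_de_table", "write_network", "read_verification_table",
           "write_verification_table", "write_promoters", "read_promoters",
           "write_truth", "upstream_to_sequence_pos", "sequence_to_upstream_pos"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    """Thresholds and run parameters for the whole pipeline."""

    cc_min: float = 0.8
    cc_p_max: float = 0.001
    pcc_max: float = 0.3
    deg_fdr_max: float = 0.05
    deg_min_fold: float = 2.0
    reg_min_fold: float = 2.0
    reg_p_max: float = 0.05
    root_tf: str = ""
    n_fragments: int = 4
    region_length: int = 2000
    strands: str = "both"
    pcc_formula: str = "standard"
    signed_cc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cc_min <= 1):
            raise ValueError("cc_min must be in (0, 1]")
        if not (0 < self.pcc_max < 1):
            raise ValueError("pcc_max must be in (0, 1)")
        if self.deg_min_fold < 1:
            raise ValueError("deg_min_fold must be >= 1")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if self.strands not in ("forward", "both"):
            raise ValueError("strands must be 'forward' or 'both'")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2)
                              + "\n")


# --------------------------------------------------------------------------
# coordinate helpers (upstream axis -L..-1 <-> 1-based sequence position)

def upstream_to_sequence_pos(upstream: int, region_length: int) -> int:
    if not (-region_length <= upstream <= -1):
        raise ValueError(f"upstream position {upstream} outside -{region_length}..-1")
    return upstream + region_length + 1


def sequence_to_upstream_pos(pos: int, region_length: int) -> int:
    if not (1 <= pos <= region_length):
        raise ValueError(f"sequence position {pos} outside 1..{region_length}")
    return pos - region_length - 1


# --------------------------------------------------------------------------
# TSV readers/writers

def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip", **kwargs)


def read_expression(path) -> ExpressionMatrix:
    """Expression TSV: first column gene id, headers genotype_condition_rep."""
    df = _read_tsv(path, index_col=0)
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate gene id(s): {sorted(set(dup))}")
    for col in df.columns:
        bad = df[col].apply(lambda v: not isinstance(v, (int, float)) or pd.isna(v))
        if bad.any():
            row = df.index[bad.argmax()]
            raise FormatError(f"non-numeric or missing cell at gene {row!r}, "
                              f"sample {col!r}")
    samples = []
    for col in df.columns:
        parts = str(col).rsplit("_", 2)
        if len(parts) != 3:
            raise FormatError(f"sample header {col!r} not genotype_condition_rep")
        genotype, condition, rep = parts
        try:
            rep_i = int(rep)
        except ValueError as exc:
            raise FormatError(f"replicate in header {col!r} not an integer") from exc
        samples.append(SampleInfo(str(col), genotype, condition, rep_i))
    return ExpressionMatrix(values=df.to_numpy(dtype=float),
                            genes=[str(g) for g in df.index], samples=samples)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene",
                           float_format="%.17g")


def read_annotation(path) -> dict[str, str]:
    """Two-column TSV gene id -> class in {TF, structural}."""
    try:
        df = _read_tsv(path, header=None, names=["gene", "class"])
    except pd.errors.EmptyDataError:
        logger.warning("empty annotation file %s", path)
        return {}
    if df.empty:
        logger.warning("empty annotation file %s", path)
        return {}
    bad = sorted(set(df["class"]) - {"TF", "structural"})
    if bad:
        raise FormatError(f"unknown gene class label(s): {bad}")
    return dict(zip(df["gene"].astype(str), df["class"]))


def write_annotation(annotation: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, cls in annotation.items():
            fh.write(f"{gene}\t{cls}\n")


def read_de_table(path) -> list[DEResultRow]:
    """DE result TSV with columns gene, log2fc, pvalue, fdr."""
    df = _read_tsv(path)
    required = {"gene", "log2fc", "pvalue", "fdr"}
    if not required <= set(df.columns):
        raise FormatError(f"DE table must have columns {sorted(required)}")
    return [DEResultRow(str(r.gene), float(r.log2fc), float(r.pvalue),
                        float(r.fdr)) for r in df.itertuples()]


def write_de_table(rows, path) -> None:
    pd.DataFrame({"gene": [r.gene for r in rows],
                  "log2fc": [r.log2_fold_change for r in rows],
                  "pvalue": [r.p_value for r in rows],
                  "fdr": [r.fdr for r in rows]}).to_csv(
                      path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# network

def write_network(net: LayeredNetwork, edge_path, summary_path,
                  orphan_path=None) -> dict:
    """Edge-list TSV + JSON summary (and optionally an orphan-edge TSV)."""
    rows = [{"regulator": e.regulator, "target": e.target,
             "regulator_layer": net.layers[e.regulator],
             "target_layer": net.layers[e.target],
             "min_pcc": e.min_pcc} for e in net.edges]
    pd.DataFrame(rows, columns=["regulator", "target", "regulator_layer",
                                "target_layer", "min_pcc"]
                 ).to_csv(edge_path, sep="\t", index=False)
    summary = summarize_network(net)
    Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
    if orphan_path is not None:
        orows = [{"regulator": e.regulator, "target": e.target,
                  "regulator_layer": net.layers.get(e.regulator, ""),
                  "target_layer": net.layers.get(e.target, ""),
                  "min_pcc": e.min_pcc} for e in net.orphan_edges]
        pd.DataFrame(orows, columns=["regulator", "target", "regulator_layer",
                                     "target_layer", "min_pcc"]
                     ).to_csv(orphan_path, sep="\t", index=False)
    return summary


def write_truth(net, edge_path, sidecar_path) -> None:
    """Planted network as a two-column edge TSV + JSON layer sidecar."""
    pd.DataFrame(sorted(net.edges), columns=["regulator", "target"]
                 ).to_csv(edge_path, sep="\t", index=False)
    sidecar = {"root_tf": net.root_tf, "layer2": list(net.layer2),
               "layer3": list(net.layer3), "layer4": list(net.layer4),
               "seed": net.seed}
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


# --------------------------------------------------------------------------
# verification tables

def read_verification_table(path) -> list[VerificationRecord]:
    df = _read_tsv(path)
    required = {"regulator", "target", "layer_pair", "chip_fragments",
                "qpcr_fold", "qpcr_p"}
    if not required <= set(df.columns):
        raise FormatError(f"verification table needs columns {sorted(required)}")
    records = []
    for r in df.itertuples():
        raw = str(r.chip_fragments)
        frags = (frozenset() if raw in ("-", "", "nan")
                 else frozenset(int(x) for x in raw.split(",")))
        records.append(VerificationRecord(
            regulator=str(r.regulator), target=str(r.target),
            layer_pair=str(r.layer_pair), chip_positive_fragments=frags,
            qpcr_fold=float(r.qpcr_fold), qpcr_p=float(r.qpcr_p)))
    return records


def write_verification_table(records, path) -> None:
    rows = [{"regulator": r.regulator, "target": r.target,
             "layer_pair": r.layer_pair,
             "chip_fragments": (",".join(str(i) for i in
                                         sorted(r.chip_positive_fragments))
                                or "-"),
             "qpcr_fold": r.qpcr_fold, "qpcr_p": r.qpcr_p}
            for r in records]
    pd.DataFrame(rows, columns=["regulator", "target", "layer_pair",
                                "chip_fragments", "qpcr_fold", "qpcr_p"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# promoters

def write_promoters(promoters: PromoterSet, path) -> None:
    """FASTA with the insertion log in the description as key=value pairs."""
    records = []
    for gene, seq in promoters.sequences.items():
        planted = ";".join(f"{p.element_id}:{p.strand}:{p.start}"
                           for p in promoters.planted.get(gene, []))
        desc = f"planted={planted or '-'} gc={promoters.gc} seed={promoters.seed}"
        records.append(SeqRecord(Seq(seq), id=gene, description=desc))
    SeqIO.write(records, path, "fasta")


def read_promoters(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(path, "fasta")}
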