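"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open on the plus strand;
conversions to and from 1-based (GFF3) or half-open (BED) happen only
here, at the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_VALID_STRANDS = {"+", "-"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """One contig: an uppercase A/C/G/T string (N allowed only in mask mode)."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A gene with its CDS interval (0-based half-open) and optional TSS."""

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.cds_start < self.cds_end:
            raise FormatError(
                f"gene {self.gene_id!r}: cds_start must be < cds_end "
                f"({self.cds_start} >= {self.cds_end})"
            )


@dataclass
class ExpressionTable:
    """Measured fold changes per unit (gene, TU or construct).

    ``df`` has columns unit_id, fold_change and optionally se plus the
    replicate columns it was aggregated from.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"unit_id", "fold_change"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"expression table missing columns: {sorted(missing)}")
        bad = self.df[self.df["fold_change"] <= 0]
        if len(bad):
            rows = ", ".join(map(str, bad["unit_id"].tolist()[:5]))
            raise FormatError(f"non-positive fold change for unit(s): {rows}")

    def fold_changes(self) -> dict[str, float]:
        return dict(zip(self.df["unit_id"], self.df["fold_change"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class TranscriptionalUnitTable:
    """Ordered gene membership of each transcriptional unit."""

    units: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for tu_id, genes in self.units.items():
            for g in genes:
                if g in seen:
                    raise FormatError(
                        f"gene {g!r} belongs to both TU {seen[g]!r} and {tu_id!r}"
                    )
                seen[g] = tu_id

    def tu_of(self, gene_id: str) -> str | None:
        for tu_id, genes in self.units.items():
            if gene_id in genes:
                return tu_id
        return None


def read_fasta(path: str | os.PathLike, ambiguous: str = "strict",
               circular: bool = False) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    ``ambiguous`` is ``"strict"`` (non-ACGT characters raise) or
    ``"mask"`` (they become N, which never matches a motif base).
    """
    if ambiguous not in ("strict", "mask"):
        raise ValueError(f"ambiguous must be 'strict' or 'mask', got {ambiguous!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGT")
        if bad:
            if ambiguous == "strict":
                raise FormatError(
                    f"{path}: record {rec.id!r} has non-ACGT characters "
                    f"{sorted(bad)} (use ambiguous='mask' to N-mask)"
                )
            seq = "".join(c if c in "ACGT" else "N" for c in seq)
        records.append(GenomeSequence(rec.id, seq, circular=circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[GenomeSequence], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _annotation_from_gff_feature(feat) -> GeneAnnotation:
    if feat.strand not in _VALID_STRANDS:
        raise FormatError(f"{feat.id}: unknown strand {feat.strand!r}")
    tss = None
    if "tss" in feat.attributes:
        # tss attribute is 1-based like all GFF3 coordinates
        tss = int(feat.attributes["tss"][0]) - 1
    gene_id = feat.attributes.get("ID", [feat.id])[0]
    return GeneAnnotation(
        gene_id=gene_id,
        contig_id=feat.seqid,
        strand=feat.strand,
        cds_start=feat.start - 1,  # GFF3 is 1-based inclusive
        cds_end=feat.end,
        tss=tss,
    )


def read_annotations(path: str | os.PathLike, format: str = "gff3") -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED6 into internal coordinates."""
    if format == "gff3":
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
        feats = list(db.features_of_type("gene"))
        if not feats:
            feats = list(db.features_of_type("CDS"))
        return [_annotation_from_gff_feature(f) for f in feats]
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["contig", "start", "end", "name", "score", "strand"],
                         dtype={"contig": str, "name": str})
        out = []
        for row in df.itertuples(index=False):
            if row.strand not in _VALID_STRANDS:
                raise FormatError(f"{path}: BED strand {row.strand!r} for {row.name!r}")
            out.append(GeneAnnotation(row.name, row.contig, row.strand,
                                      int(row.start), int(row.end)))
        return out
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotations_gff3(annotations: list[GeneAnnotation],
                           path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id}"
            if a.tss is not None:
                attrs += f";tss={a.tss + 1}"
            fh.write("\t".join([
                a.contig_id, "operscan", "gene",
                str(a.cds_start + 1), str(a.cds_end), ".", a.strand, ".", attrs,
            ]) + "\n")


def read_expression_table(path: str | os.PathLike, unit_col: str = "unit_id",
                          fc_col: str = "fold_change",
                          replicate_prefix: str = "rep") -> ExpressionTable:
    """Read a TSV of fold changes.

    If replicate columns (``rep1``, ``rep2``, ...) are present and the
    fold-change column is absent, the fold change is their arithmetic
    mean and the standard error of that mean is reported.
    """
    df = pd.read_csv(path, sep="\t")
    if unit_col not in df.columns:
        raise FormatError(f"{path}: missing unit column {unit_col!r}")
    rep_cols = [c for c in df.columns if c.startswith(replicate_prefix)
                and c[len(replicate_prefix):].isdigit()]
    out = pd.DataFrame({"unit_id": df[unit_col].astype(str)})
    if rep_cols:
        reps = df[rep_cols].to_numpy(dtype=float)
        if (reps <= 0).any():
            raise FormatError(f"{path}: non-positive replicate value")
        out["fold_change"] = reps.mean(axis=1)
        out["se"] = reps.std(axis=1, ddof=1) / np.sqrt(reps.shape[1])
        for c in rep_cols:
            out[c] = df[c]
    elif fc_col in df.columns:
        out["fold_change"] = df[fc_col].astype(float)
        if "se" in df.columns:
            out["se"] = df["se"].astype(float)
    else:
        raise FormatError(f"{path}: no {fc_col!r} or replicate columns found")
    return ExpressionTable(out)


def write_expression_table(table: ExpressionTable, path: str | os.PathLike) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_tu_table(path: str | os.PathLike) -> TranscriptionalUnitTable:
    """Read a two-column TSV (tu_id, gene_id); gene order within a TU is file order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tu_id", "gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: TU table needs columns tu_id, gene_id")
    units: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        units.setdefault(row.tu_id, []).append(row.gene_id)
    return TranscriptionalUnitTable(units)


def write_tu_table(table: TranscriptionalUnitTable, path: str | os.PathLike) -> None:
    rows = [(tu, g) for tu, genes in table.units.items() for g in genes]
    pd.DataFrame(rows, columns=["tu_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_regulon(path: str | os.PathLike) -> set[str]:
    """Read a regulon gene list: one unit_id per line, '#' comments allowed."""
    with open(path) as fh:
        return {ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")}


def write_hits_bed(hits, path: str | os.PathLike) -> None:
    """Write operator hits as BED6 covering the full operator interval."""
    with open(path, "w") as fh:
        for h in hits:
            name = f"mm{h.mismatch_up}+{h.mismatch_down}_sp{h.spacer_length}"
            score = h.mismatch_up + h.mismatch_down
            fh.write(f"{h.contig_id}\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}\n")


def write_hits_tsv(hits, path: str | os.PathLike) -> None:
    rows = [
        (h.contig_id, h.start, h.end, h.strand, h.upstream_seq, h.spacer_seq,
         h.downstream_seq, h.mismatch_up, h.mismatch_down, h.spacer_length)
        for h in hits
    ]
    pd.DataFrame(rows, columns=[
        "contig_id", "start", "end", "strand", "upstream_seq", "spacer_seq",
        "downstream_seq", "mismatch_up", "mismatch_down", "spacer_length",
    ]).to_csv(path, sep="\t", index=False)


def write_motif(pwm, path: str | os.PathLike, name: str = "motif") -> None:
    """Write a PWM as a MEME-minimal letter-probability motif file."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, pwm.background)) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} "
                 f"nsites= {pwm.source_count} E= 0\n")
        for row in pwm.probabilities:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")


def read_motif(path: str | os.PathLike):
    """Read a MEME-minimal letter-probability motif file into a PWM.

    Parsed directly (not via Bio.motifs) so probabilities survive the
    round trip to 6 decimals instead of being quantized into counts.
    """
    from .matrices import PositionWeightMatrix

    background = np.full(4, 0.25)
    nsites = 0
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        line = line.strip()
        if line.startswith("Background letter frequencies"):
            toks = next(lines).split()
            freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in BASES])
        elif line.startswith("letter-probability matrix"):
            toks = line.replace("=", " = ").split()
            kv = {toks[i]: toks[i + 2] for i in range(len(toks) - 2)
                  if toks[i + 1] == "="}
            width = int(kv["w"])
            nsites = int(float(kv.get("nsites", 20)))
            for _ in range(width):
                rows.append([float(x) for x in next(lines).split()])
    if width is None:
        raise FormatError(f"{path}: no letter-probability matrix found")
    probs = np.array(rows)
    if probs.shape != (width, 4):
        raise FormatError(f"{path}: matrix shape {probs.shape}, expected ({width}, 4)")
    sums = probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise FormatError(
            f"{path}: probability rows must sum to 1 (got {sums.min():.4f}"
            f"..{sums.max():.4f})"
        )
    return PositionWeightMatrix(probabilities=probs, background=background,
                                pseudocount=0.0, source_count=nsites)
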