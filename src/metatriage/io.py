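"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (contigs), BLAST tabular TSV (hits), TSV (counts, lengths,
self-scores, taxonomy lineages, operon reference), GFF3 (ORF calls) and
JSON/TSV reports. Files ending in ``.gz`` are read and written through
transparent gzip. All readers validate the invariants of the target
container and raise :class:`~metatriage.core.FormatError` with the
offending line where possible.
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO

from .core import (
    CONTROL,
    TREATMENT,
    ContigSet,
    CountMatrix,
    FormatError,
    HitRecord,
    Lineage,
    OperonReference,
    SelfScoreTable,
    TaxonomyTable,
)

#: Standard 12 columns of BLAST tabular output (outfmt 6); optional
#: columns 13-14 are subject taxon key and subject description.
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def _open(path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> ContigSet:
    """Read contigs; id = first whitespace token of the header, sequence
    uppercased. Duplicate ids and empty sequences are hard errors."""
    seqs: dict[str, str] = {}
    with _open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            cid = record.id
            if cid in seqs:
                raise FormatError(f"duplicate id {cid}")
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for contig {cid}")
            seqs[cid] = seq
    return ContigSet(seqs)


def write_fasta(contigs: ContigSet, path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for cid, seq in contigs.sequences.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular hits

def read_hits(path, db_tier: int) -> list[HitRecord]:
    """Parse a BLAST outfmt-6-like TSV into :class:`HitRecord` rows.

    Columns beyond 14 are ignored; missing columns 13-14 default to taxon
    ``unclassified`` and an empty description.
    """
    hits: list[HitRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
                pident = float(fields[2])
                alen = int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})")
            taxon = fields[12].strip() if len(fields) > 12 and fields[12].strip() else "unclassified"
            desc = fields[13] if len(fields) > 13 else ""
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=pident,
                    align_len=alen,
                    evalue=evalue,
                    bitscore=bitscore,
                    subject_description=desc,
                    subject_taxon=taxon,
                    db_tier=db_tier,
                )
            )
    return hits


def write_hits(hits: Iterable[HitRecord], path) -> None:
    """Write hits as 14-column BLAST tabular (qstart/qend etc. synthesised
    from the alignment length, since only the triage-relevant fields are
    carried internally)."""
    with _open(path, "wt") as fh:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.align_len),
                "0",
                "0",
                "1",
                str(h.align_len),
                "1",
                str(h.align_len),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
                h.subject_taxon,
                h.subject_description,
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Counts / lengths / self-scores

def read_counts(path) -> CountMatrix:
    """Read a counts TSV whose header is ``contig<TAB>sample...`` and whose
    second header line ``#condition`` maps samples to control/treatment.

    A header line ``#condition<TAB>control<TAB>treatment...`` directly below
    the column header carries the condition labels; without it samples whose
    name contains ``ctrl``/``control`` are control, the rest treatment.
    """
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError("counts file needs a contig column and >= 1 sample")
        samples = header[1:]
        pos = fh.tell()
        second = fh.readline()
        conditions: dict[str, str] = {}
        if second.startswith("#condition"):
            labels = second.rstrip("\n").split("\t")[1:]
            if len(labels) != len(samples):
                raise FormatError("#condition line length mismatch")
            conditions = dict(zip(samples, labels))
        else:
            fh.seek(pos)
            for s in samples:
                low = s.lower()
                conditions[s] = CONTROL if ("ctrl" in low or "control" in low) else TREATMENT
        rows = {}
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(samples) + 1:
                raise FormatError(f"{path}:{lineno}: column count mismatch")
            try:
                vals = [int(v) for v in fields[1:]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer count")
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative count")
            rows[fields[0]] = vals
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CountMatrix(counts, conditions)


def write_counts(matrix: CountMatrix, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("contig\t" + "\t".join(matrix.sample_ids) + "\n")
        fh.write(
            "#condition\t"
            + "\t".join(matrix.conditions[s] for s in matrix.sample_ids)
            + "\n"
        )
        for cid, row in matrix.counts.iterrows():
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _read_two_column(path, value_name: str, cast) -> dict:
    out = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("contig", "id", "contig_id"):
                continue
            try:
                out[fields[0]] = cast(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric {value_name}")
    return out


def read_lengths(path) -> dict[str, float]:
    """Effective contig lengths (nucleotides); must all be positive."""
    lengths = _read_two_column(path, "length", float)
    for cid, v in lengths.items():
        if v <= 0:
            raise FormatError(f"non-positive length for {cid}")
    return lengths


def write_lengths(lengths: dict[str, float], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("contig\teffective_length\n")
        for cid, v in lengths.items():
            fh.write(f"{cid}\t{v:g}\n")


def read_self_scores(path) -> SelfScoreTable:
    """Per-contig self-alignment bitscores; must all be positive."""
    scores = _read_two_column(path, "self score", float)
    for cid, v in scores.items():
        if v <= 0:
            raise FormatError(f"non-positive self score for {cid}")
    return scores


def write_self_scores(scores: SelfScoreTable, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("contig\tmax_bitscore\n")
        for cid, v in scores.items():
            fh.write(f"{cid}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Taxonomy / operons

def read_taxonomy(path) -> TaxonomyTable:
    """Taxon key -> lineage, with lineages serialized ``rank:name;...``."""
    table: TaxonomyTable = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("taxon", "taxon_key", "key"):
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                table[fields[0]] = Lineage.parse(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad lineage ({exc})")
    return table


def write_taxonomy(table: TaxonomyTable, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("taxon_key\tlineage\n")
        for key, lineage in table.items():
            fh.write(f"{key}\t{lineage}\n")


def read_operon_reference(path) -> OperonReference:
    """Operon reference TSV: operon_id <TAB> dash-joined gene symbols."""
    operons = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("operon", "operon_id"):
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            genes = tuple(g for g in fields[1].split("-") if g)
            if len(genes) < 2:
                raise FormatError(f"{path}:{lineno}: operon needs >= 2 genes")
            operons[fields[0]] = genes
    return OperonReference(operons)


def write_operon_reference(ref: OperonReference, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("operon_id\tgenes\n")
        for oid, genes in ref.items():
            fh.write(f"{oid}\t{'-'.join(genes)}\n")


# ---------------------------------------------------------------------------
# GFF3 / reports

def write_gff3(orf_calls, path) -> None:
    """Write ORF calls as GFF3 CDS features (1-based, inclusive)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for orf in orf_calls:
            attrs = f"ID={orf.contig_id}.orf.{orf.start}-{orf.end}"
            if orf.gene_symbol:
                attrs += f";gene={orf.gene_symbol}"
            attrs += f";partial5={str(orf.partial5).lower()};partial3={str(orf.partial3).lower()}"
            fh.write(
                "\t".join(
                    [
                        orf.contig_id,
                        "metatriage",
                        "CDS",
                        str(orf.start + 1),  # 0-based half-open -> 1-based incl.
                        str(orf.end),
                        "." if orf.coding_score is None else f"{orf.coding_score:.3f}",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_report(report, path, format: str = "tsv") -> None:
    """Serialize a report (DataFrame or JSON-serialisable mapping)."""
    if format == "json":
        with _open(path, "wt") as fh:
            if isinstance(report, pd.DataFrame):
                fh.write(report.to_json(orient="split", indent=2))
            else:
                json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(report, pd.DataFrame):
            report.to_csv(path, sep="\t", index=True)
        else:
            with _open(path, "wt") as fh:
                for key, value in report.items():
                    fh.write(f"{key}\t{value}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
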