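"""Readers and writers for the external formats the pipeline consumes.

Formats: BED3+ (tab-separated, 0-based half-open), bedGraph, JASPAR PFM text,
variant TSV / VCF 4.x (DAF from an INFO key), tabular BLAST (outfmt 6), FASTA,
and TSV tables with headers. All 1-based inputs are converted to the package's
0-based half-open convention here and only here.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ElementSet,
    GenomicInterval,
    HomologyHit,
    ParseError,
    PositionWeightMatrix,
    TrackRecord,
    ValidationError,
    VariantTable,
)

_BED_ATTR_NAMES = ("name", "score", "strand")


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted :class:`GenomicInterval` records.

    Columns beyond the third are preserved as attributes (``name``, ``score``,
    ``strand``, then ``field7``, ``field8``, ...).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "."
            attrs = {}
            for i, val in enumerate(fields[3:]):
                key = _BED_ATTR_NAMES[i] if i < len(_BED_ATTR_NAMES) else f"field{i + 4}"
                if key == "strand" and val in ("+", "-", "."):
                    strand = val
                else:
                    attrs[key] = val
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, attrs))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            extra = [str(v) for v in iv.attributes.values()]
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra or iv.strand != ".":
                cols.append(str(iv.attributes.get("name", ".")))
                cols.append(str(iv.attributes.get("score", "0")))
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> list[TrackRecord]:
    """Read a bedGraph file; records are sorted and must not overlap."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph line has <4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            try:
                records.append(TrackRecord(GenomicInterval(fields[0], start, end), value))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    for prev, cur in zip(records, records[1:]):
        if prev.interval.chrom == cur.interval.chrom and cur.interval.start < prev.interval.end:
            raise ValidationError(
                f"{path}: overlapping bedGraph records at "
                f"{cur.interval.chrom}:{cur.interval.start}"
            )
    return records


def write_bedgraph(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.value:.6g}\n")


def read_pfm(path) -> list[PositionWeightMatrix]:
    """Read JASPAR PFM text (">ID NAME" headers, four A/C/G/T count rows).

    Both the bracketed JASPAR dialect (``A [ 3 10 ... ]``) and plain
    whitespace-separated count rows are accepted. Counts are column-normalized
    to frequencies.
    """
    pwms = []
    header = None
    rows: list[list[float]] = []
    row_order: list[str] = []

    def _flush(lineno):
        nonlocal header, rows, row_order
        if header is None:
            return
        if len(rows) != 4:
            raise ParseError(
                f"{path}:{lineno}: motif {header[0]} has {len(rows)} nucleotide rows, expected 4"
            )
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(f"{path}:{lineno}: motif {header[0]} has rows of unequal length")
        order = row_order if all(row_order) else ["A", "C", "G", "T"]
        counts = np.zeros((len(rows[0]), 4))
        for base, row in zip(order, rows):
            counts[:, "ACGT".index(base)] = row
        if (counts < 0).any():
            raise ValidationError(f"{path}: motif {header[0]} has negative counts")
        colsums = counts.sum(axis=1)
        if (colsums <= 0).any():
            raise ValidationError(f"{path}: motif {header[0]} has an all-zero position")
        pwms.append(PositionWeightMatrix(header[0], header[1], counts / colsums[:, None]))
        header, rows, row_order = None, [], []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
                continue
            if header is None:
                raise ParseError(f"{path}:{lineno}: counts before any '>' header")
            base = ""
            body = line
            if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
                base = line[0].upper()
                body = line[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(x) for x in body.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric PFM counts") from exc
            row_order.append(base)
        _flush(lineno)
    return pwms


def write_pfm(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.name}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in pwm.freqs[:, i])
                fh.write(f"{base} [ {vals} ]\n")


def read_variants(path, daf_info_key: str = "DAF") -> VariantTable:
    """Read variants with DAFs from a TSV (chrom, pos, daf; pos 1-based) or VCF.

    VCF records lacking the DAF INFO key are skipped with a warning. Positions
    are converted to the package's 0-based convention.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, daf_info_key)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("chrom", "pos", "daf"):
        if needed not in cols:
            raise ParseError(f"{path}: variant TSV lacks column {needed!r}")
    out = pd.DataFrame(
        {
            "chrom": df[cols["chrom"]].astype(str),
            "pos": df[cols["pos"]].astype(int) - 1,
            "daf": df[cols["daf"]].astype(float),
        }
    )
    return VariantTable(out)


def _read_vcf(path, daf_info_key: str) -> VariantTable:
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if daf_info_key not in rec.info:
                skipped += 1
                continue
            val = rec.info[daf_info_key]
            if isinstance(val, tuple):
                val = val[0]
            rows.append((rec.chrom, rec.pos - 1, float(val)))
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} VCF records lacking INFO/{daf_info_key}",
            RuntimeWarning,
            stacklevel=2,
        )
    return VariantTable(pd.DataFrame(rows, columns=["chrom", "pos", "daf"]))


def write_variants(table: VariantTable, path) -> None:
    """Write a variant table as TSV with 1-based positions."""
    out = table.df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_element_set(path) -> ElementSet:
    return ElementSet.from_intervals(read_bed(path))


def write_element_set(elements: ElementSet, path) -> None:
    """Write an ElementSet as BED with attribute columns appended after strand."""
    df = elements.df
    extra = [c for c in df.columns if c not in ("chrom", "start", "end", "strand")]
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            cols = [row.chrom, str(row.start), str(row.end)]
            if extra or row.strand != ".":
                name = str(getattr(row, "id", ".")) if "id" in extra else "."
                cols += [name, "0", row.strand]
                cols += [str(getattr(row, c)) for c in extra if c != "id"]
            fh.write("\t".join(cols) + "\n")


def read_mark_matrix(path):
    """Read an element x species presence TSV (first column element ids)."""
    from .core import MarkMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return MarkMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy().astype(bool),
    )


def write_mark_matrix(marks, path) -> None:
    pd.DataFrame(
        marks.present.astype(int), index=marks.element_ids, columns=marks.species
    ).to_csv(path, sep="\t", index_label="element_id")


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_expression(path) -> pd.DataFrame:
    """Genes x tissues expression TSV (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return df


def read_homology_hits(path, query_lengths: dict[str, int]) -> list[HomologyHit]:
    """Read 12-column tabular BLAST hits (outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore. Query coverage (percent) is computed from the
    1-based inclusive qstart/qend span and the supplied query length table.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 outfmt-6 columns")
            qid, sid = fields[0], fields[1]
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed outfmt-6 fields") from exc
            if qid not in query_lengths:
                raise ValidationError(f"{path}:{lineno}: unknown query id {qid!r}")
            span = abs(qend - qstart) + 1
            cov = 100.0 * span / query_lengths[qid]
            hits.append(HomologyHit(qid, sid, evalue, min(cov, 100.0)))
    return hits


def read_config(path) -> dict[str, str]:
    """Read a flat ``key=value`` configuration file; '#' starts a comment."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out
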