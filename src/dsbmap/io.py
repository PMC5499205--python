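"""Readers and writers for the standard formats the pipeline touches.

BED (0-based half-open) is the native interval dialect; BED12 carries gene
models with exon blocks; bedGraph carries fixed-width window counts; reads
come in as BED6 with optional barcode/UMI columns or as SAM/BAM. FASTA is
read through Biopython with gzip transparency. All loaders validate eagerly
and raise errors naming the file, line number and offending field.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bliss import ReadRecord
from .digest import RestrictionSite
from .expression import GeneRecord
from .h2ax import WindowTrack


# ---------------------------------------------------------------------------
# FASTA


def iter_fasta(path: str | Path):
    """Stream (name, sequence) pairs; transparent to .gz suffixes."""
    from Bio import SeqIO

    path = Path(path)
    handle = gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
    try:
        for record in SeqIO.parse(handle, "fasta"):
            yield record.id, str(record.seq)
    finally:
        handle.close()


def read_fasta(path: str | Path) -> dict[str, str]:
    return dict(iter_fasta(path))


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# line-validated interval loading


class FormatError(ValueError):
    pass


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not an integer: {value!r}")


def _iter_data_lines(path: str | Path):
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            n += 1
            yield lineno, line.split("\t")
    if n == 0:
        raise FormatError(f"{path}: no records")


def load_intervals(path: str | Path, format: str = "bed6"):
    """Validated interval records in the requested dialect.

    Formats: ``bed6`` (DataFrame; extra columns 7/8 become barcode/umi),
    ``bed12`` (list of GeneRecord), ``bedgraph`` (DataFrame of window
    counts), ``tsv`` (pandas, tab-separated with header).
    """
    if format == "bed6":
        return _load_bed6(path)
    if format == "bed12":
        return read_genes_bed12(path)
    if format == "bedgraph":
        return _load_bedgraph_df(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise FormatError(f"{path}: no records")
        return df
    raise FormatError(f"unknown format {format!r}")


def _load_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 else "."
        score = fields[4] if len(fields) > 4 else "0"
        strand = fields[5] if len(fields) > 5 else "+"
        if strand not in ("+", "-", "."):
            raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
        barcode = fields[6] if len(fields) > 6 else None
        umi = fields[7] if len(fields) > 7 else None
        rows.append((chrom, start, end, name, score, strand, barcode, umi))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "barcode", "umi"],
    )


def _load_bedgraph_df(path: str | Path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        try:
            value = float(fields[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: value is not numeric: {fields[3]!r}")
        rows.append((fields[0], start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# reads


def read_reads_bed(path: str | Path) -> list[ReadRecord]:
    df = _load_bed6(path)
    return [
        ReadRecord(
            chrom=r.chrom, start=r.start, end=r.end, strand=r.strand,
            barcode=r.barcode, umi=r.umi,
        )
        for r in df.itertuples()
    ]


def write_reads_bed(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            cols = [r.chrom, str(r.start), str(r.end), f"read_{i}", "0", r.strand]
            if r.barcode is not None or r.umi is not None:
                cols += [r.barcode or ".", r.umi or "."]
            fh.write("\t".join(cols) + "\n")


def read_reads_sam(path: str | Path) -> list[ReadRecord]:
    """Aligned reads from SAM/BAM via pysam, converted at the boundary."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            reads.append(
                ReadRecord(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    barcode=aln.get_tag("BC") if aln.has_tag("BC") else None,
                    umi=aln.get_tag("RX") if aln.has_tag("RX") else None,
                )
            )
    return reads


def read_reads(path: str | Path) -> list[ReadRecord]:
    path = Path(path)
    if path.suffix in (".sam", ".bam"):
        return read_reads_sam(path)
    return read_reads_bed(path)


# ---------------------------------------------------------------------------
# sites


def write_sites_bed(sites: Iterable[RestrictionSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                "\t".join(
                    [s.chrom, str(s.motif_start), str(s.motif_end), s.site_id, "0", "+"]
                )
                + "\n"
            )


def read_sites_bed(path: str | Path) -> list[RestrictionSite]:
    df = _load_bed6(path)
    return [
        RestrictionSite(
            chrom=r.chrom,
            motif_start=r.start,
            motif_end=r.end,
            center=r.start + (r.end - r.start) // 2,
            site_id=r.name if r.name != "." else f"{r.chrom}:{r.start}",
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# gene models (BED12)


def write_genes_bed12(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons) if g.exons else [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - g.start) for s, e in exons) + ","
            thick = g.thick if g.thick is not None else (g.start, g.end)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                        str(thick[0]), str(thick[1]), "0",
                        str(len(exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneRecord]:
    genes = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 12:
            raise FormatError(f"{path}:{lineno}: expected 12 BED12 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        name, strand = fields[3], fields[5]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
        thick = (
            _parse_int(fields[6], path, lineno, "thickStart"),
            _parse_int(fields[7], path, lineno, "thickEnd"),
        )
        n_blocks = _parse_int(fields[9], path, lineno, "blockCount")
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(f"{path}:{lineno}: block count mismatch")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(
            GeneRecord(
                gene_id=name, chrom=chrom, tss=tss, tes=tes, strand=strand,
                exons=exons, thick=thick,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# window tracks (bedGraph)


def write_bedgraph(track: WindowTrack, path: str | Path) -> None:
    w = track.window_size
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            arr = track.counts[chrom]
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v:g}\n")


def read_bedgraph_track(path: str | Path, window_size: int | None = None) -> WindowTrack:
    df = _load_bedgraph_df(path)
    widths = (df["end"] - df["start"]).unique()
    if window_size is None:
        window_size = int(widths.max())
    counts = {}
    for chrom, grp in df.groupby("chrom"):
        n_win = int(np.ceil(grp["end"].max() / window_size))
        arr = np.zeros(n_win)
        arr[grp["start"].to_numpy() // window_size] = grp["value"].to_numpy()
        counts[chrom] = arr
    return WindowTrack(window_size=window_size, counts=counts)
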