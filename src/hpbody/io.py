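"""Readers and writers for the on-disk formats the pipeline exchanges.

Trajectories travel as long-format CSV (trajectory_id, frame, x_um, y_um);
movies as multi-frame TIFF; count tables and sample sheets as TSV; aligned
3'-end reads as SAM/BAM (via pysam) or a tabular fallback; gene models as
BED6 or GFF3; annotations as GAF 2.x or two-column TSV; ground truth and
results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .polya import AlignedRead, GeneModel

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_movie",
    "write_movie",
    "read_counts",
    "read_sample_sheet",
    "read_gene_models",
    "read_reads_table",
    "read_reads_sam",
    "read_annotation",
    "read_protein_set",
    "write_json",
]


def read_trajectories(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"trajectory_id", "frame", "x_um", "y_um"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_trajectories(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_movie(path) -> np.ndarray:
    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    return movie


def write_movie(movie: np.ndarray, path) -> None:
    tifffile.imwrite(
        path, np.asarray(movie, dtype=np.float32), photometric="minisblack"
    )


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError(f"{path}: sample sheet needs a 'sample' column")
    return meta


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from BED6 (no header) or GFF3 (``gene`` features).

    GFF3 gene ids come from the first of ID / gene_id / locus_tag / Name in
    the attributes column; GFF coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        GeneModel(str(r.name_), str(r.chrom), str(r.strand), int(r.start), int(r.end))
        for r in bed.rename(columns={"name": "name_"}).itertuples()
    ]


def _read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = next(
                (attrs[k] for k in ("ID", "gene_id", "locus_tag", "Name") if k in attrs),
                None,
            )
            if gene_id is None:
                raise ValueError(f"{path}: gene feature without an identifier")
            genes.append(
                GeneModel(
                    gene_id, fields[0], fields[6],
                    int(fields[3]) - 1, int(fields[4]),
                )
            )
    return genes


def read_reads_table(path) -> list[AlignedRead]:
    """Tabular read format: read_id, chrom, pos0, strand, sequence, sample
    [, aligned_length]."""
    table = pd.read_csv(path, sep="\t")
    has_alen = "aligned_length" in table.columns
    return [
        AlignedRead(
            read_id=str(r.read_id),
            chrom=str(r.chrom),
            pos0=int(r.pos0),
            strand=str(r.strand),
            sequence=str(r.sequence),
            sample=str(r.sample),
            aligned_length=int(r.aligned_length) if has_alen else None,
        )
        for r in table.itertuples()
    ]


def write_reads_table(reads: list[AlignedRead], path) -> None:
    pd.DataFrame(
        [
            (r.read_id, r.chrom, r.pos0, r.strand, r.sequence, r.sample,
             r.aligned_length if r.aligned_length is not None else "")
            for r in reads
        ],
        columns=["read_id", "chrom", "pos0", "strand", "sequence", "sample",
                 "aligned_length"],
    ).to_csv(path, sep="\t", index=False)


def read_reads_sam(path, sample: str | None = None) -> list[AlignedRead]:
    """Aligned reads from SAM/BAM.

    The sequence is recovered as sequenced (pysam's forward sequence), the
    strand from the reverse flag, and the aligned length from the reference
    span.  ``sample`` defaults to the file stem.
    """
    import pysam

    if sample is None:
        sample = Path(path).stem
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            seq = aln.get_forward_sequence() or aln.query_sequence
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    pos0=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    sequence=seq,
                    sample=sample,
                    aligned_length=aln.reference_end - aln.reference_start,
                )
            )
    return reads


def read_annotation(path) -> dict:
    """Protein -> GO-term map from GAF 2.x or a two-column TSV.

    GAF lines start with a database tag and carry the object id in column 2
    and the GO id in column 5; comment lines start with '!'.  A two-column
    TSV is (protein_id, term_id), with an optional header.
    """
    annotation: dict[str, set] = {}
    with open(path) as fh:
        first = True
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5 and fields[4].startswith("GO:"):
                protein, term = fields[1], fields[4]   # GAF layout
            elif len(fields) >= 2:
                protein, term = fields[0], fields[1]
                if first and term.lower() in ("term_id", "term", "go_id"):
                    first = False
                    continue
            else:
                continue
            first = False
            annotation.setdefault(protein, set()).add(term)
    return annotation


def read_protein_set(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
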