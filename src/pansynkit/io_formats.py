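"""Readers and writers for the formats the pipeline touches.

Dialects:

* orthogroups — OrthoFinder ``Orthogroups.tsv``: header of accession names,
  one row per family, cells are comma+space-joined gene lists, empty cell =
  family absent from that accession.
* SyRI — headerless TSV, >= 11 columns: ref chrom/start/end, ref seq, qry
  seq, qry chrom/start/end, id, parent, annotation type. Only top-level
  structural rows are kept; alignment-level rows (``SYNAL`` etc.) are skipped.
* depth — ``samtools depth -a`` 3-column TSV (chrom, 1-based pos, depth);
  missing positions read back as depth 0.
* PAV — native format is a counts TSV (families x accessions); a relaxed
  phylip export binarises presence for tree builders.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    SYRI_TOP_LEVEL_TYPES,
    SV_TYPES,
    DepthTrack,
    GeneModel,
    HomologyHit,
    OrthogroupTable,
    SVRecord,
    SyntenyBlock,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# orthogroups


def read_orthogroups(path) -> OrthogroupTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: orthogroup header needs >= 2 columns")
        accessions = header[1:]
        families: dict[str, dict[str, list[str]]] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            fam = fields[0]
            if fam in families:
                raise FormatError(f"{path}:{lineno}: duplicate family id {fam!r}")
            families[fam] = {
                acc: (cell.split(", ") if cell else [])
                for acc, cell in zip(accessions, fields[1:])
            }
    return OrthogroupTable(families=families, accessions=accessions)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.accessions) + "\n")
        for fam in table.families:
            cells = [
                ", ".join(table.families[fam].get(acc, []))
                for acc in table.accessions
            ]
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# SyRI blocks


def read_syri(path, accession: str) -> list[SyntenyBlock]:
    """Parse top-level annotation rows of a SyRI output file for one accession.

    Unknown annotation codes are skipped with a warning and counted in the
    module logger (dialect drift across SyRI versions).
    """
    path = Path(path)
    blocks: list[SyntenyBlock] = []
    n_skipped_unknown = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: expected >= 11 columns")
            code = fields[10]
            if code in SYRI_TOP_LEVEL_TYPES:
                qry_missing = fields[5] == "-"
                blocks.append(
                    SyntenyBlock(
                        ref_chrom=fields[0],
                        ref_start=int(fields[1]),
                        ref_end=int(fields[2]),
                        qry_chrom="-" if qry_missing else fields[5],
                        qry_start=0 if qry_missing else int(fields[6]),
                        qry_end=0 if qry_missing else int(fields[7]),
                        block_type=code,
                        accession=accession,
                    )
                )
            elif code.endswith("AL") or code in {
                "SNP", "INS", "DEL", "CPG", "CPL", "HDR", "TDM"
            }:
                continue  # alignment-level / sub-block variant rows
            else:
                n_skipped_unknown += 1
                warnings.warn(
                    f"{path}:{lineno}: unknown SyRI annotation {code!r}, skipped"
                )
    if n_skipped_unknown:
        logger.info("%s: skipped %d rows with unknown codes", path, n_skipped_unknown)
    return blocks


def write_syri(blocks: Iterable[SyntenyBlock], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for i, b in enumerate(blocks):
            qry = (
                ("-", "-", "-")
                if b.qry_chrom == "-"
                else (b.qry_chrom, str(b.qry_start), str(b.qry_end))
            )
            fh.write(
                "\t".join(
                    [
                        b.ref_chrom,
                        str(b.ref_start),
                        str(b.ref_end),
                        "-",
                        "-",
                        *qry,
                        f"{b.block_type}{i}",
                        "-",
                        b.block_type,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SV records (SyRI-derived SV TSV used by the merger)

_SV_COLUMNS = ["accession", "sv_type", "chrom", "start", "end", "length"]


def read_sv_records(path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "chrom": str})
    missing = set(_SV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing SV columns {sorted(missing)}")
    return [
        SVRecord(
            accession=row.accession,
            sv_type=row.sv_type,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            length=int(row.length),
        )
        for row in df.itertuples()
    ]


def write_sv_records(records: Iterable[SVRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.accession, r.sv_type, r.chrom, r.start, r.end, r.length)
            for r in records
        ],
        columns=_SV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology hits

_HIT_COLUMNS = [
    "query", "target", "cov_query", "cov_target", "score",
    "target_start", "target_end",
]


def read_hits(path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing hit columns {sorted(missing)}")
    return [
        HomologyHit(
            query=row.query,
            target=row.target,
            cov_query=float(row.cov_query),
            cov_target=float(row.cov_target),
            score=float(row.score),
            target_start=int(row.target_start),
            target_end=int(row.target_end),
        )
        for row in df.itertuples()
    ]


def write_hits(hits: Iterable[HomologyHit], path) -> None:
    df = pd.DataFrame(
        [
            (h.query, h.target, h.cov_query, h.cov_target, h.score,
             h.target_start, h.target_end)
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# depth tracks


def read_depth(path) -> dict[str, DepthTrack]:
    """Read a 3-column depth TSV into dense per-chromosome vectors.

    Positions must be strictly increasing within a chromosome; gaps (as
    produced without ``-a``) are filled with depth 0 up to the last reported
    position.
    """
    path = Path(path)
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            chrom, pos_s, depth_s = fields
            pos = int(pos_s)
            positions, depths = per_chrom.setdefault(chrom, ([], []))
            if positions and pos <= positions[-1]:
                raise FormatError(
                    f"{path}:{lineno}: non-monotone position {pos} on {chrom}"
                )
            positions.append(pos)
            depths.append(float(depth_s))
    tracks: dict[str, DepthTrack] = {}
    for chrom, (positions, depths) in per_chrom.items():
        dense = np.zeros(positions[-1], dtype=float)
        dense[np.asarray(positions) - 1] = depths
        tracks[chrom] = DepthTrack(chrom=chrom, depth=dense)
    return tracks


def write_depth(tracks: dict[str, DepthTrack] | Iterable[DepthTrack], path) -> None:
    if isinstance(tracks, dict):
        tracks = tracks.values()
    path = Path(path)
    with path.open("w") as fh:
        for track in tracks:
            depth = track.depth
            for i in range(len(depth)):
                d = depth[i]
                d_str = str(int(d)) if float(d).is_integer() else repr(float(d))
                fh.write(f"{track.chrom}\t{i + 1}\t{d_str}\n")


# ---------------------------------------------------------------------------
# PAV matrix


def read_pav(path) -> pd.DataFrame:
    """Counts TSV -> families x accessions integer DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate family ids")
    return df.astype(np.int64)


def write_pav(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="family")


def write_pav_phylip(matrix: pd.DataFrame, path) -> None:
    """Binary-presence export in relaxed phylip (names <= 10 chars, padded).

    Raises if truncation to 10 characters makes two accession names collide.
    """
    names = [str(c)[:10] for c in matrix.columns]
    if len(set(names)) != len(names):
        raise FormatError("accession names collide after truncation to 10 chars")
    presence = (matrix.to_numpy() >= 1).astype(int)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(names)} {matrix.shape[0]}\n")
        for j, name in enumerate(names):
            fh.write(f"{name:<10} " + "".join(map(str, presence[:, j])) + "\n")


# ---------------------------------------------------------------------------
# FASTA / GFF3


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "pansynkit",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path, accession: str) -> list[GeneModel]:
    """Read gene features of one accession via pyranges."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == "gene"]
    return [
        GeneModel(
            accession=accession,
            gene_id=str(row.ID),
            chrom=str(row.Chromosome),
            start=int(row.Start) + 1,  # pyranges is 0-based half-open
            end=int(row.End),
            strand=str(row.Strand) if "Strand" in df.columns else "+",
        )
        for row in df.itertuples()
    ]
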