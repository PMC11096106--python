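"""Shared domain records.

Coordinates are 1-based inclusive throughout (the GFF3/SyRI convention);
any half-open arithmetic is confined to the window code in :mod:`syndiv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Top-level SyRI annotation codes retained by the readers. Alignment-level
#: rows (SYNAL, INVAL, ...) and sub-SYN variant rows are skipped on input.
SYRI_TOP_LEVEL_TYPES = frozenset(
    {"SYN", "INV", "TRANS", "DUP", "INVTR", "INVDP", "NOTAL"}
)

#: Structural-variant classes handled by the cross-accession merger.
SV_TYPES = frozenset({"INS", "DEL", "INV", "TRANS", "DUP"})


@dataclass(frozen=True)
class SyntenyBlock:
    """One whole-genome-alignment block of an accession on the reference."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    block_type: str
    accession: str

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError(
                f"block {self.ref_chrom}:{self.ref_start}-{self.ref_end}: "
                "ref_start > ref_end"
            )
        if self.block_type not in SYRI_TOP_LEVEL_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class SVRecord:
    """A structural variant of one accession anchored on reference coordinates."""

    accession: str
    sv_type: str
    chrom: str
    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.start > self.end:
            raise ValueError("start > end")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class DepthTrack:
    """Dense per-base sequencing depth for one sequence.

    ``depth[i]`` is the depth at 1-based position ``i + 1``. Positions absent
    from a sparse input are depth 0.
    """

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def total(self) -> float:
        return float(self.depth.sum())


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene feature used for family adjacency and representative choice."""

    accession: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologyHit:
    """A directed gene-to-gene homology hit.

    Coverages are fractions of the query/target gene length covered by the
    alignment; ``target_start``/``target_end`` give the covered span on the
    target gene (1-based inclusive, gene-local coordinates) and are what the
    split–merge detector unions across adjacent query genes.
    """

    query: str
    target: str
    cov_query: float
    cov_target: float
    score: float
    target_start: int = 0
    target_end: int = 0

    def __post_init__(self) -> None:
        for cov in (self.cov_query, self.cov_target):
            if not 0.0 <= cov <= 1.0:
                raise ValueError("coverage outside [0, 1]")


@dataclass
class OrthogroupTable:
    """Gene families as ``family id -> accession -> gene id list``.

    The accession list fixes column order for matrix construction; absent
    (family, accession) cells are empty lists.
    """

    families: dict[str, dict[str, list[str]]]
    accessions: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, per_acc in self.families.items():
            for acc, genes in per_acc.items():
                for g in genes:
                    if g in seen and seen[g] != fam + "\t" + acc:
                        raise ValueError(f"gene id {g!r} occurs more than once")
                    seen[g] = fam + "\t" + acc

    @property
    def n_families(self) -> int:
        return len(self.families)

    def gene_to_family(self) -> dict[str, str]:
        return {
            g: fam
            for fam, per_acc in self.families.items()
            for genes in per_acc.values()
            for g in genes
        }

    def gene_to_accession(self) -> dict[str, str]:
        return {
            g: acc
            for per_acc in self.families.values()
            for acc, genes in per_acc.items()
            for g in genes
        }

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            fam: {acc: len(per_acc.get(acc, ())) for acc in self.accessions}
            for fam, per_acc in self.families.items()
        }
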