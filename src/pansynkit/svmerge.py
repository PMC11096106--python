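"""Cross-accession structural-variant merging.

Implements SURVIVOR-style single-linkage clustering: two records link iff
they have the same SV type (type matching on), lie on the same chromosome,
and both breakpoints agree within ``max_dist`` (|delta start| <= max_dist
AND |delta end| <= max_dist). Variants are merged in two size tiers as in
SURVIVOR parameter strings '1000 1 1 0 0 1' (20 bp – 10 kb, max_dist 1 kb)
and '20000 1 1 0 0 1' (> 10 kb, max_dist 20 kb): (max distance, min
support, type match, strand match off, no distance estimate, min size 1).

Cluster representatives take the per-coordinate median of their members
(robust, deterministic); support counts distinct accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SVRecord


@dataclass(frozen=True)
class MergeParams:
    max_dist: int = 1000
    min_support: int = 1
    type_match: bool = True
    size_min: int = 20
    size_max: int | None = 10_000

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")

    @classmethod
    def small_tier(cls) -> "MergeParams":
        """20 bp – 10 kb tier, breakpoint distance 1 kb."""
        return cls(max_dist=1000, size_min=20, size_max=10_000)

    @classmethod
    def large_tier(cls) -> "MergeParams":
        """> 10 kb tier, breakpoint distance 20 kb."""
        return cls(max_dist=20_000, size_min=10_001, size_max=None)

    def in_bounds(self, length: int) -> bool:
        if length < self.size_min:
            return False
        return self.size_max is None or length <= self.size_max


@dataclass
class SVCluster:
    sv_type: str
    chrom: str
    start: int
    end: int
    length: int
    support: int
    accessions: list[str]
    members: list[SVRecord] = field(repr=False, default_factory=list)


def merge_svs(
    records: list[SVRecord], params: MergeParams = MergeParams()
) -> list[SVCluster]:
    """Single-linkage merge of per-accession SV records into clusters.

    Records outside the tier's size bounds are dropped with a warning (route
    them to the other tier). Every retained record belongs to exactly one
    cluster; the result is independent of input order.
    """
    kept = [r for r in records if params.in_bounds(r.length)]
    if len(kept) != len(records):
        warnings.warn(
            f"{len(records) - len(kept)} records outside size bounds "
            f"[{params.size_min}, {params.size_max}] skipped; use the other tier"
        )

    groups: dict[tuple[str, str], list[SVRecord]] = {}
    for r in kept:
        key = (r.sv_type if params.type_match else "*", r.chrom)
        groups.setdefault(key, []).append(r)

    clusters: list[SVCluster] = []
    for recs in groups.values():
        # canonical order removes any input-order dependence
        recs = sorted(recs, key=lambda r: (r.start, r.end, r.accession))
        parent = list(range(len(recs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        starts = np.array([r.start for r in recs])
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if starts[j] - starts[i] > params.max_dist:
                    break
                if abs(recs[i].end - recs[j].end) <= params.max_dist:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)

        by_root: dict[int, list[SVRecord]] = {}
        for i, r in enumerate(recs):
            by_root.setdefault(find(i), []).append(r)
        for members in by_root.values():
            start = int(np.median([r.start for r in members]))
            end = int(np.median([r.end for r in members]))
            length = int(np.median([r.length for r in members]))
            accs = sorted({r.accession for r in members})
            if len(accs) < params.min_support:
                continue
            clusters.append(
                SVCluster(
                    sv_type=members[0].sv_type,
                    chrom=members[0].chrom,
                    start=start,
                    end=end,
                    length=length,
                    support=len(accs),
                    accessions=accs,
                    members=members,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end, c.sv_type))
    return clusters


def sv_summary(
    clusters: list[SVCluster], size_bins=None
) -> dict[str, object]:
    """Totals per type, size histogram and sharing spectrum of merged clusters."""
    if not clusters:
        return {
            "per_type": pd.Series(dtype=int),
            "size_hist": (np.array([]), np.array([])),
            "support_spectrum": {},
            "n_clusters": 0,
        }
    types = pd.Series([c.sv_type for c in clusters])
    lengths = np.array([c.length for c in clusters])
    if size_bins is None:
        size_bins = np.logspace(
            np.log10(max(lengths.min(), 1)), np.log10(lengths.max() + 1), 20
        )
    hist = np.histogram(lengths, bins=size_bins)
    supports = pd.Series([c.support for c in clusters])
    spectrum = supports.value_counts().sort_index().to_dict()
    return {
        "per_type": types.value_counts().sort_index(),
        "size_hist": hist,
        "support_spectrum": {int(k): int(v) for k, v in spectrum.items()},
        "n_clusters": len(clusters),
    }


def find_large_rearrangements(
    clusters: list[SVCluster], min_len: int = 1_000_000
) -> list[SVCluster]:
    """Megabase-scale merged events, longest first, with their carriers."""
    hits = [c for c in clusters if c.length >= min_len]
    hits.sort(key=lambda c: (-c.length, c.chrom, c.start))
    return hits


def clusters_to_frame(clusters: list[SVCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.chrom,
                c.start,
                c.end,
                c.sv_type,
                c.length,
                c.support,
                ",".join(c.accessions),
            )
            for c in clusters
        ],
        columns=["chrom", "start", "end", "sv_type", "length", "support", "accessions"],
    )
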