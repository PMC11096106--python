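"""Tandem-repeat array annotation and depth-based abundance estimation.

Centromeres of *A. thaliana* are megabase arrays of a ~178-bp satellite
monomer; telomeres are arrays of a 7-bp repeat. Assembled array length per
accession is found by scanning the assembly for approximate motif matches;
the *true* genomic array length (independent of assembly completeness) is
estimated from read depth piled onto a short concatemer of the motif:

    estimated bp = (sum of per-base depth on the concatemer) / (genome mean depth)

The ratio assembled/estimated is the assembly completeness of the arrays
(the same ratio applied to assembly size vs k-mer genome-size estimate
measures whole-genome completeness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .records import DepthTrack

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatParams:
    motif: str
    max_divergence: float = 0.20
    max_gap: int | None = None  # default: one motif length
    concatemer_copies: int = 4
    min_copies: int = 2  # arrays are tandem: drop isolated single matches

    def __post_init__(self) -> None:
        if not 0 <= self.max_divergence < 0.5:
            raise ValueError("max_divergence must be in [0, 0.5)")
        if set(self.motif.upper()) - set("ACGTN"):
            raise ValueError("motif must be DNA")

    @property
    def gap(self) -> int:
        return len(self.motif) if self.max_gap is None else self.max_gap

    @property
    def max_edits(self) -> int:
        return int(self.max_divergence * len(self.motif))

    def concatemer(self) -> str:
        return self.motif * self.concatemer_copies


@dataclass(frozen=True)
class RepeatArray:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    copy_estimate: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _seed_candidates(seq: str, motif: str, slack: int) -> np.ndarray:
    """Putative match start positions (0-based) from exact seed k-mers.

    The motif is cut into disjoint 10-mers; every exact occurrence of a seed
    votes for a candidate motif start. A copy diverged at rate d misses all
    seeds with probability ~(1 - (1-d)^10)^(#seeds), negligible below ~15%.
    """
    s = 10
    cands: set[int] = set()
    for off in range(0, len(motif) - s + 1, s):
        seed = motif[off : off + s]
        i = seq.find(seed)
        while i != -1:
            base = i - off
            for c in range(base - slack, base + slack + 1):
                if c >= 0:
                    cands.add(c)
            i = seq.find(seed, i + 1)
    return np.array(sorted(cands), dtype=np.int64)


def _hamming_hits(seq: str, motif: str, k: int) -> np.ndarray:
    """0-based positions where the motif matches within k substitutions.

    Vectorised scan used for short motifs (< 20 bp), where indel moves are
    immaterial; longer motifs go through banded edit distance.
    """
    m = len(motif)
    if len(seq) < m:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mot = np.frombuffer(motif.encode(), dtype=np.uint8)
    n_win = len(arr) - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mism += arr[j : j + n_win] != mot[j]
    return np.nonzero(mism <= k)[0].astype(np.int64)


def _greedy_hits_short(seq: str, motif: str, k: int, strand: str):
    hits = []
    m = len(motif)
    cursor = 0
    for p in _hamming_hits(seq, motif, k):
        if p < cursor:
            continue
        hits.append((int(p) + 1, int(p) + m, strand))
        cursor = int(p) + m
    return hits


def _greedy_hits_long(seq: str, motifs: dict[str, str], k: int):
    """Greedy non-overlapping tiling with banded edit distance (edlib).

    ``motifs`` maps strand -> pattern; at each candidate position the better
    strand wins ('+' on ties). Matching in prefix (SHW) mode lets a copy end
    early or late by up to k bases.
    """
    m = len(next(iter(motifs.values())))
    cand = np.unique(
        np.concatenate(
            [_seed_candidates(seq, pat, slack=3) for pat in motifs.values()]
        )
    ) if motifs else np.empty(0, dtype=np.int64)
    def try_at(p: int):
        window = seq[p : p + m + k]
        best = None
        for strand in sorted(motifs):  # '+' before '-' on ties
            r = edlib.align(motifs[strand], window, mode="SHW", task="locations", k=k)
            if r["editDistance"] >= 0 and (best is None or r["editDistance"] < best[0]):
                best = (r["editDistance"], r["locations"][0][1], strand)
        return best

    hits = []
    cursor = 0
    for p in cand:
        p = int(p)
        if p < cursor or p + m - k > len(seq):
            continue
        best = try_at(p)
        if best is None:
            continue
        # seed slack can anchor a few bases early: slide right while the
        # edit distance strictly improves, so exact copies start exactly
        while best[0] > 0 and p + 1 + m - k <= len(seq):
            nxt = try_at(p + 1)
            if nxt is None or nxt[0] >= best[0]:
                break
            p, best = p + 1, nxt
        end0 = p + best[1]  # 0-based inclusive end
        hits.append((p + 1, end0 + 1, best[2]))
        cursor = end0 + 1
    return hits


def find_repeat_arrays(
    sequence: str, params: RepeatParams, chrom: str = "chr"
) -> list[RepeatArray]:
    """Annotate tandem arrays of the motif on both strands of one sequence.

    Motif matches within edit distance ``max_divergence * len(motif)`` are
    tiled greedily left to right without overlap; runs of same-strand hits
    separated by <= ``max_gap`` bp merge into one array. ``copy_estimate``
    is array length / motif length.
    """
    seq = sequence.upper()
    motif = params.motif.upper()
    if len(motif) > len(seq):
        return []
    k = params.max_edits
    if len(motif) < 20:
        hits = sorted(
            _greedy_hits_short(seq, motif, k, "+")
            + _greedy_hits_short(seq, revcomp(motif), k, "-")
        )
        # re-run greedy over the combined strand hit lists
        merged_hits = []
        cursor = 0
        for s, e, st in hits:
            if s <= cursor:
                continue
            merged_hits.append((s, e, st))
            cursor = e
        hits = merged_hits
    else:
        hits = _greedy_hits_long(seq, {"+": motif, "-": revcomp(motif)}, k)

    arrays: list[RepeatArray] = []
    for s, e, st in hits:
        if (
            arrays
            and arrays[-1].strand == st
            and s - arrays[-1].end - 1 <= params.gap
        ):
            prev = arrays[-1]
            arrays[-1] = RepeatArray(
                chrom=chrom,
                start=prev.start,
                end=e,
                strand=st,
                copy_estimate=(e - prev.start + 1) / len(motif),
            )
        else:
            arrays.append(
                RepeatArray(
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=st,
                    copy_estimate=(e - s + 1) / len(motif),
                )
            )
    return [a for a in arrays if a.length >= params.min_copies * len(motif)]


def genome_mean_depth(
    tracks: dict[str, DepthTrack],
    mask: dict[str, np.ndarray] | None = None,
) -> float:
    """Mean depth over positions outside ``mask`` (repeat arrays).

    Masking the arrays avoids circularity when arrays are only partially
    assembled (reads from missing copies pile onto the assembled ones).
    """
    total = 0.0
    n = 0
    for chrom, track in tracks.items():
        keep = np.ones(len(track), dtype=bool)
        if mask and chrom in mask:
            for s, e in mask[chrom]:
                keep[max(int(s) - 1, 0) : int(e)] = False
        total += float(track.depth[keep].sum())
        n += int(keep.sum())
    if n == 0:
        raise ValueError("no unmasked positions")
    return total / n


def estimate_repeat_length(
    depth_concatemer: DepthTrack, genome_mean_depth: float
) -> float:
    """Genomic repeat bp implied by depth piled onto the motif concatemer."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    return depth_concatemer.total / genome_mean_depth


def completeness_ratio(assembled_bp: float, estimated_bp: float) -> float:
    """Assembled / estimated length; > 1 is possible (over-assembly) and allowed."""
    if estimated_bp <= 0:
        raise ValueError("estimated length must be positive")
    return assembled_bp / estimated_bp


def apportion_estimate(
    total_estimate: float, assembled_per_chrom: dict[str, float]
) -> dict[str, float]:
    """Split a genome-wide depth estimate over chromosomes.

    The concatemer signal is genome-wide; per-chromosome estimates are
    apportioned proportionally to each chromosome's assembled array length.
    """
    total_assembled = sum(assembled_per_chrom.values())
    if total_assembled <= 0:
        raise ValueError("no assembled arrays to apportion over")
    return {
        c: total_estimate * a / total_assembled
        for c, a in assembled_per_chrom.items()
    }


def size_correlations(
    table: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r with two-sided p for declared column pairs of a size table.

    Zero-variance columns yield NaN r/p (undefined correlation) rather than
    an error.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 accessions")
    rows = []
    for a, b in pairs:
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((a, b, np.nan, np.nan))
        else:
            r, p = stats.pearsonr(x, y)
            rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p"])


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pairwise Pearson matrix (r and p) over the table's columns."""
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            res = size_correlations(table, [(a, b)])
            r.loc[a, b] = r.loc[b, a] = res["r"].iloc[0]
            p.loc[a, b] = p.loc[b, a] = res["p"].iloc[0]
    return r, p
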