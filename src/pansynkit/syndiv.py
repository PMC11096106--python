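"""Windowed synteny diversity on reference coordinates.

Each accession's whole-genome-alignment blocks against the reference are
projected to a per-position syntenic indicator s_i(p): 1 where the position
is covered by a SYN block, 0 where it is covered only by rearranged
(INV/TRANS/DUP/...) or unaligned (NOTAL) blocks, or not covered at all.
Rearranged-but-aligned sequence deliberately counts as non-syntenic — the
statistic is meant to light up rearrangements.

For a window w of n accessions,

    pi_syn(w) = 2 / (n (n-1)) * sum_{i<j} (1/|w|) * sum_{p in w} (1 - s_i(p) s_j(p))

so pi_syn = 0 means every pair is colinear over the whole window and 1 means
no pair shares any syntenic position. Two accessions are treated as jointly
syntenic at p iff both are syntenic to the reference there (reference-
projection approximation; no all-vs-all alignment).

Internally the per-chromosome indicator stack is swept once into segments of
constant "number of syntenic accessions" m(p); then
sum_{i<j} s_i s_j = C(m, 2) per position, and window sums come from a prefix
sum over segment boundaries — exactly equal to the per-position definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .records import SyntenyBlock


@dataclass(frozen=True)
class WindowSpec:
    window: int
    step: int

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.step > self.window:
            raise ValueError("step must be <= window")


#: accession -> chromosome -> normalised syntenic interval set
SyntenyIndicator = dict[str, dict[str, np.ndarray]]


def project_synteny(
    blocks_by_accession: dict[str, list[SyntenyBlock]],
    chrom_lengths: dict[str, int],
) -> SyntenyIndicator:
    """Merge each accession's SYN blocks into per-chromosome interval sets."""
    indicator: SyntenyIndicator = {}
    for acc, blocks in blocks_by_accession.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
        for b in blocks:
            if b.ref_chrom not in chrom_lengths:
                raise ValueError(f"{acc}: block on unknown chromosome {b.ref_chrom}")
            if b.ref_end > chrom_lengths[b.ref_chrom]:
                raise ValueError(
                    f"{acc}: block {b.ref_chrom}:{b.ref_start}-{b.ref_end} "
                    f"beyond chromosome end {chrom_lengths[b.ref_chrom]}"
                )
            if b.block_type == "SYN":
                per_chrom[b.ref_chrom].append((b.ref_start, b.ref_end))
        indicator[acc] = {c: iv.merge(spans) for c, spans in per_chrom.items()}
    return indicator


def _pair_cover_segments(
    indicator: SyntenyIndicator, chrom: str, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep all accessions' intervals on one chromosome.

    Returns (bounds, q): ``bounds`` are segment start positions (1-based,
    first = 1, plus a terminal ``length + 1``); ``q[t]`` is C(m, 2) for the
    constant count m of syntenic accessions on segment
    [bounds[t], bounds[t+1] - 1].
    """
    events: list[tuple[int, int]] = []
    for per_chrom in indicator.values():
        for s, e in per_chrom.get(chrom, ()):
            events.append((int(s), 1))
            events.append((int(e) + 1, -1))
    if not events:
        return np.array([1, length + 1]), np.zeros(1)
    pos = np.array(sorted({p for p, _ in events} | {1, length + 1}))
    pos = pos[(pos >= 1) & (pos <= length + 1)]
    delta = np.zeros(len(pos), dtype=np.int64)
    lookup = {int(p): i for i, p in enumerate(pos)}
    for p, d in events:
        if 1 <= p <= length + 1:
            delta[lookup[p]] += d
    m = np.cumsum(delta)[:-1]  # count on segment [pos[t], pos[t+1]-1]
    q = m * (m - 1) / 2.0
    return pos, q


def synteny_diversity(
    indicator: SyntenyIndicator,
    chrom_lengths: dict[str, int],
    spec: WindowSpec,
) -> pd.DataFrame:
    """Sliding-window pi_syn over all chromosomes.

    Windows are anchored at position 1 and advance by ``spec.step``; the last
    window is truncated at the chromosome end and kept with its true length.
    Returns a DataFrame with chrom, start, end, pi_syn, n_pairs.
    """
    n = len(indicator)
    if n < 2:
        raise ValueError("need >= 2 accessions")
    n_pairs = n * (n - 1) // 2
    rows = []
    for chrom, length in chrom_lengths.items():
        bounds, q = _pair_cover_segments(indicator, chrom, length)
        seg_len = np.diff(bounds)
        cum = np.concatenate([[0.0], np.cumsum(q * seg_len)])

        def q_sum(a: int, b: int) -> float:
            """sum over positions a..b of C(m(p), 2), from the prefix sums."""
            ia = np.searchsorted(bounds, a, side="right") - 1
            ib = np.searchsorted(bounds, b, side="right") - 1
            if ia == ib:
                return float(q[ia] * (b - a + 1))
            total = float(cum[ib] - cum[ia + 1])
            total += float(q[ia] * (bounds[ia + 1] - a))
            total += float(q[ib] * (b - bounds[ib] + 1))
            return total

        start = 1
        while start <= length:
            end = min(start + spec.window - 1, length)
            w = end - start + 1
            mean_joint = q_sum(start, end) / (n_pairs * w)
            pi = min(1.0, max(0.0, 1.0 - mean_joint))  # guard float round-off
            rows.append((chrom, start, end, pi, n_pairs))
            if end == length:
                break
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi_syn", "n_pairs"])


def synteny_diversity_bruteforce(
    indicator: SyntenyIndicator,
    chrom_lengths: dict[str, int],
    spec: WindowSpec,
) -> pd.DataFrame:
    """Per-position oracle for :func:`synteny_diversity` (small inputs only)."""
    accs = list(indicator)
    n = len(accs)
    n_pairs = n * (n - 1) // 2
    rows = []
    for chrom, length in chrom_lengths.items():
        masks = np.stack(
            [iv.to_mask(indicator[a].get(chrom, iv.EMPTY), length) for a in accs]
        )
        start = 1
        while start <= length:
            end = min(start + spec.window - 1, length)
            sub = masks[:, start - 1 : end]
            joint = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    joint += (sub[i] & sub[j]).mean()
            rows.append((chrom, start, end, 1.0 - joint / n_pairs, n_pairs))
            if end == length:
                break
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi_syn", "n_pairs"])


def fraction_by_threshold(
    stats: pd.DataFrame, low: float = 0.2, high: float = 0.5
) -> tuple[float, float]:
    """Length-weighted genome fractions with pi_syn below/above thresholds."""
    if stats.empty:
        raise ValueError("no windows")
    lengths = (stats["end"] - stats["start"] + 1).to_numpy(dtype=float)
    total = lengths.sum()
    below = lengths[stats["pi_syn"].to_numpy() < low].sum() / total
    above = lengths[stats["pi_syn"].to_numpy() > high].sum() / total
    return float(below), float(above)


def pairwise_colinearity(
    indicator: SyntenyIndicator,
    arm_mask: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Accession x accession fraction of masked-in positions jointly syntenic.

    ``arm_mask`` gives, per chromosome, the reference intervals to evaluate
    (typically chromosome arms, excluding centromere/pericentromere). The
    diagonal holds each accession's syntenic fraction against the reference.
    """
    mask_len = sum(iv.total_length(m) for m in arm_mask.values())
    if mask_len == 0:
        raise ValueError("empty arm mask")
    accs = list(indicator)
    masked = {
        a: {c: iv.intersect(indicator[a].get(c, iv.EMPTY), m) for c, m in arm_mask.items()}
        for a in accs
    }
    out = np.zeros((len(accs), len(accs)))
    for i, a in enumerate(accs):
        out[i, i] = sum(iv.total_length(v) for v in masked[a].values()) / mask_len
        for j in range(i + 1, len(accs)):
            b = accs[j]
            joint = sum(
                iv.total_length(iv.intersect(masked[a][c], masked[b][c]))
                for c in arm_mask
            )
            out[i, j] = out[j, i] = joint / mask_len
    return pd.DataFrame(out, index=accs, columns=accs)


def group_colinearity(
    matrix: pd.DataFrame, groups: dict[str, str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Within-group means and between-group mean matrix of pairwise colinearity.

    ``groups`` maps accession -> group label; off-diagonal entries only.
    """
    labels = sorted(set(groups.values()))
    members = {g: [a for a in matrix.index if groups[a] == g] for g in labels}
    within = {}
    for g, accs in members.items():
        vals = [
            matrix.loc[a, b] for i, a in enumerate(accs) for b in accs[i + 1 :]
        ]
        within[g] = float(np.mean(vals)) if vals else np.nan
    between = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for g in labels:
        for h in labels:
            if g == h:
                between.loc[g, h] = within[g]
            else:
                vals = [matrix.loc[a, b] for a in members[g] for b in members[h]]
                between.loc[g, h] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(within, name="within"), between
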