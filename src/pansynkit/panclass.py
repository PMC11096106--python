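"""Gene-family presence/absence analysis.

The pan-genome matrix is a pandas DataFrame of non-negative integer gene
counts, families as rows and accessions as columns. A family is *present*
in an accession when its count is >= 1; ``m_f`` denotes the number of
accessions a family is present in and ``n`` the number of accessions.

Categories (with softcore fraction t, default 0.90, strict inequality):

* core         m_f = n
* softcore     t*n < m_f < n
* dispensable  2 <= m_f <= floor at the softcore bound
* private      m_f = 1
* absent       m_f = 0 (excluded from classification counts)

At n = 69, t = 0.9 this gives softcore 63–68 and dispensable 2–62.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .records import GeneModel, HomologyHit, OrthogroupTable

CATEGORIES = ("core", "softcore", "dispensable", "private")
CATEGORY_ORDER = {"absent": 0, "private": 1, "dispensable": 2, "softcore": 3, "core": 4}


@dataclass(frozen=True)
class ClassificationRules:
    softcore_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.softcore_fraction < 1.0:
            raise ValueError("softcore_fraction must be in (0, 1)")

    def category(self, m: int, n: int) -> str:
        """Category of a family present in m of n accessions.

        The softcore bound ``m > t*n`` is evaluated in exact rational
        arithmetic so the strict inequality is exact at integer boundaries.
        """
        if m == 0:
            return "absent"
        if m == n:
            return "core"
        if m == 1:
            return "private"
        t = Fraction(str(self.softcore_fraction))
        if Fraction(m) > t * n:
            return "softcore"
        return "dispensable"

    def softcore_range(self, n: int) -> tuple[int, int] | None:
        """Legal presence counts (lo, hi) for softcore at sample size n, or None."""
        t = Fraction(str(self.softcore_fraction))
        lo = int(t * n) + 1
        hi = n - 1
        return (lo, hi) if lo <= hi else None


def matrix_from_orthogroups(table: OrthogroupTable) -> pd.DataFrame:
    counts = table.counts()
    df = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    return df.reindex(columns=table.accessions, fill_value=0)


def presence_counts(matrix: pd.DataFrame) -> pd.Series:
    """m_f per family: number of accessions with count >= 1."""
    return (matrix >= 1).sum(axis=1)


def classify(
    matrix: pd.DataFrame, rules: ClassificationRules = ClassificationRules()
) -> tuple[pd.Series, dict[str, int]]:
    """Per-family category labels and per-category family counts.

    Families absent everywhere are labelled ``"absent"`` and excluded from
    the returned counts, which therefore sum to the number of families with
    m_f >= 1.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("need at least 3 accessions to classify")
    m = presence_counts(matrix)
    labels = m.map(lambda mf: rules.category(int(mf), n)).rename("category")
    counts = {cat: int((labels == cat).sum()) for cat in CATEGORIES}
    return labels, counts


def composition(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-accession gene-level category fractions (Fig-style composition).

    Uses each accession's gene *counts*, not family presence, so an accession
    carrying two copies of a core-family gene contributes both to the core
    fraction. Rows sum to 1.
    """
    out = {}
    for cat in CATEGORIES:
        fams = labels.index[labels == cat]
        out[cat] = matrix.loc[fams].sum(axis=0)
    df = pd.DataFrame(out).astype(float)
    totals = matrix.sum(axis=0).astype(float)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"accessions with zero genes: {empty}")
    return df.div(totals, axis=0)


# ---------------------------------------------------------------------------
# orthogroup fusion


def _reciprocal_best_hits(
    hits: list[HomologyHit], gene_acc: dict[str, str]
) -> set[tuple[str, str]]:
    """Gene pairs that are each other's best hit in the partner accession.

    Best = highest score among a query's hits into one target accession;
    score ties break lexicographically on target gene id (determinism).
    """
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for h in hits:
        key = (h.query, gene_acc[h.target])
        cur = best.get(key)
        cand = (-h.score, h.target)
        if cur is None or cand < cur:
            best[key] = cand
    pairs: set[tuple[str, str]] = set()
    for (query, _), (_, target) in best.items():
        back = best.get((target, gene_acc[query]))
        if back is not None and back[1] == query:
            pairs.add((min(query, target), max(query, target)))
    return pairs


def fuse_orthogroups(
    table: OrthogroupTable,
    hits: list[HomologyHit],
    cov_threshold: float = 0.95,
) -> OrthogroupTable:
    """Merge over-split families linked by high-coverage reciprocal best hits.

    A hit qualifies iff both coverages are >= ``cov_threshold`` *and* the
    gene pair is a reciprocal best hit; qualifying hits joining genes of
    different families union those families (transitive closure). The result
    is independent of hit order and idempotent.
    """
    gene_fam = table.gene_to_family()
    gene_acc = table.gene_to_accession()
    unknown = sorted(
        {g for h in hits for g in (h.query, h.target) if g not in gene_fam}
    )
    if unknown:
        raise ValueError(f"hits reference unknown genes: {unknown[:10]}")

    rbh = _reciprocal_best_hits(hits, gene_acc)
    qualifying = {
        (min(h.query, h.target), max(h.query, h.target))
        for h in hits
        if h.cov_query >= cov_threshold
        and h.cov_target >= cov_threshold
        and (min(h.query, h.target), max(h.query, h.target)) in rbh
    }

    parent = {fam: fam for fam in table.families}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(qualifying):
        ra, rb = find(gene_fam[a]), find(gene_fam[b])
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    groups: dict[str, list[str]] = {}
    for fam in table.families:
        groups.setdefault(find(fam), []).append(fam)

    families: dict[str, dict[str, list[str]]] = {}
    for root, members in sorted(groups.items()):
        merged: dict[str, list[str]] = {}
        for fam in sorted(members):
            for acc, genes in table.families[fam].items():
                merged.setdefault(acc, []).extend(genes)
        families[root] = {acc: sorted(genes) for acc, genes in merged.items()}
    return OrthogroupTable(families=families, accessions=list(table.accessions))


# ---------------------------------------------------------------------------
# split / merge annotation artifacts


def _interval_union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    end_prev = 0
    for s, e in sorted(spans):
        s = max(s, end_prev + 1)
        if e >= s:
            total += e - s + 1
            end_prev = e
    return total


def flag_split_merge(
    table: OrthogroupTable,
    gene_models: dict[str, GeneModel],
    hits: list[HomologyHit],
    cov_threshold: float = 0.95,
    reference_accession: str | None = None,
) -> pd.Series:
    """Flag families whose presence pattern stems from split/merged gene models.

    A family is flagged when some accession holds >= 2 genes *adjacent in
    that accession's gene order* whose alignments onto the family
    representative each cover < ``cov_threshold`` of it individually but
    cover >= ``cov_threshold`` jointly (union of covered positions). The
    representative is the member from ``reference_accession`` when present
    (longest such member), otherwise the longest member of the family; ties
    break on gene id.
    """
    missing = [
        g
        for per_acc in table.families.values()
        for genes in per_acc.values()
        for g in genes
        if g not in gene_models
    ]
    if missing:
        raise ValueError(f"genes without coordinates: {sorted(missing)[:10]}")

    # per-accession genome order rank
    rank: dict[str, int] = {}
    by_acc: dict[str, list[GeneModel]] = {}
    for g in gene_models.values():
        by_acc.setdefault(g.accession, []).append(g)
    for acc_genes in by_acc.values():
        acc_genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
        for i, g in enumerate(acc_genes):
            rank[g.gene_id] = i

    hits_to: dict[str, list[HomologyHit]] = {}
    for h in hits:
        hits_to.setdefault(h.target, []).append(h)

    flags = {}
    for fam, per_acc in table.families.items():
        members = [g for genes in per_acc.values() for g in genes]
        if len(members) < 2:
            flags[fam] = False
            continue
        pool = (
            per_acc.get(reference_accession)
            if reference_accession is not None and per_acc.get(reference_accession)
            else members
        )
        rep = max(pool, key=lambda g: (gene_models[g].length, g))
        rep_len = gene_models[rep].length
        rep_hits = {h.query: h for h in hits_to.get(rep, [])}

        flagged = False
        for acc, genes in per_acc.items():
            if len(genes) < 2 or flagged:
                continue
            ordered = sorted(genes, key=lambda g: rank[g])
            for g1, g2 in zip(ordered, ordered[1:]):
                if rank[g2] - rank[g1] != 1:
                    continue
                h1, h2 = rep_hits.get(g1), rep_hits.get(g2)
                if h1 is None or h2 is None:
                    continue
                if h1.cov_target >= cov_threshold or h2.cov_target >= cov_threshold:
                    continue
                union = _interval_union_length(
                    [
                        (h1.target_start, h1.target_end),
                        (h2.target_start, h2.target_end),
                    ]
                )
                if union >= cov_threshold * rep_len:
                    flagged = True
                    break
        flags[fam] = flagged
    return pd.Series(flags, name="split_merge").reindex(table.families.keys())


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction_exact(matrix: pd.DataFrame, sizes=None) -> pd.DataFrame:
    """Closed-form expected pan/core sizes under uniform subsampling.

    E[pan(k)] = sum_f [1 - C(n - m_f, k) / C(n, k)],
    E[core(k)] = sum_f C(m_f, k) / C(n, k),
    summing over families with m_f >= 1.
    """
    n = matrix.shape[1]
    m = presence_counts(matrix)
    m = m[m >= 1].to_numpy()
    if sizes is None:
        sizes = range(1, n + 1)
    rows = []
    for k in sizes:
        if not 1 <= k <= n:
            raise ValueError(f"subset size {k} outside [1, {n}]")
        denom = comb(n, k)
        pan = sum(1.0 - comb(n - mf, k) / denom for mf in m)
        core = sum(comb(mf, k) / denom for mf in m)
        rows.append((k, pan, core))
    return pd.DataFrame(rows, columns=["k", "pan_mean", "core_mean"]).set_index("k")


def rarefaction_mc(
    matrix: pd.DataFrame,
    sizes=None,
    replicates: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo pan/core rarefaction curve.

    For each subset size k, draws ``replicates`` uniform accession subsets
    without replacement (subsets may repeat across replicates); pan = number
    of families present in >= 1 sampled accession, core = present in all
    sampled. Deterministic given ``seed``. Columns: pan/core mean and sd.
    """
    n = matrix.shape[1]
    if sizes is None:
        sizes = range(2, n - 1)
    sizes = list(sizes)
    for k in sizes:
        if not 1 <= k <= n:
            raise ValueError(f"subset size {k} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    presence = (matrix.to_numpy() >= 1)
    presence = presence[presence.any(axis=1)]
    pres_f = presence.astype(np.float32)

    rows = []
    for k in sizes:
        # one-hot sample matrix (n x R): matmul gives per-family sampled-presence counts
        sel = np.zeros((n, replicates), dtype=np.float32)
        for r in range(replicates):
            sel[rng.choice(n, size=k, replace=False), r] = 1.0
        counts = pres_f @ sel
        pan = (counts > 0.5).sum(axis=0)
        core = (counts > k - 0.5).sum(axis=0)
        rows.append(
            (
                k,
                float(pan.mean()),
                float(pan.std(ddof=0)),
                float(core.mean()),
                float(core.std(ddof=0)),
            )
        )
    df = pd.DataFrame(
        rows, columns=["k", "pan_mean", "pan_sd", "core_mean", "core_sd"]
    ).set_index("k")
    df.attrs["replicates"] = replicates
    df.attrs["seed"] = seed
    return df
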