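"""Synthetic pan-genome generator with known ground truth.

Emulates the statistical structure the analysis stages assume, so every
stage is testable without sequencing data:

* a families x accessions presence/absence matrix with configurable
  category proportions (default 60/5/17/18% core/softcore/dispensable/
  private, the composition observed in the 69-accession study);
* a homology hit table planting over-split orthogroups (to exercise RBH
  fusion) and split/merged gene models (to exercise split-merge flagging);
* per-accession synteny-block annotations on a shared reference coordinate
  system with planted arm inversions (including one inversion shared by a
  configurable accession subset), indels, and structurally scrambled
  centromeres;
* assemblies carrying 178-bp centromeric and 7-bp telomeric tandem arrays
  whose total length is linearly coupled to genome size, plus genome and
  motif-concatemer depth tracks for the depth-ratio estimator.

One global seed drives four independent substreams (presence/absence,
homology, synteny, repeats/depth) via ``numpy.random.SeedSequence.spawn``,
so outputs are reproducible per component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panclass import ClassificationRules
from .records import DepthTrack, GeneModel, HomologyHit, OrthogroupTable, SVRecord, SyntenyBlock


class SimulationConfigError(ValueError):
    """Configuration that cannot produce a valid simulation."""


#: Synthetic 178-bp centromeric monomer consensus (fixed arbitrary sequence;
#: stands in for a real satellite consensus, which matters only by length here).
CEN_MOTIF_178 = (
    "GTAAAACTACTGTTCGGATATGGTGAGTACTCTGCGCCTTACTTGGGCGACAAGGTTTAT"
    "CCGCTACAAGCTCCGTAGCTACTATCGCCGCCTTTGTCGCACTAGCGAAAAAACTTTCTA"
    "AAAGTATGGTCACGTACCTTAGACTTGCGCCATCGGCATGGTACCTACGAAAATATCC"
)

#: Plant telomeric repeat unit.
TEL_MOTIF_7 = "TTTAGGG"

_DEFAULT_CHROM_LENGTHS = {
    "Chr1": 30_400_000,
    "Chr2": 19_700_000,
    "Chr3": 23_500_000,
    "Chr4": 18_600_000,
    "Chr5": 27_000_000,
}

_DEFAULT_CENTROMERES = {
    "Chr1": (13_500_000, 17_500_000),
    "Chr2": (2_500_000, 5_500_000),
    "Chr3": (12_000_000, 15_500_000),
    "Chr4": (2_800_000, 5_800_000),
    "Chr5": (10_500_000, 14_500_000),
}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator (see docs/methods.md)."""

    n_accessions: int = 69
    n_families: int = 5000
    category_props: tuple[float, float, float, float] = (0.60, 0.05, 0.17, 0.18)
    softcore_fraction: float = 0.90
    split_merge_rate: float = 0.05
    oversplit_rate: float = 0.05
    near_miss_rate: float = 0.02
    ref_chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_LENGTHS)
    )
    centromere_spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_CENTROMERES)
    )
    inversion_rate_per_genome: float = 0.1
    inversion_size_range: tuple[int, int] = (1_000_000, 2_500_000)
    indel_rate_per_genome: float = 20.0
    indel_size_max: int = 10_000
    shared_inversion_chrom: str = "Chr4"
    shared_inversion_size: int = 1_200_000
    shared_inversion_carriers: int = 8
    motif_cen: str = CEN_MOTIF_178
    motif_tel: str = TEL_MOTIF_7
    copy_range: tuple[int, int] = (50, 150)
    telomere_copies: int = 50
    arm_length: int = 15_000
    divergence_rate: float = 0.05
    size_coupling_noise_sd: float = 4500.0
    depth_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 3:
            raise SimulationConfigError("need n_accessions >= 3")
        if abs(sum(self.category_props) - 1.0) > 1e-12:
            raise SimulationConfigError("category_props must sum to 1")
        if any(p < 0 for p in self.category_props):
            raise SimulationConfigError("category_props must be non-negative")
        if any(length <= 0 for length in self.ref_chrom_lengths.values()):
            raise SimulationConfigError("chromosome lengths must be positive")
        for chrom, (s, e) in self.centromere_spans.items():
            if chrom not in self.ref_chrom_lengths:
                raise SimulationConfigError(f"centromere on unknown chromosome {chrom}")
            if not 1 <= s <= e <= self.ref_chrom_lengths[chrom]:
                raise SimulationConfigError(
                    f"centromere span {chrom}:{s}-{e} outside chromosome bounds"
                )
        if set(self.motif_cen.upper()) - set("ACGT") or set(
            self.motif_tel.upper()
        ) - set("ACGT"):
            raise SimulationConfigError("motifs must be plain DNA")
        if self.copy_range[0] > self.copy_range[1] or self.copy_range[0] < 1:
            raise SimulationConfigError("invalid copy_range")
        if self.arm_length <= 0 or self.indel_size_max < 20:
            raise SimulationConfigError("invalid length parameter")
        if self.depth_mean <= 0:
            raise SimulationConfigError("depth_mean must be positive")

    def accessions(self) -> list[str]:
        return [f"acc{i + 1:03d}" for i in range(self.n_accessions)]

    # substream indices: 0 = pav, 1 = homology, 2 = synteny, 3 = repeats
    def rng(self, component: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[component])


@dataclass
class SimTruth:
    """Everything the generator knows; the yardstick for every stage."""

    family_category: pd.Series | None = None
    split_merge_flag: pd.Series | None = None
    orthogroups_true: OrthogroupTable | None = None
    orthogroups_observed: OrthogroupTable | None = None
    oversplit_pairs: list[tuple[str, str]] = field(default_factory=list)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    planted_svs: dict[str, list[SVRecord]] = field(default_factory=dict)
    shared_inversion: dict | None = None
    true_repeat_length: dict[str, dict[str, int]] = field(default_factory=dict)
    assembled_repeat_length: dict[str, dict[str, int]] = field(default_factory=dict)
    true_genome_size: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# presence/absence


def simulate_pav(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Presence/absence matrix plus truth (categories, gene models, tables).

    Category counts are a multinomial draw from ``category_props``. Core
    families are present in all n accessions, private in exactly one;
    softcore presence counts are uniform over the legal strict-inequality
    range (e.g. 63–68 at n=69), dispensable uniform over [2, bound]. The
    observed orthogroup table additionally carries planted over-split
    families (for fusion) and split gene models (for split–merge flagging);
    the returned matrix is the *true*-family matrix.
    """
    rng = config.rng(0)
    n = config.n_accessions
    accs = config.accessions()
    rules = ClassificationRules(config.softcore_fraction)

    counts = rng.multinomial(config.n_families, config.category_props)
    soft_range = rules.softcore_range(n)
    if counts[1] > 0 and soft_range is None:
        raise SimulationConfigError(
            f"softcore proportion > 0 but no legal presence count at n={n}"
        )
    disp_hi = (soft_range[0] - 1) if soft_range else n - 1
    if counts[2] > 0 and disp_hi < 2:
        raise SimulationConfigError("dispensable range empty at this n")

    cats = np.repeat(
        np.array(["core", "softcore", "dispensable", "private"]), counts
    )
    rng.shuffle(cats)
    fam_ids = [f"OG{i:06d}" for i in range(config.n_families)]

    membership: dict[str, np.ndarray] = {}
    for fam, cat in zip(fam_ids, cats):
        if cat == "core":
            m = n
        elif cat == "softcore":
            m = int(rng.integers(soft_range[0], soft_range[1] + 1))
        elif cat == "dispensable":
            m = int(rng.integers(2, disp_hi + 1))
        else:
            m = 1
        membership[fam] = np.sort(rng.choice(n, size=m, replace=False))

    # --- plant split-merge artifacts (families present in >= 2 accessions)
    eligible = [f for f in fam_ids if len(membership[f]) >= 2]
    n_sm = min(int(round(config.split_merge_rate * config.n_families)), len(eligible))
    sm_fams = set(
        rng.choice(np.array(eligible), size=n_sm, replace=False)
    ) if n_sm else set()

    # --- choose over-split families (disjoint from split-merge set)
    eligible_os = [f for f in eligible if f not in sm_fams]
    n_os = min(int(round(config.oversplit_rate * config.n_families)), len(eligible_os))
    os_fams = set(
        rng.choice(np.array(eligible_os), size=n_os, replace=False)
    ) if n_os else set()

    # --- gene-level construction
    fam_base_len = {
        fam: int(rng.integers(900, 3000)) for fam in fam_ids
    }
    split_accession = {
        fam: int(membership[fam][rng.integers(len(membership[fam]))])
        for fam in sorted(sm_fams)  # sorted: set order is hash-salted per process
    }

    # units per accession: (family, n_genes_here)
    units_per_acc: dict[int, list[tuple[str, int]]] = {i: [] for i in range(n)}
    for fam in fam_ids:
        for acc_i in membership[fam]:
            two = fam in sm_fams and split_accession[fam] == acc_i
            units_per_acc[int(acc_i)].append((fam, 2 if two else 1))

    gene_models: dict[str, GeneModel] = {}
    true_families: dict[str, dict[str, list[str]]] = {
        fam: {} for fam in fam_ids
    }
    for acc_i in range(n):
        acc = accs[acc_i]
        units = units_per_acc[acc_i]
        order = rng.permutation(len(units))
        cursor = 1
        gene_idx = 0
        for u in order:
            fam, n_genes = units[u]
            base = fam_base_len[fam]
            ids = []
            if n_genes == 1:
                lengths = [max(300, base + int(rng.integers(-50, 51)))]
            else:  # split gene models: two halves of the representative
                lengths = [
                    max(200, int(base * 0.5) + int(rng.integers(-60, 61))),
                    max(200, int(base * 0.5) + int(rng.integers(-60, 61))),
                ]
            for length in lengths:
                gid = f"{acc}_g{gene_idx:05d}"
                gene_idx += 1
                gene_models[gid] = GeneModel(
                    accession=acc,
                    gene_id=gid,
                    chrom="chr1",
                    start=cursor,
                    end=cursor + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                )
                cursor += length + 500
                ids.append(gid)
            true_families[fam][acc] = ids

    table_true = OrthogroupTable(families=true_families, accessions=accs)

    # --- observed table: over-split families appear as two orthogroups
    observed: dict[str, dict[str, list[str]]] = {}
    oversplit_pairs: list[tuple[str, str]] = []
    for fam in fam_ids:
        per_acc = true_families[fam]
        if fam in os_fams:
            members = sorted(per_acc)
            cut = int(rng.integers(1, len(members)))
            part_a, part_b = members[:cut], members[cut:]
            observed[fam + "_a"] = {a: list(per_acc[a]) for a in part_a}
            observed[fam + "_b"] = {a: list(per_acc[a]) for a in part_b}
            oversplit_pairs.append((fam + "_a", fam + "_b"))
        else:
            observed[fam] = {a: list(g) for a, g in per_acc.items()}
    table_obs = OrthogroupTable(families=observed, accessions=accs)

    matrix = pd.DataFrame.from_dict(
        {
            fam: {acc: len(per_acc.get(acc, ())) for acc in accs}
            for fam, per_acc in true_families.items()
        },
        orient="index",
        dtype=np.int64,
    ).reindex(columns=accs, fill_value=0)

    truth = SimTruth(
        family_category=pd.Series(dict(zip(fam_ids, cats)), name="category"),
        split_merge_flag=pd.Series(
            {f: f in sm_fams for f in fam_ids}, name="split_merge"
        ),
        orthogroups_true=table_true,
        orthogroups_observed=table_obs,
        oversplit_pairs=oversplit_pairs,
        gene_models=gene_models,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# homology hits


def simulate_homology(
    pav: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> list[HomologyHit]:
    """Pairwise gene hits exercising fusion and split–merge detection.

    Plants, with disjoint score bands so reciprocal-best relations are
    unambiguous: (a) reciprocal >= 95%-coverage hits across each over-split
    orthogroup pair; (b) for each split–merge family, hits from the two
    split genes onto the family representative covering disjoint portions
    (< 95% each, >= 95% jointly); (c) reciprocal within-family hits for a
    background sample; (d) sub-threshold and non-reciprocal near-miss hits
    across random family pairs, which must never cause fusion.
    """
    if truth.orthogroups_true is None:
        raise ValueError("run simulate_pav first")
    rng = config.rng(1)
    gm = truth.gene_models
    table = truth.orthogroups_true
    hits: list[HomologyHit] = []

    def span_for(cov: float, length: int, start: int = 1) -> tuple[int, int]:
        covered = max(1, int(round(cov * length)))
        return start, min(start + covered - 1, length)

    # (a) fusion pairs across over-split orthogroups
    obs = truth.orthogroups_observed.families
    for og_a, og_b in truth.oversplit_pairs:
        genes_a = [g for gl in obs[og_a].values() for g in gl]
        genes_b = [g for gl in obs[og_b].values() for g in gl]
        ga = max(genes_a, key=lambda g: (gm[g].length, g))
        gb = max(genes_b, key=lambda g: (gm[g].length, g))
        cov_a = float(rng.uniform(0.955, 0.995))
        cov_b = float(rng.uniform(0.955, 0.995))
        score = float(rng.uniform(1000, 1100))
        sa, ea = span_for(cov_b, gm[gb].length)
        sb, eb = span_for(cov_a, gm[ga].length)
        hits.append(HomologyHit(ga, gb, cov_a, cov_b, score, sa, ea))
        hits.append(HomologyHit(gb, ga, cov_b, cov_a, score, sb, eb))

    # (b) split-merge: two adjacent genes jointly tiling the representative
    sm_fams = truth.split_merge_flag[truth.split_merge_flag].index
    for fam in sm_fams:
        per_acc = table.families[fam]
        split_acc = next(a for a, gl in per_acc.items() if len(gl) == 2)
        g1, g2 = sorted(per_acc[split_acc], key=lambda g: gm[g].start)
        members = [g for gl in per_acc.values() for g in gl]
        rep = max(members, key=lambda g: (gm[g].length, g))
        rep_len = gm[rep].length
        c1 = float(rng.uniform(0.35, 0.55))
        joint = float(rng.uniform(0.955, 0.99))
        cut = int(round(c1 * rep_len))
        end2 = int(round(joint * rep_len))
        score = float(rng.uniform(700, 780))
        hits.append(
            HomologyHit(g1, rep, 0.97, cut / rep_len, score, 1, cut)
        )
        hits.append(
            HomologyHit(g2, rep, 0.97, (end2 - cut) / rep_len, score, cut + 1, end2)
        )

    # (c) background within-family reciprocal hits
    multi = [
        f
        for f, per_acc in table.families.items()
        if sum(len(g) for g in per_acc.values()) >= 2
        and not truth.split_merge_flag.get(f, False)
    ]
    n_bg = min(len(multi), max(10, config.n_families // 10))
    for fam in rng.choice(np.array(multi), size=n_bg, replace=False):
        per_acc = table.families[fam]
        genes = [g for gl in per_acc.values() for g in gl]
        g1, g2 = rng.choice(np.array(genes), size=2, replace=False)
        cov = float(rng.uniform(0.96, 1.0))
        score = float(rng.uniform(800, 900))
        s1, e1 = span_for(cov, gm[g2].length)
        s2, e2 = span_for(cov, gm[g1].length)
        hits.append(HomologyHit(str(g1), str(g2), cov, cov, score, s1, e1))
        hits.append(HomologyHit(str(g2), str(g1), cov, cov, score, s2, e2))

    # (d) near misses: sub-threshold reciprocal, and non-reciprocal one-way
    plain = [
        f
        for f in table.families
        if f not in set(sm_fams)
        and not any(f in (a[:-2], b[:-2]) for a, b in truth.oversplit_pairs)
    ]
    n_nm = min(len(plain) // 2, int(round(config.near_miss_rate * config.n_families)))
    if n_nm:
        chosen = rng.choice(np.array(plain), size=2 * n_nm, replace=False)
        for i in range(n_nm):
            fa, fb = chosen[2 * i], chosen[2 * i + 1]
            ga = [g for gl in table.families[fa].values() for g in gl][0]
            gb = [g for gl in table.families[fb].values() for g in gl][0]
            score = float(rng.uniform(600, 680))
            if rng.random() < 0.5:  # reciprocal but below coverage threshold
                cov_lo = float(rng.uniform(0.80, 0.945))
                cov_hi = float(rng.uniform(0.96, 1.0))
                sa, ea = span_for(cov_lo, gm[gb].length)
                sb, eb = span_for(cov_hi, gm[ga].length)
                hits.append(HomologyHit(ga, gb, cov_hi, cov_lo, score, sa, ea))
                hits.append(HomologyHit(gb, ga, cov_lo, cov_hi, score, sb, eb))
            else:  # high coverage but one-directional (not reciprocal best)
                sa, ea = span_for(0.97, gm[gb].length)
                hits.append(HomologyHit(ga, gb, 0.97, 0.97, score, sa, ea))
    return hits


# ---------------------------------------------------------------------------
# synteny blocks


def simulate_synteny(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[dict[str, list[SyntenyBlock]], SimTruth]:
    """Per-accession reference-anchored block annotations with planted SVs.

    Chromosome arms are SYN except planted inversions and indels; the
    centromere spans are scrambled into NOTAL/INV/TRANS/DUP segments with
    per-accession random haplotype structure. One inversion of configured
    size is shared by a configured accession subset (with small per-
    accession breakpoint jitter); remaining arm inversions are private,
    Poisson-distributed per genome.
    """
    if truth is None:
        truth = SimTruth()
    rng = config.rng(2)
    accs = config.accessions()
    lengths = config.ref_chrom_lengths
    cens = config.centromere_spans

    # arms as (chrom, start, end)
    arms: list[tuple[str, int, int]] = []
    for chrom, L in lengths.items():
        if chrom in cens:
            cs, ce = cens[chrom]
            if cs > 1:
                arms.append((chrom, 1, cs - 1))
            if ce < L:
                arms.append((chrom, ce + 1, L))
        else:
            arms.append((chrom, 1, L))
    longest_arm = max(e - s + 1 for _, s, e in arms)
    if config.inversion_size_range[0] > longest_arm:
        raise SimulationConfigError(
            "inversion_size_range lower bound exceeds every chromosome arm"
        )

    # shared inversion locus: just distal to the centromere (pericentromeric)
    sh_chrom = config.shared_inversion_chrom
    sh_size = config.shared_inversion_size
    carrier_names: list[str] = []
    sh_start = sh_end = 0
    if config.shared_inversion_carriers > 0:
        if sh_chrom not in lengths:
            raise SimulationConfigError(
                f"shared inversion chromosome {sh_chrom} not in ref_chrom_lengths"
            )
        cs, ce = cens.get(sh_chrom, (lengths[sh_chrom] // 2, lengths[sh_chrom] // 2))
        sh_end = cs - 50_000
        sh_start = sh_end - sh_size + 1
        if sh_start < 1:
            sh_start = ce + 50_000
            sh_end = sh_start + sh_size - 1
        if sh_end > lengths[sh_chrom]:
            raise SimulationConfigError("shared inversion does not fit its chromosome")
        carriers = sorted(
            rng.choice(
                config.n_accessions, size=config.shared_inversion_carriers, replace=False
            )
        )
        carrier_names = [accs[i] for i in carriers]

    blocks_by_acc: dict[str, list[SyntenyBlock]] = {}
    planted: dict[str, list[SVRecord]] = {}
    cen_types = np.array(["NOTAL", "INV", "TRANS", "DUP"])
    cen_probs = np.array([0.5, 0.2, 0.2, 0.1])

    for acc_i, acc in enumerate(accs):
        events: dict[str, list[tuple[int, int, str]]] = {c: [] for c in lengths}
        svs: list[SVRecord] = []

        if acc in carrier_names:
            j1 = int(rng.integers(0, 2001))
            j2 = int(rng.integers(0, 2001))
            s, e = sh_start + j1, sh_end + j2
            events[sh_chrom].append((s, e, "INV"))
            svs.append(
                SVRecord(acc, "INV", sh_chrom, s, e, e - s + 1)
            )

        # private arm inversions
        for _ in range(rng.poisson(config.inversion_rate_per_genome)):
            for _attempt in range(50):
                chrom, a_s, a_e = arms[rng.integers(len(arms))]
                size = int(
                    rng.integers(
                        config.inversion_size_range[0],
                        config.inversion_size_range[1] + 1,
                    )
                )
                if size > a_e - a_s + 1:
                    continue
                start = int(rng.integers(a_s, a_e - size + 2))
                end = start + size - 1
                if any(
                    not (end < s0 or start > e0)
                    for s0, e0, _t in events[chrom]
                ):
                    continue
                events[chrom].append((start, end, "INV"))
                svs.append(SVRecord(acc, "INV", chrom, start, end, size))
                break

        # small indels (truth + SV records only; below block resolution)
        for _ in range(rng.poisson(config.indel_rate_per_genome)):
            chrom, a_s, a_e = arms[rng.integers(len(arms))]
            size = int(rng.integers(20, config.indel_size_max + 1))
            pos = int(rng.integers(a_s, a_e - size + 2))
            if rng.random() < 0.5:
                svs.append(SVRecord(acc, "DEL", chrom, pos, pos + size - 1, size))
            else:
                svs.append(SVRecord(acc, "INS", chrom, pos, pos, size))

        # centromere haplotype scramble
        for chrom, (cs_, ce_) in cens.items():
            n_seg = int(rng.integers(3, 9))
            cuts = np.sort(rng.choice(ce_ - cs_, size=n_seg - 1, replace=False))
            bounds = [cs_] + [cs_ + int(c) + 1 for c in cuts] + [ce_ + 1]
            for s0, e0 in zip(bounds[:-1], bounds[1:]):
                t = str(rng.choice(cen_types, p=cen_probs))
                events[chrom].append((s0, e0 - 1, t))

        blocks: list[SyntenyBlock] = []
        for chrom, L in lengths.items():
            evs = sorted(events[chrom])
            cursor = 1
            for s, e, t in evs:
                if s > cursor:
                    blocks.append(
                        SyntenyBlock(chrom, cursor, s - 1, chrom, cursor, s - 1, "SYN", acc)
                    )
                qs, qe = (e, s) if t == "INV" else (s, e)
                if t == "NOTAL":
                    blocks.append(
                        SyntenyBlock(chrom, s, e, "-", 0, 0, "NOTAL", acc)
                    )
                else:
                    blocks.append(
                        SyntenyBlock(chrom, s, e, chrom, min(qs, qe), max(qs, qe), t, acc)
                    )
                cursor = e + 1
            if cursor <= L:
                blocks.append(
                    SyntenyBlock(chrom, cursor, L, chrom, cursor, L, "SYN", acc)
                )
        blocks_by_acc[acc] = blocks
        planted[acc] = svs

    truth.planted_svs = planted
    truth.shared_inversion = (
        {
            "chrom": sh_chrom,
            "start": sh_start,
            "end": sh_end,
            "carriers": carrier_names,
        }
        if carrier_names
        else None
    )
    return blocks_by_acc, truth


# ---------------------------------------------------------------------------
# repeats + depth


@dataclass
class RepeatDepthSim:
    """Sequences and depth tracks for one simulated accession panel."""

    sequences: dict[str, dict[str, str]]  # accession -> chrom -> sequence
    genome_depth: dict[str, dict[str, DepthTrack]]
    concatemer_depth: dict[str, DepthTrack]
    truth: SimTruth


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return motif
    arr = np.frombuffer(motif.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()


def simulate_repeats_and_depth(
    config: SimConfig,
    truth: SimTruth | None = None,
    n_accessions: int | None = None,
    truncation: float = 1.0,
    noise: bool = True,
) -> RepeatDepthSim:
    """Assemblies with tandem arrays plus genome and concatemer depth tracks.

    Per chromosome the assembly is telomere array + arm + centromeric array
    + arm + telomere array; centromeric copy number is uniform over
    ``copy_range`` and per-copy divergence i.i.d. substitutions at
    ``divergence_rate``. Genome size is thus base + total repeat length plus
    a Gaussian term (``size_coupling_noise_sd``) absorbed into the last arm.

    ``truncation`` < 1 writes only that fraction of each centromeric
    array's copies into the assembly (emulating incomplete assemblies) while
    depth tracks still reflect the full arrays, so the planted completeness
    ratio is ``truncation``. With ``noise=False`` depth tracks are exact
    constant-rate tracks instead of Poisson draws.
    """
    if truth is None:
        truth = SimTruth()
    if not 0 < truncation <= 1:
        raise SimulationConfigError("truncation must be in (0, 1]")
    rng = config.rng(3)
    n = n_accessions if n_accessions is not None else config.n_accessions
    accs = config.accessions()[:n]
    chroms = list(config.ref_chrom_lengths)
    m = len(config.motif_cen)
    conc_len = 4 * m

    sequences: dict[str, dict[str, str]] = {}
    genome_depth: dict[str, dict[str, DepthTrack]] = {}
    conc_depth: dict[str, DepthTrack] = {}

    for acc in accs:
        seqs: dict[str, str] = {}
        tracks: dict[str, DepthTrack] = {}
        per_chrom_true: dict[str, int] = {}
        per_chrom_assembled: dict[str, int] = {}
        delta = int(round(rng.normal(0.0, config.size_coupling_noise_sd)))
        tel = config.motif_tel * config.telomere_copies
        for ci, chrom in enumerate(chroms):
            copies = int(rng.integers(config.copy_range[0], config.copy_range[1] + 1))
            kept = max(1, int(round(truncation * copies)))
            array = "".join(
                _mutate(config.motif_cen, config.divergence_rate, rng)
                for _ in range(copies)
            )
            arm_extra = delta if ci == len(chroms) - 1 else 0
            right_arm_len = max(500, config.arm_length + arm_extra)
            left = _random_dna(config.arm_length, rng)
            right = _random_dna(right_arm_len, rng)
            assembled_array = array[: kept * m]
            seqs[chrom] = tel + left + assembled_array + right + tel
            per_chrom_true[chrom] = copies * m
            per_chrom_assembled[chrom] = kept * m
            if noise:
                depth = rng.poisson(config.depth_mean, size=len(seqs[chrom])).astype(float)
            else:
                depth = np.full(len(seqs[chrom]), config.depth_mean)
            tracks[chrom] = DepthTrack(chrom=chrom, depth=depth)

        total_true = sum(per_chrom_true.values())
        lam = config.depth_mean * total_true / conc_len
        if noise:
            conc = rng.poisson(lam, size=conc_len).astype(float)
        else:
            conc = np.full(conc_len, lam)
        conc_depth[acc] = DepthTrack(chrom="cen_concatemer_x4", depth=conc)

        sequences[acc] = seqs
        genome_depth[acc] = tracks
        truth.true_repeat_length[acc] = per_chrom_true
        truth.assembled_repeat_length[acc] = per_chrom_assembled
        # true size: full arrays regardless of assembly truncation
        truth.true_genome_size[acc] = sum(
            len(seqs[c]) + (per_chrom_true[c] - per_chrom_assembled[c])
            for c in chroms
        )
    return RepeatDepthSim(
        sequences=sequences,
        genome_depth=genome_depth,
        concatemer_depth=conc_depth,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# truth serialisation


def truth_to_json(truth: SimTruth, path) -> None:
    payload = {
        "family_category": (
            truth.family_category.to_dict() if truth.family_category is not None else None
        ),
        "split_merge_flag": (
            {k: bool(v) for k, v in truth.split_merge_flag.items()}
            if truth.split_merge_flag is not None
            else None
        ),
        "oversplit_pairs": truth.oversplit_pairs,
        "planted_svs": {
            acc: [asdict(r) for r in recs] for acc, recs in truth.planted_svs.items()
        },
        "shared_inversion": truth.shared_inversion,
        "true_repeat_length": truth.true_repeat_length,
        "assembled_repeat_length": truth.assembled_repeat_length,
        "true_genome_size": truth.true_genome_size,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def truth_from_json(path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        family_category=(
            pd.Series(payload["family_category"], name="category")
            if payload["family_category"] is not None
            else None
        ),
        split_merge_flag=(
            pd.Series(payload["split_merge_flag"], name="split_merge")
            if payload["split_merge_flag"] is not None
            else None
        ),
        oversplit_pairs=[tuple(p) for p in payload["oversplit_pairs"]],
        planted_svs={
            acc: [SVRecord(**r) for r in recs]
            for acc, recs in payload["planted_svs"].items()
        },
        shared_inversion=payload["shared_inversion"],
        true_repeat_length=payload["true_repeat_length"],
        assembled_repeat_length=payload["assembled_repeat_length"],
        true_genome_size=payload["true_genome_size"],
    )
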