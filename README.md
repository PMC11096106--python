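# pansynkit

Pan-genome analysis of chromosome-level plant assemblies, built around the
questions a multi-accession *Arabidopsis thaliana* assembly panel raises:
which gene families are core to the species and which are dispensable or
private, how colinear the genomes are along chromosomes, which structural
variants are shared across accessions, and how much of each centromere the
assemblies actually captured.

The package provides five analysis stages over standard formats
(OrthoFinder orthogroup tables, SyRI whole-genome-alignment annotations,
GFF3, FASTA, `samtools depth` tracks), plus a synthetic-data generator with
known ground truth so every stage is testable end to end without
sequencing data:

* **panclass** — gene-family presence/absence classification
  (core / softcore / dispensable / private by presence count, with a strict
  90% softcore bound: 63–68 of 69 accessions), orthogroup **fusion** via
  ≥ 95%-coverage reciprocal best hits, **split–merge** gene-model flagging,
  per-genome composition, and pan/core **rarefaction** — Monte-Carlo
  (2,000 subsets per size) with a closed-form oracle
  `E[pan(k)] = Σ_f [1 − C(n−m_f,k)/C(n,k)]`.
* **syndiv** — windowed synteny diversity on reference coordinates,
  `π_syn(w) = 2/(n(n−1)) Σ_{i<j} (1/|w|) Σ_{p∈w} (1 − s_i(p) s_j(p))`,
  0 = fully colinear panel, 1 = no colinearity; threshold genome fractions
  and pairwise colinearity matrices with group summaries.
* **svmerge** — SURVIVOR-style cross-accession SV merging in two size tiers
  (20 bp–10 kb at 1 kb breakpoint distance; > 10 kb at 20 kb), sharing
  spectra and megabase-scale rearrangement reports.
* **censize** — centromeric (178-bp) and telomeric (7-bp) tandem-array
  annotation by approximate motif matching, depth-ratio repeat-length
  estimation (Σ concatemer depth / genome mean depth), assembly
  completeness ratios, and genome-size correlation analyses.
* **synthetic** — seeded generator producing all of the above inputs with
  planted truth: category proportions, over-split orthogroups, split gene
  models, shared and private inversions, indels, scrambled centromeres,
  motif arrays coupled to genome size, and Poisson depth tracks.

## Worked example

`examples/` holds one short script per capability. Classifying a simulated
69-accession panel at the observed category proportions
(`python examples/01_classify_pangenome.py`):

```
orthogroups: 2100 observed -> 2000 after fusion
  core          1164 families (58.2%)
  softcore        97 families (4.8%)
  dispensable    341 families (17.1%)
  private        398 families (19.9%)
split-merge families flagged: 100 (planted: 100)

mean per-genome gene composition (fraction of each genome's genes):
core           0.8209
softcore       0.0649
dispensable    0.1101
private        0.0041
```

Fusion collapses the 100 planted over-split orthogroup pairs back to 2,000
true families; the recovered category split matches the generator's
60/5/17/18% proportions within sampling error; all 100 planted split–merge
artifacts are flagged with no false positives. The composition lines show
why core families dominate individual genomes (~82% of genes) despite being
only ~58% of the family catalogue: dispensable and private families are
each present in few genomes.

Synteny diversity over 69 simulated genomes
(`python examples/03_synteny_diversity.py`):

```
2379 windows of 100 kb (50 kb step) over 5 chromosomes
genome fraction with pi_syn < 0.2 (highly colinear): 84.1%
genome fraction with pi_syn > 0.5 (highly diverse):  14.7%

planted shared inversion Chr4:1550001-2750000 (8 carriers)
  mean pi_syn inside the inversion: 0.220
  mean pi_syn on colinear arms:     0.0043
```

Chromosome arms sit near 0, scrambled centromeres near 1, and the 1.2 Mb
inversion carried by 8 of 69 accessions raises π_syn to ≈ 2·8·61/(69·68)
≈ 0.21 across its span — the expected pair-breaking fraction.
`examples/04_sv_merging.py` then recovers that inversion as a single merged
cluster with support 8 among otherwise private megabase events, and
`examples/05_centromere_sizing.py` measures 90%-truncated assemblies at
completeness ≈ 0.90 from the depth ratio.

## Pipeline

The same stages run end to end from one YAML config, seeded and logged,
with a sha256 manifest making re-runs verifiably identical:

```bash
pansynkit run --config examples/pipeline_config.yaml
```

Subcommands (`pansynkit simulate|classify|syndiv|svmerge|censize|report`)
run stages standalone against an existing output directory.

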