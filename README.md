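# numtscan

Screening mitochondrial gene alignments for nuclear mitochondrial
pseudogenes (**numts**) — nuclear copies of mtDNA that co-amplify with the
genuine gene, masquerade as deeply divergent haplotypes, and can wreck
phylogeographic and population-genetic inference if they go unnoticed.

The package is aimed at anyone working with population samples of a
mitochondrial protein-coding fragment (DNA barcoders, invasion biologists,
phylogeographers) who finds suspiciously divergent haplotypes and needs a
reproducible *in silico* verdict: genuine mtDNA or putative numt.

## What it computes

Starting from a gapped FASTA alignment (optionally with sampling-site
labels in the description lines), the pipeline:

1. trims ragged alignment ends and collapses identical sequences into
   haplotypes with per-site counts, testing prevalence homogeneity across
   sites with Pearson's χ²;
2. computes uncorrected distances (count and proportion of differing
   sites) and Kimura 2-parameter distances under pairwise deletion,

       d = −½ ln[(1 − 2P − Q) √(1 − 2Q)]

   with P and Q the transition and transversion proportions;
3. profiles every haplotype–reference pair by codon position: shares of
   substitutions at positions 1/2/3, the transition/transversion split at
   third positions, and the nonsynonymous share (single-site swap on both
   codon backgrounds);
4. compares each profile metric with published mtDNA expectation intervals
   (mean ± half-width, α = 0.05) and calls a haplotype a putative numt when
   it has an internal stop codon, an indel, or ≥ k (default 3) of the six
   metrics beyond their interval on the pseudogene side (too many
   pos1/pos2/tv3/nonsynonymous changes, too few pos3/ts3);
5. builds a neighbor-joining tree on K2P distances and checks whether the
   flagged haplotypes form their own exclusive cluster relative to a
   trusted outgroup;
6. simulates the whole study design (genuine lineage + numt lineages +
   trusted reference, sampled individuals with truth labels) so every
   stage is testable without any downloads.

See `docs/methods.md` for the model, the decision rule and its
calibration, and known limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data (seed 1): a 92-codon cytb-like fragment sampled from 24 individuals
over three sites, 18 carrying the genuine mitochondrial haplotype and 6 a
pseudogene.

```
$ python analysis/01_simulate_dataset.py
simulated 24 individuals (18 genuine mtDNA, 6 numt) over 276 positions, seed 1
  lineage mt: 25 accepted substitutions (by position (7, 2, 16), 2 nonsynonymous)
  lineage ref: 30 accepted substitutions (by position (4, 0, 26), 2 nonsynonymous)
  lineage numt_stem: 26 accepted substitutions (by position (8, 5, 13), 15 nonsynonymous)

$ python analysis/02_haplotypes.py
24 individuals collapse into 2 haplotypes:
  H1: 18 individuals (site1=7, site2=4, site3=7)
  H2: 6 individuals (site1=1, site2=4, site3=1)
prevalence homogeneity: Chisq = 4.00; df = 2; P = 0.14

$ python analysis/03_distances_and_tree.py
pairwise divergences (variable sites | K2P):
  H1 vs H2: 42 sites | K2P 0.173
  H1 vs REF_MT: 37 sites | K2P 0.152
  H2 vs REF_MT: 45 sites | K2P 0.188

$ python analysis/04_numt_screen.py
H1: GENUINE (truth GENUINE; 1 pseudogene-side deviations; GC 26.4%)
    vs REF_MT: {'pos1': '19', 'pos2': '5', 'pos3': '76', 'ts3': '75', 'tv3': '25', 'nonsyn': '11'} -> suspicious ('tv3',)
H2: PUTATIVE_NUMT (truth NUMT; 4 pseudogene-side deviations; GC 28.6%)
    vs REF_MT: {'pos1': '27', 'pos2': '11', 'pos3': '62', 'ts3': '75', 'tv3': '25', 'nonsyn': '40'} -> suspicious ('pos1', 'pos2', 'tv3', 'nonsyn')
```

Reading the screen: the majority haplotype H1 differs from the trusted
reference mostly at third codon positions (76%) with a modest
nonsynonymous share (11%) — one borderline excursion, below the k = 3
threshold, so it is called genuine. The minority haplotype H2 spreads its
differences across positions (27/11/62), is transversion-rich at third
positions and 40% nonsynonymous — four pseudogene-side deviations, so it
is flagged, matching the simulation's truth. `analysis/05_parameter_recovery.py`
repeats the whole study 100× (detection), 500× (regime calibration) and
100× (tree separation):

```
numt detection over 100 replicate studies: sensitivity 0.970, specificity 0.920
all six inside: True
numt haplotypes exclusive on the NJ tree in 100% of 100 replicates
```

The same stages are available as a CLI for real data:

```bash
numtscan collapse  --in aln.fasta --out haplotypes.tsv
numtscan distances --in aln.fasta --method k2p --out matrix.tsv
numtscan screen    --in aln.fasta --refs congener.fasta --out verdicts.tsv
numtscan tree      --in aln.fasta --out tree.nwk
numtscan simulate  --config sim.yaml --out sim.fasta --truth truth.tsv
```

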