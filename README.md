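# erodescan

Genome-erosion analysis for small, fragmented populations.

When a population is cut off from gene flow, drift and inbreeding erode its
genome: long runs of homozygosity (ROH) appear, heterozygosity falls, and
recessive deleterious variants become exposed in homozygous state.
`erodescan` quantifies these signatures from a multi-sample VCF, the way
conservation-genomics resequencing studies do — the motivating system is the
endangered Scandinavian arctic fox (*Vulpes lagopus*), whose fragmented
Fennoscandian subpopulations are compared against the large, connected
Siberian population (43 whole genomes).

## What it computes

* **Site filtering** — base quality ≥ QV 30, SNPs within 5 bp of an indel
  removed, per-sample depth restricted to ⅓–2× that sample's mean coverage,
  masked regions and scaffolds < 25 kb excluded, complete genotyping
  required; every removal attributed to its first failing rule.
* **ROH calling** — PLINK-style sliding windows of 200 SNPs with ≤ 3
  heterozygous calls; a SNP is in a homozygous segment when ≥ 5 % of its
  covering windows are homozygous; segments need ≥ 100 SNPs, ≥ 100 kb, one
  SNP per 50 kb, and inter-SNP gaps ≤ 1000 kb.
* **F_ROH and its age decomposition** — F_ROH is the fraction of the
  analyzable genome in ROH. A ROH of length *L* Mb dates to
  *g* = 100/(2 *r* *L*) generations since the common ancestor (recombination
  rate *r* in cM/Mb; 0.6 for foxes), so F_ROH splits into length bins
  0.1–2 Mb (historical, back to ~850 generations), 2–8 Mb (~45), and > 8 Mb
  (recent, < ~10 generations).
* **Heterozygosity** — direct heterozygous calls per kb, and a joint
  maximum-likelihood estimate of (θ, ε) from raw read profiles, where θ is
  the per-site heterozygosity probability (the population-scaled mutation
  rate 4 N_e μ under the infinite-sites model) and ε the per-read error.
* **Mutational load** — per-individual proportions of homozygous and
  heterozygous variants in LOW / MODERATE / HIGH (synonymous / missense /
  loss-of-function) impact categories, over a shared allele denominator.
* **Structure and tests** — PCA of the variance-standardized genomic
  relationship matrix; tie-corrected Kruskal–Wallis tests with Dunn post hoc
  comparisons (Holm-adjusted) for any per-individual metric between
  populations.
* **Synthetic cohorts** — a simulator that plants IBD tracts of known age
  class (exponential lengths with mean 100/(2 *r* *g*) Mb), background
  heterozygosity, impact-annotated sites under a chosen inbreeding
  coefficient, and read profiles with known error — plus a truth ledger, so
  every stage has a recovery oracle.

## Worked example

`examples/01_simulate_and_recover_roh.py` plants 25 % total inbreeding on a
120 Mb genome (10 % historical, 5 % intermediate, 10 % recent), calls ROH,
and compares recovered to planted F_ROH:

```
simulated 120,704 SNP sites; 21 planted tracts

called 21 ROH segments; longest 12.9 Mb
           bin  planted F  recovered F   age range (gen)
    historical     0.0931       0.0944            42-833
  intermediate     0.0531       0.0535             10-42
        recent     0.1077       0.1078               <10
         total     0.2540       0.2557
```

Each F is the fraction of the analyzable genome in ROH of that length class;
the age ranges come from g = 100/(2 r L) at r = 0.6 cM/Mb. The caller
recovers each planted bin to within a few percent relative; its boundary
error is about one window of SNPs.

The other examples demonstrate the (θ, ε) likelihood fit
(`02_heterozygosity_mle.py`: θ = 0.002, ε = 0.01 both recovered to ~1 %
relative from 10⁵ sites at depth 25), the inbreeding-driven shift of
deleterious variants from heterozygous to homozygous state
(`03_mutational_load.py`), and PCA separation plus rank tests
(`04_structure_and_group_tests.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
erodescan --seed 1 simulate --config sim.yaml --out-dir sim/
erodescan filter --vcf sim/cohort.vcf --layout sim/layout.tsv \
          --meta sim/metadata.tsv --out-dir out/
erodescan roh    --vcf ... --layout ... --meta ... --out-dir out/
erodescan het    --vcf ... --layout ... --meta ... --out-dir out/
erodescan load   --vcf ... --layout ... --impact impact.tsv --out-dir out/
erodescan pca    --vcf ... --layout ... --out-dir out/
erodescan stats  --table out/froh.tsv --meta sim/metadata.tsv \
          --metric froh_total --out-dir out/
```

Inputs are VCF v4.2 (GT and DP), a `scaffold<TAB>length` genome file, BED3
masks, and TSV metadata / impact tables. Every threshold can be set in a
single YAML config; flags override it.

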