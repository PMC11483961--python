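# Methods

## Scope and model

kinpipe reconstructs first-degree pedigree structure among diploid
accessions from unphased biallelic SNP genotypes, and quantifies
crop-to-wild gene flow through a marker haplotype. Genotypes are coded
HOM_REF / HET / HOM_ALT / MISSING; phase in the input is discarded — every
statistic below is defined on genotypes.

### Window system

All pairwise IBD statistics are computed in windows containing a fixed
span (default 200,000 bp) of non-repetitive sequence. Windows accumulate
non-repetitive bp left to right and close at the exact base where the
running total reaches the target; repetitive gaps contribute nothing, so a
window crossing a masked block is physically wider. The last window of a
chromosome keeps the remainder. This construction conserves the genome's
non-repetitive total exactly (a tested invariant) and makes window
information content uniform in the presence of repeat-rich regions.
Coordinates follow the two file standards exactly: VCF positions are
1-based, BED mask and internal intervals 0-based half-open. Which repeat
annotation defines "non-repetitive" is the user's choice — the mask is an
input, not a computation.

### Window IBD classification

For a pair of accessions, each window with at least `min_sites` (default
10) doubly-called sites is summarised by

* `ibs0` — opposite homozygotes (one HOM_REF, the other HOM_ALT),
* `ibs2` — identical genotypes,
* `ibs1` — the remainder,
* genotypic distance `(ibs1 + 2·ibs0) / (2·n)`.

The state rule is: IBD2 if `ibs2/n ≥ t2` (default 0.95); else IBD1 if
`ibs0/n ≤ t0` (default 0.02); else IBD0. The logic rests on the single
fact that an opposite homozygote is impossible when the pair shares at
least one haplotype — except through genotyping error. Both tolerances are
therefore calibrated to the dominant error mode of reduced-coverage
genotyping, heterozygote undercalling: at a het→hom miscall rate of 1 %
per accession, two copies of the same genome still disagree at ~1 % of
sites, and a HET miscalled as the "wrong" homozygote fakes an opposite
homozygote at ~0.5 % of the het sites of a truly IBD1 pair. `t0 = 0.02`
absorbs that; `t2 = 0.95` leaves roughly five times the expected
discordance of identical genomes per 100-site window while staying far
above the ~65 % genotype identity typical of an IBD1 window, so the IBD2
call is robust without becoming permissive. The original window
thresholding scheme this reconstructs is not fully specified in the
literature the method descends from (it defers to an earlier study), so
both cutoffs are explicit, documented and configurable here.

### Relationship calls

Per pair, the IBD fractions are computed over informative windows weighted
by their non-repetitive span, and the longest IBD0 segment is the physical
bp from the start of the first to the end of the last window of the
longest run of consecutive IBD0 windows on one chromosome. Calls:

* clone — `f(IBD2) ≥ 0.90`;
* parent–offspring — `f(IBD0) < 0.15`, `f(IBD1) > 0.60`, longest IBD0
  segment `< 3,800,000 bp` (all three jointly);
* undetermined — fewer than `min_windows` (default 50) informative
  windows; otherwise "other".

The PO thresholds are the published operating point of the method;
the clone cutoff and the min-window/min-site guards are this package's
defaults, all configurable.

### Trio validation

A candidate trio P1×P2→F is scored at sites non-missing in all three
members. A site is compatible iff some ordering (u, v) of F's two alleles
has u among P1's alleles and v among P2's — the table over the 27 ordered
genotype triples (15 compatible / 12 incompatible) is derived from this
first principle at import time and verified in the tests against the
published lists and against an exhaustive transmission enumeration.

Heterozygote undercalling creates a background of unmatching sites in
genuine trios (~0.5 % in simulation at the default error rates, ~0.8 % in
the motivating real data), uniformly distributed along the genome. Two
rejection tests formalise "low and uniform":

* **rate** — reject if genome-wide `errors/informative > max_rate`
  (default 0.013, chosen to sit between the highest genuine-trio rate the
  motivating data accepts, 1.17 %, and the 1.7 % of the pedigree it
  rejects);
* **clustering** — window w is flagged when its error count exceeds the
  one-sided Binomial(n_w, p0) tail at level `alpha_w / #windows`
  (Bonferroni, default alpha_w = 0.05); reject if any `run_min` (default
  3) consecutive windows are flagged. The baseline is
  `p0 = min(observed rate, max_rate)`: for genuine trios this is exactly
  the trio's own rate, but for a contaminated trio the observed rate is
  itself inflated by the contamination, and testing against it would mask
  the clusters the test exists to find. Capping at the genuine-trio
  ceiling keeps the test calibrated against the background process.

Clustered rejection takes precedence over rate rejection, because the
chromosomal distribution — not the rate — is what distinguishes a wrong
pedigree from a noisy genuine one. Flagged runs merge into incompatible
regions, reported with their cumulative non-repetitive span as a fraction
of the genome (the quantity used to size the incompatible share of a
contested genome).

The trio search tests, for every accession F, each unordered pair of F's
PO partners; an exhaustive mode additionally tests arbitrary user-supplied
combinations (the procedure for re-examining a contested pedigree against
every plausible parent). Full siblings are offspring of the same unordered
parent pair among accepted trios.

### Kinship network

Accepted trios orient their two parent→offspring edges; PO pairs never
resolved in a trio stay unoriented; full-sib edges connect siblings. A pair
carries at most one edge and trio evidence upgrades an unoriented edge.
Orientation is never inferred beyond trios — historical-precedence
arguments are provenance-annotated manual overrides, not computation.
Descent groups are the accessions reachable from a founder set through PO
edges in either orientation. The TSV edge list (canonical endpoint order,
orientation carried by parent/child columns) is the on-disk form; GraphML
and DOT are views.

### Haplotype sharing and dosage

The scan requires a reference accession homozygous (≥ 0.99 of non-missing
calls, checked) for the target haplotype across the scan region. Because
the reference is homozygous, phasing is unnecessary: an accession
homozygous for the opposite allele cannot carry the haplotype at that
site. The scan chromosome is cut into `n_windows` equal physical windows
(independent of, and typically coarser than, the IBD windows); per window
an accession reads `shares_none` (opposite homozygotes above `t_err`,
default 0.02), `shares_two` (genotype matches the reference at ≥ `t2`,
default 0.98), else `shares_one_or_two`, or `uninformative` below
`min_sites`. Dosage at a target interval applies the same two tolerances
to the sites pooled across the target windows: 0 / 2 / 1 by the same
logic. Pooling is deliberate — a per-window veto would make the false-zero
probability grow with the number of windows the target spans (about 8 %
per heterozygous carrier at default error rates over a 15-window target),
biasing frequencies downward; pooled, the miscall tolerance applies once
at the scale the decision is made, and dosage recovery on planted truth is
error-free in the test battery. Population frequency is
Σdosage / (2·n_called), with undetermined accessions excluded from the
denominator and counted.

Ancestry grouping takes an externally estimated Q matrix (rows sum to 1)
and assigns the argmax component iff it exceeds the threshold (default
0.85, strict) and "admixed" otherwise. Estimating Q is out of scope.

## Synthetic data

The simulator emulates the data structure the inference assumes, not the
full biology:

* **ancestry** — three components (two cultivated, one wild) under the
  Balding–Nichols model: ancestral frequency U(0.05, 0.95) per site,
  component frequency Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.05 for the
  cultivated components and 0.20 for the wild one. The divergence values
  are stated defaults, not calibrated estimates — the motivating study
  reports no quantitative component divergence.
* **sites** — 20,000 SNPs over 5 chromosomes × 10 Mb, placed around
  uniformly drawn gene anchors (40 genes/Mb, normal jitter sd 2 kb) to
  mimic the clustered spacing of gene-targeted sequencing; ~10 % of each
  chromosome is masked as repetitive blocks.
* **meiosis** — Poisson(recomb_rate × length) crossovers per chromosome,
  uniform breakpoints, random starting haplotype. `recomb_rate = 0.6 /Mb`
  preserves the genome-wide genetic length of a grapevine-like organism
  (~1300–1500 cM ≈ 26–30 crossovers per meiosis) on the 50-Mb desk
  genome. Preserving per-chromosome crossover counts instead would leave
  the miniature genome with ~4× fewer independent segments than the system
  being emulated and inflate the variance of genome-wide IBD fractions —
  full siblings would sporadically pass the PO thresholds, which the real
  genome's segment count prevents.
* **pedigree** — the default script mirrors the motivating study's
  structure: two founder sets of four, a four-offspring quartet from one
  recurrent pair, a two-offspring pair, a second-generation cross, a
  full-sib pair whose sibling seeds the false-pedigree experiment, a clone
  of a childless wild founder, and four wild populations of six. The truth
  set closes PO/trio/full-sib relations over clone equivalence, since a
  clone is genotypically indistinguishable from its source.
* **errors** — each HET flips to a random homozygote with probability
  0.01; each homozygote becomes HET at one tenth of that rate (the minor
  error mode); each call goes missing with probability 0.02.
* **planted haplotype** — one haplotype drawn from the first cultivated
  component's frequencies, fixed, and written into carrier accessions at
  explicit per-accession dosage (the reference gets two copies). Dosages
  are planted exactly, not drawn binomially, so frequency-recovery
  experiments measure estimator error rather than sampling noise.

One seeded generator drives everything in a fixed event order (mask →
sites → frequencies → founders → pedigree events → planting → errors), so
runs are bit-reproducible.

What the simulator does **not** model — coalescent ancestry and realistic
LD decay, selection, linked error processes (real undercalling is locally
correlated with coverage), population-specific missingness, crossover
interference — bounds what passing tests mean: they demonstrate that the
inference recovers the truth when its error model matches the data
generator, not that the thresholds are optimal for any real panel.

## Problem sizes and numerical choices

The validation battery runs at the default desk scale: 10 replicate panels
(43 accessions, 20,000 SNPs) for trio/PO recovery and false-pedigree
rejection, 10 error-free panels for the threshold-separation checks, and
150 small panels (28 accessions, 6,400 SNPs, two 8-Mb chromosomes) for
frequency recovery at planted frequencies 0.1/0.25/0.4. Binomial tails use
`scipy.stats.binom.sf`; IBD fractions are span-weighted ratios and sum to
1 within 1e-12 per pair; ties at thresholds are resolved by the stated
inequalities (strict where written strict — e.g. an ancestry component of
exactly 0.85 is admixed). Degenerate inputs have defined outcomes: zero
informative sites → undetermined verdicts, fully repetitive chromosomes →
zero windows with a warning, empty populations → NA frequency.

## Known limitations

* IBD classification is threshold-based, not probabilistic; pairs near the
  operating point (e.g. grandparent–grandchild under sparse data) are not
  assigned uncertainty. Probabilistic IBD HMMs and phased segment
  detection are explicit non-goals.
* The 3.8-Mb longest-IBD0-segment veto is a physical-scale rule tuned to
  real chromosome sizes; on strongly scaled-down genomes its
  discriminating power shifts to the IBD-fraction thresholds.
* The clustering test's run rule (three consecutive flagged windows)
  assumes contaminating segments span several windows; contamination
  confined to a single window is caught only by the rate test.
* Dosage calling requires a verified homozygous reference; haplotypes
  without such an anchor need phasing, which is out of scope.
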