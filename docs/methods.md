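# Methods

`capmap` models and analyses a genotyping-by-capture experiment on a
biparental population of recombinant inbred lines (RILs) of an
allotetraploid wheat (subgenomes A and B, 14 chromosomes). The two parents
are called Dic2 and Silur throughout; marker codes are `A` (Dic2
homozygote), `B` (Silur homozygote), `H` (residual heterozygote) and `-`
(missing). This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## Population model

Each RIL descends from a single F1 by `g` rounds of self-fertilisation with
single-seed descent (default g = 6, an "F6" line). Gametes are formed with
crossovers as a homogeneous Poisson process on the centimorgan scale — the
Haldane model, i.e. no crossover interference — with the number of
crossovers per chromosome drawn as Poisson(L/100) and breakpoints uniform
on (0, L). The expected residual heterozygosity after g selfings is
(1/2)^g, 1.5625% at g = 6.

Between two loci with meiotic recombination fraction r, the fraction of
*lines* that are recombinant converges, as selfing proceeds, to the
Haldane–Waddington limit

    R = 2r / (1 + 2r).

At finite g the true value sits slightly below the limit (about 0.007 in R
at d = 10 cM for g = 6); the package's tests therefore check finite-g
simulations against an exact two-locus selfing Markov-chain enumeration and
reserve the limit formula for deep-selfing runs. The mapping code applies
the inverse correction r = R/(2(1−R)) before converting to Haldane cM,
accepting the <1% residual F6-vs-F∞ bias; consequently estimated map
lengths run a few percent short of truth (92–93% in the recovery
experiments, within the 15% recovery tolerance we test).

## Synthetic reference and capture coverage

`generate_reference` builds transcriptome-like contigs: 1 + Poisson(1)
exons (lengths uniform 130–400 bp by default) separated by 20–60 bp
spacers, exactly one candidate biallelic SNP per contig placed in the
longest exon. Study-composition defaults follow the experiment the package
models: 30% of targets originate from an external discovery panel (EPO), of
which 41% are truly monomorphic between the cross parents; 23% of contigs
carry a homeologous near-copy (3% diverged) on the other subgenome bearing
its own segregating "bonus" site; 15% carry a second, perfectly linked
untargeted segregating position; 0.3% carry an embedded tandem
microsatellite near the SNP.

`simulate_capture_readcounts` draws, for each sequenced position and
individual, a depth from a negative binomial with size k (overdispersion,
default 1.0) around `mean_depth × (bait_count/2) × exp(N(0, σ))` with
σ = 0.5 (lognormal locus quality) and `mean_depth` = 11.4 reads — the
4-bait/2-bait factor encodes bait stoichiometry (type-1 loci are sequenced
about twice as deeply). Because the distribution is right-skewed the
realized median is ~10–15% below the mean, as in real capture data. A 6%
fraction of loci fail capture outright (zero reads everywhere). Allele
counts split binomially with 1% sequencing-error cross-talk; truly
monomorphic targets emit only the reference allele. Finally 20 "sink"
contigs (microsatellite daisy-chain off-target capture) absorb 42% of the
grand total read budget, which reconciles exactly: total = targeted + sink.

The generator does **not** model read-level artefacts (base qualities, PCR
duplicates, mapping ambiguity), segregation distortion, position effects
along the bait, or depth correlation between individuals (library-size
effects). Passing tests therefore demonstrate the correctness of the
calling/filtering/mapping machinery under the stated noise structure, not
robustness to alignment artefacts.

## Genotype calling and locus classification

Targeted loci accept calls from as few as 2 reads (the polymorphism is
already known); untargeted (bonus) positions require 4. A heterozygote
needs both alleles at ≥2 reads and a minor-allele fraction ≥0.2; otherwise
the majority allele is called, and an exact tie that fails the heterozygote
rule is returned as missing (no majority exists). This transparent
threshold rule replaces probabilistic callers on purpose: it is exactly
reproducible and the downstream quality filters dominate the error budget.
Loci partition into `not_captured` (no call), `monomorphic` (a single
homozygote class; a configurable number of stray H calls, default 0, may be
ignored), `het_only` (collapsed-homeolog artefacts) and `ER`
(expected-recovered, i.e. segregating). A bonus position is reported when
its calls exhibit both parental alleles at the stricter depth.

## Quality filters

Per locus, with p the Dic2-allele frequency among calls (an H counts half
to each allele), Ho the observed heterozygote fraction and He = 2p(1−p)
Nei's expected heterozygosity:

* Fis = 1 − Ho/He must exceed 0.8 (strict; selfed lines should be ~98.5%
  homozygous — excess H betrays collapsed paralogs);
* He ≥ 0.34, i.e. p within about [0.217, 0.783], a segregation-distortion
  guard (boundaries: >0.8 strict, ≥0.34 inclusive, both configurable);
* ≥100 of the 135 lines genotyped.

The three filters are a pure conjunction (order-independent). Bonus markers
are additionally de-duplicated: those on targeted contigs are discarded
(the targeted marker already represents the contig), then one marker per
remaining contig is kept (most genotyped, then highest He, then smallest
position). The accounting table reconciles exactly by construction and is
checked on every run.

## Linkage mapping

Markers are first merged into bins when their call vectors conflict nowhere
and share ≥30 co-genotyped lines (H is a genotype state for this
comparison; the transitive closure defines the bin). Heterozygote calls are
then set to missing for linkage: two-point analysis counts recombinant
lines among doubly homozygous shared lines, R̂ = k/n, with

    LOD = k·log10(R̂) + (n−k)·log10(1−R̂) + n·log10 2   (0 when R̂ ≥ 0.5).

Linkage groups are connected components over pairs with LOD ≥ 7 and
R̂ ≤ 0.14 (the distance threshold operates on the recombinant-line
fraction; both configurable). Groups are attributed to the chromosome of
the modal putative assignment of their members (ties → unassigned), pooled
per chromosome, and ordered by minimising the sum of adjacent two-point
distances (SARF):

* groups of ≤10 markers: exact Held–Karp dynamic programming;
* larger groups: greedy insertion seed, simulated annealing over 2-opt
  segment reversals (geometric cooling, 300 steps per marker from T = 5 to
  0.01, deterministic under the run seed), then exhaustive sliding-window
  permutations (window ≤ 5) to convergence; the better of the refined and
  the flip-polished greedy order is kept.

Orders are orientation-symmetric; each chromosome is flipped to correlate
positively with external putative positions when available, otherwise
canonically (first marker name < last). Positions are cumulative adjacent
Haldane distances (adjacent R̂ capped at 0.45 to keep distances finite).
Pooled sets with fewer than 3 markers are reported but left off the map.
A multipoint EM likelihood would be the classical alternative; the SARF
proxy gives near-identical orders for dense RIL data at a fraction of the
cost and is the package's main methodological simplification.

## Map validation

Per chromosome: Spearman rank correlation of map positions against putative
physical and genetic coordinates (≥3 usable markers required); a cubic
least-squares regression of genetic on centred/scaled physical position,
tagging markers outside the pointwise 95% *prediction* band (a mean-response
band is available by flag; prediction is the default because individual
markers are being screened). A scale-relative tolerance (1e-8 of the
response magnitude) keeps an exact zero-residual fit from tagging numerical
noise. Translocation blocks are maximal runs of ≥3 consecutive markers
(adjacent gaps ≤10 cM) whose putative chromosome is identical and neither
the mapped chromosome nor its homeolog (same numeral, other genome letter).
Segment recombination rates are genetic span / physical span (cM/Mb) over a
physical interval.

Null calibration: on correctly specified cubic data with Gaussian noise the
false-tag rate of the 95% prediction band is ~5% (checked at n = 300 within
binomial error), and gross displacements (±80 cM) are recovered with ≥80%
recall under a sigmoidal genetic–physical relationship.

## Problem sizes and determinism

The recovery experiments run 14 chromosomes × 100 markers × 135 RILs
(~1,400 markers), which builds a full map in a few seconds; unit tests use
2–4 chromosomes at matching density. Every stochastic stage takes an
explicit seed; the pipeline derives per-stage seeds from a single master
seed, and identical configurations reproduce byte-identical artifacts
(checked in the tests). Output tables carry a provenance header (package
version, seed, configuration hash; output paths are excluded from the
hash).

## Known limitations

* No multipoint likelihood; ordering quality at low marker density or heavy
  missingness degrades before the multipoint optimum would.
* The placement of markers genotyped in only 50–99 lines is out of scope;
  the map's `type` column reserves the `DL_mapped` label but the package
  never emits it.
* Putative assignments are consumed as a table; no sequence-similarity
  search is performed.
* The F6 map-length underestimate (a few percent) is accepted rather than
  corrected generation-exactly.
* Validation emits CSV scatter/fit/band data rather than figures.
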