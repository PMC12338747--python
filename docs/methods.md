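# Methods

## The problem

A de novo mutation (DNM) is a variant present in a child and absent from
both parents. Two properties make trio long-read data uniquely informative
about them. First, long reads span enough heterozygous inherited SNPs
("tagging SNPs") that almost every read — and therefore almost every DNM —
can be assigned to a parental haplotype. Second, haplotype-resolved pileups
separate *germline* mutations (carried by every read of the haplotype of
origin) from *postzygotic* mutations (PZMs: present in only a fraction of
cells, so the origin haplotype shows both reference and alternate reads — a
"third haplotype"). trioscope implements this full analysis: naive trio
candidate selection, three-platform read validation, informative-SNP
phasing, germline/PZM classification, callable-genome rate estimation and
spectrum statistics — plus a calibrated cohort simulator so every stage can
be tested end-to-end against known truth.

## Discovery and validation

Candidates are sites where both parents are genotyped 0/0 and the child
carries the alternate allele with GQ >= 20 (child GQ only). Two callers'
callsets are unioned by (chrom, pos, ref, alt); per-sample GQ merges by
maximum, so a record passing in either caller survives.

**Cluster filter.** Any >= 3 candidate SNVs of one child inside a sliding
1 kbp window (equivalently, any 3 whose positions span <= 999 bp) are set
aside: runs like this are almost always a dropped parental haplotype in the
caller, making inherited variants look de novo. Windows slide at every base
offset; the filter is per child, per chromosome, SNVs only.

**Read validation.** Long reads require mapping quality >= 59 (short reads
are not mapq-filtered); child HiFi reads must be blood-derived (cell lines
accumulate culture somatic variants), parental HiFi may be blood or cell
line. Base quality at the site tiers reads: > 20 high, 10–20 low, < 10
discarded. A platform calls a candidate de novo when the child has >= 1
de novo read and both parents are "clean": HiFi/Illumina at most 0
high-quality + 1 low-quality de novo reads, ONT (noisier) at most 1 + 2.
The caps are conjunctive — exceeding either breaks cleanliness; a
disjunctive reading would pass a parent with many high-quality de novo
reads, defeating the filter. One inherited-looking platform vetoes; two
supporting platforms validate. A platform with usable child reads but no
de novo read neither supports nor vetoes (NO_SUPPORT).

Cohort-level screens then remove: alleles carried by unrelated samples'
HiFi reads (recurrent errors; one unrelated carrier is tolerated inside a
tandem repeat, where genotype dropout is common); tandem-repeat variants
with mean cross-platform allele balance <= 0.05 and RepeatMasker-region
variants below 0.1 (TR) / 0.08 (non-TR); substitutions in or within 1 bp of
a homopolymer run (>= 4 identical bases) involving the run base; and
variants whose parental pileups show a >= 2-read third allele on >= 2
platforms ("dubious support"). The last two thresholds are genuinely open
choices: run length 4 is the shortest run commonly treated as an artifact
source, and the 2-read / 2-platform noise rule formalises a pattern
described only qualitatively. Mean AB averages platforms with >= 1 usable
child read, unweighted, using the phasing-grade (base quality >= 20) counts.

**Indels** (< 50 bp, non-TR; whole-motif TR expansions/contractions are
excluded) use stricter reads: mapq exactly 60 and >= 10 bp of aligned
sequence flanking the variant on both sides, so the full allele is
captured. Any parental or sibling read carrying the allele on any platform
marks it inherited; confirmation requires the child's allele in both HiFi
and Illumina. A multi-allele screen (>= 2 distinct non-ref, non-de-novo
alleles each on >= 2 reads) automates what is usually a visual IGV review.

## Phasing

Informative SNPs are inherited sites where exactly one parent can have
donated the child's alt (e.g. 0/0 x 0/1 or 1/1 -> 0/1), collected within an
80 kbp window centred on the DNM. Each child read scores
sum(w_i v_i)/sum(w_i) over the informative SNPs it spans: v = +1 if its
allele matches the maternal-donor allele, −1 paternal, with weight
w = 1/max(1, distance). The max(1, ·) guards a zero distance that cannot
arise by construction; a score of exactly 0 leaves the read unassigned, and
an allele matching neither parental allele (a sequencing error at the tag
site) contributes nothing. A DNM is phased when all its de novo reads land
on one haplotype; de novo reads on both haplotypes are a conflict. HiFi
assignments win over ONT; ONT rescues HiFi-unphased variants; a variant
with informative SNPs present that still cannot be phased is treated as
sequencing error and excluded from the callset. Variants with no
informative SNPs are retained unphased.

## Origin classification

Per platform, the origin-haplotype (ref, alt) counts call PZM at
>= 2 ref + >= 1 alt, germline at <= 1 ref + >= 1 alt, ambiguous at 0 alt.
In parallel, an allele-balance route tests the three platforms' (ref, alt)
counts for homogeneity (chi-squared without continuity correction; a table
with an empty ref or alt column is trivially concordant with statistic 0,
and fewer than two read-bearing platforms are concordant by convention);
concordant counts are pooled into a one-sided exact binomial test against
AB 0.5, predicting PZM at p < 0.05. Discordant counts default the
prediction to germline — one cannot confidently call mosaicism from
platform-inconsistent AB. Both alphas are 0.05; the concordance alpha is
fixed by the reported "p > 0.05" convention and the binomial alpha matches
it. The one-sided test also guarantees AB = 1 calls are never classified
postzygotic. Final call: HiFi and ONT agreeing (and unambiguous) win; a
lone unambiguous platform wins when the other is ambiguous; a true
disagreement or double ambiguity defers to the AB prediction. Unphased
variants are classified by the AB route alone.

Indels tolerate haplotype noise: postzygotic only if > 3 reads on the
origin haplotype carry an allele other than the called event (reference
reads and third alleles counted alike — the literal noise-robust reading),
with >= 1 de novo read.

## Rates

A site is callable when a DNM could have been discovered there: both
parents genotyped 0/0 and every trio member covered by >= 1 HiFi read with
mapq >= 59 and base quality >= 20 (child blood-only, parents blood or cell
line). Male sex chromosomes drop the parental 0/0 requirement and use only
the relevant parent's evidence (mother for X, father for Y). Rates divide
DNM counts by ploidy_factor x callable bp (2 for autosomes/female X; male X
and Y callable space is summed at factor 1). Confidence intervals are
10,000-replicate percentile bootstraps over children, which respects
between-child variance including parental-age effects (the CI construction
is an open design choice). Feature-stratified rates intersect both the DNMs
and the mask with a feature track in 0-based half-open arithmetic; a DNM
belongs to a feature iff its 0-based position lies in [start, end).
Feature-vs-genome comparisons use a paired per-sample t-test (rates are
paired by child) with Benjamini-Hochberg correction across features.

## Spectrum statistics

Substitutions collapse to the strand-symmetric classes {A>C, A>G, A>T,
C>A, C>G, C>T, CpG>TpG} (purine references reverse-complemented, CpG>TpG
split out of C>T using one base of 3' context). Ti/Tv counts A<->G and
C<->T over the rest. Parent-of-origin enrichment uses the pooled
paternal:maternal count ratio and a Wilcoxon signed-rank test on per-child
differences (exact null for small n without ties, normal approximation with
continuity correction otherwise); germline-vs-PZM paternal fractions are
compared with a two-proportion Z-test. Per-class spectrum comparisons are
2x2 chi-squared tests (class vs rest) with a Fisher fallback for degenerate
tables and BH correction across the seven classes; counts, not per-child
fractions, are compared. Multinucleotide-mutation (MnM) candidates are all
within-child same-chromosome pairs <= 500 bp apart, with an adjacency flag
at distance 1; assembly-based MnM validation is out of scope.

## The synthetic cohort

The generator's default preset is the study design every recovery test
runs against: 42 families (31 quads + 11 trios = 73 transmissions), four
12.5 Mbp autosomes per family (50 Mbp/trio — cohort statistics are
per-child counts, so genome span sets only the coordinate space and SNP
budget), inherited SNPs as a 1/1200 bp Poisson process with random allele
frequencies, and whole-haplotype transmission per chromosome (no
recombination; irrelevant below read scale and it keeps read-borne tag
alleles exactly consistent with the transmitted haplotypes).

Per child, paternal and maternal germline counts are independent Poissons
with means b_p + 1.32 x father_age and b_m + 0.46 x mother_age; the
intercepts solve to a 70-SNV/child total split 3.98:1 at the mean ages
(33, 31). Splitting the slopes by parent (rather than drawing one total and
splitting by a fixed fraction) is deliberate: parental ages are drawn
independently (truncated normals, father N(33,5), mother N(31,4.5), bounds
[18,55]), so a fixed-fraction split would attenuate the paternal-haplotype
regression slope to ~0.8 x 1.32, which is not what the slope means. PZM
counts are Poisson at 18% of the germline expectation (12.6/child, i.e.
~15.1% of SNVs), paternal with probability 1.15/2.15, allele fractions
Beta(2.2, 7.8) (mean 0.22, truncated to [0.01, 0.499)). Germline spectra
are fixed at Ti fraction 2.10/3.10 and PZM at 1.35/2.35, with the PZM
CpG>TpG share 23% below germline and A>C/A>T enriched, A>G depleted.
Indels: 7.3/child, 24.2% postzygotic, paternal fractions 3.35/4.35
(germline) and 2/3 (PZM).

Reads are simulated per site, not per base: platform depths HiFi 30x /
ONT 40x / Illumina 40x, read spans 15 kbp / 50 kbp / 150 bp, site error
rates 0.2% / 2% / 0.1% (typical figures, stated as configuration). Each
read draws a parental haplotype; origin-haplotype reads carry the alternate
(germline) or carry it with probability 2xAB (PZM cell fraction). Het
germline alt reads are additionally lost with probability
(1-2t)/(1-t) for target mean AB t = 0.48, emulating reference-bias
alignment loss; PZM reads are drawn at the recorded fraction directly.
Erroneous base calls get low quality scores most of the time
(high/low/discard 0.10/0.50/0.40 versus 0.90/0.07/0.03 for correct calls) —
without that correlation, realistic error rates would push parental
pileups over the zero-high-quality cap far more often than real data does.
Long child reads carry the alleles of their haplotype at every spanned
child-het SNP (with platform-rate errors), which is what makes phasing
earn its accuracy rather than being handed it.

Confounders are injected with truth labels: dropped-haplotype runs (3–6
truly inherited variants within 1 kbp whose donor parent shows no alt
reads), cross-family recurrent artifacts (false alt HiFi + Illumina reads
in >= 2 unrelated children at one site), and homopolymer-edge substitution
noise. Each is constructed to be removed by exactly one named filter, so
filter attribution is testable.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: sequence-level alignment (no FASTQ, no mapping
artifacts beyond a mapq distribution), recombination, STR expansion calling,
structural variants, batch effects between alignments, CpG/replication-timing
rate heterogeneity beyond the optional SD enrichment factor, and real
tissue differences between blood and cell lines (PZM fractions are shared
across platforms). Callable masks are emitted by the generator
(whole-genome minus a 3% gap budget per child) rather than re-derived
per-base, because pileups exist only at variant sites; the per-site
callable-mask computation is exercised on explicit site tables instead.

## Numerical and procedural choices

* Coordinates: VCF/evidence are 1-based, BED/masks 0-based half-open;
  conversions happen only at IO boundaries and are property-tested.
* Multiallelic VCF records are split per alt before any logic; the
  non-chosen alt maps to a sentinel allele so "other alt" genotypes stay
  distinguishable from hom-ref.
* Deletion-spanning read observations carry the allele "*".
* Filters short-circuit in a fixed order (cluster -> support -> recurrence
  -> repeat-AB -> homopolymer -> noise -> phase conflict); each removed
  record keeps its first failing filter, so stage counts are conserved.
  The three site-level screens are pure predicates and commute.
* All randomness flows from one seed through numpy SeedSequence spawning
  (cohort, features, confounders, one stream per family); identical
  config + seed reproduces outputs byte-for-byte.
* Problem sizes: recovery tests run the full 73-transmission preset
  (pooling three replicate cohorts, ~2 minutes each); the acceptance
  script pools five. Unit tests use 1–6 family cohorts.

## Known limitations

* Sensitivity for PZMs falls off below AB ~0.05 (too few supporting reads
  to clear the two-platform rule) and PZMs with AB near 0.5 are classified
  germline by construction of the haplotype rule — both are properties of
  the method, not bugs, and both slightly depress the measured mean PZM AB
  relative to the generating distribution (~0.20 observed vs 0.22
  generated).
* The indel origin rule conflates reference reads with third alleles, as
  its noise-robust definition requires; germline indels in noisy contexts
  can therefore be called postzygotic.
* Sex-chromosome logic is implemented and unit-tested but the default
  preset simulates autosomes only.
* The cohort-level recurrence screen assumes the evidence table contains
  HiFi observations for any sample carrying the allele; absence of rows is
  read as absence of the allele.
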