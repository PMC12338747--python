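# trioscope

Trio-based de novo mutation (DNM) analysis for three-platform sequencing
studies: candidate discovery from trio VCFs, orthogonal read-evidence
validation across HiFi / ONT / Illumina, parent-of-origin phasing by
informative SNPs, germline-versus-postzygotic classification,
callable-genome mutation rates, and mutational-spectrum statistics — with a
calibrated synthetic trio-cohort generator so the entire pipeline is
testable end-to-end against known truth.

It is written for people analysing family sequencing data who need the
read-level logic of a long-read DNM study as a tested, reusable library
rather than a one-off script collection.

## The core ideas

**Discovery and validation.** A candidate DNM is a site where both parents
are 0/0 and the child carries the alternate allele (child GQ >= 20).
Candidates survive only if at least two platforms support them — child
carries the de novo allele; each parent under strict per-platform alt-read
caps (HiFi/Illumina: 0 high-quality, <= 1 low-quality; ONT: <= 1, <= 2) —
and no platform looks inherited. Cohort-wide screens remove recurrent
artifacts (the allele seen in unrelated samples' HiFi reads), runs of >= 3
candidates per 1 kbp (dropped parental haplotypes), low-allele-balance
calls in repeats, and homopolymer-edge substitutions.

**Phasing.** Each child read spanning a DNM gets an inheritance score: the
average of ±1 votes from the tagging SNPs it spans (+1 maternal, −1
paternal), inversely weighted by each SNP's distance d from the DNM
(w = 1/d), over informative sites within an 80 kbp window. A DNM is phased
when all its de novo reads fall on one parental haplotype; HiFi
assignments take precedence, ONT rescues the rest.

**Origin.** A germline DNM occupies its entire haplotype of origin; a
postzygotic mutation (PZM) shows >= 2 reference and >= 1 alternate reads
there (a "third haplotype"). Platform disagreements are arbitrated by
allele balance: if the three platforms' (ref, alt) counts are homogeneous
(chi-squared, alpha 0.05), the pooled counts are tested against AB = 0.5
with a one-sided exact binomial test; significantly low AB predicts
postzygotic origin.

**Rates.** rate = n_DNMs / (ploidy x callable bp), where a site is callable
iff both parents are 0/0 and all trio members have a high-quality HiFi read
(mapq >= 59, base quality >= 20); bootstrap-over-children CIs and
feature-stratified rates (tandem repeats, RepeatMasker, SDs by percent
identity) with paired t-tests and Benjamini-Hochberg correction.

The synthetic cohort emulates a 73-transmission design: ~70 germline SNVs
per child (paternal:maternal 3.98:1, slopes 1.32/0.46 per year of
parental age, Ti/Tv 2.10, mean AB 0.48) plus ~12.6 PZMs per child
(1.15:1, Ti/Tv 1.35, AB ~ Beta(2.2, 7.8)), indels, and labelled
artifact classes. See `docs/methods.md` for the full model.

## Worked example

```python
from trioscope import study_preset, run_pipeline

result = run_pipeline(config=study_preset(seed=101))
s = result.summary
print(s["final_snvs"], s["germline"]["paternal_maternal_ratio"],
      s["pzm"]["mean_ab"], s["truth_eval"]["sensitivity"])
```

Running the numbered drivers reproduces the cohort analyses
(`analysis/01_simulate_cohort.py` … `06_sd_enrichment_recovery.py`); the
seed-101 cohort gives:

```
final callset: 5872 SNVs + 536 indels
sensitivity 0.984  precision 1.000  origin accuracy 0.986  phase accuracy 1.000
germline SNVs: 3983:1073 (ratio 3.71, Wilcoxon p=1.14e-13)
PZM SNVs: 431:385 (ratio 1.12, Wilcoxon p=0.045)
paternal age slope 1.46 DNMs/yr (p=5.84e-11)
germline: n=5056 Ti/Tv=2.074 mean AB=0.480
pzm: n=816 Ti/Tv=1.325 mean AB=0.206
PZM CpG>TpG deficit vs germline: 21.1%
```

Read this as: of 5,872 validated de novo SNVs, 86% are germline with the
expected strong paternal bias and transition-rich spectrum, while the ~14%
classified postzygotic sit at low allele balance with a transversion-shifted
spectrum — and the truth table confirms the pipeline recovered 98.4% of
simulated DNMs with no artifact leakage. Small tables land in `results/`;
bulky per-read and per-record artifacts go to `scratch/`.

A CLI covers the two common entry points:

```bash
trioscope simulate --out scratch/cohort --seed 1
trioscope run --out scratch/run --seed 1
```

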