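"""Three-platform read-evidence validation of candidate de novo variants.

The validation logic mirrors orthogonal-platform DNM confirmation as used in
trio long-read studies:

* long reads (HiFi, ONT) must map with quality >= 59; short reads are not
  mapping-quality filtered;
* a child's HiFi reads must come from blood (cell-line reads may carry
  culture-acquired somatic variants); parental HiFi may be blood or cell line;
* reads are tiered by base quality at the site (>20 high, 10-20 low, <10
  discarded);
* a platform supports de novo status when both parents are "clean"
  (HiFi/Illumina: zero high-quality and at most one low-quality de novo read;
  ONT, being noisier: at most one high-quality and two low-quality) and the
  child carries the de novo allele on at least one read;
* a variant is INHERITED if any platform says inherited, VALIDATED if at
  least two platforms support de novo status;
* cohort-level screens remove recurrent artifacts (allele seen in unrelated
  samples' HiFi reads), low-allele-balance calls in tandem repeats and
  RepeatMasker regions, homopolymer-edge substitutions, and variants with
  noisy multi-allele parental pileups.

Indels have their own stricter rule set: perfectly mapped (mapq 60) reads
spanning the site with >= 10 bp flanks, inheritance vetoed by any parental or
sibling read on any platform, and confirmation required in both HiFi and
Illumina.

Functions accept either a site-restricted :class:`pandas.DataFrame` (the
read-evidence TSV dialect) or the dict-of-arrays view from
:meth:`ReadEvidence.site_arrays`; both routes share one mask implementation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import CandidateVariant
from .io import FeatureTrack, ReadEvidence
from .model import Pedigree, PlatformAlleleCounts, Verdict

PLATFORMS = ("HIFI", "ONT", "ILLUMINA")

#: parental de novo-allele read caps per platform: (max HQ, max LQ)
PARENT_ALT_CAPS = {
    "HIFI": (0, 1),
    "ILLUMINA": (0, 1),
    "ONT": (1, 2),
}

LONG_READ_MIN_MAPQ = 59


@dataclass
class PlatformVerdict:
    platform: str
    verdict: Verdict
    child_counts: PlatformAlleleCounts
    parent_alt_hq: dict[str, int] = field(default_factory=dict)
    parent_alt_lq: dict[str, int] = field(default_factory=dict)


def _as_arrays(site) -> dict:
    if isinstance(site, dict):
        return site
    return {c: site[c].to_numpy() for c in site.columns}


def _usable_mask(arr: dict, role: str, platform: str) -> np.ndarray:
    """Read-level usability for SNV validation/pileup inspection.

    Single source of truth for the platform/tissue/quality rules.
    """
    m = arr["platform"] == platform
    if platform in ("HIFI", "ONT"):
        m &= arr["mapq"] >= LONG_READ_MIN_MAPQ
    if platform == "HIFI" and role == "child":
        m &= arr["tissue"] == "BLOOD"
    m &= arr["base_qual"] >= 10
    return m


def usable_reads(site_df: pd.DataFrame, role: str, platform: str) -> pd.DataFrame:
    """Filter one sample-role's reads at a site and annotate quality tiers.

    ``site_df`` must already be restricted to the sample(s) of interest.
    Returns a copy with a ``tier`` column ("HIGH"/"LOW"); base quality < 10
    reads are dropped.
    """
    arr = _as_arrays(site_df)
    df = site_df[_usable_mask(arr, role, platform)].copy()
    df["tier"] = np.where(df["base_qual"] > 20, "HIGH", "LOW")
    return df


def platform_verdict_snv(site, child_id: str, father_id: str,
                         mother_id: str, ref: str, alt: str,
                         platform: str) -> PlatformVerdict:
    """Per-platform de novo / inherited / no-data verdict for one candidate SNV."""
    arr = _as_arrays(site)
    sample, allele, bq = arr["sample_id"], arr["allele"], arr["base_qual"]

    child = (sample == child_id) & _usable_mask(arr, "child", platform)
    child_counts = PlatformAlleleCounts(
        platform,
        n_ref=int((allele[child] == ref).sum()),
        n_alt=int((allele[child] == alt).sum()))

    hq_cap, lq_cap = PARENT_ALT_CAPS[platform]
    parents_clean = True
    parent_alt_hq: dict[str, int] = {}
    parent_alt_lq: dict[str, int] = {}
    for pid in (father_id, mother_id):
        pmask = (sample == pid) & _usable_mask(arr, "parent", platform)
        palt = pmask & (allele == alt)
        hq = int((bq[palt] > 20).sum())
        lq = int((bq[palt] <= 20).sum())
        parent_alt_hq[pid] = hq
        parent_alt_lq[pid] = lq
        if hq > hq_cap or lq > lq_cap:
            parents_clean = False

    if not child.any():
        verdict = Verdict.NODATA
    elif not parents_clean:
        verdict = Verdict.INHERITED
    elif child_counts.n_alt >= 1:
        verdict = Verdict.DENOVO
    else:
        verdict = Verdict.NO_SUPPORT
    return PlatformVerdict(platform, verdict, child_counts, parent_alt_hq, parent_alt_lq)


def combine_verdicts(verdicts: list[PlatformVerdict]) -> str:
    """INHERITED if any platform inherited; VALIDATED if >= 2 support de novo."""
    if not verdicts:
        raise ValueError("need at least one platform verdict")
    kinds = [v.verdict for v in verdicts]
    if Verdict.INHERITED in kinds:
        return "INHERITED"
    if sum(k is Verdict.DENOVO for k in kinds) >= 2:
        return "VALIDATED"
    return "FAILED_SUPPORT"


def platform_ab_counts(site, child_id: str, ref: str, alt: str,
                       platform: str) -> PlatformAlleleCounts:
    """Child (ref, alt) counts with phasing-grade filters (base quality >= 20)
    — the counts used for allele-balance statistics and the AB origin tests."""
    arr = _as_arrays(site)
    m = ((arr["sample_id"] == child_id) & _usable_mask(arr, "child", platform)
         & (arr["base_qual"] >= 20))
    allele = arr["allele"][m]
    return PlatformAlleleCounts(platform, n_ref=int((allele == ref).sum()),
                                n_alt=int((allele == alt).sum()))


def cohort_recurrence_filter(cand: CandidateVariant, cohort_evidence: ReadEvidence,
                             pedigree: Pedigree, tr_track: FeatureTrack) -> bool:
    """True (pass) iff the de novo allele is absent from unrelated samples'
    HiFi reads — with one unrelated carrier tolerated inside a tandem repeat."""
    arr = cohort_evidence.site_arrays(cand.chrom, cand.pos)
    m = (arr["platform"] == "HIFI") & (arr["allele"] == cand.variant.alt)
    related = pedigree.related_samples(cand.child_id)
    carriers = set(arr["sample_id"][m]) - related
    in_tr = tr_track.overlaps(cand.chrom, cand.pos, "TR")
    return len(carriers) <= (1 if in_tr else 0)


def repeat_ab_filters(cand: CandidateVariant, mean_ab: float | None,
                      rm_track: FeatureTrack, tr_track: FeatureTrack) -> tuple[bool, str]:
    """Allele-balance floors for repeat-context variants.

    Tandem-repeat variants need mean AB > 0.05; RepeatMasker-flagged variants
    need mean AB > 0.1 (if also in a TR) or > 0.08.  Returns (pass, reason).
    """
    in_tr = tr_track.overlaps(cand.chrom, cand.pos, "TR")
    in_rm = rm_track.overlaps(cand.chrom, cand.pos, "RM")
    if not in_tr and not in_rm:
        return True, "OK"
    if mean_ab is None:
        return False, "NODATA"
    if in_tr and mean_ab <= 0.05:
        return False, "TR_AB"
    if in_rm and mean_ab <= (0.1 if in_tr else 0.08):
        return False, "RM_AB"
    return True, "OK"


def homopolymer_filter(ref: str, alt: str, left_context: str, right_context: str,
                       min_run: int = 4, adjacency_bp: int = 1) -> bool:
    """True (pass) unless the SNV sits in/adjacent to a homopolymer run and
    either allele equals the run base.

    The site is "in or adjacent" when it lies within ``adjacency_bp`` bases of
    a run of >= ``min_run`` identical bases in the local reference context.
    """
    if len(ref) != 1 or len(alt) != 1:
        return True  # applies to substitutions only
    seq = left_context + ref + right_context
    site = len(left_context)
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        if run_len >= min_run and (i - adjacency_bp) <= site <= (j - 1 + adjacency_bp):
            base = seq[i]
            if ref == base or alt == base:
                return False
        i = j
    return True


def noisy_support_filter(cand: CandidateVariant, site,
                         pedigree: Pedigree, min_reads: int = 2,
                         max_noisy_platforms: int = 1) -> bool:
    """True (pass) unless >= 2 platforms show noisy parental pileups.

    A platform is noisy when either parent carries >= ``min_reads`` usable
    reads of a third allele (neither reference nor the de novo allele).
    """
    arr = _as_arrays(site)
    father, mother = pedigree.parents_of(cand.child_id)
    ref, alt = cand.variant.ref, cand.variant.alt
    sample, allele = arr["sample_id"], arr["allele"]
    third_allele = (allele != ref) & (allele != alt)
    noisy = 0
    for platform in PLATFORMS:
        usable = _usable_mask(arr, "parent", platform) & third_allele
        for pid in (father.sample_id, mother.sample_id):
            third = allele[usable & (sample == pid)]
            if len(third) and max(Counter(third).values()) >= min_reads:
                noisy += 1
                break
    return noisy <= max_noisy_platforms


def _indel_usable_mask(arr: dict, min_flank: int = 10) -> np.ndarray:
    return ((arr["mapq"] == 60) & (arr["flank_left"] >= min_flank)
            & (arr["flank_right"] >= min_flank))


def usable_indel_reads(site_df: pd.DataFrame, min_flank: int = 10) -> pd.DataFrame:
    """Indel-grade reads: perfect mapping (mapq 60) and >= min_flank bp on
    both sides of the variant."""
    return site_df[_indel_usable_mask(_as_arrays(site_df), min_flank)]


def validate_indel(cand: CandidateVariant, evidence: ReadEvidence,
                   pedigree: Pedigree) -> tuple[str, dict[str, PlatformAlleleCounts]]:
    """Two-platform indel validation with the sibling-inheritance veto.

    Returns (status, per-platform child allele counts).
    """
    arr = evidence.site_arrays(cand.chrom, cand.pos)
    usable = _indel_usable_mask(arr)
    sample, allele, platform_col = arr["sample_id"], arr["allele"], arr["platform"]
    father, mother = pedigree.parents_of(cand.child_id)
    sib_ids = [s.sample_id for s in pedigree.siblings_of(cand.child_id)]
    ref, alt = cand.variant.ref, cand.variant.alt

    veto_ids = {father.sample_id, mother.sample_id, *sib_ids}
    veto = usable & (allele == alt) & np.isin(sample, list(veto_ids))
    child = usable & (sample == cand.child_id)
    counts: dict[str, PlatformAlleleCounts] = {}
    for platform in PLATFORMS:
        cm = child & (platform_col == platform)
        counts[platform] = PlatformAlleleCounts(
            platform, n_ref=int((allele[cm] == ref).sum()),
            n_alt=int((allele[cm] == alt).sum()))
    if veto.any():
        return "INHERITED", counts
    if counts["HIFI"].n_alt >= 1 and counts["ILLUMINA"].n_alt >= 1:
        return "VALIDATED", counts
    return "FAILED_SUPPORT", counts


def multiallele_filter(cand: CandidateVariant, evidence: ReadEvidence,
                       max_extra_alleles: int = 2) -> bool:
    """True (pass) unless the child's usable reads show >= ``max_extra_alleles``
    distinct non-reference, non-de-novo alleles each backed by >= 2 reads
    (an automated stand-in for visual multi-allele review)."""
    arr = evidence.site_arrays(cand.chrom, cand.pos)
    usable = _indel_usable_mask(arr) & (arr["sample_id"] == cand.child_id)
    ref, alt = cand.variant.ref, cand.variant.alt
    extra = arr["allele"][usable]
    extra = extra[(extra != ref) & (extra != alt)]
    n_supported = sum(1 for n in Counter(extra).values() if n >= 2)
    return n_supported < max_extra_alleles
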