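"""Parent-of-origin assignment of DNMs via informative SNPs.

Each child long read that covers a DNM is assigned to a parental haplotype
by the alleles it carries at nearby *informative* SNPs — inherited het sites
whose child alt allele can be traced unambiguously to one parent (e.g.
0/0 x 0/1 -> child 0/1).  A read's inheritance score is the
inverse-distance-weighted mean of per-SNP votes (+1 maternal, -1 paternal);
negative scores mark paternally inherited reads.  A DNM is phased when every
read carrying the de novo allele lands on one parental haplotype; reads on
both haplotypes leave it in conflict.  HiFi assignments are preferred, with
ONT as a fallback; variants that stay unassignable despite informative SNPs
being present are treated as sequencing errors and excluded.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .io import ReadEvidence
from .model import Phase, VariantCall

PHASING_MIN_BASE_QUAL = 20


@dataclass
class InformativeSNP:
    pos: int
    donor_parent: str  # "P" | "M"
    tag_allele: str    # allele the child inherited from donor_parent
    other_allele: str  # allele the child inherited from the other parent


@dataclass
class PhaseResult:
    platform: str
    assignment: Phase
    n_denovo_paternal: int = 0
    n_denovo_maternal: int = 0
    # per parental haplotype: (n_ref, n_alt, n_other) over all assigned reads
    hap_counts: dict[str, tuple] = field(default_factory=dict)


class TrioCallIndex:
    """Sorted per-chromosome index over one family's variant calls."""

    def __init__(self, calls: list[VariantCall]):
        self._by_chrom: dict[str, tuple[list[int], list[VariantCall]]] = {}
        groups: dict[str, list[VariantCall]] = {}
        for c in calls:
            groups.setdefault(c.chrom, []).append(c)
        for chrom, cs in groups.items():
            cs.sort(key=lambda c: c.pos)
            self._by_chrom[chrom] = ([c.pos for c in cs], cs)

    def window(self, chrom: str, lo: int, hi: int) -> list[VariantCall]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        pos, cs = entry
        i = bisect.bisect_left(pos, lo)
        j = bisect.bisect_right(pos, hi)
        return cs[i:j]


def _informative(call: VariantCall, father_id: str, mother_id: str,
                 child_id: str) -> InformativeSNP | None:
    """Classify one trio call as an informative SNP for the child, if possible."""
    if not call.is_snv:
        return None
    f = call.genotypes.get(father_id)
    m = call.genotypes.get(mother_id)
    c = call.genotypes.get(child_id)
    if f is None or m is None or c is None:
        return None
    if sorted(c) != [0, 1] or len(f) != 2 or len(m) != 2:
        return None
    # which parent could have donated the child's alt (the other giving ref)?
    from_father = (1 in f) and (0 in m)
    from_mother = (1 in m) and (0 in f)
    if from_father == from_mother:
        return None  # ambiguous (or impossible) origin
    donor = "P" if from_father else "M"
    return InformativeSNP(pos=call.pos, donor_parent=donor,
                          tag_allele=call.alt, other_allele=call.ref)


def find_informative_snps(index: TrioCallIndex, dnm_chrom: str, dnm_pos: int,
                          father_id: str, mother_id: str, child_id: str,
                          window_bp: int = 80000) -> list[InformativeSNP]:
    """Informative SNPs within a window centred on the DNM (DNM site excluded)."""
    half = window_bp // 2
    out = []
    for call in index.window(dnm_chrom, dnm_pos - half, dnm_pos + half):
        if call.pos == dnm_pos:
            continue
        snp = _informative(call, father_id, mother_id, child_id)
        if snp is not None:
            out.append(snp)
    return out


def read_inheritance_score(tag_alleles: list[tuple[int, str]],
                           snps: dict[int, InformativeSNP],
                           dnm_pos: int) -> float | None:
    """Inverse-distance-weighted haplotype vote for one read.

    Positive -> maternal, negative -> paternal, None -> no informative SNP
    spanned (or every spanned tag mismatched both parental alleles).
    """
    num = 0.0
    den = 0.0
    for pos, allele in tag_alleles:
        snp = snps.get(pos)
        if snp is None:
            continue
        v = 1.0 if snp.donor_parent == "M" else -1.0
        if allele == snp.tag_allele:
            vote = v
        elif allele == snp.other_allele:
            vote = -v
        else:
            continue  # sequencing error at the tag site
        w = 1.0 / max(1, abs(pos - dnm_pos))
        num += w * vote
        den += w
    if den == 0:
        return None
    return num / den


def phase_dnm(evidence: ReadEvidence, snps: list[InformativeSNP],
              variant: VariantCall, child_id: str, platform: str) -> PhaseResult:
    """Phase one DNM on one long-read platform.

    Uses the same read filters as validation plus base quality >= 20 at the
    DNM site; tallies per-haplotype (ref, alt) counts for origin calling.
    """
    from .validation import _usable_mask

    arr = evidence.site_arrays(variant.chrom, variant.pos)
    mask = ((arr["sample_id"] == child_id)
            & _usable_mask(arr, "child", platform)
            & (arr["base_qual"] >= PHASING_MIN_BASE_QUAL))
    snp_map = {s.pos: s for s in snps}

    counts = {"P": [0, 0, 0], "M": [0, 0, 0]}  # side -> [n_ref, n_alt, n_other]
    n_dn = {"P": 0, "M": 0}
    alleles, tag_fields = arr["allele"], arr["tag_snps"]
    for i in np.flatnonzero(mask):
        tags = ReadEvidence.parse_tags(tag_fields[i])
        score = read_inheritance_score(tags, snp_map, variant.pos)
        if score is None or score == 0:
            continue
        side = "P" if score < 0 else "M"
        if alleles[i] == variant.alt:
            counts[side][1] += 1
            n_dn[side] += 1
        elif alleles[i] == variant.ref:
            counts[side][0] += 1
        else:
            counts[side][2] += 1

    if n_dn["P"] > 0 and n_dn["M"] > 0:
        assignment = Phase.CONFLICT
    elif n_dn["P"] > 0:
        assignment = Phase.PATERNAL
    elif n_dn["M"] > 0:
        assignment = Phase.MATERNAL
    else:
        assignment = Phase.UNPHASED
    return PhaseResult(
        platform=platform, assignment=assignment,
        n_denovo_paternal=n_dn["P"], n_denovo_maternal=n_dn["M"],
        hap_counts={side: tuple(c) for side, c in counts.items()},
    )


def merge_phase(hifi: PhaseResult, ont: PhaseResult,
                has_informative_snps: bool) -> Phase | str:
    """Merge per-platform phase calls: HiFi wins, ONT rescues, and variants
    that remain unassignable despite informative SNPs are excluded."""
    if hifi.assignment in (Phase.PATERNAL, Phase.MATERNAL):
        return hifi.assignment
    if ont.assignment in (Phase.PATERNAL, Phase.MATERNAL):
        return ont.assignment
    if has_informative_snps:
        return "EXCLUDE"
    return Phase.UNPHASED
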