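"""Naive de novo candidate selection from trio callsets.

A candidate is any site where both parents are homozygous reference and the
child carries the alternate allele with genotype quality >= 20 (child GQ
only; parental GQ is not thresholded).  Runs of three or more candidate SNVs
of one child inside any 1 kbp window are set aside as likely
dropped-parental-haplotype artifacts.  Sex chromosomes use ploidy-aware
rules: female X is treated like an autosome (with a hemizygous-reference
father), male X/Y compare the child's haploid allele against the relevant
parent only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Pedigree, VariantCall
from .io import FeatureTrack


@dataclass
class CandidateVariant:
    variant: VariantCall
    child_id: str
    category: str  # SNV | INDEL_TR | INDEL_NONTR
    sex_chrom_mode: str = "AUTO"  # AUTO | FEMALE_X | MALE_X | MALE_Y

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def key(self) -> tuple:
        return (*self.variant.key, self.child_id)


def union_callsets(callsets: list[list[VariantCall]]) -> list[VariantCall]:
    """Deduplicate caller callsets by (chrom, pos, ref, alt).

    Caller provenance is unioned; per-sample GQ is merged by maximum so a
    variant passing the GQ threshold in any caller's record survives.
    """
    if not callsets:
        raise ValueError("need at least one callset")
    merged: dict[tuple, VariantCall] = {}
    for callset in callsets:
        for call in callset:
            prev = merged.get(call.key)
            if prev is None:
                merged[call.key] = VariantCall(
                    chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
                    genotypes=dict(call.genotypes), gq=dict(call.gq),
                    caller_ids=call.caller_ids,
                )
            else:
                prev.caller_ids = prev.caller_ids | call.caller_ids
                for s, gq in call.gq.items():
                    prev.gq[s] = max(prev.gq.get(s, 0), gq)
                for s, gt in call.genotypes.items():
                    if prev.genotypes.get(s) is None:
                        prev.genotypes[s] = gt
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def _is_homref(gt) -> bool:
    return gt is not None and len(gt) == 2 and gt == (0, 0)


def _carries_alt(gt) -> bool:
    return gt is not None and 1 in gt


def _select_denovo(calls, pedigree, gq_min, want_snv) -> list[CandidateVariant]:
    out: list[CandidateVariant] = []
    skipped_missing = 0
    for call in calls:
        if call.is_snv != want_snv:
            continue
        for fam in pedigree.families.values():
            f_gt = call.genotypes.get(fam.father.sample_id)
            m_gt = call.genotypes.get(fam.mother.sample_id)
            if fam.father.sample_id not in call.genotypes:
                continue  # family not in this callset
            if f_gt is None or m_gt is None:
                skipped_missing += 1
                continue
            if not (_is_homref(f_gt) and _is_homref(m_gt)):
                continue
            for child in fam.children:
                c_gt = call.genotypes.get(child.sample_id)
                if not _carries_alt(c_gt):
                    continue
                if call.gq.get(child.sample_id, 0) < gq_min:
                    continue
                out.append(CandidateVariant(
                    variant=call, child_id=child.sample_id,
                    category="SNV" if want_snv else "INDEL",
                ))
    return out


def select_candidate_snvs(calls: list[VariantCall], pedigree: Pedigree,
                          gq_min: int = 20) -> list[CandidateVariant]:
    """Autosomal candidate SNVs: parents 0/0, child carries alt, child GQ >= gq_min."""
    return _select_denovo(calls, pedigree, gq_min, want_snv=True)


def select_candidate_indels(calls: list[VariantCall], pedigree: Pedigree,
                            gq_min: int = 20) -> list[CandidateVariant]:
    """Candidate indels under the same naive trio rule as SNVs."""
    return [c for c in _select_denovo(calls, pedigree, gq_min, want_snv=False)
            if c.variant.is_indel]


def cluster_filter(candidates: list[CandidateVariant], window_bp: int = 1000,
                   min_count: int = 3) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Partition candidate SNVs into (kept, clustered).

    A candidate SNV is *clustered* if some window of ``window_bp`` consecutive
    bases contains >= ``min_count`` candidate SNVs of the same child on the
    same chromosome — equivalently, if it belongs to a group of
    ``min_count`` SNVs whose positions span <= window_bp - 1 bases.  Windows
    slide at every base offset.  Indel candidates pass through untouched.
    """
    by_group: dict[tuple, list[CandidateVariant]] = {}
    passthrough: list[CandidateVariant] = []
    for c in candidates:
        if c.category != "SNV":
            passthrough.append(c)
            continue
        by_group.setdefault((c.child_id, c.chrom), []).append(c)

    kept: list[CandidateVariant] = list(passthrough)
    clustered: list[CandidateVariant] = []
    for group in by_group.values():
        group.sort(key=lambda c: c.pos)
        pos = [c.pos for c in group]
        n = len(pos)
        flagged = [False] * n
        for i in range(n - min_count + 1):
            j = i + min_count - 1
            if pos[j] - pos[i] <= window_bp - 1:
                for k in range(i, j + 1):
                    flagged[k] = True
        for c, f in zip(group, flagged):
            (clustered if f else kept).append(c)
    kept.sort(key=lambda c: (c.chrom, c.pos, c.child_id))
    clustered.sort(key=lambda c: (c.chrom, c.pos, c.child_id))
    return kept, clustered


def select_sex_candidates(calls: list[VariantCall], pedigree: Pedigree,
                          child_sex: str, gq_min: int = 20,
                          par_track: FeatureTrack | None = None) -> list[CandidateVariant]:
    """Ploidy-aware sex-chromosome candidate selection.

    Female X behaves like an autosome with a hemizygous-reference father;
    male X compares the child's haploid allele against the mother's alleles,
    male Y against the father's.  Pseudoautosomal regions (class "PAR" in
    ``par_track``) are excluded.
    """
    out: list[CandidateVariant] = []
    for call in calls:
        if par_track is not None and par_track.overlaps(call.chrom, call.pos, "PAR"):
            continue
        on_y = call.chrom in ("chrY", "Y")
        for fam in pedigree.families.values():
            if fam.father.sample_id not in call.genotypes:
                continue
            f_gt = call.genotypes.get(fam.father.sample_id)
            m_gt = call.genotypes.get(fam.mother.sample_id)
            for child in fam.children:
                if child.sex != child_sex:
                    continue
                c_gt = call.genotypes.get(child.sample_id)
                if c_gt is None:
                    continue
                if call.gq.get(child.sample_id, 0) < gq_min:
                    continue
                if child_sex == "F":
                    if on_y:
                        continue
                    # female X: mother 0/0, father hemizygous reference
                    if m_gt == (0, 0) and f_gt == (0,) and _carries_alt(c_gt):
                        out.append(CandidateVariant(call, child.sample_id,
                                                    "SNV" if call.is_snv else "INDEL",
                                                    sex_chrom_mode="FEMALE_X"))
                else:
                    if len(c_gt) != 1:
                        raise ValueError(
                            f"male sample {child.sample_id!r} has diploid genotype "
                            f"on {call.chrom}:{call.pos}")
                    if on_y:
                        if f_gt is None:
                            continue
                        if len(f_gt) != 1:
                            raise ValueError(
                                f"male sample {fam.father.sample_id!r} has diploid "
                                f"genotype on {call.chrom}:{call.pos}")
                        if c_gt[0] != f_gt[0]:
                            out.append(CandidateVariant(call, child.sample_id,
                                                        "SNV" if call.is_snv else "INDEL",
                                                        sex_chrom_mode="MALE_Y"))
                    else:
                        if m_gt is None:
                            continue
                        if c_gt[0] not in m_gt:
                            out.append(CandidateVariant(call, child.sample_id,
                                                        "SNV" if call.is_snv else "INDEL",
                                                        sex_chrom_mode="MALE_X"))
    return out


def _indel_sequence(variant: VariantCall) -> str:
    """Inserted or deleted bases of a left-anchored indel."""
    if len(variant.alt) > len(variant.ref):
        return variant.alt[len(variant.ref):]
    return variant.ref[len(variant.alt):]


def _is_motif_multiple(seq: str, motif: str) -> bool:
    if not motif or len(seq) % len(motif) != 0:
        return False
    # allow any rotation of the motif (VCF anchoring is arbitrary in a TR)
    k = len(seq) // len(motif)
    return seq in (motif * (k + 2))


def classify_indel_category(variant: VariantCall, tr_track: FeatureTrack) -> str:
    """INDEL_TR iff the indel is a whole-motif expansion/contraction of an
    overlapping tandem repeat (motif given in the TR track's 5th column)."""
    seq = _indel_sequence(variant)
    for _, _, fclass, data in tr_track.hits(variant.chrom, variant.pos):
        if fclass != "TR":
            continue
        motif = data if isinstance(data, str) else None
        if motif and _is_motif_multiple(seq, motif):
            return "INDEL_TR"
    return "INDEL_NONTR"
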