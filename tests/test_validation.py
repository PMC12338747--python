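import itertools

import pandas as pd
import pytest

from trioscope.candidates import CandidateVariant
from trioscope.io import EVIDENCE_COLUMNS, FeatureTrack, ReadEvidence
from trioscope.model import Family, Pedigree, Person, Role, Verdict, VariantCall
from trioscope.validation import (PARENT_ALT_CAPS, combine_verdicts,
                                  cohort_recurrence_filter, homopolymer_filter,
                                  multiallele_filter, noisy_support_filter,
                                  platform_verdict_snv, repeat_ab_filters,
                                  usable_reads, validate_indel)


def _rows(sample, platform, tissue, n, allele, mapq=60, bq=30, chrom="chr1",
          pos=100, fl=500, fr=500):
    return [dict(sample_id=sample, platform=platform, tissue=tissue,
                 chrom=chrom, pos=pos, read_id=f"{sample}.{platform}.{i}.{allele}.{bq}",
                 mapq=mapq, base_qual=bq, allele=allele, flank_left=fl,
                 flank_right=fr, tag_snps=".") for i in range(n)]


def _df(rows):
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)


def _ped():
    fa = Person("fa", "F1", Role.FATHER, "M")
    mo = Person("mo", "F1", Role.MOTHER, "F")
    c1 = Person("c1", "F1", Role.PROBAND, "M", "fa", "mo", 30, 28)
    c2 = Person("c2", "F1", Role.SIBLING, "F", "fa", "mo", 32, 30)
    fa2 = Person("fa2", "F2", Role.FATHER, "M")
    mo2 = Person("mo2", "F2", Role.MOTHER, "F")
    u1 = Person("u1", "F2", Role.PROBAND, "M", "fa2", "mo2", 40, 38)
    return Pedigree([Family("F1", fa, mo, [c1, c2]), Family("F2", fa2, mo2, [u1])])


def _cand(ref="A", alt="G", pos=100, child="c1"):
    v = VariantCall(chrom="chr1", pos=pos, ref=ref, alt=alt, genotypes={}, gq={})
    return CandidateVariant(v, child, "SNV" if len(ref) == len(alt) == 1 else "INDEL")


class TestUsableReads:
    def test_child_hifi_cell_line_excluded(self):
        df = _df(_rows("c1", "HIFI", "CELL_LINE", 3, "G")
                 + _rows("c1", "HIFI", "BLOOD", 2, "G"))
        out = usable_reads(df, "child", "HIFI")
        assert len(out) == 2
        parent = usable_reads(df.assign(sample_id="fa"), "parent", "HIFI")
        assert len(parent) == 5  # parents keep both tissues

    def test_long_read_mapq_59_boundary(self):
        df = _df(_rows("c1", "ONT", "CELL_LINE", 1, "G", mapq=58)
                 + _rows("c1", "ONT", "CELL_LINE", 1, "G", mapq=59))
        assert len(usable_reads(df, "child", "ONT")) == 1

    def test_short_reads_skip_mapq_filter_and_tier(self):
        df = _df(_rows("c1", "ILLUMINA", "BLOOD", 1, "G", mapq=5, bq=30))
        out = usable_reads(df, "child", "ILLUMINA")
        assert list(out["tier"]) == ["HIGH"]

    def test_base_quality_tiers(self):
        df = _df(_rows("c1", "HIFI", "BLOOD", 1, "G", bq=21)
                 + _rows("c1", "HIFI", "BLOOD", 1, "G", bq=20)
                 + _rows("c1", "HIFI", "BLOOD", 1, "G", bq=10)
                 + _rows("c1", "HIFI", "BLOOD", 1, "G", bq=9))
        out = usable_reads(df, "child", "HIFI")
        assert sorted(out["tier"]) == ["HIGH", "LOW", "LOW"]


class TestPlatformVerdict:
    def test_clean_parents_child_support(self):
        df = _df(_rows("c1", "HIFI", "BLOOD", 3, "G") + _rows("c1", "HIFI", "BLOOD", 10, "A")
                 + _rows("fa", "HIFI", "BLOOD", 20, "A") + _rows("mo", "HIFI", "BLOOD", 20, "A"))
        v = platform_verdict_snv(df, "c1", "fa", "mo", "A", "G", "HIFI")
        assert v.verdict is Verdict.DENOVO
        assert (v.child_counts.n_ref, v.child_counts.n_alt) == (10, 3)

    def test_single_parent_hq_alt_read_fails_hifi(self):
        df = _df(_rows("c1", "HIFI", "BLOOD", 3, "G")
                 + _rows("fa", "HIFI", "BLOOD", 1, "G") + _rows("fa", "HIFI", "BLOOD", 19, "A")
                 + _rows("mo", "HIFI", "BLOOD", 20, "A"))
        assert platform_verdict_snv(df, "c1", "fa", "mo", "A", "G", "HIFI").verdict \
            is Verdict.INHERITED

    def test_ont_tolerates_one_hq_parent_read(self):
        df = _df(_rows("c1", "ONT", "CELL_LINE", 5, "G")
                 + _rows("fa", "ONT", "CELL_LINE", 1, "G")
                 + _rows("fa", "ONT", "CELL_LINE", 30, "A")
                 + _rows("mo", "ONT", "CELL_LINE", 30, "A"))
        assert platform_verdict_snv(df, "c1", "fa", "mo", "A", "G", "ONT").verdict \
            is Verdict.DENOVO

    def test_low_quality_caps(self):
        # HiFi: 2 LQ parental alt reads exceed the <2 cap; 1 passes
        base = _rows("c1", "HIFI", "BLOOD", 3, "G") + _rows("mo", "HIFI", "BLOOD", 9, "A")
        one = _df(base + _rows("fa", "HIFI", "BLOOD", 1, "G", bq=15))
        two = _df(base + _rows("fa", "HIFI", "BLOOD", 2, "G", bq=15))
        assert platform_verdict_snv(one, "c1", "fa", "mo", "A", "G", "HIFI").verdict \
            is Verdict.DENOVO
        assert platform_verdict_snv(two, "c1", "fa", "mo", "A", "G", "HIFI").verdict \
            is Verdict.INHERITED

    def test_nodata_and_no_support(self):
        parents = _rows("fa", "HIFI", "BLOOD", 5, "A") + _rows("mo", "HIFI", "BLOOD", 5, "A")
        nodata = platform_verdict_snv(_df(parents), "c1", "fa", "mo", "A", "G", "HIFI")
        assert nodata.verdict is Verdict.NODATA
        refonly = platform_verdict_snv(
            _df(parents + _rows("c1", "HIFI", "BLOOD", 5, "A")),
            "c1", "fa", "mo", "A", "G", "HIFI")
        assert refonly.verdict is Verdict.NO_SUPPORT

    def test_raising_parental_caps_never_shrinks_validated(self):
        # monotonicity: any pileup DENOVO under the strict caps stays DENOVO
        # when the caps are raised
        df = _df(_rows("c1", "HIFI", "BLOOD", 4, "G")
                 + _rows("fa", "HIFI", "BLOOD", 20, "A") + _rows("mo", "HIFI", "BLOOD", 20, "A"))
        strict = platform_verdict_snv(df, "c1", "fa", "mo", "A", "G", "HIFI")
        try:
            PARENT_ALT_CAPS["HIFI"] = (5, 5)
            loose = platform_verdict_snv(df, "c1", "fa", "mo", "A", "G", "HIFI")
        finally:
            PARENT_ALT_CAPS["HIFI"] = (0, 1)
        assert strict.verdict is Verdict.DENOVO and loose.verdict is Verdict.DENOVO


def _verdict(kind):
    from trioscope.validation import PlatformVerdict
    from trioscope.model import PlatformAlleleCounts
    return PlatformVerdict("HIFI", kind, PlatformAlleleCounts("HIFI", 1, 1))


@pytest.mark.parametrize("kinds, expected", [
    ((Verdict.DENOVO, Verdict.DENOVO, Verdict.NODATA), "VALIDATED"),
    ((Verdict.DENOVO, Verdict.INHERITED, Verdict.DENOVO), "INHERITED"),
    ((Verdict.DENOVO, Verdict.NODATA, Verdict.NODATA), "FAILED_SUPPORT"),
    ((Verdict.DENOVO, Verdict.NO_SUPPORT, Verdict.DENOVO), "VALIDATED"),
    ((Verdict.NODATA, Verdict.NODATA, Verdict.NODATA), "FAILED_SUPPORT"),
])
def test_combine_verdicts(kinds, expected):
    assert combine_verdicts([_verdict(k) for k in kinds]) == expected


NO_TR = FeatureTrack([])
TR_AT_100 = FeatureTrack([("chr1", 50, 150, "TR", "AT")])


class TestRecurrence:
    def test_non_tr_unique_required(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 3, "G")
                              + _rows("u1", "HIFI", "BLOOD", 1, "G")))
        assert not cohort_recurrence_filter(_cand(), ev, _ped(), NO_TR)

    def test_tr_allows_one_unrelated_carrier(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 3, "G")
                              + _rows("u1", "HIFI", "BLOOD", 1, "G")))
        assert cohort_recurrence_filter(_cand(), ev, _ped(), TR_AT_100)

    def test_sibling_and_parent_carriage_not_recurrence(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 3, "G")
                              + _rows("c2", "HIFI", "BLOOD", 2, "G")
                              + _rows("fa", "HIFI", "BLOOD", 1, "G")))
        assert cohort_recurrence_filter(_cand(), ev, _ped(), NO_TR)


class TestRepeatAb:
    def test_tr_ab_floor(self):
        ok, reason = repeat_ab_filters(_cand(), 0.04, NO_TR, TR_AT_100)
        assert not ok and reason == "TR_AB"
        ok, _ = repeat_ab_filters(_cand(), 0.06, NO_TR, TR_AT_100)
        assert ok

    def test_rm_thresholds_depend_on_tr(self):
        rm = FeatureTrack([("chr1", 50, 150, "RM")])
        ok, _ = repeat_ab_filters(_cand(), 0.09, rm, NO_TR)
        assert ok  # 0.09 > 0.08 outside a TR
        ok, reason = repeat_ab_filters(_cand(), 0.09, rm, TR_AT_100)
        assert not ok and reason == "RM_AB"  # needs > 0.1 inside a TR

    def test_outside_repeats_no_floor(self):
        assert repeat_ab_filters(_cand(), 0.02, NO_TR, NO_TR) == (True, "OK")

    def test_no_reads_in_repeat_fails(self):
        ok, reason = repeat_ab_filters(_cand(), None, NO_TR, TR_AT_100)
        assert not ok and reason == "NODATA"


class TestHomopolymer:
    def test_edge_substitution_of_run_base_fails(self):
        # A>T at the left edge of an AAAAA run
        assert not homopolymer_filter("A", "T", "GCGC", "AAAAAGC")

    def test_alt_equal_to_run_base_fails(self):
        assert not homopolymer_filter("C", "A", "GCGC", "AAAAGC")

    def test_unrelated_bases_pass(self):
        assert homopolymer_filter("C", "G", "GTGT", "AAAATC"[1:])

    def test_distance_rule_matches_brute_force(self):
        # G>A 2 bp left of an AAAA run: outside the 1 bp adjacency
        assert homopolymer_filter("G", "A", "GCGCGC", "CTAAAAC")
        # directly adjacent (1 bp): inside, and alt equals the run base
        assert not homopolymer_filter("G", "A", "GCGCGC", "AAAAC")

    def test_short_runs_ignored(self):
        # ref A extends AA to only 3 consecutive bases: below the 4-run floor
        assert homopolymer_filter("A", "T", "GCGC", "AAGC")

    def test_applies_to_snvs_only(self):
        assert homopolymer_filter("A", "AT", "GCGC", "AAAAAGC")


class TestIndelValidation:
    def _evidence(self, extra=()):
        rows = (_rows("c1", "HIFI", "BLOOD", 4, "ATT") + _rows("c1", "HIFI", "BLOOD", 10, "A")
                + _rows("c1", "ILLUMINA", "BLOOD", 3, "ATT", fl=40, fr=40)
                + _rows("c1", "ILLUMINA", "BLOOD", 12, "A", fl=40, fr=40)
                + _rows("fa", "HIFI", "BLOOD", 20, "A") + _rows("mo", "HIFI", "BLOOD", 20, "A")
                + list(extra))
        return ReadEvidence(_df(rows))

    def test_both_platforms_required(self):
        cand = _cand(ref="A", alt="ATT")
        ev = self._evidence()
        status, counts = validate_indel(cand, ev, _ped())
        assert status == "VALIDATED"
        assert counts["HIFI"].n_alt == 4 and counts["ILLUMINA"].n_alt == 3
        # drop Illumina support -> FAILED
        hifi_only = ReadEvidence(_df(
            _rows("c1", "HIFI", "BLOOD", 4, "ATT") + _rows("fa", "HIFI", "BLOOD", 5, "A")))
        assert validate_indel(cand, hifi_only, _ped())[0] == "FAILED_SUPPORT"

    def test_sibling_read_vetoes(self):
        cand = _cand(ref="A", alt="ATT")
        ev = self._evidence(extra=_rows("c2", "ONT", "CELL_LINE", 1, "ATT"))
        assert validate_indel(cand, ev, _ped())[0] == "INHERITED"

    def test_flank_and_mapq_requirements(self):
        cand = _cand(ref="A", alt="ATT")
        short_flank = _rows("c1", "ILLUMINA", "BLOOD", 3, "ATT", fl=40, fr=8)
        bad_mapq = _rows("c1", "ILLUMINA", "BLOOD", 3, "ATT", mapq=50, fl=40, fr=40)
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 4, "ATT")
                              + short_flank + bad_mapq))
        status, counts = validate_indel(cand, ev, _ped())
        assert counts["ILLUMINA"].n_alt == 0
        assert status == "FAILED_SUPPORT"


class TestMultiallele:
    def test_ref_plus_denovo_passes(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 5, "ATT")
                              + _rows("c1", "HIFI", "BLOOD", 10, "A")))
        assert multiallele_filter(_cand(ref="A", alt="ATT"), ev)

    def test_two_supported_extra_alleles_fail(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 5, "ATT")
                              + _rows("c1", "HIFI", "BLOOD", 3, "AG")
                              + _rows("c1", "HIFI", "BLOOD", 3, "ACC")))
        assert not multiallele_filter(_cand(ref="A", alt="ATT"), ev)

    def test_single_stray_read_tolerated(self):
        ev = ReadEvidence(_df(_rows("c1", "HIFI", "BLOOD", 5, "ATT")
                              + _rows("c1", "HIFI", "BLOOD", 3, "AG")
                              + _rows("c1", "HIFI", "BLOOD", 1, "ACC")))
        assert multiallele_filter(_cand(ref="A", alt="ATT"), ev)


def test_noisy_support_filter_needs_two_platforms():
    third = lambda platform, tissue, n: _rows("fa", platform, tissue, n, "T")
    base = _rows("c1", "HIFI", "BLOOD", 5, "G")
    one_noisy = ReadEvidence(_df(base + third("HIFI", "BLOOD", 3)))
    two_noisy = ReadEvidence(_df(base + third("HIFI", "BLOOD", 3)
                                 + third("ILLUMINA", "BLOOD", 2)))
    cand = _cand()
    site = one_noisy.at_site("chr1", 100)
    assert noisy_support_filter(cand, site, _ped())
    site = two_noisy.at_site("chr1", 100)
    assert not noisy_support_filter(cand, site, _ped())


def test_site_filters_commute():
    """Recurrence, repeat-AB, and homopolymer filters are pure predicates:
    the surviving set is identical under any application order."""
    ped = _ped()
    ev = ReadEvidence(_df(
        _rows("c1", "HIFI", "BLOOD", 3, "G")
        + _rows("u1", "HIFI", "BLOOD", 1, "G")))
    cand = _cand()
    preds = {
        "recurrence": lambda: cohort_recurrence_filter(cand, ev, ped, NO_TR),
        "repeat_ab": lambda: repeat_ab_filters(cand, 0.04, NO_TR, TR_AT_100)[0],
        "homopolymer": lambda: homopolymer_filter("A", "T", "GCGC", "AAAAAGC"),
    }
    results = {}
    for order in itertools.permutations(preds):
        results[order] = [preds[name]() for name in order]
        assert not all(results[order])  # this candidate fails every ordering
    first = {name: preds[name]() for name in preds}
    for order, vals in results.items():
        assert vals == [first[name] for name in order]
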