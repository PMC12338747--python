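import numpy as np
import pandas as pd
import pytest

from trioscope.callable_rates import (benjamini_hochberg, compare_rates,
                                      compute_callable_mask, dnms_in_feature,
                                      feature_rate, intersect_intervals,
                                      mask_feature_intersection, mutation_rate)
from trioscope.io import EVIDENCE_COLUMNS, FeatureTrack, ReadEvidence
from trioscope.model import (CallableMask, DnmRecord, Family, Pedigree, Person,
                             Role)


def _ped():
    fa = Person("fa", "F1", Role.FATHER, "M")
    mo = Person("mo", "F1", Role.MOTHER, "F")
    c1 = Person("c1", "F1", Role.PROBAND, "M", "fa", "mo", 30, 28)
    return Pedigree([Family("F1", fa, mo, [c1])])


def _evidence(rows):
    return ReadEvidence(pd.DataFrame(rows, columns=EVIDENCE_COLUMNS))


def _read(sample, pos, mapq=60, bq=30, tissue="BLOOD", platform="HIFI"):
    return dict(sample_id=sample, platform=platform, tissue=tissue,
                chrom="chr1", pos=pos, read_id=f"{sample}.{pos}.{mapq}.{bq}",
                mapq=mapq, base_qual=bq, allele="A", flank_left=100,
                flank_right=100, tag_snps=".")


class TestCallableMask:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "father_gt", "mother_gt"])

    def test_trio_covered_site_callable(self):
        sites = self._sites([("chr1", 10, "0/0", "0/0")])
        ev = _evidence([_read("fa", 10), _read("mo", 10), _read("c1", 10)])
        mask = compute_callable_mask(sites, ev, _ped(), "c1")
        assert mask.intervals == {"chr1": [(9, 10)]}
        assert mask.total_bp() == 1

    def test_parent_alt_genotype_uncallable(self):
        sites = self._sites([("chr1", 10, "0/1", "0/0")])
        ev = _evidence([_read("fa", 10), _read("mo", 10), _read("c1", 10)])
        assert compute_callable_mask(sites, ev, _ped(), "c1").total_bp() == 0

    def test_quality_thresholds(self):
        sites = self._sites([("chr1", 10, "0/0", "0/0")])
        low_mapq = _evidence([_read("fa", 10, mapq=58), _read("mo", 10),
                              _read("c1", 10)])
        assert compute_callable_mask(sites, low_mapq, _ped(), "c1").total_bp() == 0
        low_bq = _evidence([_read("fa", 10), _read("mo", 10),
                            _read("c1", 10, bq=19)])
        assert compute_callable_mask(sites, low_bq, _ped(), "c1").total_bp() == 0

    def test_child_cell_line_reads_ignored(self):
        sites = self._sites([("chr1", 10, "0/0", "0/0")])
        ev = _evidence([_read("fa", 10, tissue="CELL_LINE"), _read("mo", 10),
                        _read("c1", 10, tissue="CELL_LINE")])
        assert compute_callable_mask(sites, ev, _ped(), "c1").total_bp() == 0

    def test_male_y_ignores_parent_genotypes_and_mother(self):
        sites = self._sites([("chr1", 10, "1", ".")])
        ev = _evidence([_read("fa", 10), _read("c1", 10)])
        mask = compute_callable_mask(sites, ev, _ped(), "c1", mode="MALE_Y")
        assert mask.total_bp() == 1

    def test_adjacent_sites_merge(self):
        sites = self._sites([("chr1", p, "0/0", "0/0") for p in (10, 11, 13)])
        rows = [r for p in (10, 11, 13)
                for r in (_read("fa", p), _read("mo", p), _read("c1", p))]
        mask = compute_callable_mask(sites, _evidence(rows), _ped(), "c1")
        assert mask.intervals == {"chr1": [(9, 11), (12, 13)]}


class TestMutationRate:
    def test_arithmetic(self):
        est = mutation_rate([(100, 2_500_000_000)], ploidy_factor=2,
                            bootstrap_reps=100, seed=0)
        assert est.rate == pytest.approx(2.0e-8)
        assert est.n_mutations == 100 and est.ploidy_factor == 2

    def test_zero_mutations(self):
        est = mutation_rate([(0, 1_000_000), (0, 1_000_000)], 2,
                            bootstrap_reps=200, seed=0)
        assert est.rate == 0 and est.ci_low == 0

    def test_ci_brackets_rate(self):
        rng = np.random.default_rng(1)
        per_child = [(int(rng.poisson(50)), 1_000_000) for _ in range(40)]
        est = mutation_rate(per_child, 2, bootstrap_reps=2_000, seed=3)
        assert est.ci_low <= est.rate <= est.ci_high

    def test_zero_callable_raises(self):
        with pytest.raises(ValueError):
            mutation_rate([(1, 0)], 2)


def test_interval_intersection():
    a = [(0, 10), (20, 30)]
    b = [(5, 25), (28, 40)]
    assert intersect_intervals(a, b) == [(5, 10), (20, 25), (28, 30)]
    assert intersect_intervals(a, []) == []


SD_TRACK = FeatureTrack([("chr1", 1_000, 2_000, "SD", 99.5),
                         ("chr1", 5_000, 6_000, "SD", 95.0)])


def _dnm(pos, child="c1"):
    return DnmRecord(chrom="chr1", pos=pos, ref="A", alt="T", child_id=child,
                     variant_type="SNV", validation_status="VALIDATED")


class TestFeatureRates:
    def test_boundary_base_excluded(self):
        # BED end-exclusive: 1-based 2000 is 0-based 1999 (in), 2001 is out
        assert dnms_in_feature([_dnm(2_000)], SD_TRACK, "SD")
        assert not dnms_in_feature([_dnm(2_001)], SD_TRACK, "SD")

    def test_identity_bins(self):
        dnms = [_dnm(1_500), _dnm(5_500)]
        high = dnms_in_feature(dnms, SD_TRACK, "SD", pct_range=(99.0, 100.1))
        assert [d.pos for d in high] == [1_500]

    def test_mask_intersection_and_rate(self):
        mask = CallableMask("c1", {"chr1": [(0, 10_000)]})
        assert mask_feature_intersection(mask, SD_TRACK, "SD") == 2_000
        est = feature_rate({"c1": [_dnm(1_500), _dnm(5_500)]}, {"c1": mask},
                           SD_TRACK, "SD", bootstrap_reps=50)
        assert est.rate == pytest.approx(2 / (2 * 2_000))

    def test_empty_intersection_returns_none(self):
        mask = CallableMask("c1", {"chr2": [(0, 1_000)]})
        assert feature_rate({"c1": []}, {"c1": mask}, SD_TRACK, "SD",
                            bootstrap_reps=50) is None


def test_benjamini_hochberg_hand_computed():
    # step-up on (0.01, 0.02, 0.04) at m=3: (0.03, 0.03, 0.04)
    assert benjamini_hochberg([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])


class TestSdEnrichmentRecovery:
    def test_configured_enrichment_recovered_end_to_end(self):
        """A cohort simulated with 3x SD mutation enrichment yields an SD
        rate ~3x genome-wide through the full pipeline, detected by the
        paired per-sample t-test."""
        from trioscope.callable_rates import (compare_rates, dnms_in_feature,
                                              mask_feature_intersection)
        from trioscope.model import Origin
        from trioscope.pipeline import run_pipeline
        from trioscope.simulate import study_preset

        cfg = study_preset(seed=9)
        cfg.n_families = 6
        cfg.sd_enrichment = 3.0
        res = run_pipeline(config=cfg)
        cohort = res.cohort
        germ = [r for r in res.final if r.is_snv and r.origin is Origin.GERMLINE]
        genome_rates, sd_rates = [], []
        for c in sorted(cohort.masks):
            mask = cohort.masks[c]
            mine = [r for r in germ if r.child_id == c]
            n = sum(mask.contains(r.chrom, r.pos) for r in mine)
            genome_rates.append(n / (2 * mask.total_bp()))
            bp = mask_feature_intersection(mask, cohort.features, "SD")
            nsd = len(dnms_in_feature(mine, cohort.features, "SD"))
            sd_rates.append(nsd / (2 * bp))
        ratio = np.mean(sd_rates) / np.mean(genome_rates)
        assert 1.8 <= ratio <= 4.5
        out = compare_rates({"SD": sd_rates}, genome_rates)
        assert out["p_BH"].iloc[0] < 0.05


class TestCompareRates:
    def test_identical_rates_statistic_zero(self):
        genome = [1.0e-8, 1.2e-8, 0.9e-8]
        out = compare_rates({"SD": list(genome)}, genome)
        assert out["t"].iloc[0] == 0 and out["p"].iloc[0] == 1.0

    def test_enriched_feature_significant(self):
        rng = np.random.default_rng(0)
        genome = rng.normal(1e-8, 1e-9, 30)
        out = compare_rates({"SD": list(genome * 2), "LINE": list(genome * 1.001)},
                            list(genome))
        p = dict(zip(out["feature"], out["p_BH"]))
        assert p["SD"] < 0.01

    def test_fewer_than_two_samples_raises(self):
        with pytest.raises(ValueError):
            compare_rates({"SD": [1e-8]}, [1e-8])
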