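import numpy as np
import pytest

from trioscope.simulate import (GeneratorConfig, PZM_SPECTRUM, GERMLINE_SPECTRUM,
                                inject_confounders, study_preset, simulate_cohort)

from conftest import small_config


class TestPreset:
    def test_paternal_fractions(self):
        cfg = study_preset()
        assert cfg.germline.paternal_fraction == pytest.approx(3.98 / 4.98)
        assert cfg.pzm.paternal_fraction == pytest.approx(1.15 / 2.15)

    def test_pzm_mean_ab(self):
        assert study_preset().pzm.mean_ab == pytest.approx(0.22)

    def test_spectra_normalised(self):
        for spec in (GERMLINE_SPECTRUM, PZM_SPECTRUM):
            assert sum(spec.values()) == pytest.approx(1.0)

    def test_spectrum_ti_fractions(self):
        ti = ("A>G", "C>T", "CpG>TpG")
        g = sum(GERMLINE_SPECTRUM[c] for c in ti)
        p = sum(PZM_SPECTRUM[c] for c in ti)
        assert g == pytest.approx(2.10 / 3.10, abs=1e-6)
        assert p == pytest.approx(1.35 / 2.35, abs=1e-3)

    def test_cohort_structure(self):
        cfg = study_preset()
        n_quads = round(cfg.n_families * cfg.quads_fraction)
        n_children = 2 * n_quads + (cfg.n_families - n_quads)
        assert (cfg.n_families, n_quads, n_children) == (42, 31, 73)

    def test_age_slopes(self):
        cfg = study_preset()
        assert cfg.germline.paternal_slope == 1.32
        assert cfg.germline.maternal_slope == 0.46
        # intercepts solve to ~70 total at the mean ages, split 3.98:1
        pat, mat = cfg.germline.expected_counts(33, 31)
        assert pat + mat == pytest.approx(70.0)
        assert pat / mat == pytest.approx(3.98)

    def test_invalid_config_rejected(self):
        cfg = study_preset()
        cfg.genome = [("chr1", 5_000)]
        with pytest.raises(ValueError, match="10 kbp"):
            simulate_cohort(cfg)
        cfg2 = study_preset()
        cfg2.germline.spectrum = {"A>G": 0.7, "C>T": 0.7}
        with pytest.raises(ValueError, match="sums to"):
            simulate_cohort(cfg2)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(seed=11, n_families=1)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg).write(a, full=True)
        simulate_cohort(small_config(seed=11, n_families=1)).write(b, full=True)
        for f in sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_different_seed_differs(self):
        t1 = simulate_cohort(small_config(seed=1, n_families=1)).truth
        t2 = simulate_cohort(small_config(seed=2, n_families=1)).truth
        assert not t1.equals(t2)


class TestTruthConsistency:
    def test_pzm_rate_zero_no_pzm_truth(self):
        cfg = small_config(seed=3, n_families=1)
        cfg.pzm.rate_fraction = 0.0
        cfg.indel.pzm_fraction = 0.0
        truth = simulate_cohort(cfg).truth
        assert not (truth["true_class"] == "PZM").any()

    def test_confounder_rates_zero_identity(self):
        cfg = small_config(seed=4, n_families=1)
        cfg.confounders.dropped_hap_runs_per_child = 0
        cfg.confounders.recurrent_sites = 0
        cfg.confounders.homopolymer_noise_per_child = 0
        cohort = simulate_cohort(cfg)
        n_rows = len(cohort.evidence)
        n_truth = len(cohort.truth)
        inject_confounders(cohort, cfg, np.random.default_rng(0))
        assert len(cohort.evidence) == n_rows
        assert len(cohort.truth) == n_truth
        assert set(cohort.truth["true_class"]) <= {"GERMLINE", "PZM"}

    def test_germline_truth_ab_half_pzm_below(self, small_cohort):
        truth = small_cohort.truth
        germ = truth[truth["true_class"] == "GERMLINE"]
        pzm = truth[truth["true_class"] == "PZM"]
        assert (germ["true_ab"] == 0.5).all()
        assert (pzm["true_ab"] < 0.5).all() and len(pzm) > 0

    def test_parents_clean_at_germline_truth_sites(self, small_cohort):
        """Parental pileups at germline DNM sites stay under the validation
        caps on the strict platforms (HiFi/Illumina) at nearly every site:
        sequencing-error alt reads exist but are rare and mostly low-quality
        by construction."""
        truth = small_cohort.truth
        ev = small_cohort.evidence
        ped = small_cohort.pedigree
        germ = truth[(truth["true_class"] == "GERMLINE")
                     & (truth["variant_type"] == "SNV")]
        flagged = 0
        for row in germ.itertuples(index=False):
            father, mother = ped.parents_of(row.child_id)
            site = ev.at_site(row.chrom, int(row.pos))
            parents = site[site["sample_id"].isin([father.sample_id,
                                                   mother.sample_id])
                           & site["platform"].isin(["HIFI", "ILLUMINA"])]
            alt_hq = parents[(parents["allele"] == row.alt)
                             & (parents["base_qual"] > 20)]
            flagged += len(alt_hq) > 0
        assert flagged / max(len(germ), 1) < 0.02

    def test_dropped_haplotype_runs_clustered(self, small_cohort):
        """Injected dropped-haplotype artifacts form >=3-in-1kbp runs."""
        truth = small_cohort.truth
        art = truth[truth["true_class"] == "INHERITED_ARTIFACT"]
        if art.empty:
            pytest.skip("no runs drawn at this seed")
        for (child, chrom), grp in art.groupby(["child_id", "chrom"]):
            pos = sorted(grp["pos"])
            # every artifact belongs to a >=3-site cluster spanning <=1 kbp
            for p in pos:
                near = [q for q in pos if abs(q - p) <= 999]
                assert len(near) >= 3

    def test_recurrent_artifacts_shared_across_families(self, small_cohort):
        truth = small_cohort.truth
        rec = truth[truth["true_class"] == "RECURRENT_ERROR"]
        if rec.empty:
            pytest.skip("no recurrent sites at this seed")
        ped = small_cohort.pedigree
        for (chrom, pos), grp in rec.groupby(["chrom", "pos"]):
            fams = {ped.person(c).family_id for c in grp["child_id"]}
            assert len(fams) >= 2
            # every labelled child has HiFi reads carrying the false allele
            site = small_cohort.evidence.at_site(chrom, int(pos))
            for row in grp.itertuples(index=False):
                hifi = site[(site["sample_id"] == row.child_id)
                            & (site["platform"] == "HIFI")
                            & (site["allele"] == row.alt)]
                assert len(hifi) >= 1


class TestReadModel:
    def test_observed_germline_hifi_ab_matches_target(self, small_cohort):
        """Monte-Carlo: observed mean HiFi allele balance of germline truth
        sites tracks the reference-bias target (0.48)."""
        truth = small_cohort.truth
        ev = small_cohort.evidence
        germ = truth[(truth["true_class"] == "GERMLINE")
                     & (truth["variant_type"] == "SNV")]
        abs_ = []
        for row in germ.itertuples(index=False):
            site = ev.at_site(row.chrom, int(row.pos))
            child = site[(site["sample_id"] == row.child_id)
                         & (site["platform"] == "HIFI")
                         & (site["tissue"] == "BLOOD")
                         & (site["base_qual"] > 20)]
            n_alt = int((child["allele"] == row.alt).sum())
            n_ref = int((child["allele"] == row.ref).sum())
            if n_alt + n_ref:
                abs_.append(n_alt / (n_alt + n_ref))
        assert np.mean(abs_) == pytest.approx(0.48, abs=0.02)

    def test_tagging_snps_consistent_with_haplotype(self, small_cohort):
        """Alt-carrying reads of a paternal germline DNM carry the child's
        paternally inherited alleles at spanned het SNPs (up to rare errors)."""
        from trioscope.io import ReadEvidence
        truth = small_cohort.truth
        germ = truth[(truth["true_class"] == "GERMLINE")
                     & (truth["variant_type"] == "SNV")].head(20)
        fam_by_child = {}
        for fid, fam in small_cohort.families.items():
            for c in fam.child_ids:
                fam_by_child[c] = fam
        checked = agree = 0
        for row in germ.itertuples(index=False):
            fam = fam_by_child[row.child_id]
            cf, cm = fam.child_gt(row.chrom, row.child_id)
            pos = fam.snp_pos[row.chrom]
            refs, alts = fam.snp_ref[row.chrom], fam.snp_alt[row.chrom]
            side = 0 if row.true_parent == "P" else 1
            hap = np.where((cf if side == 0 else cm) == 1, alts, refs)
            lookup = dict(zip((int(p) for p in pos), hap))
            site = small_cohort.evidence.at_site(row.chrom, int(row.pos))
            alt_reads = site[(site["sample_id"] == row.child_id)
                             & (site["platform"] == "HIFI")
                             & (site["allele"] == row.alt)]
            for tags in alt_reads["tag_snps"]:
                for p, a in ReadEvidence.parse_tags(tags):
                    want = lookup.get(p)
                    if want is not None:
                        checked += 1
                        agree += a == want
        assert checked > 50
        assert agree / checked > 0.98
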