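"""End-to-end orchestration: simulate -> select -> validate -> phase ->
classify -> rates -> statistics.

Filters short-circuit in a documented order, and every candidate keeps the
first filter that removed it in its ``validation_status``:

    cluster -> platform support -> recurrence -> repeat-AB -> homopolymer
    -> noisy support -> phase conflict

so stage counts are conserved (candidates = final + each removed category).
All randomness derives from the generator config's seed; rerunning with the
same config yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import candidates as cand_mod
from . import validation as val_mod
from .callable_rates import mutation_rate
from .candidates import CandidateVariant, cluster_filter, union_callsets
from .io import write_dnm_table
from .model import DnmRecord, Origin, Pedigree, Phase
from .origin import (ab_prediction, classify_indel_origin, classify_origin,
                     haplotype_origin_call)
from .phasing import TrioCallIndex, find_informative_snps, merge_phase, phase_dnm
from .simulate import GeneratorConfig, SimulatedCohort, simulate_cohort
from .spectra import (age_regression, classify_substitution, find_mnm_pairs,
                      parental_ratio, spectrum_compare, spectrum_summary,
                      titv_ratio)

FILTER_ORDER = ["CLUSTER", "SUPPORT", "RECURRENCE", "REPEAT_AB", "HOMOPOLYMER",
                "NOISE", "PHASE_CONFLICT"]


@dataclass
class PipelineResult:
    records: list[DnmRecord]
    summary: dict
    cohort: SimulatedCohort | None = None
    truth_eval: dict | None = None

    @property
    def final(self) -> list[DnmRecord]:
        return [r for r in self.records if r.validation_status == "VALIDATED"]


def _single_family_pedigree(pedigree: Pedigree, family_id: str) -> Pedigree:
    return Pedigree([pedigree.families[family_id]])


def _variant_type(variant) -> str:
    if variant.is_snv:
        return "SNV"
    return "INS" if len(variant.alt) > len(variant.ref) else "DEL"


def _make_record(cand: CandidateVariant, status: str) -> DnmRecord:
    return DnmRecord(
        chrom=cand.chrom, pos=cand.pos, ref=cand.variant.ref,
        alt=cand.variant.alt, child_id=cand.child_id,
        variant_type=_variant_type(cand.variant),
        category=cand.category, validation_status=status)


def _validate_snv(cand: CandidateVariant, evidence, pedigree, features,
                  contexts) -> DnmRecord:
    """Run one SNV candidate through platform support and site-level filters."""
    father, mother = pedigree.parents_of(cand.child_id)
    site = evidence.site_arrays(cand.chrom, cand.pos)
    ref, alt = cand.variant.ref, cand.variant.alt
    verdicts = [val_mod.platform_verdict_snv(site, cand.child_id,
                                             father.sample_id, mother.sample_id,
                                             ref, alt, p)
                for p in val_mod.PLATFORMS]
    rec = _make_record(cand, "CANDIDATE")
    rec.platform_counts = {
        p: val_mod.platform_ab_counts(site, cand.child_id, ref, alt, p)
        for p in val_mod.PLATFORMS}

    status = val_mod.combine_verdicts(verdicts)
    if status != "VALIDATED":
        rec.validation_status = status
        return rec
    if not val_mod.cohort_recurrence_filter(cand, evidence, pedigree, features):
        rec.validation_status = "FAILED_RECURRENCE"
        return rec
    ok, reason = val_mod.repeat_ab_filters(cand, rec.mean_ab(), features, features)
    if not ok:
        rec.validation_status = f"FAILED_REPEAT_AB_{reason}"
        return rec
    ctx = contexts.get((cand.chrom, cand.pos))
    if ctx is not None and not val_mod.homopolymer_filter(ref, alt, ctx[0], ctx[1]):
        rec.validation_status = "FAILED_HOMOPOLYMER"
        return rec
    if not val_mod.noisy_support_filter(cand, site, pedigree):
        rec.validation_status = "FAILED_NOISE"
        return rec
    rec.validation_status = "VALIDATED"
    return rec


def _phase_and_classify(rec: DnmRecord, cand: CandidateVariant, evidence,
                        call_index: TrioCallIndex, pedigree) -> None:
    """Attach phase, per-haplotype counts, and origin to a validated record."""
    father, mother = pedigree.parents_of(rec.child_id)
    snps = find_informative_snps(call_index, rec.chrom, rec.pos,
                                 father.sample_id, mother.sample_id,
                                 rec.child_id)
    hifi = phase_dnm(evidence, snps, cand.variant, rec.child_id, "HIFI")
    ont = phase_dnm(evidence, snps, cand.variant, rec.child_id, "ONT")
    merged = merge_phase(hifi, ont, bool(snps))
    if merged == "EXCLUDE":
        rec.validation_status = "FAILED_PHASE_CONFLICT"
        rec.phase = Phase.CONFLICT
        return
    rec.phase = merged
    side = {"PATERNAL": "P", "MATERNAL": "M"}.get(rec.phase.value)
    if side is not None:
        rec.hap_counts = {"HIFI": hifi.hap_counts[side][:2],
                          "ONT": ont.hap_counts[side][:2]}
    ab = ab_prediction(list(rec.platform_counts.values()))
    if rec.variant_type == "SNV":
        if side is None:
            rec.origin = classify_origin("AMBIGUOUS", "AMBIGUOUS", ab.prediction)
        else:
            hifi_call = haplotype_origin_call(hifi.hap_counts[side][:2])
            ont_call = haplotype_origin_call(ont.hap_counts[side][:2])
            rec.origin = classify_origin(hifi_call, ont_call, ab.prediction)
    else:
        if side is None:
            rec.origin = Origin.GERMLINE
        else:
            # counts from the platform that established the phase
            res = hifi if hifi.assignment == rec.phase else ont
            n_ref, n_alt, n_other = res.hap_counts[side]
            rec.origin = classify_indel_origin(n_alt, n_ref + n_other)


def run_family(cohort: SimulatedCohort, family_id: str) -> tuple[list[DnmRecord], dict]:
    """Discovery through origin classification for one family."""
    pedigree = cohort.pedigree
    fam_ped = _single_family_pedigree(pedigree, family_id)
    callsets = cohort.variant_calls(family_id)
    union = union_callsets(list(callsets.values()))
    evidence = cohort.evidence
    features = cohort.features
    contexts = cohort.contexts

    snv_cands = cand_mod.select_candidate_snvs(union, fam_ped)
    indel_cands = cand_mod.select_candidate_indels(union, fam_ped)
    kept, clustered = cluster_filter(snv_cands)
    call_index = TrioCallIndex(union)

    records: list[DnmRecord] = []
    counts = {"candidates_snv": len(snv_cands), "candidates_indel": len(indel_cands),
              "clustered": len(clustered)}
    for cand in clustered:
        records.append(_make_record(cand, "FAILED_CLUSTER"))
    for cand in kept:
        rec = _validate_snv(cand, evidence, pedigree, features, contexts)
        if rec.validation_status == "VALIDATED":
            _phase_and_classify(rec, cand, evidence, call_index, pedigree)
        records.append(rec)
    for cand in indel_cands:
        cand.category = cand_mod.classify_indel_category(cand.variant, features)
        rec = _make_record(cand, "CANDIDATE")
        if cand.category == "INDEL_TR":
            rec.validation_status = "EXCLUDED_TR_INDEL"
            records.append(rec)
            continue
        status, icounts = val_mod.validate_indel(cand, evidence, pedigree)
        rec.platform_counts = icounts
        if status == "VALIDATED" and not val_mod.multiallele_filter(cand, evidence):
            status = "FAILED_MULTIALLELE"
        rec.validation_status = status
        if status == "VALIDATED":
            _phase_and_classify(rec, cand, evidence, call_index, pedigree)
        records.append(rec)
    return records, counts


def _phased_counts(records: list[DnmRecord]) -> dict[str, tuple[int, int]]:
    """Per-child (paternal, maternal) counts over phased records."""
    out: dict[str, list[int]] = {}
    for r in records:
        pm = out.setdefault(r.child_id, [0, 0])
        if r.phase is Phase.PATERNAL:
            pm[0] += 1
        elif r.phase is Phase.MATERNAL:
            pm[1] += 1
    return {c: (p, m) for c, (p, m) in out.items()}


def summarize(records: list[DnmRecord], cohort: SimulatedCohort) -> dict:
    """Cohort-level statistics over the final callset."""
    final = [r for r in records if r.validation_status == "VALIDATED"]
    snvs = [r for r in final if r.variant_type == "SNV"]
    indels = [r for r in final if r.variant_type != "SNV"]
    germ = [r for r in snvs if r.origin is Origin.GERMLINE]
    pzm = [r for r in snvs if r.origin is Origin.POSTZYGOTIC]
    children = {c.sample_id: c for c in cohort.pedigree.children}

    def group_stats(group: list[DnmRecord]) -> dict:
        if not group:
            return {"n": 0}
        per_child = _phased_counts(group)
        all_children = {c: per_child.get(c, (0, 0)) for c in children}
        ratio = parental_ratio(list(all_children.values()))
        abs_ = [r.mean_ab() for r in group if r.mean_ab() is not None]
        titv = titv_ratio([(r.ref, r.alt) for r in group])
        classes = []
        for r in group:
            ctx = cohort.contexts.get((r.chrom, r.pos))
            if ctx:
                classes.append(classify_substitution(r.ref, r.alt, ctx[0][-1],
                                                     ctx[1][0]))
        spec = spectrum_summary(classes)
        n_phased = sum(1 for r in group
                       if r.phase in (Phase.PATERNAL, Phase.MATERNAL))
        return {
            "n": len(group), "n_phased": n_phased,
            "phased_fraction": n_phased / len(group),
            "paternal_maternal_ratio": ratio["ratio"],
            "wilcoxon_p": ratio["wilcoxon_p"],
            "paternal": ratio["paternal"], "maternal": ratio["maternal"],
            "mean_ab": float(np.mean(abs_)) if abs_ else None,
            "titv": titv, "spectrum": spec.class_counts,
        }

    summary = {
        "n_children": len(children),
        "final_snvs": len(snvs), "final_indels": len(indels),
        "germline": group_stats(germ), "pzm": group_stats(pzm),
        "pzm_fraction": len(pzm) / len(snvs) if snvs else None,
    }

    # parental-age regressions on phased germline counts
    per_child = _phased_counts(germ)
    pat_counts, mat_counts, fa_ages, ma_ages = [], [], [], []
    for cid, person in sorted(children.items()):
        p, m = per_child.get(cid, (0, 0))
        pat_counts.append(p)
        mat_counts.append(m)
        fa_ages.append(person.father_age_at_birth)
        ma_ages.append(person.mother_age_at_birth)
    if len(pat_counts) >= 3 and len(set(fa_ages)) > 1:
        summary["paternal_age_regression"] = age_regression(pat_counts, fa_ages)
        summary["maternal_age_regression"] = age_regression(mat_counts, ma_ages)

    # autosomal rates against the generator's callable masks
    if cohort.masks:
        for label, group in (("germline", germ), ("pzm", pzm)):
            per = []
            for cid in sorted(children):
                mask = cohort.masks[cid]
                n = sum(1 for r in group if r.child_id == cid
                        and mask.contains(r.chrom, r.pos))
                per.append((n, mask.total_bp()))
            est = mutation_rate(per, ploidy_factor=2, bootstrap_reps=2000,
                                seed=cohort.config.seed)
            summary[f"{label}_rate"] = {
                "rate": est.rate, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "n": est.n_mutations, "callable_bp": est.callable_bp}

    if germ and pzm:
        summary["spectrum_compare"] = spectrum_compare(
            summary["germline"]["spectrum"], summary["pzm"]["spectrum"])
    summary["mnm_pairs"] = len(find_mnm_pairs(snvs))
    return summary


def evaluate_against_truth(records: list[DnmRecord], truth: pd.DataFrame) -> dict:
    """Confusion statistics of the final callset against simulator truth."""
    final = {r.key: r for r in records if r.validation_status == "VALIDATED"}
    truth_children = set(truth["child_id"])
    rec_children = {r.child_id for r in records}
    if records and truth_children and not (truth_children & rec_children):
        raise ValueError("callset and truth table share no children: "
                         "mismatched cohorts")
    by_key = {(t.chrom, int(t.pos), t.ref, t.alt, t.child_id): t
              for t in truth.itertuples(index=False)}
    true_dnm = {k for k, t in by_key.items() if t.true_class in ("GERMLINE", "PZM")}
    true_snv = {k for k in true_dnm if len(k[2]) == 1 and len(k[3]) == 1}

    found = set(final) & true_dnm
    sens = len(found) / len(true_dnm) if true_dnm else float("nan")
    sens_snv = (len(set(final) & true_snv) / len(true_snv)
                if true_snv else float("nan"))
    precision = len(found) / len(final) if final else float("nan")

    leakage = {"INHERITED_ARTIFACT": 0, "RECURRENT_ERROR": 0,
               "HOMOPOLYMER_ERROR": 0}
    for k in set(final) - true_dnm:
        t = by_key.get(k)
        if t is not None and t.true_class in leakage:
            leakage[t.true_class] += 1

    origin_ok = origin_total = 0
    phase_ok = phase_total = 0
    for k in found:
        t = by_key[k]
        r = final[k]
        if r.origin is not Origin.NA:
            origin_total += 1
            if (t.true_class == "GERMLINE") == (r.origin is Origin.GERMLINE):
                origin_ok += 1
        if r.phase in (Phase.PATERNAL, Phase.MATERNAL) and t.true_parent in "PM":
            phase_total += 1
            want = Phase.PATERNAL if t.true_parent == "P" else Phase.MATERNAL
            if r.phase is want:
                phase_ok += 1
    n_artifacts_total = sum(
        1 for t in by_key.values()
        if t.true_class in ("INHERITED_ARTIFACT", "RECURRENT_ERROR"))
    return {
        "sensitivity": sens, "sensitivity_snv": sens_snv,
        "precision": precision,
        "origin_accuracy": origin_ok / origin_total if origin_total else float("nan"),
        "phase_accuracy": phase_ok / phase_total if phase_total else float("nan"),
        "artifact_leakage": leakage,
        "n_true_dnms": len(true_dnm), "n_final": len(final),
        "n_artifacts_simulated": n_artifacts_total,
    }


def pool_cohort_statistics(summaries: list[dict]) -> dict:
    """Pool the headline cohort statistics over replicate pipeline runs.

    Count-based quantities (parental ratios, Ti/Tv) pool their numerators and
    denominators; allele balances weight per-run means by group size; the
    paternal-age slope averages the per-run OLS estimates.
    """
    from .spectra import TRANSITION_CLASSES

    out: dict = {}
    for group in ("germline", "pzm"):
        pat = sum(s[group]["paternal"] for s in summaries)
        mat = sum(s[group]["maternal"] for s in summaries)
        ti = sum(sum(s[group]["spectrum"].get(c, 0) for c in TRANSITION_CLASSES)
                 for s in summaries)
        total = sum(sum(s[group]["spectrum"].values()) for s in summaries)
        n = sum(s[group]["n"] for s in summaries)
        ab_num = sum(s[group]["mean_ab"] * s[group]["n"] for s in summaries
                     if s[group].get("mean_ab") is not None)
        out[f"{group}_ratio"] = pat / mat if mat else float("inf")
        out[f"{group}_titv"] = ti / (total - ti) if total > ti else float("inf")
        out[f"{group}_mean_ab"] = ab_num / n if n else float("nan")
        out[f"{group}_n"] = n
        out[f"{group}_n_phased"] = pat + mat
    slopes = [s["paternal_age_regression"]["slope"] for s in summaries
              if "paternal_age_regression" in s]
    out["paternal_age_slope"] = float(np.mean(slopes)) if slopes else float("nan")
    out["n_runs"] = len(summaries)
    return out


def run_pipeline(config: GeneratorConfig | None = None,
                 cohort: SimulatedCohort | None = None,
                 outdir: str | Path | None = None,
                 write_artifacts: str = "minimal") -> PipelineResult:
    """Run the full flow on a simulated cohort.

    ``write_artifacts``: "none", "minimal" (pedigree, truth, DNM table,
    summary), or "full" (adds per-family VCFs and the evidence TSV).
    """
    if cohort is None:
        if config is None:
            raise ValueError("need a config or a cohort")
        cohort = simulate_cohort(config)
    records: list[DnmRecord] = []
    stage_counts: dict[str, int] = {}
    for fid in sorted(cohort.families):
        fam_records, counts = run_family(cohort, fid)
        records.extend(fam_records)
        for k, v in counts.items():
            stage_counts[k] = stage_counts.get(k, 0) + v

    status_counts: dict[str, int] = {}
    for r in records:
        status_counts[r.validation_status] = status_counts.get(r.validation_status, 0) + 1

    summary = {"stage_counts": stage_counts, "status_counts": status_counts}
    summary.update(summarize(records, cohort))
    truth_eval = evaluate_against_truth(records, cohort.truth)
    summary["truth_eval"] = truth_eval

    if outdir is not None and write_artifacts != "none":
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.write(out, full=(write_artifacts == "full"))
        write_dnm_table(records, out / "dnms.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return PipelineResult(records=records, summary=summary, cohort=cohort,
                          truth_eval=truth_eval)
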