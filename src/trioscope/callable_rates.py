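"""Callable-genome accounting and mutation-rate estimation.

A site is *callable* for a trio when a DNM could have been discovered there:
both parents genotyped homozygous reference (autosomes and the female X) and
every trio member covered by at least one high-quality HiFi read (mapping
quality >= 59, base quality >= 20; child blood-derived only, parents blood or
cell line).  Male sex chromosomes relax the parental-genotype requirement and
use only the relevant parent's evidence (mother for X, father for Y).

The germline mutation rate per child is n_DNMs / (ploidy_factor x callable
bp); autosomes and the female X are diploid (factor 2), male sex chromosomes
haploid (factor 1, X and Y callable space summed).  Confidence intervals are
nonparametric bootstrap percentile intervals over children.  Feature-specific
rates intersect both the DNMs and the callable mask with a feature track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTrack
from .model import CallableMask, DnmRecord, Pedigree, RateEstimate

CALLABLE_MIN_MAPQ = 59
CALLABLE_MIN_BASE_QUAL = 20


def _has_hq_read(site_df: pd.DataFrame, sample_id: str, child: bool) -> bool:
    df = site_df[(site_df["sample_id"] == sample_id) & (site_df["platform"] == "HIFI")]
    if child:
        df = df[df["tissue"] == "BLOOD"]
    df = df[(df["mapq"] >= CALLABLE_MIN_MAPQ) & (df["base_qual"] >= CALLABLE_MIN_BASE_QUAL)]
    return len(df) > 0


def compute_callable_mask(sites: pd.DataFrame, evidence, pedigree: Pedigree,
                          child_id: str, mode: str = "AUTO") -> CallableMask:
    """Per-site callability over a base-resolution genotype table.

    ``sites`` needs columns chrom, pos (1-based), father_gt, mother_gt
    (strings like "0/0", "." for missing).  ``mode`` is AUTO (autosomes and
    female X), MALE_X, or MALE_Y.  Missing parental genotypes make a site
    uncallable.  Returns merged 0-based half-open intervals.
    """
    father, mother = pedigree.parents_of(child_id)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for row in sites.itertuples(index=False):
        site_df = evidence.at_site(row.chrom, int(row.pos))
        if mode == "AUTO":
            if row.father_gt != "0/0" or row.mother_gt != "0/0":
                continue
            needed = [(father.sample_id, False), (mother.sample_id, False),
                      (child_id, True)]
        elif mode == "MALE_X":
            needed = [(mother.sample_id, False), (child_id, True)]
        elif mode == "MALE_Y":
            needed = [(father.sample_id, False), (child_id, True)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if all(_has_hq_read(site_df, sid, is_child) for sid, is_child in needed):
            intervals.setdefault(row.chrom, []).append((int(row.pos) - 1, int(row.pos)))
    return CallableMask(child_id, intervals).normalized()


def mutation_rate(per_child: list[tuple[int, int]], ploidy_factor: int,
                  bootstrap_reps: int = 10000, seed: int = 0) -> RateEstimate:
    """Pooled mutation rate with a bootstrap-over-children percentile CI.

    ``per_child`` holds (n_mutations, callable_bp) pairs, one per child.
    """
    counts = np.array([n for n, _ in per_child], dtype=float)
    bps = np.array([bp for _, bp in per_child], dtype=float)
    total_bp = bps.sum()
    if total_bp == 0:
        raise ValueError("zero callable bp")
    rate = counts.sum() / (ploidy_factor * total_bp)
    rng = np.random.default_rng(seed)
    k = len(per_child)
    idx = rng.integers(0, k, size=(bootstrap_reps, k))
    boot = counts[idx].sum(axis=1) / (ploidy_factor * bps[idx].sum(axis=1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RateEstimate(int(counts.sum()), int(total_bp), ploidy_factor,
                        float(rate), float(lo), float(hi))


def intersect_intervals(a: list[tuple[int, int]],
                        b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted non-overlapping interval lists (half-open)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def mask_feature_intersection(mask: CallableMask, track: FeatureTrack,
                              feature_class: str,
                              pct_range: tuple[float, float] | None = None) -> int:
    """Callable bp inside a feature class (optionally an SD identity bin)."""
    feat: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, fclass, extra in track.intervals:
        if fclass != feature_class:
            continue
        if pct_range is not None:
            if not isinstance(extra, float):
                continue
            lo, hi = pct_range
            if not (lo <= extra < hi):
                continue
        feat.setdefault(chrom, []).append((s, e))
    total = 0
    for chrom, ivs in feat.items():
        merged = CallableMask("", {chrom: ivs}).normalized().intervals[chrom]
        total += sum(e - s for s, e in
                     intersect_intervals(mask.intervals.get(chrom, []), merged))
    return total


def dnms_in_feature(dnms: list[DnmRecord], track: FeatureTrack,
                    feature_class: str,
                    pct_range: tuple[float, float] | None = None) -> list[DnmRecord]:
    """DNMs whose (0-based) position lies in [start, end) of a feature interval."""
    out = []
    for d in dnms:
        for _, _, fclass, extra in track.hits(d.chrom, d.pos):
            if fclass != feature_class:
                continue
            if pct_range is not None:
                if not isinstance(extra, float):
                    continue
                lo, hi = pct_range
                if not (lo <= extra < hi):
                    continue
            out.append(d)
            break
    return out


def feature_rate(dnms_by_child: dict[str, list[DnmRecord]],
                 masks: dict[str, CallableMask], track: FeatureTrack,
                 feature_class: str,
                 pct_range: tuple[float, float] | None = None,
                 ploidy_factor: int = 2,
                 bootstrap_reps: int = 2000, seed: int = 0) -> RateEstimate | None:
    """Feature-stratified pooled rate over children; None if no callable bp."""
    per_child = []
    for child_id, mask in masks.items():
        bp = mask_feature_intersection(mask, track, feature_class, pct_range)
        n = len(dnms_in_feature(dnms_by_child.get(child_id, []), track,
                                feature_class, pct_range))
        per_child.append((n, bp))
    if sum(bp for _, bp in per_child) == 0:
        return None
    return mutation_rate(per_child, ploidy_factor, bootstrap_reps, seed)


def compare_rates(per_sample_feature_rates: dict[str, list[float]],
                  per_sample_genome_rates: list[float]) -> pd.DataFrame:
    """Paired t-test of per-sample feature rate vs genome-wide rate, with
    Benjamini-Hochberg correction across features."""
    if len(per_sample_genome_rates) < 2:
        raise ValueError("need at least two samples")
    genome = np.asarray(per_sample_genome_rates, dtype=float)
    features = list(per_sample_feature_rates)
    stats_, ps = [], []
    for f in features:
        feat = np.asarray(per_sample_feature_rates[f], dtype=float)
        if len(feat) != len(genome):
            raise ValueError(f"feature {f!r}: sample count mismatch")
        if np.allclose(feat, genome):
            stats_.append(0.0)
            ps.append(1.0)
        else:
            t, p = stats.ttest_rel(feat, genome)
            stats_.append(float(t))
            ps.append(float(p))
    p_bh = benjamini_hochberg(ps)
    return pd.DataFrame({"feature": features, "t": stats_, "p": ps, "p_BH": p_bh})


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH step-up adjusted p-values."""
    return list(multipletests(pvalues, method="fdr_bh")[1])
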