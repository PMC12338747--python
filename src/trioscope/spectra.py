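"""Mutational-spectrum and parent-of-origin statistics.

Substitutions are collapsed to strand-symmetric classes with the mutated
base reported as A or C (purine-reference changes are reverse-complemented),
with CpG>TpG transitions split out of C>T.  On top of the spectrum the
module provides Ti/Tv ratios, parental-age regressions of phased DNM counts,
pooled paternal:maternal ratios with Wilcoxon signed-rank tests, two-group
spectrum comparisons, and multinucleotide-mutation (MnM) pair detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .callable_rates import benjamini_hochberg
from .model import DnmRecord

SPECTRUM_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T", "CpG>TpG")
TRANSITION_CLASSES = ("A>G", "C>T", "CpG>TpG")

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def classify_substitution(ref: str, alt: str, prev_base: str, next_base: str) -> str:
    """Pyrimidine/A-centred spectrum class of one substitution.

    G/T reference bases are reverse-complemented (context swaps and
    complements accordingly); C>T with a 3' G is CpG>TpG.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    ref, alt, prev_base, next_base = ref.upper(), alt.upper(), prev_base.upper(), next_base.upper()
    if ref in "GT":
        ref, alt = _revcomp(ref), _revcomp(alt)
        prev_base, next_base = _revcomp(next_base), _revcomp(prev_base)
    if ref == "C" and alt == "T" and next_base == "G":
        return "CpG>TpG"
    return f"{ref}>{alt}"


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def titv(self) -> float:
        ti = sum(self.class_counts.get(c, 0) for c in TRANSITION_CLASSES)
        tv = self.total - ti
        if tv == 0:
            return float("inf")
        return ti / tv

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: self.class_counts.get(c, 0) / t for c in SPECTRUM_CLASSES}


def spectrum_summary(classes: list[str]) -> SpectrumSummary:
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for c in classes:
        if c not in counts:
            raise ValueError(f"unknown spectrum class {c!r}")
        counts[c] += 1
    return SpectrumSummary(counts)


def titv_ratio(substitutions: list[tuple[str, str]]) -> float:
    """Transitions (A<->G, C<->T) over transversions; inf if none of the latter."""
    if not substitutions:
        raise ValueError("need at least one SNV")
    ti = sum(1 for ref, alt in substitutions if {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"}))
    tv = len(substitutions) - ti
    if tv == 0:
        return float("inf")
    return ti / tv


def age_regression(counts: list[int], ages: list[float]) -> dict:
    """OLS of per-child phased DNM counts on parental age at birth."""
    import statsmodels.api as sm

    if len(counts) < 3:
        raise ValueError("need at least three children")
    x = np.asarray(ages, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant ages")
    X = sm.add_constant(x)
    fit = sm.OLS(np.asarray(counts, dtype=float), X).fit()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "p": float(fit.pvalues[1])}


def parental_ratio(per_child_counts: list[tuple[int, int]]) -> dict:
    """Pooled paternal:maternal ratio and Wilcoxon signed-rank test.

    ``per_child_counts`` holds (paternal, maternal) phased counts per child.
    """
    if len(per_child_counts) < 2:
        raise ValueError("need at least two children")
    pat = sum(p for p, _ in per_child_counts)
    mat = sum(m for _, m in per_child_counts)
    diffs = [p - m for p, m in per_child_counts]
    if all(d == 0 for d in diffs):
        wp = 1.0
    else:
        nonzero = [d for d in diffs if d != 0]
        mode = "exact" if len(nonzero) <= 25 and len(set(map(abs, nonzero))) == len(nonzero) else "approx"
        wp = float(stats.wilcoxon(diffs, zero_method="wilcox", mode=mode,
                                  correction=(mode == "approx")).pvalue)
    ratio = float("inf") if mat == 0 else pat / mat
    frac = pat / (pat + mat) if pat + mat else float("nan")
    return {"ratio": ratio, "wilcoxon_p": wp, "pooled_fraction": frac,
            "paternal": pat, "maternal": mat}


def paternal_fraction_ztest(group_a: tuple[int, int], group_b: tuple[int, int]) -> dict:
    """Two-proportion Z-test comparing pooled paternal fractions of two groups
    (e.g. germline vs postzygotic)."""
    counts = np.array([group_a[0], group_b[0]])
    nobs = np.array([sum(group_a), sum(group_b)])
    z, p = proportions_ztest(counts, nobs, alternative="two-sided")
    return {"z": float(z), "p": float(p)}


def find_mnm_pairs(dnms: list[DnmRecord], max_dist_bp: int = 500) -> list[dict]:
    """All within-child same-chromosome DNM pairs within ``max_dist_bp``."""
    by_child: dict[tuple, list[DnmRecord]] = {}
    for d in dnms:
        by_child.setdefault((d.child_id, d.chrom), []).append(d)
    pairs = []
    for (child, chrom), group in sorted(by_child.items()):
        group.sort(key=lambda d: d.pos)
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                dist = b.pos - a.pos
                if dist > max_dist_bp:
                    break
                if dist >= 1:
                    pairs.append({"child_id": child, "chrom": chrom,
                                  "pos_a": a.pos, "pos_b": b.pos,
                                  "distance": dist, "adjacent": dist == 1})
    return pairs


def spectrum_compare(counts_a: dict[str, int], counts_b: dict[str, int]) -> dict:
    """Per-class enrichment tests between two spectra.

    For each class: a 2x2 chi-squared (class vs rest, group A vs B), with a
    Fisher exact fallback for degenerate tables; BH correction across
    classes.  Also a two-proportion Z-test on the transition fractions.
    """
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    if total_a == 0 or total_b == 0:
        raise ValueError("empty spectrum group")
    ps = {}
    for c in SPECTRUM_CLASSES:
        a = counts_a.get(c, 0)
        b = counts_b.get(c, 0)
        table = np.array([[a, total_a - a], [b, total_b - b]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            _, p = stats.fisher_exact(table)
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        ps[c] = float(p)
    p_bh = dict(zip(SPECTRUM_CLASSES, benjamini_hochberg([ps[c] for c in SPECTRUM_CLASSES])))
    ti_a = sum(counts_a.get(c, 0) for c in TRANSITION_CLASSES)
    ti_b = sum(counts_b.get(c, 0) for c in TRANSITION_CLASSES)
    ti_test = paternal_fraction_ztest((ti_a, total_a - ti_a), (ti_b, total_b - ti_b))
    return {"p": ps, "p_BH": p_bh, "ti_fraction_z": ti_test}
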