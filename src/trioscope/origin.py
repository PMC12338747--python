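"""Germline versus postzygotic classification of phased DNMs.

A germline mutation is carried by every read of its parental haplotype of
origin, so that haplotype shows (almost) no reference reads.  A postzygotic
mutation (PZM) arose after fertilisation and is present in only a fraction
of cells: its origin haplotype shows both reference and alternate reads — a
"third haplotype".  Per platform:

* >= 2 reference reads and >= 1 alternate read on the origin haplotype call
  the variant postzygotic;
* <= 1 reference read with >= 1 alternate calls it germline;
* zero alternate reads leave the platform ambiguous.

When the HiFi and ONT haplotype calls disagree or are both ambiguous, an
allele-balance (AB) procedure arbitrates: if the per-platform (ref, alt)
counts are concordant (chi-squared homogeneity, p > alpha) the pooled counts
are tested against AB 0.5 with a one-sided exact binomial test; a
significantly low AB predicts postzygotic origin.  Discordant counts default
the prediction to germline.  Indels use a simpler noise-tolerant rule: more
than three non-de-novo-allele reads on the origin haplotype mark them
postzygotic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import Origin, PlatformAlleleCounts

ALPHA = 0.05


def haplotype_origin_call(hap_counts: tuple[int, int]) -> str:
    """Classify one platform's origin-haplotype (n_ref, n_alt) counts."""
    n_ref, n_alt = hap_counts
    if n_alt == 0:
        return "AMBIGUOUS"
    if n_ref >= 2:
        return "PZM"
    return "GERMLINE"


@dataclass
class AbTestResult:
    concordant: bool
    p_concordance: float | None
    prediction: str  # GERMLINE | PZM
    p_binomial: float | None


def ab_concordance_test(platform_counts: list[PlatformAlleleCounts],
                        alpha: float = ALPHA) -> tuple[bool, float | None]:
    """Chi-squared homogeneity of allele balance across platforms.

    Platforms with zero reads are dropped; with fewer than two informative
    platforms the test cannot run and counts are concordant by convention.
    A table whose ref or alt column is empty has statistic 0 (p = 1).
    """
    rows = [(c.n_ref, c.n_alt) for c in platform_counts if c.n_ref + c.n_alt > 0]
    if len(rows) < 2:
        return True, None
    table = np.array(rows)
    if (table.sum(axis=0) == 0).any():
        return True, 1.0  # degenerate: all-ref or all-alt, trivially concordant
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return bool(p > alpha), float(p)


def pooled_ab_test(platform_counts: list[PlatformAlleleCounts],
                   alpha: float = ALPHA) -> tuple[str, float]:
    """One-sided exact binomial test of pooled AB < 0.5; PZM iff p < alpha."""
    n_alt = sum(c.n_alt for c in platform_counts)
    n = sum(c.n_ref + c.n_alt for c in platform_counts)
    if n == 0:
        raise ValueError("pooled AB test needs at least one read")
    p = stats.binomtest(n_alt, n, 0.5, alternative="less").pvalue
    return ("PZM" if p < alpha else "GERMLINE"), float(p)


def ab_prediction(platform_counts: list[PlatformAlleleCounts],
                  alpha: float = ALPHA) -> AbTestResult:
    """Cross-platform AB prediction; discordant platforms default to germline."""
    concordant, p_conc = ab_concordance_test(platform_counts, alpha)
    if not concordant:
        return AbTestResult(False, p_conc, "GERMLINE", None)
    total = sum(c.n_ref + c.n_alt for c in platform_counts)
    if total == 0:
        return AbTestResult(True, p_conc, "GERMLINE", None)
    pred, p_binom = pooled_ab_test(platform_counts, alpha)
    return AbTestResult(True, p_conc, pred, p_binom)


def classify_origin(hifi_call: str, ont_call: str, ab_pred: str) -> Origin:
    """Combine per-platform haplotype calls with the AB prediction.

    An unambiguous call backed by both platforms wins; a single unambiguous
    platform (the other being ambiguous) wins alone; disagreements and fully
    ambiguous cases defer to the AB prediction.
    """
    calls = {c for c in (hifi_call, ont_call) if c != "AMBIGUOUS"}
    if len(calls) == 1:
        final = calls.pop()
    else:
        final = ab_pred
    return Origin.POSTZYGOTIC if final == "PZM" else Origin.GERMLINE


def classify_indel_origin(n_denovo: int, n_other: int) -> Origin:
    """Indel origin from origin-haplotype reads: postzygotic iff more than
    three reads carry an allele other than the called de novo event."""
    if n_other > 3 and n_denovo >= 1:
        return Origin.POSTZYGOTIC
    return Origin.GERMLINE
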