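#!/usr/bin/env python
"""Parent-of-origin and parental-age analyses of the final callset.

Reads the DNM table written by 02_run_pipeline.py, computes pooled
paternal:maternal ratios with Wilcoxon signed-rank tests (germline vs
postzygotic, SNVs and indels), the two-proportion Z-test between group
paternal fractions, and the paternal/maternal age regressions of phased
germline counts.  Writes results/parental_origin.json and
results/age_regression.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from trioscope.io import read_dnm_table, read_pedigree
from trioscope.model import Origin, Phase
from trioscope.spectra import age_regression, parental_ratio, paternal_fraction_ztest

OUT = Path("results")
PIPE = Path("scratch/pipeline")


def per_child_counts(records, pedigree):
    counts = {c.sample_id: [0, 0] for c in pedigree.children}
    for r in records:
        if r.phase is Phase.PATERNAL:
            counts[r.child_id][0] += 1
        elif r.phase is Phase.MATERNAL:
            counts[r.child_id][1] += 1
    return counts


def main() -> None:
    records = [r for r in read_dnm_table(PIPE / "dnms.tsv")
               if r.validation_status == "VALIDATED"]
    pedigree = read_pedigree(PIPE / "pedigree.tsv")

    report = {}
    groups = {
        "germline_snv": [r for r in records if r.is_snv and r.origin is Origin.GERMLINE],
        "pzm_snv": [r for r in records if r.is_snv and r.origin is Origin.POSTZYGOTIC],
        "germline_indel": [r for r in records if not r.is_snv and r.origin is Origin.GERMLINE],
        "pzm_indel": [r for r in records if not r.is_snv and r.origin is Origin.POSTZYGOTIC],
    }
    for name, group in groups.items():
        counts = per_child_counts(group, pedigree)
        report[name] = parental_ratio(list(counts.values()))

    report["germline_vs_pzm_fraction_ztest"] = paternal_fraction_ztest(
        (report["germline_snv"]["paternal"], report["germline_snv"]["maternal"]),
        (report["pzm_snv"]["paternal"], report["pzm_snv"]["maternal"]))

    counts = per_child_counts(groups["germline_snv"], pedigree)
    rows = []
    for parent, idx in (("paternal", 0), ("maternal", 1)):
        ages, ys = [], []
        for child in pedigree.children:
            ages.append(child.father_age_at_birth if idx == 0
                        else child.mother_age_at_birth)
            ys.append(counts[child.sample_id][idx])
        fit = age_regression(ys, ages)
        rows.append({"parent": parent, **fit})
    pd.DataFrame(rows).to_csv(OUT / "age_regression.tsv", sep="\t", index=False)

    with open(OUT / "parental_origin.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    g, p = report["germline_snv"], report["pzm_snv"]
    print(f"germline SNVs: {g['paternal']}:{g['maternal']} "
          f"(ratio {g['ratio']:.2f}, Wilcoxon p={g['wilcoxon_p']:.2e})")
    print(f"PZM SNVs: {p['paternal']}:{p['maternal']} "
          f"(ratio {p['ratio']:.2f}, Wilcoxon p={p['wilcoxon_p']:.3f})")
    for row in rows:
        print(f"{row['parent']} age slope {row['slope']:.2f} DNMs/yr "
              f"(p={row['p']:.2e})")


if __name__ == "__main__":
    main()
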