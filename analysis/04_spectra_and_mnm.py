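#!/usr/bin/env python
"""Mutational spectra of germline vs postzygotic SNVs, Ti/Tv, per-class
enrichment tests, allele-balance summaries, and MnM pair detection.

Writes results/spectra.tsv, results/spectrum_tests.json and
results/mnm_pairs.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from trioscope.io import read_context_table, read_dnm_table
from trioscope.model import Origin
from trioscope.simulate import study_preset, simulate_cohort
from trioscope.spectra import (SPECTRUM_CLASSES, classify_substitution,
                               find_mnm_pairs, spectrum_compare,
                               spectrum_summary)

SEED = 101
OUT = Path("results")
PIPE = Path("scratch/pipeline")


def main() -> None:
    records = [r for r in read_dnm_table(PIPE / "dnms.tsv")
               if r.validation_status == "VALIDATED" and r.is_snv]
    ctx_path = Path("scratch/cohort/contexts.tsv")
    if ctx_path.exists():
        contexts = read_context_table(ctx_path)
    else:  # regenerate deterministically if 01_simulate_cohort.py wasn't run
        contexts = simulate_cohort(study_preset(seed=SEED)).contexts

    groups = {"germline": [r for r in records if r.origin is Origin.GERMLINE],
              "pzm": [r for r in records if r.origin is Origin.POSTZYGOTIC]}
    rows, summaries = [], {}
    for name, group in groups.items():
        classes = [classify_substitution(r.ref, r.alt,
                                         contexts[(r.chrom, r.pos)][0][-1],
                                         contexts[(r.chrom, r.pos)][1][0])
                   for r in group if (r.chrom, r.pos) in contexts]
        summary = spectrum_summary(classes)
        summaries[name] = summary
        abs_ = [r.mean_ab() for r in group if r.mean_ab() is not None]
        for cls in SPECTRUM_CLASSES:
            rows.append({"group": name, "class": cls,
                         "count": summary.class_counts[cls],
                         "fraction": round(summary.fractions[cls], 4)})
        print(f"{name}: n={summary.total} Ti/Tv={summary.titv:.3f} "
              f"mean AB={sum(abs_) / len(abs_):.3f}")
    pd.DataFrame(rows).to_csv(OUT / "spectra.tsv", sep="\t", index=False)

    tests = spectrum_compare(summaries["germline"].class_counts,
                             summaries["pzm"].class_counts)
    cpg_g = summaries["germline"].fractions["CpG>TpG"]
    cpg_p = summaries["pzm"].fractions["CpG>TpG"]
    tests["cpg_deficit_fraction"] = 1 - cpg_p / cpg_g
    with open(OUT / "spectrum_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2, default=float)
    print(f"PZM CpG>TpG deficit vs germline: {tests['cpg_deficit_fraction']:.1%}")

    pairs = find_mnm_pairs(records)
    pd.DataFrame(pairs).to_csv(OUT / "mnm_pairs.tsv", sep="\t", index=False)
    n_adj = sum(p["adjacent"] for p in pairs)
    print(f"MnM pairs within 500 bp: {len(pairs)} ({n_adj} adjacent)")


if __name__ == "__main__":
    main()
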