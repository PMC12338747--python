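"""Synthetic trio-cohort generator with known truth.

Generates a cohort of trio/quad families — pedigree, per-family two-caller
variant callsets, per-read evidence across three simulated platforms (HiFi,
ONT, Illumina), feature tracks, callable masks and a truth table — so that
the whole discovery/validation/phasing/classification pipeline can be tested
end-to-end without any external data.

The default preset is calibrated to a 73-transmission autism-cohort study
design: 42 families (31 quads, 11 trios), ~70 germline SNVs and ~12.6
postzygotic SNVs (PZMs) per child at mean parental ages (33, 31), germline
paternal:maternal ratio 3.98:1 (PZM 1.15:1), paternal/maternal age slopes of
1.32 and 0.46 DNMs per year, germline Ti/Tv 2.10 versus PZM 1.35 with a 23%
CpG>TpG deficit among PZMs, mean observed germline allele balance 0.48
(via a reference-bias read-loss parameter) and PZM allele fractions drawn
from Beta(2.2, 7.8) (mean 0.22).

Mechanics worth knowing:

* Inherited SNPs are placed as a Poisson process (default 1/1200 bp) with
  parental haplotypes drawn at random allele frequencies; each child inherits
  one whole haplotype per chromosome from each parent (no recombination —
  irrelevant at read length scales), which keeps read-level tagging-SNP
  alleles consistent with the transmitted haplotypes.
* Every read at a variant site picks a parental haplotype; reads on the
  mutation's haplotype of origin carry the alternate allele (germline) or
  carry it with probability 2xAB (postzygotic cell fraction).  Het germline
  alt reads are additionally dropped with probability (1-2t)/(1-t) for
  target mean AB t, emulating reference-bias read loss; postzygotic reads
  are drawn at the recorded allele fraction directly.
* Confounders: dropped-parental-haplotype runs (>=3 apparent de novo calls
  within 1 kbp that are truly inherited), recurrent cross-family HiFi
  artifacts, and homopolymer-edge substitution noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    EVIDENCE_COLUMNS,
    FeatureTrack,
    ReadEvidence,
    write_context_table,
    write_mask_bed,
    write_pedigree,
    write_trio_vcf,
    write_truth_table,
)
from .model import CallableMask, Family, Pedigree, Person, Role, VariantCall
from .validation import homopolymer_filter

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# shared genotype tuples (memory: millions of VariantCalls share these)
_GT = {(a, b): (a, b) for a in range(3) for b in range(3)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PlatformModel:
    """Read-sampling model for one sequencing platform at a variant site."""

    depth: float
    read_length: int
    error_rate: float  # per-base error probability at the inspected site
    tissue: str  # tissue of the child's reads
    mapq_values: tuple = (60, 59, 30)
    mapq_probs: tuple = (0.96, 0.02, 0.02)
    #: base-quality value distribution (30 / 15 / 5 <-> HIGH / LOW / DISCARD)
    bq_probs_correct: tuple = (0.90, 0.07, 0.03)
    bq_probs_error: tuple = (0.10, 0.50, 0.40)


@dataclass
class GermlineModel:
    paternal_slope: float = 1.32  # additional DNMs per year of father's age
    maternal_slope: float = 0.46
    paternal_intercept: float = 12.384
    maternal_intercept: float = -0.204
    paternal_fraction: float = 3.98 / 4.98  # pooled, at mean parental ages
    target_ab: float = 0.48  # mean observed allele balance after reference bias
    spectrum: dict = field(default_factory=dict)

    def expected_counts(self, father_age: float, mother_age: float) -> tuple[float, float]:
        pat = max(self.paternal_intercept + self.paternal_slope * father_age, 0.1)
        mat = max(self.maternal_intercept + self.maternal_slope * mother_age, 0.1)
        return pat, mat


@dataclass
class PzmModel:
    rate_fraction: float = 0.18  # of the germline expectation
    ab_beta: tuple = (2.2, 7.8)
    paternal_fraction: float = 1.15 / 2.15
    spectrum: dict = field(default_factory=dict)

    @property
    def mean_ab(self) -> float:
        a, b = self.ab_beta
        return a / (a + b)


@dataclass
class IndelModel:
    mean_per_child: float = 533 / 73
    pzm_fraction: float = 129 / 533
    germline_paternal_fraction: float = 3.35 / 4.35
    pzm_paternal_fraction: float = 2.0 / 3.0
    ab_beta: tuple = (2.2, 7.8)
    max_len: int = 6


@dataclass
class ConfounderConfig:
    dropped_hap_runs_per_child: float = 1.0
    recurrent_sites: float = 20.0  # cohort-wide expectation
    homopolymer_noise_per_child: float = 2.0


@dataclass
class GeneratorConfig:
    n_families: int = 42
    quads_fraction: float = 31 / 42
    genome: list = field(default_factory=lambda: [
        ("chr1", 12_500_000), ("chr2", 12_500_000),
        ("chr3", 12_500_000), ("chr4", 12_500_000)])
    snp_density: float = 1 / 1200
    platforms: dict = field(default_factory=dict)
    germline: GermlineModel = field(default_factory=GermlineModel)
    pzm: PzmModel = field(default_factory=PzmModel)
    indel: IndelModel = field(default_factory=IndelModel)
    confounders: ConfounderConfig = field(default_factory=ConfounderConfig)
    father_age: tuple = (33.0, 5.0)  # Normal(mean, sd), truncated to age_bounds
    mother_age: tuple = (31.0, 4.5)
    age_bounds: tuple = (18.0, 55.0)
    callable_fraction: float = 0.97
    sd_enrichment: float = 1.0  # relative DNM rate inside SD intervals
    seed: int = 0

    def validate(self) -> None:
        for chrom, length in self.genome:
            if length < 10_000:
                raise ValueError(f"{chrom}: length {length} < 10 kbp")
        for name, spec in (("germline", self.germline.spectrum),
                           ("pzm", self.pzm.spectrum)):
            if spec:
                total = sum(spec.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(f"{name} spectrum sums to {total}, not 1")
                if any(not 0 <= p <= 1 for p in spec.values()):
                    raise ValueError(f"{name} spectrum has probability outside [0,1]")
        for frac in (self.quads_fraction, self.germline.paternal_fraction,
                     self.pzm.paternal_fraction, self.pzm.rate_fraction,
                     self.callable_fraction):
            if not 0 <= frac <= 1:
                raise ValueError(f"probability {frac} outside [0,1]")
        for pm in self.platforms.values():
            if not 0 <= pm.error_rate <= 1:
                raise ValueError(f"error rate {pm.error_rate} outside [0,1]")

    @property
    def ref_bias_drop(self) -> float:
        """Probability an alt-carrying read is lost, from the target germline AB."""
        t = self.germline.target_ab
        return (1 - 2 * t) / (1 - t)


_TI = ("A>G", "C>T", "CpG>TpG")


def _with_ti_fraction(spec: dict, ti_frac: float) -> dict:
    """Rescale transition and transversion masses to an exact Ti fraction."""
    ti = sum(spec[c] for c in _TI)
    tv = sum(v for c, v in spec.items() if c not in _TI)
    return {c: v * (ti_frac / ti if c in _TI else (1 - ti_frac) / tv)
            for c, v in spec.items()}


#: germline spectrum: Ti fraction 2.10/3.10, with a CpG>TpG share typical of
#: germline SNVs
GERMLINE_SPECTRUM = _with_ti_fraction({
    "A>C": 0.07, "A>G": 0.18, "A>T": 0.08,
    "C>A": 0.09, "C>G": 0.0826, "C>T": 0.3274, "CpG>TpG": 0.17,
}, 2.10 / 3.10)

#: PZM spectrum: Ti fraction 1.35/2.35, ~23% fewer CpG>TpG, A>C/A>T enriched,
#: A>G depleted
PZM_SPECTRUM = _with_ti_fraction({
    "A>C": 0.12, "A>G": 0.12, "A>T": 0.14,
    "C>A": 0.09, "C>G": 0.0755, "C>T": 0.3236, "CpG>TpG": 0.1309,
}, 1.35 / 2.35)


def study_preset(seed: int = 0, mbp_per_trio: float = 50.0) -> GeneratorConfig:
    """The calibrated default cohort: 42 families / 73 transmissions.

    Germline intercepts are solved so the expected counts at the mean
    parental ages (33, 31) total 70 SNVs/child split 3.98:1
    paternal:maternal; the PZM expectation is 18% of the germline one
    (12.6/child), giving a PZM fraction of ~0.151 of all SNVs.
    """
    chrom_len = int(mbp_per_trio * 1e6 / 4)
    germ = GermlineModel(spectrum=dict(GERMLINE_SPECTRUM))
    mean_total = 70.0
    mat_mean = mean_total * (1 - germ.paternal_fraction)
    pat_mean = mean_total * germ.paternal_fraction
    germ.paternal_intercept = pat_mean - germ.paternal_slope * 33.0
    germ.maternal_intercept = mat_mean - germ.maternal_slope * 31.0
    return GeneratorConfig(
        genome=[(f"chr{i + 1}", chrom_len) for i in range(4)],
        platforms={
            "HIFI": PlatformModel(depth=30, read_length=15_000,
                                  error_rate=0.002, tissue="BLOOD"),
            "ONT": PlatformModel(depth=40, read_length=50_000,
                                 error_rate=0.02, tissue="CELL_LINE"),
            "ILLUMINA": PlatformModel(depth=40, read_length=150,
                                      error_rate=0.001, tissue="BLOOD",
                                      mapq_values=(60, 5), mapq_probs=(0.98, 0.02)),
        },
        germline=germ,
        pzm=PzmModel(spectrum=dict(PZM_SPECTRUM)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Internal cohort containers
# ---------------------------------------------------------------------------

@dataclass
class FamilySim:
    """Compact per-family simulation state."""

    family_id: str
    father_id: str
    mother_id: str
    child_ids: list[str]
    # per chromosome: dict chrom -> arrays
    snp_pos: dict = field(default_factory=dict)      # int64[n]
    snp_ref: dict = field(default_factory=dict)      # array of single chars
    snp_alt: dict = field(default_factory=dict)
    father_hap: dict = field(default_factory=dict)   # int8[2, n]
    mother_hap: dict = field(default_factory=dict)
    # child -> chrom -> (tf, tm) transmitted haplotype indices
    transmitted: dict = field(default_factory=dict)
    events: list = field(default_factory=list)       # event dicts
    used_pos: dict = field(default_factory=dict)     # chrom -> set of taken positions

    def child_gt(self, chrom: str, child_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(paternal allele, maternal allele) int arrays at SNP sites."""
        tf, tm = self.transmitted[child_id][chrom]
        return self.father_hap[chrom][tf], self.mother_hap[chrom][tm]


class _EvidenceBuilder:
    """Accumulates read rows; built chunks are compacted into DataFrames so
    the (much larger) Python-object row lists can be freed."""

    def __init__(self):
        self.cols: dict[str, list] = {c: [] for c in EVIDENCE_COLUMNS}
        self._chunks: list[pd.DataFrame] = []

    def add(self, sample_id, platform, tissue, chrom, pos, read_ids, mapq,
            base_qual, alleles, flank_left, flank_right, tag_snps):
        n = len(read_ids)
        c = self.cols
        c["sample_id"].extend([sample_id] * n)
        c["platform"].extend([platform] * n)
        c["tissue"].extend([tissue] * n)
        c["chrom"].extend([chrom] * n)
        c["pos"].extend([pos] * n)
        c["read_id"].extend(read_ids)
        c["mapq"].extend(int(x) for x in mapq)
        c["base_qual"].extend(int(x) for x in base_qual)
        c["allele"].extend(alleles)
        c["flank_left"].extend(int(x) for x in flank_left)
        c["flank_right"].extend(int(x) for x in flank_right)
        c["tag_snps"].extend(tag_snps)

    def _compact(self) -> None:
        if not self.cols["sample_id"]:
            return
        df = pd.DataFrame({c: self.cols[c] for c in EVIDENCE_COLUMNS})
        for col in ("pos", "mapq", "base_qual", "flank_left", "flank_right"):
            df[col] = df[col].astype(np.int64)
        self._chunks.append(df)
        self.cols = {c: [] for c in EVIDENCE_COLUMNS}

    def build(self) -> ReadEvidence:
        self._compact()
        if len(self._chunks) > 1:
            self._chunks = [pd.concat(self._chunks, ignore_index=True)]
        if not self._chunks:
            return ReadEvidence(pd.DataFrame(
                {c: [] for c in EVIDENCE_COLUMNS}))
        return ReadEvidence(self._chunks[0])


@dataclass
class SimulatedCohort:
    config: GeneratorConfig
    pedigree: Pedigree
    families: dict  # family_id -> FamilySim
    features: FeatureTrack
    contexts: dict  # (chrom, pos) -> (left, right)
    masks: dict     # child_id -> CallableMask
    _builder: _EvidenceBuilder
    truth_rows: list
    _evidence: ReadEvidence | None = None

    @property
    def evidence(self) -> ReadEvidence:
        if self._evidence is None:
            self._evidence = self._builder.build()
        return self._evidence

    @property
    def truth(self) -> pd.DataFrame:
        rows = sorted(self.truth_rows,
                      key=lambda r: (r["chrom"], r["pos"], r["child_id"]))
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "ref", "alt", "child_id", "true_class",
            "true_parent", "true_ab", "variant_type"])

    # -- variant-call materialisation ------------------------------------

    def variant_calls(self, family_id: str) -> dict[str, list[VariantCall]]:
        """Per-caller VariantCall lists for one family (built on demand)."""
        fam = self.families[family_id]
        samples = [fam.father_id, fam.mother_id, *fam.child_ids]
        callsets: dict[str, list[VariantCall]] = {"gatk": [], "deepvariant": []}
        for chrom, _ in self.config.genome:
            pos = fam.snp_pos.get(chrom)
            if pos is None:
                continue
            refs, alts = fam.snp_ref[chrom], fam.snp_alt[chrom]
            f_gt = [_GT[(int(a), int(b))] for a, b in fam.father_hap[chrom].T]
            m_gt = [_GT[(int(a), int(b))] for a, b in fam.mother_hap[chrom].T]
            child_alleles = {c: fam.child_gt(chrom, c) for c in fam.child_ids}
            for i in range(len(pos)):
                genotypes = {fam.father_id: f_gt[i], fam.mother_id: m_gt[i]}
                for c in fam.child_ids:
                    cf, cm = child_alleles[c]
                    genotypes[c] = _GT[(int(cf[i]), int(cm[i]))]
                gq = {s: 99 for s in samples}
                call = VariantCall(chrom=chrom, pos=int(pos[i]), ref=str(refs[i]),
                                   alt=str(alts[i]), genotypes=genotypes, gq=gq,
                                   caller_ids=frozenset({"gatk", "deepvariant"}))
                callsets["gatk"].append(call)
                callsets["deepvariant"].append(call)
        for ev in fam.events:
            genotypes = {fam.father_id: _GT[(0, 0)], fam.mother_id: _GT[(0, 0)]}
            for c in fam.child_ids:
                genotypes[c] = _GT[(0, 1)] if c == ev["child_id"] else _GT[(0, 0)]
            gq = {s: 99 for s in samples}
            gq[ev["child_id"]] = ev["gq"]
            callers = (["gatk", "deepvariant"] if ev["callers"] == "both"
                       else [ev["callers"]])
            call = VariantCall(chrom=ev["chrom"], pos=ev["pos"], ref=ev["ref"],
                               alt=ev["alt"], genotypes=genotypes, gq=gq,
                               caller_ids=frozenset(callers))
            for caller in callers:
                callsets[caller].append(call)
        for caller in callsets:
            callsets[caller].sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        return callsets

    # -- persistence ------------------------------------------------------

    def write(self, outdir, full: bool = True) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, out / "pedigree.tsv")
        write_truth_table(self.truth, out / "truth.tsv")
        self.features.write(out / "features.bed")
        write_context_table(self.contexts, out / "contexts.tsv")
        (out / "masks").mkdir(exist_ok=True)
        for child_id, mask in self.masks.items():
            write_mask_bed(mask, out / "masks" / f"{child_id}.bed")
        if full:
            self.evidence.write(out / "evidence.tsv")
            (out / "vcf").mkdir(exist_ok=True)
            for fid, fam in self.families.items():
                callsets = self.variant_calls(fid)
                samples = [fam.father_id, fam.mother_id, *fam.child_ids]
                for caller, calls in callsets.items():
                    recs = []
                    for v in calls:
                        gt = {}
                        for s in samples:
                            t = v.genotypes.get(s)
                            gt[s] = "./." if t is None else "/".join(str(a) for a in t)
                        recs.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                                     "alts": [v.alt], "gt": gt, "gq": v.gq,
                                     "caller": caller})
                    write_trio_vcf(out / "vcf" / f"{fid}.{caller}.vcf", samples,
                                   recs, contigs=self.config.genome)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _spectrum_alleles(rng, klass: str) -> tuple[str, str, str, str]:
    """(ref, alt, left6, right6) reference context consistent with a class."""
    while True:
        left = "".join(rng.choice(list(BASES), 6))
        right = "".join(rng.choice(list(BASES), 6))
        ref, alt = klass.split(">") if klass != "CpG>TpG" else ("C", "T")
        if klass == "CpG>TpG":
            right = "G" + right[1:]
        elif klass == "C>T" and right[0] == "G":
            right = str(rng.choice(list("ACT"))) + right[1:]
        if rng.random() < 0.5:  # opposite strand representation
            ref, alt = ref.translate(_COMP), alt.translate(_COMP)
            left, right = right.translate(_COMP)[::-1], left.translate(_COMP)[::-1]
        if homopolymer_filter(ref, alt, left, right):
            return ref, alt, left, right


def _random_indel(rng, max_len: int) -> tuple[str, str, str]:
    anchor = str(rng.choice(list(BASES)))
    seq = "".join(rng.choice(list(BASES), int(rng.integers(1, max_len + 1))))
    if rng.random() < 0.5:
        return anchor, anchor + seq, "INS"
    return anchor + seq, anchor, "DEL"


def _alloc_pos(rng, fam: FamilySim, chrom: str, length: int, lo: int = 50_000,
               features: FeatureTrack | None = None,
               sd_enrichment: float = 1.0) -> int:
    """Allocate an unused event position; with ``sd_enrichment`` > 1, sites
    inside SD intervals are over-represented by that factor (rejection
    sampling of non-SD draws)."""
    used = fam.used_pos.setdefault(chrom, set())
    while True:
        p = int(rng.integers(lo, length - lo))
        if p in used:
            continue
        if (sd_enrichment > 1.0 and features is not None
                and not features.overlaps(chrom, p, "SD")
                and rng.random() >= 1.0 / sd_enrichment):
            continue
        used.add(p)
        return p


def _sample_mapq_bq(rng, pm: PlatformModel, n: int, err: np.ndarray):
    mapq = rng.choice(pm.mapq_values, size=n, p=pm.mapq_probs)
    bq = np.empty(n, dtype=np.int64)
    n_err = int(err.sum())
    if n - n_err:
        bq[~err] = rng.choice((30, 15, 5), size=n - n_err, p=pm.bq_probs_correct)
    if n_err:
        bq[err] = rng.choice((30, 15, 5), size=n_err, p=pm.bq_probs_error)
    return mapq, bq


def _flip_bases(rng, alleles: list[str], err: np.ndarray) -> list[str]:
    """Apply per-read substitution errors at the inspected base."""
    out = list(alleles)
    for i in np.flatnonzero(err):
        true = out[i]
        if len(true) == 1:
            choices = [b for b in BASES if b != true]
            out[i] = str(rng.choice(choices))
        else:
            out[i] = true + str(rng.choice(list(BASES)))  # noisy indel allele
    return out


class _TagContext:
    """Child-het SNP positions and per-haplotype allele characters on one
    chromosome, for threading tagging SNPs onto long reads."""

    def __init__(self, fam: FamilySim, chrom: str, child_id: str):
        pos = fam.snp_pos.get(chrom)
        if pos is None or len(pos) == 0:
            self.pos = np.empty(0, dtype=np.int64)
            self.pat = self.mat = np.empty(0, dtype="<U8")
            return
        cf, cm = fam.child_gt(chrom, child_id)
        het = cf != cm
        refs, alts = fam.snp_ref[chrom], fam.snp_alt[chrom]
        self.pos = pos[het]
        allele = np.where(np.stack([cf[het], cm[het]]) == 1, alts[het], refs[het])
        self.pat, self.mat = allele[0], allele[1]

    def tags_for_read(self, rng, hap: int, start: int, end: int,
                      error_rate: float) -> str:
        i = np.searchsorted(self.pos, start, side="left")
        j = np.searchsorted(self.pos, end, side="right")
        if i >= j:
            return "."
        pos = self.pos[i:j]
        alleles = (self.pat if hap == 0 else self.mat)[i:j].copy()
        if error_rate > 0:
            err = rng.random(j - i) < error_rate
            for k in np.flatnonzero(err):
                choices = [b for b in BASES if b != alleles[k]]
                alleles[k] = str(rng.choice(choices))
        return ";".join(f"{p}:{a}" for p, a in zip(pos, alleles))


def _emit_child_reads(rng, builder, pm: PlatformModel, platform: str, sample_id,
                      chrom, pos, ref, alt, origin_hap: int | None,
                      p_alt_on_origin: float, drop_alt: float,
                      tag_ctx: _TagContext | None,
                      flat_alt_prob: float = 0.0) -> None:
    """Emit one child sample's reads at a site for one platform.

    ``origin_hap`` 0 = paternal, 1 = maternal, None = haplotype-independent
    noise with per-read alt probability ``flat_alt_prob``.
    """
    n = int(rng.poisson(pm.depth))
    if n == 0:
        return
    hap = rng.integers(0, 2, n)
    if origin_hap is None:
        is_alt = rng.random(n) < flat_alt_prob
    else:
        is_alt = (hap == origin_hap) & (rng.random(n) < p_alt_on_origin)
    keep = ~(is_alt & (rng.random(n) < drop_alt))
    hap, is_alt = hap[keep], is_alt[keep]
    n = len(hap)
    if n == 0:
        return
    err = rng.random(n) < pm.error_rate
    alleles = _flip_bases(rng, [alt if a else ref for a in is_alt], err)
    mapq, bq = _sample_mapq_bq(rng, pm, n, err)
    offs = rng.integers(0, pm.read_length, n)
    fl, fr = offs, pm.read_length - 1 - offs
    if tag_ctx is not None:
        tags = [tag_ctx.tags_for_read(rng, int(h), pos - int(l), pos + int(r),
                                      pm.error_rate)
                for h, l, r in zip(hap, fl, fr)]
    else:
        tags = ["."] * n
    read_ids = [f"{sample_id}.{platform}.{pos}.{k}" for k in range(n)]
    builder.add(sample_id, platform, pm.tissue, chrom, pos, read_ids, mapq, bq,
                alleles, fl, fr, tags)


def _emit_flat_reads(rng, builder, pm: PlatformModel, platform: str, tissue,
                     sample_id, chrom, pos, ref, alt=None, n_alt: int = 0,
                     alt_tier_high: bool = True) -> None:
    """Ref-only background pileup, plus optionally ``n_alt`` injected alt reads
    (used for parents, siblings, and artifact construction)."""
    n = int(rng.poisson(pm.depth))
    total = n + n_alt
    if total == 0:
        return
    err = rng.random(n) < pm.error_rate
    alleles = _flip_bases(rng, [ref] * n, err)
    mapq, bq = _sample_mapq_bq(rng, pm, n, err)
    if n_alt:
        alleles = alleles + [alt] * n_alt
        mapq = np.concatenate([mapq, np.full(n_alt, 60)])
        bq = np.concatenate([bq, np.full(n_alt, 30 if alt_tier_high else 15)])
    offs = rng.integers(0, pm.read_length, total)
    fl, fr = offs, pm.read_length - 1 - offs
    read_ids = [f"{sample_id}.{platform}.{pos}.{k}" for k in range(total)]
    builder.add(sample_id, platform, tissue, chrom, pos, read_ids, mapq, bq,
                alleles, fl, fr, ["."] * total)


def _emit_site_pileups(rng, cohort: SimulatedCohort, fam: FamilySim, ev: dict,
                       tag_ctxs: dict, include_sibling: bool) -> None:
    """All samples' reads at one event site across the three platforms."""
    cfg = cohort.config
    chrom, pos, ref, alt = ev["chrom"], ev["pos"], ev["ref"], ev["alt"]
    child = ev["child_id"]
    origin_hap = {"P": 0, "M": 1}.get(ev["true_parent"])
    if ev["true_class"] in ("GERMLINE", "INHERITED_ARTIFACT"):
        p_alt = 1.0
        # reference-bias read loss applies to the het germline signal; PZM
        # reads are drawn directly at the record's allele fraction
        drop = cfg.ref_bias_drop
    elif ev["true_class"] == "PZM":
        p_alt = min(2 * ev["true_ab"], 1.0)
        drop = 0.0
    else:
        p_alt = 0.0  # artifact alt reads are injected separately
        drop = 0.0
    for platform, pm in cfg.platforms.items():
        long_read = platform in ("HIFI", "ONT")
        tag_ctx = tag_ctxs.get((child, chrom)) if long_read else None
        if ev["true_class"] == "HOMOPOLYMER_ERROR":
            _emit_child_reads(rng, cohort._builder, pm, platform, child, chrom,
                              pos, ref, alt, None, 0.0, 0.0, tag_ctx,
                              flat_alt_prob=ev["true_ab"])
        else:
            _emit_child_reads(rng, cohort._builder, pm, platform, child, chrom,
                              pos, ref, alt, origin_hap, p_alt, drop, tag_ctx)
        # extra child HiFi cell-line reads: must be ignored by the filters
        if platform == "HIFI":
            cl = replace(pm, depth=8.0, tissue="CELL_LINE")
            _emit_child_reads(rng, cohort._builder, cl, platform, child, chrom,
                              pos, ref, alt, origin_hap if p_alt else None,
                              p_alt, drop, None, flat_alt_prob=ev["true_ab"]
                              if ev["true_class"] == "HOMOPOLYMER_ERROR" else 0.0)
        for parent_id, side in ((fam.father_id, "P"), (fam.mother_id, "M")):
            parent_tissue = pm.tissue if platform != "HIFI" else "BLOOD"
            _emit_flat_reads(rng, cohort._builder, pm, platform, parent_tissue,
                             parent_id, chrom, pos, ref)
        if include_sibling:
            for sib in fam.child_ids:
                if sib != child:
                    _emit_flat_reads(rng, cohort._builder, pm, platform,
                                     pm.tissue, sib, chrom, pos, ref)


def _make_features(rng, config: GeneratorConfig) -> FeatureTrack:
    ivs = []
    motifs = ["AT", "AC", "AG", "CT", "AAT", "AAG", "ACT", "AGAT"]
    for chrom, length in config.genome:
        for fclass, frac, lo, hi in (("TR", 0.01, 20, 200), ("RM", 0.04, 100, 500),
                                     ("HOMOPOLYMER", 0.002, 6, 20),
                                     ("EXON", 0.03, 120, 200)):
            n = int(frac * length / ((lo + hi) / 2))
            starts = np.sort(rng.integers(0, length - hi, n))
            for s in starts:
                w = int(rng.integers(lo, hi))
                extra = str(rng.choice(motifs)) if fclass == "TR" else None
                ivs.append((chrom, int(s), int(s) + w, fclass, extra))
        n_sd = int(0.05 * length / 20_000)
        for s in np.sort(rng.integers(0, length - 60_000, n_sd)):
            w = int(rng.integers(5_000, 50_000))
            ivs.append((chrom, int(s), int(s) + w, "SD",
                        float(np.round(rng.uniform(90, 100), 2))))
        cen = int(length * 0.45)
        ivs.append((chrom, cen, cen + int(0.02 * length), "CENTROMERE", None))
    return FeatureTrack(ivs)


def _make_mask(rng, config: GeneratorConfig, child_id: str) -> CallableMask:
    intervals: dict[str, list[tuple[int, int]]] = {}
    gap_frac = 1 - config.callable_fraction
    for chrom, length in config.genome:
        n_gaps = max(int(gap_frac * length / 5000), 1)
        gap_starts = np.sort(rng.integers(0, length - 5000, n_gaps))
        cur = 0
        ivs = []
        for g in gap_starts:
            g = int(g)
            if g > cur:
                ivs.append((cur, g))
            cur = max(cur, g + 5000)
        if cur < length:
            ivs.append((cur, length))
        intervals[chrom] = ivs
    return CallableMask(child_id, intervals).normalized()


def _draw_class(rng, spectrum: dict) -> str:
    classes = list(spectrum)
    probs = np.array([spectrum[c] for c in classes])
    return str(rng.choice(classes, p=probs / probs.sum()))


def _pick_chrom(rng, config: GeneratorConfig) -> tuple[str, int]:
    lengths = np.array([l for _, l in config.genome], dtype=float)
    i = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
    return config.genome[i]


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config.validate()
    if not config.platforms:
        config.platforms = study_preset().platforms
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(config.n_families + 3)
    rng_cohort = np.random.default_rng(seeds[0])
    rng_features = np.random.default_rng(seeds[1])

    features = _make_features(rng_features, config)
    n_quads = int(round(config.n_families * config.quads_fraction))

    families: dict[str, FamilySim] = {}
    ped_families = []
    builder = _EvidenceBuilder()
    cohort = SimulatedCohort(config=config, pedigree=None, families=families,
                             features=features, contexts={}, masks={},
                             _builder=builder, truth_rows=[])

    for fi in range(config.n_families):
        rng = np.random.default_rng(seeds[3 + fi])
        fid = f"F{fi + 1:03d}"
        n_children = 2 if fi < n_quads else 1
        father_id, mother_id = f"{fid}-fa", f"{fid}-mo"
        child_ids = [f"{fid}-c{j + 1}" for j in range(n_children)]
        fam = FamilySim(fid, father_id, mother_id, child_ids)
        families[fid] = fam

        father = Person(father_id, fid, Role.FATHER, "M")
        mother = Person(mother_id, fid, Role.MOTHER, "F")
        children = []
        for j, cid in enumerate(child_ids):
            fa = _truncated_normal(rng, *config.father_age, *config.age_bounds)
            ma = _truncated_normal(rng, *config.mother_age, *config.age_bounds)
            children.append(Person(
                cid, fid, Role.PROBAND if j == 0 else Role.SIBLING,
                "M" if rng.random() < 0.5 else "F",
                father_id=father_id, mother_id=mother_id,
                father_age_at_birth=round(fa, 1), mother_age_at_birth=round(ma, 1)))
        ped_families.append(Family(fid, father, mother, children))

        # inherited SNPs
        for chrom, length in config.genome:
            n_snps = int(rng.poisson(length * config.snp_density))
            pos = np.sort(rng.choice(np.arange(1000, length - 1000), n_snps,
                                     replace=False))
            fam.snp_pos[chrom] = pos.astype(np.int64)
            refs = rng.choice(list(BASES), n_snps)
            alt_offset = rng.integers(1, 4, n_snps)
            alts = np.array([BASES[(BASES.index(r) + o) % 4]
                             for r, o in zip(refs, alt_offset)])
            fam.snp_ref[chrom] = refs
            fam.snp_alt[chrom] = alts
            freq = rng.uniform(0.1, 0.9, n_snps)
            fam.father_hap[chrom] = (rng.random((2, n_snps)) < freq).astype(np.int8)
            fam.mother_hap[chrom] = (rng.random((2, n_snps)) < freq).astype(np.int8)
            fam.used_pos[chrom] = set(int(p) for p in pos)
            for cid in child_ids:
                fam.transmitted.setdefault(cid, {})[chrom] = (
                    int(rng.integers(0, 2)), int(rng.integers(0, 2)))

        # true de novo events per child
        for child in children:
            cid = child.sample_id
            pat_mean, mat_mean = config.germline.expected_counts(
                child.father_age_at_birth, child.mother_age_at_birth)
            n_pat = rng.poisson(pat_mean)
            n_mat = rng.poisson(mat_mean)
            n_pzm = rng.poisson(config.pzm.rate_fraction * (pat_mean + mat_mean))
            n_indel = rng.poisson(config.indel.mean_per_child)
            specs = ([("GERMLINE", "P", 0.5)] * n_pat
                     + [("GERMLINE", "M", 0.5)] * n_mat)
            for _ in range(n_pzm):
                side = "P" if rng.random() < config.pzm.paternal_fraction else "M"
                a, b = config.pzm.ab_beta
                ab = float(np.clip(rng.beta(a, b), 0.01, 0.499))
                specs.append(("PZM", side, ab))
            for klass_tag, side, ab in specs:
                chrom, length = _pick_chrom(rng, config)
                pos = _alloc_pos(rng, fam, chrom, length, features=features,
                                 sd_enrichment=config.sd_enrichment)
                spectrum = (config.germline.spectrum if klass_tag == "GERMLINE"
                            else config.pzm.spectrum) or GERMLINE_SPECTRUM
                sclass = _draw_class(rng, spectrum)
                ref, alt, left, right = _spectrum_alleles(rng, sclass)
                gq = int(np.clip(rng.normal(60, 15), 2, 99))
                r = rng.random()
                callers = "both" if r < 0.9 else ("gatk" if r < 0.95 else "deepvariant")
                ev = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                      "child_id": cid, "vtype": "SNV", "true_class": klass_tag,
                      "true_parent": side, "true_ab": ab, "callers": callers,
                      "gq": gq}
                fam.events.append(ev)
                cohort.contexts[(chrom, pos)] = (left, right)
            for _ in range(n_indel):
                is_pzm = rng.random() < config.indel.pzm_fraction
                frac = (config.indel.pzm_paternal_fraction if is_pzm
                        else config.indel.germline_paternal_fraction)
                side = "P" if rng.random() < frac else "M"
                if is_pzm:
                    a, b = config.indel.ab_beta
                    ab = float(np.clip(rng.beta(a, b), 0.01, 0.499))
                else:
                    ab = 0.5
                chrom, length = _pick_chrom(rng, config)
                pos = _alloc_pos(rng, fam, chrom, length)
                ref, alt, vtype = _random_indel(rng, config.indel.max_len)
                gq = int(np.clip(rng.normal(60, 15), 2, 99))
                r = rng.random()
                callers = "both" if r < 0.9 else ("gatk" if r < 0.95 else "deepvariant")
                ev = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                      "child_id": cid, "vtype": vtype,
                      "true_class": "PZM" if is_pzm else "GERMLINE",
                      "true_parent": side, "true_ab": ab, "callers": callers,
                      "gq": gq}
                fam.events.append(ev)
            cohort.masks[cid] = _make_mask(rng, config, cid)

        # pileups for this family's events
        tag_ctxs = {(cid, chrom): _TagContext(fam, chrom, cid)
                    for cid in child_ids for chrom, _ in config.genome}
        for ev in fam.events:
            cohort.truth_rows.append(_truth_row(ev))
            _emit_site_pileups(rng, cohort, fam, ev, tag_ctxs,
                               include_sibling=ev["vtype"] != "SNV")

    cohort.pedigree = Pedigree(ped_families)
    inject_confounders(cohort, config, np.random.default_rng(seeds[2]))
    return cohort


def _truth_row(ev: dict) -> dict:
    return {"chrom": ev["chrom"], "pos": ev["pos"], "ref": ev["ref"],
            "alt": ev["alt"], "child_id": ev["child_id"],
            "true_class": ev["true_class"], "true_parent": ev["true_parent"],
            "true_ab": ev["true_ab"], "variant_type": ev["vtype"]}


# ---------------------------------------------------------------------------
# Confounders
# ---------------------------------------------------------------------------

def inject_confounders(cohort: SimulatedCohort, config: GeneratorConfig,
                       rng=None) -> SimulatedCohort:
    """Add labelled artifact classes to an already-generated cohort.

    (a) dropped-haplotype runs: >=3 apparent de novo candidates within 1 kbp
    that are truly inherited from one parent whose alt reads are absent;
    (b) recurrent artifacts: identical false alt HiFi (plus supporting
    Illumina) observations in >=2 unrelated children;
    (c) homopolymer-edge substitutions involving the run base.
    All are labelled in the truth table.  Zero rates leave the cohort
    unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cc = config.confounders
    cohort._evidence = None  # invalidate cache
    fam_list = list(cohort.families.values())

    # (a) dropped-haplotype runs
    if cc.dropped_hap_runs_per_child > 0:
        for fam in fam_list:
            tag_ctxs = {(cid, chrom): _TagContext(fam, chrom, cid)
                        for cid in fam.child_ids for chrom, _ in config.genome}
            for cid in fam.child_ids:
                for _ in range(int(rng.poisson(cc.dropped_hap_runs_per_child))):
                    chrom, length = _pick_chrom(rng, config)
                    k = int(rng.integers(3, 7))
                    start = _alloc_pos(rng, fam, chrom, length)
                    offsets = np.sort(rng.choice(np.arange(10, 800), k - 1,
                                                 replace=False))
                    side = "P" if rng.random() < 0.5 else "M"
                    positions = [start] + [start + int(o) for o in offsets]
                    for p in positions:
                        fam.used_pos[chrom].add(p)
                        ref, alt, left, right = _spectrum_alleles(
                            rng, _draw_class(rng, GERMLINE_SPECTRUM))
                        ev = {"chrom": chrom, "pos": p, "ref": ref, "alt": alt,
                              "child_id": cid, "vtype": "SNV",
                              "true_class": "INHERITED_ARTIFACT",
                              "true_parent": side, "true_ab": 0.5,
                              "callers": "both",
                              "gq": int(np.clip(rng.normal(60, 15), 20, 99))}
                        fam.events.append(ev)
                        cohort.contexts[(chrom, p)] = (left, right)
                        cohort.truth_rows.append(_truth_row(ev))
                        _emit_site_pileups(rng, cohort, fam, ev, tag_ctxs,
                                           include_sibling=False)

    # (b) recurrent cross-family artifacts
    if cc.recurrent_sites > 0 and len(fam_list) >= 2:
        n_sites = int(rng.poisson(cc.recurrent_sites))
        for _ in range(n_sites):
            chrom, length = _pick_chrom(rng, config)
            m = int(rng.integers(2, min(5, len(fam_list)) + 1))
            fam_idx = rng.choice(len(fam_list), m, replace=False)
            picked = [fam_list[i] for i in fam_idx]
            pos = None
            while pos is None:
                p = int(rng.integers(50_000, length - 50_000))
                if all(p not in f.used_pos.get(chrom, set()) for f in fam_list):
                    for f in fam_list:
                        f.used_pos.setdefault(chrom, set()).add(p)
                    pos = p
            ref, alt, left, right = _spectrum_alleles(
                rng, _draw_class(rng, GERMLINE_SPECTRUM))
            cohort.contexts[(chrom, pos)] = (left, right)
            for fam in picked:
                cid = fam.child_ids[int(rng.integers(0, len(fam.child_ids)))]
                ev = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                      "child_id": cid, "vtype": "SNV",
                      "true_class": "RECURRENT_ERROR", "true_parent": ".",
                      "true_ab": 0.15, "callers": "both",
                      "gq": int(np.clip(rng.normal(45, 15), 20, 99))}
                fam.events.append(ev)
                cohort.truth_rows.append(_truth_row(ev))
                for platform, pm in config.platforms.items():
                    n_alt = (int(rng.integers(3, 7)) if platform == "HIFI"
                             else int(rng.integers(2, 5)) if platform == "ILLUMINA"
                             else 0)
                    _emit_flat_reads(rng, cohort._builder, pm, platform,
                                     pm.tissue, cid, chrom, pos, ref, alt, n_alt)
                    for parent_id in (fam.father_id, fam.mother_id):
                        tissue = "BLOOD" if platform == "HIFI" else pm.tissue
                        _emit_flat_reads(rng, cohort._builder, pm, platform,
                                         tissue, parent_id, chrom, pos, ref)

    # (c) homopolymer-edge noise
    if cc.homopolymer_noise_per_child > 0:
        for fam in fam_list:
            for cid in fam.child_ids:
                for _ in range(int(rng.poisson(cc.homopolymer_noise_per_child))):
                    chrom, length = _pick_chrom(rng, config)
                    pos = _alloc_pos(rng, fam, chrom, length)
                    base = str(rng.choice(list(BASES)))
                    alt = str(rng.choice([b for b in BASES if b != base]))
                    run = base * int(rng.integers(3, 7))
                    left = "".join(rng.choice([b for b in BASES if b != base], 5))
                    right = run + "".join(rng.choice([b for b in BASES if b != base], 3))
                    ev = {"chrom": chrom, "pos": pos, "ref": base, "alt": alt,
                          "child_id": cid, "vtype": "SNV",
                          "true_class": "HOMOPOLYMER_ERROR", "true_parent": ".",
                          "true_ab": float(rng.uniform(0.15, 0.35)),
                          "callers": "both",
                          "gq": int(np.clip(rng.normal(40, 15), 20, 99))}
                    fam.events.append(ev)
                    cohort.contexts[(chrom, pos)] = (left, right)
                    cohort.truth_rows.append(_truth_row(ev))
                    _emit_site_pileups(rng, cohort, fam, ev, {},
                                       include_sibling=False)
    return cohort
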