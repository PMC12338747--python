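"""Readers and writers for the package's on-disk formats.

Formats
-------
* pedigree TSV: ``family_id sample_id father_id mother_id sex role
  father_age_at_birth mother_age_at_birth`` ("." for not-applicable fields)
* trio VCF 4.2 with per-sample GT and GQ (one file per family)
* read-evidence TSV: one row per read per site — ``sample_id platform tissue
  chrom pos read_id mapq base_qual allele flank_left flank_right tag_snps``;
  ``tag_snps`` is a semicolon-joined list of ``pos:allele`` pairs, "." if none
* feature BED: ``chrom start end feature_class [pct_identity]``
* DNM result table: TSV, deterministic column order, sorted by
  (chrom, pos, child_id)

All positions in VCF/evidence files are 1-based; BED is 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    CallableMask,
    DnmRecord,
    Family,
    Origin,
    Pedigree,
    Person,
    Phase,
    PlatformAlleleCounts,
    Platform,
    Role,
    Tissue,
    VariantCall,
)

PEDIGREE_COLUMNS = [
    "family_id", "sample_id", "father_id", "mother_id", "sex", "role",
    "father_age_at_birth", "mother_age_at_birth",
]

EVIDENCE_COLUMNS = [
    "sample_id", "platform", "tissue", "chrom", "pos", "read_id", "mapq",
    "base_qual", "allele", "flank_left", "flank_right", "tag_snps",
]

DNM_COLUMNS = [
    "chrom", "pos", "ref", "alt", "child_id", "variant_type", "category",
    "validation_status", "phase", "origin",
    "hifi_ref", "hifi_alt", "ont_ref", "ont_alt", "ilm_ref", "ilm_alt",
    "hap_hifi_ref", "hap_hifi_alt", "hap_ont_ref", "hap_ont_alt",
]


class PedigreeError(ValueError):
    pass


def read_pedigree(path) -> Pedigree:
    """Load and validate a pedigree TSV into a :class:`Pedigree`."""
    rows = list(csv.DictReader(open(path), delimiter="\t"))
    if not rows:
        raise PedigreeError(f"{path}: empty pedigree")
    missing = set(PEDIGREE_COLUMNS) - set(rows[0])
    if missing:
        raise PedigreeError(f"{path}: missing columns {sorted(missing)}")

    def _age(row, col, lineno):
        raw = row[col]
        if raw in (".", "", "NA"):
            return None
        try:
            age = float(raw)
        except ValueError:
            raise PedigreeError(f"row {lineno}: malformed age {raw!r}") from None
        if not 0 < age < 100:
            raise PedigreeError(f"row {lineno}: age {age} out of range")
        return age

    persons: dict[str, Person] = {}
    by_family: dict[str, list[Person]] = {}
    links: dict[str, tuple] = {}
    for i, row in enumerate(rows, start=2):
        sid = row["sample_id"]
        if sid in persons:
            raise PedigreeError(f"row {i}: duplicate sample_id {sid!r}")
        role = Role(row["role"])
        p = Person(
            sample_id=sid,
            family_id=row["family_id"],
            role=role,
            sex=row["sex"],
            father_id=None if row["father_id"] == "." else row["father_id"],
            mother_id=None if row["mother_id"] == "." else row["mother_id"],
            father_age_at_birth=_age(row, "father_age_at_birth", i),
            mother_age_at_birth=_age(row, "mother_age_at_birth", i),
        )
        if p.is_child and (p.father_id is None or p.mother_id is None):
            raise PedigreeError(f"row {i}: child {sid!r} missing a parent id")
        persons[sid] = p
        by_family.setdefault(p.family_id, []).append(p)
        links[sid] = (p.father_id, p.mother_id, i)

    families = []
    for fid, members in by_family.items():
        fathers = [p for p in members if p.role is Role.FATHER]
        mothers = [p for p in members if p.role is Role.MOTHER]
        children = [p for p in members if p.is_child]
        if len(fathers) != 1 or len(mothers) != 1:
            raise PedigreeError(f"family {fid!r}: need exactly one father and one mother")
        if not children:
            raise PedigreeError(f"family {fid!r}: no children")
        for c in children:
            _, _, lineno = links[c.sample_id]
            if c.father_id != fathers[0].sample_id or c.mother_id != mothers[0].sample_id:
                raise PedigreeError(
                    f"row {lineno}: child {c.sample_id!r} parent ids do not match family {fid!r}"
                )
        families.append(Family(fid, fathers[0], mothers[0], children))
    return Pedigree(families)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for fam in pedigree.families.values():
            for p in fam.members:
                fh.write("\t".join([
                    fam.family_id, p.sample_id,
                    p.father_id or ".", p.mother_id or ".",
                    p.sex, p.role.value,
                    "." if p.father_age_at_birth is None else f"{p.father_age_at_birth:g}",
                    "." if p.mother_age_at_birth is None else f"{p.mother_age_at_birth:g}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_trio_vcf(path, samples: list[str], records: Iterable[dict],
                   contigs: Optional[list[tuple[str, int]]] = None) -> None:
    """Write a minimal VCF 4.2 with GT:GQ per sample.

    ``records`` are dicts with keys chrom, pos, ref, alts (list), and per
    sample a genotype string like "0/1", "1", "./." plus ``gq`` dict.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs or []:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            alts = ",".join(rec["alts"])
            caller = rec.get("caller", ".")
            info = f"CALLER={caller}" if caller != "." else "."
            cells = []
            for s in samples:
                gt = rec["gt"].get(s, "./.")
                gq = rec.get("gq", {}).get(s, ".")
                cells.append(f"{gt}:{gq}")
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{alts}\t.\tPASS\t{info}\tGT:GQ\t"
                     + "\t".join(cells) + "\n")


def read_trio_vcf(path, pedigree: Pedigree) -> list[VariantCall]:
    """Read a family VCF into biallelic :class:`VariantCall` records.

    Multiallelic records are split per alt; on a split record the other alt
    is mapped to the sentinel allele index 2.  Haploid genotypes (male sex
    chromosomes) are preserved as 1-tuples.  Samples absent from the pedigree
    raise; a missing GQ is treated as 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = vcf.samples
    for s in samples:
        if s not in pedigree:
            raise ValueError(f"{path}: sample {s!r} absent from pedigree")
    out: list[VariantCall] = []
    for v in vcf:
        try:
            gqs = v.format("GQ")
        except KeyError:
            gqs = None
        try:
            caller = v.INFO.get("CALLER")
        except Exception:
            caller = None
        raw_gts = v.genotypes  # per sample: [a0, (a1,) phased]
        for ai, alt in enumerate(v.ALT, start=1):
            genotypes: dict[str, Optional[tuple]] = {}
            gq: dict[str, int] = {}
            for si, s in enumerate(samples):
                alleles = raw_gts[si][:-1]  # drop phased flag
                mapped = []
                missing = False
                for a in alleles:
                    if a < 0:
                        missing = True
                        break
                    mapped.append(0 if a == 0 else (1 if a == ai else 2))
                genotypes[s] = None if missing else tuple(mapped)
                if gqs is not None:
                    val = gqs[si]
                    try:
                        val = int(val[0]) if np.ndim(val) else int(val)
                    except (TypeError, ValueError):
                        val = 0
                    gq[s] = max(val, 0) if val == val else 0
                else:
                    gq[s] = 0
            out.append(VariantCall(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                genotypes=genotypes, gq=gq,
                caller_ids=frozenset([caller] if caller else []),
            ))
    return out


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------

_PLATFORMS = {p.value for p in Platform}
_TISSUES = {t.value for t in Tissue}


class ReadEvidence:
    """Indexed collection of per-read allele observations.

    Backed by a :class:`pandas.DataFrame` with :data:`EVIDENCE_COLUMNS`;
    rows are retrievable by (chrom, pos) site.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(EVIDENCE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"evidence table missing columns {sorted(missing)}")
        bad_platform = ~df["platform"].isin(_PLATFORMS)
        if bad_platform.any():
            i = int(np.argmax(bad_platform.to_numpy()))
            raise ValueError(
                f"line {i + 2}: unknown platform {df['platform'].iloc[i]!r}")
        bad_tissue = ~df["tissue"].isin(_TISSUES)
        if bad_tissue.any():
            i = int(np.argmax(bad_tissue.to_numpy()))
            raise ValueError(f"line {i + 2}: unknown tissue {df['tissue'].iloc[i]!r}")
        self.df = df.reset_index(drop=True)
        self._site_index = {
            site: idx.to_numpy()
            for site, idx in self.df.groupby(["chrom", "pos"], sort=False).groups.items()
        }

    def __len__(self) -> int:
        return len(self.df)

    def at_site(self, chrom: str, pos: int) -> pd.DataFrame:
        idx = self._site_index.get((chrom, pos))
        if idx is None:
            return self.df.iloc[0:0]
        return self.df.iloc[idx]

    @property
    def _columns(self) -> dict:
        if getattr(self, "_col_cache", None) is None:
            self._col_cache = {c: self.df[c].to_numpy() for c in EVIDENCE_COLUMNS}
        return self._col_cache

    def site_arrays(self, chrom: str, pos: int) -> dict:
        """Column arrays for one site — the fast path used by validation and
        phasing (same content as :meth:`at_site`)."""
        idx = self._site_index.get((chrom, pos))
        cols = self._columns
        if idx is None:
            return {c: cols[c][:0] for c in EVIDENCE_COLUMNS}
        return {c: cols[c][idx] for c in EVIDENCE_COLUMNS}

    def sites(self) -> list[tuple[str, int]]:
        return list(self._site_index)

    @staticmethod
    def parse_tags(tag_field: str) -> list[tuple[int, str]]:
        if tag_field in (".", "", None):
            return []
        out = []
        for item in tag_field.split(";"):
            pos_s, allele = item.split(":")
            out.append((int(pos_s), allele))
        return out

    @staticmethod
    def format_tags(tags: list[tuple[int, str]]) -> str:
        if not tags:
            return "."
        return ";".join(f"{p}:{a}" for p, a in tags)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, columns=EVIDENCE_COLUMNS)

    @classmethod
    def read(cls, path) -> "ReadEvidence":
        df = pd.read_csv(
            path, sep="\t",
            dtype={"chrom": str, "allele": str, "tag_snps": str,
                   "sample_id": str, "read_id": str},
            keep_default_na=False,
        )
        for col in ("pos", "mapq", "base_qual", "flank_left", "flank_right"):
            df[col] = df[col].astype(np.int64)
        return cls(df)

    @classmethod
    def concat(cls, parts: Iterable["ReadEvidence"]) -> "ReadEvidence":
        dfs = [p.df for p in parts]
        return cls(pd.concat(dfs, ignore_index=True))


# ---------------------------------------------------------------------------
# Feature tracks (BED)
# ---------------------------------------------------------------------------

class FeatureTrack:
    """Genomic intervals labelled by feature class, 0-based half-open.

    The optional 5th column holds per-class metadata: percent identity for
    SD intervals (validated to [90, 100]) or the repeat motif for TRs.
    """

    def __init__(self, intervals: Iterable[tuple]):
        # interval: (chrom, start, end, feature_class[, pct_identity|motif])
        self.intervals: list[tuple] = []
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            chrom, start, end, fclass = iv[0], int(iv[1]), int(iv[2]), iv[3]
            extra = iv[4] if len(iv) > 4 and iv[4] not in (".", None, "") else None
            if isinstance(extra, str):
                try:
                    extra = float(extra)
                except ValueError:
                    pass  # motif string
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if isinstance(extra, float) and not 90 <= extra <= 100:
                raise ValueError(f"pct_identity {extra} out of [90,100]")
            self.intervals.append((chrom, start, end, fclass, extra))
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, (fclass, extra))

    def classes_at(self, chrom: str, pos_1based: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {data[0] for _, _, data in tree[pos_1based - 1]}

    def overlaps(self, chrom: str, pos_1based: int, feature_class: str) -> bool:
        return feature_class in self.classes_at(chrom, pos_1based)

    def hits(self, chrom: str, pos_1based: int) -> list[tuple]:
        """All (start, end, feature_class, pct_identity) covering the site."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data[0], iv.data[1]) for iv in tree[pos_1based - 1]]

    def of_class(self, feature_class: str) -> "FeatureTrack":
        return FeatureTrack(
            iv for iv in self.intervals if iv[3] == feature_class)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, fclass, extra in self.intervals:
                if extra is None:
                    tail = ""
                elif isinstance(extra, float):
                    tail = f"\t{extra:g}"
                else:
                    tail = f"\t{extra}"
                fh.write(f"{chrom}\t{start}\t{end}\t{fclass}{tail}\n")

    @classmethod
    def read(cls, path) -> "FeatureTrack":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                ivs.append(tuple(parts[:5]))
        return cls(ivs)

    @classmethod
    def empty(cls) -> "FeatureTrack":
        return cls([])


# ---------------------------------------------------------------------------
# DNM tables
# ---------------------------------------------------------------------------

def _counts(rec: DnmRecord, platform: str) -> tuple[int, int]:
    c = rec.platform_counts.get(platform)
    return (c.n_ref, c.n_alt) if c is not None else (0, 0)


def write_dnm_table(records: list[DnmRecord], path) -> None:
    """Write DNM records as a TSV, sorted by (chrom, pos, child_id)."""
    rows = []
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.child_id, r.ref, r.alt)):
        hifi = _counts(r, "HIFI"); ont = _counts(r, "ONT"); ilm = _counts(r, "ILLUMINA")
        hap_h = r.hap_counts.get("HIFI", (0, 0))
        hap_o = r.hap_counts.get("ONT", (0, 0))
        rows.append([
            r.chrom, r.pos, r.ref, r.alt, r.child_id, r.variant_type,
            r.category, r.validation_status, r.phase.value, r.origin.value,
            hifi[0], hifi[1], ont[0], ont[1], ilm[0], ilm[1],
            hap_h[0], hap_h[1], hap_o[0], hap_o[1],
        ])
    pd.DataFrame(rows, columns=DNM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dnm_table(path) -> list[DnmRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str,
                                            "category": str},
                     keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        rec = DnmRecord(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            child_id=row.child_id, variant_type=row.variant_type,
            category=row.category or "",
            validation_status=row.validation_status,
            phase=Phase(row.phase), origin=Origin(row.origin),
        )
        rec.platform_counts = {
            "HIFI": PlatformAlleleCounts("HIFI", int(row.hifi_ref), int(row.hifi_alt)),
            "ONT": PlatformAlleleCounts("ONT", int(row.ont_ref), int(row.ont_alt)),
            "ILLUMINA": PlatformAlleleCounts("ILLUMINA", int(row.ilm_ref), int(row.ilm_alt)),
        }
        rec.hap_counts = {
            "HIFI": (int(row.hap_hifi_ref), int(row.hap_hifi_alt)),
            "ONT": (int(row.hap_ont_ref), int(row.hap_ont_alt)),
        }
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Masks & truth
# ---------------------------------------------------------------------------

def write_mask_bed(mask: CallableMask, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{mask.child_id}\n")


def read_mask_bed(path, child_id: str) -> CallableMask:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, *rest = line.split("\t")
            if rest and rest[0].strip() != child_id:
                continue
            intervals.setdefault(chrom, []).append((int(s), int(e)))
    return CallableMask(child_id, intervals).normalized()


def write_context_table(contexts: dict[tuple[str, int], tuple[str, str]], path) -> None:
    """Local reference context per site: chrom, pos, left, right strings."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tleft\tright\n")
        for (chrom, pos), (left, right) in sorted(contexts.items()):
            fh.write(f"{chrom}\t{pos}\t{left}\t{right}\n")


def read_context_table(path) -> dict[tuple[str, int], tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "left": str, "right": str})
    return {(r.chrom, int(r.pos)): (r.left, r.right) for r in df.itertuples(index=False)}


TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "child_id", "true_class", "true_parent",
    "true_ab", "variant_type",
]


def write_truth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                       keep_default_na=False)
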