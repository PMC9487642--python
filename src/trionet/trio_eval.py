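"""Trio-level evaluation: VCF merging, Mendelian violations, de novo calls, F1.

Merging mirrors the common trio workflow of joining the three members' VCFs
at the union of their sites, optionally keeping PASS records only, and
treating a member with no record at a site as homozygous reference.
Violations are counted over all merged sites under the 21-class Mendelian
predicate; de novo candidates are child 0/1 het calls with both parents
homozygous reference or unknown, confidence-gated on the child QUAL and
optionally restricted to confident regions.  Precision/recall use exact
position + allele + genotype matching, which is equivalent to
haplotype-aware matching on the left-aligned biallelic records the
simulator and caller emit.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .genotype_space import (
    Allele,
    allele_class_of_vcf_allele,
    genotype_from_vcf_gt,
    mismatch_count,
)
from .trio_simulator import TrioTruthRecord
from .vcf_io import SiteCall, read_vcf

__all__ = [
    "MergedTrioRecord",
    "EvalReport",
    "merge_trio",
    "count_mendelian_violations",
    "find_de_novo",
    "score_calls",
    "evaluate_trio",
    "load_bed",
]

#: fixed member order of violation-pattern keys
PATTERN_ORDER = ("parent1", "parent2", "child")


@dataclass(frozen=True)
class MergedTrioRecord:
    """One union site across the trio after merging."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gts: dict  # member -> (i, j) into (ref,)+alts, never None after merge
    missing: dict  # member -> bool, True when the member had no usable record
    quals: dict  # member -> float | None

    def gt_string(self, member: str) -> str:
        if self.missing[member]:
            return "./."
        return "/".join(str(i) for i in self.gts[member])


def _index_calls(calls: Sequence[SiteCall], pass_only: bool) -> dict:
    out = {}
    prev = None
    for c in calls:
        key = (c.contig, c.pos)
        if prev is not None and c.contig == prev[0] and c.pos < prev[1]:
            raise ValueError("VCF records out of order")
        prev = key
        if pass_only and c.filter != "PASS":
            continue
        out[key] = c
    return out


def merge_trio(
    vcf_child: str | Path | Sequence[SiteCall],
    vcf_p1: str | Path | Sequence[SiteCall],
    vcf_p2: str | Path | Sequence[SiteCall],
    pass_only: bool = True,
) -> list[MergedTrioRecord]:
    """Join three per-sample VCFs at the union of their sites.

    A member without a record at a union site receives genotype 0/0 but is
    flagged ``missing`` (the de novo definition treats it as unknown).  ALT
    lists are joined multiallelically by string identity; member genotype
    indices are remapped into the joined list.  Records at the same site with
    different REF strings are rejected.
    """
    per_member = {}
    for member, src in zip(("child", "parent1", "parent2"), (vcf_child, vcf_p1, vcf_p2)):
        calls = src if isinstance(src, (list, tuple)) else read_vcf(src)
        per_member[member] = _index_calls(calls, pass_only)
    keys = sorted(set().union(*(m.keys() for m in per_member.values())))
    merged: list[MergedTrioRecord] = []
    for key in keys:
        present = {m: per_member[m].get(key) for m in per_member}
        refs = {c.ref for c in present.values() if c is not None}
        if len(refs) != 1:
            raise ValueError(f"conflicting REF alleles at {key}: {sorted(refs)}")
        ref = refs.pop()
        alts: list[str] = []
        for c in present.values():
            if c is None:
                continue
            for a in c.alts:
                if a not in alts:
                    alts.append(a)
        gts, missing, quals = {}, {}, {}
        for m, c in present.items():
            if c is None or c.gt[0] is None or c.gt[1] is None:
                gts[m] = (0, 0)
                missing[m] = True
                quals[m] = None if c is None else c.qual
                continue
            site_alleles = (c.ref,) + c.alts
            joined = (ref,) + tuple(alts)
            gts[m] = tuple(sorted(joined.index(site_alleles[i]) for i in c.gt))
            missing[m] = False
            quals[m] = c.qual
        merged.append(
            MergedTrioRecord(
                contig=key[0], pos=key[1], ref=ref, alts=tuple(alts),
                gts=gts, missing=missing, quals=quals,
            )
        )
    return merged


def _genotype21(rec: MergedTrioRecord, member: str):
    return genotype_from_vcf_gt(rec.gts[member], rec.ref, rec.alts)


def count_mendelian_violations(
    merged: Sequence[MergedTrioRecord],
) -> tuple[int, dict[str, int]]:
    """Violation count over all merged sites, with a pattern histogram.

    Histogram keys are ``"(p1, p2, child)"`` GT strings; missing genotypes
    have already been converted to 0/0 by the merge, mirroring the
    merge-with-`-0` convention.
    """
    histogram: Counter[str] = Counter()
    count = 0
    for rec in merged:
        gts = {m: _genotype21(rec, m) for m in ("child", "parent1", "parent2")}
        if any(g is None for g in gts.values()):
            continue
        if mismatch_count(gts["child"], gts["parent1"], gts["parent2"]) > 0:
            count += 1
            key = "({}, {}, {})".format(*(rec.gt_string(m) for m in PATTERN_ORDER))
            histogram[key] += 1
    return count, dict(histogram)


def load_bed(path: str | Path) -> dict[str, IntervalTree]:
    """0-based half-open BED intervals per contig."""
    trees: dict[str, IntervalTree] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line {line_no}: {line!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED line {line_no}: {line!r}") from exc
        if end < start:
            raise ValueError(f"malformed BED interval at line {line_no}")
        trees.setdefault(parts[0], IntervalTree()).addi(start, max(end, start + 1))
    return trees


def _in_regions(trees: dict[str, IntervalTree] | None, contig: str, pos: int) -> bool:
    if trees is None:
        return True
    tree = trees.get(contig)
    return bool(tree is not None and tree.overlaps(pos - 1))  # VCF pos is 1-based


def find_de_novo(
    merged: Sequence[MergedTrioRecord],
    child_qual_threshold: float = 0.0,
    confident_regions: dict[str, IntervalTree] | str | Path | None = None,
    truth: Sequence[TrioTruthRecord] | None = None,
) -> tuple[list[MergedTrioRecord], dict[str, int]]:
    """De novo candidates: child het 0/x above the QUAL gate, parents 0/0 or unknown.

    When simulator truth is supplied, candidates are split into TP/FP by the
    truth's de novo flag at the site.
    """
    if isinstance(confident_regions, (str, Path)):
        confident_regions = load_bed(confident_regions)
    hits: list[MergedTrioRecord] = []
    for rec in merged:
        if rec.missing["child"]:
            continue
        gt = rec.gts["child"]
        if not (gt[0] == 0 and gt[1] != 0 and gt[0] != gt[1]):  # strict ref/alt het
            continue
        qual = rec.quals["child"]
        if qual is not None and qual < child_qual_threshold:
            continue
        parents_ok = all(
            rec.missing[m] or rec.gts[m] == (0, 0) for m in ("parent1", "parent2")
        )
        if not parents_ok:
            continue
        if not _in_regions(confident_regions, rec.contig, rec.pos):
            continue
        hits.append(rec)
    counts = {"n_candidates": len(hits), "tp": 0, "fp": 0}
    if truth is not None:
        denovo_positions = {(t.contig, t.position) for t in truth if t.is_denovo}
        for rec in hits:
            key = (rec.contig, rec.pos)
            counts["tp" if key in denovo_positions else "fp"] += 1
    return hits, counts


# --- per-sample scoring -------------------------------------------------------


def _variant_entries(calls: Sequence[SiteCall], regions) -> dict:
    out = {}
    for c in calls:
        if c.gt[0] is None or c.gt[1] is None or c.gt == (0, 0):
            continue
        if not _in_regions(regions, c.contig, c.pos):
            continue
        alleles = (c.ref,) + c.alts
        used = tuple(sorted(alleles[i] for i in c.gt))
        out[(c.contig, c.pos)] = (c.ref, used)
    return out


def _is_indel_entry(ref: str, used_alleles: tuple[str, ...]) -> bool:
    classes = {allele_class_of_vcf_allele(a, ref) for a in used_alleles}
    return bool(classes & {Allele.Ins, Allele.Del})


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "fp": fp, "fn": fn}


def score_calls(
    calls: str | Path | Sequence[SiteCall],
    truth: str | Path | Sequence[SiteCall],
    regions: dict[str, IntervalTree] | str | Path | None = None,
) -> dict[str, dict[str, float]]:
    """Exact-match precision/recall/F1 with an SNP/INDEL breakdown.

    A true positive requires identical position, used alleles and genotype.
    Non-reference calls absent from the truth are false positives;
    non-reference truth entries never matched are false negatives.
    """
    if isinstance(regions, (str, Path)):
        regions = load_bed(regions)
    call_list = calls if isinstance(calls, (list, tuple)) else read_vcf(calls)
    truth_list = truth if isinstance(truth, (list, tuple)) else read_vcf(truth)
    call_map = _variant_entries(call_list, regions)
    truth_map = _variant_entries(truth_list, regions)
    counts = {cls: {"tp": 0, "fp": 0, "fn": 0} for cls in ("overall", "snp", "indel")}

    def bucket(entry) -> str:
        return "indel" if _is_indel_entry(*entry) else "snp"

    for key, entry in call_map.items():
        hit = truth_map.get(key) == entry
        for cls in ("overall", bucket(entry)):
            counts[cls]["tp" if hit else "fp"] += 1
    for key, entry in truth_map.items():
        if call_map.get(key) != entry:
            for cls in ("overall", bucket(entry)):
                counts[cls]["fn"] += 1
    return {cls: _prf(**c) for cls, c in counts.items()}


@dataclass
class EvalReport:
    """Aggregate trio evaluation: per-sample scores plus trio-level metrics."""

    per_sample: dict[str, dict[str, dict[str, float]]]
    mendelian_violations: int
    violation_patterns: dict[str, int]
    de_novo: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "per_sample": self.per_sample,
                "mendelian_violations": self.mendelian_violations,
                "violation_patterns": self.violation_patterns,
                "de_novo": self.de_novo,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def patterns_tsv(self, path: str | Path) -> Path:
        lines = ["pattern\tcount"] + [
            f"{k}\t{v}" for k, v in sorted(self.violation_patterns.items(), key=lambda kv: -kv[1])
        ]
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def evaluate_trio(
    call_vcfs: dict[str, str | Path],
    truth_vcfs: dict[str, str | Path],
    truth_records: Sequence[TrioTruthRecord] | None = None,
    regions: str | Path | None = None,
    child_qual_threshold: float = 0.0,
    pass_only: bool = True,
) -> EvalReport:
    """Full trio evaluation from three call VCFs and three truth VCFs.

    Precision/recall and de novo counts honour the confident regions;
    Mendelian violations are counted over all merged sites.
    """
    region_trees = load_bed(regions) if regions is not None else None
    per_sample = {
        m: score_calls(call_vcfs[m], truth_vcfs[m], region_trees) for m in call_vcfs
    }
    merged = merge_trio(
        call_vcfs["child"], call_vcfs["parent1"], call_vcfs["parent2"], pass_only=pass_only
    )
    n_violations, patterns = count_mendelian_violations(merged)
    _, denovo_counts = find_de_novo(
        merged, child_qual_threshold, region_trees, truth_records
    )
    return EvalReport(
        per_sample=per_sample,
        mendelian_violations=n_violations,
        violation_patterns=patterns,
        de_novo=denovo_counts,
    )
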