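"""Trio merging, violation counting, de novo detection and exact-match scoring."""

import numpy as np
import pytest

from trionet.genotype_space import GENOTYPE_PAIRS, genotype_from_vcf_gt
from trionet.trio_eval import (
    MergedTrioRecord,
    count_mendelian_violations,
    evaluate_trio,
    find_de_novo,
    load_bed,
    merge_trio,
    score_calls,
)
from trionet.trio_simulator import SimConfig, simulate_truth, write_truth_vcfs
from trionet.vcf_io import SiteCall


def _call(pos, gt, ref="A", alts=("C",), qual=50.0, filter="PASS", contig="chr1"):
    return SiteCall(contig, pos, ref, alts, gt, qual, filter)


def _merged(pos, child, p1, p2, ref="A", alts=("C",), quals=(50.0, 50.0, 50.0), missing=None):
    missing = missing or {}
    return MergedTrioRecord(
        contig="chr1", pos=pos, ref=ref, alts=alts,
        gts={"child": child, "parent1": p1, "parent2": p2},
        missing={m: missing.get(m, False) for m in ("child", "parent1", "parent2")},
        quals=dict(zip(("child", "parent1", "parent2"), quals)),
    )


class TestMerge:
    def test_child_only_site_fills_parents_as_missing_homref(self):
        merged = merge_trio([_call(10, (0, 1))], [_call(99, (0, 0))], [_call(99, (0, 0))])
        rec = next(r for r in merged if r.pos == 10)
        assert rec.gts["parent1"] == (0, 0) and rec.missing["parent1"]
        assert rec.gts["child"] == (0, 1) and not rec.missing["child"]

    def test_three_identical_vcfs_collapse_to_one_record(self):
        calls = [_call(5, (0, 1))]
        merged = merge_trio(calls, calls, calls)
        assert len(merged) == 1 and merged[0].alts == ("C",)

    def test_union_count_matches_set_oracle(self, rng):
        pools = []
        for _ in range(3):
            pos = sorted(rng.choice(np.arange(1, 1000), size=500, replace=False))
            pools.append([_call(int(p), (0, 1)) for p in pos])
        merged = merge_trio(*pools)
        expected = {c.pos for pool in pools for c in pool}
        assert len(merged) == len(expected)

    def test_pass_only_drops_filtered_records(self):
        merged = merge_trio(
            [_call(1, (0, 1), filter="LowQual")], [_call(1, (0, 1))], [_call(1, (0, 1))]
        )
        assert merged[0].missing["child"] and merged[0].gts["child"] == (0, 0)

    def test_multiallelic_join_remaps_gt_indices(self):
        merged = merge_trio(
            [_call(1, (0, 1), alts=("C",))],
            [_call(1, (0, 1), alts=("G",))],
            [_call(1, (0, 0), alts=("C",))],
        )
        rec = merged[0]
        assert rec.alts == ("C", "G")
        assert rec.gts["child"] == (0, 1) and rec.gts["parent1"] == (0, 2)

    def test_conflicting_ref_rejected(self):
        with pytest.raises(ValueError):
            merge_trio([_call(1, (0, 1), ref="A")], [_call(1, (0, 1), ref="T")], [_call(2, (0, 0))])

    def test_out_of_order_records_rejected(self):
        calls = [_call(10, (0, 1)), _call(5, (0, 1))]
        with pytest.raises(ValueError):
            merge_trio(calls, [_call(1, (0, 0))], [_call(1, (0, 0))])


def _oracle_is_violation(rec: MergedTrioRecord) -> bool:
    """Brute-force re-implementation: enumerate one-allele-per-parent choices."""
    gts = {m: genotype_from_vcf_gt(rec.gts[m], rec.ref, rec.alts) for m in rec.gts}
    child = set()
    ca, cb = GENOTYPE_PAIRS[gts["child"].index]
    p1 = GENOTYPE_PAIRS[gts["parent1"].index]
    p2 = GENOTYPE_PAIRS[gts["parent2"].index]
    for x in p1:
        for y in p2:
            child.add(frozenset((x, y)) if x != y else frozenset((x,)))
    want = frozenset((ca, cb)) if ca != cb else frozenset((ca,))
    return want not in child


class TestViolationCounting:
    def test_perfect_clean_simulation_has_zero_violations(self, small_sim, tmp_path):
        _, truth, _ = small_sim
        paths = write_truth_vcfs(truth, tmp_path / "truth")
        merged = merge_trio(paths["child"], paths["parent1"], paths["parent2"])
        count, patterns = count_mendelian_violations(merged)
        assert count == 0 and patterns == {}

    def test_discussion_pattern_is_counted_once(self):
        rec = _merged(7, child=(0, 0), p1=(0, 0), p2=(1, 1))
        count, patterns = count_mendelian_violations([rec])
        assert count == 1
        assert patterns == {"(0/0, 1/1, 0/0)": 1}

    def test_random_records_agree_with_bruteforce_oracle(self, rng):
        records = [
            _merged(
                i + 1,
                child=tuple(sorted(rng.integers(0, 2, size=2))),
                p1=tuple(sorted(rng.integers(0, 2, size=2))),
                p2=tuple(sorted(rng.integers(0, 2, size=2))),
            )
            for i in range(1000)
        ]
        count, _ = count_mendelian_violations(records)
        assert count == sum(_oracle_is_violation(r) for r in records)

    def test_parent_swap_invariance(self, rng):
        records = [
            _merged(
                i + 1,
                child=tuple(sorted(rng.integers(0, 2, size=2))),
                p1=tuple(sorted(rng.integers(0, 2, size=2))),
                p2=tuple(sorted(rng.integers(0, 2, size=2))),
            )
            for i in range(300)
        ]
        swapped = [
            _merged(r.pos, r.gts["child"], r.gts["parent2"], r.gts["parent1"])
            for r in records
        ]
        assert count_mendelian_violations(records)[0] == count_mendelian_violations(swapped)[0]


class TestDeNovo:
    def test_confident_het_child_with_homref_parents_is_reported(self):
        hits, counts = find_de_novo([_merged(3, (0, 1), (0, 0), (0, 0))], 20.0)
        assert len(hits) == 1 and counts["n_candidates"] == 1

    def test_homalt_child_is_a_violation_but_not_de_novo(self):
        rec = _merged(3, (1, 1), (0, 0), (0, 0))
        assert count_mendelian_violations([rec])[0] == 1
        hits, _ = find_de_novo([rec], 0.0)
        assert hits == []

    def test_low_quality_child_calls_are_gated(self):
        rec = _merged(3, (0, 1), (0, 0), (0, 0), quals=(5.0, 50.0, 50.0))
        assert find_de_novo([rec], 20.0)[0] == []

    def test_unknown_parents_count_as_compatible(self):
        rec = _merged(3, (0, 1), (0, 0), (0, 0), missing={"parent1": True, "parent2": True})
        assert len(find_de_novo([rec], 0.0)[0]) == 1

    def test_reports_are_a_subset_of_violations_when_parents_called(self, rng):
        for _ in range(50):
            rec = _merged(
                1,
                child=tuple(sorted(rng.integers(0, 2, size=2))),
                p1=tuple(sorted(rng.integers(0, 2, size=2))),
                p2=tuple(sorted(rng.integers(0, 2, size=2))),
            )
            if find_de_novo([rec], 0.0)[0]:
                assert count_mendelian_violations([rec])[0] == 1

    def test_bed_restriction_and_malformed_bed(self, tmp_path):
        rec = _merged(100, (0, 1), (0, 0), (0, 0))
        bed = tmp_path / "conf.bed"
        bed.write_text("chr1\t0\t50\n")
        assert find_de_novo([rec], 0.0, bed)[0] == []
        bed.write_text("chr1\t0\t200\n")
        assert len(find_de_novo([rec], 0.0, bed)[0]) == 1
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\tnot_a_number\t5\n")
        with pytest.raises(ValueError):
            find_de_novo([rec], 0.0, bad)

    def test_tp_fp_split_against_simulated_truth(self, tmp_path):
        cfg = SimConfig(
            n_sites=3000, denovo_rate=0.02, seed=17,
            alt_af_spectrum=lambda r, n: np.full(n, 1e-9),
        )
        truth = simulate_truth(cfg)
        paths = write_truth_vcfs(truth, tmp_path / "t")
        merged = merge_trio(paths["child"], paths["parent1"], paths["parent2"])
        hits, counts = find_de_novo(merged, 0.0, truth=truth)
        assert counts["tp"] + counts["fp"] == counts["n_candidates"]
        assert counts["tp"] > 0 and counts["fp"] == 0  # perfect calls: no FPs


class TestScoring:
    def test_identical_call_and_truth_sets_score_one(self):
        calls = [_call(p, (0, 1)) for p in (1, 5, 9)]
        scores = score_calls(calls, list(calls))
        assert scores["overall"] == {
            "precision": 1.0, "recall": 1.0, "f1": 1.0, "tp": 3, "fp": 0, "fn": 0,
        }

    def test_empty_call_set_reports_zero_not_undefined(self):
        truth = [_call(1, (0, 1))]
        scores = score_calls([_call(1, (0, 0))], truth)
        assert scores["overall"]["precision"] == 0.0
        assert scores["overall"]["recall"] == 0.0
        assert scores["overall"]["f1"] == 0.0

    def test_counting_oracle_90_of_100(self):
        truth = [_call(p, (0, 1)) for p in range(1, 101)]
        calls = [_call(p, (0, 1)) for p in range(1, 91)] + [
            _call(p, (1, 1)) for p in range(91, 101)  # wrong genotype
        ]
        scores = score_calls(calls, truth)["overall"]
        assert scores["precision"] == pytest.approx(0.9)
        assert scores["recall"] == pytest.approx(0.9)
        assert scores["f1"] == pytest.approx(0.9)

    def test_snp_indel_split_by_allele_class(self):
        truth = [_call(1, (0, 1)), _call(2, (0, 1), ref="A", alts=("AT",))]
        scores = score_calls(list(truth), truth)
        assert scores["snp"]["tp"] == 1 and scores["indel"]["tp"] == 1

    def test_region_restriction_excludes_outside_sites(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t5\n")
        truth = [_call(2, (0, 1)), _call(50, (0, 1))]
        scores = score_calls(list(truth), truth, regions=bed)
        assert scores["overall"]["tp"] == 1


class TestEndToEndReport:
    def test_report_from_perfect_truth_calls(self, small_sim, tmp_path):
        _, truth, _ = small_sim
        paths = write_truth_vcfs(truth, tmp_path / "t")
        report = evaluate_trio(
            {m: paths[m] for m in paths}, {m: paths[m] for m in paths}, truth_records=truth
        )
        assert report.mendelian_violations == 0
        for member in ("child", "parent1", "parent2"):
            assert report.per_sample[member]["overall"]["f1"] == 1.0
        text = report.to_json(tmp_path / "report.json")
        assert "mendelian_violations" in text
        tsv = report.patterns_tsv(tmp_path / "patterns.tsv")
        assert tsv.read_text().startswith("pattern\tcount")
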