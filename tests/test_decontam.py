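"""Tests for host exclusion, three-way classification and GC partitioning."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoploss.decontam import (
    ClassifierParams,
    GcPartitionParams,
    HostFilterParams,
    Label,
    PRESET_GC_CUTOFFS,
    UnimodalGcError,
    classify_contig,
    estimate_gc_cutoff,
    gc_partition,
    host_filter,
    run_decontam_pipeline,
)
from apoploss.hits import BestHitPair, HitRecord
from apoploss.seqio_gc import Contig
from apoploss.synthdata import SimParams, simulate_assembly, simulate_hits


def _hit(identity=90.0, e_value=1e-80, bits=200.0, subject="s1"):
    return HitRecord(
        query_id="q", subject_id=subject, pct_identity=identity, aln_len=100,
        mismatches=0, gap_opens=0, q_start=1, q_end=100, s_start=1, s_end=100,
        e_value=e_value, bit_score=bits,
    )


class TestHostFilter:
    def test_passing_hit_excluded(self):
        assert host_filter("c", _hit(identity=90, e_value=1e-80)) == "exclude"

    def test_boundary_identity_is_kept(self):
        # 85 is not > 85, even with an overwhelming e-value
        assert host_filter("c", _hit(identity=85.0, e_value=1e-200)) == "keep"

    def test_boundary_evalue_is_kept(self):
        assert host_filter("c", _hit(identity=99.0, e_value=1e-75)) == "keep"

    def test_no_hit_keeps(self):
        assert host_filter("c", None) == "keep"

    def test_custom_thresholds(self):
        params = HostFilterParams(identity_threshold=50, evalue_threshold=1e-5)
        assert host_filter("c", _hit(identity=60, e_value=1e-10), params) == "exclude"


class TestClassifyContig:
    def test_clear_target(self):
        pair = BestHitPair("q", _hit(e_value=1e-100, bits=300), _hit(e_value=1e-50, bits=100))
        lab = classify_contig(pair)
        assert lab.value is Label.TARGET and lab.rule == "fold_rule"

    def test_identical_hits_not_clear(self):
        h = _hit(e_value=1e-60, bits=200)
        assert classify_contig(BestHitPair("q", h, h)).value is Label.NOT_CLEAR

    def test_near_miss_not_clear(self):
        pair = BestHitPair("q", _hit(e_value=1e-60, bits=200), _hit(e_value=1e-58, bits=190))
        assert classify_contig(pair).value is Label.NOT_CLEAR

    def test_exact_fold_boundaries_inclusive(self):
        # e-value exactly 100x less and bit score exactly 1.5x more
        pair = BestHitPair("q", _hit(e_value=1e-52, bits=150), _hit(e_value=1e-50, bits=100))
        assert classify_contig(pair).value is Label.TARGET

    def test_mirrored_contamination(self):
        pair = BestHitPair("q", _hit(e_value=1e-50, bits=100), _hit(e_value=1e-100, bits=300))
        assert classify_contig(pair).value is Label.CONTAMINATION

    def test_single_sided_evidence(self):
        assert classify_contig(BestHitPair("q", _hit(), None)).value is Label.TARGET
        assert classify_contig(BestHitPair("q", None, _hit())).value is Label.CONTAMINATION

    def test_no_hits_default_not_clear(self):
        assert classify_contig(BestHitPair("q", None, None)).value is Label.NOT_CLEAR

    def test_zero_evalues_floored(self):
        # both zero -> equal after flooring -> not decided by e-value rule
        pair = BestHitPair("q", _hit(e_value=0.0, bits=400), _hit(e_value=0.0, bits=100))
        assert classify_contig(pair).value is Label.NOT_CLEAR

    def test_zero_vs_small_uses_floor(self):
        pair = BestHitPair("q", _hit(e_value=0.0, bits=400), _hit(e_value=1e-100, bits=100))
        assert classify_contig(pair).value is Label.TARGET

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10**9))
    def test_symmetry_under_database_swap(self, seed):
        r = random.Random(seed)

        def rand_hit():
            if r.random() < 0.15:
                return None
            return _hit(e_value=10.0 ** -r.uniform(0, 180), bits=r.uniform(30, 500))

        t, c = rand_hit(), rand_hit()
        lab = classify_contig(BestHitPair("q", t, c)).value
        swapped = classify_contig(BestHitPair("q", c, t)).value
        expected = {
            Label.TARGET: Label.CONTAMINATION,
            Label.CONTAMINATION: Label.TARGET,
            Label.NOT_CLEAR: Label.NOT_CLEAR,
        }[lab]
        assert swapped is expected

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10**9), st.floats(1.01, 10.0), st.floats(1.01, 3.0))
    def test_raising_folds_only_undecides(self, seed, efold_mult, bfold_mult):
        r = random.Random(seed)
        t = _hit(e_value=10.0 ** -r.uniform(0, 150), bits=r.uniform(30, 500))
        c = _hit(e_value=10.0 ** -r.uniform(0, 150), bits=r.uniform(30, 500))
        pair = BestHitPair("q", t, c)
        base = ClassifierParams()
        strict = ClassifierParams(
            evalue_fold=base.evalue_fold * efold_mult,
            bitscore_fold=base.bitscore_fold * bfold_mult,
        )
        before = classify_contig(pair, base).value
        after = classify_contig(pair, strict).value
        if before is Label.NOT_CLEAR:
            assert after is Label.NOT_CLEAR
        else:
            assert after in (before, Label.NOT_CLEAR)


class TestGcPartition:
    def _contig(self, cid, gc, length=1000):
        n_gc = int(round(gc * length))
        return Contig(cid, "G" * n_gc + "A" * (length - n_gc))

    def test_low_gc_routed_to_target(self):
        labels = gc_partition([self._contig("a", 0.35)], GcPartitionParams(0.3903))
        assert labels["a"].value is Label.TARGET

    def test_high_gc_routed_to_contamination(self):
        labels = gc_partition([self._contig("a", 0.55)], GcPartitionParams(0.3903))
        assert labels["a"].value is Label.CONTAMINATION

    def test_boundary_inclusive_low_side(self):
        c = Contig("a", "GC" + "AT" * 49 + "AT")  # gc exactly computable
        cutoff = c.gc
        labels = gc_partition([c], GcPartitionParams(cutoff))
        assert labels["a"].value is Label.TARGET

    def test_undefined_gc_defaults_to_contamination_with_warning(self):
        warnings = []
        labels = gc_partition([Contig("a", "NNNN")], GcPartitionParams(0.4), warnings)
        assert labels["a"].value is Label.CONTAMINATION
        assert warnings and "undefined GC" in warnings[0]

    def test_auto_with_few_contigs_refuses(self):
        with pytest.raises(ValueError, match=">= 20"):
            gc_partition([self._contig("a", 0.3)], GcPartitionParams("auto"))

    def test_presets_match_published_cutoffs(self):
        assert PRESET_GC_CUTOFFS["b_plumatellae"] == pytest.approx(0.3903)
        assert PRESET_GC_CUTOFFS["t_bryosalmonae_fish"] == pytest.approx(0.4080)
        assert PRESET_GC_CUTOFFS["t_bryosalmonae_bryozoan"] == pytest.approx(0.3692)


class TestEstimateGcCutoff:
    def test_two_mode_mixture(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(0.28, 0.03, 500), rng.normal(0.55, 0.04, 500)])
        est = estimate_gc_cutoff(vals)
        assert 0.35 < est.cutoff < 0.48
        assert est.method == "kde_valley"
        # by construction the misclassification-minimizing boundary lies
        # between the modes: a brute-force threshold sweep agrees
        grid = np.arange(0.30, 0.55, 0.002)
        errs = [np.sum(vals[:500] > t) + np.sum(vals[500:] <= t) for t in grid]
        best = grid[int(np.argmin(errs))]
        assert abs(est.cutoff - best) < 0.06

    def test_unimodal_is_error(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0.28, 0.01, 200)
        with pytest.raises(UnimodalGcError):
            estimate_gc_cutoff(vals)

    def test_identical_values_is_error(self):
        with pytest.raises(UnimodalGcError):
            estimate_gc_cutoff([0.28] * 50)

    def test_point_masses_cutoff_between(self):
        est = estimate_gc_cutoff([0.25] * 30 + [0.60] * 30)
        assert 0.25 < est.cutoff < 0.60

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 20"):
            estimate_gc_cutoff([0.2, 0.6] * 5)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(0.28, 0.03, 300), rng.normal(0.55, 0.04, 300)])
        assert estimate_gc_cutoff(vals).cutoff == estimate_gc_cutoff(vals).cutoff


class TestPipeline:
    def test_all_target_hits_conserved(self):
        contigs = [Contig(f"c{i}", "ACGT" * 100) for i in range(10)]
        hits = [
            HitRecord(f"c{i}", "t", 95.0, 100, 0, 0, 1, 100, 1, 100, 1e-80, 300.0)
            for i in range(10)
        ]
        res = run_decontam_pipeline(contigs, hits, [], gc_params=GcPartitionParams(0.39))
        assert res.counts["target"] == 10
        assert res.counts["contamination"] == 0
        assert res.counts["not_clear_resolved"] == 0

    def test_empty_hit_tables_gc_rescue(self):
        contigs = [Contig(f"c{i}", "GC" * 28 + "AT" * 72) for i in range(10)]  # gc=0.28
        res = run_decontam_pipeline(contigs, [], [], gc_params=GcPartitionParams(0.39))
        assert res.counts["target"] == 10
        assert res.counts["not_clear_resolved"] == 10

    def test_label_counts_sum_to_input(self):
        params = SimParams(seed=3, n_target=150, n_contam=150, p_no_hit=0.3)
        contigs = simulate_assembly(params)
        t, c = simulate_hits(contigs, params)
        res = run_decontam_pipeline(contigs, t, c, gc_params=GcPartitionParams(0.39))
        assert res.counts["target"] + res.counts["contamination"] == len(contigs)

    def test_stray_query_warns_not_fatal(self):
        contigs = [Contig("c0", "ACGT" * 100)]
        stray = HitRecord("ghost", "t", 95.0, 100, 0, 0, 1, 100, 1, 100, 1e-80, 300.0)
        res = run_decontam_pipeline(
            contigs, [stray], [], gc_params=GcPartitionParams(0.39)
        )
        assert any("ghost" in w for w in res.warnings)

    def test_host_stage_excludes(self):
        contigs = [Contig("c0", "ACGT" * 100), Contig("c1", "ACGT" * 100)]
        host = [HitRecord("c0", "fish", 99.0, 100, 0, 0, 1, 100, 1, 100, 1e-120, 400.0)]
        t = [HitRecord(f"c{i}", "t", 95.0, 100, 0, 0, 1, 100, 1, 100, 1e-80, 300.0)
             for i in range(2)]
        res = run_decontam_pipeline(
            contigs, t, [], host_records=host, gc_params=GcPartitionParams(0.39)
        )
        assert res.counts["host_excluded"] == 1 and res.counts["target"] == 1

    def test_report_is_deterministic(self, tmp_path):
        params = SimParams(seed=4, n_target=40, n_contam=40)
        contigs = simulate_assembly(params)
        t, c = simulate_hits(contigs, params)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_decontam_pipeline(contigs, t, c, gc_params=GcPartitionParams(0.39), out_dir=out1)
        run_decontam_pipeline(contigs, t, c, gc_params=GcPartitionParams(0.39), out_dir=out2)
        for name in ("classification_report.tsv", "target_contigs.fasta"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_classifier_recovery_on_synthetic(self):
        params = SimParams(seed=5, n_target=300, n_contam=300,
                           sep_evalue=1e4, sep_bitscore=2.0)
        contigs = simulate_assembly(params)
        t, c = simulate_hits(contigs, params)
        res = run_decontam_pipeline(contigs, t, c, gc_params=GcPartitionParams(0.39))
        truth = {x.id: x.truth_label for x in contigs}
        correct = sum(
            1 for row in res.rows
            if row["rule"] == "fold_rule"
            and row["label"] == ("target" if truth[row["contig_id"]] == "target"
                                 else "contamination")
        )
        with_hits = sum(1 for row in res.rows if row["rule"] != "no_hits")
        assert correct / with_hits >= 0.99
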