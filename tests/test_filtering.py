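"""Filtering cascades: gate semantics, PoN, traces, full recovery."""

import random

import pytest

from somatic_screen.filtering import (
    AnnotationMissingError,
    FilterParams,
    build_pon,
    context_is_unique,
    rna_concordant,
    targeted_filter,
    wes_discovery_filter,
)
from somatic_screen.io_model import AnnotationRecord, GenomicPosition, VariantCall


def _call(sample, pos, depth, alt_reads, ref="C", alt="T", quality=True):
    gp = GenomicPosition("toy1", pos, ref, alt)
    return VariantCall.from_counts(sample, gp, depth, alt_reads, quality)


def _ann(call, **kw):
    defaults = dict(
        gene="FAT1",
        effect="missense",
        in_cosmic=True,
        predictor_calls=tuple("DDDDDTTTT"),
    )
    defaults.update(kw)
    return AnnotationRecord(position=call.position, **defaults)


EMPTY_PON = build_pon([[_call("N0", 999_999, 100, 5)]])  # single unrelated key


class TestPanelOfNormals:
    def test_membership_requires_two_supporting_reads(self):
        tables = [
            [_call("N1", 100, 80, 3)],  # present: 3 reads
            [_call("N2", 200, 80, 1)],  # below threshold
            [_call("N3", 300, 80, 0)],  # reference-only coverage row
        ]
        pon = build_pon(tables)
        assert ("toy1", 100, "C", "T") in pon
        assert ("toy1", 200, "C", "T") not in pon
        assert ("toy1", 300, "C", "T") not in pon

    @pytest.mark.parametrize("threshold", [1, 2])
    def test_matches_brute_force_union(self, threshold):
        rng = random.Random(3)
        tables = [
            [
                _call(f"N{i}", rng.randrange(1, 50), 60, rng.randrange(0, 5))
                for _ in range(30)
            ]
            for i in range(8)
        ]
        pon = build_pon(tables, min_alt_reads=threshold)
        brute = {
            c.key for table in tables for c in table if c.alt_reads >= threshold
        }
        assert pon.keys == brute

    def test_order_invariant_and_idempotent(self):
        rng = random.Random(5)
        tables = [
            [_call(f"N{i}", rng.randrange(1, 30), 50, rng.randrange(0, 6))
             for _ in range(20)]
            for i in range(5)
        ]
        forward = build_pon(tables)
        reversed_ = build_pon(list(reversed(tables)))
        assert forward.keys == reversed_.keys
        assert forward.provenance == reversed_.provenance
        assert build_pon(tables).keys == forward.keys

    def test_zero_tables_rejected(self):
        with pytest.raises(ValueError):
            build_pon([])


class TestWesDiscoveryFilter:
    def test_paired_clean_somatic_retained(self):
        tumor = _call("T1", 100, 50, 15)  # vaf 0.30
        normal = _call("N1", 100, 40, 0)
        trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON,
                                     matched_normal_call=normal)
        assert trace.final_verdict == "retained"
        assert trace.rejecting_gate is None

    def test_tumor_depth_nine_rejected_at_depth_gate(self):
        tumor = _call("T1", 100, 9, 3)
        normal = _call("N1", 100, 40, 0)
        trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON,
                                     matched_normal_call=normal)
        assert trace.rejecting_gate == "depth"

    def test_unpaired_depth_exactly_20_rejected(self):
        # tumor-only calling demands depth strictly above 20
        tumor = _call("T1", 100, 20, 6)  # vaf 0.30
        trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON)
        assert trace.rejecting_gate == "vaf"
        retained = wes_discovery_filter(_call("T1", 100, 21, 6),
                                        _ann(_call("T1", 100, 21, 6)), EMPTY_PON)
        assert retained.final_verdict == "retained"

    def test_strict_inequalities_match_brute_force(self):
        # 100 random unpaired calls around the thresholds: the cascade's
        # depth/VAF gate must equal the literal strict predicate.
        rng = random.Random(17)
        params = FilterParams()
        for _ in range(100):
            depth = rng.randrange(15, 26)
            alt = rng.randrange(0, depth + 1)
            tumor = _call("T1", 100, depth, alt)
            trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON)
            gate = {g.name: g.passed for g in trace.gates}["vaf"]
            assert gate == (depth > 20 and alt / depth > 0.25)
            assert gate == (
                tumor.depth > params.wes_unpaired_depth
                and tumor.vaf > params.wes_unpaired_vaf
            )

    def test_paired_normal_contamination_rejected(self):
        tumor = _call("T1", 100, 50, 20)
        normal = _call("N1", 100, 40, 2)  # normal vaf 0.05 >= 0.03
        trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON,
                                     matched_normal_call=normal)
        assert trace.rejecting_gate == "vaf"

    def test_pon_membership_rejects(self):
        tumor = _call("T1", 100, 50, 20)
        pon = build_pon([[_call("P1", 100, 60, 5)]])
        trace = wes_discovery_filter(tumor, _ann(tumor), pon)
        assert trace.rejecting_gate == "pon"

    def test_dbsnp_without_cosmic_rejected_cosmic_rescues(self):
        tumor = _call("T1", 100, 50, 20)
        germline_ann = _ann(tumor, in_dbsnp=True, kg_af=0.2, in_cosmic=False)
        trace = wes_discovery_filter(tumor, germline_ann, EMPTY_PON)
        assert trace.rejecting_gate == "germline_db"
        rescued_ann = _ann(tumor, in_dbsnp=True, kg_af=0.2, in_cosmic=True)
        rescued = wes_discovery_filter(tumor, rescued_ann, EMPTY_PON)
        assert rescued.final_verdict == "retained"

    def test_rna_concordance_gate_only_for_rna_samples(self):
        tumor = _call("T1", 100, 50, 20)
        # no RNA evidence at the key
        trace = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON,
                                     rna_table=[], has_rna=True)
        assert trace.rejecting_gate == "rna_concordance"
        no_rna = wes_discovery_filter(tumor, _ann(tumor), EMPTY_PON, has_rna=False)
        assert no_rna.final_verdict == "retained"

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(AnnotationMissingError):
            wes_discovery_filter(_call("T1", 100, 50, 20), None, EMPTY_PON)


class TestTargetedFilter:
    def test_inclusive_boundaries_retained(self):
        # exactly 10% VAF with exactly 3 variant reads passes
        tumor = _call("T1", 100, 30, 3)
        trace = targeted_filter(tumor, _ann(tumor), EMPTY_PON)
        assert trace.final_verdict == "retained"

    @pytest.mark.parametrize(
        "depth,alt,gate",
        [(20, 2, "alt_reads"), (50, 4, "vaf")],
    )
    def test_below_boundaries_rejected(self, depth, alt, gate):
        tumor = _call("T1", 100, depth, alt)
        trace = targeted_filter(tumor, _ann(tumor), EMPTY_PON)
        assert trace.rejecting_gate == gate

    def test_intronic_distance_boundary(self):
        tumor = _call("T1", 100, 60, 12)
        far = targeted_filter(tumor, _ann(tumor, effect="intronic", dist_to_cds=3),
                              EMPTY_PON)
        assert far.rejecting_gate == "effect"
        near = targeted_filter(tumor, _ann(tumor, effect="intronic", dist_to_cds=2),
                               EMPTY_PON)
        assert near.final_verdict == "retained"

    def test_synonymous_rejected_even_in_cosmic(self):
        tumor = _call("T1", 100, 60, 12)
        trace = targeted_filter(tumor, _ann(tumor, effect="synonymous"), EMPTY_PON)
        assert trace.rejecting_gate == "effect"

    def test_population_af_above_one_percent_rejected(self):
        tumor = _call("T1", 100, 60, 12)
        trace = targeted_filter(tumor, _ann(tumor, kg_af=0.011), EMPTY_PON)
        assert trace.rejecting_gate == "kg_af"

    def test_control_subtraction_rejects(self):
        tumor = _call("T1", 100, 60, 12)
        controls = build_pon([[_call("H1", 100, 80, 4)]])
        trace = targeted_filter(tumor, _ann(tumor), controls)
        assert trace.rejecting_gate == "controls"

    def test_caller_quality_gate(self):
        tumor = _call("T1", 100, 60, 12, quality=False)
        trace = targeted_filter(tumor, _ann(tumor), EMPTY_PON)
        assert trace.rejecting_gate == "call_quality"


class TestRnaConcordance:
    def test_threshold_semantics(self):
        key = ("toy1", 100, "C", "T")
        assert rna_concordant(key, [_call("T1", 100, 40, 5)])
        assert not rna_concordant(key, [_call("T1", 100, 40, 1)])
        assert not rna_concordant(key, [])
        assert not rna_concordant(key, [_call("T1", 200, 40, 5)])


class TestContextUniqueness:
    REF = {"toy1": "ACGT" * 60}  # 240 bp, heavily repetitive

    def test_unique_context_true(self):
        import random as _r

        rng = _r.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        ctx = seq[100:141]
        assert context_is_unique(ctx, seq)

    def test_duplicated_context_false(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        ctx = seq[100:141]
        assert not context_is_unique(ctx, seq + "TTTT" + ctx)

    def test_reverse_complement_hit_counts(self):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        ctx = seq[50:91]
        rc = ctx.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert not context_is_unique(ctx, seq + "AA" + rc)

    def test_wrong_length_is_error(self):
        with pytest.raises(ValueError):
            context_is_unique("ACGT", self.REF)


class TestCohortRecovery:
    """Backbone property: the cascades recover exactly the planted truth."""

    def test_wes_full_recovery(self, bundle, wes_result):
        truth = bundle.truth
        for sid, retained in wes_result.retained.items():
            got = {c.key for c, _ in retained}
            want = set(truth.somatic_by_sample[sid])
            assert got == want, f"{sid}: retained set differs from planted somatic"

    def test_targeted_full_recovery(self, bundle, targeted_result):
        truth = bundle.truth
        panel = set(bundle.profile.panel_genes)
        for sid, retained in targeted_result.retained.items():
            got = {c.key for c, _ in retained}
            want = {
                k
                for k in truth.somatic_by_sample[sid]
                if bundle.annotations[k].gene in panel
            }
            assert got == want

    def test_no_contaminant_survives_either_cascade(self, bundle, wes_result,
                                                    targeted_result):
        truth = bundle.truth
        for result in (wes_result, targeted_result):
            for sid, retained in result.retained.items():
                for call, _ in retained:
                    assert truth.label(sid, call.key) == "somatic"

    def test_monotone_and_trace_sound(self, wes_result, targeted_result):
        for result in (wes_result, targeted_result):
            assert result.n_retained <= result.n_input
            for sid, traces in result.traces.items():
                retained_keys = {c.key for c, _ in result.retained[sid]}
                for trace in traces:
                    replayed = all(g.passed for g in trace.gates)
                    assert replayed == (trace.final_verdict == "retained")
                    assert (trace.key in retained_keys) == trace.retained
                    if not trace.retained:
                        assert trace.rejecting_gate == next(
                            g.name for g in trace.gates if not g.passed
                        )

    def test_duplicated_context_artifacts_fail_context_gate(self, bundle, wes_result):
        # the generator copies the first few artifact contexts to a
        # second locus; any discovery tumor carrying one must show a
        # failed context gate in its trace
        from somatic_screen.synthetic_cohort import SPARE_REGION_START

        n_dup = bundle.profile.n_context_duplicated
        # duplicated contexts were copied into the spare reference region
        spare = bundle.reference["toy1"][SPARE_REGION_START:]
        dup_contexts = {
            ann.context41
            for ann in bundle.annotations.values()
            if ann.position.pos < SPARE_REGION_START and ann.context41 in spare
        }
        assert len(dup_contexts) == n_dup
        for ctx in dup_contexts:
            assert not context_is_unique(ctx, bundle.reference)
        seen = 0
        for sid, traces in wes_result.traces.items():
            for trace in traces:
                ann = bundle.annotations[trace.key]
                if ann.context41 in dup_contexts:
                    gate = {g.name: g.passed for g in trace.gates}["context_unique"]
                    assert not gate
                    seen += 1
        assert seen > 0
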