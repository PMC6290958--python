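"""Targeted aligner and calling rules, checked against an independent
unbanded affine-gap dynamic program and against simulator ground truth."""

import numpy as np
import pytest

from npm1mrd import (
    AmpliconAligner,
    InsertionSpec,
    SimConfig,
    align_read,
    apply_insertion,
    call_sample,
    left_normalize,
    merge_pairs,
    parse_hgvs_ins,
    simulate_run,
    simulate_sample,
    verify_bioinformatics_control,
    demultiplex,
    default_index_pairs,
)
from npm1mrd.insertion_caller import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH

NEG = float("-inf")


def gotoh_score(ref: str, read: str) -> float:
    """Unbanded global affine-gap alignment score, independent of the
    implementation under test.  A gap of length L costs -(6 + L)."""
    n, m = len(ref), len(read)
    open_cost = GAP_OPEN + GAP_EXTEND  # first gapped base
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in read (deletion)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_cost + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = open_cost + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if ref[i - 1] == read[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(
                M[i - 1][j] + open_cost,
                Iy[i - 1][j] + open_cost,
                Ix[i - 1][j] + GAP_EXTEND,
            )
            Iy[i][j] = max(
                M[i][j - 1] + open_cost,
                Ix[i][j - 1] + open_cost,
                Iy[i][j - 1] + GAP_EXTEND,
            )
    return max(M[n][m], Ix[n][m], Iy[n][m])


def _mutate(seq, rng, n_sub=0, ins_len=0, del_len=0):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = "ACGT"[(("ACGT".index(s[pos])) + rng.integers(1, 4)) % 4]
    s = "".join(s)
    if del_len:
        start = int(rng.integers(0, len(s) - del_len))
        s = s[:start] + s[start + del_len :]
    if ins_len:
        start = int(rng.integers(1, len(s)))
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, ins_len))
        s = s[:start] + ins + s[start:]
    return s


class TestAlignRead:
    def test_reference_read_is_clean(self, ref):
        aln = align_read(ref.sequence, ref)
        assert aln.insertions == ()
        assert aln.n_mismatches == 0
        assert aln.ref_span == (0, len(ref))
        assert not aln.unalignable

    def test_published_gcca_insertion_recovered(self, ref):
        spec = parse_hgvs_ins("c.873_874insGCCA", ref)
        aln = align_read(apply_insertion(spec, ref), ref)
        assert len(aln.insertions) == 1
        assert aln.insertions[0] == left_normalize(spec, ref)
        assert aln.insertions[0].inserted == "GCCA"

    def test_random_single_insertions_recovered_exactly(self, ref, rng):
        aligner = AmpliconAligner(ref)
        n_cases = 1000
        for _ in range(n_cases):
            pos = int(rng.integers(1, len(ref) - 1))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 9)))
            truth = left_normalize(InsertionSpec(pos, ins), ref)
            aln = aligner.align(apply_insertion(truth, ref))
            assert aln.insertions == (truth,)
            assert aln.n_mismatches == 0

    def test_matches_unbanded_dp_oracle_on_short_amplicons(
        self, rng, tiny_ref_factory
    ):
        for case in range(60):
            L = int(rng.integers(40, 61))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
            tiny = tiny_ref_factory(seq)
            read = _mutate(
                seq, rng,
                n_sub=int(rng.integers(0, 4)),
                ins_len=int(rng.integers(0, 7)),
                del_len=int(rng.integers(0, 4)),
            )
            aligner = AmpliconAligner(tiny, fast_path=False)
            got = aligner.align(read)
            if not got.unalignable:
                assert got.score == gotoh_score(seq, read), (seq, read)

    def test_fast_path_bit_identical_to_full_alignment(self, ref, type_a):
        cfg = SimConfig(
            sample_id="fp", seed=77, n_fragments=3000, mutant_fraction=0.05,
            mutation=type_a, sub_error_rate=2e-3, indel_error_rate=1e-4,
        )
        r1, r2, _ = simulate_sample(cfg, ref)
        sequences = {m.sequence for m in merge_pairs(zip(r1, r2))}
        fast = AmpliconAligner(ref, fast_path=True)
        slow = AmpliconAligner(ref, fast_path=False)
        for seq in sequences:
            assert fast.align(seq) == slow.align(seq)

    def test_garbage_read_is_unalignable(self, ref, rng):
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, len(ref)))
        aln = align_read(junk, ref)
        assert aln.unalignable

    def test_length_outside_half_amplicon_is_unalignable(self, ref):
        assert align_read(ref.sequence[:100], ref).unalignable


class TestCallSample:
    def _reads(self, ref, spec, n_mut, n_wt):
        return [apply_insertion(spec, ref)] * n_mut + [ref.sequence] * n_wt

    def test_single_supporting_read_reported_but_not_passed(self, ref, catalog, type_a):
        result = call_sample(self._reads(ref, type_a, 1, 999), ref, catalog)
        (call,) = result.calls
        assert call.supporting_reads == 1
        assert not call.passed

    @pytest.mark.parametrize("n_mut,expect_pass", [(1, False), (2, True), (3, True)])
    def test_two_mutant_reads_are_the_calling_threshold(
        self, ref, catalog, type_a, n_mut, expect_pass
    ):
        result = call_sample(self._reads(ref, type_a, n_mut, 500), ref, catalog)
        assert result.calls[0].passed is expect_pass

    def test_no_mutants_gives_empty_call_list(self, ref, catalog, type_a):
        result = call_sample([ref.sequence] * 100, ref, catalog)
        assert result.calls == []
        assert result.vaf_of(type_a) == 0.0

    def test_vaf_is_exact_count_ratio(self, ref, catalog, type_a):
        result = call_sample(self._reads(ref, type_a, 200, 9800), ref, catalog)
        (call,) = result.pass_calls()
        assert call.vaf == 0.02
        assert call.depth == 10_000
        assert call.label == "type A"

    def test_raising_threshold_never_flips_fail_to_pass(self, ref, catalog, type_a):
        reads = self._reads(ref, type_a, 2, 500)
        loose = call_sample(reads, ref, catalog, min_mutant_reads=2)
        strict = call_sample(reads, ref, catalog, min_mutant_reads=3)
        passed_loose = {c.spec for c in loose.pass_calls()}
        passed_strict = {c.spec for c in strict.pass_calls()}
        assert passed_strict <= passed_loose

    def test_read_conservation(self, ref, catalog, type_a):
        cfg = SimConfig(
            sample_id="c", seed=55, n_fragments=4000, mutant_fraction=0.03,
            mutation=type_a, sub_error_rate=1e-3, indel_error_rate=0.0,
        )
        r1, r2, _ = simulate_sample(cfg, ref)
        merged = list(merge_pairs(zip(r1, r2)))
        result = call_sample(merged, ref, catalog)
        supporting = sum(c.supporting_reads for c in result.calls)
        assert result.n_input == len(merged)
        assert supporting + result.n_wildtype + result.n_unalignable == result.n_input

    def test_empty_input_flags_no_coverage(self, ref, catalog):
        result = call_sample([], ref, catalog)
        assert result.no_coverage
        assert result.calls == []

    def test_multiple_distinct_insertions_all_reported(self, ref, catalog, type_a):
        other = catalog.spec_for("insGCCA")
        reads = (
            self._reads(ref, type_a, 5, 0)
            + [apply_insertion(other, ref)] * 3
            + [ref.sequence] * 92
        )
        result = call_sample(reads, ref, catalog)
        labels = {c.label for c in result.pass_calls()}
        assert labels == {"type A", "insGCCA"}
        # sorted by VAF descending
        assert result.calls[0].label == "type A"


class TestBioinformaticsControl:
    def _run_and_call(self, ref, catalog, type_a, include_control=True):
        pairs = default_index_pairs(1)
        cfgs = [
            SimConfig(
                sample_id="s0", seed=404, n_fragments=400, mutant_fraction=0.05,
                mutation=type_a, sub_error_rate=0.0, indel_error_rate=0.0,
                index_pair=pairs[0],
            )
        ]
        r1, r2, sheet, _ = simulate_run(
            cfgs, ref, include_bioinf_control=include_control, control_reads=200
        )
        demuxed = demultiplex(r1, r2, sheet)
        results = {}
        for sid, (s1, s2) in demuxed.by_sample.items():
            merged = merge_pairs(zip(s1, s2))
            results[sid] = call_sample(merged, ref, catalog, sample_id=sid)
        return results

    def test_control_run_passes_with_20nt_insertion(self, ref, catalog, type_a):
        results = self._run_and_call(ref, catalog, type_a)
        verdict = verify_bioinformatics_control(results, ref)
        assert verdict.passed
        assert len(verdict.call.spec.inserted) == 20

    def test_missing_control_fails(self, ref, catalog, type_a):
        results = self._run_and_call(ref, catalog, type_a, include_control=False)
        verdict = verify_bioinformatics_control(results, ref)
        assert not verdict.passed
        assert "missing" in verdict.detail

    def test_corrupted_control_below_threshold_fails(self, ref, catalog, type_a):
        from npm1mrd import CONTROL_SAMPLE_ID
        from npm1mrd.readsim import control_insertion

        ctrl = apply_insertion(control_insertion(ref), ref)
        weak = call_sample(
            [ctrl] * 1 + [ref.sequence] * 200, ref, catalog,
            sample_id=CONTROL_SAMPLE_ID,
        )
        verdict = verify_bioinformatics_control({CONTROL_SAMPLE_ID: weak}, ref)
        assert not verdict.passed
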