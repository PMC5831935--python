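"""Duplex geometry, Dicer-pattern classification and acceptance criteria."""

import dataclasses
import random

import numpy as np
import pytest
from hypothesis import given, settings, HealthCheck
from hypothesis import strategies as st

from premirseq.datasets import okra_known_mirnas
from premirseq.hairpin_folding import fold
from premirseq.precursor_validation import (
    LoopRegionError, PrecursorCandidate, ValidationConfig, check_dicer_pattern,
    dedupe_variants, locate_duplex, validate,
)
from premirseq.read_mapping import Placement, build_profile
from premirseq.synthetic_data import make_loop_decoy, make_precursor


def _profile_for(truth, mature_count=30, star_count=10, extra=()):
    """Read profile with clusters at the planted mature/star positions."""
    pls = []
    ms, me = truth.mature_interval
    pls.append(Placement(truth.seq[ms:me], mature_count, truth.precursor_id, ms, me))
    if star_count:
        ss, se = truth.star_interval
        pls.append(Placement(truth.seq[ss:se], star_count, truth.precursor_id, ss, se))
    for start, n, count in extra:
        pls.append(Placement(truth.seq[start:start + n], count,
                             truth.precursor_id, start, start + n))
    return build_profile(truth.precursor_id, truth.seq, pls)


def _candidate(truth, label="novel", **profile_kw):
    structure = fold(truth.seq)
    try:
        duplex = locate_duplex(structure, truth.mature_interval)
    except LoopRegionError:
        duplex = None
    return PrecursorCandidate(
        long_id=truth.precursor_id, seq=truth.seq, structure=structure,
        profile=_profile_for(truth, **profile_kw), duplex=duplex, label=label,
    )


class TestLocateDuplex:
    def test_perfect_stem_has_clean_duplex(self, rng):
        t = make_precursor(rng, n_mismatches=0, precursor_id="perfect")
        d = locate_duplex(fold(t.seq), t.mature_interval)
        assert d.n_mismatches == 0
        assert d.bulges == ()
        assert d.arm == "5p"
        assert d.star_interval == t.star_interval
        assert (d.overhang3_mature, d.overhang3_star) == (2, 2)

    def test_three_prime_arm_geometry(self, rng):
        t = make_precursor(rng, arm="3p", precursor_id="threep")
        d = locate_duplex(fold(t.seq), t.mature_interval)
        assert d.arm == "3p"
        assert abs(d.star_interval[0] - t.star_interval[0]) <= 1
        assert abs(d.overhang3_mature - 2) <= 1
        assert abs(d.overhang3_star - 2) <= 1

    def test_planted_bulge_recovered(self, rng):
        t = make_precursor(rng, bulge_spec=[("mature", 2)], precursor_id="bulged")
        d = locate_duplex(fold(t.seq), t.mature_interval)
        assert ("mature", 2) in d.bulges

    def test_mature_across_loop_is_discard_error(self, rng):
        t = make_loop_decoy(rng)
        with pytest.raises(LoopRegionError):
            locate_duplex(fold(t.seq), t.mature_interval)

    def test_interval_outside_sequence_rejected(self, rng):
        t = make_precursor(rng)
        with pytest.raises(ValueError):
            locate_duplex(fold(t.seq), (0, len(t.seq) + 5))


class TestDicerPattern:
    def test_mature_and_star_clusters_give_duplex_support(self, rng):
        t = make_precursor(rng)
        c = _candidate(t, star_count=12)
        assert check_dicer_pattern(c.profile, c.duplex, ValidationConfig()) \
            == "duplex-supported"

    def test_mature_only_with_depth_gives_expression_support(self, rng):
        t = make_precursor(rng)
        c = _candidate(t, mature_count=50, star_count=0)
        assert check_dicer_pattern(c.profile, c.duplex, ValidationConfig()) \
            == "expression-supported"

    def test_mature_only_below_depth_floor_fails(self, rng):
        t = make_precursor(rng)
        c = _candidate(t, mature_count=3, star_count=0)
        assert check_dicer_pattern(c.profile, c.duplex, ValidationConfig()) == "fail"

    def test_loop_reads_only_fail(self, rng):
        t = make_precursor(rng, loop_len=16, ext_len=8)
        structure = fold(t.seq)
        duplex = locate_duplex(structure, t.mature_interval)
        lo, hi = structure.terminal_loops()[0]
        start = max(0, lo - 5)
        prof = build_profile(
            t.precursor_id, t.seq,
            [Placement(t.seq[start:start + 20], 40, t.precursor_id, start, start + 20)],
        )
        assert check_dicer_pattern(prof, duplex, ValidationConfig()) == "fail"


class TestValidate:
    def test_well_formed_precursor_accepted(self, rng):
        t = make_precursor(rng)
        c = validate(_candidate(t))
        assert c.accepted, c.failed_criteria()
        assert c.confidence == "duplex-supported"

    def test_excess_mismatches_rejected_on_mismatch_flags(self, rng):
        for _ in range(5):
            t = make_precursor(rng, n_mismatches=6, mature_len=24)
            c = validate(_candidate(t))
            if c.duplex is not None and c.duplex.n_mismatches > 4:
                assert not c.accepted
                assert not c.criteria_flags["duplex_mismatches"]
                return
        pytest.skip("fold absorbed every planted-defect draw")

    def test_every_rejection_names_a_criterion(self, rng):
        for kind in range(4):
            t = (make_loop_decoy(rng) if kind == 0 else
                 make_precursor(rng, n_mismatches=[0, 5, 0, 0][kind],
                                bulge_spec=[(), (), [("star", 5)], ()][kind],
                                mature_len=23))
            c = validate(_candidate(t))
            if not c.accepted:
                assert c.failed_criteria()

    def test_known_candidate_waives_mfei_filter(self):
        """A known-family precursor with MFEI above the novel threshold is
        reported but not filtered (e.g. bundled miR6300, MFEI -0.670)."""
        df = okra_known_mirnas()
        row = df[df.mirna_id == "miR6300"].iloc[0]
        seq, mat = row.precursor_seq, row.mature_seq
        pos = seq.find(mat)
        structure = fold(seq)
        duplex = locate_duplex(structure, (pos, pos + len(mat)))
        ss, se = duplex.star_interval
        prof = build_profile("miR6300", seq, [
            Placement(seq[pos:pos + len(mat)], 40, "miR6300", pos, pos + len(mat)),
            Placement(seq[ss:se], 11, "miR6300", ss, se),
        ])
        base = PrecursorCandidate(
            long_id="miR6300", seq=seq, structure=structure, profile=prof,
            duplex=duplex,
        )
        assert -0.70 < structure.mfei < -0.60
        known = validate(dataclasses.replace(base, label="known:miR6300"))
        assert known.accepted, known.failed_criteria()
        novel = validate(dataclasses.replace(base, label="novel"))
        assert not novel.accepted
        assert novel.failed_criteria() == ["mfei"]

    def test_length_window_flag(self, rng):
        t = make_precursor(rng)
        cfg = ValidationConfig(min_len=100, max_len=241)
        c = validate(_candidate(t), cfg)
        if len(t.seq) < 100:
            assert not c.criteria_flags["length"]


class TestMonotonicity:
    """Tightening any threshold never enlarges the accepted set."""

    POOL = None

    @classmethod
    def _pool(cls):
        if cls.POOL is None:
            rng = np.random.default_rng(77)
            pool = []
            for i in range(14):
                kw = {}
                if i % 4 == 1:
                    kw["n_mismatches"] = int(rng.integers(0, 6))
                if i % 4 == 2:
                    kw["bulge_spec"] = [("star", int(rng.integers(1, 5)))]
                t = make_precursor(rng, mature_len=22, precursor_id=f"M{i}", **kw)
                star = int(rng.integers(0, 14))
                pool.append(_candidate(t, mature_count=int(rng.integers(2, 40)),
                                       star_count=star))
            cls.POOL = pool
        return cls.POOL

    @given(
        field=st.sampled_from([
            ("max_duplex_mismatches", -1), ("max_bulge_len", -1),
            ("mfei_max", -0.3), ("min_len", +30), ("max_len", -120),
            ("overhang_tol", -1), ("min_mature_count", +20),
            ("cluster_start_tol", -1),
        ]),
        base_kw=st.fixed_dictionaries({
            "max_duplex_mismatches": st.integers(1, 6),
            "max_bulge_len": st.integers(1, 5),
            "mfei_max": st.floats(-1.2, -0.3),
            "min_mature_count": st.integers(1, 30),
            "overhang_tol": st.integers(0, 2),
            "cluster_start_tol": st.integers(0, 2),
        }),
    )
    @settings(deadline=None, max_examples=40,
              suppress_health_check=[HealthCheck.too_slow])
    def test_tightening_shrinks_accepted_set(self, field, base_kw):
        name, delta = field
        base = ValidationConfig(**base_kw)
        tight_kw = dataclasses.asdict(base)
        tight_kw[name] = tight_kw[name] + delta
        if name in ("max_duplex_mismatches", "max_bulge_len", "overhang_tol",
                    "cluster_start_tol"):
            tight_kw[name] = max(0, tight_kw[name])
        tight = ValidationConfig(**tight_kw)
        pool = self._pool()
        loose_acc = {c.long_id for c in
                     (validate(dataclasses.replace(x), base) for x in pool)
                     if c.accepted}
        tight_acc = {c.long_id for c in
                     (validate(dataclasses.replace(x), tight) for x in pool)
                     if c.accepted}
        assert tight_acc <= loose_acc


class TestDedupe:
    def test_truncation_variant_collapses(self, rng):
        t = make_precursor(rng, ext_len=8, precursor_id="full")
        c_full = _candidate(t)
        trunc = dataclasses.replace(t, seq=t.seq[:-4], precursor_id="trunc")
        c_trunc = _candidate(trunc, star_count=0)  # 3'-truncation loses the star window
        out = dedupe_variants([c_full, c_trunc])
        assert len(out) == 1
        assert out[0].long_id == "full"
        assert out[0].variants == ["trunc"]

    def test_disjoint_sequences_kept(self, rng):
        a = _candidate(make_precursor(rng, precursor_id="a"))
        b = _candidate(make_precursor(rng, precursor_id="b"))
        assert len(dedupe_variants([a, b])) == 2

    def test_variant_groups_count(self, rng):
        reps = []
        for g in range(4):
            t = make_precursor(rng, ext_len=8, precursor_id=f"g{g}")
            reps.append(_candidate(t))
            reps.append(_candidate(dataclasses.replace(
                t, seq=t.seq[:-3], precursor_id=f"g{g}v"), star_count=0))
        assert len(dedupe_variants(reps)) == 4


def test_config_rejects_inverted_window():
    with pytest.raises(ValueError):
        ValidationConfig(min_len=100, max_len=50)
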