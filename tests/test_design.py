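"""Knockout design: transitions, search, verification, infeasibility."""

import numpy as np
import pytest

from cisquant import (
    Background,
    DesignConstraints,
    EnhancerVariant,
    InfeasibilityRecord,
    MotifLibrary,
    MutationPlan,
    PWM,
    Plant,
    ScanConfig,
    SequenceSimConfig,
    apply_plan,
    design_construct,
    design_site_knockout,
    generate_enhancer,
    information_content,
    invert_plan,
    rank_positions,
    scan_sequence,
    transition,
    verify_variant,
)

BG = Background.uniform()


class TestTransition:
    @pytest.mark.parametrize("pair", [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    def test_purine_pyrimidine_partners(self, pair):
        assert transition(pair[0]) == pair[1]

    def test_involution(self):
        for b in "ACGT":
            assert transition(transition(b)) == b

    def test_non_base_rejected(self):
        with pytest.raises(ValueError):
            transition("N")


class TestRankPositions:
    def test_one_hot_ranks_before_uniform(self):
        pwm = PWM(
            "R", "r",
            np.array([[25.0, 100.0], [25.0, 0.0], [25.0, 0.0], [25.0, 0.0]]),
        )
        assert rank_positions(pwm) == [1, 0]

    def test_all_uniform_keeps_original_order(self):
        pwm = PWM("U", "u", np.full((4, 5), 10.0))
        assert rank_positions(pwm) == [0, 1, 2, 3, 4]

    def test_matches_independent_ic_ordering(self):
        rng = np.random.default_rng(5)
        pwm = PWM("X", "x", rng.integers(1, 60, size=(4, 6)).astype(float))
        ic = information_content(pwm)
        expected = sorted(range(6), key=lambda j: (-ic[j], j))
        assert rank_positions(pwm) == expected


class TestApplyPlan:
    def test_empty_plan_is_identity(self):
        plan = MutationPlan(substitutions=())
        assert apply_plan("ACGT", plan) == "ACGT"

    def test_single_substitution(self):
        plan = MutationPlan(substitutions=((3, "A", "G"),))
        assert apply_plan("TTATT", plan) == "TTGTT"

    def test_ref_mismatch_rejected(self):
        plan = MutationPlan(substitutions=((3, "A", "G"),))
        with pytest.raises(ValueError, match="mismatch"):
            apply_plan("TTTTT", plan)

    def test_plan_then_inverse_restores_wildtype(self):
        plan = MutationPlan(substitutions=((1, "T", "C"), (4, "A", "G")))
        seq = "TGCAT"
        assert apply_plan(apply_plan(seq, plan), invert_plan(plan)) == seq

    def test_non_transition_rejected_at_construction(self):
        with pytest.raises(ValueError, match="transition"):
            MutationPlan(substitutions=((1, "A", "C"),))

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            MutationPlan(substitutions=((1, "A", "G"), (1, "A", "G")))


@pytest.fixture(scope="module")
def toy_library(toy_pwm):
    return MotifLibrary.build([toy_pwm], BG, pseudocount=0.0)


class TestSiteKnockout:
    def test_toy_single_substitution(self, toy_library):
        """A -> G at the planted 'AG' lifts the match p above threshold."""
        seq = "T" * 19 + "AG" + "T" * 29
        cfg = ScanConfig(p_threshold=0.1)
        hit = scan_sequence(seq, toy_library.loms["TOY2"], BG, cfg)[0]
        constraints = DesignConstraints(target_motif_ids=["TOY2"], watch_motif_ids=[])
        plan = design_site_knockout(seq, hit, toy_library, constraints, BG, cfg)
        assert isinstance(plan, MutationPlan)
        assert plan.substitutions == ((20, "A", "G"),)
        # the mutated window "GG" has p = 7/16 > 0.1
        variant = apply_plan(seq, plan)
        assert scan_sequence(variant, toy_library.loms["TOY2"], BG, cfg) == []

    def test_absent_hit_rejected(self, toy_library):
        from cisquant import MotifHit

        fake = MotifHit("TOY2", "seq", 5, 6, "+", 1.0, 0.01, "TT")
        constraints = DesignConstraints(target_motif_ids=["TOY2"], watch_motif_ids=[])
        with pytest.raises(ValueError, match="not a current hit"):
            design_site_knockout("T" * 50, fake, toy_library, constraints, BG, ScanConfig(p_threshold=0.1))

    def test_identical_protected_matrix_is_infeasible(self, toy_pwm):
        """A target nested in a protected hit of an identical matrix conflicts."""
        twin = PWM("PROT", "twin", toy_pwm.counts.copy())
        lib = MotifLibrary.build([toy_pwm, twin], BG, pseudocount=0.0)
        seq = "T" * 19 + "AG" + "T" * 29
        cfg = ScanConfig(p_threshold=0.1)
        target_hit = scan_sequence(seq, lib.loms["TOY2"], BG, cfg)[0]
        protected = scan_sequence(seq, lib.loms["PROT"], BG, cfg)
        constraints = DesignConstraints(
            target_motif_ids=["TOY2"], watch_motif_ids=["PROT"], protected_hits=protected
        )
        result = design_site_knockout(seq, target_hit, lib, constraints, BG, cfg)
        assert isinstance(result, InfeasibilityRecord)
        assert any("PROT" in c for c in result.conflicts)


def _plant_layout(library, motif_ids, seed, start=20, gap=18):
    rng = np.random.default_rng(seed)
    pos, plants = start, []
    for m in motif_ids:
        plants.append(Plant(m, pos, strand=str(rng.choice(["+", "-"]))))
        pos += library.pwms[m].width + gap
    return plants


class TestVerifyVariant:
    def _setup(self, library, seed=0):
        plants = _plant_layout(library, ["SYN_ETS", "SYN_FOXA", "SYN_ZIC"], seed)
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=seed), library)
        cfg = ScanConfig(p_threshold=1e-3)
        watch = ["SYN_FOXA", "SYN_ZIC", "SYN_RBPJ", "SYN_BRA", "SYN_FOSJUN"]
        protected = [
            h for m in watch for h in scan_sequence(seq, library.loms[m], BG, cfg)
        ]
        constraints = DesignConstraints(
            target_motif_ids=["SYN_ETS"], watch_motif_ids=watch, protected_hits=protected
        )
        return seq, constraints, cfg

    def test_unmutated_variant_fails_with_all_targets_surviving(self, library):
        seq, constraints, cfg = self._setup(library)
        report = verify_variant(seq, seq, library, constraints, BG, cfg)
        assert not report.passed
        assert len(report.surviving_target_hits) >= 1
        assert report.new_hits == [] and report.lost_target_hits == []

    def test_successful_knockout_verifies_clean(self, library):
        seq, constraints, cfg = self._setup(library, seed=1)
        result = design_construct(seq, constraints, library, BG, cfg)
        assert isinstance(result, EnhancerVariant)
        # independent rescan with a fresh library reproduces the verdict
        from cisquant.synthetic_motifs import demo_library

        fresh = demo_library()
        report = verify_variant(seq, result.sequence, fresh, constraints, BG, cfg)
        assert report.passed
        assert {h.key for h in report.lost_target_hits} == {
            h.key for h in result.report.lost_target_hits
        }

    def test_length_mismatch_rejected(self, library):
        seq, constraints, cfg = self._setup(library)
        with pytest.raises(ValueError, match="length"):
            verify_variant(seq, seq[:-1], library, constraints, BG, cfg)


class TestDesignConstruct:
    def test_zero_targets_returns_wildtype(self, library):
        plants = _plant_layout(library, ["SYN_FOXA"], seed=2)
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=2), library)
        cfg = ScanConfig(p_threshold=1e-3)
        constraints = DesignConstraints(target_motif_ids=["SYN_ETS"], watch_motif_ids=["SYN_FOXA"])
        result = design_construct(seq, constraints, library, BG, cfg)
        assert isinstance(result, EnhancerVariant)
        assert result.sequence == seq
        assert result.plan.substitutions == ()

    def test_two_separated_sites_both_removed(self, library):
        plants = [Plant("SYN_ETS", 40), Plant("SYN_ETS", 200)]
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=3), library)
        cfg = ScanConfig(p_threshold=1e-3)
        constraints = DesignConstraints(target_motif_ids=["SYN_ETS"], watch_motif_ids=[])
        result = design_construct(seq, constraints, library, BG, cfg)
        assert isinstance(result, EnhancerVariant)
        assert len(result.plan.substitutions) <= 8
        assert len(result.sequence) == len(seq)
        assert scan_sequence(result.sequence, library.loms["SYN_ETS"], BG, cfg) == []

    def test_overlapping_protected_without_allowlist_is_infeasible(self, library):
        """Core-sharing target/protected sites conflict unless allowlisted."""
        # plant SYN_RBPJ; its GGAA core is also a (low-scoring) SYN_ETS region,
        # so force the conflict with an identical-matrix twin instead
        plants = [Plant("SYN_ETS", 100)]
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=4), library)
        cfg = ScanConfig(p_threshold=1e-3)
        twin = PWM("SYN_ETS_TWIN", "twin", library.pwms["SYN_ETS"].counts.copy())
        lib2 = MotifLibrary.build(list(library.pwms.values()) + [twin], BG)
        protected = scan_sequence(seq, lib2.loms["SYN_ETS_TWIN"], BG, cfg)
        assert protected, "twin matrix must see the planted site"
        constraints = DesignConstraints(
            target_motif_ids=["SYN_ETS"],
            watch_motif_ids=["SYN_ETS_TWIN"],
            protected_hits=protected,
        )
        result = design_construct(seq, constraints, lib2, BG, cfg)
        assert isinstance(result, InfeasibilityRecord)
        assert any("SYN_ETS_TWIN" in c for c in result.conflicts)

    def test_allowed_collateral_permits_protected_loss(self, library):
        """The escape hatch for core-sharing sites: sacrifice named hits."""
        plants = [Plant("SYN_ETS", 100)]
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=4), library)
        cfg = ScanConfig(p_threshold=1e-3)
        twin = PWM("SYN_ETS_TWIN", "twin", library.pwms["SYN_ETS"].counts.copy())
        lib2 = MotifLibrary.build(list(library.pwms.values()) + [twin], BG)
        protected = scan_sequence(seq, lib2.loms["SYN_ETS_TWIN"], BG, cfg)
        constraints = DesignConstraints(
            target_motif_ids=["SYN_ETS"],
            watch_motif_ids=["SYN_ETS_TWIN"],
            protected_hits=protected,
            allowed_collateral=[h.hit_id for h in protected],
        )
        result = design_construct(seq, constraints, lib2, BG, cfg)
        assert isinstance(result, EnhancerVariant)
        assert result.report.passed
        assert {h.hit_id for h in result.report.lost_protected_hits} <= set(
            constraints.allowed_collateral
        )

    def test_determinism(self, library):
        plants = _plant_layout(library, ["SYN_ETS", "SYN_ZIC"], seed=6)
        seq, _ = generate_enhancer(SequenceSimConfig(plants=plants, seed=6), library)
        cfg = ScanConfig(p_threshold=1e-3)
        constraints = DesignConstraints(target_motif_ids=["SYN_ETS"], watch_motif_ids=["SYN_ZIC"])
        from cisquant.synthetic_motifs import demo_library

        r1 = design_construct(seq, constraints, library, BG, cfg)
        r2 = design_construct(seq, constraints, demo_library(), BG, cfg)
        assert isinstance(r1, EnhancerVariant) and isinstance(r2, EnhancerVariant)
        assert r1.plan.substitutions == r2.plan.substitutions
        assert r1.sequence == r2.sequence
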