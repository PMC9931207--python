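"""Essential-mutation calls and the minimal activating-set search.

The independent oracle here is plain exhaustive enumeration over subsets in
size order with the same largest-delta/lexicographic tie-break, driven by
the transparent PWM scorer — no sampling, no cap.
"""

import itertools
import math

import numpy as np
import pytest

from enhancergain.cnn import apply_edits
from enhancergain.comparative import MutationSite, extract_mutations
from enhancergain.essential import (
    deactivating_essential,
    find_minimal_activating_set,
    single_mutation_effects,
)
from enhancergain.motifs import PWMScorer, pwm_from_consensus
from enhancergain.simulate import SimConfig, random_sequence, simulate_trio


def exhaustive_minimal_set(scorer, seq, mutations, thr):
    """Brute-force reference: smallest activating subset, same tie-break."""
    sites = sorted(mutations, key=lambda s: s.position)
    base = scorer.score(seq)
    for m in range(1, len(sites) + 1):
        best = None
        for combo in itertools.combinations(range(len(sites)), m):
            edits = [(sites[i].position, sites[i].human_allele) for i in combo]
            s = scorer.score(apply_edits(seq, edits))
            if s >= thr:
                key = (-(s - base), tuple(sites[i].position for i in combo))
                if best is None or key < best[0]:
                    best = (key, combo)
        if best is not None:
            return m, tuple(sites[i].position for i in best[1])
    return None, ()


def broken_motif_instance(rng, pwm, seq_len, n_break):
    """A sequence whose planted motif needs ``n_break`` specific repairs."""
    cons = pwm.consensus
    while True:
        seq = random_sequence(rng, seq_len)
        off = int(rng.integers(0, seq_len - len(cons) + 1))
        chars = list(seq[:off] + cons + seq[off + len(cons):])
        break_pos = rng.choice(len(cons), size=n_break, replace=False)
        repairs = []
        for j in sorted(int(x) for x in break_pos):
            orig = cons[j]
            alt = "A" if orig != "A" else "G"
            chars[off + j] = alt
            repairs.append((off + j, orig, alt))
        broken = "".join(chars)
        if PWMScorer(pwm).score(broken) < 0.5:
            return broken, repairs


class TestSingleMutationEffects:
    def test_motif_completing_allele_is_essential(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "gained", index=0)
        effects = single_mutation_effects(
            pwm_scorer, t.macaque_seq, t.mutations, pwm_scorer.activity_threshold
        )
        essential_called = {e.site.position for e in effects if e.activates}
        assert essential_called == set(t.essential_positions)

    def test_neutral_flank_allele_has_small_delta(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "gained", index=1)
        effects = single_mutation_effects(
            pwm_scorer, t.macaque_seq, t.mutations, pwm_scorer.activity_threshold
        )
        neutral = [e for e in effects if e.site.position not in t.essential_positions]
        assert all(not e.activates for e in neutral)
        # no neutral allele may push the score across the activity cutoff
        assert max(e.delta for e in neutral) < 0.5

    def test_empty_mutation_list_gives_empty_output(self, pwm_scorer):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 100)
        while pwm_scorer.score(seq) >= 0.5:
            seq = random_sequence(rng, 100)
        assert single_mutation_effects(pwm_scorer, seq, [], 0.5) == []

    def test_active_start_is_an_error(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "conserved", index=0)
        with pytest.raises(ValueError, match="already active"):
            single_mutation_effects(pwm_scorer, t.macaque_seq, [], 0.5)


class TestMinimalActivatingSet:
    def test_single_essential_mutation_gives_m_one(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "gained", index=2)
        result = find_minimal_activating_set(
            pwm_scorer, t.macaque_seq, t.mutations, pwm_scorer.activity_threshold
        )
        assert result.m == 1
        assert {s.position for s in result.combination} == set(t.essential_positions)

    def test_two_joint_alleles_found_by_exhaustive_pairs(self):
        pwm = pwm_from_consensus("M", "TGACGTCATC")
        pwm.threshold = 0.9 * pwm.max_score  # two mismatches push below, one does not
        scorer = PWMScorer(pwm)
        rng = np.random.default_rng(42)
        seq, repairs = broken_motif_instance(rng, pwm, 60, n_break=2)
        mutations = [
            MutationSite(pos, human_allele=orig, macaque_allele=alt)
            for pos, orig, alt in repairs
        ]
        # a couple of decoys that repair nothing
        for extra in (2, 55):
            if seq[extra] != "T":
                mutations.append(MutationSite(extra, "T", seq[extra]))
        result = find_minimal_activating_set(scorer, seq, mutations, 0.5, cap=None)
        assert result.m == 2
        assert {s.position for s in result.combination} == {
            pos for pos, _, _ in repairs
        }

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """Capped search with cap disabled equals brute-force enumeration."""
        rng = np.random.default_rng(7)
        pwm = pwm_from_consensus("M", "TGACGTCATC")
        pwm.threshold = 0.85 * pwm.max_score
        scorer = PWMScorer(pwm)
        for trial in range(25):
            n_break = int(rng.integers(1, 3))
            seq, repairs = broken_motif_instance(rng, pwm, 60, n_break)
            mutations = [
                MutationSite(pos, orig, alt) for pos, orig, alt in repairs
            ]
            taken = {pos for pos, _, _ in repairs}
            while len(mutations) < int(rng.integers(4, 9)):
                p = int(rng.integers(0, 60))
                if p in taken:
                    continue
                taken.add(p)
                alt = "C" if seq[p] != "C" else "A"
                mutations.append(MutationSite(p, alt, seq[p]))
            got = find_minimal_activating_set(
                scorer, seq, mutations, 0.5, cap=None, seed=trial
            )
            want_m, want_pos = exhaustive_minimal_set(scorer, seq, mutations, 0.5)
            assert got.m == want_m
            assert tuple(s.position for s in got.combination) == want_pos

    def test_full_set_reproduces_human_sequence(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "gained", index=3)
        edits = [(m.position, m.human_allele) for m in t.mutations]
        assert apply_edits(t.macaque_seq, edits) == t.human_seq
        delta_full = pwm_scorer.score(t.human_seq) - pwm_scorer.score(t.macaque_seq)
        rebuilt = pwm_scorer.score(apply_edits(t.macaque_seq, edits)) - \
            pwm_scorer.score(t.macaque_seq)
        assert rebuilt == delta_full

    def test_sampling_cap_honoured_at_large_m(self):
        """With n=20 and nothing activating, capped sizes evaluate 10,000."""

        class NeverActivates:
            def score(self, seq):
                return 0.0

        seq = "A" * 20
        mutations = [MutationSite(i, "C", "A") for i in range(20)]
        result = find_minimal_activating_set(
            NeverActivates(), seq, mutations, 0.5, cap=10_000, seed=0
        )
        assert result.m is None
        assert result.capped
        by_m = dict(result.evaluations_by_m)
        assert math.comb(20, 10) == 184_756
        assert by_m[10] == 10_000
        assert by_m[2] == math.comb(20, 2)  # below the cap: exhaustive
        assert all(v <= 10_000 for v in by_m.values())

    def test_sampling_is_seed_reproducible(self):
        class ScoreByHash:
            def score(self, seq):
                return (hash(seq) % 997) / 10_000.0  # never reaches 0.5

        seq = "ACGT" * 6
        mutations = [
            MutationSite(i, "C" if seq[i] != "C" else "G", seq[i]) for i in range(18)
        ]
        a = find_minimal_activating_set(
            ScoreByHash(), seq, mutations, 0.5, cap=50, seed=11
        )
        b = find_minimal_activating_set(
            ScoreByHash(), seq, mutations, 0.5, cap=50, seed=11
        )
        assert a == b

    def test_no_mutations_is_an_error(self, pwm_scorer):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 60)
        while pwm_scorer.score(seq) >= 0.5:
            seq = random_sequence(rng, 60)
        with pytest.raises(ValueError):
            find_minimal_activating_set(pwm_scorer, seq, [], 0.5)


class TestDeactivatingEssential:
    def test_motif_destroying_variant_deactivates(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "lost", index=5)
        (pos,) = t.essential_positions
        human_allele_at_pos = t.human_seq[pos]
        # start from the active macaque sequence; the human allele destroys it
        assert deactivating_essential(
            pwm_scorer, t.macaque_seq, (pos, human_allele_at_pos), 0.5
        )

    def test_neutral_flank_variant_does_not_deactivate(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "conserved", index=6)
        start, end = t.motif_window
        pos = 0 if start > 0 else end + 1
        allele = "A" if t.human_seq[pos] != "A" else "C"
        assert not deactivating_essential(pwm_scorer, t.human_seq, (pos, allele), 0.5)

    def test_inactive_start_is_an_error(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "neutral", index=7)
        with pytest.raises(ValueError, match="not active"):
            deactivating_essential(pwm_scorer, t.human_seq, (0, "A"), 0.5)

    def test_reference_allele_variant_is_an_error(self, pwm_scorer, sim_config):
        t = simulate_trio(sim_config, "conserved", index=8)
        with pytest.raises(ValueError):
            deactivating_essential(
                pwm_scorer, t.human_seq, (0, t.human_seq[0]), 0.5
            )


class TestRecallOnPlantedTruth:
    def test_essential_recall_on_gained_trios(self, sim_config, pwm_scorer):
        """Planted essential positions are recovered with >= 0.9 recall."""
        found, total = 0, 0
        for i in range(30):
            t = simulate_trio(sim_config, "gained", index=200 + i)
            effects = single_mutation_effects(
                pwm_scorer, t.macaque_seq, t.mutations,
                pwm_scorer.activity_threshold,
            )
            called = {e.site.position for e in effects if e.activates}
            total += len(t.essential_positions)
            found += len(called & t.essential_positions)
        assert total > 0
        assert found / total >= 0.9
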