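"""Lesion placement, cleavage-agent specificity and electrophoresis modes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ribofrag import (
    ALKALI,
    RNASE_H2,
    RNASE_HI,
    CleavageAgent,
    FragmentSet,
    LesionGenome,
    LesionModel,
    digest,
    electrophorese,
    nickase,
    opposed_pair_expectation,
    simulate_genome,
)
from ribofrag.lesion_sim import NICK, RIBO_RUN


def make_genome(length, lesions, label="test"):
    df = pd.DataFrame(lesions, columns=["strand", "position", "run_length", "kind"])
    return LesionGenome(length=length, lesions=df, label=label)


class TestSimulateGenome:
    def test_empty_model_yields_no_lesions(self):
        g = simulate_genome(1_000_000, LesionModel())
        assert len(g.lesions) == 0

    def test_run_counts_poisson_mean(self):
        # both strands of 1e8 nt at 1/7600: mean 2e8/7600 ~ 26,316
        g = simulate_genome(100_000_000, LesionModel(ribo_rate=1 / 7600, seed=11))
        n = g.count(RIBO_RUN)
        mean = 2e8 / 7600
        assert abs(n - mean) < 4 * np.sqrt(mean)

    def test_rate_multiplier_doubles_run_count(self):
        g = simulate_genome(
            100_000_000,
            LesionModel(ribo_rate=1 / 7600, rate_multiplier=2.0, seed=12),
        )
        mean = 2 * 2e8 / 7600
        assert abs(g.count(RIBO_RUN) - mean) < 4 * np.sqrt(mean)

    def test_reproducible_under_seed(self):
        m = LesionModel(ribo_rate=1e-5, nick_rate=1e-6, shear_rate=1e-6, seed=3)
        a = simulate_genome(10_000_000, m)
        b = simulate_genome(10_000_000, m)
        pd.testing.assert_frame_equal(a.lesions, b.lesions)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_genome(0, LesionModel())
        with pytest.raises(ValueError):
            LesionModel(ribo_rate=-1)
        with pytest.raises(ValueError):
            LesionModel(run_length_dist={1: 0.5, 2: 0.4})

    def test_lesions_never_overlap(self):
        # high rates provoke collisions; validate() in the constructor
        # would raise on any overlap left unresolved
        g = simulate_genome(
            10_000, LesionModel(ribo_rate=5e-3, nick_rate=2e-3, shear_rate=1e-3, seed=4)
        )
        g.validate()


class TestDigest:
    def test_alkali_cuts_three_prime_of_run(self):
        g = make_genome(100, [("top", 10, 1, RIBO_RUN)])
        frags = electrophorese(digest(g, ALKALI), "denaturing")
        top = sorted(frags.lengths[frags.lengths != 100])
        assert top == [10, 90]

    def test_rnaseh2_cuts_five_prime_one_nt_upstream(self):
        g = make_genome(100, [("top", 10, 1, RIBO_RUN)])
        frags = electrophorese(digest(g, RNASE_H2), "denaturing")
        top = sorted(frags.lengths[frags.lengths != 100])
        assert top == [9, 91]

    def test_rnasehi_identity_on_mono_and_di_runs(self):
        g = make_genome(
            1000,
            [("top", 10, 1, RIBO_RUN), ("top", 500, 2, RIBO_RUN),
             ("bottom", 200, 2, RIBO_RUN)],
        )
        out = digest(g, RNASE_HI)
        pd.testing.assert_frame_equal(
            out.lesions.sort_values(["strand", "position"]).reset_index(drop=True),
            g.lesions.sort_values(["strand", "position"]).reset_index(drop=True),
        )

    def test_rnasehi_cleaves_triple_runs(self):
        g = make_genome(1000, [("top", 100, 3, RIBO_RUN)])
        out = digest(g, RNASE_HI)
        assert out.count(NICK) == 1
        assert out.count(RIBO_RUN) == 0
        # 5' of the 3'-most ribonucleotide of the run at 100..102
        assert out.lesions.iloc[0]["position"] == 101

    def test_nickase_mode_adds_poisson_nicks(self):
        g = make_genome(1_000_000, [])
        rate = 1 / 1000
        out = digest(g, nickase(rate), seed=5)
        mean = 2 * rate * 1_000_000
        assert abs(out.count(NICK) - mean) < 4 * np.sqrt(mean)

    def test_agent_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            CleavageAgent("bad", min_run=1, extra_nick_rate=1e-4)
        with pytest.raises(ValueError):
            CleavageAgent("bad")


class TestElectrophorese:
    def test_no_nicks_denaturing_gives_two_full_strands(self):
        g = make_genome(5000, [("top", 100, 2, RIBO_RUN)])
        frags = electrophorese(g, "denaturing")
        assert sorted(frags.lengths) == [5000, 5000]
        assert frags.strandedness == "single"

    def test_poisson_nicks_give_exponential_fragments(self):
        # 1e5 fragments: mean ~ 1/rate and a KS check against the exponential
        rate = 1 / 10_000
        g = simulate_genome(500_000_000, LesionModel(nick_rate=rate, seed=6))
        frags = electrophorese(g, "denaturing")
        assert frags.n_fragments > 90_000
        assert abs(frags.mean_length() - 1 / rate) / (1 / rate) < 0.02
        interior = frags.lengths[frags.lengths < 200_000]
        ks = stats.kstest(interior, "expon", args=(0, 1 / rate))
        assert ks.pvalue > 0.01

    def test_mean_fragment_at_11kb_nicking(self):
        rate = 1 / 11_000
        g = simulate_genome(250_000_000, LesionModel(nick_rate=rate, seed=7))
        frags = electrophorese(g, "denaturing")
        assert abs(frags.mean_length() - 11_000) / 11_000 < 0.03

    def test_native_mode_ignores_ribo_runs(self):
        mutant = simulate_genome(
            10_000_000, LesionModel(ribo_rate=1 / 7600, shear_rate=1 / 30000, seed=8)
        )
        control = LesionGenome(
            mutant.length,
            mutant.lesions[mutant.lesions["kind"] == NICK],
            label="shear-only",
        )
        m = electrophorese(mutant, "native")
        c = electrophorese(control, "native")
        assert np.array_equal(np.sort(m.lengths), np.sort(c.lengths))

    def test_native_pairs_opposing_nicks_within_window(self):
        g = make_genome(
            10_000,
            [("top", 2000, 1, NICK), ("bottom", 2005, 1, NICK),
             ("top", 7000, 1, NICK)],  # unopposed: no break
        )
        frags = electrophorese(g, "native", ds_break_window=10)
        assert sorted(frags.lengths) == [2000, 8000]
        frags = electrophorese(g, "native", ds_break_window=2)
        assert sorted(frags.lengths) == [10_000]

    def test_unknown_mode_raises(self):
        g = make_genome(100, [])
        with pytest.raises(ValueError):
            electrophorese(g, "pulsed-field")

    def test_hu_multiplier_stochastically_shortens_fragments(self):
        def mean_frag(mult, seed):
            g = simulate_genome(
                50_000_000,
                LesionModel(ribo_rate=1 / 7600, rate_multiplier=mult, seed=seed),
            )
            return electrophorese(digest(g, ALKALI), "denaturing").mean_length()

        assert mean_frag(2.0, 9) < mean_frag(1.0, 9)


@st.composite
def lesion_genomes(draw):
    length = draw(st.integers(min_value=50, max_value=2000))
    n = draw(st.integers(min_value=0, max_value=10))
    lesions = []
    occupied = {"top": set(), "bottom": set()}
    for _ in range(n):
        strand = draw(st.sampled_from(["top", "bottom"]))
        run = draw(st.sampled_from([1, 1, 2, 3]))
        kind = draw(st.sampled_from([RIBO_RUN, NICK]))
        if kind == NICK:
            run = 1
        pos = draw(st.integers(min_value=2, max_value=length - run))
        span = set(range(pos - 1, pos + run + 1))  # 1-nt gap avoids cut collisions
        if span & occupied[strand]:
            continue
        occupied[strand] |= span
        lesions.append((strand, pos, run, kind))
    return make_genome(length, lesions)


class TestProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(lesion_genomes(), st.sampled_from([ALKALI, RNASE_H2, RNASE_HI]))
    def test_length_conservation_per_strand(self, genome, agent):
        """Denaturing fragments of each strand always sum to the genome length."""
        frags = electrophorese(digest(genome, agent), "denaturing")
        assert frags.total_nt == 2 * genome.length

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(lesion_genomes())
    def test_alkali_rnaseh2_fragments_differ_by_at_most_1nt(self, genome):
        """The 3' vs 5' cut conventions shift every fragment by at most 1 nt."""
        a = np.sort(electrophorese(digest(genome, ALKALI), "denaturing").lengths)
        h = np.sort(electrophorese(digest(genome, RNASE_H2), "denaturing").lengths)
        assert len(a) == len(h)
        assert np.max(np.abs(a - h)) <= 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(lesion_genomes())
    def test_rnasehi_identity_when_runs_below_three(self, genome):
        short = genome.lesions[
            (genome.lesions["kind"] == NICK) | (genome.lesions["run_length"] <= 2)
        ]
        g = LesionGenome(genome.length, short)
        out = digest(g, RNASE_HI)
        assert len(out.lesions) == len(g.lesions)
        assert out.count(RIBO_RUN) == g.count(RIBO_RUN)


class TestOpposedPairs:
    def test_zero_rate(self):
        assert opposed_pair_expectation(1e9, 0.0) == 0.0

    def test_haploid_and_diploid_values(self):
        assert opposed_pair_expectation(2.5e9, 1 / 7600) == pytest.approx(43.28, abs=0.01)
        assert opposed_pair_expectation(5.0e9, 1 / 7600) == pytest.approx(86.57, abs=0.01)

    def test_monte_carlo_oracle(self):
        # independent Bernoulli sites on two strands; count coincidences
        rng = np.random.default_rng(10)
        bp, rate = 1_000_000, 0.01
        top = rng.random(bp) < rate
        bottom = rng.random(bp) < rate
        observed = int((top & bottom).sum())
        expected = opposed_pair_expectation(bp, rate)
        assert abs(observed - expected) < 4 * np.sqrt(expected)

    def test_rejects_rate_above_one(self):
        with pytest.raises(ValueError):
            opposed_pair_expectation(1e6, 1.5)


def test_fragment_set_rejects_sub_unit_lengths():
    with pytest.raises(ValueError):
        FragmentSet(np.array([0, 5]))
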