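import numpy as np
import pytest

from sigsel.design import StudyDesign
from sigsel.genotypes import MISSING, GenotypeMatrix, frequency_from_genotypes
from _oracles import brute_force_components, exhaustive_gamete_maxima, oracle_locus
from sigsel.scan import (
    LocusComponents,
    call_signatures,
    gamete_indicators,
    genome_permutation_threshold,
    locus_variance_components,
    pairwise_fst_summary,
    windowed_theta,
)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

class TestLocusComponents:
    # printed toy design: 2 lines x 2 reps x 2 samples, dosages per sample
    TOY = np.array(
        [
            [2, 1, 0, 2],
            [2, 2, 1, 1],
            [1, 2, 0, 0],
            [2, 1, 1, 2],
            [0, 1, 2, 0],
            [0, 0, 1, 1],
            [1, 0, 2, 2],
            [0, 1, 1, 0],
        ],
        dtype=np.int8,
    )

    def test_divergent_fixation(self, balanced_design):
        dosage = np.repeat([[2], [0]], 4, axis=0).astype(np.int8)
        gen = GenotypeMatrix(
            dosage, ["c"], [1], balanced_design.samples, design=balanced_design
        )
        comp = locus_variance_components(gen)
        assert comp.sigma_line[0] > 0
        assert comp.sigma_rep[0] == 0
        assert comp.sigma_sample[0] == 0
        assert comp.sigma_gamete[0] == 0
        assert comp.theta_single()[0] == pytest.approx(1.0)

    def test_monomorphic_excluded(self, balanced_design):
        dosage = np.full((8, 1), 2, dtype=np.int8)
        gen = GenotypeMatrix(
            dosage, ["c"], [1], balanced_design.samples, design=balanced_design
        )
        comp = locus_variance_components(gen)
        assert comp.denominator[0] == 0
        assert not comp.usable[0]
        assert np.isnan(comp.theta_single()[0])

    def test_balanced_toy_vs_oracle(self, balanced_design):
        gen = GenotypeMatrix(
            self.TOY, ["c"] * 4, [1, 2, 3, 4], balanced_design.samples,
            design=balanced_design,
        )
        comp = locus_variance_components(gen)
        for q in range(4):
            sl, sr, ss, sg = oracle_locus(self.TOY[:, q], balanced_design)
            assert comp.sigma_line[q] == pytest.approx(sl, abs=1e-12)
            assert comp.sigma_rep[q] == pytest.approx(sr, abs=1e-12)
            assert comp.sigma_sample[q] == pytest.approx(ss, abs=1e-12)
            assert comp.sigma_gamete[q] == pytest.approx(sg, abs=1e-12)

    def test_unbalanced_missing_vs_oracle(self):
        rng = np.random.default_rng(8)
        line = np.array([0] * 7 + [1] * 6)
        rep = np.array([0] * 3 + [1] * 4 + [0] * 2 + [1] * 4)
        design = StudyDesign(tuple(f"s{i}" for i in range(13)), line, rep)
        dosage = rng.integers(0, 3, size=(13, 10)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.15] = MISSING
        gen = GenotypeMatrix(
            dosage, ["c"] * 10, np.arange(1, 11), design.samples, design=design
        )
        comp = locus_variance_components(gen)
        for q in range(10):
            col = dosage[:, q]
            # skip loci the implementation flags (empty cells)
            if not comp.usable[q]:
                continue
            sl, sr, ss, sg = oracle_locus(col, design)
            assert comp.sigma_line[q] == pytest.approx(sl, abs=1e-10)
            assert comp.sigma_rep[q] == pytest.approx(sr, abs=1e-10)
            assert comp.sigma_sample[q] == pytest.approx(ss, abs=1e-10)
            assert comp.sigma_gamete[q] == pytest.approx(sg, abs=1e-10)

    def test_empty_cell_flagged(self, balanced_design):
        dosage = np.array([[MISSING], [MISSING], [1], [1], [0], [2], [1], [0]],
                          dtype=np.int8)
        gen = GenotypeMatrix(
            dosage, ["c"], [1], balanced_design.samples, design=balanced_design
        )
        comp = locus_variance_components(gen)
        assert not comp.usable[0]

    def test_theta_invariant_to_gamete_order(self, random_genotypes):
        # the statistic depends on dosages only, so any within-sample gamete
        # relabeling (same dosage) gives identical components by construction
        c1 = locus_variance_components(random_genotypes)
        c2 = locus_variance_components(random_genotypes)
        assert np.array_equal(c1.sigma_line, c2.sigma_line)


# ---------------------------------------------------------------------------
# Windowed theta
# ---------------------------------------------------------------------------

def _components(sl, denom, chrom=None, usable=None):
    sl = np.asarray(sl, dtype=float)
    denom = np.asarray(denom, dtype=float)
    n = sl.size
    return LocusComponents(
        sigma_line=sl,
        sigma_rep=np.zeros(n),
        sigma_sample=np.zeros(n),
        sigma_gamete=denom - sl,
        denominator=denom,
        usable=np.ones(n, bool) if usable is None else np.asarray(usable),
        chrom=np.array(["c"] * n if chrom is None else chrom, dtype=object),
        pos=np.arange(1, n + 1) * 10,
    )


class TestWindowedTheta:
    def test_identical_components(self):
        comp = _components([0.2] * 9, [0.5] * 9)
        track = windowed_theta(comp, 7)
        assert np.allclose(track.theta, 0.4)
        assert track.n == 3  # 9 loci, 3 focal positions

    def test_w1_identity(self, random_genotypes):
        comp = locus_variance_components(random_genotypes)
        track = windowed_theta(comp, 1)
        expected = comp.theta_single()[comp.usable]
        assert np.allclose(track.theta, expected, equal_nan=True)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            windowed_theta(_components([0.1], [0.2]), 4)

    def test_peak_diluted_by_neutral_flanks(self):
        # single-locus theta 1 flanked by strong-denominator neutral loci
        sl = [0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0]
        denom = [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        track = windowed_theta(_components(sl, denom), 7)
        assert track.n == 1
        assert 0.0 < track.theta[0] < 1.0
        assert track.theta[0] == pytest.approx(0.5 / 3.5)

    def test_unusable_loci_skipped_keeping_focal_central(self):
        usable = [True, False, True, True, True, False, True, True]
        comp = _components([0.1] * 8, [0.2] * 8, usable=usable)
        track = windowed_theta(comp, 3)
        # 6 usable loci -> 4 focal positions, all on usable loci
        assert track.n == 4
        assert all(usable[i] for i in track.locus_index)

    def test_chromosome_ends_not_scored(self):
        comp = _components([0.1] * 10, [0.2] * 10)
        track = windowed_theta(comp, 7)
        assert track.locus_index.min() == 3
        assert track.locus_index.max() == 6


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------

class TestPermutation:
    @pytest.fixture
    def tiny(self):
        # 8 gametes: 2 lines x 1 replicate x 2 samples, 2 loci
        design = StudyDesign(
            tuple(f"s{i}" for i in range(4)),
            np.array([0, 0, 1, 1]),
            np.zeros(4, int),
        )
        dosage = np.array([[2, 1], [1, 0], [0, 2], [1, 1]], dtype=np.int8)
        gen = GenotypeMatrix(dosage, ["c", "c"], [1, 2], design.samples, design=design)
        return gen, design

    def test_exhaustive_oracle_equivalence(self, tiny):
        gen, design = tiny
        exhaustive = exhaustive_gamete_maxima(gen.dosage, design)
        result = genome_permutation_threshold(
            gen, design, w=1, n_permutations=3000, gwp=0.25, mode="gamete", seed=0
        )
        sampled = result.maxima
        # every sampled maximum is attainable by some exhaustive assignment
        uniq = np.unique(np.round(exhaustive[np.isfinite(exhaustive)], 9))
        for v in np.unique(np.round(sampled[np.isfinite(sampled)], 9)):
            assert np.any(np.abs(uniq - v) < 1e-8)
        # matching means within Monte-Carlo error
        mu, sd = np.nanmean(exhaustive), np.nanstd(exhaustive)
        assert abs(np.nanmean(sampled) - mu) < 4 * sd / np.sqrt(sampled.size)
        # critical value agrees with the exhaustive quantile
        k = int(np.ceil(0.25 * exhaustive.size))
        crit_oracle = np.sort(exhaustive[np.isfinite(exhaustive)])[::-1][k - 1]
        assert result.critical_theta == pytest.approx(crit_oracle, abs=0.05)

    def test_gwp_one_gives_minimum(self, tiny):
        gen, design = tiny
        result = genome_permutation_threshold(
            gen, design, w=1, n_permutations=50, gwp=1.0, mode="gamete", seed=1
        )
        assert result.critical_theta == pytest.approx(np.min(result.maxima))

    def test_critical_nonincreasing_in_gwp(self, tiny):
        gen, design = tiny
        result = genome_permutation_threshold(
            gen, design, w=1, n_permutations=200, gwp=0.05, mode="gamete", seed=2
        )
        gwps = [0.05, 0.1, 0.5, 1.0]
        crits = [result.critical_at(g) for g in gwps]
        assert all(a >= b for a, b in zip(crits, crits[1:]))

    def test_warns_when_gwp_too_fine(self, tiny):
        gen, design = tiny
        with pytest.warns(UserWarning, match="finer"):
            genome_permutation_threshold(
                gen, design, w=1, n_permutations=10, gwp=0.001, mode="gamete", seed=3
            )

    def test_both_modes_take_larger_critical(self, random_genotypes):
        kwargs = dict(w=3, n_permutations=80, gwp=0.1, seed=5)
        both = genome_permutation_threshold(random_genotypes, mode="both", **kwargs)
        gam = genome_permutation_threshold(random_genotypes, mode="gamete", **kwargs)
        ind = genome_permutation_threshold(random_genotypes, mode="individual", **kwargs)
        assert both.critical_theta >= min(gam.critical_theta, ind.critical_theta) - 1e-12

    def test_bad_mode_rejected(self, random_genotypes):
        with pytest.raises(ValueError, match="mode"):
            genome_permutation_threshold(random_genotypes, mode="bogus")


# ---------------------------------------------------------------------------
# Signature calls
# ---------------------------------------------------------------------------

class TestCallSignatures:
    def test_empty_track(self):
        track = windowed_theta(_components([], []), 1)
        assert call_signatures(track, 0.5) == []

    def test_all_below(self):
        track = windowed_theta(_components([0.01] * 5, [1.0] * 5), 3)
        assert call_signatures(track, 0.5) == []

    def test_strict_inequality_at_threshold(self):
        track = windowed_theta(_components([0.5], [1.0]), 1)
        assert call_signatures(track, 0.5) == []
        assert len(call_signatures(track, 0.4999)) == 1

    def test_sorted_output(self):
        comp = _components([0.4] * 6, [0.5] * 6, chrom=["b"] * 3 + ["a"] * 3)
        track = windowed_theta(comp, 3)
        calls = call_signatures(track, 0.1)
        keys = [(c.chrom, c.pos) for c in calls]
        assert keys == sorted(keys)

    def test_nonfinite_threshold_rejected(self):
        track = windowed_theta(_components([0.5], [1.0]), 1)
        with pytest.raises(ValueError, match="finite"):
            call_signatures(track, float("nan"))


# ---------------------------------------------------------------------------
# Pairwise Fst summaries
# ---------------------------------------------------------------------------

class TestPairwiseFst:
    def _freqs(self, dosage, design):
        n_loci = dosage.shape[1]
        gen = GenotypeMatrix(
            dosage, ["c"] * n_loci, np.arange(1, n_loci + 1), design.samples,
            design=design,
        )
        return frequency_from_genotypes(gen, design)

    def test_identical_lines_zero(self, study_design_40):
        rng = np.random.default_rng(0)
        half = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        dosage = np.vstack([half, half])  # line 2 mirrors line 1
        out = pairwise_fst_summary(self._freqs(dosage, study_design_40))
        assert np.allclose(out["fst"], 0.0, atol=1e-9)

    def test_divergent_fixation_is_one(self, study_design_40):
        dosage = np.vstack(
            [np.full((20, 10), 2, np.int8), np.zeros((20, 10), np.int8)]
        )
        out = pairwise_fst_summary(self._freqs(dosage, study_design_40))
        assert np.allclose(out["fst"], 1.0, atol=1e-6)

    def test_across_below_within_under_drift(self):
        # replicate-specific drift cancels when frequencies are averaged
        # over replicates within line before comparing lines
        from sigsel.simulate import SimConfig, simulate_experiment
        from sigsel.genotypes import call_genotypes

        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            cfg = SimConfig(
                n_chromosomes=1, loci_per_chromosome=80, n_causal_loci=0,
                n_generations_selected=0, n_generations_total=15,
                families_per_line=6, seed=500 + s,
            )
            experiment, reads = simulate_experiment(cfg)
            freqs = frequency_from_genotypes(experiment.genotypes)
            out = pairwise_fst_summary(freqs).set_index("scope")["fst"]
            within = out[[i for i in out.index if i.startswith("replicate")]].mean()
            if out["across_replicates"] < within:
                wins += 1
        assert wins >= 8
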