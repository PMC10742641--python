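"""Coalescence statistics: Θ, correlations and the prediction scans."""

import math
import warnings

import numpy as np
import pytest

from ecocoalesce.coalescence import (
    correlate,
    divergence,
    enumerate_pairs,
    hill_prediction_scan,
    normalize_minmax,
    richness_predictors,
    stability_index,
    stability_table,
)
from ecocoalesce.community import (
    CommunityState,
    FunctionalGroup,
    LogAbundanceVector,
    Species,
    SpeciesTable,
)
from ecocoalesce.diversity import default_q_grid, merge_counts

from conftest import make_state


def brute_force_theta(initial, outcomes, species):
    """Independent re-derivation of Θ: plain loops, no shared helpers.

    For each source, collapse each pair's replicates to the mean of their
    log10 vectors (0 below detection), then sum squared displacement over
    pairs and species.
    """
    def logvec(state):
        out = []
        for sid in species.ids:
            c = state.counts.get(sid, 0.0)
            out.append(math.log10(c) if c >= species[sid].detection_limit else 0.0)
        return out

    thetas = {}
    for eco, init_state in initial.items():
        init_x = logvec(init_state)
        d = 0.0
        for pair, reps in outcomes.items():
            if eco not in pair:
                continue
            mean_x = [
                sum(logvec(r)[k] for r in reps) / len(reps)
                for k in range(len(species))
            ]
            d += sum((mean_x[k] - init_x[k]) ** 2 for k in range(len(species)))
        thetas[eco] = (d, math.inf if d == 0 else 1.0 / d)
    return thetas


class TestEnumeratePairs:
    def test_eight_sources_give_36_outcomes(self):
        design = enumerate_pairs(8)
        assert len(design.pairs) == 36
        assert len(set(design.pairs)) == 36

    def test_single_source_is_one_self_pair(self):
        design = enumerate_pairs(1)
        assert design.pairs == (("E0", "E0"),)

    def test_three_sources_give_six_pairs(self):
        assert len(enumerate_pairs(3).pairs) == 6

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(0)
        with pytest.raises(ValueError):
            enumerate_pairs(3, replicates=0)

    def test_pairs_containing_source(self):
        design = enumerate_pairs(8)
        assert len(design.pairs_containing("E3")) == 8  # 7 cross + self


class TestDivergence:
    def test_identical_state_has_zero_divergence(self):
        v = LogAbundanceVector(np.array([2.0, 3.0]), ("A", "B"))
        assert divergence(v, [v]) == 0.0

    def test_unit_displacement(self):
        init = LogAbundanceVector(np.array([2.0]), ("A",))
        after = LogAbundanceVector(np.array([3.0]), ("A",))
        assert divergence(init, [after]) == pytest.approx(1.0)

    def test_species_loss_uses_zero_convention(self):
        # a 10^4 population that disappears contributes (4 - 0)^2 = 16
        init = LogAbundanceVector(np.array([4.0, 0.0]), ("A", "B"))
        after = LogAbundanceVector(np.array([0.0, 0.0]), ("A", "B"))
        assert divergence(init, [after]) == pytest.approx(16.0)

    def test_mismatched_axes_rejected(self):
        a = LogAbundanceVector(np.array([1.0]), ("A",))
        b = LogAbundanceVector(np.array([1.0]), ("B",))
        with pytest.raises(ValueError, match="axes"):
            divergence(a, [b])


class TestStabilityIndex:
    @pytest.mark.parametrize("d,expected", [(1.0, 1.0), (4.0, 0.25)])
    def test_reciprocal(self, d, expected):
        assert stability_index(d) == expected

    def test_perfect_persistence_is_infinite(self):
        assert stability_index(0.0) == math.inf

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            stability_index(-1.0)


class TestStabilityTable:
    def test_self_pair_identical_outcome_gives_infinite_theta(self, species):
        state = make_state({"Ecoli": 1000}, ecosystem_id="E0")
        results = stability_table(
            {"E0": state}, {("E0", "E0"): [state]}, species
        )
        assert results[0].theta == math.inf

    def test_dominant_source_ranks_above_overwritten_one(self, species):
        a = make_state({"Ecoli": 1000}, ecosystem_id="A")
        b = make_state({"CyanoA": 1000}, ecosystem_id="B")
        outcomes = {("A", "A"): [a], ("A", "B"): [a], ("B", "B"): [a]}
        results = {r.ecosystem_id: r for r in stability_table({"A": a, "B": b}, outcomes, species)}
        assert results["A"].theta == math.inf
        assert results["A"].theta > results["B"].theta > 0

    def test_source_without_outcomes_rejected(self, species):
        a = make_state({"Ecoli": 10}, ecosystem_id="A")
        b = make_state({"Ecoli": 10}, ecosystem_id="B")
        with pytest.raises(ValueError, match="no outcome"):
            stability_table({"A": a, "B": b}, {("A", "A"): [a]}, species)

    def test_matches_brute_force_oracle_on_random_instances(self, species, rng):
        for _ in range(100):
            n_eco = int(rng.integers(1, 5))
            n_rep = int(rng.integers(1, 5))
            ids = [f"E{i}" for i in range(n_eco)]
            initial = {
                e: make_state(
                    dict(zip(species.ids, 10.0 ** rng.uniform(-1, 7, size=6))),
                    ecosystem_id=e,
                )
                for e in ids
            }
            outcomes = {}
            for i in range(n_eco):
                for j in range(i, n_eco):
                    outcomes[(ids[i], ids[j])] = [
                        make_state(
                            dict(zip(species.ids, 10.0 ** rng.uniform(-1, 7, size=6)))
                        )
                        for _ in range(n_rep)
                    ]
            results = {r.ecosystem_id: r for r in stability_table(initial, outcomes, species)}
            expected = brute_force_theta(initial, outcomes, species)
            for e in ids:
                assert results[e].divergence == pytest.approx(expected[e][0], rel=1e-12)
                assert results[e].theta == pytest.approx(expected[e][1], rel=1e-12)

    def test_theta_ordering_invariant_to_log_base(self, species, rng):
        # base change rescales every divergence by the same factor, so the
        # ranking of Θ values cannot move
        initial, outcomes = {}, {}
        ids = ["E0", "E1", "E2"]
        for e in ids:
            initial[e] = make_state(
                dict(zip(species.ids, 10.0 ** rng.uniform(0, 6, size=6))), ecosystem_id=e
            )
        for i in range(3):
            for j in range(i, 3):
                outcomes[(ids[i], ids[j])] = [
                    make_state(dict(zip(species.ids, 10.0 ** rng.uniform(0, 6, size=6))))
                ]
        results = stability_table(initial, outcomes, species)
        d10 = np.array([r.divergence for r in results])
        # divergence in natural-log units = (ln 10)^2 x divergence in log10
        dln = d10 * np.log(10) ** 2
        assert np.array_equal(np.argsort(d10), np.argsort(dln))

    def test_replicate_aggregation_switch(self, species):
        a = make_state({"Ecoli": 100}, ecosystem_id="A")
        r1 = make_state({"Ecoli": 10})
        r2 = make_state({"Ecoli": 1000})
        out = {("A", "A"): [r1, r2]}
        log_mean = stability_table({"A": a}, out, species)[0]
        pooled = stability_table({"A": a}, out, species, replicate_aggregation="none")[0]
        assert log_mean.divergence == pytest.approx(0.0, abs=1e-12)  # mean of logs is 2
        assert pooled.divergence == pytest.approx(2.0)  # (1-2)^2 + (3-2)^2


class TestNormalizeAndCorrelate:
    def test_minmax_basic(self):
        assert normalize_minmax(np.array([1.0, 2.0, 3.0])).tolist() == [0.0, 0.5, 1.0]

    def test_minmax_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_minmax(np.array([5.0, 5.0]))

    def test_minmax_affine_invariance(self, rng):
        v = rng.normal(size=10)
        assert np.allclose(normalize_minmax(v), normalize_minmax(3.5 * v - 2.0))

    def test_perfect_linear_correlation(self):
        x = np.arange(5.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r, p = correlate(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_expected = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        t = r_expected * np.sqrt(6 / (1 - r_expected**2))
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t), df=6)
        assert r == pytest.approx(r_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-9)

    def test_r_invariant_under_minmax_normalization(self, rng):
        x = rng.normal(size=8)
        y = x + rng.normal(size=8)
        r0, _ = correlate(x, y)
        r1, _ = correlate(normalize_minmax(x), y)
        r2, _ = correlate(x, normalize_minmax(y))
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert r0 == pytest.approx(r2, abs=1e-12)

    def test_infinite_theta_rows_dropped_with_warning(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([np.inf, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="non-finite"):
            r, _ = correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _random_states(species, rng, ids):
    return {
        e: make_state(
            dict(zip(species.ids, rng.integers(0, 2, size=6) * 10.0 ** rng.uniform(1, 5, size=6))),
            ecosystem_id=e,
        )
        for e in ids
    }


class TestRichnessPredictors:
    def test_perfect_merged_predictor(self, species, rng):
        design = enumerate_pairs(4, 1)
        pre = _random_states(species, rng, design.source_ids)
        post = {
            pair: [merge_counts(pre[pair[0]], pre[pair[1]])] for pair in design.pairs
        }
        scan = richness_predictors(design, pre, post, species)
        assert dict(zip(scan.keys, scan.r_squared))["merged"] == pytest.approx(1.0)

    def test_constant_outcome_explains_nothing(self, species, rng):
        design = enumerate_pairs(4, 1)
        pre = _random_states(species, rng, design.source_ids)
        constant = make_state({"Ecoli": 10}, ecosystem_id="fixed")
        post = {pair: [constant] for pair in design.pairs}
        scan = richness_predictors(design, pre, post, species)
        assert np.allclose(scan.r_squared, 0.0)

    def test_larger_parent_dominates_when_outcome_tracks_it(self, species):
        rng = np.random.default_rng(7)
        design = enumerate_pairs(6, 1)
        pre = {}
        for k, e in enumerate(design.source_ids):
            n = 2 + k % 4
            chosen = list(rng.choice(species.ids, size=n, replace=False))
            pre[e] = make_state({s: 100.0 for s in chosen}, ecosystem_id=e)
        post = {}
        from ecocoalesce.diversity import species_richness

        for pair in design.pairs:
            target = max(
                species_richness(pre[pair[0]], species),
                species_richness(pre[pair[1]], species),
            )
            keep = list(rng.choice(species.ids, size=target, replace=False))
            post[pair] = [make_state({s: 50.0 for s in keep})]
        scan = richness_predictors(design, pre, post, species)
        r2 = dict(zip(scan.keys, scan.r_squared))
        assert r2["larger"] > r2["smaller"]

    def test_too_few_pairs_rejected(self, species, rng):
        design = enumerate_pairs(1)
        pre = _random_states(species, rng, design.source_ids)
        post = {design.pairs[0]: [pre["E0"]]}
        with pytest.raises(ValueError):
            richness_predictors(design, pre, post, species)


class TestHillPredictionScan:
    def test_exact_merged_outcome_is_fully_predicted(self, species, rng):
        design = enumerate_pairs(4, 1)
        pre = _random_states(species, rng, design.source_ids)
        post = {
            pair: [merge_counts(pre[pair[0]], pre[pair[1]])] for pair in design.pairs
        }
        scan = hill_prediction_scan(design, pre, post, species, default_q_grid())
        assert np.allclose(scan.r_squared, 1.0)

    def test_abundance_reshuffling_favours_low_q(self, species):
        # composition preserved, abundances rescaled by ~1 decade of noise:
        # presence/absence survives, population structure does not
        rng = np.random.default_rng(11)
        design = enumerate_pairs(8, 2)
        pre = _random_states(species, rng, design.source_ids)
        post = {}
        for pair in design.pairs:
            merged = merge_counts(pre[pair[0]], pre[pair[1]])
            outs = []
            for rep in range(2):
                counts = {
                    k: (v * 10 ** rng.normal(0, 0.8) if v > 0 else 0.0)
                    for k, v in merged.counts.items()
                }
                outs.append(merged.with_counts(counts, replicate=rep))
            post[pair] = outs
        scan = hill_prediction_scan(design, pre, post, species, default_q_grid())
        assert float(scan.argmax_key) <= 0.5

    def test_dominance_preserving_regime_favours_high_q(self, species):
        # rare species are stochastically lost while the dominance structure
        # stays intact: high-q Hill numbers become the better predictor
        rng = np.random.default_rng(13)
        design = enumerate_pairs(8, 2)
        pre = _random_states(species, rng, design.source_ids)
        post = {}
        for pair in design.pairs:
            merged = merge_counts(pre[pair[0]], pre[pair[1]])
            total = sum(merged.counts.values())
            outs = []
            for rep in range(2):
                counts = {}
                for k, v in merged.counts.items():
                    if v > 0 and v / total < 0.05 and rng.random() < 0.5:
                        counts[k] = 0.0
                    else:
                        counts[k] = v * 10 ** rng.normal(0, 0.05)
                outs.append(merged.with_counts(counts, replicate=rep))
            post[pair] = outs
        scan = hill_prediction_scan(design, pre, post, species, default_q_grid())
        r2 = dict(zip((float(q) for q in scan.keys), scan.r_squared))
        assert r2[3.0] > r2[0.0]

    def test_argmax_ties_break_toward_smaller_q(self, species, rng):
        design = enumerate_pairs(4, 1)
        pre = _random_states(species, rng, design.source_ids)
        post = {
            pair: [merge_counts(pre[pair[0]], pre[pair[1]])] for pair in design.pairs
        }
        scan = hill_prediction_scan(design, pre, post, species, default_q_grid())
        assert float(scan.argmax_key) == 0.0  # all-ones profile

    def test_r_squared_within_unit_interval_and_label_invariant(self, species, rng):
        design = enumerate_pairs(5, 2)
        pre = _random_states(species, rng, design.source_ids)
        post = {
            pair: [
                make_state(dict(zip(species.ids, 10.0 ** rng.uniform(0, 5, size=6))))
                for _ in range(2)
            ]
            for pair in design.pairs
        }
        scan = hill_prediction_scan(design, pre, post, species, default_q_grid())
        assert np.all(scan.r_squared >= 0.0) and np.all(scan.r_squared <= 1.0)
        # relabeling species permutes counts identically everywhere: R² fixed
        perm = rng.permutation(6)
        relabel = dict(zip(species.ids, (species.ids[i] for i in perm)))
        pre2 = {
            e: s.with_counts({relabel[k]: v for k, v in s.counts.items()})
            for e, s in pre.items()
        }
        post2 = {
            pair: [s.with_counts({relabel[k]: v for k, v in s.counts.items()}) for s in reps]
            for pair, reps in post.items()
        }
        scan2 = hill_prediction_scan(design, pre2, post2, species, default_q_grid())
        assert np.allclose(scan.r_squared, scan2.r_squared)
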