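import numpy as np
import pandas as pd
import pytest

from gmpsig.scoring import (
    Direction,
    normalize_scores,
    precision_recall_at_cutoffs,
    query_targets,
    score_pvalues,
    self_recovery_ranks,
    total_correlation_score,
)
from gmpsig.synthetic import simulate_query
from gmpsig.types import (
    GeneModulePair,
    RankedGeneList,
    TargetSpace,
    ValidationError,
)

from conftest import random_space


def glist(n):
    return [f"g{i:04d}" for i in range(n)]


def make_list(genes):
    return RankedGeneList(genes=list(genes))


class TestTotalCorrelationScore:
    def test_fully_concordant_is_two(self):
        genes = glist(1000)
        g = GeneModulePair(
            target_id="T", up=frozenset(genes[:250]), down=frozenset(genes[-250:])
        )
        assert total_correlation_score(make_list(genes), g) == pytest.approx(2.0)

    def test_fully_discordant_is_minus_two(self):
        genes = glist(1000)
        g = GeneModulePair(
            target_id="T", up=frozenset(genes[-250:]), down=frozenset(genes[:250])
        )
        assert total_correlation_score(make_list(genes), g) == pytest.approx(-2.0)

    def test_same_sign_rule_zeroes(self):
        # both modules near the top: ES_up and ES_down both positive
        genes = glist(200)
        g = GeneModulePair(
            target_id="T", up=frozenset(genes[:20]), down=frozenset(genes[20:40])
        )
        assert total_correlation_score(make_list(genes), g) == 0.0

    def test_bound_fuzz(self):
        rng = np.random.default_rng(0)
        genes = np.asarray(glist(300))
        for _ in range(300):
            order = rng.permutation(genes)
            pick = rng.choice(300, size=60, replace=False)
            g = GeneModulePair(
                target_id="T",
                up=frozenset(genes[pick[:30]]),
                down=frozenset(genes[pick[30:]]),
            )
            tcs = total_correlation_score(make_list(order), g)
            assert -2.0 <= tcs <= 2.0

    def test_reversal_flips_sign_when_rule_inactive(self):
        rng = np.random.default_rng(1)
        genes = np.asarray(glist(300))
        checked = 0
        for _ in range(100):
            order = rng.permutation(genes)
            pick = rng.choice(300, size=40, replace=False)
            g = GeneModulePair(
                target_id="T",
                up=frozenset(genes[pick[:20]]),
                down=frozenset(genes[pick[20:]]),
            )
            L = make_list(order)
            fwd = total_correlation_score(L, g)
            rev = total_correlation_score(L.reversed(), g)
            if fwd != 0.0 and rev != 0.0:
                assert rev == pytest.approx(-fwd, abs=1e-12)
                checked += 1
        assert checked > 10


class TestNormalizeScores:
    def test_simple(self):
        assert np.allclose(normalize_scores([2.0, -2.0, 2.0]), [1, -1, 1])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            out = normalize_scores([0.0, 0.0, 0.0])
        assert np.allclose(out, 0.0)

    def test_hand_computed_mean_of_abs(self):
        # mu = (1 + 0.5 + 0.5 + 0) / 4 = 0.5
        out = normalize_scores([1.0, 0.5, -0.5, 0.0])
        assert np.allclose(out, [2.0, 1.0, -1.0, 0.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        tcs = rng.normal(size=20)
        assert np.allclose(normalize_scores(tcs), normalize_scores(3.7 * tcs))

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            normalize_scores([])


class TestScorePvalues:
    def test_planted_query_significant(self, default_truth, space):
        L = simulate_query(default_truth, "T001", "concordant")
        df = score_pvalues(L, space, reps=1000, seed=1)
        p_own = df.loc[df.target == "T001", "p"].iloc[0]
        assert p_own <= 0.01

    def test_null_calibration(self):
        space = random_space(20, module_size=50, universe_size=1000, seed=3)
        rng = np.random.default_rng(4)
        genes = np.asarray(space.universe)
        fracs = []
        for _ in range(50):
            L = make_list(rng.permutation(genes))
            df = score_pvalues(L, space, reps=100, seed=rng)
            fracs.append((df.p < 0.05).mean())
        assert 0.01 <= float(np.mean(fracs)) <= 0.12

    def test_below_every_null_p_one(self, default_truth, space):
        L = simulate_query(default_truth, "T001", "concordant")
        df = score_pvalues(L, space, reps=200, seed=5)
        weakest = df.loc[df.ncs.abs().idxmin()]
        if weakest.ncs == 0.0:
            assert weakest.p == 1.0

    def test_pvalues_antimonotone_in_abs_ncs(self):
        space = random_space(15, module_size=40, universe_size=800, seed=6)
        rng = np.random.default_rng(7)
        L = make_list(rng.permutation(np.asarray(space.universe)))
        df = score_pvalues(L, space, reps=200, seed=8)
        df = df.sort_values("ncs", key=lambda s: s.abs(), ascending=False)
        assert (df.p.diff().dropna() >= -1e-12).all()

    def test_reps_validation(self, space):
        L = make_list(space.universe)
        with pytest.raises(ValidationError):
            score_pvalues(L, space, reps=0)


class TestQueryTargets:
    def test_planted_query_rank_one_mimics_inhibition(self, default_truth, space):
        # synthetic perturbagens are annotated as inhibitors
        L = simulate_query(default_truth, "T002", "concordant")
        df = query_targets(L, space, reps=200, seed=9)
        assert df.iloc[0]["target"] == "T002"
        assert df.iloc[0]["rank"] == 1
        assert df.iloc[0]["direction"] == Direction.MIMICS_INHIBITION.value

    def test_reversed_query_opposes(self, default_truth, space):
        L = simulate_query(default_truth, "T002", "reversed")
        df = query_targets(L, space, reps=200, seed=10)
        row = df[df.target == "T002"].iloc[0]
        assert row.ncs < 0
        assert row.direction == Direction.OPPOSES.value

    def test_undetermined_without_annotation(self):
        space = random_space(5, module_size=20, universe_size=300, seed=11)
        rng = np.random.default_rng(12)
        L = make_list(rng.permutation(np.asarray(space.universe)))
        df = query_targets(L, space, reps=50, seed=13)
        pos = df[df.ncs > 0]
        assert (pos.direction == Direction.UNDETERMINED.value).all()

    def test_empty_space_errors(self):
        space = TargetSpace(gmps={}, universe=glist(10), module_size=2)
        with pytest.raises(ValidationError):
            query_targets(make_list(glist(10)), space)


class TestSelfRecovery:
    def test_strong_signal_rank_one(self, default_truth, compendium, space):
        from gmpsig.pipeline import group_signatures_by_target

        M, anns = compendium
        groups = group_signatures_by_target(M, anns)
        df = self_recovery_ranks(space, M, groups)
        assert (df["rank"] == 1).mean() >= 0.9

    def test_single_target_space_rank_one(self, default_truth, compendium):
        from gmpsig.pipeline import group_signatures_by_target

        M, anns = compendium
        groups = group_signatures_by_target(M, anns)
        tid = "T001"
        one = TargetSpace(
            gmps={
                tid: GeneModulePair(
                    target_id=tid,
                    up=default_truth.modules[tid][0],
                    down=default_truth.modules[tid][1],
                )
            },
            universe=list(default_truth.genes),
            module_size=default_truth.module_size,
        )
        df = self_recovery_ranks(one, M, {tid: groups[tid]})
        assert (df["rank"] == 1).all()

    def test_pure_noise_median_rank_central(self):
        space = random_space(20, module_size=30, universe_size=600, seed=14)
        rng = np.random.default_rng(15)
        from gmpsig.types import SignatureMatrix

        k = 40
        M = SignatureMatrix(
            gene_ids=list(space.universe),
            sig_ids=[f"s{j}" for j in range(k)],
            values=rng.normal(size=(600, k)),
        )
        groups = {
            tid: [f"s{2 * i}", f"s{2 * i + 1}"]
            for i, tid in enumerate(space.target_ids)
        }
        df = self_recovery_ranks(space, M, groups)
        med = df["rank"].median()
        assert 4 <= med <= 17  # near |space| / 2 under the null


class TestPrecisionRecall:
    def _results(self):
        return pd.DataFrame(
            {
                "query": ["q1", "q1", "q2", "q2"],
                "target": ["A", "B", "A", "B"],
                "ncs": [3.0, 1.0, -2.0, 0.5],
                "p": [0.001, 0.2, 0.01, 0.04],
            }
        )

    def test_cutoff_below_all_recall_one(self):
        truth = {("q1", "A"), ("q2", "A")}
        out = precision_recall_at_cutoffs(
            self._results(), truth, [0.0], alpha=0.05
        )
        assert out.recall.iloc[0] == pytest.approx(1.0)

    def test_cutoff_above_all(self):
        truth = {("q1", "A")}
        out = precision_recall_at_cutoffs(
            self._results(), truth, [10.0], alpha=0.05
        )
        assert out.recall.iloc[0] == 0.0
        assert np.isnan(out.precision.iloc[0])

    def test_monotone_trends_on_synthetic_benchmark(
        self, default_truth, space
    ):
        from scipy.stats import spearmanr

        rows = []
        truth_pairs = set()
        rng = np.random.default_rng(16)
        for tid in space.target_ids[:8]:
            L = simulate_query(default_truth, tid, "concordant", seed=rng)
            df = query_targets(L, space, reps=100, seed=rng, query_id=f"q_{tid}")
            rows.append(df)
            truth_pairs.add((f"q_{tid}", tid))
        results = pd.concat(rows, ignore_index=True)
        cutoffs = [0.0, 0.5, 1.0, 2.0, 4.0, 6.0]
        curve = precision_recall_at_cutoffs(results, truth_pairs, cutoffs)
        ok = curve.dropna(subset=["precision"])
        rho_p = spearmanr(ok.cutoff, ok.precision).statistic
        assert rho_p >= 0 or ok.precision.nunique() == 1
        assert (curve.recall.diff().dropna() <= 1e-12).all()
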