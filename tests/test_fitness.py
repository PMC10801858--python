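"""Log-enrichment fitness: formula, aggregation, landscape summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ribofitscape import (
    EnrichmentModel,
    FitnessResults,
    Reference,
    aggregate_replicates,
    fitness_by_hamming,
    per_position_mean_fitness,
    replicate_correlation,
)

from conftest import build_count_table


def _single_rep_table(pre_v, post_v, pre_wt, post_wt, label="A5G"):
    return build_count_table(
        "t1",
        {
            "wt": {("r1", "pre"): pre_wt, ("r1", "post"): post_wt},
            label: {("r1", "pre"): pre_v, ("r1", "post"): post_v},
        },
        ["r1"],
    )


class TestComputeFitness:
    def test_wildtype_is_exactly_zero_in_every_replicate(self, small_pipeline):
        res = small_pipeline["results"]
        for rep in res.replicates:
            assert res.replicate_fitness(rep)["wt"] == 0.0

    def test_log_ratio_formula(self):
        # ln((50/100)/(200/100)) = ln(0.25)
        res = EnrichmentModel(_single_rep_table(200, 50, 100, 100), pseudocount=0).fit()
        assert res.fitness("A5G") == pytest.approx(math.log(0.25), abs=1e-12)

    def test_depth_scaling_invariance(self):
        base = _single_rep_table(200, 50, 100, 100)
        scaled = build_count_table(
            "t1",
            {
                "wt": {("r1", "pre"): 100, ("r1", "post"): 1000},
                "A5G": {("r1", "pre"): 200, ("r1", "post"): 500},
            },
            ["r1"],
        )
        f1 = EnrichmentModel(base, pseudocount=0).fit().fitness("A5G")
        f2 = EnrichmentModel(scaled, pseudocount=0).fit().fitness("A5G")
        assert f1 == f2

    def test_zero_post_censored_without_pseudocount(self):
        res = EnrichmentModel(_single_rep_table(100, 0, 100, 100), pseudocount=0).fit()
        assert res.table.loc["A5G", "fitness_r1"] == -np.inf
        assert bool(res.table.loc["A5G", "censored_r1"])
        # a pseudocount removes the censoring
        res2 = EnrichmentModel(_single_rep_table(100, 0, 100, 100), pseudocount=0.5).fit()
        assert np.isfinite(res2.fitness("A5G"))

    def test_wt_zero_counts_with_zero_pseudocount_is_error(self):
        table = _single_rep_table(100, 10, 100, 0)
        with pytest.raises(ValueError, match="wild type"):
            EnrichmentModel(table, pseudocount=0).fit()

    def test_pseudocount_perturbation_shrinks_with_counts(self):
        """f(a=0.5) converges to f(a=0) as counts scale up."""
        devs = []
        for scale in (1, 10, 100):
            t = _single_rep_table(20 * scale, 5 * scale, 100 * scale, 100 * scale)
            f0 = EnrichmentModel(t, pseudocount=0).fit().fitness("A5G")
            fa = EnrichmentModel(t, pseudocount=0.5).fit().fitness("A5G")
            devs.append(abs(fa - f0))
        assert devs[0] > devs[1] > devs[2]

    def test_log_base_conversion(self):
        t = _single_rep_table(200, 50, 100, 100)
        ln = EnrichmentModel(t, pseudocount=0).fit().fitness("A5G")
        l2 = EnrichmentModel(t, pseudocount=0, log_base=2).fit().fitness("A5G")
        assert l2 == pytest.approx(ln / math.log(2))

    def test_pooled_mode_single_value(self):
        table = build_count_table(
            "t1",
            {
                "wt": {(r, p): 100 for r in ("r1", "r2") for p in ("pre", "post")},
                "A5G": {("r1", "pre"): 200, ("r1", "post"): 50,
                        ("r2", "pre"): 200, ("r2", "post"): 50},
            },
            ["r1", "r2"],
        )
        res = EnrichmentModel(table, pseudocount=0, pooled=True).fit()
        assert res.fitness("A5G") == pytest.approx(math.log(0.25))


class TestAggregateReplicates:
    def test_identical_values(self):
        mean, se, n = aggregate_replicates([-1.0, -1.0, -1.0])
        assert (mean, se, n) == (-1.0, 0.0, 3)

    def test_two_values_hand_formula(self):
        # sd of (0, -2) is sqrt(2); SE = sqrt(2)/sqrt(2) = 1
        mean, se, n = aggregate_replicates([0.0, -2.0])
        assert mean == -1.0 and se == pytest.approx(1.0) and n == 2

    def test_single_replicate_se_undefined(self):
        mean, se, n = aggregate_replicates([-0.7])
        assert mean == -0.7 and math.isnan(se) and n == 1

    def test_censored_values_excluded(self):
        mean, se, n = aggregate_replicates([-1.0, -np.inf, -3.0])
        assert mean == -2.0 and n == 2


class TestReplicateCorrelation:
    def test_identity_is_one(self):
        f = pd.Series([0.0, -1.0, -2.0, -0.5])
        assert replicate_correlation(f, f) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        f = pd.Series([0.0, -1.0, -2.0])
        assert replicate_correlation(f, -f) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        f1 = pd.Series([0.0, -1.0, -2.0])
        f2 = pd.Series([0.1, -0.9, -2.2])
        # independent oracle: direct evaluation of the product-moment formula
        x, y = f1.to_numpy(), f2.to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert replicate_correlation(f1, f2) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points_is_error(self):
        f = pd.Series([0.0, 1.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            replicate_correlation(f, f)

    def test_max_hamming_subset(self, small_pipeline):
        res = small_pipeline["results"]
        r_all = res.replicate_correlation("rep1", "rep2")
        r_low = res.replicate_correlation("rep1", "rep2", max_hamming=1)
        assert -1 <= r_all <= 1 and -1 <= r_low <= 1


class TestFitnessByHamming:
    def test_only_wildtype(self):
        table = build_count_table(
            "t1", {"wt": {("r1", "pre"): 10, ("r1", "post"): 10}}, ["r1"]
        )
        res = EnrichmentModel(table).fit()
        by_h = fitness_by_hamming(res)
        assert list(by_h.index) == [0]
        assert by_h.loc[0, "mean_fitness"] == 0.0 and by_h.loc[0, "n"] == 1

    def test_monotone_decline_on_deleterious_landscape(self, small_pipeline):
        """With mostly deleterious singles, class means decline with
        Hamming distance (negative rank correlation)."""
        by_h = small_pipeline["results"].by_hamming()
        rho, _ = spearmanr(by_h.index, by_h["mean_fitness"])
        assert rho < 0
        assert by_h.loc[0, "mean_fitness"] == 0.0


class TestPerPositionMeanFitness:
    def _results(self):
        ref = Reference("t1", "ACGT")
        rows = {
            "A1C": -1.0, "A1G": -2.0, "A1U": -3.0,   # full position: mean -2
            "C2A": -4.0, "C2G": -5.0, "C2U": -6.0,   # conserved position
            "ΔG3": -0.5,                              # deletion only
        }
        df = pd.DataFrame(
            {
                "subunit": "t1",
                "hamming": 1,
                "mean_fitness": pd.Series(rows),
                "se_fitness": 0.1,
                "n_replicates_observed": 3,
            }
        )
        return FitnessResults(df, None, ["r1"], 0.5, math.e), ref

    def test_mean_over_observed_substitutions(self):
        res, ref = self._results()
        pm = per_position_mean_fitness(res, ref)
        assert pm.loc[1, "mean_fitness"] == pytest.approx(-2.0)
        assert pm.loc[1, "n_obs"] == 3

    def test_missing_position_flagged_not_zero(self):
        res, ref = self._results()
        pm = per_position_mean_fitness(res, ref)
        assert math.isnan(pm.loc[4, "mean_fitness"]) and pm.loc[4, "n_obs"] == 0

    def test_deletions_reported_separately(self):
        res, ref = self._results()
        pm = per_position_mean_fitness(res, ref)
        assert math.isnan(pm.loc[3, "mean_fitness"])
        assert pm.loc[3, "deletion_fitness"] == pytest.approx(-0.5)

    def test_conserved_position_strongly_negative(self):
        # all three substitutions highly deleterious -> strongly negative mean,
        # the signature of an absolutely conserved nucleotide
        res, ref = self._results()
        pm = per_position_mean_fitness(res, ref)
        assert pm.loc[2, "mean_fitness"] == pytest.approx(-5.0)
        assert pm.loc[2, "mean_fitness"] < pm.loc[1, "mean_fitness"]


def test_parameter_recovery_error_free_reads(small_pipeline):
    """Estimated single-mutant fitness tracks truth closely on an
    error-free simulation at moderate depth."""
    res = small_pipeline["results"]
    truth = small_pipeline["landscape"].truth_table()
    joined = res.table.join(truth, how="inner", rsuffix="_t")
    singles = joined[joined["hamming"] == 1]
    r = np.corrcoef(singles["mean_fitness"], singles["f_true"])[0, 1]
    assert len(singles) == 456
    assert r >= 0.95


def test_fitness_tsv_round_trip(small_pipeline, tmp_path):
    res = small_pipeline["results"]
    path = tmp_path / "fitness.tsv"
    res.to_tsv(path)
    back = FitnessResults.from_tsv(path)
    assert back.replicates == res.replicates
    pd.testing.assert_series_equal(back.mean_fitness, res.mean_fitness)


def test_summary_mentions_key_quantities(small_pipeline):
    text = small_pipeline["results"].summary()
    assert "replicate" in text and "Hamming" in text
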