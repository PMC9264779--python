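import itertools
import math

import numpy as np
import pandas as pd
import pytest

import fishdiv as fd
from conftest import make_checklist


def brute_delta_lambda(assemblage, checklist):
    """Pair-by-pair enumeration, independent of the matrix implementation."""
    weights = []
    ranks = ("genus", "family", "order", "class", "phylum")
    w_by_depth = (16.667, 33.333, 50.0, 66.667, 83.333, 100.0)
    for a, b in itertools.combinations(assemblage, 2):
        ra = checklist.frame.loc[a]
        rb = checklist.frame.loc[b]
        for d, rank in enumerate(ranks):
            if ra[rank] == rb[rank]:
                weights.append(w_by_depth[d])
                break
        else:
            weights.append(w_by_depth[5])
    delta = sum(weights) / len(weights)
    lam = sum((w - delta) ** 2 for w in weights) / len(weights)
    return delta, lam


class TestPairwiseWeight:
    @pytest.mark.parametrize("pair,expected", [
        (("s1", "s2"), 16.667),   # congeneric
        (("s1", "s3"), 33.333),   # confamilial
        (("s1", "s4"), 50.000),   # same order, different family
        (("s1", "s5"), 66.667),   # same class, different order
        (("s1", "s7"), 83.333),   # same phylum, different class
        (("s1", "s1"), 0.0),
    ])
    def test_rank_path_weights(self, tiny_checklist, pair, expected):
        assert fd.pairwise_weight(*pair, tiny_checklist) == expected

    def test_symmetry(self, tiny_checklist):
        assert fd.pairwise_weight("s1", "s7", tiny_checklist) == \
            fd.pairwise_weight("s7", "s1", tiny_checklist)

    def test_unknown_species_errors(self, tiny_checklist):
        with pytest.raises(fd.ValidationError):
            fd.pairwise_weight("s1", "nope", tiny_checklist)

    def test_custom_step_scheme(self, tiny_checklist):
        scheme = fd.PathWeightScheme.from_step(10.0)
        assert fd.pairwise_weight("s1", "s2", tiny_checklist, scheme) == 10.0


class TestDeltaLambda:
    def test_two_congeners(self, tiny_checklist):
        assert fd.delta_plus(["s1", "s2"], tiny_checklist) == 16.667
        assert fd.lambda_plus(["s1", "s2"], tiny_checklist) == 0.0

    def test_hand_computed_triple(self):
        cl = make_checklist([
            ("a", "G1", "F1", "O1", "C1", "P1"),
            ("b", "G1", "F1", "O1", "C1", "P1"),
            ("c", "G2", "F2", "O1", "C1", "P1"),
        ])
        # pair weights (16.667, 50, 50)
        assert fd.delta_plus(list("abc"), cl) == pytest.approx(38.889, abs=1e-3)
        assert fd.lambda_plus(list("abc"), cl) == pytest.approx(246.91, abs=1e-2)

    def test_constant_weights_mean(self, tiny_checklist):
        # s5, s7: different classes -> all pairs at 83.333? use three mutual 50s
        assert fd.delta_plus(["s5", "s7"], tiny_checklist) == 83.333

    def test_fewer_than_two_species_errors(self, tiny_checklist):
        with pytest.raises(fd.ValidationError):
            fd.delta_plus(["s1"], tiny_checklist)

    def test_matches_brute_force_for_all_small_assemblages(self, tiny_checklist):
        """Exhaustive oracle check over every assemblage of the 8-species pool."""
        spp = list(tiny_checklist.species)
        for r in range(2, len(spp) + 1):
            for combo in itertools.combinations(spp, r):
                d_exp, l_exp = brute_delta_lambda(combo, tiny_checklist)
                res = fd.tax_distinctness(combo, tiny_checklist)
                assert res.delta_plus == pytest.approx(d_exp, abs=1e-10)
                assert res.lambda_plus == pytest.approx(l_exp, abs=1e-9)

    def test_subset_average_unbiasedness(self, tiny_checklist):
        """Mean of Delta+ over all C(S,m) subsets equals the master Delta+."""
        spp = list(tiny_checklist.species)
        master = fd.delta_plus(spp, tiny_checklist)
        for m in (2, 3, 5, 7):
            vals = [fd.delta_plus(c, tiny_checklist)
                    for c in itertools.combinations(spp, m)]
            assert np.mean(vals) == pytest.approx(master, abs=1e-10)

    def test_delta_within_weight_range(self, guangxi_data):
        cl, mx = guangxi_data
        for site in mx.sites[:4]:
            d = fd.delta_plus(list(mx.site_species(site)), cl)
            assert 16.667 <= d <= 100.0


class TestFunnel:
    def test_m_equals_s_collapses_to_master(self, tiny_checklist):
        fun = fd.funnel(tiny_checklist, sizes=[8], n_draws=50, seed=1)
        row = fun.table.iloc[0]
        assert row["delta_lo"] == row["delta_mean"] == row["delta_hi"] \
            == pytest.approx(fun.master_delta)
        assert row["lambda_mean"] == pytest.approx(fun.master_lambda)

    def test_same_seed_identical(self, tiny_checklist):
        a = fd.funnel(tiny_checklist, [3, 5], n_draws=200, seed=9)
        b = fd.funnel(tiny_checklist, [3, 5], n_draws=200, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_draw_mean_matches_exact_enumeration(self, tiny_checklist):
        """MC mean at m=3 agrees with the full C(8,3) enumeration."""
        spp = list(tiny_checklist.species)
        exact = np.mean([fd.delta_plus(c, tiny_checklist)
                         for c in itertools.combinations(spp, 3)])
        fun = fd.funnel(tiny_checklist, [3], n_draws=4000, seed=2)
        row = fun.table.iloc[0]
        se = row["delta_sd"] / math.sqrt(fun.n_draws)
        assert abs(row["delta_mean"] - exact) < 4 * se

    def test_out_of_range_size_errors(self, tiny_checklist):
        with pytest.raises(fd.ValidationError):
            fd.funnel(tiny_checklist, [1], n_draws=10, seed=0)

    def test_funnel_width_shrinks_with_m(self, guangxi_data):
        cl, _ = guangxi_data
        fun = fd.funnel(cl, sizes=[20, 60, 120, 185], n_draws=10_000, seed=7)
        widths = (fun.table["delta_hi"] - fun.table["delta_lo"]).to_numpy()
        assert (np.diff(widths) <= 0).all()


class TestClassification:
    def test_full_pool_site_is_within(self, tiny_checklist):
        frame = pd.DataFrame({"all": [1] * 8, "two": [1, 1, 0, 0, 0, 0, 0, 0]},
                             index=tiny_checklist.species.rename("species_id"))
        mx = fd.OccurrenceMatrix(frame, tiny_checklist)
        fun = fd.funnel(tiny_checklist, [2, 8], n_draws=2000, seed=3)
        out = fd.classify_sites(fun, mx, tiny_checklist)
        assert out.loc["all", "delta_status"] == "within"

    def test_single_genus_site_flagged_below(self, guangxi_data):
        cl, _ = guangxi_data
        big_genus = cl.frame.groupby("genus").size().idxmax()
        spp = list(cl.species_in("genus", big_genus))
        frame = pd.DataFrame(
            {"mono": [1 if s in spp else 0 for s in cl.species],
             "rest": [1] * len(cl.species)},
            index=cl.species.rename("species_id"))
        mx = fd.OccurrenceMatrix(frame, cl)
        fun = fd.funnel(cl, [len(spp), len(cl.species)], n_draws=2000, seed=5)
        out = fd.classify_sites(fun, mx, cl)
        # a purely congeneric assemblage sits far below the random funnel
        assert out.loc["mono", "delta_plus"] == 16.667
        assert out.loc["mono", "delta_status"] == "below"

    def test_site_below_two_species_unclassifiable(self, tiny_checklist):
        frame = pd.DataFrame({"solo": [1] + [0] * 7, "all": [1] * 8},
                             index=tiny_checklist.species.rename("species_id"))
        mx = fd.OccurrenceMatrix(frame, tiny_checklist)
        fun = fd.funnel(tiny_checklist, [2, 8], n_draws=500, seed=1)
        out = fd.classify_sites(fun, mx, tiny_checklist)
        assert out.loc["solo", "delta_status"] == "unclassifiable"
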