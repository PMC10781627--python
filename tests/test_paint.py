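import itertools

import numpy as np
import pytest

from ibdstruct import (EmptyProfileError, fit_ancestry, fit_source_sets,
                       jackknife_se, painting_profile, source_profiles,
                       uniform_map)
from ibdstruct.paint import PaintingProfile, SourceProfiles


def grid_search_fit(S, p, step=0.01):
    """Independent simplex grid-search oracle for the constrained fit."""
    k = S.shape[1]
    grid = np.arange(0.0, 1.0 + 1e-9, step)
    if k == 2:
        combos = ([w, 1.0 - w] for w in grid)
    elif k == 3:
        combos = ([w1, w2, 1.0 - w1 - w2]
                  for w1 in grid for w2 in grid if w1 + w2 <= 1.0 + 1e-9)
    else:
        raise ValueError("oracle supports 2-3 sources")
    best, best_r = None, np.inf
    for w in combos:
        w = np.asarray(w)
        r = np.linalg.norm(S @ w - p)
        if r < best_r - 1e-15:
            best, best_r = w, r
    return best


def _toy_segments(gmap, sharing):
    """sharing: list of (target, donor, chrom, start_cm, length_cm)."""
    from ibdstruct import IBDSegment
    segs = []
    for a, b, chrom, start_cm, length_cm in sharing:
        s = gmap.cm_to_bp(chrom, start_cm)
        e = gmap.cm_to_bp(chrom, start_cm + length_cm)
        segs.append(IBDSegment(a, b, chrom, s, e, gmap.segment_cm(chrom, s, e), 5.0))
    return segs


@pytest.fixture
def map2():
    return uniform_map(2, 100_000_000, 100.0)


class TestPaintingProfile:
    def test_normalized_two_group_profile(self, map2):
        donors = {"a1": "A", "b1": "B"}
        segs = _toy_segments(map2, [("t", "a1", "1", 0, 30),
                                    ("t", "b1", "1", 30, 70)])
        prof = painting_profile("t", segs, donors, map2)
        assert prof.groups == ("A", "B")
        assert prof.genome_wide == pytest.approx([0.3, 0.7])

    def test_own_segments_never_contribute(self, map2):
        donors = {"t": "A", "a1": "A"}
        segs = _toy_segments(map2, [("t", "a1", "1", 0, 10)])
        prof = painting_profile("t", segs, donors, map2)
        # the target's own group total comes only from the other member
        assert prof.genome_wide == pytest.approx([1.0])

    def test_self_only_sharing_is_empty_profile(self, map2):
        donors = {"t": "A"}
        segs = _toy_segments(map2, [("t", "t", "1", 0, 10)])  # HBD only
        with pytest.raises(EmptyProfileError):
            painting_profile("t", segs, donors, map2)

    def test_hand_enumerated_three_group_totals(self, map2):
        donors = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        segs = _toy_segments(map2, [
            ("t", "a1", "1", 0, 12), ("t", "a2", "1", 20, 8),
            ("t", "b1", "2", 0, 25), ("t", "c1", "2", 30, 5),
        ])
        prof = painting_profile("t", segs, donors, map2)
        totals = prof.per_chromosome.sum(axis=0)
        assert totals["A"] == pytest.approx(20.0)
        assert totals["B"] == pytest.approx(25.0)
        assert totals["C"] == pytest.approx(5.0)
        assert prof.genome_wide.sum() == pytest.approx(1.0)

    def test_per_chromosome_totals_sum_to_genome_wide(self, map2):
        donors = {"a1": "A", "b1": "B"}
        segs = _toy_segments(map2, [("t", "a1", "1", 0, 30),
                                    ("t", "b1", "2", 0, 50)])
        prof = painting_profile("t", segs, donors, map2)
        totals = prof.per_chromosome.sum(axis=0).to_numpy()
        assert prof.genome_wide == pytest.approx(totals / totals.sum())


class TestSourceProfiles:
    def test_single_member_column_equals_member_profile(self, map2):
        donors = {"a1": "A", "b1": "B"}
        segs = _toy_segments(map2, [("a1", "b1", "1", 0, 40)])
        srcs = source_profiles(["A"], segs, donors, map2)
        member = painting_profile("a1", segs, donors, map2)
        assert srcs.matrix()[:, 0] == pytest.approx(member.genome_wide)

    def test_mean_of_two_distinct_members(self, map2):
        donors = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        segs = _toy_segments(map2, [
            ("a1", "b1", "1", 0, 30), ("a1", "c1", "1", 40, 10),  # (0.75, 0.25)
            ("a2", "b1", "2", 0, 10), ("a2", "c1", "2", 20, 30),  # (0.25, 0.75)
        ])
        srcs = source_profiles(["A"], segs, donors, map2)
        col = srcs.to_dataframe()["A"]
        assert col["B"] == pytest.approx(0.5)
        assert col["C"] == pytest.approx(0.5)

    def test_empty_source_group_rejected(self, map2):
        with pytest.raises(EmptyProfileError):
            source_profiles(["A"], [], {"b1": "B"}, map2)


class TestFitAncestry:
    def test_identity_on_orthogonal_sources(self):
        S = np.eye(3)
        fit = fit_ancestry(S[:, 1], S)
        assert fit.proportions == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_mixture_recovered(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        p = 0.3 * S[:, 0] + 0.7 * S[:, 1]
        fit = fit_ancestry(p, S)
        assert fit.proportions == pytest.approx([0.3, 0.7], abs=1e-9)

    def test_all_zero_source_column_rejected(self):
        S = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            fit_ancestry(np.array([1.0, 0.0]), S)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_grid_search_oracle(self, k):
        rng = np.random.default_rng(17)
        for _ in range(20):
            S = rng.dirichlet(np.ones(5), size=k).T
            w_true = rng.dirichlet(np.ones(k))
            p = S @ w_true + rng.normal(0, 0.02, 5)
            p = np.clip(p, 0, None)
            p = p / p.sum()
            fit = fit_ancestry(p, S)
            oracle = grid_search_fit(S, p)
            assert np.abs(fit.proportions - oracle).max() <= 0.01 + 1e-9

    def test_adding_true_source_never_increases_residual(self):
        rng = np.random.default_rng(23)
        S = rng.dirichlet(np.ones(6), size=3).T
        p = S @ np.array([0.5, 0.3, 0.2])
        small = fit_ancestry(p, S[:, :2])
        full = fit_ancestry(p, S)
        assert full.residual <= small.residual + 1e-12


class TestJackknife:
    def _profile(self, per_chrom, groups=("A", "B")):
        import pandas as pd
        table = pd.DataFrame(per_chrom, columns=list(groups))
        table.index = [str(i + 1) for i in range(len(per_chrom))]
        totals = table.sum(axis=0).to_numpy()
        return PaintingProfile(target="t", groups=tuple(groups),
                               genome_wide=totals / totals.sum(),
                               per_chromosome=table)

    def _sources(self, member_tables, groups=("A", "B")):
        import pandas as pd
        tabs = {}
        for src, rows in member_tables.items():
            t = pd.DataFrame(rows, columns=list(groups))
            t.index = [str(i + 1) for i in range(len(rows))]
            tabs[src] = (t,)
        return SourceProfiles(groups=tuple(groups),
                              sources=tuple(member_tables), member_tables=tabs)

    def test_identical_chromosomes_give_zero_se(self):
        gmap = uniform_map(4, 100_000_000, 100.0)
        prof = self._profile([[30.0, 10.0]] * 4)
        srcs = self._sources({"A": [[40.0, 5.0]] * 4, "B": [[5.0, 40.0]] * 4})
        se = jackknife_se(prof, srcs, gmap)
        assert se == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_equal_weights_reduce_to_unweighted_jackknife(self):
        gmap = uniform_map(2, 100_000_000, 100.0)
        prof = self._profile([[30.0, 10.0], [20.0, 25.0]])
        srcs = self._sources({"A": [[40.0, 5.0], [35.0, 8.0]],
                              "B": [[5.0, 40.0], [6.0, 30.0]]})
        se = jackknife_se(prof, srcs, gmap)
        # unweighted delete-one: var = (g-1)/g * sum (theta_i - mean)^2
        loo = []
        for c in ("1", "2"):
            p = prof.excluding_chromosome(c)
            loo.append(fit_ancestry(p, srcs.matrix(exclude_chromosome=c)).proportions)
        loo = np.array(loo)
        expected = np.sqrt(0.5 * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
        assert se == pytest.approx(expected, abs=1e-9)

    def test_single_chromosome_rejected(self):
        gmap = uniform_map(1, 100_000_000, 100.0)
        prof = self._profile([[30.0, 10.0]])
        srcs = self._sources({"A": [[40.0, 5.0]], "B": [[5.0, 40.0]]})
        with pytest.raises(ValueError):
            jackknife_se(prof, srcs, gmap)


class TestFitSourceSets:
    def test_one_row_per_target_set_source(self, map2):
        donors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        segs = _toy_segments(map2, [
            ("t", "a1", "1", 0, 30), ("t", "b1", "1", 40, 20),
            ("a1", "a2", "2", 0, 10), ("b1", "b2", "2", 20, 10),
            ("a1", "b1", "2", 40, 2),
        ])
        fits = fit_source_sets(["t"], {"both": ["A", "B"], "justA": ["A"]},
                               segs, donors, map2, jackknife=False)
        assert len(fits) == 3  # 2 sources + 1 source
        assert set(fits["source_set"]) == {"both", "justA"}

    def test_unknown_group_in_set_rejected(self, map2):
        with pytest.raises(KeyError):
            fit_source_sets(["t"], {"bad": ["Z"]}, [], {"a1": "A"}, map2)

    def test_proportions_sum_to_one(self, map2):
        donors = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        segs = _toy_segments(map2, [
            ("t", "a1", "1", 0, 30), ("t", "b1", "1", 40, 20),
            ("a1", "a2", "2", 0, 10), ("b1", "b2", "2", 20, 10),
            ("a1", "b1", "2", 40, 2),
        ])
        fits = fit_source_sets(["t"], {"both": ["A", "B"]}, segs, donors, map2,
                               jackknife=False)
        assert fits["proportion"].sum() == pytest.approx(1.0, abs=1e-8)


def test_true_source_set_fits_better_than_wrong_one():
    """A target generated from groups G1+G2 is fit with lower residual by
    the {G1,G2} set than by the disjoint {G3} set, replicate after
    replicate."""
    from ibdstruct import default_map
    from ibdstruct.simulate import CohortSpec, simulate_group_ibd

    gmap = default_map()
    wins = 0
    n_reps = 10
    for seed in range(n_reps):
        spec = CohortSpec(group_sizes=(10, 10, 10), lambda_in=6.0,
                          lambda_out=0.3, admixed_targets=((0.5, 0.5, 0.0),),
                          seed=seed)
        segs, truth = simulate_group_ibd(spec, gmap)
        donors = {r["sample"]: r["group"] for _, r in truth.iterrows()
                  if r["group"] != "admixed"}
        fits = fit_source_sets(["ADM01"], {"true": ["G1", "G2"],
                                           "wrong": ["G3"]},
                               segs, donors, gmap, jackknife=False)
        res = fits.groupby("source_set")["residual"].first()
        wins += int(res["true"] < res["wrong"])
    assert wins >= int(0.95 * n_reps)
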