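import numpy as np
import pytest

from cladebin.binning import (
    OUTSIDE,
    PlacementEngine,
    attachment_scores_naive,
    bin_all,
    bootstrap_placement,
    place_query,
)
from cladebin.formats_io import MISSING, MorphMatrix
from cladebin.synthetic import default_study_scenario
from cladebin.weighting import CharacterWeights, ml_weights, mp_weights


@pytest.fixture(scope="module")
def mp_w(scenario):
    return mp_weights(scenario.ref_tree, scenario.matrix)


@pytest.fixture(scope="module")
def engine(scenario):
    return PlacementEngine(scenario.ref_tree, scenario.matrix)


def with_extra_row(matrix, label, row):
    return MorphMatrix(
        taxa=matrix.taxa + [label],
        characters=list(matrix.characters),
        states=np.vstack([matrix.states, np.asarray(row, dtype=np.int16)]),
        kinds=list(matrix.kinds),
        state_maps=[dict(m) for m in matrix.state_maps],
    )


# module-scoped copy of the session fixture so module fixtures can use it
@pytest.fixture(scope="module")
def scenario():
    return default_study_scenario(seed=1)


class TestPlaceQuery:
    def test_incremental_engine_matches_attach_and_rescore(
        self, scenario, mp_w, engine
    ):
        """The inside/outside DP must equal physically attaching the query
        on every edge and re-scoring all characters from scratch."""
        sol = scenario.solutions["4-clade"]
        for query in scenario.query_taxa[:3]:
            fast = place_query(
                scenario.ref_tree, sol, mp_w, scenario.matrix, query,
                engine=engine,
            ).edge_scores
            naive = attachment_scores_naive(
                scenario.ref_tree, mp_w, scenario.matrix, query
            )
            assert fast == pytest.approx(naive, abs=1e-9)

    def test_clone_of_reference_taxon_joins_its_group(self, scenario):
        sol = scenario.solutions["4-clade"]
        clone = scenario.matrix.row("R01").copy()
        m2 = with_extra_row(scenario.matrix, "clone", clone)
        w = mp_weights(scenario.ref_tree, m2)
        res = place_query(scenario.ref_tree, sol, w, m2, "clone")
        assert res.assigned_group == sol.assignment["R01"]

    def test_zero_weight_character_is_inert(self, scenario, mp_w, engine):
        sol = scenario.solutions["4-clade"]
        query = scenario.query_taxa[0]
        base = place_query(
            scenario.ref_tree, sol, mp_w, scenario.matrix, query,
            engine=engine,
        ).edge_scores
        # duplicate the first character but give the copy zero weight
        m2 = MorphMatrix(
            taxa=list(scenario.matrix.taxa),
            characters=scenario.matrix.characters + ["dup"],
            states=np.hstack(
                [scenario.matrix.states, scenario.matrix.states[:, :1]]
            ),
            kinds=scenario.matrix.kinds + [scenario.matrix.kinds[0]],
        )
        w2 = CharacterWeights(
            scheme="MP",
            characters=m2.characters,
            weights=np.append(mp_w.weights, 0.0),
            diagnostics=mp_w.diagnostics,
        )
        again = place_query(scenario.ref_tree, sol, w2, m2, query).edge_scores
        assert again == pytest.approx(base, abs=1e-12)

    def test_scores_bounded_below_by_reference_scores(
        self, scenario, mp_w, engine
    ):
        """Attaching a taxon can only add steps: every edge score is at
        least the weighted sum of the characters' plain tree scores."""
        sol = scenario.solutions["2-clade"]
        lower = float(np.dot(mp_w.weights, engine.base_steps))
        for query in scenario.query_taxa[:10]:
            scores = place_query(
                scenario.ref_tree, sol, mp_w, scenario.matrix, query,
                engine=engine,
            ).edge_scores
            assert scores.min() >= lower - 1e-9

    def test_all_missing_query_rejected(self, scenario, mp_w):
        m2 = with_extra_row(
            scenario.matrix, "ghost", [MISSING] * scenario.matrix.n_chars
        )
        with pytest.raises(ValueError, match="non-missing"):
            place_query(
                scenario.ref_tree, scenario.solutions["4-clade"], mp_w, m2,
                "ghost",
            )

    def test_zero_total_weight_rejected(self, scenario):
        w0 = CharacterWeights(
            scheme="MP",
            characters=list(scenario.matrix.characters),
            weights=np.zeros(scenario.matrix.n_chars),
            diagnostics=None,
        )
        with pytest.raises(ValueError, match="no informative weighted"):
            place_query(
                scenario.ref_tree, scenario.solutions["4-clade"], w0,
                scenario.matrix, scenario.query_taxa[0],
            )


class TestBootstrap:
    def test_single_replicate_support_is_indicator(
        self, scenario, mp_w, engine
    ):
        res = bootstrap_placement(
            scenario.ref_tree, scenario.solutions["4-clade"], mp_w,
            scenario.matrix, scenario.query_taxa[0],
            n_boot=1, seed=3, engine=engine,
        )
        values = sorted(res.support.values())
        assert values[-1] == 1.0 and sum(values) == pytest.approx(1.0)

    def test_supports_form_a_distribution(self, scenario, mp_w, engine):
        for query in scenario.query_taxa[:5]:
            res = bootstrap_placement(
                scenario.ref_tree, scenario.solutions["4-clade"], mp_w,
                scenario.matrix, query, n_boot=50, seed=3, engine=engine,
            )
            assert sum(res.support.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0.0 <= s <= 1.0 for s in res.support.values())
            assert set(res.support) == set(
                scenario.solutions["4-clade"].groups
            ) | {OUTSIDE}

    def test_fixed_seed_reproducible(self, scenario, mp_w, engine):
        kwargs = dict(n_boot=30, seed=19, engine=engine)
        a = bootstrap_placement(
            scenario.ref_tree, scenario.solutions["4-clade"], mp_w,
            scenario.matrix, scenario.query_taxa[1], **kwargs,
        )
        b = bootstrap_placement(
            scenario.ref_tree, scenario.solutions["4-clade"], mp_w,
            scenario.matrix, scenario.query_taxa[1], **kwargs,
        )
        assert a.support == b.support


@pytest.fixture(scope="module")
def report(scenario):
    return bin_all(
        scenario.ref_tree,
        list(scenario.solutions.values()),
        scenario.matrix,
        scenario.query_taxa,
        n_random=50,
        n_boot=50,
        seed=5,
    )


class TestBinAll:
    def test_counts_sum_to_query_total(self, scenario, report):
        for sol in scenario.solutions.values():
            for scheme in ("ML", "MP"):
                sel = report.counts[
                    (report.counts.solution == sol.name)
                    & (report.counts.scheme == scheme)
                ].set_index("group")["count"]
                group_sum = sum(sel[g] for g in sol.groups) + sel[OUTSIDE]
                assert group_sum == sel["Total"] == len(scenario.query_taxa)
                assert sel["Conflicting"] <= sel["Total"]

    def test_conflicts_are_scheme_disagreements(self, report):
        a = report.assignments
        for sol_name, conflict_list in report.conflicts.items():
            ml = a[(a.solution == sol_name) & (a.scheme == "ML")]
            mp = a[(a.solution == sol_name) & (a.scheme == "MP")]
            merged = ml.merge(mp, on="query", suffixes=("_ml", "_mp"))
            expect = sorted(
                merged[merged.group_ml != merged.group_mp]["query"]
            )
            assert conflict_list == expect

    def test_noise_free_full_signal_recovers_everything(self):
        """clade_signal=1, noise=0: placement recovery is 100% and the
        two weighting schemes never disagree."""
        sc = default_study_scenario(seed=4, clade_signal=1.0, noise_rate=0.0)
        rep = bin_all(
            sc.ref_tree, [sc.solutions["4-clade"]], sc.matrix, sc.query_taxa,
            n_random=50, n_boot=50, seed=7,
        )
        truth = sc.true_query_groups["4-clade"]
        for scheme in ("ML", "MP"):
            sub = rep.assignments[rep.assignments.scheme == scheme]
            assert all(truth[r.query] == r.group for r in sub.itertuples())
        assert rep.conflicts["4-clade"] == []
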