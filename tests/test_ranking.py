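"""Candidate ranking, the dependence filter, and improvement evaluation."""

import pytest
from hypothesis import given, settings, strategies as st

import editotype as et
from editotype.pprcode import PPRMotif, PPRProtein


def make_protein(subfamily="E+", pid="PPR1"):
    return PPRProtein(
        protein_id=pid,
        subfamily=subfamily,
        motifs=(
            PPRMotif(1, "P", "N", "D"),
            PPRMotif(2, "P", "T", "D"),
        ),
    )


class TestRankTargets:
    def test_single_candidate_rank_one(self):
        (r,) = et.rank_targets("p", {"s1"}, {"s1": 0.5})
        assert r.rank_full == 1

    def test_distinct_scores_rank_descending(self):
        ranking = et.rank_targets(
            "p", {"a", "b", "c"}, {"a": 1.0, "b": 3.0, "c": 2.0}
        )
        assert [(r.site_id, r.rank_full) for r in ranking] == [
            ("b", 1), ("c", 2), ("a", 3)
        ]

    def test_competition_ranking_ties_share_min_rank(self):
        ranking = et.rank_targets(
            "p", {"a", "b", "c", "d"}, {"a": 3.0, "b": 3.0, "c": 1.0, "d": 1.0}
        )
        assert [r.rank_full for r in ranking] == [1, 1, 3, 3]
        assert [r.site_id for r in ranking] == ["a", "b", "c", "d"]  # tie-break by id

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            et.rank_targets("p", set(), {})

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="no score"):
            et.rank_targets("p", {"a", "b"}, {"a": 1.0})

    def test_subset_reranking_matches_independent_sort(self):
        scores = {f"s{i}": ((i * 13) % 7) + 0.01 * i for i in range(20)}
        subset = {f"s{i}" for i in range(0, 20, 3)}
        ranking = et.rank_targets("p", subset, scores)
        resorted = sorted(subset, key=lambda s: (-scores[s], s))
        assert [r.site_id for r in ranking] == resorted
        for r in ranking:
            assert r.rank_full == 1 + sum(
                scores[o] > r.score for o in subset
            )


class TestDependenceFilter:
    def full_ranking(self, scores):
        return et.rank_targets("PPR1", set(scores), scores)

    def test_constructed_18_to_6(self):
        """A true target ranked 18 among many candidates climbs to 6 when
        12 of the 17 better-scoring decoys are filtered out."""
        scores = {f"d{i:02d}": 100.0 - i for i in range(17)}  # 17 better decoys
        scores["target"] = 50.0
        scores.update({f"w{i:02d}": 10.0 - i for i in range(10)})  # worse decoys
        full = self.full_ranking(scores)
        assert next(r.rank_full for r in full if r.site_id == "target") == 18
        keep_better = [f"d{i:02d}" for i in range(5)]  # 12 of 17 removed
        dependent = set(keep_better) | {"target"} | {"w00", "w01"}
        filtered = et.apply_dependence_filter(make_protein(), full, dependent)
        assert next(r.rank_filtered for r in filtered if r.site_id == "target") == 6

    def test_rank_one_stays_rank_one(self):
        scores = {"t": 9.0, "a": 5.0, "b": 1.0}
        filtered = et.apply_dependence_filter(
            make_protein(), self.full_ranking(scores), {"t", "b"}
        )
        assert next(r.rank_filtered for r in filtered if r.site_id == "t") == 1

    def test_identity_filter_preserves_ranks(self):
        scores = {f"s{i}": float(i % 5) for i in range(12)}
        full = self.full_ranking(scores)
        filtered = et.apply_dependence_filter(make_protein(), full, set(scores))
        assert [(r.site_id, r.rank_filtered) for r in filtered] == [
            (r.site_id, r.rank_full) for r in full
        ]

    @pytest.mark.parametrize("subfamily", ["E", "DYW", "P", "other"])
    def test_non_eplus_protein_refused(self, subfamily):
        full = self.full_ranking({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="only to E\\+"):
            et.apply_dependence_filter(make_protein(subfamily), full, {"a"})

    def test_dependent_ids_outside_candidates_rejected(self):
        full = self.full_ranking({"a": 1.0})
        with pytest.raises(ValueError, match="outside"):
            et.apply_dependence_filter(make_protein(), full, {"a", "zzz"})

    @given(
        scores=st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            st.floats(-10, 10, allow_nan=False),
            min_size=2, max_size=12,
        ),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=200)
    def test_filter_monotonicity_property(self, scores, data):
        """For any score map and subset, each retained site's rank in the
        subset never exceeds its rank in the superset."""
        ids = sorted(scores)
        subset = set(data.draw(st.lists(st.sampled_from(ids), min_size=1, unique=True)))
        full = et.rank_targets("PPR1", set(ids), scores)
        filtered = et.apply_dependence_filter(make_protein(), full, subset)
        assert {r.site_id for r in filtered} == subset
        for r in filtered:
            assert r.rank_filtered <= r.rank_full


class TestEvaluateImprovement:
    def test_all_equal_pairs(self):
        summary = et.evaluate_improvement([(3, 3), (5, 5)])
        assert summary["n_improved"] == 0
        assert summary["n_unchanged"] == 2

    def test_counts_and_medians(self):
        summary = et.evaluate_improvement([(10, 2), (4, 4), (8, 1)])
        assert summary["n"] == 3
        assert summary["n_improved"] == 2
        assert summary["median_full"] == 8.0
        assert summary["median_filtered"] == 2.0
        assert summary["improvement_fraction"] == pytest.approx(2 / 3)

    def test_worsened_pair_is_integrity_error(self):
        with pytest.raises(ValueError, match="cannot demote"):
            et.evaluate_improvement([(3, 5)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            et.evaluate_improvement([])

    def test_reported_rank_pairs_never_worsen(self):
        """The 45 published (full, DYW2-filtered) rank pairs replay
        cleanly: no row worsens and most improve."""
        from editotype.datasets import eplus_rank_pairs

        pairs = list(
            eplus_rank_pairs()[["rank_full", "rank_dyw2"]].itertuples(index=False)
        )
        summary = et.evaluate_improvement(pairs)
        assert summary["n"] == 45
        assert summary["n_improved"] + summary["n_unchanged"] == 45
        assert summary["median_filtered"] <= summary["median_full"]


class TestShortlist:
    def panel(self):
        return [
            make_protein("E+", "EPLUS1"),
            make_protein("DYW", "DYW_A"),
            make_protein("E", "E_A"),
        ]

    def test_independent_site_drops_eplus(self):
        shortlists = et.candidate_shortlist_for_non_eplus(
            ["ind1", "dep1"], {"dep1"}, self.panel()
        )
        assert shortlists["ind1"] == ["DYW_A", "E_A"]

    def test_dependent_site_keeps_all_subfamilies(self):
        shortlists = et.candidate_shortlist_for_non_eplus(
            ["ind1", "dep1"], {"dep1"}, self.panel()
        )
        assert shortlists["dep1"] == ["EPLUS1", "DYW_A", "E_A"]

    def test_empty_panel_gives_empty_shortlists(self):
        shortlists = et.candidate_shortlist_for_non_eplus(["s1"], set(), [])
        assert shortlists == {"s1": []}

    def test_missing_subfamily_kept_with_warning(self, caplog):
        import types

        anon = types.SimpleNamespace(protein_id="ANON", subfamily="")
        with caplog.at_level("WARNING", logger="editotype.ranking"):
            shortlists = et.candidate_shortlist_for_non_eplus(
                ["ind1"], set(), [anon]
            )
        assert shortlists["ind1"] == ["ANON"]
        assert "no subfamily" in caplog.text


class TestEndToEndRecovery:
    def test_filtered_mean_rank_improves_on_planted_panel(self, code_table):
        """Planted E+ proteins with >= 50% of candidates filtered out:
        mean true-target rank under the filtered set <= under the full
        set, strictly when a better-scoring decoy was removed."""
        cfg = et.SimulationConfig(
            genome_length=3_000, n_sites=40, coverage_mean=200,
            n_replicates=2, seed=77,
        )
        fx = et.generate_fixture(cfg, n_planted_ppr=8)
        dependent = {s.site_id for s in fx.sites[:16]}  # 40% retained
        full_ranks, filtered_ranks, decoy_removed = [], [], False
        for protein in fx.ppr_panel:
            target = fx.ppr_targets[protein.protein_id]
            scores = et.scan_sites(protein, fx.sites, fx.genome, code_table)
            full = et.rank_targets(protein, et.CandidateSet("full", set(scores)), scores)
            filtered = et.apply_dependence_filter(
                protein, full, dependent & set(scores)
            )
            rf = next(r.rank_full for r in full if r.site_id == target)
            rd = next(r.rank_filtered for r in filtered if r.site_id == target)
            full_ranks.append(rf)
            filtered_ranks.append(rd)
            if rd < rf:
                decoy_removed = True
        mean_full = sum(full_ranks) / len(full_ranks)
        mean_filtered = sum(filtered_ranks) / len(filtered_ranks)
        assert mean_filtered <= mean_full
        if decoy_removed:
            assert mean_filtered < mean_full
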