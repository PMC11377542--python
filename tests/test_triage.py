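"""Post-screen triage: filters, ledger, clustering, representatives, novelty."""

import numpy as np
import pytest

import alscreen as als
from alscreen.oracle import PoseProperties
from alscreen.triage import HitRecord, TriageError


def make_hit(cid, dG=-8.0, clogp=1.0, n_unsats=0, n_unusual=0, fp=None,
             heavy_atoms=25, mol_mass=350.0):
    rec = als.CompoundRecord(
        id=cid, smiles="", clogp=clogp, fingerprint=fp,
        heavy_atoms=heavy_atoms, mol_mass=mol_mass,
    )
    return HitRecord(record=rec, dG=dG,
                     pose=PoseProperties(n_unsats=n_unsats, n_unusual_torsion=n_unusual))


def bitvec(bits, n=32):
    v = np.zeros(n, dtype=np.uint8)
    v[list(bits)] = 1
    return v


class TestApplyFilters:
    def test_published_style_ledger_counts(self):
        """1000 candidates, 93 solubility failures, disjoint 754 unsat failures."""
        fixture = als.generate_filter_fixture(seed=3)
        hits = [HitRecord(record=r, dG=-8.0, pose=p) for r, p in fixture]
        survivors, ledger = als.apply_filters(hits, als.FilterRules())
        assert len(survivors) == 153
        assert ledger.stage_named("clogp").n_removed == 93
        assert ledger.stage_named("unsats").n_removed == 754
        assert ledger.n_in == 1000 and ledger.n_out == 153

    def test_empty_input_gives_ledger_of_zeros(self):
        survivors, ledger = als.apply_filters([], als.FilterRules())
        assert survivors == []
        assert all(s.n_in == 0 and s.n_removed == 0 for s in ledger.stages)

    def test_impossible_thresholds_are_identity(self):
        hits = [make_hit(f"h{i}", clogp=9.0, n_unsats=5) for i in range(10)]
        rules = als.FilterRules(max_clogp=float("inf"), max_unsats=10**9)
        survivors, _ = als.apply_filters(hits, rules)
        assert len(survivors) == 10

    def test_removed_at_first_failing_stage_with_reason(self):
        hit = make_hit("bad", clogp=5.0, n_unsats=3)  # fails both stages
        _, ledger = als.apply_filters([hit], als.FilterRules())
        assert ledger.stage_named("clogp").removed[0][0] == "bad"
        assert "cLogP" in ledger.stage_named("clogp").removed[0][1]
        assert ledger.stage_named("unsats").n_removed == 0

    def test_three_stage_rules_with_torsion_outliers(self):
        rules = als.FilterRules(order=("clogp", "unsats", "unusual_torsion"))
        hits = [
            make_hit("ok"),
            make_hit("greasy", clogp=4.0),
            make_hit("unsat", n_unsats=2),
            make_hit("twisted", n_unusual=3),
        ]
        survivors, ledger = als.apply_filters(hits, rules)
        assert [h.id for h in survivors] == ["ok"]
        assert [s.n_removed for s in ledger.stages] == [1, 1, 1]

    def test_survivors_independent_of_input_permutation(self, rng):
        hits = [
            make_hit(f"h{i}", clogp=float(rng.uniform(0, 6)),
                     n_unsats=int(rng.integers(0, 4)))
            for i in range(200)
        ]
        ids_fwd = {h.id for h in als.apply_filters(hits)[0]}
        shuffled = list(hits)
        rng.shuffle(shuffled)
        ids_shuf = {h.id for h in als.apply_filters(shuffled)[0]}
        assert ids_fwd == ids_shuf

    def test_ledger_conservation_chain(self, rng):
        hits = [
            make_hit(f"h{i}", clogp=float(rng.uniform(0, 6)),
                     n_unsats=int(rng.integers(0, 4)))
            for i in range(150)
        ]
        _, ledger = als.apply_filters(hits)
        for stage in ledger.stages:
            assert stage.n_out == stage.n_in - stage.n_removed
        for prev, nxt in zip(ledger.stages, ledger.stages[1:]):
            assert prev.n_out == nxt.n_in

    def test_missing_clogp_is_flagged_not_passed(self):
        hit = make_hit("nodata", clogp=1.0)
        hit.record.clogp = None
        survivors, ledger = als.apply_filters([hit])
        assert survivors == []
        assert "missing" in ledger.stage_named("clogp").removed[0][1]

    def test_unknown_stage_rejected(self):
        with pytest.raises(TriageError):
            als.FilterRules(order=("clogp", "vibes"))


class TestClustering:
    def test_all_identical_molecules_one_cluster(self):
        fp = bitvec({1, 2, 3})
        hits = [make_hit(f"h{i}", dG=-8 - i, fp=fp) for i in range(5)]
        clusters = als.cluster_compounds(hits)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5

    def test_all_dissimilar_one_cluster_each(self):
        hits = [
            make_hit("a", fp=bitvec({0, 1})),
            make_hit("b", fp=bitvec({10, 11})),
            make_hit("c", fp=bitvec({20, 21})),
        ]
        assert len(als.cluster_compounds(hits)) == 3

    def test_hand_traced_leader_pass(self):
        """Five fingerprints with pairwise similarities straddling 0.6.

        Visit order is best-dG-first: A(-10), B(-9), C(-8), D(-7), E(-6).
        A={0..9}; B shares 8/12 with A (0.667 >= 0.6, joins A);
        C={20..29} founds its own; D shares 7/13 with A (0.538 < 0.6) and
        8/12 with C (0.667, joins C); E={40..49} founds its own.
        """
        A = bitvec(set(range(10)), n=64)
        B = bitvec(set(range(8)) | {30, 31}, n=64)
        C = bitvec(set(range(20, 30)), n=64)
        D = bitvec(set(range(22, 30)) | {50, 51}, n=64)
        E = bitvec(set(range(40, 50)), n=64)
        assert als.tanimoto(A, B) == pytest.approx(8 / 12)
        assert als.tanimoto(C, D) == pytest.approx(8 / 12)
        assert als.tanimoto(A, D) < 0.6
        hits = [
            make_hit("A", dG=-10, fp=A), make_hit("B", dG=-9, fp=B),
            make_hit("C", dG=-8, fp=C), make_hit("D", dG=-7, fp=D),
            make_hit("E", dG=-6, fp=E),
        ]
        clusters = als.cluster_compounds(hits, similarity_cutoff=0.6)
        assignment = {
            h.id: c.leader.id for c in clusters for h in c.members
        }
        assert assignment == {"A": "A", "B": "A", "C": "C", "D": "C", "E": "E"}

    def test_permuting_input_does_not_change_clusters(self, rng):
        fps = (rng.random((40, 64)) < 0.25).astype(np.uint8)
        hits = [make_hit(f"h{i}", dG=float(-12 + i * 0.1), fp=fps[i]) for i in range(40)]
        ref = als.cluster_compounds(hits)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        perm = als.cluster_compounds(shuffled)
        as_sets = lambda cs: {frozenset(h.id for h in c.members) for c in cs}
        assert as_sets(ref) == as_sets(perm)


class TestRepresentatives:
    def test_singleton_under_either_policy(self):
        hit = make_hit("only")
        cluster = als.Cluster(leader=hit, members=[hit])
        assert als.pick_representative(cluster, "best_affinity").id == "only"
        assert als.pick_representative(cluster, "smallest").id == "only"

    def test_best_affinity_picks_lowest_dG(self):
        a = make_hit("a", dG=-9.0)
        b = make_hit("b", dG=-7.0)
        cluster = als.Cluster(leader=a, members=[a, b])
        assert als.pick_representative(cluster, "best_affinity").id == "a"

    def test_smallest_picks_fewest_heavy_atoms(self):
        a = make_hit("a", heavy_atoms=30)
        b = make_hit("b", heavy_atoms=20)
        cluster = als.Cluster(leader=a, members=[a, b])
        assert als.pick_representative(cluster, "smallest").id == "b"

    def test_empty_cluster_and_unknown_policy_raise(self):
        hit = make_hit("x")
        with pytest.raises(TriageError):
            als.pick_representative(als.Cluster(leader=hit, members=[]))
        with pytest.raises(TriageError):
            als.pick_representative(
                als.Cluster(leader=hit, members=[hit]), "prettiest"
            )


class TestNoveltyFilter:
    def test_empty_known_set_is_identity(self):
        hits = [make_hit("a", fp=bitvec({1, 2}))]
        survivors, _ = als.novelty_filter(hits, [])
        assert [h.id for h in survivors] == ["a"]

    def test_identical_to_known_active_removed(self):
        fp = bitvec({1, 2, 3})
        survivors, ledger = als.novelty_filter([make_hit("a", fp=fp)], [fp])
        assert survivors == []
        assert ledger.stages[0].removed[0][0] == "a"

    def test_hand_computed_similarity_below_cutoff_kept(self):
        # {0,1,2} vs {2,3,4,5,6,7,8}: intersection 1, union 9 -> 1/9 = 0.111;
        # vs {0,1,9,10,11,12}: intersection 2, union 7 -> 2/7 = 0.286 < 0.33
        hit = make_hit("n", fp=bitvec({0, 1, 2}))
        known = [bitvec({2, 3, 4, 5, 6, 7, 8}), bitvec({0, 1, 9, 10, 11, 12})]
        survivors, _ = als.novelty_filter([hit], known, max_similarity=0.33)
        assert [h.id for h in survivors] == ["n"]
        # tighten the cutoff below the max similarity and the record falls
        survivors, _ = als.novelty_filter([hit], known, max_similarity=0.28)
        assert survivors == []


class TestCampaignOrderings:
    """Filter->cluster and cluster->filter are both expressible."""

    def fixture_hits(self, rng):
        fps = (rng.random((60, 64)) < 0.25).astype(np.uint8)
        return [
            make_hit(
                f"h{i}", dG=float(-12 + 0.1 * i), fp=fps[i],
                clogp=float(rng.uniform(0, 6)), n_unsats=int(rng.integers(0, 4)),
            )
            for i in range(60)
        ]

    def test_filter_then_cluster(self, rng):
        hits = self.fixture_hits(rng)
        survivors, ledger = als.apply_filters(hits)
        reps = [
            als.pick_representative(c, "best_affinity")
            for c in als.cluster_compounds(survivors)
        ]
        assert len(reps) <= len(survivors) == ledger.n_out

    def test_cluster_then_filter(self, rng):
        hits = self.fixture_hits(rng)
        reps = [
            als.pick_representative(c, "best_affinity")
            for c in als.cluster_compounds(hits)
        ]
        survivors, ledger = als.apply_filters(reps)
        assert ledger.n_in == len(reps)
        assert len(survivors) <= len(reps)
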