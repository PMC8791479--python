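"""The greedy forward-selection algorithm: scoring, ranking, settings, baselines."""

import numpy as np
import pytest

from addontag.core import ProbeInfo, ValidationError, VariantKey
from addontag.ld import MIMatrix, mutual_information
from addontag.regions import Region
from addontag.select import (
    SelectionState,
    TagSets,
    find_candidates,
    haplogroup_addons,
    pick_best,
    random_selection,
    run_setting1,
    run_setting2,
    select_next,
)
from conftest import build_panel


def key(pos, ref="A", alt="G", chrom="1"):
    return VariantKey(chrom, pos, ref, alt)


def make_state(
    targets_mi: dict[VariantKey, dict[VariantKey, float]],
    candidates: list[VariantKey],
    existing: list[VariantKey],
    probeabilities: dict[VariantKey, float],
    region_id: str = "r0",
    setting: int = 1,
) -> SelectionState:
    """State over an injected MI matrix (rows = targets, cols = cands + tags)."""
    targets = list(targets_mi)
    cols = candidates + existing
    values = np.array([[targets_mi[j].get(k, 0.0) for k in cols] for j in targets])
    mi = MIMatrix(targets, cols, values)
    probes = {k: ProbeInfo.for_variant(k, p) for k, p in probeabilities.items()}
    region = Region(region_id, targets[0].chrom, 1, 10**7, setting)
    sets = TagSets(s1=targets, s2=list(candidates), s3=set(existing))
    return SelectionState(region, None, sets, probes, mi=mi)


def worked_example_state():
    """Two targets tracked at MI 0.2 by one existing tag; three 1-probe
    candidates where the best improves the targets by 0.4 and 0.5 and ranks
    first on efficiency but only second on probe-ability."""
    t1, t2 = key(100), key(200)
    ex = key(300)
    a, b, c = key(400), key(500), key(600)
    targets_mi = {
        t1: {a: 0.6, b: 0.5, c: 0.30, ex: 0.2},
        t2: {a: 0.7, b: 0.2, c: 0.25, ex: 0.2},
    }
    probe = {a: 0.8, b: 0.7, c: 0.95, ex: 0.5}
    return make_state(targets_mi, [a, b, c], [ex], probe), a


class TestWorkedExample:
    def test_one_probe_candidate_efficiency(self):
        state, a = worked_example_state()
        score = state.score_candidate(a)
        assert score.delta == pytest.approx({key(100): 0.4, key(200): 0.5})
        assert score.n_probes == 1
        assert score.e_k == pytest.approx(0.9)

    def test_two_probe_candidate_efficiency_halves(self):
        state, _ = worked_example_state()
        at = key(700, ref="A", alt="T")
        state.tagsets.s2.append(at)
        state.probes[at] = ProbeInfo.for_variant(at, 0.6)
        state.mi.variants_b.append(at)
        state.mi._ib[at] = state.mi.values.shape[1]
        state.mi.values = np.hstack([state.mi.values, np.array([[0.6], [0.7]])])
        score = state.score_candidate(at)
        assert score.n_probes == 2
        assert score.e_k == pytest.approx(0.45)

    def test_no_positive_delta_gives_zero_efficiency(self):
        state, _ = worked_example_state()
        c = key(600)
        # candidate c offers 0.30/0.25 against s_j = 0.2 -> positive; shrink it
        state.s = {j: 0.9 for j in state.tagsets.s1}
        assert state.score_candidate(c).e_k == 0.0

    def test_winner_selected_at_combined_rank_three(self):
        state, a = worked_example_state()
        acc = select_next(state)
        assert acc.key == a
        assert acc.score.rank_e == 1
        assert acc.score.rank_p == 2
        assert acc.score.combined_rank == 3

    def test_single_positive_candidate_selected(self):
        t1 = key(100)
        state = make_state({t1: {key(400): 0.5}}, [key(400)], [], {key(400): 0.9})
        acc = select_next(state)
        assert acc.key == key(400)

    def test_all_zero_efficiency_returns_none(self):
        t1 = key(100)
        state = make_state({t1: {key(400): 0.0}}, [key(400)], [], {key(400): 0.9})
        assert select_next(state) is None


def brute_force_rank_pick(scores):
    """Independent exhaustive rank-sum enumeration with competition ranks."""
    if all(s.e_k == 0.0 for s in scores):
        return None
    best = None
    best_key = None
    for s in scores:
        re = 1 + sum(1 for o in scores if o.e_k > s.e_k)
        rp = 1 + sum(1 for o in scores if o.probeability > s.probeability)
        tie = (re + rp, -s.e_k, s.n_probes, s.key.chrom, s.key.pos, s.key.ref, s.key.alt)
        if best is None or tie < best:
            best = tie
            best_key = s.key
    return best_key


def random_instance(rng, n_targets=None, n_cands=None, chrom="1"):
    n_targets = n_targets or int(rng.integers(1, 9))
    n_cands = n_cands or int(rng.integers(1, 9))
    n_existing = int(rng.integers(0, 3))
    n_var = n_targets + n_cands + n_existing
    mat = (rng.random((n_var, 120)) < rng.uniform(0.1, 0.9, (n_var, 1)))
    panel = build_panel(mat.astype(np.int8), spacing=97, chrom=chrom)
    vs = panel.variants
    targets = vs[:n_targets]
    cands = vs[n_targets : n_targets + n_cands]
    existing = vs[n_targets + n_cands :]
    probes = {
        v: ProbeInfo.for_variant(v, float(np.round(rng.random(), 2))) for v in vs
    }
    region = Region(f"r_{chrom}", chrom, 1, 10**7, 2)
    sets = TagSets(s1=list(targets), s2=list(cands), s3=set(existing))
    return SelectionState(region, panel, sets, probes), panel


def test_select_next_matches_exhaustive_enumeration(rng):
    """On 200 random small instances the greedy pick equals the brute-force
    rank-sum argmin computed from independently evaluated MI scores."""
    for _ in range(200):
        state, panel = random_instance(rng)
        # independent scoring route: raw MI calls, no MIMatrix
        s = {
            j: max((mutual_information(panel, i, j) for i in state.tagsets.s3),
                   default=0.0)
            for j in state.tagsets.s1
        }
        oracle_scores = []
        for k in state.tagsets.s2:
            gain = sum(
                max(0.0, mutual_information(panel, j, k) - s[j])
                for j in state.tagsets.s1
            )
            sc = state.score_candidate(k)  # reuse container for fields
            assert sc.e_k == pytest.approx(gain / sc.n_probes, abs=1e-12)
            oracle_scores.append(sc)
        expected = brute_force_rank_pick(
            [state.score_candidate(k) for k in state.tagsets.s2]
        )
        acc = select_next(state)
        got = None if acc is None else acc.key
        assert got == expected


class TestSetting1:
    def test_perfect_tag_stops_after_one_selection(self, rng):
        row = (rng.random(100) < 0.5).astype(np.int8)
        panel = build_panel([row, row.copy(), row.copy()])
        t1, t2, cand = panel.variants
        probes = {cand: ProbeInfo.for_variant(cand, 0.9)}
        region = Region("r0", "1", 1, 10**6, 1)
        sets = TagSets(s1=[t1, t2], s2=[cand], s3=set())
        state = SelectionState(region, panel, sets, probes)
        result = run_setting1([state])
        assert result.n_tags == 1
        assert result.accepted[0].key == cand

    def test_stop_threshold_counts_improved_targets(self):
        """With 10 targets and stop_frac 0.15 (threshold 2) the loop stops
        right after an accepted tag improves only one target."""
        targets = [key(100 + i) for i in range(10)]
        g1, g2, g3 = key(5000), key(6000), key(7000)
        mi = {}
        for i, t in enumerate(targets):
            mi[t] = {g1: 0.8 if i < 3 else 0.0,
                     g2: 0.5 if i == 3 else 0.0,
                     g3: 0.4 if i == 4 else 0.0}
        state = make_state(mi, [g1, g2, g3], [], {g1: 0.9, g2: 0.8, g3: 0.7})
        result = run_setting1([state], stop_frac=0.15)
        assert [a.key for a in result.accepted] == [g1, g2]
        assert result.accepted[-1].n_improved == 1
        assert g3 in state.tagsets.s2  # left behind by the stop rule

    def test_two_independent_haplotypes_need_two_tags(self, rng):
        """A region holding two uncorrelated perfectly-tagged target groups
        yields exactly one tag per group."""
        a = (rng.random(200) < 0.5).astype(np.int8)
        b = (rng.random(200) < 0.5).astype(np.int8)
        panel = build_panel([a, a.copy(), b, b.copy()])
        t_a, c_a, t_b, c_b = panel.variants
        probes = {v: ProbeInfo.for_variant(v, 0.9) for v in panel.variants}
        region = Region("r0", "1", 1, 10**6, 1)
        sets = TagSets(s1=[t_a, t_b], s2=[c_a, c_b], s3=set())
        state = SelectionState(region, panel, sets, probes)
        result = run_setting1([state])
        assert sorted(a.key for a in result.accepted) == sorted([c_a, c_b])

    def test_s_coverage_nondecreasing_through_run(self, rng):
        state, _ = random_instance(rng, n_targets=6, n_cands=8)
        before = dict(state.s)
        while True:
            acc = select_next(state)
            if acc is None:
                break
            for j, prev in before.items():
                assert state.s[j] >= prev - 1e-15
            before = dict(state.s)


class TestSetting2:
    def test_budget_two_accepts_final_two_probe_tag(self):
        t = key(100)
        at = key(400, ref="A", alt="T")
        state = make_state({t: {at: 0.9}}, [at], [], {at: 0.9}, setting=2)
        result = run_setting2([state], probe_budget=2)
        assert [a.key for a in result.accepted] == [at]
        assert result.n_probes == 2

    def test_budget_one_cannot_afford_two_probe_tags(self):
        t = key(100)
        at = key(400, ref="A", alt="T")
        state = make_state({t: {at: 0.9}}, [at], [], {at: 0.9}, setting=2)
        result = run_setting2([state], probe_budget=1)
        assert result.n_tags == 0

    def test_budget_already_exhausted_is_empty(self):
        t = key(100)
        state = make_state({t: {key(400): 0.9}}, [key(400)], [], {key(400): 0.9})
        assert run_setting2([state], probe_budget=5, already_used=5).n_tags == 0

    def test_probe_accounting_never_exceeds_budget(self, rng):
        for _ in range(20):
            states = [random_instance(rng)[0] for _ in range(3)]
            budget = int(rng.integers(1, 8))
            result = run_setting2(states, probe_budget=budget)
            assert result.n_probes <= budget

    def test_acceptance_order_matches_brute_force_global_greedy(self, rng):
        """Multi-region instances: the budgeted global loop reproduces an
        independently coded greedy (per-region rank pick, then global pick)."""
        for _ in range(30):
            n_regions = int(rng.integers(2, 4))
            seeds = [random_instance(rng, chrom=str(c + 1)) for c in range(n_regions)]
            states = [s for s, _ in seeds]
            mirror = [random_instance_copy(s) for s in states]
            budget = int(rng.integers(2, 10))
            got = [a.key for a in run_setting2(states, probe_budget=budget).accepted]
            expected = brute_force_setting2(mirror, budget)
            assert got == expected


def random_instance_copy(state):
    sets = TagSets(
        s1=list(state.tagsets.s1),
        s2=list(state.tagsets.s2),
        s3=set(state.tagsets.s3),
    )
    return SelectionState(state.region, state.panel, sets, state.probes)


def brute_force_setting2(states, budget):
    """Plain-loop re-implementation of the budgeted global greedy."""
    accepted = []
    remaining = budget
    while remaining > 0:
        winners = []
        for st in states:
            scores = [
                st.score_candidate(k)
                for k in st.tagsets.s2
                if st.probe_info(k).n_probes <= remaining
            ]
            scores = [s for s in scores if s.e_k > 0.0]
            best = brute_force_rank_pick(scores)
            if best is not None:
                winners.append((st, next(s for s in scores if s.key == best)))
        if not winners:
            break
        pick = brute_force_rank_pick([s for _, s in winners])
        st, sc = next((st, s) for st, s in winners if s.key == pick)
        st.accept(sc)
        accepted.append(sc.key)
        remaining -= sc.n_probes
    return accepted


class TestFindCandidates:
    def _fixture(self, rng):
        mat = (rng.random((6, 100)) < 0.4).astype(np.int8)
        panel = build_panel(mat)
        return panel

    def test_threshold_boundaries(self, rng):
        panel = self._fixture(rng)
        from addontag.core import ImputationQualityTable, QualityRecord

        v = panel.variants
        quality = ImputationQualityTable({
            v[0]: QualityRecord(0.79, 0.06, "x"),  # poor & common -> S1
            v[1]: QualityRecord(0.85, 0.20, "x"),  # well imputed
        })
        probes = {
            v[0]: ProbeInfo.for_variant(v[0], 0.9),
            v[1]: ProbeInfo.for_variant(v[1], 0.9),
            v[2]: ProbeInfo.for_variant(v[2], 0.25),  # below 0.3 -> excluded
            v[3]: ProbeInfo.for_variant(v[3], 0.9),   # on array -> S3 only
        }
        region = Region("r0", "1", 1, 10**6, 1, members=list(v))
        sets = find_candidates(panel, quality, probes, [v[3]], region)
        assert v[0] in sets.s1
        assert v[1] not in sets.s1
        assert v[2] not in sets.s2
        assert v[3] in sets.s3 and v[3] not in sets.s2
        # unscored variants count as never-imputed -> candidate targets
        assert v[4] in sets.s1

    def test_manifest_variant_absent_from_panel_logged(self, rng, caplog):
        panel = self._fixture(rng)
        from addontag.core import ImputationQualityTable

        ghost = key(50, chrom="1")
        region = Region("r0", "1", 1, 10**6, 1, members=list(panel.variants))
        with caplog.at_level("WARNING", logger="addontag.select"):
            sets = find_candidates(panel, ImputationQualityTable({}), {}, [ghost], region)
        assert ghost in sets.s3
        assert any("not present in panel" in r.message for r in caplog.records)


class TestRandomSelection:
    def _setup(self, rng, n_pool=50):
        mat = (rng.random((n_pool, 60)) < 0.5).astype(np.int8)
        panel = build_panel(mat)
        region = Region("r0", "1", 1, 10**7, 2, members=list(panel.variants))
        from addontag.core import ImputationQualityTable

        return panel, region, ImputationQualityTable({})

    def test_seeded_and_reproducible(self, rng):
        panel, region, quality = self._setup(rng)
        a = random_selection([region], {"r0": 5}, panel, quality, [], seed=11)
        b = random_selection([region], {"r0": 5}, panel, quality, [], seed=11)
        assert a.keys == b.keys and len(set(a.keys)) == 5

    def test_small_pool_tops_up_from_proposed(self, rng):
        panel, region, quality = self._setup(rng, n_pool=8)
        vs = panel.variants
        proposed = {"r0": vs[:5]}
        array = vs[5:8]
        # pool = nothing left outside array and proposed picks
        result = random_selection(
            [region], {"r0": 5}, panel, quality, array, seed=3, proposed=proposed
        )
        assert len(result.keys) == 5
        assert set(result.keys) <= set(vs[:5])

    def test_mixed_pool_and_proposed_topup(self, rng):
        panel, region, quality = self._setup(rng, n_pool=8)
        vs = panel.variants
        proposed = {"r0": vs[:5]}
        result = random_selection(
            [region], {"r0": 5}, panel, quality, [], seed=3, proposed=proposed
        )
        # 3 non-proposed pool members all taken, plus 2 proposed at random
        assert set(vs[5:]) <= set(result.keys)
        assert len(set(result.keys) & set(vs[:5])) == 2

    def test_empty_pool_without_proposed_raises(self, rng):
        panel, region, quality = self._setup(rng, n_pool=4)
        with pytest.raises(ValidationError):
            random_selection(
                [region], {"r0": 2}, panel, quality, list(panel.variants), seed=1
            )

    def test_uniform_sampling_frequencies(self, rng):
        panel, region, quality = self._setup(rng, n_pool=6)
        counts = {v: 0 for v in panel.variants}
        n_runs = 600
        for seed in range(n_runs):
            res = random_selection([region], {"r0": 2}, panel, quality, [], seed=seed)
            for k in res.keys:
                counts[k] += 1
        expected = n_runs * 2 / 6
        for v, c in counts.items():
            assert abs(c - expected) < 4 * np.sqrt(expected)


class TestHaplogroupAddons:
    def _tree(self):
        parents = {"L": None, "L1": "L", "L2": "L", "L1a": "L1", "L1a1": "L1a"}
        markers = {
            "L": [key(10, chrom="MT")],
            "L1": [key(20, chrom="MT")],
            "L2": [key(30, chrom="MT")],
            "L1a": [key(40, chrom="MT")],
            "L1a1": [key(50, chrom="MT")],
        }
        return parents, markers

    def test_markers_to_depth_two_below_main_haplogroup(self):
        parents, markers = self._tree()
        chosen = haplogroup_addons(parents, markers, {"s1": "L"}, [])
        # depth 0: L; depth 1: L1, L2; depth 2: L1a -- but not L1a1
        assert chosen == {key(10, chrom="MT"), key(20, chrom="MT"),
                          key(30, chrom="MT"), key(40, chrom="MT")}

    def test_markers_already_on_array_excluded(self):
        parents, markers = self._tree()
        chosen = haplogroup_addons(parents, markers, {"s1": "L"},
                                   [key(20, chrom="MT")])
        assert key(20, chrom="MT") not in chosen

    def test_empty_cohort_empty_set(self):
        parents, markers = self._tree()
        assert haplogroup_addons(parents, markers, {}, []) == set()

    def test_unknown_haplogroup_rejected(self):
        parents, markers = self._tree()
        with pytest.raises(ValidationError):
            haplogroup_addons(parents, markers, {"s1": "M"}, [])


def test_selection_is_deterministic(rng):
    state_a, _ = random_instance(rng, n_targets=5, n_cands=7)
    state_b = random_instance_copy(state_a)
    res_a = run_setting1([state_a])
    res_b = run_setting1([state_b])
    assert [a.key for a in res_a.accepted] == [a.key for a in res_b.accepted]
    assert [a.score.e_k for a in res_a.accepted] == [a.score.e_k for a in res_b.accepted]


def test_s2_s3_disjoint_after_acceptances(rng):
    state, _ = random_instance(rng, n_targets=4, n_cands=6)
    while select_next(state) is not None:
        assert not (set(state.tagsets.s2) & state.tagsets.s3)
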