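"""Cross-wave matching, structure, and relationship-change counts."""

import numpy as np
import pytest

from egowave.crosswave import (
    build_crosswave_network,
    change_counts_table,
    crosswave_components,
    crosswave_density,
    crosswave_table,
    match_alters,
    relationship_change_counts,
)
from egowave.model import (
    AlterObservation,
    DomainError,
    TieObservation,
    WaveNetwork,
)
from egowave.simulate import SimConfig, generate_cohort
from egowave.model import FLAGS


def _net(wave, labels, ego="e", flags=None, ties=()):
    alters = [
        AlterObservation(ego, wave, lab, **(flags or {}).get(lab, {})) for lab in labels
    ]
    return WaveNetwork(ego, wave, alters, [TieObservation(ego, wave, a, b) for a, b in ties])


class TestMatching:
    def test_partition_by_set_algebra(self):
        status = match_alters(_net("baseline", "abc"), _net("followup", "bcde"))
        assert status == {"b": "retained", "c": "retained", "a": "dropped", "d": "added", "e": "added"}

    def test_identical_sets_have_no_turnover(self):
        status = match_alters(_net("baseline", "abc"), _net("followup", "abc"))
        assert set(status.values()) == {"retained"}

    def test_disjoint_sets_have_no_retention(self):
        status = match_alters(_net("baseline", "ab"), _net("followup", "cd"))
        assert list(status.values()).count("retained") == 0
        assert len(status) == 4

    def test_mismatched_egos_rejected(self):
        with pytest.raises(DomainError):
            match_alters(_net("baseline", "ab", ego="e1"), _net("followup", "ab", ego="e2"))


class TestCrossWaveStructure:
    def _cross(self, w1, w2):
        return build_crosswave_network(w1, w2, match_alters(w1, w2))

    def test_baseline_only_tie_is_in_the_union(self):
        w1 = _net("baseline", "ab", ties=[("a", "b")])
        w2 = _net("followup", "ab")
        assert ("a", "b") in self._cross(w1, w2).union_ties

    def test_never_coobserved_pair_is_untied(self):
        w1 = _net("baseline", "ab", ties=[("a", "b")])
        w2 = _net("followup", "bd")
        net = self._cross(w1, w2)
        assert net.status["a"] == "dropped" and net.status["d"] == "added"
        assert ("a", "d") not in net.union_ties

    def test_union_ties_equal_set_union_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            labels = [f"x{i}" for i in range(int(rng.integers(2, 10)))]
            t1 = [tuple(sorted(rng.choice(labels, 2, replace=False))) for _ in range(4)]
            t2 = [tuple(sorted(rng.choice(labels, 2, replace=False))) for _ in range(4)]
            w1 = _net("baseline", labels, ties=set(t1))
            w2 = _net("followup", labels, ties=set(t2))
            assert self._cross(w1, w2).union_ties == set(t1) | set(t2)

    @pytest.mark.parametrize(
        "n,ties,expected",
        [(3, [("a", "b"), ("a", "c"), ("b", "c")], 1.0), (6, [], 0.0)],
    )
    def test_density_extremes(self, n, ties, expected):
        labels = "abcdef"[:n]
        net = self._cross(_net("baseline", labels, ties=ties), _net("followup", labels))
        assert crosswave_density(net) == expected

    def test_density_direct_ratio(self):
        ties = [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e"), ("a", "f")]
        net = self._cross(_net("baseline", "abcdef", ties=ties), _net("followup", "abcdef"))
        assert crosswave_density(net) == pytest.approx(5 / 15)

    def test_density_undefined_below_two_alters(self):
        net = self._cross(_net("baseline", "a"), _net("followup", "a"))
        with pytest.raises(DomainError):
            crosswave_density(net)

    def test_isolates_and_paths(self):
        iso = self._cross(_net("baseline", "abcd"), _net("followup", "abcd"))
        assert crosswave_components(iso) == 4
        path = self._cross(
            _net("baseline", "abcde", ties=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]),
            _net("followup", "abcde"),
        )
        assert crosswave_components(path) == 1

    def test_components_match_dfs_oracle_on_random_graphs(self):
        """Component counts agree with an independent depth-first-search
        oracle on 200 random cross-wave networks of up to 12 alters."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            labels = [f"x{i}" for i in range(n)]
            pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
            ties = {p for p in pairs if rng.random() < 0.2}
            net = self._cross(_net("baseline", labels, ties=ties), _net("followup", labels))
            # hand-rolled DFS, no graph library
            adj = {lab: set() for lab in labels}
            for a, b in ties:
                adj[a].add(b)
                adj[b].add(a)
            seen, comps = set(), 0
            for lab in labels:
                if lab in seen:
                    continue
                comps += 1
                stack = [lab]
                while stack:
                    cur = stack.pop()
                    if cur in seen:
                        continue
                    seen.add(cur)
                    stack.extend(adj[cur] - seen)
            assert crosswave_components(net) == comps
            assert crosswave_density(net) == pytest.approx(
                len(ties) / (n * (n - 1) / 2)
            ) if n >= 2 else True


class TestChangeCounts:
    def test_stopping_requires_retention(self):
        flags1 = {"a": {"drink_ever": True}, "b": {"drink_ever": True}}
        w1 = _net("baseline", "ab", flags=flags1)
        w2 = _net("followup", "ac")  # b (a drinker) dropped; a stopped
        counts = relationship_change_counts(w1, w2, match_alters(w1, w2))
        assert counts["stop_drink"] == 1  # only retained alter a counts
        assert counts["start_drink"] == 0

    def test_start_and_stop_are_disjoint_per_alter(self):
        w1 = _net("baseline", "ab", flags={"a": {"drink_ever": True}})
        w2 = _net("followup", "ab", flags={"b": {"drink_ever": True}})
        counts = relationship_change_counts(w1, w2, match_alters(w1, w2))
        assert counts["stop_drink"] == 1 and counts["start_drink"] == 1

    def test_any_family_uses_the_disjunction(self):
        # a: drops drinking but picks up drug use -> no "any" change
        w1 = _net("baseline", "a", flags={"a": {"drink_ever": True}})
        w2 = _net("followup", "a", flags={"a": {"drug_ever": True}})
        counts = relationship_change_counts(w1, w2, match_alters(w1, w2))
        assert counts["stop_drink"] == 1 and counts["start_drug"] == 1
        assert counts["stop_any"] == 0 and counts["start_any"] == 0

    def test_counts_match_flat_scan_oracle(self, big_tables):
        _, alt, _ = big_tables
        table = change_counts_table(alt).set_index("ego_id")
        rng = np.random.default_rng(4)
        base = alt[alt.wave == "baseline"]
        fu = alt[alt.wave == "followup"]
        for ego_id in rng.choice(sorted(set(fu.ego_id)), size=8, replace=False):
            b = base[base.ego_id == ego_id].set_index("alter_label")
            f = fu[fu.ego_id == ego_id].set_index("alter_label")
            retained = sorted(set(b.index) & set(f.index))
            for fam in ("drink", "drug", "influence"):
                stop = sum(bool(b.loc[a, f"{fam}_ever"]) and not f.loc[a, f"{fam}_ever"] for a in retained)
                start = sum(not b.loc[a, f"{fam}_ever"] and bool(f.loc[a, f"{fam}_ever"]) for a in retained)
                assert table.loc[ego_id, f"stop_{fam}"] == stop
                assert table.loc[ego_id, f"start_{fam}"] == start

    def test_recent_flag_version_switch(self):
        w1 = _net("baseline", "a", flags={"a": {"drink_ever": True, "drink_recent": True}})
        w2 = _net("followup", "a", flags={"a": {"drink_ever": True, "drink_recent": False}})
        status = match_alters(w1, w2)
        assert relationship_change_counts(w1, w2, status, "ever")["stop_drink"] == 0
        assert relationship_change_counts(w1, w2, status, "recent")["stop_drink"] == 1


class TestConservation:
    def test_turnover_identities_on_every_generated_ego(self, big_tables):
        _, alt, tie = big_tables
        table = crosswave_table(alt, tie)
        base_sizes = alt[alt.wave == "baseline"].groupby("ego_id").size()
        fu_sizes = alt[alt.wave == "followup"].groupby("ego_id").size()
        t = table.set_index("ego_id")
        assert (t.n_retained + t.n_dropped == base_sizes.loc[t.index]).all()
        assert (t.n_retained + t.n_added == fu_sizes.loc[t.index]).all()
        assert (t.total_unique_alters == t.n_retained + t.n_dropped + t.n_added).all()
        for fam in ("drink", "drug", "influence", "any"):
            assert (t[f"stop_{fam}"] + t[f"start_{fam}"] <= t.n_retained).all()

    def test_frozen_dynamics_zero_change_and_baseline_structure(self):
        import networkx as nx

        cfg = SimConfig(
            n_randomized=25,
            retention_prob={"control": 1.0, "intervention": 1.0},
            stopping_rate={f: 0.0 for f in FLAGS},
            starting_rate={f: 0.0 for f in FLAGS},
            arm_effect_recent_drink=0.0,
        )
        _, alt, tie = generate_cohort(cfg, seed=6)
        table = crosswave_table(alt, tie).set_index("ego_id")
        change_cols = [c for c in table.columns if c.startswith(("stop_", "start_"))]
        assert (table[change_cols] == 0).all().all()
        assert (table.n_dropped == 0).all() and (table.n_added == 0).all()
        # cross-wave structure equals baseline structure
        base = tie[(tie.wave == "baseline") & tie.knows]
        for ego_id, row in table.iterrows():
            labels = set(alt[(alt.ego_id == ego_id) & (alt.wave == "baseline")].alter_label)
            g = nx.Graph()
            g.add_nodes_from(labels)
            eg = base[base.ego_id == ego_id]
            g.add_edges_from(zip(eg.alter_a, eg.alter_b))
            n = len(labels)
            assert row.crosswave_components == nx.number_connected_components(g)
            assert row.crosswave_density == pytest.approx(
                g.number_of_edges() / (n * (n - 1) / 2)
            )
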