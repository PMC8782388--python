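"""Cross-wave alter matching, turnover, structure, and relationship change.

Alters are matched across the two waves by exact normalized label, yielding
a partition into *retained* (named at both waves), *dropped* (baseline
only), and *added* (follow-up only).  The cross-wave network is the union of
both waves' alters; a pair is tied if it was reported as knowing each other
at either wave (so a dropped-added pair, never co-observed, is structurally
untied).  Structural metrics exclude the ego: density is tied pairs over
C(n, 2), components are connected components of the alter-alter union graph
with isolates counting as singletons.

Relationship-change (stopping/starting) counts are computed over retained
alters only, for the three risk families and their disjunction.  By default
they use the "ever at that wave" flags — the recent window (4 weeks) is
shorter than the 3-month between-wave gap — with ``flag_version="recent"``
available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import RISK_FAMILIES, DomainError, WaveNetwork

__all__ = [
    "CHANGE_FAMILIES",
    "CrossWaveNetwork",
    "match_alters",
    "build_crosswave_network",
    "crosswave_density",
    "crosswave_components",
    "relationship_change_counts",
    "change_counts_table",
    "crosswave_table",
]

CHANGE_FAMILIES = RISK_FAMILIES + ("any",)


@dataclass
class CrossWaveNetwork:
    """Union of one ego's two wave networks with per-alter status."""

    ego_id: str
    #: alter_label -> status in {"retained", "dropped", "added"}
    status: dict[str, str] = field(default_factory=dict)
    #: alter_label -> flag dict at baseline (None for added alters)
    baseline_flags: dict[str, dict | None] = field(default_factory=dict)
    #: alter_label -> flag dict at follow-up (None for dropped alters)
    followup_flags: dict[str, dict | None] = field(default_factory=dict)
    union_ties: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_alters(self) -> int:
        return len(self.status)

    def count(self, status: str) -> int:
        return sum(1 for s in self.status.values() if s == status)


def match_alters(w1: WaveNetwork, w2: WaveNetwork) -> dict[str, str]:
    """Partition the union of alter labels into retained/dropped/added.

    ``w1`` is the baseline network and ``w2`` the follow-up network of the
    same ego; labels are assumed already normalized (ingest does this).
    """
    if w1.ego_id != w2.ego_id:
        raise DomainError(f"cannot match networks of different egos: {w1.ego_id!r} vs {w2.ego_id!r}")
    base, fu = set(w1.labels), set(w2.labels)
    status = {lab: "retained" for lab in base & fu}
    status.update({lab: "dropped" for lab in base - fu})
    status.update({lab: "added" for lab in fu - base})
    return status


def build_crosswave_network(w1: WaveNetwork, w2: WaveNetwork, status: dict[str, str]) -> CrossWaveNetwork:
    """Assemble the cross-wave union network with union ties."""
    base_flags = {a.alter_label: a.flags() for a in w1.alters}
    fu_flags = {a.alter_label: a.flags() for a in w2.alters}
    return CrossWaveNetwork(
        ego_id=w1.ego_id,
        status=dict(status),
        baseline_flags={lab: base_flags.get(lab) for lab in status},
        followup_flags={lab: fu_flags.get(lab) for lab in status},
        union_ties=w1.tie_pairs() | w2.tie_pairs(),
    )


def crosswave_density(net: CrossWaveNetwork) -> float:
    """Tied pairs over all C(n, 2) alter pairs; ego excluded."""
    n = net.n_alters
    if n < 2:
        raise DomainError(f"ego {net.ego_id}: density undefined for {n} alter(s)")
    return len(net.union_ties) / (n * (n - 1) / 2)


def crosswave_components(net: CrossWaveNetwork) -> int:
    """Connected components of the alter-alter union graph (isolates count)."""
    if net.n_alters < 1:
        raise DomainError(f"ego {net.ego_id}: components undefined for an empty network")
    g = nx.Graph()
    g.add_nodes_from(net.status)
    g.add_edges_from(net.union_ties)
    return nx.number_connected_components(g)


def _wave_flag(flags: dict, fam: str, version: str) -> bool:
    if fam == "any":
        return any(flags[f"{f}_{version}"] for f in RISK_FAMILIES)
    return flags[f"{fam}_{version}"]


def relationship_change_counts(
    w1: WaveNetwork, w2: WaveNetwork, status: dict[str, str], flag_version: str = "ever"
) -> dict[str, int]:
    """Stopping/starting counts over retained alters for the four families.

    ``stop_f`` counts retained alters with the characteristic at baseline
    but not follow-up; ``start_f`` the reverse.  Dropped and added alters
    contribute to no change count.
    """
    if flag_version not in ("ever", "recent"):
        raise DomainError(f"flag_version must be 'ever' or 'recent', got {flag_version!r}")
    base = {a.alter_label: a.flags() for a in w1.alters}
    fu = {a.alter_label: a.flags() for a in w2.alters}
    out = {f"{kind}_{fam}": 0 for kind in ("stop", "start") for fam in CHANGE_FAMILIES}
    for lab, st in status.items():
        if st != "retained":
            continue
        for fam in CHANGE_FAMILIES:
            b = _wave_flag(base[lab], fam, flag_version)
            f = _wave_flag(fu[lab], fam, flag_version)
            if b and not f:
                out[f"stop_{fam}"] += 1
            elif f and not b:
                out[f"start_{fam}"] += 1
    return out


def _any_risk(df: pd.DataFrame, version: str) -> pd.Series:
    return df[[f"{f}_{version}" for f in RISK_FAMILIES]].any(axis=1)


def change_counts_table(alter_df: pd.DataFrame, flag_version: str = "ever") -> pd.DataFrame:
    """Vectorized per-ego change counts and turnover (no graph metrics).

    One row per ego present at both waves, with stop_*/start_* for the four
    families, n_retained / n_dropped / n_added, and total_unique_alters.
    """
    if flag_version not in ("ever", "recent"):
        raise DomainError(f"flag_version must be 'ever' or 'recent', got {flag_version!r}")
    base = alter_df[alter_df["wave"] == "baseline"]
    fu = alter_df[alter_df["wave"] == "followup"]
    both = set(base["ego_id"]) & set(fu["ego_id"])
    base = base[base["ego_id"].isin(both)]
    fu = fu[fu["ego_id"].isin(both)]

    merged = base.merge(fu, on=["ego_id", "alter_label"], how="outer", suffixes=("_b", "_f"), indicator=True)
    merged["retained"] = merged["_merge"] == "both"
    merged["dropped"] = merged["_merge"] == "left_only"
    merged["added"] = merged["_merge"] == "right_only"

    fams = {fam: (f"{fam}_{flag_version}_b", f"{fam}_{flag_version}_f") for fam in RISK_FAMILIES}
    cols = {}
    ret = merged["retained"]
    for fam, (cb, cf) in fams.items():
        b = merged[cb].eq(True)  # missing (non-retained) rows count as False
        f = merged[cf].eq(True)
        cols[f"stop_{fam}"] = ret & b & ~f
        cols[f"start_{fam}"] = ret & ~b & f
    any_b = merged[[c for c, _ in fams.values()]].eq(True).any(axis=1)
    any_f = merged[[c for _, c in fams.values()]].eq(True).any(axis=1)
    cols["stop_any"] = ret & any_b & ~any_f
    cols["start_any"] = ret & ~any_b & any_f
    for name in ("retained", "dropped", "added"):
        cols[f"n_{name}"] = merged[name]
    agg = pd.DataFrame(cols).assign(ego_id=merged["ego_id"]).groupby("ego_id", sort=True).sum()
    agg = agg.astype(int)
    agg["total_unique_alters"] = agg["n_retained"] + agg["n_dropped"] + agg["n_added"]
    return agg.reset_index()


def crosswave_table(
    alter_df: pd.DataFrame, tie_df: pd.DataFrame, flag_version: str = "ever"
) -> pd.DataFrame:
    """Full cross-wave summary per ego: change counts, turnover, density,
    and component counts.  Egos observed at a single wave are omitted."""
    out = change_counts_table(alter_df, flag_version=flag_version)
    tied = tie_df[tie_df["knows"].astype(bool)]
    pairs = tied[["ego_id", "alter_a", "alter_b"]].drop_duplicates()
    pair_groups = {eid: g for eid, g in pairs.groupby("ego_id")}
    density = []
    components = []
    for r in out.itertuples(index=False):
        n = r.total_unique_alters
        g = nx.Graph()
        eg = pair_groups.get(r.ego_id)
        edges = list(zip(eg["alter_a"], eg["alter_b"])) if eg is not None else []
        labels = set(alter_df.loc[alter_df["ego_id"] == r.ego_id, "alter_label"])
        g.add_nodes_from(labels)
        g.add_edges_from(edges)
        density.append(g.number_of_edges() / (n * (n - 1) / 2) if n >= 2 else np.nan)
        components.append(nx.number_connected_components(g))
    out["crosswave_density"] = density
    out["crosswave_components"] = components
    return out
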