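"""Per-ego network composition: the 16 proportion measures.

Each alter is classified on four risk dimensions (drinking partner, drug-use
partner, AOD-use influence, and their disjunction "any risk") and four
support dimensions (emotional, informational, tangible, "any support"), each
both "ever" and "recent".  An ego's wave-level measure is the count of
alters with the classification divided by the number of alters named at that
wave — the denominator is wave-specific, never the 20-alter cap and never
the cross-wave union.  Missing flags were ingested as False and stay in the
denominator.
"""

from __future__ import annotations

import pandas as pd

from .model import (
    RISK_FAMILIES,
    SUPPORT_FAMILIES,
    AlterObservation,
    DomainError,
    WaveNetwork,
)

__all__ = [
    "PROPORTION_MEASURES",
    "classify_alter_risk",
    "classify_alter_support",
    "network_proportions",
    "composition_table",
]

_MEASURE_FAMILIES = RISK_FAMILIES + ("any_risk",) + SUPPORT_FAMILIES + ("any_support",)
#: The 16 composition measures, e.g. ``prop_drink``, ``prop_any_risk_recent``.
PROPORTION_MEASURES = tuple(
    f"prop_{fam}{suffix}" for fam in _MEASURE_FAMILIES for suffix in ("", "_recent")
)


def classify_alter_risk(a: AlterObservation) -> dict[str, bool]:
    """Risk classification: the three base flag pairs plus their disjunction.

    ``any_ever`` is true if the alter is a drinking partner, drug-use
    partner, or AOD-use influence (ever); ``any_recent`` likewise over the
    recent flags.
    """
    out = {f"{fam}_{s}": a.flag(f"{fam}_{s}") for fam in RISK_FAMILIES for s in ("ever", "recent")}
    out["any_ever"] = any(out[f"{fam}_ever"] for fam in RISK_FAMILIES)
    out["any_recent"] = any(out[f"{fam}_recent"] for fam in RISK_FAMILIES)
    return out


def classify_alter_support(a: AlterObservation) -> dict[str, bool]:
    """Support classification: emotional / informational / tangible flag
    pairs plus an any-support disjunction, ever and recent."""
    out = {f"{fam}_{s}": a.flag(f"{fam}_{s}") for fam in SUPPORT_FAMILIES for s in ("ever", "recent")}
    out["any_ever"] = any(out[f"{fam}_ever"] for fam in SUPPORT_FAMILIES)
    out["any_recent"] = any(out[f"{fam}_recent"] for fam in SUPPORT_FAMILIES)
    return out


def network_proportions(net: WaveNetwork) -> dict:
    """The 16 composition proportions for one wave network.

    Raises :class:`DomainError` on an empty network (the denominator is the
    number of alters named at the wave).
    """
    n = net.size
    if n < 1:
        raise DomainError(f"ego {net.ego_id} {net.wave}: proportions undefined for an empty network")
    counts = dict.fromkeys(PROPORTION_MEASURES, 0)
    for a in net.alters:
        risk = classify_alter_risk(a)
        support = classify_alter_support(a)
        for fam in RISK_FAMILIES:
            counts[f"prop_{fam}"] += risk[f"{fam}_ever"]
            counts[f"prop_{fam}_recent"] += risk[f"{fam}_recent"]
        counts["prop_any_risk"] += risk["any_ever"]
        counts["prop_any_risk_recent"] += risk["any_recent"]
        for fam in SUPPORT_FAMILIES:
            counts[f"prop_{fam}"] += support[f"{fam}_ever"]
            counts[f"prop_{fam}_recent"] += support[f"{fam}_recent"]
        counts["prop_any_support"] += support["any_ever"]
        counts["prop_any_support_recent"] += support["any_recent"]
    row: dict = {"ego_id": net.ego_id, "wave": net.wave, "n_alters": n}
    row.update({k: v / n for k, v in counts.items()})
    return row


def composition_table(alter_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized composition measures: one row per (ego, wave).

    Equivalent to :func:`network_proportions` applied to every wave network
    in the alter table (the object route is kept as the oracle in tests).
    """
    df = alter_df.copy()
    df["any_risk_ever"] = df[[f"{f}_ever" for f in RISK_FAMILIES]].any(axis=1)
    df["any_risk_recent"] = df[[f"{f}_recent" for f in RISK_FAMILIES]].any(axis=1)
    df["any_support_ever"] = df[[f"{f}_ever" for f in SUPPORT_FAMILIES]].any(axis=1)
    df["any_support_recent"] = df[[f"{f}_recent" for f in SUPPORT_FAMILIES]].any(axis=1)
    # source map: prop_<fam>[_recent] <- <fam>_<ever|recent>
    cols: dict[str, str] = {}
    for fam in _MEASURE_FAMILIES:
        cols[f"prop_{fam}"] = f"{fam}_ever"
        cols[f"prop_{fam}_recent"] = f"{fam}_recent"
    g = df.groupby(["ego_id", "wave"], sort=True)
    out = g[list(cols.values())].mean()
    out.columns = list(cols.keys())
    out["n_alters"] = g.size()
    return out.reset_index()
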