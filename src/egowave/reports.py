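"""Report shaping: trial-style outcome tables and recruitment arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import PROPORTION_MEASURES
from .effects import COUNT_MEASURES
from .model import SchemaError

__all__ = ["followup_retention_percent", "render_tables", "effect_size_label"]

PROPORTION_LABELS = {
    "prop_drink": "Drinking Partners",
    "prop_drink_recent": "Recent Drinking Partners",
    "prop_drug": "Drug Use Partners",
    "prop_drug_recent": "Recent Drug Use Partners",
    "prop_influence": "AOD Use Influence",
    "prop_influence_recent": "Recent AOD Use Influence",
    "prop_any_risk": "Any Risk",
    "prop_any_risk_recent": "Recent Any Risk",
    "prop_emo": "Emotional Support",
    "prop_emo_recent": "Recent Emotional Support",
    "prop_info": "Informational Support",
    "prop_info_recent": "Recent Informational Support",
    "prop_tang": "Tangible Support",
    "prop_tang_recent": "Recent Tangible Support",
    "prop_any_support": "Any Support",
    "prop_any_support_recent": "Recent Any Support",
}
COUNT_LABELS = {
    "stop_drink": "Stopped drinking with",
    "stop_drug": "Stopped using drugs with",
    "stop_influence": "Stopped being influenced to use AOD by",
    "stop_any": "Stopped any AOD risk with",
    "start_drink": "Started drinking with",
    "start_drug": "Started using drugs with",
    "start_influence": "Started being influenced to use AOD by",
    "start_any": "Started any AOD risk with",
    "total_unique_alters": "Total unique alters named",
    "crosswave_density": "Cross-wave density",
    "crosswave_components": "Cross-wave components",
    "n_dropped": "Dropped alters",
    "n_added": "Added alters",
    "n_retained": "Retained alters",
}


def followup_retention_percent(n_randomized: int, n_completed: int) -> float:
    """Follow-up completion percentage, rounded to the nearest integer as
    customarily reported in recruitment summaries."""
    if n_randomized <= 0 or n_completed < 0 or n_completed > n_randomized:
        raise ValueError("need 0 <= completers <= randomized, randomized > 0")
    return round(100.0 * n_completed / n_randomized)


def effect_size_label(d: float) -> str:
    """Conventional qualitative label for |d|: small (.20), medium (.50),
    large (.80)."""
    d = abs(d)
    if d >= 0.80:
        return "large"
    if d >= 0.50:
        return "medium"
    if d >= 0.20:
        return "small"
    return "negligible"


def _fmt(x, nd=2) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.{nd}f}"


def _proportion_table(df: pd.DataFrame) -> list[str]:
    lines = [
        "| Proportion of alter types | Ctrl base m(SD) | Ctrl FU m(SD) | Int base m(SD) | Int FU m(SD) | Est. | p-val | 95% CI | d |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for outcome in PROPORTION_MEASURES:
        sub = df[df["outcome_name"] == outcome]
        if sub.empty:
            continue
        r = sub.iloc[0]
        lines.append(
            "| {label} | {bc} ({bcs}) | {fc} ({fcs}) | {bi} ({bis}) | {fi} ({fis}) "
            "| {est}{sig} | {p} | ({lo}, {hi}) | {d} |".format(
                label=PROPORTION_LABELS.get(outcome, outcome),
                bc=_fmt(r.get("mean_b_ctrl")), bcs=_fmt(r.get("sd_b_ctrl")),
                fc=_fmt(r.get("mean_f_ctrl")), fcs=_fmt(r.get("sd_f_ctrl")),
                bi=_fmt(r.get("mean_b_int")), bis=_fmt(r.get("sd_b_int")),
                fi=_fmt(r.get("mean_f_int")), fis=_fmt(r.get("sd_f_int")),
                est=_fmt(r["estimate"]), sig=r.get("sig", ""),
                p=_fmt(r["p_value"], 3),
                lo=_fmt(r["ci_low"]), hi=_fmt(r["ci_high"]),
                d=_fmt(r.get("cohens_d")),
            )
        )
    return lines


def _count_table(df: pd.DataFrame) -> list[str]:
    lines = [
        "| Outcome | Ctrl m(SD) | Int m(SD) | Est. | p-val | 95% CI | d |",
        "|---|---|---|---|---|---|---|",
    ]
    for outcome in COUNT_MEASURES:
        sub = df[df["outcome_name"] == outcome]
        if sub.empty:
            continue
        r = sub.iloc[0]
        if r["family"] == "poisson":
            # count outcomes reported as IRRs with exponentiated CIs
            est, lo, hi = r["irr"], r["irr_low"], r["irr_high"]
        else:
            est, lo, hi = r["estimate"], r["ci_low"], r["ci_high"]
        lines.append(
            "| {label} | {mc} ({sc}) | {mi} ({si}) | {est}{sig} | {p} | ({lo}, {hi}) | {d} |".format(
                label=COUNT_LABELS.get(outcome, outcome),
                mc=_fmt(r.get("mean_ctrl")), sc=_fmt(r.get("sd_ctrl")),
                mi=_fmt(r.get("mean_int")), si=_fmt(r.get("sd_int")),
                est=_fmt(est), sig=r.get("sig", ""),
                p=_fmt(r["p_value"], 3),
                lo=_fmt(lo), hi=_fmt(hi),
                d=_fmt(r.get("cohens_d")),
            )
        )
    return lines


def render_tables(results: pd.DataFrame) -> str:
    """Render the tidy results of the two-stage analysis as markdown tables:
    per stage, a 16-row proportion table and a 14-row count table.  Count
    outcomes show IRRs (density stays on the linear scale).  An empty input
    renders headers only."""
    required = {"outcome_name", "sample", "family", "estimate", "ci_low", "ci_high", "p_value"}
    missing = required - set(results.columns)
    if missing:
        raise SchemaError(f"results table missing columns: {sorted(missing)}")
    lines = ["# Intervention effects on personal network change", ""]
    stages = [s for s in ("primary_site_only", "full") if s in set(results["sample"])]
    for stage in stages or []:
        df = results[results["sample"] == stage]
        title = "Primary site only" if stage == "primary_site_only" else "Full sample"
        n = int(df["n_egos"].iloc[0]) if len(df) else 0
        lines.append(f"## {title} (N = {n} responders)")
        lines.append("")
        lines.append("### Network composition (weighted linear models)")
        lines.extend(_proportion_table(df))
        lines.append("")
        lines.append("### Relationship change, structure, and turnover")
        lines.extend(_count_table(df))
        lines.append("")
    lines.append(
        "Significance: * p < .05, ~ p < .10. Cohen's d conventions: "
        "small (.20), medium (.50), large (.80). Count estimates are IRRs; "
        "density estimates are linear-model estimates. "
        f"{len(results)} exploratory tests were run without multiplicity correction."
    )
    return "\n".join(lines) + "\n"
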