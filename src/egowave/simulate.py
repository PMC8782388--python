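"""Synthetic two-wave egocentric cohort generator.

Emulates the statistical structure of a small two-site randomized trial of a
network-focused intervention among adults transitioning out of homelessness:

* ~149 contacted residents screened with AUDIT-C (>=4 men / >=3 women) or
  DAST (>2), yielding ~49 eligible egos;
* permuted-block randomization stratified by gender;
* a baseline personal network per ego (up to 20 alters, twelve dichotomous
  risk/support flags per alter with recent => ever by construction, and
  i.i.d. alter-alter ties);
* a follow-up network formed by per-alter retention (arm-specific), per-flag
  stopping/starting transitions for retained alters, and newly added alters
  drawn at baseline prevalences back up to the baseline size;
* an exactly calibrated intervention effect on the follow-up proportion of
  recent drinking partners; and
* covariate-dependent (income, site) follow-up nonresponse at ~16%.

All randomness flows from a single :class:`numpy.random.Generator`; a fixed
seed yields byte-identical emitted tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .model import (
    AUDIT_C_RANGE,
    DAST_RANGE,
    FAMILIES,
    FLAGS,
    ConfigError,
    DomainError,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "screen_eligibility",
    "randomize",
    "generate_cohort",
    "apply_nonresponse",
    "generate_dataset",
]

# Screener score distributions chosen so that roughly one third of contacted
# residents screen eligible (matching a 49/149 yield):
#   P(AUDIT-C >= 4) = .22 (men's threshold), P(AUDIT-C >= 3) = .32 (women's),
#   P(DAST > 2) = .12; eligibility = alcohol OR drug criterion, so
#   P(eligible | male) = 1 - .78*.88 = .3136, P(eligible | female) = .4016,
#   and at 80% male the mixture is ~.331.
AUDIT_C_PMF = (0.40, 0.16, 0.12, 0.10, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.003, 0.002)
DAST_PMF = (0.55, 0.20, 0.13, 0.06, 0.03, 0.02, 0.01)

#: Baseline marginal prevalence of each alter flag (midpoints of the trial's
#: weighted baseline descriptive means across arms and samples).
DEFAULT_PREVALENCES = {
    "drink_ever": 0.26,
    "drink_recent": 0.11,
    "drug_ever": 0.19,
    "drug_recent": 0.06,
    "influence_ever": 0.13,
    "influence_recent": 0.05,
    "emo_ever": 0.78,
    "emo_recent": 0.61,
    "info_ever": 0.76,
    "info_recent": 0.57,
    "tang_ever": 0.58,
    "tang_recent": 0.32,
}

# Per-flag transition rates for retained alters over the 3-month window.
# Recent-risk engagement re-starts at high rates under usual care (the trial's
# control arm saw recent drinking roughly double between waves), while
# support relationships are comparatively stable.
DEFAULT_STOPPING = {
    "drink_ever": 0.30, "drink_recent": 0.30,
    "drug_ever": 0.30, "drug_recent": 0.30,
    "influence_ever": 0.30, "influence_recent": 0.30,
    "emo_ever": 0.15, "emo_recent": 0.25,
    "info_ever": 0.15, "info_recent": 0.25,
    "tang_ever": 0.15, "tang_recent": 0.25,
}
DEFAULT_STARTING = {
    "drink_ever": 0.15, "drink_recent": 0.50,
    "drug_ever": 0.15, "drug_recent": 0.35,
    "influence_ever": 0.15, "influence_recent": 0.20,
    "emo_ever": 0.15, "emo_recent": 0.20,
    "info_ever": 0.15, "info_recent": 0.20,
    "tang_ever": 0.15, "tang_recent": 0.20,
}

RACES = ("african_american", "white", "latino", "other")
RACE_P = (0.56, 0.20, 0.14, 0.10)
EDUCATION = ("hs_or_less", "more_than_hs")
EDUCATION_P = (0.68, 0.32)
MARRIED = ("never_married", "ever_married")
MARRIED_P = (0.66, 0.34)


def _as_per_arm(rates, name: str) -> dict[str, dict[str, float]]:
    """Accept either {flag: p} (shared) or {arm: {flag: p}} rate mappings."""
    if not isinstance(rates, Mapping):
        raise ConfigError(f"{name} must be a mapping")
    if set(rates) <= {"control", "intervention"}:
        out = {arm: dict(rates.get(arm, {})) for arm in ("control", "intervention")}
    else:
        out = {"control": dict(rates), "intervention": dict(rates)}
    for arm, m in out.items():
        for f in FLAGS:
            p = m.setdefault(f, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}[{arm}][{f}] = {p} outside [0, 1]")
    return out


@dataclass
class SimConfig:
    """Generator configuration; defaults encode the trial's conditions."""

    n_contacted: int = 149
    n_randomized: int | None = None  # exact eligible count override (simulations)
    site_mix: float = 0.70  # share of egos at the primary site
    prob_male: float = 0.80
    network_size_distribution: Mapping[int, float] = field(default_factory=lambda: {20: 1.0})
    baseline_flag_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    tie_density: float = 0.20
    retention_prob: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.48, "intervention": 0.67}
    )
    stopping_rate: Mapping = field(default_factory=lambda: dict(DEFAULT_STOPPING))
    starting_rate: Mapping = field(default_factory=lambda: dict(DEFAULT_STARTING))
    arm_effect_recent_drink: float | None = -0.13  # target difference; None = uncalibrated
    arm_effect_income_interaction: float = 0.0  # per-SD-of-log-income effect modification
    nonresponse_rate: float = 8.0 / 49.0
    nonresponse_covariate_strength: Mapping[str, float] = field(
        default_factory=lambda: {"income": -0.6, "site": 0.8}
    )
    income_median: float = 471.0  # monthly, lognormal median
    income_sigma: float = 0.8
    audit_c_pmf: tuple = AUDIT_C_PMF
    dast_pmf: tuple = DAST_PMF
    block_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size % 2:
            raise ConfigError(f"block_size must be even, got {self.block_size}")
        for name in ("site_mix", "prob_male", "tie_density", "nonresponse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for arm, p in dict(self.retention_prob).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"retention_prob[{arm}] = {p} outside [0, 1]")
        prev = dict(self.baseline_flag_prevalences)
        for f in FLAGS:
            if f not in prev:
                raise ConfigError(f"baseline_flag_prevalences missing flag {f!r}")
            if not 0.0 <= prev[f] <= 1.0:
                raise ConfigError(f"prevalence[{f}] outside [0, 1]")
        for fam in FAMILIES:
            if prev[f"{fam}_recent"] > prev[f"{fam}_ever"] + 1e-12:
                raise ConfigError(
                    f"{fam}: recent prevalence {prev[f'{fam}_recent']} exceeds "
                    f"ever prevalence {prev[f'{fam}_ever']}"
                )
        sizes = dict(self.network_size_distribution)
        if not sizes or abs(sum(sizes.values()) - 1.0) > 1e-9:
            raise ConfigError("network_size_distribution must sum to 1")
        if any(not 1 <= k <= 20 for k in sizes):
            raise ConfigError("network sizes must be in 1..20")
        for pmf, name in ((self.audit_c_pmf, "audit_c_pmf"), (self.dast_pmf, "dast_pmf")):
            if abs(sum(pmf) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        self.stopping_rate = _as_per_arm(self.stopping_rate, "stopping_rate")
        self.starting_rate = _as_per_arm(self.starting_rate, "starting_rate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network_size_distribution"] = {int(k): float(v) for k, v in dict(self.network_size_distribution).items()}
        return d


def screen_eligibility(audit_c: int, dast: int, gender: str) -> bool:
    """Screener eligibility: AUDIT-C >= 4 (men) / >= 3 (women), or DAST > 2."""
    if not AUDIT_C_RANGE[0] <= audit_c <= AUDIT_C_RANGE[1]:
        raise DomainError(f"audit_c {audit_c} outside {AUDIT_C_RANGE}")
    if not DAST_RANGE[0] <= dast <= DAST_RANGE[1]:
        raise DomainError(f"dast {dast} outside {DAST_RANGE}")
    if gender not in ("male", "female"):
        raise DomainError(f"gender must be 'male' or 'female', got {gender!r}")
    audit_threshold = 4 if gender == "male" else 3
    return audit_c >= audit_threshold or dast > 2


def _eligible_mask(audit_c: np.ndarray, dast: np.ndarray, is_male: np.ndarray) -> np.ndarray:
    thr = np.where(is_male, 4, 3)
    return (audit_c >= thr) | (dast > 2)


def randomize(genders, block_size: int = 4, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Permuted-block randomization stratified by gender.

    ``genders`` is a sequence of "male"/"female" (or any EgoRecord-like
    objects with a ``gender`` attribute).  Within each gender stratum every
    complete block of ``block_size`` contains exactly half intervention and
    half control; the final incomplete block is a truncated permuted block,
    so stratum imbalance never exceeds ``block_size / 2``.
    """
    if block_size % 2:
        raise ConfigError(f"block_size must be even, got {block_size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genders = np.asarray([getattr(g, "gender", g) for g in genders])
    arms = np.empty(len(genders), dtype=object)
    half = block_size // 2
    block = np.array(["intervention"] * half + ["control"] * half, dtype=object)
    for stratum in ("male", "female"):
        idx = np.flatnonzero(genders == stratum)
        n_blocks = -(-len(idx) // block_size) if len(idx) else 0
        assignment = np.concatenate([rng.permutation(block) for _ in range(n_blocks)]) if n_blocks else np.array([], dtype=object)
        arms[idx] = assignment[: len(idx)]
    return arms


def _draw_sizes(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    sizes = sorted(dict(cfg.network_size_distribution).items())
    vals = np.array([s for s, _ in sizes])
    probs = np.array([p for _, p in sizes], dtype=float)
    return rng.choice(vals, size=n, p=probs / probs.sum())


def _draw_flags(cfg: SimConfig, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Baseline flag draws: ever first, recent conditional on ever, so the
    recent => ever implication holds by construction."""
    prev = dict(cfg.baseline_flag_prevalences)
    out: dict[str, np.ndarray] = {}
    for fam in FAMILIES:
        pe, pr = prev[f"{fam}_ever"], prev[f"{fam}_recent"]
        cond = pr / pe if pe > 0 else 0.0
        ever = rng.random(m) < pe
        recent = ever & (rng.random(m) < cond)
        out[f"{fam}_ever"] = ever
        out[f"{fam}_recent"] = recent
    return out


def followup_recent_drink_prevalence(cfg: SimConfig, arm: str) -> float:
    """Expected marginal prevalence of the recent-drinking flag in a
    follow-up network under the configured dynamics, before any calibrated
    arm adjustment.  Closed form under the generative model; used to solve
    for the adjustment that yields the configured arm difference."""
    prev = dict(cfg.baseline_flag_prevalences)
    pe, pr = prev["drink_ever"], prev["drink_recent"]
    c = pr / pe if pe > 0 else 0.0
    s_e = cfg.stopping_rate[arm]["drink_ever"]
    r_e = cfg.starting_rate[arm]["drink_ever"]
    s_r = cfg.stopping_rate[arm]["drink_recent"]
    r_r = cfg.starting_rate[arm]["drink_recent"]
    rho = dict(cfg.retention_prob)[arm]
    # retained alters: evolve ever, then recent conditional on follow-up ever
    q_ret = pe * c * (1 - s_e) * (1 - s_r) + (pe * (1 - c) * (1 - s_e) + (1 - pe) * r_e) * r_r
    return rho * q_ret + (1 - rho) * pr


def _followup_ever_drink_prevalence(cfg: SimConfig, arm: str) -> float:
    prev = dict(cfg.baseline_flag_prevalences)
    pe = prev["drink_ever"]
    s_e = cfg.stopping_rate[arm]["drink_ever"]
    r_e = cfg.starting_rate[arm]["drink_ever"]
    rho = dict(cfg.retention_prob)[arm]
    return rho * (pe * (1 - s_e) + (1 - pe) * r_e) + (1 - rho) * pe


def _pair_index(size: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(size, k=1)


def generate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (ego_table, alter_table, tie_table) for one randomized cohort.

    Contacted egos are screened; eligible egos are block-randomized within
    gender; every randomized ego receives a baseline and a follow-up network.
    Nonresponse is *not* applied here — see :func:`apply_nonresponse` /
    :func:`generate_dataset`.  Only ``knows=True`` tie rows are emitted
    (absent pairs are untied by convention).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # --- screening ----------------------------------------------------------
    if cfg.n_randomized is None:
        is_male = rng.random(cfg.n_contacted) < cfg.prob_male
        audit = rng.choice(len(cfg.audit_c_pmf), size=cfg.n_contacted, p=np.asarray(cfg.audit_c_pmf))
        dast = rng.choice(len(cfg.dast_pmf), size=cfg.n_contacted, p=np.asarray(cfg.dast_pmf))
        keep = _eligible_mask(audit, dast, is_male)
        is_male, audit, dast = is_male[keep], audit[keep], dast[keep]
    else:
        parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        n_found = 0
        while n_found < cfg.n_randomized:
            chunk = max(64, 4 * (cfg.n_randomized - n_found))
            m = rng.random(chunk) < cfg.prob_male
            a = rng.choice(len(cfg.audit_c_pmf), size=chunk, p=np.asarray(cfg.audit_c_pmf))
            d = rng.choice(len(cfg.dast_pmf), size=chunk, p=np.asarray(cfg.dast_pmf))
            keep = _eligible_mask(a, d, m)
            parts.append((m[keep], a[keep], d[keep]))
            n_found += int(keep.sum())
        is_male = np.concatenate([p[0] for p in parts])[: cfg.n_randomized]
        audit = np.concatenate([p[1] for p in parts])[: cfg.n_randomized]
        dast = np.concatenate([p[2] for p in parts])[: cfg.n_randomized]

    n = len(is_male)
    if n == 0:
        raise ConfigError("screening yielded zero eligible egos")
    genders = np.where(is_male, "male", "female")
    arms = randomize(genders, cfg.block_size, rng)

    # --- demographics -------------------------------------------------------
    ego_ids = np.array([f"E{i + 1:04d}" for i in range(n)])
    site = np.where(rng.random(n) < cfg.site_mix, "primary_site", "secondary_site")
    age = np.clip(np.round(rng.normal(48, 10, n)), 18, 85).astype(int)
    race = rng.choice(RACES, size=n, p=RACE_P)
    education = rng.choice(EDUCATION, size=n, p=EDUCATION_P)
    married = rng.choice(MARRIED, size=n, p=MARRIED_P)
    n_children = rng.poisson(0.89, n)
    income = np.round(cfg.income_median * np.exp(cfg.income_sigma * rng.standard_normal(n)), 2)
    readiness = rng.integers(1, 11, n)

    ego_df = pd.DataFrame(
        {
            "ego_id": ego_ids,
            "site": site,
            "arm": arms.astype(str),
            "gender": genders,
            "age": age,
            "race": race,
            "education": education,
            "married": married,
            "n_children": n_children,
            "income": income,
            "audit_c": audit,
            "dast": dast,
            "readiness_to_change": readiness,
            "responded_followup": True,
        }
    )

    # --- baseline networks --------------------------------------------------
    sizes = _draw_sizes(cfg, n, rng)
    m_base = int(sizes.sum())
    ego_row = np.repeat(np.arange(n), sizes)
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    alter_num = np.arange(m_base) - np.repeat(offsets, sizes)
    base_flags = _draw_flags(cfg, m_base, rng)

    # baseline ties (only tied pairs kept); remember them for persistence
    tie_rows_ego: list[np.ndarray] = []
    tie_rows_a: list[np.ndarray] = []
    tie_rows_b: list[np.ndarray] = []
    pair_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    base_tied: list[set[tuple[int, int]]] = []
    for e in range(n):
        s = int(sizes[e])
        if s < 2:
            base_tied.append(set())
            continue
        ii, jj = pair_cache.setdefault(s, _pair_index(s))
        knows = rng.random(len(ii)) < cfg.tie_density
        ti, tj = ii[knows], jj[knows]
        base_tied.append(set(zip(ti.tolist(), tj.tolist())))
        if len(ti):
            tie_rows_ego.append(np.full(len(ti), e))
            tie_rows_a.append(ti)
            tie_rows_b.append(tj)

    # --- follow-up networks -------------------------------------------------
    arm_row = arms[ego_row]
    rho = np.where(arm_row == "intervention",
                   dict(cfg.retention_prob)["intervention"],
                   dict(cfg.retention_prob)["control"])
    retained = rng.random(m_base) < rho

    fu_flags: dict[str, np.ndarray] = {}
    for fam in FAMILIES:
        ever_b = base_flags[f"{fam}_ever"]
        recent_b = base_flags[f"{fam}_recent"]
        s_e = np.where(arm_row == "intervention",
                       cfg.stopping_rate["intervention"][f"{fam}_ever"],
                       cfg.stopping_rate["control"][f"{fam}_ever"])
        r_e = np.where(arm_row == "intervention",
                       cfg.starting_rate["intervention"][f"{fam}_ever"],
                       cfg.starting_rate["control"][f"{fam}_ever"])
        s_r = np.where(arm_row == "intervention",
                       cfg.stopping_rate["intervention"][f"{fam}_recent"],
                       cfg.stopping_rate["control"][f"{fam}_recent"])
        r_r = np.where(arm_row == "intervention",
                       cfg.starting_rate["intervention"][f"{fam}_recent"],
                       cfg.starting_rate["control"][f"{fam}_recent"])
        u = rng.random(m_base)
        ever_f = np.where(ever_b, u >= s_e, u < r_e)
        t = np.where(recent_b, 1.0 - s_r, r_r)
        recent_f = ever_f & (rng.random(m_base) < t)
        fu_flags[f"{fam}_ever"] = ever_f
        fu_flags[f"{fam}_recent"] = recent_f

    n_ret = np.bincount(ego_row[retained], minlength=n)
    n_add = sizes - n_ret  # follow-up target size = baseline size
    m_add = int(n_add.sum())
    add_ego_row = np.repeat(np.arange(n), n_add)
    add_offsets = np.concatenate(([0], np.cumsum(n_add)[:-1]))
    add_num = sizes[add_ego_row] + (np.arange(m_add) - np.repeat(add_offsets, n_add))
    add_flags = _draw_flags(cfg, m_add, rng)

    # --- calibrated arm effect on the recent-drinking flag ------------------
    # arm_effect_recent_drink is the *target* arm difference in the follow-up
    # marginal prevalence; a value of 0 is calibrated to a true null (the
    # arm-specific retention would otherwise leak a small difference into
    # this flag).  None disables calibration entirely.
    if cfg.arm_effect_recent_drink is not None:
        q_ctrl = followup_recent_drink_prevalence(cfg, "control")
        q_int0 = followup_recent_drink_prevalence(cfg, "intervention")
        e_int0 = _followup_ever_drink_prevalence(cfg, "intervention")
        z_income = (np.log(income) - np.log(cfg.income_median)) / cfg.income_sigma
        delta = cfg.arm_effect_recent_drink + cfg.arm_effect_income_interaction * z_income
        q_target = np.clip(q_ctrl + delta, 0.0, e_int0)
        if np.any(q_ctrl + delta < -1e-9) or np.any(q_ctrl + delta > e_int0 + 1e-9):
            log.warning("arm effect target prevalence clipped into [0, %g]", e_int0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_down = np.clip((q_int0 - q_target) / q_int0 if q_int0 > 0 else 0.0, 0.0, 1.0)
            pi_up = np.clip(
                (q_target - q_int0) / max(e_int0 - q_int0, 1e-12), 0.0, 1.0
            )
        is_int_ego = arms == "intervention"

        def _adjust(flag_ever, flag_recent, ego_of_row, u):
            pi_d = np.where(is_int_ego[ego_of_row], pi_down[ego_of_row], 0.0)
            pi_u = np.where(is_int_ego[ego_of_row], pi_up[ego_of_row], 0.0)
            flip_down = flag_recent & (u < pi_d)
            flip_up = flag_ever & ~flag_recent & (u < pi_u)
            return (flag_recent & ~flip_down) | flip_up

        fu_flags["drink_recent"] = _adjust(
            fu_flags["drink_ever"], fu_flags["drink_recent"], ego_row, rng.random(m_base)
        )
        add_flags["drink_recent"] = _adjust(
            add_flags["drink_ever"], add_flags["drink_recent"], add_ego_row, rng.random(m_add)
        )

    # --- assemble alter table ----------------------------------------------
    def _labels(nums: np.ndarray) -> np.ndarray:
        if nums.size == 0:
            return np.empty(0, dtype="U3")
        return np.char.add("A", np.char.zfill((nums + 1).astype(str), 2))

    base_part = pd.DataFrame({"ego_id": ego_ids[ego_row], "wave": "baseline", "alter_label": _labels(alter_num)})
    for f in FLAGS:
        base_part[f] = base_flags[f]
    ret_part = pd.DataFrame(
        {"ego_id": ego_ids[ego_row[retained]], "wave": "followup", "alter_label": _labels(alter_num[retained])}
    )
    for f in FLAGS:
        ret_part[f] = fu_flags[f][retained]
    add_part = pd.DataFrame({"ego_id": ego_ids[add_ego_row], "wave": "followup", "alter_label": _labels(add_num)})
    for f in FLAGS:
        add_part[f] = add_flags[f]
    alter_df = pd.concat([base_part, ret_part, add_part], ignore_index=True)
    alter_df = alter_df.sort_values(["ego_id", "wave", "alter_label"], kind="stable").reset_index(drop=True)

    # --- follow-up ties: persist retained pairs, draw pairs with entrants ---
    fu_ego: list[np.ndarray] = []
    fu_a: list[np.ndarray] = []
    fu_b: list[np.ndarray] = []
    for e in range(n):
        lo, hi = offsets[e], offsets[e] + sizes[e]
        ret_nums = alter_num[lo:hi][retained[lo:hi]]
        alo, ahi = add_offsets[e], add_offsets[e] + n_add[e]
        new_nums = add_num[alo:ahi]
        present = np.concatenate([ret_nums, new_nums]).astype(int)
        if len(present) < 2:
            continue
        present.sort()
        ii, jj = pair_cache.setdefault(len(present), _pair_index(len(present)))
        a_num, b_num = present[ii], present[jj]
        # follow-up-only alter numbers start at sizes[e], so a pair is
        # retained-retained iff both numbers predate the follow-up block
        both_retained = (a_num < sizes[e]) & (b_num < sizes[e])
        tied_set = base_tied[e]
        knows = rng.random(len(a_num)) < cfg.tie_density
        rr = np.flatnonzero(both_retained)
        knows[rr] = [(int(a_num[k]), int(b_num[k])) in tied_set for k in rr]
        if knows.any():
            fu_ego.append(np.full(int(knows.sum()), e))
            fu_a.append(a_num[knows])
            fu_b.append(b_num[knows])

    def _tie_frame(ego_parts, a_parts, b_parts, wave: str) -> pd.DataFrame:
        if not ego_parts:
            return pd.DataFrame(columns=["ego_id", "wave", "alter_a", "alter_b", "knows"])
        e = np.concatenate(ego_parts)
        a = np.concatenate(a_parts)
        b = np.concatenate(b_parts)
        return pd.DataFrame(
            {
                "ego_id": ego_ids[e],
                "wave": wave,
                "alter_a": _labels(a),
                "alter_b": _labels(b),
                "knows": True,
            }
        )

    tie_df = pd.concat(
        [
            _tie_frame(tie_rows_ego, tie_rows_a, tie_rows_b, "baseline"),
            _tie_frame(fu_ego, fu_a, fu_b, "followup"),
        ],
        ignore_index=True,
    )
    tie_df = tie_df.sort_values(["ego_id", "wave", "alter_a", "alter_b"], kind="stable").reset_index(drop=True)
    return ego_df, alter_df, tie_df


def apply_nonresponse(
    ego_table: pd.DataFrame, config: SimConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw follow-up response indicators from a logistic dropout model.

    Dropout log-odds depend on standardized log income and secondary-site
    residence with the configured coefficients; the intercept is solved so
    the expected dropout rate over the realized covariates equals
    ``nonresponse_rate``.  Zero coefficients give MCAR dropout.  Returns a
    copy with ``responded_followup`` set; follow-up network rows of
    nonresponders are removed by :func:`generate_dataset`.
    """
    cfg = config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed + 1 if seed is None else seed
    )
    out = ego_table.copy()
    if cfg.nonresponse_rate <= 0:
        out["responded_followup"] = True
        return out
    strength = dict(cfg.nonresponse_covariate_strength)
    z_income = (np.log(out["income"].to_numpy(float)) - np.log(cfg.income_median)) / cfg.income_sigma
    secondary = (out["site"] == "secondary_site").to_numpy(float)
    eta = strength.get("income", 0.0) * z_income + strength.get("site", 0.0) * secondary

    def mean_dropout(a: float) -> float:
        return float(expit(a + eta).mean()) - cfg.nonresponse_rate

    intercept = brentq(mean_dropout, -30.0, 30.0)
    p_drop = expit(intercept + eta)
    out["responded_followup"] = rng.random(len(out)) >= p_drop
    return out


def generate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full emission path: generate, apply nonresponse, strip the follow-up
    network rows of nonresponders from the alter and tie tables."""
    base_seed = config.seed if seed is None else seed
    ego_df, alter_df, tie_df = generate_cohort(config, seed=base_seed)
    ego_df = apply_nonresponse(ego_df, config, seed=np.random.default_rng(base_seed + 1))
    nonresp = set(ego_df.loc[~ego_df["responded_followup"], "ego_id"])
    drop_a = (alter_df["wave"] == "followup") & alter_df["ego_id"].isin(nonresp)
    drop_t = (tie_df["wave"] == "followup") & tie_df["ego_id"].isin(nonresp)
    return (
        ego_df,
        alter_df[~drop_a].reset_index(drop=True),
        tie_df[~drop_t].reset_index(drop=True),
    )
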