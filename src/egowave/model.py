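"""Domain types for two-wave egocentric interview data.

An *ego* is an interviewed respondent; *alters* are the network members the
ego names in response to a name-generator prompt (capped at 20 adults), and
each alter carries twelve dichotomous name-interpreter flags: six AOD-risk
flags (drinking partner, drug-use partner, AOD-use influence, each "ever"
and "recent") and six social-support flags (emotional, informational,
tangible, each "ever" and "recent").  Alter-alter ties record whether two
named alters know each other; the ego is never a node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

__all__ = [
    "RISK_FAMILIES",
    "SUPPORT_FAMILIES",
    "FAMILIES",
    "FLAGS",
    "WAVES",
    "MAX_ALTERS",
    "SchemaError",
    "IntegrityError",
    "DomainError",
    "ConfigError",
    "InsufficientDataError",
    "DegenerateOutcomeError",
    "EgoRecord",
    "AlterObservation",
    "TieObservation",
    "WaveNetwork",
    "Violation",
    "normalize_label",
    "tie_key",
    "validate_wave_network",
]

RISK_FAMILIES = ("drink", "drug", "influence")
SUPPORT_FAMILIES = ("emo", "info", "tang")
FAMILIES = RISK_FAMILIES + SUPPORT_FAMILIES
#: The twelve name-interpreter flags, ordered family-major.
FLAGS = tuple(f"{fam}_{suffix}" for fam in FAMILIES for suffix in ("ever", "recent"))

WAVES = ("baseline", "followup")
#: Name-generator cap: "name 20 adults".
MAX_ALTERS = 20

AUDIT_C_RANGE = (0, 12)
DAST_RANGE = (0, 10)


class SchemaError(ValueError):
    """An input table is missing a required column or has a bad dtype."""


class IntegrityError(ValueError):
    """Input rows violate uniqueness or referential integrity."""


class DomainError(ValueError):
    """An operation was called on input outside its domain."""


class ConfigError(ValueError):
    """A configuration value is invalid."""


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested model."""


class DegenerateOutcomeError(ValueError):
    """An outcome with no variation (all-zero counts, all-respond cohorts)."""


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Canonical alter-name key: trimmed, case-folded, internal whitespace
    collapsed.  Cross-wave alter matching is exact on this key."""
    return _WS.sub(" ", str(label).strip()).casefold()


def tie_key(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered pair key for an undirected tie."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EgoRecord:
    """One trial participant (ego)."""

    ego_id: str
    site: str  # {"primary_site", "secondary_site"}
    arm: str  # {"intervention", "control"}
    gender: str  # {"male", "female"}
    age: float = float("nan")
    race: str = ""
    education: str = ""
    married: str = ""
    n_children: int = 0
    income: float = float("nan")  # currency per month
    audit_c: int = 0  # 0-12 alcohol screener
    dast: int = 0  # 0-10 drug screener
    readiness_to_change: int = 0
    responded_followup: bool = True
    nonresponse_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.arm or not self.site:
            raise DomainError(f"ego {self.ego_id}: arm and site must be non-missing")
        if not AUDIT_C_RANGE[0] <= self.audit_c <= AUDIT_C_RANGE[1]:
            raise DomainError(f"ego {self.ego_id}: audit_c {self.audit_c} outside {AUDIT_C_RANGE}")
        if not DAST_RANGE[0] <= self.dast <= DAST_RANGE[1]:
            raise DomainError(f"ego {self.ego_id}: dast {self.dast} outside {DAST_RANGE}")
        if not self.nonresponse_weight > 0:
            raise DomainError(f"ego {self.ego_id}: nonresponse_weight must be > 0")


@dataclass
class AlterObservation:
    """One alter as reported by one ego at one wave.

    Every ``*_recent`` flag is expected to imply the matching ``*_ever``
    flag; violations are surfaced by :func:`validate_wave_network`, never
    silently corrected.
    """

    ego_id: str
    wave: str
    alter_label: str
    drink_ever: bool = False
    drink_recent: bool = False
    drug_ever: bool = False
    drug_recent: bool = False
    influence_ever: bool = False
    influence_recent: bool = False
    emo_ever: bool = False
    emo_recent: bool = False
    info_ever: bool = False
    info_recent: bool = False
    tang_ever: bool = False
    tang_recent: bool = False

    def flag(self, name: str) -> bool:
        return bool(getattr(self, name))

    def flags(self) -> dict[str, bool]:
        return {f: bool(getattr(self, f)) for f in FLAGS}


# keep FLAGS aligned with the dataclass definition
assert FLAGS == tuple(f.name for f in fields(AlterObservation))[3:]


@dataclass
class TieObservation:
    """Whether two alters in one ego's wave network know each other.

    Undirected; stored with a lexicographically ordered pair key.  A missing
    record and an explicit ``knows=False`` record are equivalent (no tie).
    """

    ego_id: str
    wave: str
    alter_a: str
    alter_b: str
    knows: bool = True

    def __post_init__(self) -> None:
        self.alter_a, self.alter_b = tie_key(self.alter_a, self.alter_b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.alter_a, self.alter_b)


@dataclass
class WaveNetwork:
    """One ego's personal network at one wave: alters plus alter-alter ties."""

    ego_id: str
    wave: str
    alters: list[AlterObservation] = field(default_factory=list)
    ties: list[TieObservation] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [a.alter_label for a in self.alters]

    @property
    def size(self) -> int:
        return len(self.alters)

    def tie_pairs(self) -> set[tuple[str, str]]:
        """Set of tied (knows=True) unordered label pairs."""
        return {t.pair for t in self.ties if t.knows}


@dataclass(frozen=True)
class Violation:
    """One structural-validation finding.  Violations are data, not errors."""

    code: str
    message: str
    alter_label: str | None = None


def validate_wave_network(net: WaveNetwork) -> list[Violation]:
    """Check a wave network against the structural invariants.

    Returns an empty list iff all invariants hold.  The input is never
    mutated.  Checks: network size in 1..20, alter-label uniqueness,
    recent-implies-ever per flag pair, tie labels referencing listed alters,
    no self-ties, and at most one record per unordered pair.
    """
    out: list[Violation] = []
    if net.size < 1:
        out.append(Violation("empty_network", f"ego {net.ego_id} {net.wave}: no alters"))
    if net.size > MAX_ALTERS:
        out.append(
            Violation(
                "size_cap",
                f"ego {net.ego_id} {net.wave}: {net.size} alters exceeds the "
                f"{MAX_ALTERS}-alter name-generator cap",
            )
        )
    seen: set[str] = set()
    for a in net.alters:
        if a.alter_label in seen:
            out.append(
                Violation(
                    "duplicate_alter",
                    f"ego {net.ego_id} {net.wave}: duplicate alter label",
                    a.alter_label,
                )
            )
        seen.add(a.alter_label)
        for fam in FAMILIES:
            if a.flag(f"{fam}_recent") and not a.flag(f"{fam}_ever"):
                out.append(
                    Violation(
                        "recent_without_ever",
                        f"ego {net.ego_id} {net.wave} alter {a.alter_label!r}: "
                        f"{fam}_recent=1 but {fam}_ever=0",
                        a.alter_label,
                    )
                )
    labels = set(net.labels)
    seen_pairs: set[tuple[str, str]] = set()
    for t in net.ties:
        if t.alter_a == t.alter_b:
            out.append(Violation("self_tie", f"ego {net.ego_id} {net.wave}: self-tie {t.alter_a!r}"))
        for lab in t.pair:
            if lab not in labels:
                out.append(
                    Violation(
                        "unknown_tie_alter",
                        f"ego {net.ego_id} {net.wave}: tie {t.pair} references "
                        f"unlisted alter {lab!r}",
                        lab,
                    )
                )
        if t.pair in seen_pairs:
            out.append(Violation("duplicate_tie", f"ego {net.ego_id} {net.wave}: duplicate tie {t.pair}"))
        seen_pairs.add(t.pair)
    return out
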