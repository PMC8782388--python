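"""Ingest and emit the three long-format interview tables.

Schemas (comma-delimited, UTF-8, header row mandatory; see
``egowave.io.COLUMN_MANIFEST`` for the machine-readable version):

* **ego table** — one row per randomized ego: demographics, site, arm,
  screener scores, follow-up response status.
* **alter table** — one row per (ego, wave, alter): the alter label and the
  twelve 0/1 name-interpreter flags.
* **tie table** — one row per reported alter-alter pair per (ego, wave) with
  a 0/1 ``knows`` flag.  Absent pairs and ``knows=0`` rows are equivalent.

Flag cells may be coded 0/1 or true/false; unanswered (empty) flag cells are
ingested as missing and treated as False, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    FLAGS,
    WAVES,
    AlterObservation,
    EgoRecord,
    IntegrityError,
    SchemaError,
    TieObservation,
    WaveNetwork,
    normalize_label,
)

log = logging.getLogger(__name__)

EGO_COLUMNS = (
    "ego_id",
    "site",
    "arm",
    "gender",
    "age",
    "race",
    "education",
    "married",
    "n_children",
    "income",
    "audit_c",
    "dast",
    "readiness_to_change",
)
ALTER_COLUMNS = ("ego_id", "wave", "alter_label") + FLAGS
TIE_COLUMNS = ("ego_id", "wave", "alter_a", "alter_b", "knows")

#: Machine-readable column manifest for the three CSV schemas.
COLUMN_MANIFEST = {
    "ego": list(EGO_COLUMNS) + ["responded_followup"],
    "alter": list(ALTER_COLUMNS),
    "tie": list(TIE_COLUMNS),
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", "0.0", "1.0"}


def _coerce_flags(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> pd.DataFrame:
    """Coerce 0/1/true/false flag columns to bool; missing -> False (logged)."""
    n_missing = 0
    for c in cols:
        s = df[c]
        n_missing += int(s.isna().sum())
        if s.dtype == bool:
            continue
        if np.issubdtype(s.dtype, np.number):
            df[c] = s.fillna(0).astype(float).astype(bool)
        else:
            vals = s.astype("string").str.strip().str.lower()
            bad = vals.notna() & ~vals.isin(_TRUTHY | _FALSY)
            if bad.any():
                raise SchemaError(
                    f"{table} table: column {c!r} has non-boolean codes "
                    f"{sorted(vals[bad].unique())[:5]}"
                )
            df[c] = vals.isin(_TRUTHY).fillna(False).astype(bool)
    if n_missing:
        log.info("%s table: %d unanswered flag cells treated as False", table, n_missing)
    return df


def _require(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table} table: missing required column {c!r}")


@dataclass
class Cohort:
    """A loaded two-wave cohort: the three validated tables plus object views.

    ``egos``/``alters``/``ties`` are the canonical pandas representations the
    pipeline operates on; :meth:`wave_network` materializes the per-ego
    object view used by the structural validators.
    """

    egos: pd.DataFrame
    alters: pd.DataFrame
    ties: pd.DataFrame
    rejected_egos: list[str] = field(default_factory=list)

    @property
    def ego_ids(self) -> list[str]:
        return list(self.egos["ego_id"])

    def has_wave(self, ego_id: str, wave: str) -> bool:
        a = self.alters
        return bool(((a["ego_id"] == ego_id) & (a["wave"] == wave)).any())

    def wave_network(self, ego_id: str, wave: str) -> WaveNetwork:
        a = self.alters
        rows = a[(a["ego_id"] == ego_id) & (a["wave"] == wave)]
        t = self.ties
        trows = t[(t["ego_id"] == ego_id) & (t["wave"] == wave)]
        alters = [
            AlterObservation(ego_id, wave, r.alter_label, **{f: bool(getattr(r, f)) for f in FLAGS})
            for r in rows.itertuples(index=False)
        ]
        ties = [
            TieObservation(ego_id, wave, r.alter_a, r.alter_b, bool(r.knows))
            for r in trows.itertuples(index=False)
        ]
        return WaveNetwork(ego_id, wave, alters, ties)

    def iter_networks(self, wave: str):
        for ego_id in self.ego_ids:
            if self.has_wave(ego_id, wave):
                yield self.wave_network(ego_id, wave)

    def ego_records(self) -> list[EgoRecord]:
        recs = []
        for r in self.egos.itertuples(index=False):
            recs.append(
                EgoRecord(
                    ego_id=r.ego_id,
                    site=r.site,
                    arm=r.arm,
                    gender=r.gender,
                    age=float(r.age),
                    race=r.race,
                    education=r.education,
                    married=r.married,
                    n_children=int(r.n_children),
                    income=float(r.income),
                    audit_c=int(r.audit_c),
                    dast=int(r.dast),
                    readiness_to_change=int(r.readiness_to_change),
                    responded_followup=bool(r.responded_followup),
                )
            )
        return recs


def load_interviews(
    ego_table: str | Path | pd.DataFrame,
    alter_table: str | Path | pd.DataFrame,
    tie_table: str | Path | pd.DataFrame,
) -> Cohort:
    """Load and cross-validate the three interview tables into a cohort.

    Egos with no baseline network are rejected (dropped, listed in
    ``Cohort.rejected_egos``); egos with a baseline but no follow-up network
    are retained with ``responded_followup=False``.  Alter labels are
    normalized at ingest (trim / case-fold / whitespace collapse) and all
    downstream matching is exact on the normalized key.
    """
    egos = _read(ego_table).copy()
    alters = _read(alter_table).copy()
    ties = _read(tie_table).copy()

    _require(egos, EGO_COLUMNS, "ego")
    _require(alters, ALTER_COLUMNS, "alter")
    _require(ties, TIE_COLUMNS, "tie")

    egos["ego_id"] = egos["ego_id"].astype(str)
    for df in (alters, ties):
        df["ego_id"] = df["ego_id"].astype(str)
        bad_wave = ~df["wave"].isin(WAVES)
        if bad_wave.any():
            raise SchemaError(f"wave column must be one of {WAVES}; got {sorted(df.loc[bad_wave, 'wave'].unique())[:5]}")

    if egos["ego_id"].duplicated().any():
        dup = egos.loc[egos["ego_id"].duplicated(), "ego_id"].iloc[0]
        raise IntegrityError(f"ego table: duplicate ego_id {dup!r}")

    alters["alter_label"] = alters["alter_label"].map(normalize_label)
    alters = _coerce_flags(alters, FLAGS, "alter")
    dup = alters.duplicated(subset=["ego_id", "wave", "alter_label"])
    if dup.any():
        r = alters[dup].iloc[0]
        raise IntegrityError(
            f"alter table: duplicate alter {r['alter_label']!r} for ego "
            f"{r['ego_id']!r} at {r['wave']}"
        )

    for col in ("alter_a", "alter_b"):
        ties[col] = ties[col].map(normalize_label)
    swapped = ties["alter_a"] > ties["alter_b"]
    ties.loc[swapped, ["alter_a", "alter_b"]] = ties.loc[swapped, ["alter_b", "alter_a"]].values
    ties = _coerce_flags(ties, ("knows",), "tie")
    if (ties["alter_a"] == ties["alter_b"]).any():
        r = ties[ties["alter_a"] == ties["alter_b"]].iloc[0]
        raise IntegrityError(f"tie table: self-tie {r['alter_a']!r} for ego {r['ego_id']!r}")
    dup = ties.duplicated(subset=["ego_id", "wave", "alter_a", "alter_b"])
    if dup.any():
        r = ties[dup].iloc[0]
        raise IntegrityError(
            f"tie table: duplicate pair ({r['alter_a']!r}, {r['alter_b']!r}) "
            f"for ego {r['ego_id']!r} at {r['wave']}"
        )

    # referential integrity: every tie endpoint names a listed alter
    listed = set(map(tuple, alters[["ego_id", "wave", "alter_label"]].itertuples(index=False, name=None)))
    for col in ("alter_a", "alter_b"):
        keys = list(ties[["ego_id", "wave", col]].itertuples(index=False, name=None))
        missing = [k for k in keys if k not in listed]
        if missing:
            ego_id, wave, lab = missing[0]
            row = ties[(ties["ego_id"] == ego_id) & (ties["wave"] == wave) & (ties[col] == lab)].iloc[0]
            raise IntegrityError(
                f"tie table: pair ({row['alter_a']!r}, {row['alter_b']!r}) for ego "
                f"{ego_id!r} at {wave} references unknown alter {lab!r}"
            )

    # orphan network rows (no ego record) are an integrity problem too
    known = set(egos["ego_id"])
    for name, df in (("alter", alters), ("tie", ties)):
        orphan = ~df["ego_id"].isin(known)
        if orphan.any():
            raise IntegrityError(f"{name} table: rows for unknown ego {df.loc[orphan, 'ego_id'].iloc[0]!r}")

    has_base = set(alters.loc[alters["wave"] == "baseline", "ego_id"])
    has_fu = set(alters.loc[alters["wave"] == "followup", "ego_id"])
    rejected = sorted(known - has_base)
    if rejected:
        log.warning("rejecting %d egos with no baseline network: %s", len(rejected), rejected)
        egos = egos[egos["ego_id"].isin(has_base)].copy()
        alters = alters[alters["ego_id"].isin(has_base)].copy()
        ties = ties[ties["ego_id"].isin(has_base)].copy()

    if "responded_followup" in egos.columns:
        egos = _coerce_flags(egos, ("responded_followup",), "ego")
        # an ego cannot be a responder without a follow-up network
        egos["responded_followup"] &= egos["ego_id"].isin(has_fu)
    else:
        egos["responded_followup"] = egos["ego_id"].isin(has_fu)

    return Cohort(
        egos.reset_index(drop=True),
        alters.reset_index(drop=True),
        ties.reset_index(drop=True),
        rejected_egos=rejected,
    )


def _read(src: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src
    p = Path(src)
    if not p.exists():
        raise FileNotFoundError(p)
    return pd.read_csv(p)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the three tables as CSV; returns the emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("ego", cohort.egos), ("alter", cohort.alters), ("tie", cohort.ties)):
        out = df.copy()
        flag_cols = [c for c in out.columns if out[c].dtype == bool]
        out[flag_cols] = out[flag_cols].astype(int)
        path = outdir / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths
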