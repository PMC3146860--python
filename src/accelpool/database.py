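"""Pooling: phenotype harmonization, anonymized IDs and the long database.

Contributed phenotype tables are harmonized to a common dictionary: a
variable is pooled only if at least 3 contributing studies measured it,
categorical responses are re-coded through per-study recode maps, units
are converted, and participants lacking age or sex are excluded.  Every
participant receives a deterministic, non-identifiable pooled ID (stable
across waves).  The pooled database is long format — one row per
file-day — with flagged (spurious / temporally shifted) rows retained
but marked excluded-by-default, a baseline view (earliest wave per
participant), and attrition accounting that reconciles exactly with the
number of files presented.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .cleaning import (HARD_EXCLUSION_FLAGS, SOFT_EXCLUSION_FLAGS, Evidence,
                       FileFlag, FlagReport)

REQUIRED_COLUMNS = ("participant_id", "age", "sex")

#: canonical sex encodings accepted without a recode map
_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male", "boy": "male",
    "female": "female", "f": "female", "2": "female", "girl": "female",
}


@dataclass(frozen=True)
class RecodeMap:
    """Harmonization rule for one phenotype variable.

    categories
        Per-study mapping of source category -> pooled category.  A study
        absent from the map passes its values through unchanged.
    unit_factor
        Per-study multiplicative unit conversion (e.g. 100 for a study
        reporting height in metres when the pooled unit is cm).
    """

    variable: str
    categories: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    unit_factor: Mapping[str, float] = field(default_factory=dict)


@dataclass
class HarmonizeResult:
    participants: pd.DataFrame
    excluded: list[FlagReport]
    dropped_variables: list[str]
    errors: list[str]


def harmonize_phenotypes(
    study_tables: Mapping[str, pd.DataFrame],
    recode_maps: Mapping[str, RecodeMap] | None = None,
    min_studies: int = 3,
) -> HarmonizeResult:
    """Pool per-study phenotype tables into one participant table.

    Each table must declare ``participant_id``, ``age`` and ``sex``
    columns.  Extra variables present in fewer than ``min_studies``
    tables are dropped (and logged); categorical values are re-coded
    through the recode maps, unit conversions applied, and unmapped
    source categories set missing with an error log entry (never coerced
    silently).  Rows lacking age or sex are excluded with
    MISSING_PHENOTYPE reports.
    """
    recode_maps = recode_maps or {}
    errors: list[str] = []
    excluded: list[FlagReport] = []

    # variable coverage across studies (declared columns)
    extra_cols: dict[str, int] = {}
    for table in study_tables.values():
        for col in table.columns:
            if col not in REQUIRED_COLUMNS and col != "wave":
                extra_cols[col] = extra_cols.get(col, 0) + 1
    dropped = sorted(c for c, k in extra_cols.items() if k < min_studies)
    kept_extra = sorted(c for c, k in extra_cols.items() if k >= min_studies)

    frames = []
    for study_id, table in study_tables.items():
        missing_req = set(REQUIRED_COLUMNS) - set(table.columns)
        if missing_req:
            raise ValueError(
                f"study {study_id!r} table lacks required column(s) "
                f"{sorted(missing_req)}")
        df = table.copy()
        df["study_id"] = study_id
        if "wave" not in df.columns:
            df["wave"] = 1
        df = df[["study_id", "participant_id", "wave", *REQUIRED_COLUMNS[1:],
                 *[c for c in kept_extra if c in table.columns]]]

        # sex normalization (alias table, then any explicit recode map)
        df["sex"] = (
            df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
        )

        for var, rmap in recode_maps.items():
            if var not in df.columns:
                continue
            if rmap.unit_factor.get(study_id):
                df[var] = pd.to_numeric(df[var], errors="coerce") * \
                    rmap.unit_factor[study_id]
            cat_map = rmap.categories.get(study_id)
            if cat_map:
                src = df[var].astype(str)
                mapped = src.map(cat_map)
                bad = mapped.isna() & src.notna() & (src != "nan")
                for idx in df.index[bad]:
                    errors.append(
                        f"{study_id}/{df.at[idx, 'participant_id']}: "
                        f"unmapped {var} category {src[idx]!r}; set missing")
                df[var] = mapped
        frames.append(df)

    pooled = pd.concat(frames, ignore_index=True)
    pooled["age"] = pd.to_numeric(pooled["age"], errors="coerce")

    bad = pooled["age"].isna() | pooled["sex"].isna()
    for row in pooled[bad].itertuples(index=False):
        excluded.append(FlagReport(
            f"{row.study_id}|{row.participant_id}",
            FileFlag.MISSING_PHENOTYPE,
            (Evidence("missing_phenotype", 0, 0,
                      "missing age and/or sex (minimum inclusion rule)"),),
        ))
    pooled = pooled[~bad].reset_index(drop=True)
    return HarmonizeResult(pooled, excluded, dropped, errors)


def assign_ids(
    participants: pd.DataFrame,
    seed: int,
    id_prefix: str = "ICAD",
    digest_chars: int = 10,
) -> pd.DataFrame:
    """Attach deterministic non-identifiable pooled IDs.

    Keyed BLAKE2 hash of (study_id, participant_id) under a salt derived
    from ``seed``: bijective over source keys, stable across waves of the
    same participant, and re-salted (deterministically) whenever a digest
    collides or contains the source identifier as a substring.
    """
    keys = list(dict.fromkeys(
        zip(participants["study_id"], participants["participant_id"].astype(str))
    ))
    taken: set[str] = set()
    mapping: dict[tuple, str] = {}
    for study, pid in keys:
        attempt = 0
        while True:
            salt = f"{seed}:{attempt}".encode()
            digest = hashlib.blake2b(
                f"{study}|{pid}".encode(), key=salt,
                digest_size=16).hexdigest()[:digest_chars]
            candidate = f"{id_prefix}{digest}"
            leaks = len(pid) >= 2 and pid in candidate
            if candidate not in taken and not leaks:
                break
            attempt += 1
        taken.add(candidate)
        mapping[(study, pid)] = candidate
    out = participants.copy()
    out["icad_id"] = [
        mapping[(s, str(p))]
        for s, p in zip(out["study_id"], out["participant_id"])
    ]
    return out


@dataclass
class PooledDatabase:
    """The assembled long-format database plus its accounting."""

    table: pd.DataFrame      # one row per file-day
    attrition: dict
    data_errors: list[str] = field(default_factory=list)

    def baseline_view(self) -> pd.DataFrame:
        """Earliest wave per pooled participant (one row-group per icad_id)."""
        first_wave = (
            self.table.groupby("icad_id")["wave"].transform("min"))
        return self.table[self.table["wave"] == first_wave]

    def sample_size_distribution(self, baseline_only: bool = False) -> pd.DataFrame:
        """Viable-file sample size by sex and completed age year."""
        t = self.baseline_view() if baseline_only else self.table
        t = t[~t["excluded"]]
        per_file = t.drop_duplicates("file_key")
        g = per_file.assign(age_year=per_file["age"].astype(int))
        return (g.groupby(["sex", "age_year"]).size()
                 .rename("n_files").reset_index())


def build_database(
    day_summaries: pd.DataFrame,
    flag_reports: list[FlagReport],
    participants: pd.DataFrame,
    n_deposited: int | None = None,
) -> PooledDatabase:
    """Join per-day summaries to flags and phenotypes (long format).

    Every summary row must join to a participant (via the study /
    participant / wave components of its file key) and to a flag report;
    orphans are a hard error.  Rows from SPURIOUS / TEMPORALLY_SHIFTED
    files are retained with ``excluded=True`` (exclusion is recommended,
    not forced); hard-excluded files (corrupt, no-wear, duplicates,
    missing phenotype) contribute no rows but are counted in attrition.
    """
    from .cleaning import attrition as attrition_of

    flags = {r.file_key: r for r in flag_reports}

    key_parts = day_summaries["file_key"].str.split("|", expand=True)
    df = day_summaries.copy()
    df[["study_id", "participant_id", "wave_str"]] = key_parts[[0, 1, 2]]
    df["wave"] = pd.to_numeric(df["wave_str"], errors="coerce").fillna(1).astype(int)
    df = df.drop(columns=["wave_str"])

    missing_flags = sorted(set(df["file_key"]) - set(flags))
    if missing_flags:
        raise KeyError(f"summaries without a flag report: {missing_flags}")

    pheno = participants.copy()
    pheno["participant_id"] = pheno["participant_id"].astype(str)
    pheno["wave"] = pd.to_numeric(pheno["wave"]).astype(int)
    merged = df.merge(
        pheno, on=["study_id", "participant_id", "wave"],
        how="left", validate="many_to_one")
    orphans = sorted(merged.loc[merged["icad_id"].isna(), "file_key"].unique())
    if orphans:
        raise KeyError(f"summaries without a participant record: {orphans}")

    merged["flag"] = merged["file_key"].map(lambda k: flags[k].flag.value)
    merged["excluded"] = merged["file_key"].map(
        lambda k: flags[k].flag in SOFT_EXCLUSION_FLAGS)

    # deterministic output order
    merged = merged.sort_values(
        ["study_id", "icad_id", "wave", "file_key", "date"],
        kind="mergesort").reset_index(drop=True)
    merged = merged.drop(columns=["participant_id"])

    acct = attrition_of(flag_reports)
    if n_deposited is not None and n_deposited != acct["total"]:
        raise ValueError(
            f"attrition mismatch: {n_deposited} deposited vs "
            f"{acct['total']} accounted")
    return PooledDatabase(merged, acct)
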