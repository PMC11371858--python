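"""Twin-pair data model, CSV ingestion, recoding and descriptive tables.

The analysis operates on pair-level records: one row per twin pair with
zygosity (MZ, same-sex DZ, opposite-sex DZ), a group label (country or
cohort), and each twin's sex, age and binary lifetime phenotypes --
regular smoking initiation (``rsi``) and cannabis initiation (``ci``).
Single responders are pairs whose co-twin is absent.

Missing phenotypes are ``None``; in frames they are ``NaN``.  Input CSVs
encode missing values as the empty string or ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TwinObs",
    "TwinPairRecord",
    "ParseResult",
    "RecodeRule",
    "read_pairs",
    "write_pairs",
    "records_to_frame",
    "frame_to_records",
    "recode_binary",
    "load_recode_rules",
    "prevalence_table",
    "cross_tab",
    "sex_zygosity_class",
    "DEFAULT_SCHEMA",
    "DEFAULT_AGE_WINDOW",
]

ZYGOSITY_CODES = ("MZ", "DZ_SS", "DZ_OS")
SEX_CODES = ("M", "F")
DEFAULT_AGE_WINDOW = (10.0, 110.0)

DEFAULT_SCHEMA = {
    "pair_id": "pair_id",
    "zygosity": "zygosity",
    "group": "group",
    "sex1": "sex1", "age1": "age1", "rsi1": "rsi1", "ci1": "ci1",
    "sex2": "sex2", "age2": "age2", "rsi2": "rsi2", "ci2": "ci2",
}

_FRAME_COLUMNS = list(DEFAULT_SCHEMA)


@dataclass(frozen=True)
class TwinObs:
    """One twin's sex, age and binary phenotypes (None = missing)."""

    sex: str | None = None
    age: float | None = None
    rsi: int | None = None
    ci: int | None = None

    @property
    def has_phenotype(self) -> bool:
        return self.rsi is not None or self.ci is not None


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair; ``twin2`` is None for single responders."""

    pair_id: str
    zygosity: str
    group: str
    twin1: TwinObs
    twin2: TwinObs | None = None


class ParseResult(NamedTuple):
    records: list[TwinPairRecord]
    rejected: list[tuple[int, str]]  # (row index, diagnostic)


class TwinDataError(ValueError):
    pass


def _parse_missing(v) -> bool:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return True
    return str(v).strip() in ("", "NA")


def _parse_pheno(v, what: str) -> int | None:
    if _parse_missing(v):
        return None
    f = float(v)
    if f not in (0.0, 1.0):
        raise ValueError(f"{what} must be 0/1/missing, got {v!r}")
    return int(f)


def _validate_record(rec: TwinPairRecord,
                     age_window: tuple[float, float]) -> TwinPairRecord:
    """Enforce pair-level invariants; may reorient opposite-sex pairs."""
    if rec.zygosity not in ZYGOSITY_CODES:
        raise ValueError(f"unknown zygosity code {rec.zygosity!r}")
    sexes = [t.sex for t in (rec.twin1, rec.twin2) if t is not None]
    for s in sexes:
        if s is not None and s not in SEX_CODES:
            raise ValueError(f"unknown sex code {s!r}")
    known = [s for s in sexes if s is not None]
    if len(known) == 2:
        if rec.zygosity == "DZ_OS" and known[0] == known[1]:
            raise ValueError(
                f"DZ_OS pair has concordant sexes ({known[0]}, {known[1]})")
        if rec.zygosity in ("MZ", "DZ_SS") and known[0] != known[1]:
            raise ValueError(
                f"{rec.zygosity} pair has discordant sexes "
                f"({known[0]}, {known[1]})")
    has_pheno = rec.twin1.has_phenotype or (
        rec.twin2 is not None and rec.twin2.has_phenotype)
    if not has_pheno:
        raise ValueError("no non-missing phenotype in pair")
    for t in (rec.twin1, rec.twin2):
        if t is not None and t.age is not None:
            if not (age_window[0] <= t.age <= age_window[1]):
                raise ValueError(
                    f"age {t.age} outside plausible window {age_window}")
    # convention: opposite-sex pairs are oriented male-first
    if (rec.zygosity == "DZ_OS" and rec.twin2 is not None
            and rec.twin1.sex == "F" and rec.twin2.sex == "M"):
        logger.debug("reorienting DZ_OS pair %s male-first", rec.pair_id)
        rec = replace(rec, twin1=rec.twin2, twin2=rec.twin1)
    # convention: a present twin sits in slot 1
    if rec.twin2 is not None and rec.twin1.sex is None \
            and not rec.twin1.has_phenotype:
        rec = replace(rec, twin1=rec.twin2, twin2=None)
    return rec


def read_pairs(path, schema: dict | None = None, strict: bool = True,
               age_window: tuple[float, float] = DEFAULT_AGE_WINDOW,
               ) -> ParseResult:
    """Read pair-level records from a UTF-8 CSV with a header row.

    ``schema`` maps canonical field names (``DEFAULT_SCHEMA`` keys) to
    the file's column names.  Rows violating invariants are collected
    with row-indexed diagnostics; with ``strict=True`` any rejection
    raises ``TwinDataError`` listing them all.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise TwinDataError(f"{path}: no data rows")
    missing_cols = [c for c in schema.values() if c not in df.columns]
    if missing_cols:
        raise TwinDataError(f"{path}: missing columns {missing_cols}")

    records, rejected = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        get = lambda key: getattr(row, schema[key])
        try:
            twins = []
            for k in ("1", "2"):
                sex = None if _parse_missing(get(f"sex{k}")) \
                    else str(get(f"sex{k}")).strip().upper()
                age = None if _parse_missing(get(f"age{k}")) \
                    else float(get(f"age{k}"))
                rsi = _parse_pheno(get(f"rsi{k}"), f"rsi{k}")
                ci = _parse_pheno(get(f"ci{k}"), f"ci{k}")
                if sex is None and age is None and rsi is None and ci is None:
                    twins.append(None)
                else:
                    twins.append(TwinObs(sex=sex, age=age, rsi=rsi, ci=ci))
            if twins[0] is None and twins[1] is not None:
                twins = [twins[1], None]
            if twins[0] is None:
                raise ValueError("both twins absent")
            rec = TwinPairRecord(
                pair_id=str(get("pair_id")),
                zygosity=str(get("zygosity")).strip().upper(),
                group=str(get("group")).strip(),
                twin1=twins[0], twin2=twins[1],
            )
            records.append(_validate_record(rec, age_window))
        except (ValueError, TypeError) as exc:
            rejected.append((i, f"row {i}: {exc}"))
    if strict and rejected:
        msgs = "; ".join(m for _, m in rejected[:20])
        raise TwinDataError(
            f"{path}: {len(rejected)} invalid row(s): {msgs}")
    return ParseResult(records, rejected)


def records_to_frame(records: Iterable[TwinPairRecord]) -> pd.DataFrame:
    """Flatten records to one row per pair (NaN-coded missing)."""
    rows = []
    for r in records:
        t1, t2 = r.twin1, (r.twin2 or TwinObs())
        rows.append({
            "pair_id": r.pair_id, "zygosity": r.zygosity, "group": r.group,
            "sex1": t1.sex, "age1": t1.age, "rsi1": t1.rsi, "ci1": t1.ci,
            "sex2": t2.sex, "age2": t2.age, "rsi2": t2.rsi, "ci2": t2.ci,
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TwinPairRecord]:
    def _val(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    out = []
    for row in frame.itertuples(index=False):
        t1 = TwinObs(sex=_val(row.sex1), age=_val(row.age1),
                     rsi=None if _val(row.rsi1) is None else int(row.rsi1),
                     ci=None if _val(row.ci1) is None else int(row.ci1))
        if all(_val(getattr(row, c)) is None
               for c in ("sex2", "age2", "rsi2", "ci2")):
            t2 = None
        else:
            t2 = TwinObs(sex=_val(row.sex2), age=_val(row.age2),
                         rsi=None if _val(row.rsi2) is None else int(row.rsi2),
                         ci=None if _val(row.ci2) is None else int(row.ci2))
        out.append(TwinPairRecord(pair_id=str(row.pair_id),
                                  zygosity=row.zygosity, group=row.group,
                                  twin1=t1, twin2=t2))
    return out


def write_pairs(records: Iterable[TwinPairRecord], path) -> None:
    """Write records as CSV in the default column dialect."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------
# phenotype harmonization
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RecodeRule:
    """Config-driven binarization of one questionnaire item.

    ``response_map`` sends raw response codes to 0/1/None; codes absent
    from the map fall back to ``default`` if given, else raise.  Items a
    respondent skipped (empty/NA raw value) are filled with
    ``skipout_fill``.  ``combined_item`` marks items conflating cannabis
    with other drugs; by convention an affirmative answer on such an
    item counts as cannabis initiation, so at least one code must map
    to 1.
    """

    item_name: str
    trait: str  # "rsi" or "ci"
    response_map: dict
    skipout_fill: int | None = None
    combined_item: bool = False
    default: int | None = None
    has_default: bool = False

    def __post_init__(self):
        if self.trait not in ("rsi", "ci"):
            raise ValueError(f"trait must be rsi/ci, got {self.trait!r}")
        if self.combined_item and 1 not in self.response_map.values():
            raise ValueError(
                f"combined item {self.item_name!r} must map an affirmative "
                f"response to 1")


def load_recode_rules(path) -> list[RecodeRule]:
    """Load recode rules from a YAML/JSON config (list of mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        entry = dict(entry)
        has_default = "default" in entry
        rules.append(RecodeRule(
            item_name=str(entry["item_name"]),
            trait=str(entry["trait"]),
            response_map={str(k): v for k, v in entry["response_map"].items()},
            skipout_fill=entry.get("skipout_fill"),
            combined_item=bool(entry.get("combined_item", False)),
            default=entry.get("default"),
            has_default=has_default,
        ))
    return rules


def recode_binary(raw_table: pd.DataFrame,
                  rules: list[RecodeRule]) -> pd.DataFrame:
    """Apply recode rules to per-individual item responses.

    Returns a frame with ``rsi`` and ``ci`` columns in {0, 1, NaN}.
    When several items feed one trait (for example a cannabis-only item
    and a combined cannabis-or-other-drugs item) an affirmative on any
    of them yields 1, a definite 0 on any (with none affirmative)
    yields 0, and all-missing stays missing.
    """
    per_trait: dict[str, list[pd.Series]] = {"rsi": [], "ci": []}
    for rule in rules:
        if rule.item_name not in raw_table.columns:
            continue
        col = raw_table[rule.item_name]

        def _map_one(v, rule=rule):
            if _parse_missing(v):
                return rule.skipout_fill
            key = str(v).strip()
            if key in rule.response_map:
                return rule.response_map[key]
            if rule.has_default:
                return rule.default
            raise TwinDataError(
                f"item {rule.item_name!r}: unmapped response code {v!r}")

        per_trait[rule.trait].append(col.map(_map_one))
    out = pd.DataFrame(index=raw_table.index)
    for trait in ("rsi", "ci"):
        cols = per_trait[trait]
        if not cols:
            out[trait] = np.nan
            continue
        stacked = pd.concat(cols, axis=1).astype(float)
        any_yes = (stacked == 1).any(axis=1)
        any_no = (stacked == 0).any(axis=1)
        out[trait] = np.where(any_yes, 1.0,
                              np.where(any_no, 0.0, np.nan))
    return out


# ---------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------

def _individuals_frame(records: Iterable[TwinPairRecord]) -> pd.DataFrame:
    """One row per present twin, with pair context attached."""
    rows = []
    for r in records:
        for t in (r.twin1, r.twin2):
            if t is None:
                continue
            rows.append({
                "pair_id": r.pair_id, "group": r.group,
                "zygosity": r.zygosity, "sex": t.sex, "age": t.age,
                "rsi": np.nan if t.rsi is None else float(t.rsi),
                "ci": np.nan if t.ci is None else float(t.ci),
            })
    return pd.DataFrame(rows)


class PrevalenceTables(NamedTuple):
    marginal: pd.DataFrame  # per stratum x trait: endorsers / responders
    joint: pd.DataFrame     # neither / both / rsi_only / ci_only shares


def prevalence_table(records: Iterable[TwinPairRecord],
                     strata: tuple[str, ...] = ("group", "sex"),
                     ) -> PrevalenceTables:
    """Individual-level endorsement proportions by stratum.

    Marginal proportions use pairwise deletion (endorsers over
    non-missing responders); joint categories are computed over
    individuals with both traits observed and sum to 1 per stratum.
    Empty strata keep count 0 and NaN proportions.
    """
    allowed = {"group", "sex", "zygosity"}
    if not set(strata) <= allowed:
        raise ValueError(f"strata must be drawn from {sorted(allowed)}")
    ind = _individuals_frame(records)
    strata = list(strata)
    if not strata:
        ind["_all"] = "all"
        strata = ["_all"]

    marg_rows = []
    joint_rows = []
    for key, sub in ind.groupby(strata, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for trait in ("rsi", "ci"):
            vals = sub[trait].dropna()
            marg_rows.append({
                **dict(zip(strata, key)), "trait": trait,
                "n_yes": int(vals.sum()), "n": int(len(vals)),
                "prevalence": float(vals.mean()) if len(vals) else np.nan,
            })
        both = sub.dropna(subset=["rsi", "ci"])
        n = len(both)
        cats = {
            "neither": ((both.rsi == 0) & (both.ci == 0)).sum(),
            "both": ((both.rsi == 1) & (both.ci == 1)).sum(),
            "rsi_only": ((both.rsi == 1) & (both.ci == 0)).sum(),
            "ci_only": ((both.rsi == 0) & (both.ci == 1)).sum(),
        }
        for cat, cnt in cats.items():
            joint_rows.append({
                **dict(zip(strata, key)), "category": cat,
                "n": int(cnt),
                "proportion": float(cnt / n) if n else np.nan,
            })
    return PrevalenceTables(pd.DataFrame(marg_rows), pd.DataFrame(joint_rows))


def sex_zygosity_class(rec: TwinPairRecord) -> str | None:
    """Table-2 style cell: MZ_M, DZ_M, MZ_F, DZ_F or DZ_OS."""
    if rec.zygosity == "DZ_OS":
        return "DZ_OS"
    sex = rec.twin1.sex or (rec.twin2.sex if rec.twin2 else None)
    if sex is None:
        return None
    prefix = "MZ" if rec.zygosity == "MZ" else "DZ"
    return f"{prefix}_{sex}"


def cross_tab(records: Iterable[TwinPairRecord], arrangement: str,
              trait: str = "rsi", strata: tuple[str, ...] = (),
              ) -> dict:
    """Fourfold tables per stratum.

    ``within_person_traits`` tabulates RSI x CI over individuals with
    both observed (rows index RSI).  ``cross_twin_same_trait`` tabulates
    twin1 x twin2 for one trait over complete pairs, double-entered
    (each pair counted in both orderings) so the table is symmetric and
    order-invariant.  Strata keys are tuples; empty strata yield tables
    with zero total.
    """
    from .tetrachoric import FourfoldTable  # shared domain type

    records = list(records)
    out: dict[tuple, FourfoldTable] = {}
    if arrangement == "within_person_traits":
        ind = _individuals_frame(records)
        if ind.empty:
            return out
        keys = list(strata) if strata else []
        if not keys:
            ind["_all"] = "all"
            keys = ["_all"]
        for key, sub in ind.groupby(keys, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            both = sub.dropna(subset=["rsi", "ci"])
            out[key] = FourfoldTable(
                n11=int(((both.rsi == 1) & (both.ci == 1)).sum()),
                n10=int(((both.rsi == 1) & (both.ci == 0)).sum()),
                n01=int(((both.rsi == 0) & (both.ci == 1)).sum()),
                n00=int(((both.rsi == 0) & (both.ci == 0)).sum()),
            )
        return out

    if arrangement != "cross_twin_same_trait":
        raise ValueError(f"unknown arrangement {arrangement!r}")

    def record_key(rec):
        parts = []
        for s in strata:
            if s == "group":
                parts.append(rec.group)
            elif s == "zygosity":
                parts.append(rec.zygosity)
            elif s == "sex_zygosity":
                parts.append(sex_zygosity_class(rec))
            else:
                raise ValueError(f"unknown stratifier {s!r}")
        return tuple(parts) if parts else ("all",)

    counts: dict[tuple, list[int]] = {}
    for rec in records:
        key = record_key(rec)
        counts.setdefault(key, [0, 0, 0, 0])  # n11, n10, n01, n00
        if rec.twin2 is None:
            continue
        y1 = getattr(rec.twin1, trait)
        y2 = getattr(rec.twin2, trait)
        if y1 is None or y2 is None:
            continue
        cell = counts[key]
        for a, b in ((y1, y2), (y2, y1)):  # double entry
            if a == 1 and b == 1:
                cell[0] += 1
            elif a == 1 and b == 0:
                cell[1] += 1
            elif a == 0 and b == 1:
                cell[2] += 1
            else:
                cell[3] += 1
    for key, (n11, n10, n01, n00) in counts.items():
        out[key] = FourfoldTable(n11=n11, n10=n10, n01=n01, n00=n00)
    return out
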