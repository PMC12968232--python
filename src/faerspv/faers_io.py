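"""Reading, deduplicating and assembling FAERS quarterly data.

FAERS publishes quarterly "$"-delimited ASCII tables (DEMO, DRUG, REAC,
INDI, THER, OUTC).  This module parses them into normalized pandas tables,
applies the FDA-recommended deduplication rule (keep the most recent
FDA_DT per CASEID, ties broken by the highest PRIMARYID), removes cases
listed in the "deleted case" files, and assembles per-report
:class:`CaseReport` records for a target drug identified by a synonym
list.

Only the post-2014 FAERS layout is supported.  Files are decoded as UTF-8
with a single-byte (latin-1) fallback; undecodable byte runs are replaced
and counted.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: FAERS table stems required by :func:`read_quarter`.
TABLE_NAMES = ("demo", "drug", "reac", "indi", "ther", "outc")

# canonical column names per table, with accepted FAERS aliases
_ALIASES: dict[str, dict[str, str]] = {
    "demo": {
        "primaryid": "primaryid",
        "caseid": "caseid",
        "fda_dt": "fda_dt",
        "event_dt": "event_dt",
        "age": "age_value",
        "age_cod": "age_unit",
        "sex": "sex",
        "gndr_cod": "sex",
        "wt": "weight_value",
        "wt_cod": "weight_unit",
        "occp_cod": "reporter",
        "reporter_country": "country",
        "occr_country": "country",
    },
    "drug": {
        "primaryid": "primaryid",
        "drug_seq": "drug_seq",
        "role_cod": "role",
        "drugname": "drugname",
        "dose_amt": "dose",
        "dose_freq": "frequency",
    },
    "reac": {"primaryid": "primaryid", "pt": "pt"},
    "indi": {"primaryid": "primaryid", "indi_pt": "indication"},
    "ther": {
        "primaryid": "primaryid",
        "dsg_drug_seq": "drug_seq",
        "start_dt": "start_dt",
        "end_dt": "end_dt",
    },
    "outc": {"primaryid": "primaryid", "outc_cod": "outcome"},
}

_REQUIRED = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "role", "drugname"),
    "reac": ("primaryid", "pt"),
    "indi": ("primaryid",),
    "ther": ("primaryid",),
    "outc": ("primaryid",),
}

AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

LBS_TO_KG = 0.453592

_PUNCT_RE = re.compile(r"[^A-Z0-9]+")


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim and collapse punctuation/whitespace runs to one space.

    ``"Orkambi "`` and ``"ORKAMBI"`` normalize identically;
    ``"VX-809/VX-770"`` becomes ``"VX 809 VX 770"``.
    """
    return _PUNCT_RE.sub(" ", str(name).upper()).strip()


def normalize_synonyms(names: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_drug_name(n) for n in names if str(n).strip())


# ---------------------------------------------------------------------------
# dates


@dataclass(frozen=True)
class FaersDate:
    """Outcome of parsing a raw FAERS date string.

    ``kind`` is ``"full"`` (YYYYMMDD), ``"partial"`` (YYYYMM or YYYY — usable
    for year tabulations, not for time-to-onset) or ``"invalid"``.
    """

    kind: str
    value: date | None = None
    year: int | None = None
    month: int | None = None

    @property
    def is_full(self) -> bool:
        return self.kind == "full"


_INVALID = FaersDate("invalid")


def parse_faers_date(raw: object) -> FaersDate:
    """Classify a raw date string as full / partial / invalid."""
    s = str(raw).strip() if raw is not None else ""
    if not s.isdigit():
        return _INVALID
    if len(s) == 8:
        try:
            d = date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return _INVALID
        return FaersDate("full", d, d.year, d.month)
    if len(s) == 6:
        y, m = int(s[:4]), int(s[4:6])
        if 1 <= m <= 12:
            return FaersDate("partial", None, y, m)
        return _INVALID
    if len(s) == 4:
        return FaersDate("partial", None, int(s), None)
    return _INVALID


# ---------------------------------------------------------------------------
# raw table reading


@dataclass
class QuarterTables:
    """The six parsed tables of one FAERS quarter (or a merged range)."""

    quarter: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    deleted_caseids: frozenset[str] = frozenset()
    parse_issues: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


class MissingTableError(FileNotFoundError):
    """A required FAERS table file is absent from the quarter directory."""


def _decode(raw: bytes) -> tuple[str, int]:
    """UTF-8 with latin-1 fallback; returns (text, n suspect bytes)."""
    try:
        return raw.decode("utf-8"), 0
    except UnicodeDecodeError:
        n_bad = sum(1 for b in raw if b >= 0x80)
        return raw.decode("latin-1"), n_bad


def read_delimited(path: Path) -> tuple[pd.DataFrame, dict]:
    """Read one "$"-delimited FAERS file into a string DataFrame.

    The first line is the header; a trailing delimiter is tolerated.
    Rows with too many fields are skipped and counted, not fatal.
    """
    path = Path(path)
    text, n_bad_bytes = _decode(path.read_bytes())
    header_line, _, body = text.partition("\n")
    names = [c.strip().lower() for c in header_line.rstrip("\r").split("$")]
    trailing = names and names[-1] == ""
    if trailing:
        names = names[:-1]
    bad_rows: list[int] = [0]

    def _on_bad(line: list[str]):  # pragma: no cover - exercised via files
        if trailing and len(line) == len(names) + 1 and line[-1] in ("", None):
            return line[: len(names)]
        bad_rows[0] += 1
        return None

    df = pd.read_csv(
        io.StringIO(body),
        sep="$",
        names=names + (["_trail"] if trailing else []),
        dtype=str,
        header=None,
        engine="python",
        on_bad_lines=_on_bad,
        skip_blank_lines=True,
    )
    if trailing and "_trail" in df.columns:
        df = df.drop(columns="_trail")
    issues = {"bad_rows": bad_rows[0], "suspect_bytes": n_bad_bytes}
    if bad_rows[0]:
        log.warning("%s: skipped %d malformed rows", path.name, bad_rows[0])
    return df, issues


def _canonicalize(df: pd.DataFrame, table: str) -> pd.DataFrame:
    alias = _ALIASES[table]
    keep = {c: alias[c] for c in df.columns if c in alias}
    out = df[list(keep)].rename(columns=keep)
    # first alias wins if a file carries both spellings of one field
    out = out.loc[:, ~out.columns.duplicated()]
    missing = [c for c in _REQUIRED[table] if c not in out.columns]
    if missing:
        raise ValueError(f"{table.upper()} is missing required columns {missing}")
    for col in alias.values():
        if col not in out.columns:
            out[col] = pd.NA
    out["primaryid"] = out["primaryid"].astype(str).str.strip()
    return out[out["primaryid"] != ""].reset_index(drop=True)


def _quarter_tag(quarter: str) -> str:
    """'2015Q3' or '15Q3' -> '15Q3'."""
    q = quarter.upper().replace(" ", "")
    m = re.fullmatch(r"(\d{2}|\d{4})Q([1-4])", q)
    if not m:
        raise ValueError(f"unrecognized quarter identifier: {quarter!r}")
    return f"{m.group(1)[-2:]}Q{m.group(2)}"


def _find_table_file(directory: Path, stem: str, tag: str) -> Path | None:
    pattern = re.compile(rf"{stem}{tag}\.txt$", re.IGNORECASE)
    for p in sorted(directory.iterdir()):
        if pattern.fullmatch(p.name):
            return p
    return None


def read_quarter(path: str | Path, quarter: str) -> QuarterTables:
    """Parse the six FAERS tables of one quarter from *path*.

    Raises :class:`MissingTableError` naming the first absent table.  A
    ``DELETED<tag>.txt`` file (one caseid per line), if present, populates
    ``deleted_caseids``.
    """
    directory = Path(path)
    tag = _quarter_tag(quarter)
    tables: dict[str, pd.DataFrame] = {}
    issues: dict[str, dict] = {}
    for stem in TABLE_NAMES:
        f = _find_table_file(directory, stem, tag)
        if f is None:
            raise MissingTableError(
                f"FAERS table {stem.upper()} for quarter {tag} not found in {directory}"
            )
        raw, iss = read_delimited(f)
        tables[stem] = _canonicalize(raw, stem)
        issues[stem] = iss
    deleted: frozenset[str] = frozenset()
    del_file = _find_table_file(directory, "deleted", tag)
    if del_file is not None:
        deleted = load_deleted_caseids(del_file)
    return QuarterTables(quarter=tag, deleted_caseids=deleted, parse_issues=issues, **tables)


def merge_quarters(quarters: Sequence[QuarterTables]) -> QuarterTables:
    """Concatenate several quarters into one table set for a study window."""
    if not quarters:
        raise ValueError("no quarters to merge")
    merged = {
        name: pd.concat([q.table(name) for q in quarters], ignore_index=True)
        for name in TABLE_NAMES
    }
    deleted = frozenset().union(*(q.deleted_caseids for q in quarters))
    label = f"{quarters[0].quarter}-{quarters[-1].quarter}"
    return QuarterTables(quarter=label, deleted_caseids=deleted, **merged)


# ---------------------------------------------------------------------------
# term-list / mapping inputs


def load_term_list(path: str | Path) -> frozenset[str]:
    """Newline-delimited term list; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        t = line.strip()
        if t and not t.startswith("#"):
            out.append(t)
    return frozenset(out)


def load_deleted_caseids(path: str | Path) -> frozenset[str]:
    return load_term_list(path)


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (pt, soc) -> mapping; header row optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["pt", "soc"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["pt", "soc"])
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


# ---------------------------------------------------------------------------
# deduplication


def _fda_dt_key(raw: object) -> int:
    """Sortable integer for FDA_DT; unparseable dates sort as oldest."""
    d = parse_faers_date(raw)
    if d.kind == "full":
        return d.value.year * 10000 + d.value.month * 100 + d.value.day
    return -1


def _primaryid_key(pid: str) -> tuple[int, str]:
    s = str(pid)
    return (int(s), "") if s.isdigit() else (-1, s)


def deduplicate(demo: pd.DataFrame | Iterable) -> set[str]:
    """FDA-recommended dedup: one primaryid per caseid.

    Keeps the row with the most recent FDA_DT per CASEID; ties on FDA_DT
    keep the highest PRIMARYID.  Unparseable FDA_DT sorts as oldest.
    Duplicate primaryids in the input are an error: keys must be unique.
    """
    df = demo if isinstance(demo, pd.DataFrame) else _rows_to_frame(demo)
    pids = df["primaryid"].astype(str)
    if pids.duplicated().any():
        dupes = pids[pids.duplicated()].unique()[:5]
        raise ValueError(f"duplicate primaryid(s) in DEMO input: {list(dupes)}")
    key = pd.DataFrame(
        {
            "caseid": df["caseid"].astype(str),
            "pid": pids,
            "dt": df["fda_dt"].map(_fda_dt_key),
            "pid_key": pids.map(_primaryid_key),
        }
    )
    best = key.sort_values(["dt", "pid_key"]).groupby("caseid", sort=False).tail(1)
    return set(best["pid"])


def _rows_to_frame(rows: Iterable) -> pd.DataFrame:
    recs = []
    for r in rows:
        if isinstance(r, Mapping):
            recs.append(dict(r))
        else:  # dataclass-like
            recs.append(
                {k: getattr(r, k) for k in ("primaryid", "caseid", "fda_dt") if hasattr(r, k)}
            )
    return pd.DataFrame(recs)


def remove_deleted_cases(
    retained: set[str],
    deleted_caseids: Iterable[str],
    caseid_of: Mapping[str, str] | pd.DataFrame,
) -> set[str]:
    """Drop retained reports whose CASEID appears in a deleted-case list."""
    deleted = {str(c) for c in deleted_caseids}
    if not deleted:
        return set(retained)
    if isinstance(caseid_of, pd.DataFrame):
        caseid_of = dict(
            zip(caseid_of["primaryid"].astype(str), caseid_of["caseid"].astype(str))
        )
    return {p for p in retained if str(caseid_of.get(str(p), "")) not in deleted}


# ---------------------------------------------------------------------------
# target-drug selection


def select_drug_reports(
    drug: pd.DataFrame, synonyms: Iterable[str], role: str = "PS"
) -> set[str]:
    """Primaryids with >=1 drug row matching a synonym at the given role.

    Matching is exact on normalized names (not substring), so e.g. a bare
    "IVACAFTOR" synonym never matches combination products.
    """
    syn = normalize_synonyms(synonyms)
    if not syn:
        raise ValueError("empty synonym set")
    names = drug["drugname"].astype(str).map(normalize_drug_name)
    mask = names.isin(syn) & (drug["role"].astype(str).str.strip().str.upper() == role)
    return set(drug.loc[mask, "primaryid"].astype(str))


# ---------------------------------------------------------------------------
# case assembly


@dataclass(frozen=True)
class DrugRow:
    primaryid: str
    drug_seq: str
    role: str
    drugname: str
    dose: str | None = None
    frequency: str | None = None


@dataclass
class CaseReport:
    """One deduplicated safety report, normalized for analysis.

    Demographics are unit-normalized (age in years, weight in kg); ``pts``
    is the set of distinct reaction preferred terms (each contributes one
    PT record downstream), ``socs`` their mapped system organ classes.
    """

    primaryid: str
    caseid: str
    age_years: float | None
    sex: str | None
    weight_kg: float | None
    reporter: str | None
    country: str | None
    year: int | None
    frequency: str | None
    dose: str | None
    target_drug_rows: list[DrugRow]
    all_drug_names: frozenset[str]
    pts: frozenset[str]
    socs: frozenset[str]
    outcomes: frozenset[str]
    indications: frozenset[str]
    earliest_target_start: date | None
    event_date: date | None

    @property
    def fatal(self) -> bool:
        return "DE" in self.outcomes

    @property
    def n_records(self) -> int:
        return len(self.pts)

    def is_monotherapy(self, synonyms: Iterable[str]) -> bool:
        return self.all_drug_names <= normalize_synonyms(synonyms)


def _to_float(x: object) -> float | None:
    try:
        v = float(str(x).strip())
    except (TypeError, ValueError):
        return None
    return v if v == v else None  # NaN guard


def normalize_age(value: object, unit: object) -> float | None:
    v = _to_float(value)
    if v is None:
        return None
    factor = AGE_UNIT_TO_YEARS.get(str(unit).strip().upper(), None)
    if factor is None:
        factor = 1.0  # missing unit: FAERS convention is years
    years = v * factor
    return years if years >= 0 else None


def normalize_weight(value: object, unit: object) -> float | None:
    v = _to_float(value)
    if v is None:
        return None
    u = str(unit).strip().upper()
    kg = v * LBS_TO_KG if u == "LBS" else v
    return kg if kg > 0 else None


def assemble_cases(
    tables: QuarterTables,
    retained: Iterable[str],
    pt_to_soc: Mapping[str, str],
    synonyms: Iterable[str],
    role: str = "PS",
) -> list[CaseReport]:
    """Build one :class:`CaseReport` per retained report.

    Reports without any REAC row are excluded (counted in the log).
    ``earliest_target_start`` is the minimum valid full therapy start date
    among the target drug's therapy rows.
    """
    syn = normalize_synonyms(synonyms)
    retained = {str(p) for p in retained}
    demo = tables.demo[tables.demo["primaryid"].isin(retained)]

    def _group(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        sub = df[df["primaryid"].isin(retained)]
        return {pid: g for pid, g in sub.groupby("primaryid", sort=False)}

    drug_by = _group(tables.drug)
    reac_by = _group(tables.reac)
    indi_by = _group(tables.indi)
    ther_by = _group(tables.ther)
    outc_by = _group(tables.outc)

    cases: list[CaseReport] = []
    n_no_reac = 0
    for row in demo.itertuples(index=False):
        pid = str(row.primaryid)
        reac = reac_by.get(pid)
        pts = (
            frozenset(t for t in (str(p).strip() for p in reac["pt"].dropna()) if t)
            if reac is not None
            else frozenset()
        )
        if not pts:
            n_no_reac += 1
            continue
        drug_g = drug_by.get(pid)
        target_rows: list[DrugRow] = []
        all_names: set[str] = set()
        if drug_g is not None:
            for d in drug_g.itertuples(index=False):
                name = normalize_drug_name(d.drugname)
                if name:
                    all_names.add(name)
                if name in syn and str(d.role).strip().upper() == role:
                    target_rows.append(
                        DrugRow(
                            pid,
                            str(d.drug_seq),
                            str(d.role).strip().upper(),
                            str(d.drugname),
                            None if pd.isna(d.dose) else str(d.dose),
                            None if pd.isna(d.frequency) else str(d.frequency),
                        )
                    )
        target_seqs = {r.drug_seq for r in target_rows}
        start: date | None = None
        ther_g = ther_by.get(pid)
        if ther_g is not None and target_seqs:
            for t in ther_g.itertuples(index=False):
                if str(t.drug_seq) in target_seqs:
                    d = parse_faers_date(t.start_dt)
                    if d.is_full and (start is None or d.value < start):
                        start = d.value
        event = parse_faers_date(row.event_dt)
        fda = parse_faers_date(row.fda_dt)
        year = event.year if event.year is not None else fda.year
        outc_g = outc_by.get(pid)
        outcomes = (
            frozenset(str(o).strip().upper() for o in outc_g["outcome"].dropna())
            if outc_g is not None
            else frozenset()
        )
        indi_g = indi_by.get(pid)
        indications = (
            frozenset(str(i).strip() for i in indi_g["indication"].dropna())
            if indi_g is not None
            else frozenset()
        )
        freq = next((r.frequency for r in target_rows if r.frequency), None)
        dose = next((r.dose for r in target_rows if r.dose), None)
        sex = str(row.sex).strip().upper() if pd.notna(row.sex) and str(row.sex).strip() else None
        cases.append(
            CaseReport(
                primaryid=pid,
                caseid=str(row.caseid),
                age_years=normalize_age(row.age_value, row.age_unit),
                sex=sex,
                weight_kg=normalize_weight(row.weight_value, row.weight_unit),
                reporter=None if pd.isna(row.reporter) else str(row.reporter).strip().upper(),
                country=None if pd.isna(row.country) else str(row.country).strip().upper(),
                year=year,
                frequency=None if freq is None else str(freq).strip().upper(),
                dose=dose,
                target_drug_rows=target_rows,
                all_drug_names=frozenset(all_names),
                pts=pts,
                socs=frozenset(pt_to_soc.get(p, "UNMAPPED") for p in pts),
                outcomes=outcomes,
                indications=indications,
                earliest_target_start=start,
                event_date=event.value if event.is_full else None,
            )
        )
    if n_no_reac:
        log.info("assemble_cases: excluded %d reports without REAC rows", n_no_reac)
    return cases


def pt_record_table(
    tables: QuarterTables,
    retained: Iterable[str],
    pt_to_soc: Mapping[str, str],
) -> pd.DataFrame:
    """Database-wide PT-record table: one row per (report, distinct PT).

    This is the counting frame for every disproportionality statistic:
    columns ``primaryid``, ``pt``, ``soc``.
    """
    retained = {str(p) for p in retained}
    reac = tables.reac[tables.reac["primaryid"].isin(retained)].copy()
    reac["pt"] = reac["pt"].astype(str).str.strip()
    reac = reac[reac["pt"] != ""]
    rec = reac[["primaryid", "pt"]].drop_duplicates()
    rec["soc"] = rec["pt"].map(lambda p: pt_to_soc.get(p, "UNMAPPED"))
    return rec.reset_index(drop=True)


def case_table(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Flat per-report table (TSV-ready) of the assembled case records."""
    return pd.DataFrame(
        {
            "primaryid": [c.primaryid for c in cases],
            "caseid": [c.caseid for c in cases],
            "age_years": [c.age_years for c in cases],
            "sex": [c.sex for c in cases],
            "weight_kg": [c.weight_kg for c in cases],
            "reporter": [c.reporter for c in cases],
            "country": [c.country for c in cases],
            "year": [c.year for c in cases],
            "frequency": [c.frequency for c in cases],
            "dose": [c.dose for c in cases],
            "n_pts": [len(c.pts) for c in cases],
            "n_drugs": [len(c.all_drug_names) for c in cases],
            "fatal": [c.fatal for c in cases],
            "earliest_target_start": [c.earliest_target_start for c in cases],
            "event_date": [c.event_date for c in cases],
        }
    )
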