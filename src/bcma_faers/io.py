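"""Read, write and deduplicate FAERS-style quarterly ASCII extracts.

A quarter is a directory with one dollar-sign-delimited text file per table
(``DEMO*``, ``DRUG*``, ``REAC*``, ``OUTC*``), each with a single header row.
The dialect has no quoting or escaping: a literal ``$`` splits fields, so a
value may never contain the delimiter.  Column names are matched
case-insensitively; unknown columns are preserved in spirit but ignored.
Empty fields become missing values (``None``).

FAERS distributes successive versions of the same case under one ``caseid``
with increasing ``caseversion``; analysis uses the latest version only.
:func:`deduplicate` keeps, per case, the row with the highest
``(caseversion, numeric primaryid)`` and drops the child drug/reaction/outcome
rows of discarded versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

DELIMITER = "$"

#: FAERS seriousness outcome codes (OUTC table).
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

_TABLES = ("DEMO", "DRUG", "REAC", "OUTC")


@dataclass(frozen=True)
class DemoRecord:
    """One row of the DEMO table: a single version of a reported case."""

    primaryid: str
    caseid: str
    caseversion: int = 1
    age: float | None = None
    age_cod: str | None = None
    sex: str | None = None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    caseid: str
    drug_seq: int
    role_cod: str | None
    drugname: str


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    caseid: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    caseid: str
    outc_cod: str


@dataclass
class RawRecordSet:
    """Parsed rows of the four FAERS tables, keyed by report ``primaryid``."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)

    def primaryids(self) -> set[str]:
        return {d.primaryid for d in self.demo}


def _clean(value: str) -> str | None:
    value = value.strip()
    return value or None


def _find_table_file(directory: Path, table: str) -> Path:
    matches = sorted(
        p
        for p in directory.iterdir()
        if p.is_file() and p.name.upper().startswith(table)
    )
    if not matches:
        raise ConfigurationError(
            f"missing {table} table: no file matching {table}* in {directory}"
        )
    if len(matches) > 1:
        log.warning("multiple %s files in %s; using %s", table, directory, matches[0])
    return matches[0]


def _read_rows(path: Path) -> tuple[list[str], list[list[str | None]]]:
    """Split a dollar-delimited file into header and cleaned data rows.

    Rows whose field count disagrees with the header are rejected with a
    logged line number; parsing continues.
    """
    text = path.read_text(encoding="utf-8", errors="replace")
    if "�" in text:
        log.warning("%s: undecodable bytes replaced with U+FFFD", path.name)
    lines = text.splitlines()
    if not lines:
        raise DataError(f"{path}: empty file, no header row")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    rows: list[list[str | None]] = []
    n_bad = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != len(header):
            n_bad += 1
            log.warning(
                "%s line %d: expected %d fields, got %d; row rejected",
                path.name, lineno, len(header), len(fields),
            )
            continue
        rows.append([_clean(f) for f in fields])
    if n_bad:
        log.warning("%s: rejected %d malformed row(s)", path.name, n_bad)
    return header, rows


def _col(header: list[str], row: Sequence[str | None], name: str) -> str | None:
    try:
        return row[header.index(name)]
    except ValueError:
        return None


def _require_columns(header: list[str], names: Iterable[str], path: Path) -> None:
    missing = [n for n in names if n not in header]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")


def read_quarter(directory: str | Path) -> RawRecordSet:
    """Parse one quarter directory into a :class:`RawRecordSet`.

    Raises :class:`ConfigurationError` if any of the four table files is
    absent.  Malformed rows are rejected (logged) rather than fatal; child
    rows whose ``primaryid`` has no DEMO row are dropped with a logged count.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigurationError(f"quarter directory not found: {directory}")
    paths = {t: _find_table_file(directory, t) for t in _TABLES}

    header, rows = _read_rows(paths["DEMO"])
    _require_columns(header, ("primaryid", "caseid"), paths["DEMO"])
    demo: list[DemoRecord] = []
    for row in rows:
        pid = _col(header, row, "primaryid")
        cid = _col(header, row, "caseid")
        if pid is None or cid is None:
            log.warning("DEMO row with missing primaryid/caseid dropped")
            continue
        ver_raw = _col(header, row, "caseversion")
        try:
            version = int(ver_raw) if ver_raw is not None else 1
        except ValueError:
            log.warning("DEMO %s: unparseable caseversion %r, assuming 1", pid, ver_raw)
            version = 1
        age_raw = _col(header, row, "age")
        age: float | None = None
        if age_raw is not None:
            try:
                age = float(age_raw)
            except ValueError:
                log.warning("DEMO %s: unparseable age %r treated as missing", pid, age_raw)
        sex = _col(header, row, "sex")
        if sex is not None:
            sex = sex.upper()
            if sex not in {"F", "M"}:
                log.warning("DEMO %s: unknown sex code %r treated as missing", pid, sex)
                sex = None
        age_cod = _col(header, row, "age_cod")
        demo.append(
            DemoRecord(
                primaryid=pid, caseid=cid, caseversion=max(version, 1),
                age=age, age_cod=age_cod.upper() if age_cod else None, sex=sex,
            )
        )

    header, rows = _read_rows(paths["DRUG"])
    _require_columns(header, ("primaryid", "caseid", "drugname"), paths["DRUG"])
    drug: list[DrugRecord] = []
    for i, row in enumerate(rows):
        pid = _col(header, row, "primaryid")
        cid = _col(header, row, "caseid")
        name = _col(header, row, "drugname")
        if pid is None or cid is None or name is None:
            continue
        seq_raw = _col(header, row, "drug_seq")
        try:
            seq = int(seq_raw) if seq_raw is not None else i + 1
        except ValueError:
            seq = i + 1
        role = _col(header, row, "role_cod")
        if role is not None:
            role = role.upper()
            if role not in ROLE_CODES:
                log.warning("DRUG %s: unknown role code %r", pid, role)
                role = None
        drug.append(DrugRecord(primaryid=pid, caseid=cid, drug_seq=seq,
                               role_cod=role, drugname=name))

    header, rows = _read_rows(paths["REAC"])
    _require_columns(header, ("primaryid", "caseid", "pt"), paths["REAC"])
    reac = [
        ReacRecord(primaryid=pid, caseid=cid, pt=pt)
        for row in rows
        if (pid := _col(header, row, "primaryid")) is not None
        and (cid := _col(header, row, "caseid")) is not None
        and (pt := _col(header, row, "pt")) is not None
    ]

    header, rows = _read_rows(paths["OUTC"])
    _require_columns(header, ("primaryid", "caseid", "outc_cod"), paths["OUTC"])
    outc: list[OutcRecord] = []
    for row in rows:
        pid = _col(header, row, "primaryid")
        cid = _col(header, row, "caseid")
        cod = _col(header, row, "outc_cod")
        if pid is None or cid is None or cod is None:
            continue
        cod = cod.upper()
        if cod not in OUTCOME_CODES:
            log.warning("OUTC %s: unknown outcome code %r ignored", pid, cod)
            continue
        outc.append(OutcRecord(primaryid=pid, caseid=cid, outc_cod=cod))

    records = RawRecordSet(demo=demo, drug=drug, reac=reac, outc=outc)
    return _drop_orphans(records)


def _drop_orphans(records: RawRecordSet) -> RawRecordSet:
    known = records.primaryids()
    n_orphan = 0
    out = RawRecordSet(demo=records.demo)
    for name in ("drug", "reac", "outc"):
        kept = []
        for row in getattr(records, name):
            if row.primaryid in known:
                kept.append(row)
            else:
                n_orphan += 1
        setattr(out, name, kept)
    if n_orphan:
        log.warning("dropped %d child row(s) with no DEMO parent", n_orphan)
    return out


def _version_key(d: DemoRecord) -> tuple[int, int]:
    try:
        pid_num = int(d.primaryid)
    except ValueError:
        pid_num = -1
    return (d.caseversion, pid_num)


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Collapse multiple report versions to one row per case.

    For each ``caseid`` the DEMO row with the highest ``caseversion`` is
    retained, ties broken by numerically largest ``primaryid``; child rows of
    discarded versions are dropped.  Idempotent; empty input yields empty
    output.
    """
    best: dict[str, DemoRecord] = {}
    for d in records.demo:
        cur = best.get(d.caseid)
        if cur is None or _version_key(d) > _version_key(cur):
            best[d.caseid] = d
    keep_order = []
    seen = set()
    kept_pids = {d.primaryid for d in best.values()}
    for d in records.demo:
        if d.primaryid in kept_pids and d.caseid not in seen:
            keep_order.append(best[d.caseid])
            seen.add(d.caseid)
    n_dropped = len(records.demo) - len(keep_order)
    if n_dropped:
        log.info("deduplication dropped %d superseded report version(s)", n_dropped)
    return RawRecordSet(
        demo=keep_order,
        drug=[r for r in records.drug if r.primaryid in kept_pids],
        reac=[r for r in records.reac if r.primaryid in kept_pids],
        outc=[r for r in records.outc if r.primaryid in kept_pids],
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    text = str(value)
    if DELIMITER in text or "\n" in text or "\r" in text:
        raise DataError(
            f"value {text!r} contains the field delimiter or a newline; "
            "the FAERS dialect has no escaping"
        )
    return text


def _fmt_age(age: float | None) -> str:
    if age is None:
        return ""
    return f"{age:g}"


def write_quarter(records: RawRecordSet, directory: str | Path) -> None:
    """Write a :class:`RawRecordSet` as a FAERS-dialect quarter directory.

    ``read_quarter(write_quarter(x))`` reproduces ``x`` field for field.
    Values containing the delimiter are rejected (:class:`DataError`).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create quarter directory {directory}: {exc}") from exc

    def dump(name: str, header: list[str], rows: Iterable[list]) -> None:
        lines = [DELIMITER.join(header)]
        lines += [DELIMITER.join(_fmt(v) for v in row) for row in rows]
        (directory / f"{name}.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    dump("DEMO", ["primaryid", "caseid", "caseversion", "age", "age_cod", "sex"],
         ([d.primaryid, d.caseid, d.caseversion, _fmt_age(d.age), d.age_cod, d.sex]
          for d in records.demo))
    dump("DRUG", ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
         ([r.primaryid, r.caseid, r.drug_seq, r.role_cod, r.drugname]
          for r in records.drug))
    dump("REAC", ["primaryid", "caseid", "pt"],
         ([r.primaryid, r.caseid, r.pt] for r in records.reac))
    dump("OUTC", ["primaryid", "caseid", "outc_cod"],
         ([r.primaryid, r.caseid, r.outc_cod] for r in records.outc))
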