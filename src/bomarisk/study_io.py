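"""Data model and CSV input/output for longitudinal boma-monitoring studies.

The unit of observation is the *boma-month*: a livestock enclosure (boma)
revisited on a roughly thirty-day interval, with per-predator counts of raid
attempts and successful raids and per-livestock-class head losses recalled for
the window. Bomas come in matched pairs — one fortified ("experimental") and
one traditional ("control") enclosure in the same village.

All files are UTF-8 comma-separated tables with a header row and ISO-8601
dates:

* ``bomas.csv``       — the boma registry (pairing, arm, location, size, cost)
* ``visits.csv``      — one row per revisit window
* ``retaliation.csv`` — yearly counts of carnivores killed in retaliation
* ``prices.csv``      — local livestock prices in USD per head
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: Predator species recorded at boma raids.
PREDATORS: tuple[str, ...] = ("lion", "leopard", "spotted_hyena", "jackal", "cheetah")

#: Livestock classes priced and counted in loss records.
LIVESTOCK_CLASSES: tuple[str, ...] = (
    "cattle_adult",
    "cattle_juv",
    "donkey_adult",
    "shoat_adult",
    "shoat_juv",
)

ARMS: tuple[str, str] = ("experimental", "control")


class SchemaError(ValueError):
    """A CSV file does not conform to the documented column schema."""


class ValidationError(ValueError):
    """A parsed record violates a data-model invariant."""


@dataclasses.dataclass(frozen=True)
class BomaRecord:
    """One livestock enclosure in the paired case-control registry."""

    boma_id: str
    pair_id: str
    arm: str  # "experimental" (chain-link fortified) or "control" (thorn bush)
    village: str
    longitude: float
    latitude: float
    circumference_m: float
    construction_cost_usd: float | None  # experimental arm only
    construction_date: dt.date

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"boma {self.boma_id}: unknown arm {self.arm!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"boma {self.boma_id}: longitude {self.longitude} out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"boma {self.boma_id}: latitude {self.latitude} out of range")
        if not self.circumference_m > 0:
            raise ValidationError(f"boma {self.boma_id}: circumference must be > 0")
        if self.construction_cost_usd is not None and self.construction_cost_usd < 0:
            raise ValidationError(f"boma {self.boma_id}: negative construction cost")


@dataclasses.dataclass(frozen=True)
class VisitRecord:
    """One thirty-day revisit window at one boma.

    ``attempts`` and ``successes`` map predator species to event counts in the
    window; ``losses`` maps livestock classes to heads killed or injured.
    Successful raids are a subset of attempts, so ``successes[s] <= attempts[s]``
    for every species ``s``.
    """

    boma_id: str
    visit_date: dt.date
    window_days: int
    attempts: Mapping[str, int]
    successes: Mapping[str, int]
    losses: Mapping[str, int]

    def __post_init__(self) -> None:
        # Normalize sparse count mappings to the full key sets, so that a
        # written-then-reread record compares equal to its source.
        ident = f"visit {self.boma_id}@{self.visit_date.isoformat()}"
        for name, keys in (("attempts", PREDATORS), ("successes", PREDATORS),
                           ("losses", LIVESTOCK_CLASSES)):
            mapping = getattr(self, name)
            unknown = set(mapping) - set(keys)
            if unknown:
                kind = "predator" if keys is PREDATORS else "livestock class"
                raise ValidationError(f"{ident}: unknown {kind} {sorted(unknown)[0]!r}")
            object.__setattr__(self, name, {k: int(mapping.get(k, 0)) for k in keys})

    def validate(self) -> None:
        ident = f"visit {self.boma_id}@{self.visit_date.isoformat()}"
        for s in PREDATORS:
            a = int(self.attempts.get(s, 0))
            k = int(self.successes.get(s, 0))
            if a < 0 or k < 0:
                raise ValidationError(f"{ident}: negative count for {s}")
            if k > a:
                raise ValidationError(f"{ident}: successes ({k}) > attempts ({a}) for {s}")
        for c, n in self.losses.items():
            if c not in LIVESTOCK_CLASSES:
                raise ValidationError(f"{ident}: unknown livestock class {c!r}")
            if int(n) < 0:
                raise ValidationError(f"{ident}: negative loss count for {c}")
        if self.window_days <= 0:
            raise ValidationError(f"{ident}: window_days must be positive")


@dataclasses.dataclass(frozen=True)
class RetaliationRecord:
    """Carnivores of one species killed in retaliation in one village-year."""

    village: str
    year: int
    species: str
    killed: int

    def validate(self) -> None:
        if self.species not in PREDATORS:
            raise ValidationError(f"retaliation {self.village}/{self.year}: unknown species {self.species!r}")
        if self.killed < 0:
            raise ValidationError(f"retaliation {self.village}/{self.year}: negative kill count")


@dataclasses.dataclass(frozen=True)
class PriceTable:
    """Local livestock market prices, USD per head, by livestock class."""

    usd_per_head: Mapping[str, float]

    def validate(self) -> None:
        for c in LIVESTOCK_CLASSES:
            if c not in self.usd_per_head:
                raise ValidationError(f"price table missing class {c!r}")
        for c, p in self.usd_per_head.items():
            if not p > 0:
                raise ValidationError(f"price for {c!r} must be > 0")

    def __getitem__(self, livestock_class: str) -> float:
        return float(self.usd_per_head[livestock_class])


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

BOMA_COLUMNS = (
    "boma_id",
    "pair_id",
    "arm",
    "village",
    "longitude",
    "latitude",
    "circumference_m",
    "construction_cost_usd",
    "construction_date",
)

_ATTEMPT_COLS = tuple(f"attempts_{s}" for s in PREDATORS)
_SUCCESS_COLS = tuple(f"successes_{s}" for s in PREDATORS)
_LOSS_COLS = tuple(f"loss_{c}" for c in LIVESTOCK_CLASSES)
VISIT_COLUMNS = ("boma_id", "visit_date", "window_days") + _ATTEMPT_COLS + _SUCCESS_COLS + _LOSS_COLS

RETALIATION_COLUMNS = ("village", "year", "species", "killed")
PRICE_COLUMNS = ("livestock_class", "usd_per_head")


def _check_columns(header: Sequence[str], required: Sequence[str], path: Path,
                   optional: Sequence[str] = ()) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    unknown = [c for c in header if c not in required and c not in optional]
    if unknown:
        log.warning("%s: ignoring unknown column(s) %s", path, ", ".join(unknown))


def _parse_date(text: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValidationError(f"{where}: bad ISO-8601 date {text!r}") from exc


def _parse_int(text: str, where: str) -> int:
    try:
        return int(text.strip())
    except ValueError as exc:
        raise ValidationError(f"{where}: bad integer {text!r}") from exc


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text.strip())
    except ValueError as exc:
        raise ValidationError(f"{where}: bad number {text!r}") from exc


def read_bomas(path: str | Path) -> list[BomaRecord]:
    path = Path(path)
    out: list[BomaRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames or (), BOMA_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            cost_text = (row["construction_cost_usd"] or "").strip()
            rec = BomaRecord(
                boma_id=row["boma_id"].strip(),
                pair_id=row["pair_id"].strip(),
                arm=row["arm"].strip(),
                village=row["village"].strip(),
                longitude=_parse_float(row["longitude"], where),
                latitude=_parse_float(row["latitude"], where),
                circumference_m=_parse_float(row["circumference_m"], where),
                construction_cost_usd=None if cost_text == "" else _parse_float(cost_text, where),
                construction_date=_parse_date(row["construction_date"], where),
            )
            rec.validate()
            out.append(rec)
    _validate_pairing(out)
    return out


def _validate_pairing(bomas: Sequence[BomaRecord]) -> None:
    """Each pair_id may hold at most one boma per arm."""
    seen = Counter((b.pair_id, b.arm) for b in bomas)
    dup = [key for key, n in seen.items() if n > 1]
    if dup:
        pair, arm = dup[0]
        raise ValidationError(f"pair {pair!r} has multiple {arm} bomas")


def read_visits(path: str | Path) -> list[VisitRecord]:
    path = Path(path)
    out: list[VisitRecord] = []
    required = ("boma_id", "visit_date", "window_days") + _ATTEMPT_COLS + _SUCCESS_COLS
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or ()
        # Loss columns are conditional detail: default to 0 with a warning.
        _check_columns(header, required, path, optional=_LOSS_COLS)
        missing_losses = [c for c in _LOSS_COLS if c not in header]
        if missing_losses:
            log.warning("%s: loss column(s) %s absent; defaulting to 0",
                        path, ", ".join(missing_losses))
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            rec = VisitRecord(
                boma_id=row["boma_id"].strip(),
                visit_date=_parse_date(row["visit_date"], where),
                window_days=_parse_int(row["window_days"], where),
                attempts={s: _parse_int(row[f"attempts_{s}"], where) for s in PREDATORS},
                successes={s: _parse_int(row[f"successes_{s}"], where) for s in PREDATORS},
                losses={c: (_parse_int(row[f"loss_{c}"], where) if f"loss_{c}" in header else 0)
                        for c in LIVESTOCK_CLASSES},
            )
            rec.validate()
            out.append(rec)
    return out


def read_retaliation(path: str | Path) -> list[RetaliationRecord]:
    path = Path(path)
    out: list[RetaliationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames or (), RETALIATION_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            rec = RetaliationRecord(
                village=row["village"].strip(),
                year=_parse_int(row["year"], where),
                species=row["species"].strip(),
                killed=_parse_int(row["killed"], where),
            )
            rec.validate()
            out.append(rec)
    return out


def read_prices(path: str | Path) -> PriceTable:
    path = Path(path)
    prices: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames or (), PRICE_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            prices[row["livestock_class"].strip()] = _parse_float(
                row["usd_per_head"], f"{path}:{lineno}")
    table = PriceTable(prices)
    table.validate()
    return table


def read_study(boma_csv: str | Path, visit_csv: str | Path,
               retaliation_csv: str | Path
               ) -> tuple[list[BomaRecord], list[VisitRecord], list[RetaliationRecord]]:
    """Read and validate a full study from its three core CSV files."""
    return read_bomas(boma_csv), read_visits(visit_csv), read_retaliation(retaliation_csv)


# ---------------------------------------------------------------------------
# Writers (byte-stable given fixed record ordering)
# ---------------------------------------------------------------------------

def _writer(path: Path):
    return path.open("w", newline="", encoding="utf-8")


def write_bomas(bomas: Iterable[BomaRecord], path: str | Path) -> Path:
    path = Path(path)
    with _writer(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(BOMA_COLUMNS)
        for b in bomas:
            b.validate()
            cost = "" if b.construction_cost_usd is None else repr(float(b.construction_cost_usd))
            w.writerow([b.boma_id, b.pair_id, b.arm, b.village,
                        repr(float(b.longitude)), repr(float(b.latitude)),
                        repr(float(b.circumference_m)), cost,
                        b.construction_date.isoformat()])
    return path


def write_visits(visits: Iterable[VisitRecord], path: str | Path) -> Path:
    path = Path(path)
    with _writer(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(VISIT_COLUMNS)
        for v in visits:
            v.validate()
            row = [v.boma_id, v.visit_date.isoformat(), v.window_days]
            row += [int(v.attempts.get(s, 0)) for s in PREDATORS]
            row += [int(v.successes.get(s, 0)) for s in PREDATORS]
            row += [int(v.losses.get(c, 0)) for c in LIVESTOCK_CLASSES]
            w.writerow(row)
    return path


def write_retaliation(records: Iterable[RetaliationRecord], path: str | Path) -> Path:
    path = Path(path)
    with _writer(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(RETALIATION_COLUMNS)
        for r in records:
            r.validate()
            w.writerow([r.village, r.year, r.species, r.killed])
    return path


def write_prices(prices: PriceTable, path: str | Path) -> Path:
    path = Path(path)
    prices.validate()
    with _writer(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PRICE_COLUMNS)
        for c in LIVESTOCK_CLASSES:
            w.writerow([c, repr(float(prices[c]))])
    return path


def write_study(out_dir: str | Path,
                bomas: Sequence[BomaRecord],
                visits: Sequence[VisitRecord],
                retaliation: Sequence[RetaliationRecord],
                prices: PriceTable | None = None) -> dict[str, Path]:
    """Write a study to ``out_dir``; output is re-readable by :func:`read_study`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bomas": write_bomas(bomas, out_dir / "bomas.csv"),
        "visits": write_visits(visits, out_dir / "visits.csv"),
        "retaliation": write_retaliation(retaliation, out_dir / "retaliation.csv"),
    }
    if prices is not None:
        paths["prices"] = write_prices(prices, out_dir / "prices.csv")
    return paths


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

def filter_min_revisits(visits: Sequence[VisitRecord],
                        bomas: Sequence[BomaRecord],
                        k: int = 3) -> tuple[list[VisitRecord], list[BomaRecord]]:
    """Keep only bomas with at least ``k`` revisit records (default 3).

    Visits of excluded bomas are dropped. Pairing metadata is left untouched;
    a pair whose partner was excluded is retained and flagged with a warning.
    Idempotent: filtering an already-filtered study is a no-op.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(v.boma_id for v in visits)
    keep_ids = {b.boma_id for b in bomas if counts[b.boma_id] >= k}
    kept_bomas = [b for b in bomas if b.boma_id in keep_ids]
    kept_visits = [v for v in visits if v.boma_id in keep_ids]

    arms_per_pair: dict[str, set[str]] = {}
    for b in kept_bomas:
        arms_per_pair.setdefault(b.pair_id, set()).add(b.arm)
    incomplete = sorted(p for p, arms in arms_per_pair.items() if len(arms) < 2)
    if incomplete:
        log.warning("filter_min_revisits(k=%d): pair(s) now incomplete: %s",
                    k, ", ".join(incomplete))
    return kept_visits, kept_bomas
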