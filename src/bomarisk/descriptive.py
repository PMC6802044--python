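"""Descriptive summaries of a depredation study: monthly raid rates per arm,
species composition of attack events, retaliation-kill summaries, and
within-pair distances."""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .study_io import PREDATORS, BomaRecord, RetaliationRecord, VisitRecord

log = logging.getLogger(__name__)

#: Mean Earth radius (m) used for great-circle distances.
EARTH_RADIUS_M = 6_371_008.8


@dataclasses.dataclass(frozen=True)
class SummaryStat:
    label: str
    mean: float
    se: float | None
    n: int
    minimum: float | None = None
    maximum: float | None = None


def monthly_raid_rate(visits: Sequence[VisitRecord],
                      bomas: Sequence[BomaRecord],
                      arm: str) -> float:
    """Raid attempts (all predator species) per boma-month in one study arm.

    Uses event counts, not the binarized monthly indicator, to match a
    "raid attempts per month" reading of the data.
    """
    arm_ids = {b.boma_id for b in bomas if b.arm == arm}
    windows = [v for v in visits if v.boma_id in arm_ids]
    if not windows:
        raise ValueError(f"no visit windows in arm {arm!r}")
    events = sum(int(v.attempts.get(s, 0)) for v in windows for s in PREDATORS)
    return events / len(windows)


def species_event_counts(visits: Iterable[VisitRecord]) -> dict[str, int]:
    """Total attack events (attempts, which include the successful raids) per
    predator species."""
    counts = {s: 0 for s in PREDATORS}
    for v in visits:
        for s in PREDATORS:
            counts[s] += int(v.attempts.get(s, 0))
    return counts


def species_composition(events: Mapping[str, int] | Iterable[VisitRecord]) -> dict[str, float]:
    """Percentage share of attack events per species (sums to 100 before
    rounding). Accepts either a species->count mapping or visit records."""
    counts = dict(events) if isinstance(events, Mapping) else species_event_counts(events)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no attack events")
    return {s: 100.0 * counts.get(s, 0) / total for s in PREDATORS}


def retaliation_summary(records: Sequence[RetaliationRecord]) -> dict[str, SummaryStat]:
    """Per-species mean and SE of yearly retaliation kills across study years.

    Yearly totals are summed over villages; ``SE = SD / sqrt(#years)`` with
    the sample (n-1) standard deviation. With a single year the SE is
    undefined and reported as ``None``.
    """
    years = sorted({r.year for r in records})
    if not years:
        raise ValueError("no retaliation records")
    totals: dict[str, dict[int, int]] = {s: {y: 0 for y in years} for s in PREDATORS}
    for r in records:
        totals[r.species][r.year] += r.killed
    out = {}
    for s in PREDATORS:
        yearly = np.array([totals[s][y] for y in years], float)
        if len(years) >= 2:
            se = float(yearly.std(ddof=1) / math.sqrt(len(years)))
        else:
            se = None
            log.warning("retaliation_summary: single year, SE undefined")
        out[s] = SummaryStat(label=f"{s}_killed_per_year", mean=float(yearly.mean()),
                             se=se, n=len(years),
                             minimum=float(yearly.min()), maximum=float(yearly.max()))
    return out


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in meters between two WGS84 points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def pair_distances(bomas: Sequence[BomaRecord]) -> dict[str, float]:
    """Great-circle distance (m) between the members of each complete pair."""
    by_pair: dict[str, dict[str, BomaRecord]] = defaultdict(dict)
    for b in bomas:
        by_pair[b.pair_id][b.arm] = b
    out = {}
    for pair_id, arms in sorted(by_pair.items()):
        if len(arms) < 2:
            log.warning("pair %s incomplete; excluded from distance summary", pair_id)
            continue
        e, c = arms["experimental"], arms["control"]
        if any(map(lambda x: x is None or (isinstance(x, float) and math.isnan(x)),
                   (e.longitude, e.latitude, c.longitude, c.latitude))):
            log.warning("pair %s missing coordinates; excluded", pair_id)
            continue
        out[pair_id] = haversine_m(e.longitude, e.latitude, c.longitude, c.latitude)
    return out


def pair_distance_stats(bomas: Sequence[BomaRecord]) -> SummaryStat:
    """Mean, SE, min and max of experimental-control pair distances (m)."""
    d = np.array(list(pair_distances(bomas).values()), float)
    if d.size == 0:
        raise ValueError("no complete pairs with coordinates")
    se = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size >= 2 else None
    return SummaryStat(label="pair_distance_m", mean=float(d.mean()), se=se,
                       n=int(d.size), minimum=float(d.min()), maximum=float(d.max()))


def descriptive_report(visits: Sequence[VisitRecord],
                       bomas: Sequence[BomaRecord],
                       retaliation: Sequence[RetaliationRecord]) -> dict:
    """The full descriptive block as a JSON-serializable dictionary."""
    comp = species_composition(visits)
    ret = retaliation_summary(retaliation)
    dist = pair_distance_stats(bomas)
    return {
        "n_bomas": len(bomas),
        "n_visits": len(visits),
        "monthly_raid_rate": {
            arm: monthly_raid_rate(visits, bomas, arm)
            for arm in ("experimental", "control")
        },
        "species_composition_pct": comp,
        "retaliation_per_year": {
            s: {"mean": st.mean, "se": st.se, "n_years": st.n} for s, st in ret.items()
        },
        "pair_distance_m": {"mean": dist.mean, "se": dist.se,
                            "min": dist.minimum, "max": dist.maximum, "n_pairs": dist.n},
    }
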