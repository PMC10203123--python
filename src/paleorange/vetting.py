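"""Species-range vetting and longevity estimation.

A species' stratigraphic range in a dated sample sequence is bounded by its
first occurrence (FO, oldest sample with a nonzero count) and last occurrence
(LO, youngest).  Observed FO/LO ages underestimate true origination and
extinction, so each endpoint receives an error bar derived from the species'
own sampling record: the mean length of the gaps (maximal runs of zero-count
samples) between its occurrences, rounded up to a whole number of samples,
with a minimum of one sample.  The FO error interval extends that many sample
positions toward older ages; the LO interval toward younger ages.

Species are excluded when their range cannot be trusted:

* ``excluded_edge`` — any occurrence in the two oldest or two youngest
  samples of the composite sequence (range may extend outside the study
  interval);
* ``excluded_overflow`` — an error interval runs off either end of the
  sample sequence (possibly extant, or originating before the interval);
* ``excluded_doubling`` — the error bars more than double the observed
  range (range too poorly constrained; single-sample ranges always fail);
* ``excluded_no_occurrence`` — no specimens at all.

Longevity of an included species is the midpoint of the FO error interval
minus the midpoint of the LO error interval, in millions of years (my).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .occurrence import ExclusionList, OccurrenceTable, apply_exclusions

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRange",
    "observed_range",
    "mean_gap",
    "error_samples",
    "error_intervals",
    "edge_filter",
    "doubling_filter",
    "interval_filter",
    "longevity",
    "vet_all",
]

STATUSES = (
    "included",
    "excluded_edge",
    "excluded_overflow",
    "excluded_doubling",
    "excluded_no_occurrence",
)


@dataclass
class SpeciesRange:
    """Per-species range, error bars and vetting outcome.

    Indices refer to positions in the age-ordered (oldest-first) sample
    sequence; ``fo_interval``/``lo_interval`` are closed age intervals in Ma
    written [older endpoint, younger endpoint]; ``None`` marks an interval
    that overflows the sample sequence.
    """

    taxon_id: str
    status: str
    fo_index: Optional[int] = None
    lo_index: Optional[int] = None
    fo_age: Optional[float] = None
    lo_age: Optional[float] = None
    mean_gap: Optional[float] = None
    error_samples: Optional[int] = None
    fo_interval: Optional[tuple[float, float]] = None
    lo_interval: Optional[tuple[float, float]] = None
    longevity: Optional[float] = None

    @property
    def included(self) -> bool:
        return self.status == "included"


# ----------------------------------------------------------------------
def observed_range(
    table: OccurrenceTable, taxon_id: str
) -> Optional[tuple[int, int]]:
    """Indices of the oldest (FO) and youngest (LO) samples with a nonzero
    count, or ``None`` if the species never occurs."""
    col = table.counts[taxon_id].to_numpy()
    nz = np.flatnonzero(col > 0)
    if nz.size == 0:
        return None
    return int(nz[0]), int(nz[-1])


def mean_gap(table: OccurrenceTable, taxon_id: str) -> float:
    """Mean length, in samples, of the maximal zero-count runs strictly
    between the species' FO and LO; 0.0 when the record is gap-free."""
    rng = observed_range(table, taxon_id)
    if rng is None:
        raise ValueError(f"{taxon_id!r} has no occurrences")
    fo, lo = rng
    col = table.counts[taxon_id].to_numpy()[fo : lo + 1]
    runs = _zero_runs(col)
    return float(np.mean(runs)) if runs else 0.0


def _zero_runs(window: np.ndarray) -> list[int]:
    runs: list[int] = []
    current = 0
    for v in window:
        if v == 0:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    # window starts and ends with occurrences, so no trailing run
    return runs


def error_samples(g: float) -> int:
    """Error bar in samples: ceil of the mean gap, minimum 1."""
    if g < 0:
        raise ValueError("mean gap must be nonnegative")
    return max(1, math.ceil(g)) if g > 0 else 1


def error_intervals(
    table: OccurrenceTable, fo_index: int, lo_index: int, e: int
) -> tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]:
    """Closed age intervals [older, younger] for the FO and LO error bars.

    The FO interval spans from the sample ``e`` positions older than the FO
    down to the FO itself; the LO interval from the LO to the sample ``e``
    positions younger.  ``None`` marks an interval whose outer endpoint falls
    off the sample sequence (overflow)."""
    ages = table.ages
    n = len(ages)
    fo_outer = fo_index - e
    lo_outer = lo_index + e
    fo_iv = (float(ages[fo_outer]), float(ages[fo_index])) if fo_outer >= 0 else None
    lo_iv = (float(ages[lo_index]), float(ages[lo_outer])) if lo_outer < n else None
    return fo_iv, lo_iv


def edge_filter(table: OccurrenceTable, taxon_id: str) -> str:
    """'excluded_edge' if the species has ANY occurrence in the two oldest
    or two youngest samples of the composite sequence, else 'included'."""
    col = table.counts[taxon_id].to_numpy()
    n = len(col)
    edge = np.zeros(n, dtype=bool)
    edge[: min(2, n)] = True
    edge[max(0, n - 2):] = True
    return "excluded_edge" if (col[edge] > 0).any() else "included"


def interval_filter(
    fo_interval: Optional[tuple[float, float]],
    lo_interval: Optional[tuple[float, float]],
) -> str:
    """'excluded_overflow' if either error interval runs off the sampled
    interval (species possibly extant or originating before the study)."""
    return "excluded_overflow" if fo_interval is None or lo_interval is None else "included"


def doubling_filter(
    fo_interval: tuple[float, float],
    lo_interval: tuple[float, float],
    fo_age: float,
    lo_age: float,
) -> str:
    """'excluded_doubling' if the outer span of the error bars is strictly
    more than twice the observed range.  Single-sample ranges (raw span 0)
    necessarily fail."""
    raw = fo_age - lo_age
    extended = fo_interval[0] - lo_interval[1]
    return "excluded_doubling" if extended > 2.0 * raw else "included"


def longevity(
    fo_interval: tuple[float, float], lo_interval: tuple[float, float]
) -> float:
    """Midpoint of the FO error interval minus midpoint of the LO error
    interval, in my."""
    L = (fo_interval[0] + fo_interval[1]) / 2.0 - (lo_interval[0] + lo_interval[1]) / 2.0
    if L <= 0:
        raise ValueError(
            f"non-positive longevity {L}: sample ages are not properly ordered"
        )
    return L


# ----------------------------------------------------------------------
def vet_all(
    table: OccurrenceTable,
    exclusions: ExclusionList | None = None,
    *,
    edge_samples: int = 2,
    min_error_samples: int = 1,
) -> list[SpeciesRange]:
    """Run the full vetting cascade over every species-level taxon.

    Order of application: occurrence exclusions, edge filter, error-bar
    construction, overflow filter, doubling filter, longevity.  Every
    species-level taxon receives exactly one status; the order only affects
    which exclusion reason is recorded, never who ends up included.
    """
    if exclusions is not None and exclusions.entries:
        table = apply_exclusions(table, exclusions)

    ages = table.ages
    n = table.n_samples
    results: list[SpeciesRange] = []
    for taxon_id in table.species_taxa:
        results.append(
            _vet_one(table, taxon_id, ages, n, edge_samples, min_error_samples)
        )

    tally: dict[str, int] = {}
    for r in results:
        tally[r.status] = tally.get(r.status, 0) + 1
    logger.info("vetting statuses: %s", dict(sorted(tally.items())))
    return results


def _vet_one(
    table: OccurrenceTable,
    taxon_id: str,
    ages: np.ndarray,
    n: int,
    edge_samples: int,
    min_error_samples: int,
) -> SpeciesRange:
    rng = observed_range(table, taxon_id)
    if rng is None:
        return SpeciesRange(taxon_id, "excluded_no_occurrence")
    fo, lo = rng
    fo_age, lo_age = float(ages[fo]), float(ages[lo])

    col = table.counts[taxon_id].to_numpy()
    edge = np.zeros(n, dtype=bool)
    edge[: min(edge_samples, n)] = True
    edge[max(0, n - edge_samples):] = True
    if (col[edge] > 0).any():
        return SpeciesRange(
            taxon_id, "excluded_edge", fo, lo, fo_age, lo_age
        )

    g = mean_gap(table, taxon_id)
    e = max(error_samples(g), min_error_samples)
    fo_iv, lo_iv = error_intervals(table, fo, lo, e)
    base = dict(
        fo_index=fo, lo_index=lo, fo_age=fo_age, lo_age=lo_age,
        mean_gap=g, error_samples=e, fo_interval=fo_iv, lo_interval=lo_iv,
    )
    if interval_filter(fo_iv, lo_iv) != "included":
        return SpeciesRange(taxon_id, "excluded_overflow", **base)
    if doubling_filter(fo_iv, lo_iv, fo_age, lo_age) != "included":
        return SpeciesRange(taxon_id, "excluded_doubling", **base)
    return SpeciesRange(taxon_id, "included", longevity=longevity(fo_iv, lo_iv), **base)
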