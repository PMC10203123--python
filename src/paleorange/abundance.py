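"""Relative abundance, per-species abundance summaries, richness and coverage.

Counts are standardized within each sample to percent relative abundance,
p_ij = 100 * n_ij / N_j, where N_j sums over species-level taxa only; this
removes differences in counting effort between samples.  Per-species
summaries (mean, maximum, standard deviation of percent abundance) are taken
over every sample inside the species' observed range [FO, LO] — zero-count
samples inside the range count as zeros, since absence from a counted sample
within the range is a real observation of rarity.  Natural-log transforms
operate on the percent values.

Sample coverage is the Good-Turing/Chao estimate of the fraction of the
assemblage's individuals belonging to species already seen, computed from
singleton and doubleton species counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .occurrence import OccurrenceTable
from .vetting import SpeciesRange

logger = logging.getLogger(__name__)

__all__ = [
    "relative_abundance",
    "species_summary",
    "richness",
    "coverage_estimate",
    "sample_coverage",
    "SpeciesAbundanceSummary",
    "CoverageEstimate",
]


@dataclass
class SpeciesAbundanceSummary:
    """Mean / max / SD of percent relative abundance over a species' range,
    with their natural-log transforms (None where the argument is 0)."""

    taxon_id: str
    mean: float
    max: float
    sd: float
    ln_mean: Optional[float]
    ln_max: Optional[float]
    ln_sd: Optional[float]


@dataclass
class CoverageEstimate:
    n: int          # specimens in the sample
    f1: int         # singleton species
    f2: int         # doubleton species
    coverage: float  # estimated coverage fraction in [0, 1]


# ----------------------------------------------------------------------
def relative_abundance(table: OccurrenceTable) -> pd.DataFrame:
    """Percent relative abundance per species-level taxon and sample.

    Rows are samples (age-ordered, matching the table), columns species-level
    taxa; each row sums to 100.  Genus-level and higher columns are excluded
    from both numerator and denominator.
    """
    sp = table.species_counts()
    if sp.shape[1] == 0:
        raise ValueError("no species-level taxa in table")
    totals = sp.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(
            f"sample {empty.index[0]!r} has no species-level specimens"
        )
    return 100.0 * sp.div(totals, axis=0)


def species_summary(
    ab: pd.DataFrame, rng: SpeciesRange
) -> SpeciesAbundanceSummary:
    """Summarize a species' percent abundances over all samples in its
    observed range, zeros included; SD uses the n-1 denominator."""
    if rng.fo_index is None or rng.lo_index is None:
        raise ValueError(f"{rng.taxon_id!r} has no observed range")
    vals = ab[rng.taxon_id].to_numpy()[rng.fo_index : rng.lo_index + 1]
    a = float(np.mean(vals))
    m = float(np.max(vals))
    s = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return SpeciesAbundanceSummary(
        taxon_id=rng.taxon_id,
        mean=a,
        max=m,
        sd=s,
        ln_mean=math.log(a) if a > 0 else None,
        ln_max=math.log(m) if m > 0 else None,
        ln_sd=math.log(s) if s > 0 else None,
    )


def richness(table: OccurrenceTable) -> pd.Series:
    """Number of species-level taxa present (count > 0) in each sample."""
    return (table.species_counts() > 0).sum(axis=1)


def coverage_estimate(counts) -> CoverageEstimate:
    """Good-Turing/Chao sample coverage from one sample's species-level
    specimen counts.

    C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)], where f1 and f2 are the
    numbers of singleton and doubleton species and n the specimen total.
    C = 1 exactly when there are no singletons.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    n = int(c.sum())
    if n < 1:
        raise ValueError("coverage requires at least one specimen")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        cov = 1.0
    else:
        cov = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))
    return CoverageEstimate(n=n, f1=f1, f2=f2, coverage=cov)


def sample_coverage(table: OccurrenceTable) -> pd.Series:
    """Coverage estimate for every sample in the table."""
    sp = table.species_counts()
    return pd.Series(
        {sid: coverage_estimate(sp.loc[sid].to_numpy()).coverage for sid in sp.index},
        name="coverage",
    )
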