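"""Reading, validating and writing occurrence-count tables.

The central container is :class:`OccurrenceTable`: an age-ordered sequence of
dated sediment samples by taxa matrix of specimen counts, together with sample
metadata (site, age in Ma) and taxon metadata (order code, biogeographic code,
species-level flag).  Samples from multiple sites are merged into one composite
age-ordered sequence; ties in age are broken by (site_id, sample_id) so the
ordering is deterministic.

Counts are specimen counts, never presence/absence.  Genus- and higher-level
columns (``species_level == False``) are carried along in the table but are
excluded from every downstream computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORDER_CODES = frozenset({"C", "N", "S"})
BIOGEO_CODES = frozenset({"E", "C"})

__all__ = [
    "OccurrenceTable",
    "ExclusionList",
    "read_counts",
    "apply_exclusions",
    "write_species_table",
    "read_species_table",
]


@dataclass
class OccurrenceTable:
    """Age-ordered samples x taxa specimen counts.

    Attributes
    ----------
    counts : pd.DataFrame
        Integer counts, index = sample_id ordered oldest -> youngest,
        columns = taxon_id.
    samples : pd.DataFrame
        Index = sample_id in the same order as ``counts``; columns
        ``site_id`` and ``age`` (Ma before present).
    meta : pd.DataFrame
        Index = taxon_id; columns ``order_code`` (C/N/S), ``biogeo_code``
        (E = endemic, C = cosmopolitan) and boolean ``species_level``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self._sort_and_validate()

    # ------------------------------------------------------------------
    def _sort_and_validate(self) -> None:
        if not self.samples.index.is_unique:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if not self.meta.index.is_unique:
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValueError(f"duplicate taxon_id {dup!r}")
        if set(self.counts.index) != set(self.samples.index):
            raise ValueError("counts rows and sample table disagree on sample ids")
        if set(self.counts.columns) - set(self.meta.index):
            missing = sorted(set(self.counts.columns) - set(self.meta.index))
            raise ValueError(f"taxa missing from metadata: {missing[:5]}")

        ages = self.samples["age"].to_numpy(dtype=float)
        if (ages < 0).any():
            bad = self.samples.index[ages < 0][0]
            raise ValueError(f"negative age for sample {bad!r}")

        # composite ordering: oldest first; ties broken by (site_id, sample_id)
        order = (
            self.samples.assign(_sid=self.samples.index)
            .sort_values(["age", "site_id", "_sid"], ascending=[False, True, True])
            .index
        )
        self.samples = self.samples.loc[order]
        self.counts = self.counts.loc[order, self.meta.index.intersection(self.counts.columns)]
        # keep meta restricted & aligned to count columns
        self.meta = self.meta.loc[self.counts.columns]

        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.abs(frac).max() > 0:
                i, j = np.argwhere(frac != 0)[0]
                raise ValueError(
                    f"non-integer count at taxon {self.counts.columns[j]!r}, "
                    f"sample {self.counts.index[i]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.counts.columns[j]!r}, "
                f"sample {self.counts.index[i]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        """Sample ages in Ma, oldest first."""
        return self.samples["age"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def species_taxa(self) -> pd.Index:
        """Taxon ids flagged as species-level, in column order."""
        return self.meta.index[self.meta["species_level"].astype(bool)]

    def species_counts(self) -> pd.DataFrame:
        """Counts restricted to species-level taxa."""
        return self.counts[self.species_taxa]

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(
            self.counts.copy(), self.samples.copy(), self.meta.copy()
        )

    def equals(self, other: "OccurrenceTable") -> bool:
        return (
            self.counts.equals(other.counts)
            and np.allclose(self.ages, other.ages, rtol=1e-9)
            and self.meta.equals(other.meta)
        )


@dataclass
class ExclusionList:
    """(taxon_id, sample_id) occurrences to zero out, e.g. suspected
    reworked or misidentified specimens."""

    entries: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExclusionList":
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        return cls(set(zip(df["taxon_id"], df["sample_id"])))


# ----------------------------------------------------------------------
def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_counts(
    counts_path: str | Path,
    ages_path: str | Path,
    meta_path: str | Path,
) -> OccurrenceTable:
    """Read a counts matrix, sample ages and taxon metadata into a
    validated, age-sorted :class:`OccurrenceTable`.

    The counts file is a rectangular CSV/TSV with sample ids in the first
    column and one column per taxon; missing cells are read as 0.  The ages
    file maps sample_id -> (site_id, age); the metadata file maps taxon_id ->
    (order_code, biogeo_code, species_level).  A taxon absent from the
    metadata file is kept with ``species_level=False`` (and a warning), which
    removes it from every analysis.
    """
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path), index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts = counts.fillna(0)

    ages = pd.read_csv(ages_path, sep=_sep_for(ages_path), index_col=0)
    ages.index = ages.index.astype(str)
    if not {"site_id", "age"} <= set(ages.columns):
        raise ValueError("ages file must have columns sample_id, site_id, age")

    missing_samples = set(counts.index) - set(ages.index)
    if missing_samples:
        raise ValueError(
            f"samples present in counts but absent from ages file: "
            f"{sorted(missing_samples)[:5]}"
        )

    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), index_col=0)
    meta.index = meta.index.astype(str)
    meta = _normalize_meta(meta)

    unknown = [t for t in counts.columns if t not in meta.index]
    if unknown:
        logger.warning(
            "%d taxa absent from metadata; treated as non-species-level "
            "and excluded from analysis: %s%s",
            len(unknown), unknown[:5], "..." if len(unknown) > 5 else "",
        )
        filler = pd.DataFrame(
            {"order_code": "N", "biogeo_code": "E", "species_level": False},
            index=pd.Index(unknown, name=meta.index.name),
        )
        meta = pd.concat([meta, filler])

    table = OccurrenceTable(counts, ages.loc[counts.index], meta)
    logger.info(
        "read %d samples x %d taxa, %d specimens total (%d species-level)",
        table.n_samples,
        table.counts.shape[1],
        int(table.counts.to_numpy().sum()),
        int(table.species_counts().to_numpy().sum()),
    )
    return table


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col, alphabet in (("order_code", ORDER_CODES), ("biogeo_code", BIOGEO_CODES)):
        if col not in meta.columns:
            raise ValueError(f"taxon metadata missing column {col!r}")
        bad = set(meta[col].astype(str)) - alphabet
        if bad:
            raise ValueError(f"invalid {col} value(s): {sorted(bad)}")
    if "species_level" not in meta.columns:
        raise ValueError("taxon metadata missing column 'species_level'")
    sl = meta["species_level"]
    if sl.dtype == object:
        sl = sl.astype(str).str.lower().isin({"true", "1", "yes", "t"})
    meta["species_level"] = sl.astype(bool)
    return meta


def apply_exclusions(
    table: OccurrenceTable, exclusions: ExclusionList
) -> OccurrenceTable:
    """Zero the listed (taxon, sample) cells; everything else is unchanged."""
    out = table.copy()
    zeroed = 0
    for taxon_id, sample_id in sorted(exclusions.entries):
        if taxon_id not in out.counts.columns:
            raise KeyError(f"exclusion references unknown taxon {taxon_id!r}")
        if sample_id not in out.counts.index:
            raise KeyError(f"exclusion references unknown sample {sample_id!r}")
        if out.counts.at[sample_id, taxon_id] > 0:
            zeroed += 1
        out.counts.at[sample_id, taxon_id] = 0
    logger.info("exclusion list zeroed %d occupied cells", zeroed)
    return out


def write_counts(
    table: OccurrenceTable,
    counts_path: str | Path,
    ages_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the CSV/TSV trio that :func:`read_counts` consumes."""
    for p in (counts_path, ages_path, meta_path):
        Path(p).parent.mkdir(parents=True, exist_ok=True)
    table.counts.rename_axis("sample_id").to_csv(
        counts_path, sep=_sep_for(counts_path)
    )
    table.samples.rename_axis("sample_id").to_csv(
        ages_path, sep=_sep_for(ages_path), float_format="%.12g"
    )
    table.meta.rename_axis("taxon_id").to_csv(meta_path, sep=_sep_for(meta_path))


SPECIES_TABLE_COLUMNS = [
    "taxon_id", "order_code", "biogeo_code", "fo_age", "lo_age",
    "mean_gap", "error_samples", "longevity",
    "mean_abundance", "max_abundance", "sd_abundance",
    "ln_mean_abundance", "ln_max_abundance", "ln_sd_abundance",
    "status", "included",
]


def write_species_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write the per-species results table (one row per species: range,
    error bar, longevity, abundance summaries, vetting status)."""
    df = pd.DataFrame(list(rows), columns=SPECIES_TABLE_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")


def read_species_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))
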