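import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from paleorange.occurrence import OccurrenceTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_table(counts_rows, ages, site="X", taxa=None, species_level=None):
    """Build a small OccurrenceTable from a list of per-sample count rows
    (oldest first) and matching ages (Ma, descending)."""
    counts_rows = np.asarray(counts_rows, dtype=np.int64)
    n_samples, n_taxa = counts_rows.shape
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    counts = pd.DataFrame(counts_rows, index=sample_ids, columns=taxa)
    samples = pd.DataFrame({"site_id": site, "age": ages}, index=sample_ids)
    if species_level is None:
        species_level = [True] * n_taxa
    meta = pd.DataFrame(
        {
            "order_code": ["N"] * n_taxa,
            "biogeo_code": ["E"] * n_taxa,
            "species_level": species_level,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return OccurrenceTable(counts, samples, meta)


@pytest.fixture
def toy_table():
    """3 samples x 2 taxa, ages 10/5/1 Ma."""
    return make_table([[1, 0], [2, 3], [0, 4]], [10.0, 5.0, 1.0])


@pytest.fixture
def vetting_matrix():
    """10 age-ordered samples (ages 10..1 Ma) x 6 species, designed so each
    vetting filter claims exactly one designed victim.

    Statuses worked out by hand before implementation:
      sp_inc       occurrences at indices 3-6 (contiguous)     -> included,
                   g=0, e=1, FO iv [8,7], LO iv [4,3], L=4.0 my
      sp_edge      occurrence at index 1 (second-oldest)       -> excluded_edge
      sp_none      no occurrences                              -> excluded_no_occurrence
      sp_overflow  occurrences at 2 and 7, gap run of 4 -> e=4; error bar
                   runs off both ends                          -> excluded_overflow
      sp_double    single occurrence at index 4 (raw span 0)   -> excluded_doubling
      sp_bound     occurrences at 4 and 6, g=1, e=1; raw=2 my,
                   extended=4 my = exactly 2x raw ("more than
                   doubled" is strict)                         -> included, L=3.0 my
    """
    ages = [10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
    cols = {
        "sp_inc":      [0, 0, 0, 2, 1, 3, 1, 0, 0, 0],
        "sp_edge":     [0, 5, 0, 0, 1, 0, 0, 0, 0, 0],
        "sp_none":     [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "sp_overflow": [0, 0, 4, 0, 0, 0, 0, 2, 0, 0],
        "sp_double":   [0, 0, 0, 0, 7, 0, 0, 0, 0, 0],
        "sp_bound":    [0, 0, 0, 0, 2, 0, 3, 0, 0, 0],
    }
    rows = np.array(list(cols.values())).T
    return make_table(rows, ages, taxa=list(cols))


EXPECTED_STATUSES = {
    "sp_inc": "included",
    "sp_edge": "excluded_edge",
    "sp_none": "excluded_no_occurrence",
    "sp_overflow": "excluded_overflow",
    "sp_double": "excluded_doubling",
    "sp_bound": "included",
}
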