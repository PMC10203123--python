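"""Synthetic occurrence-data generators.

Three generators with increasing realism of purpose:

* :func:`neutral_drift_sim` — a zero-sum Moran model of ecological drift.
  Each step one uniformly-chosen individual dies and is replaced by the
  offspring of a uniformly-chosen survivor, or by a founder of a brand-new
  species with probability ``nu``.  Under pure drift, rare species random
  walk to extinction sooner, so time-averaged abundance and lifetime are
  positively correlated — the qualitative expectation this package's
  statistics are designed to test on real occurrence data.

* :func:`niche_generator` — species with *known* mean abundance and *known*
  longevity, coupled through a tunable slope (my of longevity per ln-unit of
  abundance).  Because the truth is recorded, the full
  vetting -> abundance -> regression pipeline can be checked for parameter
  and sign recovery.

* :func:`fixture_so_eep` — occurrence tables shaped like the two study
  systems this package targets: a Southern-Ocean-like composite (97 samples,
  22.65-0.04 Ma, ~7,000 species-level specimens/sample, 100-200 species per
  sample) and an eastern-equatorial-Pacific-like single-site series (14
  samples, 10.3-0 Ma, ~2,500 specimens/sample, ~350 species per sample),
  with right-skewed lognormal species-abundance distributions.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .occurrence import OccurrenceTable

__all__ = [
    "SimConfig",
    "NeutralSimResult",
    "NicheTruth",
    "neutral_drift_sim",
    "niche_generator",
    "fixture_so_eep",
]

# One Moran step mapped to my of elapsed time.  The default makes the median
# completed species lifetime at (J=100, nu=0.01) land near 8 my, the median
# longevity scale of long-lived polycystine plankton.
DEFAULT_MY_PER_STEP = 0.08


@dataclass
class SimConfig:
    """Parameters of the synthetic generators.

    Only the fields relevant to the generator being called are read; the
    rest are ignored.  ``seed`` fully determines every output.
    """

    seed: int = 0
    # --- neutral drift ---
    J: int = 100                  # community size (individuals), zero-sum
    nu: float = 0.01              # per-birth probability of speciation
    n_steps: int = 500_000        # Moran steps (one birth-death event each)
    my_per_step: float = DEFAULT_MY_PER_STEP
    # --- sampling grid ---
    sample_ages: Optional[list[float]] = None  # Ma, strictly decreasing
    specimens_per_sample: int = 3000           # species-level specimens drawn
    # --- niche generator ---
    n_species: int = 200
    richness_target: Optional[int] = None      # species per sample (fixtures)
    abundance_mu: float = -3.0    # ln of mean percent-scale abundance weight
    abundance_sigma: float = 2.0  # lognormal shape: ~4 orders of magnitude
    coupling_beta: float = 1.5    # my longevity per ln-unit mean abundance
    longevity_base: float = 15.0  # my, intercept of the longevity rule;
                                  # high enough that the min_longevity floor
                                  # truncates <1% of species, keeping the
                                  # coupling slope identifiable
    noise_sd: float = 2.0         # my, longevity scatter
    min_longevity: float = 0.5    # my, truncation floor
    wiggle_sigma: float = 0.6     # within-range lognormal abundance wiggle

    def __post_init__(self) -> None:
        if self.J < 10:
            raise ValueError("community size J must be >= 10")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("speciation probability nu must be in [0, 1]")
        if self.sample_ages is not None:
            ages = np.asarray(self.sample_ages, dtype=float)
            if len(ages) > 1 and not (np.diff(ages) < 0).all():
                raise ValueError("sample_ages must be strictly decreasing (old -> young)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class NeutralSimResult:
    """Output of the Moran drift simulation."""

    species: pd.DataFrame
    """One row per species ever alive: birth_step, death_step (NaN if extant
    at the end), lifetime_steps, mean_abundance (time-averaged individuals),
    longevity_my; completed == True when the full lifetime was observed."""

    snapshots: pd.DataFrame
    """Community composition (individuals per species) at each sample age;
    rows = sample ids, columns = species."""

    table: Optional[OccurrenceTable]
    """Fossil-like occurrence table from multinomial sampling of each
    snapshot, or None when no sampling grid was configured."""


def neutral_drift_sim(cfg: SimConfig) -> NeutralSimResult:
    """Run the zero-sum Moran model and (optionally) fossilize it.

    The community starts as a single species of ``J`` individuals.  Total
    abundance is conserved exactly at every step.  Species lifetimes are
    birth-to-extinction step counts scaled by ``my_per_step``; a species'
    mean abundance is the time average of its population size over its
    lifetime, maintained incrementally in O(1) per step.
    """
    rng = np.random.default_rng(cfg.seed)
    J, n_steps, nu = cfg.J, cfg.n_steps, cfg.nu

    community = np.zeros(J, dtype=np.int64)  # species id per individual
    counts: dict[int, int] = {0: J}
    birth: dict[int, int] = {0: 0}
    death: dict[int, int] = {}
    integral: dict[int, float] = {0: 0.0}
    last: dict[int, int] = {0: 0}
    next_id = 1

    # sampling grid mapped linearly onto the step axis, oldest age = step 0
    snap_steps: dict[int, list[int]] = {}
    ages = None
    if cfg.sample_ages is not None:
        ages = np.asarray(cfg.sample_ages, dtype=float)
        span = ages[0] - ages[-1]
        for j, a in enumerate(ages):
            s = int(round((ages[0] - a) / span * (n_steps - 1))) if span > 0 else n_steps - 1
            snap_steps.setdefault(s, []).append(j)
    snapshots: dict[int, dict[int, int]] = {}

    BLOCK = 8192
    t = 0
    while t < n_steps:
        m = min(BLOCK, n_steps - t)
        deaths = rng.integers(J, size=m)
        parents = rng.integers(J, size=m)
        speciate = rng.random(m) < nu
        for i in range(m):
            step = t + i
            if step in snap_steps:
                for j in snap_steps[step]:
                    snapshots[j] = dict(counts)
            d = int(deaths[i])
            s_old = int(community[d])
            if speciate[i]:
                s_new = next_id
                next_id += 1
            else:
                p = int(parents[i])
                while p == d:
                    p = int(rng.integers(J))
                s_new = int(community[p])
            if s_new == s_old:
                continue
            # close the running abundance integrals before the change
            integral[s_old] += counts[s_old] * (step - last[s_old])
            last[s_old] = step
            if s_new in counts:
                integral[s_new] += counts[s_new] * (step - last[s_new])
                last[s_new] = step
                counts[s_new] += 1
            else:
                birth[s_new] = step
                counts[s_new] = 1
                integral[s_new] = 0.0
                last[s_new] = step
            community[d] = s_new
            counts[s_old] -= 1
            if counts[s_old] == 0:
                death[s_old] = step
                del counts[s_old]
        t += m
    for s in counts:  # close integrals for extant species
        integral[s] += counts[s] * (n_steps - last[s])
        last[s] = n_steps

    rows = []
    for s, b in birth.items():
        dd = death.get(s)
        end = dd if dd is not None else n_steps
        lifetime = end - b
        if lifetime <= 0:
            continue  # born and died in the same step index bookkeeping
        rows.append({
            "species": s,
            "birth_step": b,
            "death_step": dd if dd is not None else np.nan,
            "lifetime_steps": lifetime,
            "mean_abundance": integral[s] / lifetime,
            "longevity_my": lifetime * cfg.my_per_step,
            "completed": dd is not None,
        })
    species = pd.DataFrame(rows).set_index("species").sort_index()

    if ages is None:
        return NeutralSimResult(species=species, snapshots=pd.DataFrame(), table=None)

    snap_df = (
        pd.DataFrame.from_dict(snapshots, orient="index")
        .reindex(range(len(ages)))
        .fillna(0)
        .astype(np.int64)
    )
    snap_df.index = [f"S{j:03d}" for j in range(len(ages))]
    table = _fossilize(snap_df, ages, cfg, rng)
    return NeutralSimResult(species=species, snapshots=snap_df, table=table)


def _fossilize(
    snap_df: pd.DataFrame, ages: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> OccurrenceTable:
    """Multinomial down-sampling of community snapshots into specimen
    counts (no time-averaging: each sample sees one instant)."""
    counts = np.zeros(snap_df.shape, dtype=np.int64)
    comp = snap_df.to_numpy(dtype=float)
    for j in range(len(ages)):
        tot = comp[j].sum()
        if tot > 0:
            counts[j] = rng.multinomial(cfg.specimens_per_sample, comp[j] / tot)
    keep = counts.sum(axis=0) > 0
    taxa = [f"sp{int(s):05d}" for s in snap_df.columns[keep]]
    counts_df = pd.DataFrame(counts[:, keep], index=snap_df.index, columns=taxa)
    samples = pd.DataFrame(
        {"site_id": "SIM", "age": ages}, index=counts_df.index
    )
    meta = pd.DataFrame(
        {
            "order_code": rng.choice(["N", "S", "C"], size=len(taxa), p=[0.7, 0.2, 0.1]),
            "biogeo_code": rng.choice(["E", "C"], size=len(taxa)),
            "species_level": True,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return OccurrenceTable(counts_df, samples, meta)


# ----------------------------------------------------------------------
@dataclass
class NicheTruth:
    """Niche-generator output: the occurrence table plus the generating
    truth, for recovery tests."""

    table: OccurrenceTable
    truth: pd.DataFrame
    """Per species: ln_mean_abundance (the generating ln weight),
    longevity_my (true duration), fo_age, lo_age."""


def niche_generator(cfg: SimConfig) -> NicheTruth:
    """Generate species with known abundance-longevity coupling.

    ln mean abundance is Normal(abundance_mu, abundance_sigma); true
    longevity is ``longevity_base + coupling_beta * ln(a)`` plus Normal
    noise truncated above ``min_longevity`` my.  Each species' range is
    placed uniformly within the sampling interval (clipped to fit) and its
    per-sample counts are multinomial draws weighted by its mean abundance
    times a lognormal within-range wiggle.
    """
    rng = np.random.default_rng(cfg.seed)
    ages = (
        np.asarray(cfg.sample_ages, dtype=float)
        if cfg.sample_ages is not None
        else np.linspace(40.0, 0.0, 81)
    )
    old, young = float(ages[0]), float(ages[-1])

    ln_a = rng.normal(cfg.abundance_mu, cfg.abundance_sigma, size=cfg.n_species)
    mu_L = cfg.longevity_base + cfg.coupling_beta * ln_a
    alpha = (cfg.min_longevity - mu_L) / cfg.noise_sd
    noise = truncnorm.rvs(
        alpha, np.inf, loc=0.0, scale=cfg.noise_sd,
        size=cfg.n_species, random_state=rng,
    )
    L = mu_L + noise

    # uniform placement of the true range [fo, fo - L]: the origination age
    # is drawn so the range may overhang either end of the study window and
    # is then clipped to it — exactly the situation the edge filter guards
    # against in real data, and it keeps every sample occupied
    fo_true = young + rng.random(cfg.n_species) * (old - young + L)
    fo = np.minimum(fo_true, old)
    lo = np.maximum(fo_true - L, young)

    taxa = [f"sp{i:04d}" for i in range(cfg.n_species)]
    weights = np.exp(ln_a)
    in_range = (ages[None, :] <= fo[:, None] + 1e-12) & (
        ages[None, :] >= lo[:, None] - 1e-12
    )  # species x samples
    counts = np.zeros((len(ages), cfg.n_species), dtype=np.int64)
    for j in range(len(ages)):
        live = in_range[:, j]
        if not live.any():
            continue
        wig = np.exp(rng.normal(-cfg.wiggle_sigma**2 / 2, cfg.wiggle_sigma, size=int(live.sum())))
        w = weights[live] * wig
        counts[j, live] = rng.multinomial(cfg.specimens_per_sample, w / w.sum())

    sample_ids = [f"S{j:03d}" for j in range(len(ages))]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    samples = pd.DataFrame({"site_id": "SIM", "age": ages}, index=sample_ids)
    meta = pd.DataFrame(
        {
            "order_code": rng.choice(["N", "S", "C"], size=cfg.n_species, p=[0.7, 0.2, 0.1]),
            "biogeo_code": rng.choice(["E", "C"], size=cfg.n_species),
            "species_level": True,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    truth = pd.DataFrame(
        {
            "ln_mean_abundance": ln_a,
            "longevity_my": L,
            "fo_age": fo,
            "lo_age": lo,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return NicheTruth(table=OccurrenceTable(counts_df, samples, meta), truth=truth)


# ----------------------------------------------------------------------
_SO_SITES = ["689", "690", "744", "747", "748", "751", "1138"]


def fixture_so_eep(which: str, seed: int = 0) -> OccurrenceTable:
    """Occurrence table shaped like one of the two study systems.

    ``which='SO'``: 97-sample composite, 22.65-0.04 Ma, ~7,000 species-level
    specimens per sample, 100-200 species per sample, order codes in roughly
    15/135/39 C/N/S proportions, plus a handful of genus-level columns that
    every analysis must ignore.  ``which='EEP'``: 14-sample single-site
    series, 10.3-0 Ma, ~2,500 specimens and ~350 species per sample.
    """
    which = which.upper()
    if which == "SO":
        cfg = SimConfig(
            seed=seed,
            sample_ages=list(np.linspace(22.65, 0.04, 97)),
            specimens_per_sample=7190,
            n_species=550,
            abundance_mu=-3.0,
            abundance_sigma=2.0,
            coupling_beta=0.0,
            longevity_base=9.0,
            noise_sd=4.0,
            min_longevity=0.5,
        )
        order_p = [15 / 189, 135 / 189, 39 / 189]  # C, N, S
        n_genus = 6
    elif which == "EEP":
        cfg = SimConfig(
            seed=seed,
            sample_ages=list(np.linspace(10.3, 0.0, 14)),
            specimens_per_sample=2500,
            n_species=1350,
            abundance_mu=-1.0,
            abundance_sigma=1.0,
            coupling_beta=0.0,
            longevity_base=5.0,
            noise_sd=2.5,
            min_longevity=0.5,
        )
        order_p = [12 / 101, 58 / 101, 31 / 101]
        n_genus = 4
    else:
        raise ValueError("which must be 'SO' or 'EEP'")

    out = niche_generator(cfg)
    table = out.table
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    n = table.counts.shape[1]
    table.meta["order_code"] = rng.choice(["C", "N", "S"], size=n, p=order_p)
    table.meta["biogeo_code"] = rng.choice(["E", "C"], size=n)

    # composite sections: spread SO samples over the real site labels
    if which == "SO":
        table.samples["site_id"] = rng.choice(_SO_SITES, size=table.n_samples)
    else:
        table.samples["site_id"] = "U1337"

    # genus-level columns: counted in the file, invisible to the analysis
    genus = pd.DataFrame(
        rng.poisson(30.0, size=(table.n_samples, n_genus)),
        index=table.counts.index,
        columns=[f"gen{k:02d}" for k in range(n_genus)],
    )
    counts = pd.concat([table.counts, genus], axis=1)
    gmeta = pd.DataFrame(
        {"order_code": "N", "biogeo_code": "C", "species_level": False},
        index=pd.Index(genus.columns, name="taxon_id"),
    )
    meta = pd.concat([table.meta, gmeta])
    return OccurrenceTable(counts, table.samples, meta)
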