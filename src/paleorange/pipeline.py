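"""End-to-end analysis runs: read -> exclude -> vet -> metrics -> stats.

A run takes one regional dataset (SO-like or EEP-like; never pooled — the
two study systems differ in interval length, sampling density and counting
effort, so pooling them would bias every comparison) and produces:

* the per-species table (range, error bar, longevity, abundance summaries,
  vetting status);
* per-sample richness and coverage;
* four longevity regressions (ln mean / ln max abundance as headline
  predictors, ln SD as supplementary) with residual diagnostics;
* one-way ANOVAs of longevity by taxonomic order and by biogeographic
  category;
* the mixed-model (random intercept on biogeography) vs abundance-only
  comparison by AICc;
* a JSON-serializable summary keyed by stable names.

Runs are deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import relative_abundance, richness, sample_coverage, species_summary
from .occurrence import (
    ExclusionList,
    OccurrenceTable,
    read_counts,
    write_species_table,
)
from .stats import (
    ModelResult,
    compare_models,
    mixed_model,
    one_way_anova,
    ols_longevity,
    residual_diagnostics,
)
from .vetting import vet_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "analyze_table", "species_dataframe"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run over one regional dataset."""

    counts_path: Optional[str] = None
    ages_path: Optional[str] = None
    meta_path: Optional[str] = None
    exclusions_path: Optional[str] = None
    dataset_label: str = "custom"     # SO, EEP or custom; informational
    edge_samples: int = 2
    min_error_samples: int = 1
    alpha: float = 0.05
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_samples < 0:
            raise ValueError("edge_samples must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ----------------------------------------------------------------------
def species_dataframe(ranges, summaries) -> pd.DataFrame:
    """Merge vetting results and abundance summaries into the per-species
    results table."""
    summaries = {s.taxon_id: s for s in summaries}
    rows = []
    for r in ranges:
        s = summaries.get(r.taxon_id)
        rows.append({
            "taxon_id": r.taxon_id,
            "fo_age": r.fo_age,
            "lo_age": r.lo_age,
            "mean_gap": r.mean_gap,
            "error_samples": r.error_samples,
            "longevity": r.longevity,
            "mean_abundance": s.mean if s else None,
            "max_abundance": s.max if s else None,
            "sd_abundance": s.sd if s else None,
            "ln_mean_abundance": s.ln_mean if s else None,
            "ln_max_abundance": s.ln_max if s else None,
            "ln_sd_abundance": s.ln_sd if s else None,
            "status": r.status,
            "included": r.included,
        })
    return pd.DataFrame(rows)


def _model_block(m: ModelResult, diag: dict | None = None) -> dict:
    out = {
        "label": m.model_label,
        "n": m.n,
        "intercept": m.coefficients.get("intercept") or m.coefficients.get("Intercept"),
        "slope": m.coefficients.get("slope"),
        "r_squared": m.r_squared,
        "f_stat": m.f_stat,
        "p_value": m.p_value,
        "aic": m.aic,
        "aicc": m.aicc,
        "loglik": m.loglik,
        "converged": m.converged,
        "notes": m.notes,
    }
    if diag is not None:
        out["diagnostics"] = {
            k: diag[k] for k in ("shapiro_p", "bp_p", "runs_p") if k in diag
        }
    return out


def analyze_table(
    table: OccurrenceTable,
    exclusions: ExclusionList | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """Run the complete analysis on an in-memory occurrence table.

    Returns a dict with the per-species DataFrame under ``"species"``,
    per-sample ``"samples"`` (richness, coverage), fitted model objects under
    ``"models"``, and the JSON-ready ``"summary"``.
    """
    cfg = cfg or RunConfig()
    ranges = vet_all(
        table,
        exclusions,
        edge_samples=cfg.edge_samples,
        min_error_samples=cfg.min_error_samples,
    )
    if exclusions is not None and exclusions.entries:
        from .occurrence import apply_exclusions
        table = apply_exclusions(table, exclusions)

    ab = relative_abundance(table)
    included = [r for r in ranges if r.included]
    summaries = [species_summary(ab, r) for r in included]
    species = species_dataframe(ranges, summaries)
    species = species.merge(
        table.meta[["order_code", "biogeo_code"]],
        left_on="taxon_id", right_index=True, how="left",
    )

    samples = pd.DataFrame({
        "site_id": table.samples["site_id"],
        "age": table.samples["age"],
        "richness": richness(table),
        "coverage": sample_coverage(table),
        "species_level_specimens": table.species_counts().sum(axis=1),
    })

    inc = species[species["included"]].copy()
    n_inc = len(inc)
    summary: dict = {
        "dataset_label": cfg.dataset_label,
        "n_samples": int(table.n_samples),
        "n_species_level_taxa": int(len(table.species_taxa)),
        "n_included": n_inc,
        "status_counts": species["status"].value_counts().to_dict(),
        "median_longevity": float(inc["longevity"].median()) if n_inc else None,
        "mean_longevity": float(inc["longevity"].mean()) if n_inc else None,
        "median_mean_abundance": float(inc["mean_abundance"].median()) if n_inc else None,
        "median_max_abundance": float(inc["max_abundance"].median()) if n_inc else None,
        "mean_longevity_by_order": (
            inc.groupby("order_code")["longevity"].mean().to_dict() if n_inc else {}
        ),
        "n_by_order": (
            inc.groupby("order_code")["longevity"].size().to_dict() if n_inc else {}
        ),
    }

    models: dict = {}
    y = inc["longevity"].to_numpy(dtype=float)

    # headline regressions: ln mean and ln max abundance; SD supplementary.
    # Species whose SD is exactly 0 have no defined ln and drop from the SD
    # regression only.
    for metric, col in (
        ("mean", "ln_mean_abundance"),
        ("max", "ln_max_abundance"),
        ("sd", "ln_sd_abundance"),
    ):
        sub = inc.dropna(subset=[col])
        if len(sub) >= 3 and sub[col].nunique() > 1:
            m = ols_longevity(
                sub[col].to_numpy(dtype=float),
                sub["longevity"].to_numpy(dtype=float),
                label=f"ols_ln_{metric}",
            )
            d = residual_diagnostics(m)
            models[f"ols_ln_{metric}"] = m
            summary[f"ols_ln_{metric}"] = _model_block(m, d)
            if len(sub) < n_inc:
                summary[f"ols_ln_{metric}"]["n_dropped_undefined_ln"] = n_inc - len(sub)

    # ANOVAs: longevity by taxonomic order, and by biogeographic category
    for factor, col in (("order", "order_code"), ("biogeo", "biogeo_code")):
        counts = inc[col].value_counts()
        usable = inc[inc[col].isin(counts[counts >= 2].index)]
        if usable[col].nunique() >= 2:
            a = one_way_anova(usable["longevity"].to_numpy(dtype=float), usable[col])
            summary[f"anova_{factor}"] = {
                "f_stat": a.f_stat,
                "p_value": a.p_value,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "groups": a.groups,
            }

    # mixed model (abundance fixed, biogeography random intercept) vs the
    # abundance-only regression, compared by AICc under ML
    sub = inc.dropna(subset=["ln_mean_abundance"])
    if len(sub) >= 10 and sub["biogeo_code"].nunique() >= 2:
        mm = mixed_model(
            sub["longevity"].to_numpy(dtype=float),
            sub["ln_mean_abundance"].to_numpy(dtype=float),
            sub["biogeo_code"],
            label="mixed_biogeo",
        )
        simple = ols_longevity(
            sub["ln_mean_abundance"].to_numpy(dtype=float),
            sub["longevity"].to_numpy(dtype=float),
            label="ols_ln_mean_matched",
        )
        cmp = compare_models(mm, simple)
        models["mixed_biogeo"] = mm
        summary["mixed_model"] = _model_block(mm)
        summary["model_comparison"] = cmp

    summary["package_version"] = __version__
    summary["seed"] = cfg.seed
    summary["config_hash"] = cfg.config_hash()
    return {"species": species, "samples": samples, "models": models, "summary": summary}


def run(cfg: RunConfig) -> dict:
    """Read the configured input files, analyze, and write the results
    bundle (species CSV, samples CSV, summary JSON) to the output directory."""
    if not (cfg.counts_path and cfg.ages_path and cfg.meta_path):
        raise ValueError("counts_path, ages_path and meta_path are required")
    table = read_counts(cfg.counts_path, cfg.ages_path, cfg.meta_path)
    exclusions = (
        ExclusionList.from_csv(cfg.exclusions_path) if cfg.exclusions_path else None
    )
    result = analyze_table(table, exclusions, cfg)

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        sp = result["species"]
        write_species_table(
            sp.assign(order_code=sp["order_code"], biogeo_code=sp["biogeo_code"])
            .to_dict("records"),
            out / "species_table.csv",
        )
        result["samples"].rename_axis("sample_id").to_csv(out / "samples.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(result["summary"], fh, indent=2, sort_keys=True, default=float)
        logger.info("results bundle written to %s", out)
    return result
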