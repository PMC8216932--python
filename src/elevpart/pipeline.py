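"""End-to-end orchestration: load -> MDE null -> model selection -> stepwise
-> diversity partition -> habitat use -> report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, core_io, habitat, mde, models, partition

log = logging.getLogger("elevpart")


def stage_seeds(seed: int, stages=("mde", "models", "habitat", "synth")) -> dict[str, int]:
    """Fan a single global seed out to independent per-stage child seeds.

    Children derive from a SeedSequence spawn, so stages are decorrelated and
    each can be re-run standalone with its own seed.  Values stay below 2^31.
    """
    ss = np.random.SeedSequence(seed)
    states = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(stages))]
    return dict(zip(stages, states))


@dataclass
class PipelineConfig:
    occurrence: str | None = None
    covariates: str | None = None
    specimens: str | None = None
    out_dir: str = "elevpart_out"
    seed: int = 0
    n_reps: int = 100_000
    ci: float = 0.95
    max_poly_degree: int = 4
    n_boot: int = 200
    top_families: int = 6
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    out_dir: Path
    artifacts: dict[str, str] = field(default_factory=dict)
    numbers: dict[str, float] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def run_all(cfg: PipelineConfig) -> RunReport:
    """Run every stage, writing CSV/JSON artifacts plus a run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    report = RunReport(out_dir=out)

    try:
        occ = core_io.read_occurrence(cfg.occurrence)
        cov = core_io.read_covariates(cfg.covariates)
        if list(cov.index) != list(occ.sites):
            raise core_io.ValidationError(
                "covariate sites do not match occurrence sites"
            )
        spec_df = core_io.read_specimens(cfg.specimens) if cfg.specimens else None
    except StageError:
        raise
    except Exception as e:
        raise StageError("core_io", e) from e

    richness = occ.site_richness()
    elev = occ.elevations

    # --- MDE null model ---------------------------------------------------
    try:
        pred = mde.mde_predict(occ, n_reps=cfg.n_reps, seed=seeds["mde"], ci=cfg.ci)
        r2, p = mde.regress_observed_on_predicted(richness, pred.mean_richness)
        pred_df = pred.to_frame(sites=occ.sites, observed=richness)
        pred_df.to_csv(out / "predictions.csv", index=False)
        report.artifacts["predictions"] = "predictions.csv"
        report.numbers.update(mde_r2=r2, mde_p=p)
    except Exception as e:
        raise StageError("mde_null", e) from e

    # --- polynomial + candidate comparison + stepwise ----------------------
    try:
        best_deg, poly_fits = models.fit_polynomial(richness, elev, cfg.max_poly_degree)
        quad_curve = models.polynomial_curve(poly_fits[2], elev)
        X = models.prepare_predictors(cov, mde_curve=pred.mean_richness)
        comparison = models.compare_candidates(richness, X)
        comparison.table.to_csv(out / "model_table.csv", index=False)
        step = models.forward_stepwise(richness, X)
        step.steps.to_csv(out / "stepwise.csv", index=False)
        report.artifacts["model_table"] = "model_table.csv"
        report.artifacts["stepwise"] = "stepwise.csv"
        report.numbers.update(
            best_poly_degree=float(best_deg),
            quadratic_aicc=poly_fits[2].aicc,
            best_model_weight=float(comparison.table.iloc[0]["weight"]),
            final_stepwise_aicc=step.final.aicc,
            final_stepwise_adj_r2=step.final.adj_r2,
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("richness_models", e) from e

    # --- additive partition -------------------------------------------------
    try:
        parts = [
            partition.partition_occurrence(occ, pred.mean_richness, "MDE"),
            partition.partition_occurrence(occ, quad_curve, "quadratic"),
        ]
        part_report = partition.partition_report(parts)
        with open(out / "partition.json", "w") as fh:
            json.dump(part_report, fh, indent=2)
        report.artifacts["partition"] = "partition.json"
        report.numbers.update(
            gamma=parts[0].gamma,
            alpha_bar=parts[0].alpha_bar,
            beta=parts[0].beta,
            mean_beta_elevation_share_pct=part_report["mean_beta_elevation_share_pct"],
            mean_contribution_elevation_pct=part_report["mean_contribution_elevation_pct"],
        )
    except Exception as e:
        raise StageError("diversity_partition", e) from e

    # --- habitat use --------------------------------------------------------
    if spec_df is not None:
        try:
            curves = habitat_curves(
                occ, spec_df, top_families=cfg.top_families,
                n_boot=cfg.n_boot, seed=seeds["habitat"],
            )
            curves.to_csv(out / "habitat_curves.csv", index=False)
            report.artifacts["habitat_curves"] = "habitat_curves.csv"
        except Exception as e:
            raise StageError("habitat_use", e) from e

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "n_reps": cfg.n_reps,
        "artifacts": report.artifacts,
        "numbers": report.numbers,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report.artifacts["manifest"] = "manifest.json"
    return report


def habitat_curves(occ: core_io.OccurrenceMatrix, specimens: pd.DataFrame,
                   top_families: int = 6, n_boot: int = 200,
                   seed: int = 0) -> pd.DataFrame:
    """Occurrence-probability and CT-use curves for the most common families.

    Families are ranked by specimen count; each gets a quadratic-logistic
    occurrence fit (on per-site presence of the family) and, when it spans
    >= 2 substrate categories, a multinomial CT-use fit.  Curves share one
    long-format table: family, kind, elevation, category, value, lo, hi.
    """
    specimens = specimens.copy()
    if "elevation" not in specimens.columns:
        elev_of = dict(zip(occ.sites, occ.elevations))
        specimens["elevation"] = specimens["site"].astype(str).map(elev_of)
    counts = specimens["family"].value_counts()
    rows = []
    elev = occ.elevations
    fam_of = dict(zip(occ.species, occ.families or [""] * occ.n_species))
    for fam in counts.index[:top_families]:
        cols = [j for j, sp in enumerate(occ.species) if fam_of[sp] == fam]
        presence = (occ.incidence[:, cols].sum(axis=1) > 0).astype(int)
        if presence.min() != presence.max():
            om = habitat.fit_occurrence(presence, elev, family=fam,
                                        n_boot=n_boot, seed=seed)
            for g, pr, lo, hi in zip(om.grid, om.prob, om.band_lo, om.band_hi):
                rows.append({"family": fam, "kind": "occurrence", "elevation": g,
                             "category": "", "value": pr, "lo": lo, "hi": hi,
                             "shape": om.shape})
        sub = specimens[specimens["family"] == fam]
        if sub["community_type"].nunique() >= 2:
            cm = habitat.fit_ct_use(sub["community_type"], sub["elevation"],
                                    family=fam, n_boot=n_boot, seed=seed)
            for c in cm.categories:
                lo = cm.band_lo[c] if cm.band_lo is not None else cm.proportions[c]
                hi = cm.band_hi[c] if cm.band_hi is not None else cm.proportions[c]
                for g, pr, l, h in zip(cm.grid, cm.proportions[c], lo, hi):
                    rows.append({"family": fam, "kind": "ct_use", "elevation": g,
                                 "category": c, "value": pr, "lo": l, "hi": h,
                                 "shape": ""})
    return pd.DataFrame(rows)
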