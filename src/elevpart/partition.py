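"""Additive alpha/beta/gamma diversity partitioning with an elevation split.

Regional richness is decomposed additively, gamma = alpha_bar + beta, where
alpha_bar is the mean within-site richness and beta the heterogeneity among
sites.  Beta is then split using a predicted richness curve (the MDE null
mean, or a quadratic polynomial fit of richness on elevation):

    beta_elevation = S_max - alpha_bar       (floored at 0)
    beta_replace   = beta - beta_elevation

with S_max the maximum of the predicted curve over sites.  beta_elevation is
the average number of species absences attributable to the elevational
constraint embodied by the curve; beta_replace is the residual species
replacement among sites.  All five quantities share the unit "species", so
their relative shares are directly comparable.

The "contribution of elevation" is defined here as 100 * S_max / max observed
site richness — the fraction of the richest site's diversity the elevational
curve can account for.  This definition is a package design choice (see
docs/methods.md); it is isolated in `contribution_of_elevation` so an
alternative can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import OccurrenceMatrix

log = logging.getLogger("elevpart")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding for percent reporting (12.25 -> 12.3)."""
    q = 10.0**ndigits
    return float(np.floor(abs(x) * q + 0.5) / q * np.sign(x)) if x else 0.0


@dataclass
class PartitionResult:
    curve_label: str
    gamma: float
    alpha_bar: float
    beta: float
    s_max: float
    beta_elevation: float
    beta_replace: float
    alpha_share_pct: float        # alpha_bar as % of gamma
    beta_share_pct: float         # beta as % of gamma
    beta_elevation_share_pct: float  # beta_elevation as % of beta
    beta_replace_share_pct: float    # beta_replace as % of beta
    contribution_elevation_pct: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def rounded(self, ndigits: int = 1) -> dict:
        """Percent fields half-up rounded to one decimal for reporting."""
        out = self.to_dict()
        for k, v in out.items():
            if k.endswith("_pct"):
                out[k] = _round_half_up(v, ndigits)
        return out


def additive_partition(occ: OccurrenceMatrix) -> tuple[float, float, float]:
    """(gamma, alpha_bar, beta): distinct species, mean site richness, difference."""
    if occ.incidence.size == 0:
        raise ValueError("empty occurrence matrix")
    gamma = float(occ.n_species)
    alpha_bar = float(occ.site_richness().mean())
    return gamma, alpha_bar, gamma - alpha_bar


def contribution_of_elevation(s_max: float, max_observed_richness: float) -> float:
    """Percent of the richest site's diversity accounted for by the curve."""
    if max_observed_richness <= 0:
        raise ValueError("max observed richness must be positive")
    return 100.0 * s_max / max_observed_richness


def partition_beta(
    alpha_bar: float,
    beta: float,
    predicted_curve,
    max_observed_richness: float,
    curve_label: str = "MDE",
    gamma: float | None = None,
) -> PartitionResult:
    """Split beta into an elevation-explained part and a replacement residual.

    ``predicted_curve`` is the per-site predicted richness (same length as the
    site list); S_max is its maximum.  A predicted maximum below alpha_bar is
    clamped to beta_elevation = 0 with a warning.
    """
    curve = np.asarray(predicted_curve, dtype=float)
    if curve.ndim != 1 or curve.size == 0:
        raise ValueError("predicted curve must be a nonempty 1-D vector")
    gamma = alpha_bar + beta if gamma is None else gamma
    s_max = float(curve.max())
    beta_elev = s_max - alpha_bar
    if beta_elev < 0:
        log.warning(
            "predicted maximum %.2f below mean observed richness %.2f; "
            "clamping beta_elevation to 0", s_max, alpha_bar
        )
        beta_elev = 0.0
    if beta_elev > beta:
        log.warning("beta_elevation %.2f exceeds beta %.2f", beta_elev, beta)
    beta_repl = beta - beta_elev
    return PartitionResult(
        curve_label=curve_label,
        gamma=gamma,
        alpha_bar=alpha_bar,
        beta=beta,
        s_max=s_max,
        beta_elevation=beta_elev,
        beta_replace=beta_repl,
        alpha_share_pct=100.0 * alpha_bar / gamma,
        beta_share_pct=100.0 * beta / gamma,
        beta_elevation_share_pct=100.0 * beta_elev / beta if beta else 0.0,
        beta_replace_share_pct=100.0 * beta_repl / beta if beta else 0.0,
        contribution_elevation_pct=contribution_of_elevation(
            s_max, max_observed_richness
        ),
    )


def partition_occurrence(occ: OccurrenceMatrix, predicted_curve,
                         curve_label: str = "MDE") -> PartitionResult:
    """Full partition from an occurrence matrix and one predicted curve."""
    curve = np.asarray(predicted_curve, dtype=float)
    if curve.shape != (occ.n_sites,):
        raise ValueError(
            f"curve length {curve.size} does not match {occ.n_sites} sites"
        )
    gamma, alpha_bar, beta = additive_partition(occ)
    return partition_beta(
        alpha_bar, beta, curve,
        max_observed_richness=float(occ.site_richness().max()),
        curve_label=curve_label, gamma=gamma,
    )


def partition_report(results: list[PartitionResult]) -> dict:
    """Average shares/contributions across curves (e.g. MDE and quadratic).

    Returns per-curve rounded partitions plus arithmetic means of the share
    and contribution percentages and the replace:elevation share ratio.
    """
    if not results:
        raise ValueError("need at least one PartitionResult")
    elev_shares = [r.beta_elevation_share_pct for r in results]
    repl_shares = [r.beta_replace_share_pct for r in results]
    contribs = [r.contribution_elevation_pct for r in results]
    mean_elev = float(np.mean(elev_shares))
    mean_repl = float(np.mean(repl_shares))
    return {
        "curves": {r.curve_label: r.rounded() for r in results},
        "mean_beta_elevation_share_pct": _round_half_up(mean_elev),
        "mean_beta_replace_share_pct": _round_half_up(mean_repl),
        "mean_contribution_elevation_pct": _round_half_up(float(np.mean(contribs))),
        "replace_to_elevation_ratio": mean_repl / mean_elev if mean_elev else float("inf"),
    }
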