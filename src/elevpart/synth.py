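"""Synthetic elevational-gradient datasets with known ground truth.

The generator emulates a montane moss survey: D evenly spaced sites along an
elevation span, each species occupying one contiguous elevational range.
Range sizes are right-skewed (many narrow species, few wide ones).  Under the
``mde_uniform`` regime ranges are placed uniformly within the bounded domain,
so the mid-domain-effect null model is the true generating process; under
``covariate_driven`` placement probability follows a site covariate (by
default the community-type count), so habitat complexity drives richness;
``mixed`` blends the two.

Covariates mimic typical montane gradients: community-type count hump-shaped
in elevation, temperature decreasing, precipitation, wind speed and solar
radiation increasing, vegetation-type count trendless, all with Gaussian
noise.
Specimen records attach a family to each species and draw a substrate
category from a multinomial-logit model in elevation with known slopes, so
habitat-use fits can be checked against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import CT_CATEGORIES, OccurrenceMatrix


@dataclass
class SyntheticTruth:
    """Generator parameters: the ground truth recovery tests check against."""

    seed: int = 0
    n_sites: int = 73
    elev_min: float = 923.0
    elev_max: float = 2282.0
    n_species: int = 191
    n_families: int = 26
    mean_range_size: float = 4.89      # sites; right-skewed (truncated geometric)
    placement: str = "mde_uniform"     # mde_uniform | covariate_driven | mixed
    covariate: str = "ct_count"        # driver under covariate_driven
    covariate_effect: float = 2.0      # log-weight per SD of the driver
    mixed_weight: float = 0.5          # share of species placed covariate-driven
    ct_hump_center: float = 1500.0     # m; CT count peaks here
    ct_hump_width: float = 350.0       # m
    noise_scale: float = 1.0           # multiplier on covariate noise SDs
    occupancy: float = 1.0             # presence prob inside a placed range
    ct_use_slopes: dict = field(default_factory=lambda: {
        # per-SD-elevation log-odds slopes vs the soil reference
        "aquatic": 0.4, "stone": 0.2, "woody": 0.8,
    })

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_species < 1 or self.n_families < 1:
            raise ValueError("counts must be >= 1")
        if not (self.elev_min < self.elev_max) and self.n_sites > 1:
            raise ValueError("elevation span must be increasing")
        if self.placement not in ("mde_uniform", "covariate_driven", "mixed"):
            raise ValueError(f"unknown placement regime {self.placement!r}")
        if self.mean_range_size < 1 or self.mean_range_size > self.n_sites:
            raise ValueError("mean range size must lie in [1, n_sites]")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def study_like_preset(seed: int = 0) -> SyntheticTruth:
    """Preset matching the emulated survey's scale: 73 sites spanning
    923-2,282 m (~19 m spacing), 191 species in 26 families, mean site
    richness near 12.8."""
    return SyntheticTruth(seed=seed)


# ---------------------------------------------------------------------------


def _range_sizes(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    """Truncated geometric range sizes with the requested mean.

    A geometric on {1, 2, ...} with mean m has p = 1/m; values above D are
    redrawn (truncation), which shifts the mean only slightly for m << D.
    """
    D, m = truth.n_sites, truth.mean_range_size
    p = min(1.0, 1.0 / m)
    sizes = rng.geometric(p, size=truth.n_species)
    while np.any(sizes > D):
        redo = sizes > D
        sizes[redo] = rng.geometric(p, size=int(redo.sum()))
    return sizes


def _covariates(truth: SyntheticTruth, elev: np.ndarray,
                rng: np.random.Generator) -> pd.DataFrame:
    ns = truth.noise_scale
    hump = np.exp(-(((elev - truth.ct_hump_center) / truth.ct_hump_width) ** 2))
    ct = np.clip(np.rint(1.0 + 3.2 * hump + ns * 0.4 * rng.standard_normal(elev.size)),
                 1, len(CT_CATEGORIES)).astype(int)
    # VT count carries no elevational trend: the emulated survey found VT
    # uninformative for richness, so it enters as pure site-level noise
    vt = np.clip(np.rint(3.0 + ns * 1.2 * rng.standard_normal(elev.size)),
                 1, 6).astype(int)
    span = elev.max() - elev.min() or 1.0
    t = (elev - elev.min()) / span
    sr = 14800 + 800 * t + ns * 120 * rng.standard_normal(elev.size)  # rising
    ap = 480 + 120 * t + ns * 12 * rng.standard_normal(elev.size)          # mm, rising
    at = 9.5 - 6.5 * t + ns * 0.3 * rng.standard_normal(elev.size)         # degC, lapse
    ws = 2.2 + 1.6 * t + ns * 0.15 * rng.standard_normal(elev.size)        # m/s, rising
    sites = [f"S{i + 1:03d}" for i in range(elev.size)]
    return pd.DataFrame(
        {"site": sites, "elevation": elev, "vt_count": vt, "ct_count": ct,
         "sr": sr, "ap": ap, "at": at, "ws": ws}
    ).set_index("site")


def _placement_weights(size: int, driver_z: np.ndarray, effect: float) -> np.ndarray:
    """Weight per feasible start: exp(effect * mean driver over covered sites)."""
    D = driver_z.size
    csum = np.concatenate([[0.0], np.cumsum(driver_z)])
    means = (csum[size:] - csum[: D - size + 1]) / size
    w = np.exp(effect * (means - means.max()))
    return w / w.sum()


def _family_sizes(n_species: int, n_families: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Skewed family composition: a few dominant families hold most species."""
    w = 1.0 / np.arange(1, n_families + 1) ** 0.9
    sizes = np.maximum(1, np.rint(w / w.sum() * n_species).astype(int))
    # adjust largest families so sizes sum exactly to n_species
    diff = n_species - sizes.sum()
    order = np.argsort(-sizes)
    i = 0
    while diff != 0:
        j = order[i % n_families]
        step = 1 if diff > 0 else -1
        if sizes[j] + step >= 1:
            sizes[j] += step
            diff -= step
        i += 1
    return sizes


def generate(truth: SyntheticTruth, include_specimens: bool = True):
    """Generate (OccurrenceMatrix, covariates, specimens, truth echo).

    Deterministic for a fixed ``truth.seed``.  ``include_specimens=False``
    skips specimen records (returns None in their slot), which speeds up
    large replicate experiments that only need the incidence matrix.
    """
    rng = np.random.default_rng(truth.seed)
    D = truth.n_sites
    elev = (np.linspace(truth.elev_min, truth.elev_max, D)
            if D > 1 else np.array([truth.elev_min]))

    cov = _covariates(truth, elev, rng)
    sizes = _range_sizes(truth, rng)
    if np.any(sizes > D):
        raise ValueError("infeasible range size exceeds the domain")

    driver = cov[truth.covariate].to_numpy(dtype=float)
    driver_z = (driver - driver.mean()) / (driver.std(ddof=0) or 1.0)

    # choose a start per species, then occupy the contiguous block
    incidence = np.zeros((D, truth.n_species), dtype=np.int8)
    starts = np.empty(truth.n_species, dtype=int)
    covariate_driven = np.zeros(truth.n_species, dtype=bool)
    if truth.placement == "covariate_driven":
        covariate_driven[:] = True
    elif truth.placement == "mixed":
        covariate_driven = rng.random(truth.n_species) < truth.mixed_weight
    for s in range(truth.n_species):
        r = int(sizes[s])
        n_feasible = D - r + 1
        if covariate_driven[s]:
            starts[s] = rng.choice(
                n_feasible, p=_placement_weights(r, driver_z, truth.covariate_effect)
            )
        else:
            starts[s] = rng.integers(n_feasible)
        block = np.arange(starts[s], starts[s] + r)
        if truth.occupancy >= 1.0 or r <= 2:
            incidence[block, s] = 1
        else:
            keep = rng.random(r) < truth.occupancy
            keep[0] = keep[-1] = True  # endpoints define the realized extent
            incidence[block[keep], s] = 1

    fam_sizes = _family_sizes(truth.n_species, truth.n_families, rng)
    families = np.repeat([f"Family{k + 1:02d}" for k in range(truth.n_families)],
                         fam_sizes)
    species = [f"sp{j + 1:03d}" for j in range(truth.n_species)]
    occ = OccurrenceMatrix(
        sites=list(cov.index), species=species, incidence=incidence,
        elevations=elev, families=list(families),
    )

    specimens = _specimens(truth, occ, elev, rng) if include_specimens else None
    return occ, cov, specimens, truth


def _specimens(truth: SyntheticTruth, occ: OccurrenceMatrix, elev: np.ndarray,
               rng: np.random.Generator) -> pd.DataFrame:
    """One specimen per (site, species) presence; substrate category from a
    multinomial logit in standardized elevation with the truth's slopes."""
    z = (elev - elev.mean()) / (elev.std(ddof=0) or 1.0)
    non_ref = [c for c in CT_CATEGORIES if c != "soil"]
    slopes = np.array([truth.ct_use_slopes.get(c, 0.0) for c in non_ref])
    intercepts = np.array([-0.3, 0.4, -0.2])  # aquatic, stone, woody vs soil
    cats = ("soil",) + tuple(non_ref)

    eta = np.zeros((elev.size, len(cats)))
    eta[:, 1:] = intercepts + np.outer(z, slopes)
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)

    site_idx, sp_idx = np.nonzero(occ.incidence)
    u = rng.random(site_idx.size)
    cum = np.cumsum(p[site_idx], axis=1)
    choice = (u[:, None] > cum).sum(axis=1)
    return pd.DataFrame(
        {
            "site": [occ.sites[i] for i in site_idx],
            "species": [occ.species[j] for j in sp_idx],
            "family": [occ.families[j] for j in sp_idx] if occ.families
                      else [""] * len(sp_idx),
            "community_type": [cats[c] for c in choice],
            "elevation": elev[site_idx],
        }
    )
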