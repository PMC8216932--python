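"""Shared data model, readers/writers and validation.

The central container is :class:`OccurrenceMatrix`, a binary site-by-species
incidence matrix whose rows are ordered by ascending site elevation.  Site
positions along the ordered gradient are 1-based, matching the discrete
bounded-domain convention used by the null model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("elevpart")

#: community-type vocabulary (substrate categories a moss specimen occupies)
CT_CATEGORIES = ("aquatic", "stone", "soil", "woody")

#: vegetation-type vocabulary (site-level habitat categories)
VT_CATEGORIES = (
    "coniferous_forest",
    "broad_leaved_forest",
    "bush_wood",
    "shrub_grass",
    "grass",
    "meadow",
)


class FormatError(ValueError):
    """A file violates the expected format (e.g. non-binary incidence cell)."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a data-model invariant."""


@dataclass
class OccurrenceMatrix:
    """Binary site x species incidence, sites sorted by ascending elevation.

    Parameters
    ----------
    sites
        Site identifiers, one per row, in ascending elevation order.
    species
        Species identifiers, one per column.
    incidence
        Integer array of shape ``(n_sites, n_species)`` with entries in {0, 1}.
    elevations
        Site elevations (m a.s.l.) aligned with ``sites``.
    families
        Optional per-species family labels aligned with ``species``.
    """

    sites: list[str]
    species: list[str]
    incidence: np.ndarray
    elevations: np.ndarray
    families: list[str] | None = None

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        self.elevations = np.asarray(self.elevations, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        inc = self.incidence
        if inc.ndim != 2:
            raise ValidationError("incidence must be a 2-D matrix")
        if inc.shape != (len(self.sites), len(self.species)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        if inc.size and not np.isin(inc, (0, 1)).all():
            bad = inc[~np.isin(inc, (0, 1))].flat[0]
            raise FormatError(f"incidence entries must be 0/1; found {bad!r}")
        if len(set(self.sites)) != len(self.sites):
            raise ValidationError("duplicate site IDs")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species IDs")
        if len(self.elevations) != len(self.sites):
            raise ValidationError("one elevation required per site")
        if np.any(np.diff(self.elevations) < 0):
            raise ValidationError("rows must be in ascending elevation order")
        if self.families is not None and len(self.families) != len(self.species):
            raise ValidationError("one family label required per species")
        empty = np.flatnonzero(inc.sum(axis=0) == 0)
        if empty.size:
            names = [self.species[i] for i in empty[:5]]
            raise ValidationError(
                f"{empty.size} species have zero presences (e.g. {names}); "
                "drop them before analysis"
            )
        zero_sites = np.flatnonzero(inc.sum(axis=1) == 0)
        if zero_sites.size:
            log.warning(
                "%d site(s) have no species: %s",
                zero_sites.size,
                [self.sites[i] for i in zero_sites[:5]],
            )

    # -- basic views -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def site_richness(self) -> np.ndarray:
        """Per-site species richness S_j (row sums)."""
        return self.incidence.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.incidence, index=self.sites, columns=self.species)
        df.insert(0, "elevation", self.elevations)
        df.index.name = "site"
        return df


@dataclass
class Summary:
    """Headline diversity numbers for an occurrence matrix."""

    gamma: int
    richness: np.ndarray
    alpha_bar: float
    max_richness: int
    range_extents: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "alpha_bar": self.alpha_bar,
            "max_richness": self.max_richness,
            "richness": [int(s) for s in self.richness],
            "range_extents": self.range_extents,
        }


def read_occurrence(path, *, drop_empty_species: bool = True) -> OccurrenceMatrix:
    """Read a site x species incidence CSV.

    Expected layout: first column site IDs, an ``elevation`` column, and one
    0/1 column per species.  Rows may appear in any order; they are sorted by
    ascending elevation (ties broken by site ID) before validation.

    Species columns with no presences are dropped with a warning when
    ``drop_empty_species`` is true, otherwise rejected.
    """
    df = pd.read_csv(path, index_col=0)
    if "elevation" not in df.columns:
        raise ValidationError(f"{path}: missing required 'elevation' column")
    elev = pd.to_numeric(df.pop("elevation"), errors="coerce")
    if elev.isna().any():
        raise ValidationError(f"{path}: non-numeric elevation values")
    order = sorted(range(len(df)), key=lambda i: (elev.iloc[i], str(df.index[i])))
    df = df.iloc[order]
    elev = elev.iloc[order]

    vals = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(vals.ravel()), errors="coerce").to_numpy()
    if np.isnan(numeric).any():
        raise FormatError(f"{path}: non-numeric incidence cell")
    inc = numeric.reshape(vals.shape)
    if not np.isin(inc, (0, 1)).all():
        bad = inc[~np.isin(inc, (0, 1))].flat[0]
        raise FormatError(f"{path}: incidence cells must be 0/1, found {bad!r}")
    inc = inc.astype(np.int8)

    keep = inc.sum(axis=0) > 0
    if not keep.all():
        dropped = list(df.columns[~keep])
        if drop_empty_species:
            log.warning("dropping %d zero-presence species: %s", len(dropped), dropped[:5])
            inc = inc[:, keep]
            df = df.loc[:, keep]
        # else: OccurrenceMatrix.validate raises
    return OccurrenceMatrix(
        sites=[str(s) for s in df.index],
        species=[str(c) for c in df.columns],
        incidence=inc,
        elevations=elev.to_numpy(),
    )


def write_occurrence(occ: OccurrenceMatrix, path) -> None:
    occ.to_frame().to_csv(path)


def read_covariates(path, *, elevation_domain: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read the per-site covariate table.

    Required columns: ``site``, ``elevation``, ``vt_count``, ``ct_count``,
    ``sr``, ``ap``, ``at``, ``ws``.  Returns a DataFrame indexed by site and
    sorted by elevation (ties by site ID).
    """
    df = pd.read_csv(path)
    required = {"site", "elevation", "vt_count", "ct_count", "sr", "ap", "at", "ws"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing covariate columns {sorted(missing)}")
    if df["site"].duplicated().any():
        raise ValidationError(f"{path}: duplicate site IDs")
    df = df.sort_values(["elevation", "site"], kind="stable").set_index("site")
    if (df["vt_count"] < 0).any() or (df["ct_count"] < 0).any():
        raise ValidationError(f"{path}: negative VT/CT counts")
    if (df["ct_count"] > len(CT_CATEGORIES)).any():
        raise ValidationError(f"{path}: ct_count exceeds {len(CT_CATEGORIES)} categories")
    if (df["vt_count"] > len(VT_CATEGORIES)).any():
        raise ValidationError(f"{path}: vt_count exceeds {len(VT_CATEGORIES)} categories")
    if elevation_domain is not None:
        lo, hi = elevation_domain
        if ((df["elevation"] < lo) | (df["elevation"] > hi)).any():
            raise ValidationError(f"{path}: elevation outside declared domain [{lo}, {hi}]")
    return df


def read_specimens(path, occ: OccurrenceMatrix | None = None) -> pd.DataFrame:
    """Read specimen-level records (site, species, family, community_type)."""
    df = pd.read_csv(path)
    required = {"site", "species", "family", "community_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing specimen columns {sorted(missing)}")
    bad_ct = set(df["community_type"]) - set(CT_CATEGORIES)
    if bad_ct:
        raise ValidationError(f"{path}: unknown community types {sorted(bad_ct)}")
    if occ is not None:
        site_ix = {s: i for i, s in enumerate(occ.sites)}
        sp_ix = {s: j for j, s in enumerate(occ.species)}
        for _, row in df.iterrows():
            i = site_ix.get(str(row["site"]))
            j = sp_ix.get(str(row["species"]))
            if i is None or j is None or occ.incidence[i, j] != 1:
                raise ValidationError(
                    f"{path}: specimen ({row['site']}, {row['species']}) not in occurrence matrix"
                )
    return df


def summarize(occ: OccurrenceMatrix) -> Summary:
    """Compute gamma, per-site richness, mean alpha, max richness, range extents.

    Range extent per species is the interpolated elevational extent in sites:
    highest occupied position - lowest occupied position + 1.
    """
    if occ.incidence.size == 0:
        raise ValidationError("empty occurrence matrix")
    richness = occ.site_richness()
    extents: dict[str, int] = {}
    for j, sp in enumerate(occ.species):
        pos = np.flatnonzero(occ.incidence[:, j])
        extents[sp] = int(pos[-1] - pos[0] + 1)
    return Summary(
        gamma=int(occ.n_species),
        richness=richness,
        alpha_bar=float(richness.mean()),
        max_richness=int(richness.max()),
        range_extents=extents,
    )


def write_summary(summary: Summary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
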