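"""Community structure from gridded cover surveys.

Both faces of each settlement tile are photographed under a 25-square grid
(5 x 5 cm squares); occupied squares per species give percent cover.  From
those counts this module derives relative covers, tile biomass via
species-specific dry-weight densities, the three-way community
classification (calcifying- / mixed- / fleshy-algae-dominated), richness
trajectories, Bray-Curtis dissimilarities, and the PERMANOVA used to test
that the community types are compositionally distinct.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "SpeciesRecord",
    "TileObservation",
    "cover_from_grid",
    "biomass_estimate",
    "classify_community",
    "richness_change",
    "standardize_to_t0",
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "GRID_SQUARES",
    "TILE_SIDE_AREA_CM2",
    "DOMINANCE_THRESHOLD",
]

GRID_SQUARES = 25
TILE_SIDE_AREA_CM2 = 225.0  # 15 x 15 cm per side
PATCH_AREA_CM2 = 25.0  # dry-weight reference patch (5 x 5 cm)
DOMINANCE_THRESHOLD = 0.6

COMMUNITY_LABELS = ("calcifying", "mixed", "fleshy")


class CommunityError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesRecord:
    """Registry entry: taxon group, functional roles, dry weight density.

    ``dry_weight_density`` is g DW per 25 cm2 patch (mean of triplicate
    collections, dried 48 h at 50 C).  Roles are a subset of
    {calcifier, primary_producer, filter_feeder}.
    """

    species_id: str
    taxon_group: str
    roles: frozenset = frozenset()
    dry_weight_density: float = 0.0

    def __post_init__(self):
        if self.dry_weight_density < 0:
            raise CommunityError("dry_weight_density must be >= 0")
        bad = set(self.roles) - {"calcifier", "primary_producer", "filter_feeder"}
        if bad:
            raise CommunityError(f"unknown roles {sorted(bad)}")

    @property
    def is_alga(self) -> bool:
        return self.taxon_group in {
            "Chlorophyta", "Phaeophyceae", "Rhodophyta", "Ochrophyta", "Turf"
        }


@dataclass
class TileObservation:
    """Per-tile, per-side, per-time-point grid counts.

    ``squares_occupied`` maps species_id -> occupied squares out of 25.
    """

    tile_id: str
    side: str  # front | back
    time_point: str
    squares_occupied: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("front", "back"):
            raise CommunityError(f"side must be front/back, got {self.side!r}")
        for sp, n in self.squares_occupied.items():
            if not 0 <= n <= GRID_SQUARES:
                raise CommunityError(
                    f"{sp}: count {n} outside [0, {GRID_SQUARES}]"
                )


def cover_from_grid(obs: TileObservation) -> dict:
    """Per-species percent cover from grid counts, rescaled if layered.

    Raw cover is count/25 * 100.  Where layering pushes the per-side total
    above 100%, covers are rescaled proportionally to sum to 100 (relative
    percentages); otherwise they are left as-is.
    """
    raw = {sp: n / GRID_SQUARES * 100.0 for sp, n in obs.squares_occupied.items()}
    total = sum(raw.values())
    if total > 100.0:
        return {sp: v * 100.0 / total for sp, v in raw.items()}
    return raw


def biomass_estimate(
    covers_by_side: dict,
    registry: dict,
    tile_area_cm2: float = TILE_SIDE_AREA_CM2,
) -> float:
    """Tile biomass in g dry weight from percent covers and the registry.

    ``covers_by_side`` maps side -> {species: percent cover}.  Each species
    contributes cover/100 * (tile_area / patch_area) * dry_weight_density,
    summed over both sides (back-side fauna carry mass too).
    """
    missing = sorted(
        {sp for covers in covers_by_side.values() for sp in covers}
        - set(registry)
    )
    if missing:
        raise CommunityError(f"species missing from registry: {missing}")
    patches_per_side = tile_area_cm2 / PATCH_AREA_CM2
    total = 0.0
    for covers in covers_by_side.values():
        for sp, cover in covers.items():
            total += cover / 100.0 * patches_per_side * registry[sp].dry_weight_density
    return total


def classify_community(
    front_covers: dict,
    registry: dict,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> tuple[str, list]:
    """Classify a tile from its front-side algal covers.

    Sums cover of calcifying algae (c) vs fleshy, non-calcifying algae
    including turf (f); label is ``calcifying`` when c >= threshold * (c+f),
    ``fleshy`` when f >= threshold * (c+f), else ``mixed``.  Returns
    (label, flags).
    """
    c = f = 0.0
    for sp, cover in front_covers.items():
        rec = registry.get(sp)
        if rec is None or not rec.is_alga:
            continue
        if "calcifier" in rec.roles:
            c += cover
        else:
            f += cover
    if c + f == 0:
        return "mixed", ["no_algae"]
    share = c / (c + f)
    if share >= dominance_threshold:
        return "calcifying", []
    if 1.0 - share >= dominance_threshold:
        return "fleshy", []
    return "mixed", []


def richness_change(obs_t: list, obs_t0: list) -> int:
    """Species lost between t0 and t, both tile sides pooled.

    Presence = cover > 0 on either side.  A species present at t but absent
    at t0 triggers a ``colonization_detected`` warning (the study observed
    no colonisation; such a record is a data problem, not a code one).
    """
    present = lambda obs_list: {
        sp for o in obs_list for sp, n in o.squares_occupied.items() if n > 0
    }
    s0, st = present(obs_t0), present(obs_t)
    gained = st - s0
    if gained:
        warnings.warn(
            f"colonization_detected: {sorted(gained)} present at t but not t0",
            stacklevel=2,
        )
    return len(s0) - len(st)


def standardize_to_t0(values, t0_value: float, mode: str = "ratio"):
    """Standardise a trajectory relative to its initial measurement.

    ``ratio`` divides by the t0 value (biomass: strictly positive ratios;
    process rates: sign-preserving, may be negative).  ``difference``
    subtracts it, for t0 = 0 cases.
    """
    values = np.asarray(values, dtype=float)
    if mode == "ratio":
        if t0_value == 0:
            raise CommunityError(
                "t0 value is 0: ratio standardisation undefined; use mode='difference'"
            )
        return values / t0_value
    if mode == "difference":
        return values - t0_value
    raise CommunityError(f"unknown standardisation mode {mode!r}")


def bray_curtis(matrix) -> tuple[np.ndarray, list]:
    """Pairwise Bray-Curtis dissimilarity between rows of a cover matrix.

    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1].  A pair of all-zero
    rows has an undefined quotient; it is set to 0 (identical emptiness)
    and flagged.  Returns (square matrix, flags).
    """
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise CommunityError("covers must be non-negative")
    n = x.shape[0]
    flags = []
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    d = np.zeros((n, n))
    nonzero = x.sum(axis=1) > 0
    if nonzero.sum() >= 2:
        sub = squareform(pdist(x[nonzero], metric="braycurtis"))
        idx = np.where(nonzero)[0]
        d[np.ix_(idx, idx)] = sub
    for i in zero_rows:
        for j in range(n):
            if j != i:
                d[i, j] = d[j, i] = 0.0 if x[j].sum() == 0 else 1.0
        for j in zero_rows:
            if i < j:
                flags.append(f"all_zero_pair:{i},{j}")
    return d, flags


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    method: str = "permutation"

    def summary(self) -> str:
        return (
            f"PERMANOVA ({self.method}, {self.n_permutations} permutations): "
            f"F = {self.pseudo_f:.3f}, R2 = {self.r_squared:.3f}, "
            f"p = {self.p_value:.4f}"
        )


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared dissimilarities and group labels."""
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    a = len(groups)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    dissimilarity: np.ndarray,
    labels,
    n_permutations: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on a dissimilarity matrix.

    pseudo-F compares among- to within-group sums of squared
    dissimilarities; the p-value is (1 + #{permuted F >= observed}) /
    (1 + n_permutations) under random label permutation, or exact over all
    distinct label orderings when ``exhaustive`` is set.
    """
    d = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise CommunityError("need >= 2 groups")
    if np.any(counts < 2):
        raise CommunityError("every group needs >= 2 members")
    d2 = d**2
    f_obs, r2 = _permanova_f(d2, labels)

    if exhaustive:
        perms = set(itertools.permutations(labels.tolist()))
        f_perm = np.array([_permanova_f(d2, np.asarray(p)) [0] for p in perms])
        # the identity ordering is part of the enumeration, so p is exact
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return PermanovaResult(f_obs, r2, p, len(perms), method="exhaustive")

    rng = np.random.default_rng(seed)
    count_ge = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _permanova_f(d2, lab)[0] >= f_obs - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations)
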