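"""Restoration prioritization: human disturbance rate, PCA species priority
rank, the species-wise grid indicator algorithm, and the 8 restoration
categories.

A (species, grid) pair is *restoration prioritized* when no negative
indicator vetoes it, the grid is suitable for the species, and at least one
further positive indicator supports it:

negative (veto) indicators
    n1: mangrove cover at the recent date > 80%  (already densely forested)
    n2: human disturbance rate HDR > 75
    n3: suitability class "not" or "slightly" suitable
    n4: natural accretion rate > 75%  (regenerating on its own)
positive indicators
    p1: species restoration-priority rank in the top half
    p2: species participates in a significant niche-overlap pair
        (p < 0.05) and the grid lies in the pair's joint suitable area
    p3: suitability class "highly" or "moderately"
    p4: degradation rate > 75%

All threshold comparisons are strict and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .ensemble import SuitabilityClassMap
from .species import IUCN_SCORES, UnknownSpeciesError

NEGATIVE_FLAGS = ("n1", "n2", "n3", "n4")
POSITIVE_FLAGS = ("p1", "p2", "p3", "p4")

#: Restoration category -> species codes (from the study's category design:
#: 1-6 are family/status groupings, 7 is the mixed Avicennia+Rhizophoraceae
#: community, 8 the common pioneer assemblage). A species may belong to
#: several categories.
CATEGORY_SPECIES: dict[int, frozenset[str]] = {
    1: frozenset({"AR", "AC"}),
    2: frozenset({"AA", "AM", "AO"}),
    3: frozenset({"BG", "CD", "CT", "RM"}),
    4: frozenset({"HF", "KC", "EA"}),
    5: frozenset({"NF", "PP"}),
    6: frozenset({"SA", "XG", "XM"}),
    7: frozenset({"AA", "AM", "AO", "BG", "CD", "CT", "RM"}),
    8: frozenset({"AR", "AC", "AA", "AM", "AO"}),
}


@dataclass(frozen=True)
class IndicatorThresholds:
    """Indicator cut values (all strict inequalities)."""

    cover_max: float = 80.0
    hdr_max: float = 75.0
    accretion_max: float = 75.0
    degradation_min: float = 75.0
    overlap_alpha: float = 0.05


def human_disturbance_rate(components: pd.DataFrame) -> np.ndarray:
    """Per-grid composite human disturbance rate, 0-100.

    Components are built-up % (BR), population count (NP), road density in
    km per cell (RD), and agriculture % (AR). Each is min-max normalized to
    [0, 1] over the grid population — percentages by /100, counts and
    densities by their landscape maxima — and HDR is 100 times the mean of
    the four normalized components.
    """
    req = ("built_pct", "population", "road_density", "agriculture_pct")
    missing = [c for c in req if c not in components.columns]
    if missing:
        raise ValueError(f"missing disturbance component(s): {missing}")
    comp = components[list(req)].to_numpy(dtype=float)
    if np.any(~np.isfinite(comp)):
        raise ValueError("disturbance components must be finite")
    if np.any(comp < 0):
        raise ValueError("disturbance components must be non-negative")
    if comp[:, 0].max() > 100 or comp[:, 3].max() > 100:
        raise ValueError("percentage components must lie in [0, 100]")
    norm = np.empty_like(comp)
    norm[:, 0] = comp[:, 0] / 100.0
    norm[:, 3] = comp[:, 3] / 100.0
    for j in (1, 2):
        m = comp[:, j].max()
        norm[:, j] = comp[:, j] / m if m > 0 else 0.0
    return 100.0 * norm.mean(axis=1)


def species_priority_rank(attrs: pd.DataFrame) -> pd.DataFrame:
    """PCA-based restoration priority rank (1 = highest priority).

    ``attrs`` has one row per species (index = code) with columns
    niche_breadth, potential_distribution, degradation_exposure and
    conservation_status_score. Columns are z-standardized, constant
    columns dropped with a warning, and the priority score is the
    projection onto the first principal component, signed so that a higher
    conservation-status score maps to a higher priority score. Ranks are
    assigned by descending score; ties break by status then code.
    """
    import warnings

    req = (
        "niche_breadth",
        "potential_distribution",
        "degradation_exposure",
        "conservation_status_score",
    )
    missing = [c for c in req if c not in attrs.columns]
    if missing:
        raise ValueError(f"missing attribute column(s): {missing}")
    if len(attrs) < 2:
        raise ValueError("need at least 2 species to rank")
    X = attrs[list(req)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("attributes must be finite")
    sd = X.std(axis=0)
    use = sd > 1e-12
    if not use.all():
        dropped = [c for c, u in zip(req, use) if not u]
        warnings.warn(f"constant attribute(s) dropped: {dropped}", stacklevel=2)
    if use.sum() == 0:
        raise ValueError("all attributes constant; cannot rank")
    Z = (X[:, use] - X[:, use].mean(axis=0)) / sd[use]
    score = PCA(n_components=1).fit_transform(Z).ravel()
    status = attrs["conservation_status_score"].to_numpy(dtype=float)
    corr = np.corrcoef(score, status)[0, 1] if status.std() > 0 else 1.0
    if np.isnan(corr):
        corr = 1.0
    if corr < 0:
        score = -score
    out = pd.DataFrame(
        {
            "priority_score": score,
            # round for ordering so SVD float noise cannot defeat the tie-break
            "_score_key": np.round(score, 9),
            "_status": status,
            "_code": attrs.index,
        },
        index=attrs.index,
    )
    order = out.sort_values(
        by=["_score_key", "_status", "_code"],
        ascending=[False, False, True],
        kind="stable",
    )
    out["priority_rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return out[["priority_score", "priority_rank"]]


def compute_species_attributes(
    surfaces,
    class_maps: dict[str, SuitabilityClassMap],
    grid_stats: pd.DataFrame,
    occupied_cells: dict[str, np.ndarray],
    status: dict[str, str],
) -> pd.DataFrame:
    """Assemble the four priority attributes per species.

    niche_breadth is Levins' B on the normalized suitability surface,
    rescaled to [0, 1] as (B - 1)/(n_cells - 1); potential_distribution is
    the fraction of grids moderately-or-highly suitable; degradation
    exposure is the mean degradation rate over the species' occupied
    grids; conservation status maps LC/NT/EN to 1/2/3.
    """
    from .overlap import normalize_surface

    rows = {}
    degr = grid_stats.set_index("cell_id")["degradation_rate_pct"]
    for code, surf in surfaces.items():
        p = normalize_surface(surf)
        b = 1.0 / np.sum(p * p)
        occ = np.asarray(occupied_cells[code])
        rows[code] = {
            "niche_breadth": (b - 1.0) / (len(p) - 1.0),
            "potential_distribution": float(class_maps[code].is_suitable().mean()),
            "degradation_exposure": float(degr.loc[occ].mean()) if len(occ) else 0.0,
            "conservation_status_score": IUCN_SCORES[status[code]],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def flag_grid(
    cover_pct: float,
    hdr: float,
    suit_class: int,
    accretion_pct: float,
    degradation_pct: float,
    overlap_significant: bool,
    rank_top_half: bool,
    thresholds: IndicatorThresholds = IndicatorThresholds(),
) -> dict[str, bool]:
    """Evaluate the 4 negative and 4 positive indicators for one (species, grid).

    ``suit_class`` is the integer suitability class (0=not .. 3=highly);
    ``overlap_significant`` states whether the grid lies in a significant
    niche-overlap pair's joint suitable area for this species.
    """
    for name, v in (
        ("cover_pct", cover_pct),
        ("hdr", hdr),
        ("accretion_pct", accretion_pct),
        ("degradation_pct", degradation_pct),
    ):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing or non-finite input: {name}")
    t = thresholds
    return {
        "n1": cover_pct > t.cover_max,
        "n2": hdr > t.hdr_max,
        "n3": suit_class <= 1,
        "n4": accretion_pct > t.accretion_max,
        "p1": bool(rank_top_half),
        "p2": bool(overlap_significant),
        "p3": suit_class >= 2,
        "p4": degradation_pct > t.degradation_min,
    }


def combine_flags(flags: dict[str, bool], rule: str = "default", min_positives: int = 2) -> bool:
    """Combination rule mapping indicator flags to the prioritized decision.

    ``default``: no negative flag AND p3 (suitability) AND at least one of
    {p1, p2, p4}. ``count``: no negative flag AND >= min_positives positive
    flags. ``veto-only``: no negative flag AND any positive flag.
    """
    if any(flags[n] for n in NEGATIVE_FLAGS):
        return False
    if rule == "default":
        return flags["p3"] and (flags["p1"] or flags["p2"] or flags["p4"])
    if rule == "count":
        return sum(flags[p] for p in POSITIVE_FLAGS) >= min_positives
    if rule == "veto-only":
        return any(flags[p] for p in POSITIVE_FLAGS)
    raise ValueError(f"unknown combination rule {rule!r}")


@dataclass
class PrioritizationInputs:
    """Everything the per-(species, grid) algorithm consumes."""

    grid_stats: pd.DataFrame  # cell_id, cover/degradation/accretion columns
    hdr: np.ndarray  # per cell
    class_maps: dict[str, SuitabilityClassMap]
    ranks: pd.DataFrame  # priority_rank per species
    overlap_pvalues: pd.DataFrame | None = None  # species x species, p-values
    thresholds: IndicatorThresholds = dc_field(default_factory=IndicatorThresholds)
    rule: str = "default"


def _significant_overlap_cells(
    code: str, inputs: PrioritizationInputs
) -> np.ndarray:
    """Boolean per-cell mask of p2 for one species: the union over partners
    with a significant pair of the two species' joint suitable area."""
    cm = inputs.class_maps[code]
    mask = np.zeros(cm.grid.n_cells, dtype=bool)
    pv = inputs.overlap_pvalues
    if pv is None or code not in pv.index:
        return mask
    mine = cm.is_suitable()
    for other in pv.columns:
        if other == code or other not in inputs.class_maps:
            continue
        p = pv.loc[code, other]
        if np.isfinite(p) and p < inputs.thresholds.overlap_alpha:
            mask |= mine & inputs.class_maps[other].is_suitable()
    return mask


def prioritize(inputs: PrioritizationInputs) -> pd.DataFrame:
    """Apply the indicator algorithm to every (species, grid).

    Returns a long table with one row per (species, grid): the 8 indicator
    flags, the prioritized decision, and the restoration category of the
    grid (see :func:`grid_category`).
    """
    stats = inputs.grid_stats.set_index("cell_id")
    n_species = len(inputs.ranks)
    half = (n_species + 1) // 2
    frames = []
    for code, cm in inputs.class_maps.items():
        cells = stats.index.to_numpy()
        cover = stats["mangrove_cover_pct_t2"].to_numpy(float)
        degr = stats["degradation_rate_pct"].to_numpy(float)
        accr = stats["accretion_rate_pct"].to_numpy(float)
        hdr = np.asarray(inputs.hdr, dtype=float)
        cls = cm.classes[cells]
        t = inputs.thresholds
        top_half = int(inputs.ranks.loc[code, "priority_rank"]) <= half
        p2_mask = _significant_overlap_cells(code, inputs)[cells]
        df = pd.DataFrame(
            {
                "species_code": code,
                "cell_id": cells,
                "n1": cover > t.cover_max,
                "n2": hdr[cells] > t.hdr_max,
                "n3": cls <= 1,
                "n4": accr > t.accretion_max,
                "p1": top_half,
                "p2": p2_mask,
                "p3": cls >= 2,
                "p4": degr > t.degradation_min,
            }
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    neg = table[list(NEGATIVE_FLAGS)].any(axis=1)
    if inputs.rule == "default":
        pos = table["p3"] & (table["p1"] | table["p2"] | table["p4"])
    elif inputs.rule == "count":
        pos = table[list(POSITIVE_FLAGS)].sum(axis=1) >= 2
    elif inputs.rule == "veto-only":
        pos = table[list(POSITIVE_FLAGS)].any(axis=1)
    else:
        raise ValueError(f"unknown combination rule {inputs.rule!r}")
    table["prioritized"] = ~neg & pos
    return table


def assign_category(species_code: str) -> int:
    """Lowest-numbered restoration category containing the species."""
    for cat in sorted(CATEGORY_SPECIES):
        if species_code in CATEGORY_SPECIES[cat]:
            return cat
    raise UnknownSpeciesError(f"species code {species_code!r} has no restoration category")


def grid_category(prioritized_species: set[str]) -> int | None:
    """Category of a grid given the species prioritized in it.

    The lowest-numbered category whose *full* species set is prioritized in
    the grid wins; otherwise the single-species category of the
    lowest-category member. Species outside every category (LR has no
    category in the study's grouping) are ignored; None when no
    categorized species is prioritized.
    """
    if not prioritized_species:
        return None
    for cat in sorted(CATEGORY_SPECIES):
        if CATEGORY_SPECIES[cat] <= prioritized_species:
            return cat
    cats = [
        assign_category(c)
        for c in prioritized_species
        if any(c in members for members in CATEGORY_SPECIES.values())
    ]
    return min(cats) if cats else None


def summarize_prioritization(table: pd.DataFrame, cell_area: float = 1.0) -> pd.DataFrame:
    """Per-category prioritized grid counts and areas (km^2).

    Grid category follows :func:`grid_category` on the set of species
    prioritized in each grid.
    """
    chosen = table[table["prioritized"]]
    by_grid = chosen.groupby("cell_id")["species_code"].agg(set)
    cats = by_grid.map(grid_category)
    counts = cats.value_counts().sort_index()
    out = pd.DataFrame(
        {
            "category": counts.index.astype(int),
            "n_grids": counts.to_numpy(),
            "area_km2": counts.to_numpy() * cell_area,
        }
    ).reset_index(drop=True)
    total = pd.DataFrame(
        {
            "category": ["all"],
            "n_grids": [len(by_grid)],
            "area_km2": [len(by_grid) * cell_area],
        }
    )
    out["category"] = out["category"].astype(object)
    return pd.concat([out, total], ignore_index=True)
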