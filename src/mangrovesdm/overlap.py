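"""Niche-overlap statistics and the grid-level spatial overlap layer.

Overlap between two species is measured on their suitability surfaces
normalized to probability distributions over grid cells:

- Schoener's D = 1 - 0.5 * sum_i |p1_i - p2_i|
- Hellinger-based I = 1 - 0.5 * sum_i (sqrt(p1_i) - sqrt(p2_i))^2

Both lie in [0, 1], equal 1 iff the distributions are identical, and are
invariant to adding zero-probability cells. Significance is assessed with
a niche-identity permutation test: occurrence labels of the two species
are pooled and re-assigned at random (preserving counts), a fast surrogate
model is refit per pseudo-species, and the observed D is compared with the
permutation null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import EnvStack, GridMismatchError
from .ensemble import LearnerSpec, SuitabilityClassMap, SuitabilitySurface, fit_learner, generate_pseudo_absences


def normalize_surface(surface) -> np.ndarray:
    """Suitability surface -> probability distribution over cells."""
    vals = surface.values if isinstance(surface, SuitabilitySurface) else np.asarray(surface, float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero surface")
    return vals / total


def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("input is not a normalized distribution")
    return p


def schoener_D(p1, p2) -> float:
    p1, p2 = _check_distribution(p1), _check_distribution(p2)
    if p1.shape != p2.shape:
        raise ValueError("distributions must share one support")
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_I(p1, p2) -> float:
    p1, p2 = _check_distribution(p1), _check_distribution(p2)
    if p1.shape != p2.shape:
        raise ValueError("distributions must share one support")
    return float(1.0 - 0.5 * np.sum((np.sqrt(p1) - np.sqrt(p2)) ** 2))


def overlap_matrix(surfaces: dict[str, SuitabilitySurface]) -> pd.DataFrame:
    """Square table with Schoener's D in the upper triangle, Hellinger I in
    the lower triangle, and 1.0 on the diagonal."""
    codes = sorted(surfaces)
    probs = {c: normalize_surface(surfaces[c]) for c in codes}
    out = pd.DataFrame(np.eye(len(codes)), index=codes, columns=codes)
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            out.loc[a, b] = schoener_D(probs[a], probs[b])
            out.loc[b, a] = hellinger_I(probs[a], probs[b])
    return out


def _surrogate_surface(stack: EnvStack, cells: np.ndarray, spec: LearnerSpec, seed: int) -> np.ndarray:
    Xall = stack.as_matrix()
    if spec.name == "SRE":
        model = fit_learner(spec, Xall[cells], np.ones(len(cells), int))
        vals = model.score_cells(Xall)
    else:
        bg = generate_pseudo_absences(stack.grid, cells, len(cells), seed=seed)
        X = np.vstack([Xall[cells], Xall[bg]])
        y = np.concatenate([np.ones(len(cells), int), np.zeros(len(bg), int)])
        model = fit_learner(spec, X, y)
        vals = model.score_cells(Xall)
    if vals.sum() <= 0:  # envelope can be empty off-sample; fall back to uniform
        vals = np.ones_like(vals)
    return vals / vals.sum()


def overlap_significance(
    occ_cells_a,
    occ_cells_b,
    stack: EnvStack,
    n_perm: int = 99,
    seed: int = 0,
    surrogate: str = "GLM",
    alternative: str = "less",
) -> tuple[float, float]:
    """Niche-identity permutation test on Schoener's D.

    Occurrence cells of the two species are pooled; each permutation
    re-assigns cells to two pseudo-species preserving the original counts,
    refits the surrogate learner for each, and recomputes D. For the
    one-sided "observed overlap lower than random" alternative,
    p = (1 + #{D_perm <= D_obs}) / (n_perm + 1); ``alternative="two-sided"``
    doubles the smaller tail. Returns (D_observed, p_value).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    a = np.asarray(occ_cells_a)
    b = np.asarray(occ_cells_b)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 occurrences per species")
    spec = LearnerSpec(surrogate, seed=seed)
    rng = np.random.default_rng(seed)

    def d_for(cells_a, cells_b, perm_seed):
        p1 = _surrogate_surface(stack, cells_a, spec, seed=perm_seed)
        p2 = _surrogate_surface(stack, cells_b, spec, seed=perm_seed + 1)
        return schoener_D(p1, p2)

    d_obs = d_for(a, b, perm_seed=int(rng.integers(2**31)))
    pooled = np.concatenate([a, b])
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = d_for(perm[: len(a)], perm[len(a) :], perm_seed=int(rng.integers(2**31)))
    n_le = int(np.sum(null <= d_obs))
    p_less = (1 + n_le) / (n_perm + 1)
    if alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        n_ge = int(np.sum(null >= d_obs))
        p = min(1.0, 2.0 * min(p_less, (1 + n_ge) / (n_perm + 1)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(d_obs), float(p)


def gridwise_overlap_layer(class_maps: dict[str, SuitabilityClassMap]) -> np.ndarray:
    """Per-cell count of species whose class is moderately-or-highly suitable."""
    maps = list(class_maps.values())
    if not maps:
        raise ValueError("no class maps supplied")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.same_geometry(grid):
            raise GridMismatchError("class maps are on different grids")
    count = np.zeros(grid.n_cells, dtype=int)
    for m in maps:
        count += m.is_suitable().astype(int)
    return count
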