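"""Synthetic landscape generator with known ground truth.

Everything downstream of data collection — occurrence cleaning, variable
screening, the 10-learner ensemble, niche overlap and restoration
prioritization — is exercised on landscapes generated here, where the true
suitability function of every species, the true land-cover transition
counts and the disturbance surfaces are all known and recorded.

The generator emulates the study design of a 1-km coastal analysis grid
(default 75x75 = 5625 cells, close to the study system's 5609), a
catalogue of 36 predictors in 6 groups of 6 (topographic, environmental,
water, soil, bioclimatic, disturbance), presence-only species records
drawn from logistic suitability functions, a two-date categorical LULC
pair with a known row-stochastic transition matrix, and per-grid human
disturbance components.

Predictor layers are Gaussian random fields: white noise smoothed with a
Gaussian kernel (the autocorrelation range parameter is the kernel SD in
cells) and standardized per layer. Layers are independent by default; an
optional correlation matrix induces collinearity for screening tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .grids import EnvStack, GridDefinition, LulcMap
from .occurrences import OccurrenceSet
from .species import IUCN_SCORES, load_species_registry

DEFAULT_GROUPS = (
    "topographic",
    "environmental",
    "water",
    "soil",
    "bioclimatic",
    "disturbance",
)

# Within-group predictor names for the default 6-per-group catalogue.
_GROUP_VARIABLES = {
    "topographic": ("elevation", "slope", "curvature", "geomorphology", "twi", "spi"),
    "environmental": (
        "ndvi",
        "flood_inundation",
        "tidal_range",
        "storm_surge",
        "ndmi",
        "erosion_accretion",
    ),
    "water": ("surface_temp", "salinity", "ph", "distance_water", "drainage_density", "mndwi"),
    "soil": ("texture", "salinity_index", "fertility_index", "sediment_yield", "ec", "vssi"),
    "bioclimatic": ("bio1", "bio2", "bio3", "bio4", "bio12", "bio15"),
    "disturbance": (
        "distance_road",
        "road_density",
        "distance_settlement",
        "population_density",
        "distance_cropfield",
        "embankment_density",
    ),
}

LULC_CLASSES = (
    "mangrove",
    "swamp",
    "water",
    "settlement",
    "wetland",
    "sandbar",
    "cropland",
    "other",
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Dimensions and structure of a synthetic landscape.

    ``spatial_autocorrelation_range`` is the Gaussian smoothing kernel SD in
    cells; 0 gives spatially independent white-noise layers.
    """

    n_rows: int = 75
    n_cols: int = 75
    cell_size: float = 1.0
    n_predictors_per_group: int = 6
    groups: tuple[str, ...] = DEFAULT_GROUPS
    spatial_autocorrelation_range: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ConfigurationError("landscape must have at least 4 cells")
        if len(self.groups) != 6:
            raise ConfigurationError("exactly 6 predictor groups are required")
        if self.n_predictors_per_group < 1:
            raise ConfigurationError("need at least one predictor per group")
        if self.spatial_autocorrelation_range < 0:
            raise ConfigurationError("autocorrelation range must be >= 0")

    @property
    def grid(self) -> GridDefinition:
        return GridDefinition(self.n_rows, self.n_cols, self.cell_size)

    def layer_names(self) -> list[str]:
        names = []
        for g in self.groups:
            known = _GROUP_VARIABLES.get(g, ())
            for i in range(self.n_predictors_per_group):
                suffix = known[i] if i < len(known) else f"v{i + 1}"
                names.append(f"{g}_{suffix}")
        return names


@dataclass(frozen=True)
class SpeciesTruth:
    """Generating suitability function for one species.

    Suitability is logistic(intercept + sum coeff_l * layer_l) on the
    standardized predictor layers; ``prevalence`` is the target landscape
    mean suitability (the intercept is shifted at sampling time to hit it).
    """

    species_code: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    prevalence: float = 0.15
    intertidal_position: str = "middle"
    iucn_status: str = "LC"

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ConfigurationError("at least one nonzero coefficient is required")
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if self.iucn_status not in IUCN_SCORES:
            raise ConfigurationError(f"unknown IUCN status {self.iucn_status!r}")

    def linear_predictor(self, stack: EnvStack) -> np.ndarray:
        missing = [n for n in self.coefficients if n not in stack]
        if missing:
            raise KeyError(f"truth references unknown layer(s): {missing}")
        eta = np.full(stack.grid.n_cells, self.intercept)
        for name, coeff in self.coefficients.items():
            eta += coeff * stack[name].ravel()
        return eta

    def suitability(self, stack: EnvStack, calibrate: bool = True) -> np.ndarray:
        """Per-cell true suitability in [0, 1]; optionally prevalence-calibrated."""
        eta = self.linear_predictor(stack)
        if calibrate:
            eta = eta + _prevalence_shift(eta, self.prevalence)
        return special.expit(eta)


def _prevalence_shift(eta: np.ndarray, prevalence: float) -> float:
    """Intercept shift c with mean(expit(eta + c)) == prevalence."""

    def f(c: float) -> float:
        return float(special.expit(eta + c).mean() - prevalence)

    return optimize.brentq(f, -30.0, 30.0)


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Generate the standardized predictor stack for a landscape config.

    Each layer is an independent Gaussian random field (white noise smoothed
    at the configured range, z-scored). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.spatial_autocorrelation_range
    layers: dict[str, np.ndarray] = {}
    for name in config.layer_names():
        white = rng.standard_normal((config.n_rows, config.n_cols))
        fieldv = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect") if sigma > 0 else white
        sd = fieldv.std()
        if sd == 0:  # pathological but possible at tiny grids
            sd = 1.0
        layers[name] = (fieldv - fieldv.mean()) / sd
    return EnvStack(config.grid, layers)


def correlated_copy(stack: EnvStack, base: str, name: str, r: float, seed: int) -> np.ndarray:
    """A layer with population correlation ~r to an existing layer (for collinearity tests)."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(stack[base].shape)
    noise = (noise - noise.mean()) / noise.std()
    lay = r * stack[base] + np.sqrt(max(0.0, 1 - r * r)) * noise
    return (lay - lay.mean()) / lay.std()


def default_species_truths(
    config: LandscapeConfig | None = None,
    coeff_primary: float = 4.0,
    coeff_secondary: float = -2.5,
    prevalence: float = 0.12,
) -> dict[str, SpeciesTruth]:
    """One generating truth per registry species.

    Each species responds strongly (+coeff_primary) to one predictor and
    moderately (coeff_secondary) to a second, both chosen deterministically
    from the catalogue so that species differ in their niches; registry
    metadata (IUCN status, intertidal position) is carried through.
    """
    config = config or LandscapeConfig()
    names = config.layer_names()
    registry = load_species_registry()
    truths: dict[str, SpeciesTruth] = {}
    for i, (code, row) in enumerate(registry.iterrows()):
        primary = names[(2 * i) % len(names)]
        secondary = names[(2 * i + 7) % len(names)]
        truths[code] = SpeciesTruth(
            species_code=code,
            coefficients={primary: coeff_primary, secondary: coeff_secondary},
            prevalence=prevalence,
            intertidal_position=row["intertidal_position"],
            iucn_status=row["iucn_status"],
        )
    return truths


def sample_occurrences(
    stack: EnvStack,
    truth: SpeciesTruth,
    n: int,
    seed: int,
    source: str = "field",
) -> OccurrenceSet:
    """Draw n presence cells without replacement, P(cell) prop. to suitability.

    Points are placed at cell centers, so a species never yields two records
    in one cell (spatial rarefaction is exercised with multi-source merges).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > stack.grid.n_cells:
        raise ValueError(f"cannot draw {n} cells from {stack.grid.n_cells}")
    rng = np.random.default_rng(seed)
    suit = truth.suitability(stack)
    p = suit / suit.sum()
    cells = rng.choice(stack.grid.n_cells, size=n, replace=False, p=p)
    x, y = stack.grid.cell_center(cells)
    df = pd.DataFrame(
        {
            "species_code": truth.species_code,
            "x": x,
            "y": y,
            "source": source,
            "cell_id": cells,
        }
    )
    return OccurrenceSet(df, stack.grid, validate_registry=False)


@dataclass(frozen=True)
class LulcTransitionSpec:
    """Row-stochastic per-cell transition model between the two LULC dates."""

    classes: tuple[str, ...] = LULC_CLASSES
    transition_probabilities: np.ndarray | None = None
    spatial_clumping: float = 4.0
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        P = self.transition_probabilities
        if P is None:
            P = default_transition_matrix(self.classes)
            object.__setattr__(self, "transition_probabilities", P)
        P = np.asarray(P, dtype=float)
        if P.shape != (len(self.classes), len(self.classes)):
            raise ConfigurationError("transition matrix shape must match class list")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition matrix rows must be stochastic")
        object.__setattr__(self, "transition_probabilities", P)
        if self.spatial_clumping < 0:
            raise ConfigurationError("spatial_clumping must be >= 0")


def default_transition_matrix(classes: tuple[str, ...] = LULC_CLASSES) -> np.ndarray:
    """Default 1975->2020-style transition rates for the mangrove row.

    The mangrove row mirrors the study system's accounting: roughly a
    quarter of the initial mangrove area lost, mostly to swamp and open
    water, with small flows to settlement, wetland and sandbar; other
    classes are strongly persistent with a small regeneration flow back
    into mangrove from swamp and water (new char land).
    """
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    P = np.full((k, k), 0.01)
    np.fill_diagonal(P, 0.0)
    for c in classes:
        P[idx[c], idx[c]] = 1.0 - P[idx[c]].sum()
    if "mangrove" in idx:
        m = idx["mangrove"]
        P[m] = 0.0
        flows = {"swamp": 0.137, "water": 0.094, "settlement": 0.007, "wetland": 0.005, "sandbar": 0.002}
        for c, p in flows.items():
            if c in idx:
                P[m, idx[c]] = p
        P[m, m] = 1.0 - P[m].sum()
        for c in ("swamp", "water"):
            if c in idx:
                r = idx[c]
                P[r] = 0.0
                P[r, m] = 0.03
                P[r, r] = 0.97
    return P


@dataclass
class LulcPair:
    """Two-date LULC maps plus the generator's true transition counts."""

    t1: LulcMap
    t2: LulcMap
    true_transitions: np.ndarray = dc_field(repr=False)

    @property
    def classes(self) -> tuple[str, ...]:
        return self.t1.classes


def generate_lulc_pair(
    config: LandscapeConfig, spec: LulcTransitionSpec, seed: int
) -> LulcPair:
    """Clumped t1 map, per-cell stochastic transitions to t2, truth recorded.

    t1 is drawn by smoothing one noise field per class (argmax of weighted
    fields gives contiguous patches); t2 applies the transition matrix
    independently per cell. ``true_transitions[i, j]`` counts cells labelled
    i at t1 and j at t2 — by construction the exact change matrix.
    """
    rng = np.random.default_rng(seed)
    k = len(spec.classes)
    shape = (config.n_rows, config.n_cols)
    weights = np.asarray(
        spec.class_weights
        if spec.class_weights is not None
        else _default_class_weights(spec.classes),
        dtype=float,
    )
    fields = np.empty((k, *shape))
    for i in range(k):
        white = rng.standard_normal(shape)
        if spec.spatial_clumping > 0:
            white = ndimage.gaussian_filter(white, sigma=spec.spatial_clumping, mode="reflect")
            white = (white - white.mean()) / white.std()
        fields[i] = white + np.log(weights[i])
    t1_codes = np.argmax(fields, axis=0)

    P = spec.transition_probabilities
    cum = np.cumsum(P, axis=1)
    u = rng.random(shape)
    t2_codes = np.empty_like(t1_codes)
    for i in range(k):
        mask = t1_codes == i
        t2_codes[mask] = np.searchsorted(cum[i], u[mask], side="right")
    t2_codes = np.clip(t2_codes, 0, k - 1)

    truth = np.zeros((k, k), dtype=int)
    np.add.at(truth, (t1_codes.ravel(), t2_codes.ravel()), 1)

    grid = config.grid
    return LulcPair(
        t1=LulcMap(grid, spec.classes, t1_codes),
        t2=LulcMap(grid, spec.classes, t2_codes),
        true_transitions=truth,
    )


def _default_class_weights(classes: tuple[str, ...]) -> list[float]:
    # Rough 1975-style class shares: mangrove ~23%, the rest split across
    # water/swamp/cropland with minor settlement/wetland/sandbar cover.
    base = {
        "mangrove": 0.23,
        "swamp": 0.12,
        "water": 0.25,
        "settlement": 0.04,
        "wetland": 0.08,
        "sandbar": 0.03,
        "cropland": 0.18,
        "other": 0.07,
    }
    return [base.get(c, 1.0 / len(classes)) for c in classes]


def generate_disturbance(config: LandscapeConfig, seed: int) -> pd.DataFrame:
    """Per-grid human-disturbance components (built-up %, population, road
    density in km per cell, agriculture %), spatially clumped and mutually
    correlated the way settlement pressure is in a delta landscape."""
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    pressure = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8, mode="reflect")
    pressure = (pressure - pressure.min()) / (pressure.max() - pressure.min() + 1e-12)

    def local(scale: float) -> np.ndarray:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2, mode="reflect")
        noise = (noise - noise.min()) / (noise.max() - noise.min() + 1e-12)
        return np.clip(scale * pressure + (1 - scale) * noise, 0, 1)

    built = 100.0 * local(0.8) ** 2
    agri = 100.0 * local(0.6)
    pop = np.round(5000.0 * local(0.85) ** 2)
    road = 4.0 * local(0.7)
    return pd.DataFrame(
        {
            "cell_id": np.arange(config.grid.n_cells),
            "built_pct": built.ravel(),
            "population": pop.ravel(),
            "road_density": road.ravel(),
            "agriculture_pct": agri.ravel(),
        }
    )


def generate_bioclim_stack(
    config: LandscapeConfig | None = None,
    seed: int = 0,
    noise_sd: float = 0.35,
) -> tuple[EnvStack, list[str]]:
    """A 19-layer bioclim-style stack for PCA screening tests.

    Six independent signal layers (BIO1, BIO2, BIO3, BIO4, BIO12, BIO15 —
    the temperature/precipitation summaries that drive coastal suitability)
    plus 13 noisy copies of them standing in for the redundant remainder
    of the BIO1-BIO19 catalogue. Each copy is its parent plus independent
    noise of sd ``noise_sd`` (re-standardized), giving parent-copy
    correlations near 0.94. Returns (stack, signal layer names);
    ``stack.parents`` maps every layer to its generating signal, the
    oracle for redundancy-removal tests.
    """
    config = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    signal_ids = (1, 2, 3, 4, 12, 15)
    signal_names = [f"bioclimatic_bio{i}" for i in signal_ids]
    other = [i for i in range(1, 20) if i not in signal_ids]

    def rf() -> np.ndarray:
        w = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4, mode="reflect")
        return (w - w.mean()) / w.std()

    signals = {name: rf() for name in signal_names}
    parents = {name: name for name in signal_names}
    layers: dict[str, np.ndarray] = {}
    for j, i in enumerate(other):
        parent = signal_names[j % len(signal_names)]
        mix = signals[parent] + noise_sd * rf()
        name = f"bioclimatic_bio{i}"
        layers[name] = (mix - mix.mean()) / mix.std()
        parents[name] = parent
    ordered: dict[str, np.ndarray] = {}
    for i in range(1, 20):
        name = f"bioclimatic_bio{i}"
        ordered[name] = signals.get(name, layers.get(name))
    stack = EnvStack(config.grid, ordered)
    stack.parents = parents  # oracle metadata for tests
    return stack, signal_names
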