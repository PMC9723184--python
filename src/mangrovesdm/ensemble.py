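"""Ten-learner habitat-suitability ensemble with validation gating.

Per species the workflow is: draw pseudo-absence background cells (1:1 by
default), hold out 20% of the data for extrinsic validation, split the
remaining 80% into 75% train / 25% intrinsic test, fit each learner in the
registry, score it on the intrinsic test set (ROC AUC, TSS and Cohen's
kappa at the max-TSS threshold), admit to the ensemble only learners with
all three scores strictly above the gate (0.75), average the qualifying
suitability surfaces weighted by TSS, discretize the ensemble into four
suitability classes, and validate the ensemble on the extrinsic holdout
with the continuous Boyce index.

Learner registry (scikit-learn estimators behind a uniform scorer):

==========  ========================================================
GLM         logistic-link linear model (effectively unpenalized)
GAM         logistic-link additive model on per-feature B-spline bases
MARS        adaptive piecewise-linear (hinge) basis + L1 logistic
RF          bagged decision-tree ensemble (vote fraction)
GBM         boosted shallow trees
CTA         single classification tree
ANN         one-hidden-layer feed-forward network
FDA         flexible discriminant: LDA on a quadratic basis expansion
MAXENT      maxent-style L1 logistic on linear+quadratic+product features
SRE         surface range envelope: 1 inside the per-predictor
            [q, 1-q] presence quantile box, else 0
==========  ========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from .grids import EnvStack, GridDefinition
from .metrics import EvalScores, boyce_index, evaluate_at_max_tss
from .occurrences import OccurrenceSet

LEARNER_NAMES = ("MAXENT", "GLM", "MARS", "GAM", "RF", "GBM", "CTA", "ANN", "FDA", "SRE")

SUITABILITY_CLASSES = ("not", "slightly", "moderately", "highly")
DEFAULT_CUTPOINTS = (0.25, 0.50, 0.75)


class NoQualifierError(RuntimeError):
    """No learner passed the validation gate for a species."""


class UnknownLearnerError(KeyError):
    """Learner name not in the registry."""


@dataclass(frozen=True)
class LearnerSpec:
    """A registry learner plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise UnknownLearnerError(
                f"unknown learner {self.name!r}; registry: {LEARNER_NAMES}"
            )


@dataclass
class SuitabilitySurface:
    """Continuous per-cell suitability in [0, 1] for one species."""

    grid: GridDefinition
    species_code: str
    values: np.ndarray  # (n_cells,)
    learners: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("surface length must equal the grid cell count")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("suitability values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def as_array(self) -> np.ndarray:
        return self.values.reshape(self.grid.n_rows, self.grid.n_cols)


@dataclass
class SuitabilityClassMap:
    """Four-class discretization of a suitability surface."""

    grid: GridDefinition
    species_code: str
    classes: np.ndarray  # (n_cells,) ints into SUITABILITY_CLASSES
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS

    def labels(self) -> np.ndarray:
        return np.array(SUITABILITY_CLASSES, dtype=object)[self.classes]

    def is_suitable(self) -> np.ndarray:
        """Boolean mask: moderately or highly suitable."""
        return self.classes >= 2


# ---------------------------------------------------------------------------
# learner registry


class _SRE:
    """Percentile envelope: score 1 iff every predictor lies inside the
    per-predictor [q, 1-q] quantile interval of the presences."""

    def __init__(self, q: float = 0.025):
        self.q = q

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SRE":
        pres = X[y == 1]
        if len(pres) == 0:
            raise ValueError("SRE needs at least one presence")
        self.lo_ = np.quantile(pres, self.q, axis=0)
        self.hi_ = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        inside = np.all((X >= self.lo_) & (X <= self.hi_), axis=1).astype(float)
        return np.column_stack([1.0 - inside, inside])


class _HingeBasis:
    """Piecewise-linear hinge expansion max(x-k, 0), max(k-x, 0) at
    per-feature quantile knots; the downstream L1 penalty selects among
    the candidate basis functions (a light-weight adaptive spline)."""

    def __init__(self, quantiles=(0.25, 0.5, 0.75)):
        self.quantiles = quantiles

    def fit(self, X, y=None):
        self.knots_ = np.quantile(X, self.quantiles, axis=0)  # (k, p)
        return self

    def transform(self, X):
        cols = [X]
        for row in self.knots_:
            cols.append(np.maximum(X - row, 0.0))
            cols.append(np.maximum(row - X, 0.0))
        return np.hstack(cols)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"quantiles": self.quantiles}

    def set_params(self, **p):
        self.quantiles = p.get("quantiles", self.quantiles)
        return self


def _build_estimator(spec: LearnerSpec):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    hp = dict(spec.hyperparameters)
    seed = spec.seed
    name = spec.name
    if name == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=hp.get("C", 1e6), max_iter=2000)),
            ]
        )
    if name == "GAM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "spline",
                    SplineTransformer(
                        n_knots=hp.get("n_knots", 4), degree=3, include_bias=False
                    ),
                ),
                ("clf", LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)),
            ]
        )
    if name == "MARS":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("hinge", _HingeBasis(hp.get("quantiles", (0.25, 0.5, 0.75)))),
                (
                    "clf",
                    LogisticRegression(
                        penalty="l1", solver="liblinear", C=hp.get("C", 1.0), max_iter=2000
                    ),
                ),
            ]
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            min_samples_leaf=hp.get("min_samples_leaf", 2),
            random_state=seed,
        )
    if name == "GBM":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 2),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=seed,
        )
    if name == "CTA":
        return DecisionTreeClassifier(
            max_depth=hp.get("max_depth", 6),
            min_samples_leaf=hp.get("min_samples_leaf", 3),
            random_state=seed,
        )
    if name == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=hp.get("hidden_layer_sizes", (8,)),
                        max_iter=hp.get("max_iter", 500),
                        random_state=seed,
                    ),
                ),
            ]
        )
    if name == "FDA":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("basis", PolynomialFeatures(degree=2, include_bias=False)),
                ("clf", LinearDiscriminantAnalysis()),
            ]
        )
    if name == "MAXENT":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("features", PolynomialFeatures(degree=2, include_bias=False)),
                (
                    "clf",
                    LogisticRegression(
                        penalty="l1", solver="liblinear", C=hp.get("C", 1.0), max_iter=2000
                    ),
                ),
            ]
        )
    if name == "SRE":
        return _SRE(q=hp.get("q", 0.025))
    raise UnknownLearnerError(name)


@dataclass
class FittedLearner:
    """A fitted scorer mapping feature rows to suitability in [0, 1]."""

    spec: LearnerSpec
    _predict: Callable[[np.ndarray], np.ndarray]

    def score_cells(self, X: np.ndarray) -> np.ndarray:
        s = self._predict(np.asarray(X, dtype=float))
        return np.clip(s, 0.0, 1.0)


def fit_learner(spec: LearnerSpec, X_train: np.ndarray, y_train: np.ndarray) -> FittedLearner:
    """Fit one registry learner on a presence(1)/background(0) design."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if spec.name != "SRE" and y_train.min() == y_train.max():
        raise ValueError("training data must contain both classes")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_train, y_train)

    def predict(X: np.ndarray) -> np.ndarray:
        proba = est.predict_proba(X)
        classes = getattr(est, "classes_", np.array([0, 1]))
        col = int(np.where(classes == 1)[0][0]) if len(classes) > 1 else 0
        return proba[:, col]

    return FittedLearner(spec=spec, _predict=predict)


# ---------------------------------------------------------------------------
# sampling, splitting, gating, ensembling


def generate_pseudo_absences(
    grid: GridDefinition, occ_cells, n: int, seed: int
) -> np.ndarray:
    """n uniform-random unoccupied cells (one point per cell), seeded."""
    occupied = np.unique(np.asarray(occ_cells))
    free = np.setdiff1d(np.arange(grid.n_cells), occupied)
    if n > len(free):
        raise ValueError(f"requested {n} background cells but only {len(free)} are unoccupied")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(free, size=n, replace=False))


def _stratified_split(idx: np.ndarray, labels: np.ndarray, frac_test: float, rng) -> tuple[np.ndarray, np.ndarray]:
    test_parts, train_parts = [], []
    for cls in np.unique(labels):
        members = idx[labels[idx] == cls]
        members = rng.permutation(members)
        n_test = int(round(frac_test * len(members)))
        test_parts.append(members[:n_test])
        train_parts.append(members[n_test:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def split_data(
    X: np.ndarray,
    y: np.ndarray,
    extrinsic_frac: float = 0.2,
    intrinsic_test_frac: float = 0.25,
    seed: int = 0,
    max_redraws: int = 10,
):
    """Nested stratified split: 20% extrinsic holdout first, then the
    remaining 80% split 75/25 into train and intrinsic test.

    Returns (train_idx, intrinsic_test_idx, extrinsic_idx), pairwise
    disjoint and exhaustive. Re-draws up to ``max_redraws`` times if any
    partition misses a class, then raises.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if int((y == 1).sum()) < 8:
        raise ValueError("need at least 8 presences to split")
    idx = np.arange(n)
    for attempt in range(max_redraws):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        rest, extrinsic = _stratified_split(idx, y, extrinsic_frac, rng)
        train, intrinsic = _stratified_split(rest, y, intrinsic_test_frac, rng)
        parts = (train, intrinsic, extrinsic)
        if all(len(np.unique(y[p])) == 2 for p in parts):
            return parts
    raise ValueError("could not produce splits containing both classes")


def gate_learners(scores: dict[str, EvalScores], gate: float = 0.75) -> list[str]:
    """Learners whose kappa, TSS and ROC are all strictly above the gate."""
    return [
        name
        for name, s in scores.items()
        if s.kappa > gate and s.tss > gate and s.roc > gate
    ]


def ensemble_weighted_mean(
    surfaces: dict[str, SuitabilitySurface], weights_metric: dict[str, float]
) -> SuitabilitySurface:
    """Per-cell weighted mean of qualifying surfaces, weights normalized to 1."""
    if not surfaces:
        raise NoQualifierError("no qualifying learner surfaces to ensemble")
    names = list(surfaces)
    w = np.array([weights_metric[n] for n in names], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    first = surfaces[names[0]]
    vals = np.zeros_like(first.values)
    for wi, n in zip(w, names):
        vals += wi * surfaces[n].values
    return SuitabilitySurface(
        grid=first.grid,
        species_code=first.species_code,
        values=vals,
        learners=tuple(names),
        weights=tuple(float(x) for x in w),
    )


def classify_suitability(
    surface: SuitabilitySurface, cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS
) -> SuitabilityClassMap:
    """Discretize into not/slightly/moderately/highly suitable.

    Left-closed on upgrade: a value equal to a cutpoint belongs to the
    higher class (0.75 is "highly").
    """
    c1, c2, c3 = cutpoints
    if not (0 < c1 < c2 < c3 < 1):
        raise ValueError("cutpoints must be strictly increasing within (0, 1)")
    classes = np.digitize(surface.values, [c1, c2, c3], right=False)
    return SuitabilityClassMap(
        grid=surface.grid,
        species_code=surface.species_code,
        classes=classes,
        cutpoints=tuple(cutpoints),
    )


# ---------------------------------------------------------------------------
# per-species and full-registry drivers


@dataclass
class SpeciesResult:
    species_code: str
    surface: SuitabilitySurface | None
    class_map: SuitabilityClassMap | None
    learner_scores: dict[str, EvalScores]
    qualifiers: list[str]
    ensemble_scores: EvalScores | None
    boyce: float | None
    fallback_used: bool = False
    n_presences: int = 0


@dataclass
class RunResult:
    """Full-registry run: per-species results, report table, fit ledger."""

    species: dict[str, SpeciesResult]
    report: pd.DataFrame
    n_fits: int
    manifest: dict

    @property
    def surfaces(self) -> dict[str, SuitabilitySurface]:
        return {c: r.surface for c, r in self.species.items() if r.surface is not None}

    @property
    def class_maps(self) -> dict[str, SuitabilityClassMap]:
        return {c: r.class_map for c, r in self.species.items() if r.class_map is not None}


def fit_species(
    stack: EnvStack,
    occ: OccurrenceSet,
    species_code: str,
    learners: tuple[LearnerSpec, ...] | None = None,
    pa_ratio: float = 1.0,
    gate: float = 0.75,
    cutpoints: tuple[float, float, float] = DEFAULT_CUTPOINTS,
    seed: int = 0,
    on_no_qualifier: str = "best",
    predictors: list[str] | None = None,
) -> tuple[SpeciesResult, int]:
    """Fit the learner suite for one species; returns (result, n_fits)."""
    pres_cells = occ.cells_for_species(species_code)
    names = predictors or stack.names
    Xall = stack.as_matrix(names)
    bg_cells = generate_pseudo_absences(
        stack.grid, pres_cells, int(round(pa_ratio * len(pres_cells))), seed=seed
    )
    cells = np.concatenate([pres_cells, bg_cells])
    X = Xall[cells]
    y = np.concatenate([np.ones(len(pres_cells), int), np.zeros(len(bg_cells), int)])
    train, intr, extr = split_data(X, y, seed=seed)

    if learners is None:
        learners = tuple(LearnerSpec(n, seed=seed) for n in LEARNER_NAMES)

    fitted: dict[str, FittedLearner] = {}
    scores: dict[str, EvalScores] = {}
    n_fits = 0
    for spec in learners:
        model = fit_learner(spec, X[train], y[train])
        n_fits += 1
        s_intr = model.score_cells(X[intr])
        scores[spec.name] = evaluate_at_max_tss(s_intr, y[intr])
        fitted[spec.name] = model

    qualifiers = gate_learners(scores, gate=gate)
    fallback = False
    members = qualifiers
    if not members:
        if on_no_qualifier == "error":
            raise NoQualifierError(
                f"species {species_code}: no learner passed the {gate} gate; "
                f"scores: { {k: (round(v.kappa, 3), round(v.tss, 3), round(v.roc, 3)) for k, v in scores.items()} }"
            )
        if on_no_qualifier == "skip":
            res = SpeciesResult(
                species_code, None, None, scores, [], None, None, False, len(pres_cells)
            )
            return res, n_fits
        members = [max(scores, key=lambda k: scores[k].tss)]
        fallback = True

    member_surfaces = {
        name: SuitabilitySurface(
            grid=stack.grid,
            species_code=species_code,
            values=fitted[name].score_cells(Xall),
            learners=(name,),
            weights=(1.0,),
        )
        for name in members
    }
    weights = {name: max(scores[name].tss, 1e-6) for name in members}
    surface = ensemble_weighted_mean(member_surfaces, weights)
    class_map = classify_suitability(surface, cutpoints)

    ens_intr = np.zeros(len(intr))
    for name in members:
        ens_intr += (weights[name] / sum(weights.values())) * fitted[name].score_cells(X[intr])
    ensemble_scores = evaluate_at_max_tss(ens_intr, y[intr])

    extr_pres = extr[y[extr] == 1]
    pres_suit = surface.values[cells[extr_pres]]
    boyce = boyce_index(pres_suit, surface.values) if len(extr_pres) >= 2 else None

    res = SpeciesResult(
        species_code=species_code,
        surface=surface,
        class_map=class_map,
        learner_scores=scores,
        qualifiers=qualifiers,
        ensemble_scores=ensemble_scores,
        boyce=boyce,
        fallback_used=fallback,
        n_presences=len(pres_cells),
    )
    return res, n_fits


def run_all(
    stack: EnvStack,
    occ: OccurrenceSet,
    species_codes: list[str] | None = None,
    learners: tuple[LearnerSpec, ...] | None = None,
    min_presences: int = 10,
    seed: int = 0,
    **species_kw,
) -> RunResult:
    """Fit the full species x learner suite, gate, ensemble and validate.

    Species with fewer than ``min_presences`` presence cells are skipped
    with a warning and recorded in the manifest. The manifest also records
    the total number of intrinsic model fits.
    """
    codes = species_codes or occ.species
    results: dict[str, SpeciesResult] = {}
    skipped: list[str] = []
    n_fits = 0
    for i, code in enumerate(codes):
        pres = occ.cells_for_species(code)
        if len(pres) < min_presences:
            warnings.warn(
                f"species {code}: {len(pres)} presences < minimum {min_presences}; skipped",
                stacklevel=2,
            )
            skipped.append(code)
            continue
        child_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        res, fits = fit_species(
            stack, occ, code, learners=learners, seed=child_seed, **species_kw
        )
        n_fits += fits
        results[code] = res

    rows = []
    for code, r in results.items():
        es = r.ensemble_scores
        rows.append(
            {
                "species_code": code,
                "roc": es.roc if es else np.nan,
                "tss": es.tss if es else np.nan,
                "kappa": es.kappa if es else np.nan,
                "boyce": r.boyce if r.boyce is not None else np.nan,
                "n_presences": r.n_presences,
                "n_qualifiers": len(r.qualifiers),
                "fallback_used": r.fallback_used,
            }
        )
    report = pd.DataFrame(rows)
    manifest = {
        "n_species_requested": len(codes),
        "n_species_modelled": len(results),
        "skipped_species": skipped,
        "n_learners": len(learners) if learners is not None else len(LEARNER_NAMES),
        "n_fits": n_fits,
        "seed": seed,
        "qualifiers": {c: r.qualifiers for c, r in results.items()},
        "fallback_species": [c for c, r in results.items() if r.fallback_used],
    }
    return RunResult(species=results, report=report, n_fits=n_fits, manifest=manifest)
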