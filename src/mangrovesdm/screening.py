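"""Predictor screening: collinearity filtering, PCA reduction of the 19
bioclimatic layers, and linear-SVM "average merit" scoring.

The merit score follows the linear maximum-margin decision function
g(x) = sgn(w'a + b): predictors whose weight magnitude |w_i| is near zero
contribute little to the presence-background separation; |w| is min-max
mapped onto the 1-10 merit scale and merit > 5 marks a predictor as
influential.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .grids import EnvStack
from .occurrences import OccurrenceSet


def collinearity_filter(stack: EnvStack, r_max: float = 0.8) -> list[str]:
    """Greedy removal of collinear layers.

    While any pair of remaining layers has |Pearson r| > r_max, the member
    of the worst (highest |r|) pair with the larger mean absolute
    correlation to all other remaining layers is dropped. Ties are broken
    deterministically by layer name, so the result is independent of input
    layer order. Constant layers are excluded up front with a warning.
    """
    if stack.n_layers < 2:
        raise ValueError("need at least 2 layers")
    if not 0 < r_max < 1:
        raise ValueError("r_max must be in (0, 1)")
    X = stack.as_matrix()
    names = stack.names
    sds = X.std(axis=0)
    keep = []
    for j, name in enumerate(names):
        if sds[j] == 0:
            warnings.warn(f"excluding constant layer {name!r}", stacklevel=2)
        else:
            keep.append(j)
    order = sorted(keep, key=lambda j: names[j])  # name-sorted for determinism
    X = X[:, order]
    active = [names[j] for j in order]
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 0.0)
    absR = np.abs(R)
    alive = list(range(len(active)))
    while True:
        sub = absR[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= r_max:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        pair = sorted((alive[i_loc], alive[j_loc]), key=lambda k: active[k])
        means = {k: absR[k, [a for a in alive if a != k]].mean() for k in pair}
        # drop the pair member more correlated with everything else
        drop = max(pair, key=lambda k: (means[k], active[k]))
        alive.remove(drop)
    return [active[k] for k in alive]


def pca_reduce_bioclim(
    bioclim: EnvStack, k: int = 6, var_target: float = 0.90, distinct_r: float = 0.8
) -> list[str]:
    """Select k bioclimatic layers by PCA loading.

    PCA is run on the standardized layers; variables are ranked by their
    maximum absolute loading across the leading components that together
    explain at least ``var_target`` of the variance, and the top-k
    *distinct* variables are returned (order of decreasing loading).
    Distinct means mutually non-redundant: a candidate with
    |r| > ``distinct_r`` to an already-selected variable is skipped, so
    the selection returns one representative per independent climate axis
    rather than several near-copies of the strongest axis.
    """
    if k > bioclim.n_layers:
        raise ValueError(f"k={k} exceeds the {bioclim.n_layers} available layers")
    X = StandardScaler().fit_transform(bioclim.as_matrix())
    pca = PCA()
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_target) + 1)
    loadings = np.abs(pca.components_[:n_comp])  # (n_comp, n_vars)
    score = loadings.max(axis=0)
    names = bioclim.names
    R = np.abs(np.corrcoef(X, rowvar=False))
    ranked = sorted(range(len(names)), key=lambda j: (-score[j], names[j]))
    chosen: list[int] = []
    for j in ranked:
        if len(chosen) == k:
            break
        if any(R[j, c] > distinct_r for c in chosen):
            continue
        chosen.append(j)
    if len(chosen) < k:  # only duplicates left; fill with the remainder
        for j in ranked:
            if j not in chosen:
                chosen.append(j)
            if len(chosen) == k:
                break
    return [names[j] for j in chosen]


def lsvm_average_merit(
    occ: OccurrenceSet,
    background: np.ndarray,
    stack: EnvStack,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species predictor merit from linear-SVM weights.

    For each species, a soft-margin linear SVM (fixed C, standardized
    inputs) separates presence cells from the supplied background cells;
    merit_i = 1 + 9 * (|w_i| - min|w|) / (max|w| - min|w|), and a predictor
    is influential iff merit > 5. When all |w| are equal the merit is set
    to 5.5 for every predictor, with a warning.

    ``background`` is an array of background cell ids shared across
    species (or a dict species_code -> cell ids).

    Returns a table with columns species_code, predictor, merit,
    influential, plus a pooled summary (species_code = "ALL") of the mean
    merit per predictor.
    """
    names = stack.names
    Xall = stack.as_matrix()
    rows = []
    for code in occ.species:
        pres_cells = occ.cells_for_species(code)
        if len(pres_cells) < 10:
            raise ValueError(f"species {code}: need >= 10 presences, got {len(pres_cells)}")
        bg_cells = background[code] if isinstance(background, dict) else background
        bg_cells = np.asarray(bg_cells)
        if len(bg_cells) == 0:
            raise ValueError("empty background")
        X = np.vstack([Xall[pres_cells], Xall[bg_cells]])
        y = np.concatenate([np.ones(len(pres_cells)), np.zeros(len(bg_cells))])
        if y.min() == y.max():
            raise ValueError("degenerate fit: a single class")
        Xs = StandardScaler().fit_transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc = LinearSVC(C=C, random_state=seed, max_iter=20000)
            svc.fit(Xs, y)
        w = np.abs(svc.coef_.ravel())
        lo, hi = w.min(), w.max()
        if len(w) == 1:  # a lone predictor tops its own scale
            merit = np.array([10.0])
        elif hi - lo < 1e-12:
            warnings.warn(f"species {code}: all |w| equal; merits set to 5.5", stacklevel=2)
            merit = np.full(len(names), 5.5)
        else:
            merit = 1.0 + 9.0 * (w - lo) / (hi - lo)
        for name, m in zip(names, merit):
            rows.append({"species_code": code, "predictor": name, "merit": m})
    table = pd.DataFrame(rows)
    pooled = table.groupby("predictor", as_index=False)["merit"].mean()
    pooled.insert(0, "species_code", "ALL")
    table = pd.concat([table, pooled], ignore_index=True)
    table["influential"] = table["merit"] > 5.0
    return table
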