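"""Five-fold voted land-use classification, post-processing, and accuracy.

Annual maps are produced by training a random-forest classifier five times,
each on a distinct four-fifths of the supervised points (stratified folds),
predicting the whole grid each time, and resolving the five candidate maps
by per-cell plurality vote.  Vote ties are broken toward the category with
more supervised points, and a double tie falls back to the fixed category
order.

Post-processing applies three map-sequence rules: plantations are
absorbing (once plantation, always plantation), urban->forest and
water->forest transitions between consecutive years are rewritten to
shrub/grass (a one-year reversion to forest is physically implausible),
and nodata gaps are filled by iterated 8-neighbour majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .parameters import CATEGORIES, Category

__all__ = [
    "five_fold_classify",
    "resolve_votes",
    "post_process",
    "accuracy_assessment",
    "ConfusionMatrix",
]


# ---------------------------------------------------------------------------
# classification


def five_fold_classify(
    features: np.ndarray,
    point_rows: np.ndarray,
    point_labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
    classifier_factory=None,
):
    """Train five classifiers on stratified 4/5 splits and map the grid.

    Parameters
    ----------
    features : (n_valid_cells, n_features) feature matrix for every cell to
        be classified
    point_rows : row indices into ``features`` of the supervised points
    point_labels : category codes of the supervised points
    classifier_factory : optional callable ``(seed) -> estimator`` with the
        sklearn fit/predict interface, replacing the default random forest

    Returns
    -------
    maps : (5, n_valid_cells) int8 candidate category maps
    folds : list of (train_idx, test_idx) into the point arrays, for
        held-out accuracy assessment
    """
    point_rows = np.asarray(point_rows)
    point_labels = np.asarray(point_labels)
    if point_rows.size == 0:
        raise ValueError("empty supervised set")
    classes, counts = np.unique(point_labels, return_counts=True)
    if counts.min() < 5:
        small = classes[counts < 5]
        raise ValueError(f"classes {small.tolist()} have fewer than 5 points")
    if classifier_factory is None:
        classifier_factory = lambda s: RandomForestClassifier(  # noqa: E731
            n_estimators=n_estimators, random_state=s, n_jobs=1
        )
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    maps = np.zeros((5, features.shape[0]), dtype=np.int8)
    folds = []
    for k, (train, test) in enumerate(skf.split(point_rows, point_labels)):
        clf = classifier_factory(seed + k)
        clf.fit(features[point_rows[train]], point_labels[train])
        maps[k] = clf.predict(features).astype(np.int8)
        folds.append((train, test))
    return maps, folds


def resolve_votes(
    candidate_maps: np.ndarray, supervised_counts: dict | np.ndarray
) -> np.ndarray:
    """Resolve five candidate maps to one by per-cell plurality vote.

    Equal top frequencies are broken toward the category with more
    supervised points; a residual tie falls back to the fixed category
    order (ascending code).

    ``supervised_counts`` maps category code -> number of supervised points
    (dict or dense array indexed by code).
    """
    candidate_maps = np.asarray(candidate_maps)
    if candidate_maps.ndim != 2 or candidate_maps.shape[0] != 5:
        raise ValueError("expected five aligned candidate maps")
    n_codes = int(Category.WATER) + 1
    sup = np.zeros(n_codes)
    if isinstance(supervised_counts, dict):
        for code, n in supervised_counts.items():
            sup[int(code)] = n
    else:
        arr = np.asarray(supervised_counts, dtype=float)
        sup[: arr.size] = arr
    # per-cell vote histogram over codes 0..5
    n_cells = candidate_maps.shape[1]
    votes = np.zeros((n_cells, n_codes), dtype=np.int64)
    for k in range(5):
        np.add.at(votes, (np.arange(n_cells), candidate_maps[k].astype(int)), 1)
    # lexicographic argmax: vote count, then supervised frequency, then
    # fixed order (smaller code wins -> subtract a tiny code-indexed epsilon)
    order_eps = np.arange(n_codes) * 1e-9
    score = votes * 1e6 + sup[None, :] * 1e-3 - order_eps[None, :]
    return np.argmax(score, axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# post-processing


_NEIGHBOUR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _fill_gaps(grid: np.ndarray, prev_grid: np.ndarray | None) -> np.ndarray:
    """Iterated 8-neighbour majority fill of nodata cells.

    Neighbourhood ties are resolved by the previous year's category when it
    is among the tied modes, else by fixed category order.  Iterates until
    no nodata remains (isolated all-nodata maps raise).
    """
    h, w = grid.shape
    out = grid.copy()
    guard = 0
    while (out == int(Category.NODATA)).any():
        guard += 1
        if guard > h * w:
            raise ValueError("gap filling cannot converge: no classified cells")
        updated = out.copy()
        progress = False
        for r, c in zip(*np.nonzero(out == int(Category.NODATA))):
            counts = np.zeros(int(Category.WATER) + 1, dtype=int)
            for dr, dc in _NEIGHBOUR_OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and out[rr, cc] != int(Category.NODATA):
                    counts[out[rr, cc]] += 1
            if counts.sum() == 0:
                continue
            top = counts.max()
            modes = np.flatnonzero(counts == top)
            if modes.size > 1 and prev_grid is not None:
                prev = prev_grid[r, c]
                if prev in modes:
                    updated[r, c] = prev
                    progress = True
                    continue
            updated[r, c] = modes[0]  # fixed ascending-code order
            progress = True
        if not progress:
            raise ValueError("gap filling stalled")
        out = updated
    return out


def post_process(maps: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Apply the map-sequence rules to chronologically ordered raw maps.

    maps : (n_cells, n_years) int8 with 0 = nodata, in year order.

    Rules, per year in order: fill nodata from the surrounding grids
    (8-neighbour majority, iterated); carry plantations over from the
    previous processed year; rewrite urban->forest and water->forest
    one-year transitions to shrub/grass.  The result has no nodata and is
    idempotent under re-application.
    """
    maps = np.asarray(maps)
    if maps.ndim != 2:
        raise ValueError("expected (n_cells, n_years) map stack")
    h, w = shape
    n_cells, n_years = maps.shape
    if h * w != n_cells:
        raise ValueError("grid shape does not match map stack")
    out = maps.copy()
    prev: np.ndarray | None = None
    for t in range(n_years):
        grid = out[:, t].reshape(h, w)
        prev_grid = prev.reshape(h, w) if prev is not None else None
        grid = _fill_gaps(grid, prev_grid)
        cur = grid.ravel()
        if prev is not None:
            # plantation is absorbing
            cur = np.where(prev == int(Category.PLANTATION), int(Category.PLANTATION), cur)
            # one-year urban/water -> forest is implausible; call it shrub/grass
            implausible = (
                np.isin(prev, (int(Category.URBAN), int(Category.WATER)))
                & (cur == int(Category.FOREST))
            )
            cur = np.where(implausible, int(Category.SHRUB_GRASS), cur)
        out[:, t] = cur.astype(np.int8)
        prev = out[:, t]
    return out


# ---------------------------------------------------------------------------
# accuracy assessment


@dataclass
class ConfusionMatrix:
    """Counts[reference, predicted] over the category codes present.

    Overall accuracy is trace/total; producer's accuracy is per reference
    class (recall); user's accuracy is per predicted class (precision).
    Undefined ratios (empty class) are reported as NaN.
    """

    labels: np.ndarray  # category codes in row/col order
    counts: np.ndarray  # (k, k) int

    @property
    def overall(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    @property
    def producers(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def users(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(col > 0, np.diag(self.counts) / col, np.nan)

    def as_dict(self) -> dict:
        names = [Category(int(c)).name.lower() for c in self.labels]
        return {
            "overall": self.overall,
            "producers": dict(zip(names, self.producers)),
            "users": dict(zip(names, self.users)),
        }


def accuracy_assessment(
    predicted: np.ndarray,
    reference_cells: np.ndarray,
    reference_labels: np.ndarray,
    collapse: str = "five_class",
) -> ConfusionMatrix:
    """Score a predicted map against reference points.

    ``collapse='forest_nonforest'`` merges the four non-forest categories
    before counting.  Points indexing outside the map are skipped (their
    count is retained on the returned matrix as ``n_skipped``).
    """
    if collapse not in ("five_class", "forest_nonforest"):
        raise ValueError(f"unknown collapse {collapse!r}")
    predicted = np.asarray(predicted)
    cells = np.asarray(reference_cells)
    labels = np.asarray(reference_labels)
    inside = (cells >= 0) & (cells < predicted.shape[0])
    n_skipped = int((~inside).sum())
    cells, labels = cells[inside], labels[inside]
    pred = predicted[cells]
    if collapse == "forest_nonforest":
        pred = np.where(pred == int(Category.FOREST), 1, 2)
        labels = np.where(labels == int(Category.FOREST), 1, 2)
        codes = np.array([1, 2])
    else:
        codes = np.array([int(c) for c in CATEGORIES])
    k = codes.size
    lut = {int(c): i for i, c in enumerate(codes)}
    counts = np.zeros((k, k), dtype=int)
    for ref, prd in zip(labels, pred):
        counts[lut[int(ref)], lut[int(prd)]] += 1
    cm = ConfusionMatrix(labels=codes, counts=counts)
    cm.n_skipped = n_skipped
    return cm
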