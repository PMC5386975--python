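"""Finger/intensity decoding: linear SVM, 10-fold CV, and resampling analyses.

The decoder is a pairwise (one-vs-one) linear soft-margin SVM with vote
aggregation (libsvm via scikit-learn; voting ties resolve to the lowest class
index).  Feature vectors are z-scored voltage time series: for each trial the
window ``[t_start, t_end)`` of every selected channel is concatenated
channel-major into an N x T vector.  Accuracy is estimated by 10-fold cross
validation: one seeded global shuffle, then contiguous folds of equal size,
each predicted by a model trained on the other nine.

For wide feature matrices the linear kernel is precomputed once as a Gram
matrix and shared across folds (and across label permutations and window
sweeps), which leaves predictions unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .geometry import ArrayGeometry
from .preprocess import zscore_apply, zscore_features, zscore_fit
from .recording import (
    CONDITIONS,
    FULL_OFFSET,
    INIT_OFFSET,
    STIM_OFFSET,
    EpochSet,
    label_from_code,
)

#: the C grid investigated for the penalty parameter
DEFAULT_C_GRID = np.logspace(-10, 2, 20)
#: adopted penalty defaults: time-series analyses / single-time-point analysis
DEFAULT_C_TIMESERIES = 1.0
DEFAULT_C_SINGLEPOINT = 0.1

#: feature dimension above which the linear Gram matrix is precomputed
_GRAM_THRESHOLD = 1500

#: merged-channel decode window: 10 samples starting 86 samples after t_stim
MERGE_WINDOW = (STIM_OFFSET + 86, STIM_OFFSET + 96)


@dataclass(frozen=True)
class FeatureMatrix:
    """Z-scored decode features: samples x (channels * time points)."""

    X: np.ndarray
    label_codes: np.ndarray
    channels: np.ndarray
    t_start: int
    t_end: int

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def window_len(self) -> int:
        return self.t_end - self.t_start


@dataclass
class DecodeResult:
    """Cross-validated decoding outcome.

    ``confusion`` is true x predicted counts accumulated over all folds, in
    ``classes`` order; ``mean_acc``/``sd_acc`` summarize the per-fold
    accuracies.
    """

    fold_acc: np.ndarray
    confusion: np.ndarray
    classes: np.ndarray
    C: float
    n_folds: int

    @property
    def mean_acc(self) -> float:
        return float(self.fold_acc.mean())

    @property
    def sd_acc(self) -> float:
        return float(self.fold_acc.std(ddof=1))

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    def class_recall(self) -> np.ndarray:
        row = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row, np.nan)

    def summary(self) -> str:
        names = [str(label_from_code(c)) if len(self.classes) == len(CONDITIONS)
                 else str(c) for c in self.classes]
        lines = [
            "Linear SVM decoding (one-vs-one, 10-fold CV)",
            f"  samples: {self.n_samples}   classes: {len(self.classes)}"
            f"   C: {self.C:g}   folds: {self.n_folds}",
            f"  accuracy: {self.mean_acc:.3f} +/- {self.sd_acc:.3f}"
            " (mean +/- SD over folds)",
            "  per-class recall:",
        ]
        for name, r in zip(names, self.class_recall()):
            lines.append(f"    {name:>8s}: {r:.3f}")
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.confusion, cmap="Blues")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_xticks(range(len(self.classes)))
        ax.set_yticks(range(len(self.classes)))
        return im


def build_features(epochs: EpochSet, channels=None,
                   t_start: int = INIT_OFFSET, t_end: int = FULL_OFFSET,
                   zscore: str = "global") -> FeatureMatrix:
    """Concatenate per-channel voltage windows channel-major, then z-score.

    ``channels`` are geometry channel ids (default: every channel in the
    epoch set); ``t_start``/``t_end`` are post-trigger sample offsets that
    must satisfy ``t_init <= t_start < t_end <= t_full``.
    """
    if not (INIT_OFFSET <= t_start < t_end <= FULL_OFFSET):
        raise ValueError(
            f"window [{t_start}, {t_end}) outside [{INIT_OFFSET}, {FULL_OFFSET}]")
    if channels is None:
        rows = np.arange(epochs.n_channels)
        chan_ids = epochs.channel_ids.copy()
    else:
        chan_ids = np.asarray(channels, dtype=np.int64)
        pos = {int(c): i for i, c in enumerate(epochs.channel_ids)}
        try:
            rows = np.array([pos[int(c)] for c in chan_ids])
        except KeyError as e:
            raise ValueError(f"channel {e} not present in the epoch set") from None
    i0 = epochs.index_of(t_start)
    i1 = epochs.index_of(t_end)
    X = epochs.data_uv[:, rows, i0:i1].reshape(epochs.n_trials, -1)
    X = zscore_features(X, mode=zscore)
    return FeatureMatrix(X=X, label_codes=epochs.label_codes.copy(),
                         channels=chan_ids, t_start=t_start, t_end=t_end)


def linear_gram(X: np.ndarray) -> np.ndarray:
    """Precomputed linear kernel X X^T (float64)."""
    X = np.asarray(X, dtype=np.float64)
    return X @ X.T


def fold_indices(n: int, n_folds: int, seed: int) -> list:
    """Seeded shuffle, then contiguous folds of equal size."""
    if n % n_folds:
        raise ValueError(f"{n} samples do not split into {n_folds} equal folds")
    perm = np.random.default_rng(seed).permutation(n)
    size = n // n_folds
    return [perm[k * size:(k + 1) * size] for k in range(n_folds)]


def crossval_svm(X: np.ndarray | FeatureMatrix, y=None, C: float = 1.0,
                 seed: int = 0, n_folds: int = 10,
                 gram: np.ndarray | None = None,
                 standardize: str | None = None) -> DecodeResult:
    """10-fold cross-validated one-vs-one linear SVM.

    ``gram`` may carry a precomputed linear kernel of ``X`` (it is computed
    automatically for wide matrices).  ``standardize='fold'`` re-scales each
    fold with training-fold statistics instead of assuming pooled z-scored
    input.
    """
    if isinstance(X, FeatureMatrix):
        y = X.label_codes if y is None else y
        X = X.X
    if y is None:
        raise ValueError("labels required")
    y = np.asarray(y)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = np.unique(y)
    folds = fold_indices(X.shape[0], n_folds, seed)

    use_gram = standardize is None and (
        gram is not None or X.shape[1] > _GRAM_THRESHOLD)
    if use_gram and gram is None:
        gram = linear_gram(X)

    fold_acc = np.empty(n_folds)
    conf = np.zeros((classes.size, classes.size), dtype=np.int64)
    for k in range(n_folds):
        te = folds[k]
        tr = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        if np.unique(y[tr]).size < 2:
            raise ValueError("degenerate single-class training fold")
        if use_gram:
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(gram[np.ix_(tr, tr)], y[tr])
            pred = clf.predict(gram[np.ix_(te, tr)])
        else:
            Xtr, Xte = X[tr], X[te]
            if standardize == "fold":
                stats = zscore_fit(Xtr)
                Xtr, Xte = zscore_apply(Xtr, stats), zscore_apply(Xte, stats)
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xtr, y[tr])
            pred = clf.predict(Xte)
        fold_acc[k] = np.mean(pred == y[te])
        conf += confusion_matrix(y[te], pred, labels=classes)
    return DecodeResult(fold_acc=fold_acc, confusion=conf, classes=classes,
                        C=C, n_folds=n_folds)


class SEPDecoder:
    """Model object wrapping the cross-validated SVM decode of an epoch set.

    Parameters
    ----------
    features
        A :class:`FeatureMatrix` (see :func:`build_features`).
    C
        Soft-margin penalty; the package default is 1 for time-series
        features and 0.1 for single-time-point features.

    ``fit(seed)`` runs the seeded 10-fold cross validation and returns a
    :class:`DecodeResult`.
    """

    def __init__(self, features: FeatureMatrix, C: float = DEFAULT_C_TIMESERIES,
                 n_folds: int = 10):
        self.features = features
        self.C = C
        self.n_folds = n_folds
        self._gram = None

    @classmethod
    def from_epochs(cls, epochs: EpochSet, channels=None,
                    t_start: int = INIT_OFFSET, t_end: int = FULL_OFFSET,
                    C: float = DEFAULT_C_TIMESERIES, **kw) -> "SEPDecoder":
        return cls(build_features(epochs, channels, t_start, t_end), C=C, **kw)

    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = linear_gram(self.features.X)
        return self._gram

    def fit(self, seed: int = 0, C: float | None = None) -> DecodeResult:
        use_gram = self.features.n_features > _GRAM_THRESHOLD
        return crossval_svm(
            self.features, C=self.C if C is None else C, seed=seed,
            n_folds=self.n_folds, gram=self.gram() if use_gram else None)


# ---------------------------------------------------------------------------
# resampling / control analyses
# ---------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def shuffled_label_control(features: FeatureMatrix, n_permutations: int = 20,
                           C: float = DEFAULT_C_TIMESERIES,
                           seed: int = 0) -> np.ndarray:
    """Chance-level control: CV accuracy under random label permutations.

    Returns the mean CV accuracy of each permutation replicate (>= 20 by
    default); with balanced 10-class data these concentrate near 0.1.
    """
    gram = linear_gram(features.X) if features.n_features > _GRAM_THRESHOLD else None
    seeds = _spawn_seeds(seed, 2 * n_permutations)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        rng = np.random.default_rng(seeds[2 * i])
        y_perm = rng.permutation(features.label_codes)
        res = crossval_svm(features.X, y_perm, C=C, seed=int(seeds[2 * i + 1]),
                           gram=gram)
        accs[i] = res.mean_acc
    return accs


def sweep_C(features: FeatureMatrix, grid=None, seed: int = 0) -> pd.Series:
    """Mean CV accuracy over the C grid (20 log-spaced points, 1e-10..1e2)."""
    grid = DEFAULT_C_GRID if grid is None else np.asarray(grid, dtype=float)
    gram = linear_gram(features.X) if features.n_features > _GRAM_THRESHOLD else None
    acc = [crossval_svm(features.X, features.label_codes, C=float(c), seed=seed,
                        gram=gram).mean_acc for c in grid]
    return pd.Series(acc, index=pd.Index(grid, name="C"), name="mean_acc")


def temporal_truncation_curve(epochs: EpochSet, channels=None, t_ends=None,
                              C: float = DEFAULT_C_TIMESERIES,
                              seed: int = 0) -> pd.Series:
    """Accuracy vs decode-window end, windows growing from ``t_init``.

    ``t_ends`` defaults to every sample from ``t_init + 1`` to ``t_full``
    (200 window lengths).  The Gram matrix is accumulated incrementally over
    the growing window, so the sweep costs one rank update per step.
    """
    if t_ends is None:
        t_ends = np.arange(INIT_OFFSET + 1, FULL_OFFSET + 1)
    t_ends = np.sort(np.asarray(t_ends, dtype=int))
    fm = build_features(epochs, channels=channels)
    n, nch = fm.n_samples, fm.channels.size
    Z = fm.X.reshape(n, nch, FULL_OFFSET - INIT_OFFSET)

    gram = np.zeros((n, n))
    prev = INIT_OFFSET
    acc = []
    for te in t_ends:
        block = np.ascontiguousarray(
            Z[:, :, prev - INIT_OFFSET:te - INIT_OFFSET]).reshape(n, -1)
        gram += block.astype(np.float64) @ block.astype(np.float64).T
        prev = int(te)
        res = crossval_svm(fm.X, fm.label_codes, C=C, seed=seed, gram=gram)
        acc.append(res.mean_acc)
    return pd.Series(acc, index=pd.Index(t_ends, name="t_end"), name="mean_acc")


def single_channel_accuracy_map(epochs: EpochSet,
                                C: float = DEFAULT_C_TIMESERIES,
                                seed: int = 0) -> pd.Series:
    """Full-length single-channel CV accuracy for every retained channel."""
    fm = build_features(epochs)
    n, nch = fm.n_samples, fm.channels.size
    Z = fm.X.reshape(n, nch, -1)
    acc = np.empty(nch)
    for i in range(nch):
        acc[i] = crossval_svm(np.ascontiguousarray(Z[:, i, :]), fm.label_codes,
                              C=C, seed=seed).mean_acc
    return pd.Series(acc, index=pd.Index(fm.channels, name="channel"),
                     name="mean_acc")


def spatial_subsampling_grid(epochs: EpochSet, n_grid=None, t_grid=None,
                             repeats: int = 30, C: float = DEFAULT_C_TIMESERIES,
                             seed: int = 0) -> pd.DataFrame:
    """Accuracy over (N randomly drawn channels) x (window length T).

    Defaults follow the published grids: N = 1:5:91, T = 1:5:196, 30 channel
    draws per cell, windows starting at ``t_init``.  Each draw re-splits the
    CV folds with a derived seed.  Returns a DataFrame indexed by N with T
    columns holding the mean accuracy over draws.
    """
    n_grid = np.arange(1, 92, 5) if n_grid is None else np.asarray(n_grid, int)
    t_grid = np.arange(1, 197, 5) if t_grid is None else np.asarray(t_grid, int)
    fm = build_features(epochs)
    n, nch = fm.n_samples, fm.channels.size
    if n_grid.max() > nch:
        raise ValueError("subsample size exceeds the retained channel count")
    Z = fm.X.reshape(n, nch, -1)
    seeds = _spawn_seeds(seed, 2 * n_grid.size * t_grid.size * repeats)
    out = np.empty((n_grid.size, t_grid.size))
    s = 0
    for i, N in enumerate(n_grid):
        for j, T in enumerate(t_grid):
            accs = np.empty(repeats)
            for r in range(repeats):
                rng = np.random.default_rng(seeds[s])
                chans = rng.choice(nch, size=N, replace=False)
                Xs = np.ascontiguousarray(Z[:, chans, :T]).reshape(n, -1)
                accs[r] = crossval_svm(Xs, fm.label_codes, C=C,
                                       seed=int(seeds[s + 1])).mean_acc
                s += 2
            out[i, j] = accs.mean()
    return pd.DataFrame(out, index=pd.Index(n_grid, name="N"),
                        columns=pd.Index(t_grid, name="T"))


def single_timepoint_map(epochs: EpochSet, n_grid=None, t_grid=None,
                         repeats: int = 30, C: float = DEFAULT_C_SINGLEPOINT,
                         seed: int = 0) -> pd.DataFrame:
    """Subsampling accuracy from a single voltage sample per channel.

    ``t_grid`` defaults to ``t_init`` to ``t_full`` in 5-sample steps; the
    feature vector at time t is the N selected channels' voltage at t.
    """
    n_grid = np.arange(1, 92, 5) if n_grid is None else np.asarray(n_grid, int)
    t_grid = np.arange(INIT_OFFSET, FULL_OFFSET, 5) if t_grid is None \
        else np.asarray(t_grid, int)
    fm = build_features(epochs)
    n, nch = fm.n_samples, fm.channels.size
    Z = fm.X.reshape(n, nch, -1)
    seeds = _spawn_seeds(seed, 2 * n_grid.size * t_grid.size * repeats)
    out = np.empty((n_grid.size, t_grid.size))
    s = 0
    for i, N in enumerate(n_grid):
        for j, t in enumerate(t_grid):
            col = t - INIT_OFFSET
            accs = np.empty(repeats)
            for r in range(repeats):
                rng = np.random.default_rng(seeds[s])
                chans = rng.choice(nch, size=N, replace=False)
                Xs = np.ascontiguousarray(Z[:, chans, col])
                accs[r] = crossval_svm(Xs, fm.label_codes, C=C,
                                       seed=int(seeds[s + 1])).mean_acc
                s += 2
            out[i, j] = accs.mean()
    return pd.DataFrame(out, index=pd.Index(n_grid, name="N"),
                        columns=pd.Index(t_grid, name="t"))


# ---------------------------------------------------------------------------
# merged ("virtual large") channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGroups:
    """A disjoint partition of the retained channels into merge groups."""

    groups: tuple

    def __post_init__(self):
        flat = [c for g in self.groups for c in g]
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("empty merge group")
        if len(flat) != len(set(flat)):
            raise ValueError("merge groups overlap")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def channel_union(self) -> set:
        return {c for g in self.groups for c in g}


def default_merge_levels(geometry: ArrayGeometry, retained=None) -> list:
    """Dyadic per-patch merge scheme, coarse to fine.

    Levels: 1 group per patch (3 virtual channels) -> 2 blocks of 16 per
    patch (6) -> 8 blocks of 2x2 per patch (24) -> singletons (94).  Broken
    channels are removed from every group.
    """
    retained = set(geometry.retained_channels if retained is None else retained)

    def rect_blocks(cols_per_block, rows_per_block):
        groups = []
        for p in range(3):
            chans = geometry.channels_of_patch(p)
            pos = geometry.pos_um[chans]
            xs = np.unique(pos[:, 0])
            ys = np.unique(pos[:, 1])
            for cb in range(len(xs) // cols_per_block):
                for rb in range(len(ys) // rows_per_block):
                    in_x = np.isin(pos[:, 0], xs[cb * cols_per_block:(cb + 1) * cols_per_block])
                    in_y = np.isin(pos[:, 1], ys[rb * rows_per_block:(rb + 1) * rows_per_block])
                    g = tuple(int(c) for c in chans[in_x & in_y] if c in retained)
                    if g:
                        groups.append(g)
        return ChannelGroups(groups=tuple(groups))

    levels = [
        rect_blocks(8, 4),    # whole patch
        rect_blocks(4, 4),    # 2 blocks of 16 per patch
        rect_blocks(2, 2),    # 8 blocks of 4 per patch
        ChannelGroups(groups=tuple((int(c),) for c in sorted(retained))),
    ]
    return levels


def merge_channels(epochs: EpochSet, groups: ChannelGroups) -> EpochSet:
    """Average each group's channels into one virtual large channel.

    Every group must consist of channels present in the epoch set.  The
    virtual channel inherits the id of the group's first member.
    """
    pos = {int(c): i for i, c in enumerate(epochs.channel_ids)}
    missing = groups.channel_union() - set(pos)
    if missing:
        raise ValueError(f"groups reference absent channels {sorted(missing)}")
    n_g = groups.n_groups
    data = np.empty((epochs.n_trials, n_g, epochs.n_samples), dtype=np.float32)
    ids = np.empty(n_g, dtype=np.int64)
    for k, g in enumerate(groups.groups):
        rows = [pos[int(c)] for c in g]
        data[:, k, :] = epochs.data_uv[:, rows, :].mean(axis=1)
        ids[k] = g[0]
    return EpochSet(data_uv=data, label_codes=epochs.label_codes.copy(),
                    channel_ids=ids, pre=epochs.pre, fs_hz=epochs.fs_hz,
                    trigger_idx=None if epochs.trigger_idx is None
                    else epochs.trigger_idx.copy())


def merged_channel_curve(epochs: EpochSet, levels=None,
                         window: tuple = MERGE_WINDOW,
                         C: float = DEFAULT_C_TIMESERIES, seed: int = 0,
                         geometry: ArrayGeometry | None = None):
    """Channel count vs accuracy across merge levels (coarse to fine).

    Features are the 10-sample window starting 86 samples after ``t_stim``.
    Returns ``(curve, results)`` where ``curve`` is a DataFrame with the
    virtual channel count and fold statistics per level and ``results`` holds
    the per-level :class:`DecodeResult` (confusion matrices included).
    """
    if levels is None:
        if geometry is None:
            raise ValueError("need explicit levels or a geometry")
        levels = default_merge_levels(geometry, retained=epochs.channel_ids)
    t0, t1 = window
    rows, results = [], []
    for lv in levels:
        merged = merge_channels(epochs, lv)
        res = SEPDecoder.from_epochs(merged, t_start=t0, t_end=t1, C=C).fit(seed)
        results.append(res)
        rows.append({"n_channels": lv.n_groups, "mean_acc": res.mean_acc,
                     "sd_acc": res.sd_acc})
    curve = pd.DataFrame(rows).set_index("n_channels")
    return curve, results
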