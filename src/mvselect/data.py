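"""Domain containers and delimited-text I/O for multiview data.

A *view* is an ``n x p`` numeric matrix over a common set of ``n`` samples;
a dataset bundles ``D >= 1`` views aligned on sample identity, with optional
per-sample labels.  Files are delimited text (comma by default, tab via
``sep``) with a header row of feature names and a leading ``sample_id``
column; views are aligned to the sample order of the first file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Sample identifiers do not match across view files."""


@dataclass
class MultiViewDataset:
    """Aligned multiview data: D matrices sharing rows (samples).

    Parameters
    ----------
    views : list of ndarray
        D matrices, each ``n x p_d``, real valued, no missing entries.
    sample_ids : list of str
        n sample identifiers, shared by every view in this row order.
    feature_names : list of list of str
        Per-view column names; unique within a view.
    labels : ndarray or None
        Optional length-n vector of integer class labels or real outcomes.
    """

    views: list[np.ndarray]
    sample_ids: list[str]
    feature_names: list[list[str]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("a dataset needs at least one view")
        n = len(self.sample_ids)
        for d, (X, names) in enumerate(zip(self.views, self.feature_names)):
            X = np.asarray(X, dtype=float)
            self.views[d] = X
            if X.ndim != 2 or X.shape[0] != n:
                raise ValueError(
                    f"view {d}: expected {n} rows, got shape {X.shape}"
                )
            if X.shape[1] != len(names):
                raise ValueError(
                    f"view {d}: {X.shape[1]} columns but {len(names)} feature names"
                )
            if len(set(names)) != len(names):
                raise ValueError(f"view {d}: duplicate feature names")
            if not np.isfinite(X).all():
                i, j = np.argwhere(~np.isfinite(X))[0]
                raise ValueError(
                    f"view {d}: non-finite value at row {i} "
                    f"(sample {self.sample_ids[i]}), column {j} ({names[j]})"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError(
                    f"labels: expected shape ({n},), got {self.labels.shape}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_features(self) -> list[int]:
        return [X.shape[1] for X in self.views]

    def subset_features(self, index_sets: Sequence[Sequence[int]]) -> "MultiViewDataset":
        """Restrict each view to the given 0-based column indices."""
        views = [X[:, list(idx)] for X, idx in zip(self.views, index_sets)]
        names = [
            [fn[j] for j in idx]
            for fn, idx in zip(self.feature_names, index_sets)
        ]
        return MultiViewDataset(views, list(self.sample_ids), names, self.labels)

    def subset_samples(self, rows: Sequence[int]) -> "MultiViewDataset":
        rows = list(rows)
        return MultiViewDataset(
            [X[rows] for X in self.views],
            [self.sample_ids[i] for i in rows],
            [list(fn) for fn in self.feature_names],
            None if self.labels is None else self.labels[rows],
        )


@dataclass
class StandardizationState:
    """Per-view, per-feature centering/scaling statistics.

    ``means[d]`` and ``stds[d]`` are length ``p_d``; all stored stds are
    strictly positive.  Applying :meth:`transform` then :meth:`inverse`
    recovers the input to floating-point tolerance.
    """

    means: list[np.ndarray]
    stds: list[np.ndarray]

    def __post_init__(self) -> None:
        for d, s in enumerate(self.stds):
            if not (np.asarray(s) > 0).all():
                raise ValueError(f"view {d}: non-positive std stored")

    def transform(self, dataset: MultiViewDataset) -> MultiViewDataset:
        views = [
            (X - m) / s
            for X, m, s in zip(dataset.views, self.means, self.stds)
        ]
        return replace(dataset, views=views)

    def inverse(self, dataset: MultiViewDataset) -> MultiViewDataset:
        views = [
            X * s + m
            for X, m, s in zip(dataset.views, self.means, self.stds)
        ]
        return replace(dataset, views=views)

    def subset_features(self, index_sets: Sequence[Sequence[int]]) -> "StandardizationState":
        return StandardizationState(
            [m[list(idx)] for m, idx in zip(self.means, index_sets)],
            [s[list(idx)] for s, idx in zip(self.stds, index_sets)],
        )


def standardize(
    dataset: MultiViewDataset, drop_constant: bool = False, ddof: int = 1
) -> tuple[MultiViewDataset, StandardizationState]:
    """Center every feature to mean 0 and scale to variance 1, per view.

    Norm-based feature ranking compares column magnitudes, so all features
    must be on a common scale first.  Zero-variance columns cannot be scaled;
    they raise unless ``drop_constant`` is set, in which case they are removed.

    Returns the transformed dataset and the :class:`StandardizationState`
    holding the training statistics (frozen for later use on test data).
    """
    views, names, means, stds = [], [], [], []
    for d, X in enumerate(dataset.views):
        m = X.mean(axis=0)
        s = X.std(axis=0, ddof=ddof)
        const = np.flatnonzero(s <= 0)
        keep = np.arange(X.shape[1])
        if const.size:
            cols = [dataset.feature_names[d][j] for j in const]
            if not drop_constant:
                raise ValueError(
                    f"view {d}: zero-variance columns {cols}; "
                    "pass drop_constant=True to remove them"
                )
            keep = np.setdiff1d(keep, const)
        views.append((X[:, keep] - m[keep]) / s[keep])
        names.append([dataset.feature_names[d][j] for j in keep])
        means.append(m[keep])
        stds.append(s[keep])
    out = MultiViewDataset(views, list(dataset.sample_ids), names, dataset.labels)
    return out, StandardizationState(means, stds)


def read_views(
    paths: Sequence[str | Path],
    label_path: str | Path | None = None,
    sep: str = ",",
) -> MultiViewDataset:
    """Read view matrices (and optionally labels) from delimited text.

    Each file has a header of feature names and a first column ``sample_id``.
    All files must cover the same sample set; rows are aligned to the sample
    order of the first file.
    """
    frames = []
    for path in paths:
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric column(s) {list(bad)}")
        if df.isna().any().any():
            j = df.columns[df.isna().any()][0]
            i = df.index[df[j].isna()][0]
            raise ValueError(f"{path}: missing value at sample {i}, column {j}")
        frames.append(df)

    order = frames[0].index
    for path, df in zip(paths[1:], frames[1:]):
        missing = set(order) - set(df.index)
        extra = set(df.index) - set(order)
        if missing or extra:
            raise AlignmentError(
                f"{path}: sample ids do not match the first view "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    views = [df.loc[order].to_numpy(dtype=float) for df in frames]
    names = [list(df.columns) for df in frames]

    labels = None
    if label_path is not None:
        ldf = pd.read_csv(label_path, sep=sep, index_col=0)
        ldf.index = ldf.index.astype(str)
        missing = set(order) - set(ldf.index)
        if missing:
            raise AlignmentError(
                f"{label_path}: labels missing for samples {sorted(missing)}"
            )
        labels = ldf.loc[order].iloc[:, 0].to_numpy()

    return MultiViewDataset(views, list(order), names, labels)


def write_views(
    dataset: MultiViewDataset,
    paths: Sequence[str | Path],
    label_path: str | Path | None = None,
    sep: str = ",",
) -> None:
    """Write each view (and optionally labels) as delimited text with sample ids."""
    for X, names, path in zip(dataset.views, dataset.feature_names, paths):
        pd.DataFrame(X, index=pd.Index(dataset.sample_ids, name="sample_id"),
                     columns=names).to_csv(path, sep=sep)
    if label_path is not None:
        if dataset.labels is None:
            raise ValueError("dataset has no labels to write")
        pd.DataFrame(
            {"label": dataset.labels},
            index=pd.Index(dataset.sample_ids, name="sample_id"),
        ).to_csv(label_path, sep=sep)


def write_selection(result, dataset: MultiViewDataset, path: str | Path) -> None:
    """Write the per-feature ranking table.

    One row per feature across all views: view index, positional index
    (0-based), feature name, reconstructed-column norm, rank (1 = largest
    norm), and whether the feature was selected.  Sorted by view then rank.
    """
    rows = []
    for d in range(dataset.n_views):
        selected = set(result.selected[d]) if result.selected is not None else set()
        order = np.argsort(result.ranks[d], kind="stable")
        for j in order:
            rows.append(
                {
                    "view": d,
                    "feature_index": int(j),
                    "feature_name": dataset.feature_names[d][j],
                    "column_norm": float(result.column_norms[d][j]),
                    "rank": int(result.ranks[d][j]),
                    "selected": bool(j in selected),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_selection(path: str | Path) -> pd.DataFrame:
    """Read back a ranking table written by :func:`write_selection`."""
    return pd.read_csv(path)
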