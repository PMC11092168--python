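"""Comparison systems: mean imputation, single-view learner, concatenation.

These are the reference points the multi-view booster is judged against:

* :func:`mean_impute_union` — extend every view to the full sample set ``N``
  by filling an absent sample's row with each feature's mean over the view's
  originally present samples.  Means are computed on a *training* subset
  only (when given), so test-time imputation reuses training means and no
  test information leaks.  The core booster never imputes; this adapter is
  what lets the complete-view binary predecessor run on incomplete data.
* :func:`fit_single_view` — an ordinary supervised fit on one view.
* :func:`fit_concat` — mean-impute, then concatenate all views' features
  horizontally (feature ids disambiguated by a view-id prefix) and fit one
  model on the combined table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .boosting import make_base_learner
from .data_model import (
    IntegrityError,
    LabelEncoding,
    MultiViewDataset,
    MvBoostError,
    ViewTable,
    assemble_dataset,
)

__all__ = [
    "mean_impute_union",
    "imputation_means",
    "fit_single_view",
    "fit_concat",
    "FittedSingleView",
    "FittedConcat",
]


def mean_impute_union(
    ds: MultiViewDataset,
    train_samples: Iterable[str] | None = None,
    means: dict | None = None,
) -> MultiViewDataset:
    """Every view extended to all of ``N``; absent rows filled with
    per-feature means over the view's present (training) samples.

    Originally present rows are never altered.  A complete view passes
    through unchanged (up to row completion, which is a no-op).  Pass
    ``means`` (view_id -> Series, e.g. from :func:`imputation_means` on the
    training fold) to impute a test fold with training means.
    """
    train = set(train_samples) if train_samples is not None else None
    new_views = []
    for v in ds.views:
        if means is not None:
            mu = means[v.view_id]
        else:
            if train is None:
                basis = v.data
            else:
                keep = [s for s in v.sample_ids if s in train]
                basis = v.data.loc[keep]
            if basis.shape[0] == 0:
                raise IntegrityError(
                    f"view {v.view_id!r}: no observed training samples to "
                    "compute imputation means from"
                )
            mu = basis.mean(axis=0)
        if mu.isna().any():
            raise IntegrityError(
                f"view {v.view_id!r}: feature(s) without observed values"
            )
        full = v.data.reindex(ds.all_samples)
        full = full.fillna(mu)
        new_views.append(ViewTable(v.view_id, full))
    return assemble_dataset(new_views, ds.labels)


def imputation_means(ds: MultiViewDataset) -> dict:
    """Per-view, per-feature means over the view's present samples."""
    out = {}
    for v in ds.views:
        if v.is_empty:
            raise IntegrityError(
                f"view {v.view_id!r}: no observed samples for imputation"
            )
        out[v.view_id] = v.data.mean(axis=0)
    return out


@dataclass
class FittedSingleView:
    view_id: str
    model: object
    encoding: LabelEncoding
    feature_ids: list[str]
    constant: bool  # training slice had a single class

    def predict(self, view: ViewTable):
        X = view.data.loc[:, self.feature_ids].to_numpy(dtype=float)
        codes = np.asarray(self.model.predict(X), dtype=int)
        return self.encoding.decode(codes)

    def predict_proba(self, view: ViewTable) -> np.ndarray:
        X = view.data.loc[:, self.feature_ids].to_numpy(dtype=float)
        raw = np.asarray(self.model.predict_proba(X))
        out = np.zeros((X.shape[0], self.encoding.n_classes))
        for k, c in enumerate(self.model.classes_):
            out[:, int(c) - 1] = raw[:, k]
        return out


def fit_single_view(
    view: ViewTable,
    labels: dict,
    base_learner: str | Callable = "rf",
    seed: int | None = None,
    encoding: LabelEncoding | None = None,
) -> FittedSingleView:
    """Standard supervised fit on one view's present samples."""
    if view.is_empty:
        raise IntegrityError(f"view {view.view_id!r} has no samples to fit on")
    missing = [s for s in view.sample_ids if s not in labels]
    if missing:
        raise IntegrityError(f"unlabeled sample(s): {missing}")
    if encoding is None:
        encoding = LabelEncoding.fit(labels[s] for s in view.sample_ids)
    y = encoding.encode(labels[s] for s in view.sample_ids)
    model = make_base_learner(base_learner, int(seed) if seed is not None else 0)
    model.fit(view.values, y)
    return FittedSingleView(
        view_id=view.view_id,
        model=model,
        encoding=encoding,
        feature_ids=view.feature_ids,
        constant=len(np.unique(y)) == 1,
    )


@dataclass
class FittedConcat:
    model: object
    encoding: LabelEncoding
    view_ids: list[str]
    feature_ids: dict  # view_id -> training feature ids
    impute_means: dict  # view_id -> pd.Series of training means

    def _design(self, ds: MultiViewDataset) -> np.ndarray:
        """Columns in view order then feature order; absent rows imputed
        with the stored training means."""
        blocks = []
        for vid in self.view_ids:
            v = ds.view(vid)
            feats = self.feature_ids[vid]
            full = v.data.reindex(ds.all_samples).reindex(columns=feats)
            full = full.fillna(self.impute_means[vid])
            blocks.append(full.to_numpy(dtype=float))
        return np.hstack(blocks)

    def predict(self, ds: MultiViewDataset):
        codes = np.asarray(self.model.predict(self._design(ds)), dtype=int)
        return self.encoding.decode(codes)

    def predict_proba(self, ds: MultiViewDataset) -> np.ndarray:
        raw = np.asarray(self.model.predict_proba(self._design(ds)))
        out = np.zeros((ds.n_samples, self.encoding.n_classes))
        for k, c in enumerate(self.model.classes_):
            out[:, int(c) - 1] = raw[:, k]
        return out


def fit_concat(
    ds: MultiViewDataset,
    base_learner: str | Callable = "rf",
    seed: int | None = None,
) -> FittedConcat:
    """Mean-impute every view over ``ds``'s samples, concatenate features
    (total width ``sum_j q_j``), and fit one model."""
    means = {}
    for v in ds.views:
        if v.is_empty:
            raise IntegrityError(
                f"view {v.view_id!r}: no observed samples for imputation"
            )
        means[v.view_id] = v.data.mean(axis=0)
    blocks = []
    names: list[str] = []
    for v in ds.views:
        full = v.data.reindex(ds.all_samples).fillna(means[v.view_id])
        blocks.append(full.to_numpy(dtype=float))
        names.extend(f"{v.view_id}::{f}" for f in v.feature_ids)
    X = np.hstack(blocks)
    if len(set(names)) != len(names):  # pragma: no cover
        raise MvBoostError("feature name collision despite view-id prefixing")
    y = ds.y
    model = make_base_learner(base_learner, int(seed) if seed is not None else 0)
    model.fit(X, y)
    return FittedConcat(
        model=model,
        encoding=ds.encoding,
        view_ids=ds.view_ids,
        feature_ids={v.view_id: v.feature_ids for v in ds.views},
        impute_means=means,
    )
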