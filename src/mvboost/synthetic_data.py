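"""Synthetic multi-view, multi-class datasets with controllable signal and
incompleteness.

Each view draws its present samples from class-conditional distributions
whose separation is set per view in units of the noise standard deviation,
so a view's informativeness is a single dial (``signal = 0`` gives a
label-independent pure-noise view) and, for two balanced Gaussian classes,
the view's Bayes accuracy has the closed form ``Phi(signal / 2)``.

Two feature models are available: spherical Gaussians (the default —
distribution-agnostic algorithms are under test and Gaussians give
closed-form separability for calibration) and a negative-binomial count
mode for sparse OTU-like fixtures.  A *complementarity* option makes view j
informative only about class j versus the rest, so no single view can solve
the full multi-class task but the views jointly can — the structural
situation in which a multi-view learner must beat every single view.

Incompleteness is controlled by a per-view missing fraction; a coverage
constraint guarantees every sample stays present in at least one view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    MultiViewDataset,
    ParameterError,
    ViewTable,
    assemble_dataset,
)

__all__ = ["ViewSpec", "SyntheticSpec", "generate", "make_incomplete_mvasd_like"]


@dataclass(frozen=True)
class ViewSpec:
    """One view's shape: feature count, class-mean separation (in noise-SD
    units), and missing fraction."""

    n_features: int = 10
    signal: float = 2.0
    missing: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if self.signal < 0:
            raise ParameterError("signal must be >= 0")
        if not 0 <= self.missing < 1:
            raise ParameterError("missing fraction must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 200
    n_classes: int = 2
    views: tuple = (ViewSpec(), ViewSpec())
    class_balance: tuple | None = None  # uniform if None
    mode: str = "gaussian"  # or "nb" (negative-binomial counts)
    complementary: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < self.n_classes:
            raise ParameterError("need at least one sample per class")
        if self.n_classes < 2:
            raise ParameterError("need at least two classes")
        if not self.views:
            raise ParameterError("need at least one view")
        if self.class_balance is not None:
            bal = np.asarray(self.class_balance, dtype=float)
            if len(bal) != self.n_classes or abs(bal.sum() - 1.0) > 1e-9:
                raise ParameterError("class balance must sum to 1 over C classes")
        if self.mode not in ("gaussian", "nb"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.complementary and len(self.views) > self.n_classes:
            raise ParameterError(
                "complementary mode needs at most one view per class"
            )


def _class_means(spec: SyntheticSpec, j: int, vs: ViewSpec) -> np.ndarray:
    """(C, q_j) mean matrix; pairwise separation scales with the signal."""
    C, q = spec.n_classes, vs.n_features
    mu = np.zeros((C, q))
    if vs.signal == 0:
        return mu
    if spec.complementary:
        # view j separates class j+1 from everything else, by `signal` SDs
        if q < 1:
            raise ParameterError("complementary mode needs >= 1 feature")
        mu[j, 0] = vs.signal
        return mu
    if q < C:
        raise ParameterError(
            f"view {j}: need n_features >= n_classes for distinct class means"
        )
    # one-hot directions scaled so every class pair sits `signal` SDs apart
    for c in range(C):
        mu[c, c] = vs.signal / np.sqrt(2.0)
    return mu


def generate(spec: SyntheticSpec):
    """Draw a dataset plus a ground-truth record.

    The record carries the class codes, per-view means and presence masks,
    and (for two balanced Gaussian classes) each view's closed-form Bayes
    accuracy ``Phi(signal / 2)`` — enough to calibrate simulations without
    refitting anything.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.n_classes
    bal = (
        np.full(C, 1.0 / C)
        if spec.class_balance is None
        else np.asarray(spec.class_balance, dtype=float)
    )
    sample_ids = [f"s{i:05d}" for i in range(spec.n_samples)]
    y = rng.choice(np.arange(1, C + 1), size=spec.n_samples, p=bal)

    # presence masks with coverage: every sample present in >= 1 view
    K = len(spec.views)
    present = np.zeros((K, spec.n_samples), dtype=bool)
    for j, vs in enumerate(spec.views):
        present[j] = rng.random(spec.n_samples) >= vs.missing
    uncovered = np.flatnonzero(~present.any(axis=0))
    if uncovered.size:
        fallback = int(np.argmin([vs.missing for vs in spec.views]))
        present[fallback, uncovered] = True

    views: list[ViewTable] = []
    means: list[np.ndarray] = []
    for j, vs in enumerate(spec.views):
        mu = _class_means(spec, j, vs)
        means.append(mu)
        idx = np.flatnonzero(present[j])
        if spec.mode == "gaussian":
            X = mu[y[idx] - 1] + rng.standard_normal((idx.size, vs.n_features))
        else:
            X = _nb_counts(rng, mu, y[idx], vs)
        df = pd.DataFrame(
            X,
            index=[sample_ids[i] for i in idx],
            columns=[f"f{j}_{k}" for k in range(vs.n_features)],
        )
        views.append(ViewTable(f"view{j + 1}", df))

    labels = {s: int(c) for s, c in zip(sample_ids, y)}
    ds = assemble_dataset(views, labels)

    from scipy.stats import norm

    ground_truth = {
        "y": {s: int(c) for s, c in zip(sample_ids, y)},
        "class_balance": bal.tolist(),
        "signals": [vs.signal for vs in spec.views],
        "missing": [vs.missing for vs in spec.views],
        "present": {f"view{j + 1}": present[j].tolist() for j in range(K)},
        "class_means": {f"view{j + 1}": means[j].tolist() for j in range(K)},
        # two balanced Gaussian classes `signal` SDs apart: acc* = Phi(s/2)
        "bayes_accuracy": [
            float(norm.cdf(vs.signal / 2.0))
            if spec.mode == "gaussian" and C == 2 and not spec.complementary
            else None
            for vs in spec.views
        ],
        "mode": spec.mode,
        "complementary": spec.complementary,
    }
    return ds, ground_truth


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, y_idx: np.ndarray, vs: ViewSpec
) -> np.ndarray:
    """Sparse OTU-like counts: lognormal baseline abundances, the class
    effect multiplies the mean by exp(signal-scaled offset), NB dispersion."""
    q = vs.n_features
    base = rng.lognormal(mean=1.0, sigma=1.0, size=q)
    log_fc = mu  # reuse the Gaussian mean layout as log fold-changes
    mean = base[None, :] * np.exp(log_fc[y_idx - 1])
    dispersion = 2.0  # NB size parameter; smaller -> noisier counts
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def make_incomplete_mvasd_like(
    n_only_large: int,
    n_only_small: int,
    n_overlap: int,
    n_classes: int = 2,
    n_features: Sequence[int] = (20, 20),
    signal: Sequence[float] = (2.0, 2.0),
    seed: int | None = None,
):
    """Two views with an explicit membership structure, at arbitrary scale:
    a large view (``n_only_large + n_overlap`` samples), a small view
    (``n_only_small + n_overlap``), and their overlap — the situation of a
    cohort where one assay covers most individuals and a second, more
    expensive assay covers a subset (plus a few exclusive to it).
    """
    for v, name in [
        (n_only_large, "n_only_large"),
        (n_only_small, "n_only_small"),
        (n_overlap, "n_overlap"),
    ]:
        if v < 0:
            raise ParameterError(f"{name} must be nonnegative")
    n = n_only_large + n_only_small + n_overlap
    if n < n_classes:
        raise ParameterError("too few samples for the number of classes")
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:05d}" for i in range(n)]
    y = rng.choice(np.arange(1, n_classes + 1), size=n)

    in_large = np.zeros(n, dtype=bool)
    in_small = np.zeros(n, dtype=bool)
    in_large[: n_only_large + n_overlap] = True
    in_small[n_only_large : n_only_large + n_overlap + n_only_small] = True

    views = []
    for vid, mask, q, s in [
        ("view1", in_large, n_features[0], signal[0]),
        ("view2", in_small, n_features[1], signal[1]),
    ]:
        mu = np.zeros((n_classes, q))
        if s > 0:
            for c in range(n_classes):
                mu[c, c % q] = s / np.sqrt(2.0)
        idx = np.flatnonzero(mask)
        X = mu[y[idx] - 1] + rng.standard_normal((idx.size, q))
        df = pd.DataFrame(
            X,
            index=[sample_ids[i] for i in idx],
            columns=[f"{vid}_f{k}" for k in range(q)],
        )
        views.append(ViewTable(vid, df))

    labels = {s_: int(c) for s_, c in zip(sample_ids, y)}
    ds = assemble_dataset(views, labels)
    ground_truth = {
        "y": labels,
        "membership": {
            "view1": in_large.tolist(),
            "view2": in_small.tolist(),
        },
    }
    return ds, ground_truth
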