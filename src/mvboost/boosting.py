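"""Shared-weight multi-view boosting driven by an adversarial bandit.

Two fitting procedures are provided:

* :func:`fit_irboost` — multi-class, tolerates incomplete views.  One
  boosting distribution ``w`` over all samples ``N`` is shared across views.
  Each iteration the bandit selects a view j, a weak learner is fitted on
  that view's present samples under the restricted (renormalized) weights,
  and the *edge*

      edge_t = 2 * sum_{i in N_j} w_i * (I[y_i = h(x_i)] - 1/2)

  is computed over the samples present in the view.  A sample absent from
  the selected view receives the artificial label 0 (never a real class,
  classes being 1..C), so it contributes nothing to the edge and its weight
  is touched only by the final renormalization.  The edge is the bandit
  reward; the round's vote weight is ``alpha = 0.5 * ln((1+edge)/(1-edge))``
  when the edge is positive and 0 otherwise (the round is kept for audit but
  excluded from the combined classifier).  Prediction combines the rounds'
  class-probability vectors, with the zero vector standing in for views a
  test instance is absent from.

* :func:`fit_rboost_binary` — the binary, complete-view predecessor, run in
  plus/minus-1 label arithmetic with ``edge_t = sum_i w_i y_i h(x_i)`` and a
  sign-of-weighted-sum final classifier.  On complete binary data the two
  procedures follow identical trajectories under a shared seed, which the
  test suite checks bit for bit.

The number of times each view wins the bandit is recorded: it serves as an
indicator of view relevance (e.g. which preprocessing pipeline carries the
most signal).

One pseudo-random stream drives each fit, consumed in a fixed order per
iteration: first the bandit draw, then the weak learner's seed.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .bandit import (
    DEFAULT_GAMMA,
    DEFAULT_SIGMA,
    init_bandit,
    select_view,
    update_bandit,
)
from .data_model import (
    IntegrityError,
    MultiViewDataset,
    ParameterError,
    UnpredictableError,
    ViewTable,
)

__all__ = [
    "SharedWeights",
    "WeakHypothesis",
    "WeakRound",
    "Ensemble",
    "make_base_learner",
    "agreement_indicator",
    "modified_predict",
    "modified_proba",
    "compute_edge",
    "compute_alpha",
    "update_weights",
    "fit_irboost",
    "fit_rboost_binary",
    "predict_ensemble",
    "DEFAULT_T",
]

DEFAULT_T = 50
_ALPHA_CLIP = 1e-10


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------


def make_base_learner(spec: str | Callable, random_state: int):
    """Instantiate an unfitted scikit-learn classifier.

    ``spec`` is ``"rf"`` (random forest, 50 trees — the default),
    ``"rf-<n>"``, ``"dt"`` (single decision tree), ``"dt-<depth>"``, or a
    callable ``random_state -> estimator``.
    """
    if callable(spec):
        return spec(random_state)
    if spec == "rf":
        return RandomForestClassifier(n_estimators=50, random_state=random_state)
    if spec.startswith("rf-"):
        return RandomForestClassifier(
            n_estimators=int(spec[3:]), random_state=random_state
        )
    if spec == "dt":
        return DecisionTreeClassifier(random_state=random_state)
    if spec.startswith("dt-"):
        return DecisionTreeClassifier(
            max_depth=int(spec[3:]), random_state=random_state
        )
    raise ParameterError(f"unknown base learner spec {spec!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SharedWeights:
    """The boosting distribution over all samples of the dataset."""

    sample_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        if (self.w < 0).any():
            raise IntegrityError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise IntegrityError("weights must sum to 1")

    @classmethod
    def uniform(cls, sample_ids: Sequence[str]) -> "SharedWeights":
        n = len(sample_ids)
        return cls(list(sample_ids), np.full(n, 1.0 / n))


@dataclass
class WeakHypothesis:
    """A fitted weak learner bound to one view.

    ``classes_seen`` holds the internal class codes present in the training
    slice (the fitted model only knows those); probability vectors are
    expanded to the full 1..C space with zeros elsewhere.
    """

    view_id: str
    model: object
    feature_ids: list[str]
    n_classes: int
    classes_seen: np.ndarray

    def _align(self, view: ViewTable) -> np.ndarray:
        try:
            return view.data.loc[:, self.feature_ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise IntegrityError(
                f"view {view.view_id!r} lacks training feature(s): {exc}"
            ) from None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(X))

    def predict_proba_full(self, X: np.ndarray) -> np.ndarray:
        """Class probability vectors over all C classes, rows summing to 1."""
        raw = np.asarray(self.model.predict_proba(X))
        out = np.zeros((X.shape[0], self.n_classes))
        for k, c in enumerate(self.classes_seen):
            out[:, int(c) - 1] = raw[:, k]
        return out


@dataclass
class WeakRound:
    """One boosting iteration: winning view, hypothesis, edge, vote weight.

    Rounds whose edge is non-positive keep ``alpha = 0`` and are retained
    for auditability (they still counted for the bandit and the winner
    tally) but contribute nothing to the combined classifier.
    """

    t: int
    view_id: str
    j: int
    hypothesis: WeakHypothesis | None
    edge: float
    alpha: float


@dataclass
class Ensemble:
    """Ordered weak rounds plus the winner-frequency tally."""

    kind: str  # "irboost" | "rboost"
    rounds: list[WeakRound]
    encoding: object  # LabelEncoding
    n_classes: int
    winner_counts: dict
    T: int
    params: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    @property
    def winner_shares(self) -> dict:
        return {v: c / self.T for v, c in self.winner_counts.items()}

    def predict(self, ds: MultiViewDataset):
        return predict_ensemble(self, ds)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Versioned archive: text manifest + serialized base models."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "kind": self.kind,
            "n_classes": self.n_classes,
            "classes": list(self.encoding.classes),
            "winner_counts": self.winner_counts,
            "T": self.T,
            "params": {
                k: v for k, v in self.params.items() if _jsonable(v)
            },
            "rounds": [
                {
                    "t": r.t,
                    "view_id": r.view_id,
                    "j": r.j,
                    "edge": r.edge,
                    "alpha": r.alpha,
                }
                for r in self.rounds
            ],
            "trace": self.trace,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(path / "models.pkl", "wb") as fh:
            pickle.dump([r.hypothesis for r in self.rounds], fh)

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        from .data_model import LabelEncoding

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("format_version") != 1:
            raise ParameterError("unsupported model archive version")
        with open(path / "models.pkl", "rb") as fh:
            hyps = pickle.load(fh)
        rounds = [
            WeakRound(
                t=r["t"],
                view_id=r["view_id"],
                j=r["j"],
                hypothesis=h,
                edge=r["edge"],
                alpha=r["alpha"],
            )
            for r, h in zip(manifest["rounds"], hyps)
        ]
        return cls(
            kind=manifest["kind"],
            rounds=rounds,
            encoding=LabelEncoding(classes=tuple(manifest["classes"])),
            n_classes=manifest["n_classes"],
            winner_counts=manifest["winner_counts"],
            T=manifest["T"],
            params=manifest.get("params", {}),
            trace=manifest.get("trace", []),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def agreement_indicator(a, b) -> int:
    """1 iff the two labels agree, else 0 (the multi-class analogue of the
    plus/minus-1 label product)."""
    return int(a == b)


def modified_predict(h: WeakHypothesis, view: ViewTable, sample_id: str) -> int:
    """The hypothesis' label for a present sample; the artificial label 0
    for a sample absent from the view (0 never equals a real class)."""
    if not view.contains(sample_id):
        return 0
    X = view.data.loc[[sample_id], h.feature_ids].to_numpy(dtype=float)
    return int(h.predict(X)[0])


def modified_proba(h: WeakHypothesis, view: ViewTable, sample_id: str) -> np.ndarray:
    """The hypothesis' class-probability vector, or the zero vector for a
    sample absent from the view (the zero vector is still used, harmlessly,
    in the prediction-phase weighted sum)."""
    if not view.contains(sample_id):
        return np.zeros(h.n_classes)
    X = view.data.loc[[sample_id], h.feature_ids].to_numpy(dtype=float)
    return h.predict_proba_full(X)[0]


def _signed_agreement(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """+1.0 where the labels agree, -1.0 where they disagree."""
    return np.where(y_pred == y_true, 1.0, -1.0)


def compute_edge(
    w: np.ndarray,
    y_pred: np.ndarray,
    y_true: np.ndarray,
    present_mask: np.ndarray | None = None,
) -> float:
    """Weighted agreement edge, summed over the view's present samples only.

    Equals ``2 * sum_i w_i (I[y_i = y_hat_i] - 1/2)`` restricted to the
    present samples; absent samples contribute exactly zero.  In the binary
    plus/minus-1 case this is identically ``sum_i w_i y_i h_i``.
    """
    sgn = _signed_agreement(y_true, y_pred)
    if present_mask is None:
        return float(np.sum(w * sgn))
    return float(np.sum(w[present_mask] * sgn[present_mask]))


def compute_alpha(edge: float, clip: float = _ALPHA_CLIP) -> float:
    """Vote weight ``0.5 * ln((1+e)/(1-e))`` with ``e`` clipped away from
    plus/minus 1 so a perfect (or perfectly wrong) round stays finite."""
    e = min(max(edge, -1.0 + clip), 1.0 - clip)
    return 0.5 * float(np.log((1.0 + e) / (1.0 - e)))


def update_weights(
    w: np.ndarray,
    alpha: float,
    sgn: np.ndarray,
    present_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multiply present samples' weights by ``exp(-alpha * sgn)`` and
    renormalize over all samples.  Absent samples keep their weight up to
    the renormalization (their multiplier is exp(0) = 1)."""
    out = w.copy()
    if present_mask is None:
        out = out * np.exp(-alpha * sgn)
    else:
        out[present_mask] = out[present_mask] * np.exp(-alpha * sgn[present_mask])
    total = out.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError(
            "boosting weights underflowed; reduce T or the vote-weight clip"
        )
    return out / total


# ---------------------------------------------------------------------------
# Fitting loops
# ---------------------------------------------------------------------------


def _view_alignment(ds: MultiViewDataset, j: int) -> tuple[np.ndarray, np.ndarray]:
    """(mask over all_samples, X rows ordered to match the masked order)."""
    view = ds.views[j]
    mask = ds.membership_mask(j)
    if view.is_empty:
        return mask, np.zeros((0, view.n_features))
    pos = {s: r for r, s in enumerate(view.sample_ids)}
    order = [pos[s] for s, m in zip(ds.all_samples, mask) if m]
    return mask, view.values[order]


def fit_irboost(
    ds: MultiViewDataset,
    T: int = DEFAULT_T,
    base_learner: str | Callable = "rf",
    sigma: float = DEFAULT_SIGMA,
    gamma: float = DEFAULT_GAMMA,
    seed=None,
    record_weights: bool = False,
) -> Ensemble:
    """Fit the multi-class, incomplete-view boosting ensemble.

    Per iteration: bandit draw -> weak fit on the winning view's present
    samples (restricted, renormalized weights) -> modified predictions over
    N -> edge -> bandit reward -> vote weight -> shared-weight update.
    Deterministic under a fixed seed.  A selected view that is empty or
    whose learner fails yields a recorded zero-weight round (reward 0).
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    rng = np.random.default_rng(seed)
    state = init_bandit(ds.n_views, sigma=sigma, gamma=gamma, rng=rng)
    n = ds.n_samples
    y = ds.y
    w = np.full(n, 1.0 / n)
    aligned = [_view_alignment(ds, j) for j in range(ds.n_views)]

    rounds: list[WeakRound] = []
    winner_counts: dict = {v: 0 for v in ds.view_ids}
    trace: list = []

    for t in range(T):
        j = select_view(state)
        fit_seed = int(rng.integers(0, 2**31))
        p_sel = float(state.p[j])
        view = ds.views[j]
        winner_counts[view.view_id] += 1
        mask, Xj = aligned[j]

        hyp = None
        edge = 0.0
        alpha = 0.0
        if Xj.shape[0] > 0:
            try:
                w_fit = w[mask]
                w_fit = w_fit / w_fit.sum()
                model = make_base_learner(base_learner, fit_seed)
                model.fit(Xj, y[mask], sample_weight=w_fit)
                hyp = WeakHypothesis(
                    view_id=view.view_id,
                    model=model,
                    feature_ids=view.feature_ids,
                    n_classes=ds.n_classes,
                    classes_seen=np.asarray(model.classes_),
                )
                y_hat = np.zeros(n, dtype=int)  # artificial label 0 if absent
                y_hat[mask] = hyp.predict(Xj).astype(int)
                sgn = _signed_agreement(y, y_hat)
                edge = float(np.sum(w[mask] * sgn[mask]))
                alpha_signed = compute_alpha(edge)
                alpha = alpha_signed if edge > 0 else 0.0
            except Exception:  # base-learner failure: skip round, reward 0
                hyp, edge, alpha = None, 0.0, 0.0

        update_bandit(state, j, edge)
        if hyp is not None and alpha > 0:
            w[mask] = w[mask] * np.exp(-alpha * sgn[mask])
            w = w / w.sum()
        rounds.append(
            WeakRound(t=t, view_id=view.view_id, j=j, hypothesis=hyp,
                      edge=edge, alpha=alpha)
        )
        entry = {
            "t": t,
            "view_id": view.view_id,
            "j": j,
            "p_selected": p_sel,
            "edge": edge,
            "reward": edge,
            "alpha": alpha,
            "p": state.p.tolist(),
        }
        if record_weights:
            entry["w"] = w.tolist()
        trace.append(entry)

    return Ensemble(
        kind="irboost",
        rounds=rounds,
        encoding=ds.encoding,
        n_classes=ds.n_classes,
        winner_counts=winner_counts,
        T=T,
        params={
            "sigma": sigma,
            "gamma": gamma,
            "T": T,
            "seed": seed,
            "base_learner": base_learner if isinstance(base_learner, str) else "custom",
        },
        trace=trace,
    )


def fit_rboost_binary(
    ds: MultiViewDataset,
    T: int = DEFAULT_T,
    base_learner: str | Callable = "rf",
    sigma: float = DEFAULT_SIGMA,
    gamma: float = DEFAULT_GAMMA,
    seed=None,
    record_weights: bool = False,
) -> Ensemble:
    """Fit the binary, complete-view predecessor in plus/minus-1 arithmetic.

    The edge is ``sum_i w_i y_i h(x_i)`` and the final classifier is the
    sign of the alpha-weighted sum of the weak hypotheses.  Raises on more
    than two classes (use :func:`fit_irboost`) or incomplete views (the
    evaluation harness pairs this method with mean imputation instead).
    """
    if T < 1:
        raise ParameterError(f"T must be >= 1, got {T}")
    if ds.n_classes != 2:
        raise ParameterError(
            f"rboost handles exactly two classes, got {ds.n_classes}; "
            "use fit_irboost for multi-class tasks"
        )
    if not ds.is_complete():
        raise IntegrityError(
            "rboost requires complete views; impute first "
            "(baselines.mean_impute_union) or use fit_irboost"
        )
    rng = np.random.default_rng(seed)
    state = init_bandit(ds.n_views, sigma=sigma, gamma=gamma, rng=rng)
    n = ds.n_samples
    # internal class 1 -> -1, class 2 -> +1
    y_pm = np.where(ds.y == 1, -1.0, 1.0)
    w = np.full(n, 1.0 / n)
    aligned = [_view_alignment(ds, j) for j in range(ds.n_views)]

    rounds: list[WeakRound] = []
    winner_counts: dict = {v: 0 for v in ds.view_ids}
    trace: list = []

    for t in range(T):
        j = select_view(state)
        fit_seed = int(rng.integers(0, 2**31))
        p_sel = float(state.p[j])
        view = ds.views[j]
        winner_counts[view.view_id] += 1
        mask, Xj = aligned[j]

        hyp = None
        edge = 0.0
        alpha = 0.0
        try:
            w_fit = w[mask]
            w_fit = w_fit / w_fit.sum()
            model = make_base_learner(base_learner, fit_seed)
            model.fit(Xj, y_pm[mask], sample_weight=w_fit)
            hyp = WeakHypothesis(
                view_id=view.view_id,
                model=model,
                feature_ids=view.feature_ids,
                n_classes=2,
                classes_seen=np.asarray([1, 2]),  # -1 -> class 1, +1 -> class 2
            )
            h_pm = np.zeros(n)
            h_pm[mask] = np.asarray(model.predict(Xj), dtype=float)
            sgn = _signed_agreement(y_pm, h_pm)  # == y_pm * h_pm on {+-1}
            edge = float(np.sum(w[mask] * sgn[mask]))
            alpha_signed = compute_alpha(edge)
            alpha = alpha_signed if edge > 0 else 0.0
        except Exception:
            hyp, edge, alpha = None, 0.0, 0.0

        update_bandit(state, j, edge)
        if hyp is not None and alpha > 0:
            w[mask] = w[mask] * np.exp(-alpha * sgn[mask])
            w = w / w.sum()
        rounds.append(
            WeakRound(t=t, view_id=view.view_id, j=j, hypothesis=hyp,
                      edge=edge, alpha=alpha)
        )
        entry = {
            "t": t,
            "view_id": view.view_id,
            "j": j,
            "p_selected": p_sel,
            "edge": edge,
            "reward": edge,
            "alpha": alpha,
            "p": state.p.tolist(),
        }
        if record_weights:
            entry["w"] = w.tolist()
        trace.append(entry)

    return Ensemble(
        kind="rboost",
        rounds=rounds,
        encoding=ds.encoding,
        n_classes=2,
        winner_counts=winner_counts,
        T=T,
        params={
            "sigma": sigma,
            "gamma": gamma,
            "T": T,
            "seed": seed,
            "base_learner": base_learner if isinstance(base_learner, str) else "custom",
        },
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_ensemble(ens: Ensemble, ds: MultiViewDataset):
    """Combined prediction for every sample of ``ds``.

    For the multi-class ensemble the score is the alpha-weighted sum of the
    rounds' modified class-probability vectors (zero vectors where the
    instance is absent from the round's view); the label is the argmax with
    ties broken toward the smallest class index; the returned score matrix
    is row-normalized to sum 1.  For the binary predecessor the label is the
    sign of the alpha-weighted hypothesis sum and no probability scores are
    produced (``scores`` is None).

    Raises :class:`UnpredictableError` for instances absent from every view
    used by a positive-weight round.
    """
    n = ds.n_samples
    active = [r for r in ens.rounds if r.alpha > 0 and r.hypothesis is not None]
    if not active:
        raise UnpredictableError("ensemble has no positive-weight rounds")

    view_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _aligned_for(hyp: WeakHypothesis):
        if hyp.view_id not in view_cache:
            vj = ds.view(hyp.view_id)
            jj = ds.view_ids.index(hyp.view_id)
            mask = ds.membership_mask(jj)
            if vj.is_empty:
                X = np.zeros((0, len(hyp.feature_ids)))
            else:
                pos = {s: r for r, s in enumerate(vj.sample_ids)}
                order = [pos[s] for s, m in zip(ds.all_samples, mask) if m]
                X = vj.data.loc[:, hyp.feature_ids].to_numpy(dtype=float)[order]
            view_cache[hyp.view_id] = (mask, X)
        return view_cache[hyp.view_id]

    covered = np.zeros(n, dtype=bool)
    if ens.kind == "rboost":
        score = np.zeros(n)
        for r in active:
            mask, X = _aligned_for(r.hypothesis)
            if X.shape[0]:
                score[mask] += r.alpha * np.asarray(
                    r.hypothesis.predict(X), dtype=float
                )
            covered |= mask
        _require_covered(ds, covered)
        # sign; a zero total ties toward the smallest class index (class 1)
        codes = np.where(score > 0, 2, 1)
        labels = ens.encoding.decode(codes)
        return labels, None

    F = np.zeros((n, ens.n_classes))
    for r in active:
        mask, X = _aligned_for(r.hypothesis)
        if X.shape[0]:
            F[mask] += r.alpha * r.hypothesis.predict_proba_full(X)
        covered |= mask
    _require_covered(ds, covered)
    totals = F.sum(axis=1)
    if (totals <= 0).any():
        bad = [ds.all_samples[i] for i in np.flatnonzero(totals <= 0)]
        raise UnpredictableError(f"no usable view for instance(s): {bad}")
    codes = np.argmax(F, axis=1) + 1  # argmax ties -> smallest class index
    labels = ens.encoding.decode(codes)
    scores = F / totals[:, None]
    return labels, scores


def _require_covered(ds: MultiViewDataset, covered: np.ndarray) -> None:
    if not covered.all():
        bad = [ds.all_samples[i] for i in np.flatnonzero(~covered)]
        raise UnpredictableError(
            f"instance(s) absent from every view used by the ensemble: {bad}"
        )
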