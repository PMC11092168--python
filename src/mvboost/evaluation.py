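"""Cross-validated model comparison.

The protocol: a k-fold plan (default 10) assigns every sample of ``N`` to
exactly ONE global fold — a sample shared by several views must never sit
in the training split of one view and the test split of another — while
keeping each view's induced split near-equal-sized and approximately
stratified by class.  Out-of-fold predictions are pooled and scored with
precision, recall, F1, accuracy (macro-averaged over classes by default;
a weighted mode is available) and one-vs-rest macro AUC from the ensembles'
normalized score vectors, all reported as percentages.  The binary
predecessor reports no AUC since it returns a label, not a score.

Method comparisons use two-sided Wilcoxon signed-rank tests on per-fold
paired scores, with Benjamini–Hochberg false-discovery-rate correction
across the comparisons.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from statsmodels.stats.multitest import multipletests

from .baselines import fit_concat, fit_single_view, imputation_means, mean_impute_union
from .boosting import fit_irboost, fit_rboost_binary, predict_ensemble
from .data_model import (
    MultiViewDataset,
    ParameterError,
    restrict_to_samples,
)

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "make_folds",
    "evaluate_method",
    "wilcoxon_fdr",
    "benjamini_hochberg",
    "summary_table",
    "METHODS",
]

METHODS = ("irboost", "rboost", "concat-rf", "rf-sv")


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """One global fold per sample; induced per-view splits stay balanced."""

    k: int
    assignment: dict  # sample_id -> fold index
    seed: int | None = None

    def fold_of(self, sample_id: str) -> int:
        return self.assignment[sample_id]

    def test_samples(self, f: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g == f]

    def train_samples(self, f: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g != f]

    def induced_sizes(self, ds: MultiViewDataset) -> dict:
        """view_id -> list of that view's samples per fold."""
        out = {}
        for j, v in enumerate(ds.views):
            counts = [0] * self.k
            for s in v.sample_ids:
                counts[self.assignment[s]] += 1
            out[v.view_id] = counts
        return out


def make_folds(ds: MultiViewDataset, k: int = 10, seed: int | None = None) -> FoldPlan:
    """Greedy balanced assignment.

    Samples are grouped by view-membership pattern; patterns spanning more
    views are placed first, and each sample goes to the fold minimizing
    (in order) the summed then the maximum induced count of the views it
    belongs to, then the fold's count of its class, then the fold total.
    This keeps every view's induced fold sizes within one of each other for
    the membership structures that arise from overlapping cohorts, which
    the test suite verifies constructively.
    """
    n = ds.n_samples
    if k < 2:
        raise ParameterError(f"need k >= 2 folds, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the {n} available samples")
    counts = np.bincount(ds.y, minlength=ds.n_classes + 1)[1:]
    if (counts < k).any():
        warnings.warn(
            "some class has fewer samples than folds; stratification relaxed",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pos = {s: i for i, s in enumerate(ds.all_samples)}

    groups: dict[tuple, list[str]] = defaultdict(list)
    for i, s in enumerate(ds.all_samples):
        pat = tuple(
            j for j in range(ds.n_views) if ds.membership_mask(j)[i]
        )
        groups[pat].append(s)

    view_cnt = np.zeros((ds.n_views, k), dtype=int)
    class_cnt = np.zeros((ds.n_classes + 1, k), dtype=int)
    total = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}

    for pat in sorted(groups, key=lambda p: (-len(p), p)):
        members = groups[pat]
        order = rng.permutation(len(members))
        for idx in order:
            s = members[idx]
            c = int(ds.y[pos[s]])
            tie = rng.random(k)
            best = min(
                range(k),
                key=lambda f: (
                    int(view_cnt[list(pat), f].sum()),
                    int(view_cnt[list(pat), f].max()),
                    int(class_cnt[c, f]),
                    int(total[f]),
                    tie[f],
                ),
            )
            assignment[s] = best
            for j in pat:
                view_cnt[j, best] += 1
            class_cnt[c, best] += 1
            total[best] += 1

    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Pooled out-of-fold performance, each metric a percentage in [0, 100]."""

    method: str
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None
    n: int
    averaging: str = "macro"
    winner_share: dict | None = None
    per_fold: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "n": self.n,
        }


def _score(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None,
    n_classes: int,
    average: str = "macro",
) -> dict:
    labels = np.arange(1, n_classes + 1)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=average, zero_division=0
    )
    acc = accuracy_score(y_true, y_pred)
    auc = None
    if scores is not None:
        try:
            if n_classes == 2:
                auc = roc_auc_score((y_true == 2).astype(int), scores[:, 1])
            else:
                auc = roc_auc_score(
                    y_true, scores, multi_class="ovr", average=average,
                    labels=labels,
                )
        except ValueError:
            auc = None  # a class absent from the test pool: undefined
    return {
        "precision": 100.0 * prec,
        "recall": 100.0 * rec,
        "f1": 100.0 * f1,
        "accuracy": 100.0 * acc,
        "auc": 100.0 * auc if auc is not None else None,
    }


def _fold_seed(seed: int | None, f: int) -> int:
    ss = np.random.SeedSequence(entropy=0 if seed is None else int(seed),
                                spawn_key=(f,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Method evaluation
# ---------------------------------------------------------------------------


def evaluate_method(
    method: str,
    ds: MultiViewDataset,
    plan: FoldPlan,
    base_learner="rf",
    sigma: float = 0.15,
    gamma: float = 0.3,
    T: int = 50,
    seed: int | None = 0,
    average: str = "macro",
):
    """Cross-validate one method under the fold plan.

    ``method`` is one of ``irboost``, ``rboost`` (mean-imputed when views
    are incomplete), ``concat-rf``, or ``rf-sv``.  The first three return a
    :class:`MetricsReport`; ``rf-sv`` returns a dict with one report per
    view plus ``worst`` / ``average`` / ``best`` summaries across views.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "rf-sv":
        return _evaluate_single_views(ds, plan, base_learner, seed, average)

    enc = ds.encoding
    y_true_all, y_pred_all, score_rows = [], [], []
    per_fold = []
    winner_acc: dict[str, list[float]] = defaultdict(list)

    for f in range(plan.k):
        train = plan.train_samples(f)
        test = plan.test_samples(f)
        ds_tr = restrict_to_samples(ds, train)
        ds_te = restrict_to_samples(ds, test)
        fs = _fold_seed(seed, f)

        if method == "irboost":
            ens = fit_irboost(
                ds_tr, T=T, base_learner=base_learner, sigma=sigma,
                gamma=gamma, seed=fs,
            )
            labels, scores = predict_ensemble(ens, ds_te)
            for vid, share in ens.winner_shares.items():
                winner_acc[vid].append(share)
        elif method == "rboost":
            if ds_tr.is_complete():
                ds_tr_c, ds_te_c = ds_tr, ds_te
            else:
                means = imputation_means(ds_tr)
                ds_tr_c = mean_impute_union(ds_tr, means=means)
                ds_te_c = mean_impute_union(ds_te, means=means)
            ens = fit_rboost_binary(
                ds_tr_c, T=T, base_learner=base_learner, sigma=sigma,
                gamma=gamma, seed=fs,
            )
            labels, scores = predict_ensemble(ens, ds_te_c)
            for vid, share in ens.winner_shares.items():
                winner_acc[vid].append(share)
            ds_te = ds_te_c
        else:  # concat-rf
            m = fit_concat(ds_tr, base_learner=base_learner, seed=fs)
            labels = m.predict(ds_te)
            scores = m.predict_proba(ds_te)

        y_t = enc.encode(ds_te.labels[s] for s in ds_te.all_samples)
        y_p = enc.encode(labels)
        y_true_all.append(y_t)
        y_pred_all.append(y_p)
        if scores is not None:
            score_rows.append(scores)
        per_fold.append(
            {"fold": f, **_score(y_t, y_p, scores, ds.n_classes, average)}
        )

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    scores = np.vstack(score_rows) if score_rows else None
    pooled = _score(y_true, y_pred, scores, ds.n_classes, average)
    return MetricsReport(
        method=method,
        n=len(y_true),
        averaging=average,
        winner_share={v: float(np.mean(x)) for v, x in winner_acc.items()}
        or None,
        per_fold=per_fold,
        **pooled,
    )


def _evaluate_single_views(ds, plan, base_learner, seed, average):
    enc = ds.encoding
    out: dict[str, MetricsReport] = {}
    for v in ds.views:
        y_true_all, y_pred_all, score_rows = [], [], []
        per_fold = []
        for f in range(plan.k):
            train = set(plan.train_samples(f))
            test = set(plan.test_samples(f))
            tr = v.subset(train)
            te = v.subset(test)
            if tr.is_empty or te.is_empty:
                continue
            m = fit_single_view(
                tr, ds.labels, base_learner=base_learner,
                seed=_fold_seed(seed, f), encoding=enc,
            )
            labels = m.predict(te)
            scores = m.predict_proba(te)
            y_t = enc.encode(ds.labels[s] for s in te.sample_ids)
            y_p = enc.encode(labels)
            y_true_all.append(y_t)
            y_pred_all.append(y_p)
            score_rows.append(scores)
            per_fold.append(
                {"fold": f, **_score(y_t, y_p, scores, ds.n_classes, average)}
            )
        y_true = np.concatenate(y_true_all)
        y_pred = np.concatenate(y_pred_all)
        scores = np.vstack(score_rows)
        pooled = _score(y_true, y_pred, scores, ds.n_classes, average)
        out[v.view_id] = MetricsReport(
            method=f"rf-sv[{v.view_id}]",
            n=len(y_true),
            averaging=average,
            per_fold=per_fold,
            **pooled,
        )

    summary = {}
    for stat, fn in [("worst", min), ("average", np.mean), ("best", max)]:
        summary[stat] = {}
        for metric in ("precision", "recall", "f1", "accuracy", "auc"):
            vals = [
                getattr(r, metric)
                for r in out.values()
                if getattr(r, metric) is not None
            ]
            summary[stat][metric] = float(fn(vals)) if vals else None
    return {"per_view": out, **summary}


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment: sorted ``p_(i) * m / i`` with cumulative-min
    enforcement (monotone in the sorted raw p-values)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def wilcoxon_fdr(comparisons: Mapping[str, tuple]) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank test per comparison, BH-corrected.

    ``comparisons`` maps a name to a pair of equal-length paired score
    sequences (e.g. per-fold F1 of two methods).  Identical pairs give
    p = 1 with a warning.  Requires at least 5 pairs per comparison.
    """
    names, raw = [], []
    for name, (a, b) in comparisons.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ParameterError(f"{name}: paired scores differ in length")
        if a.size < 5:
            raise ParameterError(
                f"{name}: need >= 5 paired observations, got {a.size}"
            )
        d = a - b
        if np.all(d == 0):
            warnings.warn(f"{name}: all paired differences are zero; p = 1",
                          stacklevel=2)
            p = 1.0
        else:
            p = float(wilcoxon(a, b, alternative="two-sided").pvalue)
        names.append(name)
        raw.append(p)
    adj = benjamini_hochberg(raw)
    return pd.DataFrame(
        {"comparison": names, "p_raw": raw, "p_adj": adj}
    ).set_index("comparison")


def summary_table(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Tidy summary: one row per method, metric columns as percentages."""
    rows = []
    for name, r in reports.items():
        d = r.as_dict()
        d["method"] = name
        rows.append(d)
    return pd.DataFrame(rows).set_index("method")
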