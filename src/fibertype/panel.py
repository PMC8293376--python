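"""Discriminative peptide-panel selection (RF-based recursive elimination).

Implements the fiber-type peptide selection pipeline: random-forest
importances over peptides, recursive feature elimination down to a minimal
panel whose cross-validated accuracy stays within tolerance of the best
observed panel, an interpretable binary threshold decision tree over the
selected peptides, and confirmation of a panel on an independent data set
with small-class exclusion.

All estimators are seeded; accuracy estimates are invariant to sample and
peptide ordering because inputs are canonically sorted before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold

from .matrix import PeptideMatrix

DEFAULT_N_TREES = 500


def _canonical(X: pd.DataFrame, y) -> tuple[pd.DataFrame, pd.Series]:
    """Sort samples and feature columns so results do not depend on order."""
    y = pd.Series(np.asarray(y), index=X.index)
    Xs = X.sort_index().sort_index(axis=1)
    return Xs, y.loc[Xs.index]


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _check_classes(y: pd.Series, min_per_class: int = 2) -> None:
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < min_per_class).any():
        small = counts[counts < min_per_class].index.tolist()
        raise ValueError(f"class(es) with < {min_per_class} samples: {small}")


# ---------------------------------------------------------------------------
# Importances
# ---------------------------------------------------------------------------

def rf_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    method: str = "permutation",
    n_repeats: int = 10,
) -> pd.Series:
    """Peptide importances from a seeded random forest.

    ``method='permutation'`` (default) reports mean accuracy drop when a
    peptide's column is permuted; ``method='impurity'`` reports the forest's
    Gini importances (cheaper, used inside the elimination loop).
    """
    X, y = _canonical(X, y)
    _check_classes(y)
    if X.isna().to_numpy().any():
        raise ValueError("missing values present; impute upstream")
    forest = _forest(n_trees, seed).fit(X.to_numpy(), y)
    if method == "impurity":
        imp = forest.feature_importances_
    elif method == "permutation":
        res = permutation_importance(
            forest, X.to_numpy(), y, n_repeats=n_repeats, random_state=seed
        )
        imp = res.importances_mean
    else:
        raise ValueError("method must be 'permutation' or 'impurity'")
    return pd.Series(imp, index=X.columns, name="importance")


# ---------------------------------------------------------------------------
# Accuracy estimation
# ---------------------------------------------------------------------------

def evaluate_panel(
    X: pd.DataFrame,
    y,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[float, np.ndarray, pd.Series]:
    """Repeated stratified k-fold accuracy of a peptide panel.

    Returns (mean accuracy over folds, per-fold accuracies, per-class
    accuracy pooled over all held-out predictions).
    """
    X, y = _canonical(X, y)
    if X.shape[1] == 0:
        raise ValueError("empty panel")
    counts = y.value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise ValueError(
            f"stratification impossible: class(es) {small} have fewer than "
            f"{folds} samples"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    fold_acc = []
    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    xv, yv = X.to_numpy(), y.to_numpy()
    for train, test in cv.split(xv, yv):
        clf = _forest(n_trees, seed).fit(xv[train], yv[train])
        pred = clf.predict(xv[test])
        fold_acc.append(float(np.mean(pred == yv[test])))
        for truth, p in zip(yv[test], pred):
            total[truth] = total.get(truth, 0) + 1
            correct[truth] = correct.get(truth, 0) + int(truth == p)
    per_class = pd.Series(
        {c: correct[c] / total[c] for c in sorted(total)}, name="accuracy"
    )
    return float(np.mean(fold_acc)), np.asarray(fold_acc), per_class


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    """Outcome of the recursive elimination."""

    elimination_trace: list[tuple[tuple[str, ...], float]]
    selected_panel: list[str]
    selected_accuracy: float
    importances: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "selected_panel": list(self.selected_panel),
            "selected_accuracy": self.selected_accuracy,
            "trace": [
                {"panel_size": len(p), "panel": list(p), "accuracy": a}
                for p, a in self.elimination_trace
            ],
        }


def rfe(
    X: pd.DataFrame,
    y,
    drop_fraction: float = 0.2,
    min_panel: int = 1,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    tolerance: float = 0.005,
    importance: str = "impurity",
) -> PanelResult:
    """Random-forest recursive feature elimination over peptides.

    Each round estimates the cross-validated accuracy of the current panel,
    then removes the ``ceil(drop_fraction * size)`` least-important peptides
    (at least one, never past ``min_panel``), recording (panel, accuracy)
    down to ``min_panel``.  The selected panel is the smallest whose
    accuracy is within ``tolerance`` of the trace maximum; remaining ties
    are broken toward the smaller panel and then lexicographic peptide
    order.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if min_panel < 1:
        raise ValueError("min_panel must be >= 1")
    X, y = _canonical(X, y)
    if min_panel > X.shape[1]:
        raise ValueError(
            f"min_panel={min_panel} exceeds number of peptides ({X.shape[1]})"
        )
    _check_classes(y)

    features = list(X.columns)
    full_importances: pd.Series | None = None
    trace: list[tuple[tuple[str, ...], float]] = []
    while True:
        acc, _, _ = evaluate_panel(
            X[features], y, folds=folds, repeats=repeats, seed=seed, n_trees=n_trees
        )
        trace.append((tuple(features), acc))
        if len(features) <= min_panel:
            break
        imp = rf_importance(
            X[features], y, n_trees=n_trees, seed=seed, method=importance
        )
        if full_importances is None:
            full_importances = imp
        n_drop = max(1, math.ceil(drop_fraction * len(features)))
        n_drop = min(n_drop, len(features) - min_panel)
        # stable ordering: importance ascending, then peptide name
        order = sorted(features, key=lambda f: (imp[f], f))
        dropped = set(order[:n_drop])
        features = [f for f in features if f not in dropped]

    best = max(a for _, a in trace)
    eligible = [(p, a) for p, a in trace if a >= best - tolerance]
    panel, acc = min(eligible, key=lambda pa: (len(pa[0]), sorted(pa[0])))
    if full_importances is None:  # started at min_panel already
        full_importances = rf_importance(
            X[features], y, n_trees=n_trees, seed=seed, method=importance
        )
    return PanelResult(
        elimination_trace=trace,
        selected_panel=sorted(panel),
        selected_accuracy=acc,
        importances=full_importances,
    )


# ---------------------------------------------------------------------------
# Threshold decision tree
# ---------------------------------------------------------------------------

@dataclass
class DecisionNode:
    """Internal node (peptide, threshold) or leaf (label, class counts)."""

    peptide: str | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None  # value <= threshold
    right: "DecisionNode | None" = None
    label: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.peptide is None

    @property
    def is_pure(self) -> bool:
        return self.is_leaf and sum(v > 0 for v in self.counts.values()) == 1


@dataclass
class DecisionRule:
    """Binary threshold tree over panel peptide log2 intensities."""

    root: DecisionNode
    peptides: list[str]

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.peptides if p not in X.columns]
        if missing:
            raise ValueError(f"input lacks panel peptides: {missing}")

        def route(row) -> str:
            node = self.root
            while not node.is_leaf:
                v = row[node.peptide]
                node = node.left if v <= node.threshold else node.right
            return node.label

        return pd.Series([route(r) for _, r in X.iterrows()], index=X.index,
                         name="predicted")

    def leaves(self) -> list[DecisionNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend([n.right, n.left])
        return out

    def n_internal(self) -> int:
        count, stack = 0, [self.root]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                count += 1
                stack.extend([n.right, n.left])
        return count

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(node: DecisionNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}-> {node.label}  {node.counts}")
            else:
                lines.append(f"{pad}{node.peptide} <= {node.threshold:.4f}:")
                rec(node.left, indent + 1)
                lines.append(f"{pad}{node.peptide} >  {node.threshold:.4f}:")
                rec(node.right, indent + 1)

        rec(self.root, 0)
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        rows: list[dict] = []

        def rec(node: DecisionNode) -> int:
            node_id = len(rows)
            rows.append({})
            if node.is_leaf:
                rows[node_id] = {
                    "node": node_id, "peptide": "", "threshold": np.nan,
                    "left": -1, "right": -1, "label": node.label,
                    "counts": ";".join(f"{k}:{v}" for k, v in sorted(node.counts.items())),
                }
            else:
                left = rec(node.left)
                right = rec(node.right)
                rows[node_id] = {
                    "node": node_id, "peptide": node.peptide,
                    "threshold": node.threshold, "left": left, "right": right,
                    "label": "", "counts": "",
                }
            return node_id

        rec(self.root)
        return pd.DataFrame(rows).set_index("node").sort_index()


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def build_decision_tree(
    X: pd.DataFrame, y, min_leaf: int = 1
) -> DecisionRule:
    """Greedy CART over 1-3 panel peptides with midpoint thresholds.

    Splits minimize weighted Gini impurity; each candidate threshold is the
    midpoint between two adjacent distinct training values.  On separable
    training data every terminal node is pure; degenerate inputs (identical
    samples with different labels) yield an impure leaf, not an error.
    """
    X, y = _canonical(X, y)
    if not 1 <= X.shape[1] <= 3:
        raise ValueError("decision tree is designed for panels of 1-3 peptides")
    classes = sorted(set(y))
    counts_all = y.value_counts()
    if min_leaf > counts_all.min():
        raise ValueError(
            f"min_leaf={min_leaf} exceeds the smallest class size "
            f"({int(counts_all.min())})"
        )

    def counts_of(yy: np.ndarray) -> dict[str, int]:
        return {c: int((yy == c).sum()) for c in classes if (yy == c).sum()}

    def majority(yy: np.ndarray) -> str:
        cnt = pd.Series(yy).value_counts()
        top = cnt[cnt == cnt.max()].index
        return sorted(top)[0]  # deterministic tie-break

    def grow(xv: np.ndarray, yy: np.ndarray, feats: list[str]) -> DecisionNode:
        if len(set(yy)) == 1:
            return DecisionNode(label=yy[0], counts=counts_of(yy))
        best = None  # (impurity, feat_idx, threshold)
        n = len(yy)
        for j, feat in enumerate(feats):
            vals = xv[:, j]
            uniq = np.unique(vals)
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = 0.5 * (lo + hi)
                left = vals <= thr
                nl = int(left.sum())
                if nl < min_leaf or n - nl < min_leaf:
                    continue
                cl = np.array([(yy[left] == c).sum() for c in classes])
                cr = np.array([(yy[~left] == c).sum() for c in classes])
                imp = (nl * _gini(cl) + (n - nl) * _gini(cr)) / n
                cand = (imp, feat, thr)
                if best is None or cand < best:
                    best = cand
        parent_imp = _gini(np.array([(yy == c).sum() for c in classes]))
        if best is None or best[0] >= parent_imp:
            return DecisionNode(label=majority(yy), counts=counts_of(yy))
        _, feat, thr = best
        j = feats.index(feat)
        mask = xv[:, j] <= thr
        return DecisionNode(
            peptide=feat,
            threshold=thr,
            left=grow(xv[mask], yy[mask], feats),
            right=grow(xv[~mask], yy[~mask], feats),
        )

    root = grow(X.to_numpy(dtype=float), y.to_numpy(), list(X.columns))
    return DecisionRule(root=root, peptides=list(X.columns))


# ---------------------------------------------------------------------------
# Confirmation on independent data
# ---------------------------------------------------------------------------

@dataclass
class ConfirmationReport:
    """Result of applying a trained panel classifier to an external set."""

    mapped_peptides: list[str]
    excluded_classes: list[str]
    n_used: int
    accuracy: float
    per_class_accuracy: pd.Series


def zscore_features(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scoring (per-data-set harmonization of panel peptides)."""
    sd = X.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(
            f"constant panel peptide(s): {list(sd.index[sd == 0])}"
        )
    return (X - X.mean()) / sd


def panel_features(
    matrix: PeptideMatrix, panel: list[str], drop_incomplete: bool = True
) -> pd.DataFrame:
    """Sample x peptide log2 intensity table restricted to the panel."""
    missing = [p for p in panel if p not in matrix.peptides]
    if missing:
        raise ValueError(f"panel peptides absent from the data set: {missing}")
    X = matrix.log2().loc[panel].T
    if drop_incomplete:
        X = X.dropna()
    return X


def confirm_panel(
    external: PeptideMatrix,
    panel: list[str],
    model,
    min_class_n: int = 4,
    standardize: bool = True,
) -> ConfirmationReport:
    """Apply a trained panel classifier to an independent labeled data set.

    Panel peptides are matched by sequence string.  Classes with fewer than
    ``min_class_n`` complete samples are excluded from scoring (and listed).
    With ``standardize`` each panel peptide is Z-scored within the external
    set before classification, absorbing global platform shifts; the model
    must then have been trained on equally standardized features.
    ``model`` is anything exposing ``predict`` over a sample x peptide
    table (a :class:`DecisionRule` or a fitted scikit-learn classifier).
    """
    if external.sample_labels is None:
        raise ValueError("external data set carries no class labels")
    X = panel_features(external, panel)
    y = external.sample_labels.loc[X.index]
    counts = y.value_counts()
    excluded = sorted(counts.index[counts < min_class_n])
    keep = ~y.isin(excluded)
    X, y = X.loc[keep], y.loc[keep]
    if y.nunique() < 2:
        raise ValueError(
            "fewer than 2 classes remain after exclusion; accuracy undefined"
        )
    if standardize:
        X = zscore_features(X)
    pred = model.predict(X)
    pred = pd.Series(np.asarray(pred), index=X.index)
    acc = float((pred == y).mean())
    per_class = (pred == y).groupby(y).mean()
    per_class.name = "accuracy"
    return ConfirmationReport(
        mapped_peptides=list(panel),
        excluded_classes=[str(c) for c in excluded],
        n_used=int(len(y)),
        accuracy=acc,
        per_class_accuracy=per_class.sort_index(),
    )
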