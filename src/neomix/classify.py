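"""Dual-omic random-forest classification with an "Unclassified" category.

One random forest per omic block, evaluated by leave-one-out
cross-validation.  Inside every fold the normalisation, variable-feature
selection (50% of training variance for expression, 5% for methylation)
and centre/scale statistics are learned from the training samples only;
minority classes are then oversampled with replacement to the majority
size before fitting.  Class probabilities are per-tree vote fractions.
A sample whose two highest class probabilities have a ratio below rho is
labelled "Unclassified"; expression- and methylation-based predictions are
merged by the two discordance rules (Unclassified + class -> class; two
different classes -> Unclassified).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from neomix.preprocess import (
    apply_normalization,
    beta_to_m,
    filter_low_expression,
    learn_normalization,
)

UNCLASSIFIED = "Unclassified"


def fold_train_samples(samples, test_sample, replicate_groups=None):
    """Training samples for one LOO fold: everything except the held-out
    sample and any sample declared as its technical replicate."""
    group = replicate_groups.get(test_sample) if replicate_groups else None
    return [
        s for s in samples
        if s != test_sample
        and not (group is not None and replicate_groups.get(s) == group)
    ]


@dataclass
class ClassifierSettings:
    trees: int = 500
    max_features: str = "sqrt"
    rho: float = 1.5
    expression_fraction: float = 0.5
    methylation_fraction: float = 0.05


@dataclass
class PredictionSet:
    probabilities: dict                      # omic -> samples x classes DataFrame
    per_omic_label: pd.DataFrame             # samples x omics
    merged: pd.Series
    rho: float = 1.5
    settings: ClassifierSettings = field(default_factory=ClassifierSettings)


def loocv_predict(
    block: pd.DataFrame,
    labels: pd.Series,
    kind: str = "expression",
    settings: ClassifierSettings | None = None,
    seed: int = 0,
    replicate_groups: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-out class-probability estimates for one omic block.

    ``block`` is raw counts (expression) or beta-values (methylation),
    features x samples; ``labels`` indexes the same samples.
    ``replicate_groups`` maps a sample to a group id; members of the same
    group are excluded from the training set of each other's folds.
    """
    settings = settings or ClassifierSettings()
    samples = [s for s in block.columns if s in labels.index and pd.notna(labels.get(s))]
    y = labels.loc[samples]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    usable_classes = counts[counts >= 2].index
    if len(usable_classes) < len(counts):
        import warnings
        dropped = sorted(set(counts.index) - set(usable_classes))
        warnings.warn(f"classes with a single sample skipped: {dropped}")
    samples = [s for s in samples if y[s] in set(usable_classes)]
    y = y.loc[samples]
    classes = sorted(y.unique())
    fraction = settings.expression_fraction if kind == "expression" else settings.methylation_fraction

    if kind == "methylation":
        values_all = beta_to_m(block[samples])
    else:
        values_all = block[samples]

    root = np.random.default_rng(seed)
    fold_seeds = root.integers(2**31, size=len(samples))
    probs = pd.DataFrame(0.0, index=samples, columns=classes)
    for i, test_sample in enumerate(samples):
        train = fold_train_samples(samples, test_sample, replicate_groups)
        train_block = values_all[train]
        if kind == "expression":
            train_block = filter_low_expression(train_block)
        model, x_train = learn_normalization(train_block, kind=kind, variance_fraction=fraction)
        if not model.selected_features:
            raise RuntimeError(f"empty feature set after filtering in fold {test_sample}")
        x_test = apply_normalization(model, values_all.loc[train_block.index, [test_sample]])

        y_train = y.loc[train]
        rng = np.random.default_rng(fold_seeds[i])
        counts_train = y_train.value_counts()
        max_n = counts_train.max()
        keep_idx: list[str] = []
        for cls in classes:
            members = [s for s in train if y_train[s] == cls]
            if not members:
                continue
            keep_idx.extend(members)
            extra = max_n - len(members)
            if extra > 0:
                keep_idx.extend(rng.choice(members, size=extra, replace=True))
        xt = x_train[keep_idx].to_numpy().T
        yt = y_train.loc[keep_idx].to_numpy()
        rf = RandomForestClassifier(
            n_estimators=settings.trees,
            max_features=settings.max_features,
            random_state=int(fold_seeds[i] % (2**31)),
            n_jobs=1,
        ).fit(xt, yt)
        xq = x_test.to_numpy().T
        votes = np.zeros(len(classes))
        order = {c: j for j, c in enumerate(rf.classes_)}
        tree_pred = np.array([t.predict(xq)[0] for t in rf.estimators_])
        for j, cls in enumerate(classes):
            if cls in order:
                votes[j] = np.sum(tree_pred == order[cls])
        probs.loc[test_sample] = votes / votes.sum()
    return probs


def classify_with_unclassified(probabilities: pd.Series, rho: float = 1.5) -> str:
    """Argmax label, or "Unclassified" if the top-two probability ratio < rho."""
    if len(probabilities) < 2:
        raise ValueError("need probabilities over at least two classes")
    p = probabilities.sort_values(ascending=False)
    p1, p2 = float(p.iloc[0]), float(p.iloc[1])
    if abs(p1 - p2) <= 1e-12:  # exact tie: the argmax itself is ambiguous
        return UNCLASSIFIED
    if p2 == 0.0:
        return str(p.index[0])
    # relative tolerance so a ratio of exactly rho (e.g. vote counts 3:2 at
    # rho=1.5) is classified despite floating-point division error
    if p1 / p2 < rho * (1.0 - 1e-12):
        return UNCLASSIFIED
    return str(p.index[0])


def merge_predictions(pred_expr: str | None, pred_meth: str | None) -> str:
    """Combine the two per-omic predictions.

    One omic only -> that prediction; equal -> that label; one Unclassified
    plus one class -> the class; two different classes -> Unclassified.
    """
    if pred_expr is None and pred_meth is None:
        raise ValueError("at least one per-omic prediction is required")
    if pred_expr is None:
        return pred_meth
    if pred_meth is None:
        return pred_expr
    if pred_expr == pred_meth:
        return pred_expr
    if pred_expr == UNCLASSIFIED:
        return pred_meth
    if pred_meth == UNCLASSIFIED:
        return pred_expr
    return UNCLASSIFIED


def dual_omic_classify(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    labels: pd.Series,
    settings: ClassifierSettings | None = None,
    seed: int = 0,
    replicate_groups: dict | None = None,
) -> PredictionSet:
    """Run both single-omic LOO classifiers and merge their predictions."""
    settings = settings or ClassifierSettings()
    probs = {}
    if expression is not None and expression.shape[1] > 0:
        probs["expression"] = loocv_predict(
            expression, labels, kind="expression", settings=settings,
            seed=seed, replicate_groups=replicate_groups,
        )
    if methylation is not None and methylation.shape[1] > 0:
        probs["methylation"] = loocv_predict(
            methylation, labels, kind="methylation", settings=settings,
            seed=seed + 1, replicate_groups=replicate_groups,
        )
    all_samples = sorted(set().union(*[set(p.index) for p in probs.values()]))
    per_omic = pd.DataFrame(index=all_samples, columns=list(probs), dtype=object)
    for omic, p in probs.items():
        for s in p.index:
            per_omic.loc[s, omic] = classify_with_unclassified(p.loc[s], settings.rho)
    merged = pd.Series(index=all_samples, dtype=object, name="merged")
    for s in all_samples:
        pe = per_omic.loc[s, "expression"] if "expression" in per_omic.columns else None
        pm = per_omic.loc[s, "methylation"] if "methylation" in per_omic.columns else None
        pe = None if pd.isna(pe) else pe
        pm = None if pd.isna(pm) else pm
        merged[s] = merge_predictions(pe, pm)
    return PredictionSet(
        probabilities=probs, per_omic_label=per_omic, merged=merged,
        rho=settings.rho, settings=settings,
    )


def prediction_groups(
    merged: pd.Series, histology: pd.Series, min_size: int = 10,
) -> pd.DataFrame:
    """Survival-comparison groups from (histology, prediction) pairs.

    Each concordant or discordant (histology, predicted) pair forms a group
    (e.g. ``Atypical>Typical``); all Unclassified predictions pool into one
    group.  Groups with <= ``min_size`` samples are marked excluded.
    """
    samples = [s for s in merged.index if s in histology.index]
    rows = []
    for s in samples:
        pred = merged[s]
        if pred == UNCLASSIFIED:
            g = UNCLASSIFIED
        elif pred == histology[s]:
            g = str(pred)
        else:
            g = f"{histology[s]}>{pred}"
        rows.append({"sample": s, "histology": histology[s], "predicted": pred, "group": g})
    out = pd.DataFrame(rows).set_index("sample")
    sizes = out["group"].value_counts()
    out["group_size"] = out["group"].map(sizes)
    out["included"] = out["group_size"] > min_size
    return out
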