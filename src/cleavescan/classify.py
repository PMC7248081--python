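"""Tumor/normal classification from island cleavage-rate vectors.

Each sample becomes a vector of island-restricted CpG cleavage rates; a
linear-kernel SVM separates tumor from normal in that space, exploiting the
fact that CpG methylation raises the CpG cleavage rate, so a demethylated
(tumour) island scores lower.  Evaluation is by balanced jack-knife:
repeatedly hold out an equal random number of samples per class, train on
the remainder, score the holdout.

Conventions: labels are the strings TUMOR / NORMAL (UNLABELED rows are
carried but never trained on); per-island features are z-scored from the
training rows before fitting, since margin classifiers are scale-sensitive
and island rates vary with CG density; decision values > 0 predict TUMOR
and ties predict NORMAL (arbitrary, documented, stable).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .genome_io import InputError

logger = logging.getLogger(__name__)

TUMOR = "TUMOR"
NORMAL = "NORMAL"
UNLABELED = "UNLABELED"


@dataclass
class IslandRateMatrix:
    """Samples x islands feature matrix with per-sample labels.

    ``values`` is a DataFrame (rows = sample ids, columns = island ids);
    missing scores surviving the build step have been median-imputed.
    ``dropped_islands`` audits columns removed for excess missingness.
    """

    values: pd.DataFrame
    labels: pd.Series
    dropped_islands: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise InputError("duplicate sample ids in matrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate island ids in matrix")
        self.labels = pd.Series(self.labels).reindex(self.values.index).fillna(UNLABELED)

    def labelled(self) -> "IslandRateMatrix":
        keep = self.labels.isin([TUMOR, NORMAL])
        return IslandRateMatrix(self.values[keep], self.labels[keep], self.dropped_islands)

    def write_tsv(self, matrix_path, labels_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="sample")
        if labels_path is not None:
            self.labels.to_csv(labels_path, sep="\t", header=False)

    @classmethod
    def read_tsv(cls, matrix_path, labels: Mapping[str, str] | None = None) -> "IslandRateMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="sample")
        lab = pd.Series(dict(labels or {}), dtype=object)
        return cls(values, lab)


def build_matrix(
    tables: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, str],
    max_missing_frac: float = 0.2,
) -> IslandRateMatrix:
    """Assemble per-sample island-score tables into a feature matrix.

    The island universe is the outer union across samples; islands missing
    (NaN or absent) in strictly more than ``max_missing_frac`` of samples
    are dropped, and remaining missing cells are imputed with the column
    median.  Raises :class:`InputError` when fewer than 2 samples or 1
    island survive.
    """
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    values = pd.DataFrame.from_dict({s: dict(t) for s, t in tables.items()}, orient="index")
    values = values.astype(float)
    if len(values) < 2:
        raise InputError(f"need >= 2 samples, got {len(values)}")
    missing_frac = values.isna().mean(axis=0)
    dropped = sorted(missing_frac.index[missing_frac > max_missing_frac])
    if dropped:
        logger.info("dropping %d island(s) for missingness: %s", len(dropped), dropped)
    values = values.drop(columns=dropped)
    if values.shape[1] < 1:
        raise InputError("no islands survive the missingness filter")
    values = values.fillna(values.median(axis=0))
    return IslandRateMatrix(values, pd.Series(dict(labels), dtype=object), list(dropped))


# ---------------------------------------------------------------------------
# Linear SVM model


@dataclass
class LinearSvmModel:
    """A trained linear-kernel SVM, self-contained for prediction.

    Carries the feature order, the training z-score parameters, the
    training medians (for imputing missing features at predict time) and
    the hyperplane (weights, bias) oriented so that decision > 0 means
    TUMOR.
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float
    medians: np.ndarray
    C: float = 1.0
    seed: int | None = None
    n_train: int = 0

    def decision_values(self, rows: pd.DataFrame) -> pd.Series:
        if not set(self.feature_names) & set(rows.columns):
            raise InputError("no overlap between model features and input features")
        X = rows.reindex(columns=self.feature_names).astype(float)
        X = X.fillna(pd.Series(self.medians, index=self.feature_names))
        Z = (X.to_numpy() - self.mean) / self.scale
        return pd.Series(Z @ self.weights + self.bias, index=rows.index)

    def to_json(self, path) -> None:
        payload = {
            "model": "linear_svm",
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "medians": self.medians.tolist(),
            "C": self.C,
            "seed": self.seed,
            "n_train": self.n_train,
        }
        with open(path, "wt") as out:
            json.dump(payload, out, indent=1)

    @classmethod
    def from_json(cls, source) -> "LinearSvmModel":
        with open(source, "rt") as handle:
            d = json.load(handle)
        return cls(
            feature_names=d["feature_names"],
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            weights=np.asarray(d["weights"]),
            bias=d["bias"],
            medians=np.asarray(d["medians"]),
            C=d["C"],
            seed=d["seed"],
            n_train=d["n_train"],
        )


def _balance(ids_by_class: dict[str, list[str]], rng: np.random.Generator) -> list[str]:
    """Down-sample the larger class to the smaller, seeded."""
    smallest = min(len(v) for v in ids_by_class.values())
    kept: list[str] = []
    for ids in ids_by_class.values():
        ids = sorted(ids)
        if len(ids) > smallest:
            ids = list(rng.choice(ids, size=smallest, replace=False))
        kept.extend(ids)
    return kept


def train_classifier(
    matrix: IslandRateMatrix,
    C: float = 1.0,
    seed: int = 0,
    balance: bool = True,
) -> LinearSvmModel:
    """Fit the linear SVM on the matrix's labelled rows.

    Class counts are equalised by seeded down-sampling of the larger class
    before fitting, mirroring training on the same number of tumor and
    control samples.
    """
    lab = matrix.labelled()
    by_class = {
        cls: list(lab.values.index[lab.labels == cls]) for cls in (NORMAL, TUMOR)
    }
    if any(len(v) == 0 for v in by_class.values()):
        raise InputError("training requires both TUMOR and NORMAL samples")
    rng = np.random.default_rng(seed)
    train_ids = _balance(by_class, rng) if balance else sorted(lab.values.index)
    X = lab.values.loc[train_ids]
    y = lab.labels.loc[train_ids]

    mean = X.to_numpy().mean(axis=0)
    scale = X.to_numpy().std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X.to_numpy() - mean) / scale

    svc = SVC(kernel="linear", C=C)
    svc.fit(Z, y.to_numpy())
    # sklearn orders classes alphabetically: NORMAL < TUMOR, so the raw
    # decision function is already positive on the TUMOR side.
    weights = svc.coef_[0].copy()
    bias = float(svc.intercept_[0])
    return LinearSvmModel(
        feature_names=list(X.columns),
        mean=mean,
        scale=scale,
        weights=weights,
        bias=bias,
        medians=X.median(axis=0).to_numpy(),
        C=C,
        seed=seed,
        n_train=len(train_ids),
    )


def predict(
    model: LinearSvmModel,
    rows: pd.DataFrame,
    return_decision: bool = False,
):
    """Predict TUMOR/NORMAL per row; ties (decision exactly 0) -> NORMAL."""
    d = model.decision_values(rows)
    labels = pd.Series(np.where(d > 0, TUMOR, NORMAL), index=rows.index)
    return (labels, d) if return_decision else labels


# ---------------------------------------------------------------------------
# Jack-knife evaluation


@dataclass
class EvaluationReport:
    """Aggregate and per-round confusion counts from balanced jack-knife.

    Percentages follow sensitivity/specificity conventions: TP% + FN% = 100
    over held-out tumor samples; TN% + FP% = 100 over held-out normals.
    """

    rounds: pd.DataFrame
    seed: int
    holdout_per_class: int

    @property
    def tp(self) -> int:
        return int(self.rounds["tp"].sum())

    @property
    def tn(self) -> int:
        return int(self.rounds["tn"].sum())

    @property
    def fp(self) -> int:
        return int(self.rounds["fp"].sum())

    @property
    def fn(self) -> int:
        return int(self.rounds["fn"].sum())

    @property
    def tp_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def tn_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def fp_pct(self) -> float:
        return 100.0 - self.tn_pct

    @property
    def fn_pct(self) -> float:
        return 100.0 - self.tp_pct

    @property
    def accuracy_pct(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total

    def summary(self) -> dict:
        return {
            "rounds": int(len(self.rounds)),
            "holdout_per_class": self.holdout_per_class,
            "seed": self.seed,
            "tp_pct": self.tp_pct,
            "tn_pct": self.tn_pct,
            "fp_pct": self.fp_pct,
            "fn_pct": self.fn_pct,
            "accuracy_pct": self.accuracy_pct,
        }

    def to_json(self, path) -> None:
        with open(path, "wt") as out:
            json.dump(self.summary(), out, indent=1)

    def write_tsv(self, path) -> None:
        self.rounds.to_csv(path, sep="\t", index=False)


def jackknife_evaluate(
    matrix: IslandRateMatrix,
    rounds: int = 100,
    holdout_per_class: int | None = None,
    seed: int = 0,
    C: float = 1.0,
) -> EvaluationReport:
    """Balanced jack-knife: hold out ``holdout_per_class`` random samples
    of each class, train on the rest, score the holdout; repeat.

    Default holdout is 20% of the smaller class (at least 1).  Identical
    inputs and seed reproduce the report exactly.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    lab = matrix.labelled()
    tumor_ids = sorted(lab.values.index[lab.labels == TUMOR])
    normal_ids = sorted(lab.values.index[lab.labels == NORMAL])
    if not tumor_ids or not normal_ids:
        raise InputError("evaluation requires both TUMOR and NORMAL samples")
    smaller = min(len(tumor_ids), len(normal_ids))
    if holdout_per_class is None:
        holdout_per_class = max(1, smaller // 5)
    if not (1 <= holdout_per_class < smaller):
        raise InputError(
            f"holdout_per_class={holdout_per_class} must be in [1, {smaller})"
        )
    rng = np.random.default_rng(seed)
    records = []
    for round_no in range(rounds):
        held_t = list(rng.choice(tumor_ids, size=holdout_per_class, replace=False))
        held_n = list(rng.choice(normal_ids, size=holdout_per_class, replace=False))
        held = held_t + held_n
        train_rows = lab.values.drop(index=held)
        train_matrix = IslandRateMatrix(
            train_rows, lab.labels.drop(index=held), lab.dropped_islands
        )
        model = train_classifier(
            train_matrix, C=C, seed=int(rng.integers(2**31)), balance=True
        )
        pred = predict(model, lab.values.loc[held])
        tp = int((pred.loc[held_t] == TUMOR).sum())
        fn = holdout_per_class - tp
        tn = int((pred.loc[held_n] == NORMAL).sum())
        fp = holdout_per_class - tn
        records.append(
            {
                "round": round_no,
                "held_out": ",".join(held),
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
            }
        )
    return EvaluationReport(pd.DataFrame(records), seed, holdout_per_class)


# ---------------------------------------------------------------------------
# Island ranking


def rank_islands(matrix: IslandRateMatrix, k: int | None = None) -> pd.DataFrame:
    """Rank islands by |tumor mean - normal mean| of cleavage rates.

    Returns columns (normal_mean, tumor_mean, difference) indexed by island
    id, sorted by absolute difference descending with lexicographic island-id
    tie-break; ``difference`` is signed (tumor - normal), so island
    demethylation in tumours shows as a negative value.  Missing values
    (NaN) are excluded from the class means.
    """
    lab = matrix.labelled()
    normal_mean = lab.values[lab.labels == NORMAL].mean(axis=0, skipna=True)
    tumor_mean = lab.values[lab.labels == TUMOR].mean(axis=0, skipna=True)
    out = pd.DataFrame(
        {
            "normal_mean": normal_mean,
            "tumor_mean": tumor_mean,
            "difference": tumor_mean - normal_mean,
        }
    )
    out["_abs"] = out["difference"].abs()
    # lexicographic index order first, then a stable sort on |difference|,
    # so ties break by island id
    out = out.sort_index().sort_values(by="_abs", ascending=False, kind="mergesort")
    out = out.drop(columns="_abs")
    if k is not None:
        if k > len(out):
            warnings.warn(
                f"k={k} exceeds island count {len(out)}; returning all islands"
            )
            k = len(out)
        out = out.iloc[:k]
    return out
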