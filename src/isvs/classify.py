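"""Simulation-calibrated pathogenicity classification.

Every variant detected during an ISVS run is summarised by two features:

* ``x`` — the number of patients in the cohort carrying at least one
  copy of the variant, and
* ``y`` — the number of those carriers in whom the variant is homozygous
  or lies *in trans* (on the opposite haplotype) with at least one other
  ISVS-detected variant.

Pathogenic variants of a recessive gene accumulate in-trans partners in
a disease cohort; rare benign variants do not. Two classifiers are
calibrated on many simulated runs: an empirical cell-count table over
(x, y) with a conservative cumulative aggregation, and a two-feature
support-vector machine with calibrated probabilities. Either yields a
posterior probability of pathogenicity and a likelihood ratio
p / (1 - p), capped at 1e7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .cohort import PATHOGENIC, Cohort
from .engine import ISVSResult
from .params import ParameterError

LR_CAP = 1.0e7

FEATURE_COLUMNS = ["sim_id", "variant_id", "x", "y", "true_class"]


def feature_rows(cohort: Cohort, result: ISVSResult, sim_id: int = 0) -> list[tuple]:
    """(sim_id, variant_id, x, y, true_class) per ISVS-detected variant."""
    if result.detected.shape[0] != cohort.n_variants:
        raise ParameterError("result does not match cohort")
    det = np.where(result.detected)[0]
    if det.size == 0:
        return []
    mat, pat = cohort.maternal, cohort.paternal
    carriers = cohort.carriers
    mat_det = mat[:, det]
    pat_det = pat[:, det]
    ids = cohort.spectrum.variant_ids
    classes = cohort.spectrum.classes
    rows = []
    for j, v in enumerate(det):
        carrier = carriers[:, v]
        x = int(carrier.sum())
        hom = mat[:, v] & pat[:, v]
        others = np.ones(det.size, dtype=bool)
        others[j] = False
        mat_other = mat_det[:, others].any(axis=1)
        pat_other = pat_det[:, others].any(axis=1)
        in_trans = hom | (mat[:, v] & pat_other) | (pat[:, v] & mat_other)
        y = int(in_trans.sum())
        rows.append((sim_id, ids[v], x, y, classes[v]))
    return rows


def extract_features(cohort: Cohort, result: ISVSResult, sim_id: int = 0) -> pd.DataFrame:
    """Feature table (one row per detected variant) for one ISVS run.

    ``x`` counts carriers cohort-wide; ``y`` counts carriers that are
    homozygous for the variant or carry another detected variant on the
    opposite haplotype. Co-occurrence restricted to the same haplotype
    (in cis) never contributes to ``y``.
    """
    return pd.DataFrame(
        feature_rows(cohort, result, sim_id=sim_id), columns=FEATURE_COLUMNS
    )


@dataclass
class CellTable:
    """Empirical (x, y) cell counts of pathogenic vs non-pathogenic variants.

    ``cells`` holds, per (x, y), the observed counts ``n_pat`` /
    ``n_nonpat`` over the training simulations and cumulative counts
    obtained by the conservative rule: a cell containing any
    non-pathogenic observation keeps its observed counts; a pure
    pathogenic cell accumulates the observed pathogenic counts of the
    pure cells at (x, y-1), (x, y-2), ... downward, skipping empty
    cells, stopping (exclusively) at the first cell with a
    non-pathogenic observation, and flooring at y = 0.
    """

    cells: dict[tuple[int, int], tuple[int, int, int, int]] = field(default_factory=dict)
    svm_lr: dict[tuple[int, int], float] = field(default_factory=dict)

    @classmethod
    def from_observed(cls, observed: dict[tuple[int, int], tuple[int, int]]) -> "CellTable":
        """Build from {(x, y): (n_pat, n_nonpat)} applying the cumulative rule."""
        cells: dict[tuple[int, int], tuple[int, int, int, int]] = {}
        for (x, y), (n_pat, n_nonpat) in observed.items():
            if n_nonpat > 0:
                cells[(x, y)] = (n_pat, n_nonpat, n_pat, n_nonpat)
                continue
            cum = n_pat
            for y2 in range(y - 1, -1, -1):
                lower = observed.get((x, y2))
                if lower is None:
                    continue
                if lower[1] > 0:
                    break
                cum += lower[0]
            cells[(x, y)] = (n_pat, n_nonpat, cum, 0)
        return cls(cells=cells)

    def observed(self, x: int, y: int) -> tuple[int, int] | None:
        cell = self.cells.get((int(x), int(y)))
        return None if cell is None else (cell[0], cell[1])

    def cumulative(self, x: int, y: int) -> tuple[int, int] | None:
        cell = self.cells.get((int(x), int(y)))
        return None if cell is None else (cell[2], cell[3])

    def prob_pathogenic(self, x: int, y: int) -> float | None:
        """cum_pat / (cum_pat + cum_nonpat), or None for an unseen cell."""
        cum = self.cumulative(x, y)
        if cum is None:
            return None
        total = cum[0] + cum[1]
        return cum[0] / total if total else None

    def to_frame(self, model: "PathogenicityModel | None" = None) -> pd.DataFrame:
        """Tidy export of the calibration table (the fraction-bi-allelic plot data)."""
        rows = []
        for (x, y), (n_pat, n_nonpat, cum_pat, cum_nonpat) in sorted(self.cells.items()):
            total = cum_pat + cum_nonpat
            rows.append(
                {
                    "x": x,
                    "y": y,
                    "n_pat": n_pat,
                    "n_nonpat": n_nonpat,
                    "cum_pat": cum_pat,
                    "cum_nonpat": cum_nonpat,
                    "prob": cum_pat / total if total else np.nan,
                    "svm_lr": (
                        likelihood_ratio(model, x, y) if model is not None else np.nan
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["x", "y", "n_pat", "n_nonpat", "cum_pat", "cum_nonpat", "prob", "svm_lr"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CellTable":
        cells = {
            (int(r.x), int(r.y)): (int(r.n_pat), int(r.n_nonpat), int(r.cum_pat), int(r.cum_nonpat))
            for r in frame.itertuples()
        }
        lrs: dict[tuple[int, int], float] = {}
        if "svm_lr" in frame.columns:
            lrs = {
                (int(r.x), int(r.y)): float(r.svm_lr)
                for r in frame.itertuples()
                if np.isfinite(r.svm_lr)
            }
        return cls(cells=cells, svm_lr=lrs)


def build_cell_table(features: pd.DataFrame) -> CellTable:
    """Tally training feature rows into a calibrated cell-count table."""
    if features.empty:
        return CellTable()
    grouped = (
        features.assign(is_pat=(features["true_class"] == PATHOGENIC).astype(int))
        .groupby(["x", "y"])["is_pat"]
        .agg(n_pat="sum", n_obs="size")
    )
    observed = {
        (int(x), int(y)): (int(row.n_pat), int(row.n_obs - row.n_pat))
        for (x, y), row in grouped.iterrows()
    }
    return CellTable.from_observed(observed)


def empirical_classify(
    table: CellTable, x: int, y: int, confidence: float = 0.5
) -> tuple[str, float | None]:
    """Classify a variant from its (x, y) cell of the calibration table.

    Returns ``(class, prob)``. The call is pathogenic when the cell's
    cumulative pathogenic fraction reaches ``confidence``. An (x, y)
    never observed in training yields a conservative non-pathogenic call
    with ``prob=None``.
    """
    if not 0.5 <= confidence < 1.0:
        raise ParameterError("confidence must lie in [0.5, 1)")
    prob = table.prob_pathogenic(x, y)
    if prob is None:
        return "non-pathogenic", None
    return (PATHOGENIC if prob >= confidence else "non-pathogenic"), prob


@dataclass
class PathogenicityModel:
    """RBF-kernel SVM over (x, y) with Platt-calibrated probabilities.

    Features are standardised by the training-set (weighted) mean and
    standard deviation; duplicate (x, y, class) rows are aggregated into
    instance weights, which leaves the SVM objective unchanged. The
    probability of pathogenicity is obtained by Platt scaling: a
    weighted logistic fit of the true labels on the SVM decision
    values, so that mixed (x, y) cells keep honestly intermediate
    probabilities. ``lr_cap`` bounds the reported likelihood ratio.
    """

    svc: SVC
    platt: LogisticRegression
    mean: np.ndarray
    scale: np.ndarray
    lr_cap: float = LR_CAP

    def predict_proba(self, x, y) -> np.ndarray:
        """Probability of pathogenicity at feature point(s) (x, y)."""
        pts = np.column_stack(
            [np.atleast_1d(np.asarray(x, dtype=float)), np.atleast_1d(np.asarray(y, dtype=float))]
        )
        pts = (pts - self.mean) / self.scale
        decision = self.svc.decision_function(pts)
        proba = self.platt.predict_proba(decision.reshape(-1, 1))
        path_col = list(self.platt.classes_).index(1)
        return proba[:, path_col]


def train_model(
    features: pd.DataFrame,
    *,
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> PathogenicityModel:
    """Fit the two-feature SVM on training feature rows.

    Raises a training error when only one class is present (a separating
    surface is then undefined).
    """
    if features.empty:
        raise ParameterError("cannot train on an empty feature set")
    agg = (
        features.assign(label=(features["true_class"] == PATHOGENIC).astype(int))
        .groupby(["x", "y", "label"])
        .size()
        .reset_index(name="weight")
    )
    labels = agg["label"].to_numpy()
    if labels.min() == labels.max():
        raise ParameterError("training data must contain both classes")
    pts = agg[["x", "y"]].to_numpy(dtype=float)
    w = agg["weight"].to_numpy(dtype=float)
    mean = np.average(pts, axis=0, weights=w)
    var = np.average((pts - mean) ** 2, axis=0, weights=w)
    scale = np.sqrt(np.maximum(var, 1e-12))
    X = (pts - mean) / scale
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(X, labels, sample_weight=w)
    decision = svc.decision_function(X).reshape(-1, 1)
    platt = LogisticRegression(C=1e10)
    platt.fit(decision, labels, sample_weight=w)
    return PathogenicityModel(svc=svc, platt=platt, mean=mean, scale=scale)


def likelihood_ratio(model: PathogenicityModel, x, y) -> float | np.ndarray:
    """Pathogenic-vs-benign odds p/(1-p) from the SVM probability, capped.

    The cap (default 1e7) keeps near-certain calls finite; the output is
    a strictly increasing transform of the model probability below it.
    """
    p = model.predict_proba(x, y)
    p = np.clip(p, 1e-300, 1.0)
    with np.errstate(divide="ignore"):
        lr = np.where(p >= 1.0, model.lr_cap, p / np.maximum(1.0 - p, 1e-300))
    lr = np.minimum(lr, model.lr_cap)
    return float(lr[0]) if lr.size == 1 and np.isscalar(x) else lr


def evaluate_classifiers(
    features: pd.DataFrame,
    confidences: tuple[float, ...] = (0.5, 0.95),
    folds: int = 5,
    seed: int = 0,
    svm_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy of the empirical and SVM classifiers.

    Simulations (not variant rows) are split into ``folds`` folds; each
    fold trains both classifiers on the remaining simulations (80% at
    five folds) and classifies the held-out rows as pathogenic when the
    predicted probability reaches each confidence threshold. Returns one
    row per (classifier, confidence, fold) with TP/TN/FP/FN counts and
    accuracy.
    """
    sims = features["sim_id"].unique()
    if len(sims) < folds:
        raise ParameterError("need at least as many simulations as folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sims)
    chunks = np.array_split(order, folds)
    svm_kwargs = svm_kwargs or {}

    records = []
    for fold, test_sims in enumerate(chunks):
        test_mask = features["sim_id"].isin(test_sims)
        train = features[~test_mask]
        test = features[test_mask]
        truth = (test["true_class"] == PATHOGENIC).to_numpy()

        table = build_cell_table(train)
        emp_prob = np.array(
            [
                p if (p := table.prob_pathogenic(x, y)) is not None else 0.0
                for x, y in zip(test["x"], test["y"])
            ]
        )
        model = train_model(train, seed=seed, **svm_kwargs)
        svm_prob = model.predict_proba(test["x"].to_numpy(), test["y"].to_numpy())

        for name, prob in (("empirical", emp_prob), ("svm", svm_prob)):
            for conf in confidences:
                pred = prob >= conf
                tp = int((pred & truth).sum())
                tn = int((~pred & ~truth).sum())
                fp = int((pred & ~truth).sum())
                fn = int((~pred & truth).sum())
                records.append(
                    {
                        "classifier": name,
                        "confidence": conf,
                        "fold": fold,
                        "tp": tp,
                        "tn": tn,
                        "fp": fp,
                        "fn": fn,
                        "n_test": len(test),
                        "accuracy": (tp + tn) / len(test),
                    }
                )
    return pd.DataFrame(records)


def summarize_accuracy(report: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per classifier and confidence over folds."""
    return (
        report.groupby(["classifier", "confidence"], as_index=False)
        .agg(accuracy=("accuracy", "mean"), accuracy_se=("accuracy", "sem"))
        .sort_values(["classifier", "confidence"], ignore_index=True)
    )
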