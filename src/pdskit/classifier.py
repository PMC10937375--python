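"""Probability-thresholded RBF-SVM subtype classifier.

Training: ssGSEA scoring with global range normalization (extremes
stored), subtype-specific feature selection, LOOCV hyperparameter tuning
and a final RBF-SVM with one-vs-one Platt-calibrated probabilities.

Prediction: ssGSEA on the model's own gene sets, scaling by the STORED
training extremes, empirical-Bayes batch correction against the training
cohort as the reference batch, then calibrated class probabilities. A
sample whose maximum probability falls below the threshold (default 0.6)
is called "mixed"; raising the threshold can only turn class labels into
"mixed", never the reverse.

The model persists as a single human-readable JSON archive embedding the
gene sets and the reference score matrix, so prediction needs no
external files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .enrichment import (
    EnrichmentParams,
    ScoreMatrix,
    score_with_stored_range,
    ssgsea_scores,
)
from .feature_selection import FeatureSelectionConfig, select_features
from .formats_io import DataError, ExpressionMatrix, GeneSetCollection, filter_sets

CLASSES = ("PDS1", "PDS2", "PDS3")
DEFAULT_THRESHOLD = 0.6
VARIANCE_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# train/test splitting
# ---------------------------------------------------------------------------

def split_train_test(
    labels, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split preserving class proportions; deterministic per seed.

    Returns (train indices, test indices).
    """
    labels = np.asarray(labels)
    n = len(labels)
    values, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = values[counts < 2]
        raise DataError(f"class {bad[0]!r} has fewer than 2 members; cannot stratify")
    if train_fraction >= 1.0:
        warnings.warn("train_fraction >= 1: test set is empty", stacklevel=2)
        return np.arange(n), np.array([], dtype=int)
    n_train = int(round(train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=n_train, stratify=labels, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# reference-batch ComBat
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Reference-batch statistics for empirical-Bayes batch adjustment.

    The reference batch defines the per-set standardization (its mean and
    maximum-likelihood variance); target batches are location/scale
    adjusted towards it while the reference itself is left untouched.
    """

    set_names: list[str]
    reference_scores: np.ndarray  # sets x reference samples

    def __post_init__(self) -> None:
        self.reference_scores = np.asarray(self.reference_scores, dtype=float)
        if self.reference_scores.shape[0] != len(self.set_names):
            raise DataError("reference score matrix does not match set names")

    @property
    def reference_mean(self) -> np.ndarray:
        return self.reference_scores.mean(axis=1)

    @property
    def reference_var(self) -> np.ndarray:
        v = self.reference_scores.var(axis=1, ddof=0)
        return np.maximum(v, VARIANCE_FLOOR)


def _eb_iterate(
    z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray, conv: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes shrinkage of batch location/scale effects.

    Normal prior on location, inverse-gamma prior on scale; prior
    hyperparameters are moment-matched from the per-set estimates and the
    posterior solved by fixed-point iteration.
    """
    n = z.shape[1]
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1) if len(g_hat) > 1 else 0.0
    m = d_hat.mean()
    s2 = d_hat.var(ddof=1) if len(d_hat) > 1 else 0.0
    if t2 <= VARIANCE_FLOOR or s2 <= VARIANCE_FLOOR:
        # degenerate priors (e.g. target identical to reference): no shrinkage
        return g_hat.copy(), d_hat.copy()
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2
    g_new = g_hat.copy()
    d_new = d_hat.copy()
    change = 1.0
    while change > conv:
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        sum2 = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
    return g_new, d_new


def combat_reference(
    target: ScoreMatrix, model: BatchModel, shrink: bool = True
) -> ScoreMatrix:
    """Adjust a target batch towards the reference batch.

    Only target samples are modified; passing the reference samples
    themselves yields them back unchanged (up to float round-off) because
    their estimated batch effects are exactly zero location / unit scale.
    With ``shrink=False`` the raw per-set estimates are used (the
    no-shrinkage limit, which removes a pure location shift exactly).
    """
    if list(target.set_names) != list(model.set_names):
        raise DataError("target sets do not match the batch model's sets")
    mu = model.reference_mean
    sigma = np.sqrt(model.reference_var)
    z = (target.scores - mu[:, None]) / sigma[:, None]
    n_t = z.shape[1]
    g_hat = z.mean(axis=1)
    if n_t < 2:
        # scale estimate undefined for a single sample: location-only fallback
        adjusted = z - g_hat[:, None]
    else:
        d_hat = np.maximum(z.var(axis=1, ddof=0), VARIANCE_FLOOR)
        if shrink:
            g_star, d_star = _eb_iterate(z, g_hat, d_hat)
            d_star = np.maximum(d_star, VARIANCE_FLOOR)
        else:
            g_star, d_star = g_hat, d_hat
        adjusted = (z - g_star[:, None]) / np.sqrt(d_star)[:, None]
    corrected = adjusted * sigma[:, None] + mu[:, None]
    return ScoreMatrix(
        set_names=list(target.set_names),
        sample_ids=list(target.sample_ids),
        scores=corrected,
        params=target.params,
        norm_min=target.norm_min,
        norm_max=target.norm_max,
    )


# ---------------------------------------------------------------------------
# SVM tuning and training
# ---------------------------------------------------------------------------

def median_heuristic_gamma(features: np.ndarray) -> float:
    """RBF gamma from the median pairwise Euclidean distance."""
    d = euclidean_distances(features)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med <= 0:
        raise DataError("degenerate feature matrix: zero median pairwise distance")
    return float(1.0 / (2.0 * med**2))


def default_grid(features: np.ndarray) -> list[tuple[float, float]]:
    """(gamma, cost) grid: median-heuristic gamma +/- one order of magnitude."""
    g0 = median_heuristic_gamma(features)
    return [
        (g, c)
        for g in (g0 / 10.0, g0, g0 * 10.0)
        for c in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    ]


def tune_svm_loocv(
    features: np.ndarray, labels, grid: list[tuple[float, float]]
) -> tuple[float, float]:
    """Leave-one-out CV over a (gamma, cost) grid; returns the best pair.

    Ties are broken towards smaller cost, then smaller kernel width
    (i.e. larger gamma). Uses a precomputed kernel per gamma so the n
    leave-one-out fits stay cheap.
    """
    if not grid:
        raise ValueError("empty tuning grid")
    labels = np.asarray(labels)
    n = len(labels)
    if features.std(axis=0).max() <= 0:
        raise DataError("all features are constant; cannot tune")
    d2 = euclidean_distances(features, squared=True)
    best: tuple[float, float, float] | None = None  # (accuracy, -cost, gamma)
    best_pair = grid[0]
    for gamma, cost in grid:
        kernel = np.exp(-gamma * d2)
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            svc = SVC(C=cost, kernel="precomputed")
            svc.fit(kernel[np.ix_(mask, mask)], labels[mask])
            pred = svc.predict(kernel[i, mask][None, :])
            correct += int(pred[0] == labels[i])
        key = (correct / n, -cost, gamma)
        if best is None or key > best:
            best = key
            best_pair = (gamma, cost)
    return best_pair


# ---------------------------------------------------------------------------
# model and calls
# ---------------------------------------------------------------------------

@dataclass
class SubtypeCall:
    sample_id: str
    p1: float
    p2: float
    p3: float
    label: str
    threshold_used: float

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3])


@dataclass
class ClassifierModel:
    """Everything needed for standalone prediction, JSON-serializable."""

    selected_sets: list[str]
    gmt: GeneSetCollection
    enrichment_params: EnrichmentParams
    norm_min: float
    norm_max: float
    batch_model: BatchModel
    svm_gamma: float
    svm_cost: float
    training_labels: list[str]
    classes: tuple[str, ...] = CLASSES
    default_threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    _svc: SVC | None = field(default=None, repr=False, compare=False)

    def fitted_svm(self) -> SVC:
        """(Re)fit the calibrated SVM on the stored reference scores.

        Fitting is deterministic given the stored seed, so a round-tripped
        model reproduces the original probabilities exactly.
        """
        if self._svc is None:
            svc = SVC(
                C=self.svm_cost,
                gamma=self.svm_gamma,
                kernel="rbf",
                probability=True,
                random_state=self.seed,
            )
            with warnings.catch_warnings():
                # one-vs-one Platt calibration with pairwise coupling is the
                # intended probability mechanism; keep SVC's built-in path
                warnings.filterwarnings("ignore", message=".*probability.*",
                                        category=FutureWarning)
                svc.fit(
                    self.batch_model.reference_scores.T,
                    np.asarray(self.training_labels),
                )
            self._svc = svc
        return self._svc

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "pdskit-classifier-v1",
            "selected_sets": self.selected_sets,
            "gmt": {
                "set_names": self.gmt.set_names,
                "members": self.gmt.members,
                "descriptions": self.gmt.descriptions,
                "provenance": self.gmt.provenance,
            },
            "enrichment_params": {
                "method": self.enrichment_params.method,
                "tau": self.enrichment_params.tau,
                "normalize": self.enrichment_params.normalize,
            },
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
            "reference_sample_ids": list(range(self.batch_model.reference_scores.shape[1])),
            "reference_scores": self.batch_model.reference_scores.tolist(),
            "svm": {"gamma": self.svm_gamma, "cost": self.svm_cost},
            "training_labels": self.training_labels,
            "classes": list(self.classes),
            "default_threshold": self.default_threshold,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "pdskit-classifier-v1":
            raise DataError(f"{path}: not a recognized classifier model file")
        gmt = GeneSetCollection(
            set_names=payload["gmt"]["set_names"],
            members=payload["gmt"]["members"],
            descriptions=payload["gmt"]["descriptions"],
            provenance=payload["gmt"]["provenance"],
        )
        ep = payload["enrichment_params"]
        return cls(
            selected_sets=payload["selected_sets"],
            gmt=gmt,
            enrichment_params=EnrichmentParams(
                method=ep["method"], tau=ep["tau"], normalize=ep["normalize"]
            ),
            norm_min=payload["norm_min"],
            norm_max=payload["norm_max"],
            batch_model=BatchModel(
                set_names=payload["selected_sets"],
                reference_scores=np.array(payload["reference_scores"]),
            ),
            svm_gamma=payload["svm"]["gamma"],
            svm_cost=payload["svm"]["cost"],
            training_labels=payload["training_labels"],
            classes=tuple(payload["classes"]),
            default_threshold=payload["default_threshold"],
            seed=payload["seed"],
        )


@dataclass
class TrainConfig:
    seed: int = 0
    min_set_size: int = 10
    tau: float = 0.25
    correlation_cutoff: float = 0.9
    threshold: float = DEFAULT_THRESHOLD
    grid: list[tuple[float, float]] | None = None  # None -> default_grid


def _labels_to_classes(labels) -> np.ndarray:
    """Map cluster ids (1..3 or PDS names) onto the canonical class labels."""
    out = []
    for lab in np.asarray(labels):
        s = str(lab)
        if s in CLASSES:
            out.append(s)
        elif s in ("1", "2", "3"):
            out.append(CLASSES[int(s) - 1])
        else:
            raise DataError(f"unrecognized subtype label {lab!r}")
    return np.array(out)


def train_classifier(
    x: ExpressionMatrix,
    labels,
    c: GeneSetCollection,
    cfg: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the full pipeline on a labeled training cohort.

    Scores the cohort (range-normalized, extremes stored), selects
    subtype-specific non-redundant sets, tunes (gamma, cost) by LOOCV and
    stores the scaled training score matrix as the reference batch.
    """
    cfg = cfg or TrainConfig()
    class_labels = _labels_to_classes(labels)
    if len(set(class_labels)) != 3:
        raise DataError("training requires exactly 3 subtype classes")
    kept = filter_sets(c, x, min_size=cfg.min_set_size)
    params = EnrichmentParams(method="ssgsea", tau=cfg.tau, normalize=True)
    scores = ssgsea_scores(x, kept, params)
    numeric = np.array([CLASSES.index(lab) + 1 for lab in class_labels])
    assigned = select_features(
        scores, numeric, FeatureSelectionConfig(correlation_cutoff=cfg.correlation_cutoff)
    )
    selected = [n for g in sorted(assigned) for n in assigned[g]]
    if len(selected) < 2:
        raise DataError("feature selection retained fewer than 2 gene sets")
    train_scores = scores.subset_sets(selected)
    features = train_scores.scores.T
    grid = cfg.grid if cfg.grid is not None else default_grid(features)
    gamma, cost = tune_svm_loocv(features, class_labels, grid)
    model = ClassifierModel(
        selected_sets=selected,
        gmt=kept.subset(selected),
        enrichment_params=params,
        norm_min=float(scores.norm_min),
        norm_max=float(scores.norm_max),
        batch_model=BatchModel(set_names=selected, reference_scores=train_scores.scores),
        svm_gamma=gamma,
        svm_cost=cost,
        training_labels=class_labels.tolist(),
        default_threshold=cfg.threshold,
        seed=cfg.seed,
    )
    model.fitted_svm()
    return model


def predict(
    model: ClassifierModel,
    x: ExpressionMatrix,
    threshold: float | None = None,
    batch_correct: bool = True,
) -> list[SubtypeCall]:
    """Classify new samples; calls below the probability threshold are "mixed"."""
    threshold = model.default_threshold if threshold is None else threshold
    if not 1.0 / 3.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (1/3, 1]")
    model_genes = sorted({g for n in model.selected_sets for g in model.gmt.members[n]})
    present = set(x.gene_ids)
    overlap = sum(g in present for g in model_genes)
    if overlap == 0:
        raise DataError("no overlap between the matrix and the model's gene sets")
    frac = overlap / len(model_genes)
    if frac < 0.8:
        warnings.warn(
            f"only {100 * frac:.1f}% of the model's genes are present; "
            "predictions may be unreliable",
            stacklevel=2,
        )
    scored = score_with_stored_range(
        x, model.gmt, model.enrichment_params, model.norm_min, model.norm_max
    ).subset_sets(model.selected_sets)
    if batch_correct:
        scored = combat_reference(scored, model.batch_model)
    svc = model.fitted_svm()
    proba = svc.predict_proba(scored.scores.T)
    order = [list(svc.classes_).index(cls) for cls in model.classes]
    return calls_from_probabilities(
        list(x.sample_ids), proba[:, order], model.classes, threshold
    )


def calls_from_probabilities(
    sample_ids: list[str],
    proba: np.ndarray,
    classes: tuple[str, ...] = CLASSES,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SubtypeCall]:
    """Thresholded calls from class probabilities: argmax if it reaches the
    threshold, else "mixed"."""
    proba = np.asarray(proba, dtype=float)
    calls = []
    for sid, p in zip(sample_ids, proba):
        top = int(np.argmax(p))
        label = classes[top] if p[top] >= threshold else "mixed"
        calls.append(
            SubtypeCall(
                sample_id=str(sid),
                p1=float(p[0]),
                p2=float(p[1]),
                p3=float(p[2]),
                label=label,
                threshold_used=threshold,
            )
        )
    return calls


def mixed_fraction(calls: list[SubtypeCall]) -> float:
    if not calls:
        raise ValueError("empty call list")
    return sum(c.label == "mixed" for c in calls) / len(calls)


def write_calls(calls: list[SubtypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tp_PDS1\tp_PDS2\tp_PDS3\tcall\tthreshold\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.p1:.6f}\t{c.p2:.6f}\t{c.p3:.6f}\t"
                f"{c.label}\t{c.threshold_used:g}\n"
            )
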