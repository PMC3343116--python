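"""Decoding persistent-activity emergence from early spike-train features.

Two classifiers mirror the discrimination analysis: an ensemble of 1-D
linear discriminants on first-AP latency, validated by leave-five-out
cross validation and combined by vote averaging, and a single-layer
perceptron on the leading inter-spike intervals, sanity-checked by
leave-one-out cross validation.  Performance is summarised as sensitivity
(persistent trials correctly detected), specificity (non-persistent trials
correctly rejected) and their macro average, the "total accuracy".

A synthetic feature-table generator provides classifier inputs with known
class structure (longer AP latencies and shifted early ISIs in persistent
trials) so the decoding stage is testable without running simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


class MetricError(ValueError):
    """Invalid inputs to a performance metric."""


class FitError(RuntimeError):
    """Degenerate training data."""


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-trial decoding features.

    ``df`` has columns: trial_id, label (1 = persistent, 0 = no-persistent),
    ap_latency (ms), and isis (list of ms values, stimulus-period ISIs).
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"trial_id", "label", "ap_latency", "isis"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        if not set(self.df["label"].unique()) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")

    def __len__(self):
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def latencies(self) -> np.ndarray:
        return self.df["ap_latency"].to_numpy(dtype=float)

    def isi_matrix(self, k: int | str = 2) -> np.ndarray:
        """First-k ISI feature matrix; ``k="all"`` right-pads shorter rows
        with their last ISI up to the corpus maximum."""
        rows = [np.asarray(r, dtype=float) for r in self.df["isis"]]
        if k == "all":
            width = max(len(r) for r in rows)
            out = np.empty((len(rows), width))
            for i, r in enumerate(rows):
                if len(r) == 0:
                    raise ValueError(f"trial {i} has no ISIs")
                out[i, :len(r)] = r
                out[i, len(r):] = r[-1]
            return out
        k = int(k)
        if any(len(r) < k for r in rows):
            bad = [i for i, r in enumerate(rows) if len(r) < k]
            raise ValueError(f"{len(bad)} trials have fewer than {k} ISIs")
        return np.vstack([r[:k] for r in rows])

    def class_counts(self) -> dict:
        lab = self.labels
        return {1: int((lab == 1).sum()), 0: int((lab == 0).sum())}

    def to_csv(self, path):
        df = self.df.copy()
        df["isis"] = df["isis"].map(lambda r: ";".join(f"{x:.6g}" for x in r))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        df["isis"] = df["isis"].map(
            lambda s: [float(x) for x in str(s).split(";") if x not in ("", "nan")]
        )
        return cls(df)

    @classmethod
    def from_trials(cls, trials) -> "FeatureTable":
        rows = []
        for i, t in enumerate(trials):
            rows.append({
                "trial_id": getattr(t, "seed", i),
                "label": int(t.persistent),
                "ap_latency": t.ap_latency,
                "isis": list(np.asarray(t.isis, dtype=float)),
            })
        return cls(pd.DataFrame(rows))


def make_feature_fixture(
    seed: int,
    n_per_class: int = 30,
    latency_shift: float = 0.25,
    isi_shift: float = 5.0,
    noise_sd: float = 0.3,
    n_isis: int = 8,
    latency_base: float = 18.0,
    isi_base: float = 45.0,
    isi_sd: float = 6.0,
) -> FeatureTable:
    """Synthetic feature table with the structure the decoders assume.

    Persistent trials (label 1) have AP latencies shifted by
    ``latency_shift`` ms (Gaussian noise ``noise_sd``) and leading ISIs
    shifted by ``isi_shift`` ms (noise ``isi_sd``); deterministic per seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    tid = 0
    for label in (1, 0):
        lat_mu = latency_base + (latency_shift if label else 0.0)
        isi_mu = isi_base + (isi_shift if label else 0.0)
        for _ in range(n_per_class):
            rows.append({
                "trial_id": tid,
                "label": label,
                "ap_latency": float(rng.normal(lat_mu, noise_sd)),
                "isis": list(np.maximum(1.0, rng.normal(isi_mu, isi_sd, n_isis))),
            })
            tid += 1
    return FeatureTable(pd.DataFrame(rows))


def stratified_split(table: FeatureTable, n_pos: int = 20, n_neg: int = 10,
                     seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Random stratified train/test split with ``n_pos``/``n_neg`` rows of
    each class per set (the 20/10 design)."""
    rng = np.random.default_rng(seed)
    df = table.df
    parts = {"train": [], "test": []}
    for label, n in ((1, n_pos), (0, n_neg)):
        idx = df.index[df["label"] == label].to_numpy()
        if len(idx) < 2 * n:
            raise ValueError(
                f"need >= {2 * n} trials of class {label}, have {len(idx)}"
            )
        perm = rng.permutation(idx)
        parts["train"].append(perm[:n])
        parts["test"].append(perm[n:2 * n])
    tr = df.loc[np.concatenate(parts["train"])].reset_index(drop=True)
    te = df.loc[np.concatenate(parts["test"])].reset_index(drop=True)
    return FeatureTable(tr), FeatureTable(te)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    sensitivity: float
    specificity: float
    total_accuracy: float  # macro average of the two
    raw_accuracy: float  # plain proportion correct (secondary)
    predictions: np.ndarray
    labels: np.ndarray
    votes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def report_metrics(predictions, labels, votes=None, **meta) -> ClassifierReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), and their mean."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise MetricError("predictions and labels differ in length")
    if len(np.unique(y)) < 2:
        raise MetricError("both classes must be present in the labels")
    tp = int(((p == 1) & (y == 1)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ClassifierReport(
        sensitivity=sens, specificity=spec,
        total_accuracy=0.5 * (sens + spec),
        raw_accuracy=float((p == y).mean()),
        predictions=p, labels=y, votes=votes, meta=meta,
    )


# ---------------------------------------------------------------------------
# LDA ensemble on AP latency
# ---------------------------------------------------------------------------

def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> list[np.ndarray]:
    """Partition indices into ``n_folds`` folds, each with a class mix as
    even as possible."""
    folds = [[] for _ in range(n_folds)]
    for label in (1, 0):
        idx = rng.permutation(np.flatnonzero(labels == label))
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.asarray(sorted(f)) for f in folds]


def lda_ensemble(train: FeatureTable, test: FeatureTable, seed: int = 0,
                 n_folds: int = 6) -> ClassifierReport:
    """Leave-five-out cross-validated LDA ensemble on first-AP latency.

    The 30-row training set is partitioned into 6 stratified folds of 5; an
    LDA is fit on each 25-row complement.  Each test trial receives one
    binary vote per fold model and is called persistent when the vote mean
    is >= 0.5.
    """
    y_tr = train.labels
    x_tr = train.latencies.reshape(-1, 1)
    if len(np.unique(y_tr)) < 2:
        raise FitError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y_tr, n_folds, rng)
    x_te = test.latencies.reshape(-1, 1)
    votes = np.zeros((len(test), n_folds))
    for f, fold in enumerate(folds):
        keep = np.setdiff1d(np.arange(len(y_tr)), fold)
        x, y = x_tr[keep], y_tr[keep]
        if len(np.unique(y)) < 2:
            raise FitError("a fold complement lost one class; use stratified folds")
        if np.ptp(x) == 0:
            raise FitError("degenerate training data: zero variance in latency")
        model = LinearDiscriminantAnalysis()
        model.fit(x, y)
        votes[:, f] = model.predict(x_te)
    mean_votes = votes.mean(axis=1)
    preds = (mean_votes >= 0.5).astype(int)
    return report_metrics(preds, test.labels, votes=votes,
                          feature="ap_latency", n_folds=n_folds)


# ---------------------------------------------------------------------------
# Perceptron on leading ISIs
# ---------------------------------------------------------------------------

@dataclass
class Perceptron:
    """Thresholded single-layer perceptron, inputs z-scored on training
    statistics; classic error-driven updates."""

    lr: float = 0.01
    max_epochs: int = 2000
    w: np.ndarray | None = None
    b: float = 0.0
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None
    converged: bool = False

    def _z(self, x):
        return (x - self.mu) / self.sd

    def fit(self, x: np.ndarray, y: np.ndarray, rng=None) -> "Perceptron":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.mu = x.mean(axis=0)
        self.sd = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
        z = self._z(x)
        rng = rng or np.random.default_rng(0)
        self.w = np.zeros(x.shape[1])
        self.b = 0.0
        order = np.arange(len(y))
        for _ in range(self.max_epochs):
            errors = 0
            rng.shuffle(order)
            for i in order:
                pred = 1 if z[i] @ self.w + self.b >= 0 else 0
                err = y[i] - pred
                if err:
                    self.w += self.lr * err * z[i]
                    self.b += self.lr * err
                    errors += 1
            if errors == 0:
                self.converged = True
                break
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self._z(np.asarray(x, dtype=float))
        return (z @ self.w + self.b >= 0).astype(int)


def perceptron_loocv(train: FeatureTable, test: FeatureTable,
                     k_isis: int | str = 2, seed: int = 0,
                     lr: float = 0.01, max_epochs: int = 2000) -> ClassifierReport:
    """Perceptron on the first-k ISIs (k in {2, 5, "all"}).

    Leave-one-out cross validation over the training set provides a
    validation accuracy (reported in ``meta``); the final model is trained
    on all training rows and evaluated on the held-out test set.
    """
    x_tr = train.isi_matrix(k_isis)
    y_tr = train.labels
    if len(np.unique(y_tr)) < 2:
        raise FitError("training set must contain both classes")
    rng = np.random.default_rng(seed)

    loo_correct = 0
    for i in range(len(y_tr)):
        keep = np.delete(np.arange(len(y_tr)), i)
        if len(np.unique(y_tr[keep])) < 2:
            continue
        p = Perceptron(lr=lr, max_epochs=max_epochs).fit(
            x_tr[keep], y_tr[keep], rng=np.random.default_rng(seed + 1 + i))
        loo_correct += int(p.predict(x_tr[i:i + 1])[0] == y_tr[i])
    loo_acc = loo_correct / len(y_tr)

    final = Perceptron(lr=lr, max_epochs=max_epochs).fit(x_tr, y_tr, rng=rng)
    x_te = test.isi_matrix(k_isis)
    preds = final.predict(x_te)
    rep = report_metrics(preds, test.labels, feature=f"isis[:{k_isis}]",
                         loocv_accuracy=loo_acc, converged=final.converged)
    return rep


def shuffle_control(table: FeatureTable, classifier="perceptron", k_isis=2,
                    n_seeds: int = 20, n_pos: int = 20, n_neg: int = 10,
                    base_seed: int = 0, max_epochs: int = 300) -> dict:
    """Label-permutation control: labels are shuffled once per seed, the full
    split+train+test pipeline re-run, and the metrics summarised."""
    accs, sens, spec = [], [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        df = table.df.copy()
        df["label"] = rng.permutation(df["label"].to_numpy())
        try:
            shuffled = FeatureTable(df)
            tr, te = stratified_split(shuffled, n_pos, n_neg, seed=base_seed + s)
            if classifier == "perceptron":
                rep = perceptron_loocv(tr, te, k_isis=k_isis, seed=base_seed + s,
                                       max_epochs=max_epochs)
            else:
                rep = lda_ensemble(tr, te, seed=base_seed + s)
        except (ValueError, FitError):
            continue
        accs.append(rep.total_accuracy)
        sens.append(rep.sensitivity)
        spec.append(rep.specificity)
    return {
        "mean_total_accuracy": float(np.mean(accs)),
        "sd_total_accuracy": float(np.std(accs)),
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec)),
        "n": len(accs),
    }
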