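"""Group-level analysis of morphometric phenotypes.

Per-metric comparisons use the two-tailed Student's t test (pooled
variance, as named; Welch available behind a flag) with significance at
alpha = 0.05, data summarised as mean +/- SD.  Strain classification
standardises the five-metric vectors, projects them onto leading
principal components, and fits logistic regression (two classes) or an
SVM (multi-class); accuracy is reported both by stratified
cross-validation and by resubstitution (the in-sample region counts the
decision-boundary plots show).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GroupComparison",
    "ClassificationReport",
    "METRIC_COLUMNS",
    "compare_groups",
    "classify",
    "simulate_strain_records",
]

METRIC_COLUMNS = ["surface_area_um2", "volume_um3", "length_um", "max_width_um", "ratio"]
ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_groups(
    records: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    group_column: str = "strain",
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed two-sample t test between two groups on one metric."""
    a = records.loc[records[group_column] == group_a, metric].to_numpy(float)
    b = records.loc[records[group_column] == group_b, metric].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        sd_pool = np.sqrt(
            ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
            / (a.size + b.size - 2)
        )
        if not welch and sd_pool == 0:
            raise ValueError("zero pooled variance: t statistic undefined")
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        t_statistic=t,
        p_value=p,
        significant=bool(p < ALPHA),
    )


@dataclass
class ClassificationReport:
    method: str  # "pca_lr" | "pca_svm"
    n_components: int
    classes: list[str]
    confusion: np.ndarray  # resubstitution counts, rows = true class
    resubstitution_accuracy: float
    cv_accuracy: float
    cv_folds: int
    per_class_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def total_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "method": self.method,
                "n_components": self.n_components,
                "classes": self.classes,
                "confusion": self.confusion.tolist(),
                "resubstitution_accuracy": self.resubstitution_accuracy,
                "cv_accuracy": self.cv_accuracy,
                "cv_folds": self.cv_folds,
                "per_class_accuracy": self.per_class_accuracy,
                "total_correct": self.total_correct,
                "total": self.total,
            },
            indent=2,
        ))


def _build_model(method: str, n_components: int, seed: int, kernel: str) -> Pipeline:
    if method == "pca_lr":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif method == "pca_svm":
        clf = SVC(kernel=kernel, C=1.0, gamma="scale", random_state=seed)
    else:
        raise ValueError("method must be 'pca_lr' or 'pca_svm'")
    return Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=n_components)),
        ("clf", clf),
    ])


def classify(
    records: pd.DataFrame,
    method: str = "pca_svm",
    label_column: str = "strain",
    metric_columns: list[str] | None = None,
    n_components: int = 2,
    folds: int = 5,
    kernel: str = "rbf",
    seed: int = 0,
) -> ClassificationReport:
    """PCA-based strain classification from the five-metric vectors.

    Metrics are z-scored, projected on ``n_components`` principal
    components (two by default -- the decision-region plots are 2-D),
    then classified.  If the smallest class has fewer members than
    ``folds`` the fold count is reduced with a warning.
    """
    cols = metric_columns or METRIC_COLUMNS
    X = records[cols].to_numpy(float)
    y = records[label_column].to_numpy()
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 3:
        raise ValueError("each class needs n >= 3")
    if method == "pca_lr" and len(classes) != 2:
        raise ValueError("logistic regression path expects exactly 2 classes")

    eff_folds = min(folds, min(counts.values()))
    if eff_folds < folds:
        import warnings

        warnings.warn(f"reducing folds {folds} -> {eff_folds} (smallest class)")

    model = _build_model(method, n_components, seed, kernel)
    model.fit(X, y)
    pred = model.predict(X)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for yt, yp in zip(y, pred):
        conf[classes.index(str(yt)), classes.index(str(yp))] += 1

    cv = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    cv_acc = float(np.mean(cross_val_score(
        _build_model(method, n_components, seed, kernel), X, y, cv=cv)))

    per_class = {
        c: float(conf[i, i] / conf[i].sum()) if conf[i].sum() else float("nan")
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        method=method,
        n_components=n_components,
        classes=classes,
        confusion=conf,
        resubstitution_accuracy=float(np.trace(conf) / conf.sum()),
        cv_accuracy=cv_acc,
        cv_folds=eff_folds,
        per_class_accuracy=per_class,
    )


def plot_decision_regions(
    records: pd.DataFrame,
    report: ClassificationReport,
    path: str | Path,
    label_column: str = "strain",
    metric_columns: list[str] | None = None,
    seed: int = 0,
) -> None:
    """2-component decision-region plot (PC1 vs PC2) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = metric_columns or METRIC_COLUMNS
    X = records[cols].to_numpy(float)
    y = records[label_column].to_numpy()
    scaler = StandardScaler().fit(X)
    pca = PCA(n_components=2).fit(scaler.transform(X))
    P = pca.transform(scaler.transform(X))
    if report.method == "pca_lr":
        clf = LogisticRegression(max_iter=2000, random_state=seed).fit(P, y)
    else:
        clf = SVC(kernel="rbf", gamma="scale", random_state=seed).fit(P, y)
    xx, yy = np.meshgrid(
        np.linspace(P[:, 0].min() - 1, P[:, 0].max() + 1, 300),
        np.linspace(P[:, 1].min() - 1, P[:, 1].max() + 1, 300),
    )
    zz = clf.predict(np.column_stack([xx.ravel(), yy.ravel()]))
    classes = report.classes
    z_idx = np.array([classes.index(str(v)) for v in zz]).reshape(xx.shape)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(xx, yy, z_idx, levels=len(classes), alpha=0.25, cmap="tab10")
    for c in classes:
        m = np.asarray([str(v) == c for v in y])
        ax.scatter(P[m, 0], P[m, 1], s=18, label=c)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------
# synthetic cohorts for the statistics layer
# ----------------------------------------------------------------------

def simulate_strain_records(
    strain_means: dict[str, np.ndarray | list[float]],
    strain_sds: dict[str, np.ndarray | list[float]] | np.ndarray | list[float],
    n_per_strain: int | dict[str, int] = 15,
    stage: str = "adult",
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian five-metric cohorts with per-strain means, for testing
    the statistics layer independently of the reconstruction pipeline."""
    rng = np.random.default_rng(seed)
    rows = []
    for strain, mu in strain_means.items():
        mu = np.asarray(mu, float)
        sd = strain_sds[strain] if isinstance(strain_sds, dict) else strain_sds
        sd = np.asarray(sd, float)
        n = n_per_strain[strain] if isinstance(n_per_strain, dict) else n_per_strain
        draws = rng.normal(mu, sd, size=(n, mu.size))
        for j, d in enumerate(draws):
            row = {"sample_id": f"{strain}_{j}", "strain": strain, "stage": stage}
            row.update({c: float(v) for c, v in zip(METRIC_COLUMNS, d)})
            # keep the ratio consistent with its defining metrics
            row["ratio"] = row["length_um"] / row["max_width_um"]
            rows.append(row)
    return pd.DataFrame(rows)
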