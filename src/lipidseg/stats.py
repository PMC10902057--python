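"""Region-fingerprint statistics: per-region relative abundances,
Welch t-test comparisons with star coding, PCA score structure and
random-forest classification of tissue regions.

The unit of replication throughout is the sample (animal/section), never
the pixel: fingerprints are first averaged within a region of one
section, and tests and classifiers see one observation per
(sample, region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from .preprocess import FeatureMatrix

__all__ = [
    "star_code", "region_fingerprint", "fingerprint_table", "compare_regions",
    "compare_all", "pca_scores", "PCAResult", "classify_regions",
    "ClassificationReport", "InsufficientReplicatesError",
]

# star thresholds as printed in the source study's figure caption
STAR_THRESHOLDS = ((1e-4, "***"), (1e-2, "**"), (5e-2, "*"))


class InsufficientReplicatesError(ValueError):
    """A group comparison needs at least two samples per group."""


def star_code(p: float, thresholds=STAR_THRESHOLDS) -> str:
    """Significance stars as a pure function of the p value."""
    if not 0 <= p <= 1:
        raise ValueError(f"p value {p} outside [0, 1]")
    for cut, stars in thresholds:
        if p < cut:
            return stars
    return ""


def region_fingerprint(features: FeatureMatrix, region_mask: np.ndarray,
                       annotations=None) -> pd.Series:
    """Relative-abundance fingerprint of one region.

    Mean over the region's pixels of the annotated species' intensities,
    renormalized to sum 1.  ``annotations`` is the list produced by
    :func:`lipidseg.annotate.annotate_peaks` (one entry per feature
    column); unannotated columns are dropped.  When ``annotations`` is
    None all columns are kept under their m/z labels.
    """
    region_mask = np.asarray(region_mask, bool)
    if region_mask.sum() == 0:
        raise ValueError("empty region mask")
    vals = features.values[region_mask]
    if annotations is not None:
        keep = [i for i, a in enumerate(annotations) if a.annotated]
        if not keep:
            raise ValueError("no annotated species among the peaks")
        names = [annotations[i].best.name for i in keep]
        vals = vals[:, keep]
    else:
        names = [f"{m:.4f}" for m in features.peak_mz]
    mean = vals.mean(axis=0)
    total = mean.sum()
    if total <= 0:
        raise ValueError("zero total signal in region")
    fp = pd.Series(mean / total, index=names)
    # merge duplicate annotations (two peaks mapping to one species)
    return fp.groupby(level=0).sum().reindex(pd.unique(np.asarray(names)))


def fingerprint_table(rows: dict) -> pd.DataFrame:
    """Assemble {(sample_id, region_name): fingerprint Series} into a
    table with a (sample, region) MultiIndex; species columns aligned,
    missing species filled with 0."""
    df = pd.DataFrame({k: v for k, v in rows.items()}).T.fillna(0.0)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["sample", "region"])
    return df


def compare_regions(table: pd.DataFrame, species: str, region_pair,
                    equal_var: bool = False) -> dict:
    """Welch (default) two-sided t-test for one species between two regions,
    across samples.  Returns a row dict with the star code."""
    ra, rb = region_pair
    a = table.xs(ra, level="region")[species].to_numpy(float)
    b = table.xs(rb, level="region")[species].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 samples per region, got {len(a)} vs {len(b)}")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {"species": species, "region_a": ra, "region_b": rb,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "mean_diff": float(a.mean() - b.mean()),
            "t": float(t), "p": float(p), "stars": star_code(float(p))}


def compare_all(table: pd.DataFrame, region_pairs=None,
                equal_var: bool = False) -> pd.DataFrame:
    """Comparison table over all species and region pairs, with an
    additional Benjamini-Hochberg column for transparency (the stars
    themselves are per-species, uncorrected, as published)."""
    regions = list(table.index.get_level_values("region").unique())
    if region_pairs is None:
        region_pairs = [(a, b) for i, a in enumerate(regions) for b in regions[i + 1:]]
    rows = [compare_regions(table, s, pair, equal_var=equal_var)
            for pair in region_pairs for s in table.columns]
    out = pd.DataFrame(rows)
    m = len(out)
    order = np.argsort(out["p"].to_numpy())
    bh = np.empty(m)
    prev = 1.0
    for rank, i in enumerate(order[::-1]):
        k = m - rank
        prev = min(prev, out["p"].iloc[i] * m / k)
        bh[i] = prev
    out["p_bh"] = bh
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None = None


def pca_scores(table: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Mean-centred PCA of the fingerprint table (unit-variance scaling
    optional).  Constant columns are dropped with a warning; the sign of
    each component is fixed so its largest-magnitude loading is positive."""
    if len(table) < 3:
        raise ValueError("need at least 3 fingerprints for PCA")
    X = table.to_numpy(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) before PCA")
        X = X[:, keep]
    cols = table.columns[keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 varying species columns")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U * S
    var = S ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i+1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=pcs),
        explained_variance_ratio=ratio, mean=mean, scale=sd)


@dataclass
class ClassificationReport:
    """Out-of-fold classification metrics built from the pooled confusion
    matrix (rows: true class, columns: predicted)."""

    confusion: pd.DataFrame
    per_class: pd.DataFrame        # precision, sensitivity, specificity
    macro: dict
    scheme: str
    seed: int
    predictions: pd.Series = field(default=None, repr=False)

    @staticmethod
    def from_confusion(confusion: pd.DataFrame, scheme: str, seed: int,
                       predictions=None) -> "ClassificationReport":
        C = confusion.to_numpy(float)
        total = C.sum()
        rows = []
        for k, cls in enumerate(confusion.index):
            tp = C[k, k]
            fn = C[k].sum() - tp
            fp = C[:, k].sum() - tp
            tn = total - tp - fn - fp
            rows.append({
                "class": cls,
                "precision": tp / (tp + fp) if tp + fp else 0.0,
                "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
                "specificity": tn / (tn + fp) if tn + fp else 0.0,
            })
        per_class = pd.DataFrame(rows).set_index("class")
        macro = {m: float(per_class[m].mean())
                 for m in ("precision", "sensitivity", "specificity")}
        macro["accuracy"] = float(np.trace(C) / total)
        return ClassificationReport(confusion=confusion, per_class=per_class,
                                    macro=macro, scheme=scheme, seed=seed,
                                    predictions=predictions)


def classify_regions(table: pd.DataFrame, labels=None, scheme: str = "loso",
                     seed: int = 0, n_estimators: int = 500,
                     n_splits: int = 3) -> ClassificationReport:
    """Random-forest classification of region fingerprints, evaluated
    strictly out-of-fold.

    ``scheme``: ``loso`` = leave-one-sample-out (all regions of one
    sample held out together) or ``stratified-kfold``.  Metrics come from
    the pooled out-of-fold confusion matrix; specificity is one-vs-rest.
    """
    X = table.to_numpy(float)
    if labels is None:
        labels = table.index.get_level_values("region").to_numpy()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    groups = table.index.get_level_values("sample").to_numpy()

    if scheme == "loso":
        splitter = LeaveOneGroupOut().split(X, labels, groups)
    elif scheme == "stratified-kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=seed).split(X, labels)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    pred = np.empty(len(labels), dtype=object)
    for train, test in splitter:
        if len(np.unique(labels[train])) < 2:
            import warnings
            warnings.warn("fold without class diversity skipped")
            pred[test] = None
            continue
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    max_features="sqrt", random_state=seed)
        rf.fit(X[train], labels[train])
        pred[test] = rf.predict(X[test])
    valid = pred != None  # noqa: E711
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(labels[valid], pred[valid]):
        conf.loc[t, p] += 1
    return ClassificationReport.from_confusion(
        conf, scheme=scheme, seed=seed,
        predictions=pd.Series(pred, index=table.index, name="predicted"))
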