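"""The three-pronged TGx-DDI classifier.

A test exposure is expressed as a 64-gene log2-ratio profile and classified
by three independent methods trained on reference agents with known
DNA-damage-inducing (DDI) or non-DDI activity:

* **PA** — nearest-shrunken-centroid probability analysis.  Class centroids
  are optionally soft-thresholded toward the overall centroid in
  standardized units; the discriminant score for class *k* is the squared
  standardized distance to the shrunken centroid minus ``2 log pi_k``, and
  the posterior is the softmax of ``-score / 2``.  A call requires a
  posterior of at least 0.9; anything less is inconclusive.
* **PCA** — the profile is projected onto the first principal component of
  the gene-centered training matrix (oriented so the DDI class mean is
  positive).  Scores inside a symmetric band around the midpoint of the two
  class means — i.e. profiles that fall "on the axis" between the classes —
  are inconclusive.
* **HCA** — the profile is clustered with the training agents
  (agglomerative, two-cluster cut).  The test sample inherits the majority
  label of its branch; a branch without a strict majority, or a singleton
  test branch, is inconclusive.

The combined sample call is deliberately conservative: DDI if *any* method
says DDI; non-DDI only if *all three* agree; otherwise the majority of
{non-DDI, inconclusive}.

Estimators follow scikit-learn conventions (``fit``/``predict``/
``get_params``) and accept either plain arrays (samples x genes) or
DataFrames, in which case gene names are recorded and later profiles are
aligned by name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import (
    AlignmentError,
    DegenerateModelError,
    DegenerateSeparationError,
)

DDI = "DDI"
NON_DDI = "nonDDI"
INCONCLUSIVE = "inconclusive"
CLASSES = (DDI, NON_DDI)

PA_THRESHOLD = 0.9

_METRICS = ("euclidean", "cityblock", "correlation", "cosine")
_LINKAGES = ("average", "complete", "single", "ward")


@dataclass(frozen=True)
class MethodCall:
    """One method's verdict: the call plus its underlying score
    (posterior for PA, PC1 coordinate for PCA, branch purity for HCA)."""

    method: str  # "PA" | "PCA" | "HCA"
    call: str  # DDI | nonDDI | inconclusive
    score: float


@dataclass(frozen=True)
class SampleCall:
    """Combined sample-level call with the three per-method sub-calls."""

    sample_id: str
    pa: MethodCall
    pca: MethodCall
    hca: MethodCall
    call: str


@dataclass
class LabeledProfileSet:
    """Training agents: 64-gene log2-ratio profiles with DDI/non-DDI labels.

    ``profiles`` is genes x agents; ``labels`` maps agent id to class.
    """

    profiles: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.profiles.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"agents without labels: {missing[:3]}")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        counts = self.labels.value_counts()
        for cls in CLASSES:
            if counts.get(cls, 0) < 2:
                raise ValueError(f"need >= 2 agents of class {cls}, got {counts.get(cls, 0)}")

    @property
    def X(self) -> pd.DataFrame:
        """Agents x genes matrix (scikit-learn orientation)."""
        return self.profiles.T

    @property
    def y(self) -> pd.Series:
        return self.labels


def _as_matrix(X, feature_names: Sequence[str] | None):
    """Coerce input to a 2-D float array, aligning DataFrame columns by name."""
    if isinstance(X, pd.Series):
        X = X.to_frame().T
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [g for g in feature_names if g not in X.columns]
            if missing:
                raise AlignmentError(f"profile missing genes: {missing[:5]}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float), list(X.index.astype(str))
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if feature_names is not None and arr.shape[1] != len(feature_names):
        raise AlignmentError(
            f"profile has {arr.shape[1]} genes, model expects {len(feature_names)}"
        )
    return arr, [str(i) for i in range(arr.shape[0])]


class ShrunkenCentroidClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-shrunken-centroid classifier with class posteriors.

    Parameters
    ----------
    shrinkage:
        Soft-threshold amount applied to the standardized centroid offsets
        (0 leaves the per-class means untouched; the 64-gene panel is
        already a selected signature, so 0 is the default).
    priors:
        Class prior probabilities in the order of ``classes_`` (sorted);
        ``None`` means equal priors.
    s0:
        Variance-offset added to each gene's pooled within-class standard
        deviation; ``None`` uses the median of the pooled SDs.
    """

    def __init__(self, shrinkage: float = 0.0, priors=None, s0: float | None = None):
        self.shrinkage = shrinkage
        self.priors = priors
        self.s0 = s0

    def fit(self, X, y):
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X, _ = _as_matrix(X, None)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected 2 classes, got {list(self.classes_)}")
        n, p = X.shape
        counts = np.array([(y == c).sum() for c in self.classes_])
        if (counts < 2).any():
            raise ValueError("need >= 2 samples per class")
        self.feature_names_in_ = names
        overall = X.mean(axis=0)
        class_means = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        # Pooled within-class SD with n - K denominator.
        resid = X - class_means[np.searchsorted(self.classes_, y)]
        s = np.sqrt((resid**2).sum(axis=0) / (n - len(self.classes_)))
        s0 = float(np.median(s)) if self.s0 is None else float(self.s0)
        if ((s + s0) == 0).any():
            raise DegenerateModelError(
                "zero pooled standard deviation with s0 = 0 for at least one gene"
            )
        m = np.sqrt(1.0 / counts - 1.0 / n)
        d = (class_means - overall) / (m[:, None] * (s + s0))
        if self.shrinkage > 0:
            d = np.sign(d) * np.clip(np.abs(d) - self.shrinkage, 0.0, None)
        shrunken = overall + m[:, None] * (s + s0) * d

        self.overall_centroid_ = overall
        self.centroids_ = shrunken
        self.pooled_sd_ = s
        self.s0_ = s0
        if self.priors is None:
            self.class_priors_ = np.full(len(self.classes_), 1.0 / len(self.classes_))
        else:
            pr = np.asarray(self.priors, dtype=float)
            self.class_priors_ = pr / pr.sum()
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Discriminant scores delta_k(x) (lower is closer), one row per sample."""
        X, _ = _as_matrix(X, self.feature_names_in_)
        denom = (self.pooled_sd_ + self.s0_) ** 2
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k, centroid in enumerate(self.centroids_):
            scores[:, k] = ((X - centroid) ** 2 / denom).sum(axis=1)
        scores -= 2.0 * np.log(self.class_priors_)
        return scores

    def predict_proba(self, X) -> np.ndarray:
        """Softmax posterior over classes, computed stably."""
        scores = self.decision_scores(X)
        z = -0.5 * scores
        z -= z.max(axis=1, keepdims=True)
        expz = np.exp(z)
        return expz / expz.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class Pc1BandClassifier(BaseEstimator, ClassifierMixin):
    """PC1-projection classifier with a symmetric inconclusive band.

    The band is centered at the midpoint of the two class means on PC1 and
    its half-width is ``band_fraction`` of the distance between them; a
    score on or inside the band is inconclusive.
    """

    def __init__(self, band_fraction: float = 0.1):
        self.band_fraction = band_fraction

    def fit(self, X, y):
        if not (0 <= self.band_fraction < 0.5):
            raise ValueError("band_fraction must be in [0, 0.5)")
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X, _ = _as_matrix(X, None)
        y = np.asarray(y)
        if X.shape[0] < 3:
            raise ValueError("need >= 3 training agents for PCA")
        self.feature_names_in_ = names
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        # Full SVD of the centered matrix; rows of Vt are the loadings.
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt.T
        ddi_mean = scores[y == DDI, 0].mean()
        non_mean = scores[y == NON_DDI, 0].mean()
        if np.isclose(ddi_mean, non_mean):
            raise DegenerateSeparationError("identical class means on PC1")
        sign = 1.0 if ddi_mean > non_mean else -1.0
        vt = vt * sign  # orient every component consistently with PC1
        scores = scores * sign
        ddi_mean, non_mean = sign * ddi_mean, sign * non_mean
        self.components_ = vt
        self.training_scores_ = scores
        self.pc1_class_means_ = {DDI: float(ddi_mean), NON_DDI: float(non_mean)}
        self.midpoint_ = 0.5 * (ddi_mean + non_mean)
        self.band_halfwidth_ = self.band_fraction * abs(ddi_mean - non_mean)
        return self

    def transform(self, X) -> np.ndarray:
        """PC1 scores of new profiles in the training projection."""
        X, _ = _as_matrix(X, self.feature_names_in_)
        return (X - self.mean_) @ self.components_[0]

    def predict(self, X) -> np.ndarray:
        scores = self.transform(X)
        out = np.full(scores.shape, INCONCLUSIVE, dtype=object)
        out[scores > self.midpoint_ + self.band_halfwidth_] = DDI
        out[scores < self.midpoint_ - self.band_halfwidth_] = NON_DDI
        return out


class DendrogramBranchClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical-clustering branch assignment.

    Each test profile is clustered jointly with the training agents
    (one profile at a time, so test samples never influence each other),
    the dendrogram is cut into two clusters, and the test sample's branch
    is labeled by its training members: the class of a strict
    ``purity_threshold`` majority, else inconclusive.  A test sample
    forming its own branch is inconclusive.
    """

    def __init__(
        self,
        metric: str = "euclidean",
        linkage: str = "average",
        purity_threshold: float = 0.5,
    ):
        self.metric = metric
        self.linkage = linkage
        self.purity_threshold = purity_threshold

    def fit(self, X, y):
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if self.linkage == "ward" and self.metric != "euclidean":
            raise ValueError("ward linkage requires the euclidean metric")
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        Xa, _ = _as_matrix(X, None)
        y = np.asarray(y)
        for cls in CLASSES:
            if (y == cls).sum() < 2:
                raise ValueError(f"need >= 2 training agents of class {cls}")
        self.feature_names_in_ = names
        self.X_ = Xa
        self.y_ = y
        return self

    def _call_one(self, x: np.ndarray) -> MethodCall:
        stacked = np.vstack([self.X_, x[None, :]])
        Z = scipy_linkage(pdist(stacked, metric=self.metric), method=self.linkage)
        assignment = fcluster(Z, t=2, criterion="maxclust")
        test_cluster = assignment[-1]
        members = self.y_[assignment[:-1] == test_cluster]
        if len(members) == 0:
            return MethodCall("HCA", INCONCLUSIVE, 0.0)
        ddi_frac = float((members == DDI).mean())
        if ddi_frac > self.purity_threshold:
            return MethodCall("HCA", DDI, ddi_frac)
        if (1.0 - ddi_frac) > self.purity_threshold:
            return MethodCall("HCA", NON_DDI, 1.0 - ddi_frac)
        return MethodCall("HCA", INCONCLUSIVE, max(ddi_frac, 1.0 - ddi_frac))

    def predict(self, X) -> np.ndarray:
        X, _ = _as_matrix(X, self.feature_names_in_)
        return np.array([self._call_one(row).call for row in X], dtype=object)

    def method_calls(self, X) -> list[MethodCall]:
        X, _ = _as_matrix(X, self.feature_names_in_)
        return [self._call_one(row) for row in X]


# ---------------------------------------------------------------------------
# Call combination
# ---------------------------------------------------------------------------

def pa_call(posterior: Mapping[str, float] | Sequence[float], threshold: float = PA_THRESHOLD) -> MethodCall:
    """Probability-analysis call from a class posterior.

    DDI if posterior(DDI) >= threshold, non-DDI if posterior(nonDDI) >=
    threshold, otherwise inconclusive.
    """
    if isinstance(posterior, Mapping):
        p_ddi = float(posterior[DDI])
        p_non = float(posterior[NON_DDI])
    else:
        p_ddi, p_non = float(posterior[0]), float(posterior[1])
    if p_ddi >= threshold:
        return MethodCall("PA", DDI, p_ddi)
    if p_non >= threshold:
        return MethodCall("PA", NON_DDI, p_ddi)
    return MethodCall("PA", INCONCLUSIVE, p_ddi)


def combine_method_calls(pa: str, pca: str, hca: str) -> str:
    """Conservative combination: DDI if any method is DDI; non-DDI only if all
    three are; otherwise the majority of {non-DDI, inconclusive}."""
    calls = (pa, pca, hca)
    if DDI in calls:
        return DDI
    if all(c == NON_DDI for c in calls):
        return NON_DDI
    n_non = sum(c == NON_DDI for c in calls)
    n_inc = sum(c == INCONCLUSIVE for c in calls)
    return NON_DDI if n_non > n_inc else INCONCLUSIVE


def three_pronged_call(
    pa: MethodCall, pca: MethodCall, hca: MethodCall, sample_id: str = ""
) -> SampleCall:
    """Combine the three method calls into a :class:`SampleCall`."""
    return SampleCall(
        sample_id=sample_id,
        pa=pa,
        pca=pca,
        hca=hca,
        call=combine_method_calls(pa.call, pca.call, hca.call),
    )


class ThreeProngedClassifier(BaseEstimator, ClassifierMixin):
    """Meta-estimator running PA, PCA, and HCA and combining their calls."""

    def __init__(
        self,
        shrinkage: float = 0.0,
        priors=None,
        s0: float | None = None,
        band_fraction: float = 0.1,
        metric: str = "euclidean",
        linkage: str = "average",
        purity_threshold: float = 0.5,
        pa_threshold: float = PA_THRESHOLD,
    ):
        self.shrinkage = shrinkage
        self.priors = priors
        self.s0 = s0
        self.band_fraction = band_fraction
        self.metric = metric
        self.linkage = linkage
        self.purity_threshold = purity_threshold
        self.pa_threshold = pa_threshold

    def fit(self, X, y=None):
        """Fit all three prongs.  ``X`` may be a LabeledProfileSet
        (in which case ``y`` is ignored) or an agents x genes matrix."""
        if isinstance(X, LabeledProfileSet):
            X, y = X.X, X.y
        self.nsc_ = ShrunkenCentroidClassifier(
            shrinkage=self.shrinkage, priors=self.priors, s0=self.s0
        ).fit(X, y)
        self.pca_ = Pc1BandClassifier(band_fraction=self.band_fraction).fit(X, y)
        self.hca_ = DendrogramBranchClassifier(
            metric=self.metric,
            linkage=self.linkage,
            purity_threshold=self.purity_threshold,
        ).fit(X, y)
        self.feature_names_in_ = self.nsc_.feature_names_in_
        return self

    def classify(self, X, sample_ids: Sequence[str] | None = None) -> list[SampleCall]:
        """Full per-sample calls with method sub-calls."""
        arr, inferred_ids = _as_matrix(X, self.feature_names_in_)
        if sample_ids is None:
            sample_ids = inferred_ids
        posteriors = self.nsc_.predict_proba(arr)
        k_ddi = int(np.where(self.nsc_.classes_ == DDI)[0][0])
        k_non = int(np.where(self.nsc_.classes_ == NON_DDI)[0][0])
        pc1 = self.pca_.transform(arr)
        pca_calls = self.pca_.predict(arr)
        hca_calls = self.hca_.method_calls(arr)
        out = []
        for i, sid in enumerate(sample_ids):
            pa = pa_call(
                {DDI: posteriors[i, k_ddi], NON_DDI: posteriors[i, k_non]},
                threshold=self.pa_threshold,
            )
            pca = MethodCall("PCA", pca_calls[i], float(pc1[i]))
            out.append(three_pronged_call(pa, pca, hca_calls[i], sample_id=str(sid)))
        return out

    def predict(self, X) -> np.ndarray:
        return np.array([sc.call for sc in self.classify(X)], dtype=object)


# ---------------------------------------------------------------------------
# Thin functional wrappers and model persistence
# ---------------------------------------------------------------------------

def train_nsc(
    training: LabeledProfileSet, shrinkage: float = 0.0, priors=None
) -> ShrunkenCentroidClassifier:
    return ShrunkenCentroidClassifier(shrinkage=shrinkage, priors=priors).fit(
        training.X, training.y
    )


def nsc_posterior(model: ShrunkenCentroidClassifier, profile) -> dict[str, float]:
    proba = model.predict_proba(profile)[0]
    return {cls: float(p) for cls, p in zip(model.classes_, proba)}


def fit_pca(training: LabeledProfileSet, band_fraction: float = 0.1) -> Pc1BandClassifier:
    return Pc1BandClassifier(band_fraction=band_fraction).fit(training.X, training.y)


def pca_call(model: Pc1BandClassifier, profile) -> MethodCall:
    return MethodCall("PCA", model.predict(profile)[0], float(model.transform(profile)[0]))


def hca_call(
    training: LabeledProfileSet,
    profile,
    metric: str = "euclidean",
    linkage: str = "average",
    purity_threshold: float = 0.5,
) -> MethodCall:
    clf = DendrogramBranchClassifier(
        metric=metric, linkage=linkage, purity_threshold=purity_threshold
    ).fit(training.X, training.y)
    return clf.method_calls(profile)[0]


def save_model(clf: ThreeProngedClassifier, path: str | Path) -> None:
    """Serialize a fitted three-pronged classifier to a JSON text file."""
    payload = {
        "params": clf.get_params(),
        "feature_names": clf.feature_names_in_,
        "nsc": {
            "classes": clf.nsc_.classes_.tolist(),
            "overall_centroid": clf.nsc_.overall_centroid_.tolist(),
            "centroids": clf.nsc_.centroids_.tolist(),
            "pooled_sd": clf.nsc_.pooled_sd_.tolist(),
            "s0": clf.nsc_.s0_,
            "priors": clf.nsc_.class_priors_.tolist(),
        },
        "pca": {
            "mean": clf.pca_.mean_.tolist(),
            "components": clf.pca_.components_.tolist(),
            "midpoint": clf.pca_.midpoint_,
            "band_halfwidth": clf.pca_.band_halfwidth_,
            "pc1_class_means": clf.pca_.pc1_class_means_,
        },
        "hca": {"X": clf.hca_.X_.tolist(), "y": clf.hca_.y_.tolist()},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> ThreeProngedClassifier:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    params = payload["params"]
    clf = ThreeProngedClassifier(**params)
    names = payload["feature_names"]

    nsc = ShrunkenCentroidClassifier(
        shrinkage=params["shrinkage"], priors=params["priors"], s0=params["s0"]
    )
    d = payload["nsc"]
    nsc.classes_ = np.array(d["classes"])
    nsc.overall_centroid_ = np.array(d["overall_centroid"])
    nsc.centroids_ = np.array(d["centroids"])
    nsc.pooled_sd_ = np.array(d["pooled_sd"])
    nsc.s0_ = d["s0"]
    nsc.class_priors_ = np.array(d["priors"])
    nsc.feature_names_in_ = names

    pca = Pc1BandClassifier(band_fraction=params["band_fraction"])
    d = payload["pca"]
    pca.mean_ = np.array(d["mean"])
    pca.components_ = np.array(d["components"])
    pca.midpoint_ = d["midpoint"]
    pca.band_halfwidth_ = d["band_halfwidth"]
    pca.pc1_class_means_ = d["pc1_class_means"]
    pca.feature_names_in_ = names

    hca = DendrogramBranchClassifier(
        metric=params["metric"],
        linkage=params["linkage"],
        purity_threshold=params["purity_threshold"],
    )
    d = payload["hca"]
    hca.X_ = np.array(d["X"])
    hca.y_ = np.array(d["y"])
    hca.feature_names_in_ = names

    clf.nsc_, clf.pca_, clf.hca_ = nsc, pca, hca
    clf.feature_names_in_ = names
    return clf
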