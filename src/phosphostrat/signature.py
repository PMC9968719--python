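"""Phosphoproteomics signature derivation and cohort stratification.

The procedure mirrors a train/validate design for splitting KMT2A-rearranged
AML into two subgroups:

1. **Feature selection** — per-feature Student t-test on the *training*
   samples contrasting KMT2A-rearranged cases against all other karyotypes;
   the k features with the lowest p-values form the signature, with
   ``k = floor(n_train / 2)`` by default to limit overfitting.
2. **Signature PCA** — principal components of the training samples over the
   signature features (missing cells imputed with training feature means);
   all cohorts are projected with the training centering.
3. **Region definition** — Ward hierarchical clustering of the
   KMT2A-rearranged training samples in the (PC1, PC2) plane, cut into two
   clusters; the larger cluster's convex hull, expanded by a margin, is the
   MLLGA region.
4. **Classification** — training samples are labelled by the region
   (MLLGA / No-MLLGA) and a seeded random forest trained on those labels
   reclassifies every sample; the forest's output is the authoritative final
   label.

Every fitted quantity (selection, centering, region, forest) depends on the
training samples only, so non-training samples can never leak into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from . import differential
from .errors import DegenerateInputError, ValidationError
from .omics import OmicsMatrix

POSITIVE_LABEL = "MLLGA"
NEGATIVE_LABEL = "No-MLLGA"


@dataclass
class Signature:
    """Selected phosphopeptide features, ordered by ascending selection p."""

    feature_ids: list[str]
    selection_p: pd.Series
    k: int
    train_sample_ids: list[str]
    contrast: tuple[str, str]


@dataclass
class PcaModel:
    """PCA fitted on training samples over the signature features."""

    loadings: pd.DataFrame            # feature x component
    explained_variance_ratio: np.ndarray
    mean: pd.Series                   # training centering vector
    feature_means: pd.Series          # training per-feature means for imputation
    scores: pd.DataFrame              # fitted training scores, sample x PC


@dataclass
class Region:
    """Convex region in the (PC1, PC2) plane defining MLLGA membership."""

    vertices: np.ndarray              # (n, 2) polygon vertices, closed ring omitted
    margin: float
    _polygon: Polygon = field(repr=False, default=None)  # type: ignore[assignment]

    def polygon(self) -> Polygon:
        if self._polygon is None:
            self._polygon = Polygon(self.vertices)
        return self._polygon

    def contains(self, x: float, y: float) -> bool:
        """Point-in-region test; the boundary counts as inside."""
        return bool(self.polygon().covers(Point(float(x), float(y))))


@dataclass
class SignatureClassifier:
    """Seeded random forest over the signature features."""

    forest: RandomForestClassifier
    feature_ids: list[str]
    feature_means: pd.Series
    oob_accuracy: float
    seed: int


@dataclass
class StratificationResult:
    """Everything :func:`stratify_cohort` derives."""

    signature: Signature
    pca: PcaModel
    region: Region
    cluster_report: pd.DataFrame
    region_assignments: pd.DataFrame
    classifier: SignatureClassifier
    assignments: pd.DataFrame
    importances: pd.DataFrame


def select_features(
    m: OmicsMatrix,
    group_pos: Sequence[str],
    group_neg: Sequence[str],
    k: int | None = None,
    min_obs: int = 3,
) -> Signature:
    """Select the signature by t-test p-value on training samples.

    ``k`` defaults to ``floor(n_train / 2)`` where ``n_train`` is the total
    number of training samples in the two contrast groups.  Ties on p are
    broken by larger ``|log2fc|`` then by feature id.
    """
    group_pos, group_neg = list(group_pos), list(group_neg)
    n_train = len(group_pos) + len(group_neg)
    if k is None:
        k = n_train // 2
    res = differential.ttest_two_group(m, group_pos, group_neg, min_obs=min_obs)
    tested = res[res["tested"]].copy()
    if k > len(tested):
        raise ValidationError(
            f"k={k} exceeds the {len(tested)} tested features"
        )
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    # p ascending, ties by larger |log2fc|, then feature id for determinism
    tested = tested.assign(abs_lfc=tested["log2fc"].abs(), _fid=tested.index)
    tested = tested.sort_values(["p", "abs_lfc", "_fid"], ascending=[True, False, True],
                                kind="mergesort")
    top = tested.head(k)
    return Signature(
        feature_ids=list(top.index),
        selection_p=top["p"].copy(),
        k=k,
        train_sample_ids=group_pos + group_neg,
        contrast=(POSITIVE_LABEL, NEGATIVE_LABEL),
    )


def _signature_matrix(
    m: OmicsMatrix,
    feature_ids: Sequence[str],
    samples: Sequence[str],
    feature_means: pd.Series | None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample x feature submatrix with mean imputation.

    When ``feature_means`` is None the means are computed from ``samples``
    (the training set); otherwise the supplied (training) means are used so
    new cohorts never influence the imputation constants.
    """
    missing = set(feature_ids) - set(m.feature_ids)
    if missing:
        raise ValidationError(f"features absent from matrix: {sorted(missing)[:10]}")
    x = m.values.loc[list(feature_ids), list(samples)].T  # samples x features
    if feature_means is None:
        feature_means = x.mean(axis=0, skipna=True)
        if feature_means.isna().any():
            bad = feature_means.index[feature_means.isna()][0]
            raise DegenerateInputError(
                f"feature {bad!r} has no observed training values to impute from"
            )
    x = x.fillna(feature_means)
    return x, feature_means


def fit_pca(m: OmicsMatrix, signature: Signature, samples: Sequence[str] | None = None,
            n_components: int | None = None) -> PcaModel:
    """Fit PCA on (training) samples restricted to the signature features."""
    samples = list(samples) if samples is not None else list(signature.train_sample_ids)
    if len(samples) < 2:
        raise ValidationError("PCA needs >= 2 samples")
    x, feature_means = _signature_matrix(m, signature.feature_ids, samples, None)
    k = min(len(samples), len(signature.feature_ids)) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    scores = pca.fit_transform(x.to_numpy())
    pc_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaModel(
        loadings=pd.DataFrame(pca.components_.T, index=list(signature.feature_ids),
                              columns=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pd.Series(pca.mean_, index=list(signature.feature_ids)),
        feature_means=feature_means,
        scores=pd.DataFrame(scores, index=samples, columns=pc_names),
    )


def project(model: PcaModel, m: OmicsMatrix, samples: Sequence[str] | None = None,
            drop_missing_features: bool = False) -> pd.DataFrame:
    """Project samples onto a fitted PCA (training centering and imputation).

    Features absent from ``m`` raise an error listing them unless
    ``drop_missing_features`` is set, in which case the shared features are
    used with the corresponding loading rows (an approximation, off by
    default).
    """
    samples = list(samples) if samples is not None else m.sample_ids
    features = list(model.loadings.index)
    absent = [f for f in features if f not in set(m.feature_ids)]
    if absent and not drop_missing_features:
        raise ValidationError(f"features absent from matrix: {absent[:10]}")
    kept = [f for f in features if f not in set(absent)]
    x, _ = _signature_matrix(m, kept, samples, model.feature_means.loc[kept])
    centered = x - model.mean.loc[kept]
    scores = centered.to_numpy() @ model.loadings.loc[kept].to_numpy()
    return pd.DataFrame(scores, index=samples, columns=list(model.loadings.columns))


def define_region(
    scores: pd.DataFrame,
    margin: float | None = None,
    pc1_range: float | None = None,
) -> tuple[Region, pd.DataFrame]:
    """Cluster positive-class training scores and define the MLLGA region.

    Ward hierarchical clustering (Euclidean) of the (PC1, PC2) coordinates,
    cut into two clusters.  The larger cluster (ties broken towards the
    cluster containing the lexicographically smallest sample id) defines the
    region: the convex hull of its points expanded outward by ``margin``
    (default 5% of the PC1 range; square caps / mitred joins keep the region
    a convex polygon, and degenerate hulls thicken into rectangles/squares).
    """
    if scores.shape[0] < 3:
        raise ValidationError("define_region needs >= 3 positive-class samples")
    pts = scores.iloc[:, :2].to_numpy(dtype=float)
    if margin is None:
        rng = pc1_range if pc1_range is not None else float(pts[:, 0].max() - pts[:, 0].min())
        margin = 0.05 * rng if rng > 0 else 0.05
    labels = fcluster(linkage(pts, method="ward"), t=2, criterion="maxclust")
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    if len(sizes) == 1:
        main = next(iter(sizes))
    else:
        best = max(sizes.values())
        candidates = [c for c, s in sizes.items() if s == best]
        if len(candidates) == 1:
            main = candidates[0]
        else:
            first = {c: min(scores.index[labels == c]) for c in candidates}
            main = min(first, key=first.get)
    members = labels == main
    geom = MultiPoint([tuple(p) for p in pts[members]]).convex_hull
    if margin > 0:
        geom = geom.buffer(margin, cap_style="square", join_style="mitre")
    if not isinstance(geom, Polygon) or geom.is_empty:
        raise DegenerateInputError(
            "region degenerates to a point/segment; use a positive margin"
        )
    vertices = np.asarray(geom.exterior.coords)[:-1]
    report = pd.DataFrame(
        {"cluster": labels, "in_region_cluster": members}, index=scores.index
    )
    return Region(vertices=vertices, margin=float(margin)), report


def assign_by_region(scores: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Label samples by region membership (boundary counts as inside)."""
    labels, probs = [], []
    for _, row in scores.iterrows():
        inside = region.contains(row.iloc[0], row.iloc[1])
        labels.append(POSITIVE_LABEL if inside else NEGATIVE_LABEL)
        probs.append(1.0 if inside else 0.0)
    return pd.DataFrame(
        {"label": labels, "probability_mllga": probs, "source": "region"},
        index=scores.index,
    )


def train_classifier(
    m: OmicsMatrix,
    signature: Signature,
    labels: pd.Series,
    seed: int,
    n_trees: int = 1000,
) -> SignatureClassifier:
    """Train the seeded random forest on training samples and region labels."""
    classes = set(labels.unique())
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    unknown = classes - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if unknown:
        raise ValidationError(f"unknown training label(s): {sorted(unknown)}")
    samples = list(labels.index)
    x, feature_means = _signature_matrix(m, signature.feature_ids, samples, None)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, bootstrap=True
    )
    forest.fit(x.to_numpy(), labels.to_numpy())
    return SignatureClassifier(
        forest=forest,
        feature_ids=list(signature.feature_ids),
        feature_means=feature_means,
        oob_accuracy=float(forest.oob_score_),
        seed=seed,
    )


def classify(clf: SignatureClassifier, m: OmicsMatrix,
             samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Assign samples with the trained forest; ties go to MLLGA at p = 0.5."""
    samples = list(samples) if samples is not None else m.sample_ids
    x, _ = _signature_matrix(m, clf.feature_ids, samples, clf.feature_means)
    proba = clf.forest.predict_proba(x.to_numpy())
    pos_col = list(clf.forest.classes_).index(POSITIVE_LABEL)
    p_pos = proba[:, pos_col]
    labels = np.where(p_pos >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame(
        {"label": labels, "probability_mllga": p_pos, "source": "classifier"},
        index=samples,
    )


def feature_importance(clf: SignatureClassifier) -> pd.DataFrame:
    """Mean-decrease-in-impurity importances, normalized, sorted descending."""
    if not hasattr(clf.forest, "feature_importances_"):
        raise ValidationError("classifier is not trained")
    imp = np.asarray(clf.forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    out = pd.DataFrame({"feature_id": clf.feature_ids, "importance": imp})
    out = out.sort_values(["importance", "feature_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out


def stratify_cohort(
    m: OmicsMatrix,
    meta: pd.DataFrame,
    *,
    positive_karyotype: str = "KMT2Ar",
    seed: int = 0,
    k: int | None = None,
    margin: float | None = None,
    n_trees: int = 1000,
    min_obs: int = 3,
) -> StratificationResult:
    """End-to-end stratification of a cohort.

    Training samples (``meta.split == 'train'``) drive feature selection
    (karyotype contrast), PCA, region definition and classifier training;
    every sample in ``m`` then receives a final label from the classifier.
    """
    train = meta.loc[meta["split"] == "train", "sample_id"].tolist()
    if not train:
        raise ValidationError("metadata contains no training samples")
    kary = meta.loc[train, "karyotype"]
    pos = [s for s in train if kary[s] == positive_karyotype]
    neg = [s for s in train if kary[s] != positive_karyotype]
    sig = select_features(m, pos, neg, k=k, min_obs=min_obs)
    pca = fit_pca(m, sig, train)
    train_scores = pca.scores
    pc1_range = float(train_scores["PC1"].max() - train_scores["PC1"].min())
    region, cluster_report = define_region(train_scores.loc[pos, ["PC1", "PC2"]],
                                           margin=margin, pc1_range=pc1_range)
    region_assign = assign_by_region(train_scores[["PC1", "PC2"]], region)
    clf = train_classifier(m, sig, region_assign["label"], seed=seed, n_trees=n_trees)
    assignments = classify(clf, m, m.sample_ids)
    return StratificationResult(
        signature=sig,
        pca=pca,
        region=region,
        cluster_report=cluster_report,
        region_assignments=region_assign,
        classifier=clf,
        assignments=assignments,
        importances=feature_importance(clf),
    )
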