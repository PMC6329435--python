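"""scikit-learn-style estimators over the clustering engine.

``FacetCleaner`` is the package's main entry point: a transformer that
learns a wrong-value -> canonical-value mapping from a column of strings
(``fit``) and rewrites columns through it (``transform``). The two
clusterer estimators expose the individual clustering strategies with the
familiar ``fit_predict`` label interface. All three compose with sklearn
pipelines and ``clone``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .cluster import (
    Cluster,
    FacetTable,
    PipelineConfig,
    build_facet,
    key_collision_cluster,
    nn_cluster,
    run_pipeline,
)
from .distance import DistanceSpec
from .keying import KeySpec


def _as_string_list(X) -> list[str]:
    if hasattr(X, "ndim") and getattr(X, "ndim", 1) == 2 and X.shape[1] == 1:
        X = np.asarray(X).ravel()
    values = list(X)
    bad = next((v for v in values if not isinstance(v, str)), None)
    if bad is not None:
        raise TypeError(
            f"expected an iterable of strings, found {type(bad).__name__}"
        )
    return values


class FacetCleaner(TransformerMixin, BaseEstimator):
    """Learn a value-merging plan from a string column and apply it.

    Parameters
    ----------
    key_stages : list of KeySpec, optional
        Key-collision stages, run in order. ``None`` selects the default
        sequence (fingerprint, n-gram fingerprint n=2 and n=1, English
        phonetic, Cologne phonetic).
    nn_stages : list of DistanceSpec, optional
        Nearest-neighbour stages, run after the key stages. ``None`` selects
        normalised edit distance at radius 0.23.
    auto_accept : bool, default True
        Accept every proposed merge. With ``False`` the fitted plan is a
        proposal only (written to ``review_path`` if set) and ``transform``
        is the identity until decisions are supplied.
    review_path : str, optional
        Where to write the review CSV when ``auto_accept=False``.

    Attributes
    ----------
    facet_ : FacetTable
        Facet of the training column.
    plan_ : MergePlan
        Ordered merge records with stage and method attribution.
    mapping_ : dict
        Resolved wrong -> canonical mapping applied by ``transform``.
    facet_cleaned_ : FacetTable
        Facet after all accepted merges.
    """

    def __init__(self, key_stages: Optional[list[KeySpec]] = None,
                 nn_stages: Optional[list[DistanceSpec]] = None,
                 auto_accept: bool = True,
                 review_path: Optional[str] = None) -> None:
        self.key_stages = key_stages
        self.nn_stages = nn_stages
        self.auto_accept = auto_accept
        self.review_path = review_path

    def _config(self) -> PipelineConfig:
        kwargs = {"auto_accept": self.auto_accept,
                  "review_path": self.review_path}
        if self.key_stages is not None:
            kwargs["key_stages"] = list(self.key_stages)
        if self.nn_stages is not None:
            kwargs["nn_stages"] = list(self.nn_stages)
        return PipelineConfig(**kwargs)

    def fit(self, X, y=None) -> "FacetCleaner":
        values = _as_string_list(X)
        self.facet_ = build_facet(values)
        self.plan_, self.facet_cleaned_ = run_pipeline(self.facet_, self._config())
        self.mapping_ = self.plan_.resolved()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "mapping_"):
            raise AttributeError("FacetCleaner is not fitted yet; call fit first")
        values = _as_string_list(X)
        return np.array([self.mapping_.get(v, v) for v in values], dtype=object)

    def fit_facet(self, facet: FacetTable) -> "FacetCleaner":
        """Fit directly from a prebuilt facet (counts already aggregated)."""
        self.facet_ = facet
        self.plan_, self.facet_cleaned_ = run_pipeline(facet, self._config())
        self.mapping_ = self.plan_.resolved()
        return self


class _BaseClusterer(ClusterMixin, BaseEstimator):
    """Shared fit_predict plumbing: facet, cluster, broadcast labels."""

    def _cluster_facet(self, facet: FacetTable) -> list[Cluster]:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        values = _as_string_list(X)
        self.facet_ = build_facet(values)
        self.clusters_ = self._cluster_facet(self.facet_)
        label_of = {}
        for lbl, cl in enumerate(self.clusters_):
            for v in cl.values:
                label_of[v] = lbl
        self.labels_ = np.array([label_of.get(v, -1) for v in values])
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_


class KeyCollisionClusterer(_BaseClusterer):
    """Cluster values sharing a key; unclustered values get label -1.

    Parameters mirror ``KeySpec``: ``method`` is one of ``fingerprint``,
    ``ngram_fingerprint``, ``phonetic_en``, ``phonetic_cologne``;
    ``ngram_size`` applies to the n-gram fingerprint only.
    """

    def __init__(self, method: str = "fingerprint", ngram_size: int = 2) -> None:
        self.method = method
        self.ngram_size = ngram_size

    def _cluster_facet(self, facet: FacetTable) -> list[Cluster]:
        return key_collision_cluster(facet, KeySpec(self.method, self.ngram_size))


class NearestNeighborClusterer(_BaseClusterer):
    """Radius-based string clustering; unclustered values get label -1.

    Parameters mirror ``DistanceSpec``: ``method`` is ``levenshtein``,
    ``normalized_levenshtein`` or ``compression``; ``threshold`` is the
    cluster radius; ``block_chars`` controls candidate blocking on large
    facets.
    """

    def __init__(self, method: str = "normalized_levenshtein",
                 threshold: float = 0.23, block_chars: int = 6) -> None:
        self.method = method
        self.threshold = threshold
        self.block_chars = block_chars

    def _cluster_facet(self, facet: FacetTable) -> list[Cluster]:
        return nn_cluster(
            facet, DistanceSpec(self.method, self.threshold, self.block_chars)
        )


def clean_column(values: Sequence[str], **params) -> tuple[np.ndarray, FacetCleaner]:
    """Convenience wrapper: fit a ``FacetCleaner`` and clean the column."""
    cleaner = FacetCleaner(**params).fit(values)
    return cleaner.transform(values), cleaner
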