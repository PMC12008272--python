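"""Text-embedding backends and variance-threshold dimensionality reduction.

Two backend families are built in:

* a bag-of-n-grams backend (word n-grams, raw counts or tf-idf) fitted on
  a corpus, the classical sparse baseline;
* a ``mock`` dense backend that maps each document to a deterministic
  unit-norm vector of hashed token features.  Its cosine similarity
  tracks token overlap, which is exactly the property the downstream
  semantic-search and retrieval stages rely on, so the whole pipeline is
  testable offline and bit-reproducible.

Adapters for real sentence-embedding checkpoints (dense vectors of size
768/1024/1536) can be registered at runtime via
:func:`register_dense_backend`; none are required.

For the ML stage, high-dimensional embeddings are reduced by PCA on
standardized columns (dense) or truncated SVD (sparse counts), keeping
the smallest leading component count whose cumulative explained variance
reaches the threshold (0.9 by default, which on the original cohort's
dense embeddings yields ~40-45 components).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.preprocessing import StandardScaler

from .errors import FitError, RegistryError, UndefinedSimilarityError

# single-letter tokens are legitimate words here ("I" pre-normalization)
_TOKEN_PATTERN = r"(?u)\b\w+\b"


@dataclass
class EmbeddingMatrix:
    """Row-per-document embedding with aligned ids."""

    vectors: np.ndarray | sp.spmatrix
    doc_ids: list[str]
    backend_name: str

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.doc_ids):
            raise ValueError(
                f"{self.vectors.shape[0]} rows != {len(self.doc_ids)} doc_ids"
            )
        dense = self.vectors.toarray() if sp.issparse(self.vectors) else self.vectors
        if np.isnan(np.asarray(dense, dtype=float)).any():
            raise ValueError("embedding matrix contains NaN")

    @property
    def n_docs(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, i: int) -> np.ndarray:
        v = self.vectors[i]
        return np.asarray(v.todense()).ravel() if sp.issparse(v) else np.asarray(v).ravel()


class EmbeddingBackend(Protocol):
    """Backend contract: fixed-dimension, deterministic embedding."""

    name: str
    requires_fit: bool

    @property
    def dimensionality(self) -> int: ...

    def embed(self, docs: Sequence[str], doc_ids: Sequence[str] | None = None) -> EmbeddingMatrix: ...


def _make_matrix(vectors, docs, doc_ids, name) -> EmbeddingMatrix:
    ids = list(doc_ids) if doc_ids is not None else [f"doc{i}" for i in range(len(docs))]
    return EmbeddingMatrix(vectors=vectors, doc_ids=ids, backend_name=name)


class NgramBackend:
    """Bag of word n-grams over a fixed fitted vocabulary.

    Out-of-vocabulary n-grams at embed time contribute zero.
    """

    requires_fit = True

    def __init__(self, n_min: int = 1, n_max: int = 3, weighting: str = "count") -> None:
        if not 1 <= n_min <= n_max:
            raise ValueError(f"invalid n-gram range ({n_min}, {n_max})")
        if weighting not in ("count", "tfidf"):
            raise ValueError(f"weighting must be 'count' or 'tfidf', got {weighting!r}")
        self.n_min, self.n_max, self.weighting = n_min, n_max, weighting
        self.name = f"ngram-{n_min}-{n_max}-{weighting}"
        cls = CountVectorizer if weighting == "count" else TfidfVectorizer
        self._vectorizer = cls(ngram_range=(n_min, n_max), token_pattern=_TOKEN_PATTERN)
        self._fitted = False

    def fit(self, corpus: Sequence[str]) -> "NgramBackend":
        if len(corpus) == 0:
            raise FitError("empty corpus")
        try:
            self._vectorizer.fit(corpus)
        except ValueError as exc:  # sklearn: empty vocabulary
            raise FitError(f"cannot build n-gram vocabulary: {exc}") from exc
        self._fitted = True
        return self

    @property
    def vocabulary(self) -> list[str]:
        return list(self._vectorizer.get_feature_names_out())

    @property
    def dimensionality(self) -> int:
        if not self._fitted:
            raise FitError("backend not fitted")
        return len(self._vectorizer.vocabulary_)

    def embed(self, docs, doc_ids=None) -> EmbeddingMatrix:
        if not self._fitted:
            raise FitError("backend not fitted")
        return _make_matrix(self._vectorizer.transform(docs), docs, doc_ids, self.name)


def fit_ngram_backend(
    corpus: Sequence[str], n_min: int = 1, n_max: int = 3, weighting: str = "count"
) -> NgramBackend:
    """Fit a bag-of-n-grams backend on a normalized corpus."""
    return NgramBackend(n_min=n_min, n_max=n_max, weighting=weighting).fit(corpus)


class MockDenseBackend:
    """Deterministic hashed-token dense embeddings (unit norm).

    Each whitespace token is hashed (keyed by ``seed``) to one of ``dim``
    coordinates with a ±1 sign; the signed token counts are L2
    normalized.  Identical texts map to identical vectors; texts sharing
    no tokens are near-orthogonal in expectation for dim >= 256.
    """

    requires_fit = False

    def __init__(self, dim: int = 256, seed: int = 0) -> None:
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self._dim = int(dim)
        self.seed = int(seed)
        self.name = f"mock-{dim}-s{seed}"

    @property
    def dimensionality(self) -> int:
        return self._dim

    def _token_feature(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(
            token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
        ).digest()
        idx = int.from_bytes(digest[:4], "big") % self._dim
        sign = 1.0 if digest[4] % 2 == 0 else -1.0
        return idx, sign

    def embed_one(self, doc: str) -> np.ndarray:
        vec = np.zeros(self._dim)
        for token in doc.split():
            idx, sign = self._token_feature(token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def embed(self, docs, doc_ids=None) -> EmbeddingMatrix:
        rows = np.vstack([self.embed_one(d) for d in docs]) if len(docs) else np.zeros((0, self._dim))
        return _make_matrix(rows, docs, doc_ids, self.name)


_DENSE_REGISTRY: dict[str, Callable[..., EmbeddingBackend]] = {
    "mock": MockDenseBackend,
}


def register_dense_backend(name: str, factory: Callable[..., EmbeddingBackend]) -> None:
    """Register an adapter for a dense sentence-embedding checkpoint."""
    _DENSE_REGISTRY[name] = factory


def dense_backend(model_name: str, **kwargs) -> EmbeddingBackend:
    """Instantiate a registered dense backend ("mock" always exists)."""
    try:
        factory = _DENSE_REGISTRY[model_name]
    except KeyError:
        raise RegistryError(
            f"unknown dense backend {model_name!r}; available: {sorted(_DENSE_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class ReductionModel:
    """Fitted variance-threshold reduction (standardized PCA or truncated SVD)."""

    method: str
    variance_threshold: float
    components: int
    fitted_on: int
    threshold_unreachable: bool = False
    _scaler: StandardScaler | None = None
    _pca: PCA | None = None
    _svd: TruncatedSVD | None = None

    def transform(self, matrix: EmbeddingMatrix) -> EmbeddingMatrix:
        if self.method == "variance_pca":
            dense = (
                matrix.vectors.toarray() if sp.issparse(matrix.vectors) else matrix.vectors
            )
            reduced = self._pca.transform(self._scaler.transform(dense))[:, : self.components]
        else:
            reduced = self._svd.transform(matrix.vectors)[:, : self.components]
        return EmbeddingMatrix(
            vectors=np.asarray(reduced),
            doc_ids=list(matrix.doc_ids),
            backend_name=f"{matrix.backend_name}+{self.method}{self.components}",
        )


def _components_for_threshold(ratios: np.ndarray, threshold: float) -> tuple[int, bool]:
    cum = np.cumsum(ratios)
    # smallest leading count reaching >= threshold (tiny slack for fp round-off)
    reach = np.nonzero(cum >= threshold - 1e-12)[0]
    if reach.size == 0:
        return len(ratios), True
    return int(reach[0]) + 1, False


def reduce(
    matrix: EmbeddingMatrix,
    method: str = "variance_pca",
    variance_threshold: float = 0.9,
) -> tuple[ReductionModel, EmbeddingMatrix]:
    """Fit a reduction on ``matrix`` and return (model, reduced matrix).

    ``variance_pca`` standardizes columns (zero mean, unit variance) then
    keeps the smallest number of leading principal components whose
    cumulative explained variance reaches the threshold; use
    ``truncated_svd`` for sparse count matrices.  When the threshold is
    unreachable all components are kept and the model is flagged.
    """
    if matrix.n_docs < 2:
        raise ValueError("reduction needs at least 2 rows")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    if method == "variance_pca":
        dense = matrix.vectors.toarray() if sp.issparse(matrix.vectors) else matrix.vectors
        scaler = StandardScaler().fit(dense)
        pca = PCA(n_components=None, svd_solver="full").fit(scaler.transform(dense))
        k, unreachable = _components_for_threshold(
            pca.explained_variance_ratio_, variance_threshold
        )
        model = ReductionModel(
            method=method,
            variance_threshold=variance_threshold,
            components=k,
            fitted_on=matrix.n_docs,
            threshold_unreachable=unreachable,
            _scaler=scaler,
            _pca=pca,
        )
    elif method == "truncated_svd":
        n_comp = min(matrix.n_docs - 1, matrix.dim - 1)
        if n_comp < 1:
            raise ValueError("matrix too small for truncated SVD")
        svd = TruncatedSVD(n_components=n_comp, random_state=0).fit(matrix.vectors)
        k, unreachable = _components_for_threshold(
            svd.explained_variance_ratio_, variance_threshold
        )
        model = ReductionModel(
            method=method,
            variance_threshold=variance_threshold,
            components=k,
            fitted_on=matrix.n_docs,
            threshold_unreachable=unreachable,
            _svd=svd,
        )
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    return model, model.transform(matrix)
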