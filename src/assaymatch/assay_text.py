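"""Assay-document embedding providers.

An assay document is the concatenated title, description and protocol text of
one bioassay. Providers turn documents into fixed-dimension real vectors
behind a single deterministic interface, so the downstream fusion network
never cares where the text representation came from:

* :func:`build_lsa_provider` — latent semantic analysis (TF-IDF followed by
  truncated SVD), the classical bag-of-words baseline encoder;
* :func:`fixture_provider` — pseudo-random unit vectors keyed by a stable hash
  of the text, for tests and synthetic pipelines;
* any user object satisfying :class:`EmbeddingProvider` — e.g. an adapter
  around a domain fine-tuned language model.

TF-IDF dialect (deliberately pinned, since LSA has many): natural term
frequency, smoothed inverse document frequency log((1+N)/(1+df)) + 1, L2
document normalization, lowercase word tokenization. This matches
scikit-learn's defaults, which implement exactly that dialect.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer

from .exceptions import (
    ConfigurationError,
    DuplicateKeyError,
    InvalidDocumentError,
)

#: Default LSA dimensionality when the caller does not choose one.
DEFAULT_LSA_K = 256


@dataclass(frozen=True)
class AssayDocument:
    """One assay's free text (title + description + protocol, concatenated)."""

    assay_id: str
    text: str


@dataclass(frozen=True)
class TextEmbedding:
    """Dense vector representation of one assay document."""

    vector: np.ndarray
    provider_tag: str

    def __post_init__(self):
        vec = np.asarray(self.vector, dtype=np.float64)
        if vec.ndim != 1:
            raise ValueError("embedding vector must be 1-D")
        if not np.isfinite(vec).all():
            raise ValueError("embedding vector has non-finite entries")
        object.__setattr__(self, "vector", vec)

    @property
    def d_text(self) -> int:
        return self.vector.shape[0]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Deterministic text -> vector map with a fixed output dimension."""

    d_text: int
    provider_tag: str

    def embed(self, text: str) -> np.ndarray: ...


class LSAProvider:
    """TF-IDF + truncated-SVD document encoder fitted on a corpus."""

    def __init__(self, vectorizer: TfidfVectorizer, components: np.ndarray, k: int):
        self._vectorizer = vectorizer
        # components: (k, vocab) with per-component sign fixed
        self._components = components
        self.d_text = k
        self.provider_tag = f"lsa-k{k}"

    def embed(self, text: str) -> np.ndarray:
        tfidf = self._vectorizer.transform([text]).toarray()[0]
        return tfidf @ self._components.T


def build_lsa_provider(
    corpus: list[AssayDocument], k: int = DEFAULT_LSA_K, seed: int = 0
) -> LSAProvider:
    """Fit an LSA encoder: TF-IDF over the corpus, then rank-k truncated SVD.

    The embedding of any document (in or out of corpus) is the projection of
    its TF-IDF vector onto the top-k right singular directions of the weighted
    document-term matrix, so it is a linear function of the TF-IDF vector.
    Singular-vector sign indeterminacy is resolved by forcing the
    largest-magnitude loading of each component to be positive.
    """
    if len(corpus) < 2:
        raise ConfigurationError(f"LSA corpus needs >= 2 documents, got {len(corpus)}")
    texts = [doc.text for doc in corpus]
    vectorizer = TfidfVectorizer(lowercase=True)
    X = vectorizer.fit_transform(texts)
    vocab_size = X.shape[1]
    if not 1 <= k < min(len(corpus), vocab_size):
        raise ConfigurationError(
            f"k={k} out of range: need 1 <= k < min(n_docs={len(corpus)}, "
            f"vocab={vocab_size})"
        )
    svd = TruncatedSVD(n_components=k, random_state=seed)
    svd.fit(X)
    components = svd.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return LSAProvider(vectorizer, components, k)


class FixtureProvider:
    """Hash-keyed pseudo-random unit vectors; deterministic, corpus-free."""

    def __init__(self, d_text: int, seed: int):
        if d_text < 1:
            raise ConfigurationError(f"d_text must be >= 1, got {d_text}")
        self.d_text = d_text
        self._seed = seed
        self.provider_tag = f"fixture-d{d_text}-s{seed}"

    def embed(self, text: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self._seed}\x00{text}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        vec = rng.standard_normal(self.d_text)
        return vec / np.linalg.norm(vec)


def fixture_provider(d_text: int, seed: int = 0) -> FixtureProvider:
    """Deterministic stand-in provider mapping text to unit vectors."""
    return FixtureProvider(d_text, seed)


def embed_batch(
    provider: EmbeddingProvider, docs: Iterable[AssayDocument]
) -> dict[str, TextEmbedding]:
    """Embed documents one by one; returns ``assay_id -> TextEmbedding``.

    Each document is embedded independently of the others, so the batch order
    cannot change any individual vector.
    """
    docs = list(docs)
    if not docs:
        raise InvalidDocumentError("no documents supplied")
    out: dict[str, TextEmbedding] = {}
    for doc in docs:
        if doc.assay_id in out:
            raise DuplicateKeyError(f"duplicate assay_id: {doc.assay_id!r}")
        if not doc.text or not doc.text.strip():
            raise InvalidDocumentError(f"empty text for assay {doc.assay_id!r}")
        vec = np.asarray(provider.embed(doc.text), dtype=np.float64)
        if vec.shape != (provider.d_text,):
            raise InvalidDocumentError(
                f"provider returned shape {vec.shape} for assay "
                f"{doc.assay_id!r}, expected ({provider.d_text},)"
            )
        out[doc.assay_id] = TextEmbedding(vector=vec, provider_tag=provider.provider_tag)
    return out


# ---------------------------------------------------------------------------
# I/O: documents and embeddings as TSV
# ---------------------------------------------------------------------------

def read_documents_tsv(path: str | Path) -> list[AssayDocument]:
    """Read assay documents from a TSV with columns ``assay_id``, ``text``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"assay_id", "text"} - set(df.columns)
    if missing:
        raise InvalidDocumentError(f"{path}: missing columns {sorted(missing)}")
    return [AssayDocument(row.assay_id, row.text) for row in df.itertuples()]


def read_documents_dir(path: str | Path) -> list[AssayDocument]:
    """Read a directory of ``<assay_id>.txt`` plain-text files."""
    docs = [
        AssayDocument(p.stem, p.read_text())
        for p in sorted(Path(path).glob("*.txt"))
    ]
    if not docs:
        raise InvalidDocumentError(f"no *.txt documents under {path}")
    return docs


def write_embeddings_tsv(
    embeddings: dict[str, TextEmbedding], path: str | Path
) -> None:
    """Write embeddings as TSV: assay_id followed by d_text numeric columns."""
    rows = {aid: emb.vector for aid, emb in embeddings.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"e{i}" for i in range(df.shape[1])]
    df.index.name = "assay_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_embeddings_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_embeddings_tsv`; returns assay_id -> vector."""
    df = pd.read_csv(path, sep="\t", index_col="assay_id")
    return {str(aid): row.to_numpy(dtype=np.float64) for aid, row in df.iterrows()}
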