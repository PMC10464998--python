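"""Sequence -> fixed-length feature vector providers.

Three providers share one contract (:class:`Embedder`): a protein
language model adapter (optional, needs externally installed weights), a
reader for precomputed per-protein embedding tables, and the deterministic
synthetic embedder defined in :mod:`protacable.synthetic`. Contact-map
pooling turns an E3-ligase x target contact-probability matrix into a
fixed-length vector on the E3 axis.

Every provider must be deterministic (same sequence, same vector), emit
vectors of its declared dimension, and be sensitive to at least one
single-residue substitution — the property that makes residue-level
mutational scanning meaningful.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import FeatureVector
from .seq_io import validate_sequence


class Embedder(ABC):
    """Deterministic sequence -> R^dimension map."""

    name: str = "embedder"
    dimension: int

    @abstractmethod
    def embed(self, sequence: str) -> np.ndarray:
        """Return the embedding of a canonical sequence (length = dimension)."""

    def __call__(self, sequence: str) -> np.ndarray:
        return self.embed(sequence)


def embed_protein(embedder: Embedder, sequence: str) -> FeatureVector:
    """Embed one canonical sequence, validating the provider contract."""
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    validate_sequence(sequence, policy="strict")
    v = np.asarray(embedder.embed(sequence), dtype=float)
    if v.shape != (embedder.dimension,):
        raise ValueError(
            f"embedder {embedder.name!r} returned shape {v.shape}, "
            f"expected ({embedder.dimension},)"
        )
    names = [f"{embedder.name}.{i}" for i in range(embedder.dimension)]
    return FeatureVector(embedder.name, v, names)


def embed_long_sequence(embedder: Embedder, sequence: str,
                        max_window: int = 1022) -> FeatureVector:
    """Length-weighted windowed embedding for sequences of any length.

    The sequence is split into consecutive non-overlapping windows of at
    most ``max_window`` residues; window embeddings are averaged with
    weights proportional to window length. For sequences no longer than
    ``max_window`` this equals :func:`embed_protein` exactly.
    """
    if max_window < 50:
        raise ValueError("max_window must be >= 50")
    if len(sequence) <= max_window:
        return embed_protein(embedder, sequence)
    windows = [sequence[i:i + max_window]
               for i in range(0, len(sequence), max_window)]
    weights = np.array([len(w) for w in windows], dtype=float)
    weights /= weights.sum()
    vecs = np.stack([embed_protein(embedder, w).values for w in windows])
    names = [f"{embedder.name}.{i}" for i in range(embedder.dimension)]
    return FeatureVector(embedder.name, weights @ vecs, names)


def embed_dataset(embedder: Embedder, dataset,
                  max_window: int | None = None) -> np.ndarray:
    """Embedding matrix for a Dataset; row i corresponds to record i."""
    rows = []
    for rec in dataset:
        if max_window is None:
            rows.append(embed_protein(embedder, rec.sequence).values)
        else:
            rows.append(embed_long_sequence(embedder, rec.sequence, max_window).values)
    return np.stack(rows)


# ---------------------------------------------------------------------------
# Contact-map pooling
# ---------------------------------------------------------------------------

def pool_contact_max(matrix) -> FeatureVector:
    """Row-wise max pooling of an n x m contact-probability matrix.

    Row axis n is the E3-ligase sequence, column axis m the target; the
    result is the length-n vector of per-E3-residue maximum contact
    probability, a fixed-length feature across targets of any length.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("contact matrix must be a non-empty 2-D array")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("contact probabilities must lie in [0, 1]")
    pooled = m.max(axis=1)
    names = [f"contact.e3res{i + 1}" for i in range(len(pooled))]
    return FeatureVector("contact-pool", pooled, names)


def load_contact_matrix(path) -> np.ndarray:
    """Load one whitespace-delimited contact matrix file."""
    m = np.loadtxt(path, ndmin=2)
    if m.size == 0:
        raise ValueError(f"empty contact matrix file: {path}")
    if m.min() < 0 or m.max() > 1:
        raise ValueError(f"contact entries outside [0, 1] in {path}")
    return m


# ---------------------------------------------------------------------------
# Precomputed embedding tables (featurize elsewhere, classify here)
# ---------------------------------------------------------------------------

def load_embedding_table(path) -> pd.DataFrame:
    """Read a TSV embedding table: first column id, remaining columns dims."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty embedding table: {path}")
    return df.astype(float)


class PrecomputedEmbedder(Embedder):
    """Embedder backed by a precomputed id-keyed table.

    Built by pairing a record list with an embedding table so lookups can be
    keyed by sequence (the Embedder contract). Unseen sequences are an
    error — this provider cannot extrapolate.
    """

    provider = "precomputed"

    def __init__(self, records, table: pd.DataFrame, name: str = "precomputed"):
        self.name = name
        self.dimension = table.shape[1]
        self._by_sequence: dict[str, np.ndarray] = {}
        for rec in records:
            if rec.id not in table.index:
                raise KeyError(f"no embedding row for record id {rec.id!r}")
            self._by_sequence[rec.sequence] = table.loc[rec.id].to_numpy(dtype=float)

    def embed(self, sequence: str) -> np.ndarray:
        try:
            return self._by_sequence[sequence]
        except KeyError:
            raise KeyError(
                "sequence not present in the precomputed embedding table; "
                "precomputed embeddings cannot embed novel sequences "
                "(use the language-model adapter or the synthetic embedder)"
            ) from None


class PLMEmbedder(Embedder):
    """Adapter around a pretrained transformer protein language model.

    Per-residue representations are mean-pooled, excluding begin/end special
    tokens, into one fixed-length vector. Model weights are an optional
    external resource: constructing this adapter without the ``fair-esm``
    and ``torch`` packages (and downloaded weights) raises immediately —
    there is no silent fallback.
    """

    provider = "plm-adapter"

    def __init__(self, model_name: str = "esm1b_t33_650M_UR50S",
                 pooling: str = "mean"):
        if pooling not in ("mean",):
            raise ValueError(f"unsupported pooling mode {pooling!r}")
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "external resource required: the protein-language-model "
                "adapter needs the 'fair-esm' and 'torch' packages with "
                "downloaded weights; install the 'esm' extra or use a "
                "precomputed embedding table"
            ) from exc
        self._model, self._alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self._model.eval()
        self._repr_layer = self._model.num_layers
        self.name = model_name
        self.dimension = self._model.embed_dim

    def embed(self, sequence: str) -> np.ndarray:
        import torch

        converter = self._alphabet.get_batch_converter()
        _, _, tokens = converter([("protein", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._repr_layer])
        rep = out["representations"][self._repr_layer][0]
        # positions 1..L are residues; 0 and L+1 are special tokens
        return rep[1:len(sequence) + 1].mean(dim=0).numpy().astype(float)
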