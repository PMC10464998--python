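"""Residue-level interpretation by embedding-space mutational scanning.

The procedure: (1) rank embedding features by mean absolute Shapley
attribution of the trained tree model(s); (2) keep the top k (default 20);
(3) mutate each residue, one at a time, to an amino acid of the opposite
physicochemical property and re-embed the full mutant sequence; (4) score
each position by the Euclidean distance between wild-type and mutant
embeddings restricted to the selected features,

    difference_score(x) = sqrt( sum_{n in selected} (f_n^ref - f_n^mut(x))^2 );

(5) the top-ranked positions are the key positions for the protein. When k
differs from 20 the sum simply runs over the selected k features; the
output metadata records the selection used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _treeshap
from .aa_tables import CANONICAL_AA
from .descriptors import FeatureVector
from .embedding import Embedder, embed_long_sequence, embed_protein
from .model_core import EnsembleModel, TrainedClassifier

#: Default opposite-property substitution: positive <-> negative charge,
#: polar -> hydrophobic, hydrophobic/special -> polar or flexibility flip.
DEFAULT_OPPOSITE = {
    "K": "E", "R": "E", "H": "D",
    "D": "K", "E": "K",
    "S": "L", "T": "L", "N": "L", "Q": "L", "Y": "L", "C": "A",
    "A": "S", "V": "T", "L": "S", "I": "S", "M": "S", "F": "S", "W": "S",
    "P": "G", "G": "P",
}


@dataclass
class MutationScheme:
    """Total map from each canonical amino acid to a replacement."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_OPPOSITE))

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.mapping)
        if missing:
            raise ValueError(f"mutation scheme missing residues: {sorted(missing)}")
        for a, b in self.mapping.items():
            if a not in CANONICAL_AA or b not in CANONICAL_AA:
                raise ValueError(f"non-canonical residue in scheme: {a}->{b}")
            if a == b:
                raise ValueError(f"scheme maps {a} to itself")

    @classmethod
    def from_tsv(cls, path) -> "MutationScheme":
        mapping = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            wt, mut = line.split("\t")[:2]
            mapping[wt] = mut
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# wild-type residue -> opposite-property replacement\n")
            for a in CANONICAL_AA:
                fh.write(f"{a}\t{self.mapping[a]}\n")


def opposite_mutation(residue: str, scheme: MutationScheme | None = None) -> str:
    """Replacement residue for one canonical amino acid under the scheme."""
    scheme = scheme or MutationScheme()
    if residue not in scheme.mapping:
        raise ValueError(f"non-canonical residue {residue!r}")
    return scheme.mapping[residue]


@dataclass
class FeatureSelection:
    """Top-k embedding features ranked by mean absolute attribution."""

    indices: np.ndarray
    importance: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.importance = np.asarray(self.importance, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("feature indices must be unique")
        if np.any(np.diff(self.importance) > 1e-12):
            raise ValueError("importance must be sorted descending")

    def __len__(self) -> int:
        return len(self.indices)


def feature_attributions(model, X) -> tuple[np.ndarray, float]:
    """Per-sample per-feature Shapley attributions of a tree model.

    Accepts a fitted sklearn tree ensemble or a :class:`TrainedClassifier`.
    Local accuracy holds: base + attributions.sum(axis=1) equals the raw
    model output (positive-class probability for forests, log-odds margin
    for boosting) to numerical precision.
    """
    if isinstance(model, TrainedClassifier):
        model = model.model
    return _treeshap.shap_values(model, X)


def ensemble_mean_attributions(ensemble: EnsembleModel, X) -> np.ndarray:
    """Mean absolute attribution per feature, averaged over members."""
    imp = np.zeros(np.asarray(X).shape[1])
    for member in ensemble.members:
        phi, _ = feature_attributions(member, X)
        imp += np.abs(phi).mean(axis=0)
    return imp / len(ensemble.members)


def select_top_features(attributions, k: int = 20) -> FeatureSelection:
    """Rank features by mean absolute attribution; keep the top k.

    ``attributions`` may be a per-sample attribution matrix or an
    already-averaged importance vector. Ties are broken by lower feature
    index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    a = np.asarray(attributions, dtype=float)
    imp = np.abs(a).mean(axis=0) if a.ndim == 2 else np.abs(a)
    if k > len(imp):
        raise ValueError(f"k={k} exceeds feature dimension {len(imp)}")
    order = np.lexsort((np.arange(len(imp)), -imp))[:k]
    return FeatureSelection(order, imp[order])


def difference_score(ref_features: FeatureVector | np.ndarray,
                     mut_features: FeatureVector | np.ndarray,
                     selection: FeatureSelection) -> float:
    """Euclidean norm of (ref - mut) restricted to the selected features."""
    ref = ref_features.values if isinstance(ref_features, FeatureVector) else np.asarray(ref_features, float)
    mut = mut_features.values if isinstance(mut_features, FeatureVector) else np.asarray(mut_features, float)
    if ref.shape != mut.shape:
        raise ValueError("reference and mutant feature dimensions differ")
    if selection.indices.max(initial=-1) >= len(ref):
        raise ValueError("selection indices exceed feature dimension")
    d = ref[selection.indices] - mut[selection.indices]
    return float(np.sqrt((d * d).sum()))


@dataclass
class PositionScoreTable:
    """Per-residue difference scores for one protein (1-based positions)."""

    protein_id: str
    table: pd.DataFrame  # columns: position, wt, mut, score
    selection: FeatureSelection
    wild_type_score: float | None = None

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path, key_set: set[int] | None = None) -> None:
        df = self.table.copy()
        df.insert(0, "id", self.protein_id)
        if key_set is not None:
            df["is_key"] = df["position"].isin(key_set).astype(int)
        with open(path, "w") as fh:
            fh.write("# positions are 1-based (residue 1 = N-terminus); "
                     f"k={len(self.selection)} selected features\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def eshap_scan(protein, embedder: Embedder,
               selection: FeatureSelection,
               scheme: MutationScheme | None = None,
               model=None,
               max_window: int | None = None) -> PositionScoreTable:
    """Opposite-property single-residue scan of one protein.

    Each position x (1-based) is mutated under the scheme, the full mutant
    sequence is re-embedded with the same windowing policy as the wild
    type, and the difference score against the wild-type embedding is
    recorded; the table has exactly one row per residue. ``model`` is
    optional and only annotates the table with the wild-type prediction.
    """
    scheme = scheme or MutationScheme()
    seq = protein.sequence

    def _embed(s: str) -> np.ndarray:
        if max_window is None:
            return embed_protein(embedder, s).values
        return embed_long_sequence(embedder, s, max_window).values

    ref = _embed(seq)
    rows = []
    for i, wt in enumerate(seq):
        mut = scheme.mapping[wt]
        try:
            mut_vec = _embed(seq[:i] + mut + seq[i + 1:])
        except Exception as exc:
            raise RuntimeError(
                f"embedding failed for {protein.id} position {i + 1} "
                f"({wt}->{mut}): {exc}"
            ) from exc
        d = ref[selection.indices] - mut_vec[selection.indices]
        rows.append((i + 1, wt, mut, float(np.sqrt((d * d).sum()))))
    table = pd.DataFrame(rows, columns=["position", "wt", "mut", "score"])
    wt_score = None
    if model is not None:
        predictor = model if hasattr(model, "predict_proba") else None
        if predictor is not None:
            wt_score = float(np.atleast_1d(
                predictor.predict_proba(ref.reshape(1, -1))
            ).ravel()[-1])
    return PositionScoreTable(protein.id, table, selection, wt_score)


def key_positions(table: PositionScoreTable, top_fraction: float = 0.05,
                  k: int | None = None) -> list[int]:
    """Top-scoring positions (1-based), score descending, ties by position.

    ``top_fraction`` keeps ceil(top_fraction * L) positions; an absolute
    count ``k`` overrides the fraction when given.
    """
    if len(table) == 0:
        raise ValueError("empty position score table")
    if k is None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        k = math.ceil(top_fraction * len(table))
    df = table.table.sort_values(["score", "position"],
                                 ascending=[False, True], kind="mergesort")
    return df["position"].head(k).tolist()


def motif_enrichment(tables, truth_spans: dict, top_fraction: float = 0.1) -> float:
    """Mean enrichment of planted-motif positions among key positions.

    For each protein: observed = |key positions inside motif spans|;
    expected under uniform placement = n_key * n_motif_residues / L. The
    returned value is the mean of observed/expected over proteins.
    """
    ratios = []
    for t in tables:
        spans = truth_spans[t.protein_id]
        motif_pos = {p for (a, b) in spans for p in range(a, b + 1)}
        if not motif_pos:
            continue
        keys = key_positions(t, top_fraction=top_fraction)
        expected = len(keys) * len(motif_pos) / len(t)
        ratios.append(len(motif_pos & set(keys)) / expected)
    if not ratios:
        raise ValueError("no proteins with motif spans")
    return float(np.mean(ratios))
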