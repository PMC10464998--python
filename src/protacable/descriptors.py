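"""Fixed-length sequence descriptors.

Implements the six descriptor families carried into the degradability
classifier: tripeptide composition (TPC, 8000-d), grouped tripeptide
composition (GTPC, 125-d), conjoint triads (CTriad, 343-d), the
distribution component of composition/transition/distribution (CTDD,
195-d), Geary autocorrelation (n_properties x n_lag) and quasi-sequence
order (QSOrder, 2 x (20 + n_lag)).

All descriptors are pure functions of (sequence, params); the composition
families (TPC, GTPC, CTriad) are count/(L-2) frequencies and sum to one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import aa_tables
from .aa_tables import AA_INDEX, CANONICAL_AA


@dataclass
class FeatureVector:
    """Named fixed-dimension numeric representation of one protein."""

    name: str
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be one-dimensional")
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in descriptor {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DescriptorParams:
    """Tunable descriptor parameters.

    n_lag:
        Maximum sequence-separation lag for Geary and QSOrder (must be
        smaller than the shortest sequence the descriptors see).
    qso_weight:
        Weight of the sequence-order terms in QSOrder.
    aa_properties:
        Named per-residue scales for Geary autocorrelation; each scale is
        z-scored over the 20 amino acids before use.
    distance_matrices:
        Two named symmetric 20x20 amino-acid distance tables for QSOrder.
    """

    n_lag: int = 30
    qso_weight: float = 0.1
    aa_properties: dict = field(
        default_factory=lambda: dict(aa_tables.DEFAULT_GEARY_PROPERTIES)
    )
    distance_matrices: dict = field(
        default_factory=aa_tables.default_qso_distance_matrices
    )

    def __post_init__(self) -> None:
        if self.n_lag < 1:
            raise ValueError("n_lag must be positive")
        if self.qso_weight <= 0:
            raise ValueError("qso_weight must be positive")
        for name, m in self.distance_matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (20, 20) or not np.allclose(m, m.T):
                raise ValueError(f"distance matrix {name!r} must be symmetric 20x20")
            self.distance_matrices[name] = m


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


def _require_length(sequence: str, minimum: int, name: str) -> None:
    if len(sequence) < minimum:
        raise ValueError(
            f"{name} requires sequence length >= {minimum}, got {len(sequence)}"
        )


def _triple_names(symbols) -> list[str]:
    return ["".join(t) for t in itertools.product(symbols, repeat=3)]


_TPC_NAMES = None


def tpc(sequence: str) -> FeatureVector:
    """Tripeptide composition: count(t) / (L - 2) for the 8000 tripeptides.

    Entries are ordered lexicographically over the canonical alphabet.
    """
    global _TPC_NAMES
    _require_length(sequence, 3, "tpc")
    codes = _encode(sequence)
    tri = codes[:-2] * 400 + codes[1:-1] * 20 + codes[2:]
    counts = np.bincount(tri, minlength=8000).astype(float)
    if _TPC_NAMES is None:
        _TPC_NAMES = [f"TPC.{t}" for t in _triple_names(CANONICAL_AA)]
    return FeatureVector("TPC", counts / (len(sequence) - 2), _TPC_NAMES)


def _grouped_triples(sequence: str, groups: dict, name: str) -> FeatureVector:
    n = len(groups)
    group_names = list(groups)
    code_of = {}
    for gi, (gname, members) in enumerate(groups.items()):
        for a in members:
            code_of[a] = gi
    codes = np.array([code_of[a] for a in sequence], dtype=np.int64)
    tri = codes[:-2] * n * n + codes[1:-1] * n + codes[2:]
    counts = np.bincount(tri, minlength=n**3).astype(float)
    names = [f"{name}.{t[0]}|{t[1]}|{t[2]}"
             for t in itertools.product(group_names, repeat=3)]
    return FeatureVector(name, counts / (len(sequence) - 2), names)


def gtpc(sequence: str, groups: dict | None = None) -> FeatureVector:
    """Grouped tripeptide composition over 5 physicochemical groups (125-d)."""
    _require_length(sequence, 3, "gtpc")
    return _grouped_triples(sequence, groups or aa_tables.GTPC_GROUPS, "GTPC")


def ctriad(sequence: str, classes: dict | None = None,
           minmax_rescale: bool = False) -> FeatureVector:
    """Conjoint-triad composition over 7 residue classes (343-d).

    Default normalisation is count/(L-2) (keeps the sum-to-one invariant);
    ``minmax_rescale=True`` applies the (c - min)/max rescaling used by some
    implementations instead.
    """
    _require_length(sequence, 3, "ctriad")
    fv = _grouped_triples(sequence, classes or aa_tables.CTRIAD_CLASSES, "CTriad")
    if minmax_rescale:
        counts = fv.values * (len(sequence) - 2)
        vmax = counts.max()
        fv = FeatureVector(
            fv.name,
            (counts - counts.min()) / (vmax if vmax > 0 else 1.0),
            fv.feature_names,
        )
    return fv


def ctdd(sequence: str, attributes: dict | None = None) -> FeatureVector:
    """Distribution component of the CTD descriptor family (195-d).

    For each of 13 physicochemical attributes the residues fall into 3
    classes; for each class the five values are the sequence positions (as
    percent of L) of the first, 25th-percentile, median, 75th-percentile and
    last occurrence of that class. Classes absent from the sequence give 0.
    """
    if not sequence:
        raise ValueError("ctdd requires a non-empty sequence")
    attributes = attributes or aa_tables.CTD_ATTRIBUTES
    L = len(sequence)
    values: list[float] = []
    names: list[str] = []
    for attr, groups in attributes.items():
        for ci, members in enumerate(groups, start=1):
            positions = [i + 1 for i, a in enumerate(sequence) if a in members]
            if not positions:
                chunk = [0.0] * 5
            else:
                n = len(positions)
                chunk = []
                for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
                    k = max(1, int(np.ceil(frac * n)))
                    chunk.append(100.0 * positions[k - 1] / L)
            values.extend(chunk)
            names.extend(
                f"CTDD.{attr}.class{ci}.{tag}"
                for tag in ("first", "p25", "p50", "p75", "last")
            )
    return FeatureVector("CTDD", np.array(values), names)


def geary(sequence: str, params: DescriptorParams | None = None) -> FeatureVector:
    """Geary spatial autocorrelation of residue properties along the chain.

    For property p (z-scored over the 20 amino acids) and lag d:

        C_p(d) = [sum_i (p_i - p_{i+d})^2 / (2 (L - d))]
                 / [sum_i (p_i - mean)^2 / (L - 1)]

    Sequences with zero property variance yield 0 for every lag.
    """
    params = params or DescriptorParams()
    _require_length(sequence, params.n_lag + 1, "geary")
    codes = _encode(sequence)
    L = len(sequence)
    values: list[float] = []
    names: list[str] = []
    for pname, scale in params.aa_properties.items():
        z = aa_tables.scale_vector(scale, standardize=True)
        p = z[codes]
        denom = ((p - p.mean()) ** 2).sum() / (L - 1)
        for d in range(1, params.n_lag + 1):
            if denom < 1e-12:
                values.append(0.0)
            else:
                num = ((p[:-d] - p[d:]) ** 2).sum() / (2.0 * (L - d))
                values.append(num / denom)
            names.append(f"Geary.{pname}.lag{d}")
    return FeatureVector("Geary", np.array(values), names)


def qsorder(sequence: str, params: DescriptorParams | None = None) -> FeatureVector:
    """Quasi-sequence-order descriptor, 2 x (20 + n_lag) values.

    For each distance matrix: tau_d = sum_i dist(s_i, s_{i+d})^2 for
    d = 1..n_lag; with residue counts f_r and weight w, the block is

        X_r      = f_r / (L + w * sum_d tau_d)          r = 1..20
        X_{20+d} = w * tau_d / (L + w * sum_d tau_d)    d = 1..n_lag

    so each block sums to one. The two blocks are concatenated.
    """
    params = params or DescriptorParams()
    _require_length(sequence, params.n_lag + 1, "qsorder")
    codes = _encode(sequence)
    L = len(sequence)
    f = np.bincount(codes, minlength=20).astype(float)
    values: list[float] = []
    names: list[str] = []
    w = params.qso_weight
    for mname, dist in params.distance_matrices.items():
        tau = np.array([
            (dist[codes[:-d], codes[d:]] ** 2).sum()
            for d in range(1, params.n_lag + 1)
        ])
        denom = L + w * tau.sum()
        values.extend(f / denom)
        names.extend(f"QSOrder.{mname}.X.{a}" for a in CANONICAL_AA)
        values.extend(w * tau / denom)
        names.extend(f"QSOrder.{mname}.tau{d}" for d in range(1, params.n_lag + 1))
    return FeatureVector("QSOrder", np.array(values), names)


def concat_features(vectors: list[FeatureVector]) -> FeatureVector:
    """Concatenate descriptor vectors of one protein, preserving order."""
    if not vectors:
        raise ValueError("cannot concatenate an empty list of feature vectors")
    if len(vectors) == 1:
        return vectors[0]
    return FeatureVector(
        "+".join(v.name for v in vectors),
        np.concatenate([v.values for v in vectors]),
        [n for v in vectors for n in v.feature_names],
    )


DESCRIPTORS = {
    "tpc": lambda seq, params: tpc(seq),
    "gtpc": lambda seq, params: gtpc(seq),
    "ctriad": lambda seq, params: ctriad(seq),
    "ctdd": lambda seq, params: ctdd(seq),
    "geary": geary,
    "qsorder": qsorder,
}


def compute_descriptor(sequence: str, which: str,
                       params: DescriptorParams | None = None) -> FeatureVector:
    """Compute one named descriptor, or the concatenation for ``all``."""
    params = params or DescriptorParams()
    if which == "all":
        return concat_features(
            [DESCRIPTORS[name](sequence, params) for name in DESCRIPTORS]
        )
    if which not in DESCRIPTORS:
        raise ValueError(f"unknown descriptor {which!r}; options: "
                         f"{sorted(DESCRIPTORS)} or 'all'")
    return DESCRIPTORS[which](sequence, params)


def featurize_records(records, which: str,
                      params: DescriptorParams | None = None):
    """Descriptor matrix for a record list as a pandas DataFrame (rows=ids)."""
    import pandas as pd

    rows = [compute_descriptor(r.sequence, which, params) for r in records]
    return pd.DataFrame(
        np.stack([fv.values for fv in rows]),
        index=[r.id for r in records],
        columns=rows[0].feature_names,
    )
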