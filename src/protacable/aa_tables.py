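"""Amino-acid reference tables used by the sequence descriptors.

Everything here is a package default and can be overridden through
:class:`protacable.descriptors.DescriptorParams` (property scales, distance
matrices) or by passing alternative group tables to the descriptor functions.
The class partitions follow the canonical
composition/transition/distribution (CTD) literature and the conjoint-triad
and grouped-composition conventions used by standard sequence-feature
toolkits.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter alphabet, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}

# ---------------------------------------------------------------------------
# Per-residue numeric property scales (used by Geary autocorrelation and to
# derive the default quasi-sequence-order distance matrices).
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Hopp-Woods hydrophilicity.
HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}

#: Monoisotopic-free residue masses (Da, residue = amino acid minus water).
RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

#: Residue volumes (A^3), Zamyatnin-style.
SIDE_CHAIN_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Polarity (Grantham scale).
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

#: Isoelectric point of the free amino acid.
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}

#: Approximate net side-chain charge at pH 7.
NET_CHARGE = {a: 0.0 for a in CANONICAL_AA}
NET_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

#: Theoretical maximum accessible surface area (A^2), Tien et al. style.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default property set for the Geary autocorrelation descriptor.
DEFAULT_GEARY_PROPERTIES = {
    "hydropathy": HYDROPATHY,
    "hydrophilicity": HYDROPHILICITY,
    "residue_mass": RESIDUE_MASS,
    "side_chain_volume": SIDE_CHAIN_VOLUME,
    "polarity": POLARITY,
    "isoelectric_point": ISOELECTRIC_POINT,
    "net_charge": NET_CHARGE,
    "max_asa": MAX_ASA,
}

# ---------------------------------------------------------------------------
# Group tables for grouped tripeptide composition and conjoint triads.
# ---------------------------------------------------------------------------

#: Five physicochemical groups for grouped tripeptide composition.
GTPC_GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

#: Seven conjoint-triad classes (dipole / side-chain volume clustering).
CTRIAD_CLASSES = {
    "g1": "AGV",
    "g2": "ILFP",
    "g3": "YMTS",
    "g4": "HNQW",
    "g5": "RK",
    "g6": "DE",
    "g7": "C",
}

# ---------------------------------------------------------------------------
# CTD attribute tables: 13 physicochemical attributes, each splitting the
# alphabet into 3 classes. Seven hydrophobicity variants plus volume,
# polarity, polarizability, charge, secondary structure and solvent access.
# ---------------------------------------------------------------------------

CTD_ATTRIBUTES = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def _check_partition(groups) -> None:
    joined = "".join(groups)
    if sorted(joined) != sorted(CANONICAL_AA):
        raise AssertionError(f"group table is not a partition of the alphabet: {groups}")


for _groups in CTD_ATTRIBUTES.values():
    _check_partition(_groups)
_check_partition(tuple(GTPC_GROUPS.values()))
_check_partition(tuple(CTRIAD_CLASSES.values()))


def scale_vector(scale: dict, standardize: bool = False) -> np.ndarray:
    """Property scale as a length-20 vector in alphabet order.

    With ``standardize=True`` the values are z-scored over the 20 amino
    acids (population standard deviation), the normalisation applied before
    autocorrelation descriptors use a scale.
    """
    v = np.array([float(scale[a]) for a in CANONICAL_AA])
    if standardize:
        v = (v - v.mean()) / v.std()
    return v


def property_distance_matrix(scales) -> np.ndarray:
    """Symmetric 20x20 amino-acid distance matrix from property scales.

    Entry (i, j) is the root mean squared difference of the z-scored scale
    values of residues i and j, i.e. the classical property-space distance
    underlying quasi-sequence-order descriptors.
    """
    zs = np.stack([scale_vector(s, standardize=True) for s in scales])
    diff = zs[:, :, None] - zs[:, None, :]
    return np.sqrt((diff**2).mean(axis=0))


def default_qso_distance_matrices() -> dict:
    """Two default distance matrices for the quasi-sequence-order descriptor.

    ``physicochemical`` is built from hydropathy, hydrophilicity and residue
    volume; ``chemical`` from polarity, net charge and residue mass. Both
    stand in for the classical literature matrices and can be replaced via
    ``DescriptorParams.distance_matrices``.
    """
    return {
        "physicochemical": property_distance_matrix(
            [HYDROPATHY, HYDROPHILICITY, SIDE_CHAIN_VOLUME]
        ),
        "chemical": property_distance_matrix([POLARITY, NET_CHARGE, RESIDUE_MASS]),
    }
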