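"""Residue-residue distance matrices for the quasi-sequence-order descriptor.

Two 20x20 symmetric matrices are provided:

* :func:`grantham_matrix` -- Grantham's (1974) amino-acid difference
  distance, recomputed from the published composition / polarity /
  molecular-volume properties so every entry is reproducible
  (spot checks: d(L,I)=5, d(D,E)=45, d(W,C)=215 after rounding).
* :func:`physicochemical_matrix` -- a normalized Euclidean distance over
  the classical hydrophobicity, hydrophilicity and side-chain-mass
  scales (each z-scored over the 20 residues).

Both are plain ``numpy`` arrays indexed by :data:`ppimm.seq_features.ALPHABET`
order and can be swapped out via ``QsoConfig.distance_matrices``.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Grantham 1974: composition c, polarity p, molecular volume v.
_GRANTHAM_PROPS = {
    "A": (0.0, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.0, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.0, 4.9, 111.0),
    "M": (0.0, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.0, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
}

# Weights alpha/beta/gamma and the overall scale constant from Grantham 1974.
_GRANTHAM_WEIGHTS = (1.833, 0.1018, 0.000399)
_GRANTHAM_SCALE = 50.723

# Classical property scales: hydrophobicity, hydrophilicity (Hopp-Woods),
# side-chain mass.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 72.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def grantham_matrix(rounded: bool = True) -> np.ndarray:
    """Grantham distance matrix in :data:`ALPHABET` order.

    Parameters
    ----------
    rounded:
        Round to integers as in the published table (default True).
    """
    a, b, g = _GRANTHAM_WEIGHTS
    props = np.array([_GRANTHAM_PROPS[r] for r in ALPHABET])
    c = props[:, 0]
    p = props[:, 1]
    v = props[:, 2]
    d2 = (
        a * (c[:, None] - c[None, :]) ** 2
        + b * (p[:, None] - p[None, :]) ** 2
        + g * (v[:, None] - v[None, :]) ** 2
    )
    mat = _GRANTHAM_SCALE * np.sqrt(d2)
    if rounded:
        mat = np.round(mat)
    return mat


def physicochemical_matrix() -> np.ndarray:
    """Symmetric distance from z-scored hydrophobicity/hydrophilicity/mass.

    ``d(a, b)^2`` is the mean squared difference of the three normalized
    property values, so entries are dimensionless and O(1).
    """
    scales = []
    for table in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS):
        vals = np.array([table[r] for r in ALPHABET])
        scales.append((vals - vals.mean()) / vals.std())
    props = np.stack(scales, axis=1)  # 20 x 3
    diff = props[:, None, :] - props[None, :, :]
    return np.sqrt((diff**2).mean(axis=2))


def default_distance_matrices() -> tuple[np.ndarray, np.ndarray]:
    """The two default QSO distance matrices (physicochemical, Grantham)."""
    return physicochemical_matrix(), grantham_matrix()
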