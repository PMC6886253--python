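"""Fixed-length physicochemical descriptors for amino-acid sequences.

Four encoders are provided and concatenated into a single 468-dim vector:

* AAC   -- amino-acid composition, 20 values
* GAAC  -- grouped amino-acid composition, 5 values
* CT    -- conjoint triad, 7^3 = 343 values
* QSO   -- quasi-sequence-order, 2 x (20 + nlag) = 100 values at defaults

Each encoder returns a :class:`DescriptorVector` carrying per-coordinate
labels, so block boundaries in the concatenated layout stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distances import default_distance_matrices

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, in fixed descriptor order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)
_ALPHABET_INDEX = {r: i for i, r in enumerate(ALPHABET)}

#: Default 5-group physicochemical partition used by GAAC.
DEFAULT_GAAC_GROUPS: dict[str, str] = {
    "g1": "GAVLMI",  # aliphatic
    "g2": "FYW",     # aromatic
    "g3": "KRH",     # positive charge
    "g4": "DE",      # negative charge
    "g5": "STCPNQ",  # uncharged
}

#: Default conjoint-triad 7-class partition.
DEFAULT_CT_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

#: Residues sometimes seen in real data but outside the canonical alphabet.
NONCANONICAL = frozenset("XBZUO")


class InvalidSequenceError(ValueError):
    """Raised when a sequence violates an encoder precondition."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its residue string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise InvalidSequenceError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}; "
                "sanitize with sanitize_sequence() first"
            )


def sanitize_sequence(raw: str, policy: str = "drop") -> str:
    """Normalize a raw residue string to the canonical alphabet.

    policy:
      ``drop``  -- remove non-canonical residues (count is logged);
      ``error`` -- raise on any non-canonical residue;
      ``map``   -- map ambiguity codes to a canonical stand-in
                   (B->N, Z->Q, U->C, O->K, X dropped).
    """
    seq = raw.strip().upper()
    bad = [c for c in seq if c not in _ALPHABET_SET]
    if not bad:
        return seq
    if policy == "error":
        raise InvalidSequenceError(f"non-canonical residues {sorted(set(bad))}")
    if policy == "map":
        table = {"B": "N", "Z": "Q", "U": "C", "O": "K"}
        out = "".join(table.get(c, c) for c in seq)
        dropped = sum(1 for c in out if c not in _ALPHABET_SET)
        if dropped:
            logger.info("dropped %d unmappable residues", dropped)
        return "".join(c for c in out if c in _ALPHABET_SET)
    if policy != "drop":
        raise ValueError(f"unknown sanitize policy {policy!r}")
    logger.info("dropped %d non-canonical residues", len(bad))
    return "".join(c for c in seq if c in _ALPHABET_SET)


@dataclass(frozen=True)
class GaacGrouping:
    """Partition of the 20 residues into five named classes."""

    groups: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GAAC_GROUPS))

    def __post_init__(self) -> None:
        joined = "".join(self.groups.values())
        if sorted(joined) != sorted(ALPHABET):
            raise ValueError("GAAC groups must partition the 20-letter alphabet")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, residue: str) -> str:
        for name, members in self.groups.items():
            if residue in members:
                return name
        raise KeyError(residue)


@dataclass(frozen=True)
class CtClassMap:
    """Residue -> class-index (0-based, 7 classes) map for conjoint triads."""

    classes: tuple[str, ...] = DEFAULT_CT_CLASSES

    def __post_init__(self) -> None:
        joined = "".join(self.classes)
        if len(self.classes) != 7 or sorted(joined) != sorted(ALPHABET):
            raise ValueError("CT classes must be a 7-way partition of the alphabet")

    def index_of(self, residue: str) -> int:
        for i, members in enumerate(self.classes):
            if residue in members:
                return i
        raise KeyError(residue)

    def as_array(self) -> np.ndarray:
        """Alphabet-ordered vector of class indices."""
        out = np.empty(20, dtype=np.int64)
        for i, members in enumerate(self.classes):
            for r in members:
                out[_ALPHABET_INDEX[r]] = i
        return out


@dataclass(frozen=True)
class QsoConfig:
    """Quasi-sequence-order parameters: weight w, lag bound, distance matrices."""

    weight: float = 0.1
    nlag: int = 30
    distance_matrices: tuple[np.ndarray, ...] = field(
        default_factory=default_distance_matrices
    )
    matrix_names: tuple[str, ...] = ("phys", "grantham")
    on_short_sequence: str = "error"  # "error" | "reduce"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("QSO weight must be positive")
        if self.nlag < 1:
            raise ValueError("QSO nlag must be >= 1")
        for m in self.distance_matrices:
            m = np.asarray(m)
            if m.shape != (20, 20):
                raise ValueError("distance matrices must be 20x20")
            if (m < 0).any() or not np.allclose(m, m.T):
                raise ValueError("distance matrices must be symmetric, non-negative")


@dataclass(frozen=True)
class DescriptorVector:
    """Fixed-length numeric encoding with per-coordinate labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("values/labels length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def _counts(sequence: str) -> np.ndarray:
    idx = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for r, i in _ALPHABET_INDEX.items():
        lut[ord(r)] = i
    return np.bincount(lut[idx], minlength=20)


def encode_aac(p: ProteinRecord) -> DescriptorVector:
    """Amino-acid composition: per-type count over sequence length."""
    freqs = _counts(p.sequence) / len(p.sequence)
    return DescriptorVector(freqs, tuple(f"aac.{r}" for r in ALPHABET))


def encode_gaac(p: ProteinRecord, grouping: GaacGrouping | None = None) -> DescriptorVector:
    """Grouped amino-acid composition over the 5-class partition."""
    grouping = grouping or GaacGrouping()
    counts = _counts(p.sequence)
    vals = np.array(
        [sum(counts[_ALPHABET_INDEX[r]] for r in members) for members in grouping.groups.values()],
        dtype=float,
    ) / len(p.sequence)
    return DescriptorVector(vals, tuple(f"gaac.{g}" for g in grouping.names))


def encode_ct(
    p: ProteinRecord,
    classmap: CtClassMap | None = None,
    minmax_denominator: bool = False,
) -> DescriptorVector:
    """Conjoint triad: 343 class-triad counts, normalized.

    The default normalization is ``(f_i - min f) / max f``; pass
    ``minmax_denominator=True`` for the conventional
    ``(f_i - min f) / (max f - min f)`` form.
    """
    if len(p.sequence) < 3:
        raise InvalidSequenceError(
            f"protein {p.id!r}: conjoint triad needs length >= 3, got {len(p.sequence)}"
        )
    classmap = classmap or CtClassMap()
    lut = classmap.as_array()
    seq_idx = np.array([_ALPHABET_INDEX[c] for c in p.sequence])
    cls = lut[seq_idx]
    triads = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    f = np.bincount(triads, minlength=343).astype(float)
    fmin, fmax = f.min(), f.max()
    denom = (fmax - fmin) if minmax_denominator else fmax
    d = np.zeros(343) if denom == 0 else (f - fmin) / denom
    labels = tuple(
        f"ct.{i // 49}{(i // 7) % 7}{i % 7}" for i in range(343)
    )
    return DescriptorVector(d, labels)


def encode_qso(p: ProteinRecord, cfg: QsoConfig | None = None) -> DescriptorVector:
    """Quasi-sequence-order descriptor.

    Per distance matrix: 20 composition descriptors
    ``X_r = f_r / (sum f + w * sum tau)`` followed by ``nlag`` coupling
    descriptors ``X_{20+d} = w * tau_d / (sum f + w * sum tau)``, where
    ``tau_d`` is the sum of squared residue distances at sequence offset d.
    """
    cfg = cfg or QsoConfig()
    n = len(p.sequence)
    nlag = cfg.nlag
    if n <= nlag:
        if cfg.on_short_sequence == "reduce":
            nlag = n - 1
            logger.warning(
                "protein %s: length %d <= nlag %d; reduced nlag to %d",
                p.id, n, cfg.nlag, nlag,
            )
            if nlag < 1:
                raise InvalidSequenceError(f"protein {p.id!r}: too short for QSO")
        else:
            raise InvalidSequenceError(
                f"protein {p.id!r}: QSO needs length > nlag ({nlag}), got {n}"
            )
    seq_idx = np.array([_ALPHABET_INDEX[c] for c in p.sequence])
    f = _counts(p.sequence) / n  # normalized occurrence
    values: list[np.ndarray] = []
    labels: list[str] = []
    for name, mat in zip(cfg.matrix_names, cfg.distance_matrices):
        mat = np.asarray(mat, dtype=float)
        taus = np.array(
            [np.sum(mat[seq_idx[:-d], seq_idx[d:]] ** 2) for d in range(1, nlag + 1)]
        )
        denom = f.sum() + cfg.weight * taus.sum()
        values.append(f / denom)
        values.append(cfg.weight * taus / denom)
        labels.extend(f"qso.{name}.comp.{r}" for r in ALPHABET)
        labels.extend(f"qso.{name}.tau{d}" for d in range(1, nlag + 1))
    return DescriptorVector(np.concatenate(values), tuple(labels))


@dataclass(frozen=True)
class EncoderConfigs:
    """Configuration bundle for the concatenated encoder."""

    gaac: GaacGrouping = field(default_factory=GaacGrouping)
    ct: CtClassMap = field(default_factory=CtClassMap)
    qso: QsoConfig = field(default_factory=QsoConfig)
    descriptors: tuple[str, ...] = ("aac", "gaac", "ct", "qso")


def encode_all(p: ProteinRecord, configs: EncoderConfigs | None = None) -> DescriptorVector:
    """Concatenate [AAC | GAAC | CT | QSO] -> 468 values at defaults."""
    configs = configs or EncoderConfigs()
    encoders = {
        "aac": lambda: encode_aac(p),
        "gaac": lambda: encode_gaac(p, configs.gaac),
        "ct": lambda: encode_ct(p, configs.ct),
        "qso": lambda: encode_qso(p, configs.qso),
    }
    parts: list[DescriptorVector] = []
    for name in configs.descriptors:
        try:
            parts.append(encoders[name]())
        except InvalidSequenceError as exc:
            raise InvalidSequenceError(f"[{name}] {exc}") from exc
    return DescriptorVector(
        np.concatenate([d.values for d in parts]),
        tuple(label for d in parts for label in d.labels),
    )


# ---------------------------------------------------------------------------
# I/O: FASTA in, labelled feature matrix out.
# ---------------------------------------------------------------------------

def read_fasta(path, sanitize_policy: str = "drop") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into sanitized :class:`ProteinRecord`s."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq), sanitize_policy)))
    return records


def write_feature_table(path, ids: Sequence[str], vectors: Iterable[DescriptorVector]) -> None:
    """TSV with block-labelled header, one protein per row."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no vectors to write")
    labels = vectors[0].labels
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(labels) + "\n")
        for pid, vec in zip(ids, vectors, strict=True):
            if vec.labels != labels:
                raise ValueError("inconsistent descriptor layouts")
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in vec.values) + "\n")


def read_feature_table(path) -> tuple[list[str], np.ndarray, tuple[str, ...]]:
    """Inverse of :func:`write_feature_table`: (ids, matrix, labels)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["id"]:
            raise ValueError(f"{path}: not a feature table (missing 'id' header)")
        labels = tuple(header[1:])
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, np.array(rows), labels
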