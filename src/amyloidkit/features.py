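"""Protein sequence feature encoders.

Two encodings are provided:

* **SVMProt-188D** — 20 amino-acid composition frequencies plus, for each of
  8 physicochemical properties that partition the 20 residues into three
  classes, the CTD descriptors: composition (3 values), transition
  (3 values, one per unordered class pair, normalized by L-1) and
  distribution (15 values: the chain-length percentages at which the first,
  25%, 50%, 75% and last occurrence of each class fall, scaled by 100).
  Total 20 + (3 + 3 + 15) x 8 = 188 features.

* **TPC** (tripeptide composition) — frequencies of the 20^3 = 8000
  overlapping tripeptides, each count divided by L - 2.

Both are exposed as plain functions over a single sequence and as
scikit-learn transformers over an iterable of sequences/records.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_fasta import STANDARD_AA, ProteinRecord


class SequenceTooShortError(ValueError):
    """Raised when a sequence is too short for the requested encoder."""


@dataclass(frozen=True)
class PropertyGrouping:
    """A physicochemical property partitioning the 20 residues into 3 classes."""

    name: str
    classes: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.classes)
        if sorted(joined) != sorted(STANDARD_AA):
            raise ValueError(
                f"grouping {self.name!r} does not partition the 20 standard letters"
            )

    def class_of(self, residue: str) -> int:
        for g, members in enumerate(self.classes):
            if residue in members:
                return g
        raise KeyError(residue)


# The canonical 3-class groupings of the 8 CTD physicochemical properties,
# in fixed row order (feature indices depend on this order).
PROPERTY_GROUPINGS: tuple[PropertyGrouping, ...] = (
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")),
    PropertyGrouping("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    PropertyGrouping("surface_tension", ("ILMFPWYV", "KTSEC", "GQDNAHR")),
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
)

GROUPING_BY_NAME = {g.name: g for g in PROPERTY_GROUPINGS}

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}

# residue -> class index lookup tables, one row per property
_CLASS_LUT = np.zeros((len(PROPERTY_GROUPINGS), 20), dtype=np.int64)
for _p, _g in enumerate(PROPERTY_GROUPINGS):
    for _a in STANDARD_AA:
        _CLASS_LUT[_p, _AA_INDEX[_a]] = _g.class_of(_a)

TRIPEPTIDES: tuple[str, ...] = tuple(
    "".join(t) for t in product(STANDARD_AA, repeat=3)
)

_DIST_ANCHORS = ("first", "p25", "p50", "p75", "p100")


def _build_188d_names() -> tuple[str, ...]:
    names = [f"AAC.{a}" for a in STANDARD_AA]
    for g in PROPERTY_GROUPINGS:
        names += [f"{g.name}.comp{c}" for c in (1, 2, 3)]
        names += [f"{g.name}.tran{r}{s}" for r, s in ((1, 2), (1, 3), (2, 3))]
        for c in (1, 2, 3):
            names += [f"{g.name}.dist{c}.{a}" for a in _DIST_ANCHORS]
    return tuple(names)


FEATURE_NAMES_188D: tuple[str, ...] = _build_188d_names()
assert len(FEATURE_NAMES_188D) == 188


def _as_indices(record: ProteinRecord | str) -> np.ndarray:
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if len(seq) == 0:
        raise ValueError("sequence must have length >= 1")
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from exc


def aa_composition(record: ProteinRecord | str) -> np.ndarray:
    """Frequencies of the 20 amino acids, alphabetical order; sums to 1."""
    idx = _as_indices(record)
    return np.bincount(idx, minlength=20) / idx.size


def ctd_composition(
    record: ProteinRecord | str, grouping: PropertyGrouping | str
) -> np.ndarray:
    """Per-class residue frequencies for one property (3 values, sum to 1)."""
    grouping = _resolve(grouping)
    idx = _as_indices(record)
    classes = _CLASS_LUT[_prop_index(grouping)][idx]
    return np.bincount(classes, minlength=3) / idx.size


def ctd_transition(
    record: ProteinRecord | str, grouping: PropertyGrouping | str
) -> np.ndarray:
    """Cross-class adjacent-pair frequencies for one property.

    Three values for the unordered class pairs (1,2), (1,3), (2,3): the
    number of adjacent positions whose residues fall in the two classes, in
    either order, divided by L - 1.  All zeros for L = 1.
    """
    grouping = _resolve(grouping)
    idx = _as_indices(record)
    if idx.size < 2:
        return np.zeros(3)
    classes = _CLASS_LUT[_prop_index(grouping)][idx]
    a, b = classes[:-1], classes[1:]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    out = np.array(
        [
            np.count_nonzero((lo == 0) & (hi == 1)),
            np.count_nonzero((lo == 0) & (hi == 2)),
            np.count_nonzero((lo == 1) & (hi == 2)),
        ],
        dtype=float,
    )
    return out / (idx.size - 1)


def ctd_distribution(
    record: ProteinRecord | str, grouping: PropertyGrouping | str
) -> np.ndarray:
    """Positional percentile anchors of each class, as chain-length percent.

    For each class occurring n >= 1 times at 1-based positions
    p_1 < ... < p_n, the five values are 100 * p_m / L at
    m = 1, ceil(0.25 n), ceil(0.50 n), ceil(0.75 n), n.  A class with no
    occurrences contributes five zeros.  15 values in [0, 100].
    """
    grouping = _resolve(grouping)
    idx = _as_indices(record)
    length = idx.size
    classes = _CLASS_LUT[_prop_index(grouping)][idx]
    out = np.zeros(15)
    for c in range(3):
        positions = np.flatnonzero(classes == c) + 1  # 1-based
        n = positions.size
        if n == 0:
            continue
        anchors = [0, int(np.ceil(0.25 * n)) - 1, int(np.ceil(0.50 * n)) - 1,
                   int(np.ceil(0.75 * n)) - 1, n - 1]
        out[c * 5 : c * 5 + 5] = 100.0 * positions[anchors] / length
    return out


def encode_188d(record: ProteinRecord | str) -> np.ndarray:
    """The full SVMProt-188D vector: AAC then C, T, D per property."""
    idx = _as_indices(record)
    length = idx.size
    parts = [np.bincount(idx, minlength=20) / length]
    for p in range(len(PROPERTY_GROUPINGS)):
        classes = _CLASS_LUT[p][idx]
        comp = np.bincount(classes, minlength=3) / length
        if length >= 2:
            a, b = classes[:-1], classes[1:]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            tran = np.array(
                [
                    np.count_nonzero((lo == 0) & (hi == 1)),
                    np.count_nonzero((lo == 0) & (hi == 2)),
                    np.count_nonzero((lo == 1) & (hi == 2)),
                ],
                dtype=float,
            ) / (length - 1)
        else:
            tran = np.zeros(3)
        dist = np.zeros(15)
        for c in range(3):
            positions = np.flatnonzero(classes == c) + 1
            n = positions.size
            if n == 0:
                continue
            anchors = [0, int(np.ceil(0.25 * n)) - 1, int(np.ceil(0.50 * n)) - 1,
                       int(np.ceil(0.75 * n)) - 1, n - 1]
            dist[c * 5 : c * 5 + 5] = 100.0 * positions[anchors] / length
        parts += [comp, tran, dist]
    return np.concatenate(parts)


def encode_tpc(record: ProteinRecord | str, counts: bool = False) -> np.ndarray:
    """Tripeptide composition: 8000 overlapping-tripeptide frequencies.

    Tripeptides are ordered lexicographically (AAA, AAC, ..., YYY).  With
    ``counts=True`` the raw occurrence counts are returned instead of
    frequencies (needed by binomial-distribution feature ranking).

    Raises
    ------
    SequenceTooShortError
        If L < 3.
    """
    idx = _as_indices(record)
    if idx.size < 3:
        raise SequenceTooShortError(
            f"sequence of length {idx.size} is too short for tripeptide "
            "composition (need L >= 3)"
        )
    tri = idx[:-2] * 400 + idx[1:-1] * 20 + idx[2:]
    c = np.bincount(tri, minlength=8000).astype(float)
    if counts:
        return c
    return c / (idx.size - 2)


def encode_multifeature(
    record: ProteinRecord | str,
    selected_188d: np.ndarray | list[int],
    selected_tpc: np.ndarray | list[int],
) -> np.ndarray:
    """Concatenate selected SVMProt-188D columns with selected TPC columns."""
    s188 = _check_subset(selected_188d, 188, "selected_188d")
    stpc = _check_subset(selected_tpc, 8000, "selected_tpc")
    parts = []
    if s188.size:
        parts.append(encode_188d(record)[s188])
    if stpc.size:
        parts.append(encode_tpc(record)[stpc])
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def _check_subset(indices, upper: int, name: str) -> np.ndarray:
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= upper):
        raise IndexError(f"{name} contains indices outside [0, {upper})")
    if np.unique(idx).size != idx.size:
        raise ValueError(f"{name} contains duplicate indices")
    return idx


def _resolve(grouping: PropertyGrouping | str) -> PropertyGrouping:
    if isinstance(grouping, str):
        return GROUPING_BY_NAME[grouping]
    return grouping


def _prop_index(grouping: PropertyGrouping) -> int:
    return PROPERTY_GROUPINGS.index(grouping)


def _sequences(X) -> list[str]:
    return [x.sequence if isinstance(x, ProteinRecord) else str(x) for x in X]


class SVMProt188Encoder(TransformerMixin, BaseEstimator):
    """Transformer mapping sequences/records to the 188-dim CTD encoding.

    Stateless: ``fit`` only records the output dimensionality.  ``transform``
    accepts an iterable of :class:`ProteinRecord` or plain sequence strings
    and returns an (n, 188) array.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        self.feature_names_out_ = np.asarray(FEATURE_NAMES_188D, dtype=object)
        return self

    def transform(self, X) -> np.ndarray:
        seqs = _sequences(X)
        if not seqs:
            return np.zeros((0, 188))
        return np.vstack([encode_188d(s) for s in seqs])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES_188D, dtype=object)


class TripeptideEncoder(TransformerMixin, BaseEstimator):
    """Transformer mapping sequences/records to the 8000-dim TPC encoding.

    Parameters
    ----------
    output : {"frequency", "count"}
        Whether to emit per-sequence frequencies (counts / (L-2)) or raw
        occurrence counts.
    """

    def __init__(self, output: str = "frequency"):
        self.output = output

    def fit(self, X, y=None):
        if self.output not in ("frequency", "count"):
            raise ValueError("output must be 'frequency' or 'count'")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        counts = self.output == "count"
        seqs = _sequences(X)
        if not seqs:
            return np.zeros((0, 8000))
        return np.vstack([encode_tpc(s, counts=counts) for s in seqs])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(TRIPEPTIDES, dtype=object)
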