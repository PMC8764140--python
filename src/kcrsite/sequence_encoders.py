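"""Linear-sequence feature encoders for site-centered windows.

Implements the classic composition encoders used in PTM site prediction:

* AAC — amino-acid composition (20 dims)
* AAPC — ordered amino-acid pair composition (400 dims)
* binary — per-position one-hot encoding ((2n+1) x 20 dims)
* CKSAAP — composition of k-spaced amino-acid pairs (400 dims per gap k)
* EAAC / EGAAC — AAC (or 5-group grouped AAC) in sliding sub-windows
* PSSM — profile rows at the window's positions

Composition counts always run over *real* residues only: pad slots ('-') and
unknown residues ('X') are excluded from both numerator and denominator, so
every composition block is a proper probability distribution (or an all-zero
block when no real residue is available). Encoders are pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AA_INDEX,
    AA_PAIRS,
    AMINO_ACIDS,
    ContactMap,
    PSSMatrix,
    ProteinRecord,
    SiteLabel,
)
from .windowing import Segment, extract_segment

#: The five physicochemical residue groups used by EGAAC.
EGAAC_GROUPS: tuple[tuple[str, str], ...] = (
    ("g1.aliphatic", "GAVLMI"),
    ("g2.aromatic", "FYW"),
    ("g3.positive", "KRH"),
    ("g4.negative", "DE"),
    ("g5.uncharged", "STCPNQ"),
)
_GROUP_OF = {aa: gi for gi, (_, members) in enumerate(EGAAC_GROUPS) for aa in members}


class EncodingError(ValueError):
    """Raised when a segment cannot be encoded under an encoder's contract."""


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, named, finite-valued feature vector."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.shape[0] or values.ndim != 1:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature-dimension names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class FeatureMatrix:
    """A samples x dimensions matrix with sample ids, class labels and column names."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, d = values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("row, label and id counts must agree")
        if len(self.names) != d:
            raise ValueError("column-name count must match value columns")
        if len(set(self.names)) != d:
            raise ValueError("column names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def y(self) -> np.ndarray:
        """Binary class vector: 1 for positive, 0 for negative."""
        return np.array([1 if lab == "positive" else 0 for lab in self.labels])

    def subset_rows(self, index: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(index, dtype=int)
        return FeatureMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            names=self.names,
            values=self.values[idx],
        )

    def select_columns(self, keep: Sequence[bool]) -> "FeatureMatrix":
        mask = np.asarray(keep, dtype=bool)
        if mask.shape[0] != self.n_features:
            raise ValueError("mask length must match feature count")
        return FeatureMatrix(
            sample_ids=self.sample_ids,
            labels=self.labels,
            names=tuple(n for n, k in zip(self.names, mask) if k),
            values=self.values[:, mask],
        )


@dataclass
class Sample:
    """One candidate site plus the auxiliary inputs its encoders may need.

    ``contact_map`` is expected to be already thresholded when contact-aware
    encoders (rrc, rrpc) are requested.
    """

    protein: ProteinRecord
    site: SiteLabel
    contact_map: ContactMap | None = None
    pssm: PSSMatrix | None = None

    @property
    def id(self) -> str:
        return f"{self.protein.id}:{self.site.position}"

    @property
    def label(self) -> str:
        return self.site.label


# ---------------------------------------------------------------------------
# helpers

def _real_residues(chars: Iterable[str]) -> list[str]:
    """Residues that participate in composition counts (20-letter alphabet only)."""
    return [c for c in chars if c in AA_INDEX]


def _aa_counts(chars: Iterable[str]) -> np.ndarray:
    counts = np.zeros(20)
    for c in chars:
        idx = AA_INDEX.get(c)
        if idx is not None:
            counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# composition encoders

def encode_aac(segment: Segment) -> FeatureVector:
    """Amino-acid composition: frequency of each residue type in the window."""
    counts = _aa_counts(segment.residues)
    total = counts.sum()
    if total == 0:
        raise EncodingError("AAC undefined: segment has no real residues")
    names = tuple(f"aac|{a}" for a in AMINO_ACIDS)
    return FeatureVector(names=names, values=counts / total)


def encode_aapc(segment: Segment) -> FeatureVector:
    """Ordered pair composition over all position pairs (p, q), p != q.

    The count of ordered pairs with residues (a, b) equals c_a*c_b for a != b
    and c_a*(c_a - 1) for a == b; the denominator D*(D-1) is exactly the number
    of ordered pairs of distinct real positions, so the vector sums to 1.
    """
    counts = _aa_counts(segment.residues)
    total = counts.sum()
    if total < 2:
        raise EncodingError("AAPC undefined: fewer than two real residues")
    pair_counts = np.outer(counts, counts) - np.diag(counts)
    names = tuple(f"aapc|{p}" for p in AA_PAIRS)
    return FeatureVector(names=names, values=pair_counts.ravel() / (total * (total - 1)))


def encode_binary(segment: Segment) -> FeatureVector:
    """Per-position one-hot over the 20 residues; pads and 'X' give zero blocks."""
    width = len(segment)
    values = np.zeros(width * 20)
    names = []
    for slot in range(width):
        offset = slot - segment.half_width
        names.extend(f"binary|{offset:+d}|{a}" for a in AMINO_ACIDS)
        idx = AA_INDEX.get(segment.residues[slot])
        if idx is not None:
            values[slot * 20 + idx] = 1.0
    return FeatureVector(names=tuple(names), values=values)


def encode_cksaap(segment: Segment, gaps: Sequence[int] = (1, 2, 3)) -> FeatureVector:
    """Composition of k-spaced residue pairs: positions (p, p+k+1) per gap k.

    Each gap's 400-dim block is normalized by the number of pairs whose two
    positions both hold real residues; a gap with no valid pair yields a zero
    block.
    """
    if not gaps:
        raise EncodingError("CKSAAP requires at least one gap value")
    gaps = sorted(set(int(k) for k in gaps))
    if any(k < 0 for k in gaps):
        raise EncodingError("CKSAAP gaps must be >= 0")
    if max(gaps) + 1 >= len(segment):
        raise EncodingError(
            f"gap {max(gaps)} too large for a segment of length {len(segment)}"
        )
    blocks, names = [], []
    res = segment.residues
    for k in gaps:
        counts = np.zeros((20, 20))
        step = k + 1
        valid = 0
        for p in range(len(res) - step):
            a, b = AA_INDEX.get(res[p]), AA_INDEX.get(res[p + step])
            if a is not None and b is not None:
                counts[a, b] += 1
                valid += 1
        blocks.append(counts.ravel() / valid if valid else counts.ravel())
        names.extend(f"cksaap|k{k}|{p}" for p in AA_PAIRS)
    return FeatureVector(names=tuple(names), values=np.concatenate(blocks))


def encode_eaac(segment: Segment, subwindow: int = 5) -> FeatureVector:
    """AAC in every sliding sub-window of the stated size, blocks left to right."""
    if subwindow < 1:
        raise EncodingError(f"sub-window size must be >= 1, got {subwindow}")
    if subwindow > len(segment):
        raise EncodingError(
            f"sub-window {subwindow} larger than segment of length {len(segment)}"
        )
    blocks, names = [], []
    for start in range(len(segment) - subwindow + 1):
        counts = _aa_counts(segment.residues[start : start + subwindow])
        total = counts.sum()
        blocks.append(counts / total if total else counts)
        names.extend(f"eaac|w{start}|{a}" for a in AMINO_ACIDS)
    return FeatureVector(names=tuple(names), values=np.concatenate(blocks))


def encode_egaac(segment: Segment, subwindow: int = 5) -> FeatureVector:
    """EAAC over the five physicochemical residue groups instead of 20 letters."""
    if subwindow < 1:
        raise EncodingError(f"sub-window size must be >= 1, got {subwindow}")
    if subwindow > len(segment):
        raise EncodingError(
            f"sub-window {subwindow} larger than segment of length {len(segment)}"
        )
    blocks, names = [], []
    for start in range(len(segment) - subwindow + 1):
        counts = np.zeros(5)
        for c in segment.residues[start : start + subwindow]:
            gi = _GROUP_OF.get(c)
            if gi is not None:
                counts[gi] += 1
        total = counts.sum()
        blocks.append(counts / total if total else counts)
        names.extend(f"egaac|w{start}|{g}" for g, _ in EGAAC_GROUPS)
    return FeatureVector(names=tuple(names), values=np.concatenate(blocks))


def encode_pssm_window(segment: Segment, pssm: PSSMatrix) -> FeatureVector:
    """Profile rows at the window's positions, flattened; pads give zero rows."""
    if pssm.protein_id != segment.protein_id:
        raise EncodingError(
            f"PSSM for {pssm.protein_id!r} does not match segment protein "
            f"{segment.protein_id!r}"
        )
    rows, names = [], []
    for slot, pos in enumerate(segment.positions):
        offset = slot - segment.half_width
        names.extend(f"pssm|{offset:+d}|{a}" for a in AMINO_ACIDS)
        rows.append(np.zeros(20) if pos is None else pssm.row(pos))
    return FeatureVector(names=tuple(names), values=np.concatenate(rows))


# ---------------------------------------------------------------------------
# matrix assembly

def _encode_one(name: str, sample: Sample, segment: Segment, params: Mapping) -> FeatureVector:
    from . import contact_features  # late import: contact_features builds on this module

    if name == "aac":
        return encode_aac(segment)
    if name == "aapc":
        return encode_aapc(segment)
    if name == "binary":
        return encode_binary(segment)
    if name == "cksaap":
        return encode_cksaap(segment, gaps=params.get("cksaap_gaps", (1, 2, 3)))
    if name == "eaac":
        return encode_eaac(segment, subwindow=params.get("subwindow", 5))
    if name == "egaac":
        return encode_egaac(segment, subwindow=params.get("subwindow", 5))
    if name == "pssm":
        if sample.pssm is None:
            raise EncodingError("pssm encoder requires a PSSM profile")
        return encode_pssm_window(segment, sample.pssm)
    if name == "rrc":
        if sample.contact_map is None:
            raise EncodingError("rrc encoder requires a contact map")
        contacts = contact_features.select_window_contacts(sample.contact_map, segment)
        expanded = contact_features.expand_segment(segment, contacts, sample.protein)
        return contact_features.encode_rrc(expanded)
    if name == "rrpc":
        if sample.contact_map is None:
            raise EncodingError("rrpc encoder requires a contact map")
        contacts = contact_features.select_window_contacts(sample.contact_map, segment)
        return contact_features.encode_rrpc(segment, contacts, sample.protein)
    raise EncodingError(f"unknown encoder {name!r}")


ENCODER_NAMES = ("aac", "aapc", "binary", "cksaap", "eaac", "egaac", "pssm", "rrc", "rrpc")


def build_matrix(
    encoder: str | Sequence[str],
    samples: Sequence[Sample],
    *,
    half_width: int = 10,
    cksaap_gaps: Sequence[int] = (1, 2, 3),
    subwindow: int = 5,
) -> FeatureMatrix:
    """Encode every sample with one encoder or a concatenation of encoders.

    For a list of encoders the columns are concatenated in listed order; the
    encoder prefix in each dimension name keeps columns unique. Any encoding
    error is re-raised with the offending sample id attached.
    """
    encoders = [encoder] if isinstance(encoder, str) else list(encoder)
    if not encoders:
        raise ValueError("no encoder given")
    for name in encoders:
        if name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {name!r}; choose from {ENCODER_NAMES}")
    if not samples:
        raise ValueError("no samples to encode")
    params = {"cksaap_gaps": tuple(cksaap_gaps), "subwindow": subwindow}
    rows: list[np.ndarray] = []
    names: tuple[str, ...] | None = None
    for sample in samples:
        try:
            segment = extract_segment(sample.protein, sample.site, half_width)
            vectors = [_encode_one(e, sample, segment, params) for e in encoders]
        except (EncodingError, ValueError) as exc:
            raise EncodingError(f"sample {sample.id}: {exc}") from exc
        row_names = tuple(n for v in vectors for n in v.names)
        if names is None:
            names = row_names
        elif row_names != names:
            raise EncodingError(f"sample {sample.id}: inconsistent feature dimensions")
        rows.append(np.concatenate([v.values for v in vectors]))
    assert names is not None
    return FeatureMatrix(
        sample_ids=tuple(s.id for s in samples),
        labels=tuple(s.label for s in samples),
        names=names,
        values=np.vstack(rows),
    )
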