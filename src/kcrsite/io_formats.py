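"""Readers and writers for every on-disk format the pipeline touches.

File coordinates are 1-based, matching the conventions of contact-prediction
tables and PSI-BLAST profiles; all conversion to 0-based array indexing
happens here, at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in fixed alphabetical one-letter order.
#: This order defines column identity for every composition-style encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: All 400 ordered residue pairs, row-major in the alphabetical order above.
AA_PAIRS: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

PAD = "-"
UNKNOWN = "X"

POSITIVE = "positive"
NEGATIVE = "negative"

_LABEL_SYNONYMS = {
    "positive": POSITIVE, "pos": POSITIVE, "1": POSITIVE,
    "negative": NEGATIVE, "neg": NEGATIVE, "0": NEGATIVE,
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length amino-acid sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {UNKNOWN}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}; "
                "normalize with read_fasta or map to 'X'"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based sequence position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside protein {self.id!r} (length {self.length})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteLabel:
    """One candidate lysine site: protein, 1-based position, class label."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be 1-based positive, got {self.position}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}")

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass(frozen=True)
class ContactRecord:
    """An undirected predicted residue contact, canonicalized to i < j."""

    i: int
    j: int
    probability: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-contact at residue {self.i}")
        if self.i > self.j:  # canonicalize: undirected pair stored i < j
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)
        if self.i < 1:
            raise ValueError(f"contact indices must be 1-based, got ({self.i}, {self.j})")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"contact ({self.i}, {self.j}): probability {self.probability} outside [0, 1]"
            )


@dataclass
class ContactMap:
    """All predicted contacts for one protein, duplicate-merged by max probability."""

    protein_id: str
    _probs: dict[tuple[int, int], float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, protein_id: str, records: Iterable[ContactRecord]) -> "ContactMap":
        cmap = cls(protein_id)
        for rec in records:
            cmap.add(rec)
        return cmap

    def add(self, rec: ContactRecord) -> None:
        key = (rec.i, rec.j)
        prev = self._probs.get(key)
        if prev is None or rec.probability > prev:
            self._probs[key] = rec.probability

    @property
    def records(self) -> tuple[ContactRecord, ...]:
        return tuple(
            ContactRecord(i, j, p) for (i, j), p in sorted(self._probs.items())
        )

    def probability(self, i: int, j: int) -> float | None:
        if i > j:
            i, j = j, i
        return self._probs.get((i, j))

    def __len__(self) -> int:
        return len(self._probs)

    def __iter__(self) -> Iterator[ContactRecord]:
        return iter(self.records)

    def validate_for(self, protein: ProteinRecord) -> None:
        """Check every contact index is a valid position of *protein*."""
        if protein.id != self.protein_id:
            raise ValueError(f"contact map {self.protein_id!r} vs protein {protein.id!r}")
        for (i, j) in self._probs:
            if j > protein.length:
                raise ValueError(
                    f"contact ({i}, {j}) outside protein {protein.id!r} "
                    f"(length {protein.length})"
                )


@dataclass
class PSSMatrix:
    """An L x 20 position-specific scoring matrix in alphabetical column order."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AMINO_ACIDS):
            raise ValueError(f"PSSM must be L x 20, got shape {self.scores.shape}")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def row(self, position: int) -> np.ndarray:
        """Score row at a 1-based sequence position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside PSSM of length {self.length}")
        return self.scores[position - 1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA.

    Sequences are upper-cased, internal whitespace removed, and any character
    outside the 20-letter alphabet mapped to ``'X'`` with a logged warning.
    Duplicate identifiers and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        raw = "".join(str(rec.seq).split()).upper()
        cleaned = "".join(c if c in AA_INDEX else UNKNOWN for c in raw)
        n_mapped = sum(1 for a, b in zip(raw, cleaned) if a != b)
        if n_mapped:
            logger.warning(
                "%s: %d non-standard residue(s) in %r mapped to 'X'", path, n_mapped, rec.id
            )
        records.append(ProteinRecord(id=rec.id, sequence=cleaned))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site labels

def read_site_labels(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteLabel]:
    """Read a site-label table (TSV or CSV: protein_id, position, label).

    Every label is validated against the referenced protein: the position must
    be in range and the residue there must be lysine ('K'). An optional header
    row is tolerated. Errors carry the offending 1-based row number.
    """
    by_id = {p.id: p for p in proteins}
    labels: list[SiteLabel] = []
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    if not any(ln.strip() for ln in lines):
        raise FormatError(f"{path}: empty site-label file")
    sep = "\t" if "\t" in next(ln for ln in lines if ln.strip()) else ","
    for rownum, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) < 3:
            raise FormatError(f"{path} row {rownum}: expected 3 columns, got {len(fields)}")
        pid, pos_str, raw_label = fields[0], fields[1], fields[2]
        try:
            position = int(pos_str)
        except ValueError:
            if rownum == 1:  # header row
                continue
            raise FormatError(f"{path} row {rownum}: non-integer position {pos_str!r}")
        label = _LABEL_SYNONYMS.get(raw_label.lower())
        if label is None:
            raise FormatError(f"{path} row {rownum}: unrecognized label {raw_label!r}")
        protein = by_id.get(pid)
        if protein is None:
            raise FormatError(f"{path} row {rownum}: unknown protein {pid!r}")
        if not 1 <= position <= protein.length:
            raise FormatError(
                f"{path} row {rownum}: position {position} outside protein "
                f"{pid!r} (length {protein.length})"
            )
        if protein.residue(position) != "K":
            raise FormatError(
                f"{path} row {rownum}: residue at {pid}:{position} is "
                f"{protein.residue(position)!r}, expected 'K'"
            )
        labels.append(SiteLabel(protein_id=pid, position=position, label=label))
    return labels


def write_site_labels(labels: Sequence[SiteLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for lab in labels:
            fh.write(f"{lab.protein_id}\t{lab.position}\t{lab.label}\n")


# ---------------------------------------------------------------------------
# Contact tables

def read_contact_table(path: str | Path, protein_id: str | None = None) -> ContactMap:
    """Read a 6-column whitespace-delimited contact-prediction table.

    Columns 1-2 are 1-based residue indices, column 5 the contact probability;
    columns 3, 4 and 6 are read and discarded. Header rows whose first token is
    non-numeric are skipped. Symmetric duplicates (i,j)/(j,i) are merged keeping
    the maximum probability; self-contacts and out-of-range probabilities are
    errors (probabilities are never clamped).
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    cmap = ContactMap(protein_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            try:
                i = int(tokens[0])
            except ValueError:
                continue  # header row
            if len(tokens) < 6:
                raise FormatError(
                    f"{path} line {lineno}: expected >=6 columns, got {len(tokens)}"
                )
            try:
                j = int(tokens[1])
                prob = float(tokens[4])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            try:
                cmap.add(ContactRecord(i, j, prob))
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return cmap


def write_contact_table(cmap: ContactMap, path: str | Path) -> None:
    """Write a contact map in the 6-column predictor format (cols 3,4,6 are filler)."""
    with open(path, "w") as fh:
        for rec in cmap.records:
            fh.write(f"{rec.i} {rec.j} 0 8 {rec.probability!r} 0\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm(
    path: str | Path,
    protein: ProteinRecord | None = None,
    protein_id: str | None = None,
) -> PSSMatrix:
    """Read a PSI-BLAST ASCII profile into an L x 20 matrix.

    The file's own column-letter header determines input column order; output
    columns are always in fixed alphabetical order. When *protein* is given the
    row count must match its length.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = protein.id if protein is not None else path.stem
    col_order: list[str] | None = None
    rows: list[np.ndarray] = []
    positions: list[int] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if col_order is None:
                letters = [t for t in tokens if len(t) == 1 and t in AA_INDEX]
                if len(letters) >= 20:
                    col_order = letters[:20]
                continue
            try:
                pos = int(tokens[0])
            except ValueError:
                continue  # footer (statistics) lines
            if len(tokens) < 22:
                continue
            try:
                scores = np.array([float(t) for t in tokens[2:22]])
            except ValueError:
                continue
            positions.append(pos)
            rows.append(scores)
    if col_order is None or not rows:
        raise FormatError(f"{path}: not a PSI-BLAST ASCII profile")
    if positions != list(range(1, len(rows) + 1)):
        raise FormatError(f"{path}: profile rows are not consecutive from position 1")
    raw = np.vstack(rows)
    ordered = np.empty_like(raw)
    for src, letter in enumerate(col_order):
        ordered[:, AA_INDEX[letter]] = raw[:, src]
    if protein is not None and len(rows) != protein.length:
        raise FormatError(
            f"{path}: {len(rows)} profile rows but protein {protein.id!r} "
            f"has length {protein.length}"
        )
    return PSSMatrix(protein_id=protein_id, scores=ordered)


#: Column-letter order used by PSI-BLAST itself (not alphabetical).
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def write_pssm(pssm: PSSMatrix, sequence: str, path: str | Path) -> None:
    """Write an L x 20 profile in PSI-BLAST ASCII layout (integer scores)."""
    if len(sequence) != pssm.length:
        raise ValueError("sequence length does not match PSSM row count")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(PSIBLAST_ORDER) + "\n")
        for pos in range(1, pssm.length + 1):
            row = pssm.row(pos)
            vals = " ".join(f"{int(round(row[AA_INDEX[a]])):3d}" for a in PSIBLAST_ORDER)
            fh.write(f"{pos:5d} {sequence[pos - 1]} {vals}\n")


# ---------------------------------------------------------------------------
# Feature matrices (CSV)

def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as CSV: sample_id, label, then one column per dimension.

    Values round-trip losslessly (shortest-repr float formatting).
    """
    names = list(matrix.names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature-dimension names: {dupes}")
    if len(matrix.sample_ids) == 0:
        raise ValueError("refusing to write an empty feature matrix")
    df = pd.DataFrame(matrix.values, columns=names)
    df.insert(0, "label", list(matrix.labels))
    df.insert(0, "sample_id", list(matrix.sample_ids))
    df.to_csv(path, index=False)


def read_feature_matrix(path: str | Path):
    from .sequence_encoders import FeatureMatrix

    df = pd.read_csv(path)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "label"]:
        raise FormatError(f"{path}: not a feature-matrix CSV")
    return FeatureMatrix(
        sample_ids=tuple(str(s) for s in df["sample_id"]),
        labels=tuple(str(s) for s in df["label"]),
        names=tuple(df.columns[2:]),
        values=df.iloc[:, 2:].to_numpy(dtype=float),
    )
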