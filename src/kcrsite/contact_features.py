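"""Contact-aware feature encoders: RRC and RRPC.

A predicted contact map is first thresholded (a pair counts as "in contact"
only when its predicted probability is strictly above the threshold, 0.80 by
default). A contact *qualifies* for a site's window when at least one of its
endpoints lies inside the 2n+1 window.

* RRC (residue-residue composition, 20 dims): the window is expanded by
  appending, at the tail, the residue of each qualifying contact's endpoint
  that lies *outside* the window (deduplicated by position), then AAC is
  computed over window plus appended residues. With no qualifying contacts
  RRC reduces exactly to AAC.
* RRPC (residue-residue pair composition, 400 dims): each qualifying contact
  (i < j) contributes the ordered residue pair (residue(i), residue(j)) --
  lower sequence index first; counts are normalized by the number of counted
  contacts, giving an all-zero vector when none qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AA_INDEX,
    AA_PAIRS,
    AMINO_ACIDS,
    ContactMap,
    ContactRecord,
    ProteinRecord,
)
from .sequence_encoders import EncodingError, FeatureVector, _aa_counts
from .windowing import Segment

DEFAULT_CONTACT_THRESHOLD = 0.80


@dataclass(frozen=True)
class ExpandedSegment:
    """A window plus the outside endpoints of its qualifying contacts."""

    base: Segment
    appended_residues: tuple[tuple[int, str], ...]  # (1-based position, residue)
    qualifying_contacts: tuple[ContactRecord, ...]

    def __post_init__(self) -> None:
        covered = self.base.covered_positions
        positions = [p for p, _ in self.appended_residues]
        if len(set(positions)) != len(positions):
            raise ValueError("appended positions must be unique")
        if any(p in covered for p in positions):
            raise ValueError("appended positions must lie outside the base window")
        for rec in self.qualifying_contacts:
            if rec.i not in covered and rec.j not in covered:
                raise ValueError(
                    f"contact ({rec.i}, {rec.j}) has no endpoint inside the window"
                )


def filter_contacts(cmap: ContactMap, threshold: float = DEFAULT_CONTACT_THRESHOLD) -> ContactMap:
    """Keep exactly the contacts with probability strictly greater than *threshold*."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return ContactMap.from_records(
        cmap.protein_id,
        (rec for rec in cmap.records if rec.probability > threshold),
    )


def select_window_contacts(cmap: ContactMap, segment: Segment) -> list[ContactRecord]:
    """Contacts with at least one endpoint inside the segment's covered positions."""
    if cmap.protein_id != segment.protein_id:
        raise ValueError(
            f"contact map {cmap.protein_id!r} does not match segment protein "
            f"{segment.protein_id!r}"
        )
    covered = segment.covered_positions
    return [rec for rec in cmap.records if rec.i in covered or rec.j in covered]


def expand_segment(
    segment: Segment,
    contacts: list[ContactRecord],
    protein: ProteinRecord,
) -> ExpandedSegment:
    """Append the outside endpoint residue of each one-endpoint-inside contact.

    Contacts with both endpoints inside the window append nothing (their
    residues are already in the segment). Duplicate outside positions are
    appended once, in ascending sequence position.
    """
    covered = segment.covered_positions
    outside: dict[int, str] = {}
    for rec in contacts:
        inside_i, inside_j = rec.i in covered, rec.j in covered
        if not inside_i and not inside_j:
            raise ValueError(
                f"contact ({rec.i}, {rec.j}) does not qualify for window at "
                f"{segment.protein_id}:{segment.center}"
            )
        if inside_i and inside_j:
            continue
        pos = rec.j if inside_i else rec.i
        if pos > protein.length:
            raise ValueError(
                f"contact endpoint {pos} beyond protein {protein.id!r} "
                f"(length {protein.length})"
            )
        outside[pos] = protein.residue(pos)
    appended = tuple(sorted(outside.items()))
    return ExpandedSegment(
        base=segment,
        appended_residues=appended,
        qualifying_contacts=tuple(contacts),
    )


def encode_rrc(expanded: ExpandedSegment) -> FeatureVector:
    """AAC over the window's real residues plus the appended contact residues."""
    chars = list(expanded.base.residues) + [r for _, r in expanded.appended_residues]
    counts = _aa_counts(chars)
    total = counts.sum()
    if total == 0:
        raise EncodingError("RRC undefined: no real residues in expanded segment")
    names = tuple(f"rrc|{a}" for a in AMINO_ACIDS)
    return FeatureVector(names=names, values=counts / total)


def encode_rrpc(
    segment: Segment,
    contacts: list[ContactRecord],
    protein: ProteinRecord,
) -> FeatureVector:
    """Pair composition of qualifying contacts, lower sequence index first.

    Pairs with an unknown ('X') endpoint fall outside the 400 residue-pair
    types and are skipped; the denominator is the number of counted pairs, so
    the vector sums to 1 when any contact is counted and is all-zero otherwise.
    """
    covered = segment.covered_positions
    counts = np.zeros((20, 20))
    counted = 0
    for rec in contacts:
        if rec.i not in covered and rec.j not in covered:
            raise ValueError(
                f"contact ({rec.i}, {rec.j}) does not qualify for window at "
                f"{segment.protein_id}:{segment.center}"
            )
        if rec.j > protein.length:
            raise ValueError(
                f"contact endpoint {rec.j} beyond protein {protein.id!r} "
                f"(length {protein.length})"
            )
        a = AA_INDEX.get(protein.residue(rec.i))
        b = AA_INDEX.get(protein.residue(rec.j))
        if a is None or b is None:
            continue
        counts[a, b] += 1
        counted += 1
    values = counts.ravel() / counted if counted else counts.ravel()
    names = tuple(f"rrpc|{p}" for p in AA_PAIRS)
    return FeatureVector(names=names, values=values)
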