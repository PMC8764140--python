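"""Fixed half-width sequence windows around candidate lysine sites.

A window of half-width ``n`` covers positions ``center - n .. center + n``
(2n+1 residues). Positions falling before the start or past the end of the
protein are filled with the pad symbol ``'-'``; padded positions carry no
sequence position and are excluded from all composition counts downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import PAD, ProteinRecord, SiteLabel

#: Half-widths used throughout the study design; any n >= 1 is accepted.
DEFAULT_HALF_WIDTHS = (10, 15, 20, 25, 30)


@dataclass(frozen=True)
class Segment:
    """A 2n+1 residue window centered on a lysine site.

    ``positions[k]`` is the 1-based sequence position covered by window slot
    ``k``, or ``None`` for pad slots.
    """

    protein_id: str
    center: int
    half_width: int
    residues: str
    positions: tuple[int | None, ...]

    def __post_init__(self) -> None:
        width = 2 * self.half_width + 1
        if len(self.residues) != width or len(self.positions) != width:
            raise ValueError(f"segment must have 2n+1 = {width} slots")
        if self.residues[self.half_width] != "K":
            raise ValueError(
                f"segment center residue is {self.residues[self.half_width]!r}, expected 'K'"
            )
        covered = [p for p in self.positions if p is not None]
        if any(b <= a for a, b in zip(covered, covered[1:])):
            raise ValueError("window positions must be strictly increasing")

    @property
    def covered_positions(self) -> frozenset[int]:
        return frozenset(p for p in self.positions if p is not None)

    def __len__(self) -> int:
        return len(self.residues)


def extract_segment(
    protein: ProteinRecord, site: SiteLabel | int, n: int
) -> Segment:
    """Extract the 2n+1 window around *site* (a SiteLabel or 1-based position)."""
    if n < 1:
        raise ValueError(f"half-width must be >= 1, got {n}")
    if isinstance(site, SiteLabel):
        if site.protein_id != protein.id:
            raise ValueError(
                f"site protein {site.protein_id!r} does not match protein {protein.id!r}"
            )
        center = site.position
    else:
        center = int(site)
    if not 1 <= center <= protein.length:
        raise ValueError(f"site position {center} outside protein {protein.id!r}")
    if protein.residue(center) != "K":
        raise ValueError(
            f"residue at {protein.id}:{center} is {protein.residue(center)!r}, expected 'K'"
        )
    chars: list[str] = []
    positions: list[int | None] = []
    for pos in range(center - n, center + n + 1):
        if 1 <= pos <= protein.length:
            chars.append(protein.residue(pos))
            positions.append(pos)
        else:
            chars.append(PAD)
            positions.append(None)
    return Segment(
        protein_id=protein.id,
        center=center,
        half_width=n,
        residues="".join(chars),
        positions=tuple(positions),
    )


def enumerate_candidate_sites(protein: ProteinRecord) -> list[int]:
    """All 1-based positions of lysine ('K') residues, ascending."""
    return [i + 1 for i, c in enumerate(protein.sequence) if c == "K"]
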