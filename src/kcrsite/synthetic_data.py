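"""Synthetic proteins, lysine-site labels, contact tables and PSSM profiles.

The generator emulates the structure of a crotonylation-site study corpus:
a few hundred proteins, candidate sites at every lysine with roughly 1:10
positive:negative imbalance, one 6-column contact-prediction table per
protein with probabilities in [0, 1], and one PSI-BLAST-style profile per
protein. Two controllable signals separate positive from negative sites:

* a *sequence motif tilt*: flanking residues of positive sites are resampled
  toward a preferred residue set with probability ``motif_strength``;
* a *planted contact enrichment*: each positive site receives on average
  ``contact_enrichment`` high-probability contacts between a residue inside
  its +-n window and a distant partner position whose residue is set to a
  designated type. With the tilt off, the *only* positive/negative difference
  lives in the contact tables, so sequence-only encoders stay at chance while
  contact-aware encoders can recover the signal.

Background contacts are drawn per candidate pair (i, j), |i - j| >= 3, with a
probability decaying exponentially in sequence separation; drawn contacts emit
probabilities uniform on [0.5, 1.0] plus Gaussian noise, and a further set of
low-probability (< 0.5) noise rows pads each table the way real predictor
output is dominated by non-contacts.

Everything is deterministic given ``seed``: per-protein generators are spawned
from (seed, protein index), so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AA_INDEX,
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    ContactMap,
    ContactRecord,
    PSSMatrix,
    ProteinRecord,
    SiteLabel,
    write_contact_table,
    write_fasta,
    write_pssm,
    write_site_labels,
)

#: Background residue frequencies (approximate vertebrate proteome usage),
#: alphabetical order.
BACKGROUND_FREQS = {
    "A": 0.083, "C": 0.014, "D": 0.054, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.022, "I": 0.059, "K": 0.058, "L": 0.096,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.029,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (80, 200)
    positive_fraction: float = 0.1
    # sequence-motif signal
    motif_strength: float = 0.0
    motif_residues: str = "DE"
    motif_half_width: int = 5
    # contact model
    contact_base_rate: float = 0.01
    contact_decay: float = 20.0
    min_separation: int = 3
    probability_noise: float = 0.02
    noise_row_rate: float = 1.0  # low-probability filler rows per residue
    # planted contact signal
    contact_enrichment: float = 5.0  # mean planted contacts per positive site
    planted_residue: str = "W"
    planted_prob_range: tuple[float, float] = (0.85, 1.0)
    half_width: int = 10  # window the planted contacts anchor into
    # profile fixture
    pssm_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if lo <= 2 * self.half_width:
            raise ValueError(
                f"minimum length {lo} must exceed the window width "
                f"{2 * self.half_width} for planting"
            )
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        for name in ("motif_strength", "contact_base_rate", "probability_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_residue not in AA_INDEX or self.planted_residue == "K":
            raise ValueError("planted_residue must be a standard residue other than 'K'")
        if any(c not in AA_INDEX or c == "K" for c in self.motif_residues):
            raise ValueError("motif_residues must be standard residues other than 'K'")
        p_lo, p_hi = self.planted_prob_range
        if not 0.0 <= p_lo <= p_hi <= 1.0:
            raise ValueError(f"invalid planted probability range {self.planted_prob_range}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus writers for the on-disk layout the pipeline reads."""

    proteins: list[ProteinRecord]
    labels: list[SiteLabel]
    contact_maps: dict[str, ContactMap]
    pssms: dict[str, PSSMatrix]
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write proteins.fasta, sites.tsv, contacts/<id>.contacts, pssm/<id>.pssm."""
        outdir = Path(outdir)
        (outdir / "contacts").mkdir(parents=True, exist_ok=True)
        (outdir / "pssm").mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteins.fasta"
        sites = outdir / "sites.tsv"
        write_fasta(self.proteins, fasta)
        write_site_labels(self.labels, sites)
        for protein in self.proteins:
            write_contact_table(
                self.contact_maps[protein.id], outdir / "contacts" / f"{protein.id}.contacts"
            )
            write_pssm(
                self.pssms[protein.id], protein.sequence,
                outdir / "pssm" / f"{protein.id}.pssm",
            )
        return {
            "fasta": fasta, "sites": sites,
            "contacts_dir": outdir / "contacts", "pssm_dir": outdir / "pssm",
        }


def _protein_rng(config: SyntheticConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index, stream])


def _draw_sequence(length: int, rng: np.random.Generator) -> list[str]:
    letters = list(BACKGROUND_FREQS)
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    seq = list(rng.choice(letters, size=length, p=probs))
    if "K" not in seq:
        seq[int(rng.integers(1, length - 1))] = "K"
    return seq


def _apply_motif_tilt(
    seq: list[str], positives: Sequence[int], config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    if config.motif_strength == 0.0:
        return
    residues = list(config.motif_residues)
    for pos in positives:  # 1-based center
        for offset in range(-config.motif_half_width, config.motif_half_width + 1):
            if offset == 0:
                continue
            p = pos + offset
            if not 1 <= p <= len(seq) or seq[p - 1] == "K":
                continue
            if rng.random() < config.motif_strength:
                seq[p - 1] = residues[int(rng.integers(len(residues)))]


def _plant_contacts(
    seq: list[str], positives: Sequence[int], config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[ContactRecord]:
    """Plant window-anchored high-probability contacts for positive sites.

    The far partner's residue is set to the designated type; partners are
    chosen outside *every* candidate site's window (more than the half-width
    away from any lysine), so the planted pairs qualify only for the intended
    positive window and sequence-only window encoders cannot see them.
    """
    planted: list[ContactRecord] = []
    n = config.half_width
    length = len(seq)
    p_lo, p_hi = config.planted_prob_range
    k_positions = [p + 1 for p, c in enumerate(seq) if c == "K"]
    far_from_k = [
        f for f in range(1, length + 1)
        if all(abs(f - k) > n for k in k_positions)
    ]
    for pos in positives:
        # every positive site carries the signal: at least one planted contact
        n_planted = 1 + int(rng.poisson(max(config.contact_enrichment - 1.0, 0.0)))
        w_all = list(range(max(1, pos - n), min(length, pos + n) + 1))
        # prefer anchors that no *other* candidate site's window covers, so the
        # planted pair qualifies only for this site
        w_specific = [
            w for w in w_all
            if all(abs(w - k) > n for k in k_positions if k != pos)
        ]
        w_pool = w_specific or w_all
        for _ in range(n_planted):
            w = w_pool[int(rng.integers(len(w_pool)))]
            candidates = [
                f for f in far_from_k if abs(f - w) >= config.min_separation
            ]
            if not candidates:
                continue
            f = candidates[int(rng.integers(len(candidates)))]
            seq[f - 1] = config.planted_residue
            prob = float(rng.uniform(p_lo, p_hi))
            prob = float(np.clip(prob + rng.normal(0.0, config.probability_noise), 0.0, 1.0))
            planted.append(ContactRecord(w, f, prob))
    return planted


def _background_contacts(
    length: int, config: SyntheticConfig, rng: np.random.Generator
) -> list[ContactRecord]:
    i0, j0 = np.triu_indices(length, k=config.min_separation)
    i, j = i0 + 1, j0 + 1
    d = j - i
    q = config.contact_base_rate * np.exp(-(d - config.min_separation) / config.contact_decay)
    draws = rng.random(len(d))
    sel = draws < q
    probs = rng.uniform(0.5, 1.0, int(sel.sum()))
    probs = np.clip(
        probs + rng.normal(0.0, config.probability_noise, probs.shape), 0.0, 1.0
    )
    records = [
        ContactRecord(int(a), int(b), float(p))
        for a, b, p in zip(i[sel], j[sel], probs)
    ]
    # low-probability filler rows, as real predictor tables are mostly non-contacts
    n_noise = min(int(round(config.noise_row_rate * length)), int((~sel).sum()))
    if n_noise > 0:
        pick = rng.choice(np.flatnonzero(~sel), size=n_noise, replace=False)
        low = rng.uniform(0.0, 0.5, n_noise)
        records.extend(
            ContactRecord(int(i[k]), int(j[k]), float(p)) for k, p in zip(pick, low)
        )
    return records


def generate_contact_table(
    protein: ProteinRecord, config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Background-only contact table for one protein (no planted signal)."""
    if rng is None:
        import zlib

        rng = np.random.default_rng([config.seed, zlib.crc32(protein.id.encode())])
    return ContactMap.from_records(
        protein.id, _background_contacts(protein.length, config, rng)
    )


def _make_pssm(seq: str, config: SyntheticConfig, rng: np.random.Generator) -> PSSMatrix:
    """Frequency-derived integer log-odds profile (synthetic stand-in).

    Scores are 2 * log2 of windowed residue frequency over background, plus
    noise, rounded to integers like a real PSI-BLAST ASCII profile.
    """
    length = len(seq)
    bg = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS])
    bg = bg / bg.sum()
    scores = np.zeros((length, 20))
    half = 5
    for p in range(length):
        lo, hi = max(0, p - half), min(length, p + half + 1)
        counts = np.zeros(20)
        for c in seq[lo:hi]:
            counts[AA_INDEX[c]] += 1
        freqs = (counts + bg) / (counts.sum() + 1.0)
        scores[p] = 2.0 * np.log2(freqs / bg)
    scores += rng.normal(0.0, config.pssm_noise, scores.shape)
    return PSSMatrix(protein_id="", scores=np.round(scores))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full corpus: proteins, labels, contact maps, profiles."""
    # pass A: sequences and site labels
    sequences: list[list[str]] = []
    positives_per_protein: list[list[int]] = []
    negatives_per_protein: list[list[int]] = []
    for idx in range(config.n_proteins):
        rng = _protein_rng(config, idx, 0)
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = _draw_sequence(length, rng)
        k_positions = [p + 1 for p, c in enumerate(seq) if c == "K"]
        flags = rng.random(len(k_positions)) < config.positive_fraction
        sequences.append(seq)
        positives_per_protein.append([p for p, f in zip(k_positions, flags) if f])
        negatives_per_protein.append([p for p, f in zip(k_positions, flags) if not f])
    if not any(positives_per_protein):
        # degenerate tiny configs: force one positive so both classes exist
        for idx, negs in enumerate(negatives_per_protein):
            if negs:
                positives_per_protein[idx].append(negs.pop(0))
                break
    if not any(negatives_per_protein):
        for idx, poss in enumerate(positives_per_protein):
            if poss:
                negatives_per_protein[idx].append(poss.pop())
                break

    # pass B: signals, contacts, profiles
    proteins: list[ProteinRecord] = []
    labels: list[SiteLabel] = []
    contact_maps: dict[str, ContactMap] = {}
    pssms: dict[str, PSSMatrix] = {}
    width = len(str(config.n_proteins - 1))
    for idx in range(config.n_proteins):
        seq = sequences[idx]
        positives = sorted(positives_per_protein[idx])
        negatives = sorted(negatives_per_protein[idx])
        pid = f"syn{idx:0{width}d}"
        _apply_motif_tilt(seq, positives, config, _protein_rng(config, idx, 1))
        planted = (
            _plant_contacts(seq, positives, config, _protein_rng(config, idx, 2))
            if config.contact_enrichment > 0
            else []
        )
        background = _background_contacts(
            len(seq), config, _protein_rng(config, idx, 3)
        )
        protein = ProteinRecord(id=pid, sequence="".join(seq))
        cmap = ContactMap.from_records(pid, background + planted)
        cmap.validate_for(protein)
        pssm = _make_pssm(protein.sequence, config, _protein_rng(config, idx, 4))
        pssm.protein_id = pid
        proteins.append(protein)
        contact_maps[pid] = cmap
        pssms[pid] = pssm
        labels.extend(
            SiteLabel(pid, p, POSITIVE) for p in positives
        )
        labels.extend(
            SiteLabel(pid, p, NEGATIVE) for p in negatives
        )
    return SyntheticDataset(
        proteins=proteins, labels=labels,
        contact_maps=contact_maps, pssms=pssms, config=config,
    )


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study conditions with every planted signal off (chance-level labels)."""
    return SyntheticConfig(
        motif_strength=0.0, contact_enrichment=0.0, seed=seed, **overrides
    )


def contact_signal_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study conditions where the only class signal lives in the contact maps."""
    return SyntheticConfig(motif_strength=0.0, seed=seed, **overrides)
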