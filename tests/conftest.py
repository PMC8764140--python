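"""Shared fixtures: random segments, a small synthetic corpus on disk."""

from __future__ import annotations

import numpy as np
import pytest

from kcrsite.io_formats import AMINO_ACIDS, PAD, ProteinRecord
from kcrsite.synthetic_data import SyntheticConfig, generate_dataset
from kcrsite.windowing import Segment, extract_segment


def make_segment(residues: str, start_position: int = 1) -> Segment:
    """Build a Segment directly from a window string (odd length, 'K' center).

    Pad slots carry no sequence position; real slots are numbered contiguously
    from *start_position* over the underlying (virtual) protein.
    """
    assert len(residues) % 2 == 1
    half = len(residues) // 2
    positions: list[int | None] = []
    pos = start_position
    for c in residues:
        if c == PAD:
            positions.append(None)
        else:
            positions.append(pos)
            pos += 1
        if c != PAD and positions[-1] is None:
            raise AssertionError
    # pads are only legal at the ends; interior pads would break position order
    return Segment(
        protein_id="toy",
        center=positions[half],
        half_width=half,
        residues=residues,
        positions=tuple(positions),
    )


def random_segment(rng: np.random.Generator, half_width: int, allow_x: bool = False) -> Segment:
    """A random window: optional terminal pads, 'K' center, random residues."""
    width = 2 * half_width + 1
    alphabet = AMINO_ACIDS + ("X" if allow_x else "")
    left_pad = int(rng.integers(0, half_width))
    right_pad = int(rng.integers(0, half_width))
    chars = [PAD] * left_pad
    chars += [alphabet[int(rng.integers(len(alphabet)))] for _ in range(width - left_pad - right_pad)]
    chars += [PAD] * right_pad
    chars[half_width] = "K"
    return make_segment("".join(chars), start_position=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 30-protein planted-signal corpus, generated once and written to disk."""
    config = SyntheticConfig(n_proteins=30, seed=3)
    dataset = generate_dataset(config)
    outdir = tmp_path_factory.mktemp("corpus")
    paths = dataset.write(outdir)
    return {"dataset": dataset, "paths": paths, "config": config}


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord(id="p1", sequence="MAKCDEFGHKLMNPQRSTVWYKA")
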