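"""Shared fixtures: all test structures are generated programmatically."""

from __future__ import annotations

import os
import urllib.request

import numpy as np
import pytest

from aptastruct.model import StructureModel, read_structure
from aptastruct.synthetic import (
    HelixSpec, ToyComplexSpec, build_c2_complex, build_helix,
)

REPO_ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
_STRUCTURE_CACHE: dict[str, StructureModel] = {}


def obtain_structure(accession: str) -> StructureModel:
    """Load a deposited crystal structure, from a local copy if present,
    otherwise from the public archive.  Fails the calling test when the
    structure cannot be obtained."""
    acc = accession.upper()
    if acc in _STRUCTURE_CACHE:
        return _STRUCTURE_CACHE[acc]
    for candidate in (
        os.path.join(REPO_ROOT, "data", "structures", f"{acc}.cif"),
        os.path.join(REPO_ROOT, "data", "structures", f"{acc}.pdb"),
        os.path.join(REPO_ROOT, "scratch", f"{acc}.cif"),
    ):
        if os.path.exists(candidate):
            model = read_structure(candidate)
            _STRUCTURE_CACHE[acc] = model
            return model
    url = f"https://files.rcsb.org/download/{acc}.cif"
    try:
        with urllib.request.urlopen(url, timeout=15) as resp:
            text = resp.read().decode()
    except Exception as exc:
        pytest.fail(
            f"deposited structure {acc} unavailable: no local copy under "
            f"data/structures/ and no network access ({exc})"
        )
    os.makedirs(os.path.join(REPO_ROOT, "scratch"), exist_ok=True)
    with open(os.path.join(REPO_ROOT, "scratch", f"{acc}.cif"), "w") as fh:
        fh.write(text)
    model = read_structure(text, fmt="mmCIF")
    _STRUCTURE_CACHE[acc] = model
    return model


@pytest.fixture(scope="session")
def gc_helix_a() -> StructureModel:
    """4-bp all-G:C A-form duplex."""
    return build_helix(HelixSpec("GCGC", form="A"))


@pytest.fixture(scope="session")
def mixed_helix_a() -> StructureModel:
    """8-bp mixed-sequence A-form RNA duplex."""
    return build_helix(HelixSpec("GAUCGAUC", form="A"))


@pytest.fixture(scope="session")
def helix_b() -> StructureModel:
    """8-bp B-form DNA duplex."""
    return build_helix(HelixSpec("ATGCATGC", form="B"))


@pytest.fixture(scope="session")
def strand_a8() -> StructureModel:
    """Single-stranded A-form 8-mer."""
    return build_helix(HelixSpec("GCGAUCGG", form="A", duplex=False))


@pytest.fixture(scope="session")
def toy_symmetric() -> StructureModel:
    return build_c2_complex(ToyComplexSpec(asymmetry="symmetric"))


@pytest.fixture(scope="session")
def toy_monomeric() -> StructureModel:
    return build_c2_complex(ToyComplexSpec(asymmetry="monomeric-L"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
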