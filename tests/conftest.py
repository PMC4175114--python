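"""Shared fixtures: toy peptides, random ensembles, synthetic clamp data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensemblemech.structure_io import ConformationalEnsemble, bead_metadata


def _peptide_metadata() -> pd.DataFrame:
    """Three-residue peptide with backbone, one side-chain carbon and hydrogens."""
    rows = []
    for res in (1, 2, 3):
        for name, elem in (
            ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
            ("CB", "C"), ("HA", "H"),
        ):
            rows.append(
                {
                    "atom_name": name,
                    "residue_name": "ALA",
                    "residue_number": res,
                    "insertion_code": "",
                    "chain_id": "A",
                    "element": elem,
                    "hetero": False,
                }
            )
    # one HETATM (cofactor-like) that selections must ignore
    rows.append(
        {
            "atom_name": "C1",
            "residue_name": "FAD",
            "residue_number": 900,
            "insertion_code": "",
            "chain_id": "A",
            "element": "C",
            "hetero": True,
        }
    )
    return pd.DataFrame(rows)


@pytest.fixture
def peptide_ensemble() -> ConformationalEnsemble:
    """2-frame toy peptide ensemble with deterministic coordinates."""
    meta = _peptide_metadata()
    rng = np.random.default_rng(7)
    coords = rng.normal(0.0, 5.0, size=(2, len(meta), 3))
    return ConformationalEnsemble(atoms=meta, coords=coords)


@pytest.fixture
def random_ensemble_factory():
    """Factory for small random bead ensembles (seeded)."""

    def make(n_frames: int = 4, n_atoms: int = 6, seed: int = 0, scale: float = 8.0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, scale, size=(n_frames, n_atoms, 3))
        return ConformationalEnsemble(atoms=bead_metadata(n_atoms), coords=coords)

    return make


@pytest.fixture
def random_rotation_factory():
    """Uniform random proper rotations via QR decomposition (seeded)."""

    def make(rng: np.random.Generator) -> np.ndarray:
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        return q

    return make
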