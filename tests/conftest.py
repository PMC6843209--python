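"""Shared fixtures: crafted PDB texts and small synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from enmfluct import StiffnessScheme, build_network
from enmfluct.structures import BeadModel
from enmfluct.synth import make_dumbbell, make_globule, make_helix


def make_pdb_text(
    method: str | None = "X-RAY DIFFRACTION",
    resolution: str | None = "1.80",
    seqres: bool = True,
    nres: int = 3,
    n_missing: int = 0,
    nonstandard: bool = False,
    nucleic_chain: bool = False,
) -> str:
    """Minimal single-chain PDB entry with controllable header defects."""
    names = ["ALA", "GLY", "SER", "LEU", "LYS"][:nres]
    if nonstandard:
        names[1] = "MSE"
    lines = ["HEADER    PROTEIN                                 01-JAN-00   1XYZ"]
    if method:
        lines.append(f"EXPDTA    {method}")
    if resolution:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution} ANGSTROMS.")
    if seqres:
        lines.append(f"SEQRES   1 A {nres:4d}  " + " ".join(names))
        if nucleic_chain:
            lines.append("SEQRES   1 B    3   DA  DC  DG")
    serial = 0
    for i, nm in enumerate(names[: nres - n_missing]):
        serial += 1
        lines.append(
            f"ATOM  {serial:5d}  CA  {nm:<3s} A{i + 1:4d}    "
            f"{3.8 * i:8.3f}{1.0 * i:8.3f}{0.5 * i:8.3f}  1.00 10.00           C"
        )
    lines.append("TER")
    if nucleic_chain:
        for i, nm in enumerate(["DA", "DC", "DG"]):
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  P   {nm:<3s} B{i + 1:4d}    "
                f"{20 + 3.8 * i:8.3f}{1.0 * i:8.3f}{0.5 * i:8.3f}  1.00 10.00           P"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_file(tmp_path):
    """Factory: write a crafted PDB text and return its path."""

    counter = {"n": 0}

    def _write(text: str):
        counter["n"] += 1
        path = tmp_path / f"fixture{counter['n']}.pdb"
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def globule30():
    return make_globule(30, seed=1)


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture
def dumbbell():
    return make_dumbbell()


@pytest.fixture(scope="session")
def globule30_net(globule30):
    return build_network(globule30, StiffnessScheme.anm(10.0))


def random_small_network(seed: int, n: int = 8):
    """Random connected network for derivative/spectral oracles."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1.8 * n ** (1 / 3), size=(n, 3)) * 3.0
    names = [sorted({"ALA", "GLY", "SER", "LEU", "LYS"})[k % 5] for k in range(n)]
    beads = BeadModel(
        coords=coords,
        residue_names=names,
        chain_ids=["A"] * n,
        seq_numbers=[str(k + 1) for k in range(n)],
        source_id=f"rand{seed}",
    )
    cutoff = 8.0
    net = build_network(beads, StiffnessScheme.anm(cutoff))
    # randomize stiffnesses so the oracle sees heterogeneous springs
    net.kappa = rng.uniform(0.2, 2.4, size=net.n_springs)
    return net
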