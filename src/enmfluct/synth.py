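"""Synthetic structures, stiffness tables, and mock experimental data.

These generators stand in for crystallographic/NMR input so the whole
pipeline — network construction, normal-mode analysis, scoring,
stratification — can be exercised without external files.  They emulate
the geometric features the analysis cares about: ~3.8 Å consecutive Cα
spacing, compact self-avoiding globules whose contact graph is connected
under a 10 Å cutoff, and structures with protruding low-connectivity
"tips" whose fluctuations elastic networks notoriously over-predict.

Every generator takes an explicit seed and owns its random generator; no
global random state is touched, so outputs are bit-reproducible.
"""

from __future__ import annotations

import itertools

import numpy as np

from .network import StiffnessScheme, StiffnessTable, build_network
from .nma import NMAParams, assemble_hessian, compute_msf, diagonalize
from .structures import STANDARD_AA, BeadModel

__all__ = [
    "make_helix",
    "make_chain",
    "make_dumbbell",
    "make_globule",
    "make_tip_structure",
    "make_stiffness_table",
    "make_synthetic_experiment",
]

_AA = sorted(STANDARD_AA)

#: Consecutive Cα spacing (Å) of a trans peptide chain.
CA_SPACING = 3.8
#: Minimum pairwise bead distance (Å) enforced in random globules.
MIN_SEPARATION = 3.5


def _residue_names(n: int, rng: np.random.Generator | None) -> list[str]:
    if rng is None:
        return [_AA[k % len(_AA)] for k in range(n)]
    return [str(a) for a in rng.choice(_AA, size=n)]


def _bead_model(coords: np.ndarray, names: list[str], source_id: str,
                tip_flags: np.ndarray | None = None) -> BeadModel:
    n = len(names)
    return BeadModel(
        coords=coords,
        residue_names=names,
        chain_ids=["A"] * n,
        seq_numbers=[str(k + 1) for k in range(n)],
        source_id=source_id,
        tip_flags=tip_flags,
    )


def make_helix(n: int) -> BeadModel:
    """Ideal α-helix Cα trace: 1.5 Å rise, 2.3 Å radius, 100°/residue."""
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    turn = np.deg2rad(100.0)
    t = np.arange(n)
    coords = np.column_stack(
        [2.3 * np.cos(turn * t), 2.3 * np.sin(turn * t), 1.5 * t]
    )
    return _bead_model(coords, _residue_names(n, None), f"helix{n}")


def make_chain(n: int) -> BeadModel:
    """Extended zig-zag chain (β-strand-like), 3.8 Å consecutive spacing."""
    if n < 2:
        raise ValueError("chain needs at least 2 residues")
    # planar zig-zag with 120° virtual angles, then a slight out-of-plane
    # twist so the geometry is generic (no accidental extra zero modes)
    step = CA_SPACING
    coords = np.zeros((n, 3))
    for k in range(1, n):
        direction = np.array([np.sqrt(3) / 2, 0.5 * (-1) ** k, 0.05 * np.sin(0.7 * k)])
        direction /= np.linalg.norm(direction)
        coords[k] = coords[k - 1] + step * direction
    return _bead_model(coords, _residue_names(n, None), f"chain{n}")


def make_dumbbell(separation: float = CA_SPACING) -> BeadModel:
    """Two beads on the x-axis — the minimal analytic test network."""
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return _bead_model(coords, ["GLY", "GLY"], "dumbbell")


def _connected_under_anm10(coords: np.ndarray) -> bool:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    pairs = cKDTree(coords).query_pairs(r=10.0, output_type="ndarray")
    if len(pairs) == 0:
        return coords.shape[0] == 1
    n = coords.shape[0]
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    return connected_components(adj, directed=False)[0] == 1


def make_globule(n: int, seed: int, max_attempts: int = 200) -> BeadModel:
    """Compact self-avoiding random cluster, connected under a 10 Å cutoff.

    Beads are placed sequentially inside a sphere whose radius scales as
    n^(1/3) at roughly protein-like packing, rejecting positions closer
    than 3.5 Å to any placed bead.  Deterministic under the seed.
    """
    if n < 5:
        raise ValueError("globule needs at least 5 residues")
    rng = np.random.default_rng(seed)
    radius = 1.75 * (n / 0.25) ** (1.0 / 3.0)
    for _attempt in range(max_attempts):
        coords = np.empty((n, 3))
        placed = 0
        tries = 0
        while placed < n and tries < 500 * n:
            tries += 1
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) > radius:
                continue
            if placed and np.min(np.linalg.norm(coords[:placed] - p, axis=1)) < MIN_SEPARATION:
                continue
            coords[placed] = p
            placed += 1
        if placed == n and _connected_under_anm10(coords):
            return _bead_model(coords, _residue_names(n, rng), f"globule{n}s{seed}")
    raise RuntimeError(f"could not place a connected {n}-bead globule in {max_attempts} attempts")


def make_tip_structure(n_core: int, n_tip: int, seed: int) -> BeadModel:
    """Globular core with a protruding helical tail ("tip").

    The tail extends outward from the most protruding surface bead as an
    ideal helical Cα trace (≈3.8 Å consecutive spacing), covalently
    continuous with the core chain, held by local springs plus whatever
    few long-range contacts reach it — exactly the sparse-connectivity
    situation in which elastic networks over-predict fluctuations.  Tip
    beads are flagged on the returned model.
    """
    if n_core < 20:
        raise ValueError("core needs at least 20 residues")
    if n_tip < 3:
        raise ValueError("tip needs at least 3 residues")
    core = make_globule(n_core, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_core, n_tip]))
    center = core.coords.mean(axis=0)
    surface = int(np.argmax(np.linalg.norm(core.coords - center, axis=1)))
    # chain continuity: make the attachment bead the last core residue
    order = [k for k in range(n_core) if k != surface] + [surface]
    coords = core.coords[order]
    names = [core.residue_names[k] for k in order]
    direction = coords[-1] - center
    direction /= np.linalg.norm(direction)
    # The tail is a helical Cα trace along the outward direction: a
    # perfectly straight pair-spring chain would bend at zero energy cost
    # (spurious mechanisms), whereas a helix is internally rigid yet still
    # protrudes with sparse long-range contacts.
    perp1 = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp1) < 1e-6:
        perp1 = np.cross(direction, [0.0, 1.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(direction, perp1)
    turn = np.deg2rad(100.0)
    base = coords[-1]
    tip_rows = [
        base
        + direction * (1.5 * k - 0.07)
        + 2.3 * (np.cos(turn * k) - 1.0) * perp1
        + 2.3 * np.sin(turn * k) * perp2
        for k in range(1, n_tip + 1)
    ]
    coords = np.vstack([coords, tip_rows])
    names += _residue_names(n_tip, rng)
    flags = np.zeros(n_core + n_tip, dtype=bool)
    flags[n_core:] = True
    return _bead_model(coords, names, f"tip{n_core}+{n_tip}s{seed}", tip_flags=flags)


def make_stiffness_table(mode: str, seed: int = 0) -> StiffnessTable:
    """Synthetic stiffness tables spanning the published heterogeneity.

    ``uniform``: every pair κ=1 (reproduces the homogeneous model
    exactly).  ``random_pairwise``: per-pair values log-uniform in
    [0.2, 2.4], i.e. about one order of magnitude of dispersion.
    ``soft_longrange``: distance-binned, κ=1 inside the classic 10 Å
    contact shell and κ=10⁻³ out to 16.5 Å, mimicking the
    distance-dependent scheme's combination of stiff short-range contacts
    with very soft far-range couplings.
    """
    pairs = list(itertools.combinations_with_replacement(_AA, 2))
    if mode == "uniform":
        return StiffnessTable({p: 1.0 for p in pairs}, distance_binned=False)
    if mode == "random_pairwise":
        rng = np.random.default_rng(seed)
        lo, hi = np.log(0.2), np.log(2.4)
        vals = np.exp(rng.uniform(lo, hi, size=len(pairs)))
        return StiffnessTable(dict(zip(pairs, vals)), distance_binned=False)
    if mode == "soft_longrange":
        bins = [(0.0, 10.0, 1.0), (10.0, 16.5, 1e-3)]
        return StiffnessTable({p: list(bins) for p in pairs}, distance_binned=True)
    raise ValueError(f"unknown table mode {mode!r}")


def make_synthetic_experiment(
    beads: BeadModel,
    reference_scheme: StiffnessScheme,
    noise_sigma: float,
    seed: int,
    params: NMAParams = NMAParams(),
) -> np.ndarray:
    """Mock experimental B-factors: reference-scheme prediction × noise.

    b_exp,i = b_pred,i · exp(σ ε_i) with ε_i i.i.d. standard normal —
    multiplicative log-normal noise keeps B-factors positive.  The
    reference network must be connected (exactly six vanishing modes).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    net = build_network(beads, reference_scheme)
    spectrum = diagonalize(assemble_hessian(net), params)
    if spectrum.n_zero != 6:
        raise ValueError(
            f"reference network has {spectrum.n_zero} vanishing modes; "
            "synthetic experiments need a connected, generic structure"
        )
    profile = compute_msf(spectrum, params)
    rng = np.random.default_rng(seed)
    noise = np.exp(noise_sigma * rng.standard_normal(beads.n_beads))
    return profile.b_pred * noise
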