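"""Normal-mode analysis of elastic networks: Hessian, spectrum, fluctuations.

The elastic energy is U = ½ Σ_{i<j} κ_ij (d_ij − d_ij⁰)², summed over the
springs of the network.  Expanding around equilibrium gives a 3N×3N
Hessian whose eigenvectors are the vibrational modes; a connected network
in generic position has exactly six zero modes (rigid translations and
rotations).  Mean-square fluctuations follow from the equipartition sum
over all non-trivial modes,

    MSF_i = (k_B T / m) Σ_k |a_i^(k)|² / ω_k²,

and predicted B-factors are B_i = (8π²/3)·MSF_i.  Since the stiffness
scale is arbitrary, predicted B-factors are usually rescaled so their mean
matches the experimental mean before per-residue comparison.

Units: with k_B T = m = 1 (the defaults) and stiffness in model units,
MSF comes out in Å² times the inverse stiffness scale; the rescaling step
absorbs that prefactor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .network import ElasticNetwork
from .structures import FilterVerdict

__all__ = [
    "BFACTOR_PER_MSF",
    "NMAParams",
    "ModeSpectrum",
    "FluctuationProfile",
    "energy",
    "assemble_hessian",
    "diagonalize",
    "reject_by_spectrum",
    "compute_msf",
    "rescale_to_experiment",
    "write_profile",
]

#: B = (8π²/3) · MSF
BFACTOR_PER_MSF = 8.0 * np.pi**2 / 3.0

#: Dense diagonalisation guard: refuse matrices beyond this dimension.
MAX_DENSE_DIM = 15000


@dataclasses.dataclass(frozen=True)
class NMAParams:
    """Thermal energy k_B T, uniform bead mass m, and zero-mode threshold.

    ``zero_tol`` is relative: eigenvalues below ``zero_tol · max(λ)`` are
    treated as vanishing (rigid-body or disconnected-part modes).
    """

    kBT: float = 1.0
    mass: float = 1.0
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.kBT <= 0 or self.mass <= 0:
            raise ValueError("kBT and mass must be positive")
        if not (0 < self.zero_tol < 1):
            raise ValueError("zero_tol must lie in (0, 1)")


@dataclasses.dataclass
class ModeSpectrum:
    """Eigen-decomposition of the (mass-scaled) Hessian.

    ``eigenvalues`` ascend and equal m·ω_k²; ``eigenvectors[:, k]`` is the
    3N displacement field of mode k, orthonormal.  ``n_zero`` counts the
    vanishing eigenvalues under the threshold used at diagonalisation.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    zero_tol: float

    @property
    def n_beads(self) -> int:
        return self.eigenvalues.shape[0] // 3


@dataclasses.dataclass
class FluctuationProfile:
    """Per-bead mean-square fluctuation and predicted B-factor (Å²)."""

    msf: np.ndarray
    b_pred: np.ndarray
    rescaled: bool = False
    scale_factor: float = 1.0


def energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Elastic energy of the network at the given bead coordinates.

    Exact (non-linearised) evaluation; serves as the differentiation
    oracle for the Hessian.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (network.n_beads, 3):
        raise ValueError("coords must match the network's bead count")
    vec = coords[network.j] - coords[network.i]
    d = np.linalg.norm(vec, axis=1)
    return float(0.5 * np.sum(network.kappa * (d - network.d0) ** 2))


def assemble_hessian(network: ElasticNetwork) -> np.ndarray:
    """Second-derivative matrix of the elastic energy at equilibrium.

    For each spring (i, j) the off-diagonal 3×3 block is −κ_ij ê⊗ê with ê
    the unit vector along the equilibrium bond; diagonal blocks accumulate
    the negated sum of the bead's off-diagonal blocks.  Accumulation is in
    double precision throughout (zero-mode detection depends on it).
    """
    n = network.n_beads
    coords = network.beads.coords
    hessian = np.zeros((3 * n, 3 * n), dtype=np.float64)
    vec = coords[network.j] - coords[network.i]
    dist = np.linalg.norm(vec, axis=1)
    if np.any(dist < 1e-9):
        bad = int(np.argmin(dist))
        raise ValueError(
            f"coincident beads {network.i[bad]} and {network.j[bad]}: "
            "spring direction undefined"
        )
    unit = vec / dist[:, None]
    for s in range(network.n_springs):
        i, j = int(network.i[s]), int(network.j[s])
        block = network.kappa[s] * np.outer(unit[s], unit[s])
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return hessian


def diagonalize(hessian: np.ndarray, params: NMAParams = NMAParams()) -> ModeSpectrum:
    """Full symmetric eigen-decomposition, ascending, with zero-mode count.

    With uniform mass the Hessian's eigenvalues are directly m·ω_k².
    Dense decomposition only — all non-trivial modes enter the MSF sum, so
    an iterative partial solver would not help.
    """
    hessian = np.asarray(hessian, dtype=np.float64)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if hessian.shape[0] > MAX_DENSE_DIM:
        raise ValueError(
            f"matrix dimension {hessian.shape[0]} exceeds the dense guard "
            f"({MAX_DENSE_DIM})"
        )
    scale = np.abs(hessian).max()
    if not np.allclose(hessian, hessian.T, atol=1e-10 * max(scale, 1.0)):
        raise ValueError("hessian must be symmetric")
    eigval, eigvec = scipy.linalg.eigh(hessian)
    top = float(eigval[-1])
    if top <= 0:
        raise ValueError("hessian has no positive eigenvalues")
    n_zero = int(np.sum(eigval < params.zero_tol * top))
    return ModeSpectrum(
        eigenvalues=eigval, eigenvectors=eigvec, n_zero=n_zero, zero_tol=params.zero_tol
    )


def reject_by_spectrum(spectrum: ModeSpectrum) -> FilterVerdict:
    """Survey acceptance on the spectrum: exactly six vanishing modes.

    More than six indicates loosely attached or disconnected network
    regions; fewer than six indicates a degenerate (e.g. collinear)
    geometry — both fail the criterion.
    """
    if spectrum.n_zero == 6:
        return FilterVerdict()
    notes = [f"{spectrum.n_zero} vanishing modes (expected 6)"]
    if spectrum.n_zero < 6:
        notes.append("degenerate geometry: fewer than six rigid-body modes")
    return FilterVerdict(reasons=["extra_zero_modes"], notes=notes)


def compute_msf(
    spectrum: ModeSpectrum,
    params: NMAParams = NMAParams(),
    allow_degenerate: bool = False,
) -> FluctuationProfile:
    """Mean-square fluctuations from the non-trivial modes.

    The sum runs over every mode whose eigenvalue clears the zero
    threshold (for a generic connected network: modes 7…3N).  Callers
    analysing degenerate toys (fewer or more than six vanishing modes)
    must opt in with ``allow_degenerate``.
    """
    if not allow_degenerate and spectrum.n_zero != 6:
        raise ValueError(
            f"spectrum has {spectrum.n_zero} vanishing modes; pass "
            "allow_degenerate=True to sum over the remaining modes anyway"
        )
    eigval = spectrum.eigenvalues
    top = float(eigval[-1])
    if top <= 0:
        raise ValueError("all eigenvalues vanish")
    keep = eigval >= spectrum.zero_tol * top
    if not np.any(keep):
        raise ValueError("no non-trivial modes above the zero threshold")
    n = spectrum.n_beads
    # |a_i^(k)|²: squared norm of bead i's 3-vector inside eigenvector k
    amp2 = spectrum.eigenvectors[:, keep].reshape(n, 3, -1) ** 2
    per_bead = amp2.sum(axis=1)  # (n, n_kept)
    # MSF_i = (kBT/m) Σ |a_i|²/ω² with λ = mω²  ⇒  kBT Σ |a_i|²/λ
    msf = params.kBT * (per_bead / eigval[keep]).sum(axis=1)
    return FluctuationProfile(msf=msf, b_pred=BFACTOR_PER_MSF * msf)


def rescale_to_experiment(profile: FluctuationProfile, b_exp: np.ndarray) -> FluctuationProfile:
    """Match the mean predicted B-factor to the experimental mean.

    The stiffness scale of an elastic network is arbitrary, so predictions
    are defined up to one multiplicative constant; this fixes it per
    structure.  Pearson correlation is unaffected.
    """
    b_exp = np.asarray(b_exp, dtype=float)
    if b_exp.shape != profile.b_pred.shape:
        raise ValueError("b_exp must have one value per bead")
    mean_pred = float(profile.b_pred.mean())
    mean_exp = float(b_exp.mean())
    if mean_pred <= 0 or mean_exp <= 0:
        raise ValueError("rescaling requires positive mean B-factors")
    factor = mean_exp / mean_pred
    return FluctuationProfile(
        msf=profile.msf * factor,
        b_pred=profile.b_pred * factor,
        rescaled=True,
        scale_factor=profile.scale_factor * factor,
    )


def write_profile(profile: FluctuationProfile, beads, path, b_exp=None) -> None:
    """Export per-bead MSF/B-factor predictions as TSV."""
    import pandas as pd

    data = {
        "bead": np.arange(len(profile.msf)),
        "chain": beads.chain_ids,
        "seq_number": beads.seq_numbers,
        "msf": profile.msf,
        "b_pred": profile.b_pred,
    }
    if b_exp is None and beads.b_exp is not None:
        b_exp = beads.b_exp
    if b_exp is not None:
        data["b_exp"] = np.asarray(b_exp, dtype=float)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")
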