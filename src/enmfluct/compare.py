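"""Score fluctuation predictions against experiment and stratify errors.

Agreement with crystallographic B-factors is scored by the Pearson
correlation coefficient between predicted and experimental profiles.
Per-residue errors are absolute MSF deviations after mean-matched
rescaling.  For NMR input, the positional spread across the superposed
conformer ensemble replaces the crystallographic B-factor as the
experimental fluctuation index.  Errors can be stratified by relative
network connectivity, residue chemistry (hydrophobic / polar / charged)
and secondary structure (helix / sheet / unstructured).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .data import chemical_classes
from .nma import BFACTOR_PER_MSF
from .structures import BeadModel, SecondaryStructureRange, StructureEnsemble, _split_label

__all__ = [
    "CHEM_CLASSES",
    "SS_CLASSES",
    "ResidueRecord",
    "pearson_correlation",
    "bfactor_to_msf",
    "msf_to_bfactor",
    "prediction_error",
    "superpose_ensemble",
    "ensemble_msf",
    "classify_chemical",
    "classify_secondary",
    "stratify",
    "records_to_frame",
]

CHEM_CLASSES = ("hydrophobic", "polar", "charged")
SS_CLASSES = ("helix", "sheet", "unstructured")

#: Fixed record-table column order for TSV export.
RECORD_COLUMNS = (
    "source_id", "scheme", "bead", "chain", "seq_number", "residue_name",
    "relative_connectivity", "abs_error", "chem_class", "ss_class",
)


@dataclasses.dataclass(frozen=True)
class ResidueRecord:
    """One survey row: a residue bead's prediction error and its strata."""

    source_id: str
    scheme: str
    bead: int
    chain: str
    seq_number: str
    residue_name: str
    relative_connectivity: float
    abs_error: float
    chem_class: str
    ss_class: str


def records_to_frame(records) -> pd.DataFrame:
    """List of :class:`ResidueRecord` → DataFrame with the fixed columns."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(RECORD_COLUMNS))


def pearson_correlation(b_pred: np.ndarray, b_exp: np.ndarray) -> float:
    """Pearson correlation coefficient between two per-bead profiles.

    Direct evaluation of the product-moment formula; both inputs must
    have at least three entries and nonzero variance.
    """
    x = np.asarray(b_pred, dtype=float)
    y = np.asarray(b_exp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least three beads")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.sum(dx * dy) / (sx * sy))


def bfactor_to_msf(b: np.ndarray) -> np.ndarray:
    """Invert B = (8π²/3)·MSF; negative B-factors are rejected."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative B-factor")
    return b / BFACTOR_PER_MSF


def msf_to_bfactor(msf: np.ndarray) -> np.ndarray:
    msf = np.asarray(msf, dtype=float)
    if np.any(msf < 0):
        raise ValueError("negative MSF")
    return BFACTOR_PER_MSF * msf


def prediction_error(msf_pred_rescaled: np.ndarray, msf_exp: np.ndarray) -> np.ndarray:
    """Per-bead |MSF_pred − MSF_exp| (inputs on a common, rescaled scale)."""
    a = np.asarray(msf_pred_rescaled, dtype=float)
    b = np.asarray(msf_exp, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return np.abs(a - b)


def _kabsch(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid-body fit of ``moving`` onto ``reference`` (uniform weights)."""
    mc = moving.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, moving - mc)
    return rot.apply(moving - mc) + rc


def superpose_ensemble(ensemble: StructureEnsemble) -> StructureEnsemble:
    """Least-squares superpose every conformer onto the first one.

    Uses all Cα beads with uniform weights; superposition is a rigid
    motion, so each conformer's internal distances are untouched.  A
    collinear reference leaves the rotation underdetermined and raises.
    """
    if ensemble.n_models < 2:
        raise ValueError("superposition needs at least two models")
    ref = ensemble.models[0].coords
    sv = np.linalg.svd(ref - ref.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("reference conformer is (nearly) collinear")
    fitted = [ensemble.models[0]]
    for m in ensemble.models[1:]:
        fitted.append(dataclasses.replace(m, coords=_kabsch(m.coords, ref)))
    return StructureEnsemble(fitted)


def ensemble_msf(aligned: StructureEnsemble) -> np.ndarray:
    """Per-bead MSF from conformer scatter: mean |R_i^(m) − ⟨R_i⟩|².

    The ensemble must already be superposed so rigid-body differences do
    not masquerade as internal fluctuations.
    """
    if aligned.n_models < 2:
        raise ValueError("ensemble MSF needs at least two models")
    stack = aligned.coordinate_stack()
    dev = stack - stack.mean(axis=0, keepdims=True)
    return np.mean(np.sum(dev**2, axis=2), axis=0)


def classify_chemical(residue_name: str) -> str:
    """Three-way chemical class from the bundled decision table."""
    table = chemical_classes()
    try:
        return table[residue_name]
    except KeyError:
        raise KeyError(f"no chemical class for residue {residue_name!r}") from None


def _geometric_ss(coords: np.ndarray) -> list[str]:
    """Cα-only secondary-structure assignment from short-range distances.

    Heuristic on i→i+2 / i→i+3 virtual distances: an α-helix turn keeps
    them near 5.4/5.1 Å, an extended strand stretches them to ~6.7/10 Å.
    Deliberately coarse — meant for Cα-only fixtures without header
    annotations, not as a DSSP replacement.
    """
    n = coords.shape[0]
    labels = ["unstructured"] * n
    for i in range(n):
        if i + 3 >= n:
            continue
        d13 = np.linalg.norm(coords[i + 2] - coords[i])
        d14 = np.linalg.norm(coords[i + 3] - coords[i])
        if 4.6 <= d13 <= 6.1 and 4.5 <= d14 <= 6.5:
            for k in range(i, i + 4):
                labels[k] = "helix"
        elif d13 >= 6.2 and d14 >= 9.0:
            for k in range(i, i + 4):
                if labels[k] == "unstructured":
                    labels[k] = "sheet"
    return labels


def classify_secondary(
    model: BeadModel,
    annotations: list[SecondaryStructureRange] | None = None,
    geometric_fallback: bool = False,
) -> list[str]:
    """Per-bead helix/sheet/unstructured labels.

    Deposited helix/sheet ranges take precedence; any residue outside them
    is unstructured.  An annotation range that matches no bead triggers a
    warning (its residues stay unstructured).  With no annotations and
    ``geometric_fallback`` enabled, a coarse Cα-geometry assignment is
    used instead.
    """
    labels = ["unstructured"] * model.n_beads
    if annotations:
        numeric = [_split_label(s)[0] for s in model.seq_numbers]
        for rng in annotations:
            hit = False
            for idx in range(model.n_beads):
                if model.chain_ids[idx] == rng.chain_id and rng.start <= numeric[idx] <= rng.end:
                    labels[idx] = rng.kind
                    hit = True
            if not hit:
                warnings.warn(
                    f"{rng.kind} range {rng.chain_id}:{rng.start}-{rng.end} "
                    "matches no resolved residue",
                    stacklevel=2,
                )
        return labels
    if geometric_fallback:
        return _geometric_ss(model.coords)
    return labels


def stratify(records, key: str, connectivity_bin_width: float = 0.05) -> pd.DataFrame:
    """Group residue records and average the absolute MSF error.

    ``key`` is one of ``connectivity`` (fixed-width bins on (0, 1]),
    ``chem_class``, ``ss_class`` or ``scheme``.  Returns a table with
    group label, mean_abs_error and count; counts sum to the number of
    records.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to stratify")
    if key == "connectivity":
        w = connectivity_bin_width
        if not (0 < w <= 1):
            raise ValueError("bin width must lie in (0, 1]")
        n_bins = int(np.ceil(1.0 / w - 1e-12))
        edges = np.minimum(np.arange(n_bins + 1) * w, 1.0)
        edges[-1] = 1.0
        # half-open (lo, hi] bins so the maximum-connectivity bead lands in the top bin
        idx = np.clip(
            np.digitize(df["relative_connectivity"], edges, right=True) - 1, 0, n_bins - 1
        )
        group = pd.Series(
            [f"({edges[k]:.2f},{edges[k + 1]:.2f}]" for k in idx], index=df.index
        )
        order = {f"({edges[k]:.2f},{edges[k + 1]:.2f}]": k for k in range(len(edges) - 1)}
        grouped = df.groupby(group, sort=False)
        out = grouped["abs_error"].agg(mean_abs_error="mean", count="count").reset_index(names="group")
        out["bin_low"] = [edges[order[g]] for g in out["group"]]
        return out.sort_values("bin_low").drop(columns="bin_low").reset_index(drop=True)
    if key not in ("chem_class", "ss_class", "scheme"):
        raise ValueError(f"unknown stratification key {key!r}")
    grouped = df.groupby(key, sort=True)
    return grouped["abs_error"].agg(mean_abs_error="mean", count="count").reset_index(names="group")
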