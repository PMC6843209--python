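"""Read protein structures into Cα bead models and screen entries.

A bead model is the coarse-grained representation used throughout the
package: one bead per amino-acid residue, placed at the Cα position of the
deposited coordinates (the crystallographic asymmetric unit, model 1 for
multi-model files).  Experimental B-factors, residue identities, chain
labels and author residue numbers travel with the beads.

Entry screening mirrors the survey protocol for crystallographic input:
X-ray entries only, resolution 2.0 Å or better, protein-only polymers,
no missing or nonstandard residues.  A further criterion — exactly six
vanishing normal modes — is evaluated by :mod:`enmfluct.nma` after the
elastic network has been built, and uses the same verdict type.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "STANDARD_AA",
    "BeadModel",
    "StructureEnsemble",
    "StructureMetadata",
    "FilterVerdict",
    "SecondaryStructureRange",
    "read_structure",
    "read_ensemble",
    "read_metadata",
    "read_secondary_structure",
    "apply_entry_filters",
    "write_bead_pdb",
    "write_bead_table",
    "read_bead_table",
]

#: The twenty standard amino acids (three-letter codes).
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Canonical order of rejection codes, so verdicts compare reproducibly.
_REASON_ORDER = (
    "not_xray",
    "resolution",
    "nucleic_acid",
    "missing_residues",
    "nonstandard_residue",
    "extra_zero_modes",
)


@dataclasses.dataclass
class BeadModel:
    """Cα bead representation of one conformer.

    coords are in Å; ``b_exp`` carries experimental B-factors (Å²) when the
    source provides them.  ``seq_numbers`` are author residue numbers kept
    as strings so insertion codes stay part of the bead identity
    (e.g. ``"52"``, ``"52A"``).
    """

    coords: np.ndarray
    residue_names: list[str]
    chain_ids: list[str]
    seq_numbers: list[str]
    b_exp: np.ndarray | None = None
    source_id: str = ""
    tip_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("bead model needs at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        for name, seq in (
            ("residue_names", self.residue_names),
            ("chain_ids", self.chain_ids),
            ("seq_numbers", self.seq_numbers),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} must have length {n}")
        if self.b_exp is not None:
            self.b_exp = np.asarray(self.b_exp, dtype=float)
            if self.b_exp.shape != (n,):
                raise ValueError("b_exp must be one value per bead")

    @property
    def n_beads(self) -> int:
        return int(self.coords.shape[0])

    def annotation(self) -> tuple[tuple[str, str, str], ...]:
        """Hashable per-bead identity (chain, seq number, residue name)."""
        return tuple(zip(self.chain_ids, self.seq_numbers, self.residue_names))


@dataclasses.dataclass
class StructureEnsemble:
    """Ordered conformer set (e.g. NMR models) sharing bead annotation."""

    models: list[BeadModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0].annotation()
        for k, m in enumerate(self.models[1:], start=2):
            if m.annotation() != ref:
                raise ValueError(
                    f"model {k} residue annotation differs from model 1"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_beads(self) -> int:
        return self.models[0].n_beads

    def coordinate_stack(self) -> np.ndarray:
        """(n_models, n_beads, 3) coordinate array."""
        return np.stack([m.coords for m in self.models])


@dataclasses.dataclass
class StructureMetadata:
    """Header facts needed by the entry filters."""

    source_id: str = ""
    experiment_method: str | None = None
    resolution: float | None = None
    has_nucleic_acid: bool = False
    has_seqres: bool = False
    seqres_lengths: dict[str, int] = dataclasses.field(default_factory=dict)
    resolved_lengths: dict[str, int] = dataclasses.field(default_factory=dict)
    seqres_residue_names: frozenset[str] = frozenset()


@dataclasses.dataclass
class FilterVerdict:
    """Outcome of entry screening; ``accepted`` iff no reason recorded."""

    reasons: list[str] = dataclasses.field(default_factory=list)
    notes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.reasons = sorted(set(self.reasons), key=_REASON_ORDER.index)

    @property
    def accepted(self) -> bool:
        return not self.reasons

    def merged_with(self, other: "FilterVerdict") -> "FilterVerdict":
        return FilterVerdict(self.reasons + other.reasons, self.notes + other.notes)


@dataclasses.dataclass(frozen=True)
class SecondaryStructureRange:
    """One deposited helix/sheet annotation: inclusive residue range."""

    kind: str  # "helix" or "sheet"
    chain_id: str
    start: int
    end: int


def _seq_label(seqid: gemmi.SeqId) -> str:
    icode = seqid.icode.strip()
    return f"{seqid.num}{icode}" if icode else str(seqid.num)


def _is_amino(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return res.name in STANDARD_AA


def _pick_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA among alternate locations (ties: first seen)."""
    best = None
    for atom in res:
        if atom.name != "CA" or atom.element != gemmi.Element("C"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def _model_to_beads(model: gemmi.Model, source_id: str) -> BeadModel:
    coords, names, chains, seqs, bvals = [], [], [], [], []
    for chain in model:
        for res in chain:
            if not _is_amino(res):
                continue  # waters, ligands, nucleotides: not part of the network
            ca = _pick_ca(res)
            if ca is None:
                raise ValueError(
                    f"residue {res.name} {chain.name}{_seq_label(res.seqid)} "
                    f"in {source_id or 'structure'} has no CA atom"
                )
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            names.append(res.name)
            chains.append(chain.name)
            seqs.append(_seq_label(res.seqid))
            bvals.append(ca.b_iso)
    if not coords:
        raise ValueError(f"no amino-acid residues found in {source_id or 'structure'}")
    return BeadModel(
        coords=np.array(coords, dtype=float),
        residue_names=names,
        chain_ids=chains,
        seq_numbers=seqs,
        b_exp=np.array(bvals, dtype=float),
        source_id=source_id,
    )


def _read_gemmi(path: str | Path, fmt: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path} contains no coordinate models")
    st.setup_entities()
    return st


def read_structure(path: str | Path, format: str = "auto") -> BeadModel:
    """Read one conformer (model 1) from a PDB/mmCIF file as a bead model.

    All chains of the deposited coordinates are retained in file order;
    waters, ligands and other non-amino-acid residues are ignored.  An
    amino-acid residue without a Cα record raises ``ValueError`` naming
    the residue.
    """
    st = _read_gemmi(path, format)
    source_id = st.name or Path(path).stem
    return _model_to_beads(st[0], source_id)


def read_ensemble(path: str | Path, format: str = "auto") -> StructureEnsemble:
    """Read every MODEL block of a multi-model file as a conformer ensemble.

    Residue annotation must be identical across models; a model with
    different residue content raises ``ValueError``.
    """
    st = _read_gemmi(path, format)
    source_id = st.name or Path(path).stem
    models = [_model_to_beads(m, source_id) for m in st]
    return StructureEnsemble(models)


def read_metadata(path: str | Path, format: str = "auto") -> StructureMetadata:
    """Extract the header facts the entry filters need."""
    st = _read_gemmi(path, format)
    info = dict(st.info)
    method = info.get("_exptl.method") or None
    resolution = st.resolution if st.resolution > 0 else None

    has_na = False
    has_seqres = False
    seqres_lengths: dict[str, int] = {}
    seqres_names: set[str] = set()
    nucleic = (
        gemmi.PolymerType.Dna,
        gemmi.PolymerType.Rna,
        gemmi.PolymerType.DnaRnaHybrid,
        gemmi.PolymerType.Pna,
    )
    peptide = (gemmi.PolymerType.PeptideL, gemmi.PolymerType.PeptideD)
    for ent in st.entities:
        if ent.entity_type != gemmi.EntityType.Polymer:
            continue
        if ent.polymer_type in nucleic:
            has_na = True
        if ent.polymer_type not in peptide:
            continue  # sequence checks apply to protein chains only
        if ent.full_sequence:
            has_seqres = True
            seq = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
            seqres_names.update(seq)
            for sub in ent.subchains:
                seqres_lengths[sub] = len(seq)

    resolved: dict[str, int] = {}
    for chain in st[0]:
        for res in chain:
            if _is_amino(res):
                resolved[res.subchain] = resolved.get(res.subchain, 0) + 1
    return StructureMetadata(
        source_id=st.name or Path(path).stem,
        experiment_method=method,
        resolution=resolution,
        has_nucleic_acid=has_na,
        has_seqres=has_seqres,
        seqres_lengths=seqres_lengths,
        resolved_lengths=resolved,
        seqres_residue_names=frozenset(seqres_names),
    )


def read_secondary_structure(path: str | Path, format: str = "auto") -> list[SecondaryStructureRange]:
    """Deposited HELIX/SHEET annotations as inclusive residue ranges."""
    st = _read_gemmi(path, format)
    ranges: list[SecondaryStructureRange] = []
    for h in st.helices:
        ranges.append(
            SecondaryStructureRange(
                "helix", h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num
            )
        )
    for sheet in st.sheets:
        for strand in sheet.strands:
            ranges.append(
                SecondaryStructureRange(
                    "sheet",
                    strand.start.chain_name,
                    strand.start.res_id.seqid.num,
                    strand.end.res_id.seqid.num,
                )
            )
    return ranges


def apply_entry_filters(metadata: StructureMetadata, model: BeadModel) -> FilterVerdict:
    """Screen an entry for the crystallographic survey.

    Accepts only X-ray entries at resolution ≤ 2.0 Å whose polymers are
    protein-only, fully resolved (sequence record vs. resolved residues)
    and built from the twenty standard amino acids.  Missing header fields
    yield the corresponding rejection code rather than an error; a missing
    sequence record makes the completeness criterion unevaluable and is
    reported as ``missing_residues`` with an explanatory note.
    """
    reasons: list[str] = []
    notes: list[str] = []

    method = (metadata.experiment_method or "").upper()
    if "X-RAY" not in method:
        reasons.append("not_xray")
        if not metadata.experiment_method:
            notes.append("experiment method missing from header")
    if metadata.resolution is None:
        reasons.append("resolution")
        notes.append("resolution missing from header")
    elif metadata.resolution > 2.0:
        reasons.append("resolution")
    if metadata.has_nucleic_acid:
        reasons.append("nucleic_acid")

    if not metadata.has_seqres:
        reasons.append("missing_residues")
        notes.append("no sequence record: completeness not evaluable")
    else:
        for sub, n_seq in metadata.seqres_lengths.items():
            if metadata.resolved_lengths.get(sub, 0) < n_seq:
                reasons.append("missing_residues")
                break

    nonstandard = set(model.residue_names) - STANDARD_AA
    nonstandard |= metadata.seqres_residue_names - STANDARD_AA
    if nonstandard:
        reasons.append("nonstandard_residue")
        notes.append("nonstandard residues: " + ",".join(sorted(nonstandard)))

    return FilterVerdict(reasons=reasons, notes=notes)


# ---------------------------------------------------------------------------
# fixture-grade writers


def _split_label(label: str) -> tuple[int, str]:
    digits = label.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    return int(digits), label[len(digits):]


def _format_atom_line(serial: int, res: str, chain: str, label: str, xyz: Sequence[float], b: float) -> str:
    num, icode = _split_label(label)
    return (
        f"ATOM  {serial:5d}  CA  {res:<3s} {chain[:1]}{num:4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}           C"
    )


def write_bead_pdb(obj: BeadModel | StructureEnsemble, path: str | Path) -> None:
    """Write a minimal Cα-only PDB file (fixture format).

    Experimental B-factors go to the B column (0 where absent).  An
    ensemble is written as MODEL/ENDMDL blocks.
    """
    models = obj.models if isinstance(obj, StructureEnsemble) else [obj]
    multi = len(models) > 1
    lines: list[str] = []
    for k, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        b = m.b_exp if m.b_exp is not None else np.zeros(m.n_beads)
        serial = 0
        prev_chain = None
        for i in range(m.n_beads):
            if prev_chain is not None and m.chain_ids[i] != prev_chain:
                lines.append("TER")
            prev_chain = m.chain_ids[i]
            serial += 1
            lines.append(
                _format_atom_line(
                    serial, m.residue_names[i], m.chain_ids[i], m.seq_numbers[i],
                    m.coords[i], float(b[i]),
                )
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_TABLE_COLS = ("source_id", "chain", "seq_number", "residue_name", "x", "y", "z", "b_exp")


def write_bead_table(model: BeadModel, path: str | Path) -> None:
    """Write the bead model as a TSV table (one row per bead)."""
    import pandas as pd

    b = model.b_exp if model.b_exp is not None else np.full(model.n_beads, np.nan)
    df = pd.DataFrame(
        {
            "source_id": model.source_id,
            "chain": model.chain_ids,
            "seq_number": model.seq_numbers,
            "residue_name": model.residue_names,
            "x": model.coords[:, 0],
            "y": model.coords[:, 1],
            "z": model.coords[:, 2],
            "b_exp": b,
        },
        columns=list(_TABLE_COLS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_bead_table(path: str | Path) -> BeadModel:
    """Read a TSV bead table written by :func:`write_bead_table`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"seq_number": str, "chain": str})
    missing = set(_TABLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"bead table missing columns: {sorted(missing)}")
    b = df["b_exp"].to_numpy(dtype=float)
    return BeadModel(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        residue_names=df["residue_name"].tolist(),
        chain_ids=df["chain"].tolist(),
        seq_numbers=df["seq_number"].tolist(),
        b_exp=None if np.all(np.isnan(b)) else b,
        source_id=str(df["source_id"].iloc[0]),
    )
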