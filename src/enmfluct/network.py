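"""Elastic-network construction with homogeneous or residue-specific springs.

Beads interact through harmonic springs with natural length equal to their
equilibrium (Cα–Cα) distance.  Three stiffness schemes are supported:

* ``anm`` — the conventional anisotropic network model: uniform stiffness κ
  for every pair closer than a cutoff distance l_c.
* ``sanm`` — sequence-specific stiffness: κ depends on the amino-acid
  identities of the pair (a symmetric 20×20 table), still gated by a
  cutoff; sequence-adjacent backbone pairs get a strong fixed constant.
* ``sdanm`` — sequence- and distance-dependent stiffness: κ additionally
  depends on the equilibrium pair distance (piecewise-constant distance
  bins), with a hard interaction radius of 16.5 Å and a very stiff
  backbone constant.

The contact rule is strict: a pair interacts iff its equilibrium distance
is strictly below the cutoff/radius.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structures import STANDARD_AA, BeadModel

__all__ = [
    "SDANM_RADIUS",
    "StiffnessTable",
    "StiffnessScheme",
    "ElasticNetwork",
    "ConnectivityProfile",
    "load_stiffness_table",
    "stiffness",
    "build_network",
    "connectivity",
    "backbone_adjacent_pairs",
    "write_edge_list",
]

#: Hard interaction radius (Å) of the distance-dependent scheme: pairs
#: farther apart than this have zero interaction strength.
SDANM_RADIUS = 16.5

#: Cα–Cα distance (Å) up to which consecutive residues of a chain are
#: treated as covalently linked backbone neighbours.
BACKBONE_MAX_DIST = 4.2


def _pair_key(aa1: str, aa2: str) -> tuple[str, str]:
    return (aa1, aa2) if aa1 <= aa2 else (aa2, aa1)


class StiffnessTable:
    """Symmetric per-pair stiffness lookup, optionally distance-binned.

    ``entries`` maps an ordered amino-acid pair to either a plain stiffness
    (pairwise dialect) or a list of ``(d_lo, d_hi, kappa)`` bins covering
    half-open intervals ``[d_lo, d_hi)`` (distance-binned dialect).
    """

    def __init__(self, entries: dict, distance_binned: bool):
        self.distance_binned = bool(distance_binned)
        self.entries: dict[tuple[str, str], object] = {}
        problems: list[str] = []
        for key, value in entries.items():
            aa1, aa2 = key
            for aa in (aa1, aa2):
                if aa not in STANDARD_AA:
                    problems.append(f"unknown amino-acid code {aa!r}")
            k = _pair_key(aa1, aa2)
            if self.distance_binned:
                bins = sorted(value, key=lambda b: b[0])
                for lo, hi, kap in bins:
                    if kap < 0:
                        problems.append(f"negative stiffness for {k} in [{lo},{hi})")
                    if hi <= lo:
                        problems.append(f"empty distance bin [{lo},{hi}) for {k}")
                for (lo1, hi1, _), (lo2, _hi2, _k2) in zip(bins, bins[1:]):
                    if lo2 < hi1:
                        problems.append(
                            f"overlapping distance bins for {k}: [{lo1},{hi1}) and [{lo2},{_hi2})"
                        )
                if k in self.entries:
                    problems.append(f"duplicate pair {k}")
                self.entries[k] = bins
            else:
                if value < 0:
                    problems.append(f"negative stiffness for {k}")
                if k in self.entries and self.entries[k] != value:
                    problems.append(f"conflicting duplicate pair {k}")
                self.entries[k] = float(value)
        if problems:
            raise ValueError("invalid stiffness table:\n  " + "\n  ".join(problems))

    def lookup(self, aa1: str, aa2: str, d0: float | None = None) -> float:
        key = _pair_key(aa1, aa2)
        try:
            value = self.entries[key]
        except KeyError:
            raise KeyError(f"pair {key} absent from stiffness table") from None
        if not self.distance_binned:
            return value  # type: ignore[return-value]
        if d0 is None:
            raise ValueError("distance-binned table requires a distance")
        for lo, hi, kap in value:  # type: ignore[union-attr]
            if lo <= d0 < hi:
                return float(kap)
        raise KeyError(f"no distance bin covers d0={d0} for pair {key}")

    def pairs(self) -> Iterable[tuple[str, str]]:
        return self.entries.keys()


def load_stiffness_table(path: str | Path, dialect: str) -> StiffnessTable:
    """Load a stiffness table from TSV.

    ``pairwise`` dialect has columns ``aa1 aa2 kappa``; ``distance_binned``
    has ``aa1 aa2 d_lo d_hi kappa`` with half-open bins.  Validation
    problems (unknown codes, overlapping bins, negative values) are
    aggregated into a single error.
    """
    import pandas as pd

    if dialect not in ("pairwise", "distance_binned"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if dialect == "pairwise":
        need = {"aa1", "aa2", "kappa"}
        if not need <= set(df.columns):
            raise ValueError(f"pairwise table needs columns {sorted(need)}")
        entries: dict = {}
        for row in df.itertuples(index=False):
            entries.setdefault(_pair_key(row.aa1, row.aa2), float(row.kappa))
            if entries[_pair_key(row.aa1, row.aa2)] != float(row.kappa):
                raise ValueError(f"conflicting rows for pair {(row.aa1, row.aa2)}")
        return StiffnessTable(entries, distance_binned=False)
    need = {"aa1", "aa2", "d_lo", "d_hi", "kappa"}
    if not need <= set(df.columns):
        raise ValueError(f"distance_binned table needs columns {sorted(need)}")
    grouped: dict[tuple[str, str], list] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault(_pair_key(row.aa1, row.aa2), []).append(
            (float(row.d_lo), float(row.d_hi), float(row.kappa))
        )
    return StiffnessTable(grouped, distance_binned=True)


@dataclasses.dataclass
class StiffnessScheme:
    """Stiffness rule: scheme kind, cutoff, and parameter table.

    For ``anm`` only ``uniform_kappa`` and ``cutoff`` matter.  For ``sanm``
    the table is pairwise and ``backbone_kappa`` overrides sequence-adjacent
    pairs (the published parameterisation uses 10).  For ``sdanm`` the table
    is distance-binned, the cutoff is the 16.5 Å interaction radius and the
    backbone constant is 43.52.
    """

    kind: str
    cutoff: float
    uniform_kappa: float = 1.0
    table: StiffnessTable | None = None
    backbone_kappa: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("anm", "sanm", "sdanm", "custom"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.kind == "anm" and self.uniform_kappa <= 0:
            raise ValueError("uniform_kappa must be positive for anm")
        if self.kind != "anm" and self.table is None:
            raise ValueError(f"{self.kind} scheme requires a stiffness table")
        if not self.name:
            self.name = self.kind + (f"{self.cutoff:g}" if self.kind != "sdanm" else "")

    @classmethod
    def anm(cls, cutoff: float, kappa: float = 1.0) -> "StiffnessScheme":
        return cls(kind="anm", cutoff=cutoff, uniform_kappa=kappa)

    @classmethod
    def sanm(cls, cutoff: float, table: StiffnessTable, backbone_kappa: float = 10.0) -> "StiffnessScheme":
        return cls(kind="sanm", cutoff=cutoff, table=table, backbone_kappa=backbone_kappa)

    @classmethod
    def sdanm(cls, table: StiffnessTable, backbone_kappa: float = 43.52,
              radius: float = SDANM_RADIUS) -> "StiffnessScheme":
        return cls(kind="sdanm", cutoff=radius, table=table, backbone_kappa=backbone_kappa)


def stiffness(scheme: StiffnessScheme, aa_i: str, aa_j: str, d0: float,
              backbone_adjacent: bool = False) -> float:
    """Spring stiffness for one residue pair at equilibrium distance d0 (Å).

    Pairs at or beyond the cutoff get zero.  For the sequence-specific
    schemes a backbone-adjacent pair always gets the backbone constant;
    a pair absent from the table is an error, never a silent default.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    for aa in (aa_i, aa_j):
        if aa not in STANDARD_AA:
            raise KeyError(f"unknown residue code {aa!r}")
    if scheme.kind == "anm":
        return scheme.uniform_kappa if d0 < scheme.cutoff else 0.0
    if backbone_adjacent and scheme.backbone_kappa is not None:
        return scheme.backbone_kappa
    if d0 >= scheme.cutoff:
        return 0.0
    assert scheme.table is not None
    if scheme.table.distance_binned:
        return scheme.table.lookup(aa_i, aa_j, d0)
    return scheme.table.lookup(aa_i, aa_j)


@dataclasses.dataclass
class ElasticNetwork:
    """Bead model plus springs under one stiffness scheme.

    Spring arrays are parallel: ``(i, j)`` with i < j, natural length d0
    (Å), stiffness κ > 0, and a backbone flag.  Zero-stiffness pairs are
    omitted.
    """

    beads: BeadModel
    i: np.ndarray
    j: np.ndarray
    d0: np.ndarray
    kappa: np.ndarray
    is_backbone: np.ndarray
    scheme: StiffnessScheme

    @property
    def n_springs(self) -> int:
        return int(self.i.shape[0])

    @property
    def n_beads(self) -> int:
        return self.beads.n_beads


def backbone_adjacent_pairs(beads: BeadModel) -> set[tuple[int, int]]:
    """Bead pairs treated as covalent backbone neighbours.

    Consecutive beads of the same chain whose author numbering is
    consecutive (insertion-code successors count) and whose Cα–Cα
    distance does not exceed 4.2 Å; larger gaps are chain breaks.
    """
    from .structures import _split_label

    pairs: set[tuple[int, int]] = set()
    for i in range(beads.n_beads - 1):
        j = i + 1
        if beads.chain_ids[i] != beads.chain_ids[j]:
            continue
        ni, ici = _split_label(beads.seq_numbers[i])
        nj, icj = _split_label(beads.seq_numbers[j])
        if not (nj - ni == 1 or (nj == ni and ici != icj)):
            continue
        if np.linalg.norm(beads.coords[j] - beads.coords[i]) > BACKBONE_MAX_DIST:
            continue
        pairs.add((i, j))
    return pairs


def build_network(beads: BeadModel, scheme: StiffnessScheme) -> ElasticNetwork:
    """Enumerate all springs with nonzero stiffness under the scheme."""
    if beads.n_beads < 2:
        raise ValueError("need at least two beads to build a network")
    coords = beads.coords
    tree = cKDTree(coords)
    candidate = tree.query_pairs(r=scheme.cutoff, output_type="ndarray")
    backbone = backbone_adjacent_pairs(beads)
    # backbone pairs carry the override regardless of the cutoff
    all_pairs = {tuple(sorted(p)) for p in candidate.tolist()} | backbone

    ii, jj, dd, kk, bb = [], [], [], [], []
    names = beads.residue_names
    for i, j in sorted(all_pairs):
        d = float(np.linalg.norm(coords[j] - coords[i]))
        is_bb = (i, j) in backbone
        k = stiffness(scheme, names[i], names[j], d, backbone_adjacent=is_bb)
        if k > 0.0:
            ii.append(i); jj.append(j); dd.append(d); kk.append(k); bb.append(is_bb)
    return ElasticNetwork(
        beads=beads,
        i=np.array(ii, dtype=int),
        j=np.array(jj, dtype=int),
        d0=np.array(dd, dtype=float),
        kappa=np.array(kk, dtype=float),
        is_backbone=np.array(bb, dtype=bool),
        scheme=scheme,
    )


@dataclasses.dataclass
class ConnectivityProfile:
    """Per-bead contact degree and its ratio to the network maximum."""

    degree: np.ndarray
    relative: np.ndarray


def connectivity(network: ElasticNetwork) -> ConnectivityProfile:
    """Contact degree D_i (springs incident to each bead) and D_i / max D.

    The interaction radius of the scheme sets which pairs count, so the
    same structure yields different profiles under different schemes.
    """
    if network.n_springs == 0:
        raise ValueError("network has no springs")
    degree = np.zeros(network.n_beads, dtype=int)
    np.add.at(degree, network.i, 1)
    np.add.at(degree, network.j, 1)
    return ConnectivityProfile(degree=degree, relative=degree / degree.max())


def write_edge_list(network: ElasticNetwork, path: str | Path) -> None:
    """Export the springs as a TSV edge list (i, j, d0, kappa, is_backbone)."""
    import pandas as pd

    pd.DataFrame(
        {
            "i": network.i,
            "j": network.j,
            "d0": network.d0,
            "kappa": network.kappa,
            "is_backbone": network.is_backbone.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
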