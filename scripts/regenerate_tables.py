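"""Regenerate the bundled synthetic stiffness tables.

The sequence-specific table assigns each residue type a stiffness factor
g(a) = exp(alpha + beta * KD(a)) from its Kyte-Doolittle hydropathy KD and
sets kappa(a, b) = clip(g(a) * g(b), 0.226, 2.348).  alpha and beta are
solved so that the two published anchor pairs come out exactly:
glycine-glycine 0.226 (the softest printed pair) and isoleucine-valine
2.348 (the stiffest printed pair).  The distance-binned table multiplies
the pairwise value by a decaying distance profile and floors the far
range at the published softness 1e-3, ending at the 16.5 A interaction
radius.  Deterministic; run from the repository root:

    python scripts/regenerate_tables.py
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "enmfluct" / "data"

KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

K_MIN, K_MAX = 0.226, 2.348

# Distance profile for the binned dialect: stiff short contacts, very soft
# long range, zero beyond 16.5 A (expressed by the table simply ending).
BINS = [(0.0, 5.5, 3.0), (5.5, 8.0, 1.0), (8.0, 11.0, 0.3),
        (11.0, 14.0, 0.03), (14.0, 16.5, None)]  # None -> hard floor 1e-3
K_FLOOR = 1e-3


def solve_factors() -> dict[str, float]:
    # 2*(alpha + beta*KD_GLY) = ln K_MIN ; (alpha+beta*KD_ILE)+(alpha+beta*KD_VAL) = ln K_MAX
    kg, ki, kv = KD["GLY"], KD["ILE"], KD["VAL"]
    a = [[2.0, 2.0 * kg], [2.0, ki + kv]]
    b = [math.log(K_MIN), math.log(K_MAX)]
    det = a[0][0] * a[1][1] - a[0][1] * a[1][0]
    alpha = (b[0] * a[1][1] - a[0][1] * b[1]) / det
    beta = (a[0][0] * b[1] - b[0] * a[1][0]) / det
    return {aa: math.exp(alpha + beta * kd) for aa, kd in KD.items()}


def main() -> None:
    g = solve_factors()
    aas = sorted(KD)
    pair_kappa = {}
    for a, b in itertools.combinations_with_replacement(aas, 2):
        k = min(max(g[a] * g[b], K_MIN), K_MAX)
        pair_kappa[(a, b)] = round(k, 3)
    assert pair_kappa[("GLY", "GLY")] == 0.226
    assert pair_kappa[("ILE", "VAL")] == 2.348

    lines = ["aa1\taa2\tkappa"]
    for (a, b), k in sorted(pair_kappa.items()):
        lines.append(f"{a}\t{b}\t{k:g}")
    (OUT / "sanm_stiffness_synthetic.tsv").write_text("\n".join(lines) + "\n")

    lines = ["aa1\taa2\td_lo\td_hi\tkappa"]
    for (a, b), k in sorted(pair_kappa.items()):
        for lo, hi, mult in BINS:
            kap = K_FLOOR if mult is None else max(round(k * mult, 4), K_FLOOR)
            lines.append(f"{a}\t{b}\t{lo:g}\t{hi:g}\t{kap:g}")
    (OUT / "sdanm_stiffness_synthetic.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {len(pair_kappa)} pairs to {OUT}")


if __name__ == "__main__":
    main()
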