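"""Generate the synthetic structure set used by the downstream analyses.

Writes Cα-only PDB files plus bead tables under results/fixtures/:
ten compact globules and three tip structures, each carrying mock
experimental B-factors (reference-scheme prediction times log-normal
noise), and one noise-free multi-model ensemble stand-in for NMR input.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np

from enmfluct.pipeline import resolve_scheme
from enmfluct.structures import StructureEnsemble, write_bead_pdb, write_bead_table
from enmfluct.synth import make_globule, make_synthetic_experiment, make_tip_structure

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    truth = resolve_scheme("anm13")
    for k in range(10):
        g = make_globule(40, seed=SEED + k)
        g = dataclasses.replace(
            g, b_exp=make_synthetic_experiment(g, truth, 0.2, seed=SEED + 100 + k)
        )
        write_bead_pdb(g, OUT / f"globule_{k:02d}.pdb")
        write_bead_table(g, OUT / f"globule_{k:02d}.tsv")

    for k in range(3):
        t = make_tip_structure(40, 8, seed=SEED + k)
        b = make_synthetic_experiment(t, resolve_scheme("anm10"), 0.0, seed=SEED + k)
        b[t.tip_flags] = np.median(b[~t.tip_flags])  # damped-tip "truth"
        t = dataclasses.replace(t, b_exp=b)
        write_bead_pdb(t, OUT / f"tip_{k:02d}.pdb")
        write_bead_table(t, OUT / f"tip_{k:02d}.tsv")
        np.savetxt(OUT / f"tip_{k:02d}.flags.tsv", t.tip_flags.astype(int), fmt="%d")

    base = make_globule(30, seed=SEED + 50)
    models = [
        dataclasses.replace(
            base, coords=base.coords + 0.4 * rng.standard_normal(base.coords.shape)
        )
        for _ in range(12)
    ]
    write_bead_pdb(StructureEnsemble(models), OUT / "ensemble.pdb")

    print(f"wrote 10 globules, 3 tip structures and a 12-model ensemble to {OUT}")


if __name__ == "__main__":
    main()
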