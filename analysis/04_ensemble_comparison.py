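"""Score schemes against conformational variability of a model ensemble.

For multi-model input (the NMR situation) the experimental fluctuation
index is not a B-factor but the positional spread of each residue across
the superposed conformers.  This driver reads the synthetic 12-model
ensemble fixture, superposes it onto model 1, derives the per-residue
ensemble MSF, and scores all six schemes against it (networks are built
on model 1).

Run 01_make_fixtures.py first.
"""

from pathlib import Path

from enmfluct.compare import ensemble_msf, superpose_ensemble
from enmfluct.pipeline import SurveyConfig, run_single
from enmfluct.structures import read_ensemble

ROOT = Path(__file__).resolve().parents[1] / "results"
SCHEMES = ["anm10", "anm13", "anm16", "sanm10", "sanm13", "sdanm"]


def main() -> None:
    path = ROOT / "fixtures" / "ensemble.pdb"
    if not path.exists():
        raise SystemExit("no ensemble fixture - run 01_make_fixtures.py first")
    ens = read_ensemble(path)
    aligned = superpose_ensemble(ens)
    msf_exp = ensemble_msf(aligned)
    print(f"{ens.n_models} models, {ens.n_beads} residues; "
          f"ensemble MSF range {msf_exp.min():.3f}-{msf_exp.max():.3f} Å²")

    report = run_single(ens.models[0], SurveyConfig(schemes=SCHEMES), msf_exp=msf_exp)
    table = report.pcc_table()
    out = ROOT / "ensemble_comparison"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "pcc_vs_ensemble.tsv", sep="\t", index=False, float_format="%.4f")
    print(table.to_string(index=False))
    print("note: the fixture's conformer scatter is isotropic noise, so the "
          "correlations quantify method plumbing, not model quality")


if __name__ == "__main__":
    main()
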