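"""Scoring, ensemble fluctuations, classification, stratification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from enmfluct.compare import (
    ResidueRecord,
    bfactor_to_msf,
    classify_chemical,
    classify_secondary,
    ensemble_msf,
    msf_to_bfactor,
    pearson_correlation,
    prediction_error,
    records_to_frame,
    stratify,
    superpose_ensemble,
)
from enmfluct.nma import BFACTOR_PER_MSF
from enmfluct.structures import SecondaryStructureRange, StructureEnsemble
from enmfluct.synth import make_chain, make_globule, make_helix


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_correlation(x, -x + 7.0) == pytest.approx(-1.0)

    def test_textbook_value(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 5.0])
        # frozen from the product-moment formula: 7.25/√(8.75·6.75)
        assert pearson_correlation(x, y) == pytest.approx(0.9433700705169156, rel=1e-12)
        assert pearson_correlation(x, y) == pytest.approx(pearsonr(x, y).statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(5), np.arange(5.0))

    @settings(max_examples=40, derandomize=True)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=999),
    )
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        assert pearson_correlation(c * x, y) == pytest.approx(pearson_correlation(x, y), rel=1e-9)


class TestBfactorConversion:
    def test_inversion_identity(self):
        assert bfactor_to_msf(np.array([BFACTOR_PER_MSF]))[0] == pytest.approx(1.0)
        assert bfactor_to_msf(np.array([0.0]))[0] == 0.0

    def test_round_trip(self):
        msf = np.linspace(0.0, 4.0, 9)
        assert np.allclose(bfactor_to_msf(msf_to_bfactor(msf)), msf, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_msf(np.array([-1.0]))


class TestPredictionError:
    def test_elementwise_abs_difference(self):
        assert prediction_error([1.0, 2.0], [2.0, 2.0]).tolist() == [1.0, 0.0]
        assert np.all(prediction_error([1.0, 2.0], [1.0, 2.0]) == 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            prediction_error([1.0], [1.0, 2.0])


def _rigidly_moved(model, angles, shift):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", angles, degrees=True)
    return dataclasses.replace(model, coords=rot.apply(model.coords) + np.asarray(shift))


def _horn_quaternion_fit(moving, reference):
    """Independent rigid-fit oracle: Horn's closed-form quaternion method."""
    mc = moving - moving.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(k)
    q = v[:, -1]  # w, x, y, z
    w0, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w0), 2 * (x * z + y * w0)],
            [2 * (x * y + z * w0), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w0)],
            [2 * (x * z - y * w0), 2 * (y * z + x * w0), 1 - 2 * (x * x + y * y)],
        ]
    )
    fitted = mc @ rot.T + reference.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1)))


class TestSuperposition:
    def test_removes_rigid_motion_exactly(self):
        g = make_globule(20, seed=5)
        moved = _rigidly_moved(g, [30, -60, 110], [4.0, -2.0, 9.0])
        ens = superpose_ensemble(StructureEnsemble([g, moved]))
        assert np.allclose(ens.models[1].coords, g.coords, atol=1e-8)

    def test_identical_models_unchanged(self):
        g = make_globule(20, seed=5)
        ens = superpose_ensemble(StructureEnsemble([g, dataclasses.replace(g)]))
        assert np.allclose(ens.models[1].coords, g.coords, atol=1e-10)

    def test_preserves_internal_distances(self):
        g = make_globule(20, seed=5)
        other = dataclasses.replace(
            g, coords=g.coords + 0.4 * np.random.default_rng(3).standard_normal(g.coords.shape)
        )
        moved = _rigidly_moved(other, [15, 25, 35], [1.0, 2.0, 3.0])
        ens = superpose_ensemble(StructureEnsemble([g, moved]))
        d_before = np.linalg.norm(moved.coords[:, None] - moved.coords[None], axis=2)
        d_after = np.linalg.norm(
            ens.models[1].coords[:, None] - ens.models[1].coords[None], axis=2
        )
        assert np.allclose(d_before, d_after, atol=1e-8)

    def test_matches_quaternion_oracle(self):
        g = make_globule(25, seed=9)
        rng = np.random.default_rng(4)
        other = dataclasses.replace(
            g, coords=g.coords + 0.8 * rng.standard_normal(g.coords.shape)
        )
        moved = _rigidly_moved(other, [40, 10, -70], [3.0, 3.0, 3.0])
        ens = superpose_ensemble(StructureEnsemble([g, moved]))
        rmsd = np.sqrt(np.mean(np.sum((ens.models[1].coords - g.coords) ** 2, axis=1)))
        assert rmsd == pytest.approx(_horn_quaternion_fit(moved.coords, g.coords), abs=1e-8)

    def test_collinear_reference_rejected(self):
        from enmfluct.structures import BeadModel

        line = BeadModel(
            coords=np.outer(np.arange(5.0), [3.8, 0.0, 0.0]),
            residue_names=["ALA"] * 5,
            chain_ids=["A"] * 5,
            seq_numbers=[str(k + 1) for k in range(5)],
        )
        ens = StructureEnsemble([line, dataclasses.replace(line)])
        with pytest.raises(ValueError, match="collinear"):
            superpose_ensemble(ens)


class TestEnsembleMSF:
    def test_identical_models_give_zero(self):
        g = make_globule(15, seed=2)
        ens = StructureEnsemble([g, dataclasses.replace(g)])
        assert np.allclose(ensemble_msf(ens), 0.0)

    def test_single_displaced_bead(self):
        g = make_globule(15, seed=2)
        coords2 = g.coords.copy()
        coords2[4] += [2.0, 0.0, 0.0]
        ens = StructureEnsemble([g, dataclasses.replace(g, coords=coords2)])
        msf = ensemble_msf(ens)  # superposition deliberately skipped
        assert msf[4] == pytest.approx(1.0)
        mask = np.ones(15, dtype=bool)
        mask[4] = False
        assert np.allclose(msf[mask], 0.0)

    def test_gaussian_ensemble_converges_to_3_sigma_sq(self):
        g = make_globule(12, seed=8)
        sigma = 0.5
        rng = np.random.default_rng(123)
        models = [
            dataclasses.replace(g, coords=g.coords + sigma * rng.standard_normal(g.coords.shape))
            for _ in range(2000)
        ]
        msf = ensemble_msf(StructureEnsemble(models))
        assert np.allclose(msf, 3 * sigma**2, rtol=0.05)

    def test_invariant_under_common_rigid_motion(self):
        g = make_globule(15, seed=2)
        rng = np.random.default_rng(6)
        models = [
            dataclasses.replace(g, coords=g.coords + 0.3 * rng.standard_normal(g.coords.shape))
            for _ in range(5)
        ]
        base = ensemble_msf(superpose_ensemble(StructureEnsemble(models)))
        moved = [_rigidly_moved(m, [25, 50, 75], [1.0, -8.0, 2.0]) for m in models]
        shifted = ensemble_msf(superpose_ensemble(StructureEnsemble(moved)))
        assert np.allclose(shifted, base, atol=1e-8)


class TestClassification:
    @pytest.mark.parametrize(
        "residue, expected",
        [("LEU", "hydrophobic"), ("GLY", "hydrophobic"), ("SER", "polar"),
         ("HIS", "polar"), ("LYS", "charged"), ("ASP", "charged")],
    )
    def test_chemical_classes(self, residue, expected):
        assert classify_chemical(residue) == expected

    def test_all_twenty_covered(self):
        from enmfluct.structures import STANDARD_AA

        for aa in STANDARD_AA:
            assert classify_chemical(aa) in ("hydrophobic", "polar", "charged")

    def test_nonstandard_rejected(self):
        with pytest.raises(KeyError):
            classify_chemical("MSE")

    def test_annotated_ranges(self, helix12):
        ann = [
            SecondaryStructureRange("helix", "A", 2, 5),
            SecondaryStructureRange("sheet", "A", 10, 12),
        ]
        labels = classify_secondary(helix12, ann)
        assert labels[0] == "unstructured"
        assert labels[1:5] == ["helix"] * 4
        assert labels[9:12] == ["sheet"] * 3

    def test_dangling_range_warns(self, helix12):
        ann = [SecondaryStructureRange("helix", "B", 1, 4)]
        with pytest.warns(UserWarning, match="matches no resolved residue"):
            labels = classify_secondary(helix12, ann)
        assert set(labels) == {"unstructured"}

    def test_geometric_fallback_recognises_helix(self):
        helix = make_helix(20)
        labels = classify_secondary(helix, geometric_fallback=True)
        assert labels.count("helix") >= 16

    def test_geometric_fallback_extended_chain_not_helix(self):
        chain = make_chain(20)
        labels = classify_secondary(chain, geometric_fallback=True)
        assert labels.count("helix") == 0


def _random_records(n, seed):
    rng = np.random.default_rng(seed)
    chem = ["hydrophobic", "polar", "charged"]
    ss = ["helix", "sheet", "unstructured"]
    return [
        ResidueRecord(
            source_id="synth", scheme="anm10", bead=k, chain="A", seq_number=str(k),
            residue_name="ALA", relative_connectivity=float(rng.uniform(0.01, 1.0)),
            abs_error=float(rng.exponential(0.5)),
            chem_class=chem[rng.integers(3)], ss_class=ss[rng.integers(3)],
        )
        for k in range(n)
    ]


class TestStratify:
    def test_single_group_mean(self):
        records = _random_records(50, seed=1)
        out = stratify(records, "scheme")
        assert len(out) == 1
        expected = np.mean([r.abs_error for r in records])
        assert out["mean_abs_error"].iloc[0] == pytest.approx(expected)
        assert out["count"].iloc[0] == 50

    def test_two_groups_exact_means(self):
        recs = _random_records(4, seed=0)
        recs = [
            dataclasses.replace(r, chem_class=c, abs_error=e)
            for r, c, e in zip(recs, ["polar", "polar", "charged", "charged"], [1.0, 1.0, 3.0, 3.0])
        ]
        out = stratify(recs, "chem_class").set_index("group")
        assert out.loc["charged", "mean_abs_error"] == pytest.approx(3.0)
        assert out.loc["polar", "mean_abs_error"] == pytest.approx(1.0)

    @pytest.mark.parametrize("key", ["chem_class", "ss_class", "connectivity"])
    def test_matches_brute_force_regrouping(self, key):
        records = _random_records(300, seed=42)
        out = stratify(records, key, connectivity_bin_width=0.1)
        # independent group-by: dict accumulation over raw records
        groups = {}
        for r in records:
            if key == "connectivity":
                k = min(int(np.ceil(r.relative_connectivity / 0.1)) - 1, 9)
                k = max(k, 0)
                label = f"({k * 0.1:.2f},{(k + 1) * 0.1:.2f}]"
            else:
                label = getattr(r, key)
            groups.setdefault(label, []).append(r.abs_error)
        assert set(out["group"]) == set(groups)
        for _, row in out.iterrows():
            assert row["mean_abs_error"] == pytest.approx(np.mean(groups[row["group"]]))
            assert row["count"] == len(groups[row["group"]])

    def test_counts_conserved_and_means_recombine(self):
        records = _random_records(200, seed=7)
        out = stratify(records, "connectivity", connectivity_bin_width=0.05)
        assert out["count"].sum() == 200
        global_mean = records_to_frame(records)["abs_error"].mean()
        weighted = (out["mean_abs_error"] * out["count"]).sum() / out["count"].sum()
        assert weighted == pytest.approx(global_mean, abs=1e-10)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            stratify(pd.DataFrame(), "chem_class")
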