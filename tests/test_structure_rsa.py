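"""Solvent-accessibility module: sphere-sampling SASA, RSA normalization,
template transfer."""

import math

import numpy as np
import pandas as pd
import pytest

from resevol.structure_rsa import (
    AtomSet,
    NormalizationTable,
    RawSASAProfile,
    compute_sasa,
    normalize_rsa,
    read_pdb,
    sphere_points,
    transfer_rsa,
    _profile_frame,
)


def shell_points(n, radius):
    return radius * sphere_points(n)


class TestComputeSasa:
    def test_isolated_atom_has_full_sphere_area(self):
        atoms = AtomSet(["C"], [1], ["A"], [[0.0, 0.0, 0.0]])
        prof = compute_sasa(atoms, probe_radius=1.4, n_points=960)
        expected = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert prof.data["value"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_fully_enclosed_atom_is_buried(self):
        shell = shell_points(80, 2.0)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        atoms = AtomSet(
            ["C"] * len(coords),
            [1] + [2] * len(shell),
            ["A"] * len(coords),
            coords,
            radii=np.array([1.7] + [2.5] * len(shell)),
        )
        prof = compute_sasa(atoms, probe_radius=1.4)
        buried = prof.data.set_index("residue_index").loc[1, "value"]
        assert buried == 0.0

    def test_diatomic_matches_spherical_cap_formula(self):
        d = 2.0
        atoms = AtomSet(["C", "C"], [1, 2], ["A", "A"], [[0, 0, 0], [d, 0, 0]])
        prof = compute_sasa(atoms, probe_radius=1.4, n_points=2000)
        R = 1.7 + 1.4
        # analytic: each sphere loses the cap inside the other sphere
        h = R - (d * d + R * R - R * R) / (2 * d)
        expected = 4 * math.pi * R * R - 2 * math.pi * R * h
        for value in prof.data["value"]:
            assert value == pytest.approx(expected, rel=0.02)

    def test_unknown_element_raises_with_name(self):
        with pytest.raises(ValueError, match="Zz"):
            AtomSet(["Zz"], [1], ["A"], [[0, 0, 0]])

    def test_empty_structure_raises(self):
        atoms = AtomSet([], [], [], np.zeros((0, 3)), radii=np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            compute_sasa(atoms)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=2.5, size=(10, 3))
        atoms = AtomSet(["C"] * 10, list(range(1, 11)), ["A"] * 10, coords)
        a = compute_sasa(atoms, n_points=480).data["value"].to_numpy()
        b = compute_sasa(atoms, n_points=960).data["value"].to_numpy()
        scale = max(b.max(), 1.0)
        assert np.all(np.abs(a - b) / scale < 0.02)

    def test_matches_independent_sphere_sampling_reference(self):
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(3)
        n = 8
        coords = rng.normal(scale=2.0, size=(n, 3))
        atoms = AtomSet(["C"] * n, list(range(1, n + 1)), ["A"] * n, coords)
        mine = compute_sasa(atoms, probe_radius=1.4, n_points=960)
        arr = biotite_structure.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.res_name = np.array(["ALA"] * n)
        arr.atom_name = np.array(["CA"] * n)
        ref = biotite_structure.sasa(
            arr, probe_radius=1.4, point_number=1000, vdw_radii=np.full(n, 1.7)
        )
        assert np.allclose(mine.data["value"].to_numpy(), ref, rtol=0.05, atol=1.0)


class TestNormalizeRsa:
    @staticmethod
    def raw(values, types):
        return RawSASAProfile(
            _profile_frame(np.arange(1, len(values) + 1), types, values)
        )

    def test_definition_cases(self):
        table = NormalizationTable({"A": 100.0})
        prof = self.raw([100.0, 0.0, 55.0], ["A", "A", "A"])
        rsa = normalize_rsa(prof, table)
        assert list(rsa.data["value"]) == [100.0, 0.0, 55.0]

    def test_outliers_capped_at_100(self):
        table = NormalizationTable({"A": 100.0})
        with pytest.warns(UserWarning, match="capped 1"):
            rsa = normalize_rsa(self.raw([120.0], ["A"]), table)
        assert rsa.data["value"].iloc[0] == 100.0
        assert rsa.metadata["n_capped"] == 1

    def test_missing_residue_type_raises(self):
        table = NormalizationTable({"A": 100.0})
        with pytest.raises(ValueError, match="'K'"):
            normalize_rsa(self.raw([10.0], ["K"]), table)

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(ValueError):
            NormalizationTable({"A": 0.0})

    def test_rsa_is_scale_free(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 150, size=20)
        types = rng.choice(list("ACDE"), size=20)
        table = {t: rng.uniform(80, 160) for t in "ACDE"}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = normalize_rsa(self.raw(values, types), NormalizationTable(table))
            scaled = normalize_rsa(
                self.raw(values * 7.3, types),
                NormalizationTable({k: v * 7.3 for k, v in table.items()}),
            )
        assert np.allclose(base.data["value"], scaled.data["value"])

    def test_empirical_percentile_table(self):
        prof = self.raw(np.linspace(0, 100, 101), ["A"] * 101)
        table = NormalizationTable.from_profiles([prof], percentile=99)
        assert table.denominators["A"] == pytest.approx(99.0)


class TestTransferRsa:
    def test_identity_map_preserves_values(self, rsa_profile_factory):
        template = rsa_profile_factory([10.0, 20.0, 30.0])
        mapping = pd.DataFrame({"template_index": [1, 2, 3], "target_index": [1, 2, 3]})
        out = transfer_rsa(template, mapping)
        assert np.allclose(out.values, [10.0, 20.0, 30.0])

    def test_gapped_position_is_missing_not_zero(self, rsa_profile_factory):
        template = rsa_profile_factory([10.0, 20.0, 30.0])
        mapping = pd.DataFrame({"template_index": [1, 3], "target_index": [1, 3]})
        out = transfer_rsa(template, mapping, target_length=3)
        assert np.isnan(out.values[1])
        assert out.values[1] != 0.0  # NaN, not a burial signal
        assert np.allclose(out.values[[0, 2]], [10.0, 30.0])

    def test_partial_coverage_count(self, rsa_profile_factory):
        template = rsa_profile_factory(np.linspace(0, 90, 10))
        mapped = [1, 2, 3, 4, 5, 6, 7]  # 70% of a 10-residue target
        mapping = pd.DataFrame({"template_index": mapped, "target_index": mapped})
        out = transfer_rsa(template, mapping, target_length=10)
        assert np.sum(~np.isnan(out.values)) == 7

    def test_never_invents_values(self, rsa_profile_factory):
        rng = np.random.default_rng(5)
        template_vals = rng.uniform(0, 100, 12)
        template = rsa_profile_factory(template_vals)
        tmpl_idx = rng.choice(np.arange(1, 13), size=8, replace=False)
        targ_idx = rng.choice(np.arange(1, 16), size=8, replace=False)
        mapping = pd.DataFrame({"template_index": tmpl_idx, "target_index": targ_idx})
        out = transfer_rsa(template, mapping, target_length=15)
        observed = out.values[~np.isnan(out.values)]
        pool = list(np.round(template_vals, 9))
        for v in np.round(observed, 9):
            assert v in pool
            pool.remove(v)

    def test_unknown_template_position_raises(self, rsa_profile_factory):
        template = rsa_profile_factory([10.0, 20.0])
        mapping = pd.DataFrame({"template_index": [5], "target_index": [1]})
        with pytest.raises(ValueError, match="absent"):
            transfer_rsa(template, mapping)

    def test_non_injective_map_rejected(self, rsa_profile_factory):
        template = rsa_profile_factory([10.0, 20.0])
        mapping = pd.DataFrame({"template_index": [1, 2], "target_index": [1, 1]})
        with pytest.raises(ValueError, match="injective"):
            transfer_rsa(template, mapping)


PDB_SNIPPET = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  H   ALA A   1      12.050   6.933  -4.810  1.00  0.00           H
ATOM      4  N   GLY A   2      10.720   4.910  -3.345  1.00  0.00           N
ATOM      5  CA  GLY A   2      10.228   4.629  -1.993  1.00  0.00           C
HETATM    6  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
END
"""


def test_read_pdb_drops_hydrogens_and_hetatms(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(PDB_SNIPPET)
    atoms = read_pdb(path, chain="A")
    assert len(atoms) == 4  # H and water dropped
    assert set(atoms.elements) == {"N", "C"}
    assert list(atoms.residue_index) == [1, 1, 2, 2]
    assert list(atoms.residue_type) == ["A", "A", "G", "G"]
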