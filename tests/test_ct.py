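"""Loewdin fragment populations and the charge-transfer descriptor."""

import numpy as np
import pandas as pd
import pytest

from medoidspec import synthetic as syn
from medoidspec.ct import (
    OmegaMatrix,
    TransitionDensity,
    characterize_states,
    load_transition_density,
    omega_ct,
    omega_matrix,
    read_map_tsv,
    read_matrix,
    sym_sqrt,
    write_matrix,
)


def random_spd(rng, n, floor=0.3):
    r = rng.normal(size=(n, n))
    w, v = np.linalg.eigh((r + r.T) / 2)
    return (v * np.maximum(w, floor)) @ v.T


class TestSymSqrt:
    def test_identity(self):
        assert np.array_equal(sym_sqrt(np.eye(4)), np.eye(4))

    def test_diagonal(self):
        d = np.diag([4.0, 9.0, 0.25])
        assert np.allclose(sym_sqrt(d), np.diag([2.0, 3.0, 0.5]))

    def test_random_spd_reconstruction(self, rng):
        s = random_spd(rng, 8)
        half = sym_sqrt(s)
        err = np.linalg.norm(half @ half - s) / np.linalg.norm(s)
        assert err < 1e-8

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sym_sqrt(np.diag([1.0, -0.5]))

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            sym_sqrt(rng.normal(size=(3, 3)))


def make_td(d, s, frag_sizes, names=None):
    frag_idx = np.concatenate([np.full(sz, i) for i, sz in enumerate(frag_sizes)])
    names = names or [chr(ord("A") + i) for i in range(len(frag_sizes))]
    return TransitionDensity(
        D=d, S_ov=s, basis_to_atom=frag_idx,
        atom_to_fragment={i: names[i] for i in range(len(frag_sizes))},
    )


class TestOmegaMatrix:
    def test_single_entry_identity_overlap(self):
        d = np.zeros((4, 4))
        d[0, 2] = 0.7  # hole in fragment A (rows 0-1), electron in B (cols 2-3)
        om = omega_matrix(make_td(d, np.eye(4), [2, 2]))
        assert om.values[0, 1] == pytest.approx(0.49)
        assert om.total() == pytest.approx(0.49)

    def test_total_equals_frobenius_norm_identity(self, rng):
        d = rng.normal(size=(6, 6))
        s = random_spd(rng, 6)
        om = omega_matrix(make_td(d, s, [2, 2, 2]))
        half = sym_sqrt(s)
        assert om.total() == pytest.approx(np.linalg.norm(half @ d @ half) ** 2, abs=1e-10)

    def test_matches_brute_force_oracle_battery(self):
        for seed in range(50):
            td, expected = syn.make_transition_density(
                10, [4, 3, 3], ct_weight=0.02 * seed, seed=seed
            )
            om = omega_matrix(td)
            assert np.abs(om.values - expected.values).max() < 1e-10

    def test_unassigned_basis_function_rejected(self):
        td = make_td(np.eye(4), np.eye(4), [2, 2])
        del td.atom_to_fragment[1]
        with pytest.raises(ValueError, match="no fragment"):
            omega_matrix(td)

    def test_fragment_permutation_invariance(self, rng):
        # permuting basis functions within fragments leaves Omega unchanged
        d = rng.normal(size=(6, 6))
        td = make_td(d, np.eye(6), [3, 3])
        om = omega_matrix(td)
        perm = np.array([2, 0, 1, 5, 3, 4])  # within-fragment cycles
        q = np.eye(6)[perm]
        td2 = make_td(q @ d @ q.T, np.eye(6), [3, 3])
        assert np.abs(omega_matrix(td2).values - om.values).max() < 1e-10


class TestOmegaCT:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            # complete two-fragment tabulations of a published CT-dimer analysis
            ({("E", "E"): 0.031, ("E", "N"): 0.001, ("N", "E"): 0.943, ("N", "N"): 0.025}, 0.944),
            ({("E", "E"): 0.031, ("E", "N"): 0.001, ("N", "E"): 0.938, ("N", "N"): 0.030}, 0.939),
            ({("E", "E"): 0.016, ("E", "N"): 0.000, ("N", "E"): 0.965, ("N", "N"): 0.018}, 0.966),
            ({("E", "E"): 0.018, ("E", "N"): 0.000, ("N", "E"): 0.963, ("N", "N"): 0.018}, 0.964),
        ],
    )
    def test_published_two_fragment_rows(self, entries, expected):
        assert omega_ct(entries) == pytest.approx(expected, abs=0.002)

    def test_pure_limits(self):
        diag = OmegaMatrix(["A", "B"], np.diag([0.6, 0.4]))
        assert omega_ct(diag) == 0.0
        off = OmegaMatrix(["A", "B"], np.array([[0.0, 0.7], [0.3, 0.0]]))
        assert omega_ct(off) == 1.0

    def test_bounds_on_random_instances(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 1, size=(3, 3))
            w = omega_ct(OmegaMatrix(["A", "B", "C"], vals))
            assert 0.0 <= w <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            omega_ct(OmegaMatrix(["A", "B"], np.zeros((2, 2))))


class TestCharacterizeStates:
    def omega_records(self):
        rows = [
            (1, 1, "E", "E", 0.014), (1, 1, "E", "N", 0.000),
            (1, 1, "N", "E", 0.968), (1, 1, "N", "N", 0.018),
            (1, 2, "E", "E", 0.90), (1, 2, "E", "N", 0.02),
            (1, 2, "N", "E", 0.03), (1, 2, "N", "N", 0.05),
        ]
        return pd.DataFrame(rows, columns=["id", "state", "hole_frag", "elec_frag", "omega"])

    def test_ct_state_dominant_pair(self):
        report = characterize_states(self.omega_records())
        s1 = report[(report.id == 1) & (report.state == 1)].iloc[0]
        assert s1.omega_ct == pytest.approx(0.968, abs=0.002)
        assert s1.dominant_pair == "N->E"
        assert s1.character == "CT"
        assert not s1.partial

    def test_diagonal_dominated_state_is_local_excitation(self):
        report = characterize_states(self.omega_records())
        s2 = report[(report.id == 1) & (report.state == 2)].iloc[0]
        assert s2.character == "LE"
        assert s2.omega_ct < 0.5

    def test_row_count_conservation(self, rng):
        frags = ["A", "B"]
        rows = [
            (i, s, h, e, float(rng.uniform()))
            for i in range(4) for s in (1, 2) for h in frags for e in frags
        ]
        rec = pd.DataFrame(rows, columns=["id", "state", "hole_frag", "elec_frag", "omega"])
        report = characterize_states(rec)
        assert len(report) == 8

    def test_join_with_state_table(self):
        from medoidspec.states import ExcitedStateTable

        table = ExcitedStateTable(pd.DataFrame(
            [(1, 1, 1.807, 0.002), (1, 2, 2.973, 0.035)],
            columns=["frame_id", "state", "energy_ev", "osc_strength"],
        ))
        report = characterize_states(self.omega_records(), table)
        assert report.energy_ev.tolist() == pytest.approx([1.807, 2.973])

    def test_join_miss_raises(self):
        from medoidspec.states import ExcitedStateTable

        table = ExcitedStateTable(pd.DataFrame(
            [(1, 1, 1.807, 0.002)], columns=["frame_id", "state", "energy_ev", "osc_strength"],
        ))
        with pytest.raises(KeyError):
            characterize_states(self.omega_records(), table)


class TestMatrixFiles:
    def test_matrix_round_trip(self, tmp_path, rng):
        m = rng.normal(size=(5, 5))
        p = tmp_path / "m.mat"
        write_matrix(m, p, "test")
        assert np.abs(read_matrix(p) - m).max() < 1e-11

    def test_load_transition_density_from_files(self, tmp_path):
        td, expected = syn.make_transition_density(8, [4, 4], ct_weight=0.7, seed=2)
        write_matrix(td.D, tmp_path / "D.mat", "density")
        write_matrix(td.S_ov, tmp_path / "S.mat", "overlap")
        (tmp_path / "basis.tsv").write_text(
            "\n".join(f"{i}\t{a}" for i, a in enumerate(td.basis_to_atom)) + "\n")
        (tmp_path / "frags.tsv").write_text(
            "\n".join(f"{a}\t{f}" for a, f in td.atom_to_fragment.items()) + "\n")
        loaded = load_transition_density(
            tmp_path / "D.mat", tmp_path / "S.mat",
            tmp_path / "basis.tsv", tmp_path / "frags.tsv")
        om = omega_matrix(loaded)
        assert np.abs(om.values - expected.values).max() < 1e-8
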