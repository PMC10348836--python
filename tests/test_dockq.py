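"""DockQ components, per-interface protocols, aggregation and classification."""

import math

import numpy as np
import pytest

from mqa import synthetic as syn
from mqa.structio import Structure, StructureError
from mqa.interfaces import ChainMapping
from mqa.dockq import (
    DockQParams,
    classify,
    dockq_interface,
    dockq_pair,
    dockq_score,
    evaluate_complex,
    fnat_fnonnat,
    success_rate,
    superpose,
)


def quaternion_rmsd(P, Q):
    """Independent optimal-superposition RMSD via Horn's quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    M = q.T @ p
    K = np.array([
        [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
        [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2], M[0, 1] + M[1, 0], M[0, 2] + M[2, 0]],
        [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0], -M[0, 0] + M[1, 1] - M[2, 2], M[1, 2] + M[2, 1]],
        [M[0, 1] - M[1, 0], M[0, 2] + M[2, 0], M[1, 2] + M[2, 1], -M[0, 0] - M[1, 1] + M[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e = (p ** 2).sum() + (q ** 2).sum() - 2.0 * lam
    return math.sqrt(max(e, 0.0) / len(P))


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_pure_translation_removed(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        _, _, rmsd = superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_four_point_displacement_matches_quaternion_oracle(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        mov = ref.copy()
        mov[3] += [0.0, 0.0, 2.0]
        _, _, rmsd = superpose(ref, mov)
        assert rmsd == pytest.approx(quaternion_rmsd(ref, mov), abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_sets_match_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        ref = rng.normal(scale=5.0, size=(n, 3))
        # random rigid motion plus noise
        axis = rng.normal(size=3)
        angle = rng.uniform(0, np.pi)
        from mqa.synthetic import _rotation_matrix
        R = _rotation_matrix(axis, angle)
        mov = ref @ R.T + rng.normal(size=3) + rng.normal(scale=0.5, size=(n, 3))
        _, _, rmsd = superpose(ref, mov)
        assert rmsd == pytest.approx(quaternion_rmsd(ref, mov), abs=1e-9)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(6, 3))
        mov = ref * np.array([-1.0, 1.0, 1.0])  # mirrored
        R, _, _ = superpose(ref, mov)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_but_returned(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.warns(UserWarning, match="collinear"):
            R, t, rmsd = superpose(line, line + 1.0)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


def _pairs(n, chain_a="A", chain_b="B"):
    return {frozenset({(chain_a, i), (chain_b, i)}) for i in range(n)}


class TestFnat:
    def test_perfect_model(self):
        native = _pairs(10)
        assert fnat_fnonnat(native, set(native)) == (1.0, 0.0)

    def test_partial_with_extras(self):
        native = _pairs(10)
        model = _pairs(6) | {frozenset({("A", 100 + i), ("B", 100 + i)}) for i in range(2)}
        fnat, fnonnat = fnat_fnonnat(native, model)
        assert fnat == pytest.approx(0.6)
        assert fnonnat == pytest.approx(0.25)

    def test_empty_model_convention(self):
        assert fnat_fnonnat(_pairs(5), set()) == (0.0, 0.0)

    def test_empty_native_is_error(self):
        with pytest.raises(StructureError, match="native"):
            fnat_fnonnat(set(), _pairs(3))


class TestCombinationFormula:
    def test_midpoint_components(self):
        # each term contributes exactly 0.5 at these values
        assert dockq_score(0.5, 1.5, 8.5) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert dockq_score(1.0, 0.0, 0.0) == pytest.approx(1.0)
        assert dockq_score(0.0, 100.0, 100.0) < 0.05


class TestDockQProtocols:
    def test_perfect_model_scores_one(self, dimer_case):
        nat, model, _, _ = dimer_case
        comp = dockq_pair(model, nat, "A", "B")
        assert comp.dockq == pytest.approx(1.0, abs=1e-9)
        assert comp.fnat == 1.0 and comp.fnonnat == 0.0
        assert comp.irms == pytest.approx(0.0, abs=1e-6)
        assert comp.lrms == pytest.approx(0.0, abs=1e-6)

    def test_far_translated_ligand_near_zero(self):
        nat, model, _, _ = syn.generate_case(seed=11, n_chains=2, undock=[1])
        comp = dockq_pair(model, nat, "A", "B", ChainMapping.identity("AB"))
        assert comp.fnat == 0.0
        assert comp.dockq < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_dimer_identity_pair_equals_interface(self, seed):
        nat, model, _, _ = syn.generate_case(
            seed=seed, n_chains=2,
            misdock=[0] if seed % 3 == 0 else [],
        )
        mapping = ChainMapping.identity("AB")
        ij = dockq_pair(model, nat, "A", "B", mapping).dockq
        for chain in "AB":
            di = dockq_interface(model, nat, chain, mapping).dockq
            assert di == pytest.approx(ij, abs=1e-9)

    def test_monotone_degradation_with_translation(self):
        # same seed -> identical translation direction, growing magnitude
        scores = []
        for t in (0.0, 1.0, 2.0, 4.0, 8.0, 16.0):
            spec = syn.GeneratorSpec(
                n_chains=2,
                perturbations=[syn.Perturbation(), syn.Perturbation(translation=t)],
                seed=21,
            )
            nat = syn.make_complex(spec)
            model = syn.perturb_model(nat, spec)
            scores.append(
                dockq_pair(model, nat, "A", "B", ChainMapping.identity("AB")).dockq
            )
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[0] == pytest.approx(1.0, abs=1e-9)
        assert scores[-1] < 0.2

    def test_symmetric_homotrimer_identical_dockq_i(self):
        # perturb each subunit by the symmetry-conjugated rigid motion, so
        # the model keeps C3 symmetry and every interface degrades equally
        from mqa.synthetic import _rotation_matrix, _transform_chain

        spec = syn.GeneratorSpec(n_chains=3, homomer=True, seed=31)
        nat = syn.make_complex(spec)
        axis0 = np.array([0.3, -0.5, 0.8])
        t0 = np.array([1.0, 0.5, -0.7])
        chains = []
        for k, chain in enumerate(nat.chains):
            phi = 2.0 * np.pi * k / 3.0
            Rz = _rotation_matrix(np.array([0.0, 0.0, 1.0]), phi)
            Rk = Rz @ _rotation_matrix(axis0, np.radians(25.0)) @ Rz.T
            chains.append(_transform_chain(chain, Rk, Rz @ t0))
        model = Structure(id="sym", chains=chains)
        mapping = ChainMapping.identity("ABC")
        vals = [dockq_interface(model, nat, c, mapping).dockq for c in "ABC"]
        assert max(vals) - min(vals) < 1e-6
        assert 0.0 < vals[0] < 1.0

    def test_components_within_ranges(self):
        nat, model, _, _ = syn.generate_case(seed=41, n_chains=3, misdock=[2])
        ev = evaluate_complex(model, nat)
        for comp in list(ev.dockq_ij.values()) + list(ev.dockq_i.values()):
            assert 0.0 <= comp.fnat <= 1.0
            assert 0.0 <= comp.fnonnat <= 1.0
            assert comp.irms >= 0.0 and comp.lrms >= 0.0
            assert 0.0 <= comp.dockq <= 1.0


class TestEvaluateComplex:
    def test_perfect_model_all(self):
        nat, model, _, _ = syn.generate_case(seed=51, n_chains=4)
        ev = evaluate_complex(model, nat)
        assert ev.label == "ALL"
        for comp in ev.dockq_i.values():
            assert comp.dockq == pytest.approx(1.0, abs=1e-9)

    def test_one_misplaced_chain_in_line_tetramer(self):
        # undocking an end chain leaves the far interfaces intact
        nat, model, _, _ = syn.generate_case(
            seed=52, n_chains=4, arrangement="line", undock=[3]
        )
        ev = evaluate_complex(model, nat)
        assert ev.dockq_i["D"].dockq < 0.05
        # A keeps its contacts (fnat 1) but D is part of A's rigid receptor,
        # so its displacement still costs A some LRMS
        assert ev.dockq_i["A"].fnat == pytest.approx(1.0)
        assert ev.dockq_i["A"].dockq > 0.5
        assert ev.dockq_ij[("A", "B")].dockq > 0.95
        assert ev.label == "SOME"
        assert ev.min_dockq_i < ev.max_dockq_i

    def test_fully_scrambled_is_none(self):
        nat, model, _, _ = syn.generate_case(seed=53, n_chains=3, undock=[0, 1, 2])
        ev = evaluate_complex(model, nat)
        assert ev.label == "NONE"

    def test_aggregates_ordered(self):
        nat, model, _, _ = syn.generate_case(seed=54, n_chains=4, misdock=[1])
        ev = evaluate_complex(model, nat)
        assert ev.min_dockq_i <= ev.max_dockq_i
        assert ev.min_dockq_ij <= ev.max_dockq_ij


class TestClassify:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.5, 0.7, 0.9], "ALL"),
            ([0.1, 0.5], "SOME"),
            ([0.0, 0.22], "NONE"),
            ([0.23], "ALL"),  # boundary: >= is inclusive
        ],
    )
    def test_examples(self, values, expected):
        assert classify(values) == expected

    def test_empty_vector(self):
        with pytest.raises(ValueError):
            classify([])


class TestSuccessRate:
    def test_strict_inequality_examples(self):
        class E:
            def __init__(self, v):
                self.min_dockq_i = v

        assert success_rate([E(0.1), E(0.3), E(0.5)]) == pytest.approx(2 / 3)
        assert success_rate([E(0.0), E(0.0)]) == 0.0
        assert success_rate([E(0.23)]) == 0.0  # strictly greater than required

    def test_empty_list(self):
        with pytest.raises(ValueError):
            success_rate([])

    def test_known_mixture_rate(self):
        evals = []
        for seed in range(30):
            correct = seed % 2 == 0
            nat, model, _, _ = syn.generate_case(
                seed=200 + seed, n_chains=2, undock=[] if correct else [1]
            )
            evals.append(evaluate_complex(model, nat))
        assert success_rate(evals) == pytest.approx(0.5)
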