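"""Boltzmann weighting, class populations, circular means, and the
ensemble summary table."""

import math

import numpy as np
import pytest

from alphaturn import (
    Conformer,
    Ensemble,
    R_KCAL,
    boltzmann_weights,
    circular_mean,
    class_fraction,
    class_min_gap,
    make_energy_set,
    table1_report,
)
from alphaturn.geometry import TurnFlags
from alphaturn.stats import ClassAbsentError


class TestBoltzmannWeights:
    def test_equal_energies_uniform(self):
        assert np.allclose(boltzmann_weights([0, 0, 0], 300.0), [1 / 3] * 3)

    def test_closed_form_case(self):
        # independent closed-form evaluation of exp(-dE/RT)/Z at 298.15 K
        de = [0.0, 1.0, 2.0]
        rt = R_KCAL * 298.15
        z = sum(math.exp(-e / rt) for e in de)
        expected = [math.exp(-e / rt) / z for e in de]
        assert np.allclose(boltzmann_weights(de, 298.15), expected)
        assert np.round(expected, 3).tolist() == [0.820, 0.152, 0.028]

    def test_rt_ln10_gives_ten_to_one(self):
        w = boltzmann_weights([0.0, 1.364], 298.15)
        assert w[0] / w[1] == pytest.approx(10.0, rel=5e-3)

    def test_sum_to_one_and_monotone(self):
        w = boltzmann_weights([0, 0.5, 1.7, 3.3, 5.9], 298.15)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(w) < 0)

    def test_temperature_limits(self):
        de = [0.0, 1.0, 2.0]
        hot = boltzmann_weights(de, 1e6)
        assert np.allclose(hot, 1 / 3, atol=1e-3)
        cold = boltzmann_weights(de, 1.0)
        assert cold[0] == pytest.approx(1.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            boltzmann_weights([], 300.0)
        with pytest.raises(ValueError):
            boltzmann_weights([0.0], -1.0)


class TestClassStatistics:
    def test_fraction_totals(self):
        w = [0.5, 0.3, 0.15, 0.05]
        assert class_fraction(w, [1, 1, 1, 1]) == pytest.approx(1.0)
        assert class_fraction(w, [0, 0, 0, 0]) == 0.0
        assert class_fraction(w, [1, 1, 1, 0]) == pytest.approx(0.95)

    def test_fraction_additive_over_disjoint_classes(self):
        w = boltzmann_weights([0, 0.3, 1.1, 2.0], 298.15)
        a = np.array([1, 0, 1, 0], bool)
        assert class_fraction(w, a) + class_fraction(w, ~a) == pytest.approx(1.0)

    def test_min_gap(self):
        assert class_min_gap([0, 2, 5.9], [1, 0, 0]) == 0.0
        assert class_min_gap([0, 2, 5.9], [0, 0, 1]) == 5.9

    def test_min_gap_absent_class(self):
        with pytest.raises(ClassAbsentError):
            class_min_gap([0, 2], [0, 0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            class_fraction([0.5, 0.5], [1])


class TestCircularMean:
    @pytest.mark.parametrize(
        "angles,expected",
        [([170, -170], 180.0), ([-80, -80, -80], -80.0), ([-60, -100], -80.0)],
    )
    def test_examples(self, angles, expected):
        assert circular_mean(angles) == pytest.approx(expected, abs=1e-9)

    def test_weighted(self):
        assert circular_mean([0.0, 90.0], [3.0, 1.0]) == pytest.approx(
            math.degrees(math.atan2(0.25, 0.75))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_mean([])


def _flags(has_a, has_b, dalpha, phi_psi=(-83.0, 65.0)):
    return TurnFlags(
        has_hbond_a=has_a,
        has_hbond_b=has_b,
        dalpha=dalpha,
        dalpha_probe_pass=dalpha < 7.0,
        torsions={2: phi_psi, 3: (146.0, 37.0), 4: (120.0, -29.0)},
    )


def _ensemble(rel_energies):
    confs = [Conformer(coords=np.zeros((3, 3)), energy=e) for e in rel_energies]
    return Ensemble(None, confs)


class TestTable1Report:
    def test_alpha_dominated_fixture(self):
        # four alpha-turn conformers + one extended decoy, as in the
        # alpha-mimic pattern: the turn class dominates the population
        eset = make_energy_set(
            [("alpha", 0.0), ("alpha", 0.3), ("alpha", 0.8), ("alpha", 1.1), ("ext", 3.0)]
        )
        ens = _ensemble(eset.relative_energies)
        flags = [
            _flags(False, lab == "alpha", 5.0 if lab == "alpha" else 11.0)
            for lab in eset.labels
        ]
        rep = table1_report(ens, flags)
        assert rep.n_conformers == 5
        assert rep.count_hbond_b == 4 and rep.count_dalpha_probe == 4
        assert rep.global_min_hbond_b and not rep.global_min_hbond_a
        assert rep.fraction_hbond_b > 0.9
        assert rep.mean_dalpha_alpha_class == pytest.approx(5.0)
        assert rep.designation == "B-αL-X"

    def test_gamma_epimer_pattern_gap(self):
        eset = make_energy_set([("gamma", 0.0), ("alpha", 5.9)])
        ens = _ensemble(eset.relative_energies)
        flags = [
            _flags(lab == "gamma", lab == "alpha", 8.0 if lab == "gamma" else 5.0,
                   phi_psi=(-80.0, 79.0))
            for lab in eset.labels
        ]
        rep = table1_report(ens, flags)
        assert rep.alpha_class_min_gap == pytest.approx(5.9)
        assert rep.gamma_class_min_gap == 0.0
        assert rep.global_min_hbond_a

    def test_counts_permutation_invariant(self):
        rng = np.random.default_rng(1)
        de = [0.0, 0.4, 1.2, 2.5, 4.0]
        fl = [_flags(bool(i % 2), not i % 2, 5.0 + i) for i in range(5)]
        rep0 = table1_report(_ensemble(de), fl)
        order = rng.permutation(5)
        # permute conformers and flags together; Ensemble re-sorts by energy,
        # so re-pair flags with the sorted order
        pairs = [(de[i], fl[i]) for i in order]
        pairs.sort(key=lambda p: p[0])
        rep1 = table1_report(
            _ensemble([p[0] for p in pairs]), [p[1] for p in pairs]
        )
        assert rep0.count_hbond_a == rep1.count_hbond_a
        assert rep0.count_hbond_b == rep1.count_hbond_b
        assert rep0.fraction_hbond_a == pytest.approx(rep1.fraction_hbond_a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            table1_report(_ensemble([]), [])

    def test_flags_length_enforced(self):
        with pytest.raises(ValueError):
            table1_report(_ensemble([0.0, 1.0]), [_flags(True, False, 5.0)])


class TestEnergySet:
    def test_requires_zero_member(self):
        with pytest.raises(ValueError):
            make_energy_set([("alpha", 1.0)])

    def test_single_member_fraction_one(self):
        eset = make_energy_set([("alpha", 0.0)])
        w = boltzmann_weights(eset.relative_energies)
        assert class_fraction(w, eset.members("alpha")) == 1.0

    def test_top4_alpha_dominance(self):
        # closed-form check of the alpha-mimic population pattern
        eset = make_energy_set(
            [("a", 0.0), ("a", 0.3), ("a", 0.8), ("a", 1.1), ("g", 3.0)]
        )
        w = boltzmann_weights(eset.relative_energies, 298.15)
        assert class_fraction(w, eset.members("a")) > 0.9
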