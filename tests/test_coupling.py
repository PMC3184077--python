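"""Flux-coupling detection, FCS partitioning and the modularity indices."""

import numpy as np
import pytest

import fluxmod as fm
from fluxmod.flux_coupling import AnalysisSystem, CouplingBounds, FCSPartition

import helpers


class TestCouplingBounds:
    def test_consecutive_chain_reactions_have_unit_ratio(self):
        universe = fm.linear_chain_universe(4)
        bounds = fm.coupling_bounds(universe, universe.full_genotype(), "R1", "R2")
        assert bounds.feasible
        assert bounds.rmin == pytest.approx(1.0, abs=1e-9)
        assert bounds.rmax == pytest.approx(1.0, abs=1e-9)

    def test_doubling_step_forces_half_ratio(self, tmp_path):
        (tmp_path / "metabolites.tsv").write_text(
            "metabolite_id\texternal\nA_ext\t1\nB\t0\nC\t0\n")
        (tmp_path / "reactions.tsv").write_text(
            "reaction_id\tequation\trole\tswappable\n"
            "EX_A\tA_ext =>\texchange\t0\n"
            "R1\tA_ext => 2 B\tmetabolic\t1\n"
            "R2\tB => C\tmetabolic\t1\n"
            "BIOMASS\tC =>\tbiomass\t0\n")
        universe = fm.read_universe(tmp_path)
        bounds = fm.coupling_bounds(universe, universe.full_genotype(), "R1", "R2")
        assert bounds.rmin == pytest.approx(0.5, abs=1e-9)
        assert bounds.rmax == pytest.approx(0.5, abs=1e-9)

    def test_branch_point_decouples(self, tmp_path):
        # one producer feeding two consumers: the ratio producer/branch varies
        (tmp_path / "metabolites.tsv").write_text(
            "metabolite_id\texternal\nA_ext\t1\nB\t0\nC_ext\t1\nD_ext\t1\n")
        (tmp_path / "reactions.tsv").write_text(
            "reaction_id\tequation\trole\tswappable\n"
            "EX_A\tA_ext =>\texchange\t0\n"
            "EX_C\tC_ext =>\texchange\t0\n"
            "EX_D\tD_ext =>\texchange\t0\n"
            "Rin\tA_ext => B\tmetabolic\t1\n"
            "Rbr1\tB => C_ext\tmetabolic\t1\n"
            "Rbr2\tB => D_ext\tmetabolic\t1\n"
            "BIOMASS\tC_ext =>\tbiomass\t0\n")
        universe = fm.read_universe(tmp_path)
        bounds = fm.coupling_bounds(universe, universe.full_genotype(), "Rin", "Rbr1")
        assert bounds.feasible and bounds.rmin < bounds.rmax
        assert not fm.fully_coupled(bounds)
        # and the Monte-Carlo cone-sampling oracle agrees there is no module
        oracle = helpers.montecarlo_partition(
            universe, universe.full_genotype(), np.random.default_rng(0))
        assert all("Rin" not in fcs or "Rbr1" not in fcs for fcs in oracle)

    def test_symmetry_of_full_coupling(self, study):
        universe, _, _, _ = study
        genotype = universe.full_genotype()
        system = AnalysisSystem(universe, genotype)
        pairs = [("R_nut1_1", "R_nut1_2"), ("R_core_1", "R_core_2"),
                 ("R_nut1_1", "R_core_1"), ("R_alt1_1", "R_alt2_1")]
        for r1, r2 in pairs:
            fwd = fm.fully_coupled(system.ratio_bounds(r1, r2))
            rev = fm.fully_coupled(system.ratio_bounds(r2, r1))
            assert fwd == rev


class TestFullyCoupledPredicate:
    @pytest.mark.parametrize(
        "rmin, rmax, feasible, expect",
        [
            (1.0, 1.0, True, True),
            (0.0, 0.0, True, False),          # locked zero ratio is not coupling
            (0.5, 0.500000000001, True, True),
            (0.5, 0.51, True, False),
            (1.0, 1.0, False, False),
            (-2.0, -2.0, True, True),         # negative fixed ratio still couples
        ],
    )
    def test_threshold_semantics(self, rmin, rmax, feasible, expect):
        bounds = CouplingBounds(rmin=rmin, rmax=rmax, feasible=feasible)
        assert fm.fully_coupled(bounds) is expect


class TestFCSPartition:
    @pytest.mark.parametrize("k", [2, 5])
    def test_linear_chain_is_one_fcs(self, k):
        universe = fm.linear_chain_universe(k)
        partition = fm.fcs_partition(universe, universe.full_genotype())
        assert partition.s == 1 and partition.M == k
        assert partition.sets[0] == frozenset(f"R{i}" for i in range(1, k + 1))

    def test_two_independent_chains(self):
        config = fm.SynthConfig(n_nutrients=2, pathway_length=3, core_length=4,
                                n_redundant_routes=0, n_distractors=0,
                                n_deep_chains=0, with_branch=False,
                                with_cycle=False, n_cofactors=0)
        universe, _, _, truth = fm.generate(config)
        partition = fm.fcs_partition(universe, universe.full_genotype())
        assert set(partition.sets) == set(truth.fcs_sets)
        assert (partition.M, partition.s) == (3 + 3 + 4, 3)

    def test_matches_designed_modules_of_default_study(self, study):
        universe, _, _, truth = study
        partition = fm.fcs_partition(universe, universe.full_genotype())
        assert set(partition.sets) == set(truth.fcs_sets)

    def test_exhaustive_mode_agrees_and_is_transitive(self, study):
        universe, _, _, _ = study
        config = fm.SynthConfig(n_nutrients=2, n_distractors=3, n_deep_chains=1,
                                deep_chain_length=3)
        small, _, _, _ = fm.generate(config)
        default = fm.fcs_partition(small, small.full_genotype())
        exhaustive = fm.fcs_partition(small, small.full_genotype(), exhaustive=True)
        assert set(default.sets) == set(exhaustive.sets)

    def test_relabeling_invariance(self, tmp_path):
        universe = fm.linear_chain_universe(4)
        fm.write_universe(universe, tmp_path)  # canonical order differs from build order
        reread = fm.read_universe(tmp_path)
        a = fm.fcs_partition(universe, universe.full_genotype())
        b = fm.fcs_partition(reread, reread.full_genotype())
        assert set(a.sets) == set(b.sets)

    def test_partition_excludes_boundary_and_sink_pseudoreactions(self, study):
        universe, _, _, _ = study
        partition = fm.fcs_partition(universe, universe.full_genotype())
        members = partition.member_reactions()
        for rid in members:
            j = universe.reaction_index[rid]
            assert universe.role[j] == "metabolic"
        assert not any(r.startswith("__sink__") for r in members)

    def test_indices_and_invariants(self):
        partition = FCSPartition(sets=(frozenset({"a", "b"}),
                                       frozenset({"c", "d", "e"})), M=5, s=2)
        assert fm.modularity_indices(partition) == (5, 2)
        empty = FCSPartition(sets=(), M=0, s=0)
        assert fm.modularity_indices(empty) == (0, 0)
        with pytest.raises(ValueError):
            FCSPartition(sets=(frozenset({"a"}),), M=1, s=1)
        with pytest.raises(ValueError):
            FCSPartition(sets=(frozenset({"a", "b"}), frozenset({"b", "c"})), M=4, s=2)


class TestOracleEquivalence:
    def test_nullspace_oracle_on_all_reversible_toys(self, rng):
        hits = 0
        for _ in range(8):
            universe = fm.random_toy_universe(
                rng, n_reactions=int(rng.integers(5, 12)), all_reversible=True)
            partition = fm.fcs_partition(universe, universe.full_genotype())
            oracle = helpers.nullspace_partition(universe, universe.full_genotype())
            assert set(partition.sets) == oracle
            hits += len(oracle)
        assert hits >= 1  # the sweep must exercise at least one genuine module

    def test_montecarlo_oracle_on_mixed_toys(self, rng):
        for _ in range(8):
            universe = fm.random_toy_universe(rng, n_reactions=int(rng.integers(5, 12)))
            partition = fm.fcs_partition(universe, universe.full_genotype())
            oracle = helpers.montecarlo_partition(universe, universe.full_genotype(), rng)
            assert set(partition.sets) == oracle
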