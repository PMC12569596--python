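import numpy as np
import pandas as pd
import pytest

from adict.celltype import (
    build_pseudobulk,
    celltype_anova,
    celltype_conservation_profiles,
    common_gene_set,
    filter_celltypes_and_individuals,
    immune_status_mixed_anova,
    per_celltype_adict,
)
from adict.core import sample_ec_correlation
from adict.errors import AnalysisError, InputError
from adict.simulate import (
    CellTypeSpec,
    SimulationConfig,
    simulate_celltype_dataset,
)


def _annotation(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "individual", "age_months", "tissue", "cell_type"]
    )


class TestPseudobulk:
    def test_single_cell_group_is_identity(self):
        m = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=["g1", "g2", "g3"])
        ann = _annotation([("c1", "i1", 3, "brain", "neuron")])
        pb = build_pseudobulk(m, ann)
        assert np.allclose(pb.values.iloc[:, 0], [1, 2, 3])
        assert pb.units["n_cells"].iloc[0] == 1

    def test_arithmetic_mean(self):
        v = np.array([1.0, 4.0, 2.0])
        m = pd.DataFrame({"c1": v, "c2": 3 * v}, index=["g1", "g2", "g3"])
        ann = _annotation(
            [("c1", "i1", 3, "brain", "neuron"), ("c2", "i1", 3, "brain", "neuron")]
        )
        pb = build_pseudobulk(m, ann)
        assert np.allclose(pb.values.iloc[:, 0], 2 * v)

    def test_matches_bruteforce_loop(self, rng):
        genes = [f"g{i}" for i in range(8)]
        cells = [f"c{i}" for i in range(20)]
        m = pd.DataFrame(rng.uniform(0, 10, size=(8, 20)), index=genes, columns=cells)
        ann = _annotation(
            [(c, f"i{k % 3}", 3, "brain", "neuron" if k % 2 else "glia")
             for k, c in enumerate(cells)]
        )
        pb = build_pseudobulk(m, ann)
        for unit, urow in pb.units.iterrows():
            members = ann[(ann.individual == urow.individual)
                          & (ann.cell_type == urow.cell_type)]["cell_id"]
            expected = m[list(members)].values.mean(axis=1)
            assert np.allclose(pb.values[unit].values, expected)

    def test_linearity(self, rng):
        m = pd.DataFrame(rng.uniform(1, 5, size=(4, 3)), index=list("abcd"),
                         columns=["c0", "c1", "c2"])
        ann = _annotation([(c, "i1", 3, "t", "x") for c in m.columns])
        pb1 = build_pseudobulk(m, ann)
        pb2 = build_pseudobulk(m * 7.0, ann)
        assert np.allclose(pb2.values.values, 7.0 * pb1.values.values)

    def test_unknown_cells_error(self):
        m = pd.DataFrame({"c1": [1.0]}, index=["g1"])
        ann = _annotation([("c1", "i1", 3, "t", "x"), ("cX", "i1", 3, "t", "x")])
        with pytest.raises(InputError):
            build_pseudobulk(m, ann)


class TestFiltering:
    def _pb(self, unit_specs):
        rows = []
        for k, (tissue, ctype, ind, age) in enumerate(unit_specs):
            rows.append((f"c{k}", ind, age, tissue, ctype))
        ann = _annotation(rows)
        m = pd.DataFrame(
            np.ones((3, len(rows))), index=["g1", "g2", "g3"],
            columns=[f"c{k}" for k in range(len(rows))],
        )
        return build_pseudobulk(m, ann)

    def test_celltype_absent_from_one_age_group_removed(self):
        units = [("t", "A", f"i{a}", a) for a in (3, 18, 24)]
        units += [("t", "B", f"i{a}", a) for a in (3, 18)]  # B missing at 24
        pb = self._pb(units)
        out, report = filter_celltypes_and_individuals(pb, age_groups_required=(3, 18, 24))
        assert set(out.units["cell_type"]) == {"A"}
        assert report["celltypes_dropped"] == 1

    def test_individual_coverage_strictly_above(self):
        # 10 cell types at one age; i_lo covers 7 (70%, dropped), i_hi covers 8
        units = []
        for t in range(10):
            for a in (3,):
                units.append(("t", f"T{t}", "i_full", a))
        units += [("t", f"T{t}", "i_lo", 3) for t in range(7)]
        units += [("t", f"T{t}", "i_hi", 3) for t in range(8)]
        pb = self._pb(units)
        out, _ = filter_celltypes_and_individuals(pb, age_groups_required=(3,))
        kept = set(out.units["individual"])
        assert "i_lo" not in kept and {"i_hi", "i_full"} <= kept

    def test_everything_filtered_errors(self):
        pb = self._pb([("t", "A", "i1", 3)])
        with pytest.raises(AnalysisError):
            filter_celltypes_and_individuals(pb, age_groups_required=(3, 18))


@pytest.fixture(scope="module")
def sim_small():
    cfg = SimulationConfig(seed=11, n_genes=300, n_individuals_per_age=4,
                           n_cells_per_individual=60)
    return simulate_celltype_dataset(cfg)


@pytest.fixture(scope="module")
def cons_small(sim_small):
    from adict.conservation import compute_conservation_scores, relative_conservation

    cons = compute_conservation_scores(sim_small.divergence)
    return relative_conservation(cons, set(cons.loc[~cons.excluded, "gene_id"]))


class TestProfiles:
    def test_disjoint_tissues_error(self):
        m = pd.DataFrame(
            {"c1": [1.0, 0.0], "c2": [0.0, 1.0]}, index=["g1", "g2"]
        )
        ann = _annotation([("c1", "i1", 3, "tA", "x"), ("c2", "i2", 3, "tB", "y")])
        with pytest.raises(AnalysisError):
            common_gene_set(build_pseudobulk(m, ann))

    def test_min_individuals_excludes_small_celltypes(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        # keep only 2 individuals of one cell type at age 3
        units = pb.units[(pb.units.age_months == 3.0)]
        drop_type = units["cell_type"].iloc[0]
        sub_idx = units[units.cell_type == drop_type].index[:2].union(
            units[units.cell_type != drop_type].index
        )
        from adict.celltype import PseudobulkDataset

        sub = PseudobulkDataset(values=pb.values[sub_idx], units=pb.units.loc[sub_idx])
        prof = celltype_conservation_profiles(sub, cons_small, min_individuals=3,
                                              age_group=3.0)
        assert drop_type not in set(prof["cell_type"])

    def test_composition_consistency_with_direct_call(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        common = common_gene_set(pb)
        prof = celltype_conservation_profiles(pb, cons_small, common_genes=common,
                                              age_group=3.0)
        row = prof.iloc[0]
        expr = pb.values.loc[:, row["unit_id"]]
        rho, _ = sample_ec_correlation(expr, cons_small, gene_subset=common)
        assert row["ec_rho"] == pytest.approx(rho, abs=1e-12)


class TestANOVA:
    def _profiles(self, ec, tissues, ctypes):
        return pd.DataFrame({"ec_rho": ec, "tissue": tissues, "cell_type": ctypes})

    def test_all_equal_gives_zero_F(self):
        prof = self._profiles([0.2] * 8, ["a", "a", "b", "b"] * 2,
                              ["x", "y"] * 4)
        rep = celltype_anova(prof)
        assert rep["tissue"]["F"] == 0.0 and rep["cell_type"]["F"] == 0.0

    def test_balanced_2x2_matches_hand_anova(self):
        # hand-worked sequential sums of squares on a balanced design:
        # cell-type effect +-0.1, no tissue effect, residuals +-0.01
        ec = [0.30, 0.32, 0.10, 0.12, 0.31, 0.29, 0.11, 0.09]
        tissues = ["a", "a", "a", "a", "b", "b", "b", "b"]
        ctypes = ["x", "x", "y", "y", "x", "x", "y", "y"]
        rep = celltype_anova(self._profiles(ec, tissues, ctypes))
        grand = np.mean(ec)
        ss_tissue = 4 * ((np.mean(ec[:4]) - grand) ** 2 + (np.mean(ec[4:]) - grand) ** 2)
        mx = np.mean([e for e, c in zip(ec, ctypes) if c == "x"])
        my = np.mean([e for e, c in zip(ec, ctypes) if c == "y"])
        ss_ct = 4 * ((mx - grand) ** 2 + (my - grand) ** 2)
        assert rep["tissue"]["sum_sq"] == pytest.approx(ss_tissue, abs=1e-12)
        assert rep["cell_type"]["sum_sq"] == pytest.approx(ss_ct, abs=1e-12)
        assert rep["cell_type"]["p"] < 0.001

    def test_planted_celltype_effect_detected(self, sim_small, cons_small):
        # generator defaults: affinities differ by cell type, no tissue effect
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        prof = celltype_conservation_profiles(pb, cons_small, age_group=3.0)
        rep = celltype_anova(prof)
        assert rep["cell_type"]["p"] < 0.01

    def test_single_level_errors(self):
        with pytest.raises(AnalysisError):
            celltype_anova(self._profiles([0.1, 0.2], ["a", "a"], ["x", "y"]))


class TestImmuneMixedModel:
    def test_planted_negative_immune_effect(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        prof = celltype_conservation_profiles(pb, cons_small, age_group=3.0)
        rep = immune_status_mixed_anova(prof)
        assert rep["immune_coefficient"] < 0  # immune types have low-CS profiles

    def test_single_tissue_fallback(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        prof = celltype_conservation_profiles(pb, cons_small, age_group=3.0)
        prof = prof[prof.tissue == "brain"]
        rep = immune_status_mixed_anova(prof)
        assert rep["model"] == "ols_fallback"

    def test_constant_immune_errors(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        prof = celltype_conservation_profiles(pb, cons_small, age_group=3.0)
        prof = prof[~prof["is_immune"].astype(bool)]
        with pytest.raises(AnalysisError):
            immune_status_mixed_anova(prof)


class TestPerCelltypeADICT:
    def test_targeted_recovery_flags_coupled_type(self, cons_small):
        hits = 0
        for rep in range(10):
            spec = (
                CellTypeSpec("aging", "t1", False, 0.34, 0.0, 0.5, 0.0),
                CellTypeSpec("calm", "t1", False, 0.33, 0.0, 0.0, 0.1),
                CellTypeSpec("other", "t1", False, 0.33, 0.0, 0.0, -0.1),
            )
            cfg = SimulationConfig(seed=100 + rep, n_genes=300, celltype_spec=spec,
                                   n_individuals_per_age=4, n_cells_per_individual=60)
            sim = simulate_celltype_dataset(cfg)
            from adict.conservation import compute_conservation_scores

            cons = compute_conservation_scores(sim.divergence)
            pb = build_pseudobulk(sim.cell_matrix, sim.annotation)
            tab = per_celltype_adict(pb, cons, gene_set="all")
            if tab.loc[tab["rho_adict"].idxmin(), "cell_type"] == "aging":
                hits += 1
        assert hits >= 9

    def test_single_celltype_q_equals_p(self, sim_small, cons_small):
        pb = build_pseudobulk(sim_small.cell_matrix, sim_small.annotation)
        keep = pb.units[(pb.units.tissue == "brain")
                        & (pb.units.cell_type == "neuron")].index
        from adict.celltype import PseudobulkDataset

        sub = PseudobulkDataset(values=pb.values[keep], units=pb.units.loc[keep])
        tab = per_celltype_adict(sub, cons_small, gene_set="all")
        assert len(tab) == 1
        assert tab["q_adict"].iloc[0] == pytest.approx(tab["p_adict"].iloc[0])
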