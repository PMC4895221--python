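import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neutronet.errors import InsufficientPairsError
from neutronet.io_formats import SampleDesign, TargetMap
from neutronet.mirna_correlation import (
    GENE_LEVEL,
    MIRNA_LEVEL,
    PAIR_LEVEL,
    CorrelationRecord,
    LevelThresholds,
    compare_negative_distributions,
    permutation_pvalues,
    pooled_correlation,
    screen,
    select_significant,
)
from neutronet.synthetic_data import SimConfig, generate_dataset


class TestPooledCorrelation:
    def test_perfect_anticorrelation(self):
        rec = pooled_correlation([1, 2, 3], [[3, 2, 1]])
        assert rec.pearson_r == pytest.approx(-1.0)
        assert rec.spearman_rho == pytest.approx(-1.0)

    def test_symmetric_cancellation(self):
        rec = pooled_correlation([-1, 0, 1], [[-1, 0, 1], [1, 0, -1]])
        assert rec.pearson_r == pytest.approx(0.0, abs=1e-12)

    def test_enumerated_point_set(self):
        """Pooled r/rho equal plain correlation on the six explicit points."""
        anchor, members = [1, 2, 3], [[3, 2, 1], [2, 2, 2]]
        rec = pooled_correlation(anchor, members)
        x = np.array(anchor * 2, dtype=float)
        y = np.array(members[0] + members[1], dtype=float)
        assert rec.pearson_r == pytest.approx(stats.pearsonr(x, y).statistic)
        assert rec.pearson_r == pytest.approx(-2 / np.sqrt(8))
        assert rec.spearman_rho == pytest.approx(stats.spearmanr(x, y).statistic)
        assert rec.n_points == 6

    def test_degenerate_flag(self):
        rec = pooled_correlation([1, 1, 1], [[1, 2, 3]])
        assert rec.degenerate and rec.pearson_r == 0.0


@pytest.fixture
def toy_screen_inputs(make_expr):
    mirna = make_expr([[1.0, 2, 3, 4], [4.0, 1, 3, 2]],
                      feature_ids=["m1", "m2"], kind="mirna")
    mrna = make_expr(np.random.default_rng(0).normal(8, 1, (4, 4)),
                     feature_ids=["g1", "g2", "g3", "g4"])
    targets = TargetMap({"m1": frozenset({"g1", "g2"}), "m2": frozenset({"g3", "g4"})})
    design = SampleDesign({f"s{i + 1}": "JIA" for i in range(4)})
    return mirna, mrna, targets, design


class TestScreen:
    def test_mirna_level_record_shape(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        records = screen(mirna, mrna, targets, design, "JIA", "mirna")
        assert [r.entity for r in records] == ["m1", "m2"]
        assert all(r.n_points == 2 * 4 for r in records)

    def test_gene_level_count_is_distinct_targeted_genes(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        records = screen(mirna, mrna, targets, design, "JIA", "gene")
        assert len(records) == 4

    def test_screen_agrees_with_pooled_reference(self, toy_screen_inputs):
        """The aggregate-based bulk path equals explicit pooling, per record."""
        mirna, mrna, targets, design = toy_screen_inputs
        for level, anchor_of in (("mirna", "anchor_mirna"), ("gene", "anchor_gene")):
            records = screen(mirna, mrna, targets, design, "JIA", level)
            for rec in records:
                if level == "mirna":
                    anchor = mirna.data.loc[rec.entity]
                    members = [mrna.data.loc[g] for g in sorted(targets.targets[rec.entity])]
                else:
                    anchor = mrna.data.loc[rec.entity]
                    members = [mirna.data.loc[m] for m in sorted(
                        m for m, gs in targets.targets.items() if rec.entity in gs)]
                ref = pooled_correlation(anchor, members)
                assert rec.pearson_r == pytest.approx(ref.pearson_r)
                assert rec.spearman_rho == pytest.approx(ref.spearman_rho)

    def test_pair_level_equals_plain_correlation(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        for rec in screen(mirna, mrna, targets, design, "JIA", "pair"):
            m, g = rec.entity
            r = np.corrcoef(mirna.data.loc[m], mrna.data.loc[g])[0, 1]
            rho = stats.spearmanr(mirna.data.loc[m], mrna.data.loc[g]).statistic
            assert rec.pearson_r == pytest.approx(r)
            assert rec.spearman_rho == pytest.approx(rho)

    def test_single_member_pooled_equals_pair(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        one = TargetMap({"m1": frozenset({"g1"})})
        pooled = screen(mirna, mrna, one, design, "JIA", "mirna")[0]
        pair = screen(mirna, mrna, one, design, "JIA", "pair")[0]
        assert pooled.pearson_r == pytest.approx(pair.pearson_r)
        assert pooled.spearman_rho == pytest.approx(pair.spearman_rho)

    def test_noiseless_planted_pair(self):
        b = generate_dataset(SimConfig(n_genes=100, n_mirnas=5, targets_per_mirna=5,
                                       group_sizes=(("JIA", 6), ("HC", 6)), noise_sd=0.0,
                                       repression_slope=1.0, n_regulated_pairs=1,
                                       frac_de_genes=0.0, frac_active_signatures=0.0, seed=2))
        (pair,) = {(m, g) for m, g, _ in b.truth.regulated_pairs}
        records = screen(b.mirna, b.mrna, b.targets, b.design, "JIA", "pair")
        rec = next(r for r in records if r.entity == pair)
        assert rec.pearson_r == pytest.approx(-1.0)


class TestPermutationPvalues:
    def test_constant_anchor_gives_p_one(self, make_expr):
        mirna = make_expr([[5.0, 5, 5, 5]], feature_ids=["m1"], kind="mirna")
        mrna = make_expr([[1.0, 2, 3, 4]], feature_ids=["g1"])
        targets = TargetMap({"m1": frozenset({"g1"})})
        design = SampleDesign({f"s{i + 1}": "JIA" for i in range(4)})
        records = screen(mirna, mrna, targets, design, "JIA", "pair")
        records = permutation_pvalues(records, mirna, mrna, targets, design, "JIA",
                                      n_perm=50, seed=0)
        assert records[0].perm_p == 1.0

    def test_extreme_statistic_gets_minimal_p(self):
        b = generate_dataset(SimConfig(n_genes=100, n_mirnas=5, targets_per_mirna=5,
                                       group_sizes=(("JIA", 10), ("HC", 6)), noise_sd=0.0,
                                       repression_slope=1.0, n_regulated_pairs=1,
                                       frac_de_genes=0.0, frac_active_signatures=0.0, seed=3))
        (pair,) = {(m, g) for m, g, _ in b.truth.regulated_pairs}
        records = screen(b.mirna, b.mrna, b.targets, b.design, "JIA", "pair")
        records = permutation_pvalues(records, b.mirna, b.mrna, b.targets, b.design,
                                      "JIA", n_perm=200, seed=4)
        rec = next(r for r in records if r.entity == pair)
        assert rec.perm_p <= 1 / 200

    def test_invariant_to_mirna_relabeling(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        records = permutation_pvalues(
            screen(mirna, mrna, targets, design, "JIA", "mirna"),
            mirna, mrna, targets, design, "JIA", n_perm=100, seed=7)
        renamed = mirna.data.rename(index={"m1": "zz1", "m2": "zz2"})
        from neutronet.io_formats import ExpressionMatrix
        mirna2 = ExpressionMatrix(renamed, "mirna")
        targets2 = TargetMap({"zz1": targets.targets["m1"], "zz2": targets.targets["m2"]})
        records2 = permutation_pvalues(
            screen(mirna2, mrna, targets2, design, "JIA", "mirna"),
            mirna2, mrna, targets2, design, "JIA", n_perm=100, seed=7)
        assert [r.perm_p for r in records] == [r.perm_p for r in records2]

    def test_add_one_mode_never_zero(self, toy_screen_inputs):
        mirna, mrna, targets, design = toy_screen_inputs
        records = permutation_pvalues(
            screen(mirna, mrna, targets, design, "JIA", "pair"),
            mirna, mrna, targets, design, "JIA", n_perm=20, seed=1, add_one=True)
        assert all(r.perm_p >= 1 / 21 for r in records)


class TestPlantedRecoveryAtStrongCoupling:
    def test_pair_screen_recovers_strongly_repressed_pairs(self):
        """With full repression coupling (slope 1.0, true r ~ -0.95) the
        pair-level screen recovers most planted pairs despite its stringent
        perm_p = 0 requirement."""
        sens = []
        for seed in range(5):
            b = generate_dataset(SimConfig(
                n_genes=500, n_mirnas=20, targets_per_mirna=20,
                group_sizes=(("JIA", 14), ("HC", 14)), n_regulated_pairs=20,
                repression_slope=1.0, noise_sd=0.5, frac_de_genes=0.0,
                frac_spliced_genes=0.0, frac_active_signatures=0.0, seed=seed))
            records = screen(b.mirna, b.mrna, b.targets, b.design, "JIA", "pair")
            records = permutation_pvalues(records, b.mirna, b.mrna, b.targets,
                                          b.design, "JIA", n_perm=1000, seed=seed)
            selected = {r.entity for r in select_significant(records, PAIR_LEVEL)}
            planted = {(m, g) for m, g, _ in b.truth.regulated_pairs}
            sens.append(len(planted & selected) / len(planted))
        assert np.mean(sens) >= 0.8


class TestSelectSignificant:
    def _rec(self, r, rho, p):
        return CorrelationRecord("pair", ("m", "g"), r, rho, 10, perm_p=p)

    def test_conjunction_rule(self):
        sel = select_significant([self._rec(-0.5, -0.5, 0.0)], PAIR_LEVEL)
        assert len(sel) == 1
        sel = select_significant([self._rec(-0.5, -0.1, 0.0)], PAIR_LEVEL)
        assert sel == []

    def test_p_boundary_is_strict(self):
        assert select_significant([self._rec(-0.5, -0.5, 0.001)], PAIR_LEVEL) == []

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ValueError):
            LevelThresholds(p_max=1e-3, r_max=0.1, rho_max=-0.1)

    def test_published_cutoffs(self):
        assert (MIRNA_LEVEL.r_max, GENE_LEVEL.r_max, PAIR_LEVEL.r_max) == (-0.0075, -0.02, -0.3)


class TestCompareNegativeDistributions:
    def _records(self, rs, level="mirna"):
        return [CorrelationRecord(level, f"m{i}", r, r, 10) for i, r in enumerate(rs)]

    def test_identical_lists_degenerate(self):
        a = self._records([-0.1 * i - 0.05 for i in range(8)])
        p, direction, n = compare_negative_distributions(a, a)
        assert p == 1.0 and direction == 0 and n == 8

    def test_uniform_shift_exact_signed_rank(self):
        a = self._records([-0.05 * (i + 1) for i in range(10)])
        b = self._records([r.pearson_r - 0.1 for r in a])
        p, direction, _ = compare_negative_distributions(a, b)
        assert p == pytest.approx(2 / 1024)
        assert direction == 1  # a - b > 0: b is more negative

    def test_pairing_is_order_independent(self):
        rng = np.random.default_rng(5)
        a = self._records(rng.uniform(-1, 0, 12))
        b = self._records(rng.uniform(-1, 0, 12))
        shuffled = list(b)
        rng.shuffle(shuffled)
        assert compare_negative_distributions(a, b) == compare_negative_distributions(a, shuffled)

    def test_too_few_pairs(self):
        a = self._records([-0.5, -0.4])
        with pytest.raises(InsufficientPairsError):
            compare_negative_distributions(a, a)
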