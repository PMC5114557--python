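"""Generators: determinism, closed-form expectations, constructed guarantees."""

import numpy as np
import pytest

from msabias import (
    CountModel,
    SimConfig,
    contact_map,
    gen_count_populations,
    gen_coupled_msa,
    gen_msa,
    gen_predictions,
    gen_structure,
    mean_entropy,
    neff,
    ranksums_test,
    top_l_precision,
)
from msabias.baseline_predictor import mutual_information
from msabias.synthetic_data import CA_SPACING, MIN_APPROACH, load_sim_config


class TestGenMsa:
    def test_diversity_one_forces_neff_one(self):
        aln = gen_msa(SimConfig(seed=0, length=25, depth=40, diversity=1))
        assert neff(aln) == 1.0

    def test_uniform_four_types_entropy_two_bits(self):
        aln = gen_msa(SimConfig(seed=1, length=30, depth=2000, diversity=4))
        assert mean_entropy(aln) == pytest.approx(2.0, abs=0.05)

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(seed=2, length=15, depth=30, diversity=8)
        assert gen_msa(cfg).rows == gen_msa(cfg).rows
        assert gen_msa(cfg).rows != gen_msa(SimConfig(seed=3, length=15,
                                                      depth=30, diversity=8)).rows

    def test_per_column_diversity_vector(self):
        ks = [1] * 5 + [20] * 5
        aln = gen_msa(SimConfig(seed=4, length=10, depth=2000, diversity=ks))
        mat = aln.to_matrix()
        observed = [len(np.unique(mat[:, c])) for c in range(10)]
        assert observed[:5] == [1] * 5
        assert all(k > 15 for k in observed[5:])

    def test_query_is_gap_free_with_gap_fraction(self):
        aln = gen_msa(SimConfig(seed=5, length=20, depth=50, gap_fraction=0.2))
        assert "-" not in aln.query
        assert any("-" in r for r in aln.rows[1:])

    def test_invalid_diversity_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(diversity=0)
        with pytest.raises(ValueError):
            SimConfig(diversity=21)


class TestGenCoupledMsa:
    def test_planted_map_has_exactly_the_planted_pairs(self):
        pairs = ((1, 8), (3, 12), (20, 30))
        _, planted = gen_coupled_msa(
            SimConfig(seed=6, length=30, depth=50, planted_pairs=pairs)
        )
        assert planted.pairs == frozenset(pairs)
        assert planted.length == 30

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ValueError, match="shares"):
            SimConfig(length=30, planted_pairs=((1, 8), (8, 15)))

    def test_close_pairs_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            SimConfig(length=30, planted_pairs=((1, 4),))

    def test_zero_coupling_indistinguishable_from_null(self):
        # MI at "planted" positions should look like background MI
        planted_mi, background_mi = [], []
        for seed in range(5):
            cfg = SimConfig(seed=seed, length=20, depth=200,
                            planted_pairs=((1, 10), (3, 15)), coupling=0.0)
            aln, planted = gen_coupled_msa(cfg)
            mi = mutual_information(aln).scores
            for i, j in planted.pairs:
                planted_mi.append(mi[i - 1, j - 1])
            background_mi.extend(
                [mi[4, 11], mi[5, 13], mi[6, 16], mi[7, 18]]
            )
        assert ranksums_test(planted_mi, background_mi).p_value > 0.05

    def test_determinism(self):
        cfg = SimConfig(seed=7, length=25, depth=60,
                        planted_pairs=((2, 9),), coupling=0.8)
        a1, _ = gen_coupled_msa(cfg)
        a2, _ = gen_coupled_msa(cfg)
        assert a1.rows == a2.rows


class TestGenStructure:
    def test_consecutive_ca_spacing(self, toy_chain):
        ca = np.array([r.ca_xyz for r in toy_chain.residues])
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(d, CA_SPACING, atol=1e-6)

    def test_self_avoidance(self, toy_chain):
        ca = np.array([r.ca_xyz for r in toy_chain.residues])
        n = len(ca)
        for i in range(n):
            for j in range(i + 2, n):
                assert np.linalg.norm(ca[i] - ca[j]) >= MIN_APPROACH - 1e-9

    def test_long_range_contact_guaranteed_at_length_30(self):
        for seed in range(4):
            coords = gen_structure(SimConfig(seed=seed, length=30))
            cmap = contact_map(coords)
            assert any(j - i >= 5 for i, j in cmap.pairs)

    def test_cb_offset(self, toy_chain):
        for r in toy_chain.residues:
            if r.cb_xyz is not None:
                d = np.linalg.norm(np.subtract(r.cb_xyz, r.ca_xyz))
                assert d == pytest.approx(1.5, abs=1e-6)

    def test_glycine_has_no_cb(self):
        coords = gen_structure(SimConfig(seed=21, length=60))
        glys = [r for r in coords.residues if r.aa == "G"]
        assert glys, "expect some glycines at L=60"
        assert all(r.cb_xyz is None for r in glys)

    def test_determinism(self):
        cfg = SimConfig(seed=8, length=25)
        c1, c2 = gen_structure(cfg), gen_structure(cfg)
        assert [r.ca_xyz for r in c1.residues] == [r.ca_xyz for r in c2.residues]


@pytest.fixture(scope="module")
def truth():
    return contact_map(gen_structure(SimConfig(seed=9, length=40)))


class TestGenPredictions:
    @pytest.mark.parametrize("ppv", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_planted_precision_closure(self, truth, ppv):
        K = 20
        preds = gen_predictions(truth, ppv, K=K, seed=3)
        res = top_l_precision(preds, truth, fraction=K / truth.length)
        assert res.n_considered == K
        assert res.ppv == pytest.approx(round(ppv * K) / K)

    def test_infeasible_target_rejected(self, truth):
        with pytest.raises(ValueError, match="cannot plant"):
            gen_predictions(truth, 1.0, K=10**6, seed=0)

    def test_scores_strictly_decreasing_and_deterministic(self, truth):
        p1 = gen_predictions(truth, 0.5, K=15, seed=4)
        p2 = gen_predictions(truth, 0.5, K=15, seed=4)
        assert p1.entries == p2.entries
        scores = [s for _, _, s in p1.entries]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestCountPopulations:
    def test_mean_ratio_near_six(self):
        struct, nostruct = gen_count_populations(SimConfig(seed=10))
        ratio = np.mean(struct) / np.mean(nostruct)
        assert ratio == pytest.approx(6.0, rel=0.2)

    def test_identical_models_give_null_pvalues(self):
        cm = CountModel(mu_struct=4.0, sigma_struct=1.5)
        pvals = []
        for seed in range(20):
            s, ns = gen_count_populations(
                SimConfig(seed=seed, count_model=CountModel(
                    mu_struct=4.0, sigma_struct=1.5,
                    n_struct=200, n_nostruct=200))
            )
            pvals.append(ranksums_test(s, ns).p_value)
        # under the null p-values are ~uniform: few small, wide spread
        assert np.mean(np.array(pvals) < 0.05) <= 0.25
        assert max(pvals) > 0.5

    def test_seed_determinism(self):
        cfg = SimConfig(seed=11)
        assert gen_count_populations(cfg) == gen_count_populations(cfg)

    def test_nonpositive_sizes_rejected(self):
        cfg = SimConfig(count_model=CountModel(n_struct=0))
        with pytest.raises(ValueError):
            gen_count_populations(cfg)

    def test_populations_significantly_different(self):
        # the selection-bias signal in miniature
        s, ns = gen_count_populations(SimConfig(seed=12))
        assert ranksums_test(s, ns).p_value < 1e-10


def test_load_sim_config_from_mapping():
    cfg = load_sim_config(
        {
            "seed": 5,
            "length": 30,
            "depth": 10,
            "planted_pairs": [[1, 8], [3, 12]],
            "count_model": {"n_struct": 100, "n_nostruct": 50},
        }
    )
    assert cfg.planted_pairs == ((1, 8), (3, 12))
    assert cfg.count_model.n_struct == 100
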