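"""CRISPR arm: counting, normalization, dispersion, NB Wald test, aggregation."""

import numpy as np
import pandas as pd
import pytest

from screenforge import (
    CrisprSimParams,
    aggregate_to_genes,
    count_sgrnas,
    estimate_dispersion,
    make_design,
    make_slc_library,
    nb_wald_test,
    run_crispr_screen,
    select_significant,
    simulate_crispr_counts,
    size_factors,
)


@pytest.fixture(scope="module")
def small_screen():
    lib = make_slc_library(seed=0).head(120).reset_index(drop=True)
    params = CrisprSimParams(
        library=lib, design=make_design(3),
        resistance_genes={"SLC000", "SLC001"}, effect_lfc=3.0,
        efficacy_prob=1.0, seed=12,
    )
    counts, truth = simulate_crispr_counts(params)
    return params, counts, truth


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def test_count_sgrnas_exact_composition(slc_library):
    lib = slc_library.head(10)
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    reads = []
    for spacer in lib["spacer"]:
        for _ in range(100):
            left = "".join(bases[rng.integers(0, 4, 10)])
            right = "".join(bases[rng.integers(0, 4, 10)])
            reads.append(left + spacer + right)
    counts, qc = count_sgrnas(reads, lib)
    assert (counts == 100).all()
    assert qc == {"assigned": 1000, "unassigned": 0, "ambiguous": 0}


def test_count_sgrnas_unassigned_and_ambiguous(slc_library):
    lib = slc_library.head(5)
    sp = lib["spacer"].tolist()
    reads = ["T" * 40, sp[0] + sp[1]]
    counts, qc = count_sgrnas(reads, lib)
    assert qc["unassigned"] == 1 and qc["ambiguous"] == 1
    assert counts.sum() == 0


def test_count_sgrnas_hamming1_rescue(slc_library):
    lib = slc_library.head(5)
    sp = lib["spacer"].iloc[0]
    mutated = ("A" if sp[3] != "A" else "C").join([sp[:3], sp[4:]])
    counts, qc = count_sgrnas([mutated], lib, hamming1=True)
    assert counts.iloc[0] == 1 and qc["assigned"] == 1
    counts, qc = count_sgrnas([mutated], lib, hamming1=False)
    assert qc["unassigned"] == 1


def test_count_sgrnas_rejects_duplicate_spacers(slc_library):
    lib = pd.concat([slc_library.head(2)] * 2, ignore_index=True)
    lib["sgrna_id"] = ["a", "b", "c", "d"]
    with pytest.raises(ValueError, match="duplicate spacers"):
        count_sgrnas([], lib)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_samples():
    c = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
    assert np.allclose(size_factors(c), [1.0, 1.0])


def test_size_factors_hand_example():
    c = pd.DataFrame([[2, 4], [2, 4]], columns=["s1", "s2"])
    assert np.allclose(size_factors(c), [2 ** -0.5, 2 ** 0.5])


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(5)
    c = pd.DataFrame(rng.poisson(100, size=(200, 4)),
                     columns=list("abcd")) + 1
    base = size_factors(c)
    scaled = c.copy()
    scaled["c"] *= 10
    s2 = size_factors(scaled)
    # ratio of sample c's factor to the others rises exactly 10-fold
    assert np.allclose((s2 / base) / (s2 / base)["a"],
                       [1, 1, 10, 1], rtol=1e-9)


def test_size_factors_fallback_warns():
    c = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
    with pytest.warns(UserWarning, match="total-count"):
        s = size_factors(c)
    assert np.allclose(np.exp(np.log(s).mean()), 1.0)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_dispersion_poisson_limit_small():
    rng = np.random.default_rng(6)
    design = make_design(3)
    counts = pd.DataFrame(rng.poisson(1000, size=(500, len(design))),
                          columns=design["sample_id"])
    s = pd.Series(1.0, index=counts.columns)
    disp = estimate_dispersion(counts, s, design)
    assert np.median(disp) <= 0.01


def test_dispersion_recovery():
    params = CrisprSimParams(design=make_design(3), dispersion=0.1, seed=7)
    counts, _ = simulate_crispr_counts(params)
    s = size_factors(counts)
    disp = estimate_dispersion(counts, s, params.design)
    assert 0.05 <= np.median(disp) <= 0.2


def test_dispersion_floor_on_constant_counts():
    design = make_design(2)
    counts = pd.DataFrame(100, index=range(5), columns=design["sample_id"])
    disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns),
                               design)
    assert (disp == 1e-8).all()


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def test_wald_exact_symmetry_on_copied_arms():
    rng = np.random.default_rng(8)
    design = make_design(2)
    n = 50
    half = rng.negative_binomial(20, 20 / 520, size=(n, 4))
    # treated columns are byte-copies of control columns
    counts = pd.DataFrame(
        np.zeros((n, 8), dtype=int), columns=design["sample_id"])
    for t in ("initial", "final"):
        ctrl = design.query("time == @t and treatment == 'control'")["sample_id"]
        trt = design.query("time == @t and treatment == 'treated'")["sample_id"]
        block = half[:, :2] if t == "initial" else half[:, 2:]
        counts[list(ctrl)] = block
        counts[list(trt)] = block
    s = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(0.05, index=counts.index)
    res = nb_wald_test(counts, design, s, disp)
    assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
    assert np.allclose(res["p"], 1.0, atol=1e-6)


def test_wald_agrees_with_statsmodels_glm(small_screen):
    sm = pytest.importorskip("statsmodels.api")
    from screenforge.crispr import design_matrix

    params, counts, _ = small_screen
    sub = counts.iloc[:25]
    s = size_factors(counts)
    disp = estimate_dispersion(counts, s, params.design).iloc[:25]
    res = nb_wald_test(sub, params.design, s, disp)
    X = design_matrix(params.design, sub.columns)
    off = np.log(s.to_numpy())
    for i in range(len(sub)):
        fit = sm.GLM(
            sub.iloc[i].to_numpy(), X,
            family=sm.families.NegativeBinomial(alpha=float(disp.iloc[i])),
            offset=off,
        ).fit()
        assert res["log2fc"].iloc[i] == pytest.approx(
            fit.params[2] / np.log(2), abs=1e-6)
        assert res["wald_z"].iloc[i] == pytest.approx(
            fit.params[2] / fit.bse[2], rel=1e-4, abs=1e-6)


def test_wald_effect_recovery(small_screen):
    params, counts, truth = small_screen
    s = size_factors(counts)
    disp = estimate_dispersion(counts, s, params.design)
    res = nb_wald_test(counts, params.design, s, disp)
    enriched = res[res["sgrna_id"].isin(truth.true_sgrnas())]
    assert enriched["log2fc"].mean() == pytest.approx(3.0, abs=0.3)


def test_wald_all_zero_sgrna_flagged():
    design = make_design(2)
    rng = np.random.default_rng(9)
    counts = pd.DataFrame(rng.poisson(100, size=(10, 8)),
                          columns=design["sample_id"])
    counts.iloc[0] = 0
    s = pd.Series(1.0, index=counts.columns)
    disp = pd.Series(0.05, index=counts.index)
    res = nb_wald_test(counts, design, s, disp)
    assert not res["converged"].iloc[0]
    assert res["p"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# selection and aggregation
# ---------------------------------------------------------------------------

def test_select_significant_contract():
    res = pd.DataFrame({
        "sgrna_id": list("ABCD"),
        "log2fc": [4.0, 2.0, 3.0, -1.5],
        "padj": [0.01, 0.02, 0.03, 0.01],
    })
    sel = select_significant(res)
    assert sel["sgrna_id"].tolist() == ["A", "C", "B"]  # D: negative lfc


def test_select_significant_empty():
    res = pd.DataFrame({"sgrna_id": ["A"], "log2fc": [1.0], "padj": [0.5]})
    assert select_significant(res).empty


def test_aggregation_requires_two_sgrnas(slc_library):
    ranked = pd.DataFrame({
        "sgrna_id": ["SLC000_sg0", "SLC001_sg0", "SLC001_sg1"],
        "log2fc": [3.0, 2.0, 1.0],
    })
    hits = aggregate_to_genes(ranked, slc_library, n_perm=200, seed=0)
    assert hits["gene_id"].tolist() == ["SLC001"]
    assert (hits["n_sig_sgrnas"] >= 2).all()


def test_aggregation_single_gene_unit_es(slc_library):
    ranked = pd.DataFrame({
        "sgrna_id": [f"SLC000_sg{k}" for k in range(3)],
        "log2fc": [3.0, 2.0, 1.0],
    })
    hits = aggregate_to_genes(ranked, slc_library, n_perm=200, seed=0)
    assert hits["es"].iloc[0] == 1.0


def test_aggregation_matches_exhaustive_small_case(slc_library):
    # 6 ranked sgRNAs from 2 genes: C(6,4)=15 placements, enumerated exactly
    ranked = pd.DataFrame({
        "sgrna_id": ["SLC000_sg0", "SLC001_sg0", "SLC000_sg1",
                     "SLC000_sg2", "SLC001_sg1", "SLC000_sg3"],
        "log2fc": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
    })
    hits = aggregate_to_genes(ranked, slc_library, n_perm=1000, seed=0)
    from itertools import combinations

    def naive_es(scores, mask):
        k = sum(mask)
        norm = sum(s for s, m in zip(scores, mask) if m)
        run, best = 0.0, 0.0
        for s_, m in zip(scores, mask):
            run += s_ / norm if m else -1.0 / (len(scores) - k)
            if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
                best = run
        return best

    scores = ranked["log2fc"].tolist()
    for gene, mask in (("SLC000", [1, 0, 1, 1, 0, 1]),
                       ("SLC001", [0, 1, 0, 0, 1, 0])):
        obs = naive_es(scores, mask)
        k = sum(mask)
        es_all = []
        for combo in combinations(range(6), k):
            m = [i in combo for i in range(6)]
            es_all.append(naive_es(scores, m))
        p_ref = (np.mean([(e >= obs) if obs >= 0 else (e <= obs)
                          for e in es_all]))
        row = hits.set_index("gene_id").loc[gene]
        assert row["es"] == pytest.approx(obs)
        assert row["p_perm"] == pytest.approx(p_ref)


def test_gene_hits_never_below_two_ranked_sgrnas(slc_library):
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(3, 25))
        ids = rng.choice(slc_library["sgrna_id"].to_numpy(), size=n,
                         replace=False)
        ranked = pd.DataFrame({
            "sgrna_id": ids,
            "log2fc": np.sort(rng.uniform(0.1, 5, n))[::-1],
        })
        hits = aggregate_to_genes(ranked, slc_library, n_perm=100, seed=1)
        assert hits.empty or (hits["n_sig_sgrnas"] >= 2).all()


# ---------------------------------------------------------------------------
# end to end
# ---------------------------------------------------------------------------

def test_run_crispr_screen_recovers_truth_and_is_deterministic(small_screen):
    params, counts, truth = small_screen
    res1, hits1 = run_crispr_screen(counts, params.library, params.design,
                                    seed=3)
    res2, hits2 = run_crispr_screen(counts, params.library, params.design,
                                    seed=3)
    pd.testing.assert_frame_equal(res1, res2)
    pd.testing.assert_frame_equal(hits1, hits2)
    top = set(hits1["gene_id"].head(5))
    assert {"SLC000", "SLC001"} <= top


def test_run_crispr_screen_null_near_empty():
    lib = make_slc_library(seed=0).head(120).reset_index(drop=True)
    params = CrisprSimParams(library=lib, design=make_design(3),
                             resistance_genes=set(), effect_lfc=0.0, seed=21)
    counts, _ = simulate_crispr_counts(params)
    _, hits = run_crispr_screen(counts, lib, params.design, seed=21)
    assert len(hits) <= 1


def test_design_validation():
    bad = make_design(2).query("time == 'initial'")
    params = CrisprSimParams(design=bad.reset_index(drop=True))
    with pytest.raises(ValueError, match="treated-final"):
        params.validate()
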