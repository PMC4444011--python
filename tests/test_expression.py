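import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from pausewave import (
    CountMatrix,
    CountSimParams,
    GeneModel,
    build_expression_table,
    call_reactive_genes,
    compute_rpkm,
    corrected_l2fc,
    simulate_counts,
    tmm_factors,
)
from pausewave.simulate import synthetic_gene_models


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------


def test_rpkm_unit_denominators(toy_counts, toy_genes):
    rpkm = compute_rpkm(toy_counts, toy_genes)
    assert rpkm.loc["g1", "mock"] == pytest.approx(10.0)  # 10 / 1kb / 1M
    assert rpkm.loc["g2", "mock"] == 0.0


def test_rpkm_matches_loop_oracle(rng):
    n, s = 50, 3
    counts = rng.integers(0, 500, size=(n, s))
    lib = rng.integers(10**6, 10**7, size=s)
    lengths = rng.integers(200, 5000, size=n)
    gene_ids = [f"g{i}" for i in range(n)]
    cm = CountMatrix(gene_ids, [f"s{j}" for j in range(s)], counts, lib)
    genes = [
        GeneModel(g, "chr1", "+", ((0, int(ln)),))
        for g, ln in zip(gene_ids, lengths)
    ]
    rpkm = compute_rpkm(cm, genes)
    for i in range(n):
        for j in range(s):
            expected = counts[i, j] / (lengths[i] / 1000) / (lib[j] / 1e6)
            assert rpkm.iloc[i, j] == pytest.approx(expected, rel=1e-12)


def test_rpkm_invariant_to_joint_count_and_library_scaling(toy_counts, toy_genes):
    scaled = CountMatrix(
        toy_counts.gene_ids,
        toy_counts.sample_ids,
        toy_counts.counts * 7,
        toy_counts.library_sizes * 7,
    )
    assert np.allclose(
        compute_rpkm(toy_counts, toy_genes), compute_rpkm(scaled, toy_genes)
    )


def test_rpkm_missing_gene_model_errors(toy_counts, toy_genes):
    with pytest.raises(ValueError, match="g3"):
        compute_rpkm(toy_counts, toy_genes[:2])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_reference_recipe(counts, lib, ref_idx):
    """Independently coded trim-and-weight recipe (explicit loops/sorting)."""
    n_samples = counts.shape[1]
    factors = []
    for j in range(n_samples):
        obs, ref = counts[:, j], counts[:, ref_idx]
        rows = [
            (o, r)
            for o, r in zip(obs, ref)
            if o > 0 and r > 0
        ]
        m = [np.log2((o / lib[j]) / (r / lib[ref_idx])) for o, r in rows]
        a = [0.5 * np.log2((o / lib[j]) * (r / lib[ref_idx])) for o, r in rows]
        w = [
            (lib[j] - o) / (lib[j] * o) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
            for o, r in rows
        ]
        if max(abs(x) for x in m) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        lo_l, hi_l = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_s, hi_s = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        from scipy.stats import rankdata

        rm, ra = rankdata(m), rankdata(a)
        num = den = 0.0
        for k in range(n):
            if lo_l <= rm[k] <= hi_l and lo_s <= ra[k] <= hi_s:
                num += m[k] / w[k]
                den += 1.0 / w[k]
        factors.append(2.0 ** (num / den))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def _random_pair(rng, n=200, contaminated=True):
    counts = rng.negative_binomial(5, 0.02, size=(n, 2))
    counts = np.maximum(counts, 0)
    if contaminated:
        idx = rng.choice(n, n // 20, replace=False)
        counts[idx, 1] *= 20  # 5% high-count contaminants
    return counts


def test_tmm_identical_libraries_give_unit_factors(toy_counts):
    cm = CountMatrix(
        toy_counts.gene_ids,
        ["a", "b"],
        np.column_stack([toy_counts.counts[:, 0]] * 2),
        np.array([10**6, 10**6]),
    )
    assert np.allclose(tmm_factors(cm), 1.0)


def test_tmm_doubled_library_gives_unit_factors(toy_counts):
    col = toy_counts.counts[:, 0]
    cm = CountMatrix(
        toy_counts.gene_ids,
        ["a", "b"],
        np.column_stack([col, col * 2]),
        np.array([col.sum(), 2 * col.sum()]),
    )
    assert np.allclose(tmm_factors(cm), 1.0)


def test_tmm_matches_independent_recipe_on_contaminated_pairs(rng):
    for _ in range(10):
        counts = _random_pair(rng)
        lib = counts.sum(axis=0)
        cm = CountMatrix(
            [f"g{i}" for i in range(len(counts))], ["a", "b"], counts, lib
        )
        ours = tmm_factors(cm, reference_sample="a").to_numpy()
        theirs = _tmm_reference_recipe(counts.astype(float), lib.astype(float), 0)
        assert np.allclose(ours, theirs, atol=1e-10)


def test_tmm_matches_edger(tmp_path, rng):
    """Cross-check factors against the Bioconductor implementation."""
    counts = rng.negative_binomial(5, 0.02, size=(300, 4))
    counts[rng.choice(300, 15, replace=False), 1] *= 20
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(300)],
                      columns=list("ABCD"))
    csv = tmp_path / "counts.csv"
    df.to_csv(csv)
    script = textwrap.dedent(
        f"""
        suppressMessages(library(edgeR))
        m <- as.matrix(read.csv("{csv}", row.names=1))
        cat(sprintf("%.12f", calcNormFactors(m)), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    edger = np.array([float(x) for x in out.stdout.split()])
    cm = CountMatrix(list(df.index), list(df.columns), counts,
                     counts.sum(axis=0))
    assert np.allclose(tmm_factors(cm).to_numpy(), edger, atol=1e-9)


def test_tmm_factor_nearly_invariant_to_scaling_one_library(rng):
    """Library-size scaling absorbs a depth change: the M-values and the
    trimming are exactly depth-invariant, so the factors move only through
    the delta-method precision weights (a sub-percent effect)."""
    counts = _random_pair(rng)
    cm1 = CountMatrix(["g%d" % i for i in range(len(counts))], ["a", "b"],
                      counts, counts.sum(axis=0))
    scaled = counts.copy()
    scaled[:, 1] *= 5
    cm2 = CountMatrix(cm1.gene_ids, ["a", "b"], scaled, scaled.sum(axis=0))
    f1 = tmm_factors(cm1, "a").to_numpy()
    f2 = tmm_factors(cm2, "a").to_numpy()
    assert np.allclose(f1, f2, rtol=0.02)
    # the unweighted statistic is exactly invariant: same trimmed M-sets
    assert np.allclose(np.log2(f1), np.log2(f2), atol=0.02)


def test_tmm_requires_shared_nonzero_genes():
    counts = np.array([[5, 0], [7, 0], [0, 3]])
    cm = CountMatrix(["g1", "g2", "g3"], ["a", "b"], counts, np.array([12, 3]))
    with pytest.raises(ValueError, match="TMM|both samples"):
        tmm_factors(cm, "a")


# ---------------------------------------------------------------------------
# corrected log2 fold change
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fc,exp_term,expected",
    [
        (1.0, 0.0, 1.0),      # correction 5^0 = 1, sign of zero is +
        (2.0, 1.0, 1.2),      # 1 + 1/5
        (4.0, 10.0, 2.0),     # correction < 2e-7: vanished
    ],
)
def test_corrected_l2fc_direct_substitution(fc, exp_term, expected):
    assert corrected_l2fc(fc, exp_term) == pytest.approx(expected, abs=1e-6)


def test_corrected_l2fc_rejects_bad_inputs():
    with pytest.raises(ValueError, match="fold change"):
        corrected_l2fc(0.0, 1.0)
    with pytest.raises(ValueError, match="gamma"):
        corrected_l2fc(2.0, 1.0, gamma=1.0)


@given(
    l2fc=st.floats(-8, 8, allow_nan=False),
    exp_term=st.floats(-2, 6, allow_nan=False),
)
@settings(derandomize=True, max_examples=200)
def test_corrected_l2fc_is_odd_in_l2fc(l2fc, exp_term):
    assume(abs(l2fc) > 1e-6)  # away from the sign-of-zero boundary
    fc = 2.0**l2fc
    up = corrected_l2fc(fc, exp_term)
    down = corrected_l2fc(1.0 / fc, exp_term)
    assert up == pytest.approx(-down, rel=1e-9, abs=1e-12)


def test_correction_decreases_monotonically_with_expression():
    exp = np.linspace(-1, 8, 50)
    corr = corrected_l2fc(np.full_like(exp, 2.0), exp) - 1.0
    assert np.all(np.diff(corr) < 0)
    assert corr[-1] < 1e-5


def test_literal_formula_is_asymmetric():
    sym = corrected_l2fc(0.5, 0.0)             # -(1 + 1) = -2
    lit = corrected_l2fc(0.5, 0.0, literal=True)  # -1 + 1 = 0
    assert sym == pytest.approx(-2.0)
    assert lit == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# reactive-gene calling
# ---------------------------------------------------------------------------


def test_call_reactive_threshold_and_direction():
    table = pd.DataFrame(
        {
            "l2fc": [2.4, -3.0, 0.2],
            "corrected_l2fc": [2.5, -3.1, 0.4],
        },
        index=["up_gene", "down_gene", "flat_gene"],
    )
    hits = call_reactive_genes(table, threshold=2.0)
    assert set(hits.index) == {"up_gene", "down_gene"}
    assert hits.loc["up_gene", "direction"] == "up"
    assert hits.loc["down_gene", "direction"] == "down"


def test_call_reactive_empty_table():
    empty = pd.DataFrame(columns=["l2fc", "corrected_l2fc"])
    assert call_reactive_genes(empty, 1.0).empty


def test_reactive_calling_recovers_planted_responders():
    """Strongly planted effects are recalled; null genes rarely called.

    Mock means are kept in the well-expressed regime (>= ~100 counts);
    recall is measured over responders planted clearly past the threshold,
    since mean-zero planted effects below it are invisible to any
    fold-change cutoff.
    """
    params = CountSimParams(
        n_genes=6000, baseline_mean=300.0, baseline_log10_sd=0.4,
        effect_sd=2.0, seed=123,
    )
    cm, truth = simulate_counts(params)
    genes = synthetic_gene_models(cm.gene_ids, seed=123)
    table = build_expression_table(cm, genes, "drb", "mock")
    called = set(call_reactive_genes(table, threshold=1.0).index)
    planted = truth[
        truth["group"].isin(["shared", "drb_only"])
        & (truth["l2fc_drb"].abs() >= 1.75)
    ]
    null = truth[truth["l2fc_drb"] == 0]
    recall = len(planted.index.intersection(called)) / len(planted)
    false_rate = len(null.index.intersection(called)) / len(null)
    assert recall >= 0.9
    assert false_rate <= 0.05


def test_expression_table_carries_contrast_metadata(toy_counts, toy_genes):
    table = build_expression_table(toy_counts, toy_genes, "treated", "mock")
    assert table.attrs["contrast"] == ("treated", "mock")
    assert set(table.columns) >= {
        "rpkm_mock", "rpkm_treated", "exp_term", "l2fc", "corrected_l2fc"
    }
    factors = table.attrs["tmm_factors"]
    gm = np.exp(np.mean(np.log(list(factors.values()))))
    assert gm == pytest.approx(1.0)
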