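from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np
import pytest

import hybridzone as hz
from hybridzone.data_model_io import GenotypePanel, SpeciesLabel
from hybridzone.marker_qc import _levene_weights


def brute_force_het_distribution(n_AA, n_Aa, n_aa):
    """Independent oracle: enumerate every distinct assignment of the allele
    multiset into n ordered diploids and count heterozygote outcomes."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    alleles = "A" * n_A + "a" * (2 * n - n_A)
    counts = {}
    for perm in set(permutations(alleles)):
        h = sum(1 for i in range(n) if perm[2 * i] != perm[2 * i + 1])
        counts[h] = counts.get(h, 0) + 1
    total = sum(counts.values())
    return {h: Fraction(c, total) for h, c in counts.items()}


@pytest.mark.parametrize(
    "counts,alt,expected",
    [
        ((1, 0, 1), "deficit", 1 / 3),
        ((0, 2, 0), "excess", 2 / 3),
        ((2, 1, 1), "deficit", None),  # checked against the brute force below
    ],
)
def test_hwe_exact_matches_enumeration(counts, alt, expected):
    res = hz.hwe_exact_test(*counts, alt)
    dist = brute_force_het_distribution(*counts)
    obs = counts[1]
    p_def = float(sum(p for h, p in dist.items() if h <= obs))
    p_exc = float(sum(p for h, p in dist.items() if h >= obs))
    assert res.p_deficit == pytest.approx(p_def, abs=1e-12)
    assert res.p_excess == pytest.approx(p_exc, abs=1e-12)
    if expected is not None:
        got = res.p_deficit if alt == "deficit" else res.p_excess
        assert got == pytest.approx(expected, abs=1e-12)


def test_hwe_monomorphic_not_testable():
    res = hz.hwe_exact_test(5, 0, 0, "deficit")
    assert not res.testable
    assert res.p_deficit is None and res.p_excess is None


def test_levene_distribution_normalised_and_onesided_bounds():
    """For every allele configuration with n <= 16 the conditional
    distribution sums to 1 exactly, and deficit+excess p-values overlap in
    the observed configuration (sum >= 1)."""
    for n in range(1, 17):
        for n_a in range(1, n + 1):  # minor-side allele count
            support, probs = _levene_weights(n, n_a)
            assert sum(probs) == Fraction(1)
            # closed-form pairing count agrees cell by cell (independent
            # derivation: multinomial pairings normalised by C(2n, n_a))
            from math import factorial

            denom = factorial(2 * n) // (factorial(n_a) * factorial(2 * n - n_a))
            for h, p in zip(support, probs):
                ways = (
                    factorial(n)
                    // (
                        factorial((n_a - h) // 2)
                        * factorial(h)
                        * factorial((2 * n - n_a - h) // 2)
                    )
                    * 2**h
                )
                assert p == Fraction(ways, denom)
    res = hz.hwe_exact_test(3, 2, 2, "deficit")
    assert res.p_deficit + res.p_excess >= 1.0


@pytest.mark.parametrize(
    "args,expected",
    [((0.05, 32), 0.0015625), ((0.05, 1), 0.05), ((0.01, 4), 0.0025)],
)
def test_corrected_alpha(args, expected):
    assert hz.corrected_alpha(*args) == pytest.approx(expected, abs=1e-15)


def _panel_from_genotypes(geno_by_loc, n_markers=1):
    ids, locs, rows = [], [], []
    k = 0
    for loc, genos in geno_by_loc.items():
        for g in genos:
            ids.append(f"i{k}")
            locs.append(loc)
            rows.append([g] * n_markers)
            k += 1
    return GenotypePanel(ids, locs, [f"m{j}" for j in range(n_markers)],
                         np.array(rows, dtype=np.int8))


def test_screen_hwe_excludes_forced_deficit_marker():
    # all heterozygotes recoded homozygous: extreme deficit in 4 populations
    genos = [0] * 8 + [2] * 8  # p = 0.5, zero heterozygotes, n = 16
    panel = _panel_from_genotypes({f"p{j}": genos for j in range(4)})
    decisions = hz.screen_hwe(panel, alpha=0.05, min_sig_pops=2,
                              n_markers_correction=32)
    assert len(decisions) == 1
    assert decisions[0].n_significant_populations == 4
    assert decisions[0].excluded


def test_screen_hwe_type_i_control_under_equilibrium():
    """Genotypes drawn at HWE should essentially never be excluded at the
    corrected threshold."""
    rng = np.random.default_rng(5)
    n_excluded = 0
    for rep in range(20):
        rows = rng.binomial(2, 0.5, size=(4 * 16, 5))
        locs = [f"p{j}" for j in range(4) for _ in range(16)]
        panel = GenotypePanel([f"i{k}" for k in range(64)], locs,
                              [f"m{j}" for j in range(5)], rows.astype(np.int8))
        decisions = hz.screen_hwe(panel, 0.05, 2, n_markers_correction=32)
        n_excluded += sum(d.excluded for d in decisions)
    assert n_excluded == 0


def test_screen_hwe_empty_panel_returns_empty_list():
    panel = GenotypePanel(["a"], ["w"], ["m1"], np.array([[0]], dtype=np.int8))
    sub = panel.subset_individuals(np.array([False]))
    assert hz.screen_hwe(sub) == []


def test_ld_test_copy_marker_hits_floor_and_is_reproducible():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.5, size=40).astype(np.int8)
    rows = np.column_stack([g, g])
    panel = GenotypePanel([f"i{k}" for k in range(40)], ["p1"] * 20 + ["p2"] * 20,
                          ["a", "b"], rows)
    p1 = hz.ld_test(panel, "a", "b", n_permutations=99, seed=7)
    p2 = hz.ld_test(panel, "a", "b", n_permutations=99, seed=7)
    assert p1 == pytest.approx(1 / 100)
    assert p1 == p2  # bit-reproducible under the seed


def test_ld_test_null_calibration_for_independent_markers():
    """p-values for independently simulated markers should look uniform:
    no excess of small values across replicates."""
    rng = np.random.default_rng(11)
    pvals = []
    for rep in range(20):
        rows = rng.binomial(2, 0.5, size=(60, 2)).astype(np.int8)
        panel = GenotypePanel([f"i{k}" for k in range(60)],
                              ["p1"] * 30 + ["p2"] * 30, ["a", "b"], rows)
        pvals.append(hz.ld_test(panel, "a", "b", n_permutations=99, seed=rep))
    pvals = np.array(pvals)
    assert (pvals <= 0.05).mean() <= 0.25
    assert pvals.mean() == pytest.approx(0.5, abs=0.25)


def test_ld_test_monomorphic_marker_flagged():
    rows = np.column_stack([np.zeros(10), np.random.default_rng(0).binomial(2, 0.5, 10)])
    panel = GenotypePanel([f"i{k}" for k in range(10)], ["p"] * 10,
                          ["mono", "seg"], rows.astype(np.int8))
    assert hz.ld_test(panel, "mono", "seg", 99, 0) is None


def test_diagnosticity_screen_retains_only_fixed_markers():
    rng = np.random.default_rng(3)
    n = 10
    fixed = np.vstack([np.zeros((n, 10)), np.full((n, 10), 2)])
    shared = rng.binomial(2, 0.5, size=(2 * n, 3))
    rows = np.hstack([fixed, shared]).astype(np.int8)
    markers = [f"fix{j}" for j in range(10)] + [f"shared{j}" for j in range(3)]
    panel = GenotypePanel([f"i{k}" for k in range(2 * n)],
                          ["nest_ref"] * n + ["ophr_ref"] * n, markers, rows)
    refs = {"nest_ref": SpeciesLabel.NESTEROVI, "ophr_ref": SpeciesLabel.OPHRYTICUS}
    kept = hz.diagnosticity_screen(panel, refs)
    assert kept == [f"fix{j}" for j in range(10)]
    with pytest.raises(ValueError, match="both species"):
        hz.diagnosticity_screen(panel, {"nest_ref": SpeciesLabel.NESTEROVI})
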