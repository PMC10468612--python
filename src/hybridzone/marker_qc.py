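"""Diagnostic-SNP panel screening.

Exact Hardy-Weinberg deficit/excess tests per marker x population (Levene's
conditional distribution over heterozygote counts, fully enumerated — sample
sizes here are at most a few dozen per locality, so enumeration is exact and
cheap), genotypic linkage-disequilibrium permutation tests stratified within
localities, Bonferroni-style per-test correction, marker exclusion decisions,
and a diagnosticity screen against pure reference populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import factorial

import numpy as np

from .data_model_io import MISSING, GenotypePanel, SpeciesLabel


@dataclass
class HweResult:
    marker_id: str
    locality_code: str
    n_AA: int
    n_Aa: int
    n_aa: int
    p_deficit: float | None
    p_excess: float | None
    testable: bool


@dataclass
class QcDecision:
    marker_id: str
    n_significant_populations: int
    excluded: bool


@lru_cache(maxsize=4096)
def _levene_weights(n: int, n_a: int) -> tuple[tuple[int, ...], tuple[Fraction, ...]]:
    """Exact conditional distribution of heterozygote count.

    Given ``n`` diploids carrying ``n_a`` copies of the minor-side allele
    (n_a <= n alleles of one type out of 2n), returns the support (possible
    heterozygote counts, matching the parity of n_a) and exact probabilities
    P(h) ∝ 2^h / ((n_a - h)/2)! h! ((2n - n_a - h)/2)!
    """
    n_b = 2 * n - n_a
    support = []
    weights = []
    h = n_a % 2
    while h <= min(n_a, n_b):
        w = Fraction(2**h, factorial((n_a - h) // 2) * factorial(h) * factorial((n_b - h) // 2))
        support.append(h)
        weights.append(w)
        h += 2
    total = sum(weights)
    return tuple(support), tuple(w / total for w in weights)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, alternative: str) -> HweResult:
    """One-sided exact HWE test conditional on allele counts.

    ``deficit`` is P(het <= observed), ``excess`` is P(het >= observed),
    under Levene's distribution. A monomorphic sample is flagged untestable
    and carries no p-value.
    """
    if alternative not in ("deficit", "excess"):
        raise ValueError("alternative must be 'deficit' or 'excess'")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty sample")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return HweResult("", "", n_AA, n_Aa, n_aa, None, None, testable=False)
    support, probs = _levene_weights(n, min(n_A, n_a))
    obs = n_Aa
    p_def = float(sum(p for h, p in zip(support, probs) if h <= obs))
    p_exc = float(sum(p for h, p in zip(support, probs) if h >= obs))
    return HweResult("", "", n_AA, n_Aa, n_aa, p_def, p_exc, testable=True)


def corrected_alpha(alpha: float, n_tests: int) -> float:
    """Per-test Bonferroni threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _genotype_counts(panel: GenotypePanel, marker_idx: int, mask: np.ndarray) -> tuple[int, int, int]:
    g = panel.dosage[mask, marker_idx]
    g = g[g != MISSING]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_table(panel: GenotypePanel) -> list[HweResult]:
    """Exact HWE results for every marker x locality combination."""
    out = []
    for loc in panel.localities():
        mask = panel.locality_mask(loc)
        for j, m in enumerate(panel.marker_ids):
            nAA, nAa, naa = _genotype_counts(panel, j, mask)
            if nAA + nAa + naa == 0:
                out.append(HweResult(m, loc, 0, 0, 0, None, None, testable=False))
                continue
            r = hwe_exact_test(nAA, nAa, naa, "deficit")
            out.append(HweResult(m, loc, nAA, nAa, naa, r.p_deficit, r.p_excess, r.testable))
    return out


def screen_hwe(
    panel: GenotypePanel,
    alpha: float = 0.05,
    min_sig_pops: int = 2,
    n_markers_correction: int | None = None,
    direction: str = "deficit",
) -> list[QcDecision]:
    """Flag markers with corrected-significant heterozygote deficit in
    ``min_sig_pops`` or more populations.

    The significance threshold is ``alpha / N`` where N defaults to the panel
    marker count (correction across markers within each population's batch).
    """
    if panel.n_individuals == 0 or panel.n_markers == 0:
        return []
    n_corr = n_markers_correction or panel.n_markers
    thresh = corrected_alpha(alpha, n_corr)
    counts = {m: 0 for m in panel.marker_ids}
    for res in hwe_table(panel):
        if not res.testable:
            continue
        p = res.p_deficit if direction == "deficit" else res.p_excess
        if p is not None and p <= thresh:
            counts[res.marker_id] += 1
    return [
        QcDecision(m, c, excluded=c >= min_sig_pops) for m, c in counts.items()
    ]


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for a 2D contingency table (zero-safe)."""
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _ld_g_sum(ga: np.ndarray, gb: np.ndarray, locs: np.ndarray) -> float:
    g_sum = 0.0
    for loc in np.unique(locs):
        m = locs == loc
        a, b = ga[m], gb[m]
        ok = (a != MISSING) & (b != MISSING)
        if ok.sum() < 2:
            continue
        table = np.zeros((3, 3))
        np.add.at(table, (a[ok], b[ok]), 1.0)
        g_sum += _g_statistic(table)
    return g_sum


def ld_test(
    panel: GenotypePanel,
    marker_a: str,
    marker_b: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float | None:
    """Genotypic-association permutation test between two markers.

    The observed statistic sums locality-wise G statistics of the 3x3
    genotype contingency tables; the null permutes one marker's genotypes
    within localities (avoiding Wahlund-driven false LD). Returns
    ``(#null >= observed + 1) / (n_permutations + 1)``, or None for a marker
    monomorphic everywhere (not testable).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    ja = panel.marker_ids.index(marker_a)
    jb = panel.marker_ids.index(marker_b)
    ga = panel.dosage[:, ja].astype(int)
    gb = panel.dosage[:, jb].astype(int)
    for g in (ga, gb):
        called = g[g != MISSING]
        if called.size == 0 or np.all(called == called[0]):
            return None
    locs = np.array(panel.locality_codes)
    observed = _ld_g_sum(ga, gb, locs)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = gb.copy()
        for loc in np.unique(locs):
            m = np.flatnonzero(locs == loc)
            perm[m] = rng.permutation(perm[m])
        if _ld_g_sum(ga, perm, locs) >= observed:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def diagnosticity_screen(
    panel: GenotypePanel, reference_labels: dict[str, SpeciesLabel]
) -> list[str]:
    """Markers fixed for alternative alleles in the two pure reference sets.

    ``reference_labels`` maps locality codes to the species each represents;
    retained markers show only dosage 0 in nesterovi references and only
    dosage 2 in ophryticus references (missing ignored).
    """
    nest = [c for c, s in reference_labels.items() if s == SpeciesLabel.NESTEROVI]
    ophr = [c for c, s in reference_labels.items() if s == SpeciesLabel.OPHRYTICUS]
    if not nest or not ophr:
        raise ValueError("need reference localities for both species")
    locs = np.array(panel.locality_codes)
    m_nest = np.isin(locs, nest)
    m_ophr = np.isin(locs, ophr)
    keep = []
    for j, marker in enumerate(panel.marker_ids):
        gn = panel.dosage[m_nest, j]
        go = panel.dosage[m_ophr, j]
        gn = gn[gn != MISSING]
        go = go[go != MISSING]
        if gn.size and go.size and (gn == 0).all() and (go == 2).all():
            keep.append(marker)
    return keep
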