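"""Hybrid indices and ancestry x interclass-heterozygosity ML (triangle plot).

The hybrid index is the proportion of diagnostic *O. ophryticus* alleles
among an individual's (or locality's) called alleles. The triangle model
places each individual by ancestry S (expected proportion of ophryticus
alleles) and interclass heterozygosity H (proportion of loci with one allele
from each species), with per-locus genotype probabilities

    P(g=2) = S - H/2,   P(g=1) = H,   P(g=0) = 1 - S - H/2,

valid on the triangle 0 <= S <= 1, 0 <= H <= 2 min(S, 1-S). F1 hybrids sit
at (0.5, 1), parentals at (0, 0) and (1, 0), F2 offspring at (0.5, E[H]=0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_model_io import MISSING, GenotypePanel

EPS = 1e-9  # probability floor inside the triangle log-likelihood


@dataclass
class HybridIndex:
    key: str  # individual id or locality code
    value: float | None
    n_called_alleles: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class TriangleEstimate:
    individual_id: str
    S: float
    H: float
    logL: float


def individual_hybrid_index(panel: GenotypePanel, individual_id: str) -> HybridIndex:
    """Sum of dosages over twice the number of called markers.

    Missing markers are excluded from numerator and denominator; an
    individual with no called markers gets an undefined (flagged) index.
    """
    i = panel.individual_ids.index(individual_id)
    g = panel.dosage[i].astype(int)
    called = g != MISSING
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        return HybridIndex(individual_id, None, 0)
    return HybridIndex(individual_id, float(g[called].sum()) / n_alleles, n_alleles)


def locality_hybrid_index(panel: GenotypePanel, locality_code: str) -> HybridIndex:
    """Pooled allele proportion over all called alleles at the locality.

    Pooling weights individuals by their call count, matching the allele
    counts the cline likelihood consumes (not the mean of individual
    indices, though the two agree closely when missingness is light).
    """
    mask = panel.locality_mask(locality_code)
    if not mask.any():
        raise ValueError(f"no individuals at locality {locality_code!r}")
    g = panel.dosage[mask].astype(int)
    called = g != MISSING
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        raise ValueError(f"no called genotypes at locality {locality_code!r}")
    return HybridIndex(locality_code, float(g[called].sum()) / n_alleles, n_alleles)


def _triangle_logl(counts: tuple[int, int, int], S: float, H: float) -> float:
    n0, n1, n2 = counts
    p2 = max(S - H / 2, EPS)
    p1 = max(H, EPS)
    p0 = max(1 - S - H / 2, EPS)
    return n0 * np.log(p0) + n1 * np.log(p1) + n2 * np.log(p2)


def _feasible(S: float, H: float) -> bool:
    return 0 <= S <= 1 and 0 <= H <= 2 * min(S, 1 - S) + 1e-12


def triangle_ml(
    panel: GenotypePanel, individual_id: str, grid_step: float = 0.005
) -> TriangleEstimate:
    """Maximum-likelihood (S, H) for one individual over the triangle.

    Coarse grid search at ``grid_step`` followed by Nelder-Mead refinement
    clamped to the triangle; ties broken toward smaller H. Missing loci are
    skipped. Probabilities are floored at 1e-9 so boundary optima never
    produce -inf.
    """
    i = panel.individual_ids.index(individual_id)
    g = panel.dosage[i].astype(int)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError(f"individual {individual_id!r} has no called markers")
    counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))

    svals = np.arange(0, 1 + grid_step / 2, grid_step)
    best = (-np.inf, 0.0, 0.0)
    for S in svals:
        hmax = 2 * min(S, 1 - S)
        for H in np.arange(0, hmax + grid_step / 2, grid_step):
            ll = _triangle_logl(counts, S, H)
            # strict improvement, or a tie resolved toward smaller H
            if ll > best[0] + 1e-12 or (abs(ll - best[0]) <= 1e-12 and H < best[2]):
                best = (ll, float(S), float(min(H, hmax)))

    def neg(x):
        S, H = x
        if not _feasible(S, H):
            return np.inf
        return -_triangle_logl(counts, S, H)

    res = minimize(neg, [best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9})
    if np.isfinite(res.fun) and -res.fun >= best[0]:
        S, H = res.x
        H = min(max(H, 0.0), 2 * min(S, 1 - S))
        return TriangleEstimate(individual_id, float(S), float(H), float(-res.fun))
    return TriangleEstimate(individual_id, best[1], best[2], best[0])


def triangle_batch(
    panel: GenotypePanel, grid_step: float = 0.005, corner_radius: float = 0.05
) -> tuple[list[TriangleEstimate], dict]:
    """Triangle estimates for every individual plus corner-occupancy summary.

    An individual is counted as a "parental corner" occupant when its
    ancestry is within ``corner_radius`` of 0 or 1 and its heterozygosity is
    at most ``corner_radius`` (a reporting convention).
    """
    estimates = []
    for ind in panel.individual_ids:
        g = panel.dosage[panel.individual_ids.index(ind)]
        if (g != MISSING).sum() == 0:
            continue
        estimates.append(triangle_ml(panel, ind, grid_step))
    n_corner = sum(
        1 for e in estimates
        if min(e.S, 1 - e.S) <= corner_radius and e.H <= corner_radius
    )
    summary = {
        "n_estimated": len(estimates),
        "n_corner": n_corner,
        "corner_fraction": n_corner / len(estimates) if estimates else float("nan"),
        "corner_radius": corner_radius,
    }
    return estimates, summary
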