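"""Tension-zone estimators: dispersal, neutral width, effective selection.

A tension zone is maintained by the balance of dispersal into the zone and
selection against hybrids. At the zone centre, mixing of divergent gene
pools generates admixture linkage disequilibrium D' among diagnostic loci,
which can be read off the variance of the hybrid index:

    Var(HI) = p q [ 1/(2L) + (L-1)/(2L) D' ]

for L unlinked diagnostic loci with mean focal-allele frequency p (q = 1-p)
and no within-locus excess (F_IS = 0, enforced upstream by HWE screening;
configurable). Dispersal-recombination balance then gives lifetime
dispersal sigma = w sqrt(r D'), the neutral-diffusion expectation of cline
width after T generations is w_neutral = sigma sqrt(2 pi T), and average
effective selection is s* = 8 sigma^2 / w^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .admixture import individual_hybrid_index
from .data_model_io import GenotypePanel, LifeStage
from .cline import ClineFit
from .transect import IsolineTransect


@dataclass
class TensionZoneEstimates:
    d_prime: float
    sigma_km_per_gen: float
    w_neutral_km: float
    s_star: float
    generations_to_cross: float
    T_generations: float
    r: float
    generation_time_years: float
    inputs: dict = field(default_factory=dict)


def dprime_from_hi_variance(
    hybrid_indices: np.ndarray, L: int, p_bar: float | None = None
) -> float:
    """Standardised admixture LD from the hybrid-index variance at the
    zone centre.

    Inverts Var(HI) = p q [1/(2L) + (L-1)/(2L) D']. Sampling noise can push
    the estimate below 0; such values are floored at 0 with a warning.
    """
    hi = np.asarray(hybrid_indices, dtype=float)
    if hi.size < 2:
        raise ValueError("need at least 2 individuals to estimate a variance")
    if L < 2:
        raise ValueError("need at least 2 loci")
    if p_bar is None:
        p_bar = float(hi.mean())
    if not 0 < p_bar < 1:
        raise ValueError("no polymorphism at center (mean frequency 0 or 1)")
    var = float(hi.var(ddof=1))
    pq = p_bar * (1 - p_bar)
    d = (2 * L * var / pq - 1) / (L - 1)
    if d < 0:
        warnings.warn("negative D' estimate floored at 0", stacklevel=2)
        return 0.0
    return float(min(d, 1.0))


def sigma_from_ld(d_prime: float, r: float, w: float) -> float:
    """Lifetime dispersal sigma = w sqrt(r D') (km per generation)."""
    if d_prime <= 0 or r <= 0 or w <= 0:
        raise ValueError("all inputs must be positive")
    return float(w * np.sqrt(r * d_prime))


def dprime_from_sigma(sigma: float, r: float, w: float) -> float:
    """Inverse of :func:`sigma_from_ld`: D' = sigma^2 / (r w^2)."""
    return float(sigma**2 / (r * w**2))


def neutral_width(sigma: float, T: float) -> float:
    """Expected cline width after T generations of neutral diffusion:
    sigma sqrt(2 pi T)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if T < 1:
        raise ValueError("T must be at least 1 generation")
    return float(sigma * np.sqrt(2.0 * np.pi * T))


def effective_selection(sigma: float, w: float) -> float:
    """Average effective selection s* = 8 sigma^2 / w^2.

    ``w`` may be the hybrid-index cline width or the mean per-marker width;
    the two conventions give different scales and callers choose explicitly.
    """
    if sigma <= 0 or w <= 0:
        raise ValueError("inputs must be positive")
    return float(8.0 * sigma**2 / w**2)


def generations_to_cross(w: float, sigma: float) -> float:
    """Generations for dispersal to traverse the zone: w / sigma."""
    if w <= 0 or sigma <= 0:
        raise ValueError("inputs must be positive")
    return float(w / sigma)


def dispersal_pipeline(
    panel: GenotypePanel,
    transect: IsolineTransect,
    hi_fit: ClineFit,
    r: float = 0.5,
    contact_age_years: float = 12_000.0,
    generation_time_years: float = 5.0,
    center_radius_km: float | None = None,
    post_metamorphic_only: bool = True,
    s_star_width: float | None = None,
) -> TensionZoneEstimates:
    """Chain D' -> sigma -> neutral width -> s* from a fitted hybrid-index
    cline and the individuals at the zone centre.

    Centre localities are those within ``center_radius_km`` of the fitted
    centre (default: half the fitted width). Only post-metamorphic
    individuals enter the LD estimate by default, since pre-metamorphic ones
    have not yet had the opportunity to disperse. T defaults to
    12,000 years / 5 years per generation = 2,400 generations (Holocene
    secondary contact). ``s_star_width`` overrides the width entering s*
    (e.g. a mean per-marker width); default is the hybrid-index width.
    """
    w = hi_fit.model.w
    c = hi_fit.model.c
    radius = center_radius_km if center_radius_km is not None else w / 2
    dist = transect.as_dict()
    center_locs = {code for code, d in dist.items() if abs(d - c) <= radius}
    if not center_locs:
        raise ValueError("no center localities within the window")

    keep = np.array([loc in center_locs for loc in panel.locality_codes])
    if post_metamorphic_only:
        stage_ok = np.array(
            [s == LifeStage.POST_METAMORPHIC for s in panel.life_stages]
        )
        # panels without stage annotation keep everyone
        if not any(s != LifeStage.UNKNOWN for s in panel.life_stages):
            stage_ok[:] = True
        keep &= stage_ok
    if not keep.any():
        raise ValueError("no dispersal-informative individuals at the center")
    sub = panel.subset_individuals(keep)
    his = [individual_hybrid_index(sub, ind) for ind in sub.individual_ids]
    hi_vals = np.array([h.value for h in his if h.defined])
    if hi_vals.size < 2:
        raise ValueError("fewer than 2 individuals with called genotypes at center")

    d_prime = dprime_from_hi_variance(hi_vals, sub.n_markers)
    T = contact_age_years / generation_time_years
    sigma = sigma_from_ld(max(d_prime, 1e-12), r, w) if d_prime > 0 else 0.0
    if sigma <= 0:
        raise ValueError("D' estimate is zero; dispersal not estimable")
    return TensionZoneEstimates(
        d_prime=d_prime,
        sigma_km_per_gen=sigma,
        w_neutral_km=neutral_width(sigma, T),
        s_star=effective_selection(sigma, s_star_width or w),
        generations_to_cross=generations_to_cross(w, sigma),
        T_generations=T,
        r=r,
        generation_time_years=generation_time_years,
        inputs={
            "n_center_individuals": int(hi_vals.size),
            "center_localities": sorted(center_locs),
            "center_radius_km": radius,
            "hi_cline_width_km": w,
            "hi_cline_center_km": c,
            "s_star_width_km": s_star_width or w,
            "contact_age_years": contact_age_years,
        },
    )
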