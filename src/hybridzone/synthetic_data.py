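"""Synthetic hybrid zones, admixed swarms and climate landscapes.

Every analysis stage in this package can be exercised without external data:

* :func:`simulate_zone` draws genotype panels whose locality allele
  frequencies follow a prescribed geographic cline and whose multilocus
  ancestry association (admixture LD) is controlled directly, via a latent
  per-individual ancestry q drawn from a Beta distribution around the local
  cline value. This hits the quantities the estimators consume (cline shape,
  zone-centre D') without forward-time simulation.
* :func:`simulate_admixed_swarm` draws individuals from the triangle model
  at chosen ancestry/heterozygosity, emulating an introduced hybrid swarm.
* :func:`simulate_climate_landscape` builds smooth correlated environmental
  rasters plus occurrence records from Gaussian suitability functions in
  environment space, with known niche separation.

All generators are pure functions of their seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cline import ClineModel, cline_predict
from .data_model_io import (
    GenotypePanel,
    LifeStage,
    LocalityFrame,
    MtdnaCalls,
    OccurrenceSet,
    RasterStack,
    SpeciesLabel,
)

import pandas as pd

KM_PER_DEGREE_LAT = 111.195  # pi/180 * 6371 km


@dataclass
class ZoneSimConfig:
    """Study design for a simulated hybrid zone.

    ``ancestry_variance`` is the variance of the latent ancestry q at a
    locality with expected frequency 0.5; at other localities the variance
    scales with p(1-p) so the Beta construction stays feasible. Zero gives
    independent loci (D' = 0); the induced zone-centre admixture LD is
    approximately 2 v / 0.25 for small v (see docs). Must be < 0.25.
    """

    seed: int
    n_markers: int = 31
    positions_km: np.ndarray = field(
        default_factory=lambda: np.linspace(-50.0, 50.0, 21)
    )
    n_per_locality: int | np.ndarray = 14
    cline: ClineModel = field(default_factory=lambda: ClineModel(c=0.0, w=3.0))
    mt_cline: ClineModel = field(default_factory=lambda: ClineModel(c=0.0, w=1.0))
    ancestry_variance: float = 0.0
    expected_freq: np.ndarray | None = None  # overrides the cline per locality
    n_mtdna_per_locality: int = 3
    post_metamorphic_fraction: float = 1.0
    origin_lat: float = 41.0
    origin_lon: float = 37.17
    lat_jitter_deg: float = 0.05  # sampling scatter off the transect line

    def __post_init__(self) -> None:
        self.positions_km = np.asarray(self.positions_km, dtype=float)
        self.n_per_locality = np.broadcast_to(
            np.asarray(self.n_per_locality, dtype=int), self.positions_km.shape
        ).copy()
        if self.expected_freq is not None:
            self.expected_freq = np.asarray(self.expected_freq, dtype=float)
            if self.expected_freq.shape != self.positions_km.shape:
                raise ValueError("expected_freq must match positions")
        if self.n_markers < 1 or (self.n_per_locality < 1).any():
            raise ValueError("counts must be >= 1")
        if not 0 <= self.ancestry_variance:
            raise ValueError("ancestry_variance must be non-negative")
        if self.ancestry_variance >= 0.25:
            raise ValueError(
                "ancestry_variance >= p(1-p) at the centre; Beta infeasible"
            )


def rho_for_dprime(d_prime: float, L: int) -> float:
    """Ancestry-variance fraction rho giving target zone-centre D'.

    With Var(q) = rho p(1-p), the hybrid-index variance implies
    D' = rho (2L - 1)/(L - 1); invert for rho. Multiply by 0.25 to get the
    ``ancestry_variance`` config value (variance at p = 0.5).
    """
    return d_prime * (L - 1) / (2 * L - 1)


def _positions_to_lonlat(x_km: np.ndarray, lat0: float, lon0: float) -> tuple[np.ndarray, np.ndarray]:
    lon = lon0 + x_km / (KM_PER_DEGREE_LAT * np.cos(np.radians(lat0)))
    lat = np.full_like(lon, lat0)
    return lon, lat


def simulate_zone(
    config: ZoneSimConfig,
) -> tuple[GenotypePanel, LocalityFrame, MtdnaCalls]:
    """Draw a full hybrid-zone dataset under the configured cline.

    Per locality at transect position x: expected frequency p(x) from the
    true cline; each individual draws latent ancestry q ~ Beta with mean
    p(x) and variance rho p(1-p) (rho = ancestry_variance / 0.25; rho = 0
    degenerates to q = p exactly), then genotypes Binomial(2, q) per locus
    independently. mtDNA haplotypes are Bernoulli draws from the (steeper)
    mtDNA cline, mirroring the near-zero mitochondrial cline width of real
    tension zones. Life stages are post-metamorphic with the configured
    fraction.
    """
    rng = np.random.default_rng(config.seed)
    x = config.positions_km
    if config.expected_freq is not None:
        p = np.clip(config.expected_freq, 0.0, 1.0)
    else:
        p = np.clip(np.atleast_1d(cline_predict(config.cline, x)), 0.0, 1.0)
    p_mt = np.clip(np.atleast_1d(cline_predict(config.mt_cline, x)), 0.0, 1.0)
    rho = config.ancestry_variance / 0.25
    L = config.n_markers

    ids, locs, stages, rows = [], [], [], []
    mt_ids, mt_calls = [], []
    loc_records = []
    for j, (xi, pi) in enumerate(zip(x, p)):
        code = f"L{j + 1:02d}"
        for i in range(int(config.n_per_locality[j])):
            ind = f"{code}_ind{i + 1:02d}"
            if rho > 0 and 0 < pi < 1:
                var = rho * pi * (1 - pi)
                # Beta with mean pi, variance var
                nu = pi * (1 - pi) / var - 1
                q = rng.beta(pi * nu, (1 - pi) * nu)
            else:
                q = pi
            g = rng.binomial(2, q, size=L)
            ids.append(ind)
            locs.append(code)
            stages.append(
                LifeStage.POST_METAMORPHIC
                if rng.uniform() < config.post_metamorphic_fraction
                else LifeStage.PRE_METAMORPHIC
            )
            rows.append(g)
        n_mt = config.n_mtdna_per_locality
        calls = rng.uniform(size=n_mt) < p_mt[j]
        for i in range(n_mt):
            mt_ids.append(f"{code}_ind{i + 1:02d}")
            mt_calls.append(
                SpeciesLabel.OPHRYTICUS if calls[i] else SpeciesLabel.NESTEROVI
            )
        loc_records.append((code, xi, n_mt, float(calls.mean())))

    panel = GenotypePanel(ids, locs, [f"m{k + 1:03d}" for k in range(L)],
                          np.array(rows, dtype=np.int8), stages)

    lon, lat = _positions_to_lonlat(x, config.origin_lat, config.origin_lon)
    # scatter localities off the exact transect line, as real sampling does
    # (and as the 2D surface interpolation requires: no all-collinear maps)
    lat = lat + rng.uniform(-config.lat_jitter_deg, config.lat_jitter_deg, lat.size)
    frame_rows = []
    for (code, xi, n_mt, mt_freq), lo, la in zip(loc_records, lon, lat):
        mask = panel.locality_mask(code)
        g = panel.dosage[mask]
        hi = float(g.sum()) / (2 * g.size)
        species = "nesterovi" if hi < 0.5 else "ophryticus"
        frame_rows.append(
            dict(code=code, locality=code, latitude=la, longitude=lo,
                 species=species, n_kasp=int(mask.sum()), hybrid_index=hi,
                 n_mtdna=n_mt, mtdna_freq=mt_freq)
        )
    localities = LocalityFrame(pd.DataFrame(frame_rows))
    return panel, localities, MtdnaCalls(mt_ids, mt_calls)


def simulate_admixed_swarm(
    n_individuals: int,
    S: float | np.ndarray,
    H: float | np.ndarray,
    n_markers: int = 31,
    seed: int = 0,
    locality_code: str = "swarm",
) -> GenotypePanel:
    """Genotypes drawn from the triangle model at given (S, H).

    Scalars apply to every individual; arrays give per-individual targets.
    Raises for pairs outside the triangle H <= 2 min(S, 1-S).
    """
    rng = np.random.default_rng(seed)
    S = np.broadcast_to(np.asarray(S, dtype=float), (n_individuals,))
    H = np.broadcast_to(np.asarray(H, dtype=float), (n_individuals,))
    for s, h in zip(S, H):
        if not (0 <= s <= 1 and 0 <= h <= 2 * min(s, 1 - s) + 1e-12):
            raise ValueError(f"(S={s}, H={h}) outside the triangle")
    rows = []
    for s, h in zip(S, H):
        probs = np.array([1 - s - h / 2, h, s - h / 2])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        rows.append(rng.choice(3, size=n_markers, p=probs))
    ids = [f"{locality_code}_ind{i + 1:03d}" for i in range(n_individuals)]
    return GenotypePanel(
        ids, [locality_code] * n_individuals,
        [f"m{k + 1:03d}" for k in range(n_markers)],
        np.array(rows, dtype=np.int8),
    )


@dataclass
class LandscapeConfig:
    seed: int
    extent: tuple[float, float, float, float] = (30.0, 45.0, 38.0, 44.0)  # lon0, lon1, lat0, lat1
    resolution: float = 0.1
    n_variables: int = 4
    smoothing_cells: float = 5.0
    gradient_weight: float = 0.85  # loading of each layer on the shared gradient
    niche_center_a: float = -1.0   # position along the shared gradient, in SD units
    niche_center_b: float = 1.0
    niche_sd: float = 1.0
    n_occurrences: int = 100


def simulate_climate_landscape(
    config: LandscapeConfig,
) -> tuple[RasterStack, OccurrenceSet, OccurrenceSet]:
    """Smooth correlated environmental rasters plus species occurrences.

    The layers share a dominant latent climatic gradient (a low-order
    spatial trend plus filtered noise), each loading on it with
    ``gradient_weight`` and carrying its own smooth residual field — the
    structure of real bioclimatic stacks, where one or two gradients
    dominate and the leading ordination axis recovers them. Suitability for
    each species is a Gaussian centred at ``niche_center_{a,b}`` along the
    standardized shared gradient; occurrences are sampled with probability
    proportional to suitability. Species separation in environment space is
    therefore ``|niche_center_a - niche_center_b| / niche_sd`` SDs — the
    ground truth for overlap checks.
    """
    rng = np.random.default_rng(config.seed)
    lon0, lon1, lat0, lat1 = config.extent
    lon = np.arange(lon0, lon1, config.resolution)
    lat = np.arange(lat1, lat0, -config.resolution)
    gl, gt = np.meshgrid(lon, lat)
    u = (gl - gl.mean()) / (gl.std() + 1e-12)
    v = (gt - gt.mean()) / (gt.std() + 1e-12)

    def smooth_field() -> np.ndarray:
        f = gaussian_filter(rng.standard_normal(gl.shape), config.smoothing_cells)
        return f / (f.std() + 1e-12)

    a, b = rng.normal(size=2)
    shared = a * u + b * v + 0.5 * smooth_field()
    shared = (shared - shared.mean()) / shared.std()

    w = config.gradient_weight
    layers = []
    for k in range(config.n_variables):
        residual = smooth_field()
        layers.append(w * shared + np.sqrt(1 - w**2) * residual)
    values = np.array(layers)
    stack = RasterStack(
        [f"env{k + 1}" for k in range(config.n_variables)], values, lat, lon
    )

    g1 = shared

    def sample(center: float) -> OccurrenceSet:
        suit = np.exp(-0.5 * ((g1 - center) / config.niche_sd) ** 2)
        p = (suit / suit.sum()).ravel()
        idx = rng.choice(p.size, size=config.n_occurrences, p=p)
        rr, cc = np.unravel_index(idx, g1.shape)
        jitter = config.resolution / 2
        return OccurrenceSet(
            "species",
            lat[rr] + rng.uniform(-jitter, jitter, rr.size),
            lon[cc] + rng.uniform(-jitter, jitter, cc.size),
        )

    occ_a = sample(config.niche_center_a)
    occ_b = sample(config.niche_center_b)
    occ_a.species, occ_b.species = "A", "B"
    return stack, occ_a, occ_b
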