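"""Object-based coupling statistics: ring-wise bivariate Ripley analysis.

Given two point populations inside a cell mask Omega, the question is
whether channel-2 objects sit closer to channel-1 objects than complete
spatial randomness (CSR) predicts, and if so at what distance.  Distances
are partitioned into concentric rings 0 = r_0 < r_1 < ... < r_K and for
each ring the edge-corrected cross statistic

    K_hat_k = |Omega| / (N1 * N2) * sum_{pairs (i,j): r_{k-1} <= d_ij < r_k} w_ij

is compared with its CSR expectation, the ring measure
A_k = pi (r_k^2 - r_{k-1}^2) in 2D (shell volume in 3D).  The weight w_ij
is the isotropic edge correction: the reciprocal of the fraction of the
circle (sphere surface) of radius d_ij around the channel-1 spot that lies
inside the mask, so that E[K_hat_k] = A_k under independence even near the
cell boundary.  The per-ring null standard deviation sigma_k comes from a
seeded Monte-Carlo that redraws the channel-2 pattern uniformly in the
mask.

A ring is declared significant when its standardized excess
G_k = (K_hat_k - A_k) / sigma_k exceeds the one-sided Sidak-corrected
normal quantile c = Phi^{-1}((1 - alpha)^{1/K}).  In a significant ring the
excess fraction p_k = (K_hat_k - A_k) / K_hat_k is the probability that a
pair at that distance is a true couple; summing pair probabilities yields
the expected number of couples, per-channel coupling fractions, and the
probability-weighted mean +/- sd coupling distance.  The global p-value is
1 - (1 - Phi_bar(max_k G_k))^K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .io import CellMask, SpotSet

try:  # scipy >= 1.8 keeps the fast EDT here
    from scipy.ndimage import distance_transform_edt
except ImportError:  # pragma: no cover
    from scipy.ndimage.morphology import distance_transform_edt

__all__ = [
    "RingSpec",
    "RipleyProfile",
    "CouplingResult",
    "EdgeWeights",
    "pair_distances",
    "edge_weight",
    "ripley_profile",
    "null_moments",
    "coupling_probabilities",
    "run_soda",
    "filter_spots_to_mask",
]

_SIGMA_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Rings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    """Concentric distance rings: strictly increasing radii starting at 0 (nm)."""

    radii: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        if radii.ndim != 1 or radii.size < 2:
            raise ValueError("need at least two radii (one ring)")
        if radii[0] != 0.0:
            raise ValueError("r_0 must be 0")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        object.__setattr__(self, "radii", radii)

    @classmethod
    def uniform(cls, width: float, n_rings: int) -> "RingSpec":
        return cls(width * np.arange(n_rings + 1, dtype=float))

    @classmethod
    def from_string(cls, text: str) -> "RingSpec":
        """Parse ``"start:stop:step"`` in nm, e.g. ``"0:300:30"``."""
        start, stop, step = (float(t) for t in text.split(":"))
        if start != 0:
            raise ValueError("ring radii must start at 0")
        return cls(np.arange(start, stop + 0.5 * step, step))

    @property
    def n_rings(self) -> int:
        return len(self.radii) - 1

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.radii)

    def ring_measures(self, dim: int) -> np.ndarray:
        """Null expectation A_k: ring area (2D) or shell volume (3D) in nm^D."""
        inner, outer = self.radii[:-1], self.radii[1:]
        if dim == 2:
            return np.pi * (outer**2 - inner**2)
        if dim == 3:
            return (4.0 / 3.0) * np.pi * (outer**3 - inner**3)
        raise ValueError("dim must be 2 or 3")


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def pair_distances(
    spots1: SpotSet, spots2: SpotSet, rings: RingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All cross-channel pairs with d < r_K, binned into rings.

    Returns ``(i, j, d, ring)`` with 0-based ring indices; binning is
    half-open ``[r_{k-1}, r_k)`` so a distance exactly equal to a boundary
    falls in the outer ring.  Uses a k-d tree, so cost is near-linear in the
    pair yield.
    """
    if spots1.n == 0 or spots2.n == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0), empty
    if spots1.dim != spots2.dim:
        raise ValueError("dimension mismatch between spot sets")
    p1, p2 = spots1.positions, spots2.positions
    tree2 = cKDTree(p2)
    neigh = tree2.query_ball_point(p1, r=rings.r_max)
    counts = np.fromiter((len(nb) for nb in neigh), dtype=np.int64, count=len(neigh))
    i = np.repeat(np.arange(spots1.n, dtype=np.int64), counts)
    j = (
        np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neigh])
        if counts.sum()
        else np.empty(0, dtype=np.int64)
    )
    d = np.linalg.norm(p1[i] - p2[j], axis=1)
    keep = d < rings.r_max
    i, j, d = i[keep], j[keep], d[keep]
    ring = np.searchsorted(rings.radii, d, side="right") - 1
    return i, j, d, ring


# ---------------------------------------------------------------------------
# Edge correction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistributed unit vectors on S^2, in (z, y, x) order."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    sin_phi = np.sin(phi)
    return np.stack(
        [np.cos(phi), sin_phi * np.sin(theta), sin_phi * np.cos(theta)], axis=1
    )


class EdgeWeights:
    """Sampled isotropic edge-correction weights for one mask.

    ``w(point, d)`` is the reciprocal of the fraction of the circle (2D,
    360 directions) or sphere surface (3D, 512 Fibonacci directions) of
    radius ``d`` centred at ``point`` that lies inside the mask; the
    fraction is floored at ``min_fraction`` (default 0.05, so w <= 20) to
    bound the variance contributed by thin mask processes.

    A Euclidean distance transform of the mask provides an exact fast path:
    when the circle cannot reach the boundary the weight is 1 without any
    sampling.  In 2D the sampled angles are offset by half a step so
    axis-aligned mask edges are never hit exactly on a sample point.
    """

    def __init__(self, mask: CellMask, n_directions: int | None = None,
                 min_fraction: float = 0.05):
        self.mask = mask
        self.min_fraction = float(min_fraction)
        px = np.asarray(mask.pixel_size, dtype=float)
        self._px = px
        self._dt = distance_transform_edt(mask.grid, sampling=px)
        self._margin = float(np.sqrt((px**2).sum()))  # pixel diagonal, nm
        if n_directions is None:
            n_directions = 360 if mask.dim == 2 else 512
        if mask.dim == 2:
            ang = (np.arange(n_directions) + 0.5) * (2.0 * np.pi / n_directions)
            self._dirs = np.stack([np.sin(ang), np.cos(ang)], axis=1)  # (dy, dx)
        else:
            self._dirs = _fibonacci_sphere(n_directions)

    def _dt_at(self, points: np.ndarray) -> np.ndarray:
        idx = np.floor(points / self._px).astype(np.int64)
        shape = np.asarray(self.mask.grid.shape)
        np.clip(idx, 0, shape - 1, out=idx)
        return self._dt[tuple(idx.T)]

    def weights(self, points: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Vectorized weights for ``points`` (P, D) at radii ``d`` (P,)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.atleast_1d(np.asarray(d, dtype=float))
        w = np.ones(len(points))
        near = self._dt_at(points) <= d + self._margin
        if near.any():
            pts = points[near][:, None, :] + d[near][:, None, None] * self._dirs[None]
            flat = pts.reshape(-1, points.shape[1])
            inside = self.mask.contains(flat).reshape(near.sum(), len(self._dirs))
            frac = np.clip(inside.mean(axis=1), self.min_fraction, None)
            w[near] = 1.0 / frac
        return w


def edge_weight(point: np.ndarray, d: float, mask: CellMask,
                weights: EdgeWeights | None = None) -> float:
    """Edge-correction weight w >= 1 at a single point and radius (nm).

    Raises when the point lies outside the mask or ``d <= 0``.
    """
    point = np.asarray(point, dtype=float)
    if d <= 0:
        raise ValueError("radius must be positive")
    if not mask.contains(point[None])[0]:
        raise ValueError("point outside mask")
    calc = weights if weights is not None else EdgeWeights(mask)
    return float(calc.weights(point[None], np.array([d]))[0])


# ---------------------------------------------------------------------------
# Ripley profile and null moments
# ---------------------------------------------------------------------------

@dataclass
class RipleyProfile:
    """Per-ring corrected Ripley statistics plus the retained pair index."""

    rings: RingSpec
    k_hat: np.ndarray           # (K,) corrected statistic, nm^D
    ring_measure: np.ndarray    # (K,) null expectation A_k, nm^D
    n1: int
    n2: int
    mask_measure: float
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_d: np.ndarray
    pair_ring: np.ndarray
    pair_w: np.ndarray
    sigma: np.ndarray | None = None  # per-ring null sd, filled by run_soda
    z: np.ndarray | None = None      # per-ring score G_k


def _khat_from_pairs(ring: np.ndarray, w: np.ndarray, n_rings: int,
                     scale: float) -> np.ndarray:
    return scale * np.bincount(ring, weights=w, minlength=n_rings)


def ripley_profile(
    spots1: SpotSet,
    spots2: SpotSet,
    rings: RingSpec,
    mask: CellMask,
    weights: EdgeWeights | None = None,
) -> RipleyProfile:
    """Edge-corrected ring-wise cross Ripley statistic K_hat_k.

    Weights are evaluated at the channel-1 spot of each pair at radius
    d_ij (asymmetric convention: channel 1 is the reference population).
    All channel-1 spots must lie inside the mask.
    """
    if spots1.n == 0 or spots2.n == 0:
        raise ValueError("empty spot set")
    if spots1.dim != mask.dim:
        raise ValueError("dimension mismatch between spots and mask")
    if not mask.contains(spots1.positions).all():
        raise ValueError("channel-1 spots outside the mask; filter first")
    calc = weights if weights is not None else EdgeWeights(mask)
    i, j, d, ring = pair_distances(spots1, spots2, rings)
    w = calc.weights(spots1.positions[i], d) if len(i) else np.empty(0)
    scale = mask.measure / (spots1.n * spots2.n)
    k_hat = _khat_from_pairs(ring, w, rings.n_rings, scale)
    return RipleyProfile(
        rings=rings,
        k_hat=k_hat,
        ring_measure=rings.ring_measures(mask.dim),
        n1=spots1.n,
        n2=spots2.n,
        mask_measure=mask.measure,
        pair_i=i,
        pair_j=j,
        pair_d=d,
        pair_ring=ring,
        pair_w=w,
    )


def null_moments(
    spots1: SpotSet,
    n2: int,
    rings: RingSpec,
    mask: CellMask,
    n_resamples: int = 500,
    seed: int | np.random.Generator = 0,
    weights: EdgeWeights | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo null moments of K_hat under CSR for channel 2.

    Channel-1 positions are held fixed; each of ``n_resamples`` draws places
    ``n2`` points uniformly in the mask and recomputes the full weighted
    statistic.  Returns per-ring (mean, sd); the sd is floored at 1e-12.
    Deterministic given the seed.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if n2 < 1 or spots1.n < 1:
        raise ValueError("need at least one point per channel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calc = weights if weights is not None else EdgeWeights(mask)
    tree1 = cKDTree(spots1.positions)
    p1 = spots1.positions
    scale = mask.measure / (spots1.n * n2)
    samples = np.empty((n_resamples, rings.n_rings))
    for b in range(n_resamples):
        pts2 = mask.sample_uniform(n2, rng)
        neigh = tree1.query_ball_point(pts2, r=rings.r_max)
        counts = np.fromiter((len(nb) for nb in neigh), dtype=np.int64, count=n2)
        total = int(counts.sum())
        if total == 0:
            samples[b] = 0.0
            continue
        i1 = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neigh])
        j2 = np.repeat(np.arange(n2, dtype=np.int64), counts)
        d = np.linalg.norm(p1[i1] - pts2[j2], axis=1)
        keep = d < rings.r_max
        i1, d = i1[keep], d[keep]
        ring = np.searchsorted(rings.radii, d, side="right") - 1
        w = calc.weights(p1[i1], d)
        samples[b] = _khat_from_pairs(ring, w, rings.n_rings, scale)
    mean = samples.mean(axis=0)
    sd = np.clip(samples.std(axis=0, ddof=1), _SIGMA_FLOOR, None)
    return mean, sd


# ---------------------------------------------------------------------------
# Coupling probabilities
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    """Coupling probabilities and summary statistics for one channel pair."""

    p_ring: np.ndarray              # per-ring coupling probability p_k
    significant: np.ndarray         # per-ring significance flags
    z: np.ndarray                   # per-ring scores G_k
    sigma: np.ndarray               # per-ring null sd
    pair_prob: np.ndarray           # per retained pair
    spot_prob_ch1: np.ndarray       # P_i = min(1, sum of its pair probs)
    spot_prob_ch2: np.ndarray
    n_coupled: float                # expected number of couples (clamped)
    coupling_fraction_ch1: float
    coupling_fraction_ch2: float
    mean_distance: float            # probability-weighted, nm (NaN if none)
    sd_distance: float
    p_value: float
    alpha: float

    @property
    def associated_ch1(self) -> np.ndarray:
        """Per-spot association flags used by the map renderer (P_i > 0.5)."""
        return self.spot_prob_ch1 > 0.5

    @property
    def associated_ch2(self) -> np.ndarray:
        return self.spot_prob_ch2 > 0.5


def coupling_probabilities(
    profile: RipleyProfile,
    moments: tuple[np.ndarray, np.ndarray],
    alpha: float = 0.05,
) -> CouplingResult:
    """Turn per-ring excesses over the CSR expectation into coupling output.

    Ring k is significant iff G_k = (K_hat_k - A_k)/sigma_k exceeds the
    one-sided Sidak-corrected quantile over the K rings; a significant ring
    assigns p_k = (K_hat_k - A_k)/K_hat_k to each of its pairs (zero when
    K_hat_k <= A_k).  Degenerate inputs yield n_coupled = 0 and p_value 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    _, sd = moments
    n_rings = profile.rings.n_rings
    k_hat, a = profile.k_hat, profile.ring_measure
    z = (k_hat - a) / sd
    crit = norm.ppf((1.0 - alpha) ** (1.0 / n_rings))
    significant = z > crit
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(k_hat > 0, (k_hat - a) / k_hat, 0.0)
    p_ring = np.where(significant, np.clip(excess, 0.0, 1.0), 0.0)

    pair_prob = p_ring[profile.pair_ring] if len(profile.pair_ring) else np.empty(0)
    spot_prob1 = np.minimum(
        1.0, np.bincount(profile.pair_i, weights=pair_prob, minlength=profile.n1)
    )
    spot_prob2 = np.minimum(
        1.0, np.bincount(profile.pair_j, weights=pair_prob, minlength=profile.n2)
    )
    total = float(pair_prob.sum())
    n_coupled = min(total, float(min(profile.n1, profile.n2)))
    cf1 = n_coupled / profile.n1 if profile.n1 else 0.0
    cf2 = n_coupled / profile.n2 if profile.n2 else 0.0

    if total > 0:
        mu = float(np.average(profile.pair_d, weights=pair_prob))
        var = float(np.average((profile.pair_d - mu) ** 2, weights=pair_prob))
        sd_d = float(np.sqrt(var))
    else:
        mu = float("nan")
        sd_d = float("nan")

    max_z = float(z.max()) if n_rings else -np.inf
    tail = float(norm.sf(max_z))
    with np.errstate(divide="ignore"):
        p_value = -np.expm1(n_rings * np.log1p(-min(tail, 1.0)))
    p_value = float(np.clip(p_value, 0.0, 1.0))

    return CouplingResult(
        p_ring=p_ring,
        significant=significant,
        z=z,
        sigma=sd,
        pair_prob=pair_prob,
        spot_prob_ch1=spot_prob1,
        spot_prob_ch2=spot_prob2,
        n_coupled=n_coupled,
        coupling_fraction_ch1=cf1,
        coupling_fraction_ch2=cf2,
        mean_distance=mu,
        sd_distance=sd_d,
        p_value=p_value,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def filter_spots_to_mask(spots: SpotSet, mask: CellMask) -> SpotSet:
    """Keep only spots whose position lies inside the mask."""
    if spots.n == 0:
        return spots
    return spots.subset(mask.contains(spots.positions))


def run_soda(
    spots1: SpotSet,
    spots2: SpotSet,
    mask: CellMask,
    rings: RingSpec | None = None,
    alpha: float = 0.05,
    n_resamples: int = 500,
    seed: int | np.random.Generator = 0,
    weights: EdgeWeights | None = None,
) -> tuple[RipleyProfile, CouplingResult]:
    """Full coupling analysis: profile, MC null, probabilities. Seeded.

    Default rings are ten 30 nm rings up to 300 nm.  Returns the profile
    (with sigma and z filled in) and the coupling result; per-spot
    association flags for the map renderer are ``result.associated_ch1/2``.
    """
    rings = rings or RingSpec.uniform(30.0, 10)
    calc = weights if weights is not None else EdgeWeights(mask)
    profile = ripley_profile(spots1, spots2, rings, mask, weights=calc)
    moments = null_moments(
        spots1, spots2.n, rings, mask, n_resamples=n_resamples, seed=seed, weights=calc
    )
    result = coupling_probabilities(profile, moments, alpha=alpha)
    profile.sigma = result.sigma
    profile.z = result.z
    return profile, result
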