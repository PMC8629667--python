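"""Bayesian fuzzy clustering (BFC) of lung-lobe regions.

The model: each pixel intensity is drawn from one of ``O`` Gaussian
clusters with prototypes ``t_w`` and a shared noise scale, and every
pixel carries a soft membership vector with a symmetric Dirichlet
prior.  Inference alternates two maximum-a-posteriori sweeps:

* membership update — per-pixel weights proportional to the Gaussian
  likelihood tempered by ``1/(fuzzifier - 1)`` times the (symmetric)
  Dirichlet prior weight, normalized to sum to one;
* prototype update — the membership^fuzzifier-weighted intensity mean,
  the exact posterior mode of the Gaussian model given the memberships.

Each sweep records the complete-data log-posterior, and the sweep with
the highest value is returned, so a late degradation can never replace
an earlier better state.

The lung-ROI selection step is plumbing around the clustering: in a CT
slice the lung fields are dark *interior* regions, so the darkest
cluster whose connected components do not frame the whole image (the
air background does) is taken as the lobe mask.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .imageio_pre import validate_image

__all__ = [
    "BFCParams",
    "BFCResult",
    "init_prototypes",
    "update_memberships",
    "update_prototypes",
    "log_posterior",
    "segment_lobes",
    "select_lung_rois",
]

_LOG_EPS = 1e-300


@dataclasses.dataclass(frozen=True)
class BFCParams:
    n_clusters: int = 3
    fuzzifier: float = 2.0
    dirichlet_concentration: float = 1.0
    n_sweeps: int = 50
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        if self.dirichlet_concentration <= 0.0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")


@dataclasses.dataclass
class BFCResult:
    """Memberships (H, W, O), prototypes (O,), argmax labels (H, W)."""

    memberships: np.ndarray
    prototypes: np.ndarray
    labels: np.ndarray
    log_posterior_trace: np.ndarray


def init_prototypes(image: np.ndarray, params: BFCParams) -> np.ndarray:
    """Deterministic quantile initialization: quantiles (w + 0.5) / O."""
    image = validate_image(image)
    qs = (np.arange(params.n_clusters) + 0.5) / params.n_clusters
    return np.quantile(image, qs)


def update_memberships(image: np.ndarray, prototypes: np.ndarray, params: BFCParams) -> np.ndarray:
    """Tempered-likelihood membership update.

    Membership of cluster ``w`` is proportional to
    ``N(x; t_w, sigma)^(1/(fuzzifier-1))`` times the symmetric Dirichlet
    prior weight (constant across clusters, hence absorbed by the
    normalization).  Computed in log space for stability.  With
    ``noise_sigma == 0`` the limit is a hard assignment to the nearest
    prototype (ties to the lowest cluster index).
    """
    image = np.asarray(image, dtype=np.float64)
    prototypes = np.asarray(prototypes, dtype=np.float64)
    if not np.all(np.isfinite(prototypes)):
        raise ValueError("prototypes must be finite")
    d2 = (image[..., None] - prototypes) ** 2  # (H, W, O)
    if params.noise_sigma == 0.0:
        labels = np.argmin(d2, axis=-1)
        m = np.zeros(d2.shape, dtype=np.float64)
        np.put_along_axis(m, labels[..., None], 1.0, axis=-1)
        return m
    logw = -d2 / (2.0 * params.noise_sigma**2 * (params.fuzzifier - 1.0))
    logw += (params.dirichlet_concentration - 1.0) * np.log(1.0 / len(prototypes))
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    total = w.sum(axis=-1, keepdims=True)
    degenerate = ~np.isfinite(total[..., 0]) | (total[..., 0] <= 0.0)
    m = np.where(degenerate[..., None], 1.0 / len(prototypes), w / np.where(total > 0, total, 1.0))
    return m


def update_prototypes(
    image: np.ndarray,
    memberships: np.ndarray,
    params: BFCParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """MAP prototypes: membership^fuzzifier-weighted intensity means.

    A cluster with zero total membership mass gets its prototype
    resampled uniformly in [0, 1] from the seeded stream.
    """
    image = np.asarray(image, dtype=np.float64)
    w = np.asarray(memberships, dtype=np.float64) ** params.fuzzifier
    mass = w.reshape(-1, w.shape[-1]).sum(axis=0)
    num = (w * image[..., None]).reshape(-1, w.shape[-1]).sum(axis=0)
    out = np.empty_like(mass)
    ok = mass > 0
    out[ok] = num[ok] / mass[ok]
    if not ok.all():
        if rng is None:
            rng = np.random.default_rng(params.seed)
        out[~ok] = rng.uniform(0.0, 1.0, size=int((~ok).sum()))
    return out


def log_posterior(
    image: np.ndarray, memberships: np.ndarray, prototypes: np.ndarray, params: BFCParams
) -> float:
    """Complete-data log-posterior: Σ m^f · log N(x; t_w, σ) + Dirichlet term."""
    image = np.asarray(image, dtype=np.float64)
    sigma = max(params.noise_sigma, 1e-12)
    d2 = (image[..., None] - prototypes) ** 2
    loglik = -0.5 * d2 / sigma**2 - np.log(sigma * np.sqrt(2.0 * np.pi))
    w = memberships**params.fuzzifier
    lp = float((w * loglik).sum())
    if params.dirichlet_concentration != 1.0:
        lp += float(
            (params.dirichlet_concentration - 1.0) * np.log(memberships + _LOG_EPS).sum()
        )
    return lp


def segment_lobes(image: np.ndarray, params: BFCParams = BFCParams()) -> BFCResult:
    """Alternate MAP sweeps and return the highest-posterior state.

    The per-sweep log-posterior trace is recorded; in the noiseless
    alternating-MAP regime the alternation reaches its fixed point
    monotonically.
    """
    image = validate_image(image)
    rng = np.random.default_rng(params.seed)
    prototypes = init_prototypes(image, params)
    best = None
    trace = []
    for _ in range(params.n_sweeps):
        memberships = update_memberships(image, prototypes, params)
        prototypes = update_prototypes(image, memberships, params, rng)
        lp = log_posterior(image, memberships, prototypes, params)
        trace.append(lp)
        if best is None or lp >= best[0]:
            best = (lp, memberships, prototypes.copy())
    _, memberships, prototypes = best
    labels = np.argmax(memberships, axis=-1)
    return BFCResult(
        memberships=memberships,
        prototypes=prototypes,
        labels=labels,
        log_posterior_trace=np.asarray(trace),
    )


def _touches_border(component: np.ndarray) -> bool:
    return bool(
        component[0, :].any()
        or component[-1, :].any()
        or component[:, 0].any()
        or component[:, -1].any()
    )


def select_lung_rois(
    result: BFCResult,
    image: np.ndarray,
    *,
    min_area_fraction: float = 0.02,
    fill_holes: bool = True,
) -> np.ndarray:
    """Heuristic lung-field extraction from the cluster labels.

    Walks the clusters from darkest prototype upward and returns the
    union of that cluster's connected components that do not touch the
    image border (lung fields are interior; the air background reaches
    the edge) and exceed ``min_area_fraction`` of the image.  Holes are
    filled so that a bright tumor inside the lung stays inside the lobe
    mask.  Returns an all-zero mask (with a warning) when no cluster
    qualifies, e.g. on a constant image.
    """
    image = validate_image(image)
    min_area = max(16, int(min_area_fraction * image.size))
    order = np.argsort(result.prototypes)
    for w in order:
        cluster = result.labels == w
        # suppress isolated texture/noise speckle before component analysis
        cluster = ndimage.binary_opening(cluster, structure=np.ones((3, 3), dtype=bool))
        if not cluster.any():
            continue
        labeled, n = ndimage.label(cluster)
        mask = np.zeros(image.shape, dtype=bool)
        for comp_id in range(1, n + 1):
            comp = labeled == comp_id
            if comp.sum() < min_area:
                continue
            if _touches_border(comp):
                continue
            mask |= comp
        if mask.any():
            if fill_holes:
                # close narrow leaks first so a bright nodule whose blur
                # bleeds through a thin parenchyma ring still counts as a hole
                closed = ndimage.binary_closing(
                    mask, structure=np.ones((3, 3), dtype=bool), iterations=2
                )
                mask = ndimage.binary_fill_holes(closed)
            return mask.astype(np.uint8)
    warnings.warn("no interior dark component found; returning empty lobe mask", stacklevel=2)
    return np.zeros(image.shape, dtype=np.uint8)
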