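"""Iterative GrabCut energy minimisation.

The segmentation alpha over pixels minimises the energy

    E(alpha, k, theta, z) = U(alpha, k, theta, z) + V(alpha, z)

where U is the data term (negative log-likelihood of each pixel's colour
under its own class's Gaussian mixture model) and V is the
contrast-sensitive smoothness term over the 8-neighbourhood.  The
algorithm alternates GMM refitting with an exact min-cut relabeling of
the unfrozen pixels; pixels seeded in T_F / T_B by the trimap stay
foreground / background throughout.

The min-cut is solved with :func:`scipy.sparse.csgraph.maximum_flow`,
which needs integer capacities: energies are scaled by 2**20 before
rounding, so labelings are optimal up to that quantisation (about 1e-6
per graph edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.special import logsumexp

from .raster import MultispectralScene
from .trimap import Trimap, lloyd_kmeans

#: integer capacity scale for the max-flow solver (capacities must fit int32)
CAPACITY_SCALE = float(2**20)
#: terminal-link capacity pinning frozen pixels (int32-safe "infinity")
FROZEN_CAPACITY = int(2**30)
#: likelihood floor before taking logs
LIKELIHOOD_FLOOR = 1e-300

#: 8-neighbourhood: offsets to east, south, south-east, south-west
_NEIGHBOR_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0)))


@dataclass
class Labeling:
    """Hard segmentation alpha in {0 = background, 1 = foreground}."""

    alpha: np.ndarray
    frozen_fg: np.ndarray
    frozen_bg: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.uint8)
        self.frozen_fg = np.asarray(self.frozen_fg, dtype=bool)
        self.frozen_bg = np.asarray(self.frozen_bg, dtype=bool)
        if not np.isin(self.alpha, (0, 1)).all():
            raise ValueError("alpha must be binary")
        if np.any(self.frozen_fg & self.frozen_bg):
            raise ValueError("a pixel cannot be frozen to both classes")
        if np.any(self.alpha[self.frozen_fg] != 1) or np.any(self.alpha[self.frozen_bg] != 0):
            raise ValueError("alpha contradicts frozen assignments")


@dataclass
class GmmModel:
    """Per-class Gaussian mixture colour models (class 0 = bg, 1 = fg)."""

    weights: list[np.ndarray]  # per class: (K,) summing to 1
    means: list[np.ndarray]  # per class: (K, C)
    covs: list[np.ndarray]  # per class: (K, C, C), SPD after jitter

    def n_components(self, cls: int) -> int:
        return len(self.weights[cls])


@dataclass
class EnergyBreakdown:
    U: float
    V: float

    @property
    def E(self) -> float:
        return self.U + self.V


def _class_log_likelihood(z: np.ndarray, weights, means, covs) -> np.ndarray:
    """log sum_k w_k N(z; mu_k, Sigma_k) for an (n, C) array of colours."""
    n, C = z.shape
    comp = np.empty((len(weights), n))
    for k, (w, mu, cov) in enumerate(zip(weights, means, covs)):
        L = np.linalg.cholesky(cov)
        diff = z - mu
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        comp[k] = np.log(max(w, 1e-300)) - 0.5 * (maha + logdet + C * np.log(2 * np.pi))
    return logsumexp(comp, axis=0)


def _jittered_cov(x: np.ndarray, jitter: float = 1e-6) -> np.ndarray:
    C = x.shape[1]
    cov = np.cov(x.T, bias=False) if len(x) > 1 else np.zeros((C, C))
    cov = np.atleast_2d(cov) + jitter * np.eye(C)
    # escalate jitter until Cholesky succeeds (pathological collinear data)
    for _ in range(12):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + 10 * jitter * np.eye(C)
            jitter *= 10
    raise np.linalg.LinAlgError("covariance not positive-definite after jitter")


def fit_gmm(
    scene: MultispectralScene,
    labeling: Labeling,
    K: int = 5,
    seed: int = 0,
) -> GmmModel:
    """Fit the per-class mixture models, GrabCut style.

    Each class's pixels are partitioned into K components by seeded
    K-means on colour, parameters estimated from the members, then one
    maximum-likelihood reassignment and re-estimation pass.  A class with
    fewer than K (distinct) pixels gets a reduced K with a warning.
    """
    z = scene.composite.reshape(-1, scene.n_channels)
    alpha = labeling.alpha.ravel()
    rng = np.random.default_rng(seed)
    weights, means, covs = [], [], []
    for cls in (0, 1):
        x = z[alpha == cls]
        if len(x) == 0:
            raise ValueError(f"class {cls} has no pixels; cannot fit GMM")
        k_eff = min(K, len(np.unique(x, axis=0)))
        if k_eff < K:
            warnings.warn(f"class {cls}: only {k_eff} distinct colours; reducing K")
        if k_eff == 1:
            assign = np.zeros(len(x), dtype=np.int64)
        else:
            # cheap single-restart, few-iteration seeding: the component
            # structure is refined by the ML reassignment pass below
            assign, _ = lloyd_kmeans(x, k_eff, rng, max_iter=10, n_init=1)
        w, mu, cov = _estimate_components(x, assign, k_eff)
        # one hard ML reassignment + re-estimation pass
        ll = np.stack(
            [
                np.log(max(w[k], 1e-300))
                + _component_logpdf(x, mu[k], cov[k])
                for k in range(k_eff)
            ]
        )
        assign = np.argmax(ll, axis=0)
        w, mu, cov = _estimate_components(x, assign, k_eff)
        weights.append(w)
        means.append(mu)
        covs.append(cov)
    return GmmModel(weights=weights, means=means, covs=covs)


def _component_logpdf(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    C = x.shape[1]
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (x - mu).T)
    return -0.5 * (np.sum(sol**2, axis=0) + 2 * np.sum(np.log(np.diag(L))) + C * np.log(2 * np.pi))


def _estimate_components(x, assign, k_eff):
    C = x.shape[1]
    w = np.empty(k_eff)
    mu = np.empty((k_eff, C))
    cov = np.empty((k_eff, C, C))
    for k in range(k_eff):
        members = x[assign == k]
        if len(members) == 0:  # emptied component: keep it tiny on the class mean
            members = x
            w[k] = 0.0
        else:
            w[k] = len(members) / len(x)
        mu[k] = members.mean(axis=0)
        cov[k] = _jittered_cov(members)
    if w.sum() == 0:
        w[:] = 1.0
    w = w / w.sum()
    return w, mu, cov


def data_term(scene: MultispectralScene, labeling: Labeling, gmm: GmmModel) -> float:
    """U: sum over pixels of -log mixture likelihood under the pixel's class."""
    return float(np.sum(_pixel_data_costs(scene, gmm)[labeling.alpha.ravel(), np.arange(labeling.alpha.size)]))


def _pixel_data_costs(scene: MultispectralScene, gmm: GmmModel) -> np.ndarray:
    """(2, n_pixels) array of -log likelihood for bg (row 0) and fg (row 1)."""
    z = scene.composite.reshape(-1, scene.n_channels)
    costs = np.empty((2, len(z)))
    for cls in (0, 1):
        ll = _class_log_likelihood(z, gmm.weights[cls], gmm.means[cls], gmm.covs[cls])
        lik = np.maximum(np.exp(ll), LIKELIHOOD_FLOOR)
        costs[cls] = -np.log(lik)
    return costs


def estimate_beta(scene: MultispectralScene) -> float:
    """Contrast scale beta = 1 / (2 <||z_p - z_q||^2>) over 8-neighbour pairs."""
    z = scene.composite
    total, count = 0.0, 0
    for dr, dc, _ in _NEIGHBOR_OFFSETS:
        a, b = _shifted_pairs(z, dr, dc)
        total += float(np.sum((a - b) ** 2))
        count += a.shape[0] * a.shape[1] if a.ndim == 3 else a.size
    if count == 0:
        return 0.0
    mean_sq = total / count if count else 0.0
    return 0.0 if mean_sq <= 0 else 1.0 / (2.0 * mean_sq)


def _shifted_pairs(arr: np.ndarray, dr: int, dc: int):
    """Aligned views (a, b) of an array and its (dr, dc)-shifted neighbour."""
    H, W = arr.shape[:2]
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = arr[r0:r1, c0:c1]
    b = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a, b


def _pair_weights(scene: MultispectralScene, gamma: float, beta: float):
    """Per-offset smoothness weights gamma * exp(-beta ||dz||^2) / dist."""
    z = scene.composite
    out = []
    for dr, dc, dist in _NEIGHBOR_OFFSETS:
        a, b = _shifted_pairs(z, dr, dc)
        d2 = np.sum((a - b) ** 2, axis=-1)
        out.append((dr, dc, gamma * np.exp(-beta * d2) / dist))
    return out


def smoothness_term(
    scene: MultispectralScene,
    labeling: Labeling,
    gamma: float = 50.0,
    beta: float | None = None,
) -> float:
    """V: contrast-weighted penalty over discordant 8-neighbour pairs."""
    if beta is None:
        beta = estimate_beta(scene)
    alpha = labeling.alpha
    V = 0.0
    for dr, dc, w in _pair_weights(scene, gamma, beta):
        a, b = _shifted_pairs(alpha, dr, dc)
        V += float(np.sum(w[a != b]))
    return V


def energy(
    scene: MultispectralScene,
    labeling: Labeling,
    gmm: GmmModel,
    gamma: float = 50.0,
    beta: float | None = None,
) -> EnergyBreakdown:
    return EnergyBreakdown(
        U=data_term(scene, labeling, gmm),
        V=smoothness_term(scene, labeling, gamma=gamma, beta=beta),
    )


def mincut_relabel(
    scene: MultispectralScene,
    labeling: Labeling,
    gmm: GmmModel,
    gamma: float = 50.0,
    beta: float | None = None,
) -> Labeling:
    """Exact minimiser of E over unfrozen pixels for the fixed GMM.

    Builds the standard s/t graph (source = foreground): the terminal
    link cut when a pixel lands background carries the background data
    cost and vice versa; discordant neighbours pay the contrast weight.
    Frozen pixels carry a huge terminal capacity on their class side.
    """
    if beta is None:
        beta = estimate_beta(scene)
    H, W = scene.shape
    n = H * W
    costs = _pixel_data_costs(scene, gmm)  # (2, n)

    # negative log-likelihoods can go below zero (pdf > 1); subtracting the
    # per-pixel minimum from both terminal links shifts E by a constant
    # independent of the labeling and keeps capacities non-negative
    base = np.minimum(costs[0], costs[1])
    cap_src = np.round((costs[0] - base) * CAPACITY_SCALE).astype(np.int64)  # cut if bg
    cap_snk = np.round((costs[1] - base) * CAPACITY_SCALE).astype(np.int64)  # cut if fg
    ffg = labeling.frozen_fg.ravel()
    fbg = labeling.frozen_bg.ravel()
    cap_src[ffg] = FROZEN_CAPACITY
    cap_snk[ffg] = 0
    cap_snk[fbg] = FROZEN_CAPACITY
    cap_src[fbg] = 0

    rows, cols, caps = [], [], []
    idx = np.arange(n).reshape(H, W)
    for dr, dc, w in _pair_weights(scene, gamma, beta):
        a_idx, b_idx = _shifted_pairs(idx, dr, dc)
        wcap = np.round(w * CAPACITY_SCALE).astype(np.int64).ravel()
        rows.extend([a_idx.ravel(), b_idx.ravel()])
        cols.extend([b_idx.ravel(), a_idx.ravel()])
        caps.extend([wcap, wcap])

    source, sink = n, n + 1
    rows.append(np.full(n, source))
    cols.append(np.arange(n))
    caps.append(cap_src)
    rows.append(np.arange(n))
    cols.append(np.full(n, sink))
    caps.append(cap_snk)

    graph = sp.csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 2, n + 2),
        dtype=np.int64,
    )
    result = maximum_flow(graph, source, sink)
    residual = (graph - result.flow).tocsr()
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True, return_predecessors=False)
    reach = np.zeros(n + 2, dtype=bool)
    reach[order] = True

    new_alpha = reach[:n].reshape(H, W).astype(np.uint8)
    new_alpha[labeling.frozen_fg] = 1
    new_alpha[labeling.frozen_bg] = 0
    return Labeling(alpha=new_alpha, frozen_fg=labeling.frozen_fg, frozen_bg=labeling.frozen_bg)


def grabcut_iterate(
    scene: MultispectralScene,
    trimap: Trimap,
    n: int = 5,
    K: int = 5,
    gamma: float = 50.0,
    seed: int = 0,
) -> tuple[Labeling, list[EnergyBreakdown]]:
    """Alternate GMM refitting and min-cut relabeling from the trimap.

    All uncertain pixels start as possible foreground.  Runs ``n``
    iterations or until alpha stops changing; returns the final labeling
    and the per-iteration energy history (evaluated after each cut).
    """
    if not np.any(trimap.T_F):
        raise ValueError("empty T_F: cannot model the foreground class")
    if not np.any(trimap.T_B):
        raise ValueError("empty T_B: cannot model the background class")
    alpha0 = ((trimap.T_F == 1) | (trimap.T_U == 1)).astype(np.uint8)
    labeling = Labeling(
        alpha=alpha0,
        frozen_fg=trimap.T_F.astype(bool),
        frozen_bg=trimap.T_B.astype(bool),
    )
    beta = estimate_beta(scene)
    history: list[EnergyBreakdown] = []
    for it in range(n):
        gmm = fit_gmm(scene, labeling, K=K, seed=seed + it)
        new_labeling = mincut_relabel(scene, labeling, gmm, gamma=gamma, beta=beta)
        history.append(energy(scene, new_labeling, gmm, gamma=gamma, beta=beta))
        if np.array_equal(new_labeling.alpha, labeling.alpha):
            labeling = new_labeling
            break
        labeling = new_labeling
    return labeling, history
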