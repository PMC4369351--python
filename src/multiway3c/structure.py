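"""Diploid-aware 3D genome inference under a Poisson count model.

Each chromosome copy is a string of beads, one per locus copy; the bead map
``phi`` sends ``n`` beads onto ``m`` observed loci (n > m when diploid
segments exist).  Observed counts ``c_kl`` cannot distinguish homologs, so
for every locus pair with a nonzero count the model introduces proportions
``mu_ij`` apportioning the count among the same-copy bead-pair
configurations (inter-homolog configurations carry no counts).  The count
assigned to a bead pair is Poisson with mean ``d_ij ** alpha`` (``alpha =
-3``), giving the (relaxed, Gamma-function) log-likelihood

    L(X, mu) = sum_{(i,j)} [ mu_ij c * alpha * log d_ij - d_ij**alpha
                             - log Gamma(mu_ij c + 1) ] .

Inference alternates (1) a quasi-Newton ascent on bead coordinates ``X``
with a smooth hinge penalty keeping adjacent-bead distances below
``d_max`` (the 97% quantile of expected adjacent distances ``c**(-1/3)`` on
haploid chromosomes) and (2) an exact grid search on each locus pair's
``mu`` vector (step 0.01, proportions of multi-configuration groups boxed
into 0.3-0.7 -- the device that keeps homolog splits identifiable).  The
optimization is non-convex; multiple restarts are run and the top fraction
by log-likelihood returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .genome import BeadMap, BinTable

__all__ = [
    "ModelConfig",
    "StructureModel",
    "ContactGroups",
    "build_groups",
    "log_likelihood",
    "estimate_dmax",
    "mu_step",
    "structure_step",
    "infer",
    "superpose_rmsd",
    "structure_diameter",
]

log = logging.getLogger(__name__)

_D_FLOOR = 1e-9  # coincident beads are clamped here (and warned about)


@dataclass
class ModelConfig:
    """Tunable parameters of the inference.

    alpha: count-distance exponent (< 0); -3 is the empirical power law.
    dmax_quantile: quantile of adjacent-bead expected distances used as the
        upper bound d_max on adjacent-bead distances.
    mu_grid: grid step for the mu search (must divide [0, 1]).
    mu_box: (lo, hi) box applied to multi-configuration groups.
    restarts / top_fraction: random restarts and the fraction kept.
    """

    alpha: float = -3.0
    dmax_quantile: float = 0.97
    mu_grid: float = 0.01
    mu_box: tuple[float, float] = (0.3, 0.7)
    restarts: int = 10
    top_fraction: float = 0.1
    max_outer: int = 50
    rel_tol: float = 1e-6
    penalty: float = 100.0
    max_inner_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("alpha must be negative")
        if not 0 < self.dmax_quantile < 1:
            raise ValueError("dmax_quantile must lie in (0, 1)")
        if abs(round(1.0 / self.mu_grid) * self.mu_grid - 1.0) > 1e-9:
            raise ValueError("mu_grid must divide [0, 1]")


@dataclass
class ContactGroups:
    """Bead-pair structure of the nonzero locus-pair counts.

    ``pair_i``/``pair_j`` index beads; ``pair_c`` repeats the locus-pair
    count; groups (one per locus pair in D) are contiguous slices.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_c: np.ndarray
    group_slices: list[slice]
    group_boxed: list[bool]    # True for diploid-diploid (same-copy) groups
    adj_i: np.ndarray
    adj_j: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)


def build_groups(counts: np.ndarray, beadmap: BeadMap, bins: BinTable) -> ContactGroups:
    """Enumerate same-configuration bead pairs for every nonzero count.

    The diagonal (self-contacts of a locus) is excluded: a bead has no
    distance to itself.  Adjacent same-copy bead pairs (consecutive loci of
    one chromosome and homolog) are collected for the d_max constraint.
    """
    counts = np.asarray(counts, dtype=float)
    phi, labels = beadmap.phi, beadmap.copy_label
    beads_of = [beadmap.beads_for_locus(k) for k in range(beadmap.m)]
    cn = beadmap.copy_number()
    pi, pj, pc, slices, boxed = [], [], [], [], []
    pos = 0
    for k in range(beadmap.m):
        for l in range(k + 1, beadmap.m):
            c = counts[k, l]
            if c <= 0:
                continue
            both_dip = cn[k] == 2 and cn[l] == 2
            if both_dip:
                pairs = [
                    (i, j)
                    for i in beads_of[k]
                    for j in beads_of[l]
                    if labels[i] == labels[j]
                ]
            else:
                pairs = [(i, j) for i in beads_of[k] for j in beads_of[l]]
            for i, j in pairs:
                pi.append(i)
                pj.append(j)
                pc.append(c)
            slices.append(slice(pos, pos + len(pairs)))
            boxed.append(both_dip)
            pos += len(pairs)

    chrom = bins.chrom_of()
    ai, aj = [], []
    for i in range(beadmap.n):
        for j in range(beadmap.n):
            if j <= i or labels[i] != labels[j]:
                continue
            k, l = phi[i], phi[j]
            if l == k + 1 and chrom[k] == chrom[l]:
                ai.append(i)
                aj.append(j)
    return ContactGroups(
        pair_i=np.asarray(pi, dtype=int),
        pair_j=np.asarray(pj, dtype=int),
        pair_c=np.asarray(pc, dtype=float),
        group_slices=slices,
        group_boxed=boxed,
        adj_i=np.asarray(ai, dtype=int),
        adj_j=np.asarray(aj, dtype=int),
    )


def _distances(X: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(X[i] - X[j], axis=1)
    if (d < _D_FLOOR).any():
        log.warning("coincident beads encountered; distances clamped")
    return np.maximum(d, _D_FLOOR)


def log_likelihood(
    X: np.ndarray, mu: np.ndarray, groups: ContactGroups, alpha: float = -3.0
) -> float:
    """Poisson log-likelihood over the nonzero-count bead pairs."""
    d = _distances(X, groups.pair_i, groups.pair_j)
    muc = mu * groups.pair_c
    return float(
        np.sum(muc * alpha * np.log(d) - d ** alpha - gammaln(muc + 1.0))
    )


def estimate_dmax(
    counts: np.ndarray,
    beadmap: BeadMap,
    bins: BinTable,
    quantile: float = 0.97,
) -> float:
    """d_max from the expected adjacent-bead distances of haploid chromosomes.

    For consecutive haploid loci (k, k+1) with a positive count the expected
    distance is ``c ** (-1/3)``; d_max is the ``quantile`` quantile (linear
    interpolation), excluding outliers arising from normalization.
    """
    counts = np.asarray(counts, dtype=float)
    cn = beadmap.copy_number()
    chrom = bins.chrom_of()
    vals = []
    for k in range(beadmap.m - 1):
        if chrom[k] != chrom[k + 1]:
            continue
        if cn[k] != 1 or cn[k + 1] != 1:
            continue
        c = counts[k, k + 1]
        if c > 0:
            vals.append(c ** (-1.0 / 3.0))
    if not vals:
        raise ValueError("no positive adjacent counts on haploid chromosomes")
    return float(np.quantile(np.asarray(vals), quantile))


def _mu_lattice(size: int, step: float, box: tuple[float, float]) -> np.ndarray:
    """All mu vectors of length ``size`` on the step lattice with sum 1.

    Size-1 groups are forced to mu = 1; larger groups respect the box.
    """
    if size == 1:
        return np.array([[1.0]])
    lo, hi = box
    n_steps = round(1.0 / step)
    ticks = np.round(np.arange(0, n_steps + 1) * step, 10)
    ticks = ticks[(ticks >= lo - 1e-12) & (ticks <= hi + 1e-12)]
    out = []

    def rec(prefix: list[float], remaining: float, depth: int) -> None:
        if depth == size - 1:
            last = round(remaining, 10)
            if lo - 1e-12 <= last <= hi + 1e-12:
                out.append(prefix + [last])
            return
        for t in ticks:
            if t <= remaining + 1e-12:
                rec(prefix + [float(t)], remaining - float(t), depth + 1)

    rec([], 1.0, 0)
    if not out:
        raise ValueError("empty mu lattice; box incompatible with group size")
    return np.asarray(out)


def mu_step(
    X: np.ndarray, groups: ContactGroups, config: ModelConfig
) -> np.ndarray:
    """Exact grid search of mu, independently per locus-pair group."""
    d = _distances(X, groups.pair_i, groups.pair_j)
    logd = np.log(d)
    mu = np.empty(groups.n_pairs)
    lattice_cache: dict[tuple[int, bool], np.ndarray] = {}
    for sl, is_boxed in zip(groups.group_slices, groups.group_boxed):
        size = sl.stop - sl.start
        if size == 1:
            mu[sl] = 1.0
            continue
        # the box applies to every multi-configuration group: it is the
        # identifiability device keeping homolog splits non-degenerate
        key = (size, is_boxed)
        if key not in lattice_cache:
            lattice_cache[key] = _mu_lattice(size, config.mu_grid, config.mu_box)
        lat = lattice_cache[key]
        c = groups.pair_c[sl][0]
        # objective terms that depend on mu only
        obj = (lat * c * config.alpha) @ logd[sl] - gammaln(lat * c + 1.0).sum(axis=1)
        mu[sl] = lat[int(np.argmax(obj))]
    return mu


def _objective(
    x_flat: np.ndarray,
    mu: np.ndarray,
    groups: ContactGroups,
    alpha: float,
    dmax: float,
    penalty: float,
    n: int,
) -> tuple[float, np.ndarray]:
    """Negative penalized log-likelihood (Gamma terms omitted: constant in X)
    and its gradient."""
    X = x_flat.reshape(n, 3)
    i, j = groups.pair_i, groups.pair_j
    diff = X[i] - X[j]
    d = np.maximum(np.linalg.norm(diff, axis=1), _D_FLOOR)
    muc = mu * groups.pair_c
    f = -np.sum(muc * alpha * np.log(d) - d ** alpha)
    # dL/dd = muc * alpha / d - alpha * d^(alpha-1); negate for minimization
    g_d = -(muc * alpha / d - alpha * d ** (alpha - 1.0))
    grad = np.zeros_like(X)
    contrib = (g_d / d)[:, None] * diff
    np.add.at(grad, i, contrib)
    np.add.at(grad, j, -contrib)
    if len(groups.adj_i):
        ai, aj = groups.adj_i, groups.adj_j
        adiff = X[ai] - X[aj]
        ad = np.maximum(np.linalg.norm(adiff, axis=1), _D_FLOOR)
        excess = np.maximum(ad - dmax, 0.0)
        f += penalty * np.sum(excess ** 2)
        a_g = 2.0 * penalty * excess / ad
        acontrib = a_g[:, None] * adiff
        np.add.at(grad, ai, acontrib)
        np.add.at(grad, aj, -acontrib)
    return float(f), grad.ravel()


def structure_step(
    X0: np.ndarray,
    mu: np.ndarray,
    groups: ContactGroups,
    config: ModelConfig,
    dmax: float,
) -> np.ndarray:
    """Quasi-Newton ascent on X with the adjacent-distance hinge penalty.

    The interior-point solver of the original formulation is a solver
    choice; bound-penalized L-BFGS reaches the same local optima.  On
    optimizer failure the start point is perturbed once and retried.
    """
    n = X0.shape[0]
    args = (mu, groups, config.alpha, dmax, config.penalty, n)
    res = minimize(
        _objective, X0.ravel(), args=args, jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_inner_iter},
    )
    if not res.success and not np.isfinite(res.fun):
        jitter = np.random.default_rng(0).normal(scale=1e-3, size=X0.shape)
        res = minimize(
            _objective, (X0 + jitter).ravel(), args=args, jac=True,
            method="L-BFGS-B", options={"maxiter": config.max_inner_iter},
        )
        if not np.isfinite(res.fun):
            log.warning("structure step failed; returning start point")
            return X0
    return res.x.reshape(n, 3)


@dataclass
class StructureModel:
    """One inferred structure: bead coordinates and its log-likelihood."""

    X: np.ndarray
    mu: np.ndarray
    log_lik: float
    penalized: float
    n_outer: int
    converged: bool


def _penalized_loglik(X, mu, groups, config, dmax) -> float:
    f, _ = _objective(
        X.ravel(), mu, groups, config.alpha, dmax, config.penalty, X.shape[0]
    )
    muc = mu * groups.pair_c
    return -f - float(gammaln(muc + 1.0).sum())


def infer(
    counts: np.ndarray,
    beadmap: BeadMap,
    bins: BinTable,
    config: ModelConfig | None = None,
) -> list[StructureModel]:
    """Multi-restart alternating optimization of (X, mu).

    Initialization: X isotropic Gaussian scaled into the d_max ball; mu
    uniform within each group (projected into the box).  The alternation is
    monotone in the penalized objective: a structure step that would lower
    it is rejected.  Returns the top ``ceil(top_fraction * restarts)``
    models sorted by log-likelihood, deterministically for a fixed seed.
    """
    config = config or ModelConfig()
    groups = build_groups(counts, beadmap, bins)
    if groups.n_pairs == 0:
        raise ValueError("no nonzero contact counts")
    dmax = estimate_dmax(counts, beadmap, bins, config.dmax_quantile)
    rng = np.random.default_rng(config.seed)
    n = beadmap.n
    models: list[StructureModel] = []
    for _ in range(config.restarts):
        X = rng.normal(size=(n, 3)) * (dmax / 2.0)
        mu = np.empty(groups.n_pairs)
        for sl in groups.group_slices:
            mu[sl] = 1.0 / (sl.stop - sl.start)
        best = _penalized_loglik(X, mu, groups, config, dmax)
        converged = False
        outer = 0
        for outer in range(1, config.max_outer + 1):
            mu = mu_step(X, groups, config)
            X_new = structure_step(X, mu, groups, config, dmax)
            cand = _penalized_loglik(X_new, mu, groups, config, dmax)
            if cand >= best:
                X = X_new
            else:
                cand = _penalized_loglik(X, mu, groups, config, dmax)
            if abs(cand - best) <= config.rel_tol * max(1.0, abs(best)):
                best = max(best, cand)
                converged = True
                break
            best = max(best, cand)
        models.append(
            StructureModel(
                X=X, mu=mu,
                log_lik=log_likelihood(X, mu, groups, config.alpha),
                penalized=best, n_outer=outer, converged=converged,
            )
        )
    models.sort(key=lambda m: m.log_lik, reverse=True)
    k = max(1, int(round(config.top_fraction * config.restarts)))
    return models[:k]


# ------------------------------------------------------------------ helpers


def superpose_rmsd(
    A: np.ndarray, B: np.ndarray, allow_reflection: bool = True
) -> float:
    """RMSD of A onto B after optimal rigid superposition (Kabsch).

    With ``allow_reflection`` the optimal orthogonal (possibly improper)
    transform is used, as the likelihood cannot distinguish mirror images.
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = (U @ Vt).T
    if not allow_reflection and np.linalg.det(R) < 0:
        D = np.diag([1.0, 1.0, -1.0])
        R = (U @ D @ Vt).T
    return float(np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1))))


def structure_diameter(X: np.ndarray) -> float:
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    return float(d.max())


def export_structure(
    path: str, model: StructureModel, beadmap: BeadMap, bins: BinTable
) -> None:
    """TSV export: bead, chrom, bin, copy, x, y, z."""
    import pandas as pd

    chrom = bins.chrom_of()
    df = pd.DataFrame(
        {
            "bead": np.arange(beadmap.n),
            "chrom": chrom[beadmap.phi],
            "bin": beadmap.phi,
            "copy": beadmap.copy_label,
            "x": model.X[:, 0],
            "y": model.X[:, 1],
            "z": model.X[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)
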