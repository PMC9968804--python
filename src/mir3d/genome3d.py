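"""Reconstruction of a 3D genome model from a binned contact matrix.

Contact frequencies are converted to target ("wish") distances through a
power law, and coordinates are found by multi-restart minimization of the
normalized Kruskal stress

    stress(X) = sqrt( sum_{i<j} (d_ij(X) - delta_ij)^2 / sum_{i<j} delta_ij^2 )

where ``delta`` are the wish distances and ``d(X)`` the realized Euclidean
distances.  Each restart starts from random coordinates (the first restart
uses a classical-MDS / Torgerson initialization, which lands in the global
basin whenever the targets are close to Euclidean) and is polished with
L-BFGS-B on the analytic gradient.  The conformation with the smallest
final stress is returned, mirroring the generate-many / keep-best-matched
protocol used for chromatin models.

miRNAs are placed in the model by locating the bin whose half-open
genomic interval contains their TSS and inheriting that bin's coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, InvalidConfigError

logger = logging.getLogger(__name__)

BIN_COLUMNS = ("bin_id", "chrom", "start", "end")


def validate_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Check a bin table: dense 0..N-1 bin ids, contiguous non-overlapping bins."""
    missing = set(BIN_COLUMNS) - set(bins.columns)
    if missing:
        raise DataError(f"bin table missing columns: {sorted(missing)}")
    ids = bins["bin_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(len(bins))):
        raise DataError("bin_ids must be dense 0..N-1")
    for chrom, grp in bins.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["end"].to_numpy() <= g["start"].to_numpy()).any():
            raise DataError(f"empty or inverted bin on {chrom}")
        if not np.array_equal(g["start"].to_numpy()[1:], g["end"].to_numpy()[:-1]):
            raise DataError(f"bins on {chrom} are not contiguous")
    return bins


@dataclass
class ContactMatrix:
    """Symmetric, zero-diagonal matrix of contact counts over genome bins."""

    counts: np.ndarray
    bins: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise DataError("contact matrix must be square")
        if not np.allclose(c, c.T):
            raise DataError("contact matrix must be symmetric")
        if (c < 0).any():
            raise DataError("contact counts must be nonnegative")
        if np.abs(np.diag(c)).max(initial=0.0) != 0.0:
            raise DataError("contact matrix diagonal must be zero")
        if self.bins is not None and len(self.bins) != c.shape[0]:
            raise DataError("contact matrix does not match bin table size")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class DistanceTargets:
    """Wish distances for the embedding; zero-contact pairs sit at ``cap``."""

    wish: np.ndarray
    alpha: float
    cap: float

    def __post_init__(self) -> None:
        w = np.asarray(self.wish, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError("wish-distance matrix must be square")
        if not np.allclose(w, w.T):
            raise DataError("wish-distance matrix must be symmetric")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off <= 0).any():
            raise DataError("off-diagonal wish distances must be positive")
        if off.size and (off > self.cap + 1e-12).any():
            raise DataError("wish distances exceed the stated cap")
        self.wish = w

    @property
    def n_points(self) -> int:
        return self.wish.shape[0]


@dataclass
class Genome3DModel:
    """Per-bin xyz coordinates plus the normalized stress of the fit."""

    coords: np.ndarray
    stress: float
    n_restarts_used: int = 0
    restart_stresses: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise DataError("coordinates must be an (n, 3) array")
        if not np.isfinite(c).all():
            raise DataError("coordinates must be finite")
        if self.stress < 0:
            raise DataError("stress must be nonnegative")
        self.coords = c

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]


def contacts_to_distances(
    contacts: ContactMatrix,
    alpha: float = 1.0,
    cap_factor: float = 1.5,
    scale: float = 1.0,
) -> DistanceTargets:
    """Convert contacts to wish distances via ``d = (c / scale) ** -alpha``.

    ``scale`` is the expected count at unit distance; it defaults to 1 (the
    plain power-law convention) and can be set to a known simulation
    contact scale so the model keeps the generating length units.
    Zero-contact pairs receive ``cap_factor`` times the largest finite
    distance.
    """
    if alpha <= 0:
        raise InvalidConfigError("alpha must be positive")
    if cap_factor < 1:
        raise InvalidConfigError("cap_factor must be >= 1")
    if scale <= 0:
        raise InvalidConfigError("scale must be positive")
    c = contacts.counts
    n = c.shape[0]
    off = ~np.eye(n, dtype=bool)
    pos = off & (c > 0)
    if not pos.any():
        raise DataError("contact matrix carries no information (all zero)")
    with np.errstate(divide="ignore"):
        d = np.where(pos, (c / scale) ** (-alpha), 0.0)
    dmax = d[pos].max()
    cap = cap_factor * dmax
    d[off & ~pos] = cap
    np.fill_diagonal(d, 0.0)
    return DistanceTargets(wish=d, alpha=alpha, cap=cap)


def stress(
    coords: np.ndarray, targets: DistanceTargets, weight_exponent: float = 0.0
) -> float:
    """Normalized stress of a configuration against wish distances.

    ``weight_exponent=0`` gives the plain normalized Kruskal stress
    ``sqrt(sum (d-delta)^2 / sum delta^2)``.  A positive exponent q weights
    each pair by ``delta^-q``; q=2 turns residuals into relative errors,
    which keeps short (well-measured) distances from being drowned out by
    long, count-starved ones.
    """
    coords = np.asarray(coords, dtype=float)
    n = targets.n_points
    if coords.shape != (n, 3):
        raise DataError(f"coords shape {coords.shape} does not match {n} targets")
    iu = np.triu_indices(n, k=1)
    delta = targets.wish[iu]
    w = delta**-weight_exponent if weight_exponent else np.ones_like(delta)
    d = pdist(coords)
    return float(np.sqrt(np.sum(w * (d - delta) ** 2) / np.sum(w * delta**2)))


def _raw_stress_and_grad(
    x: np.ndarray, wish: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Objective sum_{i<j} w_ij (d_ij - delta_ij)^2 and its gradient."""
    n = wish.shape[0]
    coords = x.reshape(n, 3)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, 1.0)  # dummy to avoid 0/0; diagonal excluded below
    resid = d - wish
    np.fill_diagonal(resid, 0.0)
    wr = w * resid
    f = 0.5 * float(np.sum(wr * resid))  # each pair counted twice -> halve
    coef = wr / np.maximum(d, 1e-12)
    grad = 2.0 * np.einsum("ij,ijk->ik", coef, diff)
    return f, grad.ravel()


def _classical_mds_init(wish: np.ndarray) -> np.ndarray:
    """Torgerson double-centering initialization from squared wish distances."""
    n = wish.shape[0]
    d2 = wish**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:3]
    vals3 = np.clip(vals[idx], 0.0, None)
    out = np.zeros((n, 3))
    out[:, : len(idx)] = vecs[:, idx] * np.sqrt(vals3)
    return out


def embed(
    targets: DistanceTargets,
    n_restarts: int = 300,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int | None = None,
    weight_exponent: float = 2.0,
) -> Genome3DModel:
    """Multi-restart stress minimization; returns the minimum-stress conformation.

    The objective is the weighted normalized stress of :func:`stress`; the
    default ``weight_exponent=2`` fits relative distance errors, the robust
    choice when long-range wish distances come from sparse counts (0 recovers
    plain Kruskal stress).  Restart 0 starts from classical MDS; the
    remaining restarts start from random Gaussian coordinates scaled to the
    mean wish distance.  Each restart is optimized with L-BFGS-B.
    Non-convergence within ``max_iter`` returns the best configuration so
    far with ``converged=False`` and a logged warning.
    """
    if n_restarts < 1:
        raise InvalidConfigError("n_restarts must be >= 1")
    if targets.n_points < 2:
        raise DataError("need at least 2 points to embed")
    wish = targets.wish
    n = targets.n_points
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    iu = np.triu_indices(n, k=1)
    scale = wish[iu].mean()
    with np.errstate(divide="ignore"):
        w = wish**-weight_exponent if weight_exponent else np.ones_like(wish)
    np.fill_diagonal(w, 0.0)
    denom = np.sum(w[iu] * wish[iu] ** 2)

    best = None
    finals = np.empty(n_restarts)
    ok = np.zeros(n_restarts, dtype=bool)
    for r in range(n_restarts):
        if r == 0:
            x0 = _classical_mds_init(wish)
        else:
            x0 = rng.normal(scale=scale, size=(n, 3))
        res = minimize(
            _raw_stress_and_grad,
            x0.ravel(),
            args=(wish, w),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        finals[r] = np.sqrt(res.fun / denom)
        ok[r] = bool(res.success)
        if best is None or finals[r] < best[0]:
            best = (finals[r], res.x.reshape(n, 3), ok[r])
    assert best is not None
    if not best[2]:
        logger.warning(
            "embedding restart did not converge within max_iter=%d; "
            "returning best configuration so far (stress=%.3g)",
            max_iter,
            best[0],
        )
    return Genome3DModel(
        coords=best[1],
        stress=float(best[0]),
        n_restarts_used=n_restarts,
        restart_stresses=finals,
        converged=bool(best[2]),
    )


def procrustes_rmsd(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = True
) -> float:
    """RMSD of ``b`` onto ``a`` after optimal translation, rotation and scaling.

    Reflections are included in the search unless ``allow_reflection`` is
    False (Kabsch-style determinant correction).  Units are those of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise DataError("point sets must share shape with >= 3 rows")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    norm_b = np.sum(bc**2)
    if norm_b == 0 or np.sum(ac**2) == 0:
        raise DataError("degenerate (all-coincident) point set")
    u, s, vt = np.linalg.svd(bc.T @ ac)
    sign = np.ones(len(s))
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        sign[-1] = -1.0
    rot = u @ np.diag(sign) @ vt
    scale = float(np.sum(s * sign)) / norm_b
    resid = ac - scale * bc @ rot
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def map_tss_to_coords(
    annotation: pd.DataFrame, bins: pd.DataFrame, model: Genome3DModel
) -> pd.DataFrame:
    """Assign each uniquely mapped miRNA the coordinates of its TSS bin.

    Bins are 0-based half-open; a TSS equal to a bin boundary belongs to the
    bin that starts there.  Non-unique miRNAs, TSSs on chromosomes absent
    from the bin table, and TSSs outside every bin are dropped with logged
    counts.  Output rows are sorted by miRNA id so the result does not
    depend on annotation row order.
    """
    validate_bins(bins)
    if model.n_bins != len(bins):
        raise DataError("model size does not match bin table")
    counts = annotation["mirna_id"].value_counts()
    multi = set(counts[counts > 1].index) | set(
        annotation.loc[~annotation["unique"].astype(bool), "mirna_id"]
    )
    uniq = annotation[~annotation["mirna_id"].isin(multi)]
    if len(multi):
        logger.info("map_tss_to_coords: dropped %d non-unique miRNAs", len(multi))

    per_chrom = {
        chrom: grp.sort_values("start") for chrom, grp in bins.groupby("chrom")
    }
    rows = []
    n_bad_chrom = n_outside = 0
    for rec in uniq.itertuples(index=False):
        grp = per_chrom.get(rec.chrom)
        if grp is None:
            n_bad_chrom += 1
            continue
        starts = grp["start"].to_numpy()
        idx = np.searchsorted(starts, rec.tss, side="right") - 1
        if idx < 0 or rec.tss >= grp["end"].iloc[idx]:
            n_outside += 1
            continue
        bid = int(grp["bin_id"].iloc[idx])
        x, y, z = model.coords[bid]
        rows.append((rec.mirna_id, bid, x, y, z))
    if n_bad_chrom:
        logger.warning(
            "map_tss_to_coords: %d miRNAs on chromosomes absent from the bin table",
            n_bad_chrom,
        )
    if n_outside:
        logger.warning("map_tss_to_coords: %d TSSs outside any bin", n_outside)
    out = pd.DataFrame(rows, columns=["mirna_id", "bin_id", "x", "y", "z"])
    return out.sort_values("mirna_id", kind="stable").reset_index(drop=True)
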