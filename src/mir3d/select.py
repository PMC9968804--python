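"""Label-association scoring, 3D density clustering and feature-panel builders.

The selection strategy: score every miRNA by Spearman correlation between
its expression vector and the 0/1 disease label; cluster the 3D-mapped
miRNAs with DBSCAN on their <x, y, z> coordinates (noise points become
singleton "standalone" clusters); then build panels —

``all``         every miRNA surviving profiling,
``top_scc``     the k highest |rho| with p below a cutoff,
``overlap_3d``  miRNAs present in both the expression matrix and the 3D model,
``cluster_3d``  per-cluster representatives: seats apportioned to clusters by
                largest remainder in proportion to cluster size, each seat
                filled by the cluster's next-highest |rho| member.

For ``cluster_3d`` an optional significance prefilter (default: on, with
Benjamini-Hochberg adjustment) restricts members and seat counts to miRNAs
whose label association survives multiple-testing control; without it,
size-proportional seats merely sample the genome uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from .errors import DataError, InvalidConfigError
from .profiling import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeaturePanel:
    """Ordered, duplicate-free list of selected miRNA ids."""

    mirna_ids: list[str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise DataError("panel ids must be unique")

    def __len__(self) -> int:
        return len(self.mirna_ids)


@dataclass
class SpatialClustering:
    """Partition of 3D-mapped miRNAs; DBSCAN noise promoted to singletons."""

    assignments: pd.Series  # index mirna_id -> cluster id
    eps: float
    min_pts: int

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignments))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.assignments.index[self.assignments == cluster_id])

    def sizes(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in self.assignments.value_counts().items()}

    def is_singleton(self, cluster_id: int) -> bool:
        return self.sizes()[cluster_id] == 1

    @property
    def n_multi(self) -> int:
        return sum(1 for n in self.sizes().values() if n > 1)

    @property
    def n_singletons(self) -> int:
        return sum(1 for n in self.sizes().values() if n == 1)


def spearman_scores(
    m: ExpressionMatrix, method: str = "t", n_perm: int = 9999, seed: int = 0
) -> pd.DataFrame:
    """Per-miRNA Spearman rho against the 0/1 label, with two-sided p.

    Mid-rank ties; p from the t approximation ``t = rho sqrt((n-2)/(1-rho^2))``
    (``method="permutation"`` draws label permutations instead, for tiny n).
    Constant miRNA vectors get rho=0, p=1 and are flagged.
    """
    y = m.labels.to_numpy()
    n = m.n_samples
    if n < 3:
        raise DataError("need at least 3 samples")
    if len(set(y)) < 2:
        raise DataError("both labels must be present")
    x = m.signal.to_numpy()
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    sx = np.sqrt((rxc**2).sum(axis=1))
    sy = np.sqrt((ryc**2).sum())
    constant = sx == 0
    denom = np.where(constant, 1.0, sx * sy)
    rho = (rxc @ ryc) / denom
    rho = np.clip(np.where(constant, 0.0, rho), -1.0, 1.0)

    if method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))  # +-inf at rho = +-1
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(rho))
        for _ in range(n_perm):
            yp = ryc[rng.permutation(n)]
            rp = (rxc @ yp) / denom
            exceed += np.abs(rp) >= np.abs(rho) - 1e-12
        p = (1.0 + exceed) / (n_perm + 1.0)
    else:
        raise InvalidConfigError(f"unknown p-value method {method!r}")
    p = np.where(constant, 1.0, p)
    if constant.any():
        logger.warning("spearman_scores: %d constant miRNA vectors", constant.sum())
    return pd.DataFrame(
        {
            "rho": rho,
            "abs_rho": np.abs(rho),
            "p": p,
            "constant": constant,
        },
        index=pd.Index(m.signal.index, name="mirna_id"),
    )


def top_k_by_score(scores: pd.DataFrame, k: int, p_max: float = 0.05) -> FeaturePanel:
    """Top-k miRNAs by |rho| among those with p < p_max (ties: id order)."""
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    passed = scores[scores["p"] < p_max]
    if passed.empty:
        logger.warning("top_k_by_score: no miRNA passes p < %g", p_max)
        return FeaturePanel([], "top_scc", {"k": k, "p_max": p_max})
    order = passed.assign(_id=passed.index.astype(str)).sort_values(
        ["abs_rho", "_id"], ascending=[False, True]
    )
    ids = list(order.index[: min(k, len(order))])
    return FeaturePanel(ids, "top_scc", {"k": k, "p_max": p_max})


def dbscan_cluster(
    table: pd.DataFrame, eps: float = 3.0, min_pts: int = 2
) -> SpatialClustering:
    """Standard DBSCAN on miRNA <x, y, z>; noise points become singletons.

    With the default ``min_pts=2`` every non-isolated point is core, so the
    partition equals the connected components of the eps-neighbourhood graph
    and is invariant to input order.  Multi-member clusters are labeled
    0..K-1 in DBSCAN discovery order; singletons get the following ids in
    row order.
    """
    if table.empty:
        raise DataError("3D table is empty")
    if eps <= 0:
        raise InvalidConfigError("eps must be positive")
    if min_pts < 2:
        raise InvalidConfigError("min_pts must be >= 2")
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(coords).labels_.copy()
    nxt = labels.max() + 1
    for i in np.flatnonzero(labels == -1):
        labels[i] = nxt
        nxt += 1
    return SpatialClustering(
        assignments=pd.Series(labels, index=pd.Index(table["mirna_id"], name="mirna_id")),
        eps=eps,
        min_pts=min_pts,
    )


def largest_remainder(sizes: Mapping[Hashable, int], m: int) -> dict:
    """Apportion ``m`` seats to clusters in proportion to their sizes.

    Floors of the exact quotas first; leftover seats go to the largest
    fractional remainders (ties: larger cluster first, then lexicographic
    cluster id).  No allocation exceeds its cluster size; the total equals
    ``min(m, sum(sizes))``.
    """
    if m < 0:
        raise InvalidConfigError("m must be >= 0")
    total = sum(sizes.values())
    if any(s < 0 for s in sizes.values()):
        raise InvalidConfigError("cluster sizes must be nonnegative")
    m_eff = min(m, total)
    if total == 0 or m_eff == 0:
        return {c: 0 for c in sizes}
    alloc = {}
    remainders = {}
    for c, s in sizes.items():
        quota = m_eff * s / total
        alloc[c] = math.floor(quota)
        remainders[c] = quota - alloc[c]
    left = m_eff - sum(alloc.values())
    order = sorted(sizes, key=lambda c: (-remainders[c], -sizes[c], str(c)))
    for c in order:
        if left == 0:
            break
        if alloc[c] < sizes[c]:
            alloc[c] += 1
            left -= 1
    assert left == 0 and sum(alloc.values()) == m_eff
    return alloc


def proportional_representatives(
    clustering: SpatialClustering,
    scores: pd.DataFrame,
    m: int,
    p_max: float | None = None,
    p_adjust: str | None = "bh",
    at_least_one: bool = False,
) -> FeaturePanel:
    """Per-cluster representatives: largest-remainder seats, filled by |rho|.

    ``p_max`` (optional) restricts members — and hence cluster sizes used
    for apportionment — to miRNAs with (BH-adjusted, unless
    ``p_adjust=None``) p below the cutoff.  ``at_least_one`` grants every
    non-empty cluster a seat before proportional apportionment of the rest.
    """
    if m < 1:
        raise InvalidConfigError("m must be >= 1")
    members = clustering.assignments
    missing = set(members.index) - set(scores.index)
    if missing:
        raise DataError(f"clustered miRNAs without scores: {sorted(missing)[:5]}")
    tab = scores.loc[members.index].copy()
    tab["cluster"] = members.to_numpy()
    if p_max is not None:
        if p_adjust == "bh":
            tab["p_eff"] = stats.false_discovery_control(tab["p"], method="bh")
        elif p_adjust is None:
            tab["p_eff"] = tab["p"]
        else:
            raise InvalidConfigError(f"unknown p adjustment {p_adjust!r}")
        tab = tab[tab["p_eff"] < p_max]
    params = {"m": m, "p_max": p_max, "p_adjust": p_adjust}
    if tab.empty:
        logger.warning("proportional_representatives: no eligible miRNAs")
        return FeaturePanel([], "cluster_3d", params)
    sizes = {int(c): int(n) for c, n in tab["cluster"].value_counts().items()}
    total = sum(sizes.values())
    if m > total:
        logger.warning(
            "requested %d representatives but only %d eligible miRNAs", m, total
        )
    base = {c: 0 for c in sizes}
    m_eff = min(m, total)
    if at_least_one:
        for c in sorted(sizes, key=lambda c: (-sizes[c], str(c))):
            if sum(base.values()) >= m_eff:
                break
            base[c] = 1
        rest = largest_remainder(
            {c: sizes[c] - base[c] for c in sizes}, m_eff - sum(base.values())
        )
        alloc = {c: base[c] + rest[c] for c in sizes}
    else:
        alloc = largest_remainder(sizes, m_eff)
    ids: list[str] = []
    for c in sorted(alloc):
        if alloc[c] == 0:
            continue
        grp = tab[tab["cluster"] == c]
        grp = grp.assign(_id=grp.index.astype(str)).sort_values(
            ["abs_rho", "_id"], ascending=[False, True]
        )
        ids.extend(grp.index[: alloc[c]])
    return FeaturePanel(ids, "cluster_3d", params)


def overlap_3d_panel(m: ExpressionMatrix, table: pd.DataFrame) -> FeaturePanel:
    """miRNAs present in both the expression matrix and the 3D table."""
    in3d = set(table["mirna_id"])
    ids = [mid for mid in m.signal.index if mid in in3d]
    if not ids:
        logger.warning("overlap_3d_panel: empty overlap")
    return FeaturePanel(ids, "overlap_3d", {})


def all_panel(m: ExpressionMatrix) -> FeaturePanel:
    """Every miRNA in the (profiled) expression matrix."""
    return FeaturePanel(list(m.signal.index), "all", {})


def random_panel(ids: Sequence[str], size: int, seed: int = 0) -> FeaturePanel:
    """Uniformly random size-matched panel (baseline for comparisons)."""
    ids = list(ids)
    if size > len(ids):
        raise InvalidConfigError("requested panel larger than id universe")
    rng = np.random.default_rng(seed)
    pick = sorted(rng.choice(ids, size=size, replace=False))
    return FeaturePanel(pick, "random", {"size": size, "seed": seed})
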