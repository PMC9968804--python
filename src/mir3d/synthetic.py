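"""Synthetic toy genomes, 3D structures, contact maps and expression data.

The generator plants a known truth so every downstream stage can be tested
for recovery: a segmented toy genome folds into compact spatial domains
(random-walk backbone, bins pulled toward their domain centroid), contacts
decay as a power law of 3D distance with optional Poisson counting noise,
miRNA TSSs are scattered uniformly over the genome (a configurable fraction
multi-mapped, hence not uniquely annotatable), and case/control expression
is log-normal with the disease effect confined to miRNAs residing in a few
designated spatial domains.  Three internal-control miRNAs with
case-independent expectation are appended so control normalization is
exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, InvalidConfigError
from .genome3d import ContactMatrix, Genome3DModel, map_tss_to_coords, validate_bins
from .profiling import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Ids of the three internal-control miRNAs appended to every simulated matrix.
CONTROL_IDS = ("ctrl-mir-1", "ctrl-mir-2", "ctrl-mir-3")

# Tags used to derive independent per-stage random substreams from one seed.
_STAGE_STRUCTURE = 1
_STAGE_CONTACTS = 2
_STAGE_ANNOTATION = 3
_STAGE_EXPRESSION = 4


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([stage, int(seed)]))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset (seed-deterministic).

    Defaults are a desk-scale rendition of a serum-miRNA case/control cohort:
    100 cases + 100 controls, 300 miRNAs of which 20 informative miRNAs sit
    in 2 spatial domains, 10% of miRNAs multi-mapped.  Length units are set
    by ``step``: with step 4 and compaction 0.9, ~10-bin domains have
    diameter ~2.5 and inter-domain gaps ~12, so a DBSCAN radius of 3 in
    model units separates domains.
    """

    n_chrom: int = 4
    bins_per_chrom: int = 50
    bin_size: int = 100_000
    n_domains: int = 20
    compaction: float = 0.9
    step: float = 4.0
    n_mirna: int = 300
    frac_multimapped: float = 0.1
    n_case: int = 100
    n_control: int = 100
    effect_size: float = 1.0
    n_informative: int = 20
    n_informative_clusters: int = 2
    log_mean_loc: float = 9.0
    log_mean_scale: float = 1.0
    log_sd: float = 1.0
    control_log_mean: float = 5.0
    control_log_sd: float = 0.1
    contact_decay_exponent: float = 1.0  # beta
    contact_scale: float = 100.0  # k, expected count at unit distance
    contact_noise: str = "poisson"
    seed: int = 0

    def validate(self) -> "SimConfig":
        positive = {
            "n_chrom": self.n_chrom,
            "bins_per_chrom": self.bins_per_chrom,
            "bin_size": self.bin_size,
            "n_domains": self.n_domains,
            "step": self.step,
            "n_mirna": self.n_mirna,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_informative": self.n_informative,
            "n_informative_clusters": self.n_informative_clusters,
            "log_mean_scale": self.log_mean_scale,
            "log_sd": self.log_sd,
            "contact_decay_exponent": self.contact_decay_exponent,
            "contact_scale": self.contact_scale,
        }
        for name, value in positive.items():
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        if not 0 <= self.frac_multimapped < 1:
            raise InvalidConfigError("frac_multimapped must be in [0, 1)")
        if not 0 <= self.compaction < 1:
            raise InvalidConfigError("compaction must be in [0, 1)")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if self.contact_noise not in ("none", "poisson"):
            raise InvalidConfigError(f"unknown contact noise {self.contact_noise!r}")
        return self


@dataclass
class TruthClustering:
    """Ground-truth spatial cluster of every mapped miRNA, plus the clusters
    designated to carry the disease signal."""

    assignments: pd.Series  # mirna_id -> cluster id
    informative_clusters: tuple[int, ...]


@dataclass
class GroundTruth:
    """Planted truth recorded next to each simulated dataset."""

    informative_mirnas: frozenset
    effect_size: float
    informative_clusters: tuple[int, ...]
    control_ids: tuple[str, ...] = CONTROL_IDS
    true_coords: np.ndarray | None = None


@dataclass
class SimulatedDataset:
    """Everything one pipeline run needs, with the planted truth attached."""

    config: SimConfig
    bins: pd.DataFrame
    structure: Genome3DModel
    domain_of_bin: np.ndarray
    contacts: ContactMatrix
    annotation: pd.DataFrame
    expression: ExpressionMatrix
    truth: GroundTruth
    truth_clusters: TruthClustering = field(repr=False, default=None)


def make_toy_genome(n_chrom: int, bins_per_chrom: int, bin_size: int) -> pd.DataFrame:
    """Segment a toy genome into equal bins, 0-based half-open coordinates."""
    if n_chrom < 1 or bins_per_chrom < 1 or bin_size < 1:
        raise InvalidConfigError("n_chrom, bins_per_chrom and bin_size must be >= 1")
    rows = []
    bid = 0
    for c in range(1, n_chrom + 1):
        for b in range(bins_per_chrom):
            rows.append((bid, f"chr{c}", b * bin_size, (b + 1) * bin_size))
            bid += 1
    return pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end"])


def domain_assignment(bins: pd.DataFrame, n_domains: int) -> np.ndarray:
    """Contiguous domain label per bin; domains never span chromosomes.

    ``n_domains`` is distributed across chromosomes as evenly as possible
    with at least one domain per chromosome, so the effective count is
    ``max(n_domains, n_chrom)``.
    """
    if n_domains < 1:
        raise InvalidConfigError("n_domains must be >= 1")
    chroms = list(dict.fromkeys(bins["chrom"]))
    n_chrom = len(chroms)
    base = max(n_domains, n_chrom)
    per_chrom = [base // n_chrom + (1 if i < base % n_chrom else 0) for i in range(n_chrom)]
    labels = np.empty(len(bins), dtype=int)
    nxt = 0
    for chrom, k in zip(chroms, per_chrom):
        idx = bins.index[bins["chrom"] == chrom].to_numpy()
        for part in np.array_split(idx, k):
            labels[part] = nxt
            nxt += 1
    return labels


def simulate_structure(
    bins: pd.DataFrame,
    n_domains: int = 20,
    compaction: float = 0.9,
    seed: int = 0,
    step: float = 4.0,
) -> Genome3DModel:
    """Ground-truth 3D structure: per-chromosome random walk + domain compaction.

    Each chromosome is an independent random walk with fixed step length,
    offset along x so chromosomes occupy distinct territories.  Bins are
    then pulled toward their domain centroid by ``compaction`` (0 leaves the
    pure walk untouched).
    """
    validate_bins(bins)
    if not 0 <= compaction < 1:
        raise InvalidConfigError("compaction must be in [0, 1)")
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    rng = _stage_rng(seed, _STAGE_STRUCTURE)
    chroms = list(dict.fromkeys(bins["chrom"]))
    max_nb = int(bins.groupby("chrom").size().max())
    spacing = 2.0 * step * np.sqrt(max_nb)
    coords = np.empty((len(bins), 3))
    for ci, chrom in enumerate(chroms):
        idx = bins.index[bins["chrom"] == chrom].to_numpy()
        nb = len(idx)
        steps = rng.normal(size=(nb, 3))
        steps *= step / np.linalg.norm(steps, axis=1, keepdims=True)
        walk = np.cumsum(steps, axis=0)
        walk += np.array([ci * spacing, 0.0, 0.0]) - walk[0]
        coords[idx] = walk
    if compaction > 0:
        labels = domain_assignment(bins, n_domains)
        for d in np.unique(labels):
            sel = labels == d
            centroid = coords[sel].mean(axis=0)
            coords[sel] = centroid + (1.0 - compaction) * (coords[sel] - centroid)
    return Genome3DModel(coords=coords, stress=0.0, n_restarts_used=0)


def structure_to_contacts(
    model: Genome3DModel,
    beta: float = 1.0,
    k: float = 100.0,
    seed: int = 0,
    noise: str = "poisson",
    bins: pd.DataFrame | None = None,
) -> ContactMatrix:
    """Contacts with expectation ``k * d^-beta`` per bin pair, zero diagonal.

    ``noise="none"`` returns the expectation itself; ``"poisson"`` draws
    counts (standard for sequencing-count data), symmetrized from one
    upper-triangle draw.
    """
    if beta <= 0 or k <= 0:
        raise InvalidConfigError("beta and k must be positive")
    if noise not in ("none", "poisson"):
        raise InvalidConfigError(f"unknown noise model {noise!r}")
    if model.n_bins < 2:
        raise DataError("need at least 2 bins")
    d = squareform(pdist(model.coords))
    n = model.n_bins
    iu = np.triu_indices(n, k=1)
    zero = np.flatnonzero(d[iu] == 0)
    if zero.size:
        i, j = iu[0][zero[0]], iu[1][zero[0]]
        raise DataError(f"bins {i} and {j} are coincident (distance 0)")
    expected = np.zeros((n, n))
    expected[iu] = k * d[iu] ** (-beta)
    if noise == "poisson":
        rng = _stage_rng(seed, _STAGE_CONTACTS)
        expected[iu] = rng.poisson(expected[iu]).astype(float)
    counts = expected + expected.T
    return ContactMatrix(counts=counts, bins=bins)


def make_annotation(
    bins: pd.DataFrame, n_mirna: int, frac_multimapped: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Random miRNA TSS annotation over the toy genome.

    Exactly ``round(frac_multimapped * n_mirna)`` miRNAs are multi-mapped:
    they appear with two genomic records, both flagged non-unique, the way
    a precursor mapping to several loci defeats unique annotation.
    """
    validate_bins(bins)
    if n_mirna < 1:
        raise InvalidConfigError("n_mirna must be >= 1")
    if not 0 <= frac_multimapped < 1:
        raise InvalidConfigError("frac_multimapped must be in [0, 1)")
    rng = _stage_rng(seed, _STAGE_ANNOTATION)
    chrom_len = bins.groupby("chrom", sort=False)["end"].max()
    chrom_names = list(chrom_len.index)
    cum = np.cumsum(chrom_len.to_numpy())
    total = int(cum[-1])

    def draw_locus() -> tuple[str, int]:
        u = int(rng.integers(0, total))
        ci = int(np.searchsorted(cum, u, side="right"))
        offset = u - (0 if ci == 0 else int(cum[ci - 1]))
        return chrom_names[ci], offset

    ids = [f"mir-{i:04d}" for i in range(1, n_mirna + 1)]
    n_multi = int(round(frac_multimapped * n_mirna))
    multi = set(rng.choice(ids, size=n_multi, replace=False)) if n_multi else set()
    rows = []
    extra = []
    for mid in ids:
        chrom, tss = draw_locus()
        strand = "+" if rng.integers(0, 2) else "-"
        uniq = mid not in multi
        rows.append((mid, chrom, tss, strand, uniq))
        if not uniq:
            chrom2, tss2 = draw_locus()
            strand2 = "+" if rng.integers(0, 2) else "-"
            extra.append((mid, chrom2, tss2, strand2, False))
    return pd.DataFrame(
        rows + extra, columns=["mirna_id", "chrom", "tss", "strand", "unique"]
    )


def simulate_expression(
    annotation: pd.DataFrame,
    clustering_truth: TruthClustering,
    cfg: SimConfig,
    true_coords: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Case/control log-normal expression with the signal planted spatially.

    Every annotated miRNA gets a per-dataset log-mean drawn from
    N(log_mean_loc, log_mean_scale) and per-sample log-normal noise with
    log-SD ``log_sd``.  miRNAs belonging to the designated informative
    spatial clusters (up to ``n_informative`` of them, filled cluster by
    cluster) have their log-mean shifted by ``effect_size * log_sd`` in
    cases only.  Three internal-control miRNAs with case-independent
    expectation are appended.  Cases come first in the sample order.
    """
    cfg.validate()
    mirna_ids = list(dict.fromkeys(annotation["mirna_id"]))
    overlap = set(mirna_ids) & set(CONTROL_IDS)
    if overlap:
        raise InvalidConfigError(f"annotation reuses reserved control ids: {overlap}")

    informative: list[str] = []
    if cfg.effect_size > 0:
        if not clustering_truth.informative_clusters:
            raise InvalidConfigError(
                "effect_size > 0 requires designated informative clusters"
            )
        members = clustering_truth.assignments
        for cid in clustering_truth.informative_clusters:
            for mid in sorted(members.index[members == cid]):
                if len(informative) < cfg.n_informative:
                    informative.append(mid)
        if not informative:
            raise InvalidConfigError("informative clusters contain no mapped miRNAs")
        if len(informative) < cfg.n_informative:
            logger.warning(
                "informative clusters hold only %d miRNAs (requested %d)",
                len(informative),
                cfg.n_informative,
            )

    rng = _stage_rng(cfg.seed, _STAGE_EXPRESSION)
    n_s = cfg.n_case + cfg.n_control
    sample_ids = [f"case_{i:04d}" for i in range(1, cfg.n_case + 1)] + [
        f"ctrl_{i:04d}" for i in range(1, cfg.n_control + 1)
    ]
    labels = pd.Series([1] * cfg.n_case + [0] * cfg.n_control, index=sample_ids)

    mus = rng.normal(cfg.log_mean_loc, cfg.log_mean_scale, size=len(mirna_ids))
    log_x = mus[:, None] + cfg.log_sd * rng.normal(size=(len(mirna_ids), n_s))
    info_mask = np.array([mid in set(informative) for mid in mirna_ids])
    case_mask = (labels.to_numpy() == 1).astype(float)
    log_x += cfg.effect_size * cfg.log_sd * info_mask[:, None] * case_mask[None, :]

    ctrl_log = cfg.control_log_mean + cfg.control_log_sd * rng.normal(
        size=(len(CONTROL_IDS), n_s)
    )
    signal = pd.DataFrame(
        np.exp(np.vstack([log_x, ctrl_log])),
        index=mirna_ids + list(CONTROL_IDS),
        columns=sample_ids,
    )
    truth = GroundTruth(
        informative_mirnas=frozenset(informative),
        effect_size=cfg.effect_size,
        informative_clusters=tuple(clustering_truth.informative_clusters),
        true_coords=true_coords,
    )
    return ExpressionMatrix(signal, labels), truth


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full known-truth dataset: genome, structure, contacts, annotation,
    expression.  The informative clusters are the ``n_informative_clusters``
    spatial domains holding the most uniquely mapped miRNAs."""
    cfg.validate()
    bins = make_toy_genome(cfg.n_chrom, cfg.bins_per_chrom, cfg.bin_size)
    structure = simulate_structure(
        bins, cfg.n_domains, cfg.compaction, seed=cfg.seed, step=cfg.step
    )
    domains = domain_assignment(bins, cfg.n_domains)
    contacts = structure_to_contacts(
        structure,
        beta=cfg.contact_decay_exponent,
        k=cfg.contact_scale,
        seed=cfg.seed,
        noise=cfg.contact_noise,
        bins=bins,
    )
    annotation = make_annotation(bins, cfg.n_mirna, cfg.frac_multimapped, seed=cfg.seed)
    mapped = map_tss_to_coords(annotation, bins, structure)
    assignments = pd.Series(
        domains[mapped["bin_id"].to_numpy()], index=mapped["mirna_id"]
    )
    sizes = assignments.value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    informative_clusters = tuple(int(c) for c in order[: cfg.n_informative_clusters])
    truth_clusters = TruthClustering(assignments, informative_clusters)
    expression, truth = simulate_expression(
        annotation, truth_clusters, cfg, true_coords=structure.coords
    )
    return SimulatedDataset(
        config=cfg,
        bins=bins,
        structure=structure,
        domain_of_bin=domains,
        contacts=contacts,
        annotation=annotation,
        expression=expression,
        truth=truth,
        truth_clusters=truth_clusters,
    )
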