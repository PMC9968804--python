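"""Expression-matrix container, internal-control normalization and filters.

The expression matrix is miRNA x sample, nonnegative, with a 0/1 disease
label per sample (1 = case).  Serum array signals are standardized per
sample by the mean of three designated internal-control miRNAs; miRNAs that
cannot be annotated to a unique genomic locus are excluded; and miRNAs that
fail a minimum-signal prevalence threshold are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidConfigError

logger = logging.getLogger(__name__)

#: Fraction of the cohort a miRNA must reach min_score in to be kept by
#: default (mirrors a 1,000-of-1,309-sample prevalence requirement).
DEFAULT_MIN_SAMPLE_FRACTION = 1000 / 1309


@dataclass
class ExpressionMatrix:
    """Nonnegative miRNA x sample signal matrix with per-sample 0/1 labels."""

    signal: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        sig = self.signal
        if sig.index.duplicated().any():
            dup = sig.index[sig.index.duplicated()][0]
            raise DataError(f"duplicate miRNA id: {dup}")
        if sig.columns.duplicated().any():
            dup = sig.columns[sig.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup}")
        vals = sig.to_numpy()
        if vals.size and ((vals < 0).any() or not np.isfinite(vals).all()):
            raise DataError("signals must be finite and nonnegative")
        if list(self.labels.index) != list(sig.columns):
            raise DataError("labels index must match sample columns")
        if not set(pd.unique(self.labels)).issubset({0, 1}):
            raise DataError("labels must be 0 (control) or 1 (case)")
        self.labels = self.labels.astype(int)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.signal.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def subset(self, mirna_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [m for m in mirna_ids if m not in self.signal.index]
        if missing:
            raise DataError(f"miRNAs absent from matrix: {missing}")
        return ExpressionMatrix(self.signal.loc[list(mirna_ids)], self.labels)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.signal[list(sample_ids)], self.labels.loc[list(sample_ids)]
        )


def normalize_by_controls(
    raw: ExpressionMatrix, control_ids: Sequence[str]
) -> ExpressionMatrix:
    """Divide every sample column by that sample's mean internal-control signal.

    Exactly three control ids are required; each must be strictly positive in
    every sample.  Control rows are removed from the output, so applying the
    per-sample ratio leaves the result invariant to any positive rescaling
    of a raw sample column.
    """
    control_ids = list(control_ids)
    if len(control_ids) != 3:
        raise InvalidConfigError(
            f"exactly 3 internal-control miRNAs required, got {len(control_ids)}"
        )
    missing = [c for c in control_ids if c not in raw.signal.index]
    if missing:
        raise DataError(f"control miRNAs absent from matrix: {missing}")
    ctrl = raw.signal.loc[control_ids]
    bad = ctrl.columns[(ctrl <= 0).any(axis=0)]
    if len(bad):
        raise DataError(
            f"control signal is not strictly positive in sample {bad[0]!r}"
        )
    factor = ctrl.mean(axis=0)
    out = raw.signal.drop(index=control_ids) / factor
    return ExpressionMatrix(out, raw.labels)


def filter_low_expression(
    m: ExpressionMatrix,
    min_score: float = 5.0,
    min_samples: int | None = None,
    reading: str = "keep_expressed",
) -> ExpressionMatrix:
    """Remove weakly expressed miRNAs.

    ``reading="keep_expressed"`` (default) keeps a miRNA iff its signal is
    >= ``min_score`` in at least ``min_samples`` samples.  The alternative
    ``reading="literal"`` removes a miRNA iff fewer than ``min_samples``
    samples fall below ``min_score`` — the other way the source filter
    sentence can be parsed; both are expressible.  ``min_samples`` defaults
    to ~76% of the cohort.
    """
    if min_samples is None:
        min_samples = int(round(DEFAULT_MIN_SAMPLE_FRACTION * m.n_samples))
    if min_samples > m.n_samples:
        raise InvalidConfigError(
            f"min_samples={min_samples} exceeds cohort size {m.n_samples}"
        )
    if reading == "keep_expressed":
        keep = (m.signal >= min_score).sum(axis=1) >= min_samples
    elif reading == "literal":
        keep = (m.signal < min_score).sum(axis=1) >= min_samples
    else:
        raise InvalidConfigError(f"unknown filter reading {reading!r}")
    out = m.signal.loc[keep]
    if out.empty:
        logger.warning("filter_low_expression removed every miRNA")
    return ExpressionMatrix(out, m.labels)


def unique_mirna_ids(annotation: pd.DataFrame) -> set[str]:
    """Ids annotated exactly once and flagged unique."""
    counts = annotation["mirna_id"].value_counts()
    once = set(counts[counts == 1].index)
    flagged = set(annotation.loc[annotation["unique"].astype(bool), "mirna_id"])
    return once & flagged


def filter_ambiguous(
    m: ExpressionMatrix, annotation: pd.DataFrame
) -> ExpressionMatrix:
    """Keep only miRNAs with a single, uniquely flagged annotation record."""
    uniq = unique_mirna_ids(annotation)
    annotated = set(annotation["mirna_id"])
    n_unannotated = sum(1 for mid in m.signal.index if mid not in annotated)
    n_multi = sum(1 for mid in m.signal.index if mid in annotated and mid not in uniq)
    if n_unannotated:
        logger.info("filter_ambiguous: dropped %d unannotated miRNAs", n_unannotated)
    if n_multi:
        logger.info("filter_ambiguous: dropped %d non-unique miRNAs", n_multi)
    keep = [mid for mid in m.signal.index if mid in uniq]
    if not keep:
        logger.warning("filter_ambiguous removed every miRNA")
    return ExpressionMatrix(m.signal.loc[keep], m.labels)
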