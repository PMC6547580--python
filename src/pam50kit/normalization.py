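"""Platform-specific preprocessing to classifier-ready log2 matrices.

Two fixed recipes:

* digital multiplexed counts: negative-probe background subtraction
  (per-sample background = mean of negatives minus ``sd_multiplier`` standard
  deviations, clamped at zero), flooring, then division by the per-sample
  geometric mean of the housekeeper genes and log2.
* RNA-Seq abundances: per-sample rescaling so the upper-quartile statistic of
  reliably detected genes equals a fixed target (default 1000), log2(x + 1),
  then subtraction of externally supplied per-gene reference medians
  (an estrogen-receptor-balanced reference aligning samples to the
  classifier's training distribution).

The step order is part of the contract; convenience wrappers
:func:`run_nanostring_pipeline` and :func:`run_rnaseq_pipeline` enforce it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .io_formats import ExpressionMatrix, ProbeCountTable


@dataclass
class NanoStringNormConfig:
    """Settings for digital-count background correction and scaling.

    sd_multiplier: how many negative-probe standard deviations below the
    mean the background estimate sits (2 by convention).  floor_value: lower
    bound (in counts) applied after background subtraction so the later log2
    is defined.
    """

    sd_multiplier: float = 2.0
    floor_value: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValidationError("sd_multiplier must be >= 0")
        if self.floor_value <= 0:
            raise ValidationError("floor_value must be > 0")


@dataclass
class RnaSeqNormConfig:
    """Settings for upper-quartile RNA-Seq normalization.

    uq_target: value the per-sample 75th percentile is rescaled to.
    min_detect_fraction: a gene enters the quantile computation only if it is
    nonzero in at least this fraction of samples.  reference_medians: per-gene
    log2 medians subtracted after transformation; when present they must
    cover every gene that reaches the classifier.
    """

    uq_target: float = 1000.0
    min_detect_fraction: float = 0.7
    reference_medians: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.uq_target <= 0:
            raise ValidationError("uq_target must be > 0")
        if not 0 <= self.min_detect_fraction <= 1:
            raise ValidationError("min_detect_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Digital multiplexed counts
# ---------------------------------------------------------------------------

def nanostring_background_correct(
    table: ProbeCountTable, cfg: NanoStringNormConfig | None = None
) -> ProbeCountTable:
    """Subtract the negative-probe background estimate from every count.

    Per sample: ``b = max(mean(neg) - sd_multiplier * sd(neg), 0)`` (sample
    standard deviation, ddof=1); every endogenous/housekeeping count becomes
    ``max(count - b, floor_value)``.  Negative and positive control probes
    are dropped from the output.
    """
    cfg = cfg or NanoStringNormConfig()
    neg = table.probes_of_class("negative")
    if len(neg) < 2:
        raise NormalizationError(
            f"need >= 2 negative probes to estimate background, found {len(neg)}"
        )
    keep = [
        p for p, cls in table.annotations["probe_class"].items()
        if cls in ("endogenous", "housekeeping")
    ]
    negs = table.counts.loc[neg]
    background = (negs.mean(axis=0) - cfg.sd_multiplier * negs.std(axis=0, ddof=1)
                  ).clip(lower=0.0)
    corrected = table.counts.loc[keep].sub(background, axis=1).clip(
        lower=cfg.floor_value
    )
    zero_samples = [s for s in table.sample_ids if (table.counts[s] == 0).all()]
    if zero_samples:
        warnings.warn(
            f"all-zero sample(s) floored at {cfg.floor_value}: {zero_samples}",
            stacklevel=2,
        )
    return ProbeCountTable(
        annotations=table.annotations.loc[keep].copy(), counts=corrected
    )


def nanostring_housekeeper_normalize(
    table: ProbeCountTable,
    housekeepers: list[str] | tuple[str, ...],
    cfg: NanoStringNormConfig | None = None,
) -> ExpressionMatrix:
    """Scale by the per-sample housekeeper geometric mean, then log2.

    Expects a background-corrected table (strictly positive counts thanks to
    the floor).  Housekeeper rows are retained in the output and flagged in
    ``gene_roles``.
    """
    cfg = cfg or NanoStringNormConfig()
    if not housekeepers:
        raise ValidationError("housekeeper list is empty")
    genes = table.annotations["gene_symbol"]
    if genes.duplicated().any():
        dups = sorted(set(genes[genes.duplicated()]))
        raise ValidationError(f"multiple probes per gene not supported: {dups}")
    counts = table.counts.copy()
    counts.index = pd.Index(genes.values, name="gene")
    missing = [h for h in housekeepers if h not in counts.index]
    if missing:
        raise ValidationError(f"housekeeper gene(s) not in table: {missing}")
    hk = counts.loc[list(housekeepers)]
    if (hk.to_numpy() <= 0).any():
        raise ValidationError(
            "zero/negative housekeeper count; background floor should prevent this"
        )
    log2 = np.log2(counts)
    normalized = log2.sub(np.log2(hk).mean(axis=0), axis=1)
    roles = pd.Series(
        ["housekeeping" if g in set(housekeepers) else "endogenous"
         for g in counts.index],
        index=counts.index,
    )
    return ExpressionMatrix(
        values=normalized, platform="nanostring", scale="log2_normalized",
        gene_roles=roles,
    )


# ---------------------------------------------------------------------------
# RNA-Seq
# ---------------------------------------------------------------------------

def rnaseq_upper_quartile_normalize(
    matrix: ExpressionMatrix, cfg: RnaSeqNormConfig | None = None
) -> ExpressionMatrix:
    """Fixed-upper-quartile scaling followed by log2(x + 1).

    The 75th percentile is computed per sample over the genes passing the
    detection rule; each sample is rescaled so that statistic equals
    ``cfg.uq_target``.
    """
    cfg = cfg or RnaSeqNormConfig()
    if matrix.scale != "raw":
        raise ValidationError("upper-quartile normalization expects raw scale")
    values = matrix.values
    if (values.to_numpy() < 0).any():
        raise ValidationError("raw RNA-Seq matrix contains negative values")
    detected = (values > 0).mean(axis=1) >= cfg.min_detect_fraction
    if not detected.any():
        raise NormalizationError("no gene passes the detection rule")
    uq = values.loc[detected].quantile(0.75, axis=0)
    zero_uq = [s for s, q in uq.items() if q == 0]
    if zero_uq:
        raise NormalizationError(f"upper quartile is 0 for sample(s): {zero_uq}")
    scaled = values.mul(cfg.uq_target / uq, axis=1)
    return ExpressionMatrix(
        values=np.log2(scaled + 1.0), platform=matrix.platform,
        scale="log2_normalized", gene_roles=matrix.gene_roles,
    )


def median_center_genes(
    matrix: ExpressionMatrix, reference_medians: pd.Series
) -> ExpressionMatrix:
    """Subtract a per-gene reference median from a log2 matrix."""
    matrix.require_log2()
    missing = [g for g in matrix.gene_ids if g not in reference_medians.index]
    if missing:
        raise ValidationError(f"no reference median for gene(s): {missing}")
    ref = reference_medians.reindex(matrix.gene_ids).astype(float)
    return ExpressionMatrix(
        values=matrix.values.sub(ref, axis=0), platform=matrix.platform,
        scale=matrix.scale, gene_roles=matrix.gene_roles,
    )


# ---------------------------------------------------------------------------
# Pipelines (fixed step order)
# ---------------------------------------------------------------------------

def run_nanostring_pipeline(
    table: ProbeCountTable,
    housekeepers: list[str] | tuple[str, ...],
    cfg: NanoStringNormConfig | None = None,
) -> ExpressionMatrix:
    """background subtraction -> housekeeper scaling -> log2."""
    table.require_normalizable()
    cfg = cfg or NanoStringNormConfig()
    corrected = nanostring_background_correct(table, cfg)
    return nanostring_housekeeper_normalize(corrected, housekeepers, cfg)


def run_rnaseq_pipeline(
    matrix: ExpressionMatrix, cfg: RnaSeqNormConfig | None = None
) -> ExpressionMatrix:
    """upper-quartile scaling -> log2(x+1) -> reference-median centering."""
    cfg = cfg or RnaSeqNormConfig()
    out = rnaseq_upper_quartile_normalize(matrix, cfg)
    if cfg.reference_medians is not None:
        out = median_center_genes(out, cfg.reference_medians)
    return out
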