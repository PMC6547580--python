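"""Nearest-centroid intrinsic subtyping and risk-of-recurrence scoring.

A sample's log2 profile is correlated (Spearman by default) with each of the
five subtype centroids; the call is the best-correlated subtype.  When the
runner-up centroid is within ``ambiguity_threshold`` (default 0.10) of the
top one the call is flagged ambiguous: either subtype is plausible.

Confidence is defined here as ``(top - second) / max(top, eps)`` clipped to
[0, 1] — a relative margin.  Published classifier outputs report a
confidence too, but its formula is not standardized; this package's
definition is its own convention and is documented as such.

The risk-of-recurrence score is a weighted sum of centroid correlations
(ROR-S), optionally plus a proliferation term (ROR+PS, using the mean log2
expression of 11 proliferation genes), linearly rescaled to 0-100 and cut
into low/med/high groups.  Weights, rescaling bounds and cutoffs are data
(a JSON config), not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClassificationError, ValidationError
from .genes import PROLIFERATION_GENES, SUBTYPES
from .io_formats import CentroidMatrix, ExpressionMatrix, load_json

_EPS = 1e-8
RISK_GROUPS = ("low", "med", "high")


@dataclass(frozen=True)
class RorCoefficientSet:
    """Weights and rescaling bounds for one ROR variant."""

    weights: Mapping[str, float]
    proliferation_weight: float
    rescale_low: float
    rescale_high: float

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(SUBTYPES)
        if unknown:
            raise ValidationError(f"ROR weights for unknown subtype(s): {sorted(unknown)}")
        if not self.rescale_high > self.rescale_low:
            raise ValidationError("rescale_high must exceed rescale_low")


@dataclass
class Pam50Config:
    """Classifier parameters; ``default()`` loads the packaged JSON."""

    correlation_method: str = "spearman"
    ambiguity_threshold: float = 0.10
    proliferation_genes: tuple[str, ...] = PROLIFERATION_GENES
    ror_s: RorCoefficientSet | None = None
    ror_ps: RorCoefficientSet | None = None
    risk_cutoffs_ror_s: tuple[float, float] = (29.0, 53.0)
    risk_cutoffs_ror_ps: tuple[float, float] = (23.0, 52.0)
    tie_break: tuple[str, ...] = SUBTYPES

    def __post_init__(self) -> None:
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValidationError(
                f"unknown correlation method {self.correlation_method!r}"
            )
        if self.ambiguity_threshold < 0:
            raise ValidationError("ambiguity_threshold must be >= 0")
        if not self.proliferation_genes:
            raise ValidationError("proliferation gene list is empty")
        for cuts in (self.risk_cutoffs_ror_s, self.risk_cutoffs_ror_ps):
            if not cuts[0] < cuts[1]:
                raise ValidationError(f"risk cutoffs not ordered: {cuts}")
        if sorted(self.tie_break) != sorted(SUBTYPES):
            raise ValidationError("tie_break must order all five subtypes")

    @classmethod
    def from_dict(cls, data: dict) -> "Pam50Config":
        def coef(key: str) -> RorCoefficientSet:
            d = data[key]
            return RorCoefficientSet(
                weights={k: float(v) for k, v in d["weights"].items()},
                proliferation_weight=float(d.get("proliferation_weight", 0.0)),
                rescale_low=float(d["rescale_low"]),
                rescale_high=float(d["rescale_high"]),
            )

        return cls(
            correlation_method=data.get("correlation_method", "spearman"),
            ambiguity_threshold=float(data.get("ambiguity_threshold", 0.10)),
            proliferation_genes=tuple(
                data.get("proliferation_genes", PROLIFERATION_GENES)
            ),
            ror_s=coef("ror_s"),
            ror_ps=coef("ror_ps"),
            risk_cutoffs_ror_s=tuple(data["risk_cutoffs"]["ror_s"]),
            risk_cutoffs_ror_ps=tuple(data["risk_cutoffs"]["ror_ps"]),
            tie_break=tuple(data.get("tie_break", SUBTYPES)),
        )

    @classmethod
    def from_json(cls, path) -> "Pam50Config":
        return cls.from_dict(load_json(path))

    @classmethod
    def default(cls) -> "Pam50Config":
        ref = resources.files("pam50kit.data").joinpath("pam50_config.json")
        with resources.as_file(ref) as path:
            return cls.from_json(path)


@dataclass
class Pam50Call:
    """Per-sample classifier output."""

    sample_id: str
    centroid_correlations: Mapping[str, float] | None = None
    call: str | None = None
    second_call: str | None = None
    confidence: float | None = None
    ambiguous: bool | None = None
    proliferation_score: float | None = None
    ror_s: float | None = None
    ror_s_group: str | None = None
    ror_ps: float | None = None
    ror_ps_group: str | None = None

    @property
    def top_margin(self) -> float:
        """Gap between best and second-best centroid correlation."""
        c = self.centroid_correlations
        return float(c[self.call] - c[self.second_call])


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def centroid_correlations(
    profile: pd.Series, centroids: CentroidMatrix, method: str = "spearman"
) -> pd.Series:
    """Correlation of one sample profile with each subtype centroid.

    Computed over the centroid gene set, in centroid gene order; the profile
    must cover every centroid gene.
    """
    missing = [g for g in centroids.genes if g not in profile.index]
    if missing:
        raise ClassificationError(f"profile missing centroid gene(s): {missing}")
    x = profile.reindex(centroids.genes).to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ClassificationError("profile contains non-finite values")
    if np.ptp(x) == 0:
        raise ClassificationError(
            "constant expression profile: correlation undefined"
        )
    out = {}
    for subtype in SUBTYPES:
        y = centroids.values[subtype].to_numpy(dtype=float)
        if method == "spearman":
            r = stats.spearmanr(x, y).statistic
        elif method == "pearson":
            r = stats.pearsonr(x, y).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if not np.isfinite(r):
            raise ClassificationError(
                f"correlation with {subtype} centroid undefined"
            )
        out[subtype] = float(r)
    return pd.Series(out)


def assign_subtype(
    correlations: Mapping[str, float], cfg: Pam50Config
) -> tuple[str, str, float, bool]:
    """Return (call, second_call, confidence, ambiguous) from 5 correlations.

    Ties are resolved by the deterministic ``cfg.tie_break`` order and
    flagged ambiguous.
    """
    corr = {s: float(correlations[s]) for s in SUBTYPES}
    if not all(np.isfinite(list(corr.values()))):
        raise ClassificationError("non-finite centroid correlation")
    order = sorted(SUBTYPES, key=lambda s: (-corr[s], cfg.tie_break.index(s)))
    call, second = order[0], order[1]
    gap = corr[call] - corr[second]
    ambiguous = gap <= cfg.ambiguity_threshold
    confidence = float(np.clip(gap / max(corr[call], _EPS), 0.0, 1.0))
    return call, second, confidence, ambiguous


def proliferation_score(
    profile: pd.Series, genes: Sequence[str] = PROLIFERATION_GENES
) -> float:
    """Arithmetic mean of the proliferation genes' log2 values."""
    missing = [g for g in genes if g not in profile.index]
    if missing:
        raise ClassificationError(f"profile missing proliferation gene(s): {missing}")
    return float(profile.reindex(list(genes)).astype(float).mean())


def ror_score(
    correlations: Mapping[str, float],
    coef: RorCoefficientSet,
    proliferation: float | None = None,
) -> float:
    """Weighted correlation sum, rescaled linearly to the 0-100 scale."""
    if coef.proliferation_weight != 0.0 and proliferation is None:
        raise ClassificationError(
            "ROR+PS requested but no proliferation score supplied"
        )
    raw = sum(w * float(correlations[s]) for s, w in coef.weights.items())
    if proliferation is not None:
        raw += coef.proliferation_weight * proliferation
    span = coef.rescale_high - coef.rescale_low
    return float(np.clip((raw - coef.rescale_low) / span * 100.0, 0.0, 100.0))


def risk_group(score: float, cutoffs: tuple[float, float]) -> str:
    """Bin a 0-100 score into low/med/high.

    Half-open convention: a score exactly at a boundary falls in the upper
    class.
    """
    low_med, med_high = cutoffs
    if score < low_med:
        return "low"
    if score < med_high:
        return "med"
    return "high"


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def classify_sample(
    sample_id: str,
    profile: pd.Series,
    centroids: CentroidMatrix,
    cfg: Pam50Config,
) -> Pam50Call:
    corr = centroid_correlations(profile, centroids, cfg.correlation_method)
    call, second, confidence, ambiguous = assign_subtype(corr, cfg)
    prolif = proliferation_score(profile, cfg.proliferation_genes)
    ror_s = ror_score(corr, cfg.ror_s)
    ror_ps = ror_score(corr, cfg.ror_ps, proliferation=prolif)
    return Pam50Call(
        sample_id=sample_id,
        centroid_correlations=dict(corr),
        call=call,
        second_call=second,
        confidence=confidence,
        ambiguous=ambiguous,
        proliferation_score=prolif,
        ror_s=ror_s,
        ror_s_group=risk_group(ror_s, cfg.risk_cutoffs_ror_s),
        ror_ps=ror_ps,
        ror_ps_group=risk_group(ror_ps, cfg.risk_cutoffs_ror_ps),
    )


def classify_cohort(
    matrix: ExpressionMatrix,
    centroids: CentroidMatrix,
    cfg: Pam50Config | None = None,
) -> list[Pam50Call]:
    """Classify every sample of a log2-normalized matrix; never drops samples."""
    cfg = cfg or Pam50Config.default()
    matrix.require_log2()
    calls = []
    for sample in matrix.sample_ids:
        try:
            calls.append(
                classify_sample(sample, matrix.values[sample], centroids, cfg)
            )
        except ClassificationError as err:
            raise ClassificationError(f"sample {sample!r}: {err}") from err
    return calls


def subtype_frequencies(calls: Sequence[Pam50Call]) -> pd.DataFrame:
    """Count and percentage of calls per subtype, in canonical order."""
    counts = pd.Series([c.call for c in calls]).value_counts()
    counts = counts.reindex(list(SUBTYPES), fill_value=0)
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / max(len(calls), 1)}
    )
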