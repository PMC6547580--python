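"""Paired-platform agreement statistics.

Covers everything needed to compare two platforms run on the same cohort:
per-gene Spearman correlation and intraclass correlation (two-way model,
single measures, consistency or absolute-agreement definition, F-based 95%
CI), subtype cross-tabulation with Cohen's kappa, raw and
ambiguity-adjusted call concordance, risk-group discordance, Bland-Altman
limits of agreement, and mean/CI cohort summaries.

Per-gene Spearman p-values are reported raw; no multiple-testing correction
is applied across genes (the report carries a footnote saying so).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConcordanceError, ValidationError
from .genes import SUBTYPES
from .io_formats import ExpressionMatrix, save_json
from .pam50 import Pam50Call

_NOTES = (
    "Per-gene Spearman p-values are unadjusted; no multiple-testing "
    "correction is applied across genes."
)


# ---------------------------------------------------------------------------
# Paired calls container
# ---------------------------------------------------------------------------

@dataclass
class PairedCalls:
    """The same samples called on two platforms, aligned and ordered."""

    platform_a: str
    platform_b: str
    calls_a: list[Pam50Call]
    calls_b: list[Pam50Call]

    def __post_init__(self) -> None:
        ids_a = [c.sample_id for c in self.calls_a]
        ids_b = [c.sample_id for c in self.calls_b]
        if ids_a != ids_b:
            raise ValidationError("paired call sets differ in samples or order")
        if len(set(ids_a)) != len(ids_a):
            raise ValidationError("duplicate sample ids in paired calls")

    @classmethod
    def from_call_lists(
        cls,
        calls_a: Sequence[Pam50Call],
        calls_b: Sequence[Pam50Call],
        platform_a: str = "a",
        platform_b: str = "b",
    ) -> "PairedCalls":
        """Align two call lists on their shared samples, in A's order."""
        by_b = {c.sample_id: c for c in calls_b}
        shared_a = [c for c in calls_a if c.sample_id in by_b]
        shared_b = [by_b[c.sample_id] for c in shared_a]
        return cls(platform_a, platform_b, list(shared_a), list(shared_b))

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.calls_a]

    def __len__(self) -> int:
        return len(self.calls_a)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)``; p uses the standard large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("inputs differ in length")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConcordanceError("constant input: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str


def _mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """ANOVA mean squares (rows=subjects, cols=raters) of a complete layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_single_measures(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "consistency",
    alpha: float = 0.05,
) -> IccResult:
    """Two-way model, single-measures intraclass correlation with 95% CI.

    ``consistency`` is ICC(3,1) (two-way mixed effects, consistency);
    ``absolute_agreement`` is ICC(A,1).  Confidence limits follow the
    F-distribution method of McGraw & Wong.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("inputs differ in length")
    n = x.size
    if n < 5:
        raise ValidationError("need at least 5 paired observations for ICC")
    if variant not in ("consistency", "absolute_agreement"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    data = np.column_stack([x, y])
    k = 2
    msr, msc, mse = _mean_squares(data)
    if msr <= 0 or np.isclose(msr, 0):
        warnings.warn("zero between-subject variance; ICC set to 0", stacklevel=2)
        return IccResult(0.0, float("nan"), float("nan"), variant)
    if np.isclose(mse, 0) and (variant == "consistency" or np.isclose(msc, mse)):
        return IccResult(1.0, 1.0, 1.0, variant)

    if variant == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        fobs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k / n * (msc - mse)
        icc = (msr - mse) / denom
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a):
            lo = hi = 1.0
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (msr - f_lo * mse)
                / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi = (
                n * (f_hi * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
            )
    return IccResult(float(icc), float(lo), float(hi), variant)


def cohen_kappa(calls_a: Sequence, calls_b: Sequence) -> float:
    """Chance-corrected agreement between two categorical call vectors."""
    a = list(calls_a)
    b = list(calls_b)
    if len(a) != len(b):
        raise ValidationError("call vectors differ in length")
    if not a:
        raise ValidationError("empty call vectors")
    n = len(a)
    cats = sorted(set(a) | set(b))
    p_obs = sum(x == y for x, y in zip(a, b)) / n
    p_exp = sum(
        (a.count(c) / n) * (b.count(c) / n) for c in cats
    )
    if np.isclose(p_exp, 1.0):
        warnings.warn(
            "both raters constant and equal; kappa defined as 1", stacklevel=2
        )
        return 1.0
    return float((p_obs - p_exp) / (1 - p_exp))


@dataclass(frozen=True)
class BlandAltmanStats:
    """Limits-of-agreement summary of paired differences ``x - y``."""

    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    pairs: tuple[tuple[float, float], ...]  # (mean, difference) per sample

    def fraction_within_limits(self) -> float:
        d = np.array([p[1] for p in self.pairs])
        return float(
            np.mean((d > self.lower_limit) & (d < self.upper_limit))
        )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanStats:
    """Mean difference and mean +/- 1.96*SD limits of agreement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need >= 2 equal-length pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltmanStats(
        mean_difference=mean_d,
        sd_difference=sd_d,
        lower_limit=mean_d - 1.96 * sd_d,
        upper_limit=mean_d + 1.96 * sd_d,
        pairs=tuple(zip(((x + y) / 2).tolist(), d.tolist())),
    )


def summary_stats(values: Sequence[float]) -> dict:
    """Mean, extrema and t-based 95% CI of the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite values in input")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    tcrit = float(stats.t.ppf(0.975, v.size - 1))
    return {
        "mean": mean,
        "min": float(v.min()),
        "max": float(v.max()),
        "ci95_low": mean - tcrit * sem,
        "ci95_high": mean + tcrit * sem,
        "n": int(v.size),
    }


# ---------------------------------------------------------------------------
# Call-level agreement
# ---------------------------------------------------------------------------

@dataclass
class DiscordanceRecord:
    sample_id: str
    call_a: str
    call_b: str
    second_a: str
    second_b: str
    gap_a: float
    gap_b: float
    rescued: bool
    reason: str  # second_call_match | near_tie_unresolved | real_discordance


def crosstab_calls(paired: PairedCalls) -> pd.DataFrame:
    """5x5 count table (rows: platform A calls, columns: platform B calls)."""
    table = pd.DataFrame(
        0, index=list(SUBTYPES), columns=list(SUBTYPES), dtype=int
    )
    for ca, cb in zip(paired.calls_a, paired.calls_b):
        table.loc[ca.call, cb.call] += 1
    return table


def raw_and_adjusted_concordance(
    paired: PairedCalls,
    threshold: float = 0.10,
    count_any_near_tie: bool = True,
) -> tuple[float, float, list[DiscordanceRecord]]:
    """Call agreement before and after the near-tie ambiguity rule.

    A raw-discordant pair is *rescued* when either platform's top-two
    centroid gap is <= ``threshold`` and that platform's second call matches
    the other platform's call.  With ``count_any_near_tie`` (default on) a
    near-tie whose second call does not match still counts toward adjusted
    concordance, but is labelled ``near_tie_unresolved`` so both tallies are
    visible in the records.
    """
    n = len(paired)
    if n == 0:
        raise ValidationError("no paired samples")
    records: list[DiscordanceRecord] = []
    n_concordant = 0
    n_adjusted = 0
    for ca, cb in zip(paired.calls_a, paired.calls_b):
        if ca.call == cb.call:
            n_concordant += 1
            n_adjusted += 1
            continue
        gap_a, gap_b = ca.top_margin, cb.top_margin
        match_rescue = (gap_a <= threshold and ca.second_call == cb.call) or (
            gap_b <= threshold and cb.second_call == ca.call
        )
        near_tie = gap_a <= threshold or gap_b <= threshold
        if match_rescue:
            reason, rescued = "second_call_match", True
        elif near_tie:
            reason = "near_tie_unresolved"
            rescued = count_any_near_tie
        else:
            reason, rescued = "real_discordance", False
        if rescued:
            n_adjusted += 1
        records.append(
            DiscordanceRecord(
                sample_id=ca.sample_id, call_a=ca.call, call_b=cb.call,
                second_a=ca.second_call, second_b=cb.second_call,
                gap_a=gap_a, gap_b=gap_b, rescued=rescued, reason=reason,
            )
        )
    return n_concordant / n, n_adjusted / n, records


def risk_group_discordance(
    paired: PairedCalls,
) -> tuple[int, int, pd.DataFrame]:
    """Count samples whose ROR (and ROR+PS) risk group differs by platform."""
    rows = []
    for ca, cb in zip(paired.calls_a, paired.calls_b):
        if ca.ror_s_group is None or cb.ror_s_group is None:
            raise ValidationError(f"sample {ca.sample_id!r} lacks a risk group")
        rows.append(
            {
                "sample_id": ca.sample_id,
                "ror_s_group_a": ca.ror_s_group,
                "ror_s_group_b": cb.ror_s_group,
                "ror_s_discordant": ca.ror_s_group != cb.ror_s_group,
                "ror_ps_group_a": ca.ror_ps_group,
                "ror_ps_group_b": cb.ror_ps_group,
                "ror_ps_discordant": ca.ror_ps_group != cb.ror_ps_group,
            }
        )
    frame = pd.DataFrame(rows)
    return (
        int(frame["ror_s_discordant"].sum()),
        int(frame["ror_ps_discordant"].sum()),
        frame,
    )


# ---------------------------------------------------------------------------
# Gene-level agreement
# ---------------------------------------------------------------------------

RHO_BIN_LABELS = (">0.9", "0.8-0.9", "0.7-0.8", "<0.7")


def bin_correlations(rhos: Sequence[float]) -> dict[str, int]:
    """Bin correlation coefficients as >0.9 / (0.8,0.9] / (0.7,0.8] / <=0.7."""
    bins = dict.fromkeys(RHO_BIN_LABELS, 0)
    for r in rhos:
        if np.isnan(r):
            continue
        if r > 0.9:
            bins[">0.9"] += 1
        elif r > 0.8:
            bins["0.8-0.9"] += 1
        elif r > 0.7:
            bins["0.7-0.8"] += 1
        else:
            bins["<0.7"] += 1
    return bins


@dataclass
class PerGeneAgreement:
    table: pd.DataFrame  # gene, rho, p, icc, note
    bins: dict[str, int]
    fraction_above_0_8: float
    median_icc: float
    mean_icc: float


def per_gene_agreement(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    icc_variant: str = "consistency",
) -> PerGeneAgreement:
    """Cross-platform Spearman rho and ICC for every shared gene.

    Genes constant in either platform get NaN statistics with an explaining
    note; they are excluded from the bins and the ICC summaries.
    """
    genes = [g for g in matrix_a.gene_ids if g in set(matrix_b.gene_ids)]
    samples = [s for s in matrix_a.sample_ids if s in set(matrix_b.sample_ids)]
    if not genes or len(samples) < 5:
        raise ValidationError("need shared genes and >= 5 shared samples")
    rows = []
    for g in genes:
        xa = matrix_a.values.loc[g, samples].to_numpy(dtype=float)
        xb = matrix_b.values.loc[g, samples].to_numpy(dtype=float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append(
                {"gene": g, "rho": np.nan, "p": np.nan, "icc": np.nan,
                 "note": "constant in one platform"}
            )
            continue
        rho, p = spearman_rho(xa, xb)
        icc = icc_single_measures(xa, xb, variant=icc_variant).icc
        rows.append({"gene": g, "rho": rho, "p": p, "icc": icc, "note": ""})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["rho"])
    bins = bin_correlations(valid["rho"])
    above = bins[">0.9"] + bins["0.8-0.9"]
    return PerGeneAgreement(
        table=table,
        bins=bins,
        fraction_above_0_8=above / len(valid) if len(valid) else float("nan"),
        median_icc=float(valid["icc"].median()),
        mean_icc=float(valid["icc"].mean()),
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    n_samples: int
    crosstab: pd.DataFrame
    kappa: float
    raw_concordance: float
    adjusted_concordance: float
    discordance_records: list[DiscordanceRecord]
    per_gene: PerGeneAgreement | None
    ror_agreement: dict
    centroidwise_rho: dict[str, float]
    risk_discordance: tuple[int, int, pd.DataFrame]
    notes: str = _NOTES


def _score_agreement(a: np.ndarray, b: np.ndarray) -> dict:
    rho, p = spearman_rho(a, b)
    icc = icc_single_measures(a, b, variant="consistency")
    icc_abs = icc_single_measures(a, b, variant="absolute_agreement")
    ba = bland_altman(a, b)
    return {
        "spearman_rho": rho,
        "spearman_p": p,
        "icc": icc.icc,
        "icc_ci_low": icc.ci_low,
        "icc_ci_high": icc.ci_high,
        "icc_absolute": icc_abs.icc,
        "icc_absolute_ci_low": icc_abs.ci_low,
        "icc_absolute_ci_high": icc_abs.ci_high,
        "bland_altman": ba,
    }


def build_concordance_report(
    paired: PairedCalls,
    expr_a: ExpressionMatrix | None = None,
    expr_b: ExpressionMatrix | None = None,
    ambiguity_threshold: float = 0.10,
    count_any_near_tie: bool = True,
) -> ConcordanceReport:
    """Assemble every agreement statistic for one paired cohort."""
    raw, adjusted, records = raw_and_adjusted_concordance(
        paired, ambiguity_threshold, count_any_near_tie
    )
    kappa = cohen_kappa(
        [c.call for c in paired.calls_a], [c.call for c in paired.calls_b]
    )
    ror_a = np.array([c.ror_s for c in paired.calls_a], dtype=float)
    ror_b = np.array([c.ror_s for c in paired.calls_b], dtype=float)
    rps_a = np.array([c.ror_ps for c in paired.calls_a], dtype=float)
    rps_b = np.array([c.ror_ps for c in paired.calls_b], dtype=float)
    prolif_a = np.array([c.proliferation_score for c in paired.calls_a])
    prolif_b = np.array([c.proliferation_score for c in paired.calls_b])
    ror_agreement = {
        "ror_s": _score_agreement(ror_a, ror_b),
        "ror_ps": _score_agreement(rps_a, rps_b),
        "proliferation": _score_agreement(prolif_a, prolif_b),
    }
    centroidwise = {}
    for s in SUBTYPES:
        ca = [c.centroid_correlations[s] for c in paired.calls_a]
        cb = [c.centroid_correlations[s] for c in paired.calls_b]
        centroidwise[s] = spearman_rho(ca, cb)[0]
    per_gene = None
    if expr_a is not None and expr_b is not None:
        per_gene = per_gene_agreement(expr_a, expr_b)
    return ConcordanceReport(
        n_samples=len(paired),
        crosstab=crosstab_calls(paired),
        kappa=kappa,
        raw_concordance=raw,
        adjusted_concordance=adjusted,
        discordance_records=records,
        per_gene=per_gene,
        ror_agreement=ror_agreement,
        centroidwise_rho=centroidwise,
        risk_discordance=risk_group_discordance(paired),
    )


def write_report(report: ConcordanceReport, out_dir: str | Path) -> list[str]:
    """Write a report as JSON summary plus TSV detail tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def _ba_dict(ba: BlandAltmanStats) -> dict:
        return {
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "lower_limit": ba.lower_limit,
            "upper_limit": ba.upper_limit,
        }

    summary = {
        "n_samples": report.n_samples,
        "kappa": report.kappa,
        "raw_concordance": report.raw_concordance,
        "adjusted_concordance": report.adjusted_concordance,
        "raw_concordance_pct": 100 * report.raw_concordance,
        "adjusted_concordance_pct": 100 * report.adjusted_concordance,
        "centroidwise_rho": report.centroidwise_rho,
        "ror_agreement": {
            key: {k: (_ba_dict(v) if isinstance(v, BlandAltmanStats) else v)
                  for k, v in val.items()}
            for key, val in report.ror_agreement.items()
        },
        "risk_group_discordance": {
            "ror_s": report.risk_discordance[0],
            "ror_ps": report.risk_discordance[1],
        },
        "notes": report.notes,
    }
    if report.per_gene is not None:
        summary["per_gene"] = {
            "bins": report.per_gene.bins,
            "fraction_above_0_8": report.per_gene.fraction_above_0_8,
            "median_icc": report.per_gene.median_icc,
            "mean_icc": report.per_gene.mean_icc,
        }
    save_json(summary, out / "summary.json")
    files.append("summary.json")

    report.crosstab.to_csv(out / "crosstab.tsv", sep="\t")
    files.append("crosstab.tsv")
    pd.DataFrame([r.__dict__ for r in report.discordance_records]).to_csv(
        out / "discordance_records.tsv", sep="\t", index=False
    )
    files.append("discordance_records.tsv")
    report.risk_discordance[2].to_csv(
        out / "risk_group_records.tsv", sep="\t", index=False
    )
    files.append("risk_group_records.tsv")
    if report.per_gene is not None:
        report.per_gene.table.to_csv(out / "per_gene.tsv", sep="\t", index=False)
        files.append("per_gene.tsv")
    for name, stats_ in report.ror_agreement.items():
        ba = stats_["bland_altman"]
        pd.DataFrame(ba.pairs, columns=["mean", "difference"]).to_csv(
            out / f"bland_altman_{name}.tsv", sep="\t", index=False
        )
        files.append(f"bland_altman_{name}.tsv")
    return files
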