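"""Paired-platform synthetic cohorts with known ground truth.

The generator emulates a 96-sample triple-negative breast cancer cohort
profiled on both a digital multiplexed counter and RNA-Seq: a
Basal-dominated subtype mixture, per-sample biological variation around the
subtype centroid, platform-specific log-normal noise, near-constant
housekeeper genes, Poisson negative-control probes, and optional samples
whose RNA-Seq profile is deliberately drawn from a different subtype
(injected call discordance).

Noise is additive Gaussian on the log2 scale before platform-specific count
generation — simple, but enough to exercise every rank-based statistic
downstream.  It does not model FFPE degradation, GC/fragment-length bias or
read-level sampling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genes import DEFAULT_HOUSEKEEPERS, PAM50_GENES, SUBTYPES
from .io_formats import (
    CentroidMatrix,
    ExpressionMatrix,
    ProbeCountTable,
    write_centroids,
    write_expression_matrix,
    write_probe_counts,
)

#: Default subtype mixture: the call distribution of a TNBC cohort on the
#: digital platform (Basal-dominated), not a population prevalence.
DEFAULT_MIXTURE = {
    "Basal": 0.82, "Her2": 0.13, "LumA": 0.04, "LumB": 0.01, "Normal": 0.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the paired-cohort generator (seed => bit-reproducible)."""

    n_samples: int = 96
    subtype_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    n_genes: int = 50
    n_housekeepers: int = 5
    n_negative_probes: int = 8
    bio_sd: float = 0.6                     # within-subtype SD, log2 units
    nanostring_noise_sd: float = 0.2        # platform noise, log2 units
    rnaseq_noise_sd: float = 0.2
    nanostring_scale: float = 600.0         # count magnitude at log2 level 0
    rnaseq_library_size_range: tuple[float, float] = (2e5, 1e6)
    sample_depth_sd: float = 0.15           # per-sample depth factor, log2 SD
    housekeeper_log2_level: float = 0.0
    housekeeper_noise_sd: float = 0.05
    negative_probe_mean: float = 8.0
    injected_discordance: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.subtype_mixture.get(s, 0.0) for s in SUBTYPES])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("subtype mixture must be a probability vector")
        for name in ("bio_sd", "nanostring_noise_sd", "rnaseq_noise_sd",
                     "sample_depth_sd", "housekeeper_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.injected_discordance > self.n_samples:
            raise ValidationError("cannot flip more samples than exist")

    @property
    def mixture_vector(self) -> np.ndarray:
        return np.array([self.subtype_mixture.get(s, 0.0) for s in SUBTYPES])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rnaseq_library_size_range"] = list(self.rnaseq_library_size_range)
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    labels: pd.Series                    # sample -> true subtype
    rnaseq_labels: pd.Series             # subtype used for the RNA-Seq profile
    flipped_samples: list[str]
    true_log2_nanostring: pd.DataFrame   # pre-noise biological profiles
    true_log2_rnaseq: pd.DataFrame


@dataclass
class SimulatedCohort:
    probe_counts: ProbeCountTable
    rnaseq_raw: ExpressionMatrix
    truth: GroundTruth
    centroids: CentroidMatrix
    housekeepers: tuple[str, ...]


def _gene_names(n_genes: int) -> list[str]:
    if n_genes == len(PAM50_GENES):
        return list(PAM50_GENES)
    return [f"SYNGENE{i + 1:03d}" for i in range(n_genes)]


def generate_centroids(
    n_genes: int = 50, seed: int = 0, gene_names: list[str] | None = None
) -> CentroidMatrix:
    """Five synthetic centroid profiles with realistic correlation structure.

    Basal is anti-correlated with LumA and Her2 positively correlated with
    LumB, mirroring the relationships seen between the real prototypes;
    Normal-like is largely independent.  This is a synthetic stand-in for
    the published centroid matrix, not a reproduction of it.
    """
    if n_genes < 10:
        raise ValidationError("need at least 10 genes for usable centroids")
    rng = np.random.default_rng(seed)
    genes = gene_names or _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValidationError("gene_names length mismatch")
    basal = rng.normal(0, 1, n_genes)
    her2 = rng.normal(0, 1, n_genes)
    lum_a = -0.85 * basal + 0.4 * rng.normal(0, 1, n_genes)
    # Her2/LumB coupling kept moderate: a rank correlation much above ~0.8
    # would leave noiseless LumB samples inside the classifier's 0.10
    # ambiguity band, i.e. the subtypes would not be identifiable.
    lum_b = 0.7 * her2 + 0.6 * rng.normal(0, 1, n_genes)
    normal = 0.35 * lum_a + 0.9 * rng.normal(0, 1, n_genes)
    values = pd.DataFrame(
        {
            "Basal": basal, "Her2": her2, "LumA": lum_a, "LumB": lum_b,
            "Normal": normal,
        },
        index=pd.Index(genes, name="gene"),
    )
    return CentroidMatrix(values=values)


def _draw_flip_targets(
    labels: np.ndarray, flip_idx: np.ndarray, mixture: np.ndarray
) -> dict[int, str]:
    """Pick, per flipped sample, the most probable subtype other than truth."""
    targets = {}
    for i in flip_idx:
        candidates = [
            (mixture[j], SUBTYPES[j])
            for j in range(len(SUBTYPES))
            if SUBTYPES[j] != labels[i] and mixture[j] > 0
        ]
        if not candidates:
            raise ValidationError(
                "mixture has no alternative subtype with support for injected "
                "discordance"
            )
        targets[int(i)] = max(candidates)[1]
    return targets


def simulate_cohort(
    cfg: SimulationConfig, centroids: CentroidMatrix | None = None
) -> SimulatedCohort:
    """Draw one paired cohort; see the module docstring for the model."""
    rng = np.random.default_rng(cfg.seed)
    if centroids is None:
        centroids = generate_centroids(cfg.n_genes, seed=cfg.seed)
    genes = centroids.genes
    if len(genes) != cfg.n_genes:
        raise ValidationError("centroid gene count does not match n_genes")
    n = cfg.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    mixture = cfg.mixture_vector

    label_idx = rng.choice(len(SUBTYPES), size=n, p=mixture)
    labels = np.array([SUBTYPES[i] for i in label_idx])

    centroid_arr = centroids.values.to_numpy()  # genes x 5
    bio = centroid_arr[:, label_idx] + rng.normal(
        0, cfg.bio_sd, (cfg.n_genes, n)
    )

    # Injected discordance: the RNA-Seq profile of selected samples is drawn
    # from a different subtype's centroid.
    rnaseq_labels = labels.copy()
    flip_idx = rng.choice(n, size=cfg.injected_discordance, replace=False)
    targets = _draw_flip_targets(labels, flip_idx, mixture)
    bio_rs = bio.copy()
    for i, target in targets.items():
        j = SUBTYPES.index(target)
        bio_rs[:, i] = centroid_arr[:, j] + rng.normal(0, cfg.bio_sd, cfg.n_genes)
        rnaseq_labels[i] = target
    flipped = [samples[i] for i in sorted(targets)]

    # Digital multiplexed platform: integer counts with per-sample depth.
    depth = rng.normal(0, cfg.sample_depth_sd, n)
    log2_counts = (
        bio + rng.normal(0, cfg.nanostring_noise_sd, bio.shape)
        + np.log2(cfg.nanostring_scale) + depth[None, :]
    )
    endog_counts = np.rint(np.power(2.0, log2_counts)).clip(min=0)

    hk_names = list(DEFAULT_HOUSEKEEPERS[: cfg.n_housekeepers]) + [
        f"SYNHK{i + 1:02d}" for i in range(max(0, cfg.n_housekeepers - 5))
    ]
    hk_log2 = (
        cfg.housekeeper_log2_level
        + rng.normal(0, cfg.housekeeper_noise_sd, (cfg.n_housekeepers, n))
        + np.log2(cfg.nanostring_scale) + depth[None, :]
    )
    hk_counts = np.rint(np.power(2.0, hk_log2)).clip(min=1)

    neg_names = [f"NEG_{i + 1:02d}" for i in range(cfg.n_negative_probes)]
    neg_counts = rng.poisson(
        cfg.negative_probe_mean, (cfg.n_negative_probes, n)
    ).astype(float)

    ann = pd.DataFrame(
        {
            "gene_symbol": genes + hk_names + neg_names,
            "probe_class": (
                ["endogenous"] * cfg.n_genes
                + ["housekeeping"] * cfg.n_housekeepers
                + ["negative"] * cfg.n_negative_probes
            ),
        },
        index=pd.Index(genes + hk_names + neg_names, name="probe_name"),
    )
    counts = pd.DataFrame(
        np.vstack([endog_counts, hk_counts, neg_counts]),
        index=ann.index, columns=samples,
    )
    probe_table = ProbeCountTable(annotations=ann, counts=counts)

    # RNA-Seq: fractional expected counts proportional to the noisy profile
    # at a drawn library size (RSEM-style expected counts).
    rel = np.power(2.0, bio_rs + rng.normal(0, cfg.rnaseq_noise_sd, bio_rs.shape))
    lib = rng.uniform(*cfg.rnaseq_library_size_range, n)
    rs_counts = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    rnaseq_raw = ExpressionMatrix(
        values=pd.DataFrame(
            rs_counts, index=pd.Index(genes, name="gene"), columns=samples
        ),
        platform="rnaseq", scale="raw",
    )

    truth = GroundTruth(
        labels=pd.Series(labels, index=samples, name="true_subtype"),
        rnaseq_labels=pd.Series(
            rnaseq_labels, index=samples, name="rnaseq_subtype"
        ),
        flipped_samples=flipped,
        true_log2_nanostring=pd.DataFrame(
            bio, index=pd.Index(genes, name="gene"), columns=samples
        ),
        true_log2_rnaseq=pd.DataFrame(
            bio_rs, index=pd.Index(genes, name="gene"), columns=samples
        ),
    )
    return SimulatedCohort(
        probe_counts=probe_table, rnaseq_raw=rnaseq_raw, truth=truth,
        centroids=centroids, housekeepers=tuple(hk_names),
    )


def generate_reference_medians(
    centroids: CentroidMatrix, uq_target: float = 1000.0
) -> pd.Series:
    """Per-gene medians of a balanced pseudo-reference, on the assay scale.

    Stands in for the externally determined estrogen-receptor-balanced
    reference medians: one noise-free pseudo-sample per subtype is pushed
    through the upper-quartile + log2 recipe and the per-gene median across
    the five subtypes is taken.  Every subtype contributes equally, so the
    reference is not dominated by a cohort's Basal excess, and the medians
    live on the same scale as the normalized data they will center.
    """
    from .normalization import RnaSeqNormConfig, rnaseq_upper_quartile_normalize

    pseudo = ExpressionMatrix(
        values=np.power(2.0, centroids.values.copy()),
        platform="rnaseq", scale="raw",
    )
    normalized = rnaseq_upper_quartile_normalize(
        pseudo, RnaSeqNormConfig(uq_target=uq_target, min_detect_fraction=0.0)
    )
    return normalized.values.median(axis=1).rename("median")


FIXTURE_FILES = (
    "centroids.tsv",
    "probe_counts.tsv",
    "rnaseq_counts.tsv",
    "reference_medians.tsv",
    "ground_truth.tsv",
    "simulation_config.json",
)


def emit_fixture_set(
    out_dir: str | Path,
    cfg: SimulationConfig,
    centroids: CentroidMatrix | None = None,
) -> dict:
    """Write a complete fixture set plus a manifest; same seed => same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg, centroids)

    write_centroids(cohort.centroids, out / "centroids.tsv")
    write_probe_counts(cohort.probe_counts, out / "probe_counts.tsv")
    write_expression_matrix(cohort.rnaseq_raw, out / "rnaseq_counts.tsv")
    ref = generate_reference_medians(cohort.centroids)
    ref.to_frame().rename_axis("gene").to_csv(
        out / "reference_medians.tsv", sep="\t", float_format="%.17g"
    )
    truth_frame = pd.DataFrame(
        {
            "sample_id": cohort.truth.labels.index,
            "true_subtype": cohort.truth.labels.values,
            "rnaseq_subtype": cohort.truth.rnaseq_labels.values,
            "flipped": [
                s in set(cohort.truth.flipped_samples)
                for s in cohort.truth.labels.index
            ],
        }
    )
    truth_frame.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    with open(out / "simulation_config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "housekeepers": list(cohort.housekeepers),
        "files": list(FIXTURE_FILES),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
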