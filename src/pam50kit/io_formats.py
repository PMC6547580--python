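"""Tabular readers/writers and gene-identifier harmonization.

All on-disk artifacts are plain text: TSV (UTF-8, ``.`` decimal) for
matrices, probe-count tables, centroids and call tables; JSON for
configuration.  Floats are written with 17 significant digits so that a
write/read round trip is bitwise lossless.

Two dialects are accepted for probe-count tables:

``tsv``
    Canonical: a tab-separated table whose first three columns are
    ``probe_name``, ``gene_symbol``, ``probe_class``, followed by one
    numeric column per sample.

``rcc_like``
    The CSV section structure of digital-counter RCC exports: a
    ``<CodeSummary>`` ... ``</CodeSummary>`` block containing a CSV table
    with columns ``CodeClass,Name,GeneSymbol,<sample...>``.  Only those
    fields are interpreted; lane/FOV/binding-density metadata outside the
    block is ignored.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AmbiguousMergeError, FormatError, ValidationError
from .genes import SUBTYPES

PROBE_CLASSES = ("endogenous", "housekeeping", "negative", "positive")
PLATFORMS = ("nanostring", "rnaseq", "other")
SCALES = ("raw", "log2_normalized")

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeCountTable:
    """Raw digital counts per probe per sample.

    Parameters
    ----------
    annotations:
        DataFrame indexed by unique ``probe_name`` with columns
        ``gene_symbol`` and ``probe_class`` (one of :data:`PROBE_CLASSES`).
    counts:
        Non-negative numeric DataFrame (probe x sample) sharing the
        annotation index. Row order is meaningful and preserved by IO.
    """

    annotations: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        ann, cnt = self.annotations, self.counts
        if list(ann.index) != list(cnt.index):
            raise ValidationError("annotation and count rows do not align")
        if ann.index.duplicated().any():
            dups = sorted(set(ann.index[ann.index.duplicated()]))
            raise ValidationError(f"duplicate probe names: {dups}")
        bad = set(ann["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe_class values: {sorted(bad)}")
        values = cnt.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("counts contain NaN or infinite values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at probe {cnt.index[r]!r}, sample {cnt.columns[c]!r}"
            )

    @property
    def probe_names(self) -> list[str]:
        return list(self.annotations.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of_class(self, probe_class: str) -> list[str]:
        mask = self.annotations["probe_class"] == probe_class
        return list(self.annotations.index[mask])

    def require_normalizable(self) -> None:
        """Check the invariants needed before background/housekeeper steps."""
        if not self.probes_of_class("negative"):
            raise ValidationError("no negative-control probes present")
        if not self.probes_of_class("housekeeping"):
            raise ValidationError("no housekeeping probes present")

    def equals(self, other: "ProbeCountTable") -> bool:
        return self.annotations.equals(other.annotations) and self.counts.equals(
            other.counts
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with platform and scale tags.

    ``scale`` distinguishes raw abundances from classifier-ready
    log2-normalized values; the classifier refuses ``raw`` input.
    ``gene_roles`` optionally flags rows (e.g. retained housekeepers) and is
    carried through harmonization.
    """

    values: pd.DataFrame
    platform: str
    scale: str
    gene_roles: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_log2(self) -> None:
        if self.scale != "log2_normalized":
            raise ValidationError(
                "classifier input must be log2_normalized, got scale="
                f"{self.scale!r}"
            )


@dataclass
class CentroidMatrix:
    """Prototype expression profile per intrinsic subtype (gene x 5)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SUBTYPES) - set(self.values.columns)
        if missing:
            raise ValidationError(f"missing subtype column(s): {sorted(missing)}")
        extra = set(self.values.columns) - set(SUBTYPES)
        if extra:
            raise ValidationError(f"unexpected subtype column(s): {sorted(extra)}")
        self.values = self.values.loc[:, list(SUBTYPES)]
        if len(self.values) < 2:
            raise ValidationError("centroid matrix needs at least 2 genes")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate genes in centroid matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("centroid matrix contains non-finite values")
        spans = arr.max(axis=0) - arr.min(axis=0)
        if (spans == 0).any():
            flat = [SUBTYPES[i] for i in np.flatnonzero(spans == 0)]
            raise ValidationError(f"constant centroid column(s): {flat}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class GeneAliasMap:
    """Functional alias -> canonical symbol mapping; idempotent by construction."""

    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, canon in self.aliases.items():
            if alias == canon:
                continue
            if canon in self.aliases and self.aliases[canon] != canon:
                raise ValidationError(
                    f"alias chain {alias!r} -> {canon!r} -> "
                    f"{self.aliases[canon]!r}: map is not idempotent"
                )

    def resolve(self, symbol: str) -> str:
        return self.aliases.get(symbol, symbol)


# ---------------------------------------------------------------------------
# Probe-count IO
# ---------------------------------------------------------------------------

def _probe_table_from_frame(frame: pd.DataFrame, where: str) -> ProbeCountTable:
    required = ["probe_name", "gene_symbol", "probe_class"]
    if list(frame.columns[:3]) != required:
        raise FormatError(
            f"{where}: header must start with {required}, got "
            f"{list(frame.columns[:3])}"
        )
    if frame.shape[1] < 4:
        raise FormatError(f"{where}: no sample columns found")
    ann = frame[required].set_index("probe_name")
    sample_cols = list(frame.columns[3:])
    counts = frame.set_index("probe_name")[sample_cols]
    for col in sample_cols:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        bad = coerced.isna() & counts[col].notna()
        if bad.any():
            probe = counts.index[bad][0]
            raise ValidationError(
                f"{where}: non-numeric count at probe {probe!r}, sample {col!r}"
            )
        counts[col] = coerced
    return ProbeCountTable(annotations=ann, counts=counts.astype(float))


def _read_rcc_like(path: Path) -> pd.DataFrame:
    lines = path.read_text(encoding="utf-8").splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.strip().lower() == "<codesummary>"
        )
    except StopIteration:
        raise FormatError(f"{path}: no <CodeSummary> block found") from None
    block: list[str] = []
    for ln in lines[start + 1:]:
        if ln.strip().lower() == "</codesummary>":
            break
        if ln.strip():
            block.append(ln)
    rows = list(csv.reader(io.StringIO("\n".join(block))))
    if not rows:
        raise FormatError(f"{path}: empty CodeSummary block")
    header = [h.strip() for h in rows[0]]
    if [h.lower() for h in header[:3]] != ["codeclass", "name", "genesymbol"]:
        raise FormatError(
            f"{path}: CodeSummary header must start with "
            f"CodeClass,Name,GeneSymbol, got {header[:3]}"
        )
    records = []
    for row in rows[1:]:
        cls = row[0].strip().lower()
        records.append([row[1].strip(), row[2].strip(), cls] + row[3:])
    cols = ["probe_name", "gene_symbol", "probe_class"] + header[3:]
    return pd.DataFrame(records, columns=cols)


def read_probe_counts(path: str | Path, dialect: str = "tsv") -> ProbeCountTable:
    """Read a probe-count table in the ``tsv`` or ``rcc_like`` dialect."""
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str},
                            float_precision="round_trip")
    elif dialect == "rcc_like":
        frame = _read_rcc_like(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _probe_table_from_frame(frame, str(path))


def write_probe_counts(table: ProbeCountTable, path: str | Path) -> None:
    out = table.annotations.copy()
    out.insert(0, "probe_name", out.index)
    frame = pd.concat([out.reset_index(drop=True),
                       table.counts.reset_index(drop=True)], axis=1)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Expression-matrix / centroid IO
# ---------------------------------------------------------------------------

def _read_numeric_table(path: Path, index_name: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus value columns")
    ids = frame.iloc[:, 0]
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"{path}: duplicate {index_name}(s): {dups}")
    frame = frame.set_index(frame.columns[0])
    frame.index.name = index_name
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise ValidationError(
                f"{path}: non-numeric value at {index_name} "
                f"{frame.index[bad][0]!r}, column {col!r}"
            )
        frame[col] = coerced
    return frame.astype(float)


def read_expression_matrix(
    path: str | Path, platform: str, scale: str
) -> ExpressionMatrix:
    """Read a gene x sample TSV and tag it with platform/scale."""
    frame = _read_numeric_table(Path(path), "gene")
    return ExpressionMatrix(values=frame, platform=platform, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_centroids(path: str | Path) -> CentroidMatrix:
    """Read a centroid table (gene rows, one column per subtype)."""
    return CentroidMatrix(values=_read_numeric_table(Path(path), "gene"))


def write_centroids(centroids: CentroidMatrix, path: str | Path) -> None:
    out = centroids.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Gene-identifier harmonization
# ---------------------------------------------------------------------------

def harmonize_gene_ids(
    matrix: ExpressionMatrix, aliases: GeneAliasMap
) -> ExpressionMatrix:
    """Replace alias symbols by canonical ones, preserving row order.

    Raises :class:`AmbiguousMergeError` if two distinct input genes would
    collapse onto one canonical symbol — values are never silently merged.
    """
    new_ids = [aliases.resolve(g) for g in matrix.gene_ids]
    seen: dict[str, str] = {}
    for old, new in zip(matrix.gene_ids, new_ids):
        if new in seen:
            raise AmbiguousMergeError(
                f"genes {seen[new]!r} and {old!r} both map to {new!r}"
            )
        seen[new] = old
    values = matrix.values.copy()
    values.index = pd.Index(new_ids, name=values.index.name)
    roles = matrix.gene_roles
    if roles is not None:
        roles = roles.copy()
        roles.index = pd.Index(new_ids)
    return ExpressionMatrix(
        values=values, platform=matrix.platform, scale=matrix.scale,
        gene_roles=roles,
    )


def read_gene_aliases(path: str | Path) -> GeneAliasMap:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "aliases" in data:
        data = data["aliases"]
    if not isinstance(data, dict):
        raise FormatError(f"{path}: alias map must be a JSON object")
    return GeneAliasMap(aliases={str(k): str(v) for k, v in data.items()})


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def load_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Call-table IO (one row per sample, mirroring Pam50Call)
# ---------------------------------------------------------------------------

CALL_COLUMNS = (
    ["sample_id"]
    + [f"corr_{s}" for s in SUBTYPES]
    + ["call", "second_call", "confidence", "ambiguous", "proliferation_score",
       "ror_s", "ror_s_group", "ror_ps", "ror_ps_group"]
)


def write_calls(calls: Iterable, path: str | Path) -> None:
    """Write classifier output as a fixed-column TSV (see CALL_COLUMNS)."""
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id}
        for s in SUBTYPES:
            row[f"corr_{s}"] = c.centroid_correlations[s]
        row.update(
            call=c.call, second_call=c.second_call, confidence=c.confidence,
            ambiguous=c.ambiguous, proliferation_score=c.proliferation_score,
            ror_s=c.ror_s, ror_s_group=c.ror_s_group,
            ror_ps=c.ror_ps, ror_ps_group=c.ror_ps_group,
        )
        rows.append(row)
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_calls(path: str | Path) -> list:
    from .pam50 import Pam50Call  # deferred: avoid circular import

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(CALL_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing call column(s): {sorted(missing)}")
    calls = []
    for _, row in frame.iterrows():
        calls.append(
            Pam50Call(
                sample_id=str(row["sample_id"]),
                centroid_correlations={s: float(row[f"corr_{s}"]) for s in SUBTYPES},
                call=row["call"],
                second_call=row["second_call"],
                confidence=float(row["confidence"]),
                ambiguous=bool(row["ambiguous"]),
                proliferation_score=float(row["proliferation_score"]),
                ror_s=float(row["ror_s"]),
                ror_s_group=row["ror_s_group"],
                ror_ps=float(row["ror_ps"]),
                ror_ps_group=row["ror_ps_group"],
            )
        )
    return calls
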