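"""Reading, writing and preprocessing of omics matrices and gene-set collections.

The preprocessing pipeline is order-sensitive and runs
``collapse_probes -> variance_filter -> zero_mean_normalize``:
probe-level rows are first averaged per gene, low-variance genes are
removed, and the surviving rows are z-scored (mean 0, unit sd) so that
downstream activity aggregation can sum genes on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: accepted spellings for the two classes in labels files (lower-cased)
_LABEL_ALIASES = {
    "case": CASE,
    "tumor": CASE,
    "tumour": CASE,
    "disease": CASE,
    "control": CONTROL,
    "normal": CONTROL,
    "healthy": CONTROL,
}


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent matrices."""


@dataclass
class OmicsMatrix:
    """A gene-by-sample numeric matrix with binary class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are gene (or probe) identifiers, columns are sample IDs.
    labels : mapping
        Sample ID -> ``"case"`` | ``"control"``; must cover every column.
    datatype : str
        ``"expression"`` or ``"methylation"``.
    """

    values: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)
    datatype: str = "expression"

    def __post_init__(self) -> None:
        if self.datatype not in ("expression", "methylation"):
            raise FormatError(f"unknown datatype {self.datatype!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate row identifiers, e.g. {dup}")
        if not self.values.columns.is_unique:
            raise FormatError("duplicate sample identifiers")
        if self.values.isna().any().any():
            raise FormatError("missing values are not allowed; impute or drop upstream")
        if self.labels:
            missing = [s for s in self.values.columns if s not in self.labels]
            if missing:
                raise FormatError(f"samples without a label: {missing[:5]}")
            seen = {self.labels[s] for s in self.values.columns}
            if seen - {CASE, CONTROL}:
                raise FormatError(f"labels must be case/control, got {seen}")
            if seen != {CASE, CONTROL}:
                raise FormatError("both classes must be non-empty")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def class_samples(self, klass: str) -> list[str]:
        """Sample IDs carrying label ``klass``."""
        return [s for s in self.values.columns if self.labels.get(s) == klass]

    def label_vector(self) -> np.ndarray:
        """Boolean vector over columns, True where the sample is a case."""
        return np.array([self.labels[s] == CASE for s in self.values.columns])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), e.g. an MSigDB-style curated collection."""

    sets: dict[str, list[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {pid!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {pid!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, genes, min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets smaller than ``min_size``."""
        universe = set(genes)
        kept, skipped = {}, 0
        for pid, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if len(inter) >= min_size:
                kept[pid] = inter
            else:
                skipped += 1
        if skipped:
            logger.info("restrict: skipped %d sets below size %d", skipped, min_size)
        return GeneSetCollection(kept, {p: self.names.get(p, "") for p in kept})


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (one tab-separated gene set per line).

    Each line must have at least three fields: name, description, then gene
    symbols.  Duplicate symbols within a line are dropped keeping the first
    occurrence; a duplicated set name is an error.
    """
    sets: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            if pid in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway ID {pid!r}")
            seen: dict[str, None] = {}
            for g in genes:
                if g and g not in seen:
                    seen[g] = None
            sets[pid] = list(seen)
            names[pid] = desc
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
        return GeneSetCollection({}, {})
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, genes in collection.sets.items():
            fh.write("\t".join([pid, collection.names.get(pid, "")] + list(genes)) + "\n")


def read_matrix(path, labels: Mapping[str, str] | None = None,
                datatype: str = "expression") -> OmicsMatrix:
    """Read a TSV or GCT 1.2 matrix (rows = genes/probes, columns = samples).

    GCT files are detected by the ``#1.2`` signature on the first line; their
    two header lines and the Description column are dropped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0,
                         float_precision="round_trip")
        # GCT column 2 is a free-text description
        df = df.drop(columns=df.columns[0])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed")
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df, dict(labels) if labels else {}, datatype)


def write_matrix(matrix: OmicsMatrix, path, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene",
                         float_format=float_format)


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV of (sample ID, label); labels are matched
    case-insensitively to case/control (tumor/normal accepted as aliases)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            sample, lab = fields
            if lineno == 1 and lab.lower() not in _LABEL_ALIASES:
                continue  # header row
            key = lab.strip().lower()
            if key not in _LABEL_ALIASES:
                raise FormatError(
                    f"{path}: line {lineno}: unrecognized label {lab!r}"
                )
            if sample in labels:
                raise FormatError(f"{path}: line {lineno}: duplicate sample {sample!r}")
            labels[sample] = _LABEL_ALIASES[key]
    return labels


def write_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlabel\n")
        for sample, lab in labels.items():
            fh.write(f"{sample}\t{lab}\n")


# ---------------------------------------------------------------------------
# preprocessing


def collapse_probes(probe_matrix: OmicsMatrix,
                    probe_map: Mapping[str, str]) -> OmicsMatrix:
    """Average probe-level rows that map to the same gene symbol.

    Probes absent from ``probe_map`` are dropped (a count is logged).
    """
    if not probe_map:
        raise FormatError("probe_map is empty")
    df = probe_matrix.values
    mapped = df.index.map(lambda p: probe_map.get(p))
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    keep = ~mapped.isna()
    collapsed = df.loc[keep].groupby(mapped[keep], sort=True).mean()
    collapsed.index.name = df.index.name
    return replace(probe_matrix, values=collapsed)


def variance_filter(matrix: OmicsMatrix, threshold: float) -> OmicsMatrix:
    """Drop rows whose sample variance (ddof=1) is below ``threshold``."""
    if threshold < 0:
        raise ValueError("variance threshold must be >= 0")
    if threshold == 0:
        return matrix
    var = matrix.values.var(axis=1, ddof=1)
    keep = var >= threshold
    if not keep.any():
        raise FormatError(
            "variance filter removed every row; lower the threshold"
        )
    return replace(matrix, values=matrix.values.loc[keep])


def zero_mean_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Row-wise z-score: subtract the row mean and divide by the row sd.

    Zero-variance rows must have been removed by :func:`variance_filter`.
    """
    if matrix.values.shape[1] < 2:
        raise FormatError("need at least 2 samples to normalize")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = vals.index[sd == 0][:3].tolist()
        raise FormatError(
            f"zero-variance rows present (e.g. {bad}); apply variance_filter first"
        )
    normed = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return replace(matrix, values=normed)


def preprocess(probe_matrix: OmicsMatrix,
               probe_map: Mapping[str, str] | None = None,
               variance_threshold: float = 0.0) -> OmicsMatrix:
    """Full preparation pipeline: collapse -> variance filter -> z-score."""
    m = probe_matrix
    if probe_map is not None:
        m = collapse_probes(m, probe_map)
    m = variance_filter(m, variance_threshold)
    # guard against zero-variance rows when the filter is off
    sd = m.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        m = replace(m, values=m.values.loc[sd > 0])
        logger.info("preprocess: dropped %d constant rows", int((sd == 0).sum()))
    return zero_mean_normalize(m)
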