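"""Core data containers and readers/writers for expression, phenotype and
genotype tables.

Expression matrices are probes-in-rows, samples-in-columns, following the
long-and-thin shape of microarray data. Two text dialects are supported: a
plain TSV with a header row, and the GEO series-matrix dialect in which the
data table is fenced by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` markers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "PhenotypeTable",
    "GenotypeMatrix",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_genotype",
    "write_genotype",
    "read_annotation",
    "write_annotation",
    "collapse_duplicates",
]

PHENOTYPE_PERCENT_FIELDS = ("pct_4h_viable", "pct_24h_viable", "pct_hatch", "pct_5dph")
PHENOTYPE_MORPHOMETRIC_FIELDS = (
    "body_length",
    "body_weight",
    "fecundity",
    "oocyte_diameter",
)
QUALITY_LABELS = ("high", "low", "intermediate", "unassigned")


class DataIOError(ValueError):
    """Raised on malformed input files or inconsistent containers."""


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix.

    ``scale_flag`` distinguishes raw fluorescence intensities (arbitrary
    units, nonnegative) from variance-stabilized values (generalized-log2
    units, any sign).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_flag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataIOError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataIOError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DataIOError("duplicated probe_id in ExpressionMatrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataIOError("duplicated sample_id in ExpressionMatrix")
        if self.scale_flag not in ("raw", "normalized"):
            raise DataIOError(f"unknown scale_flag {self.scale_flag!r}")
        if self.scale_flag == "raw" and np.nanmin(self.values) < 0:
            raise DataIOError("raw intensities must be >= 0")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_flag: str = "raw") -> "ExpressionMatrix":
        return cls(
            probe_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            scale_flag=scale_flag,
        )

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        """Row-subset (and reorder) by probe identifier."""
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise DataIOError(f"unknown probe ids: {missing[:5]}")
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(
            probe_ids=list(probe_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            scale_flag=self.scale_flag,
        )


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping with optional duplicate-spot groups.

    Probes printed more than once on the array share a ``duplicate_group``
    label; all members of a group must target the same gene.
    """

    table: pd.DataFrame  # columns: probe_id, gene_id, duplicate_group (nullable)

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id"}
        if not required.issubset(self.table.columns):
            raise DataIOError(f"annotation requires columns {sorted(required)}")
        if "duplicate_group" not in self.table.columns:
            self.table = self.table.assign(duplicate_group=pd.NA)
        if self.table["probe_id"].duplicated().any():
            raise DataIOError("duplicated probe_id in annotation")
        groups = self.table.dropna(subset=["duplicate_group"])
        bad = groups.groupby("duplicate_group")["gene_id"].nunique()
        conflicts = bad[bad > 1]
        if len(conflicts):
            raise DataIOError(
                f"duplicate_group(s) with conflicting gene_ids: {list(conflicts.index)[:5]}"
            )

    def gene_for(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["gene_id"]))


@dataclass
class PhenotypeTable:
    """Per-sample spawn-quality metrics.

    Percentages live in [0, 100]; morphometrics are in their natural units
    (length cm, weight kg, fecundity eggs/kg, oocyte diameter um).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise DataIOError("phenotype table requires a sample_id column")
        if self.table["sample_id"].duplicated().any():
            raise DataIOError("duplicated sample_id in phenotype table")
        if "quality_label" not in self.table.columns:
            self.table = self.table.assign(quality_label="unassigned")
        for col in PHENOTYPE_PERCENT_FIELDS:
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise DataIOError(f"{col} outside [0, 100]")
        bad = set(self.table["quality_label"].dropna()) - set(QUALITY_LABELS)
        if bad:
            raise DataIOError(f"unknown quality_label values: {sorted(bad)}")

    def target(self, name: str = "pct_4h_viable") -> pd.Series:
        return self.table.set_index("sample_id")[name]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]


@dataclass
class GenotypeMatrix:
    """Microsatellite allele dosages: samples x (locus:allele) columns with
    entries in {0, 1, 2}; within each locus the dosages of a sample sum to
    at most two (a diploid carries two allele copies)."""

    sample_ids: list[str]
    allele_ids: list[str]  # "locus:allele"
    dosages: np.ndarray
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.allele_ids)):
            raise DataIOError("dosage shape mismatch")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise DataIOError("dosages must be in {0, 1, 2}")
        if self._validate:
            loci = [a.split(":", 1)[0] for a in self.allele_ids]
            frame = pd.DataFrame(self.dosages.T)
            sums = frame.groupby(loci).sum()
            if (sums.to_numpy() > 2).any():
                raise DataIOError("per-locus dosage sum exceeds 2 for some sample")


# ---------------------------------------------------------------------------
# readers / writers

_PROVENANCE_PREFIX = "#"


def _provenance_line(seed: int | None = None, note: str = "") -> str:
    from eggprint import __version__

    parts = [f"eggprint v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if note:
        parts.append(note)
    return _PROVENANCE_PREFIX + " " + " ".join(parts)


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``geo_series_matrix`` text.

    TSV: first row is the header (first column probe ids, remaining columns
    sample ids). A leading ``# ... scale=normalized`` comment switches the
    scale flag. Series-matrix: only the fenced table is parsed; the first
    column holds probe ids.
    """
    if format == "tsv":
        scale = "raw"
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith(_PROVENANCE_PREFIX):
                if "scale=normalized" in line:
                    scale = "normalized"
                continue
            body.append(line)
        if not body:
            raise DataIOError(f"{path}: no data lines")
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t", index_col=0,
                         float_precision="round_trip")
        _check_rect(df, path)
        return ExpressionMatrix.from_frame(df, scale_flag=scale)
    if format == "geo_series_matrix":
        return _read_series_matrix(path)
    raise DataIOError(f"unknown expression format {format!r}")


def _check_rect(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataIOError(f"{path}: duplicated probe_id(s) {dupes[:5]}")
    if df.isna().any().any():
        raise DataIOError(f"{path}: missing values in expression table")


def _read_series_matrix(path) -> ExpressionMatrix:
    rows: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped == "!series_matrix_table_begin":
                if saw_begin:
                    raise DataIOError(f"{path}:{lineno}: repeated table_begin marker")
                saw_begin, in_table = True, True
                continue
            if stripped == "!series_matrix_table_end":
                saw_end, in_table = True, False
                continue
            if in_table:
                rows.append(line)
    if not saw_begin or not saw_end:
        raise DataIOError(
            f"{path}: missing !series_matrix_table_begin/end markers"
        )
    if not rows:
        raise DataIOError(f"{path}: empty series-matrix table")
    df = pd.read_csv(io.StringIO("".join(rows)), sep="\t", index_col=0,
                     float_precision="round_trip")
    # GEO quotes the ID_REF column header; normalize it away
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    _check_rect(df, path)
    return ExpressionMatrix.from_frame(df, scale_flag="raw")


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv",
                     seed: int | None = None) -> None:
    df = expr.to_frame()
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(_provenance_line(seed, f"scale={expr.scale_flag}") + "\n")
            df.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.17g")
    elif format == "geo_series_matrix":
        with open(path, "w") as fh:
            fh.write(_provenance_line(seed, f"scale={expr.scale_flag}") + "\n")
            fh.write("!series_matrix_table_begin\n")
            df.to_csv(fh, sep="\t", index_label='"ID_REF"', float_format="%.17g")
            fh.write("!series_matrix_table_end\n")
    else:
        raise DataIOError(f"unknown expression format {format!r}")


def read_phenotype(path) -> PhenotypeTable:
    df = pd.read_csv(path, comment=_PROVENANCE_PREFIX)
    return PhenotypeTable(df)


def write_phenotype(pheno: PhenotypeTable, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed) + "\n")
        pheno.table.to_csv(fh, index=False)


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, comment=_PROVENANCE_PREFIX)
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed) + "\n")
        ann.table.to_csv(fh, index=False)


def read_genotype(path) -> GenotypeMatrix:
    df = pd.read_csv(path, comment=_PROVENANCE_PREFIX, index_col=0)
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        allele_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=int),
    )


def write_genotype(geno: GenotypeMatrix, path, seed: int | None = None) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.allele_ids)
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed) + "\n")
        df.to_csv(fh, index_label="sample_id")


# ---------------------------------------------------------------------------


def collapsed_annotation(ann: ProbeAnnotation) -> ProbeAnnotation:
    """Gene-level annotation matching the output of :func:`collapse_duplicates`:
    each collapsed row (named by gene_id) maps to itself with no duplicate
    group. Useful for re-running downstream steps on collapsed matrices."""
    genes = pd.unique(ann.table["gene_id"])
    return ProbeAnnotation(
        pd.DataFrame({"probe_id": genes, "gene_id": genes, "duplicate_group": pd.NA})
    )


def collapse_duplicates(expr: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse duplicate-printed probes to one row per gene.

    Probes sharing a ``duplicate_group`` are replaced by their per-sample
    arithmetic mean (on whatever scale the matrix carries; the intended use
    is the normalized glog scale). The collapsed matrix is indexed by
    gene_id. Idempotent: collapsing an already-collapsed matrix is a no-op.
    """
    tab = ann.table.set_index("probe_id")
    missing = [p for p in expr.probe_ids if p not in tab.index]
    if missing:
        raise DataIOError(f"probes without annotation: {missing[:5]}")
    sub = tab.loc[expr.probe_ids]
    has_group = sub["duplicate_group"].notna().to_numpy()
    if not has_group.any():
        return expr

    # group key: the duplicate_group where present, else the probe itself
    keys = np.where(has_group, sub["duplicate_group"].astype(object), sub.index)
    df = expr.to_frame()
    order = pd.unique(keys)
    collapsed = df.groupby(keys, sort=False).mean().loc[order]

    gene_of_key: dict = {}
    for key, probe, gene in zip(keys, sub.index, sub["gene_id"]):
        gene_of_key.setdefault(key, gene)
    new_ids = [str(gene_of_key[k]) for k in order]
    if len(set(new_ids)) != len(new_ids):
        # distinct groups mapping to one gene: merge them too
        collapsed.index = new_ids
        collapsed = collapsed.groupby(level=0, sort=False).mean()
        new_ids = [str(i) for i in collapsed.index]
    return ExpressionMatrix(
        probe_ids=new_ids,
        sample_ids=list(expr.sample_ids),
        values=collapsed.to_numpy(dtype=float),
        scale_flag=expr.scale_flag,
    )
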