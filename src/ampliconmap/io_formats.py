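"""Readers and writers for the on-disk formats used across the pipeline.

Coordinate convention: 0-based half-open internally and in BED files;
human-readable reports use 1-based inclusive Mb. Gene symbols are matched
case-insensitively after upper-casing. All result files are JSON with an
explicit schema version; logs go to stderr with timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

MISSING_TOKENS = {"", "NA", "NAN", "NaN", "nan", "na", "N/A", "null", "None"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Well-formed input that violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# clone maps and aCGH profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneInterval:
    """One array probe (BAC clone): a genomic interval with an identifier."""

    clone_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"clone {self.clone_id!r}: start {self.start} >= end {self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class CloneMap:
    """An ordered collection of array clones; the copy-number substrate.

    Entries are kept sorted by (chrom, start) and clone ids must be unique.
    ``build`` is free-text genome-build metadata, carried but never resolved.
    """

    entries: list[CloneInterval]
    build: str | None = None

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda c: (c.chrom, c.start, c.end))
        seen: set[str] = set()
        for c in self.entries:
            if c.clone_id in seen:
                raise ValidationError(f"duplicate clone_id {c.clone_id!r}")
            seen.add(c.clone_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.entries]

    def index_of(self, clone_id: str) -> int:
        try:
            return self.clone_ids.index(clone_id)
        except ValueError:
            raise KeyError(clone_id) from None

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        """(min start, max end) over clones of one chromosome."""
        sel = [c for c in self.entries if c.chrom == chrom]
        if not sel:
            raise KeyError(f"no clones on {chrom!r}")
        return min(c.start for c in sel), max(c.end for c in sel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_ids,
                "chrom": [c.chrom for c in self.entries],
                "start": [c.start for c in self.entries],
                "end": [c.end for c in self.entries],
            }
        )


@dataclass
class CGHProfile:
    """Per-clone log2 tumor/reference ratios for one tumor.

    ``values`` is aligned to a :class:`CloneMap`; ``mask`` flags missing
    measurements (True = missing). Values must be finite wherever unmasked.
    """

    tumor_id: str
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask/values length mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError(
                f"profile {self.tumor_id!r}: non-finite unmasked value"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())


def read_clone_map(path: str | Path, build: str | None = None) -> CloneMap:
    """Read a 4+-column BED-like file (chrom, start, end, name), 0-based half-open."""
    entries: list[CloneInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            entries.append(CloneInterval(name, chrom, start, end))
    return CloneMap(entries, build=build)


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clone_map:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.clone_id}\n")


def read_profile_table(path: str | Path, clone_map: CloneMap) -> list[CGHProfile]:
    """Read a TSV of per-clone log2 ratios, one column per tumor.

    Every clone id in the table must exist in ``clone_map`` and vice versa;
    cells holding NA tokens become masked missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=list(MISSING_TOKENS),
                     keep_default_na=False, float_precision="round_trip")
    id_col = df.columns[0]
    table_ids = df[id_col].tolist()
    unknown = sorted(set(table_ids) - set(clone_map.clone_ids))
    if unknown:
        raise ValidationError(f"clone ids absent from clone map: {unknown[:5]}")
    missing = sorted(set(clone_map.clone_ids) - set(table_ids))
    if missing:
        raise ValidationError(f"clone map ids absent from table: {missing[:5]}")
    df = df.set_index(id_col).loc[clone_map.clone_ids]
    profiles = []
    for tumor_id in df.columns:
        col = pd.to_numeric(df[tumor_id], errors="coerce").to_numpy(dtype=float)
        profiles.append(CGHProfile(tumor_id, col, mask=~np.isfinite(col)))
    return profiles


def write_profile_table(
    profiles: Sequence[CGHProfile], clone_map: CloneMap, path: str | Path
) -> None:
    data = {"clone_id": clone_map.clone_ids}
    for p in profiles:
        col = p.values.astype(object).copy()
        col[p.mask] = np.nan
        data[p.tumor_id] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.17g")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"gene {self.name!r}: start >= end")


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """BED4 gene annotation, returned sorted by (chrom, start)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            genes.append(GeneRecord(fields[3].upper(), fields[0], start, end))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end))


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set; symbols are upper-cased and de-duplicated."""

    name: str
    description: str
    genes: frozenset[str]

    @staticmethod
    def from_iterable(name: str, description: str, genes: Iterable[str]) -> "GeneSet":
        return GeneSet(name, description, frozenset(g.upper() for g in genes))

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            sets.append(GeneSet.from_iterable(fields[0], fields[1], fields[2:]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression, genes x samples, with a phenotype label per sample."""

    values: pd.DataFrame
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [str(g).upper() for g in self.values.index]
        missing = [s for s in self.values.columns if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == label]


def read_expression_matrix(
    matrix_path: str | Path, labels_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip").astype(float)
    lab = pd.read_csv(labels_path, sep="\t")
    if not {"sample", "label"} <= set(lab.columns):
        raise ParseError(f"{labels_path}: need columns 'sample' and 'label'")
    return ExpressionMatrix(values, dict(zip(lab["sample"].astype(str), lab["label"])))


def write_expression_matrix(
    matrix: ExpressionMatrix, matrix_path: str | Path, labels_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", float_format="%.17g")
    pd.DataFrame(
        {"sample": matrix.samples, "label": [matrix.labels[s] for s in matrix.samples]}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR and IHC tables
# ---------------------------------------------------------------------------

def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Genes x tumors table of linear-scale relative quantities (all > 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip").astype(float)
    df.index = [str(g).upper() for g in df.index]
    if (df.to_numpy() <= 0).any():
        raise ValidationError("qPCR quantities must be strictly positive")
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


IHC_COLUMNS = ["case_id", "nuclear_intensity", "cytoplasmic_intensity",
               "pct_positive_nuclei"]


def read_ihc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(IHC_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing IHC columns {sorted(missing)}")
    return df[IHC_COLUMNS]


def write_ihc_table(df: pd.DataFrame, path: str | Path) -> None:
    df[IHC_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration, results, logging
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat run configuration; thresholds default to the standard presets."""

    thresholds: "object" = None  # CallThresholds; set in __post_init__
    bin_size: int = 2_000_000
    seed: int = 17
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        from .cgh_mapping import CallThresholds  # local import avoids a cycle

        if self.thresholds is None:
            self.thresholds = CallThresholds()
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    from .cgh_mapping import CallThresholds

    with open(path) as fh:
        raw = json.load(fh)
    thr = CallThresholds(**raw.pop("thresholds", {}))
    return RunConfig(thresholds=thr, **raw)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def write_json_result(obj: dict, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, cls=_JSONEncoder)
        fh.write("\n")


def json_dumps(obj) -> str:
    return json.dumps(obj, indent=2, cls=_JSONEncoder)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )
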