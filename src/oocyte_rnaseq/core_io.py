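"""Domain types and plain-text readers/writers.

Count matrices, sample metadata, gene lists, spike-in concentration tables
and per-base coverage tracks are all exchanged as tab-separated text (counts,
metadata, spikes), one-ID-per-line lists, or UCSC bedGraph (coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Length of the mouse 45S rRNA primary transcript (5'-ETS through 3'-ETS).
RRNA_TRANSCRIPT_LENGTH = 13_403

#: Last base of the 5' external transcribed spacer within the transcript.
ETS5_END = 4_007

VALID_FEATURE_CLASSES = frozenset({"gene", "spike", "rrna"})
VALID_STAGES = frozenset({"GV", "MII"})
VALID_LIBRARY_TYPES = frozenset({"polyA", "riboMinus"})
VALID_MATERIALS = frozenset({"single", "bulk"})

META_COLUMNS = ["sample_id", "stage", "dataset", "library_type", "material"]


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


@dataclass
class CountMatrix:
    """Non-negative integer read counts, features x samples.

    ``values`` rows are feature IDs (gene symbols/IDs plus spike-in IDs),
    columns are sample/library IDs.  ``feature_class`` tags each row as
    ``gene``, ``spike`` or ``rrna``.
    """

    values: pd.DataFrame
    feature_class: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate feature IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate sample IDs: {dups[:5]}")
        arr = v.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise CountMatrixError("counts must be numeric")
            if np.any(arr < 0) or np.any(arr != np.floor(arr)):
                i, j = next(zip(*np.where((arr < 0) | (arr != np.floor(arr)))))
                raise CountMatrixError(
                    f"invalid count {arr[i, j]!r} at feature "
                    f"{v.index[i]!r}, sample {v.columns[j]!r}"
                )
        self.values = v.astype(np.int64)
        if self.feature_class is None:
            self.feature_class = classify_features(v.index)
        else:
            fc = pd.Series(self.feature_class, index=v.index, dtype=object)
            bad = set(fc.unique()) - VALID_FEATURE_CLASSES
            if bad:
                raise CountMatrixError(f"unknown feature classes: {sorted(bad)}")
            self.feature_class = fc

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_features(self, ids) -> "CountMatrix":
        ids = [i for i in self.feature_ids if i in set(ids)]
        return CountMatrix(self.values.loc[ids], self.feature_class.loc[ids])

    def subset_samples(self, ids) -> "CountMatrix":
        return CountMatrix(self.values[list(ids)], self.feature_class)

    def genes_only(self) -> "CountMatrix":
        keep = self.feature_class == "gene"
        return CountMatrix(self.values.loc[keep], self.feature_class.loc[keep])

    def spike_ids(self) -> list[str]:
        return list(self.feature_ids[self.feature_class == "spike"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.feature_class.equals(
            other.feature_class
        )


def classify_features(index, feature_class_map: dict | None = None) -> pd.Series:
    """Tag features: ``ERCC-`` prefix -> spike, else gene; a map overrides."""
    classes = pd.Series(
        ["spike" if str(i).startswith("ERCC-") else "gene" for i in index],
        index=index,
        dtype=object,
    )
    if feature_class_map:
        for fid, cls in feature_class_map.items():
            if cls not in VALID_FEATURE_CLASSES:
                raise CountMatrixError(f"unknown feature class {cls!r}")
            if fid in classes.index:
                classes.loc[fid] = cls
    return classes


@dataclass(frozen=True)
class FeatureGeneSets:
    """Curated gene/spike ID sets used as supervised features or controls."""

    sn_featured: frozenset = frozenset()
    nsn_featured: frozenset = frozenset()
    const_genes: frozenset = frozenset()
    ercc_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        overlap = self.sn_featured & self.nsn_featured
        if overlap:
            raise ValueError(
                f"SN- and NSN-featured sets overlap: {sorted(overlap)[:5]}"
            )


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------


def read_count_matrix(path, feature_class_map: dict | None = None) -> CountMatrix:
    """Read a feature x sample TSV (first column ``feature_id``).

    Rows whose ID starts with ``ERCC-`` are classed as spikes unless
    ``feature_class_map`` says otherwise.  Non-integer or negative entries
    raise :class:`CountMatrixError` naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise CountMatrixError(f"non-numeric entry in {path}: {exc}") from exc
    cm = CountMatrix(numeric, classify_features(numeric.index, feature_class_map))
    return cm


def write_count_matrix(cm: CountMatrix, path) -> None:
    """Write a count matrix as TSV; inverse of :func:`read_count_matrix`."""
    out = cm.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def read_sample_meta(path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, stage, dataset, library_type, material)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dups[:5]}")
    for col, valid in [
        ("stage", VALID_STAGES),
        ("library_type", VALID_LIBRARY_TYPES),
        ("material", VALID_MATERIALS),
    ]:
        bad = set(meta[col]) - valid
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    return meta.reset_index(drop=True)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    validate_sample_meta(meta)[META_COLUMNS].to_csv(path, sep="\t", index=False)


def check_meta_covers(cm: CountMatrix, meta: pd.DataFrame) -> None:
    """Every matrix column must have exactly one metadata row (hard error)."""
    meta_ids = set(meta["sample_id"])
    missing = [s for s in cm.sample_ids if s not in meta_ids]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")


# ---------------------------------------------------------------------------
# Gene lists and spike tables
# ---------------------------------------------------------------------------


def read_gene_list(path) -> list[str]:
    """One ID per line; '#' starts a comment; blank lines ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.append(entry)
    return ids


def write_gene_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_spike_table(path) -> pd.Series:
    """Spike concentrations (TSV: spike_id, concentration), strictly positive."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["spike_id", "concentration"][: len(df.columns)]
    if df["spike_id"].duplicated().any():
        raise ValueError("duplicate spike IDs in spike table")
    conc = pd.Series(
        df["concentration"].astype(float).to_numpy(), index=df["spike_id"]
    )
    if (conc <= 0).any():
        bad = conc.index[conc <= 0].tolist()
        raise ValueError(f"non-positive spike concentrations: {bad[:5]}")
    return conc


def write_spike_table(conc: pd.Series, path) -> None:
    pd.DataFrame({"spike_id": conc.index, "concentration": conc.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Coverage (bedGraph)
# ---------------------------------------------------------------------------


def read_coverage_bedgraph(
    path, transcript_length: int = RRNA_TRANSCRIPT_LENGTH
) -> np.ndarray:
    """Expand a bedGraph track into a per-base coverage vector.

    bedGraph intervals are 0-based half-open; the returned vector is 1-based
    inclusive in spirit: entry ``p-1`` holds the coverage of transcript
    position ``p`` (1..transcript_length).  Uncovered positions are 0.
    Overlapping intervals or intervals past the transcript end are errors.
    """
    vec = np.zeros(transcript_length, dtype=float)
    covered = np.zeros(transcript_length, dtype=bool)
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("track", "#", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 'chrom start end value'")
        start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        if start < 0 or end <= start:
            raise ValueError(f"{path}:{ln}: bad interval [{start}, {end})")
        if end > transcript_length:
            raise ValueError(
                f"{path}:{ln}: interval end {end} exceeds transcript "
                f"length {transcript_length}"
            )
        if covered[start:end].any():
            raise ValueError(f"{path}:{ln}: overlapping interval [{start}, {end})")
        vec[start:end] = value
        covered[start:end] = True
    return vec


def write_coverage_bedgraph(coverage: np.ndarray, path, chrom: str = "rRNA") -> None:
    """Write a coverage vector as run-length-encoded bedGraph (zeros omitted)."""
    lines = []
    n = len(coverage)
    start = 0
    while start < n:
        val = coverage[start]
        end = start + 1
        while end < n and coverage[end] == val:
            end += 1
        if val != 0:
            lines.append(f"{chrom}\t{start}\t{end}\t{val:g}")
        start = end
    Path(path).write_text("".join(f"{l}\n" for l in lines))
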