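"""Readers and writers for the tabular formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
The SEG reader converts from the common 1-based inclusive SEG dialect; BED
input is taken as already 0-based half-open.  Tables are plain pandas objects
with documented columns so that downstream modules stay NumPy-friendly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("cnaprog")

#: Ordered early-stage levels; IA is the reference level of the survival models.
STAGES = ("IA", "IB", "IIA", "IIB")

SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "num_markers", "seg_mean"]

# case-insensitive header synonyms for the SEG dialect
_SEG_SYNONYMS = {
    "id": "sample_id", "sample": "sample_id", "sample_id": "sample_id",
    "chrom": "chromosome", "chromosome": "chromosome",
    "loc.start": "start", "start": "start",
    "loc.end": "end", "end": "end",
    "num.mark": "num_markers", "num_mark": "num_markers",
    "num_markers": "num_markers",
    "seg.mean": "seg_mean", "seg_mean": "seg_mean",
}


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval.  Strand is informational only: copy number is
    strand-agnostic and overlap computations ignore it."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def _sort_segments(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["sample_id", "chromosome", "start"], kind="mergesort").reset_index(
        drop=True
    )


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Check SegmentTable invariants: start < end, finite seg_mean, and
    non-overlapping segments within each (sample, chromosome)."""
    bad = df[~(df["start"] < df["end"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"segment with start >= end: {r['sample_id']} {r['chromosome']} "
            f"[{r['start']}, {r['end']})"
        )
    if not np.isfinite(df["seg_mean"]).all():
        raise ValidationError("non-finite seg_mean")
    df = _sort_segments(df)
    for (sample, chrom), grp in df.groupby(["sample_id", "chromosome"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValidationError(
                f"overlapping segments for {sample} {chrom}: "
                f"[{starts[i]}, {ends[i]}) and [{starts[i + 1]}, {ends[i + 1]})"
            )
    return df


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (tab-delimited, header, 1-based inclusive coordinates).

    Returns a SegmentTable: DataFrame with columns ``sample_id, chromosome,
    start, end, num_markers, seg_mean`` in 0-based half-open coordinates,
    sorted by (sample, chromosome, start).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _SEG_SYNONYMS:
            rename[col] = _SEG_SYNONYMS[key]
    raw = raw.rename(columns=rename)
    for col in SEG_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"SEG file {path}: missing column {col!r}")
    df = raw[SEG_COLUMNS].copy()
    try:
        df["start"] = df["start"].astype(np.int64) - 1  # 1-based inclusive -> 0-based half-open
        df["end"] = df["end"].astype(np.int64)
        df["num_markers"] = df["num_markers"].astype(np.int64)
        df["seg_mean"] = df["seg_mean"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"SEG file {path}: non-numeric value ({exc})") from exc
    if (df["num_markers"] <= 0).any():
        raise ValidationError(f"SEG file {path}: num_markers must be positive")
    return validate_segments(df)


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write a SegmentTable back to the 1-based inclusive SEG dialect."""
    out = segments.copy()
    out["start"] = out["start"] + 1
    out.columns = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table (TSV) and flag labeled rows.

    Returns a DataFrame indexed by ``sample_id`` with columns ``age, sex,
    stage, os_time, os_event, labeled``.  A row is labeled iff both
    ``os_time`` and ``os_event`` are present; having exactly one of the two
    is a validation error, as is a stage outside IA/IB/IIA/IIB or a
    non-positive survival time.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "age", "sex", "stage"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"clinical table {path}: missing column {col!r}")
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            df[col] = np.nan
    return validate_clinical(df.set_index("sample_id"))


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        val = df.loc[bad_stage, "stage"].iloc[0]
        raise ValidationError(
            f"stage {val!r} outside the early-stage levels {STAGES}; "
            "the method is defined for stage IA-IIB tumors only"
        )
    df["stage"] = pd.Categorical(df["stage"], categories=list(STAGES), ordered=True)
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValidationError(f"unknown sex value {df.loc[bad_sex, 'sex'].iloc[0]!r}")
    has_time = df["os_time"].notna()
    has_event = df["os_event"].notna()
    if (has_time != has_event).any():
        sample = df.index[has_time != has_event][0]
        raise ValidationError(
            f"sample {sample}: os_time and os_event must be jointly present or absent"
        )
    if (df.loc[has_time, "os_time"] <= 0).any():
        raise ValidationError("os_time must be > 0 for labeled samples")
    events = df.loc[has_event, "os_event"]
    if not events.isin([0, 1, 0.0, 1.0]).all():
        raise ValidationError("os_event must be 0 or 1")
    df["labeled"] = has_time & has_event
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.drop(columns=["labeled"], errors="ignore").to_csv(
        path, sep="\t", index=True, index_label="sample_id"
    )


def read_gene_bed(path) -> list[GeneAnnotation]:
    """Read gene annotations from a BED4+ file (0-based half-open)."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{line_no}: BED row needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            if name in seen:
                raise ValidationError(f"{path}: duplicate gene id {name!r}")
            seen.add(name)
            try:
                genes.append(GeneAnnotation(name, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return genes


def write_gene_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"matrix {path}: duplicate gene id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"matrix {path}: non-numeric cell {df.iat[i, j]!r} at "
            f"gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return numeric.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_purity(path) -> pd.Series:
    """Read the per-sample tumor purity table (TSV: sample_id, purity)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "purity"):
        if col not in df.columns:
            raise FormatError(f"purity table {path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"purity table {path}: duplicated sample id")
    s = df.set_index("sample_id")["purity"].astype(float)
    if ((s <= 0) | (s > 1)).any():
        raise ValidationError("purity must lie in (0, 1]")
    return s


def write_purity(purity: pd.Series, path) -> None:
    purity.rename("purity").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Signature document
# ---------------------------------------------------------------------------

@dataclass
class SignatureDocument:
    """Serializable form of a fitted clinical-genomic signature.

    ``models`` lists the retained candidate models (nested gene prefixes) with
    their coefficient maps, AICs and Akaike weights; ``genes`` is the union of
    genes appearing in any member model, and ``reported_genes`` the flat
    signature (genes whose models carry cumulative Akaike weight >= 0.5).
    ``centering`` holds the training covariate means used to anchor the
    linear predictors, and ``training_median`` the risk-score threshold.
    """

    histology: str
    clinical_coef: dict[str, float]
    genes: list[str]
    reported_genes: list[str]
    models: list[dict[str, Any]]
    akaike_weights: list[float]
    training_median: float
    centering: dict[str, float]
    aux_models: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.akaike_weights, dtype=float)
        if len(w) and abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"Akaike weights sum to {w.sum()}, not 1")
        member_genes = {g for m in self.models for g in m["genes"]}
        if not member_genes <= set(self.genes):
            raise ValidationError("member-model gene missing from the gene list")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def write_signature(doc: SignatureDocument, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_signature(path) -> SignatureDocument:
    with open(path) as fh:
        return SignatureDocument(**json.load(fh))
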