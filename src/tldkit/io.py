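"""Readers and writers for the plain-text table formats used across the toolkit.

All genomic coordinates are 1-based inclusive internally.  Conversion from
0-based half-open conventions (BED) happens here and only here.  Tables are
TSV/CSV with required headers; model fits are JSON; configs are YAML.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MutationRecord",
    "read_mutation_table",
    "packaged_mutation_table",
    "read_insertions",
    "write_insertions",
    "read_annotation",
    "read_annotation_bed",
    "read_annotation_gff3",
    "read_insertions_sam",
    "read_counts",
    "read_events",
    "write_events",
    "read_sort_counts",
    "read_fitness_table",
]


class TableFormatError(ValueError):
    """A table failed structural validation (missing column, bad type, bad row)."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


# ---------------------------------------------------------------------------
# Mutation table (whole-genome sequencing summary of an evolved isolate)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One row of a resequencing mutation table.

    ``gene_or_locus`` is a single gene name, or for intergenic mutations the
    two flanking locus names joined by ``/``; those are also exposed in
    ``flanking``.  ``mutation`` is the free-text description (amino-acid
    change, early stop, small indel, intergenic offsets) and ``function`` the
    annotation column.
    """

    gene_or_locus: str
    mutation: str
    function: str

    @property
    def is_intergenic(self) -> bool:
        return "/" in self.gene_or_locus

    @property
    def flanking(self) -> tuple[str, str] | None:
        """The two flanking locus names for an intergenic record, else None."""
        if not self.is_intergenic:
            return None
        left, right = self.gene_or_locus.split("/", 1)
        strip = " \t←→<>-"
        return left.strip(strip), right.strip(strip)

    @property
    def is_synonymous(self) -> bool:
        """True for amino-acid notations like V4V where the residue is unchanged."""
        token = self.mutation.split()[0] if self.mutation else ""
        return (
            len(token) >= 3
            and token[0].isalpha()
            and token[-1].isalpha()
            and token[0] == token[-1]
            and token[1:-1].isdigit()
        )


def read_mutation_table(path) -> list[MutationRecord]:
    """Parse a three-column mutation TSV into :class:`MutationRecord` rows.

    Raises :class:`TableFormatError` with the offending line number on a
    malformed row.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file, expected a header line")
    header = lines[0].split("\t")
    if header != ["gene_or_locus", "mutation", "function"]:
        raise TableFormatError(
            f"{path}: bad header {header!r}, expected gene_or_locus/mutation/function"
        )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 or not fields[0].strip():
            raise TableFormatError(f"{path}: malformed row at line {lineno}: {line!r}")
        records.append(MutationRecord(*(f.strip() for f in fields)))
    return records


def packaged_mutation_table() -> list[MutationRecord]:
    """The bundled mutation table for the TLD-resistant MDS42 evolved isolate."""
    ref = importlib.resources.files("tldkit") / "data" / "mds42_mutations.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_mutation_table(path)


# ---------------------------------------------------------------------------
# Transposon insertion tables
# ---------------------------------------------------------------------------

_INSERTION_COLS = ["chrom", "pos", "strand", "sample", "count"]


def read_insertions(path) -> pd.DataFrame:
    """Read a site-level insertion count TSV (chrom, pos, strand, sample, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "sample": str})
    _require_columns(df, _INSERTION_COLS, path)
    df = df[_INSERTION_COLS].copy()
    if not pd.api.types.is_integer_dtype(df["pos"]):
        raise TableFormatError(f"{path}: 'pos' must be integer")
    if not pd.api.types.is_integer_dtype(df["count"]):
        raise TableFormatError(f"{path}: 'count' must be integer")
    if (df["pos"] < 1).any():
        raise TableFormatError(f"{path}: positions must be >= 1 (1-based coordinates)")
    if (df["count"] < 0).any():
        raise TableFormatError(f"{path}: counts must be non-negative")
    bad_strand = ~df["strand"].isin(["+", "-", "unknown"])
    if bad_strand.any():
        raise TableFormatError(
            f"{path}: bad strand value(s) {sorted(df.loc[bad_strand, 'strand'].unique())}"
        )
    dup = df.duplicated(subset=["chrom", "pos", "strand", "sample"])
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicate (chrom,pos,strand,sample) keys, first at row {dup.idxmax()}"
        )
    return df


def write_insertions(df: pd.DataFrame, path) -> None:
    df[_INSERTION_COLS].to_csv(path, sep="\t", index=False)


def read_insertions_sam(path, sample: str) -> pd.DataFrame:
    """Thin SAM adapter: one count per primary alignment at the 5' mapped coordinate.

    The 5' coordinate is the leftmost reference position for forward-strand
    alignments and the rightmost for reverse-strand ones.
    """
    import pysam

    sites: dict[tuple[str, int, str], int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse:
                pos, strand = aln.reference_end, "-"  # reference_end is 1-based inclusive end
            else:
                pos, strand = aln.reference_start + 1, "+"
            key = (aln.reference_name, pos, strand)
            sites[key] = sites.get(key, 0) + 1
    rows = [
        {"chrom": c, "pos": p, "strand": s, "sample": sample, "count": n}
        for (c, p, s), n in sorted(sites.items())
    ]
    return pd.DataFrame(rows, columns=_INSERTION_COLS)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["gene_id", "chrom", "start", "end", "strand"]


def _validate_annotation(df: pd.DataFrame, path) -> pd.DataFrame:
    if (df["start"] > df["end"]).any():
        raise TableFormatError(f"{path}: gene interval with start > end")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise TableFormatError(f"{path}: duplicate gene_id(s) {dups}")
    return df.reset_index(drop=True)


def read_annotation_bed(path) -> pd.DataFrame:
    """BED6 (0-based half-open) -> 1-based inclusive annotation table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "bed_start", "bed_end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["bed_start"].astype(int) + 1,
            "end": df["bed_end"].astype(int),
            "strand": df["strand"],
        }
    )
    return _validate_annotation(out, path)


def read_annotation_gff3(path) -> pd.DataFrame:
    """GFF3 gene features (ID attribute) -> 1-based inclusive annotation table."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "unknown",
            }
        )
    if not rows:
        raise TableFormatError(f"{path}: no features of type 'gene' found")
    return _validate_annotation(pd.DataFrame(rows, columns=_ANNOT_COLS), path)


def read_annotation(path) -> pd.DataFrame:
    """Dispatch on extension: .bed -> BED6, anything else -> GFF3."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_annotation_bed(path)
    return read_annotation_gff3(path)


# ---------------------------------------------------------------------------
# RNA-seq count matrices, flow-cytometry event tables, sort counts, fitness
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Gene-level count matrix TSV: gene_id, length_bp, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    _require_columns(df, ["gene_id", "length_bp"], path)
    if df["gene_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate gene_id rows")
    if (df["length_bp"] <= 0).any():
        raise TableFormatError(f"{path}: gene lengths must be positive")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length_bp")]
    if not sample_cols:
        raise TableFormatError(f"{path}: no sample columns found")
    for c in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise TableFormatError(f"{path}: sample column {c!r} is not numeric")
    return df


_EVENT_COLS = ["fsc", "ssc", "fluor", "strain_condition", "batch", "rep", "is_nodye"]


def read_events(path) -> pd.DataFrame:
    """Per-cell flow cytometry event CSV."""
    df = pd.read_csv(path)
    _require_columns(df, _EVENT_COLS, path)
    for c in ("fsc", "ssc", "fluor"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise TableFormatError(f"{path}: column {c!r} is not numeric")
    df["is_nodye"] = df["is_nodye"].astype(bool)
    for c in ("strain_condition", "batch", "rep"):
        df[c] = df[c].astype(str)
    return df


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_sort_counts(path) -> pd.DataFrame:
    """FACS sort-survival TSV: survivors, n_sorted, dye, level, date."""
    df = pd.read_csv(path, sep="\t", dtype={"dye": str, "level": str, "date": str})
    _require_columns(df, ["survivors", "n_sorted", "dye", "level", "date"], path)
    if ((df["survivors"] < 0) | (df["survivors"] > df["n_sorted"])).any():
        raise TableFormatError(f"{path}: survivors must lie in [0, n_sorted]")
    bad = ~df["level"].isin(["low", "high"])
    if bad.any():
        raise TableFormatError(f"{path}: level must be 'low' or 'high'")
    return df


def read_fitness_table(path) -> pd.DataFrame:
    """Fitness-compendium TSV: gene_id, condition, fitness, t_score."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str})
    _require_columns(df, ["gene_id", "condition", "fitness", "t_score"], path)
    if df.duplicated(subset=["gene_id", "condition"]).any():
        raise TableFormatError(f"{path}: duplicate (gene_id, condition) rows")
    return df
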