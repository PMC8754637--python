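"""Genome annotation and coverage I/O.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GFF3 (1-based, inclusive) is converted at the I/O boundary; BED and bedGraph
are already half-open and pass through unchanged.

The transcription start site (TSS) of a gene is ``start`` on the plus strand
and ``end - 1`` on the minus strand; the transcript end site (TES) is the
opposite end.  These anchors drive every strand-aware computation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "CoverageTrack",
    "AnnotationError",
    "load_annotation",
    "write_annotation",
    "load_probe_table",
    "write_probe_table",
    "read_bedgraph",
    "write_bedgraph",
]

PROBE_COLUMNS = ["probe_id", "chrom", "position", "strand", "pm", "mm", "gene_id"]
UNASSIGNED = "unassigned"


class AnnotationError(ValueError):
    """Malformed annotation or probe input."""


@dataclass(frozen=True)
class Gene:
    """A genomic span with strand, the anchor for all per-gene quantities."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcript end site (0-based base position)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """An ordered gene collection plus chromosome lengths."""

    genes: list[Gene]
    chrom_lengths: dict[str, int]
    _by_id: dict[str, Gene] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in by_id:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            if g.chrom not in self.chrom_lengths:
                raise AnnotationError(
                    f"gene {g.gene_id}: unknown chromosome {g.chrom!r}"
                )
            if g.end > self.chrom_lengths[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: end {g.end} exceeds length of {g.chrom}"
                )
            by_id[g.gene_id] = g
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class CoverageTrack:
    """Per-base numeric vectors, one per chromosome.

    Missing (masked) bases are NaN.  ``normalized`` marks tracks that have
    been divided by sequencing depth and/or input.
    """

    values: dict[str, np.ndarray]
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if not self.normalized:
            for c, v in self.values.items():
                ok = v[~np.isnan(v)]
                if (ok < 0).any():
                    raise ValueError(f"raw track has negative values on {c}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}


# ---------------------------------------------------------------------------
# Annotation readers / writers
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def load_annotation(
    path: str,
    fmt: str,
    chrom_lengths: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read gene records from a GFF3 or BED6 file.

    GFF3 coordinates (1-based inclusive) are shifted to the internal 0-based
    half-open convention; BED records pass through.  For GFF3, only ``gene``
    features are kept, the identifier is taken from the ``ID`` attribute and
    the biotype from a ``biotype`` attribute when present.  When
    *chrom_lengths* is not given, each chromosome's length is the maximum
    gene end observed on it.
    """
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) < 9:
                        raise AnnotationError("fewer than 9 columns")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID")
                    if gene_id is None:
                        raise AnnotationError("gene record without ID attribute")
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])  # inclusive end == half-open end
                    strand = fields[6]
                    biotype = attrs.get("biotype", "protein_coding")
                else:
                    if len(fields) < 6:
                        raise AnnotationError("fewer than 6 columns (BED6 required)")
                    gene_id = fields[3]
                    start = int(fields[1])
                    end = int(fields[2])
                    strand = fields[5]
                    biotype = "protein_coding"
                if gene_id in seen:
                    raise AnnotationError(f"duplicate gene_id {gene_id!r}")
                seen.add(gene_id)
                genes.append(
                    Gene(gene_id, fields[0], start, end, strand, biotype)
                )
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes, chrom_lengths)


def write_annotation(annotation: GenomeAnnotation, path: str, fmt: str) -> None:
    """Write genes as GFF3 (converting back to 1-based) or BED6."""
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in annotation:
                fh.write(
                    f"{g.chrom}\tupfchip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
                )
        else:
            for g in annotation:
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------


def load_probe_table(
    path: str, annotation: GenomeAnnotation | None = None
) -> pd.DataFrame:
    """Read a tiling-array probe table (TSV).

    Columns: probe_id, chrom, position, strand, pm, mm, gene_id.  ``position``
    is the genomic coordinate of the lowest-coordinate base of the probe's
    footprint, regardless of probe strand.  When *annotation* is given, rows
    whose gene_id is not in it are re-grouped under the sentinel
    ``"unassigned"``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing probe-table columns {missing}")
    for col in ("pm", "mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise AnnotationError(f"{path}: non-numeric {col} in row {bad}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise AnnotationError(f"{path}: negative {col} in row {bad}")
        df[col] = vals.astype(float)
    df["gene_id"] = df["gene_id"].fillna(UNASSIGNED)
    if annotation is not None:
        known = df["gene_id"].isin(set(annotation.gene_ids))
        df.loc[~known, "gene_id"] = UNASSIGNED
    return df[PROBE_COLUMNS].copy()


def write_probe_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PROBE_COLUMNS)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str,
    chrom_lengths: dict[str, int],
    label: str = "",
    normalized: bool = False,
) -> CoverageTrack:
    """Read a bedGraph (0-based half-open) into per-base vectors.

    Unspecified bases are 0.  Overlapping intervals with conflicting values
    are an error; the value ``nan`` in column 4 marks masked bases.
    """
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    written = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise AnnotationError(f"{path}:{lineno}: fewer than 4 columns")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > len(values[chrom]) or start >= end:
                raise AnnotationError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside chromosome"
                )
            seg = values[chrom][start:end]
            hit = written[chrom][start:end]
            if hit.any():
                prev = seg[hit]
                same = np.isclose(prev, val) | (np.isnan(prev) & np.isnan(val))
                if not same.all():
                    raise AnnotationError(
                        f"{path}:{lineno}: overlapping intervals with conflicting values"
                    )
            values[chrom][start:end] = val
            written[chrom][start:end] = True
    return CoverageTrack(values, label=label, normalized=normalized)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a CoverageTrack as bedGraph with run-length merged intervals.

    Masked (NaN) bases are written with the literal value ``nan`` so that
    a read/write round trip is exact.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if len(v) == 0:
                continue
            # run-length encode, treating NaN as equal to NaN
            change = np.empty(len(v), dtype=bool)
            change[0] = True
            a, b = v[1:], v[:-1]
            change[1:] = ~((a == b) | (np.isnan(a) & np.isnan(b)))
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], len(v))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0.0 and not np.isnan(val):
                    continue  # unspecified bases default to 0 on read
                fh.write(f"{chrom}\t{s}\t{e}\t{float(val)!r}\n")
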