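"""Strand-aware promoter windows and cis-element annotation.

Builds fixed-size windows around transcription start sites (TSS), reads the
standard genomic track formats (BED6 TSS tables, BED / RepeatMasker ``.out``
repeat tracks, BED / narrowPeak ChIP tracks) and assigns Alu repeats and IRF
binding evidence to promoters in TSS-relative coordinates.

Coordinate conventions
----------------------
All intervals are 0-based half-open internally (BED convention).
RepeatMasker ``.out`` files use 1-based inclusive coordinates and are
converted on read.  TSS-relative coordinates are signed in the transcription
direction: negative upstream of the TSS, the TSS itself at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORY_BOTH = "both"
CATEGORY_IRF_ONLY = "irf_only"
CATEGORY_ALU_ONLY = "alu_only"
CATEGORY_NONE = "none"
CATEGORIES = (CATEGORY_BOTH, CATEGORY_IRF_ONLY, CATEGORY_ALU_ONLY, CATEGORY_NONE)


class ParseError(ValueError):
    """Malformed record in a genomic track file."""


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS: id, chromosome, strand and 0-based position."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an element-class label."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    label: str = ""
    metadata: tuple = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )


@dataclass
class PromoterAnnotation:
    """A promoter window with its Alu/IRF elements in TSS-relative coordinates."""

    gene_id: str
    window: GenomicInterval
    alu_elements: list[tuple[int, int]] = field(default_factory=list)
    irf_elements: list[tuple[int, int]] = field(default_factory=list)

    @property
    def category(self) -> str:
        has_alu = bool(self.alu_elements)
        has_irf = bool(self.irf_elements)
        if has_alu and has_irf:
            return CATEGORY_BOTH
        if has_irf:
            return CATEGORY_IRF_ONLY
        if has_alu:
            return CATEGORY_ALU_ONLY
        return CATEGORY_NONE


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_tss_table(path, dialect: str = "bed6") -> list[GeneModel]:
    """Read gene models from a BED6 or refFlat-like table.

    BED6: TSS = start for + strand genes, end - 1 for - strand genes.
    refFlat-like TSV: columns gene_id, chrom, strand, txStart, txEnd
    (TSS chosen by strand the same way).

    The first row seen for each gene id wins, mirroring "first isoform
    listed" promoter retrieval; the number of dropped duplicates is logged.
    """
    if dialect not in ("bed6", "refflat"):
        raise ValueError(f"unknown TSS table dialect {dialect!r}")
    models: dict[str, GeneModel] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed6":
                    chrom, start, end, name, _score, strand = fields[:6]
                else:
                    name, chrom, strand, start, end = fields[:5]
                start_i, end_i = int(start), int(end)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            tss = start_i if strand == "+" else end_i - 1
            if name in models:
                dropped += 1
                continue
            models[name] = GeneModel(gene_id=name, chrom=chrom, strand=strand, tss=tss)
    if dropped:
        logger.info("read_tss_table: dropped %d duplicate gene_id rows", dropped)
    return list(models.values())


def read_repeat_track(
    path,
    dialect: str = "bed",
    families: str | Sequence[str] = "Alu",
) -> list[GenomicInterval]:
    """Read a repeat annotation track, keeping repeats whose name matches.

    ``families`` is a prefix (or list of prefixes) matched against the repeat
    name; the default keeps the Alu/SINE families ("AluY", "AluJb", ...).
    RepeatMasker ``.out`` rows are 1-based inclusive and converted to 0-based
    half-open on read.
    """
    if dialect not in ("bed", "repeatmasker_out"):
        raise ValueError(f"unknown repeat track dialect {dialect!r}")
    prefixes = (families,) if isinstance(families, str) else tuple(families)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if dialect == "bed":
                if stripped.startswith(("#", "track", "browser")):
                    continue
                fields = stripped.split("\t") if "\t" in stripped else stripped.split()
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed BED line") from exc
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            else:
                fields = stripped.split()
                # RepeatMasker .out: two header lines + blank; first data field
                # is the Smith-Waterman score (an integer).
                if not fields[0].lstrip("-").isdigit():
                    continue
                try:
                    chrom = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> half-open
                    end = int(fields[6])
                    strand = "-" if fields[8] == "C" else "+"
                    name = fields[9]
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed RepeatMasker record"
                    ) from exc
            if not any(name.startswith(p) for p in prefixes):
                continue
            out.append(
                GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, label=name)
            )
    return out


def read_peaks(path, dialect: str = "narrowpeak") -> list[GenomicInterval]:
    """Read ChIP peaks from BED or narrowPeak; extra columns kept as metadata."""
    if dialect not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed peak record") from exc
            extra = tuple(fields[3:])
            out.append(
                GenomicInterval(
                    chrom=chrom, start=start, end=end, label="irf_evidence", metadata=extra
                )
            )
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_promoter_window(
    gene: GeneModel, up: int, down: int, chrom_len: int | None = None
) -> GenomicInterval:
    """Strand-aware promoter window covering TSS-relative [-up, +down).

    + strand: [tss - up, tss + down); - strand: [tss - down + 1, tss + up + 1),
    clipped to the chromosome when ``chrom_len`` is given.
    """
    if up < 0 or down < 0 or up + down <= 0:
        raise ValueError("window extents must be non-negative with up + down > 0")
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down + 1, gene.tss + up + 1
    start = max(start, 0)
    if chrom_len is not None:
        end = min(end, chrom_len)
    if start >= end:
        raise ValueError(
            f"promoter window of {gene.gene_id} lies entirely outside the chromosome"
        )
    return GenomicInterval(chrom=gene.chrom, start=start, end=end, strand=gene.strand)


def to_tss_relative(interval: GenomicInterval, gene: GeneModel) -> tuple[int, int]:
    """Map a genomic interval to signed TSS-relative coordinates.

    Positions map to ``p - tss`` on the + strand and ``tss - p`` on the -
    strand; the result is normalised half-open with start < end, negative
    meaning upstream in the transcription direction.
    """
    if interval.chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: interval on {interval.chrom}, gene on {gene.chrom}"
        )
    if gene.strand == "+":
        return interval.start - gene.tss, interval.end - gene.tss
    return gene.tss - interval.end + 1, gene.tss - interval.start + 1


def from_tss_relative(rel: tuple[int, int], gene: GeneModel) -> GenomicInterval:
    """Inverse of :func:`to_tss_relative`."""
    a, b = rel
    if a >= b:
        raise ValueError("relative interval must have start < end")
    if gene.strand == "+":
        start, end = gene.tss + a, gene.tss + b
    else:
        start, end = gene.tss - b + 1, gene.tss - a + 1
    return GenomicInterval(chrom=gene.chrom, start=start, end=end, strand=gene.strand)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _index_track(track: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_promoter(
    gene: GeneModel,
    window: GenomicInterval,
    alu_track: Iterable[GenomicInterval] | dict[str, IntervalTree],
    irf_track: Iterable[GenomicInterval] | dict[str, IntervalTree],
) -> PromoterAnnotation:
    """Assign Alu and IRF elements overlapping the window (>= 1 bp) to the gene.

    Elements are stored TSS-relative; the promoter category follows from
    which element classes are present.
    """
    alu_idx = alu_track if isinstance(alu_track, dict) else _index_track(alu_track)
    irf_idx = irf_track if isinstance(irf_track, dict) else _index_track(irf_track)
    ann = PromoterAnnotation(gene_id=gene.gene_id, window=window)
    for idx, store in ((alu_idx, ann.alu_elements), (irf_idx, ann.irf_elements)):
        tree = idx.get(gene.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(window.start, window.end), key=lambda h: (h.begin, h.end))
        for hit in hits:
            store.append(to_tss_relative(hit.data, gene))
    return ann


def annotate_promoters(
    genes: Sequence[GeneModel],
    alu_track: Iterable[GenomicInterval],
    irf_track: Iterable[GenomicInterval],
    up: int = 2500,
    down: int = 500,
    chrom_lens: dict[str, int] | None = None,
) -> dict[str, PromoterAnnotation]:
    """Annotate every gene's promoter window against both element tracks."""
    alu_idx = _index_track(alu_track)
    irf_idx = _index_track(irf_track)
    out: dict[str, PromoterAnnotation] = {}
    for gene in genes:
        clen = chrom_lens.get(gene.chrom) if chrom_lens else None
        window = make_promoter_window(gene, up=up, down=down, chrom_len=clen)
        out[gene.gene_id] = annotate_promoter(gene, window, alu_idx, irf_idx)
    return out


def write_annotations_tsv(annotations: dict[str, PromoterAnnotation], path) -> None:
    """Dump annotations as TSV: one row per element plus one per empty promoter."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\telement\trel_start\trel_end\n")
        for gid, ann in annotations.items():
            rows = [("alu", iv) for iv in ann.alu_elements]
            rows += [("irf", iv) for iv in ann.irf_elements]
            if not rows:
                fh.write(f"{gid}\t{ann.category}\t.\t.\t.\n")
            for label, (a, b) in rows:
                fh.write(f"{gid}\t{ann.category}\t{label}\t{a}\t{b}\n")


def read_annotations_tsv(path) -> dict[str, PromoterAnnotation]:
    """Read the TSV written by :func:`write_annotations_tsv`.

    The genomic window is not stored in the TSV; a placeholder window is
    attached (TSS-relative element lists carry all information downstream
    statistics need).
    """
    out: dict[str, PromoterAnnotation] = {}
    placeholder = GenomicInterval(chrom=".", start=0, end=1)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ParseError(f"{path}: missing annotation header")
        for line in fh:
            gid, _category, label, a, b = line.rstrip("\n").split("\t")
            ann = out.setdefault(gid, PromoterAnnotation(gene_id=gid, window=placeholder))
            if label == ".":
                continue
            store = ann.alu_elements if label == "alu" else ann.irf_elements
            store.append((int(a), int(b)))
    return out
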