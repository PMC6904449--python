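"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Internal convention is 0-based half-open throughout.  BED-family inputs
are already 0-based; RepeatMasker ``.out``-style 1-based starts are
converted here and nowhere else.

TE BED dialect (tab-delimited, BED6+4):
    chrom  start  end  id  score  strand  subfamily  family  class  milliDiv
where ``milliDiv`` is the RepeatMasker substitution rate in mismatches
per thousand bases, converted to a proportion on read (pass
``substitution_units="proportion"`` when the column already holds a
proportion).  An optional 11th column carries a precomputed mappability
score in [0, 1].
"""

from __future__ import annotations

import collections
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CLASS_RELABEL,
    CoverageTrack,
    EpigenomeMetadata,
    GenomeAssembly,
    GenomicInterval,
    MethylationTrack,
    PeakSet,
    Segmentation,
    TEAnnotation,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed record in an input file; message names file and line."""


def _fields(path, min_cols):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(parts)}"
                )
            yield lineno, parts


def _coord(path, lineno, text: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed coordinate {text!r}") from None
    if value < 0:
        raise ParseError(f"{path}:{lineno}: negative coordinate {value}")
    return value


def read_chrom_sizes(path, name: str = "assembly",
                     allowed_chromosomes: set[str] | None = None) -> GenomeAssembly:
    """Read a 2-column ``chrom.sizes`` file into a GenomeAssembly."""
    chroms = []
    for lineno, parts in _fields(path, 2):
        chroms.append((parts[0], _coord(path, lineno, parts[1])))
    return GenomeAssembly(name=name, chromosomes=chroms,
                          allowed_chromosomes=allowed_chromosomes)


def read_gaps_bed(path, assembly: GenomeAssembly) -> list[GenomicInterval]:
    gaps = []
    for lineno, parts in _fields(path, 3):
        chrom = parts[0]
        if chrom not in dict(assembly.chromosomes):
            continue
        gaps.append(GenomicInterval(chrom, _coord(path, lineno, parts[1]),
                                    _coord(path, lineno, parts[2])))
    return gaps


def read_te_bed(path, assembly: GenomeAssembly,
                one_based_starts: bool = False,
                substitution_units: str = "milliDiv") -> list[TEAnnotation]:
    """Read TE annotations from the BED6+4 dialect described above.

    Records on chromosomes outside ``assembly.allowed_chromosomes`` are
    dropped.  RepeatMasker classes are relabelled: Other -> SVA;
    Unknown/Unknown?/DNA?/LINE?/SINE?/LTR?/RC/RC? -> Other.  Any class
    outside the declared relabelling raises a record-level error with a
    per-class count summary.  ``substitution_units`` declares whether
    column 10 is a RepeatMasker milliDiv (divided by 1000 on read) or an
    already-converted proportion.
    """
    if substitution_units not in ("milliDiv", "proportion"):
        raise ValueError(f"unknown substitution units {substitution_units!r}")
    tes: list[TEAnnotation] = []
    unknown_classes: collections.Counter[str] = collections.Counter()
    seen_ids: set[str] = set()
    for lineno, parts in _fields(path, 10):
        chrom = parts[0]
        start = _coord(path, lineno, parts[1])
        end = _coord(path, lineno, parts[2])
        if one_based_starts:
            start -= 1
        if chrom not in assembly.allowed_chromosomes:
            continue
        raw_class = parts[8]
        if raw_class not in CLASS_RELABEL:
            unknown_classes[raw_class] += 1
            continue
        value = float(parts[9])
        sub_prop = value / 1000.0 if substitution_units == "milliDiv" else value
        mappability = float(parts[10]) if len(parts) > 10 else 1.0
        te_id = parts[3]
        if te_id in seen_ids:
            raise ParseError(f"{path}:{lineno}: duplicate TE id {te_id!r}")
        seen_ids.add(te_id)
        tes.append(TEAnnotation(
            interval=GenomicInterval(chrom, start, end, parts[5] if parts[5] in "+-" else "."),
            subfamily=parts[6], family=parts[7],
            te_class=CLASS_RELABEL[raw_class],
            substitution_proportion=sub_prop,
            mappability=mappability, id=te_id,
        ))
    if unknown_classes:
        summary = ", ".join(f"{c}: {n}" for c, n in sorted(unknown_classes.items()))
        raise ValidationError(f"{path}: records with unknown TE class ({summary})")
    return tes


def write_te_bed(path, tes: Sequence[TEAnnotation]) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write("\t".join(map(str, (
                iv.chrom, iv.start, iv.end, te.id, 0, iv.strand,
                te.subfamily, te.family,
                _unrelabel(te.te_class),
                f"{te.substitution_proportion * 1000:.6g}",
                f"{te.mappability:.6g}",
            ))) + "\n")


def _unrelabel(te_class: str) -> str:
    # inverse of the class relabelling for round-trip serialization
    return {"SVA": "Other", "Other": "Unknown"}.get(te_class, te_class)


def read_segmentation(path, assembly: GenomeAssembly, state_alphabet: Sequence[str],
                      epigenome_id: str, window_bp: int | None = 200) -> Segmentation:
    """Read a 4-column mnemonics BED (chrom, start, end, state).

    Blocks are sorted and validated: overlapping blocks are rejected and,
    unless ``window_bp`` is None (free-form mode), every block width must
    be a positive multiple of ``window_bp``.
    """
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    alphabet = set(state_alphabet)
    novel: set[str] = set()
    for lineno, parts in _fields(path, 4):
        chrom = parts[0]
        if chrom not in assembly.allowed_chromosomes:
            continue
        start = _coord(path, lineno, parts[1])
        end = _coord(path, lineno, parts[2])
        if end <= start:
            raise ParseError(f"{path}:{lineno}: empty block")
        if parts[3] not in alphabet:
            novel.add(parts[3])
            continue
        per_chrom.setdefault(chrom, []).append((start, end, parts[3]))
    if novel:
        raise ValidationError(f"{path}: states not in alphabet: {sorted(novel)}")
    blocks = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{path}: overlapping blocks on {chrom}")
        # merge into contiguous bounds; gaps between blocks split runs
        bounds: list[int] = []
        states: list[str] = []
        runs: list[tuple[np.ndarray, np.ndarray]] = []
        for (s, e, st) in rows:
            if bounds and s != bounds[-1]:
                runs.append((np.array(bounds), np.array(states)))
                bounds, states = [], []
            if not bounds:
                bounds.append(s)
            bounds.append(e)
            states.append(st)
        runs.append((np.array(bounds), np.array(states)))
        if len(runs) > 1:
            # non-contiguous coverage: stitch runs, inserting no blocks
            # (the Segmentation stores one contiguous range; re-tile by
            # concatenating with explicit uncovered handling is out of
            # scope, so require contiguity)
            raise ValidationError(
                f"{path}: segmentation on {chrom} is not contiguous"
            )
        blocks[chrom] = runs[0]
    return Segmentation(epigenome_id, tuple(state_alphabet), blocks, window_bp=window_bp)


def write_segmentation(path, seg: Segmentation) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, state in seg.iter_blocks():
            fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


def read_narrowpeak(path, assembly: GenomeAssembly, epigenome_id: str, assay: str,
                    strict: bool = True) -> PeakSet:
    """Read an ENCODE narrowPeak file (10 columns, summit offset in col 10).

    A summit of -1 is an error in strict mode; in lenient mode it falls
    back to the peak midpoint.  Summit offsets outside the peak are
    always an error.
    """
    peaks = []
    for lineno, parts in _fields(path, 10):
        chrom = parts[0]
        if chrom not in assembly.allowed_chromosomes:
            continue
        start = _coord(path, lineno, parts[1])
        end = _coord(path, lineno, parts[2])
        summit = int(parts[9])
        width = end - start
        if summit == -1:
            if strict:
                raise ParseError(f"{path}:{lineno}: summit is -1 (strict mode)")
            summit = width // 2
        if not (0 <= summit < width):
            raise ParseError(f"{path}:{lineno}: summit {summit} outside peak")
        peaks.append((GenomicInterval(chrom, start, end), summit))
    return PeakSet(epigenome_id=epigenome_id, assay=assay, peaks=peaks)


def write_narrowpeak(path, peakset: PeakSet) -> None:
    with open(path, "w") as fh:
        for i, (iv, summit) in enumerate(peakset.peaks):
            fh.write("\t".join(map(str, (
                iv.chrom, iv.start, iv.end, f"peak{i}", 0, ".",
                0.0, -1.0, -1.0, summit,
            ))) + "\n")


def read_methylation(path, epigenome_id: str) -> MethylationTrack:
    """Read a per-CpG table: chrom, position of the C, fraction, read count."""
    per_chrom: dict[str, list[tuple[int, float, int]]] = {}
    for lineno, parts in _fields(path, 4):
        pos = _coord(path, lineno, parts[1])
        per_chrom.setdefault(parts[0], []).append(
            (pos, float(parts[2]), int(parts[3]))
        )
    cpgs = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        cpgs[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=float),
            np.array([r[2] for r in rows], dtype=np.int64),
        )
    return MethylationTrack(epigenome_id, cpgs)


def write_methylation(path, track: MethylationTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            pos, frac, cov = track.cpgs[chrom]
            for p, f, c in zip(pos, frac, cov):
                fh.write(f"{chrom}\t{p}\t{f:.6g}\t{c}\n")


def read_coverage_bedgraph(path, epigenome_id: str,
                           normalization_factor: float = 1.0) -> CoverageTrack:
    """Read a bedGraph-dialect run-length coverage file."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, parts in _fields(path, 4):
        per_chrom.setdefault(parts[0], []).append(
            (_coord(path, lineno, parts[1]), _coord(path, lineno, parts[2]),
             float(parts[3]))
        )
    runs = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        bounds = [rows[0][0]]
        values = []
        for s, e, v in rows:
            if s != bounds[-1]:
                # fill the gap with explicit zero signal
                bounds.append(s)
                values.append(0.0)
            bounds.append(e)
            values.append(v)
        runs[chrom] = (np.array(bounds, dtype=np.int64), np.array(values))
    return CoverageTrack(epigenome_id, runs, normalization_factor)


def write_coverage_bedgraph(path, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            bounds, values = track.runs[chrom]
            for i, v in enumerate(values):
                if v != 0.0:
                    fh.write(f"{chrom}\t{bounds[i]}\t{bounds[i + 1]}\t{v:.6g}\n")


METADATA_COLUMNS = ["epigenome_id", "group", "anatomy", "type",
                    "age_category", "germ_layer", "cancer"]


def read_metadata(path) -> dict[str, EpigenomeMetadata]:
    """Read the tab-delimited epigenome metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.epigenome_id] = EpigenomeMetadata(
            epigenome_id=row.epigenome_id, group=row.group, anatomy=row.anatomy,
            type=row.type, age_category=row.age_category,
            germ_layer=row.germ_layer,
            cancer=str(row.cancer).lower() in ("yes", "true", "1"),
        )
    return out


def write_metadata(path, metadata: dict[str, EpigenomeMetadata]) -> None:
    rows = []
    for eid in sorted(metadata):
        m = metadata[eid]
        rows.append([m.epigenome_id, m.group, m.anatomy, m.type,
                     m.age_category, m.germ_layer, "yes" if m.cancer else "no"])
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_features_bed(path, assembly: GenomeAssembly) -> list[GenomicInterval]:
    """Read a generic BED of feature intervals (CpG islands, exons, ...)."""
    out = []
    for lineno, parts in _fields(path, 3):
        chrom = parts[0]
        if chrom not in assembly.allowed_chromosomes:
            continue
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        out.append(GenomicInterval(chrom, _coord(path, lineno, parts[1]),
                                   _coord(path, lineno, parts[2]), strand))
    return out


def build_promoters(tss_records: Iterable[tuple[str, int, str]],
                    assembly: GenomeAssembly,
                    upstream: int = 2000, downstream: int = 500) -> list[GenomicInterval]:
    """Strand-aware promoter windows around transcription start sites.

    On '+' the promoter is [TSS - upstream, TSS + downstream); on '-' it
    is mirrored, [TSS - downstream, TSS + upstream).  Windows are clipped
    to chromosome bounds and collapsed by coordinate and strand so each
    unique promoter is counted once.  The collapse is idempotent.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[GenomicInterval] = []
    for chrom, tss, strand in tss_records:
        if strand not in ("+", "-"):
            raise ValidationError(f"TSS at {chrom}:{tss} lacks a strand")
        size = assembly.size(chrom)
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start, end = max(0, start), min(size, end)
        key = (chrom, start, end, strand)
        if key not in seen and end > start:
            seen.add(key)
            out.append(GenomicInterval(chrom, start, end, strand))
    return out
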