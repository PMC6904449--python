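"""Core domain types shared across the pipeline.

All coordinates are 0-based half-open (BED convention).  Readers for
1-based external dialects convert at the boundary; nothing downstream
ever sees a 1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# The 15 consolidated Roadmap chromHMM mnemonics, in model order.  Any
# other state alphabet may be supplied; nothing in the pipeline is
# specific to this one.
ROADMAP_15_STATES = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

# Composite state definitions used throughout the analyses.
ACTIVE_REGULATORY_STATES = ("1_TssA", "2_TssAFlnk", "3_TxFlnk", "6_EnhG", "7_Enh")
TRANSCRIBED_STATES = ("4_Tx", "5_TxWk")
REPRESSED_STATES = ("9_Het", "13_ReprPC", "14_ReprPCWk")

TE_CLASSES = ("DNA", "LINE", "LTR", "SINE", "SVA", "Other")

# RepeatMasker class relabelling: the hg19 "Other" class contains only
# SVA subfamilies and is renamed; degraded/uncertain classes are pooled.
CLASS_RELABEL = {
    "DNA": "DNA", "LINE": "LINE", "SINE": "SINE", "LTR": "LTR",
    "Other": "SVA",
    "Unknown": "Other", "Unknown?": "Other", "DNA?": "Other",
    "LINE?": "Other", "SINE?": "Other", "LTR?": "Other",
    "RC": "Other", "RC?": "Other",
}

METHYLATION_STATES = ("hypo", "intermediate", "hyper", "missing")

# Methylation-state bin edges on mean fractional methylation:
# hypo < 0.30, 0.30 <= intermediate <= 0.70, hyper > 0.70.
HYPO_UPPER = 0.30
HYPER_LOWER = 0.70

# CpGs covered by <= this many reads are missing values.
MIN_CPG_READS = 3

# Subfamily enrichment thresholds: LOR cutoff, minimum members overall,
# minimum members in the state in the epigenome.
LOR_ENRICHED = 1.5
MIN_SUBFAMILY_MEMBERS = 30
MIN_MEMBERS_IN_STATE = 10
LOR_PSEUDOCOUNT = 1e-20

RPKM_EXPRESSED = 1.0


class ValidationError(ValueError):
    """Raised when an input file or object violates a declared invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return self.start + self.width // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeAssembly:
    """Chromosome names/lengths plus unplaceable (gap) regions.

    ``allowed_chromosomes`` restricts every analysis: records on other
    sequences (alternative contigs, chrM when excluded) are dropped at
    the reader boundary.
    """

    name: str
    chromosomes: list[tuple[str, int]]
    gaps: list[GenomicInterval] = field(default_factory=list)
    allowed_chromosomes: set[str] | None = None

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome names")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length}")
        for gap in self.gaps:
            if gap.chrom not in sizes or gap.end > sizes[gap.chrom]:
                raise ValidationError(f"gap {gap} outside declared chromosomes")
        if self.allowed_chromosomes is None:
            self.allowed_chromosomes = set(sizes)
        elif not self.allowed_chromosomes <= set(sizes):
            raise ValidationError("allowed_chromosomes not a subset of declared")
        self._sizes = sizes

    def size(self, chrom: str) -> int:
        return self._sizes[chrom]

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def total_length(self, allowed_only: bool = True) -> int:
        return sum(
            n for c, n in self.chromosomes
            if not allowed_only or c in self.allowed_chromosomes
        )

    def gap_intervals(self, chrom: str) -> list[tuple[int, int]]:
        return sorted(
            (g.start, g.end) for g in self.gaps if g.chrom == chrom
        )


def jukes_cantor(p: float | np.ndarray) -> float | np.ndarray:
    """Jukes-Cantor (JC69) evolutionary distance from a substitution proportion.

    d = -(3/4) * ln(1 - (4/3) p), defined for 0 <= p < 0.75.  Used as a
    TE age proxy: the substitution proportion is measured against the
    subfamily consensus, so older copies have larger d.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 0.75):
        raise ValueError("substitution proportion must lie in [0, 0.75)")
    d = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker-annotated repeat copy."""

    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str
    substitution_proportion: float
    mappability: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValidationError(f"unknown TE class {self.te_class!r}")
        if not (0 <= self.substitution_proportion < 0.75):
            raise ValidationError(
                f"substitution proportion {self.substitution_proportion} "
                "outside [0, 0.75)"
            )
        if not (0 <= self.mappability <= 1):
            raise ValidationError("mappability outside [0, 1]")

    @property
    def jc_distance(self) -> float:
        return jukes_cantor(self.substitution_proportion)


class Segmentation:
    """A per-epigenome chromatin-state tiling.

    Blocks per chromosome are stored as (boundaries, state codes): for a
    chromosome with n blocks, ``bounds`` has n+1 entries and ``states``
    has n.  Blocks tile the covered range without overlap.  When
    ``window_bp`` is set, every block width must be a positive multiple
    of it; a free-form segmentation (``window_bp=None``) has no width
    constraint and is annotated by >= 1 bp overlap downstream.
    """

    def __init__(
        self,
        epigenome_id: str,
        state_alphabet: Sequence[str],
        blocks: dict[str, tuple[np.ndarray, np.ndarray]],
        window_bp: int | None = 200,
    ):
        self.epigenome_id = epigenome_id
        self.state_alphabet = tuple(state_alphabet)
        self.state_index = {s: i for i, s in enumerate(self.state_alphabet)}
        self.window_bp = window_bp
        self.blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bounds, states) in blocks.items():
            bounds = np.asarray(bounds, dtype=np.int64)
            states = np.asarray(states)
            if states.dtype.kind in "UO":
                unknown = set(states) - set(self.state_alphabet)
                if unknown:
                    raise ValidationError(
                        f"states not in alphabet: {sorted(unknown)}"
                    )
                states = np.array(
                    [self.state_index[s] for s in states], dtype=np.int16
                )
            else:
                states = states.astype(np.int16)
            if len(bounds) != len(states) + 1:
                raise ValidationError(f"{chrom}: bounds/states length mismatch")
            widths = np.diff(bounds)
            if np.any(widths <= 0):
                raise ValidationError(f"{chrom}: blocks not sorted/positive")
            if window_bp is not None and np.any(widths % window_bp != 0):
                raise ValidationError(
                    f"{chrom}: block width not a multiple of {window_bp} "
                    "(use window_bp=None for free-form segmentations)"
                )
            self.blocks[chrom] = (bounds, states)

    @property
    def free_form(self) -> bool:
        return self.window_bp is None

    def covers(self, chrom: str) -> bool:
        return chrom in self.blocks

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.blocks)

    def state_at(self, chrom: str, pos: int) -> int:
        """State code at a single base, or -1 outside covered range."""
        bounds, states = self.blocks[chrom]
        if pos < bounds[0] or pos >= bounds[-1]:
            return -1
        i = int(np.searchsorted(bounds, pos, side="right")) - 1
        return int(states[i])

    def state_bp(self, chrom: str | None = None) -> np.ndarray:
        """Total bases per state (over one chromosome or all covered)."""
        out = np.zeros(len(self.state_alphabet), dtype=np.int64)
        chroms = [chrom] if chrom is not None else list(self.blocks)
        for c in chroms:
            bounds, states = self.blocks[c]
            np.add.at(out, states, np.diff(bounds))
        return out

    def iter_blocks(self) -> Iterable[tuple[str, int, int, str]]:
        for chrom in sorted(self.blocks):
            bounds, states = self.blocks[chrom]
            for i in range(len(states)):
                yield chrom, int(bounds[i]), int(bounds[i + 1]), self.state_alphabet[states[i]]


@dataclass
class PeakSet:
    """narrowPeak-style peaks with single-base summits for one epigenome."""

    epigenome_id: str
    assay: str
    peaks: list[tuple[GenomicInterval, int]]  # (interval, summit offset from start)

    def __post_init__(self) -> None:
        if self.assay not in ("DHS", "H3K27ac"):
            raise ValidationError(f"unknown assay {self.assay!r}")
        for iv, off in self.peaks:
            if not (0 <= off < iv.width):
                raise ValidationError(
                    f"summit offset {off} outside peak {iv.chrom}:{iv.start}-{iv.end}"
                )

    def summit_positions(self) -> dict[str, np.ndarray]:
        """Sorted summit positions per chromosome (duplicates kept)."""
        out: dict[str, list[int]] = {}
        for iv, off in self.peaks:
            out.setdefault(iv.chrom, []).append(iv.start + off)
        return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


class MethylationTrack:
    """Per-CpG fractional methylation with read coverage for one epigenome.

    Positions are the C of the CpG on the forward strand (the two
    cytosines of a CpG are assumed merged upstream).  A CpG occupies
    two bases, [pos, pos+2).
    """

    def __init__(self, epigenome_id: str, cpgs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.epigenome_id = epigenome_id
        self.cpgs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (pos, frac, cov) in cpgs.items():
            pos = np.asarray(pos, dtype=np.int64)
            frac = np.asarray(frac, dtype=float)
            cov = np.asarray(cov, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"{chrom}: CpG positions not strictly increasing")
            covered = cov > 0
            if np.any((frac[covered] < 0) | (frac[covered] > 1)):
                raise ValidationError(f"{chrom}: methylated fraction outside [0, 1]")
            self.cpgs[chrom] = (pos, frac, cov)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.cpgs)

    def n_cpgs(self) -> int:
        return sum(len(p) for p, _, _ in self.cpgs.values())


class CoverageTrack:
    """Run-length encoded nonnegative signal for one epigenome.

    ``runs[chrom] = (bounds, values)``: value[i] applies on
    [bounds[i], bounds[i+1]).  Uncovered bases count as 0 signal.
    """

    def __init__(
        self,
        epigenome_id: str,
        runs: dict[str, tuple[np.ndarray, np.ndarray]],
        normalization_factor: float = 1.0,
    ):
        if normalization_factor <= 0:
            raise ValidationError("normalization factor must be positive")
        self.epigenome_id = epigenome_id
        self.normalization_factor = float(normalization_factor)
        self.runs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bounds, values) in runs.items():
            bounds = np.asarray(bounds, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if len(bounds) != len(values) + 1 or np.any(np.diff(bounds) <= 0):
                raise ValidationError(f"{chrom}: malformed coverage runs")
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative signal")
            self.runs[chrom] = (bounds, values)

    def covers(self, chrom: str) -> bool:
        return chrom in self.runs

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean raw signal over [start, end); 0 off-track."""
        if chrom not in self.runs:
            return 0.0
        bounds, values = self.runs[chrom]
        lo = np.searchsorted(bounds, start, side="right") - 1
        hi = np.searchsorted(bounds, end, side="left")
        total = 0.0
        for i in range(max(lo, 0), min(hi, len(values))):
            a = max(start, int(bounds[i]))
            b = min(end, int(bounds[i + 1]))
            if b > a:
                total += values[i] * (b - a)
        return total / (end - start)


@dataclass
class EpigenomeMetadata:
    """Categorical labels for one epigenome, used by permutation tests."""

    epigenome_id: str
    group: str = "unknown"
    anatomy: str = "unknown"
    type: str = "unknown"
    age_category: str = "unknown"   # fetal / adult / cell line / unknown
    germ_layer: str = "other"       # endoderm/ectoderm/mesoderm/mixed/pluripotent/other
    cancer: bool = False

    CATEGORY_SCHEMES = ("group", "anatomy", "type", "age_category", "germ_layer", "cancer")

    def label(self, scheme: str) -> str:
        if scheme not in self.CATEGORY_SCHEMES:
            raise KeyError(f"unknown category scheme {scheme!r}")
        value = getattr(self, scheme)
        return {True: "yes", False: "no"}.get(value, value)
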