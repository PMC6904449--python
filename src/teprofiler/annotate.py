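"""Per-TE epigenetic state annotation across epigenomes.

Annotation conventions:

* chromHMM, ``window_center`` (default): a TE is annotated with every
  state whose 200 bp window center falls inside the TE; a TE containing
  no window center is assigned the single state with the largest bp
  overlap, so every TE on a covered chromosome gets >= 1 state.
* ``window_center_strict``: as above without the largest-overlap
  fallback (the state set may be empty).
* ``block_center``: states of whole segmentation blocks whose centers
  fall inside the TE (no fallback; may be empty).
* ``any_overlap``: every state overlapping the TE by >= 1 bp.  Free-form
  segmentations (no fixed window) are always annotated this way.
* methylation: mean fraction over CpGs overlapping the TE with more than
  3 reads; hypo < 0.30 <= intermediate <= 0.70 < hyper; ``missing`` when
  CpGs overlap but none are adequately covered; ``no_cpg`` otherwise.
* peaks: count of distinct DHS / H3K27ac summit positions inside the TE.
* expression: length-weighted mean coverage times the track's
  normalization factor.

Strand is ignored in all intersections.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .core import (
    HYPER_LOWER,
    HYPO_UPPER,
    MIN_CPG_READS,
    CoverageTrack,
    MethylationTrack,
    PeakSet,
    Segmentation,
    TEAnnotation,
    ValidationError,
)

ANNOTATION_MODES = ("window_center", "block_center", "window_center_strict", "any_overlap")

# methylation state codes in StateCallMatrix arrays
METH_HYPO, METH_INTER, METH_HYPER, METH_MISSING, METH_NO_CPG, METH_ABSENT = 0, 1, 2, 3, 4, -1
METH_STATE_NAMES = {METH_HYPO: "hypo", METH_INTER: "intermediate",
                    METH_HYPER: "hyper", METH_MISSING: "missing",
                    METH_NO_CPG: "no_cpg", METH_ABSENT: "absent"}


def _overlap_block_range(bounds: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Indices [lo, hi) of blocks overlapping [start, end) by >= 1 bp."""
    lo = int(np.searchsorted(bounds, start, side="right")) - 1
    hi = int(np.searchsorted(bounds, end, side="left"))
    return max(lo, 0), min(hi, len(bounds) - 1)


def _largest_overlap_state(bounds: np.ndarray, states: np.ndarray,
                           start: int, end: int) -> int | None:
    """State code with maximal bp overlap; ties broken by state-alphabet order."""
    lo, hi = _overlap_block_range(bounds, start, end)
    if lo >= hi:
        return None
    best_state, best_bp = None, 0
    per_state: dict[int, int] = {}
    for i in range(lo, hi):
        a = max(start, int(bounds[i]))
        b = min(end, int(bounds[i + 1]))
        if b > a:
            code = int(states[i])
            per_state[code] = per_state.get(code, 0) + (b - a)
    for code in sorted(per_state):  # alphabet order breaks ties
        if per_state[code] > best_bp:
            best_state, best_bp = code, per_state[code]
    return best_state


def annotate_chromhmm(te: TEAnnotation, segmentation: Segmentation,
                      mode: str = "window_center") -> frozenset[str] | None:
    """State names assigned to one TE; None when the chromosome is uncovered."""
    codes = _annotate_codes(te.interval.chrom, te.interval.start,
                            te.interval.end, segmentation, mode)
    if codes is None:
        return None
    return frozenset(segmentation.state_alphabet[c] for c in codes)


def _annotate_codes(chrom: str, start: int, end: int,
                    segmentation: Segmentation, mode: str) -> set[int] | None:
    if mode not in ANNOTATION_MODES:
        raise ValueError(f"unknown annotation mode {mode!r}")
    if not segmentation.covers(chrom):
        return None
    bounds, states = segmentation.blocks[chrom]
    if segmentation.free_form or mode == "any_overlap":
        lo, hi = _overlap_block_range(bounds, start, end)
        return set(int(s) for s in states[lo:hi])
    if mode == "block_center":
        lo, hi = _overlap_block_range(bounds, start, end)
        out = set()
        for i in range(lo, hi):
            center = int(bounds[i] + (bounds[i + 1] - bounds[i]) // 2)
            if start <= center < end:
                out.add(int(states[i]))
        return out
    # window_center / window_center_strict: centers of the fixed-width
    # window grid anchored at the covered range start
    w = segmentation.window_bp
    b0 = int(bounds[0])
    cov_end = int(bounds[-1])
    half = w // 2
    # window i covers [b0 + i*w, b0 + (i+1)*w), center b0 + i*w + half
    i0 = math.ceil((max(start, b0) - b0 - half) / w)
    i1 = (min(end, cov_end) - 1 - b0 - half) // w
    out: set[int] = set()
    for i in range(max(i0, 0), i1 + 1):
        center = b0 + i * w + half
        if start <= center < end:
            block = int(np.searchsorted(bounds, center, side="right")) - 1
            out.add(int(states[block]))
    if not out and mode == "window_center":
        fallback = _largest_overlap_state(bounds, states, start, end)
        if fallback is not None:
            out.add(fallback)
    return out


def primary_chromhmm_state(te: TEAnnotation, segmentation: Segmentation,
                           as_code: bool = False) -> str | int | None:
    """The single state with the largest bp overlap with the TE.

    Deterministic (ties broken by state-alphabet order) and defined for
    both windowed and free-form segmentations; None when the TE's
    chromosome is uncovered or nothing overlaps.  Used where one state
    per TE per epigenome is required, e.g. cross-species contingency
    tables.
    """
    iv = te.interval
    if not segmentation.covers(iv.chrom):
        return None
    bounds, states = segmentation.blocks[iv.chrom]
    code = _largest_overlap_state(bounds, states, iv.start, iv.end)
    if code is None or as_code:
        return code
    return segmentation.state_alphabet[code]


def annotate_methylation(te: TEAnnotation,
                         track: MethylationTrack) -> tuple[float | None, str]:
    """Mean methylated fraction over well-covered CpGs in the TE, plus state."""
    mean, code = _methylation_codes(te.interval.chrom, te.interval.start,
                                    te.interval.end, track)
    return mean, METH_STATE_NAMES[code]


def _methylation_codes(chrom: str, start: int, end: int,
                       track: MethylationTrack) -> tuple[float | None, int]:
    if chrom not in track.cpgs:
        return None, METH_NO_CPG
    pos, frac, cov = track.cpgs[chrom]
    # a CpG occupies [p, p+2); it overlaps [start, end) iff p >= start-1 and p < end
    lo = int(np.searchsorted(pos, start - 1, side="left"))
    hi = int(np.searchsorted(pos, end, side="left"))
    if lo >= hi:
        return None, METH_NO_CPG
    good = cov[lo:hi] > MIN_CPG_READS
    if not good.any():
        return None, METH_MISSING
    mean = float(frac[lo:hi][good].mean())
    return mean, _meth_state_code(mean)


def _meth_state_code(mean: float) -> int:
    if mean < HYPO_UPPER:
        return METH_HYPO
    if mean > HYPER_LOWER:
        return METH_HYPER
    return METH_INTER


def annotate_peaks(te: TEAnnotation, peakset: PeakSet,
                   _summits: dict[str, np.ndarray] | None = None) -> int:
    """Number of distinct peak summit positions inside the TE."""
    summits = _summits if _summits is not None else peakset.summit_positions()
    chrom = te.interval.chrom
    if chrom not in summits:
        return 0
    s = summits[chrom]
    lo = int(np.searchsorted(s, te.interval.start, side="left"))
    hi = int(np.searchsorted(s, te.interval.end, side="left"))
    if lo >= hi:
        return 0
    return int(np.unique(s[lo:hi]).size)


def annotate_expression(te: TEAnnotation,
                        track: CoverageTrack) -> float | None:
    """Normalized mean coverage over the TE; None when the chromosome is off-track."""
    chrom = te.interval.chrom
    if not track.covers(chrom):
        return None
    raw = track.mean_over(chrom, te.interval.start, te.interval.end)
    return raw * track.normalization_factor


class StateCallMatrix:
    """TE x epigenome assignment of state sets plus per-technique calls.

    Dense arrays keyed by (TE index, epigenome index):

    * ``membership``: bool (n_te, n_epi, n_states) chromHMM membership
    * ``nocall``: bool (n_te, n_epi), True where the TE's chromosome is
      absent from that epigenome's segmentation
    * ``meth_state``: int8 codes (METH_*); METH_ABSENT without WGBS
    * ``mean_methylation``: float, NaN when undefined
    * ``dhs`` / ``k27ac``: int16 summit counts, -1 without peak data
    * ``expression``: float normalized coverage, NaN without RNA data
    """

    def __init__(self, te_ids: Sequence[str], epigenome_ids: Sequence[str],
                 state_alphabet: Sequence[str]):
        if len(set(te_ids)) != len(te_ids):
            raise ValidationError("duplicated TE ids")
        self.te_ids = list(te_ids)
        self.epigenome_ids = list(epigenome_ids)
        self.state_alphabet = tuple(state_alphabet)
        n_te, n_epi, n_states = len(te_ids), len(epigenome_ids), len(state_alphabet)
        self.membership = np.zeros((n_te, n_epi, n_states), dtype=bool)
        self.nocall = np.zeros((n_te, n_epi), dtype=bool)
        self.meth_state = np.full((n_te, n_epi), METH_ABSENT, dtype=np.int8)
        self.mean_methylation = np.full((n_te, n_epi), np.nan)
        self.dhs = np.full((n_te, n_epi), -1, dtype=np.int16)
        self.k27ac = np.full((n_te, n_epi), -1, dtype=np.int16)
        self.expression = np.full((n_te, n_epi), np.nan)
        self.te_index = {t: i for i, t in enumerate(self.te_ids)}
        self.epi_index = {e: i for i, e in enumerate(self.epigenome_ids)}

    @property
    def n_te(self) -> int:
        return len(self.te_ids)

    @property
    def n_epigenomes(self) -> int:
        return len(self.epigenome_ids)

    def states_of(self, te_id: str, epigenome_id: str) -> frozenset[str] | None:
        i, k = self.te_index[te_id], self.epi_index[epigenome_id]
        if self.nocall[i, k]:
            return None
        codes = np.flatnonzero(self.membership[i, k])
        return frozenset(self.state_alphabet[c] for c in codes)

    def state_mask(self, states: str | Iterable[str]) -> np.ndarray:
        """Bool (n_te, n_epi): TE annotated with any of the given states."""
        if isinstance(states, str):
            states = [states]
        idx = [self.state_alphabet.index(s) for s in states]
        return self.membership[:, :, idx].any(axis=2)

    def meth_mask(self, code: int) -> np.ndarray:
        return self.meth_state == code

    def has_cpgs(self) -> np.ndarray:
        """Bool (n_te,): TE overlaps >= 1 CpG in >= 1 WGBS epigenome."""
        defined = self.meth_state != METH_ABSENT
        return ((self.meth_state != METH_NO_CPG) & defined).any(axis=1)

    def to_frame(self):
        """Long-format serialization (one row per TE x epigenome)."""
        import pandas as pd
        rows = []
        for i, te in enumerate(self.te_ids):
            for k, epi in enumerate(self.epigenome_ids):
                states = (
                    "" if self.nocall[i, k] else ",".join(
                        self.state_alphabet[c]
                        for c in np.flatnonzero(self.membership[i, k])
                    )
                )
                rows.append((
                    te, epi, states, "no_call" if self.nocall[i, k] else "ok",
                    METH_STATE_NAMES[int(self.meth_state[i, k])],
                    self.mean_methylation[i, k],
                    int(self.dhs[i, k]), int(self.k27ac[i, k]),
                    self.expression[i, k],
                ))
        return pd.DataFrame(rows, columns=[
            "te_id", "epigenome", "chromhmm_states", "call_status",
            "methylation_state", "mean_methylation",
            "dhs_summits", "k27ac_summits", "expression",
        ])


def build_state_call_matrix(
    tes: Sequence[TEAnnotation],
    segmentations: dict[str, Segmentation],
    methylation: dict[str, MethylationTrack] | None = None,
    dhs_peaks: dict[str, PeakSet] | None = None,
    k27ac_peaks: dict[str, PeakSet] | None = None,
    coverage: dict[str, CoverageTrack] | None = None,
    mode: str = "window_center",
) -> StateCallMatrix:
    """Annotate every TE in every epigenome.

    Missing data layers for an epigenome (no WGBS, no peaks, no RNA) are
    encoded as absent, never as zero; a TE whose chromosome is absent
    from a segmentation is a no-call.
    """
    epigenome_ids = sorted(segmentations)
    alphabet = segmentations[epigenome_ids[0]].state_alphabet
    for seg in segmentations.values():
        if seg.state_alphabet != alphabet:
            raise ValidationError("segmentations disagree on state alphabet")
    m = StateCallMatrix([te.id for te in tes], epigenome_ids, alphabet)

    methylation = methylation or {}
    dhs_peaks = dhs_peaks or {}
    k27ac_peaks = k27ac_peaks or {}
    coverage = coverage or {}

    for k, epi in enumerate(epigenome_ids):
        seg = segmentations[epi]
        meth = methylation.get(epi)
        dhs = dhs_peaks.get(epi)
        k27 = k27ac_peaks.get(epi)
        cov = coverage.get(epi)
        dhs_summits = dhs.summit_positions() if dhs else None
        k27_summits = k27.summit_positions() if k27 else None
        for i, te in enumerate(tes):
            iv = te.interval
            codes = _annotate_codes(iv.chrom, iv.start, iv.end, seg, mode)
            if codes is None:
                m.nocall[i, k] = True
            else:
                for c in codes:
                    m.membership[i, k, c] = True
            if meth is not None and not m.nocall[i, k]:
                mean, code = _methylation_codes(iv.chrom, iv.start, iv.end, meth)
                m.meth_state[i, k] = code
                if mean is not None:
                    m.mean_methylation[i, k] = mean
            if dhs is not None and not m.nocall[i, k]:
                m.dhs[i, k] = annotate_peaks(te, dhs, dhs_summits)
            if k27 is not None and not m.nocall[i, k]:
                m.k27ac[i, k] = annotate_peaks(te, k27, k27_summits)
            if cov is not None and cov.covers(iv.chrom) and not m.nocall[i, k]:
                m.expression[i, k] = (
                    cov.mean_over(iv.chrom, iv.start, iv.end)
                    * cov.normalization_factor
                )
    return m
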