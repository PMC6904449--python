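"""Shared fixtures: one session-scoped default toy bundle plus small
hand-built objects used across modules."""

from __future__ import annotations

import numpy as np
import pytest

from teprofiler.annotate import build_state_call_matrix
from teprofiler.core import (
    GenomeAssembly,
    GenomicInterval,
    Segmentation,
    TEAnnotation,
)
from teprofiler.simulate import SimulationConfig, simulate

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def dataset():
    return simulate(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def matrix(dataset):
    return build_state_call_matrix(
        dataset.tes, dataset.segmentations, dataset.methylation,
        dataset.dhs_peaks, dataset.k27ac_peaks, dataset.coverage,
    )


@pytest.fixture(scope="session")
def tensor(dataset, matrix):
    from teprofiler.enrichment import build_enrichment_tensor

    return build_enrichment_tensor(
        dataset.tes, dataset.segmentations, matrix,
        methylation=dataset.methylation, dhs_peaks=dataset.dhs_peaks,
        k27ac_peaks=dataset.k27ac_peaks,
    )


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly(name="tiny", chromosomes=[("chr1", 10_000)])


def make_segmentation(blocks, epigenome_id="E1", window_bp=200,
                      alphabet=("15_Quies", "7_Enh", "1_TssA", "9_Het")):
    """Build a one-chromosome segmentation from [(start, end, state), ...]."""
    bounds = [blocks[0][0]] + [b[1] for b in blocks]
    states = [b[2] for b in blocks]
    return Segmentation(epigenome_id, alphabet,
                        {"chr1": (np.array(bounds), np.array(states))},
                        window_bp=window_bp)


def make_te(start, end, chrom="chr1", subfamily="S1", te_class="SINE",
            te_id=None, sub_prop=0.1):
    return TEAnnotation(
        interval=GenomicInterval(chrom, start, end),
        subfamily=subfamily, family="F1", te_class=te_class,
        substitution_proportion=sub_prop,
        id=te_id or f"te_{chrom}_{start}_{end}",
    )


# ---- brute-force oracles (per-base; deliberately independent of the
# interval engine they check) ----

def expand_states(seg: Segmentation, chrom: str) -> np.ndarray:
    """Per-base state codes for a covered chromosome."""
    bounds, states = seg.blocks[chrom]
    out = np.full(int(bounds[-1]), -1, dtype=np.int16)
    for i in range(len(states)):
        out[int(bounds[i]):int(bounds[i + 1])] = states[i]
    return out


def brute_force_chromhmm(te, seg, mode="window_center"):
    """Per-base reimplementation of the window-center annotation rule."""
    chrom = te.interval.chrom
    if not seg.covers(chrom):
        return None
    base = expand_states(seg, chrom)
    start, end = te.interval.start, te.interval.end
    if seg.free_form or mode == "any_overlap":
        codes = {int(c) for c in base[start:end] if c >= 0}
        return codes
    w = seg.window_bp
    b0 = int(seg.blocks[chrom][0][0])
    codes = set()
    if mode == "block_center":
        bounds, states = seg.blocks[chrom]
        for i in range(len(states)):
            center = int(bounds[i] + (bounds[i + 1] - bounds[i]) // 2)
            if start <= center < end:
                codes.add(int(states[i]))
        return codes
    for center in range(b0 + w // 2, int(seg.blocks[chrom][0][-1]), w):
        if start <= center < end and base[center] >= 0:
            codes.add(int(base[center]))
    if not codes and mode == "window_center":
        counts = {}
        for pos in range(start, min(end, len(base))):
            c = int(base[pos])
            if c >= 0:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            best = max(sorted(counts), key=lambda c: counts[c])
            codes.add(best)
    return codes


def brute_force_summits(te, peakset):
    positions = set()
    for iv, off in peakset.peaks:
        pos = iv.start + off
        if iv.chrom == te.interval.chrom and \
                te.interval.start <= pos < te.interval.end:
            positions.add(pos)
    return len(positions)
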