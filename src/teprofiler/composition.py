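"""Aggregate state composition: what fraction of a feature set sits in each
epigenetic state, and what fraction of each state sits inside features.

Counting conventions:

* base counting is on coordinate-collapsed ("unique") feature bases,
  overlap at >= 1 bp;
* CpG counting applies the half-CpG rule: a CpG with only one of its two
  bases inside the feature counts 0.5;
* CpGs covered by <= 3 reads accrue to the "missing" methylation state;
* pooling across epigenomes sums numerators and denominators rather than
  averaging per-epigenome proportions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    HYPER_LOWER,
    HYPO_UPPER,
    MIN_CPG_READS,
    CoverageTrack,
    EpigenomeMetadata,
    GenomeAssembly,
    GenomicInterval,
    MethylationTrack,
    PeakSet,
    Segmentation,
    TEAnnotation,
)
from .intervals import (
    IntervalArrays,
    contains,
    merge,
    overlap_bp,
)

METH_STATE_ORDER = ("hypo", "intermediate", "hyper", "missing")


def as_intervals(features: Iterable) -> list[GenomicInterval]:
    out = []
    for f in features:
        out.append(f.interval if isinstance(f, TEAnnotation) else f)
    return out


def state_bp_in_features(features: Sequence, seg: Segmentation,
                         collapsed: IntervalArrays | None = None) -> pd.Series:
    """bp of each chromHMM state inside the (collapsed) feature set."""
    arrays = collapsed if collapsed is not None else merge(as_intervals(features))
    counts = np.zeros(len(seg.state_alphabet), dtype=np.int64)
    for chrom, (starts, ends) in arrays.items():
        if not seg.covers(chrom):
            continue
        bounds, states = seg.blocks[chrom]
        for s, e in zip(starts, ends):
            lo = int(np.searchsorted(bounds, s, side="right")) - 1
            hi = int(np.searchsorted(bounds, e, side="left"))
            for i in range(max(lo, 0), min(hi, len(states))):
                a = max(int(s), int(bounds[i]))
                b = min(int(e), int(bounds[i + 1]))
                if b > a:
                    counts[states[i]] += b - a
    return pd.Series(counts, index=list(seg.state_alphabet))


def cpg_state_counts(features: Sequence, track: MethylationTrack,
                     collapsed: IntervalArrays | None = None) -> pd.Series:
    """Half-CpG-weighted counts of feature CpGs per methylation state.

    Each CpG is classified by its own methylated fraction (missing when
    read coverage <= 3); its weight is the number of its two bases inside
    the feature set divided by two.
    """
    arrays = collapsed if collapsed is not None else merge(as_intervals(features))
    counts = pd.Series(0.0, index=list(METH_STATE_ORDER))
    for chrom, (pos, frac, cov) in track.cpgs.items():
        w = (contains(arrays, chrom, pos).astype(float)
             + contains(arrays, chrom, pos + 1).astype(float)) / 2.0
        inside = w > 0
        if not inside.any():
            continue
        w, f, c = w[inside], frac[inside], cov[inside]
        missing = c <= MIN_CPG_READS
        counts["missing"] += float(w[missing].sum())
        codes = np.where(f < HYPO_UPPER, 0, np.where(f > HYPER_LOWER, 2, 1))
        for name, code in (("hypo", 0), ("intermediate", 1), ("hyper", 2)):
            sel = ~missing & (codes == code)
            counts[name] += float(w[sel].sum())
    return counts


def peak_bp_in_features(features: Sequence, peakset: PeakSet,
                        collapsed: IntervalArrays | None = None) -> int:
    """Feature bases under peaks (full peak bodies, not just summits)."""
    arrays = collapsed if collapsed is not None else merge(as_intervals(features))
    peak_arrays = merge(iv for iv, _ in peakset.peaks)
    return overlap_bp(arrays, peak_arrays)


def summits_in_features(features: Sequence, peakset: PeakSet,
                        collapsed: IntervalArrays | None = None) -> int:
    """Distinct peak summit positions inside the feature set."""
    arrays = collapsed if collapsed is not None else merge(as_intervals(features))
    count = 0
    for chrom, positions in peakset.summit_positions().items():
        positions = np.unique(positions)
        count += int(contains(arrays, chrom, positions).sum())
    return count


def proportion_in_states(
    features: Sequence,
    segmentations: Mapping[str, Segmentation] | None = None,
    methylation: Mapping[str, MethylationTrack] | None = None,
    basis: str = "bases",
) -> pd.DataFrame:
    """Per-state proportions of feature bases (or CpGs), per epigenome and
    pooled ("all") by summing counts across epigenomes."""
    collapsed = merge(as_intervals(features))
    rows = {}
    if basis == "bases":
        if not segmentations:
            raise ValueError("bases basis requires segmentations")
        pooled = None
        for epi, seg in sorted(segmentations.items()):
            counts = state_bp_in_features(features, seg, collapsed)
            rows[epi] = counts / counts.sum()
            pooled = counts if pooled is None else pooled + counts
        rows["all"] = pooled / pooled.sum()
    elif basis == "CpGs":
        if not methylation:
            raise ValueError("CpG basis requires methylation tracks")
        pooled = None
        for epi, track in sorted(methylation.items()):
            counts = cpg_state_counts(features, track, collapsed)
            rows[epi] = counts / counts.sum()
            pooled = counts if pooled is None else pooled + counts
        rows["all"] = pooled / pooled.sum()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return pd.DataFrame(rows).T


def contribution_of_features(
    features: Sequence,
    segmentations: Mapping[str, Segmentation],
    class_features: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Fraction of each state's genome-wide bases that lie inside the
    feature set, per epigenome and pooled; optionally decomposed by class.

    The class decomposition sums to the total by construction when the
    class feature sets partition the features.
    """
    collapsed = merge(as_intervals(features))
    class_collapsed = {
        name: merge(as_intervals(f)) for name, f in (class_features or {}).items()
    }
    records = []
    pooled_num: pd.Series | None = None
    pooled_den: pd.Series | None = None
    pooled_cls: dict[str, pd.Series] = {}
    for epi, seg in sorted(segmentations.items()):
        num = state_bp_in_features(features, seg, collapsed)
        den = pd.Series(seg.state_bp(), index=list(seg.state_alphabet))
        frac = num / den.replace(0, np.nan)
        for state in seg.state_alphabet:
            records.append((epi, state, "all_features", frac[state]))
        for name, arrays in class_collapsed.items():
            cnum = state_bp_in_features([], seg, arrays)
            cfrac = cnum / den.replace(0, np.nan)
            pooled_cls[name] = cnum if name not in pooled_cls else pooled_cls[name] + cnum
            for state in seg.state_alphabet:
                records.append((epi, state, name, cfrac[state]))
        pooled_num = num if pooled_num is None else pooled_num + num
        pooled_den = den if pooled_den is None else pooled_den + den
    frac = pooled_num / pooled_den.replace(0, np.nan)
    for state in frac.index:
        records.append(("all", state, "all_features", frac[state]))
    for name, cnum in pooled_cls.items():
        cfrac = cnum / pooled_den.replace(0, np.nan)
        for state in cfrac.index:
            records.append(("all", state, name, cfrac[state]))
    return pd.DataFrame(records,
                        columns=["epigenome", "state", "feature_set", "fraction"])


def expression_ratio(
    tes: Sequence[TEAnnotation],
    coverage: Mapping[str, CoverageTrack],
    assembly: GenomeAssembly,
) -> pd.Series:
    """Per-epigenome ratio of mean TE coverage to genome-wide mean coverage."""
    collapsed = merge(as_intervals(tes))
    out = {}
    for epi, track in sorted(coverage.items()):
        te_sum = te_bp = genome_sum = genome_bp = 0.0
        for chrom in assembly.chrom_names:
            if chrom not in assembly.allowed_chromosomes or not track.covers(chrom):
                continue
            bounds, values = track.runs[chrom]
            widths = np.diff(bounds)
            genome_sum += float((values * widths).sum())
            genome_bp += float(assembly.size(chrom))
            if chrom in collapsed:
                starts, ends = collapsed[chrom]
                for s, e in zip(starts, ends):
                    te_sum += track.mean_over(chrom, int(s), int(e)) * (e - s)
                    te_bp += float(e - s)
        if genome_sum == 0 or te_bp == 0:
            out[epi] = np.nan
        else:
            out[epi] = (te_sum / te_bp) / (genome_sum / genome_bp)
    return pd.Series(out)


def signal_metaprofile(
    tes: Sequence[TEAnnotation],
    track: CoverageTrack,
    assembly: GenomeAssembly,
    window: int = 10_000,
    bin_bp: int = 50,
) -> np.ndarray:
    """Mean signal in fixed bins over a window centered on each TE.

    TEs whose centered window would extend beyond their chromosome are
    excluded.  Returns ``window // bin_bp`` per-bin means across the set.
    """
    if not tes:
        raise ValueError("empty TE subset")
    n_bins = window // bin_bp
    sums = np.zeros(n_bins)
    n_used = 0
    half = window // 2
    for te in tes:
        iv = te.interval
        center = iv.start + iv.width // 2
        lo = center - half
        if lo < 0 or center + half > assembly.size(iv.chrom):
            continue
        if not track.covers(iv.chrom):
            continue
        n_used += 1
        for b in range(n_bins):
            sums[b] += track.mean_over(iv.chrom, lo + b * bin_bp,
                                       lo + (b + 1) * bin_bp)
    if n_used == 0:
        raise ValueError("no TE fits the centered window")
    return sums / n_used


def kruskal_across_categories(
    values: Mapping[str, float],
    metadata: Mapping[str, EpigenomeMetadata],
    scheme: str = "group",
) -> tuple[float, float]:
    """Kruskal-Wallis test of per-epigenome values across metadata
    categories (Bonferroni across states is applied by the caller)."""
    groups: dict[str, list[float]] = {}
    for epi, v in values.items():
        if not np.isnan(v):
            groups.setdefault(metadata[epi].label(scheme), []).append(v)
    samples = [v for v in groups.values() if len(v) > 0]
    if len(samples) < 2:
        return np.nan, np.nan
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p)
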