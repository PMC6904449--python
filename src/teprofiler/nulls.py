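"""Genomic null models and permutation statistics.

* :func:`shuffle_tes` rebuilds the TE complement at random genomic
  positions (lengths and labels preserved; gaps and disallowed
  chromosomes excluded) — the background against which observed
  subfamily coordination is judged.
* :func:`permutation_category_test` asks whether an epigenome category
  (e.g. a tissue group) is over-represented among the epigenomes whose
  per-epigenome value exceeds (or falls below) the cross-epigenome
  reference, against a label-permutation null.
* :func:`preferential_enrichment_test` applies the same machinery to the
  enriched-epigenome sets of the LOR tensor.
* :func:`association_stats` is the chi-squared test (no continuity
  correction) with Cramér's V effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    ACTIVE_REGULATORY_STATES,
    TRANSCRIBED_STATES,
    EpigenomeMetadata,
    GenomeAssembly,
    GenomicInterval,
    TEAnnotation,
)

# states whose enrichment counts as "active" for the preferential test
ACTIVE_TEST_STATES = frozenset(
    ACTIVE_REGULATORY_STATES + TRANSCRIBED_STATES
    + ("hypo", "intermediate", "DHS", "H3K27ac")
)


@dataclass
class ShuffleSpec:
    n_iterations: int = 10
    seed: int = 0
    max_tries: int = 1000


def shuffle_tes(tes: Sequence[TEAnnotation], assembly: GenomeAssembly,
                spec: ShuffleSpec | None = None) -> list[list[TEAnnotation]]:
    """Uniformly re-place every TE over allowed, non-gap genomic space.

    Each TE keeps its length, subfamily, family, and class; shuffled TEs
    may overlap each other (only assembly gaps and disallowed
    chromosomes are excluded).  Chromosomes are drawn with probability
    proportional to allowed length; placements landing across an
    exclusion are resampled up to ``max_tries`` times.
    """
    spec = spec or ShuffleSpec()
    segments = []
    for chrom in assembly.chrom_names:
        if chrom not in assembly.allowed_chromosomes:
            continue
        pos = 0
        for gs, ge in assembly.gap_intervals(chrom):
            if gs > pos:
                segments.append((chrom, pos, gs))
            pos = max(pos, ge)
        if pos < assembly.size(chrom):
            segments.append((chrom, pos, assembly.size(chrom)))
    seg_lengths = np.array([e - s for _, s, e in segments], dtype=float)
    weights = seg_lengths / seg_lengths.sum()

    iterations = []
    for it in range(spec.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, it)))
        shuffled = []
        for te in tes:
            length = te.interval.width
            fits = seg_lengths >= length
            if not fits.any():
                raise ValueError(f"TE {te.id} ({length} bp) exceeds every "
                                 "allowed segment")
            placed = None
            for _ in range(spec.max_tries):
                si = int(rng.choice(len(segments), p=weights))
                chrom, s0, e0 = segments[si]
                if e0 - s0 < length:
                    continue
                start = int(rng.integers(s0, e0 - length + 1))
                placed = GenomicInterval(chrom, start, start + length,
                                         te.interval.strand)
                break
            if placed is None:
                raise ValueError(f"could not place TE {te.id} after "
                                 f"{spec.max_tries} tries")
            shuffled.append(TEAnnotation(
                interval=placed, subfamily=te.subfamily, family=te.family,
                te_class=te.te_class,
                substitution_proportion=te.substitution_proportion,
                mappability=te.mappability, id=f"{te.id}_shuf{it}",
            ))
        iterations.append(shuffled)
    return iterations


@dataclass
class PermutationResult:
    category_scheme: str
    category: str
    direction: str          # "higher" or "lower"
    observed: int           # category members beyond the reference
    n_members: int
    null_mean: float
    p_value: float
    q_value: float = float("nan")
    eligible: bool = True   # member of the FDR family


def _one_direction_pvalues(flags: np.ndarray, labels: np.ndarray,
                           categories: Sequence[str], n_perm: int,
                           rng: np.random.Generator) -> list[tuple[str, int, int, float, float]]:
    """For each category: count among flagged epigenomes vs permuted labels.

    Returns (category, observed, n_members, null_mean, p) with the add-one
    permutation p-value  p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    out = []
    n_flagged = int(flags.sum())
    observed = {c: int(((labels == c) & flags).sum()) for c in categories}
    null_counts = {c: np.empty(n_perm, dtype=np.int64) for c in categories}
    perm_labels = labels.copy()
    for b in range(n_perm):
        rng.shuffle(perm_labels)
        for c in categories:
            null_counts[c][b] = int(((perm_labels == c) & flags).sum())
    for c in categories:
        obs = observed[c]
        null = null_counts[c]
        p = (1.0 + float((null >= obs).sum())) / (1.0 + n_perm)
        out.append((c, obs, int((labels == c).sum()), float(null.mean()), p))
    return out


def permutation_category_test(
    values: Mapping[str, float],
    metadata: Mapping[str, EpigenomeMetadata],
    scheme: str,
    reference: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Permutation test of category representation among extreme epigenomes.

    Epigenomes above and below the cross-epigenome ``reference`` (the
    pooled value by default) are tested separately; category labels are
    permuted ``n_perm`` times.  Benjamini-Hochberg correction is applied
    only over categories with at least one member beyond the reference in
    the tested direction.
    """
    epi_ids = [e for e in sorted(values) if not np.isnan(values[e])]
    vals = np.array([values[e] for e in epi_ids])
    labels = np.array([metadata[e].label(scheme) for e in epi_ids])
    categories = sorted(set(labels))
    if len(categories) < 2:
        raise ValueError("need >= 2 categories")
    for c in categories:
        if (labels == c).sum() == 0:
            raise ValueError(f"category {c!r} has zero members")
    ref = float(np.mean(vals)) if reference is None else reference

    rng = np.random.default_rng(np.random.SeedSequence((seed, 777)))
    results: list[PermutationResult] = []
    for direction, flags in (("higher", vals > ref), ("lower", vals < ref)):
        for c, obs, n_mem, null_mean, p in _one_direction_pvalues(
                flags, labels, categories, n_perm, rng):
            results.append(PermutationResult(
                category_scheme=scheme, category=c, direction=direction,
                observed=obs, n_members=n_mem, null_mean=null_mean,
                p_value=p, eligible=obs > 0,
            ))
    _apply_bh(results)
    return results


def _apply_bh(results: list[PermutationResult]) -> None:
    family = [r for r in results if r.eligible]
    if not family:
        return
    _, q, _, _ = multipletests([r.p_value for r in family], method="fdr_bh")
    for r, qv in zip(family, q):
        r.q_value = float(qv)


def preferential_enrichment_test(
    tensor: pd.DataFrame,
    metadata: Mapping[str, EpigenomeMetadata],
    scheme: str = "group",
    n_perm: int = 1000,
    seed: int = 0,
    active_states: frozenset[str] = ACTIVE_TEST_STATES,
) -> pd.DataFrame:
    """Which epigenome categories are over-represented among the enriched
    epigenomes of each (subfamily, state)?

    Category labels are permuted across epigenomes; the statistic is the
    category count among epigenomes where the cell is enriched.  The BH
    family contains only subfamily-by-state-by-category combinations in
    active states with >= 1 enriched epigenome.
    """
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence((seed, 999)))
    epi_ids = sorted(tensor["epigenome"].unique())
    labels = np.array([metadata[e].label(scheme) for e in epi_ids])
    categories = sorted(set(labels))
    enriched_cells = tensor[tensor["enriched"]]
    for (sub, state), g in enriched_cells.groupby(["subfamily", "state"]):
        if state not in active_states:
            continue
        flagged_set = set(g["epigenome"])
        flags = np.array([e in flagged_set for e in epi_ids])
        if not flags.any():
            continue
        for c, obs, n_mem, null_mean, p in _one_direction_pvalues(
                flags, labels, categories, n_perm, rng):
            rows.append((sub, state, c, obs, n_mem,
                         int(flags.sum()), null_mean, p))
    out = pd.DataFrame(rows, columns=[
        "subfamily", "state", "category", "observed", "n_members",
        "n_enriched_epigenomes", "null_mean", "p_value",
    ])
    if len(out):
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["q_value"] = q
        out["significant"] = out["q_value"] < 0.05
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def association_stats(table: np.ndarray | pd.DataFrame,
                      drop_zero_margins: bool = True) -> tuple[float, float, float]:
    """Chi-squared test (no continuity correction) plus Cramér's V.

    V = sqrt(chi2 / (n * (min(rows, cols) - 1))).  Rows/columns with a
    zero margin are dropped (with a warning) before testing.
    """
    import warnings

    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if drop_zero_margins and (not row_ok.all() or not col_ok.all()):
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        arr = arr[row_ok][:, col_ok]
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("table degenerate after dropping zero margins")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    n = arr.sum()
    v = float(np.sqrt(chi2 / (n * (min(arr.shape) - 1))))
    return float(chi2), float(p), v
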