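"""Evolutionary age trends and cross-species epigenetic conservation.

TE age is proxied by the Jukes-Cantor distance to the subfamily
consensus, d = -(3/4) ln(1 - (4/3) p).  Age-trend responses are smoothed
with penalized cubic smoothing splines (smoothing parameter chosen by
generalized cross-validation); binary responses (CpG-island overlap) use
logistic regression with age as the sole predictor.

Orthologous TEs are source TEs whose already-lifted coordinates overlap
(>= 1 bp) a same-subfamily TE in the second species.  Conservation is
quantified by state-by-state contingency tables over anatomy-matched
epigenome pairs, with the chi-squared test and Cramér's V.  Each TE
contributes its primary (largest-overlap) state per epigenome, so every
(pair, epigenome pair) yields one (state1, state2) observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    METH_HYPO,
    METH_INTER,
    METH_HYPER,
    StateCallMatrix,
    _methylation_codes,
    primary_chromhmm_state,
)
from .core import (
    GenomicInterval,
    MethylationTrack,
    Segmentation,
    TEAnnotation,
    jukes_cantor,
)
from .nulls import association_stats

__all__ = [
    "jukes_cantor", "fit_age_trend", "pair_orthologs", "OrthologPair",
    "conservation_tables", "planted_cramers_v", "tissue_specific_tes",
    "tissue_specific_conservation", "AgeModelFit",
]


@dataclass
class AgeModelFit:
    """A fitted age-trend model: either a smoothing spline (continuous
    response) or logistic coefficients (binary response)."""

    kind: str                       # "spline" or "logistic"
    predictor_range: tuple[float, float]
    spline: object | None = None
    coef: float | None = None       # logistic slope on jc_distance
    intercept: float | None = None
    coef_pvalue: float | None = None
    n_obs: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "spline":
            return self.spline(x)
        z = self.intercept + self.coef * x
        return 1.0 / (1.0 + np.exp(-z))


def fit_age_trend(ages: np.ndarray, response: np.ndarray,
                  binary: bool = False, min_obs: int = 100) -> AgeModelFit:
    """Fit response vs. TE age.

    Continuous responses get a cubic smoothing spline with GCV-selected
    penalty (ties in age are averaged first, as required by the spline).
    Binary responses get a logistic regression reporting the age
    coefficient and its Wald p-value.
    """
    ages = np.asarray(ages, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = ~(np.isnan(ages) | np.isnan(response))
    ages, response = ages[ok], response[ok]
    if len(ages) < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {len(ages)}")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate (constant) age predictor")
    rng = (float(ages.min()), float(ages.max()))
    if binary:
        import statsmodels.api as sm
        x = sm.add_constant(ages)
        fit = sm.GLM(response, x, family=sm.families.Binomial()).fit()
        return AgeModelFit(kind="logistic", predictor_range=rng,
                           intercept=float(fit.params[0]),
                           coef=float(fit.params[1]),
                           coef_pvalue=float(fit.pvalues[1]),
                           n_obs=len(ages))
    from scipy.interpolate import make_smoothing_spline
    order = np.argsort(ages)
    xs, ys = ages[order], response[order]
    # average duplicated predictor values; with many observations, pool
    # onto a quantile grid first (count-weighted) to keep the GCV system
    # well conditioned
    ux, inv = np.unique(xs, return_inverse=True)
    if len(ux) > 400:
        edges = np.unique(np.quantile(xs, np.linspace(0, 1, 401)))
        inv = np.clip(np.searchsorted(edges, xs, side="right") - 1,
                      0, len(edges) - 2)
        ux = np.array([xs[inv == i].mean() for i in np.unique(inv)])
        inv = np.searchsorted(np.unique(inv), inv)
    sums = np.bincount(inv, weights=ys)
    counts = np.bincount(inv)
    uy = sums / counts
    spline = make_smoothing_spline(ux, uy, w=counts.astype(float))
    return AgeModelFit(kind="spline", predictor_range=rng, spline=spline,
                       n_obs=len(ages))


@dataclass(frozen=True)
class OrthologPair:
    source_id: str
    source_interval: GenomicInterval
    lifted_interval: GenomicInterval
    target_id: str
    target_interval: GenomicInterval
    subfamily: str


def pair_orthologs(
    lifted: Sequence[tuple[str, GenomicInterval]],
    source_tes: Sequence[TEAnnotation],
    target_tes: Sequence[TEAnnotation],
) -> list[OrthologPair]:
    """Pair lifted source TEs with overlapping same-subfamily target TEs.

    A pair requires >= 1 bp overlap between the lifted interval and the
    target TE, and identical subfamily names.  A source overlapping
    several same-subfamily targets yields one pair per target, so the
    per-source and per-target tallies can differ.
    """
    src_by_id = {te.id: te for te in source_tes}
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in target_tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.interval.start)
    starts = {c: np.array([t.interval.start for t in lst])
              for c, lst in by_chrom.items()}
    max_width = {c: max(t.interval.width for t in lst)
                 for c, lst in by_chrom.items()}

    pairs: list[OrthologPair] = []
    for source_id, iv in lifted:
        src = src_by_id.get(source_id)
        if src is None:
            raise KeyError(f"lifted table references unknown TE {source_id!r}")
        lst = by_chrom.get(iv.chrom)
        if not lst:
            continue
        s = starts[iv.chrom]
        lo = int(np.searchsorted(s, iv.start - max_width[iv.chrom], side="left"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        for t in lst[lo:hi]:
            if t.interval.overlaps(iv) and t.subfamily == src.subfamily:
                pairs.append(OrthologPair(
                    source_id=source_id, source_interval=src.interval,
                    lifted_interval=iv, target_id=t.id,
                    target_interval=t.interval, subfamily=src.subfamily,
                ))
    return pairs


def conservation_tables(
    pairs: Sequence[OrthologPair],
    source_tes: Mapping[str, TEAnnotation],
    target_tes: Mapping[str, TEAnnotation],
    segmentations1: Mapping[str, Segmentation],
    segmentations2: Mapping[str, Segmentation],
    epigenome_pairs: Sequence[tuple[str, str]],
    methylation1: Mapping[str, MethylationTrack] | None = None,
    methylation2: Mapping[str, MethylationTrack] | None = None,
) -> pd.DataFrame:
    """Per epigenome pair: state-by-state and hypomethylation contingency
    analyses of orthologous TEs, with chi-squared and Cramér's V.

    Returns one row per (epigenome pair, analysis) with the contingency
    table attached; ``analysis`` is "chromhmm" (full state-by-state) or
    "methylation_2x2" (hypomethylated vs. not).
    """
    rows = []
    for e1, e2 in epigenome_pairs:
        seg1, seg2 = segmentations1[e1], segmentations2[e2]
        alpha1 = list(seg1.state_alphabet)
        alpha2 = list(seg2.state_alphabet)
        table = np.zeros((len(alpha1), len(alpha2)), dtype=np.int64)
        meth_22 = np.zeros((2, 2), dtype=np.int64)
        m1 = (methylation1 or {}).get(e1)
        m2 = (methylation2 or {}).get(e2)
        for pair in pairs:
            src = source_tes[pair.source_id]
            tgt = target_tes[pair.target_id]
            c1 = primary_chromhmm_state(src, seg1, as_code=True) \
                if seg1.covers(src.interval.chrom) else None
            c2 = primary_chromhmm_state(tgt, seg2, as_code=True) \
                if seg2.covers(tgt.interval.chrom) else None
            if c1 is not None and c2 is not None:
                table[c1, c2] += 1
            if m1 is not None and m2 is not None:
                _, code1 = _methylation_codes(
                    src.interval.chrom, src.interval.start, src.interval.end, m1)
                _, code2 = _methylation_codes(
                    tgt.interval.chrom, tgt.interval.start, tgt.interval.end, m2)
                if code1 in (METH_HYPO, METH_INTER, METH_HYPER) and \
                        code2 in (METH_HYPO, METH_INTER, METH_HYPER):
                    meth_22[int(code1 != METH_HYPO), int(code2 != METH_HYPO)] += 1
        for analysis, tbl in (("chromhmm", table), ("methylation_2x2", meth_22)):
            n = int(tbl.sum())
            if n == 0 or (tbl.sum(axis=1) > 0).sum() < 2 or (tbl.sum(axis=0) > 0).sum() < 2:
                chi2 = p = v = float("nan")
            else:
                chi2, p, v = association_stats(tbl)
            rows.append((e1, e2, analysis, n, chi2, p, v, tbl))
    return pd.DataFrame(rows, columns=[
        "epigenome1", "epigenome2", "analysis", "n_pairs",
        "chi2", "p_value", "cramers_v", "table",
    ])


def planted_cramers_v(conservation_prob: float, p1: np.ndarray,
                      p2: np.ndarray | None = None) -> float:
    """Closed-form Cramér's V of the planted conservation transition model.

    state2 equals state1 with probability c, else draws from background
    ``p2``.  With shared backgrounds this reduces to V = c exactly.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = p1 if p2 is None else np.asarray(p2, dtype=float)
    c = conservation_prob
    joint = (1 - c) * np.outer(p1, p2)
    k = min(len(p1), len(p2))
    joint[np.arange(k), np.arange(k)] += c * p1[:k]
    q2 = joint.sum(axis=0)
    q1 = joint.sum(axis=1)
    expected = np.outer(q1, q2)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi2 = np.nansum(np.where(expected > 0,
                                  (joint - expected) ** 2 / expected, 0.0))
    return float(np.sqrt(phi2 / (k - 1)))


def tissue_specific_tes(
    matrix: StateCallMatrix,
    tissue_of: Mapping[str, str],
    definition: str | Sequence[str],
    min_in_tissue: int = 2,
    max_overall: int = 5,
    exactly: bool = False,
) -> dict[str, set[str]]:
    """Per tissue, the TEs annotated with the state in >= ``min_in_tissue``
    epigenomes of that tissue but fewer than ``max_overall`` overall.

    ``exactly=True`` reads the in-tissue requirement as exactly
    ``min_in_tissue``.  A TE can be specific for more than one tissue.
    Tissues with fewer than two epigenomes are undefined and omitted.
    """
    from .dynamics import technique_mask

    mask, has_data = technique_mask(matrix, definition)
    in_state = mask & has_data
    total = in_state.sum(axis=1)
    tissues = sorted(set(tissue_of.values()))
    out: dict[str, set[str]] = {}
    for tissue in tissues:
        cols = [k for k, e in enumerate(matrix.epigenome_ids)
                if tissue_of.get(e) == tissue]
        if len(cols) < 2:
            continue
        n_tissue = in_state[:, cols].sum(axis=1)
        hit = n_tissue == min_in_tissue if exactly else n_tissue >= min_in_tissue
        sel = hit & (total < max_overall)
        out[tissue] = {matrix.te_ids[i] for i in np.flatnonzero(sel)}
    return out


def tissue_specific_conservation(
    matrix1: StateCallMatrix,
    matrix2: StateCallMatrix,
    tissue_of1: Mapping[str, str],
    tissue_of2: Mapping[str, str],
    pairs: Sequence[OrthologPair],
    definition: str | Sequence[str],
    min_in_tissue: int = 2,
    max_overall: int = 5,
) -> pd.DataFrame:
    """Cross-species transfer of tissue-specific annotation.

    For each tissue: among source TEs tissue-specific for the state in
    species 1 (and possessing an ortholog), the fraction whose ortholog
    is tissue-specific for the same tissue in species 2.
    """
    spec1 = tissue_specific_tes(matrix1, tissue_of1, definition,
                                min_in_tissue, max_overall)
    spec2 = tissue_specific_tes(matrix2, tissue_of2, definition,
                                min_in_tissue, max_overall)
    targets_of: dict[str, set[str]] = {}
    for p in pairs:
        targets_of.setdefault(p.source_id, set()).add(p.target_id)
    rows = []
    for tissue in sorted(set(spec1) & set(spec2)):
        sources = [s for s in spec1[tissue] if s in targets_of]
        if not sources:
            rows.append((tissue, 0, float("nan")))
            continue
        conserved = sum(
            1 for s in sources if targets_of[s] & spec2[tissue]
        )
        rows.append((tissue, len(sources), conserved / len(sources)))
    return pd.DataFrame(rows, columns=["tissue", "n_tissue_specific",
                                       "transfer_fraction"])
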