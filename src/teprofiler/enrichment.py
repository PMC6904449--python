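"""Subfamily x state x epigenome log-odds-ratio enrichment.

The enrichment of subfamily *i* in state *j* in epigenome *k* is

    LOR = log2( 1e-20 + (ijk / ik) / (jk / k) )

where the counts depend on the technique: for chromHMM states ``ijk``
and ``jk`` are bases in the state (within the subfamily / genome-wide);
for WGBS they are CpGs; for DHS and H3K27ac they are peak summits, while
``ik`` and ``k`` remain subfamily and genome lengths in bp.  The 1e-20
pseudocount floors zero overlap at log2(1e-20) ~ -66.4 instead of -Inf.

A cell is *eligible* when the subfamily has more than 30 members (with
CpGs, for WGBS) and *enriched* when additionally more than 10 members
are annotated with the state in that epigenome and LOR > 1.5
(2^1.5 ~ 2.8, roughly a three-fold enrichment over genomic background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate as _ann
from .annotate import StateCallMatrix
from .composition import cpg_state_counts, state_bp_in_features, summits_in_features
from .intervals import merge, total_bp
from .core import (
    LOR_ENRICHED,
    LOR_PSEUDOCOUNT,
    MIN_MEMBERS_IN_STATE,
    MIN_SUBFAMILY_MEMBERS,
    MethylationTrack,
    PeakSet,
    Segmentation,
    TEAnnotation,
)
from .dynamics import METHYLATION_DEFS

LOR_FLOOR = math.log2(LOR_PSEUDOCOUNT)


def lor(ijk: float, ik: float, jk: float, k_total: float) -> float:
    """Log2 odds ratio with the 1e-20 pseudocount; NaN when the state is
    absent from the epigenome (jk = 0)."""
    if ik <= 0 or k_total <= 0:
        raise ValueError("ik and k must be positive")
    if jk == 0:
        return float("nan")
    return math.log2(LOR_PSEUDOCOUNT + (ijk / ik) / (jk / k_total))


TENSOR_COLUMNS = ["subfamily", "technique", "state", "epigenome", "basis",
                  "ijk", "ik", "jk", "k", "lor", "n_total", "n_in_state",
                  "eligible", "enriched"]


def _lor_vec(ijk, ik, jk, k_total):
    out = np.full(np.shape(ijk), np.nan)
    ok = np.asarray(jk) > 0
    ratio = np.where(ok, (np.asarray(ijk) / np.asarray(ik))
                     / np.where(ok, np.asarray(jk) / k_total, 1.0), np.nan)
    out = np.where(ok, np.log2(LOR_PSEUDOCOUNT + ratio), np.nan)
    return out


def build_enrichment_tensor(
    tes: Sequence[TEAnnotation],
    segmentations: Mapping[str, Segmentation],
    matrix: StateCallMatrix,
    methylation: Mapping[str, MethylationTrack] | None = None,
    dhs_peaks: Mapping[str, PeakSet] | None = None,
    k27ac_peaks: Mapping[str, PeakSet] | None = None,
) -> pd.DataFrame:
    """Long-format enrichment tensor over every available technique.

    ``matrix`` supplies the per-TE member state calls that feed
    ``n_in_state`` (window-center convention); the base/CpG/summit counts
    are computed here by direct interval arithmetic — the two member
    notions are intentionally distinct.

    In epigenomes whose segmentation omits a chromosome, subfamily and
    genome totals (``ik``, ``k``) exclude that chromosome.
    """
    methylation = methylation or {}
    dhs_peaks = dhs_peaks or {}
    k27ac_peaks = k27ac_peaks or {}

    subfamilies = sorted({te.subfamily for te in tes})
    by_sub: dict[str, list[TEAnnotation]] = {s: [] for s in subfamilies}
    for te in tes:
        by_sub[te.subfamily].append(te)
    collapsed = {s: merge(te.interval for te in by_sub[s]) for s in subfamilies}

    te_sub_idx = np.array([subfamilies.index(te.subfamily) for te in tes])
    rows: list[tuple] = []

    for epi in sorted(segmentations):
        seg = segmentations[epi]
        k_idx = matrix.epi_index[epi]
        covered = set(seg.blocks)
        jk_states = seg.state_bp()
        k_total = int(sum(bounds[-1] - bounds[0]
                          for bounds, _ in seg.blocks.values()))
        meth = methylation.get(epi)
        if meth is not None:
            genome_cpg_counts = _genomewide_cpg_state_counts(meth, covered)
            total_cpgs = float(genome_cpg_counts.sum())
        for s_i, sub in enumerate(subfamilies):
            members = [te for te in by_sub[sub] if te.interval.chrom in covered]
            n_total = len(members)
            arrays = {c: v for c, v in collapsed[sub].items() if c in covered}
            ik = total_bp(arrays)
            if ik == 0:
                continue
            member_rows = np.flatnonzero(te_sub_idx == s_i)
            member_rows = member_rows[~matrix.nocall[member_rows, k_idx]]
            eligible = n_total > MIN_SUBFAMILY_MEMBERS

            # chromHMM: bases basis
            ijk_states = state_bp_in_features([], seg, arrays).to_numpy()
            lors = _lor_vec(ijk_states, ik, jk_states, k_total)
            n_in = matrix.membership[member_rows, k_idx, :].sum(axis=0)
            for j, state in enumerate(seg.state_alphabet):
                enr = (eligible and n_in[j] > MIN_MEMBERS_IN_STATE
                       and not np.isnan(lors[j]) and lors[j] > LOR_ENRICHED)
                rows.append((sub, "chromhmm", state, epi, "bases",
                             float(ijk_states[j]), float(ik),
                             float(jk_states[j]), float(k_total), lors[j],
                             n_total, int(n_in[j]), eligible, enr))

            # WGBS: CpG basis, members overlapping CpGs only
            if meth is not None and total_cpgs > 0:
                sub_counts = cpg_state_counts([], meth, arrays)
                sub_cpgs = float(sub_counts.sum())
                if sub_cpgs > 0:
                    has_cpg = ~np.isin(
                        matrix.meth_state[member_rows, k_idx],
                        (_ann.METH_ABSENT, _ann.METH_NO_CPG))
                    n_total_cpg = int(has_cpg.sum())
                    elig_m = n_total_cpg > MIN_SUBFAMILY_MEMBERS
                    for name, code in METHYLATION_DEFS.items():
                        ijk_m = float(sub_counts[name])
                        jk_m = float(genome_cpg_counts[name])
                        l = lor(ijk_m, sub_cpgs, jk_m, total_cpgs) if jk_m > 0 else float("nan")
                        n_in_m = int((matrix.meth_state[member_rows, k_idx] == code).sum())
                        enr = (elig_m and n_in_m > MIN_MEMBERS_IN_STATE
                               and not math.isnan(l) and l > LOR_ENRICHED)
                        rows.append((sub, "wgbs", name, epi, "CpGs",
                                     ijk_m, sub_cpgs, jk_m, total_cpgs, l,
                                     n_total_cpg, n_in_m, elig_m, enr))

            # DHS / H3K27ac: summit basis against length denominators
            for tech, peaksets, counts in (
                ("dhs", dhs_peaks, matrix.dhs),
                ("k27ac", k27ac_peaks, matrix.k27ac),
            ):
                ps = peaksets.get(epi)
                if ps is None:
                    continue
                total_summits = sum(
                    len(np.unique(v)) for c, v in ps.summit_positions().items()
                    if c in covered)
                ijk_s = float(summits_in_features([], ps, arrays))
                l = lor(ijk_s, ik, float(total_summits), k_total) \
                    if total_summits > 0 else float("nan")
                n_in_s = int((counts[member_rows, k_idx] > 0).sum())
                enr = (eligible and n_in_s > MIN_MEMBERS_IN_STATE
                       and not math.isnan(l) and l > LOR_ENRICHED)
                rows.append((sub, tech, ps.assay, epi, "summits",
                             ijk_s, float(ik), float(total_summits),
                             float(k_total), l, n_total, n_in_s, eligible, enr))

    return pd.DataFrame(rows, columns=TENSOR_COLUMNS)


def _genomewide_cpg_state_counts(meth: MethylationTrack,
                                 covered: set[str]) -> pd.Series:
    from .core import HYPER_LOWER, HYPO_UPPER, MIN_CPG_READS
    counts = pd.Series(0.0, index=list(METHYLATION_DEFS))
    for chrom, (pos, frac, cov) in meth.cpgs.items():
        if chrom not in covered:
            continue
        missing = cov <= MIN_CPG_READS
        counts["missing"] += float(missing.sum())
        codes = np.where(frac < HYPO_UPPER, 0, np.where(frac > HYPER_LOWER, 2, 1))
        for name, code in (("hypo", 0), ("intermediate", 1), ("hyper", 2)):
            counts[name] += float((~missing & (codes == code)).sum())
    return counts


def subfamily_potential(tensor: pd.DataFrame) -> pd.DataFrame:
    """Per (subfamily, technique, state): annotated if ijk > 0 in >= 1
    epigenome, plus the fractions of epigenomes annotated and enriched."""
    def _summarize(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        return pd.Series({
            "annotated": bool((g["ijk"] > 0).any()),
            "fraction_annotated": float((g["ijk"] > 0).mean()),
            "fraction_enriched": float(g["enriched"].mean()),
            "n_epigenomes": n,
        })
    out = (tensor.groupby(["subfamily", "technique", "state"])
           .apply(_summarize, include_groups=False).reset_index())
    out["annotated"] = out["annotated"].astype(bool)
    return out


@dataclass
class PCAEmbedding:
    scores: pd.DataFrame           # objects x components
    explained_variance_ratio: np.ndarray
    n_variables: int


def pca_embed(tensor: pd.DataFrame, objects: str = "epigenomes",
              technique: str = "chromhmm", n_components: int = 5) -> PCAEmbedding:
    """PCA of the LOR tensor, on epigenomes or subfamilies.

    Only subfamilies with more than 30 members enter; undefined LOR cells
    (state absent from the epigenome) are imputed with the pseudocount
    floor, preserving "absent" as extreme depletion; variables are then
    restricted to variance > 0, centered, and scaled.
    """
    from sklearn.decomposition import PCA

    sub = tensor[(tensor["technique"] == technique) & tensor["eligible"]]
    if sub.empty:
        raise ValueError("no eligible cells for PCA")
    if objects == "epigenomes":
        wide = sub.pivot_table(index="epigenome", columns=["subfamily", "state"],
                               values="lor", aggfunc="first")
    elif objects == "subfamilies":
        wide = sub.pivot_table(index="subfamily", columns=["state", "epigenome"],
                               values="lor", aggfunc="first")
    else:
        raise ValueError(f"unknown objects {objects!r}")
    filled = wide.fillna(LOR_FLOOR)
    variances = filled.var(axis=0, ddof=0)
    filled = filled.loc[:, variances > 0]
    if filled.shape[1] == 0:
        raise ValueError("all variables have zero variance")
    x = (filled - filled.mean()) / filled.std(ddof=0)
    n_comp = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x.to_numpy())
    return PCAEmbedding(
        scores=pd.DataFrame(scores, index=filled.index,
                            columns=[f"PC{i + 1}" for i in range(scores.shape[1])]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_variables=filled.shape[1],
    )
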