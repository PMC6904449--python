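"""Per-TE epigenetic potential and dynamics across epigenomes.

"Potential" asks whether a TE is ever annotated with a state in any
epigenome; "persistence" asks in what fraction of epigenomes it stays
there.  Denominators always count only epigenomes with data for the
technique in question (and, per TE, exclude epigenomes where the TE's
chromosome is uncalled), so a missing WGBS track never deflates a
methylation fraction.

A TE in multiple chromHMM states within one epigenome counts once toward
each state's numerator, so per-epigenome state fractions summed over
states can exceed 1 for long TEs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate as _ann
from .annotate import StateCallMatrix
from .core import (
    ACTIVE_REGULATORY_STATES,
    REPRESSED_STATES,
    RPKM_EXPRESSED,
    TRANSCRIBED_STATES,
)

COMPOSITE_STATES: dict[str, tuple[str, ...]] = {
    "active_regulatory": ACTIVE_REGULATORY_STATES,
    "transcribed": TRANSCRIBED_STATES,
    "repressed": REPRESSED_STATES,
}

METHYLATION_DEFS = {
    "hypo": _ann.METH_HYPO,
    "intermediate": _ann.METH_INTER,
    "hyper": _ann.METH_HYPER,
    "missing": _ann.METH_MISSING,
}


def technique_mask(matrix: StateCallMatrix,
                   definition: str | Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a state definition to (in_state, has_data) bool matrices.

    ``definition`` may be a chromHMM state name, a composite name
    (active_regulatory / transcribed / repressed), a list of state names,
    a methylation state, "dhs", "k27ac", or "expressed" (RPKM > 1,
    strictly greater).
    """
    if isinstance(definition, str):
        if definition in COMPOSITE_STATES:
            definition = COMPOSITE_STATES[definition]
        elif definition in METHYLATION_DEFS:
            code = METHYLATION_DEFS[definition]
            has_cpg_data = ~np.isin(matrix.meth_state,
                                    (_ann.METH_ABSENT, _ann.METH_NO_CPG))
            return matrix.meth_state == code, has_cpg_data
        elif definition == "dhs":
            return matrix.dhs > 0, matrix.dhs >= 0
        elif definition == "k27ac":
            return matrix.k27ac > 0, matrix.k27ac >= 0
        elif definition == "expressed":
            has = ~np.isnan(matrix.expression)
            mask = np.zeros_like(has)
            mask[has] = matrix.expression[has] > RPKM_EXPRESSED
            return mask, has
        else:
            definition = [definition]
    unknown = set(definition) - set(matrix.state_alphabet)
    if unknown:
        raise KeyError(f"states not in alphabet: {sorted(unknown)}")
    return matrix.state_mask(list(definition)), ~matrix.nocall


def potential(matrix: StateCallMatrix,
              definition: str | Sequence[str]) -> pd.DataFrame:
    """Per-TE summary: epigenome count in state, data availability
    denominator, fraction, and the ever-in-state flag."""
    mask, has_data = technique_mask(matrix, definition)
    n_in = (mask & has_data).sum(axis=1)
    n_avail = has_data.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_avail > 0, n_in / np.maximum(n_avail, 1), np.nan)
    return pd.DataFrame({
        "te_id": matrix.te_ids,
        "n_epigenomes_in_state": n_in,
        "n_epigenomes_with_data": n_avail,
        "fraction_of_epigenomes": frac,
        "ever_in_state": n_in > 0,
    })


def ever_fraction(matrix: StateCallMatrix,
                  definition: str | Sequence[str]) -> float:
    """Fraction of TEs annotated with the state in >= 1 epigenome, among
    TEs with any data for the technique."""
    pot = potential(matrix, definition)
    with_data = pot["n_epigenomes_with_data"] > 0
    if not with_data.any():
        return float("nan")
    return float(pot.loc[with_data, "ever_in_state"].mean())


def state_count_histogram(matrix: StateCallMatrix,
                          kind: str = "chromhmm",
                          te_classes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Distinct states per TE across all epigenomes.

    chromHMM counts lie in [1, |alphabet|] for TEs with >= 1 call;
    methylation counts in [1, 4] over TEs with CpGs.
    """
    if kind == "chromhmm":
        counts = matrix.membership.any(axis=1).sum(axis=1)
        included = (~matrix.nocall).any(axis=1)
    elif kind == "methylation":
        codes = matrix.meth_state
        counts = np.zeros(matrix.n_te, dtype=np.int64)
        for code in METHYLATION_DEFS.values():
            counts += (codes == code).any(axis=1)
        included = matrix.has_cpgs()
    else:
        raise ValueError(f"unknown kind {kind!r}")
    df = pd.DataFrame({"te_id": matrix.te_ids, "n_states": counts,
                       "included": included})
    if te_classes is not None:
        df["te_class"] = [te_classes[t] for t in matrix.te_ids]
    return df[df["included"]].drop(columns="included")


def cooccurrence(matrix: StateCallMatrix, kind: str = "chromhmm") -> pd.DataFrame:
    """For TEs ever in state s1, the mean per-TE fraction of epigenomes
    annotated with state s2 (rows s1, columns s2)."""
    if kind == "chromhmm":
        names = list(matrix.state_alphabet)
        masks = [matrix.state_mask(s) for s in names]
        has_data = ~matrix.nocall
    elif kind == "methylation":
        names = list(METHYLATION_DEFS)
        masks = [matrix.meth_state == c for c in METHYLATION_DEFS.values()]
        has_data = ~np.isin(matrix.meth_state,
                            (_ann.METH_ABSENT, _ann.METH_NO_CPG))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    n_avail = has_data.sum(axis=1)
    out = np.full((len(names), len(names)), np.nan)
    fracs = np.stack([
        np.where(n_avail > 0, (m & has_data).sum(axis=1) / np.maximum(n_avail, 1), np.nan)
        for m in masks
    ])  # (n_states, n_te)
    for i, mi in enumerate(masks):
        ever = (mi & has_data).any(axis=1)
        if ever.any():
            out[i] = np.nanmean(fracs[:, ever], axis=1)
    return pd.DataFrame(out, index=names, columns=names)


def consistent_state_tes(matrix: StateCallMatrix,
                         definition: str | Sequence[str],
                         threshold: float = 1.0) -> list[str]:
    """TE ids annotated with the state in >= ``threshold`` of the
    epigenomes with data (1.0 and 0.9 are the standard thresholds)."""
    pot = potential(matrix, definition)
    sel = (pot["n_epigenomes_with_data"] > 0) & (
        pot["fraction_of_epigenomes"] >= threshold - 1e-12
    ) & pot["ever_in_state"]
    return pot.loc[sel, "te_id"].tolist()


def class_composition(te_ids: Sequence[str],
                      te_classes: Mapping[str, str]) -> pd.Series:
    """Class breakdown of a TE list (bookkeeping for consistent-state sets)."""
    if not te_ids:
        return pd.Series(dtype=float)
    classes = pd.Series([te_classes[t] for t in te_ids])
    return classes.value_counts(normalize=True)
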