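"""Simulate a toy multi-epigenome study and annotate every TE.

Builds the default synthetic bundle (2 x 1 Mb genome, ~4,700 TEs in 20
subfamilies, 12 epigenomes in 4 tissue groups), assigns each TE its
chromHMM states, methylation state, peak overlaps, and expression in
every epigenome, and prints how often TEs are ever in each kind of
active state.
"""

from teprofiler import (
    SimulationConfig,
    build_state_call_matrix,
    ever_fraction,
    proportion_in_states,
    simulate,
)

dataset = simulate(SimulationConfig(seed=1))
print(f"{len(dataset.tes)} TEs, {len(dataset.segmentations)} epigenomes")

matrix = build_state_call_matrix(
    dataset.tes, dataset.segmentations, dataset.methylation,
    dataset.dhs_peaks, dataset.k27ac_peaks, dataset.coverage,
)

# Fraction of TEs annotated with the state in at least one epigenome.
# "active_regulatory" pools the TssA/TssAFlnk/TxFlnk/EnhG/Enh states;
# dhs/k27ac require a peak summit inside the TE; expressed means RPKM > 1.
for definition in ("active_regulatory", "transcribed", "repressed",
                   "dhs", "k27ac", "hypo", "expressed"):
    print(f"ever {definition:>17}: {100 * ever_fraction(matrix, definition):5.1f}% of TEs")

# Base-level composition: what fraction of TE bases sits in each state,
# pooled over all epigenomes (rows sum to 1).
table = proportion_in_states(dataset.tes, segmentations=dataset.segmentations)
print("\npooled TE base composition (top 5 states):")
print(table.loc["all"].sort_values(ascending=False).head(5).round(3).to_string())
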