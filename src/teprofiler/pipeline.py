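"""End-to-end orchestration: simulate or load a bundle, annotate, and run
every analysis stage into an output directory of tab-delimited tables
plus a JSON run manifest recording seeds and thresholds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .annotate import build_state_call_matrix
from .composition import contribution_of_features, proportion_in_states
from .core import ROADMAP_15_STATES
from .dynamics import (
    COMPOSITE_STATES,
    cooccurrence,
    ever_fraction,
    potential,
    state_count_histogram,
)
from .enrichment import build_enrichment_tensor, subfamily_potential
from .nulls import ShuffleSpec, preferential_enrichment_test, shuffle_tes
from .simulate import SimulatedDataset, SimulationConfig, simulate

DEFAULT_THRESHOLDS = {
    "lor_cutoff": 1.5,
    "min_subfamily_members": 30,
    "min_members_in_state": 10,
    "rpkm_cutoff": 1.0,
    "methylation_bins": [0.30, 0.70],
    "min_cpg_reads_exclusive": 3,
    "shuffle_iterations": 10,
    "n_permutations": 1000,
    "consistency_thresholds": [0.9, 1.0],
}


@dataclass
class PipelineConfig:
    seed: int = 0
    mode: str = "window_center"
    output_dir: str = "teprofiler_out"
    input_dir: str | None = None      # None -> simulate
    shuffle_iterations: int = 10
    n_permutations: int = 1000
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def write_bundle(dataset: SimulatedDataset, outdir) -> None:
    """Serialize a simulated bundle to plain-text files (round-trippable
    through the genomic_io readers)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, size in dataset.assembly.chromosomes:
            fh.write(f"{chrom}\t{size}\n")
    with open(out / "gaps.bed", "w") as fh:
        for gap in dataset.assembly.gaps:
            fh.write(f"{gap.chrom}\t{gap.start}\t{gap.end}\n")
    gio.write_te_bed(out / "tes.bed", dataset.tes)
    gio.write_metadata(out / "metadata.tsv", dataset.metadata)
    seg_dir = out / "segmentations"
    seg_dir.mkdir(exist_ok=True)
    for epi, seg in dataset.segmentations.items():
        gio.write_segmentation(seg_dir / f"{epi}.bed", seg)
    for layer, writer, suffix in (
        (dataset.methylation, gio.write_methylation, "methylation.tsv"),
        (dataset.dhs_peaks, gio.write_narrowpeak, "DHS.narrowPeak"),
        (dataset.k27ac_peaks, gio.write_narrowpeak, "H3K27ac.narrowPeak"),
        (dataset.coverage, gio.write_coverage_bedgraph, "rna.bedgraph"),
    ):
        for epi, track in layer.items():
            writer(out / f"{epi}-{suffix}", track)
    with open(out / "cpg_islands.bed", "w") as fh:
        for iv in dataset.cpg_islands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "planted_folds": {
                "|".join(k): v
                for k, v in dataset.ground_truth.planted_folds.items()
            },
        }, fh, indent=1)


def load_bundle(indir) -> dict:
    """Load a bundle directory written by :func:`write_bundle`."""
    ind = Path(indir)
    assembly = gio.read_chrom_sizes(ind / "chrom.sizes", name="bundle")
    if (ind / "gaps.bed").exists():
        assembly.gaps = gio.read_gaps_bed(ind / "gaps.bed", assembly)
    tes = gio.read_te_bed(ind / "tes.bed", assembly)
    metadata = gio.read_metadata(ind / "metadata.tsv")
    segmentations = {}
    for path in sorted((ind / "segmentations").glob("*.bed")):
        epi = path.stem
        segmentations[epi] = gio.read_segmentation(
            path, assembly, ROADMAP_15_STATES, epi)
    layers = {"methylation": {}, "dhs_peaks": {}, "k27ac_peaks": {}, "coverage": {}}
    for path in sorted(ind.glob("*-methylation.tsv")):
        epi = path.name.split("-")[0]
        layers["methylation"][epi] = gio.read_methylation(path, epi)
    for path in sorted(ind.glob("*-DHS.narrowPeak")):
        epi = path.name.split("-")[0]
        layers["dhs_peaks"][epi] = gio.read_narrowpeak(path, assembly, epi, "DHS")
    for path in sorted(ind.glob("*-H3K27ac.narrowPeak")):
        epi = path.name.split("-")[0]
        layers["k27ac_peaks"][epi] = gio.read_narrowpeak(path, assembly, epi, "H3K27ac")
    for path in sorted(ind.glob("*-rna.bedgraph")):
        epi = path.name.split("-")[0]
        layers["coverage"][epi] = gio.read_coverage_bedgraph(path, epi)
    return {"assembly": assembly, "tes": tes, "metadata": metadata,
            "segmentations": segmentations, **layers}


def run(config: PipelineConfig) -> dict:
    """Run every stage; returns {table name: DataFrame} and writes the
    tables plus a manifest under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        dataset = simulate(SimulationConfig(seed=config.seed))
        bundle = {
            "assembly": dataset.assembly, "tes": dataset.tes,
            "metadata": dataset.metadata,
            "segmentations": dataset.segmentations,
            "methylation": dataset.methylation,
            "dhs_peaks": dataset.dhs_peaks,
            "k27ac_peaks": dataset.k27ac_peaks,
            "coverage": dataset.coverage,
        }
    else:
        bundle = load_bundle(config.input_dir)

    tes = bundle["tes"]
    matrix = build_state_call_matrix(
        tes, bundle["segmentations"], bundle["methylation"],
        bundle["dhs_peaks"], bundle["k27ac_peaks"], bundle["coverage"],
        mode=config.mode,
    )
    results: dict[str, pd.DataFrame] = {}
    results["state_calls"] = matrix.to_frame()
    results["composition"] = proportion_in_states(
        tes, segmentations=bundle["segmentations"])
    by_class: dict[str, list] = {}
    for te in tes:
        by_class.setdefault(te.te_class, []).append(te)
    results["contribution"] = contribution_of_features(
        tes, bundle["segmentations"], class_features=by_class)
    pot_rows = []
    for name in list(matrix.state_alphabet) + list(COMPOSITE_STATES) + \
            ["dhs", "k27ac", "expressed"]:
        try:
            frac = ever_fraction(matrix, name)
        except KeyError:
            continue
        pot_rows.append((name, frac))
    results["ever_fractions"] = pd.DataFrame(
        pot_rows, columns=["state", "fraction_of_tes_ever_in_state"])
    results["state_counts"] = state_count_histogram(
        matrix, te_classes={te.id: te.te_class for te in tes})
    results["cooccurrence"] = cooccurrence(matrix)
    tensor = build_enrichment_tensor(
        tes, bundle["segmentations"], matrix,
        methylation=bundle["methylation"], dhs_peaks=bundle["dhs_peaks"],
        k27ac_peaks=bundle["k27ac_peaks"])
    results["enrichment"] = tensor
    results["subfamily_potential"] = subfamily_potential(tensor)
    results["preferential_enrichment"] = preferential_enrichment_test(
        tensor, bundle["metadata"], scheme="group",
        n_perm=config.n_permutations, seed=config.seed)
    shuffles = shuffle_tes(tes, bundle["assembly"],
                           ShuffleSpec(n_iterations=1, seed=config.seed))
    shuffle_matrix = build_state_call_matrix(
        shuffles[0], bundle["segmentations"], mode=config.mode)
    shuffle_tensor = build_enrichment_tensor(
        shuffles[0], bundle["segmentations"], shuffle_matrix)
    results["enrichment_shuffled"] = shuffle_tensor

    for name, df in results.items():
        df.to_csv(out / f"{name}.tsv", sep="\t",
                  index=name in ("composition", "cooccurrence"))
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": config.thresholds,
        "n_tes": len(tes),
        "n_epigenomes": len(bundle["segmentations"]),
        "tables": sorted(results),
        "table_checksums": {
            name: hashlib.sha256(
                df.to_csv(index=False).encode()).hexdigest()[:16]
            for name, df in results.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results
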