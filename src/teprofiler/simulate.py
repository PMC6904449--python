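"""Synthetic multi-epigenome generator with planted, recoverable effects.

The generator emits the same kinds of inputs the real pipeline consumes
(TE annotations, per-epigenome chromatin-state segmentations, peak sets
with summits, per-CpG methylation, RNA coverage, epigenome metadata) on
a toy genome, with ground truth recorded for every planted effect.

Planting model.  The background segmentation assigns each fixed-width
window a state drawn i.i.d. from the background state distribution
``p``.  To plant subfamily ``i`` at fold ``f`` in state ``j`` of an
epigenome, every window overlapping a member of ``i`` draws state ``j``
with probability ``f * p_j`` (other states renormalized), and the
distribution used for all remaining windows is adjusted so that the
genome-wide marginal of every state stays exactly ``p``.  The realized
subfamily base fraction in ``j`` is then ``f`` times the genome-wide
fraction in expectation, so the log-odds enrichment recovers
``log2(f)``.

Each data layer draws from its own RNG stream derived from the master
seed, so layers are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ACTIVE_REGULATORY_STATES,
    ROADMAP_15_STATES,
    TRANSCRIBED_STATES,
    CoverageTrack,
    EpigenomeMetadata,
    GenomeAssembly,
    GenomicInterval,
    MethylationTrack,
    PeakSet,
    Segmentation,
    TEAnnotation,
)

# Background state frequencies for the toy genome: quiescent-heavy with
# small active states, loosely shaped like a somatic chromatin landscape.
DEFAULT_STATE_FREQS = {
    "1_TssA": 0.015, "2_TssAFlnk": 0.015, "3_TxFlnk": 0.01, "4_Tx": 0.06,
    "5_TxWk": 0.10, "6_EnhG": 0.015, "7_Enh": 0.05, "8_ZNF/Rpts": 0.01,
    "9_Het": 0.06, "10_TssBiv": 0.01, "11_BivFlnk": 0.01, "12_EnhBiv": 0.015,
    "13_ReprPC": 0.03, "14_ReprPCWk": 0.06, "15_Quies": 0.54,
}

# Beta(a, b) methylation emission by chromatin context: active contexts
# are hypomethylated, repressed/quiescent hypermethylated.
DEFAULT_METH_BETA = {
    "active": (1.2, 8.0),
    "bivalent": (2.0, 2.0),
    "default": (8.0, 1.5),
}

# Mean RNA coverage emitted per window by chromatin context.
DEFAULT_EXPRESSION_MEAN = {"transcribed": 4.0, "default": 0.15}

BIVALENT_STATES = ("10_TssBiv", "11_BivFlnk", "12_EnhBiv")


class InfeasibleFoldError(ValueError):
    """Requested planted fold exceeds what the state abundance allows."""

    def __init__(self, subfamily: str, state: str, fold: float, max_fold: float):
        self.max_fold = max_fold
        super().__init__(
            f"fold {fold} for ({subfamily}, {state}) is infeasible; "
            f"maximum feasible fold is about {max_fold:.2f}"
        )


@dataclass
class PlantedEnrichment:
    """Plant ``subfamily`` at ``fold`` x background in ``state`` for every
    epigenome whose metadata ``scheme`` equals ``value``."""

    state: str
    scheme: str  # metadata category scheme, e.g. "group"
    value: str   # category value, e.g. "Blood"
    fold: float

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("planted fold must be positive")


@dataclass
class SubfamilySpec:
    name: str
    te_class: str
    family: str
    n_members: int
    length_mean: float = 250.0
    length_log_sd: float = 0.35
    sub_prop_mean: float = 0.15
    sub_prop_sd: float = 0.05
    cpg_density: float = 0.02   # expected CpGs per bp
    planted: list[PlantedEnrichment] = field(default_factory=list)


def default_subfamilies() -> list[SubfamilySpec]:
    """Twenty toy subfamilies (~5,000 members) shaped like the major TE
    classes, with a handful of planted tissue-restricted enrichments."""
    specs: list[SubfamilySpec] = []
    sine_planted = {
        "SINE1_sim": [PlantedEnrichment("7_Enh", "group", "Blood", 5.0)],
    }
    for i in range(1, 7):
        name = f"SINE{i}_sim"
        specs.append(SubfamilySpec(
            name, "SINE", "AluSim" if i <= 3 else "MIRSim", 400,
            length_mean=150, sub_prop_mean=0.08 + 0.05 * (i - 1),
            cpg_density=max(0.05 - 0.006 * (i - 1), 0.01),
            planted=sine_planted.get(name, []),
        ))
    for i in range(1, 5):
        specs.append(SubfamilySpec(
            f"LINE{i}_sim", "LINE", "L1Sim", 180, length_mean=350,
            sub_prop_mean=0.10 + 0.06 * i, cpg_density=0.008,
        ))
    ltr_planted = {
        "LTR1_sim": [PlantedEnrichment("1_TssA", "group", "ESC", 6.0)],
        "LTR2_sim": [PlantedEnrichment("9_Het", "group", "Brain", 4.0)],
    }
    for i in range(1, 5):
        specs.append(SubfamilySpec(
            f"LTR{i}_sim", "LTR", "ERV1Sim", 220, length_mean=250,
            sub_prop_mean=0.07 + 0.05 * i, cpg_density=0.015,
            planted=ltr_planted.get(f"LTR{i}_sim", []),
        ))
    dna_planted = {
        "DNA1_sim": [PlantedEnrichment("7_Enh", "group", "Digestive", 5.0)],
    }
    for i in range(1, 4):
        specs.append(SubfamilySpec(
            f"DNA{i}_sim", "DNA", "TcMarSim", 160, length_mean=200,
            sub_prop_mean=0.12 + 0.07 * i, cpg_density=0.012,
            planted=dna_planted.get(f"DNA{i}_sim", []),
        ))
    specs.append(SubfamilySpec("SVA1_sim", "SVA", "SVASim", 40,
                               length_mean=700, sub_prop_mean=0.04,
                               cpg_density=0.09))
    for i in (1, 2):
        specs.append(SubfamilySpec(
            f"OTH{i}_sim", "Other", "UnkSim", 100, length_mean=150,
            sub_prop_mean=0.40, sub_prop_sd=0.08, cpg_density=0.006,
        ))
    return specs


def default_metadata(n_epigenomes: int) -> dict[str, EpigenomeMetadata]:
    """Twelve toy epigenomes in four groups of three by default."""
    groups = ["ESC", "Blood", "Brain", "Digestive"]
    anatomy = {"ESC": "embryo", "Blood": "blood", "Brain": "brain",
               "Digestive": "gut"}
    germ = {"ESC": "pluripotent", "Blood": "mesoderm", "Brain": "ectoderm",
            "Digestive": "endoderm"}
    out = {}
    for i in range(n_epigenomes):
        g = groups[i % len(groups)]
        eid = f"E{i + 1:03d}"
        out[eid] = EpigenomeMetadata(
            epigenome_id=eid, group=g, anatomy=anatomy[g],
            type="cell_line" if i >= n_epigenomes - 2 else "primary",
            age_category="fetal" if i % 2 else "adult",
            germ_layer=germ[g], cancer=(i == n_epigenomes - 1),
        )
    return out


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    gap_fraction: float = 0.02
    window_bp: int = 200
    state_alphabet: tuple[str, ...] = ROADMAP_15_STATES
    state_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATE_FREQS))
    n_epigenomes: int = 12
    metadata: dict[str, EpigenomeMetadata] | None = None
    subfamilies: list[SubfamilySpec] = field(default_factory=default_subfamilies)
    background_cpg_density: float = 0.008
    meth_beta: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_METH_BETA))
    cpg_read_mean: float = 12.0
    low_coverage_fraction: float = 0.10  # CpGs planted with <= 3 reads
    peaks_per_mb: float = 60.0
    peak_width: int = 300
    peak_active_bias: float = 0.5  # fraction of peaks seeded in active windows
    expression_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSION_MEAN))
    # which epigenomes carry each layer (indices into the sorted id list);
    # None means all
    wgbs_epigenomes: tuple[int, ...] | None = None
    dhs_epigenomes: tuple[int, ...] | None = None
    k27ac_epigenomes: tuple[int, ...] | None = None
    rna_epigenomes: tuple[int, ...] | None = None

    def __post_init__(self):
        total = sum(self.state_freqs.get(s, 0.0) for s in self.state_alphabet)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("state frequencies must sum to 1 over the alphabet")


@dataclass
class GroundTruth:
    """Planted effects: folds per (subfamily, state, epigenome) and, once
    a second species is simulated, the ortholog map and conservation
    probability."""

    planted_folds: dict[tuple[str, str, str], float] = field(default_factory=dict)
    ortholog_map: dict[str, str] = field(default_factory=dict)  # source id -> target id
    conservation_prob: float | None = None

    def expected_lor(self, subfamily: str, state: str, epigenome: str) -> float:
        return math.log2(self.planted_folds.get((subfamily, state, epigenome), 1.0))


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    assembly: GenomeAssembly
    tes: list[TEAnnotation]
    segmentations: dict[str, Segmentation]
    methylation: dict[str, MethylationTrack]
    dhs_peaks: dict[str, PeakSet]
    k27ac_peaks: dict[str, PeakSet]
    coverage: dict[str, CoverageTrack]
    metadata: dict[str, EpigenomeMetadata]
    cpg_islands: list[GenomicInterval]
    ground_truth: GroundTruth

    @property
    def epigenome_ids(self) -> list[str]:
        return sorted(self.segmentations)


def _build_assembly(config: SimulationConfig) -> GenomeAssembly:
    gaps = []
    for chrom, length in config.chrom_lengths:
        gap_len = int(length * config.gap_fraction)
        if gap_len > 0:
            mid = length // 2
            gaps.append(GenomicInterval(chrom, mid - gap_len // 2,
                                        mid - gap_len // 2 + gap_len))
    return GenomeAssembly(name="toy", chromosomes=list(config.chrom_lengths),
                          gaps=gaps)


def _allowed_segments(assembly: GenomeAssembly) -> list[tuple[str, int, int]]:
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
    return segments


def _place_tes(config: SimulationConfig, assembly: GenomeAssembly,
               rng: np.random.Generator) -> list[TEAnnotation]:
    """Place all subfamily members uniformly over non-gap space without
    overlap (rejection sampling with a sorted occupancy list)."""
    import bisect

    segments = _allowed_segments(assembly)
    weights = np.array([e - s for _, s, e in segments], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}

    # draw all lengths up front and place longest-first so long elements
    # still find free runs once the genome fills up
    draws: list[tuple[int, SubfamilySpec]] = []
    for spec in config.subfamilies:
        for _ in range(spec.n_members):
            length = min(
                max(30, int(rng.lognormal(
                    math.log(spec.length_mean), spec.length_log_sd))),
                int(4 * spec.length_mean))
            draws.append((length, spec))
    draws.sort(key=lambda d: -d[0])

    tes: list[TEAnnotation] = []
    n = 0
    for length, spec in draws:
        placed = False
        for _try in range(2000):
            si = rng.choice(len(segments), p=weights)
            chrom, s0, e0 = segments[si]
            if e0 - s0 <= length:
                continue
            start = int(rng.integers(s0, e0 - length))
            end = start + length
            occ = occupied[chrom]
            j = bisect.bisect_left(occ, (start, start))
            if j > 0 and occ[j - 1][1] > start:
                continue
            if j < len(occ) and occ[j][0] < end:
                continue
            occ.insert(j, (start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {length} bp TE; genome too crowded"
            )
        sub_prop = float(np.clip(
            rng.normal(spec.sub_prop_mean, spec.sub_prop_sd), 0.0, 0.70))
        n += 1
        tes.append(TEAnnotation(
            interval=GenomicInterval(chrom, start, end,
                                     "+" if rng.random() < 0.5 else "-"),
            subfamily=spec.name, family=spec.family, te_class=spec.te_class,
            substitution_proportion=sub_prop,
            mappability=float(np.clip(rng.beta(8, 1.2), 0, 1)),
            id=f"TE{n:06d}",
        ))
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return tes


def _window_grid(assembly: GenomeAssembly, window_bp: int) -> dict[str, int]:
    return {c: assembly.size(c) // window_bp for c in assembly.chrom_names}


def _planted_window_sets(tes, planted_for_epi, window_bp, n_windows):
    """Per chromosome, map window index -> plant index for every window
    overlapping a member of a planted subfamily (first plant wins)."""
    assign: dict[str, np.ndarray] = {
        c: np.full(nw, -1, dtype=np.int32) for c, nw in n_windows.items()
    }
    by_subfamily: dict[str, list[int]] = {}
    for m, (sub, _state, _fold) in enumerate(planted_for_epi):
        by_subfamily.setdefault(sub, []).append(m)
    for te in tes:
        plants = by_subfamily.get(te.subfamily)
        if not plants:
            continue
        m = plants[0]
        iv = te.interval
        w0 = iv.start // window_bp
        w1 = min((iv.end - 1) // window_bp, n_windows[iv.chrom] - 1)
        arr = assign[iv.chrom]
        for w in range(w0, w1 + 1):
            if arr[w] == -1:
                arr[w] = m
    return assign


def _plant_distributions(p: np.ndarray, planted_for_epi, state_index,
                         window_fracs: np.ndarray,
                         subfamily_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-plant window distributions P_m and the compensated background
    distribution q keeping every genome-wide state marginal at p."""
    n_states = len(p)
    n_plants = len(planted_for_epi)
    P = np.zeros((n_plants, n_states))
    for m, (sub, state, fold) in enumerate(planted_for_epi):
        j = state_index[state]
        pj = fold * p[j]
        if pj > 1.0:
            raise InfeasibleFoldError(sub, state, fold, 1.0 / p[j])
        P[m] = (1.0 - pj) * p / (1.0 - p[j])
        P[m, j] = pj
    w_rest = 1.0 - window_fracs.sum()
    q = (p - window_fracs @ P) / w_rest
    if np.any(q < -1e-12):
        # solve, per offending plant, for the fold at which its own
        # planted state's background probability hits zero
        worst = int(np.argmin(q))
        m_bad = max(range(n_plants),
                    key=lambda m: P[m, worst] * window_fracs[m])
        sub, state, fold = planted_for_epi[m_bad]
        j = state_index[state]
        others = sum(window_fracs[m] * P[m, j]
                     for m in range(n_plants) if m != m_bad)
        # p_j - others - f*p_j*w_m >= 0
        max_fold = (p[j] - others) / (p[j] * window_fracs[m_bad])
        raise InfeasibleFoldError(sub, state, fold, max(max_fold, 0.0))
    q = np.clip(q, 0.0, None)
    q /= q.sum()
    return P, q


def _simulate_segmentation(config, assembly, tes, epi_id, metadata,
                           rng: np.random.Generator) -> tuple[Segmentation, GroundTruth]:
    alphabet = config.state_alphabet
    state_index = {s: i for i, s in enumerate(alphabet)}
    p = np.array([config.state_freqs[s] for s in alphabet])
    meta = metadata[epi_id]
    planted_for_epi = [
        (spec.name, pe.state, pe.fold)
        for spec in config.subfamilies
        for pe in spec.planted
        if meta.label(pe.scheme) == pe.value
    ]
    n_windows = _window_grid(assembly, config.window_bp)
    total_windows = sum(n_windows.values())
    assign = _planted_window_sets(tes, planted_for_epi, config.window_bp, n_windows)
    counts = np.zeros(len(planted_for_epi))
    for arr in assign.values():
        for m in range(len(planted_for_epi)):
            counts[m] += int((arr == m).sum())
    window_fracs = counts / total_windows

    gt: dict[tuple[str, str, str], float] = {}
    if planted_for_epi:
        P, q = _plant_distributions(p, planted_for_epi, state_index,
                                    window_fracs, [s.name for s in config.subfamilies])
        for sub, state, fold in planted_for_epi:
            gt[(sub, state, epi_id)] = fold
    else:
        P, q = np.zeros((0, len(p))), p

    blocks = {}
    for chrom, nw in n_windows.items():
        arr = assign[chrom]
        states = np.empty(nw, dtype=np.int16)
        bg = arr == -1
        states[bg] = rng.choice(len(p), size=int(bg.sum()), p=q)
        for m in range(len(planted_for_epi)):
            sel = arr == m
            if sel.any():
                states[sel] = rng.choice(len(p), size=int(sel.sum()), p=P[m])
        bounds = np.arange(nw + 1, dtype=np.int64) * config.window_bp
        # collapse runs of equal state into blocks
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], change))
        block_bounds = np.concatenate((bounds[starts], [bounds[nw]]))
        blocks[chrom] = (block_bounds, states[starts])
    seg = Segmentation(epi_id, alphabet, blocks, window_bp=config.window_bp)
    return seg, gt


def _active_codes(alphabet) -> set[int]:
    return {alphabet.index(s) for s in ACTIVE_REGULATORY_STATES if s in alphabet}


def _simulate_peaks(config, assembly, seg, tes_by_plant, epi_id, assay,
                    rng: np.random.Generator) -> PeakSet:
    """Peaks placed partly uniformly, partly in active-state windows, plus
    one guaranteed summit inside a sample of planted-subfamily members."""
    peaks = []
    width = config.peak_width
    active = _active_codes(list(seg.state_alphabet))
    for chrom in assembly.chrom_names:
        n_peaks = int(config.peaks_per_mb * assembly.size(chrom) / 1e6)
        bounds, states = seg.blocks[chrom]
        active_blocks = [i for i in range(len(states)) if int(states[i]) in active]
        for _ in range(n_peaks):
            if active_blocks and rng.random() < config.peak_active_bias:
                i = active_blocks[int(rng.integers(len(active_blocks)))]
                lo, hi = int(bounds[i]), int(bounds[i + 1])
                center = int(rng.integers(lo, hi))
            else:
                center = int(rng.integers(0, assembly.size(chrom)))
            start = max(0, center - width // 2)
            end = min(assembly.size(chrom), start + width)
            summit = min(max(center - start, 0), end - start - 1)
            peaks.append((GenomicInterval(chrom, start, end), summit))
    for te in tes_by_plant:
        iv = te.interval
        center = iv.start + iv.width // 2
        start = max(0, center - width // 2)
        end = min(assembly.size(iv.chrom), start + width)
        peaks.append((GenomicInterval(iv.chrom, start, end), center - start))
    return PeakSet(epigenome_id=epi_id, assay=assay, peaks=peaks)


def _simulate_cpg_sites(config, assembly, tes, rng: np.random.Generator):
    """CpG positions (strictly increasing, >= 2 bp apart): background
    density genome-wide plus per-subfamily density inside TEs."""
    sites: dict[str, np.ndarray] = {}
    density = {spec.name: spec.cpg_density for spec in config.subfamilies}
    for chrom in assembly.chrom_names:
        slots = np.arange(0, assembly.size(chrom) - 1, 2, dtype=np.int64)
        prob = np.full(len(slots), min(config.background_cpg_density * 2, 1.0))
        for te in tes:
            if te.interval.chrom != chrom:
                continue
            lo = (te.interval.start + 1) // 2
            hi = te.interval.end // 2
            # CpG density decays with evolutionary age within the subfamily
            d = density[te.subfamily] * math.exp(-2.0 * te.jc_distance)
            prob[lo:hi] = min(d * 2, 1.0)
        keep = rng.random(len(slots)) < prob
        sites[chrom] = slots[keep]
    return sites


def _simulate_methylation(config, seg, cpg_sites, epi_id,
                          rng: np.random.Generator) -> MethylationTrack:
    alphabet = list(seg.state_alphabet)
    active = _active_codes(alphabet)
    bivalent = {alphabet.index(s) for s in BIVALENT_STATES if s in alphabet}
    cpgs = {}
    for chrom, pos in cpg_sites.items():
        bounds, states = seg.blocks[chrom]
        idx = np.clip(np.searchsorted(bounds, pos, side="right") - 1, 0, len(states) - 1)
        st = states[idx]
        a = np.empty(len(pos))
        b = np.empty(len(pos))
        ctx = np.full(len(pos), 2)  # 0 active, 1 bivalent, 2 default
        ctx[np.isin(st, list(active))] = 0
        ctx[np.isin(st, list(bivalent))] = 1
        for c, key in enumerate(("active", "bivalent", "default")):
            aa, bb = config.meth_beta[key]
            a[ctx == c], b[ctx == c] = aa, bb
        frac = rng.beta(a, b)
        cov = rng.poisson(config.cpg_read_mean, size=len(pos))
        low = rng.random(len(pos)) < config.low_coverage_fraction
        cov[low] = rng.integers(0, 4, size=int(low.sum()))
        frac[cov == 0] = 0.0
        cpgs[chrom] = (pos, frac, cov)
    return MethylationTrack(epi_id, cpgs)


def _simulate_coverage(config, seg, epi_id, rng: np.random.Generator) -> CoverageTrack:
    alphabet = list(seg.state_alphabet)
    transcribed = {alphabet.index(s) for s in TRANSCRIBED_STATES if s in alphabet}
    runs = {}
    for chrom, (bounds, states) in seg.blocks.items():
        means = np.where(np.isin(states, list(transcribed)),
                         config.expression_mean["transcribed"],
                         config.expression_mean["default"])
        values = rng.gamma(2.0, means / 2.0)
        runs[chrom] = (bounds.copy(), values)
    return CoverageTrack(epi_id, runs, normalization_factor=1.0)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full toy bundle; reproducible from ``config.seed``."""
    master = np.random.SeedSequence(config.seed)
    keys = ("placement", "segmentation", "peaks", "cpg", "methylation",
            "coverage", "islands")
    streams = dict(zip(keys, (np.random.default_rng(s)
                              for s in master.spawn(len(keys)))))

    assembly = _build_assembly(config)
    metadata = config.metadata or default_metadata(config.n_epigenomes)
    epi_ids = sorted(metadata)
    if len(epi_ids) != config.n_epigenomes:
        raise ValueError("metadata size disagrees with n_epigenomes")

    tes = _place_tes(config, assembly, streams["placement"])

    segmentations: dict[str, Segmentation] = {}
    ground_truth = GroundTruth()
    seg_seeds = np.random.SeedSequence(config.seed + 1).spawn(len(epi_ids))
    for epi_id, ss in zip(epi_ids, seg_seeds):
        seg, gt = _simulate_segmentation(config, assembly, tes, epi_id,
                                         metadata, np.random.default_rng(ss))
        segmentations[epi_id] = seg
        ground_truth.planted_folds.update(gt)

    def layer_ids(indices):
        if indices is None:
            return epi_ids
        return [epi_ids[i] for i in indices]

    # guaranteed summits go into members of subfamilies whose planted
    # enrichment applies to the epigenome, keeping the techniques
    # concordant (active chromatin, open chromatin, acetylation)
    members_of: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        members_of.setdefault(te.subfamily, []).append(te)

    def planted_sample(epi_id):
        meta = metadata[epi_id]
        out: list[TEAnnotation] = []
        for spec in config.subfamilies:
            if any(meta.label(pe.scheme) == pe.value for pe in spec.planted):
                members = members_of.get(spec.name, [])
                out.extend(members[:: max(len(members) // 40, 1)])
        return out

    dhs_peaks, k27ac_peaks = {}, {}
    peak_rng = streams["peaks"]
    for epi_id in layer_ids(config.dhs_epigenomes):
        dhs_peaks[epi_id] = _simulate_peaks(
            config, assembly, segmentations[epi_id], planted_sample(epi_id),
            epi_id, "DHS", peak_rng)
    for epi_id in layer_ids(config.k27ac_epigenomes):
        k27ac_peaks[epi_id] = _simulate_peaks(
            config, assembly, segmentations[epi_id], planted_sample(epi_id),
            epi_id, "H3K27ac", peak_rng)

    cpg_sites = _simulate_cpg_sites(config, assembly, tes, streams["cpg"])
    methylation = {}
    for epi_id in layer_ids(config.wgbs_epigenomes):
        methylation[epi_id] = _simulate_methylation(
            config, segmentations[epi_id], cpg_sites, epi_id, streams["methylation"])

    coverage = {}
    for epi_id in layer_ids(config.rna_epigenomes):
        coverage[epi_id] = _simulate_coverage(
            config, segmentations[epi_id], epi_id, streams["coverage"])

    # CpG islands: overlap probability declines with TE age, so the
    # age-trend logistic model has a planted negative coefficient
    island_rng = streams["islands"]
    islands = []
    for te in tes:
        p_island = 1.0 / (1.0 + math.exp(-(1.0 - 8.0 * te.jc_distance)))
        if _te_cpg_density_high(te, config) and island_rng.random() < p_island:
            iv = te.interval
            islands.append(GenomicInterval(iv.chrom, iv.start, iv.end))

    return SimulatedDataset(
        config=config, assembly=assembly, tes=tes,
        segmentations=segmentations, methylation=methylation,
        dhs_peaks=dhs_peaks, k27ac_peaks=k27ac_peaks, coverage=coverage,
        metadata=metadata, cpg_islands=islands, ground_truth=ground_truth,
    )


@dataclass
class OrthologBundle:
    """Second-species dataset with a lifted-coordinate table."""

    assembly: GenomeAssembly
    tes: list[TEAnnotation]
    segmentations: dict[str, Segmentation]
    methylation: dict[str, MethylationTrack]
    lifted: list[tuple[str, GenomicInterval]]  # (source TE id, lifted interval)
    epigenome_pairs: list[tuple[str, str]]     # (species-1 id, species-2 id)
    metadata: dict[str, EpigenomeMetadata]


def simulate_ortholog_species(
    dataset: SimulatedDataset,
    conservation_prob: float,
    liftover_rate: float = 0.6,
    target_rate: float = 0.9,
    seed: int = 0,
    state_alphabet: tuple[str, ...] | None = None,
    n_epigenomes: int | None = None,
) -> OrthologBundle:
    """Simulate a second species with lifted coordinates and planted
    epigenetic conservation.

    A ``liftover_rate`` fraction of species-1 TEs receive a lifted
    interval in species 2; with probability ``target_rate`` a
    same-subfamily target TE overlaps it (an ortholog pair).  In each
    species-2 epigenome, a target TE inherits its source's primary state
    in the paired species-1 epigenome with probability
    ``conservation_prob``, else draws from the species-2 background.
    With a shared state alphabet the planted state-by-state Cramér's V
    equals ``conservation_prob`` exactly in expectation.
    """
    if not (0.0 <= conservation_prob <= 1.0):
        raise ValueError("conservation_prob must lie in [0, 1]")
    from .annotate import primary_chromhmm_state

    config = dataset.config
    rng = np.random.default_rng(np.random.SeedSequence((seed, 12345)))
    alphabet = state_alphabet or config.state_alphabet
    p2 = np.array([config.state_freqs.get(s, 0.0) for s in alphabet])
    p2 = p2 / p2.sum()

    assembly2 = GenomeAssembly(
        name="toy_sp2",
        chromosomes=[(c, n) for c, n in config.chrom_lengths],
    )

    # lift a subset of TEs into species-2 coordinates (uniform placement,
    # non-overlapping), planting a target TE over most lifted intervals
    import bisect
    lifted: list[tuple[str, GenomicInterval]] = []
    tes2: list[TEAnnotation] = []
    ortholog_map: dict[str, str] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly2.chrom_names}
    chrom_lengths = dict(config.chrom_lengths)
    chrom_names = assembly2.chrom_names
    weights = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    n2 = 0
    w = config.window_bp
    pair_sources: list[TEAnnotation] = []
    for te in dataset.tes:
        if rng.random() >= liftover_rate:
            continue
        length = te.interval.width
        placed = None
        for _try in range(500):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
            if chrom_lengths[chrom] <= length + 2 * w:
                continue
            start = int(rng.integers(w, chrom_lengths[chrom] - length - w))
            # reserve whole windows (with margin for the target offset) so
            # no two target TEs share a segmentation window
            a_start = ((start - 24) // w) * w
            a_end = -(-(start + length + 24) // w) * w
            occ = occupied[chrom]
            j = bisect.bisect_left(occ, (a_start, a_start))
            if j > 0 and occ[j - 1][1] > a_start:
                continue
            if j < len(occ) and occ[j][0] < a_end:
                continue
            occ.insert(j, (a_start, a_end))
            placed = GenomicInterval(chrom, start, start + length)
            break
        if placed is None:
            continue
        lifted.append((te.id, placed))
        if rng.random() < target_rate:
            n2 += 1
            # target overlaps the lifted interval with a small offset
            off = int(rng.integers(-min(20, placed.start), 20))
            t_start = max(0, placed.start + off)
            t_end = min(chrom_lengths[placed.chrom], t_start + length)
            target = TEAnnotation(
                interval=GenomicInterval(placed.chrom, t_start, t_end),
                subfamily=te.subfamily, family=te.family, te_class=te.te_class,
                substitution_proportion=te.substitution_proportion,
                id=f"TE2_{n2:06d}",
            )
            tes2.append(target)
            ortholog_map[te.id] = target.id
            pair_sources.append(te)

    # anatomy-matched epigenome pairing: one species-2 epigenome per
    # species-1 epigenome
    epi1_ids = dataset.epigenome_ids
    if n_epigenomes is not None:
        epi1_ids = epi1_ids[:n_epigenomes]
    epi2_ids = [f"M{i + 1:03d}" for i in range(len(epi1_ids))]
    pairs = list(zip(epi1_ids, epi2_ids))
    metadata2 = {
        e2: EpigenomeMetadata(
            epigenome_id=e2, group=dataset.metadata[e1].group,
            anatomy=dataset.metadata[e1].anatomy,
            type=dataset.metadata[e1].type,
            age_category=dataset.metadata[e1].age_category,
            germ_layer=dataset.metadata[e1].germ_layer,
            cancer=dataset.metadata[e1].cancer,
        )
        for e1, e2 in pairs
    }

    window_bp = config.window_bp
    target_by_id = {t.id: t for t in tes2}
    segmentations2: dict[str, Segmentation] = {}
    methylation2: dict[str, MethylationTrack] = {}
    meth_ranges = {0: (0.0, 0.28), 1: (0.32, 0.68), 2: (0.72, 1.0)}

    for e1, e2 in pairs:
        seg1 = dataset.segmentations[e1]
        n_windows = _window_grid(assembly2, window_bp)
        states_per_chrom = {
            c: rng.choice(len(p2), size=nw, p=p2).astype(np.int16)
            for c, nw in n_windows.items()
        }
        # per-target-TE methylation state for species 2
        meth_pos: dict[str, list[int]] = {c: [] for c in chrom_names}
        meth_frac: dict[str, list[float]] = {c: [] for c in chrom_names}
        meth_cov: dict[str, list[int]] = {c: [] for c in chrom_names}
        meth1 = dataset.methylation.get(e1)
        for src in pair_sources:
            tgt = target_by_id[ortholog_map[src.id]]
            iv = tgt.interval
            # chromHMM inheritance
            if conservation_prob > 0 and rng.random() < conservation_prob:
                code1 = primary_chromhmm_state(src, seg1, as_code=True)
                state2 = code1 if code1 is not None and code1 < len(p2) else int(rng.choice(len(p2), p=p2))
            else:
                state2 = int(rng.choice(len(p2), p=p2))
            w0 = iv.start // window_bp
            w1 = min((iv.end - 1) // window_bp, n_windows[iv.chrom] - 1)
            states_per_chrom[iv.chrom][w0:w1 + 1] = state2
            # methylation inheritance
            if meth1 is not None:
                from .annotate import _methylation_codes
                _, code_m1 = _methylation_codes(src.interval.chrom,
                                                src.interval.start,
                                                src.interval.end, meth1)
                if code_m1 in meth_ranges:
                    if rng.random() < conservation_prob:
                        state_m2 = code_m1
                    else:
                        state_m2 = int(rng.choice(3, p=[0.15, 0.15, 0.70]))
                    lo, hi = meth_ranges[state_m2]
                    n_cpg = max(2, int(iv.width * 0.01))
                    pos = np.sort(rng.choice(
                        np.arange(iv.start, iv.end - 1, 2), size=min(
                            n_cpg, max((iv.end - 1 - iv.start) // 2, 1)),
                        replace=False))
                    for pp in pos:
                        meth_pos[iv.chrom].append(int(pp))
                        meth_frac[iv.chrom].append(float(rng.uniform(lo, hi)))
                        meth_cov[iv.chrom].append(int(rng.poisson(12) + 4))
        blocks = {}
        for chrom, st in states_per_chrom.items():
            nw = len(st)
            bounds = np.arange(nw + 1, dtype=np.int64) * window_bp
            change = np.flatnonzero(np.diff(st)) + 1
            starts = np.concatenate(([0], change))
            blocks[chrom] = (np.concatenate((bounds[starts], [bounds[nw]])),
                             st[starts])
        segmentations2[e2] = Segmentation(e2, alphabet, blocks, window_bp=None)
        cpgs = {}
        for chrom in chrom_names:
            if meth_pos[chrom]:
                order = np.argsort(meth_pos[chrom])
                pos = np.array(meth_pos[chrom], dtype=np.int64)[order]
                frac = np.array(meth_frac[chrom])[order]
                cov = np.array(meth_cov[chrom], dtype=np.int64)[order]
                keep = np.concatenate(([True], np.diff(pos) > 0))
                cpgs[chrom] = (pos[keep], frac[keep], cov[keep])
        methylation2[e2] = MethylationTrack(e2, cpgs)

    dataset.ground_truth.ortholog_map = ortholog_map
    dataset.ground_truth.conservation_prob = conservation_prob
    return OrthologBundle(
        assembly=assembly2, tes=tes2, segmentations=segmentations2,
        methylation=methylation2, lifted=lifted, epigenome_pairs=pairs,
        metadata=metadata2,
    )


def _te_cpg_density_high(te: TEAnnotation, config: SimulationConfig) -> bool:
    density = {spec.name: spec.cpg_density for spec in config.subfamilies}
    return density.get(te.subfamily, 0.0) >= 0.03
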