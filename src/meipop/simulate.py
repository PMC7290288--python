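"""Synthetic cohorts, haplotype families and annotations with known truth.

Every pipeline input can be generated here so the full analysis is
testable without any sequencing data:

* ``simulate_cohort`` builds a seven-group, 296-sample diversity panel
  with Balding-Nichols structured MEI allele frequencies, a geographic
  sampling map, an ancestry-fraction gradient decaying with distance
  from a source point, and planted QC defects (heterozygote-excess
  loci, singletons, novel loci).
* ``simulate_haplotypes`` evolves Alu-like 281-bp haplotype families
  either by star-like expansion (recent subfamily bursts, negative
  Tajima's D) or under a constant-size coalescent (D near zero).
* ``simulate_annotation`` lays out a toy genome whose feature-class
  proportions default to the genome-wide compartment sizes.

All randomness flows from a single mandatory seed through named
substreams, so identical configurations are byte-identical on disk.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .annotation import FEATURE_CLASSES, FeatureMap, GENOME_CLASS_SIZES_MB
from .geo import AncestryTable, haversine
from .model import (
    GROUP_SIZES,
    MAJOR_GROUPS,
    MEIError,
    MEICallSet,
    MEILocus,
    MISSING,
    SamplePanel,
)
from .subfamilies import HaplotypeSet, detect_mask

# Group sampling centroids (lat, lon) for the synthetic geography.
GROUP_CENTROIDS = {
    "Africa": (2.0, 22.0),
    "West Eurasia": (48.0, 15.0),
    "South Asia": (21.0, 78.0),
    "Central Asia/Siberia": (55.0, 92.0),
    "East Asia": (33.0, 112.0),
    "Oceania": (-7.0, 145.0),
    "Americas": (-5.0, -65.0),
}

# Per-group drift since each group's founding pool, arranged as a serial
# founder ladder: Africa drifts from the ancestral pool; the Eurasian
# groups share an out-of-Africa pulse before their own drift; the
# Americas are founded from the Central Asia/Siberia pool (the Beringian
# route), which plants the Native American / Central Asian affinity.
LADDER_DRIFT = {
    "Africa": 0.02,
    "West Eurasia": 0.03,
    "South Asia": 0.03,
    "Central Asia/Siberia": 0.05,
    "East Asia": 0.05,
    "Oceania": 0.10,
    "Americas": 0.12,
}
OUT_OF_AFRICA_DRIFT = 0.08

# Weights for which group receives a planted group-private rare locus;
# Africa carries the deepest within-group diversity.
PRIVATE_GROUP_WEIGHTS = {
    "Africa": 0.45,
    "West Eurasia": 0.12,
    "South Asia": 0.12,
    "Central Asia/Siberia": 0.07,
    "East Asia": 0.10,
    "Oceania": 0.08,
    "Americas": 0.06,
}

ALU_SUBFAMILY_FREQS = {
    "AluYa5": 0.258,
    "AluYb8": 0.200,
    "AluYa8": 0.065,
    "AluYa4": 0.050,
    "AluYb9": 0.040,
    "AluYb6": 0.020,
    "AluYc1": 0.060,
    "AluYe5": 0.045,
    "AluYg6": 0.025,
    "AluYh9": 0.015,
    "AluYi6": 0.012,
    "AluYk11": 0.010,
    "AluY": 0.150,
    "indeterminate": 0.050,
}
LINE1_SUBFAMILY_FREQS = {"indeterminate": 0.436, "L1Ta": 0.375, "L1preTa": 0.189}


@dataclass
class SimConfig:
    """Configuration and ground truth knobs for the synthetic cohort.

    ``fst`` is either a single Balding-Nichols F applied uniformly to
    every group (panmictic ancestral pool, used for estimator-recovery
    experiments) or the string ``"founder_ladder"`` selecting the serial-founder
    ladder that mimics the seven-group cohort.
    """

    seed: int
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    n_loci: dict[str, int] = field(
        default_factory=lambda: {"ALU": 1200, "LINE1": 250, "SVA": 80}
    )
    fst: float | str = "founder_ladder"
    p_anc_range: tuple[float, float] = (0.05, 0.95)
    frac_excess_het: float = 0.03
    frac_private: float = 0.30
    frac_novel: float = 0.50
    missing_rate: float = 0.01
    group_centroids: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_CENTROIDS)
    )
    jitter_km: float = 500.0
    ancestry_source: tuple[float, float] = (54.0, 91.0)
    ancestry_decay_km: float = 2500.0
    ancestry_amplitude: float = 0.6
    n_components: int = 7

    def __post_init__(self) -> None:
        if self.seed is None:
            raise MEIError("seed is mandatory")
        if any(v <= 0 for v in self.group_sizes.values()):
            raise MEIError("group sizes must be positive")
        if any(v <= 0 for v in self.n_loci.values()):
            raise MEIError("locus counts must be positive")
        if isinstance(self.fst, float) and not 0 <= self.fst < 1:
            raise MEIError("fst must lie in [0, 1)")
        if self.frac_excess_het + self.frac_private > 1:
            raise MEIError("planted fractions exceed 1")


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    # stream tag hashed with crc32: stable across processes, unlike hash()
    return np.random.default_rng([cfg_seed, zlib.crc32(stream.encode()) % 2**31])


def _bn_draw(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols draw of drifted frequencies around ancestral p."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))


def _simulate_panel(cfg: SimConfig) -> SamplePanel:
    rng = _rng(cfg.seed, "panel")
    rows = []
    for g in MAJOR_GROUPS:
        size = cfg.group_sizes.get(g, 0)
        clat, clon = cfg.group_centroids[g]
        for i in range(size):
            # degree jitter approximating jitter_km on the ground
            dlat = rng.normal(0, cfg.jitter_km / 111.0)
            dlon = rng.normal(0, cfg.jitter_km / (111.0 * max(np.cos(np.radians(clat)), 0.2)))
            lat = float(np.clip(clat + dlat, -89.0, 89.0))
            lon = float((clon + dlon + 180.0) % 360.0 - 180.0)
            if lon == -180.0:
                lon = 180.0
            rows.append(
                {
                    "sample": f"{g.replace('/', '-').replace(' ', '')}-{i:03d}",
                    "population": f"{g.split('/')[0].split()[0]}_pop{i % 7}",
                    "group": g,
                    "lat": lat,
                    "lon": lon,
                }
            )
    return SamplePanel(pd.DataFrame(rows))


def _group_frequencies(
    cfg: SimConfig, rng, p_anc: np.ndarray, groups: list[str]
) -> dict[str, np.ndarray]:
    if isinstance(cfg.fst, str):
        if cfg.fst != "founder_ladder":
            raise MEIError(f"unknown structure preset {cfg.fst!r}")
        p_ooa = _bn_draw(rng, p_anc, OUT_OF_AFRICA_DRIFT)
        out = {}
        for g in groups:
            if g == "Americas":
                continue
            base = p_anc if g == "Africa" else p_ooa
            out[g] = _bn_draw(rng, base, LADDER_DRIFT[g])
        if "Americas" in groups:
            founder = out.get("Central Asia/Siberia", p_ooa)
            out["Americas"] = _bn_draw(rng, founder, LADDER_DRIFT["Americas"])
        return out
    return {g: _bn_draw(rng, p_anc, float(cfg.fst)) for g in groups}


def _locus_metadata(cfg: SimConfig, rng) -> list[MEILocus]:
    loci = []
    for me_class, n in cfg.n_loci.items():
        if me_class == "ALU":
            names = list(ALU_SUBFAMILY_FREQS)
            weights = np.array(list(ALU_SUBFAMILY_FREQS.values()))
        elif me_class == "LINE1":
            names = list(LINE1_SUBFAMILY_FREQS)
            weights = np.array(list(LINE1_SUBFAMILY_FREQS.values()))
        else:
            names, weights = ["indeterminate"], np.array([1.0])
        weights = weights / weights.sum()
        subs = rng.choice(names, size=n, p=weights)
        chroms = rng.integers(1, 10, size=n)
        positions = rng.integers(10_000, 5_000_000, size=n)
        tsd = np.clip(np.round(rng.normal(14.5, 4.0, size=n)), 0, 26).astype(int)
        orientation = rng.choice(["+", "-"], size=n)
        for i in range(n):
            loci.append(
                MEILocus(
                    chrom=str(chroms[i]),
                    pos=int(positions[i]),
                    me_class=me_class,
                    subfamily=str(subs[i]),
                    orientation=str(orientation[i]),
                    tsd_len=int(tsd[i]),
                    assess=5,
                    filter_status="PASS",
                )
            )
    return loci


def _ancestry_table(cfg: SimConfig, panel: SamplePanel) -> AncestryTable:
    rng = _rng(cfg.seed, "ancestry")
    groups = panel.groups
    comp_of_group = {g: i for i, g in enumerate(groups)}
    nw = comp_of_group.get("Americas", cfg.n_components - 1)
    rows = {}
    for row in panel.frame.itertuples(index=False):
        frac = np.zeros(cfg.n_components)
        if row.group == "Americas":
            frac[nw] = rng.uniform(0.75, 0.95)
        else:
            d = haversine((row.lat, row.lon), cfg.ancestry_source)
            share = cfg.ancestry_amplitude * np.exp(-d / cfg.ancestry_decay_km)
            share *= rng.uniform(0.7, 1.3)
            frac[nw] = min(share, 0.9)
        own = comp_of_group.get(row.group, 0)
        if own == nw:
            own = (own + 1) % cfg.n_components
        frac[own] = (1 - frac[nw]) * rng.uniform(0.8, 0.95)
        rest = 1 - frac.sum()
        others = [i for i in range(cfg.n_components) if i not in (nw, own)]
        if others and rest > 0:
            frac[others] = rest * rng.dirichlet(np.ones(len(others)))
        frac = np.clip(frac, 0, None)
        frac /= frac.sum()
        rows[row.sample] = frac
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"k{i + 1}" for i in range(cfg.n_components)]
    )
    frame.index.name = "sample"
    # the New World component is reported first for convenience
    order = [f"k{nw + 1}"] + [c for c in frame.columns if c != f"k{nw + 1}"]
    return AncestryTable(frame[order])


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[MEICallSet, SamplePanel, AncestryTable, dict[str, Any]]:
    """Generate a structured MEI cohort with full ground truth.

    Returns ``(calls, panel, ancestry, truth)``.  ``truth`` records the
    planted excess-heterozygote loci, planted singleton loci (and their
    carriers), the novel-locus mask, and the drift parameters used.
    """
    panel = _simulate_panel(cfg)
    rng = _rng(cfg.seed, "genotypes")
    groups = panel.groups
    group_cols = {
        g: np.array([i for i, s in enumerate(panel.samples) if panel.group_of()[s] == g])
        for g in groups
    }
    n_samples = len(panel.samples)
    loci = _locus_metadata(cfg, _rng(cfg.seed, "loci"))
    n_loci = len(loci)

    roles = np.array(["shared"] * n_loci, dtype=object)
    idx = rng.permutation(n_loci)
    n_excess = int(round(cfg.frac_excess_het * n_loci))
    n_private = int(round(cfg.frac_private * n_loci))
    roles[idx[:n_excess]] = "excess_het"
    roles[idx[n_excess : n_excess + n_private]] = "private"

    geno = np.zeros((n_loci, n_samples), dtype=np.int8)
    shared_idx = np.flatnonzero(roles == "shared")
    p_anc = rng.uniform(*cfg.p_anc_range, size=shared_idx.size)
    freqs = _group_frequencies(cfg, rng, p_anc, groups)
    for g in groups:
        cols = group_cols[g]
        pg = freqs[g]
        draws = rng.binomial(2, pg[:, None], size=(shared_idx.size, cols.size))
        geno[np.ix_(shared_idx, cols)] = draws

    private_idx = np.flatnonzero(roles == "private")
    weights = np.array([PRIVATE_GROUP_WEIGHTS[g] for g in groups])
    weights = weights / weights.sum()
    planted_singletons: list[tuple[int, str]] = []
    for i in private_idx:
        g = groups[int(rng.choice(len(groups), p=weights))]
        cols = group_cols[g]
        n_carriers = 1 + rng.poisson(0.25)
        n_carriers = min(n_carriers, cols.size)
        chosen = rng.choice(cols, size=n_carriers, replace=False)
        geno[i, chosen] = 1
        if n_carriers == 1:
            planted_singletons.append((int(i), panel.samples[int(chosen[0])]))

    excess_idx = np.flatnonzero(roles == "excess_het")
    geno[excess_idx, :] = 1  # every sample heterozygous: extreme excess

    if cfg.missing_rate > 0:
        miss = rng.random((n_loci, n_samples)) < cfg.missing_rate
        # keep planted defects and rare-allele carriers unambiguous
        miss[excess_idx, :] = False
        miss[private_idx, :] = False
        geno[miss] = MISSING

    novel = rng.random(n_loci) < cfg.frac_novel

    order = sorted(range(n_loci), key=lambda i: (loci[i].chrom, loci[i].pos))
    remap = {old: new for new, old in enumerate(order)}
    calls = MEICallSet(
        loci=[loci[i] for i in order],
        samples=panel.samples,
        genotypes=geno[order, :],
    )
    truth = {
        "fst": cfg.fst,
        "out_of_africa_drift": OUT_OF_AFRICA_DRIFT if cfg.fst == "founder_ladder" else None,
        "group_drift": dict(LADDER_DRIFT) if cfg.fst == "founder_ladder" else None,
        "excess_het_loci": sorted(remap[int(i)] for i in excess_idx),
        "private_loci": sorted(remap[int(i)] for i in private_idx),
        "planted_singletons": sorted(
            (remap[i], s) for i, s in planted_singletons
        ),
        "novel_mask": novel[order].tolist(),
        "ancestry_source": cfg.ancestry_source,
    }
    ancestry = _ancestry_table(cfg, panel)
    return calls, panel, ancestry, truth


# ---------------------------------------------------------------------------
# Haplotype families


def _alu_like_consensus(length: int = 281) -> str:
    """Deterministic Alu-like consensus: GC-rich body, middle A-rich
    linker, and a 3' poly(A) tail."""
    rng = np.random.default_rng(281281)
    bases = np.array(list("ACGT"))
    body = rng.choice(bases, size=length, p=[0.22, 0.30, 0.30, 0.18])
    seq = body.copy()
    mid = length // 2
    seq[mid : mid + 8] = "A"  # middle A-rich region
    seq[-15:] = "A"  # poly(A) tail
    return "".join(seq)


ALU_CONSENSUS = _alu_like_consensus()

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate(
    seq: list[str],
    rng: np.random.Generator,
    n_mut: int,
    weights: np.ndarray,
    positions: np.ndarray,
    used: set[int] | None = None,
) -> None:
    """Apply ``n_mut`` substitutions in place (transition-biased).

    When ``used`` is given, positions mutated anywhere in the family are
    excluded (infinite-sites behaviour: every site mutates at most once).
    """
    if n_mut == 0:
        return
    if used is not None:
        free = np.array([i for i, p in enumerate(positions) if p not in used])
        if free.size < n_mut:
            raise MEIError("infinite-sites simulation ran out of mutable columns")
        w = weights[free] / weights[free].sum()
        chosen = rng.choice(positions[free], size=n_mut, replace=False, p=w)
        used.update(int(p) for p in chosen)
    else:
        chosen = rng.choice(positions, size=n_mut, replace=False, p=weights)
    for pos in chosen:
        base = seq[pos]
        if rng.random() < 0.7:
            seq[pos] = _TRANSITION[base]
        else:
            seq[pos] = rng.choice([b for b in "ACGT" if b not in (base, _TRANSITION[base])])


def simulate_haplotypes(
    mode: str = "star",
    n_tips: int = 50,
    mutation_rate: float = 1.0,
    cpg_multiplier: float = 6.0,
    subfamily: str = "AluYa5",
    seed: int = 0,
    consensus: str | None = None,
    infinite_sites: bool = False,
) -> tuple[HaplotypeSet, list[tuple[str, str]]]:
    """Evolve one Alu-like haplotype family; returns the set and genealogy.

    ``mode="star"`` hangs every tip directly off the founder haplotype
    with Poisson(``mutation_rate``) private mutations - a recent burst,
    which drives Tajima's D negative.  ``mode="coalescent"`` draws a
    Kingman genealogy for a constant-size population and scatters
    mutations at rate ``mutation_rate`` per lineage per coalescent time
    unit, giving D near zero in expectation.

    Mutations target unmasked columns only, with CpG-context columns
    upweighted by ``cpg_multiplier`` and a transition bias.
    ``infinite_sites=True`` lets every column mutate at most once across
    the family, so the resulting data are exactly tree-realizable.  The
    genealogy is returned as (parent sequence, child sequence) pairs over
    the full alignment.
    """
    if mutation_rate < 0:
        raise MEIError("mutation rate must be >= 0")
    cons = consensus if consensus is not None else ALU_CONSENSUS
    rng = np.random.default_rng([seed, 77])
    mask = detect_mask(cons)
    positions = np.array([i for i in range(len(cons)) if i not in mask])
    w = np.ones(positions.size)
    for k, pos in enumerate(positions):
        if cons[pos : pos + 2] == "CG" or cons[max(pos - 1, 0) : pos + 1] == "CG":
            w[k] = cpg_multiplier
    w /= w.sum()

    genealogy: list[tuple[str, str]] = []
    sequences: list[str] = []
    used: set[int] | None = set() if infinite_sites else None
    if mode == "star":
        root = cons
        for _ in range(n_tips):
            tip = list(root)
            _mutate(tip, rng, min(rng.poisson(mutation_rate), positions.size), w, positions, used)
            tip_s = "".join(tip)
            sequences.append(tip_s)
            genealogy.append((root, tip_s))
    elif mode == "coalescent":
        # Kingman genealogy: build tree bottom-up, then mutate root-down.
        nodes = list(range(n_tips))
        children: dict[int, list[int]] = {}
        lengths: dict[int, float] = {}
        heights = {i: 0.0 for i in nodes}
        t = 0.0
        nxt = n_tips
        active = list(nodes)
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(len(active), size=2, replace=False)
            a, b = active[i], active[j]
            children[nxt] = [a, b]
            heights[nxt] = t
            lengths[a] = t - heights[a]
            lengths[b] = t - heights[b]
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
        root_id = active[0]
        seq_of: dict[int, str] = {root_id: cons}
        stack = [root_id]
        while stack:
            node = stack.pop()
            for child in children.get(node, []):
                s = list(seq_of[node])
                n_mut = rng.poisson(mutation_rate * lengths[child])
                _mutate(s, rng, min(n_mut, positions.size), w, positions, used)
                seq_of[child] = "".join(s)
                genealogy.append((seq_of[node], seq_of[child]))
                stack.append(child)
        sequences = [seq_of[i] for i in range(n_tips)]
    else:
        raise MEIError(f"unknown mode {mode!r}")

    hset = HaplotypeSet(
        sequences=sequences,
        locus_ids=[f"{subfamily}_locus{i:04d}" for i in range(n_tips)],
        subfamilies=[subfamily] * n_tips,
        mask=mask,
        consensus=cons,
    )
    return hset, genealogy


# ---------------------------------------------------------------------------
# Toy annotation


def simulate_annotation(
    proportions: dict[str, float] | None = None,
    genome_mb: float = 20.0,
    mean_segment_bp: int = 5000,
    seed: int = 0,
) -> FeatureMap:
    """Toy single-chromosome genome with the requested class proportions.

    Non-overlapping segments are laid down left to right; segment classes
    are multinomial in ``proportions`` (default: the genome-wide
    compartment proportions) and nongenic stretches stay implicit.
    """
    if proportions is None:
        total = sum(GENOME_CLASS_SIZES_MB.values())
        proportions = {c: s / total for c, s in GENOME_CLASS_SIZES_MB.items()}
    if abs(sum(proportions.values()) - 1) > 1e-9:
        raise MEIError("class proportions must sum to 1")
    rng = np.random.default_rng([seed, 411])
    length = int(genome_mb * 1e6)
    classes = list(proportions)
    probs = np.array([proportions[c] for c in classes])
    rows = []
    pos = 0
    while pos < length:
        seg = max(int(rng.exponential(mean_segment_bp)), 50)
        end = min(pos + seg, length)
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if cls != "nongenic":
            strand = str(rng.choice(["+", "-"]))
            rows.append(
                {
                    "chrom": "sim1",
                    "start": pos,
                    "end": end,
                    "feature_class": cls,
                    "gene_strand": strand,
                }
            )
        pos = end
    intervals = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature_class", "gene_strand"]
    )
    return FeatureMap(intervals, chrom_lengths={"sim1": length})
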