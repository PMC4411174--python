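"""Synthetic lake-metacommunity generator.

Emulates the statistical structure the downstream analysis assumes:

* a regional species pool with lognormal ("hollow curve") abundances,
  perturbed per lake by multiplicative lognormal noise and thinned by a
  per-lake occupancy draw, so lakes overlap but differ;
* a random rooted binary phylogeny (pure-birth process) over species;
* per-region *resolution maps* — one region may split true species into
  several region-OTUs (finer taxonomic resolution, as the V4 region
  resolves more sites than V3/V5) while others lump species with a
  phylogenetic neighbour;
* multinomial sequencing of each lake to a fixed read depth;
* reads that carry a conserved 11-mer anchor flanking a region-specific
  variable segment, half of them emitted reverse-complemented;
* ARISA fragment-length profiles with per-observation length jitter.

Every operation takes an explicit seed; there is no hidden global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from ._seeds import rng_for
from .types import OTUTable, PeakProfile, Read, ReadSet

__all__ = [
    "ResolutionSpec",
    "TruthConfig",
    "Metacommunity",
    "ResolutionResult",
    "SyntheticDataset",
    "simulate_metacommunity",
    "simulate_tree",
    "apply_resolution",
    "region_abundances",
    "sample_otu_table",
    "simulate_reads",
    "simulate_background_reads",
    "simulate_arisa",
    "generate_dataset",
    "default_region_specs",
]

_DNA = np.array(list("ACGT"))

# Conserved 11-mers next to the variable regions (E. coli numbering
# neighbourhoods of the 341F / 515F / 805R primer sites).
_DEFAULT_ANCHORS = {
    "V3": "CCTACGGGAGG",
    "V4": "GTGCCAGCAGC",
    "V5": "ATTAGATACCC",
    "V3-V4": "CCTACGGGAGG",
    "V4-V5": "GTGCCAGCAGC",
}
_DEFAULT_TRIM = {"V3": 120, "V4": 120, "V5": 100, "V3-V4": 360, "V4-V5": 311}
_SEGMENT_OFFSETS = {"V3": 0, "V4": 130, "V5": 260, "V3-V4": 0, "V4-V5": 130}
_MASTER_LEN = 460  # per-species template long enough for the widest region


@dataclass(frozen=True)
class ResolutionSpec:
    """How one 16S region resolves the true species into region-OTUs.

    ``split_fraction`` of species are resolved as two region-OTUs
    (finer resolution); ``lump_fraction`` are merged with a
    phylogenetic neighbour (coarser resolution).  The two fractions are
    free knobs of the generator — no quantitative model of regional
    resolution exists — and must sum to at most 1.
    """

    region_name: str
    split_fraction: float = 0.0
    lump_fraction: float = 0.0
    anchor_11mer: str = "CCTACGGGAGG"
    trim_length: int = 120
    segment_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.anchor_11mer) != 11:
            raise ValueError("anchor must be exactly 11 bases")
        if set(self.anchor_11mer) - set("ACGT"):
            raise ValueError("anchor must be non-degenerate DNA")
        if not (0.0 <= self.split_fraction <= 1.0
                and 0.0 <= self.lump_fraction <= 1.0):
            raise ValueError("split/lump fractions must lie in [0, 1]")
        if self.split_fraction + self.lump_fraction > 1.0:
            raise ValueError("split_fraction + lump_fraction must be <= 1")
        if self.trim_length <= 0:
            raise ValueError("trim_length must be positive")


def default_region_specs() -> list[ResolutionSpec]:
    """The three single-region defaults: V4 finer (split 0.5), V3/V5 coarser."""
    return [
        ResolutionSpec("V3", split_fraction=0.0, lump_fraction=0.15,
                       anchor_11mer=_DEFAULT_ANCHORS["V3"],
                       trim_length=_DEFAULT_TRIM["V3"],
                       segment_offset=_SEGMENT_OFFSETS["V3"]),
        ResolutionSpec("V4", split_fraction=0.5, lump_fraction=0.0,
                       anchor_11mer=_DEFAULT_ANCHORS["V4"],
                       trim_length=_DEFAULT_TRIM["V4"],
                       segment_offset=_SEGMENT_OFFSETS["V4"]),
        ResolutionSpec("V5", split_fraction=0.0, lump_fraction=0.15,
                       anchor_11mer=_DEFAULT_ANCHORS["V5"],
                       trim_length=_DEFAULT_TRIM["V5"],
                       segment_offset=_SEGMENT_OFFSETS["V5"]),
    ]


@dataclass
class TruthConfig:
    """Study conditions of the synthetic 20-lake metacommunity."""

    n_species: int = 300
    n_lakes: int = 20
    meanlog: float = 0.0
    sdlog: float = 1.2          # regional-pool lognormal shape
    lake_sdlog: float = 0.75    # lake-level multiplicative noise
    occupancy: float = 0.8      # max P(species occupies a lake)
    niche_breadth: float | None = 0.35  # Gaussian niche SD on the lake axis;
    # None disables the gradient (fully exchangeable lakes)
    depth_per_lake: int = 1500  # reads per lake after trimming
    region_specs: list[ResolutionSpec] = field(default_factory=default_region_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_lakes < 2:
            raise ValueError("n_lakes must be >= 2")
        if self.depth_per_lake < 1:
            raise ValueError("depth_per_lake must be >= 1")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        names = [s.region_name for s in self.region_specs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate region names")


@dataclass
class Metacommunity:
    """True per-lake relative abundances (rows sum to 1)."""

    lake_ids: list[str]
    species_ids: list[str]
    abundances: np.ndarray      # lakes x species, rows sum to 1
    occupancy: np.ndarray       # boolean lakes x species


def simulate_metacommunity(config: TruthConfig) -> Metacommunity:
    """Draw the true metacommunity: shared pool, lake noise, niche gradient.

    Species ``i`` has regional log-abundance ``meanlog + sdlog*z_i``;
    lake ``l`` perturbs it by ``lake_sdlog * z_il``.  Lakes sit on a
    unit environmental axis and each species carries a Gaussian niche
    (optimum uniform on the axis, SD ``niche_breadth``): its occupancy
    probability is ``occupancy`` scaled by niche suitability, and its
    abundance is shaded by the same suitability.  This produces the
    between-lake structure beta-diversity analyses measure — nearby
    lakes share more species than distant ones.  With ``niche_breadth
    = None`` all lakes are exchangeable (suitability 1 everywhere).
    Each lake's retained abundances are renormalised to sum to 1.
    """
    rng = rng_for(config.seed, "metacommunity")
    n_sp, n_lk = config.n_species, config.n_lakes
    species_ids = [f"sp{i:04d}" for i in range(n_sp)]
    lake_ids = [f"lake{l:02d}" for l in range(n_lk)]
    regional = config.meanlog + config.sdlog * rng.standard_normal(n_sp)
    lake_noise = config.lake_sdlog * rng.standard_normal((n_lk, n_sp))
    log_ab = regional[None, :] + lake_noise
    if config.niche_breadth is not None:
        x = np.linspace(0.0, 1.0, n_lk)
        optimum = rng.uniform(0.0, 1.0, size=n_sp)
        b = config.niche_breadth
        suitability = np.exp(-((x[:, None] - optimum[None, :]) ** 2)
                             / (2.0 * b * b))
    else:
        suitability = np.ones((n_lk, n_sp))
    occ = rng.random((n_lk, n_sp)) < config.occupancy * suitability
    # guarantee every lake holds at least one species
    for l in range(n_lk):
        if not occ[l].any():
            occ[l, int(np.argmax(suitability[l]))] = True
    ab = np.exp(log_ab) * suitability * occ
    ab /= ab.sum(axis=1, keepdims=True)
    return Metacommunity(lake_ids, species_ids, ab, occ)


def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Pure-birth (Yule) rooted binary tree with strictly positive lengths.

    Tips are named ``sp0000`` ... in order of lineage creation so they
    match :func:`simulate_metacommunity` species ids.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = rng_for(seed, "yule-tree")
    root = TreeNode()
    left, right = TreeNode(), TreeNode()
    root.extend([left, right])
    active: list[tuple[TreeNode, float]] = [(left, 0.0), (right, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        node.length = t - birth
        a, b = TreeNode(), TreeNode()
        node.extend([a, b])
        active.append((a, t))
        active.append((b, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    for i, (node, birth) in enumerate(active):
        node.length = t_end - birth
    # deterministic tip naming in tree (postorder) order
    for tip, name in zip(root.tips(), (f"sp{i:04d}" for i in range(n_species))):
        tip.name = name
    return root


@dataclass
class ResolutionResult:
    """A region's view of the true species."""

    region_name: str
    otu_ids: list[str]
    # species id -> [(otu id, fraction of the species' abundance)]
    species_to_otus: dict[str, list[tuple[str, float]]]
    tree: TreeNode

    def allocation_matrix(self, species_ids: list[str]) -> np.ndarray:
        """Species x OTU matrix of abundance fractions (rows sum to 1)."""
        otu_index = {o: j for j, o in enumerate(self.otu_ids)}
        A = np.zeros((len(species_ids), len(self.otu_ids)))
        for i, sp in enumerate(species_ids):
            for otu, frac in self.species_to_otus[sp]:
                A[i, otu_index[otu]] += frac
        return A


def apply_resolution(tree: TreeNode, spec: ResolutionSpec,
                     seed: int,
                     lumpability: np.ndarray | None = None,
                     lumpability_jitter: float = 0.1) -> ResolutionResult:
    """Derive a region's OTU map and tree from the true phylogeny.

    Split species become a cherry of two sibling tips separated by a
    small epsilon branch; lumped species are removed and their
    abundance flows to the nearest available (non-split, not already
    merged) tip.  The expected OTU count is
    ``n * (1 + split_fraction - lump_fraction)``.

    ``lumpability`` is an optional per-species score in [0, 1]: species
    with low sequence distinctiveness that *any* coarse region tends to
    merge.  When given, the region lumps the ``lump_fraction`` quantile
    of ``lumpability + jitter`` (jitter is region-specific), so regions
    with similar resolving power lump overlapping species sets.  When
    omitted, lump/split categories are drawn independently per region.
    """
    rng = rng_for(seed, "resolution", spec.region_name)
    species = [t.name for t in tree.tips()]
    n = len(species)
    u = rng.random(n)
    split = u < spec.split_fraction
    if lumpability is None:
        lump = (~split) & (u < spec.split_fraction + spec.lump_fraction)
    elif spec.lump_fraction > 0:
        score = np.asarray(lumpability, dtype=float) \
            + lumpability_jitter * rng.random(n)
        cutoff = np.quantile(score, spec.lump_fraction)
        lump = (~split) & (score <= cutoff)
    else:
        lump = np.zeros(n, dtype=bool)
    split_set = {sp for sp, s in zip(species, split) if s}
    lump_list = [sp for sp, m in zip(species, lump) if m]

    # pair each lumped species with its nearest available neighbour tip
    merged_into: dict[str, str] = {}
    if lump_list:
        dm = tree.tip_tip_distances()
        ids = list(dm.ids)
        pos = {s: i for i, s in enumerate(ids)}
        closed: set[str] = set()
        for sp in lump_list:
            if sp in closed:
                continue
            dists = np.array(dm[pos[sp]], dtype=float)
            order = np.argsort(dists, kind="stable")
            target = None
            for j in order:
                cand = ids[int(j)]
                if cand == sp or cand in split_set or cand in closed \
                        or cand in merged_into:
                    continue
                target = cand
                break
            if target is None:
                continue  # no available neighbour; species keeps its own OTU
            merged_into[sp] = target
            closed.add(sp)
            closed.add(target)

    region_tree = tree.copy()
    eps = 1e-3 * float(np.mean([nd.length for nd in
                                tree.traverse(include_self=False)]))
    tip_nodes = {t.name: t for t in region_tree.tips()}

    species_to_otus: dict[str, list[tuple[str, float]]] = {}
    # remove lumped tips from the tree
    for sp, target in merged_into.items():
        node = tip_nodes[sp]
        parent = node.parent
        parent.remove(node)
    region_tree.prune()
    tip_nodes = {t.name: t for t in region_tree.tips()}

    for sp in species:
        if sp in merged_into:
            continue
        if sp in split_set:
            node = tip_nodes[sp]
            a, b = TreeNode(name=f"{sp}.a", length=eps), \
                TreeNode(name=f"{sp}.b", length=eps)
            node.name = None
            node.extend([a, b])
            p = float(rng.uniform(0.3, 0.7))
            species_to_otus[sp] = [(f"{sp}.a", p), (f"{sp}.b", 1.0 - p)]
        else:
            species_to_otus[sp] = [(sp, 1.0)]
    for sp, target in merged_into.items():
        # the whole lumped abundance flows to the target's (single) OTU
        species_to_otus[sp] = [(target, 1.0)]

    otu_ids = sorted({otu for lst in species_to_otus.values()
                      for otu, _ in lst})
    return ResolutionResult(spec.region_name, otu_ids, species_to_otus,
                            region_tree)


def region_abundances(meta: Metacommunity,
                      resolution: ResolutionResult,
                      seed: int | None = None,
                      split_concentration: float = 0.02) -> np.ndarray:
    """Lake x region-OTU relative abundances (rows sum to 1).

    When ``seed`` is given, each lake divides a split species' abundance
    between the two variant OTUs with its own Beta(c, c)-distributed
    proportion (c = ``split_concentration``; small c is strongly
    bimodal).  This emulates strain-level geographic variation that only
    the finer-resolving region separates: different lakes carry
    different variants, so the fine region records less between-lake
    sharing.  With ``seed=None`` the static (lake-independent) fractions
    of the resolution map are used.
    """
    if seed is None:
        A = resolution.allocation_matrix(meta.species_ids)
        ab = meta.abundances @ A
        return ab / ab.sum(axis=1, keepdims=True)
    rng = rng_for(seed, "split-allocation", resolution.region_name)
    n_lakes = len(meta.lake_ids)
    otu_index = {o: j for j, o in enumerate(resolution.otu_ids)}
    ab = np.zeros((n_lakes, len(resolution.otu_ids)))
    for i, sp in enumerate(meta.species_ids):
        dest = resolution.species_to_otus[sp]
        if len(dest) == 1:
            ab[:, otu_index[dest[0][0]]] += meta.abundances[:, i]
        else:
            (otu_a, _), (otu_b, _) = dest
            p = rng.beta(split_concentration, split_concentration,
                         size=n_lakes)
            ab[:, otu_index[otu_a]] += meta.abundances[:, i] * p
            ab[:, otu_index[otu_b]] += meta.abundances[:, i] * (1.0 - p)
    return ab / ab.sum(axis=1, keepdims=True)


def sample_otu_table(abundances: np.ndarray, otu_ids: list[str],
                     lake_ids: list[str], depth: int, seed: int,
                     region_label: str | None = None) -> OTUTable:
    """Multinomial sequencing of each lake to ``depth`` reads."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng_for(seed, "sequencing", region_label or "")
    counts = np.vstack([rng.multinomial(depth, row) for row in abundances])
    return OTUTable(sample_ids=list(lake_ids), otu_ids=list(otu_ids),
                    counts=counts, region_label=region_label)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_DNA[rng.integers(4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def species_master_sequences(species_ids: list[str], seed: int,
                             length: int = _MASTER_LEN,
                             forbidden: tuple[str, ...] = ()) -> dict[str, str]:
    """One random template sequence per species, free of anchor k-mers."""
    rng = rng_for(seed, "master-sequences")
    bad = list(forbidden) + [_revcomp(a) for a in forbidden]
    out = {}
    for sp in species_ids:
        for _ in range(50):
            seq = _random_dna(rng, length)
            if not any(b in seq for b in bad):
                out[sp] = seq
                break
        else:
            raise RuntimeError("could not generate anchor-free template")
    return out


def otu_representative_sequences(resolution: ResolutionResult,
                                 masters: dict[str, str],
                                 spec: ResolutionSpec,
                                 seed: int,
                                 split_divergence: float = 0.08) -> dict[str, str]:
    """Variable segment of each region-OTU.

    Unsplit OTUs inherit the region window of their species template;
    the second tip of a split cherry diverges at ``split_divergence``
    per base so a 97% identity threshold separates the pair.
    """
    rng = rng_for(seed, "otu-sequences", spec.region_name)
    lo, hi = spec.segment_offset, spec.segment_offset + spec.trim_length
    out: dict[str, str] = {}
    for otu in resolution.otu_ids:
        sp = otu.split(".")[0]
        seg = masters[sp][lo:hi]
        if otu.endswith(".b"):
            seg = _mutate(rng, seg, split_divergence)
        out[otu] = seg
    return out


def simulate_reads(table: OTUTable, otu_sequences: dict[str, str],
                   spec: ResolutionSpec, seed: int,
                   error_rate: float = 0.002,
                   revcomp_prob: float = 0.5,
                   flank_range: tuple[int, int] = (5, 25),
                   max_retries: int = 25):
    """Emit one read per count in ``table``.

    Each read is random-prefix + anchor + OTU variable segment +
    random-suffix; ``revcomp_prob`` of reads are reverse-complemented.
    The anchor is guaranteed to occur exactly once (and its reverse
    complement never) in the forward orientation, so anchored trimming
    recovers exactly the planted segment.

    Returns ``(ReadSet, provenance)`` where provenance maps read id ->
    ``(sample_id, otu_id, planted_segment)``.
    """
    rng = rng_for(seed, "reads", spec.region_name)
    anchor, rc_anchor = spec.anchor_11mer, _revcomp(spec.anchor_11mer)
    reads: list[Read] = []
    provenance: dict[str, tuple[str, str, str]] = {}
    counter = 0
    for si, sample in enumerate(table.sample_ids):
        for oi, otu in enumerate(table.otu_ids):
            n = int(table.counts[si, oi])
            for _ in range(n):
                for attempt in range(max_retries):
                    seg = _mutate(rng, otu_sequences[otu], error_rate)
                    pre = _random_dna(rng, int(rng.integers(*flank_range)))
                    suf = _random_dna(rng, int(rng.integers(*flank_range)))
                    fwd = pre + anchor + seg + suf
                    if fwd.count(anchor) == 1 and rc_anchor not in fwd:
                        break
                else:
                    raise RuntimeError("anchor collision persisted; "
                                       "check anchor/background lengths")
                emitted = _revcomp(fwd) if rng.random() < revcomp_prob else fwd
                rid = f"{spec.region_name}_r{counter:07d}"
                counter += 1
                reads.append(Read(id=rid, sequence=emitted))
                provenance[rid] = (sample, otu, seg)
    return ReadSet(reads=reads, region_label=spec.region_name), provenance


def simulate_background_reads(n: int, anchors: list[str], seed: int,
                              length_range: tuple[int, int] = (120, 200),
                              max_retries: int = 50) -> ReadSet:
    """Anchor-free background reads (fail trimming by construction)."""
    rng = rng_for(seed, "background-reads")
    bad = list(anchors) + [_revcomp(a) for a in anchors]
    reads = []
    for i in range(n):
        for _ in range(max_retries):
            seq = _random_dna(rng, int(rng.integers(*length_range)))
            if not any(b in seq for b in bad):
                break
        else:
            raise RuntimeError("could not generate anchor-free background")
        reads.append(Read(id=f"bg_r{i:06d}", sequence=seq))
    return ReadSet(reads=reads, region_label="background")


def simulate_arisa(meta: Metacommunity, seed: int,
                   jitter: float = 0.5,
                   length_range: tuple[float, float] = (200.0, 1200.0),
                   grid_step: float = 3.0,
                   fluorescence_scale: float = 1000.0):
    """ARISA profiles: one peak per occupied species per lake.

    Species fragment lengths are drawn without replacement from a grid
    of ``grid_step``-spaced lengths (the default 3.0 nt is a multiple
    of the 1.5 binning window, so an aligned binning frame exists) and
    each observation is jittered uniformly on +-``jitter`` nt.
    Fluorescence is proportional to relative abundance.

    Returns ``(profiles, species_lengths)``.
    """
    rng = rng_for(seed, "arisa")
    grid = np.arange(length_range[0], length_range[1], grid_step)
    n_sp = len(meta.species_ids)
    if n_sp > grid.size:
        raise ValueError(
            f"{n_sp} species exceed the {grid.size} distinct fragment "
            "lengths available; widen length_range or shrink grid_step")
    lengths = rng.choice(grid, size=n_sp, replace=False)
    species_lengths = dict(zip(meta.species_ids, lengths.tolist()))
    profiles = []
    for l, lake in enumerate(meta.lake_ids):
        occ = meta.occupancy[l]
        idx = np.nonzero(occ)[0]
        obs = lengths[idx]
        if jitter > 0:
            obs = obs + rng.uniform(-jitter, jitter, size=idx.size)
        fluo = meta.abundances[l, idx] * fluorescence_scale
        profiles.append(PeakProfile(sample_id=lake,
                                    fragment_lengths=obs,
                                    fluorescences=fluo))
    return profiles, species_lengths


def assign_classes(tree: TreeNode, n_classes: int = 12) -> dict[str, str]:
    """Phylogenetically coherent class labels: contiguous postorder blocks."""
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    labels = {}
    per = max(1, int(np.ceil(n / n_classes)))
    for i, sp in enumerate(tips):
        labels[sp] = f"class{i // per:02d}"
    return labels


@dataclass
class SyntheticDataset:
    """The full synthetic study: truth plus every region's view of it."""

    config: TruthConfig
    metacommunity: Metacommunity
    tree: TreeNode
    resolutions: dict[str, ResolutionResult]
    tables: dict[str, OTUTable]
    region_trees: dict[str, TreeNode]
    arisa_profiles: list[PeakProfile]
    species_fragment_lengths: dict[str, float]
    species_classes: dict[str, str]

    @property
    def lake_ids(self) -> list[str]:
        return self.metacommunity.lake_ids

    def true_lake_richness(self) -> dict[str, int]:
        occ = self.metacommunity.occupancy
        return {lake: int(occ[l].sum())
                for l, lake in enumerate(self.metacommunity.lake_ids)}


def generate_dataset(config: TruthConfig, arisa_jitter: float = 0.5) -> SyntheticDataset:
    """Run the whole generator: truth, tree, per-region tables, ARISA."""
    meta = simulate_metacommunity(config)
    tree = simulate_tree(config.n_species, config.seed)
    # shared per-species resolvability score: coarse regions lump
    # overlapping sets of hard-to-resolve species
    lumpability = rng_for(config.seed, "lumpability").random(config.n_species)
    resolutions: dict[str, ResolutionResult] = {}
    tables: dict[str, OTUTable] = {}
    region_trees: dict[str, TreeNode] = {}
    for spec in config.region_specs:
        res = apply_resolution(tree, spec, config.seed,
                               lumpability=lumpability)
        ab = region_abundances(meta, res, seed=config.seed)
        tables[spec.region_name] = sample_otu_table(
            ab, res.otu_ids, meta.lake_ids, config.depth_per_lake,
            config.seed, region_label=spec.region_name)
        resolutions[spec.region_name] = res
        region_trees[spec.region_name] = res.tree
    profiles, frag = simulate_arisa(meta, config.seed, jitter=arisa_jitter)
    classes = assign_classes(tree)
    return SyntheticDataset(config, meta, tree, resolutions, tables,
                            region_trees, profiles, frag, classes)
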