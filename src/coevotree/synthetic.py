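"""Synthetic benchmark generator for the co-evolution pipeline.

Real mirrortree studies start from hundreds of sequenced genomes, curated
interaction databases and all-vs-all BLAST runs — none of which fit a
self-contained, reproducible test bed.  This module generates the whole
study's inputs from a seeded generative model so that every downstream
stage (taxonomy sampling, orthology, tree building, co-evolution scoring,
ROC evaluation) can be exercised end to end without any download.

Generative model
----------------
A species phylogeny is drawn from a Yule (pure-birth) process.  Each
protein family's inter-ortholog distance matrix is a noisy multiplicative
distortion of the species patristic matrix::

    d_f(i, j) = t(i, j) * exp(g_f(i, j))

where ``t`` is the species patristic distance and ``g_f`` is a zero-mean
Gaussian rate perturbation with standard deviation ``noise_sd``,
symmetric over organism pairs.  For a designated set of *interacting*
family pairs the perturbation is partially shared: writing the
co-evolution strength as the correlation ``rho``, each member of an
interacting pair receives ``g = s + e`` with a shared component ``s`` of
variance ``rho * noise_sd**2`` and an independent component ``e`` of
variance ``(1 - rho) * noise_sd**2``, so that corr(g_f1, g_f2) = rho and
the marginal variance matches non-interacting families.

Two interaction "ages" are modeled.  *Old* interactions share the
perturbation across the whole organism set (``recent_clade_fraction = 1``).
*Recent* interactions share it only between organisms inside one clade of
the species tree, emulating interactions that exist in a group of
closely related organisms but have been rewired or lost elsewhere; outside
the clade the two families evolve independently.

Phylogenetic redundancy (over-represented strains) is modeled by
replacing randomly chosen leaves with cherries of two nearly identical
strains separated by a tiny branch length.

Reproducibility: one root seed; every stochastic step draws from its own
substream derived via ``numpy.random.SeedSequence(seed, spawn_key=...)``,
so identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .evaluation import GoldStandard, generate_negatives
from .phylo import (
    Alignment,
    DistanceMatrix,
    clone_tree,
    patristic_distances,
    read_newick,
    write_newick,
    write_phylip_square,
)
from .taxonomy import TaxonomyTree, write_taxonomy

__all__ = [
    "SimulationConfig",
    "SimulatedBenchmark",
    "SimulatedHits",
    "simulate_species_tree",
    "add_strain_redundancy",
    "simulate_family_matrix",
    "taxonomy_from_tree",
    "simulate_benchmark",
    "emit_sequences",
    "emit_hits",
    "write_benchmark",
]

# named RNG substreams (spawn keys derived from the root seed)
_STREAMS = {
    "tree": 0,
    "strains": 1,
    "family": 2,
    "shared": 3,
    "proteome": 4,
    "sequences": 5,
    "hits": 6,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    key = (_STREAMS[stream],) + tuple(int(x) for x in extra)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated benchmark.

    Defaults describe a desk-scale benchmark: 40 organisms, 60 protein
    families of which 20 pairs co-evolve strongly (rho = 0.9) under
    moderate rate noise (sigma = 0.3), full family retention, no strain
    redundancy and taxonomy-wide ("old") interactions.
    """

    n_organisms: int = 40
    n_families: int = 60
    n_interacting_pairs: int = 20
    coevolution_strength: float = 0.9  # correlation rho of rate perturbations
    noise_sd: float = 0.3  # sigma of the log-normal distance noise
    retention_prob: float = 1.0  # per-organism family presence probability
    redundancy_strains: int = 0  # leaves to duplicate into strain cherries
    strain_epsilon: float = 1e-4  # branch length of duplicated strains
    recent_clade_fraction: float = 1.0  # 1 = taxonomy-wide co-evolution
    seed: int = 0

    def __post_init__(self):
        if self.n_organisms < 3:
            raise ValueError("n_organisms must be >= 3")
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if not 0 <= self.n_interacting_pairs <= self.n_families // 2:
            raise ValueError("n_interacting_pairs must be <= n_families / 2")
        if not 0.0 <= self.coevolution_strength <= 1.0:
            raise ValueError("coevolution_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in (0, 1]")
        if self.redundancy_strains < 0:
            raise ValueError("redundancy_strains must be >= 0")
        if self.strain_epsilon <= 0:
            raise ValueError("strain_epsilon must be > 0")
        if not 0.0 < self.recent_clade_fraction <= 1.0:
            raise ValueError("recent_clade_fraction must be in (0, 1]")


@dataclass
class SimulatedBenchmark:
    """Complete simulated study: tree, taxonomy, family matrices, gold standard."""

    species_tree: dendropy.Tree
    taxonomy: TaxonomyTree
    family_matrices: dict[str, DistanceMatrix]
    gold: GoldStandard
    config: SimulationConfig
    interacting_pairs: tuple[tuple[str, str], ...]
    clade_organisms: tuple[str, ...]
    degenerate_families: frozenset[str] = field(default_factory=frozenset)

    @property
    def organisms(self) -> tuple[str, ...]:
        return tuple(sorted(lf.taxon.label for lf in self.species_tree.leaf_node_iter()))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_organisms: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Draw a binary rooted tree with ``n_organisms`` leaves from a Yule process.

    Waiting times between successive splits are exponential with rate
    ``birth_rate * k`` for ``k`` extant lineages; the lineage to split is
    chosen uniformly.  A final waiting period is appended so that every
    pendant edge has strictly positive length.  Leaves are labeled
    ``ORG000, ORG001, ...`` in tree traversal order.
    """
    if n_organisms < 3:
        raise ValueError("n_organisms must be >= 3")
    rng = _rng(seed, "tree")

    def new_node():
        return {"children": [], "pending": 0.0}

    root = new_node()
    first = [new_node(), new_node()]
    root["children"] = first
    active = list(first)
    while len(active) < n_organisms:
        k = len(active)
        dt = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node["pending"] += dt
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        kids = [new_node(), new_node()]
        parent["children"] = kids
        active.extend(kids)
    dt = rng.exponential(1.0 / (birth_rate * n_organisms))
    for node in active:
        node["pending"] += dt

    labels = iter(f"ORG{i:03d}" for i in range(n_organisms))

    def to_newick(node) -> str:
        if not node["children"]:
            return f"{next(labels)}:{node['pending']:.17g}"
        inner = ",".join(to_newick(c) for c in node["children"])
        return f"({inner}):{node['pending']:.17g}"

    inner = ",".join(to_newick(c) for c in root["children"])
    return read_newick(f"({inner});")


def add_strain_redundancy(
    tree: dendropy.Tree, k: int, epsilon: float, seed: int
) -> dendropy.Tree:
    """Duplicate ``k`` random leaves into near-identical strain cherries.

    Each chosen leaf ``X`` becomes an internal node with two children
    ``X`` and ``X_strain1`` at branch length ``epsilon``, so the two
    strains sit at patristic distance ``2 * epsilon`` while all distances
    between non-duplicated leaves are unchanged.  Returns a new tree; the
    input is not modified.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    out = clone_tree(tree)
    leaves = sorted(out.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if k > len(leaves):
        raise ValueError(f"cannot duplicate {k} of {len(leaves)} leaves")
    if k == 0:
        return out
    rng = _rng(seed, "strains")
    chosen = rng.choice(len(leaves), size=k, replace=False)
    tns = out.taxon_namespace
    for i in sorted(int(c) for c in chosen):
        leaf = leaves[i]
        label = leaf.taxon.label
        leaf.taxon = None
        c1 = leaf.new_child(edge_length=float(epsilon))
        c2 = leaf.new_child(edge_length=float(epsilon))
        c1.taxon = tns.new_taxon(label)
        c2.taxon = tns.new_taxon(f"{label}_strain1")
    return out


# ---------------------------------------------------------------------------
# family matrices
# ---------------------------------------------------------------------------

def _symmetric_normal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Zero-diagonal symmetric Gaussian field over organism pairs."""
    g = np.zeros((n, n))
    if sd > 0 and n > 1:
        iu = np.triu_indices(n, k=1)
        vals = rng.normal(0.0, sd, size=len(iu[0]))
        g[iu] = vals
        g = g + g.T
    return g


def simulate_family_matrix(
    species_tree,
    rate_perturbation: np.ndarray | None = None,
    retention_prob: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    retention_groups: Mapping[str, str] | None = None,
) -> DistanceMatrix:
    """One family's distance matrix from the multiplicative log-normal model.

    ``species_tree`` may be a tree or a precomputed species
    :class:`DistanceMatrix`.  ``rate_perturbation`` is an optional
    symmetric matrix (aligned to the species matrix's canonical organism
    order) added to the independently drawn noise of standard deviation
    ``noise_sd``.  Each organism is retained independently with
    probability ``retention_prob``; ``retention_groups`` maps organism
    labels to group keys that are retained or lost together (used to give
    redundant strains the shared gene content of their sibling).  Families
    with fewer than 3 retained organisms are still returned (flagged
    degenerate by the caller).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 < retention_prob <= 1.0:
        raise ValueError("retention_prob must be in (0, 1]")
    t = species_tree if isinstance(species_tree, DistanceMatrix) else patristic_distances(species_tree)
    n = t.n
    rng = _rng(seed, "family")
    g = _symmetric_normal(rng, n, noise_sd)
    if rate_perturbation is not None:
        pert = np.asarray(rate_perturbation, dtype=float)
        if pert.shape != (n, n):
            raise ValueError("rate_perturbation shape does not match organism count")
        g = g + pert
    d = t.values * np.exp(g)
    if retention_prob < 1.0:
        groups = sorted({
            (retention_groups or {}).get(lab, lab) for lab in t.labels
        })
        draw = dict(zip(groups, rng.random(len(groups))))
        keep = np.array([
            draw[(retention_groups or {}).get(lab, lab)] < retention_prob
            for lab in t.labels
        ])
        labels = [lab for lab, k in zip(t.labels, keep) if k]
        d = d[np.ix_(keep, keep)]
    else:
        labels = list(t.labels)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# taxonomy from the species tree
# ---------------------------------------------------------------------------

def taxonomy_from_tree(
    tree: dendropy.Tree, seed: int = 0, max_depth: int = 4
) -> TaxonomyTree:
    """Derive a ranked taxonomy by cutting the species tree at fixed depths.

    Internal tree nodes down to ``max_depth`` become taxonomy nodes (rank
    ``rank<k>`` at depth ``k``); each genome attaches to its deepest kept
    ancestor, so clades of the species tree map exactly onto taxonomic
    groups and strain cherries collapse into shared species-level nodes.
    Proteome sizes are drawn uniformly from 1000-5999 proteins.
    """
    nodes: dict[str, tuple[str, str, str]] = {"T0": ("T0", "root", "cellular organisms")}
    attachments: dict[str, str] = {}
    counter = [0]

    def walk(node, parent_id: str, depth: int):
        for child in node.child_nodes():
            if child.is_leaf():
                attachments[child.taxon.label] = parent_id
                continue
            if depth + 1 <= max_depth:
                counter[0] += 1
                nid = f"T{counter[0]}"
                nodes[nid] = (parent_id, f"rank{depth + 1}", f"clade_{counter[0]}")
                walk(child, nid, depth + 1)
            else:
                walk(child, parent_id, depth)

    walk(tree.seed_node, "T0", 0)
    genomes = sorted(attachments)
    rng = _rng(seed, "proteome")
    sizes = {g: int(rng.integers(1000, 6000)) for g in genomes}
    return TaxonomyTree(
        nodes=nodes, root="T0", genome_attachments=attachments, proteome_sizes=sizes
    )


# ---------------------------------------------------------------------------
# benchmark assembly
# ---------------------------------------------------------------------------

def _pick_clade(tree: dendropy.Tree, fraction: float) -> tuple[str, ...]:
    """Internal-node clade whose leaf count best matches ``fraction`` of leaves."""
    n = sum(1 for _ in tree.leaf_node_iter())
    target = fraction * n
    best = None
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        score = abs(len(leaves) - target)
        if best is None or score < best[0]:
            best = (score, tuple(leaves))
    if best is None:  # star tree; fall back to a prefix of the leaf list
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        return tuple(leaves[: max(3, int(round(target)))])
    return best[1]


def family_ids(n_families: int) -> list[str]:
    return [f"FAM{i:03d}" for i in range(n_families)]


_STRAIN_SUFFIX = "_strain1"


def _base_organism(label: str) -> str:
    """Strip the redundant-strain suffix added by :func:`add_strain_redundancy`."""
    return label[: -len(_STRAIN_SUFFIX)] if label.endswith(_STRAIN_SUFFIX) else label


def simulate_benchmark(config: SimulationConfig) -> SimulatedBenchmark:
    """Generate the full simulated study bundle for ``config``.

    The first ``2 * n_interacting_pairs`` families are paired off as the
    interacting (positive) pairs; the remainder evolve independently.
    With ``recent_clade_fraction < 1`` the shared perturbation applies
    only to organism pairs inside the designated clade, and the two
    families receive independent perturbations elsewhere.
    """
    if not isinstance(config, SimulationConfig):
        raise ValueError("simulate_benchmark expects a SimulationConfig")
    tree = simulate_species_tree(config.n_organisms, config.seed)
    if config.redundancy_strains > 0:
        tree = add_strain_redundancy(
            tree, config.redundancy_strains, config.strain_epsilon, config.seed
        )
    t = patristic_distances(tree)
    taxonomy = taxonomy_from_tree(tree, seed=config.seed)

    fams = family_ids(config.n_families)
    pairs = tuple(
        (fams[2 * i], fams[2 * i + 1]) for i in range(config.n_interacting_pairs)
    )
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a

    if config.recent_clade_fraction < 1.0:
        clade = _pick_clade(tree, config.recent_clade_fraction)
    else:
        clade = t.labels

    # Rate perturbations are drawn at the level of *base* organisms (strain
    # suffixes stripped) and copied to redundant strain leaves: a strain's
    # ortholog is essentially the same sequence as its sibling's, so the
    # duplicated leaves must duplicate matrix coordinates without adding
    # independent information -- that duplication is exactly what inflates
    # raw tree correlations under phylogenetic redundancy.
    base_labels = sorted({_base_organism(lab) for lab in t.labels})
    bpos = {lab: i for i, lab in enumerate(base_labels)}
    bmap = np.array([bpos[_base_organism(lab)] for lab in t.labels])
    same_base = bmap[:, None] == bmap[None, :]
    n_base = len(base_labels)

    def expand(g_base: np.ndarray) -> np.ndarray:
        g = g_base[np.ix_(bmap, bmap)].copy()
        g[same_base] = 0.0
        return g

    in_clade = np.array(
        [any(_base_organism(c) == lab for c in clade) for lab in base_labels]
    )
    clade_pair = np.outer(in_clade, in_clade)

    rho = config.coevolution_strength
    sigma = config.noise_sd
    shared_sd = sigma * np.sqrt(rho)
    indep_sd = sigma * np.sqrt(1.0 - rho)

    # shared components, one per interacting pair
    shared: dict[tuple[str, str], np.ndarray] = {}
    for pi, pr in enumerate(pairs):
        rng = _rng(config.seed, "shared", pi)
        shared[pr] = _symmetric_normal(rng, n_base, shared_sd)

    matrices: dict[str, DistanceMatrix] = {}
    degenerate: set[str] = set()
    for fi, fam in enumerate(fams):
        rng_f = _rng(config.seed, "family", fi)
        if fam in partner:
            pr = (fam, partner[fam]) if fam < partner[fam] else (partner[fam], fam)
            base = shared[pr]
            if config.recent_clade_fraction < 1.0:
                # outside the clade the interaction does not exist: replace the
                # shared component by family-private noise of equal variance
                private = _symmetric_normal(rng_f, n_base, shared_sd)
                base = np.where(clade_pair, base, private)
            g_base = base + _symmetric_normal(rng_f, n_base, indep_sd)
        else:
            g_base = _symmetric_normal(rng_f, n_base, sigma)
        dm = simulate_family_matrix(
            t,
            rate_perturbation=expand(g_base),
            retention_prob=config.retention_prob,
            noise_sd=0.0,
            seed=int(np.random.SeedSequence(config.seed, spawn_key=(100, fi)).generate_state(1)[0] % (2**31)),
            retention_groups={lab: _base_organism(lab) for lab in t.labels},
        )
        matrices[fam] = dm
        if dm.n < 3:
            degenerate.add(fam)

    gold = generate_negatives(set(map(tuple, pairs)), label="simulated")
    return SimulatedBenchmark(
        species_tree=tree,
        taxonomy=taxonomy,
        family_matrices=matrices,
        gold=gold,
        config=config,
        interacting_pairs=pairs,
        clade_organisms=tuple(clade),
        degenerate_families=frozenset(degenerate),
    )


# ---------------------------------------------------------------------------
# optional sequence-level fixtures (Jukes-Cantor-type evolution)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def emit_sequences(
    species_tree: dendropy.Tree,
    family_rates: Mapping[str, float],
    seq_length: int,
    seed: int,
    organisms: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, Alignment]:
    """Evolve aligned sequences along the species tree, one family per rate.

    Substitution follows the Jukes-Cantor model: along a branch of length
    ``d`` (scaled by the family rate) a site changes with probability
    ``(3/4) * (1 - exp(-4 d / 3))``, landing uniformly on the other three
    bases, so the expected p-distance between two leaves at patristic
    distance ``D`` is ``(3/4)(1 - exp(-4 D / 3))``.  ``organisms``
    optionally restricts each family's output to its retained organisms.
    """
    if seq_length < 50:
        raise ValueError("seq_length must be >= 50")
    out: dict[str, Alignment] = {}
    for fi, fam in enumerate(sorted(family_rates)):
        rate = float(family_rates[fam])
        if rate < 0:
            raise ValueError(f"negative rate for family {fam!r}")
        rng = _rng(seed, "sequences", fi)
        seqs: dict[str, np.ndarray] = {}

        def evolve(node, state: np.ndarray):
            for child in node.child_nodes():
                d = (child.edge.length or 0.0) * rate
                p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
                new = state.copy()
                mask = rng.random(seq_length) < p_change
                if mask.any():
                    new[mask] = (new[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
                if child.is_leaf():
                    seqs[child.taxon.label] = new
                else:
                    evolve(child, new)

        root_state = rng.integers(0, 4, seq_length)
        if species_tree.seed_node.is_leaf():
            raise ValueError("species tree has no internal structure")
        evolve(species_tree.seed_node, root_state)
        keep = sorted(seqs)
        if organisms is not None and fam in organisms:
            allowed = set(organisms[fam])
            keep = [k for k in keep if k in allowed]
        out[fam] = Alignment([(k, "".join(_BASES[seqs[k]])) for k in keep])
    return out


# ---------------------------------------------------------------------------
# synthetic all-vs-all hit tables
# ---------------------------------------------------------------------------

@dataclass
class SimulatedHits:
    """Synthetic BLAST-tabular hits with ground-truth orthology."""

    rows: list[tuple]
    genome_of: dict[str, str]
    sequence_lengths: dict[str, int]
    truth: dict[tuple[str, str], str]  # (reference protein, genome) -> ortholog
    reference_genome: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write("\t".join(str(x) for x in r) + "\n")


def emit_hits(
    benchmark: SimulatedBenchmark, seed: int | None = None, reference_genome: str | None = None
) -> SimulatedHits:
    """Emit a 12-column hit table consistent with the benchmark's families.

    Every family contributes one protein per retained organism
    (``FAM|ORG`` ids, one shared length per family); reciprocal hits
    between the reference-genome protein and each other organism's protein
    carry very low E-values and ~90% mutual coverage.  Decoy cross-family
    hits (worse E-values) and low-coverage hits are added so that E-value,
    coverage and best-hit filtering are all exercised.
    """
    seed = benchmark.config.seed if seed is None else seed
    organisms = benchmark.organisms
    reference_genome = reference_genome or organisms[0]
    rng = _rng(seed, "hits")
    rows: list[tuple] = []
    genome_of: dict[str, str] = {}
    lengths: dict[str, int] = {}
    truth: dict[tuple[str, str], str] = {}

    def hit(q, s, e, length):
        mismatch = int(rng.integers(0, max(1, length // 5)))
        rows.append(
            (
                q,
                s,
                round(80.0 + float(rng.uniform(-5, 5)), 1),
                length,
                mismatch,
                0,
                1,
                length,
                1,
                length,
                f"{e:.2e}",
                round(200.0 + float(rng.uniform(0, 300)), 1),
            )
        )

    fams = sorted(benchmark.family_matrices)
    for fam in fams:
        dm = benchmark.family_matrices[fam]
        L = int(rng.integers(150, 500))
        members = {}
        for org in dm.labels:
            pid = f"{fam}|{org}"
            genome_of[pid] = org
            lengths[pid] = L
            members[org] = pid
        if reference_genome not in members:
            continue
        ref_pid = members[reference_genome]
        aln = max(1, int(round(0.9 * L)))
        for org, pid in members.items():
            if org == reference_genome:
                continue
            e = 10.0 ** float(rng.uniform(-150, -40))
            hit(ref_pid, pid, e, aln)
            hit(pid, ref_pid, e, aln)
            truth[(ref_pid, org)] = pid
        truth[(ref_pid, reference_genome)] = ref_pid

    # decoys: cross-family hits with passable coverage but worse E-values,
    # and well-scoring hits failing the 70% coverage rule
    for fa, fb in zip(fams, fams[1:]):
        da, db = benchmark.family_matrices[fa], benchmark.family_matrices[fb]
        common = sorted(set(da.labels) & set(db.labels) - {reference_genome})[:3]
        for org in common:
            pa, pb = f"{fa}|{reference_genome}", f"{fb}|{org}"
            if pa not in lengths or pb not in lengths:
                continue
            aln = max(1, int(round(0.8 * min(lengths[pa], lengths[pb]))))
            hit(pa, pb, 10.0 ** float(rng.uniform(-20, -8)), aln)
            short = max(1, int(round(0.4 * min(lengths[pa], lengths[pb]))))
            hit(pb, pa, 10.0 ** float(rng.uniform(-40, -30)), short)

    return SimulatedHits(
        rows=rows,
        genome_of=genome_of,
        sequence_lengths=lengths,
        truth=truth,
        reference_genome=reference_genome,
    )


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_benchmark(benchmark: SimulatedBenchmark, out_dir) -> Path:
    """Write the benchmark bundle: Newick tree, taxonomy TSVs, per-family
    PHYLIP matrices, gold-standard TSV and a JSON provenance file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(benchmark.species_tree, out / "species_tree.nwk")
    write_taxonomy(benchmark.taxonomy, out / "taxonomy")
    fam_dir = out / "families"
    fam_dir.mkdir(exist_ok=True)
    for fam in sorted(benchmark.family_matrices):
        write_phylip_square(benchmark.family_matrices[fam], fam_dir / f"{fam}.phy")
    with open(out / "gold.tsv", "w") as fh:
        fh.write("protein_a\tprotein_b\tlabel\n")
        for a, b in sorted(benchmark.gold.positives):
            fh.write(f"{a}\t{b}\tpositive\n")
    provenance = {
        "config": asdict(benchmark.config),
        "clade_organisms": list(benchmark.clade_organisms),
        "degenerate_families": sorted(benchmark.degenerate_families),
        "n_organisms": len(benchmark.organisms),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
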