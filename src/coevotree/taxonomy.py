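"""Taxonomy trees and taxonomy-based organism sampling.

The reference taxonomy is a rooted hierarchy of named, ranked nodes (the
NCBI taxonomy shape) to which genomes are attached; it carries no branch
lengths.  Two sampling schemes produce nested or level-wise organism
subsets used as reference sets for tree building:

``nearest``
    Follow the reference genome's lineage from its attachment node back to
    the root and, at each visited node, take every genome in that node's
    subtree.  ``nearest_1`` is the reference genome's own species-level
    group; the last set is the whole genome collection.

``level``
    Cut the hierarchy at successive depths starting below the root and
    take one genome per resulting group — the genome with the largest
    proteome, maximizing the chance of finding orthologs in it.

Both samplers are deterministic: ties on proteome size are broken by
lexicographic genome id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, FormatError

__all__ = [
    "TaxonomyTree",
    "OrganismSet",
    "read_taxonomy",
    "write_taxonomy",
    "lineage",
    "sample_nearest",
    "sample_level",
    "read_organism_set",
    "write_organism_set",
]

_ROOT_PARENTS = {"", "-", "none", "null", "0"}


@dataclass
class OrganismSet:
    """A named, ordered subset of genomes produced by a sampling criterion."""

    label: str
    genomes: tuple[str, ...]
    criterion: str  # "nearest" | "level" | "explicit"
    index: int

    def __post_init__(self):
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError(f"duplicate genomes in organism set {self.label!r}")

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, genome: str) -> bool:
        return genome in self.genomes


@dataclass
class TaxonomyTree:
    """Rooted hierarchy of ranked nodes with genomes attached to nodes.

    ``nodes`` maps node_id -> (parent_id, rank, name); the root's parent is
    itself.  ``genome_attachments`` maps genome id -> node id;
    ``proteome_sizes`` maps genome id -> protein count (may be partial).
    """

    nodes: dict[str, tuple[str, str, str]]
    root: str
    genome_attachments: dict[str, str] = field(default_factory=dict)
    proteome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        roots = [
            nid
            for nid, (pid, _, _) in self.nodes.items()
            if pid == nid or pid in _ROOT_PARENTS
        ]
        if len(roots) != 1 or roots[0] != self.root:
            raise FormatError(f"expected exactly one root {self.root!r}, found {roots}")
        for nid, (pid, _, _) in self.nodes.items():
            if nid == self.root:
                continue
            if pid not in self.nodes:
                raise FormatError(f"node {nid!r} has unknown parent {pid!r}")
        # cycle check: every node must reach the root
        for nid in self.nodes:
            seen = set()
            cur = nid
            while cur != self.root:
                if cur in seen:
                    raise FormatError(f"cycle detected at node {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur][0]
        for g, nid in self.genome_attachments.items():
            if nid not in self.nodes:
                raise FormatError(f"genome {g!r} attached to missing node {nid!r}")

    # -- structure helpers ------------------------------------------------
    def parent(self, node_id: str) -> str:
        return self.nodes[node_id][0]

    def depth(self, node_id: str) -> int:
        d = 0
        while node_id != self.root:
            node_id = self.parent(node_id)
            d += 1
        return d

    def node_lineage(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        out = [node_id]
        while node_id != self.root:
            node_id = self.parent(node_id)
            out.append(node_id)
        return out

    def ancestor_at_depth(self, node_id: str, depth: int) -> str:
        lin = self.node_lineage(node_id)  # depth(node) .. 0
        want = len(lin) - 1 - depth
        if want < 0:
            raise ValueError(f"node {node_id!r} is shallower than depth {depth}")
        return lin[want]

    def genomes(self) -> list[str]:
        return sorted(self.genome_attachments)

    def genomes_under(self, node_id: str) -> list[str]:
        """All genomes attached at or below ``node_id`` (sorted)."""
        desc = {node_id}
        changed = True
        while changed:  # tree is small; simple fixed-point over parent links
            changed = False
            for nid, (pid, _, _) in self.nodes.items():
                if nid not in desc and pid in desc and nid != self.root:
                    desc.add(nid)
                    changed = True
        return sorted(g for g, a in self.genome_attachments.items() if a in desc)


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def read_taxonomy(nodes_source, names_source=None, genomes_source=None) -> TaxonomyTree:
    """Parse a taxonomy from NCBI-dump-style files or the simplified TSV.

    ``nodes_source``: a ``nodes.dmp``-dialect file (``\\t|\\t`` separators,
    fields tax_id, parent, rank) or a 4-column TSV with header
    ``node_id  parent_id  rank  name``.  For the NCBI dialect,
    ``names_source`` supplies scientific names.  ``genomes_source`` is an
    optional TSV with header ``genome_id  node_id  [proteome_size]``.
    """
    text = _read_text(nodes_source)
    if "\t|" in text:
        nodes = _parse_ncbi_nodes(text)
        names = _parse_ncbi_names(_read_text(names_source)) if names_source else {}
        nodes = {
            nid: (pid, rank, names.get(nid, nid)) for nid, (pid, rank) in nodes.items()
        }
    else:
        nodes = _parse_tsv_nodes(text)
    roots = [nid for nid, (pid, _, _) in nodes.items() if pid == nid or pid in _ROOT_PARENTS]
    if len(roots) != 1:
        raise FormatError(f"expected exactly one root node, found {roots}")
    attachments: dict[str, str] = {}
    sizes: dict[str, int] = {}
    if genomes_source is not None:
        for lineno, parts in _tsv_rows(_read_text(genomes_source), header="genome_id"):
            if len(parts) < 2:
                raise FormatError(f"genomes line {lineno}: expected >= 2 columns")
            attachments[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2] != "":
                sizes[parts[0]] = int(parts[2])
    return TaxonomyTree(nodes=nodes, root=roots[0], genome_attachments=attachments, proteome_sizes=sizes)


def write_taxonomy(tree: TaxonomyTree, out_dir) -> tuple[Path, Path]:
    """Write ``nodes.tsv`` and ``genomes.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes_path = out / "nodes.tsv"
    genomes_path = out / "genomes.tsv"
    with open(nodes_path, "w") as fh:
        fh.write("node_id\tparent_id\trank\tname\n")
        for nid in sorted(tree.nodes):
            pid, rank, name = tree.nodes[nid]
            fh.write(f"{nid}\t{pid}\t{rank}\t{name}\n")
    with open(genomes_path, "w") as fh:
        fh.write("genome_id\tnode_id\tproteome_size\n")
        for g in sorted(tree.genome_attachments):
            size = tree.proteome_sizes.get(g, "")
            fh.write(f"{g}\t{tree.genome_attachments[g]}\t{size}\n")
    return nodes_path, genomes_path


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    p = str(source)
    if "\n" in p or "\t" in p:
        return p
    with open(p) as fh:
        return fh.read()


def _parse_ncbi_nodes(text: str) -> dict[str, tuple[str, str]]:
    nodes = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("|\t ").split("\t|\t")]
        if len(parts) < 3:
            raise FormatError(f"nodes.dmp line {lineno}: expected >= 3 fields")
        nodes[parts[0]] = (parts[1], parts[2])
    return nodes


def _parse_ncbi_names(text: str) -> dict[str, str]:
    names: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("|\t ").split("\t|\t")]
        if len(parts) >= 4 and parts[3] == "scientific name":
            names[parts[0]] = parts[1]
        elif parts[0] not in names and len(parts) >= 2:
            names.setdefault(parts[0], parts[1])
    return names


def _parse_tsv_nodes(text: str) -> dict[str, tuple[str, str, str]]:
    nodes = {}
    for lineno, parts in _tsv_rows(text, header="node_id"):
        if len(parts) != 4:
            raise FormatError(f"taxonomy TSV line {lineno}: expected 4 columns, got {len(parts)}")
        nid, pid, rank, name = parts
        nodes[nid] = (pid, rank, name)
    return nodes


def _tsv_rows(text: str, header: str):
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty TSV input")
    first = lines[0].split("\t")
    if not first or first[0] != header:
        raise FormatError(f"TSV header must start with {header!r}, got {lines[0]!r}")
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line.rstrip("\n").split("\t")


# ---------------------------------------------------------------------------
# lineage and sampling
# ---------------------------------------------------------------------------

def lineage(tree: TaxonomyTree, genome_id: str) -> list[str]:
    """Node ids from the genome's attachment node up to the root, inclusive."""
    if genome_id not in tree.genome_attachments:
        raise KeyError(f"unknown genome {genome_id!r}")
    return tree.node_lineage(tree.genome_attachments[genome_id])


def sample_nearest(tree: TaxonomyTree, reference_genome: str) -> list[OrganismSet]:
    """Nested organism sets along the reference genome's lineage.

    ``nearest_k`` contains every genome in the subtree of the k-th lineage
    node (k=1 is the attachment node itself); the final set covers all
    genomes in the taxonomy.
    """
    sets = []
    for k, node in enumerate(lineage(tree, reference_genome), 1):
        genomes = tree.genomes_under(node)
        sets.append(
            OrganismSet(label=f"nearest_{k}", genomes=tuple(genomes), criterion="nearest", index=k)
        )
    return sets


def sample_level(tree: TaxonomyTree) -> list[OrganismSet]:
    """Level-wise organism sets: one genome per depth-k group.

    At depth k each genome belongs to the group of its attachment node's
    depth-k ancestor; genomes attached above the cut form singleton groups.
    Within a group the genome with the largest proteome is selected (ties
    broken by lexicographic genome id).  Genomes without a proteome size
    are excluded with a warning.  Cuts deepen until every genome is its own
    group, so the deepest level returns the whole usable collection.
    """
    usable = []
    for g in tree.genomes():
        if g in tree.proteome_sizes:
            usable.append(g)
        else:
            warnings.warn(f"genome {g!r} has no proteome size; excluded from 'level' sampling")
    if not usable:
        raise ConfigurationError("no genomes with proteome sizes available")
    depths = {g: tree.depth(tree.genome_attachments[g]) for g in usable}
    max_k = max(depths.values()) + 1
    sets: list[OrganismSet] = []
    for k in range(1, max_k + 1):
        groups: dict[object, list[str]] = {}
        for g in usable:
            if depths[g] >= k:
                key = tree.ancestor_at_depth(tree.genome_attachments[g], k)
            else:
                key = ("own", g)
            groups.setdefault(key, []).append(g)
        chosen = sorted(
            min(members, key=lambda g: (-tree.proteome_sizes[g], g))
            for members in groups.values()
        )
        sets.append(
            OrganismSet(label=f"level_{k}", genomes=tuple(chosen), criterion="level", index=k)
        )
        if len(chosen) == len(usable):
            break
    return sets


# ---------------------------------------------------------------------------
# organism-set files
# ---------------------------------------------------------------------------

def write_organism_set(oset: OrganismSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# criterion={oset.criterion} index={oset.index} label={oset.label}\n")
        for g in oset.genomes:
            fh.write(g + "\n")


def read_organism_set(path) -> OrganismSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    criterion, index, label = "explicit", 0, Path(str(path)).stem
    genomes = []
    for ln in lines:
        if ln.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in ln.lstrip("# ").split() if "=" in kv
            )
            criterion = meta.get("criterion", criterion)
            index = int(meta.get("index", index))
            label = meta.get("label", label)
        elif ln.strip():
            genomes.append(ln.strip())
    return OrganismSet(label=label, genomes=tuple(genomes), criterion=criterion, index=index)
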