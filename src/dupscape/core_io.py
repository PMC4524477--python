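"""Shared data model and readers/writers for FASTA, newick and tabular files.

Conventions used throughout the package:

* sequence intervals are 0-based, half-open internally; user-facing reports
  are 1-based inclusive;
* species tags are parsed from FASTA headers as the first ``|``-delimited
  token by default (configurable);
* species-tree branch lengths are differences of node *dates*, where a node's
  date is the expected pairwise synonymous distance (dS) between lineages
  that diverged at that node.  Leaves sit at date 0.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("dupscape")

__all__ = [
    "Transcript",
    "ProteinRecord",
    "AbundanceTable",
    "SearchThresholds",
    "Node",
    "Tree",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_table",
    "write_table",
    "load_config",
    "DEFAULT_CONFIG",
    "log_filter",
]


def log_filter(stage: str, n_in: int, n_out: int) -> None:
    """Log pipeline attrition for one filtering step (counts in/out)."""
    logger.info("%s: %d -> %d (removed %d)", stage, n_in, n_out, n_in - n_out)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """A nucleotide transcript with a species tag."""

    id: str
    species: str
    sequence: str
    source_library: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """Translated ORF of a transcript.

    ``frame`` follows the usual 6-frame convention: +1..+3 on the forward
    strand, -1..-3 on the reverse complement, the digit giving the 0-based
    offset + 1.  ``orf_start``/``orf_end`` are nucleotide coordinates on the
    *stranded* sequence (0-based, half-open).
    """

    transcript_id: str
    frame: int
    aa_sequence: str
    five_prime_complete: bool = False
    three_prime_complete: bool = False
    trimmed_to_first_M: bool = False
    species: Optional[str] = None
    orf_start: int = 0
    orf_end: int = 0

    def __post_init__(self) -> None:
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"invalid frame {self.frame}")
        if "*" in self.aa_sequence:
            raise ValueError(
                f"protein {self.transcript_id}: internal stop in aa sequence"
            )

    def __len__(self) -> int:
        return len(self.aa_sequence)


@dataclass
class SearchThresholds:
    """Identity/coverage thresholds for pairwise similarity searches."""

    identity_pct: float = 70.0
    coverage_pct: float = 60.0
    min_match_bp: int = 0
    evalue_cut: float = 1e-5

    def __post_init__(self) -> None:
        for v, nm in ((self.identity_pct, "identity"), (self.coverage_pct, "coverage")):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{nm}_pct must be in [0, 100], got {v}")


class AbundanceTable:
    """Transcript-by-library abundance matrix (TPM/eCPM-like values).

    Backed by a pandas DataFrame whose index is the transcript id and whose
    columns are ``(species, library)`` pairs.  The quantity used by the
    contamination filter is the *species-summed* abundance: the sum of a
    transcript's values over the libraries of one species.
    """

    def __init__(self, df: pd.DataFrame):
        if not isinstance(df.columns, pd.MultiIndex):
            raise ValueError("AbundanceTable columns must be (species, library) pairs")
        if (df.values < 0).any():
            raise ValueError("abundances must be non-negative")
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, float]]
    ) -> "AbundanceTable":
        """Build from (transcript_id, species, library, value) rows."""
        rows = list(records)
        df = pd.DataFrame(rows, columns=["transcript_id", "species", "library", "value"])
        wide = df.pivot_table(
            index="transcript_id",
            columns=["species", "library"],
            values="value",
            fill_value=0.0,
            aggfunc="sum",
        )
        return cls(wide)

    def species_sum(self, transcript_id: str, species: Optional[str] = None) -> float:
        """Summed abundance of one transcript over one species' libraries."""
        if transcript_id not in self.df.index:
            raise KeyError(f"transcript {transcript_id!r} missing from abundance table")
        row = self.df.loc[transcript_id]
        if species is None:
            return float(row.sum())
        if species not in self.df.columns.get_level_values(0):
            return 0.0
        return float(row[species].sum())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.df.index

    def to_tsv(self, path: str | Path) -> None:
        flat = self.df.copy()
        flat.columns = [f"{s}|{l}" for s, l in flat.columns]
        flat.index.name = "transcript_id"
        flat.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        flat = pd.read_csv(path, sep="\t", index_col=0)
        cols = pd.MultiIndex.from_tuples([tuple(c.split("|", 1)) for c in flat.columns])
        flat.columns = cols
        return cls(flat)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A node of a rooted tree.

    Carries the attributes every stage of the pipeline needs: an optional
    ``event`` label on internal nodes (``"duplication"`` / ``"speciation"``),
    the species-tree node each gene-tree node maps to (``species_map``),
    support, and a free-form ``meta`` dict used by the simulator for truth
    labels.
    """

    __slots__ = ("name", "length", "children", "parent", "event",
                 "species_map", "support", "meta")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.event: Optional[str] = None
        self.species_map: Optional["Node"] = None
        self.support: Optional[float] = None
        self.meta: dict = {}

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.name, self.length)
        dup.event = self.event
        dup.support = self.support
        dup.meta = dict(self.meta)
        for c in self.children:
            dup.add_child(c.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '(internal)'} children={len(self.children)}>"

    # -- serialization -----------------------------------------------------
    def to_newick(self, include_labels: bool = False) -> str:
        parts = []

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_labels and node.event:
                    s += {"duplication": "D", "speciation": "S"}.get(node.event, "")
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s

        parts.append(fmt(self))
        return "".join(parts) + ";"


class Tree:
    """A rooted tree with a single root :class:`Node`."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal shortcuts ----------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(names)
        found = {n.name for n in self.leaves()} & want
        if found != want:
            raise KeyError(f"leaves not in tree: {sorted(want - found)}")
        for node in self.postorder():
            if want <= node.leaf_names():
                return node
        raise RuntimeError("unreachable")  # root covers everything

    def to_newick(self, include_labels: bool = False) -> str:
        return self.root.to_newick(include_labels=include_labels)

    def copy(self) -> "Tree":
        return Tree(self.root.copy())


class SpeciesTree(Tree):
    """Rooted binary species tree with node dates in pairwise-dS units.

    Branch lengths encode date differences between parent and child; leaves
    are at date 0.  ``date(node)`` is the expected pairwise dS between two
    genes whose divergence traces to that node.
    """

    def __init__(self, root: Node):
        super().__init__(root)
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("species tree leaf labels must be unique")
        if not self.is_binary():
            raise ValueError("species tree must be binary")
        self._dates: dict[int, float] = {}
        self._index()

    def _index(self) -> None:
        self._by_leafset = {node.leaf_names(): node for node in self.preorder()}
        self._by_name = {n.name: n for n in self.leaves()}
        for node in self.postorder():
            if node.is_leaf:
                self._dates[id(node)] = 0.0
            else:
                self._dates[id(node)] = max(
                    self._dates[id(c)] + (c.length or 0.0) for c in node.children
                )

    def date(self, node: Node) -> float:
        return self._dates[id(node)]

    def node_by_leafset(self, names: Iterable[str]) -> Node:
        key = frozenset(names)
        if key not in self._by_leafset:
            raise KeyError(f"no species-tree node subtends exactly {sorted(key)}")
        return self._by_leafset[key]

    def leaf(self, species: str) -> Node:
        return self._by_name[species]

    def species(self) -> frozenset:
        return self.leaf_names()

    def lca(self, species_names: Iterable[str]) -> Node:
        return self.mrca(species_names)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _species_from_header(header: str, delimiter: str, field_idx: int) -> str:
    token = header.split()[0]
    parts = token.split(delimiter)
    return parts[field_idx] if field_idx < len(parts) else token


def read_fasta(
    path: str | Path,
    kind: str = "nucleotide",
    species_delimiter: str = "|",
    species_field: int = 0,
) -> list:
    """Read a FASTA file into Transcript or ProteinRecord objects.

    The header token before the first whitespace is the record id; the
    species tag is parsed from that token (first ``|``-delimited field by
    default).  Duplicate ids are a hard error; an empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("empty FASTA file: %s", path)
        return []
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        species = _species_from_header(rec.id, species_delimiter, species_field)
        if kind == "nucleotide":
            out.append(Transcript(id=rec.id, species=species, sequence=str(rec.seq)))
        elif kind == "protein":
            out.append(
                ProteinRecord(
                    transcript_id=rec.id, frame=1,
                    aa_sequence=str(rec.seq), species=species,
                )
            )
        else:
            raise ValueError(f"unknown FASTA kind {kind!r}")
    return out


def write_fasta(records: Sequence, path: str | Path) -> None:
    """Write Transcripts / ProteinRecords / (id, seq) pairs as FASTA."""
    seqrecs = []
    for r in records:
        if isinstance(r, Transcript):
            seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=""))
        elif isinstance(r, ProteinRecord):
            seqrecs.append(SeqRecord(Seq(r.aa_sequence), id=r.transcript_id, description=""))
        else:
            rid, seq = r
            seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _check_parentheses(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced parentheses at character {i}")
    if depth != 0:
        raise ValueError(f"unbalanced parentheses: {depth} unclosed '(' at end of input")


def _binarize(node: Node) -> None:
    """Resolve polytomies deterministically (left-first)."""
    for child in list(node.children):
        _binarize(child)
    while len(node.children) > 2:
        a, b = node.children[0], node.children[1]
        merged = Node(length=0.0)
        merged.add_child(a)
        merged.add_child(b)
        node.children = [merged] + node.children[2:]
        merged.parent = node


def parse_newick(text: str, strict: bool = True) -> Tree:
    """Parse a newick string into a rooted :class:`Tree`.

    Polytomies raise in strict mode and are resolved left-first in lenient
    mode.  Branch lengths and internal labels (treated as support when
    numeric) are preserved.
    """
    _check_parentheses(text)
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = Node(name=label, length=dnode.edge.length)
        if label is not None and dnode.child_nodes():
            try:
                node.support = float(label)
            except ValueError:
                pass
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    tree = Tree(root)
    if any(len(n.children) > 2 for n in tree.preorder()):
        if strict:
            raise ValueError("polytomy in newick input (strict mode)")
        _binarize(root)
    return tree


def read_newick(path: str | Path, strict: bool = True, as_species_tree: bool = False):
    text = Path(path).read_text().strip()
    tree = parse_newick(text, strict=strict)
    if as_species_tree:
        return SpeciesTree(tree.root)
    return tree


def write_newick(tree: Tree, path: str | Path, include_labels: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_labels=include_labels) + "\n")


# ---------------------------------------------------------------------------
# Tables & config
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


#: Named defaults for every threshold used by the pipeline.
DEFAULT_CONFIG: dict = {
    "species_header_delimiter": "|",
    "species_header_field": 0,
    # transcript_prep
    "redundancy_identity_pct": 98.0,
    "redundancy_min_match_bp": 50,
    "contaminant_identity_pct": 99.0,
    "contaminant_coverage_pct": 99.0,
    "contaminant_abundance_frac": 0.01,
    "min_orf_aa": 30,
    "orf_trim_m_frac": 0.75,
    # family_builder
    "cluster_identity_pct": 70.0,
    "cluster_coverage_pct": 60.0,
    "outgroup_min_score": 50.0,
    "trim_max_gap_frac": 0.25,
    "strict_max_gap_frac": 0.20,
    # molecular_rates
    "ds_min": 0.01,
    "ds_max": 2.0,
    # mixture_stats
    "gmm_k": 2,
    "pp_cutoff": 0.95,
    "support_mask_threshold": None,
}


def load_config(path: Optional[str | Path] = None) -> dict:
    """Load a YAML config, merging over the package defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
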