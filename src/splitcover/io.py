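"""File formats: SplitsTree NEXUS splits, Newick trees, plain split lists.

The NEXUS reader targets the SplitsTree4 ``st_splits`` flavour: a TAXA
block (DIMENSIONS NTAX, TAXLABELS) followed by a SPLITS block
(DIMENSIONS, optional FORMAT with labels/weights/confidences flags,
optional CYCLE, MATRIX rows of the form ``[comment] weight i1 i2 ...,``
listing one side of each split by 1-based taxon index). Weights are
parsed and retained but never influence incompatibility computations.

Newick output is canonical: the tree is written rooted at the interior
vertex adjacent to taxon 1, children ordered by smallest descendant
taxon index, no branch lengths. Reading goes through dendropy and
suppresses any degree-2 root so round trips preserve the split system.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import networkx as nx

from .core import Split, SplitSystem, TaxaSet, make_split
from .trees import PhyloTree, TreeSet

__all__ = [
    "SplitsFileModel",
    "NexusParseError",
    "read_nexus_splits",
    "write_nexus_splits",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_split_list",
]


class NexusParseError(ValueError):
    """Malformed NEXUS input; message carries the offending line number."""


@dataclass
class SplitsFileModel:
    """Parsed contents of a splits file: taxa, weighted splits, provenance."""

    taxa: TaxaSet
    entries: List[Tuple[Split, float, Optional[int]]]
    cycle: Optional[Tuple[int, ...]] = None
    source: str = "<memory>"
    dialect: str = "st_splits"

    def split_system(self) -> SplitSystem:
        return SplitSystem(self.taxa, (s for s, _, _ in self.entries))


def _strip_comments(text: str) -> str:
    """Remove NEXUS bracket comments, preserving newlines for line counts."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth:
            depth -= 1
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


def _quoted_tokens(line: str) -> List[str]:
    """Split a TAXLABELS-style line into labels, honouring single quotes."""
    return [
        tok[1:-1].replace("''", "'") if tok.startswith("'") else tok
        for tok in re.findall(r"'(?:[^']|'')*'|[^\s;]+", line)
    ]


def read_nexus_splits(path: str) -> SplitsFileModel:
    with open(path) as fh:
        raw = fh.read()
    lines = _strip_comments(raw).split("\n")
    if not raw.lstrip().upper().startswith("#NEXUS"):
        raise NexusParseError(f"{path}:1: missing #NEXUS header")

    # Walk line by line through the blocks we understand.
    taxa: Optional[TaxaSet] = None
    labels: List[str] = []
    entries: List[Tuple[Split, float, Optional[int]]] = []
    seen_sides: Dict[frozenset, int] = {}
    cycle: Optional[Tuple[int, ...]] = None
    weights_flag = True
    labels_flag = False
    confidences_flag = False
    nsplits_declared: Optional[int] = None
    block = None  # None | 'taxa' | 'splits' | 'other'
    section = None  # sub-state inside a block

    def err(lineno: int, msg: str) -> NexusParseError:
        return NexusParseError(f"{path}:{lineno}: {msg}")

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        upper = stripped.upper()
        if upper.startswith("BEGIN"):
            name = upper.replace("BEGIN", "").strip(" ;").strip()
            block = (
                "taxa"
                if name in ("TAXA", "TAXLABELS")
                else "splits"
                if name in ("SPLITS", "ST_SPLITS")
                else "other"
            )
            section = None
            continue
        if upper.startswith(("END;", "ENDBLOCK;", "END ;")):
            if block == "taxa" and labels and taxa is None:
                taxa = TaxaSet(labels)
            block, section = None, None
            continue
        if block == "taxa":
            if upper.startswith("DIMENSIONS"):
                continue
            if upper.startswith("TAXLABELS"):
                section = "taxlabels"
                stripped = stripped[len("TAXLABELS") :]
            if section == "taxlabels":
                chunk = stripped.rstrip(";").strip()
                if chunk:
                    labels.extend(_quoted_tokens(chunk))
                if ";" in stripped:
                    section = None
            continue
        if block == "splits":
            if taxa is None:
                raise err(lineno, "SPLITS block before any TAXA block")
            if upper.startswith("DIMENSIONS"):
                mt = re.search(r"NSPLITS\s*=\s*(\d+)", upper)
                if mt:
                    nsplits_declared = int(mt.group(1))
                mt = re.search(r"NTAX\s*=\s*(\d+)", upper)
                if mt and int(mt.group(1)) != taxa.n:
                    raise err(lineno, f"NTAX={mt.group(1)} but {taxa.n} taxa declared")
                continue
            if upper.startswith("FORMAT"):
                weights_flag = _flag(upper, "WEIGHTS", default=True)
                labels_flag = _flag(upper, "LABELS", default=False)
                confidences_flag = _flag(upper, "CONFIDENCES", default=False)
                continue
            if upper.startswith("CYCLE"):
                nums = [int(x) for x in re.findall(r"\d+", stripped)]
                cycle = tuple(nums)
                continue
            if upper.startswith("MATRIX"):
                section = "matrix"
                continue
            if section == "matrix":
                row = stripped.rstrip(";").strip()
                if not row:
                    continue
                for piece in filter(None, (p.strip() for p in row.split(","))):
                    entries.append(
                        _parse_matrix_row(
                            piece, taxa, weights_flag, labels_flag,
                            confidences_flag, lineno, err, seen_sides,
                        )
                    )
                continue
        # other blocks: ignored

    if taxa is None:
        raise NexusParseError(f"{path}: no TAXA block found")
    entries = [e for e in entries if e is not None]
    if nsplits_declared is not None and len(entries) != nsplits_declared:
        raise NexusParseError(
            f"{path}: NSPLITS={nsplits_declared} but {len(entries)} rows parsed"
        )
    return SplitsFileModel(
        taxa=taxa, entries=entries, cycle=cycle, source=path
    )


def _flag(upper_line: str, name: str, default: bool) -> bool:
    mt = re.search(name + r"\s*=\s*(\S+)", upper_line)
    if not mt:
        return default
    return mt.group(1).rstrip(";").lower() in ("yes", "true", "1")


def _parse_matrix_row(
    piece: str,
    taxa: TaxaSet,
    weights: bool,
    labels: bool,
    confidences: bool,
    lineno: int,
    err,
    seen_sides: Dict[frozenset, int],
):
    tokens = piece.split()
    ident: Optional[int] = None
    if labels and tokens:
        try:
            ident = int(tokens[0])
        except ValueError:
            ident = None
        tokens = tokens[1:]
    weight = 1.0
    if weights:
        if not tokens:
            raise err(lineno, "matrix row missing weight")
        try:
            weight = float(tokens[0])
        except ValueError:
            raise err(lineno, f"bad weight {tokens[0]!r}")
        tokens = tokens[1:]
    if confidences and tokens:
        tokens = tokens[1:]
    try:
        indices = [int(t) for t in tokens]
    except ValueError as exc:
        raise err(lineno, f"bad taxon index in row {piece!r}: {exc}")
    if not indices:
        raise err(lineno, "matrix row lists no taxa")
    bad = [i for i in indices if not 1 <= i <= taxa.n]
    if bad:
        raise err(lineno, f"taxon index out of range 1..{taxa.n}: {bad}")
    if len(set(indices)) == taxa.n:
        raise err(lineno, "split side equals the whole taxa set")
    side = frozenset(indices)
    split = Split(taxa, side)
    if split.side in seen_sides:
        return None  # duplicate collapses; first weight kept
    seen_sides[split.side] = lineno
    return (split, weight, ident)


def write_nexus_splits(model: SplitsFileModel, path: str) -> None:
    taxa = model.taxa
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={taxa.n};", "TAXLABELS"]
    for lab in taxa.labels:
        lines.append(f"    {_quote_label(lab)}")
    lines += [";", "END;", "", "BEGIN SPLITS;"]
    lines.append(f"DIMENSIONS NTAX={taxa.n} NSPLITS={len(model.entries)};")
    lines.append("FORMAT labels=no weights=yes confidences=no;")
    if model.cycle:
        lines.append("CYCLE " + " ".join(str(i) for i in model.cycle) + ";")
    lines.append("MATRIX")
    for i, (split, weight, _) in enumerate(model.entries, start=1):
        idx = " ".join(str(j) for j in sorted(split.side))
        lines.append(f"[{i}]\t{weight:g}\t{idx},")
    lines += [";", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _quote_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-+]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def newick_string(tree: PhyloTree) -> str:
    """Canonical Newick: rooted at the interior vertex next to taxon 1."""
    g = tree.graph
    leaf1 = tree.leaf(1)
    if tree.taxa.n == 2:
        return f"({_quote_label(tree.taxa.label(1))},{_quote_label(tree.taxa.label(2))});"
    root = next(iter(g.neighbors(leaf1)))

    def min_taxon(node: int, parent: int) -> int:
        t = g.nodes[node].get("taxon")
        if t is not None:
            return t
        return min(min_taxon(nb, node) for nb in g.neighbors(node) if nb != parent)

    def render(node: int, parent: int) -> str:
        t = g.nodes[node].get("taxon")
        if t is not None:
            return _quote_label(tree.taxa.label(t))
        children = sorted(
            (nb for nb in g.neighbors(node) if nb != parent),
            key=lambda nb: min_taxon(nb, node),
        )
        return "(" + ",".join(render(c, node) for c in children) + ")"

    children = sorted(g.neighbors(root), key=lambda nb: min_taxon(nb, root))
    return "(" + ",".join(render(c, root) for c in children) + ");"


def write_newick(tree_set: TreeSet, path: str) -> None:
    with open(path, "w") as fh:
        for tree in tree_set:
            fh.write(newick_string(tree) + "\n")


def read_newick(path: str, taxa: Optional[TaxaSet] = None) -> TreeSet:
    """Read one or more Newick trees into a TreeSet.

    If ``taxa`` is not given it is inferred from the first tree's labels,
    ordered numerically when all labels are integers, else
    lexicographically. Degree-2 roots are suppressed on input.
    """
    tree_list = dendropy.TreeList.get(path=path, schema="newick")
    if not tree_list:
        raise ValueError(f"{path}: no trees found")
    if taxa is None:
        labels = [lf.taxon.label for lf in tree_list[0].leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError(f"{path}: fewer than 2 taxa")
        try:
            labels.sort(key=lambda lab: int(lab))
        except ValueError:
            labels.sort()
        taxa = TaxaSet(labels)
    return TreeSet([_from_dendropy(t, taxa, path) for t in tree_list])


def _from_dendropy(dtree: "dendropy.Tree", taxa: TaxaSet, path: str) -> PhyloTree:
    g = nx.Graph()
    node_id: Dict[object, int] = {}

    def nid(node) -> int:
        if node not in node_id:
            node_id[node] = len(node_id)
            g.add_node(node_id[node])
        return node_id[node]

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(nid(edge.tail_node), nid(edge.head_node))
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError(f"{path}: unlabelled leaf")
        label = leaf.taxon.label
        if label not in taxa:
            raise ValueError(f"{path}: unknown taxon label {label!r}")
        g.nodes[nid(leaf)]["taxon"] = taxa.index(label)
    # Suppress degree-2 vertices (e.g. an artificial root).
    for node in [v for v in g.nodes if g.degree(v) == 2]:
        a, b = g.neighbors(node)
        g.remove_node(node)
        g.add_edge(a, b)
    return PhyloTree(taxa, g)


# ---------------------------------------------------------------------------
# Plain split lists
# ---------------------------------------------------------------------------


def read_split_list(path: str) -> SplitSystem:
    """Plain text: one split per line.

    A line reads ``A|B`` with comma- or space-separated labels, or just
    the A side when a ``taxa:`` header names the taxa set. Blank lines and
    ``#`` comments are ignored.
    """
    taxa: Optional[TaxaSet] = None
    sides: List[List[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if text.lower().startswith("taxa:"):
                taxa = TaxaSet(_split_labels(text[5:]))
                continue
            if "|" in text:
                left, right = text.split("|", 1)
                left_labels = _split_labels(left)
                right_labels = _split_labels(right)
                if taxa is None:
                    labs = left_labels + right_labels
                    try:
                        labs.sort(key=lambda lab: int(lab))
                    except ValueError:
                        labs.sort()
                    taxa = TaxaSet(labs)
                unknown = (set(left_labels) | set(right_labels)) - set(taxa.labels)
                if unknown:
                    raise ValueError(
                        f"{path}:{lineno}: unknown taxa {sorted(unknown)}"
                    )
                missing = set(taxa.labels) - set(left_labels) - set(right_labels)
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: split omits taxa {sorted(missing)}"
                    )
                sides.append(left_labels)
            else:
                if taxa is None:
                    raise ValueError(
                        f"{path}:{lineno}: side-only split line needs a "
                        "'taxa:' header first"
                    )
                sides.append(_split_labels(text))
    if taxa is None:
        raise ValueError(f"{path}: no taxa and no splits found")
    try:
        splits = [make_split(side, taxa) for side in sides]
    except KeyError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return SplitSystem(taxa, splits)


def _split_labels(chunk: str) -> List[str]:
    return [tok for tok in re.split(r"[,\s]+", chunk.strip()) if tok]
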