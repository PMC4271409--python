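"""Newick reading and writing.

Parsing is delegated to dendropy and converted into this package's ordered
tree model; writing is implemented here so that quoting, float formatting
and the support-label convention round-trip exactly.

Dialect: single quotes accepted around labels ('' escapes a quote);
underscores are passed through verbatim, never converted to spaces; a fully
numeric label on an internal node is stored as a support value, any other
internal label as a name.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy

from .tree import NewickParseError, Node, Tree, TreeError

_UNQUOTED_OK = re.compile(r"[A-Za-z0-9_.\-+|/#&*]+")


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def _convert(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
    else:
        raw = dnode.label
        if raw is not None and _is_number(raw):
            node = Node(length=dnode.edge.length, support=float(raw))
        else:
            node = Node(label=raw, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
    return node


def parse_newick(text: str) -> Tree:
    """Parse a single ``;``-terminated Newick statement into a Tree."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"missing ';' terminator at position {len(text.rstrip())}"
        )
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"unbalanced '(': {depth} unclosed")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(str(exc)) from exc
    root = _convert(dtree.seed_node)
    try:
        return Tree(root)
    except TreeError as exc:
        raise NewickParseError(str(exc)) from exc


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _fmt_label(label: str) -> str:
    if label and _UNQUOTED_OK.fullmatch(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _write_node(node: Node) -> str:
    if node.is_leaf:
        out = _fmt_label(node.label or "")
    else:
        inner = ",".join(_write_node(c) for c in node.children)
        if node.support is not None:
            tag = _fmt_num(node.support)
        elif node.label:
            tag = _fmt_label(node.label)
        else:
            tag = ""
        out = f"({inner}){tag}"
    if node.length is not None:
        out += f":{_fmt_num(node.length)}"
    return out


def write_newick(tree: Tree) -> str:
    """Serialize a Tree; parse(write(t)) reproduces t exactly."""
    return _write_node(tree.root) + ";"


def read_newick_file(path: str | Path) -> list[Tree]:
    """Read one tree per ``;``-terminated statement from a UTF-8 file."""
    text = Path(path).read_text(encoding="utf-8")
    trees: list[Tree] = []
    buf: list[str] = []
    quoted = False
    for ch in text:
        buf.append(ch)
        if ch == "'":
            quoted = not quoted
        elif ch == ";" and not quoted:
            stmt = "".join(buf).strip()
            if stmt != ";":
                trees.append(parse_newick(stmt))
            buf = []
    if "".join(buf).strip():
        raise NewickParseError("trailing content without ';' terminator")
    return trees


def write_newick_file(path: str | Path, trees: list[Tree]) -> None:
    Path(path).write_text(
        "".join(write_newick(t) + "\n" for t in trees), encoding="utf-8"
    )


def read_annotations_csv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a (taxon,key,value) annotation sidecar."""
    import csv

    rows: list[tuple[str, str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row == ["taxon", "key", "value"]:
                continue
            taxon, key, value = row
            rows.append((taxon, key, value))
    return rows


def write_annotations_csv(path: str | Path, trees: list[Tree]) -> None:
    """Persist leaf annotations of the given trees as (taxon,key,value)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "key", "value"])
        seen: set[tuple[str, str, str]] = set()
        for tree in trees:
            for leaf in tree.leaves():
                for key, value in sorted(leaf.annotations.items()):
                    row = (leaf.label or "", key, value)
                    if row not in seen:
                        seen.add(row)
                        writer.writerow(row)


def apply_annotations(trees: list[Tree], rows: list[tuple[str, str, str]]) -> None:
    index: dict[str, list[Node]] = {}
    for tree in trees:
        for leaf in tree.leaves():
            index.setdefault(leaf.label or "", []).append(leaf)
    for taxon, key, value in rows:
        for leaf in index.get(taxon, []):
            leaf.annotations[key] = value
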