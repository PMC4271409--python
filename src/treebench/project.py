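"""File-backed project store with single-writer collaboration semantics.

A project holds exactly two named tree collections plus members, a
private/public status, upload limits, an append-only timeline, named
backups, and a control token: at any moment at most one member holds the
control and only the holder may mutate shared tree data.  Guests may read
public projects but can never make changes.  Persistence is one directory
per project: Newick files per collection, annotation CSV sidecars, a JSON
metadata document, and backups as subdirectories.
"""

from __future__ import annotations

import copy
import json
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .newick import (
    apply_annotations,
    read_annotations_csv,
    read_newick_file,
    write_annotations_csv,
    write_newick_file,
)
from .tree import Tree, TreeCollection


class ProjectError(Exception):
    """Domain error raised by project operations."""


@dataclass(frozen=True)
class Limits:
    """Upload limits, enforced atomically at import time."""

    max_trees_per_project: int = 10_000
    max_taxa_per_project: int = 5_000
    max_trees_per_import: int = 1_000

    def __post_init__(self) -> None:
        if min(
            self.max_trees_per_project,
            self.max_taxa_per_project,
            self.max_trees_per_import,
        ) <= 0:
            raise ProjectError("limits must be positive integers")


@dataclass
class TimelineEvent:
    seq: int
    timestamp: str
    actor: str
    kind: str  # import | edit | backup | restore | control_change | task_done
    summary: str


@dataclass
class ControlState:
    """Single-writer token: at most one holder, ordered pending requests."""

    holder: str | None = None
    pending: list[str] = field(default_factory=list)


@dataclass
class Project:
    id: str
    name: str
    status: str  # private | public
    members: dict[str, str]  # member id -> role (administrator | member)
    collections: list[TreeCollection]
    todo: list[str] = field(default_factory=list)
    timeline: list[TimelineEvent] = field(default_factory=list)
    backups: dict[str, list[TreeCollection]] = field(default_factory=dict)
    limits: Limits = field(default_factory=Limits)
    control: ControlState = field(default_factory=ControlState)
    sync: dict[str, bool] = field(default_factory=dict)  # member -> attached?

    @property
    def administrator(self) -> str:
        for member, role in self.members.items():
            if role == "administrator":
                return member
        raise ProjectError("project has no administrator")  # pragma: no cover

    def collection(self, name: str) -> TreeCollection:
        for coll in self.collections:
            if coll.name == name:
                return coll
        raise ProjectError(f"no collection named {name!r}")

    def tree_count(self) -> int:
        return sum(len(c) for c in self.collections)

    def taxon_count(self) -> int:
        taxa: set[str] = set()
        for coll in self.collections:
            for tree in coll.trees():
                taxa |= tree.taxa
        return len(taxa)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _log(project: Project, actor: str, kind: str, summary: str) -> None:
    project.timeline.append(
        TimelineEvent(len(project.timeline), _now(), actor, kind, summary)
    )


def create_project(name: str, admin: str, limits: Limits | None = None) -> Project:
    """New private project: two empty collections, admin as sole member."""
    if not name:
        raise ProjectError("project name must be non-empty")
    return Project(
        id=uuid.uuid4().hex,
        name=name,
        status="private",
        members={admin: "administrator"},
        collections=[TreeCollection("Collection 1"), TreeCollection("Collection 2")],
        limits=limits or Limits(),
        sync={admin: True},
    )


def add_member(project: Project, admin: str, member: str) -> Project:
    if project.members.get(admin) != "administrator":
        raise ProjectError("only the administrator can invite members")
    project.members.setdefault(member, "member")
    project.sync.setdefault(member, True)
    return project


def set_status(project: Project, admin: str, status: str) -> Project:
    if project.members.get(admin) != "administrator":
        raise ProjectError("only the administrator can change the status")
    if status not in ("private", "public"):
        raise ProjectError(f"unknown status {status!r}")
    project.status = status
    return project


def set_sync(project: Project, member: str, attached: bool) -> Project:
    if member not in project.members:
        raise ProjectError(f"{member!r} is not a member")
    project.sync[member] = attached
    return project


# ---------------------------------------------------------------------------
# access control


def check_access(project: Project, actor: str | None, action: str) -> str:
    """Returns "allow" or "deny"; never raises.

    Reads are allowed to members always and to guests only on public
    projects; writes are for members only, and tree mutations additionally
    require the control token (see ``_require_write``).
    """
    is_member = actor is not None and actor in project.members
    if action == "read":
        if is_member or project.status == "public":
            return "allow"
        return "deny"
    if action == "write":
        return "allow" if is_member else "deny"
    return "deny"


def _require_write(project: Project, actor: str) -> None:
    if actor not in project.members:
        raise ProjectError(f"{actor!r} is not a member")
    if not project.sync.get(actor, True):
        raise ProjectError(f"{actor!r} is detached from the shared view")
    if len(project.members) > 1 and project.control.holder != actor:
        raise ProjectError("control required")


# ---------------------------------------------------------------------------
# control token state machine


def request_control(project: Project, requester: str) -> Project:
    """Queue a control request; granted immediately if the token is vacant."""
    if requester not in project.members:
        raise ProjectError(f"{requester!r} is not a member")
    if project.control.holder == requester:
        return project
    if project.control.holder is None:
        project.control.holder = requester
        _log(project, requester, "control_change", "took vacant control")
        return project
    if requester not in project.control.pending:
        project.control.pending.append(requester)
    return project


def resolve_request(
    project: Project, decider: str, requester: str, accept: bool
) -> Project:
    """Holder or administrator accepts/declines a pending request."""
    control = project.control
    if decider != control.holder and project.members.get(decider) != "administrator":
        raise ProjectError("only the control holder or the administrator may decide")
    if requester not in control.pending:
        raise ProjectError(f"{requester!r} has no pending request")
    control.pending.remove(requester)
    if accept:
        control.holder = requester
        _log(project, decider, "control_change", f"control passed to {requester}")
    return project


def take_control(project: Project, actor: str) -> Project:
    """The administrator may seize the token at any moment."""
    if project.members.get(actor) != "administrator":
        raise ProjectError("only the administrator can take control")
    if actor in project.control.pending:
        project.control.pending.remove(actor)
    if project.control.holder != actor:
        project.control.holder = actor
        _log(project, actor, "control_change", "administrator took control")
    return project


# ---------------------------------------------------------------------------
# tree data management


def import_trees(
    project: Project,
    collection_name: str,
    trees: list[Tree],
    actor: str,
    names: list[str] | None = None,
) -> Project:
    """Append trees to a collection, enforcing all limits atomically.

    The whole import is validated before any mutation: an import larger
    than the per-import cap, or one that would push the project past its
    tree or distinct-taxon caps, is rejected and the project is unchanged.
    Imported tree names are deduplicated with numeric suffixes.
    """
    _require_write(project, actor)
    coll = project.collection(collection_name)
    limits = project.limits
    if len(trees) > limits.max_trees_per_import:
        raise ProjectError(
            f"import limit exceeded: {len(trees)} trees "
            f"(at most {limits.max_trees_per_import} per import)"
        )
    if project.tree_count() + len(trees) > limits.max_trees_per_project:
        raise ProjectError(
            f"project limit exceeded: would hold "
            f"{project.tree_count() + len(trees)} trees "
            f"(at most {limits.max_trees_per_project})"
        )
    taxa: set[str] = set()
    for c in project.collections:
        for t in c.trees():
            taxa |= t.taxa
    for t in trees:
        taxa |= t.taxa
    if len(taxa) > limits.max_taxa_per_project:
        raise ProjectError(
            f"project limit exceeded: would cover {len(taxa)} distinct taxa "
            f"(at most {limits.max_taxa_per_project})"
        )
    existing = set()
    for c in project.collections:
        existing |= set(c.names())
    if names is None:
        names = [f"tree{i + 1}" for i in range(len(trees))]
    for base, tree in zip(names, trees):
        name = base
        k = 1
        while name in existing:
            k += 1
            name = f"{base}_{k}"
        existing.add(name)
        coll.add(name, tree)
    _log(
        project,
        actor,
        "import",
        f"imported {len(trees)} trees into {collection_name!r}",
    )
    return project


def replace_tree(
    project: Project, collection_name: str, tree_name: str, tree: Tree, actor: str
) -> Project:
    """Edit (replace) a stored tree, under the same write gate as imports."""
    _require_write(project, actor)
    project.collection(collection_name).replace(tree_name, tree)
    _log(project, actor, "edit", f"edited {tree_name!r} in {collection_name!r}")
    return project


def backup(project: Project, label: str, actor: str | None = None) -> Project:
    """Store a deep snapshot of both collections under ``label``."""
    project.backups[label] = [c.copy() for c in project.collections]
    _log(project, actor or project.administrator, "backup", f"backup {label!r}")
    return project


def restore(project: Project, label: str, actor: str | None = None) -> Project:
    """Replace current collections with a snapshot; backups survive."""
    if label not in project.backups:
        raise ProjectError(f"no backup named {label!r}")
    project.collections = [c.copy() for c in project.backups[label]]
    _log(project, actor or project.administrator, "restore", f"restored {label!r}")
    return project


def mark_task_done(project: Project, actor: str, text: str) -> Project:
    if text in project.todo:
        project.todo.remove(text)
    _log(project, actor, "task_done", text)
    return project


# ---------------------------------------------------------------------------
# persistence


def _collection_stem(index: int) -> str:
    return f"collection_{index + 1}"


def _save_collections(colls: list[TreeCollection], directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for i, coll in enumerate(colls):
        stem = _collection_stem(i)
        write_newick_file(directory / f"{stem}.nwk", coll.trees())
        write_annotations_csv(directory / f"{stem}.annotations.csv", coll.trees())
        (directory / f"{stem}.names.json").write_text(
            json.dumps({"name": coll.name, "trees": coll.names()}), encoding="utf-8"
        )


def _load_collections(directory: Path) -> list[TreeCollection]:
    colls: list[TreeCollection] = []
    i = 0
    while (directory / f"{_collection_stem(i)}.nwk").exists():
        stem = _collection_stem(i)
        meta = json.loads((directory / f"{stem}.names.json").read_text("utf-8"))
        trees = read_newick_file(directory / f"{stem}.nwk")
        rows = read_annotations_csv(directory / f"{stem}.annotations.csv")
        apply_annotations(trees, rows)
        coll = TreeCollection(meta["name"])
        for name, tree in zip(meta["trees"], trees):
            coll.add(name, tree)
        colls.append(coll)
        i += 1
    return colls


def save_project(project: Project, directory: str | Path) -> None:
    """Write the project as a diff-able directory tree."""
    base = Path(directory)
    base.mkdir(parents=True, exist_ok=True)
    meta = {
        "id": project.id,
        "name": project.name,
        "status": project.status,
        "members": project.members,
        "todo": project.todo,
        "timeline": [vars(e) for e in project.timeline],
        "limits": vars(project.limits),
        "control": {
            "holder": project.control.holder,
            "pending": project.control.pending,
        },
        "sync": project.sync,
        "backups": sorted(project.backups),
    }
    (base / "project.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    _save_collections(project.collections, base)
    for label in project.backups:
        _save_collections(project.backups[label], base / "backups" / label)


def load_project(directory: str | Path) -> Project:
    base = Path(directory)
    meta = json.loads((base / "project.json").read_text("utf-8"))
    project = Project(
        id=meta["id"],
        name=meta["name"],
        status=meta["status"],
        members=dict(meta["members"]),
        collections=_load_collections(base),
        todo=list(meta["todo"]),
        timeline=[TimelineEvent(**e) for e in meta["timeline"]],
        limits=Limits(**meta["limits"]),
        control=ControlState(
            holder=meta["control"]["holder"], pending=list(meta["control"]["pending"])
        ),
        sync=dict(meta["sync"]),
    )
    for label in meta["backups"]:
        project.backups[label] = _load_collections(base / "backups" / label)
    return project


def snapshot_equal(a: list[TreeCollection], b: list[TreeCollection]) -> bool:
    """Deep equality of collection lists (names, order, trees, annotations)."""
    from .newick import write_newick

    def key(colls: list[TreeCollection]):
        out = []
        for c in colls:
            items = []
            for name, t in c.items:
                annos = tuple(
                    (l.label, tuple(sorted(l.annotations.items())))
                    for l in t.leaves()
                )
                items.append((name, write_newick(t), annos))
            out.append((c.name, tuple(items)))
        return tuple(out)

    return key(a) == key(b)


def deep_copy_project(project: Project) -> Project:
    return copy.deepcopy(project)
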