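"""A collaborative project session: members, control token, backups.

The store enforces the single-writer rule (only the control holder may
mutate trees), upload limits, and snapshot/restore semantics; everything
persists to a plain-text directory.
"""

import tempfile

from treebench import (
    add_member,
    backup,
    create_project,
    import_trees,
    load_project,
    parse_newick,
    replace_tree,
    request_control,
    resolve_request,
    restore,
    save_project,
)

project = create_project("HGT study", admin="alice")
import_trees(project, "Collection 1",
             [parse_newick("((A,B),(C,D));"), parse_newick("((A,C),(B,D));")],
             actor="alice")

add_member(project, "alice", "bob")
request_control(project, "alice")      # token was vacant: granted at once
request_control(project, "bob")        # queued behind alice
resolve_request(project, "alice", "bob", accept=True)
print(f"control holder: {project.control.holder}")   # bob

backup(project, "before-edit")
replace_tree(project, "Collection 1", "tree1",
             parse_newick("((A,D),(B,C));"), actor="bob")
restore(project, "before-edit")        # bob's edit reverted

with tempfile.TemporaryDirectory() as d:
    save_project(project, d)
    again = load_project(d)
    print(f"reloaded {again.tree_count()} trees, "
          f"{len(again.timeline)} timeline events")
for event in project.timeline:
    print(f"  {event.kind}: {event.summary}")
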