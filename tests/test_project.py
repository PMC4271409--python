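"""Project store: collections, limits, access, control token, backups."""

import random

import pytest

from treebench import (
    Limits,
    ProjectError,
    add_member,
    backup,
    check_access,
    create_project,
    import_trees,
    load_project,
    parse_newick,
    replace_tree,
    request_control,
    resolve_request,
    restore,
    save_project,
    set_color,
    set_status,
    set_sync,
    snapshot_equal,
    take_control,
)
from treebench.simulate import FixtureConfig, generate_fixtures

from conftest import make_random_tree


def fresh_project(**kwargs):
    project = create_project("HGT study", "u1", **kwargs)
    return project


class TestCreate:
    def test_defaults(self):
        p = fresh_project()
        assert p.status == "private"
        assert p.members == {"u1": "administrator"}
        assert [c.name for c in p.collections] == ["Collection 1", "Collection 2"]
        assert p.tree_count() == 0

    def test_empty_name_rejected(self):
        with pytest.raises(ProjectError):
            create_project("", "u1")

    def test_names_are_not_unique_keys(self):
        a, b = fresh_project(), fresh_project()
        assert a.name == b.name and a.id != b.id


class TestImportLimits:
    def test_basic_import_logs_timeline(self, t):
        p = fresh_project()
        import_trees(p, "Collection 1", [t("((A,B),C);")] * 3, "u1")
        assert p.tree_count() == 3
        assert [e.kind for e in p.timeline] == ["import"]

    def test_import_names_deduplicated(self, t):
        p = fresh_project()
        import_trees(p, "Collection 1", [t("(A,B);")], "u1", names=["x"])
        import_trees(p, "Collection 1", [t("(C,D);")], "u1", names=["x"])
        assert p.collection("Collection 1").names() == ["x", "x_2"]

    def test_per_import_cap_rejects_atomically(self, t):
        p = fresh_project(limits=Limits(max_trees_per_import=5))
        trees = [t("((A,B),C);")] * 6
        with pytest.raises(ProjectError, match="import limit"):
            import_trees(p, "Collection 1", trees, "u1")
        assert p.tree_count() == 0 and not p.timeline

    def test_project_tree_cap_rejects_atomically(self, t):
        p = fresh_project(limits=Limits(max_trees_per_project=4))
        import_trees(p, "Collection 1", [t("((A,B),C);")] * 3, "u1")
        with pytest.raises(ProjectError, match="project limit"):
            import_trees(p, "Collection 2", [t("((A,B),C);")] * 2, "u1")
        assert p.tree_count() == 3

    def test_taxon_cap_counts_distinct_taxa_across_collections(self):
        p = fresh_project(limits=Limits(max_taxa_per_project=8))
        import_trees(p, "Collection 1", [make_random_tree(6, 1)], "u1")
        # same taxa again: no new distinct taxa, fine
        import_trees(p, "Collection 2", [make_random_tree(6, 2)], "u1")
        with pytest.raises(ProjectError, match="taxa"):
            import_trees(
                p, "Collection 1", [make_random_tree(6, 3, prefix="Q")], "u1"
            )
        assert p.tree_count() == 2

    def test_default_limits_match_platform_policy(self):
        limits = Limits()
        assert limits.max_trees_per_project == 10_000
        assert limits.max_taxa_per_project == 5_000
        assert limits.max_trees_per_import == 1_000


class TestAccess:
    def test_guest_reads_public_only(self, t):
        p = fresh_project()
        assert check_access(p, None, "read") == "deny"
        set_status(p, "u1", "public")
        assert check_access(p, None, "read") == "allow"

    def test_guest_never_writes(self):
        p = fresh_project()
        set_status(p, "u1", "public")
        assert check_access(p, None, "write") == "deny"
        assert check_access(p, "stranger", "write") == "deny"

    def test_member_reads_private(self):
        p = fresh_project()
        add_member(p, "u1", "u2")
        assert check_access(p, "u2", "read") == "allow"

    def test_monotone_guest_implies_member(self):
        for status in ("private", "public"):
            p = fresh_project()
            set_status(p, "u1", status)
            add_member(p, "u1", "u2")
            for action in ("read", "write"):
                if check_access(p, None, action) == "allow":
                    assert check_access(p, "u2", action) == "allow"

    def test_non_holder_member_cannot_mutate(self, t):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u1")
        with pytest.raises(ProjectError, match="control"):
            import_trees(p, "Collection 1", [t("(A,B);")], "u2")

    def test_detached_member_cannot_mutate(self, t):
        p = fresh_project()
        set_sync(p, "u1", False)
        with pytest.raises(ProjectError, match="detached"):
            import_trees(p, "Collection 1", [t("(A,B);")], "u1")


class TestControlToken:
    def test_vacant_token_granted_immediately(self):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u2")
        assert p.control.holder == "u2"

    def test_request_queues_when_held(self):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u1")
        request_control(p, "u2")
        request_control(p, "u2")  # idempotent
        assert p.control.holder == "u1"
        assert p.control.pending == ["u2"]

    def test_holder_accepts(self):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u1")
        request_control(p, "u2")
        resolve_request(p, "u1", "u2", True)
        assert p.control.holder == "u2" and p.control.pending == []

    def test_admin_declines(self):
        p = fresh_project()
        for u in ("u2", "u3"):
            add_member(p, "u1", u)
        request_control(p, "u2")
        request_control(p, "u3")
        resolve_request(p, "u1", "u3", False)  # admin is not the holder
        assert p.control.holder == "u2" and p.control.pending == []

    def test_plain_member_cannot_decide(self):
        p = fresh_project()
        for u in ("u2", "u3", "u4"):
            add_member(p, "u1", u)
        request_control(p, "u2")
        request_control(p, "u3")
        with pytest.raises(ProjectError):
            resolve_request(p, "u4", "u3", True)

    def test_admin_takes_control_any_time(self):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u2")
        take_control(p, "u1")
        assert p.control.holder == "u1"
        take_control(p, "u1")  # idempotent
        assert p.control.holder == "u1"
        with pytest.raises(ProjectError):
            take_control(p, "u2")

    def test_non_member_cannot_request(self):
        p = fresh_project()
        with pytest.raises(ProjectError):
            request_control(p, "stranger")

    @pytest.mark.parametrize("seed", range(20))
    def test_never_two_holders_under_random_events(self, seed):
        rng = random.Random(seed)
        p = fresh_project()
        members = ["u1", "u2", "u3", "u4", "u5"]
        for u in members[1:]:
            add_member(p, "u1", u)
        for _ in range(60):
            action = rng.choice(["request", "resolve", "take"])
            try:
                if action == "request":
                    request_control(p, rng.choice(members))
                elif action == "take":
                    take_control(p, rng.choice(members))
                elif p.control.pending:
                    resolve_request(
                        p,
                        rng.choice(members),
                        rng.choice(p.control.pending),
                        rng.random() < 0.5,
                    )
            except ProjectError:
                pass
            holder = p.control.holder
            assert holder is None or holder in p.members
            assert len(p.control.pending) == len(set(p.control.pending))
            assert holder not in p.control.pending


class TestBackups:
    def test_backup_restore_round_trip(self, t):
        p = fresh_project()
        import_trees(p, "Collection 1", [t("((A,B),C);")], "u1")
        backup(p, "before")
        snapshot = [c.copy() for c in p.collections]
        replace_tree(p, "Collection 1", "tree1", t("((A,C),B);"), "u1")
        assert not snapshot_equal(p.collections, snapshot)
        restore(p, "before")
        assert snapshot_equal(p.collections, snapshot)
        assert "before" in p.backups  # backups survive restore

    def test_restore_unknown_label(self):
        with pytest.raises(ProjectError):
            restore(fresh_project(), "nope")

    def test_timeline_is_append_only_and_ordered(self, t):
        p = fresh_project()
        import_trees(p, "Collection 1", [t("(A,B);")], "u1")
        backup(p, "b1")
        restore(p, "b1")
        kinds = [e.kind for e in p.timeline]
        assert kinds == ["import", "backup", "restore"]
        assert [e.seq for e in p.timeline] == [0, 1, 2]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, t):
        p = fresh_project()
        add_member(p, "u1", "u2")
        request_control(p, "u1")  # two members: imports need the token
        trees = generate_fixtures(FixtureConfig(n_taxa=6, n_trees=3, seed=9))
        trees = set_color(trees, {"T1", "T2"}, "red")
        import_trees(p, "Collection 1", trees, "u1")
        backup(p, "snap")
        request_control(p, "u2")
        save_project(p, tmp_path / "proj")
        q = load_project(tmp_path / "proj")
        assert q.id == p.id and q.members == p.members
        assert q.control.holder == p.control.holder
        assert snapshot_equal(q.collections, p.collections)
        assert snapshot_equal(q.backups["snap"], p.backups["snap"])
        assert [e.summary for e in q.timeline] == [e.summary for e in p.timeline]
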