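import itertools

import numpy as np
import pytest

from cactokey.datamodel import (
    MatrixError,
    NumericValue,
    SpecimenObservation,
    UNKNOWN,
    normalize_taxon_name,
)
from cactokey.key_engine import (
    Couplet,
    Key,
    KeyError_,
    Lead,
    Predicate,
    TriBool,
    eval_predicate,
    traverse,
    validate_key,
)

Y, N, A = TriBool.YES, TriBool.NO, TriBool.AMBIGUOUS


# ---------------------------------------------------------------------------
# helpers


def _numeric_ranges(matrix):
    """Per-character envelope across all taxa, for random profile draws."""
    out = {}
    for cdef in matrix.registry:
        if cdef.kind != "numeric":
            continue
        los, his = [], []
        for t in matrix.taxa:
            v = t.get(cdef.id)
            if isinstance(v, NumericValue):
                los.append(v.lo)
                his.append(v.hi)
        if los:
            out[cdef.id] = (min(los), max(his))
        else:  # key-only character never tabulated: pick a plausible span
            out[cdef.id] = (1.0, 10.0)
    return out


def random_point_profile(matrix, rng, characters=None):
    """A fully crisp observation: every requested character gets a point
    value or a definite category, so no predicate can be ambiguous."""
    envelopes = _numeric_ranges(matrix)
    values = {}
    for cdef in matrix.registry:
        if characters is not None and cdef.id not in characters:
            continue
        if cdef.kind == "numeric":
            lo, hi = envelopes[cdef.id]
            span = hi - lo
            x = rng.uniform(lo - 0.25 * span, hi + 0.25 * span)
            values[cdef.id] = NumericValue.point(max(x, 1e-3))
        else:
            values[cdef.id] = str(rng.choice(list(cdef.categories)))
    return SpecimenObservation("random", values)


def enumerate_paths(key):
    """All root-to-terminal lead sequences (brute-force oracle scaffold)."""
    paths = []

    def walk(cid, leads_so_far):
        for lead in key.couplets[cid].leads:
            if lead.taxon is not None:
                paths.append((lead.taxon, leads_so_far + (lead,)))
            else:
                walk(lead.goto, leads_so_far + (lead,))

    walk(key.root, ())
    return paths


# ---------------------------------------------------------------------------
# structure


class TestBundledKeyStructure:
    def test_sixteen_couplets_two_leads_each(self, key):
        assert len(key.couplets) == 16
        assert key.root == 1
        for c in key.couplets.values():
            assert len(c.leads) == 2

    def test_no_structural_errors(self, key):
        assert key.structural_errors() == []

    def test_all_seventeen_taxa_are_terminals(self, key, matrix):
        terminals = {normalize_taxon_name(t) for t in key.terminal_taxa()}
        for t in matrix.taxa:
            assert normalize_taxon_name(t.taxon) in terminals

    def test_couplet_1_first_lead_terminates_at_estonica(self, key):
        lead = key.couplets[1].leads[0]
        assert lead.taxon == "C. estonica"

    def test_couplet_16_terminals(self, key):
        taxa = {lead.taxon for lead in key.couplets[16].leads}
        assert taxa == {"C. weissi", "C. tianzhuensis"}

    def test_dangling_goto_reported_with_id(self):
        p = Predicate("x", "ge", 1.0, basis="mean")
        with pytest.raises(KeyError_, match="99"):
            Key(
                couplets={
                    1: Couplet(
                        1,
                        (
                            Lead((p,), goto=99),
                            Lead((p,), taxon="C. thornei"),
                        ),
                    )
                },
                root=1,
            )

    def test_cycle_reported(self):
        p = Predicate("x", "ge", 1.0, basis="mean")
        with pytest.raises(KeyError_, match="cycle"):
            Key(
                couplets={
                    1: Couplet(1, (Lead((p,), goto=2), Lead((p,), taxon="t"))),
                    2: Couplet(2, (Lead((p,), goto=1), Lead((p,), taxon="u"))),
                },
                root=1,
            )

    def test_lead_needs_exactly_one_outcome(self):
        p = Predicate("x", "ge", 1.0)
        with pytest.raises(KeyError_):
            Lead((p,), taxon="t", goto=2)
        with pytest.raises(KeyError_):
            Lead((p,))


# ---------------------------------------------------------------------------
# predicate evaluation


class TestEvalPredicate:
    def test_categorical_match(self, matrix):
        p = Predicate("eggshell_surface", "eq-category", "punctate")
        out = eval_predicate(p, matrix.taxon("C. thornei"), matrix)
        assert out.verdict is Y

    def test_categorical_mismatch(self, matrix):
        p = Predicate("eggshell_surface", "eq-category", "punctate")
        out = eval_predicate(p, matrix.taxon("C. tianzhuensis"), matrix)
        assert out.verdict is N

    def test_categorical_unknown_is_ambiguous(self, matrix):
        p = Predicate("vulval_denticles", "eq-category", "present")
        out = eval_predicate(p, matrix.taxon("C. acnidae"), matrix)
        assert out.verdict is A and out.missing

    def test_range_wholly_above_threshold(self, matrix):
        # mean J2 tail >= 40 versus an interval wholly above it
        obs = SpecimenObservation("s", {"tail_length": NumericValue(47, 59)})
        p = Predicate("tail_length", "ge", 40.0, basis="range")
        assert eval_predicate(p, obs, matrix).verdict is Y

    def test_range_straddles_threshold(self, matrix):
        obs = SpecimenObservation("s", {"fenestral_diam": NumericValue(20, 32)})
        p = Predicate("fenestral_diam", "lt", 25.0, basis="range")
        assert eval_predicate(p, obs, matrix).verdict is A

    def test_range_wholly_violates(self, matrix):
        obs = SpecimenObservation("s", {"fenestral_diam": NumericValue(31, 36)})
        p = Predicate("fenestral_diam", "lt", 25.0, basis="range")
        assert eval_predicate(p, obs, matrix).verdict is N

    def test_in_range_containment_yes(self, matrix):
        obs = SpecimenObservation("s", {"stylet_length": NumericValue(23, 26)})
        p = Predicate("stylet_length", "in-range", (23.0, 26.0), basis="range")
        assert eval_predicate(p, obs, matrix).verdict is Y

    def test_in_range_disjoint_no(self, matrix):
        obs = SpecimenObservation("s", {"stylet_length": NumericValue(20, 22)})
        p = Predicate("stylet_length", "in-range", (23.0, 26.0), basis="range")
        assert eval_predicate(p, obs, matrix).verdict is N

    def test_mean_basis_uses_published_mean_without_proxy(self, matrix):
        obs = SpecimenObservation(
            "s", {"tail_length": NumericValue(46.5, 59.0, mean=54.1)}
        )
        p = Predicate("tail_length", "ge", 40.0, basis="mean")
        out = eval_predicate(p, obs, matrix)
        assert out.verdict is Y and not out.proxy_mean

    def test_mean_basis_midpoint_proxy_flagged(self, matrix):
        out = eval_predicate(
            Predicate("cyst_lw_ratio", "ge", 2.0, basis="mean"),
            matrix.taxon("C. estonica"),
            matrix,
        )
        assert out.verdict is Y and out.proxy_mean  # midpoint 2.2 >= 2

    def test_unregistered_character_raises(self, matrix):
        p = Predicate("wingspan", "ge", 1.0)
        with pytest.raises(MatrixError, match="wingspan"):
            eval_predicate(p, matrix.taxon("C. thornei"), matrix)


class TestTriBool:
    def test_kleene_conjunction_table(self):
        assert Y.and_(Y) is Y
        assert Y.and_(A) is A
        assert A.and_(A) is A
        for v in (Y, N, A):
            assert v.and_(N) is N
            assert N.and_(v) is N


# ---------------------------------------------------------------------------
# traversal


class TestTraverse:
    def test_tianzhuensis_unique_path(self, key, matrix):
        res = traverse(key, matrix.taxon("C. tianzhuensis"), matrix)
        assert res.status == "unique"
        (name,) = res.taxa
        assert name == "C. tianzhuensis"
        paths = {t.path for t in res.terminals}
        assert (1, 2, 11, 14, 15, 16) in paths

    def test_estonica_terminal_at_couplet_1(self, key, matrix):
        res = traverse(key, matrix.taxon("C. estonica"), matrix)
        assert res.status == "unique"
        assert res.terminals[0].taxon == "C. estonica"
        assert res.terminals[0].path == (1,)

    def test_all_unknown_profile_reaches_all_17(self, key, matrix):
        obs = SpecimenObservation("blank", {"cyst_length": UNKNOWN})
        res = traverse(key, obs, matrix)
        assert {normalize_taxon_name(t) for t in res.taxa} == {
            normalize_taxon_name(t.taxon) for t in matrix.taxa
        }

    def test_dead_end_is_status_not_exception(self, key, matrix):
        res = traverse(key, matrix.taxon("C. solani"), matrix)
        assert res.status == "dead-end"
        assert res.terminals == []
        assert res.dead_ends  # the failing couplet is recorded

    def test_trace_records_every_decision(self, key, matrix):
        res = traverse(key, matrix.taxon("C. tianzhuensis"), matrix)
        trace = res.terminals[0].trace
        assert len(trace) == len(res.terminals[0].path)
        assert all(step.verdict in (Y, A) for step in trace)

    def test_determinism(self, key, matrix):
        a = traverse(key, matrix.taxon("C. rosae"), matrix)
        b = traverse(key, matrix.taxon("C. rosae"), matrix)
        assert [(t.taxon, t.path) for t in a.terminals] == [
            (t.taxon, t.path) for t in b.terminals
        ]


class TestTraversalProperties:
    def test_termination_and_path_bound(self, key, matrix):
        rng = np.random.default_rng(11)
        for _ in range(200):
            obs = random_point_profile(matrix, rng)
            res = traverse(key, obs, matrix)
            for t in res.terminals:
                assert len(t.path) <= 16
                assert len(set(t.path)) == len(t.path)  # no couplet revisited

    def test_monotonicity_adding_information(self, key, matrix):
        rng = np.random.default_rng(12)
        all_chars = [c.id for c in matrix.registry]
        for _ in range(150):
            k = int(rng.integers(1, len(all_chars)))
            chosen = list(rng.choice(all_chars, size=k, replace=False))
            full = random_point_profile(matrix, rng)
            partial = SpecimenObservation(
                "partial", {c: full.values[c] for c in chosen}
            )
            before = set(traverse(key, partial, matrix).taxa)
            extra = [c for c in all_chars if c not in chosen]
            if not extra:
                continue
            add = extra[int(rng.integers(len(extra)))]
            richer = SpecimenObservation(
                "richer", {**partial.values, add: full.values[add]}
            )
            after = set(traverse(key, richer, matrix).taxa)
            assert after <= before

    def test_oracle_equivalence_on_crisp_profiles(self, key, matrix):
        # brute force: enumerate all root-to-terminal paths, keep those whose
        # every lead evaluates YES; must equal traversal output when nothing
        # is ambiguous.
        rng = np.random.default_rng(13)
        paths = enumerate_paths(key)
        for _ in range(100):
            obs = random_point_profile(matrix, rng)

            def lead_is_yes(lead):
                v = Y
                for p in lead.predicates:
                    v = v.and_(eval_predicate(p, obs, matrix).verdict)
                return v is Y

            expected = sorted(
                taxon for taxon, leads in paths if all(lead_is_yes(l) for l in leads)
            )
            got = sorted(t.taxon for t in traverse(key, obs, matrix).terminals)
            assert got == expected


# ---------------------------------------------------------------------------
# audit


class TestValidateKey:
    def test_rosae_consistent_via_documented_path(self, key, matrix):
        audit = validate_key(key, matrix)
        row = audit.row("C. rosae")
        assert row.classification == "CONSISTENT"
        assert (1, 2, 3, 5, 9, 10) in row.own_paths

    def test_thornei_reaches_own_terminal(self, key, matrix):
        row = validate_key(key, matrix).row("C. thornei")
        assert row.classification == "CONSISTENT"
        assert (1, 2, 3, 4) in row.own_paths

    def test_every_taxon_labeled(self, key, matrix):
        audit = validate_key(key, matrix)
        assert len(audit.rows) == 17
        assert all(
            r.classification in ("CONSISTENT", "AMBIGUOUS", "MISROUTED")
            for r in audit.rows
        )

    def test_no_undocumented_misroutes(self, key, matrix, errata):
        audit = validate_key(key, matrix)
        documented = {
            normalize_taxon_name(e["taxon"]) for e in errata["known_misroutes"]
        }
        for row in audit.rows:
            if row.classification == "MISROUTED":
                assert normalize_taxon_name(row.taxon) in documented, row.taxon

    def test_errata_explain_each_documented_misroute(self, errata):
        for entry in errata["known_misroutes"]:
            assert entry["note"].strip()
            assert isinstance(entry["couplet"], int)

    def test_structural_report_clean_for_bundle(self, key, matrix):
        audit = validate_key(key, matrix)
        assert audit.structural_errors == []
        assert audit.missing_terminals == []
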