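import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixscreen.errors import GeometryError
from helixscreen.interface import (
    compare_maps,
    coverage_condition_holds,
    interface_residues,
    interface_residues_exhaustive,
    interface_table,
    representative_coordinate,
    write_pairs_tsv,
)
from helixscreen.model_io import Atom, BindingSiteDef, Chain, Residue, StructureModel
from helixscreen.synthetic import (
    FixtureSpec,
    make_confidence,
    make_fixture,
    make_helix_complex,
    random_fixture_spec,
)
from _util import random_rigid


def _residue(name, seq_id, atoms):
    res = Residue(author_seq_id=seq_id, name=name)
    res.atoms = [Atom(n, e, np.array(p, float)) for n, e, p in atoms]
    return res


class TestRepresentativeCoordinate:
    def test_cb_when_present(self):
        res = _residue("ALA", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (1, 2, 3))])
        np.testing.assert_array_equal(representative_coordinate(res), [1, 2, 3])

    def test_glycine_uses_ca(self):
        res = _residue("GLY", 1, [("N", "N", (9, 9, 9)), ("CA", "C", (0, 0, 0))])
        np.testing.assert_array_equal(representative_coordinate(res), [0, 0, 0])

    def test_fallback_first_atom(self):
        res = _residue("SER", 1, [("N", "N", (5, 5, 5))])
        np.testing.assert_array_equal(representative_coordinate(res), [5, 5, 5])
        with pytest.raises(GeometryError):
            representative_coordinate(res, fallback=False)

    def test_no_atoms_errors(self):
        with pytest.raises(GeometryError):
            representative_coordinate(Residue(author_seq_id=1, name="ALA"), fallback=True)


class TestTwoStageDetection:
    def test_contacts_at_3_5_detected_and_4_6_not(self):
        near, truth_near = make_helix_complex(FixtureSpec.cdca4_like(approach=3.5))
        assert interface_residues(near).pairs == truth_near.pairs
        assert len(truth_near.pairs) == 4
        far, truth_far = make_helix_complex(FixtureSpec.cdca4_like(approach=4.6))
        assert not truth_far.pairs
        assert not interface_residues(far).pairs

    def test_cutoffs_inclusive(self):
        # atoms exactly at the 4.0 A cutoff: still a contact (<=, not <)
        receptor = Chain(id="A", role="receptor")
        receptor.residues.append(_residue("ALA", 1, [("CB", "C", (0, 0, 0))]))
        binder = Chain(id="B", role="binder")
        binder.residues.append(_residue("ALA", 2, [("CB", "C", (0, 0, 4.0))]))
        model = StructureModel(chains=[receptor, binder])
        assert interface_residues(model).pairs == {(("B", 2), ("A", 1))}
        # representative distance exactly at the 8.0 A prefilter: kept
        binder.residues[0].atoms[0].position = np.array([0.0, 0.0, 8.0])
        assert not interface_residues(model).pairs  # atomic stage rejects 8.0
        assert interface_residues(model, atomic_cutoff=8.0).pairs

    def test_site_restriction_semantics(self, site):
        # receptor residue 999 is not a site member
        spec = FixtureSpec.cdca4_like(extra_contacts=((59, 999),))
        model, truth = make_helix_complex(spec)
        off_site_pair = (("B", 59), ("A", 999))
        assert off_site_pair in truth.pairs
        unrestricted = interface_residues(model, site=None)
        assert off_site_pair in unrestricted.pairs
        restricted = interface_residues(model, site=site)
        assert off_site_pair not in restricted.pairs
        assert restricted.pairs == truth.pairs - {off_site_pair}

    def test_low_plddt_residue_excluded(self):
        spec = FixtureSpec.cdca4_like(plddt_overrides={("B", 58): 49.9})
        model, truth, conf = make_fixture(spec)
        iface = interface_residues(model, conf=conf)
        assert ("B", 58) in iface.excluded_low_plddt
        assert ("B", 58) not in iface.binder_iface
        boundary = make_confidence(model, truth, plddt_overrides={("B", 58): 50.0})
        assert ("B", 58) in interface_residues(model, conf=boundary).binder_iface

    def test_empty_site_errors(self):
        model, _ = make_helix_complex(FixtureSpec.cdca4_like())
        empty = BindingSiteDef(frozenset(), frozenset(), frozenset(), frozenset())
        with pytest.raises(ValueError):
            interface_residues(model, site=empty)

    def test_roles_required(self):
        model, _ = make_helix_complex(FixtureSpec.cdca4_like())
        for c in model.chains:
            c.role = "unassigned"
        with pytest.raises(ValueError):
            interface_residues(model)


def _long_sidechain_counterexample() -> StructureModel:
    """Atoms touch at <=4 A while the CB representatives are >8 A apart."""
    receptor = Chain(id="A", role="receptor")
    receptor.residues.append(
        _residue("ARG", 10, [
            ("CA", "C", (0, 0, -1.5)),
            ("CB", "C", (0, 0, 0)),
            ("NH1", "N", (0, 0, 4.6)),  # long side chain reaching out
        ])
    )
    binder = Chain(id="B", role="binder")
    binder.residues.append(
        _residue("LYS", 5, [
            ("CA", "C", (0, 0, 10.6)),
            ("CB", "C", (0, 0, 9.1)),   # CB-CB 9.1 A > 8 A prefilter
            ("NZ", "N", (0, 0, 8.0)),   # 3.4 A from NH1 -> true contact
        ])
    )
    return StructureModel(chains=[receptor, binder])


class TestExhaustiveOracle:
    def test_equals_two_stage_on_compact_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            spec = random_fixture_spec(rng)
            model, truth = make_helix_complex(spec)
            two = interface_residues(model)
            full = interface_residues_exhaustive(model)
            assert two.pairs <= full.pairs
            assert full.pairs == truth.pairs
            if coverage_condition_holds(model):
                assert two.pairs == full.pairs

    def test_long_sidechain_contact_missed_by_prefilter(self):
        model = _long_sidechain_counterexample()
        two = interface_residues(model)
        full = interface_residues_exhaustive(model)
        missed = compare_maps(two, full)["missed_by_prefilter"]
        assert missed == {(("B", 5), ("A", 10))}
        assert not two.pairs
        assert not coverage_condition_holds(model)

    def test_distant_chains_give_empty_map(self):
        spec = FixtureSpec.cdca4_like(contacts={}, extra_contacts=())
        model, truth = make_helix_complex(spec)
        assert not truth.pairs
        assert not interface_residues_exhaustive(model).pairs


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        small=st.floats(min_value=1.0, max_value=4.0),
        extra=st.floats(min_value=0.0, max_value=4.0),
    )
    def test_enlarging_atomic_cutoff_never_removes_pairs(self, small, extra):
        model, _ = make_helix_complex(FixtureSpec.cdca4_like(seed=3))
        narrow = interface_residues(model, atomic_cutoff=small)
        wide = interface_residues(model, atomic_cutoff=small + extra)
        assert narrow.pairs <= wide.pairs

    def test_shrinking_site_never_adds_pairs(self, site):
        model, _ = make_helix_complex(
            FixtureSpec.cdca4_like(extra_contacts=((59, 337),))
        )
        full = interface_residues(model, site=site)
        smaller = BindingSiteDef(site.patch1, site.patch2, site.patch3, frozenset())
        sub = interface_residues(model, site=smaller)
        assert sub.pairs <= full.pairs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_leaves_map_unchanged(self, seed):
        model, truth = make_helix_complex(FixtureSpec.cdca4_like())
        R, t = random_rigid(np.random.default_rng(seed))
        moved = model.transformed(R, t)
        iface = interface_residues(moved)
        assert iface.pairs == truth.pairs
        for pair, d in iface.min_distances.items():
            assert d == pytest.approx(truth.min_distances[pair], abs=1e-9)

    def test_projections_consistent(self, passing_complex):
        model, truth, conf = passing_complex
        iface = interface_residues(model, conf=conf, site=BindingSiteDef.default())
        assert iface.binder_iface == {b for b, _ in iface.pairs}
        assert iface.receptor_iface == {r for _, r in iface.pairs}
        assert not (iface.excluded_low_plddt & iface.binder_iface)


def test_pair_list_export(tmp_path, passing_complex):
    model, truth, conf = passing_complex
    iface = interface_residues(model, conf=conf)
    table = interface_table(iface)
    assert len(table) == len(iface.pairs)
    assert (table["min_atom_distance"] <= 4.0).all()
    out = tmp_path / "pairs.tsv"
    write_pairs_tsv(iface, out)
    header = out.read_text().splitlines()[0].split("\t")
    assert header == [
        "binder_chain", "binder_resid", "receptor_chain", "receptor_resid",
        "min_atom_distance",
    ]
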