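import numpy as np
import pytest

from helixscreen.errors import RegisterError
from helixscreen.interface import InterfaceMap, InterfaceParams, interface_residues
from helixscreen.model_io import BindingSiteDef, StructureModel
from helixscreen.register import (
    HelixSegment,
    assign_helices,
    assign_register,
    classify_patch_contacts,
    motif_report,
    register_table,
)
from helixscreen.synthetic import FixtureSpec, build_peptide, make_helix_complex
from _util import random_rigid

PARAMS = InterfaceParams(8.0, 4.0, 50.0, True)


def _iface_from_pairs(pairs, counts=None):
    return InterfaceMap(
        pairs=frozenset(pairs),
        excluded_low_plddt=frozenset(),
        params=PARAMS,
        atom_contact_counts=dict(counts or {}),
    )


class TestAssignHelices:
    def test_ideal_helix_single_segment(self):
        model = StructureModel(chains=[build_peptide([(12, -57, -47)], chain_id="B")])
        segments = assign_helices(model, "B")
        assert len(segments) == 1
        assert segments[0].length >= 10  # termini each lack one dihedral

    def test_extended_strand_no_segments(self):
        model = StructureModel(chains=[build_peptide([(12, -120, 120)], chain_id="B")])
        assert assign_helices(model, "B") == []

    def test_helix_loop_helix_two_segments(self):
        model = StructureModel(chains=[
            build_peptide([(10, -57, -47), (5, -120, 120), (10, -57, -47)], chain_id="B")
        ])
        segments = assign_helices(model, "B")
        assert len(segments) == 2
        assert all(s.length >= 8 for s in segments)
        assert segments[0].end < segments[1].start

    def test_missing_backbone_warns_never_helical(self):
        chain = build_peptide([(12, -57, -47)], chain_id="B")
        target = chain.residues[5]
        target.atoms = [a for a in target.atoms if a.name == "CA"]
        model = StructureModel(chains=[chain])
        with pytest.warns(UserWarning, match="lacks full backbone"):
            segments = assign_helices(model, "B")
        assert all(target.author_seq_id not in s for s in segments)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            HelixSegment("B", 10, 12)


class TestClassifyPatchContacts:
    def test_patch_membership_labels(self, site):
        iface = _iface_from_pairs([
            (("B", 56), ("A", 178)),
            (("B", 58), ("A", 284)),
            (("B", 58), ("A", 340)),
        ])
        labels = classify_patch_contacts(iface, site)
        assert labels[("B", 56)] == {"patch1"}
        assert labels[("B", 58)] == {"patch2", "patch3"}
        assert ("B", 60) not in labels

    def test_off_site_receptor_asserts(self, site):
        iface = _iface_from_pairs([(("B", 56), ("A", 999))])
        with pytest.raises(AssertionError):
            classify_patch_contacts(iface, site)

    def test_removing_pairs_never_adds_labels(self, site):
        pairs = [
            (("B", 56), ("A", 178)),
            (("B", 56), ("A", 197)),
            (("B", 58), ("A", 340)),
        ]
        full = classify_patch_contacts(_iface_from_pairs(pairs), site)
        sub = classify_patch_contacts(_iface_from_pairs(pairs[:1]), site)
        for rid, labels in sub.items():
            assert labels <= full[rid]


def _annotate(model, site):
    iface = interface_residues(model, site=site)
    helices = assign_helices(model, model.binder.id)
    contacts = classify_patch_contacts(iface, site)
    return iface, helices, contacts


class TestAssignRegister:
    def test_cdca4_like_register(self, site):
        model, _ = make_helix_complex(FixtureSpec.cdca4_like())
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        assert assignment.anchor == 56
        got = {off: (rid[1], patches) for off, (rid, _, patches) in assignment.offsets.items()}
        assert got == {
            0: (56, {"patch1"}),
            2: (58, {"patch3"}),
            4: (60, {"patch1"}),
            5: (61, {"patch2"}),
        }
        assert not assignment.unassigned_contacts

    def test_single_patch1_contact_fallback_anchor(self, site):
        spec = FixtureSpec(contacts={0: "patch1"}, approach=3.6)
        model, _ = make_helix_complex(spec)
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        assert assignment.anchor == 56
        assert set(assignment.offsets) == {0}

    def test_helix_with_more_patch1_contacts_wins(self, site):
        # first helix: one patch-1 contact; second helix: three
        spec = FixtureSpec(
            segments=((10, -57.0, -47.0), (5, -120.0, 120.0), (10, -57.0, -47.0)),
            binder_start=40,
            anchor=58,  # inside the second helix (residues 55-64)
            contacts={0: "patch1", 4: "patch1"},
            extra_contacts=((44, 228), (60, 222)),
            approach=3.6,
        )
        model, _ = make_helix_complex(spec)
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        assert assignment.binding_helix.start >= 55
        assert assignment.anchor == 58

    def test_adjacent_helix_patch3_contact_stays_unassigned(self, site):
        # helix-loop-helix: patch 3 supplementation from the first helix
        spec = FixtureSpec(
            segments=((10, -57.0, -47.0), (5, -120.0, 120.0), (10, -57.0, -47.0)),
            binder_start=40,
            anchor=58,
            contacts={0: "patch1", 4: "patch1"},
            extra_contacts=((44, 340),),
            approach=3.6,
        )
        model, _ = make_helix_complex(spec)
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        assert ("B", 44) in assignment.unassigned_contacts
        assert assignment.unassigned_contacts[("B", 44)] == {"patch3"}
        assert all(rid[1] != 44 for rid, _, _ in assignment.offsets.values())

    def test_no_patch1_contacts_is_non_canonical(self, site):
        spec = FixtureSpec(contacts={2: "patch3"}, approach=3.6)
        model, _ = make_helix_complex(spec)
        iface, helices, contacts = _annotate(model, site)
        with pytest.raises(RegisterError, match="non-canonical"):
            assign_register(helices, contacts, iface, model=model, site=site)

    def test_renumbering_shifts_anchor_by_offset(self, site):
        base = FixtureSpec.cdca4_like()
        shifted = FixtureSpec.cdca4_like(binder_start=151, anchor=156)
        for spec, expected in [(base, 56), (shifted, 156)]:
            model, _ = make_helix_complex(spec)
            iface, helices, contacts = _annotate(model, site)
            assignment = assign_register(helices, contacts, iface, model=model, site=site)
            assert assignment.anchor == expected


class TestMotifReport:
    def test_patch_digits_under_register_positions(self, site):
        model, _ = make_helix_complex(FixtureSpec.cdca4_like())
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        report = motif_report(assignment, model)
        lines = {l.split()[0]: l for l in report.splitlines() if " " in l}
        first = int(lines["residues"].split()[1].split("-")[0])
        patch_row = lines["patch"][len("patch  "):]
        anchor_row = lines["anchor"][len("anchor "):]
        def char_at(resid, row):
            return row[resid - first]
        assert char_at(56, patch_row) == "1"
        assert char_at(58, patch_row) == "3"
        assert char_at(60, patch_row) == "1"
        assert char_at(61, patch_row) == "2"
        assert char_at(56, anchor_row) == "^"

    def test_rigid_transform_gives_identical_report(self, site):
        spec = FixtureSpec.cdca4_like()
        reports = []
        for seed in (0, 1):
            model, _ = make_helix_complex(spec)
            if seed:
                R, t = random_rigid(np.random.default_rng(9))
                model = model.transformed(R, t)
            iface, helices, contacts = _annotate(model, site)
            assignment = assign_register(helices, contacts, iface, model=model, site=site)
            reports.append(motif_report(assignment, model))
        assert reports[0] == reports[1]

    def test_anchor_only_assignment(self, site):
        spec = FixtureSpec(contacts={0: "patch1"}, approach=3.6)
        model, _ = make_helix_complex(spec)
        iface, helices, contacts = _annotate(model, site)
        assignment = assign_register(helices, contacts, iface, model=model, site=site)
        report = motif_report(assignment, model)
        patch_row = [l for l in report.splitlines() if l.startswith("patch")][0]
        assert patch_row.count("1") == 1
        table = register_table(assignment)
        assert list(table["offset"]) == [0]
        assert list(table["patches"]) == ["patch1"]
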