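"""Helix assignment, patch classification and register annotation.

The canonical binders dock a single alpha-helix into the conserved
receptor surface, with hydrophobic residues at helical positions i and
i+4 contacting patch 1, i+1 and/or i+5 reaching patch 2, and the residue
on the opposite helix face at i+2 forming the electrostatic contact with
patch 3.  This module assigns helices from backbone dihedrals, labels
binder residues by the receptor patch they touch, picks the binding
helix and the anchor position i, and renders a text motif report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .errors import RegisterError
from .interface import InterfaceMap, ResidueId
from .model_io import BindingSiteDef, StructureModel

__all__ = [
    "HelixSegment",
    "RegisterAssignment",
    "assign_helices",
    "classify_patch_contacts",
    "assign_register",
    "motif_report",
    "register_table",
]

REGISTER_OFFSETS = (0, 1, 2, 4, 5)

# Backbone dihedral window accepting alpha-helical residues.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)


@dataclass(frozen=True)
class HelixSegment:
    chain_id: str
    start: int  # author_seq_id, inclusive
    end: int  # author_seq_id, inclusive

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("a helix segment spans at least 4 residues")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, author_seq_id: int) -> bool:
        return self.start <= author_seq_id <= self.end


@dataclass
class RegisterAssignment:
    binding_helix: HelixSegment
    anchor: int  # author_seq_id of position i
    offsets: dict[int, tuple[ResidueId, str, frozenset[str]]]
    unassigned_contacts: dict[ResidueId, frozenset[str]] = field(default_factory=dict)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def assign_helices(
    model: StructureModel,
    chain_id: str,
    phi_window: tuple[float, float] = PHI_WINDOW,
    psi_window: tuple[float, float] = PSI_WINDOW,
    min_length: int = 4,
) -> list[HelixSegment]:
    """Assign helices as maximal runs of residues with helical (phi, psi).

    A residue is helical iff both dihedrals exist (consecutive author
    numbering, full N/CA/C backbone on the neighbours involved) and fall
    inside the windows.  Residues with missing backbone atoms are skipped
    with a warning, never silently counted helical.
    """
    chain = model.chain(chain_id)
    backbone: dict[int, dict[str, np.ndarray]] = {}
    for res in chain.residues:
        atoms = {}
        for name in ("N", "CA", "C"):
            a = res.atom(name)
            if a is not None:
                atoms[name] = a.position
        if len(atoms) < 3:
            warnings.warn(
                f"residue {chain_id}/{res.author_seq_id} lacks full backbone; "
                "skipped in helix assignment",
                stacklevel=2,
            )
            continue
        backbone[res.author_seq_id] = atoms

    helical: list[int] = []
    for rid, bb in backbone.items():
        prev = backbone.get(rid - 1)
        nxt = backbone.get(rid + 1)
        if prev is None or nxt is None:
            continue
        phi = _dihedral(prev["C"], bb["N"], bb["CA"], bb["C"])
        psi = _dihedral(bb["N"], bb["CA"], bb["C"], nxt["N"])
        if phi_window[0] < phi < phi_window[1] and psi_window[0] < psi < psi_window[1]:
            helical.append(rid)

    runs: list[list[int]] = []  # [start, end] of consecutive helical residues
    for rid in sorted(helical):
        if runs and rid == runs[-1][1] + 1:
            runs[-1][1] = rid
        else:
            runs.append([rid, rid])
    return [
        HelixSegment(chain_id, start, end)
        for start, end in runs
        if end - start + 1 >= min_length
    ]


def classify_patch_contacts(
    iface: InterfaceMap, site: BindingSiteDef
) -> dict[ResidueId, frozenset[str]]:
    """Label each contacting binder residue with the receptor patches it touches."""
    labels: dict[ResidueId, set[str]] = {}
    for binder, receptor in iface.pairs:
        assert receptor[1] in site.site, (
            f"receptor residue {receptor} outside the binding-site definition; "
            "interface must be computed against the same site"
        )
        patch = site.patch_of(receptor[1])
        if patch is not None:
            labels.setdefault(binder, set()).add(patch)
        else:
            labels.setdefault(binder, set())
    return {
        rid: frozenset(patches) for rid, patches in labels.items() if patches
    }


def _patch1_contact_weight(
    rid: ResidueId, iface: InterfaceMap, site: BindingSiteDef
) -> int:
    return sum(
        iface.atom_contact_counts.get((rid, rec), 0)
        for _, rec in iface.pairs
        if rec[1] in site.patch1
    )


def assign_register(
    helices: list[HelixSegment],
    patch_contacts: dict[ResidueId, frozenset[str]],
    iface: InterfaceMap,
    model: StructureModel | None = None,
    site: BindingSiteDef | None = None,
) -> RegisterAssignment:
    """Pick the binding helix and assign the i/i+1/i+2/i+4/i+5 register.

    Binding helix: the helix containing the most patch-1-labeled residues
    (tie: more total interface residues, then most N-terminal).  Anchor i:
    the most N-terminal helix residue r with r and r+4 both carrying
    patch 1; failing that, the patch-1 residue with most atom-level
    contacts to patch-1 receptor residues.  Contacting residues outside
    the register offsets (or outside the binding helix, e.g. supplementary
    contacts from an adjacent helix or loop) are reported in
    ``unassigned_contacts``.
    """
    if not helices:
        raise RegisterError("no helices in the binder chain")
    if site is None:
        site = BindingSiteDef.default()
    patch1_residues = {
        rid for rid, patches in patch_contacts.items() if "patch1" in patches
    }
    if not patch1_residues:
        raise RegisterError(
            "non-canonical binder: no patch-1 contacts, register undefined"
        )

    def helix_key(h: HelixSegment) -> tuple[int, int, int]:
        n_p1 = sum(
            1 for rid in patch1_residues if rid[0] == h.chain_id and rid[1] in h
        )
        n_iface = sum(
            1 for rid in iface.binder_iface if rid[0] == h.chain_id and rid[1] in h
        )
        return (-n_p1, -n_iface, h.start)

    binding_helix = min(helices, key=helix_key)
    helix_p1 = sorted(
        rid[1]
        for rid in patch1_residues
        if rid[0] == binding_helix.chain_id and rid[1] in binding_helix
    )
    if not helix_p1:
        raise RegisterError(
            "non-canonical binder: patch-1 contacts lie outside every helix"
        )

    anchor = None
    for r in helix_p1:
        if r + 4 in helix_p1 and r + 4 <= binding_helix.end:
            anchor = r
            break
    if anchor is None:
        chain_id = binding_helix.chain_id
        anchor = max(
            helix_p1,
            key=lambda r: (_patch1_contact_weight((chain_id, r), iface, site), -r),
        )

    def residue_name(rid: ResidueId) -> str:
        if model is None:
            return "UNK"
        res = model.chain(rid[0]).residue(rid[1])
        return res.name if res is not None else "UNK"

    offsets: dict[int, tuple[ResidueId, str, frozenset[str]]] = {}
    placed: set[ResidueId] = set()
    for off in REGISTER_OFFSETS:
        rid = (binding_helix.chain_id, anchor + off)
        if rid[1] in binding_helix and rid in patch_contacts:
            offsets[off] = (rid, residue_name(rid), patch_contacts[rid])
            placed.add(rid)
    unassigned = {
        rid: patches for rid, patches in patch_contacts.items() if rid not in placed
    }
    return RegisterAssignment(
        binding_helix=binding_helix,
        anchor=anchor,
        offsets=offsets,
        unassigned_contacts=unassigned,
    )


_PATCH_CHAR = {"patch1": "1", "patch2": "2", "patch3": "3", "flank": "f"}


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def motif_report(assignment: RegisterAssignment, model: StructureModel) -> str:
    """Deterministic text report of the binding helix and its patch contacts.

    Shows the one-letter sequence over the binding helix plus five
    flanking residues on each side, a helix-extent line, a patch line
    (1/2/3/f; '*' where one residue touches several patches) and the
    anchor marker.
    """
    helix = assignment.binding_helix
    chain = model.chain(helix.chain_id)
    present = {r.author_seq_id: r for r in chain.residues}
    lo, hi = helix.start - 5, helix.end + 5
    window = [rid for rid in range(lo, hi + 1) if rid in present]

    labels = dict(assignment.unassigned_contacts)
    for off, (rid, _name, patches) in assignment.offsets.items():
        labels[rid] = patches

    seq_line = []
    helix_line = []
    patch_line = []
    anchor_line = []
    for rid in window:
        seq_line.append(_one_letter(present[rid].name))
        helix_line.append("H" if rid in helix else ".")
        patches = labels.get((helix.chain_id, rid))
        if not patches:
            patch_line.append(" ")
        elif len(patches) == 1:
            patch_line.append(_PATCH_CHAR[next(iter(patches))])
        else:
            patch_line.append("*")
        anchor_line.append("^" if rid == assignment.anchor else " ")

    lines = [
        f"binding helix {helix.chain_id}:{helix.start}-{helix.end}  "
        f"anchor i = {assignment.anchor}",
        f"residues {window[0]}-{window[-1]}",
        "seq    " + "".join(seq_line),
        "helix  " + "".join(helix_line),
        "patch  " + "".join(patch_line),
        "anchor " + "".join(anchor_line),
    ]
    extra = {
        rid: patches
        for rid, patches in sorted(assignment.unassigned_contacts.items())
        if not (rid[0] == helix.chain_id and window[0] <= rid[1] <= window[-1])
    }
    if extra:
        lines.append("outside-window contacts:")
        for rid, patches in extra.items():
            lines.append(
                f"  {rid[0]}/{rid[1]}: " + ",".join(sorted(patches))
            )
    return "\n".join(lines) + "\n"


def register_table(assignment: RegisterAssignment) -> pd.DataFrame:
    """Machine-readable register (offset, residue, name, patches)."""
    rows = [
        {
            "offset": off,
            "chain": rid[0],
            "residue": rid[1],
            "name": name,
            "patches": ",".join(sorted(patches)),
        }
        for off, (rid, name, patches) in sorted(assignment.offsets.items())
    ]
    return pd.DataFrame(rows, columns=["offset", "chain", "residue", "name", "patches"])
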