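"""Synthetic fixtures: helix-receptor complexes, confidence data, titrations.

Everything downstream of the predictors is exercised on constructed
inputs whose ground truth is known exactly:

* ideal-geometry binder peptides (alpha-helical or arbitrary phi/psi
  segments) with receptor residues placed as single-residue probes so
  that exactly a prescribed set of binder-receptor contacts exists at a
  prescribed closest-approach distance, all other cross-chain residue
  pairs staying beyond a clearance margin;
* pLDDT profiles and block-valued PAE matrices with prescribed interface
  values;
* noisy one-site saturation binding curves.

All generators are pure functions of (spec, seed).  Receptor probes are
deliberately single residues rather than a folded domain: the screening
arithmetic depends only on distances, confidence values and residue
identities, which the probes control exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .binding import BindingCurve, predict_one_site
from .errors import InfeasibleFixtureError
from .interface import InterfaceMap, InterfaceParams, ResidueId
from .model_io import (
    Atom,
    BindingSiteDef,
    Chain,
    ConfidenceData,
    Residue,
    StructureModel,
)

__all__ = [
    "FixtureSpec",
    "build_peptide",
    "make_helix_complex",
    "make_confidence",
    "make_pae",
    "make_binding_curve",
    "make_fixture",
    "random_fixture_spec",
    "write_fixture_pair",
    "make_standard_fixtures",
    "DEFAULT_CONCENTRATIONS_NM",
]

# Ideal backbone geometry (lengths A, angles deg).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
ALPHA_PHI, ALPHA_PSI = -57.0, -47.0

# Cross-chain residue pairs that are not prescribed contacts must stay
# farther apart than this (A).
MIN_SEPARATION = 6.0

# Titration series used in the FP-style assays: three-fold dilutions
# spanning 1.8-500 nM receptor.
DEFAULT_CONCENTRATIONS_NM = tuple(1.8 * 3.0**k for k in range(6))

_PROBE_NAMES = {
    178: "TYR", 197: "ASP", 222: "MET", 225: "LEU", 228: "VAL",
    284: "ILE", 287: "SER", 340: "ASP", 337: "TYR", 343: "PHE",
}
_CONTACT_RESIDUE = {"patch1": "LEU", "patch2": "LEU", "patch3": "ARG", "flank": "PHE"}


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension placement: position d with given internal coordinates."""
    ang = np.radians(angle_deg)
    tor = -np.radians(torsion_deg)  # IUPAC torsion sign
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # Standard C-beta reconstruction from the backbone frame.
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_peptide(
    segments: list[tuple[int, float, float]],
    chain_id: str = "B",
    start_id: int = 1,
    names: Mapping[int, str] | None = None,
    default_name: str = "ALA",
) -> Chain:
    """Build a peptide chain with ideal geometry from (length, phi, psi) segments.

    Each residue carries N, CA, C, O and CB.  ``names`` maps author
    seq ids to 3-letter codes.
    """
    names = dict(names or {})
    n_total = sum(n for n, _, _ in segments)
    phis: list[float] = []
    psis: list[float] = []
    for n, phi, psi in segments:
        phis.extend([phi] * n)
        psis.extend([psi] * n)

    # Seed the first three backbone atoms in the xy-plane.
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": N0, "CA": CA0, "C": C0}]
    for i in range(1, n_total):
        prev = backbone[-1]
        Ni = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        CAi = _place_atom(prev["CA"], prev["C"], Ni, _B_N_CA, _A_C_N_CA, 180.0)
        Ci = _place_atom(prev["C"], Ni, CAi, _B_CA_C, _A_N_CA_C, phis[i])
        backbone.append({"N": Ni, "CA": CAi, "C": Ci})

    chain = Chain(id=chain_id)
    for i, bb in enumerate(backbone):
        seq_id = start_id + i
        res = Residue(author_seq_id=seq_id, name=names.get(seq_id, default_name))
        o_torsion = (psis[i] + 180.0) if i + 1 < n_total else 180.0
        O = _place_atom(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, o_torsion)
        CB = _cb_position(bb["N"], bb["CA"], bb["C"])
        res.atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", O),
            Atom("CB", "C", CB),
        ]
        chain.residues.append(res)
    return chain


@dataclass(frozen=True)
class FixtureSpec:
    """Prescription for one synthetic helix-receptor complex.

    ``contacts`` maps register offsets (subset of {0, 1, 2, 4, 5},
    relative to ``anchor``) to patch labels; ``extra_contacts`` adds
    arbitrary (binder author id, receptor author id) contacts, e.g. to
    grow the interface past the screen's size threshold or to probe
    off-site receptor residues.  ``approach`` is the exact closest-approach
    distance (A) realised for every prescribed contact.
    """

    binder_length: int = 14
    binder_start: int = 51
    anchor: int = 56
    contacts: Mapping[int, str] = field(default_factory=dict)
    extra_contacts: tuple[tuple[int, int], ...] = ()
    segments: tuple[tuple[int, float, float], ...] | None = None
    approach: float = 3.5
    plddt_binder: float = 90.0
    plddt_receptor: float = 90.0
    plddt_overrides: Mapping[ResidueId, float] = field(default_factory=dict)
    pae_interface: float = 5.0
    pae_background: float = 25.0
    seed: int = 0
    binder_chain: str = "B"
    receptor_chain: str = "A"
    site: BindingSiteDef = field(default_factory=BindingSiteDef.default)
    residue_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.contacts) <= {0, 1, 2, 4, 5}:
            raise ValueError("register contact offsets must lie in {0,1,2,4,5}")
        if self.pae_interface > self.pae_background:
            raise ValueError("interface PAE must not exceed background PAE")
        if self.approach <= 0:
            raise ValueError("closest-approach distance must be positive")
        end = self.binder_start + self.n_binder - 1
        for off in self.contacts:
            if not self.binder_start <= self.anchor + off <= end:
                raise ValueError(f"contact offset {off} falls outside the binder")
        for bid, _ in self.extra_contacts:
            if not self.binder_start <= bid <= end:
                raise ValueError(f"extra contact residue {bid} outside the binder")

    @property
    def n_binder(self) -> int:
        if self.segments is not None:
            return sum(n for n, _, _ in self.segments)
        return self.binder_length

    @classmethod
    def cdca4_like(cls, **overrides) -> "FixtureSpec":
        """Canonical binder: patch 1 at i/i+4, patch 3 at i+2, patch 2 at i+5."""
        base = dict(
            binder_length=14,
            binder_start=51,
            anchor=56,
            contacts={0: "patch1", 4: "patch1", 2: "patch3", 5: "patch2"},
        )
        base.update(overrides)
        return cls(**base)


def _contact_plan(spec: FixtureSpec) -> list[tuple[int, int, str | None]]:
    """Resolve contacts to (binder author id, receptor author id, patch|None)."""
    plan: list[tuple[int, int, str | None]] = []
    used: set[int] = set()
    patches = spec.site.patches()
    for off in sorted(spec.contacts):
        patch = spec.contacts[off]
        if patch not in patches:
            raise ValueError(f"unknown patch label {patch!r}")
        candidates = [r for r in sorted(patches[patch]) if r not in used]
        if not candidates:
            raise InfeasibleFixtureError(
                f"patch {patch} has no unused receptor residues left"
            )
        rec = candidates[0]
        used.add(rec)
        plan.append((spec.anchor + off, rec, patch))
    for bid, rec in spec.extra_contacts:
        if rec in used:
            raise InfeasibleFixtureError(
                f"receptor residue {rec} demanded by two contacts"
            )
        used.add(rec)
        plan.append((bid, rec, spec.site.patch_of(rec)))
    return plan


def _probe_residue(
    seq_id: int,
    name: str,
    contact_point: np.ndarray,
    u: np.ndarray,
    rng: np.random.Generator,
) -> Residue:
    """Single-residue receptor probe whose CB sits exactly at contact_point.

    The remaining atoms extend outward along u (away from the binder) with
    a small seeded jitter, so the CB stays the closest atom.
    """
    v = np.array([1.0, 0.0, 0.0])
    if abs(v @ u) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    v = v - (v @ u) * u
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)

    def jitter() -> np.ndarray:
        return rng.uniform(-0.05, 0.05, size=2) @ np.stack([v, w])

    res = Residue(author_seq_id=seq_id, name=name)
    res.atoms = [
        Atom("CB", "C", contact_point),
        Atom("CA", "C", contact_point + 1.52 * u + jitter()),
        Atom("N", "N", contact_point + 2.30 * u + 0.80 * v + jitter()),
        Atom("C", "C", contact_point + 2.30 * u - 0.80 * v + jitter()),
    ]
    return res


def make_helix_complex(spec: FixtureSpec) -> tuple[StructureModel, InterfaceMap]:
    """Build the prescribed complex and its ground-truth interface map.

    The binder is an ideal alpha-helix (or the phi/psi segments given in
    the spec); each prescribed contact gets a receptor probe placed along
    the contacted residue's CA->CB direction with minimum atom distance
    exactly ``spec.approach``.  The construction is verified numerically:
    prescribed pairs must sit at the approach distance and every other
    cross-chain residue pair beyond 6 A, otherwise the spec is rejected
    as geometrically infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    segments = (
        list(spec.segments)
        if spec.segments is not None
        else [(spec.binder_length, ALPHA_PHI, ALPHA_PSI)]
    )
    plan = _contact_plan(spec)
    names = dict(spec.residue_names)
    for bid, _rec, patch in plan:
        if patch is not None:
            names.setdefault(bid, _CONTACT_RESIDUE[patch])
    binder = build_peptide(
        segments, chain_id=spec.binder_chain, start_id=spec.binder_start, names=names
    )

    receptor = Chain(id=spec.receptor_chain)
    by_id = {r.author_seq_id: r for r in binder.residues}
    for bid, rec, _patch in sorted(plan, key=lambda item: item[1]):
        res = by_id[bid]
        cb = res.atom("CB")
        # Outward direction: radially away from the local helix axis
        # (midpoint of the flanking CA atoms sits near the axis), falling
        # back to CA->CB at chain termini.  A radial probe keeps the
        # clearance to the i+-1/i+-4 neighbours maximal.
        prev_res, next_res = by_id.get(bid - 1), by_id.get(bid + 1)
        if prev_res is not None and next_res is not None:
            origin = 0.5 * (prev_res.atom("CA").position + next_res.atom("CA").position)
        else:
            origin = res.atom("CA").position
        u = cb.position - origin
        u = u / np.linalg.norm(u)
        point = cb.position + spec.approach * u
        receptor.residues.append(
            _probe_residue(rec, _PROBE_NAMES.get(rec, "ALA"), point, u, rng)
        )
    if not plan:
        # A contact-free complex still needs a receptor chain: one probe
        # far beyond any contact range.
        center = np.mean([r.atom("CA").position for r in binder.residues], axis=0)
        far = center + np.array([25.0, 0.0, 0.0])
        rec = sorted(spec.site.patch1)[0]
        receptor.residues.append(
            _probe_residue(rec, _PROBE_NAMES.get(rec, "ALA"), far, np.array([1.0, 0, 0]), rng)
        )

    model = StructureModel(chains=[receptor, binder])
    model.assign_roles(receptor=spec.receptor_chain, binder=spec.binder_chain)
    model.validate()

    prescribed = {
        ((spec.binder_chain, bid), (spec.receptor_chain, rec)) for bid, rec, _ in plan
    }
    _verify_geometry(model, prescribed, spec.approach)

    atomic_cutoff = 4.0
    pairs: set = set()
    min_d: dict = {}
    counts: dict = {}
    if spec.approach <= atomic_cutoff:
        for (bkey, rkey) in prescribed:
            bres = by_id[bkey[1]]
            rres = receptor.residue(rkey[1])
            d = cdist(bres.coords(), rres.coords())
            pairs.add((bkey, rkey))
            min_d[(bkey, rkey)] = float(d.min())
            counts[(bkey, rkey)] = int((d <= atomic_cutoff).sum())
    truth = InterfaceMap(
        pairs=frozenset(pairs),
        excluded_low_plddt=frozenset(),
        params=InterfaceParams(
            prefilter_cutoff=float("inf"),
            atomic_cutoff=atomic_cutoff,
            plddt_min=None,
            site_restricted=False,
        ),
        min_distances=min_d,
        atom_contact_counts=counts,
    )
    return model, truth


def _verify_geometry(
    model: StructureModel,
    prescribed: set,
    approach: float,
) -> None:
    binder, receptor = model.binder, model.receptor
    for bres in binder.residues:
        for rres in receptor.residues:
            dmin = float(cdist(bres.coords(), rres.coords()).min())
            key = ((binder.id, bres.author_seq_id), (receptor.id, rres.author_seq_id))
            if key in prescribed:
                if abs(dmin - approach) > 1e-6:
                    raise InfeasibleFixtureError(
                        f"contact {key} realised at {dmin:.3f} A, not {approach} A; "
                        "another atom intrudes - the prescribed pattern is infeasible"
                    )
            elif dmin <= MIN_SEPARATION:
                raise InfeasibleFixtureError(
                    f"non-contact pair {key} at {dmin:.2f} A violates the "
                    f"{MIN_SEPARATION} A clearance; the prescribed pattern is infeasible"
                )


def make_pae(
    n_binder: int,
    n_receptor: int,
    binder_iface: list[int] | set[int],
    receptor_iface: list[int] | set[int],
    interface_value: float,
    background_value: float,
    symmetrize: bool = False,
    receptor_first: bool = True,
) -> np.ndarray:
    """Block-valued PAE matrix over the concatenated receptor+binder index.

    ``binder_iface`` / ``receptor_iface`` are 0-based positions within
    each chain; the block (binder rows x receptor columns) is set to
    ``interface_value`` on a ``background_value`` background.  With
    ``symmetrize`` the transposed block is set too.
    """
    if interface_value < 0 or background_value < 0:
        raise ValueError("PAE values must be >= 0")
    n = n_binder + n_receptor
    rec_off = 0 if receptor_first else n_binder
    bind_off = n_receptor if receptor_first else 0
    rows = [bind_off + i for i in sorted(binder_iface)]
    cols = [rec_off + j for j in sorted(receptor_iface)]
    for i in sorted(binder_iface):
        if not 0 <= i < n_binder:
            raise IndexError(f"binder index {i} out of range")
    for j in sorted(receptor_iface):
        if not 0 <= j < n_receptor:
            raise IndexError(f"receptor index {j} out of range")
    pae = np.full((n, n), float(background_value))
    if rows and cols:
        pae[np.ix_(rows, cols)] = interface_value
        if symmetrize:
            pae[np.ix_(cols, rows)] = interface_value
    return pae


def make_confidence(
    model: StructureModel,
    truth: InterfaceMap | None = None,
    plddt_binder: float = 90.0,
    plddt_receptor: float = 90.0,
    plddt_overrides: Mapping[ResidueId, float] | None = None,
    pae_interface: float = 5.0,
    pae_background: float = 25.0,
    symmetrize: bool = False,
) -> ConfidenceData:
    """ConfidenceData for a synthetic complex with prescribed block PAE."""
    order = model.residue_order()
    index_map = {key: i for i, key in enumerate(order)}
    binder, receptor = model.binder, model.receptor
    plddt = np.empty(len(order))
    overrides = dict(plddt_overrides or {})
    for key, i in index_map.items():
        base = plddt_binder if key[0] == binder.id else plddt_receptor
        plddt[i] = overrides.get(key, base)
    pae = np.full((len(order), len(order)), float(pae_background))
    if truth is not None and truth.pairs:
        rows = [index_map[b] for b in sorted(truth.binder_iface)]
        cols = [index_map[r] for r in sorted(truth.receptor_iface)]
        pae[np.ix_(rows, cols)] = pae_interface
        if symmetrize:
            pae[np.ix_(cols, rows)] = pae_interface
    return ConfidenceData(plddt, pae, index_map)


def make_fixture(spec: FixtureSpec) -> tuple[StructureModel, InterfaceMap, ConfidenceData]:
    """Complex, ground-truth interface and matching confidence in one call."""
    model, truth = make_helix_complex(spec)
    conf = make_confidence(
        model,
        truth,
        plddt_binder=spec.plddt_binder,
        plddt_receptor=spec.plddt_receptor,
        plddt_overrides=spec.plddt_overrides,
        pae_interface=spec.pae_interface,
        pae_background=spec.pae_background,
    )
    return model, truth, conf


def random_fixture_spec(
    rng: np.random.Generator,
    n_contacts_range: tuple[int, int] = (3, 8),
    binder_length_range: tuple[int, int] = (8, 20),
    approach_range: tuple[float, float] = (3.5, 3.9),
) -> FixtureSpec:
    """Random feasible fixture prescription (contacts via explicit pairs).

    Contact positions avoid the helix termini and the approach stays at
    3.5 A or more so that the 6 A clearance to neighbouring residues is
    geometrically attainable on an ideal helix.
    """
    length = int(rng.integers(binder_length_range[0], binder_length_range[1] + 1))
    start = int(rng.integers(1, 60))
    site = BindingSiteDef.default()
    n_contacts = int(rng.integers(n_contacts_range[0], min(n_contacts_range[1], len(site.site)) + 1))
    interior = np.arange(1, length - 1)
    binder_positions = rng.choice(interior, size=min(n_contacts, len(interior)), replace=False)
    receptor_ids = rng.choice(sorted(site.site), size=len(binder_positions), replace=False)
    extra = tuple(
        (start + int(b), int(r)) for b, r in zip(binder_positions, receptor_ids)
    )
    return FixtureSpec(
        binder_length=length,
        binder_start=start,
        anchor=start,
        contacts={},
        extra_contacts=extra,
        approach=float(rng.uniform(*approach_range)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_binding_curve(
    kd: float,
    bmax: float,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> BindingCurve:
    """Noisy one-site titration; identical seed gives the identical curve."""
    if kd <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    if concentrations is None:
        concentrations = DEFAULT_CONCENTRATIONS_NM
    X = np.asarray(concentrations, dtype=float)
    y = predict_one_site(kd, bmax, X)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=X.shape)
    return BindingCurve(concentrations=X, responses=np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# On-disk fixture suites
# ---------------------------------------------------------------------------

def write_fixture_pair(
    directory: str | Path,
    name: str,
    model: StructureModel,
    conf: ConfidenceData,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Write a PDB + scores-JSON fixture pair; returns the two paths."""
    from .model_io import write_structure  # local import avoids cycle at import time

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb_path = directory / f"{name}.pdb"
    json_path = directory / f"{name}_scores.json"
    write_structure(model, pdb_path, format="pdb")
    order = sorted(conf.index_map, key=conf.index_map.get)
    payload = {
        "plddt": [float(v) for v in conf.plddt],
        "predicted_aligned_error": conf.require_pae().tolist(),
        "residue_order": [[c, int(i)] for c, i in order],
    }
    if seed is not None:
        payload["generator_seed"] = int(seed)
    json_path.write_text(json.dumps(payload))
    return pdb_path, json_path


def make_standard_fixtures(directory: str | Path, seed: int = 0) -> Path:
    """Materialise a small screening test set: pass / sentinel / fail.

    Writes three structure+confidence pairs, a screening manifest and a
    noisy binding-curve CSV; returns the manifest path.
    """
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    # Nine interface residues, confident, low interface PAE: passes.
    passing = FixtureSpec.cdca4_like(
        extra_contacts=((54, 337), (55, 343), (57, 287), (59, 222), (62, 228)),
        seed=seed,
    )
    # Canonical register only (5 contacts <= 7): sentinel.
    sentinel = FixtureSpec.cdca4_like(seed=seed + 1)
    # Large interface but high interface PAE: fails the thresholds.
    failing = replace(passing, pae_interface=18.0, seed=seed + 2)

    rows = []
    for name, spec in [("passing", passing), ("sentinel", sentinel), ("failing", failing)]:
        model, truth, conf = make_fixture(spec)
        pdb_path, json_path = write_fixture_pair(directory, name, model, conf, seed=spec.seed)
        rows.append(
            {"model": str(pdb_path), "confidence": str(json_path), "receptor_chain": "A"}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    curve = make_binding_curve(kd=6.0, bmax=150.0, noise_sd=3.0, seed=seed)
    pd.DataFrame(
        {"concentration_nM": curve.concentrations, "response": curve.responses}
    ).to_csv(directory / "binding_curve.csv", index=False)
    return manifest
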