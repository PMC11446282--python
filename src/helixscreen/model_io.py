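"""Structure and confidence I/O.

Reads and writes PDB/mmCIF coordinate files (through gemmi) into a small
in-memory model — chains of residues of atoms — and loads per-residue pLDDT
plus the N x N predicted-aligned-error (PAE) matrix from the JSON dialects
emitted by common structure-prediction servers, or pLDDT stored in the
B-factor column.  Every downstream module addresses residues by the pair
``(chain_id, author_seq_id)``; the :class:`ConfidenceData` index map ties
that identity to a 0-based row/column of the PAE matrix.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import gemmi

from .errors import AbsentPAEError, ConfidenceError, StructureParseError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ConfidenceData",
    "BindingSiteDef",
    "read_structure",
    "write_structure",
    "read_confidence",
]

Role = Literal["receptor", "binder", "unassigned"]

# Residue names treated as solvent and never loaded into the model.
_SOLVENT = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) float, Angstrom
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom position must be 3D, got {self.position.shape}")


@dataclass
class Residue:
    author_seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def id(self) -> int:
        return self.author_seq_id


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    role: Role = "unassigned"

    def residue(self, author_seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.author_seq_id == author_seq_id:
                return r
        return None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """One predicted complex: an ordered set of chains.

    Exactly one chain should carry ``role='receptor'`` and one
    ``role='binder'`` before interface calculations; use
    :meth:`assign_roles`.
    """

    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model")

    def validate(self) -> None:
        for c in self.chains:
            seen: set[int] = set()
            for r in c.residues:
                if not r.atoms:
                    raise ValueError(f"residue {c.id}/{r.author_seq_id} has no atoms")
                if r.author_seq_id in seen:
                    raise ValueError(
                        f"duplicate author_seq_id {r.author_seq_id} in chain {c.id}"
                    )
                seen.add(r.author_seq_id)
                for a in r.atoms:
                    if not np.all(np.isfinite(a.position)):
                        raise ValueError(
                            f"non-finite coordinates on {c.id}/{r.author_seq_id}/{a.name}"
                        )

    def assign_roles(self, receptor: str | None = None, binder: str | None = None) -> "StructureModel":
        """Mark chain roles in place and return self.

        Default: the first chain is the receptor and the second the binder,
        matching prediction outputs where the receptor is listed first.
        """
        if len(self.chains) < 2:
            raise ValueError("role assignment requires at least two chains")
        rec_id = receptor if receptor is not None else self.chains[0].id
        if binder is None:
            binder_candidates = [c.id for c in self.chains if c.id != rec_id]
            if not binder_candidates:
                raise ValueError("no candidate binder chain")
            bind_id = binder_candidates[0]
        else:
            bind_id = binder
        if rec_id == bind_id:
            raise ValueError("receptor and binder chains must differ")
        for c in self.chains:
            if c.id == rec_id:
                c.role = "receptor"
            elif c.id == bind_id:
                c.role = "binder"
            else:
                c.role = "unassigned"
        self.chain(rec_id)
        self.chain(bind_id)
        return self

    @property
    def receptor(self) -> Chain:
        return self._by_role("receptor")

    @property
    def binder(self) -> Chain:
        return self._by_role("binder")

    def _by_role(self, role: Role) -> Chain:
        hits = [c for c in self.chains if c.role == role]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one {role} chain, found {len(hits)}; "
                "call assign_roles() first"
            )
        return hits[0]

    def residue_order(self, receptor_first: bool = False) -> list[tuple[str, int]]:
        """Residue identities in file order.

        With ``receptor_first`` the receptor chain is moved to the front
        regardless of file order (useful to match a PAE matrix whose
        concatenation order differs from the coordinate file).
        """
        chains = list(self.chains)
        if receptor_first:
            chains.sort(key=lambda c: 0 if c.role == "receptor" else 1)
        return [(c.id, r.author_seq_id) for c in chains for r in c.residues]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-body transformed copy (positions -> R @ x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = StructureModel()
        for c in self.chains:
            nc = Chain(id=c.id, role=c.role)
            for r in c.residues:
                nr = Residue(author_seq_id=r.author_seq_id, name=r.name, het=r.het)
                for a in r.atoms:
                    nr.atoms.append(
                        Atom(a.name, a.element, R @ a.position + t, a.b_factor)
                    )
                nc.residues.append(nr)
            out.chains.append(nc)
        return out


# ---------------------------------------------------------------------------
# Confidence data
# ---------------------------------------------------------------------------

class ConfidenceData:
    """Per-residue pLDDT plus optional PAE matrix with a residue index map.

    Parameters
    ----------
    plddt : array of shape (N,)
        Per-residue predicted LDDT in [0, 100].
    pae : array of shape (N, N) or None
        Predicted aligned error in Angstrom.  ``None`` when the source
        (e.g. B-factor column) carries no PAE; any PAE-dependent operation
        then raises :class:`AbsentPAEError`.
    index_map : mapping (chain_id, author_seq_id) -> int
        Bijection onto 0..N-1 giving each residue's matrix row/column.
    """

    def __init__(
        self,
        plddt: Sequence[float] | np.ndarray,
        pae: np.ndarray | None,
        index_map: Mapping[tuple[str, int], int],
    ) -> None:
        self.plddt = np.asarray(plddt, dtype=float)
        self.pae = None if pae is None else np.asarray(pae, dtype=float)
        self.index_map = dict(index_map)
        self._validate()

    def _validate(self) -> None:
        n = len(self.plddt)
        if self.plddt.ndim != 1:
            raise ConfidenceError("plddt must be a 1-D vector")
        if np.any(~np.isfinite(self.plddt)) or np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ConfidenceError("pLDDT values must lie in [0, 100]")
        if self.pae is not None:
            if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
                raise ConfidenceError(f"PAE matrix must be square, got {self.pae.shape}")
            if self.pae.shape[0] != n:
                raise ConfidenceError(
                    f"PAE side {self.pae.shape[0]} != pLDDT length {n}"
                )
            if np.any(self.pae < 0):
                raise ConfidenceError("PAE entries must be >= 0")
        if len(self.index_map) != n or set(self.index_map.values()) != set(range(n)):
            raise ConfidenceError("index_map must be a bijection onto 0..N-1")

    def __len__(self) -> int:
        return len(self.plddt)

    def index_of(self, chain_id: str, author_seq_id: int) -> int:
        try:
            return self.index_map[(chain_id, author_seq_id)]
        except KeyError:
            raise ConfidenceError(
                f"residue ({chain_id!r}, {author_seq_id}) not in confidence index map"
            ) from None

    def plddt_of(self, chain_id: str, author_seq_id: int) -> float:
        return float(self.plddt[self.index_of(chain_id, author_seq_id)])

    def require_pae(self) -> np.ndarray:
        if self.pae is None:
            raise AbsentPAEError(
                "this operation needs a PAE matrix but the confidence source "
                "(B-factor pLDDT) carries none"
            )
        return self.pae

    def pae_block(
        self,
        rows: Iterable[tuple[str, int]],
        cols: Iterable[tuple[str, int]],
    ) -> np.ndarray:
        """Submatrix PAE[rows, cols] in the given residue order."""
        pae = self.require_pae()
        ri = [self.index_of(*r) for r in rows]
        ci = [self.index_of(*c) for c in cols]
        return pae[np.ix_(ri, ci)]


@dataclass(frozen=True)
class BindingSiteDef:
    """Receptor binding-site residues partitioned into patches.

    The three patches and the aromatic flank are pairwise-disjoint sets of
    receptor author_seq_ids; ``extra`` holds further conserved-site residues
    belonging to none of them.  :meth:`default` carries the B55-alpha
    numbering: patch 1 the hydrophobic pocket (Y178, D197, M222, L225,
    V228), patch 2 (I284, S287), patch 3 the electrostatic centre (D340),
    and the flanking aromatics (Y337, F343).
    """

    patch1: frozenset[int]
    patch2: frozenset[int]
    patch3: frozenset[int]
    flank: frozenset[int]
    extra: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch1", frozenset(self.patch1))
        object.__setattr__(self, "patch2", frozenset(self.patch2))
        object.__setattr__(self, "patch3", frozenset(self.patch3))
        object.__setattr__(self, "flank", frozenset(self.flank))
        object.__setattr__(self, "extra", frozenset(self.extra))
        sets = [self.patch1, self.patch2, self.patch3, self.flank]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("patch sets must be pairwise disjoint")

    @property
    def site(self) -> frozenset[int]:
        return self.patch1 | self.patch2 | self.patch3 | self.flank | self.extra

    def patches(self) -> dict[str, frozenset[int]]:
        return {
            "patch1": self.patch1,
            "patch2": self.patch2,
            "patch3": self.patch3,
            "flank": self.flank,
        }

    def patch_of(self, author_seq_id: int) -> str | None:
        for label, members in self.patches().items():
            if author_seq_id in members:
                return label
        return None

    @classmethod
    def default(cls) -> "BindingSiteDef":
        return cls(
            patch1=frozenset({178, 197, 222, 225, 228}),
            patch2=frozenset({284, 287}),
            patch3=frozenset({340}),
            flank=frozenset({337, 343}),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _coor_format(fmt: str) -> gemmi.CoorFormat:
    return {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[fmt]


def read_structure(
    path: str | Path,
    format: str = "auto",
    receptor_chain: str | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file (optionally gzipped) into a StructureModel.

    Only the first model of multi-model files is kept; for alternate
    locations the first altloc wins; waters are dropped; insertion codes
    are rejected (prediction outputs do not use them).  When
    ``receptor_chain`` is given, or when the file has exactly two chains,
    chain roles are assigned (default: first chain = receptor).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format))
    except Exception as exc:  # gemmi raises RuntimeError with record context
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    gmodel = st[0]

    model = StructureModel()
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name in _SOLVENT:
                continue
            icode = gres.seqid.icode
            if icode not in (" ", "", "\0"):
                raise StructureParseError(
                    f"{path}: insertion code {icode!r} on {gchain.name}/"
                    f"{gres.seqid.num} is unsupported"
                )
            residue = Residue(
                author_seq_id=gres.seqid.num,
                name=gres.name,
                het=gres.het_flag == "H",
            )
            seen_names: set[str] = set()
            for gatom in gres:
                if gatom.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(gatom.name)
                residue.atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        b_factor=gatom.b_iso,
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise StructureParseError(f"{path}: no polymer chains with atoms")
    model.validate()
    if receptor_chain is not None or len(model.chains) == 2:
        model.assign_roles(receptor=receptor_chain)
    return model


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> None:
    """Write a StructureModel as PDB or mmCIF (gzipped if path ends in .gz)."""
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    if not model.chains or any(not c.residues for c in model.chains):
        raise ValueError("refusing to write a model with empty chains")
    model.validate()  # raises on non-finite coordinates

    st = gemmi.Structure()
    st.name = "helixscreen"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.author_seq_id, " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.b_iso = atom.b_factor
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()

    if format == "pdb":
        text = st.make_pdb_string()
    else:
        text = st.make_mmcif_document().as_string()
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def _load_json(path: Path) -> dict:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return json.load(fh)


def _extract_pae(data: dict) -> np.ndarray | None:
    # Two common server dialects: a top-level "predicted_aligned_error"
    # matrix, or the legacy "pae" key (possibly nested one level down).
    if "predicted_aligned_error" in data:
        return np.asarray(data["predicted_aligned_error"], dtype=float)
    if "pae" in data:
        return np.asarray(data["pae"], dtype=float)
    for value in data.values():
        if isinstance(value, dict):
            found = _extract_pae(value)
            if found is not None:
                return found
    return None


def read_confidence(
    source: str | Path | StructureModel,
    dialect: str = "scores_json",
    structure: StructureModel | None = None,
    receptor_first: bool = False,
) -> ConfidenceData:
    """Load confidence data in one of two dialects.

    ``scores_json``
        ``source`` is a JSON path with a per-residue ``plddt`` array and a
        square PAE matrix (``predicted_aligned_error`` or legacy ``pae``
        key); ``structure`` supplies the residue identities that label
        matrix indices, in file order (or receptor chain first when
        ``receptor_first`` is set).
    ``bfactor_plddt``
        ``source`` is a StructureModel whose B-factor column stores pLDDT;
        each residue's value is taken from its first atom.  No PAE.
    """
    if dialect == "bfactor_plddt":
        if not isinstance(source, StructureModel):
            source = read_structure(source)
        order = source.residue_order(receptor_first=receptor_first)
        lookup = {
            (c.id, r.author_seq_id): r.atoms[0].b_factor
            for c in source.chains
            for r in c.residues
        }
        plddt = [lookup[key] for key in order]
        index_map = {key: i for i, key in enumerate(order)}
        return ConfidenceData(plddt, None, index_map)

    if dialect != "scores_json":
        raise ValueError(f"unknown confidence dialect {dialect!r}")
    if isinstance(source, StructureModel):
        raise ConfidenceError("scores_json dialect needs a JSON file path")
    if structure is None:
        raise ConfidenceError(
            "scores_json dialect needs the structure to map matrix indices "
            "onto residues"
        )
    data = _load_json(Path(source))
    if "plddt" not in data:
        raise ConfidenceError("scores JSON has no 'plddt' array")
    plddt = np.asarray(data["plddt"], dtype=float)
    pae = _extract_pae(data)
    if pae is None:
        raise ConfidenceError(
            "scores JSON has neither 'predicted_aligned_error' nor 'pae'"
        )
    order = structure.residue_order(receptor_first=receptor_first)
    if len(order) != len(plddt):
        raise ConfidenceError(
            f"structure has {len(order)} residues but scores file has "
            f"{len(plddt)} pLDDT values"
        )
    index_map = {key: i for i, key in enumerate(order)}
    return ConfidenceData(plddt, pae, index_map)
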