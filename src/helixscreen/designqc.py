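"""Quality control for designed binders: superposition RMSD and mean pLDDT.

A refolded design is compared with its template two ways: the mean pLDDT
of the binder residues (designs must exceed 90 to pass) and the C-alpha
RMSD of the binder after superposing the two models on the receptor
chain, so the value reflects both the binder fold and its pose on the
receptor.  A fold-only mode superposes on the binder itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .model_io import ConfidenceData, StructureModel

__all__ = ["DesignQCReport", "kabsch", "superpose_rmsd", "design_metrics"]

_SELECTIONS = {
    "ca": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
    "all": None,
}


@dataclass(frozen=True)
class DesignQCReport:
    rmsd: float  # A
    n_atoms_matched: int
    selection: str
    binder_mean_plddt: float | None = None
    passed: bool | None = None
    degenerate: bool = False


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising ||R P + t - Q||.

    Reflections are excluded by flipping the sign of the smallest singular
    vector when needed, so R is always a rotation (det = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _matched_coords(
    reference: StructureModel,
    mobile: StructureModel,
    selection: str,
    chain_map: dict[str, str] | None,
    chains: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if selection not in _SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; use ca|backbone|all")
    wanted = _SELECTIONS[selection]
    if chain_map is None:
        chain_map = {c.id: c.id for c in reference.chains}
    ref_pts, mob_pts = [], []
    for ref_chain in reference.chains:
        if chains is not None and ref_chain.id not in chains:
            continue
        mob_chain_id = chain_map.get(ref_chain.id)
        if mob_chain_id is None:
            continue
        try:
            mob_chain = mobile.chain(mob_chain_id)
        except KeyError:
            continue
        mob_res = {r.author_seq_id: r for r in mob_chain.residues}
        for res in ref_chain.residues:
            other = mob_res.get(res.author_seq_id)
            if other is None:
                continue
            for atom in res.atoms:
                if wanted is not None and atom.name not in wanted:
                    continue
                counterpart = other.atom(atom.name)
                if counterpart is None:
                    continue
                ref_pts.append(atom.position)
                mob_pts.append(counterpart.position)
    return np.asarray(ref_pts, dtype=float), np.asarray(mob_pts, dtype=float)


def _is_degenerate(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 2


def superpose_rmsd(
    reference: StructureModel,
    mobile: StructureModel,
    selection: str = "ca",
    chain_map: dict[str, str] | None = None,
) -> DesignQCReport:
    """Least-squares rigid superposition RMSD over matched atoms.

    Atoms correspond by (chain via chain_map, author_seq_id, atom name);
    at least 3 matches are required.  Collinear reference coordinates are
    computed anyway but flagged ``degenerate``.
    """
    ref, mob = _matched_coords(reference, mobile, selection, chain_map)
    if len(ref) < 3:
        raise GeometryError(
            f"only {len(ref)} matched atoms; superposition needs at least 3"
        )
    R, t = kabsch(mob, ref)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return DesignQCReport(
        rmsd=rmsd,
        n_atoms_matched=len(ref),
        selection=selection,
        degenerate=_is_degenerate(ref),
    )


def design_metrics(
    refolded: StructureModel,
    conf: ConfidenceData,
    template: StructureModel,
    binder_chain: str,
    plddt_min: float = 90.0,
    selection: str = "ca",
    mode: str = "pose",
    chain_map: dict[str, str] | None = None,
) -> DesignQCReport:
    """Refolding QC: binder mean pLDDT and template-vs-refold RMSD.

    ``mode='pose'`` (default) superposes the models on the receptor chain
    and measures the binder RMSD without refitting, so a correct fold
    docked in the wrong place scores poorly; ``mode='fold'`` superposes on
    the binder itself.  ``passed`` requires mean binder pLDDT strictly
    above ``plddt_min``.
    """
    if conf is None:
        raise ValueError("design_metrics requires confidence data for the refold")
    binder = refolded.chain(binder_chain)
    plddt_vals = [conf.plddt_of(binder_chain, r.author_seq_id) for r in binder.residues]
    mean_plddt = float(np.mean(plddt_vals))

    if mode == "fold":
        bind_ref, bind_mob = _matched_coords(
            template, refolded, selection, chain_map, chains=[binder_chain]
        )
        if len(bind_ref) < 3:
            raise GeometryError("fewer than 3 binder atoms matched for superposition")
        R, t = kabsch(bind_mob, bind_ref)
        moved = bind_mob @ R.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((moved - bind_ref) ** 2, axis=1))))
        n_matched = len(bind_ref)
        degenerate = _is_degenerate(bind_ref)
    elif mode == "pose":
        receptor_chains = [
            c.id for c in template.chains if c.id != binder_chain
        ]
        if not receptor_chains:
            raise GeometryError("pose mode needs a receptor chain to superpose on")
        rec_ref, rec_mob = _matched_coords(
            template, refolded, selection, chain_map, chains=receptor_chains
        )
        if len(rec_ref) < 3:
            raise GeometryError("fewer than 3 receptor atoms matched for superposition")
        R, t = kabsch(rec_mob, rec_ref)
        bind_ref, bind_mob = _matched_coords(
            template, refolded, selection, chain_map, chains=[binder_chain]
        )
        if len(bind_ref) == 0:
            raise GeometryError("no binder atoms matched between template and refold")
        moved = bind_mob @ R.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((moved - bind_ref) ** 2, axis=1))))
        n_matched = len(bind_ref)
        degenerate = _is_degenerate(rec_ref)
    else:
        raise ValueError(f"unknown mode {mode!r}; use pose|fold")

    return DesignQCReport(
        rmsd=rmsd,
        n_atoms_matched=n_matched,
        selection=selection,
        binder_mean_plddt=mean_plddt,
        passed=mean_plddt > plddt_min,
        degenerate=degenerate,
    )
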