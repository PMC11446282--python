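"""Two-stage interface-residue detection between receptor and binder chains.

The detection follows the screening procedure used for predicted
receptor-helix complexes: a fast prefilter keeps residue pairs whose
representative (C-beta) coordinates lie within 8 A, then an all-atom pass
keeps pairs with any atom-atom distance at or below 4 A.  The receptor
side may be restricted to a conserved binding-site definition before the
prefilter, and residues with pLDDT below 50 are removed from the final
interface.  An exhaustive single-stage variant serves as an oracle for the
prefilter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import GeometryError
from .model_io import BindingSiteDef, ConfidenceData, Residue, StructureModel

__all__ = [
    "ResidueId",
    "InterfaceParams",
    "InterfaceMap",
    "representative_coordinate",
    "interface_residues",
    "interface_residues_exhaustive",
    "compare_maps",
    "interface_table",
    "write_pairs_tsv",
]

ResidueId = tuple[str, int]  # (chain id, author_seq_id)
Pair = tuple[ResidueId, ResidueId]  # (binder residue, receptor residue)


@dataclass(frozen=True)
class InterfaceParams:
    prefilter_cutoff: float  # A; inf for the exhaustive variant
    atomic_cutoff: float  # A
    plddt_min: float | None  # None when no confidence filtering applied
    site_restricted: bool


@dataclass
class InterfaceMap:
    """Contact pairs surviving distance detection and confidence exclusion.

    ``pairs`` holds (binder residue, receptor residue) identities;
    ``min_distances`` the closest atom-atom distance per pair (A) and
    ``atom_contact_counts`` the number of atom pairs at or below the atomic
    cutoff, both useful for downstream register assignment and export.
    """

    pairs: frozenset[Pair]
    excluded_low_plddt: frozenset[ResidueId]
    params: InterfaceParams
    min_distances: dict[Pair, float] = field(default_factory=dict)
    atom_contact_counts: dict[Pair, int] = field(default_factory=dict)

    @property
    def binder_iface(self) -> frozenset[ResidueId]:
        return frozenset(b for b, _ in self.pairs)

    @property
    def receptor_iface(self) -> frozenset[ResidueId]:
        return frozenset(r for _, r in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def representative_coordinate(residue: Residue, fallback: bool = True) -> np.ndarray:
    """Representative position for the distance prefilter.

    C-beta when present; C-alpha for glycine; with ``fallback`` enabled the
    first atom of residues lacking both (e.g. stripped side chains).
    """
    cb = residue.atom("CB")
    if cb is not None:
        return cb.position
    if residue.name == "GLY":
        ca = residue.atom("CA")
        if ca is not None:
            return ca.position
    if fallback and residue.atoms:
        return residue.atoms[0].position
    raise GeometryError(
        f"residue {residue.name} {residue.author_seq_id} has no representative "
        "atom (no CB, not glycine with CA, fallback disabled)"
    )


def _eligible(
    model: StructureModel, site: BindingSiteDef | None
) -> tuple[list[tuple[ResidueId, Residue]], list[tuple[ResidueId, Residue]]]:
    binder = model.binder
    receptor = model.receptor
    binder_res = [((binder.id, r.author_seq_id), r) for r in binder.residues if not r.het]
    receptor_res = [((receptor.id, r.author_seq_id), r) for r in receptor.residues if not r.het]
    if site is not None:
        if not site.site:
            raise ValueError("binding-site definition is empty")
        receptor_res = [(rid, r) for rid, r in receptor_res if rid[1] in site.site]
    return binder_res, receptor_res


def _atomic_stage(
    candidates: list[tuple[tuple[ResidueId, Residue], tuple[ResidueId, Residue]]],
    atomic_cutoff: float,
) -> tuple[set[Pair], dict[Pair, float], dict[Pair, int]]:
    pairs: set[Pair] = set()
    min_d: dict[Pair, float] = {}
    counts: dict[Pair, int] = {}
    for (bid, bres), (rid, rres) in candidates:
        d = cdist(bres.coords(), rres.coords())
        dmin = float(d.min())
        if dmin <= atomic_cutoff:
            key = (bid, rid)
            pairs.add(key)
            min_d[key] = dmin
            counts[key] = int((d <= atomic_cutoff).sum())
    return pairs, min_d, counts


def _apply_plddt_exclusion(
    pairs: set[Pair],
    conf: ConfidenceData,
    plddt_min: float,
    receptor_side: bool,
) -> tuple[set[Pair], set[ResidueId]]:
    involved = {rid for pair in pairs for rid in pair}
    low = set()
    for rid in involved:
        if conf.plddt_of(*rid) < plddt_min:
            low.add(rid)
    if not receptor_side:
        binder_side = {b for b, _ in pairs}
        low = {rid for rid in low if rid in binder_side}
    kept = {(b, r) for (b, r) in pairs if b not in low and r not in low}
    return kept, low


def interface_residues(
    model: StructureModel,
    conf: ConfidenceData | None = None,
    site: BindingSiteDef | None = None,
    prefilter_cutoff: float = 8.0,
    atomic_cutoff: float = 4.0,
    plddt_min: float = 50.0,
    receptor_side_exclusion: bool = True,
    fallback_representative: bool = True,
) -> InterfaceMap:
    """Two-stage interface detection.

    Stage 1 keeps residue pairs whose representative coordinates are within
    ``prefilter_cutoff`` (inclusive); stage 2 keeps those with any
    atom-atom distance <= ``atomic_cutoff`` (all atoms present in the file,
    hydrogens included if any).  With ``site`` given the receptor side is
    restricted to site members before stage 1; with ``conf`` given,
    residues with pLDDT below ``plddt_min`` are removed from the resulting
    pairs (both sides by default; ``receptor_side_exclusion=False`` limits
    the removal to binder residues).
    """
    binder_res, receptor_res = _eligible(model, site)
    if binder_res and receptor_res:
        brep = np.array(
            [representative_coordinate(r, fallback_representative) for _, r in binder_res]
        )
        rrep = np.array(
            [representative_coordinate(r, fallback_representative) for _, r in receptor_res]
        )
        close = cdist(brep, rrep) <= prefilter_cutoff
        candidates = [
            (binder_res[i], receptor_res[j]) for i, j in zip(*np.nonzero(close))
        ]
    else:
        candidates = []
    pairs, min_d, counts = _atomic_stage(candidates, atomic_cutoff)

    excluded: set[ResidueId] = set()
    if conf is not None:
        pairs, excluded = _apply_plddt_exclusion(
            pairs, conf, plddt_min, receptor_side_exclusion
        )
    params = InterfaceParams(
        prefilter_cutoff=prefilter_cutoff,
        atomic_cutoff=atomic_cutoff,
        plddt_min=plddt_min if conf is not None else None,
        site_restricted=site is not None,
    )
    return InterfaceMap(
        pairs=frozenset(pairs),
        excluded_low_plddt=frozenset(excluded),
        params=params,
        min_distances={k: v for k, v in min_d.items() if k in pairs},
        atom_contact_counts={k: v for k, v in counts.items() if k in pairs},
    )


def interface_residues_exhaustive(
    model: StructureModel,
    conf: ConfidenceData | None = None,
    site: BindingSiteDef | None = None,
    atomic_cutoff: float = 4.0,
    plddt_min: float = 50.0,
    receptor_side_exclusion: bool = True,
) -> InterfaceMap:
    """Single-stage all-atom all-pairs oracle (no C-beta prefilter)."""
    binder_res, receptor_res = _eligible(model, site)
    candidates = [(b, r) for b in binder_res for r in receptor_res]
    pairs, min_d, counts = _atomic_stage(candidates, atomic_cutoff)
    excluded: set[ResidueId] = set()
    if conf is not None:
        pairs, excluded = _apply_plddt_exclusion(
            pairs, conf, plddt_min, receptor_side_exclusion
        )
    params = InterfaceParams(
        prefilter_cutoff=float("inf"),
        atomic_cutoff=atomic_cutoff,
        plddt_min=plddt_min if conf is not None else None,
        site_restricted=site is not None,
    )
    return InterfaceMap(
        pairs=frozenset(pairs),
        excluded_low_plddt=frozenset(excluded),
        params=params,
        min_distances={k: v for k, v in min_d.items() if k in pairs},
        atom_contact_counts={k: v for k, v in counts.items() if k in pairs},
    )


def coverage_condition_holds(
    model: StructureModel,
    site: BindingSiteDef | None = None,
    prefilter_cutoff: float = 8.0,
    atomic_cutoff: float = 4.0,
    fallback_representative: bool = True,
) -> bool:
    """Sufficient condition for two-stage/exhaustive equality.

    If for every cross-chain residue pair the spreads r_A, r_B (maximum
    atom distance from the representative coordinate) satisfy
    r_A + r_B <= prefilter - atomic, any atomic contact at <= atomic
    implies representative distance <= prefilter, so the prefilter cannot
    drop a true contact.  Checked here with per-chain maxima.
    """
    binder_res, receptor_res = _eligible(model, site)

    def spread(entries) -> float:
        worst = 0.0
        for _, res in entries:
            rep = representative_coordinate(res, fallback_representative)
            worst = max(worst, float(np.linalg.norm(res.coords() - rep, axis=1).max()))
        return worst

    if not binder_res or not receptor_res:
        return True
    return spread(binder_res) + spread(receptor_res) <= prefilter_cutoff - atomic_cutoff


def compare_maps(two_stage: InterfaceMap, exhaustive: InterfaceMap) -> dict[str, frozenset[Pair]]:
    """Report pairs found by one route and not the other."""
    return {
        "missed_by_prefilter": exhaustive.pairs - two_stage.pairs,
        "extra_in_two_stage": two_stage.pairs - exhaustive.pairs,
    }


def interface_table(iface: InterfaceMap) -> pd.DataFrame:
    rows = [
        {
            "binder_chain": b[0],
            "binder_resid": b[1],
            "receptor_chain": r[0],
            "receptor_resid": r[1],
            "min_atom_distance": iface.min_distances.get((b, r), float("nan")),
        }
        for b, r in sorted(iface.pairs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "binder_chain",
            "binder_resid",
            "receptor_chain",
            "receptor_resid",
            "min_atom_distance",
        ],
    )


def write_pairs_tsv(iface: InterfaceMap, path: str | Path) -> None:
    interface_table(iface).to_csv(path, sep="\t", index=False, float_format="%.3f")
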