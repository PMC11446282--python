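"""Interface confidence metrics and the screening rule.

Two metrics summarise a predicted complex: the mean pLDDT over the
binder's interface residues (ipLDDT) and the median predicted aligned
error over the binder-rows x receptor-columns interface submatrix
(iPAE).  Models whose interface shrinks to seven residues or fewer after
the low-pLDDT exclusion get the sentinel values (ipLDDT = 0, iPAE = 30)
and can never pass.  The screen keeps models with iPAE < 10 and
ipLDDT > 70, both strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .interface import InterfaceMap, interface_residues
from .model_io import BindingSiteDef, ConfidenceData, read_confidence, read_structure

__all__ = [
    "SENTINEL_IPLDDT",
    "SENTINEL_IPAE",
    "ConfidenceReport",
    "score_model",
    "apply_screen",
    "screen_manifest",
]

log = logging.getLogger(__name__)

SENTINEL_IPLDDT = 0.0
SENTINEL_IPAE = 30.0


@dataclass(frozen=True)
class ConfidenceReport:
    n_binder_iface: int
    iplddt: float
    ipae_median: float
    sentinel: bool
    passed: bool = False
    min_iface: int = 7
    ipae_max: float | None = None
    iplddt_min: float | None = None

    def __post_init__(self) -> None:
        if self.sentinel != (
            self.iplddt == SENTINEL_IPLDDT and self.ipae_median == SENTINEL_IPAE
        ):
            raise ValueError("sentinel flag inconsistent with sentinel values")
        if self.passed and self.sentinel:
            raise ValueError("a sentinel report cannot pass the screen")
        if not 0.0 <= self.iplddt <= 100.0 or self.ipae_median < 0:
            raise ValueError("metric out of range")


def score_model(
    iface: InterfaceMap,
    conf: ConfidenceData,
    min_iface: int = 7,
    symmetrize: bool = False,
) -> ConfidenceReport:
    """Compute ipLDDT and median iPAE for one interface.

    Requires strictly more than ``min_iface`` binder-side interface
    residues (i.e. >= 8 with the default); otherwise the sentinel report
    (ipLDDT 0, iPAE 30) is returned with ``passed=False``.  The iPAE
    median is taken over the binder-rows x receptor-columns block only,
    unless ``symmetrize`` also pools the transposed block.
    """
    conf.require_pae()
    binder = sorted(iface.binder_iface)
    receptor = sorted(iface.receptor_iface)
    if len(binder) <= min_iface:
        return ConfidenceReport(
            n_binder_iface=len(binder),
            iplddt=SENTINEL_IPLDDT,
            ipae_median=SENTINEL_IPAE,
            sentinel=True,
            passed=False,
            min_iface=min_iface,
        )
    plddt_vals = [conf.plddt_of(*rid) for rid in binder]
    block = conf.pae_block(binder, receptor)
    values = block.ravel()
    if symmetrize:
        values = np.concatenate([values, conf.pae_block(receptor, binder).ravel()])
    return ConfidenceReport(
        n_binder_iface=len(binder),
        iplddt=float(np.mean(plddt_vals)),
        ipae_median=float(np.median(values)),
        sentinel=False,
        passed=False,
        min_iface=min_iface,
    )


def apply_screen(
    report: ConfidenceReport,
    ipae_max: float = 10.0,
    iplddt_min: float = 70.0,
) -> ConfidenceReport:
    """Set the screen verdict: iPAE < ipae_max and ipLDDT > iplddt_min, strict."""
    passed = (
        not report.sentinel
        and report.ipae_median < ipae_max
        and report.iplddt > iplddt_min
    )
    return replace(report, passed=passed, ipae_max=ipae_max, iplddt_min=iplddt_min)


def screen_manifest(
    manifest: str | Path | pd.DataFrame,
    site: BindingSiteDef | None = None,
    prefilter_cutoff: float = 8.0,
    atomic_cutoff: float = 4.0,
    plddt_min: float = 50.0,
    min_iface: int = 7,
    ipae_max: float = 10.0,
    iplddt_min: float = 70.0,
) -> pd.DataFrame:
    """Score every model of a manifest and apply the screen.

    The manifest (CSV path or DataFrame) has columns ``model`` and
    ``confidence`` plus optional ``receptor_chain``.  Unreadable rows are
    marked errored and the run continues.
    """
    if site is None:
        site = BindingSiteDef.default()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        log.warning("empty manifest: no models to screen")
    rows = []
    for _, entry in manifest.iterrows():
        record = {
            "model": entry["model"],
            "n_iface": np.nan,
            "iplddt": np.nan,
            "ipae_median": np.nan,
            "sentinel": pd.NA,
            "passed": pd.NA,
            "error": "",
        }
        try:
            receptor_chain = entry.get("receptor_chain")
            if receptor_chain is None or pd.isna(receptor_chain):
                receptor_chain = None
            model = read_structure(entry["model"], receptor_chain=receptor_chain)
            conf = read_confidence(entry["confidence"], "scores_json", structure=model)
            iface = interface_residues(
                model,
                conf=conf,
                site=site,
                prefilter_cutoff=prefilter_cutoff,
                atomic_cutoff=atomic_cutoff,
                plddt_min=plddt_min,
            )
            report = apply_screen(
                score_model(iface, conf, min_iface=min_iface),
                ipae_max=ipae_max,
                iplddt_min=iplddt_min,
            )
            record.update(
                n_iface=report.n_binder_iface,
                iplddt=report.iplddt,
                ipae_median=report.ipae_median,
                sentinel=report.sentinel,
                passed=report.passed,
            )
            log.info(
                "%s: n_iface=%d ipLDDT=%.2f iPAE=%.2f passed=%s",
                entry["model"],
                report.n_binder_iface,
                report.iplddt,
                report.ipae_median,
                report.passed,
            )
        except Exception as exc:
            record["error"] = str(exc)
            log.error("%s: %s", entry["model"], exc)
        rows.append(record)
    return pd.DataFrame(
        rows,
        columns=["model", "n_iface", "iplddt", "ipae_median", "sentinel", "passed", "error"],
    )
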