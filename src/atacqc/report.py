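"""QC report assembly: the hotspot-count / PRC / TSS-score / %mito quartet."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .core import GeneModelRecord
from .cutsites import CutSites, mito_fraction
from .hotspots import HotspotSet, concordant_hotspots
from .io import AlignmentScan, DEFAULT_MITO_NAMES
from .prc import ReferencePeakSet, prc
from .tss import tss_aggregate, tss_score, tss_sites


class StageError(RuntimeError):
    """Wraps an error with the name of the QC stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class QCReport:
    """The four headline QC numbers plus full provenance."""

    hotspot_count: int
    prc_percent: float
    tss_score: float
    mito_percent: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.prc_percent <= 100):
            raise ValueError("prc_percent must be in [0, 100]")
        if not (0 <= self.mito_percent <= 100):
            raise ValueError("mito_percent must be in [0, 100]")
        if self.hotspot_count < 0:
            raise ValueError("hotspot_count must be >= 0")

    def to_dict(self) -> dict:
        return {
            "hotspot_count": self.hotspot_count,
            "prc_percent": self.prc_percent,
            "tss_score": self.tss_score,
            "mito_percent": self.mito_percent,
            "provenance": self.provenance,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"hotspot_count\t{self.hotspot_count}\n")
            fh.write(f"prc_percent\t{self.prc_percent:.6g}\n")
            fh.write(f"tss_score\t{self.tss_score:.6g}\n")
            fh.write(f"mito_percent\t{self.mito_percent:.6g}\n")


def run_qc(
    scan: AlignmentScan,
    pooled_peaks: HotspotSet,
    replicate_peaks: Sequence[HotspotSet],
    reference: ReferencePeakSet,
    gene_model: Sequence[GeneModelRecord],
    tss_halfwidth: int = 2000,
    min_overlap_frac: float = 0.5,
    mito_names: frozenset[str] = DEFAULT_MITO_NAMES,
    inputs: dict | None = None,
    seed: int | None = None,
) -> QCReport:
    """Compose the full QC pipeline on parsed inputs.

    Any stage failure propagates as :class:`StageError` naming the stage.
    """
    try:
        mito = mito_fraction(scan.contig_tallies, mito_names)
    except Exception as exc:
        raise StageError("mito_fraction", exc) from exc
    try:
        cuts, dropped = CutSites.from_fragments(scan.fragments)
    except Exception as exc:
        raise StageError("tn5_shift", exc) from exc
    try:
        hotspots = concordant_hotspots(pooled_peaks, replicate_peaks, min_overlap_frac)
    except Exception as exc:
        raise StageError("concordant_hotspots", exc) from exc
    try:
        prc_value = prc(hotspots, reference)
    except Exception as exc:
        raise StageError("prc", exc) from exc
    try:
        agg = tss_aggregate(cuts, tss_sites(gene_model), halfwidth=tss_halfwidth)
        score = tss_score(agg)
    except Exception as exc:
        raise StageError("tss_score", exc) from exc

    provenance = {
        "tool": "atacqc",
        "version": __version__,
        "seed": seed,
        "inputs": inputs or {},
        "parameters": {
            "tss_halfwidth": tss_halfwidth,
            "min_overlap_frac": min_overlap_frac,
            "mito_names": sorted(mito_names),
            "reference_n_source_sets": reference.n_source_sets,
            "reference_presence_threshold": reference.presence_threshold,
        },
        "n_fragments": len(scan.fragments),
        "n_cut_sites": len(cuts),
        "n_cut_sites_dropped": dropped,
    }
    return QCReport(
        hotspot_count=len(hotspots),
        prc_percent=prc_value,
        tss_score=score,
        mito_percent=mito,
        provenance=provenance,
    )
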