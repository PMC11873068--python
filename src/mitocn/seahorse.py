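"""Mito-Stress-Test respiration metrics from oxygen-consumption traces.

The assay measures the oxygen consumption rate (OCR) of a well at ~3-minute
increments through four drug phases: baseline, after oligomycin (ATP-synthase
block), after FCCP (uncoupling) and after rotenone/antimycin-A (electron
transport shutdown).  Metric point rules follow the instrument vendor's
convention: last basal measurement, minimum post-oligomycin, maximum
post-FCCP, mean post-rotenone/antimycin.

    non_mito     = mean(rot/AA phase)
    basal        = last(basal phase) - non_mito
    atp_linked   = last(basal phase) - min(oligo phase)
    proton_leak  = min(oligo phase) - non_mito
    maximal      = max(FCCP phase) - non_mito

so basal = atp_linked + proton_leak holds exactly by construction.  Cells
whose FCCP response stays below basal (seen in some smooth-muscle lines) are
still quantified, with a ``sub_basal_maximal`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .synthgen import OCRTrace

__all__ = ["OCRMetrics", "ocr_metrics", "normalize_per_cell", "OCRTrace"]

METRIC_NAMES = ("non_mito", "basal", "atp_linked", "proton_leak", "maximal")


@dataclass
class OCRMetrics:
    """Respiration metrics in pmol O2/min/well (or per cell after division)."""

    non_mito: float
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    per_cell: bool = False
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def summary(self) -> str:
        unit = "pmol O2/min/cell" if self.per_cell else "pmol O2/min/well"
        body = "\n".join(f"{n:<12} {v:12.4g}" for n, v in self.as_dict().items())
        return (f"Mito Stress Test metrics ({unit})\n"
                f"{'=' * 40}\n{body}"
                + (f"\nflags: {'; '.join(self.flags)}" if self.flags else ""))


def ocr_metrics(trace: OCRTrace) -> OCRMetrics:
    """Extract the five Mito-Stress metrics from a four-phase OCR trace."""
    phases = trace.phases()
    for name, mask in phases.items():
        if mask.sum() < 3:
            raise ValueError(f"phase {name!r} has fewer than 3 measurements")
    if not (trace.t_oligo < trace.t_fccp < trace.t_rot_aa):
        raise ValueError("injections must be strictly ordered oligo < FCCP < rot/AA")
    ocr = trace.ocr
    non_mito = float(ocr[phases["rot_aa"]].mean())
    last_basal = float(ocr[phases["basal"]][-1])
    min_oligo = float(ocr[phases["oligo"]].min())
    max_fccp = float(ocr[phases["fccp"]].max())
    flags = []
    if max_fccp < last_basal:
        flags.append("sub-basal maximal response to FCCP")
    return OCRMetrics(
        non_mito=non_mito,
        basal=last_basal - non_mito,
        atp_linked=last_basal - min_oligo,
        proton_leak=min_oligo - non_mito,
        maximal=max_fccp - non_mito,
        flags=flags)


def normalize_per_cell(metrics: OCRMetrics, n_cells: int) -> OCRMetrics:
    """Divide every metric by the imaged nuclear count of the well."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    return replace(
        metrics,
        **{name: getattr(metrics, name) / n_cells for name in METRIC_NAMES},
        per_cell=True)
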