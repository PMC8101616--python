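"""Principal-strain field statistics per volume of interest.

Per-element strain tensors are reduced to the outcome measures used to
characterise the loading environment of the tibia: maximum (tensile) and
minimum (compressive) principal strains, the absolute principal strain (the
larger-magnitude of the two), 95th-percentile "peak" strains per VOI (the
order-statistic cutoff that discards anomalous high-strain elements), VOI
means, a binned strain-volume histogram (150-ue bins from 0 to 3000 ue plus
an overflow bin), and the fraction of VOI bone volume above an absolute
principal strain threshold (default 1500 ue).

All strains are reported in microstrain (ue); peak/mean compressive values
are negative by convention.  Element statistics are equal-weighted: voxel
elements have identical volumes, so element-count weighting and
volume-weighting coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .microfe import DisplacementField, FEMesh, element_strains
from .volumes import BoneMask

__all__ = [
    "StrainField",
    "VOIStrainSummary",
    "principal_strains",
    "strain_field_from_solution",
    "voi_strain_summary",
    "scale_summary",
    "summary_from_values",
    "HIST_BIN_WIDTH",
    "HIST_MAX",
    "ABS_THRESHOLD",
]

HIST_BIN_WIDTH = 150.0  # ue; 5% of 3000 ue
HIST_MAX = 3000.0  # ue
ABS_THRESHOLD = 1500.0  # ue


def _voigt_to_tensor(voigt: np.ndarray) -> np.ndarray:
    """(n, 6) Voigt (engineering shears) -> (n, 3, 3) symmetric tensors."""
    v = np.atleast_2d(voigt)
    t = np.zeros((len(v), 3, 3))
    t[:, 0, 0] = v[:, 0]
    t[:, 1, 1] = v[:, 1]
    t[:, 2, 2] = v[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = v[:, 3] / 2.0
    t[:, 1, 2] = t[:, 2, 1] = v[:, 4] / 2.0
    t[:, 0, 2] = t[:, 2, 0] = v[:, 5] / 2.0
    return t


def principal_strains(tensor: np.ndarray) -> np.ndarray:
    """Principal strains of symmetric tensor(s), descending (e1 >= e2 >= e3).

    Accepts a single (3, 3) tensor or a stack (n, 3, 3); returns (3,) or
    (n, 3).  Non-symmetric input is rejected.
    """
    t = np.asarray(tensor, dtype=np.float64)
    single = t.ndim == 2
    if single:
        t = t[None]
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    if not np.allclose(t, np.swapaxes(t, -1, -2), rtol=1e-9, atol=1e-12 * max(1.0, float(np.abs(t).max()))):
        raise ValueError("strain tensor must be symmetric")
    vals = np.linalg.eigvalsh(t)[..., ::-1]
    return vals[0] if single else vals


@dataclass
class StrainField:
    """Per-element strains of a solved model, in microstrain.

    ``voigt``: (n, 6) tensor components (exx, eyy, ezz, gxy, gyz, gxz) with
    engineering shears; ``principal``: (n, 3) descending principal strains;
    ``abs_principal``: (n,) max(|e1|, |e3|).
    """

    voigt: np.ndarray
    principal: np.ndarray
    abs_principal: np.ndarray

    @classmethod
    def from_voigt(cls, voigt_ue: np.ndarray) -> "StrainField":
        p = principal_strains(_voigt_to_tensor(voigt_ue))
        return cls(
            voigt=np.atleast_2d(voigt_ue),
            principal=p,
            abs_principal=np.maximum(np.abs(p[:, 0]), np.abs(p[:, 2])),
        )


def strain_field_from_solution(mesh: FEMesh, disp: DisplacementField) -> StrainField:
    """Centroid strain tensors of every element, converted to microstrain."""
    return StrainField.from_voigt(element_strains(mesh, disp) * 1e6)


@dataclass
class VOIStrainSummary:
    """Strain outcome measures for one VOI at one applied load."""

    voi: str
    load: float  # N
    peak_tensile: float  # ue, 95th percentile of e1
    peak_compressive: float  # ue, negative; |.| is 95th percentile of |e3|
    mean_tensile: float  # ue
    mean_compressive: float  # ue, negative
    fraction_above: float  # % of VOI volume with abs principal > threshold
    histogram: np.ndarray  # % of volume per bin, length n_bins + 1 (overflow)
    bin_edges: np.ndarray  # ue, length n_bins + 1 (lower edges incl. overflow)
    n_elements: int
    percentile: float = 95.0
    abs_threshold: float = ABS_THRESHOLD
    n_unmeshed: int = 0
    abs_values: Optional[np.ndarray] = None  # raw per-element abs strains (ue)


def _histogram(abs_ue: np.ndarray, bin_width: float, top: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(abs_ue, bins=np.append(edges, np.inf))
    pct = 100.0 * counts / abs_ue.size
    return pct, edges


def voi_strain_summary(
    field: StrainField,
    voi: BoneMask,
    mesh: FEMesh,
    load: float,
    name: str = "voi",
    percentile: float = 95.0,
    bin_width: float = HIST_BIN_WIDTH,
    abs_threshold: float = ABS_THRESHOLD,
) -> VOIStrainSummary:
    """Summarise the strain field over the elements of a VOI.

    VOI bone voxels that were dropped from the mesh as disconnected floaters
    are excluded and counted in ``n_unmeshed`` (an error above 5% of the
    VOI).  Percentiles interpolate linearly between closest order statistics.
    """
    lut = mesh.element_lookup()
    lin = np.flatnonzero(voi.values.ravel())
    if lin.size == 0:
        raise ValueError("empty VOI")
    elem = lut[lin]
    missing = int((elem < 0).sum())
    if missing > 0.05 * lin.size:
        raise ValueError(
            f"{missing}/{lin.size} VOI bone voxels have no meshed element"
        )
    elem = elem[elem >= 0]

    e1 = field.principal[elem, 0]
    e3 = field.principal[elem, 2]
    abs_ue = field.abs_principal[elem]

    hist, edges = _histogram(abs_ue, bin_width, HIST_MAX)
    return VOIStrainSummary(
        voi=name,
        load=float(load),
        peak_tensile=float(np.percentile(e1, percentile)),
        peak_compressive=-float(np.percentile(np.abs(e3), percentile)),
        mean_tensile=float(e1.mean()),
        mean_compressive=float(e3.mean()),
        fraction_above=float(100.0 * (abs_ue > abs_threshold).mean()),
        histogram=hist,
        bin_edges=edges,
        n_elements=int(elem.size),
        percentile=percentile,
        abs_threshold=abs_threshold,
        n_unmeshed=missing,
        abs_values=abs_ue,
    )


def scale_summary(summary: VOIStrainSummary, load_ratio: float) -> VOIStrainSummary:
    """Rescale a summary by a load ratio, exploiting linear elasticity.

    All strain quantities scale by ``load_ratio``; the histogram and
    supra-threshold fraction are recomputed from the rescaled raw values when
    available (summaries built from printed peak/mean values alone keep their
    histogram as missing).
    """
    if not load_ratio > 0:
        raise ValueError("load_ratio must be > 0")
    abs_values = None if summary.abs_values is None else summary.abs_values * load_ratio
    if abs_values is not None:
        bw = float(summary.bin_edges[1] - summary.bin_edges[0]) if len(summary.bin_edges) > 1 else HIST_BIN_WIDTH
        hist, edges = _histogram(abs_values, bw, HIST_MAX)
        frac = float(100.0 * (abs_values > summary.abs_threshold).mean())
    else:
        hist, edges = summary.histogram, summary.bin_edges
        frac = float("nan")
    return replace(
        summary,
        load=summary.load * load_ratio,
        peak_tensile=summary.peak_tensile * load_ratio,
        peak_compressive=summary.peak_compressive * load_ratio,
        mean_tensile=summary.mean_tensile * load_ratio,
        mean_compressive=summary.mean_compressive * load_ratio,
        fraction_above=frac,
        histogram=hist,
        bin_edges=edges,
        abs_values=abs_values,
    )


def summary_from_values(
    voi: str,
    load: float,
    peak_tensile: float,
    peak_compressive: float,
    mean_tensile: float,
    mean_compressive: float,
) -> VOIStrainSummary:
    """Build a summary from reported peak/mean values (e.g. a published table)
    so that load-ratio scaling can be applied to printed numbers."""
    return VOIStrainSummary(
        voi=voi,
        load=load,
        peak_tensile=peak_tensile,
        peak_compressive=peak_compressive,
        mean_tensile=mean_tensile,
        mean_compressive=mean_compressive,
        fraction_above=float("nan"),
        histogram=np.array([]),
        bin_edges=np.array([]),
        n_elements=0,
    )
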