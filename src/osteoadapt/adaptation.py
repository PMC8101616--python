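"""Outcome analysis: histomorphometry indices, qPCR relative expression,
paired tests, and adaptive-strain-threshold (AST) identification.

The AST for a bone compartment is the peak tissue strain at the lowest
applied load level that produced a significant anabolic response (paired
loaded-vs-control test at alpha = 0.05), and is an *upper bound* on the true
threshold: the exact threshold lies between the peak strains of the highest
non-responding and the lowest responding load.

Dynamic histomorphometry follows ASBMR nomenclature: MS/BS (%), the
mineralizing fraction of bone surface; MAR (um/day), interlabel width over
the label interval (calcein at 10 and 4 days before euthanasia gives a
6-day interval); BFR/BS = MAR x MS/BS / 100 (um^3/um^2/day).

qPCR cycle thresholds are converted to relative expression 2^-dCt against a
housekeeping gene (Ager in the source protocol) and compared loaded vs
control by exact Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DynamicLabels",
    "HistomorphometryIndices",
    "AdaptationOutcome",
    "ASTReport",
    "histomorphometry_indices",
    "delta_ct",
    "paired_t",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "identify_ast",
    "outcomes_from_table",
    "synthetic_outcome_table",
    "DEFAULT_LABEL_INTERVAL_DAYS",
    "ALPHA",
]

#: Calcein label interval implied by injections 10 and 4 days pre-euthanasia.
DEFAULT_LABEL_INTERVAL_DAYS = 6.0
ALPHA = 0.05


@dataclass(frozen=True)
class DynamicLabels:
    """Raw fluorochrome label measures for one surface (um)."""

    sl_pm: float  # single-labelled perimeter
    dl_pm: float  # double-labelled perimeter
    bs: float  # total bone surface perimeter
    ir_l_wi: float  # mean interlabel width
    label_interval: float = DEFAULT_LABEL_INTERVAL_DAYS  # days

    def __post_init__(self) -> None:
        if min(self.sl_pm, self.dl_pm, self.bs, self.ir_l_wi) < 0:
            raise ValueError("label measures must be >= 0")
        if self.dl_pm + self.sl_pm > self.bs * (1 + 1e-12):
            raise ValueError("labelled perimeter exceeds total surface")
        if not self.label_interval > 0:
            raise ValueError("label_interval must be > 0")


@dataclass(frozen=True)
class HistomorphometryIndices:
    ms_bs: float  # mineralizing surface, %
    mar: float  # mineral apposition rate, um/day
    bfr_bs: float  # bone formation rate, um^3/um^2/day


def histomorphometry_indices(labels: DynamicLabels) -> HistomorphometryIndices:
    """ASBMR indices: MS/BS = (dL.Pm + sL.Pm/2)/BS x 100; MAR = Ir.L.Wi/interval;
    BFR/BS = MAR x MS/BS / 100."""
    if labels.bs == 0:
        raise ValueError("BS = 0: indices undefined")
    ms_bs = (labels.dl_pm + labels.sl_pm / 2.0) / labels.bs * 100.0
    mar = labels.ir_l_wi / labels.label_interval
    return HistomorphometryIndices(ms_bs=ms_bs, mar=mar, bfr_bs=mar * ms_bs / 100.0)


# ---------------------------------------------------------------------------
# qPCR


def delta_ct(table: pd.DataFrame, housekeeping: str = "Ager") -> pd.DataFrame:
    """Relative expression 2^-dCt per sample and gene.

    ``table`` is long-format with columns ``sample_id``, ``gene``, ``ct``
    (extra annotation columns pass through).  dCt = Ct_gene - Ct_housekeeping
    within each sample; samples missing the housekeeping gene are an error,
    genes missing for a sample simply yield no row (excluded pairwise
    downstream).
    """
    required = {"sample_id", "gene", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    hk = table[table["gene"] == housekeeping].set_index("sample_id")["ct"]
    missing = set(table["sample_id"]) - set(hk.index)
    if missing:
        raise ValueError(f"housekeeping gene {housekeeping!r} missing for samples {sorted(missing)}")
    out = table[table["gene"] != housekeeping].copy()
    out["dct"] = out["ct"].to_numpy() - hk.loc[out["sample_id"]].to_numpy()
    out["rel_expr"] = 2.0 ** (-out["dct"])
    return out


# ---------------------------------------------------------------------------
# Paired tests


def paired_t(loaded: Sequence[float], control: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t test; returns (t, p). Zero difference variance is
    degenerate and rejected."""
    x = np.asarray(loaded, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs equal-length samples with n >= 2")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(np.std(d, ddof=1), 0.0):
        raise ValueError("degenerate: zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks used."""
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    return w, ranks


def _exact_signed_rank_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating the 2^n equiprobable sign assignments.

    Implemented as a generating-function convolution over doubled ranks
    (midranks are half-integers), which enumerates the same distribution in
    polynomial time.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    loaded: Sequence[float], control: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank test, two-sided; returns (W+, p).

    Zeros are dropped (Wilcoxon convention), ties midranked.  For n <=
    ``exact_max_n`` nonzero differences the p-value is exact over all 2^n
    sign assignments; above that a normal approximation with tie correction
    is used.
    """
    x = np.asarray(loaded, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("wilcoxon_signed_rank needs equal-length samples")
    w, ranks = _signed_rank_statistic(x - y)
    n = ranks.size
    if n <= exact_max_n:
        return w, _exact_signed_rank_p(w, ranks)
    mean = n * (n + 1) / 4.0
    # variance via sum of squared midranks: exact under ties
    var = float(np.sum(ranks**2)) / 4.0
    z = (w - mean) / np.sqrt(var)
    return w, float(2.0 * stats.norm.sf(abs(z)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free groups)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u needs two non-empty groups")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# AST identification


@dataclass(frozen=True)
class AdaptationOutcome:
    """A loaded-vs-control comparison for one VOI, load group and measure."""

    voi: str
    load: float  # N (signed, compressive negative)
    measure: str
    p_value: float
    responded: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "responded", bool(self.p_value < ALPHA))


@dataclass(frozen=True)
class ASTReport:
    """Adaptive strain thresholds for one VOI.

    When no tested load responds, ``ast_*`` are None and the highest load's
    peaks are reported as lower bounds (``exceeds_max_tested`` = True).
    ``upper_bound`` is always True for identified thresholds: the exact AST
    lies at or below the reported peak strains.
    """

    voi: str
    measure: str
    ast_compressive: Optional[float]  # ue, negative
    ast_tensile: Optional[float]  # ue
    identified_at_load: Optional[float]  # N
    upper_bound: bool
    exceeds_max_tested: bool
    non_monotone: bool
    per_load: tuple  # (load, responded, peak_compressive, peak_tensile) rows


def identify_ast(summaries, outcomes, voi: str, measure: str) -> ASTReport:
    """Find the lowest-magnitude responding load and report its VOI peak strains.

    ``summaries``: VOIStrainSummary per load for this VOI; ``outcomes``:
    AdaptationOutcome per load for this VOI and ``measure``.  Both must cover
    the same load levels.  Response patterns that are non-monotone in load
    magnitude (responding at a low load but not a higher one) are flagged.
    """
    summaries = {round(s.load, 6): s for s in summaries if s.voi == voi}
    outs = {round(o.load, 6): o for o in outcomes if o.voi == voi and o.measure == measure}
    if set(summaries) != set(outs):
        raise ValueError(
            f"load sets differ between summaries {sorted(summaries)} and outcomes {sorted(outs)}"
        )
    loads = sorted(summaries, key=abs)
    rows = tuple(
        (ld, outs[ld].responded, summaries[ld].peak_compressive, summaries[ld].peak_tensile)
        for ld in loads
    )
    responded = [outs[ld].responded for ld in loads]
    non_monotone = any(
        responded[i] and not responded[j]
        for i in range(len(loads))
        for j in range(i + 1, len(loads))
    )
    first = next((ld for ld in loads if outs[ld].responded), None)
    if first is None:
        top = loads[-1]
        return ASTReport(
            voi=voi, measure=measure,
            ast_compressive=None, ast_tensile=None,
            identified_at_load=None, upper_bound=True,
            exceeds_max_tested=True, non_monotone=non_monotone, per_load=rows,
        )
    s = summaries[first]
    return ASTReport(
        voi=voi, measure=measure,
        ast_compressive=s.peak_compressive, ast_tensile=s.peak_tensile,
        identified_at_load=first, upper_bound=True,
        exceeds_max_tested=False, non_monotone=non_monotone, per_load=rows,
    )


def outcomes_from_table(table: pd.DataFrame, test: str = "paired_t") -> list[AdaptationOutcome]:
    """Paired loaded-vs-control tests from a long-format outcome table.

    Columns: ``animal_id``, ``limb`` ("loaded"/"control"), ``load`` (N),
    ``voi``, ``measure``, ``value``.  One test per (voi, load, measure);
    animals missing either limb are excluded pairwise.
    """
    required = {"animal_id", "limb", "load", "voi", "measure", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"outcome table needs columns {sorted(required)}")
    outcomes = []
    for (voi, load, measure), grp in table.groupby(["voi", "load", "measure"], sort=True):
        wide = grp.pivot_table(index="animal_id", columns="limb", values="value").dropna()
        if not {"loaded", "control"} <= set(wide.columns) or len(wide) < 2:
            raise ValueError(f"need paired loaded/control values for {(voi, load, measure)}")
        if test == "paired_t":
            _, p = paired_t(wide["loaded"], wide["control"])
        elif test == "wilcoxon":
            _, p = wilcoxon_signed_rank(wide["loaded"], wide["control"])
        else:
            raise ValueError(f"unknown test {test!r}")
        outcomes.append(AdaptationOutcome(voi=voi, load=float(load), measure=measure, p_value=p))
    return outcomes


def synthetic_outcome_table(
    responding: dict[str, Sequence[float]],
    loads: Sequence[float] = (-3.5, -5.2, -7.0),
    vois: Sequence[str] = ("midshaft_cortical", "proximal_cancellous"),
    measure: str = "Ct.Ar" ,
    measures: Optional[dict[str, str]] = None,
    n_animals: int = 10,
    effect: float = 0.08,
    noise: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic paired outcome data with designated responding load levels.

    For each VOI, loads listed in ``responding[voi]`` get a relative loaded-
    limb effect of ``effect`` (well above the paired noise), others none.
    Used to exercise AST identification end to end without animal data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for voi in vois:
        meas = (measures or {}).get(voi, measure)
        resp = set(round(x, 6) for x in responding.get(voi, ()))
        for load in loads:
            eff = effect if round(load, 6) in resp else 0.0
            base = rng.normal(1.0, 0.05, size=n_animals)
            ctrl = base + rng.normal(0.0, noise, size=n_animals)
            loaded = base * (1.0 + eff) + rng.normal(0.0, noise, size=n_animals)
            for i in range(n_animals):
                rows.append((f"a{i}", "control", load, voi, meas, ctrl[i]))
                rows.append((f"a{i}", "loaded", load, voi, meas, loaded[i]))
    return pd.DataFrame(rows, columns=["animal_id", "limb", "load", "voi", "measure", "value"])
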