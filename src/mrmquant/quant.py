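"""Light/heavy quantification: peak integration, ratio-dot-product QC,
interference elimination, and absolute amounts in fmol/ug.

The quantification rule is the internal-standard identity: the peak-area
ratio of the endogenous (light) peptide to its stable-isotope (heavy)
partner, multiplied by the spiked internal-standard amount, is the absolute
endogenous amount. A peptide's measurement passes QC only when

* its ratio dot product exceeds 0.9 (light and heavy transition patterns
  agree),
* light and heavy apexes co-elute within an RT tolerance, and
* at least three transitions survive interference elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .chem import Label
from .simulate import ChromatogramSet

__all__ = [
    "QCStatus",
    "PeakGroup",
    "QuantResult",
    "QuantThresholds",
    "integrate_peak",
    "rdotp",
    "rt_match",
    "extract_peak_groups",
    "drop_interfered",
    "quantify",
    "roll_up",
]


class QCStatus(str, Enum):
    PASS = "pass"
    FAIL_RDOTP = "fail_rdotp"
    FAIL_RT = "fail_rt"
    FAIL_MIN_TRANSITIONS = "fail_min_transitions"


@dataclass(frozen=True)
class QuantThresholds:
    """QC gates; defaults follow standard MRM practice (rdotp strictly > 0.9)."""

    min_rdotp: float = 0.9
    rt_tolerance_min: float = 0.1
    min_transitions: int = 3
    k_mad: float = 5.0
    min_rel_dev: float = 0.2
    baseline_points: int = 3


def integrate_peak(
    times: np.ndarray,
    intensities: np.ndarray,
    window: tuple[float, float] | None = None,
    baseline_points: int = 3,
) -> float:
    """Trapezoidal peak area above an endpoint-estimated baseline.

    The baseline is the mean of the first and last ``baseline_points``
    samples inside the window; the result is clamped at zero. Units:
    intensity x minutes.
    """
    times = np.asarray(times, float)
    intensities = np.asarray(intensities, float)
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        times, intensities = times[mask], intensities[mask]
    if times.size < 3:
        raise ValueError(f"need >= 3 samples in window, got {times.size}")
    k = min(baseline_points, times.size // 2)
    baseline = float(np.mean(np.concatenate([intensities[:k], intensities[-k:]])))
    area = float(np.trapezoid(intensities - baseline, times))
    return max(area, 0.0)


def rdotp(light_areas: np.ndarray, heavy_areas: np.ndarray) -> float:
    """Ratio dot product: cosine similarity of per-transition area vectors.

    Near 1 when the endogenous peak's relative transition intensities match
    the internal standard's. A zero-norm vector yields 0 (handled upstream
    as a QC failure).
    """
    x = np.asarray(light_areas, float)
    y = np.asarray(heavy_areas, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("area vectors must have equal length >= 2")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), 0.0, 1.0))


def rt_match(light_apex: float, heavy_apex: float, tol: float = 0.1) -> bool:
    """True when the apexes co-elute within ``tol`` minutes (closed boundary)."""
    return abs(light_apex - heavy_apex) <= tol


@dataclass
class PeakGroup:
    """Integrated light/heavy areas for one peptide's transitions."""

    peptide: str
    protein: str | None
    transition_ids: list[str]
    light_areas: np.ndarray
    heavy_areas: np.ndarray
    light_apex_rt: float
    heavy_apex_rt: float
    dropped: list[str] = field(default_factory=list)
    min_transitions_ok: bool = True

    @property
    def n_retained(self) -> int:
        return len(self.transition_ids)


def _apex(times: np.ndarray, intensities: np.ndarray) -> float:
    return float(times[int(np.argmax(intensities))])


def extract_peak_groups(
    chroms: ChromatogramSet,
    assay: pd.DataFrame,
    thresholds: QuantThresholds | None = None,
) -> list[PeakGroup]:
    """Integrate every light/heavy trace pair and group by peptide.

    ``assay`` is the transition-list table; it supplies the peptide-protein
    mapping and the integration windows. The apex RT per label is taken from
    the transition-summed trace.
    """
    thresholds = thresholds or QuantThresholds()
    tid_of = {}
    for row in assay.drop_duplicates("peptide").itertuples(index=False):
        tid_of[row.peptide] = row.protein_id or None

    by_pep: dict[str, list[str]] = {}
    for (tid, label) in chroms.traces:
        pep = tid.split(".")[0]
        if label is Label.LIGHT:
            by_pep.setdefault(pep, []).append(tid)

    groups = []
    for pep in sorted(by_pep):
        tids = sorted(set(by_pep[pep]))
        la, ha = [], []
        light_sum = heavy_sum = None
        times_ref = None
        for tid in tids:
            lt, ly = chroms.traces[(tid, Label.LIGHT)]
            ht, hy = chroms.traces[(tid, Label.HEAVY)]
            la.append(integrate_peak(lt, ly, baseline_points=thresholds.baseline_points))
            ha.append(integrate_peak(ht, hy, baseline_points=thresholds.baseline_points))
            if light_sum is None:
                times_ref, light_sum, heavy_sum = lt, ly.copy(), hy.copy()
            else:
                light_sum = light_sum + ly
                heavy_sum = heavy_sum + hy
        groups.append(
            PeakGroup(
                peptide=pep,
                protein=tid_of.get(pep),
                transition_ids=tids,
                light_areas=np.array(la),
                heavy_areas=np.array(ha),
                light_apex_rt=_apex(times_ref, light_sum),
                heavy_apex_rt=_apex(times_ref, heavy_sum),
            )
        )
    return groups


def drop_interfered(
    pg: PeakGroup,
    k_mad: float = 5.0,
    min_transitions: int = 3,
    min_rel_dev: float = 0.2,
) -> PeakGroup:
    """Remove transitions whose light/heavy ratio is a robust outlier.

    Interference on a light transition inflates that transition's ratio
    relative to the others. A transition is eliminated when its ratio
    deviates from the median by more than ``k_mad`` x MAD *and* by more
    than ``min_rel_dev`` of the median — the second gate keeps the rule
    from firing on measurement noise, where MAD over a handful of
    transitions is a degenerate scale estimate. If elimination would leave
    fewer than ``min_transitions``, nothing is removed and the group is
    flagged instead (never silently quantified).
    """
    if pg.n_retained < min_transitions:
        pg.min_transitions_ok = False
        return pg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(pg.heavy_areas > 0, pg.light_areas / pg.heavy_areas, np.inf)
    med = float(np.median(ratios[np.isfinite(ratios)])) if np.isfinite(ratios).any() else 0.0
    dev = np.abs(ratios - med)
    mad = float(np.median(dev[np.isfinite(dev)]))
    # strict inequalities keep all-equal ratios untouched
    outlier = (dev > k_mad * mad) & (dev > min_rel_dev * abs(med))
    if not outlier.any():
        return pg
    keep = ~outlier
    if keep.sum() < min_transitions:
        return PeakGroup(
            peptide=pg.peptide,
            protein=pg.protein,
            transition_ids=pg.transition_ids,
            light_areas=pg.light_areas,
            heavy_areas=pg.heavy_areas,
            light_apex_rt=pg.light_apex_rt,
            heavy_apex_rt=pg.heavy_apex_rt,
            dropped=[],
            min_transitions_ok=False,
        )
    return PeakGroup(
        peptide=pg.peptide,
        protein=pg.protein,
        transition_ids=[t for t, k in zip(pg.transition_ids, keep) if k],
        light_areas=pg.light_areas[keep],
        heavy_areas=pg.heavy_areas[keep],
        light_apex_rt=pg.light_apex_rt,
        heavy_apex_rt=pg.heavy_apex_rt,
        dropped=[t for t, k in zip(pg.transition_ids, keep) if not k],
        min_transitions_ok=True,
    )


@dataclass
class QuantResult:
    """Per-peptide quantification outcome; concentration only when QC passes."""

    peptide: str
    protein: str | None
    rdotp: float
    rt_delta: float
    ratio: float | None
    concentration: float | None  # fmol/ug
    qc_status: QCStatus
    n_transitions_retained: int
    dropped_transitions: list[str] = field(default_factory=list)


def quantify(
    pg: PeakGroup,
    spiked: float,
    thresholds: QuantThresholds | None = None,
) -> QuantResult:
    """Turn a (interference-filtered) peak group into an absolute amount.

    ratio = sum(retained light areas) / sum(retained heavy areas);
    concentration = ratio x spiked amount (fmol/ug). QC requires
    rdotp > min_rdotp, apex co-elution, and >= min_transitions retained.
    """
    thresholds = thresholds or QuantThresholds()
    rd = rdotp(pg.light_areas, pg.heavy_areas) if pg.n_retained >= 2 else 0.0
    delta = pg.light_apex_rt - pg.heavy_apex_rt

    def fail(status: QCStatus) -> QuantResult:
        return QuantResult(
            peptide=pg.peptide, protein=pg.protein, rdotp=rd, rt_delta=delta,
            ratio=None, concentration=None, qc_status=status,
            n_transitions_retained=pg.n_retained, dropped_transitions=pg.dropped,
        )

    if not pg.min_transitions_ok or pg.n_retained < thresholds.min_transitions:
        return fail(QCStatus.FAIL_MIN_TRANSITIONS)
    heavy_sum = float(pg.heavy_areas.sum())
    if heavy_sum == 0.0:
        return fail(QCStatus.FAIL_RDOTP)  # internal standard absent
    if not (rd > thresholds.min_rdotp):
        return fail(QCStatus.FAIL_RDOTP)
    if not rt_match(pg.light_apex_rt, pg.heavy_apex_rt, thresholds.rt_tolerance_min):
        return fail(QCStatus.FAIL_RT)

    ratio = float(pg.light_areas.sum()) / heavy_sum
    return QuantResult(
        peptide=pg.peptide, protein=pg.protein, rdotp=rd, rt_delta=delta,
        ratio=ratio, concentration=ratio * spiked, qc_status=QCStatus.PASS,
        n_transitions_retained=pg.n_retained, dropped_transitions=pg.dropped,
    )


def quantify_all(
    chroms: ChromatogramSet,
    assay: pd.DataFrame,
    spikes: dict[str, float] | float,
    thresholds: QuantThresholds | None = None,
) -> pd.DataFrame:
    """Full pipeline on a chromatogram set: extract, filter, quantify.

    ``spikes`` maps peptide sequence -> spiked amount (fmol/ug), or is one
    number for all peptides. Returns the quant table (one row per peptide).
    """
    thresholds = thresholds or QuantThresholds()
    rows = []
    for pg in extract_peak_groups(chroms, assay, thresholds):
        pg = drop_interfered(
            pg, thresholds.k_mad, thresholds.min_transitions, thresholds.min_rel_dev
        )
        spike = spikes if isinstance(spikes, (int, float)) else spikes.get(pg.peptide, np.nan)
        res = quantify(pg, float(spike), thresholds)
        rows.append({
            "protein": res.protein,
            "peptide": res.peptide,
            "rdotp": res.rdotp,
            "rt_delta": res.rt_delta,
            "ratio": res.ratio,
            "fmol_per_ug": res.concentration,
            "qc_status": res.qc_status.value,
            "n_transitions_retained": res.n_transitions_retained,
            "dropped_transitions": ";".join(res.dropped_transitions),
        })
    return pd.DataFrame(rows)


def roll_up(quant_table: pd.DataFrame) -> pd.DataFrame:
    """Protein-level roll-up: mean of passing peptide concentrations.

    Proteins with no passing peptide appear with ``quantified=False`` and no
    value, never silently dropped.
    """
    rows = []
    for protein, grp in quant_table.groupby("protein", dropna=False):
        passing = grp[grp["qc_status"] == QCStatus.PASS.value]
        vals = passing["fmol_per_ug"].to_numpy(float)
        if vals.size:
            mean = float(vals.mean())
            cv = float(vals.std(ddof=1) / mean) if vals.size > 1 and mean else 0.0
            rows.append({
                "protein": protein, "fmol_per_ug": mean, "n_peptides": int(vals.size),
                "cv": cv, "quantified": True,
            })
        else:
            rows.append({
                "protein": protein, "fmol_per_ug": np.nan, "n_peptides": 0,
                "cv": np.nan, "quantified": False,
            })
    return pd.DataFrame(rows)
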