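"""Scheduled-MRM transition lists with instrument parameters.

Each transition is one precursor/fragment (Q1/Q3) m/z pair monitored on a
triple quadrupole at unit resolution (0.7 Da half-width). The per-transition
voltages are linear functions of Q1/Q3, the vendor-style ramps used on a
QTRAP-class instrument:

    DP  = 0.049 * Q1 + 42.6
    CE  = 0.036 * Q1 + 6.9      (2+ precursors)
    CE  = 0.054 * Q1 - 2.4      (3+ precursors)
    CXP = 0.0391 * Q3 - 2.23
    EP  = 10 (constant)

Scheduled acquisition monitors each transition only inside a retention-time
window (default 120 s) centered on its predicted RT, with a fixed target
scan time (default 1 s) shared by all concurrent transitions.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .chem import Label, Peptide, default_mass_table, fragment_mz, precursor_mz

__all__ = [
    "AssaySettings",
    "Transition",
    "declustering_potential",
    "collision_energy",
    "collision_cell_exit_potential",
    "build_transitions",
    "schedule",
    "ScheduleReport",
    "acylcarnitine_ce",
    "transitions_to_frame",
    "frame_to_transitions",
]

ENTRANCE_POTENTIAL = 10.0

#: Columns of the transition-list CSV, in fixed order (read back losslessly).
TRANSITION_COLUMNS = [
    "protein_id", "peptide", "label", "precursor_charge", "q1", "fragment",
    "q3", "dp", "ce", "cxp", "ep", "rt", "window_start", "window_end",
]


@dataclass(frozen=True)
class AssaySettings:
    """Acquisition settings for a scheduled MRM run.

    target_scan_time_s : cycle time shared by all concurrent transitions.
    detection_window_s : width of the scheduled RT window per transition.
    min_transitions    : fragments monitored per peptide (>= 3).
    """

    target_scan_time_s: float = 1.0
    detection_window_s: float = 120.0
    min_transitions: int = 3
    q1_q3_resolution: str = "unit (0.7 Da half-width)"
    max_mz_for_2plus: float = 1250.0
    overhead_ms: float = 2.0
    min_dwell_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.min_transitions < 3:
            raise ValueError("min_transitions must be >= 3")
        if self.detection_window_s <= 0:
            raise ValueError("detection_window_s must be positive")


def declustering_potential(q1: float) -> float:
    """DP in volts from precursor m/z."""
    if q1 <= 0:
        raise ValueError(f"q1 must be positive, got {q1}")
    return 0.049 * q1 + 42.6


def collision_energy(q1: float, precursor_charge: int) -> float:
    """CE in volts from precursor m/z; defined for 2+ and 3+ precursors only."""
    if q1 <= 0:
        raise ValueError(f"q1 must be positive, got {q1}")
    if precursor_charge == 2:
        return 0.036 * q1 + 6.9
    if precursor_charge == 3:
        return 0.054 * q1 - 2.4
    raise ValueError(f"collision energy defined for charges 2 and 3, got {precursor_charge}")


def collision_cell_exit_potential(q3: float) -> float:
    """CXP in volts from fragment m/z; warns when the ramp goes non-positive."""
    if q3 <= 0:
        raise ValueError(f"q3 must be positive, got {q3}")
    cxp = 0.0391 * q3 - 2.23
    if cxp <= 0:
        warnings.warn(
            f"CXP ramp non-positive ({cxp:.3f} V) at q3={q3:.2f}; "
            "fragment below the plausible m/z range",
            stacklevel=2,
        )
    return cxp


@dataclass(frozen=True)
class Transition:
    """One Q1/Q3 pair with instrument parameters and an RT window.

    Light and heavy partners share ``transition_id`` and fragment identity;
    the ``label`` field distinguishes them.
    """

    transition_id: str
    peptide: Peptide
    precursor_charge: int
    q1: float
    fragment_ion: tuple[str, int, int]  # (series, index, charge)
    q3: float
    dp: float
    ce: float
    cxp: float
    ep: float = ENTRANCE_POTENTIAL
    predicted_rt: float | None = None   # minutes
    window: tuple[float, float] | None = None  # minutes

    @property
    def label(self) -> Label:
        return self.peptide.label


def build_transitions(
    peptide: Peptide,
    settings: AssaySettings | None = None,
    predicted_rt: float | None = None,
) -> list[Transition]:
    """Build the light/heavy transition pairs for one peptide.

    Fragment choice: singly charged y-ions y3 .. y(L-1), highest index first
    (higher index = more sequence-specific), keeping ``min_transitions`` of
    them. The precursor is 2+ unless its 2+ m/z exceeds
    ``settings.max_mz_for_2plus``, then 3+. Every light transition gets a
    heavy partner whose Q1 (and Q3, for y-ions) shifts by label mass / charge.
    """
    settings = settings or AssaySettings()
    L = len(peptide.sequence)
    if L < 6:
        raise ValueError(f"peptide too short for {settings.min_transitions} y-ions: {peptide.sequence!r}")
    if peptide.sequence[-1] not in "KR":
        raise ValueError("peptide must end in K or R for a heavy partner")

    light = replace_label(peptide, Label.LIGHT)
    heavy = replace_label(peptide, Label.HEAVY)

    charge = 2
    if precursor_mz(light, 2) > settings.max_mz_for_2plus:
        charge = 3

    indices = list(range(L - 1, 2, -1))[: settings.min_transitions]
    out = []
    for p in (light, heavy):
        q1 = precursor_mz(p, charge)
        dp = declustering_potential(q1)
        ce = collision_energy(q1, charge)
        for idx in indices:
            q3 = fragment_mz(p, "y", idx, 1)
            tid = f"{peptide.sequence}.{charge}.y{idx}.1"
            out.append(
                Transition(
                    transition_id=tid,
                    peptide=p,
                    precursor_charge=charge,
                    q1=q1,
                    fragment_ion=("y", idx, 1),
                    q3=q3,
                    dp=dp,
                    ce=ce,
                    cxp=collision_cell_exit_potential(q3),
                    predicted_rt=predicted_rt,
                    window=_window(predicted_rt, settings),
                )
            )
    return out


def replace_label(p: Peptide, label: Label) -> Peptide:
    return Peptide(p.sequence, p.fixed_mods, label, p.parent_protein)


def _window(rt: float | None, settings: AssaySettings) -> tuple[float, float] | None:
    if rt is None:
        return None
    half = settings.detection_window_s / 60.0 / 2.0
    return (rt - half, rt + half)


@dataclass
class ScheduleReport:
    max_concurrent: int
    min_dwell_ms: float
    crowded_windows: list[tuple[float, int]]  # (time_min, n_concurrent) below dwell floor


def schedule(
    transitions: list[Transition], settings: AssaySettings | None = None
) -> tuple[list[Transition], ScheduleReport]:
    """Assign RT windows and report concurrency and per-cycle dwell time.

    Dwell per transition at concurrency n is
    ``(target_scan_time - n * overhead) / n``; windows below the dwell floor
    are listed in the report (with a warning) but scheduling still succeeds.
    """
    settings = settings or AssaySettings()
    missing = [t.transition_id for t in transitions if t.predicted_rt is None]
    if missing:
        raise ValueError(f"transitions lack predicted_rt: {missing[:5]}")

    scheduled = [replace(t, window=_window(t.predicted_rt, settings)) for t in transitions]

    # Sweep-line over window boundaries for maximum concurrency.
    events = []
    for t in scheduled:
        start, end = t.window
        events.append((start, 1))
        events.append((end, -1))
    events.sort()
    crowded, n, max_n, min_dwell = [], 0, 0, math.inf
    for time, delta in events:
        n += delta
        if n > 0:
            dwell = (settings.target_scan_time_s * 1000 - n * settings.overhead_ms) / n
            min_dwell = min(min_dwell, dwell)
            max_n = max(max_n, n)
            if dwell < settings.min_dwell_ms:
                crowded.append((time, n))
    if crowded:
        warnings.warn(
            f"dwell time below {settings.min_dwell_ms} ms in {len(crowded)} window(s)",
            stacklevel=2,
        )
    return scheduled, ScheduleReport(max_n, min_dwell if max_n else math.nan, crowded)


_ACYL_RE = re.compile(r"^C(\d+)(?::(\d+))?(?:[-:]?(OH|DC))?$", re.IGNORECASE)

#: Product ion common to all acylcarnitines in positive-mode precursor scans.
ACYLCARNITINE_PRODUCT_MZ = 85.05


def acylcarnitine_ce(species: str) -> tuple[float, float]:
    """(product m/z, CE in volts) for an acylcarnitine precursor-ion scan.

    All acylcarnitines share the m/z 85.05 product; CE steps with acyl chain
    length: -20 V for short chains (C0-C8), -25 V for middle chains
    (C10-C14, any unsaturation or hydroxylation), -35 V for long chains
    (C16-C18). Odd intermediate chain lengths 9 and 15 fall in no class and
    are rejected, as are carbon counts outside 0-18.
    """
    m = _ACYL_RE.match(species.strip())
    if not m:
        raise ValueError(f"unparsable acylcarnitine label {species!r}")
    carbons = int(m.group(1))
    if not 0 <= carbons <= 18:
        raise ValueError(f"acyl chain length {carbons} outside 0-18 in {species!r}")
    if carbons <= 8:
        ce = -20.0
    elif 10 <= carbons <= 14:
        ce = -25.0
    elif carbons >= 16:
        ce = -35.0
    else:
        raise ValueError(f"no collision-energy class for chain length {carbons} ({species!r})")
    return (ACYLCARNITINE_PRODUCT_MZ, ce)


def transitions_to_frame(transitions: list[Transition]) -> pd.DataFrame:
    """Serialize to the fixed-column transition-list table."""
    rows = []
    for t in transitions:
        series, idx, fcharge = t.fragment_ion
        start, end = t.window if t.window else (float("nan"), float("nan"))
        rows.append({
            "protein_id": t.peptide.parent_protein or "",
            "peptide": t.peptide.sequence,
            "label": t.label.value,
            "precursor_charge": t.precursor_charge,
            "q1": t.q1,
            "fragment": f"{series}{idx}^{fcharge}",
            "q3": t.q3,
            "dp": t.dp,
            "ce": t.ce,
            "cxp": t.cxp,
            "ep": t.ep,
            "rt": t.predicted_rt,
            "window_start": start,
            "window_end": end,
        })
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def frame_to_transitions(df: pd.DataFrame) -> list[Transition]:
    """Inverse of :func:`transitions_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        series, rest = row.fragment[0], row.fragment[1:]
        idx, fcharge = rest.split("^")
        pep = Peptide(
            row.peptide,
            label=Label(row.label),
            parent_protein=row.protein_id or None,
        )
        window = None
        if pd.notna(row.window_start):
            window = (float(row.window_start), float(row.window_end))
        out.append(
            Transition(
                transition_id=f"{row.peptide}.{row.precursor_charge}.{series}{idx}.{fcharge}",
                peptide=pep,
                precursor_charge=int(row.precursor_charge),
                q1=float(row.q1),
                fragment_ion=(series, int(idx), int(fcharge)),
                q3=float(row.q3),
                dp=float(row.dp),
                ce=float(row.ce),
                cxp=float(row.cxp),
                ep=float(row.ep),
                predicted_rt=None if pd.isna(row.rt) else float(row.rt),
                window=window,
            )
        )
    return out
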