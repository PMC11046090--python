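"""Synthetic data with known ground truth.

Two generators make every downstream stage testable without instrument data:

* scheduled-MRM chromatograms — co-eluting light/heavy Gaussian peak pairs
  that share per-transition relative intensities (the property the ratio
  dot product exploits), with multiplicative intensity noise, optional RT
  jitter between the pair, and optional interference peaks planted on
  individual light transitions;
* analyte x sample study matrices — three genotype-style groups with
  log-normal baseline abundances, multiplicative within-group noise, and
  planted fold changes recorded in an embedded truth table.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssaySettings, Transition
from .chem import Label

__all__ = [
    "PeptideTruth",
    "SimTruth",
    "ChromatogramSet",
    "random_truth",
    "simulate_chromatograms",
    "StudyMatrix",
    "simulate_study",
    "synthetic_proteome",
]

#: Detector response in counts per (fmol/ug x unit relative intensity).
RESPONSE_FACTOR = 1000.0


@dataclass
class PeptideTruth:
    """Ground truth for one peptide's light/heavy peak pair."""

    concentration: float        # endogenous amount, fmol/ug
    spiked: float               # heavy internal-standard amount, fmol/ug
    rt_true: float              # apex retention time, minutes
    peak_sigma: float = 0.05    # Gaussian peak width, minutes
    rel_intensities: dict[str, float] = field(default_factory=dict)
    heavy_rt_shift: float = 0.0  # light/heavy co-elute by default

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.spiked < 0:
            raise ValueError("amounts must be non-negative")
        if self.rel_intensities:
            total = sum(self.rel_intensities.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"relative intensities must sum to 1, got {total}")


@dataclass
class SimTruth:
    """Full simulation ground truth, keyed by peptide sequence."""

    peptides: dict[str, PeptideTruth]
    noise_cv: float = 0.05
    baseline: float = 2.0       # additive counts under every trace
    #: transition_id -> (RT offset in minutes, amplitude as a fraction of the
    #: light peak amplitude); applied to the light trace only.
    interference: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0


def random_truth(
    transitions: list[Transition],
    seed: int,
    conc_range: tuple[float, float] = (0.5, 50.0),
    spiked: float = 10.0,
    rt_range: tuple[float, float] = (5.0, 55.0),
    peak_sigma: float = 0.05,
    noise_cv: float = 0.05,
) -> SimTruth:
    """Draw a reproducible ground truth for an assay.

    Concentrations are log-uniform over ``conc_range``; per-transition
    relative intensities are Dirichlet-distributed. The true retention time
    is the transition's predicted RT when the assay is already scheduled
    (the peak then falls inside its acquisition window), otherwise uniform
    over ``rt_range``.
    """
    rng = np.random.default_rng(seed)
    by_pep: dict[str, list[str]] = {}
    rt_of: dict[str, float | None] = {}
    for t in transitions:
        if t.label is Label.LIGHT:
            by_pep.setdefault(t.peptide.sequence, []).append(t.transition_id)
            rt_of.setdefault(t.peptide.sequence, t.predicted_rt)
    peptides = {}
    for seq in sorted(by_pep):
        tids = sorted(set(by_pep[seq]))
        conc = float(np.exp(rng.uniform(*np.log(conc_range))))
        rel = rng.dirichlet(np.full(len(tids), 5.0))
        rt = rt_of[seq]
        peptides[seq] = PeptideTruth(
            concentration=conc,
            spiked=spiked,
            rt_true=float(rng.uniform(*rt_range)) if rt is None else float(rt),
            peak_sigma=peak_sigma,
            rel_intensities=dict(zip(tids, rel.tolist())),
        )
    return SimTruth(peptides=peptides, noise_cv=noise_cv, seed=seed)


@dataclass
class ChromatogramSet:
    """Time-intensity traces per (transition, label), plus the truth used."""

    traces: dict[tuple[str, Label], tuple[np.ndarray, np.ndarray]]
    settings: AssaySettings
    truth: SimTruth | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tid, label), (t, y) in self.traces.items():
            rows.append(pd.DataFrame({
                "transition_id": tid,
                "label": label.value,
                "time_min": t,
                "intensity": y,
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, settings: AssaySettings | None = None) -> "ChromatogramSet":
        traces = {}
        for (tid, label), grp in df.groupby(["transition_id", "label"], sort=False):
            grp = grp.sort_values("time_min")
            traces[(tid, Label(label))] = (
                grp["time_min"].to_numpy(float),
                grp["intensity"].to_numpy(float),
            )
        return cls(traces=traces, settings=settings or AssaySettings())


def _lognormal_sigma(cv: float) -> float:
    # multiplicative noise with the requested coefficient of variation
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_chromatograms(
    transitions: list[Transition],
    truth: SimTruth,
    settings: AssaySettings | None = None,
) -> ChromatogramSet:
    """Sample Gaussian peak pairs on the scheduled acquisition grid.

    Each trace is ``A * exp(-(t - rt)^2 / (2 sigma^2)) + baseline`` sampled
    every target scan time inside the transition's RT window. The light
    amplitude is proportional to the true concentration times the
    transition's relative intensity; the heavy amplitude uses the spiked
    amount and the *same* relative intensity. Multiplicative log-normal
    noise at the stated CV is applied pointwise; interference adds an extra
    Gaussian to the listed light transitions.
    """
    settings = settings or AssaySettings()
    have = {t.peptide.sequence for t in transitions}
    missing = sorted(set(truth.peptides) - have)
    if missing:
        raise ValueError(f"truth peptides missing from assay: {missing[:5]}")

    rng = np.random.default_rng(truth.seed)
    sigma_log = _lognormal_sigma(truth.noise_cv)
    dt = settings.target_scan_time_s / 60.0
    traces: dict[tuple[str, Label], tuple[np.ndarray, np.ndarray]] = {}

    for tr in sorted(transitions, key=lambda t: (t.transition_id, t.label.value)):
        pep = truth.peptides.get(tr.peptide.sequence)
        if pep is None:
            continue
        rel = pep.rel_intensities.get(tr.transition_id)
        if rel is None:
            raise ValueError(f"no relative intensity for transition {tr.transition_id}")
        if tr.window is not None:
            start, end = tr.window
        else:
            half = settings.detection_window_s / 120.0
            start, end = pep.rt_true - half, pep.rt_true + half
        n = int(np.floor((end - start) / dt)) + 1
        t = start + dt * np.arange(n)

        if tr.label is Label.LIGHT:
            amp = RESPONSE_FACTOR * pep.concentration * rel
            rt = pep.rt_true
        else:
            amp = RESPONSE_FACTOR * pep.spiked * rel
            rt = pep.rt_true + pep.heavy_rt_shift
        y = amp * np.exp(-((t - rt) ** 2) / (2 * pep.peak_sigma**2)) + truth.baseline

        if tr.label is Label.LIGHT and tr.transition_id in truth.interference:
            offset, factor = truth.interference[tr.transition_id]
            y = y + factor * amp * np.exp(
                -((t - (rt + offset)) ** 2) / (2 * pep.peak_sigma**2)
            )
        if sigma_log > 0:
            y = y * np.exp(rng.normal(0.0, sigma_log, size=y.shape))
        traces[(tr.transition_id, tr.label)] = (t, y)

    return ChromatogramSet(traces=traces, settings=settings, truth=truth)


@dataclass
class StudyMatrix:
    """Analyte x sample abundance matrix with group labels and planted truth."""

    values: pd.DataFrame           # analytes (rows) x samples (columns)
    sample_groups: pd.Series       # sample ID -> group label
    planted: pd.DataFrame          # columns: analyte, group, fold_change

    def __post_init__(self) -> None:
        if self.sample_groups.isna().any():
            raise ValueError("every sample needs a group label")
        unknown = set(self.planted["analyte"]) - set(self.values.index)
        if unknown:
            raise ValueError(f"planted table references unknown analytes: {sorted(unknown)[:5]}")

    def group_columns(self, group: str) -> list[str]:
        cols = self.sample_groups.index[self.sample_groups == group].tolist()
        if not cols:
            raise KeyError(f"unknown group label {group!r}")
        return cols


def simulate_study(
    n_analytes: int,
    groups: tuple[str, str, str] = ("WT", "Tg", "TgTg"),
    n_per_group: int = 5,
    planted: list[tuple[str, str, float]] | None = None,
    cv: float = 0.10,
    seed: int = 0,
    baseline_median: float = 10.0,
    baseline_log_sd: float = 1.0,
) -> StudyMatrix:
    """Simulate a three-group abundance matrix with planted fold changes.

    Baseline abundances are log-normal across analytes; within-group values
    carry multiplicative noise at the stated CV; each planted
    ``(analyte, group, fold_change)`` multiplies that group's mean. With
    ``cv=0`` the empirical fold change equals the planted value exactly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for a variance estimate")
    planted = planted or []
    for _, grp, fc in planted:
        if fc <= 0:
            raise ValueError("planted fold changes must be positive")
        if grp not in groups:
            raise ValueError(f"planted group {grp!r} not in {groups}")

    rng = np.random.default_rng(seed)
    analytes = [f"analyte{i + 1:04d}" for i in range(n_analytes)]
    samples = [f"{g}_{j + 1}" for g in groups for j in range(n_per_group)]
    group_of = pd.Series(
        [g for g in groups for _ in range(n_per_group)], index=samples, name="group"
    )

    base = baseline_median * np.exp(rng.normal(0.0, baseline_log_sd, size=n_analytes))
    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(groups))), index=analytes, columns=list(groups)
    )
    planted_df = pd.DataFrame(planted, columns=["analyte", "group", "fold_change"])
    for row in planted_df.itertuples(index=False):
        means.loc[row.analyte, row.group] *= row.fold_change

    sigma = _lognormal_sigma(cv)
    noise = (
        np.exp(rng.normal(0.0, sigma, size=(n_analytes, len(samples))))
        if sigma > 0
        else np.ones((n_analytes, len(samples)))
    )
    values = pd.DataFrame(
        means[group_of.values].to_numpy() * noise, index=analytes, columns=samples
    )
    return StudyMatrix(values=values, sample_groups=group_of, planted=planted_df)


# residue frequencies loosely following vertebrate proteome composition
_RESIDUE_FREQ = {
    "A": 7.0, "C": 2.0, "D": 5.0, "E": 7.0, "F": 4.0, "G": 7.0, "H": 2.5,
    "I": 4.5, "K": 6.0, "L": 9.5, "M": 2.0, "N": 4.0, "P": 5.5, "Q": 4.5,
    "R": 5.5, "S": 8.0, "T": 5.5, "V": 6.5, "W": 1.0, "Y": 3.0,
}


def synthetic_proteome(
    n_proteins: int = 30,
    length_range: tuple[int, int] = (150, 400),
    seed: int = 0,
    id_prefix: str = "PROT",
) -> dict[str, str]:
    """Random protein sequences with realistic residue composition.

    Serves as a stand-in proteome for design and end-to-end runs; IDs are
    ``PROT0001`` etc.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(_RESIDUE_FREQ))
    probs = np.array(list(_RESIDUE_FREQ.values()))
    probs = probs / probs.sum()
    out = {}
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=n, p=probs))
        out[f"{id_prefix}{i + 1:04d}"] = seq
    return out
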