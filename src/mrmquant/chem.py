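"""Peptide-level chemistry: proteolytic digestion, monoisotopic masses, m/z.

All mass arithmetic is driven by a single plain-text table of monoisotopic
masses (``data/monoisotopic_masses.tsv``) so that independent oracles and the
implementation share one source of constants.

Conventions
-----------
* Fixed carbamidomethylation of cysteine (+57.021464 Da) models iodoacetamide
  alkylation of reduced samples.
* "Heavy" peptides carry a stable-isotope label on the C-terminal residue:
  (13C6/15N2)-lysine (+8.014199 Da) or (13C6/15N4)-arginine (+10.008269 Da),
  the SILAC-style labels used for QconCAT internal standards.
* Isoleucine and leucine are distinct letters with identical mass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

__all__ = [
    "STANDARD_RESIDUES",
    "MassTable",
    "Label",
    "Peptide",
    "Enzyme",
    "DigestSpec",
    "cleavage_sites",
    "digest",
    "digest_with_missed",
    "peptide_mono_mass",
    "precursor_mz",
    "fragment_mz",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic mass constants.

    Attributes
    ----------
    residue_mono_mass : dict
        Residue letter -> monoisotopic residue mass in Da.
    water, proton : float
        Monoisotopic masses of H2O and a proton, Da.
    mod_masses : dict
        Fixed-modification name -> mass shift in Da.
    label_shifts : dict
        C-terminal residue (K or R) -> heavy-label mass shift in Da.
    """

    residue_mono_mass: dict[str, float]
    water: float
    proton: float
    mod_masses: dict[str, float] = field(default_factory=dict)
    label_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - self.residue_mono_mass.keys()
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_mono_mass.values()):
            raise ValueError("residue masses must be positive")
        if set(self.label_shifts) != {"K", "R"}:
            raise ValueError("label shifts must be defined exactly for K and R")


@lru_cache(maxsize=1)
def default_mass_table() -> MassTable:
    """Load the mass table shipped with the package."""
    residues: dict[str, float] = {}
    mods: dict[str, float] = {}
    labels: dict[str, float] = {}
    water = proton = None
    text = (
        importlib.resources.files("mrmquant")
        .joinpath("data/monoisotopic_masses.tsv")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        mass = float(value)
        if key == "water":
            water = mass
        elif key == "proton":
            proton = mass
        elif key.startswith("mod:"):
            mods[key[4:]] = mass
        elif key.startswith("label:"):
            labels[key[6:]] = mass
        else:
            residues[key] = mass
    assert water is not None and proton is not None
    return MassTable(residues, water, proton, mods, labels)


class Label(str, Enum):
    LIGHT = "light"
    HEAVY = "heavy"


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with fixed modifications and label state.

    ``fixed_mods`` names modifications applied wherever their residue occurs
    (only carbamidomethyl-C is shipped). ``label=heavy`` adds the isotope
    shift of the C-terminal residue, which must then be K or R.
    """

    sequence: str
    fixed_mods: frozenset[str] = frozenset({"carbamidomethyl"})
    label: Label = Label.LIGHT
    parent_protein: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Label(self.label))
        object.__setattr__(self, "fixed_mods", frozenset(self.fixed_mods))
        _validate_sequence(self.sequence)
        if self.label is Label.HEAVY and self.sequence[-1] not in "KR":
            raise ValueError(
                "heavy label requires a C-terminal K or R "
                f"(got {self.sequence[-1]!r} in {self.sequence!r})"
            )

    def as_heavy(self) -> "Peptide":
        return Peptide(self.sequence, self.fixed_mods, Label.HEAVY, self.parent_protein)


class Enzyme(str, Enum):
    TRYPSIN = "trypsin"
    LYSC = "lysc"
    LYSC_THEN_TRYPSIN = "lysc_then_trypsin"


@dataclass(frozen=True)
class DigestSpec:
    enzyme: Enzyme = Enzyme.LYSC_THEN_TRYPSIN
    max_missed_cleavages: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "enzyme", Enzyme(self.enzyme))
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, ch in enumerate(sequence):
        if ch not in STANDARD_RESIDUES:
            raise ValueError(f"invalid residue {ch!r} at position {i + 1}")


def cleavage_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Positions i such that the chain is cut between sequence[i-1] and sequence[i].

    Trypsin cuts C-terminal to K/R except before proline; LysC cuts C-terminal
    to K regardless of the next residue. The sequential LysC-then-trypsin
    digest is modeled as the union of both site sets.
    """
    enzyme = Enzyme(enzyme)
    sites = []
    for i in range(1, len(sequence)):
        prev, nxt = sequence[i - 1], sequence[i]
        tryptic = prev in "KR" and nxt != "P"
        lysc = prev == "K"
        if enzyme is Enzyme.TRYPSIN:
            cut = tryptic
        elif enzyme is Enzyme.LYSC:
            cut = lysc
        else:
            cut = tryptic or lysc
        if cut:
            sites.append(i)
    return sites


def digest(sequence: str, spec: DigestSpec | None = None) -> list[str]:
    """Fully cleaved digest products, in N-to-C order.

    The concatenation of the returned fragments reproduces the input.
    Missed-cleavage products are available via :func:`digest_with_missed`.
    """
    spec = spec or DigestSpec()
    _validate_sequence(sequence)
    bounds = [0, *cleavage_sites(sequence, spec.enzyme), len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:])]


def digest_with_missed(sequence: str, spec: DigestSpec) -> list[tuple[str, int]]:
    """All digest products up to ``spec.max_missed_cleavages``.

    Returns ``(peptide, n_missed)`` pairs ordered by start position then by
    missed-cleavage count; the ``n_missed == 0`` subset is the fully cleaved
    digest.
    """
    frags = digest(sequence, spec)
    out = []
    for i in range(len(frags)):
        for k in range(spec.max_missed_cleavages + 1):
            if i + k < len(frags):
                out.append(("".join(frags[i : i + k + 1]), k))
    return out


def peptide_mono_mass(p: Peptide, table: MassTable | None = None) -> float:
    """Neutral monoisotopic mass of the peptide in Da."""
    table = table or default_mass_table()
    mass = table.water + sum(table.residue_mono_mass[r] for r in p.sequence)
    for mod in p.fixed_mods:
        if mod == "carbamidomethyl":
            mass += table.mod_masses[mod] * p.sequence.count("C")
        else:
            raise ValueError(f"unknown fixed modification {mod!r}")
    if p.label is Label.HEAVY:
        mass += table.label_shifts[p.sequence[-1]]
    return mass


def precursor_mz(p: Peptide, charge: int, table: MassTable | None = None) -> float:
    """Precursor m/z at the given positive charge (the Q1 value)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    table = table or default_mass_table()
    return (peptide_mono_mass(p, table) + charge * table.proton) / charge


def fragment_mz(
    p: Peptide,
    ion: str,
    index: int,
    charge: int = 1,
    table: MassTable | None = None,
) -> float:
    """m/z of a b- or y-series fragment ion (the Q3 value).

    y_n covers the n C-terminal residues (plus water); b_n the n N-terminal
    residues. Heavy labels sit on the C-terminal K/R, so y-ions of heavy
    peptides carry the label shift and b-ions do not.
    """
    if ion not in ("b", "y"):
        raise ValueError(f"ion series must be 'b' or 'y', got {ion!r}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if not 1 <= index <= len(p.sequence):
        raise ValueError(
            f"fragment index {index} out of range for length {len(p.sequence)}"
        )
    table = table or default_mass_table()
    part = p.sequence[-index:] if ion == "y" else p.sequence[:index]
    mass = sum(table.residue_mono_mass[r] for r in part)
    if "carbamidomethyl" in p.fixed_mods:
        mass += table.mod_masses["carbamidomethyl"] * part.count("C")
    if ion == "y":
        mass += table.water
        if p.label is Label.HEAVY:
            mass += table.label_shifts[p.sequence[-1]]
    return (mass + charge * table.proton) / charge
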