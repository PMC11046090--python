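"""Proteotypic peptide selection and QconCAT concatamer assembly.

A QconCAT is an artificial protein made by concatenating proteotypic
peptides from many target proteins. Expressed in heavy-isotope medium and
spiked into a sample before digestion, it releases one labeled internal
standard per target peptide. The design constraint enforced here is that
LysC + trypsin digestion of the construct must release every constituent
peptide intact, exactly once.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .chem import DigestSpec, Enzyme, Peptide, digest

__all__ = [
    "SelectionRules",
    "SelectionReport",
    "QconCATConstruct",
    "ValidationReport",
    "select_proteotypic",
    "assemble_qconcat",
    "validate_qconcat",
]

#: Hard exclusion motifs applied by default: methionine anywhere (oxidation
#: risk), N-terminal glutamine (pyro-Glu), and ragged starts (peptide begins
#: with K/R, i.e. follows a KK/RR/KR double-basic junction).
DEFAULT_EXCLUDE_MOTIFS = ("M", "^Q", "^K", "^R")

#: Soft flags used only for ranking candidates (not exclusion): cysteine
#: (requires complete alkylation) and deamidation-prone NG/DG motifs.
_SOFT_MOTIFS = ("C", "NG", "DG")


@dataclass(frozen=True)
class SelectionRules:
    """Rules a digest peptide must satisfy to be a quantification surrogate.

    ``exclude_motifs`` uses a tiny pattern syntax: a plain substring means
    "contains", a leading ``^`` anchors to the N-terminus.
    """

    min_length: int = 7
    max_length: int = 20
    require_cterm_KR: bool = True
    exclude_motifs: tuple[str, ...] = DEFAULT_EXCLUDE_MOTIFS
    max_peptides_per_protein: int = 1

    def __post_init__(self) -> None:
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        if self.max_length > 30:
            raise ValueError("max_length must be <= 30")
        if self.max_peptides_per_protein < 1:
            raise ValueError("max_peptides_per_protein must be >= 1")


def _matches_motif(sequence: str, motif: str) -> bool:
    if motif.startswith("^"):
        return sequence.startswith(motif[1:])
    return motif in sequence


def _soft_flag_count(sequence: str) -> int:
    return sum(_matches_motif(sequence, m) for m in _SOFT_MOTIFS)


@dataclass
class SelectionReport:
    """Outcome of proteotypic selection; failures are reported, never dropped."""

    chosen: dict[str, list[Peptide]]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def peptides(self) -> list[Peptide]:
        return [p for peps in self.chosen.values() for p in peps]


def select_proteotypic(
    proteome: dict[str, str],
    targets: list[str],
    rules: SelectionRules | None = None,
    spec: DigestSpec | None = None,
) -> SelectionReport:
    """Choose proteotypic peptides for each target protein.

    A candidate must be a fully cleaved digest product of its parent, satisfy
    the length/terminus/motif rules, and be a digest product of no other
    protein in the whole proteome (I and L are treated as distinct letters).
    Proteins yielding no acceptable candidate are listed in the failure
    report with a reason.

    Parameters
    ----------
    proteome : dict
        Protein ID -> amino-acid sequence (the full search space for
        uniqueness, not just the targets).
    targets : list
        Protein IDs to design for; all must exist in ``proteome``.
    """
    rules = rules or SelectionRules()
    spec = spec or DigestSpec(Enzyme.LYSC_THEN_TRYPSIN, 0)

    missing = [t for t in targets if t not in proteome]
    if missing:
        raise KeyError(f"target IDs absent from proteome: {missing}")

    # Map each fully cleaved digest peptide to the set of proteins producing it.
    producers: dict[str, set[str]] = {}
    for pid, seq in proteome.items():
        for pep in set(digest(seq, spec)):
            producers.setdefault(pep, set()).add(pid)

    chosen: dict[str, list[Peptide]] = {}
    failures: dict[str, str] = {}
    for pid in targets:
        candidates = []
        n_shared = n_rules = 0
        for pep in dict.fromkeys(digest(proteome[pid], spec)):  # ordered, unique
            if len(producers[pep]) != 1:
                n_shared += 1
                continue
            if not (rules.min_length <= len(pep) <= rules.max_length):
                n_rules += 1
                continue
            if rules.require_cterm_KR and pep[-1] not in "KR":
                n_rules += 1
                continue
            if any(_matches_motif(pep, m) for m in rules.exclude_motifs):
                n_rules += 1
                continue
            candidates.append(pep)
        if not candidates:
            failures[pid] = (
                f"no proteotypic peptide ({n_shared} shared with other proteins, "
                f"{n_rules} failed selection rules)"
            )
            continue
        # Deterministic ranking: fewest soft flags, length closest to 12,
        # then lexicographic.
        candidates.sort(key=lambda s: (_soft_flag_count(s), abs(len(s) - 12), s))
        chosen[pid] = [
            Peptide(pep, parent_protein=pid)
            for pep in candidates[: rules.max_peptides_per_protein]
        ]
    return SelectionReport(chosen=chosen, failures=failures)


@dataclass(frozen=True)
class QconCATConstruct:
    construct_id: str
    peptides: tuple[Peptide, ...]
    n_term_tag: str = ""
    c_term_tag: str = ""

    @property
    def full_sequence(self) -> str:
        return self.n_term_tag + "".join(p.sequence for p in self.peptides) + self.c_term_tag


@dataclass
class ValidationReport:
    construct_id: str
    released: dict[str, int]        # peptide -> times released intact
    bad_junctions: list[int]        # 0-based junction indices suppressing cleavage
    passed: bool


def validate_qconcat(
    construct: QconCATConstruct, spec: DigestSpec | None = None
) -> ValidationReport:
    """Check that in-silico digestion releases every peptide intact exactly once."""
    spec = spec or DigestSpec(Enzyme.LYSC_THEN_TRYPSIN, 0)
    products = Counter(digest(construct.full_sequence, spec))
    released = {p.sequence: products.get(p.sequence, 0) for p in construct.peptides}

    bad = []
    seqs = [p.sequence for p in construct.peptides]
    for i in range(len(seqs) - 1):
        prev_end, next_start = seqs[i][-1], seqs[i + 1][0]
        tryptic_blocked = prev_end in "KR" and next_start == "P"
        lysc_rescues = prev_end == "K" and spec.enzyme in (
            Enzyme.LYSC,
            Enzyme.LYSC_THEN_TRYPSIN,
        )
        if tryptic_blocked and not lysc_rescues:
            bad.append(i)
    passed = all(n == 1 for n in released.values())
    return ValidationReport(construct.construct_id, released, bad, passed)


def _junction_cleavable(prev_end: str | None, next_start: str, enzyme: Enzyme) -> bool:
    """Whether digestion separates two K/R-terminated peptides at a junction."""
    if prev_end is None:  # construct N-terminus, nothing to cleave
        return True
    if enzyme is Enzyme.LYSC:
        return prev_end == "K"
    if enzyme is Enzyme.TRYPSIN:
        return next_start != "P"
    return prev_end == "K" or next_start != "P"  # LysC rescues K|P


def _order_for_junctions(peptides: list[Peptide], enzyme: Enzyme) -> list[Peptide]:
    """Reorder a chunk so every junction is cleavable, changing order minimally.

    Greedy in input order with an exact feasibility lookahead: peptides only
    interact through (C-terminal residue, starts-with-P), so feasibility of a
    remaining multiset is memoized over those class counts.
    """
    def cls(p: Peptide) -> tuple[str, bool]:
        return (p.sequence[-1], p.sequence[0] == "P")

    memo: dict[tuple, bool] = {}

    def feasible(counts: dict[tuple[str, bool], int], last_end: str | None) -> bool:
        if all(n == 0 for n in counts.values()):
            return True
        key = (tuple(sorted(counts.items())), last_end)
        if key not in memo:
            memo[key] = any(
                n > 0
                and _junction_cleavable(last_end, "P" if starts_p else "A", enzyme)
                and feasible({**counts, (end, starts_p): n - 1}, end)
                for (end, starts_p), n in counts.items()
            )
        return memo[key]

    pending = list(peptides)
    counts: dict[tuple[str, bool], int] = {}
    for p in pending:
        counts[cls(p)] = counts.get(cls(p), 0) + 1

    out: list[Peptide] = []
    last_end: str | None = None
    while pending:
        pick = None
        for p in pending:
            end, starts_p = cls(p)
            if not _junction_cleavable(last_end, p.sequence[0], enzyme):
                continue
            if feasible({**counts, (end, starts_p): counts[(end, starts_p)] - 1}, end):
                pick = p
                break
        if pick is None:
            raise ValueError(
                "no peptide ordering avoids a suppressed junction in this chunk"
            )
        pending.remove(pick)
        counts[cls(pick)] -= 1
        out.append(pick)
        last_end = pick.sequence[-1]
    return out


def assemble_qconcat(
    peptides: list[Peptide],
    capacity: int = 50,
    tags: tuple[str, str] = ("", ""),
    spec: DigestSpec | None = None,
    id_prefix: str = "QC",
) -> list[QconCATConstruct]:
    """Pack peptides into ``ceil(n / capacity)`` validated constructs.

    Peptide order is preserved except for the minimal permutations needed to
    avoid junctions that digestion cannot cleave. Every returned construct
    passes :func:`validate_qconcat`.
    """
    if capacity < 2:
        raise ValueError("capacity must be >= 2")
    bad = [p.sequence for p in peptides if p.sequence[-1] not in "KR"]
    if bad:
        raise ValueError(f"peptides must end in K or R to be released: {bad[:5]}")
    spec = spec or DigestSpec(Enzyme.LYSC_THEN_TRYPSIN, 0)

    n_constructs = math.ceil(len(peptides) / capacity)
    n_term, c_term = tags
    constructs = []
    for i in range(n_constructs):
        chunk = peptides[i * capacity : (i + 1) * capacity]
        ordered = _order_for_junctions(chunk, spec.enzyme)
        construct = QconCATConstruct(
            construct_id=f"{id_prefix}{i + 1:03d}",
            peptides=tuple(ordered),
            n_term_tag=n_term,
            c_term_tag=c_term,
        )
        report = validate_qconcat(construct, spec)
        if not report.passed:
            not_released = [s for s, n in report.released.items() if n != 1]
            raise ValueError(
                f"construct {construct.construct_id} failed validation; "
                f"not released exactly once: {not_released[:5]}"
            )
        constructs.append(construct)
    return constructs
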