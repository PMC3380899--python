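"""Peptide and protein sequence chemistry.

In-silico tryptic digestion with modification-aware cleavage blocking,
monoisotopic mass computation, b/y fragment ladders, reversed-sequence decoy
databases, and precursor planning for targeted MS/MS inclusion lists.

Masses are monoisotopic throughout.  Residue masses come from the standard
amino-acid table (``pyteomics.mass.std_aa_mass``); the water and proton
constants are fixed so that a peptide's [M+H]+ is reproducible to four
decimal places against reference values computed the same way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pmass

WATER = 18.010565
PROTON = 1.00728

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}

TERMINUS = "-"  # sentinel for a protein terminus in flanking-residue context


@dataclass(frozen=True)
class ModificationSpec:
    """A site-localized mass modification.

    ``targets`` is the set of residue letters the modification may sit on.
    ``blocks_cleavage`` marks modifications (the Gly-Gly ubiquitin remnant,
    dimethylation) that prevent trypsin from cleaving after the modified
    residue, so a modified K/R behaves like an internal residue and does not
    consume the missed-cleavage budget.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    blocks_cleavage: bool = False


#: Registry of the modifications used throughout: the +114.0429 Da Gly-Gly
#: ubiquitin remnant, mono/dimethylation, Met oxidation, and the SILAC heavy
#: labels (Lys8 = 13C6 15N2, Arg10 = 13C6 15N4).
MODIFICATIONS: dict[str, ModificationSpec] = {
    "GG": ModificationSpec("GG", 114.0429, frozenset("K"), blocks_cleavage=True),
    # pseudo-GG: lysine dialkylated by iodoacetamide at high temperature,
    # mass-identical to the GG remnant (the external-reference premise)
    "dialkyl": ModificationSpec("dialkyl", 114.0429, frozenset("K"), blocks_cleavage=True),
    "Me1": ModificationSpec("Me1", 14.0156, frozenset("KR")),
    "Me2": ModificationSpec("Me2", 28.0313, frozenset("KR"), blocks_cleavage=True),
    "Ox": ModificationSpec("Ox", 15.9949, frozenset("M")),
    "Lys8": ModificationSpec("Lys8", 8.01420, frozenset("K")),
    "Arg10": ModificationSpec("Arg10", 10.00827, frozenset("R")),
}

LYS8_DELTA = MODIFICATIONS["Lys8"].delta_mass
ARG10_DELTA = MODIFICATIONS["Arg10"].delta_mass


class ChemistryError(ValueError):
    """Invalid sequence, modification placement, or unregistered modification."""


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ChemistryError("empty sequence")
    for ch in sequence:
        if ch not in RESIDUE_MASS:
            raise ChemistryError(f"unknown residue letter {ch!r} in {sequence!r}")


@dataclass
class Peptide:
    """A peptide with site-localized modifications and protein context.

    ``mods`` holds ``(position, spec)`` pairs with 1-based positions within
    the peptide.  ``start`` is the 1-based position of the first residue in
    the parent protein when known.
    """

    sequence: str
    mods: list[tuple[int, ModificationSpec]] = field(default_factory=list)
    preceding_residue: str = TERMINUS
    following_residue: str = TERMINUS
    protein_id: str | None = None
    start: int | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        for pos, spec in self.mods:
            if not (1 <= pos <= len(self.sequence)):
                raise ChemistryError(
                    f"mod {spec.name} position {pos} outside peptide {self.sequence!r}"
                )
            if self.sequence[pos - 1] not in spec.targets:
                raise ChemistryError(
                    f"mod {spec.name} targets {sorted(spec.targets)} but position "
                    f"{pos} of {self.sequence!r} is {self.sequence[pos - 1]!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int | None:
        """1-based position of the last residue in the parent protein."""
        return None if self.start is None else self.start + len(self.sequence) - 1


@dataclass(frozen=True)
class MassResult:
    """Neutral monoisotopic mass with [M+H]+ and per-charge m/z values."""

    neutral_mass: float
    mh: float
    mz_by_charge: dict[int, float]

    def mz(self, charge: int) -> float:
        return self.mz_by_charge[charge]


@dataclass(frozen=True)
class DigestRules:
    """Trypsin digestion rules: cleave after K/R, not before P."""

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    trypticity: str = "full"  # "full" | "partial"
    min_length: int = 6

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ChemistryError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ChemistryError("max_missed_cleavages must be >= 0")
        if self.trypticity not in ("full", "partial"):
            raise ChemistryError(f"trypticity must be 'full' or 'partial', got {self.trypticity!r}")


def cleavage_sites(sequence: str, blocked: frozenset[int] = frozenset()) -> list[int]:
    """0-based indices i such that trypsin cleaves between i and i+1.

    A site is K or R not followed by P; residues in ``blocked`` (0-based,
    carrying a cleavage-blocking modification) never cleave.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P" and i not in blocked
    ]


def digest(
    protein: str,
    rules: DigestRules = DigestRules(),
    mods: list[tuple[int, ModificationSpec]] | None = None,
    protein_id: str | None = None,
) -> list[Peptide]:
    """Tryptic digest of ``protein`` into :class:`Peptide` objects.

    ``mods`` are ``(position, spec)`` pairs with 1-based protein positions.
    A K/R carrying a cleavage-blocking modification never terminates a
    peptide and does not count toward the missed-cleavage budget; unmodified
    internal K/R do.  Peptides carry protein coordinates and flanking
    residues.  With ``trypticity="partial"`` peptides need only one tryptic
    terminus (a protein terminus counts as tryptic).
    """
    _validate_sequence(protein)
    mods = list(mods or [])
    for pos, spec in mods:
        if not (1 <= pos <= len(protein)) or protein[pos - 1] not in spec.targets:
            residue = protein[pos - 1] if 1 <= pos <= len(protein) else None
            raise ChemistryError(
                f"mod {spec.name} at protein position {pos} does not match a "
                f"target residue (found {residue!r})"
            )

    n = len(protein)
    blocked = frozenset(
        pos - 1 for pos, spec in mods if spec.blocks_cleavage and protein[pos - 1] in "KR"
    )
    sites = set(cleavage_sites(protein, blocked))
    # Tryptic start/end boundaries: 0-based start indices and exclusive ends.
    tryptic_starts = {0} | {i + 1 for i in sites}
    tryptic_ends = {n} | {i + 1 for i in sites}

    def missed(s: int, e: int) -> int:
        return sum(1 for i in range(s, e - 1) if i in sites)

    peptides: list[Peptide] = []
    for s in range(n):
        for e in range(s + rules.min_length, n + 1):
            start_ok = s in tryptic_starts
            end_ok = e in tryptic_ends
            if rules.trypticity == "full":
                if not (start_ok and end_ok):
                    continue
            else:
                if not (start_ok or end_ok):
                    continue
            if missed(s, e) > rules.max_missed_cleavages:
                continue
            pep_mods = [
                (pos - s, spec) for pos, spec in mods if s + 1 <= pos <= e
            ]
            peptides.append(
                Peptide(
                    sequence=protein[s:e],
                    mods=sorted(pep_mods),
                    preceding_residue=protein[s - 1] if s > 0 else TERMINUS,
                    following_residue=protein[e] if e < n else TERMINUS,
                    protein_id=protein_id,
                    start=s + 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def _mass_result(neutral: float, charges: tuple[int, ...]) -> MassResult:
    return MassResult(
        neutral_mass=neutral,
        mh=neutral + PROTON,
        mz_by_charge={z: (neutral + z * PROTON) / z for z in charges},
    )


def monoisotopic_mass(peptide: Peptide, charges: tuple[int, ...] = (1, 2, 3, 4)) -> MassResult:
    """Neutral/[M+H]+/per-charge monoisotopic mass of a modified peptide."""
    neutral = sum(RESIDUE_MASS[aa] for aa in peptide.sequence) + WATER
    for _pos, spec in peptide.mods:
        if MODIFICATIONS.get(spec.name) is None:
            raise ChemistryError(f"unregistered modification {spec.name!r}")
        neutral += spec.delta_mass
    return _mass_result(neutral, charges)


def heavy_partner_mass(peptide: Peptide, charges: tuple[int, ...] = (1, 2, 3, 4)) -> MassResult:
    """Mass of the SILAC heavy partner: +8.01420 per K and +10.00827 per R."""
    light = monoisotopic_mass(peptide, charges)
    n_k = peptide.sequence.count("K")
    n_r = peptide.sequence.count("R")
    neutral = light.neutral_mass + n_k * LYS8_DELTA + n_r * ARG10_DELTA
    return _mass_result(neutral, charges)


def fragment_ladder(
    peptide: Peptide,
    ion_types: tuple[str, ...] = ("b", "y"),
    max_charge: int = 1,
) -> list[tuple[str, float]]:
    """b/y fragment ion m/z ladder for a modified peptide.

    b_i covers the first i residues (plus their modifications); y_j the last
    j residues plus water.  Multiply-charged variants follow
    ``(neutral + z*proton)/z``.  Labels are ``b3``, ``y5``, with ``^z``
    appended for z > 1.
    """
    if len(peptide.sequence) < 2:
        raise ChemistryError("fragment ladder requires peptide length >= 2")
    for t in ion_types:
        if t not in ("b", "y"):
            raise ChemistryError(f"unsupported ion type {t!r}")
    n = len(peptide.sequence)
    residue = [RESIDUE_MASS[aa] for aa in peptide.sequence]
    mod_at = [0.0] * n
    for pos, spec in peptide.mods:
        mod_at[pos - 1] += spec.delta_mass
    prefix = [0.0]
    for i in range(n):
        prefix.append(prefix[-1] + residue[i] + mod_at[i])
    out: list[tuple[str, float]] = []
    for i in range(1, n):
        if "b" in ion_types:
            neutral = prefix[i]
            for z in range(1, max_charge + 1):
                label = f"b{i}" if z == 1 else f"b{i}^{z}"
                out.append((label, (neutral + z * PROTON) / z))
        if "y" in ion_types:
            j = n - i
            neutral = prefix[n] - prefix[i] + WATER
            for z in range(1, max_charge + 1):
                label = f"y{j}" if z == 1 else f"y{j}^{z}"
                out.append((label, (neutral + z * PROTON) / z))
    return out


def reverse_decoy_database(fasta_in: str, fasta_out: str, prefix: str = "REV_") -> int:
    """Write a concatenated target+decoy FASTA; returns the entry count.

    Every original entry is followed (after all targets) by its full
    reversal under a ``REV_``-prefixed identifier, doubling the entry count
    and preserving per-entry length and composition.
    """
    records = list(SeqIO.parse(fasta_in, "fasta"))
    if not records:
        raise ChemistryError(f"no FASTA entries in {fasta_in!r}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ChemistryError(f"duplicate FASTA identifiers: {dupes}")
    decoys = [
        SeqRecord(Seq(str(r.seq)[::-1]), id=prefix + r.id, description="decoy")
        for r in records
    ]
    count = SeqIO.write(records + decoys, fasta_out, "fasta")
    return count


def is_decoy_id(identifier: str, prefix: str = "REV_") -> bool:
    return identifier.startswith(prefix)


@dataclass(frozen=True)
class InclusionPlan:
    """Elution-ordered precursor segments for a targeted MS/MS method."""

    segments: list[list[tuple[Peptide, float]]]
    charge: int
    isolation_width: float


def plan_inclusion_list(
    peptides: list[Peptide],
    charge: int = 2,
    isolation_width: float = 1.7,
    segment_size: int = 4,
) -> InclusionPlan:
    """Group peptides (given in elution order) into targeted-method segments.

    The isolation window for each precursor is centered 0.50 m/z above the
    monoisotopic m/z at the requested charge (rounded to 2 dp), which places
    the window over the isotope envelope of a 2+ tryptic peptide.
    """
    if charge < 1:
        raise ChemistryError("charge must be >= 1")
    if segment_size < 1:
        raise ChemistryError("segment_size must be >= 1")
    entries = [
        (p, round(monoisotopic_mass(p, charges=(charge,)).mz(charge) + 0.50, 2))
        for p in peptides
    ]
    segments = [entries[i : i + segment_size] for i in range(0, len(entries), segment_size)]
    return InclusionPlan(segments=segments, charge=charge, isolation_width=isolation_width)


# ---------------------------------------------------------------------------
# Peptide notation: "X.PEPTIDE.Z" with bracketed modification tags, e.g.
# "K.TGHSK[GG]GFGFVR.F" or "K.TGHSK[+114.0429]GFGFVR.F".

_BRACKET = re.compile(r"\[([^\]]+)\]")


def _resolve_mod(tag: str, residue: str) -> ModificationSpec:
    if tag in MODIFICATIONS:
        return MODIFICATIONS[tag]
    if tag.startswith(("+", "-")):
        delta = float(tag)
        for spec in MODIFICATIONS.values():
            if abs(spec.delta_mass - delta) < 1e-3 and residue in spec.targets:
                return spec
        raise ChemistryError(f"no registered modification with delta {delta} on {residue!r}")
    raise ChemistryError(f"unregistered modification {tag!r}")


def parse_flanked(notation: str) -> Peptide:
    """Parse ``X.PEPTIDE.Z`` notation with bracketed modification tags."""
    # Flanks are single characters: strip a leading "X." and trailing ".Z"
    # so that mass offsets like "[+114.0429]" keep their decimal points.
    prev, core, nxt = TERMINUS, notation, TERMINUS
    if len(core) > 2 and core[1] == ".":
        prev, core = core[0], core[2:]
    if len(core) > 2 and core[-2] == ".":
        core, nxt = core[:-2], core[-1]
    if not core:
        raise ChemistryError(f"cannot parse peptide notation {notation!r}")
    sequence = ""
    mods: list[tuple[int, ModificationSpec]] = []
    i = 0
    while i < len(core):
        ch = core[i]
        if ch == "[":
            m = _BRACKET.match(core, i)
            if m is None or not sequence:
                raise ChemistryError(f"malformed modification tag in {notation!r}")
            mods.append((len(sequence), _resolve_mod(m.group(1), sequence[-1])))
            i = m.end()
        else:
            sequence += ch
            i += 1
    return Peptide(
        sequence=sequence,
        mods=mods,
        preceding_residue=prev or TERMINUS,
        following_residue=nxt or TERMINUS,
    )


def format_flanked(peptide: Peptide) -> str:
    by_pos: dict[int, list[str]] = {}
    for pos, spec in peptide.mods:
        by_pos.setdefault(pos, []).append(spec.name)
    core = "".join(
        aa + "".join(f"[{name}]" for name in by_pos.get(i + 1, []))
        for i, aa in enumerate(peptide.sequence)
    )
    return f"{peptide.preceding_residue}.{core}.{peptide.following_residue}"
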