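"""Residue alphabets and exact integer mass arithmetic.

All masses in this package are integers in micro-Daltons (µDa, 1 µDa =
10⁻⁶ Da).  Exact integer arithmetic makes composition masses, histogram
bin indices and duplicate-job detection bit-exact: two isomeric prefixes
(e.g. Gly-Gly-Val vs Ala-Ala-Ala) yield the *same* integer prefix mass,
a guarantee floating-point residue tables cannot give.

The default alphabet is the 20 standard amino-acid residues.  Residue
masses are computed from elemental formulas and monoisotopic atomic
masses, then rounded to 6 decimals (1 µDa); they are not hard-coded.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

UDA_PER_DA = 10**6


class AacompError(Exception):
    """Base class for all errors raised by this package."""


class AlphabetFormatError(AacompError):
    """Malformed alphabet/caps TSV input."""


class ConfigurationError(AacompError):
    """Inconsistent run configuration (bin widths, weighting, job params...)."""


# --- element masses and residue formulas ------------------------------------

#: Monoisotopic atomic masses in Daltons (CODATA/AME values), kept as exact
#: decimal fractions so residue masses round deterministically to 1 µDa.
MONOISOTOPIC_ATOM_DA = {
    "C": Fraction("12"),
    "H": Fraction("1.00782503207"),
    "N": Fraction("14.0030740048"),
    "O": Fraction("15.9949146196"),
    "S": Fraction("31.9720711744"),
}

#: Elemental composition of each amino-acid *residue* (amino acid minus water).
RESIDUE_FORMULAS = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 2},
}


def _round_half_up(x: Fraction) -> int:
    """Round an exact fraction to the nearest integer, ties away from zero-up."""
    return math.floor(x + Fraction(1, 2))


def formula_mass_uda(formula: dict) -> int:
    """Monoisotopic mass of an elemental formula in integer µDa."""
    total = sum(MONOISOTOPIC_ATOM_DA[el] * n for el, n in formula.items())
    return _round_half_up(total * UDA_PER_DA)


#: Monoisotopic mass of water (added once per intact peptide), µDa.
WATER_UDA = formula_mass_uda({"H": 2, "O": 1})
#: Mass of a proton (for [M+H]+), µDa.
PROTON_UDA = _round_half_up(Fraction("1.00727646688") * UDA_PER_DA)

#: Named adduct presets for the per-composition additive mass.
ADDUCT_PRESETS = {
    "none": 0,
    "water": WATER_UDA,
    "water+proton": WATER_UDA + PROTON_UDA,
}


def da_to_uda(text: str) -> int:
    """Convert a decimal Dalton string to integer µDa by exact decimal scaling.

    Raises :class:`AlphabetFormatError` if the value carries more than six
    decimal places (it would not be representable at 1 µDa resolution).
    Never round-trips through binary floating point.
    """
    try:
        value = Fraction(text.strip()) * UDA_PER_DA
    except (ValueError, ZeroDivisionError) as exc:
        raise AlphabetFormatError(f"not a decimal mass: {text!r}") from exc
    if value.denominator != 1:
        raise AlphabetFormatError(
            f"mass {text!r} has more than 6 decimal places"
        )
    return int(value)


def uda_to_da_str(uda: int, decimals: int = 6) -> str:
    """Render an integer µDa mass as a decimal Dalton string, exactly."""
    if decimals < 0 or decimals > 6:
        raise ValueError("decimals must be in 0..6")
    sign = "-" if uda < 0 else ""
    uda = abs(uda)
    whole, frac = divmod(uda, UDA_PER_DA)
    digits = f"{frac:06d}"[:decimals] if decimals else ""
    return f"{sign}{whole}.{digits}" if digits else f"{sign}{whole}"


# --- core types --------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    """A single alphabet letter with its monoisotopic residue mass in µDa."""

    letter: str
    mass: int

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isprintable():
            raise AlphabetFormatError(
                f"residue letter must be one printable character: {self.letter!r}"
            )
        if self.mass <= 0:
            raise AlphabetFormatError(
                f"residue {self.letter!r} has non-positive mass {self.mass}"
            )


class Alphabet:
    """An ordered residue set, sorted ascending by mass (ties by letter).

    The ascending-mass ordering is part of the public contract: the
    enumeration recursion indexes residues by position, and the
    branch-and-bound mass pruning is only sound because every residue at
    or after the current index is at least as heavy.
    """

    __slots__ = ("_residues", "_masses", "_index")

    def __init__(self, residues: Iterable[Residue]):
        res = sorted(residues, key=lambda r: (r.mass, r.letter))
        if not res:
            raise AlphabetFormatError("alphabet must contain at least one residue")
        letters = [r.letter for r in res]
        if len(set(letters)) != len(letters):
            dup = sorted({l for l in letters if letters.count(l) > 1})
            raise AlphabetFormatError(f"duplicate letter(s) in alphabet: {dup}")
        self._residues: Tuple[Residue, ...] = tuple(res)
        self._masses: Tuple[int, ...] = tuple(r.mass for r in res)
        self._index = {r.letter: i for i, r in enumerate(res)}

    # pickling support (needed to ship alphabets to worker processes)
    def __reduce__(self):
        return (Alphabet, (list(self._residues),))

    @property
    def residues(self) -> Tuple[Residue, ...]:
        return self._residues

    @property
    def masses(self) -> Tuple[int, ...]:
        """Residue masses in µDa, ascending (the paper-style ``aam`` array)."""
        return self._masses

    @property
    def letters(self) -> Tuple[str, ...]:
        return tuple(r.letter for r in self._residues)

    @property
    def size(self) -> int:
        return len(self._residues)

    def __len__(self) -> int:
        return len(self._residues)

    def __contains__(self, letter: str) -> bool:
        return letter in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self._residues == other._residues

    def __hash__(self) -> int:
        return hash(self._residues)

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.letters)})"

    def index(self, letter: str) -> int:
        """0-based position of a letter in mass order."""
        try:
            return self._index[letter]
        except KeyError:
            raise KeyError(f"letter {letter!r} not in alphabet") from None

    def mass_of(self, letter: str) -> int:
        return self._masses[self.index(letter)]

    def without(self, letters: Iterable[str]) -> "Alphabet":
        """A reduced alphabet with the given letters removed."""
        drop = set(letters)
        return Alphabet(r for r in self._residues if r.letter not in drop)

    def digest(self) -> str:
        """SHA-256 over the canonical ``letter:mass`` listing (manifest id)."""
        payload = "\n".join(f"{r.letter}:{r.mass}" for r in self._residues)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class MassConfig:
    """Additive adduct, histogram bin width and optional mass ceiling, all µDa.

    ``adduct`` is added once per composition (0 for the bare residue sum;
    water for the intact peptide; water+proton for [M+H]+).  ``mass_max``,
    when set, bounds ``residue sum + adduct``.
    """

    adduct: int = 0
    bin_width: int = 1000  # 0.001 Da
    mass_max: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ConfigurationError("bin_width must be >= 1 µDa")
        if self.adduct < 0:
            raise ConfigurationError("adduct must be >= 0")
        if self.mass_max is not None and self.mass_max < self.adduct:
            raise ConfigurationError("mass_max must be >= adduct")


# --- operations --------------------------------------------------------------


@lru_cache(maxsize=1)
def default_alphabet() -> Alphabet:
    """The 20 standard amino-acid residues, masses from elemental formulas.

    Sorted ascending by mass; the five lightest are G, A, S, P, V.
    Leucine and isoleucine are isobaric; the mass tie is broken
    alphabetically (I before L).
    """
    return Alphabet(
        Residue(letter, formula_mass_uda(formula))
        for letter, formula in RESIDUE_FORMULAS.items()
    )


ALPHABET_TSV_HEADER = ("letter", "mass_da")


def load_alphabet(path: Union[str, Path]) -> Alphabet:
    """Read an alphabet TSV (``letter<TAB>mass_da``, '#' comments allowed).

    Masses are decimal Daltons with at most six decimals and are converted
    to integer µDa exactly.  Errors report the offending line number.
    """
    path = Path(path)
    residues: List[Residue] = []
    seen = {}
    header_done = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_done:
                if tuple(f.strip() for f in fields) != ALPHABET_TSV_HEADER:
                    raise AlphabetFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'letter<TAB>mass_da', got {line!r}"
                    )
                header_done = True
                continue
            if len(fields) != 2:
                raise AlphabetFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            letter = fields[0].strip()
            if letter in seen:
                raise AlphabetFormatError(
                    f"{path}:{lineno}: duplicate letter {letter!r} "
                    f"(first seen on line {seen[letter]})"
                )
            try:
                residue = Residue(letter, da_to_uda(fields[1]))
            except AlphabetFormatError as exc:
                raise AlphabetFormatError(f"{path}:{lineno}: {exc}") from None
            seen[letter] = lineno
            residues.append(residue)
    if not header_done:
        raise AlphabetFormatError(f"{path}: missing 'letter<TAB>mass_da' header")
    return Alphabet(residues)


def write_alphabet(alphabet: Alphabet, path: Union[str, Path]) -> None:
    """Write an alphabet TSV that :func:`load_alphabet` reads back exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("letter\tmass_da\n")
        for r in alphabet.residues:
            fh.write(f"{r.letter}\t{uda_to_da_str(r.mass)}\n")


def composition_mass(
    counts: Sequence[int], alphabet: Alphabet, cfg: Optional[MassConfig] = None
) -> int:
    """Exact composition mass Σ nᵢ·mᵢ + adduct, in integer µDa."""
    if len(counts) != alphabet.size:
        raise ValueError(
            f"count vector has length {len(counts)}, alphabet size is "
            f"{alphabet.size}"
        )
    adduct = cfg.adduct if cfg is not None else 0
    return sum(n * m for n, m in zip(counts, alphabet.masses)) + adduct


@dataclass(frozen=True)
class TrypticVariant:
    """One K/R multiset choice of a tryptic composition.

    A tryptic composition with ``c`` missed cleavages contains exactly
    ``c+1`` residues from {K, R}; the remaining residues come from the
    18-letter reduced alphabet.  ``offset_mass``/``offset_length`` are the
    fixed contribution of the K/R multiset.
    """

    alphabet: Alphabet
    offset_mass: int
    offset_length: int
    label: str


def tryptic_variants(
    alphabet: Alphabet, missed_cleavages: int = 0
) -> List[TrypticVariant]:
    """K/R multiset variants for tryptic compositions.

    With ``c`` missed cleavages there are ``c+2`` variants, one per
    multiset {j×K, (c+1−j)×R}.  Positional constraints (C-terminal K/R)
    do not affect composition counting and are ignored.
    """
    if missed_cleavages < 0:
        raise ConfigurationError("missed_cleavages must be >= 0")
    for needed in "KR":
        if needed not in alphabet:
            raise ConfigurationError(
                f"tryptic mode requires residue {needed!r} in the alphabet"
            )
    m_k = alphabet.mass_of("K")
    m_r = alphabet.mass_of("R")
    reduced = alphabet.without("KR")
    n_term = missed_cleavages + 1
    variants = []
    for j in range(n_term + 1):  # j copies of K, n_term - j copies of R
        variants.append(
            TrypticVariant(
                alphabet=reduced,
                offset_mass=j * m_k + (n_term - j) * m_r,
                offset_length=n_term,
                label="K" * j + "R" * (n_term - j),
            )
        )
    return variants


def tryptic_max_length(
    alphabet: Alphabet,
    mass_max_uda: int,
    missed_cleavages: int = 0,
    adduct_uda: int = WATER_UDA,
) -> int:
    """Longest tryptic composition whose peptide mass fits under a ceiling.

    Maximizes total length over the K/R variants by filling the remaining
    budget with the lightest reduced-alphabet residue (glycine for the
    default alphabet).  Returns -1 if not even the bare K/R multiset fits.
    """
    best = -1
    for var in tryptic_variants(alphabet, missed_cleavages):
        budget = mass_max_uda - adduct_uda - var.offset_mass
        if budget < 0:
            continue
        lightest = var.alphabet.masses[0]
        best = max(best, var.offset_length + budget // lightest)
    return best
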