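"""Monoisotopic mass arithmetic for (nitro)peptidoforms.

Residue and atomic monoisotopic masses come from pyteomics; everything
built on top of them — modification deltas from elemental formulas,
peptidoform neutral masses, precursor m/z, and b/y fragment series with
modification-aware localization — lives here.

Masses are kept at full precision internally (>= 6 decimals); rounding to
the 3 decimals conventionally printed for modification deltas happens only
at display or comparison time, because fragment matching at 0.01 Da cannot
afford accumulated rounding error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "PROTEIN_N_TERMINUS",
    "ConfigurationError",
    "InputError",
    "ModificationDefinition",
    "Peptidoform",
    "FragmentIon",
    "DEFAULT_MODIFICATIONS",
    "delta_mass_from_formula",
    "peptidoform_mass",
    "precursor_mz",
    "fragment_series",
    "load_modifications",
]


class ConfigurationError(ValueError):
    """A modification/element configuration problem (unknown element, bad target set)."""


class InputError(ValueError):
    """Invalid user input (unknown residue, bad charge, ill-formed peptidoform)."""


#: Charge carrier (proton) monoisotopic mass, Da.
PROTON_MASS = 1.007276466879
#: Water monoisotopic mass, Da (peptide bond condensation partner).
WATER_MASS = _pmass.calculate_mass(formula="H2O")

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES
}

#: Target token for protein-N-terminal modifications (e.g. acetylation).
PROTEIN_N_TERMINUS = "protein-N-term"

_FORMULA_TOKEN = re.compile(r"([+-]?)(\d*)([A-Z][a-z]?)(-?\d+)?")


def _monoisotopic(element: str) -> float:
    try:
        return _pmass.nist_mass[element][0][0]
    except KeyError:
        raise ConfigurationError(f"unknown element symbol: {element!r}") from None


def delta_mass_from_formula(formula: str | Mapping[str, int]) -> float:
    """Signed monoisotopic mass shift (Da) of an elemental composition.

    ``formula`` is either a mapping ``{element: signed count}`` or a string of
    signed tokens, e.g. ``"N O2 H-1"``, ``"+N +2O -H"`` or ``"C2H3NO"``.
    An empty formula is the identity (0.0 Da). The function is additive:
    the delta of a concatenated formula is the sum of the parts' deltas.
    """
    if isinstance(formula, Mapping):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        compact = re.sub(r"[\s,]", "", formula.replace("−", "-"))  # tolerate unicode minus
        pos = 0
        while pos < len(compact):
            m = _FORMULA_TOKEN.match(compact, pos)
            if not m or not m.group(3):
                raise ConfigurationError(
                    f"unparseable formula fragment: {compact[pos:]!r}"
                )
            sign, pre, element, post = m.groups()
            if pre and post:
                raise ConfigurationError(f"ambiguous count in token {m.group(0)!r}")
            n = int(pre or post or 1)
            if sign == "-":
                n = -n
            counts[element] = counts.get(element, 0) + n
            pos = m.end()
    return sum(count * _monoisotopic(el) for el, count in counts.items())


@dataclass(frozen=True)
class ModificationDefinition:
    """A named mass modification with its residue target set.

    ``targets`` holds one-letter residue codes and/or :data:`PROTEIN_N_TERMINUS`.
    ``variable`` distinguishes dynamic from static (always-applied) search
    modifications; the distinction is informational here — the pipeline works
    on explicitly localized peptidoforms.
    """

    name: str
    delta_mass: float
    targets: frozenset[str]
    variable: bool = True

    def __post_init__(self) -> None:
        if not self.targets:
            raise ConfigurationError(f"modification {self.name!r} has empty target set")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) < 1e6):
            raise ConfigurationError(f"modification {self.name!r} delta_mass not finite")

    @classmethod
    def from_formula(
        cls, name: str, formula: str, targets: Iterable[str], variable: bool = True
    ) -> "ModificationDefinition":
        return cls(name, delta_mass_from_formula(formula), frozenset(targets), variable)

    def applies_to(self, residue: str, peptide_position: int) -> bool:
        if residue in self.targets:
            return True
        return PROTEIN_N_TERMINUS in self.targets and peptide_position == 1


def _default_modifications() -> dict[str, ModificationDefinition]:
    return {
        m.name: m
        for m in (
            ModificationDefinition.from_formula("nitroY", "N O2 H-1", "Y"),
            ModificationDefinition.from_formula("oxidation", "O", "M"),
            ModificationDefinition.from_formula(
                "acetyl", "C2 H2 O", [PROTEIN_N_TERMINUS]
            ),
            ModificationDefinition.from_formula(
                "carbamidomethyl", "C2 H3 N O", "C", variable=False
            ),
        )
    }


#: The four modifications of the standard nitrotyrosine search space:
#: nitration of tyrosine, methionine oxidation, protein-N-terminal
#: acetylation, and static cysteine carbamidomethylation.
DEFAULT_MODIFICATIONS: Mapping[str, ModificationDefinition] = _default_modifications()


def load_modifications(path) -> dict[str, ModificationDefinition]:
    """Load modification definitions from a YAML config file.

    Each entry needs ``name``, ``targets`` and either ``formula`` or
    ``delta_mass``; ``variable`` defaults to true.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ConfigurationError("modification config must be a list of entries")
    mods = {}
    for e in entries:
        try:
            name = e["name"]
            targets = e["targets"]
        except (TypeError, KeyError) as exc:
            raise ConfigurationError(f"bad modification entry: {e!r}") from exc
        variable = bool(e.get("variable", True))
        if "formula" in e:
            mod = ModificationDefinition.from_formula(name, e["formula"], targets, variable)
        elif "delta_mass" in e:
            mod = ModificationDefinition(name, float(e["delta_mass"]), frozenset(targets), variable)
        else:
            raise ConfigurationError(f"modification {name!r} needs formula or delta_mass")
        mods[name] = mod
    return mods


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with localized modifications and a precursor charge.

    Modification positions are 1-based indices within the peptide; at most one
    modification per position. "N-terminal nitroY" means a nitroY modification
    at position 1.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or any(r not in RESIDUE_MASSES for r in seq):
            bad = sorted({r for r in seq if r not in RESIDUE_MASSES})
            raise InputError(f"sequence {seq!r} contains non-standard residues {bad}")
        mods = tuple(sorted((int(p), str(n)) for p, n in self.modifications))
        object.__setattr__(self, "modifications", mods)
        positions = [p for p, _ in mods]
        for p in positions:
            if not 1 <= p <= len(seq):
                raise InputError(
                    f"modification position {p} outside peptide 1..{len(seq)}"
                )
        if len(set(positions)) != len(positions):
            raise InputError("at most one modification per position")
        if self.charge < 1:
            raise InputError(f"charge must be >= 1, got {self.charge}")

    def validate_targets(
        self, mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS
    ) -> None:
        """Check every modification is defined and sits on an allowed residue."""
        for pos, name in self.modifications:
            if name not in mods:
                raise InputError(f"unknown modification {name!r}")
            residue = self.sequence[pos - 1]
            if not mods[name].applies_to(residue, pos):
                raise InputError(
                    f"modification {name!r} not allowed on residue "
                    f"{residue!r} at position {pos}"
                )

    @property
    def nitro_positions(self) -> tuple[int, ...]:
        return tuple(p for p, n in self.modifications if n == "nitroY")

    def proforma(self) -> str:
        """Compact text form, e.g. ``Y[nitroY]LTVAAVFR/2``."""
        out = []
        mods = dict(self.modifications)
        for i, r in enumerate(self.sequence, start=1):
            out.append(r)
            if i in mods:
                out.append(f"[{mods[i]}]")
        return "".join(out) + f"/{self.charge}"


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series backbone fragment with the modifications it carries."""

    series: str  # "b" | "y"
    ordinal: int
    charge: int
    mz: float
    modifications: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        z = "+" * self.charge
        return f"{self.series}{self.ordinal}{z if self.charge > 1 else ''}"


def _mod_deltas(
    p: Peptidoform, mods: Mapping[str, ModificationDefinition]
) -> list[tuple[int, str, float]]:
    p.validate_targets(mods)
    return [(pos, name, mods[name].delta_mass) for pos, name in p.modifications]


def peptidoform_mass(
    p: Peptidoform, mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS
) -> float:
    """Neutral monoisotopic mass (Da): residues + water + modification deltas."""
    return (
        sum(RESIDUE_MASSES[r] for r in p.sequence)
        + WATER_MASS
        + sum(d for _, _, d in _mod_deltas(p, mods))
    )


def precursor_mz(
    p: Peptidoform, mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS
) -> float:
    """Precursor m/z (Th) at the peptidoform's charge."""
    if p.charge < 1:
        raise InputError("precursor charge must be >= 1")
    return (peptidoform_mass(p, mods) + p.charge * PROTON_MASS) / p.charge


def fragment_series(
    p: Peptidoform,
    max_fragment_charge: int = 1,
    mods: Mapping[str, ModificationDefinition] = DEFAULT_MODIFICATIONS,
) -> list[FragmentIon]:
    """All b1..b(n-1) and y1..y(n-1) ions at charges 1..max_fragment_charge.

    A b_k ion carries exactly the modifications localized in the N-terminal k
    residues; y_k symmetrically carries those in the C-terminal k residues, so
    a modification's fragment-shift pattern localizes it.
    """
    n = len(p.sequence)
    if n < 2:
        raise InputError("fragmentation needs peptide length >= 2")
    if max_fragment_charge < 1:
        raise InputError("max_fragment_charge must be >= 1")
    deltas = _mod_deltas(p, mods)

    residue = [RESIDUE_MASSES[r] for r in p.sequence]
    mod_at = {pos: (name, d) for pos, name, d in deltas}

    # prefix[k] = neutral mass of N-terminal k residues incl. their mods
    prefix = [0.0]
    prefix_mods: list[tuple[str, ...]] = [()]
    acc, acc_mods = 0.0, []
    for i in range(1, n + 1):
        acc += residue[i - 1]
        if i in mod_at:
            name, d = mod_at[i]
            acc += d
            acc_mods.append(name)
        prefix.append(acc)
        prefix_mods.append(tuple(acc_mods))

    total = prefix[n]

    ions: list[FragmentIon] = []
    for series in ("b", "y"):
        for k in range(1, n):
            if series == "b":
                neutral = prefix[k]
                carried = prefix_mods[k]
            else:
                neutral = total - prefix[n - k] + WATER_MASS
                carried = tuple(name for pos, name, _ in deltas if pos > n - k)
            for z in range(1, max_fragment_charge + 1):
                ions.append(
                    FragmentIon(series, k, z, (neutral + z * PROTON_MASS) / z, carried)
                )
    return ions
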