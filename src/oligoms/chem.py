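"""Elemental-formula arithmetic, monomer registry and the sequence grammar.

The sequence grammar is vendor-style: one registry code per monomer
(``A``, ``T``, ``mC``, ``lG``, ``eG`` ...) joined by ``*`` (phosphorothioate)
or ``.`` (phosphodiester) linkage symbols, e.g. ``"lG*mC.A"``.  Terminal
chemistry defaults to 5'-OH / 3'-OH; alternate termini are registry-level
formula deltas.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .constants import MONOISOTOPIC_MASS


class ChemistryError(ValueError):
    """Raised when a finalized molecule would have a negative element count."""


class GrammarError(ValueError):
    """Raised on malformed sequence text."""


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map with group arithmetic.

    Counts may be negative transiently (loss bookkeeping); a negative count
    is only an error when the formula is finalized as a molecule via
    :meth:`finalize`.
    """

    counts: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_dict(d: dict[str, int]) -> "ElementalFormula":
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n != 0))
        return ElementalFormula(items)

    @staticmethod
    def parse(text: str) -> "ElementalFormula":
        """Parse a Hill-style string like ``"C10H13N5O3"`` (counts may be signed)."""
        counts: Counter[str] = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"unparseable formula {text!r} at offset {pos}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or "1")
        if pos != len(text):
            raise ValueError(f"unparseable formula {text!r} at offset {pos}")
        return ElementalFormula.from_dict(counts)

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = Counter(dict(self.counts))
        c.update(dict(other.counts))
        return ElementalFormula.from_dict(c)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        c = Counter(dict(self.counts))
        c.subtract(dict(other.counts))
        return ElementalFormula.from_dict(c)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __neg__(self) -> "ElementalFormula":
        return self * -1

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def is_valid(self) -> bool:
        return all(n >= 0 for _, n in self.counts)

    def finalize(self) -> "ElementalFormula":
        """Assert this formula describes a possible molecule (counts >= 0)."""
        if not self.is_valid:
            bad = {el: n for el, n in self.counts if n < 0}
            raise ChemistryError(f"impossible composition, negative counts: {bad}")
        return self

    def mass(self) -> float:
        """Monoisotopic mass in Da. Requires non-negative counts."""
        self.finalize()
        try:
            return sum(n * MONOISOTOPIC_MASS[el] for el, n in self.counts)
        except KeyError as exc:
            raise KeyError(f"unknown element symbol {exc.args[0]!r}") from None

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical)."""
        d = dict(self.counts)
        order = [el for el in ("C", "H") if el in d]
        order += sorted(el for el in d if el not in ("C", "H"))
        return "".join(f"{el}{d[el]}" if d[el] != 1 else el for el in order)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.hill() or "(empty)"


def formula_combine(
    a: ElementalFormula, b: ElementalFormula, sign: int = 1
) -> ElementalFormula:
    """Element-wise ``a + sign*b``. ``sign`` must be +1 or -1."""
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    return a + b if sign == 1 else a - b


def monoisotopic_mass(f: ElementalFormula) -> float:
    return f.mass()


# Common small molecules / deltas used throughout.
WATER = ElementalFormula.parse("H2O")
AMMONIA = ElementalFormula.parse("NH3")
TWO_H = ElementalFormula.parse("H2")
PO_LINKAGE = ElementalFormula.parse("HPO3")
PS_LINKAGE = ElementalFormula.parse("HPO2S")


# ---------------------------------------------------------------------------
# Monomers, linkages, registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Monomer:
    code: str
    label: str
    nucleobase: ElementalFormula
    nucleoside: ElementalFormula
    bridge: ElementalFormula = ElementalFormula()
    #: single-letter identity of the base for loss bookkeeping (A/T/G/C/...)
    base_code: str = ""

    def __post_init__(self) -> None:
        sugar = self.nucleoside - self.nucleobase
        if not sugar.is_valid:
            raise ChemistryError(
                f"monomer {self.code!r}: nucleoside minus base is not a sugar"
            )

    @property
    def formula(self) -> ElementalFormula:
        """Full (bridged) nucleoside composition."""
        return (self.nucleoside + self.bridge).finalize()


@dataclass(frozen=True)
class Linkage:
    kind: str  # "PO" | "PS"
    formula: ElementalFormula

    @staticmethod
    def po() -> "Linkage":
        return Linkage("PO", PO_LINKAGE)

    @staticmethod
    def ps() -> "Linkage":
        return Linkage("PS", PS_LINKAGE)

    @staticmethod
    def from_symbol(sym: str) -> "Linkage":
        if sym == "*":
            return Linkage.ps()
        if sym == ".":
            return Linkage.po()
        raise GrammarError(f"unknown linkage symbol {sym!r}")

    @property
    def symbol(self) -> str:
        return "*" if self.kind == "PS" else "."


# Free nucleobases (neutral BH form).
_ADENINE = ElementalFormula.parse("C5H5N5")
_GUANINE = ElementalFormula.parse("C5H5N5O")
_CYTOSINE = ElementalFormula.parse("C4H5N3O")
_THYMINE = ElementalFormula.parse("C5H6N2O2")
_5ME_CYTOSINE = ElementalFormula.parse("C5H7N3O")

# 2'-deoxyribose contribution within a nucleoside (nucleoside - free base).
_DEOXY_SUGAR = ElementalFormula.parse("C5H8O3")
#: LNA 2'-O,4'-C methylene bridge relative to the deoxy sugar.
LNA_BRIDGE = ElementalFormula.parse("CO")
#: cEt (constrained ethyl) bridge relative to the deoxy sugar.
CET_BRIDGE = ElementalFormula.parse("C2H2O")


def _dna(code: str, label: str, base: ElementalFormula, base_code: str) -> Monomer:
    return Monomer(code, label, base, base + _DEOXY_SUGAR, base_code=base_code)


_BUILTIN_MONOMERS: list[Monomer] = [
    _dna("A", "2'-deoxyadenosine", _ADENINE, "A"),
    _dna("C", "2'-deoxycytidine", _CYTOSINE, "C"),
    _dna("G", "2'-deoxyguanosine", _GUANINE, "G"),
    _dna("T", "thymidine", _THYMINE, "T"),
    _dna("mC", "5-methyl-2'-deoxycytidine", _5ME_CYTOSINE, "mC"),
]
# LNA ("l" prefix) and cEt ("e" prefix) variants of every built-in monomer.
for _m in list(_BUILTIN_MONOMERS):
    _BUILTIN_MONOMERS.append(
        Monomer(
            "l" + _m.code, "LNA " + _m.label, _m.nucleobase, _m.nucleoside,
            LNA_BRIDGE, base_code=_m.base_code,
        )
    )
    _BUILTIN_MONOMERS.append(
        Monomer(
            "e" + _m.code, "cEt " + _m.label, _m.nucleobase, _m.nucleoside,
            CET_BRIDGE, base_code=_m.base_code,
        )
    )


@dataclass
class MonomerRegistry:
    """Code -> Monomer map. User JSON entries override the built-ins."""

    entries: dict[str, Monomer] = field(default_factory=dict)
    source: str | None = None

    @staticmethod
    def default() -> "MonomerRegistry":
        return MonomerRegistry({m.code: m for m in _BUILTIN_MONOMERS})

    @staticmethod
    def from_json(path: str | Path) -> "MonomerRegistry":
        """Load a registry from JSON, layered on top of the built-ins.

        Schema per entry: ``{code, name, base_formula, nucleoside_formula,
        bridge_delta?, base_code?}`` with formulas as Hill strings.
        """
        reg = MonomerRegistry.default()
        data = json.loads(Path(path).read_text())
        for entry in data:
            mono = Monomer(
                code=entry["code"],
                label=entry.get("name", entry["code"]),
                nucleobase=ElementalFormula.parse(entry["base_formula"]),
                nucleoside=ElementalFormula.parse(entry["nucleoside_formula"]),
                bridge=ElementalFormula.parse(entry.get("bridge_delta", "")),
                base_code=entry.get("base_code", entry["code"]),
            )
            reg.entries[mono.code] = mono
        reg.source = str(path)
        return reg

    def __getitem__(self, code: str) -> Monomer:
        try:
            return self.entries[code]
        except KeyError:
            raise GrammarError(f"unknown monomer code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.entries


# ---------------------------------------------------------------------------
# Oligo model and the sequence grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Oligo:
    monomers: tuple[Monomer, ...]
    linkages: tuple[Linkage, ...]
    five_prime_term: ElementalFormula = ElementalFormula()
    three_prime_term: ElementalFormula = ElementalFormula()

    def __post_init__(self) -> None:
        if len(self.monomers) == 0:
            raise GrammarError("empty oligo")
        if len(self.linkages) != len(self.monomers) - 1:
            raise GrammarError("need exactly n-1 linkages for n monomers")

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def formula(self) -> ElementalFormula:
        """Neutral composition: nucleosides + linkages - (n-1) water + termini."""
        f = ElementalFormula()
        for m in self.monomers:
            f = f + m.formula
        for lk in self.linkages:
            f = f + lk.formula
        f = f - WATER * (len(self) - 1)
        f = f + self.five_prime_term + self.three_prime_term
        return f.finalize()

    def mass(self) -> float:
        return self.formula.mass()

    def serialize(self) -> str:
        parts = [self.monomers[0].code]
        for lk, m in zip(self.linkages, self.monomers[1:]):
            parts.append(lk.symbol)
            parts.append(m.code)
        return "".join(parts)


def parse_sequence(text: str, registry: MonomerRegistry | None = None) -> Oligo:
    """Parse grammar text (``"lG*mC.A"``) into an :class:`Oligo`."""
    registry = registry or MonomerRegistry.default()
    text = text.strip()
    if not text:
        raise GrammarError("empty sequence")
    monomers: list[Monomer] = []
    linkages: list[Linkage] = []
    token = ""
    expecting_monomer = True
    for ch in text:
        if ch in "*.":
            if not token:
                raise GrammarError(f"dangling linkage symbol in {text!r}")
            monomers.append(registry[token])
            linkages.append(Linkage.from_symbol(ch))
            token = ""
            expecting_monomer = True
        elif ch.isspace():
            raise GrammarError(f"whitespace inside sequence {text!r}")
        else:
            token += ch
            if token in registry:
                # Greedy-longest: only commit when the next char forces it;
                # handled by trying to extend below.
                expecting_monomer = False
            # Multi-char codes accumulate; validity checked on commit.
    if expecting_monomer or not token:
        raise GrammarError(f"sequence {text!r} ends with a dangling linkage")
    monomers.append(registry[token])
    return Oligo(tuple(monomers), tuple(linkages))


def neutral_mass(o: Oligo) -> float:
    return o.mass()


def mz_of(neutral: float, z: int) -> float:
    """m/z of the [M - zH]^z- deprotonated anion."""
    from .constants import PROTON_MASS

    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral - z * PROTON_MASS) / z
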