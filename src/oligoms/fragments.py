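"""Theoretical fragment-ion generation for modified oligonucleotides.

Terminal ions follow the standard backbone-cleavage nomenclature: cleavage
between monomer ``i`` and ``i+1`` yields 5'-side ions a/b/c/d (index = number
of monomers retained from the 5' end) and 3'-side ions w/x/y/z (index =
monomers retained from the 3' end).  End chemistry is chosen so that every
complementary pair sums exactly to the neutral precursor mass:

    b_i = prefix_i            a_i = b_i - H2O
    d_i = b_i + linkage_i     c_i = d_i - H2O
    y_k = suffix_k            z_k = y_k - H2O
    w_k = y_k + linkage_{n-k} x_k = w_k - H2O

so  a_i + w_{n-i} = b_i + x_{n-i} = c_i + y_{n-i} = d_i + z_{n-i} = M.

Internal (J) fragments contain neither terminus: a 5'-side w/x/y/z-type
cleavage after monomer ``i`` plus a 3'-side a/b/c/d-type cleavage after
monomer ``j`` retains monomers ``i+1..j``.  Isomeric style combinations
(aw/bx and cy/dz coincide in composition) are grouped under one J candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import (
    AMMONIA,
    TWO_H,
    WATER,
    ChemistryError,
    ElementalFormula,
    Oligo,
    mz_of,
)

ION_TYPES_5P = ("a", "b", "c", "d")
ION_TYPES_3P = ("w", "x", "y", "z")
ION_TYPES = ION_TYPES_5P + ION_TYPES_3P

#: named internal cleavage-style pairs (5'-side type, 3'-side type)
NAMED_INTERNAL_PAIRS = (("w", "a"), ("x", "b"), ("y", "c"), ("z", "d"))


@dataclass(frozen=True)
class LossSpec:
    label: str
    formula: ElementalFormula
    kind: str = "neutral"  # neutral | base | charged_base

    @staticmethod
    def water() -> "LossSpec":
        return LossSpec("H2O", WATER)

    @staticmethod
    def ammonia() -> "LossSpec":
        return LossSpec("NH3", AMMONIA)

    @staticmethod
    def two_h() -> "LossSpec":
        return LossSpec("2H", TWO_H)


DEFAULT_NEUTRAL_LOSSES = (LossSpec.water(), LossSpec.ammonia(), LossSpec.two_h())


@dataclass(frozen=True)
class AdductSpec:
    label: str
    formula_delta: ElementalFormula

    @staticmethod
    def sodium() -> "AdductSpec":
        return AdductSpec("+Na", ElementalFormula.parse("Na") - ElementalFormula.parse("H"))

    @staticmethod
    def potassium() -> "AdductSpec":
        return AdductSpec("+K", ElementalFormula.parse("K") - ElementalFormula.parse("H"))


@dataclass(frozen=True)
class FragmentIon:
    """A neutral fragment species, optionally charged (negative mode implied)."""

    ion_type: str  # a|b|c|d|w|x|y|z|J|precursor
    index: int | tuple[int, int] | None
    formula: ElementalFormula
    losses: tuple[LossSpec, ...] = ()
    adducts: tuple[AdductSpec, ...] = ()
    charge: int = 0  # 0 = neutral species (not yet charge-enumerated)
    #: alternative style assignments for grouped internal candidates
    variants: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        if self.ion_type == "precursor":
            base = "M"
        elif self.ion_type == "J":
            i, j = self.index  # type: ignore[misc]
            styles = ",".join(self.variants) if self.variants else "J"
            base = f"J({i},{j})[{styles}]"
        else:
            base = f"{self.ion_type}{self.index}"
        for loss in self.losses:
            base += f"-{loss.label}"
        for ad in self.adducts:
            base += ad.label
        if self.charge:
            base += f" {self.charge}-"
        return base

    def neutral_mass(self) -> float:
        return self.formula.mass()

    @property
    def mz(self) -> float:
        if self.charge < 1:
            raise ValueError("neutral species has no m/z; enumerate charges first")
        return mz_of(self.neutral_mass(), self.charge)

    def key(self) -> tuple:
        return (
            self.ion_type,
            self.index,
            tuple(l.label for l in self.losses),
            tuple(a.label for a in self.adducts),
            self.charge,
        )


def _prefix_formulas(o: Oligo) -> list[ElementalFormula]:
    """prefix_i = first i nucleosides + i-1 linkages - (i-1) water + 5' term."""
    out = []
    f = o.five_prime_term
    for i, m in enumerate(o.monomers, start=1):
        f = f + m.formula
        if i > 1:
            f = f + o.linkages[i - 2].formula - WATER
        out.append(f)
    return out


def _suffix_formulas(o: Oligo) -> list[ElementalFormula]:
    """suffix_k = last k nucleosides + k-1 linkages - (k-1) water + 3' term."""
    n = len(o)
    out = []
    f = o.three_prime_term
    for k in range(1, n + 1):
        f = f + o.monomers[n - k].formula
        if k > 1:
            f = f + o.linkages[n - k].formula - WATER
        out.append(f)
    return out


def fragment_span(ion: FragmentIon, n: int) -> tuple[int, int]:
    """1-based inclusive monomer span retained by *ion* in a length-n oligo."""
    if ion.ion_type == "precursor":
        return (1, n)
    if ion.ion_type == "J":
        return ion.index  # type: ignore[return-value]
    if ion.ion_type in ION_TYPES_5P:
        return (1, ion.index)  # type: ignore[return-value]
    return (n - ion.index + 1, n)  # type: ignore[operator]


def terminal_fragments(o: Oligo) -> list[FragmentIon]:
    """All 8 terminal ion types at all n-1 cleavage positions (neutral)."""
    n = len(o)
    if n < 2:
        raise ValueError("need at least 2 monomers to fragment")
    prefixes = _prefix_formulas(o)
    suffixes = _suffix_formulas(o)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        b = prefixes[i - 1]
        d = b + o.linkages[i - 1].formula
        ions.append(FragmentIon("a", i, b - WATER))
        ions.append(FragmentIon("b", i, b))
        ions.append(FragmentIon("c", i, d - WATER))
        ions.append(FragmentIon("d", i, d))
    for k in range(1, n):
        y = suffixes[k - 1]
        w = y + o.linkages[n - k - 1].formula
        ions.append(FragmentIon("w", k, w))
        ions.append(FragmentIon("x", k, w - WATER))
        ions.append(FragmentIon("y", k, y))
        ions.append(FragmentIon("z", k, y - WATER))
    return ions


def precursor_ion(o: Oligo) -> FragmentIon:
    return FragmentIon("precursor", None, o.formula)


def internal_fragments(o: Oligo, pairs: str = "named") -> list[FragmentIon]:
    """Internal (J) candidates for every interior span, grouped by composition.

    ``pairs="named"`` uses the four aw/bx/cy/dz style pairs; ``"full"``
    crosses all 4x4 end-chemistry combinations.
    """
    n = len(o)
    if n < 3:
        return []
    if pairs == "named":
        combos = NAMED_INTERNAL_PAIRS
    elif pairs == "full":
        combos = tuple(
            (l, r) for l in ION_TYPES_3P for r in ION_TYPES_5P
        )
    else:
        raise ValueError("pairs must be 'named' or 'full'")

    # End-chemistry deltas relative to the bare span composition
    # (span nucleosides + internal linkages - internal waters; OH both ends).
    # 5'-side (from the 3'-ion chemistry of the cleavage after monomer i):
    #   w: + linkage_i ; x: + linkage_i - H2O ; y: -0 ; z: - H2O
    # 3'-side (from the 5'-ion chemistry of the cleavage after monomer j):
    #   b: -0 ; a: - H2O ; d: + linkage_j ; c: + linkage_j - H2O
    ions: list[FragmentIon] = []
    for i in range(1, n - 1):  # 5' cleavage after monomer i
        for j in range(i + 1, n):  # 3' cleavage after monomer j; span i+1..j
            span = (i + 1, j)
            bare = ElementalFormula()
            for p in range(i, j):  # 0-based monomers i..j-1 = positions i+1..j
                bare = bare + o.monomers[p].formula
            bare = bare - WATER * (j - i - 1)
            for p in range(i + 1, j):  # internal linkages (after pos i+1..j-1)
                bare = bare + o.linkages[p - 1].formula
            link5 = o.linkages[i - 1].formula
            link3 = o.linkages[j - 1].formula
            by_formula: dict[ElementalFormula, list[str]] = {}
            for l, r in combos:
                f = bare
                if l == "w":
                    f = f + link5
                elif l == "x":
                    f = f + link5 - WATER
                elif l == "z":
                    f = f - WATER
                if r == "a":
                    f = f - WATER
                elif r == "d":
                    f = f + link3
                elif r == "c":
                    f = f + link3 - WATER
                if not f.is_valid:
                    continue
                by_formula.setdefault(f, []).append(f"{r}{l}")
            for f, styles in sorted(
                by_formula.items(), key=lambda kv: kv[0].hill()
            ):
                ions.append(
                    FragmentIon("J", span, f, variants=tuple(sorted(styles)))
                )
    return ions


def apply_neutral_losses(
    ions: Iterable[FragmentIon],
    losses: Sequence[LossSpec] = DEFAULT_NEUTRAL_LOSSES,
    depth: int = 1,
) -> list[FragmentIon]:
    """Expand *ions* with neutral-loss variants (originals retained).

    ``depth`` bounds how many losses stack on one candidate (default 1).
    Losses driving a composition negative are silently skipped.
    """
    ions = list(ions)
    out = list(ions)
    frontier = ions
    for _ in range(depth):
        new: list[FragmentIon] = []
        for ion in frontier:
            n_losses = len(ion.losses)
            for loss in losses:
                f = ion.formula - loss.formula
                if not f.is_valid:
                    continue
                # avoid duplicate unordered stacks like (H2O,NH3)/(NH3,H2O)
                if n_losses and loss.label < ion.losses[-1].label:
                    continue
                new.append(replace(ion, formula=f, losses=ion.losses + (loss,)))
        out.extend(new)
        frontier = new
    return out


def apply_base_losses(
    ions: Iterable[FragmentIon], o: Oligo, allow_stacking: bool = False
) -> list[FragmentIon]:
    """Expand with loss of each distinct neutral free base in the ion's span.

    Applies to *every* ion type (not only a ions).  Ambiguity over which copy
    of a base was lost collapses to one candidate per distinct base.
    """
    n = len(o)
    ions = list(ions)
    out = list(ions)
    for ion in ions:
        if ion.losses and not allow_stacking:
            continue
        lo, hi = fragment_span(ion, n)
        seen: dict[str, ElementalFormula] = {}
        for m in o.monomers[lo - 1 : hi]:
            seen.setdefault(m.base_code, m.nucleobase)
        for code in sorted(seen):
            f = ion.formula - seen[code]
            if not f.is_valid:
                continue
            loss = LossSpec(code, seen[code], kind="base")
            out.append(replace(ion, formula=f, losses=ion.losses + (loss,)))
    return out


def apply_adducts(
    ions: Iterable[FragmentIon], adducts: Sequence[AdductSpec]
) -> list[FragmentIon]:
    """Expand with adduct variants; deltas are summed onto the composition."""
    ions = list(ions)
    out = list(ions)
    for ion in ions:
        for ad in adducts:
            f = ion.formula + ad.formula_delta
            if not f.is_valid:
                continue
            out.append(replace(ion, formula=f, adducts=ion.adducts + (ad,)))
    return out


def apply_charged_base_loss(
    ions: Iterable[FragmentIon], o: Oligo
) -> list[FragmentIon]:
    """Charged base loss: depart of a base anion B-, reducing charge by one.

    [F - zH]^z-  ->  [(F - BH) - (z-1)H]^(z-1)-   (neutral-formula view)

    Only applies to charged ions with z >= 2 (z=1 would give a neutral).
    Observed propensity ordering A- > T- > G- > C- is reported as metadata
    (the LossSpec label order), never used as a filter.
    """
    n = len(o)
    ions = list(ions)
    out = list(ions)
    for ion in ions:
        if ion.charge < 2:
            continue
        lo, hi = fragment_span(ion, n)
        seen: dict[str, ElementalFormula] = {}
        for m in o.monomers[lo - 1 : hi]:
            seen.setdefault(m.base_code, m.nucleobase)
        for code in sorted(seen):
            f = ion.formula - seen[code]
            if not f.is_valid:
                continue
            loss = LossSpec(code + "(-)", seen[code], kind="charged_base")
            out.append(
                replace(
                    ion,
                    formula=f,
                    losses=ion.losses + (loss,),
                    charge=ion.charge - 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Catalogue assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogueConfig:
    mz_min: float = 0.0
    mz_max: float = float("inf")
    max_charge: int = 8
    neutral_losses: tuple[LossSpec, ...] = DEFAULT_NEUTRAL_LOSSES
    loss_depth: int = 1
    base_losses: bool = True
    internal: bool = True
    internal_pairs: str = "named"
    adducts: tuple[AdductSpec, ...] = ()
    charged_base_loss: bool = False
    include_precursor: bool = True

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("empty m/z window (mz_min >= mz_max)")
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")


@dataclass
class CandidateCatalogue:
    oligo: Oligo
    config: CatalogueConfig
    ions: list[FragmentIon] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ions)

    def mz_values(self):
        import numpy as np

        return np.array([ion.mz for ion in self.ions])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for ion in self.ions:
            rows.append(
                {
                    "label": ion.label,
                    "ion_type": ion.ion_type,
                    "index": str(ion.index),
                    "losses": ";".join(l.label for l in ion.losses),
                    "adducts": ";".join(a.label for a in ion.adducts),
                    "charge": ion.charge,
                    "formula": ion.formula.hill(),
                    "mz": ion.mz,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "label", "ion_type", "index", "losses",
                "adducts", "charge", "formula", "mz",
            ],
        )

    def write_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False, float_format="%.6f")


def enumerate_candidates(
    o: Oligo, config: CatalogueConfig | None = None
) -> CandidateCatalogue:
    """Build the deterministic, duplicate-free candidate catalogue."""
    config = config or CatalogueConfig()
    neutral: list[FragmentIon] = terminal_fragments(o)
    if config.internal:
        neutral.extend(internal_fragments(o, config.internal_pairs))
    if config.include_precursor:
        neutral.append(precursor_ion(o))
    if config.neutral_losses:
        neutral = apply_neutral_losses(
            neutral, config.neutral_losses, config.loss_depth
        )
    if config.base_losses:
        neutral = apply_base_losses(neutral, o)
    if config.adducts:
        neutral = apply_adducts(neutral, config.adducts)

    charged: list[FragmentIon] = []
    for ion in neutral:
        for z in range(1, config.max_charge + 1):
            charged.append(replace(ion, charge=z))
    if config.charged_base_loss:
        charged = apply_charged_base_loss(charged, o)

    seen: set[tuple] = set()
    final: list[FragmentIon] = []
    for ion in charged:
        if ion.mz < config.mz_min or ion.mz > config.mz_max:
            continue
        k = ion.key()
        if k in seen:
            continue
        seen.add(k)
        final.append(ion)
    final.sort(key=lambda i: (i.mz, i.label))
    return CandidateCatalogue(o, config, final)
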