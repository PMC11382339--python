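"""Fine-structure isotope patterns and sulfur counting.

Sulfur atoms are counted from the resolved A+2 fine structure: at
sufficiently high resolving power the 34S isotopologue (+1.9958 Da) is
separated from the 2x13C isotopologue (+2.0067 Da), and the number of
sulfurs follows directly from the area ratio of the 34S peak to the
monoisotopic peak divided by the 34S/32S natural-abundance ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ElementalFormula
from .constants import (
    DELTA_2X13C,
    DELTA_2X15N,
    DELTA_34S,
    ISOTOPES,
    PROTON_MASS,
    RATIO_34S_32S,
)


class ResolutionError(ValueError):
    """Fine structure not resolvable at the requested resolution."""


@dataclass(frozen=True)
class ResolutionModel:
    """FT-ICR-style resolution: FWHM grows quadratically with m/z.

    ``fwhm(mz) = fwhm_ref * (mz / mz_ref)**2`` — resolving power m/dm falls
    off as 1/m, as for a fixed-length transient.
    """

    fwhm_ref: float = 0.001
    mz_ref: float = 400.0

    def fwhm(self, mz: float) -> float:
        return self.fwhm_ref * (mz / self.mz_ref) ** 2

    def resolving_power(self, mz: float) -> float:
        return mz / self.fwhm(mz)


@dataclass
class IsotopePattern:
    """Stick list of fine-structure isotopologues.

    ``peaks`` rows are (m/z or neutral mass, relative abundance), sorted by
    position, abundance normalized to max = 1.
    """

    peaks: np.ndarray  # shape (k, 2)
    charge: int = 0  # 0 => neutral-mass axis
    resolution_model: ResolutionModel = field(default_factory=ResolutionModel)

    @property
    def mono(self) -> tuple[float, float]:
        return tuple(self.peaks[0])

    def to_dataframe(self):
        import pandas as pd

        axis = "mz" if self.charge else "mass"
        return pd.DataFrame(self.peaks, columns=[axis, "abundance"])


def _element_distribution(
    el: str, n: int, max_shift: int, prune: float
) -> list[tuple[float, float, int]]:
    """Isotopologue distribution of n atoms of one element.

    Returns (mass, probability, neutron shift) tuples for all heavy-isotope
    count vectors with total nominal shift <= max_shift and probability >
    prune.  Exact multinomial probabilities.
    """
    isos = ISOTOPES[el]
    if len(isos) == 1 or n == 0:
        return [(n * isos[0][0], 1.0, 0)]
    base_mass, base_ab = isos[0]
    heavies = isos[1:]
    shifts = [round(m - base_mass) for m, _ in heavies]
    out: list[tuple[float, float, int]] = []
    # enumerate heavy counts k_1..k_h with sum(k_i * shift_i) <= max_shift
    max_counts = [min(n, max_shift // s) for s in shifts]
    for ks in itertools.product(*(range(c + 1) for c in max_counts)):
        shift = sum(k * s for k, s in zip(ks, shifts))
        if shift > max_shift or sum(ks) > n:
            continue
        k0 = n - sum(ks)
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(k0 + 1)
            - sum(math.lgamma(k + 1) for k in ks)
            + k0 * math.log(base_ab)
            + sum(k * math.log(ab) for k, (_, ab) in zip(ks, heavies) if k)
        )
        p = math.exp(logp)
        if p <= prune:
            continue
        mass = k0 * base_mass + sum(k * m for k, (m, _) in zip(ks, heavies))
        out.append((mass, p, shift))
    return out


def isotope_pattern(
    f: ElementalFormula,
    charge: int = 0,
    resolution: ResolutionModel | None = None,
    max_shift: int = 3,
    prune: float = 1e-10,
) -> IsotopePattern:
    """Fine-structure isotope pattern of a formula.

    Isotopologues are enumerated exactly up to a total nominal mass shift of
    ``max_shift`` neutrons (default A+3), keeping distinct exact masses
    separate (fine structure).  ``charge`` > 0 converts to the deprotonated
    negative-ion m/z axis.
    """
    f.finalize()
    resolution = resolution or ResolutionModel()
    dist: list[tuple[float, float, int]] = [(0.0, 1.0, 0)]
    for el, n in f.counts:
        if el not in ISOTOPES:
            raise KeyError(f"unknown element symbol {el!r}")
        el_dist = _element_distribution(el, n, max_shift, prune)
        new: dict[float, tuple[float, int]] = {}
        for (m1, p1, s1), (m2, p2, s2) in itertools.product(dist, el_dist):
            if s1 + s2 > max_shift:
                continue
            m = m1 + m2
            p = p1 * p2
            if p <= prune:
                continue
            if m in new:
                new[m] = (new[m][0] + p, s1 + s2)
            else:
                new[m] = (p, s1 + s2)
        dist = [(m, p, s) for m, (p, s) in new.items()]
    # merge isotopologues closer than 1e-9 Da (identical fine peaks)
    dist.sort(key=lambda t: t[0])
    merged: list[list[float]] = []
    for m, p, _ in dist:
        if merged and abs(m - merged[-1][0]) < 1e-9:
            merged[-1][1] += p
        else:
            merged.append([m, p])
    arr = np.array(merged)
    arr[:, 1] /= arr[:, 1].max()
    if charge:
        arr[:, 0] = (arr[:, 0] - charge * PROTON_MASS) / charge
    return IsotopePattern(arr, charge=charge, resolution_model=resolution)


@dataclass(frozen=True)
class SulfurEstimate:
    n_sulfur: float
    n_sulfur_rounded: int
    ratio_observed: float
    ratio_per_s: float = RATIO_34S_32S


def estimate_sulfur_count(
    pattern: IsotopePattern, window: float | None = None
) -> SulfurEstimate:
    """Count sulfur atoms from the resolved 34S fine peak.

    ``n_S = (area(34S peak) / area(monoisotopic peak)) / (34S/32S abundance)``

    The integration window defaults to 40% of the 34S-to-2x15N fine
    splitting (the nearest A+2 neighbour, ~0.0017 Da below 34S at z=1), so
    that only the 34S isotopologue is integrated.  The resolution model must
    separate 34S from the 13C2 peak (dm ~ 0.011 Da at charge 1) or a
    :class:`ResolutionError` is raised.
    """
    z = max(pattern.charge, 1)
    mz = pattern.peaks[:, 0]
    ab = pattern.peaks[:, 1]
    # monoisotopic peak = lowest-m/z stick with >=1% relative abundance
    significant = ab >= 0.01
    mono_mz = mz[significant][0]
    mono_ab = float(ab[significant][0])

    separation = (DELTA_2X13C - DELTA_34S) / z
    fwhm = pattern.resolution_model.fwhm(mono_mz + DELTA_34S / z)
    if fwhm > 0.8 * separation:
        raise ResolutionError(
            f"insufficient resolution: FWHM {fwhm:.5f} at m/z "
            f"{mono_mz:.2f} cannot resolve the 34S/13C2 splitting "
            f"({separation:.5f})"
        )
    if window is None:
        window = 0.4 * (DELTA_34S - DELTA_2X15N) / z
    target = mono_mz + DELTA_34S / z
    sel = np.abs(mz - target) <= window
    area_34s = float(ab[sel].sum())
    ratio = area_34s / mono_ab
    n_s = ratio / RATIO_34S_32S
    return SulfurEstimate(n_s, int(round(n_s)), ratio)


def profile_spectrum(
    pattern: IsotopePattern, n_points: int = 4000, pad: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Render a stick pattern to a Gaussian profile at the model resolution."""
    mz = pattern.peaks[:, 0]
    ab = pattern.peaks[:, 1]
    lo, hi = mz.min() - pad, mz.max() + pad
    x = np.linspace(lo, hi, n_points)
    y = np.zeros_like(x)
    for m, a in zip(mz, ab):
        sigma = pattern.resolution_model.fwhm(m) / 2.3548200450309493
        y += a * np.exp(-0.5 * ((x - m) / sigma) ** 2)
    return x, y
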