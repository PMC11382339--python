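"""Peak assignment, classification, coverage, efficiency, recalibration.

Peaks are matched to the candidate catalogue within a ppm tolerance,
grouped when isobaric candidates share the winning m/z, and classified into
the experimental taxonomy: precursor, backbone-retained (precursor losses
without backbone cleavage), plain backbone cleavages, cleavages with
neutral or base loss, internal fragments, adducts, unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem import Oligo
from .fragments import CandidateCatalogue, FragmentIon

CATEGORY_PRECEDENCE = (
    "precursor",
    "backbone_retained",
    "mcluckey",
    "mcluckey_neutral_loss",
    "mcluckey_base_loss",
    "internal",
    "adduct",
    "unassigned",
)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0
    charge: int | None = None
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


def categorize_ion(ion: FragmentIon) -> str:
    """Taxonomy category of a single candidate ion."""
    if ion.adducts:
        return "adduct"
    if ion.ion_type == "precursor":
        return "precursor" if not ion.losses else "backbone_retained"
    if ion.ion_type == "J":
        return "internal"
    if not ion.losses:
        return "mcluckey"
    if any(l.kind in ("base", "charged_base") for l in ion.losses):
        return "mcluckey_base_loss"
    return "mcluckey_neutral_loss"


@dataclass
class AssignmentRecord:
    peak: Peak
    candidates: list[FragmentIon] = field(default_factory=list)
    best_ppm: float | None = None
    category: str = "unassigned"

    @property
    def assigned(self) -> bool:
        return self.category not in ("unassigned",)


def match_peaks(
    peaks: list[Peak],
    catalogue: CandidateCatalogue,
    tol_ppm: float = 5.0,
) -> list[AssignmentRecord]:
    """Match each peak to catalogue candidates within ``tol_ppm``.

    Candidates are charge-filtered when the peak carries a charge, ranked by
    absolute ppm error; all candidates isobaric with the winner (within
    1e-6 m/z) are retained on one record.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if len(catalogue) == 0:
        raise ValueError("empty candidate catalogue")
    cat_mz = catalogue.mz_values()
    order = np.argsort(cat_mz)
    cat_mz = cat_mz[order]
    ions = [catalogue.ions[i] for i in order]

    records: list[AssignmentRecord] = []
    for peak in peaks:
        tol = peak.mz * tol_ppm * 1e-6
        lo = np.searchsorted(cat_mz, peak.mz - tol, side="left")
        hi = np.searchsorted(cat_mz, peak.mz + tol, side="right")
        window = [
            ions[i]
            for i in range(lo, hi)
            if peak.charge is None or ions[i].charge == peak.charge
        ]
        if not window:
            records.append(AssignmentRecord(peak))
            continue
        best = min(window, key=lambda ion: abs(peak.mz - ion.mz))
        group = [ion for ion in window if abs(ion.mz - best.mz) < 1e-6]
        group.sort(
            key=lambda ion: (
                CATEGORY_PRECEDENCE.index(categorize_ion(ion)),
                ion.ion_type,
                str(ion.index),
                ion.label,
            )
        )
        ppm = (peak.mz - best.mz) / best.mz * 1e6
        records.append(AssignmentRecord(peak, group, ppm))
    return classify(records)


def classify(records: list[AssignmentRecord]) -> list[AssignmentRecord]:
    """Set each record's category to its best candidate's category."""
    for rec in records:
        if not rec.candidates:
            rec.category = "unassigned"
            continue
        rec.category = min(
            (categorize_ion(ion) for ion in rec.candidates),
            key=CATEGORY_PRECEDENCE.index,
        )
    return records


def sequence_coverage(
    records: list[AssignmentRecord],
    o: Oligo,
    convention: str = "positions",
) -> float:
    """Percent of inter-monomer bonds evidenced by >=1 terminal-ion match.

    A 5'-side ion of index i covers bond i; a 3'-side ion of index k covers
    bond n-k.  Internal fragments are ambiguous and never count.
    ``convention="positions"`` divides by n-1 bonds (default);
    ``convention="residues"`` divides by n.
    """
    n = len(o)
    covered: set[int] = set()
    for rec in records:
        for ion in rec.candidates:
            if ion.ion_type in ("a", "b", "c", "d"):
                covered.add(ion.index)
            elif ion.ion_type in ("w", "x", "y", "z"):
                covered.add(n - ion.index)
    denom = (n - 1) if convention == "positions" else n
    return 100.0 * len(covered) / denom


def fragmentation_efficiency(f_i, p: float) -> float:
    """``100 * sum(F_i) / (sum(F_i) + P)`` — product-ion current fraction."""
    f_i = np.asarray(list(f_i), dtype=float)
    if (f_i < 0).any() or p < 0:
        raise ValueError("intensities must be non-negative")
    total = f_i.sum() + p
    if total == 0:
        raise ValueError("efficiency undefined: no ion current")
    return 100.0 * f_i.sum() / total


def recalibrate(
    peaks: list[Peak],
    anchors: list[tuple[float, float]],
) -> tuple[list[Peak], tuple[float, float]]:
    """Linear recalibration ``mz_corr = alpha * mz + beta`` from anchors.

    Anchors are (observed, theoretical) m/z pairs; the model is least-squares
    fit and applied to every peak.  Applying a model fit on one spectrum to
    another is external calibration: call with that spectrum's peaks.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 calibration anchors")
    obs = np.array([a[0] for a in anchors])
    theo = np.array([a[1] for a in anchors])
    if np.ptp(obs) == 0:
        raise ValueError("anchors span zero m/z range")
    alpha, beta = np.polyfit(obs, theo, 1)
    corrected = [
        Peak(alpha * p.mz + beta, p.intensity, p.charge, p.snr) for p in peaks
    ]
    return corrected, (float(alpha), float(beta))


@dataclass
class AssignmentReport:
    records: list[AssignmentRecord]
    oligo: Oligo
    total_peaks: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    assigned: int = 0
    assigned_pct: float = 0.0
    sequence_coverage_pct: float = 0.0
    fragmentation_efficiency_pct: float | None = None
    f_i: list[float] = field(default_factory=list)
    p_precursor: float = 0.0

    def category_intensities(self) -> dict[str, list[float]]:
        """Per-category peak-intensity vectors (e.g. for beeswarm plots)."""
        out: dict[str, list[float]] = {c: [] for c in CATEGORY_PRECEDENCE}
        for rec in self.records:
            out[rec.category].append(rec.peak.intensity)
        return out

    def to_dict(self) -> dict:
        return {
            "sequence": self.oligo.serialize(),
            "total_peaks": self.total_peaks,
            "counts": self.counts,
            "assigned": self.assigned,
            "assigned_pct": self.assigned_pct,
            "sequence_coverage_pct": self.sequence_coverage_pct,
            "fragmentation_efficiency_pct": self.fragmentation_efficiency_pct,
            "precursor_intensity": self.p_precursor,
            "records": [
                {
                    "mz": rec.peak.mz,
                    "intensity": rec.peak.intensity,
                    "category": rec.category,
                    "best_ppm": rec.best_ppm,
                    "candidates": [ion.label for ion in rec.candidates],
                }
                for rec in self.records
            ],
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "mz": rec.peak.mz,
                    "intensity": rec.peak.intensity,
                    "charge": rec.peak.charge,
                    "category": rec.category,
                    "best_ppm": rec.best_ppm,
                    "candidates": ";".join(ion.label for ion in rec.candidates),
                }
                for rec in self.records
            ]
        )


def summary_report(
    records: list[AssignmentRecord],
    o: Oligo,
    coverage_convention: str = "positions",
) -> AssignmentReport:
    """Aggregate classified records into the summary table."""
    counts = {c: 0 for c in CATEGORY_PRECEDENCE}
    for rec in records:
        counts[rec.category] += 1
    assigned = sum(
        counts[c] for c in CATEGORY_PRECEDENCE if c != "unassigned"
    )
    total = len(records)
    f_i = [
        rec.peak.intensity
        for rec in records
        if rec.assigned and rec.category != "precursor"
    ]
    p = sum(
        rec.peak.intensity for rec in records if rec.category == "precursor"
    )
    efficiency = None
    if f_i or p > 0:
        efficiency = fragmentation_efficiency(f_i, p)
    return AssignmentReport(
        records=records,
        oligo=o,
        total_peaks=total,
        counts=counts,
        assigned=assigned,
        assigned_pct=100.0 * assigned / total if total else 0.0,
        sequence_coverage_pct=sequence_coverage(records, o, coverage_convention),
        fragmentation_efficiency_pct=efficiency,
        f_i=f_i,
        p_precursor=p,
    )
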