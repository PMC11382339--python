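"""Peak-list readers/writers (CSV/TSV/mzXML) and the fixture generator."""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assign import Peak
from .chem import MonomerRegistry, parse_sequence
from .fragments import CatalogueConfig, enumerate_candidates


class PeakListError(ValueError):
    pass


def read_peaklist(path: str | Path, fmt: str | None = None) -> list[Peak]:
    """Read a peak list from CSV/TSV (mz, intensity[, charge, snr]) or mzXML.

    Format is inferred from the extension when ``fmt`` is None.  Malformed
    rows raise with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt in ("csv", "tsv", "txt"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:
            raise PeakListError(f"unparseable peak list {path}: {exc}") from exc
        return _peaks_from_dataframe(df, str(path))
    if fmt == "mzxml":
        return read_mzxml(path)
    raise PeakListError(f"unknown peak-list format {fmt!r}")


def _peaks_from_dataframe(df: pd.DataFrame, source: str) -> list[Peak]:
    cols = {c.lower().strip(): c for c in df.columns}
    if "mz" not in cols or "intensity" not in cols:
        raise PeakListError(
            f"{source}: need 'mz' and 'intensity' columns, got {list(df.columns)}"
        )
    peaks = []
    for i, row in df.iterrows():
        try:
            charge = row[cols["charge"]] if "charge" in cols else None
            if charge is not None and pd.isna(charge):
                charge = None
            snr_v = row[cols["snr"]] if "snr" in cols else None
            if snr_v is not None and pd.isna(snr_v):
                snr_v = None
            peaks.append(
                Peak(
                    float(row[cols["mz"]]),
                    float(row[cols["intensity"]]),
                    int(charge) if charge is not None else None,
                    float(snr_v) if snr_v is not None else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise PeakListError(f"{source}, row {i + 2}: {exc}") from exc
    peaks.sort(key=lambda p: p.mz)
    return peaks


def write_peaklist(peaks: list[Peak], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "charge": [p.charge for p in peaks],
            "snr": [p.snr for p in peaks],
        }
    )
    sep = "\t" if str(path).endswith(".tsv") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Minimal mzXML support (centroided scans only)
# ---------------------------------------------------------------------------

_MZXML_NS = "{http://sashimi.sourceforge.net/schema_revision/mzXML_3.2}"


def read_mzxml(path: str | Path, scan_num: int | None = None) -> list[Peak]:
    """Read centroided peaks from an mzXML file (all scans merged by default)."""
    tree = ET.parse(path)
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    peaks: list[Peak] = []
    for scan in root.iter(f"{ns}scan"):
        if scan_num is not None and int(scan.get("num", -1)) != scan_num:
            continue
        centroided = scan.get("centroided", "1")
        if centroided not in ("1", "true"):
            raise PeakListError(
                "profile-mode mzXML scans are not supported; centroid first"
            )
        elem = scan.find(f"{ns}peaks")
        if elem is None or not (elem.text or "").strip():
            continue
        raw = base64.b64decode(elem.text)
        if elem.get("compressionType", "none") == "zlib":
            raw = zlib.decompress(raw)
        precision = int(elem.get("precision", "32"))
        byte_order = ">" if elem.get("byteOrder", "network") == "network" else "<"
        code = "f" if precision == 32 else "d"
        count = len(raw) // struct.calcsize(code)
        values = struct.unpack(f"{byte_order}{count}{code}", raw)
        for mz, inten in zip(values[::2], values[1::2]):
            peaks.append(Peak(float(mz), float(inten)))
    peaks.sort(key=lambda p: p.mz)
    return peaks


def write_mzxml(peaks: list[Peak], path: str | Path) -> None:
    """Write a single centroided scan (round-trip/testing convenience)."""
    data = []
    for p in sorted(peaks, key=lambda q: q.mz):
        data.extend([p.mz, p.intensity])
    payload = base64.b64encode(struct.pack(f">{len(data)}f", *data)).decode()
    xml = (
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        f'<mzXML xmlns="{_MZXML_NS[1:-1]}">\n'
        " <msRun scanCount=\"1\">\n"
        '  <scan num="1" msLevel="2" centroided="1" '
        f'peaksCount="{len(peaks)}">\n'
        '   <peaks precision="32" byteOrder="network" '
        f'contentType="m/z-int" compressionType="none">{payload}</peaks>\n'
        "  </scan>\n"
        " </msRun>\n"
        "</mzXML>\n"
    )
    Path(path).write_text(xml)


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    sequence: str
    config: CatalogueConfig = field(default_factory=CatalogueConfig)
    ppm_jitter: float = 0.0
    n_decoys: int = 0
    decoy_guard_ppm: float = 10.0
    intensity_model: str = "center-weighted"  # or "uniform"
    with_charges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter < 0 or self.n_decoys < 0:
            raise ValueError("jitter and decoy count must be non-negative")


def generate_fixture(
    spec: FixtureSpec, registry: MonomerRegistry | None = None
) -> tuple[list[Peak], pd.DataFrame]:
    """Synthetic peak list + ground-truth table from a known sequence.

    One peak per distinct catalogue m/z (isobars collapse onto one peak,
    exactly as in a real centroided spectrum), with optional ppm jitter and
    uniformly drawn decoy peaks kept clear of every true peak.
    """
    rng = np.random.default_rng(spec.seed)
    oligo = parse_sequence(spec.sequence, registry)
    catalogue = enumerate_candidates(oligo, spec.config)
    n = len(oligo)

    groups: dict[float, list] = {}
    for ion in catalogue.ions:
        key = round(ion.mz, 9)
        groups.setdefault(key, []).append(ion)

    truth_rows = []
    peaks: list[Peak] = []
    mzs = sorted(groups)
    for mz in mzs:
        ions = groups[mz]
        if spec.intensity_model == "center-weighted":
            # cleavages near the chain centre are most abundant
            spans = [
                ion.index if isinstance(ion.index, int) else n // 2
                for ion in ions
                if ion.index is not None
            ]
            pos = (spans[0] if spans else n / 2) / n
            intensity = 10.0 + 990.0 * float(np.exp(-8.0 * (pos - 0.5) ** 2))
        else:
            intensity = 100.0
        observed = mz * (1.0 + rng.normal(0.0, spec.ppm_jitter) * 1e-6)
        charge = ions[0].charge if spec.with_charges else None
        peaks.append(Peak(observed, intensity, charge))
        truth_rows.append(
            {
                "mz_true": mz,
                "mz_observed": observed,
                "labels": ";".join(ion.label for ion in ions),
                "is_decoy": False,
            }
        )

    lo = min(mzs)
    hi = max(mzs)
    guard = spec.decoy_guard_ppm * 1e-6
    true_arr = np.array(mzs)
    made = 0
    while made < spec.n_decoys:
        mz = float(rng.uniform(lo, hi))
        if np.min(np.abs(true_arr - mz)) / mz < 2 * guard:
            continue
        peaks.append(Peak(mz, float(rng.uniform(5.0, 50.0))))
        truth_rows.append(
            {"mz_true": mz, "mz_observed": mz, "labels": "", "is_decoy": True}
        )
        made += 1

    peaks.sort(key=lambda p: p.mz)
    truth = pd.DataFrame(truth_rows).sort_values("mz_observed").reset_index(
        drop=True
    )
    return peaks, truth
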