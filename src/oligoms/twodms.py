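"""Two-dimensional MS acquisition simulation and processing.

The simulator models the essentials of a 2D FT-ICR experiment: the
precursor's cyclotron radius is modulated along the evolution delay t1 at
its cyclotron frequency, the fragment yield follows the fragmentation-zone
profile of that modulated radius, and each t1 row is the average of m
identically-delayed scans (the multi-scan accumulation pulse scheme).
Processing is a magnitude-mode 2D FFT; denoising is a truncated low-rank
approximation along t1.  m/z <-> frequency uses the single-term inverse
law f = A / (m/z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .constants import COULOMB_EV_ANGSTROM, HC_EV_NM

DEFAULT_CALIBRATION_A = 1.0e8  # Hz * (m/z)


def mz_to_freq(mz, a: float = DEFAULT_CALIBRATION_A):
    return a / np.asarray(mz, dtype=float)


def freq_to_mz(freq, a: float = DEFAULT_CALIBRATION_A):
    freq = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore"):
        return a / freq


@dataclass(frozen=True)
class Acq2DParams:
    n_t1: int = 128  # t1 rows N
    m_scans: int = 1  # scans accumulated and averaged per t1 increment
    t1_step: float = 2.0e-6  # s
    n_t2: int = 1024  # transient points per row
    sample_rate: float = 1.0e6  # Hz
    calibration_a: float = DEFAULT_CALIBRATION_A
    mz_cutoff_high: float = 2000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_t1 < 1 or self.m_scans < 1 or self.n_t2 < 1:
            raise ValueError("N, m and n_t2 must all be >= 1")
        if self.t1_step <= 0:
            raise ValueError("t1_step must be positive")


def gaussian_profile(width: float = 0.5, center: float = 1.0) -> Callable:
    """Laser-like fragmentation zone: narrow Gaussian in modulated radius."""

    def profile(c):
        return np.exp(-0.5 * ((np.asarray(c) - center) / width) ** 2)

    return profile


def plateau_profile() -> Callable:
    """Cathode-like wide fragmentation zone: broad linear ramp of radius.

    Maps cos(w_p t1) in [-1, 1] to [0, 1]; the fragment interferogram is a
    pure cosine at the precursor frequency.
    """

    def profile(c):
        return 0.5 * (1.0 + np.asarray(c))

    return profile


@dataclass
class SpeciesModel:
    precursor_mz: float
    precursor_charge: int = 1
    fragments: Sequence[tuple[float, float]] = ()  # (m/z, base amplitude)
    profile: Callable = field(default_factory=plateau_profile)
    noise_sigma: float = 0.0  # additive white noise per scan
    scintillation_sigma: float = 0.0  # per-scan multiplicative jitter
    precursor_amplitude: float = 0.0  # residual (unfragmented) precursor


@dataclass
class Map2D:
    matrix: np.ndarray  # (N, n_t2) time domain or (n_f1, n_f2) processed
    params: Acq2DParams
    domain: str = "time"  # "time" | "spectrum"
    mz_axis_fragment: np.ndarray | None = None  # t2/x axis after processing
    mz_axis_precursor: np.ndarray | None = None  # t1/y axis after processing
    log: list[str] = field(default_factory=list)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("matrix", data=self.matrix)
            fh.attrs["domain"] = self.domain
            fh.attrs["log"] = "\n".join(self.log)
            fh.attrs["n_t1"] = self.params.n_t1
            fh.attrs["m_scans"] = self.params.m_scans
            fh.attrs["t1_step"] = self.params.t1_step
            fh.attrs["sample_rate"] = self.params.sample_rate
            fh.attrs["calibration_a"] = self.params.calibration_a
            if self.mz_axis_fragment is not None:
                fh.create_dataset("mz_fragment", data=self.mz_axis_fragment)
            if self.mz_axis_precursor is not None:
                fh.create_dataset("mz_precursor", data=self.mz_axis_precursor)

    @staticmethod
    def load_hdf5(path) -> "Map2D":
        import h5py

        with h5py.File(path, "r") as fh:
            params = Acq2DParams(
                n_t1=int(fh.attrs["n_t1"]),
                m_scans=int(fh.attrs["m_scans"]),
                t1_step=float(fh.attrs["t1_step"]),
                n_t2=fh["matrix"].shape[1],
                sample_rate=float(fh.attrs["sample_rate"]),
                calibration_a=float(fh.attrs["calibration_a"]),
            )
            return Map2D(
                matrix=fh["matrix"][...],
                params=params,
                domain=str(fh.attrs["domain"]),
                mz_axis_fragment=(
                    fh["mz_fragment"][...] if "mz_fragment" in fh else None
                ),
                mz_axis_precursor=(
                    fh["mz_precursor"][...] if "mz_precursor" in fh else None
                ),
                log=str(fh.attrs["log"]).splitlines(),
            )


def average_scans(scans: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of m equally-delayed scans -> one t1 row."""
    scans = list(scans)
    if not scans:
        raise ValueError("no scans to average")
    length = len(scans[0])
    if any(len(s) != length for s in scans):
        raise ValueError("scans must have equal length")
    return np.mean(np.stack(scans), axis=0)


def simulate_2d(params: Acq2DParams, model: SpeciesModel) -> Map2D:
    """Simulate the time-domain acquisition (N rows x n_t2 points)."""
    rng = np.random.default_rng(params.seed)
    a = params.calibration_a
    t2 = np.arange(params.n_t2) / params.sample_rate
    f_p = mz_to_freq(model.precursor_mz, a)
    frag_waves = [
        (amp, np.cos(2 * np.pi * mz_to_freq(mz, a) * t2))
        for mz, amp in model.fragments
    ]
    prec_wave = np.cos(2 * np.pi * f_p * t2)

    matrix = np.empty((params.n_t1, params.n_t2))
    for r in range(params.n_t1):
        t1 = r * params.t1_step
        c = np.cos(2 * np.pi * f_p * t1)
        g = float(model.profile(c))
        clean = np.zeros(params.n_t2)
        for amp, wave in frag_waves:
            clean += amp * g * wave
        if model.precursor_amplitude:
            # surviving precursor: radius-modulated detection
            clean = clean + model.precursor_amplitude * c * prec_wave
        scans = []
        for _ in range(params.m_scans):
            scan = clean.copy()
            if model.scintillation_sigma:
                scan = scan * (1.0 + rng.normal(0.0, model.scintillation_sigma))
            if model.noise_sigma:
                scan = scan + rng.normal(0.0, model.noise_sigma, params.n_t2)
            scans.append(scan)
        matrix[r] = average_scans(scans)
    return Map2D(
        matrix,
        params,
        domain="time",
        log=[f"simulate_2d N={params.n_t1} m={params.m_scans}"],
    )


@dataclass(frozen=True)
class DenoiseParams:
    rank: int = 10
    algorithm: str = "truncated-rank"  # or "randomized-rank"
    seed: int | None = None
    oversample: int = 8


def denoise_low_rank(map2d: Map2D, p: DenoiseParams) -> Map2D:
    """Rank-k approximation of the map along the t1 dimension."""
    m = map2d.matrix
    if p.rank < 1 or p.rank >= min(m.shape):
        raise ValueError(f"rank must be in [1, {min(m.shape) - 1}]")
    if p.algorithm == "truncated-rank":
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        approx = (u[:, : p.rank] * s[: p.rank]) @ vt[: p.rank]
    elif p.algorithm == "randomized-rank":
        rng = np.random.default_rng(p.seed)
        sketch = rng.standard_normal((m.shape[1], p.rank + p.oversample))
        q, _ = np.linalg.qr(m @ sketch)
        b = q.T @ m
        u_b, s, vt = np.linalg.svd(b, full_matrices=False)
        approx = (q @ u_b[:, : p.rank] * s[: p.rank]) @ vt[: p.rank]
    else:
        raise ValueError(f"unknown algorithm {p.algorithm!r}")
    out = replace_matrix(map2d, approx)
    out.log = map2d.log + [f"denoise {p.algorithm} rank={p.rank}"]
    return out


def replace_matrix(map2d: Map2D, matrix: np.ndarray) -> Map2D:
    return Map2D(
        matrix,
        map2d.params,
        domain=map2d.domain,
        mz_axis_fragment=map2d.mz_axis_fragment,
        mz_axis_precursor=map2d.mz_axis_precursor,
        log=list(map2d.log),
    )


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def process_2d(map2d: Map2D) -> Map2D:
    """Magnitude-mode 2D FFT: t2 then t1, axes converted to m/z.

    Dimensions are zero-filled to the next power of two.  The zero-frequency
    row/column (infinite m/z) is retained so DC/t1-noise energy stays
    visible as the familiar vertical streaks.
    """
    if map2d.domain != "time":
        raise ValueError("process_2d expects a time-domain map")
    params = map2d.params
    n1 = _next_pow2(params.n_t1)
    n2 = _next_pow2(params.n_t2)
    stage1 = np.abs(np.fft.rfft(map2d.matrix, n=n2, axis=1))
    stage2 = np.abs(np.fft.rfft(stage1, n=n1, axis=0))
    f2 = np.fft.rfftfreq(n2, d=1.0 / params.sample_rate)
    f1 = np.fft.rfftfreq(n1, d=params.t1_step)
    out = Map2D(
        stage2,
        params,
        domain="spectrum",
        mz_axis_fragment=freq_to_mz(f2, params.calibration_a),
        mz_axis_precursor=freq_to_mz(f1, params.calibration_a),
        log=map2d.log + [f"process_2d zero-fill ({n1}x{n2})"],
    )
    return out


def extract_autocorrelation(map2d: Map2D) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal where precursor m/z equals fragment m/z."""
    _require_processed(map2d)
    mz_f = map2d.mz_axis_fragment
    values = np.empty(len(map2d.mz_axis_precursor))
    for i, mz_p in enumerate(map2d.mz_axis_precursor):
        if not np.isfinite(mz_p):
            values[i] = map2d.matrix[i, 0]
            continue
        j = _nearest_finite(mz_f, mz_p)
        values[i] = map2d.matrix[i, j]
    return map2d.mz_axis_precursor, values


def extract_fragment_line(
    map2d: Map2D, precursor_mz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row nearest the requested precursor m/z: that precursor's fragments."""
    _require_processed(map2d)
    i = _nearest_finite(map2d.mz_axis_precursor, precursor_mz)
    return map2d.mz_axis_fragment, map2d.matrix[i]


def extract_precursor_line(
    map2d: Map2D, fragment_mz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Column nearest the requested fragment m/z: who makes this fragment."""
    _require_processed(map2d)
    j = _nearest_finite(map2d.mz_axis_fragment, fragment_mz)
    return map2d.mz_axis_precursor, map2d.matrix[:, j]


def _require_processed(map2d: Map2D) -> None:
    if map2d.domain != "spectrum":
        raise ValueError("map must be processed (process_2d) first")


def _nearest_finite(axis: np.ndarray, value: float) -> int:
    finite = np.isfinite(axis)
    if not finite.any():
        raise ValueError("axis has no finite m/z values")
    lo = axis[finite].min()
    hi = axis[finite].max()
    if not (lo <= value <= hi):
        raise ValueError(
            f"requested m/z {value} outside axis range [{lo:.1f}, {hi:.1f}]"
        )
    dist = np.where(finite, np.abs(axis - value), np.inf)
    return int(np.argmin(dist))


def snr(
    spectrum: np.ndarray,
    axis: np.ndarray,
    peak_mz: float,
    noise_region: tuple[float, float],
) -> float:
    """Peak magnitude over the standard deviation of the noise region."""
    i = _nearest_finite(axis, peak_mz)
    lo, hi = sorted(noise_region)
    sel = np.isfinite(axis) & (axis >= lo) & (axis <= hi)
    if not sel.any():
        raise ValueError("empty noise region")
    sigma = float(np.std(spectrum[sel]))
    if sigma == 0:
        raise ValueError("noise region has zero variance")
    return float(spectrum[i]) / sigma


def harmonic_mz(fundamental_mz: float, n: int) -> float:
    """n-th frequency harmonic in m/z units: f ~ 1/(m/z) => mz_n = mz / n."""
    if n < 1:
        raise ValueError("harmonic order must be >= 1")
    return fundamental_mz / n


def closest_approach(z: int, v_bias: float) -> float:
    """Coulomb distance of closest approach, Angstrom (z in e, V in eV)."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    if v_bias <= 0:
        raise ValueError("electron bias must be positive")
    return COULOMB_EV_ANGSTROM * z / v_bias


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy in eV for a wavelength in nm."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / wavelength_nm


@dataclass(frozen=True)
class EddGeometry:
    """Electron-capture geometry for a charge-z anion at V_bias eV."""

    z: int
    v_bias: float

    @property
    def distance(self) -> float:
        return closest_approach(self.z, self.v_bias)
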