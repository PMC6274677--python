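"""Ground-truth generators for melting diagrams and FID series.

Instrument data for this kind of experiment are not deposited anywhere,
so every analysis stage is validated against synthetic inputs whose
truth is known exactly.  The melting-diagram generator realizes the
piecewise forward model the analysis assumes — zero below the onset, a
sharp step across one grid bin, a flat plateau, and a quadratic rise —
plus homoscedastic Gaussian noise on n.  The FID generator goes one
level deeper and emits two-component time-domain traces (Gaussian solid
decay + exponential mobile decay) with dead-time truncation, Curie 1/T
amplitude scaling, and amplitude-level noise, so the full
decomposition → correction → normalization pipeline can be exercised.

Presets encode three reference systems: a compact globular protein with
a broad plateau (``ubiquitin_like``), an intrinsically disordered
protein with a short plateau and a strong heterogeneous rise
(``erd10_like``), and bulk water, a single step at T_fn = 1
(``bulk_water_like``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .fid_decomposition import AcquisitionSpec, FidTrace, write_fid
from .melting_diagram import MeltingDiagram, build_melting_diagram
from .units_scales import CELSIUS_OFFSET

__all__ = [
    "MdTruth",
    "FidSimSpec",
    "default_grid",
    "truth_curve",
    "generate_md",
    "generate_fid_series",
    "presets",
    "PRESET_NAMES",
]

PRESET_NAMES = ("ubiquitin_like", "erd10_like", "bulk_water_like")


def default_grid() -> np.ndarray:
    """Default T_fn grid: 35 temperatures from −70 to −1 °C, the
    reliable measurement window below the bulk melting point."""
    celsius = np.linspace(-70.0, -1.0, 35)
    return (celsius + CELSIUS_OFFSET) / CELSIUS_OFFSET


@dataclass(frozen=True)
class MdTruth:
    """Exact parameters of a synthetic melting diagram."""

    onset_t_fn: float
    A: float
    t_fno: float
    t_fne: float
    B: float = 0.0
    C: float = 0.0
    t_fn1: float | None = None  # defaults to t_fne
    t_fn2: float | None = None
    noise_sd: float = 0.002
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int = 0
    onset_bin_width: float = 0.005
    sample_id: str = "synthetic"

    def __post_init__(self):
        if not (self.onset_t_fn <= self.t_fno <= self.t_fne < 1.0 + 1e-9):
            raise InvalidInputError("require onset_t_fn <= t_fno <= t_fne < 1")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.A < 0:
            raise InvalidInputError("A must be >= 0")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 5 or not np.all(np.diff(grid) > 0):
            raise InvalidInputError("grid must be a strictly increasing 1-D array, length >= 5")
        object.__setattr__(self, "grid", grid)

    @property
    def anchor1(self) -> float:
        return self.t_fne if self.t_fn1 is None else self.t_fn1

    @property
    def anchor2(self) -> float:
        return self.t_fne if self.t_fn2 is None else self.t_fn2

    def to_json_dict(self) -> dict:
        return {
            "onset_t_fn": self.onset_t_fn,
            "A": self.A,
            "t_fno": self.t_fno,
            "t_fne": self.t_fne,
            "B": self.B,
            "C": self.C,
            "t_fn1": self.anchor1,
            "t_fn2": self.anchor2,
            "noise_sd": self.noise_sd,
            "grid": self.grid.tolist(),
            "seed": self.seed,
            "onset_bin_width": self.onset_bin_width,
            "sample_id": self.sample_id,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MdTruth":
        d = dict(d)
        if "grid" in d:
            d["grid"] = np.asarray(d["grid"], dtype=float)
        return cls(**d)


def truth_curve(truth: MdTruth, t_fn) -> np.ndarray:
    """Noiseless piecewise melting-diagram model n(T_fn)."""
    t = np.asarray(t_fn, dtype=float)
    step_end = min(truth.onset_t_fn + truth.onset_bin_width, truth.t_fno)
    width = max(step_end - truth.onset_t_fn, 1e-15)
    ramp = truth.A * (t - truth.onset_t_fn) / width
    u2 = t - truth.anchor2
    rise = truth.A + truth.B * (t - truth.anchor1) + truth.C * u2**2
    out = np.where(
        t < truth.onset_t_fn,
        0.0,
        np.where(t < step_end, ramp, np.where(t <= truth.t_fne, truth.A, rise)),
    )
    return float(out) if np.ndim(t_fn) == 0 else out


def generate_md(truth: MdTruth) -> MeltingDiagram:
    """Sample the truth curve on its grid with additive Gaussian noise.

    Deterministic under ``truth.seed``; with ``noise_sd = 0`` the
    output equals the piecewise model exactly.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth_curve(truth, truth.grid)
    if truth.noise_sd > 0:
        n = n + rng.normal(0.0, truth.noise_sd, size=len(n))
    n = np.clip(n, 0.0, 1.05)
    temps = truth.grid * CELSIUS_OFFSET
    errs = np.full(len(n), truth.noise_sd) if truth.noise_sd > 0 else None
    md = build_melting_diagram(
        [(temps[i], n[i], errs[i] if errs is not None else None) for i in range(len(n))],
        sample_id=truth.sample_id,
        metadata={"generator": "hydromelt.synthetic_data", "seed": truth.seed},
    )
    return md


@dataclass(frozen=True)
class FidSimSpec:
    """Signal-level parameters for synthetic FID series.

    Amplitudes are in arbitrary spectrometer units; the slow (mobile
    water) amplitude at temperature T is
    ``total_water_amplitude × n(T_fn) × (curie_reference/T)`` so that
    Curie correction recovers a quantity proportional to n.  The fast
    (rigid protons: protein + ice) amplitude is held constant.
    """

    fast_amplitude: float = 5.0
    fast_decay: float = 12.0  # µs, Gaussian solid decay
    total_water_amplitude: float = 10.0
    slow_decay: float = 400.0  # µs, mobile-water decay
    dead_time: float = 8.0  # µs
    t_max: float = 1500.0  # µs, end of the sampling window
    n_samples: int = 160
    noise_sd: float = 0.0  # amplitude units
    curie_reference: float = CELSIUS_OFFSET  # kelvin
    reference_celsius: float = 10.0  # where the all-mobile reference is taken
    seed: int = 0

    def __post_init__(self):
        if not (self.fast_decay > 0 and self.slow_decay > self.fast_decay):
            raise InvalidInputError("require slow_decay > fast_decay > 0")
        if not self.dead_time > 0 or not self.t_max > self.dead_time:
            raise InvalidInputError("require t_max > dead_time > 0")
        if self.n_samples < 8:
            raise InvalidInputError("n_samples must be >= 8")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    def time_grid(self) -> np.ndarray:
        return np.linspace(self.dead_time, self.t_max, self.n_samples)


def _simulate_trace(
    n_mobile: float, temperature: float, sim: FidSimSpec, rng: np.random.Generator
) -> FidTrace:
    t = sim.time_grid()
    slow_amp = sim.total_water_amplitude * n_mobile * (sim.curie_reference / temperature)
    # rigid protons also follow the Curie law; same 1/T factor
    fast_amp = sim.fast_amplitude * (sim.curie_reference / temperature)
    a = fast_amp * np.exp(-0.5 * (t / sim.fast_decay) ** 2) + slow_amp * np.exp(-t / sim.slow_decay)
    if sim.noise_sd > 0:
        a = a + rng.normal(0.0, sim.noise_sd, size=len(t))
    acq = AcquisitionSpec(dead_time=sim.dead_time)
    return FidTrace(time=t, amplitude=a, temperature=temperature, acquisition=acq)


def generate_fid_series(
    truth: MdTruth, sim: FidSimSpec, include_reference: bool = True
) -> list[FidTrace]:
    """Two-component FID traces across the truth grid.

    The slow amplitude tracks the truth curve with Curie scaling; one
    extra trace above 0 °C (all water mobile, n = 1) provides the
    total-water normalization reference when ``include_reference``.
    Deterministic under ``sim.seed``.
    """
    rng = np.random.default_rng(sim.seed)
    traces = [
        _simulate_trace(float(truth_curve(truth, tfn)), float(tfn * CELSIUS_OFFSET), sim, rng)
        for tfn in truth.grid
    ]
    if include_reference:
        t_ref = sim.reference_celsius + CELSIUS_OFFSET
        traces.append(_simulate_trace(1.0, t_ref, sim, rng))
    return traces


def write_fid_series(
    directory: str | Path, traces: list[FidTrace], manifest_name: str = "manifest.csv"
) -> Path:
    """Write traces plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trace in enumerate(traces):
        fname = f"fid_{i:03d}_{trace.temperature:.2f}K.txt"
        write_fid(directory / fname, trace)
        rows.append(fname)
    manifest = directory / manifest_name
    manifest.write_text("path\n" + "\n".join(rows) + "\n")
    return manifest


def presets(name: str, noise_sd: float | None = None, seed: int = 0) -> MdTruth:
    """Reference truth objects for the three study systems.

    Parameters follow the published characteristic values: plateau
    boundaries (0.832, 0.961) with plateau level 0.019 for the globular
    reference; (0.835, 0.889) with level 0.0157 and a strong quadratic
    rise for the disordered reference; bulk water is a single step at
    T_fn = 1.  The quadratic coefficients are set so the curve reaches
    level + heterogeneous fraction (0.009 and 0.098 respectively) at
    T_fn = 0.995.
    """
    if name == "ubiquitin_like":
        t_fne, top, n_he = 0.961, 0.995, 0.009
        truth = MdTruth(
            onset_t_fn=0.8316,
            A=0.019,
            t_fno=0.832,
            t_fne=t_fne,
            B=0.0,
            C=n_he / (top - t_fne) ** 2,
            sample_id="ubiquitin_like",
            seed=seed,
            noise_sd=0.002 if noise_sd is None else noise_sd,
        )
    elif name == "erd10_like":
        t_fne, top, n_he = 0.889, 0.995, 0.098
        truth = MdTruth(
            onset_t_fn=0.8346,
            A=0.0157,
            t_fno=0.835,
            t_fne=t_fne,
            B=0.0,
            C=n_he / (top - t_fne) ** 2,
            sample_id="erd10_like",
            seed=seed,
            noise_sd=0.002 if noise_sd is None else noise_sd,
        )
    elif name == "bulk_water_like":
        celsius = np.linspace(-15.0, 5.0, 41)
        grid = (celsius + CELSIUS_OFFSET) / CELSIUS_OFFSET
        truth = MdTruth(
            onset_t_fn=0.99993,
            A=1.0,
            t_fno=0.99995,
            t_fne=0.99995,
            B=0.0,
            C=0.0,
            grid=grid,
            onset_bin_width=0.00002,
            sample_id="bulk_water_like",
            seed=seed,
            noise_sd=0.002 if noise_sd is None else noise_sd,
        )
    else:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose one of {', '.join(PRESET_NAMES)}"
        )
    return truth
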