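"""Melting diagrams: mobile-water fraction vs. temperature.

The melting diagram (MD) records the fraction n of water molecules that
are mobile (rotating) at each temperature, on three equivalent axes:
°C, kelvin, and the normalized fundamental temperature T_fn = T/273.15.
For bulk water the MD is a single step of infinite slope at T_fn = 1;
for protein solutions melting of protein-bound water starts tens of
degrees lower and the shape of the curve encodes the distribution of
protein–water binding energies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fid_decomposition import (
    AcquisitionSpec,
    FidModelConfig,
    curie_correct,
    decompose_fid,
    mobile_fraction,
    read_fid,
)
from .units_scales import CELSIUS_OFFSET, DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "MeltingDiagram",
    "SampleSpec",
    "FidSeriesConfig",
    "build_melting_diagram",
    "from_fid_series",
    "read_md_csv",
    "write_md_csv",
]

#: Band just below the bulk melting point where measured points are
#: unreliable (partial bulk melting), in °C.
UNRELIABLE_BAND_CELSIUS = (-1.0, 0.0)


@dataclass(frozen=True)
class SampleSpec:
    """What was in the NMR tube, for fraction → count conversions."""

    protein_name: str
    concentration: float  # mg/mL
    molecular_weight: float  # Da
    residue_count: int
    water_molarity: float = 55.35  # mol/L, pure water near 0 °C
    water_mass_fraction: float | None = None

    def __post_init__(self):
        for name in ("concentration", "molecular_weight", "water_molarity"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"SampleSpec.{name} must be positive")
        if int(self.residue_count) != self.residue_count or self.residue_count < 1:
            raise InvalidInputError("residue_count must be a positive integer")
        if self.water_mass_fraction is not None and not 0 < self.water_mass_fraction <= 1:
            raise InvalidInputError("water_mass_fraction must be in (0, 1]")

    @property
    def protein_molarity(self) -> float:
        """mol protein per litre of solution."""
        return self.concentration / self.molecular_weight

    def to_json_dict(self) -> dict:
        d = {
            "protein_name": self.protein_name,
            "concentration_mg_ml": self.concentration,
            "molecular_weight_da": self.molecular_weight,
            "residue_count": self.residue_count,
            "water_molarity_mol_l": self.water_molarity,
        }
        if self.water_mass_fraction is not None:
            d["water_mass_fraction"] = self.water_mass_fraction
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SampleSpec":
        required = ["protein_name", "concentration_mg_ml", "molecular_weight_da", "residue_count"]
        missing = [k for k in required if k not in d]
        if missing:
            raise InvalidInputError(f"sample spec missing fields: {', '.join(missing)}")
        return cls(
            protein_name=d["protein_name"],
            concentration=float(d["concentration_mg_ml"]),
            molecular_weight=float(d["molecular_weight_da"]),
            residue_count=int(d["residue_count"]),
            water_molarity=float(d.get("water_molarity_mol_l", 55.35)),
            water_mass_fraction=d.get("water_mass_fraction"),
        )

    @classmethod
    def from_json_file(cls, path: str | Path) -> "SampleSpec":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class MeltingDiagram:
    """Ordered (T, T_fn, n) table of mobile-water fractions."""

    temperature: np.ndarray  # kelvin, strictly increasing
    t_fn: np.ndarray
    n: np.ndarray
    n_err: np.ndarray | None = None
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.t_fn = np.asarray(self.t_fn, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.n_err is not None:
            self.n_err = np.asarray(self.n_err, dtype=float)
            if self.n_err.shape != self.n.shape:
                raise InvalidInputError("n_err must match n in shape")
        if not (len(self.temperature) == len(self.t_fn) == len(self.n)):
            raise InvalidInputError("temperature, t_fn, n must have equal length")
        if len(self.n) < 5:
            raise InvalidInputError("a melting diagram needs at least 5 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        expected = self.temperature / CELSIUS_OFFSET
        if not np.allclose(self.t_fn, expected, rtol=0, atol=1e-9):
            raise InvalidInputError("t_fn inconsistent with temperature/273.15")
        if np.any(self.n < 0) or np.any(self.n > 1.05):
            raise InvalidInputError("n must lie in [0, 1.05]")

    def __len__(self) -> int:
        return len(self.n)

    @property
    def celsius(self) -> np.ndarray:
        return self.temperature - CELSIUS_OFFSET

    def reliable_mask(self, band: tuple[float, float] = UNRELIABLE_BAND_CELSIUS) -> np.ndarray:
        """True for points outside the unreliable −1–0 °C band."""
        c = self.celsius
        return ~((c > band[0]) & (c <= band[1]))


def build_melting_diagram(
    points,
    sample_id: str = "",
    metadata: dict | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> MeltingDiagram:
    """Assemble a melting diagram from per-temperature fractions.

    ``points`` is an iterable of ``(T_kelvin, n)`` or ``(T_kelvin, n,
    n_err)`` tuples in any order.  Small negative fractions (noise, down
    to −0.02) are clamped to 0 with a warning; anything outside
    [−0.02, 1.10] is rejected; duplicate temperatures are rejected.
    """
    rows = [tuple(p) for p in points]
    if len(rows) < 5:
        raise InvalidInputError("need at least 5 points")
    temps = np.array([r[0] for r in rows], dtype=float)
    ns = np.array([r[1] for r in rows], dtype=float)
    errs = np.array([r[2] if len(r) > 2 and r[2] is not None else np.nan for r in rows])
    uniq, counts = np.unique(temps, return_counts=True)
    if np.any(counts > 1):
        dups = uniq[counts > 1]
        raise InvalidInputError(f"duplicate temperatures: {dups.tolist()}")
    if np.any(ns < -0.02) or np.any(ns > 1.10):
        bad = ns[(ns < -0.02) | (ns > 1.10)]
        raise InvalidInputError(f"mobile fractions outside [-0.02, 1.10]: {bad.tolist()}")
    negative = ns < 0
    if np.any(negative):
        warnings.warn(
            f"clamped {int(negative.sum())} small negative fraction(s) to 0", stacklevel=2
        )
        ns = np.where(negative, 0.0, ns)
    ns = np.minimum(ns, 1.05)
    order = np.argsort(temps)
    temps, ns, errs = temps[order], ns[order], errs[order]
    n_err = None if np.all(np.isnan(errs)) else np.where(np.isnan(errs), 0.0, errs)
    return MeltingDiagram(
        temperature=temps,
        t_fn=temps / constants.ice_melt_temperature,
        n=ns,
        n_err=n_err,
        sample_id=sample_id,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# MD CSV format: '#'-prefixed key=value metadata, then a header row with
# either temperature_C or temperature_K, plus n and optional n_err.

def write_md_csv(path: str | Path, md: MeltingDiagram, unit: str = "C") -> None:
    if unit not in ("C", "K"):
        raise InvalidInputError("unit must be 'C' or 'K'")
    path = Path(path)
    lines = [f"# sample_id={md.sample_id}"]
    for key, value in md.metadata.items():
        lines.append(f"# {key}={value}")
    cols = [f"temperature_{unit}", "n"] + (["n_err"] if md.n_err is not None else [])
    lines.append(",".join(cols))
    temps = md.celsius if unit == "C" else md.temperature
    for i in range(len(md)):
        row = [f"{temps[i]:.12g}", f"{md.n[i]:.12g}"]
        if md.n_err is not None:
            row.append(f"{md.n_err[i]:.12g}")
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_md_csv(path: str | Path, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> MeltingDiagram:
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    for raw in path.read_text().splitlines():
        if raw.strip().startswith("#"):
            stripped = raw.strip().lstrip("# ")
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        elif raw.strip():
            body.append(raw)
    if not body:
        raise InvalidInputError(f"{path}: no data rows")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body)))
    df.columns = [c.strip() for c in df.columns]
    if "temperature_K" in df.columns:
        temps = df["temperature_K"].to_numpy(float)
    elif "temperature_C" in df.columns:
        temps = df["temperature_C"].to_numpy(float) + CELSIUS_OFFSET
    else:
        raise InvalidInputError(f"{path}: need a temperature_C or temperature_K column")
    if "n" not in df.columns:
        raise InvalidInputError(f"{path}: missing column 'n'")
    errs = df["n_err"].to_numpy(float) if "n_err" in df.columns else None
    points = [
        (temps[i], df["n"].iloc[i], errs[i] if errs is not None else None)
        for i in range(len(df))
    ]
    sample_id = meta.pop("sample_id", path.stem)
    return build_melting_diagram(points, sample_id=sample_id, metadata=meta, constants=constants)


# ---------------------------------------------------------------------------
# raw-FID route

@dataclass(frozen=True)
class FidSeriesConfig:
    """How to normalize a temperature series of FID traces.

    ``reference_mode``:

    * ``"above_melting"`` — the total-water reference is the mean
      Curie-corrected slow amplitude of traces recorded above 0 °C,
      where all water is mobile (the default, mirroring how the
      reference is obtained experimentally);
    * ``"explicit"`` — ``reference_value`` gives the Curie-corrected
      total-water amplitude directly (e.g. from gravimetric water
      content).
    """

    reference_mode: str = "above_melting"
    reference_value: float | None = None
    curie_reference: float = CELSIUS_OFFSET  # kelvin
    model: FidModelConfig = field(default_factory=FidModelConfig)

    def __post_init__(self):
        if self.reference_mode not in ("above_melting", "explicit"):
            raise InvalidInputError("reference_mode must be 'above_melting' or 'explicit'")
        if self.reference_mode == "explicit" and not (self.reference_value or 0) > 0:
            raise InvalidInputError("explicit reference_mode needs a positive reference_value")


def from_fid_series(
    manifest: str | Path,
    acquisition: AcquisitionSpec | None = None,
    config: FidSeriesConfig | None = None,
    sample_id: str = "",
) -> MeltingDiagram:
    """Build a melting diagram from a manifest of per-temperature FIDs.

    The manifest is a CSV with a ``path`` column (relative paths are
    resolved against the manifest's directory).  Each trace is
    decomposed, Curie-corrected, and normalized by the total-water
    reference; traces above 0 °C serve as the reference by default and
    are not included as MD points.  Unreadable files raise immediately;
    failed decompositions are excluded with a warning, and the build
    fails if fewer than 5 usable points remain.
    """
    config = config or FidSeriesConfig()
    manifest = Path(manifest)
    if not manifest.exists():
        raise InvalidInputError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    if "path" not in table.columns or len(table) == 0:
        raise InvalidInputError(f"{manifest}: manifest needs a non-empty 'path' column")

    corrected: list[tuple[float, float]] = []  # (T_K, curie-corrected slow amplitude)
    provenance: list[dict] = []
    for rel in table["path"]:
        fpath = (manifest.parent / rel) if not Path(rel).is_absolute() else Path(rel)
        if not fpath.exists():
            raise InvalidInputError(f"FID file not found: {fpath}")
        try:
            trace = read_fid(fpath)
            comps = decompose_fid(trace, config.model)
        except Exception as exc:  # noqa: BLE001 - recorded and excluded
            warnings.warn(f"decomposition failed for {fpath.name}: {exc}", stacklevel=2)
            provenance.append({"file": str(fpath.name), "status": f"failed: {exc}"})
            continue
        slow = curie_correct(comps.slow_amplitude_t0, trace.temperature, config.curie_reference)
        corrected.append((trace.temperature, slow))
        provenance.append(
            {"file": str(fpath.name), "status": "ok", "temperature_K": trace.temperature}
        )

    above = [s for T, s in corrected if T > CELSIUS_OFFSET]
    if config.reference_mode == "above_melting":
        if not above:
            raise InvalidInputError(
                "reference_mode='above_melting' but no trace above 0 °C in the series"
            )
        reference = float(np.mean(above))
        reference_source = "above_melting"
    else:
        reference = float(config.reference_value)
        reference_source = "explicit"

    points = [
        (T, mobile_fraction(s, reference)) for T, s in corrected if T <= CELSIUS_OFFSET
    ]
    if len(points) < 5:
        raise InvalidInputError(
            f"only {len(points)} usable sub-melting points after decomposition"
        )
    md = build_melting_diagram(points, sample_id=sample_id or manifest.stem)
    md.metadata["reference_mode"] = reference_source
    md.metadata["curie_reference_K"] = config.curie_reference
    md.metadata["provenance"] = provenance
    return md
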