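"""Model constants, unit conventions, and configuration loading/validation.

Internal unit system is CGS (cm, s, dyne, erg); calcium concentrations are
held in µM.  Configuration I/O uses the presentation units of the source
data: pressures in cmH2O and calcium transient levels in nM.  Every
parameter lives in exactly one dataclass below; :func:`load_config` is the
single entry point that produces a validated :class:`ParameterBundle`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: dyne/cm² per cmH2O
CMH2O = 980.665

#: nm expressed in cm
NM = 1.0e-7


class ConfigError(ValueError):
    """Raised for unparseable, unknown, or invariant-violating configuration."""


def convert_pressure(value_cmh2o: float) -> float:
    """Convert a pressure from cmH2O to dyne/cm²."""
    if not math.isfinite(value_cmh2o):
        raise ConfigError(f"pressure must be finite, got {value_cmh2o}")
    return value_cmh2o * CMH2O


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid parameter '{name}': {msg}")


@dataclass
class PhasicRateParams:
    """Two-state (attach/detach) rate constants for phasic myosin heads."""

    f1: float = 620.0          # attachment slope rate, 1/s
    g1: float = 50.0           # detachment slope rate, 1/s
    g2: float = 210.0          # detachment rate at negative displacement, 1/s
    h: float = 15.6 * NM       # powerstroke length, cm
    dx_trans: float | None = None  # transition half-width, cm (grid coarse spacing)

    def validate(self) -> None:
        for name in ("f1", "g1", "g2", "h"):
            _require(getattr(self, name) > 0, f"phasic.{name}", "must be > 0")
        _require(self.dx_trans is not None, "phasic.dx_trans", "unresolved")
        _require(0 < self.dx_trans < self.h, "phasic.dx_trans", "must lie in (0, h)")


@dataclass
class TonicRateParams:
    """Four-state latch-model rate constants for tonic myosin heads.

    Unspecified derived rates are filled from the standard relations
    K4_2 = 4(K3_1 + K4_1), K4_3 = 3 K4_1, K7_2 = 20 K7_1, K7_3 = 3 K7_1,
    K5 = K2, K6 = K1.
    """

    K1: float = 0.35
    K2: float = 0.1
    K3_1: float = 0.88
    K4_1: float = 0.22
    K7_1: float = 0.12
    K4_2: float | None = None
    K4_3: float | None = None
    K7_2: float | None = None
    K7_3: float | None = None
    K5: float | None = None
    K6: float | None = None

    _DERIVED = {
        "K4_2": lambda s: 4.0 * (s.K3_1 + s.K4_1),
        "K4_3": lambda s: 3.0 * s.K4_1,
        "K7_2": lambda s: 20.0 * s.K7_1,
        "K7_3": lambda s: 3.0 * s.K7_1,
        "K5": lambda s: s.K2,
        "K6": lambda s: s.K1,
    }

    def resolve(self, explicit: set[str] | None = None) -> None:
        """Fill derived rates; check consistency of explicitly given ones."""
        explicit = explicit or set()
        for name, rule in self._DERIVED.items():
            expected = rule(self)
            given = getattr(self, name)
            if given is None:
                setattr(self, name, expected)
            elif name in explicit and not math.isclose(given, expected, rel_tol=1e-12):
                raise ConfigError(
                    f"invalid parameter 'tonic.{name}': value {given} is inconsistent "
                    f"with the default relation (expected {expected}); override the "
                    f"base rates instead, or set tonic.allow_inconsistent: true"
                )

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _require(v is not None and v > 0, f"tonic.{f.name}", "must be > 0")


@dataclass
class CEGeometry:
    """Per-contractile-element counts, densities, and head stiffnesses."""

    N_P: int = 14          # series phasic CEs per row
    N_T: int = 14          # series tonic CEs per row
    Num_P: int = 4500      # myosin heads per phasic CE
    Num_T: int = 1000      # myosin heads per tonic CE
    rho: float = 6.0e5     # actin-site length density, 1/cm
    K_P: float = 0.4       # phasic head stiffness, dyne/cm
    K_T: float = 1.8       # tonic head stiffness, dyne/cm

    def validate(self) -> None:
        for name in ("N_P", "N_T", "Num_P", "Num_T"):
            v = getattr(self, name)
            _require(isinstance(v, int) and v > 0, f"geometry.{name}",
                     "must be a positive integer")
        for name in ("rho", "K_P", "K_T"):
            _require(getattr(self, name) > 0, f"geometry.{name}", "must be > 0")


@dataclass
class CellMechParams:
    """Cell-scale force network constants.

    ``YP_ref`` and ``LCell_ref`` are derived once at simulation
    initialization (from the passive equilibrium diameter) and are then
    immutable; ``ref_fraction`` is the 0.1 reducing factor of the reference formulation.
    """

    N_Rows: int = 18000       # parallel CE rows per cell
    N_Cell: int = 4           # circumferential muscle cells
    E_Cell: float = 75.0      # cell stiffness, dyne/cm
    mu_Cell: float = 50.0     # cell viscosity, dyne·s/cm
    mu_T: float = 10.0        # tonic dashpot viscosity, dyne·s/cm
    a: float = 5.1282e-23     # phasic-spring constitutive, dyne/cm
    b: float = 7.3838e3       # phasic-spring constitutive, 1/cm
    u: float = 1.0e-12        # free energy per ATP, erg
    ref_fraction: float = 0.1 # reducing factor for reference lengths
    YP_ref: float | None = None    # set once at initialization, cm
    LCell_ref: float | None = None # set once at initialization, cm

    def set_reference_lengths(self, YP_ref: float, LCell_ref: float) -> None:
        if self.YP_ref is not None or self.LCell_ref is not None:
            raise ValueError("reference lengths are set once and are immutable")
        _require(YP_ref > 0, "cell.YP_ref", "must be > 0")
        _require(LCell_ref > 0, "cell.LCell_ref", "must be > 0")
        self.YP_ref = YP_ref
        self.LCell_ref = LCell_ref

    def validate(self) -> None:
        for name in ("N_Rows", "N_Cell"):
            v = getattr(self, name)
            _require(isinstance(v, int) and v > 0, f"cell.{name}",
                     "must be a positive integer")
        for name in ("E_Cell", "mu_Cell", "mu_T", "a", "b", "u", "ref_fraction"):
            _require(getattr(self, name) > 0, f"cell.{name}", "must be > 0")


@dataclass
class CalciumParams:
    """Prescribed periodic calcium transient (internal concentrations in µM)."""

    cycletime: float = 5.0    # s
    Ca_amp: float = 0.240     # peak parameter, µM
    Ca_d: float = 0.140       # diastolic concentration, µM
    a2: float = 24.17         # s⁻⁶
    b2: float = 0.5278        # s⁻⁶
    t_Osc: float = 2.5        # oscillation onset within cycle, s
    Osc_Amp: float = 0.0      # fraction of Ca_d
    omega_Osc: float = 0.0    # oscillations per second, 1/s

    def validate(self) -> None:
        _require(self.cycletime > 0, "calcium.cycletime", "must be > 0")
        _require(self.Ca_d > 0, "calcium.Ca_d", "must be > 0")
        _require(self.Ca_amp > self.Ca_d, "calcium.Ca_amp", "must exceed Ca_d")
        _require(0 <= self.t_Osc <= self.cycletime, "calcium.t_Osc",
                 "must lie in [0, cycletime]")
        _require(self.Osc_Amp >= 0, "calcium.Osc_Amp", "must be >= 0")
        _require(self.a2 > 0 and self.b2 > 0, "calcium.a2", "a2, b2 must be > 0")
        _require(self.a2 != self.b2, "calcium.a2", "a2 must differ from b2")


@dataclass
class RegulationParams:
    """Hill-saturation constants for troponin-C and calmodulin (µM)."""

    c05_Trop: float = 0.27
    nm_Trop: float = 12.0
    c05_CaM: float = 8.0
    nm_CaM: float = 1.5

    def validate(self) -> None:
        for name in ("c05_Trop", "nm_Trop", "c05_CaM", "nm_CaM"):
            _require(getattr(self, name) > 0, f"regulation.{name}", "must be > 0")


@dataclass
class TubeLawParams:
    """Passive transmural-pressure/diameter law
    f_pas(D) = P_d·[exp(s_d·(D/D_d − 1)) − c_collapse·(D_d/D)³].

    Defaults are calibrated (see the `calibrate` CLI subcommand) so the
    passive equilibrium at reference pressures sits near 200 µm and the
    periodic reference cycle has a diastolic diameter near 165 µm.
    """

    P_d: float = 626.5876     # pressure scale, dyne/cm² (calibrated)
    D_d: float = 0.0165       # reference diameter, cm
    s_d: float = 2.5          # stiffness exponent
    c_collapse: float = 0.1   # collapse-term weight

    def validate(self) -> None:
        _require(self.P_d > 0, "tube_law.P_d", "must be > 0")
        _require(self.D_d > 0, "tube_law.D_d", "must be > 0")
        _require(self.s_d > 0, "tube_law.s_d", "must be > 0")
        _require(self.c_collapse >= 0, "tube_law.c_collapse", "must be >= 0")


@dataclass
class ValveParams:
    """Sigmoidal valve resistance R_V(dp) = R_Vn + R_Vx/(1 + exp(s_o(dp − dp_o)))."""

    R_Vn: float = 2.0e6       # open resistance, dyne·s/cm⁵
    R_Vx: float = 1.0e10      # closed increment, dyne·s/cm⁵
    s_o: float = 0.2          # slope, cm²/dyne
    dp_o: float = 10.0        # opening offset, dyne/cm²

    def validate(self) -> None:
        _require(self.R_Vn > 0, "valve.R_Vn", "must be > 0")
        _require(self.R_Vx > self.R_Vn, "valve.R_Vx", "must greatly exceed R_Vn")
        _require(self.s_o > 0, "valve.s_o", "must be > 0")
        _require(math.isfinite(self.dp_o), "valve.dp_o", "must be finite")


@dataclass
class VesselParams:
    """Lymphangion geometry, lymph viscosity, and boundary pressures (CGS)."""

    L_v: float = 0.3              # lymphangion length, cm
    mu_lymph: float = 0.01        # lymph viscosity, dyne·s/cm²
    p_a: float = 3.0 * CMH2O      # inlet pressure, dyne/cm²
    p_b: float = 3.1 * CMH2O      # outlet pressure, dyne/cm²
    p_ext: float = 2.0 * CMH2O    # external pressure, dyne/cm²
    D_init: float = 0.02          # initial diameter, cm
    tube_law: TubeLawParams = field(default_factory=TubeLawParams)
    valve1: ValveParams = field(default_factory=ValveParams)
    valve2: ValveParams = field(default_factory=ValveParams)

    def validate(self) -> None:
        _require(self.L_v > 0, "vessel.L_v", "must be > 0")
        _require(self.mu_lymph > 0, "vessel.mu_lymph", "must be > 0")
        _require(self.D_init > 0, "vessel.D_init", "must be > 0")
        for name in ("p_a", "p_b", "p_ext"):
            _require(math.isfinite(getattr(self, name)), f"vessel.{name}",
                     "must be finite")
        self.tube_law.validate()
        self.valve1.validate()
        self.valve2.validate()


@dataclass
class RunControls:
    """Grid resolution, time stepping, cycle caps, periodicity thresholds."""

    n_per_h: int = 20          # coarse bins per powerstroke length
    refine_factor: int = 10    # sub-division inside transition windows
    span: float = 15.0         # grid half-extent in units of h
    dt_max: float = 1.0e-4     # s
    cfl: float = 0.8           # Courant number
    max_cycles: int = 20
    tol_flow_pct: float = 1.0      # |Q̄2−Q̄1|/Q̄2 threshold, %
    tol_yt_cm: float = 1.0e-2      # |mean dY_T/dt|·cycletime threshold, cm
    tol_ft_pct: float = 2.0        # tonic-force drift threshold, %
    record_dt: float = 1.0e-3      # time-series sampling interval, s
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_h", "refine_factor", "max_cycles"):
            v = getattr(self, name)
            _require(isinstance(v, int) and v > 0, f"run.{name}",
                     "must be a positive integer")
        for name in ("span", "dt_max", "tol_flow_pct", "tol_yt_cm", "tol_ft_pct",
                     "record_dt"):
            _require(getattr(self, name) > 0, f"run.{name}", "must be > 0")
        _require(0 < self.cfl <= 1.0, "run.cfl", "must lie in (0, 1]")
        _require(isinstance(self.rng_seed, int), "run.rng_seed",
                 "must be an integer")


@dataclass
class ParameterBundle:
    """Validated full parameter set in internal CGS units."""

    phasic: PhasicRateParams = field(default_factory=PhasicRateParams)
    tonic: TonicRateParams = field(default_factory=TonicRateParams)
    geometry: CEGeometry = field(default_factory=CEGeometry)
    cell: CellMechParams = field(default_factory=CellMechParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    regulation: RegulationParams = field(default_factory=RegulationParams)
    vessel: VesselParams = field(default_factory=VesselParams)
    run: RunControls = field(default_factory=RunControls)

    def validate(self) -> None:
        self.phasic.validate()
        self.tonic.validate()
        self.geometry.validate()
        self.cell.validate()
        self.calcium.validate()
        self.regulation.validate()
        self.vessel.validate()
        self.run.validate()

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        """Flat dotted-key mapping of every effective value in config units."""
        out: dict[str, Any] = {}
        for section, obj in self._sections().items():
            for f in dataclasses.fields(obj):
                if f.name in ("tube_law", "valve1", "valve2"):
                    continue
                key = f"{section}.{f.name}"
                val = getattr(obj, f.name)
                out[key] = _to_config_units(key, val)
        for sub in ("tube_law", "valve1", "valve2"):
            obj = getattr(self.vessel, sub)
            for f in dataclasses.fields(obj):
                out[f"{sub}.{f.name}"] = getattr(obj, f.name)
        return out

    def _sections(self) -> dict[str, Any]:
        return {
            "phasic": self.phasic, "tonic": self.tonic, "geometry": self.geometry,
            "cell": self.cell, "calcium": self.calcium,
            "regulation": self.regulation, "vessel": self.vessel, "run": self.run,
        }

    def copy(self) -> "ParameterBundle":
        import copy as _copy
        return _copy.deepcopy(self)


# Config keys stored internally in CGS but exposed in presentation units.
_PRESSURE_KEYS = {"vessel.p_a", "vessel.p_b", "vessel.p_ext"}
_CA_NM_KEYS = {"calcium.Ca_amp", "calcium.Ca_d"}  # nM in config, µM internal


def _to_config_units(key: str, val: Any) -> Any:
    if key in _PRESSURE_KEYS:
        return val / CMH2O
    if key in _CA_NM_KEYS:
        return val * 1.0e3
    return val


def _to_internal_units(key: str, val: Any) -> Any:
    if key in _PRESSURE_KEYS:
        return convert_pressure(val)
    if key in _CA_NM_KEYS:
        return val * 1.0e-3
    return val


def _flatten(mapping: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, val in mapping.items():
        full = f"{prefix}{key}"
        if isinstance(val, Mapping):
            flat.update(_flatten(val, f"{full}."))
        else:
            flat[full] = val
    return flat


def load_config(source: str | Mapping[str, Any] | None = None) -> ParameterBundle:
    """Build a validated :class:`ParameterBundle`.

    Parameters
    ----------
    source
        ``None`` for pure defaults, a path to a YAML file, or an in-memory
        mapping.  Keys are dotted ``section.field`` names (nested mappings
        are accepted and flattened); unknown keys are rejected.  Pressures
        are given in cmH2O and ``calcium.Ca_amp``/``calcium.Ca_d`` in nM.
    """
    if source is None:
        flat: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        flat = _flatten(source)
    else:
        with open(source, "r") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {source!r} does not contain a mapping")
        flat = _flatten(loaded)

    allow_inconsistent = bool(flat.pop("tonic.allow_inconsistent", False))
    bundle = ParameterBundle()
    sections = bundle._sections()
    subsections = {"tube_law": bundle.vessel.tube_law,
                   "valve1": bundle.vessel.valve1,
                   "valve2": bundle.vessel.valve2}
    explicit_tonic: set[str] = set()

    for key, val in flat.items():
        parts = key.split(".")
        if len(parts) == 2 and parts[0] == "valve":
            # `valve.X` applies to both valves
            targets = [("valve1", parts[1]), ("valve2", parts[1])]
        elif len(parts) == 2:
            targets = [(parts[0], parts[1])]
        elif len(parts) == 3 and parts[0] == "vessel" and parts[1] in subsections:
            targets = [(parts[1], parts[2])]
        else:
            raise ConfigError(f"unknown configuration key '{key}'")
        for section, fname in targets:
            obj = sections.get(section) or subsections.get(section)
            if obj is None:
                raise ConfigError(f"unknown configuration section '{parts[0]}'")
            if fname not in {f.name for f in dataclasses.fields(obj)}:
                raise ConfigError(f"unknown configuration key '{key}'")
            current = getattr(obj, fname)
            if isinstance(current, int) and not isinstance(current, bool) \
                    and not isinstance(val, bool) and isinstance(val, (int, float)) \
                    and float(val).is_integer():
                val_cast: Any = int(val)
            else:
                val_cast = val
            setattr(obj, fname, _to_internal_units(f"{section}.{fname}", val_cast))
            if section == "tonic":
                explicit_tonic.add(fname)

    bundle.tonic.resolve(explicit=set() if allow_inconsistent else explicit_tonic)
    if bundle.phasic.dx_trans is None:
        bundle.phasic.dx_trans = bundle.phasic.h / bundle.run.n_per_h
    bundle.validate()
    return bundle
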