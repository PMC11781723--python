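"""Blood pressure from pulse transit time via a modified Moens-Korteweg model.

The Moens-Korteweg relation ``PWV = sqrt(E h / (rho D))`` links the pulse
wave velocity to the arterial elastic modulus ``E``, wall thickness ``h``,
blood density ``rho`` and lumen diameter ``D``. With the exponential
pressure-elasticity law ``E = E0 * exp(alpha * BP)`` and ``PWV = L / PTT``
for an arterial path-length difference ``L``, solving for pressure gives

    BP = -(2/alpha) * ln(PTT) + (1/alpha) * ln(rho * L^2 * D / (h * E0))

evaluated separately with the systolic transit time and diameter
(``PTT_s``, ``D_s``) for SBP and the diastolic pair for DBP. The closed-form
inverse

    PTT = L * sqrt(rho * D / (h * E0)) * exp(-alpha * BP / 2)

is exposed both as a test oracle and as the generator of model-consistent
synthetic cohorts.

Unit regime
-----------
The published constants (``E0 = 1005``, demographic diameter/thickness
regressions yielding values near 5.5 and 0.58) do not form a dimensionally
consistent SI set, so this module adopts a *model-unit* contract: ``L`` is
in metres, ``rho`` in kg/m^3, and ``D``, ``h`` and ``E0`` are used exactly
on the scale the regressions and constants imply. ``BP`` is in mmHg
(``alpha`` is per mmHg). The round-trip and ratio identities are unit-exact
and carry the verification burden; the absolute pressure scale inherits
whatever units the constants were published in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .anthropometry import BodyGeometry, Demographics
from .errors import InputError, ModelDomainError
from .transit import TransitTimes

#: Fixed-variant constants: literature values for the arterial path-length
#: difference, lumen radius and wall thickness, all in metres.
FIXED_LENGTH_M = 0.2
FIXED_RADIUS_M = 0.005
FIXED_DIAMETER_M = 2.0 * FIXED_RADIUS_M
FIXED_WALL_M = 0.001

#: Soft output range; estimates outside are flagged, never clipped.
BP_PLAUSIBLE_MMHG = (20.0, 300.0)


@dataclass(frozen=True)
class ModelConstants:
    """Population constants of the pressure-elasticity model.

    rho : blood density, kg/m^3 (1060).
    e0 : zero-pressure elastic modulus of the arterial wall, model units
        (1005).
    alpha : exponent of the pressure-elasticity law, per mmHg (0.017).
    """

    rho: float = 1060.0
    e0: float = 1005.0
    alpha: float = 0.017

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.e0 <= 0 or self.alpha <= 0:
            raise InputError("model constants must be strictly positive")


@dataclass(frozen=True)
class VesselParameters:
    """Subject-specific (or fixed) vessel parameters of the model.

    length_m : arterial path-length difference L between the two sites (m).
    diameter_s, diameter_d : systolic/diastolic lumen diameters (model
        length units; equal by default since the demographic regression
        supplies a single diameter).
    wall : wall thickness h (model length units).
    """

    variant: str  # "demographic" | "fixed"
    length_m: float
    diameter_s: float
    diameter_d: float
    wall: float
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        if self.variant not in ("demographic", "fixed"):
            raise InputError(f"unknown variant {self.variant!r}")
        for name in ("length_m", "diameter_s", "diameter_d", "wall"):
            if getattr(self, name) <= 0:
                raise ModelDomainError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "L_m": self.length_m,
            "D_s": self.diameter_s,
            "D_d": self.diameter_d,
            "h": self.wall,
            "rho": self.constants.rho,
            "E0": self.constants.e0,
            "alpha": self.constants.alpha,
        }


@dataclass
class BloodPressureEstimate:
    """One SBP/DBP estimate with full provenance of its inputs."""

    sbp_mmhg: float
    dbp_mmhg: float
    ptt_s: float
    ptt_d: float
    pwv_s: float
    pwv_d: float
    variant: str
    parameters: dict
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sbp_mmHg": self.sbp_mmhg,
            "dbp_mmHg": self.dbp_mmhg,
            "ptt_s": self.ptt_s,
            "ptt_d": self.ptt_d,
            "pwv_s": self.pwv_s,
            "pwv_d": self.pwv_d,
            "variant": self.variant,
            "parameters": self.parameters,
            "qc": self.qc,
        }


def artery_diameter(demo: Demographics) -> float:
    """Arterial lumen diameter from a demographic regression (model units).

    ``D = -0.258 + 0.029*height_cm + 0.006*age_years + 0.036*BMI`` with BMI
    in kg/m^2. The diameter is taken constant along the arterial path.
    Strictly increasing in height, age and BMI.
    """
    d = (
        -0.258
        + 0.029 * demo.height_cm
        + 0.006 * demo.age_years
        + 0.036 * demo.bmi
    )
    if d <= 0:
        raise ModelDomainError(
            f"diameter regression out of validity range (D = {d:.3f})"
        )
    return d


def wall_thickness(demo: Demographics) -> float:
    """Arterial wall thickness from a demographic regression (model units).

    ``h = 0.25 + 0.005*age_years + 0.005*BMI``; strictly increasing in age
    and BMI with intercept 0.25.
    """
    return 0.25 + 0.005 * demo.age_years + 0.005 * demo.bmi


def build_parameters(
    variant: str,
    demo: Demographics | None = None,
    geometry: BodyGeometry | None = None,
    constants: ModelConstants | None = None,
    diameter_ratio: float = 1.0,
) -> VesselParameters:
    """Assemble vessel parameters for either estimator variant.

    demographic
        requires ``demo`` and ``geometry``: L is the geometry's length
        difference converted to metres; D and h come from the demographic
        regressions. ``diameter_ratio`` optionally scales the systolic
        diameter relative to the diastolic one (default 1: the regression
        supplies a single diameter).
    fixed
        literature constants L = 0.2 m, D = 0.01 m (r = 0.005 m),
        h = 0.001 m; requires neither input.
    """
    constants = constants or ModelConstants()
    if variant == "fixed":
        return VesselParameters(
            variant="fixed",
            length_m=FIXED_LENGTH_M,
            diameter_s=FIXED_DIAMETER_M,
            diameter_d=FIXED_DIAMETER_M,
            wall=FIXED_WALL_M,
            constants=constants,
        )
    if variant == "demographic":
        if demo is None or geometry is None:
            raise InputError(
                "demographic variant requires demographics and body geometry"
            )
        d = artery_diameter(demo)
        return VesselParameters(
            variant="demographic",
            length_m=geometry.length_cm / 100.0,
            diameter_s=d * diameter_ratio,
            diameter_d=d,
            wall=wall_thickness(demo),
            constants=constants,
        )
    raise InputError(f"unknown variant {variant!r}")


def _bp_from_ptt(ptt: float, length_m: float, diameter: float, wall: float,
                 c: ModelConstants) -> float:
    if ptt <= 0:
        raise ModelDomainError("model undefined: PTT must be positive")
    if length_m <= 0:
        raise ModelDomainError("model undefined: L must be positive")
    gain = c.rho * length_m * length_m * diameter / (wall * c.e0)
    return (math.log(gain) - 2.0 * math.log(ptt)) / c.alpha


def estimate_bp(ptt: TransitTimes, params: VesselParameters) -> BloodPressureEstimate:
    """Invert the pressure-PTT relation for SBP and DBP.

    SBP uses the systolic transit time and diameter, DBP the diastolic
    ones. The pulse wave velocities ``L/PTT`` and a full parameter snapshot
    are recorded alongside the estimate; implausible outputs (outside
    20-300 mmHg, or SBP <= DBP) are flagged in ``qc`` but not altered.
    """
    c = params.constants
    sbp = _bp_from_ptt(ptt.ptt_s, params.length_m, params.diameter_s, params.wall, c)
    dbp = _bp_from_ptt(ptt.ptt_d, params.length_m, params.diameter_d, params.wall, c)
    flags = []
    if sbp <= dbp:
        flags.append("SBP <= DBP")
    lo, hi = BP_PLAUSIBLE_MMHG
    for name, v in (("SBP", sbp), ("DBP", dbp)):
        if not lo <= v <= hi:
            flags.append(f"{name} = {v:.1f} mmHg outside [{lo}, {hi}]")
    for f in flags:
        warnings.warn(f, stacklevel=2)
    return BloodPressureEstimate(
        sbp_mmhg=sbp,
        dbp_mmhg=dbp,
        ptt_s=ptt.ptt_s,
        ptt_d=ptt.ptt_d,
        pwv_s=params.length_m / ptt.ptt_s,
        pwv_d=params.length_m / ptt.ptt_d,
        variant=params.variant,
        parameters=params.to_dict(),
        qc={
            "warnings": flags,
            "n_pairs_s": ptt.n_pairs_s,
            "n_pairs_d": ptt.n_pairs_d,
        },
    )


def invert_ptt(
    bp_mmhg: float, params: VesselParameters, branch: str = "systolic"
) -> float:
    """Closed-form transit time producing a given blood pressure.

    ``PTT = L * sqrt(rho * D / (h * E0)) * exp(-alpha * BP / 2)`` with the
    branch selecting the systolic or diastolic diameter. Exact algebraic
    inverse of :func:`estimate_bp` (round trip to machine precision);
    strictly decreasing in BP and linear in L.
    """
    if branch == "systolic":
        d = params.diameter_s
    elif branch == "diastolic":
        d = params.diameter_d
    else:
        raise InputError(f"unknown branch {branch!r}")
    c = params.constants
    return (
        params.length_m
        * math.sqrt(c.rho * d / (params.wall * c.e0))
        * math.exp(-c.alpha * bp_mmhg / 2.0)
    )


def variant_offset_mmhg(a: VesselParameters, b: VesselParameters) -> float:
    """Exact BP difference between two parameter sets at equal PTT.

    ``BP_a - BP_b = (1/alpha) * ln[(L_a^2 D_a / h_a) / (L_b^2 D_b / h_b)]``
    (systolic diameters; identical constants assumed). Useful for reasoning
    about the demographic-vs-fixed variant divergence without simulation.
    """
    if a.constants != b.constants:
        raise InputError("variant offset requires identical model constants")
    num = a.length_m**2 * a.diameter_s / a.wall
    den = b.length_m**2 * b.diameter_s / b.wall
    return math.log(num / den) / a.constants.alpha
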