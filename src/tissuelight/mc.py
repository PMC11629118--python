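"""Forward Monte Carlo simulation of double-integrating-sphere measurements.

A tissue sample sandwiched between two glass slides is illuminated at
normal incidence by a narrow collimated beam; diffuse reflectance (Rd)
and total transmittance (Tt) are tallied over finite detection ports,
mirroring a double-integrating-sphere (DIS) instrument. The transport
model is the standard weighted-photon hop-drop-spin random walk in a
layered slab with Henyey-Greenstein scattering and unpolarized Fresnel
boundaries.

Conventions: lengths in mm, coefficients in mm^-1, z positive into the
sample. The collimated specular reflection at launch is computed
analytically and excluded from Rd (a DIS measurement subtracts it as
background); diffuse photons that exit close to the incidence axis can
optionally be folded into the specular tally via a small escape cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel

__all__ = [
    "Layer",
    "LayerStack",
    "BeamGeometry",
    "DetectorGeometry",
    "RTResult",
    "build_slab",
    "sample_step",
    "sample_hg_cosine",
    "fresnel",
    "specular_reflectance",
    "simulate_rt",
]

GLASS_N = 1.524
GLASS_THICKNESS_MM = 1.0
PORT_RADIUS_MM = 3.175       # half of a 0.25 inch detection port
SAMPLE_HALF_WIDTH_MM = 5.0   # samples are ~1 cm across
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class Layer:
    """One slab layer: thickness d, refractive index n, mu_a, mu_s, g."""

    thickness: float
    n: float
    mu_a: float = 0.0
    mu_s: float = 0.0
    g: float = 0.0

    def __post_init__(self):
        if not self.thickness > 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")
        if self.n < 1:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if not -1 < self.g < 1:
            raise ValueError(f"anisotropy g must satisfy -1 < g < 1, got {self.g}")

    @property
    def is_clear(self) -> bool:
        return self.mu_a == 0.0 and self.mu_s == 0.0


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers from the incidence side, in a medium of index ambient_n."""

    layers: tuple[Layer, ...]
    ambient_n: float = 1.0

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("a LayerStack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])


@dataclass(frozen=True)
class BeamGeometry:
    """Flat-top disk beam of given diameter; diameter 0 means pencil beam."""

    diameter: float = 1.0
    profile: str = "flat"

    def __post_init__(self):
        if self.diameter < 0:
            raise ValueError("beam diameter must be >= 0")
        if self.profile not in ("flat", "pencil"):
            raise ValueError(f"unknown beam profile {self.profile!r}")

    @property
    def radius(self) -> float:
        return 0.0 if self.profile == "pencil" else self.diameter / 2.0


@dataclass(frozen=True)
class DetectorGeometry:
    port_radius: float = PORT_RADIUS_MM
    specular_escape_cone_deg: float = 5.0
    sample_half_width: float = SAMPLE_HALF_WIDTH_MM

    def __post_init__(self):
        if not self.port_radius > 0:
            raise ValueError("port_radius must be > 0")
        if not 0 <= self.specular_escape_cone_deg < 90:
            raise ValueError("specular cone must be in [0, 90) degrees")


@dataclass(frozen=True)
class RTResult:
    """Monte Carlo tallies, each a fraction of launched photon weight."""

    Rd: float
    Tt: float
    specular: float
    absorbed: float
    lost: float
    se_Rd: float
    se_Tt: float
    n_photons: int
    seed: int

    def __post_init__(self):
        total = self.specular + self.Rd + self.Tt + self.absorbed + self.lost
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"energy bookkeeping violated: tallies sum to {total}")

    FIELDS = ("Rd", "Tt", "specular", "absorbed", "lost",
              "se_Rd", "se_Tt", "n_photons", "seed")


def build_slab(
    mu_a: float,
    mu_sp: float,
    sample_thickness: float,
    g: float = 0.9,
    n: float = 1.4,
    glass_n: float = GLASS_N,
    glass_thickness: float = GLASS_THICKNESS_MM,
    ambient_n: float = 1.0,
) -> LayerStack:
    """Glass / tissue / glass stack from reduced-scattering inputs.

    The tissue scattering coefficient follows the similarity relation
    mu_s = mu_sp / (1 - g).
    """
    if not sample_thickness > 0:
        raise ValueError("sample_thickness must be > 0")
    if mu_a < 0 or mu_sp < 0:
        raise ValueError("mu_a and mu_sp must be >= 0")
    if not -1 < g < 1:
        raise ValueError("g must satisfy -1 < g < 1")
    mu_s = mu_sp / (1.0 - g)
    glass = Layer(thickness=glass_thickness, n=glass_n)
    tissue = Layer(thickness=sample_thickness, n=n, mu_a=mu_a, mu_s=mu_s, g=g)
    return LayerStack(layers=(glass, tissue, glass), ambient_n=ambient_n)


def sample_step(u: float, mu_t: float) -> float:
    """Free path s = -ln(u)/mu_t for u in (0, 1]."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    if not 0 < u <= 1:
        raise ValueError("u must be in (0, 1]")
    return -math.log(u) / mu_t


def sample_hg_cosine(u: float, g: float) -> float:
    """Henyey-Greenstein deflection cosine from a uniform variate."""
    if not -1 < g < 1:
        raise ValueError("g must satisfy -1 < g < 1")
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, c))


def fresnel(n_i: float, n_t: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflection probability (1 beyond critical angle)."""
    if n_i < 1 or n_t < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0 <= cos_incident <= 1:
        raise ValueError("cos_incident must be in [0, 1]")
    r, _ = _kernel._fresnel(n_i, n_t, cos_incident)
    return r


def specular_reflectance(stack: LayerStack) -> float:
    """Analytic specular reflection of the collimated beam at launch.

    Single-interface Fresnel if the first layer scatters or absorbs;
    when the first layer is clear glass, the two-interface expression
    r1 + (1 - r1)^2 r2 / (1 - r1 r2) accounts for the multiple bounce
    between the entrance face and the glass/tissue interface.
    """
    first = stack.layers[0]
    r1 = fresnel(stack.ambient_n, first.n, 1.0)
    if first.is_clear and len(stack.layers) > 1:
        r2 = fresnel(first.n, stack.layers[1].n, 1.0)
        return r1 + (1.0 - r1) ** 2 * r2 / (1.0 - r1 * r2)
    return r1


def simulate_rt(
    stack: LayerStack,
    beam: BeamGeometry | None = None,
    detector: DetectorGeometry | None = None,
    n_photons: int = 1_000_000,
    seed: int = 0,
) -> RTResult:
    """Run the transport kernel and return normalized tallies.

    Identical (inputs, seed) give bitwise-identical results. Standard
    errors on Rd and Tt come from the per-photon contribution variance.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    beam = beam if beam is not None else BeamGeometry()
    detector = detector if detector is not None else DetectorGeometry()

    layers = stack.layers
    z_bounds = stack.boundaries
    layer_n = np.array([l.n for l in layers])
    layer_mua = np.array([l.mu_a for l in layers])
    layer_mus = np.array([l.mu_s for l in layers])
    layer_g = np.array([l.g for l in layers])

    rsp = specular_reflectance(stack)
    # MCML-style launch: a clear first layer is traversed analytically,
    # the photon starts at the top of the layer beneath it
    if layers[0].is_clear and len(layers) > 1:
        start_layer, start_z = 1, z_bounds[1]
    else:
        start_layer, start_z = 0, 0.0

    cos_cone = math.cos(math.radians(detector.specular_escape_cone_deg))

    tally = _kernel.run_photons(
        int(n_photons),
        int(seed) % (2**32),
        z_bounds,
        layer_n,
        layer_mua,
        layer_mus,
        layer_g,
        stack.ambient_n,
        stack.ambient_n,
        1.0 - rsp,
        start_layer,
        start_z,
        beam.radius,
        detector.port_radius,
        detector.sample_half_width,
        cos_cone,
        WEIGHT_THRESHOLD,
        ROULETTE_SURVIVAL,
    )

    n = float(n_photons)
    rd = tally[_kernel.RD] / n
    tt = tally[_kernel.TT] / n
    absorbed = tally[_kernel.ABSORBED] / n
    lost = tally[_kernel.LOST] / n
    spec = rsp + tally[_kernel.SPEC_DIFFUSE] / n

    def _se(total, total_sq):
        mean = total / n
        var = max(0.0, total_sq / n - mean * mean)
        return math.sqrt(var / n)

    return RTResult(
        Rd=rd,
        Tt=tt,
        specular=spec,
        absorbed=absorbed,
        lost=lost,
        se_Rd=_se(tally[_kernel.RD], tally[_kernel.SUM_RD2]),
        se_Tt=_se(tally[_kernel.TT], tally[_kernel.SUM_TT2]),
        n_photons=int(n_photons),
        seed=int(seed),
    )
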