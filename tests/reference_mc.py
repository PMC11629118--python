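"""Independent, deliberately naive single-photon-loop transport reference.

This is the oracle the production engine is checked against. It is coded
from the physics definitions with different implementation choices so
that shared bugs are unlikely:

* pure Python ``random.Random`` (not the numba/numpy generator);
* the free path is RESAMPLED after every boundary event (valid because
  the exponential distribution is memoryless) instead of carrying the
  dimensionless remaining step across layers;
* Fresnel reflectance evaluated with the angle form
  R = 1/2 [sin^2(ai-at)/sin^2(ai+at) + tan^2(ai-at)/tan^2(ai+at)];
* no Russian roulette — photons are followed until their weight falls
  below an absorption cutoff, with the residual weight sent to the
  absorbed tally (a small, explicit bias of the order of the cutoff,
  1e-6, far below the statistical comparison resolution).

Geometry and tallies (specular cone, detection ports, lateral loss)
follow the same measurement conventions as the production engine.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

W_CUTOFF = 1e-6


@dataclass
class RefResult:
    Rd: float
    Tt: float
    specular: float
    absorbed: float
    lost: float
    se_Rd: float
    se_Tt: float


def fresnel_angles(n_i: float, n_t: float, cos_i: float) -> tuple[float, float]:
    """Unpolarized reflectance via the angle formulation."""
    cos_i = min(1.0, max(0.0, cos_i))
    ai = math.acos(cos_i)
    sin_t = n_i / n_t * math.sin(ai)
    if sin_t >= 1.0:
        return 1.0, 0.0
    at = math.asin(sin_t)
    cos_t = math.cos(at)
    if ai < 1e-6:
        r = ((n_t - n_i) / (n_t + n_i)) ** 2
        return r, cos_t
    sp = math.sin(ai + at)
    sm = math.sin(ai - at)
    tp = math.tan(ai + at)
    tm = math.tan(ai - at)
    r = 0.5 * ((sm / sp) ** 2 + (tm / tp) ** 2)
    return min(1.0, r), cos_t


def simulate_reference(
    layers: list[dict],
    n_photons: int,
    seed: int,
    ambient_n: float = 1.0,
    beam_radius: float = 0.5,
    port_radius: float = 3.175,
    half_width: float = 5.0,
    cone_deg: float = 5.0,
) -> RefResult:
    """Transport ``n_photons`` through ``layers`` (dicts with thickness,
    n, mu_a, mu_s, g, ordered from the incidence side)."""
    rng = random.Random(seed)
    z_top = [0.0]
    for layer in layers:
        z_top.append(z_top[-1] + layer["thickness"])
    n_layers = len(layers)
    cos_cone = math.cos(math.radians(cone_deg))

    # analytic specular launch loss: single interface, or the explicit
    # geometric series for a clear first layer over its two faces
    first = layers[0]
    r1, _ = fresnel_angles(ambient_n, first["n"], 1.0)
    if first["mu_a"] == 0.0 and first["mu_s"] == 0.0 and n_layers > 1:
        r2, _ = fresnel_angles(first["n"], layers[1]["n"], 1.0)
        rsp, bounce = 0.0, r2
        transmitted_in = 1.0 - r1
        rsp = r1
        for _ in range(60):  # geometric series, converges immediately
            rsp += transmitted_in * bounce * (1.0 - r1)
            transmitted_in *= bounce * r1
            if transmitted_in < 1e-16:
                break
        start_layer, start_z = 1, z_top[1]
    else:
        rsp = r1
        start_layer, start_z = 0, 0.0

    t_rd = t_tt = t_abs = t_lost = t_spec = 0.0
    s_rd2 = s_tt2 = 0.0

    for _ in range(n_photons):
        if beam_radius > 0.0:
            rr = beam_radius * math.sqrt(rng.random())
            phi0 = 2.0 * math.pi * rng.random()
            x, y = rr * math.cos(phi0), rr * math.sin(phi0)
        else:
            x = y = 0.0
        z = start_z
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0 - rsp
        k = start_layer
        w_rd = w_tt = 0.0

        while True:
            lay = layers[k]
            mu_t = lay["mu_a"] + lay["mu_s"]
            if mu_t > 0.0:
                s = -math.log(1.0 - rng.random()) / mu_t
            else:
                s = float("inf")
            if uz > 0:
                d_bound = (z_top[k + 1] - z) / uz
            elif uz < 0:
                d_bound = (z_top[k] - z) / uz
            else:
                d_bound = float("inf")

            if d_bound <= s:
                # boundary event; the remaining path is resampled next pass
                x += ux * d_bound
                y += uy * d_bound
                z = z_top[k + 1] if uz > 0 else z_top[k]
                if x * x + y * y > half_width * half_width:
                    t_lost += w
                    break
                down = uz > 0
                n_i = lay["n"]
                if down:
                    n_t = layers[k + 1]["n"] if k + 1 < n_layers else ambient_n
                else:
                    n_t = layers[k - 1]["n"] if k > 0 else ambient_n
                refl, cos_t = fresnel_angles(n_i, n_t, abs(uz))
                if rng.random() < refl:
                    uz = -uz
                    continue
                if down and k == n_layers - 1:
                    if x * x + y * y <= port_radius * port_radius:
                        t_tt += w
                        w_tt = w
                    else:
                        t_lost += w
                    break
                if (not down) and k == 0:
                    if cos_t >= cos_cone:
                        t_spec += w
                    elif x * x + y * y <= port_radius * port_radius:
                        t_rd += w
                        w_rd = w
                    else:
                        t_lost += w
                    break
                scale = n_i / n_t
                ux *= scale
                uy *= scale
                uz = cos_t if down else -cos_t
                k += 1 if down else -1
                continue

            x += ux * s
            y += uy * s
            z += uz * s
            if x * x + y * y > half_width * half_width:
                t_lost += w
                break

            # absorb, then terminate on the weight cutoff
            dw = w * lay["mu_a"] / mu_t
            t_abs += dw
            w -= dw
            if w < W_CUTOFF:
                t_abs += w
                break

            # Henyey-Greenstein deflection
            g = lay["g"]
            u = rng.random()
            if g == 0.0:
                ct = 2.0 * u - 1.0
            else:
                term = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - term * term) / (2.0 * g)
                ct = min(1.0, max(-1.0, ct))
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * rng.random()
            cp, sp_ = math.cos(phi), math.sin(phi)
            if abs(uz) > 0.99999:
                ux, uy = st * cp, st * sp_
                uz = ct if uz >= 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp_) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp_) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz

        s_rd2 += w_rd * w_rd
        s_tt2 += w_tt * w_tt

    n = float(n_photons)

    def se(total, total2):
        mean = total / n
        return math.sqrt(max(0.0, total2 / n - mean * mean) / n)

    return RefResult(
        Rd=t_rd / n,
        Tt=t_tt / n,
        specular=rsp + t_spec / n,
        absorbed=t_abs / n,
        lost=t_lost / n,
        se_Rd=se(t_rd, s_rd2),
        se_Tt=se(t_tt, s_tt2),
    )
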