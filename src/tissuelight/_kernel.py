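"""Numba photon-transport kernel for layered slabs.

Implements the classic weighted hop-drop-spin random walk (MCML scheme):
dimensionless step carried across layer boundaries, unpolarized Fresnel
reflection/refraction at index mismatches, Henyey-Greenstein scattering,
and Russian roulette below a weight threshold.

Energy bookkeeping is exact per run: when roulette kills a photon its
residual weight goes to the absorbed tally, and when it survives the
weight boost (w/p - w) is subtracted from absorbed, so
specular + Rd + Tt + absorbed + lost == launched weight to float
precision while every tally stays unbiased in expectation.
"""

import math

import numpy as np
from numba import njit

# Tally vector layout
RD, TT, ABSORBED, LOST, SPEC_DIFFUSE, SUM_RD2, SUM_TT2 = range(7)

_BIG = 1e30
_MAX_EVENTS = 1_000_000  # guards TIR-trapped photons in clear layers


@njit(cache=True, fastmath=True)
def _fresnel(n_i, n_t, cos_i):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns reflectance 1.0 beyond the critical angle.
    """
    if n_i == n_t:
        return 0.0, cos_i
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    if cos_i > 0.99999:
        r = (n_t - n_i) / (n_t + n_i)
        return r * r, cos_t
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def run_photons(
    n_photons,
    seed,
    z_bounds,      # (L+1,) cumulative boundaries, z_bounds[0] == 0
    layer_n,       # (L,)
    layer_mua,     # (L,)
    layer_mus,     # (L,)
    layer_g,       # (L,)
    n_above,
    n_below,
    w_launch,      # 1 - analytic specular reflectance
    start_layer,
    start_z,
    beam_radius,   # 0 => pencil beam
    port_radius,   # np.inf => open detection
    half_width,    # lateral sample half width; np.inf => infinite slab
    cos_cone,      # back-exits with cos(theta) >= cos_cone count as specular
    w_threshold,
    roulette_p,
):
    """Transport ``n_photons`` and return the raw tally vector.

    Tallies are sums of photon weights (not yet divided by n_photons);
    SUM_RD2 / SUM_TT2 accumulate squared per-photon contributions for
    standard-error estimation.
    """
    np.random.seed(seed)
    n_layers = layer_n.shape[0]
    t_rd = 0.0
    t_tt = 0.0
    t_abs = 0.0
    t_lost = 0.0
    t_spec = 0.0
    s_rd2 = 0.0
    s_tt2 = 0.0
    pr2 = port_radius * port_radius
    hw2 = half_width * half_width

    for _ in range(n_photons):
        # launch: flat-top disk or pencil, straight down
        if beam_radius > 0.0:
            r = beam_radius * math.sqrt(np.random.random())
            ang = 2.0 * math.pi * np.random.random()
            x = r * math.cos(ang)
            y = r * math.sin(ang)
        else:
            x = 0.0
            y = 0.0
        z = start_z
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w_launch
        layer = start_layer
        sleft = 0.0  # dimensionless step remaining
        alive = True
        w_rd = 0.0
        w_tt = 0.0
        n_events = 0

        while alive:
            n_events += 1
            if n_events > _MAX_EVENTS:
                t_lost += w
                break
            mua = layer_mua[layer]
            mus = layer_mus[layer]
            mut = mua + mus

            # --- hop ---
            if mut > 0.0:
                if sleft == 0.0:
                    u = np.random.random()
                    while u <= 0.0:
                        u = np.random.random()
                    sleft = -math.log(u)
                step = sleft / mut
            else:
                step = _BIG  # clear layer: fly to the boundary

            if uz > 0.0:
                db = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_bounds[layer] - z) / uz
            else:
                db = _BIG

            if db <= step:
                # move to the boundary
                x += ux * db
                y += uy * db
                z = z_bounds[layer + 1] if uz > 0.0 else z_bounds[layer]
                if mut > 0.0:
                    sleft -= db * mut
                    if sleft < 0.0:
                        sleft = 0.0

                if x * x + y * y > hw2:
                    t_lost += w
                    alive = False
                    continue

                going_down = uz > 0.0
                n_i = layer_n[layer]
                if going_down:
                    n_t = n_below if layer == n_layers - 1 else layer_n[layer + 1]
                else:
                    n_t = n_above if layer == 0 else layer_n[layer - 1]
                refl, cos_t = _fresnel(n_i, n_t, abs(uz))

                if np.random.random() < refl:
                    uz = -uz  # internal reflection
                else:
                    if going_down and layer == n_layers - 1:
                        # exit far side
                        if x * x + y * y <= pr2:
                            t_tt += w
                            w_tt = w
                        else:
                            t_lost += w
                        alive = False
                        continue
                    if (not going_down) and layer == 0:
                        # exit incidence side
                        if cos_t >= cos_cone:
                            t_spec += w
                        elif x * x + y * y <= pr2:
                            t_rd += w
                            w_rd = w
                        else:
                            t_lost += w
                        alive = False
                        continue
                    # refract into the neighbouring layer
                    ratio = n_i / n_t
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    layer += 1 if going_down else -1
                continue

            # interior move
            x += ux * step
            y += uy * step
            z += uz * step
            sleft = 0.0

            if x * x + y * y > hw2:
                t_lost += w
                alive = False
                continue

            # --- drop ---
            dw = w * mua / mut
            t_abs += dw
            w -= dw

            # --- spin (Henyey-Greenstein) ---
            g = layer_g[layer]
            u = np.random.random()
            if g == 0.0:
                cos_sc = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cos_sc = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_sc > 1.0:
                    cos_sc = 1.0
                elif cos_sc < -1.0:
                    cos_sc = -1.0
            phi = 2.0 * math.pi * np.random.random()
            sin_sc = math.sqrt(max(0.0, 1.0 - cos_sc * cos_sc))
            cos_p = math.cos(phi)
            sin_p = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_sc * cos_p
                uy = sin_sc * sin_p
                uz = cos_sc if uz >= 0.0 else -cos_sc
            else:
                tmp = math.sqrt(1.0 - uz * uz)
                nux = sin_sc * (ux * uz * cos_p - uy * sin_p) / tmp + ux * cos_sc
                nuy = sin_sc * (uy * uz * cos_p + ux * sin_p) / tmp + uy * cos_sc
                uz = -sin_sc * cos_p * tmp + uz * cos_sc
                ux = nux
                uy = nuy

            # --- roulette ---
            if w < w_threshold:
                if w <= 0.0:
                    alive = False
                elif np.random.random() < roulette_p:
                    boost = w / roulette_p - w
                    t_abs -= boost
                    w += boost
                else:
                    t_abs += w
                    alive = False

        s_rd2 += w_rd * w_rd
        s_tt2 += w_tt * w_tt

    out = np.empty(7)
    out[RD] = t_rd
    out[TT] = t_tt
    out[ABSORBED] = t_abs
    out[LOST] = t_lost
    out[SPEC_DIFFUSE] = t_spec
    out[SUM_RD2] = s_rd2
    out[SUM_TT2] = s_tt2
    return out
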