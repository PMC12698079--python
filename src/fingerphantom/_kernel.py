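"""Compiled photon-packet transport kernel.

Everything in this module is numba ``@njit`` code operating on scalars
and small arrays; the user-facing API lives in :mod:`.mc_transport`.

Conventions (mm, mm^-1 throughout):

* right-handed coordinates, the beam travels along +z;
* slab: faces at z = 0 (illuminated) and z = d, laterally bounded by a
  cylinder of radius ``lat_r`` about the z axis;
* cylinder: axis along y, barrel x^2 + z^2 = r^2, end caps at
  y = +-half_len, illuminated perpendicular to the axis;
* photon weights: absorption by albedo scaling at each interaction,
  Russian roulette below ``w_min`` with survival probability ``p_surv``
  (survivor weight divided by ``p_surv``); any weight that never escapes
  is absorbed weight, so R + T + A + L = 1 holds exactly by bookkeeping.

The RNG is splitmix64 seeded per photon from (run seed, photon index),
making every photon's history independent of execution order.
"""

import numpy as np
from numba import njit

# geometry kind tags
SLAB = 0
CYLINDER = 1

# escape channel tags
CH_REFLECT = 0
CH_TRANSMIT = 1
CH_LOST = 2

_INV_2_53 = 1.0 / 9007199254740992.0
_MAX_STEPS = 10_000_000


@njit(cache=True)
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _photon_state(seed, idx):
    """Initial splitmix64 state for photon ``idx`` of run ``seed``."""
    a = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
    b = (np.uint64(idx) + np.uint64(1)) * np.uint64(0xD1B54A32D192ED03)
    return _mix64(a ^ b)


@njit(cache=True)
def _next_u(state):
    """Advance splitmix64; return (new_state, uniform double in [0,1))."""
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = _mix64(state)
    return state, float(z >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def hg_cos(g, u):
    """Henyey-Greenstein deflection cosine from a uniform variate."""
    if g > -1e-9 and g < 1e-9:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def fresnel(n1, n2, ci):
    """Unpolarized Fresnel reflection probability.

    Returns (R, cos_transmitted, tir_flag) for incidence cosine ``ci``
    in (0, 1] going from index ``n1`` into ``n2``.
    """
    if n1 == n2:
        return 0.0, ci, False
    eta = n1 / n2
    st2 = eta * eta * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0, 0.0, True
    ct = np.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct, False


@njit(cache=True)
def boundary_distance(kind, dim1, dim2, x, y, z, ux, uy, uz):
    """Distance to the first boundary crossing and the face hit.

    Faces: slab 0 = z=0 plane, 1 = z=d plane, 2 = lateral barrel;
    cylinder 0 = barrel, 1 = caps.
    """
    eps = 1e-12
    best = 1e30
    face = -1
    if kind == SLAB:
        d = dim1
        lat_r = dim2
        if uz < -eps:
            t = -z / uz
            if t < best:
                best = t
                face = 0
        elif uz > eps:
            t = (d - z) / uz
            if t < best:
                best = t
                face = 1
        a = ux * ux + uy * uy
        if a > eps:
            b = 2.0 * (x * ux + y * uy)
            c = x * x + y * y - lat_r * lat_r
            disc = b * b - 4.0 * a * c
            if disc > 0.0:
                t = (-b + np.sqrt(disc)) / (2.0 * a)
                if eps < t < best:
                    best = t
                    face = 2
    else:
        r = dim1
        half_len = dim2
        a = ux * ux + uz * uz
        if a > eps:
            b = 2.0 * (x * ux + z * uz)
            c = x * x + z * z - r * r
            disc = b * b - 4.0 * a * c
            if disc > 0.0:
                t = (-b + np.sqrt(disc)) / (2.0 * a)
                if eps < t < best:
                    best = t
                    face = 0
        if uy > eps:
            t = (half_len - y) / uy
            if eps < t < best:
                best = t
                face = 1
        elif uy < -eps:
            t = (-half_len - y) / uy
            if eps < t < best:
                best = t
                face = 1
    return best, face


@njit(cache=True)
def _outward_normal(kind, dim1, face, x, y, z):
    if kind == SLAB:
        if face == 0:
            return 0.0, 0.0, -1.0
        if face == 1:
            return 0.0, 0.0, 1.0
        rho = np.sqrt(x * x + y * y)
        return x / rho, y / rho, 0.0
    if face == 0:
        rho = np.sqrt(x * x + z * z)
        return x / rho, 0.0, z / rho
    return 0.0, 1.0 if y > 0.0 else -1.0, 0.0


@njit(cache=True)
def classify_exit(kind, face, x, y, z, port_r):
    """Escape channel from the exit position (position-only acceptance)."""
    if kind == SLAB:
        if face == 2:
            return CH_LOST
        rho = np.sqrt(x * x + y * y)
        if rho > port_r:
            return CH_LOST
        return CH_REFLECT if face == 0 else CH_TRANSMIT
    if face == 1:  # end caps
        return CH_LOST
    rho = np.sqrt(x * x + y * y)  # distance from the beam (z) axis
    if rho > port_r:
        return CH_LOST
    return CH_REFLECT if z < 0.0 else CH_TRANSMIT


@njit(cache=True)
def _spin(ux, uy, uz, cost, phi):
    """Rotate direction by deflection cosine ``cost`` and azimuth ``phi``."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz > 0.0 else -cost
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def run_photons(kind, dim1, dim2, mu_a, mu_s, g, n_in, n_out,
                beam_r, port_r, count_specular,
                n_photons, seed, w_min, p_surv):
    """Trace ``n_photons`` packets; return channel weight sums.

    Output array: [sum_R, sum_T, sum_L, sum_R2, sum_T2] where *2 are
    sums of squared per-photon channel weights (for standard errors).
    Absorbed weight is the exact remainder n_photons - sums.
    """
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t if mu_t > 0.0 else 1.0
    geo_r = dim1 if kind == CYLINDER else dim2  # radial bound for launch

    sum_r = 0.0
    sum_t = 0.0
    sum_l = 0.0
    sum_r2 = 0.0
    sum_t2 = 0.0

    for i in range(n_photons):
        state = _photon_state(seed, i)

        # --- launch position on the illuminated surface ---
        x0 = 0.0
        y0 = 0.0
        if beam_r > 0.0:
            # flat-top disc: rejection-free polar sampling
            state, u1 = _next_u(state)
            state, u2 = _next_u(state)
            rr = beam_r * np.sqrt(u1)
            x0 = rr * np.cos(2.0 * np.pi * u2)
            y0 = rr * np.sin(2.0 * np.pi * u2)
            if kind == CYLINDER and abs(x0) >= 0.999 * geo_r:
                x0 = 0.999 * geo_r * (1.0 if x0 > 0.0 else -1.0)
        if kind == SLAB:
            x = x0
            y = y0
            z = 0.0
            nxo, nyo, nzo = 0.0, 0.0, -1.0
        else:
            x = x0
            y = y0
            z = -np.sqrt(dim1 * dim1 - x0 * x0)
            rho = np.sqrt(x * x + z * z)
            nxo, nyo, nzo = x / rho, 0.0, z / rho

        # --- entry refraction (outside -> inside) ---
        ci = -nzo  # -(d . n_outward) with d = (0,0,1)
        rf, ct, tir = fresnel(n_out, n_in, ci)
        state, u = _next_u(state)
        if tir or u < rf:
            # specular reflection off the surface, never entered
            if count_specular:
                sum_r += 1.0
                sum_r2 += 1.0
            else:
                sum_l += 1.0
            continue
        eta = n_out / n_in
        ux = eta * 0.0 + (eta * ci - ct) * nxo
        uy = eta * 0.0 + (eta * ci - ct) * nyo
        uz = eta * 1.0 + (eta * ci - ct) * nzo
        nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= nrm
        uy /= nrm
        uz /= nrm

        w = 1.0
        alive = True
        for _step in range(_MAX_STEPS):
            if not alive:
                break
            state, u = _next_u(state)
            if mu_t > 0.0:
                s = -np.log(1.0 - u) / mu_t
            else:
                s = 1e30
            db, face = boundary_distance(kind, dim1, dim2, x, y, z, ux, uy, uz)
            if face < 0:
                # numerically stuck on a boundary edge: drop as lost
                sum_l += w
                alive = False
                break
            if s < db:
                # interaction inside the medium
                x += s * ux
                y += s * uy
                z += s * uz
                w *= albedo  # absorbed fraction stays behind
                if w <= 0.0:
                    alive = False
                    break
                state, u = _next_u(state)
                cost = hg_cos(g, u)
                state, u = _next_u(state)
                ux, uy, uz = _spin(ux, uy, uz, cost, 2.0 * np.pi * u)
                if w < w_min:
                    state, u = _next_u(state)
                    if u < p_surv:
                        w /= p_surv
                    else:
                        alive = False  # residual weight -> absorbed
                        break
            else:
                # boundary hit
                x += db * ux
                y += db * uy
                z += db * uz
                if kind == SLAB:
                    if face == 0:
                        z = 0.0
                    elif face == 1:
                        z = dim1
                else:
                    if face == 1:
                        y = dim2 if y > 0.0 else -dim2
                nxo, nyo, nzo = _outward_normal(kind, dim1, face, x, y, z)
                ci = ux * nxo + uy * nyo + uz * nzo
                if ci < 1e-12:
                    ci = 1e-12
                elif ci > 1.0:
                    ci = 1.0
                rf, ct, tir = fresnel(n_in, n_out, ci)
                state, u = _next_u(state)
                if tir or u < rf:
                    ux -= 2.0 * ci * nxo
                    uy -= 2.0 * ci * nyo
                    uz -= 2.0 * ci * nzo
                else:
                    ch = classify_exit(kind, face, x, y, z, port_r)
                    if ch == CH_REFLECT:
                        sum_r += w
                        sum_r2 += w * w
                    elif ch == CH_TRANSMIT:
                        sum_t += w
                        sum_t2 += w * w
                    else:
                        sum_l += w
                    alive = False
        else:
            # step budget exhausted (pathological): drop as lost
            sum_l += w

    out = np.empty(5)
    out[0] = sum_r
    out[1] = sum_t
    out[2] = sum_l
    out[3] = sum_r2
    out[4] = sum_t2
    return out
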