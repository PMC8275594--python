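"""Compiled weighted-photon transport kernel.

Single-threaded numba loop over photon packets.  Each packet is
launched from the truncated-Gaussian beam with weight 1 - R_spec,
propagated with exponential free paths clipped at layer interfaces
(the dimensionless optical path mu_t * s is conserved across
interfaces), loses weight by implicit capture at each interaction,
scatters by Henyey-Greenstein, undergoes Fresnel reflection/escape at
the air-tissue surface, and is terminated by Russian roulette, lateral
or bottom escape, or the event cap.

The RNG is numba's per-thread Mersenne Twister seeded at kernel entry,
so a run is bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["transport_kernel"]


@njit(cache=True)
def _fresnel_unpol(ci, n_from, n_to):
    sin_t2 = (n_from / n_to) ** 2 * (1.0 - ci * ci)
    if sin_t2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - sin_t2)
    rs = ((n_from * ci - n_to * ct) / (n_from * ci + n_to * ct)) ** 2
    rp = ((n_from * ct - n_to * ci) / (n_from * ct + n_to * ci)) ** 2
    return 0.5 * (rs + rp)


@njit(cache=True)
def transport_kernel(
    seed,
    n_photons,
    z_edges,          # (n_layers+1,) interface depths, z_edges[0] == 0
    mu_a,             # (n_layers,)
    mu_s,             # (n_layers,)
    g,
    n_tissue,
    n_external,
    half_lateral,     # lateral half-width (mm)
    beam_radius,
    beam_trunc_radii,
    flat_beam,        # bool: flat-top instead of Gaussian
    beam_center_x,
    det_x,            # detector centre x (= separation)
    det_radius,
    ring_detector,    # bool: accept an annulus |r - det_x| <= det_radius
    weight_threshold,
    roulette_survival,
    max_events,
    record_map,       # bool
    map_all_paths,    # bool: accumulate every path, not only detected ones
    map_origin,       # (3,) x0, y0, z0 of the voxel grid
    map_voxel,
    event_map,        # (nx, ny, nz) int64, modified in place
    event_buf,        # (max_events, 3) int32 scratch for detected-only maps
    exit_x,           # (n_photons,) outputs for detected packets
    exit_y,
    exit_w,
    max_depth,
    n_events_out,
    layer_path_out,   # (n_photons, n_layers) path length per layer, detected packets
):
    np.random.seed(seed)
    n_layers = mu_a.shape[0]
    mu_t = mu_a + mu_s
    r_spec = ((n_tissue - n_external) / (n_tissue + n_external)) ** 2
    total_depth = z_edges[n_layers]
    trunc = beam_trunc_radii * beam_radius
    gauss_norm = 1.0 - np.exp(-2.0 * beam_trunc_radii * beam_trunc_radii)
    nx = event_map.shape[0]
    ny = event_map.shape[1]
    nz = event_map.shape[2]

    detected_w = 0.0
    detected_w2 = 0.0
    absorbed_w = 0.0
    escaped_other_w = 0.0
    specular_w = 0.0
    n_detected = 0
    n_cap_exceeded = 0
    path_len = np.zeros(n_layers)

    for _ in range(n_photons):
        # --- launch ---
        xi = np.random.random()
        if flat_beam:
            r = trunc * np.sqrt(xi)
        else:
            r = beam_radius * np.sqrt(-0.5 * np.log(1.0 - xi * gauss_norm))
        phi = 2.0 * np.pi * np.random.random()
        x = beam_center_x + r * np.cos(phi)
        y = r * np.sin(phi)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - r_spec
        specular_w += r_spec
        layer = 0
        mz = 0.0
        nev = 0
        nbuf = 0
        alive = True
        for k in range(n_layers):
            path_len[k] = 0.0

        while alive:
            tau = -np.log(1.0 - np.random.random())
            # --- move, clipping at interfaces (mu_t * s conserved) ---
            while tau > 0.0:
                mt = mu_t[layer]
                s = tau / mt
                if uz > 0.0:
                    db = (z_edges[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_edges[layer] - z) / uz
                else:
                    db = 1.0e30
                if s < db:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    path_len[layer] += s
                    tau = 0.0
                else:
                    x += db * ux
                    y += db * uy
                    path_len[layer] += db
                    tau -= db * mt
                    if uz > 0.0:
                        z = z_edges[layer + 1]
                        if layer == n_layers - 1:
                            escaped_other_w += w  # bottom escape
                            alive = False
                        else:
                            layer += 1
                    else:
                        z = z_edges[layer]
                        if layer == 0:
                            # air-tissue surface from below
                            ci = -uz
                            if np.random.random() >= _fresnel_unpol(ci, n_tissue, n_external):
                                if ring_detector:
                                    rr = np.sqrt(x * x + y * y)
                                    hit = np.abs(rr - det_x) <= det_radius
                                else:
                                    dx = x - det_x
                                    hit = dx * dx + y * y <= det_radius * det_radius
                                if hit:
                                    detected_w += w
                                    detected_w2 += w * w
                                    exit_x[n_detected] = x
                                    exit_y[n_detected] = y
                                    exit_w[n_detected] = w
                                    max_depth[n_detected] = mz
                                    n_events_out[n_detected] = nev
                                    for k in range(n_layers):
                                        layer_path_out[n_detected, k] = path_len[k]
                                    n_detected += 1
                                    if record_map and not map_all_paths:
                                        for k in range(nbuf):
                                            event_map[
                                                event_buf[k, 0],
                                                event_buf[k, 1],
                                                event_buf[k, 2],
                                            ] += 1
                                else:
                                    escaped_other_w += w
                                alive = False
                            else:
                                uz = -uz  # internal reflection
                        else:
                            layer -= 1
                if z > mz:
                    mz = z
                if not alive:
                    break
                if x < -half_lateral or x > half_lateral or y < -half_lateral or y > half_lateral:
                    escaped_other_w += w  # lateral escape
                    alive = False
                    break
            if not alive:
                break

            # --- interaction: implicit-capture deposit ---
            dep = w * mu_a[layer] / mu_t[layer]
            absorbed_w += dep
            w -= dep
            if record_map:
                ix = int((x - map_origin[0]) / map_voxel)
                iy = int((y - map_origin[1]) / map_voxel)
                iz = int((z - map_origin[2]) / map_voxel)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    if map_all_paths:
                        event_map[ix, iy, iz] += 1
                    elif nbuf < max_events:
                        event_buf[nbuf, 0] = ix
                        event_buf[nbuf, 1] = iy
                        event_buf[nbuf, 2] = iz
                        nbuf += 1

            # --- Henyey-Greenstein scatter ---
            xi2 = np.random.random()
            if g == 0.0:
                ct = 2.0 * xi2 - 1.0
            else:
                t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi2)
                ct = (1.0 + g * g - t * t) / (2.0 * g)
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            sphi = 2.0 * np.pi * np.random.random()
            cp = np.cos(sphi)
            sp = np.sin(sphi)
            if np.abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                nrm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / nrm
                uy = nuy / nrm
                uz = nuz / nrm
            nev += 1

            if nev >= max_events:
                # safety cap: pool the residual weight with the escapes
                n_cap_exceeded += 1
                escaped_other_w += w
                alive = False
                break

            # --- Russian roulette ---
            if w < weight_threshold:
                if roulette_survival >= 1.0:
                    pass  # roulette disabled
                elif np.random.random() < roulette_survival:
                    w /= roulette_survival
                else:
                    alive = False  # terminated; weight vanishes (unbiased)

    return (
        n_detected,
        detected_w,
        detected_w2,
        absorbed_w,
        escaped_other_w,
        specular_w,
        n_cap_exceeded,
    )
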