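"""Independent reference implementations used only to cross-check the
package: an Abeles transfer-matrix reflectivity code, a numerical Fourier
transform of sampled relaxation transients, Monte-Carlo Voronoi areas, and
brute-force pair/triple enumerations for contacts and hydrogen bonds.
These deliberately share no code with the implementations they verify.
"""

import numpy as np

R_E = 2.818e-5  # classical electron radius, Å


def abeles_reflectivity(thicknesses, rhos, sigmas, subphase_rho, qz):
    """Transfer-matrix specular reflectivity with Névot–Croce roughness.

    ``thicknesses``/``rhos``/``sigmas`` describe the slabs air→subphase;
    ``sigmas`` has one extra entry for the subphase interface.
    """
    qz = np.asarray(qz, dtype=float)
    all_rho = [0.0] + list(rhos) + [subphase_rho]
    kz = [np.sqrt((qz / 2.0).astype(complex) ** 2 - 4 * np.pi * R_E * rho)
          for rho in all_rho]
    n_int = len(all_rho) - 1
    M00 = np.ones_like(kz[0])
    M01 = np.zeros_like(kz[0])
    M10 = np.zeros_like(kz[0])
    M11 = np.ones_like(kz[0])
    for i in range(n_int):
        r = (kz[i] - kz[i + 1]) / (kz[i] + kz[i + 1]) \
            * np.exp(-2.0 * kz[i] * kz[i + 1] * sigmas[i] ** 2)
        # interface matrix (scalar prefactor cancels in the ratio)
        I00, I01, I10, I11 = np.ones_like(r), r, r, np.ones_like(r)
        N00 = M00 * I00 + M01 * I10
        N01 = M00 * I01 + M01 * I11
        N10 = M10 * I00 + M11 * I10
        N11 = M10 * I01 + M11 * I11
        M00, M01, M10, M11 = N00, N01, N10, N11
        if i < n_int - 1:
            ph = np.exp(-1j * kz[i + 1] * thicknesses[i])
            P00, P11 = ph, 1.0 / ph
            M00, M01 = M00 * P00, M01 * P11
            M10, M11 = M10 * P00, M11 * P11
    return np.abs(M10 / M00) ** 2


def numerical_spectrum(time, delta_pi, u, nu_grid):
    """E*(ν) by trapezoidal Fourier transform of a sampled step-strain
    transient, with an analytic single-exponential tail correction.

    E*(ω) = E∞ + (iω/u) ∫₀^∞ (Δπ(t) − Δπ∞) e^{−iωt} dt, with Δπ∞ taken
    from the final sample and the t > T tail extrapolated from the decay
    rate of the last stretch of the record.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(delta_pi, dtype=float)
    y_inf = y[-1]
    g = y - y_inf
    omega = 2.0 * np.pi * np.asarray(nu_grid, dtype=float)
    # tail decay estimated from the last decade of |g|
    mask = g > max(g.max() * 1e-10, 1e-300)
    tt, gg = t[mask], g[mask]
    n_tail = max(5, tt.size // 10)
    lam_fit = np.polyfit(tt[-n_tail:], np.log(gg[-n_tail:]), 1)
    lam = -lam_fit[0]
    C = np.exp(lam_fit[1])
    out = np.empty(omega.size, dtype=complex)
    for k, w in enumerate(omega):
        integrand = g * np.exp(-1j * w * t)
        integral = np.trapezoid(integrand, t)
        if lam > 0:
            integral += C * np.exp(-(lam + 1j * w) * t[-1]) / (lam + 1j * w)
        out[k] = y_inf / u + 1j * w * integral / u
    return out.real, out.imag


def mc_voronoi_areas(points_xy, box_xy, n_samples, seed):
    """Per-point Voronoi areas by nearest-point Monte-Carlo integration
    with periodic minimum image."""
    rng = np.random.default_rng(seed)
    pts = np.mod(np.asarray(points_xy, dtype=float), box_xy)
    counts = np.zeros(pts.shape[0], dtype=np.int64)
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        samples = rng.uniform([0, 0], box_xy, size=(m, 2))
        disp = samples[:, None, :] - pts[None, :, :]
        for ax in range(2):
            disp[..., ax] -= box_xy[ax] * np.round(disp[..., ax] / box_xy[ax])
        d2 = (disp**2).sum(axis=-1)
        nearest = np.argmin(d2, axis=1)
        counts += np.bincount(nearest, minlength=pts.shape[0])
        remaining -= m
    return counts / n_samples * box_xy[0] * box_xy[1]


def _min_image(d, box, periodic):
    d = np.array(d, dtype=float)
    for ax in range(3):
        if periodic[ax]:
            d[ax] -= box[ax] * np.round(d[ax] / box[ax])
    return d


def brute_force_contacts(coords_a, names_a, coords_b, names_b, box, periodic,
                         cutoff):
    """O(N²) atom-pair contact counts keyed by (name_a, name_b)."""
    counts = {}
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            d = _min_image(coords_a[i] - coords_b[j], box, periodic)
            if np.sqrt((d**2).sum()) < cutoff:
                key = (names_a[i], names_b[j])
                counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_hbonds(coords, donors, acceptors, box, periodic,
                       d_max=3.5, angle_min=150.0):
    """O(N³) hydrogen-bond set: (donor_idx, h_idx, acceptor_idx) triples.

    ``donors``: list of (mol_id, donor_idx, [h_idx...]); ``acceptors``:
    list of (mol_id, acceptor_idx). One bond per donor–acceptor pair (the
    first hydrogen satisfying the geometry).
    """
    bonds = set()
    for d_mid, d_idx, h_list in donors:
        for a_mid, a_idx in acceptors:
            if d_mid == a_mid:
                continue
            da = _min_image(coords[a_idx] - coords[d_idx], box, periodic)
            if np.sqrt((da**2).sum()) >= d_max:
                continue
            for h_idx in h_list:
                hd = _min_image(coords[d_idx] - coords[h_idx], box, periodic)
                ha = _min_image(coords[a_idx] - coords[h_idx], box, periodic)
                cos_ang = np.dot(hd, ha) / np.sqrt((hd**2).sum() * (ha**2).sum())
                ang = np.degrees(np.arccos(np.clip(cos_ang, -1, 1)))
                if ang > angle_min:
                    bonds.add((d_idx, h_idx, a_idx))
                    break
    return bonds
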