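"""Numba kernels for the hot loops.

All kernels operate on the packed array form of a funnel landscape
(see :class:`sasmd.landscape.FunnelLandscape.kernel_args`):

``center``  (3,)     well centre, nm
``dirs``    (nc, 3)  unit channel directions
``kappa``   (nc,)    angular concentration, 1/width**2
``amp``     (nc,)    barrier depression per channel, B_bg - B_i, kJ/mol
``opened``  (nc,)    1.0 if the channel notches the guide wall, else 0.0
``scal``    (10,)    [depth, well_width, B_bg, shell_radius, shell_width,
                      core_softening, background_stiffness,
                      guide_amp, guide_on, guide_off]

Energies are kJ/mol, lengths nm, time ps, forces kJ/mol/nm.  Random numbers
come from a ``numpy.random.Generator`` passed in by the caller; every step
draws exactly one standard-normal 3-vector so that checkpointed generator
state fully determines the trajectory.
"""

import numpy as np
from numba import njit

# pull-loop exit statuses
STATUS_RUNNING = 0
STATUS_TRIGGER = 1
STATUS_UNBOUND = 2
STATUS_TIMEOUT = 3


@njit(cache=True)
def funnel_energy_one(r, center, dirs, kappa, amp, opened, scal):
    depth, sw, bbg, db, sb, eps, ks = scal[0], scal[1], scal[2], scal[3], scal[4], scal[5], scal[6]
    g_amp, g_on, g_off = scal[7], scal[8], scal[9]
    wx = r[0] - center[0]
    wy = r[1] - center[1]
    wz = r[2] - center[2]
    d2 = wx * wx + wy * wy + wz * wz
    u_well = -depth * np.exp(-d2 / (2.0 * sw * sw))
    d = np.sqrt(d2)
    rho = np.sqrt(d2 + eps * eps)
    # origin regularization (0.05 nm) removes the angular term's residual
    # slope at the well centre; negligible at the shell radius
    s = np.exp(-(d - db) * (d - db) / (2.0 * sb * sb)) \
        * (1.0 - np.exp(-d2 / 0.005))
    b = bbg
    p_open = 1.0
    for c in range(dirs.shape[0]):
        ca = (wx * dirs[c, 0] + wy * dirs[c, 1] + wz * dirs[c, 2]) / rho
        g = np.exp(kappa[c] * (ca - 1.0))
        b -= amp[c] * g
        if opened[c] > 0.5:
            p_open *= 1.0 - g
    u = u_well + b * s + 0.5 * ks * d2
    if g_amp > 0.0:
        guide = (1.0 - np.exp(-d2 / (2.0 * g_on * g_on))) \
            * np.exp(-(d / g_off) ** 4)
        u += g_amp * guide * p_open
    return u


@njit(cache=True)
def funnel_grad_one(r, center, dirs, kappa, amp, opened, scal, out):
    depth, sw, bbg, db, sb, eps, ks = scal[0], scal[1], scal[2], scal[3], scal[4], scal[5], scal[6]
    g_amp, g_on, g_off = scal[7], scal[8], scal[9]
    wx = r[0] - center[0]
    wy = r[1] - center[1]
    wz = r[2] - center[2]
    d2 = wx * wx + wy * wy + wz * wz
    d = np.sqrt(d2)
    rho = np.sqrt(d2 + eps * eps)
    rho3 = rho * rho * rho
    ew = np.exp(-d2 / (2.0 * sw * sw))
    cw = depth / (sw * sw) * ew  # d(-D e)/dr = +(D/sw^2) e * w
    gx = cw * wx + ks * wx
    gy = cw * wy + ks * wy
    gz = cw * wz + ks * wz
    s0 = np.exp(-(d - db) * (d - db) / (2.0 * sb * sb))
    q = 1.0 - np.exp(-d2 / 0.005)  # origin regularization, as in the energy
    qp = (2.0 * d / 0.005) * np.exp(-d2 / 0.005)
    s = s0 * q
    sp = -((d - db) / (sb * sb)) * s0 * q + s0 * qp
    nc = dirs.shape[0]
    gvals = np.empty(nc)
    dgx = np.empty(nc)
    dgy = np.empty(nc)
    dgz = np.empty(nc)
    b = bbg
    for c in range(nc):
        dot = wx * dirs[c, 0] + wy * dirs[c, 1] + wz * dirs[c, 2]
        ca = dot / rho
        g = np.exp(kappa[c] * (ca - 1.0))
        gvals[c] = g
        b -= amp[c] * g
        f = g * kappa[c]
        dgx[c] = f * (dirs[c, 0] / rho - dot * wx / rho3)
        dgy[c] = f * (dirs[c, 1] / rho - dot * wy / rho3)
        dgz[c] = f * (dirs[c, 2] / rho - dot * wz / rho3)
    dbx = 0.0
    dby = 0.0
    dbz = 0.0
    for c in range(nc):
        dbx -= amp[c] * dgx[c]
        dby -= amp[c] * dgy[c]
        dbz -= amp[c] * dgz[c]
    gx += s * dbx
    gy += s * dby
    gz += s * dbz
    if d > 1e-12:
        c2 = b * sp / d
        gx += c2 * wx
        gy += c2 * wy
        gz += c2 * wz
    if g_amp > 0.0:
        son = 1.0 - np.exp(-d2 / (2.0 * g_on * g_on))
        soff = np.exp(-(d / g_off) ** 4)
        guide = son * soff
        # radial derivative of the guide profile
        dson = np.exp(-d2 / (2.0 * g_on * g_on)) / (g_on * g_on)  # per d, times d
        dsoff = -4.0 * d2 * d / g_off ** 4 * soff  # d/dd soff, times nothing
        p_open = 1.0
        for c in range(nc):
            if opened[c] > 0.5:
                p_open *= 1.0 - gvals[c]
        # d(guide)/dr = (son' soff + son soff') * u ; son' = dson * d
        if d > 1e-12:
            cg = g_amp * p_open * (dson * soff + son * dsoff / d)
            gx += cg * wx
            gy += cg * wy
            gz += cg * wz
        # guide * d(p_open)/dr
        for c in range(nc):
            if opened[c] > 0.5:
                pj = 1.0
                for c2i in range(nc):
                    if c2i != c and opened[c2i] > 0.5:
                        pj *= 1.0 - gvals[c2i]
                cg = -g_amp * guide * pj
                gx += cg * dgx[c]
                gy += cg * dgy[c]
                gz += cg * dgz[c]
    out[0] = gx
    out[1] = gy
    out[2] = gz


@njit(cache=True)
def funnel_energy_batch(pos, center, dirs, kappa, amp, opened, scal, out):
    for i in range(pos.shape[0]):
        out[i] = funnel_energy_one(pos[i], center, dirs, kappa, amp, opened, scal)


@njit(cache=True)
def funnel_grad_batch(pos, center, dirs, kappa, amp, opened, scal, out):
    for i in range(pos.shape[0]):
        funnel_grad_one(pos[i], center, dirs, kappa, amp, opened, scal, out[i])


@njit(cache=True)
def pull_loop(r, t_start_abs, rng,
              center, dirs, kappa, amp, opened, scal,
              k, v, n, r_ref, t_seg, x_off,
              dt, gamma, noise_scale,
              trigger_on, t_last_opt, t0, f0, win, win_state,
              env_radius, cutoff_sep, max_t,
              f_buf, f_count,
              traj_buf, traj_count, traj_stride):
    """Propagate one steered segment until trigger / unbinding / timeout.

    Mutates ``r`` (ligand position), ``win`` + ``win_state`` (trailing force
    window: [sum, count, index]), appends raw per-step scalar pulling forces
    to ``f_buf`` starting at ``f_count`` and strided positions to
    ``traj_buf``.  Returns (status, t_end, n_new_samples, n_new_frames).
    """
    grad = np.empty(3)
    t = t_start_abs
    win_n = win.shape[0]
    wsum = win_state[0]
    wcount = int(win_state[1])
    widx = int(win_state[2])
    nf = 0
    ntr = 0
    status = STATUS_RUNNING
    step_i = 0
    while True:
        # termination checks on the current state
        dx = r[0] - center[0]
        dy = r[1] - center[1]
        dz = r[2] - center[2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d - env_radius >= cutoff_sep:
            status = STATUS_UNBOUND
            break
        if t >= max_t - 1e-12:
            status = STATUS_TIMEOUT
            break
        # steering force at the current state; applied over the next step
        x = v * (t - t_seg) + x_off - ((r[0] - r_ref[0]) * n[0]
                                       + (r[1] - r_ref[1]) * n[1]
                                       + (r[2] - r_ref[2]) * n[2])
        fs = k * x
        f_buf[f_count + nf] = fs
        nf += 1
        if traj_stride > 0 and step_i % traj_stride == 0:
            j = traj_count + ntr
            traj_buf[j, 0] = t
            traj_buf[j, 1] = r[0]
            traj_buf[j, 2] = r[1]
            traj_buf[j, 3] = r[2]
            ntr += 1
        # Euler-Maruyama overdamped update
        funnel_grad_one(r, center, dirs, kappa, amp, opened, scal, grad)
        xi = rng.standard_normal(3)
        c1 = dt / gamma
        r[0] += (fs * n[0] - grad[0]) * c1 + noise_scale * xi[0]
        r[1] += (fs * n[1] - grad[1]) * c1 + noise_scale * xi[1]
        r[2] += (fs * n[2] - grad[2]) * c1 + noise_scale * xi[2]
        t += dt
        step_i += 1
        # trailing force window (circular buffer)
        if wcount == win_n:
            wsum -= win[widx]
        else:
            wcount += 1
        win[widx] = fs
        wsum += fs
        widx += 1
        if widx == win_n:
            widx = 0
        if trigger_on and wcount == win_n:
            if t - t_last_opt > t0 and wsum / win_n > f0:
                status = STATUS_TRIGGER
                break
    win_state[0] = wsum
    win_state[1] = wcount
    win_state[2] = widx
    return status, t, nf, ntr


@njit(cache=True)
def trial_batch(pos, cand_n, rng,
                center, dirs, kappa, amp, opened, scal,
                k, v, x_off, n_steps, dt, gamma, noise_scale, f_mean):
    """Evaluate candidate pulling directions from a common checkpoint.

    ``pos`` is (nc, 3), every row initialised to the checkpoint position;
    ``cand_n`` is (nc, 3) unit candidate directions.  All candidates consume
    the *same* noise sequence (common random numbers): one standard-normal
    3-vector is drawn per time step and shared across candidates, which is
    identical to restoring the checkpoint generator for each candidate in
    turn.  Writes the mean scalar pulling force per candidate to ``f_mean``.
    """
    ncand = pos.shape[0]
    grad = np.empty(3)
    for c in range(ncand):
        f_mean[c] = 0.0
    r0x = pos[0, 0]
    r0y = pos[0, 1]
    r0z = pos[0, 2]
    c1 = dt / gamma
    for i in range(n_steps):
        tau = i * dt
        xi = rng.standard_normal(3)
        for c in range(ncand):
            nx = cand_n[c, 0]
            ny = cand_n[c, 1]
            nz = cand_n[c, 2]
            x = v * tau + x_off - ((pos[c, 0] - r0x) * nx
                                   + (pos[c, 1] - r0y) * ny
                                   + (pos[c, 2] - r0z) * nz)
            fs = k * x
            f_mean[c] += fs
            funnel_grad_one(pos[c], center, dirs, kappa, amp, opened, scal, grad)
            pos[c, 0] += (fs * nx - grad[0]) * c1 + noise_scale * xi[0]
            pos[c, 1] += (fs * ny - grad[1]) * c1 + noise_scale * xi[1]
            pos[c, 2] += (fs * nz - grad[2]) * c1 + noise_scale * xi[2]
    for c in range(ncand):
        f_mean[c] /= n_steps


@njit(cache=True)
def free_run(r, rng, n_steps, center, dirs, kappa, amp, opened, scal,
             dt, gamma, noise_scale):
    """Unrestrained propagation (equilibration): f_ext = 0."""
    grad = np.empty(3)
    c1 = dt / gamma
    for i in range(n_steps):
        funnel_grad_one(r, center, dirs, kappa, amp, opened, scal, grad)
        xi = rng.standard_normal(3)
        r[0] += -grad[0] * c1 + noise_scale * xi[0]
        r[1] += -grad[1] * c1 + noise_scale * xi[1]
        r[2] += -grad[2] * c1 + noise_scale * xi[2]


@njit(cache=True)
def harmonic_sample(r, rng, n_steps, kappa, center, dt, gamma, noise_scale,
                    stride, out):
    """Sample an isotropic harmonic well; used for statistical-mechanics
    validation (equipartition / Boltzmann distribution checks)."""
    c1 = dt / gamma
    j = 0
    for i in range(n_steps):
        xi = rng.standard_normal(3)
        r[0] += -kappa * (r[0] - center[0]) * c1 + noise_scale * xi[0]
        r[1] += -kappa * (r[1] - center[1]) * c1 + noise_scale * xi[1]
        r[2] += -kappa * (r[2] - center[2]) * c1 + noise_scale * xi[2]
        if (i + 1) % stride == 0 and j < out.shape[0]:
            out[j, 0] = r[0]
            out[j, 1] = r[1]
            out[j, 2] = r[2]
            j += 1
    return j
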