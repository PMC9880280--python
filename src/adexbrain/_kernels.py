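"""Numba kernels: hot loops behind the public simulation API.

Everything in this module works in internal units (ms, mV, nS, pF, pA, kHz).
Transfer-function parameters are passed as a flat float64 ``cfg`` array with the
layout defined by ``CFG_*`` indices plus a 10-element polynomial ``P``.

Conventions shared by all integrators:
  * forward Euler at the spiking level, Heun (predictor-corrector) at the
    rate level;
  * the exponential spike-initiation argument is clamped at +10 before
    exponentiation (spike detection at v_peak makes the clamp consequence-free);
  * Ornstein-Uhlenbeck drives use the exact one-step update, so their
    stationary law is dt-independent;
  * population rates are clipped at zero after every step.
"""

import math

import numpy as np
from numba import njit

# layout of the transfer-function config vector
CFG_KE, CFG_KI, CFG_TE, CFG_TI, CFG_QE, CFG_QI, CFG_EE, CFG_EI, CFG_GL, \
    CFG_EL, CFG_CM, CFG_TREFR = range(12)

# rescaling constants for the effective-threshold polynomial
MU_V0, DMU_V0 = -60.0, 10.0     # mV
SIG_V0, DSIG_V0 = 4.0, 6.0      # mV
TAU_VN0, DTAU_VN0 = 0.5, 1.0    # dimensionless

_RATE_FLOOR = 1e-9              # kHz; keeps shot-noise moments defined at zero input


@njit(cache=True)
def voltage_moments(nu_e, nu_i, W, cfg):
    """Shot-noise moments of the membrane potential under Poissonian
    conductance bombardment: (mu_Ge, mu_Gi, mu_G, mu_V, sigma_V, tau_V)."""
    ne = max(nu_e, _RATE_FLOOR)
    ni = max(nu_i, _RATE_FLOOR)
    Ke, Ki = cfg[CFG_KE], cfg[CFG_KI]
    te, ti = cfg[CFG_TE], cfg[CFG_TI]
    Qe, Qi = cfg[CFG_QE], cfg[CFG_QI]
    Ee, Ei = cfg[CFG_EE], cfg[CFG_EI]
    gL, EL, Cm = cfg[CFG_GL], cfg[CFG_EL], cfg[CFG_CM]

    mu_Ge = ne * Ke * te * Qe
    mu_Gi = ni * Ki * ti * Qi
    mu_G = mu_Ge + mu_Gi + gL
    mu_V = (mu_Ge * Ee + mu_Gi * Ei + gL * EL - W) / mu_G

    tau_m = Cm / mu_G
    Ue = Qe / mu_G * (Ee - mu_V)
    Ui = Qi / mu_G * (Ei - mu_V)
    se = Ke * ne * (Ue * te) ** 2
    si = Ki * ni * (Ui * ti) ** 2
    var = se / (2.0 * (tau_m + te)) + si / (2.0 * (tau_m + ti))
    sigma_V = math.sqrt(var) if var > 0.0 else 0.0
    den = se / (tau_m + te) + si / (tau_m + ti)
    tau_V = (se + si) / den if den > 0.0 else tau_m
    return mu_Ge, mu_Gi, mu_G, mu_V, sigma_V, tau_V


@njit(cache=True)
def mu_v(nu_e, nu_i, W, cfg):
    _, _, _, muV, _, _ = voltage_moments(nu_e, nu_i, W, cfg)
    return muV


@njit(cache=True)
def tf_rate(nu_e, nu_i, W, P, cfg):
    """Semi-analytic population transfer function, kHz.

    nu = erfc((V_thr_eff - mu_V) / (sqrt(2) sigma_V)) / (2 tau_V), with the
    effective threshold a fitted second-order polynomial in the rescaled
    voltage moments.  Output clipped to [0, 1/T_refr].
    """
    _, _, _, muV, sigV, tauV = voltage_moments(nu_e, nu_i, W, cfg)
    xm = (muV - MU_V0) / DMU_V0
    xs = (sigV - SIG_V0) / DSIG_V0
    xt = (tauV * cfg[CFG_GL] / cfg[CFG_CM] - TAU_VN0) / DTAU_VN0
    vthre = (P[0] + P[1] * xm + P[2] * xs + P[3] * xt
             + P[4] * xm * xm + P[5] * xs * xs + P[6] * xt * xt
             + P[7] * xm * xs + P[8] * xm * xt + P[9] * xs * xt)
    if sigV <= 1e-12:
        # deterministic limit: zero below threshold, saturation above
        rate = 0.0 if muV < vthre else 1.0 / cfg[CFG_TREFR]
    else:
        arg = (vthre - muV) / (math.sqrt(2.0) * sigV)
        rate = 0.5 * math.erfc(arg) / tauV
    rmax = 1.0 / cfg[CFG_TREFR]
    if rate < 0.0:
        rate = 0.0
    elif rate > rmax:
        rate = rmax
    return rate


@njit(cache=True)
def _dtf(P, cfg, ne, ni, W, h):
    """First partial derivatives of tf_rate w.r.t. (nu_e, nu_i), central differences."""
    dfe = (tf_rate(ne + h, ni, W, P, cfg) - tf_rate(ne - h, ni, W, P, cfg)) / (2 * h)
    dfi = (tf_rate(ne, ni + h, W, P, cfg) - tf_rate(ne, ni - h, W, P, cfg)) / (2 * h)
    return dfe, dfi


@njit(cache=True)
def _d2tf(P, cfg, ne, ni, W, h):
    """Second partials (d2/de2, d2/dedi, d2/di2) of tf_rate, central differences."""
    f0 = tf_rate(ne, ni, W, P, cfg)
    dee = (tf_rate(ne + h, ni, W, P, cfg) - 2 * f0 + tf_rate(ne - h, ni, W, P, cfg)) / h ** 2
    dii = (tf_rate(ne, ni + h, W, P, cfg) - 2 * f0 + tf_rate(ne, ni - h, W, P, cfg)) / h ** 2
    dei = (tf_rate(ne + h, ni + h, W, P, cfg) - tf_rate(ne + h, ni - h, W, P, cfg)
           - tf_rate(ne - h, ni + h, W, P, cfg) + tf_rate(ne - h, ni - h, W, P, cfg)) / (4 * h ** 2)
    return dee, dei, dii


# ---------------------------------------------------------------------------
# single neurons under Poisson bombardment (transfer-function calibration)
# ---------------------------------------------------------------------------

@njit(cache=True)
def sim_neurons_fixed_w(n_neurons, n_steps, discard_steps, dt,
                        rate_e_tot, rate_i_tot, W,
                        cm, gl, el, delta, vthr, vpeak, vreset, trefr,
                        qe, qi, ee, ei, te, ti, seed):
    """Independent AdEx neurons with frozen adaptation current W, driven by
    Poisson conductance trains of total rate rate_e_tot / rate_i_tot (kHz).
    Returns the spike count after the discard window."""
    np.random.seed(seed)
    dec_e = math.exp(-dt / te)
    dec_i = math.exp(-dt / ti)
    count = 0
    for _ in range(n_neurons):
        v = el
        ge = rate_e_tot * te * qe   # start conductances at their stationary mean
        gi = rate_i_tot * ti * qi
        refr = 0.0
        for s in range(n_steps):
            ge = ge * dec_e + qe * np.random.poisson(rate_e_tot * dt)
            gi = gi * dec_i + qi * np.random.poisson(rate_i_tot * dt)
            if refr > 0.0:
                refr -= dt
                v = vreset
                continue
            ex = (v - vthr) / delta
            if ex > 10.0:
                ex = 10.0
            dv = (gl * (el - v) + gl * delta * math.exp(ex) - W
                  + ge * (ee - v) + gi * (ei - v)) / cm
            v += dt * dv
            if v > vpeak:
                if s >= discard_steps:
                    count += 1
                v = vreset
                refr = trefr
    return count


# ---------------------------------------------------------------------------
# recurrent spiking network
# ---------------------------------------------------------------------------

@njit(cache=True)
def sim_spiking_network(n_steps, dt, n_e, n_i,
                        post_indptr, post_idx,
                        el, delta, vpeak, a_arr, b_arr,
                        cm, gl, vthr, vreset, trefr, uw,
                        qe, qi, ee, ei, te, ti,
                        drive_rate_tot, n_drive, seed,
                        spk_n, spk_t,
                        mon_idx, mon_stride, mon_v, mon_w, mon_ge, mon_gi):
    """Euler integration of the full AdEx network.

    post_indptr/post_idx: CSR of postsynaptic targets per (presynaptic) neuron,
    excitatory sources first (index < n_e).  drive_rate_tot is the external
    Poisson rate per neuron (kHz) delivered through Q_e synapses to the first
    n_drive neurons (n_drive = n_e matches the mean-field convention of drive
    entering the excitatory population only).
    Returns (n_spikes, status): status 0 ok, 1 spike capacity exhausted,
    2 non-finite state encountered.
    """
    np.random.seed(seed)
    n = n_e + n_i
    v = np.empty(n)
    w = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    refr = np.zeros(n)
    # spread initial voltages between rest and threshold so the network
    # self-ignites instead of depending on drive strength for the first spike
    for i in range(n):
        v[i] = el[i] + (vthr - el[i]) * np.random.random()
    dec_e = math.exp(-dt / te)
    dec_i = math.exp(-dt / ti)
    lam_ext = n_drive * drive_rate_tot * dt
    cap = spk_n.shape[0]
    n_spk = 0
    n_mon = mon_idx.shape[0]
    for s in range(n_steps):
        # conductance decay + external Poisson events (superposed across network)
        for i in range(n):
            ge[i] *= dec_e
            gi[i] *= dec_i
        n_ext = np.random.poisson(lam_ext)
        for _ in range(n_ext):
            ge[int(np.random.random() * n_drive)] += qe
        # integrate, detect spikes
        for i in range(n):
            wi = w[i]
            w[i] += dt * (-wi + a_arr[i] * (v[i] - el[i])) / uw
            if refr[i] > 0.0:
                refr[i] -= dt
                v[i] = vreset
                continue
            ex = (v[i] - vthr) / delta[i]
            if ex > 10.0:
                ex = 10.0
            dv = (gl * (el[i] - v[i]) + gl * delta[i] * math.exp(ex) - wi
                  + ge[i] * (ee - v[i]) + gi[i] * (ei - v[i])) / cm
            v[i] += dt * dv
            if v[i] > vpeak[i]:
                if n_spk >= cap:
                    return n_spk, 1
                spk_n[n_spk] = i
                spk_t[n_spk] = (s + 1) * dt
                n_spk += 1
                v[i] = vreset
                w[i] += b_arr[i]
                refr[i] = trefr
                inc = qe if i < n_e else qi
                for jj in range(post_indptr[i], post_indptr[i + 1]):
                    t = post_idx[jj]
                    if i < n_e:
                        ge[t] += inc
                    else:
                        gi[t] += inc
        if n_mon > 0 and s % mon_stride == 0:
            r = s // mon_stride
            for m in range(n_mon):
                k = mon_idx[m]
                mon_v[r, m] = v[k]
                mon_w[r, m] = w[k]
                mon_ge[r, m] = ge[k]
                mon_gi[r, m] = gi[k]
        if s % 1000 == 0:
            ok = True
            for i in range(n):
                if not math.isfinite(v[i]):
                    ok = False
                    break
            if not ok:
                return n_spk, 2
    return n_spk, 0


# ---------------------------------------------------------------------------
# single-region mean-field (first and second order)
# ---------------------------------------------------------------------------

@njit(cache=True)
def sim_region_first(n_steps, dt, T, Pe, Pi, cfg_e, cfg_i,
                     b, a, uw, drive_mu, drive_sd, drive_tau, nu_aff,
                     drive_sym, ne0, ni0, W0, seed, stride, out):
    """Heun integration of the first-order rate model with OU drive on the
    excitatory transfer-function input.  out: (n_rec, 4) = nu_e, nu_i, W, drive.
    Returns status (0 ok, 2 non-finite)."""
    np.random.seed(seed)
    EL_e = cfg_e[CFG_EL]
    ne, ni, W = ne0, ni0, W0
    alpha = math.exp(-dt / drive_tau)
    beta = drive_sd * math.sqrt(1.0 - alpha * alpha)
    xi = drive_mu
    n_rec = out.shape[0]
    for s in range(n_steps):
        if s % stride == 0 and s // stride < n_rec:
            r = s // stride
            out[r, 0] = ne
            out[r, 1] = ni
            out[r, 2] = W
            out[r, 3] = xi
        xi2 = drive_mu + (xi - drive_mu) * alpha + beta * np.random.normal()
        fe = tf_rate(ne + nu_aff + xi, ni, W, Pe, cfg_e)
        fi = tf_rate(ne + nu_aff + drive_sym * xi, ni, 0.0, Pi, cfg_i)
        k1e = (fe - ne) / T
        k1i = (fi - ni) / T
        k1w = -W / uw + b * ne + a * (mu_v(ne, ni, W, cfg_e) - EL_e)
        pe = max(ne + dt * k1e, 0.0)
        pi = max(ni + dt * k1i, 0.0)
        pw = W + dt * k1w
        fe2 = tf_rate(pe + nu_aff + xi2, pi, pw, Pe, cfg_e)
        fi2 = tf_rate(pe + nu_aff + drive_sym * xi2, pi, 0.0, Pi, cfg_i)
        k2e = (fe2 - pe) / T
        k2i = (fi2 - pi) / T
        k2w = -pw / uw + b * pe + a * (mu_v(pe, pi, pw, cfg_e) - EL_e)
        ne = max(ne + 0.5 * dt * (k1e + k2e), 0.0)
        ni = max(ni + 0.5 * dt * (k1i + k2i), 0.0)
        W = W + 0.5 * dt * (k1w + k2w)
        xi = xi2
        if not (math.isfinite(ne) and math.isfinite(ni) and math.isfinite(W)):
            return 2
    return 0


@njit(cache=True)
def _second_order_rhs(ne, ni, W, cee, cei, cii, xi, nu_aff,
                      T, Pe, Pi, cfg_e, cfg_i, b, a, uw, Ne, Ni, h, drive_sym):
    EL_e = cfg_e[CFG_EL]
    in_e = ne + nu_aff + xi
    in_i = ne + nu_aff + drive_sym * xi
    fe = tf_rate(in_e, ni, W, Pe, cfg_e)
    fi = tf_rate(in_i, ni, 0.0, Pi, cfg_i)
    dfe_e, dfe_i = _dtf(Pe, cfg_e, in_e, ni, W, h)
    dfi_e, dfi_i = _dtf(Pi, cfg_i, in_i, ni, 0.0, h)
    d2e_ee, d2e_ei, d2e_ii = _d2tf(Pe, cfg_e, in_e, ni, W, h)
    d2i_ee, d2i_ei, d2i_ii = _d2tf(Pi, cfg_i, in_i, ni, 0.0, h)

    dne = ((fe - ne) + 0.5 * (cee * d2e_ee + 2.0 * cei * d2e_ei + cii * d2e_ii)) / T
    dni = ((fi - ni) + 0.5 * (cee * d2i_ee + 2.0 * cei * d2i_ei + cii * d2i_ii)) / T
    dcee = (fe * (1.0 / T - fe) / Ne + (fe - ne) ** 2
            + 2.0 * (dfe_e * cee + dfe_i * cei) - 2.0 * cee) / T
    dcei = ((fe - ne) * (fi - ni)
            + dfe_e * cei + dfe_i * cii + dfi_e * cee + dfi_i * cei
            - 2.0 * cei) / T
    dcii = (fi * (1.0 / T - fi) / Ni + (fi - ni) ** 2
            + 2.0 * (dfi_e * cei + dfi_i * cii) - 2.0 * cii) / T
    dW = -W / uw + b * ne + a * (mu_v(ne, ni, W, cfg_e) - EL_e)
    return dne, dni, dW, dcee, dcei, dcii


@njit(cache=True)
def sim_region_second(n_steps, dt, T, Pe, Pi, cfg_e, cfg_i,
                      b, a, uw, Ne, Ni,
                      drive_mu, drive_sd, drive_tau, nu_aff, drive_sym,
                      ne0, ni0, W0, cee0, cei0, cii0, seed, stride, h, out):
    """Second-order Master-Equation integration (rates + covariances).
    out: (n_rec, 7) = nu_e, nu_i, W, c_ee, c_ei, c_ii, drive."""
    np.random.seed(seed)
    ne, ni, W = ne0, ni0, W0
    cee, cei, cii = cee0, cei0, cii0
    alpha = math.exp(-dt / drive_tau)
    beta = drive_sd * math.sqrt(1.0 - alpha * alpha)
    xi = drive_mu
    n_rec = out.shape[0]
    for s in range(n_steps):
        if s % stride == 0 and s // stride < n_rec:
            r = s // stride
            out[r, 0] = ne
            out[r, 1] = ni
            out[r, 2] = W
            out[r, 3] = cee
            out[r, 4] = cei
            out[r, 5] = cii
            out[r, 6] = xi
        xi2 = drive_mu + (xi - drive_mu) * alpha + beta * np.random.normal()
        k1 = _second_order_rhs(ne, ni, W, cee, cei, cii, xi, nu_aff,
                               T, Pe, Pi, cfg_e, cfg_i, b, a, uw, Ne, Ni, h,
                               drive_sym)
        pe = max(ne + dt * k1[0], 0.0)
        pi = max(ni + dt * k1[1], 0.0)
        pw = W + dt * k1[2]
        pee = max(cee + dt * k1[3], 0.0)
        pei = cei + dt * k1[4]
        pii = max(cii + dt * k1[5], 0.0)
        k2 = _second_order_rhs(pe, pi, pw, pee, pei, pii, xi2, nu_aff,
                               T, Pe, Pi, cfg_e, cfg_i, b, a, uw, Ne, Ni, h,
                               drive_sym)
        ne = max(ne + 0.5 * dt * (k1[0] + k2[0]), 0.0)
        ni = max(ni + 0.5 * dt * (k1[1] + k2[1]), 0.0)
        W = W + 0.5 * dt * (k1[2] + k2[2])
        cee = max(cee + 0.5 * dt * (k1[3] + k2[3]), 0.0)
        cei = cei + 0.5 * dt * (k1[4] + k2[4])
        cii = max(cii + 0.5 * dt * (k1[5] + k2[5]), 0.0)
        xi = xi2
        if not (math.isfinite(ne) and math.isfinite(ni) and math.isfinite(W)
                and math.isfinite(cee) and math.isfinite(cei) and math.isfinite(cii)):
            return 2
    return 0


# ---------------------------------------------------------------------------
# connectome-coupled network of mean-fields with delays
# ---------------------------------------------------------------------------

@njit(cache=True)
def sim_brain(n_steps, dt, T, Pe, Pi, cfg_e, cfg_i,
              b, a, uw, C_off, lag,
              drive_mu, drive_sd, drive_tau, nu_aff,
              stim_k, stim_amp, stim_on, stim_off,
              ne0, ni0, W0, seed, stride, out_e, out_i, out_w):
    """Delay-coupled network of first-order mean-fields, Heun integration.

    C_off: coupling matrix with the global strength S already applied to
    off-diagonal entries and a zero diagonal (the self term enters as the
    region's own rate, unscaled).  lag[j, k]: delay j->k in steps.
    Per-region OU drives are independent.  The stimulus (kHz) is added to the
    excitatory transfer-function input of region stim_k during
    [stim_on, stim_off) (step indices); stim_k < 0 disables it.
    """
    np.random.seed(seed)
    n = C_off.shape[0]
    EL_e = cfg_e[CFG_EL]
    ne = ne0.copy()
    ni = ni0.copy()
    W = W0.copy()
    L = lag.max() + 2
    buf = np.empty((L, n))
    for r in range(L):
        for k in range(n):
            buf[r, k] = ne0[k]
    alpha = math.exp(-dt / drive_tau)
    beta = drive_sd * math.sqrt(1.0 - alpha * alpha)
    xi = np.full(n, drive_mu)
    coup = np.empty(n)
    fe = np.empty(n)
    fi = np.empty(n)
    pe = np.empty(n)
    pi = np.empty(n)
    pw = np.empty(n)
    n_rec = out_e.shape[0]
    for s in range(n_steps):
        row = s % L
        for k in range(n):
            buf[row, k] = ne[k]
        if s % stride == 0 and s // stride < n_rec:
            r = s // stride
            for k in range(n):
                out_e[r, k] = ne[k]
                out_i[r, k] = ni[k]
                out_w[r, k] = W[k]
        # delayed long-range excitatory input
        for k in range(n):
            acc = 0.0
            for j in range(n):
                c = C_off[j, k]
                if c != 0.0:
                    acc += c * buf[(s - lag[j, k]) % L, j]
            coup[k] = acc
        stim_now = stim_amp if (stim_k >= 0 and stim_on <= s < stim_off) else 0.0
        # stage 1
        for k in range(n):
            base = xi[k] + coup[k] + nu_aff
            in_e = base + ne[k] + (stim_now if k == stim_k else 0.0)
            in_i = base + ne[k]
            fe[k] = tf_rate(in_e, ni[k], W[k], Pe, cfg_e)
            fi[k] = tf_rate(in_i, ni[k], 0.0, Pi, cfg_i)
        for k in range(n):
            pe[k] = max(ne[k] + dt * (fe[k] - ne[k]) / T, 0.0)
            pi[k] = max(ni[k] + dt * (fi[k] - ni[k]) / T, 0.0)
            pw[k] = W[k] + dt * (-W[k] / uw + b * ne[k]
                                 + a * (mu_v(ne[k], ni[k], W[k], cfg_e) - EL_e))
        # advance the OU drives (exact update)
        for k in range(n):
            xi[k] = drive_mu + (xi[k] - drive_mu) * alpha + beta * np.random.normal()
        # stage 2 (coupling held over the step; lags are >= 1 step off-diagonal)
        ok = True
        for k in range(n):
            base = xi[k] + coup[k] + nu_aff
            in_e = base + pe[k] + (stim_now if k == stim_k else 0.0)
            in_i = base + pe[k]
            fe2 = tf_rate(in_e, pi[k], pw[k], Pe, cfg_e)
            fi2 = tf_rate(in_i, pi[k], 0.0, Pi, cfg_i)
            k2w = -pw[k] / uw + b * pe[k] + a * (mu_v(pe[k], pi[k], pw[k], cfg_e) - EL_e)
            k1w = -W[k] / uw + b * ne[k] + a * (mu_v(ne[k], ni[k], W[k], cfg_e) - EL_e)
            ne[k] = max(ne[k] + 0.5 * dt * ((fe[k] - ne[k]) / T + (fe2 - pe[k]) / T), 0.0)
            ni[k] = max(ni[k] + 0.5 * dt * ((fi[k] - ni[k]) / T + (fi2 - pi[k]) / T), 0.0)
            W[k] = W[k] + 0.5 * dt * (k1w + k2w)
            if not (math.isfinite(ne[k]) and math.isfinite(ni[k]) and math.isfinite(W[k])):
                ok = False
        if not ok:
            return 2
    return 0
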