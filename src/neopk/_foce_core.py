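"""Compiled inner loop of the conditional-estimation objective.

Numerically identical to the pure-numpy path in ``estimation`` (which
remains the reference used by the diagnostics): per subject, a damped
Newton (Gauss-Newton) search for the conditional mode of the two random
effects with analytic derivatives of the log-domain infusion model,
followed by the Laplace determinant term.  Compiled with numba because
the objective is evaluated thousands of times per fit and the padded
numpy formulation is dominated by small-array overhead.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["foce_core"]

_TINY = 1e-300


@njit(cache=True)
def _subject_resid_jac(t, logy, m, dt0, drate, ddur, nd, cl, v,
                       r, J):  # pragma: no cover - exercised via foce_core
    """Residuals and d(residual)/d(eta) for one subject; returns 0 on
    success, 1 if a non-positive prediction is met."""
    k = cl / v
    for j in range(m):
        f = 0.0
        dfdcl = 0.0
        dfdk = 0.0
        for d in range(nd):
            dt = t[j] - dt0[d]
            if dt <= 0.0:
                continue
            rc = drate[d] / cl
            dur = ddur[d]
            if dt <= dur:
                ekx = np.exp(-k * dt)
                fj = rc * (1.0 - ekx)
                dk = rc * dt * ekx
            else:
                s = dt - dur
                ekd = np.exp(-k * dur)
                eks = np.exp(-k * s)
                fj = rc * (1.0 - ekd) * eks
                dk = rc * eks * (dur * ekd - s * (1.0 - ekd))
            f += fj
            dfdcl += -fj / cl
            dfdk += dk
        if f <= 0.0:
            return 1
        dfdcl += dfdk / v
        dfdv = dfdk * (-k / v)
        r[j] = logy[j] - np.log(f)
        J[j, 0] = -(cl * dfdcl) / f
        J[j, 1] = -(v * dfdv) / f
    return 0


@njit(cache=True)
def _subject_resid(t, logy, m, dt0, drate, ddur, nd, cl, v, r):  # pragma: no cover
    k = cl / v
    for j in range(m):
        f = 0.0
        for d in range(nd):
            dt = t[j] - dt0[d]
            if dt <= 0.0:
                continue
            rc = drate[d] / cl
            dur = ddur[d]
            if dt <= dur:
                f += rc * (1.0 - np.exp(-k * dt))
            else:
                f += rc * (1.0 - np.exp(-k * dur)) * np.exp(-k * (dt - dur))
        if f <= 0.0:
            return 1
        r[j] = logy[j] - np.log(f)
    return 0


@njit(cache=True)
def foce_core(T, LOGY, M, DT, DRATE, DDUR, ND, cl_typ, v_typ,
              om_cl, om_v, sigma2, eta_in, tol, max_iter):  # pragma: no cover
    """Total OFV and conditional modes over all subjects.

    Returns ``(ofv, etas, status)``; status 1 flags a non-positive model
    prediction at an observation, 2 a non-positive-definite conditional
    Hessian (the caller maps both to an error/barrier).
    """
    n = T.shape[0]
    mmax = T.shape[1]
    etas = np.zeros((n, 2))
    act0 = om_cl > 1e-12
    act1 = om_v > 1e-12
    i0 = 1.0 / om_cl if act0 else 0.0
    i1 = 1.0 / om_v if act1 else 0.0
    log_2pi_s2 = np.log(2.0 * np.pi * sigma2)
    total = 0.0
    r = np.empty(mmax)
    rt = np.empty(mmax)
    J = np.empty((mmax, 2))
    Jp = np.empty((mmax, 2))
    Jm = np.empty((mmax, 2))
    fd = 1e-5  # step for differencing the analytic Jacobian
    for i in range(n):
        m = M[i]
        if m == 0:
            continue
        t = T[i]
        logy = LOGY[i]
        dt0 = DT[i]
        drate = DRATE[i]
        ddur = DDUR[i]
        nd = ND[i]
        e0 = eta_in[i, 0] if act0 else 0.0
        e1 = eta_in[i, 1] if act1 else 0.0

        bad = _subject_resid_jac(t, logy, m, dt0, drate, ddur, nd,
                                 cl_typ[i] * np.exp(e0), v_typ[i] * np.exp(e1), r, J)
        if bad != 0:
            return 0.0, etas, 1
        q = e0 * e0 * i0 + e1 * e1 * i1
        for j in range(m):
            q += r[j] * r[j] / sigma2

        if act0 or act1:
            for _it in range(max_iter):
                g0 = 2.0 * e0 * i0
                g1 = 2.0 * e1 * i1
                h00 = 2.0 * i0
                h11 = 2.0 * i1
                h01 = 0.0
                for j in range(m):
                    g0 += 2.0 * J[j, 0] * r[j] / sigma2
                    g1 += 2.0 * J[j, 1] * r[j] / sigma2
                    h00 += 2.0 * J[j, 0] * J[j, 0] / sigma2
                    h11 += 2.0 * J[j, 1] * J[j, 1] / sigma2
                    h01 += 2.0 * J[j, 0] * J[j, 1] / sigma2
                if not act0:
                    h00 = 1.0
                    h01 = 0.0
                    g0 = 0.0
                if not act1:
                    h11 = 1.0
                    h01 = 0.0
                    g1 = 0.0
                det = h00 * h11 - h01 * h01
                if abs(det) < _TINY:
                    det = 1.0
                s0 = -(h11 * g0 - h01 * g1) / det if act0 else 0.0
                s1 = -(h00 * g1 - h01 * g0) / det if act1 else 0.0
                step_norm = np.sqrt(s0 * s0 + s1 * s1)
                if step_norm < tol:
                    break
                lam = 1.0
                moved = 0.0
                slack = 1e-12 * (1.0 + abs(q))
                for _bt in range(15):
                    te0 = e0 + lam * s0
                    te1 = e1 + lam * s1
                    bad = _subject_resid(t, logy, m, dt0, drate, ddur, nd,
                                         cl_typ[i] * np.exp(te0),
                                         v_typ[i] * np.exp(te1), rt)
                    if bad == 0:
                        qt = te0 * te0 * i0 + te1 * te1 * i1
                        for j in range(m):
                            qt += rt[j] * rt[j] / sigma2
                        if qt <= q + slack:
                            moved = lam * step_norm
                            e0, e1, q = te0, te1, qt
                            break
                    lam *= 0.5
                bad = _subject_resid_jac(t, logy, m, dt0, drate, ddur, nd,
                                         cl_typ[i] * np.exp(e0),
                                         v_typ[i] * np.exp(e1), r, J)
                if bad != 0:
                    return 0.0, etas, 1
                if moved < tol:
                    break

        etas[i, 0] = e0
        etas[i, 1] = e1
        ofv_i = m * log_2pi_s2
        for j in range(m):
            ofv_i += r[j] * r[j] / sigma2
        if act0:
            ofv_i += e0 * e0 * i0 + np.log(om_cl)
        if act1:
            ofv_i += e1 * e1 * i1 + np.log(om_v)
        if act0 or act1:
            # Gauss-Newton curvature
            g00 = 0.0
            g11 = 0.0
            g01 = 0.0
            for j in range(m):
                g00 += J[j, 0] * J[j, 0]
                g11 += J[j, 1] * J[j, 1]
                g01 += J[j, 0] * J[j, 1]
            # residual-weighted second derivatives by central differences
            # of the analytic Jacobian, per active dimension
            s00 = 0.0
            s11 = 0.0
            s01 = 0.0
            s10 = 0.0
            ok = True
            for a in range(2):
                if (a == 0 and not act0) or (a == 1 and not act1):
                    continue
                d0 = fd if a == 0 else 0.0
                d1 = fd if a == 1 else 0.0
                bad = _subject_resid_jac(t, logy, m, dt0, drate, ddur, nd,
                                         cl_typ[i] * np.exp(e0 + d0),
                                         v_typ[i] * np.exp(e1 + d1), rt, Jp)
                if bad != 0:
                    ok = False
                    break
                bad = _subject_resid_jac(t, logy, m, dt0, drate, ddur, nd,
                                         cl_typ[i] * np.exp(e0 - d0),
                                         v_typ[i] * np.exp(e1 - d1), rt, Jm)
                if bad != 0:
                    ok = False
                    break
                sa0 = 0.0
                sa1 = 0.0
                for j in range(m):
                    sa0 += r[j] * (Jp[j, 0] - Jm[j, 0]) / (2.0 * fd)
                    sa1 += r[j] * (Jp[j, 1] - Jm[j, 1]) / (2.0 * fd)
                if a == 0:
                    s00 = sa0
                    s01 = sa1
                else:
                    s10 = sa0
                    s11 = sa1
            soff = 0.5 * (s01 + s10)
            # exact-Hessian determinant, floored at half the Gauss-Newton
            # determinant so near-singular sparse-subject Hessians cannot
            # spuriously lower the objective
            if act0 and act1:
                b00 = g00 / sigma2 + i0
                b11 = g11 / sigma2 + i1
                b01 = g01 / sigma2
                det_gn = b00 * b11 - b01 * b01
                a00 = (g00 + s00) / sigma2 + i0
                a11 = (g11 + s11) / sigma2 + i1
                a01 = (g01 + soff) / sigma2
                det = a00 * a11 - a01 * a01
            elif act0:
                det_gn = g00 / sigma2 + i0
                det = (g00 + s00) / sigma2 + i0
            else:
                det_gn = g11 / sigma2 + i1
                det = (g11 + s11) / sigma2 + i1
            if not ok:
                det = det_gn
            elif det < 0.5 * det_gn:
                det = 0.5 * det_gn
            if det <= 0.0:
                return 0.0, etas, 2
            ofv_i += np.log(det)
        total += ofv_i
    return total, etas, 0
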