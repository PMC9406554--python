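"""Independent reference implementations used only to check the package.

Everything here is written from the model equations directly, sharing no
code with ``iasmark`` internals: a fixed-step RK4 integrator over a plain
dictionary of parameters, a dense-grid threshold scan, a soft-margin SVM
dual solved as a QP, and a hand-rolled stratified CV loop.
"""

from __future__ import annotations

import numpy as np


def reference_rhs(y, u, p):
    """Model derivatives computed from a parameter dict, term by term."""
    x1, x2, Q, A, P = y
    Q = max(Q, 1e-9)
    pro1 = max(p["mu"] * (1 - p["q1"] / Q) * x1, 0.0)
    pro2 = max(p["mu"] * (1 - p["q2"] / Q) * x2, 0.0)
    trans = p["c"] * p["K"] / (Q + p["K"]) * x1
    tot = x1 + x2
    dx1 = pro1 - p["d"] * x1 * tot - trans
    dx2 = pro2 - p["d"] * x2 * tot + trans
    dA = p["gamma1"] * u * (1 - A / p["A0"]) + p["gamma2"] - p["delta"] * A
    cons = 0.0
    if tot > 0:
        cons = (p["mu"] * (Q - p["q1"]) * x1 + p["mu"] * (Q - p["q2"]) * x2) / tot
    dQ = p["m"] * (A - Q) - cons
    sec1 = max(p["sigma1"] * (1 - p["q1"] / Q) * x1, 0.0)
    sec2 = max(p["sigma2"] * (1 - p["q2"] / Q) * x2, 0.0)
    dP = p["b"] * Q + sec1 + sec2 - p["eps"] * P
    return (dx1, dx2, dQ, dA, dP)


def rk4_reference(p, y0, t_grid, switch_day, u_before, u_after, dt=0.001):
    """Fixed-step RK4 with one treatment switch, states at ``t_grid``."""
    y = [float(v) for v in y0]
    out = np.empty((len(t_grid), 5))
    out[0] = y
    t = t_grid[0]
    for i, target in enumerate(t_grid[1:], start=1):
        while t < target - 1e-12:
            h = min(dt, target - t)
            # do not step across the switch
            if t < switch_day and t + h > switch_day:
                h = switch_day - t
            u = u_before if t < switch_day - 1e-12 else u_after
            k1 = reference_rhs(y, u, p)
            y2 = [y[j] + 0.5 * h * k1[j] for j in range(5)]
            k2 = reference_rhs(y2, u, p)
            y3 = [y[j] + 0.5 * h * k2[j] for j in range(5)]
            k3 = reference_rhs(y3, u, p)
            y4 = [y[j] + h * k3[j] for j in range(5)]
            k4 = reference_rhs(y4, u, p)
            y = [
                max(y[j] + h / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j]), 0.0)
                for j in range(5)
            ]
            if y[2] < 1e-9:
                y[2] = 1e-9
            t += h
        out[i] = y
        t = target
    return out


def dense_grid_best_accuracy(values, labels, direction_above, n_grid=10000):
    """Best achievable accuracy by brute force over a dense threshold grid."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    lo, hi = values.min(), values.max()
    pad = 0.01 * (hi - lo + 1.0)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    best = 0.0
    for thr in grid:
        pred = values > thr if direction_above else values < thr
        best = max(best, float(np.mean(pred == labels)))
    return best


def svm_dual_boundary(z, y, C=1.0):
    """Soft-margin linear SVM on 1-D data via its dual QP (SLSQP).

    ``z``: standardized feature; ``y``: labels in {-1, +1}.  Returns the
    decision boundary -b/w in z units.
    """
    from scipy.optimize import minimize

    z = np.asarray(z, float)
    y = np.asarray(y, float)
    n = len(z)
    G = np.outer(y * z, y * z)

    def neg_dual(a):
        return 0.5 * a @ G @ a - a.sum()

    def grad(a):
        return G @ a - np.ones(n)

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(
        neg_dual, np.full(n, 0.01), jac=grad, method="SLSQP",
        bounds=[(0.0, C)] * n, constraints=[cons],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = float(np.sum(a * y * z))
    # bias from the KKT conditions: y_i f(z_i) >= 1 wherever a_i < C and
    # <= 1 wherever a_i > 0; b lies in the bracket, libsvm-style midpoint
    f = w * z
    tol = 1e-6 * C
    lo = [-np.inf]
    hi = [np.inf]
    for fi, yi, ai in zip(f, y, a):
        if ai > tol and yi < 0:
            lo.append(-1 - fi)
        if ai < C - tol and yi > 0:
            lo.append(1 - fi)
        if ai > tol and yi > 0:
            hi.append(1 - fi)
        if ai < C - tol and yi < 0:
            hi.append(-1 - fi)
    b = 0.5 * (max(lo) + min(hi))
    return -b / w


def stratified_cv_reference(values, labels, k, replicates, seed, direction_above):
    """Hand-rolled stratified k-fold CV of the accuracy-maximising cut.

    Thresholds are refit per training split with the dense-grid scan and
    evaluated on the holdout; returns mean holdout accuracy.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(replicates):
        folds = [[] for _ in range(k)]
        for cls in (True, False):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                folds[j % k].append(i)
        for f in folds:
            te = np.array(f)
            tr = np.array([i for i in range(len(values)) if i not in set(f)])
            lo, hi = values[tr].min(), values[tr].max()
            pad = 0.01 * (hi - lo + 1.0)
            grid = np.linspace(lo - pad, hi + pad, 2000)
            best_thr, best_acc = grid[0], -1.0
            for thr in grid:
                pred = values[tr] > thr if direction_above else values[tr] < thr
                acc = float(np.mean(pred == labels[tr]))
                if acc > best_acc:
                    best_thr, best_acc = thr, acc
            pred = values[te] > best_thr if direction_above else values[te] < best_thr
            accs.append(float(np.mean(pred == labels[te])))
    return float(np.mean(accs))
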