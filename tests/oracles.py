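"""Independent brute-force reference implementations used as oracles.

Everything here is written as literal loops / direct formula
transcription, deliberately sharing no code with the package, so the
vectorized implementations can be held against them.
"""

import math

import numpy as np
from sklearn.linear_model import LinearRegression


def nearest_band(wl, target):
    return int(np.abs(np.asarray(wl) - target).argmin())


def vi_oracle(refl, wl):
    """All 30 vegetation indices via direct formula transcription."""
    def R(t):
        return float(refl[nearest_band(wl, t)])

    out = {}
    out["DVI"] = R(890) - R(670)
    out["EVI"] = 2.5 * (R(800) - R(670)) / (R(800) + 6 * R(670)
                                            - 7.5 * R(450) + 1)
    out["EVI2"] = 2.5 * (R(800) - R(670)) / (R(800) + 2.4 * R(670) + 1)
    out["GNDVI"] = (R(750) - R(550)) / (R(750) + R(550))
    out["GI"] = R(554) / R(677)
    out["LCI"] = (R(850) - R(710)) / math.sqrt(R(850) + R(670))
    out["MCARI"] = ((R(700) - R(670)) - 0.2 * (R(700) - R(550))) \
        * (R(700) / R(670))
    out["MSR"] = (R(800) / R(670) - 1) / math.sqrt(R(800) / R(670) + 1)
    out["MSAVI"] = 0.5 * (2 * R(800) + 1 - math.sqrt(
        (2 * R(800) + 1) ** 2 - 8 * (R(800) - R(670))))
    out["MTVI1"] = 1.2 * (1.2 * (R(800) - R(550)) - 2.5 * (R(670) - R(550)))
    out["MTVI2"] = 1.5 * (1.2 * (R(800) - R(500))
                          - 2.5 * (R(670) - R(550))) / math.sqrt(
        2 * (R(800) + 1) ** 2 - (6 * R(800) - 5 * math.sqrt(R(670))) - 0.5)
    out["NDVI"] = (R(800) - R(680)) / (R(800) + R(680))
    out["NDRE"] = (R(790) - R(720)) / (R(790) + R(720))
    out["NPCI"] = (R(670) - R(460)) / (R(670) + R(460))
    out["NDI"] = (R(850) - R(710)) / (R(850) + R(680))
    out["NRI"] = (R(570) - R(670)) / (R(570) + R(670))
    out["OSAVI"] = 1.16 * (R(800) - R(670)) / (R(800) + R(670) + 0.16)
    out["PSRI"] = (R(680) - R(500)) / R(750)
    out["PSND"] = (R(800) - R(470)) / (R(800) + R(470))
    out["PBI"] = R(810) / R(560)
    out["RVI"] = R(810) / R(660)
    out["RDVI"] = (R(800) - R(670)) / math.sqrt(R(800) + R(670))
    out["RASI"] = R(760) / R(500)
    out["RVSI"] = (R(712) + R(752)) / 2 - R(732)
    out["SAVI"] = 1.5 * (R(800) - R(670)) / (R(800) + R(670) + 0.5)
    out["SPVI"] = 0.4 * (3.7 * (R(800) - R(670))
                         - 1.2 * abs(R(550) - R(670)))
    out["TVI"] = 0.5 * (120 * (R(750) - R(550)) - 200 * (R(670) - R(550)))
    out["TCARI"] = 3 * ((R(710) - R(680))
                        - 0.2 * (R(700) - R(560)) * (R(710) / R(680)))
    out["VARI"] = (R(555) - R(680)) / (R(555) + R(680) - R(480))
    out["WDRVI"] = (0.1 * R(800) - R(670)) / (0.1 * R(800) + R(670))
    return out


def fdsr_loop(spectrum, dl):
    """Element-wise loop transform with replicated endpoints."""
    r = list(map(float, spectrum))
    n = len(r)
    out = [0.0] * n
    for i in range(1, n - 1):
        out[i] = (r[i - 1] - r[i + 1]) / dl
    out[0] = out[1]
    out[-1] = out[-2]
    return np.array(out)


def glcm_features_oracle(p):
    """All 18 GLCM statistics by literal double loops."""
    p = np.asarray(p, dtype=float)
    G = p.shape[0]
    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    mx = sum(i * px[i] for i in range(G))
    my = sum(j * py[j] for j in range(G))
    sx = math.sqrt(sum((i - mx) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j - my) ** 2 * py[j] for j in range(G)))
    out = {}
    out["energy"] = sum(p[i][j] ** 2 for i in range(G) for j in range(G))
    out["entropy"] = -sum(p[i][j] * math.log(p[i][j])
                          for i in range(G) for j in range(G) if p[i][j] > 0)
    if sx > 0 and sy > 0:
        out["correlation"] = sum((i - mx) * (j - my) * p[i][j]
                                 for i in range(G) for j in range(G)) \
            / (sx * sy)
    else:
        out["correlation"] = 0.0
    out["inverse_difference_moment"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    out["inertia"] = sum((i - j) ** 2 * p[i][j]
                         for i in range(G) for j in range(G))
    out["cluster_shade"] = sum((i + j - mx - my) ** 3 * p[i][j]
                               for i in range(G) for j in range(G))
    out["cluster_prominence"] = sum((i + j - mx - my) ** 4 * p[i][j]
                                    for i in range(G) for j in range(G))
    mu_t = sum(i * px[i] for i in range(G))
    var_t = sum((i - mu_t) ** 2 * px[i] for i in range(G))
    if var_t > 0:
        out["haralick_correlation"] = (sum(
            i * j * p[i][j] for i in range(G) for j in range(G))
            - mu_t ** 2) / var_t
    else:
        out["haralick_correlation"] = 0.0

    out["mean"] = sum(i * p[i][j] for i in range(G) for j in range(G))
    out["variance"] = sum((i - out["mean"]) ** 2 * p[i][j]
                          for i in range(G) for j in range(G))
    out["dissimilarity"] = sum(abs(i - j) * p[i][j]
                               for i in range(G) for j in range(G))
    psum = [0.0] * (2 * G - 1)
    pdiff = [0.0] * G
    for i in range(G):
        for j in range(G):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    sa = sum(k * psum[k] for k in range(2 * G - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k]
                              for k in range(2 * G - 1))
    out["sum_entropy"] = -sum(v * math.log(v) for v in psum if v > 0)
    md = sum(k * pdiff[k] for k in range(G))
    out["difference_variance"] = sum((k - md) ** 2 * pdiff[k]
                                     for k in range(G))
    out["difference_entropy"] = -sum(v * math.log(v) for v in pdiff if v > 0)
    hxy = out["entropy"]
    hx = -sum(v * math.log(v) for v in px if v > 0)
    hy = -sum(v * math.log(v) for v in py if v > 0)
    hxy1 = -sum(p[i][j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    out["ic1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["ic2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    return out


def runlength_features_oracle(r, n_pixels):
    """All 10 run-length statistics by literal loops (levels + 1)."""
    r = np.asarray(r, dtype=float)
    G, L = r.shape
    nr = r.sum()
    out = {}
    out["short_run_emphasis"] = sum(
        r[g][l] / (l + 1) ** 2 for g in range(G) for l in range(L)) / nr
    out["long_run_emphasis"] = sum(
        r[g][l] * (l + 1) ** 2 for g in range(G) for l in range(L)) / nr
    out["grey_level_nonuniformity"] = sum(
        sum(r[g]) ** 2 for g in range(G)) / nr
    out["run_length_nonuniformity"] = sum(
        sum(r[g][l] for g in range(G)) ** 2 for l in range(L)) / nr
    out["run_percentage"] = nr / n_pixels
    out["low_grey_level_run_emphasis"] = sum(
        r[g][l] / (g + 1) ** 2 for g in range(G) for l in range(L)) / nr
    out["high_grey_level_run_emphasis"] = sum(
        r[g][l] * (g + 1) ** 2 for g in range(G) for l in range(L)) / nr
    out["short_run_low_grey_level_emphasis"] = sum(
        r[g][l] / ((g + 1) ** 2 * (l + 1) ** 2)
        for g in range(G) for l in range(L)) / nr
    out["short_run_high_grey_level_emphasis"] = sum(
        r[g][l] * (g + 1) ** 2 / (l + 1) ** 2
        for g in range(G) for l in range(L)) / nr
    out["long_run_low_grey_level_emphasis"] = sum(
        r[g][l] * (l + 1) ** 2 / (g + 1) ** 2
        for g in range(G) for l in range(L)) / nr
    return out


def glrlm_oracle(q):
    """Run-length counts along 45-degree anti-diagonals by enumeration."""
    q = np.asarray(q)
    h, w = q.shape
    G = int(q.max()) + 1
    r = np.zeros((G, min(h, w)), dtype=int)
    for s in range(h + w - 1):
        seq = []
        for row in range(h - 1, -1, -1):
            col = s - row
            if 0 <= col < w:
                seq.append(int(q[row, col]))
        k = 0
        while k < len(seq):
            j = k
            while j + 1 < len(seq) and seq[j + 1] == seq[k]:
                j += 1
            r[seq[k], j - k] += 1
            k = j + 1
    return r


def metrics_oracle(y, yhat):
    """R^2 / RMSE / NRMSE% by direct formula transcription."""
    y = list(map(float, y))
    yhat = list(map(float, yhat))
    n = len(y)
    ybar = sum(y) / n
    ss_res = sum((y[i] - yhat[i]) ** 2 for i in range(n))
    ss_tot = sum((v - ybar) ** 2 for v in y)
    rmse = math.sqrt(ss_res / n)
    return {"r2": 1 - ss_res / ss_tot, "rmse": rmse,
            "nrmse_percent": 100 * rmse / ybar}


def gs_chain_oracle(X, start, kmax):
    """SPA chain by explicit least-squares residual projection."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    chain = [start]
    limit = min(kmax, n - 1, p)
    while len(chain) < limit:
        S = X[:, chain]
        best, best_norm = None, 1e-9
        for j in range(p):
            if j in chain:
                continue
            beta, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            resid = X[:, j] - S @ beta
            nrm = float(np.linalg.norm(resid))
            if nrm > best_norm:
                best, best_norm = j, nrm
        if best is None:
            break
        chain.append(best)
    return chain


def rmsecv_oracle(X, y, chain, folds, seed, repeats=3):
    """Prefix RMSECV path with sklearn LinearRegression, replicating the
    seeded repeated fold assignment."""
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    sq = np.zeros(len(chain))
    for _ in range(repeats):
        order = rng.permutation(n)
        fold_id = np.empty(n, dtype=int)
        fold_id[order] = np.arange(n) % folds
        for f in range(folds):
            te = fold_id == f
            tr = ~te
            for k in range(1, len(chain) + 1):
                cols = chain[:k]
                lm = LinearRegression().fit(X[tr][:, cols], y[tr])
                pred = lm.predict(X[te][:, cols])
                sq[k - 1] += ((y[te] - pred) ** 2).sum()
    return np.sqrt(sq / (n * repeats))
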