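"""Independent oracles, written without importing the package's internals.

Each oracle is a deliberately naive transcription — explicit loops, plain
``math`` arithmetic, no vectorization — so it shares no code path with the
implementation it checks.
"""

import math


def ols_slope_intercept(times, values):
    """Closed-form normal-equation OLS for y = a + b t."""
    n = len(times)
    sx = sum(times)
    sy = sum(values)
    sxx = sum(t * t for t in times)
    sxy = sum(t * y for t, y in zip(times, values))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


# --- ODC: hand transcription of the revised correction polynomials -----------

P50_STD = 26.8


def p50_oracle(ph_plasma, pco2, dpg_mm, temp_c):
    """p50 (mmHg) from the published correction polynomials, composed
    multiplicatively about the standard state (pH 7.4 / 40 mmHg / 4.65 mM / 37 C)."""
    ph_rbc = 0.795 * ph_plasma + 1.357
    dph = ph_rbc - (0.795 * 7.40 + 1.357)
    f_ph = P50_STD + (-25.535 * dph + 10.646 * dph * dph - 1.764 * dph * dph * dph)
    dco2 = pco2 - 40.0
    f_co2 = P50_STD + (1.273e-1 * dco2 + 1.083e-4 * dco2 * dco2)
    ddpg = (dpg_mm - 4.65) / 1000.0
    f_dpg = P50_STD + (7.95633e2 * ddpg - 1.96617e4 * ddpg * ddpg)
    dt = temp_c - 37.0
    f_t = P50_STD + (1.435 * dt + 4.163e-2 * dt * dt + 6.86e-4 * dt * dt * dt)
    return P50_STD * (f_ph / P50_STD) * (f_co2 / P50_STD) * (f_dpg / P50_STD) * (f_t / P50_STD)


def saturation_oracle(po2, ph_plasma, pco2, dpg_mm, temp_c):
    if po2 == 0.0:
        return 0.0
    p50 = p50_oracle(ph_plasma, pco2, dpg_mm, temp_c)
    n = 2.82 - 1.20 * 10.0 ** (-po2 / 29.25)
    x = (po2 / p50) ** n
    return x / (1.0 + x)


# --- NIRS: brute-force window means ------------------------------------------

def window_mean_oracle(time_s, signal, lo_s, hi_s):
    """Mean of samples with lo_s < t <= hi_s (half-open window), by explicit loop."""
    total, count = 0.0, 0
    for t, v in zip(time_s, signal):
        if t > lo_s + 1e-9 and t <= hi_s + 1e-9:
            total += v
            count += 1
    if count == 0:
        raise ValueError("empty window")
    return total / count


def optode_mean_oracle(rows):
    """Pointwise mean across optode rows, by explicit loops."""
    n_opt = len(rows)
    n = len(rows[0])
    return [sum(rows[k][i] for k in range(n_opt)) / n_opt for i in range(n)]


def spearman_sign_oracle(xs, ys):
    """Sign of the Spearman rank correlation via naive ranking."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(xs)), ranks(list(ys))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    if num > 0:
        return 1
    if num < 0:
        return -1
    return 0
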