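"""Independent straight-line transcription of the standard FWI daily equations.

Deliberately written as plain scalar code with explicit branching — a
separate route from the vectorised implementation in ``borealfire.fwi`` —
so the two can be compared as independent derivations of the same
published equation set.  Used only by the test suite.
"""

import math

EL = [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
FL = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]


def ffmc_day(f0: float, t: float, h: float, w: float, r: float) -> float:
    mo = 147.2 * (101.0 - f0) / (59.5 + f0)
    if r > 0.5:
        rf = r - 0.5
        if mo <= 150.0:
            mo = mo + 42.5 * rf * math.exp(-100.0 / (251.0 - mo)) * (
                1.0 - math.exp(-6.93 / rf)
            )
        else:
            mo = (
                mo
                + 42.5 * rf * math.exp(-100.0 / (251.0 - mo)) * (1.0 - math.exp(-6.93 / rf))
                + 0.0015 * (mo - 150.0) ** 2 * math.sqrt(rf)
            )
        if mo > 250.0:
            mo = 250.0
    ed = (
        0.942 * h**0.679
        + 11.0 * math.exp((h - 100.0) / 10.0)
        + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
    )
    if mo > ed:
        ko = 0.424 * (1.0 - (h / 100.0) ** 1.7) + 0.0694 * math.sqrt(w) * (
            1.0 - (h / 100.0) ** 8
        )
        kd = ko * 0.581 * math.exp(0.0365 * t)
        m = ed + (mo - ed) * 10.0 ** (-kd)
    else:
        ew = (
            0.618 * h**0.753
            + 10.0 * math.exp((h - 100.0) / 10.0)
            + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
        )
        if mo < ew:
            k1 = 0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7) + 0.0694 * math.sqrt(
                w
            ) * (1.0 - ((100.0 - h) / 100.0) ** 8)
            kw = k1 * 0.581 * math.exp(0.0365 * t)
            m = ew - (ew - mo) * 10.0 ** (-kw)
        else:
            m = mo
    f = 59.5 * (250.0 - m) / (147.2 + m)
    if f > 101.0:
        f = 101.0
    if f < 0.0:
        f = 0.0
    return f


def dmc_day(p0: float, t: float, h: float, r: float, month: int) -> float:
    if r > 1.5:
        re = 0.92 * r - 1.27
        mo = 20.0 + 280.0 / math.exp(0.023 * p0)
        if p0 <= 33.0:
            b = 100.0 / (0.5 + 0.3 * p0)
        elif p0 <= 65.0:
            b = 14.0 - 1.3 * math.log(p0)
        else:
            b = 6.2 * math.log(p0) - 17.2
        mr = mo + 1000.0 * re / (48.77 + b * re)
        pr = 244.72 - 43.43 * math.log(mr - 20.0)
        if pr < 0.0:
            pr = 0.0
    else:
        pr = p0
    if t < -1.1:
        t = -1.1
    k = 1.894 * (t + 1.1) * (100.0 - h) * EL[month - 1] * 1.0e-6
    p = pr + 100.0 * k
    if p < 0.0:
        p = 0.0
    return p


def dc_day(d0: float, t: float, r: float, month: int) -> float:
    if r > 2.8:
        rd = 0.83 * r - 1.27
        qo = 800.0 * math.exp(-d0 / 400.0)
        qr = qo + 3.937 * rd
        dr = 400.0 * math.log(800.0 / qr)
        if dr < 0.0:
            dr = 0.0
    else:
        dr = d0
    if t < -2.8:
        t = -2.8
    v = 0.36 * (t + 2.8) + FL[month - 1]
    if v < 0.0:
        v = 0.0
    d = dr + 0.5 * v
    if d < 0.0:
        d = 0.0
    return d


def isi_day(f: float, w: float) -> float:
    m = 147.2 * (101.0 - f) / (59.5 + f)
    fw = math.exp(0.05039 * w)
    ff = 91.9 * math.exp(-0.1386 * m) * (1.0 + m**5.31 / 4.93e7)
    return 0.208 * fw * ff


def bui_day(p: float, d: float) -> float:
    if p + 0.4 * d <= 0.0:
        return 0.0
    if p <= 0.4 * d:
        u = 0.8 * p * d / (p + 0.4 * d)
    else:
        u = p - (1.0 - 0.8 * d / (p + 0.4 * d)) * (0.92 + (0.0114 * p) ** 1.7)
    return max(u, 0.0)


def step_day(f0, p0, d0, t, h, w, r, month):
    f = ffmc_day(f0, t, h, w, r)
    p = dmc_day(p0, t, h, r, month)
    d = dc_day(d0, t, r, month)
    return f, p, d, isi_day(f, w), bui_day(p, d)
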