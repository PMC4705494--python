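"""Independent brute-force oracles for the non-linear HRV measures.

Plain double-loop implementations, deliberately kept free of any code
shared with the package, used to verify the vectorised implementations
on short series.
"""

from __future__ import annotations

import math


def apen_brute(x, m: int, r: float) -> float:
    """Approximate entropy with self-matches (Pincus definition)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
            total += math.log(count / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_brute(x, m: int, r: float) -> float:
    """Sample entropy without self-matches (Richman–Moorman)."""
    x = list(map(float, x))
    n = len(x)
    nt = n - m  # template count at both m and m+1

    def count(mm: int) -> int:
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i == j:
                    continue
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def rqa_brute(x, m: int, tau: int, r: float, lmin: int) -> dict[str, float]:
    """Recurrence statistics from an explicitly constructed matrix."""
    x = list(map(float, x))
    nv = len(x) - (m - 1) * tau
    emb = [[x[i + k * tau] for k in range(m)] for i in range(nv)]

    def dist(i: int, j: int) -> float:
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(emb[i], emb[j])))

    rec = [[dist(i, j) <= r for j in range(nv)] for i in range(nv)]
    npoints = sum(rec[i][j] for i in range(nv) for j in range(nv) if i != j)
    out = {"RPREC": 100.0 * npoints / (nv * nv - nv)}
    if npoints == 0:
        out.update({k: float("nan")
                    for k in ("RPDET", "RPLmean", "RPLmax", "RPShan")})
        return out
    lengths = []
    for off in list(range(-(nv - 1), 0)) + list(range(1, nv)):
        run = 0
        for i in range(nv):
            j = i + off
            if 0 <= j < nv and rec[i][j]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    lines = [L for L in lengths if L >= lmin]
    if not lines:
        out.update({"RPDET": 0.0, "RPLmean": float("nan"),
                    "RPLmax": float("nan"), "RPShan": float("nan")})
        return out
    out["RPDET"] = 100.0 * sum(lines) / npoints
    out["RPLmean"] = sum(lines) / len(lines)
    out["RPLmax"] = float(max(lines))
    ent = 0.0
    for L in set(lines):
        p = lines.count(L) / len(lines)
        ent -= p * math.log(p)
    out["RPShan"] = ent
    return out
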