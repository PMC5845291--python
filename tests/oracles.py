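"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately naive — nested loops, no grouping libraries,
direct transcriptions of the closed forms — and stays independent of the
package code paths it checks.
"""

from __future__ import annotations

import math


def brute_ingest(raw_records, ref_pairs, min_count=3, sentinels=("unknown", "")):
    """Full ingest chain on (report_id, drug, dtype, adr, serious) tuples.

    Returns {(drug, adr): (count, dtype, known)} using only loops.
    """
    sentinel_set = {s.strip().lower() for s in sentinels}
    kept = []
    for rec in raw_records:
        _rid, drug, dtype, adr, _serious = rec
        if drug.strip().lower() in sentinel_set:
            continue
        if adr.strip().lower() in sentinel_set:
            continue
        kept.append((drug, dtype, adr))

    keys = []
    for drug, dtype, adr in kept:
        if (drug, adr) not in keys:
            keys.append((drug, adr))

    out = {}
    ref_drugs = {d for d, _ in ref_pairs}
    for drug, adr in keys:
        count = 0
        dtype = None
        for d2, t2, a2 in kept:
            if d2 == drug and a2 == adr:
                count += 1
                dtype = t2
        if count >= min_count and drug in ref_drugs:
            out[(drug, adr)] = (count, dtype, (drug, adr) in ref_pairs)
    return out


def brute_table(pair_counts, key):
    """2x2 cells by double loop over a {(drug, adr): count} dict."""
    drug, adr = key
    a = b = c = d = 0
    for (d2, a2), n in pair_counts.items():
        if d2 == drug and a2 == adr:
            a += n
        elif d2 == drug:
            b += n
        elif a2 == adr:
            c += n
        else:
            d += n
    return a, b, c, d


def brute_chi2(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


def brute_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def brute_prr_signal(a, b, c, d):
    return a >= 3 and brute_prr(a, b, c, d) >= 2 and brute_chi2(a, b, c, d) >= 4


def brute_ror(a, b, c, d):
    return (a * d) / (b * c)


def brute_ror_signal(a, b, c, d):
    if min(a, b, c, d) == 0:
        return False
    low = math.exp(
        math.log(brute_ror(a, b, c, d))
        - 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    )
    return a >= 3 and low > 1.0


def brute_ic(a, b, c, d):
    n = a + b + c + d
    expected = (a + b) * (a + c) / n
    return math.log2((a + 0.5) / (expected + 0.5))


def brute_ic_sd(a, b, c, d):
    n = a + b + c + d
    row, col = a + b, a + c
    gamma = (n + 2) ** 2 / ((row + 1) * (col + 1))
    var = (
        (n - a + gamma - 1) / ((a + 1) * (1 + n + gamma))
        + (n - row + 1) / ((row + 1) * (n + 3))
        + (n - col + 1) / ((col + 1) * (n + 3))
    ) / math.log(2) ** 2
    return math.sqrt(var)


def brute_ic_signal(a, b, c, d):
    return brute_ic(a, b, c, d) - 2 * brute_ic_sd(a, b, c, d) > 0


def brute_fourfold(total_pos, sub_pos, universe, known):
    """Fourfold cells by explicit set algebra over the universe."""
    tp = set(total_pos) & set(universe)
    sp = set(sub_pos)
    cells = {}
    cells["a"] = {k for k in universe if k in tp and k in sp}
    cells["b"] = {k for k in universe if k in tp and k not in sp}
    cells["c"] = {k for k in universe if k not in tp and k in sp}
    cells["d"] = {k for k in universe if k not in tp and k not in sp}
    out = {}
    for name, members in cells.items():
        out[name + "1"] = sum(1 for k in members if known[k])
        out[name + "0"] = sum(1 for k in members if not known[k])
    return out


def brute_phi(x, y):
    """Pearson correlation of two equal-length 0/1 sequences, from sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(xi * yi for xi, yi in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sum(xi * xi for xi in x) - sx * sx)
                    * (n * sum(yi * yi for yi in y) - sy * sy))
    return num / den
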