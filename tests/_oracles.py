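"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately re-derive quantities with literal loops and textbook
formulas; they must stay independent of the package implementation paths
they are used to check.
"""

import itertools

import numpy as np

from sigsel.genotypes import MISSING
from sigsel.scan import gamete_indicators


def brute_force_components(y, line, rep, sample):
    """Nested method-of-moments from explicit group means (unbalanced-safe)."""
    y = np.asarray(y, dtype=float)
    line = np.asarray(line)
    rep = np.asarray(rep)
    sample = np.asarray(sample)
    cell = line * (rep.max() + 1) + rep if len(set(rep)) > 1 else line

    def q(codes):
        out = 0.0
        for c in set(codes):
            v = y[codes == c]
            out += v.sum() ** 2 / v.size
        return out

    n = y.size
    q_obs = (y**2).sum()
    q_s, q_c, q_l = q(sample), q(cell), q(line)
    q_grand = y.sum() ** 2 / n
    ss_g, ss_s = q_obs - q_s, q_s - q_c
    ss_r, ss_l = q_c - q_l, q_l - q_grand

    def k(u_codes, g_codes):
        tot = 0.0
        for g in set(g_codes):
            mask = g_codes == g
            tot += sum(
                (mask & (u_codes == u)).sum() ** 2 for u in set(u_codes[mask])
            ) / mask.sum()
        return tot

    grand = np.zeros(n, dtype=int)
    s_plus, c_plus, l_plus = len(set(sample)), len(set(cell)), len(set(line))
    sg = ss_g / (n - s_plus) if n > s_plus else 0.0
    c_s = n - k(sample, cell)
    ss_hat = (ss_s - sg * (s_plus - c_plus)) / c_s if c_s > 0 else 0.0
    if len(set(rep)) > 1:
        c_r = n - k(cell, line)
        sr = (
            (ss_r - sg * (c_plus - l_plus) - ss_hat * (k(sample, cell) - k(sample, line)))
            / c_r
            if c_r > 0
            else 0.0
        )
    else:
        sr = 0.0
    c_l = n - k(line, grand)
    sl = (
        ss_l
        - sg * (l_plus - 1)
        - ss_hat * (k(sample, line) - k(sample, grand))
        - sr * (k(cell, line) - k(cell, grand))
    ) / c_l
    return sl, sr, ss_hat, sg


def oracle_locus(dosage_col, design):
    """Expand one dosage column to gametes, drop missing, run the oracle."""
    y, labels = [], []
    for kk, d in enumerate(dosage_col):
        if d == MISSING:
            continue
        for copy in ((1, 1) if d == 2 else (1, 0) if d == 1 else (0, 0)):
            y.append(copy)
            labels.append((design.line[kk], design.replicate[kk], kk))
    labels = np.array(labels)
    return brute_force_components(y, labels[:, 0], labels[:, 1], labels[:, 2])


def exhaustive_gamete_maxima(dosage, design):
    """Max-theta distribution over all gamete-row permutations (w = 1)."""
    y, _ = gamete_indicators(dosage)
    n = y.shape[0]
    maxima = []
    for order in itertools.permutations(range(n)):
        order = np.array(order)
        vals = []
        for q in range(dosage.shape[1]):
            yq = y[order, q]
            sl, sr, ss, sg = brute_force_components(
                yq, design.gamete_line, design.gamete_replicate, design.gamete_sample
            )
            denom = sl + sr + ss + sg
            if denom != 0 and 0 < yq.sum() < yq.size:
                vals.append(sl / denom)
        maxima.append(max(vals) if vals else np.nan)
    return np.array(maxima)


def direct_gamete_frequencies(haps):
    """Count phased two-locus gametes directly (haps: gametes x 2 loci)."""
    out = {}
    for a in (0, 1):
        for b in (0, 1):
            out[(a, b)] = np.mean((haps[:, 0] == a) & (haps[:, 1] == b))
    return out
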