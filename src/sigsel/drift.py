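"""Fixed/lost allele counts, the drift regression and the derived FDR.

The number of loci divergently fixed between a selected line pair grows with
genome-wide drift (indexed by the average Fst), while fixation caused by
selection is drift-independent.  Regressing the fixed/lost counts on their
Fst values therefore splits the two: the intercept estimates the count fixed
by selection and ``(N - b0) / N`` the fraction attributable to drift (the
false discovery rate of "fixed" as a selection signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigsel.genotypes import FrequencyTable
from sigsel.scan import pairwise_fst_summary


@dataclass
class FixationCounts:
    """Divergently fixed/lost locus counts per scope with genome-wide Fst."""

    table: pd.DataFrame  # columns: scope, n_fixed_lost, fst

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.table["fst"], self.table["n_fixed_lost"]))


def count_fixed_lost(
    freqs: FrequencyTable, mode: str = "divergent", atol: float = 0.0
) -> FixationCounts:
    """Count loci fixed/lost between the two lines, within and across replicates.

    ``mode='divergent'`` (default) requires the non-reference frequency to be
    exactly 1 in one line and 0 in the other; ``mode='either'`` counts loci
    where at least one line is monomorphic.  The across-replicates count
    requires concordant divergent fixation (same direction) in both
    replicates.  Loci with missing cells are skipped.
    """
    if mode not in {"divergent", "either"}:
        raise ValueError(f"unknown mode: {mode}")
    lines = freqs.lines
    reps = freqs.replicates
    if len(lines) != 2:
        raise ValueError("fixation counting requires exactly two lines")
    fst = pairwise_fst_summary(freqs).set_index("scope")["fst"]

    def fixed_high(p1, p2):
        return (np.abs(p1 - 1.0) <= atol) & (np.abs(p2) <= atol)

    rows = []
    per_rep_direction = []
    for rep in reps:
        p1 = freqs.freq[freqs.cell(lines[0], rep)]
        p2 = freqs.freq[freqs.cell(lines[1], rep)]
        ok = np.isfinite(p1) & np.isfinite(p2)
        up = fixed_high(p1, p2) & ok
        down = fixed_high(p2, p1) & ok
        if mode == "divergent":
            n = int((up | down).sum())
        else:
            mono = ok & (
                (np.abs(p1) <= atol)
                | (np.abs(p1 - 1) <= atol)
                | (np.abs(p2) <= atol)
                | (np.abs(p2 - 1) <= atol)
            )
            n = int(mono.sum())
        per_rep_direction.append((up, down, ok))
        rows.append(
            {
                "scope": f"replicate_{rep}",
                "n_fixed_lost": n,
                "fst": float(fst[f"replicate_{rep}"]),
            }
        )
    if len(reps) > 1:
        up = np.logical_and.reduce([d[0] for d in per_rep_direction])
        down = np.logical_and.reduce([d[1] for d in per_rep_direction])
        rows.append(
            {
                "scope": "across_replicates",
                "n_fixed_lost": int((up | down).sum()),
                "fst": float(fst["across_replicates"]),
            }
        )
    return FixationCounts(pd.DataFrame(rows))


@dataclass
class DriftFit:
    """OLS fit of fixed/lost counts on Fst."""

    b0: float       # intercept: count fixed due to selection
    b1: float       # slope: loss rate per unit Fst
    se_b0: float
    points: list

    def fdr(self, n: float) -> float:
        """(N - b0) / N, clamped to [0, 1] with a warning if outside."""
        if n <= 0:
            return float("nan")
        raw = (n - self.b0) / n
        if raw < 0 or raw > 1:
            warnings.warn(
                f"FDR {raw:.3f} outside [0, 1]; clamping", stacklevel=2
            )
        return float(min(max(raw, 0.0), 1.0))

    def fdr_percent(self, n: float) -> float:
        """FDR rounded to the nearest integer percent (NaN when N = 0)."""
        val = self.fdr(n)
        return float("nan") if np.isnan(val) else int(round(100.0 * val))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fst": x,
                    "n_fixed_lost": y,
                    "fitted": self.b0 + self.b1 * x,
                    "fdr_percent": self.fdr_percent(y),
                }
                for x, y in self.points
            ]
        )


def drift_regression(points) -> DriftFit:
    """Ordinary least squares of fixed/lost counts on genome-wide Fst.

    ``points`` are (fst, count) pairs -- typically the two within-replicate
    scopes and the across-replicates scope.
    """
    import statsmodels.api as sm

    points = [(float(x), float(y)) for x, y in points]
    if len(points) < 3:
        raise ValueError("need at least three (fst, count) points")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct Fst values")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return DriftFit(
        b0=float(fit.params[0]),
        b1=float(fit.params[1]),
        se_b0=float(fit.bse[0]),
        points=points,
    )


def drift_fdr_report(counts: FixationCounts) -> pd.DataFrame:
    """Fit the drift regression on the counted scopes and report FDR per scope."""
    fit = drift_regression(counts.points())
    out = counts.table.copy()
    out["b0"] = fit.b0
    out["fdr_percent"] = [fit.fdr_percent(n) for n in out["n_fixed_lost"]]
    return out


def het_miscall_rate(depth: int) -> float:
    """Probability a true heterozygote shows only one allele in ``depth`` reads.

    Under binomial(depth, 1/2) allele sampling this is ``2 * (1/2) ** depth``
    -- about 6% at the study's average depth of 5.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return 2.0 * 0.5**depth
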