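"""Mismatch-analysis statistics for groups of sequences.

Implements the demographic side of the pipeline: pairwise nucleotide
differences, nucleotide diversity π, segregating sites S, Tajima's D,
Ramos-Onsins & Rozas's R2, Harpending's raggedness r, and observed/expected
mismatch distributions.

Conventions
-----------
* The default site policy is **complete deletion per group**: any column
  holding a gap, 'N' or IUPAC ambiguity code in *any* sequence of the group is
  dropped before counting, and the effective length ``L_eff`` is reported
  alongside every statistic.  This matches the convention of the standard
  desktop tools and is why different groups over the same matrix can have
  slightly different site counts.
* Ambiguity codes are treated as missing for all statistics.
* Statistics that are not identifiable are reported as explicit
  ``undefined`` values with a reason, never silently as 0: Tajima's D needs
  S > 0 and n >= 4, R2 needs S > 0, everything pairwise needs n >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Alignment

__all__ = [
    "GroupStats",
    "MismatchDistribution",
    "encode",
    "pairwise_difference_matrix",
    "group_stats",
    "mismatch_distribution",
    "raggedness",
    "tajima_constants",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode(alignment: Alignment) -> np.ndarray:
    """Integer matrix (n × L): A,C,G,T → 0..3, anything else → −1 (missing)."""
    arr = np.full((alignment.n, alignment.length), -1, dtype=np.int8)
    for i, (_, seq) in enumerate(alignment.items()):
        for j, ch in enumerate(seq):
            arr[i, j] = _CODE.get(ch, -1)
    return arr


def _admitted(arr: np.ndarray, site_policy: str) -> np.ndarray:
    if site_policy == "complete-deletion":
        return (arr >= 0).all(axis=0)
    if site_policy == "pairwise-deletion":
        return np.ones(arr.shape[1], dtype=bool)
    raise ValueError(f"unknown site policy: {site_policy}")


def pairwise_difference_matrix(
    alignment: Alignment, site_policy: str = "complete-deletion"
) -> np.ndarray:
    """Symmetric matrix of pairwise nucleotide differences.

    Under complete deletion any column with missing data in any sequence is
    excluded for every pair; under pairwise deletion columns are excluded per
    pair.
    """
    if alignment.n < 2:
        raise ValueError("need at least two sequences")
    arr = encode(alignment)
    if site_policy == "complete-deletion":
        keep = _admitted(arr, site_policy)
        if not keep.any():
            raise ValueError("no comparable sites after complete deletion")
        sub = arr[:, keep]
        diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        return diff.astype(int)
    if site_policy == "pairwise-deletion":
        n = arr.shape[0]
        out = np.zeros((n, n), dtype=int)
        ok = arr >= 0
        for i in range(n):
            for j in range(i + 1, n):
                both = ok[i] & ok[j]
                if not both.any():
                    raise ValueError(
                        f"no comparable sites between sequences {i} and {j}"
                    )
                d = int((arr[i, both] != arr[j, both]).sum())
                out[i, j] = out[j, i] = d
        return out
    raise ValueError(f"unknown site policy: {site_policy}")


@dataclass
class GroupStats:
    """Summary statistics for one group of sequences."""

    name: str
    n: int
    L_eff: int
    S: Optional[int] = None
    k_bar: Optional[float] = None
    pi: Optional[float] = None
    D: Optional[float] = None
    R2: Optional[float] = None
    r: Optional[float] = None
    singletons: Optional[list] = None
    undefined: dict = field(default_factory=dict)  # stat -> reason

    def as_row(self) -> dict:
        def fmt(x):
            return "undefined" if x is None else f"{x:.4f}"

        return {
            "group": self.name,
            "n": self.n,
            "L_eff": self.L_eff,
            "S": "undefined" if self.S is None else self.S,
            "k_bar": fmt(self.k_bar),
            "pi": fmt(self.pi),
            "tajima_D": fmt(self.D),
            "R2": fmt(self.R2),
            "raggedness": fmt(self.r),
        }


def tajima_constants(n: int) -> dict:
    """The a1..e2 coefficients of Tajima's D for sample size ``n``."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def group_stats(
    alignment: Alignment,
    site_policy: str = "complete-deletion",
    name: str = "group",
) -> GroupStats:
    """Compute S, k̄, π, singleton counts, Tajima's D, R2 and raggedness.

    π = k̄ / L_eff (mean pairwise differences per admitted site).  R2 follows
    Ramos-Onsins & Rozas: sqrt(mean over sequences of (U_i − k̄/2)²) / S with
    U_i the number of admitted sites where sequence i carries a state found in
    no other sequence of the group.
    """
    arr = encode(alignment)
    n = alignment.n
    if site_policy == "complete-deletion":
        keep = _admitted(arr, site_policy)
    else:
        keep = np.ones(arr.shape[1], dtype=bool)
    L_eff = int(keep.sum())
    stats = GroupStats(name=name, n=n, L_eff=L_eff)
    if n < 2:
        stats.undefined = {
            s: "only one sequence" for s in ("S", "k_bar", "pi", "D", "R2", "r")
        }
        return stats
    if L_eff == 0:
        raise ValueError("no comparable sites after complete deletion")

    sub = arr[:, keep]
    # segregating sites on admitted columns (missing states ignored under
    # pairwise deletion)
    S = 0
    singletons = [0] * n
    for j in range(sub.shape[1]):
        col = sub[:, j]
        present = col[col >= 0]
        states, counts = np.unique(present, return_counts=True)
        if len(states) > 1:
            S += 1
        for st, ct in zip(states, counts):
            if ct == 1 and len(states) > 1:
                i = int(np.where(col == st)[0][0])
                singletons[i] += 1
    mat = pairwise_difference_matrix(alignment, site_policy)
    iu = np.triu_indices(n, k=1)
    k_bar = float(mat[iu].mean())
    stats.S = S
    stats.k_bar = k_bar
    stats.pi = k_bar / L_eff
    stats.singletons = singletons

    if S == 0:
        stats.undefined["D"] = "no segregating sites"
        stats.undefined["R2"] = "no segregating sites"
    else:
        if n < 4:
            stats.undefined["D"] = "fewer than four sequences"
        else:
            c = tajima_constants(n)
            var = c["e1"] * S + c["e2"] * S * (S - 1)
            stats.D = (k_bar - S / c["a1"]) / math.sqrt(var)
        mean_sq = sum((u - k_bar / 2.0) ** 2 for u in singletons) / n
        stats.R2 = math.sqrt(mean_sq) / S

    stats.r = raggedness(mismatch_distribution(alignment, site_policy=site_policy))
    return stats


@dataclass
class MismatchDistribution:
    """Observed (and optionally expected) pairwise-difference spectrum."""

    counts: list                 # c_i, class i = i pairwise differences
    observed: list               # x_i, relative frequencies
    expected: Optional[list]     # e_i under the stated model, or None
    model: str
    k_bar: float

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1


def mismatch_distribution(
    alignment: Alignment,
    model: str = "none",
    site_policy: str = "complete-deletion",
    expansion_params: Optional[dict] = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> MismatchDistribution:
    """Observed mismatch distribution, with an optional expected curve.

    ``model="constant"`` uses the equilibrium expectation
    e_i = θ̂^i / (θ̂+1)^(i+1) with θ̂ = k̄.  ``model="expansion-sim"``
    averages the observed spectra of coalescent replicates simulated under a
    sudden-expansion history; parameters (theta0, t, f) are taken from
    ``expansion_params`` or moment-fitted to k̄ (see
    :func:`fit_expansion_params`).
    """
    mat = pairwise_difference_matrix(alignment, site_policy)
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    diffs = mat[iu]
    d_max = int(diffs.max())
    counts = np.bincount(diffs, minlength=d_max + 1)
    total = counts.sum()
    observed = counts / total
    k_bar = float(diffs.mean())

    expected = None
    descriptor = model
    if model == "constant":
        theta = k_bar
        i = np.arange(d_max + 1)
        expected = theta**i / (theta + 1.0) ** (i + 1)
        descriptor = f"constant(theta={theta:.4f})"
    elif model == "expansion-sim":
        from .simulate import simulate_demographic

        stats_s = group_stats(alignment, site_policy=site_policy)
        if expansion_params is None:
            expansion_params = fit_expansion_params(
                k_bar, S=stats_s.S or 0, n=n
            )
        theta0 = expansion_params["theta0"]
        t = expansion_params["t"]
        f = expansion_params["f"]
        L = max(stats_s.L_eff, 1)
        acc = np.zeros(d_max + 1)
        extra: list[float] = []
        for rep in range(n_replicates):
            sim_aln, _ = simulate_demographic(
                n=n, theta0=theta0, expansion=(t, f), L=L,
                seed=(seed * 1_000_003 + rep) % 2**31,
            )
            m = pairwise_difference_matrix(sim_aln, "complete-deletion")
            d = m[np.triu_indices(n, k=1)]
            c = np.bincount(d, minlength=d_max + 1).astype(float)
            if len(c) > d_max + 1:
                extra.append(c[d_max + 1 :].sum())
                c = c[: d_max + 1]
            acc += c / d.size
        expected = acc / n_replicates
        descriptor = (
            f"expansion-sim(theta0={theta0:.4f}, t={t:.4f}, f={f:.1f}, "
            f"R={n_replicates}, seed={seed})"
        )
    elif model != "none":
        raise ValueError(f"unknown mismatch model: {model}")

    return MismatchDistribution(
        counts=[int(c) for c in counts],
        observed=[float(x) for x in observed],
        expected=None if expected is None else [float(e) for e in expected],
        model=descriptor,
        k_bar=k_bar,
    )


def fit_expansion_params(k_bar: float, S: int, n: int, f: float = 100.0) -> dict:
    """Moment-fit sudden-expansion parameters from summary statistics.

    θ0 is the Watterson estimate S/a1 (per group, not per site); the
    expansion time t (coalescent units) is solved so that the model's
    expected pairwise difference θ0·[(1 − e^(−t)) + e^(−t)/f] matches k̄.
    When k̄ exceeds the model's range, t is clamped.
    """
    from scipy.optimize import brentq

    a1 = sum(1.0 / i for i in range(1, n)) if n > 1 else 1.0
    theta0 = S / a1 if S > 0 else max(k_bar, 1e-6)

    def mean_k(t: float) -> float:
        return theta0 * ((1.0 - math.exp(-t)) + math.exp(-t) / f)

    lo, hi = 1e-6, 50.0
    if k_bar <= mean_k(lo):
        t = lo
    elif k_bar >= mean_k(hi):
        t = hi
    else:
        t = brentq(lambda x: mean_k(x) - k_bar, lo, hi)
    return {"theta0": theta0, "t": t, "f": f}


def raggedness(mismatch: MismatchDistribution) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d+1} (x_i − x_{i−1})².

    Classes run 0..d with d the largest observed difference and a terminal
    step x_{d+1} := 0, so a spectrum concentrated at 0 has r = 1.
    """
    x = list(mismatch.observed) + [0.0]
    return float(sum((x[i] - x[i - 1]) ** 2 for i in range(1, len(x))))
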