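"""Distance-shell Kolmogorov–Smirnov scan for residual induced fit.

Atoms are collected in cumulative shells of increasing radius around the
geometric center of the binding site (an atom inside radius r stays in
every larger shell).  For a set of cross-ensemble frame pairs matched in PC
space, the superposed RMSD over each shell's atoms is computed, and each
shell's RMSD sample is compared with the far-reference shell (default 30 Å)
by a two-sample KS test.  A p-value near 0 inside the binding-site radius
with p ≈ 1 far away is the signature of residual induced fit: the local
deviations between matched unbound/bound conformations are statistically
larger than the global background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special

from .structure_io import AtomSelection, ConformationalEnsemble, SelectionError
from .superpose import fitted_rmsd_pairs, unfitted_rmsd_pairs

__all__ = [
    "KSResult",
    "ShellKSProfile",
    "shell_atom_sets",
    "shell_rmsd_profile",
    "ks_statistic",
    "ks_two_sample",
    "ks_pvalue_profile",
]

#: enumerate all C(n+n', n) label assignments up to this count; Monte-Carlo beyond
EXACT_ENUMERATION_CAP = 200_000


@dataclass
class KSResult:
    """Two-sample KS comparison.

    ``statistic_d`` is sup|F_n − F_n'| over the pooled sample points;
    ``critical_value`` is K(α) from the Kolmogorov distribution, and
    ``reject`` applies the rule √(nn'/(n+n'))·D > K(α).
    """

    statistic_d: float
    n: int
    n_prime: int
    p_value: float
    alpha: float
    critical_value: float
    reject: bool
    method: str


@dataclass
class ShellKSProfile:
    """Per-shell RMSD samples and KS p-values against a reference shell."""

    shell_radii: np.ndarray                 # ascending Å
    atom_counts: np.ndarray                 # atoms per shell
    samples: list[np.ndarray]               # one RMSD value per matched pair
    means: np.ndarray
    sds: np.ndarray
    degenerate_fit: np.ndarray              # shells with < 3 atoms (no prefit)
    p_values: np.ndarray | None = None
    reference_radius: float | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "radius_A": self.shell_radii,
            "n_atoms": self.atom_counts,
            "mean_rmsd": self.means,
            "sd_rmsd": self.sds,
        }
        if self.p_values is not None:
            data["p_value"] = self.p_values
        return pd.DataFrame(data)


def shell_atom_sets(
    reference_frame: np.ndarray,
    selection: AtomSelection,
    center_selection: AtomSelection,
    radii,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Cumulative per-radius atom index lists around the site center.

    The center is the unweighted geometric mean of the ``center_selection``
    atoms in the reference frame; shell r holds every selection atom within
    distance r.  Returns the index lists and the center point.
    """
    if not selection.resolved or not center_selection.resolved:
        raise SelectionError("selections must be resolved")
    ref = np.asarray(reference_frame, dtype=float)
    center = ref[center_selection.indices].mean(axis=0)
    sel_idx = np.asarray(selection.indices)
    dist = np.linalg.norm(ref[sel_idx] - center, axis=1)
    radii = np.asarray(sorted(float(r) for r in radii))
    sets = [sel_idx[dist <= r] for r in radii]
    if len(sets[0]) == 0 and all(len(s) == 0 for s in sets):
        raise ValueError(
            "no selection atoms inside any shell; start from a larger radius"
        )
    return sets, center


def shell_rmsd_profile(
    pairs,
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    shell_sets: list[np.ndarray],
    radii,
) -> ShellKSProfile:
    """Superposed RMSD of every matched pair over every shell's atoms.

    Each shell is fitted on its own atoms (the same subset the RMSD uses);
    shells with fewer than 3 atoms are computed without superposition and
    flagged as degenerate.
    """
    pairs = list(pairs)
    if len(pairs) == 0:
        raise ValueError("no matched pairs supplied")
    radii = np.asarray(sorted(float(r) for r in radii))
    b_idx = np.asarray([p[0] for p in pairs], dtype=int)
    u_idx = np.asarray([p[1] for p in pairs], dtype=int)
    samples: list[np.ndarray] = []
    counts = np.zeros(len(shell_sets), dtype=int)
    degenerate = np.zeros(len(shell_sets), dtype=bool)
    for i, idx in enumerate(shell_sets):
        counts[i] = len(idx)
        if len(idx) == 0:
            samples.append(np.full(len(pairs), np.nan))
            degenerate[i] = True
            continue
        a = bound.coords[b_idx][:, idx, :]
        b = unbound.coords[u_idx][:, idx, :]
        if len(idx) < 3:
            degenerate[i] = True
            samples.append(unfitted_rmsd_pairs(a, b))
        else:
            samples.append(fitted_rmsd_pairs(a, b))
    def _stat(s, fn):
        finite = s[np.isfinite(s)]
        return fn(finite) if len(finite) > 1 else np.nan

    means = np.array([_stat(s, np.mean) for s in samples])
    sds = np.array([_stat(s, lambda v: np.std(v, ddof=1)) for s in samples])
    return ShellKSProfile(
        shell_radii=radii,
        atom_counts=counts,
        samples=samples,
        means=means,
        sds=sds,
        degenerate_fit=degenerate,
    )


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov machinery
# ---------------------------------------------------------------------------

def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """D = sup over pooled points of |F_n(x) − F_n'(x)| (ties handled)."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _permutation_p(
    x: np.ndarray, y: np.ndarray, d_obs: float, rng: np.random.Generator,
    cap: int, n_monte_carlo: int,
) -> tuple[float, str]:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    total = math.comb(n + m, n)
    tol = 1e-12
    if total <= cap:
        count = 0
        idx_all = np.arange(n + m)
        for chosen in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            d = ks_statistic(pooled[mask], pooled[idx_all[~mask]])
            if d >= d_obs - tol:
                count += 1
        return count / total, "permutation_exact"
    count = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(n + m)
        d = ks_statistic(pooled[perm[:n]], pooled[perm[n:]])
        if d >= d_obs - tol:
            count += 1
    return (count + 1) / (n_monte_carlo + 1), "permutation_monte_carlo"


def ks_two_sample(
    x,
    y,
    method: str = "auto",
    alpha: float = 0.05,
    seed: int = 0,
    enumeration_cap: int = EXACT_ENUMERATION_CAP,
    n_monte_carlo: int = 10_000,
) -> KSResult:
    """Two-sample KS test with asymptotic or permutation p-value.

    ``method``: ``asymptotic`` uses the Kolmogorov distribution of
    √(nn'/(n+n'))·D; ``permutation_exact`` enumerates all C(n+n', n) label
    assignments when that count is within ``enumeration_cap`` and falls back
    to seeded Monte-Carlo permutation beyond it; ``auto`` picks asymptotic
    for min(n, n') ≥ 30 and permutation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain non-finite values")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n, m = len(x), len(y)
    d = ks_statistic(x, y)
    en = math.sqrt(n * m / (n + m))
    if method == "auto":
        method = "asymptotic" if min(n, m) >= 30 else "permutation_exact"
    if method == "asymptotic":
        p = float(special.kolmogorov(en * d))
        used = "asymptotic"
    elif method == "permutation_exact":
        rng = np.random.default_rng(seed)
        p, used = _permutation_p(x, y, d, rng, enumeration_cap, n_monte_carlo)
    else:
        raise ValueError(f"unknown method {method!r}")
    crit = float(special.kolmogi(alpha))
    return KSResult(
        statistic_d=d,
        n=n,
        n_prime=m,
        p_value=float(min(max(p, 0.0), 1.0)),
        alpha=alpha,
        critical_value=crit,
        reject=bool(en * d > crit),
        method=used,
    )


def ks_pvalue_profile(
    profile: ShellKSProfile,
    reference_radius: float = 30.0,
    method: str = "auto",
    alpha: float = 0.05,
    seed: int = 0,
) -> ShellKSProfile:
    """Fill each shell's KS p-value against the reference shell's sample.

    The reference shell compares to itself, so its p-value is exactly 1.
    """
    radii = profile.shell_radii
    ref_pos = np.flatnonzero(np.isclose(radii, reference_radius))
    if len(ref_pos) == 0:
        raise ValueError(f"reference radius {reference_radius} not in shell grid")
    ref = int(ref_pos[0])
    ref_sample = profile.samples[ref]
    ref_sample = ref_sample[np.isfinite(ref_sample)]
    p = np.empty(len(radii))
    for i, sample in enumerate(profile.samples):
        if i == ref:
            p[i] = 1.0
            continue
        s = sample[np.isfinite(sample)]
        if len(s) == 0:
            p[i] = np.nan
            continue
        p[i] = ks_two_sample(s, ref_sample, method=method, alpha=alpha, seed=seed).p_value
    profile.p_values = p
    profile.reference_radius = float(reference_radius)
    return profile
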