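"""Aggregate evidence arms into a binding-mechanism verdict and report.

Three lines of evidence are combined:

* PC-space overlap of the unbound and bound ensembles (conformational
  selection shows up as shared occupancy);
* provenance-labeled RMSD-threshold clustering of the combined ensemble
  (mixed clusters mean the unbound ensemble visits bound-like states);
* the distance-shell KS scan (p ≈ 0 inside the binding-site radius with a
  benign far-field is the residual induced-fit signature).

A noise-floor ratio (mean cross-ensemble pair RMSD over mean within-ensemble
pair RMSD on the binding site) tests lock-and-key: if bound and unbound
binding-site conformations differ no more than thermal noise, the receptor
was rigid and pre-complementary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import (
    AtomSelection,
    ConformationalEnsemble,
    SelectionError,
    StructureError,
)
from .superpose import kabsch_fit, rmsd as _rmsd

__all__ = [
    "MechanismEvidence",
    "MechanismVerdict",
    "VerdictThresholds",
    "reference_rmsd_distribution",
    "crystal_pair_rmsd",
    "cross_vs_within_ratio",
    "classify_mechanism",
    "render_report",
]

VERDICTS = (
    "lock_and_key",
    "induced_fit",
    "conformational_selection",
    "mixed",
    "inconclusive",
)


@dataclass
class VerdictThresholds:
    """Config thresholds of the rule cascade (all dimensionless or Å)."""

    kappa: float = 1.1          # lock-and-key: cross/within RMSD ratio bound
    ov_sel: float = 0.20        # PC overlap supporting conformational selection
    ov_if: float = 0.05         # PC overlap ceiling compatible with induced fit
    f_mix: float = 0.20         # mixed-cluster population supporting selection
    alpha: float = 0.05         # KS significance level


@dataclass
class MechanismEvidence:
    """Numbers feeding the verdict; binding-site scheme is the minimum."""

    overlap_fraction: dict = field(default_factory=dict)          # scheme -> fraction
    mixed_cluster_fraction: dict = field(default_factory=dict)    # scheme -> {threshold: fraction}
    within_rmsd_p90: float | None = None                          # Å, t_phys
    ks_p_values: dict | None = None                               # radius -> p
    site_radius: float | None = None                              # Å
    cross_vs_within_ratio: float | None = None
    reference_rmsd_means: dict = field(default_factory=dict)      # (ensemble, atom_class) -> Å


@dataclass
class MechanismVerdict:
    verdict: str
    rules: dict = field(default_factory=dict)                     # per-rule booleans
    thresholds: VerdictThresholds = field(default_factory=VerdictThresholds)
    explanation: str = ""


# ---------------------------------------------------------------------------
# crystal-reference comparisons
# ---------------------------------------------------------------------------

def _match_atoms(meta_a: pd.DataFrame, meta_b: pd.DataFrame,
                 indices_a: np.ndarray, indices_b: np.ndarray):
    """Match atoms by (residue_number, insertion_code, atom_name) intersection."""
    def keys(meta, idx):
        sub = meta.iloc[idx]
        return {
            (r.residue_number, r.insertion_code, r.atom_name.strip()): i
            for i, r in zip(idx, sub.itertuples())
        }

    ka = keys(meta_a, indices_a)
    kb = keys(meta_b, indices_b)
    common = sorted(set(ka) & set(kb))
    matched_a = np.array([ka[c] for c in common], dtype=int)
    matched_b = np.array([kb[c] for c in common], dtype=int)
    missing = sorted(set(ka) ^ set(kb))
    return matched_a, matched_b, missing


def reference_rmsd_distribution(
    ensemble: ConformationalEnsemble,
    reference: ConformationalEnsemble,
    selection: AtomSelection,
    atom_class: str = "backbone",
) -> tuple[np.ndarray, float, float]:
    """Per-frame RMSD of an ensemble to a reference structure.

    Atoms are matched between ensemble and reference by residue number +
    atom name over ``selection`` restricted to ``atom_class``; each frame is
    superposed on the matched atoms (the same set used for the RMSD).
    Returns the sample plus its mean and standard deviation.
    """
    from .structure_io import resolve_selection
    from dataclasses import replace

    sel_e = resolve_selection(replace(selection, atom_class=atom_class, indices=None), ensemble)
    sel_r = resolve_selection(replace(selection, atom_class=atom_class, indices=None), reference)
    ia, ib, missing = _match_atoms(ensemble.atoms, reference.atoms, sel_e.indices, sel_r.indices)
    if len(ia) == 0:
        raise StructureError(
            f"no atoms matched between ensemble and reference; first mismatches: {missing[:10]}"
        )
    ref = reference.coords[0][ib]
    samples = np.array(
        [_rmsd(ref, frame[ia], prefit=True) for frame in ensemble.coords]
    )
    return samples, float(samples.mean()), float(samples.std(ddof=1))


def crystal_pair_rmsd(
    ref_a: ConformationalEnsemble,
    ref_b: ConformationalEnsemble,
    selection: AtomSelection,
    atom_class: str = "backbone",
) -> float:
    """Superposed RMSD between two crystal structures over a selection.

    Atom matching is by residue number + atom name intersection (so two
    structures with different bound peptides still compare over their shared
    receptor atoms); fails if fewer than half the selection atoms match.
    """
    from .structure_io import resolve_selection
    from dataclasses import replace

    sel_a = resolve_selection(replace(selection, atom_class=atom_class, indices=None), ref_a)
    sel_b = resolve_selection(replace(selection, atom_class=atom_class, indices=None), ref_b)
    ia, ib, missing = _match_atoms(ref_a.atoms, ref_b.atoms, sel_a.indices, sel_b.indices)
    frac = len(ia) / max(len(sel_a.indices), len(sel_b.indices))
    if frac < 0.5:
        raise StructureError(
            f"only {len(ia)} atoms matched (<50% of selection); "
            f"first mismatches: {missing[:10]}"
        )
    return _rmsd(ref_a.coords[0][ia], ref_b.coords[0][ib], prefit=True)


# ---------------------------------------------------------------------------
# evidence helpers
# ---------------------------------------------------------------------------

def cross_vs_within_ratio(
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    selection: AtomSelection,
    max_pairs: int = 20_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Noise-floor ratio: mean cross-ensemble over mean within-ensemble pair RMSD.

    Sampled frame pairs are superposed on the selection.  Under identical
    ensembles the ratio tends to 1; local rearrangements in the bound
    ensemble push it above 1.  Also returns the 90th percentile of the
    pooled within-ensemble pair RMSD (the physically relevant clustering
    threshold ceiling, t_phys).
    """
    from .superpose import fitted_rmsd_pairs

    rng = np.random.default_rng(seed)
    xu = unbound.coords[:, selection.indices, :]
    xb = bound.coords[:, selection.indices, :]

    def sample_pairs(n_a, n_b, cross):
        total = n_a * n_b if cross else n_a * (n_a - 1) // 2
        size = min(max_pairs, total)
        i = rng.integers(0, n_a, size=size)
        j = rng.integers(0, n_b, size=size)
        if not cross:
            bad = i == j
            j[bad] = (j[bad] + 1) % n_b
        return i, j

    iu, ju = sample_pairs(len(xu), len(xu), cross=False)
    within_u = fitted_rmsd_pairs(xu[iu], xu[ju])
    ib, jb = sample_pairs(len(xb), len(xb), cross=False)
    within_b = fitted_rmsd_pairs(xb[ib], xb[jb])
    ic, jc = sample_pairs(len(xu), len(xb), cross=True)
    cross_s = fitted_rmsd_pairs(xu[ic], xb[jc])

    within = np.concatenate([within_u, within_b])
    ratio = float(cross_s.mean() / within.mean())
    t_phys = float(np.percentile(within, 90))
    return ratio, t_phys


# ---------------------------------------------------------------------------
# verdict
# ---------------------------------------------------------------------------

def classify_mechanism(
    evidence: MechanismEvidence,
    thresholds: VerdictThresholds | None = None,
) -> MechanismVerdict:
    """Rule cascade mapping evidence to a mechanism verdict.

    1. lock_and_key if the cross/within RMSD ratio ≤ κ — bound and unbound
       binding-site conformations are indistinguishable from thermal noise;
    2. conformational-selection flag if PC overlap ≥ ov_sel on the
       binding-site scheme OR the mixed-cluster population fraction ≥ f_mix
       at any threshold ≤ t_phys (the within-ensemble pair-RMSD 90th
       percentile);
    3. induced-fit flag if the KS profile is significant (p < α) at every
       shell inside the binding-site radius AND PC overlap < ov_if;
    4. both flags → mixed; one → that mechanism; neither → inconclusive.

    Missing evidence arms degrade to ``inconclusive`` with an explanation.
    """
    thr = thresholds or VerdictThresholds()
    rules: dict[str, bool | None] = {}
    notes: list[str] = []

    ratio = evidence.cross_vs_within_ratio
    if ratio is None:
        notes.append("cross/within ratio missing; lock-and-key rule skipped")
        rules["lock_and_key"] = None
    else:
        rules["lock_and_key"] = ratio <= thr.kappa
        if rules["lock_and_key"]:
            return MechanismVerdict(
                verdict="lock_and_key",
                rules=rules,
                thresholds=thr,
                explanation=(
                    f"cross/within binding-site RMSD ratio {ratio:.3f} <= "
                    f"kappa={thr.kappa}: ensembles differ no more than thermal noise"
                ),
            )

    overlap_bs = evidence.overlap_fraction.get("binding_site")
    mixed = evidence.mixed_cluster_fraction.get("binding_site", {})
    t_phys = evidence.within_rmsd_p90

    cs_flag = None
    if overlap_bs is not None or mixed:
        cs_overlap = overlap_bs is not None and overlap_bs >= thr.ov_sel
        cs_cluster = False
        if mixed and t_phys is not None:
            cs_cluster = any(
                frac >= thr.f_mix for t, frac in mixed.items() if t <= t_phys
            )
        cs_flag = bool(cs_overlap or cs_cluster)
        rules["conformational_selection_overlap"] = cs_overlap
        rules["conformational_selection_clusters"] = cs_cluster
    else:
        notes.append("no PC-overlap or clustering evidence; selection rule skipped")

    if_flag = None
    if evidence.ks_p_values is not None and evidence.site_radius is not None:
        inside = [
            p
            for r, p in evidence.ks_p_values.items()
            if r <= evidence.site_radius and np.isfinite(p)
        ]
        ks_local = len(inside) > 0 and all(p < thr.alpha for p in inside)
        rules["ks_significant_inside_site"] = ks_local
        ov_ok = overlap_bs is not None and overlap_bs < thr.ov_if
        rules["overlap_below_induced_fit_ceiling"] = ov_ok
        if_flag = bool(ks_local and ov_ok)
    else:
        notes.append("KS profile missing; induced-fit rule skipped")

    rules["conformational_selection"] = cs_flag
    rules["induced_fit"] = if_flag

    if cs_flag is None and if_flag is None:
        verdict = "inconclusive"
        notes.append("no evidence arm available")
    elif cs_flag and if_flag:
        verdict = "mixed"
    elif if_flag:
        verdict = "induced_fit"
    elif cs_flag:
        verdict = "conformational_selection"
    else:
        verdict = "inconclusive"
    return MechanismVerdict(
        verdict=verdict, rules=rules, thresholds=thr, explanation="; ".join(notes)
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(
    verdict: MechanismVerdict,
    evidence: MechanismEvidence,
    sweep_table: pd.DataFrame | None = None,
    ks_table: pd.DataFrame | None = None,
    variance_table: pd.DataFrame | None = None,
) -> str:
    """Deterministic plain-text report: identical inputs, identical bytes."""
    lines: list[str] = []
    lines.append("binding-mechanism report")
    lines.append("=" * 40)
    lines.append(f"verdict: {verdict.verdict}")
    if verdict.explanation:
        lines.append(f"notes: {verdict.explanation}")
    lines.append("")
    lines.append("rule evaluations:")
    for rule, value in verdict.rules.items():
        lines.append(f"  {rule}: {value}")
    thr = verdict.thresholds
    lines.append(
        f"thresholds: kappa={thr.kappa} ov_sel={thr.ov_sel} "
        f"ov_if={thr.ov_if} f_mix={thr.f_mix} alpha={thr.alpha}"
    )
    lines.append("")
    lines.append("evidence:")
    for scheme in sorted(evidence.overlap_fraction):
        lines.append(
            f"  overlap_fraction[{scheme}]: {evidence.overlap_fraction[scheme]:.4f}"
        )
    for scheme in sorted(evidence.mixed_cluster_fraction):
        for t in sorted(evidence.mixed_cluster_fraction[scheme]):
            lines.append(
                f"  mixed_cluster_fraction[{scheme}][{t:g} A]: "
                f"{evidence.mixed_cluster_fraction[scheme][t]:.4f}"
            )
    if evidence.cross_vs_within_ratio is not None:
        lines.append(f"  cross_vs_within_ratio: {evidence.cross_vs_within_ratio:.4f}")
    if evidence.within_rmsd_p90 is not None:
        lines.append(f"  within_rmsd_p90: {evidence.within_rmsd_p90:.4f} A")
    if evidence.site_radius is not None:
        lines.append(f"  site_radius: {evidence.site_radius:g} A")
    for key in sorted(evidence.reference_rmsd_means):
        lines.append(
            f"  reference_rmsd_mean[{key}]: {evidence.reference_rmsd_means[key]:.3f} A"
        )
    if evidence.ks_p_values is not None:
        lines.append("")
        lines.append("KS p-value profile:")
        for r in sorted(evidence.ks_p_values):
            lines.append(f"  r={r:5.1f} A  p={evidence.ks_p_values[r]:.6g}")

    def append_table(title: str, table: pd.DataFrame | None) -> None:
        if table is None:
            return
        lines.append("")
        lines.append(title)
        lines.append(table.to_csv(sep="\t", index=False, float_format="%.6g").rstrip())

    append_table("cluster threshold sweep:", sweep_table)
    append_table("shell KS profile:", ks_table)
    append_table("PC variance fractions:", variance_table)
    lines.append("")
    return "\n".join(lines)
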