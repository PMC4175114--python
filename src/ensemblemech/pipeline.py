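"""End-to-end orchestration: ensembles in, mechanism report out.

Stage order: read structures and resolve selections → superpose → combined
PCA with per-scheme overlap → provenance-labeled clustering sweep →
distance-shell KS scan on PC-matched pairs → verdict and report bundle.
Every stage logs its parameters; outputs are byte-deterministic for
identical inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import pca as _pca
from . import shell_ks as _ks
from .config import RunConfig
from .report import (
    MechanismEvidence,
    MechanismVerdict,
    classify_mechanism,
    cross_vs_within_ratio,
    render_report,
)
from .structure_io import (
    AtomSelection,
    ConformationalEnsemble,
    SelectionError,
    parse_selection,
    read_multimodel_pdb,
    resolve_selection,
)

logger = logging.getLogger("ensemblemech")

__all__ = ["PipelineResult", "run_pipeline", "analyze_ensembles"]

#: the three analysis schemes, in reporting order
ANALYSIS_SCHEMES = ("whole", "ao_domain", "binding_site")


@dataclass
class PipelineResult:
    verdict: MechanismVerdict
    evidence: MechanismEvidence
    sweep_table: pd.DataFrame
    ks_table: pd.DataFrame
    variance_table: pd.DataFrame
    n_pairs: int
    report_text: str = ""
    stages_completed: list[str] = field(default_factory=list)


def _resolve_schemes(cfg: RunConfig, ensemble: ConformationalEnsemble) -> dict[str, AtomSelection]:
    """Resolve configured selections; optional schemes that match nothing are
    skipped with a warning, but the whole and binding-site schemes must exist."""
    out = {}
    for name, sel in cfg.selections.items():
        parsed = parse_selection(
            sel["residues"], atom_class=sel.get("atom_class", "calpha"), name=name
        )
        try:
            out[name] = resolve_selection(parsed, ensemble)
        except SelectionError:
            if name in ("whole", "binding_site"):
                raise
            logger.warning("selection %r matches no atoms in this system; skipped", name)
    return out


def _subsample(ensemble: ConformationalEnsemble, max_frames: int, stride: int,
               discard: int) -> ConformationalEnsemble:
    coords = ensemble.coords[discard:]
    if stride > 1:
        coords = coords[::stride]
    if len(coords) > max_frames:
        step = int(np.ceil(len(coords) / max_frames))
        coords = coords[::step]
    return ConformationalEnsemble(
        atoms=ensemble.atoms, coords=coords, provenance=ensemble.provenance,
        frame_stride_ps=ensemble.frame_stride_ps,
    )


def analyze_ensembles(
    unbound: ConformationalEnsemble,
    bound: ConformationalEnsemble,
    config: RunConfig | None = None,
    schemes: dict[str, AtomSelection] | None = None,
    site_scheme: str = "binding_site",
    fit_scheme_for_whole: str = "tower_fit",
) -> PipelineResult:
    """Run the full three-arm comparison on in-memory ensembles.

    ``schemes`` maps scheme names to resolved selections; by default they
    are built from the configuration's residue strings.  The headline
    verdict is computed on the binding-site scheme.
    """
    cfg = config or RunConfig()
    if schemes is None:
        schemes = _resolve_schemes(cfg, unbound)
    stages = []

    cap = cfg.clustering.max_frames // 2
    unbound = _subsample(unbound, cap, cfg.clustering.stride, cfg.discard_first_frames)
    bound = _subsample(bound, cap, cfg.clustering.stride, cfg.discard_first_frames)
    reference = unbound.coords[0]

    site_sel = schemes[site_scheme]
    evidence = MechanismEvidence()

    # --- PCA arm: per-scheme combined PCA, separate projections, overlap
    logger.info("stage pca: k_overlap=%d bin_fraction=%g", cfg.pca.k_overlap, cfg.pca.bin_fraction)
    variance_rows = []
    projections = {}
    for scheme in ANALYSIS_SCHEMES:
        if scheme not in schemes:
            continue
        sel = schemes[scheme]
        if scheme == "whole" and fit_scheme_for_whole in schemes:
            fit_sel = schemes[fit_scheme_for_whole]
        else:
            fit_sel = sel
        model = _pca.fit_pc_model(unbound, bound, sel, fit_sel, reference)
        k = min(cfg.pca.k_overlap, model.eigenvectors.shape[1])
        proj_u = _pca.project(model, unbound, sel, fit_sel, reference, k=None)
        proj_b = _pca.project(model, bound, sel, fit_sel, reference, k=None)
        projections[scheme] = (model, proj_u, proj_b)
        span = np.concatenate([proj_u.scores[:, 0], proj_b.scores[:, 0]])
        bin_width = (span.max() - span.min()) * cfg.pca.bin_fraction
        frac, _, _ = _pca.overlap_fraction(
            proj_u, proj_b, k=k, bin_width=bin_width if bin_width > 0 else None
        )
        evidence.overlap_fraction[scheme] = frac
        fr, cum = _pca.variance_fractions(model, k=min(3, len(model.eigenvalues)))
        for rank, (f_, c_) in enumerate(zip(fr, cum), start=1):
            variance_rows.append(
                {"scheme": scheme, "pc": rank, "fraction": f_, "cumulative": c_}
            )
    variance_table = pd.DataFrame(variance_rows)
    stages.append("pca")

    # --- noise-floor ratio on the binding site
    ratio, t_phys = cross_vs_within_ratio(unbound, bound, site_sel, seed=cfg.seed)
    evidence.cross_vs_within_ratio = ratio
    evidence.within_rmsd_p90 = t_phys
    logger.info("stage ratio: cross/within=%.3f t_phys=%.3f", ratio, t_phys)
    stages.append("ratio")

    # --- clustering arm (binding-site scheme)
    logger.info("stage clustering: thresholds=%s", cfg.clustering.thresholds)
    sweep_table, cluster_sets = _clustering.threshold_sweep(
        unbound, bound, site_sel, cfg.clustering.thresholds
    )
    evidence.mixed_cluster_fraction[site_scheme] = {
        cs.threshold: cs.mixed_population_fraction() for cs in cluster_sets
    }
    stages.append("clustering")

    # --- KS arm: PC-matched pairs on the whole scheme, shells from site center
    whole_scheme = "whole" if "whole" in projections else site_scheme
    model_w, proj_uw, proj_bw = projections[whole_scheme]
    k_pairs = min(cfg.pca.k_pairs, proj_uw.scores.shape[1])
    pu = _pca.PCProjection(proj_uw.provenance, proj_uw.scores[:, :k_pairs], proj_uw.pc_ranks[:k_pairs])
    pb = _pca.PCProjection(proj_bw.provenance, proj_bw.scores[:, :k_pairs], proj_bw.pc_ranks[:k_pairs])
    pairs = _pca.nearest_cross_pairs(pu, pb, cutoff=cfg.pca.pair_cutoff, k=k_pairs)
    logger.info("stage ks: %d PC-matched pairs (cutoff %g)", len(pairs), cfg.pca.pair_cutoff)
    radii = cfg.ks.radii()
    shell_sel = schemes.get("whole", site_sel)
    # shells fixed from the bound-ensemble mean geometry
    bound_mean = bound.coords.mean(axis=0)
    shell_sets, center = _ks.shell_atom_sets(bound_mean, shell_sel, site_sel, radii)
    site_radius = _site_radius(bound_mean, site_sel, center)
    if pairs:
        profile = _ks.shell_rmsd_profile(pairs, unbound, bound, shell_sets, radii)
        profile = _ks.ks_pvalue_profile(
            profile, cfg.ks.reference_radius, method=cfg.ks.method,
            alpha=cfg.ks.alpha, seed=cfg.seed,
        )
        ks_table = profile.to_frame()
        evidence.ks_p_values = dict(zip(profile.shell_radii, profile.p_values))
        evidence.site_radius = site_radius
    else:
        logger.warning("no PC-matched pairs within cutoff; KS arm skipped")
        ks_table = pd.DataFrame()
    stages.append("ks")

    # --- verdict
    thr = cfg.verdict
    thr.alpha = cfg.ks.alpha
    verdict = classify_mechanism(evidence, thr)
    stages.append("verdict")
    result = PipelineResult(
        verdict=verdict,
        evidence=evidence,
        sweep_table=sweep_table,
        ks_table=ks_table,
        variance_table=variance_table,
        n_pairs=len(pairs),
        stages_completed=stages,
    )
    result.report_text = render_report(
        verdict, evidence, sweep_table, ks_table, variance_table
    )
    return result


def _site_radius(reference_frame: np.ndarray, site_sel: AtomSelection,
                 center: np.ndarray) -> float:
    """Radius of the shell that just encloses the binding-site atoms."""
    d = np.linalg.norm(reference_frame[site_sel.indices] - center, axis=1)
    return float(np.ceil(d.max()))


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    """File-level entry point: read PDB ensembles, analyze, write the bundle.

    Writes ``report.txt``, the sweep/KS/variance TSVs and a ``MANIFEST.json``
    recording completed stages into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "error": None}
    try:
        for key in ("unbound", "bound"):
            path = getattr(config, key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{key} ensemble file not found: {path!r}")
        unbound = read_multimodel_pdb(config.unbound).with_provenance("unbound")
        bound = read_multimodel_pdb(config.bound).with_provenance("bound")
        manifest["stages"].append("read")
        result = analyze_ensembles(unbound, bound, config)
        manifest["stages"].extend(result.stages_completed)
        (out / "report.txt").write_text(result.report_text)
        result.sweep_table.to_csv(out / "cluster_sweep.tsv", sep="\t", index=False)
        result.ks_table.to_csv(out / "ks_profile.tsv", sep="\t", index=False)
        result.variance_table.to_csv(out / "pc_variance.tsv", sep="\t", index=False)
        manifest["stages"].append("report")
        return result
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
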