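# ensemblemech

Classify the mechanism of receptor–ligand molecular recognition —
**lock-and-key**, **induced fit**, or **conformational selection** — from a
pair of receptor conformational ensembles: one sampled *unbound*, one
sampled *ligand-bound* (typically molecular-dynamics snapshot stacks). The
package was built around the LSD1/CoREST–H3-histone demethylase complex
(its default atom selections name that system's regions), but every stage
works on any pair of coordinate ensembles.

## What it computes

Given ensembles U (unbound) and B (bound) and an atom selection, three
independent evidence arms are evaluated:

1. **PC-space overlap** — essential-dynamics PCA of the concatenated
   ensemble (eigendecomposition of the Cartesian covariance after Kabsch
   superposition), separate projection of U and B onto the shared modes,
   and the fraction of frames in grid cells occupied by both ensembles.
   Overlap ⇒ the unbound receptor visits bound-like conformations
   (conformational selection).
2. **Combined clustering** — neighbor-count greedy (Daura/gromos) RMSD
   clustering of U ∪ B across a threshold sweep, with every cluster labeled
   `unbound_only` / `bound_only` / `mixed` by member provenance. Mixed
   clusters at physically meaningful thresholds ⇒ conformational selection;
   cleanly separated clusters ⇒ induced fit.
3. **Distance-shell KS scan** — for PC-matched cross-ensemble frame pairs,
   RMSD over cumulative 1 Å shells around the binding-site center, each
   shell's sample compared with the 30 Å reference shell by a two-sample
   Kolmogorov–Smirnov test, D = sup|F_n − F_n′|, p from the Kolmogorov
   distribution of √(nn′/(n+n′))·D (or exact permutation for small
   samples). p ≈ 0 inside the site with p ≈ 1 far away ⇒ residual induced
   fit.

A noise-floor ratio (mean cross-ensemble / mean within-ensemble pair RMSD
on the binding site) tests lock-and-key, and a rule cascade turns the arms
into a verdict (`lock_and_key` / `induced_fit` / `conformational_selection`
/ `mixed` / `inconclusive`). See `docs/methods.md` for the model, the
thresholds and their defaults.

A synthetic generator (`ensemblemech.synthetic`) produces paired
clamp-model bead ensembles with controllable ground truth — a global hinge
mode, an optional local induced-fit rearrangement of the binding site, an
optional bound-like substate the unbound ensemble visits with probability
φ, and Gaussian thermal noise — so the whole pipeline is testable without
MD trajectories.

## Worked example

Generate a synthetic induced-fit pair (2 Å binding-site rearrangement over
0.3 Å thermal noise) and run the full pipeline:

```
$ ensemblemech generate --out-prefix demo_ --delta 2.0 --sigma 0.3 --n-frames 200 --seed 11
ground truth: induced_fit

$ cat run.toml
[selections.whole]
residues = "1-122"
atom_class = "calpha"

[selections.binding_site]
residues = "1-24"
atom_class = "calpha"

$ ensemblemech run --config run.toml --unbound demo_unbound.pdb \
      --bound demo_bound.pdb --out-dir out --seed 11
binding-mechanism report
========================================
verdict: induced_fit

rule evaluations:
  lock_and_key: False
  ...
  induced_fit: True

evidence:
  overlap_fraction[binding_site]: 0.0000
  overlap_fraction[whole]: 0.0000
  mixed_cluster_fraction[binding_site][2 A]: 0.8500
  cross_vs_within_ratio: 3.0541
  within_rmsd_p90: 0.7767 A
  site_radius: 9 A

KS p-value profile:
  r=  4.0 A  p=2.76779e-87
  ...
  r= 27.0 A  p=3.31105e-19
  r= 30.0 A  p=1
```

Reading the numbers: the bound and unbound binding-site clouds share no PC
grid cell (`overlap 0.0`), cross-ensemble deviations are 3× the thermal
noise floor (`ratio 3.05`), and the shell scan is overwhelmingly
significant near the site, decaying toward the 30 Å reference — the
induced-fit signature. The mixed-cluster fractions at 2–5 Å are ignored by
the verdict because they sit above `within_rmsd_p90 ≈ 0.78 Å`, the largest
threshold at which cluster co-membership still implies genuine structural
similarity for this system.

Two crystal structures can be compared directly over any selection (e.g. a
binding site, backbone atoms), with atoms matched by residue number + atom
name so structures with different bound peptides compare over their shared
receptor atoms:

```
ensemblemech crystal-rmsd receptor_bound_A.pdb receptor_bound_B.pdb \
    --residues "353-363,370-391,529-564" --atom-class backbone
```

## Layout

```
src/ensemblemech/
  structure_io.py   multi-model PDB + XYZ-frame I/O, residue-range selections
  superpose.py      Kabsch fits, RMSD, pairwise matrices, RMSF
  pca.py            combined-ensemble PCA, overlap, nearest cross pairs
  clustering.py     neighbor-count greedy clustering, provenance labels
  shell_ks.py       distance shells, two-sample KS machinery
  report.py         crystal comparisons, verdict cascade, report rendering
  synthetic.py      clamp-model ensemble generator with ground truth
  config.py         TOML run configuration and defaults
  pipeline.py       end-to-end orchestration
  cli.py            `ensemblemech` subcommands
```
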