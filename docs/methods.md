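# Methods

`ensemblemech` decides which classical model of non-covalent recognition —
lock-and-key, induced fit, or conformational selection — best describes a
pair of receptor conformational ensembles: one sampled without the ligand
(*unbound*) and one sampled with it (*bound*). The package was built around
the LSD1/CoREST–H3-histone system (its default residue selections name that
complex), but every stage operates on generic coordinate ensembles.

## The three models, operationally

Let U and B be the unbound and bound ensembles restricted to a selection of
atoms (the binding site, a domain, or the whole receptor), compared by
root-mean-square deviation (RMSD) after optimal least-squares (Kabsch)
superposition.

* **Lock-and-key** — the receptor is rigid and pre-complementary: U and B
  differ by no more than thermal noise.
* **Conformational selection** — U already visits the conformations seen in
  B; the ligand only shifts populations. Signature: shared occupancy of
  U and B in a common low-dimensional projection, and clusters of the
  combined ensemble containing frames of both provenances.
* **Induced fit** — the ligand creates local binding-site conformations
  absent from U. Signature: disjoint ensembles at the binding site, and
  matched cross-ensemble deviations that are statistically larger near the
  site than far from it (*residual* induced fit when it survives an initial
  selection step).

## Evidence arms

### Essential-dynamics PCA and ensemble overlap

Frames of both ensembles are superposed on a fit selection (for the
whole-receptor scheme, a rigid anchor domain; otherwise the analysis
selection itself, which isolates the region's internal motion). The
Cartesian covariance of the concatenated ensemble is eigendecomposed; each
ensemble is projected separately onto the shared modes. When the coordinate
dimension exceeds the frame count the spectrum is taken from the
frame-frame Gram matrix (identical eigenvalues, cheaper).

Overlap is quantified by grid-cell co-occupancy in the leading k PCs
(default k = 2): a uniform grid with cell edge 1/20 of the combined PC1
range is anchored at the combined minimum, a cell is *shared* when at least
one frame of each ensemble falls in it, and the overlap fraction is the
fraction of all frames in shared cells. Co-occupancy was chosen over
density estimates for determinism and auditability; the fraction counts
frames, not grid area. The metric is symmetric in the two ensembles and
non-increasing under grid refinement.

### Combined clustering with provenance labels

The concatenated ensemble is clustered by the neighbor-count greedy rule
(Daura/gromos): repeatedly extract the frame with the most neighbors within
an RMSD threshold together with those neighbors. Ties in the neighbor count
are broken toward the lowest frame index — the common implementations leave
this open, so it is pinned for reproducibility. Each cluster is labeled
`unbound_only`, `bound_only`, or `mixed` by its members' provenance; the
*mixed population fraction* (frames living in mixed clusters / all frames)
is the conformational-selection readout. Pairwise RMSDs are computed with a
per-pair superposition on the clustering selection (a global one-reference
superposition is available as a flag but is not the default, since the
per-pair convention matches the RMSD definition used everywhere else).
A threshold sweep (default 2–5 Å) exposes the two failure regimes: too
small a threshold over-resolves into singletons, too large a threshold
merges everything into one cluster.

### Distance-shell Kolmogorov–Smirnov scan

For each bound frame, the nearest unbound frame in the first k PCs of the
whole-receptor model (default k = 3) is selected; pairs within a distance
cutoff are kept, unbound frames may repeat, and the pair count is treated
as data-dependent. Atoms are gathered in *cumulative* shells of radius
1–30 Å (1 Å steps) around the unweighted geometric center of the
binding-site atoms. Shells are fixed from one reference geometry — the
bound-ensemble mean — because the KS comparison across pairs is only well
defined if every pair uses the same atom sets. For every pair and shell,
the RMSD over the shell's atoms is computed after superposing on those same
atoms; shells with fewer than 3 atoms skip the (underdetermined) fit and
are flagged.

Each shell's RMSD sample is compared with the 30 Å reference shell by a
two-sample KS test. The statistic D = sup|F_n − F_n′| is evaluated on the
pooled sample points (right limits, which attain the two-sided supremum
even with ties — RMSD samples can tie at 0). The p-value comes from the
Kolmogorov distribution of √(nn′/(n+n′))·D for samples of at least 30, and
otherwise from the permutation distribution: full enumeration of all
C(n+n′, n) assignments when that count is ≤ 200 000, seeded Monte-Carlo
permutation beyond. The rejection rule √(nn′/(n+n′))·D > K(α) is also
reported, with K(α) the Kolmogorov critical value. A profile with p < α at
every shell inside the binding-site radius and p ≈ 1 at the reference is
the residual-induced-fit signature; no multiple-testing correction is
applied across shells because the profile is read as a shape, not as a
family of independent hypotheses.

### Noise-floor ratio (lock-and-key test)

The ratio of the mean cross-ensemble pair RMSD to the mean within-ensemble
pair RMSD on the binding site, estimated from up to 20 000 sampled frame
pairs per class. Both numerator and denominator are frame-to-frame
quantities, so the ratio tends to exactly 1 when bound and unbound are
statistically identical (a frame-to-ensemble-mean denominator would bias
the null ratio to √2, which is why the pair form was chosen). The 90th
percentile of the within-ensemble pair RMSD also serves as *t_phys*, the
ceiling on clustering thresholds considered physically meaningful when
reading the mixed-cluster fraction.

## Verdict cascade

With config-exposed thresholds (defaults in parentheses):

1. **lock_and_key** if the cross/within ratio ≤ κ (1.1);
2. *conformational-selection flag* if binding-site overlap ≥ ov_sel (0.20)
   **or** mixed-cluster fraction ≥ f_mix (0.20) at any threshold ≤ t_phys;
3. *induced-fit flag* if the KS profile has p < α (0.05) at every shell
   inside the binding-site radius **and** binding-site overlap < ov_if
   (0.05);
4. both flags → **mixed**; one → that mechanism; neither → **inconclusive**.

The cascade is this package's codification of a verdict the underlying
analyses support only jointly; every threshold is reported next to the
verdict, and per-scheme evidence is printed because selection can be real
at the global scale (e.g. a large clamp motion) while the binding site
shows pure induced fit — the headline verdict is the binding-site scheme's.
Missing evidence arms degrade to `inconclusive` rather than erroring.

## Synthetic clamp generator

The generator produces paired ensembles with known mechanism, standing in
for MD trajectories that are rarely shareable. The receptor is a bead model:
two rigid lobes (cubic grids at 3.8 Å spacing, the Cα virtual-bond length,
so RMSD magnitudes are protein-like) joined by a two-bead hinge; the
default 60-bead lobes span ≈ 35 Å, so 30 Å analysis shells are covered.
Per frame:

* the hinge angle is drawn from a per-ensemble Gaussian (defaults 10°
  unbound / 5° bound — binding stiffens the clamp allosterically) and
  lobe 2 is rotated rigidly about the hinge axis: the global clamp mode;
* the binding site (default: the first 24 beads of lobe 1) is displaced
  along a fixed alternating ±z pattern with amplitude
  `substate_delta + site_shift_delta` in bound frames, and amplitude
  `substate_delta` with probability φ (else 0) in unbound frames;
* iid Gaussian noise of σ per coordinate (default 0.3 Å) is added, so the
  per-atom RMSF of a noise-only bead is σ√3 and the pairwise noise floor is
  σ√6 ≈ 0.74 Å.

Two displacement choices matter and were deliberate. First, the pattern
alternates sign across beads rather than translating the site coherently:
a uniform translation of an entire analysis selection is absorbed exactly
by the least-squares fit and would be invisible to every RMSD metric; with
the alternating pattern the superposed cross-ensemble RMSD floor over a
selection containing n_shifted of n_sel displaced atoms is
amplitude·√(n_shifted/n_sel), and the full site patch is displaced by
default so that amplitude survives fitting undiminished. Second,
conformational selection is modeled as a genuine two-state mixture: the
bound-like local substate (`substate_delta`) exists independently of the
residual induced-fit displacement (`site_shift_delta`), because "the
unbound ensemble visits the bound state with probability φ" is vacuous if
there is no distinct bound state to visit. Ground truth follows:
δ > 0 contributes induced fit; φ > 0 with a nonzero substate contributes
selection; both → mixed; neither → lock-and-key.

What the generator does *not* emulate: anharmonic/multi-basin global
dynamics beyond the single hinge mode, correlated (non-iid) thermal
fluctuations, side-chain chemistry, solvent, and kinetics between
substates. Passing the recovery design therefore shows that the pipeline
reads the right signatures out of ensembles whose ground truth is known —
not that real trajectories of any particular system contain those
signatures.

## Numerical choices

* Kabsch rotations use the SVD closed form with the reflection branch
  corrected by the sign of det; fits with < 3 atoms or collinear atoms are
  rejected as degenerate. Pair matrices use the batched closed-form RMSD
  (singular values only), in blocks, without forming rotations.
* Mass weighting is not used anywhere; all averages are unweighted over
  selected atoms, and the shell center is a geometric (not mass) center.
* RMSF uses a once-iterated mean reference: fit to the naive mean,
  recompute the mean, refit.
* PCA eigenvalues are clipped at 0 (tolerating −1e−8 round-off);
  covariance normalization is 1/(F−1).
* Selections are author-numbered inclusive residue intervals; HETATM
  records are excluded from every selection; alternate locations reduce to
  the first conformer.
* Multi-model PDB coordinates are rounded to the printed 1e−3 Å precision
  before writing, so write→read round-trips to within half of the last
  digit; coordinates ≥ 10 000 Å are refused (fixed-column overflow).
* Stage problem sizes: the recovery design uses 500 frames per ensemble,
  60-bead lobes, and distance matrices capped at 2 000 combined frames
  (configurable stride); the analysis is stride-stable on synthetic data
  and is tested at two strides.

## Known limitations

* The verdict thresholds (κ, ov_sel, ov_if, f_mix) are heuristics
  calibrated on the synthetic generator's scales; real systems with
  marginal signatures will land in `inconclusive` rather than being forced
  into a class.
* Grid-cell overlap depends on the bin width; the default ties it to the
  PC1 range, which is sensible when one mode dominates but coarse when the
  spectrum is flat.
* The KS arm inherits the PC-matching step: if no cross-ensemble pairs fall
  within the cutoff, the arm is skipped and the verdict rests on the other
  two.
* Binary trajectory formats (XTC/DCD) are out of scope; ensembles enter as
  multi-model PDB or plain XYZ-frame text.
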