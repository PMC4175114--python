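"""Distance shells, per-shell RMSD samples, and the two-sample KS machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ensemblemech.shell_ks import (
    ks_pvalue_profile,
    ks_statistic,
    ks_two_sample,
    shell_atom_sets,
    shell_rmsd_profile,
)
from ensemblemech.structure_io import (
    ConformationalEnsemble,
    bead_metadata,
    parse_selection,
    resolve_selection,
)
from ensemblemech.synthetic import SyntheticSpec, generate_ensembles


def _sel(ens, spec="1-9999", cls="all"):
    return resolve_selection(parse_selection(spec, atom_class=cls), ens)


class TestShellAtomSets:
    def _line_ensemble(self):
        # atom 1 at the center; atoms 2-4 at distances 0.5, 1.5, 2.5 from it
        coords = np.array([[[0.0, 0, 0], [0.5, 0, 0], [1.5, 0, 0], [2.5, 0, 0]]])
        return ConformationalEnsemble(atoms=bead_metadata(4), coords=coords)

    def test_direct_threshold_counts(self):
        ens = self._line_ensemble()
        sel = _sel(ens, "2-4")
        center = _sel(ens, "1-1")
        sets, c = shell_atom_sets(ens.coords[0], sel, center, [1.0, 2.0, 3.0])
        assert [len(s) for s in sets] == [1, 2, 3]
        np.testing.assert_allclose(c, [0.0, 0.0, 0.0])

    def test_large_radius_captures_everything(self):
        ens = self._line_ensemble()
        sel = _sel(ens)
        sets, _ = shell_atom_sets(ens.coords[0], sel, _sel(ens, "1-1"), [100.0])
        assert len(sets[0]) == ens.n_atoms

    def test_cumulative_nesting_random_configurations(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            coords = rng.normal(scale=8.0, size=(1, 20, 3))
            ens = ConformationalEnsemble(atoms=bead_metadata(20), coords=coords)
            sets, _ = shell_atom_sets(
                ens.coords[0], _sel(ens), _sel(ens, "1-3"), [2.0, 5.0, 10.0, 30.0]
            )
            for smaller, larger in zip(sets, sets[1:]):
                assert set(smaller.tolist()) <= set(larger.tolist())


class TestShellRmsdProfile:
    def test_identity_pairs_all_zero(self):
        spec = SyntheticSpec(n_beads_per_lobe=8, n_site_beads=4, n_frames=10, seed=1)
        u, _, _, tpl = generate_ensembles(spec)
        b = u.with_provenance("bound")
        sets, _ = shell_atom_sets(
            u.coords[0], tpl.selections["whole"], tpl.selections["site"], [5.0, 15.0, 40.0]
        )
        pairs = [(i, i) for i in range(u.n_frames)]
        profile = shell_rmsd_profile(pairs, u, b, sets, [5.0, 15.0, 40.0])
        for s in profile.samples:
            np.testing.assert_allclose(s, 0.0, atol=1e-6)

    def test_locality_of_far_perturbation(self):
        """A difference confined beyond 10 Å shows only in shells ≥ 10 Å."""
        rng = np.random.default_rng(2)
        base = rng.normal(scale=3.0, size=(12, 3))
        base[:6] *= 0.2                     # 6 atoms near origin
        base[6:] = base[6:] / np.linalg.norm(base[6:], axis=1, keepdims=True) * 15.0
        a = base[None].copy()
        b = base[None].copy()
        b[0, 6:] += rng.normal(scale=1.0, size=(6, 3))
        ens_u = ConformationalEnsemble(atoms=bead_metadata(12), coords=a)
        ens_b = ConformationalEnsemble(
            atoms=bead_metadata(12), coords=b, provenance="bound"
        )
        sel = _sel(ens_u)
        center = _sel(ens_u, "1-6")
        radii = [5.0, 20.0]
        sets, _ = shell_atom_sets(a[0], sel, center, radii)
        profile = shell_rmsd_profile([(0, 0)], ens_u, ens_b, sets, radii)
        assert profile.samples[0][0] <= 1e-6
        assert profile.samples[1][0] > 0.1

    def test_induced_fit_inner_shell_exceeds_reference(self):
        """Local shift near the site center: inner-shell mean RMSD exceeds the
        diluted 30 Å value."""
        spec = SyntheticSpec(site_shift_delta=2.0, noise_sigma=0.3, n_frames=94, seed=3)
        u, b, _, tpl = generate_ensembles(spec)
        radii = [8.0, 30.0]
        sets, _ = shell_atom_sets(
            b.coords.mean(axis=0), tpl.selections["whole"], tpl.selections["site"], radii
        )
        pairs = [(i, i) for i in range(94)]
        profile = shell_rmsd_profile(pairs, u, b, sets, radii)
        assert profile.means[0] > profile.means[1]


class TestKSStatistic:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        assert ks_statistic(x, x) == 0.0
        res = ks_two_sample(x, x, method="asymptotic")
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_statistic([0.0, 0, 0], [1.0, 1, 1]) == 1.0

    def test_interleaved_hand_value(self):
        assert ks_statistic([1.0, 2, 3], [1.5, 2.5, 3.5]) == pytest.approx(1 / 3)

    def test_exact_permutation_hand_enumeration(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 assignments reach D=1 → p=0.1."""
        res = ks_two_sample([1.0, 2, 3], [4.0, 5, 6], method="permutation_exact")
        assert res.statistic_d == 1.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "permutation_exact"

    def test_monotone_transform_invariance(self):
        """D is invariant under common strictly monotone transforms."""
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(0.5, 1.2, size=25)
        d0 = ks_statistic(x, y)
        assert ks_statistic(np.exp(x), np.exp(y)) == pytest.approx(d0, abs=1e-12)
        pooled = np.concatenate([x, y])
        ranks = {v: r for r, v in enumerate(np.sort(pooled))}
        rx = np.array([ranks[v] for v in x], dtype=float)
        ry = np.array([ranks[v] for v in y], dtype=float)
        assert ks_statistic(rx, ry) == pytest.approx(d0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0, np.nan], [0.0, 1.0])

    def test_rejection_rule_consistency(self):
        """reject ⇔ √(nn'/(n+n'))·D above the Kolmogorov critical value."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = rng.normal(1.0, 1.0, size=60)
        res = ks_two_sample(x, y, method="asymptotic", alpha=0.05)
        en = math.sqrt(60 * 60 / 120)
        assert res.reject == (en * res.statistic_d > res.critical_value)
        assert res.reject == (res.p_value < 0.05)


class TestAgainstScipy:
    def test_d_and_exact_p_match_scipy_small_cases(self):
        """All size splits of ≤10 pooled points, D and exact p vs scipy."""
        rng = np.random.default_rng(6)
        for n in range(1, 6):
            for m in range(1, 11 - n):
                for _ in range(5):
                    x = rng.normal(size=n)
                    y = rng.normal(0.3, 1.1, size=m)
                    ours = ks_two_sample(x, y, method="permutation_exact")
                    ref = stats.ks_2samp(x, y, method="exact")
                    assert ours.statistic_d == pytest.approx(ref.statistic, abs=1e-12)
                    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_tied_data_matches_independent_enumeration(self):
        """With ties scipy's exact path is approximate; enumerate directly."""
        x = np.array([0.0, 0.0, 1.0])
        y = np.array([0.0, 1.0, 1.0])
        pooled = np.concatenate([x, y])
        grid = np.unique(pooled)

        def d_of(a, b):
            fa = np.array([(a <= v).mean() for v in grid])
            fb = np.array([(b <= v).mean() for v in grid])
            return np.max(np.abs(fa - fb))

        d_obs = d_of(x, y)
        count = total = 0
        for chosen in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(chosen)] = True
            total += 1
            if d_of(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
                count += 1
        ours = ks_two_sample(x, y, method="permutation_exact")
        assert ours.statistic_d == pytest.approx(d_obs, abs=1e-12)
        assert ours.p_value == pytest.approx(count / total, abs=1e-12)

    def test_asymptotic_close_to_permutation_for_large_n(self):
        """|p_asym − p_perm| ≤ 0.05 for n = n' = 50 over many random cases."""
        rng = np.random.default_rng(7)
        for case in range(200):
            shift = rng.uniform(0.0, 0.6)
            x = rng.normal(size=50)
            y = rng.normal(shift, 1.0, size=50)
            p_asym = ks_two_sample(x, y, method="asymptotic").p_value
            p_perm = ks_two_sample(
                x, y, method="permutation_exact", seed=case, n_monte_carlo=2000
            ).p_value
            assert abs(p_asym - p_perm) <= 0.05, f"case {case}"


class TestTypeIError:
    def test_null_rejection_rate_alpha(self):
        """Both samples n=94 from one normal: p<0.05 in 3–7% of 2000 replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=94)
            y = rng.normal(size=94)
            if ks_two_sample(x, y, method="asymptotic").p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07


class TestPValueProfile:
    def _profile_from_samples(self, samples, radii):
        from ensemblemech.shell_ks import ShellKSProfile

        return ShellKSProfile(
            shell_radii=np.asarray(radii, dtype=float),
            atom_counts=np.full(len(radii), 10),
            samples=[np.asarray(s, dtype=float) for s in samples],
            means=np.array([np.mean(s) for s in samples]),
            sds=np.array([np.std(s, ddof=1) for s in samples]),
            degenerate_fit=np.zeros(len(radii), dtype=bool),
        )

    def test_same_distribution_everywhere_p_one(self):
        rng = np.random.default_rng(9)
        base = rng.normal(1.0, 0.1, size=94)
        profile = self._profile_from_samples([base, base, base], [10.0, 20.0, 30.0])
        profile = ks_pvalue_profile(profile, reference_radius=30.0)
        np.testing.assert_allclose(profile.p_values, 1.0)

    def test_strong_shift_inside_p_tiny(self):
        rng = np.random.default_rng(10)
        ref = rng.normal(1.0, 0.1, size=94)
        shifted = ref + 1.0          # +10 sd
        profile = self._profile_from_samples([shifted, ref, ref], [5.0, 20.0, 30.0])
        profile = ks_pvalue_profile(profile, reference_radius=30.0)
        assert profile.p_values[0] < 1e-6
        assert profile.p_values[2] == 1.0

    def test_reference_radius_must_exist(self):
        profile = self._profile_from_samples([[1.0, 2.0]] * 2, [10.0, 30.0])
        with pytest.raises(ValueError):
            ks_pvalue_profile(profile, reference_radius=12.0)

    def test_induced_fit_profile_shape(self):
        """Local rearrangement: p ≈ 0 inside the site region, p = 1 at the
        reference — the qualitative signature of residual induced fit."""
        spec = SyntheticSpec(site_shift_delta=2.0, noise_sigma=0.3, n_frames=94, seed=11)
        u, b, _, tpl = generate_ensembles(spec)
        radii = [float(r) for r in range(4, 31)]
        sets, _ = shell_atom_sets(
            b.coords.mean(axis=0), tpl.selections["whole"], tpl.selections["site"], radii
        )
        pairs = [(i, i) for i in range(94)]
        profile = shell_rmsd_profile(pairs, u, b, sets, radii)
        profile = ks_pvalue_profile(profile, reference_radius=30.0)
        p = dict(zip(profile.shell_radii, profile.p_values))
        assert all(p[r] < 0.01 for r in (8.0, 9.0, 10.0))
        assert p[30.0] == 1.0
        # significance decays toward the reference: the far field is more
        # similar to the global background than the site region is
        assert max(p[r] for r in (27.0, 28.0, 29.0)) > max(p[r] for r in (8.0, 9.0, 10.0))
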