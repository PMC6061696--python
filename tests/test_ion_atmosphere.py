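"""Cation RDFs, site occupancy, residence episodes, density maxima."""

import numpy as np
import pytest

from uturn.ion_atmosphere import (IonSite, compute_rdf, density_maxima,
                                  residence_statistics, site_occupancy)
from uturn.model_io import AtomRef, AtomTable, Ensemble
from uturn.synthetic_data import IonSimSpec, gen_ion_ensemble


def _ion_ensemble(ion_xyz, n_ions=1, dt=None, aligned=False):
    """Reference O atom at origin plus ions; ion_xyz (frames, n_ions, 3)."""
    ion_xyz = np.asarray(ion_xyz, dtype=float)
    if ion_xyz.ndim == 2:
        ion_xyz = ion_xyz[:, None, :]
    nums = [14] + [9000 + i for i in range(n_ions)]
    table = AtomTable(nums, ["U"] + ["K"] * n_ions, ["O4"] + ["K"] * n_ions,
                      ["O"] + ["K"] * n_ions)
    coords = np.zeros((ion_xyz.shape[0], 1 + n_ions, 3))
    coords[:, 1:, :] = ion_xyz
    return Ensemble(table, coords, dt=dt, aligned=aligned)


REF = AtomRef(14, "O4")


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        n_frames, n_ions, half = 20_000, 30, 12.0
        pts = rng.uniform(-half, half, size=(n_frames, n_ions, 3))
        prof = compute_rdf(_ion_ensemble(pts, n_ions), "K", REF,
                           r_max=10.0, bin_width=0.5)
        window = (prof.bin_centers >= 3.0) & (prof.bin_centers <= 5.0)
        np.testing.assert_allclose(prof.g[window], 1.0, atol=0.05)

    def test_single_fixed_ion_is_a_spike(self):
        pts = np.tile([[2.8, 0.0, 0.0]], (50, 1))
        prof = compute_rdf(_ion_ensemble(pts), "K", REF, r_max=5.0,
                           bin_width=0.1)
        hot = int(np.argmax(prof.counts))
        assert prof.bin_centers[hot] == pytest.approx(2.8, abs=0.06)
        assert prof.counts.sum() == prof.counts[hot] == 50

    def test_doubling_bin_width_conserves_counts(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-8, 8, size=(500, 4, 3))
        fine = compute_rdf(_ion_ensemble(pts, 4), "K", REF, 8.0, 0.1)
        coarse = compute_rdf(_ion_ensemble(pts, 4), "K", REF, 8.0, 0.2)
        assert len(coarse.counts) == len(fine.counts) // 2
        assert coarse.counts.sum() == fine.counts.sum()

    def test_convergence_rate_with_frames(self):
        # flatness error of the ideal-gas RDF shrinks ~1/sqrt(frames)
        def err(n_frames, seed):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(-12, 12, size=(n_frames, 8, 3))
            prof = compute_rdf(_ion_ensemble(pts, 8), "K", REF, 10.0, 0.25)
            win = (prof.bin_centers >= 3) & (prof.bin_centers <= 5)
            return np.abs(prof.g[win] - 1).mean()

        e_small = np.mean([err(250, s) for s in range(3)])
        e_large = np.mean([err(4000, s) for s in range(3)])
        ratio = e_small / e_large
        assert 2.0 < ratio < 8.0   # ideal sqrt(16) = 4

    def test_no_ions_is_an_error(self):
        table = AtomTable([14], ["U"], ["O4"], ["O"])
        ens = Ensemble(table, np.zeros((3, 1, 3)))
        with pytest.raises(ValueError, match="no K ions"):
            compute_rdf(ens, "K", REF)


class TestSiteOccupancy:
    def test_always_bound(self):
        pts = np.tile([[2.7, 0, 0]], (20, 1))
        occ = site_occupancy(_ion_ensemble(pts), IonSite("s", REF))
        assert occ.occupancy == 1.0

    def test_generator_bound_fraction_recovery(self):
        spec = IonSimSpec(p=0.8, mean_residence_ps=250, dt=10,
                          n_frames=20_000, seed=11)
        ens, bound = gen_ion_ensemble(spec)
        occ = site_occupancy(ens, IonSite("s", REF))
        sigma3 = 3 * np.sqrt(0.8 * 0.2 / len(bound)) * \
            np.sqrt(2 * 25 - 1)  # dwell correlation inflation, ~sqrt(2m-1)
        assert occ.occupancy == pytest.approx(0.8, abs=sigma3 + 0.01)
        # detected occupancy tracks the generator's truth almost exactly
        assert occ.occupancy == pytest.approx(bound.mean(), abs=0.005)

    def test_aux_shell_labels(self):
        # bound ion 2.7 Å from the primary and 4.0 Å from the auxiliary
        table = AtomTable([14, 13, 9000], ["U", "U", "K"],
                          ["O4", "O4", "K"], ["O", "O", "K"])
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [0, 0, 6.06]        # auxiliary O4 of residue 13
        coords[0, 2] = [2.7, 0, 0]         # ion: 2.7 from primary
        coords[0, 1] = coords[0, 2] + [0, 0, 4.0]
        ens = Ensemble(table, coords)
        site = IonSite("s", REF, auxiliary=(AtomRef(13, "O4"),))
        occ = site_occupancy(ens, site)
        assert occ.occupancy == 1.0
        assert occ.aux_labels["13:O4"][0] == "outer"
        assert occ.aux_fractions["13:O4"]["outer"] == 1.0

    def test_unbound_ion_leaves_aux_none(self):
        table = AtomTable([14, 13, 9000], ["U", "U", "K"],
                          ["O4", "O4", "K"], ["O", "O", "K"])
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [0, 0, 3.0]
        coords[0, 2] = [20.0, 0, 0]
        ens = Ensemble(table, coords)
        occ = site_occupancy(ens, IonSite("s", REF,
                                          auxiliary=(AtomRef(13, "O4"),)))
        assert occ.occupancy == 0.0
        assert occ.aux_labels["13:O4"][0] == "none"


class TestResidence:
    def test_strict_episodes(self):
        res = residence_statistics([1, 1, 0, 1], dt=10.0)
        assert [(e.start, e.end, e.duration) for e in res.episodes] == \
            [(0, 1, 20.0), (3, 3, 10.0)]
        assert res.max_duration == 20.0
        assert res.mean_duration == 15.0

    def test_gap_absorption(self):
        res = residence_statistics([1, 1, 0, 1], dt=10.0, tolerance=1)
        assert [(e.start, e.end) for e in res.episodes] == [(0, 3)]
        assert res.max_duration == 40.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            residence_statistics([1, 0], dt=1.0, tolerance=-1)

    def test_geometric_dwell_mean_recovery(self):
        spec = IonSimSpec(p=0.5, mean_residence_ps=250, dt=10,
                          n_frames=50_000, seed=5)
        ens, bound = gen_ion_ensemble(spec)
        res = residence_statistics(bound, dt=10.0)
        assert res.mean_duration == pytest.approx(250.0, rel=0.10)

    def test_reversal_invariance_of_mean(self):
        rng = np.random.default_rng(1)
        occ = rng.random(500) < 0.6
        fwd = residence_statistics(occ, dt=2.0)
        rev = residence_statistics(occ[::-1], dt=2.0)
        assert fwd.mean_duration == pytest.approx(rev.mean_duration)
        assert fwd.max_duration == rev.max_duration

    def test_occupancy_episode_conservation(self):
        rng = np.random.default_rng(2)
        occ = rng.random(1000) < 0.3
        res = residence_statistics(occ, dt=1.0)
        frames_in_episodes = sum(e.end - e.start + 1 for e in res.episodes)
        assert frames_in_episodes == int(occ.sum())


class TestDensityMaxima:
    def test_single_fixed_ion_single_region(self):
        pts = np.tile([[3.0, -1.0, 2.0]], (40, 1))
        ens = _ion_ensemble(pts, aligned=True)
        regions = density_maxima(ens, "K", spacing=0.5, k=5)
        assert len(regions) == 1
        np.testing.assert_allclose(regions[0].centroid, [3.0, -1.0, 2.0],
                                   atol=0.5)
        assert regions[0].occupancy == pytest.approx(1.0)

    def test_two_sites_ranked_by_occupancy(self):
        rng = np.random.default_rng(4)
        n = 1000
        at_a = rng.random(n) < 0.7
        pts = np.where(at_a[:, None], [0.0, 0.0, 0.0],
                       [8.0, 0.0, 0.0]) + rng.normal(0, 0.2, (n, 3))
        ens = _ion_ensemble(pts[:, None, :], aligned=True)
        regions = density_maxima(ens, "K", spacing=0.5, k=2)
        assert regions[0].occupancy > regions[1].occupancy
        np.testing.assert_allclose(regions[0].centroid, [0, 0, 0], atol=0.5)
        np.testing.assert_allclose(regions[1].centroid, [8, 0, 0], atol=0.5)

    def test_top_k_count(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [6, 6, 0],
                            [3, 3, 5], [12, 12, 12], [-9, 4, 2]], dtype=float)
        which = rng.integers(0, len(centers), size=3000)
        pts = centers[which] + rng.normal(0, 0.2, (3000, 3))
        ens = _ion_ensemble(pts[:, None, :], aligned=True)
        assert len(density_maxima(ens, "K", spacing=0.5, k=5)) == 5

    def test_unaligned_ensemble_rejected(self):
        ens = _ion_ensemble(np.zeros((5, 1, 3)), aligned=False)
        with pytest.raises(ValueError, match="superpose"):
            density_maxima(ens, "K")
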