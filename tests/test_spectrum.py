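"""Binning, normalization, and spectrum assembly from fragment distributions."""

import numpy as np
import pytest

import fragspec as fs


class TestBinning:
    def test_nearest_center_assignment(self):
        spec = fs.bin_peaks([(42.49, 0.7), (42.51, 0.3)], resolution=1.0)
        assert spec.as_dict() == {42: pytest.approx(0.7), 43: pytest.approx(0.3)}

    def test_same_bin_summation(self):
        spec = fs.bin_peaks([(41.9, 0.5), (42.1, 0.5)], resolution=1.0)
        assert spec.as_dict() == {42: pytest.approx(1.0)}

    def test_fine_resolution_separates(self):
        spec = fs.bin_peaks([(41.9, 0.5), (42.1, 0.5)], resolution=0.1)
        assert len(spec) == 2
        assert spec.mz == pytest.approx([41.9, 42.1])

    def test_halfway_tie_goes_up(self):
        assert fs.bin_peaks([(42.5, 1.0)], 1.0).as_dict() == {43: 1.0}
        assert fs.bin_peaks([(0.05, 1.0)], 0.1).as_dict() == {1: 1.0}

    @pytest.mark.parametrize("resolution", [1.0, 0.5, 0.1])
    def test_conserves_total_intensity(self, resolution):
        rng = np.random.default_rng(11)
        peaks = [(float(m), float(i)) for m, i in zip(rng.random(200) * 300, rng.random(200))]
        spec = fs.bin_peaks(peaks, resolution)
        assert spec.total_intensity() == pytest.approx(sum(i for _, i in peaks), abs=1e-12)


class TestNormalize:
    def test_three_four_five(self):
        spec = fs.Spectrum(np.array([42, 43]), np.array([3.0, 4.0]))
        out = fs.normalize(spec, "L2")
        assert out.intensity == pytest.approx([0.6, 0.8])

    def test_idempotent(self):
        spec = fs.normalize(fs.Spectrum(np.array([1, 9]), np.array([2.0, 5.0])), "L2")
        again = fs.normalize(spec, "L2")
        assert np.allclose(spec.intensity, again.intensity, atol=1e-12)

    def test_single_peak(self):
        out = fs.normalize(fs.Spectrum(np.array([50]), np.array([7.0])), "L2")
        assert out.as_dict() == {50: pytest.approx(1.0)}

    def test_degenerate_error(self):
        with pytest.raises(fs.DegenerateSpectrumError):
            fs.normalize(fs.Spectrum(np.array([5]), np.array([0.0])), "L2")


class TestAssemble:
    def test_single_fragment_is_its_distribution(self):
        f = fs.Formula.from_string("C2H5")
        probs = fs.FragmentProbabilities([(f, 1.0)])
        spec = fs.assemble_spectrum(probs, resolution=1.0, prune_below=0)
        direct = fs.normalize(
            fs.bin_peaks(fs.isotope_distribution(f, 0), 1.0), "L2"
        )
        assert spec.as_dict() == pytest.approx(direct.as_dict())

    def test_disjoint_mixture_conserves_mass(self):
        probs = fs.FragmentProbabilities(
            [(fs.Formula.from_string("CH3"), 0.5), (fs.Formula.from_string("C6Cl2"), 0.5)]
        )
        raw = fs.assemble_spectrum(probs, resolution=1.0, prune_below=0, normalization=None)
        assert raw.total_intensity() == pytest.approx(1.0, abs=1e-9)

    def test_linearity_in_probability_vector(self):
        f1, f2 = fs.Formula.from_string("CH4"), fs.Formula.from_string("C2H2O")
        mix = fs.assemble_spectrum(
            fs.FragmentProbabilities([(f1, 0.3), (f2, 0.7)]),
            prune_below=0, normalization=None,
        )
        a = fs.assemble_spectrum(fs.FragmentProbabilities([(f1, 1.0)]), prune_below=0, normalization=None)
        b = fs.assemble_spectrum(fs.FragmentProbabilities([(f2, 1.0)]), prune_below=0, normalization=None)
        expect = {}
        for k, v in a.as_dict().items():
            expect[k] = expect.get(k, 0) + 0.3 * v
        for k, v in b.as_dict().items():
            expect[k] = expect.get(k, 0) + 0.7 * v
        assert mix.as_dict() == pytest.approx(expect, abs=1e-12)

    def test_uniform_glucose_deterministic(self):
        fset = [f for f in fs.enumerate_subformulae(fs.Formula.from_string("C6H12O6"))
                if not f.is_empty()]
        probs = fs.FragmentProbabilities([(f, 1.0 / len(fset)) for f in fset])
        s1 = fs.assemble_spectrum(probs, prune_below=0)
        s2 = fs.assemble_spectrum(probs, prune_below=0)
        assert (s1.bin_index == s2.bin_index).all()
        assert (s1.intensity == s2.intensity).all()
        assert s1.l2_norm() == pytest.approx(1.0, abs=1e-12)

    def test_subset_keys_resolve_through_molecule(self, ethane):
        subs = sorted(fs.break_bonds(ethane, 1))[:4]
        probs = fs.FragmentProbabilities([(s, 0.25) for s in subs])
        spec = fs.assemble_spectrum(probs, mol=ethane, prune_below=0)
        assert spec.l2_norm() == pytest.approx(1.0, abs=1e-12)

    def test_empty_distribution_error(self):
        with pytest.raises(fs.DegenerateSpectrumError):
            fs.assemble_spectrum(fs.FragmentProbabilities([]))


class TestRebin:
    def test_fine_to_coarse_matches_direct(self):
        d = fs.isotope_distribution(fs.Formula.from_string("C6H9NO2"), 0)
        fine = fs.bin_peaks(d, 0.1)
        coarse = fs.bin_peaks(d, 1.0)
        re = fs.rebin(fine, 1.0)
        assert re.as_dict() == pytest.approx(coarse.as_dict(), abs=1e-12)
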