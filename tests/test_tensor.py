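import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from breastdti.exceptions import MissingShellError
from breastdti.gradients import make_gradient_scheme
from breastdti.simulate import PhantomConfig, PhantomRegion, simulate_dwi_phantom
from breastdti.tensor import (
    DiffusionTensorModel,
    DWIVolume,
    combined_dwi,
    fa_from_eigenvalues,
    fit_tensor,
    scalar_maps,
)


def _phantom(evals, scheme, direction=(1.0, 0.0, 0.0), **kwargs):
    cfg = PhantomConfig(
        grid_shape=(3, 3, 2),
        regions=(PhantomRegion(((0, 3), (0, 3), (0, 2)), evals, direction),),
        **kwargs,
    )
    return simulate_dwi_phantom(cfg, scheme)


def test_noiseless_signal_closed_form(scheme):
    """Isotropic D = 1.5e-3 at b=800 attenuates S0=1000 to 1000*exp(-1.2)."""
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    b800 = dwi.data[..., scheme.shell_mask(800.0)]
    assert np.allclose(b800, 1000.0 * np.exp(-1.2), rtol=1e-12)
    assert np.allclose(dwi.data[..., scheme.b0_mask], 1000.0)


def test_eigenvalue_roundtrip_recovery(scheme):
    evals = (2.20e-3, 2.00e-3, 1.80e-3)
    dwi, truth = _phantom(evals, scheme, direction=(0.36, 0.48, 0.8))
    tmap = fit_tensor(dwi)
    rel = np.abs(tmap.evals - truth.evals) / truth.evals
    assert rel.max() <= 1e-9


def test_isotropic_fit_has_zero_fa(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    maps = scalar_maps(fit_tensor(dwi))
    assert np.abs(maps.fa).max() <= 1e-9


def test_rotational_invariance(scheme, rng):
    """Rotating tensor and gradients together leaves eigenvalues unchanged."""
    from scipy.spatial.transform import Rotation

    evals = (1.8e-3, 1.2e-3, 0.7e-3)
    R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    dwi, _ = _phantom(evals, scheme, direction=(1, 0, 0))
    rot_scheme = type(scheme)(scheme.bvals, scheme.bvecs @ R.T)
    dwi_rot, _ = _phantom(evals, rot_scheme, direction=tuple(R @ np.array([1.0, 0, 0])))
    ev = fit_tensor(dwi).evals
    ev_rot = fit_tensor(dwi_rot).evals
    assert np.abs(ev - ev_rot).max() <= 1e-9 * ev.max()


@pytest.mark.parametrize(
    "evals, adc_2dp, fa_2dp",
    [
        ((1.27, 1.11, 0.87), None, 0.18),
        ((2.20, 2.00, 1.80), 2.00, 0.10),
        ((1.83, 1.47, 1.11), 1.47, None),
        ((2.13, 1.58, 0.97), 1.56, None),
    ],
)
def test_scalar_values_match_published_lesion_examples(evals, adc_2dp, fa_2dp):
    """ADC and FA from reported lesion eigenvalue triples (units 1e-3 mm^2/s)."""
    maps = scalar_maps(np.array(evals) * 1e-3)
    if adc_2dp is not None:
        assert round(float(maps.adc) * 1e3, 2) == adc_2dp
    if fa_2dp is not None:
        assert round(float(maps.fa), 2) == fa_2dp


def test_fa_of_2_1_1_triple():
    assert abs(fa_from_eigenvalues(np.array([2.0, 1.0, 1.0])) - 0.4082) <= 1e-4


def test_degenerate_triples():
    maps = scalar_maps(np.array([1.3, 1.3, 1.3]))
    assert float(maps.fa) == 0.0
    assert float(maps.lambda_diff) == 0.0
    assert float(maps.axial) == float(maps.radial) == float(maps.adc) == 1.3
    assert float(fa_from_eigenvalues(np.zeros(3))) == 0.0


@given(
    st.lists(st.floats(min_value=1e-5, max_value=3e-3), min_size=3, max_size=3)
)
def test_scalar_map_identities(lams):
    """ADC == (axial + 2*radial)/3 and FA in [0,1] for any eigenvalue triple."""
    maps = scalar_maps(np.array(lams))
    assert np.isclose(maps.adc, (maps.axial + 2 * maps.radial) / 3, rtol=1e-12)
    assert 0.0 <= float(maps.fa) <= 1.0
    assert float(maps.lambda_diff) >= 0.0


def test_fa_bounded_on_noisy_data(scheme):
    dwi, _ = _phantom((1.6e-3, 1.1e-3, 0.9e-3), scheme, noise_sigma=60.0, seed=5)
    tmap = fit_tensor(dwi)
    maps = scalar_maps(tmap)
    fit = tmap.mask
    assert np.all((maps.fa[fit] >= 0) & (maps.fa[fit] <= 1))
    assert np.all(tmap.evals[fit] >= 0)


def test_nonpositive_signals_excluded(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    dwi.data[1, 1, 0, 3] = 0.0
    tmap = fit_tensor(dwi)
    assert tmap.excluded[1, 1, 0]
    assert not tmap.mask[1, 1, 0]
    assert tmap.mask.sum() == tmap.mask.size - 1


def test_empty_mask_yields_empty_map(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    tmap = fit_tensor(dwi, mask=np.zeros(dwi.grid_shape, dtype=bool))
    assert not tmap.mask.any()


def test_weighted_fit_matches_ols_noiseless(scheme):
    evals = (2.0e-3, 1.5e-3, 1.0e-3)
    dwi, truth = _phantom(evals, scheme, direction=(0.6, 0.8, 0.0))
    ols = fit_tensor(dwi, weighted=False).evals
    wls = fit_tensor(dwi, weighted=True).evals
    assert np.abs(ols - wls).max() <= 1e-12


def test_combined_dwi_geometric_mean_identity():
    """Two directions with signals 100 and 400 combine to 200."""
    bvals = np.array([0.0, 800.0, 800.0])
    bvecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    from breastdti.gradients import GradientScheme

    scheme3 = GradientScheme(bvals, bvecs)
    data = np.zeros((1, 1, 1, 3))
    data[..., 0] = 1000.0
    data[..., 1] = 100.0
    data[..., 2] = 400.0
    dwi = DWIVolume(data, scheme3)
    assert combined_dwi(dwi, 800.0)[0, 0, 0] == pytest.approx(200.0)


def test_combined_dwi_equals_adc_attenuation_on_balanced_scheme(scheme):
    """On a balanced scheme the geometric mean equals S0*exp(-b*ADC)."""
    dwi, truth = _phantom((2.2e-3, 1.7e-3, 0.9e-3), scheme, direction=(0.0, 0.6, 0.8))
    adc = truth.evals.mean(axis=-1)
    expected = 1000.0 * np.exp(-800.0 * adc)
    got = combined_dwi(dwi, 800.0)
    assert np.abs(got / expected - 1).max() <= 1e-9


def test_combined_dwi_single_direction_identity(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    keep = scheme.b0_mask | (np.arange(13) == 1)
    from breastdti.gradients import GradientScheme

    sub = GradientScheme(scheme.bvals[keep], scheme.bvecs[keep])
    dwi1 = DWIVolume(dwi.data[..., keep], sub)
    got = combined_dwi(dwi1, scheme.bvals[1])
    assert np.array_equal(got, dwi.data[..., 1])


def test_combined_dwi_missing_shell_raises(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    with pytest.raises(MissingShellError):
        combined_dwi(dwi, 600.0)


def test_combined_dwi_zero_voxel_maps_to_zero(scheme):
    dwi, _ = _phantom((1.5e-3, 1.5e-3, 1.5e-3), scheme)
    dwi.data[0, 0, 0, scheme.shell_mask(800.0)] = [0, 10, 10, 10, 10, 10]
    assert combined_dwi(dwi, 800.0)[0, 0, 0] == 0.0


def test_eigenvalue_error_monotone_in_noise():
    """Median eigenvalue error does not decrease as noise grows."""
    scheme = make_gradient_scheme()
    errs = []
    for i, sigma in enumerate((0.0, 10.0, 20.0, 40.0)):
        cfg = PhantomConfig(
            grid_shape=(200, 1, 1),
            regions=(
                PhantomRegion(((0, 200), (0, 1), (0, 1)), (1.8e-3, 1.3e-3, 0.9e-3),
                              (0.48, 0.6, 0.64)),
            ),
            noise_sigma=sigma,
            seed=42 + i,
        )
        dwi, truth = simulate_dwi_phantom(cfg, scheme)
        tmap = fit_tensor(dwi)
        err = np.abs(tmap.evals[tmap.mask] - truth.evals[tmap.mask])
        errs.append(np.median(err))
    assert all(a <= b + 1e-15 for a, b in zip(errs, errs[1:]))


def test_model_results_interface(scheme):
    dwi, _ = _phantom((2.0e-3, 1.5e-3, 1.0e-3), scheme)
    res = DiffusionTensorModel(dwi).fit()
    assert res.scalar_maps.adc.shape == dwi.grid_shape
    text = res.summary()
    assert "voxels fitted" in text and "mean ADC" in text
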