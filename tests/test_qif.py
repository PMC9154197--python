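"""QIF spiking network: heterogeneity sampling, simulation, rate binning."""

import numpy as np
import pytest

from pingctc import (ModelParams, QIFParams, empirical_rate,
                     sample_lorentzian, simulate_qif)
from pingctc.forcing import ForcingSpec, VonMisesInput
from pingctc.qif import SpikeRaster, step_protocol_comparison


def test_deterministic_quantiles_small_case():
    # closed-form tan quantiles: for n=3, tan(+-pi/4) = +-1
    eta = sample_lorentzian(3, center=-5.0, half_width=1.0)
    np.testing.assert_allclose(eta, [-6.0, -5.0, -4.0], atol=1e-12)


@pytest.mark.parametrize("n", [5, 50, 501])
def test_deterministic_quantiles_median_is_center(n):
    eta = sample_lorentzian(n, center=-5.0, half_width=1.0)
    assert np.median(eta) == pytest.approx(-5.0, abs=1e-12)


def test_random_draws_match_cauchy_cdf():
    eta = sample_lorentzian(100_000, center=-5.0, half_width=1.0,
                            mode="random", seed=42)
    # KS distance against the arctan CDF
    x = np.sort(eta)
    cdf = 0.5 + np.arctan(x + 5.0) / np.pi
    emp = (np.arange(len(x)) + 0.5) / len(x)
    assert np.max(np.abs(cdf - emp)) < 0.01


def test_no_spikes_without_drive():
    m = ModelParams(eta_e=-50.0, eta_i=-50.0, Ie_ext_bar=0.0)
    qp = QIFParams(model=m, N_e=50, N_i=50)
    raster, _ = simulate_qif(qp, t_end=20.0, dt=1e-3)
    assert len(raster.times) == 0


def test_refractory_floor_on_interspike_intervals():
    qp = QIFParams(model=ModelParams(), N_e=200, N_i=200)
    raster, _ = simulate_qif(qp, t_end=60.0, dt=1e-3)
    tref = qp.T_ref_e  # 2*8/500 = 0.032 ms
    assert tref == pytest.approx(0.032)
    for pop in ("e", "i"):
        sub = raster.population(pop)
        for nid in np.unique(sub.neuron_ids)[:50]:
            isi = np.diff(sub.times[sub.neuron_ids == nid])
            if isi.size:
                assert isi.min() >= tref - 1e-9


def test_seeded_runs_are_identical():
    qp = QIFParams(model=ModelParams(), N_e=300, N_i=300,
                   eta_mode="random", seed=11)
    r1, _ = simulate_qif(qp, t_end=40.0, dt=1e-3)
    r2, _ = simulate_qif(qp, t_end=40.0, dt=1e-3)
    np.testing.assert_array_equal(r1.times, r2.times)
    np.testing.assert_array_equal(r1.neuron_ids, r2.neuron_ids)


def test_empirical_rate_single_spike_and_conservation():
    raster = SpikeRaster(times=np.array([0.1]), neuron_ids=np.array([0]),
                         N_e=1, N_i=0, t_end=1.0)
    trace = empirical_rate(raster, bin_width=0.08)
    assert trace.rate.max() == pytest.approx(1.0 / 0.08)
    assert trace.total_spikes() == pytest.approx(1.0)


def test_empty_raster_gives_zero_trace():
    raster = SpikeRaster(times=np.empty(0), neuron_ids=np.empty(0, int),
                         N_e=10, N_i=10, t_end=5.0)
    trace = empirical_rate(raster, bin_width=0.1)
    assert np.all(trace.rate == 0.0)


def test_spike_count_conserved_in_binning():
    qp = QIFParams(model=ModelParams(), N_e=300, N_i=300)
    raster, _ = simulate_qif(qp, t_end=50.0, dt=1e-3)
    tr_e = empirical_rate(raster, 0.08, "e")
    tr_i = empirical_rate(raster, 0.08, "i")
    assert tr_e.total_spikes() + tr_i.total_spikes() == pytest.approx(
        len(raster.times))


def test_mean_field_agreement_improves_with_network_size():
    """The mean-field is exact in the thermodynamic limit: the rate RMSE
    against it must decrease as N grows."""
    Tstar = 24.235
    errs = []
    for N in (500, 2000, 5000):
        df = step_protocol_comparison(ModelParams(), N=N, dt=1e-3,
                                      T=Tstar / 2, seed=5)
        seg = df[df.t > 50.0]
        errs.append(float(np.sqrt(np.mean((seg.qif_r_e - seg.mf_r_e) ** 2))))
    assert errs[0] > errs[1] > errs[2]


def test_raster_roundtrip_preserves_spikes(tmp_path):
    qp = QIFParams(model=ModelParams(), N_e=100, N_i=100)
    raster, _ = simulate_qif(qp, t_end=30.0, dt=1e-3)
    prefix = str(tmp_path / "run")
    raster.write(prefix)
    back = SpikeRaster.read(prefix, t_end=30.0)
    assert len(back.times) == len(raster.times)
    assert back.N_e == 100 and back.N_i == 100
    np.testing.assert_allclose(back.times, raster.times, atol=1e-6)
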