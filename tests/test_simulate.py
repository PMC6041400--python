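import numpy as np
import pytest

from optonet import (
    SpikeRaster,
    SyntheticNetwork,
    make_network,
    make_protocol,
    render_movie,
    simulate_spikes,
    spikes_to_calcium,
)


def _line_network(adjacency, transmission_prob=1.0, pmax=0.0):
    n = len(adjacency)
    positions = [[100.0 + 120.0 * i, 100.0] for i in range(n)]
    return SyntheticNetwork(
        positions=positions,
        soma_radius=15.0,
        adjacency_true=np.asarray(adjacency),
        transmission_prob=transmission_prob,
        synaptic_delay=0.05,
        excitability_half=12.0,
        excitability_slope=4.0,
        excitability_pmax=pmax,
        fov=(832.0, 702.0),
    )


class TestMakeNetwork:
    def test_zero_connection_rule_gives_empty_graph(self):
        net = make_network(n_neurons=10, connection_rule=0.0, seed=0)
        assert net.adjacency_true.sum() == 0

    def test_full_connection_rule_gives_all_pairs(self):
        net = make_network(n_neurons=5, connection_rule=1.0, seed=0)
        assert net.adjacency_true.sum() == 5 * 4  # n(n-1) directed entries
        assert np.all(np.diag(net.adjacency_true) == 0)

    def test_same_seed_reproduces_network(self):
        a = make_network(n_neurons=30, connection_rule=0.2, seed=42)
        b = make_network(n_neurons=30, connection_rule=0.2, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.adjacency_true, b.adjacency_true)

    def test_somata_do_not_overlap(self):
        net = make_network(n_neurons=60, soma_radius=15.0, seed=1)
        d = np.hypot(*(net.positions[:, None] - net.positions[None, :]).transpose(2, 0, 1))
        iu = np.triu_indices(60, k=1)
        assert d[iu].min() >= 30.0

    def test_overfull_field_raises(self):
        with pytest.raises(RuntimeError, match="could not place"):
            make_network(n_neurons=100, fov=(200.0, 200.0), soma_radius=15.0, seed=0)


class TestSimulateSpikes:
    def test_no_transmission_confines_spikes_to_mask(self):
        protocol = make_protocol(mask_center=(250.0, 250.0), mask_radius=300.0)
        net = make_network(
            n_neurons=40, transmission_prob=0.0, connection_rule=1.0, seed=3,
            excitability=(12.0, 4.0, 1.0),
        )
        raster = simulate_spikes(net, protocol, seed=4)
        outside = ~protocol.in_mask(net.positions)
        assert all(raster.spike_times[i].size == 0 for i in np.flatnonzero(outside))
        inside_counts = raster.counts()[protocol.in_mask(net.positions)]
        assert inside_counts.sum() > 0

    def test_dark_protocol_yields_empty_raster(self):
        protocol = make_protocol(n_pulses=1, intensity_step=7.0)  # single pulse at 0
        net = make_network(n_neurons=10, seed=0)
        raster = simulate_spikes(net, protocol, seed=1)
        assert raster.counts().sum() == 0

    def test_chain_propagates_at_multiples_of_delay(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        net = _line_network(adj)
        protocol = make_protocol()
        raster = simulate_spikes(net, protocol, seed=0, extra_spikes=[(0, 1.0)])
        assert raster.spike_times[0].tolist() == [1.0]
        assert raster.spike_times[1].tolist() == [pytest.approx(1.05)]
        assert raster.spike_times[2].tolist() == [pytest.approx(1.10)]

    def test_refractory_blocks_reverberation(self):
        # fully bidirectional pair with certain transmission: each neuron
        # fires once per wave, not in an endless loop
        adj = np.array([[0, 1], [1, 0]])
        net = _line_network(adj)
        protocol = make_protocol()
        raster = simulate_spikes(net, protocol, seed=0, extra_spikes=[(0, 1.0)], refractory=0.4)
        assert raster.spike_times[0].size == 1
        assert raster.spike_times[1].size == 1

    def test_same_seed_reproduces_raster(self):
        protocol = make_protocol()
        net = make_network(n_neurons=25, seed=6)
        a = simulate_spikes(net, protocol, seed=7)
        b = simulate_spikes(net, protocol, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.spike_times, b.spike_times))

    def test_mean_response_nondecreasing_in_irradiance(self):
        # Monte-Carlo check of the saturating excitability curve
        net = make_network(n_neurons=1, connection_rule=0.0, seed=0)
        protocol = make_protocol()
        rng_seeds = range(400)
        per_pulse = np.zeros(protocol.n_pulses)
        for s in rng_seeds:
            raster = simulate_spikes(net, protocol, seed=s)
            for t in raster.spike_times[0]:
                per_pulse[np.flatnonzero(np.isclose(protocol.pulse_onsets, t))[0]] += 1
        rates = per_pulse / len(rng_seeds)
        probs = [net.firing_probability(i)[0] for i in protocol.pulse_intensities]
        assert np.all(np.diff(probs) >= 0)
        # observed rates track the analytic curve within Monte-Carlo error
        assert np.allclose(rates, probs, atol=0.08)


class TestSpikesToCalcium:
    def test_empty_raster_gives_zero_traces(self):
        raster = SpikeRaster([np.array([])], duration=10.0)
        ca = spikes_to_calcium(raster, frame_rate=10.0)
        assert np.all(ca.data == 0)

    def test_single_spike_peaks_at_unit_amplitude(self):
        raster = SpikeRaster([np.array([1.0])], duration=30.0)
        ca = spikes_to_calcium(raster, amplitude_per_spike=0.8, frame_rate=100.0)
        assert ca.data.max() == pytest.approx(0.8, rel=1e-3)

    def test_trace_zero_before_first_spike(self):
        raster = SpikeRaster([np.array([5.0])], duration=20.0)
        ca = spikes_to_calcium(raster, frame_rate=10.0)
        assert np.all(ca.data[:50, 0] == 0)

    def test_separated_spikes_superpose_linearly(self):
        one = spikes_to_calcium(SpikeRaster([np.array([2.0])], 60.0), frame_rate=10.0)
        two = spikes_to_calcium(SpikeRaster([np.array([2.0, 30.0])], 60.0), frame_rate=10.0)
        peaks_two = sorted(
            [two.data[:300, 0].max(), two.data[300:, 0].max()]
        )
        assert peaks_two[1] == pytest.approx(peaks_two[0], rel=0.05)
        assert np.allclose(two.data[:250, 0], one.data[:250, 0])

    def test_requires_decay_slower_than_rise(self):
        raster = SpikeRaster([np.array([1.0])], duration=10.0)
        with pytest.raises(ValueError):
            spikes_to_calcium(raster, tau_rise=2.0, tau_decay=1.0)


class TestRenderMovie:
    def test_quiet_noiseless_movie_is_constant(self):
        net = make_network(n_neurons=3, seed=0)
        ca = spikes_to_calcium(SpikeRaster([np.array([])] * 3, 5.0), frame_rate=10.0)
        movie = render_movie(net, ca, bleach_tau=1e12, noise_sd=0.0, seed=0)
        assert np.all(movie.frames == movie.frames[0])

    def test_somata_rendered_at_planted_positions(self):
        net = make_network(n_neurons=5, seed=2)
        ca = spikes_to_calcium(SpikeRaster([np.array([])] * 5, 5.0), frame_rate=10.0)
        movie = render_movie(net, ca, noise_sd=0.0, seed=0)
        frame = movie.frames[0]
        for x, y in net.positions:
            r, c = int(round(y / movie.pixel_size)), int(round(x / movie.pixel_size))
            assert frame[r, c] > frame[0, 0]  # soma pixel brighter than background

    def test_bleaching_follows_exponential_decay(self):
        net = make_network(n_neurons=1, seed=0)
        ca = spikes_to_calcium(SpikeRaster([np.array([])], 60.0), frame_rate=10.0)
        movie = render_movie(net, ca, baseline_f0=100.0, background=0.0,
                             bleach_tau=30.0, noise_sd=0.0, seed=0)
        x, y = net.positions[0]
        r, c = int(round(y / movie.pixel_size)), int(round(x / movie.pixel_size))
        ratio = movie.frames[-1, r, c] / movie.frames[0, r, c]
        t_last = (movie.n_frames - 1) / movie.frame_rate
        assert ratio == pytest.approx(np.exp(-t_last / 30.0), rel=1e-3)

    def test_frame_count_and_determinism(self):
        net = make_network(n_neurons=4, seed=1)
        ca = spikes_to_calcium(SpikeRaster([np.array([1.0])] * 4, 10.0), frame_rate=10.0)
        a = render_movie(net, ca, seed=9)
        b = render_movie(net, ca, seed=9)
        assert a.n_frames == ca.n_frames
        assert np.array_equal(a.frames, b.frames)
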