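"""Binding model, selection sampling, read generation and qPCR simulation."""

import numpy as np
import pytest

from tdel.decode import count_reads
from tdel.errors import ConfigError
from tdel.qpcr import StandardCurve, ct_to_amount
from tdel.simulate import (
    BindingModel,
    capture_weight,
    capture_weights,
    generate_fastq,
    random_binding_model,
    simulate_capture,
    simulate_qpcr,
    simulate_selection,
)


def _model(mode="target", na=3, nb=2, nc=3, **kw):
    return BindingModel(
        w_a=np.linspace(0.5, 2.0, na),
        w_c=np.linspace(0.5, 2.0, nc),
        l_b=np.linspace(0.5, 1.5, nb),
        mode=mode,
        **kw,
    )


class TestCaptureWeight:
    def test_no_target_mode_is_background_only(self):
        model = _model("no_target", beta=1.5)
        for idx in [(0, 0, 0), (2, 1, 2)]:
            assert capture_weight(idx, model) == 1.5

    def test_zero_ligand_weights_reduce_to_background(self):
        model = BindingModel(w_a=[0.0], w_c=[0.0], l_b=[0.0], beta=2.0)
        assert capture_weight((0, 0, 0), model) == 2.0

    def test_multiplicative_form(self):
        model = BindingModel(w_a=[2.0], w_c=[3.0], l_b=[0.5], beta=1.0)
        assert capture_weight((0, 0, 0), model) == 4.0

    def test_no_ligand_mode_keeps_direct_linker_term(self):
        model = BindingModel(w_a=[2.0], w_c=[3.0], l_b=[0.5], beta=1.0,
                             mode="no_ligand", epsilon_direct=0.2)
        assert capture_weight((0, 0, 0), model) == pytest.approx(1.0 + 0.2 * 0.5)

    def test_dense_array_agrees_with_scalar(self):
        model = _model()
        dense = capture_weights(model)
        for idx in np.ndindex(model.shape):
            assert dense[idx] == pytest.approx(capture_weight(idx, model))

    def test_unknown_index_rejected(self):
        with pytest.raises(ConfigError):
            capture_weight((5, 0, 0), _model())


class TestSimulateSelection:
    def test_counts_conserved(self):
        truth = simulate_selection(np.ones((3, 2, 3)), _model(), pool_size=10_000, seed=1)
        assert truth.post_counts.sum() == 10_000
        assert truth.pre_counts.sum() == 10_000
        assert np.all(truth.post_counts >= 0)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_selection(np.ones((3, 2, 3)), _model(), 5_000, seed=3)
        b = simulate_selection(np.ones((3, 2, 3)), _model(), 5_000, seed=3)
        assert np.array_equal(a.post_counts, b.post_counts)

    def test_single_live_member_takes_all_counts(self):
        ab = np.zeros((3, 2, 3))
        ab[1, 1, 1] = 1.0
        truth = simulate_selection(ab, _model(), 500, seed=0)
        assert truth.post_counts[1, 1, 1] == 500

    def test_uniform_weights_give_uniform_counts_within_binomial_tails(self):
        # exact binomial tail oracle on a 50x10x50 uniform library: every
        # per-member count must fall inside the (1e-8, 1 - 1e-8) quantiles
        # of Binomial(N, 1/M)
        from scipy.stats import binom

        shape = (50, 10, 50)
        m = int(np.prod(shape))
        n = 10**5
        model = BindingModel(
            w_a=np.zeros(shape[0]), w_c=np.zeros(shape[2]), l_b=np.zeros(shape[1]), beta=1.0
        )
        truth = simulate_selection(np.ones(shape), model, n, seed=8)
        lo = binom.ppf(1e-8, n, 1.0 / m)
        hi = binom.isf(1e-8, n, 1.0 / m)
        assert truth.post_counts.min() >= lo
        assert truth.post_counts.max() <= hi

    def test_expected_count_monotone_in_weight(self):
        # analytic expectation, no sampling: raising one member's W never
        # lowers its expected post-count
        ab = np.ones((3, 2, 3))
        base = _model()
        w_lo = capture_weights(base)
        expected_lo = w_lo / w_lo.sum()
        boosted = BindingModel(
            w_a=base.w_a * np.array([1.0, 1.0, 2.0]),
            w_c=base.w_c, l_b=base.l_b, beta=base.beta,
        )
        w_hi = capture_weights(boosted)
        expected_hi = w_hi / w_hi.sum()
        assert expected_hi[2, 1, 2] >= expected_lo[2, 1, 2]

    def test_all_zero_abundance_rejected(self):
        with pytest.raises(ConfigError):
            simulate_selection(np.zeros((3, 2, 3)), _model(), 100, seed=0)


class TestGenerateFastq:
    def test_noiseless_round_trip(self, small_scheme, small_library):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, small_library.shape)
        reads = generate_fastq(counts, small_scheme, small_library, "target", 0.0, seed=1)
        table = count_reads(reads, small_scheme)
        for role in "ABC":
            axis = {"A": 0, "B": 1, "C": 2}[role]
            marg = counts.sum(axis=tuple(i for i in range(3) if i != axis))
            expected = {
                bb.id: int(k) for bb, k in zip(small_library.sub(role).members, marg) if k > 0
            }
            assert table.channel("target", role) == expected

    def test_read_conservation_per_channel(self, small_scheme, small_library):
        counts = {("A001", "B001", "C001"): 3, ("A002", "B002", "C002"): 2}
        reads = list(generate_fastq(counts, small_scheme, small_library, "pre", 0.0, seed=0))
        assert len(reads) == 15  # 5 pool copies x 3 channels
        per_channel = {}
        for name, _, _ in reads:
            channel = name.split(":")[1]
            per_channel[channel] = per_channel.get(channel, 0) + 1
        assert per_channel == {"A": 5, "B": 5, "C": 5}

    def test_error_rate_within_5_sigma_of_binomial(self, small_scheme, small_library):
        eps = 0.01
        counts = np.full(small_library.shape, 5)
        n_mismatch = 0
        n_bases = 0
        for name, seq, _ in generate_fastq(
            counts, small_scheme, small_library, "target", eps, seed=2
        ):
            sample, channel, src, _ = name.split(":")
            code = small_scheme.codebooks[channel].code_of(src)
            template = small_scheme.read_template(sample, channel, code)
            n_mismatch += sum(a != b for a, b in zip(seq, template))
            n_bases += len(seq)
        sigma = np.sqrt(n_bases * eps * (1 - eps))
        assert abs(n_mismatch - n_bases * eps) <= 5 * sigma

    def test_unknown_sample_rejected(self, small_scheme, small_library):
        with pytest.raises(ConfigError):
            list(generate_fastq(np.ones(small_library.shape, dtype=int),
                                small_scheme, small_library, "nope"))


class TestSimulateCapture:
    def test_total_yield_orders_target_above_controls(self):
        # absolute capture: ligand synergy > direct linker contact > background
        shape = (20, 8, 20)
        model = random_binding_model(shape, seed=3)
        pool = np.full(shape, 50)
        yields = {
            mode: simulate_capture(pool, model.with_mode(mode), seed=9).sum()
            for mode in ("target", "no_ligand", "no_target")
        }
        assert yields["target"] > yields["no_ligand"] > yields["no_target"]


class TestSimulateQpcr:
    curve = StandardCurve(slope=-3.3219, intercept=30.0)

    def test_noiseless_round_trip(self):
        amounts = {"b1": 10.0, "b2": 12345.0}
        ct = simulate_qpcr(amounts, self.curve, noise_sd=0.0)
        for row in ct.itertuples(index=False):
            assert ct_to_amount(row.ct, self.curve) == pytest.approx(
                amounts[row.code_id], rel=1e-9
            )

    def test_unit_amount_gives_intercept(self):
        ct = simulate_qpcr({"x": 1.0}, self.curve, noise_sd=0.0)
        assert ct["ct"].iloc[0] == pytest.approx(30.0)

    def test_tenfold_dilutions_spaced_by_slope(self):
        series = {f"d{i}": 10.0**i for i in range(6)}
        ct = simulate_qpcr(series, self.curve, noise_sd=0.0)
        spacing = -np.diff(ct["ct"].to_numpy())
        assert spacing == pytest.approx([3.3219] * 5)

    def test_nonpositive_amount_flagged_below_detection(self):
        ct = simulate_qpcr({"x": 0.0, "y": 5.0}, self.curve)
        assert bool(ct.loc[ct.code_id == "x", "below_detection"].iloc[0])
        assert not bool(ct.loc[ct.code_id == "y", "below_detection"].iloc[0])

    def test_deterministic_noise(self):
        a = simulate_qpcr({"x": 5.0}, self.curve, noise_sd=0.5, seed=4)
        b = simulate_qpcr({"x": 5.0}, self.curve, noise_sd=0.5, seed=4)
        assert a["ct"].iloc[0] == b["ct"].iloc[0]
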