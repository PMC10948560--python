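"""SVD embedding/extraction: transform identities, exact recovery, scaling
laws and segment locality."""

import numpy as np
import pytest

import teledermo as td
from teledermo import metrics, profile, watermark
from teledermo.errors import (CapacityError, ParameterError,
                              SideInfoMismatchError)

from conftest import random_dps


class TestTransforms:
    @pytest.mark.parametrize("domain", watermark.DOMAINS)
    def test_roundtrip(self, domain, carrier):
        coeffs, meta = watermark.forward_transform(carrier.samples, domain)
        back = watermark.inverse_transform(coeffs, meta)
        assert np.abs(back - carrier.samples).max() < 1e-9

    def test_time_is_identity(self, carrier):
        coeffs, _ = watermark.forward_transform(carrier.samples, "time")
        assert np.array_equal(coeffs, carrier.samples)

    def test_dct_parseval(self, carrier):
        coeffs, _ = watermark.forward_transform(carrier.samples, "dct")
        e_time = np.sum(carrier.samples**2)
        assert np.sum(coeffs**2) == pytest.approx(e_time, rel=1e-9)

    def test_dst_scaling_identity(self, carrier):
        # the DST pair is intentionally non-unitary: the forward matrix M
        # satisfies M M = ((n+1)/2) I, so applying it twice scales by that
        x = carrier.samples
        n = x.size
        once, meta = watermark.forward_transform(x, "dst")
        twice, _ = watermark.forward_transform(once, "dst")
        assert np.allclose(twice, (n + 1) / 2.0 * x, rtol=1e-8, atol=1e-8)

    def test_unknown_domain_rejected(self, carrier):
        with pytest.raises(ParameterError):
            watermark.forward_transform(carrier.samples, "dft")


class TestEmbed:
    def test_zero_payload_keeps_carrier(self, carrier, rng):
        dp = profile.DP(matrix=np.zeros((7, 7)), source_id="z")
        dm = profile.DMpDP(form="diagonal", n_dps=1, dp_order=["z"],
                           matrix=np.zeros((7, 7)))
        wm, _ = watermark.embed(carrier, dm,
                                watermark.EmbedConfig(domain="time",
                                                      alpha=0.5, beta=1.0))
        assert np.abs(wm.samples - carrier.samples).max() < 1e-9

    def test_vanishing_alpha_preserves_correlation(self, carrier, rng):
        dm = profile.assemble(random_dps(4, rng), "sequential")
        wm, _ = watermark.embed(
            carrier, dm, watermark.EmbedConfig(domain="dct", alpha=1e-8))
        assert metrics.correlation(carrier.samples,
                                   wm.samples) > 1 - 1e-6

    def test_capacity_exceeded_raises(self, rng):
        short = watermark.RPS(samples=td.generate_rps(500, seed=0))
        dm = profile.assemble(random_dps(12, rng), "diagonal")  # needs 7056
        with pytest.raises(CapacityError):
            watermark.embed(short, dm, watermark.EmbedConfig(domain="time"))

    def test_segment_locality(self, carrier, rng):
        """Coefficients outside the embedding segment are untouched."""
        dm = profile.assemble(random_dps(4, rng), "sequential")
        size = dm.matrix.size
        for domain in watermark.DOMAINS:
            cfg = watermark.EmbedConfig(domain=domain, alpha=0.5, beta=3.0)
            wm, _ = watermark.embed(carrier, dm, cfg)
            c0, _ = watermark.forward_transform(carrier.samples, domain)
            c1, _ = watermark.forward_transform(wm.samples, domain)
            assert np.abs(c1[size:] - c0[size:]).max() < 1e-9
            if domain == "time":
                assert np.array_equal(wm.samples[size:],
                                      carrier.samples[size:])

    def test_snr_non_increasing_in_alpha(self, carrier, rng):
        dm = profile.assemble(random_dps(4, rng), "sequential")
        snrs = []
        for alpha in (1e-3, 1e-2, 1e-1, 1.0):
            wm, _ = watermark.embed(
                carrier, dm, watermark.EmbedConfig(domain="dwt", alpha=alpha))
            snrs.append(metrics.snr(carrier.samples, wm.samples))
        assert all(a >= b - 1e-6 for a, b in zip(snrs, snrs[1:]))


class TestExtract:
    @pytest.mark.parametrize("form", profile.FORMS)
    @pytest.mark.parametrize("domain", watermark.DOMAINS)
    def test_clean_roundtrip(self, form, domain, carrier, rng):
        dm = profile.assemble(random_dps(4, rng), form)
        cfg = watermark.EmbedConfig(domain=domain, alpha=0.05, beta=2.0)
        wm, side = watermark.embed(carrier, dm, cfg)
        p_star, recovered = watermark.extract(wm, side)
        truth = dm.blocks if form == "horizontal" else dm.matrix
        fid = metrics.watermark_fidelity(truth, p_star)
        assert fid.max_abs_error < 1e-6
        assert np.abs(recovered.samples - carrier.samples).max() < 1e-6

    def test_alpha_linearity(self, carrier, rng):
        """Declaring alpha' = 2 alpha at extraction halves the payload."""
        dm = profile.assemble(random_dps(4, rng), "sequential")
        wm, side = watermark.embed(
            carrier, dm, watermark.EmbedConfig(domain="time", alpha=0.1))
        side.config.alpha *= 2.0
        p_star, _ = watermark.extract(wm, side)
        assert np.abs(p_star - dm.matrix / 2.0).max() < 1e-6

    def test_beta_improves_noisy_extraction(self, rng):
        """Paired over seeds: amplification beats beta=1 at +5 dB AWGN."""
        from teledermo import channel

        dm = profile.assemble(random_dps(48, rng), "sequential")
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            carrier = td.default_carrier(n_samples=22000, seed=700 + seed)
            ref = float(np.mean(carrier.samples**2))
            cws = {}
            for beta in (1.0, 1000.0):
                cfg = watermark.EmbedConfig(domain="dwt", alpha=1.0,
                                            beta=beta)
                wm, side = watermark.embed(carrier, dm, cfg)
                noisy = channel.awgn(wm.samples, channel.ChannelConfig(
                    snr_db=5.0, seed=seed, ref_power=ref))
                p_star, _ = watermark.extract(
                    watermark.WatermarkedRPS(noisy, 8000.0), side)
                cws[beta] = metrics.watermark_fidelity(dm.matrix,
                                                       p_star).c_w
            wins += cws[1000.0] > cws[1.0]
        assert wins >= 15  # sign test: one-sided binomial p < 0.02

    def test_length_mismatch_raises(self, carrier, rng):
        dm = profile.assemble(random_dps(2, rng), "diagonal")
        wm, side = watermark.embed(carrier, dm, watermark.EmbedConfig())
        with pytest.raises(SideInfoMismatchError):
            watermark.extract(
                watermark.WatermarkedRPS(wm.samples[:-5], 8000.0), side)

    def test_side_info_file_roundtrip(self, carrier, rng, tmp_path):
        dm = profile.assemble(random_dps(3, rng), "horizontal", spacing=25)
        cfg = watermark.EmbedConfig(domain="dst", alpha=0.01, spacing=25)
        wm, side = watermark.embed(carrier, dm, cfg)
        path = side.save(tmp_path / "side.npz")
        loaded = watermark.SideInfo.load(path)
        p_star, _ = watermark.extract(wm, loaded)
        fid = metrics.watermark_fidelity(dm.blocks, p_star)
        assert fid.max_abs_error < 1e-6

    def test_orthogonality_of_side_factors(self, carrier, rng):
        dm = profile.assemble(random_dps(4, rng), "sequential")
        _, side = watermark.embed(carrier, dm,
                                  watermark.EmbedConfig(domain="dct"))
        for u, v, s in zip(side.u_w, side.v_w, side.s):
            assert np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)
            assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)
            assert np.all(np.diff(s) <= 1e-12) and np.all(s >= 0)
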