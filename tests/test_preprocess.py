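"""Probe filtering and normalization chain contracts."""

import numpy as np
import pytest

from methtopo.annotation import ProbeAnnotation
from methtopo.containers import BetaMatrix, SignalMatrix
from methtopo.errors import ValidationError
from methtopo.preprocess import (BetaMixtureQuantileCorrector,
                                 adjust_color_bias, compute_beta, compute_m,
                                 correct_type2_bias, equalize_type_backgrounds,
                                 filter_probes, quantile_normalize_samples)

from conftest import run_chain


def make_annot(n, chrom="1", design="II", channel=None, snp=False):
    return [
        ProbeAnnotation(
            probe_id=f"cg{i}", chrom=chrom, pos=i + 1, design_type=design,
            color_channel=(channel or "none") if design == "I" else "none",
            is_snp_probe=snp,
        )
        for i in range(n)
    ]


def make_signals(rng, n_probes, n_samples, ids=None):
    ids = ids or [f"cg{i}" for i in range(n_probes)]
    return SignalMatrix(
        ids, [f"s{j}" for j in range(n_samples)],
        rng.uniform(100, 5000, (n_probes, n_samples)),
        rng.uniform(100, 5000, (n_probes, n_samples)),
        rng.uniform(0, 0.005, (n_probes, n_samples)),
    )


class TestFilterProbes:
    def test_planted_failures_snp_and_sex_probes_removed(self, rng):
        annot = make_annot(100)
        for i in (90, 91):
            annot[i] = ProbeAnnotation(f"cg{i}", "X", i + 1, "II")
        for i in (92, 93):
            annot[i] = ProbeAnnotation(f"cg{i}", "1", i + 1, "II", is_snp_probe=True)
        sig = make_signals(rng, 100, 10)
        sig.detection_p[94:97, :] = 0.5  # fails detection everywhere
        out = filter_probes(sig, annot)
        assert out.n_probes == 93
        assert set(out.probe_ids) == {f"cg{i}" for i in range(100)} - {
            "cg90", "cg91", "cg92", "cg93", "cg94", "cg95", "cg96"}

    def test_sex_chromosome_probe_removed_despite_perfect_detection(self, rng):
        annot = make_annot(10)
        annot[0] = ProbeAnnotation("cg0", "X", 1, "II")
        sig = make_signals(rng, 10, 4)
        sig.detection_p[:] = 0.0
        assert "cg0" not in filter_probes(sig, annot).probe_ids

    def test_all_probes_filtered_is_an_error(self, rng):
        sig = make_signals(rng, 5, 4)
        sig.detection_p[:] = 0.9
        with pytest.raises(ValidationError, match="all probes filtered"):
            filter_probes(sig, make_annot(5))


class TestColorBias:
    def _two_channel(self, rng, ratio=1.0):
        annot = (make_annot(30, design="I", channel="red")
                 + [ProbeAnnotation(f"cg{i}", "1", i + 1, "I", "green")
                    for i in range(30, 60)])
        sig = make_signals(rng, 60, 3)
        sig.meth[30:] *= ratio
        sig.unmeth[30:] *= ratio
        return annot, sig

    def test_identical_channels_unchanged(self, rng):
        annot, sig = self._two_channel(rng)
        sig.meth[30:] = sig.meth[:30]
        sig.unmeth[30:] = sig.unmeth[:30]
        out = adjust_color_bias(sig, annot)
        np.testing.assert_allclose(out.meth, sig.meth)

    def test_doubled_green_channel_medians_equalized(self, rng):
        annot, sig = self._two_channel(rng, ratio=2.0)
        out = adjust_color_bias(sig, annot)
        for j in range(3):
            med_r = np.median(np.concatenate([out.meth[:30, j], out.unmeth[:30, j]]))
            med_g = np.median(np.concatenate([out.meth[30:, j], out.unmeth[30:, j]]))
            assert med_r == pytest.approx(med_g, rel=1e-12)

    def test_within_channel_rank_order_preserved(self, rng):
        annot, sig = self._two_channel(rng, ratio=2.0)
        out = adjust_color_bias(sig, annot)
        for block in (slice(0, 30), slice(30, 60)):
            assert (np.argsort(out.meth[block, 0]) == np.argsort(sig.meth[block, 0])).all()


class TestQuantileNormalization:
    def test_identical_samples_unchanged(self, rng):
        sig = make_signals(rng, 40, 1)
        sig2 = SignalMatrix(sig.probe_ids, ["a", "b"],
                            np.tile(sig.meth, 2), np.tile(sig.unmeth, 2),
                            np.tile(sig.detection_p, 2))
        out = quantile_normalize_samples(sig2)
        np.testing.assert_allclose(out.meth, sig2.meth)

    def test_permuted_samples_share_sorted_vectors(self, rng):
        sig = make_signals(rng, 50, 1)
        perm = rng.permutation(50)
        sig2 = SignalMatrix(sig.probe_ids, ["a", "b"],
                            np.column_stack([sig.meth[:, 0], sig.meth[perm, 0]]),
                            np.column_stack([sig.unmeth[:, 0], sig.unmeth[perm, 0]]),
                            np.zeros((50, 2)))
        out = quantile_normalize_samples(sig2)
        np.testing.assert_allclose(np.sort(out.meth[:, 0]), np.sort(out.meth[:, 1]))

    def test_sorted_columns_equal_mean_of_order_statistics(self, rng):
        sig = make_signals(rng, 50, 4)
        ref = np.sort(sig.meth, axis=0).mean(axis=1)  # definitional oracle
        out = quantile_normalize_samples(sig)
        for j in range(4):
            np.testing.assert_allclose(np.sort(out.meth[:, j]), ref)


class TestBackgroundEqualization:
    def _mixed(self, rng, shift=0.0):
        annot = make_annot(50, design="I", channel="red") + [
            ProbeAnnotation(f"cg{i}", "1", i + 1, "II") for i in range(50, 100)]
        sig = make_signals(rng, 100, 3)
        sig.meth[:50] += shift
        sig.unmeth[:50] += shift
        return annot, sig

    def test_equal_backgrounds_near_identity(self, rng):
        annot, sig = self._mixed(rng)
        sig.meth[:50] = sig.meth[50:]
        sig.unmeth[:50] = sig.unmeth[50:]
        out = equalize_type_backgrounds(sig, annot)
        np.testing.assert_allclose(out.meth, sig.meth)

    def test_planted_type1_shift_removed(self, rng):
        annot, sig = self._mixed(rng, shift=500.0)
        out = equalize_type_backgrounds(sig, annot)
        for j in range(3):
            tot = out.meth[:, j] + out.unmeth[:, j]
            assert np.percentile(tot[:50], 5) == pytest.approx(
                np.percentile(tot[50:], 5), rel=1e-9)

    def test_output_never_negative(self, rng):
        annot, sig = self._mixed(rng, shift=5000.0)
        out = equalize_type_backgrounds(sig, annot)
        assert (out.meth >= 0).all() and (out.unmeth >= 0).all()


class TestBetaAndM:
    def test_closed_form_values(self):
        sig = SignalMatrix(["a", "b", "c"], ["s"],
                           [[0.0], [900.0], [300.0]],
                           [[0.0], [0.0], [100.0]],
                           [[0.0], [0.0], [0.0]])
        b = compute_beta(sig, offset=100.0)
        assert b.values[0, 0] == 0.0
        assert b.values[1, 0] == pytest.approx(0.9)
        m = compute_m(sig, alpha=100.0)
        assert m.values[2, 0] == pytest.approx(1.0)  # log2(400/200)
        assert m.values[0, 0] == pytest.approx(0.0)  # meth == unmeth

    def test_negative_intensity_floored_before_offset(self):
        sig = SignalMatrix(["a"], ["s"], [[-50.0]], [[100.0]], [[0.0]])
        m = compute_m(sig, alpha=100.0)
        assert m.values[0, 0] == pytest.approx(np.log2(100.0 / 200.0))

    def test_beta_monotone_in_meth_at_fixed_unmeth(self):
        meth = np.linspace(0, 5000, 20)[:, None]
        sig = SignalMatrix([f"p{i}" for i in range(20)], ["s"],
                           meth, np.full((20, 1), 800.0), np.zeros((20, 1)))
        b = compute_beta(sig).values[:, 0]
        assert (np.diff(b) > 0).all()

    def test_beta_and_m_order_agree_at_fixed_total(self):
        total = 4000.0
        meth = np.linspace(100, 3900, 15)[:, None]
        sig = SignalMatrix([f"p{i}" for i in range(15)], ["s"],
                           meth, total - meth, np.zeros((15, 1)))
        b = compute_beta(sig).values[:, 0]
        m = compute_m(sig).values[:, 0]
        assert (np.argsort(b) == np.argsort(m)).all()


class TestTypeTwoCorrection:
    def _annot(self, n1, n2):
        return (make_annot(n1, design="I", channel="red")
                + [ProbeAnnotation(f"cg{i}", "1", i + 1, "II")
                   for i in range(n1, n1 + n2)])

    def _betas(self, values):
        values = np.asarray(values, dtype=float)[:, None]
        return BetaMatrix([f"cg{i}" for i in range(len(values))], ["s"], values)

    def test_equal_distributions_identity(self, rng):
        v1 = np.concatenate([rng.uniform(0.0, 0.19, 40), rng.uniform(0.2, 0.8, 40),
                             rng.uniform(0.81, 1.0, 40)])
        betas = self._betas(np.concatenate([v1, v1]))
        out = correct_type2_bias(betas, self._annot(120, 120))
        assert np.abs(out.values - betas.values).max() < 1e-6

    def test_planted_compression_restores_state_medians(self, rng):
        v1 = np.clip(rng.beta(0.4, 0.4, 400), 1e-3, 1 - 1e-3)
        v2 = 0.5 + (v1 - 0.5) * 0.9  # compressed type-II copy
        betas = self._betas(np.concatenate([v1, v2]))
        out = correct_type2_bias(betas, self._annot(400, 400))
        c = out.values[400:, 0]
        for state in ((lambda v: v < 0.2), (lambda v: (v >= 0.2) & (v <= 0.8)),
                      (lambda v: v > 0.8)):
            m1, m2 = state(v1), state(c)
            if m1.sum() >= 10 and m2.sum() >= 10:
                assert abs(np.median(v1[m1]) - np.median(c[m2])) < 0.01

    def test_output_stays_in_unit_interval(self, rng):
        v = rng.uniform(0, 1, 300)
        betas = self._betas(v)
        out = correct_type2_bias(betas, self._annot(150, 150))
        assert (out.values >= 0).all() and (out.values <= 1).all()

    def test_sparse_state_passes_through_with_warning(self, rng):
        v1 = rng.uniform(0.3, 0.7, 50)  # no type-I probes in outer states
        v2 = np.concatenate([rng.uniform(0, 0.1, 10), rng.uniform(0.3, 0.7, 40)])
        betas = self._betas(np.concatenate([v1, v2]))
        with pytest.warns(UserWarning, match="passing through"):
            out = correct_type2_bias(betas, self._annot(50, 50))
        np.testing.assert_allclose(out.values[50:60, 0], v2[:10])


class TestIdempotence:
    """Each normalization step is a projection: applying it twice equals once."""

    def test_chain_steps_idempotent_on_normalized_data(self):
        from methtopo.preprocess import (ColorBiasAdjuster, QuantileNormalizer,
                                         TypeBackgroundEqualizer)
        from methtopo.synth import SimulationConfig, generate_cohort

        cohort = generate_cohort(SimulationConfig(seed=9, n_genes=60))
        annot = cohort.manifest
        sig = filter_probes(cohort.signals, annot)
        for step in (ColorBiasAdjuster(annot), QuantileNormalizer(),
                     TypeBackgroundEqualizer(annot)):
            sig = step.transform(sig)
            again = step.transform(sig)
            np.testing.assert_allclose(again.meth, sig.meth, atol=1e-9)
            np.testing.assert_allclose(again.unmeth, sig.unmeth, atol=1e-9)
        betas = compute_beta(sig)
        corrector = BetaMixtureQuantileCorrector(annot)
        betas = corrector.transform(betas)
        again = corrector.transform(betas)
        np.testing.assert_allclose(again.values, betas.values, atol=1e-9)

    def test_chain_preserves_dimensions_after_filter(self, small_cohort):
        betas = run_chain(small_cohort)
        sig = filter_probes(small_cohort.signals, small_cohort.manifest)
        assert betas.values.shape == sig.meth.shape
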