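import numpy as np
import pytest

from hicforge import normalize as nz
from hicforge.digest import build_fend_table
from hicforge.matrix import SENT_NO_EXPECTED, SENT_NO_OBSERVED, ContactMatrix
from hicforge.pairfilter import PairRecord
from hicforge.simulate import SimConfig, simulate_genome, simulate_pairs


def _pair(chrom, pos1, pos2, fend1=0, fend2=1):
    return PairRecord(chrom, pos1, "+", fend1, chrom, pos2, "-", fend2)


class TestBinPairs:
    def test_single_off_diagonal_pair(self):
        O = nz.bin_pairs([_pair("c", 10_000, 50_000)], 40_000, 160_000, "c")
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 1
        assert np.array_equal(O.values, expected)

    def test_empty_input_zero_matrix(self):
        O = nz.bin_pairs([], 40_000, 160_000, "c")
        assert O.values.sum() == 0 and O.n_bins == 4

    def test_diagonal_counted_once(self):
        O = nz.bin_pairs([_pair("c", 120_001, 120_002)], 40_000, 160_000, "c")
        assert O.values[3, 3] == 1 and O.values.sum() == 1

    def test_beyond_chromosome_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            nz.bin_pairs([_pair("c", 10, 200_000)], 40_000, 160_000, "c")

    def test_off_diagonal_mass_conservation(self, rng):
        pairs = [
            _pair("c", int(rng.integers(0, 160_000)), int(rng.integers(0, 160_000)))
            for _ in range(200)
        ]
        O = nz.bin_pairs(pairs, 40_000, 160_000, "c")
        diag = np.trace(O.values)
        assert O.values.sum() - diag == 2 * (200 - diag)


class TestDistanceDecay:
    def test_constant_matrix_flat_profile(self):
        M = ContactMatrix("c", 1, np.full((6, 6), 3.0))
        prof = nz.estimate_distance_decay([M])
        assert np.allclose(prof.raw, 3.0)

    def test_reciprocal_distance_profile(self):
        n = 8
        i, j = np.indices((n, n))
        M = ContactMatrix("c", 1, 1.0 / (1.0 + np.abs(i - j)))
        prof = nz.estimate_distance_decay([M])
        assert np.allclose(prof.raw, 1.0 / (1.0 + np.arange(n)))

    def test_smoothed_profile_monotone(self, rng):
        M = ContactMatrix("c", 1, np.abs(rng.normal(5, 2, (10, 10))))
        M.values = (M.values + M.values.T) / 2
        prof = nz.estimate_distance_decay([M])
        assert np.all(np.diff(prof.smoothed[1:]) <= 1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no contacts"):
            nz.estimate_distance_decay([ContactMatrix("c", 1, np.zeros((4, 4)))])


class TestFeatureBinning:
    def _fends(self, small_dataset):
        return small_dataset[3]

    def test_uniform_lengths_quartiles(self, small_dataset):
        fends = self._fends(small_dataset)
        binning = nz.partition_fend_features(fends, n_groups=4)
        lab = binning.labels["length"]
        valid = lab[lab != nz.EXCLUDED_LABEL]
        counts = np.bincount(valid, minlength=4)
        # quantile groups are approximately balanced
        assert counts.min() > 0
        assert counts.max() <= 2 * counts.min() + len(fends) * 0.15

    def test_identical_values_collapse_to_one_group(self):
        from hicforge.digest import FragmentEnd

        fends = [FragmentEnd("c", i, "L", i, 100, 0.5, 0.5) for i in range(50)]
        binning = nz.partition_fend_features(fends, n_groups=4)
        assert binning.n_groups("gc") == 1

    def test_sentinel_gc_excluded(self):
        from hicforge.digest import FragmentEnd

        fends = [FragmentEnd("c", i, "L", i, 100 + i, 0.5, 0.5) for i in range(20)]
        fends.append(FragmentEnd("c", 99, "L", 99, 50, -1.0, 0.5))
        binning = nz.partition_fend_features(fends, n_groups=2)
        assert binning.labels["gc"][-1] == nz.EXCLUDED_LABEL
        assert binning.labels["length"][-1] == nz.EXCLUDED_LABEL


def _decay_dataset(seed, n_pairs=50_000, alpha=0.0, bias=None, n_chroms=2):
    cfg = SimConfig(
        seed=seed, n_chroms=n_chroms, chrom_length=200_000, sites_per_chrom=60,
        n_pairs=n_pairs, decay_exponent=alpha, bin_size=5_000,
        fend_bias=bias or {},
    )
    genome, _ = simulate_genome(cfg)
    fends = build_fend_table(genome, cfg.get_enzyme(), map_k=20, map_window=100)
    pairs, _ = simulate_pairs(cfg, fends)
    chroms = sorted(genome)
    lengths = {c: max(f.coord for f in fends if f.chrom == c) for c in chroms}
    obs = {
        c: nz.bin_pairs(
            [p for p in pairs if p.chrom1 == c == p.chrom2],
            cfg.bin_size, lengths[c], c,
        )
        for c in chroms
    }
    decay = nz.estimate_distance_decay(list(obs.values()))
    return cfg, fends, pairs, obs, decay


class TestLearnCorrections:
    def test_single_group_gives_identity(self, small_dataset):
        cfg, genome, _, fends = small_dataset
        pairs, _ = simulate_pairs(cfg, fends)
        chroms = sorted(genome)
        lengths = {c: max(f.coord for f in fends if f.chrom == c) for c in chroms}
        obs = [
            nz.bin_pairs([p for p in pairs if p.chrom1 == c == p.chrom2],
                         cfg.bin_size, lengths[c], c)
            for c in chroms
        ]
        decay = nz.estimate_distance_decay(obs)
        binning = nz.partition_fend_features(fends, n_groups=1)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg.bin_size, min_distance=20_000
        )
        for f in nz.FEATURES:
            assert np.allclose(model.tables[f], 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_gc_bias_recovered(self, seed):
        """A planted 2-group GC bias with 4:1 per-FEND effect ratio is
        recovered within 10% from 50k pairs."""
        cfg, fends, pairs, obs, decay = _decay_dataset(
            seed, bias={"gc": [1.0, 4.0]}
        )
        binning = nz.partition_fend_features(fends, n_groups=2)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg.bin_size, min_distance=20_000
        )
        C = model.tables["gc"]
        ratio = np.sqrt(C[1, 1] / C[0, 0])
        assert abs(ratio - 4.0) / 4.0 < 0.10
        assert model.final_delta < 1e-4 or model.iterations == 100

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_null_data_near_identity(self, seed):
        cfg, fends, pairs, obs, decay = _decay_dataset(seed)
        binning = nz.partition_fend_features(fends, n_groups=2)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg.bin_size, min_distance=20_000
        )
        for f in nz.FEATURES:
            assert np.abs(np.log(model.tables[f])).max() < 0.1

    def test_no_distant_pairs_errors(self, small_dataset):
        cfg, genome, _, fends = small_dataset
        pairs, _ = simulate_pairs(cfg, fends)
        decay = nz.ExpectedProfile(raw=np.ones(5), smoothed=np.ones(5))
        binning = nz.partition_fend_features(fends, n_groups=2)
        with pytest.raises(ValueError, match="min_distance"):
            nz.learn_corrections(
                pairs, fends, binning, decay, cfg.bin_size, min_distance=10**9
            )


class TestMatrices:
    def _setup(self, seed=5):
        cfg, fends, pairs, obs, decay = _decay_dataset(seed, n_pairs=30_000, alpha=1.0)
        binning = nz.partition_fend_features(fends, n_groups=2)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg.bin_size, min_distance=20_000
        )
        chrom = sorted(obs)[0]
        cpairs = [p for p in pairs if p.chrom1 == chrom == p.chrom2]
        length = obs[chrom].n_bins * cfg.bin_size
        return cfg, fends, model, decay, chrom, cpairs, obs[chrom], length

    def test_identity_model_reproduces_observed(self, small_dataset):
        cfg, genome, _, fends = small_dataset
        pairs, _ = simulate_pairs(cfg, fends)
        chrom = "chr1"
        length = max(f.coord for f in fends if f.chrom == chrom)
        binning = nz.partition_fend_features(fends, n_groups=1)
        model = nz.CorrectionModel(
            tables={f: np.ones((1, 1)) for f in nz.FEATURES}, binning=binning
        )
        cpairs = [p for p in pairs if p.chrom1 == chrom == p.chrom2]
        O = nz.bin_pairs(cpairs, cfg.bin_size, length, chrom)
        E = nz.correction_matrix(model, cpairs, cfg.bin_size, length, chrom)
        # identity model: mean correction is 1 on the support, so N == O
        assert np.array_equal(E.values > 0, O.values > 0)
        assert np.allclose(E.values[O.values > 0], 1.0)
        N = nz.normalize_matrix(O, E)
        assert np.array_equal(N.values, O.values)
        # the summed variant reproduces the observed counts instead
        Es = nz.correction_matrix(
            model, cpairs, cfg.bin_size, length, chrom, statistic="sum"
        )
        assert np.array_equal(Es.values, O.values)

    def test_correction_sum_single_pair(self):
        from hicforge.digest import FragmentEnd

        fends = [FragmentEnd("c", 0, "L", 0, 100, 0.2, 1.0),
                 FragmentEnd("c", 50_000, "R", 0, 100, 0.8, 1.0)]
        binning = nz.partition_fend_features(fends, n_groups=2)
        tables = {f: np.ones((2, 2)) for f in nz.FEATURES}
        tables["gc"] = np.array([[1.0, 2.5], [2.5, 1.0]])
        model = nz.CorrectionModel(tables=tables, binning=binning)
        pairs = [PairRecord("c", 10, "+", 0, "c", 50_000, "-", 1)]
        E = nz.correction_matrix(model, pairs, 40_000, 80_000, "c")
        assert E.values[0, 1] == 2.5 and E.values[1, 0] == 2.5

    def test_e_zero_with_o_positive_rejected(self):
        O = ContactMatrix("c", 1, np.array([[1.0, 0], [0, 0]]))
        E = ContactMatrix("c", 1, np.zeros((2, 2)), "correction")
        with pytest.raises(ValueError, match="zero where O"):
            nz.normalize_matrix(O, E)

    def test_normalized_formula(self):
        O = ContactMatrix("c", 1, np.array([[0.0, 4], [4, 0]]))
        E = ContactMatrix("c", 1, np.array([[0.0, 2], [2, 0]]), "correction")
        N = nz.normalize_matrix(O, E)
        assert N.values[0, 1] == 2.0 and N.values[0, 0] == 0.0

    def test_normalization_recovers_unbiased_structure(self):
        """With planted biases, N correlates better with the bias-free
        truth than O does."""
        seed = 4
        cfg_b, fends, pairs, obs, decay = _decay_dataset(
            seed, n_pairs=50_000, alpha=1.0, bias={"gc": [1.0, 4.0]}
        )
        binning = nz.partition_fend_features(fends, n_groups=2)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg_b.bin_size, min_distance=20_000
        )
        chrom = sorted(obs)[0]
        cpairs = [p for p in pairs if p.chrom1 == chrom == p.chrom2]
        length = obs[chrom].n_bins * cfg_b.bin_size
        O = obs[chrom]
        E = nz.correction_matrix(model, cpairs, cfg_b.bin_size, length, chrom)
        N = nz.normalize_matrix(O, E)
        # noise-free bias-free intensity: decay mass summed over the
        # observable fend pairs of each bin pair (the generator's model
        # with the bias factor removed)
        uni = nz._FendUniverse(fends, cfg_b.bin_size)
        sel = np.array([fends[p].chrom == chrom for p in uni.p])
        w = (1.0 + uni.dist_bins[sel]) ** -1.0
        n = O.n_bins
        truth = np.zeros((n, n))
        np.add.at(truth, (uni.bin_p[sel], uni.bin_q[sel]), w)
        truth = truth + np.triu(truth, 1).T
        iu = np.triu_indices(n, 1)

        def corr(a, b):
            return np.corrcoef(a[iu], b[iu])[0, 1]

        assert corr(N.values, truth) > corr(O.values, truth)

    def test_oe_sentinels_and_symmetry(self):
        cfg, fends, model, decay, chrom, cpairs, O, length = self._setup()
        OE = nz.observed_over_expected(O, model, decay, fends)
        assert OE.sentinels is not None
        # wherever observed is zero but expected positive: NO_OBSERVED
        Ef = nz.expected_matrix(model, decay, fends, cfg.bin_size, chrom)
        expect_no_obs = (O.values == 0) & (Ef.values > 0)
        assert np.array_equal(OE.sentinels == SENT_NO_OBSERVED, expect_no_obs)
        assert np.array_equal(OE.sentinels == SENT_NO_EXPECTED, Ef.values <= 0)
        OE.check_symmetric()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_oe_calibration_on_decay_only_data(self, seed):
        """Mean O/expected per distance stays within 1 +- 0.1 on unbiased
        distance-decay data (zero-observed entries included as ratio 0)."""
        cfg, fends, pairs, obs, decay = _decay_dataset(
            seed, n_pairs=200_000, alpha=1.0, n_chroms=4
        )
        binning = nz.partition_fend_features(fends, n_groups=2)
        model = nz.learn_corrections(
            pairs, fends, binning, decay, cfg.bin_size, min_distance=20_000
        )
        nmax = max(o.n_bins for o in obs.values())
        ratios = {d: [] for d in range(nmax)}
        for c in sorted(obs):
            O = obs[c]
            Ef = nz.expected_matrix(model, decay, fends, cfg.bin_size, c)
            for d in range(O.n_bins):
                iu = np.arange(0, O.n_bins - d)
                o, e = O.values[iu, iu + d], Ef.values[iu, iu + d]
                ok = e > 0
                ratios[d].extend((o[ok] / e[ok]).tolist())
        for d, r in ratios.items():
            if len(r) >= 20:
                assert abs(np.mean(r) - 1.0) <= 0.1, (d, np.mean(r))

    def test_symmetry_through_pipeline(self):
        cfg, fends, model, decay, chrom, cpairs, O, length = self._setup()
        E = nz.correction_matrix(model, cpairs, cfg.bin_size, length, chrom)
        N = nz.normalize_matrix(O, E)
        for m in (O, E, N):
            m.check_symmetric()
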