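"""Generator contracts: determinism, spacing statistics, planted-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from methdev import calls as mcalls
from methdev import simulate as msim


def tiny_genome(**kw):
    defaults = dict(
        chrom_lengths={"chr1": 200_000, "chrX": 80_000, "chrY": 40_000},
        cgi_count=10, cgi_length_bp=600, gene_count=10,
    )
    defaults.update(kw)
    return msim.GenomeSpec(**defaults)


class TestGenome:
    def test_cpg_count_matches_geometric_expectation(self):
        spec = msim.GenomeSpec(chrom_lengths={"chr1": 100_000}, cpg_spacing_mean=100,
                               cgi_count=0, gene_count=0, pseudo_y_genes=0, seed=5)
        cpg, _ = msim.simulate_genome(spec)
        n = len(cpg["chr1"])
        assert abs(n - 1000) <= 4 * np.sqrt(1000)

    def test_positions_strictly_increasing_in_bounds(self):
        cpg, _ = msim.simulate_genome(tiny_genome(seed=3))
        for chrom, pos in cpg.items():
            assert (np.diff(pos) >= 2).all()
            assert pos[0] >= 1 and pos[-1] <= tiny_genome().chrom_lengths[chrom] - 1

    def test_no_cgi_request_gives_no_cgi_annotation(self):
        _, ann = msim.simulate_genome(tiny_genome(cgi_count=0, seed=3))
        assert len(ann["cgis"]) == 0

    def test_same_seed_is_reproducible(self):
        a, _ = msim.simulate_genome(tiny_genome(seed=9))
        b, _ = msim.simulate_genome(tiny_genome(seed=9))
        for chrom in a:
            np.testing.assert_array_equal(a[chrom], b[chrom])

    def test_cgi_density_at_least_5x_background(self):
        cpg, ann = msim.simulate_genome(tiny_genome(cgi_count=8, seed=12))
        pos = cpg["chr1"]
        cgis = ann["cgis"][ann["cgis"]["chrom"] == "chr1"]
        in_cgi = np.zeros(len(pos), bool)
        for r in cgis.itertuples(index=False):
            in_cgi |= (pos > r.start) & (pos <= r.end)
        cgi_bp = (cgis["end"] - cgis["start"]).sum()
        dens_cgi = in_cgi.sum() / cgi_bp
        dens_bg = (~in_cgi).sum() / (200_000 - cgi_bp)
        assert dens_cgi >= 5 * dens_bg

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            msim.simulate_genome(tiny_genome(chrom_lengths={"chr1": 500}))


class TestPlanting:
    def _plant(self, **kw):
        cpg, ann = msim.simulate_genome(tiny_genome(cgi_count=45, seed=4))
        defaults = dict(dmr_n=10, pmd_n=0, xi_fraction=1.0,
                        sample_sexes={"s": "male"}, seed=4)
        defaults.update(kw)
        return cpg, msim.plant_features(cpg, ann, **defaults)

    def test_dmr_bookkeeping_per_origin(self):
        _, truth = self._plant(dmr_n=10)
        dmrs = truth.features_of("gamete_dmr")
        assert len(dmrs) == 20
        assert sum(f.origin == "maternal" for f in dmrs) == 10

    def test_no_xi_blocks_when_fraction_zero(self):
        _, truth = self._plant(xi_fraction=0.0)
        assert truth.features_of("xi_block") == []

    def test_pmds_disjoint_and_counted(self):
        cpg, ann = msim.simulate_genome(tiny_genome(
            chrom_lengths={"chr1": 1_000_000, "chrX": 80_000, "chrY": 40_000},
            cgi_count=0, seed=4))
        truth = msim.plant_features(cpg, ann, dmr_n=0, pmd_n=3, pmd_length_bp=200_000,
                                    xi_fraction=0.0, sample_sexes={}, seed=4)
        pmds = sorted((f.start, f.end) for f in truth.features_of("pmd"))
        assert len(pmds) == 3
        for (s1, e1), (s2, e2) in zip(pmds, pmds[1:]):
            assert e1 <= s2

    def test_saturation_raises_explicit_error(self):
        with pytest.raises(ValueError, match="CGI"):
            self._plant(dmr_n=1000)

    def test_every_planted_feature_contains_a_cpg(self):
        cpg, truth = self._plant(dmr_n=10)
        for f in truth.features:
            if f.kind == "cgi":
                continue
            pos = cpg[f.chrom]
            assert ((pos > f.start) & (pos <= f.end)).any()

    def test_truth_ledger_roundtrip_header(self, tmp_path):
        _, truth = self._plant()
        path = tmp_path / "truth.tsv"
        truth.write(path)
        text = path.read_text().splitlines()
        assert text[0] == "#methdev-truth v1"
        n_rows = len(truth.features)
        assert len([l for l in text if not l.startswith("#")]) == n_rows + 1  # + header row


class TestSampling:
    def _setup(self, sexes, cgi_count=0, seed=6):
        cpg, ann = msim.simulate_genome(tiny_genome(cgi_count=cgi_count, gene_count=6,
                                                    seed=seed))
        truth = msim.plant_features(cpg, ann, dmr_n=0, pmd_n=0, xi_fraction=0.0,
                                    sample_sexes=sexes, seed=seed)
        return cpg, truth

    def test_strand_counts_sum_to_drawn_coverage(self):
        cpg, truth = self._setup({"s": "pooled"})
        sc = msim.simulate_sample(cpg, truth, msim.SampleSpec("s", 0.5, coverage_mean=6),
                                  seed=1)
        tab = sc.calls
        plus = tab[tab["strand"] == "+"].set_index(["chrom", "pos"])
        minus = tab[tab["strand"] == "-"].copy()
        minus["pos"] -= 1
        minus = minus.set_index(["chrom", "pos"])
        total = plus[["n_meth", "n_unmeth"]] + minus[["n_meth", "n_unmeth"]]
        destranded = mcalls.destrand(tab).set_index(["chrom", "pos"])
        pd.testing.assert_frame_equal(total, destranded[["n_meth", "n_unmeth"]])

    def test_mean_recovers_configured_target_at_deep_coverage(self):
        cpg, truth = self._setup({"s": "male"})
        spec = msim.SampleSpec("s", 0.65, coverage_mean=50, conversion_error=0.0)
        sc = msim.simulate_sample(cpg, truth, spec, seed=2)
        summ = mcalls.summarize(mcalls.destrand(sc.calls))
        assert abs(summ.mean_meth - 0.65) < 0.005

    def test_zero_target_without_conversion_error_gives_zero_counts(self):
        cpg, truth = self._setup({"s": "male"})
        spec = msim.SampleSpec("s", 0.0, coverage_mean=8, conversion_error=0.0)
        sc = msim.simulate_sample(cpg, truth, spec, seed=3)
        assert sc.calls["n_meth"].sum() == 0

    def test_same_seed_reproduces_table(self):
        cpg, truth = self._setup({"s": "pooled"})
        spec = msim.SampleSpec("s", 0.7)
        a = msim.simulate_sample(cpg, truth, spec, seed=11).calls
        b = msim.simulate_sample(cpg, truth, spec, seed=11).calls
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_sample_rejected(self):
        cpg, truth = self._setup({"s": "male"})
        with pytest.raises(ValueError, match="sample_sexes"):
            msim.simulate_sample(cpg, truth, msim.SampleSpec("other", 0.5))

    def test_shared_latent_seed_shares_latent_state(self):
        cpg, truth = self._setup({"a": "male", "b": "male"})
        sa = msim.simulate_sample(cpg, truth, msim.SampleSpec("a", 0.7, coverage_mean=80),
                                  seed=1, latent_seed=99)
        sb = msim.simulate_sample(cpg, truth, msim.SampleSpec("b", 0.7, coverage_mean=80),
                                  seed=2, latent_seed=99)
        sc = msim.simulate_sample(cpg, truth, msim.SampleSpec("b", 0.7, coverage_mean=80),
                                  seed=2, latent_seed=100)

        def fracs(s):
            f = mcalls.destrand(s.calls)
            return (f["n_meth"] / (f["n_meth"] + f["n_unmeth"])).to_numpy()

        shared = np.corrcoef(fracs(sa), fracs(sb))[0, 1]
        indep = np.corrcoef(fracs(sa), fracs(sc))[0, 1]
        # the shared latent state couples per-site fractions; an independent
        # latent draw does not (diploid allele averaging halves the shared var)
        assert shared > 0.25
        assert abs(indep) < 0.1


class TestXYCounts:
    def _truth(self, sexes):
        return msim.SimTruth(features=[], sample_sexes=sexes, seed=1)

    def test_female_with_zero_noise_has_zero_y(self):
        truth = self._truth({"f": "female"})
        _, y, _ = msim.simulate_xy_counts(truth, "f", seed=1, noise_factor=0.0)
        assert y == 0

    def test_male_y_counts_near_rate(self):
        truth = self._truth({"m": "male"})
        _, y, _ = msim.simulate_xy_counts(truth, "m", seed=2, lambda_y=500)
        assert 400 <= y <= 600

    def test_pooled_sex_recorded_for_downstream_flagging(self):
        truth = self._truth({"p": "pooled"})
        msim.simulate_xy_counts(truth, "p", seed=3)
        assert truth.sample_sexes["p"] == "pooled"
        assert "p" in truth.xy_read_counts


class TestStudy:
    def test_study_truth_conservation(self, small_study):
        res = small_study
        dmrs = res.truth.features_of("gamete_dmr")
        assert len(dmrs) == 2 * res.config.dmr_n
        assert set(res.samples) == {s.name for s in res.config.samples}
        assert set(res.truth.xy_read_counts) == set(res.samples)
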