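"""Synthetic-study generator: structure, determinism and genetic statistics."""

import numpy as np
import pandas as pd
import pytest

from capmap.simulate import (
    CoverageModel,
    MapSpec,
    expected_residual_heterozygosity,
    generate_reference,
    simulate_capture_readcounts,
    simulate_ril_population,
)

from conftest import make_grid_map_spec


def frozenset_pair(pair):
    """Canonical (order-free) representation of a pair of haplotypes."""
    return tuple(sorted(pair))


def _serialize(ref) -> str:
    return (
        "".join(f">{k}\n{v}\n" for k, v in ref.contigs.items())
        + ref.exons.to_csv()
        + ref.snps.to_csv()
        + ref.homeologs.to_csv()
    )


def _two_locus_spec(d_cM: float) -> MapSpec:
    loci = pd.DataFrame(
        {
            "contig_id": ["c1", "c2"],
            "chromosome": ["1A", "1A"],
            "position_cM": [10.0, 10.0 + d_cM],
            "position_bp": [10_000_000, int(10_000_000 + max(d_cM, 0.001) * 1e6)],
        }
    )
    return MapSpec(chromosomes=[("1A", 120.0)], loci=loci)


class TestGenerateReference:
    def test_rejects_empty_and_bad_distribution(self):
        with pytest.raises(ValueError):
            generate_reference(0)
        with pytest.raises(ValueError, match="kind"):
            generate_reference(5, {"kind": "zipf"})
        with pytest.raises(ValueError):
            generate_reference(5, {"kind": "uniform", "low": 200, "high": 100})

    def test_deterministic_under_fixed_seed(self):
        a = generate_reference(100, seed=7)
        b = generate_reference(100, seed=7)
        c = generate_reference(100, seed=8)
        assert _serialize(a) == _serialize(b)
        assert _serialize(a) != _serialize(c)
        assert len(a.snps) == 100
        assert sum(1 for name in a.contigs if not name.endswith("_h")) == 100

    def test_every_contig_has_exon_and_one_valid_snp(self):
        ref = generate_reference(60, seed=2)
        exon_contigs = set(ref.exons["contig"])
        for _, row in ref.snps.iterrows():
            assert row["contig"] in exon_contigs
            assert row["allele_dic2"] != row["allele_silur"]
            seq = ref.contigs[row["contig"]]
            assert seq[row["pos_1based"] - 1] == row["allele_dic2"]
            sub = ref.exons[ref.exons["contig"] == row["contig"]]
            inside = (sub["exon_start"] <= row["pos_1based"]) & (row["pos_1based"] <= sub["exon_end"])
            assert inside.any()

    def test_homeolog_count_within_binomial_bounds(self):
        ref = generate_reference(1000, seed=5, homeolog_fraction=0.3)
        count = len(ref.homeologs)
        sd = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(count - 300) <= 3 * sd


class TestRilPopulation:
    def test_mapspec_rejects_locus_outside_chromosome(self):
        loci = pd.DataFrame(
            {"contig_id": ["c1"], "chromosome": ["1A"], "position_cM": [250.0], "position_bp": [1]}
        )
        with pytest.raises(ValueError, match="outside"):
            MapSpec(chromosomes=[("1A", 200.0)], loci=loci)

    def test_rejects_bad_parameters(self):
        spec = _two_locus_spec(10.0)
        with pytest.raises(ValueError):
            simulate_ril_population(spec, n_individuals=0)
        with pytest.raises(ValueError):
            simulate_ril_population(spec, generations=0)

    @pytest.mark.parametrize("generations", [1, 3, 6])
    def test_selfing_heterozygosity_matches_halving(self, generations):
        # 14 unlinked loci (one per chromosome) x 600 lines.
        spec = make_grid_map_spec(14, 1, seed=1)
        truth = simulate_ril_population(spec, 600, generations, seed=generations)
        expected = expected_residual_heterozygosity(generations)
        n = truth.genotypes.size
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(truth.heterozygote_frequency() - expected) <= 3 * sd

    def test_zero_distance_gives_no_recombinants(self):
        truth = simulate_ril_population(_two_locus_spec(0.0), 300, 6, seed=4)
        g = truth.genotypes.to_numpy()
        assert (g[0] == g[1]).all()

    @staticmethod
    def _two_locus_selfing_oracle(r: float, generations: int) -> float:
        """Exact recombinant-line fraction among doubly homozygous lines after
        ``generations`` selfings, by enumerating the two-locus Markov chain.

        Converges to the Haldane-Waddington limit R = 2r/(1+2r) as
        generations grow.
        """
        haplotypes = [(0, 0), (0, 1), (1, 0), (1, 1)]

        def gamete_probs(h1, h2):
            probs = {}
            for g_, p in (
                (h1, (1 - r) / 2),
                (h2, (1 - r) / 2),
                ((h1[0], h2[1]), r / 2),
                ((h2[0], h1[1]), r / 2),
            ):
                probs[g_] = probs.get(g_, 0.0) + p
            return probs

        state = {frozenset_pair(((0, 0), (1, 1))): 1.0}
        for _ in range(generations):
            nxt = {}
            for pair, p in state.items():
                h1, h2 = pair
                gp = gamete_probs(h1, h2)
                for ga, pa in gp.items():
                    for gb, pb in gp.items():
                        key = frozenset_pair((ga, gb))
                        nxt[key] = nxt.get(key, 0.0) + p * pa * pb
            state = nxt
        hom = {pair: p for pair, p in state.items() if pair[0] == pair[1]}
        recomb = sum(p for pair, p in hom.items() if pair[0] in ((0, 1), (1, 0)))
        return recomb / sum(hom.values())

    @pytest.mark.parametrize("d_cM", [1.0, 10.0, 50.0])
    def test_recombinant_fraction_haldane_waddington(self, d_cM):
        r = 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))  # Haldane map function
        limit = 2.0 * r / (1.0 + 2.0 * r)  # Haldane-Waddington F-infinity
        expected = self._two_locus_selfing_oracle(r, 6)  # exact F6 enumeration
        assert abs(expected - limit) < 0.012  # F6 sits close to the limit
        truth = simulate_ril_population(_two_locus_spec(d_cM), 10_000, 6, seed=int(d_cM))
        g = truth.genotypes.to_numpy()
        informative = np.isin(g[0], ("A", "B")) & np.isin(g[1], ("A", "B"))
        observed = (g[0][informative] != g[1][informative]).mean()
        sd = np.sqrt(expected * (1 - expected) / informative.sum())
        assert abs(observed - expected) <= 3 * sd
        # and the limit formula itself holds once selfing has gone to depth
        truth_deep = simulate_ril_population(_two_locus_spec(d_cM), 10_000, 14, seed=int(d_cM) + 50)
        g = truth_deep.genotypes.to_numpy()
        informative = np.isin(g[0], ("A", "B")) & np.isin(g[1], ("A", "B"))
        observed = (g[0][informative] != g[1][informative]).mean()
        sd = np.sqrt(limit * (1 - limit) / informative.sum())
        assert abs(observed - limit) <= 3 * sd

    def test_distinct_seeds_give_distinct_populations(self):
        spec = _two_locus_spec(10.0)
        a = simulate_ril_population(spec, 50, 6, seed=1).genotypes
        b = simulate_ril_population(spec, 50, 6, seed=1).genotypes
        c = simulate_ril_population(spec, 50, 6, seed=2).genotypes
        assert a.equals(b)
        assert not a.equals(c)


@pytest.fixture(scope="module")
def flat_truth():
    spec = make_grid_map_spec(4, 100, seed=6)  # 400 loci
    return simulate_ril_population(spec, 60, 6, seed=13)


class TestCaptureReadcounts:
    def test_deterministic_and_budget_conserved(self, flat_truth):
        model = CoverageModel()
        a = simulate_capture_readcounts(flat_truth, model, seed=3)
        b = simulate_capture_readcounts(flat_truth, model, seed=3)
        c = simulate_capture_readcounts(flat_truth, model, seed=4)
        assert a.counts.equals(b.counts) and a.sink.equals(b.sink)
        assert not a.counts.equals(c.counts)
        # exact budget accounting
        assert a.targeted_reads == int((a.counts["reads_a"] + a.counts["reads_b"]).sum())
        assert a.sink_reads == int(a.sink["reads"].sum())
        assert a.total_reads == a.targeted_reads + a.sink_reads
        share = a.sink_reads / a.total_reads
        assert abs(share - model.sink_read_fraction) < 0.005

    def test_no_sequencing_error_means_pure_homozygotes(self, flat_truth):
        model = CoverageModel(sequencing_error=0.0, capture_failure_rate=0.0)
        rc = simulate_capture_readcounts(flat_truth, model, seed=8)
        counts = rc.counts.set_index(["contig", "individual"])
        truth_long = flat_truth.genotypes.stack()
        geno = truth_long.reindex(counts.index).to_numpy()
        assert (counts["reads_b"].to_numpy()[geno == "A"] == 0).all()
        assert (counts["reads_a"].to_numpy()[geno == "B"] == 0).all()

    def test_bait_stoichiometry_doubles_depth(self, flat_truth):
        contigs = list(flat_truth.genotypes.index)
        bait_counts = {c: (4 if i % 2 == 0 else 2) for i, c in enumerate(contigs)}
        model = CoverageModel(capture_failure_rate=0.0)
        rc = simulate_capture_readcounts(flat_truth, model, seed=21, bait_counts=bait_counts)
        depth = rc.counts.assign(depth=rc.counts["reads_a"] + rc.counts["reads_b"])
        locus_mean = depth.groupby("contig")["depth"].mean()
        four = locus_mean[[c for c in contigs if bait_counts[c] == 4]]
        two = locus_mean[[c for c in contigs if bait_counts[c] == 2]]
        ratio = four.mean() / two.mean()
        se = ratio * np.sqrt(
            (four.std() / four.mean()) ** 2 / len(four) + (two.std() / two.mean()) ** 2 / len(two)
        )
        assert abs(ratio - 2.0) <= 3 * se

    def test_capture_failure_rate(self, flat_truth):
        model = CoverageModel(capture_failure_rate=0.06, depth_lognorm_sigma=0.0, mean_depth=25)
        rc = simulate_capture_readcounts(flat_truth, model, seed=17)
        depth = rc.counts.assign(depth=rc.counts["reads_a"] + rc.counts["reads_b"])
        all_zero = (depth.groupby("contig")["depth"].max() == 0).mean()
        sd = np.sqrt(0.06 * 0.94 / flat_truth.genotypes.shape[0])
        assert abs(all_zero - 0.06) <= 3 * sd

    def test_monomorphic_locus_emits_only_dic2_allele(self, flat_truth):
        from capmap.simulate import default_locus_table

        table = default_locus_table(flat_truth)
        table.loc[0, "polymorphic"] = False
        model = CoverageModel(sequencing_error=0.0)
        rc = simulate_capture_readcounts(flat_truth, model, seed=5, locus_table=table)
        mono = rc.counts[rc.counts["contig"] == table.loc[0, "contig"]]
        assert (mono["reads_b"] == 0).all()

    def test_model_validation(self):
        with pytest.raises(ValueError):
            CoverageModel(mean_depth=0)
        with pytest.raises(ValueError):
            CoverageModel(sink_read_fraction=1.5)
        with pytest.raises(ValueError):
            CoverageModel(bait_count_per_locus=3)
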