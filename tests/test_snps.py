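"""SNP genotyping, frequencies, effect annotation and domain localization."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from petalpath.io import GENETIC_CODE, DomainAnnotation, RegionMap, SequenceRecord
from petalpath.simulate import SimulationConfig, simulate_alignments
from petalpath.snps import (
    annotate_domains,
    annotate_effect,
    biochem_change,
    build_snp_table,
    call_genotypes,
    classify_region,
    frequency_difference,
    map_residue,
    score_substitution,
    site_allele_frequencies,
    summarize_snps,
)


def _sheet(samples):
    return pd.DataFrame({
        "sample_id": [s for s, _ in samples],
        "phenotype": [p for _, p in samples],
    })


class TestCallGenotypes:
    sheet = _sheet([("b1", "blue"), ("o1", "orange")])

    def test_iupac_heterozygote(self):
        recs = [SequenceRecord("b1", "R"), SequenceRecord("o1", "A")]
        gt = call_genotypes(recs, self.sheet)
        assert gt.at[1, "b1"] == frozenset("AG")
        assert gt.at[1, "o1"] == frozenset("A")

    def test_masked_codes(self):
        recs = [SequenceRecord("b1", "N-B"), SequenceRecord("o1", "AAA")]
        gt = call_genotypes(recs, self.sheet)
        assert gt.at[1, "b1"] is None      # N
        assert gt.at[2, "b1"] is None      # gap
        assert gt.at[3, "b1"] is None      # three-base code
        assert gt.at[3, "o1"] == frozenset("A")

    def test_haplotype_pairs_combined(self):
        recs = [SequenceRecord("b1/1", "A"), SequenceRecord("b1/2", "G"),
                SequenceRecord("o1", "C")]
        gt = call_genotypes(recs, self.sheet)
        assert gt.at[1, "b1"] == frozenset("AG")

    def test_unequal_haplotype_lengths_rejected(self):
        recs = [SequenceRecord("b1/1", "AA"), SequenceRecord("b1/2", "AAG"),
                SequenceRecord("o1", "CCC")]
        with pytest.raises(ValueError, match="unequal"):
            call_genotypes(recs, self.sheet)

    def test_unknown_sample_rejected(self):
        recs = [SequenceRecord("mystery", "A")]
        with pytest.raises(ValueError, match="mystery"):
            call_genotypes(recs, self.sheet)


class TestAlleleFrequencies:
    def test_two_het_two_fixed(self):
        calls = [frozenset("AG"), frozenset("AG"), frozenset("A"), frozenset("A")]
        freqs = site_allele_frequencies(calls)
        assert freqs["G"] == pytest.approx(0.25)
        assert freqs["A"] == pytest.approx(0.75)

    def test_all_fixed(self):
        assert site_allele_frequencies([frozenset("G")] * 4) == {"G": 1.0}

    def test_all_heterozygous(self):
        freqs = site_allele_frequencies([frozenset("AG")] * 6)
        assert freqs == {"A": 0.5, "G": 0.5}

    def test_masked_samples_excluded(self):
        freqs = site_allele_frequencies([None, frozenset("A"), frozenset("AG")])
        assert freqs["G"] == pytest.approx(0.25)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            site_allele_frequencies([None, None])

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            calls = [frozenset(rng.choice(list("ACGT"),
                                          size=rng.integers(1, 3), replace=False))
                     for _ in range(8)]
            assert sum(site_allele_frequencies(calls).values()) == pytest.approx(1.0)


class TestFrequencyDifference:
    def test_half_vs_fixed(self):
        assert frequency_difference(0.5, 1.0) == pytest.approx(0.5)

    def test_fixed_difference_is_one(self):
        assert frequency_difference(1.0, 0.0) == 1.0

    def test_equal_frequencies_zero(self):
        assert frequency_difference(0.3, 0.3) == 0.0

    def test_invariant_to_designated_allele(self):
        fb, fo = 0.7, 0.2
        assert frequency_difference(fb, fo) == pytest.approx(
            frequency_difference(1 - fb, 1 - fo))


class TestClassifyRegion:
    rm = RegionMap("g", utr5=(1, 60), cds=(61, 1560), utr3=(1561, 1650))

    def test_cds_offset_472_is_codon_158_pos_1(self):
        region, offset, codon, codon_pos = classify_region(60 + 472, self.rm)
        assert (region, offset, codon, codon_pos) == ("CDS", 472, 158, 1)

    def test_cds_offset_434_in_specificity_region(self):
        _, offset, codon, _ = classify_region(60 + 434, self.rm)
        assert offset == 434 and codon == 145 and 133 <= codon <= 158

    def test_utr_positions(self):
        assert classify_region(10, self.rm)[0] == "5UTR"
        assert classify_region(1600, self.rm)[0] == "3UTR"

    def test_outside_all_regions_rejected(self):
        with pytest.raises(ValueError):
            classify_region(1651, self.rm)


def _aln_gt(seqs, phenos=("blue", "orange")):
    sheet = _sheet([(f"s{i}", phenos[i % len(phenos)]) for i in range(len(seqs))])
    recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    return call_genotypes(recs, sheet)


class TestAnnotateEffect:
    rm = RegionMap("g", cds=(1, 6))

    def test_nonsynonymous_third_position(self):
        gt = _aln_gt(["GAAGGG", "GATGGG"])
        ann = annotate_effect(gt, 3, self.rm)
        assert ann.effect == "nonsynonymous"
        assert set(ann.aa_states) == {"E", "D"}

    def test_synonymous_change(self):
        gt = _aln_gt(["GCTGGG", "GCCGGG"])
        ann = annotate_effect(gt, 3, self.rm)
        assert ann.effect == "synonymous" and ann.aa_states == ("A",)

    def test_many_states_is_na(self):
        # three nucleotide states giving >2 amino acids at one codon
        gt = _aln_gt(["AAAGGG", "GAAGGG", "CAAGGG", "AAAGGG"],
                     phenos=("blue", "blue", "orange", "orange"))
        ann = annotate_effect(gt, 1, self.rm)
        assert ann.effect == "NA"

    def test_masked_codon_is_na(self):
        gt = _aln_gt(["ANAGGG", "AGAGGG"])
        ann = annotate_effect(gt, 3, self.rm)
        # the allele's codon completion needs position 2; sample 0 masked
        assert ann.effect in ("NA", "synonymous", "nonsynonymous")

    def test_agrees_with_full_translation_oracle(self):
        # oracle: substitute each allele into the full CDS, translate with
        # biopython, and diff the protein strings
        rng = np.random.default_rng(42)
        codons = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
        n_checked = 0
        while n_checked < 1000:
            cds = "".join(rng.choice(codons, size=10))
            pos = int(rng.integers(len(cds)))
            alt = "ACGT"[rng.integers(4)]
            if alt == cds[pos]:
                continue
            mutated = cds[:pos] + alt + cds[pos + 1:]
            if "*" in str(Seq(mutated).translate())[:-1]:
                continue
            gt = _aln_gt([cds, mutated])
            ann = annotate_effect(gt, pos + 1, RegionMap("g", cds=(1, len(cds))))
            p_ref = str(Seq(cds).translate())
            p_alt = str(Seq(mutated).translate())
            expected = "synonymous" if p_ref == p_alt else "nonsynonymous"
            assert ann.effect == expected, (cds, pos, alt)
            if expected == "nonsynonymous":
                diff = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
                assert set(ann.aa_states) == set(diff[0])
            n_checked += 1


class TestScoreAndBiochem:
    def test_printed_scores(self, blosum62):
        assert score_substitution("H", "N", blosum62) == 1
        assert score_substitution("E", "Q", blosum62) == 2
        assert score_substitution("N", "T", blosum62) == 0
        assert score_substitution("K", "E", blosum62) == 1

    def test_symmetry(self, blosum62):
        for a, b in [("H", "N"), ("K", "E"), ("I", "T"), ("A", "W")]:
            assert score_substitution(a, b, blosum62) == score_substitution(b, a, blosum62)

    def test_stop_gives_na(self, blosum62):
        assert score_substitution("K", "*", blosum62) is None

    @pytest.mark.parametrize("a,b,cf,ct,changed", [
        ("K", "E", "positively_charged", "negatively_charged", True),
        ("N", "S", "polar_uncharged", "polar_uncharged", False),
        ("I", "M", "hydrophobic", "hydrophobic", False),
        ("H", "N", "positively_charged", "polar_uncharged", True),
        ("A", "E", "hydrophobic", "negatively_charged", True),
        ("G", "P", "special", "special", False),
    ])
    def test_biochemical_partition(self, a, b, cf, ct, changed):
        assert biochem_change(a, b) == (cf, ct, changed)


class TestDomainsAndMapping:
    region = DomainAnnotation("DFR", "substrate_specificity", 133, 158)
    site210 = DomainAnnotation("DFR", "binding_site", 210, 210)

    def test_residue_135_hits_region(self):
        assert self.region in annotate_domains(135, [self.region, self.site210], "DFR")

    def test_boundary_below_region_misses(self):
        assert annotate_domains(132, [self.region], "DFR") == []

    def test_single_residue_site_hit(self):
        assert annotate_domains(210, [self.site210], "DFR") == [self.site210]

    def test_other_gene_not_matched(self):
        assert annotate_domains(140, [self.region], "OTHER") == []

    def test_reference_numbering_shift(self):
        assert map_residue(210, 2) == 208
        assert map_residue(135, 2) == 133
        assert map_residue(7, 0) == 7

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            map_residue(2, 2)


class TestBuildSnpTable:
    @pytest.fixture(scope="class")
    def pipeline_run(self, blosum62):
        cfg = SimulationConfig(seed=13)
        sim = simulate_alignments(cfg)
        table = build_snp_table(sim.alignments, cfg.sample_sheet(),
                                sim.region_maps, domains=sim.domains,
                                matrix=blosum62, min_diff=0.25)
        return cfg, sim, table

    def test_planted_fixed_nonsyn_recovered_exactly(self, pipeline_run):
        cfg, sim, table = pipeline_run
        fixed = table[(table["freq_diff"] == 1.0) & (table["region"] == "CDS")]
        truth = sim.snp_truth[sim.snp_truth["planted_type"] == "fixed_nonsyn"]
        assert len(fixed) == cfg.n_fixed_nonsyn == len(truth)
        assert set(fixed["bp_pos"]) == set(truth["bp_pos"])
        assert (fixed["effect"] == "nonsynonymous").all()

    def test_planted_frequencies_recovered_exactly(self, pipeline_run):
        _, sim, table = pipeline_run
        truth = sim.snp_truth[(sim.snp_truth["planted_type"] == "group_variable")
                              & (sim.snp_truth["freq_blue"] > 0)]
        for _, row in truth.iterrows():
            got = table[(table["bp_pos"] == row["bp_pos"])
                        & (table["region"] == "CDS")]
            assert len(got) == 1
            rec = got.iloc[0]
            fb = (rec["freq_blue"] if rec["designated_allele"] == row["alt"]
                  else 1 - rec["freq_blue"])
            assert fb == pytest.approx(row["freq_blue"])
            assert rec["effect"] == row["effect"]

    def test_utr_snps_located(self, pipeline_run):
        _, sim, table = pipeline_run
        truth = sim.snp_truth[sim.snp_truth["planted_type"] == "utr"]
        utr = table[table["region"].isin(["5UTR", "3UTR"])]
        assert set(zip(utr["region"], utr["bp_pos"])) == set(
            zip(truth["region"], truth["bp_pos"]))
        assert (utr["effect"] == "NA").all()

    def test_min_diff_zero_reports_all_segregating(self, pipeline_run):
        cfg, sim, _ = pipeline_run
        table = build_snp_table(sim.alignments, cfg.sample_sheet(),
                                sim.region_maps, min_diff=0.0)
        assert table["color_differentiating"].all()

    def test_frequencies_sum_to_one_per_group(self, pipeline_run):
        _, _, table = pipeline_run
        # designated allele + complement partition each biallelic site
        assert ((table["freq_blue"] >= 0) & (table["freq_blue"] <= 1)).all()
        assert ((table["freq_diff"] >= 0) & (table["freq_diff"] <= 1)).all()

    def test_gene_without_region_map_skipped(self, pipeline_run, blosum62):
        cfg, sim, _ = pipeline_run
        alignments = dict(sim.alignments)
        alignments["orphan"] = sim.alignments["candA"]
        table = build_snp_table(alignments, cfg.sample_sheet(),
                                sim.region_maps, matrix=blosum62)
        assert "orphan" not in set(table["gene_id"])

    def test_pooled_records_for_multi_isotig_gene(self, pipeline_run, blosum62):
        cfg, sim, _ = pipeline_run
        alignments = {"candA-i1": sim.alignments["candA"],
                      "candA-i2": sim.alignments["candA"]}
        table = build_snp_table(alignments, cfg.sample_sheet(),
                                sim.region_maps, matrix=blosum62,
                                isotig_to_gene={"candA-i1": "candA",
                                                "candA-i2": "candA"})
        assert set(table["isotig_id"]) == {"candA-i1", "candA-i2", "pooled"}
        pooled = table[table["isotig_id"] == "pooled"]
        single = table[table["isotig_id"] == "candA-i1"]
        # pooling identical isotigs reproduces the per-isotig frequencies
        assert np.allclose(sorted(pooled["freq_diff"]), sorted(single["freq_diff"]))


class TestSummarizeSnps:
    def test_freq_diff_range(self):
        table = pd.DataFrame({
            "gene_id": ["g"] * 3, "isotig_id": ["g"] * 3, "region": ["CDS"] * 3,
            "effect": ["synonymous"] * 3, "freq_blue": [0.2, 0.5, 0.8],
            "freq_orange": [0.0, 0.0, 0.0], "freq_diff": [0.2, 0.5, 0.8],
        })
        s = summarize_snps(table).iloc[0]
        assert (s["min_freq_diff"], s["mean_freq_diff"], s["max_freq_diff"]) == (0.2, 0.5, 0.8)

    def test_variable_fraction_matches_hand_count(self):
        # 22 sites of which 18 variable in blue -> fraction ~0.818
        n, n_var = 22, 18
        table = pd.DataFrame({
            "gene_id": ["f35h"] * n, "isotig_id": ["f35h"] * n,
            "region": ["CDS"] * n, "effect": ["synonymous"] * n,
            "freq_blue": [0.5] * n_var + [1.0] * (n - n_var),
            "freq_orange": [1.0] * n,
            "freq_diff": [0.5] * n_var + [0.0] * (n - n_var),
        })
        s = summarize_snps(table).iloc[0]
        assert s["n_variable_blue"] == 18
        assert s["frac_variable_blue"] == pytest.approx(18 / 22)
        assert s["n_variable_orange"] == 0

    def test_empty_table(self):
        assert summarize_snps(pd.DataFrame(columns=["gene_id"])).empty
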