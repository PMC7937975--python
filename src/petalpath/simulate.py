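"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: two phenotype groups of
eight samples each, negative-binomially distributed gene counts with
planted fold-changes (including a paralog-style gene nearly silent in one
group), and per-gene alignments carrying planted fixed inter-group
non-synonymous SNPs, within-group heterozygous sites, UTR SNPs, and a
diverged paralog copy differing in a declared substrate-specificity
region.  Every planted feature is recorded in truth tables so each
pipeline stage can be scored against ground truth.

Random streams are split per component (counts vs sequences) so changing
one configuration block does not perturb the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ALLELES_TO_IUPAC,
    GENETIC_CODE,
    STOP,
    DomainAnnotation,
    RegionMap,
    SequenceRecord,
    write_domains,
    write_fasta,
    write_panel,
    write_region_maps,
    write_sample_sheet,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "SimulatedAlignments",
    "simulate_counts",
    "simulate_alignments",
    "write_truth",
    "read_truth",
    "write_simulation",
]

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the targeted design: 8 samples per phenotype group,
    negative-binomial counts with common dispersion 0.1, 10% of genes
    differentially expressed at |log2FC| = 3, one gene near-silent in the
    blue group, four fixed non-synonymous inter-group SNPs, and a paralog
    pair differing at 13 of the 26 residues of a 133–158 substrate-
    specificity region.
    """

    seed: int = 0
    n_per_group: int = 8
    n_genes: int = 200
    library_size_range: tuple = (100_000, 200_000)
    dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    silent_genes: tuple = (("DFR2_like", "blue"),)
    gene_length_bp: int = 900
    utr5_bp: int = 60
    utr3_bp: int = 90
    n_fixed_nonsyn: int = 4
    n_group_variable: int = 6
    het_rate: float = 0.25
    n_utr_snps: int = 4
    paralog: tuple | None = (133, 158, 13)
    paralog_variable: tuple = (2, 1)
    haplotype_pairs: bool = False

    def __post_init__(self):
        if self.gene_length_bp % 3:
            raise ValueError("gene_length_bp must be a multiple of 3")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0,1]")
        if not (0 <= self.het_rate <= 1):
            raise ValueError("het_rate must be in [0,1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_codons = self.gene_length_bp // 3 - 1
        if self.n_fixed_nonsyn + self.n_group_variable > n_codons:
            raise ValueError("too many planted SNPs for the CDS length")
        if self.paralog is not None:
            start, end, n_diffs = self.paralog
            if n_diffs > end - start + 1:
                raise ValueError("paralog region differences exceed region length")
            if 3 * end > self.gene_length_bp:
                raise ValueError("paralog region extends beyond the CDS")

    @property
    def sample_ids(self) -> list:
        return ([f"blue_{i+1}" for i in range(self.n_per_group)]
                + [f"orange_{i+1}" for i in range(self.n_per_group)])

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "phenotype": ["blue"] * self.n_per_group + ["orange"] * self.n_per_group,
        })


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, stream]))


def simulate_counts(config: SimulationConfig) -> tuple:
    """Draw a raw count matrix and its truth table.

    Counts are negative-binomial with mean = library size x gene relative
    abundance, common dispersion phi; DE genes get a 2^(+/-de_log2fc)
    multiplier in one group (balanced up-in-blue / up-in-orange); silent
    genes get relative abundance ~1e-4 of nominal in the named group.
    """
    rng = _rng(config, stream=17)
    n = config.n_per_group
    silent_names = [g for g, _ in config.silent_genes]
    gene_ids = [f"g{i+1:04d}" for i in range(config.n_genes)] + silent_names
    n_total = len(gene_ids)

    n_de = int(config.de_fraction * config.n_genes)
    if config.de_fraction > 0 and n_de < 1 and not config.silent_genes:
        warnings.warn("differential expression requested but no gene qualifies",
                      stacklevel=2)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    up_in_blue = np.zeros(config.n_genes, dtype=bool)
    up_in_blue[de_idx[: n_de // 2]] = True

    rel = rng.lognormal(mean=0.0, sigma=1.0, size=n_total)
    rel /= rel.sum()
    lib = rng.integers(config.library_size_range[0],
                       config.library_size_range[1] + 1, size=2 * n)

    mult_blue = np.ones(n_total)
    mult_orange = np.ones(n_total)
    for j, idx in enumerate(de_idx):
        if up_in_blue[idx]:
            mult_blue[idx] = 2.0 ** config.de_log2fc
        else:
            mult_orange[idx] = 2.0 ** config.de_log2fc
    for gname, group in config.silent_genes:
        idx = gene_ids.index(gname)
        if group == "blue":
            mult_blue[idx] = 1e-4
        else:
            mult_orange[idx] = 1e-4

    mean = np.empty((n_total, 2 * n))
    for s in range(2 * n):
        mult = mult_blue if s < n else mult_orange
        mean[:, s] = lib[s] * rel * mult

    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=config.sample_ids)
    true_lfc = np.log2(mult_blue / mult_orange)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_log2fc": true_lfc,
        "is_de": np.abs(true_lfc) > 0,
        "silent_group": [dict(config.silent_genes).get(g, "") for g in gene_ids],
    })
    return counts_df, truth


# ---------------------------------------------------------------------------
# sequence simulation


@dataclass
class SimulatedAlignments:
    """Alignments, region maps, domains and truth from one simulation."""

    alignments: dict            # isotig/gene id -> list[SequenceRecord]
    region_maps: dict           # gene id -> RegionMap
    domains: list               # DomainAnnotation
    snp_truth: pd.DataFrame
    paralog_alignments: dict    # copy id -> list[SequenceRecord]
    paralog_truth: pd.DataFrame


def _random_cds(rng: np.random.Generator, n_codons: int) -> list:
    codons = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(n_codons - 1)
    ]
    codons.append("TAA")
    return codons


def _nonsyn_alternative(codon: str, rng: np.random.Generator) -> tuple:
    """(codon_pos 0-based, ref, alt) making a non-stop, non-synonymous change."""
    options = []
    for pos, alt in product(range(3), _BASES):
        if alt == codon[pos]:
            continue
        mutated = codon[:pos] + alt + codon[pos + 1:]
        if GENETIC_CODE[mutated] != STOP and GENETIC_CODE[mutated] != GENETIC_CODE[codon]:
            options.append((pos, codon[pos], alt))
    return options[rng.integers(len(options))]


def _any_alternative(codon: str, rng: np.random.Generator) -> tuple:
    options = []
    for pos, alt in product(range(3), _BASES):
        if alt == codon[pos]:
            continue
        mutated = codon[:pos] + alt + codon[pos + 1:]
        if GENETIC_CODE[mutated] != STOP:
            options.append((pos, codon[pos], alt))
    return options[rng.integers(len(options))]


def _emit_records(sample_seqs: Mapping[str, object], haplotype_pairs: bool) -> list:
    """sample -> (hap1, hap2) base lists; emit IUPAC codes or /1,/2 pairs."""
    records = []
    for sample, (h1, h2) in sample_seqs.items():
        if haplotype_pairs:
            records.append(SequenceRecord(id=f"{sample}/1", sequence="".join(h1)))
            records.append(SequenceRecord(id=f"{sample}/2", sequence="".join(h2)))
        else:
            merged = []
            for a, b in zip(h1, h2):
                merged.append(a if a == b else ALLELES_TO_IUPAC[frozenset((a, b))])
            records.append(SequenceRecord(id=sample, sequence="".join(merged)))
    return records


def simulate_alignments(config: SimulationConfig) -> SimulatedAlignments:
    """Build per-sample alignments with planted SNPs plus a paralog pair.

    The candidate gene (``candA``, an F3'5'H-style locus with UTRs) carries
    ``n_fixed_nonsyn`` sites fixed-different between groups (non-synonymous
    by construction), ``n_group_variable`` sites heterozygous in blue
    samples at ``het_rate``, and ``n_utr_snps`` fixed UTR differences.  The
    paralog pair (``DFR1_like``/``DFR2_like``) differs at exactly
    ``n_region_diffs`` residues inside the declared region; the second copy
    is emitted for orange samples only.
    """
    rng = _rng(config, stream=29)
    n = config.n_per_group
    samples = config.sample_ids
    blue = samples[:n]
    orange = samples[n:]

    n_codons = config.gene_length_bp // 3
    codons = _random_cds(rng, n_codons)
    utr5 = [_BASES[rng.integers(4)] for _ in range(config.utr5_bp)]
    utr3 = [_BASES[rng.integers(4)] for _ in range(config.utr3_bp)]

    # pick distinct codon slots for fixed and variable planted CDS SNPs
    slots = rng.permutation(n_codons - 1)
    fixed_slots = sorted(slots[:config.n_fixed_nonsyn])
    var_slots = sorted(slots[config.n_fixed_nonsyn:
                             config.n_fixed_nonsyn + config.n_group_variable])

    cds_len = config.gene_length_bp
    ref_seq = utr5 + list("".join(codons)) + utr3
    L = len(ref_seq)
    sample_seqs = {s: (list(ref_seq), list(ref_seq)) for s in samples}

    truth_rows = []

    def cds_aln_pos(cds_offset: int) -> int:
        return config.utr5_bp + cds_offset

    for slot in fixed_slots:
        codon = codons[slot]
        pos, ref, alt = _nonsyn_alternative(codon, rng)
        cds_offset = slot * 3 + pos + 1
        ap = cds_aln_pos(cds_offset)
        for s in orange:
            sample_seqs[s][0][ap - 1] = alt
            sample_seqs[s][1][ap - 1] = alt
        mutated = codon[:pos] + alt + codon[pos + 1:]
        truth_rows.append({
            "gene_id": "candA", "aln_pos": ap, "bp_pos": cds_offset,
            "region": "CDS", "ref": ref, "alt": alt,
            "effect": "nonsynonymous",
            "aa_from": GENETIC_CODE[codon], "aa_to": GENETIC_CODE[mutated],
            "aa_pos": slot + 1,
            "freq_blue": 0.0, "freq_orange": 1.0, "freq_diff": 1.0,
            "planted_type": "fixed_nonsyn",
        })

    for slot in var_slots:
        codon = codons[slot]
        pos, ref, alt = _any_alternative(codon, rng)
        cds_offset = slot * 3 + pos + 1
        ap = cds_aln_pos(cds_offset)
        n_het = 0
        for s in blue:
            if rng.random() < config.het_rate:
                sample_seqs[s][1][ap - 1] = alt
                n_het += 1
        freq_blue = n_het / (2 * n)
        mutated = codon[:pos] + alt + codon[pos + 1:]
        effect = ("synonymous" if GENETIC_CODE[mutated] == GENETIC_CODE[codon]
                  else "nonsynonymous")
        truth_rows.append({
            "gene_id": "candA", "aln_pos": ap, "bp_pos": cds_offset,
            "region": "CDS", "ref": ref, "alt": alt, "effect": effect,
            "aa_from": GENETIC_CODE[codon], "aa_to": GENETIC_CODE[mutated],
            "aa_pos": slot + 1,
            "freq_blue": freq_blue, "freq_orange": 0.0, "freq_diff": freq_blue,
            "planted_type": "group_variable",
        })

    # fixed UTR differences, alternating 5' / 3'
    utr_positions = []
    for k in range(config.n_utr_snps):
        if k % 2 == 0 and config.utr5_bp:
            ap = int(rng.integers(1, config.utr5_bp + 1))
            region = "5UTR"
        else:
            ap = int(config.utr5_bp + cds_len + rng.integers(1, config.utr3_bp + 1))
            region = "3UTR"
        while ap in utr_positions:
            ap = (ap % L) + 1 if region == "3UTR" else ap % config.utr5_bp + 1
        utr_positions.append(ap)
        ref = ref_seq[ap - 1]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        if alt == ref:
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
        for s in orange:
            sample_seqs[s][0][ap - 1] = alt
            sample_seqs[s][1][ap - 1] = alt
        truth_rows.append({
            "gene_id": "candA", "aln_pos": ap, "bp_pos": ap, "region": region,
            "ref": ref, "alt": alt, "effect": "NA", "aa_from": "", "aa_to": "",
            "aa_pos": None, "freq_blue": 0.0, "freq_orange": 1.0,
            "freq_diff": 1.0, "planted_type": "utr",
        })

    alignments = {"candA": _emit_records(sample_seqs, config.haplotype_pairs)}
    region_maps = {
        "candA": RegionMap(
            gene_id="candA",
            utr5=(1, config.utr5_bp) if config.utr5_bp else None,
            cds=(config.utr5_bp + 1, config.utr5_bp + cds_len),
            utr3=(config.utr5_bp + cds_len + 1, L) if config.utr3_bp else None,
        ),
    }

    # paralog pair: copy B = copy A + fixed in-region differences
    paralog_alignments: dict = {}
    paralog_rows = []
    domains: list = []
    if config.paralog is not None:
        start_aa, end_aa, n_diffs = config.paralog
        codons_a = _random_cds(rng, n_codons)
        codons_b = list(codons_a)
        region_slots = rng.permutation(np.arange(start_aa - 1, end_aa))
        diff_slots = sorted(region_slots[:n_diffs])
        for slot in diff_slots:
            pos, ref, alt = _nonsyn_alternative(codons_b[slot], rng)
            codons_b[slot] = codons_b[slot][:pos] + alt + codons_b[slot][pos + 1:]
            paralog_rows.append({
                "aa_pos": slot + 1, "class": "fixed_difference",
                "state_A": GENETIC_CODE[codons_a[slot]],
                "state_B": GENETIC_CODE[codons_b[slot]],
                "in_region": True,
            })

        # planted variable residues, outside the declared region
        outside = [i for i in range(n_codons - 1)
                   if not (start_aa - 1 <= i <= end_aa - 1)
                   and all(r["aa_pos"] != i + 1 for r in paralog_rows)]
        outside = list(rng.permutation(outside))
        n_var_a, n_var_b = config.paralog_variable
        var_a_slots = sorted(int(i) for i in outside[:n_var_a])
        var_b_slots = sorted(int(i) for i in outside[n_var_a:n_var_a + n_var_b])

        seqs_a = {s: (list("".join(codons_a)), list("".join(codons_a))) for s in samples}
        seqs_b = {s: (list("".join(codons_b)), list("".join(codons_b))) for s in orange}
        for slot in var_a_slots:
            pos, ref, alt = _nonsyn_alternative(codons_a[slot], rng)
            carrier = blue[int(rng.integers(len(blue)))]
            seqs_a[carrier][0][slot * 3 + pos] = alt
            seqs_a[carrier][1][slot * 3 + pos] = alt
            paralog_rows.append({
                "aa_pos": slot + 1, "class": "variable_in_A",
                "state_A": GENETIC_CODE[codons_a[slot]],
                "state_B": GENETIC_CODE[codons_b[slot]],
                "in_region": False,
            })
        for slot in var_b_slots:
            pos, ref, alt = _nonsyn_alternative(codons_b[slot], rng)
            carrier = orange[int(rng.integers(len(orange)))]
            seqs_b[carrier][0][slot * 3 + pos] = alt
            seqs_b[carrier][1][slot * 3 + pos] = alt
            paralog_rows.append({
                "aa_pos": slot + 1, "class": "variable_in_B",
                "state_A": GENETIC_CODE[codons_a[slot]],
                "state_B": GENETIC_CODE[codons_b[slot]],
                "in_region": False,
            })

        paralog_alignments = {
            "DFR1_like": _emit_records(seqs_a, config.haplotype_pairs),
            "DFR2_like": _emit_records(seqs_b, config.haplotype_pairs),
        }
        for copy in ("DFR1_like", "DFR2_like"):
            region_maps[copy] = RegionMap(gene_id=copy, cds=(1, cds_len))
            domains.append(DomainAnnotation(
                gene_id=copy, name="substrate_specificity",
                start_aa=start_aa, end_aa=end_aa, source="synthetic"))

    snp_truth = pd.DataFrame(truth_rows)
    paralog_truth = pd.DataFrame(paralog_rows)
    return SimulatedAlignments(
        alignments=alignments, region_maps=region_maps, domains=domains,
        snp_truth=snp_truth, paralog_alignments=paralog_alignments,
        paralog_truth=paralog_truth,
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth table as TSV (lossless round-trip with read_truth)."""
    write_tsv(truth, path)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Run both generators and write every pipeline input under ``outdir``.

    Returns a dict of the paths written.  The panel map assigns the planted
    candidate/paralog genes to the ABP and spreads the background count
    genes over the three panel categories deterministically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)

    counts, counts_truth = simulate_counts(config)
    sim = simulate_alignments(config)

    paths = {}
    counts_out = counts.reset_index()
    write_tsv(counts_out, outdir / "counts.tsv")
    paths["counts"] = outdir / "counts.tsv"
    write_sample_sheet(config.sample_sheet(), outdir / "samples.tsv")
    paths["samples"] = outdir / "samples.tsv"

    panel = {}
    for i, gene in enumerate(g for g in counts.index if not g.startswith(("DFR", "cand"))):
        panel[gene] = ("ABP", "nonABP", "nonABP", "regulatory")[i % 4]
    for gene, _ in config.silent_genes:
        panel[gene] = "ABP"
    for gene in ("candA", "DFR1_like", "DFR2_like"):
        panel[gene] = "ABP"
    write_panel(panel, outdir / "panel.tsv")
    paths["panel"] = outdir / "panel.tsv"

    for name, records in {**sim.alignments, **sim.paralog_alignments}.items():
        write_fasta(records, aln_dir / f"{name}.fasta")
    paths["alignments"] = aln_dir
    write_region_maps(sim.region_maps, outdir / "regions.tsv")
    paths["regions"] = outdir / "regions.tsv"
    write_domains(sim.domains, outdir / "domains.tsv")
    paths["domains"] = outdir / "domains.tsv"

    write_truth(counts_truth, outdir / "truth_counts.tsv")
    write_truth(sim.snp_truth, outdir / "truth_snps.tsv")
    write_truth(sim.paralog_truth, outdir / "truth_paralogs.tsv")
    paths["truth_counts"] = outdir / "truth_counts.tsv"
    paths["truth_snps"] = outdir / "truth_snps.tsv"
    paths["truth_paralogs"] = outdir / "truth_paralogs.tsv"
    return paths
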