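"""Color-differentiating SNP characterization from phenotype-labeled alignments.

Per-sample coding sequences (heterozygotes as IUPAC two-base codes, or as
``/1``/``/2`` haplotype pairs) are collapsed to per-site allele sets, from
which the module derives per-group allele frequencies, frequency
differences, synonymous/non-synonymous effect, BLOSUM62 score, biochemical
class change, domain localization and reference-numbering mapping.

The species under study is tetraploid; dosage is deliberately collapsed to
a homozygote/heterozygote dichotomy for frequency calculations, so a
heterozygous sample contributes one of each allele out of two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import (
    GENETIC_CODE,
    IUPAC_TO_ALLELES,
    STOP,
    DomainAnnotation,
    RegionMap,
    SequenceRecord,
    SubstitutionMatrix,
    strip_haplotype,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BIOCHEM_CLASSES",
    "SnpRecord",
    "call_genotypes",
    "site_allele_frequencies",
    "frequency_difference",
    "classify_region",
    "annotate_effect",
    "score_substitution",
    "biochem_change",
    "annotate_domains",
    "map_residue",
    "build_snp_table",
    "summarize_snps",
    "SNP_TABLE_COLUMNS",
]

#: Fixed amino-acid biochemical partition used to flag property changes.
BIOCHEM_CLASSES: Mapping[str, str] = {
    **{aa: "positively_charged" for aa in "RHK"},
    **{aa: "negatively_charged" for aa in "DE"},
    **{aa: "polar_uncharged" for aa in "STNQCY"},
    **{aa: "hydrophobic" for aa in "AVILMFW"},
    **{aa: "special" for aa in "GP"},
}


@dataclass
class SnpRecord:
    """One variant site with group frequencies and functional annotation."""

    gene_id: str
    isotig_id: str
    bp_pos: int                      # CDS-relative for CDS sites, else region-relative
    region: str                      # 5UTR / CDS / 3UTR
    alleles: str                     # e.g. "A/G"; designated allele listed second
    designated_allele: str
    freq_blue: float
    freq_orange: float
    freq_diff: float
    effect: str                      # synonymous / nonsynonymous / NA
    aa_pos: int | None = None
    aa_from: str = ""
    aa_to: str = ""
    blosum62: int | None = None
    biochem_from: str = ""
    biochem_to: str = ""
    biochem_changed: bool | None = None
    domain_hits: list = field(default_factory=list)
    color_differentiating: bool = False
    phase_assumed: bool = False


SNP_TABLE_COLUMNS = [
    "gene_id", "isotig_id", "bp_pos", "region", "alleles", "designated_allele",
    "freq_blue", "freq_orange", "freq_diff", "effect", "aa_pos", "aa_from",
    "aa_to", "blosum62", "biochem_from", "biochem_to", "biochem_changed",
    "domain_hits", "color_differentiating", "phase_assumed",
]


def call_genotypes(records: Sequence[SequenceRecord], sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Collapse aligned sequences into per-site, per-sample allele sets.

    Returns a DataFrame indexed by 1-based alignment position with one
    column per sample; cells hold frozensets of plain bases (singleton =
    fixed, two = heterozygote) or ``None`` when masked (gap, N, or an
    ambiguity code implying more than two alleles).
    """
    sheet_samples = set(sample_sheet["sample_id"])
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("aligned sequences have unequal lengths")
    (length,) = lengths

    by_sample: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        sample = rec.sample_id or strip_haplotype(rec.id)
        if sample not in sheet_samples:
            raise ValueError(f"record {rec.id!r}: sample {sample!r} not in sample sheet")
        by_sample.setdefault(sample, []).append(rec)

    columns = {}
    for sample, recs in by_sample.items():
        if len(recs) == 1:
            seq = recs[0].sequence
            calls = [_call_from_code(ch) for ch in seq]
        elif len(recs) == 2:
            h1, h2 = sorted(recs, key=lambda r: r.id)
            if len(h1.sequence) != len(h2.sequence):
                raise ValueError(f"haplotype pair for sample {sample!r} has unequal lengths")
            calls = [_call_from_pair(a, b) for a, b in zip(h1.sequence, h2.sequence)]
        else:
            raise ValueError(f"sample {sample!r} has {len(recs)} records; expected 1 or 2")
        columns[sample] = calls

    gt = pd.DataFrame(columns, index=pd.RangeIndex(1, length + 1, name="aln_pos"))
    return gt


def _call_from_code(ch: str):
    if ch == "-":
        return None
    alleles = IUPAC_TO_ALLELES.get(ch)
    if alleles is None or len(alleles) > 2:
        return None
    return alleles


def _call_from_pair(a: str, b: str):
    ea = IUPAC_TO_ALLELES.get(a) if a != "-" else None
    eb = IUPAC_TO_ALLELES.get(b) if b != "-" else None
    if ea is None or eb is None or len(ea) > 1 or len(eb) > 1:
        return None
    return frozenset(ea | eb)


def site_allele_frequencies(calls: Iterable) -> dict:
    """Allele frequencies at one site over unmasked samples.

    A fixed sample contributes 2 copies of its allele, a heterozygote 1 of
    each; frequencies over segregating alleles sum to 1.
    """
    counts: dict[str, float] = {}
    n_unmasked = 0
    for call in calls:
        if call is None:
            continue
        n_unmasked += 1
        if len(call) == 1:
            (a,) = call
            counts[a] = counts.get(a, 0) + 2
        else:
            for a in call:
                counts[a] = counts.get(a, 0) + 1
    if n_unmasked == 0:
        raise ValueError("all samples masked at site")
    total = 2 * n_unmasked
    return {a: c / total for a, c in counts.items()}


def frequency_difference(freq_blue: float, freq_orange: float) -> float:
    """Absolute difference in the designated allele's frequency."""
    return abs(freq_blue - freq_orange)


def classify_region(aln_pos: int, region_map: RegionMap) -> tuple:
    """Locate an alignment position: region label plus CDS-relative detail.

    For CDS sites returns ``(region, cds_offset, codon_index, codon_pos)``,
    all 1-based; for UTR sites the last three are ``None``.
    """
    if region_map.utr5 and region_map.utr5[0] <= aln_pos <= region_map.utr5[1]:
        return ("5UTR", None, None, None)
    if region_map.cds[0] <= aln_pos <= region_map.cds[1]:
        offset = aln_pos - region_map.cds[0] + 1
        codon_index = math.ceil(offset / 3)
        codon_pos = (offset - 1) % 3 + 1
        return ("CDS", offset, codon_index, codon_pos)
    if region_map.utr3 and region_map.utr3[0] <= aln_pos <= region_map.utr3[1]:
        return ("3UTR", None, None, None)
    raise ValueError(f"position {aln_pos} outside all regions of {region_map.gene_id}")


@dataclass(frozen=True)
class EffectAnnotation:
    effect: str                       # synonymous / nonsynonymous / NA
    aa_pos: int | None
    aa_states: tuple                  # (aa_from, aa_to) per-allele order, or all states
    allele_to_aa: Mapping[str, str]
    phase_assumed: bool = False


def _majority_allele(calls: Iterable) -> str | None:
    freqs = {}
    for call in calls:
        if call is None:
            continue
        for a in call:
            freqs[a] = freqs.get(a, 0) + (2 if len(call) == 1 else 1)
    if not freqs:
        return None
    return max(sorted(freqs), key=lambda a: freqs[a])


def annotate_effect(gt: pd.DataFrame, aln_pos: int, region_map: RegionMap,
                    genetic_code: Mapping[str, str] = GENETIC_CODE) -> EffectAnnotation:
    """Classify a CDS site as synonymous / non-synonymous / NA.

    Each allele's codon is completed with the carrying sample's own calls
    at the other two codon positions; when a sample is heterozygous there
    too, the group-majority allele is used and the result is flagged
    ``phase_assumed``.  More than two amino-acid states (or a masked codon
    position) yields effect NA.
    """
    region, offset, codon_index, codon_pos = classify_region(aln_pos, region_map)
    if region != "CDS":
        raise ValueError(f"position {aln_pos} is not in the CDS")
    codon_start = region_map.cds[0] + (codon_index - 1) * 3
    codon_positions = [codon_start, codon_start + 1, codon_start + 2]

    site_calls = gt.loc[aln_pos]
    alleles = sorted(set().union(*[c for c in site_calls if c is not None]) if any(
        c is not None for c in site_calls) else set())
    phase_assumed = False
    allele_to_aa: dict[str, str] = {}
    for allele in alleles:
        carrier = None
        for sample in gt.columns:
            call = site_calls[sample]
            if call is not None and allele in call:
                carrier = sample
                break
        codon = []
        masked = False
        for pos in codon_positions:
            if pos == aln_pos:
                codon.append(allele)
                continue
            call = gt.at[pos, carrier] if carrier is not None else None
            if call is None:
                maj = _majority_allele(gt.loc[pos])
                if maj is None:
                    masked = True
                    break
                codon.append(maj)
                phase_assumed = True
            elif len(call) == 1:
                (base,) = call
                codon.append(base)
            else:
                maj = _majority_allele(gt.loc[pos])
                codon.append(maj if maj in call else sorted(call)[0])
                phase_assumed = True
        if masked:
            return EffectAnnotation("NA", codon_index, (), {}, phase_assumed)
        allele_to_aa[allele] = genetic_code["".join(codon)]

    states = sorted(set(allele_to_aa.values()))
    if len(states) > 2:
        return EffectAnnotation("NA", codon_index, tuple(states), allele_to_aa, phase_assumed)
    effect = "synonymous" if len(states) == 1 else "nonsynonymous"
    return EffectAnnotation(effect, codon_index, tuple(states), allele_to_aa, phase_assumed)


def score_substitution(aa_from: str, aa_to: str, matrix: SubstitutionMatrix) -> int | None:
    """Symmetric substitution-matrix lookup; ``None`` when a stop is involved."""
    if STOP in (aa_from, aa_to):
        logger.warning("stop codon involved in substitution (%s,%s); score NA", aa_from, aa_to)
        return None
    return matrix.score(aa_from, aa_to)


def biochem_change(aa_from: str, aa_to: str) -> tuple:
    """(class_from, class_to, changed) under the fixed biochemical partition."""
    cf = BIOCHEM_CLASSES[aa_from]
    ct = BIOCHEM_CLASSES[aa_to]
    return cf, ct, cf != ct


def annotate_domains(aa_pos: int, domains: Iterable[DomainAnnotation],
                     gene_id: str | None = None) -> list:
    """All domain annotations whose interval contains the residue."""
    hits = []
    for dom in domains:
        if gene_id is not None and dom.gene_id != gene_id:
            continue
        if dom.contains(aa_pos):
            hits.append(dom)
    return hits


def map_residue(aa_pos_local: int, offset: int) -> int:
    """Translate a local residue number into a reference numbering.

    reference = local − offset (e.g. offset +2 maps the local alignment
    numbering onto the *Vitis vinifera* reference).
    """
    ref = aa_pos_local - offset
    if ref < 1:
        raise ValueError(f"residue {aa_pos_local} maps to non-positive reference {ref}")
    return ref


def _designate_allele(freqs_all: Mapping[str, float]) -> str:
    """Designate the overall-minor allele (ties: lexicographically last)."""
    return min(sorted(freqs_all, reverse=True), key=lambda a: freqs_all[a])


def _records_for_alignment(gene_id: str, isotig_id: str, gt: pd.DataFrame,
                           groups: pd.Series, region_map: RegionMap,
                           domains, matrix, min_diff: float) -> list:
    # pooled matrices carry "sample#iK" columns: one observation per isotig
    blue = [s for s in gt.columns if groups.get(str(s).split("#")[0]) == "blue"]
    orange = [s for s in gt.columns if groups.get(str(s).split("#")[0]) == "orange"]
    records = []
    for aln_pos in gt.index:
        calls = gt.loc[aln_pos]
        unmasked = [c for c in calls if c is not None]
        if not unmasked:
            logger.info("%s %s: site %d fully masked, dropped", gene_id, isotig_id, aln_pos)
            continue
        alleles = sorted(set().union(*unmasked))
        if len(alleles) < 2:
            continue  # invariant column
        try:
            freqs_all = site_allele_frequencies(calls)
            freqs_blue = site_allele_frequencies(calls[blue]) if blue else {}
            freqs_orange = site_allele_frequencies(calls[orange]) if orange else {}
        except ValueError:
            logger.info("%s %s: site %d masked in one group, dropped", gene_id, isotig_id, aln_pos)
            continue
        designated = _designate_allele(freqs_all)
        fb = freqs_blue.get(designated, 0.0)
        fo = freqs_orange.get(designated, 0.0)
        diff = frequency_difference(fb, fo)

        region, offset, codon_index, _ = classify_region(aln_pos, region_map)
        bp_pos = offset if region == "CDS" else aln_pos
        effect, aa_pos, aa_from, aa_to = "NA", None, "", ""
        blosum = None
        bf = bt = ""
        changed = None
        hits: list = []
        phase = False
        if region == "CDS":
            ann = annotate_effect(gt, aln_pos, region_map)
            effect, aa_pos, phase = ann.effect, ann.aa_pos, ann.phase_assumed
            if effect == "nonsynonymous":
                aa_from, aa_to = ann.aa_states
                blosum = score_substitution(aa_from, aa_to, matrix) if matrix else None
                if STOP not in (aa_from, aa_to):
                    bf, bt, changed = biochem_change(aa_from, aa_to)
            elif effect == "synonymous":
                aa_from = aa_to = ann.aa_states[0]
            if aa_pos is not None and domains:
                hits = [d.name for d in annotate_domains(aa_pos, domains, gene_id)]

        records.append(SnpRecord(
            gene_id=gene_id, isotig_id=isotig_id, bp_pos=bp_pos, region=region,
            alleles="/".join(alleles), designated_allele=designated,
            freq_blue=fb, freq_orange=fo, freq_diff=diff, effect=effect,
            aa_pos=aa_pos, aa_from=aa_from, aa_to=aa_to, blosum62=blosum,
            biochem_from=bf, biochem_to=bt, biochem_changed=changed,
            domain_hits=hits, color_differentiating=diff >= min_diff,
            phase_assumed=phase,
        ))
    return records


def build_snp_table(alignments: Mapping[str, Sequence[SequenceRecord]],
                    sample_sheet: pd.DataFrame,
                    region_maps: Mapping[str, RegionMap],
                    domains: Iterable[DomainAnnotation] = (),
                    matrix: SubstitutionMatrix | None = None,
                    min_diff: float = 0.25,
                    isotig_to_gene: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Evaluate every segregating site across per-isotig alignments.

    ``alignments`` maps isotig id -> sequence records; ``isotig_to_gene``
    (default: identity) groups isotigs under genes, which must have a
    region map.  Genes with several isotigs additionally get pooled
    records (isotig_id ``"pooled"``) with allele counts summed across
    isotigs.  Sites with ``freq_diff >= min_diff`` are flagged
    color-differentiating.
    """
    groups = sample_sheet.set_index("sample_id")["phenotype"]
    rows: list[SnpRecord] = []
    by_gene: dict[str, list] = {}
    for isotig_id, records in alignments.items():
        gene_id = (isotig_to_gene or {}).get(isotig_id, isotig_id)
        region_map = region_maps.get(gene_id)
        if region_map is None:
            logger.warning("isotig %s: gene %s has no region map, skipped", isotig_id, gene_id)
            continue
        gt = call_genotypes(records, sample_sheet)
        rows.extend(_records_for_alignment(
            gene_id, isotig_id, gt, groups, region_map, domains, matrix, min_diff))
        by_gene.setdefault(gene_id, []).append(gt)

    for gene_id, gts in by_gene.items():
        if len(gts) < 2:
            continue
        pooled = _pool_genotypes(gts)
        rows.extend(_records_for_alignment(
            gene_id, "pooled", pooled, groups, region_maps[gene_id],
            domains, matrix, min_diff))

    df = pd.DataFrame([{c: getattr(r, c) for c in SNP_TABLE_COLUMNS} for r in rows],
                      columns=SNP_TABLE_COLUMNS)
    return df


def _pool_genotypes(gts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-isotig genotype matrices as extra observations per sample."""
    lengths = {len(g.index) for g in gts}
    if len(lengths) != 1:
        raise ValueError("cannot pool isotigs with different alignment lengths")
    columns = {}
    for k, gt in enumerate(gts):
        for sample in gt.columns:
            columns[f"{sample}#i{k}"] = list(gt[sample])
    pooled = pd.DataFrame(columns, index=gts[0].index)
    return pooled


def summarize_snps(snp_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary: counts by region/effect, freq-diff range, variability.

    A site counts as variable in a group when at least one sample in that
    group is heterozygous or the group segregates for more than one allele
    (frequency strictly between 0 and 1).
    """
    if snp_table.empty:
        return pd.DataFrame(columns=[
            "gene_id", "n_snps", "n_5utr", "n_cds", "n_3utr", "n_synonymous",
            "n_nonsynonymous", "n_effect_na", "min_freq_diff", "mean_freq_diff",
            "max_freq_diff", "n_variable_blue", "frac_variable_blue",
            "n_variable_orange", "frac_variable_orange"])
    rows = []
    for gene_id, sub in snp_table.groupby("gene_id", sort=True):
        per_isotig = sub[sub["isotig_id"] != "pooled"]
        if per_isotig.empty:
            per_isotig = sub
        var_blue = ((per_isotig["freq_blue"] > 0) & (per_isotig["freq_blue"] < 1)).sum()
        var_orange = ((per_isotig["freq_orange"] > 0) & (per_isotig["freq_orange"] < 1)).sum()
        n = len(per_isotig)
        rows.append({
            "gene_id": gene_id,
            "n_snps": n,
            "n_5utr": (per_isotig["region"] == "5UTR").sum(),
            "n_cds": (per_isotig["region"] == "CDS").sum(),
            "n_3utr": (per_isotig["region"] == "3UTR").sum(),
            "n_synonymous": (per_isotig["effect"] == "synonymous").sum(),
            "n_nonsynonymous": (per_isotig["effect"] == "nonsynonymous").sum(),
            "n_effect_na": (per_isotig["effect"] == "NA").sum(),
            "min_freq_diff": per_isotig["freq_diff"].min(),
            "mean_freq_diff": per_isotig["freq_diff"].mean(),
            "max_freq_diff": per_isotig["freq_diff"].max(),
            "n_variable_blue": int(var_blue),
            "frac_variable_blue": var_blue / n if n else 0.0,
            "n_variable_orange": int(var_orange),
            "frac_variable_orange": var_orange / n if n else 0.0,
        })
    return pd.DataFrame(rows)
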