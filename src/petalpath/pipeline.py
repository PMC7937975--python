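"""Pipeline orchestration: simulate -> expression -> snps -> paralogs -> report.

A single INI-style config (sections ``[simulate]``, ``[expression]``,
``[snps]``, ``[paralogs]``, ``[output]``) drives all stages.  Runs are
deterministic for a fixed config + seed; every stage logs its record
counts into a machine-readable JSON run report next to the TSV outputs.
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import (
    DegThresholds,
    call_degs,
    format_fold_ratio,
    fold_ratio,
    normalize_expression,
    pathway_summary,
    scale_for_heatmap,
    tmm_factors,
)
from .io import (
    load_domains,
    load_panel,
    load_substitution_matrix,
    read_fasta,
    read_region_maps,
    read_sample_sheet,
    write_tsv,
)
from .paralogs import build_consensus, compare_paralogs, region_difference_count
from .simulate import SimulationConfig, write_simulation
from .snps import build_snp_table, summarize_snps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "emit_report", "load_config"]

ALL_STAGES = ("simulate", "expression", "snps", "paralogs", "report")


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage selection for one pipeline run."""

    output_dir: Path
    stages: tuple = ALL_STAGES
    seed: int = 0
    simulate: dict = dc_field(default_factory=dict)
    counts: Path | None = None
    samples: Path | None = None
    panel: Path | None = None
    fdr_max: float = 1e-5
    log2fc_min: float = 1.0
    aln_dir: Path | None = None
    regions: Path | None = None
    domains: Path | None = None
    min_diff: float = 0.25
    copy_a: Path | None = None
    copy_b: Path | None = None

    def validate(self) -> None:
        if "simulate" in self.stages:
            return  # simulate generates the downstream inputs
        checks = []
        if "expression" in self.stages:
            checks += [("counts", self.counts), ("samples", self.samples)]
        if "snps" in self.stages:
            checks += [("aln_dir", self.aln_dir), ("regions", self.regions),
                       ("samples", self.samples)]
        if "paralogs" in self.stages:
            checks += [("copy_a", self.copy_a), ("copy_b", self.copy_b)]
        for name, path in checks:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"stage input {name!r} missing: {path}")


def load_config(path) -> PipelineConfig:
    """Parse the plain-text key-value config file."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")

    out = parser["output"] if "output" in parser else {}
    cfg = PipelineConfig(
        output_dir=Path(out.get("dir", "petalpath_out")),
        stages=tuple(s.strip() for s in out.get("stages", ",".join(ALL_STAGES)).split(",")),
        seed=int(out.get("seed", 0)),
    )
    if "simulate" in parser:
        cfg.simulate = {k: v for k, v in parser["simulate"].items()}
    if "expression" in parser:
        sec = parser["expression"]
        cfg.counts = Path(sec["counts"]) if "counts" in sec else cfg.counts
        cfg.samples = Path(sec["samples"]) if "samples" in sec else cfg.samples
        cfg.panel = Path(sec["panel"]) if "panel" in sec else cfg.panel
        cfg.fdr_max = float(sec.get("fdr", cfg.fdr_max))
        cfg.log2fc_min = float(sec.get("lfc", cfg.log2fc_min))
    if "snps" in parser:
        sec = parser["snps"]
        cfg.aln_dir = Path(sec["aln_dir"]) if "aln_dir" in sec else cfg.aln_dir
        cfg.regions = Path(sec["regions"]) if "regions" in sec else cfg.regions
        cfg.domains = Path(sec["domains"]) if "domains" in sec else cfg.domains
        cfg.samples = Path(sec["samples"]) if "samples" in sec else cfg.samples
        cfg.min_diff = float(sec.get("min_diff", cfg.min_diff))
    if "paralogs" in parser:
        sec = parser["paralogs"]
        cfg.copy_a = Path(sec["copy_a"]) if "copy_a" in sec else cfg.copy_a
        cfg.copy_b = Path(sec["copy_b"]) if "copy_b" in sec else cfg.copy_b
        cfg.domains = Path(sec["domains"]) if "domains" in sec else cfg.domains
    return cfg


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    kwargs: dict = {"seed": cfg.seed}
    conv = {
        "n_per_group": int, "n_genes": int, "dispersion": float,
        "de_fraction": float, "de_log2fc": float, "gene_length_bp": int,
        "utr5_bp": int, "utr3_bp": int, "n_fixed_nonsyn": int,
        "n_group_variable": int, "het_rate": float, "n_utr_snps": int,
        "seed": int,
    }
    for key, value in cfg.simulate.items():
        if key in conv:
            kwargs[key] = conv[key](value)
        elif key == "library_size_range":
            lo, hi = value.split(",")
            kwargs[key] = (int(lo), int(hi))
        elif key == "paralog":
            parts = [int(x) for x in value.split(",")]
            kwargs[key] = tuple(parts) if parts else None
        elif key == "haplotype_pairs":
            kwargs[key] = value.lower() in ("1", "true", "yes")
    return SimulationConfig(**kwargs)


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run the requested stages in dependency order.

    Returns the run report (also written as ``run_report.json``).  On a
    stage failure the partially written outputs are renamed with a
    ``.partial`` suffix and the error re-raised.
    """
    cfg = load_config(config) if not isinstance(config, PipelineConfig) else config
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")

    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "fdr_max": cfg.fdr_max, "log2fc_min": cfg.log2fc_min,
            "min_diff": cfg.min_diff,
        },
        "stages": {},
    }
    written: list[Path] = []

    def record(stage: str, t0: float, **counts):
        report["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3), **counts}

    try:
        if "simulate" in cfg.stages:
            t0 = time.time()
            sim_cfg = _simulation_config(cfg)
            paths = write_simulation(sim_cfg, outdir / "simulated")
            cfg.counts = cfg.counts or paths["counts"]
            cfg.samples = cfg.samples or paths["samples"]
            cfg.panel = cfg.panel or paths["panel"]
            cfg.aln_dir = cfg.aln_dir or paths["alignments"]
            cfg.regions = cfg.regions or paths["regions"]
            cfg.domains = cfg.domains or paths["domains"]
            cfg.copy_a = cfg.copy_a or (paths["alignments"] / "DFR1_like.fasta")
            cfg.copy_b = cfg.copy_b or (paths["alignments"] / "DFR2_like.fasta")
            record("simulate", t0, files=len(paths))

        if "expression" in cfg.stages:
            t0 = time.time()
            counts = pd.read_csv(cfg.counts, sep="\t", comment="#", index_col=0)
            samples = read_sample_sheet(cfg.samples)
            panel = load_panel(cfg.panel) if cfg.panel else None
            thresholds = DegThresholds(fdr_max=cfg.fdr_max, log2fc_min=cfg.log2fc_min)
            degs = call_degs(counts, samples, panel=panel, thresholds=thresholds)
            deg_path = outdir / "deg_table.tsv"
            write_tsv(degs, deg_path)
            written.append(deg_path)
            factors = tmm_factors(counts)
            expr = normalize_expression(counts, factors)
            scaled = scale_for_heatmap(expr.values.loc[degs.loc[degs["is_deg"], "gene_id"]])
            scaled_path = outdir / "scaled_matrix.tsv"
            scaled.rename_axis("gene_id").reset_index().to_csv(scaled_path, sep="\t", index=False)
            written.append(scaled_path)
            record("expression", t0, n_genes=len(degs), n_degs=int(degs["is_deg"].sum()))

        if "snps" in cfg.stages:
            t0 = time.time()
            samples = read_sample_sheet(cfg.samples)
            region_maps = read_region_maps(cfg.regions)
            domains = load_domains(cfg.domains) if cfg.domains else []
            matrix = load_substitution_matrix("BLOSUM62")
            alignments = {}
            for fasta in sorted(Path(cfg.aln_dir).glob("*.fasta")):
                if fasta.stem in region_maps:
                    alignments[fasta.stem] = read_fasta(fasta)
            snp_table = build_snp_table(alignments, samples, region_maps,
                                        domains=domains, matrix=matrix,
                                        min_diff=cfg.min_diff)
            snp_path = outdir / "snp_table.tsv"
            write_tsv(snp_table, snp_path)
            written.append(snp_path)
            summary = summarize_snps(snp_table)
            sum_path = outdir / "snp_summary.tsv"
            write_tsv(summary, sum_path)
            written.append(sum_path)
            record("snps", t0, n_sites=len(snp_table),
                   n_color_differentiating=int(snp_table["color_differentiating"].sum())
                   if len(snp_table) else 0)

        if "paralogs" in cfg.stages:
            t0 = time.time()
            recs_a = read_fasta(cfg.copy_a)
            recs_b = read_fasta(cfg.copy_b)
            cons_a = build_consensus(recs_a, gene_id=Path(cfg.copy_a).stem)
            cons_b = build_consensus(recs_b, gene_id=Path(cfg.copy_b).stem)
            comparison = compare_paralogs(cons_a, cons_b)
            cmp_path = outdir / "paralog_comparison.tsv"
            write_tsv(comparison.table, cmp_path)
            written.append(cmp_path)
            domains = load_domains(cfg.domains) if cfg.domains else []
            rows = []
            for dom in domains:
                if dom.gene_id not in (cons_a.gene_id, cons_b.gene_id):
                    continue
                rows.append({
                    "gene_id": dom.gene_id, "domain": dom.name,
                    "start_aa": dom.start_aa, "end_aa": dom.end_aa,
                    "n_fixed_differences": region_difference_count(comparison, dom),
                })
            dom_path = outdir / "paralog_domain_counts.tsv"
            write_tsv(pd.DataFrame(rows, columns=[
                "gene_id", "domain", "start_aa", "end_aa", "n_fixed_differences"]), dom_path)
            written.append(dom_path)
            record("paralogs", t0,
                   n_residues=len(comparison.table),
                   n_fixed_differences=comparison.n_fixed_differences)

        if "report" in cfg.stages:
            t0 = time.time()
            report_md = emit_report(outdir)
            (outdir / "report.md").write_text(report_md)
            record("report", t0, n_chars=len(report_md))
    except Exception:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def emit_report(outdir) -> str:
    """Render a Markdown summary from the stage outputs present in outdir.

    The DEG table is sorted ascending by log2FC; the SNP section is grouped
    by gene with BLOSUM62 and biochemistry columns; regeneration is
    idempotent.
    """
    outdir = Path(outdir)
    lines = ["# petalpath run report", ""]

    deg_path = outdir / "deg_table.tsv"
    if deg_path.exists():
        degs = pd.read_csv(deg_path, sep="\t")
        deg_rows = degs[degs["is_deg"]].sort_values("log2fc", kind="mergesort")
        lines += ["## Differential expression", "",
                  f"{len(deg_rows)} DEGs out of {len(degs)} genes "
                  f"({(deg_rows['direction'] == 'B>O').sum()} B>O, "
                  f"{(deg_rows['direction'] == 'O>B').sum()} O>B).", ""]
        if len(deg_rows):
            lines += ["| Gene | TMM blue | TMM orange | log2FC | FDR | Pathway | Fold |",
                      "|---|---|---|---|---|---|---|"]
            for _, row in deg_rows.iterrows():
                hi, lo = ((row["mean_tmm_blue"], row["mean_tmm_orange"])
                          if row["log2fc"] > 0
                          else (row["mean_tmm_orange"], row["mean_tmm_blue"]))
                lines.append(
                    f"| {row['gene_id']} | {row['mean_tmm_blue']:.2f} "
                    f"| {row['mean_tmm_orange']:.2f} | {row['log2fc']:.2f} "
                    f"| {row['fdr']:.3g} | {row['category']} "
                    f"| {format_fold_ratio(fold_ratio(hi, lo))} |")
            lines.append("")

    snp_path = outdir / "snp_table.tsv"
    if snp_path.exists():
        snps = pd.read_csv(snp_path, sep="\t")
        lines += ["## Color-differentiating SNPs", ""]
        flagged = snps[snps["color_differentiating"]] if len(snps) else snps
        if len(flagged) == 0:
            lines += ["no color-differentiating SNPs", ""]
        else:
            for gene, sub in flagged.groupby("gene_id"):
                lines += [f"### {gene}", "",
                          "| Site | Region | Alleles | freq B | freq O | Δfreq "
                          "| Effect | AA | BLOSUM62 | Biochemistry | Domains |",
                          "|---|---|---|---|---|---|---|---|---|---|---|"]
                for _, row in sub.iterrows():
                    aa = (f"{row['aa_from']}{int(row['aa_pos'])}{row['aa_to']}"
                          if row["effect"] == "nonsynonymous" else "")
                    biochem = (f"{row['biochem_from']}→{row['biochem_to']}"
                               if isinstance(row.get("biochem_from"), str)
                               and row.get("biochem_from") else "")
                    blosum = ("NA" if pd.isna(row["blosum62"])
                              else str(int(row["blosum62"])))
                    lines.append(
                        f"| {int(row['bp_pos'])} | {row['region']} | {row['alleles']} "
                        f"| {row['freq_blue']:.2f} | {row['freq_orange']:.2f} "
                        f"| {row['freq_diff']:.2f} | {row['effect']} | {aa} "
                        f"| {blosum} | {biochem} | {row['domain_hits']} |")
                lines.append("")

    cmp_path = outdir / "paralog_domain_counts.tsv"
    if cmp_path.exists():
        doms = pd.read_csv(cmp_path, sep="\t")
        lines += ["## Paralog domain comparison", ""]
        if len(doms) == 0:
            lines += ["no domain annotations", ""]
        else:
            for _, row in doms.iterrows():
                length = row["end_aa"] - row["start_aa"] + 1
                lines.append(
                    f"- {row['gene_id']} {row['domain']} "
                    f"[{row['start_aa']}–{row['end_aa']}]: "
                    f"{row['n_fixed_differences']} of {length} residues fixed-different")
            lines.append("")
    return "\n".join(lines) + "\n"
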