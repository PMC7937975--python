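"""Readers, writers and reference tables shared by every pipeline stage.

Sequences travel as :class:`SequenceRecord` lists read from FASTA; tabular
inputs (sample sheet, domain annotations, gene panel, region maps) are
tab-separated UTF-8 with one header row, ``#`` lines ignored.  The standard
genetic code and the BLOSUM62 substitution matrix ship with the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "IUPAC_ALPHABET",
    "IUPAC_TO_ALLELES",
    "GENETIC_CODE",
    "STOP",
    "SequenceRecord",
    "SubstitutionMatrix",
    "DomainAnnotation",
    "RegionMap",
    "PANEL_CATEGORIES",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_substitution_matrix",
    "load_domains",
    "write_domains",
    "load_panel",
    "write_panel",
    "read_region_maps",
    "write_region_maps",
    "read_tsv",
    "write_tsv",
]

#: IUPAC nucleotide one-letter codes accepted in alignment inputs.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Expansion of each IUPAC code into the set of plain bases it denotes.
IUPAC_TO_ALLELES: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Reverse map: a two-base allele set to its IUPAC ambiguity code.
ALLELES_TO_IUPAC = {v: k for k, v in IUPAC_TO_ALLELES.items() if len(v) == 2}

STOP = "*"

PANEL_CATEGORIES = ("ABP", "nonABP", "regulatory")

PHENOTYPES = ("blue", "orange")


def _standard_genetic_code() -> dict:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = STOP
    assert len(code) == 64
    return code


#: Standard genetic code: codon (DNA, upper case) -> amino-acid letter or '*'.
GENETIC_CODE: Mapping[str, str] = _standard_genetic_code()


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned per-sample sequence.

    ``id`` encodes the sample and, optionally, a haplotype index as a
    ``/1`` / ``/2`` suffix; ``sample_id`` is the id with any haplotype
    suffix stripped.
    """

    id: str
    sequence: str
    sample_id: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"sequence record {self.id!r} is empty")
        if not self.sample_id:
            object.__setattr__(self, "sample_id", strip_haplotype(self.id))

    @property
    def haplotype(self) -> int | None:
        if self.id.endswith(("/1", "/2")):
            return int(self.id[-1])
        return None


def strip_haplotype(record_id: str) -> str:
    if record_id.endswith(("/1", "/2")):
        return record_id[:-2]
    return record_id


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Lowercase is normalized to uppercase; the header token before the first
    whitespace becomes the record id.  Characters outside the IUPAC
    nucleotide alphabet (plus ``-``) raise a ``ValueError`` naming the
    record and the 1-based offset of the first offending character.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path}: malformed FASTA, first record lacks '>' header")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_ALPHABET:
                raise ValueError(
                    f"{path}: record {rec.id!r} has illegal character "
                    f"{ch!r} at position {i + 1}"
                )
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet: columns ``sample_id``, ``phenotype`` (blue/orange)."""
    df = read_tsv(path)
    missing = {"sample_id", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"{path}: unknown phenotype(s) {sorted(bad)}")
    for pheno in PHENOTYPES:
        if not (df["phenotype"] == pheno).any():
            raise ValueError(f"{path}: no samples with phenotype {pheno!r}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    write_tsv(df[["sample_id", "phenotype"]], path)


class SubstitutionMatrix:
    """Symmetric amino-acid substitution score matrix (e.g. BLOSUM62)."""

    def __init__(self, scores: Mapping[tuple, int], alphabet: str):
        self.alphabet = alphabet
        self._scores = dict(scores)
        for a in alphabet:
            for b in alphabet:
                if (a, b) not in self._scores or (b, a) not in self._scores:
                    raise ValueError(f"substitution matrix incomplete: missing ({a},{b})")
                if self._scores[(a, b)] != self._scores[(b, a)]:
                    raise ValueError(f"substitution matrix asymmetric at ({a},{b})")

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"pair ({a},{b}) not in substitution matrix") from None

    def __contains__(self, letter: str) -> bool:
        return letter in self.alphabet


def _parse_ncbi_matrix(text: str) -> SubstitutionMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    columns = lines[0].split()
    scores = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        values = parts[1:]
        if len(values) != len(columns):
            raise ValueError(f"matrix row {row!r} has {len(values)} values, expected {len(columns)}")
        for col, val in zip(columns, values):
            scores[(row, col)] = int(val)
    return SubstitutionMatrix(scores, alphabet="".join(columns))


def load_substitution_matrix(path_or_name="BLOSUM62") -> SubstitutionMatrix:
    """Load an NCBI whitespace-delimited matrix, or the built-in BLOSUM62."""
    if str(path_or_name) == "BLOSUM62":
        text = (importlib.resources.files("petalpath") / "data" / "BLOSUM62.txt").read_text()
    else:
        text = Path(path_or_name).read_text()
    return _parse_ncbi_matrix(text)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named amino-acid interval, 1-based inclusive coordinates."""

    gene_id: str
    name: str
    start_aa: int
    end_aa: int
    source: str = ""

    def __post_init__(self):
        if self.start_aa < 1:
            raise ValueError(f"domain {self.name!r}: start_aa must be >= 1")
        if self.start_aa > self.end_aa:
            raise ValueError(
                f"domain {self.name!r}: start {self.start_aa} > end {self.end_aa}"
            )

    def __len__(self) -> int:
        return self.end_aa - self.start_aa + 1

    def contains(self, aa_pos: int) -> bool:
        return self.start_aa <= aa_pos <= self.end_aa


def load_domains(path) -> list[DomainAnnotation]:
    df = read_tsv(path)
    required = {"gene_id", "name", "start_aa", "end_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: domains table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(DomainAnnotation(
            gene_id=row["gene_id"], name=row["name"],
            start_aa=int(row["start_aa"]), end_aa=int(row["end_aa"]),
            source=row.get("source", ""),
        ))
    return out


def write_domains(domains: Iterable[DomainAnnotation], path) -> None:
    df = pd.DataFrame(
        [(d.gene_id, d.name, d.start_aa, d.end_aa, d.source) for d in domains],
        columns=["gene_id", "name", "start_aa", "end_aa", "source"],
    )
    write_tsv(df, path)


def load_panel(path) -> dict:
    """Panel map: gene_id -> category in {ABP, nonABP, regulatory}."""
    df = read_tsv(path)
    missing = {"gene_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel map missing columns {sorted(missing)}")
    panel = {}
    for _, row in df.iterrows():
        gene, cat = row["gene_id"], row["category"]
        if cat not in PANEL_CATEGORIES:
            raise ValueError(
                f"{path}: gene {gene!r} has unknown category {cat!r} "
                f"(expected one of {PANEL_CATEGORIES})"
            )
        if gene in panel:
            raise ValueError(f"{path}: gene {gene!r} assigned more than one category")
        panel[gene] = cat
    return panel


def write_panel(panel: Mapping[str, str], path) -> None:
    df = pd.DataFrame(sorted(panel.items()), columns=["gene_id", "category"])
    write_tsv(df, path)


@dataclass(frozen=True)
class RegionMap:
    """5'UTR / CDS / 3'UTR bounds on an alignment, 1-based inclusive.

    The reading frame starts at ``cds[0]``.  Empty UTRs are ``None``.
    """

    gene_id: str
    cds: tuple
    utr5: tuple | None = None
    utr3: tuple | None = None

    def __post_init__(self):
        regions = [r for r in (self.utr5, self.cds, self.utr3) if r is not None]
        for start, end in regions:
            if start < 1 or start > end:
                raise ValueError(f"{self.gene_id}: invalid region bounds ({start},{end})")
        for (_, e1), (s2, _) in zip(regions, regions[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.gene_id}: regions overlap or are out of order")

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0] + 1


def read_region_maps(path) -> dict:
    df = read_tsv(path)
    required = {"gene_id", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: region map missing columns {sorted(missing)}")

    def interval(row, prefix):
        s, e = row.get(f"{prefix}_start", ""), row.get(f"{prefix}_end", "")
        if s == "" or e == "" or int(s) == 0:
            return None
        return (int(s), int(e))

    out = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = RegionMap(
            gene_id=row["gene_id"],
            cds=(int(row["cds_start"]), int(row["cds_end"])),
            utr5=interval(row, "utr5"),
            utr3=interval(row, "utr3"),
        )
    return out


def write_region_maps(maps: Mapping[str, RegionMap], path) -> None:
    rows = []
    for gene, rm in maps.items():
        rows.append({
            "gene_id": gene,
            "utr5_start": rm.utr5[0] if rm.utr5 else 0,
            "utr5_end": rm.utr5[1] if rm.utr5 else 0,
            "cds_start": rm.cds[0], "cds_end": rm.cds[1],
            "utr3_start": rm.utr3[0] if rm.utr3 else 0,
            "utr3_end": rm.utr3[1] if rm.utr3 else 0,
        })
    write_tsv(pd.DataFrame(rows), path)
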