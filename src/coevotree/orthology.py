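"""Reciprocal-best-hit orthology from all-vs-all similarity hit tables.

Consumes precomputed BLAST-tabular (outfmt 6) hit tables; this package
does not run the similarity search itself.  Orthologs of a reference
protein in each genome are identified by the best bi-directional hit
criterion after E-value and alignment-coverage filtering (default:
E <= 1e-5 and >= 70% coverage of both query and subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "HIT_COLUMNS",
    "HitTable",
    "OrthologTable",
    "read_hits",
    "filter_hits",
    "reciprocal_best_hits",
    "build_ortholog_table",
]

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_openings",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "e_value",
    "bit_score",
]

_NUMERIC = {
    "percent_identity": float,
    "alignment_length": int,
    "mismatches": int,
    "gap_openings": int,
    "query_start": int,
    "query_end": int,
    "subject_start": int,
    "subject_end": int,
    "e_value": float,
    "bit_score": float,
}


@dataclass
class HitTable:
    """Parsed similarity hits plus genome assignments and sequence lengths."""

    df: pd.DataFrame
    sequence_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def read_hits(source, genome_of: Mapping[str, str], sequence_lengths: Mapping[str, int] | None = None) -> HitTable:
    """Parse a 12-column tab-separated hit table (BLAST outfmt-6 order).

    ``genome_of`` must resolve every protein id to its genome; malformed
    rows raise :class:`FormatError` with line numbers, unmappable proteins
    raise :class:`ConfigurationError`.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    records = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 12:
            raise FormatError(f"hits line {lineno}: expected 12 columns, got {len(parts)}")
        rec = dict(zip(HIT_COLUMNS, parts))
        try:
            for col, cast in _NUMERIC.items():
                rec[col] = cast(float(rec[col])) if cast is int else cast(rec[col])
        except ValueError as exc:
            raise FormatError(f"hits line {lineno}: {exc}") from exc
        if rec["e_value"] < 0:
            raise FormatError(f"hits line {lineno}: negative E-value")
        if rec["alignment_length"] < 1:
            raise FormatError(f"hits line {lineno}: alignment_length < 1")
        records.append(rec)
    df = pd.DataFrame(records, columns=HIT_COLUMNS)
    for col in ("query_id", "subject_id"):
        missing = set(df[col]) - set(genome_of)
        if missing:
            raise ConfigurationError(
                f"no genome assignment for protein(s): {sorted(missing)[:5]}"
            )
    df["query_genome"] = df["query_id"].map(genome_of)
    df["subject_genome"] = df["subject_id"].map(genome_of)
    return HitTable(df=df, sequence_lengths=dict(sequence_lengths or {}))


def filter_hits(hits: HitTable, e_max: float = 1e-5, coverage_min: float = 0.70) -> HitTable:
    """Keep hits with E <= ``e_max`` and coverage >= ``coverage_min`` on
    both query and subject (coverage = alignment_length / sequence_length)."""
    df = hits.df
    lengths = hits.sequence_lengths
    missing = (set(df["query_id"]) | set(df["subject_id"])) - set(lengths)
    if missing:
        raise ConfigurationError(
            f"missing sequence length for protein(s): {sorted(missing)[:5]}"
        )
    qlen = df["query_id"].map(lengths)
    slen = df["subject_id"].map(lengths)
    keep = (
        (df["e_value"] <= e_max)
        & (df["alignment_length"] / qlen >= coverage_min)
        & (df["alignment_length"] / slen >= coverage_min)
    )
    return HitTable(df=df[keep].reset_index(drop=True), sequence_lengths=lengths)


def _dedupe_hsps(df: pd.DataFrame) -> pd.DataFrame:
    # multiple HSPs per protein pair: keep the single lowest-E row
    # (ties: highest bit score)
    df = df.sort_values(
        ["query_id", "subject_id", "e_value", "bit_score"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    return df.drop_duplicates(["query_id", "subject_id"], keep="first")


def _best_hits(df: pd.DataFrame, from_genome: str, to_genome: str) -> dict[str, str]:
    sub = df[(df["query_genome"] == from_genome) & (df["subject_genome"] == to_genome)]
    if sub.empty:
        return {}
    sub = _dedupe_hsps(sub)
    # best = lowest E-value, tie-broken by highest bit score then subject id
    sub = sub.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = sub.drop_duplicates("query_id", keep="first")
    return dict(zip(best["query_id"], best["subject_id"]))


def reciprocal_best_hits(hits: HitTable, genome_a: str, genome_b: str) -> list[tuple[str, str]]:
    """Protein pairs (p in ``genome_a``, q in ``genome_b``) that are
    mutually each other's best hit.  Returns sorted pairs."""
    fwd = _best_hits(hits.df, genome_a, genome_b)
    rev = _best_hits(hits.df, genome_b, genome_a)
    return sorted((p, q) for p, q in fwd.items() if rev.get(q) == p)


@dataclass
class OrthologTable:
    """At most one ortholog per (reference protein, genome)."""

    reference_genome: str
    mapping: dict[tuple[str, str], str] = field(default_factory=dict)

    def ortholog(self, reference_protein: str, genome: str) -> str | None:
        return self.mapping.get((reference_protein, genome))

    def genomes_with_ortholog(self, reference_protein: str) -> list[str]:
        return sorted(g for (p, g) in self.mapping if p == reference_protein)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reference_protein": p, "genome": g, "ortholog": o}
            for (p, g), o in sorted(self.mapping.items())
        ]
        return pd.DataFrame(rows, columns=["reference_protein", "genome", "ortholog"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_ortholog_table(
    hits: HitTable, reference_genome: str, genome_set: Iterable[str]
) -> OrthologTable:
    """RBH orthologs of every reference-genome protein across ``genome_set``.

    The reference genome maps each of its proteins to itself; self-hits
    within the reference genome are ignored for RBH purposes.
    """
    genomes = sorted(set(genome_set))
    if reference_genome not in genomes:
        raise ValueError(f"reference genome {reference_genome!r} not in genome set")
    df = hits.df
    ref_proteins = sorted(
        set(df.loc[df["query_genome"] == reference_genome, "query_id"])
        | set(df.loc[df["subject_genome"] == reference_genome, "subject_id"])
    )
    table = OrthologTable(reference_genome=reference_genome)
    for p in ref_proteins:
        table.mapping[(p, reference_genome)] = p
    for g in genomes:
        if g == reference_genome:
            continue
        for p, q in reciprocal_best_hits(hits, reference_genome, g):
            table.mapping[(p, g)] = q
    return table
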