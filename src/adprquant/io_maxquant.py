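"""Reading and filtering MaxQuant ``proteinGroups.txt`` tables.

MaxQuant emits one row per inferred protein group, with corrected
reporter-ion intensities per TMT channel, peptide counts, and quality flags
("+" marks contaminants, reverse-database hits and proteins identified only
by a modification site).  This module parses those tables against a declared
:class:`~adprquant.layout.ExperimentLayout`, applies the protein-level
quality filters used throughout the analysis, and annotates proteins against
a reference list of known ADP-ribosylated proteins (ADPriboDB-style).

Filtering rules, applied in order (a protein is counted once, under the
first rule that removes it):

1. potential contaminant;
2. reverse-database hit;
3. identified only by site;
4. fewer than ``min_peptides`` peptides (default 2);
5. a zero (or missing) reporter intensity in any declared channel of any
   replicate.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .layout import ExperimentLayout

logger = logging.getLogger(__name__)

_ISOFORM_RE = re.compile(r"-\d+$")


class ColumnError(KeyError):
    """A required proteinGroups column is missing."""


class RowParseError(ValueError):
    """A numeric cell could not be parsed; carries the offending row index."""


@dataclass
class ColumnDialect:
    """Resolves proteinGroups column names across MaxQuant versions.

    MaxQuant names reporter columns ``Reporter intensity corrected <i>`` for
    a single experiment, or ``Reporter intensity corrected <i> <experiment>``
    when experiments are declared.  With several replicates the experiment
    name defaults to the replicate id.
    """

    intensity_template: str = "Reporter intensity corrected {channel}"
    experiment_for_replicate: dict[str, str] | None = None
    peptide_column: str = "Peptides"  # alternative: "Razor + unique peptides"
    protein_ids_column: str = "Protein IDs"
    gene_names_column: str = "Gene names"
    contaminant_column: str = "Potential contaminant"
    reverse_column: str = "Reverse"
    only_by_site_column: str = "Only identified by site"

    def intensity_column(self, replicate: str, channel_index: int, n_replicates: int) -> str:
        base = self.intensity_template.format(channel=channel_index)
        if n_replicates == 1 and self.experiment_for_replicate is None:
            return base
        exp = (self.experiment_for_replicate or {}).get(replicate, replicate)
        return f"{base} {exp}"


@dataclass
class ProteinRecord:
    """One protein group with its quality flags and reporter intensities."""

    protein_ids: tuple[str, ...]
    gene_names: tuple[str, ...]
    peptide_count: int
    is_contaminant: bool
    is_reverse: bool
    is_only_by_site: bool
    reporter_intensities: dict[tuple[str, int], float]

    @property
    def primary_accession(self) -> str:
        return self.protein_ids[0]


@dataclass
class FilterReport:
    """Tally of proteins removed by each quality rule, in rule order."""

    n_input: int = 0
    n_removed_contaminant: int = 0
    n_removed_reverse: int = 0
    n_removed_only_by_site: int = 0
    n_removed_low_peptides: int = 0
    n_removed_zero_intensity: int = 0
    n_kept: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _parse_flag(value) -> bool:
    return isinstance(value, str) and value.strip() == "+"


def _split_ids(cell) -> tuple[str, ...]:
    if not isinstance(cell, str) or not cell.strip():
        return ("",)
    return tuple(p.strip() for p in cell.split(";") if p.strip()) or ("",)


def read_protein_groups(
    path,
    layout: ExperimentLayout,
    dialect: ColumnDialect | None = None,
) -> list[ProteinRecord]:
    """Parse a proteinGroups table into one :class:`ProteinRecord` per row.

    Missing numeric cells parse as 0; an unparsable numeric cell raises
    :class:`RowParseError` naming the row.  A "+" in a flag column marks the
    flag true; anything else (including absence) is false.
    """
    dialect = dialect or ColumnDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return table_to_records(df, layout, dialect)


def table_to_records(
    df: pd.DataFrame,
    layout: ExperimentLayout,
    dialect: ColumnDialect | None = None,
) -> list[ProteinRecord]:
    """Convert an in-memory proteinGroups-style table (string cells allowed)
    to records.  Shares all parsing rules with :func:`read_protein_groups`."""
    dialect = dialect or ColumnDialect()
    n_rep = len(layout.replicates)

    intensity_cols: dict[tuple[str, int], str] = {}
    for rep, ch in layout.observations():
        col = dialect.intensity_column(rep, ch.index, n_rep)
        if col not in df.columns:
            raise ColumnError(f"required reporter-intensity column {col!r} not found")
        intensity_cols[(rep, ch.index)] = col
    for col in (dialect.protein_ids_column, dialect.peptide_column):
        if col not in df.columns:
            raise ColumnError(f"required column {col!r} not found")

    def numeric(col: str) -> pd.Series:
        raw = df[col].astype(str).str.strip()
        vals = pd.to_numeric(raw.replace("", "0"), errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = int(bad.idxmax())
            raise RowParseError(
                f"row {i}: cannot parse {col!r} value {df[col].iloc[i]!r} as a number"
            )
        return vals

    peptides = numeric(dialect.peptide_column).astype(int)
    intensities = {key: numeric(col).to_numpy(float) for key, col in intensity_cols.items()}

    def flags(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].map(_parse_flag)
        return pd.Series(False, index=df.index)

    contam = flags(dialect.contaminant_column)
    reverse = flags(dialect.reverse_column)
    site_only = flags(dialect.only_by_site_column)
    genes = (
        df[dialect.gene_names_column]
        if dialect.gene_names_column in df.columns
        else pd.Series("", index=df.index)
    )

    records = []
    for i in range(len(df)):
        records.append(
            ProteinRecord(
                protein_ids=_split_ids(df[dialect.protein_ids_column].iloc[i]),
                gene_names=_split_ids(genes.iloc[i]),
                peptide_count=int(peptides.iloc[i]),
                is_contaminant=bool(contam.iloc[i]),
                is_reverse=bool(reverse.iloc[i]),
                is_only_by_site=bool(site_only.iloc[i]),
                reporter_intensities={k: float(v[i]) for k, v in intensities.items()},
            )
        )
    return records


def apply_quality_filters(
    records: list[ProteinRecord],
    min_peptides: int = 2,
) -> tuple[list[ProteinRecord], FilterReport]:
    """Drop contaminant/reverse/site-only/low-peptide proteins, then any
    protein lacking strictly positive intensity in every declared channel.

    Each record is counted once, under the first rule that removes it.
    """
    report = FilterReport(n_input=len(records))
    kept = []
    for rec in records:
        if rec.is_contaminant:
            report.n_removed_contaminant += 1
        elif rec.is_reverse:
            report.n_removed_reverse += 1
        elif rec.is_only_by_site:
            report.n_removed_only_by_site += 1
        elif rec.peptide_count < min_peptides:
            report.n_removed_low_peptides += 1
        elif any(v <= 0 for v in rec.reporter_intensities.values()):
            report.n_removed_zero_intensity += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def load_reference_accessions(path) -> set[str]:
    """Load a one-accession-per-line reference list; isoform suffixes are
    stripped so P09874-2 matches P09874."""
    out = set()
    with open(path) as fh:
        for line in fh:
            acc = line.strip()
            if acc and not acc.startswith("#"):
                out.add(_ISOFORM_RE.sub("", acc))
    return out


def annotate_known_targets(
    ids: list[tuple[str, ...]],
    reference: set[str],
) -> list[bool]:
    """True per protein iff any of its accessions (isoform-stripped) is in
    the reference set."""
    if not reference:
        logger.warning("empty reference accession set: all annotations false")
        return [False] * len(ids)
    ref = {_ISOFORM_RE.sub("", a) for a in reference}
    return [any(_ISOFORM_RE.sub("", a) in ref for a in accs) for accs in ids]


def records_to_matrix(
    records: list[ProteinRecord],
    layout: ExperimentLayout,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble records into a proteins × observations intensity matrix and
    a protein metadata table.

    The matrix columns are a (replicate, channel) MultiIndex in the layout's
    canonical order; the row index is the primary accession.
    """
    keys = layout.observation_keys()
    ids = [r.primary_accession for r in records]
    data = [[r.reporter_intensities[k] for k in keys] for r in records]
    cols = pd.MultiIndex.from_tuples(keys, names=["replicate", "channel"])
    matrix = pd.DataFrame(data, index=pd.Index(ids, name="protein"), columns=cols)
    meta = pd.DataFrame(
        {
            "protein_ids": [";".join(r.protein_ids) for r in records],
            "gene_name": [r.gene_names[0] for r in records],
            "peptides": [r.peptide_count for r in records],
        },
        index=matrix.index,
    )
    return matrix, meta
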