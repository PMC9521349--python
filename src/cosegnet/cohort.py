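"""Alteration-call tables and binary patient × gene mutation matrices.

A liquid-biopsy comprehensive-genomic-profiling report is a long table with
one row per (patient, gene, alteration) call, annotated with an alteration
class (missense, frameshift, ...) and a clinical-significance label.  The
analysis operates on a *mutation matrix*: a binary patient × gene indicator
of "carries at least one retained pathogenic alteration in this gene".

The pathogenicity filter implements two rules: variants of unknown
significance (and benign calls) are excluded, while frameshift and nonsense
calls are treated as pathogenic regardless of their annotated significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALTERATION_CLASSES = frozenset(
    {
        "missense",
        "frameshift",
        "nonsense",
        "splice",
        "synonymous",
        "amplification",
        "fusion",
        "other",
    }
)

SIGNIFICANCE_LEVELS = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "benign", "unclassified"}
)

#: Alteration classes counted as pathogenic regardless of annotation.
ALWAYS_PATHOGENIC_CLASSES = frozenset({"frameshift", "nonsense"})

#: Significance labels retained by the pathogenicity filter.
PATHOGENIC_SIGNIFICANCE = frozenset({"pathogenic", "likely_pathogenic"})

#: Significance labels always dropped (unless the class overrides them).
EXCLUDED_SIGNIFICANCE = frozenset({"vus", "benign"})

#: Classes excluded from "mutation-positive" status by default (copy-number
#: and structural events are not point "mutations").
NON_MUTATION_CLASSES = frozenset({"amplification", "fusion"})


class CohortError(ValueError):
    """Raised for malformed cohort inputs."""


@dataclass(frozen=True)
class AlterationRecord:
    """One reported alteration call.

    ``gene`` is normalised to an upper-case, whitespace-stripped HGNC-style
    symbol.  ``alteration_class`` and ``significance`` must come from their
    closed vocabularies; use :func:`read_alteration_table` to map free-text
    labels.
    """

    patient_id: str
    gene: str
    alteration_class: str
    significance: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if not self.gene:
            raise CohortError("gene symbol must be non-empty")
        if self.alteration_class not in ALTERATION_CLASSES:
            raise CohortError(
                f"unknown alteration_class {self.alteration_class!r}"
            )
        if self.significance not in SIGNIFICANCE_LEVELS:
            raise CohortError(f"unknown significance {self.significance!r}")


@dataclass(frozen=True)
class Dialect:
    """Delimiter and column-name mapping for alteration tables.

    The commercial report schema is not standardised, so every column name
    is configurable.  ``date`` is optional; when mapped, only each patient's
    first (earliest-dated) test is kept, mirroring a first-available-result
    rule.
    """

    sep: str = "\t"
    patient_id: str = "patient_id"
    gene: str = "gene"
    alteration_class: str = "alteration_class"
    significance: str = "significance"
    date: str | None = None

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.patient_id, self.gene, self.alteration_class, self.significance)


def _canon_token(value: object) -> str:
    return str(value).strip().lower().replace(" ", "_").replace("-", "_")


def _map_class(raw: object) -> str:
    token = _canon_token(raw)
    aliases = {
        "frame_shift": "frameshift",
        "stop_gained": "nonsense",
        "stopgain": "nonsense",
        "splice_site": "splice",
        "cnv": "amplification",
        "rearrangement": "fusion",
    }
    token = aliases.get(token, token)
    if token not in ALTERATION_CLASSES:
        logger.warning("unknown alteration class %r mapped to 'other'", raw)
        return "other"
    return token


def _map_significance(raw: object) -> str:
    token = _canon_token(raw)
    aliases = {
        "variant_of_unknown_significance": "vus",
        "uncertain_significance": "vus",
        "likely_benign": "benign",
    }
    token = aliases.get(token, token)
    if token not in SIGNIFICANCE_LEVELS:
        logger.warning("unknown significance %r mapped to 'unclassified'", raw)
        return "unclassified"
    return token


def read_alteration_table(
    path: str | Path, dialect: Dialect | None = None
) -> list[AlterationRecord]:
    """Read a delimited alteration-call table into records.

    Raises :class:`CohortError` if a mapped column is missing (the error
    names the column) or if the table has no data rows.  Unknown class or
    significance strings map to ``other`` / ``unclassified`` with a logged
    warning.  When the dialect maps a date column, only rows from each
    patient's earliest date are kept.
    """
    dialect = dialect or Dialect()
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for column in dialect.required_columns:
        if column not in frame.columns:
            raise CohortError(f"missing mapped column {column!r} in {path}")
    if frame.empty:
        raise CohortError(f"alteration table {path} has no data rows")
    if dialect.date is not None:
        if dialect.date not in frame.columns:
            raise CohortError(f"missing mapped column {dialect.date!r} in {path}")
        dates = pd.to_datetime(frame[dialect.date], errors="coerce")
        first = dates.groupby(frame[dialect.patient_id]).transform("min")
        frame = frame.loc[dates == first]
    return [
        AlterationRecord(
            patient_id=str(row[dialect.patient_id]),
            gene=str(row[dialect.gene]),
            alteration_class=_map_class(row[dialect.alteration_class]),
            significance=_map_significance(row[dialect.significance]),
        )
        for _, row in frame.iterrows()
    ]


def write_alteration_table(
    records: Iterable[AlterationRecord],
    path: str | Path,
    dialect: Dialect | None = None,
) -> None:
    """Write records in the same delimited layout read_alteration_table expects."""
    dialect = dialect or Dialect()
    frame = pd.DataFrame(
        {
            dialect.patient_id: [r.patient_id for r in records],
            dialect.gene: [r.gene for r in records],
            dialect.alteration_class: [r.alteration_class for r in records],
            dialect.significance: [r.significance for r in records],
        }
    )
    frame.to_csv(path, sep=dialect.sep, index=False)


def filter_pathogenic(
    records: Iterable[AlterationRecord],
) -> list[AlterationRecord]:
    """Apply the pathogenicity filter.

    Frameshift and nonsense calls are retained regardless of annotated
    significance; otherwise only pathogenic / likely-pathogenic calls are
    kept, and VUS / benign calls are dropped.  Idempotent.
    """
    kept = []
    for record in records:
        if record.alteration_class in ALWAYS_PATHOGENIC_CLASSES:
            kept.append(record)
        elif record.significance in PATHOGENIC_SIGNIFICANCE:
            kept.append(record)
    return kept


@dataclass
class MutationMatrix:
    """Binary patient × gene pathogenic-alteration indicator matrix.

    Wraps a pandas DataFrame with the patient identifier as index and gene
    symbols as columns; every entry is 0 or 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise CohortError("duplicate patient_ids in mutation matrix")
        if self.data.columns.has_duplicates:
            raise CohortError("duplicate genes in mutation matrix")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise CohortError("mutation matrix entries must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def patient_ids(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.columns]

    @property
    def n_patients(self) -> int:
        return len(self.data.index)

    def column(self, gene: str) -> np.ndarray:
        """Boolean indicator vector for one gene (hard error if absent)."""
        if gene not in self.data.columns:
            raise CohortError(f"gene {gene!r} not in matrix")
        return self.data[gene].to_numpy(dtype=bool)

    def restrict_patients(self, mask: np.ndarray) -> "MutationMatrix":
        return MutationMatrix(self.data.loc[np.asarray(mask, dtype=bool)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        return cls(frame)

    @classmethod
    def from_arrays(
        cls,
        patient_ids: Sequence[str],
        genes: Sequence[str],
        values: np.ndarray,
    ) -> "MutationMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=np.int8),
            index=[str(p) for p in patient_ids],
            columns=[str(g) for g in genes],
        )
        return cls(frame)


def binarize(
    records: Iterable[AlterationRecord],
    patient_universe: Sequence[str] | None = None,
    panel_genes: Sequence[str] | None = None,
    include_copy_number: bool = False,
) -> MutationMatrix:
    """Collapse filtered records to a binary patient × gene matrix.

    Entry (p, g) is 1 iff at least one record exists for that pair.
    Patients listed in ``patient_universe`` but absent from the records get
    all-zero rows; ``panel_genes`` forces columns for untouched panel genes.
    Amplification and fusion calls are excluded from mutation-positive
    status unless ``include_copy_number`` is set (copy-number handling in
    panel reports is convention-dependent).
    """
    records = list(records)
    if not include_copy_number:
        records = [r for r in records if r.alteration_class not in NON_MUTATION_CLASSES]
    patients: list[str] = []
    seen_patients: set[str] = set()
    for source in (patient_universe or [], (r.patient_id for r in records)):
        for p in source:
            p = str(p)
            if p not in seen_patients:
                seen_patients.add(p)
                patients.append(p)
    genes = sorted({r.gene for r in records} | {g.strip().upper() for g in panel_genes or []})
    matrix = np.zeros((len(patients), len(genes)), dtype=np.int8)
    patient_index = {p: i for i, p in enumerate(patients)}
    gene_index = {g: j for j, g in enumerate(genes)}
    for record in records:
        matrix[patient_index[record.patient_id], gene_index[record.gene]] = 1
    return MutationMatrix.from_arrays(patients, genes, matrix)


@dataclass(frozen=True)
class LandscapeSummary:
    """Per-gene alteration frequencies and the genes above a threshold.

    ``retained_genes`` is ordered by descending frequency, alphabetical on
    ties.
    """

    frequencies: Mapping[str, float]
    counts: Mapping[str, int]
    n_patients: int
    min_freq: float
    retained_genes: tuple[str, ...] = field(default=())

    def to_tsv(self, path: str | Path) -> None:
        order = sorted(
            self.frequencies, key=lambda g: (-self.frequencies[g], g)
        )
        frame = pd.DataFrame(
            {
                "gene": order,
                "count": [self.counts[g] for g in order],
                "frequency": [self.frequencies[g] for g in order],
                "retained": [int(g in self.retained_genes) for g in order],
            }
        )
        frame.to_csv(path, sep="\t", index=False)


def landscape(matrix: MutationMatrix, min_freq: float = 0.05) -> LandscapeSummary:
    """Compute the alteration landscape: column frequencies and retained genes."""
    if matrix.n_patients == 0 or not matrix.genes:
        raise CohortError("cannot compute landscape of an empty matrix")
    if not 0.0 <= min_freq <= 1.0:
        raise CohortError("min_freq must be in [0, 1]")
    counts = {g: int(matrix.data[g].sum()) for g in matrix.genes}
    freqs = {g: counts[g] / matrix.n_patients for g in matrix.genes}
    retained = tuple(
        sorted(
            (g for g in freqs if freqs[g] >= min_freq),
            key=lambda g: (-freqs[g], g),
        )
    )
    return LandscapeSummary(
        frequencies=freqs,
        counts=counts,
        n_patients=matrix.n_patients,
        min_freq=min_freq,
        retained_genes=retained,
    )
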