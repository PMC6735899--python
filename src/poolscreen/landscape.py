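"""Landscape analyses over ranked call tables.

Per-domain tallies of the top-N hits, overlap classes between two
phenotype screens (e.g. Cip^R Vos^S vs Cip^R Vos^R), a mutational
spectrum audit against the hydroxylamine GC→AT expectation, the
selection-rate arithmetic of the plating step, and concordance
bookkeeping for validated-mutant phenotype tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calling import RankedCallTable
from .errors import ConfigError, DataError
from .reference import DomainAnnotation, UNANNOTATED, domain_of, parent_rollup


def domain_tally(
    table: RankedCallTable,
    annotations: Sequence[DomainAnnotation],
    rollup: bool = False,
) -> dict[str, int]:
    """Count table entries per deepest containing domain.

    With ``rollup`` the counts are attributed to the top-level parent
    domain instead (the alternative reading of nested-domain counting).
    Residues outside every annotation fall under ``unannotated``; the
    counts always sum to the table size.
    """
    assign = parent_rollup if rollup else domain_of
    counts: dict[str, int] = {}
    for e in table.entries:
        name = assign(annotations, e.residue)
        counts[name] = counts.get(name, 0) + 1
    return counts


@dataclass
class ScreenComparison:
    """Overlap classes between two screens' call tables.

    Membership is by residue-level identity (residue, alt_aa) by default,
    mirroring residue-sphere overlap displays; nucleotide-level identity
    is available via ``by='nt'``. ``a_only``, ``b_only`` and ``shared``
    partition the union of the two tables' identities.
    """

    label_a: str
    label_b: str
    a_only: set
    b_only: set
    shared: set

    @property
    def class_sizes(self) -> dict[str, int]:
        return {
            "A_only": len(self.a_only),
            "B_only": len(self.b_only),
            "shared": len(self.shared),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"class": "A_only", "screen": self.label_a, "residue": r, "alt": a}
            for r, a in sorted(self.a_only)
        ]
        rows += [
            {"class": "B_only", "screen": self.label_b, "residue": r, "alt": a}
            for r, a in sorted(self.b_only)
        ]
        rows += [
            {"class": "shared", "screen": f"{self.label_a}+{self.label_b}",
             "residue": r, "alt": a}
            for r, a in sorted(self.shared)
        ]
        return pd.DataFrame(rows, columns=["class", "screen", "residue", "alt"])


def compare_screens(
    table_a: RankedCallTable,
    table_b: RankedCallTable,
    label_a: str = "screen_A",
    label_b: str = "screen_B",
    by: str = "aa",
) -> ScreenComparison:
    """Classify each called substitution as A-only, B-only or shared."""
    if table_a.ref_id and table_b.ref_id and table_a.ref_id != table_b.ref_id:
        raise DataError(
            f"tables come from different references: {table_a.ref_id!r} vs {table_b.ref_id!r}"
        )
    if by == "aa":
        keys_a, keys_b = table_a.aa_keys(), table_b.aa_keys()
    elif by == "nt":
        keys_a, keys_b = table_a.keys(), table_b.keys()
    else:
        raise ConfigError(f"unknown comparison identity {by!r} (use 'aa' or 'nt')")
    return ScreenComparison(
        label_a=label_a,
        label_b=label_b,
        a_only=keys_a - keys_b,
        b_only=keys_b - keys_a,
        shared=keys_a & keys_b,
    )


def domain_count_matrix(
    tables: Mapping[str, RankedCallTable],
    annotations: Sequence[DomainAnnotation],
    rollup: bool = False,
) -> pd.DataFrame:
    """Domain × screen count matrix over several call tables."""
    data = {label: domain_tally(t, annotations, rollup=rollup) for label, t in tables.items()}
    names = [a.name for a in annotations] + [UNANNOTATED]
    df = pd.DataFrame(
        {label: [counts.get(n, 0) for n in names] for label, counts in data.items()},
        index=names,
    )
    return df


def spectrum_audit(
    calls: RankedCallTable | Iterable[tuple[str, str]],
) -> Optional[dict]:
    """Fraction of calls that are hydroxylamine-type C→T / G→A transitions.

    Accepts a ranked table or raw (ref_base, alt_base) pairs. Returns
    ``None`` on empty input (no fraction is defined). Transversion and
    non-GC→AT transition calls are listed for inspection.
    """
    if isinstance(calls, RankedCallTable):
        pairs = [(e.ref_base, e.alt_base, e) for e in calls.entries]
    else:
        pairs = [(r, a, None) for r, a in calls]
    if not pairs:
        return None
    n_gc_at = 0
    others = []
    for ref_b, alt_b, entry in pairs:
        if (ref_b, alt_b) in (("C", "T"), ("G", "A")):
            n_gc_at += 1
        else:
            others.append((ref_b, alt_b) if entry is None else entry)
    return {
        "n_calls": len(pairs),
        "n_gc_to_at": n_gc_at,
        "fraction_gc_to_at": n_gc_at / len(pairs),
        "non_gc_to_at": others,
    }


def selection_summary(n_plated: int, n_confirmed: int) -> float:
    """Percent of plated transformants confirmed resistant, to 2 d.p.

    E.g. 363 confirmed of 28 000 plated → 1.30.
    """
    if n_plated <= 0:
        raise ConfigError("n_plated must be positive")
    if not 0 <= n_confirmed <= n_plated:
        raise ConfigError("n_confirmed must lie in 0..n_plated")
    return round(100.0 * n_confirmed / n_plated, 2)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One validated mutant × drug measurement.

    ``log10_fold_change`` is the log10 increase in viable cell count on
    drug relative to the wild-type enzyme; ``screen_expectation`` is the
    phenotype the screen predicted ('resistant' or 'sensitive').
    """

    mutant: str
    drug: str
    log10_fold_change: float
    screen_expectation: str

    def __post_init__(self) -> None:
        if self.screen_expectation not in ("resistant", "sensitive"):
            raise DataError(
                f"record {self.mutant}/{self.drug}: expectation must be "
                "'resistant' or 'sensitive'"
            )
        if not pd.notna(self.log10_fold_change) or abs(self.log10_fold_change) == float("inf"):
            raise DataError(f"record {self.mutant}/{self.drug}: non-finite fold change")


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV: mutant / drug / log10_fold_change / expectation."""
    df = pd.read_csv(path, sep="\t")
    required = {"mutant", "drug", "log10_fold_change", "expectation"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        PhenotypeRecord(
            mutant=str(r.mutant),
            drug=str(r.drug),
            log10_fold_change=float(r.log10_fold_change),
            screen_expectation=str(r.expectation),
        )
        for r in df.itertuples(index=False)
    ]


def classify_resistance(
    records: Sequence[PhenotypeRecord], threshold_log10: float = 2.0
) -> dict:
    """Label each record resistant/sensitive and score screen concordance.

    A record is resistant iff log10 fold change >= ``threshold_log10``
    (default 2, the 100-fold class); resistant records are stratified as
    'weak' for [2, 4) and 'strong' for [4, ∞) — the 100-fold versus
    10 000-fold resistance classes. Concordance is the fraction of
    records whose label matches the screen expectation.
    """
    if threshold_log10 < 0:
        raise ConfigError("threshold_log10 must be >= 0")
    rows = []
    n_match = 0
    for r in records:
        resistant = r.log10_fold_change >= threshold_log10
        label = "resistant" if resistant else "sensitive"
        if resistant:
            stratum = "strong" if r.log10_fold_change >= threshold_log10 + 2 else "weak"
        else:
            stratum = ""
        match = label == r.screen_expectation
        n_match += match
        rows.append(
            {
                "mutant": r.mutant,
                "drug": r.drug,
                "log10_fold_change": r.log10_fold_change,
                "label": label,
                "stratum": stratum,
                "expectation": r.screen_expectation,
                "concordant": match,
            }
        )
    return {
        "records": pd.DataFrame(
            rows,
            columns=[
                "mutant", "drug", "log10_fold_change", "label",
                "stratum", "expectation", "concordant",
            ],
        ),
        "n_records": len(records),
        "n_concordant": n_match,
        "concordance": (n_match / len(records)) if records else float("nan"),
    }
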