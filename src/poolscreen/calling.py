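"""Quality filtering, amino-acid conversion, supporting-read ranking.

The screen's core computation: mismatches from uniquely aligned reads
are kept only when the base quality reaches ``min_quality`` (default
Q38, i.e. 99.98% base-call confidence), grouped by nucleotide change,
converted to amino-acid substitutions codon-aware, ranked by the number
of distinct supporting reads and truncated to the top N (default 100).

Rows are keyed by the nucleotide change; two degenerate nucleotide
routes to the same amino-acid substitution stay separate rows (an
AA-collapsed view is available via :meth:`RankedCallTable.collapse_aa`).
Entries beyond rank N tied with the rank-N count are reported in a
``boundary_ties`` annex, never silently included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import MismatchObservation
from .errors import ConfigError, DataError
from .reference import AaSubstitution, OrfReference, substitution_from_mismatch


def quality_confidence(q: float) -> float:
    """Base-call confidence, percent: 100 * (1 - 10^(-q/10)).

    Q38 corresponds to 99.98% confidence (2 d.p.).
    """
    if q < 0:
        raise ConfigError("Phred quality must be non-negative")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


@dataclass(frozen=True)
class CallerConfig:
    """Quality threshold and top-N cutoff for the ranked mutation table."""

    min_quality: int = 38
    top_n: int = 100
    include_synonymous: bool = False
    include_stops: bool = True

    def __post_init__(self) -> None:
        if self.min_quality < 0:
            raise ConfigError("min_quality must be >= 0")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")


def filter_mismatches(
    observations: Iterable[MismatchObservation], cfg: CallerConfig
) -> list[MismatchObservation]:
    """Keep observations with quality >= min_quality (order-preserving)."""
    return [o for o in observations if o.quality >= cfg.min_quality]


@dataclass
class RankedCallTable:
    """The ranked mutation table with its cutoff statistic and totals.

    ``threshold_reads`` is the supporting count at rank min(N, size) —
    the screen's read-cutoff statistic. ``totals`` records the funnel:
    mismatch observations in, observations passing quality, distinct
    substitutions before truncation.
    """

    entries: list[AaSubstitution]
    threshold_reads: int
    totals: dict
    boundary_ties: list[AaSubstitution] = field(default_factory=list)
    ref_id: str = ""

    def __post_init__(self) -> None:
        counts = [e.supporting_reads for e in self.entries]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise DataError("supporting_reads must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def keys(self) -> set[tuple[int, str]]:
        """Nucleotide-level identities (orf_pos, alt_base) of all entries."""
        return {e.key() for e in self.entries}

    def aa_keys(self) -> set[tuple[int, str]]:
        """Residue-level identities (residue, alt_aa) of all entries."""
        return {e.aa_key() for e in self.entries}

    def collapse_aa(self) -> "RankedCallTable":
        """Collapse degenerate nucleotide routes into amino-acid rows.

        Supporting reads of rows sharing (residue, alt_aa) are summed; the
        representative nucleotide change is the higher-supported route.
        Re-ranked with the same ordering rule; no further truncation.
        """
        grouped: dict[tuple[int, str], AaSubstitution] = {}
        for e in self.entries:
            key = e.aa_key()
            if key in grouped:
                keep = grouped[key]
                rep = keep if keep.supporting_reads >= e.supporting_reads else e
                grouped[key] = replace(
                    rep, supporting_reads=keep.supporting_reads + e.supporting_reads
                )
            else:
                grouped[key] = e
        entries = _rank(list(grouped.values()))
        threshold = entries[-1].supporting_reads if entries else 0
        return RankedCallTable(
            entries=entries,
            threshold_reads=threshold,
            totals=dict(self.totals, distinct_substitutions=len(entries)),
            ref_id=self.ref_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "residue": e.residue,
                    "ref_aa": e.ref_aa,
                    "alt_aa": e.alt_aa,
                    "orf_pos": e.orf_pos,
                    "ref_base": e.ref_base,
                    "alt_base": e.alt_base,
                    "supporting_reads": e.supporting_reads,
                    "synonymous": e.synonymous,
                }
                for e in self.entries
            ],
            columns=[
                "rank", "residue", "ref_aa", "alt_aa", "orf_pos",
                "ref_base", "alt_base", "supporting_reads", "synonymous",
            ],
        )


def _rank(subs: list[AaSubstitution]) -> list[AaSubstitution]:
    """Sort by supporting reads desc, then residue asc, then alt_aa, then
    orf_pos/alt_base for full determinism; assign ranks 1..n."""
    ordered = sorted(
        subs,
        key=lambda e: (-e.supporting_reads, e.residue, e.alt_aa, e.orf_pos, e.alt_base),
    )
    return [replace(e, rank=i + 1) for i, e in enumerate(ordered)]


def call_and_rank(
    ref: OrfReference,
    observations: Iterable[MismatchObservation],
    cfg: CallerConfig = CallerConfig(),
) -> RankedCallTable:
    """Aggregate quality-filtered mismatches into the ranked mutation table.

    Observations are grouped by (orf_pos, alt_base); supporting reads are
    counted per distinct read id. Synonymous changes are dropped unless
    ``include_synonymous``; stop gains are kept unless ``include_stops``
    is off. An observation whose ref_base disagrees with the reference
    raises a corruption-guard :class:`DataError` naming the position.
    Idempotent with respect to prior quality filtering.
    """
    observations = list(observations)
    kept = filter_mismatches(observations, cfg)
    reads_by_change: dict[tuple[int, str], set[str]] = {}
    for o in kept:
        if o.orf_pos is None:
            continue
        if ref.base(o.orf_pos) != o.ref_base:
            raise DataError(
                f"observation at ORF pos {o.orf_pos}: ref_base {o.ref_base} "
                f"disagrees with reference base {ref.base(o.orf_pos)}"
            )
        reads_by_change.setdefault((o.orf_pos, o.read_base), set()).add(o.read_id)

    subs = []
    for (pos, alt), read_ids in reads_by_change.items():
        sub = substitution_from_mismatch(ref, pos, alt, supporting_reads=len(read_ids))
        if sub.synonymous and not cfg.include_synonymous:
            continue
        if sub.is_stop and not cfg.include_stops:
            continue
        subs.append(sub)

    ranked = _rank(subs)
    entries = ranked[: cfg.top_n]
    threshold = entries[-1].supporting_reads if entries else 0
    boundary = [
        e for e in ranked[cfg.top_n :] if e.supporting_reads == threshold
    ]
    return RankedCallTable(
        entries=entries,
        threshold_reads=threshold,
        totals={
            "mismatch_reads_in": len({o.read_id for o in observations}),
            "calls_passing_quality": len(kept),
            "distinct_substitutions": len(ranked),
        },
        boundary_ties=boundary,
        ref_id=ref.id,
    )


_TSV_COLUMNS = [
    "rank", "residue", "ref_aa", "alt_aa", "orf_pos",
    "ref_base", "alt_base", "supporting_reads", "synonymous",
]


def write_calls(table: RankedCallTable, path: str | Path) -> None:
    """Write the ranked table as TSV; metadata in '#key=value' header lines."""
    lines = [
        f"#ref_id={table.ref_id}",
        f"#threshold_reads={table.threshold_reads}",
        f"#mismatch_reads_in={table.totals.get('mismatch_reads_in', 0)}",
        f"#calls_passing_quality={table.totals.get('calls_passing_quality', 0)}",
        f"#distinct_substitutions={table.totals.get('distinct_substitutions', 0)}",
        "\t".join(_TSV_COLUMNS),
    ]
    for e in table.entries:
        lines.append(
            f"{e.rank}\t{e.residue}\t{e.ref_aa}\t{e.alt_aa}\t{e.orf_pos}\t"
            f"{e.ref_base}\t{e.alt_base}\t{e.supporting_reads}\t{int(e.synonymous)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calls(path: str | Path) -> RankedCallTable:
    """Read a ranked call table written by :func:`write_calls` (lossless)."""
    meta: dict[str, str] = {}
    entries: list[AaSubstitution] = []
    lines = Path(path).read_text().splitlines()
    body_started = False
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            meta[key] = val
            continue
        if not body_started:
            if ln != "\t".join(_TSV_COLUMNS):
                raise DataError(f"{path}: unexpected header line {ln!r}")
            body_started = True
            continue
        rank_s, res_s, ref_aa, alt_aa, pos_s, ref_b, alt_b, n_s, _syn = ln.split("\t")
        entries.append(
            AaSubstitution(
                ref_aa=ref_aa, residue=int(res_s), alt_aa=alt_aa,
                orf_pos=int(pos_s), ref_base=ref_b, alt_base=alt_b,
                supporting_reads=int(n_s), rank=int(rank_s),
            )
        )
    if not body_started:
        raise DataError(f"{path}: missing column header")
    return RankedCallTable(
        entries=entries,
        threshold_reads=int(meta.get("threshold_reads", 0)),
        totals={
            "mismatch_reads_in": int(meta.get("mismatch_reads_in", 0)),
            "calls_passing_quality": int(meta.get("calls_passing_quality", 0)),
            "distinct_substitutions": int(meta.get("distinct_substitutions", 0)),
        },
        ref_id=meta.get("ref_id", ""),
    )


def write_vcf(table: RankedCallTable, ref: OrfReference, path: str | Path) -> None:
    """VCF-flavored export: CHROM = ORF id, POS 1-based ORF coordinate,
    INFO carries residue / amino-acid change / supporting reads."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.id},length={len(ref.seq)}>",
        '##INFO=<ID=RES,Number=1,Type=Integer,Description="Residue index">',
        '##INFO=<ID=AAC,Number=1,Type=String,Description="Amino acid change">',
        '##INFO=<ID=SR,Number=1,Type=Integer,Description="Supporting reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for e in table.entries:
        lines.append(
            f"{ref.id}\t{e.orf_pos}\t{e.label}\t{e.ref_base}\t{e.alt_base}\t.\tPASS\t"
            f"RES={e.residue};AAC={e.ref_aa}{e.residue}{e.alt_aa};SR={e.supporting_reads}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
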