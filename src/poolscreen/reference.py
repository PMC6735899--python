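"""ORF reference model: sequence, codon arithmetic, domain annotations.

The screen maps short reads against a single topoisomerase ORF amplified
from plasmid pools. Everything downstream is expressed in two coordinate
systems, both 1-based: nucleotide positions within the ORF and residue
numbers from the initiator methionine (residue 1 = codon 1). The amplicon
may extend past the ORF on either side (``flank5`` / ``flank3``); reads
aligning there are bookkept but never produce amino-acid calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, DataError

NUCLEOTIDES = "ACGT"
_NT_SET = frozenset(NUCLEOTIDES)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, codons ordered T,C,A,G on each base.
_CODE_BASES = "TCAG"
_CODE_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: Mapping[str, str] = {
    b1 + b2 + b3: _CODE_AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_CODE_BASES)
    for j, b2 in enumerate(_CODE_BASES)
    for k, b3 in enumerate(_CODE_BASES)
}

#: Label used for residues outside every annotated domain.
UNANNOTATED = "unannotated"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a coding-strand nucleotide string, one letter per codon.

    Stop codons are rendered ``*``. Raises :class:`DataError` for a
    non-triplet length or characters outside A/C/G/T.
    """
    if len(seq) % 3 != 0:
        raise DataError(f"sequence length {len(seq)} is not a multiple of 3")
    bad = set(seq) - _NT_SET
    if bad:
        raise DataError(f"illegal nucleotide(s) {sorted(bad)} in sequence")
    return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))


@dataclass(frozen=True)
class OrfReference:
    """An ORF nucleotide sequence with optional amplicon flanks.

    ``seq`` must be over A/C/G/T with length divisible by three; residue
    *r* occupies ORF nucleotides ``3r-2 .. 3r`` (1-based).
    """

    id: str
    seq: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise DataError(f"reference {self.id!r}: empty ORF sequence")
        if len(self.seq) % 3 != 0:
            raise DataError(
                f"reference {self.id!r}: ORF length {len(self.seq)} not divisible by 3"
            )
        for label, s in (("ORF", self.seq), ("flank5", self.flank5), ("flank3", self.flank3)):
            bad = set(s) - _NT_SET
            if bad:
                raise DataError(
                    f"reference {self.id!r}: {label} contains illegal characters {sorted(bad)}"
                )

    @property
    def codon_count(self) -> int:
        return len(self.seq) // 3

    @property
    def amplicon(self) -> str:
        """Full amplified sequence: 5' flank + ORF + 3' flank."""
        return self.flank5 + self.seq + self.flank3

    @property
    def orf_offset(self) -> int:
        """0-based start of the ORF within the amplicon."""
        return len(self.flank5)

    def base(self, orf_pos: int) -> str:
        """Reference base at 1-based ORF position ``orf_pos``."""
        if not 1 <= orf_pos <= len(self.seq):
            raise DataError(f"ORF position {orf_pos} outside 1..{len(self.seq)}")
        return self.seq[orf_pos - 1]

    def codon(self, residue: int) -> str:
        """Codon (triplet) for 1-based residue index."""
        if not 1 <= residue <= self.codon_count:
            raise DataError(f"residue {residue} outside 1..{self.codon_count}")
        return self.seq[3 * (residue - 1) : 3 * residue]

    def orf_pos_of_amplicon(self, amplicon_pos0: int) -> Optional[int]:
        """Map a 0-based amplicon index to a 1-based ORF position (None in flanks)."""
        p = amplicon_pos0 - self.orf_offset
        if 0 <= p < len(self.seq):
            return p + 1
        return None


@dataclass(frozen=True)
class DomainAnnotation:
    """A named residue interval, optionally nested inside a parent domain."""

    name: str
    start_res: int
    end_res: int
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_res < 1 or self.end_res < self.start_res:
            raise DataError(
                f"domain {self.name!r}: invalid interval {self.start_res}..{self.end_res}"
            )

    def contains(self, residue: int) -> bool:
        return self.start_res <= residue <= self.end_res


@dataclass(frozen=True)
class AaSubstitution:
    """An amino-acid substitution induced by a single-nucleotide change.

    ``residue`` is 1-based from the initiator methionine; ``nt_change``
    is carried as (orf_pos, ref_base, alt_base). ``supporting_reads`` is
    the number of distinct quality-filtered reads carrying the change.
    """

    ref_aa: str
    residue: int
    alt_aa: str
    orf_pos: int
    ref_base: str
    alt_base: str
    supporting_reads: int = 0
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise DataError(f"substitution at ORF pos {self.orf_pos}: ref == alt base")
        if self.supporting_reads < 0:
            raise DataError("supporting_reads must be non-negative")

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    @property
    def is_stop(self) -> bool:
        return self.alt_aa == "*"

    @property
    def label(self) -> str:
        """Field-style label, e.g. ``E571K`` or ``W653STOP``."""
        alt = "STOP" if self.alt_aa == "*" else self.alt_aa
        return f"{self.ref_aa}{self.residue}{alt}"

    def key(self) -> tuple[int, str]:
        """Nucleotide-level identity: (orf_pos, alt_base)."""
        return (self.orf_pos, self.alt_base)

    def aa_key(self) -> tuple[int, str]:
        """Residue-level identity: (residue, alt_aa)."""
        return (self.residue, self.alt_aa)


def substitution_from_mismatch(
    ref: OrfReference, orf_pos: int, alt_base: str, supporting_reads: int = 0
) -> AaSubstitution:
    """Convert a single-nucleotide mismatch into an amino-acid substitution.

    The affected residue is ``ceil(orf_pos / 3)``; the alternate codon has
    exactly the one base replaced. Synonymous changes are returned (and
    flagged via :attr:`AaSubstitution.synonymous`), never silently dropped.
    """
    if alt_base not in _NT_SET:
        raise DataError(f"illegal alternate base {alt_base!r}")
    ref_base = ref.base(orf_pos)  # range-checked there
    if alt_base == ref_base:
        raise DataError(f"ORF pos {orf_pos}: alternate base equals reference base {ref_base}")
    residue = (orf_pos - 1) // 3 + 1
    codon = ref.codon(residue)
    within = (orf_pos - 1) % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    return AaSubstitution(
        ref_aa=GENETIC_CODE[codon],
        residue=residue,
        alt_aa=GENETIC_CODE[alt_codon],
        orf_pos=orf_pos,
        ref_base=ref_base,
        alt_base=alt_base,
        supporting_reads=supporting_reads,
    )


def validate_annotations(
    annotations: Sequence[DomainAnnotation], codon_count: int
) -> None:
    """Check annotation invariants; raise :class:`DataError` naming offenders.

    Enforced: intervals within 1..codon_count, parents declared, children
    contained in their parent, siblings (same parent) non-overlapping.
    """
    by_name = {}
    for a in annotations:
        if a.name in by_name:
            raise DataError(f"duplicate domain name {a.name!r}")
        by_name[a.name] = a
    for a in annotations:
        if a.end_res > codon_count:
            raise DataError(
                f"domain {a.name!r}: end_res {a.end_res} beyond ORF ({codon_count} codons)"
            )
        if a.parent is not None:
            if a.parent not in by_name:
                raise DataError(f"domain {a.name!r}: unknown parent {a.parent!r}")
            p = by_name[a.parent]
            if not (p.start_res <= a.start_res and a.end_res <= p.end_res):
                raise DataError(
                    f"domain {a.name!r} not contained in parent {a.parent!r}"
                )
    # sibling overlap, grouped by parent
    groups: dict[Optional[str], list[DomainAnnotation]] = {}
    for a in annotations:
        groups.setdefault(a.parent, []).append(a)
    for parent, sibs in groups.items():
        sibs = sorted(sibs, key=lambda a: a.start_res)
        for left, right in zip(sibs, sibs[1:]):
            if right.start_res <= left.end_res:
                raise DataError(
                    f"sibling domains {left.name!r} and {right.name!r} overlap"
                )
    # cycle guard
    for a in annotations:
        seen = set()
        cur: Optional[str] = a.name
        while cur is not None:
            if cur in seen:
                raise DataError(f"domain parent cycle involving {cur!r}")
            seen.add(cur)
            cur = by_name[cur].parent


def _depth(a: DomainAnnotation, by_name: Mapping[str, DomainAnnotation]) -> int:
    d = 0
    cur = a.parent
    while cur is not None:
        d += 1
        cur = by_name[cur].parent
    return d


def domain_of(annotations: Sequence[DomainAnnotation], residue: int) -> str:
    """Deepest annotated domain containing ``residue``; ``unannotated`` if none.

    Total over valid residues: never raises for an in-range residue.
    """
    by_name = {a.name: a for a in annotations}
    best: Optional[DomainAnnotation] = None
    best_depth = -1
    for a in annotations:
        if a.contains(residue):
            d = _depth(a, by_name)
            if d > best_depth or (d == best_depth and best and a.name < best.name):
                best, best_depth = a, d
    return best.name if best is not None else UNANNOTATED


def parent_rollup(annotations: Sequence[DomainAnnotation], residue: int) -> str:
    """Top-level (depth-0) domain containing ``residue``; ``unannotated`` if none."""
    by_name = {a.name: a for a in annotations}
    name = domain_of(annotations, residue)
    if name == UNANNOTATED:
        return name
    a = by_name[name]
    while a.parent is not None:
        a = by_name[a.parent]
    return a.name


def read_reference(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> tuple[OrfReference, list[DomainAnnotation]]:
    """Load an ORF reference (FASTA) and its domain annotation table (TSV).

    The FASTA holds one ORF record, plus optional records whose ids end in
    ``flank5`` / ``flank3`` giving amplicon context outside the ORF. The
    annotation table has columns name / start_res / end_res / parent
    (1-based inclusive residues; empty parent for top-level domains).
    All type invariants are validated on load.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DataError(f"{fasta_path}: empty or unparseable FASTA")
    flank5 = flank3 = ""
    orf_records = []
    for rec in records:
        rid = rec.id.lower()
        if rid.endswith("flank5"):
            flank5 = str(rec.seq).upper()
        elif rid.endswith("flank3"):
            flank3 = str(rec.seq).upper()
        else:
            orf_records.append(rec)
    if len(orf_records) != 1:
        raise DataError(
            f"{fasta_path}: expected exactly one ORF record, found {len(orf_records)}"
        )
    orf = orf_records[0]
    ref = OrfReference(
        id=orf.id, seq=str(orf.seq).upper(), flank5=flank5, flank3=flank3
    )
    annotations: list[DomainAnnotation] = []
    if annotation_path is not None:
        df = pd.read_csv(annotation_path, sep="\t", dtype={"name": str, "parent": str})
        required = {"name", "start_res", "end_res"}
        if not required.issubset(df.columns):
            raise DataError(
                f"{annotation_path}: missing columns {sorted(required - set(df.columns))}"
            )
        for row in df.itertuples(index=False):
            parent = getattr(row, "parent", None)
            if parent is None or (isinstance(parent, float)) or parent == "" or pd.isna(parent):
                parent = None
            annotations.append(
                DomainAnnotation(
                    name=str(row.name),
                    start_res=int(row.start_res),
                    end_res=int(row.end_res),
                    parent=parent,
                )
            )
        validate_annotations(annotations, ref.codon_count)
    return ref, annotations


def write_annotations(annotations: Sequence[DomainAnnotation], path: str | Path) -> None:
    """Write the domain annotation TSV (columns name/start_res/end_res/parent)."""
    df = pd.DataFrame(
        [
            {
                "name": a.name,
                "start_res": a.start_res,
                "end_res": a.end_res,
                "parent": a.parent if a.parent is not None else "",
            }
            for a in annotations
        ],
        columns=["name", "start_res", "end_res", "parent"],
    )
    df.to_csv(path, sep="\t", index=False)
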