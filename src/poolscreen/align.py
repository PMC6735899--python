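"""Ungapped read alignment against a small amplicon reference.

The screen maps reads against a single ~4 kb ORF amplicon, keeping only
uniquely placed reads with at most one mismatch. At this reference scale
a genome aligner is unnecessary; an exact k-mer seed index with full
ungapped verification reproduces the required behaviour exactly and
deterministically.

Status semantics (made explicit because they drive downstream counting):

* placements with <=1 mismatch "survive"; if exactly one placement
  attains the minimal surviving mismatch count the read is ``unique``
  (a read with one exact placement plus extra 1-mismatch placements is
  unique at the exact locus), otherwise ``ambiguous``;
* if nothing survives but the best placement carries 2-3 mismatches the
  read is ``too_many_mismatches``;
* otherwise (best placement >3 mismatches, read shorter than the seed,
  or longer than the reference) the read is ``unmapped``.

With the default seed length k=25 and 100 nt reads, four disjoint seeds
guarantee that every placement with <=3 mismatches is found, so the
unmapped / too_many_mismatches boundary is deterministic. An N in the
read always counts as a mismatch and is never emitted as an observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import ConfigError, DataError
from .reference import OrfReference, reverse_complement

#: Placements with more mismatches than this are indistinguishable from
#: unrelated sequence and reported as unmapped.
MAX_PROBE_MISMATCHES = 3

STATUS_UNIQUE = "unique"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNMAPPED = "unmapped"
STATUS_TOO_MANY = "too_many_mismatches"
STATUSES = (STATUS_UNIQUE, STATUS_AMBIGUOUS, STATUS_UNMAPPED, STATUS_TOO_MANY)


@dataclass(frozen=True)
class MismatchObservation:
    """One coding-strand-normalized mismatch on a uniquely aligned read.

    ``orf_pos`` is the 1-based ORF nucleotide index, or ``None`` when the
    mismatch falls in flank sequence (flagged via ``region``).
    """

    orf_pos: Optional[int]
    ref_base: str
    read_base: str
    quality: int
    read_id: str
    region: str = "orf"  # "orf" or "flank"

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise DataError("mismatch observation with ref_base == read_base")
        if self.quality < 0:
            raise DataError("negative quality")


@dataclass
class AlignmentRecord:
    """Outcome of aligning one read: placement, strand and mismatches."""

    read_id: str
    status: str
    ref_start: Optional[int] = None  # 0-based on the amplicon
    strand: Optional[str] = None  # '+' or '-'
    n_mismatches: Optional[int] = None
    mismatches: list[MismatchObservation] = field(default_factory=list)


class KmerIndex:
    """Exact k-mer -> start-position map over the amplicon forward strand.

    Reads are queried in both orientations against the forward index, so
    both strands are covered without indexing the reverse complement.
    """

    def __init__(self, ref: OrfReference, k: int = 25):
        amplicon = ref.amplicon
        if k < 1:
            raise ConfigError("seed length k must be >= 1")
        if k > len(amplicon):
            raise ConfigError(f"seed length k={k} exceeds amplicon length {len(amplicon)}")
        self.ref = ref
        self.k = k
        self.amplicon = amplicon
        self._index: dict[str, list[int]] = {}
        for i in range(len(amplicon) - k + 1):
            self._index.setdefault(amplicon[i : i + k], []).append(i)

    def lookup(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])


def _count_mismatches(ref_seq: str, read: str, start: int, cap: int) -> int:
    """Mismatches of ``read`` vs ``ref_seq[start:]``, early exit past ``cap``."""
    window = ref_seq[start : start + len(read)]
    if window == read:
        return 0
    n = 0
    for a, b in zip(window, read):
        if a != b:
            n += 1
            if n > cap:
                return n
    return n


def _seed_offsets(read_len: int, k: int) -> list[int]:
    offsets = list(range(0, read_len - k + 1, k))
    tail = read_len - k
    if tail not in offsets:
        offsets.append(tail)
    return offsets


def align_read(
    index: KmerIndex, read: str, qualities: Sequence[int], read_id: str = "read"
) -> AlignmentRecord:
    """Align one read (both orientations) and extract its mismatch, if any.

    ``qualities`` are Phred scores in read order (as sequenced). The
    emitted observation is strand-normalized: bases are reported on the
    coding strand, with the quality taken from the original read position.
    """
    read = read.upper()
    rl = len(read)
    ref = index.ref
    amplicon = index.amplicon
    if rl < index.k or rl > len(amplicon):
        return AlignmentRecord(read_id, STATUS_UNMAPPED)
    if len(qualities) != rl:
        raise DataError(f"read {read_id!r}: quality length != sequence length")

    oriented = {"+": read, "-": reverse_complement(read)}
    placements: dict[tuple[int, str], int] = {}
    for strand, seq in oriented.items():
        for off in _seed_offsets(rl, index.k):
            for hit in index.lookup(seq[off : off + index.k]):
                start = hit - off
                if start < 0 or start + rl > len(amplicon):
                    continue
                key = (start, strand)
                if key not in placements:
                    placements[key] = _count_mismatches(
                        amplicon, seq, start, MAX_PROBE_MISMATCHES
                    )

    if not placements:
        return AlignmentRecord(read_id, STATUS_UNMAPPED)
    best = min(placements.values())
    if best > 1:
        if best <= MAX_PROBE_MISMATCHES:
            return AlignmentRecord(read_id, STATUS_TOO_MANY)
        return AlignmentRecord(read_id, STATUS_UNMAPPED)
    at_best = [key for key, mm in placements.items() if mm == best]
    if len(at_best) > 1:
        return AlignmentRecord(read_id, STATUS_AMBIGUOUS)

    (start, strand) = at_best[0]
    seq = oriented[strand]
    record = AlignmentRecord(
        read_id, STATUS_UNIQUE, ref_start=start, strand=strand, n_mismatches=best
    )
    if best == 1:
        j = next(i for i in range(rl) if seq[i] != amplicon[start + i])
        read_base = seq[j]
        if read_base != "N":  # N counts as a mismatch but supports no call
            qual = qualities[j] if strand == "+" else qualities[rl - 1 - j]
            orf_pos = ref.orf_pos_of_amplicon(start + j)
            record.mismatches.append(
                MismatchObservation(
                    orf_pos=orf_pos,
                    ref_base=amplicon[start + j],
                    read_base=read_base,
                    quality=int(qual),
                    read_id=read_id,
                    region="orf" if orf_pos is not None else "flank",
                )
            )
    return record


def _parse_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    n_seen = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_seen += 1
            yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]
    except ValueError as exc:
        raise DataError(
            f"{path}: malformed FASTQ near record {n_seen + 1}: {exc}"
        ) from exc


def align_batch(
    index: KmerIndex,
    fastq_path: str | Path,
    sam_path: str | Path | None = None,
    mismatch_path: str | Path | None = None,
) -> dict:
    """Stream a FASTQ through the aligner; optionally write SAM + mismatch TSV.

    Returns summary counts per status, the number of unique alignments
    carrying a mismatch, and the collected ORF mismatch observations
    (under ``"observations"``). Flank-only mismatches are counted but do
    not enter the observation list.
    """
    counts = {s: 0 for s in STATUSES}
    observations: list[MismatchObservation] = []
    n_flank_mismatches = 0
    mismatch_bearing = 0

    sam_lines: list[str] = []
    if sam_path is not None:
        sam_lines.append("@HD\tVN:1.6\tSO:unsorted")
        sam_lines.append(f"@SQ\tSN:{index.ref.id}\tLN:{len(index.amplicon)}")

    n_records = 0
    for read_id, seq, quals in _parse_fastq(fastq_path):
        n_records += 1
        rec = align_read(index, seq, quals, read_id)
        counts[rec.status] += 1
        if rec.status == STATUS_UNIQUE:
            if rec.n_mismatches:
                mismatch_bearing += 1
            for obs in rec.mismatches:
                if obs.region == "orf":
                    observations.append(obs)
                else:
                    n_flank_mismatches += 1
            if sam_path is not None:
                flag = 0 if rec.strand == "+" else 16
                out_seq = seq if rec.strand == "+" else reverse_complement(seq)
                out_qual = (
                    "".join(chr(q + 33) for q in quals)
                    if rec.strand == "+"
                    else "".join(chr(q + 33) for q in reversed(quals))
                )
                sam_lines.append(
                    f"{read_id}\t{flag}\t{index.ref.id}\t{rec.ref_start + 1}\t255\t"
                    f"{len(seq)}M\t*\t0\t0\t{out_seq}\t{out_qual}\tNM:i:{rec.n_mismatches}"
                )

    if sam_path is not None:
        Path(sam_path).write_text("\n".join(sam_lines) + "\n")
    if mismatch_path is not None:
        write_mismatch_table(observations, mismatch_path)

    unique = counts[STATUS_UNIQUE]
    return {
        **counts,
        "total": n_records,
        "mismatch_bearing_unique": mismatch_bearing,
        "mismatch_bearing_fraction": (mismatch_bearing / unique) if unique else 0.0,
        "flank_mismatches": n_flank_mismatches,
        "observations": observations,
    }


def write_mismatch_table(
    observations: Sequence[MismatchObservation], path: str | Path
) -> None:
    """Native mismatch TSV: orf_pos / ref_base / read_base / quality / read_id."""
    lines = ["orf_pos\tref_base\tread_base\tquality\tread_id"]
    for o in observations:
        lines.append(f"{o.orf_pos}\t{o.ref_base}\t{o.read_base}\t{o.quality}\t{o.read_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mismatch_table(path: str | Path) -> list[MismatchObservation]:
    """Read the native mismatch TSV back into observations."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "orf_pos\tref_base\tread_base\tquality\tread_id":
        raise DataError(f"{path}: not a mismatch table")
    out = []
    for ln in lines[1:]:
        pos_s, ref_b, read_b, q_s, rid = ln.split("\t")
        out.append(
            MismatchObservation(
                orf_pos=int(pos_s), ref_base=ref_b, read_base=read_b,
                quality=int(q_s), read_id=rid,
            )
        )
    return out
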