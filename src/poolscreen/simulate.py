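"""Synthetic mutagenized plasmid pools and Illumina-like reads.

Emulates the screen's library: plasmid-borne ORFs carrying predominantly
GC→AT transitions after hydroxylamine treatment, pooled at uneven colony
abundances, fragmented to 200–500 nt, and sequenced as single-end reads
with per-base Phred qualities. When the error channel is on, each base
miscalls with probability 10^(-Q/10) for its drawn quality — so the
downstream Q≥38 filter confronts exactly the error process it models.

Everything is reproducible: identical config + seed gives byte-identical
FASTQ and truth-table output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .reference import OrfReference, substitution_from_mismatch

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
# complement in code space: A<->T is 0<->3, C<->G is 1<->2
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class MutagenesisConfig:
    """Hydroxylamine-like mutagenesis parameters.

    ``mean_mutations_per_plasmid`` is the Poisson mean of induced changes
    per plasmid; ``gc_to_at_fraction`` is the probability that an induced
    change is a C→T or G→A transition on the coding strand.
    """

    mean_mutations_per_plasmid: float = 1.5
    gc_to_at_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_mutations_per_plasmid < 0:
            raise ConfigError("mean_mutations_per_plasmid must be >= 0")
        if not 0.0 <= self.gc_to_at_fraction <= 1.0:
            raise ConfigError("gc_to_at_fraction must lie in [0, 1]")


@dataclass
class MutantAllele:
    """One plasmid variant in the pool.

    ``substitutions`` are (orf_pos, ref_base, alt_base) triples with
    unique positions; ``abundance`` is the relative colony weight and
    ``truth_phenotype`` the ground-truth label used by selection.
    """

    allele_id: str
    substitutions: tuple[tuple[int, str, str], ...] = ()
    abundance: float = 1.0
    truth_phenotype: str = "sensitive"

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise DataError(f"allele {self.allele_id!r}: duplicate substitution positions")
        if self.abundance <= 0:
            raise DataError(f"allele {self.allele_id!r}: abundance must be positive")

    def validate_against(self, ref: OrfReference) -> None:
        for pos, ref_base, alt_base in self.substitutions:
            if ref.base(pos) != ref_base:
                raise DataError(
                    f"allele {self.allele_id!r}: ref base at ORF pos {pos} is "
                    f"{ref.base(pos)}, not {ref_base}"
                )
            if ref_base == alt_base:
                raise DataError(f"allele {self.allele_id!r}: ref == alt at pos {pos}")


@dataclass(frozen=True)
class QualityModel:
    """Discrete per-base Phred quality distribution (i.i.d. across positions)."""

    qualities: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.probs) or not self.qualities:
            raise ConfigError("qualities and probs must be equal-length, non-empty")
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ConfigError("Phred qualities must lie in 0..60")
        if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
            raise ConfigError("probs must be non-negative and sum to 1")

    @classmethod
    def constant(cls, q: int) -> "QualityModel":
        return cls((q,), (1.0,))

    @classmethod
    def hiseq(cls) -> "QualityModel":
        """Default HiSeq-like mixture: mostly Q40/Q38 with a low-quality tail."""
        return cls((40, 38, 35, 20), (0.70, 0.15, 0.10, 0.05))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        qs = np.array(self.qualities, dtype=np.int64)
        return qs[rng.choice(len(qs), size=size, p=np.array(self.probs))]

    def mean_error_prob(self) -> float:
        """E[10^(-Q/10)] under the distribution."""
        return float(sum(p * 10 ** (-q / 10) for q, p in zip(self.qualities, self.probs)))

    def mean_kept_error_prob(self, min_quality: int) -> float:
        """E[10^(-Q/10) · 1(Q >= min_quality)]."""
        return float(
            sum(
                p * 10 ** (-q / 10)
                for q, p in zip(self.qualities, self.probs)
                if q >= min_quality
            )
        )


@dataclass(frozen=True)
class ReadSimConfig:
    """Single-end read simulation parameters.

    Fragments are drawn uniformly in ``[fragment_min, fragment_max]`` nt
    (the library's 200–500 nt size selection); the read is the first
    ``read_length`` bases of a uniformly chosen strand of the fragment.
    With ``error_coupling`` on, each base miscalls to a uniformly random
    other base with probability 10^(-Q/10).
    """

    n_reads: int
    read_length: int = 100
    fragment_min: int = 200
    fragment_max: int = 500
    quality_model: QualityModel = field(default_factory=QualityModel.hiseq)
    error_coupling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")
        if self.fragment_min > self.fragment_max:
            raise ConfigError("fragment_min must be <= fragment_max")
        if self.read_length > self.fragment_min:
            raise ConfigError("read_length must be <= fragment_min")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")


def mutagenize(
    ref: OrfReference,
    cfg: MutagenesisConfig,
    n_alleles: int,
    abundance_model: str = "lognormal",
    abundance_sigma: float = 1.0,
) -> list[MutantAllele]:
    """Draw a pool of mutagenized alleles.

    Per allele, the number of induced changes is Poisson distributed. A
    change is, with probability ``gc_to_at_fraction``, a forced C→T/G→A
    transition at a uniformly drawn C/G site; otherwise a uniformly drawn
    site receives a uniformly drawn alternative base other than the
    C→T/G→A outcome, so the realized GC→AT fraction matches the
    configured one exactly in expectation. Colony abundances are
    log-normal (``sigma=abundance_sigma``) by default, or uniform.
    """
    if n_alleles < 1:
        raise ConfigError("n_alleles must be >= 1")
    if abundance_model not in ("lognormal", "uniform"):
        raise ConfigError(f"unknown abundance model {abundance_model!r}")
    rng = np.random.default_rng(cfg.seed)
    seq = ref.seq
    gc_positions = [i + 1 for i, b in enumerate(seq) if b in "CG"]
    if not gc_positions and cfg.gc_to_at_fraction > 0:
        raise DataError("reference has no C/G sites but gc_to_at_fraction > 0")
    n_digits = len(str(n_alleles))
    alleles = []
    for i in range(n_alleles):
        k = rng.poisson(cfg.mean_mutations_per_plasmid)
        subs: dict[int, tuple[int, str, str]] = {}
        guard = 0
        while len(subs) < k:
            guard += 1
            if guard > 1000 * (k + 1):
                raise DataError("could not place requested mutations at unique sites")
            if rng.random() < cfg.gc_to_at_fraction:
                pos = int(gc_positions[rng.integers(len(gc_positions))])
                ref_base = seq[pos - 1]
                alt = "T" if ref_base == "C" else "A"
            else:
                pos = int(rng.integers(1, len(seq) + 1))
                ref_base = seq[pos - 1]
                choices = [b for b in "ACGT" if b != ref_base]
                # exclude the hydroxylamine transition so the spectrum
                # fraction is exactly the configured branch probability
                if ref_base == "C":
                    choices.remove("T")
                elif ref_base == "G":
                    choices.remove("A")
                alt = choices[rng.integers(len(choices))]
            if pos not in subs:
                subs[pos] = (pos, ref_base, alt)
        if abundance_model == "lognormal":
            abundance = float(rng.lognormal(0.0, abundance_sigma))
        else:
            abundance = 1.0
        alleles.append(
            MutantAllele(
                allele_id=f"allele_{i:0{n_digits}d}",
                substitutions=tuple(subs[p] for p in sorted(subs)),
                abundance=abundance,
            )
        )
    return alleles


def apply_selection(
    alleles: Sequence[MutantAllele],
    phenotype_map: Mapping[tuple[int, str], str],
    survival_labels: Iterable[str],
    escape_fraction: float = 0.0,
    seed: int = 0,
) -> list[MutantAllele]:
    """Assign truth phenotypes and keep alleles surviving drug selection.

    ``phenotype_map`` maps ground-truth nucleotide changes
    ``(orf_pos, alt_base)`` to phenotype labels; an allele with no listed
    change is labelled ``sensitive``. If an allele carries several listed
    changes, the label of the lowest-position one is used. Non-surviving
    alleles escape selection (plating noise) with ``escape_fraction``.
    """
    survival = set(survival_labels)
    known_labels = set(phenotype_map.values()) | {"sensitive"}
    unknown = survival - known_labels
    if unknown:
        raise ConfigError(f"unknown survival label(s) {sorted(unknown)}")
    if not 0.0 <= escape_fraction <= 1.0:
        raise ConfigError("escape_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    survivors = []
    for allele in alleles:
        label = "sensitive"
        for pos, _, alt in allele.substitutions:
            hit = phenotype_map.get((pos, alt))
            if hit is not None:
                label = hit
                break
        labelled = MutantAllele(
            allele_id=allele.allele_id,
            substitutions=allele.substitutions,
            abundance=allele.abundance,
            truth_phenotype=label,
        )
        if label in survival or (escape_fraction > 0 and rng.random() < escape_fraction):
            survivors.append(labelled)
    if not survivors:
        warnings.warn("selection left an empty pool", stacklevel=2)
    return survivors


def _mutant_amplicon(ref: OrfReference, allele: MutantAllele) -> np.ndarray:
    codes = _encode(ref.amplicon).copy()
    off = ref.orf_offset
    for pos, _, alt in allele.substitutions:
        codes[off + pos - 1] = _CODE[ord(alt)]
    return codes


def simulate_reads(
    ref: OrfReference,
    alleles: Sequence[MutantAllele],
    cfg: ReadSimConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> dict:
    """Simulate single-end reads from the pool; write FASTQ and truth table.

    Reads are drawn from alleles proportional to abundance; fragment
    starts are uniform over the amplicon. Returns a summary with status
    counts and the realized per-mutation read coverage (reads drawn from
    a carrying allele whose read interval overlaps the mutated site).
    """
    if not alleles:
        raise DataError("cannot simulate reads from an empty pool")
    for allele in alleles:
        allele.validate_against(ref)
    amplicon_len = len(ref.amplicon)
    if cfg.read_length > amplicon_len:
        raise ConfigError("read_length exceeds amplicon length")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    rl = cfg.read_length

    abundances = np.array([a.abundance for a in alleles], dtype=float)
    p = abundances / abundances.sum()
    allele_idx = rng.choice(len(alleles), size=n, p=p)

    frag_len = rng.integers(cfg.fragment_min, cfg.fragment_max + 1, size=n)
    frag_len = np.maximum(np.minimum(frag_len, amplicon_len), rl)
    start = (rng.random(n) * (amplicon_len - frag_len + 1)).astype(np.int64)
    strand = rng.integers(0, 2, size=n)  # 0 = '+', 1 = '-'

    # read source interval on the amplicon (coding strand coordinates)
    src_start = np.where(strand == 0, start, start + frag_len - rl)

    amplicons = [_mutant_amplicon(ref, a) for a in alleles]
    reads = np.empty((n, rl), dtype=np.uint8)
    for i in range(n):
        window = amplicons[allele_idx[i]][src_start[i] : src_start[i] + rl]
        if strand[i] == 0:
            reads[i] = window
        else:
            reads[i] = _COMP[window[::-1]]

    quals = cfg.quality_model.sample(rng, n * rl).reshape(n, rl)
    n_errors = 0
    if cfg.error_coupling:
        err = rng.random((n, rl)) < 10.0 ** (-quals / 10.0)
        n_errors = int(err.sum())
        if n_errors:
            shift = rng.integers(1, 4, size=n_errors).astype(np.uint8)
            flat = reads.reshape(-1)
            idx = np.flatnonzero(err.reshape(-1))
            flat[idx] = (flat[idx] + shift) % 4

    qual_chars = (quals + 33).astype(np.uint8)
    n_digits = len(str(n - 1)) if n > 1 else 1
    lines = []
    for i in range(n):
        lines.append(f"@read_{i:0{n_digits}d}")
        lines.append(_decode(reads[i]))
        lines.append("+")
        lines.append(qual_chars[i].tobytes().decode())
    Path(fastq_path).write_text("\n".join(lines) + "\n")

    # realized coverage per (orf_pos, alt_base), summed over carrying alleles
    coverage: dict[tuple[int, str], int] = {}
    off = ref.orf_offset
    for ai, allele in enumerate(alleles):
        if not allele.substitutions:
            continue
        mask = allele_idx == ai
        if not mask.any():
            continue
        s, e = src_start[mask], src_start[mask] + rl
        for pos, _, alt in allele.substitutions:
            ap = off + pos - 1
            cov = int(((s <= ap) & (ap < e)).sum())
            coverage[(pos, alt)] = coverage.get((pos, alt), 0) + cov

    if truth_path is not None:
        write_truth_table(ref, alleles, truth_path)

    return {
        "n_reads": n,
        "n_alleles": len(alleles),
        "n_sequencing_errors": n_errors,
        "per_mutation_coverage": coverage,
    }


def write_truth_table(
    ref: OrfReference, alleles: Sequence[MutantAllele], path: str | Path
) -> None:
    """Write the ground-truth table (one row per allele substitution)."""
    header = "allele_id\torf_pos\tref_base\talt_base\tref_aa\tresidue\talt_aa\tabundance"
    rows = [header]
    for allele in alleles:
        for pos, ref_base, alt in allele.substitutions:
            sub = substitution_from_mismatch(ref, pos, alt)
            rows.append(
                f"{allele.allele_id}\t{pos}\t{ref_base}\t{alt}\t"
                f"{sub.ref_aa}\t{sub.residue}\t{sub.alt_aa}\t{allele.abundance:.6g}"
            )
    Path(path).write_text("\n".join(rows) + "\n")


def spiked_pool(
    ref: OrfReference,
    spikes: Sequence[tuple[int, str]],
    n_alleles: int,
    abundance_sigma: float = 1.0,
    seed: int = 0,
) -> list[MutantAllele]:
    """Build a pool of ``n_alleles`` single-mutant alleles carrying the
    given (orf_pos, alt_base) spikes, cycled so every spike is carried by
    roughly equally many alleles; abundances are log-normal.
    """
    if not spikes:
        raise ConfigError("at least one spike is required")
    rng = np.random.default_rng(seed)
    n_digits = len(str(n_alleles))
    alleles = []
    for i in range(n_alleles):
        pos, alt = spikes[i % len(spikes)]
        alleles.append(
            MutantAllele(
                allele_id=f"allele_{i:0{n_digits}d}",
                substitutions=((pos, ref.base(pos), alt),),
                abundance=float(rng.lognormal(0.0, abundance_sigma)),
            )
        )
    return alleles


def draw_spikes(
    ref: OrfReference,
    n_spikes: int,
    gc_to_at_fraction: float = 0.9,
    seed: int = 0,
    residue_min: int = 2,
    residue_max: Optional[int] = None,
    exclude_synonymous: bool = True,
) -> list[tuple[int, str]]:
    """Draw distinct ground-truth substitutions with the mutagen's spectrum.

    Restricted to residues ``residue_min..residue_max`` and (by default)
    non-synonymous changes, so each spike is visible as an amino-acid call.
    """
    rng = np.random.default_rng(seed)
    residue_max = residue_max if residue_max is not None else ref.codon_count - 1
    lo, hi = 3 * (residue_min - 1) + 1, 3 * residue_max
    gc_positions = [p for p in range(lo, hi + 1) if ref.base(p) in "CG"]
    spikes: list[tuple[int, str]] = []
    seen_pos: set[int] = set()
    guard = 0
    while len(spikes) < n_spikes:
        guard += 1
        if guard > 10000:
            raise DataError("could not draw the requested number of spikes")
        if rng.random() < gc_to_at_fraction:
            pos = int(gc_positions[rng.integers(len(gc_positions))])
            alt = "T" if ref.base(pos) == "C" else "A"
        else:
            pos = int(rng.integers(lo, hi + 1))
            choices = [b for b in "ACGT" if b != ref.base(pos)]
            if ref.base(pos) == "C":
                choices.remove("T")
            elif ref.base(pos) == "G":
                choices.remove("A")
            alt = choices[rng.integers(len(choices))]
        if pos in seen_pos:
            continue
        if exclude_synonymous and substitution_from_mismatch(ref, pos, alt).synonymous:
            continue
        seen_pos.add(pos)
        spikes.append((pos, alt))
    return spikes
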